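"""Statistical-parsimony haplotype networks.

Haplotypes whose mutational distance does not exceed a connection limit are
joined into networks; within each network only the connections of a minimum
spanning network (all co-minimal ties retained) are kept, and a retained
k-step connection is expanded through k-1 inferred intermediate nodes, so
every drawn edge spans exactly one mutational step. The most frequent
haplotype of each network is its dominant node.

The connection limit is either supplied (``fixed_limit``) or estimated as the
largest step count j for which the probability that all j observed
differences are single mutational hits — under a Jukes-Cantor correction of
the observed mean divergence — still meets the requested parsimony
probability (0.95 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

from .distances import DistanceMatrix
from .sequences import HaplotypeAssignment, SequenceAlignment, pairwise_step_matrix


@dataclass
class NetworkConfig:
    parsimony_probability: float = 0.95
    fixed_limit: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.parsimony_probability < 1.0):
            raise ValueError("parsimony_probability must be in (0, 1)")
        if self.fixed_limit is not None and self.fixed_limit < 1:
            raise ValueError("fixed_limit must be >= 1")


@dataclass
class HaplotypeNetwork:
    """Graph of observed haplotypes plus inferred single-step intermediates.

    Node attributes: ``frequency`` (0 for inferred nodes), ``is_inferred``,
    ``is_dominant``, ``component`` (N1, N2, ... by decreasing total sample
    frequency) and ``subnetwork`` ('' until :func:`group_branches` labels it).
    """

    graph: nx.Graph
    components: list[str]  # component labels, N1 first

    def nodes_in(self, component: str) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["component"] == component]

    def observed_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if not d["is_inferred"]]

    def dominant_of(self, component: str) -> str:
        for n in self.nodes_in(component):
            if self.graph.nodes[n]["is_dominant"]:
                return n
        raise KeyError(component)

    def is_unique(self, component: str) -> bool:
        """A singleton ('unique') network: one observed haplotype, no edges."""
        members = self.nodes_in(component)
        return len(members) == 1


def _single_hit_probability(p: float) -> float:
    """P(site changed exactly once | site differs) under Jukes-Cantor.

    With per-site substitution count Poisson(lam), lam from the JC correction
    of the mean pairwise divergence p.
    """
    if p <= 0.0:
        return 1.0
    if p >= 0.74999:
        return 0.0
    lam = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
    p_differ = 0.75 * (1.0 - math.exp(-4.0 * lam / 3.0))
    return lam * math.exp(-lam) / p_differ


def connection_limit(aln: SequenceAlignment, cfg: NetworkConfig | None = None) -> int:
    """Largest step count connected with at least the parsimony probability.

    The probability that a pair differing at j sites is parsimoniously
    connected is modelled as r**j, with r the single-hit probability at the
    observed mean pairwise divergence. Always >= 1; capped at the alignment
    length.
    """
    cfg = cfg or NetworkConfig()
    if cfg.fixed_limit is not None:
        return cfg.fixed_limit
    steps = pairwise_step_matrix(aln)
    tri = steps.lower_triangle()
    p = float(tri.mean()) / aln.length if tri.size else 0.0
    r = _single_hit_probability(p)
    if r >= 1.0:
        return aln.length
    if r <= 0.0:
        return 1
    j = int(math.floor(math.log(cfg.parsimony_probability) / math.log(r)))
    return max(1, min(j, aln.length))


def build_networks(
    steps: DistanceMatrix, assign: HaplotypeAssignment, j_max: int
) -> HaplotypeNetwork:
    """Minimum spanning networks over haplotype pairs within the step limit.

    Connected components of the <= j_max graph are built independently; inside
    each, edges are retained Kruskal-style keeping every tie at the minimal
    weight, then each k-step edge is expanded through k-1 inferred nodes.
    """
    if steps.units != "steps":
        raise ValueError("build_networks requires a step-count matrix")
    labels = assign.labels()
    if not labels:
        raise ValueError("empty haplotype assignment")
    if set(labels) - set(steps.ids):
        raise ValueError("step matrix does not cover all haplotypes")
    index = {h: i for i, h in enumerate(labels)}

    cand = nx.Graph()
    cand.add_nodes_from(labels)
    for i, hi in enumerate(labels):
        for hj in labels[i + 1 :]:
            d = steps.values[steps.index_of(hi), steps.index_of(hj)]
            if d <= j_max:
                cand.add_edge(hi, hj, weight=float(d))

    g = nx.Graph()
    comp_info = []  # (total_freq, lowest_index, member set)
    for members in nx.connected_components(cand):
        members = set(members)
        sub = cand.subgraph(members)
        retained = _min_spanning_network(sub)
        total = sum(assign.frequencies[h] for h in members)
        dominant = min(members, key=lambda h: (-assign.frequencies[h], index[h]))
        comp_info.append((total, min(index[h] for h in members), members, retained, dominant))

    comp_info.sort(key=lambda t: (-t[0], t[1]))
    comp_labels = []
    for k, (_total, _low, members, retained, dominant) in enumerate(comp_info, start=1):
        label = f"N{k}"
        comp_labels.append(label)
        for h in sorted(members, key=index.get):
            g.add_node(
                h,
                frequency=assign.frequencies[h],
                is_inferred=False,
                is_dominant=(h == dominant),
                component=label,
                subnetwork="",
            )
        for u, v, w in retained:
            k_steps = int(round(w))
            chain = [u]
            for s in range(1, k_steps):
                mid = f"{u}~{v}.{s}"
                g.add_node(
                    mid,
                    frequency=0,
                    is_inferred=True,
                    is_dominant=False,
                    component=label,
                    subnetwork="",
                )
                chain.append(mid)
            chain.append(v)
            for a, b in zip(chain, chain[1:]):
                g.add_edge(a, b, steps=1)
    return HaplotypeNetwork(g, comp_labels)


def _min_spanning_network(sub: nx.Graph) -> list[tuple[str, str, float]]:
    """Kruskal grouped by weight, keeping all ties that join distinct parts."""
    parent = {n: n for n in sub.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = sorted(sub.edges(data="weight"), key=lambda e: e[2])
    retained = []
    i = 0
    while i < len(edges):
        w = edges[i][2]
        group = []
        while i < len(edges) and edges[i][2] == w:
            group.append(edges[i])
            i += 1
        # decide against the partition as it stood before this weight class
        roots_before = {n: find(n) for n in sub.nodes}
        keep = [e for e in group if roots_before[e[0]] != roots_before[e[1]]]
        retained.extend(keep)
        for u, v, _ in keep:
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[ru] = rv
    return retained


def group_branches(net: HaplotypeNetwork, min_branch_size: int = 3) -> dict[str, str]:
    """Label branches hanging off each dominant node as subnetworks.

    Removing the dominant node splits its component into branches; every
    branch holding at least ``min_branch_size`` observed haplotypes gets a
    label (N1-A, N1-B, ... by decreasing observed size). Returns the node ->
    label map and records it in the graph's ``subnetwork`` attributes.
    """
    if not net.components:
        raise ValueError("network has no components")
    labels: dict[str, str] = {}
    for comp in net.components:
        members = set(net.nodes_in(comp))
        if len(members) <= 1:
            continue
        dom = net.dominant_of(comp)
        sub = net.graph.subgraph(members - {dom})
        branches = []
        for piece in nx.connected_components(sub):
            observed = [n for n in piece if not net.graph.nodes[n]["is_inferred"]]
            if len(observed) >= min_branch_size:
                branches.append((len(observed), sorted(piece)[0], piece))
        branches.sort(key=lambda t: (-t[0], t[1]))
        for rank, (_size, _anchor, piece) in enumerate(branches):
            tag = f"{comp}-{chr(ord('A') + rank)}"
            for n in piece:
                labels[n] = tag
                net.graph.nodes[n]["subnetwork"] = tag
    return labels


# ---- I/O --------------------------------------------------------------------


def export_network(net: HaplotypeNetwork, nodes_path, edges_path) -> None:
    """Deterministic TSV node table and edge list."""
    with open(nodes_path, "w") as fh:
        fh.write("id\tfrequency\tcomponent\tsubnetwork\tis_dominant\tis_inferred\n")
        for n in sorted(net.graph.nodes):
            d = net.graph.nodes[n]
            fh.write(
                f"{n}\t{d['frequency']}\t{d['component']}\t{d['subnetwork']}\t"
                f"{int(d['is_dominant'])}\t{int(d['is_inferred'])}\n"
            )
    with open(edges_path, "w") as fh:
        fh.write("source\ttarget\n")
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{u}\t{v}\n")


def load_network(nodes_path, edges_path) -> HaplotypeNetwork:
    g = nx.Graph()
    comps: dict[str, int] = {}
    with open(nodes_path) as fh:
        header = fh.readline()
        for line in fh:
            nid, freq, comp, subnet, dom, inf = line.rstrip("\n").split("\t")
            g.add_node(
                nid,
                frequency=int(freq),
                component=comp,
                subnetwork=subnet,
                is_dominant=bool(int(dom)),
                is_inferred=bool(int(inf)),
            )
            comps[comp] = comps.get(comp, 0) + int(freq)
    with open(edges_path) as fh:
        fh.readline()
        for line in fh:
            u, v = line.rstrip("\n").split("\t")
            g.add_edge(u, v, steps=1)
    order = sorted(comps, key=lambda c: int(c[1:]))
    return HaplotypeNetwork(g, order)
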