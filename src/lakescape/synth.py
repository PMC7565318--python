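"""Synthetic lake scenarios: DEM, shoreline sites, landscape partitions and
haplotype alignments with controlled population structure.

The generator emulates a boreal lake of roughly 4 x 2 km fed by two inflow
creeks, drained by one outflow, and carrying one semi-enclosed bay, with ~34
shoreline collection sites of 3 replicates each and ~600 bp haploid marker
alignments. Sequence structure follows a private-site mutation model: every
population centroid carries Poisson(m_b) substitutions at sites used by no
other population, and every individual carries Poisson(m_w) further private
substitutions. Because mutated sites never collide, the mutational step
distance is exactly additive: E[steps] = 2*m_w within a population and
2*m_b + 2*m_w between populations, which makes the generator's expectations
closed-form for testing.

All outputs are byte-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .hydro import DemGrid, SampleSites, ShorelineRing, extract_shoreline
from .popstats import PopulationPartition
from .sequences import SequenceAlignment

#: reference lake water level (metres) used for shoreline extraction
WATER_LEVEL = 20.0

SCENARIOS = ("hydrology", "wind", "in_out_bay", "bay_topography", "panmixia", "ibd")
_BASES = "ACGT"


@dataclass
class SyntheticScenario:
    scenario: str = "hydrology"
    L: int = 607
    n_sites: int = 34
    replicates_per_site: int = 3
    m_b: float = 0.05  # mean private substitutions per population centroid
    m_w: float = 0.8  # mean private substitutions per individual
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; one of {SCENARIOS}")
        if self.L < 50:
            raise ValueError("alignment length must be >= 50")
        if self.m_b < 0 or self.m_w < 0:
            raise ValueError("mutation means must be >= 0")


# ---- lake geometry -------------------------------------------------------------


def _geometry(nrows: int, ncols: int, cellsize: float) -> dict:
    """Lake layout as fractions of the domain, in planar metres."""
    W, H = ncols * cellsize, nrows * cellsize
    g = {
        "W": W,
        "H": H,
        "cx": 0.5 * W,
        "cy": 0.557 * H,
        "a": 0.346 * W,  # ellipse semi-axis, east-west
        "b": 0.271 * H,  # ellipse semi-axis, north-south
        "bay_cx": 0.596 * W,
        "bay_cy": 0.15 * H,
        "bay_r": 0.10 * H,
        "chan_halfw": 1.5 * cellsize,
        "twin_x": 0.385 * W,  # northern inflow creek
        "band_halfw": 1.5 * cellsize,  # creek/outflow valley half width
    }
    return g


def _lake_mask_fn(g: dict):
    def inside(x, y):
        ell = ((x - g["cx"]) / g["a"]) ** 2 + ((y - g["cy"]) / g["b"]) ** 2 <= 1.0
        bay = (x - g["bay_cx"]) ** 2 + (y - g["bay_cy"]) ** 2 <= g["bay_r"] ** 2
        chan = (np.abs(x - g["bay_cx"]) <= g["chan_halfw"]) & (y >= g["bay_cy"]) & (y <= g["cy"])
        return ell | bay | chan

    return inside


def make_lake_dem(
    nrows: int = 140, ncols: int = 260, cellsize: float = 20.0, seed: int = 0
) -> DemGrid:
    """Deterministic lake basin DEM.

    One submerged region at :data:`WATER_LEVEL` (elliptical main basin plus a
    semi-enclosed bay joined by a narrow channel), two inflow valleys (east
    creek and north creek) descending into the lake, and one outflow valley
    descending from the west shore to the grid edge — the unique low exit, so
    the whole basin drains through it after sink filling.
    """
    g = _geometry(nrows, ncols, cellsize)
    if g["cx"] - g["a"] <= 3 * cellsize or g["bay_cy"] - g["bay_r"] <= 2 * cellsize:
        raise ValueError("grid too small: lake would touch the edge")
    rng = np.random.default_rng(seed)
    cols, rows = np.meshgrid(np.arange(ncols), np.arange(nrows))
    x = (cols + 0.5) * cellsize
    y = (nrows - rows - 0.5) * cellsize
    lake = _lake_mask_fn(g)(x, y)

    # rising terrain away from the lake
    d_out = ndimage.distance_transform_edt(~lake) * cellsize
    z = 21.5 + 0.004 * d_out + rng.uniform(0.0, 0.3, size=(nrows, ncols))

    # lake bathymetry: deeper toward the middle, always below the water level
    d_in = ndimage.distance_transform_edt(lake) * cellsize
    z_lake = WATER_LEVEL - 1.5 - np.minimum(6.0, 0.01 * d_in)
    z = np.where(lake, z_lake + rng.uniform(0.0, 0.2, size=(nrows, ncols)), z)

    # valleys get a V cross-section (+0.02 m per metre off the centre line) so
    # each carries a single stream thread
    cross_w = 0.02 * np.abs(y - g["cy"])
    band = np.abs(y - g["cy"]) <= g["band_halfw"]
    # outflow valley: west shore (20.6 m) descending to the west edge (20.01 m)
    x_shore_w = g["cx"] - g["a"]
    sel = band & (x <= x_shore_w) & ~lake
    z[sel] = (20.01 + 0.59 * (x / x_shore_w) + cross_w)[sel]
    # east inflow creek: rises from the east shore (21.0 m) to the edge (26 m)
    x_shore_e = g["cx"] + g["a"]
    sel = band & (x >= x_shore_e) & ~lake
    z[sel] = np.minimum(
        z, 21.0 + 5.0 * (x - x_shore_e) / max(g["W"] - x_shore_e, 1.0) + cross_w
    )[sel]
    # north inflow creek
    dxn = (g["twin_x"] - g["cx"]) / g["a"]
    y_shore_n = g["cy"] + g["b"] * math.sqrt(max(1.0 - dxn**2, 0.0))
    cross_n = 0.02 * np.abs(x - g["twin_x"])
    sel = (np.abs(x - g["twin_x"]) <= g["band_halfw"]) & (y >= y_shore_n) & ~lake
    z[sel] = np.minimum(
        z, 21.0 + 5.0 * (y - y_shore_n) / max(g["H"] - y_shore_n, 1.0) + cross_n
    )[sel]

    return DemGrid(z, cellsize)


def place_sites(
    ring: ShorelineRing, n_sites: int = 34, min_spacing: float = 25.0, seed: int = 0
) -> SampleSites:
    """Shoreline sites at jittered regular arc spacing, >= min_spacing apart.

    The returned sites carry their shoreline arc positions (snap_kind
    'shoreline'), since they are generated exactly on the ring.
    """
    P = ring.perimeter
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if n_sites * min_spacing >= P:
        raise ValueError(
            f"cannot place {n_sites} sites {min_spacing} m apart on a {P:.0f} m shoreline"
        )
    rng = np.random.default_rng(seed)
    base = P / n_sites
    jitter = 0.4 * (base - min_spacing)
    offset = rng.uniform(0.0, P)
    arcs = np.array(
        [(offset + i * base + rng.uniform(-jitter, jitter)) % P for i in range(n_sites)]
    )
    order = np.argsort(arcs)
    arcs = arcs[order]
    coords = np.array([ring.point_at(s) for s in arcs])
    ids = [f"S{i + 1:02d}" for i in range(n_sites)]
    return SampleSites(
        ids,
        coords,
        snap_kind="shoreline",
        snap_xy=coords.copy(),
        snap_dist=np.zeros(n_sites),
        snap_arc=arcs,
    )


# ---- landscape partitions ------------------------------------------------------


def assign_partitions(sites: SampleSites, dem: DemGrid) -> dict[str, PopulationPartition]:
    """The four landscape hypotheses as site partitions.

    Returns {'in_out_bay' (K=3), 'bay_topography' (K=5), 'hydrology' (K=4),
    'wind' (K=4)}; every site is assigned exactly once per hypothesis, by
    geometric region (inflow caps, outflow cap, bay, central wind band,
    middle).
    """
    g = _geometry(dem.nrows, dem.ncols, dem.cellsize)
    xmax, ymax = g["W"], g["H"]
    regions: dict[str, str] = {}
    for sid, (x, y) in zip(sites.ids, sites.coords):
        if not (0 <= x <= xmax and 0 <= y <= ymax):
            raise ValueError(f"site {sid} at ({x:.0f}, {y:.0f}) lies outside the grid")
        in_bay = (
            (x - g["bay_cx"]) ** 2 + (y - g["bay_cy"]) ** 2
            <= (g["bay_r"] + 2 * dem.cellsize) ** 2
        ) or (
            abs(x - g["bay_cx"]) <= g["chan_halfw"] + 2 * dem.cellsize
            and y <= g["cy"] - 0.9 * g["b"]
        )
        if in_bay:
            regions[sid] = "bay"
        elif x <= g["cx"] - 0.85 * g["a"]:
            regions[sid] = "outflow"
        elif x >= g["cx"] + 0.85 * g["a"]:
            regions[sid] = "mistik"
        elif y >= g["cy"] + 0.55 * g["b"] and abs(x - g["twin_x"]) <= 0.12 * g["W"]:
            regions[sid] = "twin"
        else:
            regions[sid] = "middle"

    anchors = {
        "outflow": (g["cx"] - g["a"], g["cy"]),
        "mistik": (g["cx"] + g["a"], g["cy"]),
        "twin": (g["twin_x"], g["cy"] + g["b"]),
    }

    def nearest_anchor(x, y):
        return min(anchors, key=lambda k: (x - anchors[k][0]) ** 2 + (y - anchors[k][1]) ** 2)

    hydrology, bay_topo, in_out, wind = {}, {}, {}, {}
    for sid, (x, y) in zip(sites.ids, sites.coords):
        reg = regions[sid]
        hydrology[sid] = "middle" if reg in ("middle", "bay") else reg
        bay_topo[sid] = reg
        if reg == "bay":
            in_out[sid] = "bay"
        else:
            in_out[sid] = "outflow" if x < g["cx"] else "inflow"
        if reg in ("outflow", "mistik", "twin"):
            wind[sid] = reg
        elif abs(y - g["cy"]) <= 0.75 * g["b"]:
            wind[sid] = "wind"
        else:
            wind[sid] = nearest_anchor(x, y)

    parts = {
        "in_out_bay": PopulationPartition("In-Out-Bay", in_out),
        "bay_topography": PopulationPartition("Bay Topography", bay_topo),
        "hydrology": PopulationPartition("Hydrology", hydrology),
        "wind": PopulationPartition("Wind", wind),
    }
    return parts


def expand_partition(part: PopulationPartition, replicates: int) -> PopulationPartition:
    """Site-level partition -> sample-level (site x replicate) partition."""
    pop_of = {
        f"{sid}r{k}": pop
        for sid, pop in part.pop_of.items()
        for k in range(1, replicates + 1)
    }
    return PopulationPartition(part.name, pop_of)


# ---- sequence simulation -------------------------------------------------------


class _SitePool:
    """Disjoint mutation sites drawn from a seeded permutation of 0..L-1."""

    def __init__(self, L: int, rng: np.random.Generator):
        self._order = rng.permutation(L)
        self._ptr = 0

    def take(self, k: int) -> np.ndarray:
        if self._ptr + k > len(self._order):
            raise ValueError(
                "alignment too short to host the requested mutations without collision"
            )
        out = self._order[self._ptr : self._ptr + k]
        self._ptr += k
        return out


def _mutate(seq: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    out[positions] = (out[positions] + rng.integers(1, 4, size=len(positions))) % 4
    return out


def simulate_haplotypes(
    sites: SampleSites, partition: PopulationPartition, scn: SyntheticScenario
) -> SequenceAlignment:
    """Private-site mutation model over site x replicate samples.

    Population centroids carry Poisson(m_b) substitutions at population-unique
    sites (m_b forced to 0 under panmixia); individuals add Poisson(m_w)
    private substitutions. Under ibd, centroids are per collection site and
    carry a mutation count growing linearly with the site's shoreline arc
    position, so genetic distance grows with shoreline distance.
    """
    reps = scn.replicates_per_site
    sample_ids = [f"{sid}r{k}" for sid in sites.ids for k in range(1, reps + 1)]
    missing = [s for s in sample_ids if s not in partition.pop_of]
    if missing:
        raise ValueError(f"partition does not cover samples: {missing[:5]}")
    rng = np.random.default_rng(scn.seed)
    ancestral = rng.integers(0, 4, size=scn.L)
    pool = _SitePool(scn.L, rng)

    centroid_of_sample: dict[str, np.ndarray] = {}
    if scn.scenario == "ibd":
        if sites.snap_arc is None:
            raise ValueError("ibd scenario requires shoreline arc positions on the sites")
        total = max(1, int(round(scn.m_b * sites.n)))
        chain = pool.take(total)
        chain_bases = (ancestral[chain] + rng.integers(1, 4, size=total)) % 4
        arc_max = float(sites.snap_arc.max()) or 1.0
        for sid, arc in zip(sites.ids, sites.snap_arc):
            k = int(round(arc / arc_max * total))
            cen = ancestral.copy()
            cen[chain[:k]] = chain_bases[:k]
            for r in range(1, reps + 1):
                centroid_of_sample[f"{sid}r{r}"] = cen
    else:
        m_b = 0.0 if scn.scenario == "panmixia" else scn.m_b
        centroids: dict[str, np.ndarray] = {}
        for pop in sorted(set(partition.pop_of.values())):
            n_b = rng.poisson(m_b)
            centroids[pop] = _mutate(ancestral, pool.take(n_b), rng)
        for s in sample_ids:
            centroid_of_sample[s] = centroids[partition.pop_of[s]]

    seqs = []
    for s in sample_ids:
        n_w = rng.poisson(scn.m_w)
        ind = _mutate(centroid_of_sample[s], pool.take(n_w), rng)
        seqs.append("".join(_BASES[b] for b in ind))
    return SequenceAlignment(sample_ids, seqs)


# ---- one-call bundle -----------------------------------------------------------


def generate_scenario(
    scn: SyntheticScenario,
    nrows: int = 140,
    ncols: int = 260,
    cellsize: float = 20.0,
    min_spacing: float = 25.0,
):
    """Full synthetic study: DEM, shoreline, sites, the four partitions, and
    one alignment simulated under the scenario's structuring partition.

    Returns (dem, ring, sites, partitions, alignment, structuring_partition),
    where partitions are sample-level (site x replicate). For panmixia and
    ibd the hydrology partition is used as the (non-structuring) analysis
    partition.
    """
    dem = make_lake_dem(nrows, ncols, cellsize, seed=scn.seed)
    ring = extract_shoreline(dem, WATER_LEVEL)
    sites = place_sites(ring, scn.n_sites, min_spacing, seed=scn.seed)
    site_parts = assign_partitions(sites, dem)
    parts = {k: expand_partition(p, scn.replicates_per_site) for k, p in site_parts.items()}
    key = scn.scenario if scn.scenario in parts else "hydrology"
    structuring = parts[key]
    aln = simulate_haplotypes(sites, structuring, scn)
    return dem, ring, sites, parts, aln, structuring
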