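"""Single-level AMOVA with a PhiPT fixation index and permutation test.

The analysis partitions squared pairwise distances among K populations,
following the distance-based (binary/haplotype) AMOVA convention: with
delta_ij = d(i,j)^2,

    SS_total  = (1/N) * sum_{i<j} delta_ij
    SS_within = sum_p (1/n_p) * sum_{i<j in p} delta_ij
    SS_among  = SS_total - SS_within

Variance components come from the mean squares with the unequal-sample-size
coefficient n0 = (N - sum n_p^2 / N) / (K - 1); Va may be negative and is
never clamped inside PhiPT = Va / (Va + Vw) — only the percentage columns
truncate at zero. The permutation p-value reassigns individuals to
populations (sizes preserved) and uses the +1 convention, one-tailed on
large PhiPT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import DistanceMatrix


@dataclass
class PopulationPartition:
    """A named landscape hypothesis mapping every sample to one population."""

    name: str
    pop_of: dict[str, str]

    def __post_init__(self) -> None:
        if not self.pop_of:
            raise ValueError("empty partition")

    @property
    def K(self) -> int:
        return len(set(self.pop_of.values()))

    def populations(self) -> dict[str, list[str]]:
        pops: dict[str, list[str]] = {}
        for sid, p in self.pop_of.items():
            pops.setdefault(p, []).append(sid)
        return pops

    def samples(self) -> list[str]:
        return list(self.pop_of)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"sample": list(self.pop_of), "population": list(self.pop_of.values())}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, name: str | None = None) -> "PopulationPartition":
        df = pd.read_csv(path)
        return cls(
            name or str(path),
            dict(zip(df["sample"].astype(str), df["population"].astype(str))),
        )


@dataclass
class AmovaTable:
    name: str
    SS_among: float
    SS_within: float
    SS_total: float
    df_among: int
    df_within: int
    MS_among: float
    MS_within: float
    n0: float
    Va: float
    Vw: float
    pct_among: float
    pct_within: float
    PhiPT: float  # NaN when Va + Vw == 0 (undefined)
    p_value: float  # NaN when n_perm == 0
    n_perm: int

    @property
    def N(self) -> int:
        return self.df_among + self.df_within + 1

    @property
    def K(self) -> int:
        return self.df_among + 1

    @property
    def undefined(self) -> bool:
        return bool(np.isnan(self.PhiPT))


def phi_pt(Va: float, Vw: float) -> float:
    """PhiPT = Va / (Va + Vw); NaN when the total variance is zero."""
    tot = Va + Vw
    return np.nan if tot == 0.0 else Va / tot


def _ss_within(delta: np.ndarray, groups: list[np.ndarray]) -> float:
    return sum(float(np.triu(delta[np.ix_(g, g)], k=1).sum()) / len(g) for g in groups)


def amova(
    dist: DistanceMatrix,
    part: PopulationPartition,
    n_perm: int = 999,
    seed: int | None = None,
) -> AmovaTable:
    """Distance AMOVA of ``part`` over ``dist`` (distances squared internally)."""
    samples = part.samples()
    missing = [s for s in samples if s not in dist.ids]
    if missing:
        raise ValueError(f"distance matrix missing samples: {missing[:5]}")
    pops = part.populations()
    K, N = len(pops), len(samples)
    if K < 2:
        raise ValueError("AMOVA requires K >= 2 populations")
    if any(len(v) == 0 for v in pops.values()):
        raise ValueError("empty population in partition")
    if N <= K:
        raise ValueError("AMOVA requires more samples than populations")

    sub = dist.subset(samples)
    if sub.has_undefined():
        raise ValueError("distance matrix contains undefined entries")
    delta = sub.values**2
    pos = {s: i for i, s in enumerate(samples)}
    pop_names = sorted(pops)
    groups = [np.array([pos[s] for s in pops[p]], dtype=int) for p in pop_names]
    sizes = np.array([len(g) for g in groups], dtype=float)

    ss_total = float(np.triu(delta, k=1).sum()) / N
    ss_within = _ss_within(delta, groups)
    ss_among = ss_total - ss_within
    df_among, df_within = K - 1, N - K
    ms_among, ms_within = ss_among / df_among, ss_within / df_within
    n0 = (N - float((sizes**2).sum()) / N) / (K - 1)
    va = (ms_among - ms_within) / n0
    vw = ms_within
    phi = phi_pt(va, vw)
    va_disp = max(va, 0.0)
    tot_disp = va_disp + vw
    if tot_disp > 0:
        pct_among, pct_within = 100.0 * va_disp / tot_disp, 100.0 * vw / tot_disp
    else:
        pct_among, pct_within = 0.0, 100.0

    p_value = np.nan
    if n_perm > 0:
        if np.isnan(phi):
            raise ValueError("PhiPT undefined (zero total variance); no permutation test")
        rng = np.random.default_rng(seed)
        bounds = np.cumsum([len(g) for g in groups])[:-1]
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(N)
            pgroups = np.split(perm, bounds)
            ssw = _ss_within(delta, pgroups)
            ms_a = (ss_total - ssw) / df_among
            ms_w = ssw / df_within
            phi_perm = phi_pt((ms_a - ms_w) / n0, ms_w)
            if phi_perm >= phi:
                count += 1
        p_value = (count + 1) / (n_perm + 1)

    return AmovaTable(
        name=part.name,
        SS_among=ss_among,
        SS_within=ss_within,
        SS_total=ss_total,
        df_among=df_among,
        df_within=df_within,
        MS_among=ms_among,
        MS_within=ms_within,
        n0=n0,
        Va=va,
        Vw=vw,
        pct_among=pct_among,
        pct_within=pct_within,
        PhiPT=phi,
        p_value=p_value,
        n_perm=n_perm,
    )


def amova_results_frame(results: list[tuple[str, AmovaTable]]) -> pd.DataFrame:
    """Stack AMOVA tables into the two-row-per-hypothesis summary layout."""
    rows = []
    for gene, t in results:
        rows.append(
            {
                "gene": gene,
                "hypothesis": t.name,
                "source": "Among Pop.",
                "df": t.df_among,
                "MS": t.MS_among,
                "estimated_variance": max(t.Va, 0.0),
                "pct_total": t.pct_among,
                "PhiPT": t.PhiPT,
                "p_value": t.p_value,
            }
        )
        rows.append(
            {
                "gene": gene,
                "hypothesis": t.name,
                "source": "Within Pop.",
                "df": t.df_within,
                "MS": t.MS_within,
                "estimated_variance": t.Vw,
                "pct_total": t.pct_within,
                "PhiPT": np.nan,
                "p_value": np.nan,
            }
        )
    return pd.DataFrame(rows)
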