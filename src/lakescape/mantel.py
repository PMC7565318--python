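"""Mantel test between two distance matrices.

The statistic is the Pearson correlation of the corresponding strict
lower-triangle entries; significance comes from Monte Carlo permutations that
jointly shuffle rows and columns of one matrix. The one-tailed "greater"
alternative is the default because isolation-by-distance predicts a positive
association between genetic and geographic distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

from .distances import DistanceMatrix


@dataclass
class MantelResult:
    r: float  # NaN when either triangle has zero variance
    p_value: float  # NaN when n_perm == 0
    n_perm: int
    distance_label: str = ""

    @property
    def undefined(self) -> bool:
        return bool(np.isnan(self.r))


def _triangle_correlation(a: np.ndarray, b: np.ndarray) -> float:
    i, j = np.tril_indices(a.shape[0], k=-1)
    x, y = a[i, j], b[i, j]
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def mantel_test(
    Dg: DistanceMatrix,
    Dx: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    distance_label: str = "",
) -> MantelResult:
    """Mantel correlation of Dg against Dx with a one-tailed permutation p."""
    if Dg.ids != Dx.ids:
        raise ValueError("distance matrices must share the same ids in the same order")
    n = Dg.n
    if n < 4:
        raise ValueError("Mantel test requires at least 4 samples")
    if Dg.has_undefined() or Dx.has_undefined():
        raise ValueError("distance matrix contains undefined entries")

    r_obs = _triangle_correlation(Dg.values, Dx.values)
    if np.isnan(r_obs):
        return MantelResult(np.nan, np.nan, n_perm, distance_label)

    p_value = np.nan
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            r_perm = _triangle_correlation(Dg.values, Dx.values[np.ix_(perm, perm)])
            if r_perm >= r_obs:
                count += 1
        p_value = (count + 1) / (n_perm + 1)
    return MantelResult(r_obs, p_value, n_perm, distance_label)


def mantel_exact_p(Dg: DistanceMatrix, Dx: DistanceMatrix) -> float:
    """Exact one-tailed p by enumerating all n! relabelings (tiny n only)."""
    if Dg.ids != Dx.ids:
        raise ValueError("distance matrices must share the same ids in the same order")
    n = Dg.n
    if n > 8:
        raise ValueError("exact enumeration is limited to n <= 8")
    r_obs = _triangle_correlation(Dg.values, Dx.values)
    count = total = 0
    for perm in permutations(range(n)):
        idx = np.array(perm)
        r = _triangle_correlation(Dg.values, Dx.values[np.ix_(idx, idx)])
        total += 1
        if r >= r_obs - 1e-12:
            count += 1
    return count / total


def mantel_results_frame(results: list[tuple[str, MantelResult]]) -> pd.DataFrame:
    """Summary layout: gene, distance measure, Mantel statistic, p-value."""
    return pd.DataFrame(
        [
            {
                "gene": gene,
                "distance_measure": res.distance_label,
                "mantel_r": res.r,
                "p_value": res.p_value,
            }
            for gene, res in results
        ]
    )
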