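"""AICc competition among landscape dispersal hypotheses.

Each hypothesis is scored from the within-population sum of squares of its
AMOVA (in place of an ANOVA error sum of squares):

    AICc = n * ln(SSw / n) + 2K + 2K(K+1) / (n - K - 1)

with K the number of populations the hypothesis defines and n the number of
sequences analysed. Hypotheses are ranked by AICc; relative support is the
Akaike weight w_i = exp(-dAICc_i / 2) / sum_j exp(-dAICc_j / 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .popstats import AmovaTable, PopulationPartition


@dataclass
class AiccRow:
    name: str
    K: int
    n: int
    AICc: float
    dAICc: float
    weight: float


@dataclass
class AiccTable:
    rows: list[AiccRow]
    best: str

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "hypothesis": r.name,
                    "K": r.K,
                    "n": r.n,
                    "AICc": r.AICc,
                    "dAICc": r.dAICc,
                    "weight": r.weight,
                    "best": r.name == self.best,
                }
                for r in self.rows
            ]
        )


def aicc_from_ss(ss_within: float, n: int, K: int) -> float:
    """Small-sample-corrected AIC from a within-population sum of squares."""
    if ss_within <= 0:
        raise ValueError("ss_within must be positive")
    if K < 1:
        raise ValueError("K must be >= 1")
    if n <= K + 1:
        raise ValueError(f"n = {n} too small for K = {K} (correction term undefined)")
    return n * math.log(ss_within / n) + 2 * K + 2 * K * (K + 1) / (n - K - 1)


def akaike_weights(aiccs: list[float]) -> np.ndarray:
    """Normalized relative likelihoods exp(-dAICc/2); invariant to shifts."""
    a = np.asarray(aiccs, dtype=float)
    d = a - a.min()
    w = np.exp(-d / 2.0)
    return w / w.sum()


def compete(
    amova_results: list[tuple[PopulationPartition, AmovaTable]], n: int
) -> AiccTable:
    """Rank landscape hypotheses by AICc from their AMOVA tables."""
    if len(amova_results) < 2:
        raise ValueError("need at least 2 hypotheses to compete")
    sample_sets = {frozenset(part.pop_of) for part, _ in amova_results}
    if len(sample_sets) != 1:
        raise ValueError("hypotheses were not computed on the same sample set")
    if len(next(iter(sample_sets))) != n:
        raise ValueError("n does not match the AMOVA sample set")
    for _, table in amova_results:
        if table.N != n:
            raise ValueError(
                f"AMOVA table {table.name!r} has N = {table.N}, expected {n}"
            )

    aiccs = [aicc_from_ss(t.SS_within, n, part.K) for part, t in amova_results]
    weights = akaike_weights(aiccs)
    best_aicc = min(aiccs)
    rows = [
        AiccRow(part.name, part.K, n, a, a - best_aicc, float(w))
        for (part, _), a, w in zip(amova_results, aiccs, weights)
    ]
    best = min(rows, key=lambda r: r.AICc).name
    return AiccTable(rows, best)
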