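"""Pairwise distance matrices — the common currency between pipeline stages.

A :class:`DistanceMatrix` holds a symmetric, zero-diagonal matrix keyed by
sample (or haplotype) identifiers, with explicit units so genetic steps,
substitutions/site and metres never get mixed up silently. Entries may be
flagged undefined (e.g. K2P saturation) via a boolean mask rather than being
clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: recognised units
UNITS = ("steps", "substitutions/site", "metres")


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray
    units: str
    undefined: np.ndarray | None = None  # True where the distance is undefined

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids in distance matrix")
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} ids")
        if self.units not in UNITS:
            raise ValueError(f"unknown units {self.units!r}; expected one of {UNITS}")
        if self.undefined is not None:
            self.undefined = np.asarray(self.undefined, dtype=bool)
            if self.undefined.shape != (n, n):
                raise ValueError("undefined mask shape mismatch")
        ok = self._defined_mask()
        vals = self.values[ok]
        if vals.size and not np.all(np.isfinite(vals) | np.isinf(vals)):
            raise ValueError("non-finite distance outside the undefined mask")
        if not np.allclose(self.values[ok & ok.T], self.values.T[ok & ok.T], equal_nan=True):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal is not zero")

    def _defined_mask(self) -> np.ndarray:
        if self.undefined is None:
            return np.ones_like(self.values, dtype=bool)
        return ~self.undefined

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, sample_id: str) -> int:
        try:
            return self.ids.index(sample_id)
        except ValueError:
            raise KeyError(f"id {sample_id!r} not in distance matrix") from None

    def subset(self, ids: list[str]) -> "DistanceMatrix":
        """Restrict to (and reorder by) the given ids."""
        idx = [self.index_of(i) for i in ids]
        und = self.undefined[np.ix_(idx, idx)] if self.undefined is not None else None
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)], self.units, und)

    def lower_triangle(self) -> np.ndarray:
        """Vectorised strict lower triangle (row-major order)."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]

    def has_undefined(self) -> bool:
        return self.undefined is not None and bool(self.undefined.any())

    # ---- I/O ---------------------------------------------------------------

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path, units: str) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("row and column ids differ in distance CSV")
        return cls([str(i) for i in df.index], df.to_numpy(dtype=float), units)

    def to_phylip(self, path) -> None:
        """Lower-triangle PHYLIP-style text (ids padded to 10 characters)."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, sid in enumerate(self.ids):
                row = " ".join(f"{self.values[i, j]:.6f}" for j in range(i))
                fh.write(f"{sid:<10s} {row}".rstrip() + "\n")
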