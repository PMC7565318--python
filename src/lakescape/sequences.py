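"""Aligned haploid marker sequences: trimming, haplotype collapsing and
genetic distances.

Two gap conventions coexist deliberately, because different downstream tools
demand them:

* haplotype collapsing and step counts treat a gap as a fifth character
  state — a single indel is one mutational step and defines a new haplotype;
* the Kimura 2-parameter distance uses *complete deletion*: every site with a
  gap or an ambiguous base in any sequence is removed once, globally, before
  any pair is compared.

``N`` (and any IUPAC ambiguity) is treated as missing throughout: skipped
pairwise for step counts, removed globally for K2P.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .distances import DistanceMatrix

# integer encoding: A,C,G,T observable; '-' a fifth state; everything else missing
_A, _C, _G, _T, _GAP, _MISSING = 0, 1, 2, 3, 4, 5
_CODE = {"A": _A, "C": _C, "G": _G, "T": _T, "-": _GAP}
_CHAR = "ACGT-N"


@dataclass
class SequenceAlignment:
    """Equal-length aligned sequences over {A,C,G,T,-,N} with unique ids."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.seqs = [s.upper() for s in self.seqs]
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and sequences differ in number")
        if not self.seqs:
            raise ValueError("empty alignment")
        L = len(self.seqs[0])
        if L < 1:
            raise ValueError("zero-length sequences")
        for sid, s in zip(self.ids, self.seqs):
            if len(s) != L:
                raise ValueError(
                    f"alignment shape violation: record {sid!r} has length {len(s)}, expected {L}"
                )
        dup = {i for i in self.ids if self.ids.count(i) > 1}
        if dup:
            raise ValueError(f"duplicate sequence ids: {sorted(dup)}")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def encoded(self) -> np.ndarray:
        """(n, length) int8 matrix; unknown characters map to missing."""
        out = np.full((self.n, self.length), _MISSING, dtype=np.int8)
        for r, s in enumerate(self.seqs):
            out[r] = [
                _CODE.get(ch, _MISSING) for ch in s
            ]
        return out


@dataclass
class HaplotypeAssignment:
    """Samples grouped by character-identical (gaps included) sequences."""

    haplotype_of: dict[str, str]  # sample id -> haplotype label
    representatives: dict[str, str]  # haplotype label -> sequence
    frequencies: dict[str, int]  # haplotype label -> sample count

    @property
    def n_haplotypes(self) -> int:
        return len(self.representatives)

    @property
    def n_samples(self) -> int:
        return sum(self.frequencies.values())

    def labels(self) -> list[str]:
        """Haplotype labels in first-encounter order (H1, H2, ...)."""
        return sorted(self.representatives, key=lambda h: int(h[1:]))

    def haplotype_alignment(self) -> SequenceAlignment:
        """Alignment of one representative sequence per haplotype."""
        labels = self.labels()
        return SequenceAlignment(labels, [self.representatives[h] for h in labels])


# ---- I/O --------------------------------------------------------------------


def read_fasta(path) -> SequenceAlignment:
    """Read an aligned multi-FASTA; ids taken from headers up to whitespace."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no records in FASTA file {path}")
    return SequenceAlignment([r.id for r in records], [str(r.seq) for r in records])


def write_fasta(aln: SequenceAlignment, path) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(aln.ids, aln.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---- operations --------------------------------------------------------------


def trim_alignment(aln: SequenceAlignment, start: int, end: int) -> SequenceAlignment:
    """Restrict every sequence to the 1-based inclusive window [start, end]."""
    if not (1 <= start <= end <= aln.length):
        raise ValueError(
            f"trim window ({start}, {end}) out of range for alignment of length {aln.length}"
        )
    return SequenceAlignment(list(aln.ids), [s[start - 1 : end] for s in aln.seqs])


def collapse_haplotypes(aln: SequenceAlignment) -> HaplotypeAssignment:
    """Group character-identical sequences; indices in first-encounter order.

    Any single difference — substitution, insertion or deletion — separates
    haplotypes, i.e. the gap character is a fifth state.
    """
    haplotype_of: dict[str, str] = {}
    representatives: dict[str, str] = {}
    frequencies: dict[str, int] = {}
    seen: dict[str, str] = {}
    for sid, seq in zip(aln.ids, aln.seqs):
        label = seen.get(seq)
        if label is None:
            label = f"H{len(seen) + 1}"
            seen[seq] = label
            representatives[label] = seq
            frequencies[label] = 0
        haplotype_of[sid] = label
        frequencies[label] += 1
    return HaplotypeAssignment(haplotype_of, representatives, frequencies)


def pairwise_step_matrix(aln: SequenceAlignment) -> DistanceMatrix:
    """Count of differing sites per pair, gap = fifth state, N skipped.

    Sites where either sequence is missing (N/ambiguity) are excluded for that
    pair only.
    """
    enc = aln.encoded()
    n = aln.n
    vals = np.zeros((n, n), dtype=float)
    missing = enc == _MISSING
    for i in range(n):
        diff = enc[i + 1 :] != enc[i]
        usable = ~(missing[i + 1 :] | missing[i])
        counts = (diff & usable).sum(axis=1)
        vals[i, i + 1 :] = counts
        vals[i + 1 :, i] = counts
    return DistanceMatrix(list(aln.ids), vals, "steps")


_PURINE = np.array([True, False, True, False, False, False])  # A, G


def k2p_matrix(aln: SequenceAlignment, deletion: str = "complete") -> DistanceMatrix:
    """Kimura 2-parameter distances with complete deletion of missing sites.

    d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)) with P the transition and Q the
    transversion proportion over the retained sites. Pairs for which the
    logarithm's argument is non-positive (saturation) are flagged undefined,
    not clamped.
    """
    if deletion != "complete":
        raise ValueError("only complete deletion is supported")
    enc = aln.encoded()
    bad = (enc == _GAP) | (enc == _MISSING)
    keep = ~bad.any(axis=0)
    m = int(keep.sum())
    if m == 0:
        raise ValueError("complete deletion removed every site")
    sub = enc[:, keep]
    purine = _PURINE[sub]
    n = aln.n
    vals = np.zeros((n, n), dtype=float)
    undef = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            diff = sub[i] != sub[j]
            transitions = int((diff & (purine[i] == purine[j])).sum())
            transversions = int((diff & (purine[i] != purine[j])).sum())
            P, Q = transitions / m, transversions / m
            a, b = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
            if a <= 0.0 or b <= 0.0:
                undef[i, j] = undef[j, i] = True
                vals[i, j] = vals[j, i] = np.nan
            else:
                d = -0.5 * math.log(a * math.sqrt(b))
                vals[i, j] = vals[j, i] = d
    return DistanceMatrix(
        list(aln.ids), vals, "substitutions/site", undef if undef.any() else None
    )


def haplotype_accumulation(
    assign: HaplotypeAssignment, subsample_sizes: list[int]
) -> list[tuple[int, float]]:
    """Rarefaction: exact expected number of distinct haplotypes at size m.

    E[H_m] = sum_h (1 - C(N - N_h, m) / C(N, m)) under sampling without
    replacement, computed exactly with integer binomials.
    """
    N = assign.n_samples
    freqs = list(assign.frequencies.values())
    out = []
    for m in subsample_sizes:
        if not (1 <= m <= N):
            raise ValueError(f"subsample size {m} out of range 1..{N}")
        denom = math.comb(N, m)
        e = sum(1.0 - math.comb(N - f, m) / denom for f in freqs)
        out.append((m, e))
    return out


def haplotype_table(assign: HaplotypeAssignment) -> "pd.DataFrame":
    """Long-form sample/haplotype table (sample, haplotype, frequency)."""
    import pandas as pd

    rows = [
        {
            "sample": sid,
            "haplotype": h,
            "frequency": assign.frequencies[h],
        }
        for sid, h in assign.haplotype_of.items()
    ]
    return pd.DataFrame(rows)
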