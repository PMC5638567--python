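"""Promoter-allele comparison and CpG-island prediction.

The two ancestral promoter alleles are compared by optimal global pairwise
alignment (match +1, mismatch -1, linear gap -2) and a columnwise scan of
the alignment that reports SNPs and merged indel events in 1-based
coordinates of the first sequence.

CpG islands are predicted with the classic sliding-window criteria: a
200 bp window qualifies when GC content exceeds 50% and the observed to
expected CpG ratio, (N_CpG * L) / (N_C * N_G), exceeds 60%; overlapping
qualifying windows are merged and merged regions of at least 200 bp are
reported with statistics recomputed over the whole region.  N bases are
excluded from every count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from Bio import Align

__all__ = [
    "PromoterSequence",
    "VariantKind",
    "VariantSite",
    "CpGIsland",
    "PairAlignment",
    "align_pair",
    "find_variants",
    "predict_cpg_islands",
]

_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class PromoterSequence:
    """A promoter-allele DNA sequence (upper-case, alphabet ACGTN)."""

    id: str
    residues: str
    species_or_allele: str = ""

    def __post_init__(self) -> None:
        seq = str(self.residues).upper()
        if not seq:
            raise ValueError("empty sequence")
        bad = set(seq) - _ALPHABET
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)} in sequence {self.id!r}")
        object.__setattr__(self, "residues", seq)

    def __len__(self) -> int:
        return len(self.residues)


class VariantKind(str, Enum):
    SNP = "SNP"
    INSERTION = "INSERTION"
    DELETION = "DELETION"


@dataclass(frozen=True)
class VariantSite:
    """An inter-allele difference, positioned on the first sequence (1-based).

    For insertions (bases present only in sequence B) the position is that
    of the next base of sequence A.
    """

    position: int
    kind: VariantKind
    allele_a: str
    allele_b: str


@dataclass(frozen=True)
class CpGIsland:
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    length: int
    gc_fraction: float
    obs_exp_cpg: float


@dataclass(frozen=True)
class PairAlignment:
    seq_a: PromoterSequence
    seq_b: PromoterSequence
    aligned_a: str
    aligned_b: str
    score: float


def align_pair(seq_a: PromoterSequence, seq_b: PromoterSequence,
               match: float = 1.0, mismatch: float = -1.0,
               gap: float = -2.0) -> PairAlignment:
    """Optimal global alignment of two promoter alleles (linear gap penalty)."""
    aligner = Align.PairwiseAligner(mode="global")
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    aln = aligner.align(seq_a.residues, seq_b.residues)[0]
    return PairAlignment(seq_a=seq_a, seq_b=seq_b,
                         aligned_a=str(aln[0]), aligned_b=str(aln[1]),
                         score=float(aln.score))


def find_variants(alignment: PairAlignment) -> list[VariantSite]:
    """Columnwise variant scan; adjacent gap columns merge into one indel."""
    a, b = alignment.aligned_a, alignment.aligned_b
    variants: list[VariantSite] = []
    pos_a = 0
    run_kind: VariantKind | None = None
    run_bases: list[str] = []
    run_pos = 0

    def flush() -> None:
        nonlocal run_kind, run_bases
        if run_kind is VariantKind.DELETION:
            variants.append(VariantSite(run_pos, run_kind, "".join(run_bases), ""))
        elif run_kind is VariantKind.INSERTION:
            variants.append(VariantSite(run_pos, run_kind, "", "".join(run_bases)))
        run_kind, run_bases = None, []

    for ca, cb in zip(a, b):
        if ca != "-":
            pos_a += 1
        if ca == "-" and cb != "-":
            if run_kind is not VariantKind.INSERTION:
                flush()
                run_kind, run_pos = VariantKind.INSERTION, pos_a + 1
            run_bases.append(cb)
        elif cb == "-" and ca != "-":
            if run_kind is not VariantKind.DELETION:
                flush()
                run_kind, run_pos = VariantKind.DELETION, pos_a
            run_bases.append(ca)
        else:
            flush()
            if ca != cb:
                variants.append(VariantSite(pos_a, VariantKind.SNP, ca, cb))
    flush()
    return variants


def _window_stats(is_c: np.ndarray, is_g: np.ndarray, is_n: np.ndarray,
                  cpg: np.ndarray, start: int, end: int) -> tuple[float, float]:
    """(gc_fraction, obs_exp_cpg) over the half-open slice [start, end)."""
    n_c = int(is_c[start:end].sum())
    n_g = int(is_g[start:end].sum())
    l_eff = (end - start) - int(is_n[start:end].sum())
    gc = (n_c + n_g) / l_eff if l_eff else 0.0
    n_cpg = int(cpg[start:end - 1].sum()) if end - start >= 2 else 0
    oe = (n_cpg * l_eff) / (n_c * n_g) if n_c * n_g > 0 else 0.0
    return gc, oe


def predict_cpg_islands(seq: PromoterSequence, window: int = 200,
                        gc_min: float = 0.5, oe_min: float = 0.6,
                        min_len: int = 200, step: int = 1) -> list[CpGIsland]:
    """Sliding-window CpG-island prediction with merged-region statistics."""
    s = seq.residues
    n = len(s)
    if n < window:
        warnings.warn(f"sequence {seq.id!r} shorter than window ({n} < {window}); "
                      "no islands predicted", stacklevel=2)
        return []
    arr = np.frombuffer(s.encode("ascii"), dtype="S1")
    is_c = arr == b"C"
    is_g = arr == b"G"
    is_n = arr == b"N"
    cpg = np.zeros(n, dtype=bool)
    if n >= 2:
        cpg[:-1] = is_c[:-1] & is_g[1:]  # cpg[i]: dinucleotide starting at i

    # cumulative sums -> O(1) per-window counts
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_n = np.concatenate([[0], np.cumsum(is_n)])
    cum_cpg = np.concatenate([[0], np.cumsum(cpg)])

    starts = np.arange(0, n - window + 1, step)
    ends = starts + window
    n_c = cum_c[ends] - cum_c[starts]
    n_g = cum_g[ends] - cum_g[starts]
    l_eff = window - (cum_n[ends] - cum_n[starts])
    n_cpg = cum_cpg[ends - 1] - cum_cpg[starts]  # dinucleotides fully inside
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = np.where(l_eff > 0, (n_c + n_g) / np.maximum(l_eff, 1), 0.0)
        denom = n_c * n_g
        oe = np.where(denom > 0, n_cpg * l_eff / np.maximum(denom, 1), 0.0)
    qualifies = (gc > gc_min) & (oe > oe_min)

    # merge overlapping/adjacent qualifying windows into candidate regions
    islands: list[CpGIsland] = []
    cur_start = cur_end = None
    for st, q in zip(starts, qualifies):
        if not q:
            continue
        if cur_end is not None and st <= cur_end:
            cur_end = st + window
        else:
            if cur_start is not None:
                islands.extend(_finalize(seq, is_c, is_g, is_n, cpg,
                                         cur_start, cur_end, gc_min, oe_min, min_len))
            cur_start, cur_end = int(st), int(st + window)
    if cur_start is not None:
        islands.extend(_finalize(seq, is_c, is_g, is_n, cpg,
                                 cur_start, cur_end, gc_min, oe_min, min_len))
    return islands


def _finalize(seq, is_c, is_g, is_n, cpg, start, end,
              gc_min, oe_min, min_len) -> list[CpGIsland]:
    if end - start < min_len:
        return []
    gc, oe = _window_stats(is_c, is_g, is_n, cpg, start, end)
    if not (gc > gc_min and oe > oe_min):
        # merged flanks diluted the signal below threshold; drop the region
        return []
    return [CpGIsland(start=int(start) + 1, end=int(end), length=int(end - start),
                      gc_fraction=float(gc), obs_exp_cpg=float(oe))]
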