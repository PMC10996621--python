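"""Gag ORF assessment: ORF finding, intactness scoring, protein identity.

Nonautonomous ERV families of the kind modelled here encode a single long
open reading frame (Gag) on the element sense strand. A copy's Gag is scored
against the family's expected protein length: a copy is "intact" when the
canonical reading frame still starts at ATG and runs without a premature stop
to at least ``intact_fraction`` of the expected length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align

from .models import ErvFamilyModel
from .seq import translate

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class Orf:
    """An ATG-initiated, stop-terminated ORF; ``end`` includes the stop codon."""

    start: int
    end: int
    frame: int

    @property
    def protein_len(self) -> int:
        return (self.end - self.start) // 3 - 1


@dataclass
class GagAssessment:
    locus_id: str
    orf_interval: tuple[int, int] | None
    protein_len: int
    intact: bool
    stop_codon_positions: list[int]  # 1-based codon indices within the canonical frame
    frame: int | None
    protein: str | None = None
    reason: str = ""


def find_longest_orf(seq: str, min_aa: int = 50) -> Orf | None:
    """Longest ATG-initiated, stop-terminated ORF on the given strand.

    All three frames are scanned; ties are broken by leftmost start. Returns
    ``None`` if no qualifying ORF encodes at least ``min_aa`` amino acids
    (stop excluded).
    """
    best: Orf | None = None
    n = len(seq)
    for frame in range(3):
        start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in STOP_CODONS:
                orf = Orf(start, pos + 3, frame)
                if orf.protein_len >= min_aa and (
                    best is None
                    or orf.protein_len > best.protein_len
                    or (orf.protein_len == best.protein_len and orf.start < best.start)
                ):
                    best = orf
                start = None
    return best


@lru_cache(maxsize=32)
def _consensus_orf(internal_seq: str, min_aa: int = 100) -> Orf | None:
    return find_longest_orf(internal_seq, min_aa=min_aa)


def consensus_gag_orf(model: ErvFamilyModel) -> Orf:
    """Locate the canonical Gag ORF on the family's internal consensus."""
    orf = _consensus_orf(model.internal_seq)
    if orf is None:
        raise ValueError(f"family {model.family_name} has no long ORF in its internal consensus")
    return orf


def assess_gag(
    seq: str,
    model: ErvFamilyModel,
    intact_fraction: float = 0.95,
    locus_id: str = "",
    seq_is_element: bool = False,
    consensus_offset: int = 0,
) -> GagAssessment:
    """Score Gag intactness of one copy.

    ``seq`` is the copy's internal region on the element sense strand
    (``seq_is_element=True`` strips one consensus LTR length from each end
    first). ``consensus_offset`` is the internal-consensus coordinate of the
    first base of ``seq``, for 5'-truncated copies.

    The canonical frame — located once on the family consensus by the
    longest-ORF scan — is read from the canonical ATG to its first stop.
    Copies whose truncation removes the canonical start are reported
    non-intact rather than rescued by downstream ATGs.
    """
    orf = consensus_gag_orf(model)
    if seq_is_element:
        seq = seq[model.ltr_len : len(seq) - model.ltr_len]
    lo = orf.start - consensus_offset
    hi = orf.end - consensus_offset
    if not seq or lo < 0 or hi > len(seq):
        return GagAssessment(locus_id, None, 0, False, [], None,
                             reason="canonical ORF outside available sequence")
    region = seq[lo:hi]
    prot = translate(region)
    stops = [i + 1 for i, aa in enumerate(prot) if aa == "*"]
    protein_len = (stops[0] - 1) if stops else len(prot)
    start_ok = region.startswith("ATG")
    expected = model.expected_gag_aa or orf.protein_len
    intact = start_ok and protein_len >= intact_fraction * expected
    reason = ""
    if not start_ok:
        reason = "start codon lost"
    elif not intact:
        reason = "premature stop" if stops and stops[0] <= expected else "short ORF"
    return GagAssessment(
        locus_id=locus_id,
        orf_interval=(lo, hi),
        protein_len=protein_len,
        intact=intact,
        stop_codon_positions=stops,
        frame=(orf.start % 3),
        protein=prot[:protein_len],
        reason=reason,
    )


def _protein_aligner() -> Align.PairwiseAligner:
    # Simple documented scheme: match +1, mismatch 0, gap open -1, extend -0.5;
    # terminal gaps free so length variants are not over-penalised.
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -0.5
    try:
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    except AttributeError:  # older Biopython attribute names
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0
    return aligner


def pairwise_protein_identity(a: str, b: str) -> float:
    """Percent identity from a global alignment.

    Identity = matching columns / alignment columns, terminal gap columns
    excluded from the denominator.
    """
    if a == b:
        return 100.0
    aln = _protein_aligner().align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    # strip terminal gap columns (present in only one row at each end)
    lo = 0
    hi = len(sa)
    while lo < hi and (sa[lo] == "-" or sb[lo] == "-"):
        lo += 1
    while hi > lo and (sa[hi - 1] == "-" or sb[hi - 1] == "-"):
        hi -= 1
    cols = hi - lo
    if cols == 0:
        return 0.0
    matches = sum(x == y and x != "-" for x, y in zip(sa[lo:hi], sb[lo:hi]))
    return 100.0 * matches / cols


def protein_identity_matrix(proteins: dict[str, str]) -> tuple[list[str], np.ndarray, float]:
    """Symmetric percent-identity matrix and its mean off-diagonal value.

    Returns ``(labels, matrix, mean_offdiag)``; with fewer than two proteins
    the matrix is empty and a warning is emitted.
    """
    labels = list(proteins)
    n = len(labels)
    if n < 2:
        warnings.warn("protein_identity_matrix needs >= 2 proteins; returning empty matrix")
        return labels, np.zeros((n, n)), float("nan")
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ident = pairwise_protein_identity(proteins[labels[i]], proteins[labels[j]])
            mat[i, j] = mat[j, i] = ident
    off = mat[~np.eye(n, dtype=bool)]
    return labels, mat, float(off.mean())
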