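"""Presence/absence insertion polymorphism calling across assemblies.

For each occupied reference locus the flanks are anchored in a query
assembly and the distance between the anchored flank ends ("gap") is
compared with the lengths expected for each possible state of the locus:

* the full element plus one TSD copy        -> SHARED_FULL
* a single LTR plus one TSD copy            -> SOLO_LTR
* nothing (pre-integration site restored)   -> PRECISE_ABSENCE
* flanks unplaced or discordant             -> LOCUS_DELETED / UNDETERMINED

Flank convention (fixed by the gap arithmetic above): the left flank ends
immediately 5' of the left TSD copy; the right flank begins at the right TSD
copy. Under this convention a precise absence gives gap 0 and the single
surviving TSD copy sits exactly at the anchor junction, where
:func:`verify_empty_site` checks for exactly one copy of the TSD sequence —
the hallmark distinguishing a true pre-integration site from an imprecise
excision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .models import ErvFamilyModel
from .seq import revcomp

Genome = dict[str, str]


class LocusStatus(str, Enum):
    SHARED_FULL = "SHARED_FULL"
    SOLO_LTR = "SOLO_LTR"
    PRECISE_ABSENCE = "PRECISE_ABSENCE"
    LOCUS_DELETED = "LOCUS_DELETED"
    UNDETERMINED = "UNDETERMINED"


@dataclass
class ReferenceLocus:
    """An occupied locus in the reference genome.

    ``start``/``end`` span the element only; the left TSD copy occupies
    ``[start - tsd_len, start)`` and the right copy ``[end, end + tsd_len)``.
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    tsd_seq: str = ""
    structure_class: str = ""

    @property
    def tsd_len(self) -> int:
        return len(self.tsd_seq)

    @property
    def element_len(self) -> int:
        return self.end - self.start


@dataclass
class FlankPlacement:
    chrom: str
    position: int  # left: end of match; right: start of match (query coords)
    score: float
    strand: str = "+"


@dataclass
class AnchorResult:
    left: list[FlankPlacement]
    right: list[FlankPlacement]
    best: tuple[str, int, int, str] | None  # (chrom, left_end, right_start, strand)


@dataclass
class PolymorphismCall:
    locus_id: str
    assembly_id: str
    status: LocusStatus
    observed_gap: int | None = None
    expected_full: int | None = None
    expected_solo: int | None = None
    tsd_evidence: bool | None = None
    low_evidence: bool = False
    anchor_scores: tuple[float, float] | None = None
    note: str = ""


def extract_locus(
    genome: Genome, locus: ReferenceLocus, flank: int = 50_000
) -> tuple[str, str, str]:
    """(left flank, occupied segment, right flank) around a reference locus.

    The left flank ends just 5' of the left TSD copy; the occupied segment is
    left TSD + element; the right flank begins at the right TSD copy. The
    concatenation of the three pieces reproduces the reference region
    exactly. Flanks are clipped (with a warning) at chromosome ends.
    """
    seq = genome[locus.chrom]
    t = locus.tsd_len
    left_hi = locus.start - t
    left_lo = max(0, left_hi - flank)
    right_lo = locus.end
    right_hi = min(len(seq), right_lo + flank)
    if left_hi - left_lo < flank or right_hi - right_lo < flank:
        warnings.warn(f"{locus.locus_id}: flank clipped at chromosome edge")
    return seq[left_lo:left_hi], seq[left_hi:right_lo], seq[right_lo:right_hi]


def _find_placements(
    anchor: str, query: Genome, max_mismatch_frac: float, from_end: bool
) -> list[FlankPlacement]:
    """All placements of one anchor on the + orientation of the query.

    Candidate positions come from exact occurrences of a seed k-mer taken at
    the anchor end nearest the locus; candidates are verified by Hamming
    comparison of the full anchor.
    """
    k = min(25, len(anchor))
    seed = anchor[-k:] if from_end else anchor[:k]
    placements: list[FlankPlacement] = []
    for chrom, seq in query.items():
        pos = seq.find(seed)
        while pos != -1:
            a_start = pos - (len(anchor) - k) if from_end else pos
            if 0 <= a_start and a_start + len(anchor) <= len(seq):
                window = seq[a_start : a_start + len(anchor)]
                mism = sum(x != y for x, y in zip(window, anchor))
                if mism <= max_mismatch_frac * len(anchor):
                    endpoint = a_start + len(anchor) if from_end else a_start
                    placements.append(
                        FlankPlacement(chrom, endpoint, float(len(anchor) - mism))
                    )
            pos = seq.find(seed, pos + 1)
    return placements


def anchor_flanks(
    left: str,
    right: str,
    query: Genome,
    min_anchor: int = 200,
    max_offset: int = 50_000,
    max_mismatch_frac: float = 0.1,
    query_rc: Genome | None = None,
) -> AnchorResult:
    """Place both flanks in the query; unique colinear best placement or none.

    Only the ``min_anchor`` bp of each flank nearest the locus are used as
    anchors. Both query orientations are searched; a minus-strand placement
    reports coordinates on the reverse-complemented query so downstream gap
    arithmetic is strand-invariant. Ambiguous (multiple equally scoring) or
    discordant placements yield ``best=None``.
    """
    if len(left) < min_anchor or len(right) < min_anchor:
        raise ValueError("flanks shorter than min_anchor")
    left_a = left[-min_anchor:]
    right_a = right[:min_anchor]

    def search(q: Genome, strand: str) -> tuple[list[FlankPlacement], list[FlankPlacement]]:
        lp = _find_placements(left_a, q, max_mismatch_frac, from_end=True)
        rp = _find_placements(right_a, q, max_mismatch_frac, from_end=False)
        for p in lp + rp:
            p.strand = strand
        return lp, rp

    lp, rp = search(query, "+")
    rc_query = query_rc if query_rc is not None else {c: revcomp(s) for c, s in query.items()}
    lp2, rp2 = search(rc_query, "-")
    left_all = lp + lp2
    right_all = rp + rp2

    best = None
    candidates = []
    for l in left_all:
        for r in right_all:
            if l.chrom != r.chrom or l.strand != r.strand:
                continue
            gap = r.position - l.position
            if -len(right_a) < gap <= max_offset:
                candidates.append((l.score + r.score, l, r))
    if candidates:
        candidates.sort(key=lambda c: -c[0])
        if len(candidates) == 1 or candidates[0][0] > candidates[1][0]:
            _, l, r = candidates[0]
            best = (l.chrom, l.position, r.position, l.strand)
    return AnchorResult(left=left_all, right=right_all, best=best)


def verify_empty_site(tsd_seq: str, query_seq: str, junction: int) -> tuple[bool, bool]:
    """Check the empty-site hallmark: exactly one TSD copy spans the junction.

    Returns ``(passed, low_evidence)``; a zero-length TSD passes vacuously
    but is flagged low-evidence.
    """
    t = len(tsd_seq)
    if t == 0:
        return True, True
    window = query_seq[max(0, junction - t) : junction + 2 * t]
    count = 0
    at_junction = False
    for i in range(len(window) - t + 1):
        if window[i : i + t] == tsd_seq:
            count += 1
            if max(0, junction - t) + i == junction:
                at_junction = True
    return (count == 1 and at_junction), False


def classify_locus(
    locus: ReferenceLocus,
    anchors: AnchorResult,
    query: Genome,
    model: ErvFamilyModel,
    assembly_id: str = "",
    tolerance: float | None = None,
) -> PolymorphismCall:
    """Decide the status of one reference locus in one query assembly.

    Expected gaps under the flank convention: full = element + tsd;
    solo = LTR + tsd; precise absence = 0. The tolerance for each window is
    ``max(50 bp, 10% of the expected length)`` unless overridden; a
    configuration where the full and solo windows overlap is rejected.
    """
    t = locus.tsd_len
    expected_full = locus.element_len + t
    expected_solo = model.ltr_len + t

    def tol(expected: int) -> float:
        return tolerance if tolerance is not None else max(50.0, 0.1 * expected)

    # Window-disjointness guard: meaningful only where the reference copy is a
    # provirus (a solo-LTR reference locus has expected_full ~ expected_solo by
    # construction; the SHARED_FULL branch then simply means "same as reference").
    if locus.structure_class == "FULL_PROVIRUS" and (
        tol(expected_full) + tol(expected_solo) >= abs(expected_full - expected_solo)
    ):
        raise ValueError("tolerance too large: SHARED_FULL and SOLO_LTR windows overlap")

    if anchors.best is None:
        one_side = (len(anchors.left) > 0) != (len(anchors.right) > 0)
        status = LocusStatus.LOCUS_DELETED if one_side else LocusStatus.UNDETERMINED
        return PolymorphismCall(
            locus.locus_id, assembly_id, status,
            expected_full=expected_full, expected_solo=expected_solo,
            note="one flank unplaced" if one_side else "flanks unplaced or ambiguous",
        )

    chrom, left_end, right_start, strand = anchors.best
    gap = right_start - left_end
    qseq = query[chrom] if strand == "+" else revcomp(query[chrom])
    call = PolymorphismCall(
        locus.locus_id, assembly_id, LocusStatus.UNDETERMINED,
        observed_gap=gap, expected_full=expected_full, expected_solo=expected_solo,
    )
    if abs(gap - expected_full) <= tol(expected_full):
        call.status = LocusStatus.SHARED_FULL
    elif abs(gap - expected_solo) <= tol(expected_solo):
        call.status = LocusStatus.SOLO_LTR
    elif abs(gap) <= max(50.0, float(t)):
        passed, low = verify_empty_site(locus.tsd_seq, qseq, right_start)
        call.status = LocusStatus.PRECISE_ABSENCE
        call.tsd_evidence = passed
        call.low_evidence = low or not passed
        if not passed:
            call.note = "empty-site TSD check failed"
    else:
        call.note = f"gap {gap} matches no expected state"
    return call


def status_for_locus(
    locus: ReferenceLocus,
    reference: Genome,
    query: Genome,
    model: ErvFamilyModel,
    assembly_id: str = "",
    flank: int = 50_000,
    min_anchor: int = 200,
    tolerance: float | None = None,
    query_rc: Genome | None = None,
) -> PolymorphismCall:
    """extract_locus + anchor_flanks + classify_locus for one (locus, assembly)."""
    left, _mid, right = extract_locus(reference, locus, flank=flank)
    if len(left) < min_anchor or len(right) < min_anchor:
        return PolymorphismCall(
            locus.locus_id, assembly_id, LocusStatus.UNDETERMINED,
            note="insufficient flank in reference",
        )
    anchors = anchor_flanks(
        left, right, query, min_anchor=min_anchor,
        max_offset=locus.element_len + locus.tsd_len + 10_000,
        query_rc=query_rc,
    )
    return classify_locus(locus, anchors, query, model, assembly_id, tolerance)


def polymorphism_matrix(
    loci: list[ReferenceLocus],
    reference: Genome,
    assemblies: dict[str, Genome],
    model: ErvFamilyModel,
    flank: int = 50_000,
    min_anchor: int = 200,
    tolerance: float | None = None,
    include_reference: bool = True,
) -> tuple[pd.DataFrame, list[PolymorphismCall]]:
    """Status matrix (loci x assemblies) plus the underlying evidence calls.

    A locus is polymorphic iff at least two distinct statuses occur among its
    determinable cells (UNDETERMINED and LOCUS_DELETED cells are excluded
    from that determination). The returned frame carries a boolean
    ``polymorphic`` column.
    """
    columns = (["reference"] if include_reference else []) + list(assemblies)
    rows = {}
    evidence: list[PolymorphismCall] = []
    genomes = {**({"reference": reference} if include_reference else {}), **assemblies}
    genomes_rc = {
        asm: {c: revcomp(s) for c, s in g.items()} for asm, g in genomes.items()
    }
    for locus in loci:
        row = {}
        for asm in columns:
            call = status_for_locus(
                locus, reference, genomes[asm], model, assembly_id=asm,
                flank=flank, min_anchor=min_anchor, tolerance=tolerance,
                query_rc=genomes_rc[asm],
            )
            evidence.append(call)
            row[asm] = call.status.value
        determinable = {
            s for s in row.values()
            if s not in (LocusStatus.UNDETERMINED.value, LocusStatus.LOCUS_DELETED.value)
        }
        row["polymorphic"] = len(determinable) >= 2
        rows[locus.locus_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "locus_id"
    return df, evidence


def loci_from_truth(truth: pd.DataFrame, genome_id: str = "reference") -> list[ReferenceLocus]:
    """Occupied reference loci from a synthetic truth table."""
    occupied = truth[
        (truth["genome_id"] == genome_id)
        & truth["structure_class"].isin(["FULL_PROVIRUS", "SOLO_LTR", "TRUNCATED"])
    ]
    return [
        ReferenceLocus(
            locus_id=r.locus_id, chrom=r.chrom, start=int(r.start), end=int(r.end),
            strand=r.strand, tsd_seq=r.tsd_seq, structure_class=r.structure_class,
        )
        for r in occupied.itertuples()
    ]


def loci_from_calls(calls, genome: Genome) -> list[ReferenceLocus]:
    """Occupied loci from annotator insertion calls (uses detected TSDs)."""
    out = []
    for c in calls:
        out.append(
            ReferenceLocus(
                locus_id=c.locus_id, chrom=c.chrom, start=c.start, end=c.end,
                strand=c.strand, tsd_seq=c.tsd[0] if c.tsd else "",
                structure_class=c.structure_class,
            )
        )
    return out
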