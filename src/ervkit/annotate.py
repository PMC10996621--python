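"""Repeat-hit scanning, defragmentation into insertion calls, and TSDs.

The scanner is a k-mer-anchored, ungapped extend-and-trim matcher adequate
for desk-scale genomes whose copies diverge by substitutions; production runs
on real assemblies can instead feed RepeatMasker ``.out`` tables through
:func:`read_repeatmasker_out` — downstream stages only see
:class:`TeFragmentHit` rows either way.

Defragmentation merges per-fragment hits that are colinear in both genome
and consensus into one :class:`InsertionCall` per insertion, mirroring how
fragmented repeat annotations are reconstructed into LTR+internal+LTR units
before phylogenetic analysis.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .models import FULL_PROVIRUS, SOLO_LTR, TRUNCATED, ErvFamilyModel
from .seq import revcomp

Genome = dict[str, str]


@dataclass
class TeFragmentHit:
    chrom: str
    start: int  # 0-based half-open genomic interval
    end: int
    strand: str
    family_name: str
    part: str  # LTR | INTERNAL
    consensus_start: int  # 0-based half-open interval on the part consensus
    consensus_end: int
    divergence_pct: float = 0.0
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("hit start must be < end")
        if self.part not in ("LTR", "INTERNAL"):
            raise ValueError(f"unknown part {self.part!r}")


@dataclass
class InsertionCall:
    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str
    family_name: str
    structure_class: str = ""
    components: list[TeFragmentHit] = field(default_factory=list)
    tsd: tuple[str, tuple[int, int], tuple[int, int]] | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

_MISMATCH_PENALTY = 3  # trim score: match +1, mismatch -3


def scan_hits(
    genome: Genome,
    model: ErvFamilyModel,
    min_seed_kmer: int = 15,
    min_hit_len: int = 50,
    max_divergence: float = 0.15,
) -> list[TeFragmentHit]:
    """Find LTR/internal fragments of the family on both strands.

    Seeds are exact ``min_seed_kmer``-mers shared with the consensus part
    (or its reverse complement); each seeded diagonal is extended without
    gaps across the part and trimmed to its maximum-scoring run. Hits shorter
    than ``min_hit_len`` or more diverged than ``max_divergence`` are dropped.
    """
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("empty genome")
    k = min_seed_kmer
    targets: list[tuple[str, str, str]] = []  # (part, strand, oriented seq)
    for part in ("LTR", "INTERNAL"):
        pseq = model.part_seq(part)
        if len(pseq) <= k:
            raise ValueError("model part shorter than min_seed_kmer")
        targets.append((part, "+", pseq))
        targets.append((part, "-", revcomp(pseq)))

    index: dict[str, list[tuple[int, int]]] = defaultdict(list)  # kmer -> (target idx, pos)
    for ti, (_, _, tseq) in enumerate(targets):
        for i in range(len(tseq) - k + 1):
            index[tseq[i : i + k]].append((ti, i))
    index = dict(index)

    hits: list[TeFragmentHit] = []
    for chrom, seq in genome.items():
        diagonals: dict[tuple[int, int], int] = {}  # (target idx, diag) -> seed count
        n = len(seq)
        for i in range(n - k + 1):
            entry = index.get(seq[i : i + k])
            if entry is None:
                continue
            for ti, mpos in entry:
                key = (ti, i - mpos)
                diagonals[key] = diagonals.get(key, 0) + 1
        for (ti, diag), _count in diagonals.items():
            part, strand, tseq = targets[ti]
            m_lo = max(0, -diag)
            m_hi = min(len(tseq), n - diag)
            if m_hi - m_lo < min_hit_len:
                continue
            best = _best_run(seq, tseq, diag, m_lo, m_hi)
            if best is None:
                continue
            m1, m2, mismatches = best
            # terminal-mismatch rescue: a complete copy whose outermost bases
            # are mutated would otherwise be trimmed; if the whole diagonal
            # overlap stays within the divergence ceiling and the trimmed run
            # already covers most of it, report the full overlap
            full_mism = sum(
                1 for m in range(m_lo, m_hi) if seq[diag + m] != tseq[m]
            )
            if (
                full_mism <= max_divergence * (m_hi - m_lo)
                and (m2 - m1) >= 0.8 * (m_hi - m_lo)
            ):
                m1, m2, mismatches = m_lo, m_hi, full_mism
            length = m2 - m1
            if length < min_hit_len:
                continue
            div = mismatches / length
            if div > max_divergence:
                continue
            if strand == "+":
                c_start, c_end = m1, m2
            else:
                c_start, c_end = len(tseq) - m2, len(tseq) - m1
            hits.append(
                TeFragmentHit(
                    chrom=chrom,
                    start=diag + m1,
                    end=diag + m2,
                    strand=strand,
                    family_name=model.family_name,
                    part=part,
                    consensus_start=c_start,
                    consensus_end=c_end,
                    divergence_pct=100.0 * div,
                    score=float(length - (1 + _MISMATCH_PENALTY) * mismatches),
                )
            )
    return _dedup_overlaps(hits)


def _best_run(seq: str, target: str, diag: int, m_lo: int, m_hi: int):
    """Maximum-scoring ungapped run (Kadane; match +1, mismatch -3).

    Returns (start, end, mismatches) in target coordinates, or None.
    """
    best_score = 0.0
    best = None
    score = 0.0
    run_start = m_lo
    mism = 0
    best_mism = 0
    for m in range(m_lo, m_hi):
        s = 1 if seq[diag + m] == target[m] else -_MISMATCH_PENALTY
        if score <= 0:
            score = 0
            run_start = m
            mism = 0
        score += s
        if s < 0:
            mism += 1
        if score > best_score:
            best_score = score
            best = (run_start, m + 1)
            best_mism = mism
    if best is None:
        return None
    return best[0], best[1], best_mism


def _dedup_overlaps(hits: list[TeFragmentHit]) -> list[TeFragmentHit]:
    """Drop hits mostly contained in a higher-scoring hit of the same part."""
    hits = sorted(hits, key=lambda h: (h.chrom, h.part, -h.score))
    kept: list[TeFragmentHit] = []
    for h in hits:
        redundant = False
        for other in kept:
            if other.chrom != h.chrom or other.part != h.part:
                continue
            ov = min(h.end, other.end) - max(h.start, other.start)
            if ov > 0.5 * (h.end - h.start):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    kept.sort(key=lambda h: (h.chrom, h.start))
    return kept


# ---------------------------------------------------------------------------
# RepeatMasker .out input
# ---------------------------------------------------------------------------


def read_repeatmasker_out(
    path: str,
    family_name: str,
    ltr_names: set[str] | None = None,
    internal_names: set[str] | None = None,
) -> list[TeFragmentHit]:
    """Parse a RepeatMasker ``.out`` table into fragment hits.

    Columns used: SW score, % divergence, query name, query begin/end
    (1-based inclusive -> converted to 0-based half-open), strand (``+`` or
    ``C``), repeat name, and position-in-repeat begin/end (order swapped on
    ``C`` lines per RepeatMasker convention). Rows flagged with a trailing
    ``*`` (overlap with a higher-scoring match) are deduplicated, keeping the
    higher score. Repeat names ending in ``-int``/``_I`` map to the INTERNAL
    part by default; anything else containing the family name maps to LTR.
    """
    raw: list[TeFragmentHit] = []
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if not fields or not fields[0].isdigit():
                continue  # header / blank
            score = float(fields[0])
            div = float(fields[1])
            chrom = fields[4]
            qstart = int(fields[5]) - 1
            qend = int(fields[6])
            strand = "+" if fields[8] == "+" else "-"
            rname = fields[9]
            if strand == "+":
                rbegin, rend = int(fields[11]), int(fields[12])
            else:
                rbegin, rend = int(fields[13]), int(fields[12])
            starred = fields[-1] == "*"
            if internal_names and rname in internal_names:
                part = "INTERNAL"
            elif ltr_names and rname in ltr_names:
                part = "LTR"
            elif rname.endswith(("-int", "_I", "-I")):
                part = "INTERNAL"
            else:
                part = "LTR"
            if family_name not in rname:
                continue
            hit = TeFragmentHit(
                chrom=chrom,
                start=qstart,
                end=qend,
                strand=strand,
                family_name=family_name,
                part=part,
                consensus_start=rbegin - 1,
                consensus_end=rend,
                divergence_pct=div,
                score=score,
            )
            hit._starred = starred  # type: ignore[attr-defined]
            raw.append(hit)
    return _dedup_starred(raw)


def _dedup_starred(hits: list[TeFragmentHit]) -> list[TeFragmentHit]:
    out: list[TeFragmentHit] = []
    for h in sorted(hits, key=lambda h: (h.chrom, h.start, -h.score)):
        if getattr(h, "_starred", False) and out:
            prev = out[-1]
            if prev.chrom == h.chrom and min(prev.end, h.end) > max(prev.start, h.start):
                if h.score > prev.score:
                    out[-1] = h
                continue
        out.append(h)
    return out


# ---------------------------------------------------------------------------
# defragmentation and classification
# ---------------------------------------------------------------------------

_CONSENSUS_SLACK = 40  # bp of tolerated consensus overlap between merged fragments


def defragment(hits: list[TeFragmentHit], max_merge_gap: int = 500) -> list[InsertionCall]:
    """Merge colinear same-strand fragments into insertion calls.

    Fragments on one chromosome and strand separated by at most
    ``max_merge_gap`` bp are merged when their element-sense part order is
    consistent (5'LTR -> internal -> 3'LTR; internal pieces must advance
    along the consensus). Two LTRs are never merged without an intervening
    internal fragment, which keeps tandem solo LTRs separate. Every hit ends
    up in exactly one call.
    """
    groups: dict[tuple[str, str, str], list[TeFragmentHit]] = defaultdict(list)
    for h in hits:
        groups[(h.chrom, h.strand, h.family_name)].append(h)

    calls: list[InsertionCall] = []
    for (chrom, strand, family), ghits in sorted(groups.items()):
        ghits.sort(key=lambda h: h.start)
        ordered = ghits if strand == "+" else list(reversed(ghits))  # element sense
        current: list[TeFragmentHit] = []
        for h in ordered:
            if current and _can_extend(current, h, max_merge_gap):
                current.append(h)
            else:
                if current:
                    calls.append(_make_call(chrom, strand, family, current))
                current = [h]
        if current:
            calls.append(_make_call(chrom, strand, family, current))

    calls.sort(key=lambda c: (c.chrom, c.start))
    for i, c in enumerate(calls):
        c.locus_id = c.locus_id or f"call{i:04d}"
    return calls


def _genomic_gap(a: TeFragmentHit, b: TeFragmentHit) -> int:
    return max(a.start, b.start) - min(a.end, b.end)


def _can_extend(current: list[TeFragmentHit], nxt: TeFragmentHit, max_gap: int) -> bool:
    prev = current[-1]
    if _genomic_gap(prev, nxt) > max_gap:
        return False
    parts = [h.part for h in current]
    closed = "INTERNAL" in parts and parts[-1] == "LTR" and parts.index("INTERNAL") < len(parts) - 1
    if closed:
        return False
    if prev.part == "LTR" and nxt.part == "LTR":
        return False  # tandem solo LTRs / back-to-back elements
    if prev.part == "INTERNAL" and nxt.part == "INTERNAL":
        # in element-sense iteration, consensus coordinates must advance on
        # either strand (minus-strand groups are already iterated right-to-left)
        return nxt.consensus_start >= prev.consensus_end - _CONSENSUS_SLACK
    return True  # LTR->INTERNAL or INTERNAL->LTR


def _make_call(chrom: str, strand: str, family: str, comps: list[TeFragmentHit]) -> InsertionCall:
    comps = sorted(comps, key=lambda h: h.start)
    call = InsertionCall(
        locus_id="",
        chrom=chrom,
        start=comps[0].start,
        end=comps[-1].end,
        strand=strand,
        family_name=family,
        components=comps,
    )
    call.structure_class = classify(call)
    return call


def classify(call: InsertionCall) -> str:
    """LTR+INTERNAL(+)+LTR -> FULL_PROVIRUS; lone LTR -> SOLO_LTR; else TRUNCATED."""
    if not call.components:
        raise ValueError("call has no components")
    families = {h.family_name for h in call.components}
    if len(families) > 1:
        raise ValueError(f"mixed families within one call: {sorted(families)}")
    comps = sorted(call.components, key=lambda h: h.start)
    if call.strand == "-":
        comps = list(reversed(comps))  # element sense
    parts = [h.part for h in comps]
    if parts == ["LTR"]:
        return SOLO_LTR
    if (
        len(parts) >= 3
        and parts[0] == "LTR"
        and parts[-1] == "LTR"
        and all(p == "INTERNAL" for p in parts[1:-1])
    ):
        return FULL_PROVIRUS
    return TRUNCATED


def length_filter(
    calls: list[InsertionCall], min_len: int, max_len: int
) -> list[InsertionCall]:
    """Keep calls with min_len <= span <= max_len (order preserved)."""
    if min_len < 0 or max_len < 0:
        raise ValueError("length bounds must be non-negative")
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    return [c for c in calls if min_len <= c.length <= max_len]


def detect_tsd(
    genome: Genome, call: InsertionCall, min_tsd: int = 2, max_tsd: int = 20
) -> tuple[str, int] | None:
    """Longest exact duplication flanking the call within [min_tsd, max_tsd].

    Returns ``(tsd_seq, k)`` for the largest k such that the k bp immediately
    5' of the call equal the k bp immediately 3' of it; None if no k
    qualifies or the call sits too close to a chromosome edge.
    """
    seq = genome[call.chrom]
    if call.start < min_tsd or call.end + min_tsd > len(seq):
        warnings.warn(f"{call.locus_id}: insufficient flank for TSD detection")
        return None
    limit = min(max_tsd, call.start, len(seq) - call.end)
    for k in range(limit, min_tsd - 1, -1):
        left = seq[call.start - k : call.start]
        right = seq[call.end : call.end + k]
        if left == right:
            call.tsd = (left, (call.start - k, call.start), (call.end, call.end + k))
            return left, k
    return None


def census(calls: list[InsertionCall], hits: list[TeFragmentHit] | None = None) -> dict:
    """Summary counts per structure class and per family.

    Reports both merged-call counts and (when given) the raw fragment-hit
    count, since a published "insertion count" may refer to either unit.
    """
    by_class = Counter(c.structure_class for c in calls)
    by_family = Counter(c.family_name for c in calls)
    out = {
        "n_calls": len(calls),
        "by_class": {k: by_class.get(k, 0) for k in (FULL_PROVIRUS, SOLO_LTR, TRUNCATED)},
        "by_family": dict(by_family),
    }
    if hits is not None:
        out["n_raw_hits"] = len(hits)
    return out


def call_sequences(genome: Genome, calls: list[InsertionCall]) -> dict[str, str]:
    """Element-sense sequence of each call (minus-strand calls reverse-complemented)."""
    out = {}
    for c in calls:
        s = genome[c.chrom][c.start : c.end]
        out[c.locus_id] = s if c.strand == "+" else revcomp(s)
    return out


def calls_table(calls: list[InsertionCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "locus_id": c.locus_id,
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "strand": c.strand,
                "family_name": c.family_name,
                "structure_class": c.structure_class,
                "n_components": len(c.components),
                "tsd_seq": c.tsd[0] if c.tsd else "",
            }
        )
    return pd.DataFrame(rows)
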