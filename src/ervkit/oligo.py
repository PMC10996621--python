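"""Antisense-oligonucleotide target enumeration over family copies.

An antisense oligo (locked nucleic acid gapmer or morpholino) is written
5'->3' antisense to the target transcript; the genomic site it can act on is
therefore the reverse complement of the oligo, searched on the element-sense
strand of every copy. Matching is substitution-only: a copy is a target when
the site occurs with at most ``max_mismatches`` mismatches. The chemistry
label is metadata — LNA gapmers degrade the transcript, morpholinos block
translation — but the sequence computation is identical.

Module constants carry the published oligos used against the zebrafish
BHIKHARI (Bik-1/Bik-2) ERV families, handy as worked examples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .seq import check_dna, revcomp

# Published reagents targeting the zebrafish Bik families (5'->3', antisense).
BIK1_LNA = "GGTGACGACTGGCAAAGATGAC"  # 22 nt, targets the LTR near the TSS
BIK1_MO = "GTCTTTGGGGTGAGCCATGTTTTGC"  # 25 nt, translation-blocking
BIK2_MO = "GGGAAGACCTATAACTGACACTGAC"  # 25 nt, translation-blocking


@dataclass(frozen=True)
class OligoQuery:
    name: str
    sequence: str  # 5'->3', antisense to the target mRNA
    chemistry: str = "LNA"  # LNA | MO
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        check_dna(self.sequence, f"oligo {self.name}")
        if len(self.sequence) < 12:
            raise ValueError("oligo must be at least 12 nt")
        if self.chemistry not in ("LNA", "MO"):
            raise ValueError("chemistry must be LNA or MO")


@dataclass
class OligoTargetReport:
    oligo: str
    target_site: str
    max_mismatches: int
    hit_positions: dict[str, list[int]]  # locus -> site start positions (element sense)
    n_total: int
    n_targeted: int
    n_proviral_targeted: int
    n_full_gag_targeted: int
    fraction_targeted: float
    truncated_candidates: list[str] = field(default_factory=list)


def target_site(oligo: OligoQuery | str) -> str:
    """Sense-strand site bound by the oligo: its reverse complement."""
    seq = oligo.sequence if isinstance(oligo, OligoQuery) else oligo
    check_dna(seq, "oligo")
    return revcomp(seq)


def find_sites(seq: str, site: str, max_mismatches: int = 0) -> list[int]:
    """Start positions where ``site`` occurs with <= max_mismatches substitutions."""
    w = len(site)
    out = []
    for i in range(len(seq) - w + 1):
        mism = 0
        for a, b in zip(seq[i : i + w], site):
            if a != b:
                mism += 1
                if mism > max_mismatches:
                    break
        else:
            out.append(i)
    return out


def count_targets(
    oligo: OligoQuery,
    call_seqs: dict[str, str],
    max_mismatches: int | None = None,
    structure_class: dict[str, str] | None = None,
    gag_intact: dict[str, bool] | None = None,
) -> OligoTargetReport:
    """Which copies does the oligo hit, broken down by structure class?

    ``call_seqs`` maps locus id to element-sense sequence. Copies shorter
    than the site are listed separately as truncated candidates (their
    annotation cannot contain the site at all).
    """
    m = oligo.max_mismatches if max_mismatches is None else max_mismatches
    site = target_site(oligo)
    hits: dict[str, list[int]] = {}
    truncated: list[str] = []
    for locus, seq in call_seqs.items():
        if len(seq) < len(site):
            truncated.append(locus)
            continue
        pos = find_sites(seq, site, m)
        if pos:
            hits[locus] = pos
    structure_class = structure_class or {}
    gag_intact = gag_intact or {}
    n_prov = sum(1 for l in hits if structure_class.get(l) == "FULL_PROVIRUS")
    n_gag = sum(
        1 for l in hits
        if structure_class.get(l) == "FULL_PROVIRUS" and gag_intact.get(l, False)
    )
    n_total = len(call_seqs)
    return OligoTargetReport(
        oligo=oligo.name,
        target_site=site,
        max_mismatches=m,
        hit_positions=hits,
        n_total=n_total,
        n_targeted=len(hits),
        n_proviral_targeted=n_prov,
        n_full_gag_targeted=n_gag,
        fraction_targeted=len(hits) / n_total if n_total else 0.0,
        truncated_candidates=truncated,
    )


def genes_near_insertions(
    genes: pd.DataFrame,
    calls,
    distance: int = 10_000,
    de_table: pd.DataFrame | None = None,
    padj_cutoff: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Genes lying within ``distance`` bp of any insertion call.

    ``genes`` needs columns chrom/start/end/name (BED-like, 0-based
    half-open). The gap is measured between closest interval edges (overlap
    = 0); a gene is reported when its minimal gap is <= ``distance``. The
    optional DE table (gene_id, log2fc, padj) adds direction flags. Genes on
    chromosomes with no calls are returned in the second element rather than
    silently dropped.
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append((c.start, c.end, c.locus_id))
    unmatched: list[str] = []
    rows = []
    for g in genes.itertuples():
        name = getattr(g, "name", f"{g.chrom}:{g.start}-{g.end}")
        if g.chrom not in by_chrom:
            unmatched.append(name)
            continue
        best_gap = None
        best_locus = None
        for start, end, locus in by_chrom[g.chrom]:
            if end <= g.start:
                gap = g.start - end
            elif g.end <= start:
                gap = start - g.end
            else:
                gap = 0
            if best_gap is None or gap < best_gap:
                best_gap, best_locus = gap, locus
        if best_gap is not None and best_gap <= distance:
            rows.append(
                {
                    "gene": name,
                    "chrom": g.chrom,
                    "start": g.start,
                    "end": g.end,
                    "distance": best_gap,
                    "nearest_locus": best_locus,
                }
            )
    df = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "distance", "nearest_locus"])
    if de_table is not None and len(df):
        de = de_table.set_index("gene_id")
        df["log2fc"] = [de["log2fc"].get(g) for g in df["gene"]]
        df["padj"] = [de["padj"].get(g) for g in df["gene"]]
        def direction(row):
            if pd.isna(row["log2fc"]) or pd.isna(row["padj"]) or row["padj"] > padj_cutoff:
                return "ns"
            return "down" if row["log2fc"] < 0 else "up"
        df["de_direction"] = df.apply(direction, axis=1)
    return df, unmatched
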