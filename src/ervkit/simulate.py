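"""Synthetic genomes with planted ERV insertions and derived strain genomes.

The generator emulates the genomic record left by a recently active LTR
retroelement family: full proviruses with perfect target-site duplications
(TSDs), solo LTRs produced by LTR-LTR recombination, truncated fragments,
optional one-level nested insertions, and derived "strain" genomes that
differ from the reference by precise absences, solo-LTR conversions and
larger locus deletions. Every planted event is recorded in a truth table
(one row per locus per genome, 0-based half-open coordinates) that serves as
the oracle for every downstream stage.

Coordinate conventions for an insertion planted at point ``p`` with TSD
length ``t``: the ``t`` bp originally at ``p`` (site sequence ``S``) appear
duplicated on both flanks, so the modified chromosome reads
``...left | S | element | S | right...`` and the truth row spans the element
only; the left TSD copy sits at ``[start-t, start)`` and the right copy at
``[end, end+t)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gag import consensus_gag_orf
from .io import TRUTH_COLUMNS
from .models import (
    ABSENT,
    DELETED,
    FULL_PROVIRUS,
    SOLO_LTR,
    TRUNCATED,
    ErvFamilyModel,
)
from .seq import mutate, random_dna, revcomp, translate

Genome = dict[str, str]


@dataclass
class PlantEvent:
    """One insertion to plant.

    ``position`` is the 0-based insertion point in the genome as it stands
    when the event is applied (events are applied sequentially, which is what
    makes one-level nesting possible: a later event may land inside an
    earlier element). ``truncation`` is a half-open interval of element
    coordinates removed before planting; removing exactly one LTR plus the
    internal region plants a solo LTR.
    """

    chrom: str
    position: int
    divergence: float = 0.0
    truncation: tuple[int, int] | None = None
    tsd_len_used: int | None = None
    strand: str = "+"
    seed: int = 0
    locus_id: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.divergence < 0.5:
            raise ValueError("divergence must be in [0, 0.5)")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass
class StrainEvent:
    """One change applied to a reference locus when deriving a strain.

    kinds: ABSENT_PRECISE (restore the pre-integration site, leaving exactly
    one TSD copy), SOLO_LTR_CONVERSION (collapse a provirus to one LTR, both
    TSD copies retained), LOCUS_DELETION (remove the element, one TSD copy
    and ``deletion_span`` bp of flanking sequence), NOVEL_INSERTION (plant a
    fresh insertion present only in the strain; ``novel`` holds the event).
    """

    locus_id: str
    kind: str
    deletion_span: int | None = None
    novel: PlantEvent | None = None

    KINDS = ("ABSENT_PRECISE", "SOLO_LTR_CONVERSION", "LOCUS_DELETION", "NOVEL_INSERTION")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown strain event kind {self.kind!r}")
        if self.kind == "LOCUS_DELETION" and not self.deletion_span:
            raise ValueError("LOCUS_DELETION requires deletion_span")
        if self.kind == "NOVEL_INSERTION" and self.novel is None:
            raise ValueError("NOVEL_INSERTION requires a PlantEvent")


def empty_truth() -> pd.DataFrame:
    return pd.DataFrame(columns=TRUTH_COLUMNS)


def make_random_genome(
    n_chroms: int, lengths: list[int], gc: float = 0.4, seed: int = 0
) -> Genome:
    """Random i.i.d. genome; chromosome names chr1..chrN; deterministic per seed."""
    if len(lengths) != n_chroms:
        raise ValueError("lengths must have n_chroms entries")
    if any(n <= 0 for n in lengths):
        raise ValueError("chromosome lengths must be positive")
    rng = np.random.default_rng(seed)
    return {f"chr{i + 1}": random_dna(n, gc, rng) for i, n in enumerate(lengths)}


def _structure_class(model: ErvFamilyModel, truncation: tuple[int, int] | None) -> str:
    if truncation is None:
        return FULL_PROVIRUS
    a, b = truncation
    L, E = model.ltr_len, model.element_len
    if not (0 <= a < b <= E):
        raise ValueError("truncation interval outside element coordinates")
    if b - a == E:
        raise ValueError("truncation removes the entire element")
    # kept = element[:a] + element[b:]; a single complete LTR means solo
    if (a == 0 and b == E - L) or (a == L and b == E):
        return SOLO_LTR
    return TRUNCATED


def _gag_intact(model: ErvFamilyModel, mutated_element: str, structure: str) -> bool:
    """Truth-side Gag check: canonical frame read directly from the planted copy."""
    if structure != FULL_PROVIRUS or model.expected_gag_aa <= 0:
        return False
    orf = consensus_gag_orf(model)
    region = mutated_element[model.ltr_len + orf.start : model.ltr_len + orf.end]
    if not region.startswith("ATG"):
        return False
    prot = translate(region)
    first_stop = prot.find("*")
    plen = first_stop if first_stop >= 0 else len(prot)
    return plen >= 0.95 * model.expected_gag_aa


def plant_insertion(
    genome: Genome,
    model: ErvFamilyModel,
    event: PlantEvent,
    truth: pd.DataFrame | None = None,
    genome_id: str = "reference",
) -> tuple[Genome, pd.DataFrame]:
    """Plant one insertion; returns the modified genome and updated truth table.

    Existing truth rows on the same chromosome are shifted (or extended, for a
    row spanning the insertion point — the nested case) so that coordinates
    remain valid after the edit.
    """
    if event.chrom not in genome:
        raise ValueError(f"chromosome {event.chrom!r} not in genome")
    seq = genome[event.chrom]
    if not 0 <= event.position <= len(seq):
        raise ValueError("insertion position out of range")
    t = model.tsd_len if event.tsd_len_used is None else event.tsd_len_used
    if event.position + t > len(seq):
        raise ValueError("insertion point too close to chromosome end for the TSD")

    structure = _structure_class(model, event.truncation)
    element = model.element_seq
    if event.truncation is not None:
        a, b = event.truncation
        element = element[:a] + element[b:]
    rng = np.random.default_rng(event.seed)
    mutated, _ = mutate(element, event.divergence, rng)
    gag_ok = _gag_intact(model, mutated, structure)
    inserted = mutated if event.strand == "+" else revcomp(mutated)

    p = event.position
    site = seq[p : p + t]
    new_seq = seq[: p + t] + inserted + seq[p:]
    out = dict(genome)
    out[event.chrom] = new_seq

    truth = empty_truth() if truth is None else truth.copy()
    start = p + t
    end = start + len(inserted)
    shift = len(inserted) + t
    if len(truth):
        on_chrom = (truth["chrom"] == event.chrom) & (truth["genome_id"] == genome_id)
        after = on_chrom & (truth["start"] >= p)
        spanning = on_chrom & (truth["start"] < p) & (truth["end"] > p)
        truth.loc[after, ["start", "end"]] += shift
        truth.loc[spanning, "end"] += shift
    locus = event.locus_id or f"L{len(truth):04d}"
    row = {
        "locus_id": locus,
        "genome_id": genome_id,
        "chrom": event.chrom,
        "start": start,
        "end": end,
        "strand": event.strand,
        "structure_class": structure,
        "tsd_seq": site,
        "divergence": event.divergence,
        "gag_intact": gag_ok,
    }
    if len(truth):
        truth = pd.concat([truth, pd.DataFrame([row])], ignore_index=True)
    else:
        truth = pd.DataFrame([row], columns=TRUTH_COLUMNS)
    return out, truth


def plant_many(
    genome: Genome,
    model: ErvFamilyModel,
    events: list[PlantEvent],
    genome_id: str = "reference",
    truth: pd.DataFrame | None = None,
) -> tuple[Genome, pd.DataFrame]:
    for ev in events:
        genome, truth = plant_insertion(genome, model, ev, truth, genome_id)
    return genome, truth


def derive_strain(
    reference: Genome,
    truth: pd.DataFrame,
    events: list[StrainEvent],
    seed: int,
    strain_id: str,
    model: ErvFamilyModel,
    reference_id: str = "reference",
) -> tuple[Genome, pd.DataFrame]:
    """Apply strain events to a copy of the reference; returns strain genome
    plus truth rows for the strain (coordinates in strain space).

    Events must name distinct loci. Locus edits are applied right-to-left per
    chromosome so earlier coordinates are undisturbed; novel insertions are
    applied last, their positions interpreted in the edited strain genome.
    """
    ref_rows = truth[truth["genome_id"] == reference_id]
    rows = [dict(r) for _, r in ref_rows.iterrows()]
    for r in rows:
        r["genome_id"] = strain_id
    by_locus = {r["locus_id"]: r for r in rows}

    locus_events = [e for e in events if e.kind != "NOVEL_INSERTION"]
    novel_events = [e for e in events if e.kind == "NOVEL_INSERTION"]
    seen: set[str] = set()
    for e in locus_events:
        if e.locus_id not in by_locus:
            raise ValueError(f"unknown locus_id {e.locus_id!r}")
        if e.locus_id in seen:
            raise ValueError(f"multiple events on locus {e.locus_id!r}")
        seen.add(e.locus_id)

    genome = dict(reference)
    # right-to-left per chromosome
    for e in sorted(locus_events, key=lambda e: -by_locus[e.locus_id]["start"]):
        row = by_locus[e.locus_id]
        chrom, start, end = row["chrom"], row["start"], row["end"]
        t = len(row["tsd_seq"])
        seq = genome[chrom]
        if e.kind == "ABSENT_PRECISE":
            # remove element + one TSD copy -> restores pre-integration site
            new_seq = seq[:start] + seq[end + t :]
            delta = -(end - start + t)
            row.update(start=start - t, end=start, structure_class=ABSENT,
                       gag_intact=False)
        elif e.kind == "SOLO_LTR_CONVERSION":
            if row["structure_class"] != FULL_PROVIRUS:
                raise ValueError("SOLO_LTR_CONVERSION requires a FULL_PROVIRUS locus")
            L = model.ltr_len
            # recombination between the two LTRs leaves a single LTR; keep the
            # genomic-left realized LTR copy, both TSD copies untouched
            new_seq = seq[: start + L] + seq[end:]
            delta = -(end - start - L)
            row.update(end=start + L, structure_class=SOLO_LTR, gag_intact=False)
        elif e.kind == "LOCUS_DELETION":
            span = int(e.deletion_span)
            dl, dr = span // 2, span - span // 2
            lo = max(0, start - dl)
            hi = min(len(seq), end + t + dr)
            new_seq = seq[:lo] + seq[hi:]
            delta = -(hi - lo)
            row.update(start=lo, end=lo, structure_class=DELETED, gag_intact=False)
        else:  # pragma: no cover
            raise AssertionError(e.kind)
        genome[chrom] = new_seq
        for other in rows:
            if other is row or other["chrom"] != chrom:
                continue
            if other["start"] >= end:
                other["start"] += delta
                other["end"] += delta

    strain_truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    if novel_events:
        rng = np.random.default_rng(seed)
        for e in novel_events:
            ev = e.novel
            if ev.locus_id is None:
                ev = replace(ev, locus_id=e.locus_id)
            genome, strain_truth = plant_insertion(
                genome, model, ev, strain_truth, genome_id=strain_id
            )
    return genome, strain_truth


# ---------------------------------------------------------------------------
# Synthetic family construction and the standard benchmark study
# ---------------------------------------------------------------------------


def _scrub_atg(seq: str) -> str:
    """Remove every ATG trimer so a region cannot initiate an ORF."""
    while "ATG" in seq:
        seq = seq.replace("ATG", "ACG")
    return seq


def make_family_model(
    seed: int,
    family_name: str = "ERVsim-1",
    ltr_len: int = 1200,
    gag_aa: int = 617,
    utr5: int = 300,
    utr3: int = 300,
    gc: float = 0.45,
    tsd_len: int = 5,
) -> ErvFamilyModel:
    """Build a synthetic nonautonomous ERV consensus.

    The internal region carries a single long Gag ORF of ``gag_aa`` amino
    acids (ATG + non-stop codons + TAA) between ATG-free 5' UTR padding and a
    short 3' UTR, so the longest-ORF scan on the consensus recovers exactly
    the designed protein length.
    """
    rng = np.random.default_rng(seed)
    ltr = random_dna(ltr_len, gc, rng)
    utr5_seq = _scrub_atg(random_dna(utr5, gc, rng))
    sense = [c for c in _all_codons() if c not in ("TAA", "TAG", "TGA")]
    codons = rng.choice(len(sense), size=gag_aa - 1)
    orf = "ATG" + "".join(sense[i] for i in codons) + "TAA"
    utr3_seq = random_dna(utr3, gc, rng)
    internal = utr5_seq + orf + utr3_seq
    return ErvFamilyModel(
        family_name=family_name,
        ltr_seq=ltr,
        internal_seq=internal,
        tsd_len=tsd_len,
        expected_gag_aa=gag_aa,
    )


def _all_codons() -> list[str]:
    bases = "ACGT"
    return [a + b + c for a in bases for b in bases for c in bases]


@dataclass
class SimulatedStudy:
    """A reference genome, derived strains, and the complete truth table."""

    model: ErvFamilyModel
    reference: Genome
    strains: dict[str, Genome]
    truth: pd.DataFrame  # reference + strain rows
    strain_events: dict[str, list[StrainEvent]] = field(default_factory=dict)

    @property
    def reference_truth(self) -> pd.DataFrame:
        return self.truth[self.truth["genome_id"] == "reference"].reset_index(drop=True)


def simulate_study(
    seed: int,
    n_chroms: int = 4,
    chrom_len: int = 500_000,
    n_full: int = 40,
    n_solo: int = 15,
    n_trunc: int = 5,
    divergence_max: float = 0.02,
    tsd_len: int = 5,
    n_strains: int = 3,
    n_strain_events: int = 20,
    min_spacing: int = 15_000,
    edge_margin: int = 20_000,
) -> SimulatedStudy:
    """The standard benchmark: a 2-Mb reference carrying 60 planted insertions
    (40 full proviruses, 15 solo LTRs, 5 truncated; 5-bp TSDs; divergence
    uniform on [0, 2%]) and three strains with 20 planted status events.
    """
    rng = np.random.default_rng(seed)
    model = make_family_model(int(rng.integers(2**31)), tsd_len=tsd_len)
    reference = make_random_genome(
        n_chroms, [chrom_len] * n_chroms, gc=0.4, seed=int(rng.integers(2**31))
    )

    # stratified placement: one slot per insertion with jitter, so minimum
    # spacing holds by construction (spacing shrinks on small chromosomes)
    n_total = n_full + n_solo + n_trunc
    chroms = sorted(reference)
    positions: list[tuple[str, int]] = []
    per_chrom = int(np.ceil(n_total / n_chroms))
    margin = min(edge_margin, chrom_len // 10)
    usable = chrom_len - 2 * margin
    slot = usable // per_chrom
    if slot < 5000:  # room for one element plus anchorable flanks
        raise ValueError("chromosomes too short for the requested insertion count")
    jitter = max(0, slot - min(min_spacing, slot))
    for chrom in chroms:
        for i in range(per_chrom):
            if len(positions) >= n_total:
                break
            base = margin + i * slot
            pos = base + int(rng.integers(0, jitter + 1))
            positions.append((chrom, pos))
    positions = positions[:n_total]
    positions.sort()

    L, I, E = model.ltr_len, model.internal_len, model.element_len
    kinds = [FULL_PROVIRUS] * n_full + [SOLO_LTR] * n_solo + [TRUNCATED] * n_trunc
    rng.shuffle(kinds)

    events: list[PlantEvent] = []
    offsets: dict[str, int] = {c: 0 for c in chroms}
    idx = 0
    for (chrom, pos), kind in zip(positions, kinds):
        if kind == FULL_PROVIRUS:
            trunc = None
        elif kind == SOLO_LTR:
            trunc = (L, E)  # keep the 5' LTR
        else:
            # 5'-truncated copy: keep part of the internal region + 3' LTR
            cut = L + int(rng.integers(I // 4, I // 2))
            trunc = (0, cut)
        events.append(
            PlantEvent(
                chrom=chrom,
                position=pos + offsets[chrom],
                divergence=float(rng.uniform(0, divergence_max)),
                truncation=trunc,
                strand="+" if rng.random() < 0.5 else "-",
                seed=int(rng.integers(2**31)),
                locus_id=f"L{idx:04d}",
            )
        )
        inserted_len = E if trunc is None else E - (trunc[1] - trunc[0])
        offsets[chrom] += inserted_len + tsd_len
        idx += 1

    genome, truth = plant_many(reference, model, events, genome_id="reference")

    # distribute strain events; solo conversion only on full-provirus loci
    full_loci = list(truth.loc[truth["structure_class"] == FULL_PROVIRUS, "locus_id"])
    all_loci = list(truth["locus_id"])
    strains: dict[str, Genome] = {}
    strain_events: dict[str, list[StrainEvent]] = {}
    truths = [truth]
    base = n_strain_events // n_strains
    counts = [base + (1 if i < n_strain_events % n_strains else 0) for i in range(n_strains)]
    for s in range(n_strains):
        sid = f"strain{s + 1}"
        evs: list[StrainEvent] = []
        pick_full = [str(x) for x in rng.permutation(full_loci)]
        pick_any = [str(x) for x in rng.permutation(all_loci)]
        used: set[str] = set()
        kinds_cycle = ["ABSENT_PRECISE", "SOLO_LTR_CONVERSION", "LOCUS_DELETION"]
        k = 0
        while len(evs) < counts[s]:
            kind = kinds_cycle[k % 3]
            k += 1
            pool = pick_full if kind == "SOLO_LTR_CONVERSION" else pick_any
            locus = next((x for x in pool if x not in used), None)
            if locus is None:
                continue
            used.add(locus)
            evs.append(
                StrainEvent(
                    locus_id=locus,
                    kind=kind,
                    deletion_span=2000 if kind == "LOCUS_DELETION" else None,
                )
            )
        sg, st = derive_strain(
            genome, truth, evs, seed=int(rng.integers(2**31)), strain_id=sid, model=model
        )
        strains[sid] = sg
        strain_events[sid] = evs
        truths.append(st)

    combined = pd.concat(truths, ignore_index=True)
    return SimulatedStudy(
        model=model,
        reference=genome,
        strains=strains,
        truth=combined,
        strain_events=strain_events,
    )


def truth_bed6(truth: pd.DataFrame) -> list[tuple[str, int, int, str, float, str]]:
    """BED6 view of planted loci (score column carries percent divergence)."""
    return [
        (r.chrom, int(r.start), int(r.end), f"{r.locus_id}|{r.structure_class}",
         100.0 * float(r.divergence), r.strand)
        for r in truth.itertuples()
    ]
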