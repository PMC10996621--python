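"""End-to-end orchestration: simulate -> annotate -> gag -> recency ->
polymorphism -> oligo report, with a YAML-configurable run and a manifest.

Every stage communicates with the next only through its declared output
files / returned tables; all randomness flows from the single top-level seed
(per-stage generators are spawned deterministically), so two runs with the
same config are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import annotate as ann
from . import gag as gagmod
from . import oligo as oligomod
from . import polymorphism as poly
from . import recency as rec
from .io import sha256_file, write_bed6, write_fasta, write_truth_table
from .simulate import SimulatedStudy, simulate_study, truth_bed6

STAGES = ("simulate", "annotate", "gag", "recency", "polymorph", "oligo")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """All knobs of a pipeline run.

    Thresholds mirror the analysis defaults: length-filter window
    1000-8750 bp, recency threshold 0.01 substitutions/site, 10 kb
    cis-proximity, TSD search range 2-20 bp. Flank and anchor sizes default
    to desk-scale values suited to the simulated genomes; ``flank`` may be
    raised to 50 kb for real assemblies.
    """

    seed: int = 1
    outdir: str = "ervkit_run"
    # simulation
    n_chroms: int = 4
    chrom_len: int = 500_000
    n_full: int = 40
    n_solo: int = 15
    n_trunc: int = 5
    divergence_max: float = 0.02
    tsd_len: int = 5
    n_strains: int = 3
    n_strain_events: int = 20
    # annotation
    min_seed_kmer: int = 15
    min_hit_len: int = 50
    max_divergence: float = 0.15
    max_merge_gap: int = 500
    min_len: int = 1000
    max_len: int = 8750
    min_tsd: int = 2
    max_tsd: int = 20
    # gag
    intact_fraction: float = 0.95
    # recency
    recency_threshold: float = 0.01
    # polymorphism
    flank: int = 2000
    min_anchor: int = 300
    # oligo
    oligo_name: str = "demo-LNA"
    oligo_sequence: str = ""  # default: designed against the simulated LTR
    oligo_max_mismatches: int = 0
    proximity: int = 10_000

    def validate(self) -> None:
        positive = [
            "chrom_len", "min_seed_kmer", "min_hit_len", "max_merge_gap",
            "min_len", "max_len", "min_tsd", "max_tsd", "recency_threshold",
            "flank", "min_anchor", "proximity",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name!r} must be positive")
        if self.min_len > self.max_len:
            raise ValueError("config field 'min_len' must be <= 'max_len'")
        if not 0 < self.intact_fraction <= 1:
            raise ValueError("config field 'intact_fraction' must be in (0, 1]")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    unknown = set(data) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg


def demo_config(outdir: str = "ervkit_demo", seed: int = 1) -> RunConfig:
    """Small synthetic family, 2 strains — completes in seconds."""
    return RunConfig(
        seed=seed, outdir=outdir, n_chroms=2, chrom_len=120_000,
        n_full=6, n_solo=3, n_trunc=1, n_strains=2, n_strain_events=6,
        flank=1500, min_anchor=300,
    )


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages (prerequisites included) and write a manifest.

    Returns the manifest dict; all outputs live under ``config.outdir``.
    """
    config.validate()
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    # prerequisites: run everything up to the last requested stage
    last = max(STAGES.index(s) for s in stages)
    todo = STAGES[: last + 1]

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "stages": list(todo),
        "outputs": {},
        "thresholds": {
            "length_window": [config.min_len, config.max_len],
            "recency_threshold": config.recency_threshold,
            "proximity": config.proximity,
            "flank": config.flank,
            "tsd_range": [config.min_tsd, config.max_tsd],
            "max_merge_gap": config.max_merge_gap,
            "intact_fraction": config.intact_fraction,
        },
        "seed": config.seed,
    }

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": str(path.relative_to(out)),
            "sha256": sha256_file(path),
        }

    # ---- simulate -------------------------------------------------------
    study: SimulatedStudy
    try:
        study = simulate_study(
            config.seed,
            n_chroms=config.n_chroms, chrom_len=config.chrom_len,
            n_full=config.n_full, n_solo=config.n_solo, n_trunc=config.n_trunc,
            divergence_max=config.divergence_max, tsd_len=config.tsd_len,
            n_strains=config.n_strains, n_strain_events=config.n_strain_events,
        )
        if "simulate" in todo:
            write_fasta(study.reference, out / "reference.fa")
            record("reference_fasta", out / "reference.fa")
            for sid, g in study.strains.items():
                write_fasta(g, out / f"{sid}.fa")
                record(f"{sid}_fasta", out / f"{sid}.fa")
            write_truth_table(study.truth, out / "truth.tsv")
            record("truth_table", out / "truth.tsv")
            write_bed6(truth_bed6(study.reference_truth), out / "planted_loci.bed")
            record("planted_loci_bed", out / "planted_loci.bed")
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", e) from e

    model = study.model
    results: dict = {"study": study}

    # ---- annotate -------------------------------------------------------
    calls = []
    try:
        if "annotate" in todo:
            hits = ann.scan_hits(
                study.reference, model,
                min_seed_kmer=config.min_seed_kmer,
                min_hit_len=config.min_hit_len,
                max_divergence=config.max_divergence,
            )
            calls = ann.defragment(hits, max_merge_gap=config.max_merge_gap)
            calls = ann.length_filter(calls, config.min_len, config.max_len)
            for c in calls:
                ann.detect_tsd(study.reference, c, config.min_tsd, config.max_tsd)
            ann.calls_table(calls).to_csv(out / "calls.tsv", sep="\t", index=False)
            record("calls_table", out / "calls.tsv")
            write_bed6(
                [(c.chrom, c.start, c.end, f"{c.locus_id}|{c.structure_class}", 0.0, c.strand)
                 for c in calls],
                out / "calls.bed",
            )
            record("calls_bed", out / "calls.bed")
            seqs = ann.call_sequences(study.reference, calls)
            write_fasta(seqs, out / "insertions.fa")
            record("insertion_fasta", out / "insertions.fa")
            results["hits"] = hits
            results["calls"] = calls
            results["census"] = ann.census(calls, hits)
            manifest["census"] = results["census"]
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("annotate", e) from e

    # ---- gag ------------------------------------------------------------
    try:
        if "gag" in todo:
            seqs = ann.call_sequences(study.reference, calls)
            assessments = {}
            for c in calls:
                if c.structure_class != "FULL_PROVIRUS":
                    continue
                assessments[c.locus_id] = gagmod.assess_gag(
                    seqs[c.locus_id], model,
                    intact_fraction=config.intact_fraction,
                    locus_id=c.locus_id, seq_is_element=True,
                )
            rows = [
                {
                    "locus_id": a.locus_id, "protein_len": a.protein_len,
                    "intact": a.intact, "reason": a.reason,
                    "n_stops": len(a.stop_codon_positions),
                }
                for a in assessments.values()
            ]
            import pandas as pd

            pd.DataFrame(rows).to_csv(out / "gag_assessments.tsv", sep="\t", index=False)
            record("gag_table", out / "gag_assessments.tsv")
            intact_prots = {
                l: a.protein for l, a in assessments.items() if a.intact and a.protein
            }
            if len(intact_prots) >= 2:
                labels, mat, mean_ident = gagmod.protein_identity_matrix(intact_prots)
                pd.DataFrame(mat, index=labels, columns=labels).to_csv(
                    out / "gag_identity.tsv", sep="\t"
                )
                record("gag_identity", out / "gag_identity.tsv")
                manifest["mean_gag_identity_pct"] = round(mean_ident, 3)
            results["gag"] = assessments
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("gag", e) from e

    # ---- recency --------------------------------------------------------
    try:
        if "recency" in todo:
            seqs = ann.call_sequences(study.reference, calls)
            # full-length copies only: projections onto the element consensus
            full = {c.locus_id: seqs[c.locus_id] for c in calls
                    if c.structure_class == "FULL_PROVIRUS"}
            if len(full) >= 3:
                proj = rec.anchor_align(full, model.element_seq)
                dm = rec.jc_matrix(proj)
                tree = rec.nj_tree(dm)
                (out / "insertions.nwk").write_text(tree.newick() + "\n")
                record("tree_newick", out / "insertions.nwk")
                report = rec.recency_stats(tree, config.recency_threshold, dm)
                manifest["recency"] = {
                    "median_terminal_branch": report.median_terminal_branch,
                    "fraction_below_threshold": report.fraction_below_threshold,
                    "threshold": report.threshold,
                    "note": "single concatenated consensus projection; "
                            "NJ terminal branches (distance-based)",
                }
                results["recency"] = report
            ltr_div = {}
            for c in calls:
                if c.structure_class == "FULL_PROVIRUS":
                    ltr_div[c.locus_id] = rec.ltr_ltr_divergence(c, study.reference)
            results["ltr_ltr_divergence"] = ltr_div
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("recency", e) from e

    # ---- polymorphism ---------------------------------------------------
    try:
        if "polymorph" in todo:
            loci = poly.loci_from_calls(calls, study.reference)
            matrix, evidence = poly.polymorphism_matrix(
                loci, study.reference, study.strains, model,
                flank=config.flank, min_anchor=config.min_anchor,
            )
            matrix.to_csv(out / "polymorphism_matrix.tsv", sep="\t")
            record("polymorphism_matrix", out / "polymorphism_matrix.tsv")
            evidence_rows = [
                {
                    "locus_id": e.locus_id, "assembly": e.assembly_id,
                    "status": e.status.value, "gap": e.observed_gap,
                    "expected_full": e.expected_full, "expected_solo": e.expected_solo,
                    "tsd_evidence": e.tsd_evidence, "note": e.note,
                }
                for e in evidence
            ]
            (out / "polymorphism_evidence.json").write_text(
                json.dumps(evidence_rows, indent=1, sort_keys=True) + "\n"
            )
            record("polymorphism_evidence", out / "polymorphism_evidence.json")
            results["polymorphism"] = (matrix, evidence)
            manifest["n_polymorphic_loci"] = int(matrix["polymorphic"].sum())
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("polymorph", e) from e

    # ---- oligo ----------------------------------------------------------
    try:
        if "oligo" in todo:
            oseq = config.oligo_sequence
            if not oseq:
                # demo oligo: antisense to LTR positions 30-52 of the simulated
                # consensus (just downstream of a notional TSS)
                from .seq import revcomp as _rc

                oseq = _rc(model.ltr_seq[30:52])
            query = oligomod.OligoQuery(
                config.oligo_name, oseq, max_mismatches=config.oligo_max_mismatches
            )
            seqs = ann.call_sequences(study.reference, calls)
            classes = {c.locus_id: c.structure_class for c in calls}
            gags = {
                l: a.intact for l, a in results.get("gag", {}).items()
            }
            report = oligomod.count_targets(
                query, seqs, structure_class=classes, gag_intact=gags
            )
            summary = {
                "oligo": report.oligo,
                "target_site": report.target_site,
                "max_mismatches": report.max_mismatches,
                "n_total": report.n_total,
                "n_targeted": report.n_targeted,
                "n_proviral_targeted": report.n_proviral_targeted,
                "n_full_gag_targeted": report.n_full_gag_targeted,
                "fraction_targeted": report.fraction_targeted,
                "n_truncated_candidates": len(report.truncated_candidates),
            }
            (out / "oligo_report.json").write_text(
                json.dumps(summary, indent=1, sort_keys=True) + "\n"
            )
            record("oligo_report", out / "oligo_report.json")
            results["oligo"] = report
            manifest["oligo_targets"] = summary["n_targeted"]
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("oligo", e) from e

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    results["manifest"] = manifest
    results["manifest_path"] = manifest_path
    return results
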