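"""Generator correctness: determinism, TSD structure, round trips, bookkeeping."""

import pytest

from ervkit.models import ABSENT, DELETED, FULL_PROVIRUS, SOLO_LTR, TRUNCATED
from ervkit.simulate import (
    PlantEvent,
    StrainEvent,
    derive_strain,
    make_family_model,
    make_random_genome,
    plant_insertion,
    plant_many,
)
from ervkit.seq import hamming, revcomp


def test_random_genome_determinism_and_lengths():
    g1 = make_random_genome(1, [1000], 0.5, seed=7)
    g2 = make_random_genome(1, [1000], 0.5, seed=7)
    assert g1 == g2
    g = make_random_genome(2, [500, 300], 0.5, seed=1)
    assert sum(map(len, g.values())) == 800


def test_random_genome_gc_within_binomial_bounds():
    n, gc = 100_000, 0.3
    g = make_random_genome(1, [n], gc, seed=3)
    observed = sum(g["chr1"].count(b) for b in "GC")
    sd = (n * gc * (1 - gc)) ** 0.5
    assert abs(observed - n * gc) < 3 * sd


def test_random_genome_rejects_bad_input():
    with pytest.raises(ValueError):
        make_random_genome(1, [0], 0.5, seed=1)
    with pytest.raises(ValueError):
        make_random_genome(1, [100], 1.5, seed=1)


def test_plant_zero_divergence_exact_structure(small_model):
    genome = make_random_genome(1, [10_000], 0.4, seed=2)
    ev = PlantEvent(chrom="chr1", position=5000, divergence=0.0, seed=9)
    out, truth = plant_insertion(genome, small_model, ev)
    t = small_model.tsd_len
    site = genome["chr1"][5000 : 5000 + t]
    expected = site + small_model.element_seq + site
    assert out["chr1"][5000 : 5000 + len(expected)] == expected
    row = truth.iloc[0]
    assert row["structure_class"] == FULL_PROVIRUS
    assert row["tsd_seq"] == site
    assert len(out["chr1"]) == len(genome["chr1"]) + small_model.element_len + t


def test_plant_tsd_zero_no_duplication(small_model):
    genome = make_random_genome(1, [10_000], 0.4, seed=2)
    ev = PlantEvent(chrom="chr1", position=5000, tsd_len_used=0)
    out, truth = plant_insertion(genome, small_model, ev)
    assert len(out["chr1"]) == len(genome["chr1"]) + small_model.element_len
    assert truth.iloc[0]["tsd_seq"] == ""


def test_plant_divergence_matches_hamming(small_model):
    """The realized Hamming distance to consensus is binomially plausible."""
    genome = make_random_genome(1, [20_000], 0.4, seed=2)
    rate = 0.02
    ev = PlantEvent(chrom="chr1", position=9000, divergence=rate, seed=123)
    out, truth = plant_insertion(genome, small_model, ev)
    row = truth.iloc[0]
    planted = out["chr1"][row["start"] : row["end"]]
    d = hamming(planted, small_model.element_seq)
    n = small_model.element_len
    sd = (n * rate * (1 - rate)) ** 0.5
    assert abs(d - n * rate) < 3 * sd


def test_plant_minus_strand_is_revcomp(small_model):
    genome = make_random_genome(1, [10_000], 0.4, seed=2)
    ev = PlantEvent(chrom="chr1", position=5000, strand="-")
    out, truth = plant_insertion(genome, small_model, ev)
    row = truth.iloc[0]
    assert out["chr1"][row["start"] : row["end"]] == revcomp(small_model.element_seq)


def test_plant_solo_truncation_classifies_solo(small_model):
    genome = make_random_genome(1, [10_000], 0.4, seed=2)
    L, E = small_model.ltr_len, small_model.element_len
    ev = PlantEvent(chrom="chr1", position=5000, truncation=(L, E))
    out, truth = plant_insertion(genome, small_model, ev)
    row = truth.iloc[0]
    assert row["structure_class"] == SOLO_LTR
    assert out["chr1"][row["start"] : row["end"]] == small_model.ltr_seq


def test_plant_rejects_full_truncation_and_bad_position(small_model):
    genome = make_random_genome(1, [1000], 0.4, seed=2)
    with pytest.raises(ValueError):
        plant_insertion(
            genome, small_model,
            PlantEvent(chrom="chr1", position=10, truncation=(0, small_model.element_len)),
        )
    with pytest.raises(ValueError):
        plant_insertion(genome, small_model, PlantEvent(chrom="chr1", position=5000))


def test_nested_insertion_extends_outer_row(small_model):
    genome = make_random_genome(1, [20_000], 0.4, seed=2)
    g1, truth = plant_insertion(genome, small_model, PlantEvent(chrom="chr1", position=5000))
    outer = truth.iloc[0]
    inner_pos = int(outer["start"]) + 200  # inside the outer element
    g2, truth = plant_insertion(
        g1, small_model, PlantEvent(chrom="chr1", position=inner_pos), truth
    )
    outer2 = truth.iloc[0]
    grown = small_model.element_len + small_model.tsd_len
    assert outer2["end"] - outer["end"] == grown
    assert outer2["start"] == outer["start"]


def test_absent_precise_round_trip(small_model):
    """plant_insertion followed by ABSENT_PRECISE restores the chromosome byte-for-byte."""
    genome = make_random_genome(1, [10_000], 0.4, seed=2)
    ev = PlantEvent(chrom="chr1", position=5000, divergence=0.01, seed=4, locus_id="X")
    planted, truth = plant_insertion(genome, small_model, ev)
    strain, st = derive_strain(
        planted, truth, [StrainEvent("X", "ABSENT_PRECISE")],
        seed=1, strain_id="s", model=small_model,
    )
    assert strain["chr1"] == genome["chr1"]
    assert st.iloc[0]["structure_class"] == ABSENT


def test_solo_conversion_structure_and_tsds(small_model):
    genome = make_random_genome(1, [10_000], 0.4, seed=2)
    ev = PlantEvent(chrom="chr1", position=5000, locus_id="X")
    planted, truth = plant_insertion(genome, small_model, ev)
    strain, st = derive_strain(
        planted, truth, [StrainEvent("X", "SOLO_LTR_CONVERSION")],
        seed=1, strain_id="s", model=small_model,
    )
    t = small_model.tsd_len
    site = genome["chr1"][5000 : 5000 + t]
    row = st.iloc[0]
    assert row["structure_class"] == SOLO_LTR
    locus = strain["chr1"][row["start"] - t : row["end"] + t]
    assert locus == site + small_model.ltr_seq + site


def test_locus_deletion_length_bookkeeping(small_model):
    genome = make_random_genome(1, [20_000], 0.4, seed=2)
    ev = PlantEvent(chrom="chr1", position=9000, locus_id="X")
    planted, truth = plant_insertion(genome, small_model, ev)
    span = 2000
    strain, st = derive_strain(
        planted, truth, [StrainEvent("X", "LOCUS_DELETION", deletion_span=span)],
        seed=1, strain_id="s", model=small_model,
    )
    removed = span + small_model.element_len + small_model.tsd_len
    assert len(planted["chr1"]) - len(strain["chr1"]) == removed
    assert st.iloc[0]["structure_class"] == DELETED


def test_derive_strain_shifts_downstream_loci(small_model):
    genome = make_random_genome(1, [30_000], 0.4, seed=2)
    events = [
        PlantEvent(chrom="chr1", position=5000, locus_id="A"),
        PlantEvent(chrom="chr1", position=20_000, locus_id="B"),
    ]
    planted, truth = plant_many(genome, small_model, events)
    strain, st = derive_strain(
        planted, truth, [StrainEvent("A", "ABSENT_PRECISE")],
        seed=1, strain_id="s", model=small_model,
    )
    b = st[st["locus_id"] == "B"].iloc[0]
    assert strain["chr1"][b["start"] : b["end"]] == small_model.element_seq


def test_derive_strain_rejects_unknown_and_duplicate_loci(small_model):
    genome = make_random_genome(1, [10_000], 0.4, seed=2)
    planted, truth = plant_insertion(
        genome, small_model, PlantEvent(chrom="chr1", position=5000, locus_id="X")
    )
    with pytest.raises(ValueError, match="unknown locus"):
        derive_strain(planted, truth, [StrainEvent("nope", "ABSENT_PRECISE")],
                      seed=1, strain_id="s", model=small_model)
    with pytest.raises(ValueError, match="multiple events"):
        derive_strain(
            planted, truth,
            [StrainEvent("X", "ABSENT_PRECISE"), StrainEvent("X", "SOLO_LTR_CONVERSION")],
            seed=1, strain_id="s", model=small_model,
        )


def test_truth_coordinates_slice_valid_sequence(small_study):
    """Every occupied truth row indexes sequence that matches its class."""
    model = small_study.model
    genomes = {"reference": small_study.reference, **small_study.strains}
    for row in small_study.truth.itertuples():
        if row.structure_class in (ABSENT, DELETED):
            continue
        seq = genomes[row.genome_id][row.chrom][row.start : row.end]
        if row.structure_class == SOLO_LTR:
            assert len(seq) == model.ltr_len
        elif row.structure_class == FULL_PROVIRUS:
            assert len(seq) == model.element_len
        else:
            assert 0 < len(seq) < model.element_len
        # TSD copies flank the element
        t = len(row.tsd_seq)
        g = genomes[row.genome_id][row.chrom]
        if t:
            assert g[row.start - t : row.start] == row.tsd_seq
            assert g[row.end : row.end + t] == row.tsd_seq


def test_study_is_deterministic():
    from ervkit.simulate import simulate_study

    simulate_args = dict(
        n_chroms=2, chrom_len=100_000, n_full=3, n_solo=2, n_trunc=1,
        n_strains=2, n_strain_events=4,
    )
    s1 = simulate_study(42, **simulate_args)
    s2 = simulate_study(42, **simulate_args)
    assert s1.reference == s2.reference
    assert s1.strains == s2.strains
    assert s1.truth.equals(s2.truth)


def test_family_model_encodes_designed_gag():
    from ervkit.gag import consensus_gag_orf

    model = make_family_model(3, ltr_len=300, gag_aa=150, utr5=120, utr3=80)
    orf = consensus_gag_orf(model)
    assert orf.protein_len == 150
    assert orf.start == 120
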