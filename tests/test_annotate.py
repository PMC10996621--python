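"""Hit scanning, defragmentation, classification, TSDs, census."""

import numpy as np
import pytest

from ervkit import annotate as ann
from ervkit.models import FULL_PROVIRUS, SOLO_LTR, TRUNCATED
from ervkit.seq import random_dna, revcomp
from ervkit.simulate import PlantEvent, make_random_genome, plant_many

from conftest import match_calls_to_truth


def _hit(chrom="chr1", start=0, end=100, strand="+", part="LTR", cs=0, ce=100, fam="F"):
    return ann.TeFragmentHit(chrom, start, end, strand, fam, part, cs, ce)


def test_scan_finds_exact_internal_copy(small_model):
    rng = np.random.default_rng(0)
    flank = random_dna(3000, 0.4, rng)
    flank2 = random_dna(3000, 0.4, rng)
    genome = {"chr1": flank + small_model.internal_seq + flank2}
    hits = ann.scan_hits(genome, small_model)
    internal = [h for h in hits if h.part == "INTERNAL"]
    assert len(internal) == 1
    h = internal[0]
    assert (h.start, h.end) == (3000, 3000 + small_model.internal_len)
    assert (h.consensus_start, h.consensus_end) == (0, small_model.internal_len)
    assert h.divergence_pct == 0


def test_scan_no_shared_kmer_returns_empty(small_model):
    genome = {"chr1": "A" * 5000}  # model is random sequence; no shared 15-mer
    assert ann.scan_hits(genome, small_model) == []


def test_scan_rejects_empty_genome(small_model):
    with pytest.raises(ValueError):
        ann.scan_hits({"chr1": ""}, small_model)


def test_scan_recovers_planted_copies_with_divergence(small_model):
    """Most 2%-diverged planted copies are recovered within +-5 bp."""
    rng = np.random.default_rng(7)
    genome = make_random_genome(1, [400_000], 0.4, seed=70)
    events = [
        PlantEvent(
            chrom="chr1", position=4000 + i * 8000, divergence=0.02,
            strand="+" if i % 2 else "-", seed=1000 + i, locus_id=f"L{i}",
        )
        for i in range(40)
    ]
    # positions are applied sequentially; spacing >> element so no collisions
    genome, truth = plant_many(genome, small_model, events)
    hits = ann.scan_hits(genome, small_model)
    calls = ann.defragment(hits)
    mapping = match_calls_to_truth(calls, truth)
    tru = truth.set_index("locus_id")
    ok = 0
    for c in calls:
        locus = mapping.get(c.locus_id)
        if locus is None:
            continue
        row = tru.loc[locus]
        if abs(c.start - row["start"]) <= 5 and abs(c.end - row["end"]) <= 5:
            ok += 1
    assert ok >= 0.95 * len(events)


def test_defragment_canonical_patterns():
    hits = [
        _hit(start=0, end=300, part="LTR", cs=0, ce=300),
        _hit(start=310, end=2300, part="INTERNAL", cs=0, ce=1990),
        _hit(start=2310, end=2610, part="LTR", cs=0, ce=300),
    ]
    calls = ann.defragment(hits)
    assert len(calls) == 1
    assert calls[0].structure_class == FULL_PROVIRUS

    lone = ann.defragment([_hit(start=5000, end=5300, part="LTR")])
    assert len(lone) == 1 and lone[0].structure_class == SOLO_LTR


def test_defragment_never_merges_distant_ltrs():
    hits = [
        _hit(start=0, end=300, part="LTR"),
        _hit(start=100_000, end=100_300, part="LTR"),
    ]
    calls = ann.defragment(hits, max_merge_gap=500)
    assert len(calls) == 2
    assert all(c.structure_class == SOLO_LTR for c in calls)


def test_defragment_never_merges_adjacent_solo_ltrs():
    hits = [
        _hit(start=0, end=300, part="LTR"),
        _hit(start=350, end=650, part="LTR"),
    ]
    assert len(ann.defragment(hits, max_merge_gap=500)) == 2


def test_defragment_partition_conserves_hits():
    rng = np.random.default_rng(1)
    hits = []
    pos = 0
    for i in range(20):
        pos += int(rng.integers(100, 2000))
        part = "LTR" if i % 3 else "INTERNAL"
        hits.append(_hit(start=pos, end=pos + 200, part=part, cs=0, ce=200))
    calls = ann.defragment(hits)
    assigned = [h for c in calls for h in c.components]
    assert len(assigned) == len(hits)
    assert {id(h) for h in assigned} == {id(h) for h in hits}


def test_classify_rules():
    def call(parts, strand="+"):
        comps = [
            _hit(start=i * 1000, end=i * 1000 + 300, part=p, strand=strand)
            for i, p in enumerate(parts)
        ]
        return ann.InsertionCall("x", "chr1", comps[0].start, comps[-1].end, strand, "F",
                                 components=comps)

    assert ann.classify(call(["LTR", "INTERNAL", "LTR"])) == FULL_PROVIRUS
    assert ann.classify(call(["LTR"])) == SOLO_LTR
    assert ann.classify(call(["INTERNAL"])) == TRUNCATED
    assert ann.classify(call(["LTR", "INTERNAL"])) == TRUNCATED
    assert ann.classify(call(["LTR", "INTERNAL", "LTR"], strand="-")) == FULL_PROVIRUS


def test_classify_rejects_mixed_families():
    comps = [
        _hit(start=0, end=300, part="LTR", fam="A"),
        _hit(start=400, end=700, part="INTERNAL", fam="B"),
    ]
    call = ann.InsertionCall("x", "chr1", 0, 700, "+", "A", components=comps)
    with pytest.raises(ValueError, match="mixed families"):
        ann.classify(call)


def test_length_filter_window_and_idempotence():
    def call(length):
        c = ann.InsertionCall("x", "chr1", 0, length, "+", "F")
        return c

    calls = [call(900), call(1200), call(8750), call(9000)]
    kept = ann.length_filter(calls, 1000, 8750)
    assert [c.length for c in kept] == [1200, 8750]
    assert ann.length_filter(kept, 1000, 8750) == kept  # idempotent
    kept2 = ann.length_filter(calls, 1000, 9350)
    assert [c.length for c in kept2] == [1200, 8750, 9000]
    with pytest.raises(ValueError):
        ann.length_filter(calls, -1, 100)


def _brute_force_tsd(seq, start, end, kmin, kmax):
    best = None
    for k in range(kmin, kmax + 1):
        if start - k < 0 or end + k > len(seq):
            continue
        if seq[start - k : start] == seq[end : end + k]:
            best = seq[start - k : start]
    return best


def test_detect_tsd_agrees_with_brute_force(small_study, small_calls):
    genome = small_study.reference
    for c in small_calls:
        got = ann.detect_tsd(genome, c)
        expected = _brute_force_tsd(genome[c.chrom], c.start, c.end, 2, 20)
        assert (got[0] if got else None) == expected


def test_detect_tsd_longest_wins():
    # flanks engineered so both a 4-mer and a 6-mer duplication exist
    left = "CCCCCCACGTAA"
    right = "ACGTAACCCCCC"
    elem = "GGGGGGGGGG"
    genome = {"chr1": left + elem + right}
    call = ann.InsertionCall("x", "chr1", len(left), len(left) + len(elem), "+", "F")
    got = ann.detect_tsd(genome, call)
    assert got == ("ACGTAA", 6)


def test_detect_tsd_negative_and_edge_cases():
    genome = {"chr1": "AAAATTTT" + "G" * 50 + "CCCCGGGG"}
    call = ann.InsertionCall("x", "chr1", 8, 58, "+", "F")
    assert ann.detect_tsd(genome, call) is None
    edge_call = ann.InsertionCall("x", "chr1", 0, 58, "+", "F")
    with pytest.warns(UserWarning, match="insufficient flank"):
        assert ann.detect_tsd(genome, edge_call) is None


def test_census_matches_truth(small_study, small_calls):
    truth = small_study.reference_truth
    counts = ann.census(small_calls)
    expected = truth["structure_class"].value_counts().to_dict()
    for cls in (FULL_PROVIRUS, SOLO_LTR, TRUNCATED):
        assert counts["by_class"][cls] == expected.get(cls, 0)
    assert ann.census([])["n_calls"] == 0


def test_repeatmasker_out_round_trip(tmp_path):
    out = tmp_path / "hits.out"
    out.write_text(
        "   SW   perc perc perc  query     position in query    matching repeat\n"
        "score   div. del. ins.  sequence  begin end (left)     repeat class begin end (left) ID\n"
        "\n"
        " 1000    2.0  0.0  0.0  chr1      101   400  (9600)  +  FamX-LTR   LTR/ERV     1  300  (0)   1\n"
        "  900    1.5  0.0  0.0  chr1      451  2440  (7160)  +  FamX-int   LTR/ERV     1 1990  (0)   2\n"
        "  950    2.5  0.0  0.0  chr1     2501  2800  (6800)  C  FamX-LTR   LTR/ERV   (0)  300    1   3\n"
        "  100    9.0  0.0  0.0  chr1     2501  2790  (6810)  C  FamX-LTR   LTR/ERV   (0)  290    1   4 *\n"
    )
    hits = ann.read_repeatmasker_out(str(out), family_name="FamX")
    assert len(hits) == 3  # starred overlap deduplicated by score
    first = hits[0]
    assert (first.start, first.end) == (100, 400)  # 1-based inclusive -> half-open
    assert first.part == "LTR"
    assert hits[1].part == "INTERNAL"
    assert hits[2].strand == "-"


def test_call_sequences_are_element_sense(small_study, small_calls):
    seqs = ann.call_sequences(small_study.reference, small_calls)
    for c in small_calls:
        raw = small_study.reference[c.chrom][c.start : c.end]
        expected = raw if c.strand == "+" else revcomp(raw)
        assert seqs[c.locus_id] == expected
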