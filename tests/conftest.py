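import pytest

from ervkit import annotate as ann
from ervkit.simulate import make_family_model, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact simulated study shared across test modules: 2 x 100 kb
    chromosomes, 10 insertions (6 full / 3 solo / 1 truncated), 2 strains
    with 6 planted status events."""
    return simulate_study(
        11,
        n_chroms=2,
        chrom_len=100_000,
        n_full=6,
        n_solo=3,
        n_trunc=1,
        n_strains=2,
        n_strain_events=6,
    )


@pytest.fixture(scope="session")
def small_model():
    """A small family model (short LTR/ORF) for fast unit tests."""
    return make_family_model(5, ltr_len=300, gag_aa=200, utr5=150, utr3=100)


@pytest.fixture(scope="session")
def small_calls(small_study):
    """Annotator calls recovered from the small study's reference genome."""
    hits = ann.scan_hits(small_study.reference, small_study.model)
    calls = ann.defragment(hits)
    for c in calls:
        ann.detect_tsd(small_study.reference, c)
    return calls


def match_calls_to_truth(calls, truth):
    """Map call locus_id -> truth locus_id by coordinate overlap."""
    mapping = {}
    for c in calls:
        overlaps = truth[
            (truth["chrom"] == c.chrom)
            & (truth["start"] < c.end)
            & (truth["end"] > c.start)
        ]
        if len(overlaps) == 1:
            mapping[c.locus_id] = overlaps.iloc[0]["locus_id"]
    return mapping
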