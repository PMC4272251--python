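import numpy as np
import pytest

from mthet.calling import (
    CallingThresholds,
    call_column,
    call_sample,
    classify_heteroplasmy,
    flag_recurrent_artifacts,
    screen_sample_for_het,
)
from mthet.coverage import CoverageProfile
from mthet.errors import ConfigError
from mthet.io import PileupColumn
from mthet.refmodel import GenomeRegion
from mthet.stats import clopper_pearson


def col(pos, ref, **counts):
    full = {"A": 0, "C": 0, "G": 0, "T": 0}
    full.update(counts)
    return PileupColumn(pos, ref, sum(full.values()), full)


def test_call_emitted_at_reported_site(thresholds):
    rec = call_column(col(240, "A", A=14, G=3), thresholds)
    assert rec is not None
    assert (rec.alt, rec.v, rec.n) == ("G", 3, 17)
    assert rec.vaf == pytest.approx(3 / 17)
    ci = clopper_pearson(3, 17)
    assert (rec.ci_low, rec.ci_high) == (ci.low, ci.high)


@pytest.mark.parametrize(
    "counts, reason",
    [
        ({"A": 1, "G": 3}, "below min_total_depth"),
        ({"A": 8, "G": 2}, "below min_variant_reads"),
        ({"A": 38, "G": 3}, "below min_vaf"),
        ({"A": 10}, "no alternate allele"),
    ],
)
def test_no_call_below_thresholds(thresholds, counts, reason):
    assert call_column(col(50, "A", **counts), thresholds) is None, reason


def test_homoplasmic_boundary_call(thresholds):
    rec = call_column(col(60, "A", G=20), thresholds)
    assert rec.vaf == 1.0
    assert rec.ci_high == 1.0


def test_multiallelic_top_allele_with_alphabetical_tie_break(thresholds):
    rec = call_column(col(70, "A", C=5, T=5, A=10), thresholds)
    assert rec.alt == "C"


def test_caller_equivalence_with_threshold_filter_oracle(thresholds):
    """Random pileups: the caller equals a direct filter over (v, n, vaf)."""
    rng = np.random.default_rng(42)
    for _ in range(400):
        ref = "ACGT"[rng.integers(4)]
        counts = {b: int(rng.integers(0, 12)) for b in "ACGT"}
        column = col(int(rng.integers(1, 1000)), ref, **counts)
        n = column.depth
        alts = sorted(
            ((-c, b) for b, c in counts.items() if b != ref and c > 0),
        )
        expected = None
        if alts:
            v, alt = -alts[0][0], alts[0][1]
            if (
                n >= thresholds.min_total_depth
                and v >= thresholds.min_variant_reads
                and v / n >= thresholds.min_vaf
            ):
                expected = (alt, v, n)
        rec = call_column(column, thresholds)
        got = None if rec is None else (rec.alt, rec.v, rec.n)
        assert got == expected, (counts, ref)


def test_classify_heteroplasmy_bands(thresholds):
    rec = call_column(col(240, "A", A=14, G=3), thresholds)
    assert classify_heteroplasmy(rec, thresholds) == "heteroplasmic"
    rec = call_column(col(60, "A", A=1, G=19), thresholds)
    assert classify_heteroplasmy(rec, thresholds) == "homoplasmic"
    # two variant reads in forty is background noise, not heteroplasmy
    from mthet.io import CallRecord

    bg = CallRecord(80, "A", "G", 2, 40, 0.05, 0.0, 1.0)
    assert classify_heteroplasmy(bg, thresholds) == "background"


def test_call_sample_ledger_and_exclusions(thresholds, rcrs):
    columns = [
        col(100, "A", A=3, G=1),  # low coverage, no call
        col(240, "A", A=14, G=3),  # call
        col(3107, "N"),  # placeholder: skipped entirely
        col(500, "C", C=5, T=40),  # masked
        col(16186, "C", C=10, T=6),  # call inside the poly-C tract
    ]
    res = call_sample(columns, thresholds, "S1", ref_model=rcrs, masked_positions={500})
    assert res.low_coverage_positions == {100}
    positions = {r.position for r in res.records}
    assert positions == {240, 16186}
    polyc_rec = next(r for r in res.records if r.position == 16186)
    assert "polyC" in polyc_rec.filter_flags


def test_recurrent_artifact_flagged_across_all_samples(thresholds):
    def sample_records():
        return [call_column(col(5058, "A", A=20, G=6), thresholds)]

    callsets = {f"S{i}": sample_records() for i in range(13)}
    artifacts = flag_recurrent_artifacts(callsets, thresholds)
    assert artifacts == [5058]
    for records in callsets.values():
        assert "recurrent_artifact" in records[0].filter_flags


def test_private_variant_not_flagged_recurrent(thresholds):
    callsets = {
        "S1": [call_column(col(820, "A", A=20, G=6), thresholds)],
        "S2": [],
        "S3": [],
    }
    artifacts = flag_recurrent_artifacts(callsets, thresholds)
    assert artifacts == []
    assert callsets["S1"][0].filter_flags == set()


def test_recurrent_flagging_needs_cohort(thresholds):
    with pytest.raises(ConfigError):
        flag_recurrent_artifacts({"S1": []}, thresholds)


def test_polyc_flag_applied_unconditionally(thresholds):
    polyc = GenomeRegion(16184, 16193, "polyC")
    callsets = {
        "S1": [call_column(col(16186, "C", C=10, T=6), thresholds)],
        "S2": [],
    }
    flag_recurrent_artifacts(callsets, thresholds, polyc_region=polyc, genome_length=16569)
    assert "polyC" in callsets["S1"][0].filter_flags


def test_heteroplasmy_screen_mean_depth_gate(thresholds):
    rec = call_column(col(240, "A", A=14, G=3), thresholds)
    eligible, candidates = screen_sample_for_het(
        [rec], CoverageProfile("S1", np.full(100, 31.0)), thresholds
    )
    assert eligible and candidates == [rec]
    eligible, candidates = screen_sample_for_het(
        [rec], CoverageProfile("S1", np.full(100, 25.7)), thresholds
    )
    assert not eligible and candidates == []


def test_screen_drops_flagged_candidates(thresholds):
    rec = call_column(col(240, "A", A=14, G=3), thresholds)
    rec.filter_flags.add("recurrent_artifact")
    eligible, candidates = screen_sample_for_het(
        [rec], CoverageProfile("S1", np.full(100, 40.0)), thresholds
    )
    assert eligible and candidates == []


def test_threshold_invariants_enforced():
    with pytest.raises(ConfigError):
        CallingThresholds(min_vaf=0.5, het_band=(0.1, 0.9))
    with pytest.raises(ConfigError):
        CallingThresholds(min_total_depth=0)
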