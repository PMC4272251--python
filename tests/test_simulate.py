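import math

import numpy as np
import pytest
from scipy import stats as sps

from mthet.calling import call_sample, flag_recurrent_artifacts
from mthet.errors import ConfigError
from mthet.io import read_pileup
from mthet.simulate import (
    CoverageModel,
    ErrorModel,
    SimConfig,
    VariantModel,
    recovery_experiment,
    simulate_cohort,
)


@pytest.fixture(scope="module")
def small_cohort(rcrs):
    config = SimConfig(
        reference=rcrs,
        seed=11,
        n_samples=6,
        coverage=CoverageModel(baseline_mean=60, sample_sigma=0.1),
        variants=VariantModel(homoplasmic_per_sample=10, heteroplasmic_per_sample=2),
    )
    return simulate_cohort(config)


# module-scoped rcrs comes from the session fixture via this alias
@pytest.fixture(scope="module")
def rcrs():
    from mthet.refmodel import load_packaged_reference

    return load_packaged_reference()


def test_same_seed_reproduces_identical_output(rcrs, small_cohort):
    config = small_cohort.config
    again = simulate_cohort(config)
    assert again.artifact_positions == small_cohort.artifact_positions
    for s1, s2 in zip(small_cohort.samples, again.samples):
        assert s1.to_mpileup(rcrs.sequence) == s2.to_mpileup(rcrs.sequence)
        assert s1.truth.equals(s2.truth)


def test_zero_variants_zero_errors_matches_reference(rcrs):
    config = SimConfig(
        reference=rcrs,
        seed=3,
        n_samples=1,
        coverage=CoverageModel(baseline_mean=15, sample_sigma=0),
        error=ErrorModel(rate=0.0),
        variants=VariantModel(
            homoplasmic_per_sample=0, heteroplasmic_per_sample=0,
            n_artifact_positions=0, sanger_fp_rate=0.0,
        ),
    )
    sample = simulate_cohort(config).samples[0]
    for col in sample.pileup_columns(rcrs.sequence):
        assert col.counts[col.ref_base] == col.depth


def test_mean_depth_converges_to_configured_baseline(rcrs):
    baseline = 30.0
    config = SimConfig(
        reference=rcrs,
        seed=5,
        n_samples=1,
        coverage=CoverageModel(
            baseline_mean=baseline, sample_sigma=0, shape_scale=0, lognormal_sigma=0.2,
            dip_regions=[],
        ),
        error=ErrorModel(rate=0.0),
        variants=VariantModel(homoplasmic_per_sample=0, heteroplasmic_per_sample=0,
                              n_artifact_positions=0),
    )
    sample = simulate_cohort(config).samples[0]
    # one 'N' base yields usable depth 0; correct the expectation for it
    expected = baseline * (rcrs.length - 1) / rcrs.length
    assert sample.depth.mean() == pytest.approx(expected, rel=0.01)


def test_dip_region_lowers_local_coverage(rcrs):
    from mthet.refmodel import GenomeRegion

    dip = GenomeRegion(5721, 5798, "OriL")
    config = SimConfig(
        reference=rcrs, seed=6, n_samples=1,
        coverage=CoverageModel(baseline_mean=80, sample_sigma=0, shape_scale=0,
                               dip_regions=[(dip, 0.3)]),
        variants=VariantModel(homoplasmic_per_sample=0, heteroplasmic_per_sample=0,
                              n_artifact_positions=0),
    )
    sample = simulate_cohort(config).samples[0]
    inside = sample.depth[5720:5798].mean()
    outside = np.delete(sample.depth, np.arange(5720, 5798)).mean()
    assert inside == pytest.approx(0.3 * outside, rel=0.15)


def test_variant_reads_are_binomial_at_programmed_fraction(rcrs):
    """A shared 50% site across many samples: v/n averages 0.5."""
    site = 4000
    config = SimConfig(
        reference=rcrs, seed=13, n_samples=40,
        coverage=CoverageModel(baseline_mean=100, sample_sigma=0, shape_scale=0,
                               lognormal_sigma=0, dip_regions=[]),
        error=ErrorModel(rate=0.0),
        variants=VariantModel(
            homoplasmic_per_sample=0, heteroplasmic_per_sample=0,
            n_artifact_positions=0, sanger_fp_rate=0.0,
            shared_heteroplasmic_sites=[(site, 0.5)],
        ),
    )
    cohort = simulate_cohort(config)
    fractions = []
    for s in cohort.samples:
        n = s.depth[site - 1]
        alt = s.truth.loc[s.truth.position == site, "alt"].iloc[0]
        v = s.counts["ACGT".index(alt), site - 1]
        fractions.append(v / n)
    assert np.mean(fractions) == pytest.approx(0.5, abs=0.02)


def test_polyc_error_rate_elevated(rcrs):
    config = SimConfig(
        reference=rcrs, seed=21, n_samples=1,
        coverage=CoverageModel(baseline_mean=200, sample_sigma=0, shape_scale=0,
                               lognormal_sigma=0, dip_regions=[]),
        error=ErrorModel(rate=2e-3, polyc_multiplier=20),
        variants=VariantModel(homoplasmic_per_sample=0, heteroplasmic_per_sample=0,
                              n_artifact_positions=0),
    )
    sample = simulate_cohort(config).samples[0]
    seq = rcrs.sequence
    ref_idx = np.array(["ACGT".index(b) if b in "ACGT" else -1 for b in seq])
    nonref = sample.depth - np.where(
        ref_idx >= 0, sample.counts[np.maximum(ref_idx, 0), np.arange(rcrs.length)], 0
    )
    polyc = slice(16183, 16193)
    mask = np.zeros(rcrs.length, dtype=bool)
    mask[polyc] = True
    rate_in = nonref[mask].sum() / sample.depth[mask].sum()
    rate_out = nonref[~mask].sum() / sample.depth[~mask].sum()
    assert rate_in > 5 * rate_out


def test_simulator_truth_recovered_by_caller(rcrs, thresholds, small_cohort):
    """Calls close the loop with the truth table and artifact flagging."""
    results = {}
    for s in small_cohort.samples:
        results[s.sample_id] = call_sample(
            s.pileup_columns(rcrs.sequence), thresholds, s.sample_id, ref_model=rcrs
        )
    artifacts = flag_recurrent_artifacts(results, thresholds)
    assert set(small_cohort.artifact_positions) <= set(artifacts)

    for s in small_cohort.samples:
        called = {r.position: r for r in results[s.sample_id].records}
        for row in s.truth.itertuples():
            if row.kind != "homoplasmic":
                continue
            n = s.depth[row.position - 1]
            v = s.counts["ACGT".index(row.alt), row.position - 1]
            if n >= 5 and v >= 3 and v / n >= 0.1:
                assert row.position in called, (s.sample_id, row.position)
                assert called[row.position].alt == row.alt


def test_no_calls_at_clean_positions_without_errors(rcrs, thresholds):
    config = SimConfig(
        reference=rcrs, seed=17, n_samples=1,
        coverage=CoverageModel(baseline_mean=50, sample_sigma=0),
        error=ErrorModel(rate=0.0),
        variants=VariantModel(homoplasmic_per_sample=3, heteroplasmic_per_sample=0,
                              n_artifact_positions=0, sanger_fp_rate=0.0),
    )
    sample = simulate_cohort(config).samples[0]
    truth_positions = set(sample.truth["position"])
    res = call_sample(sample.pileup_columns(rcrs.sequence), thresholds, "S1")
    assert {r.position for r in res.records} <= truth_positions


def test_pileup_text_round_trip_recovers_counts(rcrs, small_cohort):
    sample = small_cohort.samples[0]
    for col in read_pileup(sample.to_mpileup(rcrs.sequence).splitlines()):
        stored = {b: int(sample.counts[j, col.position - 1]) for j, b in enumerate("ACGT")}
        assert col.counts == stored


def test_recovery_detection_rates_match_binomial_tails(thresholds):
    df = recovery_experiment(
        thresholds, vaf_grid=(0.01, 0.5), depth_grid=(10, 100), n_sites=500, seed=4
    )
    for row in df.itertuples():
        k = max(thresholds.min_variant_reads, math.ceil(thresholds.min_vaf * row.depth))
        expected = sps.binom.sf(k - 1, row.depth, row.true_vaf)
        se = math.sqrt(expected * (1 - expected) / row.n_sites)
        assert abs(row.detection_rate - expected) <= max(4 * se, 0.01)
    high = df[(df.true_vaf == 0.5) & (df.depth == 100)].iloc[0]
    assert high.detection_rate > 0.99
    low = df[(df.true_vaf == 0.01) & (df.depth == 10)].iloc[0]
    assert low.detection_rate < 0.01


def test_invalid_config_rejected(rcrs):
    with pytest.raises(ConfigError):
        SimConfig(reference=rcrs, variants=VariantModel(shared_heteroplasmic_sites=[(99999, 0.5)]))
    with pytest.raises(ConfigError):
        SimConfig(reference=rcrs, coverage=CoverageModel(dip_regions=[]), error=ErrorModel(rate=2.0))
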