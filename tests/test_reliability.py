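"""Reliability distributions, circular-shift null, noise correction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spikereadout import (
    CorrelationDistribution,
    UncorrectableUnitError,
    noise_correct,
    null_transform,
    reliability_distributions,
    sample_pair_sequences,
    tuned_test,
    well_tuned,
)


def test_null_transform_definition_and_involution():
    np.testing.assert_array_equal(null_transform(np.array([1, 2, 3, 4])), [3, 4, 1, 2])
    v = np.arange(10)
    np.testing.assert_array_equal(null_transform(null_transform(v)), v)
    with pytest.raises(ValueError):
        null_transform(np.array([1]))


@given(st.lists(st.integers(0, 9), min_size=2, max_size=40))
def test_null_transform_preserves_marginals(values):
    v = np.array(values)
    assert sorted(null_transform(v)) == sorted(v)


@pytest.mark.parametrize("m,bins,expected", [(10, 32, 320), (11, 20, 220)])
def test_pair_sequences_concatenated_length(m, bins, expected):
    rng = np.random.default_rng(0)
    resp = {f"s{i}": rng.poisson(1.0, size=(4, bins)) for i in range(m)}
    u, v = sample_pair_sequences(resp, seed=1)
    assert u.size == v.size == expected


def test_pair_sequences_forced_pair_and_errors():
    resp = {"s0": np.array([[1, 2, 3], [4, 5, 6]])}
    u, v = sample_pair_sequences(resp, seed=0)
    assert {tuple(u), tuple(v)} == {(1, 2, 3), (4, 5, 6)}
    with pytest.raises(ValueError):
        sample_pair_sequences({"s0": np.array([[1, 2, 3]])})


def test_null_correlation_centered_at_zero():
    """White-noise null correlations have zero expectation.

    Within one unit the resamples share trials, so the per-unit null mean
    carries a fixed O(1/sqrt(bins)) offset; the expectation is checked by
    averaging over independent units.
    """
    rng = np.random.default_rng(2)
    means = []
    for u in range(20):
        resp = {f"s{i}": rng.standard_normal((4, 30)) for i in range(8)}
        _, null = reliability_distributions(resp, R=500, seed=u)
        means.append(null.mean())
    # per-unit offsets ~ N(0, ~1/240); SE of the grand mean ~ 0.065/sqrt(20)
    assert abs(np.mean(means)) < 0.045


def test_identical_trials_give_ceiling_one():
    rng = np.random.default_rng(1)
    row = rng.poisson(2.0, size=30).astype(float)
    resp = {"s0": np.tile(row, (3, 1))}
    true, _ = reliability_distributions(resp, R=50, seed=0)
    np.testing.assert_allclose(true.values, 1.0, atol=1e-12)


def test_gain_zero_reliability_near_zero():
    rng = np.random.default_rng(5)
    resp = {f"s{i}": rng.poisson(0.5, size=(6, 32)) for i in range(10)}
    true, _ = reliability_distributions(resp, R=10_000, seed=1)
    assert abs(true.mean()) < 0.02


def test_gaussian_surrogate_matches_variance_ratio():
    """Ceiling estimates the signal fraction s^2/(s^2+n^2) of Gaussian data."""
    rng = np.random.default_rng(8)
    sig_var, noise_var = 1.0, 1.5
    expected = sig_var / (sig_var + noise_var)
    resp = {}
    for i in range(5):
        signal = rng.normal(0, np.sqrt(sig_var), size=800)
        resp[f"s{i}"] = signal + rng.normal(0, np.sqrt(noise_var), size=(6, 800))
    true, _ = reliability_distributions(resp, R=300, seed=2)
    assert abs(true.mean() - expected) < 0.02


def test_constant_resamples_excluded_not_zeroed():
    resp = {"s0": np.zeros((3, 10), dtype=int)}
    with pytest.raises(ValueError):
        reliability_distributions(resp, R=20, seed=0)


def test_tuned_test_exchangeable_and_separated():
    vals = np.random.default_rng(0).uniform(-0.2, 0.6, size=500)
    same = CorrelationDistribution(vals, "true"), CorrelationDistribution(vals, "null")
    assert 0.45 < tuned_test(*same) < 0.55
    hi = CorrelationDistribution(np.clip(vals + 1, -1, 1), "true")
    lo = CorrelationDistribution(vals - vals.max() - 0.01, "null")
    assert tuned_test(hi, lo) < 1e-50


def test_well_tuned_boundary_and_monotonicity():
    rng = np.random.default_rng(3)
    null_vals = rng.normal(0.0, 0.1, size=2000)
    null = CorrelationDistribution(np.clip(null_vals, -1, 1), "null")
    gap = 0.7 * null.std()
    # shift null by exactly the gap: mean(true)-mean(null) = 0.7*std(null)
    true = CorrelationDistribution(null.values + gap, "true")
    assert well_tuned(true, null, delta=0.5)
    assert not well_tuned(true, null, delta=1.0)
    # boundary inclusive at delta exactly equal to the gap ratio
    assert well_tuned(true, null, delta=0.7)
    with pytest.raises(ValueError):
        well_tuned(true, CorrelationDistribution(np.zeros(10), "null"))


def test_accepted_count_non_increasing_in_delta(tiny_reliability):
    counts = [
        len(tiny_reliability.well_tuned_units(delta=d))
        for d in [0.0, 0.25, 0.5, 1.0, 2.0, 5.0]
    ]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_noise_correct_values():
    assert noise_correct(0.3, 0.36) == pytest.approx(0.5)
    assert noise_correct(0.42, 1.0) == pytest.approx(0.42)
    with pytest.raises(UncorrectableUnitError):
        noise_correct(0.3, 1e-4)


def test_reliability_table_columns(tiny_reliability):
    df = tiny_reliability.to_frame()
    for col in ["unit_id", "ceiling", "tuned_p", "gap", "well_tuned",
                "n_excluded_resamples"]:
        assert col in df.columns
    assert df.ceiling.between(-1, 1).all()
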