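"""Synthetic-session generator: schedules, hierarchy, Poisson responses."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spikereadout import (
    FeatureMatrix,
    make_schedule,
    perturb_hierarchy,
    simulate_unit_responses,
    synth_feature_hierarchy,
    synth_waveform,
)
from spikereadout.containers import GroundTruthUnit
from spikereadout.synthetic import _unit_drive, make_units, simulate_responses


@pytest.mark.parametrize(
    "n_single,n_rep_stim,n_reps,n_stimuli,n_rep_pres",
    [
        (489, 10, 11, 499, 110),   # sentence-like design
        (292, 11, 15, 303, 165),   # vocalization-like design
        (0, 1, 1, 1, 0),           # degenerate: single stimulus, no repeat set
    ],
)
def test_schedule_design_arithmetic(n_single, n_rep_stim, n_reps, n_stimuli, n_rep_pres):
    s = make_schedule(n_single, n_rep_stim, n_reps, 1.6, 0.0, seed=0)
    assert len(s.stimuli) == n_stimuli
    assert sum(x.n_repeats for x in s.repeat_set) == n_rep_pres
    assert s.n_presentations == n_single + n_rep_stim * max(n_reps, 1)


def test_schedule_rejects_empty():
    with pytest.raises(ValueError):
        make_schedule(0, 0, 0, 1.0)


@given(st.integers(0, 20), st.integers(0, 5), st.integers(1, 6), st.integers(0, 2**31 - 1))
def test_schedule_conservation(n_single, n_rep, reps, seed):
    if n_single + n_rep == 0:
        return
    s = make_schedule(n_single, n_rep, reps, 1.0, 0.2, seed=seed)
    assert len(s.presentation_order) == sum(x.n_repeats for x in s.stimuli)
    assert len(set(s.presentation_order)) == len(s.presentation_order)


def test_schedule_determinism_and_roundtrip():
    a = make_schedule(7, 3, 4, 1.2, 0.3, seed=42)
    b = make_schedule(7, 3, 4, 1.2, 0.3, seed=42)
    assert a.presentation_order == b.presentation_order
    assert [s.duration for s in a.stimuli] == [s.duration for s in b.stimuli]
    import spikereadout

    rt = spikereadout.StimulusSchedule.from_json(a.to_json())
    assert rt.presentation_order == a.presentation_order


def test_waveform_length_and_determinism():
    w1 = synth_waveform(1.0, 16000, seed=3)
    w2 = synth_waveform(1.0, 16000, seed=3)
    assert w1.shape == (16000,)
    assert np.array_equal(w1, w2)
    assert np.all(np.isfinite(w1))


def test_waveform_pure_tone_spectrum():
    w = synth_waveform(1.0, 16000, seed=0, tone_freqs=[1000.0],
                       noise_level=0.0, modulated=False)
    spec = np.abs(np.fft.rfft(w))
    freqs = np.fft.rfftfreq(w.size, 1 / 16000)
    assert abs(freqs[np.argmax(spec)] - 1000.0) < 2.0


def test_hierarchy_rates_and_identity():
    base = FeatureMatrix(np.random.default_rng(0).standard_normal((100, 4)), 100.0)
    stack = synth_feature_hierarchy(base, 3, strides=[1, 2, 2], seed=0)
    assert stack.layer_rates == [100.0, 50.0, 25.0]
    flat = synth_feature_hierarchy(base, 3, strides=[1, 1, 1], seed=0)
    assert flat.layer_rates == [100.0, 100.0, 100.0]
    # layer 1 is the base itself
    np.testing.assert_array_equal(flat.layer(1)["stim"].values, base.values)


def test_hierarchy_small_weights_near_linear():
    """With small init the tanh acts linearly: layer 2 is ~a linear map of layer 1."""
    rng = np.random.default_rng(1)
    base = FeatureMatrix(rng.standard_normal((400, 5)), 50.0)
    stack = synth_feature_hierarchy(base, 2, strides=[1, 1], seed=2, gain=0.1)
    x1 = stack.layer(1)["stim"].values
    y2 = stack.layer(2)["stim"].values
    # lagged linear regression of layer 2 on layer 1 should be near-perfect
    from spikereadout.encoding import LagSpec, build_lagged_design

    design = build_lagged_design(FeatureMatrix(x1, 50.0), LagSpec(0.1, 50.0))
    coef, *_ = np.linalg.lstsq(design, y2, rcond=None)
    resid = y2 - design @ coef
    r2 = 1 - resid.var() / y2.var()
    assert r2 > 0.99


def test_perturb_modes():
    base = FeatureMatrix(np.random.default_rng(0).standard_normal((200, 4)), 50.0)
    stack = synth_feature_hierarchy(base, 3, seed=5, mode="structured", gain=1.0)
    r1 = perturb_hierarchy(stack, "reinitialize", seed=9)
    r2 = perturb_hierarchy(stack, "reinitialize", seed=9)
    np.testing.assert_array_equal(
        r1.layer(3)["stim"].values, r2.layer(3)["stim"].values
    )
    with pytest.raises(ValueError):
        perturb_hierarchy(stack, "scramble", seed=0)
    # all-equal weights are invariant under permutation
    eq = synth_feature_hierarchy(base, 2, seed=0)
    eq.kernels[0][:] = 0.3
    eq_layers = perturb_hierarchy(eq, "permute", seed=1)
    ref = perturb_hierarchy(eq, "permute", seed=2)
    np.testing.assert_allclose(
        eq_layers.layer(2)["stim"].values, ref.layer(2)["stim"].values
    )


def test_permute_degrades_more_than_reinitialize():
    """Shuffling large trained-like weights saturates the tanh and loses
    information about the base signal, unlike small-weight re-initialization."""
    rng = np.random.default_rng(7)
    base = FeatureMatrix(rng.standard_normal((600, 6)) * 2.0, 50.0)
    trained = synth_feature_hierarchy(base, 4, seed=3, mode="structured", gain=2.0)

    def deep_predictability(stack):
        x = stack.layers[-1]["stim"].values
        y = base.values[: x.shape[0]]
        coef, *_ = np.linalg.lstsq(
            np.column_stack([x, np.ones(len(x))]), y, rcond=None
        )
        resid = y - np.column_stack([x, np.ones(len(x))]) @ coef
        return 1 - resid.var() / y.var()

    reinit = perturb_hierarchy(trained, "reinitialize", seed=11)
    permuted = perturb_hierarchy(trained, "permute", seed=11)
    assert deep_predictability(permuted) < deep_predictability(reinit)


def _flat_schedule(duration, bin_width, n_repeats=2, seed=0):
    return make_schedule(0, 1, n_repeats, duration, 0.0, seed=seed)


def test_gain_zero_unit_rate_and_independence():
    base = FeatureMatrix(np.random.default_rng(0).standard_normal((2000, 3)), 20.0)
    stack = synth_feature_hierarchy({"repeat000": base}, 1, seed=0)
    sched = _flat_schedule(100.0, 0.05, n_repeats=2)
    unit = GroundTruthUnit("u0", 1, np.zeros((5, 3)), 0.0, 10.0, "primary")
    resp = simulate_unit_responses(unit, stack, sched, 0.05, seed=1)
    counts = resp.trials("repeat000", "u0")
    # expected count per bin = rate * bin width = 0.5
    assert abs(counts.mean() - 0.5) < 0.05
    # no stimulus locking: trial-to-trial correlation ~ 0
    r = np.corrcoef(counts[0], counts[1])[0, 1]
    assert abs(r) < 0.1


def test_poisson_reliability_matches_total_variance_law():
    """Trial-pair correlation approaches s^2/(s^2+m): signal variance over
    signal variance plus Poisson mean, per the law of total variance."""
    rng = np.random.default_rng(4)
    n_bins = 100_000
    base = FeatureMatrix(
        np.convolve(rng.standard_normal(n_bins + 8), np.ones(5) / 5, "same")[
            :n_bins, None
        ]
        * 3.0,
        20.0,
    )
    stack = synth_feature_hierarchy({"repeat000": base}, 1, seed=0)
    sched = _flat_schedule(n_bins * 0.05, 0.05, n_repeats=2)
    trf = np.zeros((5, 1))
    trf[-1, 0] = 1.0
    unit = GroundTruthUnit("u0", 1, trf, 20.0, 5.0, "primary")
    rate = _unit_drive(unit, stack, "repeat000", 0.05) * 0.05  # per-bin mean
    expected = rate.var() / (rate.var() + rate.mean())
    resp = simulate_unit_responses(unit, stack, sched, 0.05, seed=2)
    counts = resp.trials("repeat000", "u0")
    r = np.corrcoef(counts[0], counts[1])[0, 1]
    assert abs(r - expected) < 0.02


def test_poisson_marginals_and_determinism():
    sess_args = dict(n_single=2, n_repeat_stimuli=1, n_repeats=60,
                     duration_mean=1.0, n_units=2, n_layers=2, seed=21)
    from spikereadout import simulate_session

    a = simulate_session(**sess_args)
    b = simulate_session(**sess_args)
    for ca, cb in zip(a.responses.counts, b.responses.counts):
        np.testing.assert_array_equal(ca, cb)
    rep_id = a.schedule.repeat_set[0].stimulus_id
    counts = a.responses.trials(rep_id, a.responses.unit_ids[0]).astype(float)
    ratio = counts.var(axis=0, ddof=1) / np.maximum(counts.mean(axis=0), 1e-9)
    # Fano factor ~ 1 per bin for Poisson; average across bins tightens it
    assert abs(ratio.mean() - 1.0) < 0.25


def test_region_layer_assignment_soft_hierarchy():
    from spikereadout import simulate_session

    sess = simulate_session(n_single=2, n_repeat_stimuli=2, n_repeats=2,
                            n_units=300, n_layers=4, seed=3)
    prim = [u.target_layer for u in sess.units if u.region_label == "primary"]
    nonp = [u.target_layer for u in sess.units if u.region_label == "non-primary"]
    assert np.mean(prim) < np.mean(nonp)


def test_mismatched_stimuli_rejected():
    base = FeatureMatrix(np.zeros((20, 2)), 20.0)
    stack = synth_feature_hierarchy({"other": base}, 1, seed=0)
    sched = _flat_schedule(1.0, 0.05)
    unit = GroundTruthUnit("u0", 1, np.zeros((5, 2)), 1.0, 5.0, "primary")
    with pytest.raises(ValueError):
        simulate_responses([unit], stack, sched, 0.05, seed=0)
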