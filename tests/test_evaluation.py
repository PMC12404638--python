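"""Held-out scoring, paired comparisons, FDR control, correlation ratios."""

import numpy as np
import pytest

from spikereadout import (
    assemble_long_sequences,
    compare_models,
    correlation_ratio,
    score_unit,
)
from spikereadout.evaluation import UnitModelScore


def _fake_repeats(rng, m=10, reps=11, bins=32):
    return {f"s{i:02d}": rng.poisson(1.0, size=(reps, bins)) for i in range(m)}


def test_assemble_counts_and_lengths():
    rng = np.random.default_rng(0)
    repeats = _fake_repeats(rng, m=10, reps=11, bins=32)
    preds = {s: rng.standard_normal(32) for s in repeats}
    model_seq, resp_seqs = assemble_long_sequences(repeats, preds)
    assert len(resp_seqs) == 11
    assert model_seq.size == 320
    assert all(r.size == 320 for r in resp_seqs)
    repeats15 = _fake_repeats(rng, m=11, reps=15, bins=20)
    preds15 = {s: rng.standard_normal(20) for s in repeats15}
    _, seqs = assemble_long_sequences(repeats15, preds15)
    assert len(seqs) == 15 and seqs[0].size == 220


def test_assemble_degenerate_single_stimulus():
    resp = {"s0": np.array([[1, 2, 3], [4, 5, 6]])}
    preds = {"s0": np.array([0.1, 0.2, 0.3])}
    model_seq, seqs = assemble_long_sequences(resp, preds)
    assert len(seqs) == 2
    np.testing.assert_array_equal(seqs[0], [1, 2, 3])
    np.testing.assert_array_equal(seqs[1], [4, 5, 6])


def test_assemble_ragged_counts_named():
    resp = {"good": np.zeros((3, 4)), "bad": np.zeros((2, 4))}
    preds = {"good": np.zeros(4), "bad": np.zeros(4)}
    with pytest.raises(ValueError, match="ragged"):
        assemble_long_sequences(resp, preds)


def test_score_perfect_and_independent():
    rng = np.random.default_rng(1)
    seq = rng.standard_normal(300)
    perfect = score_unit(seq, [seq.copy(), seq.copy()], ceiling=1.0)
    assert perfect.mean_r == pytest.approx(1.0)
    rs = [
        score_unit(rng.standard_normal(300), [rng.standard_normal(300)], 1.0).mean_r
        for _ in range(200)
    ]
    assert abs(np.mean(rs)) < 0.02


def test_score_constant_model_flagged():
    sc = score_unit(np.ones(50), [np.random.default_rng(0).poisson(1.0, 50)], 0.5)
    assert sc.flagged and np.isnan(sc.corrected_r)


def test_score_noise_corrected():
    rng = np.random.default_rng(2)
    seq = rng.standard_normal(500)
    resp = [seq + rng.standard_normal(500) for _ in range(5)]
    sc = score_unit(seq, resp, ceiling=0.5)
    assert sc.corrected_r == pytest.approx(sc.mean_r / np.sqrt(0.5))


def _bh_step_up(pvals, alpha):
    """Textbook Benjamini-Hochberg step-up oracle."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    below = p[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        k = np.max(np.nonzero(below)[0])
        reject[order[: k + 1]] = True
    return reject


def test_bh_decisions_match_step_up_oracle():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(3)
    for L in (4, 6, 15):
        for _ in range(333):
            p = rng.uniform(0, 1, size=2 * L) ** rng.uniform(0.5, 3)
            got = multipletests(p, alpha=0.01, method="fdr_bh")[0]
            np.testing.assert_array_equal(got, _bh_step_up(p, 0.01))


def _paired_inputs(rng, L=3, n=50, shift=0.0):
    trained = {"m": {l: rng.uniform(0.2, 0.8, n) for l in range(1, L + 1)}}
    untrained = {"m": {l: trained["m"][l] - shift for l in range(1, L + 1)}}
    strf = {"m": trained["m"][1] - shift}
    return trained, untrained, strf


def test_compare_identical_vectors_no_stars():
    rng = np.random.default_rng(4)
    v = rng.uniform(0.2, 0.8, 50)
    trained = {"m": {l: v.copy() for l in range(1, 4)}}
    untrained = {"m": {l: v.copy() for l in range(1, 4)}}
    strf = {"m": v.copy()}
    res = compare_models(trained, untrained, strf)
    assert (res.table.p == 1.0).all()
    assert not res.table.reject.any()
    assert len(res.table) == 2 * 3  # 2L comparisons


def test_compare_shifted_vectors_all_significant():
    rng = np.random.default_rng(5)
    res = compare_models(*_paired_inputs(rng, shift=0.2))
    assert res.table.reject.all()
    assert (res.table.direction == "greater").all()


def test_compare_pairing_integrity():
    rng = np.random.default_rng(6)
    trained, untrained, strf = _paired_inputs(rng, shift=0.05)
    p1 = compare_models(trained, untrained, strf).table.p.values
    perm = rng.permutation(50)
    trained2 = {"m": {l: v[perm] for l, v in trained["m"].items()}}
    untrained2 = {"m": {l: v[perm] for l, v in untrained["m"].items()}}
    strf2 = {"m": strf["m"][perm]}
    p2 = compare_models(trained2, untrained2, strf2).table.p.values
    np.testing.assert_allclose(p1, p2)


def test_compare_unpaired_rejected():
    rng = np.random.default_rng(7)
    trained, untrained, strf = _paired_inputs(rng)
    untrained["m"][1] = untrained["m"][1][:-1]
    with pytest.raises(ValueError):
        compare_models(trained, untrained, strf)


def test_correlation_ratio_values_and_cancellation():
    a = UnitModelScore("u", "ann", np.array([0.3, 0.3]), ceiling=0.25)
    s = UnitModelScore("u", "strf", np.array([0.2, 0.2]), ceiling=0.25)
    assert correlation_ratio(a, s) == pytest.approx(0.3 / 0.2)
    assert correlation_ratio(s, s) == pytest.approx(1.0)
    # ceiling cancels: raw-ratio equals corrected-ratio
    a2 = UnitModelScore("u", "ann", np.array([0.3, 0.3]), ceiling=0.81)
    s2 = UnitModelScore("u", "strf", np.array([0.2, 0.2]), ceiling=0.81)
    assert correlation_ratio(a2, s2) == pytest.approx(correlation_ratio(a, s))
    with pytest.raises(ValueError):
        correlation_ratio(a, UnitModelScore("w", "strf", np.array([0.2]), 0.25))
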