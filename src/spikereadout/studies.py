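"""Canned verification studies over the synthetic generator.

Each function sets up a controlled synthetic condition, runs the
pipeline's estimators on it, and returns the measured quantities:
design arithmetic of the stimulus schedules, oracle agreement of the
ridge solver and the FDR step-up rule, calibration of the circular-shift
null, consistency of the noise-ceiling correction, and recovery of the
generating layer, the regional hierarchy, and the drive time scale.
They are used by the test suite and the acceptance script; problem
sizes are chosen to give stable Monte-Carlo estimates at desk scale.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .analyses import best_layer, hierarchy_compare, timescale_sweep
from .containers import FeatureMatrix
from .encoding import TemporalReceptiveField
from .evaluation import assemble_long_sequences, score_unit
from .pipeline import fit_and_score
from .reliability import (
    ReliabilityAnalysis,
    noise_correct,
    reliability_distributions,
    tuned_test,
)
from .synthetic import make_schedule, simulate_session

__all__ = [
    "schedule_arithmetic",
    "ridge_oracle_study",
    "poisson_ceiling_study",
    "null_calibration_study",
    "gaussian_ceiling_study",
    "layer_recovery_study",
    "median_peak_study",
    "hierarchy_study",
    "timescale_study",
    "bh_oracle_study",
]


def schedule_arithmetic(seed: int = 0) -> dict[str, int]:
    """Design arithmetic of the two stimulus-set layouts.

    489 once-presented + 10 x 11 repeated sentences of 1.6 s, and
    292 + 11 x 15 vocalizations of 1.0 s; repeat-set long sequences are
    measured at 50-ms bins via the pair-sampling operation itself.
    """
    from .reliability import sample_pair_sequences

    speech = make_schedule(489, 10, 11, 1.6, 0.0, seed=seed)
    vox = make_schedule(292, 11, 15, 1.0, 0.0, seed=seed + 1)
    out = {
        "n_unique_speech": len(speech.stimuli),
        "n_repeat_presentations_speech": sum(s.n_repeats for s in speech.repeat_set),
        "n_unique_vox": len(vox.stimuli),
        "n_repeat_presentations_vox": sum(s.n_repeats for s in vox.repeat_set),
    }
    rng = np.random.default_rng(seed)
    for name, sched in (("speech", speech), ("vox", vox)):
        resp = {
            s.stimulus_id: rng.poisson(1.0, size=(2, sched.n_bins(s.stimulus_id, 0.05)))
            for s in sched.repeat_set
        }
        u, _ = sample_pair_sequences(resp, seed=seed)
        out[f"long_sequence_bins_{name}"] = int(u.size)
    return out


def ridge_oracle_study(seed: int = 0, n_instances: int = 100) -> dict[str, float]:
    """Agreement of the CV-ridge solver with the closed-form solution."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(8, 21))
        d = int(rng.integers(1, 6))
        X = rng.standard_normal((n, d))
        y = rng.standard_normal(n)
        lam = 10.0 ** rng.uniform(-3, 3)
        res = TemporalReceptiveField(
            y, FeatureMatrix(X, 20.0), window=0.05,
            lambda_grid=np.array([lam]), standardize=False,
        ).fit(k_folds=3, seed=0)
        w_ref = np.linalg.solve(
            X.T @ X + lam * np.eye(d), X.T @ (y - y.mean())
        )
        rel = np.linalg.norm(res.coef_ - w_ref) / (np.linalg.norm(w_ref) + 1e-30)
        worst = max(worst, rel)
    # heavy-shrinkage limit
    X = rng.standard_normal((60, 4))
    y = X @ rng.standard_normal(4) + 0.1 * rng.standard_normal(60)
    fm = FeatureMatrix(X, 20.0)
    ols = TemporalReceptiveField(
        y, fm, window=0.05, lambda_grid=np.array([1e-10]), standardize=False
    ).fit(seed=0)
    heavy = TemporalReceptiveField(
        y, fm, window=0.05, lambda_grid=np.array([1e15]), standardize=False
    ).fit(seed=0)
    shrink = np.linalg.norm(heavy.coef_) / np.linalg.norm(ols.coef_)
    return {"max_rel_error": float(worst), "shrinkage_ratio": float(shrink)}


def poisson_ceiling_study(
    seed: int = 0, n_stimuli: int = 6, bins_per_stim: int = 2500, n_trials: int = 4
) -> dict[str, float]:
    """Noise correction consistency: scoring the true rate of a Poisson unit.

    The model sequence is the unit's exact per-bin rate; after dividing
    the mean model-response correlation by the square root of the
    estimated ceiling, the corrected correlation should approach 1.
    """
    rng = np.random.default_rng(seed)
    rates, resp = {}, {}
    for i in range(n_stimuli):
        smooth = np.convolve(
            rng.standard_normal(bins_per_stim + 8), np.ones(6) / 6, "same"
        )
        lam = np.maximum(0.2 + 2.0 * np.maximum(smooth[:bins_per_stim], 0), 0.01)
        rates[f"s{i}"] = lam
        resp[f"s{i}"] = rng.poisson(lam, size=(n_trials, bins_per_stim))
    true, _ = reliability_distributions(resp, R=400, seed=seed + 1)
    ceiling = true.mean()
    model_seq, resp_seqs = assemble_long_sequences(resp, rates)
    sc = score_unit(model_seq, resp_seqs, ceiling)
    return {
        "ceiling": float(ceiling),
        "raw_r": float(sc.mean_r),
        "corrected_r": float(sc.corrected_r),
    }


def null_calibration_study(
    seed: int = 0, n_units: int = 300, R: int = 4000
) -> dict[str, float]:
    """Null centering and tuned-test type-I rate on gain-0 Poisson units.

    Each unit is pure Poisson noise (no stimulus locking): the grand mean
    of the null correlations estimates 0, and the fraction of units the
    rank-sum tuned test flags at p<0.05 is the empirical type-I rate of
    the procedure (resamples are correlated, so the nominal level is not
    guaranteed).
    """
    rng = np.random.default_rng(seed)
    hits = 0
    null_means = []
    true_means = []
    for i in range(n_units):
        resp = {
            f"s{m}": rng.poisson(0.5, size=(11, 32)) for m in range(10)
        }
        t, n = reliability_distributions(resp, R=R, seed=int(rng.integers(2**31)))
        null_means.append(n.mean())
        true_means.append(t.mean())
        hits += tuned_test(t, n) < 0.05
    return {
        "null_grand_mean": float(np.mean(null_means)),
        "true_grand_mean": float(np.mean(true_means)),
        "type_i_rate": hits / n_units,
        "n_units": n_units,
    }


def gaussian_ceiling_study(
    seed: int = 0, n_stimuli: int = 5, bins_per_stim: int = 2000
) -> dict[str, float]:
    """Ceiling estimator vs the closed-form signal fraction s2/(s2+n2)."""
    rng = np.random.default_rng(seed)
    sig_var, noise_var = 1.0, 1.5
    expected = sig_var / (sig_var + noise_var)
    resp = {}
    for i in range(n_stimuli):
        signal = rng.normal(0, np.sqrt(sig_var), size=bins_per_stim)
        resp[f"s{i}"] = signal + rng.normal(
            0, np.sqrt(noise_var), size=(6, bins_per_stim)
        )
    true, _ = reliability_distributions(resp, R=300, seed=seed + 1)
    return {
        "estimated_ceiling": float(true.mean()),
        "expected_ceiling": float(expected),
        "abs_error": float(abs(true.mean() - expected)),
    }


def _session_scores(session, R, seed, unit_subset=None):
    repeat = {
        u: session.responses.repeat_responses(u, session.schedule)
        for u in session.responses.unit_ids
    }
    rel = ReliabilityAnalysis(repeat).fit(R=R, seed=seed)
    well = rel.well_tuned_units()
    if unit_subset is not None:
        well = [u for u in well if u in unit_subset]
    scores = fit_and_score(session, rel, unit_ids=well, seed=seed)
    return rel, well, scores


def layer_recovery_study(seed: int = 0, n_units: int = 200) -> dict[str, float]:
    """Fraction of well-tuned units whose best layer is the generating one."""
    sess = simulate_session(
        n_single=30, n_repeat_stimuli=8, n_repeats=8, duration_mean=1.2,
        n_units=n_units, n_layers=4, seed=seed,
    )
    rel, well, scores = _session_scores(sess, R=1000, seed=seed + 1)
    L = sess.stacks["trained"].n_layers
    target = {u.unit_id: u.target_layer for u in sess.units}
    hits = 0
    for u in well:
        vals = [
            scores[(scores.unit_id == u) & (scores.model_id == f"trained:layer{l}")]
            .corrected_r.iloc[0]
            for l in range(1, L + 1)
        ]
        pref = best_layer(vals, unit_id=u)
        hits += pref is not None and pref.best_layer == target[u]
    return {
        "n_well_tuned": len(well),
        "recovery_fraction": hits / max(len(well), 1),
        "median_corrected_r_generating_layer": float(
            np.nanmedian(
                [
                    scores[
                        (scores.unit_id == u)
                        & (scores.model_id == f"trained:layer{target[u]}")
                    ].corrected_r.iloc[0]
                    for u in well
                ]
            )
        ),
    }


def median_peak_study(
    seed: int = 0, n_seeds: int = 10, n_units: int = 16, generating_layer: int = 3
) -> dict[str, float]:
    """Across sessions generated from one layer: how often does the median
    corrected correlation across well-tuned units peak at that layer?"""
    rng = np.random.default_rng(seed)
    peaks = 0
    used = 0
    for _ in range(n_seeds):
        s = int(rng.integers(2**31))
        sess = simulate_session(
            n_single=20, n_repeat_stimuli=6, n_repeats=6, duration_mean=1.0,
            n_units=n_units, n_layers=4, target_layer=generating_layer, seed=s,
        )
        rel, well, scores = _session_scores(sess, R=800, seed=s % 10000)
        if not well:
            continue
        used += 1
        med = scores.groupby("model_id").corrected_r.median()
        layers = [med.get(f"trained:layer{l}", -np.inf) for l in range(1, 5)]
        peaks += int(np.argmax(layers)) + 1 == generating_layer
    return {"peak_fraction": peaks / max(used, 1), "n_sessions": used}


def hierarchy_study(
    seed: int = 0, n_per_group: int = 200, n_shuffles: int = 100
) -> dict[str, float]:
    """Regional hierarchy recovery on a shallow-primary / deep-non-primary
    session, plus a label-shuffle sanity check."""
    sess = simulate_session(
        n_single=16, n_repeat_stimuli=6, n_repeats=6, duration_mean=1.0,
        n_units=2 * n_per_group, n_layers=4, primary_fraction=0.5,
        crossover=0.25, seed=seed,
    )
    rel, well, scores = _session_scores(sess, R=600, seed=seed + 1)
    L = sess.stacks["trained"].n_layers
    region = {u.unit_id: u.region_label for u in sess.units}
    depths, labels = [], []
    for u in well:
        vals = [
            scores[(scores.unit_id == u) & (scores.model_id == f"trained:layer{l}")]
            .corrected_r.iloc[0]
            for l in range(1, L + 1)
        ]
        pref = best_layer(vals, unit_id=u)
        if pref is not None:
            depths.append(pref.depth_fraction)
            labels.append(region[u])
    depths = np.asarray(depths)
    labels = np.asarray(labels)
    dp = depths[labels == "primary"]
    dn = depths[labels == "non-primary"]
    p = hierarchy_compare(dp, dn)
    rng = np.random.default_rng(seed + 2)
    shuffle_ps = []
    for _ in range(n_shuffles):
        perm = rng.permutation(depths.size)
        cut = dp.size
        shuffle_ps.append(hierarchy_compare(depths[perm[:cut]], depths[perm[cut:]]))
    shuffle_ps = np.asarray(shuffle_ps)
    return {
        "rank_sum_p": float(p),
        "n_primary": int(dp.size),
        "n_non_primary": int(dn.size),
        "median_depth_primary": float(np.median(dp)),
        "median_depth_non_primary": float(np.median(dn)),
        "shuffle_p_mean": float(shuffle_ps.mean()),
        "shuffle_rejection_rate": float((shuffle_ps < 0.05).mean()),
    }


def _timescale_setup(seed, base_lowpass, n_units, trf_smooth):
    sess = simulate_session(
        n_single=16, n_repeat_stimuli=6, n_repeats=6, duration_mean=1.2,
        n_units=n_units, n_layers=1, base_rate=50.0, base_smooth=0.3,
        base_lowpass_hz=base_lowpass, bin_width=0.02, target_layer=1,
        gain_range=(40.0, 80.0), trf_smooth=trf_smooth, seed=seed,
    )
    repeat = {
        u: sess.responses.repeat_responses(u, sess.schedule)
        for u in sess.responses.unit_ids
    }
    rel = ReliabilityAnalysis(repeat).fit(R=600, seed=seed + 1)
    feats = sess.stacks["trained"].layers[0]
    counts = {
        u: {
            s.stimulus_id: sess.responses.trials(s.stimulus_id, u)[0]
            for s in sess.schedule.unique_set
        }
        for u in sess.responses.unit_ids
    }
    return sess, feats, counts, repeat, rel


def timescale_study(seed: int = 0, n_units: int = 10) -> dict:
    """Low-pass sweep on broadband-driven and 2-Hz band-limited units.

    Broadband drive: more admitted bandwidth means more explainable
    structure, so the median corrected correlation should rise with the
    cutoff and peak at the Nyquist limit.  Band-limited drive (2 Hz):
    cutoffs comfortably above the drive bandwidth admit the same signal,
    so their score distributions are mutually indistinguishable.
    """
    cutoffs = [3.125, 6.25, 12.5, 25.0]
    # sharp readouts over near-white features: drive up to the Nyquist limit
    sess, feats, counts, repeat, rel = _timescale_setup(seed, None, n_units, 0.0)
    broad = timescale_sweep(
        feats, counts, repeat, rel.ceilings(), cutoffs, bin_rate=50.0, seed=seed
    )
    sess2, feats2, counts2, repeat2, rel2 = _timescale_setup(
        seed + 100, 2.0, n_units, 1.0
    )
    cutoffs_bl = [1.0, 5.0, 10.0, 25.0]
    band = timescale_sweep(
        feats2, counts2, repeat2, rel2.ceilings(), cutoffs_bl, bin_rate=50.0,
        seed=seed,
    )
    # pairwise indistinguishability among cutoffs >= 5 Hz
    hi = [i for i, c in enumerate(cutoffs_bl) if c >= 5.0]
    pairwise_min_p = 1.0
    for ii, i in enumerate(hi):
        for j in hi[ii + 1:]:
            a, b = band.scores[i], band.scores[j]
            mask = np.isfinite(a) & np.isfinite(b)
            if mask.sum() < 2 or np.allclose(a[mask], b[mask]):
                continue
            pairwise_min_p = min(
                pairwise_min_p, float(stats.wilcoxon(a[mask], b[mask]).pvalue)
            )
    return {
        "broadband_cutoffs": cutoffs,
        "broadband_medians": [float(m) for m in broad.medians()],
        "broadband_best_cutoff": float(broad.best_cutoff),
        "bandlimited_cutoffs": cutoffs_bl,
        "bandlimited_medians": [float(m) for m in band.medians()],
        "bandlimited_min_pairwise_p": pairwise_min_p,
    }


def bh_oracle_study(seed: int = 0, n_draws: int = 1000, L: int = 6) -> dict[str, float]:
    """Step-up FDR decisions vs the textbook rule on random p-vectors."""
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_draws):
        p = rng.uniform(0, 1, size=2 * L) ** rng.uniform(0.5, 3)
        got = multipletests(p, alpha=0.01, method="fdr_bh")[0]
        m = p.size
        order = np.argsort(p)
        below = p[order] <= 0.01 * np.arange(1, m + 1) / m
        want = np.zeros(m, dtype=bool)
        if below.any():
            k = int(np.max(np.nonzero(below)[0]))
            want[order[: k + 1]] = True
        mismatches += int(np.any(got != want))
    return {"mismatch_fraction": mismatches / n_draws}
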