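"""Population analyses: layer-preference hierarchy and prediction time scale.

The hierarchy analysis asks whether units from non-primary cortex prefer
deeper feature-hierarchy layers than primary units: each unit's best
layer (argmax of corrected correlation, shallowest on ties) is expressed
as a depth fraction and the two groups compared with a one-sided rank-sum
test.  The time-scale analysis low-pass filters the features at a sweep
of cutoffs, refits the TRF per cutoff, and locates the cutoff with the
largest median corrected correlation, together with the set of cutoffs
statistically indistinguishable from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import FeatureMatrix
from .encoding import TemporalReceptiveField
from .evaluation import assemble_long_sequences, score_unit
from .features import lowpass, resample_features

__all__ = [
    "LayerPreference",
    "TimescaleCurve",
    "best_layer",
    "hierarchy_compare",
    "timescale_sweep",
]


@dataclass
class LayerPreference:
    """Best-predicting layer for one unit, as index and depth fraction."""

    unit_id: str
    stack_id: str
    best_layer: int  # 1-based
    n_layers: int
    region_label: str = ""

    @property
    def depth_fraction(self) -> float:
        return self.best_layer / self.n_layers


def best_layer(
    unit_scores: list[float] | np.ndarray,
    unit_id: str = "",
    stack_id: str = "",
    region_label: str = "",
) -> LayerPreference | None:
    """Argmax layer with the shallowest-tie rule; None if all undefined.

    ``unit_scores[l]`` is the corrected correlation of layer l+1.
    """
    scores = np.asarray(unit_scores, dtype=float)
    if scores.size < 1:
        raise ValueError("at least one layer score required")
    if np.all(~np.isfinite(scores)):
        return None
    masked = np.where(np.isfinite(scores), scores, -np.inf)
    idx = int(np.argmax(masked))  # argmax returns the first (shallowest) max
    return LayerPreference(unit_id, stack_id, idx + 1, scores.size, region_label)


def hierarchy_compare(
    depths_primary: np.ndarray, depths_non_primary: np.ndarray
) -> float:
    """One-sided rank-sum p that non-primary depth fractions are larger."""
    dp = np.asarray(depths_primary, dtype=float)
    dn = np.asarray(depths_non_primary, dtype=float)
    if dp.size == 0 or dn.size == 0:
        raise ValueError("both groups must be nonempty")
    return float(stats.ranksums(dn, dp, alternative="greater").pvalue)


@dataclass
class TimescaleCurve:
    """Corrected-correlation distributions over a low-pass cutoff sweep."""

    cutoffs: np.ndarray
    scores: np.ndarray  # (n_cutoffs x n_units) corrected correlations
    unit_ids: list[str]
    best_cutoff: float
    indistinguishable_set: list[float]

    def medians(self) -> np.ndarray:
        return np.nanmedian(self.scores, axis=1)


def timescale_sweep(
    features: dict[str, FeatureMatrix],
    counts_by_unit: dict[str, dict[str, np.ndarray]],
    repeat_responses_by_unit: dict[str, dict[str, np.ndarray]],
    ceilings: dict[str, float],
    cutoffs: list[float],
    bin_rate: float = 50.0,
    seed: int = 0,
    alpha: float = 0.01,
    **trf_kwargs,
) -> TimescaleCurve:
    """Low-pass sweep: filter features, refit TRFs, score held-out repeats.

    ``features`` are per-stimulus matrices at the spike-bin rate
    (nominally 50 Hz for 20-ms bins); ``counts_by_unit`` holds the
    training counts per unit for the once-presented stimuli and
    ``repeat_responses_by_unit`` the (trials x bins) repeat-set arrays
    used for scoring.  The best cutoff maximizes the median corrected
    correlation; cutoffs whose paired signed-rank test against the best
    has p >= ``alpha`` are reported as indistinguishable from it.
    """
    cutoffs = sorted(float(c) for c in cutoffs)
    nyquist = bin_rate / 2.0
    if any(c > nyquist * (1 + 1e-9) for c in cutoffs):
        raise ValueError("cutoffs must not exceed the Nyquist frequency")
    resampled = {
        sid: resample_features(fm, bin_rate) for sid, fm in features.items()
    }
    unit_ids = list(counts_by_unit)
    scores = np.full((len(cutoffs), len(unit_ids)), np.nan)
    for ci, cutoff in enumerate(cutoffs):
        filtered = {sid: lowpass(fm, cutoff) for sid, fm in resampled.items()}
        for ui, unit_id in enumerate(unit_ids):
            train_counts = counts_by_unit[unit_id]
            trf = TemporalReceptiveField.from_session(
                train_counts,
                {s: filtered[s] for s in train_counts},
                **trf_kwargs,
            ).fit(seed=seed)
            repeats = repeat_responses_by_unit[unit_id]
            preds = {s: trf.predict(filtered[s]) for s in repeats}
            model_seq, resp_seqs = assemble_long_sequences(repeats, preds)
            sc = score_unit(model_seq, resp_seqs, ceilings[unit_id], unit_id)
            if not sc.flagged:
                scores[ci, ui] = sc.corrected_r
    medians = np.nanmedian(scores, axis=1)
    best_idx = int(np.nanargmax(medians))
    best_cutoff = cutoffs[best_idx]
    indist = []
    for ci, cutoff in enumerate(cutoffs):
        if ci == best_idx:
            indist.append(cutoff)
            continue
        a, b = scores[best_idx], scores[ci]
        mask = np.isfinite(a) & np.isfinite(b)
        if mask.sum() < 2 or np.allclose(a[mask], b[mask]):
            indist.append(cutoff)
            continue
        p = float(stats.wilcoxon(a[mask], b[mask]).pvalue)
        if p >= alpha:
            indist.append(cutoff)
    return TimescaleCurve(np.asarray(cutoffs), scores, unit_ids, best_cutoff, indist)
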