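"""Held-out model scoring and paired model comparisons.

Each (unit, model) pair is scored on the repeat set: predictions and
responses are concatenated into long sequences in a fixed stimulus
order, one response sequence per repeat index; the per-repeat Pearson
correlations are averaged and noise-corrected by the unit's ceiling.
Models are compared across units with paired Wilcoxon signed-rank tests
— each layer against its untrained counterpart and against the STRF
baseline, 2L tests per L-layer model — with Benjamini-Hochberg FDR
control applied within each model's family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .reliability import UncorrectableUnitError, noise_correct

__all__ = [
    "UnitModelScore",
    "ComparisonResult",
    "assemble_long_sequences",
    "score_unit",
    "compare_models",
    "correlation_ratio",
]


@dataclass
class UnitModelScore:
    """Per-repeat, mean, and noise-corrected correlations for one pair."""

    unit_id: str
    model_id: str
    per_repeat_r: np.ndarray
    ceiling: float
    mean_r: float = field(init=False)
    corrected_r: float = field(init=False)
    flagged: bool = False

    def __post_init__(self) -> None:
        self.per_repeat_r = np.asarray(self.per_repeat_r, dtype=float)
        self.mean_r = float(np.mean(self.per_repeat_r))
        if self.flagged or not np.isfinite(self.mean_r):
            self.flagged = True
            self.mean_r = float("nan")
            self.corrected_r = float("nan")
        else:
            self.corrected_r = noise_correct(self.mean_r, self.ceiling)


def assemble_long_sequences(
    repeat_responses: dict[str, np.ndarray],
    predictions: dict[str, np.ndarray],
    order: list[str] | None = None,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Concatenate predictions and responses into aligned long sequences.

    Returns one model sequence and one response sequence per repeat
    index, all concatenated over the same fixed stimulus order (sorted
    ids by default).  Every repeat stimulus must have the same trial
    count; ragged counts are rejected naming the offender.
    """
    if order is None:
        order = sorted(repeat_responses)
    missing = [s for s in order if s not in predictions]
    if missing:
        raise ValueError(f"missing predictions for stimuli: {missing[:3]}")
    counts = {s: repeat_responses[s].shape[0] for s in order}
    n_rep = counts[order[0]]
    for s, c in counts.items():
        if c != n_rep:
            raise ValueError(
                f"ragged repeat counts: stimulus {s!r} has {c}, expected {n_rep}"
            )
    parts_model, parts_resp = [], [[] for _ in range(n_rep)]
    for s in order:
        resp = repeat_responses[s]
        pred = np.asarray(predictions[s], dtype=float).ravel()
        n = min(resp.shape[1], pred.size)
        parts_model.append(pred[:n])
        for k in range(n_rep):
            parts_resp[k].append(resp[k, :n])
    model_seq = np.concatenate(parts_model)
    return model_seq, [np.concatenate(p) for p in parts_resp]


def score_unit(
    model_sequence: np.ndarray,
    response_sequences: list[np.ndarray],
    ceiling: float,
    unit_id: str = "",
    model_id: str = "",
) -> UnitModelScore:
    """Mean per-repeat Pearson correlation, noise-corrected by the ceiling."""
    model_sequence = np.asarray(model_sequence, dtype=float)
    if np.std(model_sequence) == 0:
        return UnitModelScore(
            unit_id, model_id, np.full(len(response_sequences), np.nan),
            ceiling, flagged=True,
        )
    rs = []
    for resp in response_sequences:
        resp = np.asarray(resp, dtype=float)
        if resp.size != model_sequence.size:
            raise ValueError("model and response sequences differ in length")
        rs.append(
            np.nan if np.std(resp) == 0
            else float(np.corrcoef(model_sequence, resp)[0, 1])
        )
    rs = np.asarray(rs)
    if np.all(np.isnan(rs)):
        return UnitModelScore(unit_id, model_id, rs, ceiling, flagged=True)
    try:
        return UnitModelScore(unit_id, model_id, rs[np.isfinite(rs)], ceiling)
    except UncorrectableUnitError:
        return UnitModelScore(unit_id, model_id, rs, ceiling, flagged=True)


@dataclass
class ComparisonResult:
    """Per-layer paired-test table with BH-adjusted decisions."""

    table: pd.DataFrame  # columns: model, layer, test, p, direction, reject
    alpha: float

    def rejected(self) -> pd.DataFrame:
        return self.table[self.table["reject"]]


def _paired_test(a: np.ndarray, b: np.ndarray) -> tuple[float, str]:
    """Two-sided Wilcoxon signed-rank p and effect direction."""
    diff = a - b
    mask = np.isfinite(diff)
    d = diff[mask]
    if d.size == 0:
        return float("nan"), "none"
    if np.allclose(d, 0):
        return 1.0, "none"
    p = float(stats.wilcoxon(a[mask], b[mask]).pvalue)
    direction = "greater" if np.median(d) > 0 else "less"
    return p, direction


def compare_models(
    scores_by_model: dict[str, dict[int, np.ndarray]],
    untrained_scores: dict[str, dict[int, np.ndarray]],
    strf_scores: dict[str, np.ndarray],
    alpha: float = 0.01,
) -> ComparisonResult:
    """Paired per-layer comparisons with per-model BH correction.

    ``scores_by_model[model][layer]`` is the vector of corrected
    correlations across a fixed unit set; ``untrained_scores`` is
    parallel, ``strf_scores[model]`` the STRF vector over the same units.
    For each model the 2L raw p-values (trained vs untrained, trained vs
    STRF per layer) form one BH family at level ``alpha``.
    """
    rows = []
    for model, layers in scores_by_model.items():
        strf = np.asarray(strf_scores[model], dtype=float)
        ps, meta = [], []
        for layer in sorted(layers):
            trained = np.asarray(layers[layer], dtype=float)
            untrained = np.asarray(untrained_scores[model][layer], dtype=float)
            if trained.shape != untrained.shape or trained.shape != strf.shape:
                raise ValueError(
                    f"unpaired score vectors for model {model!r} layer {layer}"
                )
            for test, other in (("vs_untrained", untrained), ("vs_strf", strf)):
                p, direction = _paired_test(trained, other)
                ps.append(p)
                meta.append((model, layer, test, direction))
        ps = np.asarray(ps)
        ok = np.isfinite(ps)
        reject = np.zeros(ps.size, dtype=bool)
        if ok.any():
            reject[ok] = multipletests(ps[ok], alpha=alpha, method="fdr_bh")[0]
        for (model_, layer, test, direction), p, rej in zip(meta, ps, reject):
            rows.append(
                {"model": model_, "layer": layer, "test": test,
                 "p": p, "direction": direction, "reject": bool(rej)}
            )
    return ComparisonResult(pd.DataFrame(rows), alpha)


def correlation_ratio(score: UnitModelScore, strf_score: UnitModelScore) -> float:
    """Model-to-STRF corrected-correlation ratio for one unit.

    The common ceiling normalizer cancels, so the ratio equals the raw
    mean-correlation ratio; the STRF's own ratio is identically 1.
    """
    if score.unit_id != strf_score.unit_id:
        raise ValueError("scores belong to different units")
    if not np.isfinite(strf_score.corrected_r) or strf_score.corrected_r == 0:
        raise ZeroDivisionError(
            f"STRF correlation is zero/undefined for unit {score.unit_id!r}"
        )
    return float(score.corrected_r / strf_score.corrected_r)
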