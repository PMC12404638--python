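"""Trial-to-trial reliability, circular-shift null, and noise correction.

For each multi-unit channel, reliability is estimated from the repeat
set: for every repeat stimulus a random pair of distinct trials is drawn,
the two members are concatenated (same random stimulus order for both)
into long sequences U and V, and their Pearson correlation recorded.
Repeating this R times yields the "true" distribution; circularly
shifting V by half its length before correlating yields a null that
preserves marginals but destroys temporal alignment.  The mean of the
true distribution is the noise ceiling used to correct model-neuron
correlations: a noise-free model is normalized by the square root of the
between-trial correlation, because trial pairs carry two independent
noise sources while a model-neuron pair carries one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationDistribution",
    "UnitReliability",
    "sample_pair_sequences",
    "null_transform",
    "reliability_distributions",
    "tuned_test",
    "well_tuned",
    "noise_correct",
    "UncorrectableUnitError",
    "ReliabilityAnalysis",
]


@dataclass
class CorrelationDistribution:
    """A resampled set of correlation coefficients (true or null)."""

    values: np.ndarray
    kind: str  # "true" | "null"
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 1:
            raise ValueError("distribution must contain at least one value")
        if np.any(np.abs(self.values) > 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def R(self) -> int:
        return self.values.size

    def mean(self) -> float:
        return float(np.mean(self.values))

    def std(self) -> float:
        return float(np.std(self.values))


@dataclass
class UnitReliability:
    """Reliability summary for one unit: ceiling, tuned-test p, gap."""

    unit_id: str
    true_dist: CorrelationDistribution
    null_dist: CorrelationDistribution
    tuned_p: float = field(init=False)
    ceiling: float = field(init=False)
    gap: float = field(init=False)

    def __post_init__(self) -> None:
        self.ceiling = self.true_dist.mean()
        self.tuned_p = tuned_test(self.true_dist, self.null_dist)
        null_sd = self.null_dist.std()
        self.gap = (
            (self.ceiling - self.null_dist.mean()) / null_sd if null_sd > 0 else np.inf
        )

    @property
    def tuned(self) -> bool:
        return self.tuned_p < 0.05

    def well_tuned(self, delta: float = 0.5, alpha: float = 0.05) -> bool:
        return bool(self.gap >= delta and self.tuned_p < alpha)


def _check_repeats(repeat_responses: dict[str, np.ndarray]) -> None:
    if not repeat_responses:
        raise ValueError("no repeat stimuli supplied")
    for sid, arr in repeat_responses.items():
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise ValueError(f"stimulus {sid!r} needs >= 2 trials (trials x bins)")


def sample_pair_sequences(
    repeat_responses: dict[str, np.ndarray], seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one (U, V) pair of concatenated long sequences.

    For each repeat stimulus, two distinct trials are chosen; both
    sequences concatenate their member in the same seeded-random stimulus
    order, so U and V are aligned bin-for-bin.
    """
    _check_repeats(repeat_responses)
    rng = np.random.default_rng(seed)
    sids = list(repeat_responses)
    order = [sids[i] for i in rng.permutation(len(sids))]
    u_parts, v_parts = [], []
    for sid in order:
        arr = repeat_responses[sid]
        i, j = rng.choice(arr.shape[0], size=2, replace=False)
        u_parts.append(arr[i])
        v_parts.append(arr[j])
    return np.concatenate(u_parts), np.concatenate(v_parts)


def null_transform(v: np.ndarray) -> np.ndarray:
    """Circularly shift a sequence by half its length.

    output[i] = v[(i + floor(n/2)) mod n]; the sorted values (marginal
    histogram) are unchanged.
    """
    v = np.asarray(v)
    n = v.shape[-1] if v.ndim > 1 else v.size
    if n < 2:
        raise ValueError("sequence must have length >= 2")
    return np.roll(v, -(n // 2), axis=-1)


def _rowwise_pearson(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pearson correlation per row; rows with zero variance give NaN."""
    uc = u - u.mean(axis=1, keepdims=True)
    vc = v - v.mean(axis=1, keepdims=True)
    nu = np.sqrt(np.einsum("ij,ij->i", uc, uc))
    nv = np.sqrt(np.einsum("ij,ij->i", vc, vc))
    denom = nu * nv
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.einsum("ij,ij->i", uc, vc) / denom
    r[denom == 0] = np.nan
    return r


def reliability_distributions(
    repeat_responses: dict[str, np.ndarray],
    R: int = 100_000,
    seed: int = 0,
    chunk: int = 20_000,
) -> tuple[CorrelationDistribution, CorrelationDistribution]:
    """Resample R (true, null) correlation pairs for one unit.

    The resampling is vectorized: per chunk of resamples, trial pairs and
    stimulus orders are drawn for every resample at once and the long
    sequences assembled by fancy indexing.  Resamples whose U or V is
    constant have undefined correlations; they are excluded and counted.
    """
    _check_repeats(repeat_responses)
    if R < 1:
        raise ValueError("R must be >= 1")
    rng = np.random.default_rng(seed)
    sids = list(repeat_responses)
    arrays = [np.asarray(repeat_responses[s], dtype=float) for s in sids]
    n_trials = np.array([a.shape[0] for a in arrays])
    n_bins = np.array([a.shape[1] for a in arrays])
    M = len(sids)
    total = int(n_bins.sum())
    # flat concatenation of all (stimulus, trial) rows for one big gather
    flat = np.concatenate([a.ravel() for a in arrays])
    stim_offset = np.concatenate([[0], np.cumsum(n_trials * n_bins)])[:-1]
    bin_arange = [np.arange(b) for b in n_bins]

    r_true_parts, r_null_parts = [], []
    n_excluded = 0
    done = 0
    while done < R:
        r = min(chunk, R - done)
        # distinct trial pair per (resample, stimulus)
        i_sel = np.empty((r, M), dtype=np.int64)
        j_sel = np.empty((r, M), dtype=np.int64)
        for m in range(M):
            i = rng.integers(0, n_trials[m], size=r)
            j = rng.integers(0, n_trials[m] - 1, size=r)
            j = j + (j >= i)
            i_sel[:, m], j_sel[:, m] = i, j
        orders = np.argsort(rng.random((r, M)), axis=1)  # random stim order per row
        u = np.empty((r, total))
        v = np.empty((r, total))
        col = np.zeros(r, dtype=np.int64)
        # place stimulus blocks position-by-position in each row's order
        for pos in range(M):
            m_at = orders[:, pos]
            for m in range(M):
                rows = np.nonzero(m_at == m)[0]
                if rows.size == 0:
                    continue
                b = n_bins[m]
                cols = col[rows][:, None] + bin_arange[m][None, :]
                src_u = stim_offset[m] + i_sel[rows, m][:, None] * b + bin_arange[m]
                src_v = stim_offset[m] + j_sel[rows, m][:, None] * b + bin_arange[m]
                u[rows[:, None], cols] = flat[src_u]
                v[rows[:, None], cols] = flat[src_v]
                col[rows] += b
        r_t = _rowwise_pearson(u, v)
        r_n = _rowwise_pearson(u, null_transform(v))
        ok = np.isfinite(r_t) & np.isfinite(r_n)
        n_excluded += int((~ok).sum())
        r_true_parts.append(r_t[ok])
        r_null_parts.append(r_n[ok])
        done += r
    r_true = np.concatenate(r_true_parts)
    r_null = np.concatenate(r_null_parts)
    if r_true.size == 0:
        raise ValueError("all resamples had undefined correlations")
    return (
        CorrelationDistribution(np.clip(r_true, -1, 1), "true", n_excluded),
        CorrelationDistribution(np.clip(r_null, -1, 1), "null", n_excluded),
    )


def tuned_test(
    true: CorrelationDistribution, null: CorrelationDistribution
) -> float:
    """One-sided Wilcoxon rank-sum p-value for true > null."""
    return float(stats.ranksums(true.values, null.values, alternative="greater").pvalue)


def well_tuned(
    true: CorrelationDistribution,
    null: CorrelationDistribution,
    delta: float = 0.5,
    alpha: float = 0.05,
) -> bool:
    """Tuned-and-separated criterion.

    True iff mean(true) - mean(null) >= delta * std(null) (boundary
    inclusive) and the rank-sum test is significant at ``alpha``.
    """
    null_sd = null.std()
    if null_sd <= 0:
        raise ValueError("null distribution has zero variance")
    gap_ok = true.mean() - null.mean() >= delta * null_sd - 1e-12
    return bool(gap_ok and tuned_test(true, null) < alpha)


class UncorrectableUnitError(ValueError):
    """Raised when a unit's ceiling is too small to normalize by."""


def noise_correct(r_model: float, ceiling: float, floor: float = 1e-3) -> float:
    """Divide a model-neuron correlation by the square root of the ceiling.

    ``ceiling`` is the mean between-trial correlation; a value at or below
    ``floor`` makes the unit uncorrectable and raises, rather than
    silently clipping.
    """
    if ceiling <= floor:
        raise UncorrectableUnitError(
            f"ceiling {ceiling:.3g} at or below floor {floor:.3g}"
        )
    return float(r_model / np.sqrt(ceiling))


class ReliabilityAnalysis:
    """Session-level reliability estimation across units.

    Model-like object: construct from per-unit repeat responses, call
    :meth:`fit` to resample distributions, then query per-unit results or
    export the summary table.
    """

    def __init__(
        self,
        repeat_responses_by_unit: dict[str, dict[str, np.ndarray]],
        delta: float = 0.5,
        alpha: float = 0.05,
    ) -> None:
        if not repeat_responses_by_unit:
            raise ValueError("no units supplied")
        self.repeat_responses_by_unit = repeat_responses_by_unit
        self.delta = delta
        self.alpha = alpha

    def fit(self, R: int = 10_000, seed: int = 0) -> "ReliabilityResults":
        rng = np.random.default_rng(seed)
        per_unit = {}
        for unit_id, resp in self.repeat_responses_by_unit.items():
            t, n = reliability_distributions(resp, R=R, seed=int(rng.integers(2**31)))
            per_unit[unit_id] = UnitReliability(unit_id, t, n)
        return ReliabilityResults(per_unit, self.delta, self.alpha)


class ReliabilityResults:
    """Fitted reliability distributions and derived unit classifications."""

    def __init__(
        self, per_unit: dict[str, UnitReliability], delta: float, alpha: float
    ) -> None:
        self.per_unit = per_unit
        self.delta = delta
        self.alpha = alpha

    def __getitem__(self, unit_id: str) -> UnitReliability:
        return self.per_unit[unit_id]

    @property
    def unit_ids(self) -> list[str]:
        return list(self.per_unit)

    def ceilings(self) -> dict[str, float]:
        return {u: r.ceiling for u, r in self.per_unit.items()}

    def tuned_units(self) -> list[str]:
        return [u for u, r in self.per_unit.items() if r.tuned_p < self.alpha]

    def well_tuned_units(self, delta: float | None = None) -> list[str]:
        d = self.delta if delta is None else delta
        return [u for u, r in self.per_unit.items() if r.well_tuned(d, self.alpha)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "unit_id": u,
                "ceiling": r.ceiling,
                "null_mean": r.null_dist.mean(),
                "null_std": r.null_dist.std(),
                "tuned_p": r.tuned_p,
                "gap": r.gap,
                "tuned": r.tuned_p < self.alpha,
                "well_tuned": r.well_tuned(self.delta, self.alpha),
                "n_excluded_resamples": r.true_dist.n_excluded,
                "R": r.true_dist.R,
            }
            for u, r in self.per_unit.items()
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            "Trial-to-trial reliability",
            "=" * 40,
            f"units:            {len(df)}",
            f"tuned (p<{self.alpha:g}):   {int(df['tuned'].sum())}",
            f"well-tuned (d>={self.delta:g}): {int(df['well_tuned'].sum())}",
            f"median ceiling:   {df['ceiling'].median():.3f}",
        ]
        return "\n".join(lines)
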