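"""Shared data containers for stimulus schedules, features, and spike counts.

The containers mirror the structure of a chronic multi-electrode session:
a schedule of audio stimuli (most presented once, a small "repeat set"
presented many times), per-stimulus feature matrices arranged in a layered
hierarchy, and binned spike counts per multi-unit channel and presentation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusInfo",
    "StimulusSchedule",
    "FeatureMatrix",
    "FeatureStack",
    "GroundTruthUnit",
    "ResponseTensor",
]


@dataclass(frozen=True)
class StimulusInfo:
    """One stimulus: identifier, duration in seconds, presentation count."""

    stimulus_id: str
    duration: float
    n_repeats: int

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError(f"n_repeats must be >= 1, got {self.n_repeats}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")


@dataclass
class StimulusSchedule:
    """The set of stimuli and the randomized order of their presentations.

    ``presentation_order`` is a list of ``(stimulus_id, repeat_index)``
    pairs; each pair occurs exactly once and the total length equals the
    sum of ``n_repeats`` over stimuli.
    """

    stimuli: list[StimulusInfo]
    presentation_order: list[tuple[str, int]]

    def __post_init__(self) -> None:
        ids = [s.stimulus_id for s in self.stimuli]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate stimulus ids in schedule")
        expected = {(s.stimulus_id, k) for s in self.stimuli for k in range(s.n_repeats)}
        got = list(self.presentation_order)
        if len(got) != len(set(got)):
            raise ValueError("presentation_order contains duplicates")
        if set(got) != expected:
            raise ValueError("presentation_order does not match stimulus repeat counts")

    @property
    def n_presentations(self) -> int:
        return len(self.presentation_order)

    @property
    def stimulus_ids(self) -> list[str]:
        return [s.stimulus_id for s in self.stimuli]

    @property
    def repeat_set(self) -> list[StimulusInfo]:
        """Stimuli presented more than once (reliability / evaluation set)."""
        return [s for s in self.stimuli if s.n_repeats > 1]

    @property
    def unique_set(self) -> list[StimulusInfo]:
        """Stimuli presented exactly once (model-fitting set)."""
        return [s for s in self.stimuli if s.n_repeats == 1]

    def duration_of(self, stimulus_id: str) -> float:
        for s in self.stimuli:
            if s.stimulus_id == stimulus_id:
                return s.duration
        raise KeyError(stimulus_id)

    def n_bins(self, stimulus_id: str, bin_width: float) -> int:
        """Bins per stimulus: ceiling of duration over bin width."""
        return math.ceil(self.duration_of(stimulus_id) / bin_width - 1e-9)

    def to_json(self) -> str:
        return json.dumps(
            {
                "stimuli": [
                    [s.stimulus_id, s.duration, s.n_repeats] for s in self.stimuli
                ],
                "presentation_order": [list(p) for p in self.presentation_order],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "StimulusSchedule":
        obj = json.loads(text)
        return cls(
            stimuli=[StimulusInfo(i, float(d), int(n)) for i, d, n in obj["stimuli"]],
            presentation_order=[(i, int(k)) for i, k in obj["presentation_order"]],
        )


@dataclass
class FeatureMatrix:
    """A (time x dimensions) feature array with its sampling rate in Hz."""

    values: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D (time x dims)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_dims(self) -> int:
        return self.values.shape[1]


@dataclass
class FeatureStack:
    """A layered feature hierarchy for a set of stimuli.

    ``layers[l][stimulus_id]`` is the layer-(l+1) FeatureMatrix for one
    stimulus.  Sampling rates are non-increasing with depth (convolutional
    strides).  The generating kernels are stored so the stack can be
    re-initialized or weight-permuted and the features recomputed.
    """

    layers: list[dict[str, FeatureMatrix]]
    kernels: list[np.ndarray]  # kernels[l] maps layer l+1 -> l+2; len L-1
    strides: list[int]
    base: dict[str, np.ndarray] = field(default_factory=dict)
    base_rate: float = 0.0

    def __post_init__(self) -> None:
        rates = self.layer_rates
        if any(r2 > r1 + 1e-9 for r1, r2 in zip(rates, rates[1:])):
            raise ValueError("layer sampling rates must be non-increasing")

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def stimulus_ids(self) -> list[str]:
        return list(self.layers[0].keys())

    @property
    def layer_rates(self) -> list[float]:
        sid = next(iter(self.layers[0]))
        return [layer[sid].sampling_rate for layer in self.layers]

    def layer(self, index: int) -> dict[str, FeatureMatrix]:
        """1-based layer accessor (layer 1 is the shallowest)."""
        if not 1 <= index <= self.n_layers:
            raise IndexError(f"layer index {index} outside 1..{self.n_layers}")
        return self.layers[index - 1]


@dataclass
class GroundTruthUnit:
    """Generative description of one simulated multi-unit channel.

    The stimulus-locked drive is a linear readout (``true_trf``, lags x
    feature dims, spanning a 250-ms causal window by default) of one target
    layer; firing rate is baseline plus gain times the rectified drive.
    """

    unit_id: str
    target_layer: int
    true_trf: np.ndarray
    gain: float
    baseline_rate: float
    region_label: str  # "primary" | "non-primary"

    def __post_init__(self) -> None:
        if self.target_layer < 1:
            raise ValueError("target_layer is 1-based and must be >= 1")
        if self.gain < 0 or self.baseline_rate < 0:
            raise ValueError("gain and baseline_rate must be non-negative")
        if self.region_label not in ("primary", "non-primary"):
            raise ValueError(f"unknown region_label {self.region_label!r}")
        self.true_trf = np.atleast_2d(np.asarray(self.true_trf, dtype=float))


@dataclass
class ResponseTensor:
    """Spike counts per unit, presentation, and time bin.

    ``counts[p]`` is a (units x bins) non-negative integer array for the
    p-th entry of ``presentation_order``; bin counts follow the stimulus
    duration at the stated bin width, so the per-presentation bin axis is
    ragged across stimuli.
    """

    counts: list[np.ndarray]
    bin_width: float
    presentation_order: list[tuple[str, int]]
    unit_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.presentation_order):
            raise ValueError("one count array per presentation required")
        for c in self.counts:
            if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
                raise ValueError("counts must be non-negative integers")

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def unit_index(self, unit_id: str) -> int:
        return self.unit_ids.index(unit_id)

    def trials(self, stimulus_id: str, unit_id: str | None = None) -> np.ndarray:
        """All trials of one stimulus, stacked (trials x bins) in repeat order.

        With ``unit_id`` None, returns (units x trials x bins).
        """
        entries = sorted(
            (k, i)
            for i, (sid, k) in enumerate(self.presentation_order)
            if sid == stimulus_id
        )
        if not entries:
            raise KeyError(stimulus_id)
        stacked = np.stack([self.counts[i] for _, i in entries], axis=1)
        if unit_id is None:
            return stacked
        return stacked[self.unit_index(unit_id)]

    def repeat_responses(
        self, unit_id: str, schedule: StimulusSchedule
    ) -> dict[str, np.ndarray]:
        """Per-stimulus (trials x bins) arrays for the repeat set of one unit."""
        return {
            s.stimulus_id: self.trials(s.stimulus_id, unit_id)
            for s in schedule.repeat_set
        }
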