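"""Synthetic session generator.

Produces sessions with the statistical structure the analysis pipeline
assumes: a schedule mixing once-presented stimuli with a small repeat set,
a stacked-nonlinearity feature hierarchy standing in for the layers of a
speech-trained network, and Poisson spike counts whose stimulus-locked
drive is a ground-truth linear readout (250-ms causal window) of one
chosen layer.  Repeat presentations share the underlying rate and differ
only in the Poisson draws, so trial-to-trial reliability is controlled by
the gain-to-baseline ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .containers import (
    FeatureMatrix,
    FeatureStack,
    GroundTruthUnit,
    ResponseTensor,
    StimulusInfo,
    StimulusSchedule,
)
from .features import resample_features

__all__ = [
    "make_schedule",
    "synth_waveform",
    "synth_feature_hierarchy",
    "perturb_hierarchy",
    "simulate_unit_responses",
    "simulate_responses",
    "make_units",
    "SyntheticSession",
    "simulate_session",
]


def make_schedule(
    n_single: int,
    n_repeat_stimuli: int,
    n_repeats: int,
    duration_mean: float,
    duration_jitter: float = 0.0,
    seed: int = 0,
) -> StimulusSchedule:
    """Build a stimulus schedule with a once-presented set and a repeat set.

    Durations are drawn uniformly in ``duration_mean +/- duration_jitter``;
    the presentation order is a seeded random permutation of all
    (stimulus, repeat) pairs, emulating fully interleaved presentation.
    """
    if n_single < 0 or n_repeat_stimuli < 0 or n_repeats < 0:
        raise ValueError("counts must be non-negative")
    if n_single + n_repeat_stimuli == 0:
        raise ValueError("schedule must contain at least one stimulus")
    if duration_mean - duration_jitter <= 0:
        raise ValueError("durations must stay positive under jitter")
    rng = np.random.default_rng(seed)
    stimuli: list[StimulusInfo] = []
    for i in range(n_single):
        d = duration_mean + rng.uniform(-duration_jitter, duration_jitter)
        stimuli.append(StimulusInfo(f"single{i:04d}", float(d), 1))
    for i in range(n_repeat_stimuli):
        d = duration_mean + rng.uniform(-duration_jitter, duration_jitter)
        stimuli.append(StimulusInfo(f"repeat{i:03d}", float(d), max(n_repeats, 1)))
    order = [(s.stimulus_id, k) for s in stimuli for k in range(s.n_repeats)]
    perm = rng.permutation(len(order))
    return StimulusSchedule(stimuli, [order[i] for i in perm])


def synth_waveform(
    duration: float,
    sample_rate: float = 16000.0,
    seed: int = 0,
    n_tones: int = 4,
    noise_level: float = 0.3,
    tone_freqs: list[float] | None = None,
    modulated: bool = True,
) -> np.ndarray:
    """Synthesize an audio-like waveform with spectrotemporal structure.

    A mixture of amplitude-modulated tone complexes and slowly modulated
    broadband noise, so the cochleagram of the output has nontrivial
    structure across both time and frequency.  ``tone_freqs`` pins the
    tone frequencies (otherwise drawn log-uniformly in 100-6000 Hz);
    ``tone_freqs=[f]`` with ``noise_level=0`` and ``modulated=False``
    gives a pure tone.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if sample_rate < 16000:
        raise ValueError("sample_rate must be at least 16 kHz")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    wave = np.zeros(n)
    if tone_freqs is None:
        tone_freqs = [
            10 ** rng.uniform(np.log10(100), np.log10(6000)) for _ in range(n_tones)
        ]
    for f0 in tone_freqs:
        if modulated:
            mod_rate = rng.uniform(1.0, 8.0)
            phase = rng.uniform(0, 2 * np.pi)
            env = 0.5 * (1 + np.sin(2 * np.pi * mod_rate * t + phase))
        else:
            env = np.ones(n)
        wave += env * np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
    if noise_level > 0:
        noise = rng.standard_normal(n)
        slow = 0.5 * (1 + np.sin(2 * np.pi * rng.uniform(0.5, 4.0) * t))
        wave += noise_level * slow * noise
    peak = np.max(np.abs(wave))
    if peak > 0:
        wave = wave / peak * 0.9
    return wave


def _causal_conv(values: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Causal temporal convolution mixing dimensions.

    kernel has shape (k_t, d_in, d_out); output[t] pools inputs
    t-k_t+1 .. t (zero-padded at onset).
    """
    k_t = kernel.shape[0]
    padded = np.vstack([np.zeros((k_t - 1, values.shape[1])), values])
    windows = np.lib.stride_tricks.sliding_window_view(padded, k_t, axis=0)
    # windows: (T, d_in, k_t) -> contract with kernel (k_t, d_in, d_out)
    return np.einsum("tdk,kdo->to", windows, kernel)


def _init_kernel(
    rng: np.random.Generator,
    k_t: int,
    d_in: int,
    d_out: int,
    mode: str = "random",
    gain: float = 0.5,
) -> np.ndarray:
    """Draw a layer kernel.

    ``random`` is the small-value initialization (near-linear through the
    tanh); ``structured`` builds smoothing and temporal-differencing
    kernels with larger gain, emulating the organized filters of a
    task-trained network.
    """
    if mode == "random":
        return gain * rng.standard_normal((k_t, d_in, d_out)) / math.sqrt(k_t * d_in)
    if mode != "structured":
        raise ValueError(f"unknown kernel mode {mode!r}")
    kernel = np.zeros((k_t, d_in, d_out))
    taps = np.arange(k_t)
    for o in range(d_out):
        src = rng.integers(0, d_in)
        kind = o % 3
        if kind == 0:  # temporal smoother
            w = np.exp(-0.5 * ((taps - (k_t - 1)) / max(k_t / 2, 1)) ** 2)
            kernel[:, src, o] = w / w.sum()
        elif kind == 1:  # temporal differencer
            kernel[-1, src, o] = 1.0
            kernel[0, src, o] = -1.0
        else:  # spectral contrast between two input dims
            other = rng.integers(0, d_in)
            kernel[-1, src, o] = 1.0
            kernel[-1, other, o] -= 0.5
    kernel *= 2.0 * gain
    # small random component breaks exact ties between duplicate sources
    kernel += 0.05 * gain * rng.standard_normal(kernel.shape)
    return kernel


def _compute_layers(
    base: dict[str, np.ndarray],
    base_rate: float,
    kernels: list[np.ndarray],
    strides: list[int],
) -> list[dict[str, FeatureMatrix]]:
    layers: list[dict[str, FeatureMatrix]] = []
    rate = base_rate / strides[0]
    first = {}
    for sid, vals in base.items():
        v = vals[:: strides[0]]
        if v.shape[0] < 1:
            raise ValueError(f"stride {strides[0]} leaves no frames for {sid}")
        first[sid] = FeatureMatrix(v, rate)
    layers.append(first)
    for kernel, stride in zip(kernels, strides[1:]):
        rate = rate / stride
        nxt = {}
        for sid, fm in layers[-1].items():
            conv = _causal_conv(fm.values, kernel)
            act = np.tanh(conv)[::stride]
            if act.shape[0] < 1:
                raise ValueError(f"stride {stride} leaves no frames for {sid}")
            nxt[sid] = FeatureMatrix(act, rate)
        layers.append(nxt)
    return layers


def synth_feature_hierarchy(
    base_features: FeatureMatrix | dict[str, FeatureMatrix],
    n_layers: int,
    strides: list[int] | None = None,
    seed: int = 0,
    n_dims: int | None = None,
    kernel_width: int = 5,
    mode: str = "random",
    gain: float = 0.5,
) -> FeatureStack:
    """Stack saturating random temporal convolutions on base features.

    Layer 1 is the base (downsampled by ``strides[0]``, normally 1); each
    deeper layer applies a seeded temporal convolution followed by a tanh
    and downsampling by its stride, so the effective sampling rate is
    non-increasing with depth.  Kernels are stored on the stack so it can
    be re-initialized or weight-permuted later.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    strides = list(strides) if strides is not None else [1] * n_layers
    if len(strides) != n_layers or any(s < 1 for s in strides):
        raise ValueError("strides must be positive, one per layer")
    if isinstance(base_features, FeatureMatrix):
        base_features = {"stim": base_features}
    base_rate = next(iter(base_features.values())).sampling_rate
    base = {sid: fm.values for sid, fm in base_features.items()}
    d_in = next(iter(base.values())).shape[1]
    d_out = n_dims if n_dims is not None else d_in
    rng = np.random.default_rng(seed)
    kernels = []
    d = d_in
    for _ in range(n_layers - 1):
        kernels.append(_init_kernel(rng, kernel_width, d, d_out, mode, gain))
        d = d_out
    layers = _compute_layers(base, base_rate, kernels, strides)
    return FeatureStack(layers, kernels, strides, base=base, base_rate=base_rate)


def perturb_hierarchy(
    stack: FeatureStack, mode: str, seed: int = 0
) -> FeatureStack:
    """Return an 'untrained' counterpart of a feature stack.

    ``reinitialize`` redraws every kernel from the small-value random
    initialization; ``permute`` shuffles the existing kernel entries
    within each layer, preserving the weight distribution but destroying
    its structure (large shuffled weights drive the tanh into saturation).
    Features are recomputed from the stored base.
    """
    if not stack.kernels and stack.n_layers > 1:
        raise ValueError("stack carries no stored kernels")
    rng = np.random.default_rng(seed)
    new_kernels = []
    for kernel in stack.kernels:
        if mode == "reinitialize":
            k_t, d_in, d_out = kernel.shape
            new_kernels.append(
                0.5 * rng.standard_normal(kernel.shape) / math.sqrt(k_t * d_in)
            )
        elif mode == "permute":
            flat = kernel.ravel().copy()
            rng.shuffle(flat)
            new_kernels.append(flat.reshape(kernel.shape))
        else:
            raise ValueError(f"unknown perturbation mode {mode!r}")
    layers = _compute_layers(stack.base, stack.base_rate, new_kernels, stack.strides)
    return FeatureStack(
        layers, new_kernels, list(stack.strides), base=stack.base,
        base_rate=stack.base_rate,
    )


def _unit_drive(
    unit: GroundTruthUnit, stack: FeatureStack, stimulus_id: str, bin_width: float
) -> np.ndarray:
    """Per-bin firing rate (spikes/s) of one unit for one stimulus."""
    from .encoding import LagSpec, build_lagged_design

    fm = stack.layer(unit.target_layer)[stimulus_id]
    target_rate = 1.0 / bin_width
    fm = resample_features(fm, target_rate)
    n_lags, n_dims = unit.true_trf.shape
    spec = LagSpec(window=n_lags / target_rate, rate=target_rate)
    if spec.n_lags != n_lags:
        raise ValueError("true_trf lag count inconsistent with bin width")
    design = build_lagged_design(fm, spec)
    drive = design @ unit.true_trf.ravel()
    return unit.baseline_rate + unit.gain * np.maximum(drive, 0.0)


def simulate_unit_responses(
    unit: GroundTruthUnit,
    stack: FeatureStack,
    schedule: StimulusSchedule,
    bin_width: float = 0.05,
    seed: int = 0,
) -> ResponseTensor:
    """Poisson spike counts for one unit across all presentations."""
    return simulate_responses([unit], stack, schedule, bin_width, seed)


def simulate_responses(
    units: list[GroundTruthUnit],
    stack: FeatureStack,
    schedule: StimulusSchedule,
    bin_width: float = 0.05,
    seed: int = 0,
) -> ResponseTensor:
    """Poisson spike counts for a unit population across all presentations.

    The per-bin rate of each unit is a fixed function of the stimulus
    (baseline + gain x rectified linear readout of the target layer), so
    repeats share the rate and differ only in the Poisson draws.
    """
    missing = set(schedule.stimulus_ids) - set(stack.stimulus_ids)
    if missing:
        raise ValueError(f"stack lacks features for stimuli: {sorted(missing)[:3]}")
    for u in units:
        if u.target_layer > stack.n_layers:
            raise ValueError(f"unit {u.unit_id} targets layer beyond stack depth")
    rng = np.random.default_rng(seed)
    # rates are stimulus-locked: compute once per (unit, stimulus)
    rates: dict[str, np.ndarray] = {}
    for s in schedule.stimuli:
        n_bins = schedule.n_bins(s.stimulus_id, bin_width)
        per_unit = np.empty((len(units), n_bins))
        for i, u in enumerate(units):
            r = _unit_drive(u, stack, s.stimulus_id, bin_width)
            if r.shape[0] < n_bins:
                r = np.pad(r, (0, n_bins - r.shape[0]), constant_values=u.baseline_rate)
            per_unit[i] = r[:n_bins]
        rates[s.stimulus_id] = per_unit
    counts = [
        rng.poisson(rates[sid] * bin_width).astype(np.int64)
        for sid, _ in schedule.presentation_order
    ]
    return ResponseTensor(
        counts, bin_width, list(schedule.presentation_order), [u.unit_id for u in units]
    )


def make_units(
    stack: FeatureStack,
    n_units: int,
    bin_width: float = 0.05,
    window: float = 0.25,
    gain_range: tuple[float, float] = (20.0, 60.0),
    baseline_range: tuple[float, float] = (2.0, 10.0),
    primary_fraction: float = 0.5,
    crossover: float = 0.25,
    seed: int = 0,
    target_layer: int | None = None,
    trf_smooth: float = 1.0,
) -> list[GroundTruthUnit]:
    """Draw a ground-truth unit population over a feature stack.

    Primary units draw their target layer from the shallow half of the
    stack and non-primary units from the deep half, with a ``crossover``
    fraction swapped, emulating a soft anatomical hierarchy.  True
    readout weights are random filters over a causal ``window`` (250 ms
    by default) at the spike-bin rate, temporally smoothed with a
    Gaussian of width ``trf_smooth`` lags (0 leaves them sharp, giving
    the drive structure up to the bin Nyquist).
    """
    rng = np.random.default_rng(seed)
    rate = 1.0 / bin_width
    n_lags = int(math.floor(window * rate + 0.5))
    L = stack.n_layers
    shallow = list(range(1, L // 2 + 1)) or [1]
    deep = list(range(L // 2 + 1, L + 1)) or [L]
    units = []
    for i in range(n_units):
        is_primary = rng.random() < primary_fraction
        pool = shallow if is_primary else deep
        if rng.random() < crossover:
            pool = deep if is_primary else shallow
        layer = target_layer if target_layer is not None else int(rng.choice(pool))
        d = stack.layer(layer)[stack.stimulus_ids[0]].n_dims
        # smooth sparse readout: few dims, low-pass random lag profile
        trf = np.zeros((n_lags, d))
        active = rng.choice(d, size=min(3, d), replace=False)
        for a in active:
            prof = rng.standard_normal(n_lags)
            if trf_smooth > 0:
                kern = np.exp(-0.5 * (np.arange(-2, 3) / trf_smooth) ** 2)
                prof = np.convolve(prof, kern / kern.sum(), mode="same")
            trf[:, a] = prof
        trf /= np.linalg.norm(trf) + 1e-12
        units.append(
            GroundTruthUnit(
                unit_id=f"unit{i:04d}",
                target_layer=layer,
                true_trf=trf,
                gain=float(rng.uniform(*gain_range)),
                baseline_rate=float(rng.uniform(*baseline_range)),
                region_label="primary" if is_primary else "non-primary",
            )
        )
    return units


@dataclass
class SyntheticSession:
    """A complete simulated session: schedule, stacks, units, responses."""

    schedule: StimulusSchedule
    stacks: dict[str, FeatureStack]  # e.g. {"trained": ..., "untrained": ...}
    strf_features: dict[str, FeatureMatrix]  # cochleagram-like baseline features
    units: list[GroundTruthUnit]
    responses: ResponseTensor

    @property
    def bin_width(self) -> float:
        return self.responses.bin_width


def simulate_session(
    n_single: int = 40,
    n_repeat_stimuli: int = 10,
    n_repeats: int = 11,
    duration_mean: float = 1.6,
    duration_jitter: float = 0.0,
    n_units: int = 30,
    n_layers: int = 4,
    strides: list[int] | None = None,
    base_dims: int = 12,
    base_rate: float = 80.0,
    bin_width: float = 0.05,
    gain_range: tuple[float, float] = (20.0, 60.0),
    baseline_range: tuple[float, float] = (2.0, 10.0),
    primary_fraction: float = 0.5,
    crossover: float = 0.25,
    seed: int = 0,
    target_layer: int | None = None,
    base_smooth: float = 2.5,
    base_lowpass_hz: float | None = None,
    trf_smooth: float = 1.0,
) -> SyntheticSession:
    """Generate a full synthetic session.

    Base features are smooth band-limited noise (a stand-in for a
    cochleagram; temporal bandwidth set by ``base_smooth``, the Gaussian
    smoothing width in samples, or capped hard by ``base_lowpass_hz``),
    the "trained" stack uses structured kernels, its "untrained"
    counterpart is a re-initialization, and responses are Poisson
    readouts of the trained stack.
    """
    from .features import lowpass as _lowpass

    rng = np.random.default_rng(seed)
    schedule = make_schedule(
        n_single, n_repeat_stimuli, n_repeats, duration_mean, duration_jitter,
        seed=int(rng.integers(2**31)),
    )
    base: dict[str, FeatureMatrix] = {}
    half = max(int(round(3 * base_smooth)), 1)
    kern = np.exp(-0.5 * (np.arange(-half, half + 1) / max(base_smooth, 1e-6)) ** 2)
    for s in schedule.stimuli:
        n = int(round(s.duration * base_rate))
        raw = rng.standard_normal((n + 20, base_dims))
        smooth = np.apply_along_axis(
            lambda v: np.convolve(v, kern / kern.sum(), mode="same"), 0, raw
        )
        fm = FeatureMatrix(smooth[10 : n + 10] * 3.0, base_rate)
        if base_lowpass_hz is not None:
            fm = _lowpass(fm, base_lowpass_hz)
        base[s.stimulus_id] = fm
    trained = synth_feature_hierarchy(
        base, n_layers, strides, seed=int(rng.integers(2**31)),
        mode="structured", gain=1.0,
    )
    untrained = perturb_hierarchy(trained, "reinitialize", seed=int(rng.integers(2**31)))
    units = make_units(
        trained, n_units, bin_width=bin_width,
        gain_range=gain_range, baseline_range=baseline_range,
        primary_fraction=primary_fraction, crossover=crossover,
        seed=int(rng.integers(2**31)), target_layer=target_layer,
        trf_smooth=trf_smooth,
    )
    responses = simulate_responses(
        units, trained, schedule, bin_width, seed=int(rng.integers(2**31))
    )
    strf_features = {sid: fm for sid, fm in base.items()}
    return SyntheticSession(schedule, {"trained": trained, "untrained": untrained},
                            strf_features, units, responses)
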