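"""End-to-end pipeline: simulate -> reliability -> fit -> evaluate -> analyses.

Driven by a :class:`RunConfig` (YAML- or JSON-serializable).  Every
stochastic stage has its own seed derived from the master seed; outputs
(reliability CSV, score CSV, comparison JSON, analysis JSON, run report)
are written under the configured output directory and stamped with the
config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analyses import best_layer, hierarchy_compare, timescale_sweep
from .containers import FeatureMatrix
from .encoding import TemporalReceptiveField, default_lambda_grid
from .evaluation import assemble_long_sequences, compare_models, score_unit
from .features import resample_features
from .reliability import ReliabilityAnalysis, ReliabilityResults
from .synthetic import SyntheticSession, simulate_session

logger = logging.getLogger("spikereadout")

__all__ = ["RunConfig", "run_pipeline", "fit_and_score"]


@dataclass
class RunConfig:
    """Every knob of a pipeline run; round-trips through YAML/JSON."""

    # schedule
    n_single: int = 40
    n_repeat_stimuli: int = 10
    n_repeats: int = 11
    duration_mean: float = 1.6
    duration_jitter: float = 0.0
    # hierarchy
    n_layers: int = 4
    strides: list[int] | None = None
    base_dims: int = 12
    base_rate: float = 80.0
    # unit population
    n_units: int = 30
    gain_range: tuple[float, float] = (20.0, 60.0)
    baseline_range: tuple[float, float] = (2.0, 10.0)
    primary_fraction: float = 0.5
    crossover: float = 0.25
    # binning and fitting
    bin_width: float = 0.05
    window: float = 0.25
    n_lambdas: int = 21
    k_folds: int = 3
    # reliability
    R: int = 2000
    delta: float = 0.5
    tuned_alpha: float = 0.05
    stars_alpha: float = 0.01
    # timescale sweep (optional; run at 20-ms bins when enabled)
    timescale_cutoffs: list[float] | None = None
    # bookkeeping
    seed: int = 0
    outdir: str = "run_output"
    session_format: str = "h5"  # "h5" | "npz"
    restrict_to_well_tuned: bool = True

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        obj = yaml.safe_load(text) or {}
        kwargs = {f.name: obj[f.name] for f in dataclasses.fields(cls) if f.name in obj}
        cfg = cls(**kwargs)
        if cfg.gain_range is not None:
            cfg.gain_range = tuple(cfg.gain_range)
        if cfg.baseline_range is not None:
            cfg.baseline_range = tuple(cfg.baseline_range)
        return cfg

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def _resample_stack_layers(
    session: SyntheticSession, stack_id: str, rate: float
) -> list[dict[str, FeatureMatrix]]:
    stack = session.stacks[stack_id]
    return [
        {sid: resample_features(fm, rate) for sid, fm in layer.items()}
        for layer in stack.layers
    ]


def fit_and_score(
    session: SyntheticSession,
    reliab: ReliabilityResults | dict[str, float],
    unit_ids: list[str] | None = None,
    window: float = 0.25,
    lambda_grid: np.ndarray | None = None,
    k_folds: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit TRFs for every (unit, model) and score them on the repeat set.

    Models are every layer of every stack plus the STRF baseline.  TRFs
    are fit on the once-presented stimuli; scores are mean per-repeat
    correlations on the held-out repeat set, noise-corrected by each
    unit's ceiling.  Returns a tidy frame with one row per (unit, model).
    """
    schedule = session.schedule
    responses = session.responses
    rate = 1.0 / responses.bin_width
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    if unit_ids is None:
        unit_ids = responses.unit_ids
    unique_ids = [s.stimulus_id for s in schedule.unique_set]
    repeat_ids = [s.stimulus_id for s in schedule.repeat_set]

    model_features: dict[str, dict[str, FeatureMatrix]] = {}
    for stack_id in session.stacks:
        layers = _resample_stack_layers(session, stack_id, rate)
        for li, layer in enumerate(layers):
            model_features[f"{stack_id}:layer{li + 1}"] = layer
    model_features["strf"] = {
        sid: resample_features(fm, rate) for sid, fm in session.strf_features.items()
    }

    ceilings = reliab if isinstance(reliab, dict) else reliab.ceilings()
    region = {u.unit_id: u.region_label for u in session.units}
    target = {u.unit_id: u.target_layer for u in session.units}
    rows = []
    for unit_id in unit_ids:
        uidx = responses.unit_index(unit_id)
        train_counts = {}
        for sid in unique_ids:
            train_counts[sid] = responses.trials(sid, unit_id)[0]
        repeats = responses.repeat_responses(unit_id, schedule)
        for model_id, feats in model_features.items():
            trf = TemporalReceptiveField.from_session(
                train_counts, {s: feats[s] for s in train_counts},
                window=window, lambda_grid=lambda_grid,
            ).fit(k_folds=k_folds, seed=seed)
            preds = {s: trf.predict(feats[s]) for s in repeat_ids}
            model_seq, resp_seqs = assemble_long_sequences(repeats, preds)
            sc = score_unit(model_seq, resp_seqs, ceilings[unit_id],
                            unit_id, model_id)
            rows.append(
                {
                    "unit_id": unit_id,
                    "model_id": model_id,
                    "mean_r": sc.mean_r,
                    "corrected_r": sc.corrected_r,
                    "flagged": sc.flagged,
                    "lambda": trf.lambda_,
                    "region_label": region.get(unit_id, ""),
                    "target_layer": target.get(unit_id, -1),
                }
            )
        del uidx
    df = pd.DataFrame(rows)
    strf = df[df.model_id == "strf"].set_index("unit_id")["corrected_r"]
    df["ratio"] = df.apply(
        lambda r: r.corrected_r / strf[r.unit_id]
        if np.isfinite(r.corrected_r) and strf[r.unit_id] not in (0.0,)
        else np.nan,
        axis=1,
    )
    return df


def _scores_matrix(
    df: pd.DataFrame, model_id: str, unit_ids: list[str]
) -> np.ndarray:
    sub = df[df.model_id == model_id].set_index("unit_id")["corrected_r"]
    return np.array([sub.get(u, np.nan) for u in unit_ids])


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; write tables and reports; return the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"{config.config_hash}_seed{config.seed}"
    log_path = outdir / f"run_{tag}.log"
    handler = logging.FileHandler(log_path)
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    report: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config_hash": config.config_hash,
        "stages": {},
    }
    rng = np.random.default_rng(config.seed)
    try:
        stage = "simulate"
        logger.info("stage: simulate")
        session = simulate_session(
            n_single=config.n_single,
            n_repeat_stimuli=config.n_repeat_stimuli,
            n_repeats=config.n_repeats,
            duration_mean=config.duration_mean,
            duration_jitter=config.duration_jitter,
            n_units=config.n_units,
            n_layers=config.n_layers,
            strides=config.strides,
            base_dims=config.base_dims,
            base_rate=config.base_rate,
            bin_width=config.bin_width,
            gain_range=config.gain_range,
            baseline_range=config.baseline_range,
            primary_fraction=config.primary_fraction,
            crossover=config.crossover,
            seed=int(rng.integers(2**31)),
        )
        from .io import save_session

        session_path = outdir / f"session_{tag}.{config.session_format}"
        save_session(session_path, session)
        report["stages"]["simulate"] = {
            "n_stimuli": len(session.schedule.stimuli),
            "n_presentations": session.schedule.n_presentations,
            "n_units": len(session.units),
            "session_file": str(session_path),
        }

        stage = "reliability"
        logger.info("stage: reliability")
        repeat_by_unit = {
            u: session.responses.repeat_responses(u, session.schedule)
            for u in session.responses.unit_ids
        }
        reliab = ReliabilityAnalysis(
            repeat_by_unit, delta=config.delta, alpha=config.tuned_alpha
        ).fit(R=config.R, seed=int(rng.integers(2**31)))
        rel_df = reliab.to_frame()
        rel_path = outdir / f"reliability_{tag}.csv"
        rel_df.to_csv(rel_path, index=False)
        well = reliab.well_tuned_units()
        report["stages"]["reliability"] = {
            "n_units": len(rel_df),
            "n_tuned": len(reliab.tuned_units()),
            "n_well_tuned": len(well),
            "table": str(rel_path),
        }

        stage = "fit_evaluate"
        logger.info("stage: fit + evaluate")
        eval_units = well if config.restrict_to_well_tuned else list(repeat_by_unit)
        if not eval_units:
            raise RuntimeError("no well-tuned units to evaluate")
        scores = fit_and_score(
            session, reliab, unit_ids=eval_units,
            window=config.window,
            lambda_grid=default_lambda_grid(config.n_lambdas),
            k_folds=config.k_folds, seed=int(rng.integers(2**31)),
        )
        scores_path = outdir / f"scores_{tag}.csv"
        scores.to_csv(scores_path, index=False)

        L = session.stacks["trained"].n_layers
        trained = {"trained": {
            l: _scores_matrix(scores, f"trained:layer{l}", eval_units)
            for l in range(1, L + 1)
        }}
        untrained = {"trained": {
            l: _scores_matrix(scores, f"untrained:layer{l}", eval_units)
            for l in range(1, L + 1)
        }}
        strf = {"trained": _scores_matrix(scores, "strf", eval_units)}
        comparison = compare_models(trained, untrained, strf,
                                    alpha=config.stars_alpha)
        comp_path = outdir / f"comparisons_{tag}.json"
        comp_path.write_text(
            json.dumps(
                {"alpha": config.stars_alpha,
                 "tests": comparison.table.to_dict(orient="records")},
                indent=2,
            )
        )
        report["stages"]["fit_evaluate"] = {
            "n_units_scored": len(eval_units),
            "n_models": int(scores.model_id.nunique()),
            "median_corrected_r_best_model": float(
                scores.groupby("model_id").corrected_r.median().max()
            ),
            "scores": str(scores_path),
            "comparisons": str(comp_path),
        }

        stage = "analyses"
        logger.info("stage: analyses")
        prefs = []
        for u in eval_units:
            layer_scores = [
                _scores_matrix(scores, f"trained:layer{l}", [u])[0]
                for l in range(1, L + 1)
            ]
            pref = best_layer(
                layer_scores, unit_id=u, stack_id="trained",
                region_label=scores[scores.unit_id == u].region_label.iloc[0],
            )
            if pref is not None:
                prefs.append(pref)
        dp = np.array([p.depth_fraction for p in prefs if p.region_label == "primary"])
        dn = np.array(
            [p.depth_fraction for p in prefs if p.region_label == "non-primary"]
        )
        hier_p = (
            hierarchy_compare(dp, dn) if dp.size and dn.size else float("nan")
        )
        analyses_out = {
            "hierarchy": {
                "n_primary": int(dp.size),
                "n_non_primary": int(dn.size),
                "median_depth_primary": float(np.median(dp)) if dp.size else None,
                "median_depth_non_primary": float(np.median(dn)) if dn.size else None,
                "rank_sum_p": hier_p,
            },
            "layer_preferences": [
                {"unit_id": p.unit_id, "best_layer": p.best_layer,
                 "depth_fraction": p.depth_fraction, "region": p.region_label}
                for p in prefs
            ],
        }
        if config.timescale_cutoffs:
            bin_rate = 1.0 / config.bin_width
            feats = session.stacks["trained"].layers[-1]
            counts_by_unit = {
                u: {
                    s.stimulus_id: session.responses.trials(s.stimulus_id, u)[0]
                    for s in session.schedule.unique_set
                }
                for u in eval_units
            }
            curve = timescale_sweep(
                feats, counts_by_unit, {u: repeat_by_unit[u] for u in eval_units},
                reliab.ceilings(), config.timescale_cutoffs,
                bin_rate=bin_rate, seed=int(rng.integers(2**31)),
                alpha=config.stars_alpha, window=config.window,
            )
            analyses_out["timescale"] = {
                "cutoffs": list(map(float, curve.cutoffs)),
                "medians": [float(m) for m in curve.medians()],
                "best_cutoff": curve.best_cutoff,
                "indistinguishable_set": curve.indistinguishable_set,
            }
        analyses_path = outdir / f"analyses_{tag}.json"
        analyses_path.write_text(json.dumps(analyses_out, indent=2))
        report["stages"]["analyses"] = {
            "hierarchy_p": hier_p,
            "n_layer_preferences": len(prefs),
            "file": str(analyses_path),
        }
    except Exception as err:  # preserve partial outputs, name the stage
        report["failed_stage"] = stage
        report["error"] = str(err)
        (outdir / f"report_{tag}.json").write_text(json.dumps(report, indent=2))
        logger.removeHandler(handler)
        raise
    report_path = outdir / f"report_{tag}.json"
    report_path.write_text(json.dumps(report, indent=2))
    logger.removeHandler(handler)
    return report
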