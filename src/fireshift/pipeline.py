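"""End-to-end orchestration: windows -> sweep -> rank -> envelope ->
changepoints -> period comparison, from one YAML config, with per-stage
seed substreams and tidy artifacts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .changepoint import ChangepointDetector
from .io import (read_annual_csv, read_daily_csv, write_json, write_table)
from .null_model import build_envelope
from .periods import compare_periods
from .regression import fit_ols, lilliefors_normality, log_transform_area, \
    variance_inflation_factors
from .series import AnnualSeries
from .sweep import parameter_series, rank_predictors, sweep
from .windows import (SEASON, candidate_window_grid, optimize_window_definition,
                      seasonal_summary)

logger = logging.getLogger("fireshift")

__all__ = ["AnalysisConfig", "PipelineError", "run_full_analysis"]

# Stable stage identifiers for seed fan-out: re-running one stage alone
# reproduces its stream regardless of which other stages run.
_STAGE_SEED_IDS = {
    "windows": 1, "sweep": 2, "null_model": 3,
    "changepoints": 4, "periods": 5, "simulate": 6,
}


def stage_seed(master_seed: int, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master_seed), _STAGE_SEED_IDS[stage]])


def stage_seed_int(master_seed: int, stage: str) -> int:
    return int(stage_seed(master_seed, stage).generate_state(1)[0] % (2 ** 31))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class AnalysisConfig:
    """Validated configuration for a full run."""

    response_path: str
    predictors: dict            # name -> {"path": ..., "kind": "annual"|"daily", "category": ...}
    out_dir: str
    width: int = 21
    score_mode: str = "median_of_products"
    zero_offset_ha: float = 10.0
    grid_lengths: tuple = (1, 15, 30, 45, 60, 75, 90, 105, 120)
    grid_end_dates: tuple = ((8, 1), (8, 15), (9, 1), (9, 15), (10, 1))
    null_n_realizations: int = 10_000
    null_noise: str = "gaussian"
    changepoint_k: int = 3
    changepoint_min_segment: int = 5
    period_alpha: float = 0.05
    period_n_boot: int = 5000
    master_seed: int = 0
    predictor_sets: tuple = ()   # tuples of predictor names; default: each alone

    def __post_init__(self) -> None:
        if self.width % 2 == 0:
            raise ValueError(f"window width must be odd, got {self.width}")
        if not Path(self.response_path).exists():
            raise FileNotFoundError(self.response_path)
        for name, p in self.predictors.items():
            if not Path(p["path"]).exists():
                raise FileNotFoundError(f"predictor {name!r}: {p['path']}")
        if self.score_mode not in ("median_of_products", "product_of_medians"):
            raise ValueError(f"unknown score_mode {self.score_mode!r}")
        if self.null_noise not in ("gaussian", "resample"):
            raise ValueError(f"unknown null noise {self.null_noise!r}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent

        def resolve(p):
            q = Path(p)
            return str(q if q.is_absolute() else base / q)

        predictors = {}
        for name, entry in raw["predictors"].items():
            if isinstance(entry, str):
                entry = {"path": entry}
            predictors[name] = {
                "path": resolve(entry["path"]),
                "kind": entry.get("kind", "annual"),
                "category": entry.get("category", "climate"),
            }
        nm = raw.get("null_model", {})
        grid = raw.get("window_grid", {})
        return cls(
            response_path=resolve(raw["response"]),
            predictors=predictors,
            out_dir=resolve(raw.get("out_dir", "fireshift_out")),
            width=int(raw.get("width", 21)),
            score_mode=raw.get("score_mode", "median_of_products"),
            zero_offset_ha=float(raw.get("zero_offset_ha", 10.0)),
            grid_lengths=tuple(grid.get("lengths", cls.grid_lengths)),
            grid_end_dates=tuple(tuple(e) if not isinstance(e, str)
                                 else tuple(int(v) for v in e.split("-"))
                                 for e in grid.get("end_dates", cls.grid_end_dates)),
            null_n_realizations=int(nm.get("n_realizations", 10_000)),
            null_noise=nm.get("noise", "gaussian"),
            changepoint_k=int(raw.get("changepoint_k", 3)),
            changepoint_min_segment=int(raw.get("changepoint_min_segment", 5)),
            period_alpha=float(raw.get("period_alpha", 0.05)),
            period_n_boot=int(raw.get("period_n_boot", 5000)),
            master_seed=int(raw.get("seed", 0)),
            predictor_sets=tuple(tuple(s) for s in raw.get("predictor_sets", [])),
        )


def _load_response(config: AnalysisConfig) -> AnnualSeries:
    area = read_annual_csv(config.response_path, name="area_ha")
    return log_transform_area(area, config.zero_offset_ha)


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run every stage and write per-stage artifacts under ``config.out_dir``.

    Returns the summary dict (also written to ``summary.json``).  Any stage
    failure raises :class:`PipelineError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    log: list[dict] = []
    seeds = {stage: stage_seed_int(config.master_seed, stage)
             for stage in _STAGE_SEED_IDS}

    def record(stage, **info):
        entry = {"stage": stage, "elapsed_s": round(time.time() - t0, 3), **info}
        log.append(entry)
        logger.info("stage %s done (%.2fs)", stage, entry["elapsed_s"])

    # --- load & transform -------------------------------------------------
    try:
        response = _load_response(config)
    except Exception as exc:
        raise PipelineError("load_response", str(exc)) from exc
    record("load_response", n_years=len(response))

    # --- stage: optimal windows / predictor assembly ----------------------
    annual_predictors: dict[str, AnnualSeries] = {}
    window_choices = {}
    try:
        grid = candidate_window_grid(config.grid_lengths, config.grid_end_dates)
        for name, entry in config.predictors.items():
            if entry["kind"] == "daily":
                daily = read_daily_csv(entry["path"], name=name)
                definition, scores = optimize_window_definition(
                    daily, response, grid=grid, category=entry["category"])
                annual_predictors[name] = seasonal_summary(
                    daily, definition.window)
                window_choices[name] = definition.window.label()
                write_table(out / f"window_scores_{name}.csv", scores)
            else:
                annual_predictors[name] = read_annual_csv(entry["path"], name=name)
    except Exception as exc:
        raise PipelineError("windows", str(exc)) from exc
    record("windows", chosen=window_choices)

    # --- stage: moving-window sweep per predictor -------------------------
    sets = config.predictor_sets or tuple((n,) for n in annual_predictors)
    sweeps = {}
    global_fits = {}
    normality = {}
    vif_report = {}
    try:
        for names in sets:
            key = "+".join(names)
            preds = [annual_predictors[n] for n in names]
            results = sweep(preds, response, width=config.width)
            sweeps[key] = results
            gm = fit_ols(preds, response)
            global_fits[key] = gm.r2_adj if gm.r2_adj is not None else gm.r2
            if len(preds) >= 2:
                vifs, flagged = variance_inflation_factors(preds)
                vif_report[key] = {"max_vif": float(np.max(vifs)),
                                   "flagged": flagged}
            lo = max(p.first_year for p in preds)
            hi = min(p.last_year for p in preds)
            stat, p, ok = lilliefors_normality(response.trim(lo, hi).values)
            normality[key] = {"statistic": stat, "p": p, "passed": ok}
            traj = parameter_series(results).reset_index()
            write_table(out / f"sweep_{key}.csv", traj)
    except Exception as exc:
        raise PipelineError("sweep", str(exc)) from exc
    record("sweep", n_predictor_sets=len(sweeps))

    # --- stage: ranking ----------------------------------------------------
    try:
        ranking = rank_predictors(sweeps, global_fits, config.score_mode)
        rank_df = pd.DataFrame([{
            "predictor_set": "+".join(r.predictor_names),
            "global_fit": r.global_fit, "median_r2": r.median_r2,
            "median_ce": r.median_ce,
            "score_product_of_medians": r.score_product_of_medians,
            "score_median_of_products": r.score_median_of_products,
            "score": r.score, "rank": r.rank,
        } for r in ranking])
        write_table(out / "ranking.csv", rank_df)
    except Exception as exc:
        raise PipelineError("rank", str(exc)) from exc
    record("rank", top="+".join(ranking[0].predictor_names))

    # --- stage: null-model envelope for the top predictor ------------------
    top_name = "+".join(ranking[0].predictor_names)
    top_preds = [annual_predictors[n] for n in ranking[0].predictor_names]
    try:
        envelope = build_envelope(
            top_preds, response, width=config.width,
            n_realizations=config.null_n_realizations,
            seed=seeds["null_model"], noise=config.null_noise)
        write_table(out / "envelope.csv", envelope.to_long_frame())
        observed = parameter_series(sweeps[top_name])
        exits = envelope.exits(observed)
        write_table(out / "envelope_exits.csv", exits)
        coverage = envelope.coverage(observed)
    except Exception as exc:
        raise PipelineError("null_model", str(exc)) from exc
    record("null_model", n_realizations=config.null_n_realizations,
           seed=seeds["null_model"])

    # --- stage: changepoints ------------------------------------------------
    try:
        detector = ChangepointDetector(
            n_breakpoints=config.changepoint_k,
            min_segment=config.changepoint_min_segment).fit(response)
        write_json(out / "changepoints.json", {
            **detector.result_.to_dict(),
            "config": {"k": config.changepoint_k,
                       "min_segment": config.changepoint_min_segment},
        })
    except Exception as exc:
        raise PipelineError("changepoints", str(exc)) from exc
    record("changepoints", breakpoints=detector.breakpoint_years_)

    # --- stage: period comparison -------------------------------------------
    # use the two strongest breaks (largest SSE-improvement share) as the
    # period boundaries, mirroring three-period framing
    shares = np.array(detector.result_.improvement_share)
    keep = np.sort(np.argsort(shares)[::-1][:2])
    boundaries = [detector.breakpoint_years_[i] for i in keep]
    period_rows = []
    min_period = 10

    def usable(bounds, first, last):
        # keep only boundaries that leave every period >= min_period years;
        # on a changeless record breaks can land near the record edges
        out_b, prev = [], first
        for b in sorted(bounds):
            if b - prev >= min_period and last - b + 1 >= min_period:
                out_b.append(b)
                prev = b
        return out_b

    try:
        for name, pred in annual_predictors.items():
            interior = usable(
                [b for b in boundaries
                 if pred.first_year < b <= pred.last_year],
                pred.first_year, pred.last_year)
            if not interior:
                logger.info("periods: no usable boundaries for %s; skipped", name)
                continue
            comp = compare_periods(
                pred, interior, alpha=config.period_alpha,
                n_boot=config.period_n_boot, seed=seeds["periods"])
            d = comp.to_dict()
            d["periods"] = ";".join(d["periods"])
            d["letters"] = "" if d["letters"] is None else ";".join(d["letters"])
            period_rows.append(d)
        write_table(out / "period_comparison.csv", pd.DataFrame(period_rows))
    except Exception as exc:
        raise PipelineError("periods", str(exc)) from exc
    record("periods", boundaries=boundaries)

    # --- summary --------------------------------------------------------------
    summary = {
        "version": __version__,
        "master_seed": config.master_seed,
        "stage_seeds": seeds,
        "width": config.width,
        "score_mode": config.score_mode,
        "top_predictor_set": top_name,
        "ranking": [{"set": "+".join(r.predictor_names), "score": r.score,
                     "rank": r.rank} for r in ranking],
        "window_choices": window_choices,
        "normality": normality,
        "vif": vif_report,
        "breakpoint_years": detector.breakpoint_years_,
        "period_boundaries": boundaries,
        "envelope_coverage": {k: float(v) for k, v in coverage.items()},
        "envelope_exit_centers": sorted(set(exits["center_year"].tolist())),
        "consistent_with_null": bool(len(exits) == 0),
        "period_comparison": period_rows,
        "stage_log": log,
    }
    write_json(out / "summary.json", summary)
    return summary
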