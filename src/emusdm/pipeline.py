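"""The end-to-end modelling pipeline.

Stages, in order: simulate-or-load -> clean -> thin -> bias layer ->
environmental kernel -> pseudo-absences -> extract -> VIF screening ->
scale/centre -> multi-algorithm fitting -> skill gating -> TSS-weighted
ensemble -> max-TSS binarization -> per-scenario projection and range
change -> MESS and correlation-shift diagnostics.  Everything derives
deterministically from (config, seed): each stage's seed is
``SeedSequence([global_seed, crc32(stage_name)])`` reduced below 2^31, so
any single stage can be re-run in isolation with identical results.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .config import PipelineConfig
from .ensemble import (
    EmptyEnsembleError,
    EnsembleModel,
    RangeChangeReport,
    binarize,
    build_ensemble,
    ensemble_predict,
    ensemble_threshold,
    range_change,
    uncertainty_map,
)
from .evaluation import boyce
from .grids import GridSurface, PredictorStack
from .models import fit_all, permutation_importance
from .occurrences import clean, thin
from .predictors import (
    LABEL_COLUMN,
    build_sample_table,
    predictor_columns,
    scale_centre,
    vif_stepwise,
)
from .pseudoabsence import build_bias_surface, fit_env_kernel, sample_pseudoabsences
from .synthetic import (
    LandscapeSpec,
    ScenarioShift,
    TrueNiche,
    generate_analogue_sightings,
    generate_predictor_stack,
    make_hotspot_bias,
    sample_occurrences,
    shift_climate,
    true_suitability,
)

__all__ = ["PipelineError", "PipelineResult", "run_pipeline", "stage_seed"]

log = logging.getLogger("emusdm.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the partial run report."""

    def __init__(self, stage: str, cause: Exception, report: dict):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause
        self.report = report


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineResult:
    report: dict
    ensemble: EnsembleModel | None = None
    suitability: dict = field(default_factory=dict)      # scenario -> GridSurface
    binary_maps: dict = field(default_factory=dict)      # scenario -> BinaryRangeMap
    range_changes: dict = field(default_factory=dict)    # scenario -> RangeChangeReport
    sample_table: pd.DataFrame | None = None
    raw_sample_table: pd.DataFrame | None = None
    presences: pd.DataFrame | None = None
    pseudoabsences: pd.DataFrame | None = None
    stacks: dict = field(default_factory=dict)           # scenario -> PredictorStack
    truth: dict = field(default_factory=dict)            # synthetic ground truth


def _synthesize(cfg: PipelineConfig, report: dict):
    syn = cfg.synthetic
    spec = LandscapeSpec(
        n_rows=syn.n_rows,
        n_cols=syn.n_cols,
        cell_size_km=syn.cell_size_km,
        layer_names=tuple(syn.layer_names),
        autocorr_length_km=syn.autocorr_length_km,
        seed=stage_seed(cfg.seed, "landscape"),
    )
    stack = generate_predictor_stack(spec)
    niche = TrueNiche(
        intercept=syn.niche_intercept,
        coefficients=dict(syn.niche_coefficients),
        quadratic_coefficients=dict(syn.niche_quadratic) or None,
    )
    suit = true_suitability(stack, niche)
    bias = make_hotspot_bias(
        stack.grid,
        n_hotspots=syn.bias_hotspots,
        floor=syn.bias_floor,
        seed=stage_seed(cfg.seed, "bias_truth"),
    )
    presences = sample_occurrences(
        suit,
        bias,
        syn.n_presences,
        seed=stage_seed(cfg.seed, "presences"),
        dirty_fraction=syn.dirty_fraction,
    )
    analogues = generate_analogue_sightings(
        bias, syn.n_analogues, seed=stage_seed(cfg.seed, "analogues")
    )
    scenarios = {
        name: shift_climate(
            stack,
            ScenarioShift(
                additive_delta=dict(sh.get("additive_delta", {})),
                multiplicative_factor=dict(sh.get("multiplicative_factor", {})),
            ),
        )
        for name, sh in syn.scenario_shifts.items()
    }
    report["synthetic"] = {
        "n_presences_raw": len(presences),
        "n_analogues": len(analogues),
        "layers": stack.names,
        "grid": [spec.n_rows, spec.n_cols],
    }
    truth = {"niche": niche, "suitability": suit, "bias": bias}
    return stack, presences, analogues, scenarios, truth


def _load_files(cfg: PipelineConfig, report: dict):
    stack = _io.read_stack(cfg.stack_dir)
    presences = _io.read_occurrences(cfg.occurrences_csv)
    analogues = (
        _io.read_occurrences(cfg.analogues_csv) if cfg.analogues_csv else presences
    )
    scenarios = {
        name: _io.read_stack(path) for name, path in cfg.scenario_stack_dirs.items()
    }
    for name, sc in scenarios.items():
        stack.grid.require_same(sc.grid, f"scenario {name!r} and current stacks")
    report["inputs"] = {
        "occurrences_csv": cfg.occurrences_csv,
        "stack_dir": cfg.stack_dir,
        "scenarios": list(scenarios),
    }
    return stack, presences, analogues, scenarios, {}


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage; write artifacts and a JSON run report.

    Raises :class:`PipelineError` (with stage provenance) on any fatal
    stage failure.  Fully reproducible from (config, seed): the report
    carries the config hash and all stage seeds, and no timestamps.
    """
    cfg = config
    cfg_dict = cfg.to_dict()
    report: dict = {
        "config_hash": _io.config_hash(cfg_dict),
        "seed": cfg.seed,
        "stages": [],
    }
    result = PipelineResult(report=report)
    out_dir = Path(cfg.output_dir)
    if cfg.write_artifacts:
        out_dir.mkdir(parents=True, exist_ok=True)

    geographic = False  # synthetic grids are planar; file grids declare crs
    current_stage = "init"

    def run_stage(name, fn):
        nonlocal current_stage
        current_stage = name
        log.info("stage %s", name)
        try:
            out = fn()
        except Exception as exc:
            report["failed_stage"] = name
            report["error"] = f"{type(exc).__name__}: {exc}"
            raise PipelineError(name, exc, report) from exc
        report["stages"].append(name)
        return out

    # ---- data ----------------------------------------------------------
    if cfg.synthetic is not None:
        stack, presences_raw, analogues_raw, scenarios, truth = run_stage(
            "simulate", lambda: _synthesize(cfg, report)
        )
    else:
        stack, presences_raw, analogues_raw, scenarios, truth = run_stage(
            "load", lambda: _load_files(cfg, report)
        )
        geographic = stack.grid.crs == "epsg:4326"
    result.truth = truth
    result.stacks = {"current": stack, **scenarios}

    # ---- clean + thin ---------------------------------------------------
    city = np.array(cfg.city_points, dtype=float) if cfg.city_points else None

    def _clean():
        pres, rep_p = clean(presences_raw, cfg.cleaning, city, geographic)
        ana, rep_a = clean(analogues_raw, cfg.cleaning, city, geographic)
        if rep_p.all_removed or rep_a.all_removed:
            raise ValueError("cleaning removed every record")
        report["cleaning"] = {"presences": rep_p.to_dict(), "analogues": rep_a.to_dict()}
        return pres, ana

    presences_clean, analogues_clean = run_stage("clean", _clean)

    def _thin():
        thinned = thin(
            presences_clean, cfg.thin_km, stage_seed(cfg.seed, "thin"), geographic
        )
        report["thinning"] = {
            "min_dist_km": cfg.thin_km,
            "n_before": len(presences_clean),
            "n_after": len(thinned),
        }
        return thinned

    presences = run_stage("thin", _thin)

    # ---- pseudo-absences ------------------------------------------------
    bias = run_stage(
        "bias_layer",
        lambda: build_bias_surface(analogues_clean, stack.grid, cfg.bias_bandwidth_km),
    )
    kernel = run_stage(
        "env_kernel",
        lambda: fit_env_kernel(
            presences, stack, n_components=cfg.kernel_components,
            seed=stage_seed(cfg.seed, "kernel"),
        ),
    )

    def _pseudo():
        pa = sample_pseudoabsences(
            kernel,
            bias,
            stack,
            presences,
            min_dist_km=cfg.pseudoabsence_min_dist_km,
            seed=stage_seed(cfg.seed, "pseudoabsence"),
        )
        report["pseudoabsences"] = {
            "n_presences": len(presences),
            "n_pseudoabsences": len(pa),
            "ratio": len(pa) / len(presences),
            "min_dist_km": cfg.pseudoabsence_min_dist_km,
        }
        return pa

    pseudoabs = run_stage("pseudoabsence", _pseudo)
    result.presences = presences
    result.pseudoabsences = pseudoabs

    # ---- predictors -----------------------------------------------------
    def _extract():
        table, drops = build_sample_table(stack, presences, pseudoabs)
        report["extract"] = {"n_rows": len(table), **drops}
        return table

    raw_table = run_stage("extract", _extract)
    result.raw_sample_table = raw_table

    def _vif():
        rep = vif_stepwise(raw_table, threshold=cfg.vif_threshold)
        report["vif"] = rep.to_dict()
        return raw_table[rep.retained + [LABEL_COLUMN]]

    screened = run_stage("vif", _vif)

    def _scale():
        std_table, params = scale_centre(screened)
        report["standardization"] = params.to_dict()
        return std_table, params

    std_table, std_params = run_stage("scale", _scale)
    result.sample_table = std_table

    # ---- models ---------------------------------------------------------
    def _fit():
        models = fit_all(
            std_table,
            roster=cfg.roster,
            n_repeats=cfg.n_repeats,
            calib_fraction=cfg.calib_fraction,
            seed=stage_seed(cfg.seed, "fit"),
        )
        report["models"] = {
            "n_candidates": len(models),
            "roster": sorted({m.algorithm for m in models}),
            "n_repeats": cfg.n_repeats,
            "scores": [m.metadata() for m in models],
        }
        return models

    models = run_stage("fit", _fit)

    def _gate():
        ens, gate_report = build_ensemble(models, cfg.gates)
        report["gates"] = {
            "thresholds": {
                "tss_min": cfg.gates.tss_min,
                "auc_min": cfg.gates.auc_min,
                "kappa_min": cfg.gates.kappa_min,
            },
            "n_members": len(ens.members),
            "candidates": gate_report,
            "weights": ens.weights.tolist(),
        }
        return ens

    ensemble = run_stage("gate", _gate)
    result.ensemble = ensemble

    if cfg.compute_importance:
        def _importance():
            rows = {}
            for m in ensemble.members:
                imp = permutation_importance(
                    m, std_table, n_shuffles=cfg.n_importance_shuffles,
                    seed=stage_seed(cfg.seed, "importance"),
                )
                rows[f"{m.algorithm}#{m.repeat}"] = imp
            imp_df = pd.DataFrame(rows).T
            report["variable_importance"] = {
                "per_member": imp_df.round(6).to_dict(),
                "mean": imp_df.mean().round(6).to_dict(),
            }
            return imp_df

        run_stage("importance", _importance)

    # ---- projection + binarization -------------------------------------
    def _project():
        threshold = ensemble_threshold(ensemble, std_table)
        surfaces = {}
        binmaps = {}
        std_current = std_params.apply_to_stack(stack)
        surfaces["current"] = ensemble_predict(ensemble, std_current)
        binmaps["current"] = binarize(surfaces["current"], threshold, "current")
        for name, sc_stack in scenarios.items():
            std_sc = std_params.apply_to_stack(sc_stack)  # fitting-era params
            surfaces[name] = ensemble_predict(ensemble, std_sc)
            binmaps[name] = binarize(surfaces[name], threshold, name)
        report["binarization"] = {
            "threshold": threshold,
            "cells_present": {k: v.n_present for k, v in binmaps.items()},
        }
        return surfaces, binmaps

    surfaces, binmaps = run_stage("project", _project)
    result.suitability = surfaces
    result.binary_maps = binmaps

    if cfg.compute_boyce:
        def _boyce():
            cols = ensemble.feature_names
            pres_pred = ensemble.predict(
                std_table.loc[std_table[LABEL_COLUMN] == 1, cols].to_numpy(float)
            )
            bg = surfaces["current"].flat()
            val = boyce(bg[np.isfinite(bg)], pres_pred)
            report["boyce"] = {"index": val, "evaluated_on": "full current surface"}
            return val

        run_stage("boyce", _boyce)

    def _range_change():
        changes = {}
        for name in scenarios:
            changes[name] = range_change(binmaps["current"], binmaps[name])
        report["range_change"] = {k: v.to_dict() for k, v in changes.items()}
        return changes

    result.range_changes = run_stage("range_change", _range_change)

    def _novelty():
        from .novelty import correlation_shift, mess_map

        ref = raw_table[ensemble.feature_names]
        mess_out, corr_out = {}, {}
        cur = stack.subset(ensemble.feature_names)
        for name, sc_stack in scenarios.items():
            mm = mess_map(ref, sc_stack.subset(ensemble.feature_names))
            mess_out[name] = {"novel_fraction": mm.novel_fraction}
            _, _, diff = correlation_shift(cur, sc_stack.subset(ensemble.feature_names))
            corr_out[name] = {
                "max_abs_correlation_shift": float(np.abs(diff.to_numpy()).max())
            }
        report["mess"] = mess_out
        report["correlation_shift"] = corr_out

    if scenarios:
        run_stage("novelty", _novelty)

    # ---- artifacts ------------------------------------------------------
    if cfg.write_artifacts:
        def _write():
            _io.write_occurrences(out_dir / "presences.csv", presences)
            _io.write_occurrences(out_dir / "pseudoabsences.csv", pseudoabs)
            labelled = raw_table.copy()
            labelled.to_csv(out_dir / "sample_table.csv", index=False)
            prov = {"config_hash": report["config_hash"], "seed": cfg.seed}
            _io.write_ascii_grid(out_dir / "bias.asc", bias)
            for name, surf in surfaces.items():
                _io.write_ascii_grid(out_dir / f"suitability_{name}.asc", surf)
            for name, bm in binmaps.items():
                _io.write_ascii_grid(
                    out_dir / f"binary_{name}.asc",
                    GridSurface(bm.grid, bm.present.astype(float)),
                )
            if len(ensemble.members) >= 2:
                std_current = std_params.apply_to_stack(stack)
                _io.write_ascii_grid(
                    out_dir / "cv_current.asc", uncertainty_map(ensemble, std_current)
                )
            _io.write_json(out_dir / "run_report.json", {**report, "provenance": prov})

        run_stage("write", _write)

    report["status"] = "ok"
    return result
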