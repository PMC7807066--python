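#!/usr/bin/env python
"""Fit the nine-algorithm roster, gate by skill, ensemble, and project.

Fits 6 repeats x 9 algorithms = 54 candidate models on 70/30 splits of the
standardised sample table, scores each on its holdout (AUC, TSS, Kappa at
the max-TSS threshold), keeps the models with TSS >= 0.7, AUC >= 0.9 and
Kappa >= 0.7, and combines them with TSS-proportional weights.  The
ensemble is projected onto the current and scenario climates (standardised
with the fitting-era parameters), binarized at its max-TSS threshold, and
summarised as cell-count range change under unlimited and no dispersal.
Also reports the Boyce index and permutation variable importance.
"""

import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

warnings.filterwarnings("ignore")

from emusdm import binarize, build_ensemble, ensemble_predict, fit_all, range_change
from emusdm import io as eio
from emusdm.ensemble import ensemble_threshold, uncertainty_map
from emusdm.evaluation import boyce
from emusdm.models import permutation_importance
from emusdm.pipeline import stage_seed
from emusdm.predictors import LABEL_COLUMN, StandardizationParams

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
LAND = Path("results/analysis/landscape")
PRED = Path("results/analysis/predictors")
OUT = Path("results/analysis/ensemble")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    std_table = pd.read_csv(PRED / "sample_table_std.csv")
    std = eio.read_json(PRED / "standardization.json")
    params = StandardizationParams(pd.Series(std["means"]), pd.Series(std["sds"]))

    models = fit_all(std_table, seed=stage_seed(SEED, "fit"))
    scored = [m for m in models if m.ok]
    tss = [m.scores.tss for m in scored]
    print(f"candidates: {len(models)} (9 algorithms x 6 repeats)")
    print(f"holdout TSS: median {np.median(tss):.3f}, range {min(tss):.3f}-{max(tss):.3f}")

    ensemble, gate_report = build_ensemble(models)
    print(f"gates TSS>=0.7 / AUC>=0.9 / Kappa>=0.7 kept {len(ensemble.members)} members")

    threshold = ensemble_threshold(ensemble, std_table)
    X = std_table[ensemble.feature_names].to_numpy()
    y = std_table[LABEL_COLUMN].to_numpy()

    surfaces, binmaps = {}, {}
    for name, directory in [("current", "stack"), ("past", "stack_past"), ("future", "stack_future")]:
        stack = params.apply_to_stack(eio.read_stack(LAND / directory))
        surfaces[name] = ensemble_predict(ensemble, stack)
        binmaps[name] = binarize(surfaces[name], threshold, name)
        eio.write_ascii_grid(OUT / f"suitability_{name}.asc", surfaces[name])

    b = boyce(surfaces["current"].flat(), ensemble.predict(X[y == 1]))
    print(f"binarization threshold (max TSS on ensemble): {threshold:.3f}; Boyce {b:.3f}")

    changes = {}
    for name in ("past", "future"):
        rc = range_change(binmaps["current"], binmaps[name])
        changes[name] = rc.to_dict()
        print(rc.summary())

    imp = pd.DataFrame(
        {
            f"{m.algorithm}#{m.repeat}": permutation_importance(
                m, std_table, seed=stage_seed(SEED, "importance")
            )
            for m in ensemble.members
        }
    ).T
    imp.to_csv(OUT / "variable_importance.csv")
    print("mean variable importance: "
          + ", ".join(f"{k}={v:.2f}" for k, v in imp.mean().sort_values(ascending=False).items()))

    cv = uncertainty_map(ensemble, params.apply_to_stack(eio.read_stack(LAND / "stack")))
    eio.write_ascii_grid(OUT / "cv_current.asc", cv)
    eio.write_json(OUT / "ensemble_report.json", {
        "threshold": threshold,
        "boyce": b,
        "n_members": len(ensemble.members),
        "weights": ensemble.weights.tolist(),
        "gate_report": gate_report,
        "range_change": changes,
    })
    print(f"wrote projections and report -> {OUT}")


if __name__ == "__main__":
    main()
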