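#!/usr/bin/env python
"""Generate bias-aware pseudo-absences at a 1:1 ratio with presences.

Builds the sampling-effort bias layer from the cleaned analogue sightings
(Gaussian point density, 100-km bandwidth), fits the presence
environmental kernel in principal-component space, and draws
pseudo-absences with weight (1 - normalized presence density) x bias,
keeping every point at least 30 km from any presence or other
pseudo-absence.  Writes the combined presence/pseudo-absence sample table.
"""

import sys
from pathlib import Path

from emusdm import build_bias_surface, build_sample_table, fit_env_kernel, sample_pseudoabsences
from emusdm import io as eio
from emusdm.pipeline import stage_seed

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
LAND = Path("results/analysis/landscape")
OCC = Path("results/analysis/occurrences")
OUT = Path("results/analysis/pseudoabsence")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    stack = eio.read_stack(LAND / "stack")
    presences = eio.read_occurrences(OCC / "presences_thinned.csv")
    analogues = eio.read_occurrences(OCC / "analogues_clean.csv")

    bias = build_bias_surface(analogues, stack.grid, bandwidth_km=100.0)
    kernel = fit_env_kernel(presences, stack, seed=stage_seed(SEED, "kernel"))
    pa = sample_pseudoabsences(
        kernel, bias, stack, presences, min_dist_km=30.0,
        seed=stage_seed(SEED, "pseudoabsence"),
    )
    table, drops = build_sample_table(stack, presences, pa)

    eio.write_ascii_grid(OUT / "bias_layer.asc", bias)
    eio.write_occurrences(OUT / "pseudoabsences.csv", pa)
    table.to_csv(OUT / "sample_table.csv", index=False)

    print(f"bias layer from {len(analogues)} analogue sightings (bandwidth 100 km)")
    print(f"presence kernel: {kernel.n_components} principal components retained")
    print(f"pseudo-absences: {len(pa)} (1:1 with {len(presences)} presences)")
    print(f"sample table: {len(table)} rows ({drops})")


if __name__ == "__main__":
    main()
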