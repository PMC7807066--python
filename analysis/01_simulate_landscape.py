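#!/usr/bin/env python
"""Generate the synthetic study landscape with a known true niche.

Produces the environmental substrate for the whole analysis: five
autocorrelated predictor layers on a 200 x 200 grid of 10-km cells, the
true logistic suitability surface, a nonuniform observation-bias surface,
500 raw presence records observed through that bias (10% deliberately
violate cleaning rules), 1,500 analogue-species sightings, and two
scenario stacks ("past": precipitation seasonality +1.2 sd; "future":
wettest-month precipitation -0.6 sd).

Writes everything under results/analysis/landscape/.
"""

import sys
from pathlib import Path

from emusdm import io as eio
from emusdm.experiments import NICHE_COEFFICIENTS, NICHE_INTERCEPT, NICHE_QUADRATIC
from emusdm.pipeline import stage_seed
from emusdm.synthetic import (
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

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/analysis/landscape")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = LandscapeSpec(
        n_rows=200,
        n_cols=200,
        cell_size_km=10.0,
        layer_names=("bio13", "bio15", "bio18", "bio19", "bio1"),
        autocorr_length_km=(150.0, 120.0, 100.0, 80.0, 60.0),
        seed=stage_seed(SEED, "landscape"),
    )
    stack = generate_predictor_stack(spec)
    niche = TrueNiche(NICHE_INTERCEPT, dict(NICHE_COEFFICIENTS), dict(NICHE_QUADRATIC))
    suit = true_suitability(stack, niche)
    bias = make_hotspot_bias(stack.grid, seed=stage_seed(SEED, "bias_truth"))
    presences = sample_occurrences(suit, bias, 500, seed=stage_seed(SEED, "presences"))
    analogues = generate_analogue_sightings(bias, 1500, seed=stage_seed(SEED, "analogues"))

    eio.write_stack(OUT / "stack", stack, {"seed": SEED})
    for name, shift in {
        "past": ScenarioShift(additive_delta={"bio15": 1.2}),
        "future": ScenarioShift(additive_delta={"bio13": -0.6}),
    }.items():
        eio.write_stack(OUT / f"stack_{name}", shift_climate(stack, shift), {"seed": SEED})
    eio.write_ascii_grid(OUT / "true_suitability.asc", suit)
    eio.write_ascii_grid(OUT / "bias.asc", bias)
    eio.write_occurrences(OUT / "presences_raw.csv", presences)
    eio.write_occurrences(OUT / "analogues_raw.csv", analogues)

    print(f"landscape: {spec.n_rows}x{spec.n_cols} cells of {spec.cell_size_km} km")
    print(f"true range (suitability >= 0.5): {(suit.values >= 0.5).sum()} cells")
    print(f"wrote {len(presences)} presences, {len(analogues)} analogue sightings -> {OUT}")


if __name__ == "__main__":
    main()
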