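#!/usr/bin/env python
"""Clean the raw occurrence records and thin them to 30-km separation.

Applies the standard record-hygiene rules (coordinate uncertainty > 5 km,
recorded absences, fossils, missing or pre-1970 years, exact duplicates,
spatial outliers > 30 km from every other record) to both the focal
presences and the analogue sightings, then spatially thins the presences
so no two are closer than 30 km.  Reports how many records each rule
removed.
"""

import sys
from pathlib import Path

from emusdm import CleaningRules, clean, thin
from emusdm import io as eio
from emusdm.pipeline import stage_seed

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
LAND = Path("results/analysis/landscape")
OUT = Path("results/analysis/occurrences")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rules = CleaningRules()
    presences_raw = eio.read_occurrences(LAND / "presences_raw.csv")
    analogues_raw = eio.read_occurrences(LAND / "analogues_raw.csv")

    presences, rep_p = clean(presences_raw, rules)
    analogues, rep_a = clean(analogues_raw, rules)
    thinned = thin(presences, 30.0, seed=stage_seed(SEED, "thin"))

    eio.write_occurrences(OUT / "presences_clean.csv", presences)
    eio.write_occurrences(OUT / "presences_thinned.csv", thinned)
    eio.write_occurrences(OUT / "analogues_clean.csv", analogues)
    eio.write_json(OUT / "cleaning_report.json", {
        "presences": rep_p.to_dict(), "analogues": rep_a.to_dict(),
        "thinning": {"min_dist_km": 30.0, "n_before": len(presences), "n_after": len(thinned)},
    })

    print(f"presences: {rep_p.n_input} -> {rep_p.n_retained} after cleaning")
    for rule, n in rep_p.removed_by_rule.items():
        if n:
            print(f"  removed by {rule}: {n}")
    print(f"thinning at 30 km: {len(presences)} -> {len(thinned)}")
    print(f"analogues: {rep_a.n_input} -> {rep_a.n_retained}")


if __name__ == "__main__":
    main()
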