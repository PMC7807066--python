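#!/usr/bin/env python
"""Screen predictors for collinearity (stepwise VIF) and standardise them.

Repeatedly removes the predictor with the largest variance inflation
factor until every remaining VIF is at or below 10, then scales and
centres the retained columns, storing the fitting-era means and standard
deviations for later projection onto scenario climates.
"""

from pathlib import Path

import pandas as pd

from emusdm import io as eio
from emusdm import scale_centre, vif_stepwise
from emusdm.predictors import LABEL_COLUMN

PA = Path("results/analysis/pseudoabsence")
OUT = Path("results/analysis/predictors")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(PA / "sample_table.csv")

    report = vif_stepwise(table, threshold=10.0)
    screened = table[report.retained + [LABEL_COLUMN]]
    std_table, params = scale_centre(screened)

    eio.write_json(OUT / "vif_report.json", report.to_dict())
    eio.write_json(OUT / "standardization.json", params.to_dict())
    std_table.to_csv(OUT / "sample_table_std.csv", index=False)

    final_vifs = report.steps[-1]["vifs"]
    print(f"retained predictors: {', '.join(report.retained)}")
    if report.removed_order:
        print(f"removed (in order): {', '.join(report.removed_order)}")
    else:
        print("no predictor exceeded VIF 10")
    print("final VIFs: " + ", ".join(f"{k}={v:.2f}" for k, v in final_vifs.items()))


if __name__ == "__main__":
    main()
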