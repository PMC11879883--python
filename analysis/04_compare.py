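#!/usr/bin/env python
"""Test which sites changed significantly from baseline.

Per site, runs one-way ANOVA with Dunnett's many-to-one comparisons of
the 1 h and 4 h timepoints against baseline on the replicate-level
occupancies.  Writes results/comparisons.csv and reports how the calls
line up with the sites the generator actually perturbed.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import phosstoich as ps
from phosstoich.stoichiometry import dunnett_vs_control

RESULTS = Path(__file__).resolve().parents[1] / "results"
ALPHA = 0.05
CONTROL = "t0h"


def main() -> None:
    frame = pd.read_csv(RESULTS / "stoichiometry.csv")
    rows = []
    for site, grp in frame.groupby("site", sort=False):
        groups = {
            r.sample: np.array([float(v) for v in r.replicate_values.split(";")])
            for r in grp.itertuples(index=False)
        }
        cmp_df = dunnett_vs_control(groups, CONTROL)
        cmp_df.insert(0, "site", site)
        rows.append(cmp_df)
    comparisons = pd.concat(rows, ignore_index=True).rename(
        columns={"mean_diff": "mean_diff_pct"}
    )
    comparisons.to_csv(RESULTS / "comparisons.csv", index=False)

    truth = pd.read_csv(RESULTS / "ground_truth.csv")
    changed = set(
        truth.groupby("site_label")["theta"]
        .agg(lambda t: t.max() - t.min() > 1e-9)
        .pipe(lambda s: s[s].index)
    )
    called = set(comparisons.loc[comparisons["adj_p"] < ALPHA, "site"])
    print(f"{len(comparisons)} comparisons -> results/comparisons.csv")
    print(f"sites truly perturbed: {sorted(changed)}")
    print(f"sites with any adjusted p < {ALPHA}: {sorted(called)}")
    print(f"true positives {len(called & changed)}, "
          f"false positives {len(called - changed)}, "
          f"missed {len(changed - called)}")


if __name__ == "__main__":
    main()
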