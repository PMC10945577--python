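#!/usr/bin/env python
"""Exploration assay: grid squares entered by each cohort.

Counts the distinct 3.5 mm grid squares each simulated track crosses --
the computational analogue of superimposing a grid on the photographed
plate and counting by eye -- and compares cohorts with an unpaired t-test.

Requires 01_simulate_cohorts.py. Writes results/exploration/.
"""

from pathlib import Path

import pandas as pd

from roamdwell import ttest_unpaired
from roamdwell.pipeline import run_explore

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    scores = {}
    for name in ("wildtype", "mutant"):
        res = run_explore(
            ROOT / "cohorts" / name / "trajectories.csv", ROOT / "exploration" / name
        )
        df = pd.read_csv(res["exploration"], sep="\t")
        scores[name] = df["squares_entered"]
        print(
            f"{name}: {df['squares_entered'].mean():.1f} +/- "
            f"{df['squares_entered'].std():.1f} squares entered (n={len(df)})"
        )
    cmp = ttest_unpaired(scores["wildtype"], scores["mutant"])
    print(
        f"wildtype vs mutant squares entered: t = {cmp.t_stat:.2f}, "
        f"p = {cmp.p_two_tailed:.3g} ({cmp.significance_marker})"
    )


if __name__ == "__main__":
    main()
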