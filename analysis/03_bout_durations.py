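#!/usr/bin/env python
"""Bout-duration analysis: are mutant roaming states shorter?

Segments maximal same-state runs from the classified interval labels,
keeping only bouts strictly longer than five 10-s intervals, and compares
the per-bout durations of roaming and dwelling states between cohorts
(each bout is one observation, as in the assay's duration plots).

Requires 02_classify_roaming.py. Writes bout tables under results/bouts/.
"""

from pathlib import Path

import pandas as pd

from roamdwell import ttest_unpaired
from roamdwell.pipeline import run_bouts

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    tables = {}
    for name in ("wildtype", "mutant"):
        res = run_bouts(
            ROOT / "classify" / name / "state_annotations.tsv", ROOT / "bouts" / name
        )
        tables[name] = pd.read_csv(res["bouts"], sep="\t")
    for state in ("ROAM", "DWELL"):
        groups = {
            name: df.loc[df["state"] == state, "duration_s"]
            for name, df in tables.items()
        }
        line = ", ".join(
            f"{name}: {g.mean():.0f} s (n={len(g)})" for name, g in groups.items()
        )
        if all(len(g) >= 2 for g in groups.values()):
            cmp = ttest_unpaired(groups["wildtype"], groups["mutant"])
            line += f"; t = {cmp.t_stat:.2f}, p = {cmp.p_two_tailed:.3g} ({cmp.significance_marker})"
        print(f"{state} bout duration -- {line}")


if __name__ == "__main__":
    main()
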