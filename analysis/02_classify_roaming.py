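#!/usr/bin/env python
"""Classify roaming/dwelling intervals and compare fraction roaming.

The speed cutoff is placed once, from the wild-type (control) cohort's
interval speed distribution, and applied to both cohorts -- mirroring the
assay convention of anchoring the cutoff to the control condition of each
experiment. Per-animal fraction-roaming values are ROUT-filtered (Q = 1%)
within cohort and compared with an unpaired two-tailed t-test.

Requires 01_simulate_cohorts.py to have run. Writes per-animal summaries
and the cohort comparison under results/classify/.
"""

from pathlib import Path

import pandas as pd

from roamdwell.pipeline import run_classify, run_report

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    summaries = {}
    control = ROOT / "cohorts" / "wildtype" / "trajectories.csv"
    for name in ("wildtype", "mutant"):
        res = run_classify(
            ROOT / "cohorts" / name / "trajectories.csv",
            ROOT / "classify" / name,
            control_trajectories=control,
        )
        summaries[name] = res["per_animal_summary"]
        df = pd.read_csv(res["per_animal_summary"], sep="\t")
        print(
            f"{name}: cutoff {df['cutoff_um_s'].iloc[0]:.2f} um/s, "
            f"fraction roaming {df['fraction_roaming'].mean():.3f} "
            f"+/- {df['fraction_roaming'].std():.3f} (n={len(df)})"
        )
    report = run_report(
        summaries["wildtype"], summaries["mutant"], ROOT / "classify" / "comparison"
    )
    rec = pd.read_csv(report["comparison_tsv"], sep="\t").iloc[0]
    print(
        f"wildtype vs mutant fraction roaming: t = {rec.t_stat:.2f}, "
        f"df = {rec.df:.0f}, p = {rec.p_two_tailed:.2e} ({rec.significance})"
    )


if __name__ == "__main__":
    main()
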