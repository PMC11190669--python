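"""Subset screen, median-split scores and the score-group ANOVA.

Computes per-patient ΔeGFR (last minus first eGFR) over the >1-year
subcohort, regresses ΔeGFR on each patient-mean subset percentage,
scores patients 0-3 on the NK / naive CD4+ T / memory CD4+ T median
splits and compares ΔeGFR across score-sum groups and the collapsed
Group 1 (sum 0-1) vs Group 2 (sum 2-3).
"""

import argparse
import json
from pathlib import Path

from lnscore.cohort import read_cohort
from lnscore.pipeline import _jsonable
from lnscore.simulate import run_scoring_pipeline
from lnscore.stats import anova_from_summary

ap = argparse.ArgumentParser()
ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
ap.add_argument("--out", type=Path, default=Path("results/scores.json"))
args = ap.parse_args()

cohort = read_cohort(args.cohort)
sub, deltas, means, screen, scores, summary = run_scoring_pipeline(cohort)

stats4 = [summary.by_score[k] for k in sorted(summary.by_score)]
anova4 = anova_from_summary(stats4) if len(stats4) >= 2 else None
stats2 = [summary.by_group[k] for k in sorted(summary.by_group)]
anova2 = anova_from_summary(stats2) if len(stats2) >= 2 else None
args.out.write_text(json.dumps(_jsonable({
    "screen": screen, "scores": scores, "group_summary": summary,
    "anova_four_groups": anova4, "anova_two_groups": anova2,
}), indent=1))

print(f"long-term subcohort: {len(deltas)} patients")
for r in screen:
    flag = "*" if r.selected else " "
    print(f"  {r.subset:<11} sign {r.slope_sign}  P={r.p_value:.4f} {flag}")
for s, (n, m, sd) in sorted(summary.by_score.items()):
    print(f"score sum {s}: n={n:<3d} dEGFR = {m:9.3f} +/- {sd:.3f}")
for g, (n, m, sd) in sorted(summary.by_group.items()):
    print(f"Group {g}:     n={n:<3d} dEGFR = {m:9.3f} +/- {sd:.3f}")
if anova4:
    print(f"4-group ANOVA: P={anova4.p_value:.4f}, R2={anova4.r_squared:.6f}")
if anova2:
    print(f"2-group ANOVA: P={anova2.p_value:.4f}, R2={anova2.r_squared:.6f}")
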