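"""Label every clinic visit as non-LN / inactive LN / active LN.

Applies the exclusion windows (90 days post rituximab/steroid pulse, acute
infection) and the renal-outcome rules (improvement / no change /
deterioration / relapse) against each visit's prior baseline, then prints
the label distribution.
"""

import argparse
import collections
import json
from pathlib import Path

from lnscore.cohort import read_cohort
from lnscore.episodes import episode_report, label_episodes

ap = argparse.ArgumentParser()
ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
ap.add_argument("--out", type=Path, default=Path("results/episodes.json"))
args = ap.parse_args()

cohort = read_cohort(args.cohort)
episodes = []
for p in cohort.patients:
    episodes.extend(episode_report(p, label_episodes(p)))
args.out.write_text(json.dumps(episodes, indent=1))

labels = collections.Counter(e["label"] for e in episodes if not e["excluded"])
excl = collections.Counter(e["exclusion_reason"] for e in episodes if e["excluded"])
print(f"{len(episodes)} visits -> {args.out}")
print("labels:", dict(labels))
print("excluded:", dict(excl))
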