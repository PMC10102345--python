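#!/usr/bin/env python
"""Run the full cohort statistical plan on a simulated IS/HC cohort.

First re-checks the published group comparisons directly from the printed
summaries (Welch t on left/right ALPS and age; Yates χ² on sex), then
simulates a default cohort (20 IS / 30 HC) and runs the complete plan:
group comparisons, lateralization paired t, Spearman ALPS–FMA correlations
and partial ALPS–CST correlations controlling age and days post onset.
Writes results/published_summary_tests.csv and results/cohort_statistics.csv.
"""

from pathlib import Path

import pandas as pd

from dtialps import GroupSummary, chi_square_2x2, simulate_cohort, two_sample_t
from dtialps.pipeline import run_cohort_statistics

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEED = 20230331  # fixed analysis seed


def summary_form_tests() -> pd.DataFrame:
    comparisons = {
        "alps_left": (GroupSummary(1.424, 0.132, 20), GroupSummary(1.565, 0.197, 30)),
        "alps_right": (GroupSummary(1.381, 0.172, 20), GroupSummary(1.454, 0.107, 30)),
        "age": (GroupSummary(59.2, 12.1, 20), GroupSummary(54.6, 7.4, 30)),
    }
    rows = []
    for name, (a, b) in comparisons.items():
        for variant in ("welch", "student"):
            r = two_sample_t(a, b, variant)
            rows.append({"comparison": name, **r.to_dict()})
    sex = chi_square_2x2([[16, 4], [20, 10]], yates=True)
    rows.append({"comparison": "sex", **sex.to_dict()})
    return pd.DataFrame(rows)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    summaries = summary_form_tests()
    summaries.to_csv(RESULTS / "published_summary_tests.csv", index=False)
    print("tests from printed group summaries:")
    print(summaries[["comparison", "method", "statistic", "p_value"]]
          .to_string(index=False, float_format=lambda v: f"{v:.4f}"))

    cohort = simulate_cohort(seed=SEED)
    cohort.to_csv(RESULTS / "simulated_cohort.csv", index=False)
    stats = run_cohort_statistics(cohort)
    stats.to_csv(RESULTS / "cohort_statistics.csv", index=False)
    print(f"\nsimulated cohort (seed {SEED}): "
          f"{(cohort.group == 'IS').sum()} IS / {(cohort.group == 'HC').sum()} HC")
    cols = ["comparison", "method", "statistic", "p_value"]
    print(stats[cols].to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    print(f"\ntables -> {RESULTS / 'published_summary_tests.csv'}, "
          f"{RESULTS / 'cohort_statistics.csv'}")


if __name__ == "__main__":
    main()
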