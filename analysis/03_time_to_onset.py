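#!/usr/bin/env python
"""Summarize time-to-onset for the cohort from a finished pipeline run.

Reads results/run/tto_summary.tsv and tto_records.tsv (written by
02_signal_detection.py) and prints the onset profile: median/IQR, mean, the
within-one-year fraction and the binned distribution, together with the date
exclusions that reduced the cohort to the evaluable set.
"""

import argparse
from pathlib import Path

import pandas as pd


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--run-dir", type=Path, default=Path("results/run"))
    args = parser.parse_args()

    summary = pd.read_csv(args.run_dir / "tto_summary.tsv", sep="\t").set_index("quantity")["value"]
    n = int(summary["n_evaluable"])
    print(f"evaluable onset records: {n}")
    print(f"median {summary['median_days']:.0f} days "
          f"(IQR {summary['q1_days']:.0f}-{summary['q3_days']:.0f}); "
          f"mean {summary['mean_days']:.1f} days")
    print(f"within one year: {summary['within_365_pct']:.2f}% "
          f"(n = {int(summary['within_365_count'])})")
    print("onset distribution (days):")
    for key, value in summary.items():
        if key.startswith("bin_"):
            print(f"  {key[4:]:>8s}: {int(value):4d}")
    print("exclusions:")
    for key, value in summary.items():
        if key.startswith("excluded_"):
            print(f"  {key[9:]:>22s}: {int(value):4d}")


if __name__ == "__main__":
    main()
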