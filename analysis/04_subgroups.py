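#!/usr/bin/env python
"""Compare stratified signal tables from a finished pipeline run.

Reads the per-stratum signal tables under results/run/strata/ (age < 18 vs
>= 18, male vs female; each stratum compared against its own background with
a freshly fitted MGPS prior) and prints the consensus signals per stratum.
Sparse strata (here: females, ~1.5% of reports) are expected to lose power.
"""

import argparse
from pathlib import Path

import pandas as pd


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--run-dir", type=Path, default=Path("results/run"))
    args = parser.parse_args()

    strata_dir = args.run_dir / "strata"
    for path in sorted(strata_dir.glob("*_pt.tsv")):
        name = path.stem[:-3]
        frame = pd.read_csv(path, sep="\t")
        if frame.empty:
            print(f"{name}: no cohort members")
            continue
        eligible = frame[frame.eligible]
        hits = frame[frame.consensus]
        print(f"{name}: {len(eligible)} eligible terms, {len(hits)} consensus signals")
        for _, r in hits.iterrows():
            print(f"  {r['term']:35s} n={r['n_cases']:3.0f}  ROR {r['ror']:6.2f}  "
                  f"EBGM {r['ebgm']:6.2f} ({r['eb05']:6.2f})")


if __name__ == "__main__":
    main()
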