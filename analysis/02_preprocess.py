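#!/usr/bin/env python
"""Derive ages, enforce the 0-12-year window, keep serious reports.

Reads results/database/, writes the analysis-ready database and the
exclusion log to results/preprocessed/.
"""

import argparse
from collections import Counter
from pathlib import Path

from pedpv import icsr_model, preprocess


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--in-dir", type=Path, default=Path("results/database"))
    parser.add_argument("--out-dir", type=Path, default=Path("results/preprocessed"))
    args = parser.parse_args()

    reports = icsr_model.read_database(
        args.in_dir / "reports.csv", args.in_dir / "drugs.csv", args.in_dir / "events.csv"
    )
    serious, exclusions = preprocess.preprocess_reports(reports)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    icsr_model.write_database(serious, args.out_dir)
    preprocess.write_exclusions(exclusions, args.out_dir / "exclusions.csv")

    groups = Counter(preprocess.age_group_of(r).value for r in serious)
    print(f"retained {len(serious)} serious in-window cases "
          f"({len(exclusions)} excluded) -> {args.out_dir}")
    for group, n in groups.most_common():
        print(f"  {group:<17s} {n:5d} ({100 * n / len(serious):.1f}%)")


if __name__ == "__main__":
    main()
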