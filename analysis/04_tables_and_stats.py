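#!/usr/bin/env python
"""Build the five study tables and the chi-square association tests.

Reads the preprocessed database, the label registry and signals.csv, writes
table1..table5 and assoc_tests.csv to results/tables/.
"""

import argparse
from pathlib import Path

import pandas as pd

from pedpv import association_stats as ast
from pedpv import disproportionality as dis
from pedpv import icsr_model, label_registry, reporting


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--in-dir", type=Path, default=Path("results/preprocessed"))
    parser.add_argument("--db-dir", type=Path, default=Path("results/database"))
    parser.add_argument("--out-dir", type=Path, default=Path("results/tables"))
    args = parser.parse_args()

    reports = icsr_model.read_database(
        args.in_dir / "reports.csv", args.in_dir / "drugs.csv", args.in_dir / "events.csv"
    )
    registry = label_registry.read_label_registry(args.db_dir / "label_registry.csv")
    label_registry.apply_label_classification(reports, registry)
    monitoring = dis.read_term_list(args.db_dir / "monitoring_list.txt")
    ime = dis.read_term_list(args.db_dir / "ime_list.txt")
    results = dis.screen(reports, monitoring, ime, registry)

    summary = reporting.summarize(reports, results, registry)
    paths = reporting.write_tables(summary, args.out_dir)

    rows = []
    for name, table in (
        ("seriousness_by_age", ast.seriousness_by_age_table(reports)),
        ("ol_by_seriousness", ast.ol_by_seriousness_table(reports)),
    ):
        res = ast.chi_square_independence(ast.drop_empty_margins(table))
        rows.append({"test_name": name, "statistic": round(res.statistic, 4),
                     "df": res.df, "p_value": res.p_value,
                     "min_expected_count": round(res.min_expected_count, 3),
                     "warning": "min expected count < 5" if res.min_expected_count < 5 else ""})
    pd.DataFrame(rows).to_csv(args.out_dir / "assoc_tests.csv", index=False)

    print(f"{summary.n_reports} reports, {summary.n_drug_entries} drug entries "
          f"(mean {summary.mean_drugs_per_report} per report)")
    top = summary.atc_level1_distribution.sort_values("n", ascending=False).iloc[0]
    print(f"  most reported ATC group: {top.atc_group} ({top.atc_level1}) "
          f"{top.n} entries ({top.pct}%)")
    ol = summary.ol_summary
    print(f"  off-label drug entries: {ol.n_off_label.sum()} "
          f"({100 * ol.n_off_label.sum() / ol.n_drugs.sum():.0f}%)")
    for row in rows:
        print(f"  chi-square {row['test_name']}: chi2={row['statistic']} "
              f"df={row['df']} p={row['p_value']:.3g} {row['warning']}")
    print(f"tables written -> {', '.join(str(p) for p in paths.values())}")


if __name__ == "__main__":
    main()
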