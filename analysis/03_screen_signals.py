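#!/usr/bin/env python
"""ROR-screen every drug-event pair and apply the SDR decision rule.

Reads the preprocessed database and the term lists, writes signals.csv to
results/signals/, and reports how many injected ground-truth pairs were
recovered.
"""

import argparse
from pathlib import Path

import pandas as pd

from pedpv import disproportionality as dis
from pedpv import icsr_model, label_registry


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--in-dir", type=Path, default=Path("results/preprocessed"))
    parser.add_argument("--db-dir", type=Path, default=Path("results/database"),
                        help="where the registry, term lists and ground truth live")
    parser.add_argument("--out-dir", type=Path, default=Path("results/signals"))
    args = parser.parse_args()

    reports = icsr_model.read_database(
        args.in_dir / "reports.csv", args.in_dir / "drugs.csv", args.in_dir / "events.csv"
    )
    registry = label_registry.read_label_registry(args.db_dir / "label_registry.csv")
    monitoring = dis.read_term_list(args.db_dir / "monitoring_list.txt")
    ime = dis.read_term_list(args.db_dir / "ime_list.txt")

    results = dis.screen(reports, monitoring, ime, registry)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    dis.write_signals(results, args.out_dir / "signals.csv")

    sdrs = [r for r in results if r.is_sdr]
    by_stratum = {
        s: sum(r.stratum == s for r in sdrs)
        for s in (dis.STRATUM_A_3_TO_4, dis.STRATUM_A_GE_5)
    }
    print(f"scored {len(results)} pairs with a >= 3 over N={len(reports)} cases")
    print(f"  SDRs: {len(sdrs)} (a in [3,5): {by_stratum[dis.STRATUM_A_3_TO_4]}, "
          f"a >= 5: {by_stratum[dis.STRATUM_A_GE_5]})")
    print(f"  SDRs with event not described in label: "
          f"{sum(bool(r.unlabelled_event) for r in sdrs)}")

    truth_path = args.db_dir / "ground_truth.csv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path)
        injected = set(zip(truth.drug_name, truth.event_term))
        found = {(r.drug_name, r.event_term) for r in sdrs}
        print(f"  injected pairs recovered as SDR: "
              f"{len(injected & found)}/{len(injected)}")


if __name__ == "__main__":
    main()
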