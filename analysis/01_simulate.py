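#!/usr/bin/env python
"""Generate the study database: a synthetic pediatric serious-ADR extract.

Emulates a 2008-2013 national spontaneous-reporting extract (1,977 serious
reports, 0-12-year-olds) with known injected drug-event signals, and writes
the tidy three-file database plus the label registry and screening term
lists under results/database/.
"""

import argparse
from pathlib import Path

from pedpv import disproportionality, icsr_model, label_registry, synthetic_data as sd


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=20080101)
    parser.add_argument("--out-dir", type=Path, default=Path("results/database"))
    args = parser.parse_args()

    config = sd.default_notivisa_like_config(args.seed)
    reports, truth = sd.generate_database(config)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    icsr_model.write_database(reports, args.out_dir)
    sd.write_ground_truth(truth, args.out_dir / "ground_truth.csv")
    label_registry.write_label_registry(
        sd.registry_from_config(config), args.out_dir / "label_registry.csv"
    )
    disproportionality.write_term_list(
        sd.monitoring_list_from_config(config), args.out_dir / "monitoring_list.txt"
    )
    disproportionality.write_term_list(
        sd.ime_list_from_config(config), args.out_dir / "ime_list.txt"
    )
    sd.save_config(config, args.out_dir / "config.yaml")

    n_entries = sum(len(r.drugs) for r in reports)
    print(f"generated {len(reports)} serious case reports -> {args.out_dir}")
    print(f"  drug entries: {n_entries} (mean {n_entries/len(reports):.2f} per report)")
    print(f"  injected signals: {len(truth.injected_signals)} "
          f"(lambda {min(s.odds_multiplier for s in truth.injected_signals):g}"
          f"-{max(s.odds_multiplier for s in truth.injected_signals):g})")


if __name__ == "__main__":
    main()
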