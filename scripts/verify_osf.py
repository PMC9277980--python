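#!/usr/bin/env python
"""OPTIONAL full-data verification against the archived study deposit.

The published participant-level data (OSF project ms8w2) are NOT bundled
with this repository.  If you download the deposit yourself, this script
reruns the pipeline — exclusions, AuC scoring, distress index, and the
country-nested multilevel logistic regression — on the real tables and
prints the fitted coefficients, odds ratios, ICC, and likelihood-ratio
test for comparison with the published descriptive and regression tables.

It expects a directory containing:

  participants.csv  with columns: participant_id, country, age, education
                    (1-3), income (0-100), essential_worker (0/1),
                    gad7_1..gad7_7, phq9_1..phq9_9, vaccination_raw
                    (full/partial/unvacc_planning/unvacc_not_planning),
                    eligible, completed, attention_fails
  trials.csv        with columns: participant_id, delay_label, delay_days,
                    trial_index, immediate_amount, choice

Column names in the deposit differ; rename/recode to this schema first.
Without the data the script exits with a clear message — nothing in the
regular test suite depends on it.

Usage:
    python scripts/verify_osf.py --data-dir /path/to/deposit
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path


def main() -> None:
    parser = argparse.ArgumentParser(
        description=__doc__, formatter_class=argparse.RawDescriptionHelpFormatter
    )
    parser.add_argument(
        "--data-dir",
        type=Path,
        required=True,
        help="directory holding participants.csv and trials.csv from the deposit",
    )
    parser.add_argument(
        "--anchor", action=argparse.BooleanOptionalAction, default=True,
        help="prepend the (0, 1) anchor point before computing AuC",
    )
    args = parser.parse_args()

    participants_path = args.data_dir / "participants.csv"
    trials_path = args.data_dir / "trials.csv"
    missing = [p for p in (participants_path, trials_path) if not p.exists()]
    if missing:
        sys.exit(
            "deposit data not found: "
            + ", ".join(str(p) for p in missing)
            + "\nDownload the archived tables, map them to the documented schema, "
            "and rerun. This verification is optional and needs no network at fit time."
        )

    import pandas as pd

    from discountkit.cli import _fit_payload, _print_fit, score_participants
    from discountkit.glmm import ModelSpec

    raw = pd.read_csv(participants_path)
    trials = pd.read_csv(trials_path)
    clean, report = score_participants(raw, trials, anchor=bool(args.anchor))
    print(f"analyzed n = {len(clean)} (excluded {report.n_excluded} of {report.n_in})")
    print(clean.groupby("vaccinated")["auc"].agg(["mean", "std"]).round(3))
    _print_fit(_fit_payload(clean, ModelSpec()))


if __name__ == "__main__":
    main()
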