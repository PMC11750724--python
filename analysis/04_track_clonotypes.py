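#!/usr/bin/env python
"""Cohort-level TCR clonotype tracking statistics.

Reads the per-patient monitoring reports written by 03_immune_monitoring.py
and summarizes the validated neoantigen-specific TCRs: cumulative frequency
in post-induction blood, de novo fraction against the baseline repertoire,
and detection in on-treatment tumor samples. Writes results/tcr_tracking.tsv.
"""

import argparse
import json
from pathlib import Path

import pandas as pd


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--monitoring", type=Path, default=Path("scratch/monitoring"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    rows = []
    n_tcrs_total = 0
    n_de_novo_total = 0
    for f in sorted(args.monitoring.glob("*_monitoring.json")):
        rep = json.loads(f.read_text())
        validated = [t for t in rep["specific_tcrs"] if t["validated"]]
        tracking = rep["tracking"]
        blood = tracking.get("blood", {})
        tumors = tracking.get("tumor", [])
        n_de_novo = tracking.get("n_de_novo", 0)
        n_tcrs_total += len(validated)
        n_de_novo_total += n_de_novo
        rows.append(
            {
                "patient": rep["patient_id"],
                "n_validated_tcrs": len(validated),
                "n_de_novo_tcrs": n_de_novo,
                "blood_cumulative_frequency": blood.get("cumulative_frequency"),
                "n_neoantigens_tracked": blood.get("n_neoantigens"),
                "tumor_cumulative_frequency": (
                    tumors[0]["cumulative_frequency"] if tumors else None
                ),
            }
        )
    if not rows:
        raise SystemExit(f"no monitoring reports under {args.monitoring}; run 03 first")
    df = pd.DataFrame(rows)
    args.results.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.results / "tcr_tracking.tsv", sep="\t", index=False)

    with_tcrs = df[df.n_validated_tcrs > 0]
    print(f"patients with validated specific TCRs: {len(with_tcrs)}/{len(df)}")
    print(f"specific TCRs: {n_tcrs_total} total, "
          f"{n_de_novo_total} undetectable at baseline (de novo)")
    if len(with_tcrs):
        print("cumulative frequency of specific TCRs in post-induction blood: "
              f"median {with_tcrs.blood_cumulative_frequency.median():.1%}, "
              f"range {with_tcrs.blood_cumulative_frequency.min():.1%}-"
              f"{with_tcrs.blood_cumulative_frequency.max():.1%}")
        tumor = with_tcrs.tumor_cumulative_frequency.dropna()
        if len(tumor):
            print(f"in on-treatment tumor: median {tumor.median():.1%}")


if __name__ == "__main__":
    main()
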