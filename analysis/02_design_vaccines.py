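#!/usr/bin/env python
"""Design the individualized vaccine for every simulated patient.

Reads each patient bundle written by 01_simulate_cohort.py from files (VCF,
FASTA, TSV), runs MPS extraction with germline phasing, mock HLA-binding
scoring, tiered prioritization (<= 46), eligibility (>= 5 neoantigens),
composite-score selection (<= 20) and concatamer construct assembly, and
writes per-patient design reports + construct FASTA under scratch/designs/
and a cohort design table under results/.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from neovax.pipeline import PipelineConfig, load_patient_dir, run_design


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--cohort", type=Path, default=Path("scratch/cohort"))
    ap.add_argument("--out", type=Path, default=Path("scratch/designs"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    config = PipelineConfig(seed=args.seed)
    args.out.mkdir(parents=True, exist_ok=True)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for d in sorted(p for p in args.cohort.iterdir() if p.is_dir()):
            patient = load_patient_dir(d)
            rep = run_design(patient, config)
            rep.write(args.out / f"{rep.patient_id}_design.json")
            if rep.constructs:
                rep.write_construct_fasta(args.out / f"{rep.patient_id}_constructs.fasta")
            tiers = pd.Series([e["tier"] for e in rep.prioritized]).value_counts()
            rows.append(
                {
                    "patient": rep.patient_id,
                    "n_candidates": rep.n_candidates,
                    "eligible": rep.eligible,
                    "n_prioritized": len(rep.prioritized),
                    "n_indel_tier": int(tiers.get("INDEL", 0)),
                    "n_selected": len(rep.selected),
                    "n_constructs": len(rep.constructs),
                    "max_targets_per_construct": max(
                        (len(c.targets) for c in rep.constructs), default=0
                    ),
                }
            )
    df = pd.DataFrame(rows)
    args.results.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.results / "design_summary.tsv", sep="\t", index=False)

    print(f"designed {len(df)} patients from {args.cohort}")
    print(f"eligible (>=5 neoantigens): {df.eligible.sum()}/{len(df)}")
    print(f"prioritized MPS/patient: median {df.n_prioritized.median():.0f} (cap 46)")
    print(f"selected targets/patient (eligible): "
          f"median {df.loc[df.eligible, 'n_selected'].median():.0f} (cap 20)")
    print(f"max targets on any construct: {df.max_targets_per_construct.max()} (cap 10)")


if __name__ == "__main__":
    main()
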