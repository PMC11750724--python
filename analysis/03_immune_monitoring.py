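#!/usr/bin/env python
"""Simulate monitoring assays and call vaccine-induced immune responses.

For every eligible designed patient, simulates ELISpot plates, bulk TCR
repertoires and Jurkat reporter screens against the selected targets, then
runs response calling (permutation test + two-fold rule), multimer candidate
selection and TCR validation. Writes per-patient monitoring JSON under
scratch/monitoring/ and a cohort roll-up under results/, and compares the
called responder fraction with the planted truth.
"""

import argparse
import json
import warnings
from pathlib import Path

from neovax.pipeline import (
    DesignReport,
    PipelineConfig,
    cohort_rollup,
    load_patient_dir,
    run_design,
    run_monitoring,
)
from neovax.synthetic_data import AssayConfig, generate_assay_data


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--cohort", type=Path, default=Path("scratch/cohort"))
    ap.add_argument("--out", type=Path, default=Path("scratch/monitoring"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    config = PipelineConfig(seed=args.seed)
    assay_cfg = AssayConfig()
    args.out.mkdir(parents=True, exist_ok=True)
    designs, monitorings = [], []
    planted_responders = 0
    called_responders = 0
    n_eligible = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for d in sorted(p for p in args.cohort.iterdir() if p.is_dir()):
            patient = load_patient_dir(d)
            rep = run_design(patient, config)
            designs.append(rep)
            if not rep.selected:
                monitorings.append(None)
                continue
            n_eligible += 1
            selected = [s["variant_id"] for s in rep.selected]
            bundle = generate_assay_data(patient, selected, args.seed, assay_cfg)
            mon = run_monitoring(rep, assays=bundle, config=config)
            monitorings.append(mon)
            (args.out / f"{rep.patient_id}_monitoring.json").write_text(mon.to_json() + "\n")
            planted_responders += len(bundle.planted.immunogenic_targets) > 0
            called_responders += mon.summary.responder

    df = cohort_rollup(designs, monitorings)
    args.results.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.results / "monitoring_summary.tsv", sep="\t", index=False)

    print(f"monitored {n_eligible} eligible patients")
    print(f"planted responders: {planted_responders}/{n_eligible} "
          f"({planted_responders / max(n_eligible, 1):.0%})")
    print(f"called responders:  {called_responders}/{n_eligible} "
          f"({called_responders / max(n_eligible, 1):.0%})")


if __name__ == "__main__":
    main()
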