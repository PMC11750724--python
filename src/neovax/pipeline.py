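"""End-to-end orchestration: design and monitoring with full audit trails.

``run_design`` chains variant -> MPS extraction -> binding -> prioritization
-> eligibility -> selection -> construct assembly for one patient, recording
every candidate's fate. ``run_monitoring`` consumes the design report plus
assay tables and produces response calls, multimer candidates, validated
specific TCRs and clonotype-tracking summaries. Both are deterministic for a
fixed (inputs, config): reports carry a provenance block (config hash, seed)
sufficient to reproduce them byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .binding import CLASS_I_LENGTHS, MockPredictor, score_mps
from .constructs import (
    ConstructSpec,
    SelectionConfig,
    check_eligibility,
    design_constructs,
    select_targets,
)
from .errors import InputError
from .immunogenicity import (
    ElispotMeasurement,
    ResponseCall,
    call_response,
    select_multimer_candidates,
    summarize_patient,
)
from .mps import MutatedPeptideSequence, build_candidate, filter_candidates
from .prioritization import TierCaps, prioritize
from .synthetic_data import AssayBundle, SyntheticPatient
from .tcr import (
    RepertoireSample,
    SpecificTcr,
    biopsy_overlap,
    classify_baseline_status,
    cumulative_frequency,
    jurkat_specificity_call,
)

__version__ = "0.1.0"


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    min_phase_reads: int = 2
    phase_fraction: float = 0.8
    expressed_min: float = 0.1
    caps: TierCaps = field(default_factory=TierCaps)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    class1_lengths: tuple[int, ...] = CLASS_I_LENGTHS
    predictor_id: str = "mock-v1"
    alpha: float = 0.05
    min_spot_delta: float = 5.0
    fold_threshold: float = 2.0
    net_floor: float = 1.0
    multimer_rank_cutoff: float = 5.0
    multimer_max_pairs: int = 3
    baseline_detection_threshold: int = 0

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _mps_record(m: MutatedPeptideSequence) -> dict:
    return {
        "variant_id": m.variant_id,
        "sequence": m.sequence,
        "mutated_span": list(m.mutated_span),
        "source_kind": m.source_kind,
        "incorporated_germline": list(m.incorporated_germline),
        "rpkm": m.rpkm,
        "vaf_rna": m.vaf_rna,
        "vaf_dna": m.vaf_dna,
        "best_class1_rank": m.best_class1_rank,
        "best_class2_rank": m.best_class2_rank,
        "flags": list(m.flags),
    }


@dataclass
class DesignReport:
    patient_id: str
    hla_class1: list[str]
    hla_drb: list[str]
    fates: dict[str, dict]  # variant_id -> audit record
    n_candidates: int
    eligible: bool
    prioritized: list[dict]
    selected: list[dict]
    constructs: list[ConstructSpec]
    provenance: dict

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["constructs"] = [
            {
                "construct_id": c.construct_id,
                "target_ids": [t.variant_id for t in c.targets],
                "protein_sequence": c.protein_sequence,
                "nucleotide_sequence": c.nucleotide_sequence,
            }
            for c in self.constructs
        ]
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    def write_construct_fasta(self, path: str | Path) -> None:
        records = {}
        for c in self.constructs:
            ids = "+".join(t.variant_id for t in c.targets)
            records[f"{self.patient_id}_{c.construct_id}_protein|{ids}"] = c.protein_sequence
            records[f"{self.patient_id}_{c.construct_id}_nt|{ids}"] = c.nucleotide_sequence
        io.write_fasta(records, path)


def run_design(
    patient: SyntheticPatient, config: PipelineConfig | None = None
) -> DesignReport:
    """Design the individualized vaccine for one patient.

    Returns a report recording every candidate's fate (dropped with reason,
    prioritized with tier, selected with rank) plus the assembled constructs.
    Patients with fewer identified neoantigens than the eligibility minimum
    get a report with ``eligible=False`` and no constructs.
    """
    config = config or PipelineConfig()
    germline_by_somatic: dict[str, list] = {}
    for g in patient.germline_variants:
        germline_by_somatic.setdefault(g.somatic_id, []).append(g)

    fates: dict[str, dict] = {}
    records = []
    for v in patient.somatic_variants:
        rec = build_candidate(
            v,
            patient.cds[v.transcript_id],
            germline_by_somatic.get(v.id, []),
            min_phase_reads=config.min_phase_reads,
            phase_fraction=config.phase_fraction,
        )
        records.append(rec)
    kept, dropped = filter_candidates(records, expressed_min=config.expressed_min)
    for rec in dropped:
        fates[rec.variant.id] = {"stage": "filtered", "reason": rec.drop_reason}

    predictor = MockPredictor(config.predictor_id)
    annotated = []
    for rec in kept:
        m, _scores = score_mps(
            rec.mps, patient.hla_class1, patient.hla_drb, predictor,
            config.class1_lengths,
        )
        annotated.append(m)
        fates[rec.variant.id] = {"stage": "candidate"}

    prioritized = prioritize(annotated, config.caps)
    for e in prioritized:
        fates[e.mps.variant_id] = {
            "stage": "prioritized", "tier": e.tier.value, "rank": e.rank,
        }

    eligible = check_eligibility(
        len(kept), config.selection.min_neoantigens_eligibility
    )
    selected, constructs = [], []
    if eligible and len(prioritized) > 0:
        selected = select_targets(prioritized, config.selection)
        constructs = design_constructs(selected)
        for t in selected:
            fates[t.variant_id] = {
                "stage": "selected", "tier": t.tier.value,
                "priority_rank": t.priority_rank,
                "selection_rank": t.selection_rank,
                "score": round(t.score, 6),
            }

    return DesignReport(
        patient_id=patient.patient_id,
        hla_class1=list(patient.hla_class1),
        hla_drb=list(patient.hla_drb),
        fates=fates,
        n_candidates=len(kept),
        eligible=bool(eligible),
        prioritized=[
            {"variant_id": e.mps.variant_id, "tier": e.tier.value, "rank": e.rank,
             **_mps_record(e.mps)}
            for e in prioritized
        ],
        selected=[
            {"selection_rank": t.selection_rank, "priority_rank": t.priority_rank,
             "tier": t.tier.value, "score": round(t.score, 6), **_mps_record(t.mps)}
            for t in selected
        ],
        constructs=constructs,
        provenance={
            "config_hash": config.hash(),
            "seed": config.seed,
            "predictor_id": config.predictor_id,
            "version": __version__,
        },
    )


def load_patient_dir(path: str | Path, patient_id: str | None = None) -> SyntheticPatient:
    """Reconstruct a patient bundle from its on-disk files."""
    d = Path(path)
    cds = io.read_fasta(d / "cds.fasta")
    proteome = io.read_fasta(d / "protein.fasta")
    expression = io.read_expression_tsv(d / "expression.tsv")
    somatic = io.read_somatic_vcf(d / "somatic.vcf", expression)
    germline = io.read_germline_vcf(d / "germline.vcf")
    hla1, drb = io.read_hla_json(d / "hla.json")
    truth = {}
    truth_path = d / "truth.json"
    if truth_path.exists():
        from .synthetic_data import TruthLabel

        truth = {
            vid: TruthLabel(**rec)
            for vid, rec in json.loads(truth_path.read_text()).items()
        }
    return SyntheticPatient(
        patient_id=patient_id or d.name,
        cds=cds,
        proteome=proteome,
        hla_class1=hla1,
        hla_drb=drb,
        somatic_variants=somatic,
        germline_variants=germline,
        expression=expression,
        truth=truth,
    )


@dataclass
class MonitoringReport:
    patient_id: str
    response_calls: list[ResponseCall]
    summary: "object"
    multimer_candidates: dict[str, list[tuple[str, str, float]]]
    specific_tcrs: list[SpecificTcr]
    tracking: dict

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "responder": self.summary.responder,
            "n_targets_positive": self.summary.n_targets_positive,
            "response_calls": [dataclasses.asdict(c) for c in self.response_calls],
            "phenotypes": list(self.summary.phenotypes),
            "multimer_candidates": self.multimer_candidates,
            "specific_tcrs": [dataclasses.asdict(t) for t in self.specific_tcrs],
            "tracking": self.tracking,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1, default=str)


def _pair_measurements(
    measurements: list[ElispotMeasurement],
) -> list[tuple[ElispotMeasurement | None, ElispotMeasurement]]:
    by_key: dict[tuple, dict[str, ElispotMeasurement]] = {}
    for m in measurements:
        key = (m.target_id, m.assay, m.compartment)
        by_key.setdefault(key, {})[m.timepoint] = m
    pairs = []
    for key in sorted(by_key):
        tps = by_key[key]
        if "post_induction" in tps:
            pairs.append((tps.get("baseline"), tps["post_induction"]))
    return pairs


def run_monitoring(
    design: DesignReport,
    assays: AssayBundle | None = None,
    elispot: list[ElispotMeasurement] | None = None,
    repertoires: list[RepertoireSample] | None = None,
    jurkat=None,
    config: PipelineConfig | None = None,
) -> MonitoringReport:
    """Immune-monitoring analytics for one designed patient.

    ELISpot rows referencing targets absent from the design are listed under
    ``tracking['unknown_targets']`` and skipped, not fatal.
    """
    config = config or PipelineConfig()
    if assays is not None:
        elispot = assays.elispot
        repertoires = assays.repertoires
        jurkat = assays.jurkat
    elispot = elispot or []
    repertoires = repertoires or []

    encoded = {s["variant_id"] for s in design.selected}
    unknown = sorted({m.target_id for m in elispot} - encoded)
    usable = [m for m in elispot if m.target_id in encoded]

    calls = [
        call_response(
            base, post,
            fold_threshold=config.fold_threshold, net_floor=config.net_floor,
            alpha=config.alpha, min_spot_delta=config.min_spot_delta,
        )
        for base, post in _pair_measurements(usable)
    ]
    summary = summarize_patient(design.patient_id, calls)

    predictor = MockPredictor(config.predictor_id)
    multimer: dict[str, list[tuple[str, str, float]]] = {}
    for s in design.selected:
        m = MutatedPeptideSequence(
            variant_id=s["variant_id"], sequence=s["sequence"],
            mutated_span=tuple(s["mutated_span"]), source_kind=s["source_kind"],
        )
        _, scores = score_mps(m, design.hla_class1, [], predictor, config.class1_lengths)
        picks = select_multimer_candidates(
            scores, config.multimer_rank_cutoff, config.multimer_max_pairs
        )
        multimer[s["variant_id"]] = [
            (p.candidate.peptide, p.candidate.allele, p.percentile_rank)
            for p in picks
        ]

    specific: list[SpecificTcr] = []
    if jurkat is not None:
        for row in jurkat.rows:
            fold, ok = jurkat_specificity_call(row.luminescence, row.effectors_only)
            specific.append(
                SpecificTcr(
                    tcr_id=row.tcr_id, junction_aa=row.junction_aa,
                    specificity=row.specificity, fold_change=fold, validated=ok,
                    v_call=row.v_call or None, j_call=row.j_call or None,
                )
            )
    validated = [t for t in specific if t.validated]

    tracking: dict = {"unknown_targets": unknown}
    blood = sorted(
        (s for s in repertoires if s.compartment == "blood_CD8"),
        key=lambda s: s.timepoint,
    )
    baseline = blood[0] if blood and blood[0].timepoint <= 0 else None
    post = blood[-1] if blood and blood[-1].timepoint > 0 else None
    tumors = [s for s in repertoires if s.compartment == "tumor"]
    if post is not None:
        cf = cumulative_frequency(validated, post)
        tracking["blood"] = {
            "timepoint": post.timepoint,
            "cumulative_frequency": cf.total,
            "per_neoantigen": dict(cf.per_specificity),
            "n_tcrs": cf.n_tcrs_detected,
            "n_neoantigens": cf.n_neoantigens_detected,
        }
    status = classify_baseline_status(
        validated, baseline, config.baseline_detection_threshold
    )
    tracking["baseline_status"] = status
    tracking["n_de_novo"] = sum(1 for s in status.values() if s == "de_novo")
    tracking["tumor"] = []
    for t in tumors:
        cf = cumulative_frequency(validated, t)
        tracking["tumor"].append(
            {
                "lesion": t.lesion, "timepoint": t.timepoint,
                "cumulative_frequency": cf.total,
                "n_tcrs": cf.n_tcrs_detected,
                "n_neoantigens": cf.n_neoantigens_detected,
            }
        )
    if len(tumors) >= 2:
        ov = biopsy_overlap(tumors[0], tumors[1], validated)
        tracking["biopsy_overlap_jaccard"] = ov.jaccard

    return MonitoringReport(
        patient_id=design.patient_id,
        response_calls=calls,
        summary=summary,
        multimer_candidates=multimer,
        specific_tcrs=specific,
        tracking=tracking,
    )


def cohort_rollup(
    designs: list[DesignReport], monitorings: list[MonitoringReport | None]
) -> pd.DataFrame:
    """Cohort summary table: one row per patient (design + monitoring)."""
    rows = []
    for d, m in zip(designs, monitorings):
        row = {
            "patient": d.patient_id,
            "n_candidates": d.n_candidates,
            "eligible": d.eligible,
            "n_prioritized": len(d.prioritized),
            "n_selected": len(d.selected),
            "n_constructs": len(d.constructs),
        }
        if m is not None:
            row.update(
                responder=m.summary.responder,
                n_targets_positive=m.summary.n_targets_positive,
                n_specific_tcrs=sum(1 for t in m.specific_tcrs if t.validated),
                n_de_novo_tcrs=m.tracking.get("n_de_novo", 0),
                blood_cumulative_frequency=m.tracking.get("blood", {}).get(
                    "cumulative_frequency", float("nan")
                ),
            )
        rows.append(row)
    return pd.DataFrame(rows)
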