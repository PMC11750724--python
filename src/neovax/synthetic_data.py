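"""Deterministic synthetic patients and assay datasets.

No patient-level data from the trial this pipeline models is publicly
available, so every downstream stage is exercised on synthetic patients that
reproduce the *statistical shape* of the real inputs: a toy proteome of
random coding sequences, somatic SNV/indel calls with DNA and RNA allele
frequencies, germline variants with cis/trans phase evidence, lognormal
transcript expression, an HLA genotype, and downstream assay tables (ELISpot
spot counts, bulk TCR repertoires, Jurkat reporter readouts) with planted
immunogenicity truth.

All randomness derives from a single integer seed through named substreams
(one per patient and stage), so identical (config, seed) pairs produce
byte-identical output files. With the assay noise set to zero, downstream
response calling and clonotype classification recover the planted truth
exactly; that recoverability is what the test suite leans on.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import io
from .constructs import CODON_TABLE
from .errors import ConfigurationError, InputError
from .immunogenicity import ElispotMeasurement
from .mps import (
    GermlineVariant,
    MutatedPeptideSequence,
    SomaticVariant,
    classify_variant,
    translate_cds,
)
from .tcr import Clonotype, RepertoireSample

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)
_AA = "ACDEFGHIKLMNPQRSTVWY"

CLASS_I_POOL = [
    "A*01:01", "A*02:01", "A*03:01", "A*11:01", "A*24:02",
    "B*07:02", "B*08:01", "B*15:01", "B*35:01", "B*44:02",
    "C*03:04", "C*04:01", "C*05:01", "C*07:01", "C*07:02",
]
DRB_POOL = ["DRB1*01:01", "DRB1*03:01", "DRB1*04:01", "DRB1*07:01", "DRB1*15:01"]


def substream(seed: int, *tags) -> np.random.Generator:
    """A named random substream derived from the global seed."""
    h = hashlib.blake2b("/".join(map(str, tags)).encode(), digest_size=8).digest()
    words = [int.from_bytes(h[i : i + 4], "little") for i in (0, 4)]
    return np.random.default_rng([int(seed)] + words)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Per-patient variant counts are overdispersed: each patient's expected SNV
    and indel counts are the base rates times a shared lognormal multiplier
    (sigma = ``rate_dispersion``), which makes candidate counts span the
    5-neoantigen eligibility boundary in cohorts of a few hundred patients.
    """

    n_patients: int = 10
    seed: int = 0
    snv_rate: float = 20.0
    indel_rate: float = 2.0
    rate_dispersion: float = 0.8
    rpkm_lognormal_params: tuple[float, float] = (1.0, 1.5)
    vaf_beta_params: tuple[float, float] = (2.0, 5.0)
    frac_rna_silent: float = 0.1
    frac_unexpressed: float = 0.1
    frac_synonymous: float = 0.2
    frac_nonsense: float = 0.05
    germline_rate: float = 0.3
    n_proteins: int = 40
    immunogenic_frac: float = 0.2
    responder_frac: float = 0.71
    preexisting_frac: float = 0.3

    def __post_init__(self) -> None:
        if self.n_patients < 0 or self.n_proteins < 1:
            raise ConfigurationError("n_patients >= 0 and n_proteins >= 1 required")
        for name in ("snv_rate", "indel_rate", "rate_dispersion", "germline_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in (
            "frac_rna_silent", "frac_unexpressed", "frac_synonymous",
            "frac_nonsense", "immunogenic_frac", "responder_frac",
            "preexisting_frac",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1]")
        if self.frac_synonymous + self.frac_nonsense > 1.0:
            raise ConfigurationError("consequence fractions exceed 1")
        a, b = self.vaf_beta_params
        if a <= 0 or b <= 0:
            raise ConfigurationError("vaf_beta_params must be positive")
        if self.rpkm_lognormal_params[1] < 0:
            raise ConfigurationError("rpkm sigma must be >= 0")


@dataclass(frozen=True)
class TruthLabel:
    immunogenic: bool
    phenotype: str = "n/a"  # "CD4" | "CD8" | "both" | "n/a"
    preexisting: bool = False


@dataclass
class SyntheticPatient:
    patient_id: str
    cds: dict[str, str]  # transcript -> coding sequence (with stop)
    proteome: dict[str, str]  # transcript -> protein
    hla_class1: list[str]
    hla_drb: list[str]
    somatic_variants: list[SomaticVariant]
    germline_variants: list[GermlineVariant]
    expression: dict[str, float]
    truth: dict[str, TruthLabel] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> Path:
        d = Path(outdir) / self.patient_id
        d.mkdir(parents=True, exist_ok=True)
        io.write_fasta(self.cds, d / "cds.fasta")
        io.write_fasta(self.proteome, d / "protein.fasta")
        io.write_somatic_vcf(self.somatic_variants, self.cds, d / "somatic.vcf")
        io.write_germline_vcf(self.germline_variants, self.cds, d / "germline.vcf")
        io.write_expression_tsv(self.expression, d / "expression.tsv")
        io.write_hla_json(self.hla_class1, self.hla_drb, d / "hla.json")
        truth = {
            vid: {"immunogenic": t.immunogenic, "phenotype": t.phenotype,
                  "preexisting": t.preexisting}
            for vid, t in sorted(self.truth.items())
        }
        (d / "truth.json").write_text(json.dumps(truth, indent=1) + "\n")
        return d


def _random_cds(rng: np.random.Generator) -> str:
    n_mid = int(rng.integers(98, 999))  # total length 300..3000 nt incl. start/stop
    mid = "".join(rng.choice(_SENSE_CODONS, size=n_mid))
    return "ATG" + mid + "TAA"


def _pick_snv(rng: np.random.Generator, cds: str, cfg: CohortConfig):
    """Choose a single-nucleotide substitution with the desired consequence mix."""
    n_codons = len(cds) // 3
    codon_i = int(rng.integers(1, n_codons - 1))  # skip start and stop codons
    codon = cds[3 * codon_i : 3 * codon_i + 3]
    aa = translate_cds(codon, to_stop=False)
    options: dict[str, list[tuple[int, str]]] = {"synonymous": [], "nonsense": [], "missense": []}
    for off in range(3):
        for base in _BASES:
            if base == codon[off]:
                continue
            new = codon[:off] + base + codon[off + 1 :]
            if new in _STOPS:
                options["nonsense"].append((off, base))
            elif translate_cds(new, to_stop=False) == aa:
                options["synonymous"].append((off, base))
            else:
                options["missense"].append((off, base))
    u = rng.random()
    if u < cfg.frac_synonymous and options["synonymous"]:
        cat = "synonymous"
    elif u < cfg.frac_synonymous + cfg.frac_nonsense and options["nonsense"]:
        cat = "nonsense"
    else:
        cat = "missense" if options["missense"] else "synonymous"
    off, base = options[cat][int(rng.integers(len(options[cat])))]
    pos = 3 * codon_i + off + 1
    return pos, cds[pos - 1], base


def _pick_indel(rng: np.random.Generator, cds: str):
    """An anchored VCF-style indel: mostly frameshifts, some in-frame."""
    n_codons = len(cds) // 3
    lo, hi = 3 + 1, max(3 * (n_codons - 3), 8)  # keep clear of start/stop codons
    p = int(rng.integers(lo, hi))
    anchor = cds[p - 1]
    u = rng.random()
    if u < 0.4:  # 1-2 nt deletion
        d = int(rng.integers(1, 3))
        return p, cds[p - 1 : p + d], anchor
    if u < 0.8:  # 1-2 nt insertion
        ins = "".join(rng.choice(list(_BASES), size=int(rng.integers(1, 3))))
        return p, anchor, anchor + ins
    # in-frame: insert one sense codon
    codon = _SENSE_CODONS[int(rng.integers(len(_SENSE_CODONS)))]
    return p, anchor, anchor + codon


def _draw_vaf(rng: np.random.Generator, cfg: CohortConfig) -> tuple[float, float]:
    a, b = cfg.vaf_beta_params
    vaf_dna = float(rng.beta(a, b))
    vaf_rna = 0.0 if rng.random() < cfg.frac_rna_silent else float(rng.beta(a, b))
    return round(vaf_dna, 4), round(vaf_rna, 4)


def generate_patient(cfg: CohortConfig, index: int) -> SyntheticPatient:
    pid = f"P{index + 1:03d}"
    rng = substream(cfg.seed, "patient", index)

    cds = {f"{pid}_T{j + 1:03d}": _random_cds(rng) for j in range(cfg.n_proteins)}
    proteome = {t: translate_cds(s) for t, s in cds.items()}
    transcripts = sorted(cds)

    mu, sigma = cfg.rpkm_lognormal_params
    expression = {}
    for t in transcripts:
        if rng.random() < cfg.frac_unexpressed:
            expression[t] = 0.0
        else:
            expression[t] = round(float(rng.lognormal(mu, sigma)), 3)

    multiplier = float(rng.lognormal(0.0, cfg.rate_dispersion))
    n_snv = int(rng.poisson(cfg.snv_rate * multiplier))
    n_indel = int(rng.poisson(cfg.indel_rate * multiplier))

    somatic: list[SomaticVariant] = []
    used_sites: set[tuple[str, int]] = set()
    for k in range(n_snv + n_indel):
        is_snv = k < n_snv
        t = transcripts[int(rng.integers(len(transcripts)))]
        if is_snv:
            pos, ref_nt, alt_nt = _pick_snv(rng, cds[t], cfg)
        else:
            pos, ref_nt, alt_nt = _pick_indel(rng, cds[t])
        if (t, pos) in used_sites:
            continue
        used_sites.add((t, pos))
        vaf_dna, vaf_rna = _draw_vaf(rng, cfg)
        somatic.append(
            SomaticVariant(
                id=f"{pid}_V{len(somatic) + 1:03d}",
                kind="SNV" if is_snv else ("insertion" if len(alt_nt) > len(ref_nt) else "deletion"),
                transcript_id=t,
                cds_pos=pos,
                ref_nt=ref_nt,
                alt_nt=alt_nt,
                vaf_dna=vaf_dna,
                vaf_rna=vaf_rna,
                rpkm=expression[t],
            )
        )

    germline: list[GermlineVariant] = []
    for v in somatic:
        if rng.random() >= cfg.germline_rate:
            continue
        protein = proteome[v.transcript_id]
        approx_res = (v.cds_pos - 1) // 3 + 1
        lo = max(2, approx_res - 13)
        hi = min(len(protein), approx_res + 13)
        if hi <= lo:
            continue
        gpos = int(rng.integers(lo, hi + 1))
        ref_aa = protein[gpos - 1]
        changing = rng.random() < 0.8
        alt_aa = ref_aa
        if changing:
            choices = [a for a in _AA if a != ref_aa]
            alt_aa = choices[int(rng.integers(len(choices)))]
        in_phase = rng.random() < 0.6
        cis = int(3 + rng.poisson(8)) if in_phase else int(rng.poisson(0.3))
        trans = int(rng.poisson(0.3)) if in_phase else int(3 + rng.poisson(8))
        germline.append(
            GermlineVariant(
                id=f"{pid}_G{len(germline) + 1:03d}",
                transcript_id=v.transcript_id,
                protein_position=gpos,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
                is_protein_changing=changing and alt_aa != ref_aa,
                cis_reads=cis,
                trans_reads=trans,
                somatic_id=v.id,
                cds_pos=3 * (gpos - 1) + 1,
                ref_nt=cds[v.transcript_id][3 * (gpos - 1) : 3 * gpos],
                alt_nt=CODON_TABLE[alt_aa],
            )
        )

    idx1 = rng.choice(len(CLASS_I_POOL), size=6, replace=False)
    hla1 = sorted(CLASS_I_POOL[i] for i in idx1)
    ndrb = int(rng.integers(1, 3))
    idxd = rng.choice(len(DRB_POOL), size=ndrb, replace=False)
    drb = sorted(DRB_POOL[i] for i in idxd)

    truth = _assign_truth(rng, cfg, somatic, cds)

    return SyntheticPatient(
        patient_id=pid,
        cds=cds,
        proteome=proteome,
        hla_class1=hla1,
        hla_drb=drb,
        somatic_variants=somatic,
        germline_variants=germline,
        expression=expression,
        truth=truth,
    )


def _assign_truth(
    rng: np.random.Generator,
    cfg: CohortConfig,
    somatic: list[SomaticVariant],
    cds: dict[str, str],
) -> dict[str, TruthLabel]:
    """Plant immunogenicity truth on candidates that can reach the vaccine.

    Only variants with a peptide product, RNA VAF > 0 and expressed host
    transcripts are eligible for truth labels (a target no pipeline would
    select cannot be called immunogenic by any assay).
    """
    eligible = []
    for v in somatic:
        if v.vaf_rna <= 0 or v.rpkm < 1.0:
            continue
        if classify_variant(v, cds[v.transcript_id]) in (
            "missense", "frameshift", "inframe_indel",
        ):
            eligible.append(v.id)
    truth: dict[str, TruthLabel] = {}
    responder = rng.random() < cfg.responder_frac
    if responder and eligible and cfg.immunogenic_frac > 0:
        flags = rng.random(len(eligible)) < cfg.immunogenic_frac
        if not flags.any():
            flags[int(rng.integers(len(eligible)))] = True
        for vid, hit in zip(eligible, flags):
            if not hit:
                continue
            phenotype = ["CD4", "CD8", "both"][
                int(rng.choice(3, p=[0.35, 0.35, 0.3]))
            ]
            truth[vid] = TruthLabel(
                immunogenic=True,
                phenotype=phenotype,
                preexisting=bool(rng.random() < cfg.preexisting_frac),
            )
    return truth


def generate_cohort(config: CohortConfig) -> list[SyntheticPatient]:
    """Generate the full synthetic cohort (deterministic in (config, seed))."""
    return [generate_patient(config, i) for i in range(config.n_patients)]


def write_cohort(cohort: Sequence[SyntheticPatient], outdir: str | Path) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for p in cohort:
        p.write(out)
    return out


# ------------------------------------------------------------------ assays


@dataclass(frozen=True)
class AssayConfig:
    """Shapes and noise levels of the simulated downstream assays."""

    replicates: int = 3
    control_mean: float = 3.0
    signal_mean: float = 60.0
    preexisting_baseline_net: float = 25.0
    amplification_fold: float = 3.0
    positive_control_mean: float = 500.0
    noise: float = 1.0  # 0 disables sampling noise entirely
    read_depth: int = 20000
    n_background_clonotypes: int = 2000
    background_zipf_exponent: float = 1.1
    planted_cumulative_frequency: float | None = None
    preexisting_baseline_freq: float = 5e-4
    trafficking_frac: float = 0.8
    de_novo_frac: float | None = None  # override per-TCR status; else per-target
    tcr_per_target_rate: float = 1.0
    n_decoy_tcrs: int = 5
    jurkat_effectors_only: float = 800.0
    n_tumor_biopsies: int = 1


@dataclass(frozen=True)
class JurkatRow:
    tcr_id: str
    junction_aa: str
    specificity: str
    v_call: str
    j_call: str
    luminescence: float
    effectors_only: float


@dataclass(frozen=True)
class JurkatDataset:
    rows: tuple[JurkatRow, ...]


@dataclass(frozen=True)
class PlantedTcr:
    tcr_id: str
    junction_aa: str
    specificity: str
    de_novo: bool
    blood_frequency: float
    in_tumor: bool
    v_call: str = ""
    j_call: str = ""


@dataclass(frozen=True)
class PlantedAssayTruth:
    immunogenic_targets: tuple[str, ...]
    specific_tcrs: tuple[PlantedTcr, ...]

    @property
    def cumulative_blood_frequency(self) -> float:
        return sum(t.blood_frequency for t in self.specific_tcrs)


@dataclass(frozen=True)
class AssayBundle:
    elispot: list[ElispotMeasurement]
    repertoires: list[RepertoireSample]
    jurkat: JurkatDataset
    planted: PlantedAssayTruth


def _counts(rng, mean: float, n: int, noise: float) -> tuple[int, ...]:
    if noise <= 0:
        return tuple([int(round(mean))] * n)
    return tuple(int(c) for c in rng.poisson(mean, size=n))


def _random_cdr3(rng: np.random.Generator) -> str:
    mid = "".join(rng.choice(list(_AA), size=int(rng.integers(5, 11))))
    return "CASS" + mid + "F"


def generate_assay_data(
    patient: SyntheticPatient,
    selected_targets: Sequence[str],
    seed: int,
    config: AssayConfig | None = None,
) -> AssayBundle:
    """Simulate ELISpot, repertoire and Jurkat data for the selected targets.

    Immunogenic targets (per the patient's planted truth) receive
    post-induction spot counts at least two-fold above their baseline net
    counts; non-immunogenic targets stay at control level. Specific CDR3beta
    clonotypes are planted into the post-induction blood repertoire (absent
    at baseline when de novo) and a ``trafficking_frac`` subset into the
    tumor repertoire.
    """
    cfg = config or AssayConfig()
    known = {v.id for v in patient.somatic_variants}
    unknown = [t for t in selected_targets if t not in known]
    if unknown:
        raise InputError(f"targets not in patient {patient.patient_id}: {unknown}")
    rng = substream(seed, "assay", patient.patient_id)

    elispot = _simulate_elispot(patient, selected_targets, rng, cfg)
    planted = _plant_tcrs(patient, selected_targets, rng, cfg)
    repertoires = _simulate_repertoires(patient, planted, rng, cfg)
    jurkat = _simulate_jurkat(planted, selected_targets, rng, cfg)
    return AssayBundle(
        elispot=elispot, repertoires=repertoires, jurkat=jurkat, planted=planted
    )


def _simulate_elispot(patient, selected, rng, cfg) -> list[ElispotMeasurement]:
    out = []
    for target in selected:
        label = patient.truth.get(target)
        immunogenic = label.immunogenic if label else False
        preexisting = label.preexisting if label else False
        phenotype = label.phenotype if label else "n/a"
        for assay, compartments in (("ex_vivo", ["bulk"]), ("post_IVS", ["CD4", "CD8"])):
            for comp in compartments:
                in_comp = immunogenic and (
                    comp == "bulk"
                    or phenotype == "both"
                    or phenotype == comp
                )
                base_net = cfg.preexisting_baseline_net if (in_comp and preexisting) else 0.0
                post_net = 0.0
                if in_comp:
                    post_net = (
                        base_net * cfg.amplification_fold
                        if preexisting
                        else cfg.signal_mean
                    )
                for timepoint, net in (("baseline", base_net), ("post_induction", post_net)):
                    out.append(
                        ElispotMeasurement(
                            patient=patient.patient_id,
                            target_id=target,
                            timepoint=timepoint,
                            assay=assay,
                            compartment=comp,
                            stimulated=_counts(rng, cfg.control_mean + net, cfg.replicates, cfg.noise),
                            control=_counts(rng, cfg.control_mean, cfg.replicates, cfg.noise),
                            positive_control=_counts(rng, cfg.positive_control_mean, cfg.replicates, cfg.noise),
                        )
                    )
    return out


def _plant_tcrs(patient, selected, rng, cfg) -> PlantedAssayTruth:
    immunogenic = tuple(
        t for t in selected
        if t in patient.truth and patient.truth[t].immunogenic
    )
    tcrs: list[PlantedTcr] = []
    raw_freqs: list[float] = []
    for target in immunogenic:
        n_tcr = 1 + int(rng.poisson(cfg.tcr_per_target_rate))
        for _ in range(n_tcr):
            raw = float(np.exp(rng.normal(np.log(0.01), 1.0)))
            raw_freqs.append(raw)
            if cfg.de_novo_frac is not None:
                de_novo = bool(rng.random() < cfg.de_novo_frac)
            else:
                de_novo = not patient.truth[target].preexisting
            tcrs.append(
                PlantedTcr(
                    tcr_id=f"{patient.patient_id}_TCR{len(tcrs) + 1:03d}",
                    junction_aa=_random_cdr3(rng),
                    specificity=target,
                    de_novo=de_novo,
                    blood_frequency=raw,
                    in_tumor=bool(rng.random() < cfg.trafficking_frac),
                    v_call=f"TRBV{int(rng.integers(1, 30))}",
                    j_call=f"TRBJ{int(rng.integers(1, 3))}-{int(rng.integers(1, 7))}",
                )
            )
    total = sum(raw_freqs)
    if tcrs:
        target_total = (
            cfg.planted_cumulative_frequency
            if cfg.planted_cumulative_frequency is not None
            else min(total, 0.25)
        )
        scale = target_total / total
        tcrs = [replace(t, blood_frequency=round(t.blood_frequency * scale, 8)) for t in tcrs]
    return PlantedAssayTruth(immunogenic_targets=immunogenic, specific_tcrs=tuple(tcrs))


def _background_clonotypes(rng, cfg, exclude: set[str]) -> list[tuple[str, float, str, str]]:
    n = cfg.n_background_clonotypes
    weights = 1.0 / np.arange(1, n + 1) ** cfg.background_zipf_exponent
    weights /= weights.sum()
    out = []
    seen = set(exclude)
    while len(out) < n:
        j = _random_cdr3(rng)
        if j in seen:
            continue
        seen.add(j)
        v = f"TRBV{int(rng.integers(1, 30))}"
        jj = f"TRBJ{int(rng.integers(1, 3))}-{int(rng.integers(1, 7))}"
        out.append((j, float(weights[len(out)]), v, jj))
    return out


def _sample_repertoire(
    rng, cfg, patient_id, compartment, timepoint, specific_freqs, background, lesion=None
) -> RepertoireSample:
    spec_total = sum(f for _, f, _, _ in specific_freqs)
    bg_scale = max(1.0 - spec_total, 0.0)
    entries = list(specific_freqs) + [
        (j, w * bg_scale, v, jj) for (j, w, v, jj) in background
    ]
    probs = np.array([f for _, f, _, _ in entries])
    probs = probs / probs.sum()
    if cfg.noise <= 0:
        counts = np.round(probs * cfg.read_depth).astype(int)
    else:
        counts = rng.multinomial(cfg.read_depth, probs)
    clons = tuple(
        Clonotype(junction_aa=e[0], duplicate_count=int(c), v_call=e[2], j_call=e[3])
        for e, c in zip(entries, counts)
        if c > 0
    )
    return RepertoireSample(
        patient=patient_id, compartment=compartment, timepoint=timepoint,
        clonotypes=clons, lesion=lesion,
    )


def _simulate_repertoires(patient, planted, rng, cfg) -> list[RepertoireSample]:
    spec_junctions = {t.junction_aa for t in planted.specific_tcrs}
    background = _background_clonotypes(rng, cfg, spec_junctions)
    baseline_spec = [
        (t.junction_aa, cfg.preexisting_baseline_freq, t.v_call, t.j_call)
        for t in planted.specific_tcrs
        if not t.de_novo
    ]
    post_spec = [
        (t.junction_aa, t.blood_frequency, t.v_call, t.j_call)
        for t in planted.specific_tcrs
    ]
    tumor_spec = [
        (t.junction_aa, t.blood_frequency, t.v_call, t.j_call)
        for t in planted.specific_tcrs
        if t.in_tumor
    ]
    pid = patient.patient_id
    samples = [
        _sample_repertoire(rng, cfg, pid, "blood_CD8", 0, baseline_spec, background),
        _sample_repertoire(rng, cfg, pid, "blood_CD8", 43, post_spec, background),
    ]
    for b in range(cfg.n_tumor_biopsies):
        samples.append(
            _sample_repertoire(
                rng, cfg, pid, "tumor", 42, tumor_spec, background, lesion=f"L1.b{b + 1}"
            )
        )
    return samples


def _simulate_jurkat(planted, selected, rng, cfg) -> JurkatDataset:
    rows = []
    for t in planted.specific_tcrs:
        fold = 3.0 if cfg.noise <= 0 else float(rng.uniform(2.5, 8.0))
        rows.append(
            JurkatRow(
                tcr_id=t.tcr_id, junction_aa=t.junction_aa, specificity=t.specificity,
                v_call=t.v_call, j_call=t.j_call,
                luminescence=round(cfg.jurkat_effectors_only * fold, 1),
                effectors_only=cfg.jurkat_effectors_only,
            )
        )
    pool = list(selected) or ["none"]
    for k in range(cfg.n_decoy_tcrs):
        fold = 1.2 if cfg.noise <= 0 else float(rng.uniform(0.7, 1.7))
        rows.append(
            JurkatRow(
                tcr_id=f"decoy{k + 1:02d}", junction_aa=_random_cdr3(rng),
                specificity=pool[int(rng.integers(len(pool)))],
                v_call=f"TRBV{int(rng.integers(1, 30))}",
                j_call=f"TRBJ{int(rng.integers(1, 3))}-{int(rng.integers(1, 7))}",
                luminescence=round(cfg.jurkat_effectors_only * fold, 1),
                effectors_only=cfg.jurkat_effectors_only,
            )
        )
    return JurkatDataset(rows=tuple(rows))


# -------------------------------------------------- synthetic score sets


def make_saturating_candidates(
    seed: int = 0,
    n_indel: int = 12,
    n_snv_hi: int = 70,
    n_snv_lo: int = 70,
    n_snv_low_expr: int = 10,
    n_vaf0: int = 10,
) -> list[MutatedPeptideSequence]:
    """An oversubscribed annotated candidate set for exercising the tier caps.

    Every tier has more eligible candidates than its cap: indels, SNVs with
    >= 10 RPKM, additional SNVs with >= 1 RPKM, low-expression SNVs for the
    expression fill, and RNA-silent candidates for the backfill.
    """
    rng = substream(seed, "saturating")

    def mk(i: int, kind: str, rpkm: float, vaf_rna: float) -> MutatedPeptideSequence:
        seq = "".join(rng.choice(list(_AA), size=27))
        return MutatedPeptideSequence(
            variant_id=f"c{i:03d}",
            sequence=seq,
            mutated_span=(14, 14),
            source_kind=kind,
            rpkm=round(rpkm, 3),
            vaf_rna=round(vaf_rna, 4),
            vaf_dna=round(float(rng.beta(2, 5)), 4),
            best_class1_rank=round(float(rng.uniform(0, 100)), 3),
            best_class2_rank=round(float(rng.uniform(0, 100)), 3),
        )

    out = []
    i = 0
    for _ in range(n_indel):
        out.append(mk(i, "indel", float(rng.uniform(1, 50)), float(rng.uniform(0.05, 0.6)))); i += 1
    for _ in range(n_snv_hi):
        out.append(mk(i, "SNV", float(rng.uniform(10, 200)), float(rng.uniform(0.05, 0.6)))); i += 1
    for _ in range(n_snv_lo):
        out.append(mk(i, "SNV", float(rng.uniform(1, 10)), float(rng.uniform(0.05, 0.6)))); i += 1
    for _ in range(n_snv_low_expr):
        out.append(mk(i, "SNV", float(rng.uniform(0.1, 1)), float(rng.uniform(0.05, 0.6)))); i += 1
    for _ in range(n_vaf0):
        out.append(mk(i, "SNV", float(rng.uniform(1, 50)), 0.0)); i += 1
    return out
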