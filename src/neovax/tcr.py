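"""Tracking neoantigen-specific TCR clonotypes in bulk repertoires.

Validated specific TCRs (Jurkat NFAT-reporter fold change >= 2 versus the
effectors-only control) are tracked in bulk blood and tumor repertoires by
exact CDR3beta amino-acid match (plus V/J gene match when both sides carry
gene calls). The analytics mirror the trial's monitoring readouts: cumulative
frequency of specific clonotypes per compartment, per-neoantigen breakdowns,
de novo versus preexisting status against the baseline repertoire, and
overlap of detected specific TCRs between biopsies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .errors import AssayError, InputError

JURKAT_FOLD_CUTOFF = 2.0


@dataclass(frozen=True)
class Clonotype:
    junction_aa: str
    duplicate_count: int
    v_call: str | None = None
    j_call: str | None = None

    def __post_init__(self) -> None:
        if self.duplicate_count < 1:
            raise InputError("clonotype counts must be >= 1")


@dataclass(frozen=True)
class RepertoireSample:
    """A bulk TCR repertoire from one compartment at one timepoint (days)."""

    patient: str
    compartment: str  # "blood_CD8" | "blood_CD4" | "tumor"
    timepoint: int
    clonotypes: tuple[Clonotype, ...]
    lesion: str | None = None

    def __post_init__(self) -> None:
        if not self.clonotypes:
            raise InputError("repertoire sample must be non-empty")

    @property
    def total_reads(self) -> int:
        return sum(c.duplicate_count for c in self.clonotypes)

    def frequency_of(self, clonotype: Clonotype) -> float:
        return clonotype.duplicate_count / self.total_reads


@dataclass(frozen=True)
class SpecificTcr:
    """A cloned TCR with validated neoantigen specificity."""

    tcr_id: str
    junction_aa: str
    specificity: str  # neoantigen (variant) id
    fold_change: float
    validated: bool
    hla_restriction: str | None = None
    v_call: str | None = None
    j_call: str | None = None

    def __post_init__(self) -> None:
        if self.validated and self.fold_change < JURKAT_FOLD_CUTOFF:
            raise InputError(
                f"TCR {self.tcr_id}: validated requires fold >= {JURKAT_FOLD_CUTOFF}"
            )


def jurkat_specificity_call(
    luminescence: float, effectors_only: float, cutoff: float = JURKAT_FOLD_CUTOFF
) -> tuple[float, bool]:
    """Reporter fold change vs the effectors-only control; specific iff >= 2."""
    if effectors_only <= 0:
        raise AssayError("non-positive effectors-only control")
    fold = luminescence / effectors_only
    return fold, fold >= cutoff


@dataclass(frozen=True)
class TrackedMatch:
    tcr: SpecificTcr
    count: int
    frequency: float
    clonotype: Clonotype | None = None


def _matches(tcr: SpecificTcr, c: Clonotype) -> bool:
    if tcr.junction_aa != c.junction_aa:
        return False
    if tcr.v_call and c.v_call and tcr.v_call != c.v_call:
        return False
    if tcr.j_call and c.j_call and tcr.j_call != c.j_call:
        return False
    return True


def track(
    specific: Sequence[SpecificTcr], sample: RepertoireSample
) -> list[TrackedMatch]:
    """Locate each specific TCR in the repertoire; absent TCRs get frequency 0.

    Matching is an exact CDR3beta amino-acid join, with V/J genes required to
    agree when both the TCR and the clonotype carry calls. Multiple matching
    clonotypes (same junction, different V/J) are summed.
    """
    total = sample.total_reads
    by_junction: dict[str, list[Clonotype]] = {}
    for c in sample.clonotypes:
        by_junction.setdefault(c.junction_aa, []).append(c)
    out = []
    for tcr in specific:
        hits = [c for c in by_junction.get(tcr.junction_aa, ()) if _matches(tcr, c)]
        count = sum(c.duplicate_count for c in hits)
        out.append(
            TrackedMatch(
                tcr=tcr,
                count=count,
                frequency=count / total if total else 0.0,
                clonotype=hits[0] if hits else None,
            )
        )
    return out


@dataclass(frozen=True)
class CumulativeFrequency:
    total: float
    per_specificity: tuple[tuple[str, float], ...]
    n_tcrs_detected: int
    n_neoantigens_detected: int


def cumulative_frequency(
    specific: Sequence[SpecificTcr], sample: RepertoireSample
) -> CumulativeFrequency:
    """Cumulative repertoire share of specific clonotypes, by neoantigen.

    The total sums each matched clonotype once even if several specific TCRs
    share a junction, so it never exceeds 1; per-specificity totals sum the
    tracked frequencies of that neoantigen's TCRs.
    """
    matches = track(specific, sample)
    seen_junctions: set[str] = set()
    total = 0.0
    per_spec: dict[str, float] = {}
    detected = 0
    for m in matches:
        if m.count == 0:
            continue
        detected += 1
        per_spec[m.tcr.specificity] = per_spec.get(m.tcr.specificity, 0.0) + m.frequency
        key = m.tcr.junction_aa
        if key not in seen_junctions:
            seen_junctions.add(key)
            total += m.frequency
    return CumulativeFrequency(
        total=total,
        per_specificity=tuple(sorted(per_spec.items())),
        n_tcrs_detected=detected,
        n_neoantigens_detected=len(per_spec),
    )


def classify_baseline_status(
    specific: Sequence[SpecificTcr],
    baseline: RepertoireSample | None,
    detection_threshold: int = 0,
) -> dict[str, str]:
    """Per-TCR de novo / preexisting status against the baseline repertoire.

    A TCR is de novo when its baseline read count is at or below
    ``detection_threshold`` (default: undetectable means zero reads). With no
    baseline sample every status is "unknown".
    """
    if baseline is None:
        return {t.tcr_id: "unknown" for t in specific}
    out = {}
    for m in track(specific, baseline):
        out[m.tcr.tcr_id] = (
            "de_novo" if m.count <= detection_threshold else "preexisting"
        )
    return out


@dataclass(frozen=True)
class OverlapSummary:
    shared: tuple[str, ...]  # tcr_ids detected in both samples
    only_a: tuple[str, ...]
    only_b: tuple[str, ...]
    jaccard: float


def biopsy_overlap(
    sample_a: RepertoireSample,
    sample_b: RepertoireSample,
    specific: Sequence[SpecificTcr],
) -> OverlapSummary:
    """Overlap of detected specific TCRs between two samples (e.g. biopsies).

    Jaccard index over the detected-TCR sets; two samples detecting nothing
    are treated as identical (Jaccard 1).
    """
    a = {m.tcr.tcr_id for m in track(specific, sample_a) if m.count > 0}
    b = {m.tcr.tcr_id for m in track(specific, sample_b) if m.count > 0}
    union = a | b
    jac = len(a & b) / len(union) if union else 1.0
    return OverlapSummary(
        shared=tuple(sorted(a & b)),
        only_a=tuple(sorted(a - b)),
        only_b=tuple(sorted(b - a)),
        jaccard=jac,
    )
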