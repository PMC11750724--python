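"""Mutated peptide sequence (MPS) extraction.

The first bespoke stage of the vaccine-design pipeline: somatic variants are
turned into the peptide windows that all downstream scoring, prioritization and
construct assembly operate on.

* For amino-acid substitutions (SNVs and multi-nucleotide clusters) the MPS is
  the window of 13 residues N-terminal and 13 residues C-terminal of the
  changed residue(s), truncated at the protein ends.
* For frameshift indels the MPS is the novel reading frame translated from the
  first changed residue up to (exclusive) the next stop codon, prefixed by up
  to 13 wild-type residues for context.
* In-frame indels get a 13 + altered-region + 13 window.

Protein-changing germline variants that lie inside the window and are in phase
with the somatic mutation (by RNA read evidence) are substituted into the MPS,
so the vaccine target matches the peptide the tumour actually expresses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from Bio.Seq import Seq

from .errors import InputError, ReferenceMismatchError

SNV_FLANK = 13  # residues kept on each side of the changed residue(s)

STOP = "*"


@dataclass(frozen=True)
class SomaticVariant:
    """One somatic SNV/indel call with expression and allele-frequency context.

    Coordinates are transcript-space: ``cds_pos`` is the 1-based position of
    the first reference base of the edit within the coding sequence (VCF
    convention: ``ref_nt`` is replaced by ``alt_nt``). ``protein_position`` is
    the 1-based index of the first changed residue; for indels it is derived
    from the CDS edit.
    """

    id: str
    kind: str  # "SNV" | "insertion" | "deletion"
    transcript_id: str
    cds_pos: int
    ref_nt: str
    alt_nt: str
    vaf_dna: float
    vaf_rna: float
    rpkm: float = 0.0
    protein_position: int | None = None
    ref_aa: str = ""
    alt_aa: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf_dna <= 1.0 or not 0.0 <= self.vaf_rna <= 1.0:
            raise InputError(f"variant {self.id}: VAF outside [0,1]")
        if self.cds_pos < 1:
            raise InputError(f"variant {self.id}: cds_pos must be >= 1")

    @property
    def is_indel(self) -> bool:
        return len(self.ref_nt) != len(self.alt_nt)

    @property
    def is_frameshift(self) -> bool:
        return (len(self.alt_nt) - len(self.ref_nt)) % 3 != 0


@dataclass(frozen=True)
class GermlineVariant:
    """A germline substitution near a somatic variant, with phase evidence.

    ``cis_reads``/``trans_reads`` count RNA reads placing the germline allele
    on the same / the opposite haplotype as the named somatic variant.
    """

    id: str
    transcript_id: str
    protein_position: int
    ref_aa: str
    alt_aa: str
    is_protein_changing: bool
    cis_reads: int
    trans_reads: int
    somatic_id: str = ""
    cds_pos: int | None = None
    ref_nt: str = ""
    alt_nt: str = ""

    def __post_init__(self) -> None:
        if self.cis_reads < 0 or self.trans_reads < 0:
            raise InputError(f"germline {self.id}: negative read counts")


@dataclass(frozen=True)
class MutatedPeptideSequence:
    """A mutated peptide window: the unit of prioritization and selection.

    ``mutated_span`` is 1-based inclusive within ``sequence``.
    ``protein_window_start`` is the protein coordinate of ``sequence[0]``
    (valid for the wild-type portion of the window; used to map germline
    variants into the window).
    """

    variant_id: str
    sequence: str
    mutated_span: tuple[int, int]
    source_kind: str  # "SNV" | "indel"
    transcript_id: str = ""
    protein_window_start: int = 1
    incorporated_germline: tuple[str, ...] = ()
    rpkm: float = 0.0
    vaf_rna: float = 0.0
    vaf_dna: float = 0.0
    best_class1_rank: float | None = None
    best_class2_rank: float | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        a, b = self.mutated_span
        if self.sequence:
            if not (1 <= a <= b <= len(self.sequence)):
                raise InputError(
                    f"MPS {self.variant_id}: mutated_span {self.mutated_span} "
                    f"outside sequence of length {len(self.sequence)}"
                )
        if STOP in self.sequence:
            raise InputError(f"MPS {self.variant_id}: sequence contains a stop symbol")


@dataclass(frozen=True)
class CandidateRecord:
    """An MPS candidate or the reason it could not become one."""

    variant: SomaticVariant
    mps: MutatedPeptideSequence | None = None
    drop_reason: str | None = None


def translate_cds(cds: str, *, to_stop: bool = True) -> str:
    """Translate a CDS with the standard table; stops excluded when to_stop."""
    seq = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
    if to_stop:
        stop = seq.find(STOP)
        if stop != -1:
            seq = seq[:stop]
    return seq


def apply_cds_edit(cds: str, variant: SomaticVariant) -> str:
    """Apply a VCF-style edit (ref_nt -> alt_nt at cds_pos) to the CDS."""
    p = variant.cds_pos - 1
    if cds[p : p + len(variant.ref_nt)] != variant.ref_nt:
        raise ReferenceMismatchError(
            f"variant {variant.id}: CDS at {variant.cds_pos} is "
            f"{cds[p : p + len(variant.ref_nt)]!r}, expected {variant.ref_nt!r}"
        )
    return cds[:p] + variant.alt_nt + cds[p + len(variant.ref_nt) :]


def classify_variant(variant: SomaticVariant, cds: str) -> str:
    """Classify the protein-level consequence of a variant against its CDS.

    Returns one of ``missense``, ``synonymous``, ``nonsense``, ``stop_loss``,
    ``start_loss``, ``frameshift``, ``inframe_indel``, ``null_neo_orf``.
    """
    wt = translate_cds(cds)
    mut_cds = apply_cds_edit(cds, variant)
    mut = translate_cds(mut_cds)
    if variant.is_frameshift:
        first = _first_difference(wt, mut)
        if first is None or first >= len(mut):
            return "null_neo_orf"
        return "frameshift"
    if variant.is_indel:
        return "inframe_indel"
    # SNV
    if mut == wt:
        return "synonymous"
    if len(mut) < len(wt):
        # translation hit an early stop
        return "nonsense"
    if len(mut) > len(wt):
        return "stop_loss"
    if mut[0] != "M" and wt[0] == "M" and variant.cds_pos <= 3:
        return "start_loss"
    return "missense"


def _first_difference(a: str, b: str) -> int | None:
    """0-based index of the first differing position, or None if b extends/equals a."""
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    if len(a) != len(b):
        return n
    return None


def extract_mps_snv(
    variant: SomaticVariant, protein: str, flank: int = SNV_FLANK
) -> MutatedPeptideSequence:
    """Extract the substitution window MPS for an SNV / MNV.

    The window covers ``flank`` residues on each side of the changed
    residue(s), truncated at the protein termini; the substituted residues sit
    at ``mutated_span``.
    """
    if variant.protein_position is None or not variant.alt_aa:
        raise InputError(f"variant {variant.id}: protein-level edit not annotated")
    pos = variant.protein_position
    ref, alt = variant.ref_aa, variant.alt_aa
    if len(ref) != len(alt):
        raise InputError(f"variant {variant.id}: not a substitution")
    if not 1 <= pos <= len(protein) - len(ref) + 1:
        raise InputError(f"variant {variant.id}: position {pos} outside protein")
    if protein[pos - 1 : pos - 1 + len(ref)] != ref:
        raise ReferenceMismatchError(
            f"variant {variant.id}: protein has "
            f"{protein[pos - 1 : pos - 1 + len(ref)]!r} at {pos}, expected {ref!r}"
        )
    if STOP in alt:
        raise InputError(f"variant {variant.id}: nonsense substitution has no MPS")
    start = max(1, pos - flank)
    end = min(len(protein), pos + len(ref) - 1 + flank)
    seq = protein[start - 1 : pos - 1] + alt + protein[pos + len(ref) - 1 : end]
    span = (pos - start + 1, pos - start + len(alt))
    return MutatedPeptideSequence(
        variant_id=variant.id,
        sequence=seq,
        mutated_span=span,
        source_kind="SNV",
        transcript_id=variant.transcript_id,
        protein_window_start=start,
        rpkm=variant.rpkm,
        vaf_rna=variant.vaf_rna,
        vaf_dna=variant.vaf_dna,
    )


def extract_mps_frameshift(
    variant: SomaticVariant, cds: str, flank: int = SNV_FLANK
) -> MutatedPeptideSequence:
    """Extract the neo-ORF MPS for a frameshift or in-frame indel.

    Frameshift: the novel frame from the first changed residue until the next
    stop codon (exclusive), prefixed by up to ``flank`` wild-type residues.
    No downstream stop before the CDS end is flagged ``readthrough`` and the
    sequence is truncated there. In-frame indels are treated as short indels
    with a ``flank`` + altered-region + ``flank`` window.

    Raises :class:`InputError` (reason "null neo-ORF") when the first novel
    codon is already a stop.
    """
    if not variant.is_indel:
        raise InputError(f"variant {variant.id}: not an indel")
    wt = translate_cds(cds)
    mut_cds = apply_cds_edit(cds, variant)

    if variant.is_frameshift:
        mut_full = str(Seq(mut_cds[: len(mut_cds) - len(mut_cds) % 3]).translate())
        stop_idx = mut_full.find(STOP)
        readthrough = stop_idx == -1
        mut = mut_full if readthrough else mut_full[:stop_idx]
        first = _first_difference(wt, mut)
        if first is None or first >= len(mut):
            raise InputError(f"variant {variant.id}: null neo-ORF")
        novel = mut[first:]
        prefix_start = max(0, first - flank)
        prefix = wt[prefix_start:first]
        seq = prefix + novel
        flags = ("readthrough",) if readthrough else ()
        if readthrough:
            warnings.warn(
                f"variant {variant.id}: no stop codon before CDS end; "
                "neo-ORF truncated (readthrough)",
                stacklevel=2,
            )
        return MutatedPeptideSequence(
            variant_id=variant.id,
            sequence=seq,
            mutated_span=(len(prefix) + 1, len(seq)),
            source_kind="indel",
            transcript_id=variant.transcript_id,
            protein_window_start=prefix_start + 1,
            rpkm=variant.rpkm,
            vaf_rna=variant.vaf_rna,
            vaf_dna=variant.vaf_dna,
            flags=flags,
        )

    # in-frame indel: diff from both ends to find the altered region
    mut = translate_cds(mut_cds)
    i = 0
    while i < min(len(wt), len(mut)) and wt[i] == mut[i]:
        i += 1
    j_wt, j_mut = len(wt), len(mut)
    while j_wt > i and j_mut > i and wt[j_wt - 1] == mut[j_mut - 1]:
        j_wt -= 1
        j_mut -= 1
    if j_mut == i:
        # clean deletion with an unchanged junction: keep one flanking residue
        # so enumeration windows still straddle the junction
        i = max(0, i - 1)
        j_mut = min(len(mut), i + 1)
    start = max(0, i - flank)
    end = min(len(mut), j_mut + flank)
    seq = mut[start:end]
    return MutatedPeptideSequence(
        variant_id=variant.id,
        sequence=seq,
        mutated_span=(i - start + 1, j_mut - start),
        source_kind="indel",
        transcript_id=variant.transcript_id,
        protein_window_start=start + 1,
        rpkm=variant.rpkm,
        vaf_rna=variant.vaf_rna,
        vaf_dna=variant.vaf_dna,
    )


def phase_and_incorporate(
    mps: MutatedPeptideSequence,
    germline: list[GermlineVariant],
    min_phase_reads: int = 2,
    phase_fraction: float = 0.8,
) -> MutatedPeptideSequence:
    """Substitute in-phase protein-changing germline variants into the MPS.

    A germline variant is in phase when ``cis_reads >= min_phase_reads`` and
    ``cis / (cis + trans) >= phase_fraction``. Variants colliding with the
    somatic span are skipped (somatic wins). For indel MPS only the wild-type
    prefix (before the mutated span) is eligible, since coordinates downstream
    of the indel no longer map to the reference protein.
    """
    seq = list(mps.sequence)
    incorporated = list(mps.incorporated_germline)
    span_a, span_b = mps.mutated_span
    for g in sorted(germline, key=lambda g: g.protein_position):
        if not g.is_protein_changing:
            continue
        total = g.cis_reads + g.trans_reads
        if g.cis_reads < min_phase_reads or total == 0:
            continue
        if g.cis_reads / total < phase_fraction:
            continue
        offset = g.protein_position - mps.protein_window_start + 1  # 1-based in window
        if offset < 1 or offset > len(seq):
            continue
        if mps.source_kind == "indel" and offset >= span_a:
            continue
        if span_a <= offset <= span_b:
            warnings.warn(
                f"germline {g.id} collides with somatic span of {mps.variant_id}; "
                "somatic edit wins",
                stacklevel=2,
            )
            continue
        if len(g.alt_aa) != 1 or len(g.ref_aa) != 1 or g.alt_aa == STOP:
            continue
        if seq[offset - 1] != g.ref_aa:
            warnings.warn(
                f"germline {g.id}: window residue {seq[offset - 1]!r} does not "
                f"match ref {g.ref_aa!r}; skipped",
                stacklevel=2,
            )
            continue
        seq[offset - 1] = g.alt_aa
        incorporated.append(g.id)
    return replace(
        mps, sequence="".join(seq), incorporated_germline=tuple(incorporated)
    )


def filter_candidates(
    candidates: list[CandidateRecord], expressed_min: float = 0.1
) -> tuple[list[CandidateRecord], list[CandidateRecord]]:
    """Partition candidates into (kept, dropped-with-reasons).

    Drops records whose consequence precluded an MPS (synonymous, nonsense,
    stop/start-loss, null neo-ORF) and candidates on non-expressed transcripts
    (RPKM below ``expressed_min``). Every drop carries a machine-readable
    reason; kept + dropped is always a permutation of the input.
    """
    kept: list[CandidateRecord] = []
    dropped: list[CandidateRecord] = []
    for rec in candidates:
        if rec.drop_reason is not None or rec.mps is None:
            dropped.append(
                replace(rec, drop_reason=rec.drop_reason or "no-mps")
            )
        elif rec.variant.rpkm < expressed_min:
            dropped.append(replace(rec, drop_reason="non-expressed"))
        else:
            kept.append(rec)
    return kept, dropped


_CONSEQUENCE_DROP_REASONS = {
    "synonymous": "synonymous",
    "nonsense": "nonsense",
    "stop_loss": "stop-loss",
    "start_loss": "start-loss",
    "null_neo_orf": "null neo-ORF",
}


def build_candidate(
    variant: SomaticVariant,
    cds: str,
    germline: list[GermlineVariant] | None = None,
    min_phase_reads: int = 2,
    phase_fraction: float = 0.8,
) -> CandidateRecord:
    """Classify a variant, extract its MPS and phase in germline context.

    Consequences with no peptide product yield a record with a drop reason
    instead of an MPS; :func:`filter_candidates` removes them downstream.
    """
    consequence = classify_variant(variant, cds)
    if consequence in _CONSEQUENCE_DROP_REASONS:
        return CandidateRecord(
            variant=variant, drop_reason=_CONSEQUENCE_DROP_REASONS[consequence]
        )
    wt = translate_cds(cds)
    if consequence == "missense":
        annotated = _annotate_protein_edit(variant, cds, wt)
        mps = extract_mps_snv(annotated, wt)
    else:
        mps = extract_mps_frameshift(variant, cds)
    if germline:
        near = [g for g in germline if g.somatic_id in ("", variant.id)]
        mps = phase_and_incorporate(
            mps, near, min_phase_reads=min_phase_reads, phase_fraction=phase_fraction
        )
    return CandidateRecord(variant=variant, mps=mps)


def _annotate_protein_edit(
    variant: SomaticVariant, cds: str, wt: str
) -> SomaticVariant:
    """Fill protein_position / ref_aa / alt_aa for a substitution from the CDS."""
    if variant.protein_position is not None and variant.alt_aa:
        return variant
    mut = translate_cds(apply_cds_edit(cds, variant))
    first = _first_difference(wt, mut)
    if first is None:
        raise InputError(f"variant {variant.id}: no protein change to annotate")
    last = first
    for k in range(min(len(wt), len(mut)) - 1, first - 1, -1):
        if wt[k] != mut[k]:
            last = k
            break
    return replace(
        variant,
        protein_position=first + 1,
        ref_aa=wt[first : last + 1],
        alt_aa=mut[first : last + 1],
    )
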