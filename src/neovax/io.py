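"""File formats: FASTA, VCF 4.2, and the pipeline's TSV/JSON tables.

Variants live in transcript space: the VCF CHROM is the transcript id and POS
the 1-based coordinate within the coding sequence, so a patient bundle is
fully self-contained (CDS FASTA + VCFs + expression TSV + HLA JSON). FASTA
goes through Biopython, VCF reading through cyvcf2, tables through pandas.
All writers are deterministic: fixed column orders and float formats, sorted
records.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .errors import ParseError
from .immunogenicity import ElispotMeasurement
from .mps import GermlineVariant, SomaticVariant
from .tcr import Clonotype, RepertoireSample

FLOAT_FMT = "%.6g"


# ---------------------------------------------------------------- FASTA

def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    try:
        return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
    except Exception as exc:  # pragma: no cover - biopython error text varies
        raise ParseError(f"cannot parse FASTA {path}: {exc}") from exc


# ---------------------------------------------------------------- VCF

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=neovax
{contigs}{info}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""

_SOMATIC_INFO = (
    '##INFO=<ID=VAF_DNA,Number=1,Type=Float,Description="Tumor DNA variant allele frequency">\n'
    '##INFO=<ID=VAF_RNA,Number=1,Type=Float,Description="Tumor RNA variant allele frequency">\n'
    '##INFO=<ID=TRANSCRIPT,Number=1,Type=String,Description="Host transcript">\n'
    '##INFO=<ID=PROT_POS,Number=1,Type=Integer,Description="1-based first changed residue">\n'
)

_GERMLINE_INFO = (
    '##INFO=<ID=TRANSCRIPT,Number=1,Type=String,Description="Host transcript">\n'
    '##INFO=<ID=PROT_POS,Number=1,Type=Integer,Description="1-based residue position">\n'
    '##INFO=<ID=REF_AA,Number=1,Type=String,Description="Reference residue">\n'
    '##INFO=<ID=ALT_AA,Number=1,Type=String,Description="Alternate residue">\n'
    '##INFO=<ID=PROT_CHANGING,Number=1,Type=Integer,Description="1 if protein-changing">\n'
    '##INFO=<ID=CIS_READS,Number=1,Type=Integer,Description="RNA reads in cis with the somatic variant">\n'
    '##INFO=<ID=TRANS_READS,Number=1,Type=Integer,Description="RNA reads in trans with the somatic variant">\n'
    '##INFO=<ID=SOMATIC_ID,Number=1,Type=String,Description="Paired somatic variant id">\n'
)


def _contig_lines(cds: Mapping[str, str]) -> str:
    return "".join(
        f"##contig=<ID={name},length={len(seq)}>\n" for name, seq in sorted(cds.items())
    )


def write_somatic_vcf(
    variants: Sequence[SomaticVariant], cds: Mapping[str, str], path: str | Path
) -> None:
    lines = [_VCF_HEADER.format(contigs=_contig_lines(cds), info=_SOMATIC_INFO)]
    for v in sorted(variants, key=lambda v: (v.transcript_id, v.cds_pos, v.id)):
        info = (
            f"VAF_DNA={FLOAT_FMT % v.vaf_dna};VAF_RNA={FLOAT_FMT % v.vaf_rna};"
            f"TRANSCRIPT={v.transcript_id}"
        )
        if v.protein_position is not None:
            info += f";PROT_POS={v.protein_position}"
        lines.append(
            f"{v.transcript_id}\t{v.cds_pos}\t{v.id}\t{v.ref_nt}\t{v.alt_nt}"
            f"\t.\tPASS\t{info}\n"
        )
    Path(path).write_text("".join(lines))


def read_somatic_vcf(
    path: str | Path, expression: Mapping[str, float] | None = None
) -> list[SomaticVariant]:
    expression = expression or {}
    out = []
    try:
        for rec in VCF(str(path)):
            tid = rec.CHROM
            out.append(
                SomaticVariant(
                    id=rec.ID or f"{tid}:{rec.POS}",
                    kind=_variant_kind(rec.REF, rec.ALT[0]),
                    transcript_id=tid,
                    cds_pos=rec.POS,
                    ref_nt=rec.REF,
                    alt_nt=rec.ALT[0],
                    vaf_dna=round(float(rec.INFO.get("VAF_DNA", 0.0)), 6),
                    vaf_rna=round(float(rec.INFO.get("VAF_RNA", 0.0)), 6),
                    rpkm=float(expression.get(tid, 0.0)),
                    protein_position=(
                        int(rec.INFO["PROT_POS"]) if rec.INFO.get("PROT_POS") else None
                    ),
                )
            )
    except ParseError:
        raise
    except Exception as exc:
        raise ParseError(f"cannot parse VCF {path}: {exc}") from exc
    return out


def _variant_kind(ref: str, alt: str) -> str:
    if len(ref) == len(alt):
        return "SNV"
    return "insertion" if len(alt) > len(ref) else "deletion"


def write_germline_vcf(
    germline: Sequence[GermlineVariant], cds: Mapping[str, str], path: str | Path
) -> None:
    lines = [_VCF_HEADER.format(contigs=_contig_lines(cds), info=_GERMLINE_INFO)]
    for g in sorted(germline, key=lambda g: (g.transcript_id, g.protein_position, g.id)):
        pos = g.cds_pos if g.cds_pos else 3 * g.protein_position - 2
        ref_nt = g.ref_nt or "N"
        alt_nt = g.alt_nt or "N"
        info = (
            f"TRANSCRIPT={g.transcript_id};PROT_POS={g.protein_position};"
            f"REF_AA={g.ref_aa};ALT_AA={g.alt_aa};"
            f"PROT_CHANGING={int(g.is_protein_changing)};"
            f"CIS_READS={g.cis_reads};TRANS_READS={g.trans_reads};"
            f"SOMATIC_ID={g.somatic_id or '.'}"
        )
        lines.append(
            f"{g.transcript_id}\t{pos}\t{g.id}\t{ref_nt}\t{alt_nt}\t.\tPASS\t{info}\n"
        )
    Path(path).write_text("".join(lines))


def read_germline_vcf(path: str | Path) -> list[GermlineVariant]:
    out = []
    try:
        for rec in VCF(str(path)):
            somatic = rec.INFO.get("SOMATIC_ID") or ""
            out.append(
                GermlineVariant(
                    id=rec.ID or f"{rec.CHROM}:{rec.POS}",
                    transcript_id=rec.CHROM,
                    protein_position=int(rec.INFO["PROT_POS"]),
                    ref_aa=str(rec.INFO.get("REF_AA", "")),
                    alt_aa=str(rec.INFO.get("ALT_AA", "")),
                    is_protein_changing=bool(int(rec.INFO.get("PROT_CHANGING", 1))),
                    cis_reads=int(rec.INFO.get("CIS_READS", 0)),
                    trans_reads=int(rec.INFO.get("TRANS_READS", 0)),
                    somatic_id="" if somatic == "." else somatic,
                    cds_pos=rec.POS,
                    ref_nt=rec.REF,
                    alt_nt=rec.ALT[0],
                )
            )
    except Exception as exc:
        raise ParseError(f"cannot parse VCF {path}: {exc}") from exc
    return out


# ---------------------------------------------------------------- tables

def write_expression_tsv(expression: Mapping[str, float], path: str | Path) -> None:
    df = pd.DataFrame(
        sorted(expression.items()), columns=["transcript_id", "rpkm"]
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_expression_tsv(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    if not {"transcript_id", "rpkm"} <= set(df.columns):
        raise ParseError(f"{path}: expected columns transcript_id, rpkm")
    return dict(zip(df["transcript_id"], df["rpkm"].astype(float)))


def write_hla_json(
    class1: Sequence[str], drb: Sequence[str], path: str | Path
) -> None:
    Path(path).write_text(
        json.dumps({"class1": list(class1), "drb": list(drb)}, indent=1) + "\n"
    )


def read_hla_json(path: str | Path) -> tuple[list[str], list[str]]:
    data = json.loads(Path(path).read_text())
    return list(data["class1"]), list(data["drb"])


ELISPOT_COLUMNS = [
    "patient", "target_id", "timepoint", "assay", "compartment",
    "condition", "replicate", "spots",
]


def write_elispot_tsv(
    measurements: Sequence[ElispotMeasurement], path: str | Path
) -> None:
    rows = []
    for m in measurements:
        for cond, counts in (
            ("stimulated", m.stimulated),
            ("control", m.control),
            ("positive_control", m.positive_control or ()),
        ):
            for i, spots in enumerate(counts, start=1):
                rows.append(
                    (m.patient, m.target_id, m.timepoint, m.assay, m.compartment,
                     cond, i, spots)
                )
    pd.DataFrame(rows, columns=ELISPOT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_elispot_tsv(path: str | Path) -> list[ElispotMeasurement]:
    df = pd.read_csv(path, sep="\t")
    missing = set(ELISPOT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    out = []
    keys = ["patient", "target_id", "timepoint", "assay", "compartment"]
    for key, grp in df.groupby(keys, sort=True):
        counts = {
            cond: tuple(int(s) for s in sub.sort_values("replicate")["spots"])
            for cond, sub in grp.groupby("condition")
        }
        out.append(
            ElispotMeasurement(
                patient=key[0], target_id=key[1], timepoint=key[2],
                assay=key[3], compartment=key[4],
                stimulated=counts.get("stimulated", ()),
                control=counts.get("control", ()),
                positive_control=counts.get("positive_control") or None,
            )
        )
    return out


REPERTOIRE_COLUMNS = [
    "patient", "compartment", "timepoint", "lesion",
    "junction_aa", "v_call", "j_call", "duplicate_count",
]


def write_repertoire_tsv(
    samples: Sequence[RepertoireSample], path: str | Path
) -> None:
    rows = []
    for s in samples:
        for c in s.clonotypes:
            rows.append(
                (s.patient, s.compartment, s.timepoint, s.lesion or "",
                 c.junction_aa, c.v_call or "", c.j_call or "", c.duplicate_count)
            )
    pd.DataFrame(rows, columns=REPERTOIRE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_repertoire_tsv(path: str | Path) -> list[RepertoireSample]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    missing = set(REPERTOIRE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for key, grp in df.groupby(
        ["patient", "compartment", "timepoint", "lesion"], sort=True
    ):
        clons = tuple(
            Clonotype(
                junction_aa=r.junction_aa,
                duplicate_count=int(r.duplicate_count),
                v_call=r.v_call or None,
                j_call=r.j_call or None,
            )
            for r in grp.itertuples()
        )
        out.append(
            RepertoireSample(
                patient=key[0], compartment=key[1], timepoint=int(key[2]),
                lesion=key[3] or None, clonotypes=clons,
            )
        )
    return out


def write_scores_tsv(scores, path: str | Path) -> None:
    """Cache binding scores as (peptide, allele, rank, predictor_id)."""
    rows = sorted(
        (s.candidate.peptide, s.candidate.allele, s.percentile_rank, s.predictor_id)
        for s in scores
    )
    pd.DataFrame(
        rows, columns=["peptide", "allele", "percentile_rank", "predictor_id"]
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
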