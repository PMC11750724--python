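"""Target selection and mRNA concatamer construct assembly.

From the prioritized list, up to 20 targets are selected by a composite score
over class I/II binding, expression and DNA VAF. Selected targets are split
across at most two RNAs (<= 10 targets each) and assembled as

    SEC - target1 - linker - target2 - ... - targetN - MITD

where SEC is the secretory signal peptide routing the product into the
secretory pathway, MITD the MHC class I trafficking domain improving HLA
class I and II presentation, and the linkers are 30-nt non-immunogenic
glycine/serine spacers between consecutive targets. Nucleotide sequences come
from a fixed one-codon-per-residue reverse translation (no codon
optimization), so translation round-trips exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .errors import AssemblyError, InputError
from .mps import MutatedPeptideSequence
from .prioritization import PrioritizedEntry, PrioritizedList, Tier

SEC_PEPTIDE = "MRVMAPRTLILLLSGALALTETWAGS"
MITD_PEPTIDE = "IVGIVAGLAVLAVVVIGAVVATVMCRRKSSGGKGGSYSQAASSDSAQGSDVSLTA"

LINKER_PEPTIDE = "GGSGGSGGSG"  # 10 residues = 30 nt
LINKER_NT = "GGCGGCAGCGGCGGCAGCGGCGGCAGCGGC"

# Vendor 3' UTR element recorded verbatim as opaque metadata (amino-acid-like
# string as printed in the source vector annotation); not designed or
# interpreted here.
VECTOR_UTR3_ANNOTATION = "LVLHARNASCPFPVLGTPSLPRPRVPGMLPPPPAPLTTSASSRHL"

# Fixed codon per residue (common human codons); deterministic by design.
CODON_TABLE = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "CGG",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
}

STOP_CODON = "TAA"


@dataclass(frozen=True)
class SelectionWeights:
    """Non-negative weights of the composite selection score."""

    class1: float = 0.35
    class2: float = 0.15
    expression: float = 0.30
    vaf_dna: float = 0.20

    def __post_init__(self) -> None:
        vals = (self.class1, self.class2, self.expression, self.vaf_dna)
        if any(w < 0 for w in vals) or sum(vals) == 0:
            raise InputError("selection weights must be >= 0 and not all zero")


@dataclass(frozen=True)
class SelectionConfig:
    max_targets: int = 20
    weights: SelectionWeights = field(default_factory=SelectionWeights)
    min_neoantigens_eligibility: int = 5

    def __post_init__(self) -> None:
        if self.max_targets < 1:
            raise InputError("max_targets must be >= 1")


@dataclass(frozen=True)
class NeoantigenTarget:
    """A selected MPS with its provenance through prioritization and selection."""

    mps: MutatedPeptideSequence
    tier: Tier
    priority_rank: int
    selection_rank: int
    score: float

    @property
    def variant_id(self) -> str:
        return self.mps.variant_id


@dataclass(frozen=True)
class ConstructSpec:
    construct_id: str  # "RNA1" | "RNA2"
    targets: tuple[NeoantigenTarget, ...]
    protein_sequence: str
    nucleotide_sequence: str
    sec_peptide: str = SEC_PEPTIDE
    mitd_peptide: str = MITD_PEPTIDE
    linker_nt: str = LINKER_NT
    metadata: tuple[tuple[str, str], ...] = (
        ("utr3_annotation", VECTOR_UTR3_ANNOTATION),
    )


def check_eligibility(candidate_count: int, min_required: int = 5) -> bool:
    """Patients need at least ``min_required`` identified neoantigens."""
    if candidate_count < 0:
        raise InputError("candidate_count must be >= 0")
    return candidate_count >= min_required


def composite_scores(
    prioritized: PrioritizedList, weights: SelectionWeights
) -> list[float]:
    """Composite score per entry: weighted sum of normalized criteria.

    Binding ranks map to (100 - rank)/100 so lower percentile rank scores
    higher; expression is log-scaled and normalized to the list maximum.
    """
    rpkms = [e.mps.rpkm for e in prioritized.entries]
    max_log = max((math.log1p(max(r, 0.0)) for r in rpkms), default=0.0)
    out = []
    for e in prioritized.entries:
        m = e.mps
        c1 = (100.0 - (m.best_class1_rank if m.best_class1_rank is not None else 100.0)) / 100.0
        c2 = (100.0 - (m.best_class2_rank if m.best_class2_rank is not None else 100.0)) / 100.0
        expr = math.log1p(max(m.rpkm, 0.0)) / max_log if max_log > 0 else 0.0
        score = (
            weights.class1 * c1
            + weights.class2 * c2
            + weights.expression * expr
            + weights.vaf_dna * m.vaf_dna
        )
        out.append(score)
    return out


def select_targets(
    prioritized: PrioritizedList, config: SelectionConfig | None = None
) -> list[NeoantigenTarget]:
    """Select up to ``max_targets`` entries by descending composite score.

    Ties break on prioritization rank (ascending), so the outcome is
    deterministic for any input.
    """
    config = config or SelectionConfig()
    scores = composite_scores(prioritized, config.weights)
    order = sorted(
        range(len(prioritized.entries)),
        key=lambda i: (-scores[i], prioritized.entries[i].rank),
    )[: config.max_targets]
    targets = []
    for sel_rank, i in enumerate(order, start=1):
        e: PrioritizedEntry = prioritized.entries[i]
        targets.append(
            NeoantigenTarget(
                mps=e.mps,
                tier=e.tier,
                priority_rank=e.rank,
                selection_rank=sel_rank,
                score=scores[i],
            )
        )
    return targets


MAX_PER_CONSTRUCT = 10
MAX_TOTAL_TARGETS = 20


def partition_targets(
    selected: list[NeoantigenTarget],
) -> list[list[NeoantigenTarget]]:
    """Split selected targets over one or two RNAs (<= 10 targets each).

    More than 10 targets alternate between the two groups in selection order,
    giving groups of ceil(n/2) and floor(n/2).
    """
    n = len(selected)
    if n < 1:
        raise InputError("no targets to partition")
    if n > MAX_TOTAL_TARGETS:
        raise InputError(f"{n} targets exceed the {MAX_TOTAL_TARGETS}-target cap")
    if n <= MAX_PER_CONSTRUCT:
        return [list(selected)]
    groups: list[list[NeoantigenTarget]] = [[], []]
    for i, t in enumerate(selected):
        groups[i % 2].append(t)
    return groups


def reverse_translate(peptide: str, codon_table: dict[str, str] | None = None) -> str:
    table = codon_table or CODON_TABLE
    try:
        return "".join(table[aa] for aa in peptide)
    except KeyError as exc:
        raise AssemblyError(f"non-standard residue {exc.args[0]!r} in {peptide!r}")


def assemble_construct(
    group: list[NeoantigenTarget],
    construct_id: str = "RNA1",
    codon_table: dict[str, str] | None = None,
    linker_nt: str = LINKER_NT,
) -> ConstructSpec:
    """Assemble one RNA: SEC + linker-joined targets + MITD, protein and nt.

    Linkers sit between consecutive targets only; SEC and MITD are fused
    directly to the first and last target. A stop codon terminates the ORF
    (excluded from the protein).
    """
    if not group:
        raise InputError("cannot assemble an empty construct")
    if len(group) > MAX_PER_CONSTRUCT:
        raise InputError(f"{len(group)} targets exceed the per-construct cap")
    table = codon_table or CODON_TABLE
    linker_pep = str(Seq(linker_nt).translate())
    if "*" in linker_pep or len(linker_nt) % 3:
        raise AssemblyError("linker must be a stop-free in-frame nucleotide sequence")

    target_peps = [t.mps.sequence for t in group]
    protein = SEC_PEPTIDE + linker_pep.join(target_peps) + MITD_PEPTIDE

    parts = [reverse_translate(SEC_PEPTIDE, table)]
    for i, pep in enumerate(target_peps):
        if i:
            parts.append(linker_nt)
        parts.append(reverse_translate(pep, table))
    parts.append(reverse_translate(MITD_PEPTIDE, table))
    parts.append(STOP_CODON)
    nucleotide = "".join(parts)

    assert str(Seq(nucleotide).translate(to_stop=True)) == protein
    return ConstructSpec(
        construct_id=construct_id,
        targets=tuple(group),
        protein_sequence=protein,
        nucleotide_sequence=nucleotide,
        linker_nt=linker_nt,
    )


def design_constructs(
    selected: list[NeoantigenTarget],
    codon_table: dict[str, str] | None = None,
    linker_nt: str = LINKER_NT,
) -> list[ConstructSpec]:
    """Partition and assemble the selected targets into 1-2 ConstructSpecs."""
    groups = partition_targets(selected)
    return [
        assemble_construct(g, f"RNA{i + 1}", codon_table, linker_nt)
        for i, g in enumerate(groups)
    ]
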