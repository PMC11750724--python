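"""HLA-binding percentile-rank scoring.

Candidate epitopes are all 8-11-mers (class I) or 15-mers (class II, DRB)
of an MPS whose span intersects the mutated residues, crossed with the
patient's HLA alleles. Scoring goes through a pluggable predictor interface
returning IEDB-style percentile ranks (0-100, lower = stronger predicted
binding). The bundled :class:`MockPredictor` maps (peptide, allele) pairs to
ranks via a keyed hash, so the whole pipeline is deterministic and testable
without any external prediction tool; adapters to real predictors can
implement the same interface.

Per variant, the best (minimum) rank over all candidate pairs is associated
with the MPS and drives prioritization.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Protocol, Sequence

from .errors import ValidationError
from .mps import MutatedPeptideSequence

CLASS_I_LENGTHS = (8, 9, 10, 11)
CLASS_II_LENGTH = 15

_CLASS_I_RE = re.compile(r"^(HLA-)?[ABC]\*\d{2}:\d{2,3}$")
_CLASS_II_RE = re.compile(r"^(HLA-)?DRB[1345]\*\d{2}:\d{2,3}$")
_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")


def allele_class(allele: str) -> int:
    """Return 1 or 2 for a valid HLA allele name; raise otherwise."""
    if _CLASS_I_RE.match(allele):
        return 1
    if _CLASS_II_RE.match(allele):
        return 2
    raise ValidationError(f"unrecognized HLA allele name: {allele!r}")


@dataclass(frozen=True)
class EpitopeCandidate:
    peptide: str
    allele: str
    source_variant: str
    contains_mutation: bool = True
    start: int = 1  # 1-based start within the MPS


@dataclass(frozen=True)
class BindingScore:
    candidate: EpitopeCandidate
    percentile_rank: float
    predictor_id: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.percentile_rank <= 100.0:
            raise ValidationError(
                f"percentile rank {self.percentile_rank} outside [0,100]"
            )


def enumerate_candidates(
    mps: MutatedPeptideSequence,
    alleles: Sequence[str],
    lengths: Iterable[int] = CLASS_I_LENGTHS,
) -> list[EpitopeCandidate]:
    """All k-mers of the requested lengths that overlap the mutated span,
    crossed with the given alleles.

    An MPS shorter than every requested length yields an empty list.
    """
    for allele in alleles:
        allele_class(allele)
    span_a, span_b = mps.mutated_span
    seq = mps.sequence
    out: list[EpitopeCandidate] = []
    for k in sorted(set(lengths)):
        for start in range(1, len(seq) - k + 2):
            end = start + k - 1
            if end < span_a or start > span_b:
                continue
            for allele in alleles:
                out.append(
                    EpitopeCandidate(
                        peptide=seq[start - 1 : end],
                        allele=allele,
                        source_variant=mps.variant_id,
                        start=start,
                    )
                )
    return out


class Predictor(Protocol):
    """Interface every binding predictor (mock or adapter) implements."""

    predictor_id: str

    def predict(self, candidates: Sequence[EpitopeCandidate]) -> list[BindingScore]:
        ...


class MockPredictor:
    """Deterministic stand-in predictor: rank = keyed hash of (peptide, allele).

    Ranks are uniform-ish on [0, 100) and stable across runs and platforms.
    Specific pairs can be pinned to chosen ranks through ``pinned``, which
    tests use to build score landscapes with known structure.
    """

    def __init__(
        self,
        predictor_id: str = "mock-v1",
        pinned: Mapping[tuple[str, str], float] | None = None,
    ) -> None:
        self.predictor_id = predictor_id
        self._key = hashlib.blake2b(predictor_id.encode(), digest_size=16).digest()
        self._pinned = dict(pinned or {})

    def pin(self, peptide: str, allele: str, rank: float) -> None:
        self._pinned[(peptide, allele)] = rank

    def rank(self, peptide: str, allele: str) -> float:
        allele_class(allele)
        if not _AA_RE.match(peptide):
            raise ValidationError(f"invalid peptide: {peptide!r}")
        if (peptide, allele) in self._pinned:
            return self._pinned[(peptide, allele)]
        h = hashlib.blake2b(
            f"{peptide}|{allele}".encode(), key=self._key, digest_size=8
        ).digest()
        return (int.from_bytes(h, "big") % 1_000_000) / 10_000.0

    def predict(self, candidates: Sequence[EpitopeCandidate]) -> list[BindingScore]:
        return [
            BindingScore(
                candidate=c,
                percentile_rank=self.rank(c.peptide, c.allele),
                predictor_id=self.predictor_id,
            )
            for c in candidates
        ]


WORST_RANK = 100.0


def best_score_for_mps(
    mps: MutatedPeptideSequence, scores: Sequence[BindingScore]
) -> MutatedPeptideSequence:
    """Annotate the MPS with its best (minimum) class I and class II ranks.

    Scores for other variants are ignored. A class with no candidates gets the
    worst rank (100) and a ``no-class{1,2}-candidates`` flag.
    """
    own = [s for s in scores if s.candidate.source_variant == mps.variant_id]
    flags = list(mps.flags)
    best: dict[int, float] = {}
    for s in own:
        cls = allele_class(s.candidate.allele)
        if cls not in best or s.percentile_rank < best[cls]:
            best[cls] = s.percentile_rank
    for cls in (1, 2):
        if cls not in best:
            best[cls] = WORST_RANK
            flags.append(f"no-class{cls}-candidates")
    return replace(
        mps,
        best_class1_rank=best[1],
        best_class2_rank=best[2],
        flags=tuple(flags),
    )


def score_mps(
    mps: MutatedPeptideSequence,
    class1_alleles: Sequence[str],
    class2_alleles: Sequence[str],
    predictor: Predictor,
    class1_lengths: Iterable[int] = CLASS_I_LENGTHS,
) -> tuple[MutatedPeptideSequence, list[BindingScore]]:
    """Enumerate, score and reduce in one step; returns (annotated MPS, scores)."""
    cands = enumerate_candidates(mps, class1_alleles, class1_lengths)
    cands += enumerate_candidates(mps, class2_alleles, (CLASS_II_LENGTH,))
    scores = predictor.predict(cands)
    return best_score_for_mps(mps, scores), scores
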