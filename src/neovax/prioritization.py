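"""Tiered prioritization of MPS candidates: up to 46 targets per patient.

Only somatic mutations with RNA variant-allele frequency > 0 are considered
first. From those, tiers are filled in order:

1. ``INDEL``        - up to 5 indel MPS by class I binding rank,
2. ``SNV_HI_EXPR``  - up to 20 SNV MPS with expression >= 10 RPKM, by rank,
3. ``SNV_LO_EXPR``  - up to 20 SNV MPS with expression >= 1 RPKM, by rank,
4. ``EXPR_FILL``    - further SNV MPS by expression, to reach 46 in total.

If fewer than 46 are reached, RNA-silent mutations (RNA VAF = 0) are
backfilled by class I rank and expression (``VAF0_BACKFILL``).

Each candidate is consumed by at most one tier; an SNV with >= 10 RPKM that
misses the high-expression tier on rank still competes in the >= 1 RPKM tier
(the thresholds are nested). Ties break deterministically on
(class I rank asc, RPKM desc, variant id).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .mps import MutatedPeptideSequence


class Tier(str, Enum):
    INDEL = "INDEL"
    SNV_HI_EXPR = "SNV_HI_EXPR"
    SNV_LO_EXPR = "SNV_LO_EXPR"
    EXPR_FILL = "EXPR_FILL"
    VAF0_BACKFILL = "VAF0_BACKFILL"


@dataclass(frozen=True)
class TierCaps:
    indel: int = 5
    hi_expr: int = 20
    lo_expr: int = 20
    total: int = 46
    hi_rpkm_min: float = 10.0
    lo_rpkm_min: float = 1.0


@dataclass(frozen=True)
class PrioritizedEntry:
    mps: MutatedPeptideSequence
    tier: Tier
    rank: int  # 1-based, contiguous across the whole list


@dataclass(frozen=True)
class PrioritizedList:
    entries: tuple[PrioritizedEntry, ...] = ()
    caps: TierCaps = field(default_factory=TierCaps)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def tier_count(self, tier: Tier) -> int:
        return sum(1 for e in self.entries if e.tier is tier)


def _rank_key(m: MutatedPeptideSequence) -> tuple:
    rank = m.best_class1_rank if m.best_class1_rank is not None else 100.0
    return (rank, -m.rpkm, m.variant_id)


def _expr_key(m: MutatedPeptideSequence) -> tuple:
    rank = m.best_class1_rank if m.best_class1_rank is not None else 100.0
    return (-m.rpkm, rank, m.variant_id)


def prioritize(
    candidates: list[MutatedPeptideSequence], caps: TierCaps | None = None
) -> PrioritizedList:
    """Reduce annotated MPS candidates to the ranked, tiered list of <= 46."""
    caps = caps or TierCaps()
    chosen: list[tuple[MutatedPeptideSequence, Tier]] = []
    taken: set[str] = set()

    def take(pool: list[MutatedPeptideSequence], n: int, tier: Tier, key) -> None:
        for m in sorted(pool, key=key):
            if len(chosen) >= caps.total or n <= 0:
                return
            if m.variant_id in taken:
                continue
            chosen.append((m, tier))
            taken.add(m.variant_id)
            n -= 1

    expressed = [m for m in candidates if m.vaf_rna > 0]
    silent = [m for m in candidates if m.vaf_rna == 0]

    indels = [m for m in expressed if m.source_kind == "indel"]
    snvs = [m for m in expressed if m.source_kind == "SNV"]

    take(indels, caps.indel, Tier.INDEL, _rank_key)
    take(
        [m for m in snvs if m.rpkm >= caps.hi_rpkm_min],
        caps.hi_expr,
        Tier.SNV_HI_EXPR,
        _rank_key,
    )
    take(
        [m for m in snvs if m.rpkm >= caps.lo_rpkm_min],
        caps.lo_expr,
        Tier.SNV_LO_EXPR,
        _rank_key,
    )
    take(snvs, caps.total - len(chosen), Tier.EXPR_FILL, _expr_key)
    take(silent, caps.total - len(chosen), Tier.VAF0_BACKFILL, _rank_key)

    entries = tuple(
        PrioritizedEntry(mps=m, tier=t, rank=i + 1) for i, (m, t) in enumerate(chosen)
    )
    return PrioritizedList(entries=entries, caps=caps)
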