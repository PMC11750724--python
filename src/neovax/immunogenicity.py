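"""Immune-response analytics: OLP pools, ELISpot calling, multimer candidates.

Vaccine targets are covered by overlapping long peptides (OLPs): 15-mers with
11-residue overlaps, the last peptide anchored to the sequence end so coverage
is complete. IFN-gamma ELISpot spot counts for peptide-stimulated wells are
compared with control wells by a label-permutation exceedance test combined
with a minimum spot delta; responses are classified against baseline with a
two-fold amplification threshold (de novo responses - undetectable at
baseline - bypass the fold change). For pHLA multimer screening, all
mutation-containing 8-11-mer / HLA pairs with percentile rank < 5 are pooled
and the three lowest-rank pairs are selected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .binding import BindingScore
from .errors import AssayError, InputError
from .mps import MutatedPeptideSequence

OLP_LENGTH = 15
OLP_OVERLAP = 11


@dataclass(frozen=True)
class PeptidePool:
    target_id: str
    peptides: tuple[str, ...]
    starts: tuple[int, ...]  # 1-based start of each peptide in the MPS
    step: int = OLP_LENGTH - OLP_OVERLAP


def make_olp_pool(
    mps: MutatedPeptideSequence | str,
    target_id: str | None = None,
    length: int = OLP_LENGTH,
    overlap: int = OLP_OVERLAP,
) -> PeptidePool:
    """Cover a target sequence with overlapping long peptides.

    Peptides start at 1, 1+step, 1+2*step, ...; the final peptide is anchored
    to the sequence end (overlapping its predecessor by more than ``overlap``
    if needed) so the union of peptides reconstructs the sequence exactly.
    Sequences shorter than ``length`` yield a single full-length peptide.
    """
    if isinstance(mps, MutatedPeptideSequence):
        seq = mps.sequence
        target_id = target_id or mps.variant_id
    else:
        seq = mps
        target_id = target_id or "target"
    if not seq:
        raise InputError("empty target sequence")
    step = length - overlap
    if len(seq) <= length:
        return PeptidePool(target_id, (seq,), (1,), step)
    starts = list(range(1, len(seq) - length + 1, step))
    if starts[-1] + length - 1 < len(seq):
        starts.append(len(seq) - length + 1)
    peptides = tuple(seq[s - 1 : s - 1 + length] for s in starts)
    return PeptidePool(target_id, peptides, tuple(starts), step)


@dataclass(frozen=True)
class ElispotMeasurement:
    """Replicate spot counts for one target / timepoint / assay condition."""

    patient: str
    target_id: str
    timepoint: str  # "baseline" | "post_induction"
    assay: str = "ex_vivo"  # "ex_vivo" | "post_IVS"
    compartment: str = "bulk"  # "bulk" | "CD4" | "CD8"
    stimulated: tuple[int, ...] = ()
    control: tuple[int, ...] = ()
    positive_control: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.stimulated) < 2 or len(self.control) < 2:
            raise InputError("need >= 2 replicates per condition")
        if any(c < 0 for c in self.stimulated + self.control):
            raise InputError("spot counts must be >= 0")


@dataclass(frozen=True)
class PositivityResult:
    positive: bool
    p_value: float
    delta: float  # mean(stimulated) - mean(control)
    assay_failure: bool = False


def call_positivity(
    m: ElispotMeasurement,
    alpha: float = 0.05,
    min_spot_delta: float = 5.0,
    max_exhaustive: int = 20000,
    rng: np.random.Generator | None = None,
    n_resamples: int = 2000,
) -> PositivityResult:
    """Positivity of one measurement via label permutation plus a spot delta.

    The p-value is the fraction of relabelings of the pooled replicates whose
    mean difference strictly exceeds the observed one (exhaustive when the
    number of relabelings is small, Monte Carlo otherwise). Because this
    strict-exceedance p can be 0 for tied inputs, positivity additionally
    requires mean(stimulated) - mean(control) >= ``min_spot_delta``; the two
    conditions together control the false-positive rate.

    An all-zero positive control marks the sample as an assay failure: no
    call is made (``positive`` is False, ``assay_failure`` True).
    """
    if m.positive_control is not None and all(c == 0 for c in m.positive_control):
        return PositivityResult(False, float("nan"), float("nan"), assay_failure=True)
    stim = np.asarray(m.stimulated, dtype=float)
    ctrl = np.asarray(m.control, dtype=float)
    observed = stim.mean() - ctrl.mean()
    pooled = np.concatenate([stim, ctrl])
    n, k = len(pooled), len(stim)
    n_comb = math.comb(n, k)
    greater = 0
    if n_comb <= max_exhaustive:
        total = n_comb
        csum = pooled.sum()
        for idx in combinations(range(n), k):
            s = pooled[list(idx)].mean()
            c = (csum - pooled[list(idx)].sum()) / (n - k)
            if s - c > observed + 1e-12:
                greater += 1
    else:
        rng = rng or np.random.default_rng(0)
        total = n_resamples
        for _ in range(n_resamples):
            perm = rng.permutation(pooled)
            if perm[:k].mean() - perm[k:].mean() > observed + 1e-12:
                greater += 1
    p = greater / total
    positive = p <= alpha and observed >= min_spot_delta
    return PositivityResult(positive, p, observed)


@dataclass(frozen=True)
class ResponseCall:
    target_id: str
    positive_at_baseline: bool
    positive_post: bool
    classification: str  # de_novo | amplified_preexisting | preexisting_only | negative
    fold_change: float
    phenotype: str = "n/a"
    compartment: str = "bulk"
    assay: str = "ex_vivo"
    flags: tuple[str, ...] = ()

    @property
    def is_vaccine_response(self) -> bool:
        return self.classification in ("de_novo", "amplified_preexisting")


def call_response(
    baseline: ElispotMeasurement | None,
    post: ElispotMeasurement,
    fold_threshold: float = 2.0,
    net_floor: float = 1.0,
    alpha: float = 0.05,
    min_spot_delta: float = 5.0,
) -> ResponseCall:
    """Classify one target's response from baseline and post-induction data.

    Fold change = post net spots / max(baseline net spots, ``net_floor``).
    A post-positive target is de novo when baseline is negative, amplified
    when baseline is positive and the fold change reaches ``fold_threshold``,
    and preexisting-only otherwise. A missing baseline is flagged
    ``no-baseline`` and classified from the post measurement alone.
    """
    post_res = call_positivity(post, alpha=alpha, min_spot_delta=min_spot_delta)
    flags: list[str] = []
    if post_res.assay_failure:
        flags.append("assay-failure")
    if baseline is None:
        flags.append("no-baseline")
        classification = "de_novo" if post_res.positive else "negative"
        return ResponseCall(
            target_id=post.target_id,
            positive_at_baseline=False,
            positive_post=bool(post_res.positive),
            classification=classification,
            fold_change=float("nan"),
            compartment=post.compartment,
            assay=post.assay,
            flags=tuple(flags),
        )
    if (baseline.target_id, baseline.assay, baseline.compartment) != (
        post.target_id,
        post.assay,
        post.compartment,
    ):
        raise InputError("baseline and post measurements do not match")
    base_res = call_positivity(baseline, alpha=alpha, min_spot_delta=min_spot_delta)
    base_net = float(np.mean(baseline.stimulated) - np.mean(baseline.control))
    post_net = float(np.mean(post.stimulated) - np.mean(post.control))
    fold = post_net / max(base_net, net_floor)
    if not post_res.positive:
        classification = "preexisting_only" if base_res.positive else "negative"
    elif not base_res.positive:
        classification = "de_novo"
    elif fold >= fold_threshold:
        classification = "amplified_preexisting"
    else:
        classification = "preexisting_only"
    return ResponseCall(
        target_id=post.target_id,
        positive_at_baseline=bool(base_res.positive),
        positive_post=bool(post_res.positive),
        classification=classification,
        fold_change=fold,
        compartment=post.compartment,
        assay=post.assay,
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class PatientSummary:
    patient: str
    responder: bool
    n_targets_positive: int
    phenotypes: tuple[tuple[str, str], ...]  # (target_id, phenotype)
    phenotype_tally: tuple[tuple[str, int], ...]


def summarize_patient(
    patient: str, calls: Sequence[ResponseCall]
) -> PatientSummary:
    """Patient-level roll-up: responder flag and per-target CD4/CD8 phenotype.

    A patient responds when at least one target shows a de novo or amplified
    response in any assay/compartment. Per-target phenotype combines the CD4
    and CD8 compartment calls (bulk-only data gives "n/a").
    """
    by_target: dict[str, list[ResponseCall]] = {}
    for c in calls:
        by_target.setdefault(c.target_id, []).append(c)
    phenotypes = []
    n_pos = 0
    for target_id in sorted(by_target):
        tcalls = by_target[target_id]
        if any(c.is_vaccine_response for c in tcalls):
            n_pos += 1
        cd4 = any(c.compartment == "CD4" and c.is_vaccine_response for c in tcalls)
        cd8 = any(c.compartment == "CD8" and c.is_vaccine_response for c in tcalls)
        if cd4 and cd8:
            pheno = "CD4_and_CD8"
        elif cd4:
            pheno = "CD4_only"
        elif cd8:
            pheno = "CD8_only"
        else:
            pheno = "n/a"
        phenotypes.append((target_id, pheno))
    tally: dict[str, int] = {}
    for _, p in phenotypes:
        tally[p] = tally.get(p, 0) + 1
    return PatientSummary(
        patient=patient,
        responder=n_pos > 0,
        n_targets_positive=n_pos,
        phenotypes=tuple(phenotypes),
        phenotype_tally=tuple(sorted(tally.items())),
    )


MULTIMER_RANK_CUTOFF = 5.0
MULTIMER_MAX_PAIRS = 3


def select_multimer_candidates(
    scores: Iterable[BindingScore],
    rank_cutoff: float = MULTIMER_RANK_CUTOFF,
    max_pairs: int = MULTIMER_MAX_PAIRS,
) -> list[BindingScore]:
    """Pick pairs for pHLA multimer production: rank < 5, three lowest ranks.

    Ties break lexicographically on (peptide, allele) so the choice is
    deterministic. Duplicate (peptide, allele) pairs are collapsed.
    """
    seen: dict[tuple[str, str], BindingScore] = {}
    for s in scores:
        key = (s.candidate.peptide, s.candidate.allele)
        if s.percentile_rank < rank_cutoff:
            if key not in seen or s.percentile_rank < seen[key].percentile_rank:
                seen[key] = s
    ordered = sorted(
        seen.values(),
        key=lambda s: (s.percentile_rank, s.candidate.peptide, s.candidate.allele),
    )
    return ordered[:max_pairs]
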