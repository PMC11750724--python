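# Methods

## Overview

`neovax` implements the computational core of an individualized
neoantigen-specific mRNA vaccine (iNeST) program and its immune-monitoring
analytics. The pipeline starts downstream of alignment and variant calling:
its inputs are per-patient somatic SNV/indel calls with DNA and RNA variant
allele frequencies (VAF), germline variants with read-level phase evidence,
transcript expression (RPKM), coding sequences, and an HLA class I + DRB
genotype. Its outputs are up to two concatamer mRNA constructs encoding up
to 20 selected neoantigen targets, and — from downstream assay tables —
ELISpot response calls, pHLA multimer candidates and TCR clonotype tracking
summaries.

Because no patient-level data from such trials is publicly distributable,
the package ships a first-class synthetic-data generator; every number the
analysis scripts and tests print is computed from generated inputs.

## Mutated peptide sequences (MPS)

The unit of prioritization is the mutated peptide sequence:

- **Substitutions (SNV/MNV).** The window of 13 residues N-terminal and 13
  residues C-terminal of the changed residue(s), truncated at protein
  termini. Multi-residue substitution clusters are handled as one variant
  whose mutated span covers all changed residues.
- **Frameshift indels.** The novel reading frame translated from the first
  changed residue to (exclusive) the next stop codon, prefixed by up to 13
  wild-type residues for immunological context. A frameshift whose first
  novel codon is already a stop has no peptide product and is dropped with
  reason `null neo-ORF`; a frame with no downstream stop is truncated at the
  CDS end and flagged `readthrough`.
- **In-frame indels.** No distinct convention is in common print for these,
  so the package uses the natural generalization: 13 flanking residues on
  each side of the altered region. For a clean deletion whose junction
  restores the wild-type sequence, the span is widened to one junction
  residue so epitope enumeration still straddles the edit.
- **Germline phasing.** Protein-changing germline variants inside the
  window are substituted into the MPS when the RNA read evidence places them
  in cis with the somatic mutation: `cis_reads >= 2` and
  `cis/(cis+trans) >= 0.8` by default (both config-exposed; thresholds are a
  package choice, as phasing is usually reported without numeric cutoffs).
  Germline edits colliding with the somatic span are skipped — the somatic
  edit wins. For indel MPS only the wild-type prefix is eligible, because
  reference coordinates do not map past the frame change.

Candidates on non-expressed transcripts (RPKM < 0.1 by default) and
synonymous / nonsense / start-loss / stop-loss records are filtered with
machine-readable reasons; filtering is a partition (kept + dropped is always
the input).

## HLA binding scores

Epitope candidates are all 8–11-mers (class I) and 15-mers (class II, DRB
alleles) of an MPS whose coordinates intersect the mutated span, crossed
with the patient's alleles. Scores are IEDB-style percentile ranks in
[0, 100], lower = stronger predicted binding; per variant, the best
(minimum) rank per class is associated with the MPS ("best consensus
score"). Whether production pipelines score a fixed length per allele or all
of 8–11 is not standardized; the lengths are config-exposed.

Real predictors (NetMHCpan, IEDB consensus) are deliberately out of scope:
scoring goes through a pluggable `Predictor` interface, and the bundled
`MockPredictor` maps (peptide, allele) pairs to ranks via a keyed BLAKE2
hash — deterministic across runs and platforms, uniform-ish over [0, 100),
with a pinning hook so tests can construct score landscapes with known
structure. Adapters to real tools can implement the same interface; nothing
in the package or its tests requires one.

## Tiered prioritization (≤ 46)

Only candidates with RNA VAF > 0 enter the main tiers, filled in order:

1. up to 5 indel MPS by class I rank;
2. up to 20 SNV MPS with expression ≥ 10 RPKM, by class I rank;
3. up to 20 SNV MPS with expression ≥ 1 RPKM, by class I rank;
4. further SNV MPS by expression, to 46 total.

If fewer than 46 accumulate, RNA-silent candidates (RNA VAF = 0) are
backfilled by class I rank and expression. Design choices the printed rules
leave open, fixed here: the expression thresholds are nested, so a ≥ 10 RPKM
SNV that loses on rank in tier 2 still competes in tier 3; the expression
fill is SNV-only; "indels" means frameshift and in-frame alike; ties break
on (class I rank asc, RPKM desc, variant id) so the output is a pure
function of the input.

## Selection and construct assembly

Patients need ≥ 5 identified neoantigens to be eligible. From the
prioritized list, up to 20 targets are selected by a composite score — the
trial's selection combined binding, expression, VAF "and other criteria"
plus a human review board, so the concrete score is a package decision:

    score = 0.35·(100−rank_I)/100 + 0.15·(100−rank_II)/100
          + 0.30·log1p(RPKM)/log1p(max RPKM) + 0.20·VAF_DNA

with weights config-exposed and ties broken by prioritization rank.

Selected targets are split across at most two RNAs of ≤ 10 targets each
(alternating assignment in selection order → sizes ⌈n/2⌉ / ⌊n/2⌋). Each
construct is `SEC – target₁ – linker – … – targetₙ – MITD`: the 26-residue
secretory signal peptide, 30-nt glycine/serine linkers (encoding
`GGSGGSGGSG`; composition is specified in the field, the exact codons are a
package choice) between consecutive targets only, and the 55-residue MHC
class I trafficking domain fused directly to the last target. Reverse
translation uses one fixed common human codon per residue — no codon
optimization — so `translate(nucleotide) == protein` holds exactly and is
asserted for every assembled construct. A vendor 3′ UTR annotation string is
carried as opaque metadata, not designed or interpreted.

## ELISpot response calling

Overlapping long peptides: 15-mers with 11-residue overlap (step 4), the
final peptide end-anchored rather than emitted short, matching fixed-length
synthesis practice; coverage of every residue is a tested invariant.

Positivity of a stimulated-vs-control comparison uses a label-permutation
exceedance test plus a minimum spot delta (the production assay used an
unpublished in-house tool, so this caller is the package's own design):

- p-value: the fraction of relabelings of the pooled replicates whose mean
  difference strictly exceeds the observed one (exhaustive up to 20,000
  relabelings, Monte Carlo beyond). The strict convention makes a clearly
  separated duplicate pair like {60, 55} vs {3, 5} callable; on its own it
  is anti-conservative for tied or low-replicate data,
- so positivity additionally requires mean(stimulated) − mean(control) ≥ 5
  spots (default).

The combined caller's patient-level false-positive rate is verified ≤ alpha
on a 500-patient null cohort. An all-zero positive control voids the sample
(`assay_failure`), producing no call.

Response classification against baseline: fold change = post net spots /
max(baseline net spots, 1); a post-positive target is **de novo** when
baseline is negative (fold change not required), **amplified preexisting**
when baseline is positive and fold ≥ 2, **preexisting only** otherwise. A
patient is a responder when ≥ 1 target is de novo or amplified; per-target
CD4/CD8 phenotype comes from the post-IVS compartment calls.

For pHLA multimer production, all mutation-containing 8–11-mer/allele pairs
with percentile rank < 5 are pooled per neoantigen and the three lowest
ranks selected (ties: lexicographic on peptide, allele).

## TCR clonotype tracking

TCR specificity is validated with a Jurkat NFAT-reporter fold change ≥ 2
versus the effectors-only control. Validated TCRs are tracked in bulk
repertoires by exact CDR3β amino-acid match, with V/J genes required to
agree when called on both sides; frequencies are computed within
compartment (blood CD8 vs tumor). Cumulative frequency counts each matched
clonotype once (so it cannot exceed 1) and is broken down per neoantigen;
for tumor samples both the per-biopsy value and the overlap (Jaccard on
detected specific TCRs) between biopsies are reported. De novo status
defaults to zero matching baseline reads (threshold config-exposed, since
detection depends on sequencing depth).

## Synthetic cohort: what it emulates, and what it does not

`CohortConfig` defaults define the study conditions:

| parameter | default | rationale |
|---|---|---|
| `snv_rate` / `indel_rate` | 20 / 2 per patient | mixed-solid-tumor scale; no per-patient distribution is printed for the trial, so these are free parameters |
| `rate_dispersion` | 0.8 (lognormal σ on a per-patient rate multiplier) | real cohorts are heavily overdispersed; makes candidate counts span the 5-neoantigen eligibility boundary |
| `rpkm_lognormal_params` | (1.0, 1.5) | median ≈ 2.7 RPKM with mass on both sides of the 1 and 10 RPKM tier thresholds |
| `vaf_beta_params` | (2, 5) | clonal-to-subclonal VAFs, mean ≈ 0.29 |
| `frac_rna_silent` | 0.1 | fraction of variants with RNA VAF = 0, exercising the backfill |
| `frac_synonymous` / `frac_nonsense` | 0.2 / 0.05 | so the printed filters have work to do |
| `n_proteins` | 40 | toy proteome; random CDS of 300–3000 nt, ATG start, single terminal stop |
| `responder_frac` | 0.71 | planted patient-level response rate mirroring the reported trial rate; used as truth, recovery is always checked against the realized plant |
| `immunogenic_frac` | 0.2 | per-candidate immunogenicity within responder patients (a minority of encoded neoantigens respond) |
| `preexisting_frac` | 0.3 | ≈ 70 % of specific TCRs/targets de novo, matching the reported 99/140 split |

Assay simulation (`AssayConfig`): Poisson spot counts around control mean 3
and signal mean 60 (amplified preexisting targets rise three-fold over a
baseline net of 25); repertoires of 20,000 reads over 2,000 Zipf-distributed
background clonotypes plus planted specific CDR3βs whose per-TCR blood
frequencies are lognormal (median 1 %), giving cohort cumulative
frequencies on the single-digit-percent scale reported for such trials;
`noise=0` replaces all sampling with expectations, making downstream
recovery of the plant exact — the property the truth-recovery tests use.

Not emulated: realistic mutational signatures, HLA haplotype frequencies,
isoform structure, read-level data, batch effects, or biological
cross-reactivity. Passing tests therefore demonstrate the *logic* of the
pipeline (filters, caps, orderings, callers, trackers) and its statistical
calibration under the generator's assumptions — not predictive performance
on real tumors.

## Numerical and reproducibility choices

- All randomness derives from one integer seed through named BLAKE2-derived
  substreams (per patient, per stage), so cohorts are byte-identical across
  runs and patients can be generated independently.
- Every ordering in the pipeline has a deterministic total tie-break
  (documented per stage above); reports serialize with sorted keys and
  fixed float formats, and carry a provenance block (config hash, seed,
  version).
- Problem sizes used by the shipped analyses and tests: a 30-patient
  narrative cohort for the analysis scripts, a 200-patient cohort for the
  end-to-end and recount checks, 500 null patients for caller calibration,
  and 1,000 random instances for the prioritization and multimer property
  suites — sizes chosen to exercise every boundary while staying
  desk-scale.
- Degenerate inputs: empty candidate lists prioritize to an empty list; a
  class with no epitope candidates receives the worst rank (100) with a
  flag; zero-net baselines are floored at 1 spot in fold changes; two
  biopsies detecting no specific TCRs count as fully overlapping.

## Known limitations

- The mock predictor has no biochemical content; ranks are exchangeable
  noise. Conclusions about which peptides bind require a real predictor
  behind the interface.
- The permutation caller's strict-exceedance p-value is meaningful only
  together with the spot-delta guard; with ≤ 2 replicates per condition its
  granularity is coarse.
- One canonical transcript per gene; no isoform-aware extraction.
- The composite selection score stands in for a clinical review board; its
  weights are a tunable convention, not a validated model.
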