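import numpy as np
import pytest

from neovax.mps import MutatedPeptideSequence, SomaticVariant
from neovax.synthetic_data import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortConfig(n_patients=6, seed=11))


@pytest.fixture(scope="session")
def cohort200():
    """The full-size synthetic study cohort (200 patients, fixed seed)."""
    return generate_cohort(CohortConfig(n_patients=200, seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_mps(
    variant_id="v1",
    sequence="A" * 27,
    mutated_span=(14, 14),
    source_kind="SNV",
    rpkm=10.0,
    vaf_rna=0.3,
    vaf_dna=0.3,
    best_class1_rank=1.0,
    best_class2_rank=50.0,
):
    return MutatedPeptideSequence(
        variant_id=variant_id,
        sequence=sequence,
        mutated_span=mutated_span,
        source_kind=source_kind,
        rpkm=rpkm,
        vaf_rna=vaf_rna,
        vaf_dna=vaf_dna,
        best_class1_rank=best_class1_rank,
        best_class2_rank=best_class2_rank,
    )


def make_snv(
    vid="s1",
    transcript_id="T001",
    cds_pos=4,
    ref_nt="A",
    alt_nt="G",
    vaf_dna=0.3,
    vaf_rna=0.3,
    rpkm=10.0,
):
    return SomaticVariant(
        id=vid,
        kind="SNV",
        transcript_id=transcript_id,
        cds_pos=cds_pos,
        ref_nt=ref_nt,
        alt_nt=alt_nt,
        vaf_dna=vaf_dna,
        vaf_rna=vaf_rna,
        rpkm=rpkm,
    )
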