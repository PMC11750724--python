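"""Mutated-peptide-window extraction, frameshift translation and phasing."""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from neovax.errors import InputError, ReferenceMismatchError
from neovax.mps import (
    CandidateRecord,
    GermlineVariant,
    SomaticVariant,
    classify_variant,
    extract_mps_frameshift,
    extract_mps_snv,
    filter_candidates,
    phase_and_incorporate,
    translate_cds,
)

from conftest import make_mps

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng, n):
    return "".join(rng.choice(list(AA), size=n))


def snv_at(protein, pos, alt="W"):
    ref = protein[pos - 1]
    if alt == ref:
        alt = "G" if ref != "G" else "A"
    return SomaticVariant(
        id=f"s{pos}", kind="SNV", transcript_id="T", cds_pos=3 * pos - 2,
        ref_nt="A", alt_nt="G", vaf_dna=0.3, vaf_rna=0.3, rpkm=5.0,
        protein_position=pos, ref_aa=ref, alt_aa=alt,
    )


def window_oracle(protein, pos, alt, flank=13):
    """Independent slice-and-substitute reference for the SNV window."""
    start = max(0, pos - 1 - flank)
    end = min(len(protein), pos + flank)
    mutated = protein[: pos - 1] + alt + protein[pos:]
    return mutated[start:end], (pos - start, pos - start)


class TestSnvWindow:
    @pytest.mark.parametrize(
        "protein_len,pos,exp_len,exp_span",
        [
            (300, 100, 27, (14, 14)),  # interior: 13 + 1 + 13
            (300, 1, 14, (1, 1)),      # N-terminal truncation
            (300, 295, 19, (14, 14)),  # C-terminal truncation: 13 + 1 + 5
            (300, 300, 14, (14, 14)),
        ],
    )
    def test_window_geometry(self, rng, protein_len, pos, exp_len, exp_span):
        protein = random_protein(rng, protein_len)
        mps = extract_mps_snv(snv_at(protein, pos), protein)
        assert len(mps.sequence) == exp_len
        assert mps.mutated_span == exp_span
        oracle_seq, oracle_span = window_oracle(protein, pos, mps.sequence[mps.mutated_span[0] - 1])
        assert mps.sequence == oracle_seq and mps.mutated_span == oracle_span

    @given(pos=st.integers(1, 120), seed=st.integers(0, 10_000))
    @settings(max_examples=120, derandomize=True, deadline=None)
    def test_window_matches_slice_oracle_everywhere(self, pos, seed):
        rng = np.random.default_rng(seed)
        protein = random_protein(rng, 120)
        v = snv_at(protein, pos)
        mps = extract_mps_snv(v, protein)
        assert (mps.sequence, mps.mutated_span) == window_oracle(
            protein, pos, v.alt_aa
        )
        # removing the substitution reproduces a verbatim protein substring
        a = mps.mutated_span[0]
        reverted = mps.sequence[: a - 1] + v.ref_aa + mps.sequence[a:]
        assert reverted in protein

    def test_reference_mismatch_raises(self, rng):
        protein = random_protein(rng, 50)
        v = snv_at(protein, 10)
        wrong = v.__class__(**{**v.__dict__, "ref_aa": "X" if v.ref_aa != "X" else "Y"})
        with pytest.raises(ReferenceMismatchError):
            extract_mps_snv(wrong, protein)

    def test_mnv_span_covers_all_changed_residues(self, rng):
        protein = random_protein(rng, 60)
        ref = protein[19:22]
        alt = "".join("W" if a != "W" else "Y" for a in ref)
        v = SomaticVariant(
            id="mnv", kind="SNV", transcript_id="T", cds_pos=58, ref_nt="AAA",
            alt_nt="GGG", vaf_dna=0.2, vaf_rna=0.2, protein_position=20,
            ref_aa=ref, alt_aa=alt,
        )
        mps = extract_mps_snv(v, protein)
        a, b = mps.mutated_span
        assert b - a + 1 == 3
        assert mps.sequence[a - 1 : b] == alt
        assert len(mps.sequence) == 13 + 3 + 13


def make_cds(rng, n_codons=60):
    sense = [
        a + b + c
        for a in "ACGT" for b in "ACGT" for c in "ACGT"
        if a + b + c not in ("TAA", "TAG", "TGA")
    ]
    return "ATG" + "".join(rng.choice(sense, size=n_codons)) + "TAA"


def frameshift_oracle(cds, variant, flank=13):
    """Translate the edited CDS independently; novel frame to first stop."""
    p = variant.cds_pos - 1
    mut_cds = cds[:p] + variant.alt_nt + cds[p + len(variant.ref_nt):]
    wt = str(Seq(cds).translate(to_stop=True))
    mut = str(Seq(mut_cds[: len(mut_cds) - len(mut_cds) % 3]).translate())
    mut = mut.split("*")[0]
    first = next((i for i in range(min(len(wt), len(mut))) if wt[i] != mut[i]),
                 min(len(wt), len(mut)))
    prefix = wt[max(0, first - flank): first]
    return prefix + mut[first:]


class TestFrameshift:
    def test_deletion_matches_translation_oracle(self, rng):
        for _ in range(20):
            cds = make_cds(rng, 80)
            p = int(rng.integers(10, 150))
            v = SomaticVariant(
                id="fs", kind="deletion", transcript_id="T", cds_pos=p,
                ref_nt=cds[p - 1 : p + 1], alt_nt=cds[p - 1],
                vaf_dna=0.3, vaf_rna=0.3,
            )
            try:
                mps = extract_mps_frameshift(v, cds)
            except InputError as exc:
                assert "null neo-ORF" in str(exc)
                continue
            assert mps.sequence == frameshift_oracle(cds, v)
            assert "*" not in mps.sequence
            a, _ = mps.mutated_span
            assert a - 1 <= 13  # at most 13 wild-type prefix residues

    def test_first_novel_codon_stop_is_null_neo_orf(self):
        # wt: ATG AAA TTA ACC GGG TAA = M K L T G; deleting the T at position 7
        # shifts to ATG AAA TAA ... -> the first novel codon is already a stop
        cds = "ATG" + "AAA" + "TTA" + "ACC" + "GGG" + "TAA"
        v = SomaticVariant(
            id="fs0", kind="deletion", transcript_id="T", cds_pos=7,
            ref_nt=cds[6:8], alt_nt=cds[6], vaf_dna=0.3, vaf_rna=0.3,
        )
        with pytest.raises(InputError, match="null neo-ORF"):
            extract_mps_frameshift(v, cds)

    def test_inframe_insertion_is_13_plus_alt_plus_13(self, rng):
        cds = make_cds(rng, 80)
        p = 3 * 30 + 3  # boundary after codon 31
        v = SomaticVariant(
            id="ins", kind="insertion", transcript_id="T", cds_pos=p,
            ref_nt=cds[p - 1], alt_nt=cds[p - 1] + "TGG",  # insert W
            vaf_dna=0.3, vaf_rna=0.3,
        )
        mps = extract_mps_frameshift(v, cds)
        wt = translate_cds(cds)
        mut = wt[:31] + "W" + wt[31:]
        a, b = mps.mutated_span
        assert mps.sequence == mut[31 - 13 : 31 + 1 + 13]
        assert mps.sequence[a - 1 : b] == "W"

    def test_readthrough_flagged_when_no_stop(self):
        # Frameshift near the end with no downstream stop in the new frame
        cds = "ATG" + "AAA" * 20 + "TAA"  # poly-K; shifted frame reads AAA/ AAT...
        v = SomaticVariant(
            id="rt", kind="deletion", transcript_id="T", cds_pos=50,
            ref_nt=cds[49:51], alt_nt=cds[49], vaf_dna=0.3, vaf_rna=0.3,
        )
        with pytest.warns(UserWarning, match="readthrough"):
            mps = extract_mps_frameshift(v, cds)
        assert "readthrough" in mps.flags


class TestPhasing:
    def g(self, pos, ref, alt, cis, trans, gid="g1", changing=True):
        return GermlineVariant(
            id=gid, transcript_id="T", protein_position=pos, ref_aa=ref,
            alt_aa=alt, is_protein_changing=changing, cis_reads=cis,
            trans_reads=trans,
        )

    def test_in_phase_substituted(self, rng):
        protein = random_protein(rng, 60)
        mps = extract_mps_snv(snv_at(protein, 30), protein)
        gpos = 25
        germ = self.g(gpos, protein[gpos - 1], "W" if protein[gpos - 1] != "W" else "Y", 10, 0)
        out = phase_and_incorporate(mps, [germ])
        off = gpos - mps.protein_window_start
        assert out.sequence[off] == germ.alt_aa
        assert germ.id in out.incorporated_germline

    def test_out_of_phase_unchanged(self, rng):
        protein = random_protein(rng, 60)
        mps = extract_mps_snv(snv_at(protein, 30), protein)
        germ = self.g(25, protein[24], "W", cis=0, trans=12)
        out = phase_and_incorporate(mps, [germ])
        assert out.sequence == mps.sequence and not out.incorporated_germline

    def test_two_germline_equal_sequential_edit_oracle(self, rng):
        protein = random_protein(rng, 60)
        mps = extract_mps_snv(snv_at(protein, 30), protein)
        g1 = self.g(22, protein[21], "W" if protein[21] != "W" else "Y", 9, 1, "gA")
        g2 = self.g(35, protein[34], "H" if protein[34] != "H" else "Q", 8, 0, "gB")
        out = phase_and_incorporate(mps, [g2, g1])
        # oracle: apply edits one at a time in position order on the window
        expect = list(mps.sequence)
        for g in (g1, g2):
            expect[g.protein_position - mps.protein_window_start] = g.alt_aa
        assert out.sequence == "".join(expect)
        assert set(out.incorporated_germline) == {"gA", "gB"}

    def test_collision_with_somatic_span_somatic_wins(self, rng):
        protein = random_protein(rng, 60)
        v = snv_at(protein, 30)
        mps = extract_mps_snv(v, protein)
        germ = self.g(30, v.ref_aa, "W" if v.ref_aa != "W" else "Y", 10, 0)
        with pytest.warns(UserWarning, match="somatic"):
            out = phase_and_incorporate(mps, [germ])
        assert out.sequence == mps.sequence

    def test_phasing_monotone_in_cis_reads(self, rng):
        protein = random_protein(rng, 60)
        mps = extract_mps_snv(snv_at(protein, 30), protein)
        ref = protein[24]
        alt = "W" if ref != "W" else "Y"
        incorporated_before = False
        for cis in range(0, 30, 3):
            out = phase_and_incorporate(mps, [self.g(25, ref, alt, cis, 2)])
            now = bool(out.incorporated_germline)
            assert now >= incorporated_before  # never removed by more evidence
            incorporated_before = now
        assert incorporated_before


class TestFilter:
    def rec(self, reason=None, rpkm=5.0, vid="v"):
        mps = None if reason else make_mps(variant_id=vid, rpkm=rpkm)
        var = snv_at("A" * 30, 15)
        return CandidateRecord(variant=var.__class__(**{**var.__dict__, "rpkm": rpkm, "id": vid}),
                               mps=mps, drop_reason=reason)

    def test_non_expressed_dropped(self):
        kept, dropped = filter_candidates([self.rec(rpkm=0.0)])
        assert not kept and dropped[0].drop_reason == "non-expressed"

    def test_synonymous_dropped_with_reason(self):
        kept, dropped = filter_candidates([self.rec(reason="synonymous")])
        assert not kept and dropped[0].drop_reason == "synonymous"

    def test_partition_conserves_records(self, rng):
        recs = [
            self.rec(
                reason=rng.choice([None, "synonymous", "nonsense"], p=[0.6, 0.3, 0.1]) or None,
                rpkm=float(rng.uniform(0, 5)),
                vid=f"v{i}",
            )
            for i in range(10)
        ]
        # normalize numpy str to python
        recs = [
            CandidateRecord(r.variant, r.mps, str(r.drop_reason) if r.drop_reason else None)
            for r in recs
        ]
        kept, dropped = filter_candidates(recs)
        assert len(kept) + len(dropped) == 10
        ids = sorted(r.variant.id for r in kept + dropped)
        assert ids == sorted(r.variant.id for r in recs)
        assert all(r.drop_reason for r in dropped)


class TestClassify:
    def test_consequence_classification(self, rng):
        cds = make_cds(rng, 40)
        wt = translate_cds(cds)
        # synonymous: change codon 5 to a synonym if one exists within 1 nt
        from neovax.synthetic_data import _pick_snv, CohortConfig
        cfg = CohortConfig(frac_synonymous=1.0, frac_nonsense=0.0)
        found = {"synonymous": False, "missense": False}
        for _ in range(60):
            pos, ref, alt = _pick_snv(rng, cds, cfg)
            v = SomaticVariant(id="x", kind="SNV", transcript_id="T", cds_pos=pos,
                               ref_nt=ref, alt_nt=alt, vaf_dna=0.1, vaf_rna=0.1)
            cons = classify_variant(v, cds)
            assert cons in ("synonymous", "missense", "nonsense", "stop_loss", "start_loss")
            if cons in found:
                found[cons] = True
        assert found["synonymous"]
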