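"""Jurkat validation, clonotype tracking, cumulative frequency, biopsy overlap."""

import numpy as np
import pytest

from neovax.errors import AssayError
from neovax.tcr import (
    Clonotype,
    RepertoireSample,
    SpecificTcr,
    biopsy_overlap,
    classify_baseline_status,
    cumulative_frequency,
    jurkat_specificity_call,
    track,
)


def tcr(tid, junction, spec="neo1", fold=3.0, validated=True):
    return SpecificTcr(
        tcr_id=tid, junction_aa=junction, specificity=spec,
        fold_change=fold, validated=validated,
    )


def sample(clonotypes, compartment="blood_CD8", timepoint=43, patient="P", lesion=None):
    return RepertoireSample(
        patient=patient, compartment=compartment, timepoint=timepoint,
        clonotypes=tuple(clonotypes), lesion=lesion,
    )


class TestJurkat:
    @pytest.mark.parametrize(
        "lum,ctrl,fold,ok",
        [(2000, 800, 2.5, True), (1590, 800, 1.9875, False), (800, 800, 1.0, False)],
    )
    def test_fold_and_cutoff(self, lum, ctrl, fold, ok):
        got_fold, got_ok = jurkat_specificity_call(lum, ctrl)
        assert got_fold == pytest.approx(fold) and got_ok is ok

    def test_nonpositive_control_is_assay_error(self):
        with pytest.raises(AssayError):
            jurkat_specificity_call(1000, 0)


class TestTrack:
    def test_present_clonotype_frequency(self):
        s = sample([Clonotype("CASSAF", 50), Clonotype("CASSBF", 950)])
        m = track([tcr("t1", "CASSAF")], s)[0]
        assert m.count == 50 and m.frequency == pytest.approx(0.05)

    def test_absent_clonotype_is_zero(self):
        s = sample([Clonotype("CASSBF", 100)])
        m = track([tcr("t1", "CASSXF")], s)[0]
        assert m.count == 0 and m.frequency == 0.0

    def test_vj_mismatch_blocks_match_only_when_both_called(self):
        s = sample([Clonotype("CASSAF", 10, v_call="TRBV9")])
        assert track([tcr("t1", "CASSAF")], s)[0].count == 10  # TCR has no V call
        t_v = SpecificTcr("t2", "CASSAF", "neo1", 3.0, True, v_call="TRBV5")
        assert track([t_v], s)[0].count == 0

    def test_large_sample_matches_set_intersection_oracle(self):
        rng = np.random.default_rng(5)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        junctions = list({
            "CASS" + "".join(rng.choice(aas, size=7)) + "F" for _ in range(10_000)
        })
        clons = [Clonotype(j, int(rng.integers(1, 50))) for j in junctions]
        specific = [tcr(f"t{i}", junctions[i * 300]) for i in range(30)] + [
            tcr("tx", "CASSNOTPRESENTF")
        ]
        s = sample(clons)
        matches = track(specific, s)
        oracle_present = {t.junction_aa for t in specific} & set(junctions)
        assert {m.tcr.junction_aa for m in matches if m.count > 0} == oracle_present


class TestCumulative:
    def test_additivity_per_specificity(self):
        s = sample([Clonotype("CASSAF", 10), Clonotype("CASSBF", 10), Clonotype("CASSCF", 980)])
        cf = cumulative_frequency(
            [tcr("t1", "CASSAF", "neoA"), tcr("t2", "CASSBF", "neoA")], s
        )
        assert cf.total == pytest.approx(0.02)
        assert dict(cf.per_specificity)["neoA"] == pytest.approx(0.02)
        assert cf.n_tcrs_detected == 2 and cf.n_neoantigens_detected == 1

    def test_disjoint_set_is_zero(self):
        s = sample([Clonotype("CASSBF", 100)])
        cf = cumulative_frequency([tcr("t1", "CASSXF")], s)
        assert cf.total == 0.0 and cf.n_tcrs_detected == 0

    def test_total_never_exceeds_one_and_equals_specificity_sum(self):
        rng = np.random.default_rng(11)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(20):
            junctions = [
                "CASS" + "".join(rng.choice(aas, size=6)) + "F" for _ in range(200)
            ]
            clons = [Clonotype(j, int(rng.integers(1, 100))) for j in set(junctions)]
            specific = [
                tcr(f"t{i}", c.junction_aa, spec=f"neo{i % 4}")
                for i, c in enumerate(clons[:40])
            ]
            cf = cumulative_frequency(specific, sample(clons))
            assert 0.0 <= cf.total <= 1.0 + 1e-9
            assert cf.total == pytest.approx(sum(dict(cf.per_specificity).values()))


class TestBaselineStatus:
    def test_absent_at_baseline_is_de_novo(self):
        base = sample([Clonotype("CASSBF", 100)], timepoint=0)
        status = classify_baseline_status(
            [tcr("t1", "CASSXF"), tcr("t2", "CASSBF")], base
        )
        assert status == {"t1": "de_novo", "t2": "preexisting"}

    def test_missing_baseline_is_unknown(self):
        assert classify_baseline_status([tcr("t1", "CASSAF")], None) == {"t1": "unknown"}

    def test_planted_99_of_140_split_recovered_exactly(self):
        rng = np.random.default_rng(140)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        junctions = list({
            "CASS" + "".join(rng.choice(aas, size=8)) + "F" for _ in range(400)
        })[:140]
        specific = [tcr(f"t{i:03d}", j) for i, j in enumerate(junctions)]
        preexisting = set(rng.choice(140, size=41, replace=False))
        base_clons = [Clonotype("CASSFILLERF", 10_000)] + [
            Clonotype(junctions[i], 3) for i in preexisting
        ]
        status = classify_baseline_status(specific, sample(base_clons, timepoint=0))
        n_de_novo = sum(1 for v in status.values() if v == "de_novo")
        assert n_de_novo == 99
        assert all(
            (status[f"t{i:03d}"] == "preexisting") == (i in preexisting)
            for i in range(140)
        )


class TestBiopsyOverlap:
    def test_identical_samples_full_overlap(self):
        clons = [Clonotype("CASSAF", 5), Clonotype("CASSBF", 7)]
        spec = [tcr("t1", "CASSAF"), tcr("t2", "CASSBF")]
        ov = biopsy_overlap(sample(clons, "tumor"), sample(clons, "tumor"), spec)
        assert ov.jaccard == 1.0 and set(ov.shared) == {"t1", "t2"}

    def test_disjoint_detection_zero(self):
        a = sample([Clonotype("CASSAF", 5)], "tumor")
        b = sample([Clonotype("CASSBF", 5)], "tumor")
        spec = [tcr("t1", "CASSAF"), tcr("t2", "CASSBF")]
        assert biopsy_overlap(a, b, spec).jaccard == 0.0

    def test_subsample_matches_set_arithmetic_oracle(self):
        rng = np.random.default_rng(3)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        junctions = list({
            "CASS" + "".join(rng.choice(aas, size=6)) + "F" for _ in range(60)
        })
        spec = [tcr(f"t{i}", j) for i, j in enumerate(junctions)]
        full = [Clonotype(j, 10) for j in junctions]
        keep = rng.random(len(junctions)) < 0.5
        subset = [c for c, k in zip(full, keep) if k] or full[:1]
        ov = biopsy_overlap(sample(full, "tumor"), sample(subset, "tumor"), spec)
        a_set = set(junctions)
        b_set = {c.junction_aa for c in subset}
        assert ov.jaccard == pytest.approx(len(a_set & b_set) / len(a_set | b_set))
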