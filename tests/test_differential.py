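"""Ratios, classification, presence/absence, replicate QC and overlaps."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from glycodag.differential_abundance import (
    LABEL_DECREASED,
    LABEL_INCREASED,
    LABEL_ONLY_TREATED,
    LABEL_UNCHANGED,
    Thresholds,
    classify,
    compute_ratio,
    dag_table,
    overlap_analysis,
    presence_absence,
    replicate_qc,
)


class TestComputeRatio:
    def test_identical_abundances_give_unit_ratio(self):
        reps = np.array([1e6, 1.1e6, 0.9e6])
        ratio, _, p = compute_ratio(reps, reps, 1e6, 1e6)
        assert ratio == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_exact_doubling(self):
        c = np.array([1e6, 1e6, 1e6])
        ratio, sd, p = compute_ratio(c, 2 * c, 1e6, 2e6)
        assert ratio == pytest.approx(2.0)
        assert p == 0.0  # zero variance both sides, means differ
        assert sd == pytest.approx(0.0)

    def test_fourfold_with_tiny_jitter_is_significant(self):
        rng = np.random.default_rng(1)
        c = 1e6 * (1 + rng.normal(0, 1e-4, 3))
        t = 4e6 * (1 + rng.normal(0, 1e-4, 3))
        ratio, _, p = compute_ratio(c, t, c.mean(), t.mean())
        assert ratio == pytest.approx(4.0, rel=1e-3)
        assert p < 1e-6

    def test_ratio_sd_over_replicate_ratios(self):
        c = np.array([1e6, 1e6, 1e6])
        t = np.array([2e6, 4e6, 6e6])
        _, sd, _ = compute_ratio(c, t, 1e6, 4e6)
        assert sd == pytest.approx(np.std([2.0, 4.0, 6.0], ddof=1))

    def test_requires_positive_control_abundance(self):
        with pytest.raises(ValueError):
            compute_ratio(np.array([1.0]), np.array([1.0]), 0.0, 1.0)


class TestClassify:
    @pytest.mark.parametrize(
        "ratio,p,expected",
        [
            (3.74, 0.01, LABEL_INCREASED),  # strong up-regulation, significant
            (1.2, 0.001, LABEL_UNCHANGED),  # significant but below fold cut
            (0.5, 0.2, LABEL_UNCHANGED),  # big fold change, not significant
            (0.5, 0.01, LABEL_DECREASED),
            (1.5, 0.01, LABEL_INCREASED),  # inclusive boundary
            (0.67, 0.01, LABEL_DECREASED),
        ],
    )
    def test_rule(self, ratio, p, expected):
        assert classify(ratio, p) == expected

    def test_strict_thresholds_exclude_boundary(self):
        t = Thresholds(inclusive=False)
        assert classify(1.5, 0.01, t) == LABEL_UNCHANGED
        assert classify(0.67, 0.01, t) == LABEL_UNCHANGED

    @settings(derandomize=True, max_examples=100)
    @given(
        st.floats(0.01, 20.0),
        st.floats(0.01, 20.0),
        st.floats(0.0, 1.0, exclude_max=True),
    )
    def test_monotone_in_ratio(self, r1, r2, p):
        lo, hi = sorted((r1, r2))
        order = {LABEL_DECREASED: -1, LABEL_UNCHANGED: 0, LABEL_INCREASED: 1}
        assert order[classify(lo, p)] <= order[classify(hi, p)]

    def test_nan_p_never_regulated(self):
        assert classify(5.0, float("nan")) == LABEL_UNCHANGED


def _abundance_frames(data):
    """data: {(pid, geno, trt): [replicate abundances]} -> (cond, reps)."""
    cond_rows, rep_rows = [], []
    for (pid, geno, trt), vals in data.items():
        vals = np.asarray(vals, dtype=float)
        cond_rows.append(
            dict(protein_id=pid, genotype=geno, treatment=trt,
                 abundance=vals.mean())
        )
        for r, v in enumerate(vals, start=1):
            rep_rows.append(
                dict(protein_id=pid, genotype=geno, treatment=trt,
                     replicate=r, abundance=v)
            )
    return pd.DataFrame(cond_rows), pd.DataFrame(rep_rows)


class TestDagTable:
    def test_routes_one_sided_proteins_to_presence(self):
        cond, reps = _abundance_frames(
            {
                ("A", "WT", "control"): [1e6, 1.1e6, 0.9e6],
                ("A", "WT", "NaCl"): [4e6, 4.4e6, 3.6e6],
                ("B", "WT", "NaCl"): [1e6, 2e6],
            }
        )
        dag = dag_table(cond, reps)
        a = dag[dag["protein_id"] == "A"].iloc[0]
        b = dag[dag["protein_id"] == "B"].iloc[0]
        assert a["label"] == LABEL_INCREASED
        assert b["label"] == LABEL_ONLY_TREATED
        assert np.isnan(b["ratio"])
        pa = presence_absence(dag)
        assert pa["protein_id"].tolist() == ["B"]

    def test_scale_invariance(self):
        rng = np.random.default_rng(8)
        data = {}
        for pid in "ABCDEFGH":
            base = rng.uniform(1e5, 1e7)
            fc = rng.choice([1.0, 4.0])
            data[(pid, "WT", "control")] = base * (1 + rng.normal(0, 0.1, 3))
            data[(pid, "WT", "NaCl")] = base * fc * (1 + rng.normal(0, 0.1, 3))
        cond, reps = _abundance_frames(data)
        dag1 = dag_table(cond, reps)
        c = 137.0
        dag2 = dag_table(
            cond.assign(abundance=cond["abundance"] * c),
            reps.assign(abundance=reps["abundance"] * c),
        )
        assert dag1["label"].tolist() == dag2["label"].tolist()
        np.testing.assert_allclose(dag1["ratio"], dag2["ratio"])
        np.testing.assert_allclose(dag1["p_value"], dag2["p_value"])

    def test_welch_vs_student_configurable(self):
        cond, reps = _abundance_frames(
            {
                ("A", "WT", "control"): [1e6, 1.2e6, 0.8e6],
                ("A", "WT", "NaCl"): [2e6, 2.6e6, 1.4e6],
            }
        )
        p_w = dag_table(cond, reps, test="welch")["p_value"].iloc[0]
        p_s = dag_table(cond, reps, test="student")["p_value"].iloc[0]
        assert p_w != p_s  # different dof corrections


class TestReplicateQC:
    def _pep(self, mat, geno="WT", trt="control"):
        rows = []
        for pep_i, reps in enumerate(mat):
            for r, v in enumerate(reps, start=1):
                if v > 0:
                    rows.append(
                        dict(peptide_key=f"p{pep_i}", protein_id="P",
                             unique=True, genotype=geno, treatment=trt,
                             replicate=r, intensity=v)
                    )
        return pd.DataFrame(rows)

    def test_identical_replicates_r_one(self):
        mat = [(v, v, v) for v in (1e5, 3e6, 7e6, 2e7)]
        qc = replicate_qc(self._pep(mat))
        assert np.allclose(qc["pearson_r"], 1.0)
        assert not qc["flagged"].any()

    def test_scalar_multiple_r_one(self):
        mat = [(v, 3.7 * v, v) for v in (1e5, 3e6, 7e6, 2e7)]
        qc = replicate_qc(self._pep(mat))
        assert np.allclose(qc["pearson_r"], 1.0)

    def test_anti_ordered_ranks_negative(self):
        mat = [(1e5, 0, 1e7), (1e6, 0, 1e6), (1e7, 0, 1e5)]
        qc = replicate_qc(self._pep(mat))
        r13 = qc[(qc["replicate_a"] == 1) & (qc["replicate_b"] == 3)]
        assert r13["pearson_r"].iloc[0] < 0
        assert r13["flagged"].iloc[0]

    def test_insufficient_shared_peptides_reported_as_nan(self):
        mat = [(1e6, 0, 1e6), (0, 1e6, 1e6)]
        qc = replicate_qc(self._pep(mat))
        r12 = qc[(qc["replicate_a"] == 1) & (qc["replicate_b"] == 2)]
        assert np.isnan(r12["pearson_r"].iloc[0])
        assert r12["n_shared"].iloc[0] == 0


class TestOverlap:
    def test_three_way_intersection(self):
        sets = {"WT": {"A", "B"}, "mns": {"B", "C"}, "cgl": {"B"}}
        out = overlap_analysis(sets).set_index("genotypes")
        assert out.loc["WT&cgl&mns", "n_intersection"] == 1
        assert out.loc["WT&cgl&mns", "intersection_ids"] == "B"
        assert out.loc["WT", "n_exclusive"] == 1  # A only in WT

    def test_disjoint_sets(self):
        sets = {"WT": {"A"}, "mns": {"B"}}
        out = overlap_analysis(sets).set_index("genotypes")
        assert out.loc["WT&mns", "n_intersection"] == 0
        assert out.loc["WT", "n_exclusive"] == 1

    @settings(derandomize=True, max_examples=40)
    @given(
        st.sets(st.sampled_from([f"P{i}" for i in range(12)])),
        st.sets(st.sampled_from([f"P{i}" for i in range(12)])),
        st.sets(st.sampled_from([f"P{i}" for i in range(12)])),
    )
    def test_regions_partition_the_union(self, a, b, c):
        sets = {"g1": a, "g2": b, "g3": c}
        out = overlap_analysis(sets)
        exclusive_total = out["n_exclusive"].sum()
        union = a | b | c
        assert exclusive_total == len(union)
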