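"""Delta-Ct normalization and group statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pexvote import ClinicalTable, auc_mann_whitney
from pexvote.errors import ValidationError
from pexvote.normalize import (
    compare_raw_ct,
    delta_ct,
    group_logfc,
    log2_cpm,
)

from conftest import make_clinical_frame


def _table(frame):
    genes = tuple(c[:-3] for c in frame.columns if c.endswith("_ct"))
    return ClinicalTable(frame=frame, genes=genes)


class TestDeltaCt:
    def test_self_normalization_is_zero(self):
        frame = make_clinical_frame(n=4)
        frame["HLA-E_ct"] = frame["GAPDH_ct"]
        mat = delta_ct(_table(frame), "GAPDH")
        assert (mat["HLA-E"] == 0).all()

    def test_arithmetic(self):
        frame = make_clinical_frame(n=1)
        frame["GAPDH_ct"] = 20.0
        frame["HLA-E_ct"] = 24.0
        mat = delta_ct(_table(frame), "GAPDH")
        assert mat["HLA-E"].iloc[0] == -4.0

    def test_reference_gene_excluded(self, small_table):
        mat = delta_ct(small_table, "GAPDH")
        assert "GAPDH" not in mat.columns

    def test_missing_reference_names_patient(self):
        frame = make_clinical_frame(n=3)
        frame.loc[1, "GAPDH_ct"] = np.nan
        with pytest.raises(ValidationError, match="P001"):
            delta_ct(_table(frame), "GAPDH")

    @given(st.floats(-5, 5))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_global_ct_shift_invariance(self, c):
        frame = make_clinical_frame(n=6)
        base = delta_ct(_table(frame), "GAPDH")
        shifted = frame.copy()
        for col in ("GAPDH_ct", "HLA-E_ct", "RABL2B_ct"):
            shifted[col] = shifted[col] + c
        moved = delta_ct(_table(shifted), "GAPDH")
        pd.testing.assert_frame_equal(base, moved, atol=1e-9, rtol=0)

    def test_auc_invariant_under_exponentiation(self):
        """AUC on -dCt equals AUC on 2^-dCt for any labeling (the scale
        choice cannot change classification)."""
        rng = np.random.default_rng(0)
        frame = make_clinical_frame(n=30, seed=1)
        mat = delta_ct(_table(frame), "GAPDH")
        labels = rng.integers(0, 2, 30)
        labels[0], labels[1] = 0, 1
        v = mat["HLA-E"].to_numpy()
        assert auc_mann_whitney(v, labels) == pytest.approx(
            auc_mann_whitney(2.0 ** v, labels), abs=1e-12)


class TestCompareRawCt:
    def test_identical_groups_null(self):
        frame = make_clinical_frame(n=12)
        resp = frame["bor"].isin(["CR", "PR"])
        vals = frame.loc[resp, "HLA-E_ct"].to_numpy()
        frame["HLA-E_ct"] = np.resize(vals, len(frame))  # same values both groups
        frame.loc[resp, "HLA-E_ct"] = vals
        stat = compare_raw_ct(_table(frame), "HLA-E")
        assert stat.p_value > 0.5  # no separation

    def test_three_sd_shift_detected(self):
        rng = np.random.default_rng(0)
        frame = make_clinical_frame(n=100, seed=2)
        frame["bor"] = ["CR"] * 10 + ["PR"] * 10 + ["PD"] * 80
        frame["HLA-E_ct"] = rng.normal(25, 1, 100)
        frame.loc[frame["bor"].isin(["CR", "PR"]), "HLA-E_ct"] += 3.0
        assert compare_raw_ct(_table(frame), "HLA-E").p_value < 0.001

    def test_constant_group_finite_p(self):
        frame = make_clinical_frame(n=12)
        resp = frame["bor"].isin(["CR", "PR"])
        frame.loc[resp, "HLA-E_ct"] = 25.0  # degenerate variance on one side
        stat = compare_raw_ct(_table(frame), "HLA-E")
        assert np.isfinite(stat.p_value)

    def test_small_group_rejected(self):
        frame = make_clinical_frame(n=6)
        frame["bor"] = ["CR", "PD", "PD", "PD", "PD", "PD"]
        with pytest.raises(ValidationError):
            compare_raw_ct(_table(frame), "HLA-E")

    def test_welch_p_matches_permutation(self):
        """Welch p tracks a 10,000-draw permutation p (Welch-t statistic)
        on n=6/6 fixtures. Individual draws can deviate by ~0.03 because
        the t reference is itself an approximation at this n, so the
        check bounds the mean deviation over six fixed fixtures."""

        def welch_t(a, b):
            va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
            return abs(a.mean() - b.mean()) / np.sqrt(va + vb)

        deviations = []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            a = rng.normal(0, 1, 6)
            b = rng.normal(0.8, 1.2, 6)
            frame = make_clinical_frame(n=12)
            frame["bor"] = ["CR"] * 6 + ["PD"] * 6
            frame["HLA-E_ct"] = np.r_[a, b]
            p_welch = compare_raw_ct(_table(frame), "HLA-E").p_value

            pooled = np.r_[a, b]
            obs = welch_t(a, b)
            perm_rng = np.random.default_rng(1000 + seed)
            count = 0
            for _ in range(10_000):
                perm = perm_rng.permutation(pooled)
                count += welch_t(perm[:6], perm[6:]) >= obs - 1e-12
            deviations.append(abs(p_welch - count / 10_000))
        assert np.mean(deviations) < 0.02
        assert max(deviations) < 0.05


class TestLog2Cpm:
    def test_single_gene_whole_library(self):
        counts = pd.DataFrame({"S1": [50, 0]}, index=["G1", "G2"])
        out = log2_cpm(counts)
        assert out.loc["G1", "S1"] == pytest.approx(np.log2(1e6 + 1))
        assert out.loc["G2", "S1"] == 0.0

    def test_library_scale_invariance(self):
        counts = pd.DataFrame({"S1": [10, 30, 60]}, index=["G1", "G2", "G3"])
        doubled = counts * 2
        pd.testing.assert_frame_equal(log2_cpm(counts), log2_cpm(doubled))

    def test_cpm_sums_to_million(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 500, (40, 3)))
        total = (2.0 ** log2_cpm(counts) - 1.0).sum(axis=0)
        assert np.allclose(total, 1e6, rtol=1e-6)

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"S1": [1, 2], "S2": [0, 0]}, index=["G1", "G2"])
        with pytest.raises(ValidationError, match="S2"):
            log2_cpm(counts)


class TestGroupLogfc:
    def _expr(self, values_by_group):
        cols, data = [], []
        for grp, vals in values_by_group.items():
            for i, v in enumerate(vals):
                cols.append(f"{grp}{i}")
                data.append(v)
        expr = pd.DataFrame([data], index=["G1"], columns=cols)
        labels = pd.Series([c.rstrip("0123456789") for c in cols], index=cols)
        return expr, labels

    def test_identical_groups_zero_lfc(self):
        expr, labels = self._expr({"PR": [5, 6, 7], "PD": [5, 6, 7]})
        res = group_logfc(expr, labels, "PR_vs_PD")
        assert res.loc["G1", "log2_fc"] == 0.0

    def test_planted_fourfold_gene(self):
        rng = np.random.default_rng(0)
        pr = rng.normal(10, 0.1, 200)
        pd_vals = rng.normal(8, 0.1, 200)  # 2 log2 units below
        expr, labels = self._expr({"PR": pr, "PD": pd_vals})
        res = group_logfc(expr, labels, "PR_vs_PD")
        assert res.loc["G1", "log2_fc"] == pytest.approx(2.0, abs=0.05)

    def test_prsd_grouping_puts_sd_with_pr(self):
        # SD samples look like PR; if SD sits on PR's side the contrast
        # PR/SD-vs-PD stays large, and PR-vs-SD/PD is diluted
        expr, labels = self._expr({"PR": [10, 10.1, 9.9], "SD": [10, 10.2, 9.8],
                                   "PD": [8, 8.1, 7.9]})
        lfc_prsd = group_logfc(expr, labels, "PRSD_vs_PD").loc["G1", "log2_fc"]
        lfc_pr_sdpd = group_logfc(expr, labels, "PR_vs_SDPD").loc["G1", "log2_fc"]
        assert lfc_prsd == pytest.approx(2.0, abs=0.1)
        assert lfc_pr_sdpd < 1.2

    def test_empty_group_named(self):
        expr, labels = self._expr({"PR": [1, 2, 3], "SD": [1, 2, 3]})
        with pytest.raises(ValidationError, match="PR_vs_PD"):
            group_logfc(expr, labels, "PR_vs_PD")
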