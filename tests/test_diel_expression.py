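"""Normalization, filtering, outlier screening, regression screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quillcycle import diel_expression as de


def _cm(counts, lengths=None, tps=None):
    counts = pd.DataFrame(counts)
    counts.index = [f"g{i}" for i in range(counts.shape[0])]
    counts.columns = [f"s{j}" for j in range(counts.shape[1])]
    if lengths is None:
        lengths = pd.Series(1000.0, index=counts.index)
    else:
        lengths = pd.Series(lengths, index=counts.index)
    if tps is None:
        tps = list(range(counts.shape[1]))
    design = pd.DataFrame({"zt_hour": tps, "replicate": 1}, index=counts.columns)
    return de.CountMatrix(counts, design, lengths)


class TestTpm:
    def test_single_gene_gets_the_full_million(self):
        tpm = de.compute_tpm(_cm([[7, 3]]))
        assert np.allclose(tpm.values.values, 1e6)

    def test_two_gene_length_normalization(self):
        # counts 10/10 at lengths 1000/2000 -> rates 0.01/0.005
        tpm = de.compute_tpm(_cm([[10], [10]], lengths=[1000, 2000]))
        assert tpm.values.iloc[0, 0] == pytest.approx(666666.6667, rel=1e-6)
        assert tpm.values.iloc[1, 0] == pytest.approx(333333.3333, rel=1e-6)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.lists(st.lists(st.integers(0, 500), min_size=3, max_size=3),
                    min_size=2, max_size=8))
    def test_columns_sum_to_a_million(self, rows):
        if not any(any(r) for r in rows):
            return
        counts = np.array(rows)
        counts[0] += 1  # keep libraries nonzero
        tpm = de.compute_tpm(_cm(counts))
        assert np.allclose(tpm.values.sum(axis=0), 1e6, rtol=1e-9)

    def test_zero_library_names_the_sample(self):
        with pytest.raises(ValueError, match="s1"):
            de.compute_tpm(_cm([[3, 0], [2, 0]]))


class TestFilterExpressed:
    def test_all_zero_gene_filtered_and_boundary_kept(self):
        vals = pd.DataFrame({"s0": [0.0, 1.0, 0.5], "s1": [0.0, 1.0, 0.7]},
                            index=["dead", "boundary", "low"])
        expr = de.ExpressionMatrix(vals, "TPM")
        kept = de.filter_expressed(expr)
        assert kept == ["boundary"]

    def test_requires_tpm_scale(self):
        expr = de.ExpressionMatrix(pd.DataFrame({"s": [1.0]}, index=["g"]), "log2-CPM")
        with pytest.raises(ValueError, match="TPM"):
            de.filter_expressed(expr)

    def test_recovers_designed_expressed_fraction(self):
        from quillcycle import synthdata
        d2 = synthdata.SyntheticDesign(n_genes=300, n_contigs=3,
                                       low_expr_fraction=0.2, seed=33)
        _, ann, _ = synthdata.generate_genome_annotation(d2)
        cm, _ = synthdata.generate_diel_counts(d2, ann)
        kept = de.filter_expressed(de.compute_tpm(cm))
        frac = len(kept) / len(cm.counts)
        assert 0.75 <= frac <= 0.85


class TestMedianOfRatios:
    def test_identical_columns_unit_factors(self):
        _, sf = de.median_of_ratios_normalize(_cm([[10, 10], [4, 4], [7, 7]]))
        assert np.allclose(sf.values, 1.0)

    def test_doubled_column_doubles_factor(self):
        base = np.array([[10], [40], [25], [8]])
        counts = np.hstack([base, base * 2])
        _, sf = de.median_of_ratios_normalize(_cm(counts))
        assert sf["s1"] / sf["s0"] == pytest.approx(2.0)

    def test_idempotence(self, rng):
        counts = rng.integers(1, 400, size=(30, 6))
        norm, _ = de.median_of_ratios_normalize(_cm(counts))
        renorm = de.CountMatrix(
            norm.values, _cm(counts).design,
            pd.Series(1000.0, index=norm.values.index))
        _, sf2 = de.median_of_ratios_normalize(renorm)
        assert np.allclose(sf2.values, 1.0, atol=1e-12)

    def test_no_universal_gene_is_an_error(self):
        with pytest.raises(ValueError, match="pseudo-reference"):
            de.median_of_ratios_normalize(_cm([[5, 0], [0, 5]]))


class TestTmm:
    def test_identical_columns_unit_factors(self):
        _, f = de.cpm_tmm(_cm(np.tile([[10], [50], [200], [7]], (1, 4))))
        assert np.allclose(f.values, 1.0)

    def test_permutation_equivariance(self, rng):
        counts = rng.integers(1, 500, size=(40, 4))
        _, f = de.cpm_tmm(_cm(counts))
        perm = [2, 0, 3, 1]
        _, fp = de.cpm_tmm(_cm(counts[:, perm]))
        assert np.allclose(fp.values, f.values[perm], rtol=1e-12)

    def test_depth_doubling_keeps_factor_and_cpm(self, rng):
        base = rng.integers(10, 500, size=(50, 1))
        counts = np.hstack([base, base * 2, rng.integers(10, 500, size=(50, 1))])
        logcpm, f = de.cpm_tmm(_cm(counts))
        assert f["s1"] == pytest.approx(f["s0"], rel=1e-9)
        assert np.allclose(logcpm.values["s0"], logcpm.values["s1"], atol=1e-6)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            de.cpm_tmm(_cm([[5], [6]]))


class TestMdsOutliers:
    def _expr(self, values, tps):
        vals = pd.DataFrame(np.asarray(values, float))
        vals.index = [f"g{i}" for i in range(vals.shape[0])]
        vals.columns = [f"s{j}" for j in range(vals.shape[1])]
        design = pd.DataFrame({"zt_hour": tps, "replicate": 1}, index=vals.columns)
        return de.ExpressionMatrix(vals, "TPM"), design

    def test_identical_replicates_no_flags(self, rng):
        block = rng.uniform(0, 100, size=(30, 4))
        values = np.repeat(block, 2, axis=1)  # 2 identical replicates per tp
        expr, design = self._expr(values, np.repeat(np.arange(4) * 3, 2))
        report = de.mds_outlier_screen(expr, design)
        assert not report.flagged.any()

    def test_planted_outlier_flagged(self, rng):
        base = rng.uniform(0, 200, size=(60, 1))
        cols, tps = [], []
        for t in range(5):
            shift = base[:, 0] * (1 + 0.02 * t)
            for r in range(3):
                cols.append(shift + rng.normal(0, 0.5, 60))
                tps.append(t * 3)
        values = np.column_stack(cols)
        values[:, 7] = rng.permutation(values[:, 7])  # scramble one sample
        expr, design = self._expr(values, tps)
        report = de.mds_outlier_screen(expr, design)
        # the planted sample is flagged and is the most extreme; an
        # extreme outlier can also drag its replicate mates' mean
        # centroid, so other flags are permitted but must be milder
        assert report.flagged.iloc[7]
        assert report.centroid_distance.idxmax() == report.flagged.index[7]

    def test_outlier_removal_keeps_gene_filter_stable(self, rng):
        base = rng.uniform(2, 200, size=(40, 1))
        values = np.repeat(base, 6, axis=1)
        values[:, 2] *= 40  # one wild sample
        expr, design = self._expr(values, np.repeat([0, 3, 6], 2))
        report = de.mds_outlier_screen(expr, design)
        kept_all = de.filter_expressed(de.ExpressionMatrix(
            expr.values.div(expr.values.sum(0), axis=1) * 1e6, "TPM"))
        keep = [s for s in expr.values.columns if s not in report.flagged_samples]
        reduced = expr.values[keep]
        kept_red = de.filter_expressed(de.ExpressionMatrix(
            reduced.div(reduced.sum(0), axis=1) * 1e6, "TPM"))
        assert kept_all == kept_red


class TestRegressionScreen:
    def _expr(self, values, tps):
        vals = pd.DataFrame(np.asarray(values, float))
        vals.index = [f"g{i}" for i in range(vals.shape[0])]
        vals.columns = [f"s{j}" for j in range(vals.shape[1])]
        design = pd.DataFrame({"zt_hour": tps, "replicate": 1}, index=vals.columns)
        return de.ExpressionMatrix(vals, "TPM"), design

    def test_constant_gene_is_null(self):
        tps = [1, 4, 7, 10, 13, 16]
        expr, design = self._expr([[5.0] * 6], tps)
        res = de.regression_screen(expr, design)
        assert res["F"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0
        assert not res["significant"].iloc[0]

    def test_strong_quadratic_is_significant(self, rng):
        tps = np.array([1, 4, 7, 10, 13, 16, 19, 22, 25, 28], float)
        y = 3 + 2 * tps - 0.1 * tps ** 2 + rng.normal(0, 1e-6, len(tps))
        expr, design = self._expr([y], tps)
        res = de.regression_screen(expr, design)
        assert res["p"].iloc[0] < 1e-10

    def test_oracle_matches_statsmodels_f_test(self, rng):
        import statsmodels.api as sm
        tps = np.array([1, 4, 7, 10, 13, 16, 19, 22, 25, 28], float)
        y = rng.normal(10, 2, size=(5, len(tps)))
        expr, design = self._expr(y, tps)
        res = de.regression_screen(expr, design)
        X = sm.add_constant(np.column_stack([tps, tps ** 2]))
        for i in range(5):
            fit = sm.OLS(y[i], X).fit()
            assert res["F"].iloc[i] == pytest.approx(fit.fvalue, rel=1e-9)
            assert res["p"].iloc[i] == pytest.approx(fit.f_pvalue, rel=1e-9, abs=1e-12)

    def test_too_few_timepoints_rejected(self):
        expr, design = self._expr([[1.0, 2.0, 3.0]], [0, 3, 6])
        with pytest.raises(ValueError, match="distinct timepoints"):
            de.regression_screen(expr, design)
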