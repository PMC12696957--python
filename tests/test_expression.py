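"""Normalization, GLM fitting and the DMS/expression join."""

import math

import numpy as np
import pandas as pd
import pytest

from methylmorph import expression
from methylmorph.diffmeth import DMSRecord
from methylmorph.formats import Gene, GenomeAnnotation


def counts_frame(arr, samples, genes=None):
    genes = genes or [f"g{i+1}" for i in range(len(arr))]
    return pd.DataFrame(arr, index=genes, columns=samples)


SAMPLES6 = ["embryo_1", "embryo_2", "embryo_3", "larva_1", "larva_2", "larva_3"]


class TestSizeFactors:
    def test_identical_samples_equal_factors(self):
        df = counts_frame([[10] * 6, [20] * 6], SAMPLES6)
        sf = expression.size_factors(df)
        assert np.allclose(sf, sf.iloc[0])

    def test_scaled_sample_scaled_factor(self):
        rng = np.random.default_rng(3)
        base = rng.integers(5, 100, size=30)
        df = counts_frame(
            np.column_stack([base, base * 2]), ["embryo_1", "embryo_2"]
        )
        sf = expression.size_factors(df)
        assert sf["embryo_2"] / sf["embryo_1"] == pytest.approx(2.0, abs=1e-9)

    def test_matches_brute_force_median_of_ratios(self):
        rng = np.random.default_rng(4)
        df = counts_frame(rng.integers(1, 200, size=(20, 6)), SAMPLES6)
        sf = expression.size_factors(df)
        # independent oracle: literal median of count/geomean ratios
        logs = np.log(df.to_numpy(dtype=float))
        geo = np.exp(logs.mean(axis=1))
        for j, s in enumerate(df.columns):
            expected = np.median(df.to_numpy()[:, j] / geo)
            assert sf[s] == pytest.approx(expected, rel=1e-9)

    def test_no_universal_gene_is_error(self):
        df = counts_frame([[0, 5], [5, 0]], ["embryo_1", "larva_1"])
        with pytest.raises(ValueError):
            expression.size_factors(df)


class TestFpm:
    def test_single_gene(self):
        df = counts_frame([[10]], ["embryo_1"])
        assert expression.fpm(df).iloc[0, 0] == pytest.approx(1e6)

    def test_columns_sum_to_million(self):
        rng = np.random.default_rng(5)
        df = counts_frame(rng.integers(0, 500, size=(40, 6)) + 1, SAMPLES6)
        sums = expression.fpm(df).sum(axis=0)
        assert np.allclose(sums, 1e6)

    def test_depth_invariance(self):
        rng = np.random.default_rng(6)
        df = counts_frame(rng.integers(1, 500, size=(10, 2)), ["embryo_1", "larva_1"])
        doubled = df.copy()
        doubled["embryo_1"] *= 2
        pd.testing.assert_frame_equal(expression.fpm(df), expression.fpm(doubled))


class TestLfc:
    def test_equal_means_zero(self):
        df = counts_frame([[10, 10, 10, 10, 10, 10]], SAMPLES6)
        assert expression.compute_lfc(df, "embryo", "larva").iloc[0] == 0.0

    def test_hand_value(self):
        df = counts_frame([[10, 10, 10, 40, 40, 40]], SAMPLES6)
        lfc = expression.compute_lfc(df, "embryo", "larva").iloc[0]
        assert lfc == pytest.approx(math.log2(41 / 11), abs=1e-12)
        assert lfc == pytest.approx(1.898, abs=1e-3)

    def test_antisymmetry(self):
        rng = np.random.default_rng(7)
        df = counts_frame(rng.integers(0, 300, size=(25, 6)), SAMPLES6)
        ab = expression.compute_lfc(df, "embryo", "larva")
        ba = expression.compute_lfc(df, "larva", "embryo")
        assert np.allclose(ab, -ba)


class TestFitModel:
    def lfc_table(self, seed=0, slope=0.0, noise=1.0):
        rng = np.random.default_rng(seed)
        n = 200
        rows = []
        for comp in ("embryo_vs_larva", "larva_vs_prepupa"):
            n_dms = rng.poisson(3, n)
            lfc = slope * n_dms + rng.normal(0, noise, n)
            rows += [{"comparison": comp, "n_dms": int(d), "lfc": float(l)}
                     for d, l in zip(n_dms, lfc)]
        return pd.DataFrame(rows)

    def test_null_has_small_pseudo_r2(self):
        fit = expression.fit_model(4, self.lfc_table(seed=8))
        assert fit.pseudo_r2 < 5
        assert fit.p_value > 0.05

    def test_saturated_gaussian_pseudo_r2_100(self):
        tbl = self.lfc_table(seed=9, slope=0.5, noise=0.0)
        fit = expression.fit_model(4, tbl)
        assert fit.pseudo_r2 == pytest.approx(100.0, abs=1e-6)

    def test_gaussian_matches_closed_form_least_squares(self):
        tbl = self.lfc_table(seed=10, slope=0.3)
        fit = expression.fit_model(4, tbl)
        X = np.column_stack(
            [
                np.ones(len(tbl)),
                (tbl["comparison"] == "larva_vs_prepupa").to_numpy(float),
                tbl["n_dms"].to_numpy(float),
                tbl["n_dms"].to_numpy(float)
                * (tbl["comparison"] == "larva_vs_prepupa").to_numpy(float),
            ]
        )
        beta = np.linalg.lstsq(X, tbl["lfc"].to_numpy(), rcond=None)[0]
        assert fit.params["n_dms"] == pytest.approx(beta[2], abs=1e-8)
        assert fit.params["Intercept"] == pytest.approx(beta[0], abs=1e-8)

    def test_quasipoisson_coefficients_equal_poisson(self):
        rng = np.random.default_rng(11)
        tbl = pd.DataFrame(
            {
                "meth_pct": rng.uniform(0, 100, 300),
                "stage": rng.choice(["embryo", "larva", "pupa"], 300),
            }
        )
        tbl["counts"] = rng.poisson(np.exp(2 + 0.01 * tbl["meth_pct"]))
        fit = expression.fit_model(1, tbl)
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        pois = smf.glm(
            "counts ~ meth_pct * stage", data=tbl, family=sm.families.Poisson()
        ).fit()
        for name in fit.params.index:
            assert fit.params[name] == pytest.approx(pois.params[name], abs=1e-6)
        # dispersion scales only the standard errors
        assert np.allclose(fit.bse, pois.bse * np.sqrt(fit.dispersion))

    def test_pseudo_r2_invariant_to_predictor_rescaling(self):
        tbl = self.lfc_table(seed=12, slope=0.3)
        fit1 = expression.fit_model(4, tbl)
        tbl2 = tbl.assign(n_dms=tbl["n_dms"] * 1000.0)
        fit2 = expression.fit_model(4, tbl2)
        assert fit1.pseudo_r2 == pytest.approx(fit2.pseudo_r2, abs=1e-8)

    def test_missing_column_is_error(self):
        with pytest.raises(ValueError, match="lacks columns"):
            expression.fit_model(1, pd.DataFrame({"counts": [1, 2]}))


class TestMethylationClassModel:
    def test_consistent_with_fit_model(self):
        rng = np.random.default_rng(13)
        genes = [f"g{i}" for i in range(30)]
        counts = counts_frame(rng.poisson(50, size=(30, 6)), SAMPLES6, genes)
        classes = {g: ("high" if i % 2 else "low") for i, g in enumerate(genes)}
        fit = expression.methylation_class_model(counts, classes)
        tbl = expression.assemble_counts_table(counts, {g: np.nan for g in genes})
        tbl["meth_class"] = tbl["gene_id"].map(classes)
        direct = expression.fit_model(3, tbl)
        assert fit.chisq == pytest.approx(direct.chisq)
        assert np.allclose(fit.params, direct.params)

    def test_single_class_reduces_to_stage_only(self):
        rng = np.random.default_rng(14)
        genes = [f"g{i}" for i in range(10)]
        counts = counts_frame(rng.poisson(50, size=(10, 6)), SAMPLES6, genes)
        classes = {g: "low" for g in genes}
        with pytest.warns(UserWarning, match="absent"):
            fit = expression.methylation_class_model(counts, classes)
        # one class level: only intercept + stage terms remain estimable
        nonzero = [n for n in fit.params.index if abs(fit.params[n]) > 1e-10]
        assert len(nonzero) <= 2  # intercept + larva offset

    def test_planted_class_effect_detected(self):
        rng = np.random.default_rng(15)
        genes = [f"g{i}" for i in range(40)]
        classes = {g: ("high" if i < 20 else "low") for i, g in enumerate(genes)}
        mus = [100 if classes[g] == "high" else 50 for g in genes]
        counts = counts_frame(
            rng.poisson(np.repeat(mus, 6).reshape(40, 6)), SAMPLES6, genes
        )
        fit = expression.methylation_class_model(counts, classes)
        assert fit.params["meth_class[T.low]"] < 0
        assert fit.p_value < 0.05


class TestStageContrasts:
    def test_equal_means_contrast_zero(self):
        df = counts_frame([[5, 5, 5, 5, 5, 5]], SAMPLES6, ["tet"])
        res = expression.stage_contrasts(df)
        row = res.iloc[0]
        assert row["estimate"] == 0.0
        assert row["p"] == pytest.approx(1.0)

    def test_matches_pooled_t_test(self):
        rng = np.random.default_rng(16)
        vals = rng.normal(100, 10, 6).round().astype(int)
        df = counts_frame([vals], SAMPLES6, ["tet"])
        res = expression.stage_contrasts(df).iloc[0]
        a, b = vals[:3].astype(float), vals[3:].astype(float)
        sp2 = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        sp2 /= len(a) + len(b) - 2
        se = math.sqrt(sp2 * (1 / 3 + 1 / 3))
        t = (a.mean() - b.mean()) / se
        assert res["estimate"] == pytest.approx(a.mean() - b.mean(), abs=1e-9)
        assert res["se"] == pytest.approx(se, abs=1e-9)
        assert res["t"] == pytest.approx(t, abs=1e-9)

    def test_contrast_antisymmetry_under_relabeling(self):
        rng = np.random.default_rng(17)
        df = counts_frame([rng.integers(10, 100, 6)], SAMPLES6, ["tet"])
        res = expression.stage_contrasts(df).iloc[0]
        swapped = df.copy()
        swapped.columns = ["larva_1", "larva_2", "larva_3", "embryo_1", "embryo_2", "embryo_3"]
        res2 = expression.stage_contrasts(swapped).iloc[0]
        assert res["estimate"] == pytest.approx(-res2["estimate"])

    def test_pooled_variance_uses_all_genes(self):
        rng = np.random.default_rng(18)
        df = counts_frame(rng.integers(10, 100, size=(3, 6)), SAMPLES6)
        res = expression.stage_contrasts(df)
        assert res["df"].nunique() == 1
        assert res["df"].iloc[0] == 18 - 6  # N - cells


ANN = GenomeAnnotation(genes=[Gene("gA", "chr1", 100, 400, "+"),
                              Gene("gB", "chr1", 900, 1200, "+")])


class TestDmsExpressionJoin:
    def dms(self, pos, sig=True):
        return DMSRecord("chr1", pos, 50.0, 0.001, sig, "hyper_stage2")

    def test_all_flagged_de_gives_fraction_one(self):
        join = expression.dms_expression_join(
            [self.dms(120), self.dms(950)], ANN, {"gA": True, "gB": True}
        )
        assert join.fraction == 1.0
        assert join.n_total == 2

    def test_no_significant_dms_is_error(self):
        with pytest.raises(ValueError, match="denominator"):
            expression.dms_expression_join([self.dms(120, sig=False)], ANN, {})

    def test_counts_match_flags(self):
        join = expression.dms_expression_join(
            [self.dms(120), self.dms(950)], ANN, {"gA": True, "gB": False}
        )
        assert (join.n_de, join.n_total) == (1, 2)


def test_de_flags_detect_strong_change():
    rng = np.random.default_rng(19)
    arr = np.vstack(
        [
            np.concatenate([rng.poisson(200, 3), rng.poisson(20, 3)]),
            np.concatenate([rng.poisson(50, 3), rng.poisson(50, 3)]),
        ]
    )
    df = counts_frame(arr, SAMPLES6, ["changed", "flat"])
    flags = expression.de_flags(df, "embryo", "larva")
    assert flags["changed"] is True
    assert flags["flat"] in (True, False)  # weak screen may or may not flag noise
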