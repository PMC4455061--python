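"""NB dispersion estimation, Wald testing, multiple testing, classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from riboflow.de import (
    adjust_and_call,
    average_rna_fc,
    classify_genes,
    estimate_dispersion,
    fc_correlation,
    nb_wald_test,
)
from riboflow.prep import SizeFactors
from tests.conftest import make_counts


def _nb_matrix(mu, alpha, n_per_group, seed, log2fc=0.0):
    rng = np.random.default_rng(seed)
    n_genes = len(mu)
    mu = np.asarray(mu, dtype=float)
    half = 2.0 ** (np.asarray(log2fc) / 2.0)
    mu_mat = np.concatenate(
        [np.tile((mu / half)[:, None], (1, n_per_group)),
         np.tile((mu * half)[:, None], (1, n_per_group))], axis=1
    )
    if alpha > 0:
        lam = rng.gamma(1 / alpha, mu_mat * alpha)
    else:
        lam = mu_mat
    vals = rng.poisson(lam)
    return make_counts(vals, ["BN"] * n_per_group + ["SHR"] * n_per_group)


unit_sf = lambda cm: SizeFactors(pd.Series(1.0, index=cm.samples))


class TestDispersion:
    def test_poisson_counts_give_near_zero_dispersion(self):
        cm = _nb_matrix([1000.0] * 800, 0.0, 5, seed=1)
        alpha = estimate_dispersion(cm, cm.strain_indicator(), unit_sf(cm))
        assert alpha.median() <= 0.01

    def test_moderate_dispersion_recovered(self):
        cm = _nb_matrix([500.0] * 1000, 0.1, 5, seed=2)
        alpha = estimate_dispersion(cm, cm.strain_indicator(), unit_sf(cm))
        assert 0.05 <= alpha.median() <= 0.2

    def test_constant_counts_hit_floor(self):
        cm = make_counts(np.full((3, 6), 7), ["BN"] * 3 + ["SHR"] * 3)
        alpha = estimate_dispersion(cm, cm.strain_indicator(), unit_sf(cm))
        assert (alpha == 1e-8).all()

    def test_all_zero_gene_not_testable(self):
        vals = np.vstack([np.zeros(6), np.full(6, 50)])
        cm = make_counts(vals, ["BN"] * 3 + ["SHR"] * 3)
        alpha = estimate_dispersion(cm, cm.strain_indicator(), unit_sf(cm))
        assert np.isnan(alpha.iloc[0]) and np.isfinite(alpha.iloc[1])

    def test_shrinkage_tightens_spread_around_truth(self):
        cm = _nb_matrix([300.0] * 1500, 0.05, 5, seed=3)
        g = cm.strain_indicator()
        raw = estimate_dispersion(cm, g, unit_sf(cm))
        mod = estimate_dispersion(cm, g, unit_sf(cm), shrink=True)
        err = lambda a: np.abs(np.log(a / 0.05)).median()
        assert err(mod) < err(raw)


class TestWald:
    def test_identical_group_means_null(self):
        vals = np.tile([[40, 80, 120]], (2, 1)).T  # same counts in both groups
        cm = make_counts(np.hstack([vals, vals]), ["BN"] * 2 + ["SHR"] * 2)
        de = nb_wald_test(cm, unit_sf(cm), pd.Series(0.05, index=cm.genes))
        np.testing.assert_allclose(de["log2fc"], 0.0, atol=1e-8)
        np.testing.assert_allclose(de["pvalue"], 1.0, atol=1e-6)

    def test_null_pvalues_uniform(self):
        cm = _nb_matrix([400.0] * 2000, 0.05, 5, seed=4)
        disp = estimate_dispersion(cm, cm.strain_indicator(), unit_sf(cm), shrink=True)
        de = nb_wald_test(cm, unit_sf(cm), disp)
        ks = stats.kstest(de["pvalue"].dropna(), "uniform")
        assert ks.pvalue > 0.01

    def test_power_on_strong_effects(self):
        # two-fold effects at high depth and modest dispersion are nearly
        # always detected at Bonferroni 0.01
        cm = _nb_matrix([5000.0] * 200, 0.02, 5, seed=5, log2fc=1.0)
        disp = estimate_dispersion(cm, cm.strain_indicator(), unit_sf(cm), shrink=True)
        de = adjust_and_call(nb_wald_test(cm, unit_sf(cm), disp), "bonferroni", 0.01)
        assert de["de"].mean() > 0.9
        assert de["log2fc"].median() == pytest.approx(1.0, abs=0.05)


class TestAdjust:
    def test_bonferroni_closed_form(self):
        de = pd.DataFrame({"pvalue": [0.001] + [0.5] * 9, "testable": True})
        out = adjust_and_call(de, "bonferroni", 0.01)
        assert out["padj"].iloc[0] == pytest.approx(0.01)
        assert out["de"].iloc[0]
        assert not out["de"].iloc[1:].any()

    def test_bh_step_up(self):
        de = pd.DataFrame({"pvalue": [0.01, 0.02, 0.03, 1.0], "testable": True})
        out = adjust_and_call(de, "BH", 0.05)
        np.testing.assert_allclose(out["padj"], [0.04, 0.04, 0.04, 1.0])

    def test_all_ones_no_flags(self):
        de = pd.DataFrame({"pvalue": np.ones(5), "testable": True})
        assert not adjust_and_call(de, "bonferroni", 0.01)["de"].any()

    def test_threshold_validated(self):
        de = pd.DataFrame({"pvalue": [0.5], "testable": True})
        with pytest.raises(ValueError, match="threshold"):
            adjust_and_call(de, "bonferroni", 1.5)

    def test_non_testable_excluded_from_denominator(self):
        de = pd.DataFrame(
            {"pvalue": [0.004, np.nan, np.nan, np.nan], "testable": [True] + [False] * 3}
        )
        out = adjust_and_call(de, "bonferroni", 0.01)
        assert out["padj"].iloc[0] == pytest.approx(0.004)  # m = 1, not 4


class TestClassification:
    def _de(self, flags, fc=1.0):
        return pd.DataFrame(
            {
                "log2fc": fc,
                "pvalue": [0.001 if f else 0.9 for f in flags],
                "padj": [0.001 if f else 1.0 for f in flags],
                "de": flags,
                "testable": True,
            },
            index=[f"g{i}" for i in range(len(flags))],
        )

    def test_truth_table(self):
        patterns = [
            ((True, True, True), "RNA+RIBO"),
            ((True, True, False), "RNA_only"),
            ((False, False, True), "RIBO_only"),
            ((False, False, False), "none"),
            ((True, False, True), "discordant"),
            ((False, True, False), "discordant"),
        ]
        f1, f2, fr = (self._de([p[0][i] for p in patterns]) for i in range(3))
        out = classify_genes(f1, f2, fr)
        assert out["class_label"].tolist() == [p[1] for p in patterns]

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(0)
        flags = rng.random((30, 3)) < 0.4
        f1, f2, fr = (self._de(flags[:, i]) for i in range(3))
        base = classify_genes(f1, f2, fr)["class_label"]
        perm = rng.permutation(30)
        shuffled = classify_genes(
            f1.iloc[perm], f2.iloc[perm], fr.iloc[perm]
        )["class_label"]
        pd.testing.assert_series_equal(base.iloc[perm], shuffled)

    def test_untestable_gene_excluded_with_reason(self):
        f1 = self._de([True, True])
        f2 = self._de([True, True])
        fr = self._de([True, True])
        fr.loc["g1", "testable"] = False
        out = classify_genes(f1, f2, fr)
        assert out.loc["g1", "class_label"] == "excluded"
        assert "not testable" in out.loc["g1", "exclude_reason"]

    def test_average_rna_fc(self):
        a = self._de([True, True, True], fc=1.0)
        b = self._de([True, True, True], fc=1.0)
        a["log2fc"] = [1.0, 2.0, 0.8]
        b["log2fc"] = [1.0, 0.0, 1.2]
        np.testing.assert_allclose(average_rna_fc(a, b), [1.0, 1.0, 1.0])
        b.loc["g0", "log2fc"] = np.nan
        assert average_rna_fc(a, b).iloc[0] == pytest.approx(1.0)


class TestFCCorrelation:
    def test_perfect_correlations(self):
        x = np.array([0.1, 0.5, -0.4, 1.2, -1.0])
        assert fc_correlation(x, x)[0] == pytest.approx(1.0)
        assert fc_correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        x = np.array([0.2, -0.7, 1.1, 0.4, -0.3])
        y = np.array([0.5, -0.2, 0.8, 0.9, -1.0])
        r, _ = fc_correlation(x, y)
        manual = np.cov(x, y)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
        assert r == pytest.approx(manual, abs=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            fc_correlation([1, 1, 1, 1], [0.5, 0.2, 0.1, 0.9])
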