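"""Hurdle model: BH oracle, fixed-mode coefficient oracles, LRT arithmetic,
nesting, mixed-model cross-check against an independent implementation."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2

import scrobust as sr
from scrobust.glmm import fit_gaussian, fit_logistic
from scrobust.hurdle import HurdleFit, fit_hurdle, log2_fold_change


def brute_force_bh(p):
    """Textbook double-loop BH: q_i = min over j with p_j >= p_i of
    p_j * n / rank_j."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    for pos, i in enumerate(order):
        cand = [p[order[k]] * n / (k + 1) for k in range(pos, n)]
        q[i] = min(1.0, min(cand))
    return q


class TestBH:
    def test_closed_form_example(self):
        np.testing.assert_allclose(
            sr.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p(self):
        assert sr.bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_empty(self):
        assert sr.bh_fdr([]).size == 0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40)
    )
    def test_matches_brute_force(self, pvals):
        np.testing.assert_allclose(sr.bh_fdr(pvals), brute_force_bh(pvals),
                                   atol=1e-12)

    def test_fdr_never_below_p(self):
        rng = np.random.default_rng(0)
        p = rng.random(200)
        assert np.all(sr.bh_fdr(p) >= p - 1e-12)

    def test_agrees_with_statsmodels(self):
        rng = np.random.default_rng(1)
        p = rng.random(300)
        from statsmodels.stats.multitest import multipletests

        np.testing.assert_allclose(
            sr.bh_fdr(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )


def _toy_gene(seed=0, n=400, beta_dx=0.0):
    rng = np.random.default_rng(seed)
    samples = np.repeat([f"S{i}" for i in range(8)], n // 8)
    dx = np.repeat([1, 1, 1, 1, 0, 0, 0, 0], n // 8).astype(float)
    age = np.repeat(rng.normal(0, 1, 8), n // 8)
    cng = rng.normal(0, 1, n)
    eta = -0.2 + beta_dx * dx + 0.1 * age + 0.3 * cng
    detected = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    values = np.where(detected > 0, rng.normal(1.5 + 0.5 * beta_dx * dx, 0.5), 0.0)
    design = pd.DataFrame(
        {"Intercept": 1.0, "Dx": dx, "age": age, "cngeneson": cng}
    )
    return values, detected, design, samples


class TestFixedModeOracles:
    def test_logistic_matches_statsmodels(self):
        values, detected, design, samples = _toy_gene(3)
        fit = fit_logistic(
            design.to_numpy(), detected, list(design.columns), None, "fixed"
        )
        ref = sm.Logit(detected, design.to_numpy()).fit(disp=0)
        np.testing.assert_allclose(fit.params, ref.params, atol=1e-6)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_gaussian_matches_ols(self):
        values, detected, design, samples = _toy_gene(4)
        mask = detected > 0
        X = design.to_numpy()[mask]
        y = values[mask]
        fit = fit_gaussian(X, y, list(design.columns), None, "fixed")
        ref = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.params, ref.params, atol=1e-8)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_mixed_logistic_matches_glmer_laplace(self, tmp_path):
        """The Laplace logistic random-intercept marginal log-likelihood
        matches lme4::glmer (the independent reference implementation of
        the same approximation)."""
        import subprocess

        rng = np.random.default_rng(12)
        n, g = 400, 10
        groups = np.repeat([f"S{i}" for i in range(g)], n // g)
        u = np.repeat(rng.normal(0, 0.6, g), n // g)
        x = rng.normal(0, 1, n)
        eta = -0.3 + 0.5 * x + u
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        X = np.column_stack([np.ones(n), x])
        fit = fit_logistic(X, y, ["Intercept", "x"], groups, "mixed")
        df = pd.DataFrame({"y": y, "x": x, "g": groups})
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "m.R"
        script.write_text(
            "suppressMessages(library(lme4))\n"
            f"d <- read.csv('{csv}')\n"
            "m <- glmer(y ~ x + (1|g), data=d, family=binomial)\n"
            "cat(sprintf('%.6f %.6f %.6f', logLik(m), fixef(m)[1], fixef(m)[2]))\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True,
            timeout=120,
        )
        assert out.returncode == 0, out.stderr
        ll, b0, b1 = (float(v) for v in out.stdout.split())
        assert fit.loglik == pytest.approx(ll, abs=2e-3)
        assert fit.params[0] == pytest.approx(b0, abs=5e-3)
        assert fit.params[1] == pytest.approx(b1, abs=5e-3)

    def test_mixed_gaussian_matches_mixedlm_ml(self):
        """Profiled-GLS ML random-intercept fit equals statsmodels MixedLM
        with REML off (independent implementation)."""
        rng = np.random.default_rng(5)
        n, g = 300, 10
        groups = np.repeat([f"S{i}" for i in range(g)], n // g)
        u = np.repeat(rng.normal(0, 0.5, g), n // g)
        x = rng.normal(0, 1, n)
        y = 1.0 + 0.4 * x + u + rng.normal(0, 1, n)
        X = np.column_stack([np.ones(n), x])
        fit = fit_gaussian(X, y, ["Intercept", "x"], groups, "mixed")
        ref = sm.MixedLM(y, X, groups=groups).fit(reml=False)
        np.testing.assert_allclose(fit.params, ref.fe_params, atol=1e-5)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-4)


class TestLRT:
    def test_no_signal_gives_p_one(self):
        """A gene detected everywhere with identical positive values has no
        information in either part: chi2 0, p 1."""
        n = 60
        design = pd.DataFrame(
            {"Intercept": np.ones(n), "Dx": np.repeat([1.0, 0.0], n // 2)}
        )
        samples = np.repeat([f"S{i}" for i in range(6)], n // 6)
        values = np.full(n, 2.5)
        fit = fit_hurdle(values, np.ones(n), design, samples, mode="fixed")
        chi2_stat, df, p = sr.lrt_diagnosis(fit)
        assert chi2_stat == 0.0 and p == 1.0

    def test_combination_arithmetic(self):
        """Part log-likelihood gains of 3 and 2 combine to chi2 = 10 on
        2 df: p = exp(-5) ~ 0.006738."""
        from scrobust.glmm import RegressionFit

        def rf(ll):
            return RegressionFit(np.zeros(1), ["I"], ll)

        fit = HurdleFit(
            discrete_full=rf(3.0), discrete_reduced=rf(0.0),
            continuous_full=rf(2.0), continuous_reduced=rf(0.0),
        )
        chi2_stat, df, p = sr.lrt_diagnosis(fit)
        assert chi2_stat == pytest.approx(10.0)
        assert df == 2
        assert p == pytest.approx(0.006737947, rel=1e-6)

    def test_chi2_equals_partwise_recomputation(self):
        values, detected, design, samples = _toy_gene(6, beta_dx=0.8)
        fit = fit_hurdle(values, detected, design, samples, mode="fixed")
        chi2_stat, df, _ = sr.lrt_diagnosis(fit)
        # independent part-wise recomputation with statsmodels
        X = design.to_numpy()
        Xr = design.drop(columns="Dx").to_numpy()
        lr_disc = 2 * (
            sm.Logit(detected, X).fit(disp=0).llf
            - sm.Logit(detected, Xr).fit(disp=0).llf
        )
        mask = detected > 0
        lr_cont = 2 * (
            sm.OLS(values[mask], X[mask]).fit().llf
            - sm.OLS(values[mask], Xr[mask]).fit().llf
        )
        assert chi2_stat == pytest.approx(lr_disc + lr_cont, abs=1e-5)

    def test_nested_loglik_ordering_on_fixture_genes(self, small_study):
        dataset, _ = small_study
        from scrobust.data_model import cell_quality, normalize

        in_cl = (dataset.cell_meta["cluster_label"] == "Micro").to_numpy()
        norm = normalize(dataset).values[in_cl].tocsc()
        samples = dataset.cell_meta.loc[in_cl, "sample_id"].to_numpy()
        meta = dataset.sample_meta.loc[samples]
        cng = cell_quality(dataset, in_cl).cngeneson
        design = pd.DataFrame(
            {
                "Intercept": 1.0,
                "Dx": (meta["diagnosis"] == "case").to_numpy(float),
                "age": (meta["age"] - meta["age"].mean()).to_numpy()
                / meta["age"].std(),
                "cngeneson": cng,
            }
        )
        rate = np.asarray(norm.getnnz(axis=0)) / norm.shape[0]
        checked = 0
        for j in np.flatnonzero((rate > 0.2) & (rate < 0.9))[:10]:
            vals = np.asarray(norm[:, j].todense()).ravel()
            fit = fit_hurdle(vals, (vals > 0).astype(float), design, samples,
                             mode="mixed")
            if fit.flag != "ok":
                continue
            assert fit.delta_discrete >= 0
            assert fit.delta_continuous >= 0
            checked += 1
        assert checked >= 5

    def test_untestable_when_too_few_detected(self):
        n = 40
        design = pd.DataFrame(
            {"Intercept": np.ones(n), "Dx": np.repeat([1.0, 0.0], n // 2)}
        )
        samples = np.repeat(["S1", "S2", "S3", "S4"], n // 4)
        detected = np.zeros(n)
        detected[:1] = 1  # single detected cell, case side only
        values = detected * 1.0
        fit = fit_hurdle(values, detected, design, samples, mode="fixed")
        assert fit.flag == "untestable"


def _with_ll(fit, ll):
    from dataclasses import replace

    return replace(fit, loglik=ll)


class TestRunDE:
    def test_small_cluster_skipped(self, small_study):
        dataset, _ = small_study
        assert sr.run_de(dataset, "ExN_CALB", min_cells=1000) is None

    def test_planted_recovery_and_direction(self, small_study, de_table_mixed):
        _, truth = small_study
        de = de_table_mixed
        for direction, sign in (("up", 1), ("down", -1)):
            planted = [
                g for g in truth.true_deg["ExN_A"][direction]
                if de.loc[g, "fit_flag"] == "ok"
            ]
            sig = de.loc[planted, "fdr"] < 0.05
            correct_sign = np.sign(de.loc[planted, "log2fc"]) == sign
            assert (sig & correct_sign).mean() >= 0.8
        # sign agreement for strongly planted DEGs
        strong = [
            g
            for d in ("up", "down")
            for g in truth.true_deg["ExN_A"][d]
            if de.loc[g, "fit_flag"] == "ok"
        ]
        signs = np.sign(de.loc[strong, "log2fc"])
        expect = [1 if g in truth.true_deg["ExN_A"]["up"] else -1 for g in strong]
        assert (signs == expect).mean() >= 0.95

    def test_permuted_labels_destroy_signal(self, small_study):
        """Permuting diagnosis across samples cancels the planted effects:
        under the donor-respecting mixed model the median planted-gene p
        rises above 0.1 (the fixed model would still reject, which is the
        pseudoreplication artifact the random intercept exists to fix)."""
        dataset, truth = small_study
        from scrobust.data_model import cell_quality, normalize

        rng = np.random.default_rng(11)
        diag_perm = pd.Series(
            rng.permutation(dataset.sample_meta["diagnosis"].to_numpy()),
            index=dataset.sample_meta.index,
        )
        in_cl = (dataset.cell_meta["cluster_label"] == "ExN_A").to_numpy()
        norm = normalize(dataset).values[in_cl].tocsc()
        samples = dataset.cell_meta.loc[in_cl, "sample_id"].to_numpy()
        meta = dataset.sample_meta.loc[samples]
        age = meta["age"].to_numpy(float)
        design = pd.DataFrame(
            {
                "Intercept": 1.0,
                "Dx": (diag_perm.loc[samples] == "case").to_numpy(float),
                "age": (age - age.mean()) / age.std(),
                "cngeneson": cell_quality(dataset, in_cl).cngeneson,
            }
        )
        planted = (
            truth.true_deg["ExN_A"]["up"] + truth.true_deg["ExN_A"]["down"]
        )
        gene_pos = {g: i for i, g in enumerate(dataset.gene_ids)}
        ps = []
        for g in planted:
            vals = np.asarray(norm[:, gene_pos[g]].todense()).ravel()
            fit = fit_hurdle(vals, (vals > 0).astype(float), design, samples,
                             mode="mixed")
            if fit.flag == "ok":
                ps.append(sr.lrt_diagnosis(fit)[2])
        assert len(ps) >= 30
        assert np.median(ps) > 0.1

    def test_below_rate_reported_untested(self, de_table_mixed):
        below = de_table_mixed[de_table_mixed["fit_flag"] == "below_min_rate"]
        assert len(below) > 0
        assert below["p_value"].isna().all()
        assert below["expr_rate"].notna().all()


class TestCovariateFlag:
    def _fit_with_age_coef(self, beta):
        fit = fit_gaussian(
            np.ones((4, 2)), np.ones(4), ["Intercept", "age"], None, "fixed"
        )
        from dataclasses import replace

        return HurdleFit(
            discrete_full=None, discrete_reduced=None,
            continuous_full=replace(fit, params=np.array([0.0, beta])),
            continuous_reduced=fit,
        )

    def test_zero_coefficient_not_flagged(self):
        assert not sr.covariate_deg_flag(self._fit_with_age_coef(0.0), "age", 13.0)

    def test_boundary_is_strict(self):
        sd = 13.0
        beta = np.log(1.1) / (2 * sd)  # FC over 2 SD exactly 1.1
        assert not sr.covariate_deg_flag(self._fit_with_age_coef(beta), "age", sd)
        assert sr.covariate_deg_flag(
            self._fit_with_age_coef(beta * 1.01), "age", sd
        )

    def test_absent_covariate_errors(self):
        with pytest.raises(ValueError, match="pmi"):
            sr.covariate_deg_flag(self._fit_with_age_coef(0.1), "pmi", 10.0)

    def test_planted_age_effect_flagged_on_fixture(self, small_study):
        """The fixture plants one gene with an age effect of FC 1.3 per
        2 SD; its fitted continuous age coefficient crosses the 1.1 cut."""
        dataset, _ = small_study
        from scrobust.data_model import cell_quality, normalize
        from scrobust.synthetic import fixture_small_config

        config = fixture_small_config(2024)
        age_gene = next(iter(config.covariate_effects))
        in_cl = (dataset.cell_meta["cluster_label"] == "ExN_A").to_numpy()
        norm = normalize(dataset).values[in_cl].tocsc()
        samples = dataset.cell_meta.loc[in_cl, "sample_id"].to_numpy()
        meta = dataset.sample_meta.loc[samples]
        age = meta["age"].to_numpy(float)
        z_age = (age - age.mean()) / age.std()
        design = pd.DataFrame(
            {
                "Intercept": 1.0,
                "Dx": (meta["diagnosis"] == "case").to_numpy(float),
                "age": z_age,
                "cngeneson": cell_quality(dataset, in_cl).cngeneson,
            }
        )
        j = list(dataset.gene_ids).index(age_gene)
        vals = np.asarray(norm[:, j].todense()).ravel()
        fit = fit_hurdle(vals, (vals > 0).astype(float), design, samples,
                         mode="fixed")
        # design uses age in SD units, so sd_covariate = 1
        assert sr.covariate_deg_flag(fit, "age", 1.0, fc_threshold=1.1)
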