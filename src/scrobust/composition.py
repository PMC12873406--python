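"""Cluster-composition inference from sample x cluster nuclei counts.

Diagnosis effects on cluster proportions are tested per cluster with a
beta-binomial regression (logit link, cluster count vs sample total) whose
overdispersion absorbs the extra-multinomial variation between donors.
Covariate sets are compared by negative-binomial GLM AIC rank-sums across
regions; covariate contributions are decomposed by Type-III likelihood
ratios; and a balanced subsampling loop measures how stable the diagnosis
fold-change is to donor selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import betaln, expit, gammaln
from scipy.stats import chi2 as chi2_dist

from .data_model import CellGeneDataset
from .hurdle import bh_fdr

logger = logging.getLogger("scrobust")


@dataclass
class CompositionTable:
    """Sample x cluster nuclei counts joined with sample covariates."""

    counts: pd.DataFrame  # rows: sample_id, columns: cluster labels
    sample_meta: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.sample_meta.index):
            self.sample_meta = self.sample_meta.loc[self.counts.index]
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate samples in composition table")

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


def build_table(dataset: CellGeneDataset) -> CompositionTable:
    """Cross-tabulate cells by sample x cluster."""
    counts = pd.crosstab(
        dataset.cell_meta["sample_id"], dataset.cell_meta["cluster_label"]
    )
    counts = counts.reindex(dataset.sample_meta.index, fill_value=0)
    counts.columns.name = None
    counts.index.name = "sample_id"
    return CompositionTable(counts=counts, sample_meta=dataset.sample_meta.copy())


def normalize_10k(table: CompositionTable, scale: int = 10_000) -> CompositionTable:
    """Rescale each sample's counts to a common total and round to integers.

    Rounding is round-half-to-even (numpy convention); row totals land
    within clusters/2 of the target scale.
    """
    totals = table.totals.to_numpy(float)
    if np.any(totals <= 0):
        raise ValueError("samples with zero total cells cannot be normalized")
    scaled = np.rint(table.counts.to_numpy(float) / totals[:, None] * scale)
    counts = pd.DataFrame(
        scaled.astype(int), index=table.counts.index, columns=table.counts.columns
    )
    return CompositionTable(counts=counts, sample_meta=table.sample_meta.copy())


# ---------------------------------------------------------------------------
# Beta-binomial diagnosis test
# ---------------------------------------------------------------------------

def _design(sample_meta: pd.DataFrame, covariates: tuple[str, ...]) -> pd.DataFrame:
    cols = {"Intercept": np.ones(len(sample_meta))}
    for cov in covariates:
        if cov == "Dx":
            cols["Dx"] = (sample_meta["diagnosis"] == "case").astype(float).to_numpy()
        elif cov == "sex":
            cols["sex"] = (sample_meta["sex"] == "M").astype(float).to_numpy()
        else:
            v = sample_meta[cov].to_numpy(float)
            sd = v.std() or 1.0
            cols[cov] = (v - v.mean()) / sd
    return pd.DataFrame(cols, index=sample_meta.index)


def _bb_negloglik(theta, X, y, n):
    beta, zeta = theta[:-1], theta[-1]
    pi = expit(np.clip(X @ beta, -30, 30))
    phi = np.exp(np.clip(zeta, -10, 15))  # precision; -> inf is binomial
    a = pi * phi
    b = (1 - pi) * phi
    ll = (
        gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
        + betaln(y + a, n - y + b) - betaln(a, b)
    )
    return -float(np.sum(ll))


def _fit_betabinom(X: np.ndarray, y: np.ndarray, n: np.ndarray):
    """ML beta-binomial regression; returns (beta, zeta, loglik, converged)."""
    # binomial GLM start values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            glm = sm.GLM(
                np.column_stack([y, n - y]), X, family=sm.families.Binomial()
            ).fit()
            beta0 = np.asarray(glm.params)
        except Exception:
            beta0 = np.zeros(X.shape[1])
    best = None
    for zeta0 in (np.log(50.0), np.log(5.0), 12.0):
        res = minimize(
            _bb_negloglik,
            np.concatenate([beta0, [zeta0]]),
            args=(X, y, n),
            method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    beta = best.x[:-1]
    return beta, float(best.x[-1]), -float(best.fun), bool(best.success)


def _bb_fc(beta: np.ndarray, names: list[str], X: np.ndarray) -> float:
    """Case/control fitted-proportion ratio at reference (mean) covariates."""
    ref = X.mean(axis=0).copy()
    i_dx = names.index("Dx")
    ref[i_dx] = 0.0
    eta0 = float(ref @ beta)
    ref[i_dx] = 1.0
    eta1 = float(ref @ beta)
    return float(expit(eta1) / expit(eta0))


def betabinom_dx_test(
    table: CompositionTable,
    covariates: tuple[str, ...] = ("Dx", "age", "sex"),
    clusters: list[str] | None = None,
    with_p: bool = True,
) -> pd.DataFrame:
    """Per-cluster beta-binomial diagnosis test on cluster-vs-total counts.

    Returns per cluster the case/control proportion fold-change (evaluated
    at mean covariates), the diagnosis LRT p-value, and BH FDR across
    clusters.  Non-converged fits fall back to a dispersion-scaled binomial
    GLM (quasi-binomial) and are flagged.
    """
    if "Dx" not in covariates:
        raise ValueError("covariates must include Dx")
    dx = table.sample_meta["diagnosis"]
    if (dx == "case").sum() < 2 or (dx == "control").sum() < 2:
        raise ValueError("need at least 2 samples per diagnosis group")
    design = _design(table.sample_meta, covariates)
    names = list(design.columns)
    X = design.to_numpy(float)
    keep = [c for c in names if c != "Dx"]
    Xr = design[keep].to_numpy(float)
    totals = table.totals.to_numpy(float)
    rows = []
    for cluster in clusters or list(table.counts.columns):
        y = table.counts[cluster].to_numpy(float)
        beta, zeta, ll_full, conv = _fit_betabinom(X, y, totals)
        fc = _bb_fc(beta, names, X)
        p = np.nan
        flag = "ok" if conv else "fallback_quasibinomial"
        if with_p:
            if conv:
                _, _, ll_red, conv_r = _fit_betabinom(Xr, y, totals)
                chi2 = max(0.0, 2.0 * (ll_full - ll_red))
                p = float(chi2_dist.sf(chi2, 1))
            if not conv or not conv_r:
                p, fc_q = _quasibinom_dx(design, y, totals)
                flag = "fallback_quasibinomial"
                if not conv:
                    fc = fc_q
        rows.append(
            {"cluster": cluster, "fc": fc, "p_value": p, "flag": flag,
             "precision": float(np.exp(zeta))}
        )
    out = pd.DataFrame(rows).set_index("cluster")
    if with_p:
        out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    return out


def _quasibinom_dx(design: pd.DataFrame, y, n):
    """Dispersion-scaled binomial GLM fallback for the diagnosis test."""
    X = design.to_numpy(float)
    names = list(design.columns)
    resp = np.column_stack([y, n - y])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.GLM(resp, X, family=sm.families.Binomial()).fit()
        Xr = design[[c for c in names if c != "Dx"]].to_numpy(float)
        red = sm.GLM(resp, Xr, family=sm.families.Binomial()).fit()
    phi = max(full.pearson_chi2 / full.df_resid, 1.0)
    chi2 = max(0.0, 2.0 * (full.llf - red.llf)) / phi
    p = float(chi2_dist.sf(chi2, 1))
    return p, _bb_fc(np.asarray(full.params), names, X)


# ---------------------------------------------------------------------------
# Negative-binomial GLM, AIC selection, Type-III decomposition
# ---------------------------------------------------------------------------

@dataclass
class NBGlmFit:
    """ML negative-binomial regression fit (log link)."""

    params: pd.Series  # named coefficients (excluding dispersion)
    alpha: float  # NB2 dispersion; 0 flags the Poisson boundary
    loglik: float
    aic: float
    pvalues: pd.Series  # per-coefficient Wald p
    design: pd.DataFrame
    response: np.ndarray
    flag: str = "ok"

    def fold_changes(self) -> pd.Series:
        return np.exp(self.params)


_POISSON_ALPHA = 1e-6


def nb_glm(response_counts: np.ndarray, covariates: pd.DataFrame) -> NBGlmFit:
    """Negative-binomial GLM of counts on a named covariate design.

    Dispersion is estimated by ML; when it collapses to the Poisson
    boundary the Poisson GLM fit is returned with the dispersion capped at 0
    and flagged.
    """
    y = np.asarray(response_counts)
    X = covariates.to_numpy(float)
    names = list(covariates.columns)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.NegativeBinomial(y, X).fit(disp=0, maxiter=200)
            alpha = float(res.params[-1])
            ok = res.mle_retvals.get("converged", False) and alpha > _POISSON_ALPHA
        except Exception:
            ok = False
        if not ok:
            pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
            k = X.shape[1]
            return NBGlmFit(
                params=pd.Series(np.asarray(pois.params), index=names),
                alpha=0.0,
                loglik=float(pois.llf),
                aic=float(2 * k - 2 * pois.llf),
                pvalues=pd.Series(np.asarray(pois.pvalues), index=names),
                design=covariates,
                response=y,
                flag="poisson_boundary",
            )
    k = X.shape[1] + 1  # + dispersion
    return NBGlmFit(
        params=pd.Series(np.asarray(res.params[:-1]), index=names),
        alpha=alpha,
        loglik=float(res.llf),
        aic=float(2 * k - 2 * res.llf),
        pvalues=pd.Series(np.asarray(res.pvalues[:-1]), index=names),
        design=covariates,
        response=y,
        flag="ok",
    )


def type3_lr(fit: NBGlmFit) -> pd.DataFrame:
    """Type-III likelihood-ratio decomposition: drop each covariate in turn."""
    rows = []
    for cov in fit.design.columns:
        if cov == "Intercept":
            continue
        reduced_design = fit.design.drop(columns=[cov])
        try:
            reduced = nb_glm(fit.response, reduced_design)
            chi2 = max(0.0, 2.0 * (fit.loglik - reduced.loglik))
            rows.append(
                {"covariate": cov, "chi2": chi2, "df": 1,
                 "p_value": float(chi2_dist.sf(chi2, 1))}
            )
        except Exception:
            rows.append(
                {"covariate": cov, "chi2": np.nan, "df": 1, "p_value": np.nan}
            )
    return pd.DataFrame(rows).set_index("covariate")


def aic_model_selection(
    tables_by_region: dict[str, CompositionTable],
    candidate_models: list[tuple[str, ...]],
) -> pd.DataFrame:
    """Rank covariate models by AIC rank-sum across regions.

    For each region and candidate covariate set (always containing Dx), a
    negative-binomial GLM is fitted per cluster on counts normalized to a
    common per-sample total; AICs are summed over clusters, models ranked
    within each region, and ranks summed across regions.  Lowest rank-sum
    wins; ties share the minimum rank-sum.
    """
    model_names = ["+".join(m) for m in candidate_models]
    for m in candidate_models:
        if "Dx" not in m:
            raise ValueError(f"candidate model {m} lacks Dx")
    aic_sums = pd.DataFrame(index=model_names, columns=list(tables_by_region), dtype=float)
    for region, table in tables_by_region.items():
        norm = normalize_10k(table)
        for m, mname in zip(candidate_models, model_names):
            design = _design(norm.sample_meta, m)
            total = 0.0
            skipped = 0
            for cluster in norm.counts.columns:
                try:
                    total += nb_glm(norm.counts[cluster].to_numpy(), design).aic
                except ValueError:
                    skipped += 1
            if skipped:
                logger.warning(
                    "aic_model_selection: %d cluster fits skipped for %s in %s",
                    skipped, mname, region,
                )
            aic_sums.loc[mname, region] = total
    ranks = aic_sums.rank(axis=0, method="min")
    out = pd.DataFrame(
        {
            **{f"aic_{r}": aic_sums[r] for r in aic_sums.columns},
            **{f"rank_{r}": ranks[r] for r in ranks.columns},
            "rank_sum": ranks.sum(axis=1),
        }
    )
    out.index.name = "model"
    return out.sort_values("rank_sum", kind="mergesort")


# ---------------------------------------------------------------------------
# Subsampling robustness
# ---------------------------------------------------------------------------

def subsample_robustness(
    table: CompositionTable,
    n_per_group: int = 10,
    n_iter: int = 1000,
    seed: int = 0,
    covariates: tuple[str, ...] = ("Dx", "age", "sex"),
    clusters: list[str] | None = None,
    fc_threshold: float | None = None,
) -> dict[str, pd.DataFrame]:
    """Distribution of diagnosis fold-changes over balanced donor subsamples.

    Each iteration draws ``n_per_group`` case and control samples without
    replacement, reruns the beta-binomial diagnosis model, and records the
    per-cluster FC.  Returns the raw FC draws and per-cluster quantiles
    (2.5/50/97.5%) plus, if ``fc_threshold`` is given, the fraction of
    subsamples with FC below it.
    """
    dx = table.sample_meta["diagnosis"]
    cases = list(table.sample_meta.index[dx == "case"])
    controls = list(table.sample_meta.index[dx == "control"])
    if len(cases) < n_per_group or len(controls) < n_per_group:
        raise ValueError(
            f"need >= {n_per_group} samples per group "
            f"(have {len(cases)} case, {len(controls)} control)"
        )
    clusters = clusters or list(table.counts.columns)
    rng = np.random.default_rng(seed)
    draws = np.empty((n_iter, len(clusters)))
    for it in range(n_iter):
        pick = sorted(rng.choice(cases, n_per_group, replace=False)) + sorted(
            rng.choice(controls, n_per_group, replace=False)
        )
        sub = CompositionTable(
            counts=table.counts.loc[pick].copy(),
            sample_meta=table.sample_meta.loc[pick].copy(),
        )
        res = betabinom_dx_test(sub, covariates, clusters=clusters, with_p=False)
        draws[it] = res.loc[clusters, "fc"].to_numpy()
    fc_draws = pd.DataFrame(draws, columns=clusters)
    summary = pd.DataFrame(
        {
            "fc_q025": fc_draws.quantile(0.025),
            "fc_median": fc_draws.quantile(0.5),
            "fc_q975": fc_draws.quantile(0.975),
        }
    )
    if fc_threshold is not None:
        summary[f"frac_below_{fc_threshold}"] = (fc_draws < fc_threshold).mean()
    summary.index.name = "cluster"
    return {"draws": fc_draws, "summary": summary}
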