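"""Two-part (hurdle) differential expression with per-sample random intercepts.

For each gene in a cluster the model has

* a discrete part: logistic regression of the detection indicator
  (count > 0) on diagnosis, age, sex, and the cell-quality covariate
  ``cngeneson``, and
* a continuous part: Gaussian regression of the log-normalized expression
  over the detected cells on the same design.

In ``mixed`` mode both parts carry a per-sample random intercept so that the
diagnosis contrast is judged against between-donor variation rather than
against cells as if they were independent.  The diagnosis test is the
two-degree-of-freedom likelihood ratio combining both parts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .data_model import CellGeneDataset, NormalizedMatrix, cell_quality, normalize
from .glmm import RegressionFit, fit_gaussian, fit_logistic

logger = logging.getLogger("scrobust")

UNTESTABLE = "untestable"
OK = "ok"


@dataclass
class HurdleFit:
    """Full and diagnosis-dropped fits of both hurdle parts for one gene."""

    discrete_full: RegressionFit | None
    discrete_reduced: RegressionFit | None
    continuous_full: RegressionFit | None
    continuous_reduced: RegressionFit | None
    flag: str = OK

    @property
    def delta_discrete(self) -> float:
        if self.discrete_full is None:
            return 0.0
        return max(0.0, self.discrete_full.loglik - self.discrete_reduced.loglik)

    @property
    def delta_continuous(self) -> float:
        if self.continuous_full is None:
            return 0.0
        return max(0.0, self.continuous_full.loglik - self.continuous_reduced.loglik)


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (classic definition)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(n)
    out[order] = q
    return out


def fit_hurdle(
    values: np.ndarray,
    detected: np.ndarray,
    design: pd.DataFrame,
    sample_ids: np.ndarray,
    mode: str = "mixed",
    test_var: str = "Dx",
) -> HurdleFit:
    """Fit both hurdle parts with and without the tested covariate.

    ``values`` are log-normalized expression values (only entries where
    ``detected`` is 1 are used by the continuous part); ``design`` must
    contain an intercept column and ``test_var``.
    """
    detected = np.asarray(detected, dtype=float)
    values = np.asarray(values, dtype=float)
    if test_var not in design.columns:
        raise ValueError(f"design lacks tested covariate {test_var!r}")
    groups = np.asarray(sample_ids)
    dx = np.asarray(design[test_var], float)
    det_mask = detected > 0
    # testability: need at least 2 detected cells in each diagnosis arm
    n_det_a = int(det_mask[dx != 0].sum())
    n_det_b = int(det_mask[dx == 0].sum())
    if n_det_a < 2 or n_det_b < 2:
        return HurdleFit(None, None, None, None, flag=UNTESTABLE)

    Xf = design.to_numpy(dtype=float)
    keep = [c for c in design.columns if c != test_var]
    Xr = design[keep].to_numpy(dtype=float)
    names_f = list(design.columns)

    # discrete part: skip when detection has no variation (all detected)
    if det_mask.all() or not det_mask.any():
        dfull = dred = None
    else:
        dred = fit_logistic(Xr, detected, keep, groups, mode)
        dfull = fit_logistic(Xf, detected, names_f, groups, mode)
        if not (dfull.converged and dred.converged):
            return HurdleFit(None, None, None, None, flag=UNTESTABLE)

    yv = values[det_mask]
    if np.ptp(yv) == 0.0:  # constant positive values: no continuous signal
        cfull = cred = None
    else:
        cred = fit_gaussian(Xr[det_mask], yv, keep, groups[det_mask], mode)
        cfull = fit_gaussian(Xf[det_mask], yv, names_f, groups[det_mask], mode)
    return HurdleFit(dfull, dred, cfull, cred, flag=OK)


def lrt_diagnosis(fit: HurdleFit) -> tuple[float, int, float]:
    """Combined hurdle LRT: chi2 = 2(dLL_disc + dLL_cont), df = tested parts."""
    if fit.flag == UNTESTABLE:
        return np.nan, 0, np.nan
    df = 0
    chi2 = 0.0
    if fit.discrete_full is not None:
        chi2 += 2.0 * fit.delta_discrete
        df += 1
    if fit.continuous_full is not None:
        chi2 += 2.0 * fit.delta_continuous
        df += 1
    if df == 0:
        return 0.0, 0, 1.0
    return chi2, df, float(chi2_dist.sf(chi2, df))


def log2_fold_change(
    norm_values: np.ndarray, case_mask: np.ndarray, pseudocount: float = 1.0
) -> float:
    """log2 of (mean de-logged normalized expression + pseudocount) ratio.

    De-logging ln(1 + x) recovers the scaled counts-per-total x, so this is a
    shrunken fold-change on the normalized-count scale, stable under zeros.
    """
    expr = np.expm1(norm_values)
    m_case = float(expr[case_mask].mean())
    m_ctrl = float(expr[~case_mask].mean())
    return float(np.log2((m_case + pseudocount) / (m_ctrl + pseudocount)))


def covariate_deg_flag(
    fit: HurdleFit,
    covariate: str,
    sd_covariate: float,
    fc_threshold: float = 1.1,
) -> bool:
    """Flag a gene whose covariate effect over a 2-SD span exceeds the FC cut.

    The continuous-part coefficient (per covariate unit, natural-log scale of
    normalized expression) is converted to a fold-change over two standard
    deviations of the covariate; the flag requires |FC| strictly above the
    threshold on either side.
    """
    if fit.continuous_full is None:
        return False
    if covariate not in fit.continuous_full.names:
        raise ValueError(f"covariate {covariate!r} not in the fitted design")
    beta = fit.continuous_full.coef(covariate)
    fc = float(np.exp(beta * 2.0 * sd_covariate))
    return fc > fc_threshold or fc < 1.0 / fc_threshold


def run_de(
    dataset: CellGeneDataset,
    cluster: str,
    min_cells: int = 1000,
    min_rate: float = 0.10,
    coding_only: bool = True,
    mode: str = "mixed",
    norm: NormalizedMatrix | None = None,
    quality_scope: str = "cluster",
) -> pd.DataFrame | None:
    """Hurdle DE for one cluster; returns the per-gene DE table.

    Genes are tested when protein-coding (if ``coding_only``) and expressed
    in strictly more than ``min_rate`` of the cluster's cells; BH FDR is
    computed over the tested, testable genes.  Clusters below ``min_cells``
    nuclei are skipped (returns None) to keep per-donor counts meaningful.
    """
    in_cluster = (dataset.cell_meta["cluster_label"] == cluster).to_numpy()
    n_cluster = int(in_cluster.sum())
    if n_cluster < min_cells:
        logger.warning(
            "cluster %s has %d nuclei (< %d); DE skipped", cluster, n_cluster, min_cells
        )
        return None
    if norm is None:
        norm = normalize(dataset)
    sub_values = norm.values[in_cluster].tocsc()
    meta = dataset.cell_meta.loc[in_cluster]
    samples = meta["sample_id"].to_numpy()
    diag = dataset.sample_meta.loc[samples, "diagnosis"].to_numpy()
    case_mask = diag == "case"
    age = dataset.sample_meta.loc[samples, "age"].to_numpy(float)
    sex = (dataset.sample_meta.loc[samples, "sex"].to_numpy() == "M").astype(float)
    cq = cell_quality(
        dataset, in_cluster if quality_scope == "cluster" else None
    )
    cng = cq.cngeneson if quality_scope == "cluster" else cq.cngeneson[in_cluster]
    age_sd = float(np.std(age)) or 1.0
    design = pd.DataFrame(
        {
            "Intercept": 1.0,
            "Dx": case_mask.astype(float),
            "age": (age - age.mean()) / age_sd,
            "sex": sex,
            "cngeneson": cng,
        }
    )

    rate = np.asarray(sub_values.getnnz(axis=0)) / n_cluster
    coding = dataset.gene_meta["is_protein_coding"].to_numpy(bool)
    testable = rate > min_rate
    if coding_only:
        testable &= coding

    rows = []
    for j, gene in enumerate(dataset.gene_ids):
        row = {
            "gene_id": gene,
            "expr_rate": float(rate[j]),
            "n_cells_case": int(case_mask.sum()),
            "n_cells_control": int((~case_mask).sum()),
            "log2fc": np.nan,
            "p_value": np.nan,
            "fdr": np.nan,
            "fit_flag": "below_min_rate",
        }
        if testable[j]:
            vals = np.asarray(sub_values[:, j].todense()).ravel()
            det = (vals > 0).astype(float)
            fit = fit_hurdle(vals, det, design, samples, mode=mode)
            row["log2fc"] = log2_fold_change(vals, case_mask)
            if fit.flag == OK:
                _, _, p = lrt_diagnosis(fit)
                row["p_value"] = p
                row["fit_flag"] = OK
            else:
                row["fit_flag"] = fit.flag
        rows.append(row)
    table = pd.DataFrame(rows).set_index("gene_id")
    tested = table["fit_flag"] == OK
    if tested.any():
        table.loc[tested, "fdr"] = bh_fdr(table.loc[tested, "p_value"].to_numpy())
    return table
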