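"""Consensus NMF meta-gene programs and trans-cellular detection.

Normalized expression of the most variable genes is factorized by
non-negative matrix factorization at a sweep of ranks; the pooled,
L2-normalized gene-loading vectors are clustered by cosine similarity into
consensus meta-programs (MPs).  Each MP carries a gene signature, per-cell
activity scores, the set of major cell classes its top-scoring cells span
(trans-cellular if >= 2), and a mixed-model case-control test of its score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import chi2 as chi2_dist

from .data_model import CellGeneDataset, NormalizedMatrix
from .glmm import fit_gaussian

logger = logging.getLogger("scrobust")


@dataclass
class NMFFactor:
    """One L2-normalized gene-loading vector from a single-rank NMF run."""

    rank: int
    index: int
    loadings: np.ndarray  # length = n selected genes, unit L2 norm
    converged: bool


@dataclass
class MetaProgram:
    """Consensus meta-gene program."""

    mp_id: str
    signature: pd.Series  # gene -> consensus loading, descending
    members: list[tuple[int, int]]  # (rank, factor index)
    scores: np.ndarray | None = None
    class_span: list[str] = field(default_factory=list)
    group_test: dict | None = None

    @property
    def genes(self) -> set[str]:
        return set(self.signature.index)

    @property
    def trans_cellular(self) -> bool:
        return len(self.class_span) >= 2


def select_variable_genes(
    normalized: NormalizedMatrix, gene_ids: pd.Index, n: int = 5000,
    n_bins: int = 20,
) -> list[str]:
    """Top-n genes by standardized dispersion, computed on the de-logged
    (normalized-count) scale and z-scored within mean-abundance bins;
    deterministic ties by gene ID.  Zero-variance genes are never selected
    before variable ones."""
    v = normalized.values.copy()
    v.data = np.expm1(v.data)  # back to the normalized-count scale
    n_cells = v.shape[0]
    mean = np.asarray(v.mean(axis=0)).ravel()
    sq = np.asarray(v.multiply(v).mean(axis=0)).ravel()
    var = np.maximum(sq - mean**2, 0.0) * n_cells / max(n_cells - 1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    n_genes = len(mean)
    n_bins = max(1, min(n_bins, n_genes // 5)) if n_genes >= 10 else 1
    order = np.argsort(mean, kind="mergesort")
    bins = np.empty(n_genes, dtype=int)
    bins[order] = np.minimum(
        (np.arange(n_genes) * n_bins) // max(n_genes, 1), n_bins - 1
    )
    z = np.zeros(n_genes)
    for b in range(n_bins):
        m = bins == b
        if not m.any():
            continue
        sd = disp[m].std()
        z[m] = (disp[m] - disp[m].mean()) / (sd if sd > 0 else 1.0)
    z[var == 0] = -np.inf  # constant genes rank last
    if n > n_genes:
        logger.warning("select_variable_genes: n=%d exceeds gene count", n)
        n = n_genes
    frame = pd.DataFrame({"z": z, "gene": gene_ids}).sort_values(
        ["z", "gene"], ascending=[False, True], kind="mergesort"
    )
    return frame["gene"].head(n).tolist()


def downsample_cells(
    dataset: CellGeneDataset, cap: int = 2000, seed: int = 0
) -> CellGeneDataset:
    """Subsample each cluster above ``cap`` cells to exactly ``cap``
    (without replacement, seed-deterministic); smaller clusters untouched."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    rng = np.random.default_rng(seed)
    keep = np.zeros(dataset.n_cells, dtype=bool)
    labels = dataset.cell_meta["cluster_label"].to_numpy()
    for cluster in sorted(pd.unique(labels)):
        idx = np.flatnonzero(labels == cluster)
        if len(idx) > cap:
            idx = rng.choice(idx, size=cap, replace=False)
        keep[idx] = True
    return dataset.subset_cells(keep)


def _nndsvda_init(V: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic NNDSVD(a) initialization: split each singular vector
    pair into its positive/negative parts, keep the dominant pair, and fill
    zeros with the matrix mean."""
    U, S, Vt = np.linalg.svd(V, full_matrices=False)
    n, g = V.shape
    W = np.zeros((n, k))
    H = np.zeros((k, g))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0] = np.sqrt(S[0]) * np.abs(Vt[0])
    eps = 1e-12
    for j in range(1, min(k, len(S))):
        u, v = U[:, j], Vt[j]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        n_pos = np.linalg.norm(up) * np.linalg.norm(vp)
        n_neg = np.linalg.norm(un) * np.linalg.norm(vn)
        if n_pos >= n_neg:
            scale, wu, hv = n_pos, up, vp
        else:
            scale, wu, hv = n_neg, un, vn
        W[:, j] = np.sqrt(S[j] * scale) * wu / (np.linalg.norm(wu) + eps)
        H[j] = np.sqrt(S[j] * scale) * hv / (np.linalg.norm(hv) + eps)
    fill = V.mean()
    W[W <= 0] = fill
    H[H <= 0] = fill
    return W, H


def nmf_multi_rank(
    matrix: np.ndarray | sp.spmatrix,
    ranks: range | list[int] = range(20, 31),
    seed: int = 0,
    n_iter: int = 300,
    init: str = "nndsvd",
    return_errors: bool = False,
):
    """Multiplicative-update NMF at each rank; pooled unit-norm loadings.

    Fixed iteration count.  Initialization is deterministic NNDSVD by
    default (more reproducible and better-separated factors than random
    starts); ``init="random"`` gives seeded uniform starts.  The Frobenius
    objective is non-increasing under the updates; a factor is flagged
    non-converged when the last relative improvement exceeds 1e-4.
    """
    V = matrix.toarray() if sp.issparse(matrix) else np.asarray(matrix, float)
    if V.min() < 0:
        raise ValueError("NMF input must be non-negative")
    n, g = V.shape
    rng = np.random.default_rng(seed)
    factors: list[NMFFactor] = []
    errors: dict[int, list[float]] = {}
    eps = 1e-12
    for k in ranks:
        if init == "nndsvd":
            W, H = _nndsvda_init(V, k)
        else:
            W = rng.uniform(0.1, 1.0, size=(n, k))
            H = rng.uniform(0.1, 1.0, size=(k, g))
        errs = []
        for _ in range(n_iter):
            H *= (W.T @ V) / (W.T @ W @ H + eps)
            W *= (V @ H.T) / (W @ (H @ H.T) + eps)
            errs.append(float(np.linalg.norm(V - W @ H)))
        converged = len(errs) < 2 or (
            abs(errs[-2] - errs[-1]) <= 1e-4 * max(errs[-2], eps)
        )
        errors[k] = errs
        for i in range(k):
            h = H[i]
            norm = np.linalg.norm(h)
            if norm <= eps:
                continue
            factors.append(NMFFactor(rank=k, index=i, loadings=h / norm,
                                     converged=converged))
    if return_errors:
        return factors, errors
    return factors


def consensus_mps(
    factors: list[NMFFactor],
    gene_ids: list[str],
    max_mps: int = 20,
    top_genes: int = 300,
) -> list[MetaProgram]:
    """Cluster factor loading vectors (cosine, average linkage) into at most
    ``max_mps`` consensus programs; signature = top ``top_genes`` genes by
    mean member loading."""
    if len(factors) < 2:
        groups = {i: [i] for i in range(len(factors))}
    else:
        L = np.vstack([f.loadings for f in factors])
        d = pdist(L, metric="cosine")
        d = np.clip(d, 0.0, None)
        Z = linkage(d, method="average")
        labels = fcluster(Z, t=min(max_mps, len(factors)), criterion="maxclust")
        groups = {}
        for i, lab in enumerate(labels):
            groups.setdefault(lab, []).append(i)
    mps = []
    for lab in sorted(groups, key=lambda l: (-len(groups[l]), l)):
        idx = groups[lab]
        mean_loading = np.mean([factors[i].loadings for i in idx], axis=0)
        s = pd.Series(mean_loading, index=gene_ids)
        s = s[s > 0].sort_values(ascending=False, kind="mergesort")
        sig = s.head(top_genes)
        mps.append(
            MetaProgram(
                mp_id=f"MP{len(mps) + 1}",
                signature=sig,
                members=[(factors[i].rank, factors[i].index) for i in idx],
            )
        )
    return mps


def score_cells(
    normalized: NormalizedMatrix, gene_ids: pd.Index, mp: MetaProgram
) -> np.ndarray:
    """Loading-weighted mean of normalized expression over signature genes."""
    if mp.signature.empty:
        raise ValueError("meta-program has an empty signature")
    pos = pd.Index(gene_ids).get_indexer(mp.signature.index)
    present = pos >= 0
    w = mp.signature.to_numpy(float)[present]
    cols = pos[present]
    sub = normalized.values[:, cols]
    return np.asarray(sub @ (w / w.sum())).ravel()


def classify_span(
    mp_scores: np.ndarray,
    major_classes: np.ndarray,
    share_cut: float = 0.10,
    top_frac: float = 0.10,
) -> list[str]:
    """Major classes contributing >= share_cut of the top-decile cells."""
    n = len(mp_scores)
    n_top = max(int(np.ceil(n * top_frac)), 1)
    order = np.argsort(-np.asarray(mp_scores), kind="mergesort")
    top = np.asarray(major_classes)[order[:n_top]]
    span = []
    for cls in sorted(pd.unique(top)):
        if (top == cls).mean() >= share_cut:
            span.append(cls)
    return span


def mp_group_test(
    scores: np.ndarray,
    cell_samples: np.ndarray,
    sample_meta: pd.DataFrame,
    n_mps: int,
) -> dict:
    """Mixed-model diagnosis test of per-cell MP scores.

    Linear model of scores on diagnosis, age, and sex with a per-sample
    random intercept; the diagnosis p-value comes from the ML likelihood
    ratio and is Bonferroni-adjusted over ``n_mps`` programs.
    """
    diag = sample_meta.loc[cell_samples, "diagnosis"].to_numpy()
    if len(set(sample_meta["diagnosis"])) < 2:
        raise ValueError("need both diagnosis groups")
    age = sample_meta.loc[cell_samples, "age"].to_numpy(float)
    sex = (sample_meta.loc[cell_samples, "sex"].to_numpy() == "M").astype(float)
    age_sd = age.std() or 1.0
    X = np.column_stack(
        [np.ones(len(scores)), (diag == "case").astype(float),
         (age - age.mean()) / age_sd, sex]
    )
    names = ["Intercept", "Dx", "age", "sex"]
    Xr = X[:, [0, 2, 3]]
    full = fit_gaussian(X, scores, names, cell_samples, mode="mixed")
    red = fit_gaussian(Xr, scores, ["Intercept", "age", "sex"], cell_samples,
                       mode="mixed")
    chi2 = max(0.0, 2.0 * (full.loglik - red.loglik))
    p = float(chi2_dist.sf(chi2, 1))
    return {
        "estimate": full.coef("Dx"),
        "p_value": p,
        "adjusted_p": min(1.0, p * n_mps),
        "re_var": full.re_var,
    }
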