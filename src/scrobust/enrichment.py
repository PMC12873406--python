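"""Gene-set statistics: over-representation, term simplification, and
preranked GSEA with a fold-change x expression-rate ranking.

Two over-representation profiles mirror the upstream analysis conventions:
the GO-style profile (FDR < 0.05, term size 20-500, overlap >= 3) and the
SynGO-style profile (FDR < 0.2, term size 5-100, overlap >= 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .hurdle import bh_fdr

logger = logging.getLogger("scrobust")

PROFILES = {
    "go": {"fdr_cut": 0.05, "size_range": (20, 500), "min_overlap": 3},
    "syngo": {"fdr_cut": 0.2, "size_range": (5, 100), "min_overlap": 2},
}


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file into {term_id: gene set}; description field ignored."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            term, genes = parts[0], {g for g in parts[2:] if g}
            if term in terms:
                raise ValueError(f"duplicate term id {term!r} in {path}")
            if genes:
                terms[term] = genes
    return terms


def write_gmt(terms: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(terms):
            fh.write("\t".join([term, term, *sorted(terms[term])]) + "\n")


# ---------------------------------------------------------------------------
# Over-representation
# ---------------------------------------------------------------------------

def hypergeom_test(
    hits: set[str], term: set[str], universe: set[str]
) -> tuple[float, float, int]:
    """Upper-tail hypergeometric P(X >= k) of the hits/term overlap.

    The term is intersected with the universe before testing.  Returns
    (p, fold_enrichment, overlap); empty hits give p = 1, FE = 0.
    """
    if not universe:
        raise ValueError("universe is empty")
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    N = len(universe)
    K = len(term & universe)
    n = len(hits)
    k = len(hits & term & universe)
    if n == 0 or K == 0:
        return 1.0, 0.0, k
    p = float(hypergeom.sf(k - 1, N, K, n))
    fe = (k / n) / (K / N)
    return min(p, 1.0), float(fe), k


def enrich_collection(
    deg_set: set[str],
    collection: dict[str, set[str]],
    background: set[str],
    fdr_cut: float = 0.05,
    size_range: tuple[int, int] = (20, 500),
    min_overlap: int = 3,
    profile: str | None = None,
) -> pd.DataFrame:
    """Over-representation of each sized term in the DEG set vs background.

    BH FDR is computed across all size-eligible tested terms; only terms with
    FDR < fdr_cut and overlap >= min_overlap are returned.  ``profile``
    ('go' or 'syngo') overrides the three parameters jointly.
    """
    if profile is not None:
        conf = PROFILES[profile]
        fdr_cut, size_range = conf["fdr_cut"], conf["size_range"]
        min_overlap = conf["min_overlap"]
    lo, hi = size_range
    hits = deg_set & background
    rows = []
    for term_id in sorted(collection):
        genes = collection[term_id]
        if not lo <= len(genes) <= hi:
            continue
        p, fe, k = hypergeom_test(hits, genes, background)
        rows.append(
            {
                "term_id": term_id,
                "overlap": k,
                "term_size": len(genes & background),
                "n_hits": len(hits),
                "universe": len(background),
                "p_value": p,
                "fold_enrichment": fe,
                "genes": ",".join(sorted(hits & genes)),
            }
        )
    if not rows:
        logger.warning("enrich_collection: no terms within size range %s", size_range)
        return pd.DataFrame(
            columns=[
                "term_id", "overlap", "term_size", "n_hits", "universe",
                "p_value", "fold_enrichment", "genes", "fdr",
            ]
        ).set_index("term_id")
    table = pd.DataFrame(rows).set_index("term_id")
    table["fdr"] = bh_fdr(table["p_value"].to_numpy())
    keep = (table["fdr"] < fdr_cut) & (table["overlap"] >= min_overlap)
    return table.loc[keep].sort_values("p_value")


def simplify_terms(
    results: pd.DataFrame,
    collection: dict[str, set[str]],
    universe: set[str],
    similarity_cut: float = 0.7,
) -> pd.DataFrame:
    """Merge redundant enriched terms by gene-set Jaccard similarity.

    Terms whose universe-restricted gene sets have Jaccard >= similarity_cut
    are merged by single linkage (connected components of the thresholded
    similarity graph); each group is represented by its lowest-p term.
    """
    ids = list(results.index)
    sets = {t: collection[t] & universe for t in ids}
    parent = {t: t for t in ids}

    def find(t):
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            inter = len(sets[a] & sets[b])
            union = len(sets[a] | sets[b])
            if union and inter / union >= similarity_cut:
                parent[find(a)] = find(b)
    groups: dict[str, list[str]] = {}
    for t in ids:
        groups.setdefault(find(t), []).append(t)
    reps = []
    for members in groups.values():
        best = min(members, key=lambda t: (results.loc[t, "p_value"], t))
        reps.append(best)
    return results.loc[sorted(reps, key=ids.index)].copy()


# ---------------------------------------------------------------------------
# Preranked GSEA
# ---------------------------------------------------------------------------

@dataclass
class GseaResult:
    """Enrichment score and permutation null summary for one term."""

    es: float
    nes: float
    p_value: float
    leading_edge: list[str]
    n_perm: int


def rank_genes(de_table: pd.DataFrame, min_rate: float = 0.10) -> pd.Series:
    """Signed ranking score log2FC x expression rate, descending.

    Restricted to genes with expression rate strictly above ``min_rate``;
    the log fold-change carries the sign so down-regulated genes rank at the
    bottom.  Ties break by gene ID for determinism.
    """
    sub = de_table[
        (de_table["expr_rate"] > min_rate) & de_table["log2fc"].notna()
    ]
    score = sub["log2fc"] * sub["expr_rate"]
    frame = score.rename("score").rename_axis("gene_id").reset_index()
    frame = frame.sort_values(["score", "gene_id"], ascending=[False, True])
    return frame.set_index("gene_id")["score"]


def _running_es(scores: np.ndarray, is_hit: np.ndarray, weight: float) -> tuple[float, int]:
    """Max-deviation running sum; returns (ES, index of the extremum)."""
    w = np.abs(scores) ** weight
    hit_w = np.where(is_hit, w, 0.0)
    total_hit = hit_w.sum()
    n_miss = (~is_hit).sum()
    if total_hit == 0 or n_miss == 0:
        return 0.0, 0
    inc = hit_w / total_hit - np.where(is_hit, 0.0, 1.0 / n_miss)
    run = np.cumsum(inc)
    i = int(np.argmax(np.abs(run)))
    return float(run[i]), i


def preranked_gsea(
    ranked: pd.Series,
    term: set[str],
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> GseaResult | None:
    """Weighted Kolmogorov-Smirnov enrichment of a term in a ranked list.

    The null is gene-label permutation: random same-size gene sets drawn
    from the ranking.  The p-value and NES condition on the sign of the
    observed ES.  Terms with no gene in the ranking are skipped (None).
    """
    if n_perm < 100:
        logger.warning("preranked_gsea: n_perm=%d is low; p is coarse", n_perm)
    genes = ranked.index.to_numpy()
    scores = ranked.to_numpy(float)
    is_hit = np.isin(genes, sorted(term))
    n_hit = int(is_hit.sum())
    if n_hit == 0:
        return None
    es, peak = _running_es(scores, is_hit, weight)
    if es >= 0:
        leading = [g for g, h in zip(genes[: peak + 1], is_hit[: peak + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[peak:], is_hit[peak:]) if h]
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    null = np.empty(n_perm)
    n = len(genes)
    for b in range(n_perm):
        idx = rng.choice(n, size=n_hit, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        null[b], _ = _running_es(scores, mask, weight)
    same_sign = null >= 0 if es >= 0 else null <= 0
    n_sign = int(same_sign.sum())
    if n_sign == 0:
        p = 1.0 / (n_perm + 1)
        nes = 0.0
    else:
        extreme = int((np.abs(null[same_sign]) >= abs(es)).sum())
        p = (1 + extreme) / (1 + n_sign)
        denom = float(np.abs(null[same_sign]).mean())
        nes = es / denom if denom > 0 else 0.0
    return GseaResult(es=es, nes=float(nes), p_value=float(p),
                      leading_edge=leading, n_perm=n_perm)


def filter_gsea(results: pd.DataFrame, es_cut: float) -> pd.DataFrame:
    """Keep rows with |ES| strictly above the context's enrichment-score cut."""
    if results.empty:
        return results.copy()
    return results[results["es"].abs() > es_cut].copy()
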