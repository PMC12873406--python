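"""Threshold-grid robustness scoring of differential expression calls.

Rather than committing to one (expression-rate, fold-change, FDR) threshold
triple, every gene is classified as up- or down-regulated at each combination
of a Cartesian threshold grid (default 21 rate x 11 FC x 6 FDR = 1386
combinations; the grid factors are quoted from the source analysis, whose
printed total of 1368 disagrees with its own factors and is logged as such).
A gene's robustness score per direction is the fraction of combinations at
which it qualifies; scores above 0.5 mark "probable" and above 0 "possible"
calls.  The same frequency logic applies to enriched gene-set terms.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import enrich_collection

logger = logging.getLogger("scrobust")

SOURCE_PRINTED_COMBOS = 1368  # total printed by the source analysis; inconsistent with 21*11*6


@dataclass
class ThresholdGrid:
    """Inclusive arithmetic threshold axes and their Cartesian product."""

    rate_thresholds: np.ndarray
    fc_thresholds: np.ndarray
    fdr_thresholds: np.ndarray

    def __post_init__(self) -> None:
        for name in ("rate_thresholds", "fc_thresholds", "fdr_thresholds"):
            axis = np.asarray(getattr(self, name), dtype=float)
            if axis.size == 0 or np.any(np.diff(axis) <= 0):
                raise ValueError(f"{name} must be non-empty and strictly increasing")
            setattr(self, name, axis)

    @property
    def n_combos(self) -> int:
        return (
            self.rate_thresholds.size
            * self.fc_thresholds.size
            * self.fdr_thresholds.size
        )

    @property
    def combos(self) -> list[tuple[float, float, float]]:
        """All (rate, fc, fdr) triples in deterministic rate-major order."""
        return list(
            itertools.product(
                self.rate_thresholds, self.fc_thresholds, self.fdr_thresholds
            )
        )


def _axis(spec: tuple[float, float, float]) -> np.ndarray:
    start, stop, step = spec
    if step <= 0:
        raise ValueError("threshold step must be positive")
    if start > stop:
        raise ValueError("threshold start must not exceed stop")
    n = int(round((stop - start) / step)) + 1
    vals = start + step * np.arange(n)
    return np.round(vals[vals <= stop + 1e-9], 10)


def make_grid(
    rate_spec: tuple[float, float, float] = (0.10, 0.30, 0.01),
    fc_spec: tuple[float, float, float] = (1.10, 1.20, 0.01),
    fdr_spec: tuple[float, float, float] = (0.05, 0.10, 0.01),
) -> ThresholdGrid:
    """Build the threshold grid from (start, stop, step) axis specs."""
    grid = ThresholdGrid(_axis(rate_spec), _axis(fc_spec), _axis(fdr_spec))
    if grid.n_combos != SOURCE_PRINTED_COMBOS and grid.n_combos == 1386:
        logger.info(
            "threshold grid: %d x %d x %d = %d combinations (the source "
            "analysis prints %d, inconsistent with its own stated factors)",
            grid.rate_thresholds.size,
            grid.fc_thresholds.size,
            grid.fdr_thresholds.size,
            grid.n_combos,
            SOURCE_PRINTED_COMBOS,
        )
    return grid


def classify_at(
    de_table: pd.DataFrame,
    combo: tuple[float, float, float],
    direction: str,
) -> set[str]:
    """Genes qualifying as DEGs at one (rate, fc, fdr) threshold triple.

    A gene qualifies iff expr_rate >= rate, fdr < fdr_cut, and its log2
    fold-change clears +/- log2(fc) in the requested direction.  Untested
    genes (NaN fdr) never qualify.
    """
    if direction not in ("down", "up"):
        raise ValueError("direction must be 'down' or 'up'")
    r, f, q = combo
    lfc = de_table["log2fc"].to_numpy(float)
    ok = (
        (de_table["expr_rate"].to_numpy(float) >= r)
        & (de_table["fdr"].to_numpy(float) < q)
    )
    cut = np.log2(f)
    ok &= (lfc >= cut) if direction == "up" else (lfc <= -cut)
    return set(de_table.index[ok])


def robustness_scores(de_table: pd.DataFrame, grid: ThresholdGrid) -> pd.DataFrame:
    """Per-gene, per-direction robustness scores and probable/possible class.

    The grid is axis-separable, so each gene's qualifying-combination count
    is the product of per-axis counts; this equals the naive loop over all
    combinations exactly.
    """
    rate = de_table["expr_rate"].to_numpy(float)[:, None]
    fdr = de_table["fdr"].to_numpy(float)[:, None]
    lfc = de_table["log2fc"].to_numpy(float)[:, None]
    tested = ~np.isnan(fdr[:, 0])

    n_rate = (rate >= grid.rate_thresholds[None, :]).sum(axis=1)
    with np.errstate(invalid="ignore"):
        n_fdr = (fdr < grid.fdr_thresholds[None, :]).sum(axis=1)
        cuts = np.log2(grid.fc_thresholds)[None, :]
        n_up = (lfc >= cuts).sum(axis=1)
        n_down = (lfc <= -cuts).sum(axis=1)
    base = np.where(tested, n_rate * n_fdr, 0)
    records = []
    for direction, n_fc in (("down", n_down), ("up", n_up)):
        score = base * np.where(tested, n_fc, 0) / grid.n_combos
        klass = np.where(score > 0.5, "probable", np.where(score > 0, "possible", "none"))
        records.append(
            pd.DataFrame(
                {
                    "gene_id": de_table.index,
                    "direction": direction,
                    "robustness_score": score,
                    "deg_class": klass,
                }
            )
        )
    return pd.concat(records, ignore_index=True)


def deg_sets(
    robustness: pd.DataFrame, direction: str, klass: str = "possible"
) -> set[str]:
    """Genes at or above a robustness class ('possible' includes 'probable')."""
    sub = robustness[robustness["direction"] == direction]
    if klass == "probable":
        keep = sub["deg_class"] == "probable"
    else:
        keep = sub["deg_class"].isin(("possible", "probable"))
    return set(sub.loc[keep, "gene_id"])


def term_robustness(
    de_table: pd.DataFrame,
    grid: ThresholdGrid,
    collection: dict[str, set[str]],
    background: set[str] | None = None,
    direction: str = "down",
    term_fdr: float = 0.05,
    min_overlap: int = 3,
    term_size: tuple[int, int] = (20, 500),
) -> pd.DataFrame:
    """Per-term robustness: fraction of grid combinations at which the term
    is enriched (hypergeometric, BH FDR < term_fdr, overlap >= min_overlap)
    among that combination's DEG set.

    The background defaults to the cluster's expressed genes
    (expr_rate > 0.10).  Terms are size-filtered before testing; terms with
    score > 0.5 are flagged robust.
    """
    if background is None:
        background = set(de_table.index[de_table["expr_rate"] > 0.10])
    lo, hi = term_size
    sized = {t: g for t, g in collection.items() if lo <= len(g) <= hi}
    term_ids = sorted(sized)
    hits_per_combo: dict[frozenset, set[str]] = {}
    counts = {t: 0 for t in term_ids}
    for combo in grid.combos:
        degs = frozenset(classify_at(de_table, combo, direction))
        if degs not in hits_per_combo:
            if degs:
                res = enrich_collection(
                    set(degs),
                    sized,
                    background,
                    fdr_cut=term_fdr,
                    size_range=term_size,
                    min_overlap=min_overlap,
                )
                hits_per_combo[degs] = set(res.index)
            else:
                hits_per_combo[degs] = set()
        for t in hits_per_combo[degs]:
            counts[t] += 1
    score = pd.Series({t: counts[t] / grid.n_combos for t in term_ids}, name="robustness_score")
    out = score.rename_axis("term_id").reset_index()
    out["direction"] = direction
    out["robust"] = out["robustness_score"] > 0.5
    return out


def term_fold_change(
    term_genes: set[str],
    de_table: pd.DataFrame,
    possible_deg_set: set[str],
    method: str = "geometric",
) -> float:
    """Aggregate fold-change of a term over its possible-DEG members.

    Geometric mean (default) of the member genes' fold-changes restricted to
    possible DEGs; returns NaN when no members qualify, in which case the
    term is omitted from fold-change displays.
    """
    members = sorted(term_genes & possible_deg_set & set(de_table.index))
    if not members:
        return float("nan")
    fcs = 2.0 ** de_table.loc[members, "log2fc"].to_numpy(float)
    if method == "geometric":
        return float(np.exp(np.mean(np.log(fcs))))
    if method == "arithmetic":
        return float(np.mean(fcs))
    raise ValueError("method must be 'geometric' or 'arithmetic'")
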