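"""Cross-set statistics: Fisher's exact 2x2 test, hypergeometric set
overlap, medication-signature screening, and gene-panel expression
summaries."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import contingency, fisher_exact

from .data_model import CellGeneDataset
from .enrichment import hypergeom_test

logger = logging.getLogger("scrobust")


@dataclass
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def as_array(self) -> np.ndarray:
        t = np.array([[self.a, self.b], [self.c, self.d]])
        if (t < 0).any():
            raise ValueError("2x2 table entries must be non-negative")
        return t


def fisher_exact_2x2(
    table: ContingencyTable2x2 | np.ndarray,
) -> tuple[float, float]:
    """Two-sided Fisher exact p and the conditional-MLE odds ratio.

    The p-value sums hypergeometric probabilities no larger than the
    observed table's; the odds ratio maximizes the noncentral
    hypergeometric conditional likelihood (the convention of standard
    statistical environments), not the sample cross-product ratio.  With a
    zero margin the table is untestable: p = 1, OR = NaN.
    """
    t = table.as_array() if isinstance(table, ContingencyTable2x2) else np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        logger.warning("fisher_exact_2x2: zero margin; p=1, OR undefined")
        return 1.0, float("nan")
    p = float(fisher_exact(t, alternative="two-sided").pvalue)
    or_cmle = float(contingency.odds_ratio(t, kind="conditional").statistic)
    return p, or_cmle


def hypergeom_overlap(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> tuple[float, float, int]:
    """Upper-tail hypergeometric overlap of two sets within a universe."""
    if not set_b <= universe:
        raise ValueError("set_b must be a subset of the universe")
    return hypergeom_test(set_a & universe, set_b, universe)


def signature_screen(
    deg_sets: dict[tuple[str, str], set[str]],
    signatures: dict[tuple[str, str], set[str]],
    universes: dict[str, set[str]],
    n_tests: int = 18,
) -> pd.DataFrame:
    """Hypergeometric overlap screen of direction-matched DEG sets against
    medication/substance signatures, Bonferroni-adjusted within cell type.

    ``deg_sets`` maps (cluster, direction) to possible-DEG sets;
    ``signatures`` maps (signature name, direction) to gene sets;
    ``universes`` maps cluster to its expressed-gene background.
    """
    rows = []
    for (cluster, direction), degs in sorted(deg_sets.items()):
        universe = universes[cluster]
        for (sig_name, sig_dir), sig_genes in sorted(signatures.items()):
            if sig_dir != direction:
                continue
            sig_in = sig_genes & universe
            if not sig_in:
                rows.append(
                    {"cluster": cluster, "direction": direction,
                     "signature": sig_name, "overlap": 0, "p_value": np.nan,
                     "adjusted_p": np.nan, "flag": "signature_outside_universe"}
                )
                continue
            p, _, k = hypergeom_test(degs & universe, sig_in, universe)
            rows.append(
                {"cluster": cluster, "direction": direction,
                 "signature": sig_name, "overlap": k, "p_value": p,
                 "adjusted_p": min(1.0, p * n_tests), "flag": "ok"}
            )
    return pd.DataFrame(rows)


def select_target_substances(detection_table: pd.DataFrame) -> list[str]:
    """Substances detected in >20% of case donors and at least twice as
    frequently as in controls.

    ``detection_table`` must have columns ``case_frac`` and ``control_frac``
    indexed by substance; the 20% rule is strict, the 2x rule inclusive.
    """
    case = detection_table["case_frac"]
    ctrl = detection_table["control_frac"]
    keep = (case > 0.20) & (case >= 2.0 * ctrl)
    return sorted(detection_table.index[keep])


def panel_expression_summary(
    dataset: CellGeneDataset, panel: list[str], min_rate: float = 0.1
) -> pd.DataFrame:
    """Per-cluster count and mean expression rate of expressed panel genes.

    A panel gene is "expressed" in a cluster when its expression rate there
    is strictly above ``min_rate``; panel genes absent from the dataset are
    ignored with a warning.
    """
    if not panel:
        raise ValueError("gene panel is empty")
    present = [g for g in panel if g in dataset.gene_ids]
    missing = sorted(set(panel) - set(present))
    if missing:
        logger.warning("panel genes absent from dataset: %s", missing)
    if not present:
        raise ValueError("no panel gene is present in the dataset")
    cols = pd.Index(dataset.gene_ids).get_indexer(present)
    labels = dataset.cell_meta["cluster_label"].to_numpy()
    rows = []
    for cluster in sorted(pd.unique(labels)):
        mask = labels == cluster
        rates = dataset.expression_rate(mask)[cols]
        expressed = rates > min_rate
        rows.append(
            {
                "cluster": cluster,
                "n_expressed": int(expressed.sum()),
                "mean_rate": float(rates[expressed].mean()) if expressed.any() else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("cluster")
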