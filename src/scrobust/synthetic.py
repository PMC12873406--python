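"""Synthetic case-control single-nucleus datasets with recorded ground truth.

The generator emulates the structure the downstream statistics assume: a
two-group multi-sample design, cluster-structured cells with marker genes,
negative-binomial UMI counts whose zeros arise from low means (so the
fitted hurdle model is a working model, not the generative truth), planted
diagnosis effects on expressed level and on detection, planted cluster
proportion fold-changes, planted enriched gene-set terms, and planted
low-rank trans-cellular programs.  Every planted effect is recorded in a
:class:`GroundTruth` that serializes to JSON.

Planted detection-logit shifts stay inside the negative-binomial family:
the case-cell mean is warped so that the zero probability satisfies
``logit(p_detect_case) = logit(p_detect_control) + shift`` exactly, cell by
cell.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit, logit

from .composition import CompositionTable
from .data_model import CellGeneDataset


@dataclass
class ClusterSpec:
    label: str
    major_class: str
    baseline_prop: float
    n_markers: int = 25
    marker_boost: float = 8.0


@dataclass
class DEEffect:
    """Planted diagnosis effect on one gene in one cluster."""

    level_lfc: float = 0.0  # natural-log fold shift of the expressed mean
    detection_logit_shift: float = 0.0


@dataclass
class ProgramSpec:
    """Planted low-rank gene program spanning one or more major classes."""

    name: str
    genes: list[str]
    loadings: list[float]
    classes: list[str]
    activity: float = 0.9
    case_shift: float = 0.5  # multiplier on activity in case cells


@dataclass
class SimulationConfig:
    n_case: int = 6
    n_control: int = 6
    clusters: list[ClusterSpec] = field(default_factory=list)
    composition_effects: dict[str, float] = field(default_factory=dict)
    n_genes: int = 400
    de_effects: dict[str, dict[str, DEEffect]] = field(default_factory=dict)
    covariate_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    sample_re_sd: float = 0.15
    nb_dispersion: float = 2.0  # NB size; smaller = more overdispersion
    cells_per_sample: float = 650.0
    target_umi: float = 600.0
    library_log_sd: float = 0.35
    dirichlet_conc: float = 350.0  # donor-to-donor composition tightness
    frac_coding: float = 0.9
    n_mito: int = 5
    planted_terms: dict[str, list[str]] = field(default_factory=dict)
    planted_programs: list[ProgramSpec] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        props = [c.baseline_prop for c in self.clusters]
        if not np.isclose(sum(props), 1.0):
            raise ValueError("baseline proportions must sum to 1")
        labels = {c.label for c in self.clusters}
        for cl in self.composition_effects:
            if cl not in labels:
                raise ValueError(f"composition effect on unknown cluster {cl!r}")
        for cl in self.de_effects:
            if cl not in labels:
                raise ValueError(f"DE effect on unknown cluster {cl!r}")


@dataclass
class GroundTruth:
    """Planted effects, recorded in the terms the downstream stages report."""

    true_deg: dict[str, dict[str, list[str]]]
    composition_fc: dict[str, float]
    terms: dict[str, list[str]]
    enriched_terms: dict[str, dict[str, list[str]]]
    programs: list[ProgramSpec]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        raw["programs"] = [ProgramSpec(**p) for p in raw["programs"]]
        return cls(**raw)


# ---------------------------------------------------------------------------
# deterministic structural draws (shared between generate() and builders)
# ---------------------------------------------------------------------------

def gene_structure(config: SimulationConfig) -> dict:
    """Gene baselines, flags, and cluster marker assignments for a config.

    Deterministic given (seed, n_genes, clusters); used both inside
    ``generate`` and by fixture builders that must place planted effects on
    genes of suitable abundance.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    g = config.n_genes
    gene_ids = [f"G{i:04d}" for i in range(g)]
    base = rng.lognormal(0.0, 1.2, g)
    is_mito = np.zeros(g, dtype=bool)
    is_mito[g - config.n_mito:] = True
    base[is_mito] = base[~is_mito].mean() * 1.5  # ~modest mito share
    base = base / base.sum()
    coding = rng.random(g) < config.frac_coding
    coding[is_mito] = False
    markers: dict[str, np.ndarray] = {}
    taken = np.zeros(g, dtype=bool)
    taken[is_mito] = True
    for spec in config.clusters:
        free = np.flatnonzero(~taken)
        pick = rng.choice(free, size=min(spec.n_markers, len(free)), replace=False)
        taken[pick] = True
        markers[spec.label] = pick
    profiles = {}
    for spec in config.clusters:
        prof = base.copy()
        prof[markers[spec.label]] *= spec.marker_boost
        profiles[spec.label] = prof / prof.sum()
    return {
        "gene_ids": gene_ids,
        "base": base,
        "is_mito": is_mito,
        "is_coding": coding,
        "markers": markers,
        "profiles": profiles,
    }


def _sample_frame(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    ids = [f"BD{i + 1:02d}" for i in range(config.n_case)] + [
        f"CT{i + 1:02d}" for i in range(config.n_control)
    ]
    diagnosis = ["case"] * config.n_case + ["control"] * config.n_control
    n = len(ids)
    age = np.clip(rng.normal(48.0, 13.0, n), 20, 90).round(1)
    sex = np.where(np.arange(n) % 2 == rng.integers(0, 2), "M", "F")
    pmi = np.clip(rng.normal(30.0, 10.0, n), 5, 80).round(1)
    ph = np.clip(rng.normal(6.5, 0.25, n), 5.8, 7.2).round(2)
    batch = [f"B{i // 2 + 1:02d}" for i in range(n)]
    return pd.DataFrame(
        {"diagnosis": diagnosis, "age": age, "sex": sex, "pmi": pmi,
         "ph": ph, "batch": batch},
        index=pd.Index(ids, name="sample_id"),
    )


def _case_proportions(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray, dict]:
    """Baseline and case cluster proportions; planted clusters keep their
    exact proportion fold-change, unplanted clusters absorb the remainder
    proportionally."""
    base = np.array([c.baseline_prop for c in config.clusters])
    labels = [c.label for c in config.clusters]
    case = base.copy()
    planted = np.zeros(len(base), dtype=bool)
    for i, lab in enumerate(labels):
        if lab in config.composition_effects:
            case[i] = base[i] * config.composition_effects[lab]
            planted[i] = True
    rest = 1.0 - case[planted].sum()
    if rest <= 0:
        raise ValueError("composition effects exceed the whole composition")
    case[~planted] = base[~planted] / base[~planted].sum() * rest
    realized_fc = {lab: float(case[i] / base[i]) for i, lab in enumerate(labels)}
    return base, case, realized_fc


def detection_shift_mu(mu: np.ndarray, shift: float, size: float) -> np.ndarray:
    """Warp NB means so the detection probability moves by ``shift`` logits.

    p(mu) = 1 - (size/(size+mu))^size; the returned mu' satisfies
    logit(p(mu')) = logit(p(mu)) + shift exactly.
    """
    p0 = 1.0 - (size / (size + mu)) ** size
    p0 = np.clip(p0, 1e-12, 1 - 1e-12)
    p1 = expit(logit(p0) + shift)
    return size * ((1.0 - p1) ** (-1.0 / size) - 1.0)


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def generate(config: SimulationConfig) -> tuple[CellGeneDataset, GroundTruth]:
    """Draw one dataset from the configured generative model."""
    config.validate()
    struct = gene_structure(config)
    gene_ids = struct["gene_ids"]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    sample_meta = _sample_frame(config, rng)
    labels = [c.label for c in config.clusters]
    classes = {c.label: c.major_class for c in config.clusters}
    base_prop, case_prop, realized_fc = _case_proportions(config)
    size = config.nb_dispersion
    g = config.n_genes

    age = sample_meta["age"].to_numpy(float)
    z_age = (age - age.mean()) / (age.std() or 1.0)
    sex_m = (sample_meta["sex"] == "M").to_numpy().astype(float)

    # per-gene covariate effect vectors (per SD of age; per male sex)
    beta_age = np.zeros(g)
    beta_sex = np.zeros(g)
    gene_pos = {gid: i for i, gid in enumerate(gene_ids)}
    for gid, effs in config.covariate_effects.items():
        beta_age[gene_pos[gid]] = effs.get("age", 0.0)
        beta_sex[gene_pos[gid]] = effs.get("sex", 0.0)

    blocks = []
    cell_rows = []
    for s_idx, (sid, row) in enumerate(sample_meta.iterrows()):
        is_case = row["diagnosis"] == "case"
        props = case_prop if is_case else base_prop
        props = rng.dirichlet(props * config.dirichlet_conc)
        n_cells = max(int(rng.poisson(config.cells_per_sample)), 10)
        assign = rng.choice(len(labels), size=n_cells, p=props)
        lib = rng.lognormal(0.0, config.library_log_sd, n_cells)
        u = rng.normal(0.0, config.sample_re_sd, g)  # per-sample, per-gene
        cov = np.exp(beta_age * z_age[s_idx] + beta_sex * sex_m[s_idx] + u)
        mu = np.empty((n_cells, g))
        for k, lab in enumerate(labels):
            rows = assign == k
            if not rows.any():
                continue
            prof = struct["profiles"][lab] * cov
            mu[rows] = np.outer(lib[rows] * config.target_umi, prof)
            # planted trans-cellular programs (multiplicative on the mean)
            for prog in config.planted_programs:
                if classes[lab] not in prog.classes:
                    continue
                act = prog.activity * rng.uniform(0.5, 1.5, int(rows.sum()))
                if is_case:
                    act = act * prog.case_shift
                cols = [gene_pos[x] for x in prog.genes]
                w = np.asarray(prog.loadings)
                mu[np.ix_(np.flatnonzero(rows), cols)] *= np.exp(
                    np.outer(act, w)
                )
            # planted diagnosis effects (cases only)
            if is_case and lab in config.de_effects:
                for gid, eff in config.de_effects[lab].items():
                    j = gene_pos[gid]
                    if eff.level_lfc:
                        mu[rows, j] *= np.exp(eff.level_lfc)
                    if eff.detection_logit_shift:
                        mu[rows, j] = detection_shift_mu(
                            mu[rows, j], eff.detection_logit_shift, size
                        )
        counts = rng.negative_binomial(size, size / (size + mu))
        blocks.append(sp.csr_matrix(counts))
        for c in range(n_cells):
            cell_rows.append(
                {
                    "barcode": f"{sid}_C{c:05d}",
                    "sample_id": sid,
                    "cluster_label": labels[assign[c]],
                    "major_class": classes[labels[assign[c]]],
                }
            )

    counts = sp.vstack(blocks).tocsr()
    cell_meta = pd.DataFrame(cell_rows).set_index("barcode")
    gene_meta = pd.DataFrame(
        {
            "symbol": [f"MT-{i}" if m else gid
                       for i, (gid, m) in enumerate(zip(gene_ids, struct["is_mito"]))],
            "is_protein_coding": struct["is_coding"],
            "is_mito": struct["is_mito"],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    dataset = CellGeneDataset(counts, cell_meta, sample_meta, gene_meta)

    true_deg: dict[str, dict[str, list[str]]] = {}
    for lab, effs in config.de_effects.items():
        up = sorted(gid for gid, e in effs.items() if e.level_lfc > 0)
        down = sorted(gid for gid, e in effs.items() if e.level_lfc < 0)
        true_deg[lab] = {"up": up, "down": down}
    enriched = {
        lab: {
            d: sorted(
                t for t, genes in config.planted_terms.items()
                if len(set(genes) & set(true_deg[lab][d])) >= 3
            )
            for d in ("down", "up")
        }
        for lab in true_deg
    }
    truth = GroundTruth(
        true_deg=true_deg,
        composition_fc=realized_fc,
        terms={t: sorted(gs) for t, gs in config.planted_terms.items()},
        enriched_terms=enriched,
        programs=list(config.planted_programs),
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def fixture_small_config(seed: int = 2024) -> SimulationConfig:
    """Desk-scale study emulation: 6 vs 6 donors, 4 clusters, 400 genes.

    Plants (a) a composition reduction (FC 0.55) on a small excitatory
    cluster, (b) 20 down- and 20 up-regulated genes (|log-FC| = ln 2.2) in
    the large excitatory cluster, each direction backing one enriched term,
    (c) an age-driven gene sized to FC 1.3 per 2 SD of age, and (d) one
    two-class (excitatory + microglia) program with halved case activity.
    """
    config = SimulationConfig(
        n_case=6,
        n_control=6,
        clusters=[
            ClusterSpec("ExN_A", "Excitatory", 0.40),
            ClusterSpec("ExN_CALB", "Excitatory", 0.08),
            ClusterSpec("Micro", "Microglia", 0.22),
            ClusterSpec("Oligo", "Oligodendrocyte", 0.30),
        ],
        composition_effects={"ExN_CALB": 0.55},
        n_genes=400,
        seed=seed,
    )
    struct = gene_structure(config)
    mu_a = config.target_umi * struct["profiles"]["ExN_A"]
    marker_set = set(np.concatenate(list(struct["markers"].values())))
    eligible = [
        i
        for i in np.argsort(-mu_a)
        if struct["is_coding"][i]
        and i not in marker_set
        and 0.35 <= mu_a[i] <= 1.5  # moderate expression-rate band
    ]
    gid = struct["gene_ids"]
    down = [gid[i] for i in eligible[:20]]
    up = [gid[i] for i in eligible[20:40]]
    null_pool = [gid[i] for i in eligible[40:]]
    # the age-effect gene must be highly expressed: only then does the
    # expressed-magnitude (continuous) part track the planted mean shift
    high = [
        i
        for i in np.argsort(-mu_a)
        if struct["is_coding"][i] and i not in marker_set and mu_a[i] >= 5.0
    ]
    age_gene = gid[high[0]] if high else gid[eligible[40]]
    prog_pool = [
        gid[i]
        for i in np.argsort(-mu_a)
        if struct["is_coding"][i] and i not in marker_set
        and gid[i] not in set(down) | set(up) | {age_gene}
        and 0.2 <= mu_a[i] <= 2.0
    ]
    prog_genes = prog_pool[:40]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    config.de_effects = {
        "ExN_A": {
            **{g: DEEffect(level_lfc=-float(np.log(2.2))) for g in down},
            **{g: DEEffect(level_lfc=float(np.log(2.2))) for g in up},
        }
    }
    config.covariate_effects = {age_gene: {"age": float(np.log(1.3) / 2.0)}}
    terms: dict[str, list[str]] = {
        "TERM_DOWN_SYNAPTIC": sorted(down + null_pool[:5]),
        "TERM_UP_TRANSPORT": sorted(up + null_pool[5:10]),
    }
    pool = [g for g in null_pool[10:]] + [
        g for g in gid if g not in set(down) | set(up) and g not in null_pool
    ]
    for t in range(12):
        size = int(rng.integers(20, 45))
        terms[f"TERM_NULL_{t:02d}"] = sorted(
            rng.choice(pool, size=min(size, len(pool)), replace=False).tolist()
        )
    config.planted_terms = terms
    config.planted_programs = [
        ProgramSpec(
            name="ExcitMicro",
            genes=prog_genes,
            loadings=rng.uniform(0.5, 1.0, len(prog_genes)).round(4).tolist(),
            classes=["Excitatory", "Microglia"],
            activity=0.9,
            case_shift=0.5,
        )
    ]
    return config


def fixture_small(seed: int = 2024) -> tuple[CellGeneDataset, GroundTruth]:
    """The deterministic test-suite dataset (~8000 cells, runs in seconds)."""
    return generate(fixture_small_config(seed))


def null_de_config(
    seed: int = 0,
    n_case: int = 20,
    n_control: int = 20,
    n_genes: int = 600,
    cells_per_sample: float = 40.0,
    sample_re_sd: float = 0.3,
) -> SimulationConfig:
    """Null diagnosis effect with real per-sample random intercepts: the
    calibration condition for the hurdle LRT, at the study's donor scale."""
    return SimulationConfig(
        n_case=n_case,
        n_control=n_control,
        clusters=[ClusterSpec("C1", "Excitatory", 1.0, n_markers=0)],
        n_genes=n_genes,
        cells_per_sample=cells_per_sample,
        target_umi=900.0,
        sample_re_sd=sample_re_sd,
        seed=seed,
    )


def fixture_composition(
    seed: int = 0,
    n_case: int = 12,
    n_control: int = 12,
    planted_fc: float = 0.55,
    conc: float = 350.0,
    mean_total: float = 8000.0,
) -> tuple[CompositionTable, dict[str, float]]:
    """Sample x cluster counts only (no gene matrix): a Dirichlet-
    multinomial composition fixture for subsampling robustness studies."""
    config = SimulationConfig(
        n_case=n_case,
        n_control=n_control,
        clusters=[
            ClusterSpec("ExN_A", "Excitatory", 0.40),
            ClusterSpec("ExN_CALB", "Excitatory", 0.08),
            ClusterSpec("InN", "Inhibitory", 0.10),
            ClusterSpec("Micro", "Microglia", 0.12),
            ClusterSpec("Astro", "Astrocyte", 0.10),
            ClusterSpec("Oligo", "Oligodendrocyte", 0.20),
        ],
        composition_effects={"ExN_CALB": planted_fc},
        dirichlet_conc=conc,
        seed=seed,
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 41]))
    sample_meta = _sample_frame(config, rng)
    base, case, realized = _case_proportions(config)
    labels = [c.label for c in config.clusters]
    rows = []
    for sid, row in sample_meta.iterrows():
        p = rng.dirichlet((case if row["diagnosis"] == "case" else base) * conc)
        total = int(rng.poisson(mean_total))
        rows.append(rng.multinomial(total, p))
    counts = pd.DataFrame(rows, index=sample_meta.index, columns=labels)
    return CompositionTable(counts=counts, sample_meta=sample_meta), realized


def fixture_aic_regions(
    seed: int = 0,
    n_case: int = 20,
    n_control: int = 20,
    n_clusters: int = 8,
    beta_age: float = 0.3,
    beta_sex: float = 0.4,
    beta_dx: float = -0.3,
    nb_size: float = 15.0,
) -> dict[str, CompositionTable]:
    """Two-region sample x cluster counts generated from Dx + age + sex:
    the model-recovery condition for AIC rank-sum selection.

    Covariate effects carry cluster-specific signs/sizes so they move the
    composition (not just per-sample totals, which per-sample count
    normalization would cancel)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 53]))
    out = {}
    for region in ("thalamus", "cortex"):
        sample_meta = _sample_frame(
            SimulationConfig(n_case=n_case, n_control=n_control), rng
        )
        z_age = sample_meta["age"].to_numpy(float)
        z_age = (z_age - z_age.mean()) / (z_age.std() or 1.0)
        sex = (sample_meta["sex"] == "M").to_numpy().astype(float)
        dx = (sample_meta["diagnosis"] == "case").to_numpy().astype(float)
        base = rng.dirichlet(np.full(n_clusters, 5.0)) * 10_000
        b_age = beta_age * rng.choice([-1.0, 1.0], n_clusters) * rng.uniform(
            0.7, 1.3, n_clusters
        )
        b_sex = beta_sex * rng.choice([-1.0, 1.0], n_clusters) * rng.uniform(
            0.7, 1.3, n_clusters
        )
        counts = np.empty((len(sample_meta), n_clusters), dtype=int)
        for k in range(n_clusters):
            mu = base[k] * np.exp(
                b_age[k] * z_age + b_sex[k] * sex + beta_dx * dx * (k % 2 == 0)
            )
            counts[:, k] = rng.negative_binomial(nb_size, nb_size / (nb_size + mu))
        out[region] = CompositionTable(
            counts=pd.DataFrame(
                counts, index=sample_meta.index,
                columns=[f"{region[:3]}_C{k}" for k in range(n_clusters)],
            ),
            sample_meta=sample_meta,
        )
    return out
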