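"""Synthetic input bundles with planted ground truth.

Emulates the five inputs the analysis consumes — a ranked regulator->target
network, a gene->co-expression-module table, a two-group count matrix, a
gene catalog (TF flag + protein class) and gene->term annotations — for a
single tissue, with a recorded :class:`SyntheticTruth` so every downstream
stage can be tested for recovery without any external download.

The planted design mirrors an RNAi silencing experiment during grain
filling: a small "gliadin-like" gene family is strongly knocked down in the
treated group, a handful of causal TFs respond, and a fraction of each
causal TF's network targets shift expression (down with probability 0.8).
Counts are negative-binomial with log-normal baseline abundances and
log-normal library sizes; two tissues are two independent bundles.

All randomness flows from ``SimulationConfig.seed`` through fixed per-stage
substreams, so identical configs give byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .comod import ModuleAssignment
from .dge import CONTROL, TREATED, CountMatrix
from .enrich import TermAnnotation
from .regnet import RankedEdgeList

__all__ = [
    "ConfigurationError",
    "SimulationConfig",
    "SyntheticTruth",
    "Bundle",
    "generate_network",
    "generate_truth",
    "generate_modules",
    "generate_counts",
    "generate_catalog_and_annotations",
    "simulate_bundle",
    "write_fixture_bundle",
    "read_bundle",
]

# per-stage RNG substream indices (documented stream splitting)
_STREAM_NETWORK = 0
_STREAM_TRUTH = 1
_STREAM_MODULES = 2
_STREAM_COUNTS = 3
_STREAM_ANNOT = 4
_STREAM_BASELINE = 5


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of a synthetic bundle.

    Defaults follow the emulated experiment: two groups (wild-type-like
    control vs. silenced treated) with three biological replicates each, a
    strongly silenced storage-protein-like family (50-fold knockdown), a few
    causal TFs whose targets shift 4-fold, moderate biological variability
    (NB dispersion 0.1) and million-read libraries.
    """

    n_genes: int = 5000
    n_tfs: int = 250
    targets_per_tf_mean: float = 20.0
    targets_per_tf_dispersion: float = 1.0
    n_modules: int = 30
    n_causal_tfs: int = 5
    n_silenced_genes: int = 20
    knockdown_fold: float = 50.0
    propagation_fold: float = 4.0
    propagated_fraction: float = 0.5
    causal_tf_fold: float = 4.0
    down_probability: float = 0.8
    n_replicates_per_group: int = 3
    nb_dispersion: float = 0.1
    library_size_mean: int = 1_000_000
    library_size_cv: float = 0.1
    baseline_log_sd: float = 1.5
    module_mixing: float = 0.3
    network_min_expected_count: float = 10.0
    n_terms: int = 40
    mean_term_size: int = 40
    planted_term_size: int = 30
    planted_term_de_fraction: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ConfigurationError("n_genes must be >= 2")
        if not (0 < self.n_tfs < self.n_genes):
            raise ConfigurationError("n_tfs must satisfy 0 < n_tfs < n_genes")
        if self.n_causal_tfs < 0 or self.n_causal_tfs > self.n_tfs:
            raise ConfigurationError("n_causal_tfs must be in [0, n_tfs]")
        if not (0.0 <= self.propagated_fraction <= 1.0):
            raise ConfigurationError("propagated_fraction must be in [0, 1]")
        if not (0.0 <= self.module_mixing <= 1.0):
            raise ConfigurationError("module_mixing must be in [0, 1]")
        for name in (
            "targets_per_tf_mean",
            "knockdown_fold",
            "propagation_fold",
            "causal_tf_fold",
            "library_size_mean",
            "baseline_log_sd",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.nb_dispersion < 0 or self.targets_per_tf_dispersion < 0:
            raise ConfigurationError("dispersions must be >= 0")
        if self.n_replicates_per_group < 2:
            raise ConfigurationError("n_replicates_per_group must be >= 2")
        if self.n_modules < 1:
            raise ConfigurationError("n_modules must be >= 1")
        if self.n_silenced_genes > self.n_genes - self.n_tfs:
            raise ConfigurationError("n_silenced_genes exceeds available non-TF genes")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % 2**31, stream])

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i:06d}" for i in range(1, self.n_genes + 1)]

    @property
    def tf_ids(self) -> list[str]:
        return self.gene_ids[: self.n_tfs]


@dataclass
class SyntheticTruth:
    """Ground-truth ledger: who was planted, where, and in which direction."""

    causal_tfs: set[str] = field(default_factory=set)
    silenced_family: set[str] = field(default_factory=set)
    de_direction: dict[str, int] = field(default_factory=dict)  # gene -> +1/-1
    fold_of: dict[str, float] = field(default_factory=dict)  # treated/control fold
    module_of: dict[str, str] = field(default_factory=dict)
    propagated_targets: dict[str, list[str]] = field(default_factory=dict)

    @property
    def true_de_genes(self) -> set[str]:
        return set(self.de_direction)

    def to_json_dict(self) -> dict:
        return {
            "causal_tfs": sorted(self.causal_tfs),
            "silenced_family": sorted(self.silenced_family),
            "de_direction": dict(sorted(self.de_direction.items())),
            "fold_of": dict(sorted(self.fold_of.items())),
            "propagated_targets": {
                k: sorted(v) for k, v in sorted(self.propagated_targets.items())
            },
        }

    @classmethod
    def from_json_dict(cls, d: dict, module_of: dict[str, str] | None = None):
        return cls(
            causal_tfs=set(d["causal_tfs"]),
            silenced_family=set(d["silenced_family"]),
            de_direction={k: int(v) for k, v in d["de_direction"].items()},
            fold_of={k: float(v) for k, v in d["fold_of"].items()},
            module_of=module_of or {},
            propagated_targets={k: list(v) for k, v in d.get("propagated_targets", {}).items()},
        )


def baseline_abundances(cfg: SimulationConfig) -> np.ndarray:
    """Log-normal baseline relative abundances, one per gene.

    Drawn in a dedicated seed stream so the network, the counts and the
    truth all see the same expression landscape.
    """
    rng = cfg.rng(_STREAM_BASELINE)
    w = rng.lognormal(mean=0.0, sigma=cfg.baseline_log_sd, size=cfg.n_genes)
    return w / w.sum()


def expressed_mask(cfg: SimulationConfig) -> np.ndarray:
    """Genes whose expected baseline count clears the network floor.

    Expression-inferred networks only contain genes with usable signal; the
    floor (expected count >= ``network_min_expected_count`` at the configured
    mean library size) mirrors the standard low-count exclusion used when
    building co-expression networks.
    """
    expected = baseline_abundances(cfg) * cfg.library_size_mean
    mask = expected >= cfg.network_min_expected_count
    if mask.sum() < 2:  # degenerate tiny configs: fall back to all genes
        mask = np.ones(cfg.n_genes, dtype=bool)
    return mask


def generate_network(cfg: SimulationConfig) -> RankedEdgeList:
    """Ranked regulator->target edge list with Pareto-tailed importances.

    Regulators are the designated TFs only; targets are drawn from the
    expressed gene pool (see :func:`expressed_mask`); out-degrees are shifted
    negative-binomial around ``targets_per_tf_mean`` (minimum 1); no
    self-loops; importances are continuous, hence a.s. unique, so the
    canonical ordering is reproducible from the seed.
    """
    rng = cfg.rng(_STREAM_NETWORK)
    genes = np.array(cfg.gene_ids)
    pool_all = np.flatnonzero(expressed_mask(cfg))
    rows = []
    mean_extra = max(cfg.targets_per_tf_mean - 1.0, 1e-9)
    disp = cfg.targets_per_tf_dispersion
    for i, tf in enumerate(cfg.tf_ids):
        if disp > 0:
            extra = rng.negative_binomial(1.0 / disp, 1.0 / (1.0 + disp * mean_extra))
        else:
            extra = rng.poisson(mean_extra)
        pool = pool_all[pool_all != i]
        d = min(1 + int(extra), len(pool))
        targets = genes[rng.choice(pool, size=d, replace=False)]
        imp = 1.0 + rng.pareto(1.5, size=d)
        for t, w in zip(targets, imp):
            rows.append((tf, t, float(w)))
    df = pd.DataFrame(rows, columns=["regulator", "target", "importance"])
    return RankedEdgeList.from_frame(df)


def generate_truth(cfg: SimulationConfig, network: RankedEdgeList) -> SyntheticTruth:
    """Plant the silenced family, the causal TFs and their propagated targets."""
    rng = cfg.rng(_STREAM_TRUTH)
    truth = SyntheticTruth()
    mask = expressed_mask(cfg)
    non_tf = [g for i, g in enumerate(cfg.gene_ids) if i >= cfg.n_tfs and mask[i]]
    if len(non_tf) < cfg.n_silenced_genes:
        raise ConfigurationError(
            "not enough expressed non-TF genes for the silenced family"
        )
    silenced = sorted(rng.choice(non_tf, size=cfg.n_silenced_genes, replace=False))
    truth.silenced_family = set(silenced)
    for g in silenced:
        if cfg.knockdown_fold != 1.0:
            truth.de_direction[g] = -1
            truth.fold_of[g] = 1.0 / cfg.knockdown_fold

    targets_of = network.targets_of()
    # a causal TF must be observably expressed: its response is what the
    # DE stage is meant to see (an unexpressed regulator never reaches the
    # candidate rule, which requires the TF itself to be called DE)
    expressed_tfs = [g for i, g in enumerate(cfg.tf_ids) if mask[i]]
    pool = expressed_tfs if len(expressed_tfs) >= cfg.n_causal_tfs else cfg.tf_ids
    causal = sorted(rng.choice(pool, size=cfg.n_causal_tfs, replace=False))
    truth.causal_tfs = set(causal)
    for tf in causal:
        if cfg.causal_tf_fold != 1.0:
            truth.de_direction[tf] = -1
            truth.fold_of[tf] = 1.0 / cfg.causal_tf_fold
        targets = sorted(targets_of.get(tf, set()) - truth.silenced_family)
        n_prop = int(round(cfg.propagated_fraction * len(targets)))
        chosen = sorted(rng.choice(targets, size=n_prop, replace=False)) if n_prop else []
        truth.propagated_targets[tf] = list(chosen)
        for g in chosen:
            if cfg.propagation_fold == 1.0 or g in truth.fold_of:
                continue
            down = rng.random() < cfg.down_probability
            truth.de_direction[g] = -1 if down else 1
            truth.fold_of[g] = (
                1.0 / cfg.propagation_fold if down else cfg.propagation_fold
            )
    return truth


def generate_modules(
    cfg: SimulationConfig, network: RankedEdgeList, truth: SyntheticTruth | None = None
) -> ModuleAssignment:
    """Assign every gene one module label ("module_k").

    Each TF gets a home module; with probability ``1 - module_mixing`` a
    regulated gene joins the home module of its strongest regulator,
    otherwise (and for unregulated genes) a uniformly random module.  Mixing
    0 therefore makes co-targets of a TF share one module; mixing 1 makes
    labels independent of the network.
    """
    rng = cfg.rng(_STREAM_MODULES)
    labels = [f"module_{k}" for k in range(1, cfg.n_modules + 1)]
    home = {tf: labels[rng.integers(cfg.n_modules)] for tf in cfg.tf_ids}
    # strongest regulator per target: first occurrence in the canonical order
    strongest = (
        network.edges.drop_duplicates(subset="target", keep="first")
        .set_index("target")["regulator"]
        .to_dict()
    )
    module_of: dict[str, str] = {}
    for g in cfg.gene_ids:
        reg = strongest.get(g)
        if reg is not None and rng.random() >= cfg.module_mixing:
            module_of[g] = home[reg]
        else:
            module_of[g] = labels[rng.integers(cfg.n_modules)]
    if truth is not None:
        truth.module_of = dict(module_of)
    return ModuleAssignment(module_of=module_of)


def generate_counts(cfg: SimulationConfig, truth: SyntheticTruth) -> CountMatrix:
    """Negative-binomial counts with group-specific means.

    Baseline relative abundances are log-normal; the treated-group mean of a
    planted gene is its baseline times the recorded fold; library sizes are
    log-normal around ``library_size_mean``.
    """
    rng = cfg.rng(_STREAM_COUNTS)
    n = cfg.n_genes
    q = baseline_abundances(cfg)
    fold = np.ones(n)
    idx = {g: i for i, g in enumerate(cfg.gene_ids)}
    for g, f in truth.fold_of.items():
        fold[idx[g]] = f
    nrep = cfg.n_replicates_per_group
    cv = cfg.library_size_cv
    sigma2 = math.log(1.0 + cv * cv)
    mu_log = math.log(cfg.library_size_mean) - sigma2 / 2.0
    libs = rng.lognormal(mean=mu_log, sigma=math.sqrt(sigma2), size=2 * nrep)
    samples = [f"{CONTROL}_{i+1}" for i in range(nrep)] + [
        f"{TREATED}_{i+1}" for i in range(nrep)
    ]
    counts = np.empty((n, 2 * nrep), dtype=np.int64)
    phi = cfg.nb_dispersion
    for j, lib in enumerate(libs):
        mean = q * lib * (fold if j >= nrep else 1.0)
        if phi == 0:
            counts[:, j] = rng.poisson(mean)
        else:
            counts[:, j] = rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + phi * mean))
    cm = pd.DataFrame(counts, index=cfg.gene_ids, columns=samples)
    groups = pd.Series(
        [CONTROL] * nrep + [TREATED] * nrep, index=samples, name="group"
    )
    return CountMatrix(counts=cm, groups=groups)


def generate_catalog_and_annotations(
    cfg: SimulationConfig, truth: SyntheticTruth, network: RankedEdgeList
) -> tuple[pd.DataFrame, TermAnnotation]:
    """Gene catalog (is_tf, protein_class) and term annotations.

    The silenced family is classed "gliadin_like"; down-propagated targets
    seed an "ssrg_like" class; non-DE genes seed a "globulin_like" class.
    One term per domain pair is planted to be enriched in the true DE set by
    construction: "T_planted" (BP) and "T_planted_pw" (pathway).
    """
    rng = cfg.rng(_STREAM_ANNOT)
    genes = cfg.gene_ids
    tf_set = set(cfg.tf_ids)
    cls = pd.Series("other", index=genes, name="protein_class")
    cls.loc[sorted(truth.silenced_family)] = "gliadin_like"
    down_targets = sorted(
        g
        for tgts in truth.propagated_targets.values()
        for g in tgts
        if truth.de_direction.get(g) == -1
    )
    cls.loc[down_targets[:14]] = "ssrg_like"
    non_de = [g for g in genes if g not in truth.true_de_genes and g not in tf_set]
    n_glob = min(10, len(non_de))
    glob = sorted(rng.choice(non_de, size=n_glob, replace=False)) if n_glob else []
    cls.loc[glob] = "globulin_like"
    catalog = pd.DataFrame(
        {"is_tf": [g in tf_set for g in genes], "protein_class": cls}, index=genes
    )
    catalog.index.name = "gene_id"

    domains = ("BP", "MF", "CC", "pathway")
    gene_terms: dict[str, set[str]] = {}
    term_rows = []
    for t in range(1, cfg.n_terms + 1):
        tid = f"T{t:04d}"
        dom = domains[(t - 1) % 4]
        term_rows.append({"term_id": tid, "name": f"synthetic term {t}", "domain": dom})
        size = max(2, int(rng.poisson(cfg.mean_term_size)))
        for g in rng.choice(genes, size=min(size, cfg.n_genes), replace=False):
            gene_terms.setdefault(g, set()).add(tid)
    de = sorted(truth.true_de_genes)
    background = [g for g in genes if g not in truth.true_de_genes]
    for tid, dom in (("T_planted", "BP"), ("T_planted_pw", "pathway")):
        term_rows.append(
            {"term_id": tid, "name": f"planted enriched term ({dom})", "domain": dom}
        )
        n_de = min(int(round(cfg.planted_term_size * cfg.planted_term_de_fraction)), len(de))
        n_bg = min(cfg.planted_term_size - n_de, len(background))
        chosen = list(rng.choice(de, size=n_de, replace=False)) + list(
            rng.choice(background, size=n_bg, replace=False)
        )
        for g in chosen:
            gene_terms.setdefault(g, set()).add(tid)
    terms = pd.DataFrame(term_rows).set_index("term_id")
    return catalog, TermAnnotation(gene_terms=gene_terms, terms=terms)


@dataclass
class Bundle:
    """One tissue's complete synthetic input set plus its ground truth."""

    cfg: SimulationConfig
    network: RankedEdgeList
    truth: SyntheticTruth
    modules: ModuleAssignment
    counts: CountMatrix
    catalog: pd.DataFrame
    annotations: TermAnnotation


def simulate_bundle(cfg: SimulationConfig) -> Bundle:
    """Run every generator stage in order and return the full bundle."""
    network = generate_network(cfg)
    truth = generate_truth(cfg, network)
    modules = generate_modules(cfg, network, truth)
    counts = generate_counts(cfg, truth)
    catalog, ann = generate_catalog_and_annotations(cfg, truth, network)
    return Bundle(
        cfg=cfg,
        network=network,
        truth=truth,
        modules=modules,
        counts=counts,
        catalog=catalog,
        annotations=ann,
    )


def write_fixture_bundle(path, bundle: Bundle) -> dict:
    """Write the bundle as plain TSV/JSON files; returns the manifest."""
    path = Path(path)
    try:
        path.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create bundle directory {path}: {exc}") from exc

    counts = bundle.counts.counts.copy()
    counts.index.name = "gene_id"
    counts.to_csv(path / "counts.tsv", sep="\t")
    groups = bundle.counts.groups.rename_axis("sample_id").rename("group")
    groups.to_frame().to_csv(path / "groups.tsv", sep="\t")
    bundle.network.to_tsv(path / "network.tsv")
    pd.Series(bundle.modules.module_of, name="module").rename_axis("gene_id").to_frame().to_csv(
        path / "modules.tsv", sep="\t"
    )
    cat = bundle.catalog.copy()
    cat["is_tf"] = cat["is_tf"].map({True: "true", False: "false"})
    cat.to_csv(path / "catalog.tsv", sep="\t")
    ann_rows = [
        {"gene_id": g, "term_id": t}
        for g in sorted(bundle.annotations.gene_terms)
        for t in sorted(bundle.annotations.gene_terms[g])
    ]
    pd.DataFrame(ann_rows, columns=["gene_id", "term_id"]).to_csv(
        path / "annotations.tsv", sep="\t", index=False
    )
    bundle.annotations.terms.to_csv(path / "terms.tsv", sep="\t")
    with open(path / "truth.json", "w") as fh:
        json.dump(bundle.truth.to_json_dict(), fh, indent=1, sort_keys=True)
    cfg_dict = dataclasses.asdict(bundle.cfg)
    manifest = {
        "config": cfg_dict,
        "seed": bundle.cfg.seed,
        "files": [
            "counts.tsv",
            "groups.tsv",
            "network.tsv",
            "modules.tsv",
            "catalog.tsv",
            "annotations.tsv",
            "terms.tsv",
            "truth.json",
        ],
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
    }
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def read_bundle(path) -> Bundle:
    """Round-trip loader: reads a written bundle through the module readers."""
    from .regnet import read_network
    from .comod import read_modules

    path = Path(path)
    with open(path / "manifest.json") as fh:
        manifest = json.load(fh)
    cfg = SimulationConfig(**manifest["config"])
    counts = CountMatrix.from_tsv(path / "counts.tsv", path / "groups.tsv")
    network = read_network(path / "network.tsv")
    modules = read_modules(path / "modules.tsv")
    catalog = pd.read_csv(path / "catalog.tsv", sep="\t", comment="#", index_col=0)
    catalog["is_tf"] = catalog["is_tf"].map({"true": True, "false": False, True: True, False: False})
    ann = TermAnnotation.from_tsv(path / "annotations.tsv", path / "terms.tsv")
    with open(path / "truth.json") as fh:
        truth = SyntheticTruth.from_json_dict(json.load(fh), module_of=dict(modules.module_of))
    return Bundle(
        cfg=cfg,
        network=network,
        truth=truth,
        modules=modules,
        counts=counts,
        catalog=catalog,
        annotations=ann,
    )
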