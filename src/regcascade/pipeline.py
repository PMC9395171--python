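"""End-to-end orchestration: simulate-or-load -> DE -> candidates ->
communities -> module integration -> enrichment, per tissue.

Every stage's table is written under the output directory with a provenance
stamp (version, config hash, seed); the run is summarised in a
machine-readable ``run_report.json``.  Identical config + seed reproduce all
analysis tables byte-for-byte; the report carries wall-clock timestamps plus
a ``content_hash`` computed over everything except them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .comod import (
    ModuleAssignment,
    assign_tf_modules,
    crosstab_links,
    module_de_percentages,
    read_modules,
)
from .dge import CountMatrix, NBExactDGE
from .enrich import DOMAINS, TermAnnotation, enrich_terms, rich_factor_table
from .regnet import (
    greedy_modularity_communities,
    induced_subgraph,
    rank_candidates,
    read_network,
    select_candidates,
    shared_ratios,
    top_k_edges,
)
from .synthdata import Bundle, SimulationConfig, read_bundle, simulate_bundle, write_fixture_bundle

logger = logging.getLogger(__name__)

INPUT_KEYS = ("counts", "groups", "network", "modules", "catalog", "annotations", "terms")


class PipelineError(RuntimeError):
    """Stage-tagged runtime failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class ValidationError(PipelineError):
    """Fatal input-validation failure (CLI exit code 2)."""

    def __init__(self, issues: list[str]):
        super().__init__("validate", "; ".join(issues))
        self.issues = issues


@dataclass
class TissueSpec:
    """Inputs for one tissue: either file paths or a simulation block."""

    name: str
    inputs: dict | None = None
    simulate: SimulationConfig | None = None

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError(
                f"tissue {self.name!r}: exactly one of 'inputs' or 'simulate' required"
            )


@dataclass
class PipelineConfig:
    """Run configuration; thresholds default to the study's settings."""

    tissues: list[TissueSpec]
    out: Path
    alpha: float = 0.05
    top_k: int = 1_000_000
    cpm_threshold: float = 1.0
    domains: tuple = DOMAINS
    seed: int = 0
    class_scope: tuple = ("gliadin_like", "globulin_like", "ssrg_like")
    include_non_de_classes: tuple = ()

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.top_k <= 0:
            raise ValueError("top_k must be positive")
        self.out = Path(self.out)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        seed = int(raw.pop("seed", 0))
        tissues_raw = raw.pop("tissues", None)
        if tissues_raw is None:
            block = {}
            for key in ("inputs", "simulate"):
                if key in raw:
                    block[key] = raw.pop(key)
            tissues_raw = {"tissue": block}
        tissues = []
        for i, (name, block) in enumerate(tissues_raw.items()):
            sim = None
            inputs = block.get("inputs")
            if "simulate" in block:
                sim_kw = dict(block["simulate"] or {})
                sim_kw.setdefault("seed", (seed + i) % 2**31)
                sim = SimulationConfig(**sim_kw)
            tissues.append(TissueSpec(name=name, inputs=inputs, simulate=sim))
        known = {"out", "alpha", "top_k", "cpm_threshold", "domains", "class_scope", "include_non_de_classes"}
        kw = {k: v for k, v in raw.items() if k in known}
        if "domains" in kw:
            kw["domains"] = tuple(kw["domains"])
        if "class_scope" in kw:
            kw["class_scope"] = tuple(kw["class_scope"])
        if "include_non_de_classes" in kw:
            kw["include_non_de_classes"] = tuple(kw["include_non_de_classes"])
        return cls(tissues=tissues, seed=seed, **kw)

    def to_canonical_dict(self) -> dict:
        d = {
            "alpha": self.alpha,
            "top_k": self.top_k,
            "cpm_threshold": self.cpm_threshold,
            "domains": list(self.domains),
            "seed": self.seed,
            "class_scope": list(self.class_scope),
            "include_non_de_classes": list(self.include_non_de_classes),
            "tissues": {
                t.name: (
                    {"inputs": {k: str(v) for k, v in t.inputs.items()}}
                    if t.inputs is not None
                    else {"simulate": dataclasses.asdict(t.simulate)}
                )
                for t in self.tissues
            },
        }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_canonical_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def version_and_provenance(config: PipelineConfig) -> str:
    """Provenance stamp embedded in every output table header."""
    return f"regcascade v{__version__} config={config.config_hash()[:12]} seed={config.seed}"


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Pre-flight checks; returns warnings, raises ValidationError on fatals."""
    fatal: list[str] = []
    warnings_: list[str] = []
    for tissue in config.tissues:
        if tissue.simulate is not None:
            continue
        paths = {k: Path(v) for k, v in tissue.inputs.items()}
        missing_keys = [k for k in INPUT_KEYS if k not in paths]
        if missing_keys:
            fatal.append(f"{tissue.name}: missing input path(s): {missing_keys}")
            continue
        absent = [str(p) for p in paths.values() if not p.exists()]
        if absent:
            fatal.append(f"{tissue.name}: missing file(s): {absent}")
            continue
        try:
            cm = CountMatrix.from_tsv(paths["counts"], paths["groups"])
        except ValueError as exc:
            fatal.append(f"{tissue.name}: {exc}")
            continue
        try:
            net = read_network(paths["network"])
        except ValueError as exc:
            fatal.append(f"{tissue.name}: {exc}")
            continue
        if len(net) == 0:
            fatal.append(f"{tissue.name}: network {paths['network']} is empty")
            continue
        net_genes = set(net.edges["regulator"]) | set(net.edges["target"])
        overlap = len(net_genes & set(cm.gene_ids)) / max(len(net_genes), 1)
        if overlap < 0.5:
            warnings_.append(
                f"{tissue.name}: only {overlap:.0%} of network gene ids appear in "
                f"{paths['counts']} (vs {paths['network']})"
            )
    if fatal:
        raise ValidationError(fatal)
    for w in warnings_:
        logger.warning(w)
    return warnings_


def _load_tissue(tissue: TissueSpec, outdir: Path) -> Bundle:
    if tissue.simulate is not None:
        bundle = simulate_bundle(tissue.simulate)
        write_fixture_bundle(outdir / "bundle", bundle)
        return bundle
    p = {k: Path(v) for k, v in tissue.inputs.items()}
    counts = CountMatrix.from_tsv(p["counts"], p["groups"])
    network = read_network(p["network"])
    modules = read_modules(p["modules"])
    catalog = pd.read_csv(p["catalog"], sep="\t", comment="#", index_col=0)
    catalog["is_tf"] = catalog["is_tf"].map(
        {"true": True, "false": False, True: True, False: False}
    )
    ann = TermAnnotation.from_tsv(p["annotations"], p["terms"])
    return Bundle(
        cfg=None, network=network, truth=None, modules=modules,
        counts=counts, catalog=catalog, annotations=ann,
    )


def _write(df: pd.DataFrame, path: Path, stamp: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {stamp}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage per tissue; returns the run report dict."""
    started = datetime.now(timezone.utc).isoformat()
    validate_inputs(config)
    stamp = version_and_provenance(config)
    config.out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "tool": "regcascade",
        "version": __version__,
        "config_hash": config.config_hash(),
        "config": config.to_canonical_dict(),
        "tissues": {},
    }
    for tissue in config.tissues:
        tdir = config.out / tissue.name
        tdir.mkdir(parents=True, exist_ok=True)
        stage = "load"
        try:
            bundle = _load_tissue(tissue, tdir)

            stage = "dge"
            model = NBExactDGE(bundle.counts, cpm_threshold=config.cpm_threshold)
            results = model.fit(alpha=config.alpha)
            results.to_tsv(tdir / "dge.tsv", stamp=stamp)
            de_genes = results.de_genes
            expressed = set(
                results.table.index[results.table["status"] != "filtered"]
            )

            stage = "candidates"
            net = top_k_edges(bundle.network, config.top_k)
            tf_universe = set(bundle.catalog.index[bundle.catalog["is_tf"]])
            de_tfs = de_genes & tf_universe
            records = shared_ratios(net, de_genes, tf_universe, de_tfs)
            candidates = select_candidates(records)
            graph = greedy_modularity_communities(induced_subgraph(net, candidates))
            module_of_tf = assign_tf_modules(candidates, bundle.modules)
            ranked = rank_candidates(
                records,
                log2fc=results.table["log2fc"],
                community_of=graph.community_of,
                module_of=module_of_tf,
            )
            _write(ranked, tdir / "candidates.tsv", stamp)
            _write(records, tdir / "shared_ratios.tsv", stamp)
            with open(tdir / "graph.edgelist", "w") as fh:
                fh.write(f"# {stamp}\n")
                for e in sorted(tuple(sorted(e)) for e in graph.edges):
                    fh.write(f"{e[0]}\t{e[1]}\n")
            _write(
                pd.DataFrame(
                    sorted(graph.community_of.items()), columns=["tf", "community"]
                ),
                tdir / "communities.tsv",
                stamp,
            )
            with open(tdir / "graph_summary.json", "w") as fh:
                json.dump(
                    {
                        "n_nodes": len(graph.nodes),
                        "n_edges": len(graph.edges),
                        "n_communities": graph.n_communities,
                        "Q": graph.q,
                    },
                    fh,
                    indent=1,
                    sort_keys=True,
                )

            stage = "integrate"
            mod_stats = module_de_percentages(bundle.modules, results.table)
            _write(mod_stats, tdir / "module_stats.tsv", stamp)
            cm_links, mc_links = crosstab_links(
                graph.community_of,
                bundle.modules,
                results.table,
                bundle.catalog,
                class_scope=config.class_scope,
                include_non_de_classes=config.include_non_de_classes,
            )
            _write(cm_links, tdir / "crosstab_community_module.tsv", stamp)
            _write(mc_links, tdir / "crosstab_module_class.tsv", stamp)

            stage = "enrich"
            for direction in ("up", "down"):
                query = results.genes_with_status(direction)
                enr = enrich_terms(
                    query, expressed, bundle.annotations, domains=config.domains
                )
                _write(enr, tdir / f"enrichment_{direction}.tsv", stamp)
            rf = rich_factor_table(
                results.table, bundle.annotations, universe=expressed
            )
            _write(rf, tdir / "rich_factor.tsv", stamp)
        except (ValueError, OSError, KeyError) as exc:
            raise PipelineError(f"{tissue.name}:{stage}", str(exc)) from exc

        report["tissues"][tissue.name] = {
            "n_genes_input": int(len(results.table)),
            "n_genes_expressed": int(results.n_expressed),
            "n_up": int(results.n_up),
            "n_down": int(results.n_down),
            "phi": float(results.phi),
            "n_tfs_in_network": int(len(records)),
            "n_candidates": int(len(candidates)),
            "n_communities": int(graph.n_communities),
            "Q": float(graph.q),
            "modules": {
                row["module"]: {
                    "n_genes": int(row["n_genes"]),
                    "n_up": int(row["n_up"]),
                    "n_down": int(row["n_down"]),
                    "pct_de": float(row["pct_de"]),
                }
                for row in mod_stats.to_dict("records")
            },
        }
    blob = json.dumps(report, sort_keys=True).encode()
    report["content_hash"] = hashlib.sha256(blob).hexdigest()
    report["started"] = started
    report["finished"] = datetime.now(timezone.utc).isoformat()
    with open(config.out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
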