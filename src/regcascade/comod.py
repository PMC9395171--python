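"""Integration of DE calls and candidate TFs with co-expression modules.

Per-module DE percentages (module size taken from the module table itself),
candidate-TF module annotation, and the community <-> module <-> protein-class
cross-tabulations used to relate the candidate-TF communities to the grain
protein and starch-synthesis gene classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

PROTEIN_CLASSES = (
    "gliadin_like",
    "hmw_like",
    "lmw_like",
    "globulin_like",
    "ati_like",
    "alp_like",
    "ltp_like",
    "serpin_like",
    "ssrg_like",
    "other",
)

__all__ = [
    "ModuleAssignment",
    "read_modules",
    "module_de_percentages",
    "assign_tf_modules",
    "crosstab_links",
    "PROTEIN_CLASSES",
    "UNASSIGNED",
]


@dataclass
class ModuleAssignment:
    """gene -> co-expression module label; absent genes are 'unassigned'."""

    module_of: dict[str, str]

    def get(self, gene: str) -> str:
        return self.module_of.get(gene, UNASSIGNED)

    def genes_of(self, module: str) -> set[str]:
        return {g for g, m in self.module_of.items() if m == module}

    @property
    def modules(self) -> list[str]:
        return sorted(set(self.module_of.values()))


def read_modules(path) -> ModuleAssignment:
    """Read a two-column gene_id/module TSV.

    Duplicate rows with the same module are deduplicated with a warning;
    conflicting duplicates raise.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return ModuleAssignment(module_of={})
    if df.empty:
        return ModuleAssignment(module_of={})
    gene_col, mod_col = df.columns[:2]
    dup = df[df.duplicated(subset=[gene_col], keep=False)]
    if not dup.empty:
        conflicts = dup.groupby(gene_col)[mod_col].nunique()
        bad = conflicts[conflicts > 1]
        if not bad.empty:
            raise ValueError(
                f"conflicting module assignments for gene(s): {list(bad.index)[:10]}"
            )
        logger.warning("deduplicated %d repeated module row(s)", len(dup) - dup[gene_col].nunique())
    df = df.drop_duplicates(subset=[gene_col])
    return ModuleAssignment(module_of=dict(zip(df[gene_col], df[mod_col])))


def module_de_percentages(
    modules: ModuleAssignment, dge_table: pd.DataFrame
) -> pd.DataFrame:
    """Per-module DE gene percentages.

    For each module of the table: n_genes (module size within the module
    table), n_up / n_down among those genes, pct_de = 100*(n_up+n_down)/n_genes.
    Genes of the DE table absent from the module table form the pseudo-module
    'unassigned'.  Sorted by pct_de descending, then label.
    """
    status = dge_table["status"]
    rows = []
    for mod in modules.modules:
        genes = modules.genes_of(mod)
        sub = status.reindex(genes).dropna()
        n_up = int((sub == "up").sum())
        n_down = int((sub == "down").sum())
        n_genes = len(genes)
        rows.append(
            {
                "module": mod,
                "n_genes": n_genes,
                "n_up": n_up,
                "n_down": n_down,
                "pct_de": 100.0 * (n_up + n_down) / n_genes if n_genes else 0.0,
            }
        )
    unassigned = [g for g in dge_table.index if g not in modules.module_of]
    if unassigned:
        sub = status.reindex(unassigned)
        n_up = int((sub == "up").sum())
        n_down = int((sub == "down").sum())
        rows.append(
            {
                "module": UNASSIGNED,
                "n_genes": len(unassigned),
                "n_up": n_up,
                "n_down": n_down,
                "pct_de": 100.0 * (n_up + n_down) / len(unassigned),
            }
        )
    df = pd.DataFrame(rows, columns=["module", "n_genes", "n_up", "n_down", "pct_de"])
    return df.sort_values(
        ["pct_de", "module"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def assign_tf_modules(candidates: set[str], modules: ModuleAssignment) -> dict[str, str]:
    """Map each candidate TF to its module, or 'unassigned'."""
    return {tf: modules.get(tf) for tf in sorted(candidates)}


def crosstab_links(
    candidate_communities: dict[str, int],
    modules: ModuleAssignment,
    dge_table: pd.DataFrame,
    catalog: pd.DataFrame,
    class_scope,
    include_non_de_classes=(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Community<->module and module<->protein-class link counts.

    Community->module links are counted over candidate TFs that have a module
    assignment.  Module->class links are counted over genes whose
    protein_class is in ``class_scope`` and that are DE (status up/down);
    classes named in ``include_non_de_classes`` are counted regardless of DE
    status (genes without a module fall in the 'unassigned' module row).

    ``catalog`` is indexed by gene_id with a ``protein_class`` column.
    """
    known = set(PROTEIN_CLASSES)
    bad = set(class_scope) - known
    if bad:
        raise ValueError(f"unknown protein class(es) in scope: {sorted(bad)}")
    bad = set(include_non_de_classes) - known
    if bad:
        raise ValueError(f"unknown protein class(es) in include list: {sorted(bad)}")

    cm_rows: dict[tuple[int, str], int] = {}
    for tf in sorted(candidate_communities):
        mod = modules.get(tf)
        if mod == UNASSIGNED:
            continue
        key = (candidate_communities[tf], mod)
        cm_rows[key] = cm_rows.get(key, 0) + 1
    cm = pd.DataFrame(
        [{"community": c, "module": m, "count": n} for (c, m), n in sorted(cm_rows.items())],
        columns=["community", "module", "count"],
    )

    status = dge_table["status"]
    mc_rows: dict[tuple[str, str], int] = {}
    scope = set(class_scope)
    always = set(include_non_de_classes)
    for gene, cls in catalog["protein_class"].items():
        if cls not in scope:
            continue
        st = status.get(gene, "ns")
        if st not in ("up", "down") and cls not in always:
            continue
        key = (modules.get(gene), cls)
        mc_rows[key] = mc_rows.get(key, 0) + 1
    mc = pd.DataFrame(
        [{"module": m, "protein_class": c, "count": n} for (m, c), n in sorted(mc_rows.items())],
        columns=["module", "protein_class", "count"],
    )
    return cm, mc
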