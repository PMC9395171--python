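"""Over-representation analysis of gene sets against term annotations.

One-sided hypergeometric upper-tail p-values per term, Benjamini-Hochberg
correction within each term domain (BP/MF/CC/pathway), and the pathway
"rich factor" k/K (DE-annotated genes over all annotated genes in a term).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .dge import bh_adjust

DOMAINS = ("BP", "MF", "CC", "pathway")

__all__ = [
    "TermAnnotation",
    "hypergeom_upper_p",
    "enrich_terms",
    "rich_factor_table",
    "enrich_module",
]


@dataclass
class TermAnnotation:
    """gene -> set of terms plus a term catalog (name, domain)."""

    gene_terms: dict[str, set[str]]
    terms: pd.DataFrame  # index term_id, columns name, domain

    def __post_init__(self) -> None:
        bad = set(self.terms["domain"]) - set(DOMAINS)
        if bad:
            raise ValueError(f"unknown term domains: {sorted(bad)}")

    @classmethod
    def from_tsv(cls, annotations_path, terms_path) -> "TermAnnotation":
        ann = pd.read_csv(annotations_path, sep="\t", comment="#")
        terms = pd.read_csv(terms_path, sep="\t", comment="#").set_index("term_id")
        gene_terms: dict[str, set[str]] = {}
        for g, t in zip(ann["gene_id"], ann["term_id"]):
            gene_terms.setdefault(g, set()).add(t)
        return cls(gene_terms=gene_terms, terms=terms)

    def genes_of(self, universe: set[str]) -> dict[str, set[str]]:
        """term -> annotated genes restricted to the universe."""
        out: dict[str, set[str]] = {}
        for g in universe:
            for t in self.gene_terms.get(g, ()):
                out.setdefault(t, set()).add(g)
        return out


def hypergeom_upper_p(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n) (over-representation tail)."""
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(k, K, n, N) < 0:
        raise ValueError(f"invalid hypergeometric bounds k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_terms(
    query: set[str],
    universe: set[str],
    ann: TermAnnotation,
    domains=DOMAINS,
) -> pd.DataFrame:
    """One record per term with >= 1 annotated gene in the universe.

    BH adjustment is applied within each domain separately; the result is
    sorted by adjusted p then term id.  The query must be a subset of the
    universe.
    """
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:10]}")
    cols = ["term_id", "name", "domain", "k", "K", "n", "N", "pvalue", "rich_factor", "padj"]
    if not query:
        return pd.DataFrame(columns=cols)
    term_genes = ann.genes_of(universe)
    n, N = len(query), len(universe)
    recs = []
    for term in sorted(term_genes):
        if term not in ann.terms.index:
            continue
        dom = ann.terms.loc[term, "domain"]
        if dom not in domains:
            continue
        K = len(term_genes[term])
        k = len(term_genes[term] & query)
        recs.append(
            {
                "term_id": term,
                "name": ann.terms.loc[term, "name"],
                "domain": dom,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "pvalue": hypergeom_upper_p(k, K, n, N),
                "rich_factor": k / K,
            }
        )
    cols = ["term_id", "name", "domain", "k", "K", "n", "N", "pvalue", "rich_factor", "padj"]
    if not recs:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(recs)
    df["padj"] = 1.0
    for dom in df["domain"].unique():
        mask = df["domain"] == dom
        df.loc[mask, "padj"] = bh_adjust(df.loc[mask, "pvalue"].to_numpy())
    df = df.sort_values(["padj", "term_id"], kind="mergesort").reset_index(drop=True)
    return df[cols]


def rich_factor_table(
    dge_table: pd.DataFrame,
    ann: TermAnnotation,
    universe: set[str] | None = None,
    domain: str = "pathway",
    statuses=("up", "down"),
) -> pd.DataFrame:
    """Pathway-style enrichment of DE genes with counts and rich factors.

    The query is the set of genes with status in ``statuses``; terms with
    zero DE genes (k = 0) are omitted.
    """
    if universe is None:
        universe = set(dge_table.index[dge_table["status"] != "filtered"])
    query = set(dge_table.index[dge_table["status"].isin(statuses)]) & universe
    df = enrich_terms(query, universe, ann, domains=(domain,))
    df = df[df["k"] > 0].reset_index(drop=True)
    return df.rename(columns={"k": "count"})


def enrich_module(
    module: str,
    modules: dict[str, str],
    universe: set[str],
    ann: TermAnnotation,
    domains=DOMAINS,
) -> pd.DataFrame:
    """Enrichment of one co-expression module's genes against the universe."""
    genes = {g for g, m in modules.items() if m == module}
    if not genes:
        raise ValueError(f"unknown or empty module: {module!r}")
    return enrich_terms(genes & universe, universe, ann, domains=domains)
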