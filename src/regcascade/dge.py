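"""Two-group differential expression on raw RNA-seq counts.

The stage is a classical count-based testing chain: genes with a summed CPM
at or below a threshold are removed, libraries are normalised by the trimmed
mean of M-values (TMM), a single common negative-binomial dispersion phi is
estimated by conditional maximum likelihood, and each gene is tested with a
conditional two-sided exact test on the rounded group sums of the
library-equalised pseudo-counts.  P-values are adjusted with the
Benjamini-Hochberg step-up procedure and genes are called up/down at
FDR < alpha (strict).

The public surface is the model/results pair :class:`NBExactDGE` /
:class:`DGEResults`; the individual steps are exposed as functions so that
each can be tested against an independent oracle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

CONTROL = "control"
TREATED = "treated"

__all__ = [
    "CountMatrix",
    "NBExactDGE",
    "DGEResults",
    "compute_cpm",
    "filter_low_expression",
    "tmm_factors",
    "equalize_libraries",
    "estimate_common_dispersion",
    "exact_nb_test",
    "bh_adjust",
    "call_de",
]


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with a two-group design.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, genes in rows (index = gene ids),
        samples in columns.
    groups
        Series mapping sample id -> ``"control"`` or ``"treated"``.
    """

    counts: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.counts.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValueError(f"samples without a group label: {missing}")
        bad = set(self.groups.unique()) - {CONTROL, TREATED}
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}; expected control/treated")
        sizes = self.groups.value_counts()
        if sizes.get(CONTROL, 0) < 2 or sizes.get(TREATED, 0) < 2:
            raise ValueError("each group needs at least 2 samples")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @classmethod
    def from_tsv(cls, counts_path, groups_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", comment="#", index_col=0)
        groups = pd.read_csv(groups_path, sep="\t", comment="#")
        groups = groups.set_index(groups.columns[0]).iloc[:, 0]
        return cls(counts=counts, groups=groups)


def compute_cpm(cm: CountMatrix) -> pd.DataFrame:
    """Counts per million: ``counts / library_size * 1e6`` per sample."""
    lib = cm.library_sizes
    zero = lib.index[lib == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero)}")
    return cm.counts / lib * 1e6


def filter_low_expression(cm: CountMatrix, threshold: float = 1.0) -> CountMatrix:
    """Keep genes whose CPM summed over all samples exceeds ``threshold`` (strict)."""
    keep = compute_cpm(cm).sum(axis=1) > threshold
    return CountMatrix(counts=cm.counts.loc[keep], groups=cm.groups)


def _quantile_ref(counts: np.ndarray, lib: np.ndarray) -> int:
    f75 = np.quantile(counts / lib, 0.75, axis=0)
    return int(np.argmin(np.abs(f75 - f75.mean())))


def tmm_factors(
    cm: CountMatrix,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
    ref: str | None = None,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    The reference sample is the one whose upper-quartile of count/library is
    closest to the mean upper-quartile (unless given).  For each sample the
    factor is 2**(weighted mean of log2 ratios M after doubly trimming by M
    and by average abundance A), weights being the inverse asymptotic
    binomial variance of M.
    """
    y = cm.counts.to_numpy(dtype=float)
    lib = cm.library_sizes.to_numpy(dtype=float)
    samples = list(cm.sample_ids)
    if ref is None:
        ridx = _quantile_ref(y, lib)
    else:
        ridx = samples.index(ref)
    yr, nr = y[:, ridx], lib[ridx]
    factors = np.ones(len(samples))
    for j in range(len(samples)):
        if j == ridx:
            continue
        ys, ns = y[:, j], lib[j]
        pos = (ys > 0) & (yr > 0)
        if not pos.any():
            raise ValueError(
                f"no genes positive in both sample {samples[j]!r} and reference {samples[ridx]!r}"
            )
        m = np.log2((ys[pos] / ns) / (yr[pos] / nr))
        a = 0.5 * np.log2((ys[pos] / ns) * (yr[pos] / nr))
        w = (ns - ys[pos]) / (ns * ys[pos]) + (nr - yr[pos]) / (nr * yr[pos])
        if np.max(np.abs(m)) < 1e-6:
            continue
        n = m.size
        lo_m = math.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep.any() and w[keep].sum() > 0:
            factors[j] = 2 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.sample_ids, name="norm_factor")


def equalize_libraries(
    cm: CountMatrix, factors: pd.Series
) -> tuple[pd.DataFrame, float]:
    """Rescale counts so every sample has the same effective library size.

    Effective sizes are library_size x factor; the common size N* is their
    geometric mean; pseudo-counts are counts x (N* / effective size).
    """
    eff = cm.library_sizes * factors.reindex(cm.sample_ids)
    n_star = float(np.exp(np.mean(np.log(eff))))
    pseudo = cm.counts * (n_star / eff)
    return pseudo, n_star


def _cond_loglik(pseudo: pd.DataFrame, groups: pd.Series, phi: float) -> float:
    """Summed per-gene NB log-likelihood conditional on group totals."""
    r = 1.0 / phi
    total = 0.0
    for g in (CONTROL, TREATED):
        y = pseudo.loc[:, groups[groups == g].index].to_numpy(dtype=float)
        n = y.shape[1]
        if n < 2:
            continue
        z = y.sum(axis=1)
        ll = (
            gammaln(y + r).sum(axis=1)
            - n * gammaln(r)
            + gammaln(n * r)
            - gammaln(z + n * r)
        )
        total += float(ll.sum())
    return total


def estimate_common_dispersion(
    pseudo: pd.DataFrame,
    groups: pd.Series,
    grid_min: float = 1e-6,
    grid_max: float = 10.0,
    grid_points: int = 25,
) -> float:
    """Common NB dispersion by conditional maximum likelihood.

    Maximises the summed per-gene conditional log-likelihood over a
    log-spaced grid, refined with golden-section search.  An optimum at the
    grid floor is reported as exactly 0 (Poisson).
    """
    within_var = 0.0
    for g in (CONTROL, TREATED):
        sub = pseudo.loc[:, groups[groups == g].index]
        if sub.shape[1] >= 2:
            within_var += float(sub.var(axis=1, ddof=1).sum())
    if within_var == 0.0:
        warnings.warn("no within-group variability; dispersion set to 0", stacklevel=2)
        return 0.0

    grid = np.logspace(np.log10(grid_min), np.log10(grid_max), grid_points)
    ll = np.array([_cond_loglik(pseudo, groups, p) for p in grid])
    i = int(np.argmax(ll))
    if i == 0:
        return 0.0
    lo = grid[i - 1]
    hi = grid[min(i + 1, grid_points - 1)]
    # golden-section on log scale
    gr = (math.sqrt(5) - 1) / 2
    a, b = math.log(lo), math.log(hi)
    c = b - gr * (b - a)
    d = a + gr * (b - a)
    fc = _cond_loglik(pseudo, groups, math.exp(c))
    fd = _cond_loglik(pseudo, groups, math.exp(d))
    for _ in range(40):
        if b - a < 1e-8:
            break
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = _cond_loglik(pseudo, groups, math.exp(c))
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = _cond_loglik(pseudo, groups, math.exp(d))
    phi = math.exp((a + b) / 2)
    return 0.0 if phi <= grid_min * (1 + 1e-6) else phi


def _cond_logpmf(t: int, n1: int, n2: int, phi: float) -> np.ndarray:
    """Log-pmf of the group-1 sum given the total, under the NB null.

    The sum of n i.i.d. NB(mu, phi) variables is NB with size n/phi; with a
    common per-sample mean the NB success probability cancels from the
    conditional law, which is therefore free of mu.  phi = 0 gives
    Binomial(t, n1/(n1+n2)).
    """
    s = np.arange(t + 1)
    if phi <= 0:
        return binom.logpmf(s, t, n1 / (n1 + n2))
    r1, r2 = n1 / phi, n2 / phi
    lp = (
        gammaln(s + r1)
        - gammaln(s + 1)
        + gammaln(t - s + r2)
        - gammaln(t - s + 1)
    )
    return lp - logsumexp(lp)


def exact_pvalue(s1: int, t: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided conditional exact p-value, minimum-likelihood rule."""
    if t == 0:
        return 1.0
    lp = _cond_logpmf(t, n1, n2, phi)
    keep = lp <= lp[s1] + 1e-10
    return min(1.0, float(np.exp(logsumexp(lp[keep]))))


def exact_nb_test(
    pseudo: pd.DataFrame, groups: pd.Series, phi: float, prior_count: float = 0.125
) -> pd.DataFrame:
    """Per-gene conditional exact NB test on rounded pseudo-count group sums.

    Returns a DataFrame with columns ``log2fc`` (treated vs. control, with a
    small prior count) and ``pvalue``.
    """
    c_samples = groups[groups == CONTROL].index
    t_samples = groups[groups == TREATED].index
    n1, n2 = len(c_samples), len(t_samples)
    s1 = pseudo.loc[:, c_samples].sum(axis=1).round().astype(np.int64)
    s2 = pseudo.loc[:, t_samples].sum(axis=1).round().astype(np.int64)
    lfc = np.log2((s2 + prior_count) / n2) - np.log2((s1 + prior_count) / n1)
    cache: dict[tuple[int, int], float] = {}
    pvals = np.empty(len(pseudo.index))
    for i, (a, t) in enumerate(zip(s1.to_numpy(), (s1 + s2).to_numpy())):
        key = (int(a), int(t))
        p = cache.get(key)
        if p is None:
            p = exact_pvalue(int(a), int(t), n1, n2, phi)
            cache[key] = p
        pvals[i] = p
    return pd.DataFrame({"log2fc": lfc, "pvalue": pvals}, index=pseudo.index)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Assign up/down/ns by FDR < alpha (strict) and the sign of log2FC."""
    status = np.where(
        (table["fdr"] < alpha) & (table["log2fc"] > 0),
        "up",
        np.where((table["fdr"] < alpha) & (table["log2fc"] < 0), "down", "ns"),
    )
    out = table.copy()
    out["status"] = status
    return out


class NBExactDGE:
    """Two-group NB exact-test differential expression model.

    Parameters
    ----------
    counts
        A :class:`CountMatrix` (raw integer counts, two groups).
    cpm_threshold
        Genes whose CPM summed over all samples is <= this are excluded
        before normalization and testing (strict ``>`` keeps a gene).
    """

    def __init__(self, counts: CountMatrix, cpm_threshold: float = 1.0):
        self.data = counts
        self.cpm_threshold = cpm_threshold

    @classmethod
    def from_tsv(cls, counts_path, groups_path, cpm_threshold: float = 1.0) -> "NBExactDGE":
        return cls(CountMatrix.from_tsv(counts_path, groups_path), cpm_threshold)

    def fit(self, alpha: float = 0.05) -> "DGEResults":
        kept = filter_low_expression(self.data, self.cpm_threshold)
        if kept.counts.shape[0] == 0:
            raise ValueError("no genes pass the CPM filter")
        factors = tmm_factors(kept)
        pseudo, n_star = equalize_libraries(kept, factors)
        phi = estimate_common_dispersion(pseudo, kept.groups)
        res = exact_nb_test(pseudo, kept.groups, phi)
        res["fdr"] = bh_adjust(res["pvalue"].to_numpy())
        res = call_de(res, alpha=alpha)
        filtered = self.data.gene_ids.difference(kept.gene_ids)
        if len(filtered):
            pad = pd.DataFrame(
                {
                    "log2fc": np.nan,
                    "pvalue": np.nan,
                    "fdr": np.nan,
                    "status": "filtered",
                },
                index=filtered,
            )
            res = pd.concat([res, pad])
        res = res.reindex(self.data.gene_ids)
        res.index.name = "gene_id"
        return DGEResults(
            table=res,
            phi=phi,
            norm_factors=factors,
            common_library_size=n_star,
            alpha=alpha,
            cpm_threshold=self.cpm_threshold,
        )


@dataclass
class DGEResults:
    """Fitted DE results: per-gene table plus the model-level estimates."""

    table: pd.DataFrame
    phi: float
    norm_factors: pd.Series
    common_library_size: float
    alpha: float
    cpm_threshold: float
    _counts: dict = field(default_factory=dict, repr=False)

    def genes_with_status(self, status: str) -> set[str]:
        return set(self.table.index[self.table["status"] == status])

    @property
    def de_genes(self) -> set[str]:
        return self.genes_with_status("up") | self.genes_with_status("down")

    @property
    def n_up(self) -> int:
        return int((self.table["status"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["status"] == "down").sum())

    @property
    def n_expressed(self) -> int:
        return int((self.table["status"] != "filtered").sum())

    def summary(self) -> str:
        lines = [
            "Two-group NB exact-test differential expression",
            "=" * 48,
            f"genes (input / expressed): {len(self.table)} / {self.n_expressed}",
            f"CPM filter threshold:      sum CPM > {self.cpm_threshold}",
            f"common NB dispersion phi:  {self.phi:.4g}",
            f"common library size N*:    {self.common_library_size:.1f}",
            f"alpha (FDR, strict <):     {self.alpha}",
            f"up-regulated (treated):    {self.n_up}",
            f"down-regulated (treated):  {self.n_down}",
            "TMM factors: "
            + ", ".join(f"{s}={f:.3f}" for s, f in self.norm_factors.items()),
        ]
        return "\n".join(lines)

    def to_tsv(self, path, stamp: str | None = None) -> None:
        with open(path, "w") as fh:
            if stamp:
                fh.write(f"# {stamp}\n")
            out = self.table.reset_index()
            out.columns = ["gene_id", "log2FC", "pvalue", "fdr", "status"]
            out.to_csv(fh, sep="\t", index=False)

    @staticmethod
    def read_table(path) -> pd.DataFrame:
        t = pd.read_csv(path, sep="\t", comment="#")
        return t.set_index("gene_id").rename(columns={"log2FC": "log2fc"})
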