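# Methods

This note documents the models and procedures implemented in `regcascade`,
their assumptions, the parameters that matter, the numerical choices, and
the known limitations. It states nothing that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Differential expression

The DE stage models raw counts y_gs for gene g in sample s as negative
binomial with group-specific means and a *single common dispersion* φ
(variance μ + φμ²). The chain is:

1. **Expression filter.** Keep genes with Σ_s CPM_gs > 1 (strict). Filtered
   genes never receive a p-value; they appear in the output with status
   `filtered`.
2. **TMM normalisation.** Reference sample: upper quartile of count/library
   closest to the mean upper quartile. Per sample, the factor is
   2^(weighted mean of M = log₂ fold-ratios vs. the reference), after
   removing the top/bottom 30% by M and 5% by A, weights = inverse
   asymptotic (binomial) variance of M, computed over genes positive in both
   samples; factors are rescaled to geometric mean 1. A sample whose log
   ratios are all below 1e-6 in magnitude keeps factor 1.
3. **Library equalisation.** Effective size = library × factor;
   N* = geometric mean of effective sizes; pseudo-counts = counts × (N*/
   effective size). Pseudo-counts stay fractional internally and are rounded
   only where the exact test needs integer support (group sums).
4. **Dispersion.** φ maximises the summed per-gene conditional NB
   log-likelihood (conditioning on each gene's group totals, which removes
   the mean parameter) over a 25-point log grid on [1e-6, 10], refined by
   golden-section search around the grid optimum. An optimum on the grid
   floor is reported as exactly 0, and data with no within-group
   variability return 0 with a warning; φ = 0 routes the exact test through
   its Poisson/binomial limit.
5. **Exact test.** For rounded group sums S₁, S₂ (n₁, n₂ samples) and
   T = S₁+S₂, the null conditional law of S₁ | T is free of the mean: the
   sum of n i.i.d. NB(μ, φ) is NB with size n/φ and the shared success
   probability cancels, leaving
   P(s | T) ∝ C(s+r₁−1, s)·C(T−s+r₂−1, T−s) with rᵢ = nᵢ/φ
   (Binomial(T, n₁/(n₁+n₂)) when φ = 0). The two-sided p-value sums all
   outcomes with probability ≤ the observed one (minimum-likelihood rule),
   with a 1e-10 log-space tolerance so exact ties are included; T = 0 gives
   p = 1 and log₂FC = 0. A prior count of 0.125 stabilises
   log₂FC = log₂((S₂+0.125)/n₂) − log₂((S₁+0.125)/n₁) (treated vs control).
6. **Multiplicity.** Benjamini–Hochberg step-up (via statsmodels), calls at
   FDR < α (strict), α = 0.05 by default.

Assumptions: a two-group design with ≥2 replicates per group; one shared
dispersion across genes (tagwise/trended dispersion and GLM designs are out
of scope); independence across genes in the BH step.

**Calibration, and a note on discreteness.** Because the test is exact and
discrete, its p-values are *conservative* at low counts: each p-value is the
largest achievable value ≤ its nominal level, so a KS comparison against
Uniform(0,1) measures the granularity of the staircase, not mis-calibration.
The suite therefore checks (a) KS uniformity on a 5000-gene null in the
near-continuous regime (median ~1000 counts per gene, matched φ), where the
staircase is negligible, and (b) the empirical false-discovery proportion at
FDR 0.05 under a 10%-DE mixture (20 seeds), which directly bounds the
quantity the procedure is supposed to control at all count levels. Observed
rejection rates at low counts sit at or below the nominal level, as expected
for an exact test.

## 2. Shared-ratio scoring and candidate selection

The network is consumed as a ranked edge list: importance descending, ties
broken by (regulator, target) lexicographically; duplicate pairs keep the
maximum importance; self-loops are dropped with a warning. Scoring uses the
top-k filtered network (k = 10⁶ by default, matching the convention of
taking the top million interactions of a genome-scale GENIE3 network), not
the full list. For every TF of the supplied catalog present as a regulator:

    shared_ratio = n_de_targets / n_targets,

and candidates = {TF : TF is DE ∧ shared_ratio > 0}. The TF universe comes
from the catalog (an external TF annotation), not from the regulator column,
so TFs absent from the network simply get no record.

## 3. Candidate graph and communities

The candidate graph is undirected, unweighted and simple: an edge joins two
candidates when a regulatory link exists between them in either direction;
isolated candidates stay as singleton nodes. Edge importances are *not* used
as weights because classical greedy modularity is defined on unweighted
graphs and nothing downstream needs the weights.

Communities come from agglomerative greedy modularity maximisation
(Clauset–Newman–Moore): start from singletons and repeatedly merge the
connected pair of communities with the largest

    ΔQ(a, b) = e_ab/m − d_a·d_b/(2m²),

stopping when no merge has ΔQ > 0. Ties are broken by the lexicographically
smallest community pair, communities being labelled by their smallest member
node, so the partition is bit-reproducible and invariant to input order.
Q is reported for the returned partition (Q = 0 for an edgeless graph).

**Known limitation (measured by the suite).** Greedy merging is a heuristic:
on small random graphs it occasionally returns Q well below the true optimum
over all partitions (the suite's exhaustive-search comparison finds cases
around 0.5–0.9 of the optimum; reference implementations of the same
algorithm in networkx and igraph return identical partitions on these
graphs). On separable structures — disjoint unions of cliques — it recovers
the exact optimal partition, which the suite also verifies.

## 4. Module integration

Per-module DE percentages use the module size *within the module table* as
the denominator (not the expressed universe), matching the definition
"percentage of DE genes in each module"; genes absent from the table form an
explicit `unassigned` pseudo-module rather than being dropped, because real
co-expression networks routinely miss genes (e.g. genes annotated after the
network was built). Cross-tabulations count community→module links over
candidate TFs with a module assignment, and module→class links over genes of
the requested protein classes that are DE; named classes can additionally be
included regardless of DE status (off by default — used to display non-DE
globulins alongside DE storage-protein genes).

## 5. Enrichment

One-sided hypergeometric over-representation (scipy's stable log-space
implementation): p = P(X ≥ k) for X ~ Hypergeom(N, K, n). BH correction is
applied within each term domain (BP/MF/CC/pathway) separately; results are
sorted by adjusted p then term id. The default universe is the set of genes
passing the CPM filter (the expressed universe); callers may pass any other
universe. The pathway table reports count = k and rich factor = k/K and
omits pathways with k = 0. Depletion testing and GO-graph propagation are
out of scope. BH was chosen as the correction because it is the method the
reported analyses state, even though some enrichment web services default to
other corrections.

## 6. Synthetic-data generator

The generator emulates the five consumed inputs for one tissue with planted
ground truth; two tissues are two independent bundles. All randomness flows
from a single seed through fixed per-stage substreams (network, truth,
modules, counts, annotations, baseline abundances), so identical configs
reproduce byte-identical bundles.

* **Baseline abundances**: log-normal (σ = 1.5 by default, a realistic
  span of bulk RNA-seq abundances), shared between the network and the
  counts.
* **Network**: regulators are the designated TFs; out-degrees are shifted
  negative-binomial (mean 20, dispersion 1); importances are Pareto-tailed
  (only the ranking matters downstream); targets are sampled among genes
  whose expected baseline count clears a floor (10 counts at the configured
  library size) because expression-inferred networks cannot contain genes
  without usable signal — the standard low-count exclusion used when
  building co-expression networks.
* **Planted truth**: a silenced family of 20 expressed non-TF genes
  (class `gliadin_like`), knocked down 50-fold in the treated group
  (emulating strong RNAi silencing of an abundant storage-protein family);
  5 causal TFs drawn from expressed TFs (a regulator can only enter the
  candidate rule if it is observably DE), themselves down-regulated 4-fold;
  half of each causal TF's targets shift 4-fold, downward with probability
  0.8 (mirroring the predominance of down-regulation among grain genes in
  such experiments).
* **Counts**: NB with dispersion 0.1 and group-specific means; library sizes
  log-normal around 10⁶ with CV 0.1; 3 replicates per group, matching a
  typical three-biological-replicate design.
* **Modules**: each TF gets a home module; a regulated gene follows its
  strongest regulator's home module with probability 1 − mixing
  (mixing = 0.3 by default), otherwise a uniform module; unregulated genes
  are uniform. Mixing 0 makes a TF's targets share one module; mixing 1
  makes labels independent of the network.
* **Catalog/annotations**: TF flags consistent with the network; the
  silenced family is `gliadin_like`; down-propagated targets seed
  `ssrg_like`; non-DE genes seed `globulin_like`. Forty background terms of
  ~40 genes across four domains, plus one term per {BP, pathway} planted to
  be enriched in the true DE set (30 genes, 85% drawn from true DE genes).

What the generator does **not** emulate: read-level data, homeologs or
subgenomes, multi-tissue shared regulation, correlated gene-gene noise,
batch effects, or compositional renormalisation of library sizes after
silencing (treated-group totals simply shrink by the removed mass, which
TMM then absorbs). Passing recovery tests on these bundles therefore shows
the pipeline's rules and statistics behave as specified under a clean NB
world — not that any particular biological dataset will yield the same
candidate lists.

## 7. Pipeline, determinism and problem sizes

`regcascade run` executes simulate-or-load → validate → DE → candidates →
communities → module integration → enrichment per tissue, writing every
intermediate with a provenance stamp (version, config hash, seed). Exit
codes: 0 ok, 2 validation failure, 1 runtime error. Identical config + seed
reproduce all analysis tables byte-for-byte; the JSON run report additionally
carries wall-clock timestamps plus a `content_hash` computed over everything
except the timestamps, so reproducibility can be asserted on the hash.

The test suite and acceptance script run everything at desk scale by choice:
calibration uses 2000–5000-gene simulations (20 seeds for the FDP check),
recovery uses ten 2000-gene / 100-TF bundles, the exhaustive-search
comparisons use graphs of ≤ 8 nodes, and the scale/determinism check runs a
20,000-gene / 1,000-TF / ~200,000-edge bundle end to end twice. Headline
numbers from the original grain/leaf experiments depend on the deposited
sequencing data and external genome-scale networks and are not reproduced
here; the suite verifies the *properties* of the procedure instead.
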