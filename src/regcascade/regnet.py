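"""Candidate-TF scoring on a ranked regulatory network.

A GENIE3-style network is a ranked list of directed regulator -> target
edges.  After keeping the top-k edges, each transcription factor present in
the network is scored with its shared ratio:

    shared_ratio(tf) = |targets(tf) ∩ DE genes| / |targets(tf)|

A TF is a *candidate* when it is itself differentially expressed and its
shared ratio is strictly positive.  Candidates induce an undirected simple
graph (edge when either regulatory direction exists among candidates) that
is partitioned into communities by greedy agglomerative modularity
optimisation (Clauset-Newman-Moore), with deterministic lexicographic
tie-breaking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RankedEdgeList",
    "CandidateGraph",
    "read_network",
    "top_k_edges",
    "shared_ratios",
    "select_candidates",
    "induced_subgraph",
    "modularity",
    "greedy_modularity_communities",
    "rank_candidates",
]


@dataclass
class RankedEdgeList:
    """Directed regulator->target edges ordered by descending importance.

    Ties in importance are broken by (regulator, target) lexicographic order.
    Pairs are unique, importances strictly positive, no self-loops.
    """

    edges: pd.DataFrame  # columns: regulator, target, importance

    @staticmethod
    def _canonical(df: pd.DataFrame) -> pd.DataFrame:
        df = df.sort_values(
            ["importance", "regulator", "target"],
            ascending=[False, True, True],
            kind="mergesort",
        )
        return df.reset_index(drop=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RankedEdgeList":
        df = df[["regulator", "target", "importance"]].copy()
        if (df["importance"] <= 0).any():
            raise ValueError("importance values must be strictly positive")
        loops = df["regulator"] == df["target"]
        if loops.any():
            logger.warning("dropping %d self-loop edge(s)", int(loops.sum()))
            df = df[~loops]
        n0 = len(df)
        df = (
            df.groupby(["regulator", "target"], as_index=False, sort=False)["importance"]
            .max()
        )
        if len(df) < n0:
            logger.warning("deduplicated %d edge pair(s), keeping max importance", n0 - len(df))
        return cls(cls._canonical(df))

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def regulators(self) -> set[str]:
        return set(self.edges["regulator"])

    def targets_of(self) -> dict[str, set[str]]:
        return {
            tf: set(sub)
            for tf, sub in self.edges.groupby("regulator", sort=True)["target"]
        }

    def to_tsv(self, path, header: bool = True, stamp: str | None = None) -> None:
        with open(path, "w") as fh:
            if stamp:
                fh.write(f"# {stamp}\n")
            self.edges.to_csv(fh, sep="\t", index=False, header=header)


def read_network(path, dialect: str = "auto") -> RankedEdgeList:
    """Read a 3-column (regulator, target, importance) TSV, header optional.

    ``dialect`` is one of ``auto`` (sniff), ``header``, ``noheader``.
    Malformed rows raise with their line number; duplicates keep the maximum
    importance; the result is canonically ordered.
    """
    rows = []
    with open(path) as fh:
        lines = [
            (i + 1, ln.rstrip("\n"))
            for i, ln in enumerate(fh)
            if ln.strip() and not ln.startswith("#")
        ]
    if not lines:
        logger.warning("empty network file: %s", path)
        return RankedEdgeList(
            pd.DataFrame(columns=["regulator", "target", "importance"])
        )
    start = 0
    first = lines[0][1].split("\t")
    if dialect == "header":
        start = 1
    elif dialect == "auto":
        try:
            float(first[2])
        except (IndexError, ValueError):
            start = 1
    for lineno, ln in lines[start:]:
        parts = ln.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}")
        try:
            imp = float(parts[2])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: importance {parts[2]!r} is not a number") from None
        if imp <= 0:
            raise ValueError(f"{path}:{lineno}: importance must be > 0, got {imp}")
        rows.append((parts[0], parts[1], imp))
    df = pd.DataFrame(rows, columns=["regulator", "target", "importance"])
    return RankedEdgeList.from_frame(df)


def top_k_edges(net: RankedEdgeList, k: int = 1_000_000) -> RankedEdgeList:
    """The first min(k, |edges|) edges of the canonical order."""
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    return RankedEdgeList(net.edges.head(k).reset_index(drop=True))


def shared_ratios(
    net: RankedEdgeList,
    de_genes: set[str],
    tf_universe: set[str],
    de_tfs: set[str],
) -> pd.DataFrame:
    """Per-TF shared-ratio records for TFs present in the network.

    One row per regulator of ``net`` that is also in ``tf_universe``:
    n_targets, n_de_targets, shared_ratio = n_de_targets/n_targets, the DE
    flag and the candidate flag (DE and ratio > 0).
    """
    recs = []
    for tf, targets in sorted(net.targets_of().items()):
        if tf not in tf_universe:
            continue
        n_t = len(targets)
        n_de = len(targets & de_genes)
        is_de = tf in de_tfs
        ratio = n_de / n_t
        recs.append(
            {
                "tf": tf,
                "n_targets": n_t,
                "n_de_targets": n_de,
                "shared_ratio": ratio,
                "is_de": is_de,
                "is_candidate": is_de and ratio > 0,
            }
        )
    return pd.DataFrame(
        recs,
        columns=["tf", "n_targets", "n_de_targets", "shared_ratio", "is_de", "is_candidate"],
    )


def select_candidates(records: pd.DataFrame) -> set[str]:
    """Candidate TFs: DE and shared ratio strictly positive."""
    if records.empty:
        return set()
    mask = records["is_de"] & (records["shared_ratio"] > 0)
    return set(records.loc[mask, "tf"])


@dataclass
class CandidateGraph:
    """Undirected simple graph on candidate TFs with a community partition."""

    nodes: tuple[str, ...]
    edges: frozenset  # of frozenset pairs
    community_of: dict[str, int] = field(default_factory=dict)
    q: float = float("nan")

    @property
    def n_communities(self) -> int:
        return len(set(self.community_of.values())) if self.community_of else 0

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {v: set() for v in self.nodes}
        for e in self.edges:
            a, b = sorted(e)
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def communities(self) -> list[set[str]]:
        out: dict[int, set[str]] = {}
        for v, c in self.community_of.items():
            out.setdefault(c, set()).add(v)
        return [out[c] for c in sorted(out)]


def induced_subgraph(net: RankedEdgeList, candidates: set[str]) -> CandidateGraph:
    """Undirected graph on the candidates; edge iff a->b or b->a in ``net``.

    Isolated candidates are retained as singleton nodes.
    """
    cand = set(candidates)
    sub = net.edges[
        net.edges["regulator"].isin(cand) & net.edges["target"].isin(cand)
    ]
    edges = frozenset(
        frozenset((a, b)) for a, b in zip(sub["regulator"], sub["target"]) if a != b
    )
    return CandidateGraph(nodes=tuple(sorted(cand)), edges=edges)


def modularity(graph: CandidateGraph, partition: dict[str, int]) -> float:
    """Newman modularity Q of an unweighted partition; 0 for an empty graph."""
    missing = [v for v in graph.nodes if v not in partition]
    if missing:
        raise ValueError(f"nodes missing from partition: {missing}")
    m = len(graph.edges)
    if m == 0:
        return 0.0
    intra: dict[int, int] = {}
    deg_sum: dict[int, int] = {}
    adj = graph.adjacency()
    for v in graph.nodes:
        c = partition[v]
        deg_sum[c] = deg_sum.get(c, 0) + len(adj[v])
    for e in graph.edges:
        a, b = sorted(e)
        if partition[a] == partition[b]:
            c = partition[a]
            intra[c] = intra.get(c, 0) + 1
    q = 0.0
    for c in set(partition[v] for v in graph.nodes):
        q += intra.get(c, 0) / m - (deg_sum.get(c, 0) / (2 * m)) ** 2
    return q


def greedy_modularity_communities(graph: CandidateGraph) -> CandidateGraph:
    """Agglomerative greedy modularity (Clauset-Newman-Moore).

    Starts from singletons and repeatedly merges the connected community pair
    with the largest positive modularity gain

        dQ(a, b) = e_ab/m - d_a * d_b / (2 m^2),

    ties broken by the lexicographically smallest (community, community)
    pair, communities being labelled by their smallest member.  Stops when no
    merge improves Q.  Returns the graph with ``community_of`` (dense integer
    ids in order of the sorted community labels) and its Q.
    """
    nodes = list(graph.nodes)
    m = len(graph.edges)
    # community label = smallest member node id
    label = {v: v for v in nodes}
    members: dict[str, set[str]] = {v: {v} for v in nodes}
    deg: dict[str, int] = {v: 0 for v in nodes}
    between: dict[str, dict[str, int]] = {v: {} for v in nodes}
    for e in graph.edges:
        a, b = sorted(e)
        deg[a] += 1
        deg[b] += 1
        between[a][b] = between[a].get(b, 0) + 1
        between[b][a] = between[b].get(a, 0) + 1
    if m > 0:
        while True:
            best = None  # (dq, a, b)
            for a in sorted(between):
                for b in sorted(between[a]):
                    if a >= b:
                        continue
                    dq = between[a][b] / m - deg[a] * deg[b] / (2 * m * m)
                    if best is None or dq > best[0] + 1e-15 or (
                        abs(dq - best[0]) <= 1e-15 and (a, b) < (best[1], best[2])
                    ):
                        best = (dq, a, b)
            if best is None or best[0] <= 1e-15:
                break
            _, a, b = best
            # merge b into a (a < b so the merged label stays the min member)
            members[a] |= members.pop(b)
            deg[a] += deg.pop(b)
            nbrs_b = between.pop(b)
            for c, w in nbrs_b.items():
                if c == a:
                    continue
                between[c].pop(b, None)
                between[a][c] = between[a].get(c, 0) + w
                between[c][a] = between[a][c]
            between[a].pop(b, None)
            for v in members[a]:
                label[v] = a
    order = {lab: i + 1 for i, lab in enumerate(sorted(members))}
    community_of = {v: order[label[v]] for v in nodes}
    q = modularity(graph, community_of) if nodes else 0.0
    return CandidateGraph(
        nodes=graph.nodes, edges=graph.edges, community_of=community_of, q=q
    )


def rank_candidates(
    records: pd.DataFrame,
    log2fc: pd.Series | None = None,
    community_of: dict[str, int] | None = None,
    module_of: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Candidate report sorted by shared_ratio desc, n_de_targets desc, id.

    Joins per-TF log2 fold-change, community and co-expression module labels
    when available.
    """
    out = records[records["is_candidate"]].copy()
    if log2fc is not None:
        out["log2fc"] = out["tf"].map(log2fc)
    if community_of is not None:
        out["community"] = out["tf"].map(community_of)
    if module_of is not None:
        out["module"] = out["tf"].map(lambda t: module_of.get(t, "unassigned"))
    out = out.sort_values(
        ["shared_ratio", "n_de_targets", "tf"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    return out.reset_index(drop=True)
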