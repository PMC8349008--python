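"""Modularity and fast-greedy (Clauset-Newman-Moore) community detection,
applied hierarchically to yield communities and nested sub-communities.

The agglomerative algorithm starts from singleton communities and repeatedly
merges the connected pair of communities with the largest modularity gain
dQ, recording the full merge history; the returned partition is the one at
the peak of the modularity trajectory.  Ties in dQ are broken toward the
lexicographically smallest (community_a, community_b) pair, where a
community's identifier is the smallest provider id it contains — this makes
the output deterministic regardless of vertex iteration order.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class CommunityPartition:
    """A flat partition of graph vertices with its modularity.

    ``labels`` maps each vertex to a public label ("C1", "C2", ... ordered by
    decreasing size, or "C2.S1" for sub-communities).  ``merge_history``
    lists every agglomerative merge as ((community_a, community_b), dQ)
    using internal smallest-member identifiers.
    """

    labels: dict
    modularity: float
    level: str = "community"
    parent: str | None = None
    merge_history: list = field(default_factory=list)

    def members(self) -> dict:
        out: dict[str, list] = {}
        for node, lab in self.labels.items():
            out.setdefault(lab, []).append(node)
        return {lab: sorted(m) for lab, m in out.items()}

    def sizes(self) -> dict:
        return {lab: len(m) for lab, m in self.members().items()}


def modularity(graph: nx.Graph, labels: dict) -> float:
    """Newman modularity Q = sum_c [ e_c/m - (d_c/(2m))^2 ].

    ``labels`` must cover every vertex; raises on an edgeless graph, where Q
    is undefined.
    """
    m = graph.number_of_edges()
    if m == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    missing = set(graph.nodes) - set(labels)
    if missing:
        raise ValueError(f"partition does not cover {len(missing)} vertices")
    within: dict = {}
    degsum: dict = {}
    for node in graph.nodes:
        degsum[labels[node]] = degsum.get(labels[node], 0) + graph.degree(node)
    for u, v in graph.edges:
        if labels[u] == labels[v]:
            within[labels[u]] = within.get(labels[u], 0) + 1
    q = 0.0
    for lab, d in degsum.items():
        q += within.get(lab, 0) / m - (d / (2.0 * m)) ** 2
    return q


def _cnm_merge_sequence(graph: nx.Graph):
    """Run CNM agglomeration to exhaustion.

    Returns (history, q0) where history is the ordered list of merges
    ((cid_a, cid_b), dq) — cid_a < cid_b, the merged community keeps cid_a —
    and q0 is the modularity of the all-singletons start.
    """
    m = graph.number_of_edges()
    two_m = 2.0 * m
    a = {n: graph.degree(n) / two_m for n in graph.nodes}  # degree fractions
    alive = {n: True for n in graph.nodes}
    # inter-community edge counts, nested dicts, symmetric
    e: dict = {n: {} for n in graph.nodes}
    for u, v in graph.edges:
        if u == v:
            continue
        e[u][v] = e[u].get(v, 0) + 1
        e[v][u] = e[v].get(u, 0) + 1

    def dq(i, j):
        return e[i][j] / m - 2.0 * a[i] * a[j]

    heap = []
    for u in graph.nodes:
        for v in e[u]:
            if u < v:
                heapq.heappush(heap, (-dq(u, v), u, v))

    q0 = -sum(x * x for x in a.values())
    history = []
    while heap:
        negdq, i, j = heapq.heappop(heap)
        if not (alive.get(i) and alive.get(j)) or j not in e[i]:
            continue
        if -negdq != dq(i, j):  # stale entry
            continue
        history.append(((i, j), -negdq))
        # merge j into i (i < j so the merged community keeps the smallest id)
        alive[j] = False
        a[i] += a[j]
        nbrs_j = e.pop(j)
        e[i].pop(j, None)
        nbrs_j.pop(i, None)
        for x, cnt in nbrs_j.items():
            e[x].pop(j, None)
            e[i][x] = e[i].get(x, 0) + cnt
            e[x][i] = e[i][x]
        for x in e[i]:
            lo, hi = (i, x) if i < x else (x, i)
            heapq.heappush(heap, (-dq(i, x), lo, hi))
    return history, q0


def fast_greedy_communities(graph: nx.Graph, level: str = "community",
                            parent: str | None = None) -> CommunityPartition:
    """Modularity-maximising agglomerative communities.

    The number of communities is chosen by the algorithm itself: merging runs
    to exhaustion (one community per connected component) and the partition
    at the running maximum of Q is returned.  Graphs with fewer than two
    vertices, or without edges, yield the trivial partition.
    """
    nodes = sorted(graph.nodes)
    prefix = "C" if level == "community" else "S"
    if len(nodes) < 2:
        labels = {n: f"{prefix}1" for n in nodes}
        return CommunityPartition(labels=labels, modularity=float("nan"),
                                  level=level, parent=parent)
    if graph.number_of_edges() == 0:
        logger.warning("fast_greedy_communities: edgeless graph, singleton partition")
        labels = {n: f"{prefix}{k}" for k, n in enumerate(nodes, start=1)}
        return CommunityPartition(labels=labels, modularity=float("nan"),
                                  level=level, parent=parent)

    history, q0 = _cnm_merge_sequence(graph)
    # peak of the Q trajectory (prefix of merges maximising Q)
    best_q, best_k, q = q0, 0, q0
    for k, (_, gain) in enumerate(history, start=1):
        q += gain
        if q > best_q + 1e-15:
            best_q, best_k = q, k

    # replay the first best_k merges with union-find keyed on smallest member
    root = {n: n for n in nodes}

    def find(x):
        while root[x] != x:
            root[x] = root[root[x]]
            x = root[x]
        return x

    for (i, j), _ in history[:best_k]:
        ri, rj = find(i), find(j)
        keep, drop = (ri, rj) if ri < rj else (rj, ri)
        root[drop] = keep

    groups: dict = {}
    for n in nodes:
        groups.setdefault(find(n), []).append(n)
    # public labels ordered by decreasing size, ties by smallest member id
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    labels = {}
    for k, (_, members) in enumerate(ordered, start=1):
        for n in members:
            labels[n] = f"{prefix}{k}"
    q_final = modularity(graph, labels)
    if abs(q_final - best_q) > 1e-9:
        logger.warning("modularity bookkeeping drift: %.3e", q_final - best_q)
    return CommunityPartition(
        labels=labels, modularity=q_final, level=level, parent=parent,
        merge_history=history,
    )


def nested_subcommunities(
    graph: nx.Graph,
    communities: CommunityPartition,
    min_size: int = 10,
) -> list[CommunityPartition]:
    """Re-run detection inside each large community.

    Communities below ``min_size`` providers are excluded outright; inside
    each remaining community the algorithm runs on the induced subgraph (with
    that subgraph's own edge count), and resulting sub-communities below
    ``min_size`` are dropped from the returned labels.
    """
    results = []
    for lab, members in sorted(communities.members().items()):
        if len(members) < min_size:
            logger.info("community %s (%d providers) excluded (< %d)", lab, len(members), min_size)
            continue
        sub = graph.subgraph(members)
        part = fast_greedy_communities(sub, level="subcommunity", parent=lab)
        sizes = part.sizes()
        kept = {n: f"{lab}.{s}" for n, s in part.labels.items() if sizes[s] >= min_size}
        dropped = sum(v for k, v in sizes.items() if v < min_size)
        if dropped:
            logger.info("community %s: %d providers in undersized sub-communities dropped", lab, dropped)
        results.append(
            CommunityPartition(
                labels=kept, modularity=part.modularity, level="subcommunity",
                parent=lab, merge_history=part.merge_history,
            )
        )
    return results


def partition_table(
    graph: nx.Graph,
    communities: CommunityPartition,
    subpartitions: list[CommunityPartition],
) -> pd.DataFrame:
    """Flat provider_id -> (community, subcommunity) table; the subcommunity
    label is empty for providers excluded at either level."""
    sub_labels: dict = {}
    for part in subpartitions:
        sub_labels.update(part.labels)
    rows = [
        (n, communities.labels.get(n, ""), sub_labels.get(n, ""))
        for n in sorted(graph.nodes)
    ]
    return pd.DataFrame(rows, columns=["provider_id", "community", "subcommunity"])


def modularity_summary(
    communities: CommunityPartition, subpartitions: list[CommunityPartition]
) -> pd.DataFrame:
    """Per-level modularity report (community level plus one row per parent)."""
    rows = [("community", "", communities.modularity, len(communities.sizes()))]
    for part in subpartitions:
        rows.append(("subcommunity", part.parent, part.modularity, len(part.sizes())))
    return pd.DataFrame(rows, columns=["level", "parent", "modularity", "n_groups"])
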