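"""Patient-sharing provider graph: shared-patient counting, edge
thresholding and largest-connected-component extraction.

Two providers are connected when they billed claims for at least
``min_shared`` (default 3) of the same patients anywhere in the study
window.  The graph is undirected and, after thresholding, unweighted for all
downstream computation; the underlying shared-patient counts are retained as
edge metadata only.
"""

from __future__ import annotations

import logging
from collections import Counter
from itertools import combinations

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

EDGE_SOURCES = ("all_claims", "outpatient_visits")


def count_shared_patients(
    claims: pd.DataFrame,
    providers: pd.DataFrame,
    edge_source: str = "all_claims",
    visits: pd.DataFrame | None = None,
) -> Counter:
    """Distinct shared patients for every unordered provider pair.

    ``providers`` gives the eligible individual providers (rows with
    provider_id, specialty_group); facility claims and ineligible providers
    never contribute.  With ``edge_source='outpatient_visits'`` the supplied
    deduplicated ``visits`` table is used instead of all claim lines.
    Duplicated patient-provider claims add nothing: the count is over
    distinct patients.
    """
    if edge_source not in EDGE_SOURCES:
        raise ValueError(f"edge_source must be one of {EDGE_SOURCES}")
    if edge_source == "outpatient_visits":
        if visits is None:
            raise ValueError("edge_source='outpatient_visits' requires a visits table")
        pairs = visits[["patient_id", "provider_id"]]
    else:
        pairs = claims.loc[
            claims["provider_id"].fillna("").astype(str).str.len() > 0,
            ["patient_id", "provider_id"],
        ]
    eligible = set(providers["provider_id"])
    pairs = pairs[pairs["provider_id"].isin(eligible)].drop_duplicates()

    counts: Counter = Counter()
    for _, grp in pairs.groupby("patient_id", sort=False)["provider_id"]:
        provs = sorted(grp)
        for a, b in combinations(provs, 2):
            counts[(a, b)] += 1
    return counts


def threshold_graph(
    counts: Counter,
    providers: pd.DataFrame,
    min_shared: int = 3,
) -> nx.Graph:
    """Unweighted graph with an edge wherever the shared count reaches the
    threshold; all eligible providers are kept as (possibly isolated) nodes."""
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")
    G = nx.Graph(min_shared=min_shared, lcc_extracted=False)
    spec = dict(zip(providers["provider_id"], providers["specialty_group"]))
    G.add_nodes_from((p, {"specialty_group": s}) for p, s in sorted(spec.items()))
    for (a, b), n in counts.items():
        if n >= min_shared:
            G.add_edge(a, b, shared_patients=int(n))
    return G


def largest_connected_component(
    graph: nx.Graph, claims: pd.DataFrame | None = None
) -> tuple[nx.Graph, dict]:
    """Induced subgraph on the largest component (ties broken toward the
    component containing the lexicographically smallest provider id).

    Returns (subgraph, report); the report carries the retained fraction of
    providers and, when claims are supplied, of patients (those with at least
    one claim with a retained provider).
    """
    report: dict = {"n_providers_total": graph.number_of_nodes()}
    if graph.number_of_nodes() == 0:
        logger.warning("largest_connected_component: empty graph")
        report.update(n_providers_retained=0, provider_retention=float("nan"))
        return graph.copy(), report
    components = list(nx.connected_components(graph))
    # tie rule: among maximal components pick the one whose smallest member
    # sorts first
    max_size = max(len(c) for c in components)
    candidates = [c for c in components if len(c) == max_size]
    best = min(candidates, key=min)
    sub = graph.subgraph(best).copy()
    sub.graph["lcc_extracted"] = True
    report["n_providers_retained"] = sub.number_of_nodes()
    report["provider_retention"] = sub.number_of_nodes() / graph.number_of_nodes()
    if claims is not None:
        with_provider = claims[claims["provider_id"].isin(set(graph.nodes))]
        all_patients = set(with_provider["patient_id"])
        kept = set(with_provider.loc[
            with_provider["provider_id"].isin(best), "patient_id"
        ])
        report["n_patients_total"] = len(all_patients)
        report["n_patients_retained"] = len(kept)
        report["patient_retention"] = (
            len(kept) / len(all_patients) if all_patients else float("nan")
        )
    logger.info("largest component: %s", report)
    return sub, report


def write_edge_list(graph: nx.Graph, path) -> None:
    """TSV edge list provider_a, provider_b, shared_patients (sorted)."""
    rows = sorted((min(a, b), max(a, b), d.get("shared_patients", ""))
                  for a, b, d in graph.edges(data=True))
    pd.DataFrame(rows, columns=["provider_a", "provider_b", "shared_patients"]).to_csv(
        path, sep="\t", index=False
    )


def write_node_attributes(graph: nx.Graph, path) -> None:
    rows = sorted((n, d.get("specialty_group", "")) for n, d in graph.nodes(data=True))
    pd.DataFrame(rows, columns=["provider_id", "specialty_group"]).to_csv(path, index=False)


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)
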