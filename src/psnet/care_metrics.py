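"""Continuity-of-care and structural network metrics.

The Bice-Boxerman continuity-of-care index for one patient-year is

    CoC = (sum_i n_i^2 - n) / (n (n - 1))

over that year's deduplicated outpatient visits, where n_i is the visit
count with provider i and n the total; it equals 1 when every visit is with
one provider and 0 when every visit is with a different provider.  Following
common practice it is computed only for patient-years with at least
``min_visits`` (default 4) visits.

Provider-level metrics: degree and specialty-specific degree on the
thresholded patient-sharing graph, local transitivity (fraction of a
provider's neighbour pairs that are themselves connected; undefined below
degree 2), the provider's mean CoC over eligible patient-years, and the mean
CoC of the provider's direct network neighbours ("alter CoC").
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROFILE_COLUMNS = [
    "provider_id", "specialty_group", "community", "subcommunity",
    "degree", "degree_to_pcp", "degree_to_pcp_same_community",
    "transitivity", "n_patients", "n_patients_with_pcp",
    "n_patients_with_pcp_same_community", "mean_coc", "alter_mean_coc",
]


def patient_coc(visits_of_patient_year: pd.DataFrame, min_visits: int = 4) -> dict | None:
    """Bice-Boxerman CoC for one patient-year; None when under min_visits.

    ``visits_of_patient_year`` must already be deduplicated to one visit per
    (provider, day).
    """
    n = len(visits_of_patient_year)
    if n < min_visits:
        return None
    n_i = visits_of_patient_year.groupby("provider_id").size()
    coc = (float((n_i**2).sum()) - n) / (n * (n - 1))
    return {
        "patient_id": visits_of_patient_year["patient_id"].iloc[0],
        "year": int(visits_of_patient_year["year"].iloc[0]),
        "p": int(len(n_i)),
        "n": int(n),
        "coc": coc,
    }


def coc_table(visits: pd.DataFrame, min_visits: int = 4) -> pd.DataFrame:
    """Per patient-year CoC over all eligible patient-years (vectorised).

    Returns columns patient_id, year, p, n, coc.
    """
    if visits.empty:
        return pd.DataFrame(columns=["patient_id", "year", "p", "n", "coc"])
    per_prov = (
        visits.groupby(["patient_id", "year", "provider_id"], sort=True)
        .size()
        .rename("n_i")
        .reset_index()
    )
    agg = per_prov.groupby(["patient_id", "year"]).agg(
        p=("n_i", "size"), n=("n_i", "sum"), sumsq=("n_i", lambda s: int((s**2).sum()))
    ).reset_index()
    agg = agg[agg["n"] >= min_visits].copy()
    agg["coc"] = (agg["sumsq"] - agg["n"]) / (agg["n"] * (agg["n"] - 1))
    return agg[["patient_id", "year", "p", "n", "coc"]].reset_index(drop=True)


def provider_mean_coc(visits: pd.DataFrame, coc_records: pd.DataFrame) -> pd.Series:
    """Unweighted mean CoC over the eligible patient-years a provider appears in.

    A provider "appears in" a patient-year when they had at least one visit
    with that patient that year; patient-years from both study years pool
    into a single per-provider average.  Providers seen only by ineligible
    (< min-visit) patients get NaN.
    """
    if visits.empty or coc_records.empty:
        return pd.Series(dtype=float, name="mean_coc")
    appear = visits[["provider_id", "patient_id", "year"]].drop_duplicates()
    merged = appear.merge(coc_records, on=["patient_id", "year"], how="inner")
    return merged.groupby("provider_id")["coc"].mean().rename("mean_coc")


def alter_mean_coc(graph: nx.Graph, mean_coc: pd.Series) -> pd.Series:
    """Mean of network neighbours' mean CoC, skipping neighbours with missing
    values; NaN for isolated providers or all-missing neighbourhoods."""
    out = {}
    for node in graph.nodes:
        vals = [mean_coc[nb] for nb in graph.neighbors(node)
                if nb in mean_coc.index and not pd.isna(mean_coc[nb])]
        out[node] = float(np.mean(vals)) if vals else float("nan")
    return pd.Series(out, name="alter_mean_coc").sort_index()


def local_transitivity(graph: nx.Graph, provider) -> float:
    """Fraction of a provider's neighbour pairs that are connected; NaN for
    degree < 2."""
    k = graph.degree(provider)
    if k < 2:
        return float("nan")
    nbrs = list(graph.neighbors(provider))
    links = sum(
        1
        for i in range(len(nbrs))
        for j in range(i + 1, len(nbrs))
        if graph.has_edge(nbrs[i], nbrs[j])
    )
    return links / (k * (k - 1) / 2)


def transitivity_series(graph: nx.Graph) -> pd.Series:
    """Local transitivity for every vertex (NaN below degree 2)."""
    clus = nx.clustering(graph)
    deg = dict(graph.degree())
    return pd.Series(
        {n: (clus[n] if deg[n] >= 2 else float("nan")) for n in graph.nodes},
        name="transitivity",
    ).sort_index()


def _patient_provider_pairs(claims: pd.DataFrame, nodes: set) -> pd.DataFrame:
    pairs = claims.loc[
        claims["provider_id"].fillna("").astype(str).str.len() > 0,
        ["patient_id", "provider_id"],
    ].drop_duplicates()
    return pairs[pairs["provider_id"].isin(nodes)]


def structural_profile(
    graph: nx.Graph,
    partition: pd.DataFrame,
    claims: pd.DataFrame | None = None,
    visits: pd.DataFrame | None = None,
    coc_records: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per provider with degree, PCP-degree (overall and within own
    community), transitivity, patient counts and CoC averages.

    Patient counts use all claim types by default (mirroring network
    construction); CoC columns require ``visits`` and ``coc_records``.
    """
    part = partition.set_index("provider_id")
    spec = nx.get_node_attributes(graph, "specialty_group")
    trans = transitivity_series(graph)

    rows = []
    for node in sorted(graph.nodes):
        com = part["community"].get(node, "")
        nbrs = list(graph.neighbors(node))
        pcp_nbrs = [nb for nb in nbrs if spec.get(nb) == "pcp"]
        pcp_same = [nb for nb in pcp_nbrs if part["community"].get(nb, None) == com and com != ""]
        rows.append({
            "provider_id": node,
            "specialty_group": spec.get(node, ""),
            "community": com,
            "subcommunity": part["subcommunity"].get(node, ""),
            "degree": len(nbrs),
            "degree_to_pcp": len(pcp_nbrs),
            "degree_to_pcp_same_community": len(pcp_same),
            "transitivity": trans[node],
        })
    profiles = pd.DataFrame(rows, columns=[
        "provider_id", "specialty_group", "community", "subcommunity",
        "degree", "degree_to_pcp", "degree_to_pcp_same_community", "transitivity",
    ])

    nodes = set(graph.nodes)
    if claims is not None:
        pairs = _patient_provider_pairs(claims, nodes)
        n_pat = pairs.groupby("provider_id")["patient_id"].nunique()
        pcp_ids = {n for n, s in spec.items() if s == "pcp"}
        pat_with_pcp = set(pairs.loc[pairs["provider_id"].isin(pcp_ids), "patient_id"])
        with_pcp = pairs[pairs["patient_id"].isin(pat_with_pcp)]
        n_with_pcp = with_pcp.groupby("provider_id")["patient_id"].nunique()
        # same-community variant: patient must share a PCP in the provider's community
        com_of = part["community"].to_dict()
        pcp_pairs = pairs[pairs["provider_id"].isin(pcp_ids)].copy()
        pcp_pairs["pcp_com"] = pcp_pairs["provider_id"].map(com_of)
        pat_coms = pcp_pairs.groupby("patient_id")["pcp_com"].agg(set)
        own_com = profiles["provider_id"].map(com_of)
        same = []
        prov_pat = pairs.groupby("provider_id")["patient_id"].agg(list)
        for pid, com in zip(profiles["provider_id"], own_com):
            pats = prov_pat.get(pid, [])
            same.append(sum(1 for pt in pats if com and com in pat_coms.get(pt, set())))
        profiles["n_patients"] = profiles["provider_id"].map(n_pat).fillna(0).astype(int)
        profiles["n_patients_with_pcp"] = (
            profiles["provider_id"].map(n_with_pcp).fillna(0).astype(int)
        )
        profiles["n_patients_with_pcp_same_community"] = same
    else:
        profiles["n_patients"] = 0
        profiles["n_patients_with_pcp"] = 0
        profiles["n_patients_with_pcp_same_community"] = 0

    if visits is not None and coc_records is not None:
        mc = provider_mean_coc(visits, coc_records)
        profiles["mean_coc"] = profiles["provider_id"].map(mc)
        am = alter_mean_coc(graph, mc)
        profiles["alter_mean_coc"] = profiles["provider_id"].map(am)
    else:
        profiles["mean_coc"] = float("nan")
        profiles["alter_mean_coc"] = float("nan")
    return profiles[PROFILE_COLUMNS]


def five_number_summary(profiles: pd.DataFrame) -> pd.DataFrame:
    """Min / median / mean / max for each numeric provider metric."""
    metrics = [
        "degree", "transitivity", "degree_to_pcp", "degree_to_pcp_same_community",
        "n_patients", "n_patients_with_pcp", "n_patients_with_pcp_same_community",
        "mean_coc", "alter_mean_coc",
    ]
    rows = []
    for met in metrics:
        s = profiles[met].dropna()
        if s.empty:
            rows.append((met, *([float("nan")] * 4), 0))
        else:
            rows.append((met, s.min(), s.median(), s.mean(), s.max(), len(s)))
    return pd.DataFrame(rows, columns=["metric", "min", "median", "mean", "max", "n"])


def _pcp_degree_within(graph: nx.Graph, labels: pd.Series, spec: dict) -> pd.Series:
    """Per provider: fraction of their PCP connections inside their own
    sub-community (NaN with zero PCP connections)."""
    out = {}
    for node in graph.nodes:
        lab = labels.get(node, "")
        if not lab:
            continue
        pcps = [nb for nb in graph.neighbors(node) if spec.get(nb) == "pcp"]
        if not pcps:
            out[node] = float("nan")
        else:
            out[node] = sum(1 for nb in pcps if labels.get(nb, "") == lab) / len(pcps)
    return pd.Series(out)


def subcommunity_summary(
    graph: nx.Graph, profiles: pd.DataFrame, min_size: int = 10
) -> pd.DataFrame:
    """One row per retained sub-community: size, mean connections, mean PCP
    connections, % of PCP connections kept within the sub-community, mean
    transitivity, average CoC and specialty composition proportions."""
    spec = nx.get_node_attributes(graph, "specialty_group")
    labeled = profiles[profiles["subcommunity"] != ""].copy()
    if labeled.empty:
        return pd.DataFrame(columns=[
            "subcommunity", "community", "size", "mean_degree", "mean_degree_to_pcp",
            "pct_pcp_within", "mean_transitivity", "mean_coc",
            "prop_pcp", "prop_psychiatrist", "prop_psychologist", "prop_bh_specialist",
        ])
    labels = labeled.set_index("provider_id")["subcommunity"]
    within = _pcp_degree_within(graph, labels, spec)
    labeled["pcp_within_frac"] = labeled["provider_id"].map(within)
    rows = []
    for lab, grp in labeled.groupby("subcommunity", sort=True):
        if len(grp) < min_size:
            continue
        comp = grp["specialty_group"].value_counts(normalize=True)
        rows.append({
            "subcommunity": lab,
            "community": lab.split(".")[0],
            "size": len(grp),
            "mean_degree": grp["degree"].mean(),
            "mean_degree_to_pcp": grp["degree_to_pcp"].mean(),
            "pct_pcp_within": 100.0 * grp["pcp_within_frac"].dropna().mean(),
            "mean_transitivity": grp["transitivity"].dropna().mean(),
            "mean_coc": grp["mean_coc"].dropna().mean(),
            "prop_pcp": comp.get("pcp", 0.0),
            "prop_psychiatrist": comp.get("psychiatrist", 0.0),
            "prop_psychologist": comp.get("psychologist", 0.0),
            "prop_bh_specialist": comp.get("bh_specialist", 0.0),
        })
    return pd.DataFrame(rows)


def community_ranges(summary: pd.DataFrame) -> pd.DataFrame:
    """Per community: number of sub-communities and min-max ranges of each
    sub-community characteristic."""
    if summary.empty:
        return pd.DataFrame()
    rows = []
    for com, grp in summary.groupby("community", sort=True):
        row = {"community": com, "n_subcommunities": len(grp)}
        for col in ["size", "mean_degree", "mean_degree_to_pcp", "pct_pcp_within",
                    "mean_transitivity", "mean_coc"]:
            row[f"{col}_min"] = grp[col].min()
            row[f"{col}_max"] = grp[col].max()
        rows.append(row)
    return pd.DataFrame(rows)
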