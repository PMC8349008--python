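"""End-to-end orchestration: cohort -> network -> communities -> metrics ->
models, with table artifacts and a machine-readable audit of every dropped
record."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association_models import (
    correlate_size_vs_characteristics,
    fit_coc_model,
    model_report,
    unadjusted_association,
)
from .care_metrics import (
    coc_table,
    community_ranges,
    five_number_summary,
    structural_profile,
    subcommunity_summary,
)
from .claims_domain import (
    DiagnosisHierarchy,
    apply_cohort_filters,
    classify_patient_year_table,
    classify_providers,
    derive_insurance_table,
    identify_outpatient_visits,
    load_taxonomy_mapping,
    read_claims_csv,
)
from .community_structure import (
    fast_greedy_communities,
    modularity_summary,
    nested_subcommunities,
    partition_table,
)
from .config import PipelineConfig
from .provider_network import (
    count_shared_patients,
    largest_connected_component,
    threshold_graph,
    write_edge_list,
    write_node_attributes,
)

logger = logging.getLogger(__name__)

STAGES = ("cohort", "network", "communities", "metrics", "model")

_FLOAT_FMT = "%.6f"


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _write(df: pd.DataFrame, path: Path, stamp: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {stamp}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def cohort_summary_table(
    claims: pd.DataFrame, patients: pd.DataFrame, hierarchy: DiagnosisHierarchy,
    years,
) -> pd.DataFrame:
    """Sample-characteristics table: sex, age bands in the first study year,
    hierarchical diagnosis category over the window, and insurance class."""
    n = len(patients)
    rows = [("total", "n", n, 100.0)]

    def add(characteristic, counts: pd.Series):
        for cat, cnt in counts.items():
            rows.append((characteristic, str(cat), int(cnt),
                         100.0 * cnt / n if n else float("nan")))

    add("sex", patients["sex"].value_counts())
    base = min(years)
    age = base - patients["birth_year"].astype(int)
    bands = pd.cut(age, bins=[-1, 29, 40, 51, 200],
                   labels=["17_29", "30_40", "41_51", "52_plus"])
    add("age_band", bands.value_counts().sort_index())
    dx = classify_patient_year_table(claims, hierarchy)
    if not dx.empty:
        rank = {name: i for i, (name, _) in enumerate(hierarchy.categories)}
        best = (dx.assign(r=dx["category"].map(rank))
                  .sort_values(["patient_id", "r"], kind="mergesort")
                  .drop_duplicates("patient_id"))
        add("diagnosis", best["category"].value_counts())
    ins = derive_insurance_table(claims)
    add("insurance", ins.value_counts())
    return pd.DataFrame(rows, columns=["characteristic", "category", "count", "percent"])


def run_pipeline(config: PipelineConfig, until: str = "model") -> dict:
    """Run the analysis through ``until`` (a STAGES entry), writing each
    stage's artifacts into the output directory; returns in-memory results."""
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}")
    last = STAGES.index(until)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = f"psnet {__version__} config_hash={config.config_hash()} seed={config.seed}"

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("psnet")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    results: dict = {"audit": {}}
    audit = results["audit"]
    try:
        try:
            stage = "cohort"
            hierarchy = (DiagnosisHierarchy.from_csv(config.hierarchy_path)
                         if config.hierarchy_path else DiagnosisHierarchy.default())
            mapping = load_taxonomy_mapping(config.taxonomy_path or None)
            claims = read_claims_csv(config.claims_path)
            patients = pd.read_csv(config.patients_path, dtype={"patient_id": str})
            providers = pd.read_csv(config.providers_path, dtype=str)
            providers = classify_providers(providers, mapping)
            audit["input_claims"] = len(claims)
            cohort_cfg = config.cohort_config()
            claims, patients, cohort_audit = apply_cohort_filters(
                claims, patients, providers, cohort_cfg, hierarchy
            )
            audit.update(cohort_audit)
            summary = cohort_summary_table(claims, patients, hierarchy, config.study_years)
            _write(summary, outdir / "cohort_summary.csv", stamp)
            results.update(claims=claims, patients=patients, providers=providers,
                           cohort_summary=summary, hierarchy=hierarchy)
            if last == 0:
                return results

            stage = "network"
            eligible = providers[providers["specialty_group"] != "other"]
            audit["providers_other_excluded"] = len(providers) - len(eligible)
            visits = identify_outpatient_visits(claims, cohort_cfg)
            audit["outpatient_visits"] = len(visits)
            counts = count_shared_patients(
                claims, eligible, edge_source=config.edge_source, visits=visits
            )
            full_graph = threshold_graph(counts, eligible, min_shared=config.min_shared)
            if full_graph.number_of_edges() == 0:
                logger.warning("thresholded graph has no edges (min_shared=%d)",
                               config.min_shared)
            graph, lcc_report = largest_connected_component(full_graph, claims=claims)
            audit.update({f"lcc_{k}": v for k, v in lcc_report.items()})
            write_edge_list(graph, outdir / "edge_list.tsv")
            write_node_attributes(graph, outdir / "node_attributes.csv")
            results.update(visits=visits, graph=graph, lcc_report=lcc_report)
            if last == 1:
                return results

            stage = "communities"
            communities = fast_greedy_communities(graph)
            subparts = nested_subcommunities(
                graph, communities, min_size=config.min_community_size
            )
            parts = partition_table(graph, communities, subparts)
            _write(parts, outdir / "partitions.csv", stamp)
            _write(modularity_summary(communities, subparts),
                   outdir / "modularity_summary.csv", stamp)
            results.update(communities=communities, subpartitions=subparts,
                           partitions=parts)
            if last == 2:
                return results

            stage = "metrics"
            cocs = coc_table(visits, min_visits=config.min_visits)
            audit["eligible_patient_years"] = len(cocs)
            profiles = structural_profile(graph, parts, claims=claims,
                                          visits=visits, coc_records=cocs)
            audit["providers_transitivity_missing"] = int(profiles["transitivity"].isna().sum())
            _write(profiles, outdir / "provider_profiles.csv", stamp)
            _write(five_number_summary(profiles),
                   outdir / "provider_summary.csv", stamp)
            subsum = subcommunity_summary(graph, profiles,
                                          min_size=config.min_community_size)
            _write(subsum, outdir / "subcommunity_summary.csv", stamp)
            _write(community_ranges(subsum), outdir / "community_ranges.csv", stamp)
            results.update(coc_records=cocs, profiles=profiles,
                           subcommunity_summary=subsum)
            if last == 3:
                return results

            stage = "model"
            if len(subsum) >= 3:
                corr = correlate_size_vs_characteristics(subsum)
            else:
                logger.warning("fewer than 3 sub-communities; correlations skipped")
                corr = pd.DataFrame(columns=["characteristic", "pearson", "spearman", "n"])
            _write(corr, outdir / "correlations.csv", stamp)
            pear, spear = unadjusted_association(profiles)
            results["unadjusted"] = {"pearson": pear, "spearman": spear}
            complete = profiles.dropna(subset=["mean_coc", "transitivity"])
            fits = []
            if len(complete) < 10:
                logger.warning("only %d complete provider rows; continuity models skipped",
                               len(complete))
            else:
                if config.include_model1:
                    fits.append(fit_coc_model(profiles, include_alter_coc=False,
                                              grouping=config.model_grouping))
                if config.include_model2:
                    fits.append(fit_coc_model(profiles, include_alter_coc=True,
                                              grouping=config.model_grouping))
            report = model_report(fits) if fits else pd.DataFrame(
                columns=["model", "term", "estimate", "se", "p"])
            _write(report, outdir / "model_report.csv", stamp)
            results.update(correlations=corr, fits=fits, model_report=report)
        except Exception as exc:  # noqa: BLE001 - stage-named abort by contract
            raise StageError(stage, exc) from exc

        audit_rows = pd.DataFrame(
            sorted(audit.items()), columns=["counter", "value"]
        )
        _write(audit_rows, outdir / "audit.csv", stamp)
        return results
    finally:
        root.removeHandler(handler)
        handler.close()


def plot_community_composition(profiles: pd.DataFrame, path) -> None:
    """Stacked bar of specialty composition per community (size-ordered)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    comp = (profiles[profiles["community"] != ""]
            .groupby(["community", "specialty_group"]).size().unstack(fill_value=0))
    comp = comp.loc[comp.sum(axis=1).sort_values(ascending=False).index]
    ax = comp.plot(kind="bar", stacked=True, figsize=(8, 5))
    ax.set_xlabel("network community")
    ax.set_ylabel("providers")
    ax.figure.tight_layout()
    ax.figure.savefig(path, dpi=150)
    plt.close(ax.figure)
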