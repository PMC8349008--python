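"""Bice-Boxerman continuity of care, transitivity and provider profiles."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psnet.care_metrics import (
    alter_mean_coc,
    coc_table,
    community_ranges,
    five_number_summary,
    local_transitivity,
    patient_coc,
    provider_mean_coc,
    structural_profile,
    subcommunity_summary,
    transitivity_series,
)

from conftest import make_visits


def visits_from_counts(counts, patient="p1", year=2016):
    """Visit table with counts[i] visits to provider i, on distinct days."""
    entries = []
    day = 1
    for i, n in enumerate(counts):
        for _ in range(n):
            entries.append((patient, f"prov{i}", f"{year}-{1 + day // 28:02d}-{1 + day % 28:02d}"))
            day += 1
    return make_visits(entries)


def coc_pair_counting(counts):
    """Independent oracle: fraction of visit pairs that share a provider."""
    visits = [i for i, n in enumerate(counts) for _ in range(n)]
    n = len(visits)
    same = sum(1 for a, b in itertools.combinations(visits, 2) if a == b)
    return same / (n * (n - 1) / 2)


class TestPatientCoc:
    def test_all_one_provider(self):
        rec = patient_coc(visits_from_counts([4]))
        assert rec["coc"] == pytest.approx(1.0)
        assert rec["p"] == 1 and rec["n"] == 4

    def test_all_distinct_providers(self):
        rec = patient_coc(visits_from_counts([1, 1, 1, 1]))
        assert rec["coc"] == pytest.approx(0.0)

    def test_hand_example(self):
        # n_i = (3,2,1): (9+4+1-6)/30 = 4/15
        rec = patient_coc(visits_from_counts([3, 2, 1]))
        assert rec["coc"] == pytest.approx(4 / 15)
        assert rec["coc"] == pytest.approx(coc_pair_counting([3, 2, 1]))

    def test_below_minimum_ineligible(self):
        assert patient_coc(visits_from_counts([2, 1])) is None
        assert patient_coc(visits_from_counts([3]), min_visits=4) is None

    def test_pair_counting_identity_random(self, rng):
        for _ in range(100):
            k = int(rng.integers(1, 6))
            counts = [int(rng.integers(1, 5)) for _ in range(k)]
            if sum(counts) < 4:
                continue
            rec = patient_coc(visits_from_counts(counts))
            assert rec["coc"] == pytest.approx(coc_pair_counting(counts), abs=1e-12)
            assert 0.0 <= rec["coc"] <= 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=6), min_size=1, max_size=6)
           .filter(lambda c: sum(c) >= 4))
    def test_pair_counting_identity_property(self, counts):
        """CoC equals the fraction of visit pairs sharing a provider, and
        stays in [0, 1], for arbitrary visit multisets."""
        rec = patient_coc(visits_from_counts(counts))
        assert 0.0 <= rec["coc"] <= 1.0
        assert rec["coc"] == pytest.approx(coc_pair_counting(counts), abs=1e-12)
        assert (rec["coc"] == 1.0) == (len(counts) == 1)
        assert (rec["coc"] == 0.0) == all(c == 1 for c in counts)

    def test_majorization_monotonicity(self):
        # moving a visit from a second provider onto the first raises CoC
        low = patient_coc(visits_from_counts([3, 3]))["coc"]
        high = patient_coc(visits_from_counts([4, 2]))["coc"]
        assert high > low

    def test_coc_table_matches_scalar(self, rng):
        entries = []
        for p in range(6):
            counts = [int(rng.integers(1, 4)) for _ in range(int(rng.integers(1, 4)))]
            vis = visits_from_counts(counts, patient=f"p{p}", year=2016 + p % 2)
            entries.append(vis)
        visits = pd.concat(entries, ignore_index=True)
        table = coc_table(visits)
        for _, row in table.iterrows():
            sub = visits[(visits["patient_id"] == row["patient_id"])
                         & (visits["year"] == row["year"])]
            assert row["coc"] == pytest.approx(patient_coc(sub)["coc"], abs=1e-12)


class TestProviderCoc:
    def test_single_patient_year(self):
        visits = make_visits([("p1", "A", "2016-01-01")])
        cocs = pd.DataFrame({"patient_id": ["p1"], "year": [2016], "coc": [0.5],
                             "p": [1], "n": [4]})
        assert provider_mean_coc(visits, cocs)["A"] == pytest.approx(0.5)

    def test_two_patient_years_average(self):
        visits = make_visits([("p1", "A", "2016-01-01"), ("p2", "A", "2016-02-01")])
        cocs = pd.DataFrame({"patient_id": ["p1", "p2"], "year": [2016, 2016],
                             "coc": [1.0, 0.0], "p": [1, 4], "n": [4, 4]})
        assert provider_mean_coc(visits, cocs)["A"] == pytest.approx(0.5)

    def test_provider_with_only_ineligible_patients_missing(self):
        visits = make_visits([("p1", "A", "2016-01-01")])
        cocs = pd.DataFrame(columns=["patient_id", "year", "p", "n", "coc"])
        assert "A" not in provider_mean_coc(visits, cocs).index

    def test_patient_year_pooling(self):
        # same patient, two years, counts as two records
        visits = make_visits([("p1", "A", "2016-01-01"), ("p1", "A", "2017-01-01")])
        cocs = pd.DataFrame({"patient_id": ["p1", "p1"], "year": [2016, 2017],
                             "coc": [0.2, 0.6], "p": [2, 2], "n": [4, 5]})
        assert provider_mean_coc(visits, cocs)["A"] == pytest.approx(0.4)


class TestAlterCoc:
    def build(self):
        G = nx.Graph([("A", "B"), ("A", "C"), ("A", "D")])
        G.add_node("E")  # isolated
        return G

    def test_single_neighbor(self):
        G = nx.Graph([("A", "B")])
        mc = pd.Series({"B": 0.3})
        assert alter_mean_coc(G, mc)["A"] == pytest.approx(0.3)

    def test_isolated_vertex_missing(self):
        out = alter_mean_coc(self.build(), pd.Series({"A": 0.5}))
        assert np.isnan(out["E"])

    def test_missing_neighbors_skipped(self):
        mc = pd.Series({"B": 0.2, "C": 0.4, "D": np.nan})
        assert alter_mean_coc(self.build(), mc)["A"] == pytest.approx(0.3)


class TestTransitivity:
    def test_triangle(self):
        G = nx.complete_graph(3)
        assert local_transitivity(G, 0) == pytest.approx(1.0)

    def test_star_center(self):
        G = nx.star_graph(4)
        assert local_transitivity(G, 0) == pytest.approx(0.0)

    def test_one_of_three_pairs(self):
        G = nx.Graph([("x", "a"), ("x", "b"), ("x", "c"), ("a", "b")])
        assert local_transitivity(G, "x") == pytest.approx(1 / 3)

    def test_degree_below_two_missing(self):
        G = nx.path_graph(3)
        assert np.isnan(local_transitivity(G, 0))

    def test_series_matches_scalar_and_networkx(self, rng):
        G = nx.gnp_random_graph(40, 0.15, seed=9)
        series = transitivity_series(G)
        clus = nx.clustering(G)
        for n in G:
            if G.degree(n) < 2:
                assert np.isnan(series[n])
            else:
                assert series[n] == pytest.approx(local_transitivity(G, n), abs=1e-12)
                assert series[n] == pytest.approx(clus[n], abs=1e-12)

    def test_clique_and_tree_means(self):
        clique = transitivity_series(nx.complete_graph(8))
        assert clique.mean() == pytest.approx(1.0)
        tree = transitivity_series(nx.random_labeled_tree(12, seed=3))
        assert tree.dropna().mean() == pytest.approx(0.0)

    def test_degree_sum_equals_twice_edges(self, rng):
        G = nx.gnp_random_graph(30, 0.2, seed=2)
        assert sum(dict(G.degree()).values()) == 2 * G.number_of_edges()


@pytest.fixture
def fixture_graph():
    """8 providers, hand-checkable structure, two communities."""
    G = nx.Graph()
    spec = {"A": "psychiatrist", "B": "pcp", "C": "pcp", "D": "psychologist",
            "E": "pcp", "F": "bh_specialist", "G": "pcp", "H": "bh_specialist"}
    G.add_nodes_from((n, {"specialty_group": s}) for n, s in spec.items())
    G.add_edges_from([("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"),
                      ("E", "F"), ("E", "G"), ("F", "G"), ("G", "H"), ("D", "E")])
    part = pd.DataFrame({
        "provider_id": list("ABCDEFGH"),
        "community": ["C1"] * 4 + ["C2"] * 4,
        "subcommunity": ["C1.S1"] * 4 + ["C2.S1"] * 4,
    })
    return G, part


class TestStructuralProfile:
    def test_hand_computed_row(self, fixture_graph):
        G, part = fixture_graph
        prof = structural_profile(G, part).set_index("provider_id")
        a = prof.loc["A"]
        assert a["degree"] == 3
        assert a["degree_to_pcp"] == 2          # B and C
        assert a["degree_to_pcp_same_community"] == 2
        assert a["transitivity"] == pytest.approx(1 / 3)  # only B-C among {B,C,D}
        d = prof.loc["D"]
        assert d["degree"] == 2 and d["degree_to_pcp"] == 1  # E is a pcp
        assert d["degree_to_pcp_same_community"] == 0        # E in other community
        h = prof.loc["H"]
        assert h["degree"] == 1 and np.isnan(h["transitivity"])

    def test_patient_counts(self, fixture_graph):
        G, part = fixture_graph
        claims = pd.DataFrame({
            "patient_id": ["p1", "p1", "p2", "p2", "p3"],
            "provider_id": ["A", "B", "A", "D", "A"],
            "service_date": pd.Timestamp("2016-06-01"),
            "claim_type": "outpatient",
            "dx1": "F32.9", "dx2": "", "procedure_code": "99213",
            "payer": "medicaid",
        })
        prof = structural_profile(G, part, claims=claims).set_index("provider_id")
        assert prof.loc["A", "n_patients"] == 3
        assert prof.loc["A", "n_patients_with_pcp"] == 1  # only p1 saw a pcp (B)
        assert prof.loc["A", "n_patients_with_pcp_same_community"] == 1


class TestSubcommunitySummary:
    def test_small_subcommunity_excluded(self, fixture_graph):
        G, part = fixture_graph
        prof = structural_profile(G, part)
        assert subcommunity_summary(G, prof, min_size=10).empty
        summary = subcommunity_summary(G, prof, min_size=4)
        assert len(summary) == 2

    def test_fixture_means(self, fixture_graph):
        G, part = fixture_graph
        prof = structural_profile(G, part)
        summary = subcommunity_summary(G, prof, min_size=4).set_index("subcommunity")
        # community 1 degrees: A=3, B=2, C=2, D=2
        assert summary.loc["C1.S1", "mean_degree"] == pytest.approx(9 / 4)
        assert summary.loc["C1.S1", "prop_pcp"] == pytest.approx(0.5)
        # ranges table covers both communities
        ranges = community_ranges(summary.reset_index())
        assert len(ranges) == 2 and set(ranges["n_subcommunities"]) == {1}

    def test_empty_profiles(self, fixture_graph):
        G, part = fixture_graph
        prof = structural_profile(G, part).iloc[0:0]
        assert subcommunity_summary(G, prof).empty

    def test_pcp_within_fraction(self, fixture_graph):
        G, part = fixture_graph
        prof = structural_profile(G, part)
        summary = subcommunity_summary(G, prof, min_size=4).set_index("subcommunity")
        # in C1.S1: A's pcp links (B,C) both inside; B: pcp link C inside;
        # C: pcp link B inside; D: pcp link E outside -> fractions 1,1,1,0
        assert summary.loc["C1.S1", "pct_pcp_within"] == pytest.approx(75.0)


def test_five_number_summary(fixture_graph):
    G, part = fixture_graph
    prof = structural_profile(G, part)
    table = five_number_summary(prof).set_index("metric")
    assert table.loc["degree", "min"] == 1
    assert table.loc["degree", "max"] == 3
    assert table.loc["transitivity", "n"] == int(prof["transitivity"].notna().sum())
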