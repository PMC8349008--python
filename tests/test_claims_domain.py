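"""Cohort filtering, provider/diagnosis classification and visit rules."""

import numpy as np
import pandas as pd
import pytest

from psnet.claims_domain import (
    CohortConfig,
    DiagnosisHierarchy,
    OutpatientCodeSet,
    apply_cohort_filters,
    classify_patient_diagnosis,
    classify_provider,
    derive_insurance_category,
    identify_outpatient_visits,
    load_taxonomy_mapping,
    read_claims_csv,
    write_claims_csv,
)

from conftest import make_claims


@pytest.fixture(scope="module")
def mapping():
    return load_taxonomy_mapping()


@pytest.fixture(scope="module")
def hierarchy():
    return DiagnosisHierarchy.default()


@pytest.mark.parametrize("code,expected", [
    ("2084P0800X", "psychiatrist"),   # psychiatry
    ("207R00000X", "pcp"),            # internal medicine
    ("103T00000X", "psychologist"),
    ("1041C0700X", "bh_specialist"),  # social worker
    ("", "other"),                    # unmapped by contract
    ("XXXXXXXXXX", "other"),
])
def test_classify_provider(code, expected, mapping):
    assert classify_provider(code, mapping) == expected


class TestDiagnosisClassification:
    def _claims(self, codes):
        return make_claims([
            ("p1", "A", "2016-03-01", "outpatient", [c], "99213", "medicaid")
            for c in codes
        ]) if codes else make_claims([]).reindex(columns=[
            "patient_id", "provider_id", "service_date", "claim_type",
            "dx1", "dx2", "procedure_code", "payer"])

    def test_hierarchy_picks_highest_category(self, hierarchy):
        # depression + schizophrenia codes -> psychotic category wins
        assert classify_patient_diagnosis(
            self._claims(["F32.9", "F20.0"]), hierarchy
        ) == "schizophrenia_psychotic"

    def test_nicotine_only_is_excluded(self, hierarchy):
        assert classify_patient_diagnosis(self._claims(["F17.200"]), hierarchy) is None

    def test_no_codes(self, hierarchy):
        assert classify_patient_diagnosis(self._claims([]), hierarchy) is None

    def test_non_bh_code(self, hierarchy):
        assert classify_patient_diagnosis(self._claims(["I10"]), hierarchy) is None

    def test_malformed_code_skipped(self, hierarchy):
        assert classify_patient_diagnosis(
            self._claims(["??bad", "F41.1"]), hierarchy
        ) == "anxiety_stress"

    def test_order_independent(self, hierarchy, rng):
        codes = ["F32.9", "F10.20", "F41.1", "F31.9", "F90.0"]
        results = set()
        for _ in range(10):
            rng.shuffle(codes)
            results.add(classify_patient_diagnosis(self._claims(codes), hierarchy))
        assert results == {"bipolar"}

    def test_categories_mutually_exclusive(self, hierarchy):
        seen = set()
        for _, prefixes in hierarchy.categories:
            assert not (seen & prefixes)
            seen |= prefixes


@pytest.mark.parametrize("payers,expected", [
    ({"medicaid"}, "medicaid_only"),
    ({"medicare"}, "medicare_only"),
    ({"medicaid", "medicare"}, "dual"),
    ({"commercial"}, "commercial_only"),
    ({"commercial", "medicaid"}, "commercial_plus_public"),
    ({"commercial", "medicare"}, "commercial_plus_public"),
    ({"commercial", "medicaid", "medicare"}, "dual"),
])
def test_insurance_derivation(payers, expected):
    assert derive_insurance_category(payers) == expected


class TestCohortFilters:
    def _setup(self, birth_years, claim_rows):
        patients = pd.DataFrame({
            "patient_id": list(birth_years),
            "birth_year": list(birth_years.values()),
            "sex": "female",
        })
        providers = pd.DataFrame({
            "provider_id": ["A"], "taxonomy_code": ["207R00000X"],
            "specialty_group": ["pcp"],
        })
        claims = make_claims(claim_rows)
        return claims, patients, providers

    def test_too_young_both_years_excluded(self, hierarchy):
        claims, patients, providers = self._setup(
            {"p1": 1999},  # 17 in 2016, 18 in 2017 -> qualifies 2017 only
            [("p1", "A", "2016-05-01", "outpatient", ["F32.9"], "99213", "medicaid")],
        )
        # claims only in 2016, when under-age -> excluded
        _, kept, audit = apply_cohort_filters(claims, patients, providers,
                                              CohortConfig(), hierarchy)
        assert kept.empty and audit["excluded_age"] == 0  # age ok in 2017...
        # ...but no 2017 claims, so the diagnosis criterion fails
        assert audit["excluded_diagnosis"] == 1

    def test_under_18_every_year(self, hierarchy):
        claims, patients, providers = self._setup(
            {"p1": 2001},
            [("p1", "A", "2016-05-01", "outpatient", ["F32.9"], "99213", "medicaid"),
             ("p1", "A", "2017-05-01", "outpatient", ["F32.9"], "99213", "medicaid")],
        )
        _, kept, audit = apply_cohort_filters(claims, patients, providers,
                                              CohortConfig(), hierarchy)
        assert kept.empty and audit["excluded_age"] == 1

    def test_turns_65_excluded(self, hierarchy):
        # 65 at the end of 2016 and 66 at the end of 2017 -> out both years
        claims, patients, providers = self._setup(
            {"p1": 1951},
            [("p1", "A", "2016-05-01", "outpatient", ["F32.9"], "99213", "medicare"),
             ("p1", "A", "2017-05-01", "outpatient", ["F32.9"], "99213", "medicare")],
        )
        _, kept, audit = apply_cohort_filters(claims, patients, providers,
                                              CohortConfig(), hierarchy)
        assert kept.empty and audit["excluded_age"] == 1

    def test_qualifying_second_year_only_retained(self, hierarchy):
        claims, patients, providers = self._setup(
            {"p1": 1999},
            [("p1", "A", "2017-05-01", "outpatient", ["F32.9"], "99213", "medicaid")],
        )
        _, kept, _ = apply_cohort_filters(claims, patients, providers,
                                          CohortConfig(), hierarchy)
        assert list(kept["patient_id"]) == ["p1"]

    def test_missing_birth_year_counted(self, hierarchy):
        claims, patients, providers = self._setup(
            {"p1": np.nan},
            [("p1", "A", "2016-05-01", "outpatient", ["F32.9"], "99213", "medicaid")],
        )
        _, kept, audit = apply_cohort_filters(claims, patients, providers,
                                              CohortConfig(), hierarchy)
        assert kept.empty and audit["missing_birth_year"] == 1

    def test_idempotent(self, hierarchy):
        claims, patients, providers = self._setup(
            {"p1": 1980, "p2": 2005},
            [("p1", "A", "2016-05-01", "outpatient", ["F32.9"], "99213", "medicaid"),
             ("p2", "A", "2016-05-01", "outpatient", ["F32.9"], "99213", "medicaid")],
        )
        c1, p1, _ = apply_cohort_filters(claims, patients, providers,
                                         CohortConfig(), hierarchy)
        c2, p2, _ = apply_cohort_filters(c1, p1, providers, CohortConfig(), hierarchy)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(p1, p2)


class TestOutpatientVisits:
    def test_same_day_same_pair_collapses(self):
        claims = make_claims([
            ("p1", "A", "2016-01-05", "outpatient", ["F32.9"], "99213", "medicaid"),
            ("p1", "A", "2016-01-05", "outpatient", ["F32.9"], "99214", "medicaid"),
        ])
        visits = identify_outpatient_visits(claims, CohortConfig())
        assert len(visits) == 1

    def test_pharmacy_claim_yields_no_visit(self):
        claims = make_claims([
            ("p1", "", "2016-01-05", "pharmacy", [], "", "medicaid"),
        ])
        assert identify_outpatient_visits(claims, CohortConfig()).empty

    def test_distinct_days_all_count(self):
        claims = make_claims([
            ("p1", "A", f"2016-01-0{d}", "outpatient", ["F32.9"], "99213", "medicaid")
            for d in (1, 2, 3)
        ])
        assert len(identify_outpatient_visits(claims, CohortConfig())) == 3

    def test_facility_claim_yields_no_visit(self):
        claims = make_claims([
            ("p1", "", "2016-01-05", "outpatient", ["F32.9"], "99213", "medicaid"),
        ])
        assert identify_outpatient_visits(claims, CohortConfig()).empty

    def test_dedup_bound(self, rng):
        rows = []
        for _ in range(60):
            rows.append((f"p{rng.integers(3)}", f"A{rng.integers(3)}",
                         f"2016-01-{rng.integers(1, 9)}", "outpatient",
                         ["F32.9"], "99213", "medicaid"))
        claims = make_claims(rows)
        visits = identify_outpatient_visits(claims, CohortConfig())
        assert len(visits) <= len(claims)
        assert len(visits) == len(
            claims[["patient_id", "provider_id", "service_date"]].drop_duplicates()
        )


def test_code_set_ranges():
    cs = OutpatientCodeSet(["99201-99499", "0510"])
    assert "99213" in cs and "0510" in cs
    assert "99500" not in cs and "" not in cs and "J1100" not in cs
    with pytest.raises(ValueError):
        OutpatientCodeSet([])


def test_claims_csv_round_trip(tmp_path):
    claims = make_claims([
        ("p1", "A", "2016-01-05", "outpatient", ["F32.9", "F41.1"], "99213", "medicaid"),
        ("p2", "", "2017-06-05", "pharmacy", [], "", "commercial"),
    ])
    path = tmp_path / "claims.csv"
    write_claims_csv(claims, path, header_comment="seed=1")
    back = read_claims_csv(path)
    assert list(back["patient_id"]) == ["p1", "p2"]
    assert back["service_date"].dt.year.tolist() == [2016, 2017]
    assert back.loc[0, "dx2"] == "F41.1" and back.loc[1, "dx1"] == ""
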