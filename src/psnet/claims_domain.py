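"""Domain model for administrative claims: cohort filters, provider and
diagnosis classification, and outpatient-visit identification.

Claims are held as a pandas DataFrame with columns

    patient_id, provider_id, service_date, claim_type, dx1..dxK,
    procedure_code, payer

where ``provider_id`` is empty for facility-only claims and the diagnosis
columns hold ICD-10 code strings (``dx1`` is the principal diagnosis; empty
strings mark unused slots).  Behavioral-health diagnoses are classified
against a six-category hierarchy (psychotic disorders first, substance use
last) so that each patient-year receives at most one, mutually exclusive,
category.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

CLAIM_TYPES = ("inpatient", "outpatient", "pharmacy")
PAYERS = ("medicaid", "medicare", "commercial")
SPECIALTY_GROUPS = ("pcp", "psychiatrist", "psychologist", "bh_specialist", "other")
ANALYTIC_SPECIALTIES = ("pcp", "psychiatrist", "psychologist", "bh_specialist")
INSURANCE_CATEGORIES = (
    "medicaid_only",
    "medicare_only",
    "dual",
    "commercial_only",
    "commercial_plus_public",
)
DIAGNOSIS_CATEGORIES = (
    "schizophrenia_psychotic",
    "bipolar",
    "depression_mood",
    "anxiety_stress",
    "other_mental",
    "substance_use",
)

_ICD10_RE = re.compile(r"^[A-Z]\d\d")


def _dx_columns(claims: pd.DataFrame) -> list[str]:
    return [c for c in claims.columns if re.fullmatch(r"dx\d+", c)]


# ---------------------------------------------------------------------------
# outpatient code set


class OutpatientCodeSet:
    """Set of procedure codes counting as outpatient visits.

    Entries are either literal codes ("99213", "0510") or inclusive numeric
    ranges written "lo-hi" over all-digit CPT codes (the Evaluation and
    Management range is "99201-99499").
    """

    def __init__(self, entries: Iterable[str]):
        self.codes: set[str] = set()
        self.ranges: list[tuple[int, int]] = []
        for entry in entries:
            entry = str(entry).strip()
            if not entry:
                continue
            if "-" in entry:
                lo, hi = entry.split("-", 1)
                self.ranges.append((int(lo), int(hi)))
            else:
                self.codes.add(entry)
        if not self.codes and not self.ranges:
            raise ValueError("outpatient code set must be non-empty")

    def __contains__(self, code: object) -> bool:
        code = str(code).strip()
        if code in self.codes:
            return True
        if code.isdigit():
            value = int(code)
            return any(lo <= value <= hi for lo, hi in self.ranges)
        return False


# ---------------------------------------------------------------------------
# configuration types


@dataclass
class CohortConfig:
    """Cohort and visit rules for the analysis window."""

    study_years: Sequence[int] = (2016, 2017)
    min_age_at_year_start: int = 18
    max_age_at_year_end_exclusive: int = 65
    bh_code_range: tuple[str, str] = ("F01", "F99")
    eligible_specialties: frozenset[str] = frozenset(ANALYTIC_SPECIALTIES)
    outpatient_code_set: OutpatientCodeSet = field(
        default_factory=lambda: OutpatientCodeSet(["99201-99499"])
    )

    def __post_init__(self) -> None:
        if self.min_age_at_year_start >= self.max_age_at_year_end_exclusive:
            raise ValueError("min_age must be below max_age")


@dataclass(frozen=True)
class DiagnosisHierarchy:
    """Ordered, mutually exclusive behavioral-health categories.

    ``categories`` maps category name -> set of ICD-10 prefixes, in priority
    order (a patient with codes in several categories is assigned the first
    match).  Codes starting with any entry of ``exclusions`` (nicotine
    dependence, neonatal abstinence, fetal alcohol) never qualify.
    """

    categories: tuple[tuple[str, frozenset[str]], ...]
    exclusions: frozenset[str]

    def __post_init__(self) -> None:
        if not self.categories or any(not p for _, p in self.categories):
            raise ValueError("every hierarchy category must be non-empty")

    @classmethod
    def from_frame(cls, table: pd.DataFrame) -> "DiagnosisHierarchy":
        """Build from a (category_rank, category_name, icd10_prefix) table.

        Rank 0 rows are exclusion prefixes.
        """
        table = table.copy()
        table["category_rank"] = table["category_rank"].astype(int)
        exclusions = frozenset(
            table.loc[table["category_rank"] == 0, "icd10_prefix"].astype(str)
        )
        cats = []
        ranked = table[table["category_rank"] > 0].sort_values("category_rank")
        for (rank, name), grp in ranked.groupby(
            ["category_rank", "category_name"], sort=True
        ):
            cats.append((str(name), frozenset(grp["icd10_prefix"].astype(str))))
        return cls(categories=tuple(cats), exclusions=exclusions)

    @classmethod
    def from_csv(cls, path) -> "DiagnosisHierarchy":
        return cls.from_frame(pd.read_csv(path, dtype=str))

    @classmethod
    def default(cls) -> "DiagnosisHierarchy":
        with resources.files("psnet.data").joinpath(
            "diagnosis_hierarchy_default.csv"
        ).open() as fh:
            return cls.from_csv(fh)

    def classify_code(self, code: str) -> str | None:
        """Category of one ICD-10 code, or None (non-BH, excluded, malformed)."""
        code = str(code).strip().upper()
        if not code:
            return None
        if not _ICD10_RE.match(code):
            logger.warning("malformed ICD-10 code skipped: %r", code)
            return None
        if any(code.startswith(x) for x in self.exclusions):
            return None
        prefix = code[:3]
        for name, prefixes in self.categories:
            if prefix in prefixes:
                return name
        return None

    def rank_of(self, category: str) -> int:
        for i, (name, _) in enumerate(self.categories, start=1):
            if name == category:
                return i
        raise KeyError(category)


# ---------------------------------------------------------------------------
# provider classification


def load_taxonomy_mapping(path=None) -> dict[str, str]:
    """Two-column (code, group) CSV -> dict; default ships a compact NUCC subset."""
    if path is None:
        with resources.files("psnet.data").joinpath("taxonomy_default.csv").open() as fh:
            table = pd.read_csv(fh, dtype=str)
    else:
        table = pd.read_csv(path, dtype=str)
    mapping = dict(zip(table["code"].str.strip(), table["group"].str.strip()))
    bad = set(mapping.values()) - set(SPECIALTY_GROUPS)
    if bad:
        raise ValueError(f"unknown specialty groups in taxonomy mapping: {bad}")
    return mapping


def classify_provider(taxonomy_code: str, mapping: Mapping[str, str]) -> str:
    """Specialty group for a taxonomy code; unmapped codes fall to 'other'."""
    group = mapping.get(str(taxonomy_code).strip())
    if group is None:
        logger.debug("unmapped taxonomy code %r -> other", taxonomy_code)
        return "other"
    return group


def classify_providers(providers: pd.DataFrame, mapping: Mapping[str, str]) -> pd.DataFrame:
    """Attach a specialty_group column to a providers table (provider_id, taxonomy_code)."""
    out = providers.copy()
    out["specialty_group"] = [
        classify_provider(c, mapping) for c in out["taxonomy_code"].astype(str)
    ]
    return out


# ---------------------------------------------------------------------------
# diagnosis classification


def classify_patient_diagnosis(
    claims_of_patient_year: pd.DataFrame, hierarchy: DiagnosisHierarchy
) -> str | None:
    """Highest-priority category over all diagnosis codes on the given claims.

    All claim types and all diagnosis positions count; order of claims is
    irrelevant.  Returns None when no qualifying behavioral-health code is
    present.
    """
    best: int | None = None
    best_name: str | None = None
    for col in _dx_columns(claims_of_patient_year):
        for code in claims_of_patient_year[col].dropna():
            name = hierarchy.classify_code(code)
            if name is None:
                continue
            rank = hierarchy.rank_of(name)
            if best is None or rank < best:
                best, best_name = rank, name
    return best_name


def classify_patient_year_table(
    claims: pd.DataFrame, hierarchy: DiagnosisHierarchy
) -> pd.DataFrame:
    """Vectorised per-(patient, year) diagnosis categories.

    Returns columns patient_id, year, category for every patient-year with a
    qualifying code.
    """
    dx_cols = _dx_columns(claims)
    if not dx_cols or claims.empty:
        return pd.DataFrame(columns=["patient_id", "year", "category"])
    year = pd.to_datetime(claims["service_date"]).dt.year
    melted = claims[["patient_id"]].assign(year=year)
    pieces = []
    for col in dx_cols:
        piece = melted.assign(code=claims[col].fillna("").astype(str).str.strip().str.upper())
        pieces.append(piece[piece["code"] != ""])
    codes = pd.concat(pieces, ignore_index=True)
    if codes.empty:
        return pd.DataFrame(columns=["patient_id", "year", "category"])
    # map distinct codes once
    uniq = pd.Series(codes["code"].unique())
    ranks = {}
    for code in uniq:
        name = hierarchy.classify_code(code)
        ranks[code] = hierarchy.rank_of(name) if name else 99
    codes["rank"] = codes["code"].map(ranks)
    codes = codes[codes["rank"] < 99]
    if codes.empty:
        return pd.DataFrame(columns=["patient_id", "year", "category"])
    best = codes.groupby(["patient_id", "year"], sort=True)["rank"].min().reset_index()
    names = {i + 1: name for i, (name, _) in enumerate(hierarchy.categories)}
    best["category"] = best["rank"].map(names)
    return best[["patient_id", "year", "category"]]


# ---------------------------------------------------------------------------
# insurance derivation


def derive_insurance_category(payers: Iterable[str]) -> str:
    """Five-way coverage class from the set of payers seen on a patient's claims."""
    observed = set(payers)
    public = {"medicaid", "medicare"} & observed
    if "medicaid" in observed and "medicare" in observed:
        return "dual"
    if "commercial" in observed and public:
        return "commercial_plus_public"
    if observed == {"medicaid"}:
        return "medicaid_only"
    if observed == {"medicare"}:
        return "medicare_only"
    return "commercial_only"


def derive_insurance_table(claims: pd.DataFrame) -> pd.Series:
    """patient_id -> insurance category over the whole window."""
    return claims.groupby("patient_id", sort=True)["payer"].agg(
        lambda s: derive_insurance_category(s)
    )


# ---------------------------------------------------------------------------
# cohort filtering


def apply_cohort_filters(
    claims: pd.DataFrame,
    patients: pd.DataFrame,
    providers: pd.DataFrame,
    config: CohortConfig,
    hierarchy: DiagnosisHierarchy | None = None,
):
    """Retain patients qualifying in at least one study year.

    A patient qualifies in year Y when (a) age at Jan 1 of Y is >=
    ``min_age_at_year_start`` and age at Dec 31 is below
    ``max_age_at_year_end_exclusive``; (b) some claim of theirs in Y carries a
    qualifying behavioral-health diagnosis; and (c) some claim of theirs in Y
    names a provider of an eligible specialty.  Returns (claims, patients,
    audit) where audit counts exclusions per criterion.
    """
    hierarchy = hierarchy or DiagnosisHierarchy.default()
    years = list(config.study_years)

    patients = patients.copy()
    spec = providers.set_index("provider_id")["specialty_group"]

    claims = claims.copy()
    claims["_year"] = pd.to_datetime(claims["service_date"]).dt.year
    claims = claims[claims["_year"].isin(years)]

    missing_by = patients["birth_year"].isna()
    audit: dict[str, int] = {"input_patients": len(patients)}
    audit["missing_birth_year"] = int(missing_by.sum())

    by = patients.set_index("patient_id")["birth_year"]

    dx_table = classify_patient_year_table(claims, hierarchy)
    dx_ok = set(map(tuple, dx_table[["patient_id", "year"]].itertuples(index=False)))

    eligible = claims["provider_id"].fillna("").astype(str).str.len() > 0
    prov_claims = claims[eligible].copy()
    prov_claims["_spec"] = prov_claims["provider_id"].map(spec)
    prov_claims = prov_claims[prov_claims["_spec"].isin(config.eligible_specialties)]
    prov_ok = set(
        map(tuple, prov_claims[["patient_id", "_year"]].drop_duplicates().itertuples(index=False))
    )

    def qualifies(pid: str) -> tuple[bool, str]:
        b = by.get(pid)
        if pd.isna(b):
            return False, "missing_birth_year"
        fail = "age"
        for year in years:
            age_start = year - int(b)
            age_end = year - int(b)  # year arithmetic: age at Dec 31 of the same year
            if age_start < config.min_age_at_year_start:
                continue
            if age_end >= config.max_age_at_year_end_exclusive:
                continue
            fail = "diagnosis" if fail == "age" else fail
            if (pid, year) not in dx_ok:
                continue
            fail = "provider_type"
            if (pid, year) in prov_ok:
                return True, ""
        return False, fail

    verdicts = {pid: qualifies(pid) for pid in patients["patient_id"]}
    keep = {pid for pid, (ok, _) in verdicts.items() if ok}
    for reason in ("age", "diagnosis", "provider_type"):
        audit[f"excluded_{reason}"] = sum(
            1 for ok, why in verdicts.values() if not ok and why == reason
        )
    audit["retained_patients"] = len(keep)

    patients_out = patients[patients["patient_id"].isin(keep)].reset_index(drop=True)
    claims_out = (
        claims[claims["patient_id"].isin(keep)].drop(columns=["_year"]).reset_index(drop=True)
    )
    audit["retained_claims"] = len(claims_out)
    logger.info("cohort filter audit: %s", audit)
    return claims_out, patients_out, audit


# ---------------------------------------------------------------------------
# outpatient visits


def identify_outpatient_visits(claims: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """One visit per unique (patient, provider, day) among E&M-coded claims.

    Facility-only claims (empty provider id) never produce visits; several
    claims by one provider for one patient on one day collapse to one visit.
    Returns columns patient_id, provider_id, date, year.
    """
    has_provider = claims["provider_id"].fillna("").astype(str).str.len() > 0
    in_set = claims["procedure_code"].fillna("").astype(str).map(
        lambda c: c in config.outpatient_code_set
    )
    visits = claims.loc[has_provider & in_set, ["patient_id", "provider_id", "service_date"]]
    visits = visits.rename(columns={"service_date": "date"}).copy()
    visits["date"] = pd.to_datetime(visits["date"])
    visits = visits.drop_duplicates(["patient_id", "provider_id", "date"])
    visits["year"] = visits["date"].dt.year
    return visits.sort_values(["patient_id", "provider_id", "date"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# claims I/O


def read_claims_csv(path) -> pd.DataFrame:
    """Read the claims CSV dialect (gzip-transparent)."""
    claims = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    claims["service_date"] = pd.to_datetime(claims["service_date"])
    return claims


def write_claims_csv(claims: pd.DataFrame, path, header_comment: str | None = None) -> None:
    out = claims.copy()
    out["service_date"] = pd.to_datetime(out["service_date"]).dt.strftime("%Y-%m-%d")
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out.to_csv(fh, index=False)
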