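"""Synthetic administrative-claims generator with planted hierarchical
provider-community structure.

The generator emulates the structure of a two-year all-payer claims extract
for adults with mental illness: thousands of individual providers of four
specialty types organised into planted communities and nested
sub-communities, and patients whose outpatient visits concentrate on a small
personal set of providers inside their home sub-community.  Three dials
matter downstream:

* ``p_within_sub`` / ``p_within_com`` control how local provider choice is
  (driving the assortativity the community detector must recover),
* ``concentration`` sharpens each patient's personal provider weights
  (driving the Bice-Boxerman continuity index), and
* within every pool providers are chosen with Zipf-like popularity weights,
  so that busy providers share enough patients to clear the edge threshold
  and form a connected network core, as in real claims data where patient
  volume is highly skewed.

Ground truth (planted community, sub-community, specialty, diagnosis
category, insurance) is returned alongside the claims so every downstream
stage can be tested without external data.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .claims_domain import (
    DIAGNOSIS_CATEGORIES,
    INSURANCE_CATEGORIES,
    write_claims_csv,
)

logger = logging.getLogger(__name__)

# marginal composition defaults follow the published Colorado cohort tables
_SPECIALTY_MIX = {
    "pcp": 3833 / 8256,
    "psychiatrist": 823 / 8256,
    "psychologist": 498 / 8256,
    "bh_specialist": 3102 / 8256,
}
_DIAGNOSIS_PROBS = {
    "schizophrenia_psychotic": 29887 / 476802,
    "bipolar": 38984 / 476802,
    "depression_mood": 205378 / 476802,
    "anxiety_stress": 146790 / 476802,
    "other_mental": 37031 / 476802,
    "substance_use": 18732 / 476802,
}
_INSURANCE_PROBS = {
    "medicaid_only": 161843 / 476802,
    "medicare_only": 21698 / 476802,
    "dual": 42514 / 476802,
    "commercial_only": 223103 / 476802,
    "commercial_plus_public": 27644 / 476802,
}

_DX_CODES = {
    "schizophrenia_psychotic": ["F20.9", "F25.0", "F29"],
    "bipolar": ["F31.9", "F31.81", "F30.2"],
    "depression_mood": ["F32.9", "F33.1", "F34.1"],
    "anxiety_stress": ["F41.1", "F41.9", "F43.10"],
    "other_mental": ["F90.0", "F84.0", "F60.3"],
    "substance_use": ["F10.20", "F11.20", "F19.10"],
}
_EXCLUDED_DX = "F17.200"  # nicotine dependence: never qualifies

_TAXONOMY_BY_GROUP = {
    "pcp": ["207Q00000X", "207R00000X", "208D00000X", "363L00000X"],
    "psychiatrist": ["2084P0800X", "2084P0804X"],
    "psychologist": ["103T00000X", "103TC0700X"],
    "bh_specialist": ["1041C0700X", "101YM0800X", "101Y00000X"],
}

_EM_CODES = np.array(["99203", "99212", "99213", "99214", "99215"])
_EM_PROBS = np.array([0.10, 0.25, 0.35, 0.20, 0.10])


@dataclass
class CocModelParams:
    """Coefficients for planting provider-level continuity outcomes."""

    intercept: float = 0.25
    beta_transitivity: float = -0.011
    beta_n_patients: float = 0.0000060
    beta_specialty: dict = field(default_factory=lambda: {
        "pcp": 0.0, "bh_specialist": 0.061, "psychiatrist": 0.027,
        "psychologist": 0.034,
    })
    beta_alter_coc: float = 0.0
    sigma_u: float = 0.05
    sigma_e: float = 0.10


@dataclass
class SimConfig:
    """Generator configuration; defaults give the two-year desk-scale study
    conditions (5 communities x 5 sub-communities x 80 providers = 2,000
    providers; 20,000 patients)."""

    seed: int = 42
    n_communities: int = 5
    subcommunities_per_community: int = 5
    providers_per_subcommunity: int = 80
    n_patients: int = 20_000
    study_years: tuple[int, ...] = (2016, 2017)
    specialty_mix: dict = field(default_factory=lambda: dict(_SPECIALTY_MIX))
    diagnosis_probs: dict = field(default_factory=lambda: dict(_DIAGNOSIS_PROBS))
    insurance_probs: dict = field(default_factory=lambda: dict(_INSURANCE_PROBS))
    sex_probs: dict = field(default_factory=lambda: {
        "female": 0.620, "male": 0.379, "missing": 0.001,
    })
    p_within_sub: float = 0.80
    p_within_com: float = 0.90
    visits_per_patient_year: float = 6.0
    visits_dispersion: float = 2.0  # negative-binomial shape; smaller = more spread
    concentration: float = 1.5  # Zipf exponent of the personal weight vector
    personal_set_size: int = 4
    provider_popularity_exponent: float = 0.8
    p_age_out_of_range: float = 0.03
    p_excluded_dx_only: float = 0.01
    pharmacy_mean: float = 1.0  # background pharmacy claims per patient-year
    facility_prob: float = 0.5  # chance of one facility claim per patient-year
    coc_model_params: CocModelParams | None = None

    def __post_init__(self) -> None:
        for name in ("specialty_mix", "diagnosis_probs", "insurance_probs", "sex_probs"):
            probs = getattr(self, name)
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        for name in ("n_communities", "subcommunities_per_community",
                     "providers_per_subcommunity", "n_patients"):
            if getattr(self, name) < 0 or (name != "n_patients" and getattr(self, name) < 1):
                raise ValueError(f"{name} must be positive")
        if self.personal_set_size > self.providers_per_subcommunity:
            raise ValueError("personal_set_size exceeds providers per sub-community")
        if not (0 <= self.p_within_sub <= 1 and 0 <= self.p_within_com <= 1):
            raise ValueError("locality probabilities must lie in [0, 1]")

    @property
    def n_providers(self) -> int:
        return (self.n_communities * self.subcommunities_per_community
                * self.providers_per_subcommunity)

    def config_hash(self) -> str:
        payload = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class GroundTruth:
    """Planted labels for every generated provider and patient."""

    providers: pd.DataFrame  # provider_id, community, subcommunity, specialty_group
    patients: pd.DataFrame   # patient_id, home_subcommunity, diagnosis_category, insurance_category


def _choice(rng: np.random.Generator, table: dict, size: int) -> np.ndarray:
    keys = np.array(list(table.keys()))
    probs = np.array(list(table.values()), dtype=float)
    return rng.choice(keys, size=size, p=probs / probs.sum())


def _personal_weights(m: int, concentration: float) -> np.ndarray:
    if np.isinf(concentration):
        w = np.zeros(m)
        w[0] = 1.0
        return w
    w = np.arange(1, m + 1, dtype=float) ** (-concentration)
    return w / w.sum()


def generate_claims(config: SimConfig):
    """Generate a full synthetic dataset.

    Returns (claims, patients, providers, truth): claims in the standard CSV
    dialect columns, a patient demographics table, a provider table with
    taxonomy codes, and the planted GroundTruth.  Byte-identical output for
    identical configuration (including seed).
    """
    rng = np.random.default_rng(config.seed)
    years = list(config.study_years)

    # ---- providers -------------------------------------------------------
    n_sub_total = config.n_communities * config.subcommunities_per_community
    n_prov = config.n_providers
    width = max(5, len(str(n_prov)))
    provider_ids = np.array([f"D{i:0{width}d}" for i in range(1, n_prov + 1)])
    sub_index = np.repeat(np.arange(n_sub_total), config.providers_per_subcommunity)
    com_index = sub_index // config.subcommunities_per_community
    com_labels = np.array([f"c{i + 1}" for i in range(config.n_communities)])
    sub_labels = np.array([
        f"c{s // config.subcommunities_per_community + 1}"
        f".s{s % config.subcommunities_per_community + 1}"
        for s in range(n_sub_total)
    ])
    specialty = _choice(rng, config.specialty_mix, n_prov)
    taxonomy = np.array([
        _TAXONOMY_BY_GROUP[g][rng.integers(len(_TAXONOMY_BY_GROUP[g]))]
        for g in specialty
    ])
    # Zipf-like popularity within each sub-community (rank by provider index)
    rank_in_sub = np.arange(n_prov) % config.providers_per_subcommunity + 1
    popularity = rank_in_sub.astype(float) ** (-config.provider_popularity_exponent)

    providers = pd.DataFrame({
        "provider_id": provider_ids,
        "taxonomy_code": taxonomy,
    })
    truth_providers = pd.DataFrame({
        "provider_id": provider_ids,
        "community": com_labels[com_index],
        "subcommunity": sub_labels[sub_index],
        "specialty_group": specialty,
    })

    # ---- patients --------------------------------------------------------
    n_pat = config.n_patients
    pwidth = max(6, len(str(n_pat)))
    patient_ids = np.array([f"M{i:0{pwidth}d}" for i in range(1, n_pat + 1)])
    home_sub = rng.integers(0, n_sub_total, size=n_pat) if n_sub_total else np.zeros(n_pat, int)
    home_com = home_sub // config.subcommunities_per_community

    base_year = min(years) if years else 2016
    birth_year = rng.integers(base_year - 64, base_year - 18 + 1, size=n_pat)
    out_of_range = rng.random(n_pat) < config.p_age_out_of_range
    young = rng.random(n_pat) < 0.5
    birth_year = np.where(out_of_range & young,
                          rng.integers(base_year - 17, base_year - 10, size=n_pat),
                          birth_year)
    birth_year = np.where(out_of_range & ~young,
                          rng.integers(base_year - 75, base_year - 65, size=n_pat),
                          birth_year)

    sex = _choice(rng, config.sex_probs, n_pat)
    category = _choice(rng, config.diagnosis_probs, n_pat)
    excluded_only = rng.random(n_pat) < config.p_excluded_dx_only
    category = np.where(excluded_only, "none", category)
    insurance = _choice(rng, config.insurance_probs, n_pat)

    patients = pd.DataFrame({
        "patient_id": patient_ids,
        "birth_year": birth_year,
        "sex": sex,
    })
    truth_patients = pd.DataFrame({
        "patient_id": patient_ids,
        "home_subcommunity": sub_labels[home_sub] if n_sub_total else "",
        "diagnosis_category": category,
        "insurance_category": insurance,
    })

    if n_pat == 0 or n_prov == 0:
        claims = _empty_claims()
        return claims, patients, providers, GroundTruth(truth_providers, truth_patients)

    # ---- personal provider sets (Gumbel top-k weighted sampling) ---------
    m = config.personal_set_size
    personal = np.empty((n_pat, m), dtype=int)
    for s in range(n_sub_total):
        pat_idx = np.flatnonzero(home_sub == s)
        if pat_idx.size == 0:
            continue
        prov_idx = np.flatnonzero(sub_index == s)
        logw = np.log(popularity[prov_idx])
        keys = logw[None, :] + rng.gumbel(size=(pat_idx.size, prov_idx.size))
        top = np.argsort(-keys, axis=1)[:, :m]
        personal[pat_idx] = prov_idx[top]

    personal_w = _personal_weights(m, config.concentration)
    personal_cum = np.cumsum(personal_w)

    # per-community and global popularity tables for out-of-pool visits
    com_prov = [np.flatnonzero(com_index == c) for c in range(config.n_communities)]
    com_cum = []
    for idx in com_prov:
        w = popularity[idx]
        com_cum.append(np.cumsum(w / w.sum()))
    gw = popularity / popularity.sum()
    global_cum = np.cumsum(gw)

    # ---- outpatient visits ----------------------------------------------
    frames = []
    r = config.visits_dispersion
    p_nb = r / (r + config.visits_per_patient_year)
    for year in years:
        counts = rng.negative_binomial(r, p_nb, size=n_pat)
        pat_rep = np.repeat(np.arange(n_pat), counts)
        total = pat_rep.size
        u_pool = rng.random(total)
        pool = np.where(u_pool < config.p_within_sub, 0,
                        np.where(rng.random(total) < config.p_within_com, 1, 2))
        prov = np.empty(total, dtype=int)

        mask = pool == 0
        ranks = np.searchsorted(personal_cum, rng.random(mask.sum()))
        prov[mask] = personal[pat_rep[mask], ranks]

        mask = pool == 1
        coms = home_com[pat_rep[mask]]
        draws = rng.random(mask.sum())
        sel = np.empty(mask.sum(), dtype=int)
        for c in range(config.n_communities):
            cmask = coms == c
            if cmask.any():
                sel[cmask] = com_prov[c][np.searchsorted(com_cum[c], draws[cmask])]
        prov[mask] = sel

        mask = pool == 2
        prov[mask] = np.searchsorted(global_cum, rng.random(mask.sum()))

        days = rng.integers(0, 365, size=total)
        dates = np.datetime64(f"{year}-01-01") + days.astype("timedelta64[D]")
        codes = rng.choice(_EM_CODES, size=total, p=_EM_PROBS)
        frames.append(pd.DataFrame({
            "patient_id": patient_ids[pat_rep],
            "provider_id": provider_ids[prov],
            "service_date": dates,
            "claim_type": "outpatient",
            "procedure_code": codes,
            "_pat": pat_rep,
        }))

    # ---- background pharmacy and facility claims -------------------------
    for year in years:
        ph_counts = rng.poisson(config.pharmacy_mean, size=n_pat)
        pat_rep = np.repeat(np.arange(n_pat), ph_counts)
        days = rng.integers(0, 365, size=pat_rep.size)
        frames.append(pd.DataFrame({
            "patient_id": patient_ids[pat_rep],
            "provider_id": "",
            "service_date": np.datetime64(f"{year}-01-01") + days.astype("timedelta64[D]"),
            "claim_type": "pharmacy",
            "procedure_code": "",
            "_pat": pat_rep,
        }))
        fac = np.flatnonzero(rng.random(n_pat) < config.facility_prob)
        days = rng.integers(0, 365, size=fac.size)
        frames.append(pd.DataFrame({
            "patient_id": patient_ids[fac],
            "provider_id": "",
            "service_date": np.datetime64(f"{year}-01-01") + days.astype("timedelta64[D]"),
            "claim_type": "outpatient",
            "procedure_code": "0510",  # clinic revenue code, outside the E&M range
            "_pat": fac,
        }))

    claims = pd.concat(frames, ignore_index=True)

    # ---- diagnoses -------------------------------------------------------
    cat_primary = {}
    for cat, codes in _DX_CODES.items():
        cat_primary[cat] = codes
    cat_primary["none"] = [_EXCLUDED_DX]
    pat_cat = category  # per patient index
    dx_choice = rng.integers(0, 3, size=len(claims))
    dx1 = np.array([
        cat_primary[pat_cat[p]][dx_choice[i] % len(cat_primary[pat_cat[p]])]
        for i, p in enumerate(claims["_pat"])
    ])
    dx1 = np.where(claims["claim_type"].to_numpy() == "pharmacy", "", dx1)
    has_secondary = rng.random(len(claims)) < 0.3
    dx2_choice = rng.integers(0, 3, size=len(claims))
    dx2 = np.array([
        cat_primary[pat_cat[p]][dx2_choice[i] % len(cat_primary[pat_cat[p]])]
        if has_secondary[i] else ""
        for i, p in enumerate(claims["_pat"])
    ])
    dx2 = np.where(dx1 == "", "", dx2)
    claims["dx1"] = dx1
    claims["dx2"] = dx2

    # ---- payers (deterministic alternation inside mixed categories) ------
    claims = claims.sort_values(
        ["patient_id", "service_date", "claim_type", "provider_id", "procedure_code"],
        kind="mergesort",
    ).reset_index(drop=True)
    seq = claims.groupby("patient_id").cumcount().to_numpy()
    ins = insurance[claims["_pat"].to_numpy()]
    payer = np.select(
        [
            ins == "medicaid_only",
            ins == "medicare_only",
            ins == "commercial_only",
            (ins == "dual") & (seq % 2 == 0),
            (ins == "dual") & (seq % 2 == 1),
            (ins == "commercial_plus_public") & (seq % 2 == 0),
            (ins == "commercial_plus_public") & (seq % 2 == 1),
        ],
        ["medicaid", "medicare", "commercial", "medicaid", "medicare",
         "commercial", "medicaid"],
        default="commercial",
    )
    claims["payer"] = payer
    claims = claims.drop(columns=["_pat"])
    claims = claims[[
        "patient_id", "provider_id", "service_date", "claim_type",
        "dx1", "dx2", "procedure_code", "payer",
    ]]
    logger.info("generated %d claims for %d patients / %d providers",
                len(claims), n_pat, n_prov)
    return claims, patients, providers, GroundTruth(truth_providers, truth_patients)


def _empty_claims() -> pd.DataFrame:
    return pd.DataFrame(columns=[
        "patient_id", "provider_id", "service_date", "claim_type",
        "dx1", "dx2", "procedure_code", "payer",
    ])


def write_dataset(outdir, config: SimConfig) -> dict:
    """Generate and write claims/patients/providers/ground-truth CSVs plus a
    manifest recording the seed and configuration hash."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    claims, patients, providers, truth = generate_claims(config)
    stamp = f"seed={config.seed} config_hash={config.config_hash()}"
    write_claims_csv(claims, outdir / "claims.csv", header_comment=stamp)
    patients.to_csv(outdir / "patients.csv", index=False)
    providers.to_csv(outdir / "providers.csv", index=False)
    truth.providers.to_csv(outdir / "truth_providers.csv", index=False)
    truth.patients.to_csv(outdir / "truth_patients.csv", index=False)
    manifest = {"seed": config.seed, "config_hash": config.config_hash(),
                "n_claims": len(claims), "n_patients": len(patients),
                "n_providers": len(providers)}
    with open(outdir / "manifest.txt", "w") as fh:
        for k, v in sorted(manifest.items()):
            fh.write(f"{k}={v}\n")
    return manifest


# ---------------------------------------------------------------------------
# direct provider-profile simulation for model-recovery testing


def simulate_provider_profiles(
    n_communities: int,
    providers_per_community: int,
    seed: int | np.random.Generator = 0,
    alter_from_transitivity: tuple[float, float, float] | None = None,
) -> pd.DataFrame:
    """Provider-level covariate table decoupled from the claims generator.

    Transitivity is Beta-distributed around the observed 0.6 average, patient
    counts are skewed lognormal, specialties follow the default mix.  When
    ``alter_from_transitivity`` = (a0, a1, sd) is given, alter CoC is drawn
    as a0 + a1*T + Normal(0, sd), planting a path from transitivity through
    the neighbourhood average.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = n_communities * providers_per_community
    community = np.repeat([f"c{i + 1}" for i in range(n_communities)],
                          providers_per_community)
    transitivity = rng.beta(6, 4, size=n)
    n_patients = np.maximum(1, rng.lognormal(mean=4.5, sigma=0.9, size=n)).astype(int)
    specialty = _choice(rng, _SPECIALTY_MIX, n)
    if alter_from_transitivity is not None:
        a0, a1, sd = alter_from_transitivity
        alter = a0 + a1 * transitivity + rng.normal(0, sd, size=n)
    else:
        alter = np.clip(rng.normal(0.30, 0.05, size=n), 0, 1)
    return pd.DataFrame({
        "provider_id": [f"D{i:05d}" for i in range(1, n + 1)],
        "community": community,
        "specialty_group": specialty,
        "transitivity": transitivity,
        "n_patients": n_patients,
        "alter_mean_coc": alter,
    })


def plant_coc_outcome(
    profiles: pd.DataFrame,
    params: CocModelParams,
    seed: int | np.random.Generator = 0,
    clip: bool = True,
) -> tuple[pd.Series, float]:
    """Provider-level CoC from the linear random-intercept model.

    CoC = I + b_T*T + b_P*P + b_S[specialty] + b_A*A_CoC + u_community + e,
    with u ~ N(0, sigma_u^2), e ~ N(0, sigma_e^2), clipped to [0, 1] when
    ``clip`` is set (disable it to simulate from the exact linear model, e.g.
    for estimator-recovery studies where censoring would distort coverage).
    Returns (coc, clipped_fraction).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    communities = sorted(profiles["community"].unique())
    u = dict(zip(communities, rng.normal(0, params.sigma_u, size=len(communities))))
    e = rng.normal(0, params.sigma_e, size=len(profiles))
    lin = (
        params.intercept
        + params.beta_transitivity * profiles["transitivity"].to_numpy()
        + params.beta_n_patients * profiles["n_patients"].to_numpy()
        + profiles["specialty_group"].map(params.beta_specialty).to_numpy()
        + params.beta_alter_coc * profiles["alter_mean_coc"].to_numpy()
        + profiles["community"].map(u).to_numpy()
        + e
    )
    if not clip:
        return pd.Series(lin, index=profiles.index, name="mean_coc"), 0.0
    clipped = np.clip(lin, 0.0, 1.0)
    frac = float(np.mean(clipped != lin))
    if frac > 0:
        logger.info("plant_coc_outcome: %.2f%% of outcomes clipped to [0,1]", 100 * frac)
    return pd.Series(clipped, index=profiles.index, name="mean_coc"), frac
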