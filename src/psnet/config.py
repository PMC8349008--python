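"""Flat key=value pipeline configuration.

Every default equals the study's analytic setting out of the box: edge
threshold 3 shared patients, 10-provider minimum community size, 4-visit
minimum for the continuity index, F01-F99 qualifying range, 18/65 age
bounds, study years 2016-2017.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

from .claims_domain import CohortConfig, OutpatientCodeSet


@dataclass
class PipelineConfig:
    claims_path: str = ""
    taxonomy_path: str = ""   # empty -> packaged default mapping
    hierarchy_path: str = ""  # empty -> packaged default hierarchy
    patients_path: str = ""
    providers_path: str = ""
    output_dir: str = "psnet_output"
    study_years: tuple[int, ...] = (2016, 2017)
    min_age: int = 18
    max_age: int = 65
    outpatient_codes: tuple[str, ...] = ("99201-99499",)
    min_shared: int = 3
    edge_source: str = "all_claims"
    min_community_size: int = 10
    min_visits: int = 4
    model_grouping: str = "community"
    include_model1: bool = True
    include_model2: bool = True
    seed: int = 0

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            study_years=self.study_years,
            min_age_at_year_start=self.min_age,
            max_age_at_year_end_exclusive=self.max_age,
            outpatient_code_set=OutpatientCodeSet(self.outpatient_codes),
        )

    def config_hash(self) -> str:
        # hash covers inputs and analytic settings, not the output location
        items = {k: v for k, v in self.__dict__.items() if k != "output_dir"}
        payload = repr(sorted(items.items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


_KEY_MAP = {
    "paths.claims": ("claims_path", str),
    "paths.patients": ("patients_path", str),
    "paths.providers": ("providers_path", str),
    "paths.taxonomy": ("taxonomy_path", str),
    "paths.hierarchy": ("hierarchy_path", str),
    "paths.output": ("output_dir", str),
    "cohort.years": ("study_years", lambda v: tuple(int(y) for y in v.split(","))),
    "cohort.min_age": ("min_age", int),
    "cohort.max_age": ("max_age", int),
    "cohort.outpatient_codes": ("outpatient_codes", lambda v: tuple(v.split(","))),
    "network.min_shared": ("min_shared", int),
    "network.edge_source": ("edge_source", str),
    "community.min_size": ("min_community_size", int),
    "coc.min_visits": ("min_visits", int),
    "model.grouping": ("model_grouping", str),
    "model.include_model1": ("include_model1", lambda v: v.lower() in ("1", "true", "yes")),
    "model.include_model2": ("include_model2", lambda v: v.lower() in ("1", "true", "yes")),
    "seed": ("seed", int),
}


def load_config(path, overrides: dict | None = None) -> PipelineConfig:
    """Parse a flat key=value file (``#`` comments allowed); ``overrides``
    maps the same namespaced keys to string values."""
    cfg = PipelineConfig()
    entries: dict[str, str] = {}
    if path:
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            key, value = line.split("=", 1)
            entries[key.strip()] = value.strip()
    entries.update(overrides or {})
    for key, value in entries.items():
        if key not in _KEY_MAP:
            raise ValueError(f"unknown config key: {key!r}")
        attr, conv = _KEY_MAP[key]
        setattr(cfg, attr, conv(value))
    return cfg


def dump_config(cfg: PipelineConfig) -> str:
    inverse = {attr: key for key, (attr, _) in _KEY_MAP.items()}
    lines = []
    for attr, key in sorted(inverse.items(), key=lambda kv: kv[1]):
        value = getattr(cfg, attr)
        if isinstance(value, tuple):
            value = ",".join(str(v) for v in value)
        lines.append(f"{key}={value}")
    return "\n".join(lines) + "\n"
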