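"""Delimited-table readers/writers and run configuration.

All pipeline inputs are plain delimited text (CSV/TSV, auto-sniffed):

* sites:     name, latitude, longitude, utc_base_offset, dst_offset, dst_rule
* patients:  patient_id, site_name, clinical covariates, course fields,
             CTCAE grade columns
* fractions: patient_id, site_name, date (ISO-8601), local_time (HH:MM or
             decimal hours), optional utc_offset
* genotypes: patient_id plus one dosage column per rsid

``RunConfig`` mirrors the CLI flags; a YAML config file provides the same
keys, with CLI values taking precedence.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .solar import GeoSite

__all__ = [
    "RunConfig",
    "read_sites",
    "read_table",
    "write_table",
    "load_config",
    "provenance",
]

REQUIRED_PATIENT_COLS = ("patient_id", "site_name", "bmi", "n_fractions", "dose_per_fraction")
REQUIRED_FRACTION_COLS = ("patient_id", "site_name", "date", "local_time")


@dataclass
class RunConfig:
    """One analysis run: inputs, endpoint, time handling, CV and seeding."""

    patients: str | None = None
    fractions: str | None = None
    sites: str | None = None
    genotypes: str | None = None
    endpoint: str = "atrophy"
    alpha_beta: float | None = None  # default 10 Gy acute / 3 Gy late
    time_origin: float | None = None  # fixed origin; None -> AIC scan
    scan_grid_step: float = 0.5
    snps: tuple[str, ...] = ()
    cv_folds: int = 4
    cv_repeats: int = 100
    sensitivity: bool = False
    seed: int = 0
    outdir: str = "chronotox_results"


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus CLI overrides."""
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        values.update(loaded)
    for k, v in overrides.items():
        if v is not None:
            values[k] = v
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "snps" in values and values["snps"] is not None:
        values["snps"] = tuple(values["snps"])
    return RunConfig(**values)


def read_table(path: str | Path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index)


def read_sites(path: str | Path) -> dict[str, GeoSite]:
    df = read_table(path, ("name", "latitude", "longitude", "utc_base_offset"))
    sites = {}
    for _, r in df.iterrows():
        sites[r["name"]] = GeoSite(
            name=r["name"],
            latitude=float(r["latitude"]),
            longitude=float(r["longitude"]),
            utc_base_offset=float(r["utc_base_offset"]),
            dst_offset=float(r.get("dst_offset", 1.0)),
            dst_rule=str(r.get("dst_rule", "eu")),
        )
    return sites


def provenance(config: RunConfig, exclusions: dict, extra: dict | None = None) -> dict:
    """Machine-readable run record: config hash, seed, exclusion counts."""
    cfg = dataclasses.asdict(config)
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    rec = {
        "config": cfg,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": config.seed,
        "exclusions": exclusions,
    }
    if extra:
        rec.update(extra)
    return rec
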