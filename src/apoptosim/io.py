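"""CSV schemas and configuration loading.

Column contracts for the pipeline's interchange files, light validation on
read, and YAML configuration for kinetic parameters / simulation settings
with a logged, hashable resolved-parameter record.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from .model import ClassificationRule, KineticParameters, SimulationSettings

logger = logging.getLogger("apoptosim")

DENSITOMETRY_COLUMNS = ["sample_id", "batch_id", "protein",
                        "band_intensity", "actin_intensity"]
STANDARDS_COLUMNS = ["protein", "normalized_intensity", "known_concentration_uM"]
PROFILE_COLUMNS = ["sample_id", "history", "apaf1_uM", "pc3_uM", "pc9_uM",
                   "smac_uM", "xiap_uM"]
SIMULATION_COLUMNS = ["sample_id", "sc_at_15min_percent", "apoptosis_class"]
CLINICAL_COLUMNS = ["sample_id", "pfs_months", "event"]


class SchemaError(ValueError):
    pass


def _read(path, required: list[str], name: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} file {path} is missing columns {missing}")
    return df


def read_densitometry(path) -> pd.DataFrame:
    return _read(path, DENSITOMETRY_COLUMNS, "densitometry")


def read_standards(path) -> pd.DataFrame:
    return _read(path, STANDARDS_COLUMNS, "standards")


def read_profiles(path) -> pd.DataFrame:
    df = _read(path, PROFILE_COLUMNS, "profiles")
    conc = df[[c for c in PROFILE_COLUMNS if c.endswith("_uM")]]
    if (conc < 0).any().any() or not conc.map(lambda v: pd.notna(v)).all().all():
        raise SchemaError(f"profiles file {path} has negative or missing concentrations")
    return df


def read_simulations(path) -> pd.DataFrame:
    return _read(path, SIMULATION_COLUMNS, "simulations")


def read_clinical(path) -> pd.DataFrame:
    df = _read(path, CLINICAL_COLUMNS, "clinical")
    if (df["pfs_months"] <= 0).any():
        raise SchemaError(f"clinical file {path}: pfs_months must be > 0")
    return df


def load_config(path=None) -> tuple[KineticParameters, SimulationSettings, ClassificationRule]:
    """Resolve kinetics/settings/threshold from a YAML file (all optional).

    Logs the fully resolved parameter set and a short content hash so every
    run records exactly which constants it used.
    """
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    params = KineticParameters(**raw.get("kinetics", {}))
    settings = SimulationSettings(**raw.get("settings", {}))
    rule = ClassificationRule(**raw.get("classification", {}))
    resolved = {
        "kinetics": params.as_dict(),
        "settings": {"t_end": settings.t_end, "readout_time": settings.readout_time,
                     "rtol": settings.rtol, "atol": settings.atol,
                     "grid_dt": settings.grid_dt},
        "classification": {"threshold": rule.threshold,
                           "readout_time": rule.readout_time},
    }
    blob = json.dumps(resolved, sort_keys=True)
    digest = hashlib.sha256(blob.encode()).hexdigest()[:12]
    logger.info("resolved configuration (hash %s): %s", digest, blob)
    return params, settings, rule
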