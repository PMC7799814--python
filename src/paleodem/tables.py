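"""Readers for date, site-phase and survey tables (CSV or XLSX).

Column names are normalized case-insensitively and a few common aliases are
accepted (e.g. ``CRA``/``C14Age`` for the ¹⁴C age, ``SD``/``C14SD`` for the
lab error), so supplementary tables exported from spreadsheets load without
manual renaming.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import SchemaError

_DATE_ALIASES = {
    "labid": "lab_id",
    "lab_code": "lab_id",
    "siteid": "site_id",
    "sitename": "site_id",
    "site": "site_id",
    "c14age": "cra",
    "c14_age": "cra",
    "bp": "cra",
    "age": "cra",
    "c14sd": "error",
    "sd": "error",
    "std": "error",
    "longitude": "lon",
    "latitude": "lat",
    "material": "material_class",
}

_PHASE_ALIASES = {
    "siteid": "site_id",
    "site": "site_id",
    "surveyid": "survey_id",
    "survey": "survey_id",
    "start_bp": "start",
    "end_bp": "end",
    "phase_start": "start",
    "phase_end": "end",
    "area": "area_ha",
    "size_ha": "area_ha",
    "longitude": "lon",
    "latitude": "lat",
}

_SURVEY_ALIASES = {
    "surveyid": "survey_id",
    "survey": "survey_id",
    "area": "area_km2",
    "size_km2": "area_km2",
}


def _read_any(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    return pd.read_csv(path)


def _normalize(df: pd.DataFrame, aliases: dict) -> pd.DataFrame:
    cols = {}
    for c in df.columns:
        key = str(c).strip().lower().replace(" ", "_")
        cols[c] = aliases.get(key, key)
    return df.rename(columns=cols)


def load_dates(path, required=("lab_id", "site_id", "cra", "error")) -> pd.DataFrame:
    """Load a radiocarbon-date table from CSV or XLSX."""
    df = _normalize(_read_any(path), _DATE_ALIASES)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: date table missing columns {missing}")
    return df


def load_phases(path, required=("site_id", "start", "end")) -> pd.DataFrame:
    """Load a site-phase table from CSV or XLSX."""
    df = _normalize(_read_any(path), _PHASE_ALIASES)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: phase table missing columns {missing}")
    return df


def load_surveys(path, required=("survey_id", "area_km2")) -> pd.DataFrame:
    """Load a survey-area table from CSV or XLSX."""
    df = _normalize(_read_any(path), _SURVEY_ALIASES)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: survey table missing columns {missing}")
    return df
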