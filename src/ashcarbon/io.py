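"""Table readers/writers and YAML configuration.

Plain-text TSV (CSV accepted by extension) is the interchange format at
this scale. Readers validate schemas eagerly and raise
:class:`ValidationError` naming the offending column, so pipeline failures
are diagnosable from the message alone.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from .core import EndMembers, TreatmentSpec

__all__ = [
    "ValidationError",
    "read_table",
    "read_titrations",
    "read_pools",
    "read_deltas",
    "load_config",
]

TITRATION_COLUMNS = ["treatment", "replicate", "day", "hcl_conc", "v_sample", "v_blank", "soil_mass"]
POOL_REQUIRED = ["treatment", "replicate"]
DELTA_COLUMNS = ["treatment", "replicate", "delta13c"]


class ValidationError(ValueError):
    """Input table or config fails schema validation."""


def read_table(path) -> pd.DataFrame:
    """Read a TSV/CSV table, sniffing the delimiter from the extension."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: no records") from None
    if df.empty:
        raise ValidationError(f"{path}: no records")
    return df


def _require(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")


def _require_numeric(df: pd.DataFrame, columns: list[str], path) -> None:
    for c in columns:
        if not pd.api.types.is_numeric_dtype(df[c]):
            raise ValidationError(
                f"{path}: column {c!r} is not numeric (check decimal separators)"
            )


def read_titrations(path) -> pd.DataFrame:
    df = read_table(path)
    _require(df, TITRATION_COLUMNS, path)
    _require_numeric(df, TITRATION_COLUMNS[2:], path)
    return df


def read_pools(path) -> pd.DataFrame:
    df = read_table(path)
    _require(df, POOL_REQUIRED, path)
    value_cols = [c for c in df.columns if c not in POOL_REQUIRED]
    if not value_cols:
        raise ValidationError(f"{path}: no measurement columns besides {POOL_REQUIRED}")
    _require_numeric(df, value_cols, path)
    return df


def read_deltas(path) -> pd.DataFrame:
    df = read_table(path)
    _require(df, DELTA_COLUMNS, path)
    _require_numeric(df, ["delta13c"], path)
    return df


def load_config(path) -> dict:
    """Load a YAML run configuration into plain dicts / domain objects.

    Recognized top-level keys: ``seed``, ``alpha``, ``end_members``
    (field overrides), ``treatments`` (list of dicts with ``code`` and
    doses), ``simulation`` (keyword overrides for ``SimulationConfig``),
    ``inputs`` (paths to real tables). Unknown keys are rejected.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    allowed = {"seed", "alpha", "end_members", "treatments", "simulation", "inputs"}
    unknown = set(raw) - allowed
    if unknown:
        raise ValidationError(f"{path}: unknown config key(s) {sorted(unknown)}")
    if "inputs" in raw and "simulation" in raw:
        raise ValidationError(
            f"{path}: choose either real input paths or a simulation config, not both"
        )
    cfg = dict(raw)
    if "end_members" in cfg:
        try:
            cfg["end_members"] = EndMembers(**cfg["end_members"])
        except TypeError as exc:
            raise ValidationError(f"{path}: bad end_members: {exc}") from None
    if "treatments" in cfg:
        cfg["treatments"] = [TreatmentSpec(**t) for t in cfg["treatments"]]
    return cfg
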