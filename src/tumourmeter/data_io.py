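"""Readers/writers for tabular measurement records plus a synthetic generator.

The canonical record schema is a pandas DataFrame with columns::

    study_id, mouse_id, day, operator_id, instrument,
    length, width, height, area, weight, excluded

lengths in mm, area in mm^2, weight in g.  ``SchemaMap`` adapts an
arbitrary CSV dialect onto this schema (column renames, unit factors,
constant fills), so reading a new file layout requires only a schema edit.

``generate_records`` emulates a multi-operator calliper/scan study with
controlled variance components (between-tumour spread, per-operator bias,
per-observation noise) and also returns the latent truth table, enabling
parameter-recovery tests of every downstream statistic.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._errors import ConfigurationError, DataError, SchemaError

CANONICAL_FIELDS = (
    "study_id",
    "mouse_id",
    "day",
    "operator_id",
    "instrument",
    "length",
    "width",
    "height",
    "area",
    "weight",
    "excluded",
)
REQUIRED_FIELDS = ("mouse_id", "day", "operator_id", "length", "width")
NUMERIC_FIELDS = ("length", "width", "height", "area", "weight")
POSITIVE_FIELDS = ("length", "width", "weight")


@dataclass
class SchemaMap:
    """Mapping from a CSV dialect onto the canonical record schema.

    ``columns`` maps canonical field -> CSV column name; ``units`` maps a
    numeric field -> multiplicative factor into canonical units (e.g. 10
    for lengths recorded in cm); ``constants`` fills fields absent from the
    file (e.g. instrument).
    """

    columns: dict[str, str] = field(default_factory=dict)
    units: dict[str, float] = field(default_factory=dict)
    constants: dict[str, object] = field(default_factory=dict)
    date_format: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.columns) - set(CANONICAL_FIELDS)
        if unknown:
            raise SchemaError(f"schema maps unknown fields: {sorted(unknown)}")
        for f, factor in self.units.items():
            if factor <= 0:
                raise SchemaError(f"unit factor for {f!r} must be positive")
        missing = [
            f
            for f in REQUIRED_FIELDS
            if f not in self.columns and f not in self.constants
        ]
        if missing:
            raise SchemaError(f"schema leaves required fields unmapped: {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SchemaMap":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            columns=raw.get("columns", {}),
            units={k: float(v) for k, v in raw.get("units", {}).items()},
            constants=raw.get("constants", {}),
            date_format=raw.get("date_format"),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "columns": self.columns,
                    "units": self.units,
                    "constants": self.constants,
                    "date_format": self.date_format,
                },
                sort_keys=False,
            )
        )


def identity_schema() -> SchemaMap:
    """Schema for files already in the canonical layout."""
    return SchemaMap(columns={f: f for f in REQUIRED_FIELDS})


_BUNDLED_SCHEMAS = {
    "s1": "s1_calliper.yaml",
    "s2": "s2_comparison.yaml",
    "s3": "s3_weight.yaml",
}


def default_schema(name: str) -> SchemaMap:
    """Load one of the bundled editable schema maps ('s1', 's2', 's3',
    'canonical')."""
    if name == "canonical":
        return identity_schema()
    try:
        fname = _BUNDLED_SCHEMAS[name]
    except KeyError:
        raise SchemaError(
            f"unknown bundled schema {name!r}; expected one of "
            f"{sorted(_BUNDLED_SCHEMAS) + ['canonical']}"
        ) from None
    return SchemaMap.from_yaml(Path(__file__).parent / "schemas" / fname)


def read_records(
    path: str | Path, schema: SchemaMap | None = None
) -> tuple[pd.DataFrame, dict]:
    """Read a delimited file into canonical records.

    Rows violating record invariants (non-numeric or non-positive
    length/width, non-positive weight) are rejected; the report dict
    carries kept/rejected counts and per-row reasons.
    """
    schema = schema or identity_schema()
    try:
        raw = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - wrap any parse failure
        raise DataError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in schema.columns.values() if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: mapped columns missing from file: {missing}")

    df = pd.DataFrame(index=raw.index)
    for canon in CANONICAL_FIELDS:
        if canon in schema.columns:
            df[canon] = raw[schema.columns[canon]]
        elif canon in schema.constants:
            df[canon] = schema.constants[canon]
        elif canon in raw.columns:  # unmapped optional field, canonical name
            df[canon] = raw[canon]
        else:
            df[canon] = np.nan

    reasons: dict[int, str] = {}
    for f in NUMERIC_FIELDS:
        coerced = pd.to_numeric(df[f], errors="coerce")
        bad = df[f].notna() & coerced.isna()
        for i in df.index[bad]:
            reasons.setdefault(i, f"non-numeric {f}: {df.at[i, f]!r}")
        df[f] = coerced * schema.units.get(f, 1.0)
    if schema.date_format:
        df["day"] = pd.to_datetime(df["day"], format=schema.date_format, errors="coerce")
        for i in df.index[df["day"].isna()]:
            reasons.setdefault(i, "unparseable day")
    for f in ("length", "width"):
        bad = df[f].isna() | (df[f] <= 0)
        for i in df.index[bad]:
            reasons.setdefault(i, f"missing or non-positive {f}")
    bad_w = df["weight"].notna() & (df["weight"] <= 0)
    for i in df.index[bad_w]:
        reasons.setdefault(i, "non-positive weight")

    keep = ~df.index.isin(list(reasons))
    out = df[keep].reset_index(drop=True)
    out["excluded"] = out["excluded"].map(
        lambda v: bool(v) and str(v).lower() not in ("false", "0", "no", "nan", "")
        if pd.notna(v)
        else False
    )
    report = {
        "kept": int(keep.sum()),
        "rejected": int(len(df) - keep.sum()),
        "reasons": {int(k): v for k, v in reasons.items()},
    }
    return out, report


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    """Write canonical records as comma-delimited UTF-8 with a header row."""
    cols = [c for c in CANONICAL_FIELDS if c in records.columns]
    records.to_csv(path, index=False, columns=cols)


@dataclass
class GeneratorConfig:
    """Controls for the synthetic multi-operator measurement generator.

    Linear dimensions carry multiplicative log-normal noise and per-operator
    multiplicative bias factors; true volumes are log-normal.  Dimensions
    derive from volume through the spheroid identity V = (pi/6) l w^2 with
    the length/width ratio drawn per tumour.
    """

    n_mice: int = 50
    n_operators: int = 3
    n_days: int = 1
    mean_log_volume: float = math.log(500.0)  # log mm^3
    sd_log_volume: float = 0.5
    operator_bias_sd: float = 0.02  # sdlog of per-dimension operator factor
    noise_cv: float = 0.05  # sdlog of per-observation per-dimension noise
    lw_ratio_mean: float = 1.3  # length/width ratio
    lw_ratio_sd: float = 0.1
    hw_ratio_mean: float = 0.7  # height/width ratio
    hw_ratio_sd: float = 0.05
    density: float = 1.0  # g/cm^3, for excised weights
    missing_rate: float = 0.0
    excluded_rate: float = 0.0
    instrument: str = "calliper"
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_mice < 1 or self.n_operators < 1 or self.n_days < 1:
            problems.append("n_mice, n_operators and n_days must be >= 1")
        if self.noise_cv < 0 or self.operator_bias_sd < 0:
            problems.append("noise_cv and operator_bias_sd must be >= 0")
        if self.lw_ratio_mean <= 0 or self.hw_ratio_mean <= 0:
            problems.append("shape ratios must be positive")
        if self.density <= 0:
            problems.append("density must be positive")
        for r in ("missing_rate", "excluded_rate"):
            if not 0.0 <= getattr(self, r) <= 1.0:
                problems.append(f"{r} must lie in [0, 1]")
        if problems:
            raise ConfigurationError("; ".join(problems))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown generator config keys: {sorted(unknown)}")
        return cls(**raw)


def generate_records(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw synthetic measurement records plus the latent truth table.

    Returns (records, truth): records in the canonical schema; truth has one
    row per (mouse, day) with the true volume/dimensions/weight, and the
    per-operator bias factors attached as ``operator_factor_<id>`` columns.
    Identical seeds give identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    c = config

    op_ids = [f"op{j + 1:02d}" for j in range(c.n_operators)]
    op_factors = np.exp(rng.normal(0.0, c.operator_bias_sd, size=c.n_operators))

    truth_rows = []
    rec_rows = []
    for m in range(c.n_mice):
        mouse = f"m{m + 1:04d}"
        for day in range(c.n_days):
            v_true = float(np.exp(rng.normal(c.mean_log_volume, c.sd_log_volume)))
            ratio = max(1.0, float(rng.normal(c.lw_ratio_mean, c.lw_ratio_sd)))
            hw = max(0.05, float(rng.normal(c.hw_ratio_mean, c.hw_ratio_sd)))
            # invert V = (pi/6) * (ratio * w) * w^2
            w_true = (6.0 * v_true / (math.pi * ratio)) ** (1.0 / 3.0)
            l_true = ratio * w_true
            h_true = hw * w_true
            weight = v_true * c.density / 1000.0
            truth_rows.append(
                {
                    "mouse_id": mouse,
                    "day": day,
                    "true_volume_mm3": v_true,
                    "true_length": l_true,
                    "true_width": w_true,
                    "true_height": h_true,
                    "true_weight_g": weight,
                }
            )
            for j, op in enumerate(op_ids):
                if rng.random() < c.missing_rate:
                    continue
                eps = np.exp(rng.normal(0.0, c.noise_cv, size=3))
                length = l_true * op_factors[j] * eps[0]
                width = w_true * op_factors[j] * eps[1]
                height = h_true * op_factors[j] * eps[2]
                if width > length:
                    length, width = width, length
                rec_rows.append(
                    {
                        "study_id": "synth",
                        "mouse_id": mouse,
                        "day": day,
                        "operator_id": op,
                        "instrument": c.instrument,
                        "length": length,
                        "width": width,
                        "height": height,
                        "area": math.pi / 4.0 * length * width,
                        "weight": weight,
                        "excluded": bool(rng.random() < c.excluded_rate),
                    }
                )
    records = pd.DataFrame(rec_rows, columns=list(CANONICAL_FIELDS))
    truth = pd.DataFrame(truth_rows)
    for op, f in zip(op_ids, op_factors):
        truth[f"operator_factor_{op}"] = f
    return records, truth
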