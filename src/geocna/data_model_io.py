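"""Tabular data model and I/O for the geoconfigurational pipeline.

Two containers travel through the pipeline:

* :class:`RawTable` — one row per neighborhood case (ZCTA-keyed), continuous
  raw variables (percentages, ICE components, vaccination rates per 10,000).
* :class:`CaseTable` — the calibrated table: integer factor levels plus a
  designated binary outcome factor.

Case identifiers are opaque strings (ZCTAs keep leading zeros).  Missing
declared values are hard errors unless ``drop_missing=True`` is requested.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import IntegrityError, JoinError, SchemaError, TableParseError

logger = logging.getLogger(__name__)

__all__ = [
    "RawTable",
    "CaseTable",
    "OutputBundle",
    "read_raw_table",
    "write_raw_table",
    "write_condition_table",
    "read_condition_table_csv",
    "write_membership",
    "export_membership_geojoin",
]


@dataclass(frozen=True)
class RawTable:
    """Validated table of raw continuous variables, one row per case."""

    data: pd.DataFrame  # index = case_id (str), columns = numeric variables
    case_id_column: str = "zcta"

    def __post_init__(self) -> None:
        idx = self.data.index
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise IntegrityError(f"duplicate case identifiers: {dups}")
        if self.data.isna().any().any():
            bad = self.data.columns[self.data.isna().any()].tolist()
            raise TableParseError(f"missing values in columns {bad}")

    @property
    def case_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_cases(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class CaseTable:
    """Calibrated multi-value factor levels plus binary outcome per case.

    ``levels`` holds one integer column per factor (including the outcome);
    ``domains`` declares each factor's admissible level set.
    """

    levels: pd.DataFrame  # index = case_id, int columns
    outcome_name: str
    domains: Mapping[str, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.outcome_name not in self.levels.columns:
            raise SchemaError(f"outcome factor {self.outcome_name!r} not in table")
        if self.levels.index.has_duplicates:
            raise IntegrityError("duplicate case identifiers in case table")
        domains = dict(self.domains)
        for col in self.levels.columns:
            observed = frozenset(int(v) for v in self.levels[col].unique())
            declared = domains.get(col)
            if declared is None:
                domains[col] = observed
            elif not observed <= frozenset(declared):
                raise SchemaError(
                    f"factor {col!r} has levels {sorted(observed)} outside its "
                    f"declared domain {sorted(declared)}"
                )
        out_dom = frozenset(int(v) for v in self.levels[self.outcome_name].unique())
        if not out_dom <= {0, 1}:
            raise SchemaError("outcome must be binary (levels in {0,1})")
        object.__setattr__(self, "domains", domains)

    @property
    def factors(self) -> list[str]:
        return [c for c in self.levels.columns if c != self.outcome_name]

    @property
    def case_ids(self) -> list[str]:
        return list(self.levels.index)

    @property
    def n_cases(self) -> int:
        return len(self.levels)

    def domain(self, factor: str) -> frozenset[int]:
        try:
            return frozenset(self.domains[factor])
        except KeyError:
            raise SchemaError(f"unknown factor {factor!r}") from None


@dataclass
class OutputBundle:
    """Everything one pipeline run produces, ready for serialization."""

    condition_table: object  # cna_core.ConditionTable
    models: list  # model_builder.SolutionFormula
    membership: pd.DataFrame  # per-case outcome flag + per-conjunct flags


def read_raw_table(
    path: str | Path,
    schema: Mapping[str, type] | Sequence[str],
    case_id_column: str = "zcta",
    drop_missing: bool = False,
) -> RawTable:
    """Read and validate a raw-variable CSV.

    ``schema`` declares the required value columns (a list of names, or a
    mapping name -> type; only float is meaningful).  Rows with missing
    declared values raise :class:`TableParseError` unless ``drop_missing``.
    """
    path = Path(path)
    columns = list(schema)
    df = pd.read_csv(path, dtype={case_id_column: str})
    if case_id_column not in df.columns:
        raise SchemaError(f"missing case-id column {case_id_column!r}")
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"missing declared column {col!r}")
    df = df.set_index(case_id_column)[columns]
    for col in columns:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise TableParseError(
                f"non-numeric value {df.loc[row, col]!r} at row {row!r}, column {col!r}"
            )
        df[col] = parsed
    if df.isna().any().any():
        if drop_missing:
            n_before = len(df)
            df = df.dropna()
            logger.warning("dropped %d rows with missing values", n_before - len(df))
        else:
            row = df.index[df.isna().any(axis=1)][0]
            col = df.columns[df.loc[row].isna()][0]
            raise TableParseError(f"missing value at row {row!r}, column {col!r}")
    rate_cols = [c for c in columns if c.lower().startswith(("vax", "rate"))]
    for col in rate_cols:
        if (df[col] < 0).any():
            row = df.index[df[col] < 0][0]
            raise TableParseError(f"negative rate at row {row!r}, column {col!r}")
    return RawTable(data=df, case_id_column=case_id_column)


def write_raw_table(table: RawTable, path: str | Path) -> None:
    """Write a RawTable back to CSV (UTF-8, comma-separated, header row)."""
    df = table.data.copy()
    df.index.name = table.case_id_column
    df.to_csv(Path(path), encoding="utf-8")


def write_condition_table(table, path: str | Path, allow_empty: bool = False) -> None:
    """Serialize a condition table to CSV.

    One row per retained configuration with columns ``configuration``
    (canonical string), ``outcome``, ``consistency``, ``coverage``,
    ``n_instantiating``, ``n_overlap``; metric values keep full precision
    (>= 6 decimal places survive a round trip).
    """
    rows = list(table.rows)
    if not rows and not allow_empty:
        raise ValueError("refusing to write empty condition table (set allow_empty)")
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["configuration", "outcome", "consistency", "coverage",
             "n_instantiating", "n_overlap"]
        )
        for row in rows:
            writer.writerow(
                [
                    str(row.conjunction),
                    str(row.outcome),
                    repr(float(row.consistency)),
                    repr(float(row.coverage)),
                    row.n_instantiating,
                    row.n_overlap,
                ]
            )


def read_condition_table_csv(path: str | Path) -> pd.DataFrame:
    """Read a condition-table CSV back as a DataFrame (strings + floats)."""
    df = pd.read_csv(Path(path))
    expected = {"configuration", "outcome", "consistency", "coverage"}
    if not expected <= set(df.columns):
        raise SchemaError(f"condition-table CSV missing columns {sorted(expected - set(df.columns))}")
    return df


def write_membership(membership: pd.DataFrame, path: str | Path) -> None:
    """Write the per-case membership table (outcome + per-conjunct flags)."""
    membership.to_csv(Path(path), encoding="utf-8")


def export_membership_geojoin(
    bundle: OutputBundle,
    geo_path: str | Path,
    out_path: str | Path,
    zcta_property: str = "ZCTA",
) -> dict:
    """Annotate a GeoJSON FeatureCollection with per-case membership flags.

    Each feature whose ``zcta_property`` matches a case id gains the outcome
    flag and one boolean per solution conjunct; unmatched features get
    ``"geocna_unmatched": true``.  Geometry is passed through untouched.
    Returns the annotated FeatureCollection (also written to ``out_path``).
    """
    geo_path = Path(geo_path)
    with geo_path.open(encoding="utf-8") as fh:
        collection = json.load(fh)
    if collection.get("type") != "FeatureCollection":
        raise SchemaError("geo file is not a GeoJSON FeatureCollection")
    membership = bundle.membership
    case_ids = set(membership.index.astype(str))
    feature_ids = {
        str(f.get("properties", {}).get(zcta_property))
        for f in collection.get("features", [])
    }
    if not (case_ids & feature_ids):
        raise JoinError(
            f"no overlap between GeoJSON {zcta_property!r} values and case ids"
        )
    n_matched = 0
    for feature in collection["features"]:
        props = feature.setdefault("properties", {})
        key = str(props.get(zcta_property))
        if key in case_ids:
            n_matched += 1
            for col in membership.columns:
                name = col
                if name in props:
                    warnings.warn(
                        f"property {name!r} already present; writing {name + '_geocna'!r}"
                    )
                    name = name + "_geocna"
                value = membership.loc[key, col]
                props[name] = bool(value) if membership[col].dtype != object else value
        else:
            props["geocna_unmatched"] = True
    out_path = Path(out_path)
    with out_path.open("w", encoding="utf-8") as fh:
        json.dump(collection, fh, indent=1, sort_keys=True)
    logger.info("annotated %d features (%d unmatched)", n_matched,
                len(collection["features"]) - n_matched)
    return collection
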