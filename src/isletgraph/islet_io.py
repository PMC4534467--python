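"""Reading, validating and writing islet cell-coordinate tables.

The canonical on-disk form is delimited text (CSV or TSV, autodetected),
one row per cell, with columns resolvable to::

    subject_id, islet_id, cell_id, x, y[, z], cell_type

Coordinates are micrometres and are stored as-is (no re-centering).  The
cohort group (``control`` vs ``t2d``) is a property of the *file* a record
came from, not of the subject label, and is supplied by the caller at read
time.  A :class:`Dialect` maps whatever header the deposited files use onto
this schema, since the published description of the data only lists the
fields, not the header.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CELL_TYPES",
    "GROUPS",
    "Dialect",
    "IsletTable",
    "SchemaError",
    "ValidationError",
    "read_dataset",
    "write_dataset",
    "filter_cells",
    "summarize",
]

CELL_TYPES = ("alpha", "beta", "delta")
GROUPS = ("control", "t2d")

#: tokens accepted for each cell type on input (case-insensitive)
_DEFAULT_TYPE_TOKENS: Mapping[str, str] = {
    "alpha": "alpha", "a": "alpha", "α": "alpha",
    "beta": "beta", "b": "beta", "β": "beta",
    "delta": "delta", "d": "delta", "δ": "delta",
}

_SCHEMA_FIELDS = ("subject_id", "islet_id", "cell_id", "x", "y", "cell_type")


class SchemaError(ValueError):
    """A required column cannot be resolved from the file header."""


class ValidationError(ValueError):
    """Rows violate the table invariants (duplicates, bad coordinates...)."""


@dataclass(frozen=True)
class Dialect:
    """Maps a delimited file onto the cell-record schema.

    Parameters
    ----------
    column_map
        schema field -> column name in the file.  Fields absent from the
        map are looked up under their own name.
    delimiter
        Field separator; ``None`` autodetects between comma and tab.
    type_tokens
        token (lower-cased) -> canonical cell type.
    """

    column_map: Mapping[str, str] = field(default_factory=dict)
    delimiter: str | None = None
    type_tokens: Mapping[str, str] = field(default_factory=lambda: dict(_DEFAULT_TYPE_TOKENS))

    def source_column(self, schema_field: str) -> str:
        return self.column_map.get(schema_field, schema_field)


@dataclass
class IsletTable:
    """A validated collection of cell records grouped into islets.

    ``df`` columns: subject_id (str), group (str), islet_id (int),
    cell_id (int), x, y (float, μm), optionally z (float, μm),
    cell_type (str in :data:`CELL_TYPES`).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        df = self.df
        required = ["subject_id", "group", "islet_id", "cell_id", "x", "y", "cell_type"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        bad_group = set(df["group"].unique()) - set(GROUPS)
        if bad_group:
            raise ValidationError(f"unknown group labels: {sorted(bad_group)}")
        bad_type = set(df["cell_type"].unique()) - set(CELL_TYPES)
        if bad_type:
            raise ValidationError(f"unknown cell types: {sorted(bad_type)}")
        coord_cols = ["x", "y"] + (["z"] if "z" in df.columns else [])
        coords = df[coord_cols].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            rows = df.index[~np.isfinite(coords).all(axis=1)].tolist()[:10]
            raise ValidationError(f"non-finite coordinates at rows {rows}")
        dup = df.duplicated(subset=["subject_id", "islet_id", "cell_id"], keep=False)
        if dup.any():
            first = df.loc[dup, ["subject_id", "islet_id", "cell_id"]].iloc[0]
            raise ValidationError(
                "duplicate (subject_id, islet_id, cell_id) triple: "
                f"({first.subject_id!r}, {first.islet_id}, {first.cell_id})"
            )
        # one islet never spans subjects by construction of the key; check group
        ngroup = df.groupby(["subject_id", "islet_id"], sort=False)["group"].nunique()
        if (ngroup > 1).any():
            raise ValidationError("an islet mixes group labels")

    # -- accessors --------------------------------------------------------
    @property
    def has_z(self) -> bool:
        return "z" in self.df.columns

    @property
    def n_cells(self) -> int:
        return len(self.df)

    @property
    def n_islets(self) -> int:
        return self.df.groupby(["subject_id", "islet_id"], sort=False).ngroups

    def islets(self) -> Iterator[tuple[tuple[str, int], pd.DataFrame]]:
        """Yield ((subject_id, islet_id), sub-frame) per islet."""
        yield from self.df.groupby(["subject_id", "islet_id"], sort=True)

    def coords(self, frame: pd.DataFrame | None = None) -> np.ndarray:
        df = self.df if frame is None else frame
        cols = ["x", "y", "z"] if "z" in df.columns else ["x", "y"]
        return df[cols].to_numpy(dtype=float)


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","


def read_dataset(
    path: str | Path,
    group: str,
    dialect: Dialect | None = None,
) -> IsletTable:
    """Read one deposited coordinate file into a validated :class:`IsletTable`.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    group
        ``"control"`` or ``"t2d"``; which cohort file this is.
    dialect
        Header mapping and delimiter; defaults autodetect.
    """
    path = Path(path)
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    dialect = dialect or Dialect()
    sep = dialect.delimiter or _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    raw.columns = [c.strip() for c in raw.columns]

    rename = {}
    for fieldname in _SCHEMA_FIELDS + ("z",):
        src = dialect.source_column(fieldname)
        if src in raw.columns:
            rename[src] = fieldname
    raw = raw.rename(columns=rename)
    missing = [f for f in _SCHEMA_FIELDS if f not in raw.columns]
    if missing:
        raise SchemaError(f"{path.name}: cannot resolve columns {missing}; "
                          f"file has {list(raw.columns)}")

    out = pd.DataFrame()
    out["subject_id"] = raw["subject_id"].astype(str).str.strip()
    out["group"] = group
    for col in ("islet_id", "cell_id"):
        try:
            out[col] = raw[col].astype(float).astype(int)
        except ValueError as exc:
            bad = _first_bad_row(raw[col], kind="int")
            raise ValidationError(f"{path.name}: non-integer {col} at data row {bad}") from exc
    coord_cols = ["x", "y"] + (["z"] if "z" in raw.columns else [])
    for col in coord_cols:
        try:
            out[col] = raw[col].astype(float)
        except ValueError as exc:
            bad = _first_bad_row(raw[col], kind="float")
            raise ValidationError(f"{path.name}: non-numeric {col} at data row {bad}") from exc
    tokens = {k.lower(): v for k, v in dialect.type_tokens.items()}
    ct = raw["cell_type"].astype(str).str.strip().str.lower().map(tokens)
    if ct.isna().any():
        row = int(np.flatnonzero(ct.isna().to_numpy())[0])
        raise ValidationError(
            f"{path.name}: unknown cell_type token {raw['cell_type'].iloc[row]!r} "
            f"at data row {row + 2}"  # 1-based, after header
        )
    out["cell_type"] = ct
    return IsletTable(out.reset_index(drop=True))


def _first_bad_row(series: pd.Series, kind: str) -> int:
    for i, v in enumerate(series):
        try:
            float(v)
        except (TypeError, ValueError):
            return i + 2  # 1-based line number incl. header
    return -1


def write_dataset(table: IsletTable, path: str | Path, delimiter: str = ",") -> None:
    """Write a table back to delimited text; round-trips with `read_dataset`."""
    cols = ["subject_id", "islet_id", "cell_id", "x", "y", "cell_type"]
    if table.has_z:
        cols.insert(5, "z")
    table.df[cols].to_csv(path, sep=delimiter, index=False)


def filter_cells(table: IsletTable, cell_type: str) -> IsletTable:
    """Keep only records of one endocrine type (e.g. the β-cell vertices).

    Islets that lose all their cells drop out of the grouping index; the
    count of dropped islets is available by comparing ``n_islets``.
    """
    if cell_type not in CELL_TYPES:
        raise ValueError(f"cell_type must be one of {CELL_TYPES}, got {cell_type!r}")
    sub = table.df[table.df["cell_type"] == cell_type].reset_index(drop=True)
    out = IsletTable.__new__(IsletTable)  # may legitimately be empty
    out.df = sub
    if len(sub):
        out.validate()
    return out


def summarize(table: IsletTable, size_classifier=None) -> pd.DataFrame:
    """Per-subject islet and cell counts, optionally split large/small.

    Parameters
    ----------
    size_classifier
        Callable mapping an (n, 2/3) coordinate array of *all* endocrine
        cells of one islet to ``"large"`` or ``"small"``; when given the
        output carries islet/cell counts per size class.

    Returns
    -------
    DataFrame with one row per subject plus one ``__total__`` row per group.
    """
    rows = []
    for (subject, islet_id), sub in table.islets():
        size = size_classifier(table.coords(sub)) if size_classifier else "all"
        rows.append((subject, sub["group"].iloc[0], islet_id, len(sub), size))
    per_islet = pd.DataFrame(rows, columns=["subject_id", "group", "islet_id", "n_cells", "size"])

    def _agg(df: pd.DataFrame) -> dict:
        rec = {"n_islets": len(df), "n_cells": int(df["n_cells"].sum())}
        if size_classifier is not None:
            for cls in ("large", "small"):
                sel = df[df["size"] == cls]
                rec[f"n_islets_{cls}"] = len(sel)
                rec[f"n_cells_{cls}"] = int(sel["n_cells"].sum())
        return rec

    out = []
    for (group, subject), df in per_islet.groupby(["group", "subject_id"]):
        out.append({"group": group, "subject_id": subject, **_agg(df)})
    for group, df in per_islet.groupby("group"):
        out.append({"group": group, "subject_id": "__total__", **_agg(df)})
    return pd.DataFrame(out)


def concat_tables(*tables: IsletTable) -> IsletTable:
    """Concatenate (e.g. control + t2d files) into one validated table."""
    return IsletTable(pd.concat([t.df for t in tables], ignore_index=True))
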