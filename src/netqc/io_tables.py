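"""Tabular domain objects and their plain-CSV readers/writers.

All interchange is comma-separated UTF-8 with a header row (RFC 4180 quoting,
"." as the only decimal separator). Default column names are ``id``, ``x``,
``y``, ``class`` and ``sample``; every reader accepts a column map so that
exports from different cell-profiling tools can be ingested unchanged.

The enrichment-matrix layout is a square named matrix: ``#``-prefixed comment
lines carry the run metadata (radius, permutations, seed, method), then a
header row whose first cell is empty and whose remaining cells are the class
names (columns = the randomized/query type B), then one row per focal type A
starting with its name. Undefined scores are written as empty fields.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

DEFAULT_COLUMNS = {"id": "id", "x": "x", "y": "y", "class": "class", "sample": "sample"}


def _first_appearance_order(labels: Iterable[str]) -> list[str]:
    return list(pd.unique(np.asarray(list(labels), dtype=object)))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellTable:
    """Positions and class labels of the cells of one tissue sample.

    ``ids`` are unique identity strings, ``xy`` is an (n, 2) float array in the
    user's planar length units, ``labels`` holds one whitespace-trimmed,
    non-empty class label per cell. ``dropped`` (not part of equality) records
    rows a reader discarded because the class field was empty.
    """

    ids: np.ndarray
    xy: np.ndarray
    labels: np.ndarray
    sample_id: str | None = None
    dropped: pd.DataFrame | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        ids = np.asarray(self.ids, dtype=object)
        xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        labels = np.asarray([str(l).strip() for l in self.labels], dtype=object)
        if not (len(ids) == len(xy) == len(labels)):
            raise ValidationError("ids, xy and labels must have equal length")
        if len(ids) != len(set(ids)):
            dupes = pd.Series(ids)[pd.Series(ids).duplicated()].unique()[:10]
            raise ValidationError(f"duplicate cell_id values: {list(dupes)}")
        if len(xy) and not np.all(np.isfinite(xy)):
            raise ValidationError("cell coordinates must be finite")
        if any(l == "" for l in labels):
            raise ValidationError("empty class labels are not allowed in a CellTable")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "xy", xy)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def class_set(self) -> list[str]:
        """Unique class labels in first-appearance order."""
        return _first_appearance_order(self.labels)

    def positions_of(self, label: str) -> np.ndarray:
        """(m, 2) coordinates of all cells carrying ``label``."""
        if label not in self.class_set:
            raise ValidationError(f"unknown class label: {label!r}")
        return self.xy[self.labels == label]

    def n_of(self, label: str) -> int:
        return int(np.sum(self.labels == label))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"id": self.ids, "x": self.xy[:, 0], "y": self.xy[:, 1], "class": self.labels}
        )
        if self.sample_id is not None:
            df["sample"] = self.sample_id
        return df


@dataclass(frozen=True)
class FeatureTable:
    """Per-cell numeric features tagged by sample/core.

    ``data`` has columns ``id``, ``sample`` followed by the feature columns in
    ``feature_names``. Missing measurements are NaN.
    """

    data: pd.DataFrame
    feature_names: list[str]

    def __post_init__(self) -> None:
        if not self.feature_names:
            raise ValidationError("a FeatureTable needs at least one feature column")
        missing = [c for c in ("id", "sample", *self.feature_names) if c not in self.data.columns]
        if missing:
            raise ValidationError(f"FeatureTable is missing columns: {missing}")
        df = self.data.loc[:, ["id", "sample", *self.feature_names]].reset_index(drop=True)
        for name in self.feature_names:
            if not pd.api.types.is_numeric_dtype(df[name]):
                raise ValidationError(f"feature column {name!r} is not numeric")
            df[name] = df[name].astype(float)
        object.__setattr__(self, "data", df)
        object.__setattr__(self, "feature_names", list(self.feature_names))

    def __len__(self) -> int:
        return len(self.data)

    @property
    def sample_ids(self) -> list[str]:
        return _first_appearance_order(self.data["sample"].astype(str))


@dataclass(frozen=True)
class PairedClassification:
    """Matched expected/predicted class labels per cell id (plus coordinates)."""

    ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    expected: np.ndarray
    predicted: np.ndarray

    def __post_init__(self) -> None:
        ids = np.asarray(self.ids, dtype=object)
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate cell_id values in paired classification")
        for name in ("expected", "predicted"):
            vals = np.asarray([str(v).strip() for v in getattr(self, name)], dtype=object)
            if any(v == "" for v in vals):
                raise ValidationError(f"empty {name} label")
            object.__setattr__(self, name, vals)
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class EnrichmentMatrix:
    """K x K ordered-pair z-score matrix with full provenance.

    ``scores[i, j]`` is the enrichment z-score with focal (row) type i kept
    fixed and query (column) type j randomized; NaN marks undefined entries
    (diagonal under the default policy, or a degenerate null with sigma = 0).
    ``observed``, ``null_mean`` and ``null_std`` hold the ingredients of the
    z-score; ``notes`` records per-pair reasons for undefined entries.
    """

    class_names: list[str]
    scores: np.ndarray
    radius: float
    n_permutations: int
    seed: int
    method: str
    observed: np.ndarray | None = None
    null_mean: np.ndarray | None = None
    null_std: np.ndarray | None = None
    notes: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        k = len(self.class_names)
        scores = np.asarray(self.scores, dtype=float).reshape(k, k)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "class_names", list(self.class_names))
        if self.method not in ("conditional", "full_shuffle"):
            raise ValidationError(f"unknown enrichment method: {self.method!r}")
        for name in ("observed", "null_mean", "null_std"):
            arr = getattr(self, name)
            if arr is not None:
                object.__setattr__(self, name, np.asarray(arr, dtype=float).reshape(k, k))

    def score(self, focal: str, query: str) -> float:
        i = self.class_names.index(focal)
        j = self.class_names.index(query)
        return float(self.scores[i, j])


# ---------------------------------------------------------------------------
# atomic writing helper
# ---------------------------------------------------------------------------


def _atomic_write_text(path: str | os.PathLike, text: str) -> None:
    """Write to a temp file in the target directory, then rename into place."""
    directory = os.path.dirname(os.fspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _fmt(value: float) -> str:
    """Full-precision float formatting so write -> read round-trips exactly."""
    return "" if np.isnan(value) else repr(float(value))


# ---------------------------------------------------------------------------
# cell tables
# ---------------------------------------------------------------------------


def _resolve_columns(overrides: Mapping[str, str] | None) -> dict[str, str]:
    cols = dict(DEFAULT_COLUMNS)
    if overrides:
        unknown = set(overrides) - set(cols)
        if unknown:
            raise ValidationError(f"unknown column-map keys: {sorted(unknown)}")
        cols.update(overrides)
    return cols


def read_cell_table(path: str | os.PathLike, columns: Mapping[str, str] | None = None) -> CellTable:
    """Read a cell table CSV into a validated :class:`CellTable`.

    Rows with an empty class label are dropped; the dropped rows are available
    on the returned table's ``dropped`` attribute.
    """
    cols = _resolve_columns(columns)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for key in ("id", "x", "y", "class"):
        if cols[key] not in df.columns:
            raise FormatError(f"cell table {path} is missing required column {cols[key]!r}")
    for key in ("x", "y"):
        converted = pd.to_numeric(df[cols[key]], errors="coerce")
        if converted.isna().any():
            row = int(np.flatnonzero(converted.isna().to_numpy())[0]) + 2  # 1-based, incl. header
            raise FormatError(f"non-numeric {cols[key]!r} coordinate in {path} at line {row}")
        df[cols[key]] = converted
    labels = df[cols["class"]].str.strip()
    keep = labels != ""
    dropped = df.loc[~keep].copy()
    df = df.loc[keep]
    sample_id = None
    if cols["sample"] in df.columns:
        uniq = df[cols["sample"]].str.strip().unique()
        if len(uniq) == 1:
            sample_id = str(uniq[0]) or None
    return CellTable(
        ids=df[cols["id"]].to_numpy(dtype=object),
        xy=df[[cols["x"], cols["y"]]].to_numpy(dtype=float),
        labels=labels.loc[keep].to_numpy(dtype=object),
        sample_id=sample_id,
        dropped=dropped if len(dropped) else None,
    )


def write_cell_table(table: CellTable, path: str | os.PathLike) -> None:
    _atomic_write_text(path, table.to_dataframe().to_csv(index=False))


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------


def read_feature_table(
    path: str | os.PathLike, columns: Mapping[str, str] | None = None
) -> FeatureTable:
    """Read a per-cell feature CSV; every non-id/sample column is a feature."""
    cols = _resolve_columns(columns)
    df = pd.read_csv(path)
    for key in ("id", "sample"):
        if cols[key] not in df.columns:
            raise FormatError(f"feature table {path} is missing required column {cols[key]!r}")
    feature_names = [c for c in df.columns if c not in (cols["id"], cols["sample"])]
    if not feature_names:
        raise FormatError(f"feature table {path} has no feature columns")
    renamed = df.rename(columns={cols["id"]: "id", cols["sample"]: "sample"})
    renamed["id"] = renamed["id"].astype(str)
    renamed["sample"] = renamed["sample"].astype(str)
    for name in feature_names:
        if not pd.api.types.is_numeric_dtype(renamed[name]):
            raise FormatError(f"feature column {name!r} in {path} is not numeric")
    return FeatureTable(data=renamed, feature_names=feature_names)


def write_feature_table(table: FeatureTable, path: str | os.PathLike) -> None:
    _atomic_write_text(path, table.data.to_csv(index=False))


# ---------------------------------------------------------------------------
# enrichment matrices
# ---------------------------------------------------------------------------


def write_enrichment_csv(matrix: EnrichmentMatrix, path: str | os.PathLike) -> None:
    """Write the square named z-score matrix with ``#`` metadata comment lines."""
    lines = [
        f"# radius={_fmt(matrix.radius)}",
        f"# n_permutations={matrix.n_permutations}",
        f"# seed={matrix.seed}",
        f"# method={matrix.method}",
    ]
    header = "," + ",".join(matrix.class_names)
    lines.append(header)
    for name, row in zip(matrix.class_names, matrix.scores):
        lines.append(name + "," + ",".join(_fmt(v) for v in row))
    _atomic_write_text(path, "\n".join(lines) + "\n")


def read_enrichment_csv(path: str | os.PathLike) -> EnrichmentMatrix:
    meta: dict[str, str] = {}
    body: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value.strip()
            else:
                body.append(line)
    if not body:
        raise FormatError(f"enrichment CSV {path} has no matrix body")
    from io import StringIO

    df = pd.read_csv(StringIO("".join(body)), index_col=0, float_precision="round_trip")
    class_names = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != class_names:
        raise FormatError(f"enrichment CSV {path} is not a square named matrix")
    try:
        return EnrichmentMatrix(
            class_names=class_names,
            scores=df.to_numpy(dtype=float),
            radius=float(meta.get("radius", "nan")),
            n_permutations=int(meta.get("n_permutations", 0)),
            seed=int(meta.get("seed", 0)),
            method=meta.get("method", "conditional"),
        )
    except ValueError as exc:
        raise FormatError(f"bad metadata in enrichment CSV {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# paired classifications and confusion matrices
# ---------------------------------------------------------------------------


def read_paired_classification(
    path: str | os.PathLike,
    second_path: str | os.PathLike | None = None,
    expected_col: str = "expected",
    predicted_col: str = "predicted",
    columns: Mapping[str, str] | None = None,
) -> PairedClassification:
    """Read matched expected/predicted labels.

    Either one CSV carrying both label columns, or two CSVs (expected first)
    joined on cell id; any id present on one side only is a validation error.
    """
    cols = _resolve_columns(columns)

    def _load(p):
        df = pd.read_csv(p, dtype=str, keep_default_na=False)
        if cols["id"] not in df.columns:
            raise FormatError(f"paired classification {p} is missing column {cols['id']!r}")
        return df

    if second_path is None:
        df = _load(path)
        for col in (expected_col, predicted_col):
            if col not in df.columns:
                raise FormatError(f"paired classification {path} is missing column {col!r}")
        expected = df[expected_col]
        predicted = df[predicted_col]
        base = df
    else:
        left = _load(path)
        right = _load(second_path)
        label_col_left = cols["class"] if cols["class"] in left.columns else expected_col
        label_col_right = cols["class"] if cols["class"] in right.columns else predicted_col
        for p, df, col in ((path, left, label_col_left), (second_path, right, label_col_right)):
            if col not in df.columns:
                raise FormatError(f"paired classification {p} is missing a class column")
        only_left = sorted(set(left[cols["id"]]) - set(right[cols["id"]]))
        only_right = sorted(set(right[cols["id"]]) - set(left[cols["id"]]))
        if only_left or only_right:
            sample = (only_left + only_right)[:10]
            raise ValidationError(
                f"cell ids do not match between {path} and {second_path}; "
                f"{len(only_left) + len(only_right)} unmatched, e.g. {sample}"
            )
        merged = left.merge(
            right[[cols["id"], label_col_right]].rename(columns={label_col_right: "__pred"}),
            on=cols["id"],
        )
        expected = merged[label_col_left]
        predicted = merged["__pred"]
        base = merged

    n = len(base)
    x = pd.to_numeric(base[cols["x"]], errors="coerce") if cols["x"] in base else pd.Series([np.nan] * n)
    y = pd.to_numeric(base[cols["y"]], errors="coerce") if cols["y"] in base else pd.Series([np.nan] * n)
    return PairedClassification(
        ids=base[cols["id"]].to_numpy(dtype=object),
        x=x.to_numpy(dtype=float),
        y=y.to_numpy(dtype=float),
        expected=expected.to_numpy(dtype=object),
        predicted=predicted.to_numpy(dtype=object),
    )


def write_confusion_csv(matrix, path: str | os.PathLike) -> None:
    """Write a confusion matrix (rows = expected, columns = predicted) as CSV."""
    lines = [f"# total={matrix.total}"]
    lines.append("," + ",".join(matrix.predicted_classes))
    for name, row in zip(matrix.expected_classes, matrix.counts):
        lines.append(name + "," + ",".join(str(int(v)) for v in row))
    _atomic_write_text(path, "\n".join(lines) + "\n")


def write_selection_csv(selection: Sequence[tuple], path: str | os.PathLike) -> None:
    """Write a (cell_id, x, y) selection list as CSV."""
    df = pd.DataFrame(selection, columns=["id", "x", "y"])
    _atomic_write_text(path, df.to_csv(index=False))
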