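"""Tabular input/output: intensity matrices, sample annotations, metabolite sets.

All tables are plain delimited text (CSV or TSV, auto-detected from the file
extension with an explicit override). Metabolite and sample identifiers are
opaque strings; values are nonnegative intensities with missing entries
represented as empty cells, ``NA`` or ``NaN``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

MISSING_TOKENS = ["", "NA", "NaN", "nan", "na", "N/A"]

HOSTS = frozenset({"human", "mouse"})
PIGMENTATION_LEVELS = frozenset({"pigmented", "non-pigmented", "unknown"})

#: Columns expected in a sample annotation table besides the sample_id index.
ANNOTATION_COLUMNS = (
    "origin",
    "host",
    "passage",
    "pigmentation",
    "braf",
    "sex",
    "site_class",
    "batch",
)


def _detect_sep(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if str(path).lower().endswith(".csv") else "\t"


@dataclass
class IntensityTable:
    """Metabolite x sample matrix of raw, nonnegative intensities.

    ``values`` is indexed by metabolite id with one column per sample id;
    missing measurements are NaN.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise ValidationError(f"duplicate metabolite identifiers: {dups}")
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique())
            raise ValidationError(f"duplicate sample identifiers: {dups}")
        vals = self.values.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] < 0):
            rows = self.values.index[(self.values < 0).any(axis=1)]
            raise ValidationError(
                f"negative intensities in rows: {sorted(map(str, rows))}"
            )
        self.values = self.values.astype(float)
        self.values.index.name = None
        self.values.columns.name = None

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def missing_fraction(self) -> pd.Series:
        """Per-metabolite fraction of missing samples."""
        return self.values.isna().mean(axis=1)


def read_intensity_table(
    path: str | Path,
    orientation: str = "metabolites_by_samples",
    sep: str | None = None,
) -> IntensityTable:
    """Read a delimited intensity table and normalize it to metabolites x samples.

    Parameters
    ----------
    path:
        Delimited text file with one header row and one identifier column.
    orientation:
        ``"metabolites_by_samples"`` (rows are metabolites, the default) or
        ``"samples_by_metabolites"`` (table is transposed after reading).
    sep:
        Field separator; by default inferred from the extension
        (``.csv`` -> comma, anything else -> TAB).
    """
    if orientation not in ("metabolites_by_samples", "samples_by_metabolites"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    sep = _detect_sep(path, sep)
    try:
        df = pd.read_csv(
            path,
            sep=sep,
            index_col=0,
            na_values=MISSING_TOKENS,
            keep_default_na=False,
        )
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ParseError(f"{path}: {exc}") from exc
    if orientation == "samples_by_metabolites":
        df = df.T
    non_numeric = []
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            non_numeric.append(col)
    if non_numeric:
        raise ParseError(f"{path}: non-numeric values in columns {non_numeric}")
    try:
        return IntensityTable(df)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_intensity_table(
    table: IntensityTable, path: str | Path, sep: str | None = None
) -> None:
    table.values.to_csv(path, sep=_detect_sep(path, sep), index_label="metabolite_id")


@dataclass
class SampleAnnotation:
    """Per-sample experimental factors.

    ``table`` is indexed by sample id and carries at least ``origin``,
    ``host`` and ``passage``; the remaining annotation columns default to
    ``"unknown"`` when absent. Patient tumours are host ``human`` at passage
    0; xenografts are host ``mouse`` at passage >= 1.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        if df.index.has_duplicates:
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise ValidationError(f"duplicate sample identifiers: {dups}")
        for required in ("origin", "host", "passage"):
            if required not in df.columns:
                raise ValidationError(f"annotation missing column {required!r}")
        for optional in ANNOTATION_COLUMNS:
            if optional not in df.columns:
                df[optional] = "unknown"
        bad_host = set(df["host"]) - HOSTS
        if bad_host:
            raise ValidationError(f"unknown host values: {sorted(bad_host)}")
        df["passage"] = df["passage"].astype(int)
        human = df["host"] == "human"
        if not (df.loc[human, "passage"] == 0).all() or not (
            df.loc[~human, "passage"] >= 1
        ).all():
            raise ValidationError(
                "host/passage mismatch: human samples must be passage 0 "
                "and mouse samples passage >= 1"
            )
        df.index.name = "sample_id"
        self.table = df[list(ANNOTATION_COLUMNS)]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def subset(self, sample_ids: Sequence[str]) -> "SampleAnnotation":
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise ValidationError(f"samples not in annotation: {missing}")
        return SampleAnnotation(self.table.loc[list(sample_ids)])

    def check_covers(self, table: IntensityTable) -> None:
        """Every sample of the intensity table must be annotated."""
        missing = [s for s in table.sample_ids if s not in self.table.index]
        if missing:
            raise ValidationError(f"samples missing from annotation: {missing}")


def read_sample_annotation(path: str | Path, sep: str | None = None) -> SampleAnnotation:
    sep = _detect_sep(path, sep)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    try:
        return SampleAnnotation(df)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_sample_annotation(
    ann: SampleAnnotation, path: str | Path, sep: str | None = None
) -> None:
    ann.table.to_csv(path, sep=_detect_sep(path, sep), index_label="sample_id")


@dataclass
class MetaboliteSetCollection:
    """Named metabolite sets with free-text descriptions (GMT semantics)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise ValidationError(f"metabolite set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValidationError(f"duplicate members within set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def members(self, name: str) -> list[str]:
        return list(self.sets[name][1])


def read_metabolite_sets(path: str | Path) -> MetaboliteSetCollection:
    """Parse a GMT file: per line, TAB-separated name, description, members.

    Duplicate members within a line are dropped with a warning; duplicate set
    names are a parse error.
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 3 TAB-separated fields, "
                    f"got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            members: list[str] = []
            seen: set[str] = set()
            for member in fields[2:]:
                if not member:
                    continue
                if member in seen:
                    warnings.warn(
                        f"{path}:{lineno}: duplicate member {member!r} in set "
                        f"{name!r}; deduplicated"
                    )
                    continue
                seen.add(member)
                members.append(member)
            sets[name] = (description, members)
    return MetaboliteSetCollection(sets)


def write_metabolite_sets(
    collection: MetaboliteSetCollection, path: str | Path
) -> None:
    with open(path, "w") as handle:
        for name, (description, members) in collection:
            handle.write("\t".join([name, description, *members]) + "\n")
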