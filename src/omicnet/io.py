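"""Readers and writers for the on-disk formats the pipeline touches.

All tabular inputs are plain TSV with header rows; pathway collections use
the standard GMT format (set name, description, tab-separated members).
Validation is strict: duplicate identifiers, non-numeric cells and missing
values are errors unless explicitly relaxed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

FACTORS = ("variety", "location", "stage")
DESIGN_COLUMNS = ("sample_id", "variety", "location", "stage", "replicate")


class ValidationError(ValueError):
    """Input data violates a structural contract (duplicates, schema, range)."""


class ParseError(ValueError):
    """Input file could not be parsed (non-numeric cell, malformed line)."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    s = pd.Index(ids)
    if s.has_duplicates:
        dups = sorted(s[s.duplicated()].unique().tolist())
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class FeatureMatrix:
    """A features-by-samples abundance matrix on the log2 scale.

    ``data`` is indexed by feature id with sample ids as columns.
    ``omics_kind`` is ``"transcript"`` or ``"metabolite"``.
    """

    data: pd.DataFrame
    omics_kind: str
    allow_missing: bool = False

    def __post_init__(self) -> None:
        if self.omics_kind not in ("transcript", "metabolite"):
            raise ValidationError(f"unknown omics_kind: {self.omics_kind!r}")
        _check_unique(self.data.index, "feature ids")
        _check_unique(self.data.columns, "sample ids")
        if self.data.shape[0] < 2 or self.data.shape[1] < 4:
            raise ValidationError(
                f"matrix too small: {self.data.shape}; need >=2 features and >=4 samples"
            )
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ParseError("matrix contains non-numeric values")
        if not self.allow_missing:
            bad = np.argwhere(~np.isfinite(values))
            if bad.size:
                r, c = bad[0]
                raise ValidationError(
                    f"non-finite value at feature {self.data.index[r]!r}, "
                    f"sample {self.data.columns[c]!r} "
                    f"({bad.shape[0]} offending cells total)"
                )

    @property
    def feature_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset(self, feature_ids: Iterable[str]) -> "FeatureMatrix":
        keep = [f for f in feature_ids if f in self.data.index]
        return FeatureMatrix(self.data.loc[keep], self.omics_kind, self.allow_missing)


@dataclass
class SampleDesign:
    """Per-sample factor levels: variety, location, ordered stage, replicate."""

    table: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        missing = [c for c in ("variety", "location", "stage", "replicate") if c not in self.table.columns]
        if missing:
            raise ValidationError(f"design table missing columns: {missing}")
        _check_unique(self.table.index, "sample ids")
        if (self.table["replicate"].astype(int) < 1).any():
            raise ValidationError("replicate numbers must be positive integers")
        if not isinstance(self.table["stage"].dtype, pd.CategoricalDtype):
            order = list(dict.fromkeys(self.table["stage"]))
            self.table = self.table.assign(
                stage=pd.Categorical(self.table["stage"], categories=order, ordered=True)
            )

    @property
    def sample_ids(self) -> list[str]:
        return self.table.index.tolist()

    def levels(self, factor: str) -> list:
        if factor not in FACTORS:
            raise ValidationError(f"unknown factor {factor!r}; expected one of {FACTORS}")
        col = self.table[factor]
        if isinstance(col.dtype, pd.CategoricalDtype):
            return [l for l in col.cat.categories if (col == l).any()]
        return sorted(col.unique().tolist())

    def n_levels(self, factor: str) -> int:
        return len(self.levels(factor))

    def check_for_anova(self) -> None:
        for f in FACTORS:
            if self.n_levels(f) < 2:
                raise ValidationError(f"factor {f!r} has <2 levels; unusable in ANOVA")

    def stage_index(self) -> pd.Series:
        """0-based ordinal position of each sample's stage level."""
        return self.table["stage"].cat.codes.astype(int)


@dataclass
class PathwaySets:
    """Named feature-id sets (curated pathways, module truth, GO slims)."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"pathway set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_feature_matrix(
    path: str | Path,
    omics_kind: str,
    allow_missing: bool = False,
    input_scale: str = "log2",
) -> FeatureMatrix:
    """Read a TSV matrix (first column feature id, header row of sample ids).

    ``input_scale="linear"`` log2-transforms at load (zeros/negatives are
    errors); the pipeline's models consume log2 abundances throughout.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str},
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.argmax()]
                raise ParseError(
                    f"non-numeric cell at (feature {row!r}, sample {col!r}): "
                    f"{df.loc[row, col]!r}"
                )
            df[col] = coerced
    if input_scale == "linear":
        vals = df.to_numpy(dtype=float)
        if np.nanmin(vals) <= 0:
            raise ValidationError("linear-scale input contains values <= 0; cannot log2")
        df = pd.DataFrame(np.log2(vals), index=df.index, columns=df.columns)
    elif input_scale != "log2":
        raise ValidationError(f"input_scale must be 'log2' or 'linear', got {input_scale!r}")
    return FeatureMatrix(df.astype(float), omics_kind, allow_missing)


def read_design(path: str | Path, stage_order: list[str] | None = None) -> SampleDesign:
    """Read the sample design TSV (sample_id, variety, location, stage, replicate).

    Stage levels are ordered by first appearance unless ``stage_order`` is given.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"design table missing columns: {missing}")
    df["replicate"] = df["replicate"].astype(int)
    df = df.set_index("sample_id")
    if stage_order is not None:
        unknown = set(df["stage"]) - set(stage_order)
        if unknown:
            raise ValidationError(f"stage levels not in given order: {sorted(unknown)}")
        df["stage"] = pd.Categorical(df["stage"], categories=stage_order, ordered=True)
    return SampleDesign(df)


def read_gmt(path: str | Path) -> PathwaySets:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>members...``."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields; need "
                    "name, description and at least one member"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ParseError(f"{path}:{lineno}: GMT set {name!r} has no members")
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = set(members)
            descriptions[name] = desc
    return PathwaySets(sets, descriptions)


def write_gmt(pathways: PathwaySets, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(pathways.sets):
            desc = pathways.descriptions.get(name, "")
            members = "\t".join(sorted(pathways.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    """Write at full precision so that a read-back reproduces values bit-exactly."""
    df = fm.data.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format=None)


def write_design(design: SampleDesign, path: str | Path) -> None:
    df = design.table.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Deterministic TSV writer for result tables (column order as given)."""
    df.to_csv(path, sep="\t", index=index)


def align_to_design(fm: FeatureMatrix, design: SampleDesign) -> FeatureMatrix:
    """Reorder matrix samples to the design order (the design is the master order)."""
    missing = [s for s in design.sample_ids if s not in fm.data.columns]
    extra = [s for s in fm.data.columns if s not in design.table.index]
    if missing or extra:
        raise ValidationError(
            f"sample mismatch between matrix and design; missing from matrix: "
            f"{missing[:5]}, absent from design: {extra[:5]}"
        )
    return FeatureMatrix(fm.data.loc[:, design.sample_ids], fm.omics_kind, fm.allow_missing)
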