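"""Typed tables for the cohort, steroid, and untargeted-feature data.

All tables are thin wrappers over :class:`pandas.DataFrame` that validate on
construction and read/write UTF-8 comma- or tab-delimited text (dialect
chosen by the ``.csv``/``.tsv`` extension).  Missing cells are represented
as ``NaN`` in memory; on input the tokens empty string, ``NA`` and ``NaN``
(case-insensitive) are accepted, on output missing cells are written empty.
Validation is total: malformed input raises a typed error, never a silent
coercion.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import STEROIDS, canonical_steroid

GROUPS = ("NFAT", "MACS1", "MACS2", "CS")
#: 1 mg-dexamethasone suppression test cortisol windows (nmol/L) per group.
DST_WINDOWS = {"NFAT": (0.0, 50.0), "MACS1": (51.0, 138.0), "MACS2": (138.0, np.inf)}

_NA_TOKENS = ["", "NA", "na", "Na", "NaN", "nan", "NAN"]


class SchemaError(ValueError):
    """A required column is absent or the file layout is wrong."""


class ValidationError(ValueError):
    """Values are present but violate a table invariant."""


class PipelineOrderError(RuntimeError):
    """A preprocessing stage was invoked out of its fixed order."""


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


def _read_delimited(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(
        path, sep=_sep_for(path), na_values=_NA_TOKENS, keep_default_na=False, **kw
    )


def _write_delimited(df: pd.DataFrame, path: str | Path, index: bool) -> None:
    df.to_csv(path, sep=_sep_for(path), na_rep="", index=index)


# --------------------------------------------------------------------------
# CohortTable
# --------------------------------------------------------------------------

_COHORT_REQUIRED = ("patient_id", "group", "sex", "age", "bmi",
                    "hypertension", "t2d", "bilateral")
_COHORT_OPTIONAL = ("dyslipidaemia", "dst_cortisol")
_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False,
             "yes": True, "no": False, True: True, False: False, 1: True, 0: False}


@dataclasses.dataclass
class CohortTable:
    """Per-patient clinical record with diagnostic group and comorbidities."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in _COHORT_REQUIRED if c not in df.columns]
        if missing:
            raise SchemaError(f"cohort table missing required columns: {missing}")
        if df["patient_id"].duplicated().any():
            dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
            raise ValidationError(f"duplicate patient_id: {dup!r}")
        bad = set(df["group"]) - set(GROUPS)
        if bad:
            raise ValidationError(f"unknown diagnostic group(s): {sorted(bad)}")
        if not set(df["sex"]) <= {"F", "M"}:
            raise ValidationError("sex must be 'F' or 'M'")
        for col in ("age", "bmi"):
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                raise ValidationError(f"non-numeric {col}")
            if (vals <= 0).any():
                raise ValidationError(f"{col} must be positive")
            df[col] = vals.astype(float)
        for col in ("hypertension", "t2d", "bilateral", "dyslipidaemia"):
            if col not in df.columns:
                continue
            try:
                df[col] = df[col].map(
                    lambda v: v if (isinstance(v, float) and np.isnan(v))
                    else _BOOL_MAP[str(v).lower() if not isinstance(v, (bool, np.bool_)) else bool(v)]
                )
            except KeyError as exc:
                raise ValidationError(f"non-boolean value in {col}: {exc}") from exc
        if "dst_cortisol" in df.columns:
            vals = pd.to_numeric(df["dst_cortisol"], errors="coerce")
            if ((vals < 0) & vals.notna()).any():
                raise ValidationError("dst_cortisol must be non-negative")
            df["dst_cortisol"] = vals.astype(float)
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def patient_ids(self) -> pd.Series:
        return self.df["patient_id"]

    def check_dst_consistency(self) -> None:
        """Raise if any DST cortisol value contradicts its diagnostic group.

        NFAT requires post-dexamethasone cortisol <= 50 nmol/L, MACS1
        51-138 nmol/L and MACS2 > 138 nmol/L; CS carries no window (its
        definition adds clinical signs on top of failed suppression).
        """
        if "dst_cortisol" not in self.df.columns:
            return
        for _, row in self.df.iterrows():
            v = row["dst_cortisol"]
            if pd.isna(v) or row["group"] not in DST_WINDOWS:
                continue
            lo, hi = DST_WINDOWS[row["group"]]
            ok = (v <= 50.0) if row["group"] == "NFAT" else (lo <= v <= hi if row["group"] == "MACS1" else v > 138.0)
            if not ok:
                raise ValidationError(
                    f"patient {row['patient_id']!r}: DST cortisol {v} nmol/L "
                    f"inconsistent with group {row['group']}"
                )


def read_cohort(path: str | Path, strict: bool = False) -> CohortTable:
    """Read a cohort table; with ``strict=True`` also enforce DST windows."""
    table = CohortTable(_read_delimited(path, dtype={"patient_id": str}))
    if strict:
        table.check_dst_consistency()
    return table


def write_cohort(table: CohortTable, path: str | Path) -> None:
    _write_delimited(table.df, path, index=False)


# --------------------------------------------------------------------------
# SteroidMatrix
# --------------------------------------------------------------------------


@dataclasses.dataclass
class SteroidMatrix:
    """Patients x 17 urinary steroid excretions (ug / 24 h).

    Columns are canonicalised against the packaged panel; unknown metabolite
    names are rejected.
    """

    df: pd.DataFrame  # index: patient_id, columns: STEROIDS

    def __post_init__(self) -> None:
        df = self.df
        try:
            df = df.rename(columns={c: canonical_steroid(c) for c in df.columns})
        except KeyError as exc:
            raise SchemaError(str(exc)) from exc
        missing = [s for s in STEROIDS if s not in df.columns]
        if missing:
            raise SchemaError(f"steroid matrix missing metabolites: {missing}")
        df = df[list(STEROIDS)]
        vals = df.apply(pd.to_numeric, errors="coerce")
        if vals.isna().any().any():
            raise ValidationError("non-numeric steroid excretion value")
        if (vals < 0).any().any():
            raise ValidationError("steroid excretions must be >= 0")
        if df.index.duplicated().any():
            raise ValidationError("duplicate patient_id in steroid matrix")
        self.df = vals.astype(float)

    def aligned_to(self, cohort: CohortTable) -> "SteroidMatrix":
        """Return rows reordered to the cohort's patients; all must exist."""
        ids = cohort.patient_ids
        extra = set(self.df.index) - set(ids)
        if extra:
            raise ValidationError(f"steroid rows without cohort record: {sorted(extra)[:3]}")
        return SteroidMatrix(self.df.loc[[i for i in ids if i in self.df.index]].copy())

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()


def read_steroids(path: str | Path) -> SteroidMatrix:
    df = _read_delimited(path, index_col=0)
    df.index = df.index.astype(str)
    return SteroidMatrix(df)


def write_steroids(matrix: SteroidMatrix, path: str | Path) -> None:
    _write_delimited(matrix.df.rename_axis("patient_id"), path, index=True)


# --------------------------------------------------------------------------
# FeatureTable
# --------------------------------------------------------------------------

_META_REQUIRED = ("sample_id", "sample_type", "injection_order", "assay", "ion_mode")
#: fixed preprocessing order; see preprocess module
STAGES = ("raw", "corrected", "filtered", "normalised")


@dataclasses.dataclass
class FeatureTable:
    """Samples x untargeted metabolite features with missing values.

    ``abundances`` is indexed by sample_id; ``metadata`` carries sample type
    (study / pooled QC), injection order, assay and ion mode.  ``stage``
    tracks progress through the fixed preprocessing order
    raw -> corrected -> filtered -> normalised.
    """

    abundances: pd.DataFrame
    metadata: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        meta = self.metadata
        missing = [c for c in _META_REQUIRED if c not in meta.columns]
        if missing:
            raise SchemaError(f"feature metadata missing columns: {missing}")
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        bad = set(meta["sample_type"]) - {"study", "QC"}
        if bad:
            raise ValidationError(f"unknown sample_type(s): {sorted(bad)}")
        meta = meta.copy()
        meta["injection_order"] = pd.to_numeric(meta["injection_order"], errors="raise").astype(int)
        if (meta["injection_order"] <= 0).any():
            raise ValidationError("injection_order must be positive")
        for _, batch in meta.groupby(["assay", "ion_mode"]):
            if batch["injection_order"].duplicated().any():
                raise ValidationError("duplicate injection_order within an assay/ion-mode batch")
        ab = self.abundances
        unknown = set(ab.index) - set(meta["sample_id"])
        if unknown:
            raise SchemaError(
                f"samples in abundance matrix absent from metadata: {sorted(unknown)[:3]}"
            )
        ab = ab.apply(pd.to_numeric, errors="coerce").astype(float)
        if self.stage in ("raw", "corrected") and (ab < 0).any().any():
            raise ValidationError("abundances must be >= 0 or missing")
        meta = meta.set_index("sample_id", drop=False)
        ab.index.name = "sample_id"
        self.metadata = meta.loc[ab.index]
        self.abundances = ab

    # convenience views -----------------------------------------------------
    @property
    def is_qc(self) -> pd.Series:
        return self.metadata["sample_type"] == "QC"

    @property
    def qc(self) -> pd.DataFrame:
        return self.abundances.loc[self.is_qc]

    @property
    def study(self) -> pd.DataFrame:
        return self.abundances.loc[~self.is_qc]

    @property
    def n_missing(self) -> int:
        return int(self.abundances.isna().sum().sum())

    def require_stage(self, *allowed: str) -> None:
        if self.stage not in allowed:
            raise PipelineOrderError(
                f"operation requires stage in {allowed}, table is {self.stage!r}"
            )

    def with_abundances(self, ab: pd.DataFrame, stage: str) -> "FeatureTable":
        return FeatureTable(ab, self.metadata.reset_index(drop=True), stage=stage)


def read_feature_table(path: str | Path, metadata_path: str | Path,
                       stage: str = "raw") -> FeatureTable:
    """Read an abundance matrix + metadata; ``stage`` restores provenance
    for tables written after preprocessing (e.g. ``"normalised"``, whose
    z-scores may legitimately be negative)."""
    ab = _read_delimited(path, index_col=0)
    ab.index = ab.index.astype(str)
    meta = _read_delimited(metadata_path, dtype={"sample_id": str})
    return FeatureTable(ab, meta, stage=stage)


def write_feature_table(table: FeatureTable, path: str | Path,
                        metadata_path: str | Path) -> None:
    _write_delimited(table.abundances.rename_axis("sample_id"), path, index=True)
    _write_delimited(table.metadata.reset_index(drop=True), metadata_path, index=False)


# --------------------------------------------------------------------------
# AnnotationMap
# --------------------------------------------------------------------------


@dataclasses.dataclass
class AnnotationMap:
    """feature_id -> set of class labels (lipid class or pathway id)."""

    mapping: dict[str, frozenset[str]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        stray = set(self.mapping) - set(self.background)
        if stray:
            raise ValidationError(
                f"annotated features outside background: {sorted(stray)[:3]}"
            )
        self.mapping = {k: frozenset(v) for k, v in self.mapping.items()}
        self.background = frozenset(self.background)

    def classes(self) -> dict[str, set[str]]:
        """Invert to class label -> member feature ids."""
        out: dict[str, set[str]] = {}
        for feat, labels in self.mapping.items():
            for lab in labels:
                out.setdefault(lab, set()).add(feat)
        return out


def read_annotations(path: str | Path, background: set[str] | None = None) -> AnnotationMap:
    """Read a two-column (feature_id, label) table; one row per pairing."""
    df = _read_delimited(path, dtype=str)
    if not {"feature_id", "label"} <= set(df.columns):
        raise SchemaError("annotation table needs columns feature_id,label")
    mapping: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        mapping.setdefault(row["feature_id"], set()).add(row["label"])
    bg = frozenset(background) if background is not None else frozenset(mapping)
    return AnnotationMap({k: frozenset(v) for k, v in mapping.items()}, bg)
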