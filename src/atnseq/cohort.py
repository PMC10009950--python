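"""Cohort tables and analysis configuration.

A cohort is one row per participant: CSF biomarkers (Aβ42/Aβ40 ratio,
phospho-tau, total tau), hippocampal volume, the five standard covariates
(age, sex, education, total intracranial volume, white-matter-hyperintensity
load) and an optional clinical diagnosis.  The table is the substrate for
ATN classification and for every model fit downstream; missing biomarker
values are preserved as missing (never imputed) and surfaced explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, SchemaError, ValidationError

__all__ = [
    "REQUIRED_COLUMNS",
    "COVARIATE_COLUMNS",
    "MARKER_COLUMNS",
    "CohortTable",
    "AnalysisConfig",
    "read_cohort_table",
    "write_cohort_table",
    "validate_config",
    "load_config",
]

#: Covariates adjusted for throughout: age (years), sex (0 = male,
#: 1 = female), education (years), TICV (ml), WMH (ml).
COVARIATE_COLUMNS: tuple[str, ...] = ("age", "sex", "education", "ticv", "wmh")

#: Biomarkers: Aβ42/Aβ40 ratio (unitless), p-tau181 and total tau (pg/ml),
#: hippocampal volume (μl).
MARKER_COLUMNS: tuple[str, ...] = (
    "abeta_ratio",
    "ptau",
    "ttau",
    "hippocampal_volume",
)

REQUIRED_COLUMNS: tuple[str, ...] = ("subject_id",) + COVARIATE_COLUMNS + MARKER_COLUMNS

VALID_DIAGNOSES = {"NC", "SCD", "MCI", "DAT"}

# columns that must be strictly positive / non-negative when present
_POSITIVE = ("age", "ticv")
_NONNEGATIVE = ("education", "wmh", "abeta_ratio", "ptau", "ttau", "hippocampal_volume")


@dataclass
class CohortTable:
    """Validated participant table plus provenance metadata.

    ``df`` keeps one row per subject in input order; biomarker units are
    recorded in ``units``.  Access rows as plain pandas; helpers below cover
    the common alignment and missingness queries.
    """

    df: pd.DataFrame
    source: str | None = None
    units: dict[str, str] = field(default_factory=lambda: {
        "abeta_ratio": "ratio", "ptau": "pg/ml", "ttau": "pg/ml",
        "hippocampal_volume": "ul", "ticv": "ml", "wmh": "ml",
        "age": "years", "education": "years",
    })

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        ids = self.df["subject_id"].astype(str)
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate subject_id(s): {dupes}")
        df = self.df.copy()
        df["subject_id"] = ids
        for col in COVARIATE_COLUMNS + MARKER_COLUMNS:
            df[col] = pd.to_numeric(df[col], errors="coerce")
        for col in _POSITIVE:
            bad = df.loc[df[col].notna() & (df[col] <= 0), "subject_id"]
            if len(bad):
                raise ValidationError(f"{col} must be > 0 (subjects {bad.tolist()})")
        for col in _NONNEGATIVE:
            bad = df.loc[df[col].notna() & (df[col] < 0), "subject_id"]
            if len(bad):
                raise ValidationError(f"{col} must be >= 0 (subjects {bad.tolist()})")
        if "diagnosis" in df.columns:
            known = df["diagnosis"].dropna()
            bad = set(known) - VALID_DIAGNOSES
            if bad:
                raise ValidationError(f"unknown diagnosis label(s): {sorted(bad)}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def subject_ids(self) -> list[str]:
        return self.df["subject_id"].tolist()

    def missing_markers(self, markers: tuple[str, ...] | list[str]) -> pd.Series:
        """Boolean per subject: any of the given markers missing."""
        return self.df[list(markers)].isna().any(axis=1)

    def covariate_matrix(self, covariates: list[str] | None = None) -> pd.DataFrame:
        cols = list(covariates) if covariates is not None else list(COVARIATE_COLUMNS)
        unknown = [c for c in cols if c not in self.df.columns]
        if unknown:
            raise SchemaError(f"unknown covariate column(s): {unknown}")
        return self.df[cols]


def read_cohort_table(path: str | Path) -> CohortTable:
    """Read a CSV/TSV cohort table (UTF-8, header row) and validate it.

    The delimiter follows the file extension (``.tsv``/``.txt`` → tab,
    otherwise comma).  Missing cells stay missing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, encoding="utf-8")
    return CohortTable(df=df, source=str(path))


def write_cohort_table(table: CohortTable, path: str | Path) -> Path:
    """Write the cohort back to CSV/TSV (extension picks the delimiter)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    table.df.to_csv(path, sep=sep, index=False, encoding="utf-8")
    return path


_N_MARKERS = ("ahv", "ttau")
_SEQUENCE_SETS = ("permutations24", "paths6", "custom")


@dataclass
class AnalysisConfig:
    """Everything tunable about a run, with field-level validation.

    Cutoffs may be numbers or the directive ``"gmm"`` (estimate from the
    data by two-component Gaussian mixture); the N-category marker is either
    adjusted hippocampal volume (``"ahv"``) or CSF total tau (``"ttau"``).
    """

    n_marker: str = "ahv"
    abeta_cutoff: float | str = 0.09
    ptau_cutoff: float | str = 57.0
    n_cutoff: float | str = "gmm"
    covariates: list[str] = field(default_factory=lambda: list(COVARIATE_COLUMNS))
    sequence_set: str = "permutations24"
    gm_threshold: float = 0.05
    fdr_q: float = 0.05
    seed: int = 0
    min_group_size: int = 3
    adjust_on: str = "all"  # or "atn_negative": restrict aHV fit to A-T-N-
    hippocampal_volume_unit: str = "ul"  # "ml" inputs converted on read

    def __post_init__(self) -> None:
        if self.n_marker not in _N_MARKERS:
            raise ConfigError(
                f"unsupported N marker {self.n_marker!r}; choose from {_N_MARKERS}"
            )
        for name in ("abeta_cutoff", "ptau_cutoff", "n_cutoff"):
            val = getattr(self, name)
            if isinstance(val, str):
                if val != "gmm":
                    raise ConfigError(f"{name}: non-numeric cutoff {val!r}")
            elif not np.isfinite(val) or val <= 0:
                raise ConfigError(f"{name}: cutoff must be finite and positive")
        if not 0 < self.gm_threshold < 1:
            raise ConfigError("gm_threshold must lie in (0, 1)")
        if not 0 < self.fdr_q < 1:
            raise ConfigError("fdr_q must lie in (0, 1)")
        unknown = set(self.covariates) - set(COVARIATE_COLUMNS)
        if unknown:
            raise ConfigError(f"unknown covariate(s): {sorted(unknown)}")
        if self.sequence_set not in _SEQUENCE_SETS:
            raise ConfigError(f"unknown sequence set {self.sequence_set!r}")
        if self.min_group_size < 1:
            raise ConfigError("min_group_size must be >= 1")
        if self.hippocampal_volume_unit not in ("ul", "ml"):
            raise ConfigError("hippocampal_volume_unit must be 'ul' or 'ml'")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def validate_config(raw: Mapping[str, Any] | None = None) -> AnalysisConfig:
    """Build an :class:`AnalysisConfig` from a raw mapping, filling defaults.

    Unknown keys raise; an empty/None mapping yields the standard defaults
    (GM threshold 0.05, FDR q 0.05, all five covariates).
    """
    raw = dict(raw or {})
    valid = set(AnalysisConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    return AnalysisConfig(**raw)


def load_config(path: str | Path) -> AnalysisConfig:
    """Load YAML (or JSON — a YAML subset) configuration from disk."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    return validate_config(raw)
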