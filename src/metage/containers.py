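"""Core tabular containers: feature tables and sample metadata.

Both are thin, validated wrappers around pandas DataFrames with TSV
round-tripping, so that every stage of the pipeline exchanges the same
plain-text artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "SampleMetadata", "LEVELS"]

LEVELS = ("ko", "module", "pathway", "both")

METADATA_COLUMNS = [
    "sample_id",
    "subject_id",
    "age_months",
    "cohort",
    "breastfed",
    "formula_fed",
    "abx_current",
    "abx_prior",
]


@dataclass
class FeatureTable:
    """Features x samples nonnegative abundance matrix.

    Parameters
    ----------
    data : DataFrame
        Rows indexed by feature id, columns by sample id, values
        nonnegative finite abundances.
    level : {"ko", "module", "pathway"}
        Functional resolution of the rows.
    normalized : bool
        Whether abundances have been scaled by the per-sample median of
        universal single-copy genes (approximate average copy number per
        cell).
    """

    data: pd.DataFrame
    level: str
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}, got {self.level!r}")
        if not self.data.index.is_unique:
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dup[:5]}")
        if not self.data.columns.is_unique:
            raise ValueError("duplicate sample ids")
        values = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("abundances must be finite")
        if (values < 0).any():
            raise ValueError("abundances must be nonnegative")
        self.data = self.data.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids) -> "FeatureTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in table: {missing[:5]}")
        return FeatureTable(self.data[list(sample_ids)], self.level, self.normalized)

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = f"{self.level}_id"
        out.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, level: str, normalized: bool = False) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(df, level, normalized)


@dataclass
class SampleMetadata:
    """Per-sample subject, age, cohort and covariate flags."""

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"sample_id", "subject_id", "age_months", "cohort"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        if self.data["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in metadata")
        ages = self.data["age_months"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ages)) or (ages <= 0).any():
            raise ValueError("age_months must be finite and positive")
        self.data = self.data.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def cohorts(self) -> list[str]:
        return sorted(self.data["cohort"].unique())

    @property
    def timepoints(self) -> list[float]:
        return sorted(self.data["age_months"].unique())

    def samples_at(self, cohort: str, timepoint: float) -> list[str]:
        mask = (self.data["cohort"] == cohort) & (self.data["age_months"] == timepoint)
        return list(self.data.loc[mask, "sample_id"])

    def ages_for(self, sample_ids) -> np.ndarray:
        lookup = self.data.set_index("sample_id")["age_months"]
        return lookup.loc[list(sample_ids)].to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        cols = [c for c in METADATA_COLUMNS if c in self.data.columns]
        cols += [c for c in self.data.columns if c not in cols]
        self.data[cols].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SampleMetadata":
        df = pd.read_csv(path, sep="\t")
        df["sample_id"] = df["sample_id"].astype(str)
        return cls(df)


def read_universal_kos(path) -> list[str]:
    """Read a universal single-copy KO list, one id per line."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]
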