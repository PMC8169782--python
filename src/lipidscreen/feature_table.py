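"""Lipid feature x sample intensity matrix with metadata and preprocessing.

The on-disk layout is two CSV files: ``table.csv`` with features as rows
(columns ``feature_id``, ``mz``, ``annotation``, then one column per
sample) and ``samples.csv`` with per-sample metadata (``sample_id``,
``group``, ``matrix``, ``is_qc``).

Preprocessing operations never touch samples: only features may be
dropped, and the sample order is preserved.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "MATRICES",
    "SampleInfo",
    "FeatureTable",
    "read_table",
    "write_table",
    "tic_normalize",
    "qc_rsd_filter",
    "impute_halfmin",
]

logger = logging.getLogger(__name__)

GROUPS = ("control", "UF", "RUF")
MATRICES = ("plasma", "myometrium", "fibroid")


class TableFormatError(ValueError):
    """Feature table violates the documented format."""


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    group: str
    matrix: str = "plasma"
    is_qc: bool = False

    def __post_init__(self) -> None:
        if not self.is_qc and self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.matrix not in MATRICES:
            raise ValueError(f"matrix must be one of {MATRICES}, got {self.matrix!r}")


@dataclass
class FeatureTable:
    """Intensity matrix (features x samples) plus feature/sample metadata.

    ``intensities`` is a DataFrame indexed by feature id with sample ids
    as columns; ``features`` carries per-feature ``mz`` and ``annotation``;
    ``samples`` is the list of :class:`SampleInfo` in column order.
    """

    intensities: pd.DataFrame
    features: pd.DataFrame
    samples: list[SampleInfo] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.intensities.index.has_duplicates:
            dups = self.intensities.index[self.intensities.index.duplicated()].tolist()
            raise TableFormatError(f"duplicate feature ids: {dups}")
        if (self.intensities.fillna(0).to_numpy() < 0).any():
            bad = self.intensities.index[
                (self.intensities.fillna(0) < 0).any(axis=1)
            ].tolist()
            raise TableFormatError(f"negative intensities in features: {bad}")
        if list(self.features.index) != list(self.intensities.index):
            raise TableFormatError("feature metadata does not match matrix rows")
        ids = [s.sample_id for s in self.samples]
        if ids != list(self.intensities.columns):
            raise TableFormatError("sample metadata does not match matrix columns")

    # -- views -------------------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    @property
    def sample_groups(self) -> pd.Series:
        return pd.Series(
            [s.group for s in self.samples], index=self.intensities.columns)

    @property
    def qc_mask(self) -> np.ndarray:
        return np.array([s.is_qc for s in self.samples])

    def group_columns(self, group: str) -> list[str]:
        cols = [s.sample_id for s in self.samples if s.group == group and not s.is_qc]
        if not cols:
            raise KeyError(f"no samples with group {group!r}")
        return cols

    def subset_features(self, feature_ids) -> "FeatureTable":
        return FeatureTable(
            self.intensities.loc[feature_ids].copy(),
            self.features.loc[feature_ids].copy(),
            list(self.samples),
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.intensities.copy(), self.features.copy(), list(self.samples))


def write_table(table: FeatureTable, table_path, samples_path) -> None:
    """Write ``table.csv`` + ``samples.csv`` (UTF-8, '.' decimals)."""
    out = table.features[["mz", "annotation"]].copy()
    out.insert(0, "feature_id", table.intensities.index)
    df = pd.concat([out.reset_index(drop=True),
                    table.intensities.reset_index(drop=True)], axis=1)
    df.to_csv(table_path, index=False)
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in table.samples],
            "group": [s.group for s in table.samples],
            "matrix": [s.matrix for s in table.samples],
            "is_qc": [s.is_qc for s in table.samples],
        }
    ).to_csv(samples_path, index=False)


def read_table(table_path, samples_path) -> FeatureTable:
    """Read the two-file CSV layout back into a :class:`FeatureTable`."""
    df = pd.read_csv(table_path)
    for col in ("feature_id", "mz", "annotation"):
        if col not in df.columns:
            raise TableFormatError(f"missing column {col!r} in {Path(table_path).name}")
    sdf = pd.read_csv(samples_path)
    samples = [
        SampleInfo(str(r.sample_id), str(r.group), str(r.matrix), bool(r.is_qc))
        for r in sdf.itertuples()
    ]
    sample_cols = [s.sample_id for s in samples]
    missing = [c for c in sample_cols if c not in df.columns]
    if missing:
        raise TableFormatError(f"samples absent from table: {missing}")
    intensities = df[sample_cols].copy()
    intensities.index = pd.Index(df["feature_id"].astype(str), name="feature_id")
    features = df[["mz", "annotation"]].copy()
    features.index = intensities.index
    return FeatureTable(intensities, features, samples)


def tic_normalize(table: FeatureTable) -> FeatureTable:
    """Scale each sample so its total intensity equals the median total.

    Total-ion-current normalization removes gross per-sample loading
    differences while preserving within-sample feature ratios.
    """
    totals = table.intensities.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"samples with non-positive total intensity: {bad}")
    target = float(np.median(totals))
    scaled = table.intensities * (target / totals)
    return FeatureTable(scaled, table.features.copy(), list(table.samples))


def qc_rsd_filter(table: FeatureTable, max_rsd: float = 0.30) -> FeatureTable:
    """Drop features with RSD across QC injections above ``max_rsd``.

    Repeated pooled-QC injections measure purely analytical variability;
    a feature that is unstable there is unreliable in the study samples.
    With fewer than 3 QC samples the filter is skipped with a warning.
    """
    qc = table.qc_mask
    if qc.sum() < 3:
        msg = f"only {int(qc.sum())} QC samples; RSD filter skipped"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
        return table.copy()
    qc_cols = [s.sample_id for s, q in zip(table.samples, qc) if q]
    qc_data = table.intensities[qc_cols]
    mean = qc_data.mean(axis=1)
    sd = qc_data.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = (sd / mean).replace([np.inf, -np.inf], np.nan).fillna(0.0)
    keep = rsd <= max_rsd
    return table.subset_features(table.intensities.index[keep])


def impute_halfmin(table: FeatureTable) -> FeatureTable:
    """Replace zeros/missing with half the feature's minimum positive value;
    features with no positive value anywhere are dropped."""
    mat = table.intensities.to_numpy(dtype=float)
    pos = np.where(mat > 0, mat, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        halfmin = np.nanmin(pos, axis=1) / 2.0
    keep = ~np.isnan(halfmin)
    mat = mat[keep]
    fill = halfmin[keep][:, None]
    mat = np.where((mat > 0) & ~np.isnan(mat), mat, np.broadcast_to(fill, mat.shape))
    ids = table.intensities.index[keep]
    return FeatureTable(
        pd.DataFrame(mat, index=ids, columns=table.intensities.columns),
        table.features.loc[ids].copy(),
        list(table.samples),
    )
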