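"""Core containers for LC-MS normalization.

Three containers cover the inputs of every method in this package:

* :class:`FeatureMatrix` — the p x n intensity matrix (features in rows,
  samples in columns) with per-feature retention time and m/z annotations.
  Missing measurements are stored as NaN, never as zero: several methods
  (median-scale reference choice, quantile normalization) treat missingness
  as first-class information.
* :class:`SampleTable` — per-sample analysis (injection) order, batch,
  experiment (forward/reverse) and group (case / control / QC).
* :class:`EICCollection` — long-format scan-level intensity traces, one row
  per (feature, sample, scan).

All three round-trip losslessly through plain TSV/CSV.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    DuplicateIDError,
    MissingColumnError,
    NegativeIntensityError,
    NonMonotoneScanError,
    ShortTraceError,
    UnknownGroupError,
    ValidationError,
)

logger = logging.getLogger(__name__)

GROUPS = ("case", "control", "QC")

_GROUP_ALIASES = {
    "case": "case",
    "cases": "case",
    "control": "control",
    "controls": "control",
    "ctrl": "control",
    "qc": "QC",
    "qcs": "QC",
    "quality control": "QC",
}

MIN_SCANS = 3  # shortest EIC trace that still supports integration + alignment
MIN_QC_FIT = 3  # fewest QC points accepted by any drift-model fit


def normalize_group_label(label: str) -> str:
    """Canonicalize a group label (case-insensitively) to case/control/QC."""
    key = str(label).strip().lower()
    if key not in _GROUP_ALIASES:
        raise UnknownGroupError(
            f"unknown group label {label!r}; expected one of {sorted(set(_GROUP_ALIASES))}"
        )
    return _GROUP_ALIASES[key]


# ---------------------------------------------------------------------------
# FeatureMatrix
# ---------------------------------------------------------------------------


@dataclass
class FeatureMatrix:
    """p x n matrix of non-negative ion intensities with feature annotations.

    Parameters
    ----------
    values
        Array of shape (p, n); NaN marks a missing measurement.
    feature_ids, sample_ids
        Unique identifiers for rows and columns.
    feature_rt, feature_mz
        Retention time (seconds) and m/z per feature; NaN when unknown.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    feature_rt: np.ndarray | None = None
    feature_mz: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.feature_rt is None:
            self.feature_rt = np.full(self.n_features, np.nan)
        if self.feature_mz is None:
            self.feature_mz = np.full(self.n_features, np.nan)
        self.feature_rt = np.asarray(self.feature_rt, dtype=float)
        self.feature_mz = np.asarray(self.feature_mz, dtype=float)
        self.validate()

    # -- properties ---------------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValidationError("intensity values must be a 2-D array")
        p, n = self.values.shape
        if p < 1 or n < 2:
            raise ValidationError(f"need p >= 1 features and n >= 2 samples, got {p} x {n}")
        for name, ids, expect in (
            ("feature_ids", self.feature_ids, p),
            ("sample_ids", self.sample_ids, n),
        ):
            if len(ids) != expect:
                raise ValidationError(f"{name} has length {len(ids)}, expected {expect}")
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
            if dupes:
                raise DuplicateIDError(f"duplicate {name}: {dupes}")
        if len(self.feature_rt) != p or len(self.feature_mz) != p:
            raise ValidationError("feature_rt / feature_mz length must equal n_features")
        neg = np.argwhere(np.nan_to_num(self.values, nan=0.0) < 0)
        if neg.size:
            i, j = neg[0]
            raise NegativeIntensityError(
                f"negative intensity at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}: {self.values[i, j]}"
            )

    # -- conversion ---------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        """Wide table: feature_id, rt, mz, then one column per sample."""
        df = pd.DataFrame(self.values, columns=self.sample_ids)
        df.insert(0, "mz", self.feature_mz)
        df.insert(0, "rt", self.feature_rt)
        df.insert(0, "feature_id", self.feature_ids)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureMatrix":
        if "feature_id" not in df.columns:
            raise MissingColumnError("feature matrix needs a 'feature_id' column")
        df = df.copy()
        feature_ids = df.pop("feature_id").astype(str).tolist()
        rt = df.pop("rt").to_numpy(float) if "rt" in df.columns else None
        mz = df.pop("mz").to_numpy(float) if "mz" in df.columns else None
        if rt is None or mz is None:
            # feature ids of the form "<rt>_<mz>" carry the annotations
            parsed = _parse_rt_mz(feature_ids)
            if parsed is not None:
                rt_p, mz_p = parsed
                rt = rt if rt is not None else rt_p
                mz = mz if mz is not None else mz_p
        values = df.to_numpy(float)
        return cls(values, feature_ids, df.columns.astype(str).tolist(), rt, mz)

    def copy_with(self, values: np.ndarray) -> "FeatureMatrix":
        """New matrix with the same annotations and replaced values."""
        return FeatureMatrix(
            np.asarray(values, float),
            list(self.feature_ids),
            list(self.sample_ids),
            self.feature_rt.copy(),
            self.feature_mz.copy(),
        )

    def subset_features(self, keep: np.ndarray | list) -> "FeatureMatrix":
        idx = np.asarray(keep)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return FeatureMatrix(
            self.values[idx],
            [self.feature_ids[i] for i in idx],
            list(self.sample_ids),
            self.feature_rt[idx],
            self.feature_mz[idx],
        )

    # -- IO -----------------------------------------------------------------
    def write(self, path, sep: str = "\t") -> None:
        self.to_dataframe().to_csv(path, sep=sep, index=False)


def _parse_rt_mz(ids: list[str]):
    rt, mz = [], []
    for fid in ids:
        parts = fid.split("_")
        if len(parts) != 2:
            return None
        try:
            rt.append(float(parts[0]))
            mz.append(float(parts[1]))
        except ValueError:
            return None
    return np.array(rt), np.array(mz)


def read_feature_matrix(path, sep: str | None = None) -> FeatureMatrix:
    """Read a features-in-rows TSV/CSV into a validated :class:`FeatureMatrix`.

    The delimiter is sniffed (tab vs comma) unless given. The first column is
    ``feature_id``; optional ``rt`` / ``mz`` columns follow; remaining columns
    are samples. Empty cells become NaN (missing), never zero.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if sep is None:
        sep = "\t" if header.count("\t") >= header.count(",") else ","
    names = header.split(sep)
    dup_cols = pd.Index(names)[pd.Index(names).duplicated()].unique().tolist()
    if dup_cols:
        raise DuplicateIDError(f"duplicate sample columns: {dup_cols}")
    df = pd.read_csv(path, sep=sep)
    return FeatureMatrix.from_dataframe(df)


# ---------------------------------------------------------------------------
# SampleTable
# ---------------------------------------------------------------------------


@dataclass
class SampleTable:
    """Per-sample run metadata: analysis order, batch, experiment, group."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "analysis_order", "batch", "group")

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise MissingColumnError(f"sample metadata needs column {col!r}")
        if "experiment" not in df.columns:
            df["experiment"] = "F"
        df["sample_id"] = df["sample_id"].astype(str)
        df["analysis_order"] = df["analysis_order"].astype(int)
        df["batch"] = df["batch"].astype(str)
        df["experiment"] = df["experiment"].astype(str)
        df["group"] = [normalize_group_label(g) for g in df["group"]]
        if (df["analysis_order"] < 1).any():
            raise ValidationError("analysis_order must be a positive integer (1-based)")
        dup = df["sample_id"][df["sample_id"].duplicated()].unique().tolist()
        if dup:
            raise DuplicateIDError(f"duplicate sample_id: {dup}")
        for (b, e), grp in df.groupby(["batch", "experiment"]):
            d = grp["analysis_order"][grp["analysis_order"].duplicated()].unique().tolist()
            if d:
                raise DuplicateIDError(
                    f"duplicate analysis_order within batch {b!r} experiment {e!r}: {d}"
                )
        self.table = df.reset_index(drop=True)

    # -- accessors ----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.table)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def loc(self, sample_ids: list[str]) -> pd.DataFrame:
        """Rows for the given samples, in the given order."""
        idx = self.table.set_index("sample_id")
        missing = [s for s in sample_ids if s not in idx.index]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")
        return idx.loc[sample_ids].reset_index()

    def is_qc(self, sample_ids: list[str]) -> np.ndarray:
        return (self.loc(sample_ids)["group"] == "QC").to_numpy()

    def blocks(self, sample_ids: list[str]):
        """Yield (batch, experiment, column-index array) per run block."""
        meta = self.loc(sample_ids)
        for (b, e), grp in meta.groupby(["batch", "experiment"], sort=True):
            yield b, e, grp.index.to_numpy()

    def n_qc(self) -> int:
        return int((self.table["group"] == "QC").sum())

    # -- IO -----------------------------------------------------------------
    def write(self, path) -> None:
        self.table.to_csv(path, index=False)


def read_sample_metadata(path) -> SampleTable:
    """Read a CSV of sample metadata into a validated :class:`SampleTable`."""
    return SampleTable(pd.read_csv(path))


# ---------------------------------------------------------------------------
# EICCollection
# ---------------------------------------------------------------------------


@dataclass
class EICCollection:
    """Scan-level extracted-ion-chromatogram traces in long format.

    One row per (feature, sample, scan); within a trace scan indices are
    strictly increasing and retention times non-decreasing. Traces shorter
    than :data:`MIN_SCANS` scans are excluded at validation with a warning.
    """

    table: pd.DataFrame
    excluded: list[tuple[str, str]] = field(default_factory=list)

    COLUMNS = ("feature_id", "sample_id", "scan_index", "rt", "intensity")

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in self.COLUMNS:
            if col not in df.columns:
                raise MissingColumnError(f"EIC table needs column {col!r}")
        df["feature_id"] = df["feature_id"].astype(str)
        df["sample_id"] = df["sample_id"].astype(str)
        df["scan_index"] = df["scan_index"].astype(int)
        df["rt"] = df["rt"].astype(float)
        df["intensity"] = df["intensity"].astype(float)
        if (df["intensity"].dropna() < 0).any():
            raise NegativeIntensityError("negative intensity in EIC table")
        if (df["scan_index"] < 1).any():
            raise ValidationError("scan_index must be >= 1")
        df = df.sort_values(["feature_id", "sample_id", "scan_index"], kind="stable")
        keep_parts, excluded = [], []
        for (fid, sid), grp in df.groupby(["feature_id", "sample_id"], sort=True):
            s = grp["scan_index"].to_numpy()
            if np.any(np.diff(s) <= 0):
                raise NonMonotoneScanError(
                    f"scan_index not strictly increasing for feature {fid!r}, sample {sid!r}"
                )
            if np.any(np.diff(grp["rt"].to_numpy()) < 0):
                raise NonMonotoneScanError(
                    f"rt decreasing within trace for feature {fid!r}, sample {sid!r}"
                )
            if len(grp) < MIN_SCANS:
                excluded.append((fid, sid))
                continue
            keep_parts.append(grp)
        for fid, sid in excluded:
            msg = f"EIC trace ({fid!r}, {sid!r}) has < {MIN_SCANS} scans; excluded"
            warnings.warn(msg, stacklevel=2)
            logger.warning(msg)
        if not keep_parts:
            raise ShortTraceError("no EIC trace has the minimum number of scans")
        self.table = pd.concat(keep_parts, ignore_index=True)
        self.excluded = excluded

    # -- accessors ----------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return sorted(self.table["feature_id"].unique().tolist())

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.table["sample_id"].unique().tolist())

    def trace(self, feature_id: str, sample_id: str) -> pd.DataFrame:
        t = self.table[
            (self.table["feature_id"] == str(feature_id))
            & (self.table["sample_id"] == str(sample_id))
        ]
        if t.empty:
            raise KeyError(f"no trace for ({feature_id!r}, {sample_id!r})")
        return t.reset_index(drop=True)

    def scan_counts(self) -> pd.Series:
        """Scans per (feature, sample) trace."""
        return self.table.groupby(["feature_id", "sample_id"]).size()

    # -- IO -----------------------------------------------------------------
    def write(self, path, sep: str = "\t") -> None:
        self.table.to_csv(path, sep=sep, index=False)


def read_eic_table(path, sep: str = "\t") -> EICCollection:
    """Read a long-format EIC TSV into a validated :class:`EICCollection`."""
    return EICCollection(pd.read_csv(path, sep=sep))


def read_eic_mzml(
    path,
    feature_ids: list[str],
    feature_rt: np.ndarray,
    feature_mz: np.ndarray,
    sample_id: str,
    mz_tol: float = 0.01,
    rt_window: float = 30.0,
) -> pd.DataFrame:
    """Extract EIC traces from an mzML file by windowed summation.

    For each feature, sums intensity within ``feature_mz`` +/- ``mz_tol`` Da
    across scans whose RT lies within ``feature_rt`` +/- ``rt_window`` s.
    Returns a long-format DataFrame ready for :class:`EICCollection`.
    """
    from pyteomics import mzml as _mzml

    rows = []
    feats = list(zip(feature_ids, np.asarray(feature_rt, float), np.asarray(feature_mz, float)))
    with _mzml.read(str(path)) as reader:
        for spec in reader:
            if spec.get("ms level", 1) != 1:
                continue
            rt = float(spec["scanList"]["scan"][0]["scan start time"])
            if "second" not in str(
                spec["scanList"]["scan"][0].get("scan start time", "")
            ):  # pyteomics returns unitfloat; minutes are the mzML default
                rt_s = rt * 60.0 if rt < 300 else rt
            else:
                rt_s = rt
            mz_arr = np.asarray(spec["m/z array"], float)
            int_arr = np.asarray(spec["intensity array"], float)
            sidx = int(spec.get("index", 0)) + 1
            for fid, frt, fmz in feats:
                if not (frt - rt_window <= rt_s <= frt + rt_window):
                    continue
                sel = np.abs(mz_arr - fmz) <= mz_tol
                rows.append(
                    {
                        "feature_id": fid,
                        "sample_id": sample_id,
                        "scan_index": sidx,
                        "rt": rt_s,
                        "intensity": float(int_arr[sel].sum()),
                    }
                )
    return pd.DataFrame(rows, columns=list(EICCollection.COLUMNS))
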