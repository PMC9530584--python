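"""Reading and writing CGM traces, cohort metadata and analysis reports.

File formats are deliberately plain: long-format CSV for glucose traces
(``patient_id,timestamp,glucose_mmol_l`` with ISO-8601 UTC timestamps), a flat
cohort CSV (``patient_id,diagnosis,fcp_ng_ml,c2h_ng_ml,insulin_treated``), and
JSON plus a per-fold CSV for classification reports.

On ingest each patient's samples are regularized onto the nominal sampling
grid (default 5 min): gaps of at most 15 minutes are linearly interpolated
(counted and logged), longer gaps split the trace into contiguous segments so
that downstream detrending windows never span a sensor dropout. Glucose values
outside the plausible sensor range [2.2, 22.2] mmol/L are flagged, never
silently clipped or dropped.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    DuplicateSampleError,
    FormatError,
    InputError,
    JoinError,
    ParseError,
)

logger = logging.getLogger(__name__)

#: plausible interstitial-glucose sensor dynamic range, mmol/L
SENSOR_RANGE = (2.2, 22.2)
#: gaps up to this many seconds are filled by linear interpolation
MAX_INTERP_GAP_S = 900

DIAGNOSES = ("LADA", "T2DM")

_CGM_COLUMNS = ("patient_id", "timestamp", "glucose_mmol_l")
_COHORT_COLUMNS = ("patient_id", "diagnosis", "fcp_ng_ml", "c2h_ng_ml", "insulin_treated")

_DEFAULT_START = pd.Timestamp("2000-01-01T00:00:00", tz="UTC")


@dataclass
class GlucoseTrace:
    """One patient's regularized CGM glucose series.

    ``time_s`` holds seconds since the first sample on the nominal grid;
    ``start_time`` anchors the series in absolute (UTC) time for
    serialization only — all analysis works on the relative grid.
    """

    patient_id: str
    time_s: np.ndarray
    values: np.ndarray
    sampling_interval: int = 300
    start_time: pd.Timestamp = _DEFAULT_START
    n_interpolated: int = 0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.time_s.shape != self.values.shape:
            raise InputError("time_s and values must be 1-D arrays of equal length")
        if len(self.values) < 2:
            raise InputError(f"trace {self.patient_id!r}: need at least 2 samples")
        if not np.all(np.diff(self.time_s) > 0):
            raise InputError(f"trace {self.patient_id!r}: timestamps not strictly increasing")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise InputError(f"trace {self.patient_id!r}: glucose values must be finite and > 0")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def out_of_range(self) -> np.ndarray:
        """Boolean mask of samples outside the plausible sensor range."""
        lo, hi = SENSOR_RANGE
        return (self.values < lo) | (self.values > hi)

    def segments(self) -> list[slice]:
        """Contiguous runs on the nominal grid (split at unfilled gaps)."""
        breaks = np.flatnonzero(np.diff(self.time_s) > self.sampling_interval)
        starts = np.concatenate(([0], breaks + 1))
        stops = np.concatenate((breaks + 1, [len(self.values)]))
        return [slice(int(a), int(b)) for a, b in zip(starts, stops)]

    def longest_segment(self) -> int:
        return max(s.stop - s.start for s in self.segments())


@dataclass
class PatientRecord:
    """A trace joined with diagnosis and beta-cell function markers.

    ``trace`` may be None for table-only workflows (e.g. classifying from a
    precomputed fluctuation-profile CSV); operations that need raw glucose
    will then raise.
    """

    patient_id: str
    diagnosis: str
    fcp: float
    c2h: float
    insulin_treated: bool
    trace: GlucoseTrace | None = None

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise InputError(
                f"diagnosis must be one of {DIAGNOSES}, got {self.diagnosis!r}"
            )
        for name in ("fcp", "c2h"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InputError(f"{name} must be finite and non-negative, got {v!r}")


@dataclass
class Cohort:
    """Ordered collection of patient records with unique ids."""

    records: list[PatientRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"duplicate patient ids in cohort: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def patient_ids(self) -> list[str]:
        return [r.patient_id for r in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.diagnosis for r in self.records])

    @property
    def fcp(self) -> np.ndarray:
        return np.array([r.fcp for r in self.records], dtype=float)

    @property
    def c2h(self) -> np.ndarray:
        return np.array([r.c2h for r in self.records], dtype=float)

    @property
    def traces(self) -> list[GlucoseTrace]:
        if any(r.trace is None for r in self.records):
            raise InputError("cohort has records without glucose traces")
        return [r.trace for r in self.records]

    def subset(self, mask) -> "Cohort":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return Cohort([self.records[int(i)] for i in idx])

    def insulin_treated_only(self) -> "Cohort":
        return Cohort([r for r in self.records if r.insulin_treated])


def _regularize(rel_s: np.ndarray, values: np.ndarray, interval: int,
                max_gap: int = MAX_INTERP_GAP_S) -> tuple[np.ndarray, np.ndarray, int]:
    """Snap an irregular series onto the nominal grid.

    Grid points falling inside an observation gap <= ``max_gap`` seconds are
    linearly interpolated; points inside longer gaps are dropped (the trace
    splits there). Returns (grid_times, grid_values, n_interpolated).
    """
    grid = np.arange(0, rel_s[-1] + 1, interval, dtype=np.int64)
    right = np.searchsorted(rel_s, grid, side="left")
    exact = (right < len(rel_s)) & (rel_s[np.minimum(right, len(rel_s) - 1)] == grid)
    left = np.clip(right - 1, 0, len(rel_s) - 1)
    right = np.clip(right, 0, len(rel_s) - 1)
    gap = rel_s[right] - rel_s[left]
    keep = exact | (gap <= max_gap)
    vals = np.interp(grid, rel_s, values)
    # exact grid hits keep the observed value bit-for-bit (interp can be 1 ulp off)
    vals[exact] = values[np.searchsorted(rel_s, grid[exact])]
    n_interp = int(np.sum(keep & ~exact))
    return grid[keep], vals[keep], n_interp


def read_cgm_csv(path: str | Path, sampling_interval: int = 300) -> list[GlucoseTrace]:
    """Read a long-format CGM CSV into one :class:`GlucoseTrace` per patient.

    Raises :class:`FormatError` for missing columns, :class:`ParseError`
    (with 1-based data row number) for non-numeric glucose or unparseable
    timestamps, and :class:`DuplicateSampleError` for repeated
    (patient, timestamp) pairs.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    for col in _CGM_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"CGM file {path} is missing required column {col!r}")

    glucose = pd.to_numeric(df["glucose_mmol_l"], errors="coerce")
    bad = glucose.isna() & df["glucose_mmol_l"].notna() | df["glucose_mmol_l"].isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ParseError(
            f"non-numeric glucose value {df['glucose_mmol_l'].iloc[row - 1]!r} "
            f"in data row {row}", row=row)
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True, format="ISO8601")
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna().to_numpy())[0]) + 1
        raise ParseError(f"unparseable timestamp in data row {row}", row=row)

    df = df.assign(_ts=ts, _glu=glucose)
    if df.duplicated(subset=["patient_id", "_ts"]).any():
        dupes = df[df.duplicated(subset=["patient_id", "_ts"], keep=False)]
        pairs = dupes[["patient_id", "_ts"]].drop_duplicates().values[:5]
        raise DuplicateSampleError(
            f"duplicate (patient, timestamp) samples, e.g. {pairs.tolist()}")

    traces = []
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("_ts")
        start = grp["_ts"].iloc[0]
        rel = ((grp["_ts"] - start).dt.total_seconds()).to_numpy(dtype=np.int64)
        time_s, vals, n_interp = _regularize(rel, grp["_glu"].to_numpy(float),
                                             sampling_interval)
        trace = GlucoseTrace(str(pid), time_s, vals,
                             sampling_interval=sampling_interval,
                             start_time=start, n_interpolated=n_interp)
        if n_interp:
            logger.info("trace %s: interpolated %d grid points", pid, n_interp)
        n_oor = int(trace.out_of_range.sum())
        if n_oor:
            logger.warning("trace %s: %d values outside sensor range %s (retained)",
                           pid, n_oor, SENSOR_RANGE)
        traces.append(trace)
    return traces


def write_cgm_csv(traces: list[GlucoseTrace], path: str | Path) -> None:
    """Serialize traces back to the long CSV format (ISO-8601 UTC)."""
    frames = []
    for t in traces:
        ts = t.start_time + pd.to_timedelta(t.time_s, unit="s")
        frames.append(pd.DataFrame({
            "patient_id": t.patient_id,
            "timestamp": [x.isoformat() for x in ts],
            "glucose_mmol_l": t.values,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_cohort_csv(path: str | Path, traces: list[GlucoseTrace] | None) -> Cohort:
    """Join cohort metadata to traces; every metadata row must match a trace.

    With ``traces=None`` the cohort is built without glucose data (for
    table-only workflows); no join is attempted.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    for col in _COHORT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"cohort file {path} is missing required column {col!r}")
    bad = ~df["diagnosis"].isin(DIAGNOSES)
    if bad.any():
        raise InputError(
            f"diagnosis values outside {DIAGNOSES}: "
            f"{sorted(df.loc[bad, 'diagnosis'].unique().tolist())}")
    if traces is None:
        by_id: dict[str, GlucoseTrace | None] = {pid: None for pid in df["patient_id"]}
    else:
        by_id = {t.patient_id: t for t in traces}
        missing = [pid for pid in df["patient_id"] if pid not in by_id]
        if missing:
            raise JoinError(f"metadata rows without a matching trace: {missing}",
                            missing_ids=missing)
    records = [
        PatientRecord(
            patient_id=row.patient_id,
            diagnosis=row.diagnosis,
            fcp=float(row.fcp_ng_ml),
            c2h=float(row.c2h_ng_ml),
            insulin_treated=bool(row.insulin_treated),
            trace=by_id[row.patient_id],
        )
        for row in df.itertuples()
    ]
    unmatched = sorted(set(by_id) - set(df["patient_id"]))
    if unmatched:
        logger.warning("traces without metadata (ignored): %s", unmatched)
    return Cohort(records)


def write_cohort_csv(cohort: Cohort, path: str | Path) -> None:
    pd.DataFrame({
        "patient_id": cohort.patient_ids,
        "diagnosis": cohort.labels,
        "fcp_ng_ml": cohort.fcp,
        "c2h_ng_ml": cohort.c2h,
        "insulin_treated": [r.insulin_treated for r in cohort],
    }).to_csv(path, index=False)


def write_report(report, path: str | Path) -> None:
    """Serialize a ClassificationReport to JSON plus a per-fold CSV.

    The CSV (``<stem>_folds.csv``) mirrors the cross-validation table layout:
    one row per fold with the selected scale and train/test AUC, sensitivity
    and specificity. The JSON carries every field at full float precision and
    round-trips losslessly through :func:`read_report`.
    """
    path = Path(path)
    payload = dataclasses.asdict(report)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    folds = payload.get("cv_folds") or []
    fold_df = pd.DataFrame(folds, columns=[
        "fold_index", "l_selected", "train_auc", "train_sensitivity",
        "train_specificity", "test_auc", "test_sensitivity", "test_specificity"])
    fold_df.to_csv(path.with_name(path.stem + "_folds.csv"), index=False)


def read_report(path: str | Path):
    """Inverse of :func:`write_report` (JSON side)."""
    from .classify import ClassificationReport, CVFold, ROCResult

    payload = json.loads(Path(path).read_text())
    payload["markers"] = [ROCResult(**m) for m in payload.get("markers", [])]
    payload["cv_folds"] = [CVFold(**f) for f in payload.get("cv_folds", [])]
    return ClassificationReport(**payload)
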