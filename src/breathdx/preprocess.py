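"""eNose preprocessing: triplicate aggregation and unit-range normalization.

Each subject contributes repeated (typically triplicate) readings of a
32-channel chemical sensor array.  Repeated measurements are aggregated by
the per-sensor median — robust against the heterogeneity seen in repeated
smell-prints — and each sensor column is then normalized to the range 0–1.

Normalization is per sensor (column-wise): sensors have heterogeneous
response scales and a global map would let one channel dominate.  When a
training/test split exists the min/max are fit on training data only and
test values are clamped into [0, 1], so no information leaks from held-out
samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import ValidationError

GROUPS = ("AD", "PD", "HC")


@dataclass
class SampleRecord:
    """One subject: id, diagnostic group, site and replicate sensor vectors."""

    subject_id: str
    group: str
    site: str
    replicates: list[np.ndarray]

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValidationError(f"{self.subject_id}: at least one replicate required")
        self.replicates = [np.asarray(r, dtype=float) for r in self.replicates]
        n = self.replicates[0].shape[0]
        if any(r.ndim != 1 or r.shape[0] != n for r in self.replicates):
            raise ValidationError(f"{self.subject_id}: ragged replicate lengths")

    @property
    def n_sensors(self) -> int:
        return self.replicates[0].shape[0]


@dataclass
class SensorMatrix:
    """Samples x sensors response matrix with id bookkeeping."""

    values: np.ndarray
    sample_ids: list[str]
    sensor_ids: list[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("sensor matrix must be 2-D")
        if self.values.shape != (len(self.sample_ids), len(self.sensor_ids)):
            raise ValidationError("matrix shape does not match id lists")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sensor_ids)


def _sensor_ids(n: int) -> list[str]:
    return [f"s{i:02d}" for i in range(1, n + 1)]


def aggregate_replicates(
    records: list[SampleRecord], method: str = "median"
) -> SensorMatrix:
    """One row per subject: the per-sensor median across replicates."""
    if method != "median":
        raise ValidationError(f"unknown aggregation method {method!r}")
    if not records:
        raise ValidationError("no records to aggregate")
    n_sensors = records[0].n_sensors
    if any(r.n_sensors != n_sensors for r in records):
        raise ValidationError("records disagree on sensor count")
    values = np.array([np.median(np.stack(r.replicates), axis=0) for r in records])
    return SensorMatrix(
        values=values,
        sample_ids=[r.subject_id for r in records],
        sensor_ids=_sensor_ids(n_sensors),
        normalized=False,
    )


class RangeNormalizer:
    """Column-wise (x - min)/(max - min) map fit on training data.

    Constant columns map to 0 everywhere so downstream PCA/LDA never sees
    non-finite values.  ``transform(..., clamp=True)`` clips out-of-range
    test values into [0, 1].
    """

    def fit(self, values: np.ndarray) -> "RangeNormalizer":
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise ValidationError("cannot fit normalizer on an empty matrix")
        self.min_ = values.min(axis=0)
        self.max_ = values.max(axis=0)
        self.range_ = self.max_ - self.min_
        return self

    def transform(self, values: np.ndarray, clamp: bool = False) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        rng = np.where(self.range_ > 0, self.range_, 1.0)
        out = (values - self.min_) / rng
        out[:, self.range_ == 0] = 0.0
        if clamp:
            out = np.clip(out, 0.0, 1.0)
        return out


def normalize_unit_range(m: SensorMatrix) -> SensorMatrix:
    """Map every sensor column onto [0, 1]; constant columns map to 0."""
    if m.normalized:
        raise ValidationError("matrix is already normalized")
    if m.values.size == 0:
        raise ValidationError("cannot normalize an empty matrix")
    norm = RangeNormalizer().fit(m.values)
    return SensorMatrix(
        values=norm.transform(m.values),
        sample_ids=list(m.sample_ids),
        sensor_ids=list(m.sensor_ids),
        normalized=True,
    )


# ---------------------------------------------------------------------------
# Observation tables and CSV I/O
# ---------------------------------------------------------------------------

def observation_table(
    records: list[SampleRecord], per: str = "replicate"
) -> pd.DataFrame:
    """Flatten records into one observation per row.

    ``per="replicate"`` keeps every repeated measurement as its own
    observation (matching cross-validation totals of subjects x replicates);
    ``per="subject"`` aggregates replicates by the median first.  Columns:
    ``subject_id, group, site, s01..sNN``.
    """
    rows = []
    if per == "replicate":
        for r in records:
            for rep in r.replicates:
                rows.append((r.subject_id, r.group, r.site, *rep))
    elif per == "subject":
        for r in records:
            med = np.median(np.stack(r.replicates), axis=0)
            rows.append((r.subject_id, r.group, r.site, *med))
    else:
        raise ValidationError("per must be 'replicate' or 'subject'")
    n_sensors = records[0].n_sensors
    cols = ["subject_id", "group", "site", *_sensor_ids(n_sensors)]
    return pd.DataFrame(rows, columns=cols)


def records_to_frame(records: list[SampleRecord]) -> pd.DataFrame:
    """Raw CSV layout: one row per replicate with a replicate_index column."""
    rows = []
    for r in records:
        for i, rep in enumerate(r.replicates, start=1):
            rows.append((r.subject_id, r.group, r.site, i, *rep))
    cols = ["subject_id", "group", "site", "replicate_index",
            *_sensor_ids(records[0].n_sensors)]
    return pd.DataFrame(rows, columns=cols)


def frame_to_records(df: pd.DataFrame) -> list[SampleRecord]:
    """Inverse of :func:`records_to_frame`."""
    required = {"subject_id", "group", "site", "replicate_index"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")
    sensor_cols = [c for c in df.columns if c not in required]
    records = []
    for sid, sub in df.groupby("subject_id", sort=False):
        sub = sub.sort_values("replicate_index")
        records.append(
            SampleRecord(
                subject_id=str(sid),
                group=str(sub["group"].iloc[0]),
                site=str(sub["site"].iloc[0]),
                replicates=[row for row in sub[sensor_cols].to_numpy(dtype=float)],
            )
        )
    return records


def read_enose_csv(path) -> list[SampleRecord]:
    return frame_to_records(pd.read_csv(path))


def write_enose_csv(records: list[SampleRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)
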