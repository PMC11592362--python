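"""ROI time-series I/O and condition segmentation.

Input is assumed to be fully preprocessed BOLD data reduced to one mean
time series per atlas ROI (volumes x ROIs).  Each volume carries a
condition token — ``baseline``, ``semantic``, ``pragmatic`` or
``discard`` — supplied either as a per-volume label file or derived from
a BIDS-style events table (onset/duration/trial_type) and the repetition
time.  Segmentation partitions the non-discard volumes of a run into
per-condition sub-series that feed the connectivity estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("baseline", "semantic", "pragmatic")
DISCARD = "discard"
_VALID_TOKENS = set(CONDITIONS) | {DISCARD}

__all__ = [
    "CONDITIONS",
    "DISCARD",
    "RunData",
    "SubjectRecord",
    "load_roi_timeseries",
    "load_labels",
    "labels_from_events",
    "segment_conditions",
    "load_cohort",
]


@dataclass
class RunData:
    """One run's ROI matrix (volumes x ROIs) with per-volume condition labels."""

    data: np.ndarray
    labels: list[str]
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("run data must be a 2-D (volumes x ROIs) matrix")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"label vector length {len(self.labels)} != number of volumes {self.data.shape[0]}"
            )
        bad = sorted(set(self.labels) - _VALID_TOKENS)
        if bad:
            raise ValueError(f"unknown condition token(s): {bad}")
        if not np.isfinite(self.data).all():
            raise ValueError("run data contains NaN/Inf")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class SubjectRecord:
    """One subject: group label plus ordered runs."""

    subject_id: str
    group: str
    runs: list[RunData] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.runs:
            raise ValueError(f"subject {self.subject_id}: at least one run required")
        dims = {r.n_rois for r in self.runs}
        if len(dims) != 1:
            raise ValueError(f"subject {self.subject_id}: runs disagree on ROI count {dims}")


def load_roi_timeseries(path: str | Path, pmap=None) -> np.ndarray:
    """Read a tab-separated numeric matrix (one row per volume).

    An optional single header row of roi_ids is detected and skipped.  If a
    :class:`~connscreen.atlas.ParcellationMap` is given, the column count is
    validated against it.
    """
    first = pd.read_csv(path, sep="\t", header=None, nrows=1)
    has_header = first.iloc[0].map(lambda v: isinstance(v, str)).any()
    df = pd.read_csv(path, sep="\t", header=0 if has_header else None)
    arr = df.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        r, c = np.argwhere(~np.isfinite(arr))[0]
        raise ValueError(f"{path}: non-finite value at row {r}, column {c}")
    if pmap is not None and arr.shape[1] != pmap.n_rois:
        raise ValueError(
            f"{path}: {arr.shape[1]} columns but parcellation has {pmap.n_rois} ROIs"
        )
    return arr


def load_labels(path: str | Path) -> list[str]:
    """Read a per-volume label file: one condition token per line."""
    tokens = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    bad = sorted(set(tokens) - _VALID_TOKENS)
    if bad:
        raise ValueError(f"{path}: unknown condition token(s): {bad}")
    return tokens


def labels_from_events(
    events: pd.DataFrame, tr_seconds: float, n_volumes: int
) -> list[str]:
    """Assign each volume the trial_type of the event covering its onset time.

    Volume v starts at ``v * tr_seconds``; events are half-open intervals
    ``[onset, onset + duration)``.  Volumes covered by no event are labelled
    ``discard``.  No hemodynamic-lag shift is applied here; shift the labels
    afterwards if the acquisition design calls for one.
    """
    required = {"onset", "duration", "trial_type"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"events table missing column(s) {sorted(missing)}")
    ev = events.sort_values("onset").reset_index(drop=True)
    bad = sorted(set(ev["trial_type"]) - set(CONDITIONS))
    if bad:
        raise ValueError(f"trial_type outside vocabulary {CONDITIONS}: {bad}")
    ends = ev["onset"].to_numpy() + ev["duration"].to_numpy()
    if (ev["onset"].to_numpy()[1:] < ends[:-1] - 1e-9).any():
        raise ValueError("overlapping events")
    labels = [DISCARD] * n_volumes
    for onset, duration, ttype in zip(ev["onset"], ev["duration"], ev["trial_type"]):
        # half-open [onset, onset+duration): first volume at or after onset,
        # last volume strictly before the offset
        v0 = int(np.ceil(onset / tr_seconds - 1e-9))
        v1 = int(np.ceil((onset + duration) / tr_seconds - 1e-9))
        for v in range(max(v0, 0), min(v1, n_volumes)):
            labels[v] = ttype
    return labels


def segment_conditions(run: RunData) -> dict[str, np.ndarray]:
    """Split a run's volumes by condition, preserving temporal order.

    Returns a sub-matrix per condition in :data:`CONDITIONS`; a condition
    absent from the labels maps to an empty (0 x ROIs) matrix.  ``discard``
    volumes appear in no sub-matrix.
    """
    lab = np.asarray(run.labels)
    return {c: run.data[lab == c] for c in CONDITIONS}


def load_cohort(manifest: str | Path, pmap=None) -> list[SubjectRecord]:
    """Read a cohort manifest and assemble SubjectRecords.

    The manifest is tab-separated with columns subject_id, group, run,
    timeseries and labels (path to a per-volume label file, relative paths
    resolved against the manifest's directory).  Runs are ordered by their
    ``run`` index within each subject; subjects keep manifest order.
    """
    manifest = Path(manifest)
    df = pd.read_csv(manifest, sep="\t")
    required = {"subject_id", "group", "run", "timeseries", "labels"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{manifest}: missing column(s) {sorted(missing)}")
    root = manifest.parent
    subjects: list[SubjectRecord] = []
    for sid in df["subject_id"].drop_duplicates():
        rows = df[df["subject_id"] == sid].sort_values("run")
        groups = rows["group"].unique()
        if len(groups) != 1:
            raise ValueError(f"subject {sid}: inconsistent group labels {groups}")
        runs = []
        for _, row in rows.iterrows():
            data = load_roi_timeseries(root / str(row["timeseries"]), pmap)
            labels = load_labels(root / str(row["labels"]))
            runs.append(RunData(data, labels))
        subjects.append(SubjectRecord(str(sid), str(groups[0]), runs))
    return subjects
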