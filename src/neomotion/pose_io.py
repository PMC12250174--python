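"""Reading, validating and writing pose-landmark time series.

A recording is a CSV file with a ``timestamp`` column (Unix epoch
milliseconds) and 33 landmark columns following the 33-point full-body pose
convention (nose = 0 ... right foot index = 32).  Each landmark cell is a
``(x, y, z)`` tuple: ``x`` and ``y`` are normalized to [0, 1] relative to the
image edges, and ``z`` is a signed relative depth (negative = closer to the
camera).  A flat dialect with 99 numeric coordinate columns plus the
timestamp is also accepted.

This module also defines the decomposition of the 33 landmarks into nine
named body regions (whole body, head, arms, trunk, legs, upper/lower body)
used for regional movement analysis.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    InsufficientDataError,
    OrderingError,
    UnknownRegionError,
)

logger = logging.getLogger(__name__)

N_LANDMARKS = 33

#: Landmark-index sets for the nine body regions, following the 33-point
#: pose-landmark convention (odd indices left side, even indices right side
#: for paired landmarks 11-32; 0-10 are face landmarks).
#: ``trunk`` is the shoulder/hip quadrilateral; hips are shared between the
#: trunk and the legs.  ``upper_body`` and ``lower_body`` partition the
#: whole body at the waist.
DEFAULT_REGIONS: dict[str, frozenset[int]] = {
    "whole_body": frozenset(range(33)),
    "head": frozenset(range(11)),
    "left_arm": frozenset({11, 13, 15, 17, 19, 21}),
    "right_arm": frozenset({12, 14, 16, 18, 20, 22}),
    "trunk": frozenset({11, 12, 23, 24}),
    "left_leg": frozenset({23, 25, 27, 29, 31}),
    "right_leg": frozenset({24, 26, 28, 30, 32}),
    "upper_body": frozenset(range(23)),
    "lower_body": frozenset(range(23, 33)),
}

REGION_NAMES: tuple[str, ...] = tuple(DEFAULT_REGIONS)

_TUPLE_RE = re.compile(
    r"^\s*[\(\[]?\s*([^,;\s]+)\s*[,;]\s*([^,;\s]+)\s*[,;]\s*([^,;\s\)\]]+)\s*[\)\]]?\s*$"
)


@dataclass(frozen=True)
class RegionMap:
    """A named subset of the 33 landmark indices."""

    name: str
    indices: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "indices", tuple(sorted(set(self.indices))))
        if any(i < 0 or i >= N_LANDMARKS for i in self.indices):
            raise UnknownRegionError(
                f"region {self.name!r} has indices outside 0..{N_LANDMARKS - 1}"
            )

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class LandmarkSequence:
    """An ordered series of timestamped 33-point (or region-restricted) poses.

    Attributes
    ----------
    subject_id:
        Opaque identifier of the recorded subject/session.
    timestamps_ms:
        Strictly increasing int64 Unix-millisecond timestamps, shape (n,).
    coords:
        float64 array of shape (n, k, 3) with columns (x, y, z).  ``k`` is 33
        for a full sequence or the region size for a projected view.  NaN
        marks a landmark as invalid in that frame (e.g. occluded).
    landmark_indices:
        Which of the 33 landmark slots the ``k`` columns correspond to.
    region:
        Name of the region this sequence is restricted to ("whole_body"
        for a full sequence).
    fps:
        Frame rate derived as 1000 / median inter-frame gap in ms.
    n_rejected:
        Rows dropped (or clamped) during CSV validation.
    """

    subject_id: str
    timestamps_ms: np.ndarray
    coords: np.ndarray
    landmark_indices: np.ndarray = field(default_factory=lambda: np.arange(N_LANDMARKS))
    region: str = "whole_body"
    n_rejected: int = 0

    def __post_init__(self):
        self.timestamps_ms = np.asarray(self.timestamps_ms, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.landmark_indices = np.asarray(self.landmark_indices, dtype=np.intp)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise FormatError(f"coords must have shape (n, k, 3), got {self.coords.shape}")
        if self.coords.shape[0] != self.timestamps_ms.shape[0]:
            raise FormatError("coords and timestamps_ms disagree on frame count")
        if self.coords.shape[1] != self.landmark_indices.shape[0]:
            raise FormatError("coords and landmark_indices disagree on landmark count")
        diffs = np.diff(self.timestamps_ms)
        if np.any(diffs <= 0):
            row = int(np.argmax(diffs <= 0)) + 1
            raise OrderingError(
                f"timestamps not strictly increasing at row {row}", row=row
            )
        if np.any(self.timestamps_ms <= 0):
            raise FormatError("timestamps must be strictly positive Unix ms")

    def __len__(self) -> int:
        return int(self.timestamps_ms.shape[0])

    @property
    def n_frames(self) -> int:
        return len(self)

    @property
    def n_points(self) -> int:
        return int(self.coords.shape[1])

    @property
    def median_gap_ms(self) -> float:
        if len(self) < 2:
            raise InsufficientDataError("need >= 2 frames to derive a frame gap")
        return float(np.median(np.diff(self.timestamps_ms)))

    @property
    def fps(self) -> float:
        """Frames per second: 1000 / median inter-frame gap (robust to drops)."""
        return 1000.0 / self.median_gap_ms

    @property
    def duration_ms(self) -> int:
        return int(self.timestamps_ms[-1] - self.timestamps_ms[0])

    def slice(self, start: int, stop: int) -> "LandmarkSequence":
        """Frame-range view sharing the underlying arrays."""
        out = replace(
            self,
            timestamps_ms=self.timestamps_ms[start:stop],
            coords=self.coords[start:stop],
        )
        return out


def region_indices(
    name: str, overrides: Mapping[str, Iterable[int]] | None = None
) -> RegionMap:
    """Return the landmark-index set for a named body region.

    ``overrides`` (e.g. loaded from a JSON region-map file) replace entries
    of the built-in table.
    """
    table: Mapping[str, Iterable[int]] = DEFAULT_REGIONS
    if overrides:
        table = {**DEFAULT_REGIONS, **{k: frozenset(v) for k, v in overrides.items()}}
    try:
        idx = table[name]
    except KeyError:
        raise UnknownRegionError(
            f"unknown region {name!r}; valid: {sorted(table)}"
        ) from None
    return RegionMap(name, tuple(idx))


def load_region_overrides(path: str | Path) -> dict[str, frozenset[int]]:
    """Load a ``{region_name: [indices]}`` JSON override file."""
    with open(path) as fh:
        raw = json.load(fh)
    return {k: frozenset(int(i) for i in v) for k, v in raw.items()}


def project(seq: LandmarkSequence, region: RegionMap | str) -> LandmarkSequence:
    """Restrict a sequence to the landmarks of one body region.

    Idempotent; projecting onto ``whole_body`` is the identity (same frame
    timestamps, all landmark columns).  The returned view shares the frame
    axis with the parent, so totals computed on it use the parent's gap
    statistics.
    """
    if isinstance(region, str):
        region = region_indices(region)
    mask = np.isin(seq.landmark_indices, np.fromiter(region.indices, dtype=np.intp))
    if mask.all() and seq.region in (region.name, "whole_body"):
        return replace(seq, region=region.name)
    return replace(
        seq,
        coords=seq.coords[:, mask, :],
        landmark_indices=seq.landmark_indices[mask],
        region=region.name,
    )


def _landmark_columns(columns: Sequence[str]) -> tuple[list[str], str]:
    """Identify the timestamp column and the landmark columns, in file order."""
    ts_candidates = [c for c in columns if c.strip().lower() == "timestamp"]
    if not ts_candidates:
        raise FormatError("missing 'timestamp' column")
    ts_col = ts_candidates[0]
    lm_cols = [c for c in columns if c != ts_col]
    if len(lm_cols) == N_LANDMARKS:
        return lm_cols, ts_col
    if len(lm_cols) == 3 * N_LANDMARKS:
        return lm_cols, ts_col
    raise FormatError(
        f"expected {N_LANDMARKS} tuple columns or {3 * N_LANDMARKS} flat "
        f"coordinate columns besides 'timestamp', found {len(lm_cols)}"
    )


def _parse_tuple_cells(values: pd.Series) -> np.ndarray:
    """Parse a column of '(x,y,z)' strings into an (n, 3) float array.

    Unparseable cells become all-NaN triples and are reported by the caller's
    validation policy.
    """
    out = np.full((len(values), 3), np.nan)
    for i, cell in enumerate(values.to_numpy()):
        if isinstance(cell, (tuple, list)) and len(cell) == 3:
            out[i] = cell
            continue
        m = _TUPLE_RE.match(str(cell))
        if m is None:
            continue
        try:
            out[i] = [float(m.group(1)), float(m.group(2)), float(m.group(3))]
        except ValueError:
            out[i] = np.nan
    return out


def read_landmark_csv(
    path: str | Path,
    validation: str = "reject",
    subject_id: str | None = None,
) -> LandmarkSequence:
    """Read a landmark CSV into a :class:`LandmarkSequence`.

    Parameters
    ----------
    path:
        CSV file with a ``timestamp`` column plus either 33 tuple columns or
        99 flat coordinate columns.
    validation:
        ``"reject"`` (default) drops rows whose finite x or y falls outside
        [0, 1] or whose timestamp fails to parse; ``"clamp"`` clips x and y
        into [0, 1] instead.  NaN coordinates are kept and mark the landmark
        invalid for that frame.  The number of affected rows is logged and
        recorded on the sequence.

    Raises
    ------
    FormatError, OrderingError, InsufficientDataError
    """
    if validation not in ("reject", "clamp"):
        raise ValueError(f"validation must be 'reject' or 'clamp', got {validation!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    lm_cols, ts_col = _landmark_columns(list(df.columns))

    ts = pd.to_numeric(df[ts_col], errors="coerce").to_numpy()
    n = len(df)
    if len(lm_cols) == N_LANDMARKS:
        coords = np.empty((n, N_LANDMARKS, 3))
        for j, col in enumerate(lm_cols):
            coords[:, j, :] = _parse_tuple_cells(df[col])
    else:
        flat = df[lm_cols].apply(pd.to_numeric, errors="coerce").to_numpy()
        coords = flat.reshape(n, N_LANDMARKS, 3)

    xy = coords[:, :, :2]
    with np.errstate(invalid="ignore"):
        finite = np.isfinite(xy)
        bad = finite & ((xy < 0.0) | (xy > 1.0))
    out_of_range = bad.any(axis=(1, 2))
    # a row where every landmark failed to parse carries no pose at all
    all_nan = np.isnan(coords).all(axis=(1, 2))
    bad_ts = ~np.isfinite(ts) | (np.nan_to_num(ts) <= 0)

    if validation == "clamp":
        coords[:, :, :2] = np.clip(coords[:, :, :2], 0.0, 1.0)
        drop = bad_ts | all_nan
        n_touched = int(out_of_range.sum() + drop.sum())
    else:
        drop = bad_ts | all_nan | out_of_range
        n_touched = int(drop.sum())
    if n_touched:
        logger.info("%s: %d row(s) rejected or clamped during validation", path, n_touched)

    keep = ~drop
    ts_kept = ts[keep].astype(np.int64)
    coords_kept = coords[keep]
    if len(ts_kept) < 3:
        raise InsufficientDataError(
            f"{path}: only {len(ts_kept)} valid rows; need >= 3 for kinematics"
        )
    diffs = np.diff(ts_kept)
    if np.any(diffs <= 0):
        row = int(np.argmax(diffs <= 0)) + 1
        raise OrderingError(
            f"{path}: timestamps not strictly increasing at data row {row}", row=row
        )
    return LandmarkSequence(
        subject_id=subject_id or path.stem,
        timestamps_ms=ts_kept,
        coords=coords_kept,
        n_rejected=n_touched,
    )


def write_landmark_csv(seq: LandmarkSequence, path: str | Path) -> None:
    """Write a sequence in the tuple CSV dialect (6-decimal coordinates)."""
    if seq.n_points != N_LANDMARKS:
        raise FormatError("only full 33-landmark sequences can be written")
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        header = ["timestamp"] + [f"landmark_{i}" for i in range(N_LANDMARKS)]
        fh.write(",".join(header) + "\n")
        for t, frame in zip(seq.timestamps_ms, seq.coords):
            cells = [
                '"({:.6f},{:.6f},{:.6f})"'.format(*pt) for pt in frame
            ]
            fh.write(str(int(t)) + "," + ",".join(cells) + "\n")
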