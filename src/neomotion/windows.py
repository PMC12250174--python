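"""Fixed-interval windowing and per-window movement summaries.

A recording is segmented by timestamp into consecutive, non-overlapping,
half-open windows ``[t0 + k*L, t0 + (k+1)*L)`` of exactly L seconds; the
trailing partial window is discarded.  For each
(subject, interval, region, method) combination the per-window movement
totals form the ``values`` list of a :class:`MovementSummary`, together with
min/max/mean/median and the population standard deviation.

The study layout — four default intervals (30, 60, 120, 180 s), nine body
regions, nine methods — yields ``subjects x 4 x 9 x 9`` summary files.
"""

from __future__ import annotations

import json
import logging
import statistics
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import EmptySummaryError, InsufficientDataError
from .pose_io import REGION_NAMES, LandmarkSequence, project
from .quantifiers import METHOD_NAMES, step_series, total_motion

logger = logging.getLogger(__name__)

DEFAULT_INTERVALS: tuple[float, ...] = (30.0, 60.0, 120.0, 180.0)


@dataclass
class MovementSummary:
    """Per-window totals and their order statistics for one combination."""

    subject: str
    interval_s: float
    region: str
    method: str
    values: list[float]
    min_value: float
    max_value: float
    avg: float
    std: float
    median: float
    n_windows: int

    @classmethod
    def from_values(
        cls, subject: str, interval_s: float, region: str, method: str,
        values: Sequence[float],
    ) -> "MovementSummary":
        if len(values) == 0:
            raise EmptySummaryError(
                f"no usable windows for {subject}/{interval_s}s/{region}/{method}"
            )
        vals = [float(v) for v in values]
        return cls(
            subject=subject,
            interval_s=float(interval_s),
            region=region,
            method=method,
            values=vals,
            min_value=min(vals),
            max_value=max(vals),
            avg=float(np.mean(vals)),
            std=float(np.std(vals)),  # population SD
            median=float(statistics.median(vals)),
            n_windows=len(vals),
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def _window_edges(seq: LandmarkSequence, interval_s: float) -> np.ndarray:
    if interval_s <= 0:
        raise ValueError(f"interval must be positive, got {interval_s}")
    t0 = int(seq.timestamps_ms[0])
    span = int(seq.timestamps_ms[-1]) - t0
    length = int(round(interval_s * 1000))
    n_windows = span // length
    return t0 + length * np.arange(n_windows + 1, dtype=np.int64)


def segment(seq: LandmarkSequence, interval_s: float) -> list[LandmarkSequence]:
    """Split a sequence into full windows of ``interval_s`` seconds.

    Windows are half-open by timestamp; the trailing partial window is
    discarded, and windows left with fewer than 2 frames are dropped (with a
    log entry).  A sequence shorter than one interval yields an empty list
    with a warning rather than raising.
    """
    edges = _window_edges(seq, interval_s)
    if len(edges) < 2:
        logger.warning(
            "%s: duration %.1f s shorter than interval %.1f s; no windows",
            seq.subject_id, seq.duration_ms / 1000.0, interval_s,
        )
        return []
    idx = np.searchsorted(seq.timestamps_ms, edges, side="left")
    out = []
    for k in range(len(edges) - 1):
        view = seq.slice(int(idx[k]), int(idx[k + 1]))
        if len(view) >= 2:
            out.append(view)
        else:
            logger.info(
                "%s: window %d (%.0f s) dropped with %d frame(s)",
                seq.subject_id, k, interval_s, len(view),
            )
    return out


def summarize(
    seq: LandmarkSequence,
    interval_s: float,
    region: str,
    method: str,
    params: Mapping | None = None,
) -> MovementSummary:
    """Movement summary of one (interval, region, method) combination.

    Each window's value is the cumulative motion total of ``method`` on the
    window projected to ``region``.
    """
    view = project(seq, region)
    windows = segment(view, interval_s)
    values = []
    for w in windows:
        try:
            values.append(total_motion(w, method, params).value)
        except InsufficientDataError:
            logger.info("%s: window skipped (insufficient valid frames)", seq.subject_id)
    return MovementSummary.from_values(seq.subject_id, interval_s, region, method, values)


def _window_values_from_series(series, edges: np.ndarray) -> list[float]:
    """Sum per-step contributions into windows; steps must lie fully inside."""
    lo = np.searchsorted(edges, series.t_start, side="right") - 1
    hi = np.searchsorted(edges, series.t_end, side="right") - 1
    n_windows = len(edges) - 1
    inside = (lo == hi) & (lo >= 0) & (lo < n_windows)
    sums = np.zeros(n_windows)
    np.add.at(sums, lo[inside], series.values[inside])
    return [float(v) for v in sums]


def summary_filename(subject: str, interval_s: float, region: str, method: str) -> str:
    return f"{subject}__{interval_s:g}s__{region}__{method}.json"


def emit_summary_files(
    cohort: Mapping[str, LandmarkSequence] | Iterable[LandmarkSequence],
    intervals: Sequence[float] = DEFAULT_INTERVALS,
    regions: Sequence[str] = REGION_NAMES,
    methods: Sequence[str] = METHOD_NAMES,
    outdir: str | Path = ".",
    params: Mapping | None = None,
) -> int:
    """Write one summary JSON per (subject, interval, region, method).

    Per-step contributions are computed once per (subject, region, method)
    and re-summed for every interval; the Mahalanobis quantifier is the
    exception, re-fitted per window because its covariance scope is the
    analysis window.  Returns the number of files written, which equals
    ``len(cohort) * len(intervals) * len(regions) * len(methods)``.
    """
    if not isinstance(cohort, Mapping):
        cohort = {seq.subject_id: seq for seq in cohort}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    count = 0
    for subject, seq in cohort.items():
        for region in regions:
            view = project(seq, region)
            for method in methods:
                if method == "mahalanobis":
                    series = None
                else:
                    series = step_series(view, method, params)
                for interval_s in intervals:
                    if method == "mahalanobis":
                        summary = summarize(seq, interval_s, region, method, params)
                    else:
                        edges = _window_edges(view, interval_s)
                        values = _window_values_from_series(series, edges)
                        summary = MovementSummary.from_values(
                            subject, interval_s, region, method, values
                        )
                    fname = summary_filename(subject, interval_s, region, method)
                    (outdir / fname).write_text(summary.to_json())
                    count += 1
    return count
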