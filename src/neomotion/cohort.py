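"""Cohort-level comparison statistics.

Given per-session movement summaries, this module computes the comparative
quantities used to rank quantifiers and body-region proxies:

* **percent change** between an early ("near admission") and a late
  ("near discharge") session of the same subject:
  ``100 * (late - early) / early`` on mean per-window movement levels;
* the **coefficient of variation** ``CV = 100 * sigma / mu`` used to rank
  methods by relative variability;
* the **cohort table**: methods x regions matrix of mean percent changes,
  with an Average column over the eight non-whole-body regions and a CV
  column;
* **interval proportionality**: mean per-window totals at each interval
  expressed as ratios to a baseline interval (movement grows ~linearly with
  window length for stationary motion, so 60/120/180 s sit near 2/4/6 times
  the 30 s level);
* **region similarity**: relative difference between each region's value
  and the whole-body value, with a 10% tolerance defining an acceptable
  regional proxy;
* a **timing profile** of wall-clock cost per (method, region).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ZeroBaselineError
from .pose_io import REGION_NAMES, LandmarkSequence, project
from .quantifiers import METHOD_NAMES, total_motion
from .windows import MovementSummary

logger = logging.getLogger(__name__)

#: Column order of the cohort table (whole body first, then regions).
TABLE_REGION_ORDER: tuple[str, ...] = (
    "whole_body", "head", "left_arm", "right_arm",
    "left_leg", "right_leg", "trunk", "upper_body", "lower_body",
)
#: Regions entering the Average column (whole body excluded).
AVERAGE_REGIONS: tuple[str, ...] = TABLE_REGION_ORDER[1:]

SIMILARITY_TOLERANCE_PCT = 10.0


@dataclass
class PercentChange:
    """Admission-to-discharge relative change for one combination."""

    subject_id: str
    region: str
    method: str
    early_level: float
    late_level: float
    pct: float
    undefined: bool = False  # early level was zero; excluded from cohort means


def percent_change(early: MovementSummary, late: MovementSummary) -> PercentChange:
    """``100 * (late.avg - early.avg) / early.avg`` for matched summaries."""
    for attr in ("subject", "region", "method", "interval_s"):
        if getattr(early, attr) != getattr(late, attr):
            raise ValueError(
                f"early/late summaries disagree on {attr}: "
                f"{getattr(early, attr)!r} vs {getattr(late, attr)!r}"
            )
    if early.avg == 0:
        logger.warning(
            "%s/%s/%s: zero early movement level; percent change undefined",
            early.subject, early.region, early.method,
        )
        return PercentChange(
            early.subject, early.region, early.method,
            early.avg, late.avg, float("nan"), undefined=True,
        )
    pct = 100.0 * (late.avg - early.avg) / early.avg
    return PercentChange(early.subject, early.region, early.method,
                         early.avg, late.avg, pct)


def coefficient_of_variation(values: Iterable[float]) -> float:
    """``100 * sigma / mu`` with sigma the population standard deviation."""
    arr = np.asarray(list(values), dtype=float)
    mu = arr.mean()
    if mu == 0:
        raise ZeroBaselineError("coefficient of variation undefined for zero mean")
    return float(100.0 * arr.std() / mu)


def build_cohort_table(
    changes: Iterable[PercentChange],
    cv_basis: str = "subjects_whole_body",
    methods: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Methods x regions table of cohort-mean percent changes.

    Each cell is the mean over subjects of the per-subject percent change
    (undefined-baseline records are excluded with a log entry).  The
    ``Average`` column is the mean of the eight non-whole-body region cells;
    ``Coef. Var.`` depends on ``cv_basis``:

    * ``"subjects_whole_body"`` (default): CV across per-subject whole-body
      percent changes for each method;
    * ``"regions"``: CV across the eight region cells of the row;
    * ``"subjects_all"``: CV across all per-subject, per-region changes.

    Single-subject tables get CV 0 where the basis is degenerate.
    """
    if cv_basis not in ("subjects_whole_body", "regions", "subjects_all"):
        raise ValueError(f"unknown cv_basis {cv_basis!r}")
    changes = list(changes)
    records = [c for c in changes if not c.undefined]
    if len(records) < len(changes):
        logger.info(
            "%d undefined-baseline record(s) excluded from cohort means",
            len(changes) - len(records),
        )
    df = pd.DataFrame(
        [(c.method, c.region, c.subject_id, c.pct) for c in records],
        columns=["method", "region", "subject", "pct"],
    )
    if df.empty:
        raise ValueError("no defined percent-change records")
    if methods is None:
        methods = [m for m in METHOD_NAMES if m in set(df["method"])]
    cells = df.pivot_table(index="method", columns="region", values="pct", aggfunc="mean")
    table = cells.reindex(index=methods, columns=list(TABLE_REGION_ORDER))
    table["Average"] = table[list(AVERAGE_REGIONS)].mean(axis=1)
    cv = []
    for m in methods:
        sub = df[df["method"] == m]
        if cv_basis == "regions":
            basis = table.loc[m, list(AVERAGE_REGIONS)].to_numpy(dtype=float)
        elif cv_basis == "subjects_whole_body":
            basis = sub[sub["region"] == "whole_body"]["pct"].to_numpy()
        else:
            basis = sub["pct"].to_numpy()
        basis = basis[np.isfinite(basis)]
        if basis.size < 2 or basis.mean() == 0:
            logger.info("method %s: CV basis degenerate (n=%d); reporting 0", m, basis.size)
            cv.append(0.0)
        else:
            cv.append(coefficient_of_variation(basis))
    table["Coef. Var."] = cv
    table.index.name = "method"
    return table


def interval_proportionality(
    summaries: Iterable[MovementSummary],
    baseline_s: float = 30.0,
) -> pd.DataFrame:
    """Mean per-window total at each interval, relative to the baseline.

    Returns a table indexed by (method, region) with one column per
    interval; the baseline column is identically 1.  Raises if the baseline
    interval is absent for any (method, region) present.
    """
    rows = [
        (s.method, s.region, s.interval_s, s.avg) for s in summaries
    ]
    if not rows:
        raise ValueError("no summaries given")
    df = pd.DataFrame(rows, columns=["method", "region", "interval_s", "avg"])
    wide = df.pivot_table(
        index=["method", "region"], columns="interval_s", values="avg", aggfunc="mean"
    )
    if baseline_s not in wide.columns:
        raise ZeroBaselineError(f"baseline interval {baseline_s} s missing")
    base = wide[baseline_s]
    if (base == 0).any():
        raise ZeroBaselineError("zero movement at baseline interval")
    return wide.div(base, axis=0)


def region_similarity(table: pd.DataFrame) -> pd.DataFrame:
    """Relative difference of each region cell to the whole-body cell.

    For every method row of a cohort table, ``rel_diff_pct =
    100 * |region - whole_body| / whole_body``; ``acceptable`` is a strict
    ``< 10%`` test marking the region a reasonable whole-body proxy.
    Whole-body values of zero yield NaN (undefined) cells.
    """
    if "whole_body" not in table.columns:
        raise ValueError("cohort table lacks a whole_body column")
    out = []
    for method, row in table.iterrows():
        whole = row["whole_body"]
        for region in AVERAGE_REGIONS:
            if region not in table.columns or not np.isfinite(row[region]):
                continue
            if whole == 0 or not np.isfinite(whole):
                rel = float("nan")
            else:
                rel = 100.0 * abs(row[region] - whole) / abs(whole)
            out.append(
                {
                    "method": method,
                    "region": region,
                    "rel_diff_pct": rel,
                    "acceptable": bool(np.isfinite(rel) and rel < SIMILARITY_TOLERANCE_PCT),
                }
            )
    return pd.DataFrame(out)


def timing_profile(
    seq: LandmarkSequence,
    methods: Sequence[str] = METHOD_NAMES,
    regions: Sequence[str] = REGION_NAMES,
    repeats: int = 3,
    params: Mapping | None = None,
) -> pd.DataFrame:
    """Median wall-clock time (seconds) of each (method, region) total.

    Reported for orientation only; timings depend on the host and are never
    asserted against reference values.
    """
    if repeats < 3:
        raise ValueError("repeats must be >= 3 for a stable median")
    rows = []
    for method in methods:
        for region in regions:
            view = project(seq, region)
            times = []
            for _ in range(repeats):
                t0 = time.perf_counter()
                total_motion(view, method, params)
                times.append(time.perf_counter() - t0)
            rows.append(
                {
                    "method": method,
                    "region": region,
                    "median_s": float(np.median(times)),
                    "repeats": repeats,
                }
            )
    return pd.DataFrame(rows)
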