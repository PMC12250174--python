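"""The nine motion quantifiers.

Every quantifier maps a (possibly region-restricted) landmark sequence to a
single non-negative movement total: the cumulative motion difference summed
over all frame transitions and all landmarks in the sequence,

    total = sum_i sum_landmarks  m(step i, landmark)

where the per-step measure ``m`` depends on the method:

==============  =============================================================
euclidean       straight-line length of the displacement vector
manhattan       sum of absolute coordinate differences
chebyshev       maximum absolute coordinate difference
minkowski       p-norm of the displacement (p=1 Manhattan, p=2 Euclidean)
mahalanobis     sqrt(D' S^-1 D) with S the coordinate covariance of the
                analysis window (correlation-aware distance)
diffacc         absolute change of per-dimension velocity between consecutive
                transitions (second difference scaled by fps)
angular         turning angle between successive displacement vectors
lucas_kanade    norm of the least-squares velocity solved from the gradient
                system of a three-frame stencil
farneback       total magnitude of dense optical flow between synthetic
                images rasterized from the landmarks
==============  =============================================================

Distance totals are in normalized image units (dimensionless); angular
totals are radians summed; flow totals are pixels summed over the rendered
image.  Transitions whose inter-frame gap exceeds ``gap_factor`` times the
sequence's median gap are excluded from totals (recording dropouts would
otherwise register as spurious motion), and frames containing an invalid
(NaN) landmark within the analysed region are dropped before quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

from . import farneback as _fb
from .errors import InsufficientDataError, ParameterError, UnknownMethodError
from .pose_io import LandmarkSequence

METHOD_NAMES: tuple[str, ...] = (
    "euclidean",
    "manhattan",
    "chebyshev",
    "minkowski",
    "mahalanobis",
    "diffacc",
    "angular",
    "lucas_kanade",
    "farneback",
)

#: Methods whose per-step measure uses a three-frame stencil.
THREE_FRAME_METHODS = frozenset({"diffacc", "angular", "lucas_kanade"})

DEFAULT_PARAMS: dict[str, Any] = {
    "minkowski_p": 3.0,
    "gap_factor": 3.0,
    "mahalanobis_cond_threshold": 1e8,
    "mahalanobis_ridge_scale": 1e-9,
    "fps": None,  # derived from timestamps unless overridden
    "render": None,  # farneback RenderParams / dict
    "flow": None,  # farneback FlowParams / dict
}


def _merge_params(params: Mapping[str, Any] | None) -> dict[str, Any]:
    out = dict(DEFAULT_PARAMS)
    if params:
        unknown = set(params) - set(DEFAULT_PARAMS)
        if unknown:
            raise ParameterError(f"unknown method parameter(s): {sorted(unknown)}")
        out.update(params)
    return out


# ---------------------------------------------------------------------------
# per-step distance measures (operate on displacement vectors, last axis 3)
# ---------------------------------------------------------------------------

def step_euclidean(d) -> np.ndarray | float:
    """Straight-line length sqrt(dx^2 + dy^2 + dz^2)."""
    d = np.asarray(d, dtype=float)
    return np.sqrt((d * d).sum(axis=-1))


def step_manhattan(d) -> np.ndarray | float:
    """Taxicab length |dx| + |dy| + |dz|."""
    d = np.asarray(d, dtype=float)
    return np.abs(d).sum(axis=-1)


def step_chebyshev(d) -> np.ndarray | float:
    """Largest per-axis difference max(|dx|, |dy|, |dz|)."""
    d = np.asarray(d, dtype=float)
    return np.abs(d).max(axis=-1)


def step_minkowski(d, p: float) -> np.ndarray | float:
    """p-norm (|dx|^p + |dy|^p + |dz|^p)^(1/p); requires p >= 1."""
    if p < 1:
        raise ParameterError(f"Minkowski order must satisfy p >= 1, got {p}")
    d = np.abs(np.asarray(d, dtype=float))
    if p == 1:
        return d.sum(axis=-1)
    if p == 2:
        return np.sqrt((d * d).sum(axis=-1))
    # rescale by the max to keep |d|^p in range for large p
    m = d.max(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(m[..., None] > 0, d / np.where(m[..., None] > 0, m[..., None], 1.0), 0.0)
        s = (r**p).sum(axis=-1) ** (1.0 / p)
    return m * s


@dataclass
class CovarianceModel:
    """3x3 coordinate covariance with optional diagonal ridge.

    ``S + ridge * I`` must be positive definite; ``solve`` maps displacement
    vectors D to S^-1-weighted half-solutions so that the Mahalanobis length
    is the Euclidean norm of the result.
    """

    S: np.ndarray
    ridge: float = 0.0
    degenerate: bool = False
    _chol: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        if self.S.shape != (3, 3) or not np.allclose(self.S, self.S.T, atol=1e-12):
            raise ParameterError("covariance must be a symmetric 3x3 matrix")
        reg = self.S + self.ridge * np.eye(3)
        try:
            self._chol = np.linalg.cholesky(reg)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "covariance not positive definite after ridge regularization"
            )

    def whiten(self, d: np.ndarray) -> np.ndarray:
        """Solve L y = d for the Cholesky factor L of the regularized S."""
        d = np.asarray(d, dtype=float)
        flat = d.reshape(-1, 3).T
        y = np.linalg.solve(self._chol, flat)
        return y.T.reshape(d.shape)


def fit_covariance(
    seq_or_coords,
    cond_threshold: float = 1e8,
    ridge_scale: float = 1e-9,
) -> CovarianceModel:
    """Estimate the (x, y, z) covariance from all coordinates of a window.

    Samples are pooled over frames and landmarks of the (projected) sequence.
    A diagonal ridge of ``ridge_scale * trace(S) / 3`` is added when the
    condition number exceeds ``cond_threshold``; an all-identical sample set
    degenerates to the identity model, flagged via ``degenerate``.
    """
    if isinstance(seq_or_coords, LandmarkSequence):
        coords = seq_or_coords.coords
        if len(seq_or_coords) < 4:
            raise InsufficientDataError("covariance fit needs >= 4 frames")
    else:
        coords = np.asarray(seq_or_coords, dtype=float)
    samples = coords.reshape(-1, 3)
    samples = samples[~np.isnan(samples).any(axis=1)]
    if samples.shape[0] < 4:
        raise InsufficientDataError("covariance fit needs >= 4 coordinate samples")
    S = np.cov(samples.T)
    tr = float(np.trace(S))
    # trace at rounding-noise level means the window carries no real motion
    if not np.isfinite(S).all() or tr <= 1e-18:
        return CovarianceModel(np.eye(3), degenerate=True)
    ridge = 0.0
    if np.linalg.cond(S) > cond_threshold:
        ridge = ridge_scale * tr / 3.0
        # escalate until the Cholesky factorization succeeds
        for _ in range(40):
            try:
                return CovarianceModel(S, ridge=ridge)
            except np.linalg.LinAlgError:
                ridge *= 10.0
        raise np.linalg.LinAlgError("covariance not repairable by ridge escalation")
    return CovarianceModel(S, ridge=ridge)


def step_mahalanobis(d, cov: CovarianceModel) -> np.ndarray | float:
    """Correlation-aware length sqrt(D' (S + ridge I)^-1 D)."""
    y = cov.whiten(d)
    return np.sqrt((y * y).sum(axis=-1))


# ---------------------------------------------------------------------------
# per-step series
# ---------------------------------------------------------------------------

@dataclass
class StepSeries:
    """Per-step contributions of one quantifier on one sequence view.

    ``values[i]`` is the movement contributed by the step whose frames span
    timestamps ``[t_start[i], t_end[i]]``.  Used internally to window totals
    without recomputation; ``values.sum()`` is the sequence total.
    """

    method: str
    region: str
    values: np.ndarray
    t_start: np.ndarray
    t_end: np.ndarray
    n_excluded: int = 0
    flags: tuple[str, ...] = ()


@dataclass
class MotionTotal:
    """Cumulative motion difference of one method over one sequence view."""

    method: str
    region: str
    value: float
    n_steps: int
    n_excluded: int = 0
    flags: tuple[str, ...] = ()


def _drop_invalid_frames(seq: LandmarkSequence) -> tuple[np.ndarray, np.ndarray, int]:
    """Remove frames with any NaN landmark in the view; return (ts, coords, ndropped)."""
    bad = np.isnan(seq.coords).any(axis=(1, 2))
    n_dropped = int(bad.sum())
    if n_dropped:
        return seq.timestamps_ms[~bad], seq.coords[~bad], n_dropped
    return seq.timestamps_ms, seq.coords, 0


def _gap_mask(ts: np.ndarray, gap_factor: float) -> np.ndarray:
    gaps = np.diff(ts)
    med = np.median(gaps)
    return gaps <= gap_factor * med


def _pairwise_series(
    seq: LandmarkSequence, method: str, p: dict
) -> StepSeries:
    ts, coords, n_dropped = _drop_invalid_frames(seq)
    if len(ts) < 2:
        raise InsufficientDataError(f"{method} needs >= 2 valid frames")
    d = coords[1:] - coords[:-1]
    if method == "euclidean":
        per = step_euclidean(d)
    elif method == "manhattan":
        per = step_manhattan(d)
    elif method == "chebyshev":
        per = step_chebyshev(d)
    elif method == "minkowski":
        per = step_minkowski(d, p["minkowski_p"])
    elif method == "mahalanobis":
        cov = fit_covariance(
            coords,
            cond_threshold=p["mahalanobis_cond_threshold"],
            ridge_scale=p["mahalanobis_ridge_scale"],
        )
        per = step_mahalanobis(d, cov)
    else:  # pragma: no cover - guarded by dispatch
        raise UnknownMethodError(method)
    vals = per.sum(axis=1)
    ok = _gap_mask(ts, p["gap_factor"])
    return StepSeries(
        method=method,
        region=seq.region,
        values=vals[ok],
        t_start=ts[:-1][ok],
        t_end=ts[1:][ok],
        n_excluded=int((~ok).sum()) + n_dropped,
    )


def _stencil_inputs(seq: LandmarkSequence, method: str, p: dict):
    ts, coords, n_dropped = _drop_invalid_frames(seq)
    if len(ts) < 3:
        raise InsufficientDataError(f"{method} needs >= 3 valid frames")
    ok_gap = _gap_mask(ts, p["gap_factor"])
    ok = ok_gap[:-1] & ok_gap[1:]  # both gaps of the stencil within bounds
    return ts, coords, ok, n_dropped


def differential_acceleration(
    seq: LandmarkSequence, fps: float | None = None, params: Mapping | None = None
) -> MotionTotal:
    """Sum of absolute frame-to-frame velocity changes (fps-scaled second
    differences) over dimensions, landmarks and interior frames."""
    p = _merge_params(params)
    if fps is not None:
        p["fps"] = fps
    return _finalize(_diffacc_series(seq, p), seq)


def _diffacc_series(seq: LandmarkSequence, p: dict) -> StepSeries:
    fps = p["fps"] if p["fps"] is not None else seq.fps
    if fps <= 0:
        raise ParameterError(f"fps must be positive, got {fps}")
    ts, coords, ok, n_dropped = _stencil_inputs(seq, "diffacc", p)
    accel = (coords[2:] - 2 * coords[1:-1] + coords[:-2]) * fps
    vals = np.abs(accel).sum(axis=(1, 2))
    return StepSeries(
        "diffacc", seq.region, vals[ok], ts[:-2][ok], ts[2:][ok],
        n_excluded=int((~ok).sum()) + n_dropped,
    )


def angular_displacement(seq: LandmarkSequence, params: Mapping | None = None) -> MotionTotal:
    """Sum of absolute turning angles between successive displacement
    vectors of each landmark, in radians.

    For interior frame i the vectors are a = P_i - P_{i-1} and
    b = P_{i+1} - P_i; the angle is arccos(a.b / |a||b|) with the cosine
    clamped to [-1, 1], and a zero-length vector contributes zero angle.
    """
    return _finalize(_angular_series(seq, _merge_params(params)), seq)


def _angular_series(seq: LandmarkSequence, p: dict) -> StepSeries:
    ts, coords, ok, n_dropped = _stencil_inputs(seq, "angular", p)
    a = coords[1:-1] - coords[:-2]
    b = coords[2:] - coords[1:-1]
    na = np.sqrt((a * a).sum(axis=-1))
    nb = np.sqrt((b * b).sum(axis=-1))
    dot = (a * b).sum(axis=-1)
    denom = na * nb
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.where(denom > 0, dot / np.where(denom > 0, denom, 1.0), 1.0)
    theta = np.arccos(np.clip(cos, -1.0, 1.0))
    vals = np.abs(theta).sum(axis=1)
    return StepSeries(
        "angular", seq.region, vals[ok], ts[:-2][ok], ts[2:][ok],
        n_excluded=int((~ok).sum()) + n_dropped,
    )


def lucas_kanade_motion(seq: LandmarkSequence, params: Mapping | None = None) -> MotionTotal:
    """Gradient least-squares motion magnitude on three-frame stencils.

    Per landmark and interior frame i, the gradient row
    g = (P_{i+1} - P_{i-1}) / 2 (central differences per dimension) and the
    temporal difference b = P_{i+1} - P_i form the system A v = b with A
    stacking g once per dimension of the stencil.  The system is solved by
    pseudoinverse, giving ||v|| = |sum(b)| / (3 |g|) and 0 whenever g = 0;
    stencils with g = 0 but b != 0 are flagged ill-conditioned rather than
    raising.
    """
    return _finalize(_lucas_kanade_series(seq, _merge_params(params)), seq)


def _lucas_kanade_series(seq: LandmarkSequence, p: dict) -> StepSeries:
    ts, coords, ok, n_dropped = _stencil_inputs(seq, "lucas_kanade", p)
    g = (coords[2:] - coords[:-2]) / 2.0
    b = coords[2:] - coords[1:-1]
    gn = np.sqrt((g * g).sum(axis=-1))
    s = b.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vnorm = np.where(gn > 0, np.abs(s) / (3.0 * np.where(gn > 0, gn, 1.0)), 0.0)
    flags = ()
    if np.any((gn == 0) & (np.abs(s) > 0)):
        flags = ("ill_conditioned_stencils",)
    vals = vnorm.sum(axis=1)
    return StepSeries(
        "lucas_kanade", seq.region, vals[ok], ts[:-2][ok], ts[2:][ok],
        n_excluded=int((~ok).sum()) + n_dropped, flags=flags,
    )


def farneback_motion(
    seq: LandmarkSequence,
    render: "_fb.RenderParams | Mapping | None" = None,
    flow: "_fb.FlowParams | Mapping | None" = None,
    params: Mapping | None = None,
) -> MotionTotal:
    """Dense-optical-flow movement total on rasterized landmark images.

    Each frame is drawn as a grayscale image (landmarks as filled circles;
    z is not rendered), dense polynomial-expansion flow is estimated between
    consecutive images, and each transition contributes the sum of per-pixel
    flow magnitudes.
    """
    p = _merge_params(params)
    if render is not None:
        p["render"] = render
    if flow is not None:
        p["flow"] = flow
    return _finalize(_farneback_series(seq, p), seq)


def _farneback_series(seq: LandmarkSequence, p: dict) -> StepSeries:
    ts, coords, n_dropped = _drop_invalid_frames(seq)
    if len(ts) < 2:
        raise InsufficientDataError("farneback needs >= 2 valid frames")
    render = _fb.RenderParams.coerce(p["render"])
    flow = _fb.FlowParams.coerce(p["flow"])
    vals = _fb.transition_flow_magnitudes(coords, render, flow)
    ok = _gap_mask(ts, p["gap_factor"])
    return StepSeries(
        "farneback", seq.region, vals[ok], ts[:-1][ok], ts[1:][ok],
        n_excluded=int((~ok).sum()) + n_dropped,
    )


_SERIES_DISPATCH = {
    "euclidean": _pairwise_series,
    "manhattan": _pairwise_series,
    "chebyshev": _pairwise_series,
    "minkowski": _pairwise_series,
    "mahalanobis": _pairwise_series,
}


def step_series(
    seq: LandmarkSequence, method: str, params: Mapping | None = None
) -> StepSeries:
    """Per-step contribution series for any registered method."""
    p = _merge_params(params)
    if method in _SERIES_DISPATCH:
        return _SERIES_DISPATCH[method](seq, method, p)
    if method == "diffacc":
        return _diffacc_series(seq, p)
    if method == "angular":
        return _angular_series(seq, p)
    if method == "lucas_kanade":
        return _lucas_kanade_series(seq, p)
    if method == "farneback":
        return _farneback_series(seq, p)
    raise UnknownMethodError(
        f"unknown method {method!r}; valid: {list(METHOD_NAMES)}"
    )


def _finalize(series: StepSeries, seq: LandmarkSequence) -> MotionTotal:
    return MotionTotal(
        method=series.method,
        region=series.region,
        value=float(series.values.sum()),
        n_steps=int(series.values.size),
        n_excluded=series.n_excluded,
        flags=series.flags,
    )


def total_motion(
    seq: LandmarkSequence, method: str, params: Mapping | None = None
) -> MotionTotal:
    """Cumulative motion difference of ``method`` over the whole sequence.

    Raises :class:`InsufficientDataError` below 2 frames (3 for the
    three-frame-stencil methods) and :class:`UnknownMethodError` for an
    unregistered method name.
    """
    return _finalize(step_series(seq, method, params), seq)
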