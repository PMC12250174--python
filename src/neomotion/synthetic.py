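"""Synthetic landmark sequences with known ground-truth kinematics.

The generator emulates the statistical shape of contactless NICU pose
recordings — 33 landmarks in normalized image coordinates around a supine
infant pose, millisecond timestamps at a nominal frame rate — without any
claim of biomechanical realism.  Each landmark follows

    base pose + amplitude * (sinusoid + Gaussian random-walk jitter)

where the amplitude is set per body region.  Jitter is a random walk (not
i.i.d. noise around the base pose) so that expected path length grows
linearly with observation time, the property that makes windowed totals
proportional to window duration.  Coordinates are clipped to [0, 1] with
clip events counted; profiles used in tests keep clipping negligible.

Every generated sequence carries exact bookkeeping of its Euclidean path
length per landmark and per region, providing ground truth for quantifier
and cohort-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .pose_io import DEFAULT_REGIONS, N_LANDMARKS, LandmarkSequence, write_landmark_csv

#: Neutral supine-infant pose: (x, y, z) per landmark, head toward the top of
#: the image.  The exact values are arbitrary plausible choices; only their
#: rough anatomical layout (regions occupy distinct image areas, margins to
#: the image border) matters to the generator.
BASE_POSE: np.ndarray = np.array([
    (0.500, 0.180, -0.05),  # 0 nose
    (0.520, 0.160, -0.04), (0.535, 0.160, -0.04), (0.550, 0.160, -0.04),  # 1-3 left eye
    (0.480, 0.160, -0.04), (0.465, 0.160, -0.04), (0.450, 0.160, -0.04),  # 4-6 right eye
    (0.570, 0.170, -0.02), (0.430, 0.170, -0.02),  # 7-8 ears
    (0.520, 0.210, -0.04), (0.480, 0.210, -0.04),  # 9-10 mouth
    (0.600, 0.300, 0.00), (0.400, 0.300, 0.00),    # 11-12 shoulders
    (0.660, 0.380, -0.01), (0.340, 0.380, -0.01),  # 13-14 elbows
    (0.640, 0.460, -0.02), (0.360, 0.460, -0.02),  # 15-16 wrists
    (0.645, 0.490, -0.02), (0.355, 0.490, -0.02),  # 17-18 pinkies
    (0.635, 0.495, -0.02), (0.365, 0.495, -0.02),  # 19-20 index fingers
    (0.625, 0.480, -0.02), (0.375, 0.480, -0.02),  # 21-22 thumbs
    (0.570, 0.550, 0.00), (0.430, 0.550, 0.00),    # 23-24 hips
    (0.620, 0.680, -0.02), (0.380, 0.680, -0.02),  # 25-26 knees
    (0.600, 0.780, -0.01), (0.400, 0.780, -0.01),  # 27-28 ankles
    (0.600, 0.810, 0.00), (0.400, 0.810, 0.00),    # 29-30 heels
    (0.630, 0.840, -0.03), (0.370, 0.840, -0.03),  # 31-32 foot indices
])

#: Fine region driving each landmark's motion amplitude (hips and shoulders
#: move with the trunk).
AMPLITUDE_REGIONS: tuple[str, ...] = (
    "head", "left_arm", "right_arm", "trunk", "left_leg", "right_leg",
)
_PRIMARY_REGION: tuple[str, ...] = tuple(
    ["head"] * 11
    + ["trunk", "trunk"]
    + ["left_arm", "right_arm"] * 5
    + ["trunk", "trunk"]
    + ["left_leg", "right_leg"] * 4
)
assert len(_PRIMARY_REGION) == N_LANDMARKS

#: Epoch offset so generated timestamps are plausible positive Unix ms.
EPOCH_MS = 1_700_000_000_000


@dataclass(frozen=True)
class MotionProfile:
    """Statistical description of one generated recording.

    ``jitter_sd`` is the per-frame random-walk step SD in normalized image
    units; ``smooth_amp`` and ``smooth_freq_hz`` add a deterministic sinusoid
    (random phase per landmark and dimension).  Region amplitudes multiply
    both components.
    """

    amplitudes: Mapping[str, float] = field(
        default_factory=lambda: {r: 1.0 for r in AMPLITUDE_REGIONS}
    )
    jitter_sd: float = 0.002
    smooth_freq_hz: float = 0.25
    smooth_amp: float = 0.005
    fps: float = 10.0
    duration_s: float = 185.0
    seed: int = 0

    def __post_init__(self):
        if self.fps <= 0 or self.duration_s <= 0:
            raise ValueError("fps and duration_s must be positive")
        if self.jitter_sd < 0 or self.smooth_amp < 0:
            raise ValueError("noise amplitudes must be non-negative")
        amps = {r: 1.0 for r in AMPLITUDE_REGIONS}
        amps.update(self.amplitudes)
        if any(v < 0 for v in amps.values()):
            raise ValueError("region amplitudes must be non-negative")
        object.__setattr__(self, "amplitudes", amps)

    def scaled(self, factor: float) -> "MotionProfile":
        """Profile with every region amplitude multiplied by ``factor``."""
        return replace(
            self, amplitudes={r: a * factor for r, a in self.amplitudes.items()}
        )

    def to_json(self) -> str:
        d = {
            "amplitudes": dict(self.amplitudes),
            "jitter_sd": self.jitter_sd,
            "smooth_freq_hz": self.smooth_freq_hz,
            "smooth_amp": self.smooth_amp,
            "fps": self.fps,
            "duration_s": self.duration_s,
            "seed": self.seed,
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MotionProfile":
        return cls(**json.loads(text))


@dataclass
class GroundTruth:
    """Exact kinematic bookkeeping of a generated sequence."""

    path_length: float  # whole-body Euclidean total
    per_landmark_path: np.ndarray  # (33,)
    region_path_length: dict[str, float]
    clip_events: int


def _landmark_amplitudes(profile: MotionProfile) -> np.ndarray:
    return np.array([profile.amplitudes[r] for r in _PRIMARY_REGION])


def generate_sequence(
    profile: MotionProfile,
    subject_id: str = "synthetic",
    t0_ms: int = EPOCH_MS,
) -> tuple[LandmarkSequence, GroundTruth]:
    """Generate one deterministic landmark sequence and its ground truth.

    Frame i is stamped ``t0_ms + round(i * 1000 / fps)``; the sequence spans
    ``duration_s`` seconds (``round(duration_s * fps) + 1`` frames).
    """
    rng = np.random.default_rng(profile.seed)
    n = int(round(profile.duration_s * profile.fps)) + 1
    rel = np.rint(np.arange(n) * 1000.0 / profile.fps).astype(np.int64)
    ts = t0_ms + rel
    amp = _landmark_amplitudes(profile)[None, :, None]  # (1, 33, 1)

    t = rel[:, None, None] / 1000.0
    phase = rng.uniform(0, 2 * np.pi, size=(1, N_LANDMARKS, 3))
    sinus = profile.smooth_amp * np.sin(2 * np.pi * profile.smooth_freq_hz * t + phase)
    steps = rng.normal(0.0, profile.jitter_sd, size=(n - 1, N_LANDMARKS, 3))
    walk = np.concatenate(
        [np.zeros((1, N_LANDMARKS, 3)), np.cumsum(steps, axis=0)], axis=0
    )
    coords = BASE_POSE[None, :, :] + amp * (sinus + walk)

    inside = (coords[:, :, :2] >= 0.0) & (coords[:, :, :2] <= 1.0)
    clip_events = int((~inside).sum())
    coords[:, :, :2] = np.clip(coords[:, :, :2], 0.0, 1.0)

    seq = LandmarkSequence(subject_id=subject_id, timestamps_ms=ts, coords=coords)
    truth = _ground_truth(coords, clip_events)
    return seq, truth


def _ground_truth(coords: np.ndarray, clip_events: int) -> GroundTruth:
    d = coords[1:] - coords[:-1]
    norms = np.sqrt((d * d).sum(axis=-1))  # (n-1, 33)
    per_landmark = norms.sum(axis=0)
    region_path = {}
    for name, idx in DEFAULT_REGIONS.items():
        cols = sorted(idx)
        # same summation order as the Euclidean quantifier: landmarks within
        # a transition first, then transitions
        region_path[name] = float(norms[:, cols].sum(axis=1).sum())
    return GroundTruth(
        path_length=region_path["whole_body"],
        per_landmark_path=per_landmark,
        region_path_length=region_path,
        clip_events=clip_events,
    )


@dataclass
class SubjectPair:
    """Matched admission/discharge recordings of one synthetic subject."""

    subject_id: str
    early: LandmarkSequence
    late: LandmarkSequence
    early_truth: GroundTruth
    late_truth: GroundTruth
    amplitude_effect: float  # per-subject lognormal multiplier


def generate_cohort(
    n_subjects: int,
    early_profile: MotionProfile | None = None,
    late_profile: MotionProfile | None = None,
    seed: int = 0,
    subject_sd: float = 0.2,
) -> dict[str, SubjectPair]:
    """Paired early/late sequences for ``n_subjects`` synthetic subjects.

    A per-subject lognormal amplitude effect (sigma ``subject_sd`` on the
    log scale; 0 disables it) multiplies the region amplitudes of *both*
    sessions, modelling between-infant activity differences while keeping
    each subject's early-to-late amplitude ratio at the profile-specified
    value.  Deterministic given ``seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    early_profile = early_profile or MotionProfile()
    late_profile = late_profile or early_profile.scaled(2.0)
    rng = np.random.default_rng(seed)
    out: dict[str, SubjectPair] = {}
    for i in range(n_subjects):
        effect = float(np.exp(rng.normal(0.0, subject_sd))) if subject_sd > 0 else 1.0
        seeds = rng.integers(0, 2**31 - 1, size=2)
        sid = f"subject{i:02d}"
        e_prof = replace(early_profile.scaled(effect), seed=int(seeds[0]))
        l_prof = replace(late_profile.scaled(effect), seed=int(seeds[1]))
        e_seq, e_truth = generate_sequence(e_prof, subject_id=f"{sid}_early")
        l_seq, l_truth = generate_sequence(l_prof, subject_id=f"{sid}_late")
        out[sid] = SubjectPair(sid, e_seq, l_seq, e_truth, l_truth, effect)
    return out


def occlude(
    seq: LandmarkSequence, region: str, fraction: float, seed: int = 0
) -> LandmarkSequence:
    """Mark a region's landmarks invalid (NaN) in a random frame fraction.

    Emulates blanket/equipment occlusion: downstream quantification of the
    occluded region loses those frames while other regions are unaffected.
    Deterministic given ``seed``; ``fraction`` 0 returns an identical copy.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    coords = seq.coords.copy()
    idx = sorted(DEFAULT_REGIONS[region])
    cols = np.flatnonzero(np.isin(seq.landmark_indices, idx))
    n = len(seq)
    n_occ = int(round(fraction * n))
    if n_occ and len(cols):
        rng = np.random.default_rng(seed)
        frames = rng.choice(n, size=n_occ, replace=False)
        coords[np.ix_(frames, cols)] = np.nan
    return replace(seq, coords=coords)


def write_cohort(
    cohort: Mapping[str, SubjectPair], outdir: str | Path
) -> list[Path]:
    """Write each session as CSV plus a ground-truth JSON; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for sid, pair in cohort.items():
        for phase, seq, truth in (
            ("early", pair.early, pair.early_truth),
            ("late", pair.late, pair.late_truth),
        ):
            csv_path = outdir / f"{sid}_{phase}.csv"
            write_landmark_csv(seq, csv_path)
            gt_path = outdir / f"{sid}_{phase}.truth.json"
            gt_path.write_text(
                json.dumps(
                    {
                        "path_length": truth.path_length,
                        "region_path_length": truth.region_path_length,
                        "clip_events": truth.clip_events,
                        "amplitude_effect": pair.amplitude_effect,
                    },
                    indent=1,
                )
            )
            written.extend([csv_path, gt_path])
    return written
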