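"""Naive-loop reference implementations used only to cross-check quantifiers.

Each oracle is written as a literal, frame-by-frame translation of the
method definition — explicit Python loops, no vectorization, no code shared
with the package's computation paths.
"""

import math

import numpy as np


def _metric(name, d, p=3.0, inv_cov=None):
    if name == "euclidean":
        return math.sqrt(sum(v * v for v in d))
    if name == "manhattan":
        return sum(abs(v) for v in d)
    if name == "chebyshev":
        return max(abs(v) for v in d)
    if name == "minkowski":
        return sum(abs(v) ** p for v in d) ** (1.0 / p)
    if name == "mahalanobis":
        dv = np.asarray(d)
        return math.sqrt(float(dv @ inv_cov @ dv))
    raise KeyError(name)


def pairwise_total(coords, name, p=3.0, inv_cov=None):
    """Sum of the per-step metric over all transitions and landmarks."""
    total = 0.0
    n, k, _ = coords.shape
    for i in range(n - 1):
        for j in range(k):
            d = [coords[i + 1, j, a] - coords[i, j, a] for a in range(3)]
            total += _metric(name, d, p=p, inv_cov=inv_cov)
    return total


def diffacc_total(coords, fps):
    """Triple loop over interior frames, landmarks and dimensions."""
    total = 0.0
    n, k, _ = coords.shape
    for i in range(1, n - 1):
        for j in range(k):
            for a in range(3):
                v1 = (coords[i, j, a] - coords[i - 1, j, a]) * fps
                v2 = (coords[i + 1, j, a] - coords[i, j, a]) * fps
                total += abs(v2 - v1)
    return total


def angular_total(coords):
    """Turning angles via atan2(|a x b|, a . b) (alternative formula)."""
    total = 0.0
    n, k, _ = coords.shape
    for i in range(1, n - 1):
        for j in range(k):
            a = coords[i, j] - coords[i - 1, j]
            b = coords[i + 1, j] - coords[i, j]
            na = math.sqrt(float(a @ a))
            nb = math.sqrt(float(b @ b))
            if na == 0 or nb == 0:
                continue
            cross = np.cross(a, b)
            theta = math.atan2(math.sqrt(float(cross @ cross)), float(a @ b))
            total += abs(theta)
    return total


def lucas_kanade_total(coords):
    """Literal gradient/pseudoinverse evaluation of the stencil system.

    A stacks the central-difference gradient row once per dimension and the
    system A v = (P_{i+1} - P_i) is solved with numpy's pinv.
    """
    total = 0.0
    n, k, _ = coords.shape
    for i in range(1, n - 1):
        for j in range(k):
            g = (coords[i + 1, j] - coords[i - 1, j]) / 2.0
            b = coords[i + 1, j] - coords[i, j]
            A = np.vstack([g, g, g])
            v = np.linalg.pinv(A) @ b
            total += math.sqrt(float(v @ v))
    return total
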