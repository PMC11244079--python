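"""Elliptic Fourier descriptors of closed outlines.

A closed outline, parameterised by arc length t in [0, T), is expanded as

    x(t) = A0 + sum_n  a_n cos(2 pi n t / T) + b_n sin(2 pi n t / T)
    y(t) = C0 + sum_n  c_n cos(2 pi n t / T) + d_n sin(2 pi n t / T)

with one quadruple (a_n, b_n, c_n, d_n) per harmonic n.  The coefficients are
computed with the exact closed-form sums for a polyline (piecewise-linear
contour), not by FFT on sampled points.  Prior to coefficient extraction the
outline is normalised for position (centroid at origin), scale (unit centroid
size, the RMS radius) and starting point / in-plane rotation (the point
farthest from the centroid becomes the first point and is rotated onto the
positive x axis), so the retained 24 features (six harmonics, four
coefficients each) are invariant to translation, scale, rotation and the
arbitrary start of the trace.  Reflection is deliberately not normalised:
dorsal-view scans have a fixed handedness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .outline import Outline, perimeter

__all__ = [
    "EFDSet",
    "N_HARMONICS",
    "N_FEATURES",
    "FEATURE_NAMES",
    "normalize_outline",
    "compute_efds",
    "features",
    "reconstruct",
    "harmonic_power",
]

#: Harmonics retained for classification (four coefficients each).
N_HARMONICS = 6
N_FEATURES = 4 * N_HARMONICS
#: Reference harmonic count for "total" harmonic power.
POWER_REFERENCE_HARMONICS = 30

FEATURE_NAMES = tuple(
    f"{coef}{n}" for n in range(1, N_HARMONICS + 1) for coef in "abcd"
)


@dataclass
class EFDSet:
    """Per-harmonic coefficient quadruples plus outline metadata.

    ``coefficients`` has shape (n_harmonics, 4) in (a, b, c, d) order.
    ``centroid_size`` is the RMS distance of the outline points from their
    centroid; ``perimeter`` is the closed polygon length T.
    """

    coefficients: np.ndarray
    centroid: Tuple[float, float]
    centroid_size: float
    perimeter: float
    n_points: int

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.ndim != 2 or self.coefficients.shape[1] != 4:
            raise ValueError("coefficients must have shape (n_harmonics, 4)")
        if self.coefficients.shape[0] < 1:
            raise ValueError("need at least one harmonic")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite coefficients")

    @property
    def n_harmonics(self) -> int:
        return self.coefficients.shape[0]

    def flatten(self) -> np.ndarray:
        """Harmonic-major (a1, b1, c1, d1, a2, ...) flat vector."""
        return self.coefficients.ravel().copy()

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "coefficients": self.coefficients.tolist(),
                "centroid": list(self.centroid),
                "centroid_size": self.centroid_size,
                "perimeter": self.perimeter,
                "n_points": self.n_points,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "EFDSet":
        import json

        d = json.loads(text)
        return cls(
            coefficients=np.array(d["coefficients"]),
            centroid=tuple(d["centroid"]),
            centroid_size=d["centroid_size"],
            perimeter=d["perimeter"],
            n_points=d["n_points"],
        )


def normalize_outline(o: Outline) -> Outline:
    """Normalise position, scale, start point and rotation of an outline.

    Steps: (1) translate the centroid to the origin; (2) divide by the
    centroid size (RMS radius); (3) cyclically re-index so the point farthest
    from the centroid comes first (ties broken by lowest original index);
    (4) rotate rigidly so that first point lies on the positive x axis.
    Orientation (CCW) is preserved.
    """
    pts = o.points - o.points.mean(axis=0)
    radii = np.linalg.norm(pts, axis=1)
    size = float(np.sqrt(np.mean(radii**2)))
    if size <= 0 or not np.isfinite(size):
        raise ValueError("degenerate outline: all points coincident")
    pts = pts / size
    start = int(np.argmax(radii))  # argmax takes the lowest index on ties
    pts = np.roll(pts, -start, axis=0)
    angle = np.arctan2(pts[0, 1], pts[0, 0])
    c, s = np.cos(-angle), np.sin(-angle)
    rot = np.array([[c, -s], [s, c]])
    return Outline(pts @ rot.T)


def compute_efds(o: Outline, n_harmonics: int = N_HARMONICS) -> EFDSet:
    """Closed-form elliptic Fourier coefficients of a polyline outline.

    With segment increments (dx_p, dy_p), lengths dt_p and cumulative arc
    lengths t_p (t_0 = 0, t_K = T):

        a_n = T / (2 n^2 pi^2) * sum_p (dx_p / dt_p)
              * [cos(2 pi n t_p / T) - cos(2 pi n t_{p-1} / T)]

    b_n analogously with sines, and c_n, d_n with dy_p.  These sums are exact
    for the polyline; no quadrature approximation is involved.  The outline
    is expected to be centred (or the caller accepts the recorded centroid;
    the DC terms are not carried).
    """
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    pts = o.points
    if len(pts) < 3:
        raise ValueError("outline needs at least 3 points")
    closed = np.vstack([pts, pts[:1]])
    d = np.diff(closed, axis=0)
    dt = np.linalg.norm(d, axis=1)
    zero = np.flatnonzero(dt == 0)
    if zero.size:
        raise ValueError(
            f"repeated consecutive points at indices {zero.tolist()}"
        )
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]

    n = np.arange(1, n_harmonics + 1)[:, None]  # (H, 1)
    phase = 2.0 * np.pi * n * t[None, :] / T  # (H, K+1)
    dcos = np.cos(phase[:, 1:]) - np.cos(phase[:, :-1])
    dsin = np.sin(phase[:, 1:]) - np.sin(phase[:, :-1])
    scale = T / (2.0 * (n.ravel() ** 2) * np.pi**2)

    vx = d[:, 0] / dt
    vy = d[:, 1] / dt
    a = scale * (dcos @ vx)
    b = scale * (dsin @ vx)
    c = scale * (dcos @ vy)
    dd = scale * (dsin @ vy)

    centroid = pts.mean(axis=0)
    radii = np.linalg.norm(pts - centroid, axis=1)
    size = float(np.sqrt(np.mean(radii**2)))
    return EFDSet(
        coefficients=np.column_stack([a, b, c, dd]),
        centroid=(float(centroid[0]), float(centroid[1])),
        centroid_size=size,
        perimeter=float(T),
        n_points=len(pts),
    )


def features(o: Outline) -> np.ndarray:
    """24-element normalized descriptor vector of an outline.

    Composes :func:`normalize_outline` with :func:`compute_efds` at six
    harmonics and flattens harmonic-major: (a1, b1, c1, d1, ..., a6, ..., d6).
    """
    return compute_efds(normalize_outline(o), N_HARMONICS).flatten()


def reconstruct(e: EFDSet, n_points: int = 360) -> Outline:
    """Evaluate the truncated Fourier series at equal steps of t.

    The inverse of :func:`compute_efds` up to truncation; used by the
    synthetic generator and for reconstruction diagnostics.  An all-zero
    coefficient set yields every point at the centroid (degenerate, flagged
    by downstream validation rather than here).
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    coef = e.coefficients
    n = np.arange(1, e.n_harmonics + 1)[:, None]
    # Phase is n * 2 pi t / T on an equal grid of t; T cancels.
    tau = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)[None, :]
    cos = np.cos(n * tau)
    sin = np.sin(n * tau)
    x = e.centroid[0] + coef[:, 0] @ cos + coef[:, 1] @ sin
    y = e.centroid[1] + coef[:, 2] @ cos + coef[:, 3] @ sin
    return Outline(np.column_stack([x, y]))


def harmonic_power(e: EFDSet) -> Tuple[np.ndarray, np.ndarray]:
    """Per-harmonic power P_n = (a_n^2 + b_n^2 + c_n^2 + d_n^2) / 2.

    Returns ``(powers, cumulative_fraction)`` where the cumulative fraction
    is P_1..k over the total across the harmonics present in ``e``.  Callers
    wanting the conventional reference total should compute ``e`` with
    :data:`POWER_REFERENCE_HARMONICS` harmonics.
    """
    powers = 0.5 * np.sum(e.coefficients**2, axis=1)
    total = float(powers.sum())
    if total <= 0:
        raise ValueError("degenerate outline: zero harmonic power")
    return powers, np.cumsum(powers) / total
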