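"""Smoothing and resampling of raw digitizer traces.

Each raw fascicle trace is smoothed by fitting every coordinate as a
quadratic polynomial of a monotone curve parameter (the normalized
cumulative chord length of the raw points — the natural abscissa for a
digitizer stream recorded at fixed rate with variable hand speed). The
fitted space curve is then evaluated at 20 points with equal *arc length*
spacing, which defines the fascicle length L_F as the sum of the 19
segment lengths. A parameter-equidistant mode is kept for sensitivity
checks.

The arc length of a quadratic space curve has a closed form: with
r(t) = a t^2 + b t + c the squared speed |r'(t)|^2 = A t^2 + B t + C is a
nonnegative quadratic, and the antiderivative of its square root is
elementary. Equal-arc-length parameters are recovered by root finding on
that antiderivative.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .core import Fascicle, FascicleTrace, MuscleDataset, N_FASCICLE_POINTS

_EPS = 1e-14


def _arc_antiderivative(A: float, B: float, C: float, t: np.ndarray) -> np.ndarray:
    """Antiderivative (at 0 equal 0) of sqrt(A s^2 + B s + C) evaluated at t.

    Requires A >= 0, C >= 0 and B^2 <= 4AC (true for any squared speed).
    Handles the degenerate straight-line (A ~ 0) and cusp (discriminant ~ 0)
    branches explicitly.
    """
    t = np.asarray(t, dtype=float)
    scale = A + abs(B) + C
    if scale <= 0.0:
        return np.zeros_like(t)
    if A <= _EPS * scale:
        # |B| <= 2 sqrt(A C) is then negligible too: constant speed.
        return np.sqrt(C) * t
    disc = 4.0 * A * C - B * B
    if disc <= _EPS * scale * scale:
        # speed = sqrt(A) |s - t0|: piecewise linear in s.
        t0 = -B / (2.0 * A)
        sa = np.sqrt(A)

        def ramp(x):
            return np.where(x > 0, x * x, 0.0)

        return 0.5 * sa * (ramp(t - t0) - ramp(-t0) + ramp(t0) - ramp(t0 - t))
    root = np.sqrt(A * t * t + B * t + C)
    sq_a = np.sqrt(A)
    term = lambda u, r: (2.0 * A * u + B) * r / (4.0 * A) + disc / (
        8.0 * A * sq_a
    ) * np.arcsinh((2.0 * A * u + B) / np.sqrt(disc))
    return term(t, root) - term(0.0, np.sqrt(C))


@dataclass
class QuadraticCurve:
    """Quadratic space-curve model r(t) = a t^2 + b t + c, t in [0, 1].

    ``coef`` is a (3, 3) array whose rows are a, b, c. ``residual_rms`` is
    the root-mean-square fit residual over all coordinates of the raw trace.
    """

    fascicle_id: str
    coef: np.ndarray
    residual_rms: float

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        if self.coef.shape != (3, 3):
            raise ValueError("coef must have shape (3, 3) (rows a, b, c)")

    def evaluate(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        a, b, c = self.coef
        return np.outer(t * t, a) + np.outer(t, b) + c

    def _speed_poly(self) -> tuple:
        a, b = self.coef[0], self.coef[1]
        return 4.0 * a @ a, 4.0 * a @ b, b @ b

    def arc_length(self, t: float = 1.0) -> float:
        """Arc length of the fitted curve from parameter 0 to ``t``."""
        A, B, C = self._speed_poly()
        return float(_arc_antiderivative(A, B, C, np.asarray(t)))

    def parameter_at_arc_length(self, s: float, tol: float = 1e-10) -> float:
        """Invert the arc-length function: t such that arc(0..t) = s."""
        total = self.arc_length(1.0)
        if not 0.0 <= s <= total * (1.0 + 1e-12):
            raise ValueError(f"arc length {s} outside [0, {total}]")
        if s <= 0.0:
            return 0.0
        if s >= total:
            return 1.0
        A, B, C = self._speed_poly()
        f = lambda t: float(_arc_antiderivative(A, B, C, np.asarray(t))) - s
        return float(brentq(f, 0.0, 1.0, xtol=tol))


def chord_parameter(points: np.ndarray) -> np.ndarray:
    """Normalized cumulative chord length of a polyline, in [0, 1]."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] <= 0.0:
        raise ValueError("polyline has zero total chord length")
    return cum / cum[-1]


def smooth_fascicle(trace: FascicleTrace) -> QuadraticCurve:
    """Fit each coordinate as a quadratic polynomial of chord-length parameter.

    Collinear input is valid (the quadratic degenerates to a line). Fewer
    than 3 points is an error (enforced by :class:`FascicleTrace`).
    """
    pts = trace.points
    t = chord_parameter(pts)
    design = np.column_stack([t * t, t, np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(design, pts, rcond=None)
    resid = design @ coef - pts
    residual_rms = float(np.sqrt(np.mean(resid**2)))
    return QuadraticCurve(trace.fascicle_id, coef, residual_rms)


def resample_fascicle(
    curve: QuadraticCurve,
    n_points: int = N_FASCICLE_POINTS,
    spacing: str = "arc",
) -> Fascicle:
    """Evaluate the fitted curve at ``n_points`` equidistant points.

    ``spacing='arc'`` (default) spaces the points at equal arc length along
    the curve; ``spacing='parameter'`` spaces them at equal curve parameter
    (useful only for sensitivity checks — the two differ on curved
    fascicles).
    """
    total = curve.arc_length(1.0)
    if total <= 0.0:
        raise ValueError(f"curve {curve.fascicle_id!r} has zero arc length")
    if spacing == "arc":
        targets = np.linspace(0.0, total, n_points)
        t = np.array([curve.parameter_at_arc_length(s) for s in targets])
    elif spacing == "parameter":
        t = np.linspace(0.0, 1.0, n_points)
    else:
        raise ValueError(f"unknown spacing {spacing!r}")
    return Fascicle(curve.fascicle_id, curve.evaluate(t))


def preprocess_dataset(dataset: MuscleDataset, spacing: str = "arc") -> MuscleDataset:
    """Smooth and resample every raw trace; returns a new dataset.

    Traces whose fitted curve degenerates to zero length are dropped with a
    warning. Landmarks and metadata are carried over unchanged.
    """
    if not dataset.traces:
        raise ValueError("dataset has no raw traces to preprocess")
    out = dataset.copy()
    fascicles = []
    dropped = []
    for trace in out.traces:
        try:
            curve = smooth_fascicle(trace)
            fascicles.append(resample_fascicle(curve, spacing=spacing))
        except ValueError as exc:
            dropped.append((trace.fascicle_id, str(exc)))
    if dropped:
        warnings.warn(f"dropped {len(dropped)} degenerate trace(s): {dropped}")
    out.fascicles = fascicles
    return out


def smoothing_residuals(dataset: MuscleDataset) -> dict:
    """Per-fascicle quadratic-fit RMS residuals (mm), for diagnostics."""
    return {
        t.fascicle_id: smooth_fascicle(t).residual_rms for t in dataset.traces
    }
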