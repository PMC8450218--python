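"""Four-parameter geometric growth transformation for unipennate muscles.

Growth between two ages is modelled as the superposition of four
operations applied to every fascicle of a dataset, in this canonical
order:

1. *length scaling* — each fascicle is translated rigidly along e1 by
   ``dx_F = x_F * (dL_MB / L_MB) * f_c`` where ``x_F`` is its midpoint
   coordinate measured from the proximal extreme of the point cloud and
   ``f_c >= 1`` corrects for the fact that midpoints occupy only a
   subdomain of (0, L_MB);
2. *width scaling* — each fascicle is translated along its side's
   transversal direction (y- or y+) by ``dy_F = y_F * (dW_MB / W_MB)``,
   where ``y_F`` is the midpoint's distance from the dividing plane. The
   two transversal directions follow the local orientation of the crested
   aponeurosis on either side of the plane, preserving the cross-sectional
   shape of muscles with a central crest;
3. *fascicle lengthening* — every fascicle's arc length grows by
   ``dL_F`` through an affine stretch along its chord; the two endpoint
   displacements are proportional to the endpoints' distances from the
   muscle's line of action (|u2|/|u1| = d2/d1, |u1|+|u2| = dL_F for
   straight fascicles), which keeps fascicles from protruding through
   internal structures;
4. *fascicle rotation* — every fascicle is rotated rigidly by ``dbeta``
   about its arc-length midpoint, in the vertical plane spanned by e2 and
   the chord's in-plane projection, so pennation changes while the
   transversal angle and the fascicle length stay fixed.

The frame, belly dimensions, dividing plane and transversal directions
are derived once from the input dataset. Because lengthening and rotation
also move the e1-extremal points, :func:`grow` solves the length-scaling
shift coefficient against the *final* composed geometry, so the belly
length of the output exceeds the input's by exactly ``dL_MB``; with the
other three parameters zero this coincides with the correction factor of
:func:`determine_fc`.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .architecture import (
    MuscleFrame,
    _pca,
    aponeurosis_points,
    compute_frame,
    belly_dims,
    sample_std,
)
from .core import ArchitectureSummary, Fascicle, GrowthParams, MuscleDataset

#: Summary metrics the model is scored on (they are not model inputs).
DEFAULT_ERROR_METRICS = (
    "apo_length_mean_mm",
    "apo_width_mean_mm",
    "muscle_height_mm",
    "muscle_mass_g",
)


@dataclass
class SideSplit:
    """Dividing plane and per-side transversal scaling directions.

    The plane is spanned by e1 and e2 (normal along e3) through the
    centroid of all fascicle midpoints; ``y_minus``/``y_plus`` are unit
    vectors with zero e1 component pointing away from the plane on the
    negative/positive e3 side.
    """

    plane_point: np.ndarray
    plane_normal: np.ndarray
    y_minus: np.ndarray
    y_plus: np.ndarray

    def side_of(self, point: np.ndarray) -> float:
        return float((np.asarray(point) - self.plane_point) @ self.plane_normal)


@dataclass
class GrowthContext:
    """Preprocessing products the growth operations share.

    Everything here is derived once from the input dataset: the frame, the
    belly dimensions, the correction factor f_c for isolated length
    scaling, the side split, and the muscle's line of action (through the
    MTC landmarks when recorded, else along e1 through the fascicle-point
    centroid).
    """

    frame: MuscleFrame
    l_mb: float
    w_mb: float
    f_c: float
    side_split: SideSplit
    line_point: np.ndarray
    line_direction: np.ndarray
    x_offset: float  # e1 coordinate of the proximal extreme of the cloud
    midpoint_x: dict  # fascicle_id -> x_F in [0, L_MB]


def _extent_along(points: np.ndarray, direction: np.ndarray) -> float:
    c = points @ direction
    return float(c.max() - c.min())


def _fascicle_shift_data(dataset: MuscleDataset, frame: MuscleFrame):
    """Per-fascicle e1 spans and midpoint coordinates from the proximal
    extreme: (x_F, min_e1, max_e1, x_offset, L_MB)."""
    e1 = frame.e1
    mins, maxs, mids = [], [], []
    for f in dataset.fascicles:
        c = f.points @ e1
        mins.append(c.min())
        maxs.append(c.max())
        mids.append(f.midpoint @ e1)
    mins = np.asarray(mins)
    maxs = np.asarray(maxs)
    mids = np.asarray(mids)
    x_offset = float(mins.min())
    l_mb = float(maxs.max() - x_offset)
    return mids - x_offset, mins, maxs, x_offset, l_mb


def _solve_shift_scale(x_f, mins, maxs, target_extent, tol=1e-13):
    """Find lam such that extent of {[min_i, max_i] + lam * x_f_i} equals
    ``target_extent``; picks the root on the order-preserving branch."""

    def extent(lam):
        return float((maxs + lam * x_f).max() - (mins + lam * x_f).min())

    def g(lam):
        return extent(lam) - target_extent

    # The extent is piecewise linear and convex in lam with a minimum near
    # lam = -1 (midpoints collapse); scan for a bracket on the physical
    # (increasing) branch first, then fall back to the full scan.
    grid = np.linspace(-0.95, 6.0, 400)
    values = np.array([g(x) for x in grid])
    sign_change = np.flatnonzero(np.sign(values[:-1]) != np.sign(values[1:]))
    exact = np.flatnonzero(values == 0.0)
    if exact.size:
        return float(grid[exact[0]])
    if sign_change.size == 0:
        raise ValueError(
            "no length-scaling correction reproduces the requested belly "
            "length (pathological geometry)"
        )
    k = int(sign_change[0])
    return float(brentq(g, grid[k], grid[k + 1], xtol=tol))


def determine_fc(
    dataset: MuscleDataset, frame: MuscleFrame, delta_l_mb: float
) -> float:
    """Correction factor f_c for the isolated length-scaling operation.

    f_c is the unique factor such that shifting every fascicle rigidly by
    ``x_F * (dL_MB / L_MB) * f_c`` along e1 changes the extent of all
    fascicle points along e1 by exactly ``dL_MB``. ``dL_MB = 0`` gives
    f_c = 1 by convention. Raises if no root exists in [1, 10].
    """
    if delta_l_mb == 0.0:
        return 1.0
    x_f, mins, maxs, _, l_mb = _fascicle_shift_data(dataset, frame)
    if delta_l_mb <= -l_mb:
        raise ValueError("delta_l_mb would make the belly length nonpositive")
    rel = delta_l_mb / l_mb
    target = l_mb + delta_l_mb

    def g(fc):
        lam = rel * fc
        return float((maxs + lam * x_f).max() - (mins + lam * x_f).min()) - target

    if abs(g(1.0)) < 1e-12:
        return 1.0
    # scan [1, 10] for a sign-change bracket (the extent is monotone in f_c
    # over the physical branch but can fold back for extreme shrinkage)
    grid = np.linspace(1.0, 10.0, 200)
    values = np.array([g(x) for x in grid])
    sign_change = np.flatnonzero(np.sign(values[:-1]) != np.sign(values[1:]))
    if sign_change.size == 0:
        raise ValueError("no f_c in [1, 10] satisfies the extent contract")
    k = int(sign_change[0])
    return float(brentq(g, grid[k], grid[k + 1], xtol=1e-13))


def build_side_split(dataset: MuscleDataset, frame: MuscleFrame) -> SideSplit:
    """Dividing plane and transversal directions y-, y+.

    The plane is spanned by e1 and e2 through the centroid of all fascicle
    midpoints. Each side's direction follows the local in-plane width axis
    of the crested aponeurosis (the one with the larger out-of-plane
    spread, identified by its third principal component), obtained by PCA
    of that side's endpoints and orthogonalized against e1. A side with
    fewer than 2 endpoints falls back to +-e3 with a warning.
    """
    midpoints = np.asarray([f.midpoint for f in dataset.fascicles])
    plane_point = midpoints.mean(axis=0)
    e1, e2, e3 = frame.e1, frame.e2, frame.e3

    pts_a, pts_b = aponeurosis_points(frame, dataset)
    spread = []
    for pts in (pts_a, pts_b):
        if len(pts) < 3:
            spread.append(0.0)
        else:
            _, _, s = _pca(pts)
            spread.append(float(s[2]))
    crest_pts = pts_a if spread[0] >= spread[1] else pts_b

    directions = []
    for sign in (-1.0, 1.0):
        side_pts = crest_pts[
            np.sign((crest_pts - plane_point) @ e3) * sign >= 0
        ]
        if len(side_pts) < 2:
            warnings.warn(
                f"side {'+' if sign > 0 else '-'} of the dividing plane has "
                "fewer than 2 aponeurosis endpoints; falling back to e3"
            )
            directions.append(sign * e3)
            continue
        _, vt, s = _pca(side_pts)
        if len(side_pts) >= 3 and s[1] > 1e-9 * max(s[0], 1.0):
            normal = vt[2]
            y = np.cross(normal, e1)
        else:
            y = vt[0] - (vt[0] @ e1) * e1  # near-collinear side: project PC1
        y -= (y @ e1) * e1
        n = np.linalg.norm(y)
        if n < 1e-12:
            warnings.warn("degenerate side geometry; falling back to e3")
            directions.append(sign * e3)
            continue
        y /= n
        if (y @ e3) * sign < 0:
            y = -y
        directions.append(y)
    return SideSplit(
        plane_point=plane_point,
        plane_normal=e3.copy(),
        y_minus=directions[0],
        y_plus=directions[1],
    )


def line_of_action(dataset: MuscleDataset, frame: MuscleFrame):
    """(point, unit direction) of the muscle's line of action.

    Uses the MTC landmark line when both landmarks are recorded, otherwise
    e1 through the centroid of all fascicle points.
    """
    if dataset.has_landmarks():
        direction = dataset.mtc_insertion - dataset.mtc_origin
        n = np.linalg.norm(direction)
        if n <= 0.0:
            raise ValueError("MTC landmarks coincide; line of action undefined")
        return dataset.mtc_origin.copy(), direction / n
    return dataset.all_points().mean(axis=0), frame.e1.copy()


def build_context(
    dataset: MuscleDataset, delta_l_mb: float = 0.0
) -> GrowthContext:
    """Run the preprocessing step of the growth model once."""
    frame = compute_frame(dataset)
    x_f, _, _, x_offset, l_mb = _fascicle_shift_data(dataset, frame)
    _, w_mb = belly_dims(frame, dataset)
    f_c = determine_fc(dataset, frame, delta_l_mb)
    split = build_side_split(dataset, frame)
    point, direction = line_of_action(dataset, frame)
    midpoint_x = {
        f.fascicle_id: float(x_f[i]) for i, f in enumerate(dataset.fascicles)
    }
    return GrowthContext(
        frame=frame,
        l_mb=l_mb,
        w_mb=w_mb,
        f_c=f_c,
        side_split=split,
        line_point=point,
        line_direction=direction,
        x_offset=x_offset,
        midpoint_x=midpoint_x,
    )


def scale_length(
    dataset: MuscleDataset,
    ctx: GrowthContext,
    delta_l_mb: float,
    f_c: Optional[float] = None,
) -> MuscleDataset:
    """Shift each fascicle rigidly along e1 by x_F * (dL_MB / L_MB) * f_c."""
    if delta_l_mb == 0.0:
        return dataset.copy()
    if f_c is None:
        f_c = ctx.f_c
    lam = (delta_l_mb / ctx.l_mb) * f_c
    e1 = ctx.frame.e1
    fascicles = [
        f.translated(ctx.midpoint_x[f.fascicle_id] * lam * e1)
        for f in dataset.fascicles
    ]
    return dataset.replace_fascicles(fascicles)


def scale_width(
    dataset: MuscleDataset, ctx: GrowthContext, delta_w_mb: float
) -> MuscleDataset:
    """Shift each fascicle along its side's transversal direction by
    y_F * (dW_MB / W_MB)."""
    if delta_w_mb == 0.0:
        return dataset.copy()
    if ctx.w_mb <= 0.0:
        raise ValueError("belly width must be positive for width scaling")
    split = ctx.side_split
    rel = delta_w_mb / ctx.w_mb
    fascicles = []
    for f in dataset.fascicles:
        y_f = split.side_of(f.midpoint)
        direction = split.y_plus if y_f >= 0 else split.y_minus
        fascicles.append(f.translated(abs(y_f) * rel * direction))
    return dataset.replace_fascicles(fascicles)


def _point_line_distance(point, line_point, line_dir):
    rel = point - line_point
    return float(np.linalg.norm(rel - (rel @ line_dir) * line_dir))


def lengthen_fascicles(
    dataset: MuscleDataset, ctx: GrowthContext, delta_l_f: float
) -> MuscleDataset:
    """Stretch every fascicle along its chord so its arc length grows by
    ``delta_l_f``.

    The stretch is an affine map about an anchor on the chord placed at
    fraction d1/(d1+d2) from endpoint 1, where d1 and d2 are the
    endpoints' perpendicular distances to the muscle's line of action;
    the endpoint displacements therefore satisfy |u2|/|u1| = d2/d1. The
    scale factor is solved so the polyline arc length hits the target
    within 1e-9 mm; curvature (perpendicular offsets from the chord) is
    left unscaled, so relative curvature drops as fascicles lengthen.
    """
    if delta_l_f == 0.0:
        return dataset.copy()
    fascicles = []
    for f in dataset.fascicles:
        target = f.length + delta_l_f
        if target <= 0.0:
            raise ValueError(
                f"delta_l_f = {delta_l_f} would make fascicle "
                f"{f.fascicle_id!r} non-positive in length"
            )
        d1 = _point_line_distance(f.p1, ctx.line_point, ctx.line_direction)
        d2 = _point_line_distance(f.p2, ctx.line_point, ctx.line_direction)
        if d1 + d2 <= 1e-12:
            warnings.warn(
                f"fascicle {f.fascicle_id!r} lies on the line of action; "
                "splitting the length change equally between endpoints"
            )
            frac = 0.5
        else:
            frac = d1 / (d1 + d2)
        chord = f.chord
        chord_len = np.linalg.norm(chord)
        if chord_len <= 0.0:
            raise ValueError(f"fascicle {f.fascicle_id!r} has zero chord")
        c_hat = chord / chord_len
        anchor = f.p1 + frac * chord
        rel = f.points - anchor
        along = rel @ c_hat
        perp = rel - np.outer(along, c_hat)
        d_along = np.diff(along)
        d_perp = np.diff(perp, axis=0)
        perp_sq = np.einsum("ij,ij->i", d_perp, d_perp)

        def arc(s):
            return float(np.sqrt(s * s * d_along**2 + perp_sq).sum())

        lo, hi = 0.0, max(2.0, 2.0 * target / max(chord_len, 1e-12))
        if arc(lo) > target:
            raise ValueError(
                f"fascicle {f.fascicle_id!r} cannot shrink to {target} mm: "
                "its perpendicular structure is already longer"
            )
        while arc(hi) < target:
            hi *= 2.0
            if hi > 1e9:
                raise ValueError("lengthening scale did not bracket")
        s = brentq(lambda x: arc(x) - target, lo, hi, xtol=1e-12)
        new_points = anchor + np.outer(s * along, c_hat) + perp
        fascicles.append(f.with_points(new_points))
    return dataset.replace_fascicles(fascicles)


def rotate_fascicles(
    dataset: MuscleDataset, ctx: GrowthContext, delta_beta: float
) -> MuscleDataset:
    """Rotate every fascicle rigidly by ``delta_beta`` about its arc-length
    midpoint so that its pennation angle changes by exactly ``delta_beta``
    while the transversal angle, fascicle length and midpoint stay fixed.

    The rotation axis is perpendicular to the vertical plane spanned by e2
    and the chord's projection onto the aponeurosis plane. Rotations that
    would push the pennation angle outside [0, 90] degrees are clamped
    with a warning; fascicles already perpendicular to the aponeurosis
    plane are skipped with a warning.
    """
    if delta_beta == 0.0:
        return dataset.copy()
    e2 = ctx.frame.e2
    fascicles = []
    clamped, skipped = [], []
    for f in dataset.fascicles:
        chord = f.chord
        c2 = chord @ e2
        proj = chord - c2 * e2
        proj_norm = np.linalg.norm(proj)
        if proj_norm < 1e-12 * np.linalg.norm(chord):
            skipped.append(f.fascicle_id)
            fascicles.append(f.with_points(f.points.copy()))
            continue
        u = proj / proj_norm
        v = e2 if c2 >= 0 else -e2
        beta = np.degrees(np.arctan2(abs(c2), proj_norm))
        step = delta_beta
        if beta + step > 90.0:
            step = 90.0 - beta
            clamped.append(f.fascicle_id)
        elif beta + step < 0.0:
            step = -beta
            clamped.append(f.fascicle_id)
        axis = np.cross(u, v)
        theta = np.radians(step)
        # Rodrigues rotation about the arc-length midpoint; rotating u
        # toward v by theta increases the pennation angle by exactly theta.
        mid = f.midpoint
        rel = f.points - mid
        cos_t, sin_t = np.cos(theta), np.sin(theta)
        rotated = (
            rel * cos_t
            + np.cross(np.broadcast_to(axis, rel.shape), rel) * sin_t
            + np.outer(rel @ axis, axis) * (1.0 - cos_t)
        )
        fascicles.append(f.with_points(mid + rotated))
    if clamped:
        warnings.warn(
            f"pennation change clamped to stay within [0, 90] deg for "
            f"{len(clamped)} fascicle(s): {clamped[:5]}..."
        )
    if skipped:
        warnings.warn(
            f"skipped rotation of {len(skipped)} fascicle(s) perpendicular "
            f"to the aponeurosis plane: {skipped[:5]}..."
        )
    return dataset.replace_fascicles(fascicles)


def grow(dataset: MuscleDataset, params: GrowthParams) -> MuscleDataset:
    """Apply the four-parameter growth transformation.

    Operations are composed in the canonical order (length scaling, width
    scaling, fascicle lengthening, fascicle rotation) with the frame,
    dividing plane and line of action derived once from the input. The
    length-scaling shift coefficient is solved against the composed
    geometry so the output's belly length along the input frame's e1
    exceeds the input's by exactly ``delta_l_mb``; see the module
    docstring. With all four parameters zero the input is returned
    unchanged (coordinates bit-equal).
    """
    if not dataset.fascicles:
        raise ValueError("growth requires a preprocessed dataset")
    ctx = build_context(dataset, delta_l_mb=params.delta_l_mb)
    _validate_params(dataset, ctx, params)
    if params.is_identity():
        return dataset.copy()

    # Width scaling, lengthening and rotation commute with the per-fascicle
    # e1 translations of length scaling (their displacement fields depend
    # only on e2/e3 offsets, chords and the fixed frame), so the length
    # shifts can be solved after composing the other three operations.
    out = scale_width(dataset, ctx, params.delta_w_mb)
    out = lengthen_fascicles(out, ctx, params.delta_l_f)
    out = rotate_fascicles(out, ctx, params.delta_beta)
    if params.delta_l_mb != 0.0:
        e1 = ctx.frame.e1
        x_f = np.array([ctx.midpoint_x[f.fascicle_id] for f in out.fascicles])
        mins = np.array([(f.points @ e1).min() for f in out.fascicles])
        maxs = np.array([(f.points @ e1).max() for f in out.fascicles])
        target = ctx.l_mb + params.delta_l_mb
        lam = _solve_shift_scale(x_f, mins, maxs, target)
        fascicles = [
            f.translated(ctx.midpoint_x[f.fascicle_id] * lam * e1)
            for f in out.fascicles
        ]
        out = out.replace_fascicles(fascicles)
    return out


def _validate_params(dataset, ctx, params: GrowthParams) -> None:
    if params.delta_l_mb <= -ctx.l_mb:
        raise ValueError(
            f"delta_l_mb = {params.delta_l_mb} mm makes the belly length "
            f"non-positive (L_MB = {ctx.l_mb:.3f} mm)"
        )
    if params.delta_w_mb <= -ctx.w_mb:
        raise ValueError(
            f"delta_w_mb = {params.delta_w_mb} mm makes the belly width "
            f"non-positive (W_MB = {ctx.w_mb:.3f} mm)"
        )
    min_lf = min(f.length for f in dataset.fascicles)
    if params.delta_l_f <= -min_lf:
        raise ValueError(
            f"delta_l_f = {params.delta_l_f} mm makes the shortest fascicle "
            f"non-positive (min L_F = {min_lf:.3f} mm)"
        )


def compare(
    predicted: ArchitectureSummary,
    measured: ArchitectureSummary,
    metrics=DEFAULT_ERROR_METRICS,
) -> pd.DataFrame:
    """Relative model error per metric: 100 * (predicted - measured) / measured.

    Metrics whose measured value is zero are skipped with a warning.
    Returns a DataFrame indexed by metric with columns ``predicted``,
    ``measured`` and ``error_pct``.
    """
    rows = {}
    for metric in metrics:
        pred = getattr(predicted, metric)
        meas = getattr(measured, metric)
        if pred is None or meas is None:
            warnings.warn(f"metric {metric!r} missing in a summary; skipped")
            continue
        if meas == 0.0:
            warnings.warn(f"metric {metric!r} has measured value 0; skipped")
            continue
        rows[metric] = {
            "predicted": pred,
            "measured": meas,
            "error_pct": 100.0 * (pred - meas) / meas,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def aggregate_errors(errors) -> tuple:
    """Mean and sample standard deviation of a collection of relative
    errors (the row-aggregate convention of model-error tables)."""
    errors = np.asarray(list(errors), dtype=float)
    if errors.size == 0:
        raise ValueError("no errors to aggregate")
    return float(errors.mean()), sample_std(errors)
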