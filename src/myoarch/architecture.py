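"""Muscle coordinate frame and architectural parameter measurement.

The muscle frame (e1, e2, e3) is an orthonormal right-handed triad derived
from the fascicle endpoints: e1 points in aponeurosis length direction,
e3 in aponeurosis width direction (together they span the aponeurosis
plane), and e2 is the plane normal. Endpoints are first assigned to the
two superficial aponeuroses (A and B) with a provisional PCA of all
endpoints; per-aponeurosis PCAs are then averaged to form the axes, and
the assignment is refined once in the resulting frame.

Sign conventions (so that reported values are reproducible): e1 points
proximal-to-distal (using the MTC origin landmark when present, otherwise
the sign that makes the endpoint distribution's skewness along e1
nonnegative); e2 points from aponeurosis B to A; e3 completes the
right-handed triad.

The muscle volume is estimated from a boundary triangulation of all
fascicle points: an alpha-complex of the Delaunay tetrahedralization whose
alpha sits on the spectrum between the tightest single-component complex
covering all points (shrink factor 1) and the convex hull (shrink factor
0), interpolated by the shrink fraction over the sorted circumradius
spectrum. The default shrink factor is 0.6.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.spatial import Delaunay
from scipy.spatial import QhullError

from .core import (
    ArchitectureSummary,
    Fascicle,
    MuscleDataset,
    MUSCLE_DENSITY_G_PER_MM3,
)

DEFAULT_SHRINK = 0.6


def sample_std(values) -> float:
    """Sample standard deviation (ddof=1); 0.0 for fewer than two values."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return 0.0
    return float(np.std(values, ddof=1))


@dataclass
class MuscleFrame:
    """Orthonormal muscle axes plus the endpoint-to-aponeurosis assignment.

    ``side_a_endpoint`` maps fascicle_id -> index (0 for p1, 1 for p2) of
    the endpoint attached to aponeurosis A.
    """

    e1: np.ndarray
    e2: np.ndarray
    e3: np.ndarray
    origin: np.ndarray
    side_a_endpoint: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("e1", "e2", "e3", "origin"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        basis = np.column_stack([self.e1, self.e2, self.e3])
        if abs(abs(np.linalg.det(basis)) - 1.0) > 1e-9:
            raise ValueError("frame axes are not orthonormal")

    def coords(self, points: np.ndarray) -> np.ndarray:
        """Coordinates of points in the frame (columns e1, e2, e3)."""
        rel = np.atleast_2d(points) - self.origin
        return rel @ np.column_stack([self.e1, self.e2, self.e3])


def _pca(points: np.ndarray):
    """Centered SVD; returns (centroid, components rows desc., singular values)."""
    centroid = points.mean(axis=0)
    _, s, vt = np.linalg.svd(points - centroid, full_matrices=False)
    return centroid, vt, s


def aponeurosis_points(frame: MuscleFrame, dataset: MuscleDataset):
    """Fascicle endpoints grouped by aponeurosis label: (points_A, points_B)."""
    pts_a, pts_b = [], []
    for f in dataset.fascicles:
        ia = frame.side_a_endpoint.get(f.fascicle_id, 1)
        pts_a.append(f.points[-1] if ia == 1 else f.points[0])
        pts_b.append(f.points[0] if ia == 1 else f.points[-1])
    return np.asarray(pts_a), np.asarray(pts_b)


def _axes_from_assignment(endpoints, side_a, dataset, mtc_origin):
    """Average per-aponeurosis PCAs into (e1, e2, e3) with sign conventions."""
    pts_a = endpoints[np.arange(len(side_a)), side_a]
    pts_b = endpoints[np.arange(len(side_a)), 1 - side_a]
    _, vt_a, _ = _pca(pts_a)
    _, vt_b, _ = _pca(pts_b)
    pc1_a, pc2_a = vt_a[0], vt_a[1]
    pc1_b, pc2_b = vt_b[0], vt_b[1]
    if pc1_a @ pc1_b < 0:
        pc1_b = -pc1_b
    e1 = pc1_a + pc1_b
    e1 /= np.linalg.norm(e1)
    if pc2_a @ pc2_b < 0:
        pc2_b = -pc2_b
    e3 = pc2_a + pc2_b
    e3 -= (e3 @ e1) * e1
    n3 = np.linalg.norm(e3)
    if n3 < 1e-12:
        # averaged width components collapsed onto e1; fall back to pc2_a
        e3 = pc2_a - (pc2_a @ e1) * e1
        n3 = np.linalg.norm(e3)
        if n3 < 1e-12:
            raise ValueError("degenerate aponeurosis geometry: no width axis")
    e3 /= n3
    e2 = np.cross(e3, e1)

    all_pts = endpoints.reshape(-1, 3)
    centroid = all_pts.mean(axis=0)
    # e1 orientation: proximal -> distal
    if mtc_origin is not None:
        if (centroid - mtc_origin) @ e1 < 0:
            e1 = -e1
    else:
        c = (all_pts - centroid) @ e1
        skew = np.mean(c**3)
        if skew < 0:
            e1 = -e1
    # e2 orientation: from aponeurosis B to A
    if (pts_a.mean(axis=0) - pts_b.mean(axis=0)) @ e2 < 0:
        e2 = -e2
    e3 = np.cross(e1, e2)
    return e1, e2, e3, centroid


def _single_fascicle_frame(fascicle: Fascicle) -> MuscleFrame:
    """Degenerate frame for a one-fascicle dataset: e1 along the chord."""
    e1 = fascicle.chord / np.linalg.norm(fascicle.chord)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(e1 @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e3 = np.cross(e1, helper)
    e3 /= np.linalg.norm(e3)
    e2 = np.cross(e3, e1)
    return MuscleFrame(
        e1=e1,
        e2=e2,
        e3=np.cross(e1, e2),
        origin=fascicle.points.mean(axis=0),
        side_a_endpoint={fascicle.fascicle_id: 1},
    )


def compute_frame(dataset: MuscleDataset) -> MuscleFrame:
    """Derive the muscle frame by PCA of fascicle endpoints.

    Raises on a degenerate endpoint cloud (fewer than two fascicles, or all
    endpoints collinear).
    """
    if dataset.n_fascicles < 2:
        raise ValueError("frame computation requires at least 2 fascicles")
    endpoints = dataset.endpoints()  # (n, 2, 3)
    all_pts = endpoints.reshape(-1, 3)
    _, vt, s = _pca(all_pts)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise ValueError("degenerate endpoint cloud (rank < 2)")
    normal = vt[2]
    # provisional assignment: endpoint with larger normal coordinate -> A
    coords_n = endpoints @ normal
    side_a = np.where(coords_n[:, 1] >= coords_n[:, 0], 1, 0)
    e1, e2, e3, centroid = _axes_from_assignment(
        endpoints, side_a, dataset, dataset.mtc_origin
    )
    # one refinement iteration: reassign by e2 coordinate in the new frame
    coords_2 = endpoints @ e2
    side_a_new = np.where(coords_2[:, 1] >= coords_2[:, 0], 1, 0)
    ambiguous = np.isclose(coords_2[:, 1], coords_2[:, 0], atol=1e-12)
    if ambiguous.any():
        ids = [dataset.fascicles[i].fascicle_id for i in np.flatnonzero(ambiguous)]
        warnings.warn(
            f"fascicle endpoint aponeurosis assignment ambiguous (equal e2 "
            f"coordinates), keeping tie-break for: {ids}"
        )
    if not np.array_equal(side_a_new, side_a):
        side_a = side_a_new
        e1, e2, e3, centroid = _axes_from_assignment(
            endpoints, side_a, dataset, dataset.mtc_origin
        )
    # label convention: A is the aponeurosis extending farther distally
    idx = np.arange(len(side_a))
    c_a = endpoints[idx, side_a].mean(axis=0)
    c_b = endpoints[idx, 1 - side_a].mean(axis=0)
    if (c_a - c_b) @ e1 < 0:
        side_a = 1 - side_a
        e1, e2, e3, centroid = _axes_from_assignment(
            endpoints, side_a, dataset, dataset.mtc_origin
        )
    mapping = {
        f.fascicle_id: int(side_a[i]) for i, f in enumerate(dataset.fascicles)
    }
    return MuscleFrame(e1=e1, e2=e2, e3=e3, origin=centroid, side_a_endpoint=mapping)


def fascicle_angles(fascicle: Fascicle, frame: MuscleFrame):
    """Transversal angle alpha and pennation angle beta of one fascicle.

    Both angles are computed from the fascicle chord: beta is the angle
    between the chord and its projection onto the aponeurosis (e1-e3)
    plane, alpha the angle between that projection and e1; both in
    [0, 90] degrees. For a chord perpendicular to the aponeurosis plane the
    transversal angle is undefined and returned as 0 with a warning.
    """
    chord = fascicle.chord
    norm = np.linalg.norm(chord)
    if norm <= 0.0:
        raise ValueError(f"fascicle {fascicle.fascicle_id!r} has zero chord")
    c1 = chord @ frame.e1
    c2 = chord @ frame.e2
    c3 = chord @ frame.e3
    proj = np.hypot(c1, c3)
    if proj < 1e-12 * norm:
        warnings.warn(
            f"fascicle {fascicle.fascicle_id!r} is perpendicular to the "
            "aponeurosis plane; transversal angle undefined, reported as 0"
        )
        return 0.0, 90.0
    beta = np.degrees(np.arctan2(abs(c2), proj))
    alpha = np.degrees(np.arctan2(abs(c3), abs(c1)))
    return float(alpha), float(beta)


def dataset_angles(dataset: MuscleDataset, frame: MuscleFrame):
    """(alpha, beta) arrays in degrees, one entry per fascicle."""
    pairs = [fascicle_angles(f, frame) for f in dataset.fascicles]
    arr = np.asarray(pairs, dtype=float)
    return arr[:, 0], arr[:, 1]


def aponeurosis_dims(frame: MuscleFrame, dataset: MuscleDataset) -> dict:
    """Length (extent along e1) and width (along e3) per aponeurosis.

    Returns ``{'A': (length, width), 'B': (...), 'mean': (...)}``. An
    aponeurosis with fewer than 2 endpoints gets dims (0, 0) with a warning.
    """
    dims = {}
    for label, pts in zip("AB", aponeurosis_points(frame, dataset)):
        if len(pts) < 2:
            warnings.warn(f"aponeurosis {label} has fewer than 2 endpoints")
            dims[label] = (0.0, 0.0)
            continue
        c = frame.coords(pts)
        dims[label] = (
            float(c[:, 0].max() - c[:, 0].min()),
            float(c[:, 2].max() - c[:, 2].min()),
        )
    dims["mean"] = (
        (dims["A"][0] + dims["B"][0]) / 2.0,
        (dims["A"][1] + dims["B"][1]) / 2.0,
    )
    return dims


def muscle_height(frame: MuscleFrame, dataset: MuscleDataset) -> float:
    """Distance of the two aponeurosis centroids along e2, mm."""
    pts_a, pts_b = aponeurosis_points(frame, dataset)
    if len(pts_a) == 0 or len(pts_b) == 0:
        raise ValueError("empty aponeurosis; cannot compute muscle height")
    return float(abs((pts_a.mean(axis=0) - pts_b.mean(axis=0)) @ frame.e2))


def belly_dims(frame: MuscleFrame, dataset: MuscleDataset):
    """Belly length L_MB (extent of all fascicle points along e1) and belly
    width W_MB (same along e3)."""
    c = frame.coords(dataset.all_points())
    return (
        float(c[:, 0].max() - c[:, 0].min()),
        float(c[:, 2].max() - c[:, 2].min()),
    )


class BoundarySurface(NamedTuple):
    points: np.ndarray
    triangles: np.ndarray  # (m, 3) indices into points


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        parent = self.parent
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[ri] = rj


def _circumradii(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    a = points[tets[:, 0]]
    rows = np.stack([points[tets[:, k]] - a for k in (1, 2, 3)], axis=1)
    rhs = 0.5 * np.einsum("mkd,mkd->mk", rows, rows)
    det = np.linalg.det(rows)
    scale = np.abs(rows).max(axis=(1, 2)) ** 3 + 1e-300
    radii = np.full(len(tets), np.inf)
    ok = np.abs(det) > 1e-12 * scale
    if ok.any():
        centers = np.linalg.solve(rows[ok], rhs[ok][..., None])[..., 0]
        radii[ok] = np.linalg.norm(centers, axis=1)
    return radii


def _tet_volumes(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    a = points[tets[:, 0]]
    m = np.stack([points[tets[:, k]] - a for k in (1, 2, 3)], axis=1)
    return np.abs(np.linalg.det(m)) / 6.0


def boundary_volume(points: np.ndarray, shrink: float = DEFAULT_SHRINK):
    """Volume and boundary triangulation of a point cloud.

    ``shrink`` in [0, 1] selects the boundary tightness: 0 is the convex
    hull, 1 the tightest alpha complex that still forms one connected
    component covering every point; fractions interpolate on the sorted
    circumradius spectrum between those two. Returns ``(volume_mm3,
    BoundarySurface)``.
    """
    if not 0.0 <= shrink <= 1.0:
        raise ValueError(f"shrink factor must be in [0, 1], got {shrink}")
    points = np.asarray(points, dtype=float)
    if len(points) < 4:
        raise ValueError("boundary volume requires at least 4 points")
    try:
        tri = Delaunay(points)
    except QhullError as exc:
        raise ValueError(f"degenerate (coplanar?) point cloud: {exc}") from exc
    tets = tri.simplices
    radii = _circumradii(points, tets)
    vols = _tet_volumes(points, tets)
    order = np.argsort(radii, kind="stable")
    n_vertices = len(np.unique(tets))

    def connected(k: int) -> bool:
        """Do the k smallest-radius tets cover all vertices in one component?"""
        kept = tets[order[:k]]
        verts = np.unique(kept)
        if len(verts) < n_vertices:
            return False
        remap = {v: i for i, v in enumerate(verts)}
        uf = _UnionFind(len(verts))
        for tet in kept:
            i0 = remap[tet[0]]
            for v in tet[1:]:
                uf.union(i0, remap[v])
        root = uf.find(0)
        return all(uf.find(i) == root for i in range(len(verts)))

    lo, hi = 1, len(tets)
    if not connected(hi):  # cannot happen for a valid triangulation
        raise ValueError("Delaunay complex is not connected")
    while lo < hi:
        mid = (lo + hi) // 2
        if connected(mid):
            hi = mid
        else:
            lo = mid + 1
    k_critical = lo
    k = int(round(k_critical + (1.0 - shrink) * (len(tets) - k_critical)))
    keep = order[:k]
    volume = float(vols[keep].sum())

    faces = {}
    kept_tets = tets[keep]
    for tet in kept_tets:
        for face in (
            (tet[0], tet[1], tet[2]),
            (tet[0], tet[1], tet[3]),
            (tet[0], tet[2], tet[3]),
            (tet[1], tet[2], tet[3]),
        ):
            key = tuple(sorted(face))
            faces[key] = faces.get(key, 0) + 1
    boundary = np.array(
        [face for face, count in faces.items() if count == 1], dtype=int
    )
    return volume, BoundarySurface(points=points, triangles=boundary)


def muscle_volume(dataset: MuscleDataset, shrink: float = DEFAULT_SHRINK):
    """Boundary-enclosed volume of all fascicle points (see
    :func:`boundary_volume`)."""
    return boundary_volume(dataset.all_points(), shrink=shrink)


def mass_and_pcsa(
    volume_mm3: float,
    mean_fascicle_length_mm: float,
    density_g_per_mm3: float = MUSCLE_DENSITY_G_PER_MM3,
):
    """Muscle mass (g) and physiological cross-sectional area (mm^2).

    PCSA = V_m / mean L_F; mass = V_m * density. Note the fascicles are not
    necessarily at optimal length, so this is the PCSA at the recorded
    joint configuration.
    """
    if volume_mm3 < 0.0:
        raise ValueError("volume must be nonnegative")
    if volume_mm3 == 0.0:
        return 0.0, 0.0
    if mean_fascicle_length_mm <= 0.0:
        raise ValueError("mean fascicle length must be positive")
    return (
        volume_mm3 * density_g_per_mm3,
        volume_mm3 / mean_fascicle_length_mm,
    )


def free_tendon_length(dataset: MuscleDataset, belly_length_mm: float) -> float:
    """MTC landmark distance minus muscle belly length, mm.

    Negative values (landmark/frame inconsistency) are returned with a
    warning rather than suppressed.
    """
    if not dataset.has_landmarks():
        raise ValueError("free tendon length requires both MTC landmarks")
    mtc = float(np.linalg.norm(dataset.mtc_insertion - dataset.mtc_origin))
    tendon = mtc - belly_length_mm
    if tendon < 0.0:
        warnings.warn(
            f"free tendon length is negative ({tendon:.3f} mm): muscle belly "
            "length exceeds the recorded MTC length"
        )
    return tendon


def summarize(
    dataset: MuscleDataset,
    shrink: float = DEFAULT_SHRINK,
    density_g_per_mm3: float = MUSCLE_DENSITY_G_PER_MM3,
) -> ArchitectureSummary:
    """Measure every architectural parameter of a preprocessed dataset."""
    if not dataset.fascicles:
        raise ValueError(
            "dataset has no processed fascicles; run preprocess_dataset first"
        )
    if dataset.n_fascicles == 1:
        frame = _single_fascicle_frame(dataset.fascicles[0])
        warnings.warn(
            "single-fascicle dataset: frame aligned with the fascicle chord, "
            "volume undefined (reported as 0)"
        )
        volume = 0.0
    else:
        frame = compute_frame(dataset)
        volume, _ = muscle_volume(dataset, shrink=shrink)
    lengths = np.array([f.length for f in dataset.fascicles])
    alpha, beta = dataset_angles(dataset, frame)
    apo = aponeurosis_dims(frame, dataset)
    l_mb, w_mb = belly_dims(frame, dataset)
    height = muscle_height(frame, dataset)
    mean_lf = float(lengths.mean())
    mass, pcsa = mass_and_pcsa(volume, mean_lf, density_g_per_mm3)
    tendon = None
    if dataset.has_landmarks():
        tendon = free_tendon_length(dataset, l_mb)
    return ArchitectureSummary(
        belly_length_mm=l_mb,
        belly_width_mm=w_mb,
        fascicle_length_mean_mm=mean_lf,
        fascicle_length_std_mm=sample_std(lengths),
        pennation_mean_deg=float(beta.mean()),
        pennation_std_deg=sample_std(beta),
        transversal_mean_deg=float(alpha.mean()),
        transversal_std_deg=sample_std(alpha),
        apo_length_a_mm=apo["A"][0],
        apo_length_b_mm=apo["B"][0],
        apo_length_mean_mm=apo["mean"][0],
        apo_width_a_mm=apo["A"][1],
        apo_width_b_mm=apo["B"][1],
        apo_width_mean_mm=apo["mean"][1],
        muscle_height_mm=height,
        muscle_volume_mm3=volume,
        muscle_mass_g=mass,
        pcsa_mm2=pcsa,
        free_tendon_mm=tendon,
    )


def per_fascicle_table(dataset: MuscleDataset, frame: MuscleFrame = None):
    """Per-fascicle diagnostics: id, length, alpha, beta, aponeurosis label
    of the first endpoint. Returns a pandas DataFrame."""
    import pandas as pd

    if frame is None:
        frame = compute_frame(dataset)
    rows = []
    for f in dataset.fascicles:
        a, b = fascicle_angles(f, frame)
        ia = frame.side_a_endpoint.get(f.fascicle_id, 1)
        rows.append(
            {
                "fascicle_id": f.fascicle_id,
                "length_mm": f.length,
                "alpha_deg": a,
                "beta_deg": b,
                "p1_aponeurosis": "A" if ia == 0 else "B",
            }
        )
    return pd.DataFrame(rows)
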