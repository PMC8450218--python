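"""Core domain containers for 3D muscle fascicle architecture.

All coordinates are in millimetres and live in one common laboratory frame.
Angles cross module boundaries in degrees; radians stay internal to the
functions that need them.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Skeletal muscle density, stored per mm^3 (1.056 g/cm^3).
MUSCLE_DENSITY_G_PER_MM3 = 1.056e-3

#: Number of points a processed fascicle polyline carries.
N_FASCICLE_POINTS = 20


def as_points(points, name: str = "points") -> np.ndarray:
    """Coerce to a float (n, 3) coordinate array and validate finiteness."""
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"{name} must have shape (n, 3), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite coordinates")
    return arr


def as_point(point, name: str = "point") -> np.ndarray:
    arr = np.asarray(point, dtype=float).reshape(-1)
    if arr.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite coordinates")
    return arr


def polyline_length(points: np.ndarray) -> float:
    """Sum of straight segment lengths of a polyline."""
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


@dataclass
class FascicleTrace:
    """Raw digitizer polyline for one fascicle (variable point count)."""

    fascicle_id: str
    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = as_points(self.points, f"trace {self.fascicle_id!r}")
        if len(self.points) < 3:
            raise ValueError(
                f"trace {self.fascicle_id!r} has {len(self.points)} points; "
                "at least 3 are required"
            )
        if polyline_length(self.points) <= 0.0:
            raise ValueError(
                f"trace {self.fascicle_id!r} has zero total length "
                "(all points identical)"
            )

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass
class Fascicle:
    """Smoothed fascicle as an equidistant 20-point polyline.

    The fascicle length ``L_F`` is the sum of the 19 segment lengths; the
    midpoint is the point at arc length ``L_F / 2`` interpolated on the
    polyline (not the chord midpoint).
    """

    fascicle_id: str
    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = as_points(self.points, f"fascicle {self.fascicle_id!r}")
        if len(self.points) != N_FASCICLE_POINTS:
            raise ValueError(
                f"fascicle {self.fascicle_id!r} must have exactly "
                f"{N_FASCICLE_POINTS} points, got {len(self.points)}"
            )
        if polyline_length(self.points) <= 0.0:
            raise ValueError(f"fascicle {self.fascicle_id!r} has zero length")

    @property
    def p1(self) -> np.ndarray:
        return self.points[0]

    @property
    def p2(self) -> np.ndarray:
        return self.points[-1]

    @property
    def chord(self) -> np.ndarray:
        """Endpoint-to-endpoint vector."""
        return self.points[-1] - self.points[0]

    @property
    def length(self) -> float:
        """Fascicle length L_F (polyline arc length), mm."""
        return polyline_length(self.points)

    @property
    def midpoint(self) -> np.ndarray:
        """Point at half the arc length, interpolated on the polyline."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        half = cum[-1] / 2.0
        k = int(np.searchsorted(cum, half, side="right")) - 1
        k = min(max(k, 0), len(seg) - 1)
        if seg[k] == 0.0:
            return self.points[k].copy()
        frac = (half - cum[k]) / seg[k]
        return self.points[k] + frac * (self.points[k + 1] - self.points[k])

    def translated(self, vector) -> "Fascicle":
        v = as_point(vector, "translation")
        return Fascicle(self.fascicle_id, self.points + v)

    def with_points(self, points) -> "Fascicle":
        return Fascicle(self.fascicle_id, points)


@dataclass
class MuscleDataset:
    """A muscle's fascicles plus optional MTC landmarks and metadata.

    ``traces`` holds raw digitizer polylines as read from disk; ``fascicles``
    holds the smoothed 20-point polylines produced by preprocessing. Either
    may be empty depending on the pipeline stage.
    """

    muscle_id: str = "muscle"
    fascicles: list = field(default_factory=list)
    traces: list = field(default_factory=list)
    mtc_origin: Optional[np.ndarray] = None
    mtc_insertion: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mtc_origin is not None:
            self.mtc_origin = as_point(self.mtc_origin, "mtc_origin")
        if self.mtc_insertion is not None:
            self.mtc_insertion = as_point(self.mtc_insertion, "mtc_insertion")

    @property
    def n_fascicles(self) -> int:
        return len(self.fascicles)

    def all_points(self) -> np.ndarray:
        """All 20-point samples of all fascicles, stacked (n*20, 3)."""
        if not self.fascicles:
            raise ValueError("dataset has no processed fascicles")
        return np.vstack([f.points for f in self.fascicles])

    def endpoints(self) -> np.ndarray:
        """Fascicle endpoints as an (n, 2, 3) array (p1, p2 per fascicle)."""
        if not self.fascicles:
            raise ValueError("dataset has no processed fascicles")
        return np.stack([[f.p1, f.p2] for f in self.fascicles])

    def has_landmarks(self) -> bool:
        return self.mtc_origin is not None and self.mtc_insertion is not None

    def copy(self) -> "MuscleDataset":
        return MuscleDataset(
            muscle_id=self.muscle_id,
            fascicles=[Fascicle(f.fascicle_id, f.points.copy()) for f in self.fascicles],
            traces=[FascicleTrace(t.fascicle_id, t.points.copy()) for t in self.traces],
            mtc_origin=None if self.mtc_origin is None else self.mtc_origin.copy(),
            mtc_insertion=None if self.mtc_insertion is None else self.mtc_insertion.copy(),
            metadata=dict(self.metadata),
        )

    def replace_fascicles(self, fascicles) -> "MuscleDataset":
        out = self.copy()
        out.fascicles = list(fascicles)
        return out


@dataclass
class GrowthParams:
    """The four growth-model inputs.

    delta_l_mb : change in muscle belly length, mm
    delta_w_mb : change in muscle belly width, mm
    delta_l_f  : change applied to every fascicle's length, mm
    delta_beta : change applied to every fascicle's pennation angle, degrees
    """

    delta_l_mb: float = 0.0
    delta_w_mb: float = 0.0
    delta_l_f: float = 0.0
    delta_beta: float = 0.0

    def __post_init__(self) -> None:
        for name in ("delta_l_mb", "delta_w_mb", "delta_l_f", "delta_beta"):
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite")
            setattr(self, name, v)

    def is_identity(self) -> bool:
        return (
            self.delta_l_mb == 0.0
            and self.delta_w_mb == 0.0
            and self.delta_l_f == 0.0
            and self.delta_beta == 0.0
        )


# Field names double as headers in the summary files, so units are embedded.
SUMMARY_FIELDS = (
    "belly_length_mm",
    "belly_width_mm",
    "fascicle_length_mean_mm",
    "fascicle_length_std_mm",
    "pennation_mean_deg",
    "pennation_std_deg",
    "transversal_mean_deg",
    "transversal_std_deg",
    "apo_length_a_mm",
    "apo_length_b_mm",
    "apo_length_mean_mm",
    "apo_width_a_mm",
    "apo_width_b_mm",
    "apo_width_mean_mm",
    "muscle_height_mm",
    "muscle_volume_mm3",
    "muscle_mass_g",
    "pcsa_mm2",
    "free_tendon_mm",
)


@dataclass
class ArchitectureSummary:
    """All architectural parameters measured for one muscle.

    Aponeurosis length/width are reported per aponeurosis (A = the sheet the
    frame's e2 axis points toward, B = the opposite one) and averaged.
    ``free_tendon_mm`` is None when MTC landmarks were not recorded (missing,
    not zero). By construction ``pcsa_mm2 * fascicle_length_mean_mm ==
    muscle_volume_mm3`` and ``muscle_mass_g == muscle_volume_mm3 * 1.056e-3``.
    """

    belly_length_mm: float = 0.0
    belly_width_mm: float = 0.0
    fascicle_length_mean_mm: float = 0.0
    fascicle_length_std_mm: float = 0.0
    pennation_mean_deg: float = 0.0
    pennation_std_deg: float = 0.0
    transversal_mean_deg: float = 0.0
    transversal_std_deg: float = 0.0
    apo_length_a_mm: float = 0.0
    apo_length_b_mm: float = 0.0
    apo_length_mean_mm: float = 0.0
    apo_width_a_mm: float = 0.0
    apo_width_b_mm: float = 0.0
    apo_width_mean_mm: float = 0.0
    muscle_height_mm: float = 0.0
    muscle_volume_mm3: float = 0.0
    muscle_mass_g: float = 0.0
    pcsa_mm2: float = 0.0
    free_tendon_mm: Optional[float] = None

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in SUMMARY_FIELDS}

    @classmethod
    def from_dict(cls, data: dict) -> "ArchitectureSummary":
        kwargs = {}
        for name in SUMMARY_FIELDS:
            if name in data and data[name] is not None:
                kwargs[name] = float(data[name])
            elif name == "free_tendon_mm":
                kwargs[name] = None
        return cls(**kwargs)
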