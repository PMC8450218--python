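"""Synthetic unipennate muscle phantoms with known ground truth.

The generator emulates the geometry a fascicle digitizer records from a
primarily unipennate calf muscle: two superficial aponeurosis sheets
separated by the muscle height, fascicles spanning the sheets at a common
pennation with normally distributed lengths, an optional central crest on
one aponeurosis (a ridge running along the length axis, as seen on the
rabbit plantaris), optional quadratic fascicle bowing, and Gaussian
digitizer noise applied to irregularly sampled raw traces.

Default dimensions correspond to a young (about 4-week-old) rabbit
plantaris: belly roughly 51 x 7.7 mm, fascicles 13.7 +- 1.2 mm at about
11.6 degrees of pennation, free tendon 14.5 mm, digitizer noise 0.076 mm.

Construction: fascicle lower attachments sit on a jittered grid spanning
the lower sheet (boundary rows and columns unjittered so extents are
controlled); each fascicle's length is drawn from the normal law and its
pennation follows from the sheet separation at its location,
``beta_i = asin(dz_i / L_i)``, so both endpoints lie exactly on their
sheets and the mean pennation matches the configured value whenever
height, mean length and pennation are mutually consistent (the defaults
are). Ground truth is computed from the construction itself, never by the
measurement pipeline.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .architecture import MuscleFrame, sample_std
from .core import (
    ArchitectureSummary,
    FascicleTrace,
    MuscleDataset,
    MUSCLE_DENSITY_G_PER_MM3,
)
from .preprocess import _arc_antiderivative


@dataclass
class SynthConfig:
    """Phantom configuration; all dimensions in mm, angles in degrees."""

    n_fascicles: int = 80
    belly_length: float = 50.8
    belly_width: float = 7.7
    height: float = 2.754  # ~ 13.7 * sin(11.6 deg): consistent defaults
    mean_pennation: float = 11.6
    fascicle_length_mean: float = 13.7
    fascicle_length_std: float = 1.2
    crest_angle: float = 0.0  # dihedral of the upper sheet's central ridge
    curvature: float = 0.3  # bow amplitude of the fascicle path
    noise_std: float = 0.076  # digitizer noise
    points_per_trace: int = 25
    free_tendon: float = 14.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "belly_length",
            "belly_width",
            "height",
            "fascicle_length_mean",
        ):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")
        for name in ("fascicle_length_std", "curvature", "noise_std"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_fascicles < 4:
            raise ValueError("need at least 4 fascicles")
        if self.points_per_trace < 3:
            raise ValueError("raw traces need at least 3 points")
        if not 0.0 <= self.crest_angle < 60.0:
            raise ValueError("crest_angle must be in [0, 60) degrees")
        if not 0.0 < self.mean_pennation < 90.0:
            raise ValueError("mean_pennation must be in (0, 90) degrees")

    def scaled(self, k: float) -> "SynthConfig":
        """Scale every linear dimension by ``k`` (angles unchanged)."""
        return replace(
            self,
            belly_length=self.belly_length * k,
            belly_width=self.belly_width * k,
            height=self.height * k,
            fascicle_length_mean=self.fascicle_length_mean * k,
            fascicle_length_std=self.fascicle_length_std * k,
            curvature=self.curvature * k,
            noise_std=self.noise_std * k,
            free_tendon=self.free_tendon * k,
        )


@dataclass
class SynthTruth:
    """Ground-truth architecture of a generated phantom."""

    summary: ArchitectureSummary
    frame: MuscleFrame
    lower_endpoints: np.ndarray  # (n, 3), on the lower sheet (aponeurosis B)
    upper_endpoints: np.ndarray  # (n, 3), on the upper sheet (aponeurosis A)
    beta_deg: np.ndarray
    alpha_deg: np.ndarray
    fascicle_lengths: np.ndarray  # true arc lengths
    config: SynthConfig

    def upper_sheet_height(self, y) -> np.ndarray:
        """z of the upper sheet at transversal coordinate(s) y."""
        cfg = self.config
        tan_c = math.tan(math.radians(cfg.crest_angle))
        return cfg.height + tan_c * (cfg.belly_width / 2.0 - np.abs(np.asarray(y)))


def _grid_layout(cfg: SynthConfig):
    # at least 4 width rows so each side of the dividing plane keeps a
    # two-row strip for its local PCA
    ny = max(4, int(round(math.sqrt(cfg.n_fascicles * cfg.belly_width / cfg.belly_length))))
    nx = max(2, int(round(cfg.n_fascicles / ny)))
    return nx, ny


def _bow_arc_length(chord: np.ndarray, bow: float, normal: np.ndarray) -> float:
    """Arc length of p(t) = t*chord + 4 bow t (1-t) normal, t in [0, 1]."""
    a = -4.0 * bow * normal
    b = chord + 4.0 * bow * normal
    A = 4.0 * float(a @ a)
    B = 4.0 * float(a @ b)
    C = float(b @ b)
    return float(_arc_antiderivative(A, B, C, np.asarray(1.0)))


def generate(cfg: SynthConfig):
    """Generate a phantom; returns ``(dataset, truth)``.

    The dataset carries raw traces (noisy, irregularly sampled) pending
    preprocessing, plus MTC landmarks on the muscle's line of action.
    ``truth`` holds the analytic ground-truth summary and frame. The same
    seed reproduces the dataset bit for bit.
    """
    rng = np.random.default_rng(cfg.seed)
    nx, ny = _grid_layout(cfg)
    n = nx * ny
    beta0 = math.radians(cfg.mean_pennation)
    run0 = cfg.fascicle_length_mean * math.cos(beta0)
    lx = cfg.belly_length - run0
    if lx <= 0.0:
        raise ValueError(
            "infeasible geometry: the fascicle run "
            f"({run0:.2f} mm at {cfg.mean_pennation} deg) exceeds the belly "
            f"length ({cfg.belly_length} mm)"
        )
    xs = np.linspace(0.0, lx, nx)
    ys = np.linspace(-cfg.belly_width / 2.0, cfg.belly_width / 2.0, ny)
    dx = lx / (nx - 1)
    dy = cfg.belly_width / (ny - 1)
    # jitter per column / per row (boundaries fixed): the product structure
    # of the grid keeps the x-y sample covariance exactly zero, so the
    # endpoint PCA of the measurement pipeline identifies the construction
    # axes instead of a randomly tilted frame
    jx = rng.uniform(-0.3 * dx, 0.3 * dx, nx)
    jy = rng.uniform(-0.3 * dy, 0.3 * dy, ny)
    jx[0] = jx[-1] = 0.0
    jy[0] = jy[-1] = 0.0
    x0 = np.repeat(xs + jx, ny)
    y0 = np.tile(ys + jy, nx)

    lengths = rng.normal(cfg.fascicle_length_mean, cfg.fascicle_length_std, n)
    tan_c = math.tan(math.radians(cfg.crest_angle))
    dz = cfg.height + tan_c * (cfg.belly_width / 2.0 - np.abs(y0))
    if np.any(lengths <= dz):
        k = int(np.argmax(dz - lengths))
        raise ValueError(
            "infeasible geometry: drawn fascicle length "
            f"{lengths[k]:.2f} mm is shorter than the sheet separation "
            f"{dz[k]:.2f} mm (length must exceed height / sin(pennation))"
        )
    run = np.sqrt(lengths**2 - dz**2)
    # orthogonalize the run residuals against the grid coordinates: random
    # pairing of lengths with grid cells would otherwise leave an O(1/sqrt(n))
    # covariance that tilts the upper sheet's principal axes
    design = np.column_stack(
        [x0 - x0.mean(), y0 - y0.mean(), np.abs(y0) - np.abs(y0).mean()]
    )
    coef, *_ = np.linalg.lstsq(design, run - run.mean(), rcond=None)
    run = run - design @ coef
    if np.any(run <= 0.0):
        raise ValueError(
            "infeasible geometry: fascicle runs collapse after "
            "decorrelation; increase fascicle length or reduce its spread"
        )
    lengths = np.hypot(run, dz)
    beta = np.degrees(np.arcsin(dz / lengths))

    lower = np.column_stack([x0, y0, np.zeros(n)])
    upper = np.column_stack([x0 + run, y0, dz])
    chords = upper - lower
    # bow normal: perpendicular to the chord within its vertical plane
    bow_normal = np.column_stack([-dz, np.zeros(n), run]) / lengths[:, None]

    arc_lengths = np.array(
        [
            _bow_arc_length(chords[i], cfg.curvature, bow_normal[i])
            if cfg.curvature > 0.0
            else lengths[i]
            for i in range(n)
        ]
    )

    traces = []
    m = cfg.points_per_trace
    for i in range(n):
        incr = rng.uniform(0.5, 1.5, m - 1)  # variable digitizer hand speed
        t = np.concatenate([[0.0], np.cumsum(incr)])
        t /= t[-1]
        pts = (
            lower[i]
            + np.outer(t, chords[i])
            + np.outer(4.0 * cfg.curvature * t * (1.0 - t), bow_normal[i])
        )
        if cfg.noise_std > 0.0:
            pts = pts + rng.normal(0.0, cfg.noise_std, pts.shape)
        traces.append(FascicleTrace(f"f{i:03d}", pts))

    x_min = float(lower[:, 0].min())  # 0 by construction
    x_max = float(upper[:, 0].max())
    l_mb = x_max - x_min
    z_mid = float(dz.mean()) / 2.0
    origin = np.array([x_min, 0.0, z_mid])
    insertion = np.array([x_max + cfg.free_tendon, 0.0, z_mid])

    dataset = MuscleDataset(
        muscle_id=f"synthetic-seed{cfg.seed}",
        traces=traces,
        mtc_origin=origin,
        mtc_insertion=insertion,
        metadata={"synthetic": True, "seed": cfg.seed},
    )

    # ground truth, straight from the construction
    e1 = np.array([1.0, 0.0, 0.0])
    e2 = np.array([0.0, 0.0, 1.0])
    e3 = np.cross(e1, e2)
    frame = MuscleFrame(
        e1=e1,
        e2=e2,
        e3=e3,
        origin=np.vstack([lower, upper]).mean(axis=0),
        side_a_endpoint={t.fascicle_id: 1 for t in traces},
    )
    apo_a_len = float(upper[:, 0].max() - upper[:, 0].min())
    apo_b_len = float(lower[:, 0].max() - lower[:, 0].min())
    width = cfg.belly_width
    height = float(dz.mean())  # centroid separation along e2
    cross_section = width * cfg.height + tan_c * width**2 / 4.0
    volume = lx * cross_section
    mean_lf = float(arc_lengths.mean())
    mass = volume * MUSCLE_DENSITY_G_PER_MM3
    summary = ArchitectureSummary(
        belly_length_mm=l_mb,
        belly_width_mm=width,
        fascicle_length_mean_mm=mean_lf,
        fascicle_length_std_mm=sample_std(arc_lengths),
        pennation_mean_deg=float(beta.mean()),
        pennation_std_deg=sample_std(beta),
        transversal_mean_deg=0.0,
        transversal_std_deg=0.0,
        apo_length_a_mm=apo_a_len,
        apo_length_b_mm=apo_b_len,
        apo_length_mean_mm=(apo_a_len + apo_b_len) / 2.0,
        apo_width_a_mm=width,
        apo_width_b_mm=width,
        apo_width_mean_mm=width,
        muscle_height_mm=height,
        muscle_volume_mm3=volume,
        muscle_mass_g=mass,
        pcsa_mm2=volume / mean_lf,
        free_tendon_mm=cfg.free_tendon,
    )
    truth = SynthTruth(
        summary=summary,
        frame=frame,
        lower_endpoints=lower,
        upper_endpoints=upper,
        beta_deg=beta,
        alpha_deg=np.zeros(n),
        fascicle_lengths=arc_lengths,
        config=cfg,
    )
    return dataset, truth
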