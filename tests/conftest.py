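import numpy as np
import pytest

from myoarch import (
    Fascicle,
    MuscleDataset,
    MuscleFrame,
    SynthConfig,
    generate,
    preprocess_dataset,
)


def straight_fascicle(fascicle_id, p1, p2):
    """20-point straight polyline from p1 to p2."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    t = np.linspace(0.0, 1.0, 20)
    return Fascicle(fascicle_id, p1 + np.outer(t, p2 - p1))


def random_rotation(rng):
    """Uniform-ish random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def transform_dataset(dataset, rotation, translation):
    """Rigidly transform every coordinate of a dataset."""
    out = dataset.copy()
    out.fascicles = [
        Fascicle(f.fascicle_id, f.points @ rotation.T + translation)
        for f in out.fascicles
    ]
    out.traces = [
        type(t)(t.fascicle_id, t.points @ rotation.T + translation)
        for t in out.traces
    ]
    if out.mtc_origin is not None:
        out.mtc_origin = rotation @ out.mtc_origin + translation
    if out.mtc_insertion is not None:
        out.mtc_insertion = rotation @ out.mtc_insertion + translation
    return out


def axis_frame():
    """Lab-axis-aligned muscle frame (e1=x, e2=z, right-handed)."""
    e1 = np.array([1.0, 0.0, 0.0])
    e2 = np.array([0.0, 0.0, 1.0])
    return MuscleFrame(e1=e1, e2=e2, e3=np.cross(e1, e2), origin=np.zeros(3))


@pytest.fixture(scope="session")
def planar_phantom():
    """Noise-free, straight-fascicle phantom with its ground truth."""
    cfg = SynthConfig(n_fascicles=48, noise_std=0.0, curvature=0.0, seed=11)
    raw, truth = generate(cfg)
    return preprocess_dataset(raw), truth


@pytest.fixture(scope="session")
def crest_phantom():
    cfg = SynthConfig(
        n_fascicles=48, noise_std=0.0, curvature=0.0, crest_angle=20.0, seed=11
    )
    raw, truth = generate(cfg)
    return preprocess_dataset(raw), truth


@pytest.fixture()
def parallel_plane_dataset():
    """Endpoints on z=0 and z=5 gridded over x in [0,50], y in [0,10]."""
    fascicles = []
    xs = np.linspace(0.0, 48.0, 7)
    ys = np.linspace(0.0, 10.0, 4)
    k = 0
    for x in xs:
        for y in ys:
            fascicles.append(
                straight_fascicle(f"pp{k:02d}", (x, y, 0.0), (x + 2.0, y, 5.0))
            )
            k += 1
    return MuscleDataset(muscle_id="parallel-planes", fascicles=fascicles)
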