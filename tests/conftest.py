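import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for reference_scc

from surfcode.morphometry import MMSField, PatchSet, SurfaceGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cylinder(radius=2.0, height=10.0, shape=(30, 24), elliptic=None):
    """Cylinder grid: u runs along the axis, v around the circumference."""
    U, V = shape
    phi = 2.0 * np.pi * np.arange(V) / V
    z = np.linspace(0.0, height, U)
    a, b = (radius, radius) if elliptic is None else elliptic
    verts = np.empty((U, V, 3))
    verts[:, :, 0] = a * np.cos(phi)[None, :]
    verts[:, :, 1] = b * np.sin(phi)[None, :]
    verts[:, :, 2] = z[:, None]
    return SurfaceGrid(verts, hemisphere="left", subject_id="cyl")


def make_sphere(shape=(80, 80), radius=1.0):
    U, V = shape
    theta = np.linspace(1e-3, np.pi - 1e-3, U)
    phi = 2.0 * np.pi * np.arange(V) / V
    verts = np.empty((U, V, 3))
    verts[:, :, 0] = radius * np.outer(np.sin(theta), np.cos(phi))
    verts[:, :, 1] = radius * np.outer(np.sin(theta), np.sin(phi))
    verts[:, :, 2] = radius * np.outer(np.cos(theta), np.ones(V))
    return SurfaceGrid(verts, hemisphere="left", subject_id="sphere")


def make_mms_field(rng, shape=(20, 16), subject_id="s1", hemisphere="left"):
    return MMSField(
        rd=rng.normal(2.0, 0.1, size=shape),
        mtbm=rng.normal(0.0, 0.05, size=shape + (3,)),
        subject_id=subject_id,
        hemisphere=hemisphere,
    )


def make_patchset(rng, p=12, n=40):
    """Plain patch matrix wrapper for optimizer tests (no geometry)."""
    ps = PatchSet.__new__(PatchSet)
    ps.X = rng.normal(size=(p, n))
    ps.subject_ids = np.array([f"s{i % 4}" for i in range(n)], dtype=object)
    ps.hemispheres = np.array(["left"] * n, dtype=object)
    ps.corners = np.zeros((n, 2), dtype=int)
    ps.patch_size = 0
    return ps


def rigid_motion(grid: SurfaceGrid, seed=0) -> SurfaceGrid:
    """Random rotation + translation of a grid."""
    gen = np.random.default_rng(seed)
    A = gen.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    t = gen.normal(scale=5.0, size=3)
    return SurfaceGrid(grid.vertices @ Q.T + t, hemisphere=grid.hemisphere,
                       subject_id=grid.subject_id)
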