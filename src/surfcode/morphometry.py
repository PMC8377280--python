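"""Per-vertex surface morphometry on registered conformal grids.

A :class:`SurfaceGrid` holds the 3-D coordinates of a registered surface
sampled on a canonical ``(U, V)`` parameter grid (default 150 x 100) with
one-to-one vertex correspondence to a template.  From a template/subject
pair this module computes a per-vertex 4-vector feature field:

* radial distance (RD) — Euclidean distance from each vertex to the
  geometric center of its isoparametric cross-section, capturing
  deformation along the surface normal;
* three tangential deformation components — the log-Euclidean
  vectorization of the deformation tensor ``S = (J^T J)^{1/2}`` of the
  tangent-plane Jacobian ``J`` between corresponding grid cells.

It also extracts random overlapping square patches from the flattened
field and computes whole-surface area/volume summary measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

DEFAULT_GRID_SHAPE = (150, 100)
MMS_CHANNELS = 4


@dataclass
class SurfaceGrid:
    """Registered surface vertices on a (U, V) parameter grid, in mm."""

    vertices: np.ndarray  # (U, V, 3)
    hemisphere: str = "left"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 3 or self.vertices.shape[2] != 3:
            raise ValueError(f"vertices must be (U, V, 3), got {self.vertices.shape}")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("vertices contain non-finite coordinates")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.vertices.shape[0], self.vertices.shape[1]


@dataclass
class MMSField:
    """Per-vertex 4-vector field (rd, mtbm1, mtbm2, mtbm3) on one grid."""

    rd: np.ndarray  # (U, V)
    mtbm: np.ndarray  # (U, V, 3)
    hemisphere: str = "left"
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.rd.shape != self.mtbm.shape[:2]:
            raise ValueError(f"rd shape {self.rd.shape} != mtbm grid {self.mtbm.shape[:2]}")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.rd.shape

    @property
    def combined(self) -> np.ndarray:
        """(U, V, 4) stack in channel order (rd, mtbm1, mtbm2, mtbm3)."""
        return np.concatenate([self.rd[:, :, None], self.mtbm], axis=2)

    def flattened(self) -> np.ndarray:
        """Row-major flat vector, channel innermost; length = U*V*4."""
        return self.combined.reshape(-1)


@dataclass
class PatchSpec:
    size: int
    count_per_hemisphere: int
    seed: int = 0
    allow_overlap: bool = True

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("patch size must be >= 1")
        if self.count_per_hemisphere < 1:
            raise ValueError("count_per_hemisphere must be >= 1")


@dataclass
class PatchSet:
    """Vectorized patches as columns of X (p x n) with per-column provenance."""

    X: np.ndarray
    subject_ids: np.ndarray  # (n,) str
    hemispheres: np.ndarray  # (n,) str
    corners: np.ndarray  # (n, 2) int — top-left (u, v)
    patch_size: int

    def __post_init__(self) -> None:
        expected = self.patch_size**2 * MMS_CHANNELS
        if self.X.shape[0] != expected:
            raise ValueError(f"patch dim {self.X.shape[0]} != size^2*4 = {expected}")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("patch matrix contains non-finite values")

    @property
    def p(self) -> int:
        return self.X.shape[0]

    @property
    def n(self) -> int:
        return self.X.shape[1]


def concat_patch_sets(sets: list[PatchSet]) -> PatchSet:
    if not sets:
        raise ValueError("no patch sets to concatenate")
    size = sets[0].patch_size
    if any(s.patch_size != size for s in sets):
        raise ValueError("patch sizes differ")
    return PatchSet(
        X=np.concatenate([s.X for s in sets], axis=1),
        subject_ids=np.concatenate([s.subject_ids for s in sets]),
        hemispheres=np.concatenate([s.hemispheres for s in sets]),
        corners=np.concatenate([s.corners for s in sets], axis=0),
        patch_size=size,
    )


# ---------------------------------------------------------------------------
# radial distance
# ---------------------------------------------------------------------------


def radial_distance(grid: SurfaceGrid, longitudinal_axis: str = "u") -> np.ndarray:
    """Distance from each vertex to the centroid of its cross-section curve.

    ``longitudinal_axis='u'`` means cross-sections are the curves at fixed
    ``u`` (each spanning all ``v``); the core of each curve is the
    arithmetic mean of its vertices.
    """
    if longitudinal_axis not in ("u", "v"):
        raise ValueError("longitudinal_axis must be 'u' or 'v'")
    V = grid.vertices if longitudinal_axis == "u" else grid.vertices.transpose(1, 0, 2)
    cores = V.mean(axis=1, keepdims=True)  # (U, 1, 3)
    rd = np.linalg.norm(V - cores, axis=2)
    degenerate = np.all(rd < 1e-300, axis=1)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} degenerate cross-section curve(s); RD set to 0",
            stacklevel=2,
        )
    return rd if longitudinal_axis == "u" else rd.T


# ---------------------------------------------------------------------------
# tangential deformation (mTBM)
# ---------------------------------------------------------------------------


def _cell_edges(vertices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Edge vectors of each quad cell at its lower-left corner: (U-1, V-1, 3) x2."""
    e1 = vertices[1:, :-1, :] - vertices[:-1, :-1, :]
    e2 = vertices[:-1, 1:, :] - vertices[:-1, :-1, :]
    return e1, e2


def _tangent_coords(e1: np.ndarray, e2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Express cell edges in an orthonormal tangent basis built from them.

    Returns the 2x2 edge matrices M (columns are e1, e2 in basis coords)
    and a boolean mask of degenerate cells.
    """
    n1 = np.linalg.norm(e1, axis=-1)
    b1 = np.divide(e1, n1[..., None], out=np.zeros_like(e1), where=n1[..., None] > 0)
    proj = np.sum(e2 * b1, axis=-1)
    orth = e2 - proj[..., None] * b1
    n2 = np.linalg.norm(orth, axis=-1)
    b2 = np.divide(orth, n2[..., None], out=np.zeros_like(orth), where=n2[..., None] > 0)
    M = np.empty(e1.shape[:-1] + (2, 2))
    M[..., 0, 0] = n1
    M[..., 1, 0] = 0.0
    M[..., 0, 1] = proj
    M[..., 1, 1] = n2
    degenerate = (n1 <= 0) | (n2 <= 0)
    return M, degenerate


def _log_spd_2x2(S: np.ndarray) -> np.ndarray:
    """Matrix log of symmetric positive-definite 2x2 matrices (batched)."""
    w, Q = np.linalg.eigh(S)
    logw = np.log(w)
    return np.einsum("...ij,...j,...kj->...ik", Q, logw, Q)


def mtbm(template: SurfaceGrid, subject: SurfaceGrid) -> np.ndarray:
    """Per-vertex tangential deformation vector field (U, V, 3).

    Per quad cell the 2x2 Jacobian ``J = M_subj @ inv(M_tmpl)`` maps
    template cell edges to subject cell edges, each expressed in its own
    orthonormal tangent basis.  The output components are
    ``(L11, sqrt(2) L12, L22)`` of ``L = log (J^T J)^{1/2}``, so the vector
    2-norm equals the Frobenius norm of ``L``.  Cell values sit at the
    cell's lower-left vertex; the last row/column replicate neighbors.
    Degenerate or non-finite cells yield the zero vector (warned, counted).
    """
    if template.grid_shape != subject.grid_shape:
        raise ValueError(
            f"grid shapes differ: template {template.grid_shape} vs subject {subject.grid_shape}"
        )
    Mt, bad_t = _tangent_coords(*_cell_edges(template.vertices))
    Ms, bad_s = _tangent_coords(*_cell_edges(subject.vertices))
    bad = bad_t | bad_s

    # guard inversion on degenerate cells, zero them afterwards
    Mt_safe = np.where(bad[..., None, None], np.eye(2), Mt)
    J = Ms @ np.linalg.inv(Mt_safe)
    JtJ = np.swapaxes(J, -1, -2) @ J
    # S = (J^T J)^{1/2}; log S = (1/2) log(J^T J)
    with np.errstate(invalid="ignore", divide="ignore"):
        L = 0.5 * _log_spd_2x2(np.where(bad[..., None, None], np.eye(2), JtJ))
    nonfinite = ~np.all(np.isfinite(L), axis=(-1, -2))
    bad = bad | nonfinite
    L[bad] = 0.0

    if bad.any():
        warnings.warn(f"{int(bad.sum())} degenerate grid cell(s); mtbm set to 0", stacklevel=2)

    comp = np.stack([L[..., 0, 0], np.sqrt(2.0) * L[..., 0, 1], L[..., 1, 1]], axis=-1)
    U, V = template.grid_shape
    field = np.zeros((U, V, 3))
    field[: U - 1, : V - 1] = comp
    field[U - 1, : V - 1] = comp[U - 2]
    field[:, V - 1] = field[:, V - 2]
    return field


def assemble_mms(rd_field: np.ndarray, mtbm_field: np.ndarray, **meta: str) -> MMSField:
    """Stack RD and mTBM into the per-vertex 4-vector field."""
    if rd_field.shape != mtbm_field.shape[:2]:
        raise ValueError(
            f"rd shape {rd_field.shape} incompatible with mtbm shape {mtbm_field.shape}"
        )
    return MMSField(rd=np.asarray(rd_field, dtype=np.float64),
                    mtbm=np.asarray(mtbm_field, dtype=np.float64), **meta)


def compute_mms(template: SurfaceGrid, subject: SurfaceGrid,
                longitudinal_axis: str = "u") -> MMSField:
    """RD + mTBM in one call."""
    return assemble_mms(
        radial_distance(subject, longitudinal_axis),
        mtbm(template, subject),
        hemisphere=subject.hemisphere,
        subject_id=subject.subject_id,
    )


# ---------------------------------------------------------------------------
# patch extraction
# ---------------------------------------------------------------------------


def sample_patches(mms: MMSField, spec: PatchSpec,
                   rng: np.random.Generator | None = None) -> PatchSet:
    """Random overlapping square patches, vectorized row-major with channel
    innermost.  Corners are drawn uniformly with replacement from all valid
    top-left positions; duplicates are allowed."""
    U, V = mms.grid_shape
    s = spec.size
    if s > U or s > V:
        raise ValueError(f"patch size {s} exceeds grid shape ({U}, {V})")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.count_per_hemisphere
    cu = rng.integers(0, U - s + 1, size=n)
    cv = rng.integers(0, V - s + 1, size=n)
    stacked = mms.combined  # (U, V, 4)
    X = np.empty((s * s * MMS_CHANNELS, n))
    for j in range(n):
        X[:, j] = stacked[cu[j]:cu[j] + s, cv[j]:cv[j] + s, :].reshape(-1)
    return PatchSet(
        X=X,
        subject_ids=np.full(n, mms.subject_id, dtype=object),
        hemispheres=np.full(n, mms.hemisphere, dtype=object),
        corners=np.stack([cu, cv], axis=1),
        patch_size=s,
    )


def sample_subject_patches(fields: dict[str, MMSField], spec: PatchSpec) -> PatchSet:
    """Patches for one subject from both hemispheres (2 x count total).

    A single generator seeded with ``spec.seed`` draws corners for the left
    hemisphere then the right, so the subject total is deterministic.
    """
    rng = np.random.default_rng(spec.seed)
    sets = []
    for hemi in ("left", "right"):
        if hemi in fields:
            sets.append(sample_patches(fields[hemi], spec, rng=rng))
    if not sets:
        raise ValueError("no hemisphere fields provided")
    return concat_patch_sets(sets)


# ---------------------------------------------------------------------------
# summary measures
# ---------------------------------------------------------------------------


def summary_measures(grid: SurfaceGrid, *, close_v: bool = True,
                     cap_ends: bool = True) -> tuple[float, float]:
    """(surface_area mm^2, enclosed_volume mm^3) of the grid's triangulation.

    ``close_v`` stitches the last v column back to the first (tube seam);
    ``cap_ends`` closes the two u-boundary curves with triangle fans to
    their centroids.  Volume uses the divergence theorem and is reported as
    an absolute value (orientation-free).
    """
    P = grid.vertices
    if close_v:
        P = np.concatenate([P, P[:, :1, :]], axis=1)
    a = P[:-1, :-1].reshape(-1, 3)
    b = P[1:, :-1].reshape(-1, 3)
    c = P[1:, 1:].reshape(-1, 3)
    d = P[:-1, 1:].reshape(-1, 3)
    tris = [(a, b, c), (a, c, d)]
    if cap_ends:
        for row in (P[0], P[-1][::-1]):  # reverse one cap for consistent orientation
            centroid = np.broadcast_to(row[:-1].mean(axis=0), row[:-1].shape)
            tris.append((centroid, row[:-1], row[1:]))
    area = 0.0
    vol6 = 0.0
    for t0, t1, t2 in tris:
        cross = np.cross(t1 - t0, t2 - t0)
        area += 0.5 * np.linalg.norm(cross, axis=1).sum()
        vol6 += np.einsum("ij,ij->i", t0, np.cross(t1, t2)).sum()
    volume = abs(vol6) / 6.0
    if not (np.isfinite(area) and np.isfinite(volume)):
        raise ValueError("non-finite surface summary measure")
    return float(area), float(volume)
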