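"""Synthetic inputs for every stage of the pipeline, at desk scale.

Two generators back the test suite and the acceptance runs:

* ground-truth dictionary patch data — unit-norm atoms with bounded
  mutual coherence, k-sparse Laplace codes, Gaussian measurement noise and
  an optional fraction of whole-patch large-amplitude uniform outliers
  (the non-Gaussian contamination the correntropy loss is built to
  resist);
* two-group surface cohorts — a tube-like template grid deformed per
  subject by smooth random fields, with positives additionally receiving
  an inward radial deformation (and hence tangential compression) inside a
  planted effect region; centiloid values are drawn consistent with each
  subject's label around the cutoff.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .aggregate_classify import CENTILOID_CUTOFF
from .io_formats import FeatureContainer, write_grid, write_metadata
from .morphometry import MMSField, PatchSet, SurfaceGrid


@dataclass
class PatchGenSpec:
    p: int = 20
    m_true: int = 5
    n: int = 500
    k: int = 3
    noise_sd: float = 0.01
    outlier_frac: float = 0.0
    outlier_amp: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k > self.m_true:
            raise ValueError("sparsity k must be <= m_true")
        if not 0.0 <= self.outlier_frac < 1.0:
            raise ValueError("outlier_frac must be in [0, 1)")


@dataclass
class CohortSpec:
    n_pos: int = 100
    n_neg: int = 100
    grid_shape: tuple[int, int] = (40, 24)
    effect_region: tuple[int, int, int, int] = (10, 6, 26, 18)  # u0, v0, u1, v1
    effect_size: float = 0.6  # mm inward deformation for positives
    noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        u0, v0, u1, v1 = self.effect_region
        U, V = self.grid_shape
        if not (0 <= u0 < u1 <= U and 0 <= v0 < v1 <= V):
            raise ValueError(f"effect_region {self.effect_region} outside grid {self.grid_shape}")


@dataclass
class Cohort:
    """Per-subject surface grids (both hemispheres) plus metadata table."""

    grids: dict[str, dict[str, SurfaceGrid]]
    metadata: pd.DataFrame
    template: dict[str, SurfaceGrid] = dc_field(default_factory=dict)


# ---------------------------------------------------------------------------
# dictionary / patch generators
# ---------------------------------------------------------------------------


def gen_true_dictionary(spec: PatchGenSpec,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """m_true unit-norm atoms with pairwise |cosine| <= 0.5, by rejection."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    atoms: list[np.ndarray] = []
    for _ in range(10_000):
        cand = rng.standard_normal(spec.p)
        cand /= np.linalg.norm(cand)
        if all(abs(cand @ a) <= 0.5 for a in atoms):
            atoms.append(cand)
        if len(atoms) == spec.m_true:
            return np.stack(atoms, axis=1)
    raise RuntimeError(
        f"could not draw {spec.m_true} atoms with coherence <= 0.5 at p={spec.p}; "
        "increase p"
    )


def gen_patches(spec: PatchGenSpec,
                D_true: np.ndarray | None = None) -> tuple[PatchSet, np.ndarray, np.ndarray]:
    """Patch matrix X = D Z + noise (+ outliers); returns (patches, D, Z).

    Codes are exactly k-sparse with uniform random support and Laplace(0,1)
    nonzeros.  A seeded outlier_frac of the columns receives additive
    uniform(-amp, amp) noise over the whole patch.
    """
    rng = np.random.default_rng(spec.seed)
    if D_true is None:
        D_true = gen_true_dictionary(spec, rng=rng)
    Z = np.zeros((spec.m_true, spec.n))
    for j in range(spec.n):
        support = rng.choice(spec.m_true, size=spec.k, replace=False)
        Z[support, j] = rng.laplace(0.0, 1.0, size=spec.k)
    X = D_true @ Z
    if spec.noise_sd > 0:
        X = X + rng.normal(0.0, spec.noise_sd, size=X.shape)
    if spec.outlier_frac > 0:
        mask = rng.random(spec.n) < spec.outlier_frac
        X[:, mask] += rng.uniform(-spec.outlier_amp, spec.outlier_amp,
                                  size=(spec.p, int(mask.sum())))
    # patch_size bookkeeping is geometric; synthetic optimizer data bypasses it
    patches = PatchSet.__new__(PatchSet)
    patches.X = X
    patches.subject_ids = np.full(spec.n, "synthetic", dtype=object)
    patches.hemispheres = np.full(spec.n, "left", dtype=object)
    patches.corners = np.zeros((spec.n, 2), dtype=int)
    patches.patch_size = 0
    return patches, D_true, Z


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------


def _tube_template(grid_shape: tuple[int, int]) -> np.ndarray:
    """Tube-like template: circular cross-sections with a smoothly varying
    radius along u; v wraps short of 2*pi so the seam can be stitched."""
    U, V = grid_shape
    u = np.linspace(0.0, 1.0, U)
    phi = 2.0 * np.pi * np.arange(V) / V
    radius = 2.0 + 0.5 * np.sin(np.pi * u)  # bulge in the middle
    verts = np.empty((U, V, 3))
    verts[:, :, 0] = radius[:, None] * np.cos(phi)[None, :]
    verts[:, :, 1] = radius[:, None] * np.sin(phi)[None, :]
    verts[:, :, 2] = (10.0 * u)[:, None]
    return verts


def _smooth_field(rng: np.random.Generator, grid_shape: tuple[int, int],
                  scale: float, modes: int = 3) -> np.ndarray:
    """Low-frequency random scalar field over the grid, O(scale) amplitude."""
    U, V = grid_shape
    uu = np.linspace(0.0, 1.0, U)[:, None]
    vv = np.linspace(0.0, 1.0, V)[None, :]
    out = np.zeros((U, V))
    for a in range(1, modes + 1):
        for b in range(1, modes + 1):
            amp = rng.normal(0.0, scale / (a + b))
            pha_u, pha_v = rng.uniform(0, 2 * np.pi, size=2)
            out += amp * np.sin(2 * np.pi * a * uu + pha_u) * np.sin(2 * np.pi * b * vv + pha_v)
    return out


def gen_cohort(spec: CohortSpec) -> Cohort:
    """Two-group cohort with a planted radial effect in the positives.

    Every subject's grid is the template with a smooth random radial
    perturbation (amplitude `noise`).  Positive subjects additionally have
    radius reduced by `effect_size` (smoothly tapered) inside
    `effect_region`, shrinking both radial distance and the tangential
    metric there.  Centiloids are drawn truncated on the matching side of
    the cutoff, so labels and centiloid-derived labels agree everywhere.
    """
    rng = np.random.default_rng(spec.seed)
    base = _tube_template(spec.grid_shape)
    axis = base.copy()
    axis[:, :, 0] = 0.0
    axis[:, :, 1] = 0.0
    radial_dir = base - axis
    radial_norm = np.linalg.norm(radial_dir, axis=2, keepdims=True)
    radial_unit = radial_dir / radial_norm

    u0, v0, u1, v1 = spec.effect_region
    taper = np.zeros(spec.grid_shape)
    uu = np.arange(spec.grid_shape[0])[:, None]
    vv = np.arange(spec.grid_shape[1])[None, :]
    inside = (uu >= u0) & (uu < u1) & (vv >= v0) & (vv < v1)
    # raised-cosine taper to keep the deformation smooth at the region edge
    tu = np.clip((uu - u0) / max(u1 - u0 - 1, 1), 0, 1)
    tv = np.clip((vv - v0) / max(v1 - v0 - 1, 1), 0, 1)
    bump = np.sin(np.pi * tu) * np.sin(np.pi * tv)
    taper[inside] = np.broadcast_to(bump, spec.grid_shape)[inside]

    grids: dict[str, dict[str, SurfaceGrid]] = {}
    rows = []
    labels = ["positive"] * spec.n_pos + ["negative"] * spec.n_neg
    for i, label in enumerate(labels):
        sid = f"S{i:04d}"
        positive = label == "positive"
        per_hemi: dict[str, SurfaceGrid] = {}
        for hemi in ("left", "right"):
            dr = _smooth_field(rng, spec.grid_shape, spec.noise)
            if positive:
                dr = dr - spec.effect_size * taper
            verts = base + dr[:, :, None] * radial_unit
            per_hemi[hemi] = SurfaceGrid(verts, hemisphere=hemi, subject_id=sid)
        grids[sid] = per_hemi
        if positive:
            centiloid = _trunc_normal(rng, 71.0, 20.0, low=CENTILOID_CUTOFF)
        else:
            centiloid = _trunc_normal(rng, 8.0, 9.0, high=CENTILOID_CUTOFF)
        rows.append({
            "subject_id": sid,
            "cohort": "synthetic",
            "group_label": "CU",
            "centiloid": round(centiloid, 2),
            "abeta_status": label,
            "age": round(float(rng.normal(73.0, 6.0)), 1),
            "sex": str(rng.choice(["M", "F"])),
        })
    template = {
        "left": SurfaceGrid(base.copy(), hemisphere="left", subject_id="template"),
        "right": SurfaceGrid(base.copy(), hemisphere="right", subject_id="template"),
    }
    return Cohort(grids=grids, metadata=pd.DataFrame(rows), template=template)


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  low: float | None = None, high: float | None = None) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if (low is None or x >= low) and (high is None or x < high):
            return float(x)
    return float(low if low is not None else high - 1e-6)  # pragma: no cover


# ---------------------------------------------------------------------------
# fixture suite
# ---------------------------------------------------------------------------


def gen_fixture_suite(out_dir: str | Path, force: bool = False) -> dict[str, str]:
    """Write the small frozen fixtures used by unit tests; returns a
    manifest mapping relative path -> sha256."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is non-empty; pass force=True")
    out.mkdir(parents=True, exist_ok=True)

    cohort = gen_cohort(CohortSpec(n_pos=3, n_neg=3, grid_shape=(8, 6),
                                   effect_region=(2, 1, 6, 5), seed=7))
    write_metadata(cohort.metadata, out / "metadata.csv")
    for sid, per_hemi in cohort.grids.items():
        for hemi, grid in per_hemi.items():
            container = FeatureContainer(
                subject_id=sid, hemisphere=hemi, grid_shape=grid.grid_shape,
                payload=grid.vertices.reshape(-1, 3))
            write_grid(out / f"grid_{sid}_{hemi}.txt", container)

    patches, D_true, Z = gen_patches(PatchGenSpec(p=8, m_true=3, n=20, k=2, seed=7))
    np.savetxt(out / "patches.tsv", patches.X, delimiter="\t", fmt="%.17e")
    np.savetxt(out / "true_dictionary.tsv", D_true, delimiter="\t", fmt="%.17e")

    preds = pd.DataFrame({
        "y_true": [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
        "y_pred": [1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 1],
        "y_score": [0.9, 0.8, 0.85, 0.7, 0.95, 0.6, 0.75, 0.65, 0.8, 0.4,
                    0.1, 0.2, 0.15, 0.3, 0.25, 0.35, 0.05, 0.45, 0.55, 0.6],
    })
    preds.to_csv(out / "predictions.csv", index=False)

    manifest = {}
    for path in sorted(out.glob("*")):
        if path.name == "manifest.json":
            continue
        manifest[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
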