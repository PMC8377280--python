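"""Correntropy-induced sparse coding of patch matrices.

Fits a dictionary ``D`` (p x m, atom norms <= 1) and sparse codes ``Z`` to
a patch matrix ``X`` by visiting one patch at a time:

1. a half-quadratic weight ``h = exp(-||Dz - x||^2 / sigma^2)`` is computed
   from the incoming (D, z) and held fixed for the visit;
2. the code is updated by coordinate descent — one full pass over all m
   coordinates, then a few passes restricted to the nonzero support —
   where each scalar update is the weighted soft-threshold rule
   ``z_l = soft(rho_l, lam) / (h * ups_l)`` with
   ``rho_l = h * d_l . (x - D z + d_l z_l)`` and ``ups_l = ||d_l||^2``;
3. atoms on the code's support take a stochastic gradient step
   ``d_l <- d_l - (1 / r_l) * h * (D z - x) * z_l`` with per-atom step
   sizes from the diagonal accumulator ``r <- r + z^2``, then are
   projected back onto the unit-norm ball.

The weight ``h`` downweights patches that the current model reconstructs
poorly, making the fit robust to large-amplitude non-Gaussian outliers.
In the limit ``sigma -> inf`` (h = 1) the procedure reduces to plain
l1 stochastic coordinate coding.

The monitored objective is the sigma^2-scaled Welsch form
``sigma^2 * sum_i (1 - exp(-||D z_i - x_i||^2 / sigma^2)) / 2
+ lam * sum_i ||z_i||_1``,
whose half-quadratic majorizer is exactly the weighted-lasso surrogate the
updates minimize; it reduces to the plain least-squares sparse-coding
objective as sigma -> inf.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import RunLogger
from .morphometry import PatchSet

DEFAULT_M = 1800
DEFAULT_LAM = 0.22
DEFAULT_SIGMA = 3.6


@dataclass
class PascsHyper:
    """Hyperparameters of the sparse-coding fit."""

    m: int = DEFAULT_M
    lam: float = DEFAULT_LAM
    sigma: float = DEFAULT_SIGMA
    epochs: int = 10
    cd_support_passes: int = 3
    seed: int = 0
    renormalize_atoms: bool = False  # force ||d_l|| = 1 instead of <= 1
    refresh_h_before_sgd: bool = False

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def as_dict(self) -> dict:
        return {
            "m": int(self.m),
            "lam": float(self.lam),
            "sigma": float(self.sigma),
            "epochs": int(self.epochs),
            "cd_support_passes": int(self.cd_support_passes),
            "seed": int(self.seed),
            "renormalize_atoms": bool(self.renormalize_atoms),
            "refresh_h_before_sgd": bool(self.refresh_h_before_sgd),
        }


@dataclass
class PascsModel:
    """Dictionary, hyperparameters and optimizer state."""

    D: np.ndarray  # (p, m)
    hyper: PascsHyper
    hessian_diag: np.ndarray  # (m,) accumulated z_l^2
    visit_count: np.ndarray  # (m,) times each atom received a gradient step
    codes: np.ndarray | None = None  # (m, n) codes from the final fit epoch
    epoch_losses: list[float] | None = None
    epoch: int = 0

    @property
    def p(self) -> int:
        return self.D.shape[0]

    @property
    def m(self) -> int:
        return self.D.shape[1]


def init_model(patches: PatchSet, hyper: PascsHyper) -> PascsModel:
    """Initialize atoms from m distinct random patch columns, unit-normed.

    All-zero columns are replaced by normalized Gaussian directions."""
    p, n = patches.X.shape
    if n < hyper.m:
        warnings.warn(f"fewer patches ({n}) than atoms ({hyper.m})", stacklevel=2)
    rng = np.random.default_rng(hyper.seed)
    if n >= hyper.m:
        idx = rng.choice(n, size=hyper.m, replace=False)
    else:
        idx = rng.choice(n, size=hyper.m, replace=True)
    D = patches.X[:, idx].astype(np.float64).copy()
    norms = np.linalg.norm(D, axis=0)
    zero = norms < 1e-300
    if zero.any():
        repl = rng.standard_normal((p, int(zero.sum())))
        D[:, zero] = repl / np.linalg.norm(repl, axis=0)
        norms = np.linalg.norm(D, axis=0)
    D /= norms
    return PascsModel(
        D=D,
        hyper=hyper,
        hessian_diag=np.zeros(hyper.m),
        visit_count=np.zeros(hyper.m, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# half-quadratic weight
# ---------------------------------------------------------------------------


def hq_weight(x: np.ndarray, D: np.ndarray, z: np.ndarray, sigma: float) -> float:
    """h = exp(-||Dz - x||_2^2 / sigma^2), in (0, 1]."""
    r = D @ z - x
    sq = float(r @ r)
    if not np.isfinite(sq):
        raise FloatingPointError("non-finite residual in half-quadratic weight")
    return float(np.exp(-sq / sigma**2))


# ---------------------------------------------------------------------------
# coordinate descent
# ---------------------------------------------------------------------------


def cd_coordinate_step(l: int, x: np.ndarray, D: np.ndarray, z: np.ndarray,
                       h: float, lam: float) -> float:
    """Closed-form minimizer of the weighted-lasso surrogate in z_l.

    rho_l = h * sum_k d_kl (x_k - sum_{r != l} d_kr z_r); the update is the
    three-branch soft-threshold rule, dividing by h * ||d_l||^2.  Mutates
    z[l] and returns the new value.
    """
    d = D[:, l]
    ups = float(d @ d)
    if ups <= 0.0:
        warnings.warn(f"atom {l} has zero norm; z_l set to 0", stacklevel=2)
        z[l] = 0.0
        return 0.0
    partial = x - D @ z + d * z[l]
    rho = h * float(d @ partial)
    if rho < -lam:
        z[l] = (rho + lam) / (h * ups)
    elif rho > lam:
        z[l] = (rho - lam) / (h * ups)
    else:
        z[l] = 0.0
    return float(z[l])


def _cd_pass(x: np.ndarray, D: np.ndarray, z: np.ndarray, resid: np.ndarray,
             h: float, lam: float, ups: np.ndarray, coords: np.ndarray) -> None:
    """In-place CD sweep over `coords`, maintaining resid = x - D z."""
    for l in coords:
        d = D[:, l]
        zl_old = z[l]
        rho = h * (d @ resid + ups[l] * zl_old)
        if rho < -lam:
            zl = (rho + lam) / (h * ups[l])
        elif rho > lam:
            zl = (rho - lam) / (h * ups[l])
        else:
            zl = 0.0
        if zl != zl_old:
            resid += d * (zl_old - zl)
            z[l] = zl


def cd_code_update(x: np.ndarray, D: np.ndarray, z_in: np.ndarray, h: float,
                   lam: float, passes: int = 3) -> np.ndarray:
    """One full CD pass over all coordinates, then `passes` passes on the
    current nonzero support; h held fixed throughout."""
    z = np.asarray(z_in, dtype=np.float64).copy()
    ups = np.einsum("ij,ij->j", D, D)
    if np.any(ups <= 0.0):
        warnings.warn("zero-norm atom(s) skipped in CD", stacklevel=2)
    ok = ups > 0.0
    resid = x - D @ z
    m = D.shape[1]
    _cd_pass(x, D, z, resid, h, lam, ups, np.arange(m)[ok])
    for _ in range(passes):
        support = np.flatnonzero((z != 0.0) & ok)
        if support.size == 0:
            break
        _cd_pass(x, D, z, resid, h, lam, ups, support)
    z[~ok] = 0.0
    return z


# ---------------------------------------------------------------------------
# dictionary update
# ---------------------------------------------------------------------------


def sgd_dict_update(x: np.ndarray, z: np.ndarray, D: np.ndarray, h: float,
                    hessian_diag: np.ndarray, visit_count: np.ndarray,
                    renormalize: bool = False) -> None:
    """In-place SGD step on the atoms of z's support.

    Accumulates r <- r + z^2, then for each l with z_l != 0 steps
    d_l <- d_l - (1/r_l) h (Dz - x) z_l and projects onto ||d_l|| <= 1
    (or rescales to exactly 1 when `renormalize`).  Atoms with z_l = 0 are
    untouched.
    """
    hessian_diag += z * z
    support = np.flatnonzero(z)
    if support.size == 0:
        return
    grad_common = h * (D @ z - x)  # (p,)
    steps = z[support] / hessian_diag[support]
    D[:, support] -= np.outer(grad_common, steps)
    norms = np.linalg.norm(D[:, support], axis=0)
    if renormalize:
        scale = np.where(norms > 0, norms, 1.0)
    else:
        scale = np.where(norms > 1.0, norms, 1.0)
    D[:, support] /= scale
    visit_count[support] += 1


# ---------------------------------------------------------------------------
# fit / encode / objective
# ---------------------------------------------------------------------------


def fit(patches: PatchSet, hyper: PascsHyper,
        logger: RunLogger | None = None) -> PascsModel:
    """Alternating half-quadratic sparse coding over seeded random patch
    visits; codes warm-start across epochs and the final epoch's codes are
    persisted on the model."""
    model = init_model(patches, hyper)
    X = np.ascontiguousarray(patches.X, dtype=np.float64)
    p, n = X.shape
    Z = np.zeros((hyper.m, n))
    rng = np.random.default_rng(hyper.seed)
    losses: list[float] = []
    if logger is not None:
        logger.log("fit_start", n_patches=n, p=p, **hyper.as_dict())
    for epoch in range(hyper.epochs):
        order = rng.permutation(n)
        for i in order:
            x = X[:, i]
            h = hq_weight(x, model.D, Z[:, i], hyper.sigma)
            Z[:, i] = cd_code_update(x, model.D, Z[:, i], h, hyper.lam,
                                     passes=hyper.cd_support_passes)
            if hyper.refresh_h_before_sgd:
                h = hq_weight(x, model.D, Z[:, i], hyper.sigma)
            sgd_dict_update(x, Z[:, i], model.D, h, model.hessian_diag,
                            model.visit_count, renormalize=hyper.renormalize_atoms)
        model.epoch = epoch + 1
        loss = _welsch_objective(X, model.D, Z, hyper.lam, hyper.sigma)
        if not np.isfinite(loss):
            bad = _first_nonfinite_patch(X, model.D, Z, hyper.sigma)
            raise FloatingPointError(f"non-finite loss at epoch {epoch + 1}, patch {bad}")
        losses.append(loss)
        if logger is not None:
            logger.log("fit_epoch", epoch=epoch + 1, loss=loss)
    model.codes = Z
    model.epoch_losses = losses
    return model


def encode(patches: PatchSet, model: PascsModel, passes: int = 50,
           tol: float = 1e-6, z0: np.ndarray | None = None) -> np.ndarray:
    """Sparse codes for patches under the fitted dictionary (D untouched).

    Per patch, alternate {recompute h; CD update} until the max absolute
    code change drops below `tol` or `passes` outer iterations elapse.
    """
    X = np.asarray(patches.X, dtype=np.float64)
    p, n = X.shape
    if p != model.p:
        raise ValueError(f"patch dim {p} != model dim {model.p}")
    hyper = model.hyper
    Z = np.zeros((model.m, n)) if z0 is None else np.array(z0, dtype=np.float64)
    for i in range(n):
        x = X[:, i]
        z = Z[:, i]
        for _ in range(passes):
            h = hq_weight(x, model.D, z, hyper.sigma)
            z_new = cd_code_update(x, model.D, z, h, hyper.lam,
                                   passes=hyper.cd_support_passes)
            delta = float(np.max(np.abs(z_new - z))) if z_new.size else 0.0
            z = z_new
            if delta < tol:
                break
        Z[:, i] = z
    return Z


def _welsch_objective(X: np.ndarray, D: np.ndarray, Z: np.ndarray,
                      lam: float, sigma: float) -> float:
    R = D @ Z - X
    sq = np.einsum("ij,ij->j", R, R)
    data = sigma**2 * np.sum(1.0 - np.exp(-sq / sigma**2)) / 2.0
    return float(data + lam * np.abs(Z).sum())


def _first_nonfinite_patch(X, D, Z, sigma) -> int:
    R = D @ Z - X
    sq = np.einsum("ij,ij->j", R, R)
    bad = np.flatnonzero(~np.isfinite(sq))
    return int(bad[0]) if bad.size else -1


def objective(patches: PatchSet, model: PascsModel,
              Z: np.ndarray | None = None) -> float:
    """Scaled-Welsch monitoring objective at the given (or stored) codes."""
    if Z is None:
        Z = model.codes
    if Z is None:
        raise ValueError("no codes available; pass Z or fit the model first")
    return _welsch_objective(np.asarray(patches.X, dtype=np.float64),
                             model.D, Z, model.hyper.lam, model.hyper.sigma)


def surrogate_objective(x: np.ndarray, D: np.ndarray, z: np.ndarray,
                        h: float, lam: float) -> float:
    """Weighted-lasso surrogate (h/2)||Dz - x||^2 + lam ||z||_1."""
    r = D @ z - x
    return float(0.5 * h * (r @ r) + lam * np.abs(z).sum())
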