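"""Independent plain l1 stochastic coordinate coding reference.

A deliberately separate, correntropy-free implementation of online sparse
coding (lasso coordinate descent per signal + diagonal-Hessian SGD on the
dictionary).  Used as the sigma -> infinity oracle: the package's fit must
reduce to this when the kernel size is huge.  No imports from the package's
optimizer internals.
"""

from __future__ import annotations

import numpy as np


def scc_init(X: np.ndarray, m: int, seed: int) -> np.ndarray:
    p, n = X.shape
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=m, replace=False) if n >= m else rng.choice(n, size=m, replace=True)
    D = X[:, idx].astype(np.float64).copy()
    norms = np.linalg.norm(D, axis=0)
    zero = norms < 1e-300
    if zero.any():
        repl = rng.standard_normal((p, int(zero.sum())))
        D[:, zero] = repl / np.linalg.norm(repl, axis=0)
        norms = np.linalg.norm(D, axis=0)
    return D / norms


def lasso_cd(x: np.ndarray, D: np.ndarray, z: np.ndarray, lam: float,
             support_passes: int = 3) -> np.ndarray:
    """One full CD pass then `support_passes` passes on the nonzero support."""
    z = z.copy()
    ups = (D * D).sum(axis=0)
    resid = x - D @ z

    def sweep(coords):
        nonlocal resid
        for l in coords:
            d = D[:, l]
            rho = d @ resid + ups[l] * z[l]
            if rho < -lam:
                znew = (rho + lam) / ups[l]
            elif rho > lam:
                znew = (rho - lam) / ups[l]
            else:
                znew = 0.0
            if znew != z[l]:
                resid = resid + d * (z[l] - znew)
                z[l] = znew

    sweep(range(D.shape[1]))
    for _ in range(support_passes):
        support = np.flatnonzero(z)
        if support.size == 0:
            break
        sweep(support)
    return z


def scc_fit(X: np.ndarray, m: int, lam: float, epochs: int, seed: int,
            support_passes: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Full plain-SCC run; returns (D, Z)."""
    p, n = X.shape
    D = scc_init(X, m, seed)
    Z = np.zeros((m, n))
    r = np.zeros(m)
    order_rng = np.random.default_rng(seed)
    for _ in range(epochs):
        for i in order_rng.permutation(n):
            x = X[:, i]
            Z[:, i] = lasso_cd(x, D, Z[:, i], lam, support_passes)
            z = Z[:, i]
            r += z * z
            support = np.flatnonzero(z)
            if support.size == 0:
                continue
            grad = D @ z - x
            D[:, support] -= np.outer(grad, z[support] / r[support])
            norms = np.linalg.norm(D[:, support], axis=0)
            D[:, support] /= np.where(norms > 1.0, norms, 1.0)
    return D, Z
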