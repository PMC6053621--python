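"""Twin support vector machine for binary patch classification.

Unlike a single-plane SVM, the TWSVM learns two nonparallel hyperplanes in
kernel space, one hugging each class, and labels a sample by the nearer
plane.  With A the m1 ear samples, B the m2 background samples and
C = [A; B] the reference matrix, the two primal problems are

    min_{w1,b1}  1/2 ||K(A,C')w1 + e1 b1||^2 + c1 e2' q
       s.t.     -(K(B,C')w1 + e2 b1) + q >= e2,  q >= 0

and symmetrically for (w2, b2) with the roles of A and B swapped and
penalty c2.  Writing H = [K(A,C') e1] and G = [K(B,C') e2], the dual of the
first problem is the box-constrained QP

    max_alpha  e2' alpha - 1/2 alpha' G (H'H + eps I)^{-1} G' alpha,
               0 <= alpha <= c1,

with plane parameters [w1; b1] = -(H'H + eps I)^{-1} G' alpha; the second
problem swaps H and G (bound c2) and flips the sign of the recovery.  The
ridge eps keeps the Gram inversion well-posed for rank-deficient kernels.

Distances are normalized in kernel space,
d_i(x) = |K(x,C')w_i + b_i| / sqrt(w_i' K(C,C') w_i), and ties go to class 1.
The box QPs are Jacobi-preconditioned and solved by L-BFGS-B with a
projected-Newton finisher (exact coordinate descent as a last resort); the
projected-gradient KKT residual is verified in the original variables.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

__all__ = [
    "TwsvmModel",
    "QPSolverError",
    "rbf_kernel",
    "fit",
    "decision",
    "predict",
    "grid_search",
    "solve_box_qp",
]

_KKT_TOL = 1e-6


class QPSolverError(RuntimeError):
    """Raised when a dual QP cannot be solved to the KKT tolerance."""


@dataclass
class TwsvmModel:
    """Fitted twin SVM: reference matrix and the two kernel hyperplanes."""

    C: np.ndarray        # (m1+m2) x d stacked training samples [A; B]
    w1: np.ndarray       # kernel expansion coefficients, length m1+m2
    b1: float
    w2: np.ndarray
    b2: float
    c1: float
    c2: float
    gamma: float
    eps: float
    kernel: str = "rbf"
    norm1: float = 1.0   # sqrt(w1' K(C,C') w1), precomputed at fit
    norm2: float = 1.0


def rbf_kernel(x: np.ndarray, y: np.ndarray, gamma: float) -> np.ndarray:
    """K_ij = exp(-gamma * ||x_i - y_j||^2)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[1] != y.shape[1]:
        raise ValueError("x and y must have matching feature dimensions")
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    return np.exp(-gamma * cdist(x, y, "sqeuclidean"))


def _kernel(x: np.ndarray, y: np.ndarray, gamma: float, kind: str) -> np.ndarray:
    if kind == "rbf":
        return rbf_kernel(x, y, gamma)
    if kind == "linear":
        return np.atleast_2d(x) @ np.atleast_2d(y).T
    raise ValueError(f"unknown kernel {kind!r}")


def _projected_gradient(alpha: np.ndarray, grad: np.ndarray, ub: float) -> np.ndarray:
    r = grad.copy()
    at_lo = alpha <= 1e-12
    at_hi = alpha >= ub - 1e-12
    r[at_lo] = np.minimum(grad[at_lo], 0.0)
    r[at_hi] = np.maximum(grad[at_hi], 0.0)
    return r


def solve_box_qp(q: np.ndarray, ub: float, tol: float = _KKT_TOL,
                 max_iter: int = 200) -> np.ndarray:
    """Minimize 1/2 a'Qa - e'a subject to 0 <= a <= ub.

    The dual Gram matrices arising here are badly scaled (diagonals spanning
    many orders of magnitude), so the problem is Jacobi-preconditioned to a
    unit diagonal first.  L-BFGS-B minimizes the scaled problem, then a
    projected Newton iteration with Armijo backtracking along the
    projection arc finishes: coordinates pressed against a bound with an
    outward gradient are frozen and a Newton step is taken on the free
    block, with exact cyclic coordinate descent as a last resort.  The KKT
    projected-gradient residual is verified in the original (unscaled)
    variables against ``tol``, floored at the float64 noise level of the
    gradient evaluation.
    """
    m = q.shape[0]
    diag = np.diag(q).copy()
    scale = np.sqrt(np.maximum(diag, max(float(diag.max()), 1.0) * 1e-14))
    qs = q / np.outer(scale, scale)
    es = 1.0 / scale
    ubs = ub * scale  # per-coordinate box in the scaled variables
    eps_b = 1e-12 * np.maximum(ubs, 1.0)

    def objective(b: np.ndarray) -> float:
        return 0.5 * b @ (qs @ b) - es @ b

    def proj_grad(b: np.ndarray, grad: np.ndarray) -> np.ndarray:
        r = grad.copy()
        at_lo = b <= eps_b
        at_hi = b >= ubs - eps_b
        r[at_lo] = np.minimum(grad[at_lo], 0.0)
        r[at_hi] = np.maximum(grad[at_hi], 0.0)
        return r

    def orig_resid(b: np.ndarray) -> float:
        # residual of the original problem at alpha = b / scale
        return float(np.abs(proj_grad(b, qs @ b - es) * scale).max())

    # scaled diagonal is 1 except where the original diagonal was clamped
    qs_diag = np.diag(qs).copy()
    qs_diag[qs_diag <= 0] = np.inf

    def cd_sweeps(b: np.ndarray, grad: np.ndarray, sweeps: int) -> np.ndarray:
        for _ in range(sweeps):
            for i in range(m):
                new = min(max(b[i] - grad[i] / qs_diag[i], 0.0), ubs[i])
                delta = new - b[i]
                if delta != 0.0:
                    grad += qs[:, i] * delta
                    b[i] = new
            if np.abs(proj_grad(b, grad) * scale).max() <= tol:
                break
        return b

    # accuracy floor: Q is assembled through a ridged inversion and carries
    # relative error orders above machine eps, so KKT residuals below
    # ~1e-12 of the gradient scale are not meaningful
    noise_floor = 1e-12 * (float(np.abs(q).sum(axis=1).max()) * ub + 1.0)
    tol = max(tol, noise_floor)

    res = minimize(
        lambda b: (0.5 * b @ (qs @ b) - es @ b, qs @ b - es),
        np.zeros(m), jac=True, method="L-BFGS-B",
        bounds=np.stack([np.zeros(m), ubs], axis=1),
        options={"maxiter": 5000, "maxcor": 50, "ftol": 0.0,
                 "gtol": 1e-14, "maxls": 100},
    )
    beta = np.clip(res.x, 0.0, ubs)
    for _ in range(max_iter):
        grad = qs @ beta - es
        if np.abs(proj_grad(beta, grad) * scale).max() <= tol:
            return beta / scale
        binding = ((beta <= eps_b) & (grad > 0)) | ((beta >= ubs - eps_b) & (grad < 0))
        free = ~binding
        direction = np.where(binding, grad, 0.0)
        if free.any():
            qff = qs[np.ix_(free, free)]
            try:
                step = np.linalg.solve(qff + 1e-12 * np.eye(qff.shape[0]), grad[free])
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(qff, grad[free], rcond=None)[0]
            direction[free] = step
        f0 = objective(beta)
        t = 1.0
        cand = beta
        for _ls in range(60):
            trial = np.clip(beta - t * direction, 0.0, ubs)
            if objective(trial) <= f0 - 1e-4 * grad @ (beta - trial):
                cand = trial
                break
            t *= 0.5
        if np.array_equal(cand, beta):
            beta = cd_sweeps(beta.copy(), grad.copy(), sweeps=500)
            break
        beta = cand
    if orig_resid(beta) > tol:
        beta = cd_sweeps(beta.copy(), (qs @ beta - es).copy(), sweeps=500)
    resid = orig_resid(beta)
    if resid <= tol:
        return beta / scale
    raise QPSolverError(
        f"box QP did not reach KKT tolerance {tol}: residual {resid:.3e}"
    )


def fit(
    a: np.ndarray,
    b: np.ndarray,
    c1: float = 1.0,
    c2: float = 1.0,
    gamma: float = 1.0,
    eps: float = 1e-6,
    kernel: str = "rbf",
) -> TwsvmModel:
    """Train both hyperplanes from class-1 samples ``a`` and class-0 ``b``."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[0] < 1 or b.shape[0] < 1:
        raise ValueError("both classes need at least one sample")
    if min(c1, c2, eps) <= 0 or (kernel == "rbf" and gamma <= 0):
        raise ValueError("c1, c2, gamma and eps must be > 0")
    c = np.vstack([a, b])
    ka = _kernel(a, c, gamma, kernel)
    kb = _kernel(b, c, gamma, kernel)
    h = np.hstack([ka, np.ones((a.shape[0], 1))])
    g = np.hstack([kb, np.ones((b.shape[0], 1))])

    def plane(grm: np.ndarray, other: np.ndarray, bound: float) -> np.ndarray:
        m = grm.T @ grm + eps * np.eye(grm.shape[1])
        try:
            factor = cho_factor(m)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise QPSolverError(f"Gram matrix factorization failed: {exc}") from exc
        x = cho_solve(factor, other.T)  # (n+1) x m_other
        q = other @ x
        q = 0.5 * (q + q.T)
        alpha = solve_box_qp(q, bound)
        return x @ alpha

    u1 = -plane(h, g, c1)
    u2 = plane(g, h, c2)

    kcc = _kernel(c, c, gamma, kernel)
    w1, b1 = u1[:-1], float(u1[-1])
    w2, b2 = u2[:-1], float(u2[-1])
    norm1 = float(np.sqrt(max(w1 @ kcc @ w1, 0.0)))
    norm2 = float(np.sqrt(max(w2 @ kcc @ w2, 0.0)))
    return TwsvmModel(C=c, w1=w1, b1=b1, w2=w2, b2=b2, c1=c1, c2=c2,
                      gamma=gamma, eps=eps, kernel=kernel,
                      norm1=norm1, norm2=norm2)


def decision(model: TwsvmModel, x: np.ndarray) -> np.ndarray:
    """Per-sample normalized distances (d1, d2) to the two hyperplanes."""
    kx = _kernel(np.atleast_2d(np.asarray(x, dtype=float)), model.C,
                 model.gamma, model.kernel)
    d1 = np.abs(kx @ model.w1 + model.b1) / max(model.norm1, model.eps)
    d2 = np.abs(kx @ model.w2 + model.b2) / max(model.norm2, model.eps)
    return np.stack([d1, d2], axis=1)


def predict(model: TwsvmModel, x: np.ndarray) -> np.ndarray:
    """Nearest-plane labels in {0, 1}; ties go to class 1 (ear)."""
    d = decision(model, x)
    return (d[:, 0] <= d[:, 1]).astype(np.int64)


def _stratified_folds(labels: np.ndarray, folds: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(labels), dtype=np.int64)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < folds:
            raise ValueError(
                f"class {cls} has {len(idx)} samples, fewer than {folds} folds; "
                "use fewer folds"
            )
        rng.shuffle(idx)
        fold_of[idx] = np.arange(len(idx)) % folds
    return fold_of


def grid_search(
    train: np.ndarray,
    labels: np.ndarray,
    c_grid: tuple[float, ...] = tuple(2.0**p for p in range(-5, 6, 2)),
    gamma_grid: tuple[float, ...] = tuple(2.0**p for p in range(-5, 6, 2)),
    folds: int = 5,
    seed: int = 0,
    eps: float = 1e-6,
    kernel: str = "rbf",
) -> tuple[tuple[float, float], pd.DataFrame]:
    """Stratified k-fold CV over (c, gamma) with c1 = c2 = c.

    Returns the accuracy-maximizing pair (ties broken toward smaller c, then
    smaller gamma) and the full CV table.
    """
    train = np.asarray(train, dtype=float)
    labels = np.asarray(labels)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if not c_grid or not gamma_grid:
        raise ValueError("grids must be nonempty")
    c_grid = tuple(sorted(set(c_grid)))
    gamma_grid = tuple(sorted(set(gamma_grid)))
    fold_of = _stratified_folds(labels, folds, seed)

    records = []
    best = None
    for cval, gval in product(c_grid, gamma_grid):
        accs = []
        for f in range(folds):
            tr = fold_of != f
            te = ~tr
            model = fit(train[tr & (labels == 1)], train[tr & (labels == 0)],
                        c1=cval, c2=cval, gamma=gval, eps=eps, kernel=kernel)
            accs.append(float((predict(model, train[te]) == labels[te]).mean()))
        acc = float(np.mean(accs))
        records.append({"c": cval, "gamma": gval, "cv_accuracy": acc})
        if best is None or acc > best[0] + 1e-15:
            best = (acc, cval, gval)
    table = pd.DataFrame.from_records(records)
    return (best[1], best[2]), table
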