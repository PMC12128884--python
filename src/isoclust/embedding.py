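"""Low-dimensional embedding of the pairwise correlation matrix.

Each data set i is represented by coordinates x_i in d dimensions, chosen to
minimize

    Phi(x) = sum_{i<j} w_ij (r_ij - x_i . x_j)^2,

so the inner products of the coordinates reproduce the observed pairwise
correlations, with reliability weights w_ij damping the poorly determined
pairs.  The residual Phi at the optimum, as a function of d, tells how many
dimensions the systematic differences in the study need: the scan over
d = 1..min(N, 50) is summarized by the elbow of the residual curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .correlation import PairwiseMatrix

__all__ = [
    "EmbeddingResult",
    "DimensionScan",
    "minimize_objective",
    "scan_dimensions",
    "elbow_point",
    "cosine_distance_matrix",
    "pca_align",
]

GRADIENT_TOL = 1e-6
MAX_ITERATIONS = 1000
DEFAULT_MAX_DIM = 50
#: residuals below this are indistinguishable from zero at the gradient
#: tolerance used; the elbow treats them as one flat noise floor
RESIDUAL_FLOOR = 1e-8


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray  # (N, d)
    residual: float
    dimension: int
    seed: int
    n_iterations: int


@dataclass
class DimensionScan:
    dims_tested: list[int]
    residuals: list[float]
    selected: int


@njit(cache=True, fastmath=True)
def _phi_grad(x, r, w):
    """Phi = sum_{i<j} w_ij (r_ij - x_i.x_j)^2 and its gradient.

    w must have a zero diagonal (and zeros at invalid pairs), so the
    diagonal terms contribute nothing.
    """
    n = x.shape[0]
    g = x @ x.T
    phi = 0.0
    for i in range(n):
        for j in range(n):
            t = r[i, j] - g[i, j]
            wt = w[i, j] * t
            phi += wt * t
            g[i, j] = wt
    grad = g @ x
    for i in range(n):
        for j in range(x.shape[1]):
            grad[i, j] *= -2.0
    return 0.5 * phi, grad


@njit(cache=True)
def _lbfgs_minimize(x0, r, w, d, pgtol, maxiter, memory=10):
    """Limited-memory BFGS with Armijo backtracking, fully compiled.

    Minimizes Phi over flattened (N, d) coordinates.  Two-loop recursion
    with the standard s.y/y.y initial Hessian scaling; curvature pairs
    with non-positive s.y are skipped.  Stops when the gradient max-norm
    falls below ``pgtol`` or after ``maxiter`` iterations.
    """
    n = r.shape[0]
    nd = n * d
    x = x0.copy()
    f, g2 = _phi_grad(x.reshape(n, d), r, w)
    g = g2.ravel().copy()

    s_mem = np.zeros((memory, nd))
    y_mem = np.zeros((memory, nd))
    rho = np.zeros(memory)
    alpha = np.zeros(memory)
    n_pairs = 0
    head = 0  # next slot to write
    nit = 0
    for _ in range(maxiter):
        if np.max(np.abs(g)) < pgtol:
            break
        # two-loop recursion
        q = -g.copy()
        for i in range(n_pairs):
            idx = (head - 1 - i) % memory
            alpha[idx] = rho[idx] * np.dot(s_mem[idx], q)
            q -= alpha[idx] * y_mem[idx]
        if n_pairs > 0:
            last = (head - 1) % memory
            sy = 1.0 / rho[last]
            yy = np.dot(y_mem[last], y_mem[last])
            q *= sy / yy
        for i in range(n_pairs):
            idx = (head - n_pairs + i) % memory
            beta = rho[idx] * np.dot(y_mem[idx], q)
            q += (alpha[idx] - beta) * s_mem[idx]
        gp = np.dot(g, q)
        if gp >= 0.0:  # not a descent direction: restart from -g
            q = -g.copy()
            gp = -np.dot(g, g)
            n_pairs = 0
        # Armijo backtracking
        t = 1.0
        if n_pairs == 0:
            gnorm = np.sqrt(-gp)
            t = min(1.0, 1.0 / max(gnorm, 1e-12))
        f_new = f
        ok = False
        for _ls in range(40):
            x_new = x + t * q
            f_new, g2_new = _phi_grad(x_new.reshape(n, d), r, w)
            if f_new <= f + 1e-4 * t * gp:
                ok = True
                break
            t *= 0.5
        if not ok:
            break
        g_new = g2_new.ravel().copy()
        s = x_new - x
        y = g_new - g
        sy = np.dot(s, y)
        if sy > 1e-12 * np.sqrt(np.dot(s, s)) * np.sqrt(np.dot(y, y)):
            s_mem[head] = s
            y_mem[head] = y
            rho[head] = 1.0 / sy
            head = (head + 1) % memory
            if n_pairs < memory:
                n_pairs += 1
        x = x_new
        f = f_new
        g = g_new
        nit += 1
    return x, f, nit


def minimize_objective(
    m: PairwiseMatrix, d: int, seed: int, restarts: int = 1
) -> EmbeddingResult:
    """Fit N x d coordinates whose inner products reproduce r_ij.

    Quasi-Newton (L-BFGS-B) descent with the analytic gradient
    dPhi/dx_i = -2 sum_j w_ij (r_ij - x_i.x_j) x_j, started from
    coordinates drawn uniformly in [0, 1]^d with the given seed;
    terminates at projected-gradient max-norm < 1e-6 or 1000 iterations.
    With ``restarts`` > 1 independent starts are run and the lowest
    residual kept.
    """
    if d < 1:
        raise ValueError("dimension must be >= 1")
    w = np.asarray(m.weights, dtype=float).copy()
    np.fill_diagonal(w, 0.0)
    if not np.any(w > 0):
        raise ValueError("no calculable pairs: all weights are zero")
    r = np.where(m.valid, m.r, 0.0)
    np.fill_diagonal(r, 0.0)
    n = m.n_datasets

    best = None
    for k in range(restarts):
        rng = np.random.default_rng([int(seed), d, k])
        x0 = rng.uniform(0.0, 1.0, size=(n, d))
        xopt, fopt, nit = _lbfgs_minimize(
            x0.ravel(), r, w, d, GRADIENT_TOL, MAX_ITERATIONS
        )
        if best is None or fopt < best[1]:
            best = (xopt, fopt, nit)
    return EmbeddingResult(
        coordinates=best[0].reshape(n, d),
        residual=float(best[1]),
        dimension=d,
        seed=int(seed),
        n_iterations=int(best[2]),
    )


def scan_dimensions(
    m: PairwiseMatrix,
    max_dim: int = DEFAULT_MAX_DIM,
    seed: int = 0,
    restarts: int = 1,
) -> DimensionScan:
    """Minimize the objective for every d in 1..min(N, max_dim).

    Per-dimension starting coordinates derive deterministically from the
    master seed.  The selected dimension is the elbow of the residual
    curve — the first dimension at which the residual has dropped to its
    noise floor.
    """
    n = m.n_datasets
    if n < 2:
        raise ValueError("dimension scan needs at least two data sets")
    dims = list(range(1, min(n, max_dim) + 1))
    residuals = [
        minimize_objective(m, d, seed=seed, restarts=restarts).residual for d in dims
    ]
    return DimensionScan(
        dims_tested=dims, residuals=residuals, selected=elbow_point(residuals)
    )


def elbow_point(residuals) -> int:
    """Elbow (knee) of a decreasing residual curve, as a 1-based dimension.

    The curve is normalized to the unit square on both axes and the point
    with the greatest perpendicular distance from the chord joining the
    first and last points is returned.  Curves of length <= 2, flat curves
    and strictly linear decays all yield dimension 1; ties break toward the
    smaller dimension.  Residuals beneath the optimizer's noise floor are
    clamped so that fluctuations between "converged to zero" values cannot
    masquerade as structure.
    """
    y = np.asarray(residuals, dtype=float)
    if len(y) == 0:
        raise ValueError("empty residual list")
    if len(y) <= 2:
        return 1
    y = np.maximum(y, RESIDUAL_FLOOR)
    span = y.max() - y.min()
    # a flat curve (absolutely, or relative to its magnitude) has no elbow
    if span <= 1e-9 * max(y.max(), 1.0):
        return 1
    yn = (y - y.min()) / span
    xn = np.linspace(0.0, 1.0, len(y))
    # signed area distance from the chord (x0,y0)-(x1,y1); |cross product|
    dx, dy = xn[-1] - xn[0], yn[-1] - yn[0]
    dist = np.abs(dy * (xn - xn[0]) - dx * (yn - yn[0]))
    interior = dist[1:-1]
    chord_gap = 1e-12
    if interior.max() <= chord_gap:
        return 1
    return int(np.argmax(interior)) + 2  # +1 for slice offset, +1 for 1-based


def cosine_distance_matrix(e: EmbeddingResult) -> np.ndarray:
    """Pairwise 1 - cos(x_i, x_j) of the embedded coordinates.

    A zero-norm coordinate row is degenerate: it is assigned the maximal
    distance 1 to every other data set (with a warning) so it behaves as an
    isolated point downstream.
    """
    x = e.coordinates
    norms = np.linalg.norm(x, axis=1)
    zero = norms == 0
    safe = np.where(zero, 1.0, norms)
    unit = x / safe[:, None]
    cos = np.clip(unit @ unit.T, -1.0, 1.0)
    dist = 1.0 - cos
    if zero.any():
        import warnings

        warnings.warn(
            f"{int(zero.sum())} data set(s) have zero-norm coordinates; "
            "assigned maximal cosine distance",
            stacklevel=2,
        )
        dist[zero, :] = 1.0
        dist[:, zero] = 1.0
    np.fill_diagonal(dist, 0.0)
    return dist


def pca_align(e: EmbeddingResult) -> tuple[np.ndarray, list[float]]:
    """Center and rotate coordinates onto their principal axes.

    Returns the rigidly rotated coordinates (pairwise distances preserved)
    and the percentage of variance carried by each axis, in decreasing
    order and summing to 100.
    """
    x = e.coordinates - e.coordinates.mean(axis=0)
    # SVD of the centered coordinates gives the principal axes directly
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rotated = u * s
    var = s**2
    total = var.sum()
    if total == 0:
        percents = [100.0] + [0.0] * (len(s) - 1)
    else:
        percents = list(100.0 * var / total)
    return rotated, percents
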