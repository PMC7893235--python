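"""Independent oracles used by the tests.

These deliberately avoid the implementation's own code paths: the pairwise
alignment oracle searches rotation space directly, the TPS oracle solves the
interpolation system instead of inverting for the bending-energy block, and
the dip oracle minimizes the sup-distance over an explicit family of
piecewise-linear unimodal CDFs by linear programming.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog, minimize
from scipy.spatial.transform import Rotation


# ---------------------------------------------------------------------------
# rotation-space alignment oracle

def _residual_given_rotation(R: np.ndarray, Xc: np.ndarray, Yc: np.ndarray,
                             scale: bool) -> float:
    XR = Xc @ R
    if scale:
        s = float(np.sum(XR * Yc)) / float(np.sum(Xc ** 2))
    else:
        s = 1.0
    return float(np.sum((s * XR - Yc) ** 2))


def align_pair_oracle(target: np.ndarray, reference: np.ndarray,
                      scale: bool = True, n_grid: int = 30) -> float:
    """Minimum summed squared residual over proper rotations by grid search
    plus local refinement (no SVD)."""
    X = np.asarray(target, float)
    Y = np.asarray(reference, float)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    angles = np.linspace(0.0, 2.0 * np.pi, n_grid, endpoint=False)
    half = np.linspace(0.0, np.pi, n_grid // 2 + 1)
    best, best_e = None, np.inf
    for a in half:
        for b in angles:
            for c in angles:
                R = Rotation.from_euler("zyz", [b, a, c]).as_matrix()
                e = _residual_given_rotation(R, Xc, Yc, scale)
                if e < best_e:
                    best_e, best = e, (b, a, c)

    def f(v):
        return _residual_given_rotation(
            Rotation.from_euler("zyz", v).as_matrix(), Xc, Yc, scale)

    res = minimize(f, np.array(best), method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000})
    return float(min(best_e, res.fun))


# ---------------------------------------------------------------------------
# TPS energy via the interpolation system

def tps_energy_oracle(reference: np.ndarray, target: np.ndarray) -> float:
    """Bending energy by explicitly solving the TPS interpolation system
    mapping the reference onto the target and evaluating w' K w."""
    X = np.asarray(reference, float)
    V = np.asarray(target, float)
    k = X.shape[0]
    d = np.sqrt(np.sum((X[:, None] - X[None, :]) ** 2, axis=2))
    K = -d
    P = np.column_stack([np.ones(k), X])
    L = np.zeros((k + 4, k + 4))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    total = 0.0
    for dim in range(3):
        rhs = np.concatenate([V[:, dim], np.zeros(4)])
        sol = np.linalg.solve(L, rhs)
        w = sol[:k]
        total += float(w @ K @ w)
    return total


# ---------------------------------------------------------------------------
# dip statistic via LP over unimodal CDFs

def _solve_knot_mode(x: np.ndarray, j0: int, n: int) -> float:
    nc = j0 + 1
    nd = n - j0
    nv = nc + nd + 1
    A, b = [], []

    def idx_c(j):
        return j

    def idx_d(j):
        return nc + (j - j0)

    def slope_con(vidx, ja, jb, jc, sign):
        row = np.zeros(nv)
        dx01 = x[jb] - x[ja]
        dx12 = x[jc] - x[jb]
        row[vidx(jc)] += 1.0 / dx12
        row[vidx(jb)] += -1.0 / dx12 - 1.0 / dx01
        row[vidx(ja)] += 1.0 / dx01
        A.append(-sign * row)
        b.append(0.0)

    for j in range(1, j0):
        slope_con(idx_c, j - 1, j, j + 1, +1)
    for j in range(j0 + 1, n - 1):
        slope_con(idx_d, j - 1, j, j + 1, -1)
    if j0 >= 1:
        row = np.zeros(nv); row[idx_c(0)] = 1; row[idx_c(1)] = -1
        A.append(row); b.append(0.0)
    if j0 <= n - 2:
        row = np.zeros(nv); row[idx_d(n - 2)] = 1; row[idx_d(n - 1)] = -1
        A.append(row); b.append(0.0)
    row = np.zeros(nv); row[idx_c(j0)] = 1; row[idx_d(j0)] = -1
    A.append(row); b.append(0.0)
    for j in range(n):
        row = np.zeros(nv)
        row[idx_d(j) if j >= j0 else idx_c(j)] = -1
        row[-1] = -1
        A.append(row); b.append(-(j + 1) / n)
    for j in range(1, n):
        row = np.zeros(nv)
        row[idx_c(j) if j <= j0 else idx_d(j)] = 1
        row[-1] = -1
        A.append(row); b.append(j / n)
    row = np.zeros(nv); row[idx_c(0)] = 1; row[-1] = -1
    A.append(row); b.append(0.0)
    row = np.zeros(nv); row[idx_d(j0)] = 1; row[-1] = -1
    A.append(row); b.append((j0 + 1) / n)
    row = np.zeros(nv); row[idx_d(n - 1)] = -1; row[-1] = -1
    A.append(row); b.append(-1.0)
    c = np.zeros(nv); c[-1] = 1.0
    bounds = [(0.0, 1.0)] * (nc + nd) + [(0.0, None)]
    r = linprog(c, A_ub=np.array(A), b_ub=np.array(b), bounds=bounds,
                method="highs")
    return r.fun if r.status == 0 else np.inf


def dip_oracle(values) -> float:
    """Exact dip for small distinct samples: minimize the sup-distance over
    piecewise-linear unimodal CDFs (knots at the data, mode at any knot, an
    atom at the mode allowed).  A mode strictly inside a gap is dominated by
    a mode at an adjacent knot, so scanning knots is exhaustive."""
    x = np.sort(np.asarray(values, float).ravel())
    n = x.size
    if np.any(np.diff(x) == 0):
        raise ValueError("oracle requires distinct values")
    return float(min(_solve_knot_mode(x, j0, n) for j0 in range(n)))
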