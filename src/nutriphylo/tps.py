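"""Penalised thin-plate-spline surface fitting.

The surface f(x, y) minimises

    sum_i (z_i - f(x_i, y_i))^2 + penalty * J(f)

where J is the bending energy. The minimiser is an expansion in the radial
kernel phi(r) = r^2 log r plus an affine polynomial part; the coefficients
solve the symmetric augmented system

    [K + penalty*I  P] [w]   [z]
    [P^T            0] [c] = [0]

with K_ij = phi(|x_i - x_j|) and P = [1, x, y]. penalty = 0 interpolates
exactly; penalty -> inf tends to the least-squares plane. The generalised
cross-validation (GCV) score n*RSS / (n - tr(H))^2 selects the penalty when
requested; the hat matrix H is computed from the same augmented system, which
is why this solver is written out rather than delegated to a black-box
interpolator.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg


def _tps_kernel(r: np.ndarray) -> np.ndarray:
    # phi(0) = 0 by the r^2 log r limit
    with np.errstate(divide="ignore", invalid="ignore"):
        k = r * r * np.log(r)
    return np.where(r > 0, k, 0.0)


def average_duplicates(coords: np.ndarray, values: np.ndarray):
    """Average z over exactly coincident (x, y) coordinates.

    Returns (unique_coords, mean_values, n_duplicates_merged).
    """
    coords = np.asarray(coords, float)
    values = np.asarray(values, float)
    uniq, inverse = np.unique(coords, axis=0, return_inverse=True)
    if len(uniq) == len(coords):
        return coords, values, 0
    sums = np.bincount(inverse, weights=values, minlength=len(uniq))
    counts = np.bincount(inverse, minlength=len(uniq))
    return uniq, sums / counts, len(coords) - len(uniq)


class ThinPlateSpline:
    """Fitted penalised thin-plate spline over 2-D coordinates.

    Parameters
    ----------
    coords : (n, 2) array
        Distinct (x, y) locations; coincident duplicates must be averaged
        beforehand (see :func:`average_duplicates`).
    values : (n,) array
    smoothing : float
        Bending-energy penalty, >= 0.
    """

    def __init__(self, coords, values, smoothing: float = 0.0):
        coords = np.asarray(coords, float)
        values = np.asarray(values, float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must be (n, 2)")
        n = len(coords)
        if n < 6:
            raise ValueError("need at least 6 points for a thin-plate spline")
        if smoothing < 0:
            raise ValueError("smoothing penalty must be >= 0")
        P = np.column_stack([np.ones(n), coords])
        if np.linalg.matrix_rank(P) < 3:
            raise ValueError("points are collinear; surface is not identifiable")
        if len(np.unique(coords, axis=0)) != n:
            raise ValueError("duplicate coordinates; average them before fitting")

        r = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        K = _tps_kernel(r)
        A = np.zeros((n + 3, n + 3))
        A[:n, :n] = K + smoothing * np.eye(n)
        A[:n, n:] = P
        A[n:, :n] = P.T
        lu, piv = linalg.lu_factor(A)

        b = np.concatenate([values, np.zeros(3)])
        sol = linalg.lu_solve((lu, piv), b)
        self.coords = coords
        self.values = values
        self.smoothing = float(smoothing)
        self.w = sol[:n]
        self.c = sol[n:]
        self._lu = (lu, piv)
        self.fitted = K @ self.w + P @ self.c
        self.residuals = values - self.fitted
        self._K = K
        self._P = P

    def predict(self, coords) -> np.ndarray:
        coords = np.atleast_2d(np.asarray(coords, float))
        r = np.sqrt(((coords[:, None, :] - self.coords[None, :, :]) ** 2).sum(-1))
        return _tps_kernel(r) @ self.w + np.column_stack(
            [np.ones(len(coords)), coords]
        ) @ self.c

    def hat_trace(self) -> float:
        """Trace of the hat matrix mapping observed z to fitted z."""
        n = len(self.coords)
        rhs = np.zeros((n + 3, n))
        rhs[:n, :] = np.eye(n)
        sol = linalg.lu_solve(self._lu, rhs)
        H = self._K @ sol[:n, :] + self._P @ sol[n:, :]
        return float(np.trace(H))

    def gcv_score(self) -> float:
        n = len(self.coords)
        rss = float(self.residuals @ self.residuals)
        denom = n - self.hat_trace()
        if denom <= 1e-8:
            return np.inf
        return n * rss / denom**2


def select_smoothing_gcv(coords, values, penalties=None) -> float:
    """Pick the penalty minimising the GCV score over a log-spaced grid."""
    if penalties is None:
        penalties = np.logspace(-6, 3, 13)
    best, best_score = penalties[0], np.inf
    for lam in penalties:
        score = ThinPlateSpline(coords, values, smoothing=lam).gcv_score()
        if score < best_score:
            best, best_score = lam, score
    return float(best)
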