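"""Independent reference implementations used to cross-check the fitters.

These deliberately avoid the package's optimisation paths: the
exponential and Michaelis-Menten oracles are zooming grid searches with
linear amplitude solves, and the kinetic-scheme oracle is the
matrix-exponential solution of the linear ODE system.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import expm


def biexp_grid_oracle(
    t: np.ndarray,
    y: np.ndarray,
    k_range: tuple[float, float] = (1e-4, 1.0),
    n_grid: int = 31,
    n_zoom: int = 6,
) -> dict[str, float]:
    """Brute-force bi-exponential fit: grid over (k_fast, k_slow), linear solve.

    The grid zooms around the best pair ``n_zoom`` times, giving a final
    rate resolution far below 1e-4 relative.
    """
    bounds_f = [np.log10(k_range[0]), np.log10(k_range[1])]
    bounds_s = [np.log10(k_range[0]), np.log10(k_range[1])]
    best = None
    for _ in range(n_zoom):
        grid_f = np.logspace(*bounds_f, n_grid)
        grid_s = np.logspace(*bounds_s, n_grid)
        for kf, ks in itertools.product(grid_f, grid_s):
            if kf <= ks:
                continue
            X = np.column_stack([np.ones_like(t), np.exp(-ks * t), np.exp(-kf * t)])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = X @ coef - y
            ss = float(r @ r)
            if best is None or ss < best["ss"]:
                best = {
                    "ss": ss,
                    "k_fast": kf,
                    "k_slow": ks,
                    "f_inf": float(coef[0]),
                    "a_slow": float(coef[1]),
                    "a_fast": float(coef[2]),
                }
        # zoom to +/- 2 grid steps: rate correlation can park the discrete
        # argmin more than one step from the continuous optimum
        wf = 2 * (bounds_f[1] - bounds_f[0]) / (n_grid - 1)
        ws = 2 * (bounds_s[1] - bounds_s[0]) / (n_grid - 1)
        bounds_f = [np.log10(best["k_fast"]) - wf, np.log10(best["k_fast"]) + wf]
        bounds_s = [np.log10(best["k_slow"]) - ws, np.log10(best["k_slow"]) + ws]
    return best


def monoexp_grid_oracle(
    t: np.ndarray, y: np.ndarray, k_range=(1e-4, 1.0), n_grid=60, n_zoom=4
) -> dict[str, float]:
    lo, hi = np.log10(k_range[0]), np.log10(k_range[1])
    best = None
    for _ in range(n_zoom):
        for k in np.logspace(lo, hi, n_grid):
            X = np.column_stack([np.ones_like(t), np.exp(-k * t)])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = X @ coef - y
            ss = float(r @ r)
            if best is None or ss < best["ss"]:
                best = {"ss": ss, "k": k, "f_inf": float(coef[0]), "a": float(coef[1])}
        width = (hi - lo) / (n_grid - 1)
        lo, hi = np.log10(best["k"]) - width, np.log10(best["k"]) + width
    return best


def expm_trajectory(scheme, atp_uM: float, grid: np.ndarray) -> np.ndarray:
    """Matrix-exponential occupancies for the pseudo-first-order system."""
    Q = scheme.rate_matrix(atp_uM)
    p0 = scheme.initial_occupancy()
    return np.stack([expm(Q * t) @ p0 for t in grid])


def mm_grid_oracle(
    a: np.ndarray, v: np.ndarray, k_range=(1e-2, 1e4), n_grid=60, n_zoom=4
) -> dict[str, float]:
    """Michaelis-Menten fit by grid over K with linear solve for (v0, k_cat)."""
    lo, hi = np.log10(k_range[0]), np.log10(k_range[1])
    best = None
    for _ in range(n_zoom):
        for K in np.logspace(lo, hi, n_grid):
            X = np.column_stack([np.ones_like(a), a / (K + a)])
            coef, *_ = np.linalg.lstsq(X, v, rcond=None)
            r = X @ coef - v
            ss = float(r @ r)
            if best is None or ss < best["ss"]:
                best = {"ss": ss, "K": K, "v0": float(coef[0]), "k_cat": float(coef[1])}
        width = (hi - lo) / (n_grid - 1)
        lo, hi = np.log10(best["K"]) - width, np.log10(best["K"]) + width
    return best
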