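"""Local-linear kernel smoothers (Epanechnikov) for curves and surfaces.

These are the building blocks of the sparse-FPCA estimators: a 1-D
local-linear smoother for the mean function and the diagonal of the raw
second moments, and a 2-D local-linear smoother for the covariance
surface.  Both accept per-point weights so that pre-binned data (cell
means carrying counts) smooth like the raw cloud, and both widen the
bandwidth locally, with a warning, where a target has no kernel support.

Bandwidth selection is by generalized cross-validation over a candidate
grid: GCV(h) = RSS(h) / (1 - df(h)/N)^2, where df is the trace of the
smoother ("hat") matrix on the design points.  The trace is computed
exactly from the local-linear normal equations, so interpolating fits
(h -> 0 on binned data) are properly penalized.
"""

from __future__ import annotations

import warnings

import numpy as np

from .exceptions import DegenerateInputError


def epanechnikov(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    out = 0.75 * (1.0 - u * u)
    return np.where(np.abs(u) <= 1.0, out, 0.0)


def _ll1d_at(x, y, w, x0, h, max_widen=40):
    """Local-linear estimate at one target; returns (fit, own_weight, widened).

    ``own_weight`` is the hat-matrix weight that a datum located exactly at
    ``x0`` receives (0 if no datum sits there); the degenerate single-
    abscissa design falls back to the local weighted mean.
    """
    widened = False
    for _ in range(max_widen):
        kw = w * epanechnikov((x - x0) / h)
        act = kw > 0
        if np.any(act):
            dx = x[act] - x0
            ww = kw[act]
            yy = y[act]
            s0 = ww.sum()
            s1 = float(ww @ dx)
            s2 = float(ww @ (dx * dx))
            denom = s0 * s2 - s1 * s1
            at0 = dx == 0
            w0 = float(ww[at0].sum())
            if denom > 1e-10 * max(s0 * s2, 1e-300):
                t0 = float(ww @ yy)
                t1 = float(ww @ (dx * yy))
                fit = (s2 * t0 - s1 * t1) / denom
                own = w0 * s2 / denom
            else:
                fit = float(ww @ yy) / s0
                own = w0 / s0
            return fit, own, widened
        h *= 1.5
        widened = True
    raise DegenerateInputError(f"no data within any bandwidth around x = {x0}")


def local_linear_1d(
    x: np.ndarray,
    y: np.ndarray,
    xout: np.ndarray,
    bandwidth: float,
    weights: np.ndarray = None,
    max_widen: int = 40,
) -> np.ndarray:
    """Local-linear fit of ``y`` on ``x`` evaluated at ``xout``.

    At each target the weighted least-squares line through the in-kernel
    points is evaluated at the target.  A degenerate local design (single
    distinct abscissa) falls back to the weighted mean; an empty kernel
    window is widened by 50% steps (with a warning) until support appears.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if weights is None:
        weights = np.ones_like(x)
    xout_arr = np.atleast_1d(np.asarray(xout, dtype=float))
    out = np.empty(xout_arr.shape)
    widened_any = False
    for idx, x0 in enumerate(xout_arr):
        out[idx], _, widened = _ll1d_at(x, y, weights, float(x0), float(bandwidth), max_widen)
        widened_any = widened_any or widened
    if widened_any:
        warnings.warn("bandwidth widened locally at targets with empty kernel windows", stacklevel=2)
    return out


def gcv_bandwidth_1d(
    x: np.ndarray,
    y: np.ndarray,
    candidates: np.ndarray,
    weights: np.ndarray = None,
) -> float:
    """GCV bandwidth for the 1-D smoother, fitted at the design points."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if weights is None:
        weights = np.ones_like(x)
    n = x.size
    best_h, best_score = None, np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for h in candidates:
            try:
                fits = np.empty(n)
                df = 0.0
                for i in range(n):
                    fits[i], own, _ = _ll1d_at(x, y, weights, float(x[i]), float(h))
                    df += own
            except DegenerateInputError:
                continue
            shrink = 1.0 - df / n
            if shrink <= 1e-8:
                continue
            rss = float(weights @ (y - fits) ** 2)
            score = rss / shrink**2
            if score < best_score:
                best_h, best_score = float(h), score
    if best_h is None:
        raise DegenerateInputError("no admissible GCV candidate bandwidth for the curve smoother")
    return best_h


def _llsurf_at(grid, vals, counts, p, q, h, max_widen=40):
    """Local-linear surface estimate at grid cell (p, q) with own-cell weight."""
    u = grid - grid[p]
    v = grid - grid[q]
    widened = False
    for _ in range(max_widen):
        wp = epanechnikov(u / h)
        wq = epanechnikov(v / h)
        W = counts * np.outer(wp, wq)
        s00 = W.sum()
        if s00 > 0:
            rw = W.sum(axis=1)
            cw = W.sum(axis=0)
            sx = float(u @ rw)
            sy = float(v @ cw)
            sxx = float((u * u) @ rw)
            syy = float((v * v) @ cw)
            sxy = float(u @ W @ v)
            WC = W * vals
            t0 = WC.sum()
            tx = float(u @ WC.sum(axis=1))
            ty = float(WC.sum(axis=0) @ v)
            A = np.array([[s00, sx, sy], [sx, sxx, sxy], [sy, sxy, syy]])
            b = np.array([t0, tx, ty])
            sol, *_ = np.linalg.lstsq(A, b, rcond=None)
            est = sol[0] if np.isfinite(sol[0]) else t0 / s00
            own = 0.0
            if counts[p, q] > 0:
                z, *_ = np.linalg.lstsq(A, np.array([1.0, 0.0, 0.0]), rcond=None)
                own = float(W[p, q] * z[0])
            return est, own, widened
        h *= 1.5
        widened = True
    raise DegenerateInputError("covariance surface has an unreachable target cell")


def local_linear_surface(
    grid: np.ndarray,
    values: np.ndarray,
    counts: np.ndarray,
    bandwidth: float,
    max_widen: int = 40,
):
    """Local-linear smooth of a binned surface on ``grid x grid``.

    ``values[p, q]`` is the mean of raw surface points in lattice cell
    ``(p, q)`` and ``counts[p, q]`` how many; empty cells are ignored.
    Only the upper triangle is fitted and the result symmetrized exactly.
    """
    grid = np.asarray(grid, dtype=float)
    m = grid.size
    vals = np.where(counts > 0, values, 0.0)
    G = np.empty((m, m))
    widened_any = False
    for p in range(m):
        for q in range(p, m):
            est, _, widened = _llsurf_at(grid, vals, counts, p, q, float(bandwidth), max_widen)
            G[p, q] = G[q, p] = est
            widened_any = widened_any or widened
    if widened_any:
        warnings.warn("surface bandwidth widened locally at empty target neighbourhoods", stacklevel=2)
    return G
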