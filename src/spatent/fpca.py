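"""Sparse functional principal component analysis via conditional expectation.

Subjects contribute irregularly observed curves: subject ``i`` has values
``y_ik`` at abscissae ``s_ik``, ``k = 1..K_i`` (here, SPI values at distance
bin midpoints; empty bins are simply absent).  The model is

    y_ik = X_i(s_ik) + eps_ik,
    X_i(s) = mu(s) + sum_l  xi_il phi_l(s),

with mean function ``mu``, covariance ``G(s, t) = sum_l lambda_l
phi_l(s) phi_l(t)``, uncorrelated scores ``xi_il`` of variance
``lambda_l``, and iid measurement error of variance ``sigma^2``.

Estimation follows the pooling strategy for sparse designs: a local-linear
smoother of all points pooled across subjects estimates ``mu``; raw
covariances ``(y_ij - mu)(y_il - mu)``, ``j != l``, smoothed over the
plane estimate ``G`` (the diagonal is excluded because it is contaminated
by ``sigma^2``); the error variance is the average positive gap between
the smoothed diagonal of the raw second moments and the diagonal of
``G-hat`` over the central half of the domain.  Eigenanalysis of the
discretized surface with trapezoid quadrature yields eigenpairs, and
scores are best linear predictors (conditional expectations under
Gaussianity), which remain well-defined however few observations a
subject has:

    xi_il = lambda_l phi_il^T  Sigma_i^{-1} (y_i - mu_i),
    Sigma_i[j, l] = G(s_ij, s_il) + sigma^2 delta_jl.

The linear systems are solved by Cholesky factorization, with a small
ridge (1e-8 x mean diagonal) only if the factorization fails.

The number of retained components ``L`` is the smallest number whose
eigenvalues account for at least a fraction ``fve_threshold`` (default
0.92) of the total eigenvalue mass.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from ._smoothing import gcv_bandwidth_1d, local_linear_1d, local_linear_surface
from .exceptions import DegenerateInputError, ValidationError

__all__ = [
    "FunctionalSample",
    "FPCAConfig",
    "FPCAModel",
    "estimate_mean",
    "estimate_covariance",
    "eigendecompose",
    "select_n_components",
    "estimate_scores_conditional",
    "fit_fpca",
]


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class FunctionalSample:
    """A collection of irregularly observed curves."""

    ids: tuple
    abscissae: tuple  # of 1-D float arrays
    values: tuple  # of matching 1-D float arrays

    def __post_init__(self):
        if not (len(self.ids) == len(self.abscissae) == len(self.values)):
            raise ValidationError("ids, abscissae and values must align")
        if len(self.ids) == 0:
            raise ValidationError("empty functional sample")
        absc, vals = [], []
        for s, y in zip(self.abscissae, self.values):
            s = np.asarray(s, dtype=float)
            y = np.asarray(y, dtype=float)
            if s.ndim != 1 or s.shape != y.shape or s.size < 1:
                raise ValidationError("each subject needs >= 1 (abscissa, value) pair")
            if not (np.all(np.isfinite(s)) and np.all(np.isfinite(y))):
                raise ValidationError("non-finite observation in functional sample")
            absc.append(s)
            vals.append(y)
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "abscissae", tuple(absc))
        object.__setattr__(self, "values", tuple(vals))

    @property
    def n_subjects(self) -> int:
        return len(self.ids)

    @property
    def domain(self) -> tuple[float, float]:
        lo = min(float(s.min()) for s in self.abscissae)
        hi = max(float(s.max()) for s in self.abscissae)
        return lo, hi

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        return np.concatenate(self.abscissae), np.concatenate(self.values)

    @classmethod
    def from_curves(cls, curves: dict) -> "FunctionalSample":
        """Build from ``{subject_id: SPICurve}``, dropping empty bins."""
        ids, absc, vals = [], [], []
        for sid, curve in curves.items():
            s, y = curve.observed()
            if s.size == 0:
                warnings.warn(f"subject {sid!r} has no defined SPI values; skipped", stacklevel=2)
                continue
            ids.append(sid)
            absc.append(s)
            vals.append(y)
        return cls(tuple(ids), tuple(absc), tuple(vals))

    @classmethod
    def from_matrix(cls, abscissae: np.ndarray, values: np.ndarray, ids: Sequence = None) -> "FunctionalSample":
        """Dense regular design: every row observed on the same abscissae."""
        values = np.asarray(values, dtype=float)
        n = values.shape[0]
        if ids is None:
            ids = [f"s{i + 1}" for i in range(n)]
        s = np.asarray(abscissae, dtype=float)
        return cls(tuple(ids), tuple(s for _ in range(n)), tuple(values[i] for i in range(n)))

    @classmethod
    def from_dataframe(cls, df, id_col="subject_id", s_col="midpoint", y_col="spi") -> "FunctionalSample":
        ids, absc, vals = [], [], []
        for sid, sub in df.dropna(subset=[y_col]).groupby(id_col, sort=True):
            ids.append(sid)
            absc.append(sub[s_col].to_numpy(dtype=float))
            vals.append(sub[y_col].to_numpy(dtype=float))
        return cls(tuple(ids), tuple(absc), tuple(vals))


@dataclass(frozen=True)
class FPCAConfig:
    """Tuning knobs for the sparse FPCA fit.

    ``mean_bandwidth`` / ``cov_bandwidth`` are either ``"auto"`` (GCV over a
    geometric candidate grid, expressed as fractions of the domain range)
    or a fixed float for reproducibility-critical pipelines.
    """

    n_grid: int = 51
    mean_bandwidth: float | str = "auto"
    cov_bandwidth: float | str = "auto"
    #: "subject" gives every curve equal total weight in the covariance
    #: (robust to very unbalanced K_i); "obs" weights every raw pair equally.
    cov_weighting: str = "subject"
    fve_threshold: float = 0.92
    max_components: int = 20
    mean_bin_threshold: int = 4000  # pre-bin pooled mean data beyond this size
    mean_candidates: tuple = (0.02, 0.5, 10)  # geomspace(lo*r, hi*r, num)
    cov_candidates: tuple = (0.04, 0.35, 10)


@dataclass(frozen=True)
class FPCAModel:
    """Fitted mean, covariance, eigenstructure, noise and subject scores.

    ``eigenvalues``/``eigenfunctions`` hold all retained (positive)
    components; ``n_selected`` is the count reaching the FVE threshold and
    ``scores`` has one column per retained component (use
    ``scores[:, :n_selected]`` for the selected set).
    """

    grid: np.ndarray
    mean: np.ndarray
    covariance: np.ndarray
    sigma2: float
    eigenvalues: np.ndarray
    eigenfunctions: np.ndarray  # (n_grid, n_components)
    fve: np.ndarray  # cumulative fraction of variance explained
    n_selected: int
    scores: np.ndarray  # (n_subjects, n_components)
    ids: tuple
    config: FPCAConfig = field(default_factory=FPCAConfig)

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size

    def mean_at(self, s: np.ndarray) -> np.ndarray:
        return np.interp(s, self.grid, self.mean)

    def eigenfunctions_at(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return np.column_stack(
            [np.interp(s, self.grid, self.eigenfunctions[:, l]) for l in range(self.n_components)]
        )

    def reconstruct(self, i: int, n_components: int = None) -> np.ndarray:
        """Fitted trajectory for subject ``i`` on the working grid."""
        L = self.n_selected if n_components is None else n_components
        return self.mean + self.eigenfunctions[:, :L] @ self.scores[i, :L]


# ---------------------------------------------------------------------------
# estimation steps


def _quadrature_weights(grid: np.ndarray) -> np.ndarray:
    """Trapezoid weights on a (possibly non-uniform) grid."""
    w = np.empty_like(grid)
    w[0] = (grid[1] - grid[0]) / 2
    w[-1] = (grid[-1] - grid[-2]) / 2
    w[1:-1] = (grid[2:] - grid[:-2]) / 2
    return w


def _working_grid(sample: FunctionalSample, n_grid: int) -> np.ndarray:
    lo, hi = sample.domain
    if hi <= lo:
        raise DegenerateInputError("functional sample has zero-length domain")
    return np.linspace(lo, hi, n_grid)


def _bin_1d(x, y, grid):
    """Nearest-grid-cell binning: (cell means, cell counts)."""
    step = grid[1] - grid[0]
    idx = np.clip(np.rint((x - grid[0]) / step).astype(int), 0, grid.size - 1)
    counts = np.bincount(idx, minlength=grid.size).astype(float)
    sums = np.bincount(idx, weights=y, minlength=grid.size)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return means, counts, idx


def estimate_mean(
    sample: FunctionalSample,
    bandwidth: float | str = "auto",
    grid: np.ndarray = None,
    config: FPCAConfig = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Local-linear mean function on the working grid.

    Returns ``(grid, mu_hat, bandwidth_used)``.  Pooled observations are
    pre-binned onto a fine lattice when very numerous; binning carries the
    counts as smoother weights, so estimates are unchanged up to within-cell
    rounding.
    """
    config = config or FPCAConfig()
    if grid is None:
        grid = _working_grid(sample, config.n_grid)
    s, y = sample.pooled()
    if s.size < 10:
        raise DegenerateInputError("need at least 10 pooled observations to estimate the mean")
    weights = np.ones_like(s)
    if s.size > config.mean_bin_threshold:
        fine = np.linspace(grid[0], grid[-1], 4 * config.n_grid - 3)
        means, counts, _ = _bin_1d(s, y, fine)
        keep = counts > 0
        s, y, weights = fine[keep], means[keep], counts[keep]
    if bandwidth == "auto":
        r = grid[-1] - grid[0]
        lo, hi, num = config.mean_candidates
        candidates = r * np.geomspace(lo, hi, int(num))
        if s.size > 600:  # GCV cost is quadratic in design size; bin first
            fine = np.linspace(grid[0], grid[-1], 4 * config.n_grid - 3)
            means, counts, _ = _bin_1d(s, y, fine)
            keep = counts > 0
            bandwidth = gcv_bandwidth_1d(fine[keep], means[keep], candidates, counts[keep])
        else:
            bandwidth = gcv_bandwidth_1d(s, y, candidates, weights)
    mu = local_linear_1d(s, y, grid, float(bandwidth), weights)
    return grid, mu, float(bandwidth)


def _cv_bandwidth_surface(grid, fold_sum, fold_cnt, candidates) -> float:
    """K-fold (by subject) CV for the covariance-surface bandwidth.

    For each candidate the surface is smoothed from all-but-one fold's
    binned raw covariances and scored against the held-out fold's cells;
    within-curve dependence therefore cannot reward interpolation.
    """
    import warnings as _warnings

    n_folds = fold_sum.shape[0]
    total_sum = fold_sum.sum(axis=0)
    total_cnt = fold_cnt.sum(axis=0)
    best_h, best_err = None, np.inf
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        for h in candidates:
            err = 0.0
            ok = True
            for f in range(n_folds):
                train_cnt = total_cnt - fold_cnt[f]
                test_cnt = fold_cnt[f]
                if train_cnt.sum() == 0 or test_cnt.sum() == 0:
                    continue
                train_mean = np.where(
                    train_cnt > 0, (total_sum - fold_sum[f]) / np.where(train_cnt > 0, train_cnt, 1.0), 0.0
                )
                try:
                    G = local_linear_surface(grid, train_mean, train_cnt, float(h))
                except DegenerateInputError:
                    ok = False
                    break
                mask = test_cnt > 0
                test_mean = fold_sum[f][mask] / test_cnt[mask]
                err += float((test_cnt[mask] * (test_mean - G[mask]) ** 2).sum())
            if ok and err < best_err:
                best_h, best_err = float(h), err
    if best_h is None:
        raise DegenerateInputError("no admissible candidate bandwidth for the covariance surface")
    return best_h


def estimate_covariance(
    sample: FunctionalSample,
    bandwidth: float | str = "auto",
    grid: np.ndarray = None,
    mean: np.ndarray = None,
    config: FPCAConfig = None,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Covariance surface and noise variance from raw cross-products.

    Off-diagonal raw covariances (within-subject cross-products of mean
    residuals, ``j != l``) are binned onto the ``grid x grid`` lattice and
    smoothed with a 2-D local-linear smoother; the surface is symmetrized.
    ``sigma^2`` is the average gap, over the central half of the domain,
    between the smoothed diagonal of the raw second moments and the
    diagonal of the smoothed covariance, floored at zero.

    Returns ``(grid, G_hat, sigma2, bandwidth_used)``.
    """
    config = config or FPCAConfig()
    if grid is None:
        grid = _working_grid(sample, config.n_grid)
    if mean is None:
        grid, mean, _ = estimate_mean(sample, config.mean_bandwidth, grid, config)
    if max(s.size for s in sample.abscissae) < 2:
        raise DegenerateInputError(
            "covariance is inestimable: every subject has a single observation"
        )

    m = grid.size
    step = grid[1] - grid[0]
    n_folds = 5
    fold_sum = np.zeros((n_folds, m, m))
    fold_cnt = np.zeros((n_folds, m, m))
    diag_sum = np.zeros(m)
    diag_cnt = np.zeros(m)
    fold_ids = [
        zlib.crc32(s.tobytes() + y.tobytes()) % n_folds
        for s, y in zip(sample.abscissae, sample.values)
    ]  # content-derived folds: invariant to subject order
    if config.cov_weighting not in ("subject", "obs"):
        raise ValidationError(f"unknown cov_weighting {config.cov_weighting!r}")
    for i, (s, y) in enumerate(zip(sample.abscissae, sample.values)):
        resid = y - np.interp(s, grid, mean)
        idx = np.clip(np.rint((s - grid[0]) / step).astype(int), 0, m - 1)
        w_diag = 1.0 / s.size if config.cov_weighting == "subject" else 1.0
        np.add.at(diag_sum, idx, w_diag * resid * resid)
        np.add.at(diag_cnt, idx, np.full(s.size, w_diag))
        if s.size < 2:
            continue
        w_pair = 1.0 / (s.size * (s.size - 1)) if config.cov_weighting == "subject" else 1.0
        outer = np.outer(resid, resid)
        off = ~np.eye(s.size, dtype=bool)
        rows = np.repeat(idx, s.size)[off.ravel()]
        cols = np.tile(idx, s.size)[off.ravel()]
        f = fold_ids[i]
        np.add.at(fold_sum[f], (rows, cols), w_pair * outer[off])
        np.add.at(fold_cnt[f], (rows, cols), np.full(rows.size, w_pair))
    cross_sum = fold_sum.sum(axis=0)
    cross_cnt = fold_cnt.sum(axis=0)

    if cross_cnt.sum() == 0:
        raise DegenerateInputError("no within-subject pairs available for the covariance")
    with np.errstate(invalid="ignore", divide="ignore"):
        cross_mean = np.where(cross_cnt > 0, cross_sum / np.where(cross_cnt > 0, cross_cnt, 1.0), 0.0)

    if bandwidth == "auto":
        # leave-subjects-out cross-validation: raw covariances from the same
        # curve are strongly dependent, so pointwise GCV undersmooths badly
        r = grid[-1] - grid[0]
        lo, hi, num = config.cov_candidates
        candidates = r * np.geomspace(lo, hi, int(num))
        bandwidth = _cv_bandwidth_surface(grid, fold_sum, fold_cnt, candidates)
    G = local_linear_surface(grid, cross_mean, cross_cnt, float(bandwidth))
    G = 0.5 * (G + G.T)

    # noise variance from the diagonal gap on the central half of the domain
    keep = diag_cnt > 0
    diag_mean = diag_sum[keep] / diag_cnt[keep]
    V = local_linear_1d(grid[keep], diag_mean, grid, float(bandwidth), diag_cnt[keep])
    lo_q, hi_q = grid[0] + 0.25 * (grid[-1] - grid[0]), grid[0] + 0.75 * (grid[-1] - grid[0])
    central = (grid >= lo_q) & (grid <= hi_q)
    sigma2 = float(max(0.0, np.mean(V[central] - np.diag(G)[central])))
    return grid, G, sigma2, float(bandwidth)


def eigendecompose(G: np.ndarray, grid: np.ndarray, max_components: int = None):
    """Eigenpairs of the discretized covariance operator.

    The surface is turned into the symmetric matrix ``W^1/2 G W^1/2`` with
    trapezoid quadrature weights ``W``; eigenvalues below a relative floor
    (and all negative ones, which a smoothed surface can produce) are
    discarded.  Eigenfunctions are normalized to unit L2 norm on the grid
    and signed so that their integral is positive (first non-zero
    coordinate positive when the integral vanishes).

    Returns ``(eigenvalues, eigenfunctions)`` with eigenfunctions in
    columns, sorted by decreasing eigenvalue.
    """
    G = np.asarray(G, dtype=float)
    if not np.all(np.isfinite(G)):
        raise ValidationError("covariance surface contains non-finite entries")
    w = _quadrature_weights(grid)
    sw = np.sqrt(w)
    B = sw[:, None] * G * sw[None, :]
    B = 0.5 * (B + B.T)
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    floor = 1e-12 * max(vals.max(), 0.0) if vals.size else 0.0
    keep = vals > max(floor, 0.0)
    vals, vecs = vals[keep], vecs[:, keep]
    if max_components is not None:
        vals, vecs = vals[:max_components], vecs[:, :max_components]
    if vals.size == 0:
        raise DegenerateInputError("covariance surface has no positive eigenvalues")
    phi = vecs / sw[:, None]
    # unit L2 norm (true up to round-off already) and sign convention
    for l in range(phi.shape[1]):
        nrm = np.sqrt(np.trapezoid(phi[:, l] ** 2, grid))
        phi[:, l] /= nrm
        integral = np.trapezoid(phi[:, l], grid)
        if abs(integral) > 1e-10:
            sign = np.sign(integral)
        else:
            nz = phi[np.abs(phi[:, l]) > 1e-12 * np.abs(phi[:, l]).max(), l]
            sign = np.sign(nz[0]) if nz.size else 1.0
        phi[:, l] *= sign
    return vals, phi


def select_n_components(eigenvalues: np.ndarray, threshold: float = 0.92) -> int:
    """Smallest L whose cumulative fraction of variance reaches ``threshold``."""
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size == 0 or np.all(lam <= 0):
        raise DegenerateInputError("all eigenvalues are zero")
    if np.any(lam < 0):
        raise ValidationError("eigenvalues must be non-negative")
    if np.any(np.diff(lam) > 1e-12 * lam[0]):
        raise ValidationError("eigenvalues must be non-increasing")
    fve = np.cumsum(lam) / lam.sum()
    return int(np.searchsorted(fve, threshold - 1e-12) + 1)


def estimate_scores_conditional(
    sample: FunctionalSample,
    model: FPCAModel,
    n_components: int = None,
    ridge: float = 1e-8,
) -> np.ndarray:
    """Conditional-expectation (BLUP) scores for each subject.

    Uses the truncated covariance ``sum_l lambda_l phi_l phi_l^T`` at the
    subject's abscissae plus ``sigma^2 I``; subjects sharing identical
    abscissae share one Cholesky factorization.  If a factorization fails
    (possible when ``sigma^2 = 0`` and the truncated covariance is
    rank-deficient) a ridge of ``ridge x mean diagonal`` is added with a
    warning.
    """
    L = model.n_components if n_components is None else int(n_components)
    lam = model.eigenvalues[:L]
    scores = np.zeros((sample.n_subjects, L))
    groups: dict = {}
    for i, s in enumerate(sample.abscissae):
        groups.setdefault(s.tobytes(), []).append(i)
    for members in groups.values():
        s = sample.abscissae[members[0]]
        Phi = model.eigenfunctions_at(s)[:, :L]
        mu = model.mean_at(s)
        Sigma = (Phi * lam[None, :]) @ Phi.T + model.sigma2 * np.eye(s.size)
        try:
            factor = cho_factor(Sigma, lower=True)
        except np.linalg.LinAlgError:
            warnings.warn("singular score system; adding ridge regularization", stacklevel=2)
            Sigma = Sigma + ridge * max(np.trace(Sigma) / s.size, 1.0) * np.eye(s.size)
            factor = cho_factor(Sigma, lower=True)
        resid = np.column_stack([sample.values[i] - mu for i in members])
        b = cho_solve(factor, resid)  # (K, n_members)
        scores[members, :] = (lam[:, None] * (Phi.T @ b)).T
    return scores


def fit_fpca(sample: FunctionalSample, config: FPCAConfig = None) -> FPCAModel:
    """Full sparse-FPCA fit: mean, covariance, eigenpairs, noise, scores.

    Deterministic given the sample and config; subject order does not
    matter beyond the row order of ``scores``.
    """
    config = config or FPCAConfig()
    grid = _working_grid(sample, config.n_grid)
    grid, mu, mean_bw = estimate_mean(sample, config.mean_bandwidth, grid, config)
    grid, G, sigma2, cov_bw = estimate_covariance(sample, config.cov_bandwidth, grid, mu, config)
    lam, phi = eigendecompose(G, grid, config.max_components)
    fve = np.cumsum(lam) / lam.sum()
    L = select_n_components(lam, config.fve_threshold)
    model = FPCAModel(
        grid=grid,
        mean=mu,
        covariance=G,
        sigma2=sigma2,
        eigenvalues=lam,
        eigenfunctions=phi,
        fve=fve,
        n_selected=L,
        scores=np.zeros((sample.n_subjects, lam.size)),
        ids=sample.ids,
        config=replace(config, mean_bandwidth=mean_bw, cov_bandwidth=cov_bw),
    )
    scores = estimate_scores_conditional(sample, model)
    return replace(model, scores=scores)
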