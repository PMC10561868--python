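"""Spatial entropy decomposition of multitype cell point patterns.

A tissue image is reduced to a marked point pattern: cell centroids with a
categorical phenotype label out of ``J`` types.  Every unordered pair of
cells realises a *co-occurrence* category ``z_r`` (one of ``R = J(J+1)/2``
unordered type pairs) at some inter-cell distance.  Binning pairs by
distance into ranges ``w_k = (d_{k-1}, d_k]`` decomposes the Shannon
entropy of co-occurrences into a spatial and an aspatial part::

    H(Z) = SPI(Z) + H^W(Z)

where ``SPI(Z)`` is the mutual information between pair category and
distance (entropy *due to* space) and ``H^W(Z)`` is the residual entropy
left once distance has been accounted for.  The per-bin profile ``SPI_k``,
read as a function of distance, is the subject-level "SPI curve" consumed
downstream by sparse functional PCA and survival modelling.

Under complete spatial randomness the conditional pair distribution does
not depend on distance and the SPI curve is flat at zero; type-segregated
(clustered) patterns push SPI up at short range.

All entropies are in nats by default (``base`` switches the logarithm).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import cached_property
import numpy as np
from scipy.spatial.distance import pdist

from .exceptions import ConsistencyError, DegenerateInputError, ValidationError

__all__ = [
    "MAX_BINS",
    "CellPattern",
    "DistanceBinning",
    "PairHistogram",
    "SPICurve",
    "PermutationNull",
    "shannon_entropy",
    "enumerate_pair_categories",
    "compute_distance_breaks",
    "bin_pairs",
    "residual_entropy_curve",
    "spi_curve",
    "spi_from_pattern",
    "permutation_null_spi",
    "diversity_baselines",
]

#: Hard cap on the number of distance bins per subject.  More bins than
#: this leave short-range bins with no pairs and undefined entropies.
MAX_BINS = 50

#: Default ratio d_K / d_1 for the log-spaced distance breaks.
DEFAULT_FLOOR_RATIO = 20.0


# ---------------------------------------------------------------------------
# elementary measures


def shannon_entropy(pmf, *, base: float = math.e, atol: float = 1e-8) -> float:
    """Shannon entropy ``sum p log(1/p)`` of a probability vector.

    Zero entries contribute zero (the ``0 log(1/0)`` convention).  The
    result lies in ``[0, log(len(pmf))]``.

    Parameters
    ----------
    pmf : array-like
        Non-negative entries summing to 1 (tolerance ``atol``).
    base : float
        Logarithm base; natural log by default.
    """
    p = np.asarray(pmf, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("pmf must be a non-empty 1-D probability vector")
    if not np.all(np.isfinite(p)):
        raise ValidationError("pmf entries must be finite")
    if np.any(p < 0):
        raise ValidationError("pmf entries must be non-negative")
    total = float(p.sum())
    if abs(total - 1.0) > atol:
        raise ValidationError(f"pmf must sum to 1 within {atol:g}; got {total!r}")
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    if base != math.e:
        h /= math.log(base)
    return max(h, 0.0)


def enumerate_pair_categories(types) -> list[tuple]:
    """Canonically ordered unordered type pairs (the categories of ``Z``).

    ``types`` may be an integer ``J`` (labels become ``t1..tJ``) or a
    sequence of labels.  Returns ``R = J(J+1)/2`` pairs ``(a, b)`` with
    ``a <= b`` in sorted-label order, so the ordering is deterministic.
    """
    if isinstance(types, (int, np.integer)):
        if types < 1:
            raise ValidationError("number of types must be >= 1")
        labels = [f"t{i + 1}" for i in range(int(types))]
    else:
        labels = sorted(set(types))
        if not labels:
            raise ValidationError("empty label set")
    return [(labels[i], labels[j]) for i in range(len(labels)) for j in range(i, len(labels))]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class CellPattern:
    """One subject's cells: planar coordinates plus categorical type labels.

    Parameters
    ----------
    subject_id : str
        Identifier carried through to tidy outputs.
    coords : (n, 2) float array
        Cell centroid positions, conventionally in microns.  The origin and
        orientation are arbitrary: every quantity derived here depends on
        coordinates only through inter-cell distances.
    types : (n,) array of labels
        Per-cell phenotype label.
    labels : tuple, optional
        The declared label set (size ``J``).  Defaults to the sorted set of
        observed labels; declare it explicitly when some type may be absent
        from a particular image.
    """

    subject_id: str
    coords: np.ndarray
    types: np.ndarray
    labels: tuple = None

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        types = np.asarray(self.types)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValidationError("coords must be an (n, 2) array")
        if coords.shape[0] < 2:
            raise ValidationError("a cell pattern needs at least 2 cells")
        if not np.all(np.isfinite(coords)):
            raise ValidationError("coordinates must be finite")
        if types.shape != (coords.shape[0],):
            raise ValidationError("types must be one label per cell")
        labels = self.labels
        if labels is None:
            labels = tuple(sorted(set(types.tolist())))
        else:
            labels = tuple(labels)
            observed = set(types.tolist())
            if not observed.issubset(set(labels)):
                extra = sorted(observed - set(labels))
                raise ValidationError(f"cell types {extra} not in declared label set {labels}")
        if len(labels) < 1:
            raise ValidationError("label set must contain at least one type")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "types", types)
        object.__setattr__(self, "labels", labels)

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    @property
    def n_types(self) -> int:
        """J, the size of the declared label set."""
        return len(self.labels)

    @cached_property
    def type_codes(self) -> np.ndarray:
        """Integer code of each cell's label, in ``labels`` order."""
        index = {lab: i for i, lab in enumerate(self.labels)}
        return np.fromiter((index[t] for t in self.types.tolist()), dtype=np.int64, count=self.n_cells)

    def with_coords(self, coords: np.ndarray) -> "CellPattern":
        """Same cells at new positions (used by rigid-motion checks)."""
        return CellPattern(self.subject_id, coords, self.types, self.labels)


@dataclass(frozen=True)
class DistanceBinning:
    """Distance breaks ``d_0 = 0 < d_1 < ... < d_K`` defining half-open bins.

    Bin ``w_k = (d_{k-1}, d_k]`` is open on the left and closed on the
    right, so pairs at distance exactly ``d_K`` are included and coincident
    pairs (distance 0) never are.
    """

    breaks: np.ndarray

    def __post_init__(self):
        breaks = np.asarray(self.breaks, dtype=float)
        if breaks.ndim != 1 or breaks.size < 2:
            raise ValidationError("breaks must contain at least d_0 and d_1")
        if breaks[0] != 0.0:
            raise ValidationError("d_0 must be 0")
        if not np.all(np.diff(breaks) > 0):
            raise ValidationError("breaks must be strictly increasing")
        if breaks.size - 1 > MAX_BINS:
            raise ValidationError(f"K = {breaks.size - 1} exceeds the K <= {MAX_BINS} rule")
        object.__setattr__(self, "breaks", breaks)

    @property
    def n_bins(self) -> int:
        return self.breaks.size - 1

    @property
    def d_max(self) -> float:
        return float(self.breaks[-1])

    @cached_property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.breaks[:-1] + self.breaks[1:])

    @property
    def intervals(self) -> list[tuple]:
        return list(zip(self.breaks[:-1].tolist(), self.breaks[1:].tolist()))


def _breaks_from_dmax(d_max: float, n_bins: int, d_floor: float) -> np.ndarray:
    """Breaks whose logs decrease linearly from log d_max to log d_floor."""
    if n_bins == 1:
        return np.array([0.0, d_max])
    if not 0 < d_floor < d_max:
        raise ValidationError("d_floor must lie strictly between 0 and d_max")
    rate = math.log(d_max / d_floor) / (n_bins - 1)
    ks = np.arange(1, n_bins + 1)
    interior = d_max * np.exp(-rate * (n_bins - ks))
    breaks = np.concatenate([[0.0], interior])
    breaks[-1] = d_max  # exact, not exp(log(...))
    return breaks


def compute_distance_breaks(
    pattern: CellPattern,
    n_bins: int = MAX_BINS,
    *,
    floor: str = "ratio",
    floor_ratio: float = DEFAULT_FLOOR_RATIO,
) -> DistanceBinning:
    """Log-spaced distance breaks anchored at the median inter-cell distance.

    ``d_K`` is the median of all ``n(n-1)/2`` pairwise Euclidean distances
    (the focus is local cell-to-cell interaction, so the upper half of the
    distance distribution is discarded).  Interior breaks decrease linearly
    from ``d_K`` towards 0 on a log scale, i.e. geometrically, down to a
    floor ``d_1``:

    - ``floor="ratio"`` (default): ``d_1 = d_K / floor_ratio``, giving
      breaks that span a fixed number of decades regardless of how close
      the two nearest cells happen to be.  This keeps the shortest bins
      populated with enough pairs for the conditional pair distribution to
      be estimable.
    - ``floor="min-distance"``: ``d_1`` equals the smallest positive
      inter-cell distance, so the first bin captures exactly the nearest
      pair(s).  Short-range bins then hold very few pairs and their SPI
      values are noisy; offered for sensitivity analysis.

    Raises
    ------
    ValidationError
        If ``n_bins`` violates the ``K <= 50`` rule.
    DegenerateInputError
        If all cells are coincident (median distance 0).
    """
    if not 1 <= n_bins <= MAX_BINS:
        raise ValidationError(f"n_bins must satisfy 1 <= K <= {MAX_BINS} (got {n_bins})")
    d = pdist(pattern.coords)
    d_max = float(np.median(d))
    if d_max <= 0:
        raise DegenerateInputError("median inter-cell distance is 0 (all cells coincident)")
    if n_bins == 1:
        return DistanceBinning(np.array([0.0, d_max]))
    if floor == "ratio":
        if floor_ratio <= 1:
            raise ValidationError("floor_ratio must exceed 1")
        d_floor = d_max / floor_ratio
    elif floor == "min-distance":
        positive = d[d > 0]
        d_floor = float(positive.min())
        if d_floor >= d_max:  # fewer than 2 distinct distances below the median
            d_floor = d_max / DEFAULT_FLOOR_RATIO
    else:
        raise ValidationError(f"unknown floor rule {floor!r}")
    return DistanceBinning(_breaks_from_dmax(d_max, n_bins, d_floor))


@dataclass(frozen=True)
class PairHistogram:
    """Counts ``N[r, k]`` of unordered cell pairs by category and distance bin.

    Derived probability mass functions are exposed as properties; all are
    computed from pairs at distance in ``(0, d_K]`` only, which makes the
    marginal consistency ``p(z_r) = sum_k p(z_r, w_k)`` exact and the
    entropy decomposition additive.
    """

    counts: np.ndarray
    binning: DistanceBinning
    pair_categories: tuple
    labels: tuple

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be an (R, K) matrix")
        if counts.shape != (len(self.pair_categories), self.binning.n_bins):
            raise ValidationError(
                f"counts shape {counts.shape} inconsistent with R={len(self.pair_categories)}, "
                f"K={self.binning.n_bins}"
            )
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            raise ValidationError("counts must be non-negative integers")
        if counts.sum() == 0:
            raise DegenerateInputError("histogram contains no pairs")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "pair_categories", tuple(self.pair_categories))
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n_categories(self) -> int:
        return len(self.pair_categories)

    @property
    def n_bins(self) -> int:
        return self.binning.n_bins

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())

    @cached_property
    def bin_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @cached_property
    def p_joint(self) -> np.ndarray:
        """Joint pmf p(z_r, w_k)."""
        return self.counts / self.n_pairs

    @cached_property
    def p_w(self) -> np.ndarray:
        """Marginal pmf p(w_k) over distance bins."""
        return self.bin_totals / self.n_pairs

    @cached_property
    def p_z(self) -> np.ndarray:
        """Marginal pmf p(z_r) over co-occurrence categories."""
        return self.counts.sum(axis=1) / self.n_pairs

    @cached_property
    def p_z_given_w(self) -> np.ndarray:
        """Conditional pmf p(z_r | w_k); NaN columns for empty bins."""
        totals = self.bin_totals.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            q = self.counts / totals[None, :]
        q[:, totals == 0] = np.nan
        return q

    @property
    def empty_bins(self) -> np.ndarray:
        return self.bin_totals == 0


def bin_pairs(pattern: CellPattern, binning: DistanceBinning) -> PairHistogram:
    """Tabulate unordered cell pairs by type pair and distance bin.

    Each pair with distance in ``(0, d_K]`` increments exactly one cell of
    the ``(R, K)`` count matrix; pairs beyond ``d_K`` are excluded, and
    coincident pairs (distance exactly 0) are excluded with a warning.
    """
    n = pattern.n_cells
    d = pdist(pattern.coords)
    ii, jj = np.triu_indices(n, 1)  # same ordering as pdist
    codes = pattern.type_codes

    pairs = enumerate_pair_categories(pattern.labels)
    J = pattern.n_types
    pair_index = np.empty((J, J), dtype=np.int64)
    r = 0
    for a in range(J):
        for b in range(a, J):
            pair_index[a, b] = pair_index[b, a] = r
            r += 1

    n_zero = int(np.count_nonzero(d <= 0))
    if n_zero:
        warnings.warn(
            f"{n_zero} cell pair(s) at distance 0 (duplicate coordinates) excluded from all bins",
            stacklevel=2,
        )
    keep = (d > 0) & (d <= binning.d_max)
    if not np.any(keep):
        raise DegenerateInputError("no cell pairs with distance in (0, d_K]")
    k = np.searchsorted(binning.breaks, d[keep], side="left") - 1
    cat = pair_index[codes[ii[keep]], codes[jj[keep]]]
    K = binning.n_bins
    counts = np.bincount(cat * K + k, minlength=len(pairs) * K).reshape(len(pairs), K)
    return PairHistogram(counts=counts, binning=binning, pair_categories=tuple(pairs), labels=pattern.labels)


# ---------------------------------------------------------------------------
# decomposition


def _decompose_counts(counts: np.ndarray, base: float = math.e):
    """SPI_k, H_k^W and totals from an (R, K) count matrix.

    Empty bins yield NaN per-bin values and drop out of the weighted totals
    (their weight p(w_k) is zero).  Returns a dict of arrays/floats.
    """
    total = counts.sum()
    totals_k = counts.sum(axis=0).astype(float)
    p_w = totals_k / total
    p_z = counts.sum(axis=1) / total

    with np.errstate(invalid="ignore", divide="ignore"):
        q = counts / totals_k[None, :]
    nonempty = totals_k > 0
    if np.any((counts > 0) & (p_z == 0)[:, None]):
        raise ConsistencyError("category with zero marginal but positive conditional probability")

    logq = np.where(counts > 0, np.log(np.where(counts > 0, q, 1.0)), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        logpz = np.where(p_z > 0, np.log(np.where(p_z > 0, p_z, 1.0)), 0.0)
    qsafe = np.where(counts > 0, q, 0.0)

    residual = -(qsafe * logq).sum(axis=0)
    spi = (qsafe * (logq - logpz[:, None])).sum(axis=0)
    residual[~nonempty] = np.nan
    spi[~nonempty] = np.nan
    # KL divergence: clip the tiny negative values floating summation can leave
    spi[nonempty] = np.maximum(spi[nonempty], 0.0)

    spi_total = float(np.dot(p_w[nonempty], spi[nonempty]))
    residual_total = float(np.dot(p_w[nonempty], residual[nonempty]))
    h_total = shannon_entropy(p_z)
    if base != math.e:
        scale = math.log(base)
        spi, residual = spi / scale, residual / scale
        spi_total, residual_total, h_total = (v / scale for v in (spi_total, residual_total, h_total))
    return {
        "spi": spi,
        "residual": residual,
        "spatial_information": spi_total,
        "residual_entropy": residual_total,
        "total_entropy": h_total,
        "bin_totals": counts.sum(axis=0),
    }


@dataclass(frozen=True)
class SPICurve:
    """Per-bin spatial information and residual entropy, plus totals.

    ``spi[k]`` is the Kullback-Leibler divergence of the conditional pair
    distribution in bin ``w_k`` from the marginal pair distribution;
    ``residual[k]`` is the Shannon entropy of the conditional distribution.
    Bins with no pairs carry NaN ("missing", not zero) and are simply
    absent from the subject's functional sample downstream.
    """

    binning: DistanceBinning
    n_pairs: np.ndarray
    spi: np.ndarray
    residual: np.ndarray
    total_entropy: float
    spatial_information: float
    residual_entropy: float
    labels: tuple

    @property
    def midpoints(self) -> np.ndarray:
        return self.binning.midpoints

    @property
    def empty_bins(self) -> np.ndarray:
        return self.n_pairs == 0

    @property
    def n_types(self) -> int:
        return len(self.labels)

    @property
    def n_categories(self) -> int:
        J = self.n_types
        return J * (J + 1) // 2

    def observed(self) -> tuple[np.ndarray, np.ndarray]:
        """(midpoints, spi) restricted to non-empty bins."""
        m = ~self.empty_bins
        return self.midpoints[m], self.spi[m]

    def to_frame(self, subject_id: str = None):
        import pandas as pd

        b = self.binning.breaks
        return pd.DataFrame(
            {
                "subject_id": subject_id,
                "k": np.arange(1, self.binning.n_bins + 1),
                "d_lo": b[:-1],
                "d_hi": b[1:],
                "midpoint": self.midpoints,
                "n_pairs": self.n_pairs,
                "spi": self.spi,
                "residual_entropy": self.residual,
            }
        )

    def totals_dict(self) -> dict:
        return {
            "H": self.total_entropy,
            "SPI": self.spatial_information,
            "HW": self.residual_entropy,
            "J": self.n_types,
            "R": self.n_categories,
            "K": self.binning.n_bins,
        }


def residual_entropy_curve(hist: PairHistogram, *, base: float = math.e) -> np.ndarray:
    """Per-bin residual entropy ``H_k^W``; NaN for empty bins."""
    return _decompose_counts(hist.counts, base=base)["residual"]


def spi_curve(hist: PairHistogram, *, base: float = math.e) -> SPICurve:
    """Decompose a pair histogram into SPI and residual entropy curves.

    The totals satisfy ``H(Z) = SPI(Z) + H^W(Z)`` to numerical precision,
    with ``SPI(Z) = sum_k p(w_k) SPI_k`` and ``H^W(Z) = sum_k p(w_k) H_k^W``.
    """
    parts = _decompose_counts(hist.counts, base=base)
    return SPICurve(
        binning=hist.binning,
        n_pairs=parts["bin_totals"],
        spi=parts["spi"],
        residual=parts["residual"],
        total_entropy=parts["total_entropy"],
        spatial_information=parts["spatial_information"],
        residual_entropy=parts["residual_entropy"],
        labels=hist.labels,
    )


def spi_from_pattern(
    pattern: CellPattern,
    n_bins: int = MAX_BINS,
    *,
    floor: str = "ratio",
    floor_ratio: float = DEFAULT_FLOOR_RATIO,
    base: float = math.e,
) -> SPICurve:
    """Convenience: breaks -> histogram -> SPI curve for one pattern."""
    binning = compute_distance_breaks(pattern, n_bins, floor=floor, floor_ratio=floor_ratio)
    return spi_curve(bin_pairs(pattern, binning), base=base)


# ---------------------------------------------------------------------------
# permutation null and aspatial baselines


@dataclass(frozen=True)
class PermutationNull:
    """Label-permutation reference distribution of the SPI curve."""

    binning: DistanceBinning
    observed: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    curves: np.ndarray  # (n_perm, K)
    quantiles: tuple


def permutation_null_spi(
    pattern: CellPattern,
    n_bins: int = MAX_BINS,
    n_perm: int = 199,
    seed=None,
    *,
    quantiles: tuple = (0.025, 0.975),
    floor: str = "ratio",
    floor_ratio: float = DEFAULT_FLOOR_RATIO,
) -> PermutationNull:
    """SPI curve null obtained by permuting cell labels over fixed positions.

    Coordinates (hence distances, breaks and bin assignments) stay fixed;
    only the type labels are shuffled, which preserves the type frequency
    table and therefore the aspatial entropy while destroying any
    label-space association.  Returns the pointwise mean and the requested
    quantile envelope over ``n_perm`` permutations.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    binning = compute_distance_breaks(pattern, n_bins, floor=floor, floor_ratio=floor_ratio)
    hist = bin_pairs(pattern, binning)
    observed = _decompose_counts(hist.counts)["spi"]

    # pre-resolve pair membership and bin assignment once
    n = pattern.n_cells
    d = pdist(pattern.coords)
    ii, jj = np.triu_indices(n, 1)
    keep = (d > 0) & (d <= binning.d_max)
    k = np.searchsorted(binning.breaks, d[keep], side="left") - 1
    ii, jj = ii[keep], jj[keep]
    J = pattern.n_types
    R = J * (J + 1) // 2
    pair_index = np.empty((J, J), dtype=np.int64)
    r = 0
    for a in range(J):
        for b in range(a, J):
            pair_index[a, b] = pair_index[b, a] = r
            r += 1
    K = binning.n_bins
    codes = pattern.type_codes

    curves = np.empty((n_perm, K))
    for p in range(n_perm):
        perm = rng.permutation(codes)
        cat = pair_index[perm[ii], perm[jj]]
        counts = np.bincount(cat * K + k, minlength=R * K).reshape(R, K)
        curves[p] = _decompose_counts(counts)["spi"]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN (empty) bins
        mean = np.nanmean(curves, axis=0)
        lower = np.nanquantile(curves, quantiles[0], axis=0)
        upper = np.nanquantile(curves, quantiles[1], axis=0)
    return PermutationNull(
        binning=binning,
        observed=observed,
        mean=mean,
        lower=lower,
        upper=upper,
        curves=curves,
        quantiles=tuple(quantiles),
    )


def diversity_baselines(pattern: CellPattern, *, base: float = math.e) -> dict:
    """Aspatial Shannon and Simpson diversity of the type frequencies.

    These depend only on the per-type cell counts, not on where cells sit,
    and so cannot separate spatial configurations — the limitation the SPI
    decomposition addresses.  Simpson is returned as ``1 - sum p_j^2``.
    """
    counts = np.bincount(pattern.type_codes, minlength=pattern.n_types).astype(float)
    p = counts / counts.sum()
    return {
        "shannon": shannon_entropy(p, base=base),
        "simpson": float(1.0 - np.sum(p**2)),
    }
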