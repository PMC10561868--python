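"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (pure-Python nested loops,
dictionary bookkeeping) so they share no code path with the package.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np
import pytest

from spatent import CellPattern


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_csr_pattern(rng, n=60, n_types=3, subject_id="t", side=1.0):
    """Uniform pattern on a square window with roughly equal type counts."""
    coords = rng.uniform(0, side, size=(n, 2))
    labels = [chr(ord("A") + j) for j in range(n_types)]
    types = np.array([labels[i % n_types] for i in range(n)])
    return CellPattern(subject_id, coords, types, tuple(labels))


# ---------------------------------------------------------------------------
# brute-force spatial-entropy oracle


def _dist(a, b):
    # plain sqrt(dx^2 + dy^2); math.dist rescales internally and can differ
    # in the last ulp, which matters for pairs sitting exactly on a break
    return math.sqrt((a[0] - b[0]) ** 2 + (a[1] - b[1]) ** 2)


def brute_force_median(coords):
    d = []
    n = len(coords)
    for i in range(n):
        for j in range(i + 1, n):
            d.append(_dist(coords[i], coords[j]))
    d.sort()
    m = len(d)
    return d[m // 2] if m % 2 else 0.5 * (d[m // 2 - 1] + d[m // 2])


def brute_force_counts(coords, types, breaks):
    """(pair, bin) -> count via exhaustive pair enumeration."""
    counts = defaultdict(int)
    n = len(coords)
    K = len(breaks) - 1
    for i in range(n):
        for j in range(i + 1, n):
            d = _dist(coords[i], coords[j])
            if d <= 0 or d > breaks[-1]:
                continue
            for k in range(K):
                if breaks[k] < d <= breaks[k + 1]:
                    pair = tuple(sorted((types[i], types[j])))
                    counts[(pair, k)] += 1
                    break
    return counts


def brute_force_spi(coords, types, breaks, labels):
    """Straight-line re-implementation of the SPI decomposition.

    Returns (spi per bin with NaN for empty, residual per bin, H, SPI, HW).
    """
    counts = brute_force_counts(coords, types, breaks)
    K = len(breaks) - 1
    total = sum(counts.values())
    pairs = [(a, b) for ai, a in enumerate(labels) for b in labels[ai:]]
    p_z = {p: sum(c for (pp, _), c in counts.items() if pp == p) / total for p in pairs}
    spi = np.full(K, np.nan)
    resid = np.full(K, np.nan)
    H = -sum(v * math.log(v) for v in p_z.values() if v > 0)
    spi_total = 0.0
    resid_total = 0.0
    for k in range(K):
        n_k = sum(c for (_, kk), c in counts.items() if kk == k)
        if n_k == 0:
            continue
        s = r = 0.0
        for p in pairs:
            c = counts.get((p, k), 0)
            if c == 0:
                continue
            q = c / n_k
            s += q * math.log(q / p_z[p])
            r -= q * math.log(q)
        spi[k], resid[k] = s, r
        w = n_k / total
        spi_total += w * s
        resid_total += w * r
    return spi, resid, H, spi_total, resid_total


# ---------------------------------------------------------------------------
# synthetic functional cohorts


def sine_cohort(n_subjects, seed, *, sparse=True, noise_sd=0.2, exact_variance=True,
                eigenvalues=(4.0, 1.0), n_grid=51):
    """Curves from a low-rank functional model on [0, 1].

    mean 1 + 2s; orthonormal eigenfunctions sqrt(2) sin(pi s) and
    sqrt(2) cos(pi s) (at most two).  With ``exact_variance`` the drawn
    scores are standardized so their sample variance equals the nominal
    eigenvalues, making the recovery target exact rather than a sampled
    quantity.  Returns (ids, abscissae, values, truth-dict).
    """
    assert len(eigenvalues) <= 2
    rng = np.random.default_rng(seed)
    phi = (
        lambda s: np.sqrt(2) * np.sin(np.pi * s),
        lambda s: np.sqrt(2) * np.cos(np.pi * s),
    )[: len(eigenvalues)]
    xi = np.column_stack([rng.normal(0.0, np.sqrt(lam), n_subjects) for lam in eigenvalues])
    if exact_variance:
        # make the cohort's sample moments equal the population model
        # exactly: mean 0, uncorrelated scores, variance = eigenvalue
        Q, _ = np.linalg.qr(xi - xi.mean(axis=0))
        xi = Q * np.sqrt(n_subjects * np.asarray(eigenvalues))
    ids, absc, vals = [], [], []
    for i in range(n_subjects):
        if sparse:
            K = int(rng.integers(5, 51))
            s = np.sort(rng.uniform(0.0, 1.0, K))
        else:
            s = np.linspace(0.0, 1.0, n_grid)
        y = 1 + 2 * s + sum(xi[i, l] * phi[l](s) for l in range(len(eigenvalues)))
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, s.size)
        ids.append(f"s{i}")
        absc.append(s)
        vals.append(y)
    truth = {"eigenvalues": np.asarray(eigenvalues), "phi": phi, "scores": xi,
             "mean": lambda s: 1 + 2 * s, "noise_sd": noise_sd}
    return tuple(ids), tuple(absc), tuple(vals), truth
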