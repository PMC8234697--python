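"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the code paths they check: windowed statistics
are computed by explicitly materializing every circular-window shift,
convolution by direct kernel sampling, and the exact tests by exhaustive
enumeration of their null distributions.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy import stats


def phansalkar_oracle(
    pixels: np.ndarray,
    radius: int,
    k: float = 0.25,
    r_norm: float = 0.5,
    p: float = 2.0,
    q: float = 10.0,
) -> np.ndarray:
    """Per-pixel Phansalkar threshold via an explicit circular window.

    Boundaries are handled by reflection with edge duplication
    (``np.pad(mode="symmetric")``); sigma is the population standard
    deviation over the window.
    """
    h, w = pixels.shape
    padded = np.pad(pixels, radius, mode="symmetric")
    shifts = []
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            if dy * dy + dx * dx <= radius * radius:
                shifts.append(padded[radius + dy : radius + dy + h, radius + dx : radius + dx + w])
    stack = np.stack(shifts)
    mu = stack.mean(axis=0)
    sigma = stack.std(axis=0)  # population std
    return mu * (1.0 + p * np.exp(-q * mu) + k * (sigma / r_norm - 1.0))


def gaussian_blur_oracle(pixels: np.ndarray, sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Direct 2-D convolution with an explicitly sampled truncated kernel."""
    radius = int(truncate * sigma + 0.5)
    ax = np.arange(-radius, radius + 1, dtype=float)
    k1 = np.exp(-0.5 * (ax / sigma) ** 2)
    k1 /= k1.sum()
    kernel = np.outer(k1, k1)
    h, w = pixels.shape
    padded = np.pad(pixels, radius, mode="symmetric")
    out = np.zeros_like(pixels, dtype=float)
    for i, dy in enumerate(range(-radius, radius + 1)):
        for j, dx in enumerate(range(-radius, radius + 1)):
            out += kernel[i, j] * padded[radius + dy : radius + dy + h, radius + dx : radius + dx + w]
    return out


def fisher_enumeration_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by summing hypergeometric point probabilities.

    Minimum-likelihood rule: include every table with the observed
    margins whose point probability is at most the observed one
    (small relative slack absorbs float rounding of equal pmfs).
    """
    n_total = a + b + c + d
    row1, col1 = a + b, a + c
    lo = max(0, row1 + col1 - n_total)
    hi = min(row1, col1)
    dist = stats.hypergeom(n_total, col1, row1)
    pmf = dist.pmf(np.arange(lo, hi + 1))
    observed = dist.pmf(a)
    return float(pmf[pmf <= observed * (1 + 1e-12)].sum())


def mann_whitney_enumeration_oracle(x, y) -> float:
    """Two-sided Mann-Whitney p by enumerating all rank splits.

    Valid for small untied samples: enumerates every assignment of the
    pooled ranks to the first sample and counts U statistics at least as
    extreme (two-sided, doubling the smaller tail, capped at 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    assert np.unique(pooled).size == pooled.size, "oracle requires untied data"
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    u_all = []
    for combo in combinations(range(nx + ny), nx):
        r = ranks[list(combo)].sum() - nx * (nx + 1) / 2
        u_all.append(r)
    u_all = np.asarray(u_all)
    mean_u = nx * ny / 2
    dist_obs = abs(u_obs - mean_u)
    p = np.mean(np.abs(u_all - mean_u) >= dist_obs - 1e-12)
    return float(min(1.0, p))
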