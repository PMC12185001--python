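"""Shared fixtures and independent oracles for the test suite.

Oracles here are deliberately naive (exact rational arithmetic, flood fill,
full enumeration, textbook formulas) and never call the code paths they
check.
"""

from __future__ import annotations

import math
from collections import deque
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from periquant import SceneSpec, SegmentedObjects


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def otsu_brute_force(counts, values) -> float:
    """Exhaustive between-class-variance maximization in exact arithmetic.

    sigma_b^2(k) = w0 * w1 * (mu0 - mu1)^2 over all cuts k; lowest
    maximizing cut wins; returns the bin value at the cut.
    """
    counts = [int(c) for c in counts]
    vals = [Fraction(float(v)) for v in values]
    total = sum(counts)
    total_mass = sum(c * v for c, v in zip(counts, vals))
    best_score, best_k = None, None
    n0 = 0
    mass0 = Fraction(0)
    for k in range(len(counts) - 1):
        n0 += counts[k]
        mass0 += counts[k] * vals[k]
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            continue
        w0 = Fraction(n0, total)
        w1 = Fraction(n1, total)
        mu0 = mass0 / n0
        mu1 = (total_mass - mass0) / n1
        score = w0 * w1 * (mu0 - mu1) ** 2
        if best_score is None or score > best_score:
            best_score, best_k = score, k
    return float(values[best_k])


def flood_fill_label(binary: np.ndarray, connectivity: int = 8):
    """BFS connected-component oracle -> (object count, sorted areas,
    set of frozen pixel sets)."""
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    h, w = binary.shape
    seen = np.zeros_like(binary, dtype=bool)
    components = []
    fg = np.argwhere(binary)
    for r0, c0 in fg:
        if seen[r0, c0]:
            continue
        comp = []
        q = deque([(r0, c0)])
        seen[r0, c0] = True
        while q:
            r, c = q.popleft()
            comp.append((r, c))
            for dr, dc in nbrs:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and binary[rr, cc] and not seen[rr, cc]:
                    seen[rr, cc] = True
                    q.append((rr, cc))
        components.append(frozenset(comp))
    areas = sorted(len(c) for c in components)
    return len(components), areas, set(components)


def all_pairs_nn(gfp_centroids: np.ndarray, cd_centroids: np.ndarray):
    """Naive O(n*m) nearest-neighbor scan -> (distances, argmin indices)."""
    dists = np.empty(len(gfp_centroids))
    idx = np.empty(len(gfp_centroids), dtype=int)
    for i, (gr, gc) in enumerate(gfp_centroids):
        best_d, best_j = np.inf, -1
        for j, (cr, cc) in enumerate(cd_centroids):
            d = np.sqrt((gr - cr) ** 2 + (gc - cc) ** 2)
            if d < best_d:
                best_d, best_j = d, j
        dists[i], idx[i] = best_d, best_j
    return dists, idx


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Full hypergeometric enumeration of the two-sided exact p-value.

    With margins fixed, tables are indexed by the top-left cell x; the
    p-value sums P(x) over all tables whose point probability does not
    exceed the observed one (relative tie tolerance 1e-7).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def prob(x: int) -> Fraction:
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), denom)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    cutoff = p_obs * (1 + Fraction(1, 10**7))
    return float(sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= cutoff))


def pooled_t_oracle(x: np.ndarray, y: np.ndarray):
    """Textbook pooled-variance Student t statistic and df."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    return t, nx + ny - 2


def ols_normal_equations(x: np.ndarray, y: np.ndarray):
    """Closed-form OLS slope/intercept/R^2 from the normal equations."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sxx = (x**2).sum() - x.sum() ** 2 / n
    sxy = (x * y).sum() - x.sum() * y.sum() / n
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / ss_tot
    return slope, intercept, r2


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251002)


@pytest.fixture
def small_scene_spec() -> SceneSpec:
    """Quick-to-render field used by most segmentation-level tests."""
    return SceneSpec(
        height_px=128, width_px=128, n_vessels=6, n_gfp=25, n_nuclei=40,
        coupling_scale_px=4.0, min_separation=True, seed=11,
    )


def make_objects(centroids, areas=None, channel="GFP", image_id="img") -> SegmentedObjects:
    """Hand-built SegmentedObjects from centroid coordinates."""
    centroids = np.asarray(centroids, dtype=float)
    n = len(centroids)
    table = pd.DataFrame(
        {
            "object_id": np.arange(1, n + 1),
            "area_px": np.asarray(areas, int) if areas is not None else np.full(n, 9),
            "centroid_row": centroids[:, 0],
            "centroid_col": centroids[:, 1],
        }
    )
    return SegmentedObjects(
        channel=channel, labels=np.zeros((1, 1), np.int32), table=table,
        threshold_used=float("nan"), image_id=image_id,
    )
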