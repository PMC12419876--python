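"""Shared fixtures and independent numerical oracles.

The oracles here deliberately avoid the package's closed-form paths: the
section-property oracle rasterises each region on a dense grid and sums
pixel contributions, and the rank-sum oracle enumerates every assignment
of ranks to the smaller sample.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from abscission import MorphParams
from abscission.section_geometry import (
    POROUS_DISC,
    RECTANGLE,
    SEMI_ELLIPSE,
    SectionRegion,
)


@pytest.fixture
def measured_params() -> MorphParams:
    """Population-mean morphology (the packaged defaults)."""
    return MorphParams()


def region_mask(region: SectionRegion, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pixel membership (density-weighted) of a region on grid (X, Y)."""
    d = region.dims
    if region.shape == POROUS_DISC:
        return d["k"] * ((X - region.centroid_x) ** 2 + Y**2 <= d["c"] ** 2)
    if region.shape == RECTANGLE:
        return 1.0 * (
            (np.abs(X - region.centroid_x) <= d["d"] / 2.0)
            & (np.abs(Y) <= d["b"] / 2.0)
        )
    if region.shape == SEMI_ELLIPSE:
        a, b, bulge = d["a"], d["b"], d.get("bulge", -1.0)
        flat_x = region.centroid_x - bulge * 4.0 * a / (3.0 * math.pi)
        u = bulge * (X - flat_x)
        return 1.0 * ((u >= 0) & ((u / a) ** 2 + (Y / b) ** 2 <= 1.0))
    raise ValueError(region.shape)


def grid_section_props(
    regions, about_x: float = 0.0, n: int = 1201
) -> tuple[float, float, float]:
    """Brute-force (weighted area, weighted centroid x, weighted I about
    ``about_x``) by midpoint-rule integration over a shared bounding box."""
    xs_lo, xs_hi, ys_hi = [], [], []
    for g in regions:
        d = g.dims
        if g.shape == POROUS_DISC:
            half_x = half_y = d["c"]
        elif g.shape == RECTANGLE:
            half_x, half_y = d["d"] / 2.0, d["b"] / 2.0
        else:
            bulge = d.get("bulge", -1.0)
            flat_x = g.centroid_x - bulge * 4.0 * d["a"] / (3.0 * math.pi)
            lo = min(flat_x, flat_x + bulge * d["a"]) - g.centroid_x
            hi = max(flat_x, flat_x + bulge * d["a"]) - g.centroid_x
            xs_lo.append(g.centroid_x + lo)
            xs_hi.append(g.centroid_x + hi)
            ys_hi.append(d["b"])
            continue
        xs_lo.append(g.centroid_x - half_x)
        xs_hi.append(g.centroid_x + half_x)
        ys_hi.append(half_y)
    x_lo, x_hi = min(xs_lo), max(xs_hi)
    y_hi = max(ys_hi)
    x = np.linspace(x_lo, x_hi, n)
    y = np.linspace(-y_hi, y_hi, n)
    dx = (x[1] - x[0]) * (y[1] - y[0])
    X, Y = np.meshgrid(x, y, sparse=True)
    area = cx = I = 0.0
    for g in regions:
        dens = g.weight * region_mask(g, X, Y)
        a = float(dens.sum()) * dx
        area += a
        cx += float((dens * X).sum()) * dx
        I += float((dens * (X - about_x) ** 2).sum()) * dx
    return area, cx / area, I


def exact_ranksum(x, y) -> tuple[float, float]:
    """Full-enumeration Wilcoxon rank-sum: (rank sum of x, two-sided p).

    Valid only for tie-free data; enumerates all C(nx+ny, nx) rank splits.
    """
    x, y = list(x), list(y)
    nx, N = len(x), len(x) + len(y)
    ranks = {v: i + 1 for i, v in enumerate(sorted(x + y))}
    w_obs = sum(ranks[v] for v in x)
    dist = np.array(
        [sum(comb) for comb in itertools.combinations(range(1, N + 1), nx)]
    )
    p_lo = np.mean(dist <= w_obs)
    p_hi = np.mean(dist >= w_obs)
    return float(w_obs), float(min(1.0, 2.0 * min(p_lo, p_hi)))


def random_region(rng: np.random.Generator) -> SectionRegion:
    """A random primitive region with dimensions spanning ~two decades."""
    shape = rng.choice([POROUS_DISC, RECTANGLE, SEMI_ELLIPSE])
    cx = float(rng.uniform(-50, 50))
    if shape == POROUS_DISC:
        return SectionRegion(
            POROUS_DISC,
            {"c": float(rng.uniform(2, 60)), "k": float(rng.uniform(0.1, 1.0))},
            centroid_x=0.0,
        )
    if shape == RECTANGLE:
        return SectionRegion(
            RECTANGLE,
            {"d": float(rng.uniform(2, 80)), "b": float(rng.uniform(2, 120))},
            centroid_x=cx,
            weight=float(rng.uniform(0.05, 1.0)),
        )
    return SectionRegion(
        SEMI_ELLIPSE,
        {
            "a": float(rng.uniform(2, 80)),
            "b": float(rng.uniform(2, 120)),
            "bulge": float(rng.choice([-1.0, 1.0])),
        },
        centroid_x=cx,
        weight=float(rng.uniform(0.05, 1.0)),
    )
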