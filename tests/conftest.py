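"""Shared fixtures and independent oracles used across the test modules."""

from __future__ import annotations

import numpy as np
import pytest

from snadlab import AssayCondition, AssaySeries


@pytest.fixture
def rng():
    return np.random.default_rng(20140204)


def make_linear_series(
    slope_per_h: float = -10.0,
    intercept: float = 200.0,
    species: str = "TAN",
    n: int = 7,
    dt_min: float = 30.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    condition: AssayCondition | None = None,
) -> AssaySeries:
    """A single-species bottle lying exactly (or noisily) on a line."""
    t = np.arange(n) * dt_min
    c = intercept + slope_per_h / 60.0 * t
    if noise_sd > 0:
        c = c + np.random.default_rng(seed).normal(0, noise_sd, size=n)
    c = np.clip(c, 0, None)
    return AssaySeries(
        times=t,
        concentrations={species: c},
        condition=condition or AssayCondition(),
    )


def ols_normal_equations(t, c):
    """Independent OLS oracle: slope, slope stderr and r^2 via the
    normal equations, coded without scipy."""
    t = np.asarray(t, float)
    c = np.asarray(c, float)
    n = len(t)
    tbar, cbar = t.mean(), c.mean()
    sxx = ((t - tbar) ** 2).sum()
    sxy = ((t - tbar) * (c - cbar)).sum()
    slope = sxy / sxx
    intercept = cbar - slope * tbar
    resid = c - intercept - slope * t
    dof = n - 2
    s2 = (resid**2).sum() / dof if dof > 0 else 0.0
    stderr = np.sqrt(s2 / sxx)
    sst = ((c - cbar) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / sst if sst > 0 else 1.0
    return slope, stderr, r2


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """Random additive distance matrix built by independent agglomeration.

    Grows a random binary tree by repeatedly joining two active clusters
    with fresh positive branch lengths, accumulating leaf-to-leaf path
    lengths directly; never touches the package's tree code.
    Returns (leaf names, distance matrix ndarray).
    """
    names = [f"L{i}" for i in range(n_leaves)]
    d = np.zeros((n_leaves, n_leaves))
    clusters = [[i] for i in range(n_leaves)]
    depth = {i: 0.0 for i in range(n_leaves)}  # leaf -> distance to cluster root
    while len(clusters) > 1:
        ia, ib = sorted(rng.choice(len(clusters), size=2, replace=False))
        a, b = clusters[ia], clusters[ib]
        la, lb = rng.uniform(0.05, 1.0, size=2)
        for x in a:
            depth[x] += la
        for y in b:
            depth[y] += lb
        for x in a:
            for y in b:
                d[x, y] = d[y, x] = depth[x] + depth[y]
        clusters = [c for k, c in enumerate(clusters) if k not in (ia, ib)] + [a + b]
    return names, d
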