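"""Latent-trait simulation: the test bed for every diagnostic.

Items are defined by their step response functions P(X >= s | theta).  The
available kinds:

``logistic``
    Graded-response style cumulative logistic steps with ordered
    thresholds; equal-discrimination sets have non-intersecting response
    functions (satisfying double monotonicity), unequal discriminations
    produce crossings.
``step``
    Deterministic threshold functions of theta (probabilistic Guttman
    responses when thresholds differ).
``unimodal``
    A deliberately nonmonotone (rise-then-fall) binary response function,
    used to plant monotonicity violations.
``table``
    Step probabilities constant in theta (e.g. mutually independent items
    with fixed endorsement probabilities).

Respondents draw theta from a standard normal by default; category
responses are then drawn independently given theta, so local independence
holds by construction.  A seed fully determines the output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .data import DataError, ItemResponseMatrix

__all__ = [
    "ItemModel",
    "SyntheticConfig",
    "generate",
    "generate_blocks",
    "generate_guttman",
    "inject_crossing_pair",
    "inject_unimodal_item",
    "population_scalability",
    "equal_discrimination_binary",
    "constant_binary",
    "graded_items",
]


@dataclass(frozen=True)
class ItemModel:
    """Response-function specification for one item.

    locations : per-step thresholds (ascending); one per category boundary.
    discrimination : slope (logistic) or concentration (unimodal); >= 0.
    probs : per-step constant probabilities (``table`` kind only).
    peak : maximum endorsement probability (``unimodal`` kind only).
    """

    kind: str = "logistic"
    locations: tuple = (0.0,)
    discrimination: float = 1.0
    probs: tuple = ()
    peak: float = 0.9

    def __post_init__(self) -> None:
        if self.kind not in {"logistic", "step", "unimodal", "table"}:
            raise DataError(f"unknown item kind {self.kind!r}")
        if self.discrimination < 0:
            raise DataError("discrimination must be >= 0")
        locs = tuple(float(x) for x in self.locations)
        object.__setattr__(self, "locations", locs)
        if self.kind in {"logistic", "step"} and list(locs) != sorted(locs):
            raise DataError("step locations must be ascending")
        if self.kind == "table":
            pr = tuple(float(x) for x in self.probs)
            if not pr:
                raise DataError("table kind requires step probabilities")
            if any(not 0 <= x <= 1 for x in pr):
                raise DataError("table probabilities must lie in [0, 1]")
            if list(pr) != sorted(pr, reverse=True):
                raise DataError("table step probabilities must be nonincreasing")
            object.__setattr__(self, "probs", pr)
        if self.kind == "unimodal":
            if not 0 < self.peak <= 1:
                raise DataError("unimodal peak must be in (0, 1]")
            if len(locs) != 1:
                raise DataError("unimodal items are binary (one location)")

    @property
    def n_steps(self) -> int:
        if self.kind == "table":
            return len(self.probs)
        return len(self.locations)

    def step_probabilities(self, theta: np.ndarray) -> np.ndarray:
        """P(X >= s | theta) for s = 1..m; shape (len(theta), m)."""
        theta = np.asarray(theta, dtype=float)
        if self.kind == "logistic":
            z = self.discrimination * (
                theta[:, None] - np.asarray(self.locations)[None, :]
            )
            return 1.0 / (1.0 + np.exp(-z))
        if self.kind == "step":
            return (
                theta[:, None] >= np.asarray(self.locations)[None, :]
            ).astype(float)
        if self.kind == "unimodal":
            loc = self.locations[0]
            return (
                self.peak
                * np.exp(-0.5 * self.discrimination * (theta - loc) ** 2)
            )[:, None]
        # table
        return np.broadcast_to(
            np.asarray(self.probs)[None, :], (theta.size, len(self.probs))
        ).copy()


@dataclass(frozen=True)
class SyntheticConfig:
    """Sample size, item models, trait distribution and seed."""

    n: int
    items: tuple
    theta_distribution: str = "normal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DataError("sample size must be positive")
        object.__setattr__(self, "items", tuple(self.items))
        if len(self.items) < 2:
            raise DataError("need at least 2 items")


def _draw_theta(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    if config.theta_distribution == "normal":
        return rng.standard_normal(config.n)
    if config.theta_distribution == "uniform":
        return rng.uniform(-3, 3, config.n)
    raise DataError(
        f"unknown theta distribution {config.theta_distribution!r}"
    )


def _sample_items(
    items: Sequence[ItemModel], theta: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    cols = []
    for item in items:
        P = item.step_probabilities(theta)
        if np.any(P < -1e-12) or np.any(P > 1 + 1e-12):
            raise DataError("invalid step probabilities outside [0, 1]")
        u = rng.uniform(size=theta.size)
        # cumulative sampling: X >= s iff u < P(X >= s); P nonincreasing in s
        cols.append((u[:, None] < P).sum(axis=1))
    return np.column_stack(cols).astype(np.int64)


def generate(config: SyntheticConfig) -> ItemResponseMatrix:
    """Draw theta per respondent, then responses independently given theta."""
    rng = np.random.default_rng(config.seed)
    theta = _draw_theta(config, rng)
    values = _sample_items(config.items, theta, rng)
    labels = [f"item{j + 1}" for j in range(len(config.items))]
    return ItemResponseMatrix(values=values, item_labels=labels)


def generate_blocks(configs: Sequence[SyntheticConfig], seed: int) -> ItemResponseMatrix:
    """Concatenate independent blocks, each driven by its own latent trait.

    All blocks must share the same sample size; block traits are mutually
    independent, so between-block item correlations are 0 in expectation
    (a planted multi-scale structure for selection tests).
    """
    ns = {c.n for c in configs}
    if len(ns) != 1:
        raise DataError("all blocks must share the same sample size")
    rng = np.random.default_rng(seed)
    blocks = []
    for config in configs:
        theta = _draw_theta(config, rng)
        blocks.append(_sample_items(config.items, theta, rng))
    values = np.hstack(blocks)
    labels = []
    for b, config in enumerate(configs):
        labels += [f"b{b + 1}_item{j + 1}" for j in range(len(config.items))]
    return ItemResponseMatrix(values=values, item_labels=labels)


def generate_guttman(pattern_counts: Sequence[int]) -> ItemResponseMatrix:
    """Deterministic error-free cumulative data (H = 1 by construction).

    ``pattern_counts[t]`` is the number of respondents with the triangular
    pattern of t ones followed by zeros; k = len(pattern_counts) - 1 items.
    """
    counts = [int(c) for c in pattern_counts]
    if any(c < 0 for c in counts):
        raise DataError("pattern counts must be >= 0")
    k = len(counts) - 1
    if k < 2:
        raise DataError("need at least 2 items (3 triangular patterns)")
    if sum(c > 0 for c in counts) < 2:
        raise DataError(
            "all respondents share a single pattern: zero-variance data"
        )
    rows = []
    for t, c in enumerate(counts):
        pattern = [1] * t + [0] * (k - t)
        rows += [pattern] * c
    values = np.asarray(rows, dtype=np.int64)
    labels = [f"item{j + 1}" for j in range(k)]
    return ItemResponseMatrix(values=values, item_labels=labels)


def inject_crossing_pair(
    config: SyntheticConfig,
    i: int,
    j: int,
    crossing_point: float = 0.0,
    discriminations: tuple = (0.5, 2.0),
) -> SyntheticConfig:
    """Make the response functions of binary items i and j cross.

    Both curves are forced through the same probability at
    ``crossing_point`` with different slopes, so their ordering reverses
    there - the negation of non-intersection used to plant IIO violations.
    """
    if i == j:
        raise DataError("crossing pair needs two distinct items")
    items = list(config.items)
    for idx in (i, j):
        it = items[idx]
        if it.kind != "logistic" or it.n_steps != 1:
            raise DataError("crossing injection requires binary logistic items")
    if abs(crossing_point) > 3:
        warnings.warn(
            "crossing point beyond 3 SD of the trait: the curves are ordered "
            "for nearly all respondents, expect low detection power",
            stacklevel=2,
        )
    it_i, it_j = items[i], items[j]
    logit0 = 0.5 * (
        it_i.discrimination * (crossing_point - it_i.locations[0])
        + it_j.discrimination * (crossing_point - it_j.locations[0])
    )
    a_i, a_j = discriminations
    items[i] = replace(
        it_i, discrimination=a_i, locations=(crossing_point - logit0 / a_i,)
    )
    items[j] = replace(
        it_j, discrimination=a_j, locations=(crossing_point - logit0 / a_j,)
    )
    return replace(config, items=tuple(items))


def inject_unimodal_item(
    config: SyntheticConfig, i: int, location: float = 0.0,
    concentration: float = 1.0, peak: float = 0.9,
) -> SyntheticConfig:
    """Replace item i with a rise-then-fall (nonmonotone) binary item."""
    items = list(config.items)
    items[i] = ItemModel(
        kind="unimodal", locations=(location,),
        discrimination=concentration, peak=peak,
    )
    return replace(config, items=tuple(items))


# ----------------------------------------------------------------------
# convenience constructors


def equal_discrimination_binary(
    locations: Sequence[float], discrimination: float = 1.0
) -> tuple:
    """Binary logistic items with a common slope (non-intersecting ICCs)."""
    return tuple(
        ItemModel(kind="logistic", locations=(b,), discrimination=discrimination)
        for b in locations
    )


def constant_binary(probs: Sequence[float]) -> tuple:
    """Mutually independent binary items with constant ICCs."""
    return tuple(ItemModel(kind="table", probs=(p,)) for p in probs)


def graded_items(
    locations: Sequence[Sequence[float]], discrimination: float = 1.0
) -> tuple:
    """Polytomous graded-response items with ordered cumulative thresholds."""
    return tuple(
        ItemModel(kind="logistic", locations=tuple(locs),
                  discrimination=discrimination)
        for locs in locations
    )


# ----------------------------------------------------------------------
# population (infinite-N) scalability


def _comonotone_exy(px: np.ndarray, py: np.ndarray) -> float:
    """E[XY] under the comonotonic coupling of two score distributions."""
    cx = np.cumsum(px)
    cy = np.cumsum(py)
    grid = np.unique(np.concatenate([[0.0], cx, cy]))
    grid = grid[grid <= 1 + 1e-12]
    exy = 0.0
    for lo, hi in zip(grid[:-1], grid[1:]):
        mid = 0.5 * (lo + hi)
        x = int(np.searchsorted(cx, mid, side="right"))
        y = int(np.searchsorted(cy, mid, side="right"))
        exy += (hi - lo) * x * y
    return exy


def population_scalability(config: SyntheticConfig, n_nodes: int = 61):
    """Population H, H_i and H_ij by quadrature over the trait distribution.

    Only defined for the standard-normal trait (Gauss-Hermite nodes).
    Returns (h, hi, hij).
    """
    if config.theta_distribution != "normal":
        raise DataError("population coefficients implemented for normal theta")
    # probabilists' Hermite quadrature for N(0,1)
    x, w = np.polynomial.hermite_e.hermegauss(n_nodes)
    w = w / math.sqrt(2 * math.pi)
    k = len(config.items)
    cond_mean = np.zeros((n_nodes, k))
    cat_probs = []
    for j, item in enumerate(config.items):
        P = item.step_probabilities(x)  # (n_nodes, m)
        cond_mean[:, j] = P.sum(axis=1)
        m = P.shape[1]
        cum = np.hstack([np.ones((n_nodes, 1)), P, np.zeros((n_nodes, 1))])
        probs = cum[:, :-1] - cum[:, 1:]  # P(X = c | theta), c = 0..m
        cat_probs.append(w @ probs)
    mu = w @ cond_mean
    cov = np.zeros((k, k))
    covmax = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            exy = w @ (cond_mean[:, i] * cond_mean[:, j])
            cov[i, j] = exy - mu[i] * mu[j]
            covmax[i, j] = (
                _comonotone_exy(cat_probs[i], cat_probs[j]) - mu[i] * mu[j]
            )
    off = ~np.eye(k, dtype=bool)
    hij = np.full((k, k), np.nan)
    hij[off] = cov[off] / covmax[off]
    hi = (cov * off).sum(axis=1) / (covmax * off).sum(axis=1)
    iu = np.triu_indices(k, 1)
    h = float(cov[iu].sum() / covmax[iu].sum())
    return h, hi, hij
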