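"""Prediction under a fitted autologistic model.

Marginal probabilities are intractable for ``lambda > 0``, so they are
estimated by Gibbs sampling from the joint, averaging over retained sweeps.
The default estimator is Rao-Blackwellised: instead of averaging class
indicators, it averages the full-conditional probabilities evaluated at
each retained sweep, which has lower variance and collapses to the exact
closed form when ``lambda = 0``.

The 4-neighbour lattice is bipartite, so a chequerboard (two-colour)
systematic scan updates each half of the lattice in one vectorized step;
this is the default scan and is what makes prediction feasible on
megapixel images.  A raster (pixel-by-pixel) scan is provided for
cross-checks on small lattices.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

from .lattice import (
    PM1,
    AutologisticModel,
    Coding,
    LatticeGraph,
    _as_design,
    neighbor_sum,
    unary_field,
)

__all__ = [
    "GibbsConfig",
    "gibbs_marginals",
    "gibbs_sample",
    "classify",
    "confusion",
    "ConfusionSummary",
]


@dataclass(frozen=True)
class GibbsConfig:
    """Settings for the Gibbs marginal estimator.

    ``burnin`` sweeps are discarded, then ``sweeps`` sweeps are retained.
    ``scan`` is ``"chequerboard"`` (vectorized, default) or ``"raster"``.
    ``estimator`` is ``"rao-blackwell"`` (average of conditionals) or
    ``"indicator"`` (average of sampled classes).  Initialization is an
    independent draw from the ``lambda = 0`` model.
    """

    burnin: int = 200
    sweeps: int = 500
    scan: str = "chequerboard"
    estimator: str = "rao-blackwell"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.burnin < 0:
            raise ValueError("burnin must be >= 0")
        if self.sweeps < 1:
            raise ValueError("at least one retained sweep is required")
        if self.scan not in ("chequerboard", "raster"):
            raise ValueError(f"unknown scan scheme {self.scan!r}")
        if self.estimator not in ("rao-blackwell", "indicator"):
            raise ValueError(f"unknown estimator {self.estimator!r}")

    def with_seed(self, seed) -> "GibbsConfig":
        return replace(self, seed=seed)


def _init_field(model: AutologisticModel, xb: np.ndarray, rng) -> np.ndarray:
    c = model.coding
    p0 = expit(c.span * xb)
    return np.where(rng.random(xb.shape) < p0, c.high, c.low)


def gibbs_marginals(
    model: AutologisticModel,
    X,
    graph: LatticeGraph,
    cfg: GibbsConfig | None = None,
) -> np.ndarray:
    """Estimate ``P(Z_i = high)`` for every pixel of one image.

    Reproducible given ``cfg.seed``.  When ``lambda = 0`` the conditionals
    do not depend on the field, so the Rao-Blackwellised estimate equals the
    closed form ``antilogit((H-L) X beta)`` and is returned directly.
    """
    cfg = cfg or GibbsConfig()
    c = model.coding
    xb = (_as_design(X) @ model.beta).reshape(graph.shape)
    # effective unary offset: standard -> X beta; centred -> X beta - lam * A mu
    a = unary_field(model, X, graph)
    if model.lam == 0 and cfg.estimator == "rao-blackwell":
        return expit(c.span * a)
    rng = np.random.default_rng(cfg.seed)
    z = _init_field(model, xb, rng)
    if cfg.scan == "raster":
        return _run_raster(model, a, graph, z, cfg, rng)
    return _run_chequerboard(model, a, graph, z, cfg, rng)


def _run_chequerboard(model, a, graph, z, cfg, rng) -> np.ndarray:
    c = model.coding
    span, lam = c.span, model.lam
    rows, cols = np.indices(graph.shape)
    colour = (rows + cols) % 2
    masks = (colour == 0, colour == 1)
    acc = np.zeros(graph.shape)
    for sweep in range(cfg.burnin + cfg.sweeps):
        for m in masks:
            eta = span * (a + lam * neighbor_sum(z, graph))
            pi = expit(eta)
            u = rng.random(graph.shape)
            z = np.where(m, np.where(u < pi, c.high, c.low), z)
        if sweep >= cfg.burnin:
            if cfg.estimator == "rao-blackwell":
                acc += expit(span * (a + lam * neighbor_sum(z, graph)))
            else:
                acc += z == c.high
    return acc / cfg.sweeps


def _run_raster(model, a, graph, z, cfg, rng) -> np.ndarray:
    # Plain per-pixel sweep; intended for small-lattice validation only.
    c = model.coding
    span, lam = c.span, model.lam
    R, C = graph.shape
    acc = np.zeros(graph.shape)
    for sweep in range(cfg.burnin + cfg.sweeps):
        for r in range(R):
            for col in range(C):
                s = 0.0
                if r > 0:
                    s += z[r - 1, col]
                if r + 1 < R:
                    s += z[r + 1, col]
                if col > 0:
                    s += z[r, col - 1]
                if col + 1 < C:
                    s += z[r, col + 1]
                pi = expit(span * (a[r, col] + lam * s))
                z[r, col] = c.high if rng.random() < pi else c.low
        if sweep >= cfg.burnin:
            if cfg.estimator == "rao-blackwell":
                acc += expit(span * (a + lam * neighbor_sum(z, graph)))
            else:
                acc += z == c.high
    return acc / cfg.sweeps


def gibbs_sample(
    model: AutologisticModel,
    X,
    graph: LatticeGraph,
    sweeps: int = 300,
    seed: int | None = None,
) -> np.ndarray:
    """One (approximate) draw from the joint: chequerboard chain state after
    ``sweeps`` sweeps from an independence initialization."""
    rng = np.random.default_rng(seed)
    c = model.coding
    xb = (_as_design(X) @ model.beta).reshape(graph.shape)
    a = unary_field(model, X, graph)
    z = _init_field(model, xb, rng)
    span, lam = c.span, model.lam
    rows, cols = np.indices(graph.shape)
    colour = (rows + cols) % 2
    for _ in range(sweeps):
        for m in (colour == 0, colour == 1):
            pi = expit(span * (a + lam * neighbor_sum(z, graph)))
            u = rng.random(graph.shape)
            z = np.where(m, np.where(u < pi, c.high, c.low), z)
    return z


def classify(p: np.ndarray, c: float = 0.5, coding: Coding = PM1) -> np.ndarray:
    """Threshold a probability map at cutoff ``c``.

    A pixel is assigned the high class iff ``p_i > c`` (strict); ties at the
    cutoff go to the low class.  ``c`` must lie strictly inside (0, 1).
    """
    if not 0.0 < c < 1.0:
        raise ValueError(f"cutoff must be in (0, 1), got {c}")
    p = np.asarray(p, dtype=float)
    return np.where(p > c, coding.high, coding.low)


@dataclass(frozen=True)
class ConfusionSummary:
    """Pixel counts with the high class treated as positive."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def overall_error(self) -> float:
        return (self.fp + self.fn) / self.total

    @property
    def high_error(self) -> float:
        """Fraction of truly-high pixels predicted low."""
        n = self.tp + self.fn
        return self.fn / n if n else 0.0

    @property
    def low_error(self) -> float:
        """Fraction of truly-low pixels predicted high."""
        n = self.tn + self.fp
        return self.fp / n if n else 0.0

    def __add__(self, other: "ConfusionSummary") -> "ConfusionSummary":
        return ConfusionSummary(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "overall_error": self.overall_error,
            "high_error": self.high_error,
            "low_error": self.low_error,
        }


def _as_indicator(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.dtype == bool:
        return arr
    vals = np.unique(arr)
    if np.isin(vals, (-1.0, 0.0, 1.0)).all():
        return np.asarray(arr, dtype=float) > 0.0 if -1.0 in vals else arr.astype(bool)
    raise ValueError("cannot interpret field values as binary classes")


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionSummary:
    """Tabulate prediction vs truth.  Accepts boolean or coded fields.

    For coded inputs the high class is the positive one: value 1 under
    either coding (with -1 or 0 the low class).
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    p = _as_indicator(pred)
    t = _as_indicator(truth)
    return ConfusionSummary(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
        tn=int(np.sum(~p & ~t)),
    )
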