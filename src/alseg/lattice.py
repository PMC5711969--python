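"""Model algebra for autologistic regression on 4-neighbour pixel lattices.

The joint law of a binary field ``z`` on a lattice with adjacency ``A`` is

.. math::

    \\Pr(Z = z) \\propto \\exp\\left( a^T z + \\tfrac{\\lambda}{2} z^T A z \\right),

where the unary coefficients ``a`` carry the regression part (``a = X beta``
for the standard model, with a centring adjustment for the centred variant)
and ``lambda >= 0`` controls the strength of the pairwise spatial
association.  Each pixel takes one of two numeric values, its *coding*:
either ``{0, 1}`` or ``{-1, 1}``.  The two codings define genuinely
different restricted models once ``lambda > 0``.

The conditional probability that pixel ``i`` takes the high value, given
the rest of the field, has the logistic form

.. math::

    \\mathrm{logit}\\, \\pi_i = (H - L)\\left(x_i^T\\beta
        + \\lambda \\sum_{j \\sim i} z_j\\right)

for the standard model, and with ``z_j`` replaced by ``z_j - \\mu_j``
(``mu_j`` the independence expectation of ``Z_j``) for the centred model.
Setting ``lambda = 0`` recovers ordinary logistic regression.

Pixel ordering is row-major, 0-based ``(row, col)`` throughout, for all
flattened vectors and serializations.

This module also provides brute-force enumeration of the joint PMF on tiny
lattices (``n <= 20`` pixels), which serves as the exact oracle for the
sampling-based machinery elsewhere in the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
from scipy.special import expit, logsumexp

__all__ = [
    "Coding",
    "PM1",
    "ZERO_ONE",
    "coding_from_name",
    "LatticeGraph",
    "AutologisticModel",
    "DesignMatrix",
    "build_lattice",
    "neighbor_sum",
    "encode_field",
    "decode_field",
    "unary_field",
    "negpotential",
    "conditional_probabilities",
    "conditional_logits",
    "independence_expectation",
    "enumerate_pmf",
    "exact_marginals",
    "convert_coding",
    "save_model",
    "load_model",
]

_ENUMERATION_CAP = 20
_ENUM_CHUNK = 1 << 16


@dataclass(frozen=True)
class Coding:
    """Numeric pair ``{low, high}`` assigned to the two pixel classes.

    Only the two conventional codings ``{0, 1}`` and ``{-1, 1}`` are
    supported; they are the ones for which coding conversion formulas are
    implemented.
    """

    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"coding requires low < high, got ({self.low}, {self.high})")
        if (self.low, self.high) not in ((0.0, 1.0), (-1.0, 1.0)):
            raise ValueError(
                f"unsupported coding ({self.low}, {self.high}); use (0, 1) or (-1, 1)"
            )

    @property
    def span(self) -> float:
        """``high - low``; the scale factor in the conditional logit."""
        return self.high - self.low

    @property
    def name(self) -> str:
        return "pm1" if self.low == -1.0 else "01"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Coding({{{self.low:g}, {self.high:g}}})"


#: The plus/minus coding ``{-1, 1}``.
PM1 = Coding(-1.0, 1.0)
#: The zero/one coding ``{0, 1}``.
ZERO_ONE = Coding(0.0, 1.0)


def coding_from_name(name: str) -> Coding:
    """Return the :class:`Coding` for the short name ``"pm1"`` or ``"01"``."""
    table = {"pm1": PM1, "01": ZERO_ONE}
    try:
        return table[name]
    except KeyError:
        raise ValueError(f"unknown coding name {name!r}; expected 'pm1' or '01'") from None


class DimensionError(ValueError):
    """Raised for non-positive lattice dimensions."""


@dataclass(frozen=True)
class LatticeGraph:
    """Regular square-grid graph: each pixel linked to the pixels directly
    above, below, left, and right of it.

    Interior pixels have degree 4, edge pixels 3, corner pixels 2.  Vertex
    ``i`` of the flattened representation is pixel ``(i // n_cols,
    i % n_cols)``.
    """

    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise DimensionError(
                f"lattice dimensions must be positive, got ({self.n_rows}, {self.n_cols})"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_edges(self) -> int:
        return self.n_rows * (self.n_cols - 1) + self.n_cols * (self.n_rows - 1)

    def degrees(self) -> np.ndarray:
        """Per-pixel neighbour count as an ``(n_rows, n_cols)`` array."""
        return neighbor_sum(np.ones(self.shape), self)

    def edges(self) -> Iterator[tuple[int, int]]:
        """Yield each undirected edge once as a pair of flat indices (i < j)."""
        nc = self.n_cols
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                i = r * nc + c
                if c + 1 < self.n_cols:
                    yield i, i + 1
                if r + 1 < self.n_rows:
                    yield i, i + nc

    def adjacency(self):
        """Symmetric sparse adjacency matrix (CSR) over flat pixel indices."""
        from scipy.sparse import coo_matrix

        rows, cols = [], []
        for i, j in self.edges():
            rows += [i, j]
            cols += [j, i]
        data = np.ones(len(rows))
        n = self.n_pixels
        return coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()


def build_lattice(n_rows: int, n_cols: int) -> LatticeGraph:
    """Construct the 4-neighbour lattice graph for an image of the given shape."""
    return LatticeGraph(int(n_rows), int(n_cols))


@dataclass(frozen=True)
class AutologisticModel:
    """Full parameterization of an autologistic regression model.

    Parameters
    ----------
    beta
        Regression coefficients, on the scale of the conditional-logit form
        (the ``(H - L)`` factor is *not* folded into ``beta``).
    lam
        Pairwise association parameter; ``lam = 0`` is the independence
        (plain logistic) case.
    coding
        Numeric coding of the two classes.
    centred
        If True, the pairwise term uses centred neighbour values
        ``z_j - mu_j`` in the conditionals; the joint is adjusted
        accordingly (see :func:`unary_field`).
    """

    beta: np.ndarray
    lam: float
    coding: Coding = PM1
    centred: bool = False
    columns: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        b = np.atleast_1d(np.asarray(self.beta, dtype=float))
        object.__setattr__(self, "beta", b)
        if not np.all(np.isfinite(b)):
            raise ValueError("beta must be finite")
        if not np.isfinite(self.lam) or self.lam < 0:
            raise ValueError(f"lambda must be finite and >= 0, got {self.lam}")

    def with_lambda(self, lam: float) -> "AutologisticModel":
        return AutologisticModel(self.beta, float(lam), self.coding, self.centred, self.columns)

    def to_dict(self) -> dict:
        d = {
            "beta": [float(b) for b in self.beta],
            "lambda": float(self.lam),
            "coding": self.coding.name,
            "centred": bool(self.centred),
        }
        if self.columns is not None:
            d["columns"] = list(self.columns)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AutologisticModel":
        return cls(
            beta=np.asarray(d["beta"], dtype=float),
            lam=float(d["lambda"]),
            coding=coding_from_name(d["coding"]),
            centred=bool(d.get("centred", False)),
            columns=tuple(d["columns"]) if d.get("columns") is not None else None,
        )


@dataclass(frozen=True)
class DesignMatrix:
    """Per-pixel predictor matrix ``X`` (n_pixels x r, row-major pixels)."""

    values: np.ndarray
    columns: tuple[str, ...] = ()
    intercept: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError(f"design matrix must be 2-D, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("design matrix contains non-finite entries")
        object.__setattr__(self, "values", v)
        if not self.columns:
            object.__setattr__(
                self, "columns", tuple(f"x{j}" for j in range(v.shape[1]))
            )
        elif len(self.columns) != v.shape[1]:
            raise ValueError("number of column names does not match design width")

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    @property
    def r(self) -> int:
        return self.values.shape[1]


def _as_design(X) -> np.ndarray:
    if isinstance(X, DesignMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def _check_field(z, graph: LatticeGraph) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if z.shape != graph.shape:
        raise ValueError(f"field shape {z.shape} does not match lattice {graph.shape}")
    return z


def encode_field(indicator: np.ndarray, coding: Coding) -> np.ndarray:
    """Map a boolean high-class indicator array to coded values {L, H}."""
    ind = np.asarray(indicator, dtype=bool)
    return np.where(ind, coding.high, coding.low).astype(float)


def decode_field(z: np.ndarray, coding: Coding) -> np.ndarray:
    """Map a coded field back to a boolean high-class indicator."""
    z = np.asarray(z, dtype=float)
    ok = np.isin(z, (coding.low, coding.high))
    if not ok.all():
        raise ValueError("field contains values outside the coding {low, high}")
    return z == coding.high


def neighbor_sum(z: np.ndarray, graph: LatticeGraph) -> np.ndarray:
    """Per-pixel sum of the 4-neighbour values; pixels with no neighbours get 0."""
    z = _check_field(z, graph)
    s = np.zeros_like(z)
    s[1:, :] += z[:-1, :]
    s[:-1, :] += z[1:, :]
    s[:, 1:] += z[:, :-1]
    s[:, :-1] += z[:, 1:]
    return s


def independence_expectation(model: AutologisticModel, X) -> np.ndarray:
    """Expected pixel value under the model with ``lambda = 0``.

    ``mu_j = L + (H - L) * antilogit((H - L) x_j' beta)``; flat, row-major.
    """
    xb = _as_design(X) @ model.beta
    c = model.coding
    return c.low + c.span * expit(c.span * xb)


def unary_field(model: AutologisticModel, X, graph: LatticeGraph) -> np.ndarray:
    """Unary coefficients ``a`` of the joint negpotential, shaped like the lattice.

    Standard model: ``a_i = x_i' beta``.  Centred model:
    ``a_i = x_i' beta - lambda * sum_{j ~ i} mu_j``, which makes the joint's
    full conditionals equal the centred conditional-logit form.
    """
    xb = (_as_design(X) @ model.beta).reshape(graph.shape)
    if not model.centred:
        return xb
    mu = independence_expectation(model, X).reshape(graph.shape)
    return xb - model.lam * neighbor_sum(mu, graph)


def negpotential(model: AutologisticModel, X, z, graph: LatticeGraph) -> float:
    """Exponent of the joint PMF (log unnormalized probability) at state ``z``."""
    z = _check_field(z, graph)
    a = unary_field(model, X, graph)
    val = float(np.sum(a * z) + 0.5 * model.lam * np.sum(z * neighbor_sum(z, graph)))
    if not np.isfinite(val):
        raise FloatingPointError("negpotential is non-finite; parameters at overflow scale")
    return val


def conditional_logits(model: AutologisticModel, X, z, graph: LatticeGraph) -> np.ndarray:
    """Logit of P(Z_i = high | rest of the field), per pixel."""
    z = _check_field(z, graph)
    a = unary_field(model, X, graph)
    return model.coding.span * (a + model.lam * neighbor_sum(z, graph))


def conditional_probabilities(model: AutologisticModel, X, z, graph: LatticeGraph) -> np.ndarray:
    """Full-conditional probabilities ``pi_i = P(Z_i = high | z_{-i})``.

    Extreme logits saturate smoothly to 0/1 (no NaN).
    """
    return expit(conditional_logits(model, X, z, graph))


def _edge_arrays(graph: LatticeGraph) -> tuple[np.ndarray, np.ndarray]:
    e = np.fromiter(
        (k for ij in graph.edges() for k in ij), dtype=np.int64, count=2 * graph.n_edges
    ).reshape(-1, 2)
    if e.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return e[:, 0], e[:, 1]


def enumerate_pmf(model: AutologisticModel, X, graph: LatticeGraph) -> tuple[np.ndarray, np.ndarray]:
    """Exact joint PMF by enumeration of all ``2**n`` states.

    Returns ``(states, probs)`` where ``states`` is ``(2**n, n)`` of coded
    values (flat row-major pixels; state ``k`` has bit ``i`` of ``k`` giving
    pixel ``i``'s class) and ``probs`` sums to 1.  Refuses lattices with more
    than 20 pixels.
    """
    n = graph.n_pixels
    if n > _ENUMERATION_CAP:
        raise ValueError(f"enumeration refused for n_pixels={n} > {_ENUMERATION_CAP}")
    a = unary_field(model, X, graph).ravel()
    ei, ej = _edge_arrays(graph)
    c = model.coding
    n_states = 1 << n
    bit_cols = np.arange(n, dtype=np.uint32)
    states = np.empty((n_states, n), dtype=np.int8)
    logp = np.empty(n_states)
    for start in range(0, n_states, _ENUM_CHUNK):
        stop = min(start + _ENUM_CHUNK, n_states)
        idx = np.arange(start, stop, dtype=np.uint32)
        bits = ((idx[:, None] >> bit_cols) & 1).astype(np.int8)
        states[start:stop] = bits
        Z = c.low + c.span * bits.astype(float)
        e = Z @ a
        if len(ei):
            e += model.lam * np.einsum("ke,ke->k", Z[:, ei], Z[:, ej])
        logp[start:stop] = e
    probs = np.exp(logp - logsumexp(logp))
    probs /= probs.sum()
    coded = (c.low + c.span * states.astype(float))
    return coded, probs


def exact_marginals(model: AutologisticModel, X, graph: LatticeGraph) -> np.ndarray:
    """Exact marginal probabilities P(Z_i = high), via :func:`enumerate_pmf`."""
    states, probs = enumerate_pmf(model, X, graph)
    high = states == model.coding.high
    return (probs[:, None] * high).sum(axis=0).reshape(graph.shape)


def convert_coding(
    unary: np.ndarray,
    lam: float,
    graph: LatticeGraph,
    from_coding: Coding,
    to_coding: Coding,
) -> tuple[np.ndarray, float]:
    """Re-express a general autologistic joint under the other coding.

    Given unary coefficients ``a`` and association ``lam`` defining
    ``exp(a'z + lam/2 z'Az)`` under ``from_coding``, return the parameters
    of the *same* joint distribution under ``to_coding``.  With ``d_i`` the
    degree of pixel ``i``:

    * ``(0,1) -> (-1,1)``:  ``lam' = lam / 4``,  ``a'_i = a_i / 2 + lam d_i / 4``
    * ``(-1,1) -> (0,1)``:  ``lam' = 4 lam``,   ``a'_i = 2 a_i - 2 lam d_i``

    The round trip is the identity.
    """
    unary = _check_field(unary, graph)
    if from_coding == to_coding:
        return unary.copy(), float(lam)
    d = graph.degrees()
    if from_coding == ZERO_ONE and to_coding == PM1:
        return unary / 2.0 + lam * d / 4.0, lam / 4.0
    if from_coding == PM1 and to_coding == ZERO_ONE:
        return 2.0 * unary - 2.0 * lam * d, 4.0 * lam
    raise ValueError("unsupported coding pair")  # pragma: no cover - Coding restricts


def save_model(model: AutologisticModel, path: str | Path) -> None:
    """Serialize a model to JSON (keys: beta, lambda, coding, centred, columns)."""
    Path(path).write_text(json.dumps(model.to_dict(), indent=2))


def load_model(path: str | Path) -> AutologisticModel:
    return AutologisticModel.from_dict(json.loads(Path(path).read_text()))
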