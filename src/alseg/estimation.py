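"""Parameter estimation: balanced pixel sampling, stage-1 logistic fits,
pseudolikelihood, joint MPL, and stage-2 plug-in selection of lambda.

The two-stage ("plug-in") procedure estimates the regression coefficients
under pixel independence from a balanced sample of labelled pixels, then
holds them fixed and picks the association parameter lambda on a grid by
predictive performance on whole validation images.  Maximum
pseudolikelihood (MPL) instead maximizes the product of full conditionals
jointly over (beta, lambda) and serves as the comparison estimator.

Coefficient scale convention: a standard logistic fit of the high-class
indicator yields raw coefficients ``b`` with ``logit p = x'b``; we store
``beta = b / (H - L)`` so that the conditional-logit form at ``lambda = 0``
reproduces the fitted probabilities exactly under either coding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .lattice import (
    PM1,
    AutologisticModel,
    Coding,
    DesignMatrix,
    LatticeGraph,
    encode_field,
    neighbor_sum,
)
from .prediction import GibbsConfig, gibbs_marginals
from .simulate import Scene, SceneSet

__all__ = [
    "PixelSample",
    "ClassShortageError",
    "sample_pixels",
    "LogisticFit",
    "fit_logistic",
    "deviance",
    "pseudolikelihood",
    "MplFit",
    "fit_mpl",
    "LambdaSearchResult",
    "tune_lambda_plugin",
    "intercept_bands_builder",
]

_PROB_FLOOR = 1e-12


class ClassShortageError(ValueError):
    """Requested more pixels of a class than the split contains."""


@dataclass(frozen=True)
class PixelSample:
    """Balanced sample of labelled pixels pooled across the images of a split.

    ``features`` holds the raw per-band values (n x k); ``labels`` is True
    for the high (foreground) class.  Provenance records where each pixel
    came from.
    """

    features: np.ndarray
    labels: np.ndarray
    scene_ids: np.ndarray
    rows: np.ndarray
    cols: np.ndarray
    high_fraction: float

    @property
    def n(self) -> int:
        return len(self.labels)


def sample_pixels(
    scenes: SceneSet,
    split: str,
    n: int,
    high_fraction: float = 0.5,
    seed: int | None = None,
    allow_test: bool = False,
) -> PixelSample:
    """Draw a class-balanced pixel sample without replacement from one split.

    Exactly ``round(n * high_fraction)`` high-class pixels and the remainder
    low-class, uniformly across all images of the split.  Raises
    :class:`ClassShortageError` if a class cannot supply its quota.  The
    test split is refused unless ``allow_test=True`` (it is reserved for
    final evaluation).
    """
    if split == "test" and not allow_test:
        raise ValueError("sampling from the test split is disabled; pass allow_test=True")
    imgs = scenes.split(split)
    if not imgs:
        raise ValueError(f"split {split!r} contains no images")
    n_high = int(round(n * high_fraction))
    n_low = n - n_high
    ids, rows, cols, labels = [], [], [], []
    # global pools of (scene, row, col) per class
    pools = {True: [], False: []}
    for s in imgs:
        for cls in (True, False):
            r, c = np.nonzero(s.mask if cls else ~s.mask)
            pools[cls].append((s.scene_id, r, c))
    rng = np.random.default_rng(seed)
    for cls, want in ((True, n_high), (False, n_low)):
        sizes = [len(r) for _, r, c in pools[cls]]
        total = int(np.sum(sizes))
        if want > total:
            name = "high (foreground)" if cls else "low (background)"
            raise ClassShortageError(
                f"requested {want} {name} pixels but split {split!r} has only {total}"
            )
        pick = rng.choice(total, size=want, replace=False)
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        for k, (sid, r, c) in enumerate(pools[cls]):
            local = pick[(pick >= offsets[k]) & (pick < offsets[k + 1])] - offsets[k]
            ids.append(np.full(len(local), sid))
            rows.append(r[local])
            cols.append(c[local])
            labels.append(np.full(len(local), cls))
    ids = np.concatenate(ids)
    rows_a = np.concatenate(rows)
    cols_a = np.concatenate(cols)
    labels_a = np.concatenate(labels)
    by_id = {s.scene_id: s for s in imgs}
    n_bands = imgs[0].stack.shape[-1]
    feats = np.empty((len(ids), n_bands))
    for sid in np.unique(ids):
        m = ids == sid
        feats[m] = by_id[sid].stack[rows_a[m], cols_a[m]]
    return PixelSample(
        features=feats,
        labels=labels_a,
        scene_ids=ids,
        rows=rows_a,
        cols=cols_a,
        high_fraction=high_fraction,
    )


def intercept_bands_builder(stack: np.ndarray) -> DesignMatrix:
    """Default design: a column of ones plus the raw band values."""
    v = np.asarray(stack, dtype=float)
    flat = v.reshape(-1, v.shape[-1])
    names = ("intercept",) + tuple(f"band{j}" for j in range(flat.shape[1]))
    return DesignMatrix(
        np.column_stack([np.ones(len(flat)), flat]), columns=names, intercept=True
    )


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    # pivoted QR: columns with negligible diagonal R entries are dependent
    from scipy.linalg import qr

    _, Rm, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(Rm))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = piv[len(diag[diag > tol]):]
    return [names[j] for j in sorted(bad)]


@dataclass(frozen=True)
class LogisticFit:
    """Stage-1 result.  ``beta`` is on the conditional-logit scale
    (raw coefficients divided by the coding span)."""

    beta: np.ndarray
    raw_coef: np.ndarray
    coding: Coding
    columns: tuple[str, ...]
    deviance: float
    separation_detected: bool = False

    def model(self, lam: float = 0.0, centred: bool = False) -> AutologisticModel:
        return AutologisticModel(self.beta, lam, self.coding, centred, self.columns)


def fit_logistic(
    sample: PixelSample,
    coding: Coding = PM1,
    l1_penalty: float = 0.0,
    design_builder: Callable[[np.ndarray], DesignMatrix] = intercept_bands_builder,
) -> LogisticFit:
    """Maximum-likelihood (optionally L1-penalized) logistic fit on a sample.

    Unpenalized fits require a full-rank design; rank deficiency raises an
    error naming the collinear columns.  Apparent perfect separation
    (diverging coefficients) triggers a warning and a lightly penalized
    refit.
    """
    design = design_builder(sample.features)
    X, names = design.values, design.columns
    y = sample.labels.astype(int)
    if l1_penalty < 0:
        raise ValueError("l1_penalty must be >= 0")
    if l1_penalty == 0:
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            bad = _collinear_columns(X, names)
            raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
        clf = LogisticRegression(
            penalty=None, fit_intercept=False, max_iter=2000, tol=1e-10
        )
    else:
        clf = LogisticRegression(
            penalty="l1",
            C=1.0 / l1_penalty,
            solver="liblinear",
            fit_intercept=False,
            max_iter=2000,
            tol=1e-10,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y)
    b = clf.coef_.ravel().astype(float)
    separated = False
    if l1_penalty == 0 and np.abs(b).max(initial=0.0) > 30.0:
        separated = True
        warnings.warn(
            "possible perfect separation detected; refitting with a small L2 penalty",
            RuntimeWarning,
            stacklevel=2,
        )
        clf = LogisticRegression(
            penalty="l2", C=1e3, fit_intercept=False, max_iter=2000, tol=1e-10
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            clf.fit(X, y)
        b = clf.coef_.ravel().astype(float)
    probs = expit(X @ b)
    dev = deviance(y, probs)
    return LogisticFit(
        beta=b / coding.span,
        raw_coef=b,
        coding=coding,
        columns=tuple(names),
        deviance=dev,
        separation_detected=separated,
    )


def deviance(labels: np.ndarray, probs: np.ndarray) -> float:
    """``-2 * Bernoulli log-likelihood`` of the high-class indicator.

    Probabilities are clamped to ``[1e-12, 1 - 1e-12]`` so degenerate inputs
    stay finite.
    """
    y = np.asarray(labels).astype(float).ravel()
    p = np.clip(np.asarray(probs, dtype=float).ravel(), _PROB_FLOOR, 1 - _PROB_FLOOR)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def _log1pexp(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _scene_arrays(scene: Scene, design_builder) -> tuple[np.ndarray, np.ndarray, np.ndarray, LatticeGraph]:
    graph = LatticeGraph(*scene.shape)
    X = design_builder(scene.stack).values
    y = scene.mask.ravel().astype(float)
    return X, y, scene.mask, graph


def pseudolikelihood(
    model: AutologisticModel,
    scenes: Sequence[Scene],
    design_builder: Callable[[np.ndarray], DesignMatrix] = intercept_bands_builder,
) -> float:
    """Log pseudolikelihood: sum over images and pixels of
    ``log P(z_i | neighbours)`` with observed labels as neighbour values."""
    total = 0.0
    span, lam = model.coding.span, model.lam
    for scene in scenes:
        X, y, mask, graph = _scene_arrays(scene, design_builder)
        z = encode_field(mask, model.coding)
        s = neighbor_sum(z, graph).ravel()
        xb = X @ model.beta
        if model.centred:
            mu = model.coding.low + span * expit(span * xb)
            s = s - neighbor_sum(mu.reshape(graph.shape), graph).ravel()
        eta = span * (xb + lam * s)
        total += float(np.sum(y * eta - _log1pexp(eta)))
    return total


@dataclass(frozen=True)
class MplFit:
    model: AutologisticModel
    converged: bool
    n_iter: int
    message: str
    log_pl: float


def fit_mpl(
    scenes: Sequence[Scene],
    design_builder: Callable[[np.ndarray], DesignMatrix] = intercept_bands_builder,
    coding: Coding = PM1,
    centred: bool = False,
    init: tuple[np.ndarray, float] | None = None,
    lam_max: float = 10.0,
) -> MplFit:
    """Joint maximum-pseudolikelihood estimate of (beta, lambda).

    Quasi-Newton (L-BFGS-B) with the analytic gradient; lambda is box
    constrained to ``[0, lam_max]``.  If no starting point is supplied, beta
    starts at a quick independence logistic fit and lambda at 0.5.
    Non-convergence is flagged on the result, not raised.
    """
    if not scenes:
        raise ValueError("at least one labelled image is required")
    span = coding.span
    pre = []
    for scene in scenes:
        X, y, mask, graph = _scene_arrays(scene, design_builder)
        z = encode_field(mask, coding)
        s = neighbor_sum(z, graph).ravel()
        A = graph.adjacency() if centred else None
        pre.append((X, y, s, A, graph))
    r = pre[0][0].shape[1]

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        beta, lam = theta[:r], theta[r]
        f = 0.0
        g = np.zeros(r + 1)
        for X, y, s, A, graph in pre:
            xb = X @ beta
            if centred:
                sig_mu = expit(span * xb)
                mu = coding.low + span * sig_mu
                sm = A @ mu
                sc = s - sm
            else:
                sc = s
            eta = span * (xb + lam * sc)
            p = expit(eta)
            f -= float(np.sum(y * eta - _log1pexp(eta)))
            resid = p - y  # gradient of -loglik wrt eta
            g[:r] += span * (X.T @ resid)
            if centred:
                # d eta / d beta includes -lam * A d(mu)/d(beta)
                w = span**2 * sig_mu * (1.0 - sig_mu)  # d mu / d(x'beta)
                g[:r] -= span * lam * (X.T @ (w * (A @ resid)))
            g[r] += span * float(sc @ resid)
        return f, g

    if init is None:
        beta0 = _quick_logistic(pre, span)
        lam0 = 0.5
    else:
        beta0 = np.asarray(init[0], dtype=float)
        lam0 = float(init[1])
    theta0 = np.concatenate([beta0, [lam0]])
    bounds = [(None, None)] * r + [(0.0, lam_max)]
    res = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"gtol": 1e-8, "ftol": 1e-12, "maxiter": 500},
    )
    model = AutologisticModel(res.x[:r], float(res.x[r]), coding, centred)
    return MplFit(
        model=model,
        converged=bool(res.success),
        n_iter=int(res.nit),
        message=str(res.message),
        log_pl=float(-res.fun),
    )


def _quick_logistic(pre, span: float, cap: int = 200_000) -> np.ndarray:
    X = np.concatenate([p[0] for p in pre])
    y = np.concatenate([p[1] for p in pre])
    if len(y) > cap:
        step = len(y) // cap + 1
        X, y = X[::step], y[::step]
    clf = LogisticRegression(penalty=None, fit_intercept=False, max_iter=1000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y.astype(int))
    return clf.coef_.ravel() / span


@dataclass(frozen=True)
class LambdaSearchResult:
    """Criterion curve over the lambda grid and the selected minimizer."""

    grid: np.ndarray
    criterion_values: np.ndarray
    selected: float
    criterion: str

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"lambda": self.grid, self.criterion: self.criterion_values})


def tune_lambda_plugin(
    beta: np.ndarray,
    grid: Sequence[float],
    validation_scenes: Sequence[Scene],
    design_builder: Callable[[np.ndarray], DesignMatrix] = intercept_bands_builder,
    coding: Coding = PM1,
    centred: bool = False,
    criterion: str = "error",
    gibbs: GibbsConfig | None = None,
    cutoff: float = 0.5,
    seed: int | None = None,
) -> LambdaSearchResult:
    """Stage-2 plug-in: pick lambda on a grid with beta held fixed.

    For each candidate lambda, marginal probabilities are estimated by Gibbs
    sampling on every validation image and the criterion is computed on the
    pooled pixels: ``"error"`` is the overall misclassification rate at the
    cutoff, ``"deviance"`` the Bernoulli deviance of the marginals.  Ties
    break toward the smaller lambda.  Per-image Gibbs seeds are derived from
    ``seed`` and the image only (common random numbers across the grid).
    """
    if len(grid) == 0:
        raise ValueError("lambda grid must be non-empty")
    if criterion not in ("error", "deviance"):
        raise ValueError(f"unknown criterion {criterion!r}")
    gibbs = gibbs or GibbsConfig()
    grid = np.sort(np.asarray(grid, dtype=float))
    scenes = list(validation_scenes)
    seeds = np.random.default_rng(seed).integers(0, 2**63 - 1, size=len(scenes))
    designs = [design_builder(s.stack) for s in scenes]
    graphs = [LatticeGraph(*s.shape) for s in scenes]
    values = np.empty(len(grid))
    for gi, lam in enumerate(grid):
        model = AutologisticModel(beta, float(lam), coding, centred)
        n_err = 0
        n_tot = 0
        dev = 0.0
        for s, X, graph, sd in zip(scenes, designs, graphs, seeds):
            p = gibbs_marginals(model, X, graph, gibbs.with_seed(int(sd)))
            if criterion == "error":
                pred = p > cutoff
                n_err += int(np.sum(pred != s.mask))
                n_tot += s.mask.size
            else:
                dev += deviance(s.mask.ravel(), p.ravel())
        values[gi] = n_err / n_tot if criterion == "error" else dev
    best = int(np.argmin(values))  # argmin takes the first minimum: smallest lambda
    return LambdaSearchResult(
        grid=grid, criterion_values=values, selected=float(grid[best]), criterion=criterion
    )
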