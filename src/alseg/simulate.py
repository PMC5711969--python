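"""Synthetic labelled scenes: elliptical foreground over GMRF textures.

A scene is built in the unit square.  The truth mask is the union of a
number of random ellipses (foreground class); each colour channel of the
image is then drawn, separately for each class, as

    value = antilogit( logit(class_mean) + gmrf_field ),

where the zero-mean Gaussian Markov random field has a 3x3-neighbourhood
precision and is sampled spectrally on a torus (FFT), which keeps the field
stationary and avoids boundary artefacts.  Foreground pixels take their
channel values from the foreground draw, the rest from the background draw.

Class means live on the [0, 1] intensity scale; the field is added on the
logit scale, so the sd/dependence knobs control within-class texture while
the means control class separation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "EllipseParams",
    "Ellipse",
    "GmrfSpec",
    "Scene",
    "SceneSet",
    "DEFAULT_BACKGROUND",
    "DEFAULT_FOREGROUND",
    "sample_ellipses",
    "rasterize_foreground",
    "gmrf_spectrum",
    "sample_gmrf",
    "compose_scene",
    "generate_scene",
    "generate_suite",
]

SPLITS = ("train", "validation", "test")


@dataclass(frozen=True)
class Ellipse:
    """An ellipse given by its two foci and major-axis length ``2a``."""

    f1: tuple[float, float]
    f2: tuple[float, float]
    major: float  # = 2a

    def __post_init__(self) -> None:
        d = math.dist(self.f1, self.f2)
        if self.major < d:
            raise ValueError("major axis must be >= the inter-focus distance")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        d1 = np.hypot(x - self.f1[0], y - self.f1[1])
        d2 = np.hypot(x - self.f2[0], y - self.f2[1])
        return d1 + d2 <= self.major


@dataclass(frozen=True)
class EllipseParams:
    """Controls for random ellipse generation in the unit square.

    The first focus is uniform on the square; the second is displaced in a
    uniform direction by a U(0, ``max_focus_sep``) distance (clipped back
    into the square); the major axis is the inter-focus distance plus a
    U(``axis_slack``) amount, so every ellipse is valid.
    """

    n_ellipses: int = 25
    max_focus_sep: float = 0.2
    axis_slack: tuple[float, float] = (0.02, 0.16)

    def __post_init__(self) -> None:
        if self.n_ellipses < 0:
            raise ValueError("n_ellipses must be >= 0")
        lo, hi = self.axis_slack
        if not (0 <= lo <= hi):
            raise ValueError("axis_slack must be an increasing non-negative pair")


def sample_ellipses(params: EllipseParams, rng: np.random.Generator) -> list[Ellipse]:
    """Draw ``params.n_ellipses`` random ellipses with foci in the unit square."""
    out = []
    lo, hi = params.axis_slack
    for _ in range(params.n_ellipses):
        f1 = rng.uniform(0.0, 1.0, size=2)
        theta = rng.uniform(0.0, 2.0 * math.pi)
        d = rng.uniform(0.0, params.max_focus_sep)
        f2 = np.clip(f1 + d * np.array([math.cos(theta), math.sin(theta)]), 0.0, 1.0)
        dist = math.dist(f1, f2)
        major = dist + rng.uniform(lo, hi)
        out.append(Ellipse(tuple(f1), tuple(f2), major))
    return out


def rasterize_foreground(
    ellipses: Sequence[Ellipse], n_rows: int, n_cols: int
) -> np.ndarray:
    """Boolean mask: pixel centre inside the union of the ellipses.

    The image is mapped onto the unit square with pixel centres at
    ``((col + 0.5) / n_cols, (row + 0.5) / n_rows)``.
    """
    x = (np.arange(n_cols) + 0.5) / n_cols
    y = (np.arange(n_rows) + 0.5) / n_rows
    xx, yy = np.meshgrid(x, y)
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    for e in ellipses:
        mask |= e.contains(xx, yy)
    return mask


@dataclass(frozen=True)
class GmrfSpec:
    """Class texture: per-channel means plus a GMRF on the logit scale.

    ``dependence`` scales the 3x3 precision stencil: the precision kernel is
    1 at the centre and ``-dependence / 8`` at each of the 8 neighbours, so
    the stencil is valid (positive spectrum on any torus) for
    ``0 <= dependence < 1``; the default sits at 90% of that limit.
    """

    means: tuple[float, ...] = (0.75, 0.65, 0.55)
    sd: float = 1.0
    dependence: float = 0.9

    def __post_init__(self) -> None:
        if not all(0.0 < m < 1.0 for m in self.means):
            raise ValueError("class means must lie strictly inside (0, 1)")
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if not 0.0 <= self.dependence < 1.0:
            raise ValueError("dependence must be in [0, 1)")


DEFAULT_BACKGROUND = GmrfSpec(means=(0.75, 0.65, 0.55))
DEFAULT_FOREGROUND = GmrfSpec(means=(0.6, 0.5, 0.7))


def gmrf_spectrum(n_rows: int, n_cols: int, dependence: float) -> np.ndarray:
    """Eigenvalues of the torus-circulant 3x3 precision stencil (via FFT)."""
    kernel = np.zeros((n_rows, n_cols))
    kernel[0, 0] = 1.0
    w = dependence / 8.0
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            kernel[dr % n_rows, dc % n_cols] -= w
    ev = np.fft.fft2(kernel).real
    if ev.min() <= 0:
        raise ValueError(
            f"dependence {dependence} gives a non-positive-definite precision "
            f"on a {n_rows}x{n_cols} torus"
        )
    return ev


def sample_gmrf(
    n_rows: int, n_cols: int, spec: GmrfSpec, rng: np.random.Generator
) -> np.ndarray:
    """One zero-mean stationary GMRF draw with marginal sd ``spec.sd``.

    White noise is filtered in the Fourier domain by ``ev**-1/2`` (giving
    covariance proportional to the stencil inverse), then scaled so the
    theoretical marginal standard deviation equals ``spec.sd``.
    """
    ev = gmrf_spectrum(n_rows, n_cols, spec.dependence)
    e = rng.standard_normal((n_rows, n_cols))
    x = np.fft.ifft2(np.fft.fft2(e) / np.sqrt(ev)).real
    marg_var = float(np.mean(1.0 / ev))
    return x * (spec.sd / math.sqrt(marg_var))


def compose_scene(
    mask: np.ndarray,
    bg: GmrfSpec,
    fg: GmrfSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Assemble the image stack for a given truth mask.

    Per channel, independent background and foreground fields are drawn;
    each pixel takes ``antilogit(logit(mean) + field)`` from its class's
    draw.  Result has shape ``(n_rows, n_cols, n_channels)``, values in (0, 1).
    """
    mask = np.asarray(mask, dtype=bool)
    if len(bg.means) != len(fg.means):
        raise ValueError("background and foreground must have the same channel count")
    R, C = mask.shape
    stack = np.empty((R, C, len(bg.means)))
    for ch, (mb, mf) in enumerate(zip(bg.means, fg.means)):
        vb = expit(logit(mb) + sample_gmrf(R, C, bg, rng))
        vf = expit(logit(mf) + sample_gmrf(R, C, fg, rng))
        stack[:, :, ch] = np.where(mask, vf, vb)
    return stack


@dataclass(frozen=True)
class Scene:
    """One labelled image: stack (R, C, k) in (0,1), boolean truth mask."""

    stack: np.ndarray
    mask: np.ndarray
    split: str
    scene_id: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mask.shape != self.stack.shape[:2]:
            raise ValueError("mask shape does not match image shape")
        if self.split not in SPLITS:
            raise ValueError(f"split must be one of {SPLITS}, got {self.split!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass
class SceneSet:
    """A suite of scenes partitioned into train/validation/test splits."""

    scenes: list[Scene]
    params: dict = dc_field(default_factory=dict)
    master_seed: int | None = None

    def split(self, tag: str) -> list[Scene]:
        if tag not in SPLITS:
            raise ValueError(f"unknown split {tag!r}")
        return [s for s in self.scenes if s.split == tag]

    def __len__(self) -> int:
        return len(self.scenes)


def generate_scene(
    n_rows: int,
    n_cols: int,
    ellipse_params: EllipseParams,
    bg: GmrfSpec,
    fg: GmrfSpec,
    seed: int,
    split: str = "train",
    scene_id: int = 0,
) -> Scene:
    """Generate one scene deterministically from its seed."""
    rng = np.random.default_rng(seed)
    ellipses = sample_ellipses(ellipse_params, rng)
    mask = rasterize_foreground(ellipses, n_rows, n_cols)
    stack = compose_scene(mask, bg, fg, rng)
    return Scene(stack=stack, mask=mask, split=split, scene_id=scene_id, seed=seed)


def generate_suite(
    size: int | tuple[int, int],
    n_scenes: int = 90,
    split_counts: tuple[int, int, int] = (30, 30, 30),
    ellipse_params: EllipseParams | None = None,
    bg: GmrfSpec | None = None,
    fg: GmrfSpec | None = None,
    master_seed: int = 0,
) -> SceneSet:
    """Generate a full suite of independent scenes with recorded seeds.

    ``split_counts`` must sum to ``n_scenes``; scenes are assigned to the
    splits in order (train block, then validation, then test), which is
    exchangeable because scenes are i.i.d.  The same ``master_seed``
    reproduces the suite bit for bit.
    """
    if sum(split_counts) != n_scenes:
        raise ValueError("split counts must sum to n_scenes")
    if isinstance(size, int):
        size = (size, size)
    ellipse_params = ellipse_params or EllipseParams()
    bg = bg or DEFAULT_BACKGROUND
    fg = fg or DEFAULT_FOREGROUND
    # Per-scene integer seeds derived from the master seed; stored on each
    # scene so any single scene can be regenerated in isolation.
    seed_rng = np.random.default_rng(master_seed)
    seeds = seed_rng.integers(0, 2**63 - 1, size=n_scenes)
    tags = [t for t, k in zip(SPLITS, split_counts) for _ in range(k)]
    scenes = [
        generate_scene(
            size[0], size[1], ellipse_params, bg, fg, int(seeds[i]), tags[i], scene_id=i
        )
        for i in range(n_scenes)
    ]
    params = {
        "size": list(size),
        "n_scenes": n_scenes,
        "split_counts": list(split_counts),
        "ellipses": {
            "n_ellipses": ellipse_params.n_ellipses,
            "max_focus_sep": ellipse_params.max_focus_sep,
            "axis_slack": list(ellipse_params.axis_slack),
        },
        "background": {"means": list(bg.means), "sd": bg.sd, "dependence": bg.dependence},
        "foreground": {"means": list(fg.means), "sd": fg.sd, "dependence": fg.dependence},
    }
    return SceneSet(scenes=scenes, params=params, master_seed=master_seed)
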