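"""Seeded synthetic phantoms with ground truth.

The benchmark imagery is not distributable, so this module regenerates its
*conditions*: piecewise-constant objects on a darker background, optionally
corrupted by a smooth intensity bias (linear ramp or radial illumination
falloff) and additive Gaussian noise, then clipped to [0, 1].  Clipping
truncates the noise distribution; that is part of the contract.  The ground
truth mask is always the pre-corruption geometry.

Kinds
-----
``gourd``
    Silhouette of a gourd: two overlapping discs of different radii.
``three_objects``
    A disc, a rectangle and an ellipse; with the default linear bias of
    amplitude 0.4 the brightest background pixels exceed the dimmest
    foreground pixels, which is exactly the condition under which a global
    two-constant model leaks.
``t_shape``
    A T-shaped object under radial (nonuniform-illumination) bias.
``vessel``
    A curvilinear tube of varying width (3-7 px) along a sinusoidal
    centerline, crossed by a strong linear bias so that parts of the
    background are brighter than parts of the vessel.

All randomness is seeded through ``numpy.random.default_rng(spec.seed)``;
identical specs produce bit-identical images.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import ConfigurationError
from .levelset import HybridParams

__all__ = ["Bias", "PhantomSpec", "SuiteItem", "make_phantom", "default_suite"]

KINDS = ("gourd", "three_objects", "t_shape", "vessel")


@dataclass(frozen=True)
class Bias:
    """Smooth intensity bias field.

    ``kind="linear"``: amplitude * normalized coordinate along ``direction``
    (a (drow, dcol) vector), running 0 -> amplitude across the image.
    ``kind="radial"``: amplitude * (1 - (d/dmax)^2) around ``center``
    (bright at the center, fading outward).
    ``mode``: "additive" adds the field; "multiplicative" scales the base
    image by (1 + field).
    """

    kind: str = "linear"
    amplitude: float = 0.0
    direction: tuple[float, float] = (0.0, 1.0)
    center: Optional[tuple[float, float]] = None
    mode: str = "additive"

    def field(self, shape) -> np.ndarray:
        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
        if self.kind == "linear":
            dr, dc = self.direction
            norm = np.hypot(dr, dc)
            if norm == 0:
                raise ConfigurationError("linear bias needs a nonzero direction")
            t = (rows * dr + cols * dc) / norm
            t = (t - t.min()) / max(t.max() - t.min(), 1e-12)
            return self.amplitude * t
        if self.kind == "radial":
            cr, cc = self.center if self.center is not None else (
                (shape[0] - 1) / 2.0,
                (shape[1] - 1) / 2.0,
            )
            d = np.hypot(rows - cr, cols - cc)
            dmax = max(float(d.max()), 1e-12)
            return self.amplitude * (1.0 - (d / dmax) ** 2)
        raise ConfigurationError(f"unknown bias kind {self.kind!r}")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom; regeneration is deterministic."""

    kind: str
    shape: tuple[int, int]
    fg_level: float = 0.8
    bg_level: float = 0.2
    bias: Optional[Bias] = None
    noise_sigma: float = 0.0
    seed: int = 0
    geometry: tuple = ()  # ((key, value), ...) overrides of the kind's geometry

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ConfigurationError(f"unknown phantom kind {self.kind!r}")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if self.fg_level == self.bg_level:
            raise ConfigurationError("fg_level must differ from bg_level")

    def geo(self) -> dict:
        return dict(self.geometry)


def _grid(shape):
    return np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)


def _gourd_mask(shape, geo):
    rows, cols = _grid(shape)
    cr1, cc1, r1 = geo.get("body", (36.0, 33.0, 15.0))
    cr2, cc2, r2 = geo.get("head", (16.0, 33.0, 9.0))
    return ((rows - cr1) ** 2 + (cols - cc1) ** 2 <= r1**2) | (
        (rows - cr2) ** 2 + (cols - cc2) ** 2 <= r2**2
    )


def _three_objects_mask(shape, geo):
    # disc in the low-bias corner (dimmest foreground), tall rectangle over
    # the high-bias strip (so the hot zone is mostly object), ellipse between
    rows, cols = _grid(shape)
    cr, cc, r = geo.get("disc", (16.0, 24.0, 10.0))
    r0, c0, r1, c1 = geo.get("rect", (4.0, 56.0, 76.0, 75.0))
    er, ec, sa, sb = geo.get("ellipse", (58.0, 30.0, 11.0, 9.0))
    disc = (rows - cr) ** 2 + (cols - cc) ** 2 <= r**2
    rect = (rows >= r0) & (rows < r1) & (cols >= c0) & (cols < c1)
    ell = ((rows - er) / sa) ** 2 + ((cols - ec) / sb) ** 2 <= 1.0
    return disc | rect | ell


def _t_shape_mask(shape, geo):
    rows, cols = _grid(shape)
    hr0, hc0, hr1, hc1 = geo.get("hbar", (18.0, 18.0, 39.0, 109.0))
    vr0, vc0, vr1, vc1 = geo.get("vbar", (39.0, 52.0, 82.0, 75.0))
    hbar = (rows >= hr0) & (rows < hr1) & (cols >= hc0) & (cols < hc1)
    vbar = (rows >= vr0) & (rows < vr1) & (cols >= vc0) & (cols < vc1)
    return hbar | vbar


def _vessel_mask(shape, geo):
    h, w = shape
    rows = np.arange(h, dtype=float)
    c0 = geo.get("center_col", w / 2.0)
    amp = geo.get("sweep", 0.18 * w)
    cycles = geo.get("cycles", 1.2)
    phase = geo.get("phase", 0.3)
    w_top, w_bot = geo.get("width", (3.0, 7.0))
    centerline = c0 + amp * np.sin(2.0 * np.pi * cycles * rows / h + phase)
    halfw = 0.5 * np.linspace(w_top, w_bot, h)
    cols = np.arange(w, dtype=float)
    return np.abs(cols[None, :] - centerline[:, None]) <= halfw[:, None]


_MASKS = {
    "gourd": _gourd_mask,
    "three_objects": _three_objects_mask,
    "t_shape": _t_shape_mask,
    "vessel": _vessel_mask,
}


def make_phantom(spec: PhantomSpec):
    """Generate ``(image, ground_truth_mask)`` from a spec.

    Pipeline: two-level base from the geometry, then bias (additive or
    multiplicative), then Gaussian noise, then clip to [0, 1].
    """
    mask = _MASKS[spec.kind](spec.shape, spec.geo())
    img = np.where(mask, float(spec.fg_level), float(spec.bg_level))
    if spec.bias is not None and spec.bias.amplitude != 0:
        b = spec.bias.field(spec.shape)
        img = img * (1.0 + b) if spec.bias.mode == "multiplicative" else img + b
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    return np.clip(img, 0.0, 1.0), mask


@dataclass(frozen=True)
class SuiteItem:
    """One benchmark entry: phantom spec, seed contour and solver settings."""

    name: str
    spec: PhantomSpec
    init: str
    params: HybridParams


def default_suite() -> list[SuiteItem]:
    """The fixed six-phantom benchmark.

    Sizes match the reference imagery (59x67 gourd, 79x75 three objects,
    96x127 T-shape, 110x111 and 131x103 vessels); corruption levels are a
    noiseless gourd, a noisy gourd (sigma 0.05), three objects under a 0.4
    linear bias with sigma 0.03 noise, a radially lit T-shape, and two
    vessels crossing a 0.45 linear bias.  Solver settings keep the default
    weights (alpha = beta = 1, omega = 0.1, dt = 0.45); only the iteration
    cap varies with problem difficulty.
    """
    p = HybridParams()
    long = p.replace(max_iters=3000)
    return [
        SuiteItem(
            name="gourd",
            spec=PhantomSpec(kind="gourd", shape=(59, 67), fg_level=0.8, bg_level=0.2),
            init="circle:30,33,20",
            params=p,
        ),
        SuiteItem(
            name="noisy_gourd",
            spec=PhantomSpec(
                kind="gourd", shape=(59, 67), fg_level=0.8, bg_level=0.2,
                noise_sigma=0.05, seed=11,
            ),
            init="circle:30,33,20",
            params=p,
        ),
        SuiteItem(
            name="three_objects",
            spec=PhantomSpec(
                kind="three_objects", shape=(79, 75), fg_level=0.5, bg_level=0.2,
                bias=Bias(kind="linear", amplitude=0.4, direction=(0.0, 1.0)),
                noise_sigma=0.03, seed=23,
            ),
            init="circle:39,44,25",
            params=long,
        ),
        SuiteItem(
            name="t_shape",
            spec=PhantomSpec(
                kind="t_shape", shape=(96, 127), fg_level=0.7, bg_level=0.25,
                bias=Bias(kind="radial", amplitude=0.3, center=(10.0, 63.0)),
                noise_sigma=0.02, seed=37,
            ),
            init="circle:48,63,20",
            params=long,
        ),
        SuiteItem(
            name="vessel_1",
            spec=PhantomSpec(
                kind="vessel", shape=(110, 111), fg_level=0.55, bg_level=0.2,
                bias=Bias(kind="linear", amplitude=0.45, direction=(1.0, 0.0)),
                noise_sigma=0.02, seed=41,
            ),
            init="circle:55,55,30",
            params=long,
        ),
        SuiteItem(
            name="vessel_2",
            spec=PhantomSpec(
                kind="vessel", shape=(131, 103), fg_level=0.55, bg_level=0.2,
                bias=Bias(kind="linear", amplitude=0.45, direction=(-1.0, 0.0)),
                noise_sigma=0.02, seed=43,
                geometry=(("sweep", 22.0), ("cycles", 0.9), ("phase", 2.0),
                          ("width", (7.0, 3.0))),
            ),
            init="circle:65,51,30",
            params=long,
        ),
    ]


def reseed_suite(items: list[SuiteItem], seeds) -> list[SuiteItem]:
    """Return the suite with each phantom's noise seed replaced."""
    return [
        SuiteItem(
            name=it.name,
            spec=replace(it.spec, seed=int(s)),
            init=it.init,
            params=it.params,
        )
        for it, s in zip(items, seeds)
    ]
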