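"""Level-set primitives.

A contour ``C`` is represented implicitly as the zero set of a scalar field
``phi`` defined on the image grid, with the convention

    phi > 0  inside C,      phi < 0  outside C,      phi = 0  on C.

Region integrals over the interior/exterior are written with a smoothed
(arctangent-regularized) Heaviside function ``H_eps`` and its derivative, the
smoothed Dirac delta ``delta_eps``.  Because ``H_eps`` has global support,
every pixel participates — weakly — in the region statistics and in the
evolution, which is what lets a far-away object eventually be captured.

This module also holds the shared parameter container :class:`HybridParams`
and the geometric helpers used to build initial level sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, ParameterError

__all__ = [
    "HybridParams",
    "heaviside_eps",
    "delta_eps",
    "region_mask",
    "init_levelset",
    "orient_levelset",
    "curvature",
    "mask_from_levelset",
]

#: floor added in quadrature to the gradient magnitude so that the unit
#: normal (and hence the curvature) is defined where ``grad phi = 0``.
GRAD_ETA = 1e-8


@dataclass(frozen=True)
class HybridParams:
    """Parameters of the hybrid evolution.

    Attributes
    ----------
    alpha, beta, omega
        Non-negative weights of the global fitting term, the ball-localized
        fitting term and the arc-length regularizer.  At least one must be
        positive.  ``alpha`` and ``beta`` are typically chosen in ``[0, 2]``
        with ``alpha ~ beta``, larger ``beta`` for stronger inhomogeneity.
    dt
        Explicit (forward-Euler) time step.
    eps
        Width of the smoothed Heaviside/delta, in the same units as ``phi``.
    r
        Ball radius of the localization kernel, in pixels (``>= 1``).
    c0
        Magnitude of the binary step initialization (``phi0 = +-c0``).
    max_iters
        Iteration cap.
    tol
        Convergence tolerance: the evolution has converged when the fraction
        of pixels whose sign changed over the last ``check_every`` iterations
        is strictly below ``tol``.  ``tol = 0`` disables early stopping.
    check_every
        Iterations between convergence checks / energy-trace records.
    stats_every
        Iterations between recomputations of the region statistics
        (``1`` = every step, the reference behaviour).
    """

    alpha: float = 1.0
    beta: float = 1.0
    omega: float = 0.1
    dt: float = 0.45
    eps: float = 1.0
    r: float = 9.0
    c0: float = 2.0
    max_iters: int = 2000
    tol: float = 1e-4
    check_every: int = 20
    stats_every: int = 1

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.omega < 0:
            raise ParameterError("alpha, beta, omega must be non-negative")
        if self.alpha == 0 and self.beta == 0 and self.omega == 0:
            raise ParameterError("alpha, beta, omega must not all be zero")
        if self.dt <= 0:
            raise ParameterError("dt must be positive")
        if self.eps <= 0:
            raise ParameterError("eps must be positive")
        if self.r < 1:
            raise ParameterError("ball radius r must be >= 1")
        if self.c0 <= 0:
            raise ParameterError("c0 must be positive")
        if self.max_iters < 0:
            raise ParameterError("max_iters must be >= 0")
        if self.tol < 0:
            raise ParameterError("tol must be >= 0")
        if self.check_every < 1 or self.stats_every < 1:
            raise ParameterError("check_every and stats_every must be >= 1")

    def replace(self, **kw) -> "HybridParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kw)


def heaviside_eps(z, eps: float):
    """Smoothed Heaviside ``H_eps(z) = (1/2)(1 + (2/pi) atan(z/eps))``.

    Strictly increasing, values in the open interval (0, 1), and satisfies
    ``H_eps(z) + H_eps(-z) = 1`` exactly.  Elementwise on arrays.
    """
    if eps <= 0:
        raise ParameterError("eps must be positive")
    return 0.5 * (1.0 + (2.0 / math.pi) * np.arctan(np.asarray(z, dtype=float) / eps))


def delta_eps(z, eps: float):
    """Smoothed Dirac delta ``delta_eps(z) = eps / (pi (eps^2 + z^2))``.

    The exact derivative of :func:`heaviside_eps`; even, strictly positive,
    integrates to 1 over the real line.
    """
    if eps <= 0:
        raise ParameterError("eps must be positive")
    z = np.asarray(z, dtype=float)
    return (eps / math.pi) / (eps * eps + z * z)


def _parse_region_string(spec: str):
    """Parse ``circle:row,col,r`` / ``rect:r0,c0,r1,c1`` into a tuple."""
    try:
        kind, _, rest = spec.partition(":")
        vals = [float(v) for v in rest.split(",")]
    except ValueError as exc:  # non-numeric pieces
        raise ConfigurationError(f"cannot parse region spec {spec!r}") from exc
    if kind == "circle" and len(vals) == 3:
        return ("circle", vals[0], vals[1], vals[2])
    if kind == "rect" and len(vals) == 4:
        return ("rect", *vals)
    raise ConfigurationError(f"cannot parse region spec {spec!r}")


def region_mask(shape, region) -> np.ndarray:
    """Resolve a region description into a boolean mask.

    ``region`` may be a boolean/integer array of the right shape, a tuple
    ``("circle", row, col, radius)`` (pixels with squared center distance
    ``<= radius**2``) or ``("rect", r0, c0, r1, c1)`` (half-open row/col
    ranges), or the equivalent string grammar ``circle:row,col,r`` /
    ``rect:r0,c0,r1,c1``.  Coordinates are (row, col), 0-based.
    """
    if isinstance(region, str):
        region = _parse_region_string(region)
    if isinstance(region, np.ndarray):
        if region.shape != tuple(shape):
            raise ConfigurationError(
                f"region mask shape {region.shape} != image shape {tuple(shape)}"
            )
        return region.astype(bool)
    kind = region[0]
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    if kind == "circle":
        _, cr, cc, rad = region
        return (rows - cr) ** 2 + (cols - cc) ** 2 <= rad**2
    if kind == "rect":
        _, r0, c0, r1, c1 = region
        return (rows >= r0) & (rows < r1) & (cols >= c0) & (cols < c1)
    raise ConfigurationError(f"unknown region kind {kind!r}")


def init_levelset(shape, region, c0: float = 2.0, invert: bool = False) -> np.ndarray:
    """Binary step initialization: ``+c0`` inside the seed region, ``-c0`` outside.

    The seed must be a nonempty proper subset of the image.  ``invert``
    swaps the signs (seed treated as exterior).
    """
    if c0 <= 0:
        raise ParameterError("c0 must be positive")
    mask = region_mask(shape, region)
    if not mask.any():
        raise ConfigurationError("initialization region is empty")
    if mask.all():
        raise ConfigurationError("initialization region covers the whole image")
    phi = np.where(mask, float(c0), -float(c0))
    return -phi if invert else phi


def orient_levelset(I: np.ndarray, phi: np.ndarray, eps: float = 1.0) -> np.ndarray:
    """Flip ``phi`` if needed so the seeded interior is the brighter phase.

    The two-phase energies are symmetric under swapping interior and
    exterior, so a seed whose inside is darker than its outside converges to
    the complement labeling.  This helper fixes the convention
    "foreground = brighter phase" by comparing the soft region means.
    """
    h = heaviside_eps(phi, eps)
    I = np.asarray(I, dtype=float)
    m = float((I * h).sum() / h.sum())
    n = float((I * (1.0 - h)).sum() / (1.0 - h).sum())
    return np.asarray(phi, dtype=float) if m >= n else -np.asarray(phi, dtype=float)


def _grad_central(f: np.ndarray):
    """Central differences with replicate (Neumann) boundary handling.

    Returns ``(d/drow, d/dcol)``.  At the boundary the replicate pad makes
    the one-sided difference appear with a factor 1/2, i.e. the normal
    derivative is biased toward zero — the Neumann convention.
    """
    p = np.pad(f, 1, mode="edge")
    fy = 0.5 * (p[2:, 1:-1] - p[:-2, 1:-1])
    fx = 0.5 * (p[1:-1, 2:] - p[1:-1, :-2])
    return fy, fx


def curvature(phi: np.ndarray) -> np.ndarray:
    """Mean curvature of the level lines, ``div(grad phi / |grad phi|)``.

    Central differences, replicate boundaries; the gradient magnitude is
    regularized as ``sqrt(phi_x^2 + phi_y^2 + eta^2)`` with ``eta = 1e-8`` so
    the result is finite everywhere (0 where ``phi`` is flat).
    """
    phi = np.asarray(phi, dtype=float)
    fy, fx = _grad_central(phi)
    mag = np.sqrt(fy * fy + fx * fx + GRAD_ETA * GRAD_ETA)
    ny = fy / mag
    nx = fx / mag
    dyy, _ = _grad_central(ny)
    _, dxx = _grad_central(nx)
    return dyy + dxx


def mask_from_levelset(phi: np.ndarray) -> np.ndarray:
    """Binary segmentation ``phi > 0``; the zero set itself counts as outside."""
    return np.asarray(phi) > 0
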