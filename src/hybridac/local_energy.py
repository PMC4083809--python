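"""Ball-localized region statistics, energy and force.

Intensity inhomogeneity breaks the two-constant global model: a smooth bias
field can make background brighter than foreground in parts of the image.
The local term therefore recomputes the interior/exterior means *inside a
ball* of radius ``r`` around every pixel ``x``:

    u_x = sum_y B(x,y) H(phi(y)) I(y) / sum_y B(x,y) H(phi(y))
    v_x = sum_y B(x,y) (1-H(phi(y))) I(y) / sum_y B(x,y) (1-H(phi(y)))

with ``B(x,y) = 1`` iff ``||x-y|| < r`` (strict Euclidean inequality on
pixel-center offsets).  ``Au``/``Av`` are the corresponding soft areas.
All four fields are plain correlations with the binary ball stencil and are
evaluated here by FFT with replicate padding.  Balls that see (softly) only
one phase have a vanishing denominator; such pixels are flagged undefined
and contribute nothing to forces or energies.

Two energies are reported, because their roles differ:

* ``local_energy`` — the *mean-separation* reading
  ``sum_x W(x) (u_x - v_x)^2`` with ``W(x)`` the in-domain ball size.  Large
  when local interior and exterior means are pulled apart, i.e. when the
  contour sits on a locally contrasted boundary.  It is a diagnostic.
* ``local_residual_energy`` — the area-normalized local fitting residual
  ``sum_x sum_y B [H (I-u_x)^2/Au + (1-H)(I-v_x)^2/Av]``, the quantity the
  local force actually descends.

The local force at the evolving pixel ``x`` samples, over the near-contour
pixels ``y`` of its own ball (weighted by the smoothed delta, which is what
confines the comparison to where the classification is actually being
decided), the residual contrast against that ball's statistics:

    F(x) = sum_y B(x,y) delta_eps(phi(y))
               [ (I(y)-v_x)^2 / Av(x) - (I(y)-u_x)^2 / Au(x) ]

positive (pixel pulled inside) when the contour pixels near ``x`` fit the
ball's exterior model worse than its interior model.  The delta weight
inside the sum matters: balls lying entirely in one phase see almost no
contour, so their (meaningless, tail-dominated) statistics contribute
almost nothing.  Expanding the squares turns the double sum into three
correlations of ``delta``, ``delta*I`` and ``delta*I^2`` with the ball
stencil.

Every fast path here has a brute-force double-loop twin
(``*_bruteforce``) used as an independent oracle in the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.fft as _fft

from .errors import ParameterError
from .levelset import delta_eps, heaviside_eps

__all__ = [
    "BallKernel",
    "LocalStats",
    "ball_kernel",
    "local_stats",
    "local_energy",
    "local_residual_energy",
    "local_force",
    "local_stats_bruteforce",
    "local_energy_bruteforce",
    "local_residual_energy_bruteforce",
    "local_force_bruteforce",
]

#: denominators below this are flagged as undefined local means
AREA_FLOOR = 1e-10


class BallKernel:
    """Binary Euclidean-ball stencil of radius ``r`` (strict ``< r``).

    The stencil is a ``(2 ceil(r)+1)`` square window; offsets whose
    pixel-center Euclidean norm is ``< r`` are 1.  ``correlate`` computes the
    correlation of a field with the stencil via FFT, with either replicate
    (``mode="nearest"``, the evolution default) or zero (``mode="constant"``)
    padding; the kernel transform is cached per padded shape.
    """

    def __init__(self, r: float):
        if not np.isfinite(r) or r < 1:
            raise ParameterError("ball radius r must be finite and >= 1")
        self.r = float(r)
        self.k = int(math.ceil(self.r))
        oy, ox = np.mgrid[-self.k : self.k + 1, -self.k : self.k + 1]
        self.window = (np.hypot(oy, ox) < self.r).astype(np.float64)
        self._fft_cache: dict[tuple, np.ndarray] = {}

    @property
    def size(self) -> int:
        """Number of pixels in the ball."""
        return int(round(self.window.sum()))

    def correlate(self, field: np.ndarray, mode: str = "nearest") -> np.ndarray:
        """Correlation of ``field`` with the ball stencil, same shape out."""
        k = self.k
        pad_mode = "edge" if mode == "nearest" else "constant"
        p = np.pad(np.asarray(field, dtype=float), k, mode=pad_mode)
        fshape = tuple(_fft.next_fast_len(s + 2 * k) for s in p.shape)
        fk = self._fft_cache.get(fshape)
        if fk is None:
            fk = _fft.rfft2(self.window, fshape)
            self._fft_cache[fshape] = fk
        full = _fft.irfft2(_fft.rfft2(p, fshape) * fk, fshape)
        h, w = field.shape
        # kernel is symmetric, so convolution == correlation; 'valid' block
        return full[2 * k : 2 * k + h, 2 * k : 2 * k + w]

    def area_field(self, shape, mode: str = "nearest") -> np.ndarray:
        """``sum_y B(x,y)`` per center: constant ``size`` for replicate
        padding, the in-domain ball count for zero padding."""
        if mode == "nearest":
            return np.full(shape, float(self.size))
        return self.correlate(np.ones(shape), mode="constant")


def ball_kernel(r: float) -> BallKernel:
    """Build the ball stencil of radius ``r`` pixels."""
    return BallKernel(r)


@dataclass(frozen=True)
class LocalStats:
    """Per-pixel local means and soft areas.

    ``u``/``v`` are the local interior/exterior mean intensities, ``au``/``av``
    the soft areas (``au + av`` equals the ball size at every pixel by
    construction).  ``u_defined``/``v_defined`` flag pixels whose denominator
    exceeded :data:`AREA_FLOOR`; undefined means are stored as 0 and never
    enter forces or energies.
    """

    u: np.ndarray
    v: np.ndarray
    au: np.ndarray
    av: np.ndarray
    u_defined: np.ndarray
    v_defined: np.ndarray


def local_stats(
    I: np.ndarray, phi: np.ndarray, kernel: BallKernel, eps: float, mode: str = "nearest"
) -> LocalStats:
    """Local means/areas by correlation with the ball stencil.

    ``mode="nearest"`` (replicate padding) is the evolution convention;
    ``mode="constant"`` restricts the ball to the image domain, which is the
    right comparison when a huge ball should reproduce the global means.
    """
    I = np.asarray(I, dtype=float)
    h = heaviside_eps(phi, eps)
    area = kernel.area_field(I.shape, mode)
    au = kernel.correlate(h, mode)
    av = area - au
    num_u = kernel.correlate(h * I, mode)
    num_v = kernel.correlate(I, mode) - num_u
    u_def = au > AREA_FLOOR
    v_def = av > AREA_FLOOR
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(u_def, num_u / np.where(u_def, au, 1.0), 0.0)
        v = np.where(v_def, num_v / np.where(v_def, av, 1.0), 0.0)
    return LocalStats(u=u, v=v, au=au, av=av, u_defined=u_def, v_defined=v_def)


def local_energy(
    I: np.ndarray,
    phi: np.ndarray,
    kernel: BallKernel,
    eps: float,
    stats: LocalStats | None = None,
) -> float:
    """Mean-separation energy ``sum_x W(x) (u_x - v_x)^2``.

    ``W(x)`` is the number of in-domain pixels of the ball at ``x`` (the
    inner sum of the double integral).  Centers with an undefined mean
    contribute zero.  Nonnegative; a diagnostic, not the descent target.
    """
    I = np.asarray(I, dtype=float)
    if stats is None:
        stats = local_stats(I, phi, kernel, eps)
    w = kernel.area_field(I.shape, mode="constant")
    ok = stats.u_defined & stats.v_defined
    sep = np.where(ok, (stats.u - stats.v) ** 2, 0.0)
    return float((w * sep).sum())


def _inv_areas(stats: LocalStats):
    a = np.where(stats.u_defined, 1.0 / np.where(stats.u_defined, stats.au, 1.0), 0.0)
    b = np.where(stats.v_defined, 1.0 / np.where(stats.v_defined, stats.av, 1.0), 0.0)
    return a, b


def local_residual_energy(
    I: np.ndarray,
    phi: np.ndarray,
    kernel: BallKernel,
    eps: float,
    stats: LocalStats | None = None,
) -> float:
    """Area-normalized local fitting residual (the force's descent target).

    ``sum_x sum_y B(x,y) [H(y)(I(y)-u_x)^2/Au(x) + (1-H(y))(I(y)-v_x)^2/Av(x)]``
    computed by swapping the sums into correlations of the center fields.
    """
    I = np.asarray(I, dtype=float)
    if stats is None:
        stats = local_stats(I, phi, kernel, eps)
    h = heaviside_eps(phi, eps)
    a, b = _inv_areas(stats)
    qu = (
        I * I * kernel.correlate(a)
        - 2.0 * I * kernel.correlate(a * stats.u)
        + kernel.correlate(a * stats.u**2)
    )
    qv = (
        I * I * kernel.correlate(b)
        - 2.0 * I * kernel.correlate(b * stats.v)
        + kernel.correlate(b * stats.v**2)
    )
    return float((h * qu + (1.0 - h) * qv).sum())


def local_force(
    I: np.ndarray,
    phi: np.ndarray,
    stats: LocalStats,
    kernel: BallKernel,
    eps: float,
) -> np.ndarray:
    """Per-pixel local descent force (delta-weighted ball residuals).

    ``F(x) = sum_y B(x,y) d(y) [(I(y)-v_x)^2/Av(x) - (I(y)-u_x)^2/Au(x)]``
    with ``d = delta_eps(phi)``, evaluated through the correlations
    ``C(d)``, ``C(d I)`` and ``C(d I^2)`` as

        F = b (C(dI^2) - 2 v C(dI) + v^2 C(d))
          - a (C(dI^2) - 2 u C(dI) + u^2 C(d))

    where ``a = 1/Au``, ``b = 1/Av`` (zero where flagged undefined).
    Returned without the outer ``delta_eps(phi(x))`` and the ``beta``
    weight; the evolver applies both.
    """
    I = np.asarray(I, dtype=float)
    d = delta_eps(phi, eps)
    a, b = _inv_areas(stats)
    c0 = kernel.correlate(d)
    c1 = kernel.correlate(d * I)
    c2 = kernel.correlate(d * I * I)
    res_v = c2 - 2.0 * stats.v * c1 + stats.v**2 * c0
    res_u = c2 - 2.0 * stats.u * c1 + stats.u**2 * c0
    return b * res_v - a * res_u


# ---------------------------------------------------------------------------
# brute-force twins: direct double loops, independent of the FFT path
# ---------------------------------------------------------------------------


def local_stats_bruteforce(I, phi, kernel, eps, mode="nearest"):
    """Per-pixel window loops over padded arrays; oracle for local_stats."""
    I = np.asarray(I, dtype=float)
    h = heaviside_eps(phi, eps)
    k, W = kernel.k, kernel.window
    pad_mode = "edge" if mode == "nearest" else "constant"
    hp = np.pad(h, k, mode=pad_mode)
    Ip = np.pad(I, k, mode=pad_mode)
    onep = np.pad(np.ones_like(I), k, mode=pad_mode)
    rows, cols = I.shape
    u = np.zeros_like(I)
    v = np.zeros_like(I)
    au = np.zeros_like(I)
    av = np.zeros_like(I)
    u_def = np.zeros(I.shape, bool)
    v_def = np.zeros(I.shape, bool)
    for i in range(rows):
        for j in range(cols):
            hw = hp[i : i + 2 * k + 1, j : j + 2 * k + 1]
            iw = Ip[i : i + 2 * k + 1, j : j + 2 * k + 1]
            ow = onep[i : i + 2 * k + 1, j : j + 2 * k + 1]
            a_in = float((W * hw).sum())
            a_out = float((W * (ow - hw)).sum())
            au[i, j] = a_in
            av[i, j] = a_out
            if a_in > AREA_FLOOR:
                u_def[i, j] = True
                u[i, j] = float((W * hw * iw).sum()) / a_in
            if a_out > AREA_FLOOR:
                v_def[i, j] = True
                v[i, j] = float((W * (ow - hw) * iw).sum()) / a_out
    return LocalStats(u=u, v=v, au=au, av=av, u_defined=u_def, v_defined=v_def)


def local_energy_bruteforce(I, phi, kernel, eps):
    """Double sum over centers and in-domain ball pixels; oracle."""
    I = np.asarray(I, dtype=float)
    st = local_stats_bruteforce(I, phi, kernel, eps)
    k, W = kernel.k, kernel.window
    rows, cols = I.shape
    total = 0.0
    for i in range(rows):
        for j in range(cols):
            if not (st.u_defined[i, j] and st.v_defined[i, j]):
                continue
            count = 0
            for dy in range(-k, k + 1):
                for dx in range(-k, k + 1):
                    if W[dy + k, dx + k] and 0 <= i + dy < rows and 0 <= j + dx < cols:
                        count += 1
            total += count * (st.u[i, j] - st.v[i, j]) ** 2
    return total


def local_residual_energy_bruteforce(I, phi, kernel, eps):
    """Direct double sum of the area-normalized fitting residual; oracle.

    Oriented as the force is: the outer sum runs over image pixels ``y``,
    the inner one over the (replicate-padded) ball centers covering ``y``.
    """
    I = np.asarray(I, dtype=float)
    h = heaviside_eps(phi, eps)
    st = local_stats_bruteforce(I, phi, kernel, eps)
    k, W = kernel.k, kernel.window
    a = np.where(st.u_defined, 1.0 / np.where(st.u_defined, st.au, 1.0), 0.0)
    b = np.where(st.v_defined, 1.0 / np.where(st.v_defined, st.av, 1.0), 0.0)
    ap = np.pad(a, k, mode="edge")
    bp = np.pad(b, k, mode="edge")
    up = np.pad(st.u, k, mode="edge")
    vp = np.pad(st.v, k, mode="edge")
    rows, cols = I.shape
    total = 0.0
    for i in range(rows):
        for j in range(cols):
            aw = ap[i : i + 2 * k + 1, j : j + 2 * k + 1]
            bw = bp[i : i + 2 * k + 1, j : j + 2 * k + 1]
            uw = up[i : i + 2 * k + 1, j : j + 2 * k + 1]
            vw = vp[i : i + 2 * k + 1, j : j + 2 * k + 1]
            Iy = I[i, j]
            total += h[i, j] * float((W * aw * (Iy - uw) ** 2).sum())
            total += (1.0 - h[i, j]) * float((W * bw * (Iy - vw) ** 2).sum())
    return total


def local_force_bruteforce(I, phi, kernel, eps):
    """Per-center window loop over delta-weighted residuals; oracle."""
    I = np.asarray(I, dtype=float)
    st = local_stats_bruteforce(I, phi, kernel, eps)
    k, W = kernel.k, kernel.window
    a = np.where(st.u_defined, 1.0 / np.where(st.u_defined, st.au, 1.0), 0.0)
    b = np.where(st.v_defined, 1.0 / np.where(st.v_defined, st.av, 1.0), 0.0)
    d = delta_eps(phi, eps)
    dp = np.pad(d, k, mode="edge")
    Ip = np.pad(I, k, mode="edge")
    rows, cols = I.shape
    F = np.zeros_like(I)
    for i in range(rows):
        for j in range(cols):
            dw = dp[i : i + 2 * k + 1, j : j + 2 * k + 1]
            iw = Ip[i : i + 2 * k + 1, j : j + 2 * k + 1]
            F[i, j] = float(
                (W * dw * (
                    (iw - st.v[i, j]) ** 2 * b[i, j]
                    - (iw - st.u[i, j]) ** 2 * a[i, j]
                )).sum()
            )
    return F
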