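"""Global (piecewise-constant) fitting term.

The global term models the image as two constants: the mean intensity ``m``
of the foreground (``phi > 0``) and ``n`` of the background, both taken over
the whole image with the smoothed Heaviside as soft membership.  Its energy
is the summed squared residual against whichever constant a pixel is
assigned to, and its gradient-descent velocity at a pixel is
``-(I-m)^2 + (I-n)^2``: positive (pixel pulled inside) when the intensity is
closer to the foreground mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateRegionError
from .levelset import heaviside_eps

__all__ = ["GlobalStats", "global_means", "global_energy", "global_force"]

_AREA_FLOOR = 1e-10


@dataclass(frozen=True)
class GlobalStats:
    """Foreground / background mean intensities."""

    m: float
    n: float


def global_means(I: np.ndarray, phi: np.ndarray, eps: float) -> GlobalStats:
    """Soft region means ``m = sum(I H)/sum(H)``, ``n = sum(I (1-H))/sum(1-H)``."""
    I = np.asarray(I, dtype=float)
    h = heaviside_eps(phi, eps)
    a_in = float(h.sum())
    a_out = float((1.0 - h).sum())
    if a_in < _AREA_FLOOR or a_out < _AREA_FLOOR:
        raise DegenerateRegionError(
            "global region mean undefined: soft interior/exterior area vanished"
        )
    m = float((I * h).sum() / a_in)
    n = float((I * (1.0 - h)).sum() / a_out)
    return GlobalStats(m=m, n=n)


def global_energy(I: np.ndarray, phi: np.ndarray, stats: GlobalStats, eps: float) -> float:
    """Sum of ``H (I-m)^2 + (1-H) (I-n)^2`` over all pixels (unit pixel area)."""
    I = np.asarray(I, dtype=float)
    h = heaviside_eps(phi, eps)
    return float((h * (I - stats.m) ** 2 + (1.0 - h) * (I - stats.n) ** 2).sum())


def global_force(I: np.ndarray, stats: GlobalStats) -> np.ndarray:
    """Per-pixel descent velocity ``-(I-m)^2 + (I-n)^2``.

    Algebraically identical to ``(m-n)(2I-m-n)``.  Returned without the
    smoothed delta and the ``alpha`` weight; the evolver applies both.
    """
    I = np.asarray(I, dtype=float)
    return -((I - stats.m) ** 2) + (I - stats.n) ** 2
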