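"""Baseline segmenters: pure-global (Chan-Vese style) and pure-local flows.

``cv_evolve`` is a deliberately self-contained implementation of the
piecewise-constant two-phase flow

    dphi/dt = delta_eps(phi) [ mu div(grad phi/|grad phi|)
                               - (I - c1)^2 + (I - c2)^2 ]

with the region constants ``c1``/``c2`` recomputed from the current phi each
iteration.  It duplicates the Heaviside/delta/curvature arithmetic on
purpose: agreement with ``evolve(beta=0, omega=mu)`` to machine precision
cross-validates both code paths.  ``mu`` here plays exactly the role of the
hybrid model's length weight ``omega``.

``local_evolve`` is the hybrid flow with the global weight forced to zero —
a configuration wrapper, independent only in that sense.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import NumericalInstabilityError
from .evolve import EnergyRecord, EvolutionResult
from .levelset import GRAD_ETA, HybridParams

__all__ = ["cv_step", "cv_evolve", "local_evolve"]


def _cv_heaviside(z, eps):
    return 0.5 * (1.0 + (2.0 / math.pi) * np.arctan(z / eps))


def _cv_delta(z, eps):
    return (eps / math.pi) / (eps * eps + z * z)


def _cv_grad(f):
    p = np.pad(f, 1, mode="edge")
    return (
        0.5 * (p[2:, 1:-1] - p[:-2, 1:-1]),
        0.5 * (p[1:-1, 2:] - p[1:-1, :-2]),
    )


def _cv_curvature(phi):
    fy, fx = _cv_grad(phi)
    mag = np.sqrt(fy * fy + fx * fx + GRAD_ETA * GRAD_ETA)
    dyy, _ = _cv_grad(fy / mag)
    _, dxx = _cv_grad(fx / mag)
    return dyy + dxx


def _cv_means(I, phi, eps):
    h = _cv_heaviside(phi, eps)
    c1 = float((I * h).sum() / h.sum())
    c2 = float((I * (1.0 - h)).sum() / (1.0 - h).sum())
    return c1, c2


def cv_step(phi, I, mu, dt, eps):
    """One explicit piecewise-constant update (lambda1 = lambda2 = 1)."""
    c1, c2 = _cv_means(I, phi, eps)
    vel = -((I - c1) ** 2) + (I - c2) ** 2
    fmax = float(np.abs(vel).max())
    if fmax > 0:
        vel = vel / fmax  # unit-max data force, same convention as evolve
    if mu != 0:
        vel = vel + mu * _cv_curvature(phi)
    upd = _cv_delta(phi, eps) * vel
    vmax = float(np.abs(upd).max())
    return phi + dt * upd / vmax if vmax > 0 else phi.copy()


def cv_evolve(
    I: np.ndarray,
    phi0: np.ndarray,
    mu: float = 0.1,
    dt: float = 0.45,
    eps: float = 1.0,
    max_iters: int = 2000,
    tol: float = 1e-4,
    check_every: int = 20,
) -> EvolutionResult:
    """Run the global two-phase flow to label stability.

    Returns the same :class:`EvolutionResult` as the hybrid evolver; the
    trace's local components are zero and ``total = E_global + mu * length``.
    """
    I = np.asarray(I, dtype=float)
    phi = np.asarray(phi0, dtype=float).copy()

    def record(it):
        c1, c2 = _cv_means(I, phi, eps)
        h = _cv_heaviside(phi, eps)
        eg = float((h * (I - c1) ** 2 + (1.0 - h) * (I - c2) ** 2).sum())
        fy, fx = _cv_grad(phi)
        ln = float((_cv_delta(phi, eps) * np.hypot(fy, fx)).sum())
        return EnergyRecord(
            iteration=it,
            total=eg + mu * ln,
            global_=eg,
            local_printed=0.0,
            local_residual=0.0,
            length=ln,
        )

    records = [record(0)]
    prev_mask = phi > 0
    converged = False
    it = 0
    for it in range(1, max_iters + 1):
        phi = cv_step(phi, I, mu, dt, eps)
        if not np.isfinite(phi).all():
            raise NumericalInstabilityError(
                f"non-finite phi in cv_evolve; try a smaller time step (dt={dt})"
            )
        if it % check_every == 0 or it == max_iters:
            mask = phi > 0
            changed = int((mask != prev_mask).sum())
            prev_mask = mask
            records.append(record(it))
            if it % check_every == 0 and changed < tol * phi.size:
                converged = True
                break
    return EvolutionResult(
        phi=phi, mask=phi > 0, energies=records, iterations=it, converged=converged
    )


def local_evolve(I: np.ndarray, phi0: np.ndarray, params: HybridParams) -> EvolutionResult:
    """Hybrid evolution with the global weight forced to zero."""
    from .evolve import evolve

    if params.beta == 0 and params.omega == 0:
        raise ValueError("local_evolve needs beta or omega nonzero")
    return evolve(I, phi0, params.replace(alpha=0.0))
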