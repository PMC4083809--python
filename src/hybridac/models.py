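"""Model / Results interface.

Three model classes share one pattern: construct from an image plus an
initial-contour specification, call :meth:`fit`, get a
:class:`SegmentationResult` holding the final level set, the binary mask,
the energy trace and convergence diagnostics.

>>> from hybridac import HybridActiveContour, phantoms
>>> img, truth = phantoms.make_phantom(phantoms.default_suite()[0].spec)
>>> res = HybridActiveContour(img, init="circle:26,33,12").fit()
>>> res.score(truth).dice  # doctest: +SKIP
0.99...
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .baselines import cv_evolve, local_evolve
from .evolve import EvolutionResult, evolve
from .levelset import HybridParams, init_levelset
from .metrics import SegScore, seg_score

__all__ = ["SegmentationResult", "HybridActiveContour", "ChanVese", "LocalRegion"]


class SegmentationResult:
    """Outcome of one contour evolution."""

    def __init__(self, model: "ActiveContourModel", result: EvolutionResult):
        self.model = model
        self._result = result

    # -- direct views -------------------------------------------------
    @property
    def phi(self) -> np.ndarray:
        return self._result.phi

    @property
    def mask(self) -> np.ndarray:
        return self._result.mask

    @property
    def iterations(self) -> int:
        return self._result.iterations

    @property
    def converged(self) -> bool:
        return self._result.converged

    @property
    def records(self):
        return self._result.energies

    @property
    def energies(self) -> pd.DataFrame:
        """Energy trace as a DataFrame (one row per checkpoint)."""
        return pd.DataFrame([r.as_dict() for r in self._result.energies])

    # -- diagnostics ---------------------------------------------------
    def score(self, reference) -> SegScore:
        """Overlap metrics against a reference mask."""
        return seg_score(self.mask, reference)

    def summary(self, reference=None) -> str:
        """Plain-text run summary, optionally scored against a reference."""
        first, last = self.records[0], self.records[-1]
        lines = [
            f"{type(self.model).__name__} segmentation",
            "=" * 40,
            f"image shape:        {self.model.image.shape}",
            f"parameters:         {self.model.describe_params()}",
            f"iterations:         {self.iterations}",
            f"converged:          {self.converged}",
            f"foreground pixels:  {int(self.mask.sum())}",
            f"total energy:       {first.total:.6g} -> {last.total:.6g}",
            f"global term:        {first.global_:.6g} -> {last.global_:.6g}",
            f"local (separation): {first.local_printed:.6g} -> {last.local_printed:.6g}",
            f"local (residual):   {first.local_residual:.6g} -> {last.local_residual:.6g}",
            f"length term:        {first.length:.6g} -> {last.length:.6g}",
        ]
        if reference is not None:
            s = self.score(reference)
            lines += [
                f"dice:               {s.dice:.4f}",
                f"jaccard:            {s.jaccard:.4f}",
                f"hausdorff:          {s.hausdorff:.2f} px",
            ]
        return "\n".join(lines)

    def plot(self, ax=None, truth=None):
        """Overlay the final (and initial) contour on the image."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.imshow(self.model.image, cmap="gray", vmin=0, vmax=1)
        ax.contour(self.model.phi0, levels=[0.0], colors="deepskyblue", linewidths=1)
        ax.contour(self.phi, levels=[0.0], colors="lime", linewidths=1.5)
        if truth is not None:
            ax.contour(np.asarray(truth, float), levels=[0.5], colors="red",
                       linestyles="dotted", linewidths=1)
        ax.set_axis_off()
        return ax

    def save(self, outdir) -> dict:
        """Write mask.png, phi.tif and trace.csv under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "mask": outdir / "mask.png",
            "phi": outdir / "phi.tif",
            "trace": outdir / "trace.csv",
        }
        _io.save_mask(paths["mask"], self.mask)
        _io.save_phi(paths["phi"], self.phi)
        _io.save_trace(paths["trace"], self.records)
        return paths


class ActiveContourModel:
    """Shared construction: image + initial contour."""

    def __init__(self, image, init, c0: float = 2.0, invert_init: bool = False):
        image = np.asarray(image, dtype=float)
        if image.ndim != 2:
            raise ValueError("image must be 2-D grayscale")
        self.image = image
        if isinstance(init, np.ndarray) and init.dtype != bool and np.any(init < 0):
            self.phi0 = np.asarray(init, dtype=float)  # a level set was given
        else:
            self.phi0 = init_levelset(image.shape, init, c0=c0, invert=invert_init)

    @classmethod
    def from_file(cls, path, init, **kw):
        return cls(_io.load_image(path), init, **kw)

    def describe_params(self) -> str:  # pragma: no cover - overridden
        return ""

    def fit(self) -> SegmentationResult:  # pragma: no cover - overridden
        raise NotImplementedError


class HybridActiveContour(ActiveContourModel):
    """Hybrid global + local + length evolution (the full model)."""

    def __init__(self, image, init, params: HybridParams | None = None,
                 invert_init: bool = False, **kw):
        if params is None:
            params = HybridParams(**kw)
        elif kw:
            params = params.replace(**kw)
        self.params = params
        super().__init__(image, init, c0=params.c0, invert_init=invert_init)

    def describe_params(self) -> str:
        p = self.params
        return (f"alpha={p.alpha} beta={p.beta} omega={p.omega} dt={p.dt} "
                f"eps={p.eps} r={p.r}")

    def fit(self, **overrides) -> SegmentationResult:
        params = self.params.replace(**overrides) if overrides else self.params
        return SegmentationResult(self, evolve(self.image, self.phi0, params))


class ChanVese(ActiveContourModel):
    """Independent global two-phase baseline (piecewise-constant flow)."""

    def __init__(self, image, init, mu: float = 0.1, dt: float = 0.45,
                 eps: float = 1.0, max_iters: int = 2000, tol: float = 1e-4,
                 check_every: int = 20, c0: float = 2.0, invert_init: bool = False):
        super().__init__(image, init, c0=c0, invert_init=invert_init)
        self.mu, self.dt, self.eps = mu, dt, eps
        self.max_iters, self.tol, self.check_every = max_iters, tol, check_every

    def describe_params(self) -> str:
        return f"mu={self.mu} dt={self.dt} eps={self.eps}"

    def fit(self) -> SegmentationResult:
        return SegmentationResult(
            self,
            cv_evolve(self.image, self.phi0, mu=self.mu, dt=self.dt, eps=self.eps,
                      max_iters=self.max_iters, tol=self.tol,
                      check_every=self.check_every),
        )


class LocalRegion(HybridActiveContour):
    """Pure-local baseline: the hybrid flow with the global weight at zero."""

    def __init__(self, image, init, params: HybridParams | None = None,
                 invert_init: bool = False, **kw):
        super().__init__(image, init, params=params, invert_init=invert_init, **kw)
        self.params = self.params.replace(alpha=0.0)

    def fit(self, **overrides) -> SegmentationResult:
        params = self.params.replace(**overrides) if overrides else self.params
        return SegmentationResult(self, local_evolve(self.image, self.phi0, params))
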