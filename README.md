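# hybridac

Level-set segmentation of 2-D grayscale images with a **hybrid
global/local region energy** — built for the situation, ubiquitous in
medical imaging, where a smooth intensity bias (nonuniform illumination,
coil shading, X-ray thickness variation) makes parts of the background
brighter than parts of the object, so that neither a purely global nor a
purely local region model segments reliably on its own.

## The model

A closed contour *C* is the zero set of a field φ (φ > 0 inside). The
segmentation minimizes

```
E(φ) = α E_global + β E_local + ω L(φ)
```

* **Global term** (piecewise-constant fitting): with m, n the mean
  intensities inside/outside the contour,
  `E_global = Σ H(φ)(I−m)² + (1−H(φ))(I−n)²`. It captures objects anywhere
  in the image but fails under intensity inhomogeneity.
* **Local term**: a binary ball B(x,y) = 1(‖x−y‖ < r) restricts the same
  statistics to a radius-r neighbourhood of every pixel, giving local
  interior/exterior means u_x, v_x with soft areas A_u, A_v. The resulting
  force at a pixel compares how well nearby contour pixels fit that ball's
  interior vs exterior model, `Σ_y B δ(φ(y)) [(I−v_x)²/A_v − (I−u_x)²/A_u]`,
  and is insensitive to smooth bias because both means shift together.
* **Length term** `L = Σ δ(φ)|∇φ|` penalizes contour length, keeping the
  contour smooth under noise.

All region integrals use the arctangent-smoothed Heaviside
`H_ε(z) = ½(1 + (2/π) atan(z/ε))` and its derivative
`δ_ε(z) = ε/(π(ε²+z²))`. The gradient flow is stepped explicitly with the
velocity field normalized to unit maximum, so `dt` (default 0.45) is the
largest per-iteration change of φ; every local quantity is evaluated by
FFT correlation with the ball stencil, with a brute-force double-loop twin
kept as test oracle. Two baselines ship alongside: the pure-global
two-phase flow (an independent implementation, cross-validated against the
hybrid at β = 0 to machine precision) and the pure-local flow (α = 0).

## Worked example

The package generates its own benchmark imagery. The `three_objects`
phantom is a 79×75 scene — a disc, a rectangle and an ellipse on a darker
background — corrupted by a linear bias ramp of amplitude 0.4 (strong
enough that the brightest background exceeds the dimmest object) and
Gaussian noise (σ = 0.03):

```python
from hybridac import HybridActiveContour, ChanVese, phantoms

item = [x for x in phantoms.default_suite() if x.name == "three_objects"][0]
image, truth = phantoms.make_phantom(item.spec)

res = HybridActiveContour(image, item.init, params=item.params).fit()
print(res.summary(truth))
```

prints

```
HybridActiveContour segmentation
========================================
image shape:        (79, 75)
parameters:         alpha=1.0 beta=1.0 omega=0.1 dt=0.45 eps=1.0 r=9.0
iterations:         400
converged:          True
foreground pixels:  1996
total energy:       1394.68 -> 68696.6
global term:        308.681 -> 78.9743
local (separation): 1081.78 -> 68615.8
local (residual):   126.067 -> 47.3624
length term:        42.2778 -> 18.3441
dice:               0.9995
jaccard:            0.9990
hausdorff:          1.00 px
```

The hybrid contour converges in 400 iterations with Dice 0.9995 against
the ground truth. Both local readings are reported: the mean-*separation*
energy grows as the contour locks onto contrasted boundaries (separation
is a reward, not a cost), while the local fitting *residual* — the
quantity the local force actually descends — drops from 126 to 47. On the
same input the global baseline leaks along the bias ramp
(`ChanVese(image, item.init, mu=0.1, max_iters=3000).fit()` reaches Dice
0.9847) and the pure-local flow, started from the same off-object circle,
gets trapped near its initialization (Dice ≈ 0.17).

The same runs are available from a shell:

```
hybridac phantom --suite-item three_objects --out-dir ph
hybridac segment ph/image.tif --init circle:39,44,25 --ref-mask ph/mask.png --out-dir seg
hybridac bench --out bench.csv      # 6 phantoms x 3 models table
```

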