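# Methods

## Model

The segmenter evolves a level-set field φ on the pixel grid (unit pixel
area, (row, col) indexing, φ > 0 inside the contour) to minimize

E(φ) = α·E_global + β·E_local + ω·L(φ),

with all region memberships expressed through the arctangent-smoothed
Heaviside H_ε and its derivative δ_ε. H_ε has global support: every pixel
carries a little of both phases, which is what allows the flow to capture
objects far from the current contour, at the price of softly blended
statistics (see *Numerical choices*).

**Global term.** Two-constant fitting over the whole image with soft
means m (interior) and n (exterior). Its descent force at a pixel is
−(I−m)² + (I−n)² ≡ (m−n)(2I−m−n): positive where the intensity is closer
to the interior constant.

**Local term.** A binary Euclidean ball B of radius r (strict inequality
on pixel-center offsets, window side 2⌈r⌉+1) localizes the same
statistics around every pixel: u_x, v_x are the ball-restricted
interior/exterior means, A_u, A_v the soft areas (A_u + A_v equals the
ball size identically). The force at the evolving pixel x samples the
near-contour pixels of its own ball,

F(x) = Σ_y B(x,y) δ_ε(φ(y)) [ (I(y)−v_x)²/A_v(x) − (I(y)−u_x)²/A_u(x) ],

so a pixel is pulled inside when the contour activity near it fits the
ball's interior model better than its exterior model. The δ-weight inside
the sum is essential and deliberate: balls lying entirely in one phase
have tail-dominated, meaningless statistics with soft areas of only a few
pixels, and without the weight their 1/A factors poison the force field
(we measured the advancing front stalling several pixels short of true
boundaries under the unweighted reading). With the weight, such balls see
almost no contour and contribute almost nothing. Degenerate denominators
(soft area < 1e-10) are flagged and contribute zero.

**Two local energies are reported.** The mean-separation reading
Σ_x W(x)(u_x−v_x)² (W = in-domain ball size) *rewards* separation — it
grows as the contour locks onto contrasted boundaries and is reported as
a diagnostic. The quantity the local force actually descends is the
area-normalized local fitting residual
Σ_x Σ_y B [H(y)(I−u_x)²/A_u + (1−H(y))(I−v_x)²/A_v]. Every energy trace
records both, so the ambiguity between the two readings is observable
rather than hidden; descent tests use the residual.

**Length term.** L = Σ δ_ε(φ)|∇φ| with central differences; its variation
contributes ω·δ_ε(φ)·div(∇φ/|∇φ|), the mean-curvature flow that removes
noise-induced speckle components.

## Time stepping

Explicit forward Euler. Each data force (global, local) is first scaled
to unit maximum magnitude — the raw local force carries 1/ball-area
factors that would otherwise leave it orders of magnitude weaker than the
global force, making the advertised regime "α ≈ β, both in [0, 2]"
meaningless — then the combined update δ_ε(φ)·(α·Ĝ + β·F̂ + ω·κ) is itself
normalized to unit maximum and scaled by dt. Thus dt (default 0.45) is
exactly the largest per-iteration change of φ, the scheme is scale-free
in the image intensities, and |φ| can grow by at most dt per iteration
(the stability tests assert |φ| ≤ c0 + dt·iterations over 5000
iterations). This normalization is the convention of the localized
active-contour reference implementations from which the dt = 0.45 default
originates. The statistics (m, n, u, v, A_u, A_v) are recomputed from the
current φ before every step (`stats_every` exposes a cheaper schedule; the
default is 1 and all tests use it).

**Convergence** is declared on label stability: every `check_every` = 20
iterations the number of pixels whose sign changed since the previous
check is compared with tol·N (tol = 1e-4, i.e. 0.01 % of pixels; tol = 0
disables early stopping and runs to the cap). No signed-distance
reinitialization is performed anywhere; φ is a step function initially
(±c0, c0 = 2) and is *not* maintained as a signed distance function.

## Parameters

| name | default | units | role |
|------|---------|-------|------|
| α, β | 1.0, 1.0 | — | weights of normalized global/local forces; 0–2, α ≈ β |
| ω | 0.1 | — | length weight against unit-max data forces |
| dt | 0.45 | φ-units/iter | max per-iteration change of φ |
| ε | 1.0 | φ-units | Heaviside/delta width; 1.0 keeps δ effectively global-support, which helps escape local minima |
| r | 9 | px | ball radius; ~1/10 of the image side for the 60–130 px benchmark images |
| c0 | 2.0 | φ-units | binary initialization magnitude |
| tol, check_every | 1e-4, 20 | — | label-stability stopping rule |

ε and c0 are conventional choices (no principled value exists for this
family of models); r is exposed as `--radius`. Initialization assigns
+c0 to the seed region — the φ>0-inside convention used consistently by
all energies — with an `invert` flag for the opposite choice. Pixels with
φ = 0 exactly are classified outside (a deterministic, measure-zero tie
break). All spatial derivatives use replicate (Neumann) boundaries; the
curvature denominator is floored at η = 1e-8 in quadrature.

Because both two-phase energies are symmetric under swapping the labels,
a seed whose interior is darker than its exterior converges to the
complement segmentation. `orient_levelset` flips a seed so its interior
is the brighter phase; the benchmark seeds are chosen so this holds
already.

## Implementation

Every ball-kernel quantity is a correlation of a per-pixel field with the
binary stencil and is evaluated by FFT (cached kernel transform; explicit
replicate padding so boundaries match the Neumann convention; zero
padding where the in-domain ball is needed). The module keeps brute-force
double-loop implementations of the statistics, both energies and the
force, and the test suite asserts agreement to 1e-8–1e-10 on random
instances up to 32×32 — the FFT path is never trusted on its own. The
pure-global baseline is an independent implementation (own Heaviside,
means, curvature, loop) and must agree with the hybrid at β = 0 to 1e-12
per step; the pure-local baseline is the hybrid with α forced to 0,
bit-identical by construction. Everything is deterministic: identical
inputs give bit-identical traces.

## Synthetic benchmark

The suite regenerates the *conditions* of the reference imagery — the
original pixel data are not distributable — at the original sizes:

| phantom | size | corruption |
|---------|------|-----------|
| gourd (two overlapping discs) | 59×67 | none |
| noisy gourd | 59×67 | σ = 0.05 noise |
| three objects (disc, rectangle, ellipse) | 79×75 | linear bias 0.4 + σ = 0.03 |
| T-shape | 96×127 | radial illumination 0.3 + σ = 0.02 |
| vessel 1 (sinusoidal tube, width 3–7 px) | 110×111 | linear bias 0.45 + σ = 0.02 |
| vessel 2 | 131×103 | linear bias 0.45 + σ = 0.02 |

Noise is added after the bias and the image clipped to [0, 1] (the
clipping truncates the noise distribution; masks are the pre-corruption
geometry). The three-objects geometry was calibrated to reproduce the
documented qualitative failure modes, not any quantitative figure: the
bias-hot strip is mostly covered by the rectangle (so the unavoidable
above-threshold background is small), the disc sits in the low-bias zone
where it is the dimmest foreground, and the 0.4 ramp makes the brightest
background exceed it. Under these conditions, stable across noise seeds,
the hybrid reaches Dice ≈ 0.999 from an off-object seed circle, the
global baseline leaks along the ramp (≈ 0.98), and the pure-local flow
is trapped near its seed (≈ 0.17). With bias and noise stripped, every
suite geometry is segmentable by the global baseline alone at Dice ≥ 0.98
(tested) — failures on the corrupted versions are therefore attributable
to the corruption.

**What the phantoms do not emulate:** textured tissue, partial-volume
boundary blur, spatially correlated noise, and multiplicative speckle.
Passing this suite shows the model handles smooth additive bias and
moderate i.i.d. Gaussian noise on piecewise-constant scenes; it does not
certify performance on real modality-specific artifacts.

## Known limitations

* **Macroscopic above-threshold background.** When a monotone bias lifts
  a *large, locally homogeneous* background region above the global
  threshold, no ball-restricted statistic can reject it: its false
  boundary has no local contrast, and the global term actively retains
  it. The vessel phantoms are deliberately in this regime (the bias makes
  background near one end brighter than the vessel at the other), and all
  three models score Dice ≈ 0.15–0.2 there while still satisfying
  energy descent, stability and determinism. Real vessel images are
  usually milder: their bright-background patches are small.
* **Nonconvexity.** The energy has local minima; results depend on the
  seed contour. The pure-local flow is the extreme case — it only moves
  where balls see the current contour, so seeds must lie within about r
  of the true boundary.
* **Polarity.** The seed interior must be the brighter phase (or
  `invert`/`orient_levelset` used); otherwise the complement is found.
* No narrow-band optimization, no reinitialization, no 3-D support —
  full-field updates on ≤ 131×103 images are already interactive-speed
  via the FFT path.
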