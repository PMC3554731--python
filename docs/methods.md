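# Methods

## Model

A micrograph is segmented by minimizing the joint convex energy

```
E(u, t) = TV(u) + μ ⟨u, s⟩ + λ ‖t‖₁ + (α/2) ‖u − D t‖₂²,
0 ≤ u ≤ 1,   0 ≤ t ≤ 1,
```

over the relaxed labeling `u` and the atom-coefficient stack `t` (one
map per dictionary radius). The pieces:

* **Data term.** `s(x) = (c₁ − f(x))² − (c₂ − f(x))²` is the classic
  region-based (active contour without edges) force: negative where the
  pixel resembles the expected foreground intensity `c₁`, positive where
  it resembles the background `c₂`. Both constants are estimated per
  image as the class means of an Otsu split of the preprocessed image.
  Because they are fixed during optimization, the energy is convex; the
  relaxation of the binary labeling to [0, 1] makes any threshold of the
  minimizer in (0, 1) a global minimizer of the binary problem, so the
  result is independent of initialization.
* **Shape prior.** `D` synthesizes a segmentation-shaped field from the
  coefficients: each coefficient map is convolved (zero-padded) with a
  binary closed-disk kernel of its radius and the results are summed.
  Because the superposition is a plain sum, two overlapping disks produce
  values above 1 and are penalized by the quadratic term — a pixel can
  belong to only one nucleus. The `ℓ₁` norm of `t` is the convex
  surrogate of the atom count; the quadratic coupling replaces the hard
  constraint `u = D t`, tolerating mild deviations from disk shape and
  partial overlap.

### Discretization

Fields are float64 arrays on a pixel grid, (row, col) indexed, pixel
centers on the integer lattice. The gradient uses forward differences
with a Neumann (replicate) boundary; TV is isotropic. Disk membership is
`distance ≤ r` (closed disk, ties inside). Physical radii in micrometres
are converted to pixels through the per-image pixel size before the
dictionary is built. Grids of at most 64 px a side use exact direct
convolution; larger grids use FFT convolution.

## Optimization

The energy is minimized by block alternation (default at most 300 outer
iterations, stopping when the relative energy change drops below 1e-5):

* **u-update** (30 inner iterations per outer): primal-dual
  (Chambolle–Pock) iterations on the exact u-subproblem with step sizes
  τ = 0.25, σ = 0.5 (τσ‖∇‖² ≤ 1), warm-starting the dual field across
  outer iterations. The box constraint enters as a projection inside the
  proximal step — the exact proximal map of a barrier that is flat inside
  [0, 1] and grows outside. The returned iterate is accepted only if the
  exact subproblem energy did not increase, so the outer energy trace is
  non-increasing by construction.
* **t-update** (10 sweeps per outer): proximal-gradient sweeps
  `t ← clip(t − τ (α Dᵀ(Dt − u) + λ), 0, 1)` — a soft-threshold whose
  out-of-bound solutions are clipped to the nearer bound, which is the
  exact scalar rule because the quadratic is monotone on any interval
  excluding its extremum. Steps backtrack from an aggressive
  `1/(2α‖D‖₁)` down to the safe majorization step `1/(α‖D‖₁²)`
  (`‖D‖₁ = Σ_r` atom areas bounds the operator norm), accepting only
  non-increasing subproblem energies.

Degenerate (constant) images short-circuit to an empty segmentation with
a warning. Non-convergence returns the best iterate flagged
`converged=False`. Bounds on `u` and `t` hold exactly at every iterate
(they are produced by clipping), and the energy trace is checked
non-increasing to 1e-9 relative in the tests.

The u-update is implemented with a primal-dual scheme rather than a
smoothed-TV Newton root-finder: the standard solver family for this
convex TV model, it needs no gradient-magnitude smoothing constant and
has no spurious stationary points. (A lagged-diffusivity Newton variant
was evaluated first; at a flat start its linearized diffusivity `1/ε`
over-smooths the forcing and can lock the iteration at `u ≡ 0`.)

## Defaults and rationale

| parameter | default | meaning / rationale |
|---|---|---|
| `mu` | 2.0 | data-term weight; large enough that a blurred nucleus interior outweighs its TV perimeter plus the coupling cost while `t` is still growing |
| `alpha_coupling` | 0.5 | weight of the `u = Dt` relaxation; stronger values bind the contour tighter to the disk model |
| `lambda_sparsity` | `0.05 · median atom area · α` | prices one full atom at 5% of its coupling benefit; an atom activates where the mean residual over its support exceeds 0.05 |
| `u_threshold` | 0.5 | any level in (0, 1) yields a global minimizer; 0.5 is the convention |
| `norm_radius` | `4 × r_max` (px) | local-max normalization window; must contain at least one nucleus at benchmark densities (≈ 5 · 10⁻⁴ nuclei/px²), which 1–2 nucleus radii do not guarantee |
| `epsilon` | 0.25 | floor on the local max as a fraction of the global max, so nucleus-free neighborhoods are not amplified to full brightness |
| `gamma` | 2.0 | suppresses faint residual staining (apoptotic debris) after normalization |
| dictionary step | 1 px | radius discretization of the size interval |
| `closing_radius` | 2 px | merges fragments of one nucleus in the binarized coefficient image |
| `clutter_opening_radius` | `1.5 × r_max` | structuring element strictly larger than any legal nucleus, so the opening isolates oversized clutter only |
| match radius | 3.2 µm | detection-to-truth matching distance (pixel fixtures use 1 µm/px) |

Detection tie rules are fixed for determinism: dominant radius ties go to
the smaller radius; candidate score ties to the larger component, then
row-major centroid order. Matching is one-to-one, closest pairs first,
hence independent of input order; in adversarial geometry this greedy
rule can fall below the maximum-cardinality assignment, but on the
well-separated point sets nuclei produce it agrees with the exhaustive
oracle (verified in tests).

## Synthetic benchmark

The generator emulates the degradations that make real DAPI micrographs
hard: nuclei as filled disks at `fg_level` 0.8 over `bg_level` 0.1, a
configurable fraction placed as touching pairs (center distance in
`(r_i + r_j − 2, r_i + r_j)`: boundary contact, < 2 px overlap, all
other pairs separated by > `r_i + r_j + 4`), a multiplicative linear
illumination ramp (default 30% drop across the diagonal), oversized
bright clutter disks (default one blob at 2 × r_max, mimicking apoptotic
debris), Gaussian blur (σ = 2 px) and additive Gaussian noise
(σ = 0.05), clipped to [0, 1]. All randomness flows from one explicit
seed; samples are bit-reproducible. Low-exposure acquisitions can be
emulated by shrinking `fg_level − bg_level` and raising `noise_sd`; shot
noise is not modeled.

The default configuration — 256×256 px, 30 nuclei of radius 10 px, 30%
touching — matches the density of public synthetic nuclei benchmarks
(about 3–5 · 10⁻⁴ nuclei/px²). What passing on it shows: separation of
touching pairs, robustness to the illumination ramp, blur, moderate
noise and oversized clutter, and correct radius recovery. What it does
not show: performance on irregular (non-disk) nucleus shapes, textured
nuclei, dye smears, bleed-through, or chains of three and more nuclei at
high density — real-data claims need real annotated images, which the
CLI consumes directly (TIFF in, CSV out).

Dice on the suite (~0.85) is structurally below 1 even for perfect
detection: the truth mask is the pre-blur union of disks, while the
segmentation follows the blurred boundaries and (correctly, as far as
the energy is concerned) labels the bright clutter blob as foreground;
clutter is rejected later, in the detection chain, not in `u`.

## Known limitations

* Nuclei are modeled as disks; strongly elongated (e.g. horseshoe-shaped
  neutrophil) nuclei violate the prior and may be split or mis-sized.
* The greedy suppression uses only the accepted candidate's dominant
  radius, as specified — not the sum of both radii — so two accepted
  detections can in principle lie closer than the sum of their radii.
* `c₁, c₂` come from a global Otsu split; images whose foreground is a
  tiny area fraction with a heavy-tailed background may need explicit
  intensities.
* The quadratic relaxation never enforces `u = Dt` exactly; `λ` and `α`
  trade segmentation fidelity against decomposition sparsity, and very
  small nuclei (radius ≲ 2 × blur σ) lose the contrast the data term
  needs.
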