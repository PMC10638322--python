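# Methods

## The model

`numercode` implements a rate-based recurrent network account of visual
numerosity perception.  The network is a single layer of `N = 64` units
arranged conceptually as an 8×8 grid.  Every unit excites itself with
strength `α` and inhibits every other unit with strength `β` (an
on-center/off-surround architecture).  Unit activations `x_i ≥ 0` evolve
by explicit Euler steps of

    dx_i/dt = −λ x_i + α F(x_i) − β Σ_{j≠i} F(x_j) + I_i + ξ_i

with the saturating transfer function

    F(x) = x / (1 + x)   for x > 0,   F(x) = 0 otherwise,

per-unit, per-step Gaussian noise `ξ_i ~ N(0, 0.03²)`, and an external
current `I_i = 1` injected into the first `k` units for the first 100 of
5000 steps.  `k` — the *set size* — is the model's representation of
stimulus numerosity.  The scalar readout is the steady-state mean
activation `MA = (1/N) Σ_i x_i` of the final state.

**Rectification.**  After every Euler step the state is clipped at zero.
Activations are firing rates and cannot be negative; without the clip,
mutual inhibition drives every silent unit to a large negative value
(−βkF(x_active)/λ) and, because 59–63 of 64 units are silent in any
coded state, the network mean becomes negative and no longer carries any
set-size information.  The closed-form steady states used as test
oracles are provided in both conventions
(`analytic_fixed_point(..., rectified=...)`).

**Why MA encodes number, and only locally.**  In the noise-free
symmetric state with `k` active units, each sits at
`x* = (α − β(k−1))/λ − 1`, so `MA(k) = k·x*/N` is an inverted parabola
in `k` peaking at `k* = (α + β − λ)/(2β)`.  Strong inhibition
(β = 0.15) therefore rises only over the first few set sizes; weak
inhibition (β = 0.01) rises across the whole 1–50 range.  Two noise
phenomena shape the curves away from this closed form: *spontaneous
ignition* (at weak inhibition the rest state is unstable, so noise
ignites undriven units until their mutual inhibition self-limits the
ignited count — this produces the elevated, slowly *decreasing* MA at
small set sizes for weak β) and *winner collapse* (beyond the stability
limit of the symmetric state, a subset of winners survives, producing
the plateau past the peak at strong β).

## Parameters

| parameter | default | meaning / provenance |
|---|---|---|
| `N` | 64 | units, 8×8 object-location grid |
| `α` | 2.2 | self-excitation; held fixed (does not change curve shapes qualitatively) |
| `β` | 0.01–0.15, step 0.01 | mutual inhibition, the one adaptable parameter |
| `λ` | 1.0 | decay per unit time; the only value that makes the stated α and β grid produce the published range structure (see "Known limitations") |
| noise sd | 0.03 | per unit, per step, mean 0 |
| presentation | 100 steps | input current 1 on the driven units |
| horizon | 5000 steps | Euler steps, `dt = 1` per step |
| ensemble | 30 runs | per (set size, β) condition |
| readout window | 1 step | MA of the final state (a trailing-window average is available but not default) |

Reproducibility: every (set size, β, run) triple draws noise from its
own `numpy` `SeedSequence`-derived stream keyed on the physical
condition, so a sweep cell is bit-identical to a standalone ensemble at
the same seed, regardless of batching, and re-runs are byte-identical.

## Encoding, decoding, ranges, selection

1. **Sweep** — ensemble MA for every set size 1–50 × 15 strengths.
2. **Monotonic regions** — per strength, the longest contiguous run of
   strictly increasing ensemble MA.  On ensemble data two noise guards
   qualify a run as an *encoding* region: its total rise must exceed 3
   standard errors of an MA difference (√2·median sd/√30), and
   leading/trailing steps smaller than 2 such standard errors are
   trimmed.  Without the guards, chains of sub-noise up-ticks on the
   post-peak plateau can out-length the genuine rise (observed at some
   seeds for β = 0.15), which no reader of the MA curve would call an
   encoding region.  Both guards default to 0 in the low-level API.
3. **Codebook** — ordinary least squares of MA on set size over each
   region; only positive slopes are kept, so the inverse map exists.
4. **Decoding** — `estimate = (MA − intercept)/slope`, real-valued,
   deliberately unclamped: out-of-region decodes are exactly the
   mismatch/adaptation experiment.
5. **Range cover** — exact exhaustive search for the subset of regions
   covering 1–50, optimising lexicographically (points covered, fewer
   strengths, larger total region length, larger β on lower intervals).
   Overlaps between chosen regions are cut at the midpoint, the shared
   odd point going to the weaker strength.  The third criterion is a
   deliberate design choice: preferring the longest (most informative)
   regions keeps the middle interval from collapsing to a narrow,
   barely-monotone strength that happens to tile the gap.
6. **Selection Algorithm** — for an input `k`, the local
   finite-difference slope of each candidate strength's MA curve at `k`
   is its sensitivity; the steepest candidate wins (ties to the larger
   β).  Candidates default to the cover's strengths.  The algorithm is
   given the true input set size, as in the original demonstration; the
   circularity (the system cannot know `k` before estimating it) is a
   property of the method being modelled, not resolved here.
7. **Error table / adaptation** — every cell decoded with its own
   strength's inverse fit; signed error = estimate − set size; estimates
   within ±0.5 (half a count) are labelled accurate, otherwise
   under-/over-estimates.

## Object-Location-Map stage

A grayscale saliency map is rescaled to 0–255, thresholded at 30,
connected-component labelled (8-connectivity default, `min_area`
exposed for speckle), and each patch marks the single 8×8 cell holding
its centroid — removing object size and shape by construction.  Active
cells become the driven units (row-major).  Saliency computation itself
is out of scope; the synthetic generator `synth_blob_image` emulates a
saliency map of k spatially separated objects: disk or Gaussian blobs,
peak ≥ 200/255 on a ≤ 10/255 background, pairwise separation ≥ 2r+2 px
and at most one blob per projection cell (objects closer than one grid
cell are unresolvable by an 8×8 occupancy map by construction, so the
generator does not produce them).  What the synthetic fixtures do *not*
emulate: real saliency maps' graded intensities, speckle, halos, or
near-touching objects — pipeline tests on blobs certify the geometry of
the normalization, not robustness to real imagery.

## Numerical choices and degenerate inputs

- Explicit Euler at `dt = 1` is intentionally the model: "time steps"
  are the unit of description (presentation 100, horizon 5000), and the
  saturating `F` keeps the update stable at this step size.  No
  adaptive solver is used.
- Noise is discrete-time: sd 0.03 per step, no √dt scaling.
- All-zero initial state; driven units default to indices `0..k−1`
  (exchange symmetry makes the choice immaterial — verified by test).
- Region detection needs ≥ 2 points; fully decreasing series yield no
  region and the strength is omitted from the codebook with a warning.
- `fit_line` refuses fits with zero set-size spread; decoding a strength
  absent from the codebook raises a `KeyError` naming it.
- Cover search is exact (≤ 15 regions ⇒ ≤ 32768 subsets); ties are fully
  deterministic.
- Two patches whose centroids share a grid cell merge into one active
  cell (logged); the OLM therefore bounds, rather than equals, the patch
  count in pathological scenes.

## Problem sizes

The standard sweep is 50 set sizes × 15 strengths × 30 runs × 5000
steps on 64 units (≈ 2.3·10¹⁰ unit-updates), vectorised over runs and
set sizes; it completes in about 4–5 minutes on one CPU core.  All
other computations (codebook, cover, error table, selection, OLM) are
sub-second.  The test suite runs one full sweep and reuses it across
all steady-state tests.

## Known limitations

- **The published MA scale and the published range boundaries are
  mutually inconsistent under this model class.**  The noise-free peak
  of `MA(k)` at `k* = (α+β−λ)/(2β)` ties the region ends to λ: the
  published region ends (≈ 4 for β = 0.15; monotone to 50 for
  β = 0.01) require λ ≈ 1, while the published worked example
  (MA ≈ 0.53 for k = 5 at β = 0.15, decoding to 4.82) requires
  λ ≈ 0.2 — at which point the β = 0.02 region spans ≈ 8–50 and the
  minimal cover needs only two strengths, destroying the three-range
  partition.  This package fixes λ = 1: the partition, the selection
  behaviour, the error-table structure and the adaptation signs are
  reproduced; the absolute MA values run ≈ 10× smaller than the worked
  example, and decoding the literal value 0.53 through the β = 0.15
  fit yields ≈ 70, not 4.82.
- The weak-inhibition ignition plateau ends near set size 10–14 here
  (≈ 20 in the published curves), so the third interval begins near
  14–17 rather than 21.  The plateau length grows with noise diffusion
  per unit time; discretisations that lengthen it to ≈ 20 (e.g.
  unscaled per-step noise at dt ≈ 0.4) simultaneously prevent any
  strength's region from reaching set size 50.
- The cover's middle strength lands on 0.03 or 0.04 depending on the
  seed (adjacent grid strengths with near-identical regions).
- The "initial guess from continuous visual cues" pathway for choosing
  the inhibition strength is conceptual in the source account and is
  not implemented; nor are reaction-time/switch-cost simulations.
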