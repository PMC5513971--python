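# Methods

## Model

A uniform, omnidirectional landmark constrains the home position only
through its remembered distance.  The single-landmark likelihood is a
circular ridge ("donut") around the landmark:

- **Gaussian variant** — radial profile `exp(−(d − r)²/2σ_c²)`, where `d`
  is the distance of a candidate position to the landmark, `r` the
  remembered home–landmark distance, and `σ_c` the central spread.
- **Mixture variant** — the same central ridge plus a pedestal Gaussian
  centred on the same radius: profile
  `exp(−(d−r)²/2σ_c²) + a·exp(−(d−r)²/2σ_t²)`.

Multi-landmark predictions multiply the per-landmark densities pointwise
and renormalize; the global maximum is the maximum-likelihood home
estimate.  Products are computed in log space so deeply conflicting
likelihoods cannot underflow before their overlap is visible.

**Density convention.** The 2D density is proportional to the radial
profile at the cell's distance — no `2πd` Jacobian is applied — so the
density ridge sits exactly at `d = r`.  This mirrors the construction of
fitting a 1D Gaussian to collapsed distances and mapping it back around
the landmark.  A consequence (see *Calibration*) is that distances of
points drawn from this density follow `φ(d−r)·d`, not `φ(d−r)`.

## Parameters

| parameter | meaning | default | origin |
|---|---|---|---|
| `r` (ridge_radius) | remembered home–landmark distance | fitted (true value 2 m auditory / 6 vm visual) | calibration |
| `σ_c` (sigma_center) | radial spread of the central ridge | fitted | calibration |
| `σ_t` (sigma_tail) | pedestal spread | `max(10·σ_c, 10)` length units | fixed by rule |
| `a` (tail_amplitude) | pedestal peak-height ratio | 0.12 | fixed by rule |

The pedestal parameters are never fitted: the data contain too few
peripheral responses to constrain them, and the predictions are robust to
their exact values as long as the pedestal is low-amplitude and
essentially flat across the workspace.  The floor of 10 length units
keeps it flat even when `σ_c` is small.  Two documented alternative
readings are selectable: `tail_amplitude_mode="weight"` treats the 12% as
a mixture weight on area-normalized components, and
`tail_sigma(..., scale="variance")` reads the "×10" on the variance scale
(`σ_t = √10·σ_c`).  Peak-height and the sigma scaling with the flatness
floor are the defaults, because a pedestal that decays within the
workspace cannot produce the vetoing behavior the mixture exists for.

**Pedestal mass.** With the defaults, the pedestal carries a mass fraction
of roughly `0.12·σ_t/σ_c / (1 + 0.12·σ_t/σ_c)` of each ring (≈55% at
`σ_c = 1`).  Full-distribution moments of the mixture are therefore much
larger than the Gaussian variant's; the two variants agree in the
*location* and local shape of the dominant peak under no conflict, not in
their global covariance.  Quantities that matter for the conflict
analysis (MLE location, modality, mode dominance) are insensitive to
this; global variance comparisons across variants are not meaningful
without stating the workspace.

## Grids

Densities are evaluated on a square grid centred on home with cell size
`σ_c/5` (≥5 cells across the ridge) and half-width
`r + max(6σ_c, 10)`, enlarged when a relocated landmark's central ridge
(`r + 4σ_c` around the landmark) would not fit.  Home falls on a cell
center, which keeps symmetric configurations exactly symmetric after
discretization.  The grid must contain every central ridge (an error
names the required extent); the pedestal may be clipped by the workspace,
which is the intended "covers the experimental space" behavior.
Normalized grids integrate to 1 within 1e−9.

## Calibration (single-landmark condition)

Endpoints are converted to polar coordinates about the landmark and
collapsed onto the distance axis; the sample mean and SD (n−1) of the
distances estimate `r` and `σ_c` (`fit_radial_gaussian` implements this
literal recipe).  Because the collapse picks up the polar area element,
those raw moments are consistent for the *tilted* distance distribution
`φ(d−r)·d`, whose mean is `r + σ²/r` and variance `σ²(1 − σ²/r²)`.
`fit_single_landmark_condition` therefore inverts the tilted moments by a
short fixed-point iteration (the correction is second order in `σ/r`;
it can be disabled with `jacobian_correction=False`).  Without it, the
fitted radius is biased upward by `σ²/r` — 0.17 vm at the default
geometry — which propagates into a measurable over-prediction of the
2-landmark variance.  Fits pool all participants by default; a
per-participant mode exists and is used for the slope analyses and the
paired model-vs-data tests.

## Prediction summaries

From the normalized product density we report:

- `mle` — global argmax (ties: lowest row-major index, deterministic);
- `expected_accuracy` — mean distance to home under the density, and
  `mle_accuracy`, the distance of the MLE itself to home;
- `total_variance` — trace of the density covariance; ellipse areas
  `π·σ_major·σ_minor` (SD ellipse) and `π·χ²₂(0.95)·√det Σ` (95% ellipse);
- `modes` — 8-neighborhood local maxima at ≥50% of the global maximum,
  with discretization plateaus deduplicated by connected grouping;
  modality is unimodal/bimodal/multimodal by mode count.  Local maxima
  (rather than connected super-threshold regions) are used because two
  genuine peaks can be joined by a saddle channel above half maximum
  when `σ_c/r` is not small; a single-landmark ring legitimately reports
  many modes.

## Relocation sweep

The conflict experiment relocates the apex landmark of the trained
triangle by 0, 1.5, 3, 4.5, 6 vm along the direction orthogonal to (and
away from) the other two.  Rings are always centred on the *test*
positions with the *trained* (fitted) radius.  Breakdown is detected when
the mixture MLE comes within `2σ_c` of the stationary-pair ring
intersection on the deviant side (the trained home) while sitting more
than `2σ_c` from the integrated compromise point (the least-squares
intersection of all three distance constraints, computed independently by
Nelder–Mead).  The breakdown relocation is a function of `σ_c`; at the
generator default `σ_c = 1` vm it falls between 3 and 4.5 vm.  The
retained mode on the deviant landmark's side always carries more density
than its mirror, because the deviant's pedestal is asymmetric across the
stationary pair — the vetoed landmark still disambiguates.

## Synthetic participants

The generator is an ideal observer: each participant `k` receives a
spread `σ_k = σ_base·exp(ε_k)`, `ε_k ~ N(0, 0.2)` (lognormal around
`σ_base = 1` length unit — the study reports no per-participant spreads,
so this population is a stated emulation choice), and that participant's
endpoints in every condition are drawn from the model density of that
condition (cell sampled by mass, position jittered uniformly within the
cell).  Participant streams are independent and reproducible:
participant `k` depends only on `(seed, k)`.

Default designs mirror the study: 10 participants × 3 conditions × 40
trials (landmarks at 2 m auditory / 6 vm visual), and 5 relocation
conditions × 40 trials plus a single-landmark calibration condition.
No-conflict conditions are generated from the *gaussian* ridge: empirical
response clouds in such conditions are clean rings/clusters, and the
pedestal is a modelling device for conflict, not a feature of response
scatter (a mixture-generated cloud would put over half its endpoints in a
uniform halo and break the collapse calibration).  Relocation conditions
are generated from the mixture density, since only it contains the
breakdown structure.  An optional confusion mode (`p_confusion`) emulates
the auditory segmentation failure by answering some 3-landmark trials
from a random landmark-pair density; it is off by default.

The generator emulates endpoint statistics only: no trajectories,
learning dynamics, release points, or sensory noise models.  Passing
tests therefore demonstrate internal consistency of the
calibrate-predict-compare loop under the model's own assumptions, not
that human data would match.

## Statistics

Accuracy is the mean Euclidean distance of responses to home; precision
is the spread about the response mean (covariance trace, SD-ellipse and
95%-covariance-ellipse areas; the 95% ellipse uses the χ² quantile
convention rather than a data-quantile hull).  Per-participant regression
slopes are ordinary least squares on the three (landmark count, condition
mean) pairs.  One-sample and paired t-tests use n−1 degrees of freedom
and two-sided p-values unless a tail is requested; a zero-variance sample
with nonzero mean is an error, all-zero differences give t = 0, p = 1.

Model-vs-data comparisons pair *per-participant* parameter-free
predictions (each from that participant's own calibration fit) with
per-participant (experiment 1) or per-relocation pooled (experiment 2)
empirical summaries.  A pooled prediction would inject its sampling error
as a common offset into every pair — invisible to the paired SE and
measurably anti-conservative — whereas per-participant prediction errors
are independent across pairs and enter the SE correctly.

## Numerical choices and limitations

- Cell size `σ_c/5` bounds the discretization error of all moments well
  below sampling noise at the study's trial counts; the argmax is exact
  on the grid by construction.
- Mixture moments depend on the declared workspace (a flat pedestal has
  no intrinsic scale); generator and predictions use the same grid
  construction so comparisons are consistent.
- The sweep reports the breakdown point on the tested 1.5 vm lattice; the
  underlying transition is continuous in `σ_c` and finer sweeps resolve
  it more precisely.
- Degenerate inputs are rejected with actionable errors: empty endpoint
  sets, <3 distances, zero radial spread (advises a sigma floor), grids
  too small for a ridge, mismatched grids in a product, and all-zero
  products (total conflict).
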