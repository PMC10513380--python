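# Methods

## FRAP recovery model

Curves are analyzed on a min–max normalized scale (pre-bleach ≈ 1, bleach
minimum = 0), matching the normalize-then-fit convention of batch FRAP
analysis. With `t` measured from the bleach frame:

- **whole FRAP** (entire GC bleached): `F(t) = plateau · (1 − e^(−t/τ))`.
  The single constant τ is the nucleoplasmic-exchange time of NPM1.
- **half FRAP** (part of the GC bleached):
  `F(t) = plateau − A₁·e^(−t/τ₁) − A₂·e^(−t/τ₂)`, with τ₂ held fixed to the
  whole-FRAP τ so that the free fast constant τ₁ isolates internal mixing.
  The constraint `A₁ + A₂ = plateau` is enforced by parametrization
  (`plateau ≡ A₁ + A₂`), pinning `F(0) = 0`: min–max normalization makes the
  post-bleach minimum exactly 0, so a free intercept would only absorb noise.

Percent recovery is `100 · plateau`, i.e. the fitted asymptote relative to
the normalized pre-bleach level. An empirical last-frames estimate is easy
to compute from the trajectory but the fitted plateau is the reported
quantity, since fit parameters are what get averaged across cells.

### Fitting

Bounded nonlinear least squares (`scipy.optimize.least_squares`, trust
region reflective). Initialization: `plateau₀` = mean of the last 5 frames,
`τ₀` = time to half of `plateau₀` divided by ln 2. Bounds:
τ ∈ [frame_interval/10, 10 × trace duration], amplitudes ∈ [0, 1.1]; a
parameter landing on a bound sets `converged = False` with a flag rather
than being clipped silently. Up to 5 restarts from jittered initializations
(deterministic RNG) on non-convergence; a flat post-bleach trace is flagged
`degenerate-plateau`.

One genuine degeneracy needs a tie-break: on a curve that is actually a
single exponential with the fixed τ₂, the half-FRAP model has a
zero-residual manifold (τ₁ = τ₂ with arbitrary amplitude split). When the
fitted τ₁ lands within 1% of τ₂ the amplitudes are collapsed onto the slow
component (`A₂ ← A₁ + A₂`, `A₁ ← 0`, flag `components-degenerate`). Real
half-FRAP fits have τ₂ ≥ 5×τ₁ and never trigger the rule.

### Dataset-level protocol

`fit_frap_dataset` fits all whole-FRAP curves first and injects a whole-FRAP
τ into each half fit. Which τ is an open choice — per cell, per condition,
or global; the default is the **per-condition mean** of converged whole
fits, because whole and half bleaches are acquired on different cells, with
per-cell pairing and a global mean available as options.

Bleach alignment pads shorter pre-bleach segments with NaN (never fabricated
frames) up to the latest bleach index; per-frame averages ignore NaNs.
Group comparison is the classical pooled-variance two-sample t test
(two-sided), with Welch's variant behind a flag.

## Immunogold detection

Scale-normalized Laplacian of Gaussian, `σ_px = (d/pixel_size)/(2√2)` — the
standard blob-radius relation `r = σ√2` — signed so dark (gold) blobs give
positive response. Detection threshold defaults to a robust background
estimate, median + 5·MAD of the response map (MAD scaled by 1.4826);
overridable per class. Diameters below `2 × pixel_size` are rejected as
unresolvable.

The two-pass procedure: find 12 nm maxima; keep only maxima whose
scale-normalized response at the 12 nm scale exceeds the 6 nm-scale response
at the same location (scale selection — otherwise the large-scale filter
also fires on small particles); suppress same-class duplicates within one
diameter (highest response wins); exclude a radius around each accepted
12 nm particle (default `1.5 × 6 nm + 3 nm = 12 nm`, configurable — no
published value exists); then detect 6 nm maxima on the remainder. All
exclusion and duplicate distances are open at the boundary (strictly-less
removes); coordinates are 0-based integer pixel centers.

ROI masking happens **after** detection: outside-ROI hits stay inspectable,
densities count `in_roi` particles only, and
`density = count / (mask pixels × pixel_size²)` exactly. Cross-image group
comparison uses per-image densities (mean ± SEM, t test per size class).

## Time-lapse morphometry

Per nucleus and channel, components are segmented by Otsu thresholding
within the nucleus mask (fixed-threshold override available for
reproducibility) and filtered by a minimum size (default 4 px ≈ 0.05 µm² at
0.2 µm/px, to drop noise speckle). A guard rejects "foreground" that is not
at least 4 background-SDs above the background mean, so a channel containing
only noise yields zero components rather than segmented noise islands.

Shape: in 2-D the reported "sphericity" is circularity `4πA/P²` and labeled
as such (the in-vivo metric is 3-D; the desk-scale generator is 2-D — both
formulas are implemented, with `Ψ = π^{1/3}(6V)^{2/3}/S` and a
marching-cubes surface in 3-D). The perimeter is the Crofton estimate
(4 directions): the chain-code perimeter systematically biases the
circularity of small rasterized disks far below the analytic limit, while
Crofton converges (0.88, 0.96, 0.98 at radii 5, 15, 30). Values are clipped
at 1.05 to absorb discretization overshoot; single-pixel components get NaN
sphericity.

Tracking: greedy nearest-centroid linking of nucleus ROIs between
consecutive frames with a displacement gate (default 10 µm/frame); links
beyond the gate are refused, so implausible jumps terminate tracks instead
of swapping identities. Population summaries are per-frame mean with a
t-based 95% CI (`mean ± t₀.₉₇₅,ₙ₋₁·SE`) — t-based rather than normal because
the study-scale populations are ~12–15 cells; single-cell frames are
flagged with an undefined CI.

### Phenotype rule

No quantitative published criterion exists for calling a nucleolus
"fragmented" (such scoring is typically manual), so the classifier is an
explicit, configurable stand-in evaluated at the final frame of each track:

- **fragmented**: ≥ 6 NPM1 components and the largest holds < 50% of total
  NPM1 area — many dispersed puncta, none dominant;
- **condensed**: exactly 1 component with circularity ≥ 0.9;
- **normal** otherwise; cells with no NPM1 signal are *unclassifiable* and
  excluded from denominators.

The cell-level sphericity readout is the area-weighted mean over NPM1
components, so a dominant component dominates the call. Fractions are
`100 · fragmented / classifiable` per condition, with a one-way ANOVA across
conditions on per-replicate percentages.

## Synthetic-data generators

The generators emulate the study conditions and are first-class, tested
code; their defaults are fixed once:

**FRAP** (`sim.frap_sim`): 0.5 s frames, 2 min recovery, 5 pre-bleach
frames, curves generated already normalized with the analytic recovery
expectation plus i.i.d. Gaussian noise per frame (the simplest model
consistent with mean-ROI photon noise after averaging); `noise_sd = 0.02`.
The study prints fast constants (3.33 s control, 9.05 s inhibited) but no
whole-FRAP τ; the package assumes 25 s (control) and 60 s (inhibited),
keeping τ₂ ≥ 5×τ₁ in both regimes and the inhibited exchange slower, as
observed. Amplitudes default to A₁ = 0.5, A₂ = 0.4. Neither the noise level
nor the 20% cell-to-cell τ variability option reflects published values;
recovery-protocol ensembles vary only the noise realization. An optional
affine raw-intensity mode exercises the normalization path.

**EM** (`sim.em_sim`): 512×512 px at 2 nm/px, elliptical nucleolar ROI,
anti-aliased uniform dark disks (no PSF — detection operates on the LoG
response, which is insensitive to fine edge structure at these sizes) on a
Gaussian-textured background (level 200, noise SD 8, contrast 120). Defaults
place 30 × 12 nm and 60 × 6 nm particles inside the ROI and 20 outside
(split ceil-large/floor-small). The 30 nm minimum center separation is
enforced across *all* particles, a superset of the per-class requirement: a
6 nm particle rendered under a 12 nm one is unresolvable by construction and
the exclusion pass would delete it anyway. Placement is rejection sampling;
an unplaceable request raises rather than silently truncating.

**Time-lapse** (`sim.timelapse_sim`): 31 frames at 10 min (5 h), 3 channels,
2-D mosaic of 48 px tiles (0.2 µm/px), one drifting nucleus per tile. NPM1
is an axis-aligned ellipse, UBF/FBL are small disks, so per-frame truth
(counts, area, Ramanujan-perimeter circularity) is analytic. Control cells
are stationary (aspect-2 ellipse, circularity 0.84). Inhibited cells shrink
NPM1 area by 45% and morph aspect 2 → 1 linearly (circularity rises
monotonically to 1) while UBF/FBL puncta pairwise-merge at 0.15/frame
(area-conserving, counts non-increasing). Division dissolves all components
for one frame; afterwards the cell reassembles into one component (round and
smaller when inhibited — the condensed fate) or, with
`fragmentation_probability` per dividing cell, scatters into 8 small NPM1
puncta plus dispersed UBF/FBL. The unsynchronized-inhibition scenario lets
only a fraction of cells divide (default 0.5, division frames random) and
sets the per-divider probability to `marginal_rate / divide_fraction`, so
the population-marginal fragmented fraction equals the study's
unsynchronized rate while the per-divider contract is preserved.

What the generators do **not** emulate: optical PSFs, camera-specific noise,
photobleaching outside the deliberate bleach event, reaction–diffusion FRAP
kinetics, clumped or touching nucleoli, cap-geometry substructure, chromatin
dynamics, z-stacks by default. Passing tests therefore demonstrate that the
computations are correct on data obeying the stated models — parameter
recovery, detection fidelity, classifier accuracy under known truth — not
that the pipelines are robust to every artifact of real microscopy.

## Problem sizes and runtime

Evaluation protocols use 30-curve FRAP ensembles, five 512² EM fields, and
200-cell / 31-frame populations for the fragmentation scenarios (12-cell
populations for tracking fidelity), sizes chosen so the full suite and the
acceptance script each complete in minutes on one CPU while keeping binomial
and Monte-Carlo bounds meaningful. All generators are bit-reproducible for
a fixed seed; pipeline runs derive per-stage sub-seeds from one global seed
via sha256 of `"seed:stage"`.

## Known limitations

- 2-D rendering means the "sphericity" acceptance path exercises
  circularity; the 3-D formula is implemented and tested on rasterized balls
  only.
- The phenotype thresholds (6 components, 50% area fraction, 0.9
  circularity) are package choices, not published values; the recovered
  fragmented fractions are exact on the generator because the generator's
  fragmented state is unambiguous under the rule.
- Otsu within small masks dilates faint blurred objects slightly; absolute
  areas carry a positive bias of order the perimeter × edge width, which
  cancels in ratios (area fractions) and directions but not in absolute
  cross-frame sums — the mass-conservation check uses the fixed
  mid-amplitude threshold for that reason.
- Nearest-centroid tracking has no motion model and will fragment tracks
  under displacements beyond the gate; adequate for tile-confined synthetic
  nuclei and slow-moving adherent cells.
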