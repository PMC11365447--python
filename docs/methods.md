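# Methods

## The two-population mixture model

Both activity assays probe only the outer leaflet of reconstituted vesicles:
dithionite bleaches outer-leaflet NBD-PC, and concanavalin A captures
outer-leaflet mannosylated glycolipid. A vesicle containing at least one
active scramblase equilibrates its probe across the bilayer over the assay,
so its entire probe pool becomes accessible; a vesicle with none behaves
like the protein-free control. The population signal is therefore a
two-component mixture, and the scramblase-positive fraction is

    f = (S_PL − S_L) / (1 − S_L),

where `S` is the bleached (or captured) fraction of the proteoliposome
sample (PL) and the protein-free control (L).

Two deliberate choices:

* **The baseline is empirical, not theoretical.** Ideal symmetric vesicles
  would bleach exactly 50%, but real protein-free preparations typically
  bleach somewhat more (probe asymmetry, slow dithionite permeation, small
  vesicle sub-populations). The formula uses the *measured* control level
  rather than 0.5; the theoretical symmetric value is exposed separately via
  `predicted_capture_fraction`, whose protein-free prediction is exactly
  50%.
* **The formula is a reconstruction.** It is the simplest model consistent
  with complete exposure of positive vesicles and control-like behaviour of
  negative ones, and it reproduces typical published values (57%/80%
  bleaching → 53.5% ≈ 55% positive; 50%/65% capture → 30%). Whether every
  published occupancy analysis uses exactly this expression is not
  verifiable from end-point values alone; the package states its model
  explicitly rather than claiming equivalence to any particular prior
  calculation.

Noise can push `f` slightly outside [0, 1]; such values are clamped with a
warning. Physically impossible inputs (fractions outside [0, 1], a baseline
of exactly 1) raise instead.

## Poisson occupancy and abundance

Reconstitution by detergent removal partitions solubilized protein over
vesicles independently and uniformly, so copies per vesicle are modelled as
Poisson with mean `m`; the positive fraction is `f = 1 − exp(−m)` and the
inverse uses `log1p`/`expm1` for accuracy at small `f`. A brute-force
simulation of 10⁴ Poisson-occupied vesicles agrees with the closed form
within binomial error (property-tested).

Vesicle geometry uses the thin-shell approximation: both leaflets are
counted at the outer radius, `N = 8π(d/2)²/a`. At d = 175 nm and
a = 0.71 nm² this gives 2.71 × 10⁵ lipids per vesicle; the inner-leaflet
undercount is a few percent, well inside the precision of this kind of
estimate.

Defaults (all overridable, also via the YAML constants file read by
`scramkit.config.load_constants`):

| parameter | default | unit | rationale |
|---|---|---|---|
| area per phospholipid | 0.71 | nm² | standard fluid-phase PC cross-section |
| egg PC molar mass | 770 | g/mol | average for egg PC |
| vesicle diameter | 175 | nm | typical DLS diameter of detergent-removal LUVs |
| average membrane-protein mass | 50 | kDa | standard assumption for ER membrane proteins |
| membrane proteins per cell | 2 × 10⁶ | — | literature estimate for haploid yeast ER |
| scramblase mass | = average | — | unknown protein; exposed as `mass_ratio` |

The protein/phospholipid ratio of a prep is computed from input values
(protein volume × concentration over the aliquot's lipid amount in mmol) and
is numerically identical in mg/mmol and g/mol, which makes the weight
fraction `w = m·M_scr / (N·PPR)` dimensionless without conversion factors.
Whether "average protein mass" means a number- or mass-weighted average is
left to the caller through `mass_ratio` (scramblase mass / average mass,
default 1).

## Trace fitting

Traces are normalized to the mean of all pre-addition samples (t < 0); the
post-addition decay is fit by least squares with

    F/F_max(t) = p + (1 − p)·exp(−k·t),

with `p` bounded in [0, 1] and `k > 0`. The plateau `p` (protected fraction)
is the downstream contract; the decay of real vesicle populations can be
multiphasic (fast outer-leaflet chemistry plus slower scrambling-limited
bleaching and dithionite permeation), so `rate_k` is descriptive only. If
the optimizer fails, or the tail rises more than 0.05 above the early
post-addition level, the mean of the final 10% of samples is used instead
and the fit is marked `method="tail_mean"`. Fits with residual sums of
squares above a caller-supplied threshold are flagged, not rejected.
Fitting requires at least 5 pre-addition and 20 post-addition samples.

## Doubling time

The window rule is concrete: `t₁` is the *first* reading with A600 ≥ 0.35
and `t₂` the *last* reading with A600 ≤ 0.5 after `t₁`;
`T_d = (t₂−t₁)·log 2/(log C₂ − log C₁)`. Alternative point pairs inside the
window are not searched. The thresholds are absolute A600 values on
purpose: a rescaled curve raises a window error rather than silently
measuring a different growth phase. For a pure exponential sampled every
15 min the rule is exact (the discretization of `t` and of `C` cancel).
For logistic growth it is unbiased only while the window sits well below
the carrying capacity; at a realistic plate-reader plateau of A600 ≈ 2 the
0.35–0.5 window already overlaps the logistic slowdown and the estimate
runs high by tens of percent. This is a property of the fixed-window
definition itself, not of the implementation; recovery tests therefore use
a generator configuration whose carrying capacity is far above the window
(K = 50), where the estimator recovers ln 2/r within the 15-min sampling
error.

## Glycoscore, expression, calibration

The Glycoscore weights band intensities by glycan count,
`100·Σ n·Iₙ/(4·Σ Iₙ)`; it equals the percentage form of the classic
procedure (relative intensities × 4…0, summed, divided by 400) and is
invariant under lane rescaling, so background-subtracted raw intensities
and lane percentages give the same score. Band identity comes from column
headers (`glycans_4` … `glycans_0`), never from gel position. Background
subtraction is the caller's responsibility throughout (image analysis is
out of scope).

Expression levels are double ratios, `(sample/loading control)` normalized
to the same ratio in a designated reference lane. Copies-per-cell
calibration fits an ordinary least-squares line *with* intercept through
(standard amount, intensity) — blots have background — inverts it for the
sample lane and converts mass to copies with Avogadro's number, the protein
molar mass and the cells loaded. Sample intensities outside [0.5×, 2×] of
the standard intensity range are flagged as extrapolated; negative fitted
amounts are clamped to zero with a warning.

All summary statistics use the sample SD (n − 1). `summarize_groups` wraps
one-way ANOVA (overall, and pairwise against a named reference group when
sample sizes permit); it deliberately adds no multiple-testing machinery.

## Synthetic-data generators

Each generator emulates the *shape* of one readout with known ground truth:

* **Traces** — flat unit pre-addition segment, single-exponential decay to
  the population plateau `(1 − f)·p_L` (liposomes: `p_L`), additive
  Gaussian noise. Not emulated: multiphasic bleaching, instrument drift,
  dithionite exhaustion, display offsets.
* **Capture** — per-vesicle Poisson occupancy; positive vesicles contribute
  their whole glycolipid pool, others half; binomial counting statistics at
  the per-tube radiolabel (default 13,000 cpm, one third of a ~40,000 cpm
  three-sample prep). Not emulated: incomplete lectin binding, vesicle
  size dispersity coupling pool size to occupancy.
* **Bands** — true glycoform proportions × unit-mean multiplicative
  lognormal densitometry noise (default CV 3%). Not emulated: band overlap
  or saturation.
* **Growth** — logistic curves sampled every 15 min for 36 h from
  A600 = 0.01, additive Gaussian noise, default plateau A600 = 2. Not
  emulated: lag phase, diauxie, evaporation.
* **Calibration** — linear standard curve with intercept and multiplicative
  noise; the sample lane is synthesized from a true copies-per-cell value.

Noise models follow each measurement's physics: additive Gaussian for
fluorescence and optical density, multiplicative lognormal for
densitometry, binomial for counts. Randomness derives from NumPy seed
sequences keyed by `(seed, replicate index)`, so outputs are
bit-reproducible and extending a replicate series never changes earlier
replicates. Noiseless limits equal the closed forms exactly and are
asserted for every generator.

Because the generators idealize in these ways, passing recovery tests shows
that the estimators are correct *under the stated models* — not that real
traces are single-exponential or real growth is logistic. The recovery
studies use 200 traces per condition (plateaus 0.2/0.43/0.7, rates
0.01/0.05 s⁻¹, noise SD 0.01), 25 simulated trace pairs for the end-to-end
chain, 100 band lanes, and 1000 capture replicates for the statistical
consistency check; these sizes keep the default suite fast while leaving
Monte-Carlo error well below the asserted tolerances.

## Known limitations

* The mixture model treats scramblase-positive vesicles as fully exposed at
  the end point; partially scrambled (kinetically limited) vesicles would
  bias `f` downward.
* No correction for dithionite permeation or probe photobleaching; these
  inflate the apparent bleached fraction of the *control* as well, which
  the empirical-baseline choice partly absorbs.
* The Poisson model ignores vesicle size dispersity (larger vesicles get
  proportionally more protein) and any protein aggregation, both of which
  make true occupancy over-dispersed.
* The fixed-window doubling time is definitionally biased near saturation
  (see above).
* The one-way ANOVA wrapper reports raw p-values only.
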