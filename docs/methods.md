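# Methods

## The measurement problem

In asymmetrically dividing α-proteobacteria, the two daughter cells differ
in cell-cycle structure: the smaller swarmer progeny undergoes an extended
G1 phase before initiating DNA replication, while the stalked progeny
initiates with little or no delay. During G1 the relative growth rate
(area increment per unit area per minute) transiently drops, so a longer
G1 translates into a lower whole-cycle average growth rate. The package
quantifies this coupling from tracked cell areas and replication-marker
focus counts, and ships a generator that produces data with exactly this
structure plus known ground truth, so every estimator can be validated by
parameter recovery.

## Birth definitions

Two conventions for "birth" coexist and are both supported:

- **separation** — birth at the frame assigned to visible daughter
  separation. On soft-agarose preparations the swarmer daughter swims away,
  making this event directly observable.
- **cytokinesis** — birth at the frame where the late predivisional mother
  mask first splits into two labels, i.e. near cytokinesis completion, when
  the compartments already have separate cytoplasms. Quantities under this
  convention carry an asterisk (G1 duration\*, growth rate\*).

Cytokinesis precedes visible separation by a delay the generator draws from
Normal(18, 5) min truncated at zero (the membrane-fusion interval for this
organism class). Consequently stalked progenies whose replication initiates
between cytokinesis and separation have G1 = 0 under the separation
convention but G1\* > 0 under the cytokinesis convention — the package
reproduces this definitional shift quantitatively (the acceptance run
reports both fractions).

Event bookkeeping is symmetric across generations: a cell's division event
is its daughters' birth event. `A_b` is the cell's area at its birth-event
frame, `A_d` the summed area of its two daughters at *their* birth-event
frame (the outline of the just-divided mother), and the interdivision time
Δt runs between those two frames. With this convention
`λ = ln(A_d/A_b)/Δt` recovers the true rate *exactly* on noiseless
exponential data, and Δt\* − Δt equals the cell's own
cytokinesis-to-separation offset minus its daughters' — both identities are
asserted in the tests.

## Growth-rate estimation

- **Smoothing**: centred sliding average over `window = 12` frames
  (interpreted as half-width `window // 2`, i.e. a 13-point ≈ 18 min window
  at 1.5-min framing). At trajectory edges the window shrinks
  symmetrically — the first and last points are unsmoothed. Shrinking
  avoids inventing data beyond the observed trajectory; the cost is that
  the first/last few rate steps carry substantially more measurement noise,
  which matters for trough localisation (below).
- **Instantaneous relative rate**: `r_i = (A_{i+1} − A_i)/(A_i · Δt_frame)`
  on the smoothed series, in min⁻¹; the increment is normalised by the
  *first* frame of each pair.
- **Exponential-fit residuals**: straight-line least squares on ln(area) vs
  time; score = mean over frames of |area − exp(fit)|/area. Zero for a pure
  exponential; systematically higher for cells with a G1 dip.
- **Cell-cycle alignment**: each inter-frame step maps to
  `(t_mid − t_birth)/(t_div − t_birth)`; rates are averaged in `n_bins = 30`
  equal-width bins (binning density is not externally prescribed; 30 bins
  put ~2–3 steps per bin for a typical 80-frame cycle). Empty bins are NaN.
- **Population curve**: per-bin mean over cells with a percentile bootstrap
  (default 1000 resamples) over *cells*, preserving within-cell correlation;
  deterministic under a seed. Bins with fewer than two contributing cells
  get no CI.
- **Tempogram**: the cells × bins matrix with rows sorted by ascending
  interdivision time.

### Trough localisation

The per-cell argmin of the 30-bin curve is a heavy-tailed statistic: edge
bins average partially smoothed (up to raw) areas and occasionally produce
large spurious minima. Recovery of the trough position is therefore
summarised by the **median** per-cell bin error, which the validation
experiments require to lie within one bin of the true G1 end.

### Flat control

With the dip disabled, the aligned population curve must show no structure.
"No structure" is operationalised as: the difference between the highest
and lowest bin means stays within 3 standard errors of that difference,
`range < 3·√(SE²_max-bin + SE²_min-bin)` with bootstrap SEs. This is the
uncertainty of the quantity actually measured (a difference of two bin
means); a real dip exceeds the bound several-fold.

## Focus detection and G1 calling

The detector is deliberately parameter-light: difference of Gaussians at
the PSF scale (σ vs 1.6σ, default σ = 1.3 px); per-cell threshold at
median + `snr_threshold` (default 5) robust SDs (1.4826·MAD) of the
filtered values; greedy brightness-ranked merging of maxima closer than
`min_separation` px (default 3, keeping the brighter); brightness =
integrated raw intensity in a disc of radius 2σ minus the cell's median
background; position = intensity-weighted centroid of that disc. Detection
counts are monotone non-increasing in the threshold and the whole pipeline
is translation-equivariant — both asserted as properties.

G1 ends at the **first** fluorescence frame, at or after the active birth
time, showing ≥ 2 foci; if two foci are already present at the first frame
at or after birth, G1 = 0 ("no G1 phase"). No persistence requirement is
imposed (a two-frame persistence variant would only shift calls by one
fluorescence interval; the round-trip experiments show the single-frame
rule recovers the truth to one frame already). Durations are reported at
fluorescence-frame resolution (3 min), never interpolated. Cells whose
counts never reach two are flagged, not guessed.

Polarity calls: a focus is polar if its axis-relative coordinate is below
`pole_fraction = 0.2` or above 0.8; bipolar/unipolar/other follows from
which poles are occupied.

## Curation

Rejection rules, evaluated on the smoothed rate series, with strict
comparisons exactly as the thresholds are stated (boundary values are
retained): Δt < 30 min; area gain A_d − A_b < 0.61 µm² (a fixed constant —
the smallest credible birth size — not a population statistic); any
smoothed rate > 0.015 min⁻¹ or < −0.0025 min⁻¹; missing mother or
daughters; unresolvable progeny identity; optionally birth later than
60 min into acquisition (strain comparisons). Manual removals are supported
only as an explicit id list in the config, never hard-coded. Each rejected
cell carries every reason code it violates; retention is idempotent and
monotone in every threshold.

## Progeny classification

A mechanised proxy for what is usually a visual call: **stalked** if the
cell has a visible stalk or its sister moved more than `motion_threshold =
1 µm` net over the 3 frames after separation (the swarmer swims off);
**swarmer** if the cell itself moved beyond threshold and lacks a stalk;
otherwise **uncertain** (dropped downstream). When nothing moves
(immobilised preparations), the stalk flag alone decides. Ties (both
siblings moving, no stalk) deliberately fall to *uncertain* rather than to
a guess.

## The synthetic generator

Per cell: the relative growth rate declines linearly from μ0 at birth
(cytokinesis) to μ0·(1 − d) at the end of G1, recovers linearly to μ0 over
`recovery_width` min, and stays flat. Area integrates this profile exactly
(closed-form piecewise-quadratic integral), so noiseless trajectories obey
`A(t₂)/A(t₁) = exp(∫r dt)` to machine precision. Division splits the mother
area into fractions s (swarmer) and 1 − s; separation lags cytokinesis by a
truncated-normal offset shared by the sibling pair; observed areas are the
truth times i.i.d. lognormal noise per frame.

Defaults (the simulated study conditions): μ0 = 0.006 min⁻¹ with a 10%
lognormal cell-to-cell CV (single-cell growth-rate distributions are
broad); dip depth d = 0.4; recovery width 30 min; G1\* gamma-distributed
with mean 40 min (swarmer) / 12 min (stalked) and CV 0.5 (right-skewed,
positive support); s = 0.45 (the swarmer is the smaller daughter);
interdivision time Normal(120, 15) min; area noise CV 0.5% per frame
(consecutive-frame mask areas from a fixed segmentation pipeline are highly
reproducible; much larger i.i.d. noise would trip the printed
instantaneous-rate curation bounds on every real cell, so sub-1% jitter is
the self-consistent regime); phase framing 1.5 min, fluorescence 3 min.
Founders are stalked-like cells born at t = 0; every cell divides once at
its drawn interdivision time; final-generation cells leave no daughters and
are therefore rejected by the complete-lineage filter, as in real data
where the movie ends.

Focus schedule: one polar focus until G1 ends, two afterwards; the
duplicated focus appears 0.5 µm from its sibling (patches are called as
"two" only once visibly split) and segregates at 0.15 µm/min towards the
far pole. Rendering: stadium-shaped (rod) label masks, isotropic Gaussian
foci of sd `psf_sigma` on a flat background, Poisson (or Gaussian/none)
noise; SNR is defined as amplitude/√background.

The trough is placed *at* the G1 end by default but `trough_offset` is an
explicit parameter, since empirical curves suggest the minimum may slightly
precede the G1/S transition and the true functional form of the dip is not
known.

### What the generator does not emulate

No phase-contrast rendering; no stalk/flagellum morphology, motility
physics, or alarmone kinetics (perturbations such as (p)ppGpp-null strains
are expressed only as altered G1 means / dip parameters); no size-based
division control (division triggers on a drawn interdivision time, not an
adder/sizer rule); no segmentation or tracking errors beyond multiplicative
area noise — so passing tests validate the estimators' correctness and
conventions, not robustness to segmentation failure modes, which is what
the curation layer is for on real data. With a fixed-depth dip, cells with
different G1 lengths share the same trough value; groups binned by G1 are
therefore separated by *when* the trough occurs and how long the slow phase
lasts, not by trough depth.

## Determinism and problem sizes

All randomness flows from integer seeds through `numpy.random.default_rng`;
identical config + seed give byte-identical CSV outputs. The validation
experiments use ~400 complete cells (29 founders × 4 generations) for the
population comparisons, ~170 cells for the flat control, 30 rendered cells
(~2200 foci) for detection, and 500 replicates for bootstrap coverage —
sizes at which every experiment completes in seconds on one CPU while
leaving the qualitative effects many standard errors wide.

## Known limitations

- The area-noise model is i.i.d. per frame; real segmentation error is
  autocorrelated (drift-like), which would deflate the instantaneous-rate
  noise relative to equal-magnitude i.i.d. noise.
- The dip's piecewise-linear shape is the simplest monotone-down/up form;
  it is config-swappable but no alternative shapes ship.
- `exp_fit_residuals` normalises per frame by that frame's area (not by the
  mean area), an explicit choice where conventions differ.
- The separation-mode cycle of a cell whose daughters separate after the
  observation window cannot be closed and is flagged incomplete rather than
  extrapolated.
- No super-exponential growth models and no multiple-testing correction
  (single pairwise comparisons only).
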