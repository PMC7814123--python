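# Methods

This note records the models behind pixinorm, the parameters that matter,
what the synthetic data generator does and does not emulate, and the
numerical choices a user may want to audit. It states no result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Image quantification

The per-well score is the summed positive deviation of each pixel below
its local background:

1. background `B = G_sigma * I` (Gaussian low-pass, edge-replicated
   boundary),
2. inverted signal `S = clip(B - I, 0, inf)`,
3. central crop (default 5% per border),
4. total pixel intensity `T = sum(S)`.

**Why subtract-then-clip.** Defining the inversion as `clip(B - I, 0)`
rather than `1 - (I - B)` makes an empty well score exactly ~0 and keeps
`T` proportional to cell-occupied area: the alternative adds a constant
offset of one per pixel, which would destroy linearity through the origin
and make `T` depend on frame size. Whether negatives are clipped or summed
signed is configurable (`clip_negative`); clipping is the default because
shot noise is symmetric and would otherwise cancel real signal.

**Background scale.** `background_sigma_px = 50` at a 4x-objective pixel
pitch of ~1.7 um/px, i.e. roughly ten lymphocyte diameters. The filter
must be wide enough that individual cells do not survive into the
background estimate (otherwise their own signal is partially subtracted)
yet narrow enough to track illumination gradients. Any sigma well above
the largest cell diameter and well below the frame works; results are
insensitive in that window. Boundary handling is edge replication;
reflected padding differs by <0.1% on flat-ish borders and is not exposed.

**Crop rule.** `floor(fraction * dim)` rows/columns removed from each
side independently; 0.25 per border on a 100 px image leaves 50 px. The
5% default removes plate-nodge artefacts; the dilution-series linearity is
insensitive to crops up to 25% (checked in the acceptance suite).

A note on two invariants: for isolated objects the pipeline is *exactly*
additive once object separations exceed the truncated kernel support
(4 sigma), because the blur of one object then cannot reach another's
footprint. The unclipped signal always sums to ~0 (convolution conserves
mass); it is the clipping of the negative halo that produces a positive,
area-proportional total.

## Calibration

Per plate (and donor), plated cell count is regressed on total pixel
intensity with a second-order polynomial, fitted by ordinary least squares
in a max-scaled intensity variable for conditioning. Fitting cells *as the
response* (rather than inverting an intensity-on-cells fit) makes the
intensity-to-cells transform single-valued by construction. Replicates
enter as individual points so replicate noise propagates into the fit
diagnostics. Both the quadratic coefficient of determination (`fit_r2`)
and the squared Pearson correlation of the raw pairs (`pearson_r2`) are
reported; the former nests the latter.

Predictions are restricted to `[0.8 * I_min, 1.2 * I_max]` around the
fitted intensity domain — quadratics are untrustworthy outside their
support — with estimates beyond the domain itself flagged as
extrapolated. A curve that decreases anywhere on its domain records a
warning rather than an error: mild edge non-monotonicity occurs with
noisy replicates and predictions remain single-valued. Curves refuse
cross-plate application unless explicitly overridden, because
illumination and plating conditions are plate-specific.

## Flux parameters

The default injection scheme is 12 cycles in four 3-cycle phases
(baseline, FCCP, antimycin A + rotenone, monensin); any contiguous
partition can be supplied via YAML, including real-time-activation
protocols with a concanavalin-A phase. Operational definitions, chosen
here because the underlying quantities are conventionally reported
without precise cycle assignments:

- *initial OCR* = cycle-1 OCR; *basal OCR* = baseline-phase mean. They
  coincide only when the baseline is flat.
- *basal OCR is reported raw* (no non-mitochondrial subtraction);
  `nonmito_ocr` is exposed separately so users can subtract.
- *FCCP-uncoupled OCR* uses the phase maximum by default (uncoupler
  responses peak then decay); the mean is available via configuration.
- *monensin GR* sets mitochondrial OCR to zero because antimycin/rotenone
  precede monensin, so it equals the phase's maximal ECAR.

The CO₂ correction `GR = ECAR - ccf * OCR_mito / (BF * V * Kvol)` uses
ccf = 0.61 pmol H⁺ per pmol O₂ (maximal H⁺/O₂ of complete glucose
oxidation) and 96-well micro-chamber conventions BF = 2.60 mM/pH,
V = 2.28 uL, Kvol = 1.60 by default. All four are pure configuration —
instrument medium and cartridge geometry vary — and ccf = 0 disables the
correction (GR = ECAR). Negative mitochondrial OCR attaches a QC flag
instead of failing, since near-zero respiration plus noise produces it
legitimately.

## Normalization statistics

`normalized = raw * reference_cells / cells_used`, with
`reference_cells = 225 000` by default (the standard assay plating
density; configurable). Statistics use the sample (n−1) standard
deviation throughout and linear-interpolation quartiles — the IQR of n
standard scores depends on the quantile convention, so it is fixed
explicitly.

The accuracy metric is the group-mean absolute z-score and the precision
metric the IQR of signed z-scores, averaged over (donor, density)
replicate groups. One property worth noting: z-statistics are
affine-invariant, so a *uniform* rescaling of within-group spread changes
neither metric; they respond to changes in the shape of the replicate
distribution (e.g. removal or introduction of discordant wells), which is
exactly what swapping the normalization denominator does.

Donor improvement compares each donor's absolute deviation from the group
mean *scaled by that method's own group mean*, because the two
normalizations shift group means and raw distances are not comparable:
`pct_closer = 100 * (rel_std - rel_pixi) / rel_std`. Donors at exactly
zero standard-route distance are flagged and excluded from counts. The
5% threshold for "meaningfully improved/worsened" donors is a reporting
convention, not a test.

## Synthetic data

The generator exists so that every stage has exact ground truth.

**Images.** Cells are cosine-tapered dark disks (no diffraction or phase
optics) on a bright field (level 0.85) with a 10% corner-to-corner
illumination gradient and additive Gaussian pixel noise (sd 0.01 of full
scale). The default PBMC-like mixture is platelets 2.5 ± 0.5 um (20%,
depth 0.10), lymphocytes 8 ± 1 um (65%, 0.35), monocytes 16 ± 2 um (15%,
0.45) — plausible magnitudes for a mixed mononuclear prep, not measured
values. Overlaps resolve to the darkest value, so intensity saturates as
confluence grows; this deliberately reproduces the sub-linearity that
motivates a quadratic calibration. Specs whose expected union coverage
`1 - exp(-n * area / frame)` exceeds 95% are rejected as super-confluent.
The default frame is 994 x 994 px at 1.7 um/px (a 4x-objective field);
per-well densities are converted to in-frame counts via the frame/well
area ratio against a 32 mm² growth area. Per-well plating noise is
multiplicative with CV 5% by default.

**Traces.** Per-cycle rates are linear in cell number with phase
multipliers (FCCP x2.0, antimycin/rotenone floor x0.15 — which OCR keeps
through the monensin phase — monensin ECAR x1.8) and multiplicative
noise (CV 5%). Baseline magnitudes (13 pmol O₂/min and 3.2 mpH/min per
10⁵ cells) put a 225k-cell well near 29 pmol/min basal OCR and
6.4 mpH/min basal ECAR, typical of resting PBMCs. A density-inhibition
term reduces per-cell ECAR by 5% per 10⁵ cells/well by default, emulating
crowding-limited glycolysis; it is what makes GR correlate less tightly
with cell number than OCR in the simulated dilution series.

**Cohort model.** `simulate_cohort` builds one plate per donor: a
volumetrically prepared calibration dilution series (accurate up to
per-well plating noise) plus a block of assay wells seeded from a counted
suspension carrying a *donor-level* multiplicative counting/seeding error
(CV 12% by default) shared by all of that donor's assay wells. Donors
also differ biologically (independent per-cell OCR and ECAR scalings, CV
12%). Because the images see the delivered cells while the intended count
does not, PIXI normalization can remove the counting error and the
standard route cannot — this is the mechanism the cohort benchmarks
exercise. Cohort images default to a 256 x 256 px frame (same pixel
pitch and optics as the full-size frame) to keep whole-cohort simulation
cheap; the full-size frame is used for the single-plate dilution-series
benchmarks (6 densities x 14 replicates).

**What passing tests do not show.** The generator has no optics (PSF,
defocus, phase halos), no cell clumping or spatial inhomogeneity, no
well-to-well illumination variation beyond a fixed gradient, no
debris/artefacts, and its rate model is stationary within phases. Results
on synthetic data therefore demonstrate correctness of the computations
and the *mechanism* of the normalization benefit, not performance on any
particular instrument's images.

## Numerical choices and degenerate inputs

- Images rescale by the source bit-depth full scale (255/65535), never by
  per-image min/max, preserving cross-well comparability.
- Gaussian filtering truncates at 4 sigma (the reference implementation
  in the test suite builds the same sampled kernel densely).
- Calibration needs ≥4 points over ≥3 distinct densities; identical
  intensities are a degenerate design (error).
- CV is undefined at zero mean, standard scores at zero spread (errors);
  replicate groups need ≥3 wells.
- Negative processed intensities (clipping disabled) must be summed
  explicitly via `allow_signed=True`; the default refuses them.
- All simulation randomness flows through a single seeded generator per
  call; identical seeds are bit-for-bit reproducible.

## Known limitations

- The calibration is per plate; no pooling or hierarchical sharing across
  donors is provided (deliberately out of scope).
- No weighted or robust regression variants; heteroscedastic replicate
  noise mildly biases the quadratic at the dense end.
- The GR correction assumes the configured buffer factor and chamber
  geometry; it is only as accurate as those constants.
- Fluorescence quantification, cell segmentation and per-cell diameter
  classification are out of scope.
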