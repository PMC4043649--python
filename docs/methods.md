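# Methods

This note documents the statistical model behind the generator, the
numerical conventions of the processing chain, the design decisions that
were genuinely open, and what the synthetic experiments can and cannot
show about real data.

## Generator model

**Between-animal variation.** Every population's true concentration
(cells/µl of blood) is log-normal across animals: strictly positive,
right-skewed, and able to carry coefficients of variation up to ~86%
without producing negative concentrations.  CVs map to the log scale via
σ² = ln(1 + CV²), and distributions are parameterized by their mean, so
configured cohort means are reproduced exactly in expectation.

**Monocyte subsets: fraction × total construction.** The three MHCII⁻
subsets are not drawn independently.  Each animal receives a total
monocyte concentration T (log-normal) and a composition
(f_cl, f_int, f_nc) with f_nc = 1 − f_cl − f_int, so subset concentrations
sum to the drawn total exactly.  The published cohort tables constrain
both the expected composition (52.4 / 40.4 / 7.2%) and the expected
absolute concentrations (classical 135.6, non-classical 86.1 cells/µl),
and these are mutually consistent only if composition and total co-vary:
E[f_s·T] = E[f_s]·E[T] + cov(f_s, T).  `calibrate_cohort_preset` solves
for the implied correlations on a shared Gaussian latent
(cov(z, T) = E[T]·σ_lnT), raising a calibration error whenever an implied
correlation leaves [−1, 1].  The construction is self-consistent for any
E[T]; with the default E[T] = 240 cells/µl the classical covariance is
+9.84 cells/µl — the generator's encoding of Ly6C^hi monocytosis — and the
intermediate mean is implied as E[T] − 135.6 − 86.1 = 18.3 cells/µl.
Fractions are Gaussian around their means (SDs back-computed from the
printed SEs at n = 180); draws leaving the open simplex are rejected and
redrawn (< 1% of animals), a negligible truncation at these parameters.

**Free parameters.** E[T] = 240 cells/µl and CV(T) = 0.55 are not
published.  E[T] only relocates the covariance split; CV(T) = 0.55 was
chosen so the implied classical-monocyte concentration CV (≈ 0.70–0.74)
brackets the published 0.688.  Both are ordinary config fields.

**Acquisition.** A sample of volume V at acquisition fraction f yields
Poisson(conc · V · f) events per population and Poisson(beads_per_tube · f)
bead events (default 50 000 beads per tube, a per-lot constant).  Per-event
channel intensities are log-normal around the population template medians
(median-parameterized, so zero spread means every event sits exactly at the
template).  Default robust CVs: 0.25 on fluorescence channels, 0.15 on
scatter, 0.05 for the tight bead singlet peak.  Observed intensities are
the true intensities mixed through the spillover matrix
(observed = true · S), clipped at the 18-bit instrument range (262 144 a.u.,
saturation counted in metadata), and shuffled; ground-truth labels travel
with every event.  Template F4/80 medians for the monocytic subsets are the
published MFIs (421 / 455 / 794 / 1350 a.u.), so MFI recovery is a direct
echo test; the remaining medians are plausible instrument-scale values
placed ≥ 3 log-SDs from every gate at the default spread.

**Technical (duplicate) noise.** Each acquisition multiplies every
population's Poisson rate by an independent log-normal factor with CV τ
(mean 1), modelling pipetting/staining variation.  The published duplicate
statistic — the mean over 12 animals of per-pair CVs — is a biased,
composite estimator: an SD from two values underestimates σ by
c4(2) = √(2/π) ≈ 0.798, and the per-measurement CV also contains Poisson
cell counting (E[1/N] ≈ (1+CV²)/(mean·V·f) across the cohort) and bead
counting.  The presets therefore *calibrate* τ by inverting that
relationship, so the expected duplicate statistic equals the published
inter-assay CV (2.1% classical, 4.6% non-classical, 3.8% neutrophils,
5.1% eosinophils).  For intermediate monocytes the published 2.1% lies
below the Poisson counting floor at the implied concentration (≈ 3.3% at
50 µl), so τ is floored at zero and the simulated statistic is
counting-dominated.  Populations without a published value (activated,
lymphocytes) default to τ = 0.03.

**Post-operative kinetics.** Each subset and group carries a median
multiplier m(t) anchored at days {0, 1, 3, 5, 7, 14, 21} and interpolated
log-linearly.  MI and sham share identical anchors (the response is
surgery-driven); non-operated controls are flat.  Anchor magnitudes are
config values, not published numbers — only their shape is asserted: an
early dip deepest for non-classical monocytes (day-1 multiplier 0.4) and
eosinophils, then classical (day-3 peak 2.5) and non-classical
monocytosis.  Sequential designs reuse each animal's baseline draw;
cross-sectional designs draw fresh animals per day.  Day-level biological
noise (CV η = 0.10) multiplies every animal × day × population rate.

**Dispersion under sequential sampling.** Any model in which day t scales
each animal's baseline identically gives the same cross-animal CV in both
designs.  The reported design difference is reproduced phenomenologically:
in sequential mode the animal-level log effect is scaled by a dispersion
factor s(t) (same anchor grid; s(0) = 1, dropping to 0.27 at day 7, which
encodes the reported up-to-four-fold day-7 CV reduction for classical
monocytes), while cross-sectional draws keep full cohort dispersion.  This
is a modelling choice, not a mechanism: it represents the empirical
variance suppression of repeated-measures designs (each animal its own
control) without claiming to explain it.

## Processing conventions

- **Spillover estimation**: medians, not means, for outlier robustness;
  entry (i,j) = (median_j(pos) − median_j(neg)) / (median_i(pos) −
  median_i(neg)), diagonal forced to 1, rows keyed by the control's primary
  channel so input order is irrelevant.
- **Compensation** is the exact inverse observed·S⁻¹; negative compensated
  values are retained (truncation would bias MFIs); scatter channels are
  never touched.
- **Transform**: f(x) = asinh(x/cofactor)/ln 10 with cofactor 150 a.u.
  (per-channel overridable) — linear-like through zero, ~log10 above a few
  hundred a.u., exactly invertible.  Gating on transformed values with
  transformed cuts is equivalent to gating raw values with back-transformed
  cuts because the map is strictly monotone.
- **Gating**: half-open [cut, ∞) convention — an event exactly on a cut
  goes to the upper side.  The Ly6C × CD43 plane is partitioned with Ly6C
  as the primary axis (high → classical, low → non-classical, intermediate
  band split by CD43 bin), which agrees with the canonical subset
  definitions on their home bins and guarantees that the three subsets
  partition the monocyte gate exactly.  The activated gate takes the union
  Ly6C < high-cut AND CD43 ≥ low-cut, reading the descriptive
  "Ly6C^low/int CD43^int/high" phenotype as interval-bin unions.  "Lin⁺" in
  the SSC^high branch operationally encodes Ly6G positivity because Ly6G
  is carried on the PE dump channel.  Lymphocytes are gated SSC^low Lin⁺
  CD11b⁻ (their published counts come without an explicit gate).
  "Ungated" is retained and reported, never dropped silently.
- **Data-driven cuts** (optional) are placed at the minimum-density valley
  between the two tallest KDE modes, deterministic given bandwidth and
  grid, falling back to template midpoints when unimodal.  The analyses and
  acceptance runs use the template-midpoint gates for determinism.
- **MFIs** are computed on compensated, untransformed values (the transform
  is treated as display-only) and require ≥ 20 events (unstable medians
  below that are reported missing with a reason).
- **QC** reads "at least" inclusively: pass ⇔ leukocyte events ≥ 30 000 and
  bead events ≥ 3 000; failed samples are excluded from cohort statistics
  unless overridden (serial 20 µl draws legitimately acquire fewer events).
- **Statistics**: sample SD (n−1), SE = SD/√n, CV = SD/mean, linear
  percentile interpolation; duplicate CVs aggregate per-pair CVs by
  arithmetic mean (RMS behind a flag); design CVs are computed on absolute
  counts (deltas are used only for kinetics curves); per-day MI-vs-sham
  tests are unpaired t-tests on deltas with Bonferroni correction across
  days, a transparent simplification of two-way-ANOVA interaction
  contrasts; correlations are Spearman with midrank ties.

## Problem sizes and reporting

The acceptance script runs the studies at their stated designs — 180
animals at 50 µl, 12 duplicate pairs — and reports stochastic quantities
as Monte-Carlo averages over replicate experiments (6 cohorts, 12
duplicate experiments) purely to shrink the reported value's Monte-Carlo
error; the per-experiment design is untouched.  A single 180-animal cohort
statistic carries substantial sampling noise of its own (the cohort-mean
neutrophil count has SE ≈ 6%, the cohort CV estimator SD ≈ 12% with a
small negative bias), which the in-repo tests acknowledge by testing
single cohorts against 2-SE bands derived from the configured truth and
against replicate-oracle expectations — never against bands fitted to the
tested run itself.  Event-level tests run at reduced acquisition fractions
(0.02–0.3); the bead-ratio estimator is invariant to the acquisition
fraction, which is itself one of the tested properties.

## What the synthetic experiments do not show

The generator emulates the statistical skeleton of murine whole-blood
cytometry, not its physics: no red-cell lysis chemistry, doublets, debris,
dead cells, or autofluorescence; spillover is exactly linear and constant;
population intensity distributions are clean log-normals with no
instrument drift; lymphocytes are a single aggregate population.  Passing
tests therefore demonstrate that the *pipeline* is correct and that the
published cohort statistics are mutually consistent under the stated
model — they do not validate gating performance on real listmode files,
where population overlap and acquisition artifacts are worse.  The
sequential-design dispersion advantage is reproduced by construction (see
above), so the design-CV analysis illustrates the consequence of that
empirical structure rather than independently deriving it.
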