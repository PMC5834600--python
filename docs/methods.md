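# Methods

## The screen being modelled

Two cell populations are compared in a single pass: one is labelled with a
barcoding dye (CellTrace-Violet-like), the other left unlabelled; they are
pooled 1:1 and distributed over four 96-well plates in which each well
carries one APC-conjugated antibody (356 marker wells, 9 isotype-control
wells, 19 empty). Each well is acquired once on a plate-loading cytometer,
so the analysis must (i) clean the events, (ii) split each well back into
its two source populations on the barcode channel, and (iii) score each
population's reporter signal against the matched isotype control.

## Synthetic event model

No event-level distributions are dictated by the protocol, only counts and
ratios; the generator's distributional choices are package conventions:

* **Scatter** (FSC-A, SSC-A): bivariate normal per population. The
  serum-grown ("FCS") population has a higher SSC-A mean (32,000 vs 18,000
  a.u.), reflecting the higher granularity of serum-expanded cells. FSC-H is
  FSC-A times 1 ± 0.02 relative noise, so singlets sit on a tight
  proportionality line.
* **Dye intensities** are log-normal on the linear scale (non-negative,
  right-skewed, the standard first-order model for fluorescence). The
  reporter channel is a two-component log-normal mixture: background with
  per-population log-mean/log-SD, plus a positive component shifted upward
  by `positive_logshift` (default 3.0 log units ≈ 20×). The default
  background asymmetry is 13× (FCS log-mean = log(1300), PLT = log(100)),
  exercising the background-aware stain index.
* **Barcode**: log-normal modes at 20,000 (labelled) and 120 (unlabelled)
  a.u., ≈ 20 common log-SDs apart — comfortably above the ≥ 6 log-SD design
  floor for clean demultiplexing. An `overlap_populations(sep)` preset
  shrinks the separation (default 2 log-SDs with equal log-SDs, so the
  two-Gaussian Bayes misassignment rate has the closed form Φ(−sep/2)) for
  stress tests.
* **Contamination**: 5% debris (small lognormal scatter, dim on all dyes),
  4% doublets (area signals doubled, FSC-H only ×1.2 — sub-proportional, so
  the area/height gate can see them; pulse width widened), and 5% dead cells
  per population (viability dye ~100× brighter). Categories are exclusive
  and conserve the event total.
* **Pooling**: each cell is assigned to the barcode-positive population with
  probability `pooling_ratio/(1+pooling_ratio)` (default ratio 1.0).
* **Donor variability**: per-donor positive fractions are logit-normal
  around the planted value (`donor_logit_sd`, default 0.15 ≈ ±4 percentage
  points at p = 0.5, resembling the inter-donor spread such screens report;
  fractions of exactly 0 or 1 stay fixed). Draws are per donor and shared
  across that donor's wells.

Reproducibility: every well's RNG seed derives from
`SeedSequence([root_seed, donor, plate, well])`; identical `(config, seed)`
give bit-identical events and truth.

**What the generator does not emulate** — spectral spillover (events are
"pre-compensated"), acquisition-time drift and carryover, marker-marker
correlations within a cell, heavy-tailed autofluorescence and aggregates
with irregular pulse shapes. Recovery results on this generator therefore
show that the *decision logic* is correct under the stated statistical
structure, not that the gates are robust to every instrument artifact.

## Gating conventions

* **QC**: a well fails below 10,000 total events.
* **Scatter gate**: the FSC-A density (binned Gaussian KDE on the log scale,
  Silverman bandwidth) locates the main cell mode; the debris threshold is
  `debris_cut_frac` (default 0.4) of the mode's linear position. Anchoring
  on the mode rather than a fixed intensity keeps the gate instrument-scale
  free. Because the mode itself is always retained, an entirely-empty gate
  can only arise from empty input, which is flagged rather than raised.
* **Singlet gate**: robust singlet line through the origin with slope
  median(FSC-H/FSC-A) over the central (10th–90th percentile) FSC-A mass;
  events outside ±4 robust SDs (1.4826·MAD) of residual are removed. Wells
  with < 50 events skip the fit with a warning.
* **Live gate**: threshold at the 0.999 quantile of the viability-control
  channel; skipped automatically when no viability channel is bound (the
  plate-screen protocol carries no viability dye; the validation-mode
  channel map binds DAPI).
* **Demultiplexing**: threshold at the minimum-density valley between the
  two largest modes of the log-barcode KDE. Modes below 5% of the peak
  density, or a valley shallower than that prominence, mean the distribution
  is judged unimodal and the well raises a demultiplexing error. An Otsu
  (between-class-variance-maximizing) split and a fixed threshold are
  available; Otsu is the right tool near the bimodality boundary, where an
  equal two-Gaussian mixture at 2σ separation has no stable interior valley.
* **Positivity gate**: the empirical `confidence` quantile (default 0.999)
  of the matched isotype control's reporter channel, computed per population
  (the two populations have very different backgrounds, so one shared gate
  would be wrong). Quantiles are linear-interpolated order statistics
  (type 7) — stated because gate placement is sensitive to the convention.
  Events exactly at the threshold count negative (deterministic ties).
  The protocol names the isotype rule but not its quantile; one consistent,
  configurable default is used for screening and validation modes alike.

Recovery oracle used in tests: with a control gate at confidence c, the
expected measured positive share of a well with planted fraction p is
p + (1 − p)(1 − c), not p; tests compare against that expectation within
3 binomial SEs.

## Screening statistics

* **Positivity**: max of the two population means across donors ≥ 5.5%
  (inclusive). **Enrichment**: fold ≥ 1.5 (inclusive) and p < 0.05 (strict),
  read literally from the rule's phrasing.
* **Fold change**: PLT mean over FCS mean, denominator floored at 0.5
  percentage points (flagged when applied) so near-zero backgrounds stay
  finite.
* **Test**: two-group one-way ANOVA across donors (identical to the unpaired
  two-sided t for two groups); a paired t is available, and
  Benjamini–Hochberg correction sits behind a flag (raw p-values by
  default, matching common practice in these screens).
* **Variable vs equally-expressed partition**: fold ≥ 1.25 or absolute
  difference ≥ 10 percentage points. This rule is a module convention — the
  screen protocol publishes no formula for the partition — and is
  configurable.
* **Stain index** uses robust spread (1.4826·MAD of the control) by default;
  plain sample SD is available via `robust=False`. SI is undefined (NaN,
  flagged) for empty inputs or zero control spread, and SI folds with a
  non-positive denominator are undefined rather than signed.
* **ΔΔCt**: ΔCt = mean(Ct target) − mean(Ct reference) per condition,
  fold = 2^−(ΔCt₁ − ΔCt₂).

## Profiles

PCA operates on column-centered, unscaled percentages (unit-variance scaling
behind a flag); clustering is agglomerative with Euclidean distance and
average linkage, of both samples and markers; the top split is the
two-cluster cut. Histogram overlays use an arcsinh display transform
(cofactor 150 by default) — display only, all statistics stay linear.

## Problem sizes

The default simulated screen is the full protocol scale: four plates × 96
wells (365 active) × 50,000 events × 3 donors. The package streams the
screen well by well, so the full run needs ~1 minute and a few hundred MB.
Tests exercise single wells at 50,000 events where a distributional oracle
needs tight SEs, and reduced wells (1,000–20,000 events) elsewhere; the
multi-seed recovery property runs the full 356-marker layout at 10,000
events/well over three seeds.

## Known limitations

* The FCS reader targets list-mode files from the instruments this protocol
  uses (float 3.x, or integer 2.0/3.0 with `$PnE` log scaling); it does not
  implement the full keyword surface (no `$NEXTDATA` chains, analysis
  segments, or bit-packed widths beyond whole bytes).
* The scatter gate is one-dimensional in FSC-A; a 2-D density gate would be
  needed for debris that overlaps cells in forward scatter.
* The variable/equal partition rule and the isotype-gate quantile are
  conventions, configurable but not protocol-mandated; results that depend
  on them should be read accordingly.
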