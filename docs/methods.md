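# Methods

## Gradient-trace quantification

A polysome profile is modelled as absorbance over a normalized gradient
coordinate in [0, 1], 0 at the gradient top (low sucrose). Complexes
appear in sedimentation order 40S < 60S < 80S < polysome n-mers.
Quantification:

* **Blank subtraction.** The blank trace of the same centrifugation run is
  linearly interpolated onto the sample grid and subtracted. Traces from
  different runs are only compared after this correction. An optional
  floor clips the corrected trace; the default applies no clipping.
* **Segmentation.** Boundaries between adjacent complexes are placed at
  the absorbance minimum between their anchor positions (anchors supplied
  from configuration, or auto-located as the most prominent smoothed
  peaks). Flat valleys tie-break at the anchor midpoint. The polysome
  region extends from the 80S right boundary to the trace end, so
  everything denser than 80S counts toward the polysome and total areas.
* **Integration.** Trapezoid rule per interval. A negative interval area
  (possible after blank subtraction) is clipped to zero at the *area*
  level. Clipping per point would add a strictly positive bias of about
  `noise_sd/√(2π)` per unit length in near-baseline regions, which alone
  can exceed the 2% recovery tolerance on small peaks; area-level clipping
  keeps the integral unbiased under zero-mean noise while still forbidding
  negative physical areas.
* **Comparison.** log2(mutant/wild-type) per complex and for the total
  (the sum of the four component areas, exactly). Zero wild-type areas
  yield flagged NaN entries rather than dropped rows. Pearson correlation
  between complexes is computed across all (genotype, timepoint) pairs.
* **Half-mers** (stalled 40S preinitiation complexes on polysomal mRNAs)
  are flagged qualitatively as extra local maxima between the 80S and
  first-polysome apexes, above 5% of the smaller apex to ignore numerical
  ripple. They are not quantified.
* **KCl sensitivity.** For a paired 200/400 mM KCl preparation of one
  sample, the sensitive share of the 80S pool is
  `(A80S,normal − A80S,elevated)/A80S,normal`, reported with the
  concomitant 40S and 60S gains; the sign contract (80S down, both
  subunits up) distinguishes true dissociation from drift.

No between-sample rescaling is applied: loading at equal fresh weight is
assumed done upstream.

## Compositional analysis of fraction-wise LFQ tables

Detection is binary at LFQ > 0; a zero means not detected (the convention
of label-free quantification output tables).

* **Fraction identity.** For every RP class the across-fraction share
  profile (class sum per fraction divided by the class total) is computed.
  Scoring each (fraction, label) pair with fixed class weights — e.g. the
  30S/40S label weights cytosolic 40S and organellar 30S RP shares, the
  60S label weights 60S RP and biogenesis-factor shares — makes the
  assignment invariant to the absolute abundance of each class. Labels are
  assigned by the order-preserving injective assignment maximizing the
  total score, under the constraint that fractions holding the abundance
  maximum of a pre-60S marker (eIF6A, NMD3) may only receive the 60S or
  60S/80S labels. With ≤ 8 fractions and 5 labels the assignment space is
  enumerated exactly.
* **Normalization.** Within each compartment fraction, every protein's
  abundance is divided by the summed abundance of the reference RP class
  (60S RPs for the 60S and 60S/80S fractions, 40S RPs for the 30S/40S
  fraction); the opposite subunit's RPs are excluded from the analysis.
  Reference-class shares therefore sum to 1 per fraction, and all
  downstream calls are invariant to per-fraction rescaling. Fractions with
  a zero reference sum are excluded with a warning.
* **Combining 60S and 60S/80S.** The combined per-protein value is the
  mean of the two fractions' shares, with a missing value contributing 0
  while the divisor stays 2. A sum would double-weight proteins detected
  in both fractions; the mean down-weights single-fraction detections,
  which is the conservative choice.
* **Abundance-maximum filter.** A protein enters the 60S compositional
  report only if its raw LFQ maximum over the non-translating fractions
  lies in the 60S or 60S/80S fractions (ties resolve against inclusion);
  the 40S report requires more abundance in the 30S/40S than in the 60S
  fraction. This guards against co-purification artifacts. In the paired
  comparison the filter is satisfied if it passes in either the mutant or
  the wild-type sample, so presence/absence calls remain possible.
* **Change calls.** Presence in mutant with absence in wild type is `+`;
  the reverse is `−`; both detected gives log2-FC with strong/weak classes
  split at |1| (a fold change of exactly 0 classifies as weak_up by
  convention but carries no direction). For the 40S compartment,
  organellar RPs and a configurable contaminant list are excluded; eIF3
  subunits are retained.
* **Shared-change selection.** A protein is selected when its cold-
  temperature calls agree in direction between the two experiments
  (`+`/up = increase, `−`/down = decrease, so categorical and numeric
  calls can agree); the stringent mode additionally requires the same
  direction at the warm temperature in both experiments. No significance
  testing is applied — selection is purely this shared-direction rule, so
  proteins with small same-sign fluctuations pass alongside planted
  effects; the magnitude classes in the call table are the reader's guide.

## Transcriptome statistics

* **Quantile normalization** replaces rank r in each sample by the mean of
  the r-th order statistics across samples; ties within a sample share the
  mean of the quantile means they span. The operation is idempotent.
  Expression values are treated as log2 after normalization; a flag
  applies log2 first for linear-scale input.
* **Probe collapsing** averages redundant probes per gene model; unmapped
  probes are dropped with a warning.
* **Welch's t test** (unequal variances, Welch–Satterthwaite df) backs the
  pairwise contrasts. At 3 replicates per group the approximation is
  conservative: the Monte-Carlo null rejection rate at α = 0.05 is ≈ 0.035
  (it reaches ≈ 0.044 at n = 5 and ≈ 0.048 at n ≥ 8). The test suite
  freezes both facts: the calibration check runs at n = 5, and a separate
  test documents the n = 3 conservatism. Zero-variance ties are handled
  explicitly (equal means → P = 1).
* **Two-factor ANOVA** uses the closed-form balanced decomposition
  (SS_genotype, SS_time, SS_interaction against the residual mean square),
  vectorized over genes, and requires a balanced design with ≥ 2
  replicates per cell — in the balanced case type-I/II/III sums of squares
  coincide, so the choice is immaterial. It is verified against an
  independent sums-of-squares oracle and against statsmodels' `anova_lm`.
* **PAGE.** For each gene set with ≥ 10 mapped genes,
  `z = (Sm − μ)·√m/δ` with μ, δ the mean and population SD of all fold
  changes; P is two-sided normal by default (one-sided available, since
  the original method's variant is one-tailed); BH-FDR is applied across
  all tested sets within one condition, significance at adjusted
  P < 0.05. z is equivariant under affine transforms of the fold-change
  vector (`fc → a + b·fc` gives `z → sign(b)·z`).
* **Constitutive screen.** A gene passes when every mutant-vs-wild-type
  Welch comparison (each mutant genotype × each timepoint) has P < 0.05
  *and* all fold changes share one sign. Direction consistency is required
  on top of the significance threshold because a constitutive response is
  by definition one-sided; genes missing any comparison are excluded.

## Synthetic study and what it does (not) show

The generators emulate the study conditions: traces with 40S/60S/80S and
two polysome peaks over a drifting sucrose baseline (closed-form truth
areas `amplitude·width·√(2π)`), a planted genotype × timepoint log2-FC
design with two-fold subunit over-accumulation before cold shift,
transient day-1 subunit depletion and persistent (up to four-fold) 80S
depletion in lines lacking the second biogenesis-factor paralog; paired
proteome experiments (wild type vs each allelic double mutant, 20 °C and
10 °C) with class-specific fraction profiles over six fractions, planted
biogenesis-factor accumulation (factor 2.5), paralog shifts (2.2 up, 0.45
down), one presence-only factor, mean-preserving log-normal noise
(CV = 0.2) and a detection limit censoring 10% of values to exactly 0; an
expression design of 3 genotypes × 3 timepoints × 3 replicates with
residual SD 0.25 log2 units, three planted 50-gene set shifts of ±0.5 and
six constitutively shifted genes (1.0–3.0 log2, matching the strong
activation such screens are meant to find). LFQ base abundances span
about three orders of magnitude with structural RPs at the top, as in
ribosome preparations.

What passing tests do **not** show about real data: peaks are exactly
Gaussian and baselines linear (no detector saturation, spikes or fraction
boundary effects); LFQ noise is independent across fractions (no shared
run effects or peptide-level structure); missingness is a hard threshold
rather than probabilistic; expression noise is homoscedastic Gaussian
with no array batch effects; and the annotation catalog is complete and
error-free. The packaged real-protein catalog covers only proteins named
in the compositional analysis; real studies must supply a full catalog.

## Problem sizes and numerical choices

Default sizes keep the full suite and the acceptance script desk-scale:
400-point traces, a ~72-protein catalog over 6 fractions, 2000 genes ×
27 samples, 10,000-replicate null calibrations and 100-replicate
enrichment recovery simulations. All random streams derive from one
integer seed (numpy `default_rng` with keyed sub-streams); identical seeds
give byte-identical outputs, and provenance headers in every CLI output
record the seed and package version. Degenerate inputs (flat traces, zero
reference sums, zero-variance genes, empty catalogs) raise or flag rather
than silently propagate.

## Known limitations

Absolute (molar) quantification, polysome-to-monosome ratio
interpretation, peptide-level inference, moderated-variance testing and
GO-hierarchy propagation are out of scope. The shared-direction selection
has no error control by design. The fraction-identity scoring weights are
heuristic; with fewer than four fractions, identities rely heavily on the
marker constraint. The paper-facing deposited-data comparisons (real
PRIDE/GEO accessions) require downloads and are not part of the test
surface; the synthetic study is calibrated to the reported qualitative
structure, not to reproduce deposited numbers.
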