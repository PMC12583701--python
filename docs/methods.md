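# Methods

## Model and procedure

The pipeline treats each cassette exon as a short time series of inclusion
levels. Per (exon, condition, timepoint, replicate), the skipped-exon
junction counts I (inclusion) and S (skipping) with effective form lengths
lI and lS give the length-normalised estimate PSI = (I/lI)/(I/lI + S/lS);
replicates with I+S below `min_total_reads` (default 10) or zero coverage
are uninformative, and the cell value is the mean over informative
replicates (missing if none). Trajectories with fewer than two observed
timepoints are *untestable* and excluded — they are counted separately,
never folded into Unaffected, so category denominators stay honest.

The relative inclusion rate z_t = (PSI_t − PSI_μ)/PSI_σ standardises each
trajectory against its own mean and standard deviation; a switch is a sign
reversal of z. The switching time is ordinal (a timepoint index), not a
duration: the analysis compares the *order* of switches between conditions,
not elapsed days, so uneven timepoint spacing (DIV0/3/5/10) is irrelevant
to the call.

Classification between conditions follows a fixed rule table (see
`switch_classify`): ties on index and direction are Unaffected; a control
switch without a perturbed switch is Late (the deferred switch is treated
as index +∞, matching the interpretation of a knockdown that *delays*
splicing transitions); the converse is Early; opposite directions are
Reversed regardless of index. "Reversed" is defined by direction
inversion, not by index order inversion — the operational definition is
stated here because it is genuinely open; the trajectory-mirroring picture
of reversal motivated the choice.

## Numerical choices

- **PSI_σ is the population SD** (ddof=0), matching heatmap-style
  z-scoring of a complete, fixed set of timepoints; `ddof=1` is a config
  toggle.
- **sigma_tol = 1e-8** and **zero_tol = 1e-8**: trajectories with SD below
  tolerance are degenerate (all z = 0, no switch); |z| below zero_tol maps
  to sign 0, and zeros inherit the most recent non-zero sign so a
  mean-crossing cannot produce a spurious double reversal.
- **Missing timepoints** propagate as missing z; a reversal is only called
  between two observed signs.
- **Multiple reversals**: the switch index is the *first* reversal (the
  definition is singular); the total reversal count is retained so
  non-monotonic exons can be flagged downstream.
- **Amplitude filter `min_psi_range` (default 0.05 in the pipeline, 0 at
  the operator level)**: z-scoring is scale-free, so a flat trajectory
  whose total PSI range is pure count noise would be amplified into random
  sign flips and spurious switch calls. Trajectories with range below a
  |ΔPSI| of 0.05 — the conventional floor for a meaningful splicing change
  — are treated as degenerate (no switch). Without this hygiene filter,
  exons whose perturbed switch lies beyond the observation window are
  systematically misread under replicate noise.

## Enrichment stage

Affected exons (Early+Late+Reversed) are compared against Unaffected exons
(the default background; "all non-affected" is a config option — the
appropriate background is genuinely underdetermined, and the choice is
exposed). Each exon contributes three disjoint transcript-sense windows:
the exon body and up to 200 nt of each adjacent intron, truncated at
neighbouring exon boundaries and chromosome ends; minus-strand loci are
reverse-complemented. Scanning is exact IUPAC sliding-window matching
(overlaps counted; an N in the genome never matches); presence (≥1 match
in any window) rather than match counts enters the per-RBP 2×2 table,
the standard choice for Fisher tests on region sets — counts are kept for
diagnostics. P-values are two-sided Fisher exact tests; odds ratios are
displayed with the Haldane–Anscombe 0.5 correction when a cell is zero
(the p-value always comes from the exact test); q-values are
Benjamini–Hochberg. Motifs are IUPAC consensus k-mers for the 46-RBP
eCLIP-characterised panel shipped as package data; position-weight-matrix
scoring is out of scope since no threshold convention is imposed by the
analysis.

The IP-MS refinement keeps RBPs that are significant (q ≤ α, default 0.05)
*and* present in the interactome list produced by the abundance-ratio
filter (ratio ≤ 0.78, non-strict by default with a `strict` toggle; the
boundary value is kept, following the more permissive of the two published
readings of the cutoff).

## Synthetic data: what it emulates, and what it does not

The generator plants logistic inclusion trajectories
ψ(t) = ψ_low + (ψ_high−ψ_low)/(1+exp(−k(t−t0))) with ψ_low/ψ_high =
0.1/0.9 and steepness k = 10 /day. Control switch times sit at the
midpoints of the inter-timepoint gaps (1.5, 4.0, 7.5 days) with ±0.2 d
jitter shared between conditions; the perturbation delay δ = 3 d maps
midpoints onto midpoints, so no planted switch falls on a sampled
timepoint and the truth is recoverable exactly in the noise-free limit.
Late exons whose delayed switch would leave the window are pushed to
t0 = 13 d so "never switches" is unambiguous. Junction counts are
T ~ Poisson(100) per replicate with inclusion reads Binomial(T, p),
p = ψ·lI/(ψ·lI+(1−ψ)·lS), making the length-normalised PSI estimator
unbiased for ψ. Default category counts 30/100/35/135 reproduce the
Early < Reversed < Late ordering of perturbed splicing programmes at
one-tenth scale — a conventional desk-size choice.

For the enrichment ground truth, windows are i.i.d. nucleotides at 45% GC;
for the designated enriched RBPs, chance motif occurrences are scrubbed
and one concrete consensus instance is planted with probability 0.6
(affected exons) vs 0.1 (background), with a rebuild guard so realised
presence equals the plant indicator exactly. Real flanking sequence is not
i.i.d. (splice-site signal, conservation, repeat content all structure
it), real trajectories are not logistic, and real replicate counts are
overdispersed relative to Poisson–Binomial; passing the recovery and power
checks therefore validates the *inference machinery* under its stated
assumptions, not the biology of any particular dataset.

## Validation studies and problem sizes

All validation runs are desk-sized by design: 300-exon studies, 200
affected + 200 background exons for the motif studies, 200 null replicates
for type-I calibration, 100 runs for power, and exhaustive enumeration of
2×2 tables to row margins of 30. The type-I study reports the pooled
fraction of null tests with p < 0.05 against a 3-SD binomial band around
the nominal level computed from the 200 simulation replicates; Fisher's
exact test is conservative on discrete tables (observed fractions run
0.03–0.04), so the check guards against anti-conservative behaviour rather
than demanding exact nominal attainment.

## Known limitations

- Switch calls are deterministic given the trajectory; no per-exon
  significance (e.g. an rMATS-style likelihood ratio test on ΔPSI) is
  attached, so the category table inherits the noise level of the input
  PSI estimates.
- Matches spanning an exon/intron boundary are not sought (windows are
  scanned independently).
- The 46-RBP consensus table is a curated example set; swapping in a
  project-specific motif file via `RunConfig.motifs` is expected for real
  analyses.
- One-sided-switch rules (Late/Early when only one condition switches) and
  the direction-based definition of Reversed are design choices; both are
  config-locked and documented rather than inferred from any single
  dataset.
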