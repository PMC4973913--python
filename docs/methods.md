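# Methods

This note records the statistical models implemented by the package, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical conventions that matter for reproducing a
run.

## Quantification indices

All indices are computed from protein-group level quantities as delivered
by the upstream search engine; the package never re-derives peptide
identifications or LFQ normalisation.

- **emPAI** is implemented as `10^(PN/PO)`.  The classical definition
  subtracts 1 so that a protein with no identified peptides scores 0; both
  forms are provided (`subtract_one=True` selects the classical one), with
  the plain power form as the default.  The two differ by a constant −1
  and are rank-equivalent.
- **NSAF** normalises length-corrected spectral counts to sum to exactly 1
  per table; an all-zero spectral-count table has no defined NSAF and is an
  error rather than a silent 0/0.
- **iBAQ** is `log10(MQ/PO)` by default; base 2 is available.  Intensity 0
  means not detected and yields a typed "not detected" result (`None`),
  never −inf.
- **Abundance classes** cut the log2 mean LFQ intensity at 18/23/28/33
  into `-`, `+`, `++`, `+++`, `++++`.  Intervals are half-open and closed
  on the left (a protein at exactly 33 is `++++`); the boundary convention
  is a package choice since "18 to 23" does not specify the endpoints.
  Proteins never detected are classed `-`, which treats the lowest class as
  sub-detection.  The mean is taken over raw LFQ values and then
  log-transformed (`log_of_mean=True`); averaging log2 values of the
  detected replicates instead is available as an option, because with
  missing values the two conventions differ.

Ranking for the enrichment analysis sorts by summed raw intensity across
experiments (mean LFQ is the alternative statistic) and breaks ties by
ascending accession, which makes bin membership invariant to input row
order.

## Observable-peptide counting

Tryptic digestion cleaves after K or R, suppressed before P by default
(the proline rule is a flag, since search engines differ by version), with
up to two missed cleavages.  PO counts *distinct* peptide sequences passing
all enabled filters; a positional (non-distinct) count is available, for
which the closed form (c+1) + c + (c−1) in the number of cleavage sites c
holds exactly.

Observability filters and defaults:

- length 6–35 residues (the range hard-wired into common iBAQ
  implementations);
- charge proxy = 1 + #(K, R, H), an electrospray charge-state stand-in
  (off by default);
- GRAVY, the mean Kyte–Doolittle hydropathy, rejecting extremes (off by
  default);
- predicted retention time from a linear model on GRAVY whose admissible
  interval can be estimated from an observed peptide/RT table as the
  1st–99th percentile of fitted predictions (off by default).  This is a
  deliberate first-order proxy, not a full retention model.

## Binned enrichment

For every intensity bin (default 50 proteins) and term, the p-value is the
one-sided upper-tail hypergeometric probability P(X ≥ k) with population
N, K term members in the universe and draws equal to the bin size.  The
universe defaults to the identified proteins of the same sample, not the
whole database: without knowledge of the abundance distribution of a term
among all proteins, a database-wide uniform assumption is not defensible.
The remedy implemented for that residual assumption is the two-profile
comparison: compute the same profile for a surface-enriched and a
total-proteome sample and difference the −log10 p values per bin.

Conventions: one-sided (enrichment only); Bonferroni correction across the
terms tested within a bin, not across bins; terms with fewer than
`min_members = 2` members in a bin report p = 1; a term absent from the
universe reports p = 1 with a warning.  Annotations are consumed as given —
no GO-graph ancestor propagation.

## Surface classifier

`((GA ∨ TM) ∧ PM) ∨ (SP ∧ (ECS ∨ ECR ∨ ECM))`, a monotone Boolean
expression over caller-supplied feature flags.  Flags come from the
annotation table; the package performs no transmembrane or signal-peptide
prediction.  Conflicting annotations (e.g. TM ∧ PM ∧ a cytosolic term) are
accepted as surface — the expression considers positive evidence only.
The first matching clause (GA∧PM, TM∧PM, then the SP clause) is recorded
per protein.

## Differential testing

The exact algorithm of the popular desktop implementation of this test is
unpublished; the package implements a SAM-style surrogate and documents it
fully:

1. **Filtering**: rows carrying any of the three categorical flags (only
   identified by site, reverse, contaminant) are removed; LFQ 0 becomes
   missing; log2 transform.  A protein is kept when it has at least
   `min_valid` (default 3) detected values in at least one group
   (`require_in="any"`, the rule for two-condition biological comparisons)
   or in every group (`require_in="all"`, used for benchmark designs in
   which a protein must be quantifiable in both compared conditions —
   this is why the lowest spike-in amount, which rarely yields three
   values, is excluded from testing rather than imputed into a fake
   fold change).
2. **Imputation**: missing cells are drawn per sample column from
   Normal(mean − 1.8·sd, (0.3·sd)²), the de-facto convention for
   left-censored proteomics missingness; both parameters are exposed.
   Column statistics use the observed values with ddof = 1.  Column-wise
   (rather than whole-matrix) distributions were chosen to follow the
   common desktop default.  A fixed seed reproduces the imputation
   bit for bit.
3. **Statistic**: d = (mean₁ − mean₂)/(se + s₀) with the pooled
   equal-variance two-sample standard error; at s₀ = 0, d is exactly the
   classical t statistic.  s₀ damps low-variance artifacts; typical
   working values are 0.2–1.0.
4. **Permutation FDR**: group labels are permuted over all distinct
   assignments when their number is ≤ 1000 (68 for 4 vs 4, 18 for 3 vs 3
   after exclusions), otherwise 250 seeded random assignments.  The
   identity assignment and its mirror are excluded — they reproduce ±d and
   carry no information about the null.  At a cutoff c the estimated FDR
   is (1 + T(c))/(B · R(c)), with T the pooled count of permuted |d| ≥ c
   over all B permutations and R the observed count.  The +1 pseudo-count
   keeps the estimate strictly positive; without it (or with a
   median-over-permutations numerator) the estimate collapses to 0
   whenever the top observed |d| exceeds all permuted values, which under
   a complete null happens in a large fraction of data sets and produces
   guaranteed false calls.  Per-protein q-values are the running minimum
   of the estimate over cutoffs including the protein; calls are q ≤ fdr,
   and the cutoff |d*| is the smallest significant |d|.
5. **Threshold curve**: the significance boundary |diff|/(se + s₀) = |d*|
   mapped into volcano coordinates (log2 difference, −log10 two-sided
   t-test p), defined for |diff| > |d*|·s₀ and symmetric about zero.

Null calibration is verified by simulation (200 null data sets of 1000
proteins, 3 vs 3): the realised false-discovery proportion stays at or
below the nominal level at FDR 0.01, 0.05 and 0.25 — raising the threshold
to 0.25 does not blow up false positives.

## Synthetic data

The generators define explicit, seeded study conditions; every parameter
is a dataclass field.

**Spike-in design** (differential benchmark): 48 spike proteins at 20,
6.7, 2.2, 0.74, 0.24 fmol in quadruplicate over a constant background of
1500 proteins with log10 intensity ~ Normal(10.5, 1.2).  Spike response
factors are log-normal (log10 ~ Normal(9.0, 0.3) per fmol), replicate noise
is multiplicative log-normal with CV 0.2, and detection is left-censored by
a logistic in log2 intensity with midpoint 4·10⁸ — just below the response
of the 0.74 fmol condition, so that 0.24 fmol rarely yields three valid
values — and slope 0.4.  Detection events share a per-protein latent
factor (Gaussian copula, ρ = 0.8): technical replicates of one digest,
especially with match-between-runs, lose a protein nearly all-or-none
rather than independently per injection.  This correlation matters: with
independent per-cell dropout, background proteins near the detection limit
frequently show 3-vs-1 detection splits whose imputed halves masquerade as
large fold changes.

**Dilution series**: two synthetic standard proteins (a large albumin-like
and a small casein-like stand-in) over 500 amol–500 pmol.  Spectral counts
follow a saturating Poisson rate `sc_rate · PO · I/(I + half_sat)` and
peptide numbers a coupon-collector binomial `PN ~ Binomial(PO,
1 − e^(−SC/PO))`, so count-based indices flatten near the top of the grid
while intensity stays proportional — the mechanism behind the inferior
dynamic range of spectral counting.

**Staggered accuracy standard**: 49 proteins in six tiers from 0.5 to
50,000 fmol in one sample.  Total response scales with PO (a protein's
signal is the sum over its peptides) times a log-normal per-peptide
response; dividing intensity by PO (iBAQ) removes exactly the systematic
part, which is why iBAQ attains sub-order-of-magnitude outliers while raw
intensity improves when compared against mass rather than molar input.

What the generators do **not** emulate: peptide-level spectra,
chromatographic drift, shared/razor peptide ambiguity, ratio compression,
between-sample normalisation error (raw and LFQ intensities are set equal),
and real annotation structure.  Passing benchmarks on these simulations
shows the statistical machinery is correct and calibrated under the
declared model, not that any particular laboratory data set satisfies the
model.

**Accuracy evaluation** regresses log10 index on log10 input.  In dilution
designs points are centred per protein (each protein has its own response
factor); in staggered designs a single pooled regression is used — that is
the absolute-quantification reading in which response heterogeneity shows
up as outliers.  The maximum outlier is measured against a robust line
(Theil–Sen slope, median intercept) so that a single corrupted value
registers its own full displacement; the dynamic range is the span of
input orders over which per-amount mean deviations stay within 0.5 orders.

## Numerical conventions and degenerate inputs

- Missing/empty intensity cells parse as 0; 0 means not detected
  everywhere.
- Multi-accession protein groups are keyed by the leading (razor)
  accession.
- Ties in intensity ranking break by ascending accession.
- The simple-TSV writer renders floats with 6 significant digits; a
  written table re-reads equal to the original at that precision.
- Degenerate cases raise typed errors rather than returning silent
  defaults: PO = 0 (emPAI/iBAQ undefined), all spectral counts zero
  (NSAF), an imputation column with fewer than two observed values, groups
  with fewer than two samples, no non-trivial permutation.
- Problem sizes used by the test-suite simulations (1000-protein null
  matrices, 200 null repeats, 1000 annotation permutations, 500 random
  digestion sequences, one 1548-protein spike-in table) were chosen to
  keep Monte-Carlo standard errors small relative to the tested margins
  while the whole suite stays fast.

## Known limitations

- The permutation FDR has limited tail resolution at 3 vs 3 replicates
  (18 permutations); with the +1 guard the procedure is conservative
  rather than anti-conservative there.
- The SP clause of the surface classifier cannot distinguish secreted from
  surface-tethered extracellular proteins; that distinction requires
  evidence beyond the seven feature flags.
- Retention-time observability is a linear hydrophobicity proxy; peptides
  whose elution is dominated by other properties are misjudged.
- emPAI and PN saturate at PO per construction; their accuracy reports are
  meaningful only below saturation.
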