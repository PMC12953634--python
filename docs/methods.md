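# Methods

This note documents the models behind each analysis stage, the synthetic
data they are validated against, and the numerical choices that were
genuinely open.

## Synthetic sequencing data

A clone genome is a set of copy-number segments tiling each chromosome plus
SNVs with explicit allele configuration (`alt_copies` of
`site_total_copies`). Resistance events are applied in a fixed order:
whole-genome duplication (doubling both alt and total copies, so expected
allele fractions are invariant), segmental gains/losses (segments split at
event boundaries; SNV totals re-synced and alt clipped to the new total),
then SNV gains (novel variants at one copy), losses (alt set to 0) and
fixations (alt set to the site total; idempotent on already-fixed
variants).

Sequencing observables:

* **Per-site depth** is negative binomial via a gamma–Poisson mixture. The
  `depth_dispersion` parameter is the **coefficient of variation of the
  gamma mixing distribution** — the relative extra-Poisson depth noise —
  so `var = μ + (cv·μ)²`. At the default 60× and cv = 0.2 the depth SD is
  ≈ 14 reads, typical of a well-behaved short-read library. The depth model
  is deliberately overdispersed (not Poisson) because the ploidy fit must
  tolerate realistic depth heterogeneity.
* **Allele depths** are binomial in `alt_copies / site_total_copies` given
  the drawn depth; an optional beta-binomial (`af_overdispersion` = the
  intraclass correlation ρ) adds allelic overdispersion and is off by
  default so closed-form oracle checks stay exact.
* **Window counts** are negative binomial with mean proportional to the
  length-weighted mean copy number of the window. The expected count of a
  full window at base ploidy is `mean_depth × window_size / 150` (150 bp
  reads). The multiplicative depth bias is modelled as correlated over
  ~1 kb, so a window of `w` bp averages `w/1000` independent bias
  fluctuations and its extra-Poisson CV is `depth_dispersion·√(1000/w)`
  (≈ 2.8 % for 50 kb windows at cv = 0.2). Without this aggregation a 50 kb
  window would inherit the full per-site 20 % CV, which no real library
  shows and which would make focal events statistically invisible at the
  depths studied.
* **Panel sites** are germline-like heterozygous positions present in every
  sample; at local copy number m each draws `alt_copies` uniformly from
  1..m−1, so expected allele fractions populate the full k/m lattice. They
  stand in for a population SNV panel used for B-allele-frequency spectra.
  An optional `site_catalog` emulates joint calling: catalogued sites a
  clone does not carry are emitted with reference-only coverage at the
  local copy number, so parental samples report read support at positions
  private to a resistant derivative.
* Everything is deterministic given `(seed, sample_name)`; the per-sample
  stream is derived from a SHA-256 digest of the sample name.

What the generator does **not** model: read-level artefacts, mappability,
sequencing error, mutational signatures, and subclonal mixtures — each
clone is a single homogeneous population. Passing recovery tests therefore
show the estimators work under clonal, bias-free conditions; they do not
certify behaviour on contaminated or subclonal real data. In particular
the hypothesis that a resistant line's tetraploidy arises from expansion of
a pre-existing tetraploid subpopulation is outside the simulated model
space.

## Copy-number profiling

`ratio_i = count_i / median(counts > 0) × ploidy`. The median (not mean) is
used for robustness to focal amplification, and zero-count windows are
excluded from it. Ploidy is an explicit input so that a genome-doubled
sample can be normalised at 4 while its parental line is normalised at 2.
GC correction rescales counts by global-median / per-GC-bin median over
equal-width GC bins; bins with fewer than 20 windows are left unscaled.

Segmentation is recursive binary segmentation: the candidate breakpoint
maximises the two-sample mean-difference z-score and is accepted when it
exceeds `z_threshold` (default 5) with at least `min_windows` (default 5)
windows per side. Two numerical choices matter:

* the z denominator uses a **robust global noise SD** — the MAD of lag-1
  window differences, which is insensitive to the very level shifts being
  tested — rather than within-side SDs, which a true step inflates;
* after recursion, adjacent segments whose mean difference does not itself
  clear the threshold are merged, and state calling reports contiguous
  segments with the same state and integer copy number as a single event
  (a true boundary falling within `min_windows` of a breakpoint otherwise
  leaves a same-CN stub).

Per-segment level is the median of member windows. States use a half-copy
margin (default 0.5): the midpoint between adjacent integer copy states.
Gene-level copy number is the median ratio of fine windows overlapping the
gene after the same normalisation. The procedure is deterministic;
identical input yields identical breakpoints.

## Ploidy inference

For a candidate total copy number m, interior allele fractions are modelled
as a mixture of (m−1) normal components truncated to (0,1) with means fixed
at k/m, one shared SD σ, free weights, and a Uniform(0,1) component for
noise. Fixing the means turns the fit into the hypothesis test actually
wanted ("which ploidy lattice explains the spectrum?") and avoids label
switching; the shared σ keeps m = 4 identifiable at moderate n. σ is
bounded above by 0.15 — component widths must stay on the scale of an AF
peak (the binomial width at realistic depths), or a near-flat "peak" would
impersonate the uniform and destroy identifiability.

Fitting is EM; the weights M-step is closed-form, while the truncated
shared-σ step has no closed form and is done by bounded 1-D maximisation of
the expected complete-data log-likelihood (ECM), preserving the monotone
log-likelihood guarantee, which is asserted per iteration. Convergence:
absolute log-likelihood change < 1e−6, max 300 iterations.

Model selection is BIC = −2ℓ + p·ln n with p = (m−1) weights + 1 σ (the
uniform weight is implied by normalisation), minimised over candidates
{2, 3, 4} by default, ties toward smaller m. Per chromosome, up to 10,000
AF values are subsampled without replacement (seeded). AF values of exactly
0 or 1 are excluded from spectra (no interior peak can host them) but are
retained upstream for fixation analysis. Fits are per sample; pooling
resistant lines is left to the caller.

## Variant frequency shifts

The 2×2 table [parental (ref, alt); resistant (ref, alt)] is tested with a
two-sided Fisher exact test — two-sided because gains and losses are both
of interest. The p-value is the sum of hypergeometric masses of all tables
as or less probable than the observed one (relative tie guard 1e−7),
computed vectorised in log-gamma space; a call costs tens of microseconds,
which is what makes exhaustive enumeration checks and genome-scale scans
affordable. Tables where one sample has zero depth are returned as missing.

The loss test conditions on zero alt reads in the resistant sample:
p = (1 − f)^D evaluated in log space, with f the parental point-estimate AF
(a ploidy-lattice expected frequency is available as an option; the
point estimate is the default because it uses no ploidy assumption).

The Fisher and binomial families are BH-adjusted **separately**, matching
their distinct operating thresholds (q < 0.05 and q < 0.1). Categories are
assigned with precedence lost > gained > fixed > changed > stable; a
variant is *fixed* when its resistant AF ≥ 0.95 (configurable) and its
parental AF was below that. Because a novel variant can be both
significantly gained and fixed, fixation is additionally recorded as an
independent boolean flag, and the fixation fraction is the share of novel
variants carrying that flag — so the exclusive category and the fixation
summary cannot shadow each other.

## Phospho-statistics

Row z-scoring uses the sample-SD convention, ignores missing entries and
leaves (flagged) constant rows unscaled. The differential statistic is
t_s0 = (mean_B − mean_A) / (SE_pooled + s0) with the classical
pooled-variance SE (Student rather than Welch as the base; an option) and
s0 = 0.1 by default. With s0 = 0 it reduces exactly to the classical t;
zero-variance features stay finite at Δ/s0.

Permutation FDR: distinct group relabellings are enumerated (complementary
pairs collapsed in balanced designs, observed labelling excluded) and
seeded-subsampled when they exceed `n_permutations` (default 250). The
candidate subset is ordered canonically by sample names, which makes the
significant set exactly symmetric under a group-label swap of a balanced
design. FDR(c) = mean permuted exceedance count / observed exceedance
count, clipped to [0,1] and made monotone non-increasing in c; the cutoff
is the smallest observed |t_s0| with FDR ≤ target. The estimator uses the
mean over permutations and no π₀ correction — conservative. With 3 vs 3
samples only 9 distinct relabellings exist, so attainable FDR values are
coarse (granularity 1/9 per feature-free scaling); this is an intrinsic
property of the design, visible in the pipeline demo's modest power.
Features with fewer than two valid values in either group are excluded
*before* permutation so the permutation null stays exchangeable.

## Pharmacology

POC = 100 × raw / mean(vehicle). The 4PL
`POC(d) = bottom + (top − bottom) / (1 + (d/ic50)^hill)` is fitted by
trust-region least squares on log10 dose with multi-start (IC50 at every
observed dose × hill ∈ {±1, ±2}); the (top, bottom, hill) ↔
(bottom, top, −hill) symmetry is canonicalised to top ≥ bottom. Two IC50s
are reported: the fitted inflection (`ic50_uM`) and the **absolute IC50**
(dose where the fitted curve crosses POC = 50) — the operative assay
definition; as an estimator the crossing is markedly more stable because
errors in top/bottom/hill largely cancel there (under the default screen
conditions its relative SD is ~4–5 % versus ~6.5 % for the inflection,
which sits at the Cramér–Rao bound of the 4-parameter fit).

AUC is the trapezoid integral of POC over log10 dose divided by the log10
span — a 0–100-scale quantity (flat POC 100 → AUC 100) on which the
hit-rule threshold "difference > 50" is meaningful. One AUC per replicate
series gives the mean ± SD used by the hit rule. A line passes when
AUC_fib − Sd_fib > AUC_line + Sd_line **and** AUC_fib − AUC_line > 50; a
compound is a hit at ≥ 2 passing lines (1 permitted for single-line
screens).

Synergy operates on fractional inhibition y = 1 − POC/100, clipped to
[0, 1]:

* **Bliss**: expected = yA + yB − yA·yB from the observed monotherapy
  rows; excess in percentage points; identically zero on monotherapy cells.
* **Loewe**: the expected response solves a/DA(y) + b/DB(y) = 1 with DX the
  inverse 4PL dose, by root bracketing to 1e−6 on the shared response
  range; cells with no root take the nearer boundary (flagged behaviour of
  saturated corners). A sham combination (a drug against itself) scores
  < 1 point everywhere.
* **ZIP**: marginal logistic fits (inhibition scale, 0→1) define the
  zero-interaction expectation; for each positive partner dose a
  conditional logistic is refitted along the other axis with the
  partner-induced inhibition as the fixed lower asymptote and 1 as the
  upper; delta = mean of the two conditional fitted responses minus the
  expectation. Rows too sparse to refit (< 4 positive doses) are flagged
  NaN rather than imputed.

MSA is the maximum mean excess over a `window × window` (default 3×3)
contiguous block of the strictly-positive-dose surface; smaller surfaces
fall back to the largest available square. The constant-delta generator
contract (Bliss excess exactly the planted delta at every interior cell)
holds on grids away from the inhibition ceiling; recovery checks therefore
use IC50s at the top dose so no cell saturates.

Assay utilities: calliper tumour volume L×W²/2 (warns when width exceeds
length) and the comparative-Cq expression fold change 2^−ΔΔCq.

## Pipeline

`run_pipeline` executes simulate → cnv → ploidy → shift → phospho →
screen → synergy on simulated inputs, with one global seed fanned out to
per-stage seeds by a counter-based rule recorded in the manifest. The shift
stage analyses the somatic catalogue only — panel heterozygous sites draw
their allele configuration per sample and are not frequency-shift
candidates. Demo problem sizes (two 5 Mb chromosomes, 4,000 panel sites
per chromosome, 1,000 somatic SNVs, 1,000-feature phospho matrices) were
chosen so a full run completes in well under a minute on one CPU while
every stage still has clear statistical signal; all are configurable.

## Known limitations

* Clonal populations only; no subclonality, contamination or purity model.
* The ploidy mixture assumes one shared peak width; strongly
  depth-stratified spectra violate this mildly (the uniform component
  absorbs the tails).
* The loss test uses the parental point-estimate frequency; at low
  parental depth this underestimates uncertainty in f.
* Loewe scoring requires monotone, invertible monotherapy fits; flat or
  bell-shaped responses are not supported.
* ZIP deltas are biased toward zero for synergy patterns a shifted
  logistic cannot represent (e.g. a constant additive offset), by roughly
  a quarter under the constant-delta generator.
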