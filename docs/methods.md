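# Methods

This note documents the statistical procedures implemented in `mrtri`,
the generative model behind its synthetic data, the numerical choices
that were genuinely open, and what the package's tests do and do not
establish about real data.

## The three evidence streams

**Liability scan.** A genetic risk score is built from an external
disease GWAS: per-allele log-odds weights for an LD-independent variant
panel. Scoring follows the standard external-weights construction
(`score_grs`): dosage (0–2) × weight, summed over the variants observed
for an individual, divided by that count (a strict mode divides by the
full panel size instead; the per-individual denominator keeps scores
comparable under sporadic missingness). The scan regresses each
metabolite, at each time point, on the score with sex and mean-centred
age as covariates, using OLS with HC1 sandwich standard errors and a
normal reference for Wald p-values. Two scale conventions circulate for
such scores: the per-SNP-average-and-z-scored GRS (convenient
descriptively) and the summed log-odds scale. Only the latter supports
the per-doubling reading — multiplying a per-unit-log-odds coefficient
by ln 2 ≈ 0.693 gives the effect per doubling of the odds of disease —
so the scan regresses on the summed log-odds score and applies ×ln 2 to
the estimate, its SE and both CI bounds as the final step (p-values are
invariant to this rescaling). The z-scored GRS remains available via
`zscore` for descriptive use.

Metabolites are standardized and normalized before regression with the
rank-based inverse normal transformation: rank r of n maps to the
standard-normal quantile at (r − c)/(n − 2c + 1). The offset c = 3/8
(Blom) is the default; ties take average ranks so the transform is
deterministic, and the transformation is applied within time point.
Analysis is complete-case per time point, with a collinearity guard that
drops the sex column for single-sex designs.

Benjamini–Hochberg FDR adjustment is applied across metabolites within
each time point × sensitivity family, matching the per-age presentation
of repeated-measures scans; adjusted p < 0.05 is the association
heuristic throughout. A gene-region exclusion sensitivity rerun (e.g.
dropping FADS1/2/3-cluster variants, a canonical direct-lipid-effect
concern) rescores and re-estimates everything; region tags come from a
user-supplied variant→gene map, since coordinate windows for such
clusters are convention-dependent.

**Two-sample MR.** Instruments are selected by p < 5×10⁻⁸ followed by
greedy LD clumping: candidates ordered by ascending p (ties broken
lexicographically by variant id for determinism), each accepted only if
its r² with every already-accepted variant stays at or below the
threshold (0.001 by default). Exposure and outcome tables are harmonized
to a common effect allele: swapped labels flip the outcome beta and
complement its frequency; unambiguous strand flips are resolved by
complementing; palindromic (A/T, C/G) variants are dropped when either
frequency is missing or the exposure EAF lies in (0.42, 0.58), otherwise
aligned so minor/major status agrees across datasets. Every drop is
logged with a reason; no proxy-variant lookup is attempted — instruments
absent from the outcome are dropped.

Per-variant Wald ratios use the first-order delta-method SE σᵧ/|β̂ₓ| (a
second-order correction is available behind a flag). The estimators:

- *IVW, multiplicative random effects*: precision-weighted mean of the
  ratios; equivalently WLS of outcome on exposure betas through the
  origin with weights σᵧ⁻² (this equivalence is enforced in the test
  suite against an independent WLS fit). The fixed-effect SE is
  multiplied by max(1, √(Q/(L−1))), so the random-effects SE never falls
  below the fixed-effect one. A single instrument degrades to the Wald
  ratio, labelled as such.
- *Weighted median*: instruments sorted by ratio; with standardized
  weights w′ⱼ and cumulative midpoints sⱼ = Σₖ≤ⱼw′ₖ − w′ⱼ/2, the
  estimate interpolates linearly between the ratios bracketing s = 0.5.
- *Weighted mode*: maximizer of a Gaussian-kernel weighted density over
  the ratios on a fixed 512-point grid spanning the ratio range ± 3
  bandwidths. Bandwidth h = φ·1.4826·MAD(ratios), φ = 1 by default. When
  the MAD is 0 (a majority of identical ratios) the fallback is the
  Silverman-scaled weighted SD, φ·0.9·σ_w·L^(−1/5): a raw-SD fallback
  makes the kernel so wide that a 3-vs-1 majority cluster's mode is
  dragged visibly toward the minority, whereas the Silverman factor — the
  standard KDE bandwidth scaling — resolves the cluster.

Median and mode SEs come from a parametric bootstrap (both betas redrawn
from their SEs; 1000 resamples by default, seeded); p-values use the
normal approximation on the bootstrap SE rather than percentile
intervals, matching common practice. `n_boot=0` skips the bootstrap for
simulation loops that need only point estimates. Instrument strength is
summarized by per-variant F = (β̂ₓ/σₓ)², with a warning flag when the
minimum falls below the conventional 10.

Direction-specific post-processing: reverse runs (liability → metabolite)
rescale estimates by ln 2 to the per-doubling scale; forward runs
(metabolite → disease) exponentiate the estimate and CI bounds to odds
ratios per SD, keeping the SE on the log scale. FDR families are
(direction × method × sensitivity) across traits, computed on the
pre-transformation p-values (both rescalings leave them unchanged;
scaling is deliberately applied after inference).

**Triangulation.** Each metabolite receives one consistency class from
the signs of its FDR-flagged results: the scan direction is taken from
the time point with the smallest adjusted p; MR directions from the IVW
row (primary), with a note when median/mode disagree in sign. The rules,
in precedence order: flagged streams with conflicting signs →
`inconsistent`; all three flagged, same sign → `consistent-causal-
candidate`; otherwise a flagged forward stream → `forward-only`; flagged
scan and/or reverse without forward → `liability-marker-only` (a
predictive marker of liability without downstream causal support — the
pattern classically seen for cholesterol-related traits); nothing flagged
→ `insufficient`. "Consistent evidence across approaches" has no
standard formalization, so these rules are an explicit operationalization
and the output says so; the precedence also fixes the otherwise-undefined
case of a forward flag plus exactly one concordant liability-side flag
(classified `forward-only`, since the causal-candidate label is reserved
for full three-stream support). Metabolites missing from a stream are
classified from the available streams and annotated, never dropped.
Classes partition the metabolite set and are invariant to row order and
to a simultaneous sign flip of all three streams.

## Synthetic data: what it emulates

`gen_variant_panel` emulates a disease-liability GWAS panel: minor-allele
frequencies uniform on (0.05, 0.5]; per-allele log-odds weights
half-normal with scale 0.08 plus a small floor (risk-raising orientation,
effect sizes in the range typical of common-variant disease loci).
Observed betas are the weights plus sampling noise, with |z| drawn
uniform in (6, 12) and floored so every variant stays genome-wide
significant when requested — per-variant F ≈ 36–144, the range reported
for real liability panels. LD blocks are generated through a Gaussian
copula (haplotype alleles share a latent equicorrelated factor at
√r²_target), and the LD matrix handed to clumping holds the *realized*
r² of a 2000-haplotype-pair reference draw within correlated blocks.
Pairs that are independent by construction (across blocks, and within
blocks whose target r² is 0) carry exact zeros: a finite reference
sample's empirical r² between independent variants exceeds a 0.001
clumping threshold with probability ≈ 0.16, which would make clumping
behaviour on "independent" synthetic panels non-deterministic for no
scientific gain.

`gen_cohort` draws Hardy–Weinberg genotypes (no population structure —
the real analyses adjust for ancestry, which is out of scope here), a
liability score S = Σwg in log-odds units, and metabolites
θ_k·(S/ln 2) + b_sex·(sex − mean) + b_age·(age − mean) + ε at each time
point, so θ_k is *exactly* the per-doubling estimand of the scan. Default
covariate effects are 0.1 (sex) and 0.01/year (age), small relative to
noise as observed for most NMR traits at these ages. With
standardization requested (`noise_sd=None`) the residual SD is calibrated
per metabolite so the marginal variance is ≈ 1, which keeps the rank-INT
transform close to the identity and the estimand undistorted; an
explicit `noise_sd` (including 0, for deterministic limiting cases) is
used as given. Liability stays continuous — no binary disease status is
generated, since the scan's estimand involves only the weighted score.

`gen_two_sample` emulates paired exposure/outcome GWAS: true instrument
effects γⱼ with |γ|/se uniform in (10, 20) (F ≈ 100–400) and exposure
SE 0.05. Instrument strength was fixed at this level by a design
calculation, not after the fact: the calibration study measures each
estimator's mean over 500 replicates against a 3-Monte-Carlo-SE band of
≈ 0.001–0.002, and first-order weak-instrument attenuation of order
θ/F̄ must sit well inside that band (at F̄ ≈ 230 it is ≈ 0.0004).
Instruments are oriented to the exposure-raising allele — the standard
instrument convention — which matters for the pleiotropy scenarios:
with randomly signed γ, a constant outcome-scale pleiotropic shift
averages out on the ratio scale and "directional" pleiotropy would not
bias IVW at all. Outcome betas are θγⱼ + αⱼ + noise with αⱼ = 0 for
valid instruments, Normal(0, σ_p) under balanced pleiotropy and
Normal(+σ_p, σ_p/2) under directional pleiotropy (σ_p = 0.3 by default,
several times the mediated effect — a deliberately strong contamination
regime in which the robust estimators' consistency conditions hold while
IVW's fail). Allele labels can be scrambled in the outcome table to
exercise harmonization without changing information content.

`gen_triangulation_scenario` assembles a full synthetic study: a 65-SNP
liability panel (the count available in the motivating cohort analysis),
a cohort of 3000 with the first 5 of 20 metabolites causal at θ = 0.15
per doubling in the scan sense, reverse-MR outcome GWAS for each
metabolite over the panel variants (metabolite SE 0.02), and per-
metabolite 30-instrument forward sets against one pooled disease GWAS
(SE 0.05). Effects are sized so each stream flags causal metabolites
with high but not certain probability; occasional single-metabolite
omissions across seeds are FDR-threshold behaviour, not pipeline
failure, and the recovery study reports false inclusions separately
(expected: none).

All generators draw from one seeded `numpy` Generator per call —
identical seed and parameters give byte-identical outputs — and can
write a YAML truth sidecar recording every generative parameter.

## What passing tests do and do not show

The synthetic cohorts have Gaussian metabolites, binomial genotypes, no
population structure, no assortative mating or dynastic effects, no
selection, and pleiotropy confined to the stylized balanced/directional
mechanisms. Passing the calibration, robustness-ordering and recovery
studies therefore establishes that the *implementation* of each
estimator and of the pipeline is correct under its own assumptions — it
does not establish that those assumptions hold in any real cohort, nor
the real-data power of the design. The variance explained by a real
liability GRS in a real cohort is unknown here; synthetic effect sizes
were chosen for testability, not realism.

## Monte-Carlo study sizes

Chosen so the full verification battery (test suite plus reproduction
script) completes in minutes on one CPU while leaving the Monte-Carlo
error well below the effects being checked: calibration and robustness
studies use 500 replicates of 50 instruments; scan recovery uses 200
cohorts of n = 5000 (one time point, 20 causal + 20 null metabolites —
FDR behaviour across a metabolite family needs the family, not the full
231-trait panel); triangulation recovery uses 3 full scenario runs;
oracle-equivalence checks use 100–1000 random instances at tolerance
1e-10 or exact brute force.

## Known limitations

No MR-Egger, Steiger filtering, multivariable MR or colocalization (not
part of this design); no proxy-instrument lookup; no VCF/BGEN/PLINK
parsing (dosages arrive as rectangular text); additive random-effects
IVW is not implemented (the multiplicative form with the √(Q/df) floor
is the common reading of "random-effects IVW"); sex-stratified scans are
not implemented. The weighted-mode grid resolution (512 points) bounds
the estimate's precision at (range + 6h)/511; the bootstrap SE treats
per-variant betas as independent normals.
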