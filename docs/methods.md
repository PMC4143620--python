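# Methods

This note documents the models implemented in `ibdassoc`, the defaults and
why they were chosen, what the simulator does and does not emulate, and the
numerical choices a user relying on the results should know about.

## Pedigree quantities

Kinship Φ is computed by the standard recursion over a topological order of
the pedigree (founders assumed non-inbred and mutually unrelated; a missing
parent contributes 0). The coefficient-of-relationship matrix is R = 2Φ,
block-diagonal by family, with diagonal 1 + f.

**Unrelated pairs.** "Unrelated" is kinship exactly 0 under the pedigree.
This deliberately includes within-family pairs of married-in founders, not
only cross-family pairs: it is the literal definition, and cross-family
pairs dominate the lists anyway. Individuals with missing case status are
silently excluded (logged).

## The pairwise IBD model

The latent IBD state of a pair at a locus is k ∈ {0, 1, 2}, the number of
haplotype pairs sharing an allele IBD. Each of the two haplotype pairs is an
independent 2-state Markov chain with stationary IBD probability β and
transition kernel over genetic distance d (cM)

P(d) = Π + e^{−αd}(I − Π),  Π rows = (1−β, β),

and the 3-state chain is the symmetrized product (count of IBD component
pairs). Consequences used as test oracles: P(0) = I, Chapman–Kolmogorov
holds exactly, and the stationary law is ((1−β)², 2β(1−β), β²).

This condensed genotype-level state space is a documented simplification of
detailed pair-IBD state spaces used by dedicated linkage software. For
non-inbred, pedigree-unrelated pairs — the only pairs the scan uses — the
finer states are not identifiable from unphased genotypes, and the
downstream summaries only distinguish Any-IBD from Not-IBD.

**Defaults.** α = 0.05 per cM and β = 0.01 target recent, population-level
IBD segments; the calling threshold is κ = 0.9. The genotype error rate
defaults to ε = 0.01 (typical array/sequencing error magnitude); ε enters
as a mixture E_k ← (1−ε)² E_k + (1−(1−ε)²) E_0 of the IBS-given-IBD
emission table toward the independent table.

**Decoding.** Scaled forward–backward with the stationary initial
distribution; missing genotypes and monomorphic markers emit 1 in every
state (skipped, not errors). A state is called at a marker iff its
posterior ≥ κ, else NO_CALL. Segments are maximal runs of the same call
class (Any-IBD / Not-IBD / No-call); a segment's length is the cM span from
its first to last marker, so single-marker runs have length 0 but still
count. Per-step scaling makes the likelihood exact in log space for
arbitrarily long panels. If a panel lacks cM positions, 1 cM/Mb is assumed.

## Region selection

Sharing rates use called states (not posteriors): rate_g(m) = fraction of
group-g pairs called Any-IBD at marker m, with NO_CALL pairs kept in the
denominator. This matches summarizing by called-state proportions. Each
group's curve is centred by its genomic mean. A marker is flagged when the
centred CaCa rate exceeds the *genome-wide maximum* of the centred CaCo
rate plus τ; a `pointwise` comparison mode is also provided, but the
max-mode is the default, being the more conservative reading of "larger
than the maximum CaCo ratio". τ defaults to 0 (no published value exists);
regions are maximal runs of ≥ 2 flagged markers, with boundaries at the
first/last flagged marker's position (no midpoint extension).

Marker preparation: markers with sample MAF < 5% are removed before IBD
inference (a spuriously shared rare allele is otherwise overwhelming
evidence of IBD). Optional LD pruning uses a 1 cM sliding window advancing
by half a window; while any within-window pair has r² above the ceiling,
the pair with the largest r² loses its lower-MAF member (tie: higher
index). "Linkage information content" is thus operationalized as MAF,
consistent with removing the lowest-MAF markers.

## Two-stage association

**Stage 1 (EB load).** Genotypes (or dosages) of the region are
standardized per marker, z = (g − 2p̂)/√(2p̂(1−p̂)), and modeled as
z_im = b_i + ε_im with b ~ N(0, σ²_b), ε ~ N(0, σ²_ε), fitted by ML on
per-individual sufficient statistics (missing markers dropped per
individual). The load is the BLUP
EB_i = m_i σ²_b / (m_i σ²_b + σ²_ε) · z̄_i. The concrete one-way
specification (single shared variance, ML, BLUP shrinkage) is this
package's design choice — published two-stage analyses defer the details to
prior work without equations — and is validated by parameter recovery, not
by matching any external implementation. If σ̂²_b hits 0 the EB loads are
all 0 and the summary is flagged.

**Rare burden.** s_i = summed minor-allele dosage over region markers with
0 < MAF < `rare_maf_max` (default 0.01, configurable; "rare" is nowhere
given an operational definition in this literature — the 5% cutoff belongs
to the IBD panel, not the burden). Missing genotypes contribute the marker
mean (logged).

**Stage 2 (LMM).** Marginal family covariance
V_i = σ²ᵤ (R_i ⊗ J_T) + I ⊗ Σₑ restricted to observed rows (row deletion,
valid under MAR). T is fixed at 4 waves; an internal report of "6 repeated
measurements" alongside a 4×4 covariance in the source literature is
treated as a typo for 4. Fixed effects are profiled by GLS; (σ²ᵤ, Σₑ) are
maximized numerically with σ²ᵤ log-parameterized and Σₑ log-Cholesky
parameterized, starting from method-of-moments values (OLS residual
covariance by wave; between-family variance of mean residuals), with up to
5 perturbed restarts on failure. Estimation is ML by default so that
log-likelihoods are comparable across fixed-effect specifications; REML is
available (`method="reml"`) and is the right choice when unbiased variance
components are the goal — the acceptance-grade recovery simulation uses it.
σ²ᵤ may hit the 0 boundary; the fit is then flagged and no SE is reported
for it. SE(σ̂²ᵤ) otherwise comes from the observed information of the
profile likelihood via the delta method.

For complete balanced data the likelihood is evaluated through a per-family
eigendecomposition of R_i, reducing every evaluation to batched T×T
Cholesky factorizations; the general (missing-data) path builds each
family's V_i directly. Both paths agree to 10 significant digits and the
general path is cross-checked in the tests against a dense multivariate
normal built from first principles and against statsmodels MixedLM in the
random-intercept special case.

**Test.** W = (β̂₂, β̂₃) Cov⁻¹ (β̂₂, β̂₃)ᵀ referred to χ²₂
(p = e^{−W/2}). Single-coefficient p-values are reported from the joint
model (the marginal-versus-joint choice is not determined by the source
analyses; the joint model is used consistently). When the burden covariate
is degenerate (no polymorphic rare marker), the β₂-only model is fitted and
the row flagged. Multiple testing uses plain Bonferroni at the per-dataset
region count, reported exactly and at one significant figure.

## The simulator: what it states, what it omits

The generator's defaults are a fixed "stated world", chosen once:

| quantity | default | rationale |
|---|---|---|
| families | 20 | cohort scale of the motivating study |
| family template | 3 generations, 3 children, 2 grandchildren each (14 members) | multigeneration structure with married-in founders |
| markers | 784 on 220 cM | LD-pruned GWAS panel density on a chr-3-sized map |
| marker MAF | Uniform(0.05, 0.5) | post-MAF-filter GWAS spectrum |
| β₀ | 70 mmHg | mean DBP ≈ 85 at mean age → ~30% hypertension prevalence at the 90 mmHg clinical cutoff, typical of BP-ascertained family studies |
| β_age, β_smoke | 0.3 mmHg/yr, 2 mmHg | epidemiological magnitudes |
| σ²ᵤ | 10.6 mmHg² | the motivating study's own estimate of the family variance |
| Σₑ | AR(1)-like, var 60 mmHg², ρ = 0.5 | realistic serial correlation across 4 waves 5 years apart |
| dosage noise | sd 0.1, clipped to [0, 2] | imputation-quality dosages |
| causal variants | 5 at MAF 0.04 on one ancestral segment (100–110 cM) | "multiple rare variants of moderate effect" on a shared founder haplotype |

Rare causal variants all ride on a single ancestral haplotype segment: a
fraction `causal_maf` of founder haplotypes have their alleles across the
causal interval replaced by one shared segment carrying the alternate
allele at every causal marker. Carriers in different families therefore
share a long identical haplotype there — exactly the signature pairwise IBD
mapping exploits — while remaining unrelated by pedigree. Phenotypic
enrichment of carriers among cases comes from β₃ acting on DBP before
thresholding at 90 mmHg.

LD, when requested, comes from a finite founder-haplotype pool
(`pool_size`, default 8) rather than a coalescent simulation: it is
controllable, dependency-free, and sufficient to reproduce the qualitative
effect that ignoring LD inflates apparent IBD. The simulator does **not**
emulate: real imputation or phasing (dosages are truth + Gaussian noise),
ascertainment of families through the phenotype, medication-based
hypertension definitions or treatment censoring of DBP, time-varying
genetic effects, sequencing reads, or X-chromosome inheritance. A green
test on simulated data establishes internal consistency of the estimators
with this generative model, not robustness to those unmodeled features.

Other simulator conventions: the hypertension boundary is inclusive
(DBP ≥ threshold at wave 1); age enters linearly, +5 years per wave;
smoking is a per-individual Bernoulli(0.25), constant over waves; optional
genotyping error replaces a call by a fresh HWE draw; founder-origin labels
are propagated through gene dropping (Haldane recombination,
r = ½(1 − e^{−2d/100})) so the true IBD state of any pair at any marker is
recoverable.

## Validation scale-downs and known limitations

- The acceptance-grade simulations run at desk scale: type-I error uses 500
  phenotype replicates on a fixed 20-family backbone (~10 members each);
  recovery uses 200 replicates on a relative-richer 12-member template
  (σ²ᵤ is only weakly identified when families contain many married-in
  founders, because a compound-symmetric component of Σₑ can absorb it —
  with few relatives, ML point estimates of σ²ᵤ are noticeably biased
  down, which is why the recovery check uses REML).
  The permutation-calibration test decodes each replicate once and
  re-labels pairs across 50 shuffles.
- The unstructured Σₑ (10 free parameters) lies on a nearly flat likelihood
  ridge at small sample sizes; log-likelihoods and fixed effects are stable
  but individual Σₑ entries can wander at the few-percent level between
  equivalent optima.
- Single-chromosome scope per run; multi-chromosome analyses are multiple
  runs.
- α and β of the IBD process are user-set, never estimated from data.
- Segment boundaries and region boundaries are marker positions; no
  interpolation between markers.
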