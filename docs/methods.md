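# Methods

## The model behind every estimator

All statistics in this package read history from the genetic-distance scale
of correlations along the genome.

**Admixture LD.**  When two populations with allele-frequency differences
δ(x) = p_A(x) − p_B(x) mix in a pulse *n* generations before sampling, local
ancestry is correlated along each chromosome with correlation e^(−n d) at
separation *d* Morgans (recombination breaks ancestry blocks at rate *n* per
Morgan).  The dosage covariance between two SNPs in the admixed population
therefore contains a term proportional to δ(x)δ(y)e^(−n d).  The weighted
statistic

R(d) = (1/|pairs at d|) Σ cov(x,y) · w(x) · w(y)

with w ≈ δ turns that term into a positive exponential whose rate is the
date.  Any weight proportional to δ works; the product w(x)w(y) makes R(d)
invariant to global sign and scale of the weights, which is why unit-norm PCA
loadings (whose leading axis tracks δ when the panel spans both sources) are
interchangeable with frequency differences.

The curve is fit as A·e^(−n d) + c by count-weighted nonlinear least squares.
The affine term c absorbs distance-independent covariance (shared drift,
array batch structure); A is the admixture-LD amplitude and carries no date
information.  Fits start from rates {5, 20, 50, 150, 400} per Morgan and keep
the best optimum; the two-pulse model A₁e^(−n₁d)+A₂e^(−n₂d)+c starts from all
ordered pairs of {2, 5, 10, 20, 40, 80, 160, 320}.

**Two-pulse composition.**  A single pulse (t, α) is a rate-t breakpoint
process with iid Bernoulli(α) segment labels.  A later pulse (t₂, β) cuts
the haplotype at rate t₂; each piece is fresh pool-A material with
probability β and otherwise holds an *independent* stretch of the older
process with its rates reduced by t₂ — a breakpoint laid down since the
recent pulse joins two unrelated older-era haplotypes, so the older ancestry
pattern must not persist across it.  (An earlier overlay formulation that
let it persist produced a spurious e^(−(t₁+t₂)d) cross term and biased the
fitted older date upward by ~10%.)  The resulting ancestry covariance is the
clean genealogical sum

β(1−β)(1−α₁)²·e^(−t₂d) + (1−β)α₁(1−α₁)·e^(−t₁d),

verified against direct enumeration of truth tracks.  Validation scenarios
split a total of 0.8 as β = 0.6 recent over α₁ = 0.5 older, leaving both
amplitudes resolvable.  A fitted ratio n₁/n₂ < 1.5 is declared degenerate
and falls back to the single-pulse model.

**Correlation-form diagnostic.**  The legacy statistic divides the weighted
SNP-pair correlation by the root of the per-bin mean squared correlation
z²(d).  Without a bottleneck z² is flat in d (pure sampling noise ~1/n);
a founder event g generations ago adds drift LD whose squared correlation
decays as e^(−2gd), so the normalization itself decays at roughly twice the
event age and drags correlation-form dates downward.  The covariance form
has no such denominator and stays unbiased.  The exact algebra of the
original normalization is not public in a transcribable form; this module
reconstructs its documented behavior and labels itself a diagnostic.

**Founder events.**  Two individuals of a bottlenecked population share
chromosome stretches inherited from the founder generation; with *t*
generations of recombination on both lineages of a pair, the autocorrelation
of allele sharing decays as e^(−2tD).  Sharing s between two genotypes is the
identity-in-state fraction 1 − |g₁−g₂|/2 ∈ {0, ½, 1}; the curve takes, per
SNP pair at distance D, the Pearson correlation of s across individual pairs,
and subtracts the same quantity computed on (target, reference) cross-pairs
to cancel allele sharing inherited from the common ancestral population.
The fit A·e^(−2tD)+c reports t (a `rate_factor=1` flag dates one-lineage
processes instead).

*Fit window.*  The default window is 0.5–4 cM.  The lower cutoff mirrors the
dating statistic's convention.  The upper cutoff matters more: coalescences
through the post-event pedigree (probability ≈ 1/2N per pair per generation
after the event) contribute slower-decaying components that dominate the
curve beyond a few cM and bias the rate downward if included.  Within ~2
e-foldings of the event-age signal the founder component dominates.  For
young events (t ≲ 15) the window should be widened (e.g. to 8 cM) so that
amplitude and affine term separate; the examples do this explicitly.

**f-statistics.**  f4(A,B;C,D) is the plain mean over usable SNPs of
(a−b)(c−d) on population allele frequencies; no small-sample h correction is
applied (frequencies, not genotype sums, enter the statistic — the behavior
of the field's tool lineage varies here, and the jackknife SE already
reflects sampling noise).  The 4-population test uses the correlation form
ρ(A−B, C−D) with |Z| > 3 reported as a tree violation, and the companion
f4-based Z is returned alongside.  F4 Ratio Estimation forms the ratio of
f4 sums over the same SNP set and jackknifes the ratio.  F_st is Hudson's
ratio of averages with the (n−1) sample-size correction per population.

**Block jackknife.**  Blocks are cut per chromosome on the genetic map
(default 5 cM, last partial block kept) or per whole chromosome (for dates).
With block weights m_j (SNP counts), h_j = n/m_j, the variance is the
weighted pseudovalue form (1/g)Σ(τ_j − θ_J)²/(h_j − 1),
τ_j = h_jθ̂ − (h_j−1)θ̂_(j).  Delete-one recomputation is cheap for the decay
curves because per-chromosome bin sums are stored with the curve.

## The synthetic-data generator

The generator emulates the study conditions the estimators are designed for:

- Two ancestral pools under the Balding–Nichols model: pool frequency
  ~ Beta(p₀(1−F)/F, (1−p₀)(1−F)/F) around a shared ancestral p₀ ~ U(0.05,
  0.95), default F = 0.1 (continental-scale differentiation, similar to
  European/East-Asian panels).
- A sorted-uniform map over 20 chromosomes of 1 Morgan by default, with
  physical positions at ~1 cM/Mb; SNP counts 20K–500K depending on the
  scenario.
- Pulse admixture as above; default 27 admixed samples and 50 reference
  samples per pool (array-cohort scale).
- Founder events: the founder set is drawn, then `time` generations of
  random mating are simulated forward with crossovers as an exact Poisson
  parity process (per-gap odd-crossover probability (1−e^(−2Δ))/2) at 1 per
  Morgan per meiosis.  Pulse times in a scenario always count generations
  before the present; with a founder event at T the pre-founding panel is
  simulated at ages (t − T) and then aged T generations.  The post-founding
  size defaults to 20× the founder count — a severe event followed by
  expansion.  Holding the population small instead floods the sharing curve
  with recent-pedigree coalescences and flattens its decay; the expansion
  default keeps the event the dominant source of sharing, matching the
  demographic regime the dating model assumes.
- A matched non-bottlenecked panel (`ADMIXREF`) is always generated as the
  subtraction reference for founder dating; for a no-event scenario the
  difference curve is flat by construction and the fit returns a no-event
  verdict.

**What the generator does not emulate.**  Alleles are drawn independently
per SNP given local ancestry: there is no background LD within the ancestral
pools, no mutation, no selection, and the recombination map is uniform.
Passing recovery tests therefore demonstrates correctness of the estimators
under the admixture/founder model itself, not robustness to background LD —
on real data the < 0.5 cM region is excluded for exactly that reason, and the
default fit windows keep that convention.  Coalescent machinery (msprime)
could supply fully realistic haplotypes; it is deliberately not a dependency
of the generator, which needs ancestry-level truth tracks above all.

## Numerical and design choices

- Genetic positions are Morgans internally; cM accepted at I/O boundaries.
- Dosages are alt-allele counts in {0,1,2} with −1 for missing; covariance
  and correlation are pairwise-complete under missingness (masked
  cross-products give exact per-pair counts, means and variances).
- Bin values are accumulated sums divided by pair counts; normalization
  affects amplitude only, never the fitted rate.
- Default binning 0.1 cM to 30 cM, fit from 0.5 cM; the 300-generation
  scenarios use 0.02 cM bins from 0.05 cM (no background LD in synthetic
  data) to resolve the fast decay.
- Fits that converge to rates faster than two bins can resolve are flagged
  as no-signal (they are one-bin spikes chasing noise), as are negative
  amplitudes.
- Missingness filtering removes samples first, then SNPs (the order is a
  fixed convention); LD thinning repeats its greedy windowed pass to a fixed
  point so the operation is idempotent, keeping the lower-index SNP of any
  pair with r² > 0.1 in 50-SNP windows stepped by 5.
- ROH scanning enumerates maximal stretches satisfying all four thresholds
  via cumulative het/missing counts and resolves overlaps longest-first into
  a non-overlapping set.
- IBD seeds tile each chromosome at fixed 75-SNP word boundaries; a shared
  word nominates a haplotype pair, whose maximal mismatch-free runs
  containing at least one aligned word are reported.  Runs between 75 and
  149 SNPs can be missed when they straddle a word boundary — the same
  word-alignment property as the original hashing matcher.
- The ancestry-correction covariate for IBD sharing is the pair-mean
  ancestry proportion (alternatives: product, min); residuals are averaged
  per population pair, so corrected values are centered near zero and only
  their ranking is meaningful.
- The f4-ratio validation graph places REF inside the W clade (sharing the
  W-side stem drift), the admixed leaf X between hidden sisters of W and S —
  the configuration in which the ratio's expectation equals the mixing
  proportion exactly.

## Problem sizes used in validation

The recovery scenarios run at desk scale, chosen so each estimator sees the
information content it needs: 200K SNPs/20 chromosomes/27 samples for dating
at 30–100 generations (and the two-pulse case), 500K SNPs for 10–300
generations with 0.02 cM bins, 50K SNPs for the f4-ratio graph, 40K SNPs/
25+25 samples for founder dating with a bottleneck of 25 founders expanding
to 1000.  These sizes are stated in `scripts/acceptance.py` and the
acceptance tests; scaling them up tightens recovery but does not change any
estimator.

## Known limitations

- Dates beyond ~300 generations need sub-0.05 cM information and clean maps;
  with array data and background LD the practical limit is lower.
- The founder-event fit assumes a single dominant event followed by
  expansion; prolonged small population size produces a mixture of decay
  rates and a downward-biased (older-looking ages underestimated) date.
- The two-pulse fit needs both components visible in amplitude; histories in
  which the recent pulse contributed little ancestry are effectively
  single-pulse to the fit (reported via the degeneracy flag).
- The IBD matcher requires phased, error-free haplotypes (synthetic data is
  born phased); it is a stand-in with the original tool's stated parameters,
  not a reimplementation of its genotype-extension mode.
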