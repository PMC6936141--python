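# Methods

## Problem setting

Whole-exome sequencing covers only ~1–2 % of the genome, and most published
ancestry-informative marker (AIM) panels sit in intronic or intergenic
regions that exome capture misses.  `exaim` therefore designs AIM panels
*inside* exonic target regions, so that a cohort's ancestry composition can
be estimated from the WES variant calls it already has.  The package
assumes three continental reference ancestries by default (African, East
Asian, European) but every stage is generic in the number of populations K.

## Informativeness statistic

Marker ranking uses Rosenberg's informativeness for assignment,

    I_n = -(p ln p + (1-p) ln(1-p)) + (1/K) Σ_i [p_i ln p_i + (1-p_i) ln(1-p_i)],

with `0·ln 0 ≡ 0`.  Two numerical conventions:

- The overall frequency `p` defaults to the **unweighted mean** of the K
  population frequencies, which makes `I_n` invariant to reference-panel
  size imbalance; a `pooled` option weights by called alleles instead (the
  literal "across all individuals" reading).  Real reference panels are
  unbalanced (e.g. 504/405/396 individuals), so the default avoids letting
  panel composition leak into marker ranking.
- Computed values are clamped to `[0, ln K]` and snapped to exactly 0 below
  1e-12, absorbing floating-point residue in the analytically-zero
  equal-frequency case.

## Variant filtering and LD

Pipeline defaults mirror standard AIM-design practice: restrict to exonic
regions (BED input; internal coordinates are 0-based half-open, VCF
positions 1-based), biallelic SNPs only, drop variants with more than 10 %
missing genotypes (strictly greater), drop MAF < 0.01, then greedy
left-to-right LD pruning at r² < 0.2 within 100 kb windows.  Missingness
uses strict comparison so "more than 10 %" keeps a variant at exactly 10 %.

**LD is measured within populations.**  Pooled-sample genotype correlation
at two ancestry-informative loci is dominated by allele-frequency structure
(admixture LD), not physical linkage: with three differentiated populations
the most informative markers are all strongly "correlated" in the pooled
sample even on different chromosomes, and a pooled r² screen would veto
exactly the markers a panel needs.  All LD statistics in the design path
therefore compute r² per population and compare the maximum to the
threshold; `genotype_r2` itself remains a plain pooled correlation for
generic use.  Constant-in-population dosage vectors make r² undefined; such
pairs are treated as unlinked.

## Panel selection

Candidates surviving the filters are ranked by overall `I_n` (ties broken
by chromosome/position) and truncated to a 5000-candidate pool.  Each
candidate is assigned a **dominant population** — the population whose
frequency deviates most, in absolute value, from the mean of the others;
ties fall to the first population in configured order.

Selection is a deterministic round-robin: populations take turns in
configured order, each turn picking its highest-ranked remaining candidate
that keeps (a) ≥ 100 kb distance from every selected marker on the same
chromosome and (b) within-population r² ≤ 0.1 against every selected
marker.  An exhausted population's turn falls to the best remaining
candidate of any population.  Panels of different sizes are designed
independently, so a larger panel need not contain a smaller one.  The
round-robin produces near-equal dominant-population counts (difference ≤ 1)
whenever the pool allows; a published panel with a mildly uneven split
(e.g. 90/80/80) reflects additional unpublished balancing choices that this
implementation does not attempt to reverse-engineer.

`choose_optimal_size` picks the smallest evaluated panel size after which
no population's classification accuracy improves by the tolerance at any
larger size.  (A "minimum gain" rule would let one stagnant population mask
real improvement in another; the implementation uses the maximum
per-population gain.)

## Supervised admixture model

Genotype dosage `g_j ∈ {0,1,2}` at unlinked marker `j` is modeled as
Binomial(2, π_j) with `π_j = Σ_k q_k p_kj`, reference frequencies `p_kj`
fixed (clamped to `[1e-6, 1-1e-6]`).  The log-likelihood is concave in `q`,
so a single EM run from the uniform start suffices; the EM attributes each
of the `2M` observed alleles to source populations by responsibility
`q_k p_kj / π_j` (alternate) and `q_k (1-p_kj) / (1-π_j)` (reference) and
renormalizes.  Stopping: log-likelihood improvement < 1e-8 or 2000
iterations.  The trace is retained and non-decrease is asserted in the test
suite.  Missing genotypes are dropped per marker, never imputed.
Classification is arg-max over `q`, ties to the first population with a
flag; per-population error is the mean shortfall `1 - q_k` over samples
assigned to population `k`.

This estimator is the maximum-likelihood core of what STRUCTURE (Bayesian)
and ADMIXTURE (ML) fit in supervised mode; numerical equality with either
external tool is not claimed — the two tools themselves disagree slightly.

## Panel evaluation

Genotypes are encoded 0/1/2 with missing → NA, imputed (column mean by
default; an iterative low-rank SVD completion is available and is exact on
noiseless low-rank input), centered and unit-variance scaled (zero-variance
markers dropped with a warning), and projected onto the top `d = 3`
principal components by SVD.  Loading signs are fixed by making each
loading's largest-magnitude entry positive; fitted transforms are stored so
new cohorts are projected, never refitted.

Each population's scores are fitted as a multivariate normal (sample mean,
unbiased covariance; ridge `1e-9·I` added when numerically singular).  The
misclassification probability `P_m(i,j)` — the mass of `f_i` in the region
where `f_j` has higher density, compared in log space — is estimated by
Monte Carlo from `f_i` with a binomial standard error (default `n_mc = 1e6`,
seeded via `SeedSequence` spawning per ordered pair).  `P_AIM` is the sum
over ordered pairs.  With the strict inequality, identical distributions
give `P_m = 0` (degenerate but documented).  Monte Carlo cannot resolve the
extremely small `P_AIM` values well-separated panels can reach (~1e-37 in
published comparisons); the supported use is the *ordering* of panels, which
the test suite asserts.  Confidence ellipses use the chi-square(2) quantile
of the marginal 2-D Gaussian.

## Synthetic cohorts

The generator emulates the reference/admixed design of continental-scale
studies:

- **Allele frequencies:** Balding–Nichols — ancestral frequency uniform on
  [0.05, 0.95], population frequency Beta-drifted with parameter `F`
  (mean-preserving, variance `F·p(1-p)`).  `F = 0.15` approximates
  continental differentiation.
- **Individuals:** `n_ref = 100` per reference population (one-hot ancestry)
  and `n_admixed = 100` with Dirichlet(1,1,1) ancestry vectors by default.
- **Genotypes:** unlinked Binomial(2, Σ_k q_k p_kj) draws; optional i.i.d.
  missingness; optional LD "block-copy" mode that appends noisy duplicates
  of each marker for exercising the pruning stages.
- **Output:** unphased VCF plus truth tables (q, p_kj); everything is
  bit-reproducible from one seed.

`SimulationConfig.exome_scale` fixes the validation conditions for panel
design: a **100 000-marker pool**, the order of magnitude an exome-wide SNP
set retains after LD/MAF filtering.  Pool size matters scientifically: a
250-AIM panel drawn from ~1e5 markers sits in the extreme tail of the
differentiation distribution, and a much smaller pool would understate the
informativeness real design achieves.  The end-to-end recovery test runs at
these conditions with seed 0; measured mean absolute error per ancestry
component is ≈ 0.03 (the statistical floor of 250 markers at F = 0.15 —
re-estimating with the true generating frequencies does not reduce it), and
reference individuals classify into their own population at 100 %.

What the simulation does **not** emulate: real LD structure (markers are
unlinked unless block-copies are requested), mutation/genotyping error,
related individuals, more than binomial sampling noise in reference
frequencies, and real exome ascertainment.  Passing tests therefore
demonstrate correctness of the statistics and estimators under the model's
own assumptions, not performance on any particular real cohort.

## Numerical and interface choices

- Dosage matrices are float64 with NaN missing; any genotype containing a
  `.` allele (including half-calls) is missing.
- VCF reading goes through cyvcf2/htslib; multi-allelic records are
  retained but flagged, and removed by the biallelic filter.
- WES genotype extraction reconciles REF/ALT orientation against the panel
  (swapped records contribute `2 - dosage`); loci absent, below the depth
  minimum (FORMAT/DP), or allele-incompatible are missing, and a sample
  whose depth is unreported is treated as not demonstrably covered.
- LD pruning requires position-sorted input and errors rather than sorting
  silently; selection and pruning are deterministic for fixed input.
- Monte Carlo and simulation randomness always flow from explicit seeds.

## Known limitations

- The balanced-selection heuristic is greedy; no joint/integer-programming
  optimization of panel composition is attempted.
- Supervised estimation only: reference frequencies are not re-estimated
  from the admixed cohort, K is never inferred, and there is no linkage
  model, so dense panels with real LD would need prior pruning.
- `P_m` is Monte Carlo only; probabilities far below `1/n_mc` are reported
  as 0 with a standard-error caveat rather than resolved analytically.
- Insertions/deletions and multi-allelic informativeness are out of scope.
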