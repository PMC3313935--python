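# Methods

## Substitution mapping

The mapped quantity is the posterior expectation of the number of type-*s*
substitutions on branch *b* at site *i*,

    n̂_{b,i}(s) = Σ_{x,y} P(x, y | D_i, θ) · E[N_s | x, y, t_b],

with two ingredients computed separately.

**Joint flanking-state posteriors.** A post-order (pruning) pass computes,
for every node, the conditional likelihood of the subtree below it, with
per-site rescaling by the maximum partial to keep all arrays in [0, 1];
log-scaling accumulators carry the magnitudes. A pre-order (outside) pass
computes, for every branch, the root prior times everything outside the
branch's subtree. For branch *b* with transition matrix `P_b(t_b)`, outside
array `D` and inside array `U`, the joint posterior is the normalized
bilinear form `D[x] · P_b[x,y] · U[y]`; because numerator and denominator
are assembled in the same scaling, the ratio needs no scale bookkeeping.
Leaves contribute indicator vectors; IUPAC ambiguities and gaps set 1 for
every compatible state (standard missing-data treatment). Sites with zero
likelihood report `-inf` log-likelihood; mapping refuses them by name.

**Endpoint-conditioned counts by uniformization.** With uniformization rate
`μ = 1.05 · max_i |Q_ii|` (the 5% slack keeps a positive self-loop in every
row; results are invariant to μ, which is tested) and `R = I + Q/μ`, the
expected number of real type-*s* jumps given *n* uniformized jumps follows
the recursion `C_n = R C_{n-1} + L_s R^{n-1}` with `L_s = R ∘ mask_s`.
Poisson(μt) weights sum these terms; the series stops at the Poisson
inverse-CDF point for tail mass 1e-10 (hard cap 10⁴ terms). Endpoint
probabilities come from the same truncated series, so the conditional
expectations are internally consistent; cells whose endpoint probability
underflows below 1e-300 are flagged unreliable and zeroed. One kernel per
distinct (branch model, branch length) pair is cached and reused across all
sites — the dominant cost saver.

Zero-length branches carry zero counts by convention (the t → 0 limit).
Typed counts partition the total exactly because the register masks
partition the ordered unequal state pairs.

**Validation.** The counter is checked three ways: (i) against a
forward-Gillespie Monte-Carlo path oracle (rejection sampling on the final
state) within 3 standard errors, with the exact zero-observation bound 3/n
for cells whose conditional count distribution is degenerate in the sample;
(ii) against the analytic identity `Σ_{x,y} π_x P_xy(t) E[N|x,y,t] = t`
for normalized models; (iii) end to end, mapped totals against the true
counts logged by the simulator, pooled over replicates within 3 standard
errors of the replicate spread. Likelihoods and joint posteriors are
checked against brute-force enumeration over all node-state assignments on
trees with up to 5 leaves at 1e-10.

## Trees and branch indexing

Trees are stored as the rooted display of an unrooted phylogeny. A
bifurcating root is collapsed on input — its two subtending edges become
one mapped branch of summed length — so an unrooted binary tree with *n*
leaves exposes `m = 2n − 3` mapped branches and, for reversible homogeneous
models, every quantity is invariant to the input rooting (pulley
principle; tested for likelihoods and for whole counts tables). Branches
are numbered 1..m in preorder, so tables are comparable across runs; sites
are 1-based in every report.

## Models

All generators are reversible and normalized so `−Σ_i π_i Q_ii = 1`
(branch lengths are expected substitutions per site at stationarity; for
branch-specific models each branch's generator is normalized with its own
stationary distribution, keeping branch lengths in substitutions/site per
branch). Stationarity (`πQ = 0`), normalization and detailed balance are
asserted to 1e-10 at construction time by the test suite.

* **Equal rates** (`jc`): all ordered pairs at one rate, uniform π. Over
  the 61 sense codons the default places equal rates on *all* pairs,
  including multi-nucleotide changes; a `codon_single_step` switch
  restricts rates to single-nucleotide neighbours for exploring that
  alternative. The all-pairs choice matches a model in which "all
  substitution rates are fixed and equal" and reproduces the expected
  over-estimation of dN at low ω.
* **T92** (`t92`): π determined by the equilibrium GC content θ
  (π_G = π_C = θ/2), transitions scaled by κ.
* **YN98** (`yn98`): single-nucleotide codon exchanges proportional to the
  target codon frequency, × κ for transitions, × ω for amino-acid changes.
  Mapping-side codon frequencies default to F3X4 computed from the
  alignment (with a 0.5 pseudo-count per positional nucleotide so every
  codon stays reachable), overridable to uniform or user-supplied.

Transition probabilities use the spectral decomposition of the symmetrized
generator `D^{1/2} Q D^{-1/2}` (exact for reversible models), with
`scipy.linalg.expm` as the fallback whenever the symmetry check fails or π
has zeros. Rows are verified to sum to 1 within 1e-8 and clipped to [0, 1].

## Fitting

`fit_homogeneous` implements the deliberately rough protocol that the
mapping's robustness permits: round-robin bounded Brent searches over the
free substitution parameters (log scale for κ and ω), then a
branch-length round, stopping when a full round gains fewer than
`tol_lnl = 1.0` log-likelihood units (a strict 0.001 mode exists for
tests). The branch-length round freezes one inside/outside pass and
optimizes every branch against its exact one-dimensional profile
(simultaneous, Jacobi-style updates); if the collective update ever lowers
the total log-likelihood it is rolled back and replayed sequentially,
which is exactly monotone — so the reported trace never decreases. Branch
lengths are constrained to [1e-6, 100] to avoid degenerate exponentials;
a 100-round cap returns the best visited point with a warning flag.

## Estimators

**dN/dS.** The raw mapped counts N_b and S_b are not comparable across
models because synonymous and non-synonymous changes have different
opportunity. Each count is therefore divided by the neutral flux of its
class — `E_s^(1) = Σ_{(x,y)∈s} π_x q_xy` of the mapping model with ω set
to 1 — which makes ω̂ equal to the simulating ω in expectation when mapping
and simulating models coincide (an exact identity verified in the tests,
plus a neutral-simulation bias check that recovers ω̂ ≈ 1). The raw N/S
ratio remains available (`norm="raw_ratio"`). Degenerate branches are
flagged values, not exceptions: S = 0 with N > 0 gives +∞ (`zero_ds`),
N = 0 gives 0 (`zero_dn`), 0/0 is undefined with both flags.

**Equilibrium GC.** `θ* = AT→GC / (AT→GC + GC→AT)` is a *disequilibrium*
statistic: at stationarity detailed balance equalizes the two fluxes and
θ* = 1/2 for every θ, so the approximation carries information only while
a lineage is moving toward a new equilibrium — precisely the
branch-heterogeneous setting it is used in. (The tests assert both facts:
stationary flux balance at 1/2, and θ* rising toward the branch θ out of
equilibrium.) Branches with fewer than 10 total mapped substitutions
(expected counts compared as reals) are flagged as too sparse; flagged
values are reported, never dropped, and downstream summaries exclude them
explicitly.

**Summaries.** Relative error is `|estimate − truth| / truth` (a signed
variant exists behind a flag); dispersion uses the median absolute
deviation, `MAD = median(|x − median(x)|)`, because interval-based measures
are dominated by the outliers these estimators legitimately produce.
Binned summaries use equal-count quantile classes on the binning key
(class boundaries are not otherwise identifiable); class sizes differ by
at most one.

## Simulator

Sites evolve independently (no rate-across-sites variation). Root states
are drawn from the stationary distribution of a designated root model —
by default the shared parameters, overridable via root-specific
parameters — and full substitution paths are simulated per branch by the
(vectorized) Gillespie algorithm; every jump is typed and tallied, so the
truth record and the alignment come from the same paths. One master seed
spawns independent per-branch substreams (plus one for the root draw), so
truth and alignment are jointly reproducible and a non-homogeneous
configuration with all overrides equal reproduces the homogeneous stream
bitwise (tested). Simulator codon frequencies default to uniform over the
61 sense codons.

Study-condition defaults follow the simulation protocol the experiments
emulate: branch-specific ω from a gamma distribution of mean 0.2 and shape
0.5 (variance mean²/shape = 0.08); branch-specific θ from Uniform(0, 1),
clipped by 1e-6 for model validity; branch-length distortion multiplies
each branch independently by Uniform(1 − f, 1 + f) with f = 0.25
(multiplicative form chosen so distorted lengths stay positive at any f < 1).

## Experiment drivers and problem sizes

`run_experiment_codon` simulates branch-heterogeneous YN98 data and maps it
under four conditions: (i) the true non-homogeneous model, (ii) a refitted
homogeneous YN98 model, (iii) a refitted equal-rates codon model, (iv) the
homogeneous fit with ±25%-distorted branch lengths and no refit. Default
scale: 10 replicates × 500 codon sites on one 20-leaf tree with
Uniform(0.02, 0.3) branch lengths; branch ω are redrawn each replicate
(broadening the truth spread that pooled rank correlations are computed
over). Evaluation compares ω̂ against the dN/dS actually realized along
the simulated paths (true typed counts normalized by the simulating
model's neutral fluxes), restricted to branches with at least 10 expected
substitutions.

`run_experiment_nt` is the nucleotide analogue with T92 and the
AT→GC/GC→AT register; default 2 replicates × 5000 sites on a 33-leaf
tree. The 33-taxon default matters: per-branch θ* recovery depends on
ancestral-state reconstruction, which needs reasonably dense taxon
sampling on a 4-letter alphabet — at 20 taxa the rank correlation between
θ* and the true per-branch values averages ≈ 0.66, at 33 taxa (the
taxon sampling of the study this emulates) ≈ 0.78.

These synthetic conditions deliberately omit several features of real
data: no rate variation across sites, no indels or alignment error, site-
independent evolution, and a single stationary root composition. Passing
tests therefore demonstrate correctness of the counting machinery and
robustness of the estimators *under the stated generative model*, not
immunity to real-data model violations.

## Known limitations

* No hypothesis-testing framework: mapped counts are descriptive posterior
  expectations; the package intentionally provides no likelihood-ratio
  machinery, and no higher moments of the count distribution (means only).
* ω̂ and θ* inherit the mapping model's biases on long branches (multiple
  hidden substitutions are typed by the model — quantified by the
  equal-rates condition in the codon experiment).
* θ* is uninformative at equilibrium (see above) and shrinks toward the
  homogeneous model's equilibrium on branches with weak signal.
* Model families are limited to the three used by the experiments (no GTR,
  no Gamma rate heterogeneity, no covarion models); fitting of
  non-homogeneous models is out of scope by design.
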