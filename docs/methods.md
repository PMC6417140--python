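# Methods

## The model

`dosealign` assigns single cells measured by scRNA-seq to clones defined by
copy-number profiles from independent shallow scDNA-seq. The only link
between the two modalities is gene dosage: a gene's transcript output is
assumed to scale with its genomic copy number, up to saturation.

For cell *n* (of *N*) and gene *g* (of *G*), with clone assignment
*z_n ∈ {1..C}* and clone copy numbers λ_gc, the expected count is

    E[y_ng | z_n = c] = s_n · μ_g f(λ_gc) exp(x_n·β_g + ψ_n·w_g)
                        / Σ_g' μ_g' f(λ_g'c) exp(x_n·β_g' + ψ_n·w_g')

with

* `s_n` — the cell's read depth (by default fixed to its total count over
  the modelled genes; optionally inferred as a free parameter);
* `μ_g` — per-copy expression relative to gene 1 (`μ_1 ≡ 1` anchors the
  scale, since the normalized mean is invariant to rescaling all μ;
  prior `log μ_g ~ N(0,1)`);
* `f(λ) = min(λ, ζ)` — the capped dosage function, ζ = 6 by default. A
  copy number of 3 on a diploid background is expected to give ~3/2× the
  transcripts; very high amplifications saturate at ζ-fold. `f(0)` is set
  to 1e-6 rather than 0 so a homozygously deleted gene keeps a positive
  (near-zero) mean and the likelihood stays finite;
* `x_n·β_g` — optional known covariates (batch, cell-cycle scores) with
  unpenalized coefficients B;
* `ψ_n·w_g` — rank-Q structured noise (Q = 6, or 1 when G < 100) absorbing
  expression variation not explained by copy number, with priors
  ψ_nk ~ N(0,1), w_gk ~ N(0, χ_k⁻¹), χ_k ~ Gamma(2,1).

The denominator implements total-RNA normalization: expression is relative,
so amplifying a highly expressed gene *depresses* the expected counts of all
other genes in that clone. Rows of the expected-count matrix sum to `s_n`
exactly by construction.

Counts are negative binomial with mean *m* and inverse-dispersion
`r = φ(m)`, in the convention `Var[y] = m (1 + m/r)` (so r → ∞ recovers
Poisson). The dispersion is a non-parametric function of the mean built from
M = 20 radial basis kernels, `φ(m) = Σ_i a_i exp(-b (m - c_i)²)`, with
centers `c_i` evenly spaced over the observed raw-count range, bandwidth
`b = 1/(2δ²)` for center spacing δ, and amplitudes `a_i ≥ 0` learned from
the data (softplus-parameterized). φ is floored at 1e-3 to keep the NB mass
defined when a mean falls far outside every kernel; the floor region
contributes no dispersion gradient. φ is evaluated at the per-clone mean
m_ngc, i.e. inside the assignment expectation, since the model never forms
a clone-averaged mean.

Variants at germline heterozygous SNVs can augment the likelihood. In a
region where clone *c* carries one copy (LOH), the RNA allelic ratio
collapses toward 0 or 1; in a two-copy heterozygous region it centers on
1/2. With alt/ref counts a_nv, r_nv and variant-level clone copy number
λ_vc, the per-variant likelihood is BetaBinomial(a; a+r, α=2, β=2) when
λ_vc = 2 and the symmetric mixture ½BB(α=0.1, β=1.9) + ½BB(α=1.9, β=0.1)
when λ_vc = 1. These shape parameters are fixed calibration constants, not
fitted. Variant terms are conditionally independent given the clone, so they
add an N×C log-likelihood offset that is constant over iterations and is
precomputed once. Variants whose copy number is outside {1, 2} in any clone
are dropped (with a logged count): the observation model defines only those
two states, and extrapolating allelic ratios to higher ploidies would be
guesswork. Copy-neutral LOH is not modelled; when it is suspected the fit
should use expression alone (the CLI prints this warning and offers
`--no-allele`).

## Inference

Mean-field variational Bayes with
`q(z, μ) = Π_n q(z_n) Π_g q(μ_g)`: categorical `q(z_n = c) = φ_nc` and
log-normal `q(μ_g)` via the reparameterization `μ_g = exp(ν_g + ρ_g ε)`,
ε ~ N(0,1). All other parameters (ψ, W, B, a, optionally log s) are
optimized as points. The expectation over q(z) is analytic; the expectation
over q(μ) is a Monte-Carlo estimate with S = 1 draws per iteration. The
KL between q(log μ) and its N(0,1) prior is taken in closed form, so the
single noisy term is the reparameterized likelihood.

Gradients are derived analytically (no autodiff): because every per-gene
parameter enters through log u_ngc = log μ_g + log f(λ_gc) + x_n·β_g +
ψ_n·w_g and the mean is the normalized m_ngc = s_n u_ngc / Σ u, the chain
rule reduces to one φ-weighted residual matrix

    H_ng = Σ_c φ_nc [ (∂ℓ/∂m · m)_ngc − (m_ngc/s_n) Σ_g' (∂ℓ/∂m · m)_ng'c ]

contracted against each parameter's design (1 for ν, ε for ρ, X for B, W/ψ
for the factor pair). ∂ℓ/∂m includes the indirect dispersion path
∂ℓ/∂r · ∂φ/∂m. The implementation is verified against central finite
differences in the test suite, and the fused single-sweep kernel (numba)
against the plain vectorized path.

Per iteration: draw ε, take one Adam step (learning rate 0.05) on all
unconstrained parameters, then set φ to its exact coordinate optimum
φ_nc ∝ exp(E_q[log p(y_n | z_n=c)]) and χ_k to its conditional maximizer
(G/2 + 1)/(Σ_g w_gk²/2 + 1). The closed-form φ update keeps rows exactly on
the simplex and avoids N×C extra logit parameters; the closed-form χ update
is exact and free. Convergence is declared when the window-10 smoothed ELBO
changes by less than 1e-6 percent. With S = 1 the Monte-Carlo noise in the
trace often exceeds that threshold, so in practice the iteration cap
(default 500) ends most fits; assignment probabilities plateau well before
it (typically by iteration ~150–300 at the benchmark sizes below), and
non-convergence is reported as a flag on the results, never an exception.

Numerical choices: means are floored at 1e-12; the covariate/noise exponent
is clipped at ±50; ρ and a use softplus transforms; argmax ties in MAP
assignment break to the lowest clone index; gene 1 is the anchor
(ν_1 = ρ_1 = 0 throughout). Initialization is deterministic given the seed:
φ uniform, ν_g at the log mean-expression ratio to gene 1, ρ = 0.1,
ψ/W/B ~ 0.01·N(0,1), a_i = 1, s_n = total counts. All randomness flows
through one `numpy` Generator; fits are bit-reproducible given a seed.

## The simulator

The generator draws from the model itself, so simulator output is a
parameter-recovery bed, not a realism claim about any particular dataset.
Defaults define the benchmark conditions:

* per-copy expression `log μ_g ~ N(0,1)`, `μ_1 = 1`;
* library sizes `s_n ~ LogNormal(log(depth_scale · 0.86 · G), 0.3)` —
  0.86 reads per gene per cell is the reference droplet-assay depth the
  quality scenario scales down from;
* copy-number profiles in contiguous 20-gene segments. Shared segments sit
  at copy 2 in every clone. In clone-distinct segments *every* clone draws
  its own value from {1,2,3,4} (pairwise distinct from the first clone's
  draw): real tumor clone pairs both deviate from diploid, and giving one
  clone an all-neutral profile would systematically attract the cells whose
  genes carry no dosage effect;
* a fraction π of genes ("dosage proportion") actually follows its copy
  number; the remainder is generated at copy 2 for every clone, while the
  emitted profile still reports the true copy numbers — the fit is not told
  which genes respond;
* NB dispersion from the same RBF form with generating amplitudes
  a_i ~ U(2, 6), i.e. inverse-dispersion ≈ 5–15 over the mean range: the
  weakly overdispersed regime of droplet UMI counts;
* structured noise off by default (`noise_sd = 0`): the benchmark
  generating-parameter set is {μ, s, Λ, dispersion}. Rank-Q noise can be
  switched on (`noise_factors`, `noise_sd`) to study misspecification; note
  that strong clone-correlated structured noise creates a genuine
  identifiability tension with the Q = 6 residual factors (the ELBO can
  prefer explaining a minority clone through a factor rather than through
  its assignment), which is worth knowing before interpreting fits on data
  with dominant non-CN structure.

Five scenario grids (`run_scenario`) vary the dosage proportion, the number
of clone-distinct genes, the clone count (scored by MAP accuracy; all other
scenarios by one-vs-rest AUC against simulation truth), the minor-clone
frequency and the sequencing depth.

What the simulator does not emulate: empirical per-gene expression
distributions from any real tumor, segment-length heterogeneity, doublets,
ambient RNA and batch structure. Passing benchmarks here demonstrates
correct inference under the model's own assumptions and the stated noise
regime, not performance on arbitrary real data.

## Validation procedures

**Held-out chromosomes.** The model is refitted without the genes on chosen
chromosomes; each cell's MAP clone then predicts the held-out expression
through the dosage mean. Per-copy expression of unseen genes cannot come
from the fit, so it is estimated by pooled-mean normalization: each gene's
depth-normalized count divided by its dosage factor under the cell's
assigned clone, averaged over cells. Predictions and observations are
compared by RMSE on per-gene z-scored log1p size-factor-normalized
expression, against a null of permuted assignment vectors; the one-sided
p-value uses the add-one rule, p = (1 + #{null ≤ observed})/(1 + P), hence
never 0 and never below 1/(P+1). Because predictions are relative within the
held-out gene set, a held-out region whose copy-number contrast is uniform
across all its genes carries no signal; the test requires (and errors
without) clone-distinct held-out genes, and discriminates best when the
held-out chromosomes span several segments.

**Gene-selection robustness.** The fit is repeated after dropping either the
least-variable fraction of genes (variance in log-expression space;
deterministic) or a random fraction (default 10 replicates), and the
reduced fit's MAP assignments are scored by per-clone precision and recall
treating the full-gene fit as truth. A reduced gene set that loses every
clone-distinct gene makes the model unidentifiable; that condition is
flagged in the output table and scored as missing rather than failing the
run.

## Problem sizes used in the shipped checks

The test suite exercises the benchmark properties at 200–1000 cells and
100–200 genes with 5–10 replicates per condition; the acceptance script runs
the two headline operating points (dosage proportion 0.3 at clone prevalence
0.88/0.12, and 10 clone-distinct genes) at 1000 cells × 200 genes × 5
replicates, reporting median one-vs-rest AUC. These sizes reproduce the
claimed regimes while keeping a full run in the tens of minutes on one CPU;
grids, replicate counts and sizes are arguments throughout.

## Known limitations

* The dosage cap ζ and the dosage function are fixed, not inferred.
* φ(m) shares one amplitude vector across genes; gene-specific dispersion
  is absorbed only through the mean dependence.
* Point-optimized ψ, W, B carry no posterior uncertainty.
* With single-sample Monte-Carlo gradients the formal ELBO convergence rule
  rarely fires; runtime is governed by the iteration cap.
* The allele model covers only copy-1 (LOH) and copy-2 (retained
  heterozygous) states and assumes no copy-neutral LOH.
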