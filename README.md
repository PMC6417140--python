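# dosealign

Assign single cells measured by scRNA-seq to tumor clones defined by
copy-number profiles from independent shallow single-cell DNA sequencing.

Tumors are mosaics of genomic clones, but the two single-cell assays that
characterize them measure *different* cells: scDNA-seq yields clone-level
copy-number profiles, scRNA-seq yields per-cell transcriptomes with no
genotype attached. `dosealign` maps each expression profile to its
clone-of-origin using only the gene-dosage assumption — that a gene's
transcript output scales with its copy number, saturating at high
amplification — so clone-specific transcriptional programs (and with them,
candidate mechanisms of clonal fitness) can be read out of ordinary droplet
scRNA-seq. It is written for analysts of multi-modal tumor single-cell data:
the inputs are a raw count matrix, a gene × clone integer copy-number table,
and optionally per-cell covariates and allele counts at germline
heterozygous SNVs in clone-specific LOH regions.

## Model

With cells *n = 1..N*, genes *g = 1..G*, clones *c = 1..C* and latent
assignment *z_n*, counts are negative binomial with mean

    E[y_ng | z_n = c] = s_n · μ_g f(λ_gc) e^{x_n·β_g + ψ_n·w_g}
                        / Σ_g' μ_g' f(λ_g'c) e^{x_n·β_g' + ψ_n·w_g'}

where s_n is the cell's depth, μ_g the per-copy expression (μ_1 ≡ 1),
f(λ) = min(λ, ζ) the capped dosage function (ζ = 6), x_n·β_g known
covariates and ψ_n·w_g low-rank structured noise. The denominator makes
expression relative: a high-copy, highly expressed gene depresses every
other gene in that clone. The NB inverse-dispersion is a radial-basis
function of the mean, learned jointly. Inference is mean-field variational
Bayes: categorical q(z_n), reparameterized log-normal q(μ_g), analytic
expectation over assignments, one-sample Monte-Carlo expectation over μ,
and Adam ascent with analytically derived gradients. Allele counts at
heterozygous SNVs add a fixed beta-binomial likelihood that distinguishes
LOH (copy 1) from retained-heterozygous (copy 2) regions. See
`docs/methods.md` for the full account.

## Worked example

Simulate a 300-cell, 120-gene, two-clone dataset in which only half the
genes actually respond to copy number, then fit:

```python
import numpy as np
import dosealign as da

config = da.SimulationConfig(n_cells=300, n_genes=120, n_clones=2,
                             dosage_proportion=0.5,
                             clone_frequencies=np.array([0.8, 0.2]), seed=7)
sim = da.simulate_dataset(config, seed=7)

model = da.CloneAssignModel(sim.expression, sim.clone_profile)
res = model.fit(seed=7)
print(res.summary())

auc = da.assignment_auc(res.state.phi, sim.true_clone_index)
acc = da.assignment_accuracy(res.state.phi, sim.true_clone_index)
print(f"AUC vs simulation truth: {auc:.3f}")
print(f"MAP accuracy vs truth:   {acc:.3f}")
```

Output:

```
Clone assignment (copy-number dosage model)
==============================================
cells: 300    genes: 120    clones: 2
residual factors Q: 6    dosage cap zeta: 6
iterations: 500    converged: False
final ELBO: -38515.27

MAP clone prevalence:
  A: 0.760
  B: 0.240
mean MAP probability: 1.000

AUC vs simulation truth: 0.982
MAP accuracy vs truth:   0.947
```

The fit recovers the 80/20 clone structure (76/24 by MAP call) and ranks
cells almost perfectly by clone (AUC 0.98) even though half the genes carry
no dosage signal. `converged: False` reports that the strict smoothed-ELBO
rule did not fire within the iteration cap — expected with single-sample
stochastic gradients — while the assignments themselves have long
plateaued; `res.assignment_probabilities` holds the full posterior table
and `res.plot_elbo()` the trace.

`CloneAssignResults` also exposes `map_clone`, `clone_prevalence()`,
`predict_expected_counts()` and writers via `dosealign.io`. Validation
utilities live in `dosealign.validate` (held-out-chromosome permutation
test, gene-removal robustness) and benchmark grids in
`dosealign.simulate.run_scenario`.

## Command line

```
dosealign fit --expression counts_dir/ --clone-profile clones.csv --out fit/
dosealign simulate --cells 1000 --genes 200 --clones 2 --seed 1 --out sim/
dosealign scenario dosage_proportion --replicates 10 --seed 1 --out grid.csv
dosealign validate-heldout --expression ... --clone-profile ... --hold-out chr5 --out heldout.json
dosealign robustness --expression ... --clone-profile ... --out robustness.csv
```

Expression is read from a Matrix Market triplet directory (genes × cells,
with `genes.tsv`/`barcodes.tsv`) or a dense CSV; clone profiles from a
`gene_id` + one-integer-column-per-clone table. Every run writes its
resolved configuration next to its outputs.

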