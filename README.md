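# clonaltree

Bayesian reconstruction of cancer clonal trees that integrates bulk DNA-seq
variant read counts with single-cell RNA-seq allelic read counts.

## The problem

Bulk sequencing observes, at each somatic SNV, the fraction of reads carrying
the variant allele — a convolution of the clonal tree, each clone's cellular
prevalence, and local copy number.  Deconvolving a tree from variant allele
frequencies alone is notoriously underdetermined: a branching tree and a
linear one can explain the same bulk data exactly.  Single-cell RNA-seq reads
covering those SNVs carry the missing signal — mutations that co-occur within
the same cells must lie on the same root-to-leaf path — but the data are
sparse and bursty: cells frequently express only one allele at a locus, so
absence of a variant read is weak evidence of absence.

`clonaltree` fits a joint Bayesian model for both data types.  It is aimed at
researchers doing tumor phylogenetics who have standard bulk variant/copy
number calls plus per-cell allelic pileups at the same loci (e.g. from
full-length scRNA-seq protocols).

## The model

- **Tree prior** — a tree-structured stick-breaking (TSSB) process over
  clonal trees of unbounded width and depth assigns each SNV *n* to a clone
  *z_n*; node *u* receives stick mass pi_u = nu_u \* upsilon_u with
  nu_u ~ Beta(1, lambda0 lam^|u|) and child splits psi ~ Beta(1, gamma).
- **Prevalences** — each clone has a cellular prevalence phi_v per region
  (children sum to at most their parent); clone fractions
  eta_u = phi_u − sum of children's phi carry a Dirichlet(1) prior.
- **Bulk likelihood** — variant reads b_n ~ Binomial(d_n, theta(g, phi, eps))
  with the genotype g marginalized uniformly over the set compatible with the
  clonal major/minor copy numbers (M_n, m_n).
- **Single-cell likelihood** — at a carried locus, variant reads follow a
  mixture of Beta-Binomials: a mono-allelic component with tiny symmetric
  shapes (alpha0 = beta0 = 0.01) and a per-locus bi-allelic component
  (alpha_n, beta_n), mixed with weight delta0 = 0.5; at an uncarried locus,
  BetaBinomial(d, eps, 1−eps).  Cell-to-clone assignments are uniform a
  priori and marginalized, so the cost per evaluation is O(C·|V|).

Inference is MCMC: slice sampling of SNV assignments on the stick partition,
conjugate Gibbs updates of the sticks, and Metropolis–Hastings on clone
fractions, yielding posterior samples, a MAP tree, clonal genotypes, and
posterior cell-to-clone assignments.  A generative simulator matched to the
likelihood (including optional birth–death copy-number evolution) and the
standard evaluation metrics (V-measure, ARI, AMI, ancestral reconstruction
error, expected per-cell genotype loss) are included.  See
`docs/methods.md` for the full model, numerical choices, and limitations.

## Worked example

Simulate a cherry-shaped tumor (a progenitor clone with two sibling
subclones), fit it, and score the result against the ground truth:

```bash
clonaltree simulate --out sim --seed 7 --topology cherry --n-snvs 60 --n-cells 40
# wrote dataset with 60 SNVs, 40 cells to sim

clonaltree run --bulk sim/bulk.tsv --sc sim/sc.tsv \
    --hyperparams sim/hyperparams.tsv --out fit \
    --iterations 600 --burn-in 300 --seed 3
# MAP log joint -633.265 with 4 nodes

clonaltree evaluate --truth-prefix sim/truth --map-prefix fit/map --out eval
# {"v_measure": 1.0, "adjusted_rand_index": 1.0,
#  "adjusted_mutual_information": 1.0, "ancestral_error": 0.0, ...}
```

The MAP tree has 4 nodes — the healthy root, the progenitor, and the two
subclones — and every SNV is placed in its true clone: the clustering scores
are all 1 and no SNV pair's ancestral relation is wrong (`ancestral_error`
0.0).  `fit/` also contains the newick tree with a per-node sidecar table
(prevalences, clone fractions, SNV lists), the per-iteration trace, each
cell's posterior over clones with its MAP clone, and the predicted per-cell
mutation-status matrix.  Bulk-only deconvolution of this dataset cannot
identify the branching: the two subclones' allele frequencies are equally
consistent with a linear expansion, which is the point of integrating the
single-cell reads.

Library use mirrors the CLI:

```python
import clonaltree as ct

cfg = ct.SimulationConfig(topology="cherry", n_snvs=60, n_cells=40, seed=7)
truth, bulk, sc = ct.simulate_dataset(cfg)
trace = ct.run_mcmc(bulk, sc, ct.SamplerConfig(n_iterations=600, burn_in=300, seed=3),
                    sc_hyper=truth.sc_hyper)
best = ct.map_estimate(trace)
v, ari, ami = ct.clustering_scores(truth.snv_labels, best.snv_labels)
```

## Input formats

- Bulk TSV: `snv_id chrom pos ref alt region var_reads total_reads major_cn
  minor_cn` (1-based positions; one row per SNV and region).
- Single-cell TSV (long/sparse): `cell_id snv_id var_reads total_reads`;
  absent pairs mean zero depth.
- Optional per-SNV hyperparameter TSV (`snv_id alpha beta delta0`), produced
  by `clonaltree preprocess`, which also filters SNVs on single-cell support
  (keep if ≥ 2 cells have ≥ 2 variant reads; `--tenx` relaxes to ≥ 1 read
  for shallow droplet data).

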