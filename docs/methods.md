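# Model and methods

`clonaltree` reconstructs a cancer clonal tree by jointly modeling bulk
DNA-seq variant read counts and single-cell RNA-seq allelic read counts.
This note records the model, the inference machinery, the simulator, the
numerical choices, and the design decisions made where the design was
genuinely open.

## The model

**Clonal tree.** A rooted tree whose nodes are clones; the root represents
healthy cells and has exactly one child, the cancer progenitor clone.  Nodes
are addressed by canonical child-index paths (root `()`, progenitor `(0,)`).
SNVs attach to cancer clones through the assignment vector **z** (never to
the healthy root); a cell at clone *u* carries every SNV assigned to *u* or
to any ancestor of *u* (infinite-sites assumption).

**Tree prior.** The tree and assignment get a tree-structured stick-breaking
(TSSB) prior: node *u* keeps the fraction `nu_u ~ Beta(1, lambda0 *
lam^depth(u))` of the stick mass `upsilon_u` that reaches it (`pi_u = nu_u *
upsilon_u`), and the remainder `(1 - nu_u) * upsilon_u` is split among its
children by sticks `psi_{u,k} ~ Beta(1, gamma)`:

    upsilon_{u,k} = (1 - nu_u) * upsilon_u * psi_{u,k} * prod_{j<k} (1 - psi_{u,j}).

Using `(1 - nu_u)` for the child residual conserves stick mass exactly
(`pi_u` + child masses + unbroken remainder = `upsilon_u`); a published
variant writes the residual with `(1 - pi_u)`, which does not conserve mass
when `upsilon_u < 1`, so we use the standard convention.  `lambda0` and
`lam` govern tree depth; `gamma` governs width only — an item's stopping
probability at depth *d* is `Beta(1, lambda0 * lam^d)` whichever child it
descends into, so the item-depth marginal is gamma-invariant (the test suite
asserts this).  Defaults `lambda0 = 1, lam = 0.5, gamma = 1` are
configuration, not estimates.

**Prevalences.** Each clone has a cellular prevalence `phi_v` per bulk
region (fraction of cells carrying its mutations), with `phi_root = 1` and
the children of every node summing to at most their parent.  Clone fractions
`eta_u = phi_u - sum_children phi` sum to one per region and get a symmetric
Dirichlet(1) prior over the nodes of the current tree.  Multi-region data
share one tree and assignment; `phi`/`eta` are region-specific.

**Bulk likelihood.** Variant reads at SNV *n* are binomial in the depth with
success probability `theta(g, phi, eps)` determined by the latent genotype
`g = (v copies variant, c copies total)`:

    theta = eps                          if v = 0
          = phi (1-eps) + (1-phi) eps    if v = c
          = phi v/c + (1-phi) eps        otherwise.

The genotype is marginalized uniformly over the set compatible with the
clonal major/minor copy numbers `(M, m)`: the mutation sits on one parental
allele, so `v` ranges over `1..M` union `1..m` with `c = M + m`.  Loci with
`M = 0` (homozygous deletion) must be excluded upstream.  Multi-region
counts are independent binomials per region with the genotype marginalized
per region.  The sequencing error rate defaults to `eps = 0.001`
(configurable).

**Single-cell likelihood.** Allelic expression is bursty: a cell expressing
only one allele is common.  At a locus the cell carries, the variant read
count follows a two-component Beta-Binomial mixture — a mono-allelic
component `BetaBinomial(d, alpha0, beta0)` with tiny symmetric shapes
(default 0.01, putting mass near 0 and 1) and a bi-allelic component
`BetaBinomial(d, alpha_n, beta_n)` with per-locus shapes — mixed with prior
weight `delta0 = 0.5` for bi-allelic expression and the indicator
marginalized out.  At a locus the cell does not carry, variant reads arise
only through error: `BetaBinomial(d, eps, 1-eps)`.  Uncovered entries
(depth 0) contribute likelihood one.  Cell-to-clone assignments get a
uniform prior over all `|V|` current nodes (healthy root included — normal
contamination is representable) and are marginalized, so one evaluation of
the single-cell term costs `O(C * |V|)`.

## Inference

One MCMC iteration: a slice-sampling sweep reassigning every SNV in input
order, pruning of unoccupied leaf clones, conjugate Gibbs resampling of all
sticks, and Metropolis-Hastings updates of the clone fractions.

**Slice moves.** A uniform variable on [0, 1) indexes nodes through the
stick partition (an interval of mass `pi_v` per node, in preorder); the
slice level is drawn under the current assignment's data log-likelihood and
the interval shrinks toward the current node's interval by preorder
comparisons.  Sticks, nodes, and prevalences are instantiated lazily from
the prior during the search; a new node's prevalence is drawn uniformly on
its feasible interval per region, so the sum constraints hold by
construction.  A hard cap of 1000 shrinkages guards against pathological
loops.

Two corrections beyond the textbook scheme were found necessary by
forward/successive-conditional (Geweke-style) calibration:

1. *Configuration prior in the slice weight.*  A candidate assignment that
   promotes a represented-but-unoccupied node into the minimal tree changes
   the dimension of the Dirichlet prior on clone fractions.  Each candidate
   configuration is therefore scored with its clone-fraction prior density —
   `Gamma(K)` for the Dirichlet over its minimal tree's `K` nodes per
   region, times uniform-lift densities `1/avail` for represented nodes
   outside it (with `avail` the feasible width at instantiation).  Without
   this term the sampler systematically under-weights moves onto new clones
   whenever the data are informative, biasing trees shallow and small.
2. *Pairwise clone-fraction moves.*  Pruning an emptied leaf merges its
   clone fraction into its parent, which (by Dirichlet aggregation)
   concentrates `eta` relative to the prior faster than a Dirichlet
   random-walk MH can relax it.  Each iteration therefore also applies
   pairwise conditional moves: pick two nodes, redraw one coordinate
   uniformly on `(0, eta_u + eta_w)` — exactly the Dirichlet(1) prior
   conditional — and accept on the bulk likelihood ratio alone.

With both corrections the sampler passes a bulk-only Geweke test (6 SNVs,
depth 50) within three standard errors on mean assignment depth, progenitor
prevalence, clone-fraction concentration (`sum eta^2`), and node count.
Within a single slice move the uniform cell-prior normalization `1/|V|` is
held fixed (the represented node set can grow lazily mid-move); the node
count used in the joint density is that of the pruned tree.

**Stick updates.** Conjugate: `nu_u ~ Beta(1 + n_u, lambda0 lam^depth +
n_descendants)`, `psi_{u,k} ~ Beta(1 + n_subtree(k), gamma + n_subtrees>k)`,
where the counts are SNVs per node.  Unoccupied parts of the tree draw from
the prior.

**Clone-fraction updates.** Per region, a Dirichlet random walk `eta' ~
Dirichlet(kappa eta + kappa0)` (defaults `kappa = 50`, `kappa0 = 0.01`, 10
steps per iteration) accepted with the MH ratio (bulk likelihood plus
proposal asymmetry; the symmetric Dirichlet(1) prior cancels), preceded by
the pairwise conditional moves described above (4 passes per node per
region).  Acceptance counts are tracked on the sampler.  Prevalences are
recomputed from fractions by subtree sums.

**Outputs.** The trace stores the per-iteration log joint and thinned
post-burn-in snapshots.  The MAP estimate is the retained sample with
maximal log joint (earliest iteration on ties).  Cells are mapped onto the
MAP tree by their posterior over nodes (uniform prior; likelihood as above);
the reported MAP node breaks ties by shallower depth, then path order.  The
default run length is 2000 iterations with 1000 burn-in; the benchmark
scripts use 400/200 (integrated) and 1000/500 (bulk-only), which the
convergence of the V-measure on the simulated designs supports.

## Simulator

The generator mirrors the likelihood exactly and defines the study
conditions used throughout the tests:

- Topologies: chain, cherry (progenitor with two subclones), multifurcating
  (progenitor with three subclones; the central design), complete binary of
  depth 2 below the progenitor, or a TSSB prior draw.
- Clone fractions per region are symmetric Dirichlet(1) over the cancer
  clones, so the progenitor's prevalence is 1 (purity-one tumor) and no cell
  sits at the healthy root; cells are multinomial in the first region's
  fractions; every clone receives at least one SNV when the SNV count
  allows.
- Bulk: depth `d ~ NegativeBinomial(mean 1000, dispersion 10)` per SNV and
  region; variant reads binomial with the origin clone's genotype.
- Single cell: each (cell, locus) pair is covered with probability `p_cov`
  (default 0.1; the sweep values are 0.1/0.05/0.02); covered depth is
  `1 + Poisson(mean 20 - 1)`; mutated loci draw the variant fraction from
  the bursty mixture (`delta0 = 0.5`, `alpha0 = beta0 = 0.01`, per-locus
  bi-allelic shapes `~ Uniform(0.5, 2)`), unmutated loci from the error
  rate.
- Optional copy-number evolution: per locus, the diploid state evolves over
  every tree edge with a gain probability `1 - exp(-0.2)` and loss
  probability `1 - exp(-0.1)` hitting a uniformly chosen copy; the variant
  arises on the edge into its origin clone on one parental allele and is
  protected there (events that would erase it, or empty the locus, are
  redrawn among legal targets).  The copy numbers reported to inference are
  the origin clone's profile, mimicking a clonal copy-number caller, so
  subclonal copy-number change acts as a deliberate model-misspecification
  stressor.

What the simulator does **not** emulate: read-level artifacts (mapping,
UMIs, allelic mapping bias), doublets, expression-level variation between
genes, transcriptional covariation between loci, or subclonal copy-number
effects on the single-cell counts.  Passing the recovery benchmarks on
matched simulations therefore demonstrates correctness and calibration of
the inference, not robustness to every artifact of real scRNA-seq.

## Preprocessing

SNVs are kept when at least 2 cells show at least 2 variant reads (the
droplet-data mode relaxes the read threshold to 1); an empty result raises
an error recommending the relaxed mode.  Per-locus bi-allelic shapes
`(alpha_n, beta_n)` are fit from cells with `0 < b < d`: a binomial-noise-
corrected method of moments provides the start and a truncated
Beta-Binomial maximum likelihood refines it.  The truncation matters: at
covered depths near 20, selecting `0 < b < d` clips the Beta tails and a
plain moment fit is biased well beyond 30% relative error.  Fewer than 3
informative cells, or a degenerate fit, falls back to the flat (1, 1).

## Evaluation metrics

V-measure, adjusted Rand index and adjusted mutual information
(scikit-learn) score the SNV clustering.  The ancestral reconstruction
error is the mean absolute difference between true and predicted SNV-pair
ancestry matrices, by default over ordered pairs `i != j` with denominator
`N(N-1)` (ancestry is asymmetric); an unordered variant is available behind
a flag.  Per-cell genotype loss counts mutation-status disagreements, and
its expectation weighs each node by the cell's posterior.

## Numerical choices

- All likelihoods in log space; log-sum-exp for mixtures and marginals
  (a lean numpy implementation — profiling showed the scipy wrapper
  dominating the sampler's inner loop of many tiny arrays).  Depths up to
  10^6 stay finite.
- Binomial success probabilities clipped to `[1e-300, 1 - 1e-16]`; stick
  draws clipped to `[1e-12, 1 - 1e-12]`; stick values of exactly 1 are
  accepted in frozen fixtures (they exhaust the partition).
- Ties and orderings are always resolved by canonical path order; empty
  leaves are pruned after every sweep and paths renumbered, so serialized
  states are unique.
- Degenerate inputs: zero-depth observations contribute zero log-likelihood
  everywhere; a cell with no covered loci has a flat assignment posterior;
  proposals with a zero Dirichlet component are rejected, never raised.

## Known limitations

- Subclonal copy-number inference is out of scope; the model conditions on
  clonal `(M, m)` calls, and the genotype enumeration is a declared choice
  (`v in 1..M union 1..m`, uniform prior) rather than an estimate.
- The uniform cell prior deliberately ignores clone sizes; cells with no
  informative reads cannot be placed better than uniformly.
- Topology mixing between bulk-equivalent trees (e.g., cherry vs. chain at
  nested prevalences) is slow at large SNV counts; multiple seeded chains
  are recommended, and the benchmark of record for that regime pools chains.
- Hyperparameters `lambda0, lam, gamma` are fixed configuration; no
  empirical-Bayes updates.
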