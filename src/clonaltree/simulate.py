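"""Generative simulator matched to the observation model.

Produces bulk and single-cell read-count datasets from a known ground-truth
clonal tree, for benchmarking and for every synthetic fixture in the test
suite.  The generative process mirrors the likelihood exactly: bulk variant
reads are binomial with the genotype/prevalence success probability, and
single-cell variant reads follow the bursty Beta-Binomial mixture (a covered
cell expresses mono-allelically with probability 1 - delta0).

Clone fractions are drawn symmetric-Dirichlet over the cancer clones, so the
progenitor clone has cellular prevalence 1 (a purity-one tumor) and no cell
sits at the healthy root.  Optional copy-number evolution runs a birth-death
process over the tree edges at every SNV locus; the copy-number profile
reported to the inference is the SNV's origin clone's profile, mimicking a
clonal copy-number caller, so subclonal copy-number change acts as a
realistic model-misspecification stressor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .likelihood import BulkData, ScReadMatrix, ScRnaHyperparams, theta
from .tree import (
    ClonalTree,
    NodePath,
    PROGENITOR,
    PrevalenceField,
    TssbHyperparams,
    mutation_status,
    path_str,
    prevalences_from_fractions,
    sample_tssb,
)

Topology = Literal["chain", "cherry", "multifurcating", "binary", "tssb"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults follow the central simulation design: 100 SNVs on a
    multifurcating tree (progenitor plus three subclones), single-region bulk
    at mean depth 1000, 400 cells with per-locus coverage probability 0.1 and
    mean covered depth 20, no copy-number evolution.
    """

    topology: Topology = "multifurcating"
    n_snvs: int = 100
    n_cells: int = 400
    n_regions: int = 1
    chain_length: int = 3
    n_children: int = 3
    binary_depth: int = 2
    mean_bulk_depth: float = 1000.0
    bulk_depth_dispersion: float = 10.0
    p_cov: float = 0.1
    mean_sc_depth: float = 20.0
    cnv_enabled: bool = False
    cnv_birth_rate: float = 0.2
    cnv_death_rate: float = 0.1
    delta0: float = 0.5
    alpha0: float = 0.01
    beta0: float = 0.01
    alpha_beta_low: float = 0.5
    alpha_beta_high: float = 2.0
    epsilon: float = 0.001
    tssb: TssbHyperparams = field(default_factory=TssbHyperparams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snvs < 1 or self.n_cells < 0 or self.n_regions < 1:
            raise ValueError("n_snvs >= 1, n_cells >= 0, n_regions >= 1 required")
        if not 0 < self.p_cov <= 1:
            raise ValueError("coverage probability must be in (0, 1]")
        if self.cnv_birth_rate < 0 or self.cnv_death_rate < 0:
            raise ValueError("birth/death rates must be >= 0")
        if self.mean_sc_depth < 1:
            raise ValueError("mean_sc_depth must be >= 1")


@dataclass
class GroundTruth:
    """Latent state a simulated dataset was generated from."""

    tree: ClonalTree
    z: list[NodePath]
    phi: PrevalenceField
    eta: dict[NodePath, np.ndarray]
    zeta: list[NodePath]
    mu: np.ndarray  # (n_cells, n_snvs) uint8
    clone_genotypes: dict[NodePath, np.ndarray]  # node -> (N, 3) [n_major, n_minor, v]
    snv_M: np.ndarray
    snv_m: np.ndarray
    snv_v: np.ndarray
    sc_hyper: ScRnaHyperparams
    config: SimulationConfig

    @property
    def snv_labels(self) -> list[str]:
        return [path_str(v) for v in self.z]

    @property
    def cell_labels(self) -> list[str]:
        return [path_str(v) for v in self.zeta]


def _build_topology(config: SimulationConfig, rng: np.random.Generator) -> tuple[ClonalTree, list[NodePath] | None]:
    """Tree for the requested shape; for 'tssb' also returns the prior draw of z."""
    if config.topology == "chain":
        paths: list[NodePath] = [PROGENITOR]
        for _ in range(config.chain_length - 1):
            paths.append(paths[-1] + (0,))
        return ClonalTree([(), *paths]), None
    if config.topology == "cherry":
        return ClonalTree([(), (0,), (0, 0), (0, 1)]), None
    if config.topology == "multifurcating":
        kids = [(0, k) for k in range(config.n_children)]
        return ClonalTree([(), (0,), *kids]), None
    if config.topology == "binary":
        paths = [PROGENITOR]
        frontier = [PROGENITOR]
        for _ in range(config.binary_depth):
            nxt = []
            for u in frontier:
                nxt.extend([u + (0,), u + (1,)])
            paths.extend(nxt)
            frontier = nxt
        return ClonalTree([(), *paths]), None
    if config.topology == "tssb":
        tree, z, _ = sample_tssb(config.tssb, config.n_snvs, rng)
        return tree, z
    raise ValueError(f"unknown topology {config.topology!r}")


def simulate_truth(config: SimulationConfig, rng: np.random.Generator | None = None) -> GroundTruth:
    """Draw the latent state: tree, SNV assignment, prevalences, cell clones.

    Clone fractions per region are symmetric Dirichlet(1) over the cancer
    clones; SNVs cover every cancer clone at least once when feasible; cells
    are multinomial in the first region's clone fractions.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    tree, z_prior = _build_topology(config, rng)
    cancer = [u for u in tree.nodes if u]
    k = len(cancer)

    # SNV assignment
    if z_prior is not None:
        z = list(z_prior)
    else:
        z = [cancer[i] for i in rng.integers(0, k, size=config.n_snvs)]
        if config.n_snvs >= k:
            # guarantee every clone carries at least one SNV
            slots = rng.choice(config.n_snvs, size=k, replace=False)
            for node, s in zip(cancer, slots):
                z[s] = node
        else:
            warnings.warn(
                f"only {config.n_snvs} SNVs for {k} clones: some clones stay empty",
                stacklevel=2,
            )

    # clone fractions and prevalences (eta at the healthy root is 0)
    eta_cancer = rng.dirichlet(np.ones(k), size=config.n_regions).T  # (k, R)
    eta = {(): np.zeros(config.n_regions)}
    for i, node in enumerate(cancer):
        eta[node] = eta_cancer[i]
    regions = [f"R{r}" for r in range(config.n_regions)]
    phi = prevalences_from_fractions(tree, eta, regions)

    # cell-to-clone assignment from region-0 clone fractions
    zeta_idx = rng.choice(k, size=config.n_cells, p=eta_cancer[:, 0])
    zeta = [cancer[i] for i in zeta_idx]
    mu = np.zeros((config.n_cells, config.n_snvs), dtype=np.uint8)
    status = {node: mutation_status(tree, z, node) for node in cancer}
    for c, node in enumerate(zeta):
        mu[c] = status[node]

    # per-SNV bi-allelic shapes
    alpha_n = rng.uniform(config.alpha_beta_low, config.alpha_beta_high, size=config.n_snvs)
    beta_n = rng.uniform(config.alpha_beta_low, config.alpha_beta_high, size=config.n_snvs)
    sc_hyper = ScRnaHyperparams(
        alpha0=config.alpha0,
        beta0=config.beta0,
        delta0=np.full(config.n_snvs, config.delta0),
        alpha=alpha_n,
        beta=beta_n,
        epsilon=config.epsilon,
    )

    n = config.n_snvs
    truth = GroundTruth(
        tree=tree,
        z=z,
        phi=phi,
        eta=eta,
        zeta=zeta,
        mu=mu,
        clone_genotypes={u: np.tile([1, 1, 1], (n, 1)) for u in cancer},
        snv_M=np.ones(n, dtype=np.int64),
        snv_m=np.ones(n, dtype=np.int64),
        snv_v=np.ones(n, dtype=np.int64),
        sc_hyper=sc_hyper,
        config=config,
    )
    if config.cnv_enabled:
        simulate_copy_number(truth, config, rng)
    return truth


# ---------------------------------------------------------------------------
# Copy-number birth-death process
# ---------------------------------------------------------------------------


def apply_cn_event(
    state: tuple[int, int, int], kind: str, copy_index: int
) -> tuple[int, int, int]:
    """Apply one gain/loss to a locus state (n_carrier, n_other, v).

    ``n_carrier`` counts copies of the parental allele carrying the variant,
    ``v`` of which are variant copies; ``copy_index`` in [0, n_carrier +
    n_other) selects the affected copy, variant copies ordered first.
    """
    n_car, n_oth, v = state
    c = n_car + n_oth
    if not 0 <= copy_index < c:
        raise ValueError("copy_index out of range")
    step = 1 if kind == "birth" else -1
    if kind not in ("birth", "death"):
        raise ValueError(f"unknown event kind {kind!r}")
    if copy_index < v:
        return (n_car + step, n_oth, v + step)
    if copy_index < n_car:
        return (n_car + step, n_oth, v)
    return (n_car, n_oth + step, v)


def simulate_copy_number(
    truth: GroundTruth, config: SimulationConfig, rng: np.random.Generator
) -> None:
    """Evolve each locus' copy-number state over the tree by birth-death events.

    The state starts diploid (1, 1) at the root; on each edge a gain occurs
    with probability 1 - exp(-birth_rate) and a loss with 1 - exp(-death_rate),
    hitting a uniformly chosen copy.  The variant arises on the edge into its
    origin clone (one copy of a random parental allele) before that edge's
    events, so gains at the origin can duplicate it.  Events that would drop
    the total copy number to zero, or erase the variant at its origin, are
    resampled (at most 100 tries).
    """
    p_birth = 1.0 - np.exp(-config.cnv_birth_rate)
    p_death = 1.0 - np.exp(-config.cnv_death_rate)
    tree, z = truth.tree, truth.z
    cancer = [u for u in tree.nodes if u]
    n = config.n_snvs
    genotypes = {u: np.tile([1, 1, 0], (n, 1)) for u in cancer}

    def edge_events(state: tuple[int, int, int], protect_variant: bool) -> tuple[int, int, int]:
        for kind, p in (("birth", p_birth), ("death", p_death)):
            if rng.uniform() >= p:
                continue
            # illegal outcomes (total copy 0, or losing a protected variant)
            # are resampled, which is a uniform draw over the legal targets;
            # an event with no legal target is skipped
            legal = [
                cand
                for idx in range(sum(state[:2]))
                if (cand := apply_cn_event(state, kind, idx))[0] + cand[1] > 0
                and not (protect_variant and cand[2] == 0)
            ]
            if legal:
                state = legal[int(rng.integers(0, len(legal)))]
        return state

    for i in range(n):
        origin = tuple(z[i])
        for u in cancer:  # preorder: parents precede children
            parent = u[:-1]
            st = (1, 1, 0) if parent == () else tuple(genotypes[parent][i])
            if u == origin:
                # mutation lands on one copy of a uniformly chosen parental copy
                n_car, n_oth, _ = st
                if rng.uniform() < n_car / (n_car + n_oth):
                    st = (n_car, n_oth, 1)
                else:
                    st = (n_oth, n_car, 1)  # relabel: carrier allele first
                st = edge_events(st, protect_variant=True)
            else:
                st = edge_events(st, protect_variant=False)
            genotypes[u][i] = st

    truth.clone_genotypes = genotypes
    for i in range(n):
        n_car, n_oth, v = genotypes[tuple(z[i])][i]
        truth.snv_M[i] = max(n_car, n_oth)
        truth.snv_m[i] = min(n_car, n_oth)
        truth.snv_v[i] = v


# ---------------------------------------------------------------------------
# Read-count generation
# ---------------------------------------------------------------------------


def simulate_bulk(
    truth: GroundTruth, config: SimulationConfig, rng: np.random.Generator
) -> BulkData:
    """Bulk read counts: depth negative-binomial, variant reads binomial with
    the origin-clone genotype's success probability."""
    n, r = config.n_snvs, config.n_regions
    size = config.bulk_depth_dispersion
    p = size / (size + config.mean_bulk_depth)
    d = rng.negative_binomial(size, p, size=(n, r))
    b = np.zeros_like(d)
    for i in range(n):
        v = int(truth.snv_v[i])
        c = int(truth.snv_M[i] + truth.snv_m[i])
        phi = truth.phi.phi[tuple(truth.z[i])]
        th = np.clip(theta(v, c, phi, config.epsilon), 0.0, 1.0)
        b[i] = rng.binomial(d[i], th)
    return BulkData(
        snv_ids=[f"s{i}" for i in range(n)],
        b=b,
        d=d,
        M=truth.snv_M.copy(),
        m=truth.snv_m.copy(),
        regions=[f"R{j}" for j in range(r)],
    )


def simulate_scrna(
    truth: GroundTruth, config: SimulationConfig, rng: np.random.Generator
) -> ScReadMatrix:
    """Single-cell variant read counts.

    Per (cell, SNV): covered with probability p_cov; covered depth is
    1 + Poisson(mean_sc_depth - 1).  At a mutated locus the variant fraction
    chi is Beta(alpha_n, beta_n) with probability delta0 (bi-allelic) and
    Beta(alpha0, beta0) otherwise (mono-allelic); at an unmutated locus
    variant reads appear at the error rate only.
    """
    C, N = config.n_cells, config.n_snvs
    covered = rng.random((C, N)) < config.p_cov
    cell_idx, snv_idx = np.nonzero(covered)
    k = len(cell_idx)
    d = 1 + rng.poisson(config.mean_sc_depth - 1.0, size=k)
    mu = truth.mu[cell_idx, snv_idx].astype(bool)
    alpha_n, beta_n, delta0_n = truth.sc_hyper.per_snv(N)
    chi = np.empty(k)
    biallelic = rng.random(k) < delta0_n[snv_idx]
    idx_bi = mu & biallelic
    idx_mono = mu & ~biallelic
    chi[idx_bi] = rng.beta(alpha_n[snv_idx[idx_bi]], beta_n[snv_idx[idx_bi]])
    chi[idx_mono] = rng.beta(config.alpha0, config.beta0, size=int(idx_mono.sum()))
    chi[~mu] = config.epsilon
    b = rng.binomial(d, chi)
    return ScReadMatrix(
        cell_ids=[f"c{c}" for c in range(C)],
        snv_ids=[f"s{i}" for i in range(N)],
        cell_idx=cell_idx,
        snv_idx=snv_idx,
        b=b,
        d=d,
    )


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[GroundTruth, BulkData, ScReadMatrix]:
    """Full draw: truth, bulk table, and single-cell matrix, one seed."""
    rng = np.random.default_rng(config.seed)
    truth = simulate_truth(config, rng)
    bulk = simulate_bulk(truth, config, rng)
    sc = simulate_scrna(truth, config, rng)
    return truth, bulk, sc


# ---------------------------------------------------------------------------
# Coupled-dataset helpers (nested comparisons)
# ---------------------------------------------------------------------------


def thin_coverage(sc: ScReadMatrix, keep_prob: float, rng: np.random.Generator) -> ScReadMatrix:
    """Drop each covered entry independently with probability 1 - keep_prob.

    Thinning a dataset simulated at coverage p gives an exact draw at coverage
    keep_prob * p coupled to the original, which makes coverage sweeps
    comparable replicate by replicate.
    """
    if not 0 < keep_prob <= 1:
        raise ValueError("keep_prob must be in (0, 1]")
    keep = rng.random(sc.n_entries) < keep_prob
    return ScReadMatrix(
        cell_ids=list(sc.cell_ids),
        snv_ids=list(sc.snv_ids),
        cell_idx=sc.cell_idx[keep],
        snv_idx=sc.snv_idx[keep],
        b=sc.b[keep],
        d=sc.d[keep],
    )


def subset_cells(sc: ScReadMatrix, n_cells: int) -> ScReadMatrix:
    """Restrict to the first n_cells cells (nested cell-count comparisons)."""
    if n_cells > sc.n_cells:
        raise ValueError("cannot take more cells than present")
    keep = sc.cell_idx < n_cells
    return ScReadMatrix(
        cell_ids=list(sc.cell_ids[:n_cells]),
        snv_ids=list(sc.snv_ids),
        cell_idx=sc.cell_idx[keep],
        snv_idx=sc.snv_idx[keep],
        b=sc.b[keep],
        d=sc.d[keep],
    )
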