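"""MCMC over (tree, SNV assignment, cellular prevalences).

One iteration re-assigns every SNV by slice sampling on the tree-structured
stick-breaking (TSSB) partition, prunes empty leaves, Gibbs-resamples the
sticks from their conjugate Beta conditionals, and updates the clone
fractions by Metropolis-Hastings with a Dirichlet random-walk proposal.

The slice move follows the standard lazy TSSB scheme: a uniform variable
u in [0, 1) indexes nodes through the stick partition (an interval of length
pi_v maps to node v, intervals in preorder), the slice level is drawn under
the data log-likelihood of the current assignment, and the interval shrinks
toward the current node's interval using preorder comparisons until a node
above the slice is found.  Sticks and nodes are instantiated lazily from the
prior during the search; newly created nodes receive prevalences drawn
uniformly from the feasible range so the subtree-sum constraints hold by
construction.

The single-cell likelihood is marginal over cell-to-clone assignments with a
uniform prior over the |V| current nodes; the sampler maintains a cells x
nodes matrix of cell log-likelihoods so one slice evaluation costs
O(C_n * |V|) where C_n is the number of cells covering the SNV being moved.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import gammaln

from .likelihood import (
    BulkData,
    BulkLikelihood,
    ScReadMatrix,
    ScRnaHyperparams,
    cell_node_logliks,
    entry_logliks,
    logsumexp,
)
from .tree import (
    ClonalTree,
    NodePath,
    PROGENITOR,
    PrevalenceField,
    ROOT,
    StickState,
    TssbHyperparams,
    find_node,
    is_ancestor_or_equal,
    mutation_status,
    path_str,
    stick_masses,
)

_STICK_EPS = 1e-12


@dataclass(frozen=True)
class SamplerConfig:
    """Run-length, proposal, and hyperparameter settings for the sampler."""

    n_iterations: int = 2000
    burn_in: int = 1000
    thinning: int = 1
    seed: int = 0
    mh_concentration: float = 50.0
    mh_pseudocount: float = 0.01
    mh_steps: int = 10
    pairwise_eta_moves: int = 4  # pairwise conditional passes per node per region
    prune_empty: bool = True
    slice_shrink_cap: int = 1000
    tssb: TssbHyperparams = field(default_factory=TssbHyperparams)

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("require 0 <= burn_in < n_iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.mh_concentration <= 0 or self.mh_pseudocount <= 0:
            raise ValueError("MH proposal parameters must be positive")


@dataclass
class TraceSample:
    """One retained posterior sample, serialized by value."""

    iteration: int
    log_joint: float
    tree_paths: list[NodePath]
    z: list[NodePath]
    phi: dict[NodePath, np.ndarray]
    sticks: StickState
    regions: list[str]

    @property
    def n_clones(self) -> int:
        return len(self.tree_paths)

    def tree(self) -> ClonalTree:
        return ClonalTree(self.tree_paths)

    def prevalence_field(self) -> PrevalenceField:
        return PrevalenceField(phi={k: v.copy() for k, v in self.phi.items()}, regions=list(self.regions))

    @property
    def snv_labels(self) -> list[str]:
        return [path_str(v) for v in self.z]


@dataclass
class PosteriorTrace:
    """Per-iteration scalar trace plus the retained (thinned) samples."""

    log_joint: np.ndarray
    n_clones: np.ndarray
    samples: list[TraceSample]

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class CellAssignmentPosterior:
    """Posterior cell-to-clone assignment under the uniform cell prior."""

    cell_ids: list[str]
    nodes: list[NodePath]
    probabilities: np.ndarray  # (n_cells, n_nodes), rows sum to 1
    map_nodes: list[NodePath]
    mu_hat: np.ndarray  # (n_cells, n_snvs) predicted mutation status


def _dirichlet_logpdf(x: np.ndarray, alpha: np.ndarray) -> float:
    x = np.clip(x, 1e-300, None)
    return float(gammaln(alpha.sum()) - gammaln(alpha).sum() + ((alpha - 1.0) * np.log(x)).sum())


class SliceSearchError(RuntimeError):
    """Slice search failed to terminate within the shrinkage cap."""


class TreeSampler:
    """Stateful MCMC sampler; one instance owns one chain.

    ``loglik_override``, if given, replaces the data term of the SNV
    conditional with an arbitrary function (n, node_path) -> log-likelihood;
    it exists so the slice kernel can be validated against enumerable
    conditionals on frozen fixtures.
    """

    def __init__(
        self,
        bulk: BulkData,
        sc: ScReadMatrix | None,
        config: SamplerConfig,
        sc_hyper: ScRnaHyperparams | None = None,
        loglik_override: Callable[[int, NodePath], float] | None = None,
    ):
        if sc is not None and sc.n_cells > 0 and list(sc.snv_ids) != list(bulk.snv_ids):
            raise ValueError("bulk and single-cell SNV ids must align")
        self.bulk = bulk
        self.sc = sc if (sc is not None and sc.n_cells > 0) else None
        self.config = config
        self.sc_hyper = sc_hyper if sc_hyper is not None else ScRnaHyperparams()
        self.loglik_override = loglik_override
        self.rng = np.random.default_rng(config.seed)
        self.n_snvs = bulk.n_snvs
        self.n_regions = bulk.n_regions
        self.regions = list(bulk.regions)

        self.bulk_lik = BulkLikelihood(bulk, epsilon=self.sc_hyper.epsilon)
        if self.sc is not None:
            ll1, ll0 = entry_logliks(self.sc, self.sc_hyper)
            self._diff = ll1 - ll0
            self._base = np.zeros(self.sc.n_cells)
            np.add.at(self._base, self.sc.cell_idx, ll0)
            # entry indices grouped per SNV
            order = np.argsort(self.sc.snv_idx, kind="stable")
            bounds = np.searchsorted(self.sc.snv_idx[order], np.arange(self.n_snvs + 1))
            self._snv_entries = [order[bounds[i] : bounds[i + 1]] for i in range(self.n_snvs)]

        # initial state: minimal tree, every SNV at the progenitor
        self.tree = ClonalTree()
        self.sticks = StickState()
        self.sticks.nu[PROGENITOR] = float(self.rng.beta(1.0, config.tssb.nu_prior_beta(PROGENITOR)))
        self.z: list[NodePath] = [PROGENITOR] * self.n_snvs
        phi0 = self.rng.uniform(size=self.n_regions)
        self.phi: dict[NodePath, np.ndarray] = {
            ROOT: np.ones(self.n_regions),
            PROGENITOR: phi0,
        }
        self.mh_proposals = 0
        self.mh_accepts = 0
        self._move_real: set[NodePath] | None = None
        self._rebuild()

    # -- cached view of the current state ---------------------------------

    def _rebuild(self) -> None:
        """Recompute every derived cache from the primary state."""
        nodes = self.tree.nodes
        self.nodes = nodes
        self.node_index = {p: i for i, p in enumerate(nodes)}
        self._lift_cache: dict[NodePath, float] = {}
        v = len(nodes)
        anc = np.zeros((v, v), dtype=float)
        for i, u in enumerate(nodes):
            for j, w in enumerate(nodes):
                if is_ancestor_or_equal(u, w):
                    anc[i, j] = 1.0
        self.anc = anc
        self.phi_mat = np.stack([self.phi[p] for p in nodes])  # (V, R)
        self.z_idx = np.array([self.node_index[p] for p in self.z], dtype=np.int64)
        phi_snv = self.phi_mat[self.z_idx]
        # per-SNV, per-region bulk log-likelihoods at the current state
        self.bulk_site_mat = np.stack(
            [self.bulk_lik.region_logliks(phi_snv[:, r], r) for r in range(self.n_regions)],
            axis=1,
        )
        if self.sc is not None:
            s = np.zeros((self.sc.n_cells, v))
            np.add.at(s, (self.sc.cell_idx, self.z_idx[self.sc.snv_idx]), self._diff)
            self.A = s @ anc  # A[c, j] = sum of diffs for SNVs ancestral to node j
            self.rowlse = logsumexp(self.A, axis=1)

    def _eta_mat(self) -> np.ndarray:
        """Clone fractions (V, R) implied by the current prevalences."""
        eta = self.phi_mat.copy()
        for p, i in self.node_index.items():
            for c in self.tree.children(p):
                eta[i] -= self.phi_mat[self.node_index[c]]
        return eta

    # -- log joint ---------------------------------------------------------

    def bulk_total(self) -> float:
        return float(self.bulk_site_mat.sum())

    def sc_total(self) -> float:
        if self.sc is None:
            return 0.0
        return float(self.rowlse.sum() + self._base.sum() - self.sc.n_cells * np.log(len(self.nodes)))

    def log_joint(self) -> float:
        pi, _ = stick_masses(self.tree, self.sticks)
        lp_z = float(sum(np.log(max(pi[p], 1e-300)) for p in self.z))
        lp_eta = float(self.n_regions * gammaln(len(self.nodes)))
        return self.bulk_total() + self.sc_total() + lp_z + lp_eta

    # -- state injection (validation and diagnostics) ----------------------

    def set_state(
        self,
        tree: ClonalTree,
        sticks: StickState,
        z: Sequence[NodePath],
        phi: dict[NodePath, np.ndarray],
    ) -> None:
        self.tree = tree
        self.sticks = sticks
        self.z = [tuple(p) for p in z]
        self.phi = {tuple(k): np.atleast_1d(np.asarray(v, dtype=float)) for k, v in phi.items()}
        self._rebuild()

    def set_bulk_counts(self, b: np.ndarray, d: np.ndarray) -> None:
        """Swap in new bulk read counts (same loci); used by calibration checks."""
        self.bulk.b = np.atleast_2d(np.asarray(b, dtype=np.int64))
        self.bulk.d = np.atleast_2d(np.asarray(d, dtype=np.int64))
        self.bulk_lik = BulkLikelihood(self.bulk, epsilon=self.sc_hyper.epsilon)
        self._rebuild()

    # -- SNV conditional ----------------------------------------------------

    def _occupied_without(self, n: int) -> set[NodePath]:
        """Nodes of the minimal (occupied + ancestors) representation when
        SNV n is left out."""
        counts = np.bincount(self.z_idx, minlength=len(self.nodes))
        counts[self.z_idx[n]] -= 1
        real: set[NodePath] = {ROOT, PROGENITOR}
        for i, c in enumerate(counts):
            if c > 0:
                p = self.nodes[i]
                for k in range(len(p) + 1):
                    real.add(p[:k])
        return real

    def _lift_logwidth(self, e: NodePath) -> float:
        """Log feasible width of node e's prevalence at instantiation: the
        parent's prevalence minus earlier-index siblings (later siblings did
        not exist yet), summed over regions."""
        parent = e[:-1]
        avail = self.phi[parent].copy()
        for c in self.tree.children(parent):
            if c[-1] < e[-1]:
                avail -= self.phi[c]
        return float(np.log(np.clip(avail, 1e-12, None)).sum())

    def _lift_cached(self, e: NodePath) -> float:
        v = self._lift_cache.get(e)
        if v is None:
            v = self._lift_logwidth(e)
            self._lift_cache[e] = v
        return v

    def _config_logprior(self, path: NodePath, real_base: set[NodePath]) -> float:
        """Clone-fraction prior density of the configuration with the moving
        SNV at ``path``, over the currently represented nodes.

        The minimal tree of a configuration is occupied nodes plus ancestors;
        its clone fractions carry a Dirichlet(1) prior per region (density
        Gamma(K)).  Every other represented node is an auxiliary coordinate
        whose prevalence was a uniform draw on its feasible interval, and
        contributes its lift density 1/avail.  Assigning the SNV to ``path``
        promotes the unoccupied nodes along its path from auxiliary to real,
        trading their lift terms for a higher Dirichlet dimension.  Omitting
        this term makes the sampler systematically under-weight moves onto
        new clones when the data are informative (empirically verified by
        forward/successive-conditional calibration).
        """
        real = set(real_base)
        for k in range(len(path) + 1):
            real.add(tuple(path[:k]))
        out = self.n_regions * float(gammaln(len(real)))
        for e in self.nodes:
            if e and e not in real:
                out -= self._lift_cached(e)
        return out

    def _conditional_loglik(self, n: int, path: NodePath) -> float:
        """Unnormalized log conditional of assigning SNV n to ``path``
        (bulk term, single-cell delta relative to the current assignment,
        and the clone-fraction prior of the resulting configuration)."""
        if self.loglik_override is not None:
            return self.loglik_override(n, path)
        j = self.node_index[path]
        out = self._bulk_site(n, j)
        if self._move_real is not None:
            out += self._config_logprior(path, self._move_real)
        if self.sc is not None:
            cur_j = int(self.z_idx[n])
            if j != cur_j:
                rows = self._snv_entries[n]
                if len(rows):
                    cells = self.sc.cell_idx[rows]
                    shift = self._diff[rows][:, None] * (self.anc[j] - self.anc[cur_j])[None, :]
                    cand = logsumexp(self.A[cells] + shift, axis=1)
                    out += float((cand - self.rowlse[cells]).sum())
        return out

    def _bulk_site_regions(self, n: int, j: int) -> np.ndarray:
        """Per-region genotype-marginalized bulk log-likelihoods of SNV n at node j."""
        phi = self.phi_mat[j]  # (R,)
        v, c = self.bulk_lik.gv[n], self.bulk_lik.gc[n]  # (G,)
        eps = self.bulk_lik.epsilon
        th = np.where(
            v[:, None] == c[:, None],
            phi[None, :] * (1 - eps) + (1 - phi[None, :]) * eps,
            phi[None, :] * (v[:, None] / c[:, None]) + (1 - phi[None, :]) * eps,
        )
        th = np.where(v[:, None] == 0, eps, th)
        th = np.clip(th, 1e-300, 1 - 1e-16)
        b = self.bulk.b[n][None, :]
        d = self.bulk.d[n][None, :]
        ll = self.bulk_lik.logcoef[n][None, :] + b * np.log(th) + (d - b) * np.log1p(-th)
        return logsumexp(ll + self.bulk_lik.gmask[n][:, None], axis=0) - self.bulk_lik.log_gsize[n]

    def _bulk_site(self, n: int, j: int) -> float:
        return float(self._bulk_site_regions(n, j).sum())

    def _set_assignment(self, n: int, path: NodePath) -> None:
        j = self.node_index[path]
        cur_j = int(self.z_idx[n])
        if j == cur_j:
            return
        if self.sc is not None:
            rows = self._snv_entries[n]
            if len(rows):
                cells = self.sc.cell_idx[rows]
                self.A[cells] += self._diff[rows][:, None] * (self.anc[j] - self.anc[cur_j])[None, :]
                self.rowlse[cells] = logsumexp(self.A[cells], axis=1)
        self.z[n] = path
        self.z_idx[n] = j
        self.bulk_site_mat[n] = self._bulk_site_regions(n, j)

    # -- lazy tree growth ---------------------------------------------------

    def _grow(self, u: float) -> NodePath:
        before = self.tree.n_nodes
        path = find_node(u, self.tree, self.sticks, self.config.tssb, self.rng)
        if self.tree.n_nodes != before:
            self._init_new_phi()
            self._rebuild()
        return path

    def _init_new_phi(self) -> None:
        """Prevalences for newly instantiated nodes: uniform on the feasible
        interval (0, available mass under the parent), per region."""
        for p in self.tree.nodes:
            if p in self.phi:
                continue
            parent = p[:-1]
            taken = np.zeros(self.n_regions)
            for sib in self.tree.children(parent):
                if sib != p and sib in self.phi:
                    taken += self.phi[sib]
            avail = np.clip(self.phi[parent] - taken, 0.0, None)
            self.phi[p] = self.rng.uniform(0.0, avail)

    # -- kernels ------------------------------------------------------------

    def slice_resample_assignment(self, n: int) -> None:
        """Slice-sample the clone assignment of SNV n."""
        cur = tuple(self.z[n])
        self._move_real = self._occupied_without(n)
        try:
            s = self._conditional_loglik(n, cur) + float(np.log(self.rng.uniform()))
            u_min, u_max = 0.0, 1.0
            for _ in range(self.config.slice_shrink_cap):
                u = float(self.rng.uniform(u_min, u_max))
                path = self._grow(u)
                if self._conditional_loglik(n, path) > s:
                    self._set_assignment(n, path)
                    return
                if u_max - u_min < 1e-12:
                    return
                if path < cur:
                    u_min = u
                elif path > cur:
                    u_max = u
                else:  # pragma: no cover - current node always clears the slice
                    return
            raise SliceSearchError(
                f"slice search for SNV {n} did not terminate; "
                f"current={path_str(cur)}, interval=({u_min}, {u_max}), "
                f"tree={[path_str(p) for p in self.nodes]}"
            )
        finally:
            self._move_real = None

    def gibbs_resample_sticks(self) -> None:
        """Conjugate Beta updates of all nu- and psi-sticks given SNV counts."""
        counts = np.bincount(self.z_idx, minlength=len(self.nodes)).astype(float)
        sub = self.anc @ counts  # subtree counts
        hyper = self.config.tssb
        new_nu: dict[NodePath, float] = {}
        new_psi: dict[NodePath, list[float]] = {}
        for p, i in self.node_index.items():
            if not p:
                continue
            a = 1.0 + counts[i]
            b = hyper.nu_prior_beta(p) + (sub[i] - counts[i])
            new_nu[p] = float(np.clip(self.rng.beta(a, b), _STICK_EPS, 1 - _STICK_EPS))
            kids = self.tree.children(p)
            subs = [sub[self.node_index[c]] for c in kids]
            psis = []
            for k in range(len(kids)):
                a_k = 1.0 + subs[k]
                b_k = hyper.gamma + sum(subs[k + 1 :])
                psis.append(float(np.clip(self.rng.beta(a_k, b_k), _STICK_EPS, 1 - _STICK_EPS)))
            new_psi[p] = psis
        self.sticks = StickState(nu=new_nu, psi=new_psi)

    def mh_update_prevalences(self) -> None:
        """Metropolis-Hastings on the clone fractions, one region at a time.

        Two proposal flavours per region: a global Dirichlet random walk
        (eta' ~ Dirichlet(kappa * eta + kappa0)) and pairwise conditional
        moves that redraw one coordinate uniformly on (0, eta_u + eta_w)
        given the rest.  The pairwise proposal coincides with the Dirichlet(1)
        prior conditional, so its acceptance ratio is the likelihood ratio
        alone; it restores the prior exactly when the data are uninformative
        and undoes the clone-fraction aggregation that pruning applies.
        Prevalences follow from eta by subtree sums, so the constraints hold
        by construction.
        """
        kappa = self.config.mh_concentration
        kappa0 = self.config.mh_pseudocount
        eta = self._eta_mat()
        for r in range(self.n_regions):
            self._pairwise_eta_moves(eta, r)
            for _ in range(self.config.mh_steps):
                self.mh_proposals += 1
                cur = np.clip(eta[:, r], 1e-12, None)
                cur = cur / cur.sum()
                alpha_fwd = kappa * cur + kappa0
                prop = self.rng.dirichlet(alpha_fwd)
                if np.any(prop <= 0.0):
                    continue  # rejected, never an exception
                phi_prop = self.anc @ prop
                site_prop = self.bulk_lik.region_logliks(phi_prop[self.z_idx], r)
                alpha_rev = kappa * prop + kappa0
                log_ratio = (
                    float(site_prop.sum())
                    - float(self.bulk_site_mat[:, r].sum())
                    + _dirichlet_logpdf(cur, alpha_rev)
                    - _dirichlet_logpdf(prop, alpha_fwd)
                )
                if np.log(self.rng.uniform()) < log_ratio:
                    self.mh_accepts += 1
                    eta[:, r] = prop
                    self.phi_mat[:, r] = phi_prop
                    self.bulk_site_mat[:, r] = site_prop
        for p, i in self.node_index.items():
            self.phi[p] = self.phi_mat[i].copy()

    def _pairwise_eta_moves(self, eta: np.ndarray, r: int) -> None:
        """Conditional Metropolis moves on pairs of clone fractions.

        For a random pair (u, w) with s = eta_u + eta_w, propose
        eta_u' ~ Uniform(0, s) (the Dirichlet(1) prior conditional given all
        other coordinates) and accept on the bulk likelihood ratio.
        """
        v = len(self.nodes)
        if v < 2:
            return
        for _ in range(self.config.pairwise_eta_moves * v):
            i, j = self.rng.choice(v, size=2, replace=False)
            s = eta[i, r] + eta[j, r]
            if s <= 0:
                continue
            new_i = float(self.rng.uniform(0.0, s))
            prop = eta[:, r].copy()
            prop[i] = new_i
            prop[j] = s - new_i
            phi_prop = self.anc @ prop
            site_prop = self.bulk_lik.region_logliks(phi_prop[self.z_idx], r)
            log_ratio = float(site_prop.sum()) - float(self.bulk_site_mat[:, r].sum())
            if np.log(self.rng.uniform()) < log_ratio:
                eta[:, r] = prop
                self.phi_mat[:, r] = phi_prop
                self.bulk_site_mat[:, r] = site_prop

    def prune_empty_leaves(self) -> None:
        """Remove unoccupied leaf clones and renumber paths canonically."""
        occupied: set[NodePath] = {ROOT, PROGENITOR}
        for p in self.z:
            for k in range(len(p) + 1):
                occupied.add(tuple(p[:k]))
        if occupied == set(self.tree.nodes):
            return
        new_tree, mapping = self.tree.pruned(occupied)
        self.z = [mapping[p] for p in self.z]
        self.phi = {mapping[p]: self.phi[p] for p in mapping}
        new_sticks = StickState()
        for old, new in mapping.items():
            if not old:
                continue
            if old not in self.sticks.nu:  # lazily created, never visited
                self.sticks.nu[old] = float(
                    self.rng.beta(1.0, self.config.tssb.nu_prior_beta(old))
                )
            new_sticks.nu[new] = self.sticks.nu[old]
        for old, new in mapping.items():
            if not old:
                continue  # the healthy root carries no sticks
            old_kids = [c for c in self.tree.children(old) if c in mapping]
            old_psi = self.sticks.psi.get(old, [])
            new_sticks.psi[new] = [old_psi[c[-1]] for c in old_kids]
        self.sticks = new_sticks
        self.tree = new_tree
        self._rebuild()

    # -- driver -------------------------------------------------------------

    def sweep(self) -> None:
        """One full iteration: slice sweep, prune, stick Gibbs, MH prevalences."""
        for n in range(self.n_snvs):
            self.slice_resample_assignment(n)
        if self.config.prune_empty:
            self.prune_empty_leaves()
        self.gibbs_resample_sticks()
        self.mh_update_prevalences()
        self._rebuild()  # refresh incremental caches against drift

    def snapshot(self, iteration: int, lj: float) -> TraceSample:
        return TraceSample(
            iteration=iteration,
            log_joint=lj,
            tree_paths=list(self.tree.nodes),
            z=list(self.z),
            phi={k: v.copy() for k, v in self.phi.items()},
            sticks=copy.deepcopy(self.sticks),
            regions=list(self.regions),
        )

    def run(self, progress: Callable[[int, float], None] | None = None) -> PosteriorTrace:
        cfg = self.config
        log_joint = np.empty(cfg.n_iterations)
        n_clones = np.empty(cfg.n_iterations, dtype=np.int64)
        samples: list[TraceSample] = []
        for it in range(cfg.n_iterations):
            self.sweep()
            lj = self.log_joint()
            if not np.isfinite(lj):
                raise RuntimeError(
                    f"non-finite log joint at iteration {it}: "
                    f"bulk={self.bulk_total():.3f} sc={self.sc_total():.3f}"
                )
            log_joint[it] = lj
            n_clones[it] = len(self.nodes)
            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thinning == 0:
                samples.append(self.snapshot(it, lj))
            if progress is not None:
                progress(it, lj)
        return PosteriorTrace(log_joint=log_joint, n_clones=n_clones, samples=samples)


def run_mcmc(
    bulk: BulkData,
    sc: ScReadMatrix | None,
    config: SamplerConfig,
    sc_hyper: ScRnaHyperparams | None = None,
    progress: Callable[[int, float], None] | None = None,
) -> PosteriorTrace:
    """Run one chain; with no cells this is the bulk-only TSSB sampler."""
    sampler = TreeSampler(bulk, sc, config, sc_hyper=sc_hyper)
    return sampler.run(progress=progress)


def map_estimate(trace: PosteriorTrace) -> TraceSample:
    """Retained sample with maximal log joint; ties go to the earliest."""
    if not trace.samples:
        raise ValueError("empty trace")
    best = max(trace.samples, key=lambda s: (s.log_joint, -s.iteration))
    return best


def assign_cells(
    sample: TraceSample,
    sc: ScReadMatrix,
    sc_hyper: ScRnaHyperparams,
) -> CellAssignmentPosterior:
    """Posterior cell-to-clone assignment under the MAP state.

    P(zeta_c = v) is proportional to the cell's likelihood at v (uniform
    prior); the MAP node breaks ties by shallower depth then path order.
    Also emits each cell's predicted mutation-status vector at its MAP node.
    """
    tree = sample.tree()
    L, nodes = cell_node_logliks(tree, sample.z, sc, sc_hyper)
    probs = np.exp(L - np.asarray(logsumexp(L, axis=1))[:, None])
    # tie-break: evaluate nodes in (depth, path) order and keep the first argmax
    order = sorted(range(len(nodes)), key=lambda i: (len(nodes[i]), nodes[i]))
    map_nodes = []
    for c in range(L.shape[0]):
        row = L[c]
        best = order[0]
        for i in order[1:]:
            if row[i] > row[best] + 1e-12:
                best = i
        map_nodes.append(nodes[best])
    mu_hat = np.stack([mutation_status(tree, sample.z, v) for v in map_nodes]) if map_nodes else np.zeros((0, len(sample.z)), dtype=np.uint8)
    return CellAssignmentPosterior(
        cell_ids=list(sc.cell_ids),
        nodes=nodes,
        probabilities=probs,
        map_nodes=map_nodes,
        mu_hat=mu_hat,
    )
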