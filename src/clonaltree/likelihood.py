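"""Observation models for bulk DNA-seq and single-cell RNA-seq variant counts.

Bulk model: the variant read count at a locus follows a binomial whose success
probability depends on the clone's cellular prevalence phi and on the latent
genotype g = (v, c) (variant copies / total copies), marginalized uniformly
over the genotypes compatible with the clonal major/minor copy numbers (M, m):

    theta(g, phi, eps) = eps                              if v = 0
                       = phi (1 - eps) + (1 - phi) eps    if v = c
                       = phi v / c + (1 - phi) eps        otherwise

Single-cell model: for a cell carrying the mutation the variant fraction chi
is bursty -- mono-allelic expression pushes chi to 0 or 1 -- so counts follow
a two-component Beta-Binomial mixture (mono-allelic component Beta(alpha0,
beta0) with tiny symmetric shapes, bi-allelic component Beta(alpha_n, beta_n),
mixture weight delta0 marginalized out).  A cell without the mutation sees
variant reads only through sequencing error: BetaBinomial(d, eps, 1 - eps).

All computation is in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import betabinom as _betabinom


def logsumexp(a: np.ndarray, axis: int | None = None) -> np.ndarray | float:
    """Minimal log-sum-exp (numpy only; the scipy wrapper is too slow for the
    sampler's inner loop of many tiny arrays)."""
    a = np.asarray(a, dtype=float)
    m = np.max(a, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(divide="ignore"):
        s = np.log(np.sum(np.exp(a - m), axis=axis))
    if axis is None:
        return float(m.reshape(()) + s)
    return np.squeeze(m, axis=axis) + s

from .tree import (
    ClonalTree,
    ConstraintViolation,
    NodePath,
    PrevalenceField,
    is_ancestor_or_equal,
    stick_masses,
)

# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass
class BulkData:
    """Per-SNV, per-region variant/total read counts with clonal copy numbers.

    Arrays: b, d have shape (N, R); M, m have shape (N,) (copy numbers are a
    property of the locus, shared across regions).
    """

    snv_ids: list[str]
    b: np.ndarray
    d: np.ndarray
    M: np.ndarray
    m: np.ndarray
    regions: list[str] = field(default_factory=lambda: ["R0"])

    def __post_init__(self) -> None:
        self.b = np.atleast_2d(np.asarray(self.b, dtype=np.int64))
        self.d = np.atleast_2d(np.asarray(self.d, dtype=np.int64))
        self.M = np.asarray(self.M, dtype=np.int64)
        self.m = np.asarray(self.m, dtype=np.int64)
        n = len(self.snv_ids)
        if self.b.shape != (n, len(self.regions)) or self.d.shape != self.b.shape:
            raise ValueError("b, d must have shape (n_snvs, n_regions)")
        if np.any(self.b < 0) or np.any(self.b > self.d):
            raise ValueError("require 0 <= b <= d")
        if np.any(self.M < 1):
            raise ValueError("major copy number must be >= 1 (homozygous deletions excluded)")
        if np.any(self.m < 0) or np.any(self.m > self.M):
            raise ValueError("require 0 <= m <= M")

    @property
    def n_snvs(self) -> int:
        return len(self.snv_ids)

    @property
    def n_regions(self) -> int:
        return len(self.regions)


@dataclass
class ScReadMatrix:
    """Sparse cell x SNV variant/total read counts; absent entries mean d = 0."""

    cell_ids: list[str]
    snv_ids: list[str]
    cell_idx: np.ndarray
    snv_idx: np.ndarray
    b: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        self.cell_idx = np.asarray(self.cell_idx, dtype=np.int64)
        self.snv_idx = np.asarray(self.snv_idx, dtype=np.int64)
        self.b = np.asarray(self.b, dtype=np.int64)
        self.d = np.asarray(self.d, dtype=np.int64)
        if not (len(self.cell_idx) == len(self.snv_idx) == len(self.b) == len(self.d)):
            raise ValueError("entry arrays must have equal length")
        if np.any(self.b < 0) or np.any(self.b > self.d):
            raise ValueError("require 0 <= b <= d per entry")
        if len(self.cell_idx) and (
            self.cell_idx.max() >= len(self.cell_ids)
            or self.snv_idx.max() >= len(self.snv_ids)
        ):
            raise ValueError("entry indices out of range")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_snvs(self) -> int:
        return len(self.snv_ids)

    @property
    def n_entries(self) -> int:
        return len(self.b)

    def dense(self) -> tuple[np.ndarray, np.ndarray]:
        """Dense (b, d) matrices of shape (n_cells, n_snvs)."""
        b = np.zeros((self.n_cells, self.n_snvs), dtype=np.int64)
        d = np.zeros_like(b)
        b[self.cell_idx, self.snv_idx] = self.b
        d[self.cell_idx, self.snv_idx] = self.d
        return b, d


@dataclass
class ScRnaHyperparams:
    """Hyperparameters of the single-cell allelic expression model.

    alpha0 = beta0 = 0.01 give a symmetric U-shaped Beta for mono-allelic
    (bursty) expression; alpha_n, beta_n (per SNV) shape the bi-allelic
    component and are estimated in preprocessing; delta0 is the prior
    probability of bi-allelic expression; epsilon is the sequencing error
    probability.
    """

    alpha0: float = 0.01
    beta0: float = 0.01
    delta0: float | np.ndarray = 0.5
    alpha: float | np.ndarray = 1.0
    beta: float | np.ndarray = 1.0
    epsilon: float = 0.001

    def __post_init__(self) -> None:
        if not (self.alpha0 > 0 and self.beta0 > 0):
            raise ValueError("alpha0, beta0 must be positive")
        if np.any(np.asarray(self.alpha) <= 0) or np.any(np.asarray(self.beta) <= 0):
            raise ValueError("alpha_n, beta_n must be positive")
        d0 = np.asarray(self.delta0, dtype=float)
        if np.any(d0 < 0) or np.any(d0 > 1):
            raise ValueError("delta0 must be in [0, 1]")
        if not 0 < self.epsilon < 0.5:
            raise ValueError("epsilon must be in (0, 0.5)")

    def per_snv(self, n_snvs: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(alpha_n, beta_n, delta0_n) broadcast to length n_snvs."""
        a = np.broadcast_to(np.asarray(self.alpha, dtype=float), (n_snvs,))
        b = np.broadcast_to(np.asarray(self.beta, dtype=float), (n_snvs,))
        d0 = np.broadcast_to(np.asarray(self.delta0, dtype=float), (n_snvs,))
        return a, b, d0


# ---------------------------------------------------------------------------
# Bulk likelihood
# ---------------------------------------------------------------------------


def genotype_set(M: int, m: int) -> list[tuple[int, int]]:
    """Genotypes (v, c) compatible with major/minor copy numbers (M, m).

    The mutation resides on one of the two parental alleles, so the variant
    copy count v ranges over 1..M (major carrier) union 1..m (minor carrier);
    the total copy number is c = M + m.  Genotypes get a uniform prior.
    """
    if M < 1:
        raise ValueError("homozygous deletion (M = 0): locus must be excluded upstream")
    if not 0 <= m <= M:
        raise ValueError("require 0 <= m <= M")
    c = M + m
    vs = sorted(set(range(1, M + 1)) | set(range(1, m + 1)))
    return [(v, c) for v in vs]


def theta(v: int, c: int, phi: float | np.ndarray, epsilon: float) -> float | np.ndarray:
    """Success probability of the bulk binomial for genotype (v, c)."""
    phi = np.asarray(phi, dtype=float)
    if v == 0:
        out = np.full_like(phi, epsilon)
    elif v == c:
        out = phi * (1.0 - epsilon) + (1.0 - phi) * epsilon
    else:
        out = phi * (v / c) + (1.0 - phi) * epsilon
    return out if out.ndim else float(out)


def binom_logpmf(b, d, p):
    b = np.asarray(b, dtype=float)
    d = np.asarray(d, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), 1e-300, 1 - 1e-16)
    coef = gammaln(d + 1) - gammaln(b + 1) - gammaln(d - b + 1)
    return coef + b * np.log(p) + (d - b) * np.log1p(-p)


def bulk_site_loglik(
    b, d, M: int, m: int, phi, epsilon: float = 0.001
) -> float:
    """Log-likelihood of one SNV's bulk counts, genotype-marginalized.

    ``b``, ``d``, ``phi`` may be scalars (single region) or length-R arrays;
    multi-region input returns the sum of the per-region log-likelihoods.
    A region with d = 0 contributes 0.
    """
    b = np.atleast_1d(np.asarray(b, dtype=np.int64))
    d = np.atleast_1d(np.asarray(d, dtype=np.int64))
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    gset = genotype_set(M, m)
    if not gset:
        raise ValueError("empty genotype set")
    # (G, R) matrix of per-genotype, per-region binomial log-pmfs
    terms = np.stack([binom_logpmf(b, d, theta(v, c, phi, epsilon)) for v, c in gset])
    per_region = logsumexp(terms, axis=0) - np.log(len(gset))
    return float(per_region.sum())


class BulkLikelihood:
    """Vectorized genotype-marginalized bulk likelihood over all SNVs.

    Precomputes padded genotype arrays so evaluating the total log-likelihood
    for a full vector of prevalences is a single broadcast expression.
    """

    def __init__(self, bulk: BulkData, epsilon: float = 0.001):
        self.bulk = bulk
        self.epsilon = float(epsilon)
        n = bulk.n_snvs
        gsets = [genotype_set(int(bulk.M[i]), int(bulk.m[i])) for i in range(n)]
        gmax = max(len(g) for g in gsets) if n else 1
        self.gv = np.zeros((n, gmax), dtype=float)
        self.gc = np.ones((n, gmax), dtype=float)
        self.gmask = np.full((n, gmax), -np.inf)
        self.log_gsize = np.zeros(n)
        for i, gs in enumerate(gsets):
            for j, (v, c) in enumerate(gs):
                self.gv[i, j] = v
                self.gc[i, j] = c
                self.gmask[i, j] = 0.0
            self.log_gsize[i] = np.log(len(gs))
        # binomial coefficients, (N, R)
        b, d = bulk.b, bulk.d
        self.logcoef = gammaln(d + 1) - gammaln(b + 1) - gammaln(d - b + 1)

    def site_logliks(self, phi_snv: np.ndarray) -> np.ndarray:
        """Per-SNV log-likelihoods given phi_snv of shape (N, R)."""
        phi = np.asarray(phi_snv, dtype=float)[:, None, :]  # (N, 1, R)
        v = self.gv[:, :, None]
        c = self.gc[:, :, None]
        eps = self.epsilon
        th = np.where(
            v == c,
            phi * (1 - eps) + (1 - phi) * eps,
            phi * (v / c) + (1 - phi) * eps,
        )
        th = np.where(v == 0, eps, th)
        th = np.clip(th, 1e-300, 1 - 1e-16)
        b = self.bulk.b[:, None, :]
        d = self.bulk.d[:, None, :]
        ll = b * np.log(th) + (d - b) * np.log1p(-th)  # (N, G, R)
        # per-region genotype marginalization, then sum over regions
        ll = ll + self.logcoef[:, None, :]
        per_region = logsumexp(ll + self.gmask[:, :, None], axis=1) - self.log_gsize[:, None]
        return per_region.sum(axis=1)

    def region_logliks(self, phi_snv_col: np.ndarray, r: int) -> np.ndarray:
        """Per-SNV log-likelihoods for one region given phi per SNV (length N)."""
        phi = np.asarray(phi_snv_col, dtype=float)[:, None]  # (N, 1)
        v, c = self.gv, self.gc
        eps = self.epsilon
        th = np.where(v == c, phi * (1 - eps) + (1 - phi) * eps, phi * (v / c) + (1 - phi) * eps)
        th = np.where(v == 0, eps, th)
        th = np.clip(th, 1e-300, 1 - 1e-16)
        b = self.bulk.b[:, r : r + 1]
        d = self.bulk.d[:, r : r + 1]
        ll = self.logcoef[:, r : r + 1] + b * np.log(th) + (d - b) * np.log1p(-th)
        return logsumexp(ll + self.gmask, axis=1) - self.log_gsize


# ---------------------------------------------------------------------------
# Single-cell likelihood
# ---------------------------------------------------------------------------


def betabinom_logpmf(b, d, alpha: float, beta: float):
    """Exact log Beta-Binomial pmf (log-gamma form, via scipy)."""
    b_arr = np.asarray(b)
    d_arr = np.asarray(d)
    if np.any(b_arr < 0) or np.any(b_arr > d_arr):
        raise ValueError("require 0 <= b <= d")
    if not (alpha > 0 and beta > 0):
        raise ValueError("alpha, beta must be positive")
    out = _betabinom.logpmf(b_arr, d_arr, alpha, beta)
    return out if out.ndim else float(out)


def scrna_site_loglik(
    b: int,
    d: int,
    mu: int,
    hyper: ScRnaHyperparams,
    alpha_n: float | None = None,
    beta_n: float | None = None,
    delta0_n: float | None = None,
) -> float:
    """Log-likelihood of one (cell, SNV) read-count pair given mutation status.

    mu = 1: Beta-Binomial mixture of the mono-allelic (alpha0, beta0) and
    bi-allelic (alpha_n, beta_n) components with weight delta0 marginalized.
    mu = 0: error model BetaBinomial(d, eps, 1 - eps).  d = 0 gives 0.
    """
    if d == 0:
        return 0.0
    if mu == 0:
        return float(betabinom_logpmf(b, d, hyper.epsilon, 1.0 - hyper.epsilon))
    a_n = float(np.asarray(hyper.alpha).flat[0]) if alpha_n is None else alpha_n
    b_n = float(np.asarray(hyper.beta).flat[0]) if beta_n is None else beta_n
    d0 = float(np.asarray(hyper.delta0).flat[0]) if delta0_n is None else delta0_n
    mono = betabinom_logpmf(b, d, hyper.alpha0, hyper.beta0)
    bi = betabinom_logpmf(b, d, a_n, b_n)
    if d0 <= 0.0:
        return float(mono)
    if d0 >= 1.0:
        return float(bi)
    return float(np.logaddexp(np.log1p(-d0) + mono, np.log(d0) + bi))


def entry_logliks(sc: ScReadMatrix, hyper: ScRnaHyperparams) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (ll_mut, ll_nomut) for every nonzero-depth entry of ``sc``."""
    alpha_n, beta_n, delta0_n = hyper.per_snv(sc.n_snvs)
    a = alpha_n[sc.snv_idx]
    be = beta_n[sc.snv_idx]
    d0 = delta0_n[sc.snv_idx]
    ll0 = _betabinom.logpmf(sc.b, sc.d, hyper.epsilon, 1.0 - hyper.epsilon)
    mono = _betabinom.logpmf(sc.b, sc.d, hyper.alpha0, hyper.beta0)
    bi = _betabinom.logpmf(sc.b, sc.d, a, be)
    with np.errstate(divide="ignore"):
        ll1 = np.logaddexp(np.log1p(-d0) + mono, np.log(d0) + bi)
    ll1 = np.where(d0 <= 0.0, mono, np.where(d0 >= 1.0, bi, ll1))
    zero = sc.d == 0
    ll0 = np.where(zero, 0.0, ll0)
    ll1 = np.where(zero, 0.0, ll1)
    return ll1, ll0


def cell_node_logliks(
    tree: ClonalTree,
    z: Sequence[NodePath],
    sc: ScReadMatrix,
    hyper: ScRnaHyperparams,
) -> tuple[np.ndarray, list[NodePath]]:
    """Matrix L[c, v] = log P(cell c's reads | cell at node v), nodes in
    canonical order.  Only nonzero-depth entries contribute."""
    nodes = tree.nodes
    ll1, ll0 = entry_logliks(sc, hyper)
    diff = ll1 - ll0
    base = np.zeros(sc.n_cells)
    np.add.at(base, sc.cell_idx, ll0)
    L = np.tile(base[:, None], (1, len(nodes)))
    z = [tuple(v) for v in z]
    for j, node in enumerate(nodes):
        mut = np.array([is_ancestor_or_equal(z[s], node) for s in sc.snv_idx], dtype=bool)
        if mut.any():
            np.add.at(L[:, j], sc.cell_idx[mut], diff[mut])
    return L, nodes


def cell_loglik_given_clone(
    cell: int,
    node: NodePath,
    tree: ClonalTree,
    z: Sequence[NodePath],
    sc: ScReadMatrix,
    hyper: ScRnaHyperparams,
) -> float:
    """Log-likelihood of one cell's reads given its clone assignment."""
    node = tuple(node)
    if node not in tree:
        raise ValueError(f"unknown node {node}")
    L, nodes = cell_node_logliks(tree, z, sc, hyper)
    return float(L[cell, nodes.index(node)])


def scrna_loglik_marginal(
    tree: ClonalTree,
    z: Sequence[NodePath],
    sc: ScReadMatrix,
    hyper: ScRnaHyperparams,
) -> float:
    """Single-cell log-likelihood with cell-to-clone assignments marginalized
    under a uniform prior over all |V| nodes (healthy root included).

    Cost is O(C * |V|) plus the sparse entry scatter."""
    if sc.n_cells == 0:
        return 0.0
    L, nodes = cell_node_logliks(tree, z, sc, hyper)
    return float(np.sum(logsumexp(L, axis=1) - np.log(len(nodes))))


# ---------------------------------------------------------------------------
# Joint density
# ---------------------------------------------------------------------------


def log_tssb_assignment_prior(pi: dict[NodePath, float], z: Sequence[NodePath]) -> float:
    """Log prior mass of the SNV assignment under the current stick state."""
    return float(sum(np.log(pi[tuple(v)]) for v in z))


def log_eta_prior(tree: ClonalTree, field_: PrevalenceField) -> float:
    """Log density of a symmetric Dirichlet(1) prior on the clone fractions,
    one independent simplex per region (= log Gamma(|V|) per region)."""
    k = tree.n_nodes
    return float(field_.n_regions * gammaln(k))


def log_joint(
    tree: ClonalTree,
    sticks,
    z: Sequence[NodePath],
    field_: PrevalenceField,
    bulk: BulkData,
    sc: ScReadMatrix | None,
    hyper: ScRnaHyperparams,
) -> float:
    """Unnormalized log posterior density of a full state.

    Returns -inf (rather than raising) on constraint violations so rejected
    states can be scored.
    """
    try:
        field_.validate(tree)
    except ConstraintViolation:
        return -np.inf
    pi, _ = stick_masses(tree, sticks)
    blik = BulkLikelihood(bulk, epsilon=hyper.epsilon)
    phi_snv = np.stack([field_.phi[tuple(v)] for v in z])
    total = float(blik.site_logliks(phi_snv).sum())
    if sc is not None and sc.n_cells > 0:
        total += scrna_loglik_marginal(tree, z, sc, hyper)
    total += log_tssb_assignment_prior(pi, z)
    total += log_eta_prior(tree, field_)
    return total
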