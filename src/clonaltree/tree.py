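"""Clonal tree structure, the tree-structured stick-breaking (TSSB) prior,
and cellular prevalence / clone fraction algebra.

A clonal tree is a rooted tree whose nodes are clones.  The root represents
healthy cells and has exactly one child, the cancer progenitor clone.  Nodes
are addressed by canonical child-index paths: the root is the empty tuple
``()``, the progenitor is ``(0,)``, its second child is ``(0, 1)``, and so on.
Tuple (lexicographic) order of paths equals depth-first preorder of the tree
and is used everywhere ties must be broken reproducibly.

The TSSB prior partitions a unit-length stick over the nodes of an unbounded
tree.  Each node u holds a nu-stick (the fraction of the mass reaching u that
u keeps) and an ordered list of psi-sticks (how the remainder is split among
its children).  With ``upsilon_u`` the mass reaching u,

    pi_u          = nu_u * upsilon_u
    upsilon_{u,k} = (1 - nu_u) * upsilon_u * psi_{u,k} * prod_{j<k}(1 - psi_{u,j})

The child residual uses ``(1 - nu_u)`` so that mass is conserved exactly:
pi_u plus the mass handed to the children plus the unbroken psi remainder
equals upsilon_u.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

NodePath = tuple[int, ...]

ROOT: NodePath = ()
PROGENITOR: NodePath = (0,)


class InvalidStateError(ValueError):
    """Raised when a tree, stick, or prevalence state violates an invariant."""


class ConstraintViolation(ValueError):
    """Raised when prevalences violate the subtree sum constraints."""


def path_str(path: NodePath) -> str:
    """Canonical string label for a node path; the root is ``"r"``."""
    if not path:
        return "r"
    return "r." + ".".join(str(i) for i in path)


def parse_path(label: str) -> NodePath:
    if label == "r":
        return ROOT
    if not label.startswith("r."):
        raise ValueError(f"not a node label: {label!r}")
    return tuple(int(tok) for tok in label.split(".")[1:])


class ClonalTree:
    """Rooted clonal tree with a healthy root that has exactly one child.

    Nodes are stored as a prefix-closed set of child-index paths.  The set of
    nodes is mutable (the sampler lazily grows and prunes the tree) but the
    root/progenitor invariant is always maintained.
    """

    def __init__(self, paths: Iterable[NodePath] = (ROOT, PROGENITOR)):
        self._nodes: set[NodePath] = set(map(tuple, paths))
        self._validate()

    def _validate(self) -> None:
        if ROOT not in self._nodes:
            raise InvalidStateError("tree must contain the healthy root ()")
        for p in self._nodes:
            if p and p[:-1] not in self._nodes:
                raise InvalidStateError(f"node {p} has no parent in the tree")
        root_children = [p for p in self._nodes if len(p) == 1]
        if root_children != [PROGENITOR]:
            raise InvalidStateError(
                "healthy root must have exactly one child, the progenitor (0,)"
            )

    # -- queries ---------------------------------------------------------
    @property
    def nodes(self) -> list[NodePath]:
        """All nodes in canonical (preorder / lexicographic) order."""
        return sorted(self._nodes)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    def __contains__(self, path: NodePath) -> bool:
        return tuple(path) in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def parent(self, path: NodePath) -> NodePath:
        if not path:
            raise ValueError("root has no parent")
        return path[:-1]

    def children(self, path: NodePath) -> list[NodePath]:
        path = tuple(path)
        n = len(path)
        return sorted(p for p in self._nodes if len(p) == n + 1 and p[:n] == path)

    def is_leaf(self, path: NodePath) -> bool:
        return not self.children(path)

    def subtree(self, path: NodePath) -> list[NodePath]:
        path = tuple(path)
        n = len(path)
        return sorted(p for p in self._nodes if p[:n] == path)

    # -- mutation --------------------------------------------------------
    def add_child(self, parent: NodePath) -> NodePath:
        """Append a new child of ``parent`` with the next free index."""
        parent = tuple(parent)
        if parent not in self._nodes:
            raise InvalidStateError(f"parent {parent} not in tree")
        k = len(self.children(parent))
        child = parent + (k,)
        self._nodes.add(child)
        return child

    def add_node(self, path: NodePath) -> None:
        """Add a node (and check the parent exists and indices stay canonical)."""
        path = tuple(path)
        if not path:
            raise InvalidStateError("root always exists")
        if path[:-1] not in self._nodes:
            raise InvalidStateError(f"parent of {path} missing")
        if path[-1] > len(self.children(path[:-1])):
            raise InvalidStateError(f"child index of {path} leaves a gap")
        self._nodes.add(path)

    def pruned(self, keep: set[NodePath]) -> tuple["ClonalTree", dict[NodePath, NodePath]]:
        """Return a new tree restricted to ``keep`` with canonical renumbering.

        ``keep`` must be prefix-closed and contain the root and progenitor.
        Returns the new tree and the old-path -> new-path mapping.
        """
        keep = set(keep) | {ROOT, PROGENITOR}
        mapping: dict[NodePath, NodePath] = {ROOT: ROOT}

        def recurse(old: NodePath, new: NodePath) -> None:
            kept_children = [p for p in self.children(old) if p in keep]
            for j, child in enumerate(kept_children):
                mapping[child] = new + (j,)
                recurse(child, new + (j,))

        recurse(ROOT, ROOT)
        return ClonalTree(mapping.values()), mapping


def is_ancestor_or_equal(u: NodePath, v: NodePath) -> bool:
    """True iff u lies on the path from the root to v (inclusive)."""
    return len(u) <= len(v) and v[: len(u)] == tuple(u)


def is_strict_ancestor(u: NodePath, v: NodePath) -> bool:
    return len(u) < len(v) and v[: len(u)] == tuple(u)


# ---------------------------------------------------------------------------
# TSSB prior
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TssbHyperparams:
    """Hyperparameters of the tree-structured stick-breaking prior.

    lambda0 and lam control depth (nu_u ~ Beta(1, lambda0 * lam**depth(u)),
    depth counted from the progenitor clone); gamma controls width
    (psi_{u,k} ~ Beta(1, gamma)).  Small gamma concentrates mass on the first
    child, favouring chains; gamma = 1 draws psi uniformly.
    """

    lambda0: float = 1.0
    lam: float = 0.5
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not self.lambda0 > 0:
            raise ValueError("lambda0 must be > 0")
        if not 0 < self.lam <= 1:
            raise ValueError("lam must be in (0, 1]")
        if not self.gamma > 0:
            raise ValueError("gamma must be > 0")

    def nu_prior_beta(self, path: NodePath) -> float:
        """Second Beta shape of the nu-stick prior at a cancer node."""
        depth = len(path) - 1  # progenitor has depth 0
        return self.lambda0 * self.lam**depth


@dataclass
class StickState:
    """nu- and psi-sticks for the cancer nodes (paths at or below (0,)).

    Stick values live in (0, 1]; a value of exactly 1 exhausts the stick
    (useful for frozen test fixtures), values outside (0, 1] are invalid.
    """

    nu: dict[NodePath, float] = field(default_factory=dict)
    psi: dict[NodePath, list[float]] = field(default_factory=dict)

    def validate(self) -> None:
        for path, v in self.nu.items():
            if not 0 < v <= 1:
                raise InvalidStateError(f"nu at {path} outside (0, 1]: {v}")
        for path, lst in self.psi.items():
            for k, v in enumerate(lst):
                if not 0 < v <= 1:
                    raise InvalidStateError(f"psi_{k} at {path} outside (0, 1]: {v}")


def stick_masses(
    tree: ClonalTree, sticks: StickState
) -> tuple[dict[NodePath, float], dict[NodePath, float]]:
    """Node masses pi_u and residuals upsilon_u for all cancer nodes.

    upsilon at the progenitor is 1 (the healthy root carries no stick mass).
    """
    sticks.validate()
    pi: dict[NodePath, float] = {}
    upsilon: dict[NodePath, float] = {PROGENITOR: 1.0}

    for u in tree.nodes:
        if not u:
            continue  # healthy root
        if u not in sticks.nu:
            raise InvalidStateError(f"missing nu stick at {u}")
        ups = upsilon[u]
        nu = sticks.nu[u]
        pi[u] = nu * ups
        rem = (1.0 - nu) * ups
        psis = sticks.psi.get(u, [])
        children = tree.children(u)
        if len(psis) < len(children):
            raise InvalidStateError(f"missing psi sticks at {u}")
        carry = 1.0
        for k, child in enumerate(children):
            upsilon[child] = rem * psis[k] * carry
            carry *= 1.0 - psis[k]
    return pi, upsilon


def find_node(
    x: float,
    tree: ClonalTree,
    sticks: StickState,
    hyper: TssbHyperparams,
    rng: np.random.Generator,
    max_depth: int = 100,
) -> NodePath:
    """Map a uniform draw x in [0, 1) to a node of the TSSB partition.

    Missing sticks are drawn lazily from the prior and missing nodes are
    instantiated (mutates ``tree`` and ``sticks``).  The u -> node map sends
    an interval of length pi_u to node u, so a Uniform(0,1) draw lands on u
    with probability pi_u; intervals are ordered by preorder of the tree.
    """
    path = PROGENITOR
    if path not in tree:
        tree.add_node(path)
    for _ in range(max_depth):
        if path not in sticks.nu:
            sticks.nu[path] = float(rng.beta(1.0, hyper.nu_prior_beta(path)))
        nu = sticks.nu[path]
        if x < nu or nu >= 1.0:
            return path
        x = (x - nu) / (1.0 - nu)
        psis = sticks.psi.setdefault(path, [])
        k = 0
        while True:
            if k >= len(psis):
                psis.append(float(rng.beta(1.0, hyper.gamma)))
            psi_k = psis[k]
            if x < psi_k or psi_k >= 1.0:
                x = x / psi_k
                child = path + (k,)
                if child not in tree:
                    # children are instantiated left to right, so no gaps;
                    # every new node gets a nu stick immediately
                    for j in range(len(tree.children(path)), k + 1):
                        sib = path + (j,)
                        tree.add_node(sib)
                        if sib not in sticks.nu:
                            sticks.nu[sib] = float(
                                rng.beta(1.0, hyper.nu_prior_beta(sib))
                            )
                path = child
                break
            x = (x - psi_k) / (1.0 - psi_k)
            k += 1
    raise InvalidStateError("find_node exceeded maximum depth")


def sample_tssb(
    hyper: TssbHyperparams, n_items: int, rng_seed: int | np.random.Generator
) -> tuple[ClonalTree, list[NodePath], StickState]:
    """Draw a tree and item-to-node assignments from the TSSB prior.

    Items land on cancer nodes only (the healthy root carries no stick).
    Deterministic under a fixed seed.
    """
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    tree = ClonalTree()
    sticks = StickState()
    us = rng.uniform(size=n_items)
    z = [find_node(float(u), tree, sticks, hyper, rng) for u in us]
    return tree, z, sticks


# ---------------------------------------------------------------------------
# Prevalence / clone-fraction algebra
# ---------------------------------------------------------------------------

_TOL = 1e-9


@dataclass
class PrevalenceField:
    """Cellular prevalences phi per (node, region), with derived clone fractions.

    phi maps node path -> array of length n_regions.  The healthy root has
    phi = 1 in every region and for every node the children's phi sum to at
    most the node's own phi.
    """

    phi: dict[NodePath, np.ndarray]
    regions: list[str]

    def __post_init__(self) -> None:
        self.phi = {tuple(k): np.atleast_1d(np.asarray(v, dtype=float)) for k, v in self.phi.items()}

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def validate(self, tree: ClonalTree) -> None:
        if set(self.phi) != set(tree.nodes):
            raise ConstraintViolation("phi must be defined for exactly the tree's nodes")
        if not np.allclose(self.phi[ROOT], 1.0):
            raise ConstraintViolation("phi at the healthy root must be 1 in every region")
        for v, arr in self.phi.items():
            if arr.shape != (self.n_regions,):
                raise ConstraintViolation(f"phi at {v} has wrong number of regions")
            if np.any(arr < -_TOL) or np.any(arr > 1 + _TOL):
                raise ConstraintViolation(f"phi at {v} outside [0, 1]")
            kids = tree.children(v)
            if kids:
                ssum = np.sum([self.phi[c] for c in kids], axis=0)
                if np.any(ssum > arr + _TOL):
                    raise ConstraintViolation(
                        f"children prevalences under {path_str(v)} sum to "
                        f"{ssum} > parent {arr}"
                    )


def clone_fractions(
    tree: ClonalTree, field_: PrevalenceField
) -> dict[NodePath, np.ndarray]:
    """Clone fractions eta_u = phi_u - sum of children's phi, per region.

    Validates the sum constraints first; the etas over all nodes sum to one
    per region because phi at the root is one.
    """
    field_.validate(tree)
    eta: dict[NodePath, np.ndarray] = {}
    for v in tree.nodes:
        kids = tree.children(v)
        s = np.sum([field_.phi[c] for c in kids], axis=0) if kids else 0.0
        eta[v] = np.clip(field_.phi[v] - s, 0.0, None)
    return eta


def prevalences_from_fractions(
    tree: ClonalTree, eta: Mapping[NodePath, np.ndarray], regions: Sequence[str]
) -> PrevalenceField:
    """Inverse of :func:`clone_fractions`: phi_v = subtree sum of eta."""
    phi: dict[NodePath, np.ndarray] = {}
    for v in reversed(tree.nodes):  # children before parents
        total = np.atleast_1d(np.asarray(eta[v], dtype=float)).copy()
        for c in tree.children(v):
            total = total + phi[c]
        phi[v] = total
    return PrevalenceField(phi=phi, regions=list(regions))


# ---------------------------------------------------------------------------
# SNV assignment bookkeeping
# ---------------------------------------------------------------------------

def validate_assignment(tree: ClonalTree, z: Sequence[NodePath]) -> None:
    for n, v in enumerate(z):
        v = tuple(v)
        if v == ROOT:
            raise InvalidStateError(f"SNV {n} assigned to the healthy root")
        if v not in tree:
            raise InvalidStateError(f"SNV {n} assigned to unknown node {v}")


def mutation_status(
    tree: ClonalTree, z: Sequence[NodePath], cell_node: NodePath
) -> np.ndarray:
    """Binary vector over SNVs: 1 iff the SNV's clone is ancestral to (or equals)
    the cell's clone.  Cells at the healthy root carry no mutations."""
    cell_node = tuple(cell_node)
    if cell_node not in tree:
        raise ValueError(f"unknown node {cell_node}")
    return np.array(
        [1 if is_ancestor_or_equal(tuple(v), cell_node) else 0 for v in z],
        dtype=np.uint8,
    )


def ancestral_matrix(tree: ClonalTree, z: Sequence[NodePath]) -> np.ndarray:
    """N x N binary matrix with A[i, j] = 1 iff clone of SNV i is a strict
    ancestor of the clone of SNV j.  Co-clustered SNVs get 0 both ways."""
    validate_assignment(tree, z)
    n = len(z)
    a = np.zeros((n, n), dtype=np.uint8)
    for i in range(n):
        zi = tuple(z[i])
        for j in range(n):
            if i != j and is_strict_ancestor(zi, tuple(z[j])):
                a[i, j] = 1
    return a
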