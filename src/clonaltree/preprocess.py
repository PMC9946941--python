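"""SNV filtering and per-locus allelic-imbalance hyperparameter estimation.

SNVs with too little single-cell support carry no co-occurrence signal, so a
locus is kept only if enough cells show enough variant reads (default: at
least two cells with b >= 2; shallow droplet data such as 10X should relax
the read threshold to 1).  The bi-allelic Beta shapes (alpha_n, beta_n) of
the expression mixture are fit per locus from the cells that show both
alleles (0 < b < d): a binomial-noise-corrected method of moments provides
the starting point and a truncated Beta-Binomial maximum-likelihood step
refines it, since the 0 < b < d selection itself truncates the Beta tails
at typical single-cell depths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import betabinom as _betabinom

from .likelihood import BulkData, ScReadMatrix


class NoSnvsRetainedError(ValueError):
    """All SNVs were filtered out; consider 10X mode (min_var_reads=1)."""


@dataclass(frozen=True)
class FilterPolicy:
    """Keep an SNV iff at least ``min_cells`` cells have b >= ``min_var_reads``."""

    min_cells: int = 2
    min_var_reads: int = 2

    def __post_init__(self) -> None:
        if self.min_cells < 1 or self.min_var_reads < 1:
            raise ValueError("filter thresholds must be >= 1")

    @classmethod
    def tenx(cls) -> "FilterPolicy":
        """Relaxed policy for shallow droplet (10X-like) data."""
        return cls(min_cells=2, min_var_reads=1)


def filter_snvs(sc: ScReadMatrix, policy: FilterPolicy = FilterPolicy()) -> list[str]:
    """SNV ids passing the support filter, in the original order."""
    if sc.n_snvs == 0:
        raise ValueError("empty single-cell matrix")
    supporting = sc.b >= policy.min_var_reads
    n_cells_support = np.bincount(sc.snv_idx[supporting], minlength=sc.n_snvs)
    keep = n_cells_support >= policy.min_cells
    retained = [sid for sid, k in zip(sc.snv_ids, keep) if k]
    if not retained:
        raise NoSnvsRetainedError(
            "no SNVs passed the support filter; for shallow data use "
            "FilterPolicy.tenx() (min_var_reads=1)"
        )
    return retained


def subset_snvs(
    bulk: BulkData, sc: ScReadMatrix, snv_ids: list[str]
) -> tuple[BulkData, ScReadMatrix]:
    """Restrict both tables to ``snv_ids`` (order preserved from the list)."""
    bulk_pos = {sid: i for i, sid in enumerate(bulk.snv_ids)}
    missing = [sid for sid in snv_ids if sid not in bulk_pos]
    if missing:
        raise ValueError(f"SNVs absent from bulk table: {missing}")
    bidx = np.array([bulk_pos[sid] for sid in snv_ids])
    new_bulk = BulkData(
        snv_ids=list(snv_ids),
        b=bulk.b[bidx],
        d=bulk.d[bidx],
        M=bulk.M[bidx],
        m=bulk.m[bidx],
        regions=list(bulk.regions),
    )
    sc_pos = {sid: i for i, sid in enumerate(sc.snv_ids)}
    remap = np.full(sc.n_snvs, -1, dtype=np.int64)
    for new_i, sid in enumerate(snv_ids):
        if sid in sc_pos:
            remap[sc_pos[sid]] = new_i
    keep = remap[sc.snv_idx] >= 0
    new_sc = ScReadMatrix(
        cell_ids=list(sc.cell_ids),
        snv_ids=list(snv_ids),
        cell_idx=sc.cell_idx[keep],
        snv_idx=remap[sc.snv_idx[keep]],
        b=sc.b[keep],
        d=sc.d[keep],
    )
    return new_bulk, new_sc


def _moment_start(ratios: np.ndarray, depths: np.ndarray) -> tuple[float, float] | None:
    """Binomial-noise-corrected method-of-moments Beta fit of the variant
    fraction; None when the moments are degenerate or infeasible."""
    mean = float(np.mean(ratios))
    var_obs = float(np.var(ratios))
    if var_obs <= 1e-12:
        return None
    # Var(b/d) = Var(chi) + E[chi (1 - chi)] / d
    inv_d = float(np.mean(1.0 / depths))
    var = (var_obs - mean * (1.0 - mean) * inv_d) / (1.0 - inv_d)
    if var <= 1e-12 or var >= mean * (1.0 - mean):
        return None
    common = mean * (1.0 - mean) / var - 1.0
    alpha, beta = mean * common, (1.0 - mean) * common
    if alpha <= 0 or beta <= 0:
        return None
    return float(alpha), float(beta)


def estimate_bursting(
    sc: ScReadMatrix,
    snv: int,
    fallback: tuple[float, float] = (1.0, 1.0),
    min_informative: int = 3,
) -> tuple[float, float]:
    """Beta shape fit of the bi-allelic variant fraction at one locus.

    Uses cells with 0 < b < d (both alleles seen, so plausibly bi-allelic).
    Because that selection truncates the extremes of the Beta at finite
    depth, the shapes are fit by maximum likelihood of the Beta-Binomial
    truncated to 0 < b < d, initialized from a noise-corrected method of
    moments.  With fewer than ``min_informative`` informative cells, or on a
    degenerate fit, returns the flat fallback.
    """
    sel = (sc.snv_idx == snv) & (sc.b > 0) & (sc.b < sc.d)
    b = sc.b[sel]
    d = sc.d[sel]
    if len(b) < min_informative:
        return fallback
    ratios = b / d
    start = _moment_start(ratios, d) or fallback
    if float(np.var(ratios)) <= 1e-12:
        return fallback

    def nll(log_params: np.ndarray) -> float:
        alpha, beta = np.exp(np.clip(log_params, -8, 8))
        ll = _betabinom.logpmf(b, d, alpha, beta)
        # renormalize over the observable support 0 < b < d
        trunc = 1.0 - _betabinom.pmf(0, d, alpha, beta) - _betabinom.pmf(d, d, alpha, beta)
        if np.any(trunc <= 1e-12):
            return 1e12
        return float(-(ll - np.log(trunc)).sum())

    res = minimize(nll, np.log(start), method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400})
    if not res.success and not np.isfinite(res.fun):
        return start if start != fallback else fallback
    alpha, beta = np.exp(np.clip(res.x, -8, 8))
    if not (np.isfinite(alpha) and np.isfinite(beta)):
        return fallback
    return float(alpha), float(beta)


def estimate_all_bursting(
    sc: ScReadMatrix,
    fallback: tuple[float, float] = (1.0, 1.0),
    min_informative: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """(alpha_n, beta_n) arrays over all SNVs of the matrix."""
    alphas = np.empty(sc.n_snvs)
    betas = np.empty(sc.n_snvs)
    for n in range(sc.n_snvs):
        alphas[n], betas[n] = estimate_bursting(sc, n, fallback, min_informative)
    return alphas, betas
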