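"""On-disk formats: bulk/single-cell count tables, hyperparameters, tree bundles.

All tabular formats are TSV with headers; genomic coordinates are 1-based
(VCF convention).  The single-cell table is long/sparse: absent (cell, SNV)
rows mean zero depth.  Trees are interchanged as a bundle: a newick string
whose node labels are canonical path strings, a sidecar TSV with per-node
metadata (parent, prevalences, clone fractions, SNV ids), and a JSON dump of
the full state; the JSON is the lossless master copy.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .likelihood import BulkData, ScReadMatrix, ScRnaHyperparams
from .tree import (
    ClonalTree,
    NodePath,
    PrevalenceField,
    StickState,
    clone_fractions,
    parse_path,
    path_str,
)

BULK_COLUMNS = [
    "snv_id", "chrom", "pos", "ref", "alt", "region",
    "var_reads", "total_reads", "major_cn", "minor_cn",
]
SC_COLUMNS = ["cell_id", "snv_id", "var_reads", "total_reads"]


class TableFormatError(ValueError):
    """A table violates its schema."""


# ---------------------------------------------------------------------------
# Bulk table
# ---------------------------------------------------------------------------


def read_bulk_table(path: str | Path) -> BulkData:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in BULK_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"bulk table missing columns: {missing}")
    dup = df.duplicated(subset=["snv_id", "region"])
    if dup.any():
        rows = df.loc[dup, ["snv_id", "region"]].values.tolist()
        raise TableFormatError(f"duplicate (snv_id, region) rows: {rows[:5]}")
    bad = df["var_reads"] > df["total_reads"]
    if bad.any():
        raise TableFormatError(
            f"var_reads > total_reads at rows {df.index[bad].tolist()[:5]}"
        )
    if (df["major_cn"] < 1).any():
        raise TableFormatError("major_cn = 0 (homozygous deletion): exclude locus upstream")
    if (df["minor_cn"] > df["major_cn"]).any():
        raise TableFormatError("minor_cn exceeds major_cn")
    if (df["pos"] < 1).any():
        raise TableFormatError("positions must be 1-based")

    snv_ids = list(dict.fromkeys(df["snv_id"]))
    regions = list(dict.fromkeys(df["region"]))
    n, r = len(snv_ids), len(regions)
    sidx = {s: i for i, s in enumerate(snv_ids)}
    ridx = {s: i for i, s in enumerate(regions)}
    b = np.zeros((n, r), dtype=np.int64)
    d = np.zeros((n, r), dtype=np.int64)
    M = np.zeros(n, dtype=np.int64)
    m = np.zeros(n, dtype=np.int64)
    for row in df.itertuples(index=False):
        i, j = sidx[row.snv_id], ridx[row.region]
        b[i, j] = row.var_reads
        d[i, j] = row.total_reads
        M[i] = row.major_cn
        m[i] = row.minor_cn
    return BulkData(snv_ids=snv_ids, b=b, d=d, M=M, m=m, regions=regions)


def write_bulk_table(
    path: str | Path,
    bulk: BulkData,
    chrom: Sequence[str] | None = None,
    pos: Sequence[int] | None = None,
    ref: Sequence[str] | None = None,
    alt: Sequence[str] | None = None,
) -> None:
    n = bulk.n_snvs
    chrom = chrom if chrom is not None else ["1"] * n
    pos = pos if pos is not None else list(range(1, n + 1))
    ref = ref if ref is not None else ["A"] * n
    alt = alt if alt is not None else ["T"] * n
    rows = []
    for i, sid in enumerate(bulk.snv_ids):
        for j, region in enumerate(bulk.regions):
            rows.append(
                (sid, chrom[i], pos[i], ref[i], alt[i], region,
                 int(bulk.b[i, j]), int(bulk.d[i, j]), int(bulk.M[i]), int(bulk.m[i]))
            )
    pd.DataFrame(rows, columns=BULK_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Single-cell table
# ---------------------------------------------------------------------------


def read_sc_table(path: str | Path, bulk: BulkData | None = None) -> ScReadMatrix:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SC_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"single-cell table missing columns: {missing}")
    if df.duplicated(subset=["cell_id", "snv_id"]).any():
        raise TableFormatError("duplicate (cell_id, snv_id) rows")
    if len(df) and (df["var_reads"] > df["total_reads"]).any():
        raise TableFormatError("var_reads > total_reads in single-cell table")
    if bulk is not None:
        unknown = sorted(set(df["snv_id"]) - set(bulk.snv_ids))
        if unknown:
            raise TableFormatError(f"single-cell SNVs absent from bulk table: {unknown[:10]}")
        snv_ids = list(bulk.snv_ids)
    else:
        snv_ids = list(dict.fromkeys(df["snv_id"]))
    cell_ids = list(dict.fromkeys(df["cell_id"]))
    cidx = {s: i for i, s in enumerate(cell_ids)}
    sidx = {s: i for i, s in enumerate(snv_ids)}
    return ScReadMatrix(
        cell_ids=cell_ids,
        snv_ids=snv_ids,
        cell_idx=np.array([cidx[c] for c in df["cell_id"]], dtype=np.int64),
        snv_idx=np.array([sidx[s] for s in df["snv_id"]], dtype=np.int64),
        b=df["var_reads"].to_numpy(np.int64),
        d=df["total_reads"].to_numpy(np.int64),
    )


def write_sc_table(path: str | Path, sc: ScReadMatrix) -> None:
    df = pd.DataFrame(
        {
            "cell_id": [sc.cell_ids[i] for i in sc.cell_idx],
            "snv_id": [sc.snv_ids[i] for i in sc.snv_idx],
            "var_reads": sc.b,
            "total_reads": sc.d,
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Hyperparameter table
# ---------------------------------------------------------------------------


def write_hyperparam_table(
    path: str | Path, snv_ids: Sequence[str], hyper: ScRnaHyperparams
) -> None:
    alpha, beta, delta0 = hyper.per_snv(len(snv_ids))
    pd.DataFrame(
        {"snv_id": list(snv_ids), "alpha": alpha, "beta": beta, "delta0": delta0}
    ).to_csv(path, sep="\t", index=False)


def read_hyperparam_table(
    path: str | Path,
    snv_ids: Sequence[str],
    alpha0: float = 0.01,
    beta0: float = 0.01,
    epsilon: float = 0.001,
) -> ScRnaHyperparams:
    df = pd.read_csv(path, sep="\t").set_index("snv_id")
    missing = [s for s in snv_ids if s not in df.index]
    if missing:
        raise TableFormatError(f"hyperparameter table missing SNVs: {missing[:10]}")
    sub = df.loc[list(snv_ids)]
    return ScRnaHyperparams(
        alpha0=alpha0,
        beta0=beta0,
        delta0=sub["delta0"].to_numpy(float),
        alpha=sub["alpha"].to_numpy(float),
        beta=sub["beta"].to_numpy(float),
        epsilon=epsilon,
    )


# ---------------------------------------------------------------------------
# Tree bundle (newick + sidecar TSV + JSON)
# ---------------------------------------------------------------------------


def tree_to_newick(tree: ClonalTree) -> str:
    def render(node: NodePath) -> str:
        kids = tree.children(node)
        label = path_str(node)
        if not kids:
            return label
        return "(" + ",".join(render(k) for k in kids) + ")" + label

    return render(()) + ";"


_LABEL_RE = re.compile(r"r(?:\.\d+)*")


def newick_to_tree(newick: str) -> ClonalTree:
    labels = _LABEL_RE.findall(newick)
    if not labels:
        raise TableFormatError("no node labels found in newick string")
    return ClonalTree(parse_path(lab) for lab in labels)


def write_tree_bundle(
    prefix: str | Path,
    tree: ClonalTree,
    z: Sequence[NodePath],
    phi_field: PrevalenceField,
    snv_ids: Sequence[str],
    sticks: StickState | None = None,
    log_joint: float | None = None,
) -> None:
    """Write <prefix>.nwk, <prefix>_nodes.tsv and <prefix>.json."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    prefix.with_suffix(".nwk").write_text(tree_to_newick(tree) + "\n")

    eta = clone_fractions(tree, phi_field)
    snvs_by_node: dict[NodePath, list[str]] = {p: [] for p in tree.nodes}
    for sid, p in zip(snv_ids, z):
        snvs_by_node[tuple(p)].append(sid)
    rows = []
    for p in tree.nodes:
        row = {
            "node": path_str(p),
            "parent": path_str(p[:-1]) if p else "",
        }
        for j, region in enumerate(phi_field.regions):
            row[f"phi_{region}"] = float(phi_field.phi[p][j])
            row[f"eta_{region}"] = float(eta[p][j])
        row["snvs"] = ",".join(snvs_by_node[p])
        rows.append(row)
    pd.DataFrame(rows).to_csv(f"{prefix}_nodes.tsv", sep="\t", index=False)

    state = {
        "regions": list(phi_field.regions),
        "snv_ids": list(snv_ids),
        "nodes": [path_str(p) for p in tree.nodes],
        "z": {sid: path_str(p) for sid, p in zip(snv_ids, z)},
        "phi": {path_str(p): [float(x) for x in phi_field.phi[p]] for p in tree.nodes},
        "log_joint": log_joint,
    }
    if sticks is not None:
        state["sticks"] = {
            "nu": {path_str(p): v for p, v in sticks.nu.items()},
            "psi": {path_str(p): list(v) for p, v in sticks.psi.items()},
        }
    prefix.with_suffix(".json").write_text(json.dumps(state, indent=1))


def read_tree_bundle(prefix: str | Path):
    """Read the JSON master copy back; returns (tree, z, phi_field, snv_ids, sticks, log_joint)."""
    prefix = Path(prefix)
    state = json.loads(prefix.with_suffix(".json").read_text())
    tree = ClonalTree(parse_path(s) for s in state["nodes"])
    snv_ids = state["snv_ids"]
    z = [parse_path(state["z"][sid]) for sid in snv_ids]
    phi = {parse_path(k): np.array(v, dtype=float) for k, v in state["phi"].items()}
    field_ = PrevalenceField(phi=phi, regions=state["regions"])
    sticks = None
    if "sticks" in state:
        sticks = StickState(
            nu={parse_path(k): float(v) for k, v in state["sticks"]["nu"].items()},
            psi={parse_path(k): [float(x) for x in v] for k, v in state["sticks"]["psi"].items()},
        )
    return tree, z, field_, snv_ids, sticks, state.get("log_joint")


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(out_dir: str | Path, config: dict, inputs: Sequence[str | Path] = ()) -> None:
    """Record everything needed to reproduce a run: config, seed, input hashes."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config": config,
        "inputs": {str(p): _checksum(Path(p)) for p in inputs},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Optional VCF ingestion
# ---------------------------------------------------------------------------


def read_vcf_sites(path: str | Path) -> pd.DataFrame:
    """Bulk-table skeleton from the PASS biallelic SNV sites of a VCF.

    Returns a frame with the bulk table's identity columns (snv_id, chrom,
    pos, ref, alt) and variant/total read counts taken from the first
    sample's AD field when present (zeros otherwise).  Copy-number columns
    must be joined from a caller's segment file before use.
    """
    from cyvcf2 import VCF

    rows = []
    for rec in VCF(str(path)):
        if rec.FILTER is not None:  # None means PASS in cyvcf2
            continue
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            continue
        var_reads = total_reads = 0
        try:
            ad = rec.format("AD")
            if ad is not None and ad.shape[1] >= 2:
                ref_d, var_d = int(ad[0][0]), int(ad[0][1])
                if ref_d >= 0 and var_d >= 0:
                    var_reads, total_reads = var_d, ref_d + var_d
        except (KeyError, TypeError):
            pass
        rows.append(
            {
                "snv_id": f"{rec.CHROM}_{rec.POS}_{rec.REF}_{rec.ALT[0]}",
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0],
                "region": "R0",
                "var_reads": var_reads,
                "total_reads": total_reads,
            }
        )
    return pd.DataFrame(rows)
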