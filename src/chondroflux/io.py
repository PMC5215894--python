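"""Readers and writers for the pipeline's plain-text formats.

All formats round-trip losslessly; numbers are serialized with 12
significant digits.  Long-format intensity CSV is the native input
(columns sample_id, group, time_min, metabolite_id, intensity); a
wide-format matrix (metabolites x samples) plus a sample-metadata sheet
is accepted and converted.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.cluster import hierarchy

from .accumulation import AccumulationVector, IntensityTable
from .flux_solver import FluxProfile
from .network import StoichiometricNetwork

__all__ = [
    "read_intensity_csv",
    "read_intensity_wide",
    "write_intensity_csv",
    "write_accumulation_csv",
    "write_flux_csv",
    "read_flux_csv",
    "read_fasta",
    "packaged_protein_fasta",
    "write_matrix_csv",
    "linkage_to_newick",
    "write_manifest",
    "file_checksum",
]

_FLOAT_FMT = "%.12g"


def read_intensity_csv(path: str | Path) -> IntensityTable:
    """Read a long-format intensity CSV/TSV (separator sniffed)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep)
        return IntensityTable(df)
    except (ValueError, KeyError) as exc:
        raise ValueError(f"{path}: malformed intensity table: {exc}") from exc


def read_intensity_wide(matrix_path: str | Path, metadata_path: str | Path) -> IntensityTable:
    """Wide-format matrix (rows metabolites, columns sample ids) plus a
    metadata sheet with columns sample_id, group, time_min."""
    wide = pd.read_csv(matrix_path, index_col=0)
    meta = pd.read_csv(metadata_path)
    missing = {"sample_id", "group", "time_min"} - set(meta.columns)
    if missing:
        raise ValueError(f"{metadata_path}: metadata lacks columns {sorted(missing)}")
    meta = meta.set_index("sample_id")
    unknown = set(wide.columns) - set(meta.index)
    if unknown:
        raise ValueError(f"samples without metadata: {sorted(unknown)}")
    long = (wide.rename_axis("metabolite_id").reset_index()
            .melt(id_vars="metabolite_id", var_name="sample_id", value_name="intensity"))
    long["group"] = long["sample_id"].map(meta["group"])
    long["time_min"] = long["sample_id"].map(meta["time_min"])
    return IntensityTable(long)


def write_intensity_csv(table: IntensityTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_accumulation_csv(acc: AccumulationVector, path: str | Path) -> None:
    df = acc.table.copy()
    df["constrained_zero"] = df["constrained_zero"].astype(int)
    df["lowest_weight"] = df["lowest_weight"].astype(int)
    df.to_csv(path, float_format=_FLOAT_FMT)


def write_flux_csv(profile: FluxProfile, net: StoichiometricNetwork, path: str | Path,
                   bound_tol: float = 1e-9) -> None:
    """Flux CSV: reaction_id, pathway, flux, at_bound(0/1)."""
    at_bound = []
    for r, v in zip(net.reactions, profile.v):
        at_bound.append(int((not r.reversible) and v <= bound_tol))
    pd.DataFrame({
        "reaction_id": net.reaction_ids,
        "pathway": [r.pathway for r in net.reactions],
        "flux": profile.v,
        "at_bound": at_bound,
    }).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_flux_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"reaction_id", "flux"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: flux table lacks columns {sorted(missing)}")
    return df


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences keyed by the first header token."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"{path}: no FASTA records")
    return seqs


def packaged_protein_fasta() -> Path:
    """Path to the packaged synthetic stand-in PCM protein sequences
    (composition-realistic surrogates for collagen II/VI, aggrecan, albumin)."""
    return Path(str(resources.files("chondroflux").joinpath(
        "data", "synthetic_pcm_proteins.fasta")))


def write_matrix_csv(net: StoichiometricNetwork, path: str | Path) -> None:
    """Stoichiometric matrix with metabolite-id row labels and reaction-id
    column labels."""
    net.matrix_frame().to_csv(path, float_format=_FLOAT_FMT)


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick tree with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def render(node, parent_height: float) -> str:
        length = _FLOAT_FMT % (parent_height - node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{length}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path: str | Path, entries: dict) -> dict:
    """JSON run manifest; file paths under an 'outputs' key get checksums.
    Returns the enriched manifest dict as written."""
    entries = dict(entries)
    outputs = entries.get("outputs", {})
    entries["outputs"] = {
        name: {"path": str(p), "sha256": file_checksum(p)} for name, p in outputs.items()
    }
    Path(path).write_text(json.dumps(entries, indent=1, sort_keys=True, default=str) + "\n")
    return entries
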