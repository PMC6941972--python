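"""Readers and writers for the package's external formats.

SMILES come in as plain text (one molecule per line) or CSV with a named
``smiles`` column; signatures as delimited numeric tables (rows = samples,
columns = genes).  A reader for L1000-style GCTX matrices (HDF5) is
provided for real landmark-gene data; grammars serialize to the
human-readable one-production-per-line form.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from gexmol.exceptions import ConfigurationError
from gexmol.grammar import GrammarSpec
from gexmol.synthetic import DESCRIPTOR_NAMES, PairedDataset, QuerySignature

__all__ = [
    "read_smiles",
    "write_smiles",
    "read_signatures",
    "write_signatures",
    "read_gctx",
    "write_grammar",
    "read_grammar",
    "write_dataset",
    "read_dataset",
]


def read_smiles(path, column: str = "smiles") -> list[str]:
    """Read SMILES from plain text (one per line) or CSV with a smiles column."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        frame = pd.read_csv(path)
        if column not in frame.columns:
            raise ConfigurationError(f"{path} has no column {column!r}")
        return [str(s) for s in frame[column].dropna()]
    lines = path.read_text().splitlines()
    return [ln.split()[0] for ln in lines if ln.strip() and not ln.startswith("#")]


def write_smiles(path, smiles: list[str]) -> None:
    Path(path).write_text("\n".join(smiles) + "\n")


def read_signatures(path, index_col: int | None = None) -> pd.DataFrame:
    """Numeric signature table: rows = samples, columns = genes."""
    frame = pd.read_csv(path, index_col=index_col)
    non_numeric = [c for c in frame.columns if not np.issubdtype(frame[c].dtype, np.number)]
    if non_numeric:
        raise ConfigurationError(f"non-numeric signature columns: {non_numeric}")
    return frame


def write_signatures(path, signatures: np.ndarray, gene_names: list[str] | None = None) -> None:
    signatures = np.atleast_2d(signatures)
    cols = gene_names or [f"gene_{i}" for i in range(signatures.shape[1])]
    pd.DataFrame(signatures, columns=cols).to_csv(path, index=False)


def read_gctx(path, rids: list[str] | None = None, cids: list[str] | None = None) -> pd.DataFrame:
    """Read an L1000 GCTX matrix (HDF5 layout ``/0/DATA/0/matrix``).

    Returns a DataFrame with row ids (genes) as columns and column ids
    (signatures) as the index, optionally restricted to the given ids.
    """
    import h5py

    with h5py.File(path, "r") as f:
        matrix = f["0/DATA/0/matrix"]
        row_ids = [r.decode() if isinstance(r, bytes) else str(r) for r in f["0/META/ROW/id"][:]]
        col_ids = [c.decode() if isinstance(c, bytes) else str(c) for c in f["0/META/COL/id"][:]]
        data = matrix[:]
    # GCTX stores signatures as columns of shape (n_cols, n_rows)
    frame = pd.DataFrame(data, index=col_ids, columns=row_ids)
    if rids is not None:
        frame = frame.loc[:, [r for r in rids if r in frame.columns]]
    if cids is not None:
        frame = frame.loc[[c for c in cids if c in frame.index]]
    return frame


def write_grammar(path, grammar: GrammarSpec) -> None:
    Path(path).write_text(grammar.to_text())


def read_grammar(path) -> GrammarSpec:
    return GrammarSpec.from_text(Path(path).read_text())


def write_dataset(directory, dataset: PairedDataset) -> None:
    """Write molecules.smi, signatures.csv and queries.csv with target profiles."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_smiles(directory / "molecules.smi", dataset.smiles)
    write_signatures(directory / "signatures.csv", dataset.signatures)
    n_genes = dataset.signatures.shape[1]
    rows = []
    for q in dataset.queries:
        row = {f"gene_{i}": q.signature[i] for i in range(n_genes)}
        row.update({f"target_{n}": v for n, v in zip(DESCRIPTOR_NAMES, q.target_descriptors)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(directory / "queries.csv", index=False)
    meta = {"n_molecules": len(dataset.smiles), "n_genes": n_genes, "n_queries": len(dataset.queries)}
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))


def read_dataset(directory) -> PairedDataset:
    directory = Path(directory)
    smiles = read_smiles(directory / "molecules.smi")
    signatures = read_signatures(directory / "signatures.csv").to_numpy()
    qframe = pd.read_csv(directory / "queries.csv")
    gene_cols = [c for c in qframe.columns if c.startswith("gene_")]
    target_cols = [c for c in qframe.columns if c.startswith("target_")]
    queries = [
        QuerySignature(
            signature=row[gene_cols].to_numpy(dtype=float),
            target_descriptors=row[target_cols].to_numpy(dtype=float),
        )
        for _, row in qframe.iterrows()
    ]
    return PairedDataset(smiles=smiles, signatures=signatures, queries=queries)
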