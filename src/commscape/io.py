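"""Readers and writers for expression matrices, labels and result tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .expression import ExpressionMatrix
from .grouping import CellGrouping


def read_expression(
    matrix_path,
    genes_path=None,
    cells_path=None,
    dialect: str = "matrix_market",
) -> ExpressionMatrix:
    """Read a genes x cells expression matrix.

    ``matrix_market`` expects a sparse triplet .mtx plus one-name-per-line
    gene and cell files; ``tsv`` expects a dense table with gene rows, a
    header of cell names and the gene name in the first column.
    """
    matrix_path = Path(matrix_path)
    if dialect == "matrix_market":
        if genes_path is None or cells_path is None:
            raise ValueError("matrix_market dialect requires genes_path and cells_path")
        m = scipy.io.mmread(matrix_path)
        genes = Path(genes_path).read_text().split()
        cells = Path(cells_path).read_text().split()
        values = sp.csr_matrix(m)
    elif dialect == "tsv":
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
        genes = [str(g) for g in df.index]
        cells = [str(c) for c in df.columns]
        values = df.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return ExpressionMatrix(values=values, gene_names=genes, cell_names=cells)


def write_expression_mtx(expr: ExpressionMatrix, matrix_path, genes_path, cells_path) -> None:
    scipy.io.mmwrite(str(matrix_path), sp.coo_matrix(expr.matrix()))
    Path(genes_path).write_text("\n".join(expr.gene_names) + "\n")
    Path(cells_path).write_text("\n".join(expr.cell_names) + "\n")


def read_labels(path) -> CellGrouping:
    """Two-column TSV (cell, label) -> grouping in file order."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell", "label"], dtype=str)
    return CellGrouping.from_labels(df["label"].to_numpy(), cell_names=df["cell"].tolist())


def write_labels(grouping: CellGrouping, path, cell_names=None) -> None:
    cells = cell_names if cell_names is not None else [f"cell{i}" for i in range(grouping.n)]
    pd.DataFrame({"cell": cells, "label": grouping.labels}).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_embedding(path) -> tuple[list[str], np.ndarray]:
    """TSV (cell, dim1..dimd) -> (cell names, cells x d array)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [str(c) for c in df.index], df.to_numpy(dtype=float)


def tensor_to_frame(ct) -> pd.DataFrame:
    """Long-format table of the communication tensor (one row per entry)."""
    rows = []
    names = ct.grouping.group_names
    for k, pid in enumerate(ct.pair_index):
        for i, src in enumerate(names):
            for j, tgt in enumerate(names):
                rows.append(
                    {
                        "source_group": src,
                        "target_group": tgt,
                        "interaction_id": pid,
                        "pathway": ct.pathway_index[k] if ct.pathway_index else "",
                        "prob": ct.P[i, j, k],
                        "pval": ct.pvals[i, j, k] if ct.pvals is not None else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def network_to_frame(net) -> pd.DataFrame:
    rows = []
    for i, src in enumerate(net.group_names):
        for j, tgt in enumerate(net.group_names):
            rows.append(
                {
                    "source_group": src,
                    "target_group": tgt,
                    "pathway": net.pathway,
                    "weight": net.adjacency[i, j],
                }
            )
    return pd.DataFrame(rows)
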