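"""Optional smoothing of expression by network propagation on a PPI graph.

A random walk with restart diffuses each cell's signaling-gene profile over
a weighted undirected protein-protein interaction network, sharing signal
between interacting genes.  Genes absent from the PPI pass through
unchanged, and each cell's total mass over PPI genes is preserved, so the
transform redistributes rather than creates expression.  Off by default in
the pipeline: the core model is well defined without it.
"""

from __future__ import annotations

import numpy as np

from .expression import ExpressionMatrix


def project_on_ppi(
    expr: ExpressionMatrix,
    ppi_edges: list[tuple[str, str, float]],
    restart_prob: float = 0.5,
) -> ExpressionMatrix:
    """Random walk with restart: f = r (I - (1-r) W)^-1 f0 per cell.

    W is the column-normalized weighted adjacency of the PPI restricted to
    genes present in the matrix.  ``restart_prob`` = 1 is the identity.
    """
    if not 0 < restart_prob <= 1:
        raise ValueError("restart_prob must be in (0, 1]")
    if not ppi_edges or restart_prob == 1.0:
        return expr
    gene_idx = expr.gene_index()
    ppi_genes = sorted(
        {a for a, b, _ in ppi_edges} | {b for a, b, _ in ppi_edges}
    )
    ppi_genes = [g for g in ppi_genes if g in gene_idx]
    if len(ppi_genes) < 2:
        return expr
    pos = {g: i for i, g in enumerate(ppi_genes)}
    m = len(ppi_genes)
    A = np.zeros((m, m))
    for a, b, w in ppi_edges:
        if a in pos and b in pos and a != b:
            A[pos[a], pos[b]] = max(A[pos[a], pos[b]], float(w))
            A[pos[b], pos[a]] = A[pos[a], pos[b]]
    col = A.sum(axis=0)
    W = np.divide(A, col, out=np.zeros_like(A), where=col > 0)
    kernel = restart_prob * np.linalg.inv(np.eye(m) - (1 - restart_prob) * W)
    X = expr.matrix()
    rows = [gene_idx[g] for g in ppi_genes]
    sub = X[rows, :]  # ppi genes x cells
    smoothed = kernel @ sub
    # preserve each cell's total mass over PPI genes
    tot_old = sub.sum(axis=0)
    tot_new = smoothed.sum(axis=0)
    scale = np.divide(tot_old, tot_new, out=np.ones_like(tot_old), where=tot_new > 0)
    smoothed = smoothed * scale
    out = X.copy()
    out[rows, :] = smoothed
    return ExpressionMatrix(out, list(expr.gene_names), list(expr.cell_names))
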