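"""Expression matrix container.

Values are assumed library-normalized and log-transformed upstream, with a
dynamic range compatible with the mass-action model's half-saturation
constant (Kh = 0.5 expects data roughly in [0, 1]).  The container checks
non-negativity and warns when the maximum exceeds a configurable bound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

#: warn when the matrix maximum exceeds this (suggests un-rescaled input)
DEFAULT_RANGE_BOUND = 10.0


@dataclass
class ExpressionMatrix:
    """Genes x cells non-negative expression values with name lists."""

    values: object  # dense ndarray or scipy sparse, genes x cells
    gene_names: list[str]
    cell_names: list[str]
    range_bound: float = field(default=DEFAULT_RANGE_BOUND, repr=False)

    def __post_init__(self):
        n_genes, n_cells = self.shape
        if n_genes != len(self.gene_names):
            raise ValueError(
                f"gene list length {len(self.gene_names)} != matrix rows {n_genes}"
            )
        if n_cells != len(self.cell_names):
            raise ValueError(
                f"cell list length {len(self.cell_names)} != matrix columns {n_cells}"
            )
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValueError("gene names are not unique")
        mn = self.values.min() if not sp.issparse(self.values) else self.values.min()
        if mn < 0:
            if sp.issparse(self.values):
                coo = self.values.tocoo()
                bad = np.argmin(coo.data)
                raise ValueError(
                    f"negative value {coo.data[bad]} at gene {coo.row[bad]}, cell {coo.col[bad]}"
                )
            idx = np.unravel_index(np.argmin(self.values), self.values.shape)
            raise ValueError(f"negative value {self.values[idx]} at {idx}")
        if self.max() > self.range_bound:
            warnings.warn(
                f"matrix maximum {self.max():.3g} exceeds {self.range_bound}; the "
                "mass-action model expects normalized input (roughly [0, 1]); "
                "consider rescale_to_unit()",
                stacklevel=2,
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_genes(self) -> int:
        return self.shape[0]

    @property
    def n_cells(self) -> int:
        return self.shape[1]

    def max(self) -> float:
        return float(self.values.max()) if self.values.size else 0.0

    def matrix(self) -> np.ndarray:
        """Dense genes x cells array."""
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_names)}

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        idx = self.gene_index()
        rows = [idx[g] for g in genes]
        vals = self.values[rows, :]
        return ExpressionMatrix(
            vals,
            [self.gene_names[r] for r in rows],
            list(self.cell_names),
            range_bound=self.range_bound,
        )

    def rescale_to_unit(self) -> "ExpressionMatrix":
        """Divide by the global maximum so values lie in [0, 1]."""
        mx = self.max()
        vals = self.values / mx if mx > 0 else self.values
        return ExpressionMatrix(
            vals, list(self.gene_names), list(self.cell_names), range_bound=self.range_bound
        )
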