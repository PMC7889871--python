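"""Over-expressed signaling gene identification (group-vs-rest Wilcoxon).

The differential-expression step is a permissive pre-filter: an interaction
only enters the probability computation if at least one of its ligand or
receptor subunits is up-regulated somewhere.  Significance of individual
communications is established later by the permutation test, so the raw
0.05 threshold is used without multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .database import LRDatabase
from .expression import ExpressionMatrix
from .grouping import CellGrouping

DEFAULT_ALPHA = 0.05


@dataclass
class DEResult:
    """One-sided rank-sum p-values per (signaling gene, group)."""

    table: pd.DataFrame  # columns: gene, group, p_value, flagged
    alpha: float

    def flagged_genes(self, group: str | None = None) -> set[str]:
        t = self.table[self.table["flagged"]]
        if group is not None:
            t = t[t["group"] == group]
        return set(t["gene"])

    def is_flagged_anywhere(self, gene: str) -> bool:
        return gene in self.flagged_genes()


def identify_overexpressed(
    expr: ExpressionMatrix,
    grouping: CellGrouping,
    db: LRDatabase,
    alpha: float = DEFAULT_ALPHA,
) -> DEResult:
    """One-sided Wilcoxon rank-sum of each group against all other cells.

    Tests only genes shared between the matrix and the database gene
    universe.  Constant genes short-circuit to p = 1 (never flagged).
    """
    if grouping.n_groups < 2:
        raise ValueError("need at least 2 groups for differential expression")
    if np.any(grouping.group_sizes < 2):
        raise ValueError("every group needs at least 2 cells")
    genes = [g for g in expr.gene_names if g in db.gene_universe]
    if not genes:
        raise ValueError("database/matrix gene overlap is empty")
    X = expr.subset_genes(genes).matrix()  # genes x cells
    codes = grouping.codes()
    rows = []
    for gi, gname in enumerate(grouping.group_names):
        in_g = codes == gi
        Xg, Xr = X[:, in_g], X[:, ~in_g]
        const = np.array(
            [np.all(X[r] == X[r, 0]) for r in range(X.shape[0])]
        )
        pvals = np.ones(X.shape[0])
        if np.any(~const):
            res = stats.mannwhitneyu(
                Xg[~const], Xr[~const], alternative="greater", axis=1
            )
            pvals[~const] = res.pvalue
        for r, gene in enumerate(genes):
            rows.append(
                {
                    "gene": gene,
                    "group": gname,
                    "p_value": float(pvals[r]),
                    "flagged": bool(pvals[r] < alpha),
                }
            )
    return DEResult(table=pd.DataFrame(rows), alpha=alpha)


def eligible_interactions(db: LRDatabase, de: DEResult, strictness: str = "any") -> list[str]:
    """Interaction ids passing the DE pre-filter.

    ``any``: at least one ligand or receptor subunit flagged in some group.
    ``all``: every ligand subunit flagged somewhere AND every receptor
    subunit flagged somewhere (stricter variant).
    """
    flagged = de.flagged_genes()
    out = []
    for it in db.interactions:
        subunits = list(it.ligand_subunits) + list(it.receptor_subunits)
        if strictness == "any":
            ok = any(g in flagged for g in subunits)
        elif strictness == "all":
            ok = all(g in flagged for g in it.ligand_subunits) and all(
                g in flagged for g in it.receptor_subunits
            )
        else:
            raise ValueError(f"unknown strictness {strictness!r}")
        if ok:
            out.append(it.id)
    return out
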