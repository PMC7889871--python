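"""Cross-dataset comparison and method-evaluation metrics.

Covers: ranking shared pathways by their change in overall information
flow between two conditions (with on/off/up/down categories), the
multi-subunit false-positive metric for single-gene-pair prediction
tools, and a subsampling harness measuring how stable the inferred
significant communications are when cells are removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .database import LRDatabase
from .expression import ExpressionMatrix
from .grouping import CellGrouping
from .inference import (
    CommunicationTensor,
    InferenceParams,
    SignalingNetwork,
    information_flow,
    permutation_test,
)


def compare_information_flow(
    nets_A: list[SignalingNetwork],
    nets_B: list[SignalingNetwork],
    tol: float = 1e-9,
    rel_tol: float = 0.05,
) -> pd.DataFrame:
    """Rank shared pathways by signed information-flow difference.

    Categories: ``off_in_B`` (flow vanishes in B), ``on_in_B`` (appears in
    B), ``unchanged`` (|difference| within ``rel_tol`` of the larger
    flow), otherwise ``decreased`` / ``increased``.  Pathways present in
    only one condition enter with zero flow in the other.
    """
    flows_A = {n.pathway: information_flow(n) for n in nets_A}
    flows_B = {n.pathway: information_flow(n) for n in nets_B}
    rows = []
    for p in sorted(set(flows_A) | set(flows_B)):
        fa, fb = flows_A.get(p, 0.0), flows_B.get(p, 0.0)
        diff = fa - fb
        if fb <= tol < fa:
            cat = "off_in_B"
        elif fa <= tol < fb:
            cat = "on_in_B"
        elif abs(diff) <= rel_tol * max(fa, fb):
            cat = "unchanged"
        elif diff > 0:
            cat = "decreased"
        else:
            cat = "increased"
        rows.append(
            {"pathway": p, "flow_A": fa, "flow_B": fb, "difference": diff, "category": cat}
        )
    df = pd.DataFrame(rows).sort_values("difference", ascending=False, kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


@dataclass(frozen=True)
class Prediction:
    """One single-gene-pair prediction from an external tool."""

    source_group: str
    target_group: str
    ligand_gene: str
    receptor_gene: str


def partial_complex_fpr(
    predictions: list[Prediction],
    db: LRDatabase,
    denominator: str = "all",
) -> tuple[float, list[Prediction]]:
    """False-positive rate of partially identified multi-subunit complexes.

    A prediction is a false positive when its (ligand, receptor) gene pair
    names some but not all subunit pairs of a multi-subunit interaction in
    the ground-truth database, i.e. the prediction list for the same
    source/target does not cover the complete complex.  ``denominator``
    is "all" predictions or only the "multi_subunit" ones that match some
    multi-subunit interaction.
    """
    if not predictions:
        return 0.0, []
    pred_pairs_by_st: dict[tuple[str, str], set[tuple[str, str]]] = {}
    for p in predictions:
        pred_pairs_by_st.setdefault((p.source_group, p.target_group), set()).add(
            (p.ligand_gene, p.receptor_gene)
        )
    false_positives = []
    n_relevant = 0
    for p in predictions:
        seen = pred_pairs_by_st[(p.source_group, p.target_group)]
        matches = [
            it
            for it in db.interactions
            if it.is_heteromeric
            and p.ligand_gene in it.ligand_subunits
            and p.receptor_gene in it.receptor_subunits
        ]
        if not matches:
            continue
        n_relevant += 1
        complete = any(
            all((lg, rg) in seen for lg in it.ligand_subunits for rg in it.receptor_subunits)
            for it in matches
        )
        if not complete:
            false_positives.append(p)
    denom = len(predictions) if denominator == "all" else max(n_relevant, 1)
    return len(false_positives) / denom, false_positives


def score_edge_sets(
    predicted: set, truth: set, n_tested: int
) -> dict[str, float]:
    """TPR / FPR / ACC of a predicted edge set against a reference set."""
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    tn = n_tested - tp - fp - fn
    tpr = tp / len(truth) if truth else 1.0
    negatives = n_tested - len(truth)
    fpr = fp / negatives if negatives else 0.0
    acc = (tp + tn) / n_tested if n_tested else 1.0
    return {"TPR": tpr, "FPR": fpr, "ACC": acc}


def _stratified_subsample(grouping: CellGrouping, fraction: float, rng) -> np.ndarray:
    keep = []
    for g in grouping.group_names:
        idx = grouping.indices(g)
        m = max(1, int(round(fraction * len(idx))))
        if fraction >= 1.0:
            keep.append(idx)
        else:
            keep.append(rng.choice(idx, size=m, replace=False))
    return np.sort(np.concatenate(keep))


def subsample_robustness(
    expr: ExpressionMatrix,
    grouping: CellGrouping,
    db: LRDatabase,
    params: InferenceParams,
    fractions: list[float] = (0.9, 0.8, 0.7),
    seed: int = 0,
    reference: CommunicationTensor | None = None,
) -> pd.DataFrame:
    """Stability of significant communications under uniform subsampling.

    Cells are subsampled uniformly at random within each group (stratified
    so group proportions are preserved), inference is re-run end to end,
    and the significant (source, target, pair) set is scored against the
    full-data result: TPR = recovered fraction of full-data edges, FPR =
    spurious fraction of the remaining tested entries, ACC = overall
    agreement.
    """
    if reference is None:
        reference = permutation_test(expr, grouping, db, de=None, params=params)
    truth = reference.significant_edges(params.alpha)
    n_tested = reference.P.size
    rng = np.random.default_rng(seed)
    X = expr.matrix()
    rows = []
    for frac in fractions:
        cols = _stratified_subsample(grouping, frac, rng)
        sub_expr = ExpressionMatrix(
            X[:, cols],
            list(expr.gene_names),
            [expr.cell_names[c] for c in cols],
        )
        sub_grouping = CellGrouping(
            labels=grouping.labels[cols],
            group_names=list(grouping.group_names),
        )
        ct = permutation_test(sub_expr, sub_grouping, db, de=None, params=params)
        scores = score_edge_sets(ct.significant_edges(params.alpha), truth, n_tested)
        rows.append({"fraction": frac, **scores})
    return pd.DataFrame(rows)
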