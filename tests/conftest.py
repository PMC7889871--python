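import numpy as np
import pytest

import commscape as cs


@pytest.fixture
def tiny_db():
    """Three interactions incl. a heteromeric receptor and cofactors."""
    return cs.LRDatabase(
        [
            cs.LRInteraction(
                id="tgfb1",
                ligand_subunits=["Tgfb1"],
                receptor_subunits=["Tgfbr1", "Tgfbr2"],
                pathway="TGFb",
                annotation="secreted_signaling",
            ),
            cs.LRInteraction(
                id="wnt1",
                ligand_subunits=["Wnt1"],
                receptor_subunits=["Fzd1"],
                agonists=frozenset({"Rspo1"}),
                antagonists=frozenset({"Dkk1"}),
                pathway="WNT",
                annotation="secreted_signaling",
            ),
            cs.LRInteraction(
                id="col1",
                ligand_subunits=["Col1a1"],
                receptor_subunits=["Itga1"],
                co_stimulatory=frozenset({"Cd44"}),
                pathway="Collagen",
                annotation="ecm_receptor",
            ),
        ]
    )


@pytest.fixture
def planted_dataset():
    """Synthetic grouped expression with 10 planted communications."""
    spec = cs.SyntheticSpec(seed=11)
    spec = cs.plant_edges(spec, 10, effect_size=10.0)
    db = cs.make_database(spec)
    expr, grouping, truth = cs.make_expression(spec, db)
    return spec, db, expr, grouping, truth


def constant_group_expression(levels: dict[str, list[float]], cells_per_group: int = 4):
    """Expression where every cell of a group has a constant value.

    Trimeans then equal those constants exactly, turning the tensor into a
    direct evaluation of the mass-action arithmetic.
    """
    genes = sorted(levels)
    K = len(next(iter(levels.values())))
    n = K * cells_per_group
    X = np.zeros((len(genes), n))
    for r, g in enumerate(genes):
        for k in range(K):
            X[r, k * cells_per_group:(k + 1) * cells_per_group] = levels[g][k]
    labels = np.repeat([f"G{k}" for k in range(K)], cells_per_group)
    expr = cs.ExpressionMatrix(X, genes, [f"c{i}" for i in range(n)])
    grouping = cs.CellGrouping.from_labels(labels)
    return expr, grouping
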