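"""Synthetic ligand-receptor databases and grouped expression matrices.

The generator emulates the data regime the mass-action model consumes:
normalized expression roughly in [0, 1], K cell groups, a database of
interactions across several pathways with a controlled fraction of
multi-subunit receptors and cofactor-bearing pairs, and planted directed
communications in which the ligand genes are elevated in a chosen sender
group and the receptor genes in a chosen receiver group.  Baseline
expression is log-normal noise; dropout is independent Bernoulli zeroing
at a constant rate (the simplest adversarial case for the trimean's
dropout robustness), with an expression-dependent option.  Ground truth
is returned so downstream recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .database import ANNOTATION_CLASSES, LRDatabase, LRInteraction
from .expression import ExpressionMatrix
from .grouping import CellGrouping


@dataclass(frozen=True)
class PlantedEdge:
    pair_id: str
    source_group: str
    target_group: str
    effect_size: float = 10.0  # fold elevation of the planted genes over baseline


@dataclass
class SyntheticSpec:
    """Study conditions for the generator.

    Defaults mirror a small unsorted single-cell experiment: 4 groups of
    50 cells, 50 interactions over 5 pathways, 30% heteromeric receptors,
    20% cofactor-bearing pairs, log-normal baseline centered at 0.1 (so a
    ten-fold planted effect sits near 1.0, the Hill half-saturation
    regime's upper range), and 20% dropout on planted signal.

    ``baseline_expressed_fraction`` controls sparsity: a baseline gene is
    detected in this fraction of cells, the rest being zeros, as in real
    log-normalized single-cell data where most genes are off in most
    cells.  The default 0.15 keeps unexpressed genes below the trimean's
    one-quarter detection threshold, which is exactly the regime the
    robust mean is designed for; set it to 1.0 for a dense continuous
    baseline (e.g. to study permutation calibration).
    """

    n_groups: int = 4
    cells_per_group: int = 50
    n_pairs: int = 50
    n_pathways: int = 5
    frac_heteromeric: float = 0.3
    frac_cofactor: float = 0.2
    planted_edges: list[PlantedEdge] = field(default_factory=list)
    baseline_location: float = 0.1  # median of the log-normal baseline
    baseline_sigma: float = 0.3
    baseline_expressed_fraction: float = 0.15
    dropout: float = 0.2
    dropout_expression_dependent: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.n_pathways < 3:
            raise ValueError("need >= 3 pathways")

    @property
    def group_names(self) -> list[str]:
        return [f"G{i}" for i in range(self.n_groups)]


def plant_edges(
    spec: SyntheticSpec,
    n_edges: int,
    effect_size: float = 10.0,
    rng: np.random.Generator | None = None,
) -> SyntheticSpec:
    """Return a copy of ``spec`` with ``n_edges`` random planted edges.

    Each edge uses a distinct interaction and a random ordered group pair,
    drawn reproducibly from ``spec.seed`` unless ``rng`` is given.
    """
    rng = rng or np.random.default_rng(spec.seed + 7)
    if n_edges > spec.n_pairs:
        raise ValueError("more planted edges than interactions")
    pair_ids = [f"LR{k}" for k in rng.choice(spec.n_pairs, size=n_edges, replace=False)]
    groups = spec.group_names
    edges = []
    for pid in pair_ids:
        i, j = rng.choice(spec.n_groups, size=2, replace=False)
        edges.append(PlantedEdge(pid, groups[i], groups[j], effect_size))
    out = SyntheticSpec(**{**spec.__dict__, "planted_edges": edges})
    return out


def make_database(spec: SyntheticSpec) -> LRDatabase:
    """Synthetic interaction rules realizing the spec's fractions exactly.

    Interaction k is named ``LRk`` with ligand gene ``Lk`` (plus subunit
    ``LkB`` for heteromeric ligands), receptor ``Rk`` (+ ``RkB``), and
    cofactor genes ``AGk``/``ANk``/``CSk``/``CIk`` when assigned.  The
    first round(frac_heteromeric * n) interactions get two receptor
    subunits; cofactor-bearing pairs alternate the four cofactor classes.
    """
    n = spec.n_pairs
    n_het = int(round(spec.frac_heteromeric * n))
    n_cof = int(round(spec.frac_cofactor * n))
    interactions = []
    for k in range(n):
        receptor = [f"R{k}", f"R{k}B"] if k < n_het else [f"R{k}"]
        kwargs = {}
        if k < n_cof:
            kind = ("agonists", "antagonists", "co_stimulatory", "co_inhibitory")[k % 4]
            prefix = {"agonists": "AG", "antagonists": "AN", "co_stimulatory": "CS",
                      "co_inhibitory": "CI"}[kind]
            kwargs[kind] = frozenset({f"{prefix}{k}"})
        interactions.append(
            LRInteraction(
                id=f"LR{k}",
                ligand_subunits=[f"L{k}"],
                receptor_subunits=receptor,
                pathway=f"PW{k % spec.n_pathways}",
                annotation=ANNOTATION_CLASSES[k % len(ANNOTATION_CLASSES)],
                evidence="synthetic",
                **kwargs,
            )
        )
    return LRDatabase(interactions)


def make_expression(
    spec: SyntheticSpec, db: LRDatabase | None = None
) -> tuple[ExpressionMatrix, CellGrouping, list[PlantedEdge]]:
    """Grouped expression with planted ligand/receptor signals.

    Baseline is log-normal around ``baseline_location``.  For each planted
    edge the ligand subunits are scaled by the effect size in the sender
    group's cells, and the receptor subunits (plus any co-stimulatory
    genes of the pair) in the receiver group's cells.  Dropout then zeroes
    entries independently; in the expression-dependent mode the dropout
    probability is scaled by how weakly a value is expressed.  Values are
    clipped to [0, 10].  Edges with effect size <= 1 are not planted and
    are excluded from the returned ground truth.
    """
    db = db or make_database(spec)
    rng = np.random.default_rng(spec.seed)
    genes = sorted(db.gene_universe)
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_cells = spec.n_groups * spec.cells_per_group
    labels = np.repeat(spec.group_names, spec.cells_per_group)
    grouping = CellGrouping(labels=labels, group_names=spec.group_names)

    X = rng.lognormal(
        mean=np.log(spec.baseline_location), sigma=spec.baseline_sigma,
        size=(len(genes), n_cells),
    )
    planted_mask = np.zeros(X.shape, dtype=bool)
    truth = [e for e in spec.planted_edges if e.effect_size > 1.0]
    for edge in truth:
        it = db[edge.pair_id]
        src_cols = grouping.indices(edge.source_group)
        tgt_cols = grouping.indices(edge.target_group)
        for g in it.ligand_subunits:
            X[gene_idx[g], src_cols] *= edge.effect_size
            planted_mask[gene_idx[g], src_cols] = True
        for g in list(it.receptor_subunits) + sorted(it.co_stimulatory):
            X[gene_idx[g], tgt_cols] *= edge.effect_size
            planted_mask[gene_idx[g], tgt_cols] = True

    # detection: planted signal survives at 1 - dropout, baseline is seen
    # only in the expressed fraction of cells
    if spec.dropout_expression_dependent:
        scale = np.clip(1.0 - X / max(X.max(), 1e-12), 0.0, 1.0)
        keep_prob = np.where(
            planted_mask,
            1.0 - spec.dropout * 2 * scale,
            spec.baseline_expressed_fraction,
        )
    else:
        keep_prob = np.where(
            planted_mask, 1.0 - spec.dropout, spec.baseline_expressed_fraction
        )
    X *= rng.random(X.shape) < keep_prob
    np.clip(X, 0.0, 10.0, out=X)

    cells = [f"cell{i}" for i in range(n_cells)]
    expr = ExpressionMatrix(X, genes, cells)
    return expr, grouping, truth
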