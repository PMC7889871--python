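"""Mass-action inference of intercellular communication probabilities.

For a sender group i, receiver group j and ligand-receptor pair k the
communication probability is

    P[i,j,k] = Hill(L_i * R_j)
               * (1 + AG_i/(Kh + AG_i)) * (1 + AG_j/(Kh + AG_j))
               * Kh/(Kh + AN_i) * Kh/(Kh + AN_j)
               * n_i * n_j / n^2                      (optional)

with Hill(x) = x^n / (Kh^n + x^n).  L_i is the geometric mean of the
ligand subunits' trimean expression in group i (zero if any subunit is
unexpressed); R_j is the receptor complex's geometric mean scaled by
(1 + RA_j)/(1 + RI_j), the linear modulation by co-stimulatory /
co-inhibitory receptor means; AG/AN are agonist/antagonist set means
(their factors are 1 when the set is empty).  The population-size factor
n_i n_j / n^2 models the fact that abundant groups collectively send and
receive more signal; it can be disabled for sorting-enriched data.

Significance comes from a label-permutation test: group labels are
shuffled M times, trimeans and the tensor recomputed end to end, and each
entry's p-value is the fraction of permutations whose probability reaches
the observed one (upper tail).  The per-pathway network sums significant
pair probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .database import LRDatabase
from .expression import ExpressionMatrix
from .grouping import CellGrouping
from .markers import DEResult, eligible_interactions

DEFAULT_KH = 0.5
DEFAULT_PERMUTATIONS = 100
DEFAULT_ALPHA = 0.05
DEFAULT_MIN_CELLS = 10


@dataclass
class InferenceParams:
    """Tunable parameters of the mass-action model and permutation test."""

    Kh: float = DEFAULT_KH
    hill_n: float = 1.0
    M: int = DEFAULT_PERMUTATIONS
    alpha: float = DEFAULT_ALPHA
    population_size: bool = True
    seed: int = 0
    min_cells: int = DEFAULT_MIN_CELLS
    de_strictness: str = "any"
    tail: str = "upper"  # "lower" reproduces the printed counting direction

    def __post_init__(self):
        if self.Kh <= 0:
            raise ValueError("Kh must be positive")
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.tail not in ("upper", "lower"):
            raise ValueError("tail must be 'upper' or 'lower'")


@dataclass
class GroupedExpression:
    """Trimean expression per gene per group."""

    EM: np.ndarray  # genes x K
    gene_names: list[str]
    grouping: CellGrouping

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_names)}


@dataclass
class CommunicationTensor:
    """K x K x N probabilities with matched permutation p-values."""

    P: np.ndarray
    pvals: np.ndarray | None
    pair_index: list[str]
    grouping: CellGrouping
    pathway_index: list[str] = field(default_factory=list)

    def significant_mask(self, alpha: float = DEFAULT_ALPHA) -> np.ndarray:
        if self.pvals is None:
            raise ValueError("p-values not computed; run permutation_test first")
        return (self.pvals < alpha) & (self.P > 0)

    def significant_edges(self, alpha: float = DEFAULT_ALPHA) -> set[tuple[str, str, str]]:
        """Set of (source group, target group, interaction id)."""
        mask = self.significant_mask(alpha)
        names = self.grouping.group_names
        out = set()
        for i, j, k in zip(*np.nonzero(mask)):
            out.add((names[i], names[j], self.pair_index[k]))
        return out


@dataclass
class SignalingNetwork:
    """One pathway's K x K weighted directed communication network."""

    pathway: str
    adjacency: np.ndarray
    group_names: list[str]
    pair_ids: list[str] = field(default_factory=list)


def trimean(values) -> float:
    """Tukey's trimean 0.5*Q2 + 0.25*(Q1 + Q3), type-7 quartiles.

    A robust location estimate: it is zero unless a gene is expressed in
    more than a quarter of the cells, which suppresses dropout noise.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("trimean of an empty vector")
    q1, q2, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    return float(0.5 * q2 + 0.25 * (q1 + q3))


def _grouped_trimean(X: np.ndarray, codes: np.ndarray, K: int) -> np.ndarray:
    """Trimean of every row of X within each label group -> genes x K."""
    EM = np.empty((X.shape[0], K))
    for g in range(K):
        cols = codes == g
        if not np.any(cols):
            raise ValueError(f"group {g} has 0 cells")
        q = np.quantile(X[:, cols], [0.25, 0.5, 0.75], axis=1)
        EM[:, g] = 0.5 * q[1] + 0.25 * (q[0] + q[2])
    return EM


def group_expression(expr: ExpressionMatrix, grouping: CellGrouping) -> GroupedExpression:
    """Summarize expression to a trimean per gene per group."""
    if grouping.n != expr.n_cells:
        raise ValueError("grouping does not cover all cells")
    X = expr.matrix()
    EM = _grouped_trimean(X, grouping.codes(), grouping.n_groups)
    return GroupedExpression(EM=EM, gene_names=list(expr.gene_names), grouping=grouping)


def complex_expression(values: dict[str, float], subunits: list[str]) -> float:
    """Geometric mean of subunit expression; 0 if any subunit is 0/missing."""
    vals = np.array([values.get(g, 0.0) for g in subunits], dtype=float)
    if np.any(vals <= 0):
        return 0.0
    return float(np.exp(np.mean(np.log(vals))))


def modulated_receptor(R_core: float, RA_mean: float, RI_mean: float) -> float:
    """Linear co-stimulatory / co-inhibitory modulation of the receptor."""
    return R_core * (1.0 + RA_mean) / (1.0 + RI_mean)


@dataclass
class _ResolvedPair:
    """Gene row indices of one interaction against an EM row order.

    Missing required subunits are flagged (complex forced inactive);
    missing cofactor genes are silently dropped from their mean.
    """

    pair_id: str
    pathway: str
    ligand_rows: np.ndarray
    receptor_rows: np.ndarray
    ligand_complete: bool
    receptor_complete: bool
    agonist_rows: np.ndarray
    antagonist_rows: np.ndarray
    costim_rows: np.ndarray
    coinhib_rows: np.ndarray


def _resolve_pairs(db: LRDatabase, gene_index: dict[str, int], pair_ids: list[str]):
    resolved = []
    missing_subunits = set()
    for pid in pair_ids:
        it = db[pid]
        lig = [gene_index.get(g) for g in it.ligand_subunits]
        rec = [gene_index.get(g) for g in it.receptor_subunits]
        for g, r in zip(list(it.ligand_subunits) + list(it.receptor_subunits), lig + rec):
            if r is None:
                missing_subunits.add(g)
        resolved.append(
            _ResolvedPair(
                pair_id=pid,
                pathway=it.pathway,
                ligand_rows=np.array([r for r in lig if r is not None], dtype=int),
                receptor_rows=np.array([r for r in rec if r is not None], dtype=int),
                ligand_complete=all(r is not None for r in lig),
                receptor_complete=all(r is not None for r in rec),
                agonist_rows=np.array(
                    sorted(gene_index[g] for g in it.agonists if g in gene_index), dtype=int
                ),
                antagonist_rows=np.array(
                    sorted(gene_index[g] for g in it.antagonists if g in gene_index), dtype=int
                ),
                costim_rows=np.array(
                    sorted(gene_index[g] for g in it.co_stimulatory if g in gene_index), dtype=int
                ),
                coinhib_rows=np.array(
                    sorted(gene_index[g] for g in it.co_inhibitory if g in gene_index), dtype=int
                ),
            )
        )
    if missing_subunits:
        warnings.warn(
            f"{len(missing_subunits)} subunit gene(s) absent from the matrix are "
            f"treated as unexpressed (complexes inactivated): "
            f"{sorted(missing_subunits)[:5]}...",
            stacklevel=3,
        )
    return resolved


def _geomean_rows(EM: np.ndarray, rows: np.ndarray, complete: bool) -> np.ndarray:
    """Geometric mean across subunit rows per group; 0 where any is 0."""
    K = EM.shape[1]
    if not complete or len(rows) == 0:
        return np.zeros(K)
    vals = EM[rows, :]  # m x K
    out = np.zeros(K)
    ok = np.all(vals > 0, axis=0)
    if np.any(ok):
        out[ok] = np.exp(np.mean(np.log(vals[:, ok]), axis=0))
    return out


def _mean_rows(EM: np.ndarray, rows: np.ndarray) -> np.ndarray:
    if len(rows) == 0:
        return np.zeros(EM.shape[1])
    return EM[rows, :].mean(axis=0)


def _tensor_from_em(
    EM: np.ndarray,
    resolved: list[_ResolvedPair],
    group_sizes: np.ndarray,
    params: InferenceParams,
) -> np.ndarray:
    """Evaluate the mass-action probability for every (i, j, pair)."""
    K = EM.shape[1]
    n = group_sizes.sum()
    Kh, hn = params.Kh, params.hill_n
    P = np.zeros((K, K, len(resolved)))
    pop = np.outer(group_sizes, group_sizes) / float(n) ** 2 if params.population_size else None
    for k, rp in enumerate(resolved):
        L = _geomean_rows(EM, rp.ligand_rows, rp.ligand_complete)
        R = _geomean_rows(EM, rp.receptor_rows, rp.receptor_complete)
        if len(rp.costim_rows) or len(rp.coinhib_rows):
            RA = _mean_rows(EM, rp.costim_rows)
            RI = _mean_rows(EM, rp.coinhib_rows)
            R = R * (1.0 + RA) / (1.0 + RI)
        LR = np.outer(L, R)
        with np.errstate(divide="ignore", invalid="ignore"):
            x = LR**hn
            slab = x / (Kh**hn + x)
        if len(rp.agonist_rows):
            AG = _mean_rows(EM, rp.agonist_rows)
            ag = 1.0 + AG / (Kh + AG)
            slab = slab * np.outer(ag, ag)
        if len(rp.antagonist_rows):
            AN = _mean_rows(EM, rp.antagonist_rows)
            an = Kh / (Kh + AN)
            slab = slab * np.outer(an, an)
        if pop is not None:
            slab = slab * pop
        P[:, :, k] = slab
    return P


def _active_grouping(grouping: CellGrouping, min_cells: int):
    """Drop groups below the size floor (trimeans unstable for tiny groups)."""
    sizes = grouping.group_sizes
    keep = [g for g, s in zip(grouping.group_names, sizes) if s >= min_cells]
    if len(keep) < len(grouping.group_names):
        dropped = sorted(set(grouping.group_names) - set(keep))
        warnings.warn(
            f"excluding group(s) with fewer than {min_cells} cells: {dropped}",
            stacklevel=3,
        )
        mask = np.isin(grouping.labels, keep)
        sub = CellGrouping(labels=grouping.labels[mask], group_names=keep)
        return sub, mask
    return grouping, np.ones(grouping.n, dtype=bool)


def compute_probability(
    expr: ExpressionMatrix,
    grouping: CellGrouping,
    db: LRDatabase,
    de: DEResult | None = None,
    params: InferenceParams | None = None,
) -> CommunicationTensor:
    """Communication probability tensor from Eq.-of-mass-action scoring.

    ``de`` restricts the tensor to interactions passing the over-expression
    pre-filter; pass None to score every interaction (all eligible).
    """
    params = params or InferenceParams()
    grouping, cell_mask = _active_grouping(grouping, params.min_cells)
    if grouping.n_groups < 2:
        raise ValueError("need at least 2 groups (after the size floor) for inference")
    genes = [g for g in expr.gene_names if g in db.gene_universe]
    if not genes:
        raise ValueError("database/matrix gene overlap is empty")
    sub = expr.subset_genes(genes)
    X = sub.matrix()[:, cell_mask]
    gene_index = {g: i for i, g in enumerate(genes)}
    eligible = (
        eligible_interactions(db, de, params.de_strictness)
        if de is not None
        else [it.id for it in db.interactions]
    )
    all_ids = [it.id for it in db.interactions]
    resolved = _resolve_pairs(db, gene_index, eligible)
    EM = _grouped_trimean(X, grouping.codes(), grouping.n_groups)
    P_eligible = _tensor_from_em(EM, resolved, grouping.group_sizes, params)
    K = grouping.n_groups
    P = np.zeros((K, K, len(all_ids)))
    for slot, pid in enumerate(eligible):
        P[:, :, all_ids.index(pid)] = P_eligible[:, :, slot]
    return CommunicationTensor(
        P=P,
        pvals=None,
        pair_index=all_ids,
        grouping=grouping,
        pathway_index=[db.pathway_of(p) for p in all_ids],
    )


def permutation_test(
    expr: ExpressionMatrix,
    grouping: CellGrouping,
    db: LRDatabase,
    de: DEResult | None = None,
    params: InferenceParams | None = None,
) -> CommunicationTensor:
    """Label-permutation significance for every tensor entry.

    Each permutation shuffles the cell-to-group assignment once and is
    reused for all pairs, preserving cross-pair correlation under the
    null; trimeans and the full probability model are recomputed per
    permutation.  p = #{m : P^(m) >= P_obs} / M (upper tail; the observed
    statistic is not added to the permutation set, so p has resolution
    1/M and can be 0).
    """
    params = params or InferenceParams()
    grouping, cell_mask = _active_grouping(grouping, params.min_cells)
    if grouping.n_groups < 2:
        raise ValueError("need at least 2 groups (after the size floor) for inference")
    genes = [g for g in expr.gene_names if g in db.gene_universe]
    if not genes:
        raise ValueError("database/matrix gene overlap is empty")
    X = expr.subset_genes(genes).matrix()[:, cell_mask]
    gene_index = {g: i for i, g in enumerate(genes)}
    eligible = (
        eligible_interactions(db, de, params.de_strictness)
        if de is not None
        else [it.id for it in db.interactions]
    )
    all_ids = [it.id for it in db.interactions]
    resolved = _resolve_pairs(db, gene_index, eligible)
    codes = grouping.codes()
    K = grouping.n_groups
    sizes = grouping.group_sizes

    EM_obs = _grouped_trimean(X, codes, K)
    P_obs = _tensor_from_em(EM_obs, resolved, sizes, params)

    rng = np.random.default_rng(params.seed)
    counts = np.zeros_like(P_obs)
    for _ in range(params.M):
        perm_codes = rng.permutation(codes)
        EM_m = _grouped_trimean(X, perm_codes, K)
        P_m = _tensor_from_em(EM_m, resolved, sizes, params)
        if params.tail == "upper":
            counts += P_m >= P_obs
        else:
            counts += P_m <= P_obs
    pvals_eligible = counts / params.M

    P = np.zeros((K, K, len(all_ids)))
    pvals = np.ones((K, K, len(all_ids)))
    for slot, pid in enumerate(eligible):
        idx = all_ids.index(pid)
        P[:, :, idx] = P_obs[:, :, slot]
        pvals[:, :, idx] = pvals_eligible[:, :, slot]
    return CommunicationTensor(
        P=P,
        pvals=pvals,
        pair_index=all_ids,
        grouping=grouping,
        pathway_index=[db.pathway_of(p) for p in all_ids],
    )


def aggregate_pathways(
    ct: CommunicationTensor, db: LRDatabase, alpha: float = DEFAULT_ALPHA
) -> list[SignalingNetwork]:
    """Per-pathway networks summing significant pair probabilities.

    Pathways whose adjacency is all zero (no significant communication)
    are dropped.
    """
    mask = ct.significant_mask(alpha)
    nets = []
    for pathway, pair_ids in db.pathways.items():
        ks = [ct.pair_index.index(p) for p in pair_ids if p in ct.pair_index]
        if not ks:
            continue
        adj = (ct.P[:, :, ks] * mask[:, :, ks]).sum(axis=2)
        if np.all(adj == 0):
            continue
        nets.append(
            SignalingNetwork(
                pathway=pathway,
                adjacency=adj,
                group_names=list(ct.grouping.group_names),
                pair_ids=[ct.pair_index[k] for k in ks],
            )
        )
    return nets


def information_flow(net: SignalingNetwork) -> float:
    """Total communication probability over all group pairs."""
    return float(net.adjacency.sum())


def pair_contribution(
    ct: CommunicationTensor, db: LRDatabase, pathway: str, alpha: float = DEFAULT_ALPHA
) -> dict[str, float]:
    """Fraction of a pathway's total flow carried by each of its pairs."""
    mask = ct.significant_mask(alpha)
    pair_ids = db.pathways.get(pathway)
    if not pair_ids:
        raise KeyError(f"unknown pathway {pathway!r}")
    totals = {}
    for pid in pair_ids:
        k = ct.pair_index.index(pid)
        totals[pid] = float((ct.P[:, :, k] * mask[:, :, k]).sum())
    grand = sum(totals.values())
    if grand == 0:
        warnings.warn(f"pathway {pathway!r} has zero flow; contributions are 0", stacklevel=2)
        return {pid: 0.0 for pid in pair_ids}
    return {pid: v / grand for pid, v in totals.items()}
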