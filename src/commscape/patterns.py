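"""Global communication-pattern discovery via non-negative matrix factorization.

The masked probability tensor is collapsed to a role matrix: summing over
targets gives each group's outgoing signal per pathway, summing over
sources the incoming signal.  NMF (min ||Pj - W H||_F, W, H >= 0)
decomposes the role matrix into R latent patterns: W (groups x R) says
which groups act together, H (R x signals) which pathways they use.  The
pattern number is selected where the cophenetic correlation and silhouette
of a consensus over repeated factorizations first drop, mirroring standard
NMF rank-selection practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import silhouette_score

from ._consensus import consensus_matrix, cophenetic_correlation, cut_consensus
from .inference import CommunicationTensor, SignalingNetwork

DEFAULT_RUNS = 10
DEFAULT_PATTERNS = 5
DEFAULT_DROP_TOL = 0.025


@dataclass
class SignalRoleMatrix:
    """Groups x signals matrix of outgoing or incoming communication."""

    values: np.ndarray
    group_names: list[str]
    signal_names: list[str]
    direction: str  # outgoing | incoming


@dataclass
class PatternDecomposition:
    """NMF factors with selection diagnostics."""

    W: np.ndarray  # K x R
    H: np.ndarray  # R x N
    R: int
    group_names: list[str]
    signal_names: list[str]
    direction: str
    reconstruction_error: float
    diagnostics: pd.DataFrame | None = field(default=None, repr=False)


def build_role_matrix(
    source,
    direction: str,
    alpha: float = 0.05,
) -> SignalRoleMatrix:
    """Collapse significant communication onto groups x signals.

    ``source`` is either a CommunicationTensor (signals = interaction
    pairs; only entries significant at ``alpha`` contribute) or a list of
    SignalingNetwork (signals = pathways; the significance mask was
    already applied during aggregation).
    """
    if direction not in ("outgoing", "incoming"):
        raise ValueError("direction must be 'outgoing' or 'incoming'")
    axis = 1 if direction == "outgoing" else 0
    if isinstance(source, CommunicationTensor):
        masked = source.P * source.significant_mask(alpha)
        values = masked.sum(axis=axis)
        return SignalRoleMatrix(
            values=values,
            group_names=list(source.grouping.group_names),
            signal_names=list(source.pair_index),
            direction=direction,
        )
    nets: list[SignalingNetwork] = list(source)
    if not nets:
        raise ValueError("no signaling networks supplied")
    values = np.stack([n.adjacency.sum(axis=axis) for n in nets], axis=1)
    return SignalRoleMatrix(
        values=values,
        group_names=list(nets[0].group_names),
        signal_names=[n.pathway for n in nets],
        direction=direction,
    )


def _drop_zero(Pj: np.ndarray):
    rows = np.flatnonzero(Pj.sum(axis=1) > 0)
    cols = np.flatnonzero(Pj.sum(axis=0) > 0)
    return Pj[np.ix_(rows, cols)], rows, cols


def _nmf_best_of(Pj: np.ndarray, R: int, n_runs: int, seed: int):
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for t in range(n_runs):
            model = NMF(
                n_components=R,
                init="random",
                solver="cd",
                max_iter=5000,
                tol=1e-7,
                random_state=seed + t,
            )
            W = model.fit_transform(Pj)
            if best is None or model.reconstruction_err_ < best[2]:
                best = (W, model.components_, model.reconstruction_err_)
    return best


def nmf_factorize(
    role: SignalRoleMatrix,
    R: int,
    n_runs: int = DEFAULT_RUNS,
    seed: int = 0,
) -> PatternDecomposition:
    """Frobenius NMF, best of ``n_runs`` random initializations.

    Zero rows/columns are removed before factorization and re-inserted
    as all-zero loadings afterwards.
    """
    Pj = np.asarray(role.values, dtype=float)
    core, rows, cols = _drop_zero(Pj)
    if R >= min(core.shape):
        raise ValueError(
            f"R={R} must be < min(non-zero groups, signals) = {min(core.shape)}"
        )
    W_c, H_c, err = _nmf_best_of(core, R, n_runs, seed)
    W = np.zeros((Pj.shape[0], R))
    H = np.zeros((R, Pj.shape[1]))
    W[rows, :] = W_c
    H[:, cols] = H_c
    return PatternDecomposition(
        W=W,
        H=H,
        R=R,
        group_names=role.group_names,
        signal_names=role.signal_names,
        direction=role.direction,
        reconstruction_error=float(err),
    )


def _consensus_metrics(core: np.ndarray, R: int, n_runs: int, seed: int):
    """Cophenetic correlation and silhouette of the run-consensus at rank R."""
    labelings = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for t in range(n_runs):
            # multiplicative updates with a modest iteration budget: rank
            # stability is probed through init-dependence of the solution
            model = NMF(
                n_components=R,
                init="random",
                solver="mu",
                max_iter=200,
                tol=1e-9,
                random_state=seed + t,
            )
            W = model.fit_transform(core)
            labelings.append(np.argmax(W, axis=1))
    C = consensus_matrix(labelings)
    coph = cophenetic_correlation(C)
    labels = cut_consensus(C, R)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    if len(set(labels.tolist())) < 2 or len(set(labels.tolist())) >= len(labels):
        sil = 1.0 if np.allclose(D[np.triu_indices_from(D, 1)], 0) else 0.0
    else:
        sil = float(silhouette_score(D, labels, metric="precomputed"))
    return coph, sil


def select_pattern_number(
    role: SignalRoleMatrix,
    candidate_R: range = range(2, 11),
    n_runs: int = DEFAULT_RUNS,
    seed: int = 0,
    drop_tol: float = DEFAULT_DROP_TOL,
) -> tuple[int, pd.DataFrame]:
    """Pick the pattern number where cophenetic and silhouette first drop.

    Both metrics are tracked against their running maxima over increasing
    R; the selected R is the last candidate before the first R at which
    either falls by more than ``drop_tol`` (the cophenetic correlation of
    a small near-binary consensus is insensitive, so requiring a
    simultaneous drop of both metrics would rarely trigger; a sudden drop
    in either signals redundant patterns).  If no drop occurs the default
    of 5 patterns (clipped to the candidate list) is returned.
    """
    Pj = np.asarray(role.values, dtype=float)
    core, _, _ = _drop_zero(Pj)
    cands = [R for R in candidate_R if R < min(core.shape)]
    if not cands:
        raise ValueError("no feasible candidate pattern numbers for this matrix")
    records = []
    for R in cands:
        coph, sil = _consensus_metrics(core, R, n_runs, seed)
        records.append({"R": R, "cophenetic": coph, "silhouette": sil})
    diag = pd.DataFrame(records)
    run_max_c, run_max_s = -np.inf, -np.inf
    selected = None
    for idx, rec in enumerate(records):
        if idx > 0 and (
            run_max_c - rec["cophenetic"] > drop_tol
            or run_max_s - rec["silhouette"] > drop_tol
        ):
            selected = records[idx - 1]["R"]
            break
        run_max_c = max(run_max_c, rec["cophenetic"])
        run_max_s = max(run_max_s, rec["silhouette"])
    if selected is None:
        fallback = DEFAULT_PATTERNS
        selected = min(cands, key=lambda R: abs(R - fallback))
    return int(selected), diag


def _minmax_rows(M: np.ndarray) -> np.ndarray:
    """Row-wise min-max to [0, 1].

    All-equal non-zero rows map to 1 (documented convention); all-zero
    rows stay 0.
    """
    out = np.zeros_like(M, dtype=float)
    for i in range(M.shape[0]):
        lo, hi = M[i].min(), M[i].max()
        if hi == lo:
            out[i] = 1.0 if hi > 0 else 0.0
        else:
            out[i] = (M[i] - lo) / (hi - lo)
    return out


def threshold_loadings(
    dec: PatternDecomposition, mode: str = "alluvial"
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize and threshold loadings for display tables.

    Rows of W and columns of H are min-max normalized to [0, 1]; entries
    below 0.5 (``alluvial``, one pattern per group/pathway) or 1/R
    (``dotplot``, more permissive) are zeroed.
    """
    if mode == "alluvial":
        cutoff = 0.5
    elif mode == "dotplot":
        cutoff = 1.0 / dec.R
    else:
        raise ValueError("mode must be 'alluvial' or 'dotplot'")
    Wn = _minmax_rows(dec.W)
    Hn = _minmax_rows(dec.H.T).T
    Wn[Wn < cutoff] = 0.0
    Hn[Hn < cutoff] = 0.0
    return Wn, Hn


def contribution_scores(dec: PatternDecomposition) -> np.ndarray:
    """Group-to-pathway contribution scores W H.

    Loadings are multiplied on their original scale, but entries that the
    dot-plot thresholding (min-max normalize, zero below 1/R) removes are
    zeroed first, so only pattern-enriched loadings contribute.
    """
    Wn, Hn = threshold_loadings(dec, mode="dotplot")
    return (dec.W * (Wn > 0)) @ (dec.H * (Hn > 0))
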