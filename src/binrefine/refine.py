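"""Regularized label propagation over the link graph.

The refined edge binning F minimizes a smoothness-plus-fidelity cost: the
quadratic form of the normalized Laplacian of the link graph H (soft bins of
strongly linked edges should agree) plus a per-edge penalty μ_i·‖F_i − Y_i‖²
tying F to the initial binning Y. With α_i = 1/μ_i rescaled into [0, 1], the
minimizer is the fixed point of the damped diffusion

    F ← diag(α) · S · F + diag(1 − α) · Y,    S = D^(−1/2) L D^(−1/2),

where L is the (weighted) adjacency of H and D its degree matrix. α_i = 0
freezes edge i at its initial label; α_i = 1 makes it fully determined by its
neighbors. The iteration is a contraction whenever the labeled part anchors
each component, and converges to the unique solution of
(I − diag(α)S) F = diag(1 − α) Y.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp

from binrefine.edge_binning import EdgeBinning
from binrefine.graph_io import AssemblyGraph

logger = logging.getLogger(__name__)

PROPAGATION = "propagation"
CORRECTION = "correction"


@dataclass
class RefineConfig:
    """Knobs of the refinement pipeline.

    mode: "propagation" preserves initial labels (α=0 on binned unique
        edges) and only fills unbinned ones; "correction" lets labels be
        revised (α=alpha_default on binned edges).
    alpha_default: α for binned edges ≥ length_threshold in correction mode.
    length_threshold: bp below which α tapers linearly up to 1 at length 1 —
        short edges are likely unresolved repeats whatever the binner said.
    tolerance / max_iterations: stopping rule (max-abs entry change).
    sparse: enable sparse-binning mode (distance-damped propagation).
    distance_threshold: bp; edges farther than this from any labeled edge are
        "distant" in sparse mode.
    kmer_size: k for the unique-k-mer read aligner.
    reassembly_threshold: minimal normalized weight t for an edge to support
        a bin during read extraction.
    multiple_coverage: cumulative score fraction for multiple assignment.
    """

    mode: str = PROPAGATION
    alpha_default: float = 0.6
    length_threshold: int = 1000
    tolerance: float = 1e-5
    max_iterations: int = 100
    sparse: bool = False
    distance_threshold: float = 10_000.0
    kmer_size: int = 31
    reassembly_threshold: float = 0.1
    multiple_coverage: float = 0.95
    strategy: str = "max-likelihood"
    multiple: bool = False

    def __post_init__(self) -> None:
        if self.mode not in (PROPAGATION, CORRECTION):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 <= self.alpha_default <= 1.0:
            raise ValueError("alpha_default must be in [0, 1]")
        for name in ("length_threshold", "tolerance", "max_iterations", "distance_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class RefineReport:
    converged: bool
    iterations: int
    final_delta: float


class SingularSystemError(np.linalg.LinAlgError):
    """The fixed-point system is unconstrained (an all-α=1 component with no
    label source has no unique solution)."""


def correction_alpha(length: int, config: RefineConfig) -> float:
    """α(ℓ) schedule for binned edges in correction mode: alpha_default for
    ℓ ≥ length_threshold, rising linearly to 1 at ℓ = 1."""
    if length >= config.length_threshold:
        return config.alpha_default
    span = config.length_threshold - 1
    return 1.0 - (1.0 - config.alpha_default) * (length - 1) / span


def regularization_parameters(
    graph: AssemblyGraph,
    Y: EdgeBinning,
    repetitive: set[str],
    config: RefineConfig,
) -> np.ndarray:
    """Per-edge α vector.

    Repetitive edges (≥2 scaffold-path occurrences) always get α=1: their
    single scaffold label is unreliable, and the propagated result may keep
    several bins. Unbinned edges get α=1 (nothing to preserve). Binned unique
    edges get α=0 in propagation mode, and the length-tapered schedule in
    correction mode.
    """
    alpha = np.ones(len(Y.segment_ids))
    for i, seg in enumerate(Y.segment_ids):
        if seg in repetitive or not Y.binned[i]:
            continue
        if config.mode == PROPAGATION:
            alpha[i] = 0.0
        else:
            alpha[i] = correction_alpha(graph.segments[seg].length, config)
    return alpha


def propagation_operator(H: nx.Graph, nodelist: list[str]) -> sp.csr_array:
    """Symmetric normalized similarity S = D^(−1/2) L D^(−1/2) of H.

    Self-loops are removed before normalization (they contribute nothing to
    between-edge propagation); isolated nodes get zero rows.
    """
    W = nx.to_scipy_sparse_array(H, nodelist=nodelist, weight="weight", format="csr")
    W = W.tolil()
    W.setdiag(0.0)
    W = W.tocsr()
    W.eliminate_zeros()
    deg = np.asarray(W.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        dinv = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    D = sp.diags_array(dinv)
    return (D @ W @ D).tocsr()


def refine_iterate(
    S: sp.csr_array,
    Y: np.ndarray,
    alpha: np.ndarray,
    config: RefineConfig,
    frozen_column: int | None = None,
) -> tuple[np.ndarray, RefineReport]:
    """Iterate F ← diag(α)·S·F + diag(1−α)·Y from F(0)=Y to convergence.

    ``frozen_column`` (used by sparse mode) names a column whose values are
    zeroed in the neighbor-aggregation term each iteration, so that label can
    be held but never propagated.

    Stops when the max-abs entry change drops below ``config.tolerance`` or
    after ``config.max_iterations`` (then a warning is logged and the report
    is flagged unconverged).
    """
    Y = np.asarray(Y, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    F = Y.copy()
    hold = (1.0 - alpha)[:, None] * Y
    a = alpha[:, None]
    delta = np.inf
    it = 0
    for it in range(1, config.max_iterations + 1):
        prop = F if frozen_column is None else _mask_column(F, frozen_column)
        F_next = a * (S @ prop) + hold
        delta = float(np.max(np.abs(F_next - F))) if F.size else 0.0
        F = F_next
        if delta < config.tolerance:
            return F, RefineReport(True, it, delta)
    logger.warning(
        "refinement did not converge in %d iterations (last delta %.3g)",
        config.max_iterations,
        delta,
    )
    return F, RefineReport(False, it, delta)


def _mask_column(F: np.ndarray, col: int) -> np.ndarray:
    masked = F.copy()
    masked[:, col] = 0.0
    return masked


def solve_fixed_point(S: sp.csr_array, Y: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Dense direct solve of (I − diag(α)S) F = diag(1−α) Y.

    Exact fixed point of the iteration; intended as an oracle for small
    instances (≤ a few thousand nodes).
    """
    n = Y.shape[0]
    A = np.eye(n) - alpha[:, None] * np.asarray(S.todense())
    b = (1.0 - alpha)[:, None] * np.asarray(Y, dtype=float)
    try:
        F = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as err:
        raise SingularSystemError(
            "fixed-point system is singular: a fully free (α=1) component "
            "has no label source"
        ) from err
    return F


def refine(
    H: nx.Graph,
    Y: EdgeBinning,
    alpha: np.ndarray,
    config: RefineConfig,
) -> tuple[EdgeBinning, RefineReport]:
    """Standard-mode refinement: returns F̃ as an EdgeBinning plus a report."""
    S = propagation_operator(H, Y.segment_ids)
    F, report = refine_iterate(S, Y.matrix, alpha, config)
    return Y.with_matrix(F), report
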