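"""Bin-overlap distances from the soft binning via the prob-Jaccard index.

Each bin's column of the refined matrix, normalized to sum 1, is a
probability distribution over assembly-graph edges. The prob-Jaccard index

    J_p(c, d) = Σ_{i: p_i(c)>0, p_i(d)>0} ( Σ_j max(p_j(c)/p_i(c), p_j(d)/p_i(d)) )^(-1)

is a fuzzy-set generalization of the Jaccard index: scale-invariant, equal to
1 iff the distributions coincide, 0 on disjoint supports, and 1 − J_p is a
proper metric, so the exported distance matrix can feed hierarchical
clustering without tree inversions. Overlapping bins (shared or contaminated
MAGs) show up as small distances.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from binrefine.edge_binning import EdgeBinning


def bin_distributions(refined: EdgeBinning) -> tuple[list[str], np.ndarray]:
    """Column-normalized edge distributions, one per nonempty bin.

    Returns (kept bin labels, matrix with one column per kept bin summing
    to 1). All-zero columns (empty bins) are excluded.
    """
    M = refined.matrix
    sums = M.sum(axis=0)
    keep = sums > 0
    labels = [b for b, k in zip(refined.bins, keep) if k]
    P = M[:, keep] / sums[keep]
    return labels, P


def prob_jaccard(p: np.ndarray, q: np.ndarray) -> float:
    """Prob-Jaccard similarity of two distributions over the same support
    universe; in [0, 1]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    both = (p > 0) & (q > 0)
    if not both.any():
        return 0.0
    # for each i in the common support: inner_i = sum_j max(p_j/p_i, q_j/q_i)
    ratios_p = p[None, :] / p[both, None]
    ratios_q = q[None, :] / q[both, None]
    inner = np.maximum(ratios_p, ratios_q).sum(axis=1)
    return float(np.sum(1.0 / inner))


def distance_matrix(refined: EdgeBinning) -> pd.DataFrame:
    """Symmetric 1 − J_p distance matrix over all nonempty bins."""
    labels, P = bin_distributions(refined)
    if len(labels) < 2:
        raise ValueError("need at least two nonempty bins for a distance matrix")
    m = len(labels)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            d = 1.0 - prob_jaccard(P[:, i], P[:, j])
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=labels, columns=labels)


def write_distance_matrix(refined: EdgeBinning, path: str | Path) -> None:
    distance_matrix(refined).to_csv(path)
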