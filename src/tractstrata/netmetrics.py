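"""Weighted graph topology: characteristic path length, clustering,
local and global efficiency.

Conventions (fixed so every number is oracle-testable):

* edge distance d(i,j) = 1 / w(i,j) for w > 0, infinite otherwise
  (``distance="log"`` uses d = -log(w / w_max) for weights in (0, 1]);
* characteristic (shortest) path length Lp = mean shortest distance over
  *connected* ordered node pairs, with disconnected pairs counted
  separately rather than folded into the mean;
* global efficiency Eglob = mean of 1/d over all ordered pairs,
  disconnected pairs contributing 0 (Latora-Marchiori);
* clustering coefficient Cp = mean over nodes of the Onnela geometric-mean
  triangle intensity on weights normalized by the maximum weight;
* local efficiency Eloc = mean over nodes of Eglob of the subgraph induced
  by each node's neighbors; nodes with fewer than two neighbors
  contribute 0 to both Cp and Eloc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .datamodel import ValidationError


@dataclass
class NetworkMetrics:
    shortest_path_length: float   # Lp
    clustering_coefficient: float  # Cp
    local_efficiency: float       # Eloc
    global_efficiency: float      # Eglob
    disconnected_pair_count: int


def _check_weights(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValidationError(f"weight matrix must be square, got {W.shape}")
    if not np.allclose(W, W.T, rtol=0, atol=1e-12 * max(1.0, np.abs(W).max())):
        raise ValidationError("weight matrix must be symmetric")
    if (W < 0).any():
        raise ValidationError("weight matrix must be nonnegative")
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 0.0)
    return W


def _distance_matrix(W: np.ndarray, distance: str) -> np.ndarray:
    D = np.full_like(W, np.inf)
    pos = W > 0
    if distance == "inverse":
        D[pos] = 1.0 / W[pos]
    elif distance == "log":
        wmax = W.max()
        if wmax <= 0:
            return D
        # -log(w/wmax) is 0 on the strongest edge; shift epsilon keeps it positive
        D[pos] = -np.log(W[pos] / wmax) + 1e-12
    else:
        raise ValidationError(f"unknown distance transform {distance!r}")
    np.fill_diagonal(D, np.inf)
    return D


def _efficiency_terms(W: np.ndarray, distance: str) -> tuple[float, float, int]:
    """(mean connected distance, mean inverse distance, #disconnected pairs)."""
    n = W.shape[0]
    if n < 2:
        return 0.0, 0.0, 0
    D = _distance_matrix(W, distance)
    SP = shortest_path(D, method="D", directed=False)
    off = ~np.eye(n, dtype=bool)
    d = SP[off]
    finite = np.isfinite(d)
    n_disc = int((~finite).sum())
    lp = float(d[finite].mean()) if finite.any() else 0.0
    inv = np.where(finite, 1.0 / np.where(finite, d, 1.0), 0.0)
    eglob = float(inv.mean())
    return lp, eglob, n_disc


def _onnela_clustering(W: np.ndarray) -> float:
    """Mean Onnela weighted clustering; weights scaled by the global max."""
    wmax = W.max()
    if wmax <= 0:
        return 0.0
    Wn = np.cbrt(W / wmax)
    triangles = np.diagonal(Wn @ Wn @ Wn)  # 2 * sum of cyclic triangle intensities
    k = (W > 0).sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, triangles / np.where(denom > 0, denom, 1), 0.0)
    return float(c.mean())


def network_metrics(
    W: np.ndarray,
    weight_mode: str = "max_normalized",
    distance: str = "inverse",
) -> NetworkMetrics:
    """Compute the four global topology metrics of a weighted network.

    ``weight_mode="max_normalized"`` (default) rescales weights by the
    maximum before the distance transform, which bounds Eglob and Eloc by 1
    and makes metrics comparable across subjects with different total
    streamline counts; ``"raw"`` uses the weights as given. The clustering
    coefficient is always computed on max-normalized weights, so it is
    identical under both modes.
    """
    W = _check_weights(W)
    if weight_mode not in ("raw", "max_normalized"):
        raise ValidationError(f"unknown weight_mode {weight_mode!r}")
    n = W.shape[0]
    if not (W > 0).any():
        return NetworkMetrics(0.0, 0.0, 0.0, 0.0, n * (n - 1))
    Wd = W / W.max() if weight_mode == "max_normalized" else W

    lp, eglob, n_disc = _efficiency_terms(Wd, distance)
    cp = _onnela_clustering(W)

    # local efficiency: Eglob of each node's neighbor-induced subgraph
    eloc_terms = np.zeros(n)
    adj = Wd > 0
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        if nbrs.size < 2:
            continue
        sub = Wd[np.ix_(nbrs, nbrs)]
        _, e_sub, _ = _efficiency_terms(sub, distance)
        eloc_terms[i] = e_sub
    return NetworkMetrics(
        shortest_path_length=lp,
        clustering_coefficient=cp,
        local_efficiency=float(eloc_terms.mean()),
        global_efficiency=eglob,
        disconnected_pair_count=n_disc,
    )


def threshold_by_sparsity(
    C: np.ndarray, sparsity: float, binarize: bool = True
) -> np.ndarray:
    """Keep the strongest positive edges of a (functional) correlation matrix.

    Retains the top ``ceil(sparsity * n(n-1)/2)`` positive upper-triangle
    entries and zeroes everything else; negative correlations are never
    retained. Ties at the cutoff break deterministically by (i, j) index
    order. With ``binarize`` kept weights become 1.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValidationError(f"matrix must be square, got {C.shape}")
    if not np.allclose(C, C.T, rtol=0, atol=1e-9 * max(1.0, np.abs(C).max())):
        raise ValidationError("matrix must be symmetric")
    if not (0 < sparsity <= 1):
        raise ValidationError(f"sparsity must be in (0, 1], got {sparsity}")
    n = C.shape[0]
    iu = np.triu_indices(n, 1)
    vals = C[iu]
    k = int(np.ceil(sparsity * n * (n - 1) / 2))
    pos = np.flatnonzero(vals > 0)
    # stable sort on -value keeps earlier (i, j) pairs on ties
    order = pos[np.argsort(-vals[pos], kind="stable")]
    keep = order[:k]
    W = np.zeros_like(C)
    rows, cols = iu[0][keep], iu[1][keep]
    W[rows, cols] = 1.0 if binarize else vals[keep]
    W = W + W.T
    return W
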