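"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — explicit Floyd-Warshall triple
loops and per-node triangle enumeration — and shares no code with the
package implementation it checks.
"""

from __future__ import annotations

import numpy as np


def floyd_warshall(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    dist = D.copy()
    np.fill_diagonal(dist, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                via = dist[i, k] + dist[k, j]
                if via < dist[i, j]:
                    dist[i, j] = via
    return dist


def _pair_terms(W: np.ndarray) -> tuple[float, float, int]:
    n = W.shape[0]
    D = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(n):
            if i != j and W[i, j] > 0:
                D[i, j] = 1.0 / W[i, j]
    sp = floyd_warshall(D)
    dists, inv, disc = [], [], 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if np.isfinite(sp[i, j]):
                dists.append(sp[i, j])
                inv.append(1.0 / sp[i, j])
            else:
                disc += 1
                inv.append(0.0)
    lp = float(np.mean(dists)) if dists else 0.0
    eglob = float(np.mean(inv)) if inv else 0.0
    return lp, eglob, disc


def oracle_metrics(W: np.ndarray, weight_mode: str = "max_normalized") -> dict:
    """Reference values for the four global topology metrics."""
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if not (W > 0).any():
        return dict(
            shortest_path_length=0.0, clustering_coefficient=0.0,
            local_efficiency=0.0, global_efficiency=0.0,
            disconnected_pair_count=n * (n - 1),
        )
    Wd = W / W.max() if weight_mode == "max_normalized" else W

    lp, eglob, disc = _pair_terms(Wd)

    # Onnela clustering on globally max-normalized weights
    Wn = W / W.max()
    cs = []
    for i in range(n):
        nbrs = [j for j in range(n) if W[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            cs.append(0.0)
            continue
        s = 0.0
        for j in nbrs:
            for h in nbrs:
                if j != h and W[j, h] > 0:
                    s += (Wn[i, j] * Wn[i, h] * Wn[j, h]) ** (1.0 / 3.0)
        cs.append(s / (k * (k - 1)))
    cp = float(np.mean(cs))

    # local efficiency: Eglob of each neighbor-induced subgraph
    es = []
    for i in range(n):
        nbrs = [j for j in range(n) if Wd[i, j] > 0]
        if len(nbrs) < 2:
            es.append(0.0)
            continue
        sub = Wd[np.ix_(nbrs, nbrs)]
        _, e_sub, _ = _pair_terms(sub)
        es.append(e_sub)
    eloc = float(np.mean(es))

    return dict(
        shortest_path_length=lp, clustering_coefficient=cp,
        local_efficiency=eloc, global_efficiency=eglob,
        disconnected_pair_count=disc,
    )


def random_test_graph(rng: np.random.Generator, n: int, binary: bool) -> np.ndarray:
    """Random symmetric nonnegative weight matrix with zero diagonal."""
    A = rng.random((n, n)) < rng.uniform(0.2, 0.8)
    A = np.triu(A, 1)
    W = A.astype(float)
    if not binary:
        W *= rng.uniform(0.1, 5.0, (n, n))
    W = W + W.T
    np.fill_diagonal(W, 0.0)
    return W


def stratified_summary_oracle(triplet, mask_labels: np.ndarray) -> dict:
    """Per-edge loop recomputation of the class FN sums and FA means."""
    n = triplet.n_nodes
    fn = {0: 0.0, 1: 0.0, 2: 0.0}
    fa = {0: [], 1: [], 2: []}
    for i in range(n):
        for j in range(i + 1, n):
            if triplet.fn[i, j] <= 0:
                continue
            lab = int(mask_labels[i, j])
            if lab < 0:
                continue
            fn[lab] += triplet.fn[i, j]
            fa[lab].append(triplet.fa[i, j])
    out = {}
    for code, name in ((0, "short"), (1, "middle"), (2, "long")):
        out[f"fn_{name}"] = fn[code]
        out[f"fa_{name}"] = float(np.mean(fa[code])) if fa[code] else None
    out["fn_total"] = sum(fn.values())
    return out
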