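"""Weighted network measures with surrogate normalization.

The full PLI matrix is treated as a complete weighted graph on the 16
electrode nodes.  Two absolute measures are computed:

* **average weighted clustering** ``C``: per node,
  ``C_i = Σ_{k≠l} w_ik w_il w_kl / Σ_{k≠l} w_ik w_il`` over ordered
  neighbor pairs ``k ≠ l ≠ i`` (triple-product weighted clustering);
  the node average is reported.  A node with fewer than two nonzero
  weights has ``C_i = 0``.
* **average weighted path length** ``L``: edge length is the inverse
  weight ``1/w`` (infinite for ``w = 0``); ``L`` is the mean
  shortest-path length over the 120 unordered node pairs.  Any
  unreachable pair makes ``L`` infinite (flagged upstream), which for
  PLI input only signals pathological data.

Because both measures depend on network density, they are normalized
by surrogate networks: each surrogate redistributes the 120
upper-triangle weights uniformly at random over the edge slots
(re-symmetrized), preserving density and the weight distribution
exactly.  ``rC = C / <C_surr>``, ``rL = L / <L_surr>`` over 50
surrogates by default, and the small-world index is ``SWI = rC / rL``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .connectivity import ConnectivityMatrix

DEFAULT_N_SURROGATES = 50

#: recorded in output metadata: the clustering/path-length conventions
WEIGHTED_CONVENTIONS = {
    "clustering": "triple-product weighted clustering "
                  "C_i = sum w_ik w_il w_kl / sum w_ik w_il (k != l != i)",
    "path_length": "Dijkstra on edge lengths 1/w; mean over unordered pairs",
    "surrogates": "uniform random permutation of upper-triangle weights",
}


@dataclass
class WeightedMetrics:
    """Weighted-network summary for one connectivity matrix."""

    pli_mean: float
    C_abs: float
    L_abs: float
    rC: float
    rL: float
    SWI: float
    n_surrogates: int = DEFAULT_N_SURROGATES
    seed: int | None = None

    def as_dict(self) -> dict[str, float]:
        return {"pli_mean": self.pli_mean, "C_abs": self.C_abs,
                "L_abs": self.L_abs, "rC": self.rC, "rL": self.rL,
                "SWI": self.SWI}


def _check_weights(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("weight matrix must be symmetric")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    return w


def weighted_clustering(cm: ConnectivityMatrix | np.ndarray):
    """Per-node triple-product weighted clustering and its average.

    Returns ``(per_node, average)``.  For a matrix with all weights
    equal to ``w`` the ratio collapses to ``w`` for every node.
    """
    w = _check_weights(cm.values if isinstance(cm, ConnectivityMatrix) else cm).copy()
    np.fill_diagonal(w, 0.0)
    n = w.shape[0]
    # numerator_i = sum_{k!=l} w_ik w_il w_kl = [W (W∘W-ish)]: use matrix form
    # (W @ W @ W)_ii counts ordered triples i->k->l->i = sum_{k,l} w_ik w_kl w_li
    w3 = w @ w @ w
    num = np.diag(w3).copy()
    # denominator_i = sum_{k!=l} w_ik w_il = (sum_k w_ik)^2 - sum_k w_ik^2
    s1 = w.sum(axis=1)
    s2 = (w ** 2).sum(axis=1)
    den = s1 ** 2 - s2
    per_node = np.zeros(n)
    ok = den > 1e-300
    per_node[ok] = num[ok] / den[ok]
    return per_node, float(per_node.mean())


def weighted_path_length(cm: ConnectivityMatrix | np.ndarray):
    """Mean shortest-path length over unordered pairs, lengths ``1/w``.

    Returns ``(L_abs, finite)`` where ``finite`` is False when some
    pair is unreachable (L_abs is then ``inf``).
    """
    w = _check_weights(cm.values if isinstance(cm, ConnectivityMatrix) else cm).copy()
    np.fill_diagonal(w, 0.0)
    n = w.shape[0]
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(lengths, 0.0)
    dist = shortest_path(lengths, method="D", directed=False)
    iu = np.triu_indices(n, k=1)
    pair_dists = dist[iu]
    finite = bool(np.all(np.isfinite(pair_dists)))
    return float(pair_dists.mean()) if finite else float("inf"), finite


def surrogate_weights(w: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One surrogate: upper-triangle weights permuted over edge slots."""
    n = w.shape[0]
    iu = np.triu_indices(n, k=1)
    shuffled = rng.permutation(w[iu])
    out = np.zeros_like(w)
    out[iu] = shuffled
    return out + out.T


def surrogate_normalize(
    cm: ConnectivityMatrix | np.ndarray,
    n_surrogates: int = DEFAULT_N_SURROGATES,
    seed: int | None = None,
) -> tuple[float, float]:
    """Normalize clustering and path length by weight-shuffled surrogates.

    Returns ``(rC, rL)``; deterministic given ``seed``.  A degenerate
    matrix with all weights equal yields surrogates identical to the
    input, hence ``rC = rL = 1`` exactly.
    """
    if n_surrogates < 1:
        raise ValueError("need at least one surrogate network")
    w = _check_weights(cm.values if isinstance(cm, ConnectivityMatrix) else cm)
    rng = np.random.default_rng(seed)
    _, c_abs = weighted_clustering(w)
    l_abs, _ = weighted_path_length(w)
    c_surr = np.empty(n_surrogates)
    l_surr = np.empty(n_surrogates)
    for s in range(n_surrogates):
        ws = surrogate_weights(w, rng)
        _, c_surr[s] = weighted_clustering(ws)
        l_surr[s], _ = weighted_path_length(ws)
    rC = c_abs / c_surr.mean()
    rL = l_abs / l_surr.mean()
    return float(rC), float(rL)


def small_world_index(rC: float, rL: float) -> float:
    """SWI = rC / rL (balance of local clustering vs path length)."""
    if rL == 0:
        raise ValueError("rL must be positive to form the small-world index")
    return rC / rL


def compute_weighted_metrics(
    cm: ConnectivityMatrix,
    n_surrogates: int = DEFAULT_N_SURROGATES,
    seed: int | None = None,
) -> WeightedMetrics:
    """All weighted measures for one matrix (PLI mean, C, L, rC, rL, SWI)."""
    from .connectivity import mean_pli

    _, c_abs = weighted_clustering(cm)
    l_abs, _ = weighted_path_length(cm)
    rC, rL = surrogate_normalize(cm, n_surrogates=n_surrogates, seed=seed)
    return WeightedMetrics(pli_mean=mean_pli(cm), C_abs=c_abs, L_abs=l_abs,
                           rC=rC, rL=rL, SWI=small_world_index(rC, rL),
                           n_surrogates=n_surrogates, seed=seed)


def threshold_edges(cm: ConnectivityMatrix, threshold: float):
    """Edge list ``(label_i, label_j, weight)`` with ``PLI > threshold``.

    Supports threshold-based network visualizations; no plotting here.
    """
    labels = cm.channel_labels
    n = cm.n_nodes
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if cm.values[i, j] > threshold:
                edges.append((labels[i], labels[j], float(cm.values[i, j])))
    return edges
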