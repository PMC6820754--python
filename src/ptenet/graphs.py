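"""Weighted graph characterization of significant networks.

Metrics follow the standard brain-connectivity conventions: edge weights
(t-values or z-scores) are treated as connection strengths, path lengths use
the reciprocal weight ``1/w``, and the global indices are

* node strength — sum of |weights| of edges incident to a node (in + out),
* density — present edges over possible unordered pairs ``N(N-1)/2``,
* global efficiency — mean inverse shortest-path distance over ordered pairs
  (disconnected pairs contribute zero),
* characteristic path length — mean finite shortest-path distance,
* small-worldness propensity (SWP) — a [0, 1] index comparing observed
  weighted clustering and path length against weight-matched lattice and
  random null networks:

      SWP = 1 - sqrt((dC^2 + dL^2) / 2),
      dC = (C_latt - C_obs) / (C_latt - C_rand),
      dL = (L_obs - L_rand) / (L_latt - L_rand),

  with each delta clipped to [0, 1].

Group contrasts use the Mann-Whitney U test (reported raw and standardized)
and brain-behavior relations use Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats as sp_stats
from scipy.sparse.csgraph import shortest_path

from .stats import SignificantNetwork

__all__ = [
    "GraphMetrics",
    "MetricComparison",
    "node_strength",
    "network_density",
    "global_efficiency",
    "characteristic_path_length",
    "small_worldness_propensity",
    "swp_from_deltas",
    "subject_graph_metrics",
    "compare_group_metrics",
    "correlate_metrics_with_scores",
]

#: floor for masked z-weights before the 1/w length conversion.  A subject
#: with below-average flow (z <= 0) on a masked edge keeps the connection as
#: a tenuous one: the floor caps any single edge length at 1/0.1 = 10 (z
#: units), keeping path metrics finite and bounded instead of letting a few
#: near-zero weights dominate every shortest path.
WEIGHT_EPS = 0.1


@dataclass
class GraphMetrics:
    swp: float
    efficiency: float
    cpl: float
    strengths: np.ndarray
    density: float = float("nan")  # group-level quantity; nan per subject
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.strengths = np.asarray(self.strengths, dtype=float)
        if not (np.isnan(self.swp) or 0.0 <= self.swp <= 1.0):
            raise ValueError(f"swp={self.swp} outside [0, 1]")


@dataclass
class MetricComparison:
    metric_name: str
    u: float  # raw Mann-Whitney U for the first sample
    u_standardized: float  # (U - mean) / sd under H0, tie-corrected
    p: float
    mean_a: float
    mean_b: float


def _distance_matrix(weights: np.ndarray) -> np.ndarray:
    """Directed shortest-path distances with edge length = 1/weight."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, np.inf)
    np.fill_diagonal(lengths, 0.0)
    return shortest_path(lengths, method="D", directed=True)


def node_strength(net: SignificantNetwork | np.ndarray, n_nodes: int | None = None) -> np.ndarray:
    """Sum of |weights| of incident edges (incoming plus outgoing) per node."""
    if isinstance(net, SignificantNetwork):
        w = net.to_matrix(n_nodes)
    else:
        w = np.asarray(net, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite")
    aw = np.abs(w)
    return aw.sum(axis=0) + aw.sum(axis=1)


def network_density(n_nodes_total: int, n_edges: int) -> float:
    """Fraction of present connections among possible node pairs (4 d.p.).

    The denominator counts unordered pairs ``N(N-1)/2``.
    """
    if n_nodes_total < 2:
        raise ValueError("need at least 2 nodes")
    return round(n_edges / (n_nodes_total * (n_nodes_total - 1) / 2.0), 4)


def global_efficiency(weights: np.ndarray) -> float:
    """Mean inverse shortest-path distance over ordered pairs (1/inf = 0)."""
    d = _distance_matrix(weights)
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    inv = np.zeros_like(d)
    reachable = np.isfinite(d) & (d > 0)
    inv[reachable] = 1.0 / d[reachable]
    return float(inv[off].mean())


def characteristic_path_length(weights: np.ndarray, return_infinite_count: bool = False):
    """Mean finite shortest-path distance over ordered pairs.

    Pairs with no connecting path are excluded from the mean; their count is
    available via ``return_infinite_count``.  Raises if no pair is connected.
    """
    d = _distance_matrix(weights)
    off = ~np.eye(d.shape[0], dtype=bool)
    vals = d[off]
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("no finite pair distances; graph has no edges")
    cpl = float(vals[finite].mean())
    if return_infinite_count:
        return cpl, int((~finite).sum())
    return cpl


def _symmetrize(weights: np.ndarray) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    sym = np.maximum(w, w.T)
    np.fill_diagonal(sym, 0.0)
    return sym


def _weighted_clustering(sym: np.ndarray) -> float:
    g = nx.from_numpy_array(sym)
    return nx.average_clustering(g, weight="weight", count_zeros=True)


def _undirected_cpl(sym: np.ndarray) -> float:
    full = np.maximum(sym, sym.T)
    return characteristic_path_length(full)


def _upper_pairs(n: int) -> np.ndarray:
    iu = np.triu_indices(n, k=1)
    return np.column_stack(iu)


def _lattice_surrogate(sym: np.ndarray) -> np.ndarray:
    """Ring-lattice reordering: strongest weights on shortest ring distances."""
    n = sym.shape[0]
    iu = np.triu_indices(n, k=1)
    weights = sym[iu]
    present = weights > 0
    w_sorted = np.sort(weights[present])[::-1]
    pairs = _upper_pairs(n)
    ring_dist = np.minimum(np.abs(pairs[:, 0] - pairs[:, 1]), n - np.abs(pairs[:, 0] - pairs[:, 1]))
    order = np.lexsort((pairs[:, 1], pairs[:, 0], ring_dist))
    latt = np.zeros_like(sym)
    for w, idx in zip(w_sorted, order):
        i, j = pairs[idx]
        latt[i, j] = latt[j, i] = w
    return latt


def _random_surrogate(sym: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random placement of the same weight multiset on the same node set."""
    n = sym.shape[0]
    iu = np.triu_indices(n, k=1)
    weights = sym[iu]
    w_present = weights[weights > 0]
    pairs = _upper_pairs(n)
    chosen = rng.choice(len(pairs), size=len(w_present), replace=False)
    w_shuffled = rng.permutation(w_present)
    rand = np.zeros_like(sym)
    for w, idx in zip(w_shuffled, chosen):
        i, j = pairs[idx]
        rand[i, j] = rand[j, i] = w
    return rand


def swp_from_deltas(delta_c: float, delta_l: float) -> float:
    """SWP from clustering / path-length deviations, each clipped to [0, 1]."""
    dc = min(max(delta_c, 0.0), 1.0)
    dl = min(max(delta_l, 0.0), 1.0)
    return 1.0 - float(np.sqrt((dc**2 + dl**2) / 2.0))


def small_worldness_propensity(
    weights: np.ndarray, seed: int = 0, n_null: int = 50
) -> float:
    """Small-worldness propensity of a weighted network.

    The directed matrix is symmetrized (max of the two directions) since
    clustering is an undirected notion; observed clustering (geometric-mean
    triangle weights) and path length are compared against a ring-lattice
    reordering of the weights and ``n_null`` random placements of the same
    weight multiset.
    """
    sym = _symmetrize(weights)
    if np.any(sym < 0):
        raise ValueError("weights must be non-negative")
    if not (sym > 0).any():
        raise ValueError("empty network; SWP undefined")
    rng = np.random.default_rng(seed)
    c_obs = _weighted_clustering(sym)
    l_obs = _undirected_cpl(sym)
    latt = _lattice_surrogate(sym)
    c_latt = _weighted_clustering(latt)
    l_latt = _undirected_cpl(latt)
    c_rand_vals, l_rand_vals = [], []
    for _ in range(n_null):
        r = _random_surrogate(sym, rng)
        c_rand_vals.append(_weighted_clustering(r))
        try:
            l_rand_vals.append(_undirected_cpl(r))
        except ValueError:
            continue
    c_rand = float(np.mean(c_rand_vals))
    l_rand = float(np.mean(l_rand_vals)) if l_rand_vals else np.nan
    if np.isclose(c_latt, c_rand):
        raise ValueError(
            f"degenerate clustering nulls (C_latt={c_latt:.6g}, C_rand={c_rand:.6g}); "
            "network too small or too dense for SWP"
        )
    if not np.isfinite(l_rand) or np.isclose(l_latt, l_rand):
        raise ValueError(
            f"degenerate path-length nulls (L_latt={l_latt:.6g}, L_rand={l_rand:.6g})"
        )
    delta_c = (c_latt - c_obs) / (c_latt - c_rand)
    delta_l = (l_obs - l_rand) / (l_latt - l_rand)
    return swp_from_deltas(delta_c, delta_l)


def subject_graph_metrics(
    connectome,
    edge_mask: np.ndarray,
    n_nodes_total: int | None = None,
    seed: int = 0,
    n_null: int = 50,
) -> GraphMetrics:
    """Per-subject metrics on the subject's weights restricted to a mask.

    The mask is typically the group-level significant network; restricting
    each subject's z-weights to it yields subject-level variation of the
    same topology.  Negative or zero masked weights are floored at a small
    positive epsilon so the 1/w length conversion stays defined.  Metrics
    are computed on the subgraph induced by the masked nodes; density is a
    group-level quantity and left NaN here.
    """
    w_full = connectome.weights if hasattr(connectome, "weights") else np.asarray(connectome, float)
    mask = np.asarray(edge_mask, dtype=bool)
    if mask.shape != w_full.shape:
        raise ValueError("edge_mask shape must match the connectome")
    if not mask.any():
        raise ValueError("empty edge mask; no network to characterize")
    masked = np.where(mask, np.maximum(w_full, WEIGHT_EPS), 0.0)
    np.fill_diagonal(masked, 0.0)
    touched = np.flatnonzero(mask.any(axis=0) | mask.any(axis=1))
    sub = masked[np.ix_(touched, touched)]
    strengths = node_strength(masked)
    return GraphMetrics(
        swp=small_worldness_propensity(sub, seed=seed, n_null=n_null),
        efficiency=global_efficiency(sub),
        cpl=characteristic_path_length(sub),
        strengths=strengths,
        subject_id=getattr(connectome, "subject_id", ""),
    )


def compare_group_metrics(
    values_a: np.ndarray, values_b: np.ndarray, metric_name: str = ""
) -> MetricComparison:
    """Mann-Whitney U comparison of a graph metric between two groups.

    Exact two-sided p for small samples (n <= 8 per group, no ties), normal
    approximation with tie correction otherwise.  The standardized statistic
    ``(U - n1 n2 / 2) / sd`` is reported alongside the raw U.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        u = a.size * b.size / 2.0
        return MetricComparison(metric_name, u, 0.0, 1.0, float(a.mean()), float(b.mean()))
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = sp_stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u = float(res.statistic)
    # standardized form with tie correction
    n1, n2 = a.size, b.size
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    sd = np.sqrt(n1 * n2 / 12.0 * ((n + 1) - tie_term))
    z = (u - n1 * n2 / 2.0) / sd if sd > 0 else 0.0
    return MetricComparison(
        metric_name=metric_name,
        u=u,
        u_standardized=float(z),
        p=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
    )


def correlate_metrics_with_scores(metric: np.ndarray, score: np.ndarray) -> tuple[float, float]:
    """Pearson r between a graph metric and a behavioral score, with p."""
    m = np.asarray(metric, dtype=float)
    s = np.asarray(score, dtype=float)
    if m.size != s.size or m.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if m.std() == 0 or s.std() == 0:
        raise ValueError("constant vector; correlation undefined")
    r, p = sp_stats.pearsonr(m, s)
    return float(r), float(p)
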