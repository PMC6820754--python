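"""Edge-wise permutation statistics over connectomes.

Within-group networks are detected with a one-sample t statistic per edge
whose null is built by randomly flipping the sign of each subject's edge
values (valid when edge weights are symmetric about zero, as z-scored
connectomes are).  Group differences use an independent-samples t statistic
with a group-label permutation null (optionally combined with sign
flipping).  Multiplicity over all ordered node pairs is handled by
Benjamini-Hochberg FDR, and the surviving edges form the significant
network handed to the graph-metric stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .pte import Connectome

__all__ = [
    "EdgeStatMap",
    "SignificantNetwork",
    "edgewise_one_sample_test",
    "edgewise_two_sample_test",
    "fdr_threshold",
    "extract_significant_network",
]

logger = logging.getLogger(__name__)

#: permutations evaluated per vectorized batch
_BATCH = 500


@dataclass
class EdgeStatMap:
    """Per-edge t statistics and permutation p-values (n x n, diagonal inert)."""

    t: np.ndarray
    p: np.ndarray
    n_permutations: int
    test_kind: str  # "one_sample" | "two_sample"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.t.shape != self.p.shape:
            raise ValueError("t and p must share a shape")
        off = ~np.eye(self.t.shape[0], dtype=bool)
        if np.any((self.p[off] < 0) | (self.p[off] > 1)):
            raise ValueError("p-values outside [0, 1]")


@dataclass
class SignificantNetwork:
    """Directed edges surviving FDR, with their t-values."""

    edges: list[tuple[int, int, float]]
    nodes: set[int] = field(default_factory=set)
    alpha_q: float = 0.001
    n_nodes_total: int = 0

    def __post_init__(self) -> None:
        endpoint_union = {v for s, t, _ in self.edges for v in (s, t)}
        if not self.nodes:
            self.nodes = endpoint_union
        elif self.nodes != endpoint_union:
            raise ValueError("nodes must equal the union of edge endpoints")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_matrix(self, n: int | None = None) -> np.ndarray:
        n = n or self.n_nodes_total or (max(self.nodes) + 1 if self.nodes else 0)
        w = np.zeros((n, n))
        for s, t, tv in self.edges:
            w[s, t] = tv
        return w


def _stack_offdiag(connectomes: list[Connectome] | list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    mats = [c.weights if isinstance(c, Connectome) else np.asarray(c, float) for c in connectomes]
    shapes = {m.shape for m in mats}
    if len(shapes) > 1:
        raise ValueError(f"connectomes have mixed shapes: {shapes}")
    n = mats[0].shape[0]
    off = ~np.eye(n, dtype=bool)
    return np.stack([m[off] for m in mats]), off


def _unstack(vec: np.ndarray, off: np.ndarray, fill: float = 0.0) -> np.ndarray:
    out = np.full(off.shape, fill)
    out[off] = vec
    return out


def _one_sample_t(x: np.ndarray) -> np.ndarray:
    """Vectorized one-sample t vs 0 along axis 0; zero-variance edges -> t=0."""
    n = x.shape[0]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(sd == 0, 0.0, t)


def _two_sample_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pooled-variance independent-samples t (a minus b) along axis 0."""
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / denom
    return np.where(denom == 0, 0.0, t)


def edgewise_one_sample_test(
    connectomes: list[Connectome] | list[np.ndarray],
    n_permutations: int = 5000,
    seed: int = 0,
    flip_scope: str = "subject",
    exhaustive: bool = False,
) -> EdgeStatMap:
    """One-sample sign-flip permutation test of each edge against zero.

    The null randomly negates subject values (``flip_scope='subject'``: one
    flip per subject per permutation, preserving within-subject edge
    correlation; ``'cell'``: independent flips per subject x edge cell).
    Two-sided p-values count permuted |t| >= observed |t| with the observed
    statistic included in the null (add-one rule), so p >= 1/(B+1).
    Zero-variance edges are reported as t = 0, p = 1 and logged.

    With ``exhaustive=True`` (subject scope only, feasible up to ~16
    subjects) all 2^n sign patterns are enumerated and p is the exact
    fraction of patterns with |t| at least the observed value, so the
    minimal attainable two-sided p is 2/2^n.
    """
    x, off = _stack_offdiag(connectomes)
    n_subj, n_edges = x.shape
    if n_subj < 3:
        raise ValueError("need at least 3 subjects")
    if flip_scope not in ("subject", "cell"):
        raise ValueError("flip_scope must be 'subject' or 'cell'")
    if exhaustive:
        if flip_scope != "subject":
            raise ValueError("exhaustive enumeration requires flip_scope='subject'")
        if n_subj > 16:
            raise ValueError("exhaustive enumeration limited to 16 subjects (2^16 patterns)")
        t_obs = _one_sample_t(x)
        degenerate = x.std(axis=0, ddof=1) == 0
        patterns = ((np.arange(2**n_subj)[:, None] >> np.arange(n_subj)) & 1) * 2.0 - 1.0
        sum_sq = np.sum(x**2, axis=0)
        exceed = np.zeros(n_edges)
        for start in range(0, patterns.shape[0], _BATCH):
            signs = patterns[start : start + _BATCH]
            mean_perm = signs @ x / n_subj
            var_perm = np.maximum((sum_sq[None, :] - n_subj * mean_perm**2) / (n_subj - 1), 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                t_perm = mean_perm / np.sqrt(var_perm / n_subj)
            t_perm = np.where(var_perm == 0, 0.0, t_perm)
            exceed += np.sum(np.abs(t_perm) >= np.abs(t_obs)[None, :] - 1e-12, axis=0)
        p = np.where(degenerate, 1.0, exceed / 2**n_subj)
        return EdgeStatMap(
            t=_unstack(np.where(degenerate, 0.0, t_obs), off),
            p=_unstack(p, off, fill=1.0),
            n_permutations=2**n_subj,
            test_kind="one_sample",
        )
    t_obs = _one_sample_t(x)
    degenerate = x.std(axis=0, ddof=1) == 0
    if degenerate.any():
        logger.warning("%d edges have zero variance; t=0, p=1", int(degenerate.sum()))
    rng = np.random.default_rng(seed)
    exceed = np.ones(n_edges)  # add-one rule: observed counts as one null draw
    abs_obs = np.abs(t_obs)
    # under sign flips sum(x_i^2) is invariant, so permuted t statistics are a
    # closed form of the permuted mean -- evaluated in vectorized batches
    sum_sq = np.sum(x**2, axis=0)
    for start in range(0, n_permutations, _BATCH):
        nb = min(_BATCH, n_permutations - start)
        if flip_scope == "subject":
            signs = rng.choice([-1.0, 1.0], size=(nb, n_subj))
            mean_perm = signs @ x / n_subj
        else:
            mean_perm = np.empty((nb, n_edges))
            for j in range(nb):
                s = rng.choice([-1.0, 1.0], size=(n_subj, n_edges))
                mean_perm[j] = (x * s).mean(axis=0)
        var_perm = (sum_sq[None, :] - n_subj * mean_perm**2) / (n_subj - 1)
        var_perm = np.maximum(var_perm, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = mean_perm / np.sqrt(var_perm / n_subj)
        t_perm = np.where(var_perm == 0, 0.0, t_perm)
        exceed += np.sum(np.abs(t_perm) >= abs_obs[None, :], axis=0)
    p = exceed / (n_permutations + 1)
    p = np.where(degenerate, 1.0, p)
    return EdgeStatMap(
        t=_unstack(np.where(degenerate, 0.0, t_obs), off),
        p=_unstack(p, off, fill=1.0),
        n_permutations=n_permutations,
        test_kind="one_sample",
    )


def edgewise_two_sample_test(
    group_a: list[Connectome] | list[np.ndarray],
    group_b: list[Connectome] | list[np.ndarray],
    n_permutations: int = 5000,
    seed: int = 0,
    sign_flip: bool = False,
) -> EdgeStatMap:
    """Independent-samples permutation test of group A vs group B per edge.

    The t statistic contrasts A minus B (a > b in positive t; the opposite
    contrast is the negation).  The null permutes group labels; with
    ``sign_flip=True`` each permuted subject is additionally negated at
    random, combining shuffling with sign flipping.  Two-sided p-values use
    the add-one rule as in the one-sample test.
    """
    xa, off = _stack_offdiag(group_a)
    xb, _ = _stack_offdiag(group_b)
    if xa.shape[1] != xb.shape[1]:
        raise ValueError("groups have different edge counts")
    na, nb = xa.shape[0], xb.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 subjects per group")
    pooled = np.vstack([xa, xb])
    t_obs = _two_sample_t(xa, xb)
    denom_zero = (pooled.var(axis=0, ddof=1) == 0)
    if denom_zero.any():
        logger.warning("%d edges degenerate in two-sample test", int(denom_zero.sum()))
    rng = np.random.default_rng(seed)
    exceed = np.ones(pooled.shape[1])
    abs_obs = np.abs(t_obs)
    n_total = na + nb
    n_edges = pooled.shape[1]
    sq = pooled**2
    for start in range(0, n_permutations, _BATCH):
        nb_batch = min(_BATCH, n_permutations - start)
        # membership matrix: row = one permutation, 1 marks group-A subjects
        sel = np.zeros((nb_batch, n_total))
        for j in range(nb_batch):
            sel[j, rng.permutation(n_total)[:na]] = 1.0
        if sign_flip:
            signs = rng.choice([-1.0, 1.0], size=(nb_batch, n_total))
            w_a = sel * signs
            w_b = (1.0 - sel) * signs
        else:
            w_a = sel
            w_b = 1.0 - sel
        sum_a = w_a @ pooled
        sum_b = w_b @ pooled
        mean_a = sum_a / na
        mean_b = sum_b / nb
        # squares are sign-invariant, so group sums of squares use membership only
        ss_a = sel @ sq
        ss_b = (1.0 - sel) @ sq
        va = (ss_a - na * mean_a**2) / (na - 1)
        vb = (ss_b - nb * mean_b**2) / (nb - 1)
        sp2 = ((na - 1) * np.maximum(va, 0) + (nb - 1) * np.maximum(vb, 0)) / (na + nb - 2)
        denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = (mean_a - mean_b) / denom
        t_perm = np.where(denom == 0, 0.0, t_perm)
        exceed += np.sum(np.abs(t_perm) >= abs_obs[None, :], axis=0)
    p = exceed / (n_permutations + 1)
    p = np.where(denom_zero, 1.0, p)
    return EdgeStatMap(
        t=_unstack(t_obs, off),
        p=_unstack(p, off, fill=1.0),
        n_permutations=n_permutations,
        test_kind="two_sample",
    )


def fdr_threshold(p: np.ndarray, q: float = 0.001) -> np.ndarray:
    """Benjamini-Hochberg step-up over all off-diagonal ordered pairs.

    Returns a boolean rejection mask of the same shape; the diagonal is
    never rejected.
    """
    p = np.asarray(p, dtype=float)
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    off = ~np.eye(p.shape[0], dtype=bool)
    reject_flat, *_ = multipletests(p[off], alpha=q, method="fdr_bh")
    mask = np.zeros_like(p, dtype=bool)
    mask[off] = reject_flat
    return mask


def extract_significant_network(
    stats: EdgeStatMap, mask: np.ndarray, alpha_q: float = 0.001
) -> SignificantNetwork:
    """Collect the masked directed edges and their t-values into a network."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stats.t.shape:
        raise ValueError("mask shape must match the statistic map")
    srcs, dsts = np.nonzero(mask & ~np.eye(mask.shape[0], dtype=bool))
    edges = [(int(s), int(t), float(stats.t[s, t])) for s, t in zip(srcs, dsts)]
    return SignificantNetwork(
        edges=edges, alpha_q=alpha_q, n_nodes_total=stats.t.shape[0]
    )
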