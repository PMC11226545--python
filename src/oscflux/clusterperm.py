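"""Sign-aware strongly-connected-component cluster permutation test on
directed PSI matrices.

Group inference proceeds in three steps.  (1) For every ordered channel pair
a paired t-statistic contrasts the standardised PSI between conditions
across participants.  (2) Edges with uncorrected p > .05 are discarded; each
surviving edge is assigned to the condition with the larger absolute group
mean PSI on that edge (so a "condition B cluster" collects edges whose
directed synchronisation is stronger in B); within each condition's edge set
the edges are oriented by the sign of that condition's group-mean PSI
(positive PSI: first channel drives) and the nodes are partitioned into
strongly connected components; a cluster is the set of surviving edges with
both endpoints inside one SCC, and surviving edges not captured by any
multi-node SCC form singleton clusters so isolated effects are not silently
dropped.  (3) The cluster statistic is the sum of edge t-values; its null
distribution comes from randomly flipping each participant's condition
labels (the participant's own data are never altered) and recording the
maximum absolute cluster statistic per iteration.  The two-tailed t-critical
value is the (1 - alpha/2) quantile of that null; cluster p-values use the
add-one permutation estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.stats import t as t_dist

logger = logging.getLogger("oscflux.clusterperm")


@dataclass
class EdgeStats:
    t: np.ndarray        # (n_ch, n_ch); nan where undefined
    p: np.ndarray        # two-tailed p-values
    n: np.ndarray        # participants used per edge (pairwise exclusion)


@dataclass
class Cluster:
    edges: list[tuple[int, int]]        # directed (driver, receiver) index pairs
    condition_membership: str           # "A" or "B"
    cluster_stat: float                 # sum of edge t-values
    p_value: float | None = None
    significant: bool | None = None


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    null_distribution: np.ndarray
    t_critical: float
    alpha: float
    n_permutations: int
    channels: list[str] | None = None

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.significant]


# ---------------------------------------------------------------------------
# Edge statistics
# ---------------------------------------------------------------------------

def _stack(psis) -> np.ndarray:
    arr = np.asarray([np.asarray(m, float) for m in psis])
    if arr.ndim != 3 or arr.shape[1] != arr.shape[2]:
        raise ValueError("expected a stack of square PSI matrices")
    return arr


def edge_tstats(psiA, psiB) -> EdgeStats:
    """Paired t-statistics of (PSI_B - PSI_A) for every ordered channel pair.

    ``psiA`` / ``psiB`` are per-participant stacks of standardised PSI
    matrices in the same participant order.  Edges missing (nan) for a
    participant are excluded pairwise, with the per-edge n recorded.
    """
    A, B = _stack(psiA), _stack(psiB)
    if A.shape != B.shape:
        raise ValueError("condition stacks differ in shape")
    if A.shape[0] < 3:
        raise ValueError("paired t-test needs at least 3 participants")
    D = B - A
    ok = ~np.isnan(D)
    n = ok.sum(axis=0)
    Dz = np.where(ok, D, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = Dz.sum(axis=0) / n
        var = (np.where(ok, (D - mean) ** 2, 0.0).sum(axis=0)) / (n - 1)
        tval = mean / np.sqrt(var / n)
    tval[n < 2] = np.nan
    with np.errstate(invalid="ignore"):
        p = 2.0 * t_dist.sf(np.abs(tval), np.maximum(n - 1, 1))
    p[np.isnan(tval)] = np.nan
    np.fill_diagonal(tval, 0.0)
    np.fill_diagonal(p, 1.0)
    return EdgeStats(t=tval, p=p, n=n)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def strongly_connected_partition(n_nodes: int, edges: list[tuple[int, int]],
                                 mode: str = "strong") -> list[set[int]]:
    """Partition nodes into strongly (or weakly) connected components of the
    directed graph given by ``edges``."""
    g = nx.DiGraph()
    g.add_nodes_from(range(n_nodes))
    g.add_edges_from(edges)
    if mode == "strong":
        comps = nx.strongly_connected_components(g)
    elif mode == "weak":
        comps = nx.weakly_connected_components(g)
    else:
        raise ValueError("mode must be 'strong' or 'weak'")
    return [set(c) for c in comps]


def build_clusters(stats: EdgeStats, mean_psi_a: np.ndarray, mean_psi_b: np.ndarray,
                   alpha_edge: float = 0.05, scc_mode: str = "strong") -> list[Cluster]:
    """Form candidate clusters from supra-threshold edges.

    Surviving (p <= alpha_edge) unordered pairs are assigned to the condition
    with the larger |group-mean PSI|, oriented by that condition's mean PSI
    sign, and grouped by connected component (strong by default).  Surviving
    edges not inside a multi-node component become singleton clusters.
    """
    n_ch = stats.t.shape[0]
    mean_psi = {"A": np.asarray(mean_psi_a, float), "B": np.asarray(mean_psi_b, float)}
    # unordered pairs: PSI antisymmetry makes (i,j) and (j,i) equivalent
    edges_by_cond: dict[str, list[tuple[int, int]]] = {"A": [], "B": []}
    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            p = stats.p[i, j]
            if not np.isfinite(p) or p > alpha_edge:
                continue
            cond = "B" if abs(mean_psi["B"][i, j]) >= abs(mean_psi["A"][i, j]) else "A"
            # orient by the winning condition's mean PSI: psi[i, j] > 0 => i drives j
            if mean_psi[cond][i, j] >= 0:
                edges_by_cond[cond].append((i, j))
            else:
                edges_by_cond[cond].append((j, i))

    clusters: list[Cluster] = []
    for cond, edges in edges_by_cond.items():
        if not edges:
            continue
        comps = strongly_connected_partition(n_ch, edges, mode=scc_mode)
        node_to_comp = {}
        for ci, comp in enumerate(comps):
            for node in comp:
                node_to_comp[node] = ci
        grouped: dict[int, list[tuple[int, int]]] = {}
        singles: list[tuple[int, int]] = []
        for (u, v) in edges:
            if node_to_comp[u] == node_to_comp[v]:
                grouped.setdefault(node_to_comp[u], []).append((u, v))
            else:
                singles.append((u, v))
        for comp_edges in grouped.values():
            stat = float(sum(stats.t[u, v] for (u, v) in comp_edges))
            clusters.append(Cluster(edges=comp_edges, condition_membership=cond,
                                    cluster_stat=stat))
        for (u, v) in singles:
            clusters.append(Cluster(edges=[(u, v)], condition_membership=cond,
                                    cluster_stat=float(stats.t[u, v])))
    return clusters


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

def _perm_edge_t(D: np.ndarray, signs: np.ndarray):
    """Vectorised paired t for sign-flipped difference stacks.

    D: (n, ch, ch) finite differences; signs: (n_iter, n) of +/-1.
    Returns t arrays (n_iter, ch, ch).  Uses the identity that sign flips
    leave sum(D^2) unchanged.
    """
    n = D.shape[0]
    flat = D.reshape(n, -1)
    ssq = np.sum(flat ** 2, axis=0)                       # (E,)
    mean = signs @ flat / n                               # (n_iter, E)
    var = (ssq - n * mean ** 2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tval = mean / np.sqrt(var / n)
    return tval.reshape(signs.shape[0], *D.shape[1:])


def permutation_test(psiA, psiB, n_perm: int = 5000, alpha: float = 0.05,
                     seed: int = 0, alpha_edge: float = 0.05,
                     scc_mode: str = "strong",
                     channels: list[str] | None = None) -> ClusterResult:
    """Non-parametric cluster permutation test on paired PSI matrices.

    Each iteration flips every participant's condition labels independently
    with probability 1/2 (paired exchangeability), recomputes the edge
    t-contrast and the clusters, and keeps the maximum absolute cluster
    statistic.  The two-tailed t-critical value is the (1 - alpha/2)
    quantile of this null; observed clusters exceeding it are significant,
    with add-one permutation p-values.  Deterministic given ``seed``.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be at least 10")
    if n_perm < 100:
        logger.warning("n_perm=%d is very small; p-values will be coarse", n_perm)
    A, B = _stack(psiA), _stack(psiB)
    if A.shape != B.shape:
        raise ValueError("condition stacks differ in shape")
    n = A.shape[0]
    if n < 3:
        raise ValueError("insufficient sample: paired permutation needs >= 3 participants")

    observed_stats = edge_tstats(A, B)
    mean_a = np.nanmean(A, axis=0)
    mean_b = np.nanmean(B, axis=0)
    observed = build_clusters(observed_stats, mean_a, mean_b,
                              alpha_edge=alpha_edge, scc_mode=scc_mode)

    # permutation core operates on complete differences; participants with
    # any missing edge fall back to the slow path
    D = B - A
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    null = np.zeros(n_perm)
    complete = np.all(np.isfinite(D))
    if complete:
        t_all = _perm_edge_t(D, signs)                      # (n_perm, ch, ch)
        df = n - 1
        t_edge_crit = t_dist.ppf(1.0 - alpha_edge / 2.0, df)
        sum_a, sum_b = A.sum(axis=0), B.sum(axis=0)
        sum_diff = D.sum(axis=0)
        for it in range(n_perm):
            flipped = signs[it] < 0
            # label flip swaps A and B for flipped participants
            d_flip = D[flipped].sum(axis=0)
            m_b = (sum_b - d_flip) / n
            m_a = (sum_a + d_flip) / n
            tmat = t_all[it]
            pmat = np.full_like(tmat, 1.0)
            mask = np.abs(tmat) >= t_edge_crit
            pmat[mask] = alpha_edge  # exact p not needed, only the <= test
            stats_it = EdgeStats(t=tmat, p=pmat,
                                 n=np.full(tmat.shape, n))
            clusters_it = build_clusters(stats_it, m_a, m_b,
                                         alpha_edge=alpha_edge, scc_mode=scc_mode)
            null[it] = max((abs(c.cluster_stat) for c in clusters_it), default=0.0)
    else:
        for it in range(n_perm):
            flip = signs[it] < 0
            A_it = np.where(flip[:, None, None], B, A)
            B_it = np.where(flip[:, None, None], A, B)
            stats_it = edge_tstats(A_it, B_it)
            clusters_it = build_clusters(stats_it, np.nanmean(A_it, axis=0),
                                         np.nanmean(B_it, axis=0),
                                         alpha_edge=alpha_edge, scc_mode=scc_mode)
            null[it] = max((abs(c.cluster_stat) for c in clusters_it), default=0.0)

    t_critical = float(np.quantile(null, 1.0 - alpha / 2.0))
    for c in observed:
        exceed = int(np.sum(null >= abs(c.cluster_stat)))
        c.p_value = (1 + exceed) / (1 + n_perm)
        c.significant = abs(c.cluster_stat) > t_critical
    return ClusterResult(clusters=observed, null_distribution=null,
                         t_critical=t_critical, alpha=alpha,
                         n_permutations=n_perm, channels=channels)


# ---------------------------------------------------------------------------
# Topography contrasts
# ---------------------------------------------------------------------------

def contrast_topography(measuresA: np.ndarray, measuresB: np.ndarray,
                        channels: list[str] | None = None):
    """Per-channel paired t map of condition B minus condition A.

    Inputs are (n_participants, n_channels) arrays of per-participant channel
    means; participants missing a channel (nan) are excluded pairwise.
    Returns a list of dicts (channel, t, n) suitable for a DataFrame.
    """
    A = np.asarray(measuresA, float)
    B = np.asarray(measuresB, float)
    if A.shape != B.shape:
        raise ValueError("condition arrays differ in shape")
    D = B - A
    ok = np.isfinite(D)
    n = ok.sum(axis=0)
    rows = []
    for j in range(D.shape[1]):
        d = D[ok[:, j], j]
        if d.size >= 2 and d.std(ddof=1) > 0:
            tval = float(d.mean() / (d.std(ddof=1) / np.sqrt(d.size)))
        elif d.size >= 2:
            tval = 0.0 if d.mean() == 0 else float("inf") * np.sign(d.mean())
        else:
            tval = float("nan")
        name = channels[j] if channels else str(j)
        rows.append({"channel": name, "t": tval, "n": int(n[j])})
    return rows
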