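"""Independent brute-force oracles for the permutation corrections.

Everything here is deliberately naive: Pearson r via scipy.stats.pearsonr on
explicit loops, connected components via breadth-first search over neighbour
offsets, full enumeration of all subject orderings, and a from-scratch Holm
step-down. These never touch the package's vectorized engine, so exact
agreement on tiny instances is a genuine cross-check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats


def all_perms(n: int) -> list[tuple[int, ...]]:
    """All orderings of range(n), identity first (itertools order)."""
    return list(itertools.permutations(range(n)))


def naive_rmap(stack: np.ndarray, cov: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Voxelwise Pearson r by looping scipy.stats.pearsonr; 0 outside mask."""
    out = np.zeros(stack.shape[:3])
    for idx in np.argwhere(mask):
        out[tuple(idx)] = stats.pearsonr(stack[tuple(idx)], cov)[0]
    return out


def neighbor_deltas(connectivity: int) -> list[tuple[int, int, int]]:
    deltas = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        nz = sum(abs(x) for x in d)
        if connectivity == 6 and nz > 1:
            continue
        if connectivity == 18 and nz > 2:
            continue
        deltas.append(d)
    return deltas


def bfs_components(sup: np.ndarray, connectivity: int) -> list[list[tuple[int, int, int]]]:
    """Connected components of a boolean volume by breadth-first search."""
    deltas = neighbor_deltas(connectivity)
    seen = np.zeros(sup.shape, bool)
    comps = []
    for start in map(tuple, np.argwhere(sup)):
        if seen[start]:
            continue
        comp, queue = [], [start]
        seen[start] = True
        while queue:
            v = queue.pop()
            comp.append(v)
            for d in deltas:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if all(0 <= w[a] < sup.shape[a] for a in range(3)) and sup[w] and not seen[w]:
                    seen[w] = True
                    queue.append(w)
        comps.append(comp)
    return comps


def naive_holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p, from the definition."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def oracle_voxel_p(stack, cov, mask):
    """Max-|r| permutation corrected p per masked voxel (C-order)."""
    perms = all_perms(len(cov))
    nulls = [np.abs(naive_rmap(stack, np.asarray(cov)[list(pi)], mask)[mask]).max()
             for pi in perms]
    obs = np.abs(naive_rmap(stack, np.asarray(cov), mask)[mask])
    return np.array([sum(nv >= o for nv in nulls) / len(perms) for o in obs])


def oracle_kmax_p(stack, cov, mask, k):
    perms = all_perms(len(cov))
    nulls = []
    for pi in perms:
        a = sorted(np.abs(naive_rmap(stack, np.asarray(cov)[list(pi)], mask)[mask]), reverse=True)
        nulls.append(a[k - 1])
    obs = np.abs(naive_rmap(stack, np.asarray(cov), mask)[mask])
    # floored at 1/n_perm (a voxel can exceed every k-th max for k > 1)
    return np.array([max(sum(nv >= o for nv in nulls), 1) / len(perms) for o in obs])


def oracle_cluster_extent(stack, cov, mask, r_thr, connectivity):
    """(per-cluster extents, per-cluster p) for the observed map, clusters in
    BFS discovery order keyed by their member sets."""
    perms = all_perms(len(cov))
    nulls = []
    for pi in perms:
        sup = (np.abs(naive_rmap(stack, np.asarray(cov)[list(pi)], mask)) >= r_thr) & mask
        comps = bfs_components(sup, connectivity)
        nulls.append(max((len(c) for c in comps), default=0))
    sup = (np.abs(naive_rmap(stack, np.asarray(cov), mask)) >= r_thr) & mask
    comps = bfs_components(sup, connectivity)
    out = {}
    for c in comps:
        p = sum(nv >= len(c) for nv in nulls) / len(perms)
        out[frozenset(c)] = (len(c), p)
    return out


def naive_tfce(vol, mask, H, E, dt, connectivity):
    """Per-voxel TFCE: positive and negated passes merged by maximum (their
    supports are disjoint), each a plain threshold/BFS accumulation."""
    pos = _naive_tfce_one_sign(vol, mask, H, E, dt, connectivity)
    neg = _naive_tfce_one_sign(-vol, mask, H, E, dt, connectivity)
    return np.maximum(pos, neg)


def _naive_tfce_one_sign(vol, mask, H, E, dt, connectivity):
    out = np.zeros(vol.shape)
    vmax = vol[mask].max() if mask.any() else 0.0
    n_steps = math.floor(vmax / dt + 1e-9)
    for k in range(1, n_steps + 1):
        t = k * dt
        sup = (vol >= t * (1 - 1e-9)) & mask
        for comp in bfs_components(sup, connectivity):
            for v in comp:
                out[v] += len(comp) ** E * t**H * dt
    return out


def oracle_tfce_p(stack, cov, mask, H, E, dt, connectivity):
    perms = all_perms(len(cov))
    nulls = []
    for pi in perms:
        r = naive_rmap(stack, np.asarray(cov)[list(pi)], mask)
        nulls.append(naive_tfce(r, mask, H, E, dt, connectivity)[mask].max())
    r = naive_rmap(stack, np.asarray(cov), mask)
    obs = naive_tfce(r, mask, H, E, dt, connectivity)[mask]
    return np.array([sum(nv >= o for nv in nulls) / len(perms) for o in obs])


def oracle_organ(stack, cov, mask, labels_vol, supports, weights):
    """Per-organ weighted-signal permutation p + naive Holm.

    supports/weights: dict label -> (list of voxel tuples, list of weights).
    Returns (labels, p_raw, p_holm) with labels sorted.
    """
    perms = all_perms(len(cov))
    labs = sorted(supports)
    S = np.empty((len(perms), len(labs)))
    for i, pi in enumerate(perms):
        r = naive_rmap(stack, np.asarray(cov)[list(pi)], mask)
        for j, lab in enumerate(labs):
            vox, w = supports[lab], weights[lab]
            S[i, j] = sum(r[v] * wi for v, wi in zip(vox, w)) / len(vox)
    p_raw = np.array([
        sum(abs(S[i, j]) >= abs(S[0, j]) for i in range(len(perms))) / len(perms)
        for j in range(len(labs))
    ])
    return labs, p_raw, naive_holm(p_raw)


def oracle_anat_cluster(stack, cov, mask, labels_vol, r_thr, connectivity, extents_by_label):
    """Organ-constrained scaled-extent permutation p per observed cluster."""
    perms = all_perms(len(cov))
    e_max = max(extents_by_label.values())

    def clusters_and_stats(r):
        items = []
        for lab, e_X in extents_by_label.items():
            sup = (np.abs(r) >= r_thr) & mask & (labels_vol == lab)
            for comp in bfs_components(sup, connectivity):
                items.append((frozenset(comp), len(comp) * e_max / e_X))
        return items

    nulls = []
    for pi in perms:
        r = naive_rmap(stack, np.asarray(cov)[list(pi)], mask)
        stats_ = [s for _, s in clusters_and_stats(r)]
        nulls.append(max(stats_, default=0.0))
    r = naive_rmap(stack, np.asarray(cov), mask)
    return {
        members: (s, sum(nv >= s for nv in nulls) / len(perms))
        for members, s in clusters_and_stats(r)
    }


def oracle_cba_perm(stack, cov, mask, cluster_labels):
    """Max-|cluster mean r| permutation p per cluster (1-based cluster ids)."""
    perms = all_perms(len(cov))
    ids = sorted(set(cluster_labels[mask]) - {0})

    def means(r):
        return np.array([r[(cluster_labels == i) & mask].mean() for i in ids])

    nulls = []
    for pi in perms:
        r = naive_rmap(stack, np.asarray(cov)[list(pi)], mask)
        nulls.append(np.abs(means(r)).max())
    obs = np.abs(means(naive_rmap(stack, np.asarray(cov), mask)))
    return np.array([sum(nv >= o for nv in nulls) / len(perms) for o in obs])
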