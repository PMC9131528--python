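"""Connected-component utilities shared by the permutation cluster tests.

Both the region-level morphometry correction and the channel x time EEG
cluster test reduce to the same primitive: given a boolean suprathreshold
mask over N nodes and an undirected edge list, group suprathreshold nodes
into connected clusters and score each cluster by its mass (sum of |stat|).
The permutation null only needs the *maximum* cluster mass, for which a
lightweight union-find over the surviving edges is used.
"""

from __future__ import annotations

import numpy as np

__all__ = ["cluster_labels", "max_cluster_mass", "lattice_edges"]


def cluster_labels(mask: np.ndarray, edges: np.ndarray, n_nodes: int) -> tuple[np.ndarray, int]:
    """Label connected clusters of ``mask`` nodes under ``edges``.

    Parameters
    ----------
    mask : boolean array (n_nodes,)
        Suprathreshold indicator.
    edges : int array (n_edges, 2)
        Undirected edges over node indices. May be empty, in which case every
        suprathreshold node is its own cluster.

    Returns
    -------
    labels : int array (n_nodes,)
        Cluster id per node, ``-1`` outside the mask. Ids are dense 0..k-1 and
        deterministic (ordered by smallest member node index).
    n_clusters : int
    """
    labels = np.full(n_nodes, -1, dtype=np.int64)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return labels, 0
    parent = {int(i): int(i) for i in idx}

    def find(a: int) -> int:
        root = a
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:
            parent[a], a = root, parent[a]
        return root

    if edges.size:
        keep = mask[edges[:, 0]] & mask[edges[:, 1]]
        for a, b in edges[keep]:
            ra, rb = find(int(a)), find(int(b))
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    roots = np.array([find(int(i)) for i in idx])
    uniq, dense = np.unique(roots, return_inverse=True)
    labels[idx] = dense
    return labels, len(uniq)


def max_cluster_mass(stat_abs: np.ndarray, mask: np.ndarray, edges: np.ndarray) -> float:
    """Maximum cluster mass (sum of ``stat_abs``) over connected clusters.

    Fast path used inside permutation loops; equivalent to scoring
    :func:`cluster_labels` output but without materializing labels.
    """
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return 0.0
    if edges.size:
        keep = mask[edges[:, 0]] & mask[edges[:, 1]]
        kept = edges[keep]
    else:
        kept = np.empty((0, 2), dtype=np.int64)
    if len(kept) == 0:
        return float(stat_abs[idx].max())
    parent: dict[int, int] = {}

    def find(a: int) -> int:
        parent.setdefault(a, a)
        root = a
        while parent.setdefault(root, root) != root:
            root = parent[root]
        while parent[a] != root:
            parent[a], a = root, parent[a]
        return root

    for a, b in kept:
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[rb] = ra
    in_comp = np.zeros(len(stat_abs), dtype=bool)
    masses: dict[int, float] = {}
    for node in parent:
        in_comp[node] = True
        root = find(node)
        masses[root] = masses.get(root, 0.0) + float(stat_abs[node])
    best = max(masses.values())
    singles = idx[~in_comp[idx]]
    if singles.size:
        best = max(best, float(stat_abs[singles].max()))
    return best


def lattice_edges(n_channels: int, n_times: int, channel_edges: np.ndarray) -> np.ndarray:
    """Edge list for a channel x time lattice, flattened C-order (channel-major).

    Temporal neighbours are always adjacent; ``channel_edges`` (pairs of
    channel indices) link channels at identical time points.
    """
    node = lambda c, t: c * n_times + t
    parts = []
    t = np.arange(n_times - 1)
    for c in range(n_channels):
        parts.append(np.column_stack([node(c, t), node(c, t + 1)]))
    tt = np.arange(n_times)
    for a, b in np.asarray(channel_edges, dtype=np.int64).reshape(-1, 2):
        parts.append(np.column_stack([node(a, tt), node(b, tt)]))
    if not parts:
        return np.empty((0, 2), dtype=np.int64)
    return np.concatenate(parts).astype(np.int64)
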