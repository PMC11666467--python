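"""Sparse voxel-graph utilities shared by segmentation and morphometry.

Foreground voxels form the nodes of a 26-connected graph whose edge weight is
the physical centre-to-centre distance in μm. Shortest paths on this graph
realise the within-object ("geodesic") distance maps used for villus length,
crypt depth, EdU migration and marker regrowth.
"""

from __future__ import annotations

import heapq
import itertools

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

# The 13 half-neighbourhood offsets of 26-connectivity (each undirected pair once).
HALF_OFFSETS: tuple[tuple[int, int, int], ...] = tuple(
    off for off in itertools.product((-1, 0, 1), repeat=3) if off > (0, 0, 0)
)


def mask_graph(mask: np.ndarray, spacing) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Build the 26-connected graph over True voxels of ``mask``.

    Returns ``(graph, node_index)`` where ``graph`` is a symmetric CSR matrix
    of physical edge lengths and ``node_index`` maps voxel -> node id (-1 for
    background).
    """
    mask = np.asarray(mask, dtype=bool)
    spacing = np.asarray(spacing, dtype=float)
    n = int(mask.sum())
    node_index = np.full(mask.shape, -1, dtype=np.int64)
    node_index[mask] = np.arange(n)

    rows, cols, weights = [], [], []
    for off in HALF_OFFSETS:
        w = float(np.linalg.norm(spacing * off))
        src = _shift_slices(mask.shape, off, source=True)
        dst = _shift_slices(mask.shape, off, source=False)
        pair = mask[src] & mask[dst]
        a = node_index[src][pair]
        b = node_index[dst][pair]
        if a.size:
            rows.append(a)
            cols.append(b)
            weights.append(np.full(a.size, w))
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        w = np.concatenate(weights)
        graph = sparse.csr_matrix(
            (np.concatenate([w, w]), (np.concatenate([r, c]), np.concatenate([c, r]))),
            shape=(n, n),
        )
    else:
        graph = sparse.csr_matrix((n, n))
    return graph, node_index


def _shift_slices(shape, off, source: bool):
    """Slices selecting voxels that have (source) / are (dest) an ``off`` neighbour."""
    sl = []
    for size, o in zip(shape, off):
        o = o if source else -o
        if o > 0:
            sl.append(slice(0, size - o))
        elif o < 0:
            sl.append(slice(-o, size))
        else:
            sl.append(slice(None))
    return tuple(sl)


def geodesic_field(mask: np.ndarray, sources: np.ndarray, spacing) -> np.ndarray:
    """Geodesic (within-mask shortest-path) distance in μm from a source set.

    ``sources`` is a boolean grid (subset of ``mask``). Returns a float grid:
    +inf outside the mask or in mask regions unreachable from any source.
    """
    mask = np.asarray(mask, dtype=bool)
    sources = np.asarray(sources, dtype=bool)
    if not sources.any():
        raise ValueError("geodesic_field: empty source set")
    if (sources & ~mask).any():
        raise ValueError("geodesic_field: sources must lie inside the mask")
    graph, node_index = mask_graph(mask, spacing)
    src_nodes = node_index[sources]
    dist = _csgraph_dijkstra(graph, directed=False, indices=src_nodes, min_only=True)
    field = np.full(mask.shape, np.inf)
    field[mask] = dist
    return field


def multi_source_label_distances(
    mask: np.ndarray, seed_labels: np.ndarray, spacing
) -> tuple[np.ndarray, np.ndarray]:
    """Per-seed-label geodesic distance over the mask.

    ``seed_labels`` is an integer grid (0 = no seed) whose positive voxels lie
    inside ``mask``. Returns ``(ids, dist)``: ``ids`` the sorted positive
    labels, ``dist`` an array of shape ``(len(ids), n_mask_voxels)`` holding,
    for each label, the geodesic distance from that label's seed set to every
    mask voxel (np.inf if unreachable).

    Each label is attached to one zero-weight virtual node so a multi-voxel
    seed behaves as a single source.
    """
    mask = np.asarray(mask, dtype=bool)
    seed_labels = np.asarray(seed_labels)
    ids = np.unique(seed_labels)
    ids = ids[ids > 0]
    graph, node_index = mask_graph(mask, spacing)
    n = graph.shape[0]
    k = len(ids)
    if k == 0:
        return ids, np.empty((0, n))
    # augment with k virtual source nodes
    rows, cols = [], []
    for i, lab in enumerate(ids):
        seeds = node_index[seed_labels == lab]
        rows.append(np.full(seeds.size, n + i))
        cols.append(seeds)
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    coo = graph.tocoo()
    aug = sparse.csr_matrix(
        (
            np.concatenate([coo.data, np.full(r.size, 1e-300)]),
            (np.concatenate([coo.row, r]), np.concatenate([coo.col, c])),
        ),
        shape=(n + k, n + k),
    )  # virtual-edge weight is effectively zero; csgraph drops exact zeros
    dist = _csgraph_dijkstra(aug, directed=False, indices=np.arange(n, n + k))
    return ids, dist[:, :n]


def dijkstra_reference(mask: np.ndarray, sources: np.ndarray, spacing) -> np.ndarray:
    """Plain heapq Dijkstra over the voxel grid (reference implementation).

    Kept deliberately independent of :func:`mask_graph` /
    scipy.sparse.csgraph so it can serve as a cross-check.
    """
    mask = np.asarray(mask, dtype=bool)
    sources = np.asarray(sources, dtype=bool)
    spacing = np.asarray(spacing, dtype=float)
    shape = mask.shape
    dist = np.full(shape, np.inf)
    heap: list[tuple[float, tuple[int, int, int]]] = []
    for idx in np.argwhere(sources):
        idx = tuple(idx)
        dist[idx] = 0.0
        heapq.heappush(heap, (0.0, idx))
    neighbours = [off for off in itertools.product((-1, 0, 1), repeat=3) if off != (0, 0, 0)]
    steps = [(off, float(np.linalg.norm(spacing * np.array(off)))) for off in neighbours]
    while heap:
        d, idx = heapq.heappop(heap)
        if d > dist[idx]:
            continue
        z, y, x = idx
        for (oz, oy, ox), w in steps:
            nz, ny, nx = z + oz, y + oy, x + ox
            if not (0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2]):
                continue
            if not mask[nz, ny, nx]:
                continue
            nd = d + w
            if nd < dist[nz, ny, nx]:
                dist[nz, ny, nx] = nd
                heapq.heappush(heap, (nd, (nz, ny, nx)))
    return dist
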