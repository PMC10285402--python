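"""Decode predicted maps into instance segmentations.

Affinity predictions go through a zwatershed-style pipeline: seed the
segmentation with connected components of the high-confidence affinity
graph, grow seeds over edges in decreasing affinity down to a low
threshold, absorb undersized fragments into their strongest-affinity
neighbor, then greedily agglomerate fragment pairs whose boundary mean
affinity clears a merge threshold.

BCD predictions use marker-based watershed: markers are connected
components of confidently-interior voxels (high binary, low contour), the
flooding surface is the inverted distance channel, and flooding is
restricted to the binary foreground.

Both decoders are deterministic; ties are broken by raster order and
output labels are canonicalized by first-voxel raster order.
"""

from __future__ import annotations

import heapq

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from skimage.segmentation import watershed

from .targets import AffinityMap, BCDTarget
from .volumes import LabelVolume


def _canonicalize(lab: np.ndarray) -> np.ndarray:
    """Relabel instances 1..k in order of first raster appearance."""
    flat = lab.ravel()
    ids, first = np.unique(flat, return_index=True)
    keep = ids > 0
    if not keep.any():
        return np.zeros_like(lab, dtype=np.int64)
    order = np.argsort(first[keep], kind="stable")
    mapping = np.zeros(int(ids.max()) + 1, dtype=np.int64)
    mapping[ids[keep][order]] = np.arange(1, int(keep.sum()) + 1)
    return mapping[flat].reshape(lab.shape)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = np.arange(n, dtype=np.int64)

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, a: int, b: int) -> int:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return ra
        if rb < ra:  # deterministic: smaller index wins
            ra, rb = rb, ra
        self.parent[rb] = ra
        return ra


def _edge_list(aff: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All graph edges as (u_index, v_index, affinity), flattened raster ids.

    Channel c at voxel v encodes the edge between v and v − e_c; each edge
    is stored once (no reciprocal averaging).
    """
    shape = aff.shape[1:]
    idx = np.arange(np.prod(shape), dtype=np.int64).reshape(shape)
    us, vs, ws = [], [], []
    for c in range(3):
        a = [slice(None)] * 3
        b = [slice(None)] * 3
        a[c] = slice(1, None)
        b[c] = slice(None, -1)
        us.append(idx[tuple(a)].ravel())
        vs.append(idx[tuple(b)].ravel())
        ws.append(aff[(c, *a)].ravel())
    return np.concatenate(us), np.concatenate(vs), np.concatenate(ws)


def zwatershed(
    aff: AffinityMap,
    t_high: float = 0.9,
    t_low: float = 0.1,
    min_size: int = 128,
    merge_threshold: float = 0.3,
) -> LabelVolume:
    """Affinity-graph watershed with size filtering and greedy agglomeration."""
    if not (0.0 <= t_low <= t_high <= 1.0):
        raise ValueError(f"need 0 <= t_low <= t_high <= 1, got {t_low}, {t_high}")
    a = aff.data
    shape = a.shape[1:]
    n_vox = int(np.prod(shape))
    u, v, w = _edge_list(a)
    strong = w >= t_high

    # 1) seeds: connected components of the graph restricted to strong edges
    graph = coo_matrix(
        (np.ones(int(strong.sum()), dtype=np.int8), (u[strong], v[strong])),
        shape=(n_vox, n_vox),
    )
    n_comp, comp = connected_components(graph, directed=False)
    seeded = np.zeros(n_comp, dtype=bool)
    seeded[comp[u[strong]]] = True

    # 2) growth: edges in decreasing affinity down to t_low; never merge two
    #    distinct seeds at this stage
    uf = _UnionFind(n_comp)
    grow = np.flatnonzero((w >= t_low) & (w < t_high))
    order = grow[np.lexsort((grow, -w[grow]))]  # stable: affinity desc, edge id asc
    cu, cv = comp[u], comp[v]
    for i in order:
        ra, rb = uf.find(int(cu[i])), uf.find(int(cv[i]))
        if ra == rb:
            continue
        if seeded[ra] and seeded[rb]:
            continue
        merged = uf.union(ra, rb)
        seeded[merged] = seeded[ra] or seeded[rb]

    # voxels that touched no edge >= t_low stay background
    live = w >= t_low
    touched = np.zeros(n_vox, dtype=bool)
    touched[u[live]] = True
    touched[v[live]] = True
    comp_root = np.array([uf.find(c) for c in range(n_comp)], dtype=np.int64)
    roots = np.where(touched, comp_root[comp], -1)

    lab = np.zeros(n_vox, dtype=np.int64)
    fg = roots >= 0
    if fg.any():
        _, lab_fg = np.unique(roots[fg], return_inverse=True)
        lab[fg] = lab_fg + 1
    lab = lab.reshape(shape)

    lab = _filter_and_agglomerate(lab, a, min_size, merge_threshold)
    return LabelVolume(_canonicalize(lab))


def _boundary_pairs(
    lab: np.ndarray, aff: np.ndarray, max_id: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Unique adjacent fragment pairs (lo < hi) with boundary affinity
    sums and counts, fully vectorized."""
    los, his, ws = [], [], []
    for c in range(3):
        a = [slice(None)] * 3
        b = [slice(None)] * 3
        a[c] = slice(1, None)
        b[c] = slice(None, -1)
        la, lb = lab[tuple(a)].ravel(), lab[tuple(b)].ravel()
        wv = aff[(c, *a)].ravel()
        sel = (la != lb) & (la > 0) & (lb > 0)
        x, y = la[sel], lb[sel]
        los.append(np.minimum(x, y))
        his.append(np.maximum(x, y))
        ws.append(wv[sel].astype(np.float64))
    lo = np.concatenate(los)
    hi = np.concatenate(his)
    w = np.concatenate(ws)
    if lo.size == 0:
        z = np.zeros(0, dtype=np.int64)
        return z, z, np.zeros(0), np.zeros(0)
    key = lo.astype(np.int64) * (max_id + 1) + hi
    uk, inv = np.unique(key, return_inverse=True)
    sums = np.bincount(inv, weights=w)
    cnts = np.bincount(inv).astype(np.float64)
    return uk // (max_id + 1), uk % (max_id + 1), sums, cnts


def _vec_roots(parent: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Vectorized union-find root lookup by pointer jumping."""
    r = parent[x]
    while True:
        rr = parent[r]
        if np.array_equal(rr, r):
            return r
        r = rr


class _RegionGraph:
    """Adjacency with boundary-affinity statistics, mergeable in O(degree).

    Each edge carries ``[sum, count, pmax]``: the summed affinity and voxel
    count of the shared boundary, plus the maximum mean over the original
    fragment-pair boundaries folded into the edge (the statistic the size
    filter ranks neighbors by).
    """

    def __init__(self, lo, hi, sums, cnts):
        self.adj: dict[int, dict[int, list[float]]] = {}
        for a, b, s, c in zip(lo.tolist(), hi.tolist(), sums.tolist(), cnts.tolist()):
            edge = [s, c, s / c]
            self.adj.setdefault(a, {})[b] = edge
            self.adj.setdefault(b, {})[a] = edge

    def neighbors(self, r: int) -> dict[int, list[float]]:
        return self.adj.get(r, {})

    def merge(self, keep: int, gone: int) -> None:
        """Fold region ``gone`` into ``keep``."""
        gone_adj = self.adj.pop(gone, {})
        keep_adj = self.adj.setdefault(keep, {})
        keep_adj.pop(gone, None)
        for x, (s, c, pmax) in gone_adj.items():
            if x == keep:
                continue
            self.adj[x].pop(gone, None)
            if x in keep_adj:
                edge = keep_adj[x]
                edge[0] += s
                edge[1] += c
                edge[2] = max(edge[2], pmax)
            else:
                edge = [s, c, pmax]
                keep_adj[x] = edge
            self.adj[x][keep] = edge


def _filter_and_agglomerate(
    lab: np.ndarray, aff: np.ndarray, min_size: int, merge_threshold: float
) -> np.ndarray:
    ids, counts = np.unique(lab[lab > 0], return_counts=True)
    if len(ids) == 0:
        return lab
    max_id = int(ids.max())
    lo, hi, sums, cnts = _boundary_pairs(lab, aff, max_id)
    graph = _RegionGraph(lo, hi, sums, cnts)
    uf = _UnionFind(max_id + 1)
    size = dict(zip(ids.tolist(), counts.tolist()))

    def union(a: int, b: int) -> int:
        keep = uf.union(a, b)
        gone = b if keep == a else a
        graph.merge(keep, gone)
        size[keep] = size.get(keep, 0) + size.pop(gone, 0)
        return keep

    # 3) size filter: undersized groups absorb into their strongest-affinity
    # neighbor, original fragments visited in ascending (size, id) order
    for i in sorted(ids.tolist(), key=lambda k: (size.get(k, 0), k)):
        ri = uf.find(i)
        if size.get(ri, 0) >= min_size:
            continue
        best = None
        for other, edge in graph.neighbors(ri).items():
            cand = (edge[2], other)
            if best is None or cand > best:
                best = cand
        if best is not None:
            union(ri, best[1])

    # 4) greedy agglomeration: repeatedly merge the adjacent pair with the
    # highest boundary mean affinity >= threshold (ties -> smallest pair),
    # statistics recomputed after every merge via a lazy heap
    heap: list[tuple[float, int, int, float, float]] = []
    for a, nbrs in graph.adj.items():
        for b, (s, c, _) in nbrs.items():
            if a < b and s / c >= merge_threshold:
                heapq.heappush(heap, (-s / c, a, b, s, c))
    while heap:
        _negm, a, b, s, c = heapq.heappop(heap)
        if uf.find(a) != a or uf.find(b) != b:
            continue
        cur = graph.neighbors(a).get(b)
        if cur is None or cur[0] != s or cur[1] != c:
            continue  # stale entry; a fresher one exists if still eligible
        keep = union(a, b)
        for x, (s2, c2, _p) in graph.neighbors(keep).items():
            if s2 / c2 >= merge_threshold:
                p, q = (keep, x) if keep < x else (x, keep)
                heapq.heappush(heap, (-s2 / c2, p, q, s2, c2))

    mapping = np.arange(max_id + 1, dtype=np.int64)
    mapping[ids] = _vec_roots(uf.parent, ids)
    out = mapping[lab]
    # drop fragments that stayed below min_size with no neighbor to join
    ids2, counts2 = np.unique(out[out > 0], return_counts=True)
    undersized = ids2[counts2 < min_size]
    if undersized.size:
        drop = np.zeros(max_id + 1, dtype=bool)
        drop[undersized] = True
        out[drop[out]] = 0
    return out


def decode_bcd(
    pred: BCDTarget,
    theta_binary: float = 0.5,
    theta_contour: float = 0.5,
    min_size: int = 64,
) -> LabelVolume:
    """Marker-based watershed decoding of binary/contour/distance maps."""
    if not (0.0 < theta_binary < 1.0 and 0.0 < theta_contour < 1.0):
        raise ValueError(
            f"thresholds must lie in (0, 1), got {theta_binary}, {theta_contour}"
        )
    binary = np.asarray(pred.binary, dtype=np.float32)
    contour = np.asarray(pred.contour, dtype=np.float32)
    distance = np.asarray(pred.distance, dtype=np.float32)
    fg = binary > theta_binary
    if not fg.any():
        return LabelVolume(np.zeros(binary.shape, dtype=np.int64))
    seeds = fg & (contour < theta_contour)
    markers, n = ndimage.label(seeds, structure=ndimage.generate_binary_structure(3, 1))
    if n == 0:
        return LabelVolume(np.zeros(binary.shape, dtype=np.int64))
    surface = 1.0 - distance if distance.max() > 0 else contour
    lab = watershed(surface, markers=markers, mask=fg)
    ids, counts = np.unique(lab[lab > 0], return_counts=True)
    for i, c in zip(ids, counts):
        if c < min_size:
            lab[lab == i] = 0
    return LabelVolume(_canonicalize(lab.astype(np.int64)))
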