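"""Subdivision of labelled surface regions into contiguous, similar-sized subparcels.

Atlas regions vary widely in surface area, which biases network measures that
treat each region as a single node. To limit this, each labelled region of a
mesh is split into subparcels of approximately ``target_vertices`` vertices
each; subparcels then serve as network nodes, and node-level results are
averaged back to regions when comparing against region-level data such as
laminar gene expression.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SurfaceMesh",
    "Parcellation",
    "subdivide",
    "parcel_centroids",
    "region_mean",
]


@dataclass
class SurfaceMesh:
    """Triangulated-sheet surface: vertex coordinates, adjacency and region labels.

    Parameters
    ----------
    coords : (V, 3) float array of vertex coordinates in mm.
    edges : (E, 2) int array of undirected vertex adjacency pairs.
    region : (V,) array of region labels (one label per vertex).
    """

    coords: np.ndarray
    edges: np.ndarray
    region: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.edges = np.asarray(self.edges, dtype=np.int64)
        self.region = np.asarray(self.region)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (V, 3)")
        v = self.n_vertices
        if self.region.shape != (v,):
            raise ValueError("one region label per vertex required")
        if self.edges.size and (self.edges.min() < 0 or self.edges.max() >= v):
            raise ValueError("edge endpoint out of range")

    @property
    def n_vertices(self) -> int:
        return self.coords.shape[0]

    @property
    def regions(self) -> np.ndarray:
        return np.unique(self.region)

    def adjacency_lists(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_vertices)]
        for a, b in self.edges:
            if a != b:
                adj[a].append(int(b))
                adj[b].append(int(a))
        return adj


@dataclass
class Parcellation:
    """An exact partition of mesh vertices into contiguous subparcels.

    ``labels[v]`` is the subparcel id of vertex ``v`` (ids are dense,
    ``0..n_subparcels-1``); ``subparcel_region[s]`` gives the region each
    subparcel belongs to.
    """

    labels: np.ndarray
    subparcel_region: np.ndarray
    counts: np.ndarray = field(default=None)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subparcel_region = np.asarray(self.subparcel_region)
        n_sub = len(self.subparcel_region)
        if self.labels.min(initial=0) < 0 or (
            self.labels.size and self.labels.max() >= n_sub
        ):
            raise ValueError("subparcel label out of range")
        if self.counts is None:
            self.counts = np.bincount(self.labels, minlength=n_sub)
        self.counts = np.asarray(self.counts, dtype=np.int64)

    @property
    def n_subparcels(self) -> int:
        return len(self.subparcel_region)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "vertex_id": np.arange(len(self.labels)),
                "subparcel_id": self.labels,
                "region_id": self.subparcel_region[self.labels],
            }
        )


def _components(members: np.ndarray, adj: list[list[int]]) -> int:
    """Number of connected components of the subgraph induced by `members`."""
    member_set = set(int(m) for m in members)
    seen: set[int] = set()
    n_comp = 0
    for start in members:
        start = int(start)
        if start in seen:
            continue
        n_comp += 1
        stack = [start]
        seen.add(start)
        while stack:
            u = stack.pop()
            for w in adj[u]:
                if w in member_set and w not in seen:
                    seen.add(w)
                    stack.append(w)
    return n_comp


def _bfs_hops(sources: list[int], member_set: set[int], adj) -> dict[int, int]:
    dist = {s: 0 for s in sources}
    frontier = list(sources)
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for w in adj[u]:
                if w in member_set and w not in dist:
                    dist[w] = d
                    nxt.append(w)
        frontier = nxt
    return dist


def subdivide(mesh: SurfaceMesh, target_vertices: int, seed: int = 0) -> Parcellation:
    """Split every region into ``round(v / target_vertices)`` contiguous subparcels.

    Each region with ``v`` vertices is divided into ``max(1, round(v/target))``
    subparcels by farthest-point seeding on hop distance followed by
    competitive balanced growth (the smallest subparcel claims the next
    adjacent unassigned vertex). Subparcels are contiguous by construction and,
    within a region, near-equal in size.

    Raises
    ------
    ValueError
        if ``target_vertices < 1`` or a region's vertices are disconnected
        in the mesh adjacency (the offending region is named).
    """
    if target_vertices < 1:
        raise ValueError("target_vertices must be >= 1")
    rng = np.random.default_rng(seed)
    adj = mesh.adjacency_lists()
    labels = np.full(mesh.n_vertices, -1, dtype=np.int64)
    sub_region: list = []
    next_id = 0
    for reg in mesh.regions:
        members = np.flatnonzero(mesh.region == reg)
        member_set = set(int(m) for m in members)
        if _components(members, adj) != 1:
            raise ValueError(f"region {reg!r} has a disconnected vertex set")
        v = len(members)
        n_sub = max(1, int(np.floor(v / target_vertices + 0.5)))
        if n_sub == 1:
            labels[members] = next_id
            sub_region.append(reg)
            next_id += 1
            continue

        # farthest-point seeding on hop distance
        seeds = [int(rng.choice(members))]
        while len(seeds) < n_sub:
            dist = _bfs_hops(seeds, member_set, adj)
            far = max(member_set, key=lambda u: (dist.get(u, -1), -u))
            if far in seeds:
                break
            seeds.append(far)
        n_sub = len(seeds)

        # competitive balanced growth: the currently smallest parcel pops the
        # nearest unassigned vertex from its frontier heap
        local = {int(m): -1 for m in members}
        heaps: list[list[tuple[int, int]]] = [[] for _ in range(n_sub)]
        sizes = np.zeros(n_sub, dtype=int)
        for i, s in enumerate(seeds):
            heapq.heappush(heaps[i], (0, s))
        n_assigned = 0
        alive = set(range(n_sub))
        while n_assigned < v and alive:
            order = sorted(alive, key=lambda i: (sizes[i], i))
            progressed = False
            for i in order:
                h = heaps[i]
                got = None
                while h:
                    d, u = heapq.heappop(h)
                    if local[u] == -1:
                        got = (d, u)
                        break
                if got is None:
                    alive.discard(i)
                    continue
                d, u = got
                local[u] = i
                sizes[i] += 1
                n_assigned += 1
                for w in adj[u]:
                    if w in member_set and local[w] == -1:
                        heapq.heappush(h, (d + 1, w))
                progressed = True
                break
            if not progressed and not alive:
                break
        # connected region + frontier growth guarantees full assignment
        assert n_assigned == v, "internal error: region not fully assigned"

        _rebalance(local, sizes, adj, member_set)

        for u, i in local.items():
            labels[u] = next_id + i
        sub_region.extend([reg] * n_sub)
        next_id += n_sub

    return Parcellation(labels=labels, subparcel_region=np.asarray(sub_region))


def _rebalance(local: dict[int, int], sizes: np.ndarray, adj, member_set: set[int],
               max_ratio: float = 2.0, max_moves: int = 10000) -> None:
    """Move boundary vertices from large to small subparcels until the
    max/min size ratio within the region is <= max_ratio (best effort)."""
    n_sub = len(sizes)
    if n_sub < 2:
        return
    for _ in range(max_moves):
        small = int(np.argmin(sizes))
        big = int(np.argmax(sizes))
        if sizes[big] <= max_ratio * sizes[small]:
            return
        moved = False
        # boundary vertices of a larger parcel adjacent to the smallest parcel
        for u, lab in sorted(local.items()):
            if lab == small or sizes[lab] <= sizes[small] + 1:
                continue
            if not any(local.get(w, -2) == small for w in adj[u] if w in member_set):
                continue
            donor = [x for x, l2 in local.items() if l2 == lab and x != u]
            if donor and _components(np.asarray(donor), adj) != 1:
                continue
            local[u] = small
            sizes[lab] -= 1
            sizes[small] += 1
            moved = True
            break
        if not moved:
            return


def parcel_centroids(mesh: SurfaceMesh, parc: Parcellation) -> np.ndarray:
    """Arithmetic-mean coordinate of each subparcel's member vertices (mm)."""
    if len(parc.labels) != mesh.n_vertices:
        raise ValueError("parcellation does not match mesh")
    n_sub = parc.n_subparcels
    if np.any(parc.counts == 0):
        raise ValueError("empty subparcel")
    out = np.zeros((n_sub, 3))
    for d in range(3):
        out[:, d] = np.bincount(
            parc.labels, weights=mesh.coords[:, d], minlength=n_sub
        ) / parc.counts
    return out


def region_mean(values: np.ndarray, parc: Parcellation) -> pd.Series:
    """Unweighted mean of a subparcel-level vector within each region."""
    values = np.asarray(values, dtype=float)
    if values.shape != (parc.n_subparcels,):
        raise ValueError(
            f"expected one value per subparcel ({parc.n_subparcels}), "
            f"got shape {values.shape}"
        )
    s = pd.Series(values).groupby(pd.Series(parc.subparcel_region)).mean()
    s.index.name = "region"
    return s
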