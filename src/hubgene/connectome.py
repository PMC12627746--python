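"""Group consensus structural networks and cohort robustness summaries.

A cohort of per-subject weighted connectomes is reduced to a single binary
group network by keeping connections that are (i) present in more than a
given fraction of subjects and (ii) among the strongest by mean weight, up to
a target connection density. Node degree in this consensus network is the
basis for hub detection downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from ._utils import as_symmetric_weights

__all__ = [
    "SubjectConnectome",
    "GroupConsensus",
    "build_consensus",
    "node_degree",
    "edge_lengths",
    "classify_edges",
    "subsample_stability",
    "individual_hubness",
]


@dataclass
class SubjectConnectome:
    """One subject's symmetric weighted adjacency with node metadata."""

    weights: np.ndarray
    node_ids: np.ndarray = None
    coords: np.ndarray = None
    region: np.ndarray = None

    def __post_init__(self):
        self.weights = as_symmetric_weights(np.asarray(self.weights, dtype=float))
        n = self.n_nodes
        if self.node_ids is None:
            self.node_ids = np.arange(n)
        self.node_ids = np.asarray(self.node_ids)
        if len(self.node_ids) != n:
            raise ValueError("node_ids length mismatch")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (n, 3):
                raise ValueError("coords must be (n_nodes, 3)")
        if self.region is not None:
            self.region = np.asarray(self.region)
            if len(self.region) != n:
                raise ValueError("region length mismatch")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def binary_degree(self) -> np.ndarray:
        return (self.weights > 0).sum(axis=0)


def _as_weight_stack(subjects) -> tuple[np.ndarray, "SubjectConnectome | None"]:
    """Stack subject weight matrices into (S, n, n); return first subject's metadata."""
    first_meta = None
    mats = []
    node_ids = None
    for s in subjects:
        if isinstance(s, SubjectConnectome):
            if first_meta is None:
                first_meta = s
            if node_ids is None:
                node_ids = s.node_ids
            elif not np.array_equal(node_ids, s.node_ids):
                raise ValueError("subjects have mismatched node sets")
            mats.append(s.weights)
        else:
            mats.append(as_symmetric_weights(np.asarray(s, dtype=float)))
    w = np.stack(mats)
    if len({m.shape for m in mats}) != 1:
        raise ValueError("subjects have mismatched node sets")
    return w, first_meta


class GroupConsensus(BaseEstimator):
    """Binary group consensus network from a cohort of weighted connectomes.

    Parameters
    ----------
    presence_threshold : float, default 0.30
        Candidate edges must be present (weight > 0) in strictly more than
        this fraction of subjects.
    density : float, default 0.15
        Target connection density: among candidates, the top
        ``floor(density * n*(n-1)/2)`` edges by mean weight (mean across all
        subjects, zeros included) are retained. Ties at the cutoff are broken
        deterministically by the lower (i, j) node-id pair.

    Attributes
    ----------
    adjacency_ : (n, n) bool array — retained edges.
    mean_weight_ : (n, n) float array — mean weight of retained edges, 0 elsewhere.
    presence_ : (n, n) float array — fraction of subjects with each edge (audit).
    degree_ : (n,) int array — binary node degree.
    edges_ : (E, 2) int array — retained edges, i < j.
    density_ : float — achieved density.
    """

    def __init__(self, presence_threshold: float = 0.30, density: float = 0.15):
        self.presence_threshold = presence_threshold
        self.density = density

    def fit(self, X, y=None):
        if not (0 <= self.presence_threshold <= 1) or not (0 < self.density <= 1):
            raise ValueError("presence_threshold and density must be proportions")
        if len(X) < 2:
            raise ValueError("need at least 2 subjects")
        w, meta = _as_weight_stack(X)
        n_subj, n, _ = w.shape
        presence = (w > 0).mean(axis=0)
        mean_w = w.mean(axis=0)

        iu, ju = np.triu_indices(n, k=1)
        cand = presence[iu, ju] > self.presence_threshold
        n_pairs = n * (n - 1) // 2
        target = int(np.floor(self.density * n_pairs))
        ci, cj = iu[cand], ju[cand]
        cw = mean_w[ci, cj]
        if cand.sum() < target:
            warnings.warn(
                f"only {int(cand.sum())} candidate edges survive the presence "
                f"threshold; target was {target} — retaining all candidates",
                stacklevel=2,
            )
            keep = slice(None)
        else:
            order = np.lexsort((cj, ci, -cw))
            keep = order[:target]
        ei, ej = ci[keep], cj[keep]

        adj = np.zeros((n, n), dtype=bool)
        adj[ei, ej] = adj[ej, ei] = True
        mw = np.zeros((n, n))
        mw[ei, ej] = mw[ej, ei] = mean_w[ei, ej]

        self.n_nodes_ = n
        self.n_subjects_ = n_subj
        self.adjacency_ = adj
        self.mean_weight_ = mw
        self.presence_ = presence
        order_e = np.lexsort((ej, ei))
        self.edges_ = np.column_stack([ei, ej])[order_e]
        self.degree_ = adj.sum(axis=0).astype(int)
        self.n_edges_ = len(ei)
        self.density_ = self.n_edges_ / n_pairs
        if meta is not None:
            self.node_ids_ = meta.node_ids
            self.coords_ = meta.coords
            self.region_ = meta.region
        else:
            self.node_ids_ = np.arange(n)
            self.coords_ = None
            self.region_ = None
        return self

    def to_dict(self) -> dict:
        d = {
            "n_nodes": int(self.n_nodes_),
            "edges": self.edges_.tolist(),
            "mean_weights": [float(self.mean_weight_[i, j]) for i, j in self.edges_],
            "presence": [float(self.presence_[i, j]) for i, j in self.edges_],
            "degree": self.degree_.tolist(),
            "params": {
                "presence_threshold": self.presence_threshold,
                "density": self.density,
            },
            "density": float(self.density_),
        }
        if self.coords_ is not None:
            d["coords"] = np.asarray(self.coords_).tolist()
        if self.region_ is not None:
            d["region"] = np.asarray(self.region_).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroupConsensus":
        est = cls(**d.get("params", {}))
        n = d["n_nodes"]
        edges = np.asarray(d["edges"], dtype=np.int64).reshape(-1, 2)
        adj = np.zeros((n, n), dtype=bool)
        mw = np.zeros((n, n))
        pres = np.zeros((n, n))
        for (i, j), w, p in zip(edges, d["mean_weights"], d["presence"]):
            adj[i, j] = adj[j, i] = True
            mw[i, j] = mw[j, i] = w
            pres[i, j] = pres[j, i] = p
        est.n_nodes_ = n
        est.adjacency_ = adj
        est.mean_weight_ = mw
        est.presence_ = pres
        est.edges_ = edges
        est.degree_ = adj.sum(axis=0).astype(int)
        est.n_edges_ = len(edges)
        est.density_ = d.get("density", est.n_edges_ / (n * (n - 1) / 2))
        est.node_ids_ = np.arange(n)
        est.coords_ = np.asarray(d["coords"]) if "coords" in d else None
        est.region_ = np.asarray(d["region"]) if "region" in d else None
        return est


def build_consensus(
    subjects, presence_threshold: float = 0.30, density: float = 0.15
) -> GroupConsensus:
    """Fit and return a :class:`GroupConsensus` network (thin wrapper)."""
    return GroupConsensus(presence_threshold, density).fit(subjects)


def node_degree(net: GroupConsensus) -> np.ndarray:
    """Binary node degree of the consensus network."""
    return net.adjacency_.sum(axis=0).astype(int)


def edge_lengths(net: GroupConsensus, centroids: np.ndarray = None) -> np.ndarray:
    """Euclidean distance (mm) between edge endpoint centroids, per retained edge."""
    if centroids is None:
        centroids = net.coords_
    if centroids is None:
        raise ValueError("no coordinates available")
    centroids = np.asarray(centroids, dtype=float)
    if centroids.shape[0] < net.n_nodes_ or np.any(~np.isfinite(centroids)):
        raise ValueError("missing coordinate for one or more nodes")
    i, j = net.edges_.T
    return np.linalg.norm(centroids[i] - centroids[j], axis=1)


def classify_edges(net: GroupConsensus, hub_mask: np.ndarray) -> np.ndarray:
    """Label each retained edge rich (hub–hub), feeder (hub–nonhub) or local."""
    hub_mask = np.asarray(hub_mask, dtype=bool)
    if hub_mask.shape != (net.n_nodes_,):
        raise ValueError("hub_mask length must equal node count")
    i, j = net.edges_.T
    n_hub_ends = hub_mask[i].astype(int) + hub_mask[j].astype(int)
    return np.array(["local", "feeder", "rich"])[n_hub_ends]


def subsample_stability(
    subjects,
    sizes,
    n_reps: int,
    reference_degree: np.ndarray,
    consensus_params: dict | None = None,
    seed: int = 0,
):
    """Stability of consensus degree under random cohort subsampling.

    For each subsample size, draws ``n_reps`` subject subsets without
    replacement, rebuilds the consensus network, and Pearson-correlates its
    degree vector with ``reference_degree``. Returns a dict
    ``{size: (mean_r, sd_r)}``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    params = consensus_params or {}
    ref = np.asarray(reference_degree, dtype=float)
    rng = np.random.default_rng(seed)
    n_cohort = len(subjects)
    out = {}
    for size in sizes:
        if size > n_cohort:
            raise ValueError(f"subsample size {size} exceeds cohort size {n_cohort}")
        rs = []
        for _ in range(n_reps):
            idx = rng.choice(n_cohort, size=size, replace=False)
            net = build_consensus([subjects[k] for k in idx], **params)
            d = net.degree_.astype(float)
            rs.append(float(np.corrcoef(d, ref)[0, 1]))
        rs = np.asarray(rs)
        out[int(size)] = (float(rs.mean()), float(rs.std()))
    return out


def individual_hubness(subjects, percentile: float = 90) -> np.ndarray:
    """Fraction of subjects in which each node is an individual-network hub.

    Per subject, hubs are nodes whose binary degree strictly exceeds that
    subject's ``percentile``-th degree percentile (linear interpolation).
    """
    if len(subjects) < 1:
        raise ValueError("need at least 1 subject")
    w, _ = _as_weight_stack(subjects)
    deg = (w > 0).sum(axis=2)  # (S, n)
    thr = np.percentile(deg, percentile, axis=1, keepdims=True)
    return (deg > thr).mean(axis=0)
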