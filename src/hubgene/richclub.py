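"""Rich-club statistics, degree-preserving nulls and hub identification.

The rich-club coefficient at degree threshold k,

    phi(k) = 2 * E_{>k} / (N_{>k} * (N_{>k} - 1)),

is the density of the subnetwork induced by nodes with degree strictly greater
than k. Because high-degree nodes connect to each other by chance more often
than low-degree ones, phi(k) is normalised against degree-sequence-preserving
rewired nulls: phi_norm(k) = phi(k) / <phi_rand(k)>, with an empirical one-sided
p-value per k. Hubs are nodes whose degree exceeds a percentile of the degree
distribution (90th by default); the rich-club curve is reported alongside so
users can confirm the hub regime coincides with phi_norm(k) > 1.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator

from ._utils import check_adjacency, rng_for

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f

        return deco if not (a and callable(a[0])) else a[0]

__all__ = [
    "phi",
    "rich_club_curve",
    "rewire_null",
    "phi_norm",
    "identify_hubs",
    "hubness_index",
    "RichClub",
]


def _as_binary(net) -> np.ndarray:
    if hasattr(net, "adjacency_"):
        net = net.adjacency_
    a = check_adjacency(np.asarray(net))
    return a > 0


def phi(net, k: int) -> float:
    """Rich-club coefficient at a single degree threshold.

    Returns NaN (undefined) when fewer than two nodes have degree > k.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    a = _as_binary(net)
    deg = a.sum(axis=0)
    keep = deg > k
    n_keep = int(keep.sum())
    if n_keep < 2:
        return float("nan")
    e = int(a[np.ix_(keep, keep)].sum()) // 2
    return 2.0 * e / (n_keep * (n_keep - 1))


def rich_club_curve(net) -> tuple[np.ndarray, np.ndarray]:
    """phi(k) for k = 0 .. max_degree - 1 in one vectorised pass.

    Returns ``(k_grid, phi_values)`` with NaN where fewer than two nodes
    exceed k.
    """
    a = _as_binary(net)
    deg = a.sum(axis=0)
    iu, ju = np.nonzero(np.triu(a, k=1))
    kmax = int(deg.max(initial=0))
    ks = np.arange(max(kmax, 1))
    # N_{>k}: nodes with degree > k; E_{>k}: edges whose endpoint min degree > k
    n_gt = (deg[None, :] > ks[:, None]).sum(axis=1).astype(float)
    if len(iu):
        edge_min = np.minimum(deg[iu], deg[ju])
        e_gt = (edge_min[None, :] > ks[:, None]).sum(axis=1).astype(float)
    else:
        e_gt = np.zeros_like(ks, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = 2.0 * e_gt / (n_gt * (n_gt - 1.0))
    vals[n_gt < 2] = np.nan
    return ks, vals


@njit(cache=True)
def _swap_kernel(adj, edges, n_attempts, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    n_edges = edges.shape[0]
    for _ in range(n_attempts):
        e1 = np.random.randint(n_edges)
        e2 = np.random.randint(n_edges)
        if e1 == e2:
            continue
        a, b = edges[e1, 0], edges[e1, 1]
        c, d = edges[e2, 0], edges[e2, 1]
        if np.random.randint(2) == 1:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = adj[b, a] = False
        adj[c, d] = adj[d, c] = False
        adj[a, d] = adj[d, a] = True
        adj[c, b] = adj[b, c] = True
        edges[e1, 0] = a
        edges[e1, 1] = d
        edges[e2, 0] = c
        edges[e2, 1] = b


def _rewire_one(a: np.ndarray, swaps_per_edge: int, seed: int) -> np.ndarray:
    adj = a.copy()
    iu, ju = np.nonzero(np.triu(adj, k=1))
    edges = np.column_stack([iu, ju]).astype(np.int64)
    n_attempts = int(swaps_per_edge) * len(edges)
    if len(edges) >= 2:
        _swap_kernel(adj, edges, n_attempts, seed)
    return adj


def rewire_null(
    net, n_nulls: int = 100, swaps_per_edge: int = 50, seed: int = 0
) -> list[np.ndarray]:
    """Degree-preserving rewired null ensemble (Maslov–Sneppen double-edge swap).

    Each null performs ``swaps_per_edge * n_edges`` swap *attempts*; attempts
    that would create a self-loop or multi-edge are rejected, so every null is
    a simple graph with exactly the original degree sequence. Graphs admitting
    no valid swap (e.g. a triangle) come back unchanged.
    """
    a = _as_binary(net)
    if int(np.triu(a, k=1).sum()) < 2:
        raise ValueError("need at least 2 edges to rewire")
    rng = rng_for(seed, "rewire")
    seeds = rng.integers(0, 2**31 - 1, size=n_nulls)
    return [_rewire_one(a, swaps_per_edge, int(s)) for s in seeds]


def phi_norm(net, nulls) -> dict:
    """Normalised rich-club curve against a null ensemble.

    Returns a dict with ``k``, ``phi``, ``phi_rand_mean``, ``phi_norm`` and the
    per-k empirical p-value ``(1 + #{phi_rand >= phi}) / (1 + n_nulls)``.
    phi_norm and p are NaN where phi is undefined or the null mean is zero.
    """
    ks, emp = rich_club_curve(net)
    null_curves = np.full((len(nulls), len(ks)), np.nan)
    for i, nn in enumerate(nulls):
        nk, nv = rich_club_curve(nn)
        null_curves[i, : min(len(nv), len(ks))] = nv[: len(ks)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        null_mean = (
            np.nanmean(null_curves, axis=0) if len(nulls) else np.full_like(emp, np.nan)
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = emp / null_mean
    norm[~np.isfinite(norm)] = np.nan
    n_nulls = len(nulls)
    with np.errstate(invalid="ignore"):
        n_ge = np.nansum(null_curves >= emp[None, :], axis=0)
    p = (1.0 + n_ge) / (1.0 + n_nulls)
    bad = np.isnan(emp) | np.isnan(null_mean) | (null_mean == 0)
    p = np.where(bad, np.nan, p)
    norm = np.where(bad, np.nan, norm)
    return {
        "k": ks,
        "phi": emp,
        "phi_rand_mean": null_mean,
        "phi_norm": norm,
        "p": p,
    }


def identify_hubs(degree: np.ndarray, percentile: float = 90.0):
    """Hub mask and threshold: nodes with degree strictly above the percentile.

    The threshold is the ``percentile``-th percentile of the degree vector
    under linear interpolation; ties at the threshold are not hubs.
    Returns ``(hub_mask, threshold)``.
    """
    degree = np.asarray(degree, dtype=float)
    if degree.size == 0:
        raise ValueError("empty degree vector")
    thr = float(np.percentile(degree, percentile))
    return degree > thr, thr


def hubness_index(hub_mask: np.ndarray, parc) -> "pd.Series":
    """Per-region hubness RC%: fraction of a region's subparcels that are hubs."""
    import pandas as pd

    hub_mask = np.asarray(hub_mask, dtype=bool)
    if hub_mask.shape != (parc.n_subparcels,):
        raise ValueError("hub_mask length must equal subparcel count")
    if np.any(parc.counts == 0):
        raise ValueError("region with zero subparcels")
    s = pd.Series(hub_mask.astype(float)).groupby(
        pd.Series(parc.subparcel_region)
    ).mean()
    s.index.name = "region"
    s.name = "RC%"
    return s


class RichClub(BaseEstimator):
    """Rich-club analysis of a binary network with rewired nulls.

    Parameters
    ----------
    n_nulls : int, default 100
        Number of degree-preserving null networks.
    swaps_per_edge : int, default 50
        Swap attempts per edge when rewiring each null.
    percentile : float, default 90
        Degree percentile above which nodes are designated hubs.
    random_state : int, default 0

    Attributes (after ``fit``)
    --------------------------
    k_, phi_, phi_rand_mean_, phi_norm_, pvalues_ : per-k curves.
    hub_threshold_ : float — the degree percentile value.
    hub_mask_ : (n,) bool — degree strictly above the threshold.
    """

    def __init__(
        self,
        n_nulls: int = 100,
        swaps_per_edge: int = 50,
        percentile: float = 90.0,
        random_state: int = 0,
    ):
        self.n_nulls = n_nulls
        self.swaps_per_edge = swaps_per_edge
        self.percentile = percentile
        self.random_state = random_state

    def fit(self, X, y=None):
        a = _as_binary(X)
        nulls = rewire_null(
            a, self.n_nulls, self.swaps_per_edge, seed=self.random_state
        )
        res = phi_norm(a, nulls)
        deg = a.sum(axis=0).astype(int)
        mask, thr = identify_hubs(deg, self.percentile)
        self.degree_ = deg
        self.k_ = res["k"]
        self.phi_ = res["phi"]
        self.phi_rand_mean_ = res["phi_rand_mean"]
        self.phi_norm_ = res["phi_norm"]
        self.pvalues_ = res["p"]
        self.hub_threshold_ = thr
        self.hub_mask_ = mask
        return self

    def to_dict(self) -> dict:
        def _lst(x):
            return [None if not np.isfinite(v) else float(v) for v in x]

        return {
            "k": self.k_.tolist(),
            "phi": _lst(self.phi_),
            "phi_rand_mean": _lst(self.phi_rand_mean_),
            "phi_norm": _lst(self.phi_norm_),
            "p": _lst(self.pvalues_),
            "hub_threshold": float(self.hub_threshold_),
            "hub_mask": self.hub_mask_.astype(int).tolist(),
            "degree": self.degree_.tolist(),
            "params": {
                "n_nulls": self.n_nulls,
                "swaps_per_edge": self.swaps_per_edge,
                "percentile": self.percentile,
                "seed": self.random_state,
            },
        }
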