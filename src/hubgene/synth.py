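"""Synthetic inputs with the statistical structure the analysis assumes.

Every downstream stage of the pipeline — parcellation, consensus networks,
rich-club detection, expression QC, degree association and enrichment — can be
exercised end-to-end on data generated here, without any imaging or microarray
downloads. The generators plant known structure (a densely interconnected
network core; genes whose zonal expression tracks node degree; gene sets with
fixed overlaps; cells whose geneset score rises with pseudotime) and return a
:class:`SyntheticTruth` record for recovery checks.

All generators are pure functions of their arguments including ``seed``: the
single integer seed is split into labelled substreams so each artefact is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from ._utils import rng_for
from .connectome import SubjectConnectome
from .parcellation import SurfaceMesh

__all__ = [
    "ZONES",
    "SyntheticTruth",
    "gen_surface",
    "gen_cohort_connectomes",
    "gen_expression_dataset",
    "gen_gene_sets",
    "gen_cells",
    "gaussian_random_field",
    "gen_spatial_map",
]

#: Transient laminar compartments of the fetal brain, outer to inner:
#: cortical plate, subplate, intermediate, subventricular, ventricular zone.
ZONES = ("CP", "SP", "IZ", "SVZ", "VZ")

#: Default specimens: two mid-gestation age groups (~15/16 and 21 post-conception
#: weeks), two specimens per group so same-age pairs exist for stability checks
#: and the age covariate is estimable.
DEFAULT_SPECIMENS = (("S1", 16.0), ("S2", 16.0), ("S3", 21.0), ("S4", 21.0))


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators.

    planted_core_nodes : node ids forming the densely interconnected core.
    planted_gene_effects : gene -> (zone, true degree slope).
    noise_correlation_length : length scale (same units as coordinates) of the
        spatially correlated expression noise field.
    specimen_ages : ages in post-conception weeks of the simulated specimens.
    """

    planted_core_nodes: frozenset = frozenset()
    planted_gene_effects: dict = field(default_factory=dict)
    noise_correlation_length: float = float("nan")
    specimen_ages: tuple = ()
    # non-serialised extras for tests / pipelines
    template_adjacency: np.ndarray = None
    template_weights: np.ndarray = None
    region_coords: np.ndarray = None
    regions: tuple = ()

    def __post_init__(self):
        if any(a <= 0 for a in self.specimen_ages):
            raise ValueError("specimen ages must be positive")

    def to_dict(self) -> dict:
        return {
            "planted_core_nodes": sorted(int(i) for i in self.planted_core_nodes),
            "planted_gene_effects": {
                g: [z, float(b)] for g, (z, b) in self.planted_gene_effects.items()
            },
            "noise_correlation_length": float(self.noise_correlation_length),
            "specimen_ages": list(self.specimen_ages),
        }


def gen_surface(n_regions: int, vertices_per_region: int, seed: int = 0) -> SurfaceMesh:
    """Generate a labelled triangulated sheet embedded in 3D.

    Regions are laid out as a near-square block grid of rectangular vertex
    patches; within-region adjacency is a grid triangulation and neighbouring
    regions are stitched along their shared border, so the sheet is connected
    and every region's vertex set is connected.
    """
    if n_regions < 1 or vertices_per_region < 1:
        raise ValueError("n_regions and vertices_per_region must be >= 1")
    rng = rng_for(seed, "surface")
    spacing = 2.0  # mm between neighbouring vertices
    vpr = vertices_per_region
    cols = int(np.ceil(np.sqrt(vpr)))
    rows = int(np.ceil(vpr / cols))
    reg_cols = int(np.ceil(np.sqrt(n_regions)))

    coords = np.zeros((n_regions * vpr, 3))
    region = np.zeros(n_regions * vpr, dtype=np.int64)
    edges: list[tuple[int, int]] = []

    def vid(reg: int, k: int) -> int:
        return reg * vpr + k

    for g in range(n_regions):
        gr, gc = divmod(g, reg_cols)
        x0 = gc * (cols + 1) * spacing
        y0 = gr * (rows + 1) * spacing
        for k in range(vpr):
            r, c = divmod(k, cols)
            x = x0 + c * spacing
            y = y0 + r * spacing
            z = 5.0 * np.sin(x / 40.0) + 5.0 * np.cos(y / 40.0)
            coords[vid(g, k)] = (x, y, z)
            region[vid(g, k)] = g
            # grid triangulation within the region
            if c + 1 < cols and k + 1 < vpr:
                edges.append((vid(g, k), vid(g, k + 1)))
            if k + cols < vpr:
                edges.append((vid(g, k), vid(g, k + cols)))
            if c + 1 < cols and k + cols + 1 < vpr:
                edges.append((vid(g, k), vid(g, k + cols + 1)))
    # stitch neighbouring regions
    for g in range(n_regions):
        gr, gc = divmod(g, reg_cols)
        if gc + 1 < reg_cols and g + 1 < n_regions:  # right neighbour
            for r in range(rows):
                a, b = r * cols + (cols - 1), r * cols
                if a < vpr and b < vpr:
                    edges.append((vid(g, a), vid(g + 1, b)))
        if g + reg_cols < n_regions:  # lower neighbour
            for c in range(cols):
                a, b = (rows - 1) * cols + c, c
                if a >= vpr:
                    a -= cols  # partial last row: use the row above
                if a >= 0 and b < vpr:
                    edges.append((vid(g, a), vid(g + reg_cols, b)))

    coords += rng.uniform(-0.1, 0.1, size=coords.shape)  # break exact ties
    return SurfaceMesh(coords=coords, edges=np.asarray(edges), region=region)


def gaussian_random_field(
    coords: np.ndarray,
    length: float,
    rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Draw zero-mean unit-variance Gaussian fields with exponential covariance.

    Covariance between locations i, j is ``exp(-d_ij / length)``. Returns an
    array of shape ``(n_locations, size)``. ``length -> 0`` degenerates to
    independent noise.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = coords.shape[0]
    if length <= 1e-12:
        return rng.standard_normal((n, size))
    d = cdist(coords, coords)
    cov = np.exp(-d / length) + 1e-9 * np.eye(n)
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal((n, size))


def gen_spatial_map(
    coords: np.ndarray, sac_length: float, low: float, high: float, seed: int = 0
) -> np.ndarray:
    """A single spatially autocorrelated map rescaled to the range [low, high]."""
    rng = rng_for(seed, "spatial_map")
    f = gaussian_random_field(coords, sac_length, rng, size=1)[:, 0]
    lo, hi = f.min(), f.max()
    if hi - lo < 1e-12:
        return np.full_like(f, (low + high) / 2.0)
    return low + (f - lo) * (high - low) / (hi - lo)


def gen_cohort_connectomes(
    n_subjects: int,
    n_nodes: int = 200,
    core_size: int = 20,
    distance_decay: float = 15.0,
    core_boost: float = 8.0,
    subject_noise: float = 0.1,
    seed: int = 0,
    coords: np.ndarray = None,
    core_nodes=None,
    region: np.ndarray = None,
    weight_scale: float = 1.0,
):
    """Generate a cohort of noisy subject connectomes with a planted core.

    A group template is sampled once: nodes live in 3D space, edge probability
    decays exponentially with Euclidean distance (``exp(-d/distance_decay)``)
    and is multiplied by ``core_boost`` (capped at 1) among the ``core_size``
    core nodes, a random subset, so the planted rich club spans the whole
    sheet as cortical hubs span distributed areas. Template edge weights are
    ``probability * (1 + U(0,1))``, keeping weight ordering correlated with
    connection probability as in streamline-count data. Each subject flips
    every node pair's presence independently with rate ``subject_noise``
    (consistent template edges survive; spurious weak edges appear) and jitters
    surviving weights log-normally with the same rate, so ``subject_noise=0``
    reproduces the template exactly.

    Returns ``(subjects, truth)``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if core_size >= n_nodes:
        raise ValueError("core_size must be < n_nodes")
    if not (0 <= subject_noise <= 1):
        raise ValueError("subject_noise must be in [0, 1]")
    rng_c = rng_for(seed, "cohort", "coords")
    rng_t = rng_for(seed, "cohort", "template")
    rng_s = rng_for(seed, "cohort", "subjects")

    if coords is None:
        coords = rng_c.uniform(0.0, 100.0, size=(n_nodes, 3))
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (n_nodes, 3):
        raise ValueError("coords must be (n_nodes, 3)")

    if core_nodes is None and core_size > 0:
        core_nodes = rng_t.choice(n_nodes, size=core_size, replace=False)
    if core_nodes is None:
        core_nodes = []
    core_nodes = np.asarray(sorted(int(i) for i in np.atleast_1d(core_nodes)), dtype=int)

    iu, ju = np.triu_indices(n_nodes, k=1)
    d = np.linalg.norm(coords[iu] - coords[ju], axis=1)
    p = np.exp(-d / distance_decay)
    in_core = np.zeros(n_nodes, dtype=bool)
    in_core[core_nodes] = True
    core_pair = in_core[iu] & in_core[ju]
    p = np.where(core_pair, np.minimum(1.0, p * core_boost), p)

    present = rng_t.random(len(p)) < p
    tw = np.where(present, p * (1.0 + rng_t.random(len(p))) * weight_scale, 0.0)

    template = np.zeros((n_nodes, n_nodes))
    template[iu, ju] = template[ju, iu] = tw

    subjects = []
    for _ in range(n_subjects):
        flip = rng_s.random(len(p)) < subject_noise
        pres_s = present ^ flip
        jitter = np.exp(subject_noise * rng_s.standard_normal(len(p)))
        spurious_w = 0.1 * weight_scale * rng_s.random(len(p))
        w = np.where(pres_s, np.where(present, tw * jitter, spurious_w), 0.0)
        mat = np.zeros((n_nodes, n_nodes))
        mat[iu, ju] = mat[ju, iu] = w
        subjects.append(
            SubjectConnectome(weights=mat, coords=coords.copy(), region=region)
        )

    truth = SyntheticTruth(
        planted_core_nodes=frozenset(int(i) for i in core_nodes),
        template_adjacency=(template > 0),
        template_weights=template,
    )
    return subjects, truth


def gen_expression_dataset(
    degree_map,
    n_genes: int,
    frac_assoc: float = 0.15,
    beta_range: tuple = (0.004, 0.02),
    zones=ZONES,
    specimens=DEFAULT_SPECIMENS,
    sac_length: float = 30.0,
    region_coords: np.ndarray = None,
    probes_per_gene: int = 2,
    absent_rate: float = 0.1,
    missing_rate: float = 0.02,
    seed: int = 0,
    noise_sd: float = 0.1,
    shared_sd: float = 0.5,
    shared_spatial_frac: float = 0.3,
    specimen_sd: float = 0.15,
    age_effect_sd: float = 0.02,
    replicate_rate: float = 0.15,
):
    """Probe-level long-format expression with planted degree associations.

    For a fraction ``frac_assoc`` of genes, expression in one randomly
    designated tissue zone follows ``intercept + beta * degree(region) +
    age effect + spatial noise``, with ``|beta|`` uniform in ``beta_range``
    and random sign. All genes, in all zones, additionally carry:

    - a specimen-shared regional signature (sd ``shared_sd``) — this is what
      makes faithful probes reproducible across specimens. A fraction
      ``shared_spatial_frac`` of its variance is spatially correlated
      (exponential covariance, length ``sac_length``); the rest is
      region-specific identity, reproducible but not smooth in space;
    - a specimen-specific spatial field (sd ``specimen_sd``) plus iid
      measurement noise (sd ``noise_sd``);
    - a small per-gene age slope (sd ``age_effect_sd`` per week).

    Each gene emits ``probes_per_gene`` probes: even-indexed probes are
    faithful replicates of the gene signal; odd-indexed probes are decoys
    carrying only independent (specimen-unshared) spatial noise, so a
    differential-stability filter has a guaranteed discriminating case. A
    fraction ``absent_rate`` of probes is flagged 'absent'; a fraction
    ``missing_rate`` of sample cells is dropped; a fraction ``replicate_rate``
    of cells receives a duplicate sample to exercise sample averaging.

    Returns ``(long_dataframe, truth)`` with columns
    probe_id, gene, specimen, age_weeks, region, zone, absent_flag, value.
    """
    if not (0 <= frac_assoc <= 1):
        raise ValueError("frac_assoc must be in [0, 1]")
    specimens = list(specimens)
    if len(specimens) < 2:
        raise ValueError("need at least 2 specimens (stability is undefined)")
    degree_map = pd.Series(degree_map, dtype=float)
    regions = list(degree_map.index)
    if len(regions) < 4:
        raise ValueError("need at least 4 regions")
    zones = list(zones)
    if probes_per_gene < 1:
        raise ValueError("probes_per_gene must be >= 1")

    rng_lay = rng_for(seed, "expr", "layout")
    rng_sig = rng_for(seed, "expr", "signal")
    rng_noise = rng_for(seed, "expr", "noise")

    R, Z, S, G = len(regions), len(zones), len(specimens), n_genes
    if region_coords is None:
        region_coords = rng_lay.uniform(0.0, 100.0, size=(R, 3))
    region_coords = np.asarray(region_coords, dtype=float)

    genes = [f"G{i:05d}" for i in range(G)]
    n_assoc = int(round(frac_assoc * G))
    assoc_idx = rng_lay.choice(G, size=n_assoc, replace=False) if n_assoc else []
    betas = np.zeros(G)
    gene_zone = np.full(G, -1)
    effects = {}
    for gi in assoc_idx:
        b = rng_lay.uniform(*beta_range) * rng_lay.choice([-1.0, 1.0])
        zi = int(rng_lay.integers(Z))
        betas[gi], gene_zone[gi] = b, zi
        effects[genes[gi]] = (zones[zi], float(b))

    ages = np.array([a for _, a in specimens], dtype=float)
    age_c = ages - ages.mean()
    deg = degree_map.to_numpy()

    intercept = rng_sig.normal(7.0, 1.0, size=G)
    age_slope = rng_sig.normal(0.0, age_effect_sd, size=G)
    # specimen-shared signature per (gene, zone): (R, G*Z) -> (G, Z, R)
    if not (0 <= shared_spatial_frac <= 1):
        raise ValueError("shared_spatial_frac must be in [0, 1]")
    sp = (
        gaussian_random_field(region_coords, sac_length, rng_sig, size=G * Z)
        .T.reshape(G, Z, R)
    )
    iid = rng_sig.standard_normal((G, Z, R))
    shared = shared_sd * (
        np.sqrt(shared_spatial_frac) * sp + np.sqrt(1 - shared_spatial_frac) * iid
    )
    # specimen-specific field per (gene, zone, specimen)
    spec = (
        gaussian_random_field(region_coords, sac_length, rng_sig, size=G * Z * S)
        .T.reshape(G, Z, S, R) * specimen_sd
    )

    # mean signal mu[g, z, s, r]
    mu = (
        intercept[:, None, None, None]
        + shared[:, :, None, :]
        + np.transpose(spec, (0, 1, 2, 3))
        + (age_slope[:, None] * age_c[None, :])[:, None, :, None]
    )
    planted = gene_zone >= 0
    bump = betas[:, None] * deg[None, :]  # (G, R)
    for gi in np.flatnonzero(planted):
        mu[gi, gene_zone[gi], :, :] += bump[gi]

    # assemble long table over probes
    frames = []
    probe_absent = {}
    for pk in range(probes_per_gene):
        probe_ids = [f"{g}_p{pk}" for g in genes]
        if pk % 2 == 0:
            vals = mu + rng_noise.normal(0.0, noise_sd, size=mu.shape)
        else:
            decoy = (
                gaussian_random_field(
                    region_coords, sac_length, rng_noise, size=G * Z * S
                ).T.reshape(G, Z, S, R) * shared_sd
            )
            vals = (
                intercept[:, None, None, None]
                + decoy
                + rng_noise.normal(0.0, noise_sd, size=mu.shape)
            )
        frames.append(_long_frame(vals, probe_ids, genes, zones, specimens, regions))
        for p in probe_ids:
            probe_absent[p] = False

    df = pd.concat(frames, ignore_index=True)

    # replicate samples for a fraction of cells
    if replicate_rate > 0:
        rep_mask = rng_noise.random(len(df)) < replicate_rate
        reps = df[rep_mask].copy()
        reps["value"] = reps["value"] + rng_noise.normal(0, noise_sd, size=len(reps))
        df = pd.concat([df, reps], ignore_index=True)

    # absent probes
    all_probes = sorted(probe_absent)
    n_absent = int(round(absent_rate * len(all_probes)))
    absent_set = set(
        rng_noise.choice(all_probes, size=n_absent, replace=False)
    ) if n_absent else set()
    df["absent_flag"] = df["probe_id"].isin(absent_set)

    # missing cells
    if missing_rate > 0:
        keep = rng_noise.random(len(df)) >= missing_rate
        df = df[keep].reset_index(drop=True)

    truth = SyntheticTruth(
        planted_gene_effects=effects,
        noise_correlation_length=float(sac_length),
        specimen_ages=tuple(ages),
        region_coords=region_coords,
        regions=tuple(regions),
    )
    return df, truth


def _long_frame(vals, probe_ids, genes, zones, specimens, regions):
    G, Z, S, R = vals.shape
    spec_ids = [s for s, _ in specimens]
    ages = [a for _, a in specimens]
    idx = pd.MultiIndex.from_product(
        [probe_ids, zones, spec_ids, regions], names=["probe_id", "zone", "specimen", "region"]
    )
    df = pd.DataFrame({"value": vals.ravel()}, index=idx).reset_index()
    gene_of = dict(zip(probe_ids, genes))
    age_of = dict(zip(spec_ids, ages))
    df["gene"] = df["probe_id"].map(gene_of)
    df["age_weeks"] = df["specimen"].map(age_of)
    return df[["probe_id", "gene", "specimen", "age_weeks", "region", "zone", "value"]]


def gen_gene_sets(
    universe, n_sets: int, set_sizes, planted_overlap: dict | None = None, seed: int = 0
) -> dict:
    """Random gene sets from a universe, with optional exact planted overlaps.

    ``planted_overlap`` maps a set name to ``(target_genes, k)``: that set will
    contain exactly ``k`` genes from ``target_genes`` (and none of the others).

    Returns ``{set_name: [genes]}`` (writable as GMT).
    """
    universe = list(dict.fromkeys(universe))
    set_sizes = list(set_sizes)
    if len(set_sizes) == 1:
        set_sizes = set_sizes * n_sets
    if len(set_sizes) != n_sets:
        raise ValueError("set_sizes must have length n_sets (or 1)")
    if any(s > len(universe) for s in set_sizes):
        raise ValueError("set size exceeds universe size")
    rng = rng_for(seed, "genesets")
    planted_overlap = planted_overlap or {}
    out = {}
    for i, size in enumerate(set_sizes):
        name = f"SET{i:03d}"
        if name in planted_overlap:
            target, k = planted_overlap[name]
            target = [g for g in dict.fromkeys(target) if g in set(universe)]
            if k > size:
                raise ValueError(f"requested overlap {k} exceeds set size {size}")
            if k > len(target):
                raise ValueError("requested overlap exceeds target list size")
            inside = list(rng.choice(target, size=k, replace=False)) if k else []
            pool = [g for g in universe if g not in set(target)]
            if size - k > len(pool):
                raise ValueError("not enough non-target genes to fill the set")
            rest = list(rng.choice(pool, size=size - k, replace=False))
            out[name] = sorted(inside + rest)
        else:
            out[name] = sorted(rng.choice(universe, size=size, replace=False))
    return out


def gen_cells(
    n_cells: int,
    populations,
    pseudotime_model: dict | None = None,
    geneset=(),
    effect: float = 0.0,
    seed: int = 0,
    n_background_genes: int = 30,
    noise_sd: float = 0.3,
) -> ad.AnnData:
    """Cells with population labels, pseudotime and log-normalised expression.

    Geneset genes increase linearly with pseudotime at slope ``effect`` (plus
    Gaussian noise, clipped at zero as log-normalised data are non-negative);
    background genes are flat. ``pseudotime_model`` maps population name to a
    (lo, hi) interval from which that population's pseudotime is drawn.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    populations = list(populations)
    if not populations:
        raise ValueError("populations must be non-empty")
    pseudotime_model = pseudotime_model or {p: (0.0, 1.0) for p in populations}
    rng = rng_for(seed, "cells")

    pop = rng.choice(populations, size=n_cells)
    lo = np.array([pseudotime_model[p][0] for p in pop])
    hi = np.array([pseudotime_model[p][1] for p in pop])
    t = rng.uniform(lo, hi)

    geneset = list(dict.fromkeys(geneset))
    bg = [f"BG{i:04d}" for i in range(n_background_genes)]
    genes = geneset + bg
    base = np.abs(rng.normal(1.0, 0.5, size=len(genes)))
    X = base[None, :] + rng.normal(0.0, noise_sd, size=(n_cells, len(genes)))
    if geneset:
        X[:, : len(geneset)] += effect * t[:, None]
    X = np.clip(X, 0.0, None).astype(np.float32)

    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(
            {"population": pd.Categorical(pop), "pseudotime": t},
            index=[f"cell{i}" for i in range(n_cells)],
        ),
        var=pd.DataFrame(index=genes),
    )
    return adata
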