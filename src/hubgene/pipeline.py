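"""End-to-end orchestration: synthetic inputs through enrichment, with a manifest.

A single :class:`RunConfig` carries every stage's parameters (the analysis
defaults mirror the study design: 30% edge presence, 15% density, 100 nulls x
50 rewires, 90th-percentile hubs, DS >= 0.3, <=10% missingness, FDR 0.05,
1000 surrogates) and one master seed that is split into per-stage substreams.
``run_end_to_end`` executes

    surface -> subdivide -> cohort -> consensus -> rich club ->
    expression prep -> degree association -> enrichment

writing one delimited/JSON artefact per stage plus a manifest with parameters,
seeds and SHA-256 hashes of every output, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .association import run_association
from .connectome import build_consensus
from .enrichment import cell_geneset_score, geneset_overlap_test, score_pseudotime_correlation
from .expression import ExpressionPrep
from .parcellation import parcel_centroids, region_mean, subdivide
from .richclub import RichClub, hubness_index
from .synth import (
    DEFAULT_SPECIMENS,
    gen_cells,
    gen_cohort_connectomes,
    gen_expression_dataset,
    gen_gene_sets,
    gen_surface,
)

__all__ = ["RunConfig", "run_end_to_end", "compare_resolutions"]


@dataclass
class RunConfig:
    """All pipeline parameters with study-default analysis settings."""

    seed: int = 0
    # synthetic cohort / surface
    n_regions: int = 27
    vertices_per_region: int = 630
    target_vertices: int = 90
    n_subjects: int = 50
    core_size: int = 15
    distance_decay: float = 80.0
    core_boost: float = 1e4
    subject_noise: float = 0.1
    # synthetic expression
    n_genes: int = 1000
    frac_assoc: float = 0.15
    beta_range: tuple = (0.02, 0.12)
    sac_length: float = 30.0
    probes_per_gene: int = 2
    absent_rate: float = 0.1
    missing_rate: float = 0.02
    # consensus / rich club
    presence_threshold: float = 0.30
    density: float = 0.15
    n_nulls: int = 100
    swaps_per_edge: int = 50
    percentile: float = 90.0
    # expression prep / association
    ds_min: float = 0.3
    max_missing: float = 0.10
    n_surr: int = 1000
    alpha: float = 0.05
    # enrichment / cells
    n_gene_sets: int = 5
    gene_set_size: int = 80
    n_cells: int = 2000
    cell_effect: float = 1.0

    def __post_init__(self):
        for name in ("presence_threshold", "density", "frac_assoc", "absent_rate",
                     "missing_rate", "max_missing", "alpha"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_regions", "vertices_per_region", "target_vertices",
                     "n_subjects", "n_genes", "n_nulls", "swaps_per_edge",
                     "n_surr", "n_cells"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "RunConfig":
        """Desk-scale profile: one-CPU full run (~200 nodes, 1000 genes,
        200 surrogates)."""
        return cls(seed=seed, n_surr=200)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "beta_range" in d:
            d["beta_range"] = tuple(d["beta_range"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["beta_range"] = list(d["beta_range"])
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_end_to_end(config: RunConfig, out_dir) -> dict:
    """Run every stage on synthetic inputs; returns the manifest dict.

    Stage outputs (all under ``out_dir``): parcellation.tsv, consensus.json,
    richclub.json, expression_prep.tsv, association.tsv, enrichment.tsv, plus
    truth.json and manifest.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    stages: dict[str, Path] = {}

    # 1. surface + parcellation (subparcels become network nodes)
    mesh = gen_surface(config.n_regions, config.vertices_per_region, seed=seed)
    parc = subdivide(mesh, config.target_vertices, seed=seed)
    centroids = parcel_centroids(mesh, parc)
    io.write_parcellation(out / "parcellation.tsv", parc)
    stages["parcellation"] = out / "parcellation.tsv"

    # 2. cohort + consensus network
    # plant the core at the sheet's most central subparcels, where the
    # geometry already concentrates connectivity (as association cortex does)
    central = np.argsort(
        np.linalg.norm(centroids - centroids.mean(axis=0), axis=1)
    )[: config.core_size]
    subjects, net_truth = gen_cohort_connectomes(
        config.n_subjects,
        n_nodes=parc.n_subparcels,
        core_size=config.core_size,
        core_nodes=central,
        distance_decay=config.distance_decay,
        core_boost=config.core_boost,
        subject_noise=config.subject_noise,
        seed=seed,
        coords=centroids,
        region=parc.subparcel_region,
    )
    net = build_consensus(subjects, config.presence_threshold, config.density)
    io.write_network(out / "consensus.json", net)
    stages["consensus"] = out / "consensus.json"

    # 3. rich club + hubs
    rc = RichClub(
        n_nulls=config.n_nulls,
        swaps_per_edge=config.swaps_per_edge,
        percentile=config.percentile,
        random_state=seed,
    ).fit(net)
    rc_dict = rc.to_dict()
    rc_dict["hubness_by_region"] = {
        str(k): float(v) for k, v in hubness_index(rc.hub_mask_, parc).items()
    }
    io.write_json(out / "richclub.json", rc_dict)
    stages["richclub"] = out / "richclub.json"

    # 4. synthetic expression + prep
    region_degree = region_mean(net.degree_.astype(float), parc)
    region_degree.index = region_degree.index.map(str)
    region_coords = (
        pd.DataFrame(centroids, columns=["x", "y", "z"])
        .groupby(pd.Series(parc.subparcel_region).astype(str))
        .mean()
        .loc[region_degree.index]
        .to_numpy()
    )
    expr, expr_truth = gen_expression_dataset(
        region_degree,
        n_genes=config.n_genes,
        frac_assoc=config.frac_assoc,
        beta_range=config.beta_range,
        specimens=DEFAULT_SPECIMENS,
        sac_length=config.sac_length,
        region_coords=region_coords,
        probes_per_gene=config.probes_per_gene,
        absent_rate=config.absent_rate,
        missing_rate=config.missing_rate,
        seed=seed,
    )
    prep = ExpressionPrep(ds_min=config.ds_min, max_missing=config.max_missing)
    tensor = prep.fit_transform(expr)
    io.write_tensor(out / "expression_prep.tsv", tensor)
    stages["expression_prep"] = out / "expression_prep.tsv"

    # 5. association with spatial surrogate null
    assoc = run_association(
        tensor,
        region_degree,
        coords=region_coords,
        n_surr=config.n_surr,
        alpha=config.alpha,
        seed=seed,
    )
    assoc.to_csv(out / "association.tsv", sep="\t", index=False)
    stages["association"] = out / "association.tsv"

    # 6. enrichment of hub+ genes + cell-level score vs pseudotime
    universe = sorted(set(assoc["gene"]))
    planted = sorted(
        g for g, (_, b) in expr_truth.planted_gene_effects.items()
        if b > 0 and g in set(universe)
    )
    set_size = min(config.gene_set_size, max(1, len(universe) // 2))
    overlap_k = min(len(planted), set_size // 2)
    gsets = gen_gene_sets(
        universe,
        config.n_gene_sets,
        [set_size],
        planted_overlap={"SET000": (planted, overlap_k)} if planted else None,
        seed=seed,
    )
    hub_pos = sorted(set(assoc.loc[assoc["class"] == "hub+", "gene"]))
    rows = []
    for name, genes in gsets.items():
        res = geneset_overlap_test(hub_pos, genes, universe)
        rows.append({"query": "hub+", "target": name, **res.as_row()})
    enr = pd.DataFrame(rows)
    enr["p_fdr"] = np.nan
    if len(enr):
        from .association import fdr_correct

        enr["p_fdr"] = fdr_correct(enr["p"].to_numpy())

    cell_geneset = hub_pos or planted or universe[:10]
    cells = gen_cells(
        config.n_cells,
        populations=["progenitor", "neuron_immature", "neuron_mature"],
        pseudotime_model={
            "progenitor": (0.0, 0.4),
            "neuron_immature": (0.3, 0.7),
            "neuron_mature": (0.6, 1.0),
        },
        geneset=cell_geneset,
        effect=config.cell_effect,
        seed=seed,
    )
    scores = cell_geneset_score(cells, cell_geneset)
    cell_rows = []
    for pop in cells.obs["population"].cat.categories:
        rho, n = score_pseudotime_correlation(scores, pop)
        cell_rows.append({"query": "hub+", "target": f"pseudotime:{pop}",
                          "x": n, "n": n, "K": 0, "M": 0,
                          "enrichment": rho, "p": np.nan, "p_fdr": np.nan})
    enr = pd.concat([enr, pd.DataFrame(cell_rows)], ignore_index=True)
    enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    stages["enrichment"] = out / "enrichment.tsv"

    io.write_json(out / "truth.json", {
        "network": net_truth.to_dict(), "expression": expr_truth.to_dict(),
    })

    manifest = {
        "config": config.to_dict(),
        "seed": seed,
        "stages": {
            name: {"path": str(p.name), "sha256": _sha256(p)}
            for name, p in stages.items()
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def compare_resolutions(assoc_a: pd.DataFrame, assoc_b: pd.DataFrame) -> dict:
    """Agreement of association results across two parcellation resolutions.

    Returns the Pearson correlation of beta_degree over common (gene, zone)
    pairs and the fraction of A's significant set also significant in B.
    """
    m = assoc_a.merge(assoc_b, on=["gene", "zone"], suffixes=("_a", "_b"))
    m = m.dropna(subset=["beta_degree_a", "beta_degree_b"])
    if m.empty:
        raise ValueError("no common (gene, zone) pairs")
    r = float(np.corrcoef(m["beta_degree_a"], m["beta_degree_b"])[0, 1])
    sig_a = m["class_a"].isin(["hub+", "hub-"])
    sig_b = m["class_b"].isin(["hub+", "hub-"])
    overlap = float((sig_a & sig_b).sum() / sig_a.sum()) if sig_a.sum() else np.nan
    return {"beta_correlation": r, "significant_overlap": overlap,
            "n_common": int(len(m))}
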