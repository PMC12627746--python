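"""Plain-text readers and writers for the pipeline's artefacts.

All formats are delimited text or JSON: square weight matrices or 3-column
edge lists for connectomes, a node table (id, x, y, z, region), long-format
expression tables, GMT gene sets, and JSON for networks, rich-club results
and ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import GroupConsensus, SubjectConnectome

__all__ = [
    "write_subject", "read_subject", "write_edge_list", "read_edge_list",
    "write_expression", "read_expression", "write_gmt", "read_gmt",
    "write_network", "read_network", "write_json", "read_json",
    "write_mesh", "read_mesh", "write_parcellation",
    "write_tensor", "read_tensor",
]


def write_mesh(prefix, mesh) -> None:
    """Vertex table ``<prefix>.vertices.tsv`` + edge list ``<prefix>.edges.tsv``."""
    prefix = Path(prefix)
    pd.DataFrame(
        {
            "id": np.arange(mesh.n_vertices),
            "x": mesh.coords[:, 0],
            "y": mesh.coords[:, 1],
            "z": mesh.coords[:, 2],
            "region": mesh.region,
        }
    ).to_csv(f"{prefix}.vertices.tsv", sep="\t", index=False)
    pd.DataFrame(mesh.edges, columns=["v1", "v2"]).to_csv(
        f"{prefix}.edges.tsv", sep="\t", index=False
    )


def read_mesh(prefix):
    from .parcellation import SurfaceMesh

    prefix = Path(prefix)
    v = pd.read_csv(f"{prefix}.vertices.tsv", sep="\t")
    e = pd.read_csv(f"{prefix}.edges.tsv", sep="\t")
    return SurfaceMesh(
        coords=v[["x", "y", "z"]].to_numpy(),
        edges=e[["v1", "v2"]].to_numpy(),
        region=v["region"].to_numpy(),
    )


def write_parcellation(path, parc) -> None:
    parc.to_frame().to_csv(path, sep="\t", index=False)


def write_tensor(path, tensor) -> None:
    """Gene tensor as a long table (gene, region, zone, specimen, age_weeks, value)."""
    df = tensor.to_series().dropna().reset_index()
    df = df.rename(columns={df.columns[-1]: "value"})
    ages = tensor.attrs.get("ages", {})
    df["age_weeks"] = df["specimen"].map(lambda s: ages.get(str(s), float("nan")))
    df.to_csv(path, sep="\t", index=False)


def read_tensor(path):
    import xarray as xr

    df = pd.read_csv(path, sep="\t", dtype={"region": str, "specimen": str})
    g = df.set_index(["gene", "region", "zone", "specimen"])["value"]
    da = xr.DataArray.from_series(g).transpose("gene", "region", "zone", "specimen")
    ages = df.drop_duplicates("specimen").set_index("specimen")["age_weeks"]
    da.attrs["ages"] = {str(s): float(a) for s, a in ages.items()}
    return da


def write_subject(path, subject: SubjectConnectome) -> None:
    """Square weight matrix as TSV plus a sibling ``<stem>.nodes.tsv`` table."""
    path = Path(path)
    np.savetxt(path, subject.weights, delimiter="\t", fmt="%.6g")
    nodes = pd.DataFrame({"id": subject.node_ids})
    if subject.coords is not None:
        nodes[["x", "y", "z"]] = subject.coords
    if subject.region is not None:
        nodes["region"] = subject.region
    nodes.to_csv(path.with_suffix(".nodes.tsv"), sep="\t", index=False)


def read_subject(path) -> SubjectConnectome:
    path = Path(path)
    w = np.loadtxt(path, delimiter="\t", ndmin=2)
    kwargs = {}
    npath = path.with_suffix(".nodes.tsv")
    if npath.exists():
        nodes = pd.read_csv(npath, sep="\t")
        kwargs["node_ids"] = nodes["id"].to_numpy()
        if {"x", "y", "z"} <= set(nodes.columns):
            kwargs["coords"] = nodes[["x", "y", "z"]].to_numpy()
        if "region" in nodes.columns:
            kwargs["region"] = nodes["region"].to_numpy()
    return SubjectConnectome(weights=w, **kwargs)


def write_edge_list(path, subject: SubjectConnectome) -> None:
    """3-column edge list (node_i, node_j, weight) with 0-based ids, i < j."""
    i, j = np.nonzero(np.triu(subject.weights, k=1))
    pd.DataFrame(
        {"node_i": i, "node_j": j, "weight": subject.weights[i, j]}
    ).to_csv(path, sep="\t", index=False)


def read_edge_list(path, n_nodes: int) -> SubjectConnectome:
    df = pd.read_csv(path, sep="\t")
    w = np.zeros((n_nodes, n_nodes))
    i = df["node_i"].to_numpy(dtype=int)
    j = df["node_j"].to_numpy(dtype=int)
    w[i, j] = w[j, i] = df["weight"].to_numpy(dtype=float)
    return SubjectConnectome(weights=w)


def write_expression(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"region": str, "specimen": str})


def write_gmt(path, gene_sets: dict) -> None:
    """GMT: one line per set — name, description tab genes."""
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, "na", *map(str, genes)]) + "\n")


def read_gmt(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2:
                out[parts[0]] = [g for g in parts[2:] if g]
    return out


def write_network(path, net: GroupConsensus) -> None:
    write_json(path, net.to_dict())


def read_network(path) -> GroupConsensus:
    return GroupConsensus.from_dict(read_json(path))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_jsonable)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
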