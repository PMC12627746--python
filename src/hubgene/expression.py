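"""Probe-level QC and aggregation of laminar microarray-style expression.

Input is a long-format table with one row per measured sample:
``probe_id, gene, specimen, age_weeks, region, zone, absent_flag, value``
(log2 intensities over cortical regions x 5 transient tissue zones x several
mid-gestation specimens). The pipeline mirrors standard microarray practice:

1. drop probes flagged 'absent' (low signal);
2. score each probe's differential stability (DS) — the mean Pearson
   correlation of its regional expression profile within a tissue zone
   between pairs of specimens sampled at the same age;
3. drop probes with DS below a threshold (0.3 by default) and collapse each
   gene to its single most stable probe;
4. average replicate samples per (gene, region, zone, specimen);
5. drop genes missing in more than a given fraction of sample slots.

Each stage can only shrink the probe/gene universe; the result is a
gene x region x zone x specimen tensor (xarray) ready for degree association.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import xarray as xr
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "filter_absent",
    "differential_stability",
    "collapse_probes",
    "aggregate_samples",
    "filter_missingness",
    "ExpressionPrep",
]

LONG_COLUMNS = [
    "probe_id",
    "gene",
    "specimen",
    "age_weeks",
    "region",
    "zone",
    "absent_flag",
    "value",
]


def filter_absent(data: pd.DataFrame) -> pd.DataFrame:
    """Remove every record of probes flagged 'absent'."""
    if "absent_flag" not in data.columns:
        raise ValueError("absent_flag column required")
    absent_probes = set(data.loc[data["absent_flag"].astype(bool), "probe_id"])
    out = data[~data["probe_id"].isin(absent_probes)].reset_index(drop=True)
    if out.empty and not data.empty:
        warnings.warn("all probes flagged absent; dataset is empty", stacklevel=2)
    return out


def _rowwise_corr(a: np.ndarray, b: np.ndarray, min_n: int = 3) -> np.ndarray:
    """Pearson correlation of each row pair, pairwise-complete, NaN if < min_n."""
    m = np.isfinite(a) & np.isfinite(b)
    n = m.sum(axis=1)
    a0 = np.where(m, a, 0.0)
    b0 = np.where(m, b, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ma = a0.sum(axis=1) / n
        mb = b0.sum(axis=1) / n
        ac = np.where(m, a - ma[:, None], 0.0)
        bc = np.where(m, b - mb[:, None], 0.0)
        num = (ac * bc).sum(axis=1)
        den = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
        r = num / den
    r[(n < min_n) | ~np.isfinite(r)] = np.nan
    return r


def differential_stability(data: pd.DataFrame) -> pd.Series:
    """Differential stability per probe.

    For every tissue zone and every pair of specimens sharing the same age,
    the probe's regional profiles (replicate samples averaged first, regions
    present in both specimens) are Pearson-correlated; DS is the mean over all
    such (zone, specimen-pair) contexts. A probe with fewer than 3 common
    regions in every context gets a missing DS.
    """
    ages = data.drop_duplicates("specimen").set_index("specimen")["age_weeks"]
    pairs = []
    for _, grp in ages.groupby(ages):
        ss = sorted(grp.index)
        pairs += [(ss[i], ss[j]) for i in range(len(ss)) for j in range(i + 1, len(ss))]
    if not pairs:
        raise ValueError("differential stability undefined: no two specimens share an age")

    cell = (
        data.groupby(["probe_id", "zone", "specimen", "region"], observed=True)["value"]
        .mean()
    )
    wide = cell.unstack(["zone", "specimen", "region"])
    probes = wide.index
    corrs = []
    for zone in data["zone"].unique():
        if zone not in wide.columns.get_level_values(0):
            continue
        wz = wide[zone]
        for s1, s2 in pairs:
            lev = wz.columns.get_level_values(0)
            if s1 not in lev or s2 not in lev:
                continue
            a, b = wz[s1], wz[s2]
            common = a.columns.intersection(b.columns)
            if len(common) == 0:
                continue
            r = _rowwise_corr(a[common].to_numpy(), b[common].to_numpy())
            corrs.append(r)
    if not corrs:
        return pd.Series(np.nan, index=probes, name="DS")
    stack = np.column_stack(corrs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        ds = np.nanmean(stack, axis=1)
    return pd.Series(ds, index=probes, name="DS")


def collapse_probes(
    data: pd.DataFrame, ds: pd.Series, ds_min: float = 0.3
) -> pd.DataFrame:
    """Drop unstable probes and keep one probe (the max-DS one) per gene.

    Probes with DS below ``ds_min`` — or with missing DS — are removed; among
    a gene's survivors the probe with the highest DS is kept (ties broken by
    lexicographically smallest probe id). Genes with no surviving probe
    disappear from the output.
    """
    ok = ds[(ds >= ds_min) & ds.notna()]
    sub = data[data["probe_id"].isin(set(ok.index))].copy()
    if sub.empty:
        return sub.reset_index(drop=True)
    probe_gene = sub.drop_duplicates("probe_id").set_index("probe_id")["gene"]
    tbl = pd.DataFrame({"gene": probe_gene, "DS": ok.reindex(probe_gene.index)})
    tbl = tbl.sort_values(["gene", "DS", "probe_id"], ascending=[True, False, True],
                          key=None).reset_index()
    best = tbl.groupby("gene", observed=True).first()["probe_id"]
    return sub[sub["probe_id"].isin(set(best))].reset_index(drop=True)


def aggregate_samples(data: pd.DataFrame) -> xr.DataArray:
    """Average replicate samples into a gene x region x zone x specimen tensor.

    Cells with no sample are NaN. Specimen ages are carried in
    ``tensor.attrs['ages']``.
    """
    g = data.groupby(["gene", "region", "zone", "specimen"], observed=True)["value"].mean()
    da = xr.DataArray.from_series(g)
    da = da.transpose("gene", "region", "zone", "specimen")
    ages = data.drop_duplicates("specimen").set_index("specimen")["age_weeks"]
    da.attrs["ages"] = {str(s): float(a) for s, a in ages.items()}
    da.name = "expression"
    return da


def filter_missingness(tensor: xr.DataArray, max_missing: float = 0.10) -> xr.DataArray:
    """Drop genes missing in strictly more than ``max_missing`` of sample slots.

    The denominator is the set of (region, zone, specimen) slots observed for
    at least one gene — i.e. the sample slots that exist in the dataset.
    """
    observed = tensor.notnull()
    in_scope = observed.any("gene")
    n_slots = int(in_scope.sum())
    if n_slots == 0:
        return tensor
    frac_missing = 1.0 - observed.where(in_scope).sum(
        ["region", "zone", "specimen"]
    ) / n_slots
    keep = frac_missing <= max_missing
    out = tensor.sel(gene=keep)
    out.attrs = dict(tensor.attrs)
    return out


class ExpressionPrep(BaseEstimator, TransformerMixin):
    """Full probe-to-tensor preparation pipeline as a transformer.

    ``fit_transform(long_df)`` runs absent-probe removal, differential
    stability, probe collapse, sample averaging and the missingness filter, in
    that order, and returns the gene tensor.

    Attributes
    ----------
    ds_ : pd.Series — differential stability per probe (post absent-filter).
    qc_report_ : dict — probe/gene counts removed at each stage.
    """

    def __init__(self, ds_min: float = 0.3, max_missing: float = 0.10):
        self.ds_min = ds_min
        self.max_missing = max_missing

    def fit(self, X: pd.DataFrame, y=None):
        n_probes0 = X["probe_id"].nunique()
        step1 = filter_absent(X)
        n_probes1 = step1["probe_id"].nunique()
        ds = differential_stability(step1)
        step2 = collapse_probes(step1, ds, self.ds_min)
        n_genes2 = step2["gene"].nunique()
        tensor = aggregate_samples(step2) if not step2.empty else None
        if tensor is not None:
            tensor_f = filter_missingness(tensor, self.max_missing)
        else:
            tensor_f = None
        self.ds_ = ds
        self.tensor_ = tensor_f
        self.qc_report_ = {
            "probes_input": int(n_probes0),
            "probes_removed_absent": int(n_probes0 - n_probes1),
            "probes_removed_ds": int(n_probes1 - step2["probe_id"].nunique()),
            "genes_after_collapse": int(n_genes2),
            "genes_removed_missingness": int(
                n_genes2 - (tensor_f.sizes["gene"] if tensor_f is not None else 0)
            ),
            "genes_final": int(tensor_f.sizes["gene"]) if tensor_f is not None else 0,
        }
        return self

    def transform(self, X: pd.DataFrame = None) -> xr.DataArray:
        return self.tensor_

    def fit_transform(self, X: pd.DataFrame, y=None) -> xr.DataArray:
        return self.fit(X).transform(X)
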