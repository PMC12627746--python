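import numpy as np
import pandas as pd
import pytest

import hubgene as hg
from hubgene.expression import LONG_COLUMNS


def make_long(records):
    df = pd.DataFrame(records, columns=LONG_COLUMNS)
    return df


def two_specimen_probe(probe, gene, values_by_specimen, zone="CP", absent=False):
    rows = []
    for spec, vals in values_by_specimen.items():
        for i, v in enumerate(vals):
            rows.append([probe, gene, spec, 16.0, f"R{i}", zone, absent, v])
    return rows


class TestFilterAbsent:
    def test_identity_and_counts(self):
        rows = []
        for i in range(10):
            rows += two_specimen_probe(f"p{i}", f"g{i}", {"S1": [1, 2, 3]},
                                       absent=(i < 3))
        df = make_long(rows)
        out = hg.filter_absent(df)
        assert out["probe_id"].nunique() == 7
        clean = df[~df["absent_flag"]]
        pd.testing.assert_frame_equal(
            hg.filter_absent(clean).reset_index(drop=True),
            clean.reset_index(drop=True),
        )

    def test_all_absent_warns(self):
        df = make_long(two_specimen_probe("p0", "g0", {"S1": [1.0]}, absent=True))
        with pytest.warns(UserWarning):
            out = hg.filter_absent(df)
        assert out.empty


class TestDifferentialStability:
    def test_identical_profiles_ds_one(self):
        prof = [1.0, 2.0, 5.0, 3.0]
        df = make_long(two_specimen_probe("p0", "g0", {"S1": prof, "S2": prof}))
        ds = hg.differential_stability(df)
        assert ds["p0"] == pytest.approx(1.0)

    def test_negated_profiles_ds_minus_one(self):
        prof = np.array([1.0, 2.0, 5.0, 3.0])
        df = make_long(
            two_specimen_probe("p0", "g0", {"S1": list(prof), "S2": list(-prof)})
        )
        assert hg.differential_stability(df)["p0"] == pytest.approx(-1.0)

    def test_independent_profiles_ds_near_zero(self):
        rng = np.random.default_rng(0)
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            a, b = rng.standard_normal(27), rng.standard_normal(27)
            r = np.corrcoef(a, b)[0, 1]
            hits += abs(r) < 0.4
        assert hits / n_sim >= 0.95

    def test_too_few_common_regions_missing(self):
        rows = two_specimen_probe("p0", "g0", {"S1": [1.0, 2.0], "S2": [2.0, 1.0]})
        ds = hg.differential_stability(make_long(rows))
        assert np.isnan(ds["p0"])

    def test_requires_same_age_pair(self):
        rows = []
        for spec, age in [("S1", 15.0), ("S2", 21.0)]:
            for i, v in enumerate([1.0, 2.0, 3.0]):
                rows.append(["p0", "g0", spec, age, f"R{i}", "CP", False, v])
        with pytest.raises(ValueError):
            hg.differential_stability(make_long(rows))

    def test_decoy_probes_fail_ds_filter(self, small_expression):
        df, _, _ = small_expression
        clean = hg.filter_absent(df)
        ds = hg.differential_stability(clean)
        decoys = [p for p in ds.index if p.endswith("_p1")]
        faithful = [p for p in ds.index if p.endswith("_p0")]
        assert (ds[decoys] < 0.3).mean() >= 0.95
        assert (ds[faithful] >= 0.3).mean() >= 0.95


class TestCollapseAndAggregate:
    def test_keeps_max_ds_probe(self):
        rows = (
            two_specimen_probe("pA", "g0", {"S1": [1, 2, 3, 4], "S2": [1, 2, 3, 4]})
            + two_specimen_probe("pB", "g0", {"S1": [1, 2, 3, 4], "S2": [4, 2, 1, 3]})
        )
        df = make_long(rows)
        ds = pd.Series({"pA": 0.9, "pB": 0.5})
        out = hg.collapse_probes(df, ds)
        assert set(out["probe_id"]) == {"pA"}

    def test_gene_dropped_when_all_probes_unstable(self):
        df = make_long(two_specimen_probe("pA", "g0", {"S1": [1, 2, 3]}))
        out = hg.collapse_probes(df, pd.Series({"pA": 0.1}))
        assert out.empty

    def test_filter_disabled_keeps_every_gene(self, small_expression):
        df, _, _ = small_expression
        clean = hg.filter_absent(df)
        ds = hg.differential_stability(clean)
        out = hg.collapse_probes(clean, ds, ds_min=-1.0)
        assert out["gene"].nunique() == clean["gene"].nunique()
        # one probe per gene
        assert out.groupby("gene")["probe_id"].nunique().max() == 1

    def test_collapse_idempotent(self, small_expression):
        df, _, _ = small_expression
        clean = hg.filter_absent(df)
        ds = hg.differential_stability(clean)
        once = hg.collapse_probes(clean, ds)
        twice = hg.collapse_probes(once, ds)
        pd.testing.assert_frame_equal(once, twice)

    def test_aggregate_means(self):
        rows = [
            ["p0", "g0", "S1", 16.0, "R0", "CP", False, 4.0],
            ["p0", "g0", "S1", 16.0, "R0", "CP", False, 6.0],
            ["p0", "g0", "S1", 16.0, "R1", "CP", False, 2.5],
        ]
        t = hg.aggregate_samples(make_long(rows))
        assert float(t.sel(gene="g0", region="R0", zone="CP", specimen="S1")) == 5.0
        assert float(t.sel(gene="g0", region="R1", zone="CP", specimen="S1")) == 2.5

    def test_aggregate_matches_bruteforce(self, small_expression):
        df, _, _ = small_expression
        sub = df[df["gene"].isin(sorted(df["gene"].unique())[:5])]
        t = hg.aggregate_samples(sub)
        rng = np.random.default_rng(1)
        rows = sub.sample(20, random_state=2)
        for _, r in rows.iterrows():
            cell = sub[
                (sub["probe_id"] == r["probe_id"]) & (sub["region"] == r["region"])
                & (sub["zone"] == r["zone"]) & (sub["specimen"] == r["specimen"])
            ]["value"].mean()
            got = float(
                t.sel(gene=r["gene"], region=r["region"], zone=r["zone"],
                      specimen=r["specimen"])
            )
            # tensor averages over all probes of the gene present in `sub`
            gene_cell = sub[
                (sub["gene"] == r["gene"]) & (sub["region"] == r["region"])
                & (sub["zone"] == r["zone"]) & (sub["specimen"] == r["specimen"])
            ]["value"].mean()
            assert got == pytest.approx(gene_cell)


class TestMissingness:
    def test_threshold_is_strict(self):
        # gene g1 missing in exactly 11% of slots is dropped; 10% retained
        rows = []
        n_slots = 100
        for i in range(n_slots):
            rows.append(["p0", "g0", "S1", 16.0, f"R{i}", "CP", False, 1.0])
        for i in range(n_slots - 11):
            rows.append(["p1", "g1", "S1", 16.0, f"R{i}", "CP", False, 1.0])
        for i in range(n_slots - 10):
            rows.append(["p2", "g2", "S1", 16.0, f"R{i}", "CP", False, 1.0])
        t = hg.aggregate_samples(make_long(rows))
        kept = hg.filter_missingness(t, 0.10)
        genes = set(kept.coords["gene"].values)
        assert genes == {"g0", "g2"}

    def test_disabled_filter_identity(self, small_expression):
        df, _, _ = small_expression
        t = hg.aggregate_samples(hg.filter_absent(df))
        out = hg.filter_missingness(t, 1.0)
        assert out.sizes == t.sizes


class TestPrepPipeline:
    def test_monotone_shrinkage_and_report(self, small_expression):
        df, _, _ = small_expression
        prep = hg.ExpressionPrep()
        tensor = prep.fit_transform(df)
        rep = prep.qc_report_
        assert rep["probes_removed_absent"] > 0
        assert rep["probes_removed_ds"] > 0
        assert rep["genes_final"] <= rep["genes_after_collapse"] <= rep["probes_input"]
        assert tensor.sizes["zone"] == 5
        assert tensor.sizes["region"] == 27
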