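import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

import hubgene as hg
from hubgene.parcellation import _components
from hubgene.synth import gaussian_random_field
from hubgene._utils import rng_for


class TestSurface:
    def test_single_region(self):
        mesh = hg.gen_surface(1, 10, seed=1)
        assert mesh.n_vertices == 10
        assert len(np.unique(mesh.region)) == 1

    def test_regions_connected(self, small_mesh):
        adj = small_mesh.adjacency_lists()
        assert small_mesh.n_vertices == 400
        for reg in small_mesh.regions:
            members = np.flatnonzero(small_mesh.region == reg)
            assert _components(members, adj) == 1

    def test_determinism_and_errors(self):
        a = hg.gen_surface(4, 100, seed=7)
        b = hg.gen_surface(4, 100, seed=7)
        assert np.array_equal(a.coords, b.coords)
        with pytest.raises(ValueError):
            hg.gen_surface(0, 10)


class TestCohort:
    def test_zero_noise_identical_subjects(self):
        subjects, truth = hg.gen_cohort_connectomes(
            4, n_nodes=40, core_size=5, subject_noise=0.0, seed=2
        )
        for s in subjects:
            assert np.array_equal(s.weights, subjects[0].weights)
        assert np.array_equal(s.weights > 0, truth.template_adjacency)

    def test_symmetry_zero_diagonal_nonnegative(self, small_cohort):
        subjects, _ = small_cohort
        for s in subjects[:3]:
            assert np.array_equal(s.weights, s.weights.T)
            assert np.all(np.diag(s.weights) == 0)
            assert np.all(s.weights >= 0)

    def test_core_in_top_degree_decile(self):
        _, truth = hg.gen_cohort_connectomes(
            1, n_nodes=200, core_size=20, core_boost=1e6, subject_noise=0.0, seed=4
        )
        deg = truth.template_adjacency.sum(axis=0)
        thr = np.percentile(deg, 90)
        core = sorted(truth.planted_core_nodes)
        assert np.mean(deg[core] >= thr) >= 0.9

    def test_core_size_error(self):
        with pytest.raises(ValueError):
            hg.gen_cohort_connectomes(2, n_nodes=10, core_size=10)

    def test_determinism(self):
        a, _ = hg.gen_cohort_connectomes(3, n_nodes=30, core_size=4, seed=9)
        b, _ = hg.gen_cohort_connectomes(3, n_nodes=30, core_size=4, seed=9)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.weights, sb.weights)


class TestSpatialField:
    def test_short_length_uncorrelated(self):
        rng = rng_for(0, "test")
        coords = rng.uniform(0, 100, size=(20, 3))
        f = gaussian_random_field(coords, 1e-15, rng, size=1000)
        c = np.corrcoef(f)
        off = c[np.triu_indices(20, k=1)]
        assert np.abs(off).max() < 0.15

    def test_correlation_monotone_in_length(self):
        rng0 = rng_for(1, "test")
        coords = rng0.uniform(0, 100, size=(25, 3))
        mean_r = []
        for sac in (5.0, 30.0, 200.0):
            f = gaussian_random_field(coords, sac, rng_for(1, "f", sac), size=800)
            c = np.corrcoef(f)
            mean_r.append(c[np.triu_indices(25, k=1)].mean())
        assert mean_r[0] < mean_r[1] < mean_r[2]

    def test_field_tracks_distance(self):
        rng = rng_for(2, "test")
        coords = rng.uniform(0, 100, size=(30, 3))
        f = gaussian_random_field(coords, 30.0, rng, size=2000)
        emp = np.corrcoef(f)
        d = squareform(pdist(coords))
        iu = np.triu_indices(30, k=1)
        rho = spearmanr(d[iu], emp[iu]).statistic
        assert rho < -0.8  # correlation decays with distance


class TestExpressionGenerator:
    def test_null_dataset(self):
        deg = pd.Series(np.arange(10, dtype=float), index=[f"R{i}" for i in range(10)])
        _, truth = hg.gen_expression_dataset(deg, n_genes=20, frac_assoc=0.0, seed=1)
        assert truth.planted_gene_effects == {}

    def test_noiseless_limit_recovers_beta(self):
        regions = [f"R{i}" for i in range(27)]
        deg = pd.Series(np.linspace(0, 200, 27), index=regions)
        df, truth = hg.gen_expression_dataset(
            deg, n_genes=10, frac_assoc=1.0, beta_range=(0.02, 0.02),
            noise_sd=1e-12, shared_sd=1e-12, specimen_sd=1e-12, age_effect_sd=0.0,
            absent_rate=0.0, missing_rate=0.0, replicate_rate=0.0, seed=3,
        )
        gene, (zone, beta) = next(iter(truth.planted_gene_effects.items()))
        sub = df[(df["gene"] == gene) & (df["zone"] == zone)
                 & df["probe_id"].str.endswith("_p0")]
        prof = sub.groupby("region")["value"].mean().loc[regions]
        slope = np.polyfit(deg.to_numpy(), prof.to_numpy(), 1)[0]
        assert slope == pytest.approx(beta, abs=1e-6)

    def test_structure_and_determinism(self, small_expression):
        df, truth, _ = small_expression
        assert set(df["zone"]) == set(hg.synth.ZONES)
        assert df["value"].notna().all()
        assert set(truth.planted_gene_effects) <= set(df["gene"])
        df2, _ = hg.gen_expression_dataset(
            pd.Series(np.linspace(60, 250, 27), index=[f"R{i:02d}" for i in range(27)]),
            n_genes=60, seed=5,
        )
        pd.testing.assert_frame_equal(df, df2)

    def test_specimen_count_error(self):
        deg = pd.Series(np.arange(5, dtype=float), index=list("abcde"))
        with pytest.raises(ValueError):
            hg.gen_expression_dataset(deg, n_genes=5, specimens=[("S1", 16.0)])


class TestGeneSets:
    def test_planted_overlap_exact(self):
        universe = [f"G{i}" for i in range(500)]
        target = universe[:40]
        sets = hg.gen_gene_sets(
            universe, 3, [30], planted_overlap={"SET001": (target, 12)}, seed=2
        )
        assert len(set(sets["SET001"]) & set(target)) == 12
        assert all(len(s) == 30 for s in sets.values())

    def test_overlap_extremes(self):
        universe = [f"G{i}" for i in range(100)]
        target = universe[:20]
        full = hg.gen_gene_sets(universe, 1, [15],
                                planted_overlap={"SET000": (target, 15)}, seed=0)
        assert set(full["SET000"]) <= set(target)
        none = hg.gen_gene_sets(universe, 1, [15],
                                planted_overlap={"SET000": (target, 0)}, seed=0)
        assert set(none["SET000"]) & set(target) == set()

    def test_gmt_roundtrip(self, tmp_path):
        universe = [f"G{i}" for i in range(7457)]
        sets = hg.gen_gene_sets(universe, 2, [50, 100], seed=4)
        path = tmp_path / "sets.gmt"
        from hubgene import io

        io.write_gmt(path, sets)
        assert io.read_gmt(path) == sets

    def test_overlap_too_large(self):
        with pytest.raises(ValueError):
            hg.gen_gene_sets(list("abcdefgh"), 1, [3],
                             planted_overlap={"SET000": (list("abcd"), 4)})


class TestCells:
    def test_null_effect_uncorrelated(self):
        cells = hg.gen_cells(5000, ["A"], geneset=["X1", "X2"], effect=0.0, seed=1)
        scores = hg.cell_geneset_score(cells, ["X1", "X2"])
        r, _ = hg.score_pseudotime_correlation(scores, "A")
        assert abs(r) < 0.1

    def test_strong_effect_high_correlation(self):
        cells = hg.gen_cells(
            2000, ["A"], geneset=["X1"], effect=5.0, noise_sd=0.05, seed=2
        )
        scores = hg.cell_geneset_score(cells, ["X1"])
        r, _ = hg.score_pseudotime_correlation(scores, "A")
        assert r > 0.9

    def test_finite_and_reproducible(self):
        a = hg.gen_cells(100, ["A", "B"], geneset=["X1"], effect=1.0, seed=3)
        b = hg.gen_cells(100, ["A", "B"], geneset=["X1"], effect=1.0, seed=3)
        assert np.all(np.isfinite(a.X))
        assert np.array_equal(a.X, b.X)
        with pytest.raises(ValueError):
            hg.gen_cells(10, [])
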