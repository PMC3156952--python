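import json

import numpy as np
import pytest

from sfspipe import io as sio
from sfspipe.coalescent import (DemographicModel, STUDY_POPULATIONS, expected_sfs,
                                joint_sfs, make_study_mimic, sfs_by_block,
                                simulate_dataset, write_truth, _simulate_genealogy)
from sfspipe.inference import PRESET_OOA3_AF_EASTASIA_EUROPE, build_model

from conftest import build_manifest


class TestModelGrammar:
    def test_duplicate_population_rejected(self):
        with pytest.raises(ValueError):
            DemographicModel(["A", "A"])

    def test_two_roots_rejected(self):
        model = DemographicModel(["A", "B"])
        with pytest.raises(ValueError, match="root"):
            model.compile()

    def test_double_split_rejected(self):
        model = DemographicModel(["A", "B", "C"])
        model.add_split(0.1, "B", "A").add_split(0.2, "B", "C")
        with pytest.raises(ValueError, match="splits twice"):
            model.compile()

    def test_unknown_population(self):
        model = DemographicModel(["A"])
        with pytest.raises(KeyError):
            model.set_size("Z", 1.0, 0.1)

    def test_growth_epochs_compile_to_constant_tail(self):
        # the final (infinite) interval is always constant-size, so any
        # single-root model is guaranteed to coalesce
        model = DemographicModel(["A"])
        model.set_growth("A", 0.0, 0.5, 1.0, 100.0)
        tl = model.compile()
        assert tl.grow[-1, 0] == 0.0
        assert tl.size0[-1, 0] == 100.0

    def test_merge_chain_same_time(self):
        model = DemographicModel(["A", "B", "C"])
        model.add_split(0.1, "C", "B").add_split(0.1, "B", "A")
        tl = model.compile()
        assert set(tl.merge_dst) <= {0}


class TestSimulateDataset:
    def test_expected_segregating_sites_n2(self):
        # E[S] = theta * a1 with a1 = 1 for two chromosomes
        N, mu, L = 8_000, 5e-8, 10_000
        model = DemographicModel(["X"], reference_size=N)
        theta = 4 * N * mu * L
        counts = []
        rng = np.random.default_rng(1)
        for _ in range(2000):
            sim = simulate_dataset(model, {"X": 1}, mu, L,
                                   seed=int(rng.integers(2**31)), n_subloci=1)
            counts.append(sim.n_sites)
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - theta) < 3 * se

    def test_mean_tmrca_two_lineages(self):
        model = DemographicModel(["X"], reference_size=1.0).compile()
        rng = np.random.default_rng(2)
        tm = []
        for _ in range(3000):
            _, _, _, node_time = _simulate_genealogy(
                model, np.zeros(2, np.int64), int(rng.integers(2**31)))
            tm.append(node_time[-1])
        # scaled units: E[TMRCA] = 1 (i.e. 2N generations)
        se = np.std(tm) / np.sqrt(len(tm))
        assert abs(np.mean(tm) - 1.0) < 3 * se

    def test_growth_raises_singleton_fraction(self):
        N, mu, L = 10_000, 1e-7, 5_000
        const = DemographicModel(["X"], reference_size=N)
        growth = DemographicModel(["X"], reference_size=N)
        growth.set_growth("X", 0.0, 0.05, 1.0, 0.02)
        rng = np.random.default_rng(3)
        wins = 0
        trials = 0
        for _ in range(500):
            s1 = simulate_dataset(const, {"X": 5}, mu, L,
                                  seed=int(rng.integers(2**31)), n_subloci=1)
            s2 = simulate_dataset(growth, {"X": 5}, mu, L,
                                  seed=int(rng.integers(2**31)), n_subloci=1)
            if s1.n_sites == 0 or s2.n_sites == 0:
                continue
            f1 = np.mean(s1.haplotypes.sum(axis=1) == 1)
            f2 = np.mean(s2.haplotypes.sum(axis=1) == 1)
            trials += 1
            wins += f2 > f1
        # sign test: growth should win far more often than chance
        assert wins > trials * 0.5 + 3 * np.sqrt(trials * 0.25)

    def test_positions_unique_sorted_within_region(self):
        model = DemographicModel(["X"], reference_size=50_000)
        sim = simulate_dataset(model, {"X": 10}, 1e-7, 2_000, seed=5, n_subloci=4)
        assert len(np.unique(sim.positions)) == sim.n_sites
        assert np.all(np.diff(sim.positions) > 0)
        assert sim.positions.min() >= 1 and sim.positions.max() <= 2_000
        assert np.all((sim.haplotypes.sum(axis=1) > 0)
                      & (sim.haplotypes.sum(axis=1) < sim.n_chrom))

    def test_sample_size_validation(self):
        model = DemographicModel(["X"])
        with pytest.raises(ValueError):
            simulate_dataset(model, {"X": 0}, 1e-8, 100, seed=1)
        with pytest.raises(ValueError):
            simulate_dataset(model, {"X": 2}, 0.0, 100, seed=1)


class TestJointSfs:
    def test_zero_tensor_without_sites(self):
        model = DemographicModel(["X"], reference_size=10.0)
        sim = simulate_dataset(model, {"X": 2}, 1e-9, 10, seed=1, n_subloci=1)
        sfs = joint_sfs(sim, ["X"])
        assert sfs.shape == (5,)
        assert sfs.sum() == sim.n_sites

    def test_single_site_entry(self):
        model = DemographicModel(["A", "B"], reference_size=5_000)
        model.add_split(0.5, "B", "A")
        sim = simulate_dataset(model, {"A": 2, "B": 2}, 1e-7, 1_000, seed=7, n_subloci=1)
        sfs = joint_sfs(sim, ["A", "B"])
        i, j = np.nonzero(sfs)
        counts = np.stack([sim.haplotypes[:, :4].sum(axis=1),
                           sim.haplotypes[:, 4:].sum(axis=1)], axis=1)
        for (a, b), k in zip(zip(i, j), sfs[i, j]):
            assert np.sum((counts[:, 0] == a) & (counts[:, 1] == b)) == k

    def test_total_conserved(self):
        model = DemographicModel(["A", "B"], reference_size=20_000)
        model.add_split(0.2, "B", "A")
        sim = simulate_dataset(model, {"A": 4, "B": 4}, 1e-7, 5_000, seed=9, n_subloci=5)
        sfs = joint_sfs(sim, ["A", "B"])
        assert sfs.sum() == sim.n_sites        # every simulated site segregates
        blocks = sfs_by_block(sim, ["A", "B"])
        assert len(blocks) == 5
        np.testing.assert_array_equal(np.sum(blocks, axis=0), sfs)

    def test_unpolarized_matrix_rejected(self):
        from conftest import build_matrix
        m = build_matrix([[0, 1]])
        mani = build_manifest({"s0": ("P", "G"), "s1": ("P", "G")})
        with pytest.raises(ValueError, match="polarize"):
            joint_sfs(m, ["P"], mani)


class TestExpectedSfs:
    def test_neutral_spectrum(self):
        # E[xi_i] = theta / i for a constant-size population
        n, theta = 10, 2.0
        model = DemographicModel(["X"])
        sfs = expected_sfs(model, {"X": n}, theta, n_replicates=5_000, seed=3)
        i = np.arange(1, n)
        expected = theta / i
        _, se = expected_sfs(model, {"X": n}, theta, n_replicates=2_000, seed=4,
                             return_se=True)
        assert np.all(np.abs(sfs[1:n] - expected) < 3 * np.maximum(se[1:n], 0.02))

    def test_linear_in_theta(self):
        model = DemographicModel(["X"])
        a = expected_sfs(model, {"X": 6}, 1.0, n_replicates=500, seed=7)
        b = expected_sfs(model, {"X": 6}, 2.0, n_replicates=500, seed=7)
        np.testing.assert_allclose(b, 2 * a, rtol=1e-12)

    def test_symmetric_model_symmetric_tensor(self):
        model = DemographicModel(["A", "B"])
        model.add_split(0.3, "B", "A")
        sfs = expected_sfs(model, {"A": 6, "B": 6}, 1.0, n_replicates=20_000, seed=11)
        asym = np.abs(sfs - sfs.T) / (sfs + sfs.T + 0.05)
        assert np.median(asym) < 0.1

    def test_migration_falls_back_to_python_path(self):
        model = DemographicModel(["A", "B"])
        model.add_migration("A", "B", 1.0).add_migration("B", "A", 1.0)
        model.add_split(5.0, "B", "A")
        sfs = expected_sfs(model, {"A": 4, "B": 4}, 1.0, n_replicates=200, seed=2)
        assert sfs.shape == (5, 5)
        assert sfs.sum() > 0

    def test_against_msprime_oracle(self):
        # published three-population model: entrywise agreement with an
        # independent coalescent simulator on marginal spectra
        msprime = pytest.importorskip("msprime")
        p = PRESET_OOA3_AF_EASTASIA_EUROPE
        model, theta = build_model(p, 1.48e-8, 100_000, 25.0)
        n = 10
        mine = expected_sfs(model, {"AF": n, "P1": n, "P2": n}, theta,
                            n_replicates=8_000, seed=1)

        g = 25.0
        r1 = np.log(p.N1 / p.N1_0) / (p.T_12 / g)
        r2 = np.log(p.N2 / p.N2_0) / (p.T_12 / g)
        dem = msprime.Demography()
        dem.add_population(name="AF", initial_size=p.N_Af)
        dem.add_population(name="P1", initial_size=p.N1, growth_rate=r1)
        dem.add_population(name="P2", initial_size=p.N2, growth_rate=r2)
        dem.add_mass_migration(time=p.T_12 / g, source="P2", dest="P1", proportion=1.0)
        dem.add_population_parameters_change(time=p.T_12 / g, population="P1",
                                             initial_size=p.N_B, growth_rate=0)
        dem.add_mass_migration(time=p.T_B / g, source="P1", dest="AF", proportion=1.0)
        dem.add_population_parameters_change(time=p.T_Af / g, population="AF",
                                             initial_size=p.N_A)
        reps = 3_000
        afs = np.zeros((n + 1, n + 1, n + 1))
        for ts in msprime.sim_ancestry(samples={"AF": n // 2, "P1": n // 2, "P2": n // 2},
                                       demography=dem, ploidy=2,
                                       num_replicates=reps, random_seed=17):
            ss = [ts.samples(population=i) for i in range(3)]
            afs += ts.allele_frequency_spectrum(sample_sets=ss, mode="branch",
                                                polarised=True, span_normalise=False)
        afs = afs / reps * 1.48e-8 * 100_000   # branch generations -> expected counts
        mask = np.ones_like(afs, bool)
        mask[0, 0, 0] = mask[n, n, n] = False
        for ax, other in [(0, (1, 2)), (1, (0, 2)), (2, (0, 1))]:
            a = np.where(mask, mine, 0).sum(axis=other)
            b = np.where(mask, afs, 0).sum(axis=other)
            denom = np.maximum(a + b, 1e-3)
            rel = np.abs(a[1:n] - b[1:n]) / denom[1:n]
            assert np.median(rel) < 0.08, (a, b)


class TestStudyMimic:
    def test_population_design(self, mimic_small):
        matrix, manifest, truth = mimic_small
        assert len(manifest.populations) == 12
        assert sorted(manifest.groups) == ["Africa", "EastAsia", "Europe", "India"]
        sizes = {p: len(manifest.samples_of(p)) for p in manifest.populations}
        assert sizes == {p: n for p, (_g, n) in STUDY_POPULATIONS.items()}
        assert matrix.phased and matrix.derived_is_alt is not None
        assert truth["outgroup_divergence"] == 0.012

    def test_seed_reproducible_vcf(self, tmp_path):
        a = make_study_mimic(seed=77, L=5_000, n_subloci=5)[0]
        b = make_study_mimic(seed=77, L=5_000, n_subloci=5)[0]
        pa, pb = tmp_path / "a.vcf", tmp_path / "b.vcf"
        sio.write_genotype_vcf(a, str(pa))
        sio.write_genotype_vcf(b, str(pb))
        assert pa.read_bytes() == pb.read_bytes()

    def test_truth_roundtrip(self, tmp_path):
        _, _, truth = make_study_mimic(seed=5, L=2_000, n_subloci=2)
        path = write_truth(truth, str(tmp_path / "truth.json"))
        assert json.load(open(path)) == truth


class TestSplitTimeFst:
    def test_fst_increases_with_split_time(self):
        from sfspipe import differentiation as diff
        rng = np.random.default_rng(6)
        means = []
        for tau in (0.01, 0.05, 0.1):
            model = DemographicModel(["A", "B"], reference_size=10_000)
            model.add_split(tau, "B", "A")
            vals = []
            for _ in range(200):
                sim = simulate_dataset(model, {"A": 6, "B": 6}, 5e-8, 20_000,
                                       seed=int(rng.integers(2**31)), n_subloci=2)
                if sim.n_sites < 2:
                    continue
                m = sim.to_genotype_matrix()
                mani = build_manifest({s: (p, "G")
                                       for s, p in zip(m.samples, sim.sample_pops)})
                vals.append(diff.wc_fst(m, mani, ["A", "B"]))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]
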