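"""The synthetic-study generator: pedigree structure, gene dropping,
housing constraints, and the trait generative processes."""

import numpy as np
import pytest

import microherit as mh
from microherit.pedigree import PedigreeRecord

RNG = np.random.default_rng


class TestSimulatePedigree:
    def test_no_generations_is_founders_only(self):
        cfg = mh.SimulationConfig(n_founders=6, n_generations=0, seed=0)
        recs, gens = mh.simulate_pedigree(cfg, RNG(0))
        assert len(recs) == 6 and len(gens) == 1
        A = mh.build_relationship_matrix(recs)
        assert np.array_equal(A.values, np.eye(6))

    def test_offspring_counts_are_matings_times_litter_size(self):
        # one litter per female: 5 matings in gen 1, then 10 in gen 2
        cfg = mh.SimulationConfig(n_founders=10, n_generations=2, litter_size=4,
                                  observed_litter_size=4, seed=1)
        recs, gens = mh.simulate_pedigree(cfg, RNG(1))
        assert len(gens[1]) == 5 * 4 and len(gens[2]) == 10 * 4
        assert len(recs) == 10 + 20 + 40

    def test_odd_founders_rejected(self):
        with pytest.raises(ValueError, match="even"):
            mh.SimulationConfig(n_founders=7)

    def test_small_population_accumulates_inbreeding(self):
        # repeated matings among few relatives: some diagonal of A exceeds 1
        cfg = mh.SimulationConfig(n_founders=4, n_generations=4, litter_size=4, seed=3)
        recs, _ = mh.simulate_pedigree(cfg, RNG(3))
        A = mh.build_relationship_matrix(recs)
        assert np.max(np.diag(A.values)) > 1.0


class TestBreedingValues:
    def test_founder_variance(self):
        recs = [PedigreeRecord(f"f{i}", None, None) for i in range(10_000)]
        u = mh.simulate_breeding_values(recs, 2.0, RNG(0))
        assert u.var() == pytest.approx(2.0, rel=0.03)

    def test_full_sib_covariance(self):
        # 10^4 independent families: Cov(sib1, sib2) = 0.5 * sigma2_a
        recs = []
        for f in range(10_000):
            recs += [PedigreeRecord(f"s{f}", None, None),
                     PedigreeRecord(f"d{f}", None, None),
                     PedigreeRecord(f"o1_{f}", f"s{f}", f"d{f}"),
                     PedigreeRecord(f"o2_{f}", f"s{f}", f"d{f}")]
        recs = mh.sort_pedigree(recs)
        u = mh.simulate_breeding_values(recs, 1.0, RNG(1),
                                        inbreeding=np.zeros(len(recs)))
        idx = {r.animal: i for i, r in enumerate(recs)}
        o1 = u[[idx[f"o1_{f}"] for f in range(10_000)]]
        o2 = u[[idx[f"o2_{f}"] for f in range(10_000)]]
        cov = np.cov(o1, o2)[0, 1]
        assert cov == pytest.approx(0.5, abs=0.04)
        assert o1.var() == pytest.approx(1.0, rel=0.05)

    def test_unsorted_pedigree_rejected(self):
        recs = [PedigreeRecord("o", "s", "d"), PedigreeRecord("s", None, None),
                PedigreeRecord("d", None, None)]
        with pytest.raises(ValueError, match="sorted"):
            mh.simulate_breeding_values(recs, 1.0, RNG(0),
                                        inbreeding=np.zeros(3))


class TestLittersAndCages:
    def test_constraint_holds_over_many_seeds(self):
        cfg = mh.SimulationConfig(n_founders=12, n_generations=1, litter_size=6,
                                  observed_litter_size=6,
                                  cage_size=4, max_littermates_per_cage=2)
        for seed in range(100):
            recs, gens = mh.simulate_pedigree(cfg, RNG(seed))
            md = mh.assign_litters_cages(recs, gens[-1], cfg, RNG(seed + 1))
            counts = md.table.groupby(["litter", "cage"]).size()
            assert counts.max() <= 2
            assert md.table.groupby("cage").size().max() <= 4

    def test_one_litter_spreads_over_enough_cages(self):
        cfg = mh.SimulationConfig(n_founders=2, n_generations=1, litter_size=8,
                                  observed_litter_size=8,
                                  cage_size=8, max_littermates_per_cage=2)
        recs, gens = mh.simulate_pedigree(cfg, RNG(5))
        md = mh.assign_litters_cages(recs, gens[-1], cfg, RNG(6))
        assert md.table["cage"].nunique() >= 4  # pigeonhole: 8 kits, <=2 per cage

    def test_single_pair_single_cage(self):
        cfg = mh.SimulationConfig(n_founders=2, n_generations=1, litter_size=2,
                                  cage_size=2, max_littermates_per_cage=2)
        recs, gens = mh.simulate_pedigree(cfg, RNG(7))
        md = mh.assign_litters_cages(recs, gens[-1], cfg, RNG(8))
        assert md.table["cage"].nunique() == 1

    def test_batch_constant_within_litter(self):
        cfg = mh.SimulationConfig(n_founders=12, n_generations=1, litter_size=6)
        recs, gens = mh.simulate_pedigree(cfg, RNG(9))
        md = mh.assign_litters_cages(recs, gens[-1], cfg, RNG(10))
        assert (md.table.groupby("litter")["batch"].nunique() == 1).all()


class TestLmmTrait:
    def test_null_ratios_leave_no_litter_signal(self):
        # beta off: batch is litter-constant, so fixed effects would add a
        # between-litter component of their own
        cfg = mh.SimulationConfig(n_founders=800, n_generations=1, litter_size=4,
                                  observed_litter_size=4,
                                  true_ratios=mh.VarianceRatios(0, 0, 0),
                                  trait_kind="genus", beta_scale=0.0, seed=21)
        st = mh.simulate_study(cfg)  # 400 litters of 4
        y = st.traits.trait("trait_1")
        df = st.metadata.table.assign(y=y)
        litters = df.groupby("litter")["y"]
        k, m = 4, litters.ngroups
        msb = litters.mean().var(ddof=1) * k
        msw = litters.var(ddof=1).mean()
        var_litter = (msb - msw) / k  # one-way ANOVA component
        # 3x the analytic sd of the null component estimate
        sd = np.sqrt(2 * (1 / (m - 1) + 1 / (m * (k - 1))) / k**2) * y.var()
        assert abs(var_litter) < 3 * sd

    def test_sigma2_scaling_doubles_variance(self):
        base = dict(n_founders=40, n_generations=2, litter_size=4,
                    trait_kind="otu", otu_baseline_sd=20.0, seed=31)
        y1 = mh.simulate_study(mh.SimulationConfig(sigma2_P=1.0, **base)).traits.trait("trait_1")
        y2 = mh.simulate_study(mh.SimulationConfig(sigma2_P=2.0, **base)).traits.trait("trait_1")
        assert y2.var() / y1.var() == pytest.approx(2.0, rel=0.02)

    def test_covariance_structure_recovers_true_ratios(self):
        """Moment oracle: regressing the empirical covariance of many
        replicate traits on the kernels recovers (h2, l2, c2) within 0.08."""
        true = mh.VarianceRatios(0.3, 0.2, 0.1)
        cfg = mh.SimulationConfig(n_founders=32, n_generations=2, litter_size=4,
                                  true_ratios=true, trait_kind="otu",
                                  otu_baseline_sd=20.0, beta_scale=0.0,
                                  n_traits=300, seed=41)
        st = mh.simulate_study(cfg)
        Y = st.traits.values.to_numpy(dtype=float)  # n x 300
        mu = 100.0 * (st.design.X @ st.truth["beta_true"]
                      + cfg.otu_baseline_sd * np.sqrt(cfg.sigma2_P))
        R = Y - mu[:, None]
        Shat = R @ R.T / Y.shape[1]
        n = Shat.shape[0]
        feats = np.column_stack([
            (st.kernels.K_A - np.eye(n)).ravel(),
            (st.kernels.K_L - np.eye(n)).ravel(),
            (st.kernels.K_C - np.eye(n)).ravel(),
            np.eye(n).ravel(),
        ])
        coef, *_ = np.linalg.lstsq(feats, Shat.ravel(), rcond=None)
        total = coef[3]
        est = coef[:3] / total
        assert np.all(np.abs(est - true.as_array()) < 0.08)


class TestZipTrait:
    def test_zero_fraction_matches_structural_probability(self):
        cfg = mh.SimulationConfig(n_founders=504, n_generations=1, litter_size=8,
                                  observed_litter_size=8,
                                  model="zip", trait_kind="otu", p_structural=0.3,
                                  sigma2_P=0.5, seed=51)
        st = mh.simulate_study(cfg)  # n = 2016, exp-scale means ~ 30
        y = st.traits.trait("trait_1")
        assert np.mean(y == 0) == pytest.approx(0.3, abs=0.03)

    def test_no_inflation_high_mean_has_no_zeros(self):
        cfg = mh.SimulationConfig(n_founders=40, n_generations=1, litter_size=8,
                                  observed_litter_size=8,
                                  model="zip", trait_kind="otu", p_structural=0.0,
                                  sigma2_P=0.2, zip_baseline=np.log(50.0), seed=52)
        y = mh.simulate_study(cfg).traits.trait("trait_1")
        assert np.mean(y == 0) < 0.01

    def test_outputs_nonnegative_integers(self):
        cfg = mh.SimulationConfig(n_founders=20, n_generations=1, litter_size=4,
                                  model="zip", trait_kind="otu", p_structural=0.5,
                                  seed=53)
        y = mh.simulate_study(cfg).traits.trait("trait_1")
        assert np.all(y >= 0) and np.all(y == np.round(y))


class TestDeterminismAndIO:
    def test_identical_config_identical_study(self):
        cfg = mh.SimulationConfig(n_founders=16, n_generations=2, litter_size=4,
                                  n_traits=2, seed=77)
        a, b = mh.simulate_study(cfg), mh.simulate_study(cfg)
        assert a.traits.values.equals(b.traits.values)
        assert a.metadata.table.equals(b.metadata.table)
        assert a.pedigree == b.pedigree

    def test_roundtrip_through_files(self, tmp_path):
        cfg = mh.SimulationConfig(n_founders=16, n_generations=2, litter_size=4,
                                  trait_kind="otu", model="zip", seed=78)
        st = mh.simulate_study(cfg)
        paths = mh.write_study(st, tmp_path)
        recs = mh.read_pedigree(paths["pedigree"])
        assert set(r.animal for r in recs) == set(r.animal for r in st.pedigree)
        md = mh.StudyMetadata.read(paths["metadata"])
        assert list(md.animals) == st.observed
        tt = mh.TraitTable.read(paths["traits"])
        assert np.array_equal(tt.trait("trait_1"), st.traits.trait("trait_1"))
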