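"""Synthetic incubation generator: contracts, determinism, recovery."""

import numpy as np
import pandas as pd
import pytest

from ashcarbon.core import EndMembers
from ashcarbon.gas_flux import flux_series
from ashcarbon.isotope import fraction_new
from ashcarbon.synthetic import (
    SimulationConfig,
    default_community_profiles,
    generate_asv_table,
    generate_incubation,
    mineralization_schedule,
)


class TestConfigValidation:
    def test_non_increasing_days_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            SimulationConfig(sampling_days=(2, 3, 3, 5))

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            SimulationConfig(true_fraction_new={"S": 1.2})

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            SimulationConfig(noise_sd={"doc": -1.0})


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        a = generate_incubation(SimulationConfig(seed=11))
        b = generate_incubation(SimulationConfig(seed=11))
        pd.testing.assert_frame_equal(a.titrations, b.titrations)
        pd.testing.assert_frame_equal(a.pools, b.pools)
        pd.testing.assert_frame_equal(a.deltas, b.deltas)
        pd.testing.assert_frame_equal(a.asv.counts, b.asv.counts)

    def test_different_seed_differs(self):
        a = generate_incubation(SimulationConfig(seed=11))
        b = generate_incubation(SimulationConfig(seed=12))
        assert not a.pools.equals(b.pools)


class TestNoiseFreeStructure:
    def test_deltas_are_exact_mixtures(self):
        cfg = SimulationConfig(
            seed=0,
            true_fraction_new={"Control": 0.0, "W": 0.0, "S": 0.25, "SW": 0.25},
            end_members=EndMembers(delta_soc_b=-19.5, delta_straw=-27.5, ash_organic_c=0.0),
        ).zero_noise()
        ds = generate_incubation(cfg)
        s_deltas = ds.deltas.query("treatment == 'S'")["delta13c"]
        # 0.25 * (-27.5) + 0.75 * (-19.5) = -21.5 exactly
        assert np.allclose(s_deltas, -21.5, atol=1e-12)

    def test_zero_effect_pools_are_equal(self):
        base = SimulationConfig(seed=0)
        flat = {trt: dict(base.pool_effects["Control"]) for trt in base.pool_effects}
        ds = generate_incubation(
            SimulationConfig(seed=0, pool_effects=flat).zero_noise()
        )
        for col in ds.pools.columns:
            if col in ("treatment", "replicate"):
                continue
            assert ds.pools[col].nunique() == 1

    def test_coverage_one_record_per_cell(self, noisy_dataset):
        ds = noisy_dataset
        assert len(ds.pools) == 12 and len(ds.deltas) == 12
        counts = ds.titrations.groupby(["treatment", "replicate"]).size()
        assert (counts == 14).all()


class TestMineralizationSchedule:
    def test_intervals_nonnegative_and_declining(self):
        ints = mineralization_schedule([2, 3, 4, 5, 7, 10], 900, 0.45, 0.25, 0.05)
        assert (ints >= 0).all()
        # per-day rates decline under first-order decay
        widths = np.diff([0, 2, 3, 4, 5, 7, 10])
        rates = ints / widths
        assert (np.diff(rates) < 0).all()

    def test_conserves_total_when_run_to_completion(self):
        days = np.concatenate([np.arange(1, 119), [1000.0]])
        ints = mineralization_schedule(days, 900.0, 0.45, 0.25, 0.05)
        assert ints.sum() == pytest.approx(900.0, rel=1e-6)

    def test_generated_intervals_nonnegative_with_noise(self, noisy_dataset):
        fluxes = flux_series(noisy_dataset.titrations)
        assert (fluxes["interval_c"] >= 0).all()


class TestParameterRecovery:
    def test_noise_free_recovery_exact(self, noisefree_dataset, treatments_by_code):
        ds = noisefree_dataset
        em = EndMembers()
        for trt in ("S", "SW"):
            dm = ds.truth["material_delta"][trt]
            for d in ds.deltas.query("treatment == @trt")["delta13c"]:
                f = fraction_new(d, em.delta_soc_b, dm)
                assert f == pytest.approx(ds.truth["true_fraction_new"][trt], abs=1e-10)

    def test_mean_recovery_within_2se_under_noise(self):
        """With 0.1 permil delta noise, mean recovered f over 200 runs is unbiased."""
        em = EndMembers()
        truth = 0.25
        n_runs, n_rep = 200, 3
        rng = np.random.default_rng(42)
        dm = em.delta_straw
        mu = truth * dm + (1 - truth) * em.delta_soc_b
        estimates = []
        for _ in range(n_runs):
            deltas = mu + rng.normal(0, 0.1, n_rep)
            estimates.append(
                np.mean([fraction_new(d, em.delta_soc_b, dm) for d in deltas])
            )
        est = np.array(estimates)
        se = est.std(ddof=1) / np.sqrt(n_runs)
        assert abs(est.mean() - truth) < 2 * se


class TestAsvGenerator:
    def test_degenerate_single_taxon(self):
        taxonomy = pd.Series(["P"], index=["t0"])
        table = generate_asv_table(
            {"Control": np.array([1.0])}, taxonomy, n_replicates=5, depth=1000, seed=0
        )
        assert (table.counts["t0"] == 1000).all()

    def test_row_sums_equal_depth(self, noisy_dataset):
        assert (noisy_dataset.asv.counts.sum(axis=1) == 20000).all()

    def test_same_seed_identical(self):
        taxonomy = pd.Series(["P"] * 4, index=[f"t{i}" for i in range(4)])
        profiles = {"Control": np.full(4, 0.25)}
        a = generate_asv_table(profiles, taxonomy, depth=500, seed=3)
        b = generate_asv_table(profiles, taxonomy, depth=500, seed=3)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_uniform_profile_mean_abundance(self):
        """Mean relative abundance approx 0.25 per taxon, within 3 SE of 100 samples."""
        taxonomy = pd.Series(["P"] * 4, index=[f"t{i}" for i in range(4)])
        depth = 1000
        table = generate_asv_table(
            {"Control": np.full(4, 0.25)},
            taxonomy,
            n_replicates=100,
            depth=depth,
            overdispersion=50.0,
            seed=5,
        )
        props = table.counts.div(table.counts.sum(axis=1), axis=0)
        for t in taxonomy.index:
            se = props[t].std(ddof=1) / np.sqrt(len(props))
            assert abs(props[t].mean() - 0.25) < 3 * se

    def test_negative_probability_rejected(self):
        taxonomy = pd.Series(["P"] * 2, index=["t0", "t1"])
        with pytest.raises(ValueError, match="nonnegative"):
            generate_asv_table({"Control": np.array([1.5, -0.5])}, taxonomy, seed=0)

    def test_unnormalized_profile_rejected(self):
        taxonomy = pd.Series(["P"] * 2, index=["t0", "t1"])
        with pytest.raises(ValueError, match="sum to 1"):
            generate_asv_table({"Control": np.array([0.6, 0.5])}, taxonomy, seed=0)

    def test_default_profiles_are_valid(self):
        profiles, taxonomy = default_community_profiles()
        for trt, p in profiles.items():
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            assert (p >= 0).all()
            assert len(p) == len(taxonomy)
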