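"""Forward Wright-Fisher simulator: determinism, demography, age statistics."""

import numpy as np
import pandas as pd
import pytest

import alleleclock as ac
from alleleclock import diffusion as dth
from alleleclock.simulate import (
    AlleleTrajectory,
    DemographyEpoch,
    build_size_schedule,
    per_mutation_mean_ages,
)

SMALL = dict(
    N=60,
    theta=1e-3,
    rho=5e-4,
    region_length=20_000,
    fraction_selected=0.5,
    gamma=-5.0,
)


class TestConfigAndSchedule:
    def test_defaults_follow_population_size(self):
        cfg = ac.SimulationConfig(N=200, seed=1)
        assert cfg.burn_in == 2000
        assert cfg.run_length == 410

    def test_epoch_validation(self):
        with pytest.raises(ValueError):
            DemographyEpoch(start_generation=0)
        with pytest.raises(ValueError):
            DemographyEpoch(start_generation=0, size=100, fraction=0.5)

    def test_schedule_fraction_and_growth(self):
        cfg = ac.SimulationConfig(
            N=100,
            burn_in=10,
            run_length=20,
            seed=1,
            demography=[
                DemographyEpoch(start_generation=5, fraction=0.5),
                DemographyEpoch(start_generation=5, growth_rate=np.log(2.0) / 5),
            ],
        )
        sizes = build_size_schedule(cfg)
        assert sizes[10 + 4] == 100
        # halved at generation 5, then doubling every 5 generations
        assert sizes[10 + 9] == pytest.approx(100, rel=0.05)
        assert sizes[-1] > sizes[10 + 9]

    def test_schedule_collapse_error(self):
        cfg = ac.SimulationConfig(
            N=10,
            burn_in=5,
            run_length=10,
            seed=1,
            demography=[DemographyEpoch(start_generation=1, fraction=0.01)],
        )
        with pytest.raises(ValueError, match="below 2"):
            build_size_schedule(cfg)


class TestSimulation:
    def test_no_mutation_rate_no_alleles(self):
        cfg = ac.SimulationConfig(N=30, theta=0.0, region_length=1000, seed=3)
        res = ac.simulate_trajectories(cfg)
        assert len(res.mutation_table) == 0
        assert res.population.shape[1] == 0

    def test_determinism(self):
        a = ac.simulate_trajectories(ac.SimulationConfig(seed=7, **SMALL))
        b = ac.simulate_trajectories(ac.SimulationConfig(seed=7, **SMALL))
        pd.testing.assert_frame_equal(a.mutation_table, b.mutation_table)
        np.testing.assert_array_equal(a.population, b.population)
        np.testing.assert_array_equal(a.occupancy["count"], b.occupancy["count"])

    def test_every_segregating_allele_has_origin_and_gamma(self):
        res = ac.simulate_trajectories(ac.SimulationConfig(seed=7, **SMALL))
        mt = res.mutation_table
        seg = mt[mt["fate"] == "segregating"]
        assert len(seg) == res.population.shape[1]
        assert (seg["origin_generation"] >= 1).all()
        assert set(np.unique(seg["gamma"])) <= {0.0, SMALL["gamma"]}

    def test_trajectories_start_at_single_copy(self):
        res = ac.simulate_trajectories(
            ac.SimulationConfig(seed=11, N=40, theta=5e-4, rho=0.0,
                                region_length=10_000, fraction_selected=0.0)
        )
        trajs = res.trajectories
        assert trajs, "expected some mutations"
        for tr in trajs[:50]:
            assert tr.frequencies[0] == pytest.approx(1.0 / 80)

    def test_neutral_fixation_probability(self):
        # a neutral new mutation fixes with probability 1/(2N)
        N = 50
        cfg = ac.SimulationConfig(
            N=N,
            burn_in=100,
            run_length=2500,
            theta=4e-3,
            rho=0.0,
            region_length=100_000,
            fraction_selected=0.0,
            seed=13,
            free_recombination=True,
            record_trajectories=False,
        )
        res = ac.simulate_trajectories(cfg)
        mt = res.mutation_table
        resolved = mt[mt["origin_generation"] <= 1500]
        assert len(resolved) > 1e5
        p_hat = (resolved["fate"] == "fixed").mean()
        p = 1.0 / (2 * N)
        se = np.sqrt(p * (1 - p) / len(resolved))
        assert abs(p_hat - p) < 3 * se


class TestAgeByFrequency:
    def _traj(self, freqs, gamma=0.0, fate="segregating"):
        f = np.asarray(freqs, dtype=float)
        return AlleleTrajectory(
            site=1, origin_generation=1, frequencies=f, gamma=gamma,
            final_frequency=f[-1], fate=fate,
        )

    def test_single_allele_bin(self):
        # allele at frequency 0.035 at sampling, age 57 (58 recorded states)
        tr = self._traj(np.full(58, 0.035))
        tab = ac.age_by_frequency([tr], bins=np.arange(0, 1.01, 0.01), mode="final")
        row = tab[np.isclose(tab["bin_low"], 0.03) & (tab["n"] > 0)].iloc[0]
        assert row["n"] == 1
        assert row["mean_age"] == 57
        assert np.isnan(row["se"])

    def test_empty_bins_emitted_flagged(self):
        tr = self._traj([0.5])
        tab = ac.age_by_frequency([tr], bins=np.array([0.0, 0.25, 0.5, 0.75, 1.0]))
        assert len(tab) == 4
        empty = tab[tab["n"] == 0]
        assert (~empty["defined"]).all()

    def test_identical_classes_identical_rows(self):
        t1 = self._traj([0.02, 0.03, 0.02], gamma=0.0)
        t2 = self._traj([0.02, 0.03, 0.02], gamma=-10.0)
        tab = ac.age_by_frequency([t1, t2], bins=np.arange(0, 1.01, 0.01))
        a = tab[tab["gamma"] == 0.0].drop(columns="gamma").reset_index(drop=True)
        b = tab[tab["gamma"] == -10.0].drop(columns="gamma").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            ac.age_by_frequency([])

    def test_deleterious_younger_in_populated_bins(self, theory_sim):
        tab = ac.age_by_frequency(theory_sim, bins=np.arange(0.0, 0.13, 0.01))
        merged = tab[tab["n"] >= 50].pivot_table(
            index="bin_low", columns="gamma", values="mean_age"
        ).dropna()
        assert len(merged) >= 4
        assert (merged[-10.0] < merged[0.0]).all()

    def test_occupation_agrees_with_diffusion(self, theory_sim):
        # the dedicated acceptance check covers every bin; spot-check one here
        tab = ac.age_by_frequency(theory_sim, bins=np.array([0.0, 0.02, 0.04, 1.0]))
        row = tab[np.isclose(tab["bin_low"], 0.02) & (tab["gamma"] == 0.0)].iloc[0]
        theory = dth.expected_age_in_bin(0.02, 0.04, 0.0, n_grid=60) * 2 * 1000
        assert abs(row["mean_age"] - theory) < 3 * row["se"]


@pytest.fixture(scope="module")
def small_run():
    return ac.simulate_trajectories(ac.SimulationConfig(seed=17, **SMALL))


class TestSamplePanel:

    def test_full_sample_matches_population_counts(self, small_run):
        H = small_run.population.shape[0]
        panel, truth = ac.sample_panel(small_run, H, seed=1)
        np.testing.assert_array_equal(
            panel.alt_counts(), truth["sample_count"].to_numpy()
        )
        pop_counts = small_run.population.sum(axis=0)
        seg = (pop_counts > 0) & (pop_counts < H)
        np.testing.assert_array_equal(panel.alt_counts(), pop_counts[seg])

    def test_determinism(self, small_run):
        p1, t1 = ac.sample_panel(small_run, 30, seed=5)
        p2, t2 = ac.sample_panel(small_run, 30, seed=5)
        np.testing.assert_array_equal(p1.matrix, p2.matrix)
        pd.testing.assert_frame_equal(t1, t2)

    def test_oversampling_rejected(self, small_run):
        with pytest.raises(ValueError):
            ac.sample_panel(small_run, small_run.population.shape[0] + 1)

    def test_sample_frequency_unbiased(self, small_run):
        # E[sample frequency] equals population frequency (binomial sampling)
        H = small_run.population.shape[0]
        pop_counts = small_run.population.sum(axis=0)
        seg = (pop_counts > 0) & (pop_counts < H)
        pop_freq = pop_counts[seg] / H
        n, reps = 30, 200
        rng = np.random.default_rng(23)
        tot = np.zeros(pop_freq.size)
        for _ in range(reps):
            p, _ = ac.sample_panel(small_run, n, seed=rng)
            # map sampled variants back by position
            sampled = dict(zip(p.variants["pos"], p.alt_counts()))
            pos = small_run.positions[seg]
            tot += np.array([sampled.get(q, 0) for q in pos])
        mean_freq = tot / (reps * n)
        se = np.sqrt(pop_freq * (1 - pop_freq) * (1 - n / H) / (reps * n))
        ok = np.abs(mean_freq - pop_freq) <= 3 * np.maximum(se, 1e-12)
        assert ok.mean() > 0.98


class TestPerMutationAges:
    def test_selected_younger_observation_units(self, theory_sim):
        neut = per_mutation_mean_ages(theory_sim, (0.02, 0.04), 0.0)
        sel = per_mutation_mean_ages(theory_sim, (0.02, 0.04), -10.0)
        assert neut.size > 100 and sel.size > 100
        assert sel.mean() < neut.mean()
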