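"""Likelihood-model correctness and calibration of the fitness machinery."""

import numpy as np
import pandas as pd
import pytest

from poolcomp.fitness import (
    combine_replicate_estimates,
    estimate_dispersion,
    estimate_mean_fitness,
    frequencies,
    infer_fitness,
    interval_fitness,
    negbin_loglik,
)
from poolcomp.simdata import make_pool, sample_reads, simulate_competition

G = 8


def _noiseless_counts(s_map, f0_map, n_timepoints, depth=1e8, g=G):
    """Exact expected counts under deterministic replicator dynamics."""
    ids = list(s_map)
    s = np.array([s_map[i] for i in ids])
    f = np.array([f0_map[i] for i in ids], float)
    cols = {}
    for t in range(n_timepoints):
        cols[t] = np.round(f * depth).astype(int)
        w = f * np.exp(g * s)
        f = w / w.sum()
    return pd.DataFrame(cols, index=ids)


@pytest.fixture(scope="module")
def sim_setup():
    """300-strain pool, 6 timepoints, depth 1e6, kappa=2 counts."""
    pool = make_pool(300, fitness_spec={"name": "uniform", "low": -0.05, "high": 0.15},
                     n_reference=6, reference_mass=0.1, seed=42)
    traj = simulate_competition(pool, 5, g=G, bottleneck=None, seed=42)
    counts = sample_reads(traj, depth=1e6, dispersion=2.0, seed=42)
    return pool, traj, counts


class TestFrequencies:
    def test_plain_normalisation(self):
        counts = pd.DataFrame({0: [50, 50]}, index=["a", "b"])
        assert np.allclose(frequencies(counts, 0.0)[0], [0.5, 0.5])

    def test_pseudocount_formula(self):
        counts = pd.DataFrame({0: [0, 100]}, index=["a", "b"])
        f = frequencies(counts, 0.5)[0]
        assert np.allclose(f, [0.5 / 101, 100.5 / 101])

    def test_columns_sum_to_one_random(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 100, size=(20, 5)) + 1)
        for pc in (0.0, 0.5, 2.0):
            assert np.allclose(frequencies(counts, pc).sum(axis=0), 1.0)

    def test_all_zero_sample_named(self):
        counts = pd.DataFrame({"T0": [1, 2], "T1": [0, 0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="T1"):
            frequencies(counts)


class TestMeanFitness:
    def test_constant_reference_zero(self):
        freq = pd.DataFrame({t: [0.1, 0.9] for t in range(4)}, index=["REF", "w"])
        track = estimate_mean_fitness(freq, {"REF"}, g=G)
        assert np.allclose(track.xbar, 0.0)

    def test_halving_reference(self):
        freq = pd.DataFrame({0: [0.2, 0.8], 1: [0.1, 0.9]}, index=["REF", "w"])
        track = estimate_mean_fitness(freq, {"REF"}, g=8)
        assert np.isclose(track.xbar[0], np.log(2) / 8)

    def test_matches_simulator_truth(self, sim_setup):
        """Reference decline tracks the true population mean fitness."""
        pool, traj, counts = sim_setup
        freq = frequencies(counts.counts, 0.5)
        track = estimate_mean_fitness(freq, pool.reference_ids, g=G)
        f_true = traj.barcode_frequencies().to_numpy()
        s = pool.fitness
        xbar_true = np.array([
            (f_true[:, t] * s).sum() / f_true[:, t].sum() for t in range(6)])
        mid = (xbar_true[:-1] + xbar_true[1:]) / 2  # interval average
        assert np.all(np.abs(track.xbar - mid) < 0.01)

    def test_requires_reference(self):
        freq = pd.DataFrame({0: [1.0]}, index=["w"])
        with pytest.raises(ValueError):
            estimate_mean_fitness(freq, {"REF"})


class TestDispersion:
    def test_poisson_counts_near_floor(self, neutral_pool):
        """kappa-hat stays near the Poisson floor: median over replicate
        count samplings within [1, 2] (the floor truncates below 1)."""
        traj = simulate_competition(neutral_pool, 5, bottleneck=None, seed=1)
        kaps = [
            estimate_dispersion(
                sample_reads(traj, depth=1e6, dispersion=1.0, seed=s).counts,
                neutral_pool.reference_ids).kappa
            for s in range(50)
        ]
        assert 1.0 <= np.median(kaps) <= 2.0

    def test_kappa_four_calibration(self, neutral_pool):
        """Median kappa-hat over 100 replicate count samplings of a
        neutral pool lands near the true value 4."""
        traj = simulate_competition(neutral_pool, 5, bottleneck=None, seed=2)
        kaps = [
            estimate_dispersion(
                sample_reads(traj, depth=1e5, dispersion=4.0, seed=s).counts,
                neutral_pool.reference_ids).kappa
            for s in range(100)
        ]
        assert 2.5 <= np.median(kaps) <= 6.0

    def test_identical_counts_floor(self):
        counts = pd.DataFrame({t: [100, 100, 100, 700] for t in range(4)},
                              index=["r1", "r2", "r3", "w"])
        noise = estimate_dispersion(counts, {"r1", "r2", "r3"})
        assert noise.kappa == 1.0

    def test_too_few_references(self):
        counts = pd.DataFrame({0: [10, 10, 80], 1: [10, 0, 90]},
                              index=["r1", "r2", "w"])
        with pytest.raises(ValueError, match="reference"):
            estimate_dispersion(counts, {"r1", "r2"})


class TestNegbinLoglik:
    def _track(self, n_tp):
        freq = pd.DataFrame({t: [0.1, 0.9] for t in range(n_tp)}, index=["REF", "w"])
        return estimate_mean_fitness(freq, {"REF"}, g=G)

    def test_poisson_limit_saturated(self):
        """At the saturated point with kappa -> 1 and large counts, the NB
        log-likelihood approaches the Poisson saturated value."""
        track = self._track(4)
        depths = np.full(4, 1e6)
        f0 = 0.01
        counts = np.round(f0 * depths)  # s = 0 predicts the data exactly
        from scipy import stats
        saturated = stats.poisson.logpmf(counts, counts).sum()
        ll = negbin_loglik(0.0, f0, counts, depths, track, kappa=1.0 + 1e-12)
        assert abs(ll - saturated) < 1e-6

    def test_gauge_invariance_of_loglik(self):
        """Adding a constant to s and every mean-fitness value leaves the
        likelihood unchanged."""
        track = self._track(5)
        depths = np.full(5, 1e5)
        counts = np.array([1000, 1100, 1300, 1200, 1500], float)
        base = negbin_loglik(0.03, 0.01, counts, depths, track, kappa=2.0)
        c = 0.17
        shifted = type(track)(track.timepoints, track.xbar + c, track.g)
        other = negbin_loglik(0.03 + c, 0.01, counts, depths, shifted, kappa=2.0)
        assert np.isclose(base, other, atol=1e-9)

    def test_unimodal_profile_on_noiseless_data(self):
        """The 1-D profile in s (f0 fixed at truth) decreases moving away
        from the optimum on noiseless data."""
        counts = _noiseless_counts({"b": 0.05, "REF": 0.0, "bulk": 0.0},
                                   {"b": 0.01, "REF": 0.1, "bulk": 0.89}, 5)
        track = estimate_mean_fitness(frequencies(counts, 0.5), {"REF"}, g=G)
        depths = counts.sum(axis=0).to_numpy(float)
        row = counts.loc["b"].to_numpy(float)
        grid = np.linspace(-0.1, 0.2, 301)
        ll = np.array([negbin_loglik(s, 0.01, row, depths, track, kappa=1.0)
                       for s in grid])
        peak = np.argmax(ll)
        assert np.all(np.diff(ll[:peak]) > 0)
        assert np.all(np.diff(ll[peak:]) < 0)
        assert abs(grid[peak] - 0.05) < 2e-3


class TestInferFitness:
    def test_noiseless_recovery_to_1e6(self):
        counts = _noiseless_counts(
            {"b": 0.1, "r1": 0.0, "r2": 0.0, "r3": 0.0, "bulk": 0.0},
            {"b": 0.01, "r1": 0.1, "r2": 0.1, "r3": 0.1, "bulk": 0.69}, 6)
        est = infer_fitness(counts, {"r1", "r2", "r3"}, g=G)
        assert abs(est.loc["b", "s_hat"] - 0.1) < 1e-6
        assert abs(est.loc["b", "f0_hat"] - 0.01) < 1e-5

    def test_reference_self_consistency(self, sim_setup):
        pool, _, counts = sim_setup
        est = infer_fitness(counts.counts, pool.reference_ids, g=G)
        for r in pool.reference_ids:
            assert abs(est.loc[r, "s_hat"]) < 2 * est.loc[r, "se"] + 1e-3

    def test_parameter_recovery_rmse(self, sim_setup):
        """RMSE of s-hat vs truth <= 0.01/generation for strains starting
        at f0 >= 1e-4."""
        pool, _, counts = sim_setup
        est = infer_fitness(counts.counts, pool.reference_ids, g=G)
        joined = est.join(pool.table.set_index("strain_id"))
        ok = (joined.init_freq >= 1e-4) & ~joined.is_reference & joined.s_hat.notna()
        err = joined.loc[ok, "s_hat"] - joined.loc[ok, "true_fitness"]
        assert len(err) > 250
        assert np.sqrt((err ** 2).mean()) <= 0.01

    def test_se_coverage(self):
        """s_true falls in s_hat +/- 2*se for >= 86% of barcodes.

        Pooled over three independent experiments: within one experiment
        all barcodes share the same mean-fitness and dispersion
        calibration draw, so coverage only concentrates across
        realisations of that shared noise.
        """
        inside_all = []
        for seed in (41, 42, 43):
            pool = make_pool(300, fitness_spec={"name": "uniform", "low": -0.05,
                                                "high": 0.15},
                             n_reference=6, reference_mass=0.1, seed=seed)
            traj = simulate_competition(pool, 5, g=G, bottleneck=None, seed=seed)
            counts = sample_reads(traj, depth=1e6, dispersion=2.0, seed=seed)
            est = infer_fitness(counts.counts, pool.reference_ids, g=G)
            joined = est.join(pool.table.set_index("strain_id"))
            ok = (joined.init_freq >= 1e-4) & ~joined.is_reference & joined.se.notna()
            inside_all.append(
                np.abs(joined.loc[ok, "s_hat"] - joined.loc[ok, "true_fitness"])
                <= 2 * joined.loc[ok, "se"])
        inside = pd.concat(inside_all)
        assert len(inside) >= 200
        assert inside.mean() >= 0.86

    def test_rmse_decreases_with_depth(self):
        """Consistency: deeper sequencing gives tighter estimates."""
        pool = make_pool(50, fitness_spec={"name": "uniform", "low": -0.05, "high": 0.1},
                         n_reference=6, reference_mass=0.1, seed=7,
                         freq_spec={"name": "uniform"})
        traj = simulate_competition(pool, 5, g=G, bottleneck=None, seed=7)
        truth = pool.table.set_index("strain_id")
        rmse = {}
        for depth in (1e4, 1e5, 1e6):
            counts = sample_reads(traj, depth=depth, dispersion=2.0, seed=8)
            est = infer_fitness(counts.counts, pool.reference_ids, g=G)
            j = est.join(truth)
            ok = ~j.is_reference & j.s_hat.notna()
            rmse[depth] = float(np.sqrt(((j.loc[ok, "s_hat"]
                                          - j.loc[ok, "true_fitness"]) ** 2).mean()))
        assert rmse[1e6] < rmse[1e5] * 1.1
        assert rmse[1e5] < rmse[1e4] * 1.1
        assert rmse[1e6] < rmse[1e4]

    def test_extinct_barcode_flagged(self, neutral_pool):
        traj = simulate_competition(neutral_pool, 4, bottleneck=None, seed=3)
        counts = sample_reads(traj, depth=1e4, seed=3).counts
        counts.iloc[0] = 0
        est = infer_fitness(counts, neutral_pool.reference_ids, g=G)
        assert est.iloc[0]["flags"] == "extinct"
        assert np.isnan(est.iloc[0]["s_hat"])

    def test_gauge_invariance_of_estimates(self):
        """Shifting every true fitness by a constant and re-simulating
        leaves reference-relative estimates unchanged (within 1e-3)."""
        base = make_pool(40, fitness_spec={"name": "uniform", "low": -0.05, "high": 0.1},
                         n_reference=6, reference_mass=0.1, seed=9)
        shifted_table = base.table.copy()
        shifted_table["true_fitness"] += 0.25
        import poolcomp.simdata as sd
        shifted = sd.StrainPool(shifted_table)
        results = []
        for pool in (base, shifted):
            traj = simulate_competition(pool, 5, g=G, bottleneck=None, seed=10)
            counts = sample_reads(traj, depth=1e6, dispersion=2.0, seed=10)
            results.append(infer_fitness(counts.counts, base.reference_ids, g=G))
        diff = (results[0]["s_hat"] - results[1]["s_hat"]).abs()
        assert diff.max() < 1e-3


class TestIntervalFitness:
    def test_doubling_rate(self):
        freq = pd.DataFrame({5: [0.05, 0.95], 9: [0.10, 0.90]}, index=["a", "b"])
        out = interval_fitness(freq, 5, 9, g=8)
        assert np.isclose(out.loc["a", "log_fold_change"], np.log(2))
        assert np.isclose(out.loc["a", "per_generation"], np.log(2) / 32)

    def test_constant_zero(self):
        freq = pd.DataFrame({0: [0.4, 0.6], 3: [0.4, 0.6]}, index=["a", "b"])
        assert (interval_fitness(freq, 0, 3)["log_fold_change"] == 0).all()

    def test_telescoping(self):
        rng = np.random.default_rng(1)
        f = rng.dirichlet(np.ones(5), size=4).T
        freq = pd.DataFrame(f, columns=[0, 2, 5, 9])
        full = interval_fitness(freq, 0, 9)["log_fold_change"]
        parts = (interval_fitness(freq, 0, 2)["log_fold_change"]
                 + interval_fitness(freq, 2, 5)["log_fold_change"]
                 + interval_fitness(freq, 5, 9)["log_fold_change"])
        assert np.allclose(full, parts)

    def test_extinct_undefined_and_t1_eq_t2(self):
        freq = pd.DataFrame({0: [0.0, 1.0], 1: [0.5, 0.5]}, index=["a", "b"])
        out = interval_fitness(freq, 0, 1)
        assert np.isnan(out.loc["a", "log_fold_change"])
        with pytest.raises(ValueError):
            interval_fitness(freq, 1, 1)


class TestCombineReplicates:
    def test_inverse_variance_weighting(self):
        reps = {
            "R1": pd.DataFrame({"s_hat": [0.1], "se": [0.01]}, index=pd.Index(["a"], name="strain_id")),
            "R2": pd.DataFrame({"s_hat": [0.2], "se": [0.02]}, index=pd.Index(["a"], name="strain_id")),
        }
        out = combine_replicate_estimates(reps)
        w1, w2 = 1 / 0.01 ** 2, 1 / 0.02 ** 2
        assert np.isclose(out.loc["a", "s_hat"], (0.1 * w1 + 0.2 * w2) / (w1 + w2))
        assert np.isclose(out.loc["a", "se"], np.sqrt(1 / (w1 + w2)))
        assert np.isclose(out.loc["a", "s_mean_unweighted"], 0.15)
        assert out.loc["a", "n_replicates"] == 2
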