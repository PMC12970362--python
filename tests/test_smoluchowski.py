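"""Coagulation dynamics, kernel estimation, and kernel-form discovery."""

import numpy as np
import pytest

from slicdd.smoluchowski import (ClusterTimeseries, constant_kernel_closed_form,
                                 discover_kernel, estimate_kernel,
                                 simulate_smoluchowski, synthetic_cluster_data)


@pytest.fixture(scope="module")
def constant_runs():
    return synthetic_cluster_data("constant", k0=0.8, seed=3)


@pytest.fixture(scope="module")
def constant_estimate(constant_runs):
    runs, _ = constant_runs
    return estimate_kernel(runs)


class TestSimulator:
    def test_constant_kernel_matches_closed_form(self):
        kmax, k0, n_total = 50, 1.0, 1.0
        kern = np.full((kmax, kmax), k0)
        n0 = np.zeros(kmax)
        n0[0] = n_total
        t = np.linspace(0.0, 2.0, 21)
        sim = simulate_smoluchowski(kern, n0, t)
        sizes = np.arange(1, kmax + 1)
        mass = sim.counts @ sizes
        assert np.abs(mass / mass[0] - 1.0).max() < 0.01  # truncation negligible
        ref = constant_kernel_closed_form(k0, n_total, sizes, t)
        sel = ref > 1e-6
        assert np.abs((sim.counts[sel] - ref[sel]) / ref[sel]).max() < 5e-3

    def test_zero_kernel_freezes_counts(self):
        kern = np.zeros((5, 5))
        n0 = np.array([0.5, 0.3, 0.1, 0.05, 0.05])
        sim = simulate_smoluchowski(kern, n0, np.linspace(0, 5, 11))
        assert np.allclose(sim.counts, n0, atol=1e-12)

    def test_monomer_mass_conserved_until_truncation(self):
        kmax = 20
        kern = np.full((kmax, kmax), 0.5)
        n0 = np.zeros(kmax)
        n0[0] = 1.0
        t = np.linspace(0, 1.0, 21)
        sim = simulate_smoluchowski(kern, n0, t)
        sizes = np.arange(1, kmax + 1)
        mass = sim.counts @ sizes
        top = sim.counts[:, -kmax // 10:] @ sizes[-kmax // 10:]
        while_empty = top / mass[0] < 1e-6
        assert np.abs(mass[while_empty] / mass[0] - 1.0).max() < 1e-3
        assert np.all(np.diff(mass) <= 1e-12)  # mass never increases

    def test_agrees_with_brute_force_euler(self):
        """Independent oracle: double-loop explicit Euler at tiny steps."""
        kmax = 5
        rng = np.random.default_rng(2)
        kern = rng.uniform(0.2, 1.0, size=(kmax, kmax))
        kern = 0.5 * (kern + kern.T)
        n = np.array([1.0, 0.2, 0.1, 0.05, 0.02])
        t_end, n_steps = 0.5, 200_000
        dt = t_end / n_steps
        state = n.copy()
        for _ in range(n_steps):
            dn = np.zeros(kmax)
            for k in range(1, kmax + 1):
                gain = sum(kern[i - 1, k - i - 1] * state[i - 1] * state[k - i - 1]
                           for i in range(1, k))
                loss = state[k - 1] * sum(kern[k - 1, j - 1] * state[j - 1]
                                          for j in range(1, kmax + 1))
                dn[k - 1] = 0.5 * gain - loss
            state = state + dt * dn
        sim = simulate_smoluchowski(kern, n, np.array([0.0, t_end]))
        assert np.abs(sim.counts[-1] - state).max() < 1e-4

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_smoluchowski(-np.ones((3, 3)), np.ones(3), np.linspace(0, 1, 5))
        with pytest.raises(ValueError):
            simulate_smoluchowski(np.triu(np.ones((3, 3))), np.ones(3),
                                  np.linspace(0, 1, 5))
        with pytest.raises(ValueError):
            ClusterTimeseries(-np.ones((4, 3)), np.linspace(0, 1, 4))


class TestEstimation:
    def test_constant_kernel_recovered_within_five_percent(self, constant_estimate):
        assert constant_estimate.converged
        assert np.abs(constant_estimate.values - 0.8).max() / 0.8 < 0.05

    def test_zero_kernel_estimates_near_zero(self):
        kmax = 4
        n0 = np.array([0.5, 0.3, 0.15, 0.05])
        data = simulate_smoluchowski(np.zeros((kmax, kmax)), n0,
                                     np.linspace(0, 2, 11))
        est = estimate_kernel(data)
        assert np.abs(est.values).max() < 1e-4

    def test_dilution_halves_growth_rate(self):
        """Constant kernel: the early mean-size growth rate scales with the
        initial concentration (basis of the dilution prediction)."""
        kmax = 20
        kern = np.full((kmax, kmax), 1.0)
        t = np.linspace(0, 0.4, 9)
        rates = []
        for n_total in (1.0, 0.5):
            n0 = np.zeros(kmax)
            n0[0] = n_total
            sim = simulate_smoluchowski(kern, n0, t)
            sizes = np.arange(1, kmax + 1)
            mean_size = (sim.counts @ sizes) / sim.counts.sum(axis=1)
            rates.append((mean_size[1] - mean_size[0]) / (t[1] - t[0]))
        assert rates[0] / rates[1] == pytest.approx(2.0, rel=0.1)

    def test_symmetrized_target_doubles_pairs(self, constant_estimate):
        i, j, v = constant_estimate.symmetrized()
        n = constant_estimate.values.size
        assert i.size == 2 * n
        assert np.array_equal(i[:n], constant_estimate.j_idx[:n] * 0 + constant_estimate.i_idx)
        assert np.array_equal(i[n:], constant_estimate.j_idx)

    def test_too_few_timepoints(self):
        with pytest.raises(ValueError):
            estimate_kernel(ClusterTimeseries(np.ones((2, 4)), np.array([0.0, 1.0])))


class TestDiscovery:
    def test_constant_kernel_yields_constant_component_alone(self, constant_runs,
                                                             constant_estimate):
        runs, _ = constant_runs
        model = discover_kernel(runs, criterion="slic", seed=3,
                                estimate=constant_estimate)
        assert model.active_components == ["1"]
        coef = model.component_coefficients.coefficients[0, 0]
        assert coef == pytest.approx(0.8, rel=0.05)
        assert np.allclose(model.kernel_values, model.kernel_values.T)

    def test_planted_fractal_dimension_recovered(self):
        runs, kern = synthetic_cluster_data("shear", df=2.0, seed=5)
        est = estimate_kernel(runs, max_nfev=1000, ridge=1e-10)
        model = discover_kernel(runs, criterion="slic", seed=5, estimate=est)
        assert abs(model.df - 2.0) < 0.1
        active = set(model.active_components)
        assert {"(i/j)^(1/df)", "(j/i)^(1/df)"} <= active
        coefs = dict(zip(model.component_coefficients.term_labels,
                         model.component_coefficients.coefficients[:, 0]))
        dominant = max(abs(coefs["(i/j)^(1/df)"]), abs(coefs["(j/i)^(1/df)"]))
        assert dominant == pytest.approx(0.4, rel=0.05)
        for lab, c in coefs.items():
            if lab not in ("(i/j)^(1/df)", "(j/i)^(1/df)"):
                assert abs(c) < 0.02 * dominant, lab

    def test_seed_contract(self, constant_runs, constant_estimate):
        runs, _ = constant_runs
        a = discover_kernel(runs, criterion="slic", seed=11, estimate=constant_estimate)
        b = discover_kernel(runs, criterion="slic", seed=11, estimate=constant_estimate)
        assert a.df == b.df
        assert np.array_equal(a.component_coefficients.coefficients,
                              b.component_coefficients.coefficients)

    def test_slic_no_denser_than_aic_across_seeds(self, constant_runs):
        """Sparsity contrast on noisy estimates of a constant kernel."""
        runs, _ = constant_runs
        rng = np.random.default_rng(0)
        slic_k, aic_k = [], []
        for seed in range(10):
            noisy = [ClusterTimeseries(
                np.clip(r.counts * (1 + 0.02 * rng.normal(size=r.counts.shape)), 0, None),
                r.time_grid) for r in runs]
            est = estimate_kernel(noisy, max_nfev=60)
            ms = discover_kernel(noisy, criterion="slic", seed=seed, estimate=est)
            ma = discover_kernel(noisy, criterion="aic", seed=seed, estimate=est)
            slic_k.append(len(ms.active_components))
            aic_k.append(len(ma.active_components))
        assert all(s <= a for s, a in zip(slic_k, aic_k))
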