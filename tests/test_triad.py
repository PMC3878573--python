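import itertools

import numpy as np
import pandas as pd
import pytest

from gatatriad import synthetic, triad
from gatatriad.triad import (
    ALL_EDGES,
    DEFAULT_TIME_GRID,
    GENES,
    UNKNOWN_EDGES,
    CircuitArchitecture,
    DynamicsParameters,
    FitResult,
    InteractionTimeProfile,
    default_timeprofiles,
    derive_timeprofiles,
    energy,
    enumerate_architectures,
    fit_architecture,
    knockdown_predict,
    normalize_minmax,
    rank_and_consensus,
    simulate,
)


class TestEnumeration:
    def test_exactly_32_distinct(self):
        archs = enumerate_architectures()
        assert len(archs) == 32
        vectors = {a.unknown_signs for a in archs}
        assert vectors == set(itertools.product([+1, -1], repeat=5))

    def test_id_zero_all_negative(self):
        a0 = CircuitArchitecture.from_id(0)
        assert all(a0.signs[e] == -1 for e in UNKNOWN_EDGES)
        a31 = CircuitArchitecture.from_id(31)
        assert all(a31.signs[e] == +1 for e in UNKNOWN_EDGES)

    def test_fixed_edges_constant_across_architectures(self):
        for a in enumerate_architectures():
            assert a.signs["G1->G1"] == +1 and a.signs["P->P"] == +1
            assert a.signs["G1-|P"] == -1 and a.signs["P-|G1"] == -1

    def test_a2_is_most_significant_bit(self):
        # id 16 = 10000 -> only G2->G2 positive
        a = CircuitArchitecture.from_id(16)
        assert a.signs["G2->G2"] == +1
        assert all(a.signs[e] == -1 for e in UNKNOWN_EDGES[1:])


class TestTimeProfiles:
    def test_trend_classification(self):
        profiles = derive_timeprofiles(
            {
                "G2->G2": (10.0, 2.0),  # strongest in MP, diminishes
                "P->P": (8.0, 9.0),  # essentially constant
                "G1->G1": (1.0, 8.0),  # appears in E cells
            }
        )
        assert profiles["G2->G2"].trend == "decreasing"
        assert profiles["P->P"].trend == "constant"
        assert profiles["G1->G1"].trend == "increasing"

    def test_zero_mp_capped(self):
        profiles = derive_timeprofiles({"G1->G1": (0.0, 5.0)})
        assert profiles["G1->G1"].trend == "increasing"
        assert profiles["G1->G1"].lam == pytest.approx(np.log(8.0))

    def test_constant_requires_zero_rate(self):
        with pytest.raises(ValueError):
            InteractionTimeProfile("constant", 0.5)


class TestSimulate:
    def test_pure_decay_matches_closed_form(self):
        arch = CircuitArchitecture.from_id(0)
        gamma = np.array([0.08, 0.05, 0.12])
        params = DynamicsParameters(
            alpha=np.zeros(3), gamma=gamma,
            strengths={e: 1.0 for e in ALL_EDGES}, x_input=0.0,
        )
        x0 = np.array([0.9, 0.5, 0.7])
        tr = simulate(arch, default_timeprofiles(), params, x0=x0, rtol=1e-10, atol=1e-12)
        expected = x0[:, None] * np.exp(-gamma[:, None] * tr.time[None, :])
        assert np.max(np.abs(tr.values - expected)) < 1e-6

    def test_saturating_activation_steady_state(self):
        # enormous constant self-activation: production saturates at alpha
        arch = CircuitArchitecture.from_id(31)
        params = DynamicsParameters(
            alpha=np.array([0.2, 0.2, 0.2]), gamma=np.array([0.1, 0.1, 0.1]),
            strengths={e: (1e8 if e in ("G1->G1", "G2->G2", "P->P") else 0.0) for e in ALL_EDGES},
            x_input=0.0,
        )
        profiles = {e: InteractionTimeProfile("constant", 0.0) for e in ALL_EDGES}
        grid = np.linspace(0, 500, 26)
        tr = simulate(arch, profiles, params, time_grid=grid, x0=np.array([0.5, 0.5, 0.5]))
        assert np.allclose(tr.values[:, -1], 2.0, atol=1e-4)  # alpha/gamma

    def test_constant_trends_converge_to_fixed_point(self):
        arch, _prof, params, x0 = synthetic.triad_truth()
        profiles = {e: InteractionTimeProfile("constant", 0.0) for e in ALL_EDGES}
        grid = np.linspace(0, 4000, 41)
        tr = simulate(arch, profiles, params, time_grid=grid, x0=x0)
        rhs = triad._rhs_factory(arch, profiles, params, False)
        assert np.linalg.norm(rhs(grid[-1], tr.values[:, -1])) < 1e-8

    def test_tolerance_convergence(self):
        arch, prof, params, x0 = synthetic.triad_truth()
        t1 = simulate(arch, prof, params, x0=x0, rtol=1e-8, atol=1e-10)
        t2 = simulate(arch, prof, params, x0=x0, rtol=5e-9, atol=5e-11)
        assert np.max(np.abs(t1.values - t2.values)) < 1e-5


class TestEnergy:
    def test_zero_iff_equal(self):
        obs = np.random.default_rng(0).random((3, 13))
        assert energy(obs, obs) == 0.0
        assert energy(obs + 1e-3, obs) > 0

    def test_uniform_offset_arithmetic(self):
        obs = np.zeros((3, 13))
        sim = obs + 0.1
        assert energy(sim, obs) == pytest.approx(0.39)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(1)
        sim, obs = rng.random((3, 13)), rng.random((3, 13))
        perm = [2, 0, 1]
        assert energy(sim, obs) == pytest.approx(energy(sim[perm], obs[perm]))

    def test_grid_mismatch_rejected(self):
        tr = triad.Trajectory(time=np.arange(5.0), values=np.zeros((3, 5)))
        obs = synthetic.simulate_noisy_timecourse(*_truth_args(), noise_sd=0.0, seed=0)[0]
        with pytest.raises(ValueError):
            energy(tr, obs)

    def test_normalize_minmax_range(self):
        vals = np.array([[1.0, 3.0, 2.0], [5.0, 5.0, 5.0], [0.0, 10.0, 5.0]])
        out = normalize_minmax(vals)
        assert out.min() >= 0 and out.max() <= 1
        assert np.allclose(out[1], 0.0)  # flat gene pinned at zero


def _truth_args():
    arch, prof, params, x0 = synthetic.triad_truth()
    return arch, params


class TestFitting:
    def test_seed_reproducibility(self):
        arch, prof, params, x0 = synthetic.triad_truth()
        obs, _ = synthetic.simulate_noisy_timecourse(
            arch, params, noise_sd=0.05, seed=0, timeprofiles=prof, x0=x0
        )
        f1 = fit_architecture(arch, obs, prof, n_starts=40, n_keep=10, seed=5,
                              refine="stochastic", refine_rounds=5)
        f2 = fit_architecture(arch, obs, prof, n_starts=40, n_keep=10, seed=5,
                              refine="stochastic", refine_rounds=5)
        assert [f.energy for f in f1] == [f.energy for f in f2]
        assert all(np.array_equal(a.u, b.u) for a, b in zip(f1, f2))

    def test_energies_sorted_and_nonnegative(self):
        arch, prof, params, x0 = synthetic.triad_truth()
        obs, _ = synthetic.simulate_noisy_timecourse(
            arch, params, noise_sd=0.05, seed=1, timeprofiles=prof, x0=x0
        )
        fits = fit_architecture(arch, obs, prof, n_starts=50, n_keep=20, seed=0,
                                refine=None)
        es = [f.energy for f in fits]
        assert es == sorted(es) and es[0] >= 0

    def test_n_starts_must_cover_n_keep(self):
        arch, prof, params, x0 = synthetic.triad_truth()
        obs, _ = synthetic.simulate_noisy_timecourse(
            arch, params, noise_sd=0.05, seed=1, timeprofiles=prof, x0=x0
        )
        with pytest.raises(ValueError):
            fit_architecture(arch, obs, prof, n_starts=5, n_keep=10)

    def test_true_architecture_outfits_wrong_sign(self):
        # noise-free data; the sign-flipped architecture cannot reach the
        # truth's energy floor
        arch, prof, params, x0 = synthetic.triad_truth(-1)
        obs, _ = synthetic.simulate_noisy_timecourse(
            arch, params, noise_sd=0.0, seed=0, timeprofiles=prof, x0=x0
        )
        flipped = CircuitArchitecture.from_id(arch.arch_id | 0b00010)
        # the local search is a multi-start method: take the best of two
        # independent restarts per architecture
        e_true = min(
            fit_architecture(arch, obs, prof, n_starts=300, n_keep=50, seed=s,
                             refine="stochastic", refine_rounds=30)[0].energy
            for s in (0, 2)
        )
        e_flip = min(
            fit_architecture(flipped, obs, prof, n_starts=300, n_keep=50, seed=s,
                             refine="stochastic", refine_rounds=30)[0].energy
            for s in (0, 2)
        )
        assert e_true < 0.2
        assert e_flip >= 5 * e_true


class TestConsensus:
    @staticmethod
    def _fit(arch_id, e):
        arch = CircuitArchitecture.from_id(arch_id)
        return FitResult(architecture=arch, u=np.zeros(triad.N_PARAMS),
                         params=None, energy=e)

    def test_single_architecture_consensus_is_its_signs(self):
        fits = {7: [self._fit(7, 0.1), self._fit(7, 0.2)]}
        consensus, _ = rank_and_consensus(fits, low_energy_quantile=1.0)
        arch = CircuitArchitecture.from_id(7)
        for _, row in consensus.iterrows():
            assert row["consensus_sign"] == arch.signs[row["edge"]]

    def test_low_energy_selection(self):
        # low-energy fits all share arch 0 (all-negative); high-energy arch 31
        fits = {0: [self._fit(0, 0.1)] * 3, 31: [self._fit(31, 10.0)] * 3}
        consensus, summary = rank_and_consensus(fits, low_energy_quantile=0.5)
        assert (consensus["consensus_sign"] == -1).all()
        assert set(summary["arch_id"]) == {0, 31}

    def test_empty_fits_rejected(self):
        with pytest.raises(ValueError):
            rank_and_consensus({0: []})

    def test_grouping_by_gata2_pu1_sign(self):
        fits = {i: [self._fit(i, float(i))] for i in range(32)}
        _, summary = rank_and_consensus(fits)
        for _, row in summary.iterrows():
            expected = CircuitArchitecture.from_id(int(row["arch_id"])).signs["G2->P"]
            assert row["gata2_pu1_sign"] == expected


class TestKnockdown:
    @staticmethod
    def _truth_fit(sign=-1):
        arch, prof, params, x0 = synthetic.triad_truth(sign)
        fit = FitResult(architecture=arch, u=np.zeros(triad.N_PARAMS),
                        params=params, energy=0.0, x0=x0)
        return fit, prof

    def test_zero_fraction_no_change(self):
        fit, prof = self._truth_fit()
        out = knockdown_predict(fit, "Gata2", 0.0, timeprofiles=prof)
        assert all(abs(v["delta"]) < 1e-9 for v in out.values())

    def test_gata2_kd_increases_pu1(self):
        fit, prof = self._truth_fit(-1)
        out = knockdown_predict(fit, "Gata2", 0.7, timeprofiles=prof)
        assert out["Pu.1"]["sign"] == +1

    def test_pu1_kd_leaves_autonomous_gata2_unchanged(self):
        # in the ground-truth circuit no PU.1->GATA2 (or GATA1->GATA2) edge
        # carries weight, so Gata2 is autonomous
        fit, prof = self._truth_fit(-1)
        out = knockdown_predict(fit, "Pu.1", 0.7, timeprofiles=prof)
        assert abs(out["Gata2"]["delta"]) < 1e-3

    def test_invalid_fraction(self):
        fit, prof = self._truth_fit()
        with pytest.raises(ValueError):
            knockdown_predict(fit, "Gata2", 1.0, timeprofiles=prof)
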