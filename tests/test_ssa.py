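import math

import numpy as np
import pytest
from scipy import stats

import epigrn as eg
from conftest import zero_rate_params


def _protein_only_params(p_bar_O=0.0, gamma_hat=1.0, **kw):
    """Chromatin frozen (all chromatin rates 0); only protein channels act."""
    return zero_rate_params(p_bar_O=p_bar_O, gamma_hat=gamma_hat, **kw)


class TestSimulateBasics:
    def test_empty_system_keeps_state_constant(self):
        params = zero_rate_params()
        system = eg.build_reaction_system(params)
        init = eg.initial_state(params, "repressed")
        init[15:18] = (7, 3, 1)
        traj = eg.simulate(system, init,
                           eg.SimulationConfig(tau_end=50.0, seed=4))
        assert traj.event_count == 0
        assert np.all(traj.states == init)

    def test_seed_reproducibility_is_bit_identical(self, default_params,
                                                   warm_kernel):
        system = eg.build_reaction_system(default_params)
        init = eg.initial_state(default_params, "active")
        cfg = lambda s: eg.SimulationConfig(tau_end=30.0, seed=s)
        t1 = eg.simulate(system, init, cfg(123))
        t2 = eg.simulate(system, init, cfg(123))
        t3 = eg.simulate(system, init, cfg(124))
        assert np.array_equal(t1.states, t2.states)
        assert t1.event_count == t2.event_count
        assert not np.array_equal(t1.states, t3.states)

    def test_nucleosome_conservation_at_every_sample(self, default_params,
                                                     warm_kernel):
        system = eg.build_reaction_system(default_params)
        init = eg.initial_state(default_params, "active")
        traj = eg.simulate(system, init,
                           eg.SimulationConfig(tau_end=201.6, seed=11))
        for g in range(3):
            sums = traj.gene_counts(g).sum(axis=1)
            assert np.all(sums == default_params.D_tot)

    def test_invalid_init_rejected(self, default_params):
        system = eg.build_reaction_system(default_params)
        bad = np.zeros(18, dtype=np.int64)   # gene sums are 0, not D_tot
        with pytest.raises(eg.ParameterError, match="D_tot"):
            eg.simulate(system, bad, eg.SimulationConfig(tau_end=1.0))

    def test_trajectory_frame_is_tidy(self, default_params, warm_kernel):
        system = eg.build_reaction_system(default_params)
        init = eg.initial_state(default_params, "active")
        traj = eg.simulate(system, init,
                           eg.SimulationConfig(tau_end=9.6, seed=2))
        df = traj.to_frame(replicate=3)
        assert set(df.columns) == {"tau", "day", "gene", "n_D", "n_A", "n_R1",
                                   "n_R2", "n_R12", "X_O", "X_T", "X_J",
                                   "replicate"}
        assert sorted(df["gene"].unique()) == ["J", "O", "T"]
        assert (df["replicate"] == 3).all()

    def test_child_seeds_are_stable_distinct_and_below_2_31(self):
        seeds = [eg.child_seed(42, i) for i in range(500)]
        assert seeds == [eg.child_seed(42, i) for i in range(500)]
        assert len(set(seeds)) == 500
        assert all(0 <= s < 2 ** 31 for s in seeds)


class TestProteinBirthDeath:
    def test_stationary_law_is_poisson(self, warm_kernel):
        """Frozen n^A = 10 with p_bar*gamma = 0.4 gives birth rate 4 and unit
        decay: the stationary law is Poisson(4)."""
        params = _protein_only_params(p_bar_O=0.4, gamma_hat=1.0).with_updates(
            D_tot=10)
        system = eg.build_reaction_system(params)
        init = np.zeros(18, dtype=np.int64)
        for g in range(3):
            init[5 * g + 1] = 10   # n_A frozen at 10
        init[15] = 4
        spacing, n_samples = 8.0, 2500
        grid = np.arange(1, n_samples + 1) * spacing
        cfg = eg.SimulationConfig(tau_end=grid[-1], sample_grid=grid, seed=77)
        traj = eg.simulate(system, init, cfg)
        x = traj.states[:, 15]
        lam = 4.0
        se = math.sqrt(lam / n_samples)
        assert abs(x.mean() - lam) < 3 * se
        kmax = int(x.max())
        counts = np.bincount(x, minlength=kmax + 1)
        probs = stats.poisson.pmf(np.arange(kmax + 1), lam)
        # pool bins with small expectation into the tails
        exp = probs * n_samples
        lo = np.searchsorted(np.cumsum(exp), 5.0)
        hi = kmax - np.searchsorted(np.cumsum(exp[::-1]), 5.0)
        obs = np.array([counts[:lo + 1].sum(), *counts[lo + 1:hi],
                        counts[hi:].sum()])
        expd = np.array([exp[:lo + 1].sum(), *exp[lo + 1:hi], exp[hi:].sum()])
        expd = expd * obs.sum() / expd.sum()
        _, pval = stats.chisquare(obs, expd)
        assert pval > 0.01


class TestPiecewiseConstantInputs:
    def test_transient_overexpression_matches_closed_form_mean(self, warm_kernel):
        """Pure input/decay for one gene: u on [0, 2) then off. The mean is
        u(1 - e^-t) during the pulse and decays as e^-(t-2) afterwards."""
        params = _protein_only_params(gamma_hat=1.0)
        system = eg.build_reaction_system(params)
        init = eg.initial_state(params, "repressed")
        u = 50.0
        sched = eg.OverexpressionSchedule({"O": [(0.0, 2.0, u)]})
        grid = np.array([2.0, 4.0])
        n = 2000
        vals = np.empty((n, 2))
        for i in range(n):
            cfg = eg.SimulationConfig(tau_end=4.0, sample_grid=grid.copy(),
                                      seed=eg.child_seed(5, i))
            vals[i] = eg.simulate(system, init, cfg, sched).states[:, 15]
        m_pulse = u * (1 - math.exp(-2.0))
        m_after = m_pulse * math.exp(-2.0)
        for k, expected in enumerate((m_pulse, m_after)):
            se = vals[:, k].std(ddof=1) / math.sqrt(n)
            assert abs(vals[:, k].mean() - expected) < 3 * se


class TestDivisionMode:
    def test_division_requires_matching_system(self, default_params):
        system = eg.build_reaction_system(default_params)  # dilution kept
        init = eg.initial_state(default_params, "active")
        with pytest.raises(eg.ParameterError, match="division"):
            eg.simulate(system, init,
                        eg.SimulationConfig(tau_end=10.0,
                                            division_mode="binomial"))

    def test_invalid_division_period_rejected(self):
        with pytest.raises(eg.ParameterError):
            eg.SimulationConfig(tau_end=10.0, division_period=-1.0)

    def test_protein_partitioning_is_binomial_half(self, warm_kernel):
        """One division of 100 molecules: mean 50, binomial(100, 1/2) spread."""
        params = zero_rate_params(eps_d=0.2)
        system = eg.build_reaction_system(params, division_mode=True)
        init = eg.initial_state(params, "repressed")
        init[15] = 100
        period = math.log(2) / 0.2
        grid = np.array([period + 0.01])
        n = 1000
        vals = np.empty(n)
        for i in range(n):
            cfg = eg.SimulationConfig(tau_end=period + 0.01, sample_grid=grid.copy(),
                                      seed=eg.child_seed(6, i),
                                      division_mode="binomial")
            vals[i] = eg.simulate(system, init, cfg).states[0, 15]
        se = math.sqrt(100 * 0.25 / n)
        assert abs(vals.mean() - 50.0) < 3 * se
        assert 3.0 < vals.std(ddof=1) < 7.0   # ~ sqrt(25) = 5

    @pytest.mark.parametrize("eta, lost_fraction", [(0.0, 0.0), (1.0, 0.5)])
    def test_cpg_loss_at_division_follows_eta(self, eta, lost_fraction,
                                              warm_kernel):
        """eta = 0: perfect maintenance, no CpGme loss; eta = 1: pure
        dilution, each mark lost with probability 1/2."""
        params = zero_rate_params(eps_d=0.2, eta=eta)
        system = eg.build_reaction_system(params, division_mode=True)
        init = np.zeros(18, dtype=np.int64)
        for g in range(3):
            init[5 * g + 2] = params.D_tot     # all CpGme-only (D^R1)
        period = math.log(2) / 0.2
        grid = np.array([period + 0.01])
        n = 400
        kept = np.empty(n)
        for i in range(n):
            cfg = eg.SimulationConfig(tau_end=period + 0.01, sample_grid=grid.copy(),
                                      seed=eg.child_seed(8, i),
                                      division_mode="binomial")
            kept[i] = eg.simulate(system, init, cfg).states[0, 2]
        mean_kept = kept.mean() / params.D_tot
        if eta == 0.0:
            assert mean_kept == 1.0
        else:
            se = math.sqrt(0.25 / (params.D_tot * n))
            assert abs(mean_kept - 0.5) < 3 * se

    def test_ensemble_protein_decay_matches_first_order_rate(self, warm_kernel):
        """Halving at every ln2/eps_d matches e^{-eps_d t} sampled just after
        divisions, within 10%."""
        eps_d = 0.2
        params = zero_rate_params(eps_d=eps_d)
        system = eg.build_reaction_system(params, division_mode=True)
        init = eg.initial_state(params, "repressed")
        init[15] = 256
        T = 3 * math.log(2) / eps_d + 0.01
        grid = np.array([T])
        n = 400
        vals = np.empty(n)
        for i in range(n):
            cfg = eg.SimulationConfig(tau_end=T, sample_grid=grid.copy(),
                                      seed=eg.child_seed(9, i),
                                      division_mode="binomial")
            vals[i] = eg.simulate(system, init, cfg).states[0, 15]
        expected = 256 * math.exp(-eps_d * T)
        assert abs(vals.mean() - expected) / expected < 0.10

    def test_division_mode_conserves_nucleosomes(self, default_params,
                                                 warm_kernel):
        system = eg.build_reaction_system(default_params, division_mode=True)
        init = eg.initial_state(default_params, "active")
        traj = eg.simulate(
            system, init,
            eg.SimulationConfig(tau_end=50.0, seed=13,
                                division_mode="binomial"))
        for g in range(3):
            assert np.all(traj.gene_counts(g).sum(axis=1) == default_params.D_tot)
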