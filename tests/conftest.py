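import numpy as np
import pytest

import epigrn as eg


@pytest.fixture(scope="session")
def default_params():
    return eg.DimensionlessParams()


def zero_rate_params(**overrides) -> eg.DimensionlessParams:
    """Params with every rate constant zero (all propensities vanish)."""
    base = dict(alpha=0.0, alpha_bar=0.0, r=0.0, eta=0.0, mu_tilde=0.0,
                mu_tilde_prime=0.0, eps_d=0.0, eps_e=0.0, eps_prime=0.0,
                beta_tilde=0.0, b_tilde=0.0, kappa_WA=0.0, kappa_WR1=0.0,
                kappa_WR2=0.0, p_bar_O=0.0, p_bar_T=0.0, p_bar_J=0.0,
                gamma_hat=0.0)
    base.update(overrides)
    return eg.DimensionlessParams().with_updates(**base)


@pytest.fixture(scope="session")
def warm_kernel(default_params):
    """Trigger numba compilation once so per-test timings are meaningful."""
    system = eg.build_reaction_system(default_params)
    init = eg.initial_state(default_params, "active")
    eg.simulate(system, init, eg.SimulationConfig(tau_end=1.0, seed=0))
    dsys = eg.build_reaction_system(default_params, division_mode=True)
    eg.simulate(dsys, init, eg.SimulationConfig(tau_end=4.0, seed=0,
                                                division_mode="binomial"))
    return True


def random_full_state(rng, params) -> np.ndarray:
    """Random reachable full-network state (valid gene compositions)."""
    state = np.zeros(18, dtype=np.int64)
    for g in range(3):
        cut = np.sort(rng.integers(0, params.D_tot + 1, size=4))
        comp = np.diff(np.concatenate([[0], cut, [params.D_tot]]))
        state[5 * g:5 * g + 5] = comp
    state[15:18] = rng.integers(0, 400, size=3)
    return state
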