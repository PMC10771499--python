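"""Independent correctness references for the SSA engine and reaction table.

Two oracles, both driven by the same encoded channel table but evaluated
through numpy/scipy rather than the compiled kernel:

* an exact chemical-master-equation (CME) solution on the enumerated state
  space of a single gene with frozen modifier activities (tractable for
  D_tot <= 6), against which the empirical SSA state distribution is
  compared in total variation;
* a mean-field ODE reduction of the full network (counts replaced by
  continuous means), against which SSA ensemble means are compared in
  monostable parameter regimes.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .params import DimensionlessParams, ParameterError
from .reactions import ReactionSystem, build_single_gene_system

_MAX_DTOT = 6


def enumerate_compositions(D_tot: int, k: int = 5) -> list[tuple]:
    """All ways to place D_tot indistinguishable nucleosomes into k species."""
    states = []
    for cut in combinations_with_replacement(range(D_tot + 1), k - 1):
        prev = 0
        comp = []
        for c in cut:
            comp.append(c - prev)
            prev = c
        comp.append(D_tot - prev)
        states.append(tuple(comp))
    return states


@dataclass
class EnumeratedStateSpace:
    """Enumerated single-gene state space with its CME generator matrix."""

    system: ReactionSystem
    states: list
    index: dict
    generator: np.ndarray   # G[i, j] = rate i -> j; rows sum to 0

    @classmethod
    def build(cls, params: DimensionlessParams, g_T: float = 1.0,
              g_J: float = 1.0, hill_input: float = 0.0) -> "EnumeratedStateSpace":
        if params.D_tot > _MAX_DTOT:
            raise ParameterError(
                f"CME oracle refuses D_tot={params.D_tot} > {_MAX_DTOT} "
                f"({len(enumerate_compositions(params.D_tot))} states)")
        system = build_single_gene_system(params, g_T=g_T, g_J=g_J,
                                          hill_input=hill_input)
        states = enumerate_compositions(params.D_tot)
        index = {s: i for i, s in enumerate(states)}
        n = len(states)
        G = np.zeros((n, n))
        for i, s in enumerate(states):
            sv = np.array(s, dtype=float)
            a = system.propensities(sv)
            for j, ch in enumerate(system.channels):
                if a[j] <= 0:
                    continue
                target = tuple(np.array(s) + ch.update)
                G[i, index[target]] += a[j]
                G[i, i] -= a[j]
        return cls(system=system, states=states, index=index, generator=G)

    def state_vector(self, composition) -> np.ndarray:
        """Point-mass distribution on one composition."""
        p0 = np.zeros(len(self.states))
        p0[self.index[tuple(composition)]] = 1.0
        return p0


def cme_solve(space: EnumeratedStateSpace, p0, tau: float) -> np.ndarray:
    """Exact distribution p(tau) = exp(G^T tau) p0."""
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (len(space.states),) or abs(p0.sum() - 1.0) > 1e-9 or np.any(p0 < 0):
        raise ParameterError("p0 must be a distribution over the state space")
    if tau < 0:
        raise ParameterError(f"tau must be >= 0, got {tau}")
    p = expm(space.generator.T * tau) @ p0
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())


def empirical_distribution(space: EnumeratedStateSpace,
                           compositions) -> np.ndarray:
    """Empirical distribution of sampled compositions on the enumerated space."""
    p = np.zeros(len(space.states))
    for comp in compositions:
        p[space.index[tuple(int(c) for c in comp)]] += 1.0
    return p / p.sum()


def meanfield_ode(system: ReactionSystem, init, tau_grid,
                  schedule=None, rtol: float = 1e-8, atol: float = 1e-9):
    """Deterministic mean-field trajectories of the reaction system.

    The right-hand side is the propensity table with counts replaced by
    continuous means; piecewise-constant inputs are handled by integrating
    segment by segment.  Returns an array of shape (len(tau_grid), nstate).
    """
    tau_grid = np.asarray(tau_grid, dtype=float)
    y0 = np.asarray(init, dtype=float)
    if schedule is None:
        breaks = np.array([0.0, tau_grid[-1]])
        u = np.zeros((1, 3))
    else:
        breaks, u = schedule.compile(tau_grid[-1])
    out = np.empty((tau_grid.size, system.nstate))
    filled = 0
    y = y0.copy()
    for k in range(len(breaks) - 1):
        t0, t1 = breaks[k], breaks[k + 1]
        if t1 <= t0:
            continue
        uk = tuple(u[k])
        mask = (tau_grid >= t0 - 1e-12) & (tau_grid <= t1 + 1e-12)
        t_eval = np.unique(np.concatenate([tau_grid[mask], [t1]]))
        t_eval = t_eval[(t_eval >= t0) & (t_eval <= t1)]
        sol = solve_ivp(lambda t, s: system.rhs(s, uk), (t0, t1), y,
                        t_eval=t_eval, rtol=rtol, atol=atol, method="LSODA")
        if not sol.success:
            raise RuntimeError(f"mean-field ODE integration failed: {sol.message}")
        y = sol.y[:, -1].copy()
        for ti, tv in enumerate(sol.t):
            while filled < tau_grid.size and abs(tau_grid[filled] - tv) <= 1e-9:
                out[filled] = sol.y[:, ti]
                filled += 1
    if filled < tau_grid.size:   # grid points at tau=0 before any segment
        raise RuntimeError("mean-field ODE did not cover the requested grid")
    return out
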