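"""Exact stochastic simulation (Gillespie direct method) of the reaction system.

The kernel handles piecewise-constant overexpression inputs exactly: a
proposed jump that would land beyond the next schedule breakpoint (or
division time, or the horizon) is discarded and the clock advanced to that
barrier -- valid because propensities are constant between barriers and the
exponential clock is memoryless.

An optional division mode replaces first-order dilution with synchronous
binomial partitioning: every ``division_period`` (default ln2/eps_d) each
protein molecule and each histone mark is retained with probability 1/2,
while each CpG methylation mark is lost with probability eta/2 (the DNMT1
maintenance machinery re-methylates the (1 - eta) fraction of the diluted
half in expectation).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .params import GENES, ParameterError, SPECIES, TAU_PER_DAY
from .reactions import ReactionSystem
from .schedules import OverexpressionSchedule

#: global state index of the OCT4 active-nucleosome count n_O^A
OCT4_ACTIVE_IDX = 1

_MASK64 = (1 << 64) - 1


def child_seed(base_seed: int, index: int) -> int:
    """Stable per-trajectory seed derived from (base_seed, index).

    SplitMix64-style mixing, reduced below 2**31 for the kernel RNG.
    """
    x = ((base_seed & _MASK64) * 0x9E3779B97F4A7C15 + index + 1) & _MASK64
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _MASK64
    x ^= x >> 31
    return int(x % 2147483647)


class ConservationError(RuntimeError):
    """A sampled state violated the per-gene nucleosome conservation law."""


@dataclass
class SimulationConfig:
    """Horizon, sampling grid, seed and division-mode settings (tau units)."""

    tau_end: float = 201.6
    sample_grid: np.ndarray | None = None   # default: ~0.1-day spacing
    seed: int = 0
    division_mode: str = "off"              # "off" | "binomial"
    division_period: float | None = None    # default ln2/eps_d

    def __post_init__(self):
        if self.tau_end < 0:
            raise ParameterError(f"tau_end must be >= 0, got {self.tau_end}")
        if self.division_mode not in ("off", "binomial"):
            raise ParameterError(
                f"division_mode must be 'off' or 'binomial', got {self.division_mode!r}")
        if self.division_period is not None and self.division_period <= 0:
            raise ParameterError(
                f"division_period must be > 0, got {self.division_period}")
        if self.sample_grid is None:
            n = max(2, int(round(self.tau_end / 0.96)) + 1)
            self.sample_grid = np.linspace(0.0, self.tau_end, n)
        else:
            g = np.asarray(self.sample_grid, dtype=float)
            if g.size == 0 or np.any(np.diff(g) < 0) or g[0] < 0 or g[-1] > self.tau_end:
                raise ParameterError(
                    "sample_grid must be sorted within [0, tau_end]")
            self.sample_grid = g


@dataclass
class Trajectory:
    """One sampled realization of the network."""

    times: np.ndarray
    states: np.ndarray            # (len(times), nstate) integer counts
    event_count: int
    n_genes: int
    protein_offset: int
    #: exact first time the watched count reached the upper/lower threshold
    #: (NaN if never, None if no watch was requested)
    first_passage_up: float | None = None
    first_passage_down: float | None = None

    def gene_counts(self, gene_index: int) -> np.ndarray:
        return self.states[:, 5 * gene_index:5 * gene_index + 5]

    def active_counts(self, gene_index: int = 0) -> np.ndarray:
        """n_X^A over the sampling grid (default: OCT4)."""
        return self.states[:, 5 * gene_index + 1]

    def to_frame(self, replicate: int = 0) -> pd.DataFrame:
        """Tidy long-format trajectory table (one row per gene per sample)."""
        frames = []
        prot = {}
        if self.protein_offset >= 0:
            prot = {f"X_{g}": self.states[:, self.protein_offset + i]
                    for i, g in enumerate(GENES)}
        genes = GENES[:self.n_genes] if self.n_genes > 1 else ("X",)
        for gi, gene in enumerate(genes):
            block = self.gene_counts(gi)
            df = pd.DataFrame({
                "tau": self.times,
                "day": self.times / TAU_PER_DAY,
                "gene": gene,
                **{name: block[:, si] for si, name in enumerate(SPECIES)},
                **prot,
                "replicate": replicate,
            })
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


@njit(cache=True)
def _partition(state, eta, n_genes, protein_offset):  # pragma: no cover - jitted
    for g in range(n_genes):
        b = 5 * g
        nD, nA = state[b], state[b + 1]
        nR1, nR2, nR12 = state[b + 2], state[b + 3], state[b + 4]
        keep_a = np.random.binomial(nA, 0.5)
        keep_r2 = np.random.binomial(nR2, 0.5)
        lose_r1 = np.random.binomial(nR1, eta * 0.5)
        keep_k = np.random.binomial(nR12, 0.5)          # H3K9me3 survives
        lose_c_keep_k = np.random.binomial(keep_k, eta * 0.5)
        lose_c_lose_k = np.random.binomial(nR12 - keep_k, eta * 0.5)
        state[b + 1] = keep_a
        state[b + 2] = nR1 - lose_r1 + (nR12 - keep_k) - lose_c_lose_k
        state[b + 3] = keep_r2 + lose_c_keep_k
        state[b + 4] = keep_k - lose_c_keep_k
        state[b] = (nD + (nA - keep_a) + (nR2 - keep_r2)
                    + lose_r1 + lose_c_lose_k)
    if protein_offset >= 0:
        for i in range(protein_offset, protein_offset + 3):
            state[i] = np.random.binomial(state[i], 0.5)


@njit(cache=True)
def _ssa_run(state, rate, subst, cat_indptr, cat_idx, mod, update,
             K_A, gt_scale, gj_scale, xo_idx, xt_idx, xj_idx,
             sched_breaks, sched_u, tau_end, grid, samples,
             watch, thr_on, thr_off,
             div_on, div_period, eta, n_genes, protein_offset,
             seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    nc = rate.shape[0]
    nstate = state.shape[0]
    a = np.empty(nc)
    t = 0.0
    gi = 0
    si = 0
    events = 0
    fp_up = -1.0
    fp_down = -1.0
    if watch >= 0:
        if state[watch] >= thr_on:
            fp_up = 0.0
        if state[watch] <= thr_off:
            fp_down = 0.0
    next_div = div_period if div_on else 1.0e300
    while True:
        u0 = sched_u[si, 0]
        u1 = sched_u[si, 1]
        u2 = sched_u[si, 2]
        total = 0.0
        for j in range(nc):
            v = rate[j]
            s = subst[j]
            if s >= 0:
                v *= state[s]
            p0 = cat_indptr[j]
            p1 = cat_indptr[j + 1]
            if p1 > p0:
                csum = 0.0
                for k in range(p0, p1):
                    csum += state[cat_idx[k]]
                v *= csum
            m = mod[j]
            if m == 1:
                x = state[xo_idx]
                v *= x / (x + K_A)
            elif m == 2:
                v *= state[xt_idx] * gt_scale
            elif m == 3:
                v *= state[xj_idx] * gj_scale
            elif m == 4:
                v *= u0
            elif m == 5:
                v *= u1
            elif m == 6:
                v *= u2
            a[j] = v
            total += v
        if total > 0.0:
            t_next = t + np.random.exponential(1.0 / total)
        else:
            t_next = 1.0e300
        barrier = tau_end
        nb = sched_breaks[si + 1]
        if nb < barrier:
            barrier = nb
        if next_div < barrier:
            barrier = next_div
        if t_next >= barrier:
            while gi < grid.shape[0] and grid[gi] <= barrier:
                for q in range(nstate):
                    samples[gi, q] = state[q]
                gi += 1
            t = barrier
            if barrier >= tau_end:
                break
            if div_on and barrier == next_div:
                _partition(state, eta, n_genes, protein_offset)
                next_div += div_period
                if watch >= 0:
                    if fp_up < 0.0 and state[watch] >= thr_on:
                        fp_up = t
                    if fp_down < 0.0 and state[watch] <= thr_off:
                        fp_down = t
            if barrier == nb and si + 1 < sched_u.shape[0]:
                si += 1
            continue
        while gi < grid.shape[0] and grid[gi] < t_next:
            for q in range(nstate):
                samples[gi, q] = state[q]
            gi += 1
        t = t_next
        rsel = np.random.random() * total
        acc = 0.0
        jsel = nc - 1
        for j in range(nc):
            acc += a[j]
            if rsel < acc:
                jsel = j
                break
        for q in range(nstate):
            state[q] += update[jsel, q]
        events += 1
        if watch >= 0:
            if fp_up < 0.0 and state[watch] >= thr_on:
                fp_up = t
            if fp_down < 0.0 and state[watch] <= thr_off:
                fp_down = t
    return fp_up, fp_down, events


def _check_init(system: ReactionSystem, init) -> np.ndarray:
    state = np.asarray(init, dtype=np.int64).copy()
    if state.shape != (system.nstate,):
        raise ParameterError(
            f"init must have shape ({system.nstate},), got {state.shape}")
    if np.any(state < 0):
        raise ParameterError("init counts must be >= 0")
    D_tot = system.params.D_tot
    for g in range(system.n_genes):
        s = int(state[5 * g:5 * g + 5].sum())
        if s != D_tot:
            raise ParameterError(
                f"gene {g}: nucleosome counts sum to {s}, expected D_tot={D_tot}")
    return state


def _check_conservation(system: ReactionSystem, states: np.ndarray):
    D_tot = system.params.D_tot
    for g in range(system.n_genes):
        sums = states[:, 5 * g:5 * g + 5].sum(axis=1)
        if not np.all(sums == D_tot):
            raise ConservationError(
                f"gene {g}: nucleosome sum deviates from D_tot={D_tot}")


def simulate(system: ReactionSystem, init, config: SimulationConfig,
             schedule: OverexpressionSchedule | None = None,
             watch: int | None = None,
             threshold_on: float = np.inf,
             threshold_off: float = -np.inf) -> Trajectory:
    """Exact SSA sample of the continuous-time Markov chain.

    ``watch`` (a state index, e.g. :data:`OCT4_ACTIVE_IDX`) enables exact
    first-passage recording against ``threshold_on`` (upward) and
    ``threshold_off`` (downward) at event times.  Identical
    (system, init, config, schedule) with the same seed give a bit-identical
    trajectory.
    """
    state = _check_init(system, init)
    if schedule is None:
        schedule = OverexpressionSchedule()
    breaks, u = schedule.compile(config.tau_end)
    grid = config.sample_grid
    samples = np.zeros((grid.shape[0], system.nstate), dtype=np.int64)
    div_on = config.division_mode == "binomial"
    if div_on:
        labels = {ch.label for ch in system.channels}
        if "A3" in labels or "P2" in labels:
            raise ParameterError(
                "division mode requires a system built with division_mode=True "
                "(dilution channels removed)")
        period = config.division_period
        if period is None:
            if system.params.eps_d <= 0:
                raise ParameterError(
                    "division_period must be given when eps_d = 0")
            period = math.log(2.0) / system.params.eps_d
    else:
        period = 1.0e300
    w = -1 if watch is None else int(watch)
    fp_up, fp_down, events = _ssa_run(
        state, system.rate, system.subst, system.cat_indptr, system.cat_idx,
        system.mod, system.update,
        system.K_A, system.gt_scale, system.gj_scale,
        system.xo_idx, system.xt_idx, system.xj_idx,
        breaks, u, float(config.tau_end), grid, samples,
        w, float(threshold_on), float(threshold_off),
        div_on, float(period), float(system.params.eta),
        system.n_genes, system.protein_offset,
        int(config.seed))
    _check_conservation(system, samples)
    return Trajectory(
        times=grid.copy(), states=samples, event_count=int(events),
        n_genes=system.n_genes, protein_offset=system.protein_offset,
        first_passage_up=(None if w < 0 else (fp_up if fp_up >= 0 else np.nan)),
        first_passage_down=(None if w < 0 else (fp_down if fp_down >= 0 else np.nan)),
    )


def simulate_with_division(system: ReactionSystem, init,
                           config: SimulationConfig,
                           schedule: OverexpressionSchedule | None = None,
                           **kwargs) -> Trajectory:
    """SSA with synchronous binomial partitioning at division times.

    ``system`` must be built with ``division_mode=True``; ``config`` is
    promoted to division mode if necessary.
    """
    if config.division_mode != "binomial":
        config = SimulationConfig(
            tau_end=config.tau_end, sample_grid=config.sample_grid,
            seed=config.seed, division_mode="binomial",
            division_period=config.division_period)
    return simulate(system, init, config, schedule, **kwargs)
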