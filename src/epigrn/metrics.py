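"""Ensemble summary statistics: efficiency %O^A, latency distribution f_L,
and latency variability.

Latency is the first-passage time of the OCT4 active-nucleosome count
n_O^A to a threshold (upward for reprogramming, downward for silencing),
censored at the horizon.  Efficiency %O^A(tau) is the percentage of
trajectories whose latency is <= tau.  The latency histogram f_L bins
realized latencies by day and normalizes by the ensemble size N, so the
histogram mass plus the censored fraction equals 1.  Variability statistics
(SD, IQR, CV) are computed over uncensored latencies only, with the censored
count reported alongside.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .params import TAU_PER_DAY
from .ssa import Trajectory


def first_passage(trajectory: Trajectory, threshold: float,
                  direction: str = "up", gene_index: int = 0) -> float:
    """Earliest sampled tau at which n^A crosses ``threshold``.

    ``direction="up"`` looks for n^A >= threshold, ``"down"`` for
    n^A <= threshold.  Returns NaN if the trajectory never crosses
    (censored).  Resolution is the trajectory's sampling grid; the
    experiment drivers use exact event-time crossings recorded by the SSA
    kernel instead.
    """
    if trajectory.times.size == 0:
        raise ValueError("empty trajectory")
    series = trajectory.active_counts(gene_index)
    if direction == "up":
        hits = np.nonzero(series >= threshold)[0]
    elif direction == "down":
        hits = np.nonzero(series <= threshold)[0]
    else:
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    if hits.size == 0:
        return float("nan")
    return float(trajectory.times[hits[0]])


def efficiency_curve(latencies, tau_grid) -> np.ndarray:
    """%O^A over time: 100 x fraction of trajectories with latency <= tau.

    ``latencies`` holds one first-passage time per trajectory, NaN for
    censored trajectories; stepwise non-decreasing in tau.
    """
    lat = np.asarray(latencies, dtype=float)
    if lat.size == 0:
        raise ValueError("need at least one trajectory")
    grid = np.atleast_1d(np.asarray(tau_grid, dtype=float))
    ok = lat[~np.isnan(lat)]
    return 100.0 * (ok[None, :] <= grid[:, None]).mean(axis=1) * ok.size / lat.size \
        if ok.size else np.zeros_like(grid)


def latency_histogram(latencies, bin_days: float = 1.0):
    """Day-binned latency frequencies f_L normalized by ensemble size N.

    Returns ``(bin_edges_days, freq, censored_mass)``; ``freq`` sums to the
    uncensored fraction so that total mass (freq + censored) is 1.  With all
    trajectories censored, an empty histogram is returned with a warning.
    """
    lat = np.asarray(latencies, dtype=float)
    if lat.size == 0:
        raise ValueError("need at least one trajectory")
    if bin_days <= 0:
        raise ValueError("bin_days must be > 0")
    days = lat[~np.isnan(lat)] / TAU_PER_DAY
    censored_mass = 1.0 - days.size / lat.size
    if days.size == 0:
        warnings.warn("all trajectories censored: empty latency histogram")
        return np.array([0.0, bin_days]), np.zeros(1), censored_mass
    top = np.ceil(max(days.max(), bin_days) / bin_days) * bin_days
    edges = np.arange(0.0, top + bin_days, bin_days)
    counts, edges = np.histogram(days, bins=edges)
    return edges, counts / lat.size, censored_mass


def latency_variability(latencies) -> dict:
    """SD, IQR and CV (in days) of uncensored latencies, plus censored count."""
    lat = np.asarray(latencies, dtype=float)
    days = lat[~np.isnan(lat)] / TAU_PER_DAY
    out = {"n_uncensored": int(days.size), "censored_n": int(lat.size - days.size)}
    if days.size == 0:
        out.update(mean_days=np.nan, sd_days=np.nan, iqr_days=np.nan, cv=np.nan)
        return out
    q1, q3 = np.percentile(days, [25, 75])
    mean = float(days.mean())
    sd = float(days.std(ddof=1)) if days.size > 1 else 0.0
    out.update(mean_days=mean, sd_days=sd, iqr_days=float(q3 - q1),
               cv=(sd / mean if mean > 0 else np.nan))
    return out


@dataclass
class EnsembleResult:
    """Latencies and summary statistics of one simulated ensemble."""

    latencies: np.ndarray          # tau units, NaN = censored
    tau_end: float
    name: str = ""
    direction: str = "up"
    trajectories: list = field(default_factory=list, repr=False)

    @property
    def N(self) -> int:
        return int(self.latencies.size)

    @property
    def censored_n(self) -> int:
        return int(np.isnan(self.latencies).sum())

    @property
    def efficiency_final(self) -> float:
        """%O^A at the horizon: exactly 100 x (1 - censored/N)."""
        return 100.0 * (1.0 - self.censored_n / self.N)

    def efficiency_curve(self, tau_grid=None) -> tuple[np.ndarray, np.ndarray]:
        if tau_grid is None:
            tau_grid = np.linspace(0.0, self.tau_end, 212)
        grid = np.asarray(tau_grid, dtype=float)
        return grid, efficiency_curve(self.latencies, grid)

    def latency_histogram(self, bin_days: float = 1.0):
        return latency_histogram(self.latencies, bin_days)

    def variability(self) -> dict:
        return latency_variability(self.latencies)

    def summary(self) -> dict:
        v = self.variability()
        return {
            "name": self.name,
            "N": self.N,
            "efficiency_final": self.efficiency_final,
            "latency_mean_days": v["mean_days"],
            "latency_sd_days": v["sd_days"],
            "latency_iqr_days": v["iqr_days"],
            "censored_n": v["censored_n"],
        }
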