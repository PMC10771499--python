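"""Piecewise-constant overexpression inputs u_X(tau) for X in {O, T, J}."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import GENES, ParameterError


@dataclass
class OverexpressionSchedule:
    """Per-gene lists of (tau_start, tau_end, u) segments.

    Segments must be non-overlapping with u >= 0; the input is 0 outside all
    segments.  A constant input is a single segment covering the horizon.
    """

    segments: dict = field(default_factory=lambda: {g: [] for g in GENES})

    def __post_init__(self):
        for g in GENES:
            self.segments.setdefault(g, [])
        unknown = set(self.segments) - set(GENES)
        if unknown:
            raise ParameterError(f"unknown gene(s) in schedule: {sorted(unknown)}")
        for g in list(self.segments):
            segs = sorted((float(t0), float(t1), float(u))
                          for (t0, t1, u) in self.segments[g])
            self.segments[g] = segs
            prev_end = -np.inf
            for (t0, t1, u) in segs:
                if u < 0:
                    raise ParameterError(f"u_{g} must be >= 0, got {u}")
                if t1 < t0 or t0 < 0:
                    raise ParameterError(
                        f"invalid segment [{t0}, {t1}) for gene {g}")
                if t0 < prev_end:
                    raise ParameterError(f"overlapping segments for gene {g}")
                prev_end = t1

    @classmethod
    def constant(cls, u_O: float = 0.0, u_T: float = 0.0, u_J: float = 0.0,
                 tau_end: float = np.inf) -> "OverexpressionSchedule":
        segs = {}
        for g, u in zip(GENES, (u_O, u_T, u_J)):
            segs[g] = [(0.0, float(tau_end), float(u))] if u > 0 else []
        return cls(segs)

    def is_zero(self) -> bool:
        return all(all(u == 0 for (_, _, u) in segs)
                   for segs in self.segments.values())

    def max_level(self, gene: str) -> float:
        segs = self.segments[gene]
        return max((u for (_, _, u) in segs), default=0.0)

    def value(self, gene: str, tau: float) -> float:
        for (t0, t1, u) in self.segments[gene]:
            if t0 <= tau < t1:
                return u
        return 0.0

    def compile(self, tau_end: float):
        """Merge all genes onto one breakpoint grid.

        Returns ``(breaks, u)`` with ``breaks`` of shape (K+1,) spanning
        [0, tau_end] and ``u`` of shape (K, 3): u[k] applies on
        [breaks[k], breaks[k+1]).
        """
        pts = {0.0, float(tau_end)}
        for segs in self.segments.values():
            for (t0, t1, _) in segs:
                if t0 > tau_end:
                    raise ParameterError(
                        f"schedule breakpoint {t0} beyond horizon {tau_end}")
                pts.add(float(t0))
                pts.add(float(min(t1, tau_end)))
        breaks = np.array(sorted(pts), dtype=np.float64)
        u = np.zeros((len(breaks) - 1, 3), dtype=np.float64)
        for k in range(len(breaks) - 1):
            mid = 0.5 * (breaks[k] + breaks[k + 1])
            for gi, g in enumerate(GENES):
                u[k, gi] = self.value(g, mid)
        return breaks, u

    def to_config(self) -> dict:
        return {f"u_{g}": [[t0, t1, u] for (t0, t1, u) in self.segments[g]]
                for g in GENES if self.segments[g]}


def sequential_schedule(u_level: float, switch_tau: float, tau_end: float,
                        u_O: float = 0.0) -> OverexpressionSchedule:
    """TET1-first / JMJD2-later transient overexpression.

    TET1 receives ``u_level`` on [0, switch_tau), JMJD2 receives it on
    [switch_tau, tau_end); OCT4 is constant at ``u_O``.  The boundaries
    switch_tau = 0 and switch_tau = tau_end give the pure-JMJD2 and
    pure-TET1 transient schedules.
    """
    if not (0.0 <= switch_tau <= tau_end):
        raise ParameterError(
            f"switch_tau must lie in [0, tau_end], got {switch_tau}")
    if u_level < 0 or u_O < 0:
        raise ParameterError("overexpression levels must be >= 0")
    segs = {"O": [(0.0, float(tau_end), float(u_O))] if u_O > 0 else [],
            "T": [(0.0, float(switch_tau), float(u_level))] if switch_tau > 0 else [],
            "J": [(float(switch_tau), float(tau_end), float(u_level))]
                 if switch_tau < tau_end else []}
    return OverexpressionSchedule(segs)
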