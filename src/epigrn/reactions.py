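"""Reaction table of the epigenetic OCT4 GRN.

Every reaction channel is encoded in one generic form evaluated identically
by the Python path (channel objects, chemical-master-equation generator,
mean-field ODE) and the compiled SSA kernel:

    propensity = rate * state[subst] * sum(state[cat]) * modifier

where the substrate and catalyst-group factors are optional and ``modifier``
is one of: 1, the Hill occupancy of OCT4, the TET1 / JMJD2 activity scalings
g_T / g_J, or the current overexpression input u_X(tau).  ``rate`` already
carries any 1/D_tot factor of bimolecular (read-write) channels.

Channel labels follow a fixed naming scheme per gene:

* ``A1..A5``   -- activating-mark (H3K4me3/ac) writing, auto-catalysis,
  dilution, basal and recruited erasure;
* ``K1..K6``   -- H3K9me3 de-novo writing, auto- and cross-catalysis,
  dilution, basal and recruited erasure by JMJD2 (a/b variants act on the
  nucleosome without/with the other repressive mark);
* ``M1..M5``   -- CpG-methylation counterparts, erased by TET1, with
  replication dilution attenuated by DNMT1 maintenance (eta);
* ``P1/P2/P3`` -- protein production from active nucleosomes, first-order
  turnover, and exogenous overexpression.

H3K9me3 and CpGme channels fire at identical rates whether or not the other
repressive mark is present on the same nucleosome.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .params import (DimensionlessParams, GENES, N_SPECIES, ParameterError,
                     hill_activation)

# modifier codes shared with the numba kernel
MOD_NONE, MOD_HILL, MOD_GT, MOD_GJ, MOD_UO, MOD_UT, MOD_UJ = range(7)
_MOD_U = {"O": MOD_UO, "T": MOD_UT, "J": MOD_UJ}

# local species indices within one gene block
_D, _A, _R1, _R2, _R12 = range(5)

#: channel labels removed in binomial-partitioning (division) mode, where
#: first-order dilution is replaced by partitioning at division events
DILUTION_LABELS = ("A3", "K4a", "K4b", "M3a", "M3b", "P2")


def _chromatin_rows(p: DimensionlessParams):
    """Per-gene chromatin channel table: (label, rate, subst, cats, mod, src, dst)."""
    iD = 1.0 / p.D_tot
    ap = p.alpha_prime
    mtp = p.effective_mu_tilde_prime()
    rep = [_R1, _R2, _R12]
    k9 = [_R2, _R12]   # nucleosomes carrying H3K9me3
    cpg = [_R1, _R12]  # nucleosomes carrying CpGme
    return [
        # activating mark
        ("A1", p.kappa_WA, _D, [], MOD_HILL, _D, _A),
        ("A2", iD, _D, [_A], MOD_NONE, _D, _A),
        ("A3", p.eps_d, _A, [], MOD_NONE, _A, _D),
        ("A4", p.eps_e, _A, [], MOD_NONE, _A, _D),
        ("A5", p.eps_prime * iD, _A, rep, MOD_NONE, _A, _D),
        # H3K9me3
        ("K1a", p.kappa_WR2, _D, [], MOD_NONE, _D, _R2),
        ("K1b", p.kappa_WR2, _R1, [], MOD_NONE, _R1, _R12),
        ("K2a", p.alpha * iD, _D, k9, MOD_NONE, _D, _R2),
        ("K2b", p.alpha * iD, _R1, k9, MOD_NONE, _R1, _R12),
        ("K3a", p.alpha_bar * iD, _D, cpg, MOD_NONE, _D, _R2),
        ("K3b", p.alpha_bar * iD, _R1, cpg, MOD_NONE, _R1, _R12),
        ("K4a", p.eps_d, _R2, [], MOD_NONE, _R2, _D),
        ("K4b", p.eps_d, _R12, [], MOD_NONE, _R12, _R1),
        ("K5a", p.b_tilde * p.mu_tilde * p.eps_e, _R2, [], MOD_GJ, _R2, _D),
        ("K5b", p.b_tilde * p.mu_tilde * p.eps_e, _R12, [], MOD_GJ, _R12, _R1),
        ("K6a", p.mu_tilde * p.eps_prime * iD, _R2, [_A], MOD_GJ, _R2, _D),
        ("K6b", p.mu_tilde * p.eps_prime * iD, _R12, [_A], MOD_GJ, _R12, _R1),
        # CpG methylation
        ("M1a", p.kappa_WR1, _D, [], MOD_NONE, _D, _R1),
        ("M1b", p.kappa_WR1, _R2, [], MOD_NONE, _R2, _R12),
        ("M2a", ap * iD, _D, k9, MOD_NONE, _D, _R1),
        ("M2b", ap * iD, _R2, k9, MOD_NONE, _R2, _R12),
        ("M3a", p.eta * p.eps_d, _R1, [], MOD_NONE, _R1, _D),
        ("M3b", p.eta * p.eps_d, _R12, [], MOD_NONE, _R12, _R2),
        ("M4a", p.beta_tilde * mtp * p.eps_e, _R1, [], MOD_GT, _R1, _D),
        ("M4b", p.beta_tilde * mtp * p.eps_e, _R12, [], MOD_GT, _R12, _R2),
        ("M5a", mtp * p.eps_prime * iD, _R1, [_A], MOD_GT, _R1, _D),
        ("M5b", mtp * p.eps_prime * iD, _R12, [_A], MOD_GT, _R12, _R2),
    ]


@dataclass
class ReactionChannel:
    """One stochastic reaction channel in normalized-time units."""

    label: str
    gene: str
    rate: float
    subst: int              # global state index of the substrate, -1 for none
    cat: tuple              # global state indices whose sum multiplies the rate
    mod: int                # MOD_* code
    update: np.ndarray      # integer state-change vector
    system: "ReactionSystem" = field(repr=False, default=None)

    def propensity(self, state, u=(0.0, 0.0, 0.0)) -> float:
        """Evaluate this channel's propensity at a full system state."""
        state = np.asarray(state, dtype=float)
        a = self.rate
        if self.subst >= 0:
            a *= state[self.subst]
        if self.cat:
            a *= float(sum(state[i] for i in self.cat))
        a *= self.system._modifier_factor(self.mod, state, u)
        return a


class ReactionSystem:
    """A complete channel set plus its compiled array encoding.

    ``nstate`` is 5 * n_genes (+3 protein counts for the full network).  The
    compiled arrays (``rate``, ``subst``, ``cat_indptr``/``cat_idx``, ``mod``,
    ``update``) are consumed by the SSA kernel; :meth:`propensities` and
    :meth:`rhs` evaluate the same encoding in numpy for tests, the
    master-equation oracle and the mean-field reduction.
    """

    def __init__(self, channels: Sequence[ReactionChannel], nstate: int,
                 params: DimensionlessParams, protein_offset: int = -1,
                 n_genes: int = 3):
        self.channels = list(channels)
        self.nstate = nstate
        self.params = params
        self.protein_offset = protein_offset   # -1 if proteins not modelled
        self.n_genes = n_genes
        for ch in self.channels:
            ch.system = self
        nc = len(self.channels)
        self.rate = np.array([ch.rate for ch in self.channels], dtype=np.float64)
        self.subst = np.array([ch.subst for ch in self.channels], dtype=np.int64)
        self.mod = np.array([ch.mod for ch in self.channels], dtype=np.int64)
        self.update = np.array([ch.update for ch in self.channels], dtype=np.int64)
        indptr = [0]
        idx: list[int] = []
        for ch in self.channels:
            idx.extend(ch.cat)
            indptr.append(len(idx))
        self.cat_indptr = np.array(indptr, dtype=np.int64)
        self.cat_idx = np.array(idx, dtype=np.int64)
        p = params
        self.K_A = float(p.K_A)
        self.gt_scale = 1.0 / (p.p_bar_T * p.D_tot) if p.p_bar_T > 0 else 0.0
        self.gj_scale = 1.0 / (p.p_bar_J * p.D_tot) if p.p_bar_J > 0 else 0.0
        if protein_offset >= 0:
            self.xo_idx, self.xt_idx, self.xj_idx = (protein_offset,
                                                     protein_offset + 1,
                                                     protein_offset + 2)
        else:
            self.xo_idx = self.xt_idx = self.xj_idx = -1

    # --- shared evaluation -------------------------------------------------
    def _modifier_factor(self, mod: int, state, u) -> float:
        if mod == MOD_NONE:
            return 1.0
        if mod == MOD_HILL:
            x = float(state[self.xo_idx])
            return x / (x + self.K_A)
        if mod == MOD_GT:
            return float(state[self.xt_idx]) * self.gt_scale
        if mod == MOD_GJ:
            return float(state[self.xj_idx]) * self.gj_scale
        return float(u[mod - MOD_UO])

    def propensities(self, state, u=(0.0, 0.0, 0.0)) -> np.ndarray:
        """All channel propensities at ``state`` (works for float states too)."""
        state = np.asarray(state, dtype=float)
        if state.shape != (self.nstate,):
            raise ValueError(f"state must have shape ({self.nstate},)")
        a = self.rate.copy()
        has_sub = self.subst >= 0
        a[has_sub] *= state[self.subst[has_sub]]
        for j, ch in enumerate(self.channels):
            if ch.cat:
                a[j] *= float(sum(state[i] for i in ch.cat))
            if ch.mod != MOD_NONE:
                a[j] *= self._modifier_factor(ch.mod, state, u)
        return a

    def rhs(self, state, u=(0.0, 0.0, 0.0)) -> np.ndarray:
        """Mean-field drift: update vectors weighted by propensities."""
        return self.update.T @ self.propensities(state, u)

    def labels(self) -> list[str]:
        return [f"{ch.gene}:{ch.label}" for ch in self.channels]


def _make_channel(label, gene, rate, subst, cats, mod, update) -> ReactionChannel:
    if rate < 0:
        raise ParameterError(f"negative rate for channel {gene}:{label}")
    return ReactionChannel(label=label, gene=gene, rate=float(rate),
                           subst=subst, cat=tuple(cats), mod=mod,
                           update=np.asarray(update, dtype=np.int64))


def build_reaction_system(params: DimensionlessParams,
                          division_mode: bool = False) -> ReactionSystem:
    """Construct the full 3-gene, 90-channel network (30 channels per gene).

    With ``division_mode=True`` the first-order dilution channels
    (``A3``, ``K4a/b``, ``M3a/b``, ``P2``) are omitted; their effect is
    applied by binomial partitioning at division events in the SSA engine.
    """
    params.validate()
    nstate = 5 * len(GENES) + 3
    poff = 5 * len(GENES)
    channels: list[ReactionChannel] = []
    for g, gene in enumerate(GENES):
        base = 5 * g
        for (label, rate, subst, cats, mod, src, dst) in _chromatin_rows(params):
            if division_mode and label in DILUTION_LABELS:
                continue
            upd = np.zeros(nstate, dtype=np.int64)
            upd[base + src] -= 1
            upd[base + dst] += 1
            channels.append(_make_channel(
                label, gene, rate, base + subst,
                [base + c for c in cats], mod, upd))
        xi = poff + g
        prod = np.zeros(nstate, dtype=np.int64); prod[xi] = 1
        dec = np.zeros(nstate, dtype=np.int64); dec[xi] = -1
        channels.append(_make_channel(
            "P1", gene, params.p_bar(gene) * params.gamma_hat,
            base + _A, [], MOD_NONE, prod))
        if not division_mode:
            channels.append(_make_channel(
                "P2", gene, params.gamma_hat, xi, [], MOD_NONE, dec))
        channels.append(_make_channel(
            "P3", gene, params.gamma_hat, -1, [], _MOD_U[gene], prod.copy()))
    return ReactionSystem(channels, nstate, params, protein_offset=poff,
                          n_genes=len(GENES))


def build_single_gene_system(params: DimensionlessParams,
                             g_T: float = 1.0, g_J: float = 1.0,
                             hill_input: float = 0.0,
                             division_mode: bool = False) -> ReactionSystem:
    """Single-gene chromatin circuit with frozen modifier activities.

    TET1/JMJD2 activities are frozen at ``g_T``/``g_J`` and the OCT4 input at
    Hill occupancy ``hill_input`` (a value in [0, 1), e.g.
    ``hill_activation(X_O, K_A)``), folding all modifiers into constant
    rates.  With g_T = g_J = 1 this is exactly the standalone single-gene
    chromatin-modification circuit; it is the state space used by the
    master-equation oracle.
    """
    params.validate()
    if not (0.0 <= hill_input <= 1.0):
        raise ParameterError(f"hill_input must lie in [0, 1], got {hill_input}")
    if g_T < 0 or g_J < 0:
        raise ParameterError("frozen modifier activities must be >= 0")
    nstate = 5
    channels = []
    for (label, rate, subst, cats, mod, src, dst) in _chromatin_rows(params):
        if division_mode and label in DILUTION_LABELS:
            continue
        if mod == MOD_HILL:
            rate, mod = rate * hill_input, MOD_NONE
        elif mod == MOD_GT:
            rate, mod = rate * g_T, MOD_NONE
        elif mod == MOD_GJ:
            rate, mod = rate * g_J, MOD_NONE
        upd = np.zeros(nstate, dtype=np.int64)
        upd[src] -= 1
        upd[dst] += 1
        channels.append(_make_channel(label, "X", rate, subst, cats, mod, upd))
    return ReactionSystem(channels, nstate, params, protein_offset=-1, n_genes=1)
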