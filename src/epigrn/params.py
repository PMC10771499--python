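"""Dimensionless parameters of the epigenetic OCT4 gene regulatory network.

The model couples three genes -- the pluripotency transcription factor OCT4
and the chromatin-modifier genes TET1 (DNA demethylase) and JMJD2 (H3K9me3
demethylase).  Each gene carries an internal chromatin-modification circuit
over ``D_tot`` nucleosomes, which can be unmodified (D), carry the activating
mark H3K4me3/ac (D^A), DNA methylation (D^R1), H3K9me3 (D^R2), or both
repressive marks (D^R12).  Time is normalized: tau = t * k_M^A * D_tot, and
all rate constants below are expressed relative to the activating-mark
auto-catalysis rate k_M^A.  21 days of real time correspond to tau = 201.6,
i.e. 9.6 tau units per day.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

GENES = ("O", "T", "J")
SPECIES = ("n_D", "n_A", "n_R1", "n_R2", "n_R12")
N_SPECIES = len(SPECIES)
#: normalized-time units per day: 21 days == tau 201.6
TAU_PER_DAY = 9.6


class ParameterError(ValueError):
    """Raised when a model parameter is outside its admissible range."""


def hill_activation(X_O: float, K_A: float) -> float:
    """Transcription-factor occupancy factor (X_O/K_A) / (1 + X_O/K_A).

    Hill function with cooperativity 1 modelling recruitment of
    activating-mark writers by the TF at abundance ``X_O`` with TF-DNA
    dissociation constant ``K_A`` (both in molecule counts).
    """
    if K_A <= 0:
        raise ParameterError(f"K_A must be > 0, got {K_A}")
    if X_O < 0:
        raise ParameterError(f"X_O must be >= 0, got {X_O}")
    x = X_O / K_A
    return x / (1.0 + x)


def mbd_modulated_mu(B: float, K_B: float, F2: float, F5: float) -> float:
    """DNA-methylation erasure asymmetry mu'~ as shaped by MBD proteins.

    MBD proteins (abundance ``B``, dissociation constant ``K_B``) shield
    methylated CpG from TET1, so mu'~ = F5 / (F2 * B/K_B + 1): knocking MBDs
    down (B = 0) or preventing binding (K_B -> inf) raises mu'~ to F5.
    """
    if K_B <= 0:
        raise ParameterError(f"K_B must be > 0, got {K_B}")
    if B < 0 or F2 < 0 or F5 < 0:
        raise ParameterError("B, F2 and F5 must all be >= 0")
    return F5 / (F2 * B / K_B + 1.0)


def maintenance_inefficiency(delta_prime: float, delta: float) -> float:
    """DNMT1 maintenance inefficiency eta = delta'/delta in [0, 1].

    eta = 0 when maintenance methylation is perfect (no effective CpGme
    dilution), eta = 1 when DNMT1 is absent (CpGme diluted like any mark).
    """
    if delta <= 0:
        raise ParameterError(f"delta must be > 0, got {delta}")
    if delta_prime < 0:
        raise ParameterError(f"delta_prime must be >= 0, got {delta_prime}")
    eta = delta_prime / delta
    if eta > 1.0:
        raise ParameterError(
            f"eta = delta_prime/delta = {eta} exceeds 1 (delta_prime > delta)")
    return eta


@dataclass
class DimensionlessParams:
    """Normalized rate parameters of the three-gene network.

    Defaults reproduce the differentiation baseline (eps_d = 0.3, eps_e = 0.3,
    eps' = 1, eta = 0.1, mu~ = 1, p_bar = 3.2).  The de-novo writing scales
    (kappa_WA, kappa_WR1, kappa_WR2), the TF dissociation constant K_A, the
    protein turnover gamma_hat and the O(1) coefficients beta_tilde / b_tilde
    are not printed in the main text; the values below are this package's
    calibrated defaults (see docs/methods.md).
    """

    D_tot: int = 50
    #: repressive-histone (H3K9me3) auto-catalysis, alpha = k_M / k_M^A
    alpha: float = 0.2
    #: CpGme -> H3K9me3 cross-catalysis, alpha_bar = k_bar_M / k_M^A
    alpha_bar: float = 0.01
    #: r = alpha'/alpha, H3K9me3 -> CpGme cross-catalysis relative to auto-catalysis
    r: float = 1.0
    #: DNMT1 maintenance inefficiency, eta = delta'/delta in [0, 1]
    eta: float = 0.1
    #: H3K9me3 vs activating-mark erasure asymmetry
    mu_tilde: float = 1.0
    #: CpGme vs activating-mark erasure asymmetry (overridden by MBD block if B set)
    mu_tilde_prime: float = 1.0
    #: replication-dilution rate, eps_d = delta / (k_M^A D_tot)
    eps_d: float = 0.3
    #: basal-erasure scale, eps_e = k_bar_E^A / (k_M^A D_tot)
    eps_e: float = 0.3
    #: recruited-erasure scale, eps' = k_E^A / k_M^A
    eps_prime: float = 1.0
    #: O(1) coefficient linking basal to recruited CpGme erasure
    beta_tilde: float = 0.3
    #: O(1) coefficient linking basal to recruited H3K9me3 erasure
    b_tilde: float = 2.0
    # --- calibrated defaults (not printed in the source model's main text) ---
    #: TF-recruited activating-writing scale (normalized k~_W^A / (k_M^A D_tot))
    kappa_WA: float = 2.0
    #: de-novo CpGme writing rate per unmodified/H3K9me3 nucleosome
    kappa_WR1: float = 0.06
    #: de-novo H3K9me3 writing rate per unmodified/CpGme nucleosome
    kappa_WR2: float = 0.02
    #: TF-DNA dissociation constant, molecule counts
    K_A: float = 100.0
    #: expression capacity per active nucleosome, p_bar_X = alpha_X / gamma_X
    p_bar_O: float = 3.2
    p_bar_T: float = 3.2
    p_bar_J: float = 3.2
    #: normalized protein turnover rate
    gamma_hat: float = 0.2
    # --- MBD modulation (Eq.-style shielding of CpGme from TET1) ---
    #: MBD abundance; None means "use mu_tilde_prime directly"
    B: float | None = None
    K_B: float = 1.0
    F2: float = 1.0
    F5: float = 1.0

    @property
    def alpha_prime(self) -> float:
        """H3K9me3 -> CpGme cross-catalysis, alpha' = r * alpha."""
        return self.r * self.alpha

    def effective_mu_tilde_prime(self) -> float:
        """mu'~ actually used by the reaction table (MBD-modulated if B is set)."""
        if self.B is None:
            return self.mu_tilde_prime
        return mbd_modulated_mu(self.B, self.K_B, self.F2, self.F5)

    def p_bar(self, gene: str) -> float:
        return {"O": self.p_bar_O, "T": self.p_bar_T, "J": self.p_bar_J}[gene]

    def validate(self) -> "DimensionlessParams":
        if not (isinstance(self.D_tot, (int,)) and self.D_tot >= 1):
            raise ParameterError(f"D_tot must be a positive integer, got {self.D_tot}")
        nonneg = ("alpha", "alpha_bar", "r", "mu_tilde", "mu_tilde_prime",
                  "eps_d", "eps_e", "eps_prime", "beta_tilde", "b_tilde",
                  "kappa_WA", "kappa_WR1", "kappa_WR2",
                  "p_bar_O", "p_bar_T", "p_bar_J", "gamma_hat", "F2", "F5")
        for name in nonneg:
            v = getattr(self, name)
            if not (v >= 0):
                raise ParameterError(f"{name} must be >= 0, got {v}")
        if not (0.0 <= self.eta <= 1.0):
            raise ParameterError(f"eta must lie in [0, 1], got {self.eta}")
        if self.K_A <= 0:
            raise ParameterError(f"K_A must be > 0, got {self.K_A}")
        if self.K_B <= 0:
            raise ParameterError(f"K_B must be > 0, got {self.K_B}")
        if self.B is not None and self.B < 0:
            raise ParameterError(f"B must be >= 0, got {self.B}")
        return self

    def with_updates(self, **kwargs) -> "DimensionlessParams":
        """Return a copy with fields replaced.

        Accepts the convenience keys ``alpha_prime`` (converted to ``r``) and
        ``p_bar`` (sets all three expression capacities).
        """
        kw = dict(kwargs)
        if "p_bar" in kw:
            pb = kw.pop("p_bar")
            kw.setdefault("p_bar_O", pb)
            kw.setdefault("p_bar_T", pb)
            kw.setdefault("p_bar_J", pb)
        if "alpha_prime" in kw:
            ap = kw.pop("alpha_prime")
            alpha = kw.get("alpha", self.alpha)
            if alpha <= 0:
                raise ParameterError("alpha must be > 0 to set alpha_prime")
            if "r" in kw and abs(kw["r"] * alpha - ap) > 1e-9 * max(1.0, abs(ap)):
                raise ParameterError(
                    "inconsistent r and alpha_prime: r must equal alpha_prime/alpha")
            kw["r"] = ap / alpha
        unknown = set(kw) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        return dataclasses.replace(self, **kw).validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def day_to_tau(days: float) -> float:
    """Convert days to normalized time (21 days == tau 201.6)."""
    if days < 0:
        raise ParameterError(f"days must be >= 0, got {days}")
    return days * TAU_PER_DAY


def tau_to_day(tau: float) -> float:
    """Convert normalized time to days."""
    if tau < 0:
        raise ParameterError(f"tau must be >= 0, got {tau}")
    return tau / TAU_PER_DAY
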