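# Methods

## Model

`epigrn` simulates a three-gene regulatory network — OCT4, TET1, JMJD2 —
in which regulation acts entirely through chromatin state.  Each gene owns
`D_tot = 50` modifiable nucleosomes in five states: unmodified (D),
activating H3K4me3/ac (D^A), DNA-methylated (D^R1), H3K9me3-marked (D^R2),
and doubly repressed (D^R12).  The per-gene reaction table (27 chromatin
channels + 3 protein channels) implements:

* **writing** — TF-recruited activating writing at rate
  κ_WA · Hill(X_O/K_A) per D nucleosome (cooperativity-1 Hill, so there is
  no TF-independent activating writing: at X_O = 0 the gene cannot
  activate); de-novo repressive writing at κ_WR1 (CpGme) and κ_WR2
  (H3K9me3);
* **read–write catalysis** — activating auto-catalysis at the reference
  rate (1/D_tot per catalyst–substrate pair; this reaction defines the time
  unit), H3K9me3 auto-catalysis at α, CpGme→H3K9me3 cross-catalysis at ᾱ,
  and H3K9me3→CpGme cross-catalysis at α′ = r·α;
* **dilution** — every mark is lost at the replication-dilution rate ε_d,
  except CpGme, which is maintained by DNMT1 and diluted only at η·ε_d
  (η = δ′/δ ∈ [0, 1]: 0 = perfect maintenance, 1 = none);
* **erasure** — basal (ε_e) and D^A-recruited (ε′) erasure; repressive-mark
  erasure is scaled by μ̃ (H3K9me3, carried out by JMJD2) and μ̃′ (CpGme, by
  TET1) and by the current modifier activity (below).  The O(1)
  coefficients b̃ and β̃ relate the basal repressive-erasure rates to the
  recruited ones.  A channel's rate does not depend on whether the other
  repressive mark sits on the same nucleosome;
* **expression** — lumped transcription–translation at p̄_X·γ̂ per D^A
  nucleosome, first-order turnover γ̂·X, and exogenous overexpression
  ū_X(τ)·γ̂, so a constant input contributes exactly ū_X molecules at
  stationarity.

**Modifier activity scaling.** TET1 and JMJD2 abundances are state
variables; the erasure channels are scaled linearly by
g_T = X_T/(p̄_T·D_tot) and g_J = X_J/(p̄_J·D_tot).  The normalization makes
a fully active, non-overexpressed modifier gene (stationary X ≈ p̄·D_tot)
reproduce exactly the nominal μ̃, μ̃′ of the frozen-modifier single-gene
circuit, preserving the published meaning of those parameters at the
reference operating point.  A saturating dependence would be a drop-in
alternative; linear was chosen as the minimal assumption.

**MBD proteins.** When an MBD abundance `B` is configured, μ̃′ is computed
as F₅/(F₂·B/K_B + 1): abundant MBDs shield methylated CpG from TET1 and
suppress DNA demethylation; knockdown (B = 0) restores μ̃′ = F₅.

**Units.** Time is normalized, τ = t·k_M^A·D_tot, with the fixed anchor
21 days ≡ τ = 201.6 (9.6 τ/day).  All latencies are reported in days.

## Simulation

Trajectories are exact samples of the continuous-time Markov chain via the
Gillespie direct method (cumulative-sum channel selection over the 90
channels), compiled with numba.  Piecewise-constant inputs are handled
exactly: a proposed jump beyond the next schedule breakpoint is discarded
and the clock advanced to the breakpoint (propensities are constant in
between and the exponential clock is memoryless).  States are sampled on a
fixed grid (default 0.1-day spacing, recording the left limit where a jump
coincides with a grid point); first-passage times of n_O^A across the
activation/silencing thresholds are recorded at exact event times.  Each
trajectory uses one RNG stream seeded by a SplitMix64-style mix of
(base seed, trajectory index), so repeat runs are bit-identical and sweep
arms share paired seeds.

**Division mode.** Optionally, first-order dilution (channels for mark
dilution and protein turnover) is removed and replaced by synchronous
divisions every ln 2/ε_d: each protein molecule and each histone mark is
retained with probability 1/2, and each CpGme mark is lost with probability
η/2 — the maintained (1 − η) fraction of the diluted half survives, which
reproduces the effective rate δ′ = η·δ in expectation.  Divisions are
deterministic and synchronous (simplest reading of partitioning "at the end
of the cell cycle"); γ̂ is treated as pure dilution, so protein turnover in
this mode is ln 2/period = ε_d.

## Experiments and metrics

* *Differentiation*: input-free runs from the fully active state (all genes
  D^A, proteins at p̄·D_tot); latency = first passage of n_O^A down to 0.
* *Reprogramming*: runs from the fully repressed state under overexpression;
  latency = first passage of n_O^A up to 40 of 50.  The repressed initial
  composition is all-D^R12 with zero proteins — the paper-style constraint
  fixes only n^A = 0; the dual-marked choice matches a differentiated,
  DNA-methylated locus and is the conservative (slowest-reactivating)
  composition.  Both thresholds and the composition are configurable.
* *Metrics*: %O^A(τ) = 100 × (fraction of N trajectories with latency ≤ τ);
  f̄_L = day-binned latency frequencies normalized by N with the censored
  mass reported separately (histogram mass + censored mass = 1); latency
  variability as SD, IQR and CV over uncensored latencies only (no
  survival estimator is introduced — censored counts are reported
  alongside).  Ensembles default to N = 100; the bundled validation studies
  use N = 50 per arm.

## Validation oracles

1. **Chemical master equation** — for a single gene with frozen modifier
   activities the state space (compositions of D_tot into 5 species,
   C(D_tot+4, 4) states) is enumerated and p(τ) = exp(Gᵀτ)p₀ computed with
   a dense matrix exponential (refused above D_tot = 6).  The empirical SSA
   distribution at τ = 5 over 10,000 runs agrees within total-variation
   distance 0.05 (measured ≈ 0.016 at D_tot = 3); this is the primary joint
   gate on the kernel and the propensity table.
2. **Protein birth–death law** — with chromatin frozen, the stationary
   protein count is Poisson(p̄·n^A); checked by mean (3·SE) and chi-square.
3. **Mean-field ODE** — the propensity table with counts replaced by
   continuous means, integrated segment-by-segment (LSODA, rtol 1e-8).
   For linear (protein) kinetics the mean-field mean is exact and SSA
   ensemble means agree within 3·SE.  For bimolecular chromatin kinetics
   the mean-field solution carries a systematic O(1/D_tot) gap from the
   true mean (~1.4 counts of 50 in the driven-reactivation corner), so that
   comparison uses max(3·SE, 0.05·D_tot).

## Parameters

Printed study parameters (ε_d, ε_e, ε′, η, μ̃, μ̃′, p̄, ū, D_tot, N,
thresholds, horizon) are taken as given per study arm.  The remaining
constants are **calibrated defaults**, chosen once so that the simulator
reproduces the documented qualitative behaviour, and not revisited:

| parameter | default | role / why this value |
| --- | --- | --- |
| α | 0.2 | H3K9me3 auto-catalysis; ≫0.5 would lock the repressed state so hard that OCT4-only reprogramming cannot occur within 21 days even at ε_d = 0.3 |
| ᾱ | 0.01 | CpGme→H3K9me3 cross-catalysis; must be ≪ α, otherwise full DNA methylation keeps re-seeding H3K9me3 and erasing H3K9me3 (JMJD2) can never interrupt re-methylation — consistent with H3K9me3 decaying much faster than CpGme |
| r (α′/α) | 1.0 | H3K9me3→CpGme cross-catalysis ratio; swept {0.2–10} in the comparison studies |
| κ_WA | 2.0 | TF-recruited activating writing; large enough that saturating OCT4 input wins the capture race against repressive re-marking on bare nucleosomes |
| κ_WR1 | 0.06 | de-novo CpGme writing; drives differentiation — CpG accumulates when μ̃′ is small and is held near zero when μ̃′ ≈ 1 |
| κ_WR2 | 0.02 | de-novo H3K9me3 writing; kept small so cleared H3K9me3 does not trivially re-seed |
| K_A | 100 | TF–DNA dissociation constant (counts); overexpression at ū = 160–320 gives Hill occupancy 0.6–0.8 |
| β̃ | 0.3 | basal/recruited CpGme-erasure coefficient; small, so at low μ̃′ basal TET1 action cannot outrun α′-driven re-methylation |
| b̃ | 2.0 | basal/recruited H3K9me3-erasure coefficient; lets overexpressed JMJD2 clear H3K9me3 before any activating marks exist |
| γ̂ | 0.2 | protein turnover; proteins equilibrate in ~0.5 day, fast against the 21-day horizon. Held fixed when ε_d is swept (the sweeps probe chromatin dilution); coupling γ̂ to ε_d is a one-line config change |

With these values: differentiation silences 0% / ~85% / 100% of
trajectories at μ̃′ = 1 / 0.15 / 0.07; OCT4-only reprogramming yields
%O^A ≈ 0 / 90 / 100 at ε_d = 0.06 / 0.1 / 0.3; TET1 co-overexpression
tightens latency SD from ~1.0 to ~0.2 days across ū_T = 0→160; and the
JMJD2 arm beats the TET1 arm only at (low μ̃′, high r), as the efficiency
comparison requires.  All of these are recomputed by the test suite and
`scripts/acceptance.py`, not asserted as constants.

## What the simulations do and do not show

The ensembles emulate idealized clonal populations: one locus per gene,
well-mixed nucleosomes without positional structure, lumped
transcription–translation, no oxidized-cytosine intermediates (TET1's
product chain is collapsed into a single demethylation step), no Sox2/Nanog
layer, and — outside division mode — dilution as a first-order rate rather
than discrete divisions.  Passing trends therefore support the *mechanistic
logic* (which barriers dominate under which parameter regimes), not
quantitative predictions of colony counts in reprogramming experiments.
Efficiencies saturate at 100% in several overexpression arms under the
calibrated defaults; in those arms the discriminating statistic is the
latency distribution, not the endpoint efficiency.

## Numerical choices and degenerate inputs

Zero total propensity is legal (the chain rests until the next breakpoint
or the horizon).  tau_end = 0 censors every latency.  All-censored
ensembles report an empty latency histogram with a warning and NaN
variability.  Threshold crossings are detected after every event and every
division.  Nucleosome conservation (Σ species = D_tot per gene) is enforced
by construction of every update vector and re-checked on every sampled
trajectory.  Config validation rejects unknown keys by name, η outside
[0, 1], negative rates, and thresholds outside 0 ≤ off < on ≤ D_tot.

## Problem sizes

The bundled validation suite and `scripts/acceptance.py` run N = 50
trajectories per study arm (paired base seeds across arms), 10,000 runs for
the master-equation comparison at D_tot = 3, and 10,000 spaced stationary
samples for the Poisson check — sizes at which every reported trend is
resolved with comfortable Monte Carlo margin on a single CPU.
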