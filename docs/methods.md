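# Methods

## Model and assumptions

The cascade is a chain of n push–pull (kinase/phosphatase) cycles in an
isothermal, isovolumic, well-mixed reactor held out of equilibrium by
chemostatted ATP/ADP/Pi. Each step j carries a conserved pool
X_j + X_j* = `totals[j]`; conservation encodes the assumption that protein
synthesis and degradation are slow compared with signalling. The reaction
channels are

    X_j* + X_{j+1} -> X_j* + X_{j+1}*      propensity k_fwd[j+1] · X_j* · X_{j+1}
    X_{j+1}*       -> X_{j+1}              propensity k_bwd[j+1] · X_{j+1}*

with step 1 activated by a constant receptor drive
`k_fwd[1] · stimulus · X_1`. This constant-stimulus closure is the minimal
boundary condition that makes the chain well-posed without modelling
receptor–ligand kinetics; the chemostats never appear as state variables
because their fixed chemical potentials are absorbed into the effective
rate coefficients. A vanishing phosphatase rate (`k_bwd = 0`) is legal and
gives the irreversible limit, in which the simulator reports an absorbing,
truncated trajectory.

Occurrence probabilities are pool fractions: p_j = X_j/X, p_j* = X_j*/X
with X = Σ_j totals[j], normalised as Σ_j (p_j + p_j*) = 1. They double as
symbol-selection probabilities in the message-coding picture.

## Parameters that matter

| parameter | units | default | role |
|---|---|---|---|
| `k_fwd[j]` | 1/(count·time) (1/time for step 1) | fixture-dependent | activation drive |
| `k_bwd[j]` | 1/time | 1 | phosphatase recovery |
| `totals[j]` | counts | 1000 | pool size; sets Stirling accuracy and Monte-Carlo noise |
| `tau[j]` | time | 1 | signal-step duration entering ζ_j = −ln(p_j)/τ_j |
| `stimulus` | — | 1 | receptor drive multiplier on step 1 |
| `kB`, `temperature` | energy scale | 1, 1 | all entropies/currents reported in k_B·T units; an SI mode is a unit change only |

Logarithms are natural throughout (the pairing of log with k_B fixes nats);
the CLI offers a bits conversion (divide by ln 2).

## Entropy bookkeeping

`log_multiplicity` evaluates ln ψ = ln X! − Σ ln X_j! − Σ ln X_j*! with
log-gamma, exact to floating precision at any pool size.
`stirling_entropy` is the Stirling form S = −k_B X Σ(p ln p) with the
0·ln 0 := 0 limit; at 10³ molecules the two agree to just under 1%
(the leading correction is ½(k−1)ln(2πX) for k occupied forms). The mixing
entropy of a step under an active-form fluctuation dp* (with dp = −dp*
inside the step) is exposed both as the perturbed value and as its
unperturbed baseline; the derivative of their difference at dp* = 0 is
k_B X ln(p_j/p_j*), which is where the current density comes from. The
current operations, unlike the entropies, **reject** zero occupancies: the
log-odds diverge there and silent infinities would corrupt every pooled
average.

## Fluctuation-theorem estimator and its sign convention

A step's forward transition is operationalised as an activation event of
its species and the backward transition as its deactivation — the only
reading consistent with the two channels above. Raw event counts cannot
test the stationary fluctuation theorem: in steady state the activation
and deactivation counts of the same species balance to within one pool
size whatever the drive, so ln(n_fwd/n_bwd) → 0 always. The estimator
therefore uses **per-molecule conditional rates**, normalising counts by
species holding-time integrals:

    r̂_fwd = n_fwd / ∫X_j dt,   r̂_bwd = n_bwd / ∫X_j* dt.

Stationary flux balance gives r_fwd·p_j = r_bwd·p_j*, hence the exact
relation ln(r_fwd/r_bwd) = −ln(p_j/p_j*): the transition log-ratio equals
the occupancy log-odds **with a minus sign** in this orientation
(forward = activation). The package keeps that orientation, reports the
occupancy log-odds and the expected ratio side by side, and checks their
difference against a delta-method 95% band (half-width
1.96·√(1/n_fwd + 1/n_bwd), the asymptotic variance of the two independent
rate MLEs of a continuous-time Markov chain). The τ → ∞ limit in the
theorem is replaced by the full post-burn-in window with this CI — finite
trajectories are all a simulator can offer. Supplying an independent
reference occupancy (analytic or deterministic) makes the check a genuine
test of the dynamics; supplying the same trajectory's occupancy reduces it
to the raw count ratio, which vanishes identically in stationarity.

Related sign note: the printed defining relations of ζ and J carry
opposite signs (ζ = −C_j/(k_B T τ_j) versus J = k_B T ζ > 0). The currents
module does not silently pick one: it reports per-step magnitudes with an
explicit `sign` field, and `zeta_from_occurrence` uses the unambiguous
ζ_j = −ln(p_j)/τ_j > 0.

## ζ, the coding closure, and step-independence

For symbol durations τ_j, the maximal-rate (Kraft-equality) closure
Σ_j e^(−ζτ_j) = 1 has a unique positive root for n ≥ 2, found by Brent's
method bracketed at [10⁻¹², ln(n)/min τ + 1] to |residual| < 10⁻¹²; it
obeys ζ(aτ) = ζ(τ)/a. A single symbol admits no positive root and is
rejected. When the steady state obeys p_j = e^(−ζτ_j), every ζ_j coincides
and J_j = k_B T ζ_j is constant along the cascade; the pooled ζ is
duration-weighted by default (plain mean by flag — no canonical pooling
rule exists, and the weighted form is exact on coding-law cascades either
way). The amplitude ΔX_j* in C_j = c_j ΔX_j* is an explicit argument
(default 1, a single activation event); whether it should be a one-event
increment or a coarse-grained amplitude is a modelling choice the API
leaves to the user.

## Simulation and numerics

- **SSA**: direct method with a numpy `default_rng(seed)`; propensities
  are recomputed per event in plain Python (2n channels is tiny), with
  block-drawn uniforms. Exact, reproducible, ~10⁵ events/s.
- **Deterministic steady state**: the catalysis is feed-forward (step j's
  balance involves only a_{j−1}), so the mass-action fixed point is solved
  exactly step by step: a_j = drive·totals_j/(drive + k_bwd[j]) with
  drive = k_fwd[j]·a_{j−1}. No iteration, hence no convergence failure
  mode.
- **Burn-in**: default 20% of the horizon; the steady-state analysis
  needs transients discarded and no principled criterion exists at this
  level of description.
- **Occupancy SE**: batch means over 20 slabs of the post-burn-in window,
  which absorbs autocorrelation at the slab scale.
- **Spatial gradients**: `np.gradient` with second-order one-sided
  boundary stencils — exact on linear and quadratic profiles.
- **Transport identification**: D_j = c_j is implemented literally in
  model units; it equates an energy-scaled log-odds with a diffusion
  coefficient, so an SI interpretation needs a user-supplied
  length²/time conversion the package deliberately does not invent
  (`entropy_current_gradient` takes D as separate input only through c,
  so a user may break the identification upstream).

## Synthetic fixtures: what they emulate and what they do not

Three regimes instantiate the study conditions (defaults n = 3, 1000
molecules/step, τ = (1,1,1), seed 42 — small cascades in the spirit of the
three-step MAPK chain, with pools large enough for ~1% Stirling accuracy):

- `equilibrium`: rates back-solved so the steady state has p_j = p_j*
  (zero current density) — the null for the FT machinery;
- `driven`: stationary active fraction 2/3 at every step, a uniform drive
  c_j = −ln 2;
- `eq19_consistent`: rates back-solved from the mass-action balance so the
  steady state realises p_j = e^(−ζτ_j) (default ζ = 1.5; feasibility
  requires Σe^(−ζτ_j) ≤ 1 and e^(−ζτ_j) < totals_j/X, rejected otherwise
  with a diagnostic). The Kraft-equality boundary (Σ = 1) leaves the whole
  pool inactive and is realisable only by the unstimulated cascade; it is
  special-cased as such.

The generator emulates well-mixed, single-compartment cascades with fixed
pools and constant stimulus. It does not emulate receptor/ligand kinetics,
spatial compartmentalisation, multi-site phosphorylation, enzyme
saturation, or protein turnover — so passing tests certify the estimators
and the thermodynamic identities on the idealised model, not the fidelity
of that model to any real pathway's data.

## Known limitations

- The FT estimator needs both forms occupied after burn-in; deeply driven
  cascades with near-empty forms raise `InsufficientEventsError` rather
  than returning unstable estimates.
- The delta-method CI ignores residual correlation between counts and
  holding-time integrals; empirical coverage on the driven chain is ≈98%
  at 10⁴ events (slightly conservative).
- Exact SSA only: no tau-leaping, so pools ≫10⁵ or stiff rate ratios are
  slow by design.
- Problem sizes used in the shipped checks (10⁴-event trajectories, 50
  replicates, 10⁴ copies/step for the law-of-large-numbers comparison)
  were chosen as the smallest scales at which the stochastic tolerances
  are comfortably resolved.
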