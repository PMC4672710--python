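# Methods

This note records the models implemented in `mitonet`, their
assumptions, the parameter conventions, and the numerical and design
choices that were genuinely open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Fluctuating bond lattice

Mitochondrial material is discretised into equal "units" occupying the
nodes of an `L^d` square lattice (d = 2 or 3). Each bond between
neighbouring units is an independent two-state Markov process: off → on
at the fusion rate λ_fus, on → off at the fission rate λ_fis, both
constants per bond. The stationary fused fraction is
p = λ_fus/(λ_fus + λ_fis) and the bond relaxation time is
τ = 1/(λ_fus + λ_fis) — the decay constant of the bond autocorrelation,
the standard relaxation time of a two-state process. Bonds are
initialised from the stationary law, so the on-fraction has no
transient, and are advanced with the exact finite-interval transition
probabilities

    P(on | on, Δt)  = p + (1 − p) e^(−Δt/τ),
    P(on | off, Δt) = p (1 − e^(−Δt/τ)),

which makes `step_bonds` free of time-discretisation error for any Δt
(composition of two half-steps has the same law as one full step, and
the suite checks this distributionally).

Conventions: lattice constant a = 1; node coordinates are 0-based
integer tuples; each bond is stored once, keyed by its lexicographically
smaller endpoint; open boundaries by default (spanning along axis 0 is
well defined), periodic boundaries for diffusion runs. A single
vectorised RNG stream in fixed bond order replaces per-bond substreams:
the API exposes no operation that reorders bonds, so this is equally
reproducible and much faster.

Morphology labels follow the p / λ_fis taxonomy: fragmented (p = 0),
microfused (0 < p ≤ ε), mesofused (ε < p < p_c), dynamic hyperfused
(p_c ≤ p ≤ 1 − ε with λ_fis > 0) and static hyperfused (p > 1 − ε, or no
fission at all while percolating). ε defaults to 0.05 — the sources give
no numeric cut-off for "≈ 0" and "≈ 1", so one is fixed here. p_c
defaults to the exact square-lattice value 1/2; in 3D it must be
supplied or estimated by simulation (`estimate_percolation_threshold`
performs bisection on the Monte-Carlo spanning probability).

## Tracer diffusion

Walkers model fast-diffusing matrix species. Each walker attempts hops
as a Poisson process of total rate λ_dif, draws one of the 2d neighbours
uniformly, and crosses iff the connecting bond is on at that instant
(blind-ant rule — chosen over the myopic ant because it makes the
fast-flicker limit D → p·λ_dif/(2d) exact). Bond states are sampled
lazily at walker query times using the exact transition law above, which
is an exact event-driven co-simulation: the bond process is Markov, so
its state needs resolving only when observed. Walkers are given
independent bond-environment realisations; since walkers do not
interact, the single-walker law (hence the mean-squared displacement) is
unchanged, only cross-walker covariance is dropped, which if anything
makes the reported standard errors slightly optimistic on shared
environments. Walkers start at uniformly random cells (the stationary
law of the walk) and displacement is tracked unwrapped on the periodic
lattice. `estimate_D` fits a weighted straight line to MSD(t) over a
window (default: the second half of the run) and reports
D = slope/(2d), clipping negative fitted slopes to zero with a warning.

For static configurations the test suite cross-checks the simulated D
against an exact master-equation computation (the discrete
homogenisation / corrector linear solve) on 4×4 lattices.

### Dynamic effective-medium closure

The mean-field D(p, τ) replaces every bond by an effective conductance
θ solving the bond-EMA self-consistency condition with the flicker rate
1/τ entering as an additive frequency shift γ of all conductances
(conductances in units of the per-bond hop rate λ_dif/z, z = 2d):

    p (1 + γ − θ′)/(1 + γ + (z/2 − 1) θ′)
      + (1 − p) (γ − θ′)/(γ + (z/2 − 1) θ′) = 0,
    θ = θ′ − γ,      D = θ · λ_dif/(2d),
    γ = C0 / (λ_dif τ).

Both limits are exact and independent of C0: γ → 0 recovers the static
bond EMA, D/D_free = (zp/2 − 1)/(z/2 − 1) above p = 2/z and 0 below
(= 2p − 1 on the square lattice, vanishing below p = 1/2); γ → ∞
recovers the annealed result D = p·D_free, because a bond flickering
much faster than it is probed acts as its time average. Near p = 1/2
the shift lifts D above zero like √γ, the square-root rounding familiar
from AC conduction at a percolation threshold, so the static switch
smooths progressively as τ falls — the qualitative shape of the D(p, τ)
surface. The crossover constant C0 is the closure's one free parameter
(an exact dynamic-EMA kernel would fix it); it was calibrated once
against the agent-based simulator at (p, τ) = (0.5, 10), d = 2, giving
C0 = 1.5, and then frozen. With that single calibration the closure
tracks the simulator within ~10% relative error across
p ∈ {0.2, 0.5, 0.8} × τ ∈ {0.1, 10}.

### Locating the switch

The static conductivity of the 2D lattice rises from zero at p_c and
keeps growing essentially linearly all the way to p = 1 — there is no
plateau — so on a finite-difference grid extending deep into the
hyperfused regime the largest gradient sits *above* the threshold. The
"abrupt change at p = 1/2" is an onset non-analyticity, not an
inflection. The shape checks therefore probe the transition with a
p-grid bracketing the threshold from below and across, and the
percolation location itself is estimated by bisection on the spanning
probability (L = 128, 200 snapshots per candidate p), which converges
to 0.500 ± 0.002 in a few seconds.

`kiss_and_run_range(D, t, d)` is the only operation in physical units:
it returns the RMS displacement √(2dDt), e.g. ≈ 73.5 µm for a matrix
protein with D = 20 µm²/s over a mean 45 s transient fusion contact —
ample for matrix-content equilibration without any large-scale network.

## Quality control ("blind surveillance")

State: fractions (h_f, h_n, d_f, d_n) of healthy/dysfunctional ×
fragmented/networked units, summing to one. Mechanisms: blind fission
(rate λ_fis for everyone), selective fusion (healthy fragments at
λ_fus, dysfunctional at s·λ_fus, s ∈ [0,1]), size-selective
function-blind mitophagy (rate μ, fragments only), damage (rate δ,
healthy → dysfunctional), and biogenesis that replaces every degraded
unit with a fresh healthy fragment, conserving the total exactly. The
dynamics are linear, so the steady state is computed exactly as the
normalised null vector of the rate matrix (SVD), with long LSODA
integration as the independent fallback and cross-check whenever the
null space is degenerate (e.g. λ_fis = 0 traps a networked pool).

Where damage acts was genuinely open. The default applies δ to
fragmented units only; `damage="network"` and `"both"` are config
options. The choice matters: with damage confined to fragments the
model has the clean closed form (derived by hand, used as a test
oracle)

    h* = (1 + x) / (1 + x + (δ/μ)(1 + s x)),    x = λ_fus/λ_fis,

which is strictly increasing in λ_fus for s < 1, exactly flat at s = 1
(blind fusion confers no surveillance benefit), and gives the fragment
pool a dysfunction share exceeding the network pool's by the factor
(1/s)·(1 + sδ/μ)/(1 + δ/μ) — the mechanism that makes blind mitophagy
effectively selective. If networked units can also be damaged, raising
fusion additionally shelters dysfunctional units from size-selective
mitophagy and h* can *decrease* with λ_fus even at s = 0; the suite
exercises this variant too. Biogenesis as healthy material is the
default (new organelles are built from fresh components);
`biogenesis="proportional"` replaces degraded units like-for-like as a
sensitivity option (it neutralises mitophagy entirely).

## Bioenergetics of fusion

ATP synthesis rate per unit mass is a logistic in membrane potential,
r(Δψ) = r_max/(1 + e^(−(Δψ − ψ_half)/k)). The defaults ψ_half = 150 mV,
k = 10 mV are illustrative, chosen only so that a physiological
potential range exhibits all three regimes (convex "exponential" tail,
steep rise, plateau); they are not fitted to measurements. Only Δψ is
modelled — the full proton-motive force Δp = Δψ + ΔpH, which actually
drives synthesis, is out of scope.

Fusing two units equilibrates their potentials to a weighted mean:
`mean` weights by mass, `capacitor` conserves charge across
capacitances C_i = size_i · cristae_factor_i, allowing cristae
structure to bias the combination. Either way the result is bounded by
the input potentials (chain fusion beyond the weighted-mean family is
flagged as an open question, not modelled). The net rate change

    Δr = r(ψ_fused)·(m₁+m₂) − r(ψ₁)m₁ − r(ψ₂)m₂

is then a pure Jensen's-inequality statement: negative where the
sigmoid is convex over [ψ₁, ψ₂], positive where concave, zero at equal
potentials (exactly) and on the plateau (to < 10⁻³·r_max).
`superadditivity_check` implements the general usefulness criterion
f(x+y) > f(x) + f(y); linear responses never pass.

## Calcium chains

A chain of n fused units with n_high ER-adjacent members (default 1)
has averaged matrix calcium c(n) = (n_high·c_high + (n−n_high)·c_low)/n
— total calcium is conserved. Enzyme activation is logistic in calcium
(defaults: half-activation 1 µM, width 0.15 µM, c_high = 10 µM,
c_low = 0.05 µM), and total output is n·a(c(n)), optionally minus the
unfused baseline. In this regime output rises (distal units climb the
sigmoid at little cost to the saturated unit) and then falls (dilution
below the activation threshold), with a unique interior optimum
(n* = 8 at the defaults; the suite cross-checks every optimum against
exhaustive scan). Two caveats are structural: (i) a logistic is never
exactly zero at c_low, so for any strictly positive basal activation
total output eventually rises again ~n·a(c_low) at very large n — the
unimodal statement holds where basal activation is negligible, which
the default width guarantees over n ≤ 50; (ii) the model is a snapshot
valid on timescales short compared with calcium extrusion; no uptake or
buffering kinetics are included.

## Robustness

**Capacitor-leak fluctuations.** A spherical mitochondrion of radius r
with membrane area A = 4πr² obeys C·dψ/dt = I_pump − (G_leak +
g_p·N_open(t))·ψ with C = c_m·y·A, I_pump = j·A, G_leak = g_0·A — all
fluxes proportional to surface area, with y ≥ 1 an invagination
(cristae) factor. Pore openings arrive as a Poisson process of rate
ν·A and hold an extra conductance g_p for a fixed lifetime t_p. The
baseline potential ψ₀ = j/g_0 and the membrane time constant c_m·y/g_0
are intensive. Integration is event-driven and exact (piecewise-linear
ODE between events; time-weighted first and second moments accumulated
in closed form after a burn-in of ten membrane time constants).
Defaults (j = 150, g_0 = 1, c_m = 0.02, y = 5, ν = 2, g_p = 0.5,
t_p = 0.05, in the arbitrary-but-coherent unit system with ψ in
mV-like units) put a 0.5 µm mitochondrion at ψ ≈ 143 with ~4% relative
fluctuation. Because one pore perturbs the relative leak by
g_p/(g_0·A) ∝ 1/r² while events arrive at rate ∝ r², the shot-noise
amplitude of σ(ψ)/⟨ψ⟩ scales like 1/r; this exponent is the
implementation's measured result (the fitted log-log slope is reported
by `fluctuation_scaling`, ≈ −0.95 at the defaults), not an asserted
one — larger surface area does make perturbations more frequent, but
their relative size shrinks faster. Added leak can only depolarise, so
⟨ψ⟩ ≤ j/g_0 always.

**Spin-coupled agents.** Mitochondria are binary agents (functional
+1 / failed −1) with Ising energy E = −J Σ_edges s_i s_j − h Σ s_i on a
complete graph, a chain, or the contact graph of a lattice cluster.
Dynamics are single-flip heat-bath (Glauber) rates 1/(1 + e^(ΔE/θ)) at
noise temperature θ, attempt rate one per agent; a Metropolis variant
shares the same Boltzmann stationary law (detailed balance is verified
transition-by-transition in the suite). "Catastrophic loss of
function" defaults to first hitting of the all-failed configuration at
or before the horizon T (made absorbing); an `at_horizon` occupancy
variant is also provided, and it is the variant under which J = 0
factorises *exactly* into the closed-form two-state occupancy per agent
— simultaneous hitting does not factorise, so for the first-hit
definition the independent product is an upper bound. Exact
probabilities use the master equation on the 2^N state space via sparse
`expm_multiply` (N ≤ 12); Gillespie sampling covers larger ensembles
with binomial standard errors. Ferromagnetic coupling makes the
all-functional state metastable: P_catastrophe is non-increasing in J
in the regimes exercised, the quantitative content of
"fused groups resist collective failure".

## Scenario running and provenance

`run_scenario` executes a validated YAML config (unknown keys rejected
with the offending name), derives one seed per scenario from the root
seed via `SeedSequence.spawn` in scenario order, writes one CSV per
scenario and a `provenance.json` containing the SHA-256 of the
canonicalised config, the toolkit version, the root seed and every
derived seed — identical config + seed reproduces every byte.
`generate_fixtures` emits small self-describing demo configs
(byte-identical under regeneration) used by the tests and docs.

## Problem sizes

Defaults were chosen so the whole suite and the acceptance script run
in minutes on one core: percolation bisection at L = 128 with 200
snapshots per candidate p; diffusion surfaces at L = 64 with
1500–4000 walkers and t_max = 300 (the numba kernel processes ~10⁶
events per second per walker batch); fluctuation scaling with 200
replicates of 60 time units; spin ensembles at N = 3–4 exactly and
2000–3000 Gillespie replicates.

## Known limitations

- Lattice topology and constant per-bond rates are idealisations;
  membrane-potential-dependent fusion rates and off-lattice geometries
  are deliberately out of scope.
- The dynamic EMA is an approximate closure with a calibrated crossover
  constant, not an exact kernel; only its two limits are exact.
- The quality-control model is deterministic and non-spatial.
- Δψ stands in for the full proton-motive force; the capacitor fusion
  rule need not capture chain fusion.
- The calcium and fluctuation models are snapshot/stationary
  descriptions with arbitrary-but-coherent units; their numerical
  outputs are illustrative of mechanisms, not predictions of measured
  values.
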