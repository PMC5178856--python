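# Methods

## Model

`ordcamk` implements a human ventricular myocyte as a 42-state ODE
system: the O'Hara–Rudy dynamic (ORd) endocardial formulation — fast and
late Na⁺ currents, the L-type Ca²⁺ channel complex (I_CaL with its K⁺
and Na⁺ components I_CaK, I_CaNa), I_to, I_Kr, I_Ks, I_K1, the Na/Ca
exchanger (myoplasmic and subspace), the Na/K pump, background and pump
currents, SR release/uptake/leak/translocation fluxes, and
buffered Ca²⁺ in four compartments — extended with two regulatory
layers:

**CaMKII.** Activation follows the bound/trapped kinetics

    CaMKbound = CaMK₀ (1 − CaMKtrap) / (1 + KmCaM / Ca_ss)
    dCaMKtrap/dt = α·CaMKbound·(CaMKbound + CaMKtrap) − β·CaMKtrap
    CaMKactive = CaMKbound + CaMKtrap

with α = 0.05 ms⁻¹, β = 0.00068 ms⁻¹, KmCaM = 0.0015 mM and CaMK₀ =
0.05 (control) or 0.12 (overexpression). CaMKactive drives the
phosphorylated-mode fractions φ_X = 1/(1 + Km,CaMK/CaMKactive) of
I_NaL, the I_CaL complex, I_to, SR release and SERCA (Km,CaMK = 0.15).
Because the protocols overexpress CaMKII *at one target at a
time*, the package integrates one CaMKtrap ODE per distinct CaMK₀ in
use (at most two) and routes each target's φ to its track; the bound
fraction uses the target's own CaMK₀. A config switch
(`RegulationConfig.shared_trap`) provides the alternative reading — a
single trap ODE driven by the overexpressed CaMK₀ whose output feeds
only the named target — but two-track routing is the default because it
perturbs no other target's phosphorylation.

**PKA (β-adrenergic, ISO).** Only the downstream phosphorylated-fraction
effects are modelled, at two operating points (no ISO / saturated ISO;
1 µM saturates, sub-micromolar doses map to saturation with a warning):

* I_CaL: current scaled by f_avail = 0.017·lcc_ratio + 0.983;
  activation midpoint shifted from −3.94 mV to −10.0 mV; Ca permeability
  ×1.10; activation time constant ×1.20.
* I_Ks: G_Ks scaled by frac_IKs_avail = 0.49·iks_ratio + 0.51; the XS1
  activation midpoint offset is Xs05 = 11.60·frac_IKs_avail (11.60 mV is
  the unmodified value, so no ISO is exactly the base model). The second
  activation gate (XS2) keeps the unmodified steady state: shifting it
  too abolishes the EADs the protocols are meant to reproduce.
* SERCA/PLB: fPKA_PLB = plb_ratio/4 + 3/4 multiplies Km,CaMK inside the
  phosphorylated-SERCA fraction fJupp = 1/(1 + Km,CaMK·fPKA_PLB/
  CaMKactive); Jup = (1 − fJupp)·Jupnp + fJupp·Jupp − Jleak.

I_Kr block is maximal-conductance scaling: G_Kr × (1 − block fraction).

## Saturated PKA ratios

The saturated values of the three phosphorylation ratios are not fixed
by the equations above; they are configuration
(`beta_adrenergic.SATURATED_RATIOS`). The defaults — lcc 2.098
(f_avail ≈ 1.019, the Soltis–Saucerman maximum), plb 0.2
(fPKA_PLB = 0.80), iks 7.5 (G_Ks ×4.185, XS1 midpoint −48.5 mV) — were
chosen once so that the saturated operating point reproduces the
documented ISO phenomenology simultaneously: APD90 shortening at every
cycle length, stable EADs at 85 % I_Kr block under ISO, their
disappearance at 77 %, and EAD persistence at 77 % when CaMK₀(I_NaL) is
0.12. They were then frozen. The choice is a genuine trade-off: pushing
the short-cycle-length APD shortening fully into the reported range
requires an I_Ks boost that suppresses the reported EADs. The frozen
point favours the qualitative EAD table; the APD90 shortening at
CL 500/1000 ms runs ~20 % low, and the single-target I_CaNa increase
(+5.5 % vs +8.1 %) is the other known residual.

## Protocols and integrator

Runs pace from the published resting state for a fixed 500 beats
(`Protocol.n_beats`) with a rectangular stimulus (−80 µA/µF, 0.5 ms) and
take metrics from the final recorded beats — the last two beats for
scalar quantities, and the final EAD/non-EAD pair for the alternans
run. `steady_state_check` classifies period-1/period-2 convergence of
end-of-beat states by relative L∞ distance at configurable tolerance.
The base model carries a well-known slow monovalent-ion equilibration
(τ ~ 10⁴–10⁵ beats, dominated by intracellular K⁺); at beat 500 the
per-beat relative state change is ~10⁻⁵, which moves no reported metric
by more than ~0.1 %, so the fixed 500-cycle protocol is used as stated
rather than paced to machine-precision periodicity.

The default engine is an adaptive operator-split scheme compiled with
numba: all Hodgkin–Huxley gates (plus the L-type mode fraction and SR
release fluxes, which are linear relaxations) advance by their exact
exponential (Rush–Larsen) update, while voltage, concentrations and the
CaMKtrap tracks advance by forward Euler. The step is capped at the
protocol's 2 ms bound, at 0.5 ms during the action potential
(V > −70 mV), by a 0.5 mV-per-step voltage limiter during fast
depolarization, and by a 5 % relative-change limiter on subspace and
junctional-SR Ca²⁺ during release; recorded beats additionally land on
the uniform 0.1 ms output grid. This removes gate stiffness entirely
and integrates a 2 s beat in a few milliseconds, which is what makes
the ~30 pre-paced scenarios of the test suite and acceptance script
tractable on one CPU. A scipy-LSODA path over the same compiled
right-hand side (`Protocol(solver="lsoda")`, tolerances 10⁻⁶/10⁻⁸) is
kept as an independent time-stepping cross-check; the two agree on
APD90 to well under 1 ms, and halving the step caps moves control APD90
by far less than 0.5 ms.

## Metrics

* **APD90** — from maximum upstroke velocity (parabolically refined so
  the estimate is stable under grid refinement) to the interpolated
  crossing of V_peak − 0.9·(V_peak − V_rest); repolarization failure
  returns the full beat flagged.
* **EAD detection** — after the initial AP peak and while V > −40 mV, a
  fall of ≥ 1 mV below the running maximum followed by a rise of ≥ 1 mV
  above the running minimum counts one event; the two-sided prominence
  gives hysteresis, so bounded noise below half the prominence can never
  change a count. Both parameters are configurable; the defaults follow
  conventional cardiology definitions, as the source protocols do not
  state them.
* **Pattern classification** — over ≥ 4 converged beats: none / stable /
  alternating (strict beat-to-beat alternation) / indeterminate.
* **I_NaL deactivation time** — from the |I_NaL| extremum to first decay
  below 5 % of it. The threshold was calibrated once against the control
  condition and frozen; it turns out to have almost no leverage (5 % → 2 %
  moves the control value only ~30 ms) because I_NaL collapses with
  repolarization, so the EAD/normal *ratio* is the robust quantity
  (~168 %) while absolute times inherit the reimplementation's small APD
  offset.

## Synthetic fixtures

`cli_io.make_fixture_trace` builds analytic traces for testing the
metrics layer without the ODE model: a trapezoidal action potential with
a smooth cosine upstroke (analytic APD90), an injected dip-then-hump
secondary depolarization (exactly one EAD), an alternans beat list, and
an exponential |I_NaL| decay (deactivation time = ln 20/λ at the 5 %
threshold). Optional bounded uniform noise exercises the hysteresis
guarantee. These fixtures emulate the *geometry* the metrics rely on,
not cardiac electrophysiology: passing them validates measurement code,
not the model; model-level behaviour is tested separately against the
paced scenarios.

## Numerical and design notes

* Cell type defaults to the endocardial parameterization (exposed as
  `Protocol.celltype`); the source protocols do not state a cell type.
* GHK driving forces guard the removable singularity at V = 0 by a 1 µV
  nudge.
* CaMKtrap starts at 0 and equilibrates during pre-pacing.
* Determinism: identical configurations produce bitwise-identical runs;
  no randomness exists outside the fixture generator's seeded noise.
* Known limitations: no CaMKII effects on RyR or I_K1, no chronic
  remodeling, no PKA effect on I_NaK, no dynamic cAMP/PKA network (two
  operating points only), single cell only (no tissue coupling).
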