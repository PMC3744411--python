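# Methods

This note documents the model equations, the parameter choices that matter,
the numerical scheme, and the design decisions that were genuinely open, in
enough detail to re-derive every number the package computes.

## Receptor model

Each nAChR subtype is reduced to two independent gating variables, an
activation gate `a` (fast, milliseconds) and a sensitization gate `s` (slow,
seconds to minutes); only receptors that are simultaneously activated and
sensitized conduct, so the normalized open fraction is `a·s`. Both gates
relax exponentially toward Hill-type steady states:

    da/dt = (a∞(c_act) − a) / τ_a
    ds/dt = (s∞(c_des) − s) / τ_s(c_des)

    c_act = ACh + α·Nic          (ACh-equivalent µM)
    c_des = Nic + η·ACh          (Nic-equivalent µM)

The activation drive folds nicotine into ACh-equivalents through the potency
factor α > 1; the desensitization drive is measured in nicotine units
because the half-maximum desensitization constants are tabulated for
nicotine. η ∈ [0, 1] models acetylcholinesterase efficiency: at η = 0
(default) ACh is hydrolyzed too quickly to desensitize receptors; at η = 1
ACh and nicotine desensitize to equal amounts. η enters both `s∞` and the
concentration argument of `τ_s`. The α4β2/α7 parameter sets shipped as
presets (EC50 30/80 µM, α 3/2, Hill coefficients 1.05/1.73 and 0.5/2,
IC50 0.061/1.3 µM, τ_a 5 ms, τ_max 10/2 min, τ_0 500/50 ms, K_τ 0.11/1.73 µM)
encode the defining subtype contrast: nicotine at the physiological
0.5 µM substantially activates and desensitizes α4β2 but barely touches α7.

Three conventions were open and are fixed project-wide:

* **τ_s midpoint.** `τ_s` is a decreasing Hill sigmoid between τ_max (zero
  ligand) and τ_0 (saturating ligand) with midpoint K_τ, i.e.
  τ_s(K_τ) = (τ_max + τ_0)/2. A reading in which the time constant reaches
  "half of its minimum" is impossible given τ_s ≥ τ_0 and was rejected.
* **α and desensitization.** α scales nicotine only inside the activation
  drive. The desensitization constants are nicotine-referenced, so adding a
  second potency factor there would double-count.
* **η placement.** Receptor parameter sets carry a per-subtype η (default
  0); a protocol-level η overrides the α4β2 value only, since the
  esterase-efficiency question is studied for the dominant α4β2 pathway.

## Circuit model

DA and GABA population rates obey threshold-linear mean-field dynamics,

    τ_DA ν̇_DA = −ν_DA + Φ(I_Glu + r·I_α4β2 − I_GABA + I_intr + I0_DA)
    τ_G  ν̇_G  = −ν_G  + Φ(I_Glu + (1−r)·I_α4β2 + I0_G)

with Φ(I) = max(I, 0), I_GABA = w_G·ν_G, I_α4β2 = w_α4β2·(a·s)_α4β2 and
I_Glu = w_Glu·(ν_Glu + (a·s)_α7 − ν_Glu·(a·s)_α7). The Glu drive is a
probabilistic OR: either afferent firing or presynaptic α7 activation alone
saturates transmission. The balance parameter r sends a fraction r of the
α4β2 current to DA cells and 1 − r to GABA cells; r = 1 is pure direct
stimulation, r = 0 pure disinhibition substrate.

Choices that were open:

* **r convention.** r is the DA-side share. Fixed project-wide and
  threaded through every preset and test.
* **Membrane time constants** τ_DA = τ_G = 20 ms. All reported outcomes
  evolve on seconds to minutes; a test verifies that 10× slower membranes
  change the response metrics by < 1%.
* **Background currents.** I_intr = 1 (DA pacemaker), I0_DA = I0_G = 0.
  Both populations expose an I0 field because the constant-background
  bookkeeping could plausibly target either; all shipped results normalize
  to the pre-nicotine baseline, which makes absolute units immaterial.
* **GABA input.** GABA cells receive the same glutamatergic drive plus
  their α4β2 share, giving them a nonzero, ACh-sensitive baseline — required
  for the slice IPSC phenomenology (baseline inhibitory tone that nicotine
  first boosts, then suppresses below baseline).
* **Blockade semantics.** Antagonist and knockout are both modeled by
  clamping the subtype's open fraction to zero in the currents (gates keep
  evolving); blocked transmission pathways have their current zeroed.

With unit weights and no clipping the fixed point is linear, which yields
two structural results used as oracles in the tests: the glutamatergic term
cancels out of the DA fixed point (it enters once directly and once, with
opposite sign, through the GABA relay), and the steady-state DA response to
any change of the α4β2 open fraction is (2r − 1) times that change — so
direct and disinhibitory routes cancel exactly at r = ½, and the
direct-stimulation ACh threshold (below) is independent of r for r > ½.

## Pharmacokinetics and protocols

Applied nicotine (bath or injection) reaches the receptor site through a
first-order lag with τ_PK = 60 s; overlapping applications sum. Protocols
start from the analytic steady state ("pre-equilibrated" always means the
closed-form fixed point, never a burn-in simulation) and by default extend
6·τ_max(α4β2) past the last washout, capturing > 99 % of the recovery tail.

Scenario presets (overridable in any call or config):

| scenario            | r   | ν_ACh (µM) | ν_Glu     | Nic duration |
|---------------------|-----|------------|-----------|--------------|
| direct_stimulation  | 0.8 | 0.1        | 0.2       | 10 min       |
| disinhibition       | 0.2 | 1.77       | 0.2       | 2 min        |
| in_vitro_ipsc       | 0.5 | 0.266587   | 0 (Glu blocked) | 2 min  |
| in_vitro_epsc       | 0.5 | 0.266587   | 3.768e-4 (GABA blocked) | 2 min |

The in-vivo ν_Glu = 0.2 is a free choice: in the unclipped unit-weight
regime the Glu term cancels from the DA fixed point, so it only sets the
GABA baseline level. The in-vitro drives are **not** free: they are the
outputs of the two calibration bisections — ν_ACh such that 1 µM nicotine
yields a 300 % peak increase of the GABAergic input to DA cells (slice IPSC
protocol, Glu blocked), and ν_Glu such that the same dose yields a 325 %
peak increase of the glutamatergic input (slice EPSC protocol, GABA
blocked). "A 300 % increase" is read as Δ/baseline = 3. The committed
values are regenerated by `vtanic calibrate` and re-verified by the tests;
because the α7 open-fraction excursion is independent of ν_Glu, the EPSC
calibration also has a closed-form inverse through the OR gate, used as a
cross-check.

## Metrics

All metrics are computed on traces normalized to the analytic baseline:
peak relative change, its time, the signed net-change integral, the width
of the elevation between its two half-maximum crossings (linearly
interpolated), and the deepest post-washout undershoot. The net-change
integral runs from application onset to the end of the record rather than
stopping when the trace re-enters a tolerance band around baseline: near
the direct-stimulation sign-change threshold the whole response is of the
same order as any reasonable band, and a band-truncated tail would bias the
bisection; with the 6·τ_max horizon the missing tail is < 1 % of the
response area. The critical-ACh bisection brackets [0.05, 2.0] µM and stops
at 0.005 µM; the net DA change is strictly decreasing in ν_ACh across the
bracket, so the root is unique.

## Numerics

The two-gate/circuit system is stiff (5 ms activation vs. 10 min recovery),
so all state updates are exact exponential relaxations toward the
(piecewise-constant) target of each step — unconditionally stable for any
step size. Default dt = 10 ms with the activation gate in quasi-steady
state (its 5 ms time constant is below the step); receptor-only pulse
protocols that resolve the activation transient use dt = 0.1 ms with full
activation dynamics. The trajectory integrator is vectorized: receptor
drives depend only on the prescribed nicotine trace, and both populations
are feedforward in the rates, so the scans reduce to linear recurrences
(one `lfilter` per population); a unit test pins it to the scalar
single-step implementation at machine precision. Rates stay non-negative by
construction (each step is a convex combination of non-negative values).
Half-maximum searches use geometric bisection to 1e-4 relative accuracy
after monotonicity and saturation checks; dose–response asymptotes are
probed at 1e5 µM, bounding the EC50 bias at ~0.04 %. CSV output is written
at 10 significant digits so identical protocols produce byte-identical
files.

Problem sizes: protocol runs integrate 2–4×10⁵ steps (tens of minutes of
model time at 10 ms); pulse protocols 2×10³ steps; the bisections evaluate
10–40 protocol runs. These sizes make every shipped result reproducible in
seconds on one core.

## Katz–Thesleff oracle

The 4-state cycle (R ↔ AR* ↔ AD ↔ D ↔ R, with AR* the only open state and
binding first-order in agonist) is integrated by per-segment matrix
exponentials, conserving probability to 1e-10. Its eight rate constants are
not independently known; they are produced by a bundled least-squares fit
(log-rate space, starting values derived from the two-gate time constants)
to the two-gate α7 open-fraction trace for a 1 s, 100 µM agonist pulse, and
committed with the fit-time deviations. In this bath regime the agonist
both activates and desensitizes (equivalently η = 1 fed through the ACh
channel). Because the cycle binds first order while the two-gate model has
Hill exponent ~2, test concentrations are mapped through
c_KT = ref·(c/ref)², with ref = 100 µM; the Hill exponent is an argument of
the mapping rather than hard-coded, since the subtype's activation exponent
(1.73) and desensitization exponent (2) differ. Agreement is ~2×10⁻⁵ at
the fit concentration and degrades toward the range ends (0.45 at the
highest dose), where a single first-order cycle cannot reproduce the
Hill-shaped activation transient; the committed per-concentration
deviations are the tolerances the cross-validation tests enforce.

## What the synthetic protocols do and do not show

All inputs are generated by the package itself (there is no external data
path): constant mean-field afferent drives, a deterministic pharmacokinetic
lag, and noiseless population rates. Passing tests therefore demonstrate
the internal consistency of the mechanism — which receptor/circuit
configurations can produce which DA response shapes, and what each scenario
predicts for timing and ACh-dependence. They do not capture bursting vs.
tonic firing of DA cells, synaptic plasticity, α6-containing receptors
(absorbed into the constant background current), extrinsic GABA sources,
trial-to-trial variability, or VTA spatial heterogeneity — so quantitative
agreement with in-vivo firing magnitudes is out of scope by design, and the
in-vivo comparisons are confined to normalized response shapes and timing.

## Known limitations

* The threshold-linear transfer makes the circuit piecewise-linear; strong
  inhibition or weak pacemaker currents can clip rates at zero, where the
  (2r − 1) structure and the r-invariance of the ACh threshold no longer
  hold. The shipped presets stay in the unclipped regime.
* Activation and desensitization use single Hill functions with a shared
  maximal response for ACh and nicotine; known two-component α4β2
  dose-response structure is deliberately collapsed.
* The quasi-steady-state activation default misses sub-10-ms transients;
  use the full-dynamics mode (dt ≤ 0.1 ms) when pulse peaks matter.
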