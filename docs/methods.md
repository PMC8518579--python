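# Methods

`cdisorb` predicts the electrosorption of weak polyprotic organic acids in
flow-by capacitive deionization (CDI) cells.  The model chain has three
layers — acid speciation, potential-free adsorption, and double-layer
charging — plus the corrections needed for real constant-current
operation.  This note records the model, its assumptions, the numerical
choices, and what the synthetic-data machinery does and does not show.

## Speciation and conductivity

A diprotic acid H₂A dissociates in two steps with pKa₁ < pKa₂ (maleic
acid: 1.92 and 6.23, M = 116.07 g/mol).  Given total concentration and
pH, the species fractions follow the Henderson–Hasselbalch closed form;
Na⁺ (the only counter-cation, from NaOH pH adjustment) comes from
electroneutrality, and the ionic strength from the full composition.

Two modes exist everywhere:

* **ideal** (default for isotherm and Donnan predictions):
  concentration-based equilibrium constants, pH read as −log₁₀ c_H.
* **activity_corrected**: Davies activity coefficients
  (log γ = −A z² (√I/(1+√I) − 0.3 I), A = 0.509 at 25 °C) shift the
  concentration-based pKa values; pH is read as H⁺ activity; the
  ionic-strength → γ → speciation loop is iterated to a fixed point
  (tolerance 1e−10 mol/L on I, cap 100 iterations — convergence is
  geometric and takes < 10 iterations in practice).

Conductivity is the sum of per-species contributions κ = Σ λᵢ cᵢ with
limiting molar conductivities λ° (S·cm²/mol): Na⁺ 50.1, H⁺ 349.8, OH⁻
198.0 from standard tables, and hydrogen-maleate 41 / maleate 120 as
documented estimates by analogy with similar dicarboxylates (both
config-overridable).  In activity-corrected mode each λᵢ is scaled by
the Davies γ of its charge — a pragmatic ionic-strength correction that
reproduces the ~30% conductivity suppression observed at tens of
millimolar; a rigorous Onsager-type treatment is out of scope.  The
constant-current chain uses the corrected conductivity by default (it
yields κ ≈ 0.15 S/m for the 10 mM pH-8 feed, the value consistent with
the electrolyte voltage-drop arithmetic), while speciation for the
isotherm stays ideal.

Inversion — recovering c_total from a measured (κ, pH) pair — is a
bracketed `brentq` root search on the forward model over c_total ∈
[0, 1 M]; the round trip is exact to < 0.1% across pH 3–10 and
0.5–60 mM.  Conductivities below the H⁺/OH⁻ floor at the given pH are
rejected.

Temperature is fixed at 298.15 K throughout; no temperature-dependent
equilibrium constants, no ion pairing, no carbonate chemistry (feeds are
assumed N₂-degassed).

## Potential-free adsorption: the cooperative Moreau isotherm

Organic acids adsorb onto activated carbon without any applied voltage.
That potential-free loading (PFL) is the coion reservoir that later
degrades charge efficiency, so modelling it well is the heart of the
framework.  The two charged species A = HA⁻ and B = A²⁻ adsorb
competitively and cooperatively following the two-species Moreau
isotherm (fractional loading of A):

    q_A/q_max = [2K_Ac_A + 2c_A²K_A²e^(−βU_AA) + 2c_AK_Ac_BK_Be^(−βU_AB)] / D
    D = 1 + 2c_AK_A + c_A²K_A²e^(−βU_AA) + 2c_BK_B + c_B²K_B²e^(−βU_BB)
        + 2c_AK_Ac_BK_Be^(−βU_AB)

with q_B symmetric.  β = 1/(RT) with the interaction energies U in
kJ/mol (they are tabulated as molar energies; positive U = repulsion
between adsorbed molecules).  The neutral H₂A is excluded — it is
practically absent above pH 4 and carries no charge.

Two structural features deserve note.  First, the single-species limit
saturates at **2·q_max**, a direct consequence of the doubled linear and
quadratic numerator coefficients; the expression is implemented exactly
as stated.  Second, PFL = |z_A| q_A + |z_B| q_B = q_A + 2 q_B converts
the molar loadings into the equivalent loading (meq/g) that enters the
charge-efficiency expressions; loadings are per gram of electrode pair,
the basis on which batch experiments measure them.

Reference parameters for maleic acid on the studied electrodes:
K_A = 23.4 L/mol, K_B = 5.3 L/mol, q_max = 1.23 mmol/g, U_AA = −0.36,
U_AB = 29.9, U_BB = 3.04 kJ/mol.  The monovalent species binds ~4×
stronger than the divalent one, which is why the PFL collapses across
pKa₂ — the step that drives every pH trend downstream.

## Batch bookkeeping and the genetic algorithm

Equilibrium loadings come from a sequential-spike batch experiment run
in the CDI cell itself (50 mL recirculated; per cycle, 4 mL replaced by
200 mM stock, i.e. +16 mM per spike).  Loadings are reconstructed by
cumulative mass balance; negative increments (desorption on dilution)
are legal.

The six isotherm parameters are estimated by a steady-state genetic
algorithm with the fitness R² = 1 − SS_res/SS_tot between predicted and
observed *total* loadings:

* population 10; the single best set survives unchanged (elitism);
* the other nine are recombinations of two distinct parents drawn from
  the best five: per gene, with probability ½ the child takes one
  parent's value unchanged, otherwise a draw from the BLX-0.5 blend
  interval [min − ½·span, max + ½·span], clipped to bounds.  The blend
  component matters: a pure value-exchange recombination can never
  create new gene values between the initial random draws, and a
  10-member population then cannot refine continuous parameters;
* each gene of a child mutates with probability 0.2 into a uniform draw
  over its full bound range (K ∈ [0, 10⁵] L/mol, q_max ∈ [0, 2.5]
  mmol/g, U ∈ [−30, 30] kJ/mol) — preserving global reachability;
* restarts run on independent child streams spawned from one master
  seed (`numpy.random.SeedSequence`), so a `FitResult` is
  bit-reproducible and reports per-restart values plus mean ± SD.

The default budget is 20,000 iterations × 10 restarts (≈30 s on one
CPU core), which the parameter-recovery experiments use throughout; the
full study-scale budget (200,000 × 100) is a config choice away.

**Identifiability.**  On 36-point data at 2% noise, K_A, K_B and q_max
are recovered to within ~5–10% (restart mean); across noise
realisations the estimator itself scatters up to ~15% on q_max — that is
sampling error at n = 36, not optimizer failure (best R² ≥ 0.998
always).  U_AB is unidentified above ~15 kJ/mol: any strong cross
repulsion suppresses the mixed term equally well.  A flat ridge trading
K against q_max (lower K_A, higher q_max) lies ~3·SS_res above the
optimum; at reduced budgets individual restarts can stall there.

## The modified-Donnan charge-efficiency chain

Micropore and macropore concentrations are linked by one dimensionless
Donnan potential (plus an optional chemical-attraction term μ_att):
c_mi = c_ma·exp(−z φ_D + μ_att).  For a symmetric cell the micropore
charge density obeys Δc_mi = 2 c0_mi sinh(φ_D), and the charge
efficiency — equivalents captured per unit charge — is Λ = tanh(φ_D/2).
Eliminating φ_D gives the explicit closed form

    Λ = tanh(½ · arcsinh(Σ / PFL_eff)),    Σ = Δφ_cell·C_g/(4F)

where the micropore salt reservoir v_m·c0_mi has been replaced by the
charge-weighted potential-free loading.  Because the Moreau PFL
saturates with concentration, this construction avoids the runaway
loadings a constant μ_att produces at high feed concentration; μ_att is
retained for micropore pedagogy (pH-shift estimates) but plays no role
in Λ.

**Mass-basis convention.**  PFL is measured per gram of electrode pair,
but the coion reservoir opposing one electrode's charge is that
electrode's share: PFL_eff = PFL/2.  This single-electrode convention —
exposed as a config switch — simultaneously reproduces the worked
efficiency pair 42%/63% (pH 4/8, 5 mM, 1.2 V), the Donnan potential 0.97
of the constant-current experiment, and the ~13 min coion lag; the
pair-mass alternative misses all three.

The specific capacitance C_g = 45 F/g is treated as constant in voltage
and electrolyte — a deliberate first-order simplification; the ¼ in Σ
reflects two equal series capacitances and the pair-mass basis.

## Constant-current operation and non-idealities

Constant-current mode adds three effects, applied in sequence:

1. **Voltage drops**: Δφ_eff = Δφ_pot − R_setup·I − (k_cell/κ)·I², with
   R_setup = 0.9 Ω and k_cell = 6 (A·m)⁻¹ for the studied cell.  The
   quadratic current term follows from the cell constant's units.  κ is
   the feed conductivity held constant over the step — a conservative
   choice (depletion lowers κ further); a user-supplied κ overrides it.
2. **Parasitic (Tafel) currents**: I_redox = a·exp((Δφ_cell − Δφ_crit)/b)
   above the onset Δφ_crit = 1 V, clamped to zero below.  The charge lost,
   Q_redox, is the trapezoidal time integral of I_redox along the linear
   charging ramp Δφ_cell(t) = drops + 4·I·t/(m_pair·C_g), ≥ 200 steps
   (400 by default).  Λ_corr = Λ·(1 − Q_redox/Σ_total).  The defaults
   a = 1 mA, b = 0.12 V are placeholders — the cell-specific values
   require a dedicated leakage measurement — and `calibrate_tafel`
   rescales `a` (the integral is linear in it) to hit a measured
   parasitic-charge fraction.  Traversing the same terminal-voltage
   window at doubled current halves Q_redox and lowers the parasitic
   fraction; note that raising the threshold (1.3 → 1.4 V) can offset
   this, since the Tafel exponential grows faster than the ramp.
3. **Coion-expulsion lag**: before net capture appears in the effluent,
   the supplied charge must expel the preloaded coions:
   t_E = PFL_eff·m_pair·F/I (equivalently PFL × one electrode mass × F/I).
   At 10 mM, pH 8.5, 50 mA this is ≈ 12.8 min.

Capacity follows as SAC_eq = Λ_corr·Σ (eq/g of pair) and in molar terms
SAC_mol = SAC_eq/z̄ with the mean charge z̄ = α + 2(1−α), α the
monovalent fraction of dissolved charged acid.  As I → 0 the chain
degenerates continuously to the equilibrium constant-voltage
prediction.

The micropore–bulk pH shift implied by a common Donnan potential is
ΔpH = φ_D·log₁₀e (≈ 0.42 at φ_D = 0.97); an upper bound from the maximal
micropore ion concentration is log₁₀(c_mi,max/c_feed).

**Energy cost.**  The operating-cost estimator charges rate·z̄·F/Λ per
unit product and prices the electrical energy at the capacitor-average
voltage ½·Δφ_max — an order-of-magnitude model (≈1.2 €/h, 0.014 €/mol at
fermenter scale with Λ = 25%) that ignores pumping, recuperation and
capital cost.

## Effluent-trace analysis and synthesis

Analysis mirrors experimental practice: per sample, (κ, pH) is inverted
through the speciation model to c_total (failures are flagged, not
fatal); cycles are delimited by the applied-current program; SAC is the
trapezoidal integral of V̇·(c₀ − c_out)/m_E over the depletion dip; the
charge efficiency is Λ = F·SAC·z̄·m_E/∫I dt·100% with z̄ from the
flow-weighted mean α over the adsorption window.  The first cycles are
dropped and later ones averaged (default: skip 2, average 4) to work in
cyclic steady state.  The depletion dip is integrated to its end — the
first return to feed level — which can lie inside the zero-current
phase: the cell's inner volume (10.8 mL, residence time ≈ 5.4 min at
2 mL/min) washes captured-phase depletion out after the current stops.

The trace synthesizer is the forward counterpart used for testing: a
lag phase of duration t_E at feed level, a depletion dip with a fast
capture rise and a washout tail (time constant V_cell/flow) sized so the
integrated SAC matches the prediction, a short feed-level gap, then a
desorption overshoot releasing the same amount — enforcing full-cycle
mass conservation in cyclic steady state.  Conductivity and pH come from
the forward speciation model (with a small re-equilibration pH dip);
optional Gaussian sensor noise applies to conductivity.  What it does
*not* emulate: axial dispersion beyond single-CSTR washout, probe
drift, electrode ageing, temperature excursions, and the pronounced
desorption pH spike of real cells.  Closure tests (analysis recovers the
synthesized SAC to < 1% at zero noise, < 5% at 2% noise) therefore
validate the bookkeeping and inversion machinery, not transient
transport physics — which the quasi-static framework deliberately omits.

## Problem sizes and determinism

Parameter-recovery runs use the 36-point design (6 pH × 6 linearly
spaced concentrations, 1–60 mM — the spike protocol's arithmetic ladder)
at 2% multiplicative noise, 20,000 GA iterations × 10 restarts; trace
closure runs use 3–5 cycles at 5–10 s sampling.  Every stochastic path
(noise generation, GA streams, sensor noise) descends from one integer
seed via `SeedSequence`, so all results in the README and the
reproduction table are bit-reproducible.

## Known limitations

* The Davies λ°·γ conductivity correction and the maleate λ° estimates
  are documented approximations, adequate at ≤ 0.1 M ionic strength.
* Tafel a, b defaults are placeholders pending a leakage measurement.
* The constant-κ assumption overestimates voltage drops least at low
  depletion; strongly depleted runs need a measured κ profile.
* Quasi-static only: no time-resolved effluent prediction, no spatial
  electrode resolution, no membrane (MCDI) variant.
* Experimental capacities of a physical cell (e.g. ~40 mmol/kg at pH 8,
  1.3 V) reflect surface chemistry the model does not carry; the model's
  role is magnitude-and-trend prediction from independently measured
  parameters, and its orderings (pH, current, voltage) are the tested
  claims.
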