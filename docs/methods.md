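# Methods

## Conjugation reaction model

The package models a site-specific DAR-2 conjugation: a maleimide payload
(D) reacts with engineered cysteines on an antibody. Antibody molecules are
partitioned by how many conjugation-competent ("activated") cysteines they
carry — p₂, p₁, p₀ with p₂+p₁+p₀ = 1 — giving seven chemical species: A2,
A1, A0 (unconjugated antibody with 2/1/0 activated sites), M1a (mono-
conjugate that can still react), M1b (terminal mono-conjugate from A1), M2
(bi-conjugate) and D, plus a bookkeeping accumulator D_inact for payload
lost to the first-order sink. Mass-action kinetics:

    dA2/dt  = −k1·A2·D        dM1a/dt = k1·A2·D − k2·M1a·D
    dA1/dt  = −k1·A1·D        dM1b/dt = k1·A1·D
    dA0/dt  = 0               dM2/dt  = k2·M1a·D
    dD/dt   = −k1·(A2+A1)·D − k2·M1a·D − k3·D + S_feed(t)
    dDinact/dt = k3·D

Assumptions: isothermal, constant volume and density (the payload stock is
~1.7% v/v of the vessel and its volume is neglected), zero backward rates.
The single-activated species A1 reacts with the same constant k1 as A2 —
the payload–cysteine chemistry is identical and no separate constant is
available — and pre-inactivated cysteines consume no payload. With p₂ = 1
the system collapses exactly onto the plain three-reaction scheme
(mAb → mono → bi), which the test suite verifies against an independently
coded four-species oracle.

Defaults (calibrated small-scale values for the DAR-2 system):
k1 = 0.797 mM⁻¹s⁻¹, k2 = 1.476 mM⁻¹s⁻¹, k3 = 0.00155 s⁻¹; activation
distribution (0.8859, 0.0860, 0.0281), which caps the DAR at
2p₂ + p₁ = 1.8578; antibody molar mass 150 kDa (configurable), so 5 mg/mL
= 0.0333 mM. The units of k1/k2 are read as per-mM-per-s, the only
dimensionally consistent interpretation of a bimolecular mass-action rate.

The feed is either batch-instant (full dose at t = 0) or constant-rate
(total/duration for t ≤ duration). Payload amounts are vessel-basis
concentrations; the stock concentration (default 10 mM) only enters the
volume-fraction bookkeeping.

## Ideal-mixed (0D) simulation

`simulate_0d` integrates the ODEs with LSODA at rtol 1e-8 / atol 1e-10,
splitting the horizon at the feed discontinuity so the solver never steps
across it. Output values within −1e-9 mM are clipped to zero; anything more
negative raises. Two conservation diagnostics are carried on every
trajectory: total antibody drift and the payload balance
D + D_inact + mono + 2·bi versus cumulatively fed payload, both ≤ 1e-6
relative by construction (observed ≈ 1e-15).

## Compartment-network surrogate

The spatially resolved reactor is a network of well-mixed zones on a
levels × rings grid (default 4 × 3 = 12 compartments, equal volumes;
supported 8–48) exchanging liquid through constant ("frozen") flows
Q[i→j]. Transport of every dissolved species obeys
dcᵢ/dt = (Σⱼ Q[j→i]cⱼ − cᵢ Σⱼ Q[i→j]) / Vᵢ; per-compartment outflow equals
inflow, so total volume and mass are conserved identically. Three
archetypes encode the qualitative flow structures of the studied vessels:

* **GST-1** (300 mL, anchor stirrer): uniform symmetric exchange — fast,
  near-homogeneous bulk.
* **GST-2** (22 L, centric pitched-blade): strong in-level (rotational)
  exchange, weak axial exchange (ratio 0.15) with an additional ×0.3
  bottleneck at the lowest interface — slow final homogenization.
* **SUM** (25 L, eccentric bottom-mounted impeller): moderate symmetric
  base (axial ratio 0.3) plus a directed circulation loop up the outer side
  and down the core; a closed cycle, hence balance-preserving.

The topology is a heuristic emulation, not a flow-field computation.
Quantitative fidelity comes solely from calibration: because frozen-flow
transport is linear, scaling every flow by α scales the mixing time by
exactly 1/α, so `calibrate_exchange` measures the base network's global 95%
mixing time once and applies a single exact factor to hit the target
(anchors: 9.4 s GST-1, 32.2 s GST-2, 17.6 s SUM). The stirrer-speed analog
in the parameter study rescales flows proportionally to speed — an
emulation of mixing time ∝ 1/N, not a turbulence claim. CFD-derived flow
maps can replace the templates through the JSON flow-map format.

Payload enters the feed compartment only (default: top level, outer ring,
i.e. sub-surface addition near the wall): batch mode as a concentration
spike scaled by V_total/V_feed, constant-rate mode as a local source term.
Tracer transport (being linear) is propagated exactly with the matrix
exponential on a uniform grid; the reacting network uses BDF with an
explicit Jacobian sparsity pattern (8×8 chemistry blocks plus same-species
exchange coupling) at rtol 1e-8 / atol 1e-12. In the fast-exchange limit
(flows ×1e6) the volume-averaged network trajectory matches the 0D model to
<0.01% — the limit check in the test suite uses atol 1e-10 there, since
atol 1e-12 on µs-scale transport modes makes the stiff integration
needlessly slow.

One surrogate-specific effect is worth knowing: in the first seconds of a
feed the network's volume-averaged DAR can slightly *exceed* the 0D value,
because mono-conjugate and payload are co-located in the feed zone and the
second conjugation step is bimolecular. The mass-transfer-limitation lag
that dominates ΔDAR develops over the addition window and the curves
converge after the feed, with max ΔDAR ordered GST-2 > SUM > GST-1 at the
calibrated anchors.

## Mixing metrics

M_global(t) = 1 − (1/V) Σᵢ Vᵢ (cᵢ/c∞ − 1)², implemented exactly as a
squared deviation (no square root), so values near the injection are
strongly negative early on. Mixing times use the last-crossing convention
(earliest time after which the criterion holds permanently) with linear
interpolation between samples — robust to transient re-crossings. Probe
mixing times treat "95% criterion" as a two-sided ±5% band around the final
value (±1% for 99%); the sensor dead time is a pure delay subtracted before
evaluation. The relative validation error is 100·|exp − sim|/exp.

## Scale-up analysis

P/V = 2π(N/60)·M/V and Re = ρ(N/60)D²/μ with the conjugation-medium fluid
defaults ρ = 1010.5 kg/m³, μ = 0.00106 Pa·s; both are strictly linear in
speed/torque, and `scale_reynolds` exploits the linearity to move a
measured anchor to another speed. The reaction time-scale is
τ_R = 1/(k(c̃₁+c̃₂)); `classify_regime` declares the process
mixing-sensitive when τ_R ≤ margin·τ_mix with margin 1 by default (the
boundary is assigned conservatively to mixing-sensitive, since the
literature states only "significantly larger" without a number).
ΔDAR(t) = |DAR_0D − DAR_network| is computed on the 0D grid (linear
interpolation of the network DAR); its convergence time is the first time
at/after feed end from which ΔDAR stays below 0.005 (~0.25% of the target
DAR 2; configurable). The parameter study is strictly one-factor-at-a-time
around the standard condition (60 rpm, 60 s feed, 5 mg/mL, 5× excess) with
a horizon of max(900 s, feed + 600 s); because the chemistry is a selective
consecutive reaction, the final DAR is invariant (≤1e-3) across all rows.

## Parameter estimation

`fit_rate_constants` minimizes weighted residuals between the 0D model and
observed species series (unconjugated, mono, bi — what a quenched
chromatographic assay reports) with scipy `least_squares`, parameters
bounded at zero. Weights are 1/max(obs) per species, floored at 5% of the
overall data scale so an identically-zero species cannot dominate the
objective. Five log-spaced restarts (1/10× to 10× the guess, fixed order)
guard against local minima while keeping the result deterministic.
Confidence intervals come from the linearized residual covariance
s²(JᵀJ)⁻¹. Estimates pinned at the zero bound are flagged (`at_bound`), and
structurally flat Jacobian columns are reported as `unidentifiable` rather
than silently fitted. In practice k3 is weakly identified from
species-fraction data (it acts only through slight payload depletion late
in the rise) and collapses to the bound under 2% noise, with a
correspondingly wide interval; k1 and k2 are recovered with ~2% median
bias there and all three constants to <0.1% from noise-free data.

The activation distribution is recovered from the end state: at completion
every activated site has reacted, so the final unconjugated/mono/bi
fractions equal (p₀, p₁, p₂) directly. R² is computed jointly over all
observed species, 1 − SS_res/SS_tot.

## Synthetic data

The kinetic generator samples the 0D ground truth at the nominal timepoints
(quenching is treated as instantaneous and perfect) and applies
multiplicative Gaussian noise, value·(1 + σε), truncated at zero — the
error structure of chromatographic peak-area ratios — with σ = 2% by
default; sampling spans the 60–120 s rise phase densely plus sparser points
out to one hour. The tracer generator returns the probe compartment's
concentration, delayed by the dead time and perturbed with additive noise
scaled to c∞. Both are reproducible from an integer seed. What the
generators do *not* emulate: chromatogram deconvolution errors, quench
kinetics, baseline drift or sensor dynamics beyond a pure delay — so
passing recovery tests show identifiability under the stated noise model,
not robustness to real assay artefacts.

## Problem sizes and runtimes

Default analyses use 12-compartment networks, 300–900 s horizons at 0.1–0.5 s
reporting resolution, and 10-seed recovery studies with 3 restarts each;
the full test suite runs in well under a minute on one core. Larger
networks (to 48 compartments), finer grids and more restarts are supported
and covered by tests.

## Known limitations

No flow–reaction feedback (frozen flows), no inter-compartment diffusion
(convective exchange dominates at this granularity), no turbulence or
torque prediction, no shear/aggregation or DAR-8 stochastic-conjugation
chemistry, no temperature dependence. The quantitative ΔDAR maxima of a
CFD-resolved vessel are not reproducible by the surrogate; only their
ordering and magnitude class across vessels and process parameters are
claimed, anchored by the calibrated mixing times.
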