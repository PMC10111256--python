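# adcscale

Kinetic and mixing analysis of antibody–drug-conjugate (ADC) conjugation
reactions during process scale-up.

ADC manufacturing adds a maleimide-functionalized cytotoxic payload to a
solution of functionalized antibodies in a stirred vessel. Whether a
conjugation process transfers cleanly from a reaction tube to a 50 L reactor
depends on the race between two time-scales: the bimolecular conjugation
kinetics and the vessel's mixing time. `adcscale` provides the pieces a
process engineer needs to examine that race *in silico*:

* **0D fed-batch kinetic model** — a site-specific DAR-2 conjugation network
  with two consecutive bimolecular steps and a parallel first-order payload
  sink,

  ```
  mAb + D  --k1-->  mAb·D          (k1 = 0.797 mM⁻¹ s⁻¹)
  mAb·D + D --k2--> mAb·D₂         (k2 = 1.476 mM⁻¹ s⁻¹)
  D --k3--> D_inactive             (k3 = 0.00155 s⁻¹)
  ```

  extended to seven ODEs by an activation distribution (p₂, p₁, p₀) — the
  fractions of antibody carrying two, one or zero conjugation-competent
  cysteines — and driven by an instantaneous (batch) or constant-rate
  payload feed. The drug-to-antibody ratio is
  DAR(t) = (c_mono + 2 c_bi) / c_mAb,0.
* **Compartment-network reactor surrogate** — a network-of-zones model with
  frozen convective exchange flows emulating three vessel archetypes (small
  anchor-stirred glass tank GST-1, large pitched-blade glass tank GST-2,
  eccentric single-use mixer SUM), calibrated exactly to a target global 95%
  mixing time via the linear flow-scaling law.
* **Mixing metrics** — the variance-based global homogenization index
  M_global(t) = 1 − (1/V) Σᵢ Vᵢ (cᵢ/c∞ − 1)², criterion-based mixing times
  (95%/99%, last-crossing convention) and mixing-time extraction from
  external conductivity probe traces with dead-time correction.
* **Scale-up analysis** — P/V = 2πNM/V, impeller Reynolds number ρND²/μ,
  the reaction time-scale τ_R = 1/(k(c̃₁+c̃₂)) versus mixing time, and the
  ΔDAR(t) = |DAR_0D − DAR_network| deviation with a one-factor-at-a-time
  process-parameter study (stirrer speed, feed duration, antibody
  concentration).
* **Calibration & synthetic data** — weighted nonlinear least-squares
  estimation of (k1, k2, k3) from species time courses, activation
  distribution recovery from end-state ratios, and seeded generators for
  noisy chromatographic-style datasets and probe traces.

## Worked example

```python
import adcscale as a

params = a.KineticParameters()                  # calibrated rate constants
dist   = a.ActivationDistribution()             # (0.8859, 0.0860, 0.0281)
c0     = a.molar_from_mass(5.0, 150000.0)       # 5 mg/mL antibody -> mM
feed   = a.FeedSchedule("constant-rate", 60.0, 5 * c0, 10.0)  # 5x excess / 60 s

traj = a.simulate_0d(a.initial_state(c0, dist), params, feed, 300.0, 0.1)
tpl  = a.vessel_template("GST-2")
net  = a.calibrate_exchange(a.build_template(tpl), tpl.target_global_mixing_time)
avg  = a.simulate_reaction_network(net, params, a.initial_state(c0, dist),
                                   feed, 300.0, 0.5).volume_averaged()
res  = a.delta_dar(traj, avg, feed_end=60.0)
```

prints (via the obvious `print` calls):

```
initial mAb:        0.0333 mM
payload dose:       0.1667 mM (1.67% v/v)
final DAR (300 s):  1.8578
99% completion at:  84.3 s
GST-2 mixing time:  32.2 s
max ΔDAR:           0.114 at t = 53 s
ΔDAR < 0.005 after 113 s
tau_R = 6.27 s vs tau_mix = 32.2 s -> mixing-sensitive
```

Reading: at the standard condition the reaction consumes >99% of the
activated antibody in 84 s and plateaus at DAR 1.8578 = 2p₂ + p₁ (the
ceiling set by the activation distribution). In the slow-mixing GST-2 the
spatially resolved model briefly deviates from the ideal-mixed prediction
while payload is being added (max ΔDAR ≈ 0.11 near the end of the 60 s
feed) and converges back within ~2 minutes — the deviation is transient and
the reaction endpoint is unchanged. The time-scale comparison (τ_R ≈ 6 s
against a 32 s mixing time) flags the same conclusion without running the
spatial model.

The same pipeline is scriptable from a shell:

```bash
adcscale simulate --config config.yaml --out run/
adcscale compare  --config config.yaml --out run/   # ΔDAR across GST-1/GST-2/SUM
adcscale metrics  --config config.yaml --out run/   # Re, P/V, tau_R, regime
adcscale generate --config config.yaml --out run/ --seed 7
adcscale fit      --config config.yaml --data run/kinetic_dataset.csv --out run/
```

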