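# stmrf

Cramér–Rao-bound-guided design of pulsed **saturation-transfer MR
fingerprinting** (ST MRF) acquisition schedules, with a Bloch–McConnell
signal simulator, dictionary matching, and a synthetic-phantom evaluation
harness.

## The problem

CEST and semisolid-MT imaging encode the proton volume fraction *f*ₛ and
the solute→water exchange rate *k*sw of exchanging proton pools into the
water signal. MR fingerprinting quantifies them by matching a measured
signal trajectory *s*[n] — one sample per acquired raw image — against a
dictionary of Bloch–McConnell-simulated trajectories. The encoding power
of the trajectory depends strongly on the acquisition schedule: the
per-image saturation powers B₁[n], frequency offsets Δω[n] and timing.
Because no closed-form signal model exists for clinical *pulsed*
saturation trains, this package optimizes the schedule numerically:

1. **Dictionary** — simulate *s*[n; θ] on a grid of θ = (*f*ₛ, *k*sw)
   with a matrix-exponential Bloch–McConnell propagator,
   M(t+Δt) = (M + A⁻¹C)·e^{AΔt} − A⁻¹C.
2. **Objective** — the trace of the normalized Cramér–Rao bound,
   nCRB(θ) = I(θ)⁻¹ scaled by θ, with the Fisher information
   I(θ) = (1/σ²) Σₙ (∂s[n]/∂θ)ᵀ(∂s[n]/∂θ) evaluated by two-point finite
   differences on the dictionary grid, averaged over the grid.
3. **Search** — sequential quadratic programming (SLSQP) inside a seeded
   basin-hopping loop over the box constraints of the scanner.

Quantification uses the standard normalized dot product
argmax ⟨e, d(θ)⟩ / (‖e‖·‖d(θ)‖) over the dictionary, and the evaluation
harness scores reconstructed maps with MAPE, range-normalized RMSE
(NRMSE), SSIM, Pearson r and a paired two-tailed t-test on digital
phantoms with known ground truth.

Intended users: MR physicists designing CEST/MT fingerprinting protocols
and anyone needing a compact, fully scriptable multi-pool
Bloch–McConnell simulator with an experiment-design loop on top.

## Worked example

Optimize a 4-image continuous-wave protocol (3 s saturation, 1 s
recovery, offset fixed at 3 ppm, B₁ ∈ [0, 6] µT) from a random start:

```sh
$ stmrf optimize --protocol cw7t_larg --n-images 4 --seed 0 \
      --grid-size 5 --n-hops 1 --out opt_schedule.yaml --trace trace.json
initial loss 720.608 -> best loss 293.548; wrote opt_schedule.yaml
```

The CRB trace loss of the random schedule (720.6) drops to 293.5 — the
expected relative estimation variance of (*f*ₛ, *k*sw) is more than
halved at identical scan time. Inspecting the result:

```python
>>> from stmrf import load_schedule, simulate_schedule, schedule_duration
>>> from stmrf.cli_config import get_template
>>> s = load_schedule("opt_schedule.yaml")
>>> s.b1_values.round(2)
array([6.  , 5.13, 1.17, 0.  ])
>>> schedule_duration(s)
16.0
>>> simulate_schedule(get_template("cw7t_larg").pool_system, s).values.round(4)
array([0.497 , 0.4935, 0.6381, 0.8114])
```

The optimizer spreads the powers across the available range and pins two
of them to the box bounds — high powers saturate strongly (signal ≈ 0.49
of the readout maximum), the B₁ = 0 image provides an unsaturated
anchor (0.81 = sin 60°·M_z after partial recovery). A 4-image schedule
lasts 16 s; the 30-image reference protocol of the same timing lasts
120 s, a 7.5-fold acceleration (3.75-fold for 8 images).

The same loop is available programmatically via
`stmrf.basin_hopping_optimize`, and `stmrf run --config cfg.yaml`
executes schedule search → dictionary → phantom acquisition → matching →
metrics in one call.

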