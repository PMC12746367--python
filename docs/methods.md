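# Methods

This note records the physical model, the numerical choices, and the
design decisions behind `stmrf`, in the spirit of a model-description
appendix.

## Signal model

Magnetization of a water pool plus exchanging solute/semisolid pools
evolves under the Bloch–McConnell equations, written as the linear ODE
dM/dt = A·M + C. The matrix A collects transverse/longitudinal
relaxation (1/T₂, 1/T₁), chemical-exchange coupling (rate k from solute
to water, back-rate f·k by detailed balance), off-resonance precession
(Δω of the RF relative to each pool's chemical shift, plus any
isochromat-specific ΔB₀), and RF nutation ω₁ = γB₁ about the x axis; C
carries the M₀/T₁ recovery drive. Within any segment of
piecewise-constant RF the propagation is exact:

    M(t+Δt) = (M + A⁻¹C)·e^{AΔt} − A⁻¹C.

The matrix exponential is `scipy.linalg.expm`; correctness is defined by
the step-splitting invariant (one Δt step equals two Δt/2 steps to
1e-10 relative), not by the algorithm's identity. Within a pulsed
saturation event, the pulse step and the gap step are each exponentiated
once and reused across all train cycles, which makes a 13-pulse
spin-lock train as cheap as three exponentials.

A saturation event is parameterized as `pulse_count` cycles of an RF-on
segment of `pulse_duration` followed by a gap of
`pulse_duration·(1−duty)/duty`, with any remaining time up to `t_sat`
RF-free; continuous wave is the degenerate single-pulse, unit-duty case.
The trailing gap is included inside `t_sat` — the edge convention is a
package choice and is configurable through the event fields.

### Readout

The 3D snapshot readout with centric reordering samples the k-space
center at the excitation instant, so the recorded signal is
s[n] = sin(FA)·|M_z^water| at that instant. By default the readout is a
pure snapshot: it does **not** consume longitudinal magnetization. This
keeps the exact identity that a schedule with all powers at zero yields
s[n] = sin(FA) for every image. A consuming model (M_z → M_z·cos FA for
every pool after the sample) is available via
`simulate_schedule(..., excitation_consumes_mz=True)`; with a 12°
readout the difference is at the percent level, at 60° it is
substantial. Water (and solute) transverse components are spoiled after
each readout by default (`spoil_transverse`), emulating crusher
gradients. Scan time is Σ(t_sat + t_rec) with the readout counted as
instantaneous, which reproduces the 4·(3+1) = 16 s arithmetic of the
continuous-wave protocols exactly; real pulsed protocols add an
unmodelled per-image readout duration.

### T2* and isochromats

Sub-voxel B₀ inhomogeneity is modelled by an ensemble of isochromats
whose ΔB₀ shifts follow a Cauchy–Lorentz distribution with HWHM
Γ = 1/T₂* − 1/T₂. The ensemble is deterministic: offsets sit on a
uniform grid at integer multiples of Γ spanning ±(n−1)Γ/2, each carrying
the exact Cauchy probability mass of its cell (arctan differences,
renormalized after truncation). Determinism matters because the CRB
objective must be smooth for finite-difference SQP gradients; random
draws would inject sampling noise into the loss. The summed free decay
tracks the exp(−t/T₂*) envelope to ≈2 % for t ≤ T₂* at n ≈ 101
isochromats. A plain equal-weight inverse-CDF quantile construction was
tried first and rejected: its unweighted tail isochromats oscillate
without cancelling and leave ≈8 % envelope error at the same n. The
degenerate `single_isochromat()` (no broadening) is the default for
optimization runs.

### Semisolid pools and lineshapes

Two representations are available. The default at 3 T is a full
Bloch–McConnell pool whose short T₂ yields a Lorentzian absorption
implicitly — the faster option, since it adds nothing beyond three state
components. Alternatively a pool may be declared `superlorentzian_rate`:
it then contributes a single M_z component saturated at
W = π·ω₁²·g(Δ), with g the powder-averaged super-Lorentzian lineshape
evaluated by 128-point Gauss–Legendre quadrature over the fiber
orientation angle. The |3cos²φ−1| pole makes g divergent on resonance,
so inside |Δ| < 2π·1.5 kHz the value is bridged by a cubic spline
through anchors at ±(1, 1.5, 2, 3)× the cutoff — the standard handling
of this singularity.

## The CRB objective

For Gaussian noise N(0, σ²) on each trajectory sample, the Fisher
information of θ = (fₛ, k_sw) is I(θ) = (1/σ²) Σₙ JₙᵀJₙ with
J = ∂s/∂θ taken as a two-point finite difference **on the dictionary
grid itself** (central differences at interior nodes, one-sided at the
boundary, step = grid spacing). The normalized CRB divides the inverse
Fisher matrix entries by θᵢθⱼ by default (dimensionless relative
variance), making fₛ ≈ 10⁻³ and k_sw ≈ 10³ s⁻¹ commensurate under equal
weights; dividing once by θ is selectable. The loss is the trace of the
normalized CRB averaged over interior grid nodes (grid-size invariant;
sum/max and boundary inclusion are options). σ defaults to 1 because it
rescales the loss uniformly (∝ σ²) and cannot change the optimizer's
ranking of schedules — verified as a test invariant.

**Which trajectory enters the derivative.** The matcher compares
L2-normalized trajectories, so the package differentiates s/‖s‖ by
default (`normalize_trajectories=True`). Differentiating the raw s[n]
additionally counts pure-amplitude differences that the scale-invariant
dot product discards; in end-to-end experiments an optimizer driven by
the raw-signal bound *worsened* map accuracy (mean k_sw MAPE 13.5 % →
23.1 %) while the normalized bound improved it in every seed (→ 7.8 %).
The raw reading remains selectable for comparison. Conditioning of the
2×2 Fisher matrix is assessed on the θ-scaled matrix D·I·D (D = diag θ),
which is scale-invariant; a node whose scaled condition number exceeds
`condition_cap` raises an explicit "unidentifiable" error carrying the
node coordinates.

## Schedule search

Powers (µT) and, where free, offsets (ppm) are rescaled to [0, 1] and
minimized by SLSQP with forward-difference gradients (step 1e-4 of the
range — deliberately above the objective's numerical noise floor; the
default 1.5e-8 step stalls on flat seeds). The outer basin-hopping loop
perturbs the accepted point uniformly within `hop_stepsize` (default
0.25) of each range, clips to the box, re-runs SLSQP, and applies
Metropolis acceptance at `temperature` (default 1.0 loss units). Every
candidate is recorded in a replayable trace; the best-ever point is
returned and can never be worse than the start because the initial point
participates. Candidates whose dictionary contains an unidentifiable
node receive a large finite penalty instead of aborting the line search.
Defaults: 20 hops, 4 independent restarts, `ftol` 1e-6, all randomness
from one seeded generator (bit-exact reproducibility under a fixed
seed). The hop loop is implemented in the package rather than through a
library wrapper so the trace, the clipping audit and the seeding are
fully under test.

## Quantification

Per-pixel matching maximizes the normalized dot product over all
dictionary rows; estimates take values only from the grid (no
interpolation), ties go to the lowest row-major index, and negative
scores are allowed (no absolute value). Zero-norm trajectories are
flagged unmatchable and left NaN. The vectorized implementation is
tested against a naive per-row loop.

## Synthetic phantoms and evaluation

The vial-grid phantom arranges circular vials of constant
(fₛ, k_sw) on a square grid, emulating concentration phantoms (tens to
hundreds of mM of a 3-labile-proton solute in buffer); the two-tissue
layout interleaves two block regions inside a disc as a crude
white/gray-matter stand-in. The solute fraction follows the harness
convention fₛ = 3·[c in M]/111 (3 guanidinium protons against the 111 M
water-proton pool); exchange-rate truths are user-specified —
pH-derived base catalysis is out of scope. Acquisition noise is i.i.d.
Gaussian on the magnitude signal, matching the likelihood the CRB
assumes, so design and evaluation share one statistical model; Rician
noise is not modelled. Each distinct truth pair is simulated once and
broadcast to its pixels before noise is added.

Metrics: MAPE per ROI (100·mean|est−true|/true), NRMSE = RMSE divided
by the reference range, SSIM (K₁ = 0.01, K₂ = 0.03, 7-pixel window,
data range = reference range; computed on the full rectangular maps with
background zeroed, since the windowed SSIM needs a rectangular domain),
Pearson r over masked pixels, and a paired two-tailed t-test with
`*`/`**`/`***` at p < 0.05/0.01/0.001. Identical metric lists return
(t = 0, p = 1) by convention; constant nonzero differences have no
variance and raise.

What the harness shows — and does not. Passing tests demonstrate that
the optimization loop improves parameter recovery *under its own noise
model and a simulator-matched dictionary*. Real acquisitions add B₀/B₁
inhomogeneity beyond the Cauchy ensemble, Rician noise at low SNR,
readout-train weighting, partial-volume effects and model mismatch in
the fixed relaxation parameters; none of these are emulated, so
synthetic MAPE values do not transfer to scanner data.

## Default parameters

Protocol templates (timing and bounds):

| template | saturation | t_rec | FA | B₁ box | offsets |
|---|---|---|---|---|---|
| `cw7t_larg` | CW, 3 s | 1 s | 60° | 0–6 µT | fixed 3 ppm |
| `pw3t_larg` | 13×100 ms, 50 % duty (2.6 s) | 1 s | 12° | 0–4 µT | fixed 3 ppm |
| `pw3t_mt` | 13×100 ms, 50 % duty (2.6 s) | 1 s | 12° | 0–4 µT | free 10–75 ppm |

Tissue defaults are package choices from typical phantom/brain
literature values, not measured constants, and are fully configurable:
buffer phantom water T₁/T₂ = 2.8/0.6 s with an amide-like solute at
3 ppm (T₁/T₂ = 2.8/0.04 s); brain water T₁/T₂ = 1.3/0.075 s with a
semisolid pool at −2.5 ppm (T₁/T₂ = 1.0 s/10 µs). Default grids: fₛ
spanning 10–250 mM equivalent (2.7e-4–6.8e-3) × k_sw 100–1200 s⁻¹ for
the solute case; f_ss 0.02–0.30 × k_ssw 5–100 s⁻¹ for semisolid MT,
15 points per axis (optimization subsamples to 5×5).

Problem sizes used by the shipped evaluation runs — 5×5 optimization
grid with a single isochromat, 15×15 matching dictionary, 32×32
phantom, 4-image schedules, 1–2 hops — were chosen so a full
random-vs-optimized comparison over several seeds completes in well
under a minute while leaving the qualitative behavior (bound-seeking,
power-spread increase, MAPE reduction) intact; all sizes scale up
through configuration.

## Known limitations

- Two quantified parameters only; the grid/Fisher interfaces are written
  for extension but nothing beyond (fₛ, k_sw) is implemented.
- No gradient through the propagator (no adjoint/autodiff); SQP uses
  finite differences on the loss.
- Shaped pulses are piecewise-constant rectangles; no Gaussian/sinc
  discretization, no diffusion, no transverse dynamics for rate-model
  semisolid pools.
- Scan time is fixed by the protocol template; it is not an optimization
  variable.
- No scanner export, B₀/B₁ mapping, denoising, or neural-network
  reconstruction.
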