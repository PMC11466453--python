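# Methods

`sensmem` models how the characteristic error structure of orientation
working memory — bias *away* from the cardinal orientations (0°/90°) that
grows during the memory delay, together with error variability that is
*smallest* at the cardinals — can arise from the interaction of an
efficient-coding sensory circuit with a ring-attractor memory circuit.
This note records the models, the numerical choices, and the places where
the design was genuinely open.

## 1. One-dimensional attractor models (`sensmem.attractor`)

The remembered orientation follows the Itô SDE
`dθ = μ(θ) dt + σ(θ) dW`, θ 180°-periodic, σ = √(2D).  Three presets span
the qualitative alternatives:

| preset | μ(θ) | σ(θ) | behaviour |
|---|---|---|---|
| `continuous` | 0 | 2° | flat potential, uniform SD |
| `discrete_constant` | sin 4θ | 2° | oblique attractors, SD *minimal* at obliques |
| `discrete_nonuniform` | sin 4θ | 2°(1 − cos 4θ) | oblique attractors, SD *maximal* at obliques |

Only the third reproduces both the repulsive bias and the cardinal
precision advantage: the oblique-peaked noise must overcome the
contraction of the flow at the attractors.  Integration is
Euler–Maruyama with `dt = 0.01` (time unitless), σ evaluated at the
pre-step state, orientations wrapped into [0°, 180°), errors wrapped to
(−90°, 90°].  Bias is the mean wrapped error and SD its linear standard
deviation.  One seeded generator drives the whole vectorized
(realization × initial-orientation) batch; per-realization streams were
rejected as prohibitively slow for 50 000-realization ensembles, so
draws are assigned by (step, realization) and determinism holds per
(seed, n_real).  The potential is U(θ) = −∫μ dθ (zero-mean, trapezoidal);
drift with nonzero circulation around the ring is rejected because no
single-valued potential exists.

## 2. Efficient-coding Bayesian observer (`sensmem.bayes`)

The prior over orientation is q(θ) ∝ 3 + cos 4θ (cardinals most common).
Efficient coding allocates Fisher information J(θ) ∝ q(θ)², implemented
by the cumulative-prior map F(θ) = 2π · CDF_q(θ) from stimulus space
[0, π) to a homogeneous sensory circle [0, 2π).  Encoding draws
m ~ vonMises(F(θ), κ_m) with κ_m = 250; decoding forms the posterior
∝ exp(κ_m cos(m − F(θ))) q(θ) on a 2048-point grid and takes its circular
mean under angle doubling (equivalent to the arithmetic mean for the
narrow posteriors that occur here, but well defined at the domain edges).
The memory stage adds plain Gaussian noise ξ ~ N(0, (1.3°)²) — legitimate
because 1.3° ≪ 180° — and feeds θ̂ + ξ back as the next iteration's
stimulus.

The sensory-space convention was open: the von Mises likelihood needs a
2π-periodic coordinate, and with range 2π the first-iteration sensory
estimates at a cardinal have circular SD ≈ 1.35° and the memory outputs
SD ≈ 1.87° at 10 000 samples (delta-method prediction: sensory SD
≈ (1/√κ_m)/F′(0) = 1.36°, memory SD ≈ √(1.3² + 1.3²) = 1.84°), so the
[0, 2π) convention is kept and the [0, π) fallback was never needed.

## 3. Firing-rate networks (`sensmem.network`)

Each module is a ring of N = 300 units with index angles
ψ_i = (i−1)/N · 180°.  Rates follow currents instantaneously through a
Naka–Rushton transfer f(x) = f_max (x−T)^q / (w^q + (x−T)^q) for x > T,
else 0 (sensory: f_max=100, T=0.1, q=2, w=6; memory: q=1.5, w=6.6);
synapses low-pass filter the rates with τ = 10 ms and carry the noise:

    r = f(W s + I_ext),   τ ds/dt = −s + r + ξ,
    ⟨ξ_i(t) ξ_j(t′)⟩ = r_i(t) δ_ij δ(t−t′).

The rate-proportional ("Poisson-like") noise is discretized as
`s += (dt/τ)(r − s) + (1/τ)√(r·dt)·η` with η ~ N(0,1), independent per
neuron, step, and synaptic population (`s_s, s_f, s_m, s_b` in the
coupled network — the sensory rate drives both s_s and s_f, the memory
rate both s_m and s_b, each with its own noise stream).  An
`additive_gaussian` mode replaces √(r·dt) with a constant `gauss_sd·√dt`.
Euler integration with dt = 1 ms (≤ τ/5 enforced); stochastic ensembles
run in float32 (noise dominates round-off), noise-free runs in float64
(so symmetry invariants hold to 1e−10).

**Ring geometry.**  Because orientation is 180°-periodic, the ring lives
on the angle-doubled circle: ψ maps to φ = 2ψ ∈ [0, 2π), kernel
distances are wrapped differences on that circle, a stimulus θ enters at
φ = 2θ, and every cos 4ψ modulation equals cos 2φ.  This convention was
forced, not chosen: with distances measured on [0, π) (wrapped at ±π/2)
the printed amplitudes/widths give the homogeneous memory kernel a
*positive* row sum (+0.22) — total local excitation then exceeds the
broadest possible inhibition, a recruitment wave saturates the whole
ring at ~81 Hz, and no persistent bump exists.  On the doubled circle
the row sums balance (memory +0.089, sensory −0.16): the isolated memory
module is bistable (low baseline vs ~44 Hz bump), the isolated sensory
module decays during the delay, and the coupled network shows persistent
tuned delay activity with low sensory rates — the qualitative behaviour
the architecture is built to produce.

**Connectivity** (all amplitudes scaled by 1/N_presynaptic):

* combined sensory kernel: −J_I,s + J_E,s (1 − α cos 4ψ_post)
  exp(−Δφ²/λ_E,s²) — excitation strongest at the *obliques*;
* segregated sensory kernels: −J_I,s (1 + β cos 4ψ_post) Gaussian(λ_I,s)
  + J_E,s (1 + α cos 4ψ_post) Gaussian(λ_E,s) — both strongest at the
  *cardinals*;
* memory kernel: difference of Gaussians (λ_E,m, λ_I,m), optionally with
  the same cardinal-enhancing modulations (one-module network);
* feedforward/feedback: nonnegative Gaussians with amplitudes J_f, J_b;
  γ = J_f·J_b is the effective loop gain.

Reference values: J_E,s=0.6, J_I,s=0.35, J_E,m=1, J_I,m=0.17, J_f=0.1,
J_b=0.25, λ_E,s=0.36π, λ_I,s=1.1π, λ_E,m=0.2π, λ_I,m=0.6π, λ_f=λ_b=0.17π.
The stimulus current to the sensory module is
C(1 − 2ε + 2ε exp(−Δφ²/λ_ext²)) with C=4, ε=0.2, λ_ext=0.3π, on for
0.5 s (5 s for tuning-curve estimation), zero afterwards.  The isolated
memory module receives (cos Δφ + 1)/2 + I_c,m during the stimulus.

**Background current I_c,m = 0.7.**  No value is printed anywhere for
this constant drive to the memory module; it is the one calibrated
parameter.  Delay-bump persistence requires I_c,m ≳ 0.6; at 0.7 the
no-stimulus state is a low (~8 Hz) untuned spontaneous baseline, clearly
bistable against the ~44 Hz bump, and both the isolated and the coupled
networks hold a tuned bump for ≥ 4 s.  A strictly quiescent no-stimulus
state (r ≈ 0) is incompatible with bump persistence under these kernels,
so the spontaneous-baseline regime was adopted; I_c,m is exposed on
`NetworkParams` for exploration.

**Perturbation ("TMS").**  The feedforward interruption gates the
W_f·s_f current to zero from a set time in the delay; the s_f dynamics
keep running.  This models interruption of the pathway, not destruction
of the synapses, and leaves the matched-seed noise streams of the
control and perturbed arms identical.

## 4. Readout (`sensmem.readout`)

Preferred features (PFs) are estimated once from the steady state of a
5 s noise-free stimulus epoch over a uniform cue grid: each neuron's
tuning curve is upsampled to 1000 orientations with a periodic cubic
spline; PF = argmax (plateau-averaged within 1e−9), FWHM = width of the
contiguous above-half region around the peak.  The half level defaults
to min + (max−min)/2 (robust to the nonzero delay baseline); exact
half-of-max is available.  The width index
WI = (FWHM(ψ=45°) − FWHM(ψ=0°)) / (FWHM(ψ=45°) + FWHM(ψ=0°)) is
positive when cardinally indexed neurons are more sharply tuned.

Decoding uses the population vector on the doubled circle,
θ̂ = ½ Arg Σ_j r_j exp(2i·PF_j), from memory-module rates by default.
Bias is the mean wrapped error, SD its linear standard deviation, and
SD index = (SD(45°) − SD(0°)) / (SD(45°) + SD(0°)) (periodic linear
interpolation when 0°/45° are off the grid).  Fisher information per
neuron assumes Gaussian rate variability:
FI_i(θ) = (∂E[r_i]/∂θ)² / Var[r_i], with periodic central differences
over the stimulus grid; neurons below a 1e−12 variance floor are
excluded from the total with a logged count.  Note the population-vector
exponent is the standard rate-weighted form — a rate-inside-the-exponent
reading would be dimensionally inconsistent.

## 5. Drift-diffusion reduction (`sensmem.reduction`)

The noise-free delay dynamics relax onto a 1-D manifold s̄(θ)
parameterized by the cue (snapshot at 1 s into the delay by default, 4 s
for the α=0.05 condition; the residual speed τ‖ṡ‖/‖s̄‖ is measured and
warned about above 1e−3).  Writing the dynamics as
τṡ = −s + φ(Ws + h), the linearization K = −I + G·W is evaluated at each
grid point, and the slow direction u is the right eigenvector with the
largest real eigenvalue (≈ 0 on the homogeneous ring; realified with a
1e−6 tolerance, sign-aligned with the tangent s̄′).  Then

    μ(θ) = uᵀ[−s̄ + φ(Ws̄ + h)] / (τ‖s̄′‖),
    2D(θ) = Σ_i u_i² φ_i(Ws̄ + h) / (τ‖s̄′‖)²,

with φ_i read as the operating-point *rate* (the variance of the
Poisson-like noise), s̄′ by periodic central differences per degree, and
units converted to deg/s and deg/√s (τ in ms).  In the coupled network
every eigenmode with λ ≠ −1 has equal (s_s, s_f) and (s_m, s_b)
components, so the slow mode is computed from the condensed 2N×2N matrix
[[G_s W_s, G_s W_b], [G_m W_f, G_m W_m]] − I and expanded — an exact
reduction validated against the dense 4N eigensolve in the tests.  The
right-eigenvector projection follows the construction above; the adjoint
(left-eigenvector) alternative can be obtained by passing Kᵀ to
`slow_mode` but is not used in the shipped pipelines.

U(θ) integrates −μ (zero-mean; non-closing circulation is flagged);
ΔU = U(0°) − U(45°) > 0 means oblique attractors; the noise-coefficient
index (σ(45°) − σ(0°))/(σ(45°) + σ(0°)) is positive when diffusion peaks
at the obliques.  `reduced_sde_spec` packages μ and σ as periodic cubic
splines for direct simulation with `sensmem.attractor` (drift recentred
to zero circulation; time unit seconds).

Mechanistic picture confirmed by the extraction: sensory heterogeneity
α > 0 tilts the potential toward oblique attractors (μ(22.5°) ≈ +1 deg/s
at α = 0.04, matching the decoded drift of the full network) while the
denser cardinal representation (larger ‖s̄′‖) *suppresses* diffusion at
the cardinals — exactly the discrete-attractor-with-nonuniform-noise
regime of the 1-D models.  The one-module heterogeneous network instead
produces a deeper potential with a weaker noise asymmetry, so its SD
pattern follows the drift (minimum at the obliques) — the wrong sign.

**Limits of the round trip.**  Simulating the extracted 1-D SDE
reproduces the full network's *bias* profile essentially exactly
(Pearson r > 0.99 at 4 s of delay) and its SD profile early in the delay.
At long delays the *observed* SD comparison degrades in this
implementation: by 4 s the accumulated bias (≈ 6° at α = 0.04) gives the
cue-to-decoded-orientation map slopes of ≈ 1.5 near cardinals and ≈ 0.67
near obliques, and the instantaneous population-vector decode scatter is
itself largest at the obliques (the inverse of the Fisher-information
pattern).  Both observation-layer effects counteract the
oblique-maximal manifold diffusion, leaving the network's measured SD
profile nearly flat at 4 s, whereas the reduced SDE — which lives in the
manifold coordinate and has no observation layer — retains the σ(θ)
pattern.  The effect persists over the entire admissible range of the
background current (drift 0.7–2.0 deg/s for I_c,m 0.6–0.9), so it is a
property of this network regime, not of one calibration.  The reduced
model is therefore a faithful description of the *manifold dynamics*;
mapping it onto decoded-orientation statistics at long delays would
additionally require the static decode map and the decode-noise floor.

## 6. Experiments (`sensmem.experiments`)

Presets: `two_module` (α=0.04), `two_module_reduction` (α=0.05),
`segregated_ei` (α=0.03, β=0.08), `one_module` (α=5e−4, β=2.4e−3),
`tms` (segregated + feedforward gate at 2.5 s), the three attractor
presets, and `bayes`.  Full-scale defaults are 50 cue orientations and
1000 realizations (3000 for Fisher information and grid sweeps);
pipelines accept reduced sizes, and "1 s into the delay" always means
1000 ms after stimulus *offset*.  Sweep cells derive their seeds
deterministically from (seed, cell index) and record failures as NaN
rows with the error message.  CSV outputs use round-trippable precision
and carry JSON sidecars with the fully resolved parameters.

## 7. Test scale and what passing shows

The test suite runs scaled-down versions of each analysis chosen to keep
Monte-Carlo error well below the contrasts being asserted: 10 000
observer samples; 50 000 SDE realizations; 200 network realizations for
bias/SD contracts (MC standard error ≈ 0.07° on bias); a shared
8-orientation × 500-realization two-module ensemble for the Fisher
information pattern and the reduction round trip; 24-point manifold
grids (the pipeline default is 50).  Statistical assertions use bounds
of ≥ 4–6 standard errors.  The one-module SD-index contract is evaluated
at 4 s into the delay, where the drift-dominance effect has accumulated
well beyond MC noise (at 1 s it is still within noise at this ensemble
size).  All inputs are generated by the package itself; nothing here
constrains how well the model describes empirical data — the tests
establish internal correctness and the qualitative contracts (sign
patterns, orderings, symmetry properties) of the models.

## Known limitations

* The bias accumulates already during the stimulus epoch (the model
  starts from a flat baseline), and the error variance during the
  stimulus is negligible compared to the delay — both known departures
  from perception-task data.
* Single-item memory only: no distractors, no multi-item load.
* The Gaussian assumption in the Fisher-information estimator ignores
  rate rectification at very low rates.
* The segregated-E/I network routes excitation and inhibition through a
  single signed current sum (separate conductance pathways are not
  modelled), and kernel heterogeneity modulates the postsynaptic index,
  both literal readings of the connectivity definitions.
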