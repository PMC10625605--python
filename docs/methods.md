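# Methods

This note documents the models implemented in `neurosampler`, the
conventions and numerical choices behind them, what the synthetic-data
generator does and does not emulate, and the protocols used by the test
suite. All angles are degrees on the ring (−180, 180], precisions are
deg⁻², and information quantities are bits.

## Generative models

**Tuning.** N_E neurons have preferred stimuli θ_j evenly spaced on the
ring (spacing Δθ = L/N_E, L = 360°) and log-tuning
h_j(s) = −d(s, θ_j)²/(2a²), with d the minimal-arc difference and a the
tuning width (default 40°). Defaults N_E = 180, so Δθ = 2°.

**Feedforward input.** One input realization is a vector of independent
Poisson counts u^f_j ~ Poisson(U_f e^{h_j(s)}). Because the tuning is
log-quadratic, a single realization encodes an exactly Gaussian likelihood
over s with mean μ_f = Σ u_j θ_j / n_f (the linear population vector) and
precision Λ_f = n_f/a², n_f = Σ u_j. Default U_f = 5 counts per draw gives
E[n_f] = U_f √(2π) a/Δθ ≈ 250 spikes per volley — a plausible 20-ms
feedforward volley into a hypercolumn-sized population — and a likelihood
SD of ≈ 2.5°.

**Hierarchical world.** A stimulus parameter z is uniform on the ring, the
stimulus is s | z ~ N(z, Λ_s⁻¹), and s drives the input. The joint
posterior is Gaussian with mean (μ_f, μ_f) and precision
[[Λ_f+Λ_s, −Λ_s], [−Λ_s, Λ_s]]. At Λ_s = 0 the z marginal is uniform and
the posterior object is flagged degenerate rather than pseudo-inverted.

**Parallel world.** Two stimuli share the improper prior
p(s) ∝ exp[−Λ_s (s1−s2)²/2]; only the difference is constrained and each
marginal is uniform. Sampling convention: a uniform common center z₀ and a
difference δ ~ N(0, Λ_s⁻¹), s_{1,2} = z₀ ± δ/2. The posterior precision is
the likelihood precision diag(Λ_f1, Λ_f2) plus the prior precision matrix,
and the posterior mean is the precision-weighted likelihood mean, computed
in wrapped coordinates around the circular mean of the two likelihood means.

**Circularity.** The theory mixes a ring stimulus with non-periodic
Gaussians; all Gaussian formulas here use wrapped differences, and tests
restrict to posterior SD < 30°, where the wrap error is negligible.

## Decoding conventions

Three readouts coexist, and their distinction matters numerically:

- `readout.population_vector` uses the circular resultant-vector mean. It
  is well defined at the wrap point and agrees with the linear weighted
  mean to < 0.1° for narrow bumps; it is the generic activity decoder.
- `generative.decode_likelihood` uses the *wrap-safe linear* population
  vector (the circular mean refined by iterated linear means of wrapped
  deviations). The linear mean is the exact mean of the Gaussian
  likelihood encoded by log-linear Poisson counts; using the raw circular
  resultant instead leaves a skewness-dependent bias of up to ~0.7° per
  input draw that shows up as a systematic offset between the network and
  the Gibbs oracle.
- The E-only network kernel decodes linearly around μ_f, matching the
  likelihood convention exactly.

A subtlety worth recording: the population-vector sample drawn from Poisson
spikes has conditional variance a_real²/n, where a_real² is the second
moment of the *realized* rate profile, not the nominal a². Over input
draws E[a_real²] = a², with a relative SD of √3/√n_f (≈ 9% at n_f ≈ 250).
Single-draw comparisons between decoded network moments and the analytic
posterior therefore carry an irreducible draw-specific factor; protocols
below average over a few draws where tolerances are tight.

## Reference Gibbs samplers

The hierarchical sampler alternates
s̃ ~ N((Λ_f μ_f + Λ_s z̃)/(Λ_f+Λ_s), (Λ_f+Λ_s)⁻¹) and z̃ ~ N(s̃, Λ_s⁻¹);
the parallel sampler alternates the two symmetric conditionals. Conditional
means use wrapped differences relative to μ_f. Initialization is z̃₀ = μ_f
(resp. s̃_{m,0} = μ_fm): the chain starts in the high-density region,
matching an input-driven network at stimulus onset; the initialization is a
package convention, not part of the theory. Burn-in defaults to 10% of the
chain with a 100-sample floor — chains mix within tens of steps given the
strong conditionals. Sample moments use the n−1 convention. At Λ_s = 0 the
z conditional is improper; z̃ is drawn uniform on the ring and flagged.

## Spiking networks

**E-only theory network.** Per step, λ_t Δt = u^f + u^r_t with
u^r_t = w_E r_{t−Δt} + √([w_E r_{t−Δt}]₊) ξ_t (variance = mean, mimicking
Poisson variability of recurrent transmission), spikes
r_t ~ Poisson([λ_t Δt]₊), negative rates meaning zero spiking probability.
Recurrent drive uses only the previous step's spikes, which produces the
Gibbs alternation; one decoded sample is emitted per step. The diffusive
term is exactly what lets the recurrent input represent a stimulus-parameter
sample: decoding u^r gives z̃ with conditional variance 1/Λ_eff where
Λ_eff(w_E) = Λ_f w_E/(1−w_E), so the network realizes the Gibbs sampler of
a hierarchical model with prior precision Λ_eff, and Λ_eff = Λ_s exactly at
w_E* = Λ_s/(Λ_f+Λ_s). An additive-noise variant (σ_r) is available for
ablation and defaults to 0. A stability guard aborts when the population
spike count exceeds 10× the feedforward count (runaway excitation outside
the modeled regime, reached for w_E ≳ 1).

**E–I ring.** A time-discretized multivariate Hawkes process: Euler step
dt = 0.1 ms; every spike is filtered by η(t) = e^{−t/τ_d}/τ_d with
τ_d = 2 ms; rates are the summed filtered feedforward and recurrent inputs;
spiking is Poisson(λ dt) with a 2 ms refractory period (on by default, off
in theory-validation tests since it perturbs Poisson statistics).
E→E connectivity is a Gaussian ring, J^EE_jk = w_E L/(√(2π)a) e^{−d²/(2a²)}
(row sums = N_E w_E); E→I, I→E, I→I are unstructured with w_IE = w_E and
w_EI = w_II = w_I = 5 w_E; all weights are scaled by 1/√N at use. The
feedforward drive to E cells uses a broader tuning (exponent 4a², i.e.
width √2·a) by default — the simulator exposes `input_width_factor` because
the source theory states both 2a² and 4a² conventions in different places —
and I cells receive untuned drive w_If/N_I · Σ_j ⟨u^Ef_j⟩ with w_If = 0.8
to maintain balance. Recurrent inputs carry the multiplicative
(variance = mean) noise term; in discrete time the noise is scaled by
1/√dt so that its integral over a window has Poisson-count variance.
Decoding uses non-overlapping 20 ms windows (population vector of E spike
counts; stimulus-parameter samples from the window-averaged excitatory
recurrent input); empty windows are skipped and counted, since the
conditional sample is undefined when no spikes are emitted.

Magnitudes not fixed by the theory are package defaults chosen once: peak
feedforward rate U_f = 0.05 spikes/ms (50 Hz) and w_E ≤ ~0.1, below the
linear-stability bound of the structured ring mode
(w_E N_E/√N · e^{−(2πa/L)²/2} < 1 gives w_E ≲ 0.106 at N = 225).
With untuned inhibition the E bump rides on a negative baseline, so the
E–I network's window-decoded precision tracks the likelihood precision
proportionally but sits below it; the package treats the E–I simulator as a
qualitative testbed (monotonicity, positioning, variability structure) and
places the quantitative claims on the E-only network and the Gibbs oracle.

**Coupled rings.** Two identical E–I rings with no within-ring E–E
connections (uniform marginal priors), exchanging excitatory projections:
Gaussian ring profile onto the partner's E cells (peak w_mn, symmetric) and
unstructured projections of the same peak weight onto the partner's I
cells; no recurrent-noise term in the coupled configuration. Each ring's
spikes are decoded locally; the pair of readouts is one joint sample.

## Information accounting and diagnostics

**KL and mutual information.** The KL direction is D_KL[p‖q], p the true
posterior, q the moment-matched Gaussian of the sampling distribution
(first two circular-aware moments; higher-moment mismatch is assessed by KS
tests in the suite, not folded into KL). The mutual-information lower bound
is I_q = log L + ½[1 + log(|K_q|/(2πΛ_s)) − tr(K_q K_p⁻¹) − ΔᵀK_qΔ], with
the ideal I attained at q = p; the identity I = I_q + D_KL holds to
numerical precision and is asserted at 10⁻⁹ bits.

**Degenerate prior (Λ_s = 0).** The information bound is undefined and the
posterior z marginal is uniform. Convention: the reference posterior is
N(s|μ_f, Λ_f⁻¹) × Uniform(z); D_KL[p‖q] against a 2-D Gaussian q is
computed in closed form using E[d²] = L²/12 for wrapped uniform deviations.
A network whose recurrent input carries no mass (w_E = 0) represents no
stimulus parameter at all and is scored on the s marginal with q(z) taken
uniform. Under this convention any w_E > 0 pays ≳ 0.2 bits for fitting a
Gaussian to a uniform z marginal, which reproduces the claim that with no
prior coupling the uncoupled network is optimal.

**Weight scans.** One fixed input per scan; for each w on the grid the
E-only network runs (all weights simulated in one vectorized kernel against
the same input), the chain is moment-matched, and D_KL[p‖q] is recorded;
unstable grid points are recorded as missing. Where tolerances are tight
the suite averages KL curves over three independent input draws (see the
decoding subtlety above) before taking the grid argmin.

**Linear Fisher information.** The empirical LFI is f′ᵀΣ⁻¹f′ with f′ the
finite difference of mean responses at s ± δs/2 and Σ the trial-pooled
covariance, bias-corrected as (2T−N−3)/(2T−2)·naive − 2N/(T δs²). Neurons
silent at both stimuli are dropped before inversion (they carry no
information and make Σ singular). Bootstrap SEs use 50 trial resamples.

**Differential correlations.** V(s̄|u^f) is the variance of the decoded
rate position over time under a fixed input; V(s̄|s) redraws the input each
trial (80 settling steps, one sample per trial). Their theoretical values
are a²n_f⁻¹w_E* and a²n_f⁻¹(w_E*+1); the inherited excess is compared
against a²/E[n_f] with the ensemble-mean count, since it averages over
input draws. The f′f′ᵀ amplitude is the least-squares coefficient of the
outer product in Σ − diag(f), with f′ from central differences of the mean
tuning over ±2° (small relative to a = 40°).

**Subjective-prior fit.** Given a sampling chain and its decoded
likelihood(s), the predicted mean is Σ_s Λ_f μ_f (wrapped coordinates); the
single parameter Λ_s is fitted by minimizing D_KL[predicted posterior ‖
sampling distribution] with bounded scalar optimization, and the predicted
precision Λ_s-matrix + Λ_f is compared with the empirical precision.

## What the synthetic data does and does not emulate

All inputs are generated internally from the stated models; there is no
external data. The generator reproduces the statistical structure the
theory assumes — independent Poisson counts with Gaussian tuning, exact
Gaussian priors, stationary stimuli. It does not emulate temporal stimulus
dynamics, non-Poisson input variability, heterogeneous tuning widths or
preferred-stimulus jitter, or realistic synaptic conductances. Passing
tests therefore validate the internal consistency of the sampling theory
and its circuit implementation, not its fit to biological recordings.

## Problem sizes and determinism

Default study sizes: N_E = 180 (E–I: +45 I cells), chains of 10⁵ steps for
stationary-moment checks, 5×10⁴-step scans over 13-point weight grids,
2×10³–10⁴ trials for LFI and Fano estimates, E–I runs of 4–8 s simulated
time. These desk-scale sizes put Monte-Carlo errors comfortably below the
stated tolerances (e.g. covariance SEs < 1% at 10⁵ samples). Every run is
driven by a single seeded `numpy.random.Generator`; experiment bundles
record seed, spec hash and library versions, and identical spec + seed
reruns are bit-identical.

## Known limitations

- The E–I simulator's effective recurrent weight has no closed-form map to
  the theoretical w_E*; it is located empirically by weight scans.
- Rectification of negative rates and of the recurrent-noise argument
  biases sampling slightly at large w_E; the theory's validated regime
  keeps recurrent weights modest (w_E ≤ 0.6 in scans).
- The moment-matched Gaussian summary understates non-Gaussian tails of
  the sampling distribution near the wrap point; all tested configurations
  keep posterior SD < 30° where this is negligible.
- With untuned inhibition the E–I ring's decoded sampling precision is
  proportionally below the decoded likelihood precision (see above); exact
  equality would require tuning magnitudes the theory does not pin down.
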