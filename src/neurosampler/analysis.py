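"""Information-theoretic and correlation diagnostics.

Covers the quantitative checks of the sampling framework: Gaussian KL
divergence and the mutual-information bound it controls, KL-vs-weight scans
locating the optimal recurrent weight, the bias-corrected linear Fisher
information (LFI) estimator, internally vs externally generated differential
correlations, Fano factors, and the posterior-vs-sampling comparison with a
fitted subjective prior.

Conventions: KL direction is D_KL[p || q] with p the true posterior and q
the moment-matched sampling distribution; all information quantities are
reported in bits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from ._ring import circ_mean, wrap
from .generative import (
    FeedforwardInput,
    GaussianPosterior,
    HierarchicalWorld,
    posterior_hierarchical,
    sample_feedforward,
)
from .gibbs import SampleChain, SamplingDistribution, fit_distribution
from .netsim import (
    UnstableSimulationError,
    optimal_weight,
    run_sampler_grid,
)

__all__ = [
    "InfoReport",
    "DiffCorrReport",
    "WeightScanResult",
    "LFIResult",
    "PosteriorComparison",
    "kl_gaussian",
    "mutual_info_bound",
    "weight_scan",
    "linear_fisher_information",
    "lfi_halving_experiment",
    "differential_correlations",
    "position_variance_given_input",
    "position_variance_given_stimulus",
    "fit_differential_amplitude",
    "fano_factor",
    "compare_to_posterior",
]

_LN2 = float(np.log(2.0))


# ---------------------------------------------------------------------------
# Gaussian KL and mutual information
# ---------------------------------------------------------------------------

def _as_moments(dist) -> tuple[np.ndarray, np.ndarray]:
    """Extract (mean, covariance) from a SamplingDistribution, a
    GaussianPosterior, or a plain (mean, cov) pair."""
    if isinstance(dist, SamplingDistribution):
        return np.atleast_1d(dist.mean), np.atleast_2d(dist.cov)
    if isinstance(dist, GaussianPosterior):
        return np.atleast_1d(dist.mu_p), np.atleast_2d(dist.cov())
    mean, cov = dist
    return np.atleast_1d(np.asarray(mean, float)), np.atleast_2d(np.asarray(cov, float))


def kl_gaussian(q, p, L: float = 360.0) -> float:
    """Closed-form Gaussian KL divergence D_KL[p || q] in bits.

    ``p`` is the reference (true posterior), ``q`` the approximation.  Mean
    differences are wrapped onto the ring.  Raises on singular covariances,
    naming the degenerate axis.
    """
    mu_p, S_p = _as_moments(p)
    mu_q, S_q = _as_moments(q)
    d = mu_p.size
    for name, S in (("p", S_p), ("q", S_q)):
        if np.linalg.matrix_rank(S) < d or np.linalg.det(S) <= 0:
            axis = int(np.argmin(np.diag(S)))
            raise np.linalg.LinAlgError(
                f"singular covariance in {name} (degenerate axis {axis})"
            )
    K_q = np.linalg.inv(S_q)
    delta = wrap(mu_p - mu_q, L)
    nats = 0.5 * (
        np.trace(K_q @ S_p) - d + delta @ K_q @ delta
        + np.log(np.linalg.det(S_q) / np.linalg.det(S_p))
    )
    return float(nats) / _LN2


@dataclass(frozen=True)
class InfoReport:
    """Mutual-information accounting: I = I_q + D_KL[p||q] (all in bits)."""

    kl_bits: float
    I_q_bits: float
    I_bits: float


def mutual_info_bound(
    q, p: GaussianPosterior, Lambda_s: float, L: float | None = None
) -> InfoReport:
    """Lower-bound mutual information of the sampling distribution.

    I_q(Theta; u^f) = log L + 1/2 [1 + log(|K_q|/(2 pi Lambda_s))
        − tr(K_q K_p^{-1}) − (mu_p−mu_q)^T K_q (mu_p−mu_q)]
    and the ideal I obtained when q = p; I − I_q equals the Gaussian KL
    to numerical precision.  Undefined at Lambda_s = 0.
    """
    if Lambda_s <= 0:
        raise ValueError("mutual information bound undefined for Lambda_s = 0")
    if L is None:
        L = p.L
    mu_q, S_q = _as_moments(q)
    K_q = np.linalg.inv(S_q)
    K_p = np.asarray(p.K_p, float)
    S_p = np.linalg.inv(K_p)
    delta = wrap(p.mu_p - mu_q, L)
    iq = np.log(L) + 0.5 * (
        1.0 + np.log(np.linalg.det(K_q) / (2.0 * np.pi * Lambda_s))
        - np.trace(K_q @ S_p) - delta @ K_q @ delta
    )
    ideal = np.log(L) - 0.5 * (
        1.0 + np.log(2.0 * np.pi * Lambda_s) - np.log(np.linalg.det(K_p))
    )
    iq_bits, i_bits = float(iq) / _LN2, float(ideal) / _LN2
    return InfoReport(kl_bits=i_bits - iq_bits, I_q_bits=iq_bits, I_bits=i_bits)


def _kl_vs_degenerate(
    mu_q: np.ndarray,
    S_q: np.ndarray,
    mu_f: float,
    Lambda_f: float,
    L: float,
) -> float:
    """D_KL[p || q] in bits for the degenerate reference posterior
    p = N(s | mu_f, 1/Lambda_f) x Uniform(z on the ring) against a 2-D
    Gaussian q.  Uses E[d^2] = L^2/12 for wrapped uniform deviations."""
    v_s = 1.0 / Lambda_f
    K_q = np.linalg.inv(S_q)
    C = np.diag([v_s, L**2 / 12.0])
    d = np.array([wrap(mu_f - mu_q[0], L), 0.0])
    e_ln_p = -0.5 * (np.log(2.0 * np.pi * v_s) + 1.0) - np.log(L)
    e_ln_q = (
        -np.log(2.0 * np.pi) - 0.5 * np.log(np.linalg.det(S_q))
        - 0.5 * (np.trace(K_q @ C) + d @ K_q @ d)
    )
    return float(e_ln_p - e_ln_q) / _LN2


def _kl_1d(mu_q: float, v_q: float, mu_p: float, v_p: float, L: float) -> float:
    d = wrap(mu_p - mu_q, L)
    nats = 0.5 * (v_p / v_q - 1.0 + d**2 / v_q + np.log(v_q / v_p))
    return float(nats) / _LN2


# ---------------------------------------------------------------------------
# Weight scan
# ---------------------------------------------------------------------------

@dataclass
class WeightScanResult:
    """KL-vs-weight curve of the E-only sampling network."""

    w_grid: np.ndarray
    kl_bits: np.ndarray
    w_argmin: float
    w_star_theory: float
    I_q_bits: np.ndarray | None = None


def _chain_moments(s: np.ndarray, z: np.ndarray, burn_in: int, L: float):
    """Joint circular moments of decoded (s, z) arrays (nan = skipped)."""
    samples = np.column_stack([s[burn_in:], z[burn_in:]])
    chain = SampleChain(samples=samples, labels=("s", "z"), burn_in=0, L=L)
    fit = fit_distribution(chain)
    return fit.mean, fit.cov


def weight_scan(
    inp: FeedforwardInput,
    Lambda_s: float,
    w_grid,
    n_steps: int,
    rng: np.random.Generator,
    burn_in: int | None = None,
) -> WeightScanResult:
    """Scan the recurrent weight and locate the KL-minimizing value.

    One fixed feedforward input is presented for every grid point; each run
    is decoded, summarized by its first two circular moments, and compared
    with the analytic posterior via D_KL[p||q].  At Lambda_s = 0 the
    reference posterior factorizes into the normalized likelihood over s and
    a uniform stimulus-parameter marginal; a network whose recurrent input
    carries no mass (w = 0) represents no stimulus parameter and is scored
    on the s marginal alone.  Unstable grid points are recorded as nan.
    """
    w_grid = np.asarray(w_grid, dtype=float)
    if burn_in is None:
        burn_in = min(max(n_steps // 10, 100), n_steps - 1)
    L = inp.tuning.L
    post = posterior_hierarchical(inp, Lambda_s)
    try:
        res = run_sampler_grid(inp, w_grid, n_steps, rng)
        per_w = [(res["s"][i], res["z"][i]) for i in range(len(w_grid))]
    except UnstableSimulationError:
        per_w = []
        for w in w_grid:  # fall back to per-weight runs, skipping unstable ones
            try:
                r1 = run_sampler_grid(inp, [w], n_steps, rng)
                per_w.append((r1["s"][0], r1["z"][0]))
            except UnstableSimulationError:
                per_w.append(None)

    kl = np.full(len(w_grid), np.nan)
    iq = np.full(len(w_grid), np.nan)
    for i, sz in enumerate(per_w):
        if sz is None:
            continue
        s, z = sz
        if Lambda_s == 0.0:
            s_valid = s[burn_in:][~np.isnan(s[burn_in:])]
            mu_s = circ_mean(s_valid, L=L)
            v_s = float(np.var(wrap(s_valid - mu_s, L), ddof=1))
            z_valid = z[burn_in:][~np.isnan(z[burn_in:])]
            base = _kl_1d(mu_s, v_s, inp.mu_f, 1.0 / inp.Lambda_f, L)
            if z_valid.size < 2:
                kl[i] = base  # no represented stimulus parameter: uniform q(z)
            else:
                mean, cov = _chain_moments(s, z, burn_in, L)
                kl[i] = _kl_vs_degenerate(mean, cov, inp.mu_f, inp.Lambda_f, L)
        else:
            z_valid = z[burn_in:][~np.isnan(z[burn_in:])]
            if z_valid.size < 2:
                # no represented stimulus parameter (w = 0): q(z) uniform;
                # the z part of D_KL[p||q] is log L − (differential entropy
                # of the z conditional N(s, 1/Lambda_s))
                s_valid = s[burn_in:][~np.isnan(s[burn_in:])]
                mu_s = circ_mean(s_valid, L=L)
                v_s = float(np.var(wrap(s_valid - mu_s, L), ddof=1))
                z_term = np.log(L) - 0.5 * np.log(2.0 * np.pi * np.e / Lambda_s)
                kl[i] = (
                    _kl_1d(mu_s, v_s, inp.mu_f, 1.0 / inp.Lambda_f, L)
                    + z_term / _LN2
                )
                continue
            mean, cov = _chain_moments(s, z, burn_in, L)
            kl[i] = kl_gaussian((mean, cov), post, L=L)
            iq[i] = mutual_info_bound((mean, cov), post, Lambda_s).I_q_bits
    w_argmin = float(w_grid[int(np.nanargmin(kl))])
    return WeightScanResult(
        w_grid=w_grid, kl_bits=kl, w_argmin=w_argmin,
        w_star_theory=optimal_weight(Lambda_s, inp.Lambda_f),
        I_q_bits=iq if Lambda_s > 0 else None,
    )


# ---------------------------------------------------------------------------
# Linear Fisher information
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LFIResult:
    """Bias-corrected linear Fisher information f'^T Sigma^{-1} f' (deg^-2)."""

    value: float
    naive: float
    f_prime: np.ndarray
    se: float | None = None


def linear_fisher_information(
    resp_minus: np.ndarray,
    resp_plus: np.ndarray,
    ds: float,
    n_boot: int = 0,
    rng: np.random.Generator | None = None,
) -> LFIResult:
    """Empirical LFI from trial-by-neuron responses at two nearby stimuli.

    f' is estimated by the finite difference of the two mean responses over
    ``ds``; Sigma is the trial-pooled covariance.  The finite-sample bias is
    removed with the correction (2T−N−3)/(2T−2)·naive − 2N/(T·ds²).
    Optionally bootstraps trials (``n_boot`` resamples) for a standard
    error.
    """
    A = np.asarray(resp_minus, float)
    B = np.asarray(resp_plus, float)
    if B.shape != A.shape:
        raise ValueError("response blocks must have identical shape")
    # silent neurons (zero variance at both stimuli) carry no information
    # and make Sigma singular; drop them before inverting
    active = (A.var(axis=0) + B.var(axis=0)) > 0
    A, B = A[:, active], B[:, active]
    T, N = A.shape
    if T <= (N + 3) / 2:
        raise ValueError("too few trials for the bias correction (T <= (N+3)/2)")

    def _estimate(a, b):
        fp = (b.mean(axis=0) - a.mean(axis=0)) / ds
        S = 0.5 * (np.cov(a, rowvar=False, ddof=1) + np.cov(b, rowvar=False, ddof=1))
        naive = float(fp @ np.linalg.solve(S, fp))
        corrected = naive * (2 * T - N - 3) / (2 * T - 2) - 2 * N / (T * ds**2)
        return corrected, naive, fp

    value, naive, fp = _estimate(A, B)
    se = None
    if n_boot:
        rng = rng or np.random.default_rng()
        vals = np.empty(n_boot)
        for k in range(n_boot):
            ia = rng.integers(0, T, size=T)
            ib = rng.integers(0, T, size=T)
            vals[k] = _estimate(A[ia], B[ib])[0]
        se = float(vals.std(ddof=1))
    return LFIResult(value=value, naive=naive, f_prime=fp, se=se)


def lfi_halving_experiment(
    world: HierarchicalWorld,
    s: float,
    n_trials: int,
    rng: np.random.Generator,
    ds: float = 4.0,
) -> dict:
    """LFI of the feedforward input vs the Poisson spiking response.

    For stimuli s ± ds/2, draws ``n_trials`` independent feedforward inputs
    u^f and, per trial, one extra Poisson spike-generation stage
    r ~ Poisson(u^f) (the w_E = 0 network).  Because the added stage doubles
    the response variance while leaving the mean tuning unchanged, the LFI
    of r converges to half the LFI of u^f.
    """
    tun = world.tuning
    out = {}
    blocks = {}
    for tag, stim in (("minus", s - ds / 2.0), ("plus", s + ds / 2.0)):
        rates = world.U_f * np.exp(tun.log_tuning(stim))
        u = rng.poisson(rates, size=(n_trials, tun.n_e))
        r = rng.poisson(u)
        blocks[tag] = (u, r)
    lfi_in = linear_fisher_information(blocks["minus"][0], blocks["plus"][0], ds)
    lfi_out = linear_fisher_information(blocks["minus"][1], blocks["plus"][1], ds)
    out["lfi_input"] = lfi_in.value
    out["lfi_response"] = lfi_out.value
    out["ratio"] = lfi_out.value / lfi_in.value
    return out


# ---------------------------------------------------------------------------
# Differential correlations
# ---------------------------------------------------------------------------

@dataclass
class DiffCorrReport:
    """Differential-correlation decomposition of network variability.

    ``V_internal``: variance (deg²) of the rate position s_bar under a fixed
    input — the internally generated amplitude a²·n_f⁻¹·w_E.  ``V_total``:
    variance under a fixed stimulus with the input redrawn per trial, which
    adds the inherited term a²/n_f.  ``amplitude_fit`` is the least-squares
    coefficient of f'f'^T in the residual covariance Sigma − diag(f).
    """

    V_internal: float
    V_total: float
    f_prime: np.ndarray | None = None
    amplitude_fit: float | None = None


def position_variance_given_input(
    inp: FeedforwardInput,
    w_E: float,
    n_steps: int,
    rng: np.random.Generator,
    burn_in: int | None = None,
) -> float:
    """Variance of the decoded rate position s_bar_t with the input fixed."""
    res = run_sampler_grid(inp, [w_E], n_steps, rng)
    if burn_in is None:
        burn_in = min(max(n_steps // 10, 100), n_steps - 1)
    sb = res["s_bar"][0][burn_in:]
    sb = sb[~np.isnan(sb)]
    mu = circ_mean(sb, L=inp.tuning.L)
    return float(np.var(wrap(sb - mu, inp.tuning.L), ddof=1))


def position_variance_given_stimulus(
    world: HierarchicalWorld,
    s: float,
    w_E: float,
    n_trials: int,
    rng: np.random.Generator,
    settle_steps: int = 80,
) -> float:
    """Variance of s_bar across trials with the stimulus fixed.

    Each trial redraws the feedforward input from p(u^f | s), runs the
    E-only network to equilibrium and records one rate-position sample; the
    trial-to-trial variance combines internal sampling variability and the
    inherited likelihood-mean jitter.
    """
    L = world.tuning.L
    vals = np.empty(n_trials)
    for k in range(n_trials):
        inp = sample_feedforward(world, s, rng)
        if inp.empty:
            vals[k] = np.nan
            continue
        res = run_sampler_grid(inp, [w_E], settle_steps, rng)
        vals[k] = res["s_bar"][0, -1]
    vals = vals[~np.isnan(vals)]
    mu = circ_mean(vals, L=L)
    return float(np.var(wrap(vals - mu, L), ddof=1))


def fit_differential_amplitude(
    cov: np.ndarray, mean_rates: np.ndarray, f_prime: np.ndarray
) -> float:
    """Least-squares coefficient of f'f'^T in (Sigma − diag(f))."""
    R = np.asarray(cov, float) - np.diag(np.asarray(mean_rates, float))
    P = np.outer(f_prime, f_prime)
    denom = float((P * P).sum())
    if denom == 0:
        raise ValueError("zero tuning derivative")
    return float((R * P).sum() / denom)


def differential_correlations(
    world: HierarchicalWorld,
    s: float,
    w_E: float,
    rng: np.random.Generator,
    mode: str = "given_input",
    n_steps: int = 20000,
    n_trials: int = 1500,
    f_prime_ds: float = 4.0,
) -> DiffCorrReport:
    """Differential-correlation report for the E-only sampling network.

    ``mode`` selects which variance fills ``V_total``: "given_stimulus"
    redraws the input per trial; "given_input" reports the fixed-input run
    for both (V_total = V_internal).  The amplitude of the f'f'^T component
    is fitted on the spike-count covariance of the fixed-input run, with f'
    estimated by central differences of the mean tuning at s ± ds/2.
    """
    inp = sample_feedforward(world, s, rng)
    V_int = position_variance_given_input(inp, w_E, n_steps, rng)
    if mode == "given_stimulus":
        V_tot = position_variance_given_stimulus(world, s, w_E, n_trials, rng)
    elif mode == "given_input":
        V_tot = V_int
    else:
        raise ValueError(f"unknown mode {mode!r}")

    # covariance of spike counts around the fixed input, for the pattern fit
    from .netsim import simulate_e_only

    trace = simulate_e_only(inp, w_E, min(n_steps, 20000), rng)
    counts = trace.counts_E[min(n_steps, 20000) // 10:]
    S = np.cov(counts.astype(float), rowvar=False, ddof=1)
    f = counts.mean(axis=0)
    gain = 1.0 / (1.0 - w_E) if w_E < 1 else 1.0
    tun = world.tuning
    fp = gain * world.U_f * (
        np.exp(tun.log_tuning(s + f_prime_ds / 2.0))
        - np.exp(tun.log_tuning(s - f_prime_ds / 2.0))
    ) / f_prime_ds
    amp = fit_differential_amplitude(S, f, fp)
    return DiffCorrReport(
        V_internal=V_int, V_total=V_tot, f_prime=fp, amplitude_fit=amp
    )


# ---------------------------------------------------------------------------
# Fano factor
# ---------------------------------------------------------------------------

def fano_factor(count_matrix: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-neuron and mean Fano factor (variance/mean over repeats).

    ``count_matrix`` is trials x neurons; neurons with zero mean count are
    excluded from the average.
    """
    x = np.asarray(count_matrix, float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a trials x neurons matrix with >= 2 repeats")
    mean = x.mean(axis=0)
    if np.all(mean == 0):
        raise ValueError("all-zero count matrix")
    var = x.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fano = np.where(mean > 0, var / mean, np.nan)
    return fano, float(np.nanmean(fano))


# ---------------------------------------------------------------------------
# Posterior-vs-sampling comparison (subjective prior fit)
# ---------------------------------------------------------------------------

@dataclass
class PosteriorComparison:
    """Predicted-vs-actual sampling statistics with a fitted subjective prior."""

    predicted_mean: np.ndarray
    sampling_mean: np.ndarray
    fitted_Lambda_s: float
    K_pred: np.ndarray
    empirical_precision: np.ndarray


def _prior_matrix(Lambda_s: float) -> np.ndarray:
    return Lambda_s * np.array([[1.0, -1.0], [-1.0, 1.0]])


def compare_to_posterior(
    chain: SampleChain,
    inputs,
    Lambda_s_max: float | None = None,
) -> PosteriorComparison:
    """Compare a sampling chain with the posterior family it should match.

    The predicted sampling mean is <s~>_pred = Sigma_s · Lambda_f · mu_f
    (in wrapped coordinates); the subjective prior precision Lambda_s is
    fitted by minimizing D_KL[predicted posterior || sampling distribution],
    and the predicted precision K_pred = prior(Lambda_s) + diag(Lambda_f) is
    returned next to the empirical precision.

    ``inputs`` is the hierarchical FeedforwardInput (chains labeled
    ("s","z")) or the pair of inputs (chains labeled ("s1","s2")).
    """
    fit = fit_distribution(chain)
    if fit.degenerate:
        raise np.linalg.LinAlgError("singular sampling covariance")
    L = chain.L
    hier = "z" in chain.labels
    if hier:
        inp = inputs
        Lf_vec = np.array([inp.Lambda_f, 0.0])
        mu_vec = np.array([inp.mu_f, inp.mu_f])
    else:
        inp1, inp2 = inputs
        Lf_vec = np.array([inp1.Lambda_f, inp2.Lambda_f])
        mu_vec = np.array([inp1.mu_f, inp2.mu_f])
    ref = circ_mean(mu_vec[Lf_vec > 0], L=L)
    d = wrap(mu_vec - ref, L)
    pred_mean = wrap(ref + fit.cov @ (Lf_vec * d), L)

    S_q = fit.cov
    mu_q_d = wrap(fit.mean - ref, L)
    Lf_max = float(Lf_vec.max())
    if Lambda_s_max is None:
        Lambda_s_max = 50.0 * Lf_max

    def objective(Ls):
        K = _prior_matrix(Ls) + np.diag(Lf_vec)
        if np.linalg.det(K) <= 1e-300:
            return np.inf
        mu_p = np.linalg.solve(K, Lf_vec * d)
        return kl_gaussian((mu_q_d, S_q), (mu_p, np.linalg.inv(K)), L=L)

    res = optimize.minimize_scalar(
        objective, bounds=(1e-9 * Lf_max, Lambda_s_max), method="bounded",
        options={"xatol": 1e-6 * Lf_max},
    )
    Ls_fit = float(res.x)
    # a boundary solution at the lower end means "no prior coupling"
    if objective(1e-9 * Lf_max) <= res.fun:
        Ls_fit = 0.0
    K_pred = _prior_matrix(Ls_fit) + np.diag(Lf_vec)
    return PosteriorComparison(
        predicted_mean=pred_mean,
        sampling_mean=fit.mean,
        fitted_Lambda_s=Ls_fit,
        K_pred=K_pred,
        empirical_precision=np.linalg.inv(S_q),
    )
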