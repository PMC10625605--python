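"""Spiking-network samplers.

Three simulators of increasing biological detail:

* :func:`simulate_e_only` / :func:`run_sampler` — the theory network: N_E
  excitatory Poisson neurons with self-connections of weight ``w_E`` and a
  diffusive (variance = mean) noise term on the recurrent input.  Per step,
  rates are ``lambda_t*dt = u^f + u^r_t`` with ``u^r_t = w_E*r_{t-dt} +
  sqrt([w_E*r_{t-dt}]_+)*xi``; spikes are Poisson with negative rates
  rectified to zero spiking probability.  Decoding the spike counts gives
  stimulus samples and decoding the recurrent input gives stimulus-parameter
  samples; at ``w_E = Lambda_s/(Lambda_f+Lambda_s)`` the chain reproduces the
  Gibbs sampler of the hierarchical posterior.

* :func:`simulate_ei` — a full E–I ring network modeled as a discretized
  multivariate Hawkes process: Euler steps of 0.1 ms, exponential synaptic
  filtering (tau_d = 2 ms), a 2 ms refractory period, Gaussian ring E-to-E
  connectivity and unstructured E–I / I–I coupling scaled by 1/sqrt(N), and
  untuned inhibitory neurons driven to balance the excitatory feedforward
  input.

* :func:`simulate_coupled` — two E–I rings with no within-ring E–E
  connections, exchanging excitatory projections (onto both E and I cells)
  whose weight encodes the pairwise stimulus prior.

The weight laws ``optimal_weight`` and ``cross_network_weight`` give the
recurrent strengths at which sampling matches the true posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._ring import wrap
from .generative import EmptyInputError, FeedforwardInput, TuningModel

__all__ = [
    "NetworkConfig",
    "SimulationTrace",
    "UnstableSimulationError",
    "optimal_weight",
    "cross_network_weight",
    "build_ring_connectivity",
    "simulate_e_only",
    "run_sampler",
    "run_sampler_grid",
    "feedforward_rates",
    "simulate_ei",
    "simulate_coupled",
]


class UnstableSimulationError(RuntimeError):
    """Raised when population activity runs away (rate ceiling exceeded)."""


@dataclass(frozen=True)
class NetworkConfig:
    """Parameters of the E–I ring simulator.

    Weights are dimensionless peak strengths before the 1/sqrt(N) scaling;
    ``w_ratio`` ties the inhibitory weights to the excitatory one
    (w_I = w_ratio * w_E) and ``w_If`` scales the feedforward drive to the
    inhibitory population.  ``input_width_factor`` multiplies the tuning
    width of the feedforward drive to E cells (default sqrt(2), i.e. a
    4a^2 exponent; set to 1.0 for the 2a^2 convention of the theory
    modules).
    """

    N_E: int = 180
    N_I: int = 45
    w_E: float = 0.05
    w_ratio: float = 5.0
    w_If: float = 0.8
    w_mn: float = 0.0
    a_deg: float = 40.0
    L_deg: float = 360.0
    tau_d_ms: float = 2.0
    dt_ms: float = 0.1
    refractory_ms: float = 2.0
    T_ms: float = 1000.0
    input_width_factor: float = float(np.sqrt(2.0))
    recurrent_noise: bool = True
    rate_ceiling: float = 10.0
    seed: int | None = None

    def __post_init__(self):
        if self.N_E <= 0 or self.N_I <= 0:
            raise ValueError("neuron counts must be positive")
        if not self.dt_ms < self.tau_d_ms:
            raise ValueError("dt_ms must be smaller than tau_d_ms")
        if min(self.w_E, self.w_ratio, self.w_If, self.w_mn) < 0:
            raise ValueError("weights must be nonnegative")

    @property
    def w_I(self) -> float:
        return self.w_ratio * self.w_E

    @property
    def tuning(self) -> TuningModel:
        return TuningModel(n_e=self.N_E, a=self.a_deg, L=self.L_deg)

    @property
    def input_tuning(self) -> TuningModel:
        """Tuning of the feedforward drive (possibly broader than a_deg)."""
        return TuningModel(
            n_e=self.N_E, a=self.a_deg * self.input_width_factor, L=self.L_deg
        )


@dataclass
class SimulationTrace:
    """Windowed record of a network simulation.

    ``counts_E``: spike counts of E neurons per decoding window
    (windows x N_E).  ``ff_counts_E``: feedforward spikes received in the
    same windows.  ``u_rec_E``: window-mean excitatory recurrent input to E
    neurons (the quantity that encodes the stimulus-parameter sample).
    ``lam_E``: window-mean unrectified rate (diagnostic; the rate used for
    spiking is rectified at zero).  For the E-only theory network each
    window is a single Euler step and ``u_f`` holds the fixed input counts.
    """

    kind: str
    dt_ms: float
    window_ms: float
    tuning: TuningModel
    counts_E: np.ndarray
    ff_counts_E: np.ndarray | None = None
    u_rec_E: np.ndarray | None = None
    lam_E: np.ndarray | None = None
    counts_I: np.ndarray | None = None
    u_f: np.ndarray | None = None
    spikes_E: np.ndarray | None = None
    input_tuning: TuningModel | None = None
    config: NetworkConfig | None = None
    seed: int | None = None

    @property
    def n_windows(self) -> int:
        return self.counts_E.shape[0]


def optimal_weight(Lambda_s: float, Lambda_f: float) -> float:
    """Recurrent weight encoding the prior: w* = Lambda_s/(Lambda_f+Lambda_s).

    Zero prior coupling needs no recurrence (w*=0); w* -> 1 as the prior
    dominates.  The weight depends on the likelihood precision, i.e. on the
    feedforward input strength.
    """
    if Lambda_f <= 0:
        raise ValueError("Lambda_f must be positive")
    if Lambda_s < 0:
        raise ValueError("Lambda_s must be >= 0")
    return Lambda_s / (Lambda_f + Lambda_s)


def cross_network_weight(Lambda_s: float, Lambda_f_n: float) -> float:
    """Optimal coupling from network n onto its partner:
    w*_mn = Lambda_s/(Lambda_s + Lambda_fn) — same law as
    :func:`optimal_weight` with the partner's likelihood precision."""
    return optimal_weight(Lambda_s, Lambda_f_n)


def build_ring_connectivity(config: NetworkConfig) -> dict[str, np.ndarray]:
    """Weight matrices of the E–I ring (before 1/sqrt(N) scaling).

    J^EE_jk = w_E * L/(sqrt(2*pi)*a) * exp[−d(theta_j,theta_k)^2/(2a^2)]
    with periodic wrapping, so each row sums to ~N_E*w_E / N_E ... i.e. the
    total E-to-E strength is N_E*w_E.  E->I, I->E and I->I connections are
    unstructured: J^IE = w_E, J^EI = J^II = w_I, all-to-all.
    """
    th = config.tuning.theta
    a, L = config.a_deg, config.L_deg
    d = wrap(th[:, None] - th[None, :], L)
    gain = config.w_E * L / (np.sqrt(2.0 * np.pi) * a)
    J_EE = gain * np.exp(-(d**2) / (2.0 * a**2))
    J_EI = np.full((config.N_E, config.N_I), config.w_I)
    J_IE = np.full((config.N_I, config.N_E), config.w_E)
    J_II = np.full((config.N_I, config.N_I), config.w_I)
    return {"EE": J_EE, "EI": J_EI, "IE": J_IE, "II": J_II}


# ---------------------------------------------------------------------------
# E-only theory network
# ---------------------------------------------------------------------------

def _e_only_kernel(
    inp: FeedforwardInput,
    w_arr: np.ndarray,
    n_steps: int,
    rng: np.random.Generator,
    sigma_r: float = 0.0,
    noise: str = "multiplicative",
    rate_ceiling: float = 10.0,
    record_trace: bool = False,
):
    """Shared Euler loop for a batch of recurrent weights.

    Simulates W independent copies of the self-connected E network (one per
    weight) against the same fixed input, decoding stimulus samples
    s~ (from spikes), stimulus-parameter samples z~ (from recurrent input)
    and the rate position s_bar on the fly.  Returns dict of (W, n_steps)
    arrays plus optional full traces (W == 1 only).
    """
    if inp.empty:
        raise EmptyInputError("network needs a non-empty feedforward input")
    uf = inp.counts.astype(float)
    n_f = float(inp.n_f)
    L = inp.tuning.L
    dth = wrap(inp.tuning.theta - inp.mu_f, L)  # decode around the likelihood mean
    W = len(w_arr)
    w = np.asarray(w_arr, dtype=float)[:, None]
    r = np.tile(rng.poisson(uf), (W, 1)).astype(float)

    s_out = np.full((W, n_steps), np.nan)
    z_out = np.full((W, n_steps), np.nan)
    sbar_out = np.full((W, n_steps), np.nan)
    n_r_out = np.zeros((W, n_steps))
    sum_ur_out = np.zeros((W, n_steps))
    if record_trace:
        if W != 1:
            raise ValueError("trace recording supports a single weight")
        tr_lam = np.empty((n_steps, uf.size), dtype=np.float32)
        tr_r = np.empty((n_steps, uf.size), dtype=np.int32)
        tr_ur = np.empty((n_steps, uf.size), dtype=np.float32)

    multiplicative = noise == "multiplicative"
    for t in range(n_steps):
        ubar = w * r
        u_r = ubar + (
            np.sqrt(np.maximum(ubar, 0.0)) * rng.standard_normal(ubar.shape)
            if multiplicative
            else 0.0
        )
        if sigma_r > 0.0:
            u_r = u_r + sigma_r * rng.standard_normal(ubar.shape)
        lam = uf + u_r
        lam_rect = np.maximum(lam, 0.0)
        r = rng.poisson(lam_rect).astype(float)

        n_r = r.sum(axis=1)
        n_r_out[:, t] = n_r
        ok = n_r > 0
        s_out[ok, t] = inp.mu_f + (r[ok] @ dth) / n_r[ok]
        s_ur = u_r.sum(axis=1)
        sum_ur_out[:, t] = s_ur
        okz = s_ur > 1e-12
        z_out[okz, t] = inp.mu_f + (u_r[okz] @ dth) / s_ur[okz]
        n_lam = lam_rect.sum(axis=1)
        okl = n_lam > 0
        sbar_out[okl, t] = inp.mu_f + (lam_rect[okl] @ dth) / n_lam[okl]
        if record_trace:
            tr_lam[t], tr_r[t], tr_ur[t] = lam[0], r[0], u_r[0]
        if np.any(n_r > rate_ceiling * n_f):
            raise UnstableSimulationError(
                f"population rate exceeded {rate_ceiling}x the feedforward "
                f"rate (w_E={w_arr[int(np.argmax(n_r))]:g}); network is unstable"
            )
    out = {
        "s": wrap(s_out, L), "z": wrap(z_out, L), "s_bar": wrap(sbar_out, L),
        "n_r": n_r_out, "sum_ur": sum_ur_out,
    }
    if record_trace:
        out["trace"] = (tr_lam, tr_r, tr_ur)
    return out


def simulate_e_only(
    inp: FeedforwardInput,
    w_E: float,
    n_steps: int,
    rng: np.random.Generator,
    sigma_r: float = 0.0,
    noise: str = "multiplicative",
    rate_ceiling: float = 10.0,
) -> SimulationTrace:
    """Simulate the self-connected E-only network, storing the full trace.

    A fixed input ``inp`` is presented at every step; recurrent drive uses
    only the previous step's spikes so the network alternates like a Gibbs
    sampler.  For long chains prefer :func:`run_sampler`, which decodes on
    the fly without storing per-step matrices.  An empty input yields an
    all-zero trace (the network has nothing to amplify).
    """
    if inp.empty:
        n = inp.tuning.n_e
        zeros = np.zeros((n_steps, n))
        return SimulationTrace(
            kind="eonly", dt_ms=1.0, window_ms=1.0, tuning=inp.tuning,
            counts_E=zeros.astype(np.int32), u_rec_E=zeros.astype(np.float32),
            lam_E=zeros.astype(np.float32), u_f=inp.counts,
        )
    res = _e_only_kernel(
        inp, np.array([w_E]), n_steps, rng, sigma_r=sigma_r, noise=noise,
        rate_ceiling=rate_ceiling, record_trace=True,
    )
    lam, r, ur = res["trace"]
    return SimulationTrace(
        kind="eonly", dt_ms=1.0, window_ms=1.0, tuning=inp.tuning,
        counts_E=r, u_rec_E=ur, lam_E=lam, u_f=inp.counts,
    )


def run_sampler(
    inp: FeedforwardInput,
    w_E: float,
    n_steps: int,
    rng: np.random.Generator,
    burn_in: int | None = None,
    **kwargs,
):
    """Run the E-only network and return the decoded (s~, z~) SampleChain.

    The pairing (z~_t decoded from u^r_t, s~_t decoded from r_t) matches the
    Gibbs alternation: z~_t is conditioned on the previous step's spikes.
    """
    from .gibbs import SampleChain, default_burn_in

    res = _e_only_kernel(inp, np.array([w_E]), n_steps, rng, **kwargs)
    if burn_in is None:
        burn_in = default_burn_in(n_steps)
    samples = np.column_stack([res["s"][0], res["z"][0]])
    return SampleChain(
        samples=samples, labels=("s", "z"), burn_in=burn_in, L=inp.tuning.L,
        n_skipped=int(np.isnan(res["s"][0]).sum()),
        meta={"w_E": w_E, "mean_n_r": float(res["n_r"].mean()),
              "mean_sum_ur": float(res["sum_ur"].mean())},
    )


def run_sampler_grid(
    inp: FeedforwardInput,
    w_grid,
    n_steps: int,
    rng: np.random.Generator,
    **kwargs,
) -> dict:
    """Vectorized E-only runs over a grid of weights with one shared input.

    Returns the raw kernel output: (W, n_steps) arrays of decoded samples.
    """
    return _e_only_kernel(inp, np.asarray(w_grid, dtype=float), n_steps, rng, **kwargs)


# ---------------------------------------------------------------------------
# E–I Hawkes-process ring network
# ---------------------------------------------------------------------------

def feedforward_rates(
    tuning: TuningModel, s: float, U_f_per_ms: float
) -> np.ndarray:
    """Mean feedforward spike rate (spikes/ms) per E neuron for stimulus s."""
    return U_f_per_ms * np.exp(tuning.log_tuning(s))


def _ei_core(
    ff_rates: list[np.ndarray],
    config: NetworkConfig,
    rng: np.random.Generator,
    T_ms: float,
    window_ms: float,
    w_EE_within: float,
    coupled: bool,
    recurrent_noise: bool,
    refractory: bool,
    store_spikes: bool,
    deterministic_input: bool = False,
):
    """Euler integration of one or two coupled E–I rings.

    State per ring: filtered spike trains y (1/ms) of E, I and feedforward
    channels; each spike adds 1/tau_d and decays exponentially.  Rates are
    sums of filtered inputs; spikes are Poisson(lambda*dt) with rectification
    and an optional refractory period.  Returns per-window aggregates.
    """
    M = len(ff_rates)
    NE, NI = config.N_E, config.N_I
    N = NE + NI
    dt, tau = config.dt_ms, config.tau_d_ms
    decay = np.exp(-dt / tau)
    sqN = np.sqrt(N)
    n_steps = int(round(T_ms / dt))
    steps_per_win = max(int(round(window_ms / dt)), 1)
    n_win = n_steps // steps_per_win

    J = build_ring_connectivity(replace(config, w_E=max(config.w_E, 1e-12)))
    # within-ring E–E strength may differ from the w_E used for E–I balance
    J_EE = J["EE"] * (w_EE_within / max(config.w_E, 1e-12))
    if coupled:
        Jx = J["EE"] * (config.w_mn / max(config.w_E, 1e-12))

    ff_I = config.w_If / NI * np.array([r.sum() for r in ff_rates])

    yE = [np.zeros(NE) for _ in range(M)]
    yI = [np.zeros(NI) for _ in range(M)]
    yfE = [np.zeros(NE) for _ in range(M)]
    yfI = [np.zeros(NI) for _ in range(M)]
    ref_E = [np.zeros(NE, dtype=int) for _ in range(M)]
    ref_I = [np.zeros(NI, dtype=int) for _ in range(M)]
    ref_steps = int(round(config.refractory_ms / dt)) if refractory else 0

    counts_E = [np.zeros((n_win, NE), dtype=np.int32) for _ in range(M)]
    counts_I = [np.zeros((n_win, NI), dtype=np.int32) for _ in range(M)]
    ffc_E = [np.zeros((n_win, NE), dtype=np.int32) for _ in range(M)]
    urec = [np.zeros((n_win, NE)) for _ in range(M)]
    lamE_acc = [np.zeros((n_win, NE)) for _ in range(M)]
    spk = [np.zeros((n_steps, NE), dtype=np.int8) for _ in range(M)] if store_spikes else None

    ceiling = config.rate_ceiling * max(float(np.sum(r)) for r in ff_rates) + 1e-9
    run_rate = np.zeros(M)

    for t in range(n_steps):
        win = min(t // steps_per_win, n_win - 1)
        for m in range(M):
            if deterministic_input:
                # clamp the filtered feedforward drive at its mean rate
                yfE[m] = ff_rates[m]
                yfI[m] = np.full(NI, ff_I[m])
            else:
                # external feedforward Poisson spikes, filtered
                fsp = rng.poisson(ff_rates[m] * dt)
                fspI = rng.poisson(ff_I[m] * dt, size=NI)
                yfE[m] = yfE[m] * decay + fsp / tau
                yfI[m] = yfI[m] * decay + fspI / tau
                ffc_E[m][win] += fsp

        for m in range(M):
            exc_E = (J_EE @ yE[m]) / sqN
            if coupled:
                exc_E = exc_E + (Jx @ yE[1 - m]) / sqN
            inh_E = config.w_I * yI[m].sum() / sqN
            ubar_E = exc_E - inh_E
            exc_I = config.w_E * yE[m].sum() / sqN
            if coupled:
                exc_I = exc_I + config.w_mn * yE[1 - m].sum() / sqN
            inh_I = config.w_I * yI[m].sum() / sqN
            ubar_I = exc_I - inh_I

            if recurrent_noise:
                u_E = ubar_E + np.sqrt(np.maximum(ubar_E, 0.0) / dt) * rng.standard_normal(NE)
                u_I = ubar_I + np.sqrt(max(ubar_I, 0.0) / dt) * rng.standard_normal(NI)
            else:
                u_E, u_I = ubar_E, ubar_I

            lam_E = yfE[m] + u_E
            lam_I = yfI[m] + u_I
            pE = np.maximum(lam_E, 0.0) * dt
            pI = np.maximum(lam_I, 0.0) * dt
            sE = rng.poisson(pE)
            sI = rng.poisson(pI)
            if ref_steps:
                sE[ref_E[m] > 0] = 0
                sI[ref_I[m] > 0] = 0
                ref_E[m] -= 1
                ref_I[m] -= 1
                ref_E[m][sE > 0] = ref_steps
                ref_I[m][sI > 0] = ref_steps
            yE[m] = yE[m] * decay + sE / tau
            yI[m] = yI[m] * decay + sI / tau

            counts_E[m][win] += sE
            counts_I[m][win] += sI
            urec[m][win] += exc_E
            lamE_acc[m][win] += lam_E
            if store_spikes:
                spk[m][t] = sE
            run_rate[m] += sE.sum()
        if (t + 1) % 2000 == 0:
            if np.any(run_rate / 2000.0 / dt > ceiling):
                raise UnstableSimulationError(
                    "E population rate exceeded the stability ceiling"
                )
            run_rate[:] = 0.0

    traces = []
    for m in range(M):
        traces.append(
            SimulationTrace(
                kind="coupled" if coupled else "ei",
                dt_ms=dt, window_ms=window_ms, tuning=config.tuning,
                counts_E=counts_E[m], ff_counts_E=ffc_E[m],
                u_rec_E=urec[m] / steps_per_win,
                lam_E=lamE_acc[m] / steps_per_win,
                counts_I=counts_I[m],
                spikes_E=spk[m] if store_spikes else None,
                input_tuning=config.input_tuning, config=config,
            )
        )
    return traces


def simulate_ei(
    ff_rates: np.ndarray,
    config: NetworkConfig,
    rng: np.random.Generator,
    T_ms: float | None = None,
    window_ms: float = 20.0,
    w_EE: float | None = None,
    refractory: bool = True,
    store_spikes: bool = False,
    deterministic_input: bool = False,
) -> SimulationTrace:
    """Simulate a single E–I ring driven by Poisson input at ``ff_rates``.

    ``w_EE`` overrides the within-ring E–E peak weight (set 0 for the pure
    feedforward regime while keeping the E–I loop that stabilizes rates).
    ``deterministic_input`` clamps the feedforward drive at its mean rate
    (no input spikes), isolating spike-generation variability.
    """
    if T_ms is None:
        T_ms = config.T_ms
    (trace,) = _ei_core(
        [np.asarray(ff_rates, dtype=float)], config, rng, T_ms, window_ms,
        w_EE_within=config.w_E if w_EE is None else w_EE,
        coupled=False, recurrent_noise=config.recurrent_noise,
        refractory=refractory, store_spikes=store_spikes,
        deterministic_input=deterministic_input,
    )
    return trace


def simulate_coupled(
    ff_rates_pair,
    config: NetworkConfig,
    rng: np.random.Generator,
    T_ms: float | None = None,
    window_ms: float = 20.0,
    refractory: bool = True,
) -> tuple[SimulationTrace, SimulationTrace]:
    """Simulate two symmetrically coupled E–I rings (weight ``config.w_mn``).

    Within a ring there are no E–E connections (uniform marginal priors);
    cross-ring excitation has the Gaussian ring profile onto E cells and an
    unstructured projection onto I cells, with no recurrent-noise term.
    """
    if T_ms is None:
        T_ms = config.T_ms
    t1, t2 = _ei_core(
        [np.asarray(r, dtype=float) for r in ff_rates_pair], config, rng,
        T_ms, window_ms, w_EE_within=0.0, coupled=True,
        recurrent_noise=False, refractory=refractory, store_spikes=False,
    )
    return t1, t2
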