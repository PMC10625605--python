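"""Reference Gibbs samplers for the hierarchical and parallel worlds.

These are plain (non-neural) samplers that alternate draws from the exact
Gaussian conditionals of each generative model.  They serve as the
algorithmic oracle that the spiking-network samplers must match: the
stationary moments of a chain converge to the analytic posterior mean and
covariance.

All conditional means are computed with wrapped differences relative to the
decoded likelihood mean, so chains stay on the ring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._ring import DEFAULT_L, circ_mean, wrap
from .generative import EmptyInputError, FeedforwardInput

__all__ = [
    "SampleChain",
    "SamplingDistribution",
    "gibbs_step_hier",
    "gibbs_step_parallel",
    "run_chain",
    "fit_distribution",
]


@dataclass
class SampleChain:
    """Time-indexed latent samples decoded from a Gibbs run or a simulation.

    ``samples`` is (n_steps, n_latents) in degrees, wrapped to (−L/2, L/2].
    ``burn_in`` initial samples are excluded by :meth:`post_burn_in`.
    ``n_skipped`` counts decoding windows that were empty (network chains).
    """

    samples: np.ndarray
    labels: tuple[str, ...]
    burn_in: int = 0
    dt_sample: float = 1.0
    L: float = DEFAULT_L
    seed: int | None = None
    n_skipped: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[0] and self.burn_in >= len(self):
            raise ValueError("burn_in must be smaller than the chain length")

    def __len__(self) -> int:
        return self.samples.shape[0]

    def post_burn_in(self) -> np.ndarray:
        return self.samples[self.burn_in:]

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        df = pd.DataFrame(self.post_burn_in(), columns=list(self.labels))
        df.insert(0, "step", np.arange(self.burn_in, len(self)))
        df["n_skipped"] = self.n_skipped
        df.to_csv(path, index=False)
        meta = {
            "seed": self.seed, "burn_in": self.burn_in,
            "dt_sample": self.dt_sample, "L": self.L, **self.meta,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1, default=str))


@dataclass(frozen=True)
class SamplingDistribution:
    """First two circular-aware moments of a sample chain.

    ``mean`` per-latent circular mean (degrees); ``cov`` covariance of
    wrapped deviations from the mean (deg², sample convention ddof=1).
    ``degenerate`` flags an all-identical chain (zero covariance).
    """

    mean: np.ndarray
    cov: np.ndarray
    n_samples: int
    degenerate: bool = False


def default_burn_in(n_steps: int) -> int:
    """10% of the chain, at least 100 samples (never the whole chain)."""
    return min(max(n_steps // 10, 100), max(n_steps - 1, 0))


def gibbs_step_hier(
    z_prev: float,
    inp: FeedforwardInput,
    Lambda_s: float,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """One alternation of the hierarchical sampler.

    s_new ~ N(s_bar, 1/(Λ_f+Λ_s)) with s_bar the precision-weighted mean of
    mu_f and z_prev; z_new ~ N(s_new, 1/Λ_s).  At Λ_s = 0 the z conditional
    is improper and z_new is drawn uniform on the ring.
    """
    if inp.empty:
        raise EmptyInputError("Gibbs step requires a non-empty input")
    Lf, Ls, L = inp.Lambda_f, float(Lambda_s), inp.tuning.L
    s_bar = inp.mu_f + Ls * wrap(z_prev - inp.mu_f, L) / (Lf + Ls)
    s_new = wrap(s_bar + rng.normal(0.0, (Lf + Ls) ** -0.5), L)
    if Ls == 0.0:
        z_new = wrap(rng.uniform(-L / 2.0, L / 2.0), L)
    else:
        z_new = wrap(s_new + rng.normal(0.0, Ls**-0.5), L)
    return s_new, z_new


def gibbs_step_parallel(
    s_other_prev: float,
    inp_m: FeedforwardInput,
    Lambda_s: float,
    rng: np.random.Generator,
) -> float:
    """One conditional draw of the parallel sampler for stimulus m:
    s_m ~ N((Λ_fm·mu_fm + Λ_s·s_other)/(Λ_fm+Λ_s), 1/(Λ_fm+Λ_s))."""
    if inp_m.empty:
        raise EmptyInputError("Gibbs step requires a non-empty input")
    Lf, Ls, L = inp_m.Lambda_f, float(Lambda_s), inp_m.tuning.L
    s_bar = inp_m.mu_f + Ls * wrap(s_other_prev - inp_m.mu_f, L) / (Lf + Ls)
    return wrap(s_bar + rng.normal(0.0, (Lf + Ls) ** -0.5), L)


def run_chain(
    model: str,
    inputs,
    Lambda_s: float,
    n_steps: int,
    burn_in: int | None = None,
    seed: int | None = None,
) -> SampleChain:
    """Run a Gibbs chain for ``model`` in {"hierarchical", "parallel"}.

    Alternation order is fixed (s then z; network 1 then network 2) and the
    chain is deterministic given ``seed``.  Initialization: z_0 = mu_f
    (hierarchical) and s_{m,0} = mu_fm (parallel) — start in the
    high-density region, matching an input-driven network at onset.
    """
    if burn_in is None:
        burn_in = default_burn_in(n_steps)
    if n_steps <= burn_in:
        raise ValueError("n_steps must exceed burn_in")
    rng = np.random.default_rng(seed)
    if model == "hierarchical":
        inp = inputs
        out = np.empty((n_steps, 2))
        z = inp.mu_f
        for t in range(n_steps):
            s, z = gibbs_step_hier(z, inp, Lambda_s, rng)
            out[t] = (s, z)
        labels = ("s", "z")
    elif model == "parallel":
        inp1, inp2 = inputs
        out = np.empty((n_steps, 2))
        s1, s2 = inp1.mu_f, inp2.mu_f
        for t in range(n_steps):
            s1 = gibbs_step_parallel(s2, inp1, Lambda_s, rng)
            s2 = gibbs_step_parallel(s1, inp2, Lambda_s, rng)
            out[t] = (s1, s2)
        labels = ("s1", "s2")
    else:
        raise ValueError(f"unknown model {model!r}")
    return SampleChain(
        samples=out, labels=labels, burn_in=burn_in, seed=seed,
        meta={"model": model, "Lambda_s": Lambda_s},
    )


def chain_mean_se(chain: SampleChain, block: int = 100) -> np.ndarray:
    """Batch-means standard error of the chain mean, per latent.

    Accounts for serial correlation by aggregating the wrapped deviations
    into non-overlapping blocks before taking the variance of block means.
    """
    x = chain.post_burn_in()
    mean = np.array(
        [
            circ_mean(col[~np.isnan(col)], L=chain.L)
            if np.any(~np.isnan(col)) else np.nan
            for col in x.T
        ]
    )
    dev = wrap(x - mean, chain.L)
    n_blocks = len(dev) // block
    if n_blocks < 2:
        raise ValueError("chain too short for batch-means SE")
    se = np.empty(dev.shape[1])
    for j in range(dev.shape[1]):
        col = dev[: n_blocks * block, j].reshape(n_blocks, block)
        bm = np.nanmean(col, axis=1)
        se[j] = np.nanstd(bm, ddof=1) / np.sqrt(n_blocks)
    return se


def fit_distribution(chain: SampleChain) -> SamplingDistribution:
    """Circular-aware mean and covariance of the post-burn-in samples.

    The mean is the per-latent resultant-vector mean; the covariance is the
    sample covariance (ddof=1) of wrapped deviations from that mean, ignoring
    nan entries (skipped windows) row-wise per latent pair.
    """
    x = chain.post_burn_in()
    if x.shape[0] < 2:
        raise ValueError("need at least 2 post-burn-in samples")
    k = x.shape[1]
    mean = np.array(
        [
            circ_mean(col[~np.isnan(col)], L=chain.L)
            if np.any(~np.isnan(col)) else np.nan
            for col in x.T
        ]
    )
    dev = wrap(x - mean, chain.L)
    cov = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            pair = dev[:, [i, j]]
            ok = ~np.isnan(pair).any(axis=1)
            d = pair[ok]
            if len(d) < 2:
                continue
            cov[i, j] = cov[j, i] = float(
                (d[:, 0] * d[:, 1]).sum() / (len(d) - 1)
                - d[:, 0].mean() * d[:, 1].mean() * len(d) / (len(d) - 1)
            )
    degenerate = bool(np.allclose(cov, 0.0))
    n = int((~np.isnan(x).any(axis=1)).sum())
    return SamplingDistribution(mean=mean, cov=cov, n_samples=n, degenerate=degenerate)
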