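"""Generative models of feedforward spiking input and their exact posteriors.

The sensory world is described by Gaussian-tuned Poisson inputs on a ring of
stimulus values.  Three generative models are implemented:

* a single-stimulus model: ``s`` drives independent Poisson counts ``u^f``
  with Gaussian tuning, so one input realization encodes a whole Gaussian
  likelihood N(s | mu_f, 1/Lambda_f) with mu_f the population-vector position
  of the counts and Lambda_f = n_f / a**2 proportional to the total count;
* a hierarchical model: a stimulus parameter ``z`` is uniform on the ring,
  the stimulus is s ~ N(z, 1/Lambda_s), and s drives the input.  The joint
  posterior p(s, z | u^f) is bivariate Gaussian with precision matrix
  [[Lambda_f + Lambda_s, −Lambda_s], [−Lambda_s, Lambda_s]];
* a parallel model: two stimuli with an improper pairwise prior
  p(s1, s2) ∝ exp[−Lambda_s (s1 − s2)² / 2] each drive their own input, and
  the posterior precision is the sum of likelihood and prior precisions.

All Gaussian formulas use wrapped (minimal-arc) differences; they are accurate
whenever the distributions are narrow relative to the ring (SD ≪ L).

This module doubles as the synthetic-data generator for the whole package:
every simulation and test consumes inputs drawn here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._ring import DEFAULT_L, circ_mean, linear_popvec, wrap

__all__ = [
    "TuningModel",
    "HierarchicalWorld",
    "ParallelWorld",
    "FeedforwardInput",
    "GaussianPosterior",
    "EmptyInputError",
    "log_tuning",
    "sample_feedforward",
    "decode_likelihood",
    "sample_world",
    "posterior_hierarchical",
    "posterior_parallel",
    "load_world",
]


class EmptyInputError(ValueError):
    """Raised when a feedforward input carries no spikes (likelihood undefined)."""


@dataclass(frozen=True)
class TuningModel:
    """Ring code: N_E preferred stimuli evenly spaced on (−L/2, L/2].

    Parameters
    ----------
    n_e : number of excitatory neurons (= number of input channels).
    a : tuning width in degrees; the log-tuning map is
        h_j(s) = −d(s, theta_j)² / (2 a²) with d the wrapped difference.
    L : length of the stimulus range in degrees (360 for orientation-like
        variables measured over the full circle).
    """

    n_e: int
    a: float
    L: float = DEFAULT_L

    def __post_init__(self):
        if self.n_e <= 0:
            raise ValueError("n_e must be positive")
        if self.a <= 0:
            raise ValueError("tuning width a must be positive")

    @property
    def spacing(self) -> float:
        return self.L / self.n_e

    @property
    def theta(self) -> np.ndarray:
        """Preferred stimuli, strictly increasing, spacing L/N_E, max = L/2."""
        j = np.arange(1, self.n_e + 1)
        return -self.L / 2.0 + j * self.spacing

    def log_tuning(self, s: float) -> np.ndarray:
        """h(s): log firing-rate profile; all entries ≤ 0, zero at theta_j = s."""
        if not np.isfinite(s):
            raise ValueError("stimulus must be finite")
        d = wrap(s - self.theta, self.L)
        return -(d**2) / (2.0 * self.a**2)

    def profile(self, s: float, peak: float = 1.0) -> np.ndarray:
        """Gaussian population profile peak·exp[h(s)]."""
        return peak * np.exp(self.log_tuning(s))


def log_tuning(tuning: TuningModel, s: float) -> np.ndarray:
    """Module-level alias for :meth:`TuningModel.log_tuning`."""
    return tuning.log_tuning(s)


@dataclass(frozen=True)
class HierarchicalWorld:
    """Hierarchical world: z ~ Uniform(ring), s | z ~ N(z, 1/Lambda_s).

    ``Lambda_s`` (deg⁻²) is the prior precision coupling stimulus and stimulus
    parameter; ``U_f`` is the peak mean feedforward count per draw.
    """

    Lambda_s: float
    U_f: float
    tuning: TuningModel

    def __post_init__(self):
        if self.Lambda_s < 0:
            raise ValueError("Lambda_s must be >= 0")
        if self.U_f <= 0:
            raise ValueError("U_f must be > 0")


@dataclass(frozen=True)
class ParallelWorld:
    """Two-stimulus world with improper pairwise prior ∝ exp[−Λ_s(s1−s2)²/2].

    The prior precision matrix Λ_s·[[1,−1],[−1,1]] is singular by
    construction: only the difference s1 − s2 is constrained, each marginal
    is uniform on the ring.  Both networks share one tuning model.
    """

    Lambda_s: float
    U_f: float
    tuning: TuningModel

    def __post_init__(self):
        if self.Lambda_s < 0:
            raise ValueError("Lambda_s must be >= 0")
        if self.U_f <= 0:
            raise ValueError("U_f must be > 0")

    @property
    def prior_precision(self) -> np.ndarray:
        return self.Lambda_s * np.array([[1.0, -1.0], [-1.0, 1.0]])


@dataclass(frozen=True)
class FeedforwardInput:
    """One realization of Poisson input counts with its decoded likelihood.

    ``mu_f`` is the circular population-vector mean of the counts (degrees),
    ``Lambda_f = n_f / a²`` the likelihood precision (deg⁻²), ``n_f`` the
    total count.  ``empty`` flags the n_f = 0 case in which the likelihood
    is undefined (Lambda_f = 0, mu_f = nan).
    """

    counts: np.ndarray
    tuning: TuningModel
    mu_f: float
    Lambda_f: float
    n_f: int
    seed: int | None = None

    @property
    def empty(self) -> bool:
        return self.n_f == 0

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        pd.DataFrame(
            {
                "neuron_index": np.arange(self.tuning.n_e),
                "theta_deg": self.tuning.theta,
                "count": self.counts.astype(int),
            }
        ).to_csv(path, index=False)
        sidecar = {
            "mu_f": None if self.empty else float(self.mu_f),
            "Lambda_f": float(self.Lambda_f),
            "n_f": int(self.n_f),
            "a_deg": self.tuning.a,
            "L_deg": self.tuning.L,
            "seed": self.seed,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeedforwardInput":
        path = Path(path)
        df = pd.read_csv(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        tuning = TuningModel(n_e=len(df), a=meta["a_deg"], L=meta["L_deg"])
        return decode_likelihood(df["count"].to_numpy(), tuning, seed=meta.get("seed"))


@dataclass(frozen=True)
class GaussianPosterior:
    """Analytic Gaussian posterior: mean vector (degrees), precision (deg⁻²).

    ``degenerate`` marks the Λ_s = 0 hierarchical case where the stimulus
    parameter z has a uniform marginal and K_p is singular; ``mu_p`` and
    ``K_p`` then describe the proper s-marginal only (z slot is nan / zero
    row).
    """

    mu_p: np.ndarray
    K_p: np.ndarray
    labels: tuple[str, ...]
    L: float = DEFAULT_L
    degenerate: bool = False

    def __post_init__(self):
        K = np.asarray(self.K_p, dtype=float)
        if not np.allclose(K, K.T):
            raise ValueError("precision matrix must be symmetric")

    def cov(self) -> np.ndarray:
        if self.degenerate:
            raise np.linalg.LinAlgError("degenerate posterior has no covariance")
        return np.linalg.inv(self.K_p)

    def marginal(self, label: str) -> tuple[float, float]:
        """(mean, variance) of one latent's marginal."""
        i = self.labels.index(label)
        if self.degenerate and label == "s":
            return float(self.mu_p[i]), 1.0 / float(self.K_p[i, i])
        return float(self.mu_p[i]), float(self.cov()[i, i])


def sample_feedforward(world, s: float, rng: np.random.Generator) -> FeedforwardInput:
    """Draw u^f_j ~ Poisson(U_f · exp[h_j(s)]) and decode its likelihood."""
    tuning = world.tuning
    if not np.isfinite(s):
        raise ValueError("stimulus must be finite")
    rates = world.U_f * np.exp(tuning.log_tuning(s))
    counts = rng.poisson(rates)
    return decode_likelihood(counts, tuning)


def decode_likelihood(
    counts: np.ndarray, tuning: TuningModel, seed: int | None = None
) -> FeedforwardInput:
    """Decode (mu_f, Lambda_f) from a count vector.

    mu_f is the population-vector mean over preferred stimuli — the
    wrap-safe linear weighted mean, which is the exact mean of the Gaussian
    likelihood encoded by log-linear Poisson activity — and
    Lambda_f = n_f / a² exactly.  An all-zero vector is flagged empty.
    """
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    n_f = int(counts.sum())
    if n_f == 0:
        return FeedforwardInput(
            counts=counts, tuning=tuning, mu_f=float("nan"), Lambda_f=0.0,
            n_f=0, seed=seed,
        )
    mu_f = linear_popvec(tuning.theta, counts, L=tuning.L)
    Lambda_f = n_f / tuning.a**2
    return FeedforwardInput(
        counts=counts, tuning=tuning, mu_f=mu_f, Lambda_f=Lambda_f,
        n_f=n_f, seed=seed,
    )


def sample_world(world, rng: np.random.Generator):
    """Draw latents and feedforward input(s) from a world model.

    Hierarchical: returns ``(s, z, input)`` with z uniform on the ring and
    s ~ N(z, 1/Lambda_s) wrapped (s uniform in the Lambda_s = 0 limit).

    Parallel: returns ``((s1, s2), (input1, input2))``; the improper prior is
    realized by a uniform common center z0 and a difference
    delta ~ N(0, 1/Lambda_s), s_{1,2} = z0 ± delta/2, which reproduces the
    stated density of s1 − s2 and uniform marginals.
    """
    L = world.tuning.L
    if isinstance(world, HierarchicalWorld):
        z = wrap(rng.uniform(-L / 2.0, L / 2.0), L)
        if world.Lambda_s == 0:
            s = wrap(rng.uniform(-L / 2.0, L / 2.0), L)
        else:
            s = wrap(z + rng.normal(0.0, world.Lambda_s**-0.5), L)
        return s, z, sample_feedforward(world, s, rng)
    if isinstance(world, ParallelWorld):
        z0 = rng.uniform(-L / 2.0, L / 2.0)
        if world.Lambda_s == 0:
            # independent limit: both stimuli uniform
            s1 = wrap(rng.uniform(-L / 2.0, L / 2.0), L)
            s2 = wrap(rng.uniform(-L / 2.0, L / 2.0), L)
        else:
            delta = rng.normal(0.0, world.Lambda_s**-0.5)
            s1, s2 = wrap(z0 + delta / 2.0, L), wrap(z0 - delta / 2.0, L)
        inp1 = sample_feedforward(world, s1, rng)
        inp2 = sample_feedforward(world, s2, rng)
        return (s1, s2), (inp1, inp2)
    raise TypeError(f"unsupported world type {type(world).__name__}")


def posterior_hierarchical(inp: FeedforwardInput, Lambda_s: float) -> GaussianPosterior:
    """Joint posterior of (s, z) given one input draw.

    mu_p = (mu_f, mu_f), K_p = [[Λ_f+Λ_s, −Λ_s], [−Λ_s, Λ_s]].  At Λ_s = 0
    the z marginal is uniform and the returned posterior is flagged
    degenerate (s-marginal N(mu_f, 1/Λ_f), zero z block).
    """
    if inp.empty:
        raise EmptyInputError("cannot form a posterior from an empty input")
    Lf, Ls = inp.Lambda_f, float(Lambda_s)
    if Ls < 0:
        raise ValueError("Lambda_s must be >= 0")
    K = np.array([[Lf + Ls, -Ls], [-Ls, Ls]])
    mu = np.array([inp.mu_f, inp.mu_f])
    return GaussianPosterior(
        mu_p=mu, K_p=K, labels=("s", "z"), L=inp.tuning.L, degenerate=(Ls == 0.0)
    )


def posterior_parallel(
    inputs: tuple[FeedforwardInput, FeedforwardInput], Lambda_s: float
) -> GaussianPosterior:
    """Joint posterior of (s1, s2) for the parallel model.

    K_p = diag(Λ_f1, Λ_f2) + Λ_s·[[1,−1],[−1,1]];
    mu_p = K_p⁻¹ · diag(Λ_f)·(mu_f1, mu_f2), computed in wrapped coordinates
    around the circular mean of the two likelihood means.
    """
    inp1, inp2 = inputs
    if inp1.empty or inp2.empty:
        raise EmptyInputError("cannot form a posterior from an empty input")
    Ls = float(Lambda_s)
    if Ls < 0:
        raise ValueError("Lambda_s must be >= 0")
    Lf = np.array([inp1.Lambda_f, inp2.Lambda_f])
    K = np.diag(Lf) + Ls * np.array([[1.0, -1.0], [-1.0, 1.0]])
    if np.linalg.det(K) <= 0:
        raise np.linalg.LinAlgError("singular posterior precision")
    L = inp1.tuning.L
    ref = circ_mean([inp1.mu_f, inp2.mu_f], L=L)
    d = wrap(np.array([inp1.mu_f, inp2.mu_f]) - ref, L)
    mu = wrap(ref + np.linalg.solve(K, Lf * d), L)
    return GaussianPosterior(mu_p=mu, K_p=K, labels=("s1", "s2"), L=L)


def load_world(path: str | Path):
    """Read a world model from a YAML config.

    Keys: ``N_E, a_deg, L_deg, U_f, Lambda_s, seed`` and optional
    ``model: hierarchical|parallel`` (default hierarchical).  Returns
    ``(world, seed)``.
    """
    cfg = yaml.safe_load(Path(path).read_text())
    tuning = TuningModel(
        n_e=int(cfg["N_E"]), a=float(cfg["a_deg"]), L=float(cfg.get("L_deg", DEFAULT_L))
    )
    cls = {"hierarchical": HierarchicalWorld, "parallel": ParallelWorld}[
        cfg.get("model", "hierarchical")
    ]
    world = cls(Lambda_s=float(cfg["Lambda_s"]), U_f=float(cfg["U_f"]), tuning=tuning)
    return world, cfg.get("seed")
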