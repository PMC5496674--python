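"""Data-augmented Metropolis–Hastings-within-Gibbs sampler.

Targets the joint posterior of the trajectory parameters ``(alpha, beta,
delta, tau)`` and the per-individual latent class labels ``r_i`` given a
longitudinal dataset with a known, common change-point ``c``.  Priors are
vague and proper: Normal(0, 10^2) on ``alpha`` and ``beta``, a half-normal
with scale 10 restricted to the negative reals on ``delta``, Gamma(1, 1) on
``tau``, and independent Bernoulli(``p_r``) on each label.

One sweep updates ``alpha``, ``beta``, ``delta`` and ``tau`` by scalar
Metropolis–Hastings moves, then redraws every label from its exact full
conditional (a Gibbs step).  ``alpha``, ``beta`` and ``tau`` use symmetric
Gaussian random walks; ``delta`` uses a multiplicative log-normal proposal
(which preserves its negative sign) with the corresponding asymmetric
Hastings correction ``|delta'| / |delta|``.  Every proposal standard
deviation is shrunk by ``f(n) = log(25) / log(n)`` so mixing stays comparable
across the sample sizes of a design study.

The sweep itself is compiled with numba; :func:`mh_update_scalar` and
:func:`update_labels` expose the identical single-step mathematics in plain
NumPy for testing and inspection.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from .simulate import LongitudinalDataset

__all__ = [
    "ChainSettings",
    "ChainState",
    "PosteriorChain",
    "f_scale",
    "log_prior",
    "mh_update_scalar",
    "label_change_probabilities",
    "update_labels",
    "run_chain",
    "write_chain",
    "read_chain",
]

_LOG_2PI = math.log(2.0 * math.pi)
_PARAMS = ("alpha", "beta", "delta", "tau")


@dataclass(frozen=True)
class ChainSettings:
    """MCMC run length, proposal dispersions and prior hyperparameters.

    Defaults: 10^5 iterations with the first 10^3 discarded as burn-in and
    every 50th retained thereafter, giving 1980 retained draws.  Proposal
    base scales are multiplied by ``f_scale(n)`` at run time.
    """

    iterations: int = 100_000
    burn_in: int = 1_000
    thin: int = 50
    scale_alpha: float = 1.2
    scale_beta: float = 0.85
    scale_delta: float = 1.0
    scale_tau: float = 0.85
    prior_sd_alpha: float = 10.0
    prior_sd_beta: float = 10.0
    prior_scale_delta: float = 10.0
    prior_tau_shape: float = 1.0
    prior_tau_rate: float = 1.0
    delta_proposal_correction: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.burn_in >= self.iterations:
            raise ValueError("require 0 <= burn_in < iterations")
        if self.thin < 1:
            raise ValueError("thin must be at least 1")
        for name in (
            "scale_alpha", "scale_beta", "scale_delta", "scale_tau",
            "prior_sd_alpha", "prior_sd_beta", "prior_scale_delta",
            "prior_tau_shape", "prior_tau_rate",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_retained < 1:
            raise ValueError("settings retain no draws; lengthen the chain")

    @property
    def n_retained(self) -> int:
        """Number of retained draws, ``(iterations - burn_in) // thin``."""
        return (self.iterations - self.burn_in) // self.thin

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ChainSettings":
        return cls(**d)


@dataclass
class ChainState:
    """Mutable parameter state threaded through single-step updates."""

    alpha: float
    beta: float
    delta: float
    tau: float
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if not self.delta < 0:
            raise ValueError("delta must be strictly negative")
        if not self.tau > 0:
            raise ValueError("tau must be positive")


def f_scale(n: int) -> float:
    """Sample-size scaling ``log(25) / log(n)`` for proposal dispersions.

    Lies in (0, 1] for n >= 25 and decreases with n, shrinking proposals as
    the posterior tightens.  Defined for all n >= 2; values above 1 (n < 25)
    are permitted with a warning since design studies rarely go that small.
    """
    if n < 2:
        raise ValueError(f"f_scale requires n >= 2, got {n}")
    if n < 25:
        warnings.warn(
            f"f_scale({n}) = {math.log(25) / math.log(n):.3f} > 1: "
            "proposal scales are inflated below n = 25",
            stacklevel=2,
        )
    return math.log(25.0) / math.log(n)


def log_prior(shape, settings: Optional[ChainSettings] = None) -> float:
    """Joint log prior density of ``(alpha, beta, delta, tau)``.

    ``shape`` is anything exposing ``alpha``, ``beta``, ``delta`` and ``tau``
    attributes.  Returns ``-inf`` outside the support (``delta >= 0`` or
    ``tau <= 0``).
    """
    s = settings or ChainSettings()
    alpha, beta = float(shape.alpha), float(shape.beta)
    delta, tau = float(shape.delta), float(shape.tau)
    if delta >= 0 or tau <= 0:
        return -np.inf
    lp = stats.norm.logpdf(alpha, scale=s.prior_sd_alpha)
    lp += stats.norm.logpdf(beta, scale=s.prior_sd_beta)
    # half-normal on the negative axis: 2 phi(delta / scale) / scale
    lp += stats.halfnorm.logpdf(-delta, scale=s.prior_scale_delta)
    lp += stats.gamma.logpdf(tau, a=s.prior_tau_shape, scale=1.0 / s.prior_tau_rate)
    return float(lp)


# ---------------------------------------------------------------------------
# Flattened design helpers shared by the reference updates and the kernel.
# ---------------------------------------------------------------------------

def _design_arrays(data: LongitudinalDataset, change_point: float):
    """Return (y, t, u, indptr) where u = max(t - c, 0) per observation."""
    y = np.ascontiguousarray(data.outcomes, dtype=np.float64)
    t = np.ascontiguousarray(data.times, dtype=np.float64)
    u = np.maximum(t - change_point, 0.0)
    indptr = np.ascontiguousarray(data.indptr, dtype=np.int64)
    return y, t, u, indptr


def _ssr(y, t, u, obs_labels, alpha, beta, delta) -> float:
    resid = y - alpha - beta * t - delta * (u * obs_labels)
    return float(resid @ resid)


def _log_post_terms(ssr: float, n_obs: int, state_val: dict, s: ChainSettings) -> float:
    """Log likelihood + log prior (up to label terms, which cancel in MH)."""
    tau = state_val["tau"]
    if tau <= 0 or state_val["delta"] >= 0:
        return -np.inf
    ll = 0.5 * n_obs * (math.log(tau) - _LOG_2PI) - 0.5 * tau * ssr
    lp = (
        -0.5 * state_val["alpha"] ** 2 / s.prior_sd_alpha**2
        - 0.5 * state_val["beta"] ** 2 / s.prior_sd_beta**2
        - 0.5 * state_val["delta"] ** 2 / s.prior_scale_delta**2
        + (s.prior_tau_shape - 1.0) * math.log(tau)
        - s.prior_tau_rate * tau
    )
    return ll + lp


def mh_update_scalar(
    which: str,
    state: ChainState,
    data: LongitudinalDataset,
    change_point: float,
    settings: ChainSettings,
    rng: np.random.Generator,
) -> Tuple[float, bool]:
    """One Metropolis–Hastings step for a single trajectory parameter.

    ``alpha``, ``beta`` and ``tau`` use symmetric Gaussian random walks with
    standard deviation ``f_scale(n) * base_scale`` (no Hastings correction;
    ``tau`` proposals at or below zero are rejected through the prior's zero
    density).  ``delta`` is updated multiplicatively, ``delta' = delta * X``
    with ``log X ~ Normal(0, (f_scale(n) * base)^2)``, which keeps the
    negative sign; the acceptance ratio includes the asymmetric-proposal
    correction ``|delta'| / |delta|``.

    Returns ``(new_value, accepted)`` without mutating ``state``.
    """
    if which not in _PARAMS:
        raise ValueError(f"unknown parameter {which!r}; expected one of {_PARAMS}")
    y, t, u, _ = _design_arrays(data, change_point)
    obs_labels = state.labels[data.obs_individual].astype(np.float64)
    n_obs = y.size
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f = f_scale(data.n)

    cur = {p: float(getattr(state, p)) for p in _PARAMS}
    prop = dict(cur)
    log_hastings = 0.0
    if which == "alpha":
        prop["alpha"] = cur["alpha"] + f * settings.scale_alpha * rng.normal()
    elif which == "beta":
        prop["beta"] = cur["beta"] + f * settings.scale_beta * rng.normal()
    elif which == "delta":
        ratio = math.exp(f * settings.scale_delta * rng.normal())
        prop["delta"] = cur["delta"] * ratio
        if settings.delta_proposal_correction:
            log_hastings = math.log(abs(prop["delta"]) / abs(cur["delta"]))
    else:  # tau
        prop["tau"] = cur["tau"] + f * settings.scale_tau * rng.normal()

    ssr_cur = _ssr(y, t, u, obs_labels, cur["alpha"], cur["beta"], cur["delta"])
    ssr_prop = _ssr(y, t, u, obs_labels, prop["alpha"], prop["beta"], prop["delta"])
    log_ratio = (
        _log_post_terms(ssr_prop, n_obs, prop, settings)
        - _log_post_terms(ssr_cur, n_obs, cur, settings)
        + log_hastings
    )
    if math.log(rng.random()) < log_ratio:
        return prop[which], True
    return cur[which], False


def label_change_probabilities(
    data: LongitudinalDataset,
    change_point: float,
    state: ChainState,
    p_r: float,
) -> np.ndarray:
    """Exact full-conditional change probability of every latent label.

    For individual ``i``, ``P(r_i = 1 | rest) = p_r L_i1 / (p_r L_i1 +
    (1 - p_r) L_i0)`` where ``L_i1`` and ``L_i0`` are the individual's
    likelihood under each label.  Only observations past the change-point
    distinguish the labels, so an individual with none sits at exactly
    ``p_r``.  Computed on the log scale.
    """
    if p_r >= 1.0:
        return np.ones(data.n)
    if p_r <= 0.0:
        return np.zeros(data.n)
    y, t, u, indptr = _design_arrays(data, change_point)
    logit_pr = math.log(p_r) - math.log1p(-p_r)
    e0 = y - state.alpha - state.beta * t
    e1 = e0 - state.delta * u
    per_obs = e1 * e1 - e0 * e0  # SSR_i1 - SSR_i0 contributions
    diff = np.add.reduceat(per_obs, indptr[:-1])
    diff[np.diff(indptr) == 0] = 0.0
    logits = logit_pr - 0.5 * state.tau * diff
    return 1.0 / (1.0 + np.exp(-logits))


def update_labels(
    data: LongitudinalDataset,
    change_point: float,
    state: ChainState,
    p_r: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gibbs draw of every latent label from its exact full conditional.

    Each label is drawn independently with success probability
    :func:`label_change_probabilities`.
    """
    p1 = label_change_probabilities(data, change_point, state, p_r)
    return (rng.random(data.n) < p1).astype(np.int8)


# ---------------------------------------------------------------------------
# Compiled sweep.
# ---------------------------------------------------------------------------

@njit(cache=True)
def _chain_kernel(
    y, t, u, indptr, labels0,
    alpha, beta, delta, tau,
    p_r, iterations, burn_in, thin,
    sa, sb, sd, st,
    var_a, var_b, var_d, tau_shape, tau_rate,
    delta_jacobian, seed,
):  # pragma: no cover - exercised through run_chain
    np.random.seed(seed)
    n = indptr.size - 1
    n_obs = y.size
    r = labels0.copy()
    w = np.zeros(n_obs)
    for i in range(n):
        if r[i] == 1:
            for j in range(indptr[i], indptr[i + 1]):
                w[j] = u[j]
    ssr = 0.0
    for j in range(n_obs):
        e = y[j] - alpha - beta * t[j] - delta * w[j]
        ssr += e * e

    n_keep = (iterations - burn_in) // thin
    out = np.empty((n_keep, 4))
    label_acc = np.zeros(n)
    acc = np.zeros(4)
    if p_r >= 1.0:
        logit_pr = np.inf
    elif p_r <= 0.0:
        logit_pr = -np.inf
    else:
        logit_pr = np.log(p_r) - np.log(1.0 - p_r)

    kept = 0
    for it in range(1, iterations + 1):
        # alpha: symmetric Gaussian walk
        prop = alpha + sa * np.random.normal(0.0, 1.0)
        ssr_p = 0.0
        for j in range(n_obs):
            e = y[j] - prop - beta * t[j] - delta * w[j]
            ssr_p += e * e
        logr = (
            -0.5 * tau * (ssr_p - ssr)
            - 0.5 * (prop * prop - alpha * alpha) / var_a
        )
        if np.log(np.random.random()) < logr:
            alpha = prop
            ssr = ssr_p
            acc[0] += 1.0

        # beta: symmetric Gaussian walk
        prop = beta + sb * np.random.normal(0.0, 1.0)
        ssr_p = 0.0
        for j in range(n_obs):
            e = y[j] - alpha - prop * t[j] - delta * w[j]
            ssr_p += e * e
        logr = (
            -0.5 * tau * (ssr_p - ssr)
            - 0.5 * (prop * prop - beta * beta) / var_b
        )
        if np.log(np.random.random()) < logr:
            beta = prop
            ssr = ssr_p
            acc[1] += 1.0

        # delta: multiplicative log-normal walk, Hastings term |d'|/|d|
        prop = delta * np.exp(sd * np.random.normal(0.0, 1.0))
        ssr_p = 0.0
        for j in range(n_obs):
            e = y[j] - alpha - beta * t[j] - prop * w[j]
            ssr_p += e * e
        logr = (
            -0.5 * tau * (ssr_p - ssr)
            - 0.5 * (prop * prop - delta * delta) / var_d
            + delta_jacobian * np.log(np.abs(prop) / np.abs(delta))
        )
        if np.log(np.random.random()) < logr:
            delta = prop
            ssr = ssr_p
            acc[2] += 1.0

        # tau: symmetric Gaussian walk; prop <= 0 rejected by zero prior
        prop = tau + st * np.random.normal(0.0, 1.0)
        if prop > 0.0:
            logr = (
                0.5 * n_obs * (np.log(prop) - np.log(tau))
                - 0.5 * (prop - tau) * ssr
                + (tau_shape - 1.0) * (np.log(prop) - np.log(tau))
                - tau_rate * (prop - tau)
            )
            if np.log(np.random.random()) < logr:
                tau = prop
                acc[3] += 1.0

        # labels: exact Gibbs from the full conditional
        changed = False
        for i in range(n):
            d = 0.0
            for j in range(indptr[i], indptr[i + 1]):
                if u[j] > 0.0:
                    e0 = y[j] - alpha - beta * t[j]
                    e1 = e0 - delta * u[j]
                    d += e1 * e1 - e0 * e0
            if logit_pr == np.inf:
                newr = 1
            elif logit_pr == -np.inf:
                newr = 0
            else:
                lo = logit_pr - 0.5 * tau * d
                if lo >= 0.0:
                    p1 = 1.0 / (1.0 + np.exp(-lo))
                else:
                    el = np.exp(lo)
                    p1 = el / (1.0 + el)
                newr = 1 if np.random.random() < p1 else 0
            if newr != r[i]:
                r[i] = newr
                changed = True
                for j in range(indptr[i], indptr[i + 1]):
                    w[j] = u[j] if newr == 1 else 0.0
        if changed:
            ssr = 0.0
            for j in range(n_obs):
                e = y[j] - alpha - beta * t[j] - delta * w[j]
                ssr += e * e

        if it > burn_in and (it - burn_in) % thin == 0:
            out[kept, 0] = alpha
            out[kept, 1] = beta
            out[kept, 2] = delta
            out[kept, 3] = tau
            for i in range(n):
                label_acc[i] += r[i]
            kept += 1

    return out, label_acc / n_keep, acc / iterations


@dataclass
class PosteriorChain:
    """Retained posterior draws plus per-individual label probabilities."""

    draws_alpha: np.ndarray
    draws_beta: np.ndarray
    draws_delta: np.ndarray
    draws_tau: np.ndarray
    label_prob: np.ndarray
    acceptance_rates: dict
    n_fitted: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.draws_tau <= 0):
            raise ValueError("all retained tau draws must be positive")
        if np.any(self.draws_delta >= 0):
            raise ValueError("all retained delta draws must be negative")
        if np.any((self.label_prob < 0) | (self.label_prob > 1)):
            raise ValueError("label probabilities must lie in [0, 1]")

    @property
    def n_retained(self) -> int:
        return int(self.draws_alpha.size)

    def draws(self, which: str) -> np.ndarray:
        if which not in _PARAMS:
            raise ValueError(f"unknown parameter {which!r}")
        return getattr(self, f"draws_{which}")

    def posterior_median(self, which: str) -> float:
        return float(np.median(self.draws(which)))

    def posterior_variance(self, which: str) -> float:
        return float(np.var(self.draws(which), ddof=1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "alpha": self.draws_alpha,
                "beta": self.draws_beta,
                "delta": self.draws_delta,
                "tau": self.draws_tau,
            }
        )


def run_chain(
    data: LongitudinalDataset,
    settings: ChainSettings,
    change_point: float,
    p_change: float = 0.5,
) -> PosteriorChain:
    """Run the full data-augmented sampler on one dataset.

    Each iteration performs the four scalar Metropolis–Hastings updates and
    one Gibbs sweep over all labels.  The first ``burn_in`` iterations are
    discarded and every ``thin``-th iteration retained thereafter.  Per-
    individual change probabilities are the mean of the retained label draws.

    Initialisation: ``alpha`` at the mean first-wave outcome, ``beta`` at the
    pooled least-squares slope of the pre-change-point observations,
    ``delta = -0.1``, ``tau = 1`` and labels drawn Bernoulli(``p_change``).
    The sampler reads only times and outcomes — never the truth columns.
    """
    if data.n < 1 or data.n_obs < 1:
        raise ValueError("dataset must contain at least one observation")
    if not 0.0 <= p_change <= 1.0:
        raise ValueError(f"p_change must lie in [0, 1], got {p_change}")
    y, t, u, indptr = _design_arrays(data, change_point)
    f = f_scale(data.n)

    # initial values: cheap, data-driven for the linear part
    first_idx = indptr[:-1]
    alpha0 = float(np.mean(y[first_idx]))
    pre = t <= change_point
    if np.unique(t[pre]).size >= 2:
        beta0 = float(np.polyfit(t[pre], y[pre], 1)[0])
    else:
        beta0 = 0.0
    delta0, tau0 = -0.1, 1.0

    root = np.random.SeedSequence(int(settings.seed) & 0x7FFFFFFF)
    init_ss, kernel_ss = root.spawn(2)
    init_rng = np.random.default_rng(init_ss)
    labels0 = (init_rng.random(data.n) < p_change).astype(np.int8)
    kernel_seed = int(kernel_ss.generate_state(1)[0] & 0x7FFFFFFF)

    out, label_prob, acc = _chain_kernel(
        y, t, u, indptr, labels0,
        alpha0, beta0, delta0, tau0,
        float(p_change),
        int(settings.iterations), int(settings.burn_in), int(settings.thin),
        f * settings.scale_alpha, f * settings.scale_beta,
        f * settings.scale_delta, f * settings.scale_tau,
        settings.prior_sd_alpha**2, settings.prior_sd_beta**2,
        settings.prior_scale_delta**2,
        settings.prior_tau_shape, settings.prior_tau_rate,
        1.0 if settings.delta_proposal_correction else 0.0,
        kernel_seed,
    )
    meta = {
        "settings": settings.to_dict(),
        "change_point": change_point,
        "p_change": p_change,
        "f_scale": f,
        "init": {"alpha": alpha0, "beta": beta0, "delta": delta0, "tau": tau0},
    }
    return PosteriorChain(
        draws_alpha=out[:, 0],
        draws_beta=out[:, 1],
        draws_delta=out[:, 2],
        draws_tau=out[:, 3],
        label_prob=label_prob,
        acceptance_rates={p: float(a) for p, a in zip(_PARAMS, acc)},
        n_fitted=data.n,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Chain round-trip: draws CSV + label probabilities CSV + JSON sidecar.
# ---------------------------------------------------------------------------

def write_chain(chain: PosteriorChain, prefix) -> dict:
    """Write ``<prefix>_draws.csv``, ``<prefix>_labels.csv`` and
    ``<prefix>_meta.json``; returns the paths written."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "draws": prefix.with_name(prefix.name + "_draws.csv"),
        "labels": prefix.with_name(prefix.name + "_labels.csv"),
        "meta": prefix.with_name(prefix.name + "_meta.json"),
    }
    chain.to_frame().to_csv(paths["draws"], index=False)
    pd.DataFrame(
        {"individual_id": np.arange(chain.label_prob.size),
         "p_change": chain.label_prob}
    ).to_csv(paths["labels"], index=False)
    meta = dict(chain.meta)
    meta["acceptance_rates"] = chain.acceptance_rates
    meta["n_fitted"] = chain.n_fitted
    paths["meta"].write_text(json.dumps(meta, indent=2))
    return {k: str(v) for k, v in paths.items()}


def read_chain(prefix) -> PosteriorChain:
    prefix = Path(prefix)
    draws = pd.read_csv(prefix.with_name(prefix.name + "_draws.csv"))
    labels = pd.read_csv(prefix.with_name(prefix.name + "_labels.csv"))
    meta = json.loads(prefix.with_name(prefix.name + "_meta.json").read_text())
    acceptance = meta.pop("acceptance_rates")
    n_fitted = meta.pop("n_fitted")
    return PosteriorChain(
        draws_alpha=draws["alpha"].to_numpy(),
        draws_beta=draws["beta"].to_numpy(),
        draws_delta=draws["delta"].to_numpy(),
        draws_tau=draws["tau"].to_numpy(),
        label_prob=labels["p_change"].to_numpy(),
        acceptance_rates=acceptance,
        n_fitted=int(n_fitted),
        meta=meta,
    )
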