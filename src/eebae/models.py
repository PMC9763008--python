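"""Psychometric response models.

A psychometric function maps a physical stimulus ``d`` and a subject
parameter vector ``theta`` to the probability of a binary response
``y = 1`` (accept / correct).  Two classic models are provided:

* the contrast sensitivity function (CSF) — a truncated log-parabola
  giving log10 grating sensitivity versus spatial frequency, wrapped in a
  detection-probability form with a lapse-bounded upper asymptote; and
* the gap acceptance function (GAF) — a probit model
  ``Phi((d - t_cr) / sigma)`` for a driver accepting a traffic gap of
  ``d`` seconds.

Every downstream component (gridding, information computation, the trial
loop) depends only on the :class:`PsychometricModel` contract, so further
models plug in by implementing ``response_prob``.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass
from typing import ClassVar

import numpy as np
from scipy.special import ndtr

from .errors import ModelError

__all__ = [
    "CSFParams",
    "CSFStimulus",
    "GAFParams",
    "GAFStimulus",
    "PsychometricModel",
    "CSFModel",
    "GAFModel",
    "csf_log_parabola",
    "csf_sensitivity",
    "csf_response_prob",
    "gaf_response_prob",
    "likelihood",
    "DEFAULT_LAPSE_BOUND",
]

#: log10(2); curvature constant kappa of the log-parabola.
LOG10_2: float = float(np.log10(2.0))

#: Default lapse bound mu: the CSF response probability is capped at 1 - mu.
DEFAULT_LAPSE_BOUND: float = 0.04


# ---------------------------------------------------------------------------
# parameter / stimulus containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CSFParams:
    """CSF parameter vector.

    gamma_max : peak sensitivity (dimensionless gain)
    f_max     : peak spatial frequency, cycles/degree
    beta1     : bandwidth, octaves
    delta1    : low-frequency truncation depth, log10 sensitivity units
    """

    gamma_max: float
    f_max: float
    beta1: float
    delta1: float

    def __post_init__(self) -> None:
        for name in ("gamma_max", "f_max", "beta1", "delta1"):
            v = np.asarray(getattr(self, name), dtype=float)
            if not (np.all(np.isfinite(v)) and np.all(v > 0)):
                raise ModelError(f"CSF parameter {name!r} must be finite and > 0")

    @property
    def kappa(self) -> float:
        return LOG10_2

    @property
    def beta_prime(self) -> float:
        """log10(2 * beta1); half of it is the log-frequency half-bandwidth."""
        return float(np.log10(2.0 * self.beta1))


@dataclass(frozen=True)
class CSFStimulus:
    """Grating stimulus in log10 units: spatial frequency and contrast."""

    log_f: float
    log_c: float

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.log_f)) and np.all(np.isfinite(self.log_c))):
            raise ModelError("CSF stimulus components must be finite")


@dataclass(frozen=True)
class GAFParams:
    """Gap-acceptance parameters: critical-gap mean (s) and spread (s)."""

    t_cr: float
    sigma: float

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.t_cr)) and np.all(np.isfinite(self.sigma))):
            raise ModelError("GAF parameters must be finite")
        if not np.all(np.asarray(self.sigma) > 0):
            raise ModelError("GAF spread sigma must be > 0")


@dataclass(frozen=True)
class GAFStimulus:
    """Offered traffic gap in seconds."""

    gap: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.gap)):
            raise ModelError("gap must be finite")


# ---------------------------------------------------------------------------
# array-level kernels (shared by the scalar API and the vectorized models)
# ---------------------------------------------------------------------------


def _csf_sprime(gamma_max, f_max, beta1, log_f):
    beta_prime = np.log10(2.0 * np.asarray(beta1, dtype=float))
    offset = np.asarray(log_f, dtype=float) - np.log10(f_max)
    return np.log10(gamma_max) - LOG10_2 * (offset / (beta_prime / 2.0)) ** 2


def _csf_sensitivity(gamma_max, f_max, beta1, delta1, log_f):
    sprime = _csf_sprime(gamma_max, f_max, beta1, log_f)
    plateau = np.log10(gamma_max) - delta1
    low_freq = np.asarray(log_f, dtype=float) < np.log10(f_max)
    return np.where(low_freq & (sprime < plateau), plateau, sprime)


def _csf_prob(sensitivity, log_c, mu):
    # min(1 - mu, 0.5 + 0.5 * 10^(2 (S + log10 c))): guess rate 0.5 at zero
    # contrast, lapse-bounded ceiling 1 - mu once contrast exceeds threshold.
    inner = 0.5 + 0.5 * 10.0 ** (2.0 * (np.asarray(sensitivity, float) + np.asarray(log_c, float)))
    return np.minimum(1.0 - mu, inner)


def _gaf_prob(t_cr, sigma, gap):
    return ndtr((np.asarray(gap, dtype=float) - t_cr) / sigma)


# ---------------------------------------------------------------------------
# scalar operations
# ---------------------------------------------------------------------------


def csf_log_parabola(params: CSFParams, log_f) -> float:
    """Log-parabola S'(f): log10 sensitivity before low-frequency truncation.

    ``S'(f) = log10(gamma_max) - kappa * ((log_f - log10 f_max) / (beta'/2))^2``
    with ``kappa = log10 2`` and ``beta' = log10(2 beta1)``.
    """
    if not np.all(np.isfinite(np.asarray(log_f, dtype=float))):
        raise ModelError("log_f must be finite")
    out = _csf_sprime(params.gamma_max, params.f_max, params.beta1, log_f)
    return float(out) if np.ndim(out) == 0 else out


def csf_sensitivity(params: CSFParams, log_f) -> float:
    """Truncated log-parabola S(f).

    Equals S'(f) at and above the peak frequency; below the peak the curve is
    clipped from below at the plateau ``log10(gamma_max) - delta1``.
    """
    if not np.all(np.isfinite(np.asarray(log_f, dtype=float))):
        raise ModelError("log_f must be finite")
    out = _csf_sensitivity(params.gamma_max, params.f_max, params.beta1, params.delta1, log_f)
    return float(out) if np.ndim(out) == 0 else out


def csf_response_prob(params: CSFParams, stim: CSFStimulus, mu: float = DEFAULT_LAPSE_BOUND) -> float:
    """Probability of a correct response to a grating.

    ``min(1 - mu, 0.5 + 0.5 * 10^(2 (S(f) + log10 c)))`` — a guess rate of 0.5
    for vanishing contrast rising to the lapse-bounded ceiling ``1 - mu``
    (mu defaults to 4%).  Monotone non-decreasing in contrast.
    """
    s = _csf_sensitivity(params.gamma_max, params.f_max, params.beta1, params.delta1, stim.log_f)
    out = _csf_prob(s, stim.log_c, mu)
    return float(out) if np.ndim(out) == 0 else out


def gaf_response_prob(params: GAFParams, stim: GAFStimulus) -> float:
    """Probability that a gap of ``stim.gap`` seconds is accepted.

    Standard-normal CDF of the standardized gap, ``Phi((d - t_cr)/sigma)``.
    """
    out = _gaf_prob(params.t_cr, params.sigma, stim.gap)
    return float(out) if np.ndim(out) == 0 else out


def likelihood(prob_y1, y) -> float:
    """Bernoulli likelihood of a binary response: ``p`` if y=1 else ``1 - p``."""
    p = np.asarray(prob_y1, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ModelError("prob_y1 must lie in [0, 1]")
    if y not in (0, 1):
        raise ModelError(f"binary response must be 0 or 1, got {y!r}")
    out = p if y == 1 else 1.0 - p
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# vectorized model contract
# ---------------------------------------------------------------------------


class PsychometricModel(abc.ABC):
    """Contract: ``response_prob(theta, stim) -> P(y = 1 | theta, stim)``.

    ``theta`` has shape ``(..., n_params)`` and ``stim`` shape
    ``(..., n_stim)``; leading dimensions broadcast.
    """

    param_names: ClassVar[tuple[str, ...]]
    stim_names: ClassVar[tuple[str, ...]]

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @abc.abstractmethod
    def response_prob(self, theta, stim):
        """Probability of response y=1; broadcasts over leading dimensions."""

    def prob_table(self, nodes: np.ndarray, points: np.ndarray, dtype=np.float64) -> np.ndarray:
        """Dense ``(n_nodes, n_points)`` table of response probabilities."""
        nodes = np.asarray(nodes, dtype=float)
        points = np.asarray(points, dtype=float)
        out = self.response_prob(nodes[:, None, :], points[None, :, :])
        return np.asarray(out, dtype=dtype)


class CSFModel(PsychometricModel):
    """Truncated log-parabola contrast sensitivity model."""

    param_names = ("gamma_max", "f_max", "beta1", "delta1")
    stim_names = ("log_f", "log_c")

    def __init__(self, mu: float = DEFAULT_LAPSE_BOUND):
        if not 0.0 <= mu < 0.5:
            raise ModelError("lapse bound mu must lie in [0, 0.5)")
        self.mu = float(mu)

    def response_prob(self, theta, stim):
        theta = np.asarray(theta, dtype=float)
        stim = np.asarray(stim, dtype=float)
        s = _csf_sensitivity(
            theta[..., 0], theta[..., 1], theta[..., 2], theta[..., 3], stim[..., 0]
        )
        return _csf_prob(s, stim[..., 1], self.mu)

    def prob_table(self, nodes, points, dtype=np.float64):
        # Sensitivity depends on the stimulus only through log_f, which takes
        # few distinct values on a product grid — factor it out so the table
        # is filled column-by-column without (n_nodes, n_points) temporaries.
        nodes = np.asarray(nodes, dtype=float)
        points = np.asarray(points, dtype=float)
        log_f_vals, col_f = np.unique(points[:, 0], return_inverse=True)
        s = _csf_sensitivity(
            nodes[:, 0:1], nodes[:, 1:2], nodes[:, 2:3], nodes[:, 3:4], log_f_vals[None, :]
        )
        out = np.empty((nodes.shape[0], points.shape[0]), dtype=dtype)
        for j in range(points.shape[0]):
            out[:, j] = _csf_prob(s[:, col_f[j]], points[j, 1], self.mu)
        return out


class GAFModel(PsychometricModel):
    """Probit gap-acceptance model with heterogeneous critical gap."""

    param_names = ("t_cr", "sigma")
    stim_names = ("gap",)

    def response_prob(self, theta, stim):
        theta = np.asarray(theta, dtype=float)
        stim = np.asarray(stim, dtype=float)
        return _gaf_prob(theta[..., 0], theta[..., 1], stim[..., 0])
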