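"""Stimulus-selection policies and the per-trial experiment loop.

Three policies drive the same Bayes core:

* ``classical`` — always explore: pick the stimulus maximizing mutual
  information, every trial.
* ``random``    — always exploit: pick a uniformly random stimulus.
* ``ee``        — exploration-exploitation: explore while the parameter
  entropy H(Theta) exceeds a threshold ``epsilon`` (bits), exploit
  otherwise.  The switch condition is re-evaluated every trial on the
  prior of that trial; the boundary H = epsilon resolves to exploit.

Exploit trials never compute mutual information — skipping the
grid-by-stimulus sweep is exactly where the policy's speed-up comes from —
so the trial record stores ``None`` for ``max_mi_bits`` on those trials.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConfigError, EntropyBoundError, InferenceError
from .inference import (
    LikelihoodTable,
    ParameterGrid,
    PosteriorState,
    StimulusGrid,
    estimate_mean,
    posterior_update,
    squared_error,
    uniform_prior,
)
from .infotheory import mi_sweep, parameter_entropy
from .models import PsychometricModel

__all__ = [
    "PolicyConfig",
    "TrialRecord",
    "select_explore",
    "select_exploit",
    "ee_decide",
    "run_experiment",
    "EXPLORE",
    "EXPLOIT",
]

EXPLORE = "explore"
EXPLOIT = "exploit"
_KINDS = ("ee", "classical", "random")


@dataclass(frozen=True)
class PolicyConfig:
    """Which selection strategy to run, for how many trials.

    ``epsilon`` (bits) is required for the ``ee`` kind and must be positive.
    """

    kind: str
    trials: int
    epsilon: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigError(f"unknown policy kind {self.kind!r}; expected one of {_KINDS}")
        if self.trials < 1:
            raise ConfigError("trials must be >= 1")
        if self.kind == "ee":
            if self.epsilon is None or not (self.epsilon > 0):
                raise ConfigError("ee policy requires an entropy threshold epsilon > 0")


@dataclass(frozen=True)
class TrialRecord:
    """Everything logged about one trial."""

    trial: int  # 1-based
    stimulus_index: int
    stimulus: tuple[float, ...]
    strategy: str  # explore | exploit
    response: int
    entropy_bits: float  # H(Theta) of the prior used this trial
    max_mi_bits: Optional[float]  # None on exploit trials (MI not computed)
    estimate: tuple[float, ...]
    sq_error: tuple[float, ...]


def select_explore(report) -> int:
    """Index of the MI-maximizing stimulus (lowest index on ties)."""
    return int(report.argmax_index)


def select_exploit(rng: np.random.Generator, point_count: int) -> int:
    """Uniformly random stimulus index from the menu."""
    if point_count < 1:
        raise ConfigError("point_count must be >= 1")
    return int(rng.integers(point_count))


def ee_decide(entropy_bits: float, epsilon: float) -> str:
    """Explore iff H(Theta) > epsilon; the boundary H = epsilon exploits."""
    if not (np.isfinite(entropy_bits) and np.isfinite(epsilon) and epsilon > 0):
        raise ConfigError("ee_decide requires finite entropy and epsilon > 0")
    return EXPLORE if entropy_bits > epsilon else EXPLOIT


def run_experiment(
    model: PsychometricModel,
    grid: ParameterGrid,
    stim_grid: StimulusGrid,
    table: LikelihoodTable,
    policy: PolicyConfig,
    truth,
    rng_subject: np.random.Generator,
    rng_policy: np.random.Generator,
    *,
    mse_scale: str = "natural",
    sweep_mass_cutoff: float = 0.0,
    entropy_bound_tol: float = 1e-9,
    initial_state: Optional[PosteriorState] = None,
    start_trial: int = 1,
) -> list[TrialRecord]:
    """Run one adaptive experiment of ``policy.trials`` trials.

    Each trial: evaluate the entropy of the current prior, pick a strategy,
    select a stimulus, draw the virtual subject's response at the
    *continuous* true parameter point (which need not be a grid node),
    update the posterior, and record the MEAN estimate with its
    per-parameter squared error.

    ``rng_subject`` and ``rng_policy`` are independent streams so exploit
    randomness never perturbs response randomness.  ``sweep_mass_cutoff``
    (off by default) lets the MI sweep skip nodes whose posterior mass has
    fallen below the cutoff; posterior updates always use the full grid.

    ``initial_state``/``start_trial`` resume an experiment mid-way (the
    caller supplies the posterior reached after ``start_trial - 1`` trials
    and suitably advanced random streams); records are returned for trials
    ``start_trial .. policy.trials`` only.
    """
    truth = np.asarray(truth, dtype=float)
    if truth.shape != (len(grid.axes),):
        raise ConfigError("truth dimension does not match the parameter grid")
    if start_trial < 1:
        raise ConfigError("start_trial must be >= 1")

    state = uniform_prior(grid) if initial_state is None else initial_state
    lik, h_lik = table.table, table.h_table
    # Active-subset views for the MI sweep; rebuilt only when the live
    # support has at least halved, so compaction cost stays amortized.
    sweep_idx: Optional[np.ndarray] = None
    sweep_lik, sweep_h = lik, h_lik
    active_n = lik.shape[0]

    records: list[TrialRecord] = []
    for t in range(start_trial, policy.trials + 1):
        entropy = parameter_entropy(state)

        if policy.kind == "classical":
            strategy = EXPLORE
        elif policy.kind == "random":
            strategy = EXPLOIT
        else:
            strategy = ee_decide(entropy, policy.epsilon)

        max_mi: Optional[float] = None
        if strategy == EXPLORE:
            if sweep_mass_cutoff > 0.0:
                live = state.mass > sweep_mass_cutoff
                n_live = int(live.sum())
                if 1 <= n_live < int(0.7 * active_n):
                    sweep_idx = np.flatnonzero(live)
                    sweep_lik = np.ascontiguousarray(lik[sweep_idx])
                    sweep_h = np.ascontiguousarray(h_lik[sweep_idx])
                    active_n = n_live
            mass = state.mass if sweep_idx is None else state.mass[sweep_idx]
            mi = mi_sweep(mass, sweep_lik, sweep_h)
            idx = int(np.argmax(mi))
            max_mi = float(mi[idx])
            if max_mi > entropy + entropy_bound_tol:
                raise EntropyBoundError(
                    f"trial {t}: max MI {max_mi:.12g} bits exceeds "
                    f"parameter entropy {entropy:.12g} bits"
                )
        else:
            idx = select_exploit(rng_policy, stim_grid.point_count)

        stim = stim_grid.points[idx]
        p_true = float(model.response_prob(truth, stim))
        y = 1 if rng_subject.random() < p_true else 0

        try:
            state = posterior_update(state, lik[:, idx], y)
        except InferenceError as exc:
            raise InferenceError(f"trial {t} (stimulus {stim.tolist()}): {exc}") from exc

        est = estimate_mean(state, grid)
        sq = squared_error(est, truth, scale=mse_scale)
        records.append(
            TrialRecord(
                trial=t,
                stimulus_index=idx,
                stimulus=tuple(float(v) for v in stim),
                strategy=strategy,
                response=y,
                entropy_bits=entropy,
                max_mi_bits=max_mi,
                estimate=tuple(float(v) for v in est),
                sq_error=tuple(float(v) for v in sq),
            )
        )
    return records
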