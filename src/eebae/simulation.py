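"""Virtual subject, replication harness, and policy comparison.

An :class:`ExperimentConfig` fully describes a simulated experiment: the
psychometric model, parameter/stimulus ranges and grid sizes, the true
subject parameters, the selection policy, and the replication protocol.
:func:`run_replications` executes many independent experiments with
deterministically derived seeds and aggregates per-trial means (entropy,
per-parameter MSE, exploit fraction); :func:`compare_policies` runs the
EE and classical policies head to head on matched settings.

Wall-clock timings are measured and reported for qualitative comparison
only — they depend on hardware and are never asserted.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .errors import ConfigError
from .inference import (
    LikelihoodTable,
    ParameterGrid,
    StimulusGrid,
    build_parameter_grid,
    build_stimulus_grid,
    posterior_update,
    precompute_likelihoods,
    uniform_prior,
)
from .models import CSFModel, GAFModel, PsychometricModel
from .policy import EXPLOIT, PolicyConfig, TrialRecord, run_experiment

__all__ = [
    "ExperimentConfig",
    "AggregateTrajectory",
    "PolicyComparison",
    "simulate_response",
    "run_replications",
    "compare_policies",
    "exploitation_count",
    "build_model",
    "build_grids",
]

_MODEL_CLASSES: dict[str, type[PsychometricModel]] = {"csf": CSFModel, "gaf": GAFModel}

#: Default axis spacing per model: the CSF parameters span 1-3 orders of
#: magnitude and are gridded log10-equispaced; GAF parameters are linear.
_DEFAULT_SPACING: dict[str, dict[str, str]] = {
    "csf": {"gamma_max": "log10", "f_max": "log10", "beta1": "log10", "delta1": "log10"},
    "gaf": {"t_cr": "linear", "sigma": "linear"},
}


class PolicySpec(BaseModel):
    """JSON-facing policy description."""

    model_config = ConfigDict(extra="forbid")

    kind: Literal["ee", "classical", "random"]
    trials: int
    epsilon: Optional[float] = None

    def to_policy(self) -> PolicyConfig:
        return PolicyConfig(kind=self.kind, trials=self.trials, epsilon=self.epsilon)

    @model_validator(mode="after")
    def _check(self) -> "PolicySpec":
        try:
            self.to_policy()
        except ConfigError as exc:
            raise ValueError(str(exc)) from exc
        return self


class ExperimentConfig(BaseModel):
    """Complete description of one simulated estimation experiment."""

    model_config = ConfigDict(extra="forbid")

    model: Literal["csf", "gaf"]
    param_ranges: dict[str, tuple[float, float]]
    param_grid_sizes: dict[str, int]
    param_spacing: Optional[dict[str, Literal["linear", "log10"]]] = None
    stim_ranges: dict[str, tuple[float, float]]
    stim_grid_sizes: dict[str, int]
    truth: dict[str, float]
    policy: PolicySpec
    replications: int = 100
    seed: int = 0
    mu: float = 0.04
    likelihood_dtype: Literal["float64", "float32"] = "float64"
    mse_scale: Literal["natural", "log10"] = "natural"
    sweep_mass_cutoff: float = 1e-11

    @model_validator(mode="after")
    def _validate(self) -> "ExperimentConfig":
        cls = _MODEL_CLASSES[self.model]
        pnames, snames = set(cls.param_names), set(cls.stim_names)
        for label, keys, expected in (
            ("param_ranges", set(self.param_ranges), pnames),
            ("param_grid_sizes", set(self.param_grid_sizes), pnames),
            ("stim_ranges", set(self.stim_ranges), snames),
            ("stim_grid_sizes", set(self.stim_grid_sizes), snames),
            ("truth", set(self.truth), pnames),
        ):
            if keys != expected:
                raise ValueError(f"{label} keys {sorted(keys)} != expected {sorted(expected)}")
        for name, (lo, hi) in self.param_ranges.items():
            if not lo < hi:
                raise ValueError(f"param range {name}: lo must be < hi")
            if not lo <= self.truth[name] <= hi:
                raise ValueError(f"truth[{name}]={self.truth[name]} outside range [{lo}, {hi}]")
        for name, (lo, hi) in self.stim_ranges.items():
            if not lo < hi:
                raise ValueError(f"stimulus range {name}: lo must be < hi")
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if not 0.0 <= self.mu < 0.5:
            raise ValueError("mu must lie in [0, 0.5)")
        if self.sweep_mass_cutoff < 0:
            raise ValueError("sweep_mass_cutoff must be >= 0")
        return self

    @property
    def spacing(self) -> dict[str, str]:
        if self.param_spacing is not None:
            return dict(self.param_spacing)
        return dict(_DEFAULT_SPACING[self.model])

    def truth_vector(self) -> np.ndarray:
        names = _MODEL_CLASSES[self.model].param_names
        return np.array([self.truth[n] for n in names], dtype=float)


def build_model(config: ExperimentConfig) -> PsychometricModel:
    return CSFModel(mu=config.mu) if config.model == "csf" else GAFModel()


def build_grids(config: ExperimentConfig) -> tuple[ParameterGrid, StimulusGrid]:
    """Parameter and stimulus grids in the model's canonical axis order."""
    cls = _MODEL_CLASSES[config.model]
    spacing = config.spacing
    pranges = {n: config.param_ranges[n] for n in cls.param_names}
    psizes = {n: config.param_grid_sizes[n] for n in cls.param_names}
    sranges = {n: config.stim_ranges[n] for n in cls.stim_names}
    ssizes = {n: config.stim_grid_sizes[n] for n in cls.stim_names}
    grid = build_parameter_grid(pranges, psizes, spacing)
    stim_grid = build_stimulus_grid(sranges, ssizes)
    return grid, stim_grid


def simulate_response(
    rng: np.random.Generator, model: PsychometricModel, truth, stimulus
) -> int:
    """Virtual subject: Bernoulli draw at the continuous true parameters."""
    p = float(model.response_prob(np.asarray(truth, float), np.asarray(stimulus, float)))
    return 1 if rng.random() < p else 0


@dataclass(frozen=True)
class AggregateTrajectory:
    """Per-trial means across replications, plus per-replication summaries."""

    param_names: tuple[str, ...]
    trials: int
    replications: int
    entropy_bits: np.ndarray  # (trials,) mean H_t across replications
    mse: np.ndarray  # (trials, n_params) mean squared error per trial
    exploit_fraction: np.ndarray  # (trials,) share of replications exploiting at t
    exploit_counts: np.ndarray  # (replications,) exploit-trial count per run
    final_estimates: np.ndarray  # (replications, n_params) trial-T MEAN estimates
    elapsed_seconds: float  # informational; hardware-dependent
    logs: Optional[list[list[TrialRecord]]] = field(default=None, repr=False)

    @property
    def exploit_count_mean(self) -> float:
        return float(self.exploit_counts.mean())


class _Accumulator:
    """Streams per-replication trial records into aggregate arrays."""

    def __init__(self, n_trials: int, n_params: int, n_reps: int, keep_logs: bool):
        self.ent_sum = np.zeros(n_trials)
        self.sq_sum = np.zeros((n_trials, n_params))
        self.exploit_sum = np.zeros(n_trials)
        self.counts = np.zeros(n_reps, dtype=int)
        self.finals = np.zeros((n_reps, n_params))
        self.logs: Optional[list[list[TrialRecord]]] = [] if keep_logs else None

    def add(self, r: int, records: list[TrialRecord]) -> None:
        for i, rec in enumerate(records):
            self.ent_sum[i] += rec.entropy_bits
            self.sq_sum[i] += rec.sq_error
            if rec.strategy == EXPLOIT:
                self.exploit_sum[i] += 1.0
        self.counts[r] = exploitation_count(records)
        self.finals[r] = records[-1].estimate
        if self.logs is not None:
            self.logs.append(records)

    def finalize(
        self, param_names: tuple[str, ...], trials: int, reps: int, elapsed: float
    ) -> AggregateTrajectory:
        n = float(reps)
        return AggregateTrajectory(
            param_names=param_names,
            trials=trials,
            replications=reps,
            entropy_bits=self.ent_sum / n,
            mse=self.sq_sum / n,
            exploit_fraction=self.exploit_sum / n,
            exploit_counts=self.counts,
            final_estimates=self.finals,
            elapsed_seconds=elapsed,
            logs=self.logs,
        )


def _replication_seeds(config: ExperimentConfig):
    return np.random.SeedSequence(config.seed).spawn(config.replications)


def run_replications(
    config: ExperimentConfig,
    *,
    keep_logs: bool = False,
    table: Optional[LikelihoodTable] = None,
) -> AggregateTrajectory:
    """Run ``config.replications`` independent experiments and aggregate.

    Per-replication seeds are spawned from ``config.seed`` via numpy's
    ``SeedSequence`` (pairwise-distinct, reproducible); each replication
    splits again into independent subject and policy streams.  A
    precomputed likelihood ``table`` may be passed to share the (possibly
    large) table across calls with identical grids.
    """
    model = build_model(config)
    grid, stim_grid = build_grids(config)
    if table is None:
        table = precompute_likelihoods(
            model, grid, stim_grid, dtype=np.dtype(config.likelihood_dtype)
        )
    policy = config.policy.to_policy()
    truth = config.truth_vector()

    acc = _Accumulator(policy.trials, len(grid.axes), config.replications, keep_logs)
    t0 = time.perf_counter()
    for r, child in enumerate(_replication_seeds(config)):
        seq_subject, seq_policy = child.spawn(2)
        records = run_experiment(
            model,
            grid,
            stim_grid,
            table,
            policy,
            truth,
            np.random.default_rng(seq_subject),
            np.random.default_rng(seq_policy),
            mse_scale=config.mse_scale,
            sweep_mass_cutoff=config.sweep_mass_cutoff,
        )
        acc.add(r, records)
    elapsed = time.perf_counter() - t0
    return acc.finalize(tuple(grid.names), policy.trials, config.replications, elapsed)


def exploitation_count(records: list[TrialRecord]) -> int:
    """Number of trials in one replication that used the exploit strategy."""
    return sum(1 for r in records if r.strategy == EXPLOIT)


def _replay_ee_arm(
    config_ee: ExperimentConfig,
    classical: AggregateTrajectory,
    model: PsychometricModel,
    grid: ParameterGrid,
    stim_grid: StimulusGrid,
    table: LikelihoodTable,
    keep_logs: bool,
) -> AggregateTrajectory:
    """Reconstruct the EE arm of a comparison from the classical arm's logs.

    With shared seeds and deterministic argmax selection, an EE replication
    is identical to its classical counterpart on every trial before the
    entropy first drops to the threshold (both explore the same stimuli and
    see the same responses).  The shared prefix is therefore replayed with
    cheap posterior updates and the EE run is simulated only from the
    switch trial onward, with the subject stream advanced past the prefix
    and the policy stream untouched (explore trials never draw from it).
    """
    policy = config_ee.policy.to_policy()
    eps = policy.epsilon
    truth = config_ee.truth_vector()
    acc = _Accumulator(policy.trials, len(grid.axes), config_ee.replications, keep_logs)
    t0 = time.perf_counter()
    for r, child in enumerate(_replication_seeds(config_ee)):
        cl_records = classical.logs[r]
        switch = next((rec.trial for rec in cl_records if rec.entropy_bits <= eps), None)
        if switch is None:
            # Entropy never reached the threshold: the EE run is the
            # classical run (every trial explores).
            acc.add(r, cl_records)
            continue
        state = uniform_prior(grid)
        for rec in cl_records[: switch - 1]:
            state = posterior_update(state, table.table[:, rec.stimulus_index], rec.response)
        seq_subject, seq_policy = child.spawn(2)
        rng_subject = np.random.default_rng(seq_subject)
        if switch > 1:
            rng_subject.random(switch - 1)  # prefix already consumed these draws
        continuation = run_experiment(
            model,
            grid,
            stim_grid,
            table,
            policy,
            truth,
            rng_subject,
            np.random.default_rng(seq_policy),
            mse_scale=config_ee.mse_scale,
            sweep_mass_cutoff=config_ee.sweep_mass_cutoff,
            initial_state=state,
            start_trial=switch,
        )
        acc.add(r, cl_records[: switch - 1] + continuation)
    elapsed = time.perf_counter() - t0
    return acc.finalize(tuple(grid.names), policy.trials, config_ee.replications, elapsed)


@dataclass(frozen=True)
class PolicyComparison:
    """Side-by-side aggregate of two policies on matched settings."""

    first: AggregateTrajectory
    second: AggregateTrajectory
    final_mse_ratio: np.ndarray  # first / second, per parameter, at trial T
    first_arm_replayed: bool = False

    def summary(self) -> dict:
        return {
            "param_names": list(self.first.param_names),
            "trials": self.first.trials,
            "replications": self.first.replications,
            "final_mse_first": self.first.mse[-1].tolist(),
            "final_mse_second": self.second.mse[-1].tolist(),
            "final_mse_ratio": self.final_mse_ratio.tolist(),
            "exploit_count_mean_first": self.first.exploit_count_mean,
            "exploit_count_mean_second": self.second.exploit_count_mean,
            "elapsed_seconds_first": self.first.elapsed_seconds,
            "elapsed_seconds_second": self.second.elapsed_seconds,
            "first_arm_replayed": self.first_arm_replayed,
        }


def compare_policies(
    config_a: ExperimentConfig,
    config_b: ExperimentConfig,
    *,
    keep_logs: bool = False,
    shared_prefix: bool = True,
) -> PolicyComparison:
    """Run two configs that differ only in policy, sharing one likelihood table.

    When the pair is (ee, classical) and ``shared_prefix`` is true, the EE
    arm is reconstructed from the classical arm's logs (see
    :func:`_replay_ee_arm`); its ``elapsed_seconds`` then measures the
    replay, not a standalone EE run — use ``run_replications`` directly for
    wall-clock comparisons.
    """
    dump_a = config_a.model_dump(exclude={"policy"})
    dump_b = config_b.model_dump(exclude={"policy"})
    if dump_a != dump_b:
        raise ConfigError("compare_policies: configs differ beyond the policy block")
    if config_a.policy.trials != config_b.policy.trials:
        raise ConfigError("compare_policies: trial counts must match")
    model = build_model(config_a)
    grid, stim_grid = build_grids(config_a)
    table = precompute_likelihoods(
        model, grid, stim_grid, dtype=np.dtype(config_a.likelihood_dtype)
    )
    replayed = False
    if shared_prefix and config_a.policy.kind == "ee" and config_b.policy.kind == "classical":
        traj_b = run_replications(config_b, keep_logs=True, table=table)
        traj_a = _replay_ee_arm(config_a, traj_b, model, grid, stim_grid, table, keep_logs)
        if not keep_logs:
            traj_b = dataclasses.replace(traj_b, logs=None)
        replayed = True
    else:
        traj_a = run_replications(config_a, keep_logs=keep_logs, table=table)
        traj_b = run_replications(config_b, keep_logs=keep_logs, table=table)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = traj_a.mse[-1] / traj_b.mse[-1]
    return PolicyComparison(
        first=traj_a, second=traj_b, final_mse_ratio=ratio, first_arm_replayed=replayed
    )
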