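"""Grid discretization, discrete Bayes updates, and the MEAN estimator.

The posterior over psychometric parameters lives on a finite Cartesian grid
(no interpolation): the state is a probability mass vector over grid nodes,
updated multiplicatively by the Bernoulli likelihood of each observed
response and renormalized.  Updates are pure — a new state is returned —
so replicated experiments cannot leak state into each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError, InferenceError, ModelError
from .models import PsychometricModel

__all__ = [
    "Axis",
    "ParameterGrid",
    "StimulusGrid",
    "PosteriorState",
    "LikelihoodTable",
    "build_parameter_grid",
    "build_stimulus_grid",
    "uniform_prior",
    "precompute_likelihoods",
    "posterior_update",
    "estimate_mean",
    "squared_error",
]

_SPACINGS = ("linear", "log10")


@dataclass(frozen=True)
class Axis:
    """One grid dimension: ordered raw node coordinates plus a spacing rule.

    ``spacing`` records the scale the nodes were laid out on ("linear" or
    "log10"); posterior means along a log axis are taken on the log scale.
    """

    name: str
    values: np.ndarray
    spacing: str = "linear"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.spacing not in _SPACINGS:
            raise ConfigError(f"unknown axis spacing {self.spacing!r}")
        if self.values.ndim != 1 or self.values.size < 1:
            raise ConfigError(f"axis {self.name!r}: values must be a non-empty 1-D array")
        if self.values.size > 1 and not np.all(np.diff(self.values) > 0):
            raise ConfigError(f"axis {self.name!r}: values must be strictly increasing")
        if self.spacing == "log10" and not np.all(self.values > 0):
            raise ConfigError(f"axis {self.name!r}: log10 spacing requires positive values")

    @property
    def size(self) -> int:
        return int(self.values.size)

    @property
    def scale_values(self) -> np.ndarray:
        """Node coordinates on the axis's working scale."""
        return np.log10(self.values) if self.spacing == "log10" else self.values

    def from_scale(self, x):
        """Inverse of the working-scale transform."""
        return 10.0 ** x if self.spacing == "log10" else x


def _cartesian(axes_values: Sequence[np.ndarray]) -> np.ndarray:
    mesh = np.meshgrid(*axes_values, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=-1)


@dataclass(frozen=True)
class ParameterGrid:
    """Cartesian discretization of the parameter space."""

    axes: tuple[Axis, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "axes", tuple(self.axes))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(ax.name for ax in self.axes)

    @property
    def node_count(self) -> int:
        return int(np.prod([ax.size for ax in self.axes]))

    @cached_property
    def nodes(self) -> np.ndarray:
        """All grid nodes in raw units, shape ``(node_count, n_params)``."""
        return _cartesian([ax.values for ax in self.axes])

    @cached_property
    def scale_nodes(self) -> np.ndarray:
        """All grid nodes on each axis's working scale."""
        return _cartesian([ax.scale_values for ax in self.axes])


@dataclass(frozen=True)
class StimulusGrid:
    """Finite stimulus menu: Cartesian product of the stimulus axes."""

    axes: tuple[Axis, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "axes", tuple(self.axes))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(ax.name for ax in self.axes)

    @property
    def point_count(self) -> int:
        return int(np.prod([ax.size for ax in self.axes]))

    @cached_property
    def points(self) -> np.ndarray:
        return _cartesian([ax.values for ax in self.axes])


def _build_axes(
    ranges: Mapping[str, Sequence[float]],
    sizes: Mapping[str, int],
    spacing: Mapping[str, str] | None,
) -> tuple[Axis, ...]:
    axes = []
    for name, (lo, hi) in ranges.items():
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ConfigError(f"axis {name!r}: need finite lo < hi, got [{lo}, {hi}]")
        size = int(sizes[name])
        if size < 2:
            raise ConfigError(f"axis {name!r}: need at least 2 grid points, got {size}")
        rule = (spacing or {}).get(name, "linear")
        if rule == "log10":
            if lo <= 0:
                raise ConfigError(f"axis {name!r}: log10 spacing requires lo > 0")
            values = 10.0 ** np.linspace(np.log10(lo), np.log10(hi), size)
            values[0], values[-1] = lo, hi  # endpoints exactly
        else:
            values = np.linspace(lo, hi, size)
        axes.append(Axis(name=name, values=values, spacing=rule))
    return tuple(axes)


def build_parameter_grid(
    ranges: Mapping[str, Sequence[float]],
    sizes: Mapping[str, int],
    spacing: Mapping[str, str] | None = None,
) -> ParameterGrid:
    """Build a parameter grid with endpoint-inclusive axes.

    ``spacing`` maps parameter names to "linear" (default) or "log10"
    (log10-equispaced nodes, for parameters spanning orders of magnitude).
    """
    return ParameterGrid(axes=_build_axes(ranges, sizes, spacing))


def build_stimulus_grid(
    ranges: Mapping[str, Sequence[float]],
    sizes: Mapping[str, int],
) -> StimulusGrid:
    """Build a stimulus grid, linear in the units the ranges are stated in."""
    return StimulusGrid(axes=_build_axes(ranges, sizes, None))


@dataclass(frozen=True)
class PosteriorState:
    """Probability mass over grid nodes; the single mutable state, held immutably."""

    mass: np.ndarray
    trial_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mass", np.asarray(self.mass, dtype=float))
        if self.mass.ndim != 1:
            raise InferenceError("posterior mass must be a 1-D vector")
        if np.any(self.mass < 0):
            raise InferenceError("posterior mass must be non-negative")
        if abs(float(self.mass.sum()) - 1.0) > 1e-9:
            raise InferenceError(f"posterior mass must sum to 1, got {self.mass.sum()!r}")


def uniform_prior(grid: ParameterGrid) -> PosteriorState:
    """Non-informative prior: equal mass on every grid node."""
    n = grid.node_count
    return PosteriorState(mass=np.full(n, 1.0 / n), trial_index=0)


@dataclass(frozen=True)
class LikelihoodTable:
    """P(y=1 | node i, stimulus j) for every grid node and stimulus point.

    Precomputed once per configuration and shared across trials and
    replications.  ``h_table`` caches the binary entropy of every entry,
    which the per-stimulus information sweep reuses every explore trial.
    """

    table: np.ndarray

    @cached_property
    def h_table(self) -> np.ndarray:
        from .infotheory import binary_entropy_array

        return binary_entropy_array(self.table).astype(self.table.dtype, copy=False)

    @property
    def node_count(self) -> int:
        return int(self.table.shape[0])

    @property
    def point_count(self) -> int:
        return int(self.table.shape[1])


def precompute_likelihoods(
    model: PsychometricModel,
    grid: ParameterGrid,
    stimuli: StimulusGrid,
    dtype=np.float64,
) -> LikelihoodTable:
    """Evaluate the model over the full (node, stimulus) product.

    ``dtype`` may be ``float32`` for very large grids; posterior state and
    entropies remain float64 regardless.
    """
    table = model.prob_table(grid.nodes, stimuli.points, dtype=np.dtype(dtype))
    bad = ~np.isfinite(table) | (table < 0) | (table > 1)
    if np.any(bad):
        i, j = map(int, np.argwhere(bad)[0])
        raise ModelError(
            f"model produced invalid probability {table[i, j]!r} at "
            f"node {grid.nodes[i].tolist()} / stimulus {stimuli.points[j].tolist()}"
        )
    return LikelihoodTable(table=table)


def posterior_update(state: PosteriorState, lik_column, y: int) -> PosteriorState:
    """One Bayes-rule update: mass_i ∝ mass_i * p(y | theta_i, d), renormalized.

    Returns a new state with ``trial_index`` incremented; the input state is
    untouched.  Raises :class:`InferenceError` if the observed response has
    zero probability under the entire prior support.
    """
    if y not in (0, 1):
        raise InferenceError(f"binary response must be 0 or 1, got {y!r}")
    lik = np.asarray(lik_column, dtype=np.float64)
    if lik.shape != state.mass.shape:
        raise InferenceError("likelihood column and posterior mass differ in length")
    if np.any(lik < -1e-6) or np.any(lik > 1 + 1e-6):
        raise InferenceError("likelihood column entries must lie in [0, 1]")
    lik = np.clip(lik, 0.0, 1.0)
    weights = lik if y == 1 else 1.0 - lik
    new_mass = state.mass * weights
    z = float(new_mass.sum())
    if z <= 0.0:
        raise InferenceError("response has zero probability under the entire prior support")
    return PosteriorState(mass=new_mass / z, trial_index=state.trial_index + 1)


def estimate_mean(state: PosteriorState, grid: ParameterGrid) -> np.ndarray:
    """Posterior-mean (MEAN) point estimate, in raw parameter units.

    The mean along each axis is taken on that axis's working scale and mapped
    back, so a log10-spaced axis yields the posterior geometric mean (the
    uniform-prior estimate is then the per-axis range midpoint — the
    log-midpoint on log axes).
    """
    scale_mean = state.mass @ grid.scale_nodes
    return np.array([ax.from_scale(m) for ax, m in zip(grid.axes, scale_mean)])


def squared_error(estimate, truth, scale: str = "natural") -> np.ndarray:
    """Per-parameter squared error of an estimate against the simulated truth.

    ``scale="log10"`` compares log10-transformed values instead of raw ones
    (both inputs must then be positive).  The summed components give the
    squared Euclidean error.
    """
    est = np.asarray(estimate, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if est.shape != tru.shape:
        raise InferenceError(f"dimension mismatch: {est.shape} vs {tru.shape}")
    if scale == "log10":
        est, tru = np.log10(est), np.log10(tru)
    elif scale != "natural":
        raise ConfigError(f"unknown squared-error scale {scale!r}")
    return (est - tru) ** 2
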