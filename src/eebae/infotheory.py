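"""Entropies and mutual information for the binary-response design problem.

All quantities are in bits (log base 2).  For a discrete posterior ``p(theta)``
over grid nodes and a candidate stimulus ``d`` with per-node response
probabilities ``q_i = P(y=1 | theta_i, d)``, the information gain decomposes as

    I(Theta; Y | d) = h( sum_i p_i q_i ) - sum_i p_i h(q_i)

where ``h`` is the binary entropy function.  Two invariants are enforced at
runtime and in tests: ``max_d I <= H(Theta)`` (the per-trial information gain
can never exceed the current parameter uncertainty) and the "information
cannot hurt" bound (expected posterior entropy never exceeds prior entropy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .errors import EEBAEError, EntropyBoundError
from .inference import LikelihoodTable, PosteriorState

__all__ = [
    "InformationReport",
    "binary_entropy",
    "binary_entropy_array",
    "parameter_entropy",
    "mutual_information",
    "mutual_information_joint",
    "expected_posterior_entropy",
    "information_sweep",
    "mi_sweep",
]

_LN2 = float(np.log(2.0))


def binary_entropy_array(p: np.ndarray) -> np.ndarray:
    """Binary entropy h(p) in bits, elementwise, with 0*log(0) := 0.

    Computed in the input dtype (the likelihood-table cache may be float32);
    assumes entries already lie in [0, 1] — the validated scalar entry point
    is :func:`binary_entropy`.
    """
    p = np.asarray(p)
    q = 1.0 - p
    with np.errstate(divide="ignore", invalid="ignore"):
        out = -(p * np.log2(p) + q * np.log2(q))
    # p in {0, 1} yields 0 * -inf = nan; the 0 log 0 := 0 convention applies.
    return np.where(np.isnan(out), 0.0, out)


def binary_entropy(p) -> float:
    """h(p) = -p log2 p - (1-p) log2(1-p); domain [0, 1], range [0, 1]."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1) or not np.all(np.isfinite(arr)):
        raise EEBAEError(f"binary_entropy: probability outside [0, 1]: {p!r}")
    out = binary_entropy_array(arr)
    return float(out) if np.ndim(out) == 0 else out


def parameter_entropy(state: PosteriorState) -> float:
    """Shannon entropy H(Theta) of the discrete posterior, in bits."""
    m = state.mass
    return float(-xlogy(m, m).sum() / _LN2)


def mutual_information(state: PosteriorState, lik_column) -> float:
    """I(Theta; Y | d) via the entropy decomposition, in bits.

    ``h(predictive p(y=1)) - E_theta[h(q_theta)]``; non-negative, at most
    1 bit (binary outcome), and at most the current parameter entropy.
    """
    m = state.mass
    lik = np.asarray(lik_column, dtype=np.float64)
    py1 = float(np.clip(m @ lik, 0.0, 1.0))
    mi = binary_entropy_array(py1) - m @ binary_entropy_array(lik)
    return max(float(mi), 0.0)


def mutual_information_joint(state: PosteriorState, lik_column) -> float:
    """Brute-force joint-sum mutual information (the definitional form).

    Sums ``p(theta, y | d) log2[ p(theta, y|d) / (p(theta) p(y|d)) ]`` over
    all (node, outcome) pairs.  Serves as an independent oracle for
    :func:`mutual_information`; the two agree to ~1e-10.
    """
    m = np.asarray(state.mass, dtype=np.float64)
    lik = np.asarray(lik_column, dtype=np.float64)
    total = 0.0
    for cond in (lik, 1.0 - lik):
        joint = m * cond
        py = float(joint.sum())
        if py <= 0.0:
            continue
        mask = joint > 0.0
        total += float(np.sum(joint[mask] * np.log2(joint[mask] / (m[mask] * py))))
    return max(total, 0.0)


def expected_posterior_entropy(state: PosteriorState, lik_column) -> float:
    """E_y[ H(posterior | y) ] in bits: the entropy expected after one trial.

    By the chain rule this equals ``H(Theta) - I(Theta; Y | d)`` and so never
    exceeds the prior entropy ("information cannot hurt").
    """
    m = np.asarray(state.mass, dtype=np.float64)
    lik = np.asarray(lik_column, dtype=np.float64)
    total = 0.0
    for cond in (lik, 1.0 - lik):
        joint = m * cond
        py = float(joint.sum())
        if py <= 0.0:
            continue
        post = joint / py
        total += py * float(-xlogy(post, post).sum() / _LN2)
    return total


def mi_sweep(mass: np.ndarray, lik: np.ndarray, h_lik: np.ndarray) -> np.ndarray:
    """Per-stimulus mutual information for a dense likelihood table.

    ``lik`` is ``(n_nodes, n_stimuli)`` with ``h_lik`` its precomputed binary
    entropy; the sweep is two matrix-vector products.  The mass vector is
    cast to the table dtype (the sweep may run in float32 for very large
    grids; results are returned in float64 and clipped at 0).
    """
    md = np.ascontiguousarray(mass, dtype=lik.dtype)
    py1 = np.clip(np.asarray(md @ lik, dtype=np.float64), 0.0, 1.0)
    cond = np.asarray(md @ h_lik, dtype=np.float64)
    mi = binary_entropy_array(py1) - cond
    return np.maximum(mi, 0.0)


@dataclass(frozen=True)
class InformationReport:
    """MI for every candidate stimulus plus the current parameter entropy."""

    mi_per_stimulus: np.ndarray
    entropy: float
    argmax_index: int

    def check_entropy_bound(self, tol: float = 1e-9) -> None:
        """Raise if any stimulus's MI exceeds H(Theta) beyond ``tol``."""
        worst = float(self.mi_per_stimulus.max())
        if worst > self.entropy + tol:
            raise EntropyBoundError(
                f"max MI {worst:.12g} bits exceeds parameter entropy "
                f"{self.entropy:.12g} bits"
            )


def information_sweep(state: PosteriorState, table: LikelihoodTable) -> InformationReport:
    """MI of every stimulus column, the current entropy, and the argmax.

    Ties are broken by the lowest stimulus index for reproducibility.
    """
    mi = mi_sweep(state.mass, table.table, table.h_table)
    report = InformationReport(
        mi_per_stimulus=mi,
        entropy=parameter_entropy(state),
        argmax_index=int(np.argmax(mi)),
    )
    report.check_entropy_bound()
    return report
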