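"""Plug-in estimators of entropy, mutual information and conditional MI.

All estimates use empirical (maximum-likelihood) cell probabilities with no
bias correction and are reported in bits (log base 2).  The convention
0*log 0 = 0 applies throughout, and tiny negative floating-point residue is
clamped to zero.  Abundance counts are mapped to small discrete supports by
:func:`discretize` before estimation: the raw distinct values when there are
few of them, otherwise equal-frequency bins, which are robust to the heavy
zero-inflation of OTU tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiscreteVector",
    "discretize",
    "entropy",
    "mutual_information",
    "conditional_mutual_information",
    "joint_variable",
]


@dataclass(frozen=True)
class DiscreteVector:
    """A realized discrete variable: integer states in [0, cardinality)."""

    states: np.ndarray
    cardinality: int

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=np.int64)
        object.__setattr__(self, "states", states)
        if states.ndim != 1 or states.size < 1:
            raise ValueError("states must be a nonempty 1-D array")
        if states.min() < 0 or states.max() >= self.cardinality:
            raise ValueError("states must lie in [0, cardinality)")

    def __len__(self) -> int:
        return self.states.size


def discretize(values, n_bins: int = 10) -> DiscreteVector:
    """Map raw values to a small discrete support.

    Integer-valued inputs with at most ``n_bins`` distinct values are
    rank-encoded as-is; anything else is split into ``n_bins``
    equal-frequency bins (ties can merge bins, so the realized cardinality
    may be lower).  Deterministic for fixed input.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 1:
        raise ValueError("values must be a nonempty 1-D array")
    uniq = np.unique(v)
    if uniq.size == 1:
        return DiscreteVector(np.zeros(v.size, dtype=np.int64), 1)
    integral = np.all(np.floor(v) == v)
    if integral and uniq.size <= n_bins:
        states = np.searchsorted(uniq, v)
        return DiscreteVector(states, uniq.size)
    # interior equal-frequency cut points; a value equal to a cut point
    # falls in the lower bin, so heavy ties collapse into one bin
    edges = np.quantile(v, np.linspace(0.0, 1.0, n_bins + 1)[1:-1])
    states = np.searchsorted(edges, v, side="left")
    used = np.unique(states)
    states = np.searchsorted(used, states)
    return DiscreteVector(states, used.size)


def _check_aligned(*vecs: DiscreteVector) -> int:
    n = len(vecs[0])
    for v in vecs[1:]:
        if len(v) != n:
            raise ValueError(f"length mismatch: {len(v)} vs {n}")
    return n


def _entropy_from_counts(counts: np.ndarray, n: int) -> float:
    p = counts[counts > 0] / n
    return float(max(0.0, -(p * np.log2(p)).sum()))


def _mi_states(xs: np.ndarray, cx: int, ys: np.ndarray, cy: int) -> float:
    """Plug-in MI in bits from two aligned state arrays."""
    n = xs.size
    joint = np.bincount(xs * cy + ys, minlength=cx * cy).reshape(cx, cy)
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    pj = joint[nz] / n
    outer = np.outer(px, py)[nz] / (n * n)
    return float(max(0.0, (pj * np.log2(pj / outer)).sum()))


def entropy(x: DiscreteVector) -> float:
    """Empirical Shannon entropy H(X) in bits."""
    counts = np.bincount(x.states, minlength=x.cardinality)
    return _entropy_from_counts(counts, len(x))


def mutual_information(x: DiscreteVector, y: DiscreteVector) -> float:
    """Empirical mutual information I(X;Y) in bits, clamped to >= 0."""
    _check_aligned(x, y)
    return _mi_states(x.states, x.cardinality, y.states, y.cardinality)


def conditional_mutual_information(
    x: DiscreteVector, x2: DiscreteVector, y: DiscreteVector
) -> float:
    """Empirical I(X;X'|Y) = sum_y p(y) I(X;X' | Y=y), in bits."""
    n = _check_aligned(x, x2, y)
    total = 0.0
    for ystate in range(y.cardinality):
        mask = y.states == ystate
        ny = int(mask.sum())
        if ny == 0:
            continue
        total += (ny / n) * _mi_states(
            x.states[mask], x.cardinality, x2.states[mask], x2.cardinality
        )
    return float(max(0.0, total))


def joint_variable(x: DiscreteVector, x2: DiscreteVector) -> DiscreteVector:
    """The pair (X, X') as a single discrete variable with a compacted support."""
    _check_aligned(x, x2)
    combined = x.states * x2.cardinality + x2.states
    used = np.unique(combined)
    return DiscreteVector(np.searchsorted(used, combined), used.size)
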