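"""Neyman-Pearson Feature Selection (NPFS).

NPFS wraps any fixed-k base selector ("NPFS-SF", where SF is a scoring
function such as MIM, mRMR or JMI): it maps bootstrap subsamples of the data
to the base selector, counts how often each feature is chosen across
replicates, and in a reduction phase applies a Neyman-Pearson binomial test
to the counts.  Under the no-information null every feature is equally
likely to be picked, a Bernoulli(k/K) event per replicate, so a feature is
declared relevant when its count exceeds the smallest critical value zeta
with P(Binomial(n, k/K) > zeta) <= alpha.  The size of the relevant set is
therefore data-driven: k only needs to be a guess.

Replicates are seeded independently (seed + replicate index), so the result
is identical for any worker count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed
from scipy.stats import binom

from .greedy import ObjectiveParams, _greedy_core, make_objective
from .infotheory import DiscreteVector

__all__ = [
    "NPFSConfig",
    "NPFSResult",
    "bootstrap_selection_counts",
    "np_critical_value",
    "npfs_select",
]


@dataclass
class NPFSConfig:
    base_objective: ObjectiveParams = field(default_factory=lambda: make_objective("mim"))
    k: int = 10
    n_bootstraps: int = 100
    alpha_level: float = 0.05
    subsample_fraction: float = 1.0
    seed: int = 0
    n_workers: int = 1
    n_bins: int = 10

    def __post_init__(self) -> None:
        if self.n_bootstraps < 1:
            raise ValueError("n_bootstraps must be >= 1")
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValueError("subsample_fraction must be in (0, 1]")
        if not 0.0 < self.alpha_level < 1.0:
            raise ValueError("alpha_level must be in (0, 1)")
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")


@dataclass
class NPFSResult:
    selection_counts: np.ndarray
    critical_value: int
    relevant: set[int]
    null_rate: float


def _one_replicate(
    counts: np.ndarray,
    y_states: np.ndarray,
    n_classes: int,
    config: NPFSConfig,
    replicate: int,
) -> np.ndarray:
    """Draw one bootstrap subsample, run the base selector, return an indicator."""
    rng = np.random.default_rng((config.seed + replicate) % 2**31)
    n_samples = counts.shape[1]
    draw = math.ceil(config.subsample_fraction * n_samples)
    for _ in range(100):
        idx = rng.integers(0, n_samples, size=draw)
        y_sub = y_states[idx]
        if np.unique(y_sub).size >= 2:
            break
    else:
        raise RuntimeError(
            f"replicate {replicate}: could not draw a subsample with two classes "
            "in 100 attempts"
        )
    labels = DiscreteVector(y_sub, n_classes)
    selected, _ = _greedy_core(
        counts[:, idx], labels, config.k, config.base_objective, config.n_bins
    )
    indicator = np.zeros(counts.shape[0], dtype=np.int64)
    indicator[selected] = 1
    return indicator


def bootstrap_selection_counts(table, labels, config: NPFSConfig) -> np.ndarray:
    """Per-feature selection counts over the bootstrap replicates."""
    if config.k >= table.n_features:
        raise ValueError("k must be smaller than the number of features")
    y_states = labels.as_states()
    n_classes = len(labels.classes)
    if config.n_workers == 1:
        indicators = [
            _one_replicate(table.counts, y_states, n_classes, config, b)
            for b in range(config.n_bootstraps)
        ]
    else:
        indicators = Parallel(n_jobs=config.n_workers)(
            delayed(_one_replicate)(table.counts, y_states, n_classes, config, b)
            for b in range(config.n_bootstraps)
        )
    return np.sum(indicators, axis=0)


def np_critical_value(n_bootstraps: int, null_rate: float, alpha_level: float) -> int:
    """Smallest integer zeta with P(Binomial(n, p0) > zeta) <= alpha."""
    if not 0.0 < null_rate < 1.0:
        raise ValueError("null_rate must be in (0, 1)")
    if not 0.0 < alpha_level < 1.0:
        raise ValueError("alpha_level must be in (0, 1)")
    zetas = np.arange(n_bootstraps + 1)
    tail = binom.sf(zetas, n_bootstraps, null_rate)  # P(X > zeta)
    return int(np.argmax(tail <= alpha_level))


def npfs_select(table, labels, config: NPFSConfig) -> NPFSResult:
    """Bootstrap the base selector and test which features are relevant."""
    counts = bootstrap_selection_counts(table, labels, config)
    null_rate = config.k / table.n_features
    zeta = np_critical_value(config.n_bootstraps, null_rate, config.alpha_level)
    relevant = set(np.flatnonzero(counts > zeta).tolist())
    return NPFSResult(
        selection_counts=counts,
        critical_value=zeta,
        relevant=relevant,
        null_rate=null_rate,
    )
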