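"""Seeded synthetic abundance tables with planted statistical structure.

The generator emulates a feature-by-sample OTU count table for a balanced
two-class study: feature baseline abundances are heavy-tailed (lognormal
weights scaled to an expected per-sample depth) and counts are drawn from a
negative binomial, the standard overdispersed count model for microbiome
data.  Four kinds of features can be planted:

* informative - the negative-binomial mean is shifted between classes by
  ``effect_size`` baseline standard deviations;
* redundant - noisy copies (plus Poisson noise) of informative features;
* XOR pairs - presence/absence pairs whose joint parity determines the
  class while each member, by an exactly class-balanced construction, is
  marginally independent of it (an idealized jointly-informative pair);
* noise - class-independent negative-binomial counts.

Everything is determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AbundanceTable, SampleMetadata

__all__ = ["SyntheticSpec", "generate"]


@dataclass
class SyntheticSpec:
    K: int = 100
    M: int = 100
    n_informative: int = 10
    n_redundant: int = 0
    n_xor_pairs: int = 0
    effect_size: float = 2.0
    depth: float = 5000.0
    dispersion: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1 or self.M < 2:
            raise ValueError("need K >= 1 and M >= 2")
        if self.M % 2 != 0:
            raise ValueError("M must be even (balanced classes)")
        planted = self.n_informative + self.n_redundant + 2 * self.n_xor_pairs
        if planted > self.K:
            raise ValueError(f"{planted} planted features exceed K={self.K}")
        if self.n_redundant > 0 and self.n_informative == 0:
            raise ValueError("redundant features need informative features to copy")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.dispersion <= 0 or self.depth <= 0:
            raise ValueError("dispersion and depth must be positive")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, r: float) -> np.ndarray:
    """Negative binomial with mean ``mean`` and shape r (var = mu + mu^2/r)."""
    mean = np.maximum(mean, 1e-9)
    return rng.negative_binomial(r, r / (r + mean))


def generate(
    spec: SyntheticSpec,
) -> tuple[AbundanceTable, SampleMetadata, dict[str, object]]:
    """Draw one synthetic study; returns (table, metadata, ground truth).

    Ground truth holds the planted index sets: ``informative``,
    ``redundant``, ``xor`` (flattened), ``xor_pairs`` (member tuples) and
    ``noise``.  The metadata carries a binary ``class`` column with values
    ``case``/``control`` (first half of the samples are cases).
    """
    rng = np.random.default_rng(spec.seed)
    K, M = spec.K, spec.M
    half = M // 2
    class_bit = np.array([1] * half + [0] * half)  # case=1, control=0
    labels = np.where(class_bit == 1, "case", "control")

    ni, nr, nx = spec.n_informative, spec.n_redundant, 2 * spec.n_xor_pairs
    informative = np.arange(ni)
    redundant = np.arange(ni, ni + nr)
    xor_flat = np.arange(ni + nr, ni + nr + nx)
    noise = np.arange(ni + nr + nx, K)

    # heavy-tailed baseline composition scaled to the expected depth
    weights = rng.lognormal(mean=0.0, sigma=1.5, size=K)
    base_mean = weights / weights.sum() * spec.depth

    counts = np.zeros((K, M), dtype=np.int64)
    r = spec.dispersion

    for j in np.concatenate([informative, noise]):
        mu = np.full(M, base_mean[j])
        if j in informative:
            sd = np.sqrt(base_mean[j] + base_mean[j] ** 2 / r)
            mu = np.where(class_bit == 1, base_mean[j] + spec.effect_size * sd, mu)
        counts[j] = _nb_draw(rng, mu, r)

    for i, j in enumerate(redundant):
        src = counts[informative[i % ni]]
        counts[j] = src + rng.poisson(0.05 * src + 1.0)

    high = max(3, int(round(spec.depth * 0.02)))
    xor_pairs = []
    for p in range(spec.n_xor_pairs):
        j1, j2 = xor_flat[2 * p], xor_flat[2 * p + 1]
        # b exactly balanced within each class: both members are exactly
        # class-balanced marginally, while b XOR class determines member 2
        b = np.empty(M, dtype=np.int64)
        for cls in (0, 1):
            idx = np.flatnonzero(class_bit == cls)
            pattern = np.array([0, 1] * (idx.size // 2) + [0] * (idx.size % 2))
            b[idx] = rng.permutation(pattern)
        counts[j1] = b * high
        counts[j2] = (b ^ class_bit) * high
        xor_pairs.append((int(j1), int(j2)))

    sample_ids = [f"S{i:04d}" for i in range(M)]
    feature_ids = [f"OTU_{j:05d}" for j in range(K)]
    taxonomy = [
        f"k__Bacteria; p__Phylum{j % 7}; g__Genus{j}; s__species{j}" for j in range(K)
    ]
    table = AbundanceTable(counts, feature_ids, sample_ids, taxonomy)
    metadata = SampleMetadata(
        {sid: {"class": str(lab)} for sid, lab in zip(sample_ids, labels)}
    )
    truth = {
        "informative": informative,
        "redundant": redundant,
        "xor": xor_flat,
        "xor_pairs": xor_pairs,
        "noise": noise,
    }
    return table, metadata, truth
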