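"""Hierarchical spiking-raster predictions of the four coding schemes.

A two-level architecture: command neurons (one per synergy) whose firing
probability per time bin is the synergy's usage value scaled by a peak
probability, and synergy-generator neurons (one per degree of freedom per
synergy) that can fire only if their DoF lies in the atom's support, with
the same usage-modulated probability.  Spikes are independent Bernoulli
draws per 30 ms bin over a 1000 ms action; partial trailing bins are
dropped.  The four coding schemes differ only through the structural zero
pattern of the probability matrices (dense for PCA, support-restricted
and/or usage-gated for the sparse schemes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class RasterSpec:
    """Simulation geometry: neuron counts, bin structure, peak probability."""

    n_command_neurons: int = 32
    dofs_per_synergy: int = 10
    duration_ms: float = 1000.0
    bin_ms: float = 30.0
    p_max: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_max <= 1.0):
            raise ValueError(f"p_max must lie in (0, 1], got {self.p_max}")
        if self.bin_ms <= 0 or self.duration_ms <= 0:
            raise ValueError("durations must be positive")

    @property
    def n_bins(self) -> int:
        return int(self.duration_ms // self.bin_ms)


@dataclass
class RasterResult:
    """Binary spike matrices for one action class."""

    class_index: int
    command_spikes: np.ndarray  # (n_command_neurons, n_bins)
    synergy_spikes: np.ndarray  # (n_command_neurons * dofs_per_synergy, n_bins)
    command_probs: np.ndarray
    synergy_probs: np.ndarray


def usage_to_firing_prob(usage_value: float, p_max: float) -> float:
    """Linear map of a usage fraction to a per-bin firing probability."""
    if not (0.0 <= usage_value <= 1.0):
        raise ValueError(f"usage must lie in [0, 1], got {usage_value}")
    return float(np.clip(usage_value * p_max, 0.0, 1.0))


def firing_probabilities(
    usage: np.ndarray, dof_supports: list[np.ndarray], spec: RasterSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class probability matrices for both hierarchical levels.

    Returns (command_probs (r, C), synergy_probs (r*d, C)); a lower-level
    neuron's probability is zero unless its DoF is in its atom's support.
    """
    usage = np.asarray(usage, dtype=float)
    r, C = usage.shape
    if r != spec.n_command_neurons:
        raise ValueError(
            f"usage has {r} atoms but spec declares {spec.n_command_neurons} "
            "command neurons"
        )
    if len(dof_supports) != r:
        raise ValueError("one DoF support per atom required")
    command = usage * spec.p_max
    synergy = np.zeros((r * spec.dofs_per_synergy, C))
    for k, support in enumerate(dof_supports):
        for d in np.asarray(support, dtype=int):
            if not (0 <= d < spec.dofs_per_synergy):
                raise ValueError(f"DoF index {d} outside [0, {spec.dofs_per_synergy})")
            synergy[k * spec.dofs_per_synergy + d] = command[k]
    return command, synergy


def simulate_raster(
    usage: np.ndarray, dof_supports: list[np.ndarray], spec: RasterSpec,
) -> list[RasterResult]:
    """Sample one raster per action class.

    Every neuron fires independently in each bin with its assigned
    probability; the same seeded generator drives all classes.
    """
    command_probs, synergy_probs = firing_probabilities(usage, dof_supports, spec)
    rng = np.random.default_rng(spec.seed)
    n_bins = spec.n_bins
    results = []
    for c in range(usage.shape[1]):
        cp = command_probs[:, c][:, None]
        sp = synergy_probs[:, c][:, None]
        results.append(RasterResult(
            class_index=c,
            command_spikes=(rng.random((cp.shape[0], n_bins)) < cp).astype(int),
            synergy_spikes=(rng.random((sp.shape[0], n_bins)) < sp).astype(int),
            command_probs=cp.ravel(),
            synergy_probs=sp.ravel(),
        ))
    return results


def scheme_probability_patterns(spec: RasterSpec, n_classes: int,
                                rng: np.random.Generator | None = None):
    """Illustrative probability matrices for the four coding schemes.

    Builds usage matrices and DoF supports that caricature each scheme:
    'pca' (all atoms used by all classes, dense supports), 'se' (all used,
    sparse supports), 'sc' (class-restricted usage, dense supports) and
    'ds' (class-restricted usage, sparse supports).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    r, d = spec.n_command_neurons, spec.dofs_per_synergy
    dense_support = [np.arange(d) for _ in range(r)]
    sparse_support = [np.sort(rng.choice(d, size=max(1, d // 3), replace=False))
                      for _ in range(r)]
    full_usage = np.ones((r, n_classes))
    partial = np.zeros((r, n_classes))
    shared = max(1, r // 4)
    partial[:shared] = 1.0
    for c in range(n_classes):
        own = shared + (np.arange(max(1, (r - shared) // n_classes))
                        + c * max(1, (r - shared) // n_classes))
        own = own[own < r]
        partial[own, c] = 1.0
    out = {}
    for tag, (u, sup) in {
        "pca": (full_usage, dense_support),
        "se": (full_usage, sparse_support),
        "sc": (partial, dense_support),
        "ds": (partial, sparse_support),
    }.items():
        out[tag] = firing_probabilities(u, sup, spec)
    return out
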