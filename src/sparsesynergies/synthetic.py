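"""Synthetic dataglove-style grasp datasets with known synergy structure.

Generates trials as weighted sums of temporal postural synergy atoms, each
atom restricted to a small set of joints (the double-sparsity generative
story): a shared pool of atoms is available to every action class while
each class additionally owns selective atoms.  Because the ground-truth
dictionary, class supports and coefficients are returned alongside the
data, every downstream stage — factorization, metrics, classification —
can be tested for recovery without any recorded human data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .groups import GroupStructure, build_joint_groups
from .preprocessing import KinematicDataset


@dataclass
class SynthSpec:
    """Study-design parameters for the generator.

    Defaults mirror the benchmark layout: 9 grasp classes x 50 trials,
    s = 10 joint-angle sensors, trials resampled to 20 time points, and a
    double-sparse dictionary of 13 atoms (4 shared across all classes plus
    one selective atom per class), each atom touching 3 of the 10 joints.
    """

    n_classes: int = 9
    trials_per_class: int = 50
    s: int = 10
    length: int = 20
    r_true: int = 13
    joints_per_atom: int = 3
    n_shared_atoms: int = 4
    n_selective_atoms_per_class: int = 1
    coeff_scale: float = 1.0
    coeff_low: float = 0.5
    coeff_high: float = 1.5
    sigma_gen: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (1 <= self.joints_per_atom <= self.s):
            raise ValueError(
                f"joints_per_atom must lie in [1, s={self.s}], got {self.joints_per_atom}"
            )
        expected = self.n_shared_atoms + self.n_classes * self.n_selective_atoms_per_class
        if expected != self.r_true:
            raise ValueError(
                f"n_shared_atoms + n_classes*n_selective_atoms_per_class = {expected} "
                f"must equal r_true = {self.r_true}"
            )
        if self.sigma_gen < 0:
            raise ValueError(f"sigma_gen must be >= 0, got {self.sigma_gen}")
        if not (0 < self.coeff_low <= self.coeff_high):
            raise ValueError("need 0 < coeff_low <= coeff_high")
        if self.n_classes < 1 or self.trials_per_class < 1 or self.length < 2:
            raise ValueError("need n_classes >= 1, trials_per_class >= 1, length >= 2")

    @property
    def p(self) -> int:
        return self.s * self.length

    @property
    def n(self) -> int:
        return self.n_classes * self.trials_per_class

    @property
    def class_labels(self) -> list[str]:
        return [f"A{i + 1}" for i in range(self.n_classes)]


@dataclass
class GroundTruth:
    """What the generator knows: atoms, per-class supports, coefficients."""

    V_true: np.ndarray  # (p, r_true), unit-norm columns
    class_supports: list[np.ndarray]  # per class, atom indices it may use
    U_true: np.ndarray  # (n, r_true) coefficients actually drawn
    group_structure: GroupStructure
    atom_joints: list[np.ndarray]  # per atom, the joint indices it touches


def _smooth_profile(length: int, rng: np.random.Generator) -> np.ndarray:
    """A smooth, everywhere-nonzero temporal profile for one joint of one atom.

    One to three raised-cosine bumps with random centers, widths and
    amplitudes on a small positive baseline, the whole excursion given a
    random sign (flexion vs extension).  Random bump placement keeps
    different atoms' profiles dissimilar, which is what makes distinct
    grasp types distinguishable; the baseline guarantees no in-support
    sample is exactly zero.
    """
    t = np.arange(length, dtype=float)
    prof = np.zeros(length)
    for _ in range(rng.integers(1, 4)):
        center = rng.uniform(0.1, 0.9) * (length - 1)
        width = rng.uniform(0.2, 0.5) * length
        bump = 0.5 * (1.0 + np.cos(np.pi * (t - center) / width))
        bump[np.abs(t - center) > width] = 0.0
        prof += rng.uniform(0.3, 1.0) * bump
    sign = -1.0 if rng.random() < 0.5 else 1.0
    return sign * (0.1 + prof)


def make_ground_truth_dictionary(
    spec: SynthSpec, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, GroupStructure, list[np.ndarray]]:
    """Draw the ground-truth atom matrix V_true (p x r_true).

    Each atom's support is the union of ``joints_per_atom`` randomly chosen
    joint groups; within each chosen joint the temporal profile is smooth
    and nonzero at every sample; columns are normalized to unit l2 norm.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    gs = build_joint_groups(spec.s, spec.length)
    V = np.zeros((spec.p, spec.r_true))
    atom_joints: list[np.ndarray] = []
    for k in range(spec.r_true):
        joints = rng.choice(spec.s, size=spec.joints_per_atom, replace=False)
        joints = np.sort(joints)
        atom_joints.append(joints)
        for j in joints:
            V[gs.groups[j], k] = _smooth_profile(spec.length, rng)
        V[:, k] /= np.linalg.norm(V[:, k])
    return V, gs, atom_joints


def make_class_supports(spec: SynthSpec) -> list[np.ndarray]:
    """Atom indices usable by each class.

    The first ``n_shared_atoms`` indices belong to every class; the
    remaining indices are partitioned, ``n_selective_atoms_per_class`` to
    each class in order.
    """
    spec.validate()
    shared = np.arange(spec.n_shared_atoms)
    supports = []
    for c in range(spec.n_classes):
        lo = spec.n_shared_atoms + c * spec.n_selective_atoms_per_class
        own = np.arange(lo, lo + spec.n_selective_atoms_per_class)
        supports.append(np.concatenate([shared, own]))
    return supports


def generate_dataset(spec: SynthSpec) -> tuple[KinematicDataset, GroundTruth]:
    """Generate a labelled synthetic grasp dataset plus its ground truth.

    Each trial of class c is  x = sum_{j in support(c)} u_j V_true^j + eps
    with u_j ~ Uniform(coeff_low, coeff_high) * coeff_scale and eps i.i.d.
    Gaussian(0, sigma_gen); each sensor's pooled values are then mapped
    linearly into [-1, 1].  Bit-identical under the same spec + seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    V_true, gs, atom_joints = make_ground_truth_dictionary(spec, rng)
    supports = make_class_supports(spec)

    n = spec.n
    U = np.zeros((n, spec.r_true))
    labels = np.empty(n, dtype=object)
    row = 0
    for c, label in enumerate(spec.class_labels):
        for _ in range(spec.trials_per_class):
            u = rng.uniform(spec.coeff_low, spec.coeff_high, size=supports[c].size)
            U[row, supports[c]] = u * spec.coeff_scale
            labels[row] = label
            row += 1
    X = U @ V_true.T
    if spec.sigma_gen > 0:
        X = X + rng.normal(0.0, spec.sigma_gen, size=X.shape)

    # per-sensor linear map of pooled values into [-1, 1]
    sensor_min = np.empty(spec.s)
    sensor_max = np.empty(spec.s)
    for j, g in enumerate(gs.groups):
        vals = X[:, g]
        sensor_min[j], sensor_max[j] = vals.min(), vals.max()
        span = sensor_max[j] - sensor_min[j]
        if span <= 0:
            # a sensor touched by no atom under zero noise stays flat;
            # park it at the center of the normalized range
            X[:, g] = 0.0
        else:
            X[:, g] = 2.0 * (vals - sensor_min[j]) / span - 1.0

    dataset = KinematicDataset(
        X=X, labels=labels.astype(str), s=spec.s, length=spec.length,
        sensor_min=sensor_min, sensor_max=sensor_max,
    )
    truth = GroundTruth(
        V_true=V_true, class_supports=supports, U_true=U,
        group_structure=gs, atom_joints=atom_joints,
    )
    return dataset, truth
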