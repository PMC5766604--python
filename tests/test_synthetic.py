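"""Generator contracts: supports, sparsity, balance, determinism."""

import numpy as np
import pytest

from sparsesynergies import (
    SynthSpec,
    dict_sparsity,
    generate_dataset,
    make_class_supports,
    make_ground_truth_dictionary,
    metric_report,
)


def _spec(**kw):
    base = dict(n_classes=3, trials_per_class=10, s=6, length=8, r_true=5,
                joints_per_atom=2, n_shared_atoms=2,
                n_selective_atoms_per_class=1, sigma_gen=0.0, seed=1)
    base.update(kw)
    return SynthSpec(**base)


class TestGroundTruthDictionary:
    def test_columns_are_unit_norm(self):
        V, _, _ = make_ground_truth_dictionary(_spec())
        np.testing.assert_allclose(np.linalg.norm(V, axis=0), 1.0, atol=1e-12)

    def test_dict_sparsity_equals_one_minus_q_over_s(self):
        # q = 3 of s = 10 joints with all in-support entries nonzero
        spec = _spec(s=10, joints_per_atom=3, length=20)
        V, _, _ = make_ground_truth_dictionary(spec)
        assert dict_sparsity(V) == pytest.approx(1 - 3 / 10)

    def test_full_joint_atoms_have_no_zeros(self):
        spec = _spec(joints_per_atom=6)  # q = s
        V, _, _ = make_ground_truth_dictionary(spec)
        assert dict_sparsity(V) == 0.0

    def test_atom_support_confined_to_declared_joints(self):
        spec = _spec()
        V, gs, atom_joints = make_ground_truth_dictionary(spec)
        for k, joints in enumerate(atom_joints):
            inside = np.concatenate([gs.groups[j] for j in joints])
            outside = np.setdiff1d(np.arange(spec.p), inside)
            assert np.all(V[outside, k] == 0.0)
            assert np.all(np.abs(V[inside, k]) > 1e-6)

    def test_joints_per_atom_larger_than_s_rejected(self):
        with pytest.raises(ValueError):
            _spec(joints_per_atom=7)


class TestClassSupports:
    def test_shared_then_partitioned(self):
        # 2 classes, 1 shared + 1 selective each -> supports {0,1} and {0,2}
        spec = _spec(n_classes=2, r_true=3, n_shared_atoms=1,
                     n_selective_atoms_per_class=1)
        supports = make_class_supports(spec)
        np.testing.assert_array_equal(supports[0], [0, 1])
        np.testing.assert_array_equal(supports[1], [0, 2])

    def test_all_shared_means_identical_supports(self):
        spec = _spec(n_shared_atoms=5, n_selective_atoms_per_class=0)
        for sup in make_class_supports(spec):
            np.testing.assert_array_equal(sup, np.arange(5))

    def test_no_shared_means_disjoint_supports(self):
        spec = _spec(r_true=6, n_shared_atoms=0,
                     n_selective_atoms_per_class=2)
        supports = make_class_supports(spec)
        for i in range(len(supports)):
            for j in range(i + 1, len(supports)):
                assert np.intersect1d(supports[i], supports[j]).size == 0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            _spec(n_shared_atoms=3)  # 3 + 3*1 != 5


class TestGenerateDataset:
    def test_default_layout_is_450_trials(self):
        dataset, _ = generate_dataset(SynthSpec(seed=0))
        assert dataset.n == 450
        assert dataset.p == 200

    def test_labels_balanced(self):
        dataset, _ = generate_dataset(_spec())
        _, counts = np.unique(dataset.labels, return_counts=True)
        assert np.all(counts == 10)

    def test_noiseless_reconstruction_is_exact_before_rescaling(self):
        spec = _spec(sigma_gen=0.0)
        _, truth = generate_dataset(spec)
        # U_true and V_true reproduce the pre-normalization signal exactly
        X_raw = truth.U_true @ truth.V_true.T
        assert np.all(np.isfinite(X_raw))
        # coefficients appear only inside the class support
        labels = np.repeat(np.arange(spec.n_classes), spec.trials_per_class)
        for c in range(spec.n_classes):
            rows = truth.U_true[labels == c]
            outside = np.setdiff1d(np.arange(spec.r_true),
                                   truth.class_supports[c])
            assert np.all(rows[:, outside] == 0.0)
            assert np.all(rows[:, truth.class_supports[c]] > 0.0)

    def test_values_lie_in_unit_interval(self):
        dataset, _ = generate_dataset(_spec(sigma_gen=0.05))
        assert dataset.X.min() >= -1.0 - 1e-12
        assert dataset.X.max() <= 1.0 + 1e-12

    def test_single_atom_noiseless_rows_identical_up_to_rescale(self):
        spec = _spec(n_classes=1, r_true=1, n_shared_atoms=1,
                     n_selective_atoms_per_class=0, sigma_gen=0.0,
                     coeff_low=1.0, coeff_high=1.0)
        dataset, truth = generate_dataset(spec)
        # all rows identical: same coefficient, same atom, no noise
        np.testing.assert_allclose(dataset.X - dataset.X[0][None, :], 0.0,
                                   atol=1e-12)

    def test_same_seed_bit_identical(self):
        a, _ = generate_dataset(_spec(sigma_gen=0.1, seed=9))
        b, _ = generate_dataset(_spec(sigma_gen=0.1, seed=9))
        assert np.array_equal(a.X, b.X)
        assert np.array_equal(a.labels, b.labels)

    def test_different_seed_differs(self):
        a, _ = generate_dataset(_spec(sigma_gen=0.1, seed=9))
        b, _ = generate_dataset(_spec(sigma_gen=0.1, seed=10))
        assert not np.array_equal(a.X, b.X)


class TestGroundTruthUsageStatistics:
    def test_selective_atoms_have_selectivity_one_and_shared_commonality_one(self):
        spec = _spec()
        dataset, truth = generate_dataset(spec)
        report = metric_report(truth.U_true, truth.V_true, dataset.labels)
        # shared atoms: used by every trial of every class -> commonality 1
        for k in range(spec.n_shared_atoms):
            assert report.commonality[k] == pytest.approx(1.0)
        # selective atoms: exclusively used by their own class -> selectivity 1
        for c in range(spec.n_classes):
            k = spec.n_shared_atoms + c
            assert report.selectivity[k, c] == pytest.approx(1.0)

    def test_coeff_sparsity_matches_support_construction(self):
        spec = _spec()
        dataset, truth = generate_dataset(spec)
        # each trial uses exactly n_shared + n_selective of the r atoms
        used = spec.n_shared_atoms + spec.n_selective_atoms_per_class
        expected = 1 - used / spec.r_true
        report = metric_report(truth.U_true, truth.V_true, dataset.labels)
        assert report.coeff_sparsity == pytest.approx(expected)
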