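"""Quaternion primitives, the two-phase optimizer, and the Kabsch oracle."""

import numpy as np
import pytest

import quatfit as qf
from quatfit.core import OptimizerSchedule, QuaternionBatch, _loss_and_grad
from quatfit.pdb_io import CoordinateBatch, ReferenceFrame

from conftest import make_rotated_batch


class TestCenterBatch:
    def test_centering_is_idempotent_on_full_mask(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(2, 6, 3))
        coords -= coords.mean(axis=1, keepdims=True)
        batch = CoordinateBatch(coords.copy(), np.ones((2, 6)), ["a", "b"])
        centered, centroids = qf.center_batch(batch)
        assert np.abs(centroids).max() < 1e-12
        assert np.allclose(centered.coords, coords)

    def test_masked_centroid_uses_only_unmasked_rows(self):
        # 5-point fixture, 2 rows masked with garbage: hand-computed mean of the other 3
        coords = np.array(
            [[[0, 0, 0], [3, 0, 0], [0, 6, 0], [99, 99, 99], [-50, 1, 2]]], dtype=float
        )
        mask = np.array([[1, 1, 1, 0, 0]], dtype=float)
        centered, centroids = qf.center_batch(CoordinateBatch(coords, mask, ["s"]))
        assert np.allclose(centroids[0], [1.0, 2.0, 0.0])
        assert np.all(centered.coords[0][3:] == 0.0)  # masked rows reset to zero

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(1, 8, 3))
        batch = CoordinateBatch(coords, np.ones((1, 8)), ["s"])
        shifted = CoordinateBatch(coords + np.array([10.0, 0, 0]), np.ones((1, 8)), ["s"])
        c1, _ = qf.center_batch(batch)
        c2, _ = qf.center_batch(shifted)
        assert np.allclose(c1.coords, c2.coords)

    def test_empty_mask_row_errors(self):
        batch = CoordinateBatch(np.zeros((1, 4, 3)), np.zeros((1, 4)), ["s"])
        with pytest.raises(ValueError, match="no unmasked"):
            qf.center_batch(batch)


class TestInitQuaternions:
    def test_seed_determinism_and_support(self):
        a = qf.init_quaternions(1000, seed=42).q
        b = qf.init_quaternions(1000, seed=42).q
        assert np.array_equal(a, b)
        assert a.min() >= 0.0 and a.max() < 1.0

    def test_component_means_near_half(self):
        q = qf.init_quaternions(10_000, seed=3).q
        assert np.all(q.mean(axis=0) > 0.45) and np.all(q.mean(axis=0) < 0.55)


class TestRotate:
    def test_identity_quaternion_is_noop(self):
        coords = np.random.default_rng(0).normal(size=(3, 5, 3))
        q = np.tile([1.0, 0, 0, 0], (3, 1))
        assert np.allclose(qf.rotate(q, coords), coords)

    def test_half_turn_about_z(self):
        coords = np.random.default_rng(0).normal(size=(1, 5, 3))
        got = qf.rotate(np.array([[0.0, 0, 0, 1.0]]), coords)
        assert np.allclose(got, coords * [-1, -1, 1])

    def test_rotation_matrices_proper_orthogonal(self):
        q = np.random.default_rng(5).normal(size=(50, 4))
        R = qf.quaternion_matrix(q)
        eye = np.einsum("nab,ncb->nac", R, R)
        assert np.abs(eye - np.eye(3)).max() < 1e-9
        assert np.allclose(np.linalg.det(R), 1.0, atol=1e-9)

    def test_distances_preserved(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(4, 10, 3)) * 5
        rotated = qf.rotate(rng.normal(size=(4, 4)), coords)
        d0 = np.linalg.norm(coords[:, :, None] - coords[:, None], axis=-1)
        d1 = np.linalg.norm(rotated[:, :, None] - rotated[:, None], axis=-1)
        assert np.abs(d0 - d1).max() < 1e-9

    def test_zero_quaternion_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            qf.rotate(np.zeros((1, 4)), np.zeros((1, 3, 3)))

    def test_q_and_minus_q_encode_the_same_rotation(self):
        q = np.random.default_rng(3).normal(size=(20, 4))
        assert np.allclose(qf.quaternion_matrix(q), qf.quaternion_matrix(-q), atol=1e-12)


class TestMaskedRMSD:
    def test_zero_for_identical_coordinates(self):
        ref = np.random.default_rng(0).normal(size=(6, 3))
        out = qf.masked_rmsd(ref[None], ref, np.ones((1, 6)))
        assert out[0] == 0.0

    def test_two_points_at_distance_d_give_rmsd_d(self):
        ref = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        coords = ref + np.array([0.0, 3.0, 0.0])  # both displaced by d=3
        assert qf.masked_rmsd(coords[None], ref, np.ones((1, 2)))[0] == pytest.approx(3.0)

    def test_masked_garbage_slots_are_ignored(self):
        ref = np.random.default_rng(1).normal(size=(5, 3))
        coords = ref.copy()
        coords[[1, 4]] = 1e6  # garbage at masked slots
        mask = np.array([[1.0, 0, 1, 1, 0]])
        got = qf.masked_rmsd(coords[None], ref, mask)
        # hand computation over the three real points: identical -> 0
        assert got[0] == pytest.approx(0.0)

    def test_all_masked_row_errors(self):
        with pytest.raises(ValueError, match="zero unmasked"):
            qf.masked_rmsd(np.zeros((1, 3, 3)), np.zeros((3, 3)), np.zeros((1, 3)))


class TestKabsch:
    def test_self_fit_gives_identity(self):
        ref = np.random.default_rng(0).normal(size=(10, 3))
        ref -= ref.mean(axis=0)
        R, rmsd = qf.kabsch_superimpose(ref, ref)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(R, np.eye(3), atol=1e-9)

    def test_recovers_an_applied_rotation(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(12, 3))
        ref -= ref.mean(axis=0)
        q = qf.random_quaternions(1, rng)[0]
        R_true = qf.quaternion_matrix(q[None])[0]
        moved = ref @ R_true.T
        R, rmsd = qf.kabsch_superimpose(moved, ref)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.abs(R @ R_true - np.eye(3)).max() < 1e-9

    def test_agrees_with_scipy_align_vectors(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(2)
        ref = rng.normal(size=(15, 3)) * 4
        ref -= ref.mean(axis=0)
        moved = rng.normal(size=(15, 3)) * 4
        moved -= moved.mean(axis=0)
        R, rmsd = qf.kabsch_superimpose(moved, ref)
        rot, rssd = Rotation.align_vectors(ref, moved)
        assert np.abs(R - rot.as_matrix()).max() < 1e-9
        assert rmsd == pytest.approx(rssd / np.sqrt(15), abs=1e-9)

    def test_mirrored_set_gets_proper_rotation_beating_brute_force_search(self):
        # reflection correction: det stays +1, rmsd > 0, and no sampled proper
        # rotation does better than the closed form on a mirrored 4-point set
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(4, 3)) * 3
        ref -= ref.mean(axis=0)
        mirrored = ref * np.array([1.0, 1.0, -1.0])
        mirrored -= mirrored.mean(axis=0)
        R, rmsd = qf.kabsch_superimpose(mirrored, ref)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1
        qs = qf.random_quaternions(200_000, rng)
        rots = qf.quaternion_matrix(qs)
        cand = np.einsum("nab,lb->nla", rots, mirrored)
        best = np.sqrt(((cand - ref) ** 2).sum(axis=2).mean(axis=1)).min()
        assert rmsd <= best + 1e-6

    def test_collinear_points_rejected(self):
        line = np.outer(np.arange(5) - 2.0, [1.0, 0, 0])
        with pytest.raises(ValueError, match="rank-deficient"):
            qf.kabsch_superimpose(line, line)


class TestOptimizerSchedule:
    def test_phase1_length_non_increasing_in_residue_count(self):
        sched = OptimizerSchedule()
        lengths = [sched.phase1_steps(L) for L in (3, 4, 10, 50, 300, 5000)]
        assert lengths == sorted(lengths, reverse=True)
        assert lengths[-1] >= sched.phase1_min_steps

    def test_step_size_ordering_enforced(self):
        with pytest.raises(ValueError):
            OptimizerSchedule(phase1_lr=0.01, phase2_lr=0.05)


class TestOptimize:
    def test_exact_rotated_copies_recover_to_sub_millianstrom(self, frame50):
        batch, _ = make_rotated_batch(frame50, n=20, seed=0)
        centered, centroids = qf.center_batch(batch)
        result = qf.optimize(centered, frame50, centroids=centroids)
        assert result.rmsd.max() <= 1e-3

    def test_reference_itself_yields_zero_rmsd_and_identity_rotation(self, frame50):
        coords = frame50.ref_coords[None].copy()
        batch = CoordinateBatch(coords, np.ones((1, len(frame50))), ["ref"])
        result = qf.optimize(batch, frame50)
        assert result.rmsd[0] <= 1e-6
        # identity up to sign: |w| ~ 1
        assert abs(result.quaternions[0, 0]) > 1 - 1e-6

    def test_noisy_structures_match_kabsch_oracle(self, frame50):
        batch, _ = make_rotated_batch(frame50, n=30, seed=1, noise_sigma=1.0)
        centered, centroids = qf.center_batch(batch)
        result = qf.optimize(centered, frame50, centroids=centroids)
        for i in range(30):
            _, k = qf.kabsch_superimpose(centered.coords[i], frame50.ref_coords, centered.mask[i])
            assert abs(result.rmsd[i] - k) <= 1e-3

    def test_rigidity_transform_reproduces_internal_coordinates(self, frame50):
        batch, _ = make_rotated_batch(frame50, n=5, seed=2, noise_sigma=0.5)
        centered, centroids = qf.center_batch(batch)
        result = qf.optimize(centered, frame50, centroids=centroids)
        internal = qf.rotate(result.quaternions, centered.coords)
        for i, t in enumerate(result.transforms):
            external = qf.apply_transform(t, batch.coords[i]) - frame50.ref_centroid
            m = centered.mask[i].astype(bool)
            assert np.abs(external[m] - internal[i][m]).max() < 1e-6

    def test_seed_determinism_is_bitwise(self, frame50):
        batch, _ = make_rotated_batch(frame50, n=4, seed=3, noise_sigma=0.5)
        centered, centroids = qf.center_batch(batch)
        r1 = qf.optimize(centered, frame50, OptimizerSchedule(seed=9), centroids=centroids)
        r2 = qf.optimize(centered, frame50, OptimizerSchedule(seed=9), centroids=centroids)
        assert np.array_equal(r1.quaternions, r2.quaternions)

    def test_joint_and_single_optimization_agree(self, frame50):
        batch, _ = make_rotated_batch(frame50, n=6, seed=4, noise_sigma=0.5)
        centered, centroids = qf.center_batch(batch)
        joint = qf.optimize(centered, frame50, centroids=centroids)
        init = qf.init_quaternions(6, OptimizerSchedule().seed).q
        for i in range(6):
            # same per-structure starting quaternion: slice the joint init
            single_batch = CoordinateBatch(
                centered.coords[i : i + 1], centered.mask[i : i + 1], [batch.names[i]]
            )
            single = qf.optimize(single_batch, frame50, init=init[i : i + 1])
            assert abs(joint.rmsd[i] - single.rmsd[0]) <= 1e-6

    def test_phase2_loss_is_monotonically_non_increasing(self, frame50):
        for sigma in (0.0, 0.5, 2.0):
            batch, _ = make_rotated_batch(frame50, n=8, seed=5, noise_sigma=sigma)
            centered, centroids = qf.center_batch(batch)
            result = qf.optimize(centered, frame50, centroids=centroids, track_loss=True)
            tail = result.loss_history[-10:]
            drops = np.diff(tail, axis=0)
            assert np.all(drops <= 1e-12 * np.maximum(tail[:-1], 1.0))

    def test_masked_garbage_does_not_change_rmsd(self, frame50):
        batch, _ = make_rotated_batch(frame50, n=5, seed=6, deletion_fraction=0.2)
        centered, centroids = qf.center_batch(batch)
        clean = qf.optimize(centered, frame50, centroids=centroids)
        dirty_coords = centered.coords.copy()
        rng = np.random.default_rng(0)
        garbage = rng.normal(scale=1e3, size=dirty_coords.shape)
        dirty_coords[centered.mask == 0] = garbage[centered.mask == 0]
        dirty = CoordinateBatch(dirty_coords, centered.mask, centered.names)
        redone = qf.optimize(dirty, frame50, centroids=centroids)
        assert np.abs(clean.rmsd - redone.rmsd).max() <= 1e-9

    def test_too_few_unmasked_residues_rejected(self, frame50):
        batch, _ = make_rotated_batch(frame50, n=1, seed=7)
        batch.mask[0, 2:] = 0.0
        with pytest.raises(ValueError, match="fewer than 3"):
            qf.optimize(batch, frame50)


def test_analytic_gradient_matches_finite_differences():
    rng = np.random.default_rng(0)
    coords = rng.normal(size=(2, 7, 3))
    mask = np.ones((2, 7))
    mask[1, [2, 5]] = 0
    coords *= mask[:, :, None]
    ref = rng.normal(size=(7, 3))
    counts = mask.sum(axis=1)
    q = rng.normal(size=(2, 4))
    _, grad = _loss_and_grad(q, coords, ref, mask, counts)
    eps = 1e-6
    for i in range(2):
        for k in range(4):
            qp, qm = q.copy(), q.copy()
            qp[i, k] += eps
            qm[i, k] -= eps
            lp, _ = _loss_and_grad(qp, coords, ref, mask, counts)
            lm, _ = _loss_and_grad(qm, coords, ref, mask, counts)
            assert grad[i, k] == pytest.approx((lp[i] - lm[i]) / (2 * eps), abs=1e-6)


def test_quaternion_batch_normalization():
    qb = QuaternionBatch(np.array([[2.0, 0, 0, 0], [1.0, 1, 1, 1]]))
    norms = np.linalg.norm(qb.normalized().q, axis=1)
    assert np.abs(norms - 1).max() < 1e-9
    with pytest.raises(ValueError, match="degenerate"):
        QuaternionBatch(np.zeros((1, 4))).normalized()
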