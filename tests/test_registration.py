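"""Transformation estimation, validation gate and max-point motion."""

import numpy as np
import pytest

from aaamotion.registration import (
    CorrespondenceSet,
    DegenerateGeometryError,
    GateError,
    Landmark,
    LinearTransform,
    TooFewPairsError,
    apply_transform,
    estimate_transform,
    maxpoint_motion,
    validate_transform,
)
from conftest import (
    affine_normal_equations_oracle,
    landmark_cloud,
    make_correspondences,
    procrustes_oracle,
    random_affine,
    random_rotation,
)


class TestEstimateTransform:
    def test_identity_on_self_correspondences(self, rng):
        src = landmark_cloud(rng)
        corr = make_correspondences(src, np.eye(3), np.zeros(3))
        T = estimate_transform(corr, "affine")
        assert np.allclose(T.matrix, np.eye(3), atol=1e-10)
        assert np.allclose(T.translation, 0, atol=1e-9)
        assert T.fit_rms == pytest.approx(0, abs=1e-9)

    def test_pure_translation_rigid(self, rng):
        src = landmark_cloud(rng)
        corr = make_correspondences(src, np.eye(3), np.array([10.0, 0.0, 0.0]))
        T = estimate_transform(corr, "rigid")
        assert np.allclose(T.matrix, np.eye(3), atol=1e-10)
        assert np.allclose(T.translation, [10, 0, 0], atol=1e-9)
        assert T.fit_rms == pytest.approx(0, abs=1e-9)

    @pytest.mark.parametrize("rep", range(5))
    def test_planted_affine_recovered_entrywise(self, rng, rep):
        src = landmark_cloud(rng)
        A, t = random_affine(rng)
        corr = make_correspondences(src, A, t)
        T = estimate_transform(corr, "affine")
        assert np.allclose(T.matrix, A, atol=1e-8)
        assert np.allclose(T.translation, t, atol=1e-8)

    def test_rotation_only_input_yields_orthogonal_affine_solution(self, rng):
        src = landmark_cloud(rng)
        R, t = random_rotation(rng), rng.uniform(-30, 30, 3)
        corr = make_correspondences(src, R, t)
        T = estimate_transform(corr, "affine")
        assert np.allclose(T.matrix @ T.matrix.T, np.eye(3), atol=1e-8)
        assert np.allclose(T.matrix, R, atol=1e-8)

    @pytest.mark.parametrize("mode", ["rigid", "similarity", "affine"])
    def test_oracle_equivalence(self, rng, mode):
        """Rigid agrees with SVD Procrustes, affine with normal equations."""
        for _ in range(100):
            src = landmark_cloud(rng, n=7)
            dst = src @ random_rotation(rng).T + rng.uniform(-20, 20, 3)
            dst = dst + rng.normal(0, 3.0, dst.shape)  # noisy: solutions nontrivial
            corr = CorrespondenceSet(
                "X", tuple((s, d, f"l{i}") for i, (s, d) in enumerate(zip(src, dst)))
            )
            T = estimate_transform(corr, mode)
            if mode == "rigid":
                R, t = procrustes_oracle(src, dst)
                assert np.allclose(T.matrix, R, atol=1e-8)
                assert np.allclose(T.translation, t, atol=1e-8)
            elif mode == "affine":
                A, t = affine_normal_equations_oracle(src, dst)
                assert np.allclose(T.matrix, A, atol=1e-8)
                assert np.allclose(T.translation, t, atol=1e-8)
            else:
                s = np.linalg.det(T.matrix) ** (1 / 3)
                assert s > 0
                assert np.allclose((T.matrix / s) @ (T.matrix / s).T, np.eye(3), atol=1e-8)

    def test_mode_nesting_of_fit_residuals(self, rng):
        """Wider families fit at least as well: affine <= similarity <= rigid."""
        for _ in range(20):
            src = landmark_cloud(rng, n=8)
            dst = src @ random_rotation(rng).T * 1.05 + rng.normal(0, 4, (8, 3))
            corr = CorrespondenceSet(
                "X", tuple((s, d, f"l{i}") for i, (s, d) in enumerate(zip(src, dst)))
            )
            rms = {m: estimate_transform(corr, m).fit_rms for m in ("rigid", "similarity", "affine")}
            assert rms["affine"] <= rms["similarity"] + 1e-9
            assert rms["similarity"] <= rms["rigid"] + 1e-9

    def test_left_invariance_under_common_rigid_motion(self, rng):
        """Composing both frames with one rigid motion changes no distance."""
        src = landmark_cloud(rng)
        A, t = random_affine(rng)
        val_src = rng.uniform(-40, 40, 3)
        mp = [(rng.uniform(-40, 40, 3), rng.uniform(-40, 40, 3), "max_ilt")]
        corr = make_correspondences(src, A, t, noise_sd=2.0, rng=rng,
                                    validation_src=val_src, maxpoints=mp)
        R, c = random_rotation(rng), rng.uniform(-100, 100, 3)

        def move(p):
            return R @ p + c

        corr2 = CorrespondenceSet(
            "T01",
            tuple((move(s), move(d), lab) for s, d, lab in corr.fit_pairs),
            (move(corr.validation_pair[0]), move(corr.validation_pair[1]), "validation"),
            tuple((move(s), move(d), lab) for s, d, lab in corr.maxpoint_pairs),
        )
        for mode in ("rigid", "similarity", "affine"):
            T1, T2 = estimate_transform(corr, mode), estimate_transform(corr2, mode)
            assert T1.fit_rms == pytest.approx(T2.fit_rms, abs=1e-8)
            v1, v2 = validate_transform(T1, corr), validate_transform(T2, corr2)
            assert v1.distance == pytest.approx(v2.distance, abs=1e-8)
            m1 = maxpoint_motion(T1, corr)
            m2 = maxpoint_motion(T2, corr2)
            assert m1[0].distance == pytest.approx(m2[0].distance, abs=1e-8)

    def test_inverse_direction_reproduces_distances_noise_free(self, rng):
        """Swapping roles and inverting the affine fit gives the same motions."""
        src = landmark_cloud(rng)
        A, t = random_affine(rng)
        mp_src = rng.uniform(-40, 40, 3)
        mp_dst = A @ mp_src + t + np.array([3.0, 0, 4.0])  # planted 5 mm motion
        corr = make_correspondences(src, A, t, maxpoints=[(mp_src, mp_dst, "max_ilt")])
        T = estimate_transform(corr, "affine")
        fwd = maxpoint_motion(T, corr)[0].distance
        corr_rev = CorrespondenceSet(
            "T01",
            tuple((d, s, lab) for s, d, lab in corr.fit_pairs),
            None,
            ((mp_dst, mp_src, "max_ilt"),),
        )
        T_rev = estimate_transform(corr_rev, "affine")
        # the swapped-roles fit equals the inverse of the forward fit ...
        assert np.allclose(T_rev.matrix, T.inverse().matrix, atol=1e-6)
        assert np.allclose(T_rev.translation, T.inverse().translation, atol=1e-6)
        # ... and the reverse-measured motion, mapped back into CT2, matches
        pred_ct1 = apply_transform(T_rev, mp_dst)
        rev = np.linalg.norm(apply_transform(T, pred_ct1) - apply_transform(T, mp_src))
        assert rev == pytest.approx(fwd, abs=1e-6)

    def test_too_few_pairs_raises_counted_error(self, rng):
        src = landmark_cloud(rng, n=4)[:3]
        corr = CorrespondenceSet(
            "X", tuple((s, s, f"l{i}") for i, s in enumerate(src))
        )
        with pytest.raises(TooFewPairsError, match="affine"):
            estimate_transform(corr, "affine")
        estimate_transform(corr, "rigid")  # 3 pairs suffice for rigid

    def test_coplanar_points_rejected_for_affine_with_labels(self):
        src = np.array(
            [[0, 0, 0], [40, 0, 0], [0, 40, 0], [40, 40, 0], [20, 20, 0]], float
        )
        corr = CorrespondenceSet(
            "X", tuple((s, s, f"plane_{i}") for i, s in enumerate(src))
        )
        with pytest.raises(DegenerateGeometryError, match="plane_0"):
            estimate_transform(corr, "affine")
        estimate_transform(corr, "rigid")  # planar clouds are fine for rigid

    def test_collinear_points_rejected_for_rigid(self):
        src = np.array([[0, 0, 0], [10, 0, 0], [20, 0, 0], [30, 0, 0]], float)
        corr = CorrespondenceSet("X", tuple((s, s, f"line_{i}") for i, s in enumerate(src)))
        with pytest.raises(DegenerateGeometryError, match="collinear"):
            estimate_transform(corr, "rigid")


class TestApplyTransform:
    def test_identity_and_translation(self):
        T = LinearTransform(np.eye(3), np.zeros(3))
        assert np.allclose(apply_transform(T, [1, 2, 3]), [1, 2, 3])
        T = LinearTransform(np.eye(3), np.array([0, 0, 5.0]))
        assert np.allclose(apply_transform(T, [0, 0, 0]), [0, 0, 5])

    def test_matches_direct_arithmetic(self, rng):
        A, t = random_affine(rng)
        T = LinearTransform(A, t)
        p = rng.uniform(-50, 50, 3)
        assert np.allclose(apply_transform(T, p), A @ p + t, atol=1e-12)
        pts = rng.uniform(-50, 50, (6, 3))
        assert np.allclose(apply_transform(T, pts), pts @ A.T + t, atol=1e-12)


class TestValidationGate:
    def test_noise_free_validation_distance_zero(self, rng):
        src = landmark_cloud(rng)
        A, t = random_affine(rng)
        corr = make_correspondences(src, A, t, validation_src=rng.uniform(-40, 40, 3))
        T = estimate_transform(corr, "affine")
        v = validate_transform(T, corr)
        assert v.distance == pytest.approx(0, abs=1e-8)
        assert v.accepted

    def test_boundary_distance_exactly_15_is_rejected(self, rng):
        src = landmark_cloud(rng)
        corr0 = make_correspondences(src, np.eye(3), np.zeros(3))
        T = LinearTransform(np.eye(3), np.zeros(3), "affine", 0.0)
        val_src = np.zeros(3)
        val_tgt = np.array([15.0, 0.0, 0.0])  # displaced exactly 15 mm
        corr = CorrespondenceSet("X", corr0.fit_pairs, (val_src, val_tgt, "validation"))
        v = validate_transform(T, corr, threshold=15.0)
        assert v.distance == pytest.approx(15.0, abs=1e-12)
        assert not v.accepted  # strict inequality

    def test_missing_validation_pair_raises(self, rng):
        src = landmark_cloud(rng)
        corr = make_correspondences(src, np.eye(3), np.zeros(3))
        T = estimate_transform(corr, "affine")
        with pytest.raises(ValueError, match="validation"):
            validate_transform(T, corr)

    def test_monte_carlo_distances_match_brute_force_resimulation(self, rng):
        """Noisy validation distances agree with an independent re-simulation."""
        src = landmark_cloud(rng)
        R, t = random_rotation(rng), rng.uniform(-30, 30, 3)
        val_src = rng.uniform(-40, 40, 3)
        sd = 2.0
        seeds = np.arange(500)
        dists = []
        for s in seeds:
            r2 = np.random.default_rng(s)
            corr = make_correspondences(src, R, t, noise_sd=sd, rng=r2,
                                        validation_src=val_src)
            T = estimate_transform(corr, "rigid")
            dists.append(validate_transform(T, corr).distance)
        dists = np.asarray(dists)
        assert np.all(dists >= 0)
        # brute-force re-simulation with identical streams must reproduce exactly
        r2 = np.random.default_rng(int(seeds[0]))
        dst = src @ R.T + t + r2.normal(0, sd, src.shape)
        vt = R @ val_src + t + r2.normal(0, sd, 3)
        Ro, to = procrustes_oracle(src, dst)
        assert np.linalg.norm(Ro @ val_src + to - vt) == pytest.approx(dists[0], abs=1e-8)
        # acceptance rate at the 15 mm gate is reported and high at sd = 2 mm
        assert np.mean(dists < 15.0) > 0.95


class TestMaxpointMotion:
    def _corr_with_motion(self, rng, motions):
        src = landmark_cloud(rng)
        A, t = random_affine(rng)
        labels = ["max_ilt", "max_pws", "max_pwri"]
        mps = []
        for d, lab in zip(motions, labels):
            s = rng.uniform(-40, 40, 3)
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            mps.append((s, A @ s + t + d * direction, lab))
        corr = make_correspondences(src, A, t, validation_src=rng.uniform(-40, 40, 3),
                                    maxpoints=mps)
        return corr

    def test_zero_motion_measured_zero(self, rng):
        corr = self._corr_with_motion(rng, [0.0])
        T = estimate_transform(corr, "affine")
        assert maxpoint_motion(T, corr)[0].distance == pytest.approx(0, abs=1e-9)

    def test_planted_motions_recovered(self, rng):
        corr = self._corr_with_motion(rng, [0.0, 5.0, 15.0])
        T = estimate_transform(corr, "affine")
        got = {m.label: m.distance for m in maxpoint_motion(T, corr)}
        assert got["max_ilt"] == pytest.approx(0.0, abs=1e-6)
        assert got["max_pws"] == pytest.approx(5.0, abs=1e-6)
        assert got["max_pwri"] == pytest.approx(15.0, abs=1e-6)

    def test_rejected_gate_blocks_motion_unless_overridden(self, rng):
        corr = self._corr_with_motion(rng, [5.0])
        T = estimate_transform(corr, "affine")
        from aaamotion.registration import ValidationResult

        failed = ValidationResult(distance=20.0, threshold=15.0, accepted=False)
        with pytest.raises(GateError, match="gate"):
            maxpoint_motion(T, corr, failed)
        with pytest.warns(UserWarning, match="despite"):
            out = maxpoint_motion(T, corr, failed, override_gate=True)
        assert len(out) == 1


class TestDomainTypes:
    def test_validation_point_must_be_held_out_of_fit(self, rng):
        src = landmark_cloud(rng, n=4)
        pairs = tuple((s, s, f"l{i}") for i, s in enumerate(src))
        with pytest.raises(ValueError, match="held out"):
            CorrespondenceSet("X", pairs, (src[0], src[0], "l0"))

    def test_duplicate_fit_labels_rejected(self, rng):
        src = landmark_cloud(rng, n=4)
        pairs = tuple((s, s, "same") for s in src)
        with pytest.raises(ValueError, match="duplicate"):
            CorrespondenceSet("X", pairs)

    def test_rigid_transform_requires_orthogonal_matrix(self):
        with pytest.raises(ValueError, match="orthogonal"):
            LinearTransform(np.diag([1.0, 2.0, 1.0]), np.zeros(3), "rigid")

    def test_landmark_rejects_nonfinite_positions(self):
        with pytest.raises(ValueError, match="finite"):
            Landmark("sma", np.array([np.nan, 0, 0]))
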