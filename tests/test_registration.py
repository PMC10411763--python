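"""Registration costs against brute-force oracles; transform recovery."""
import dataclasses

import numpy as np
import pytest

import voxdose as vd
from voxdose.registration import mse_cost, ncc_cost

from conftest import random_volume


def brute_force_mse(ref_vals, tgt_vals):
    """Independent double-loop evaluation of the mean squared difference."""
    total, n = 0.0, 0
    for i in range(ref_vals.shape[0]):
        for j in range(ref_vals.shape[1]):
            for k in range(ref_vals.shape[2]):
                d = ref_vals[i, j, k] - tgt_vals[i, j, k]
                total += d * d
                n += 1
    return total / n


class TestMseCost:
    def test_identical_volumes_identity_transform_is_zero(self, rng):
        v = random_volume(rng)
        cost, mask = mse_cost(v, v, vd.RigidTransform.identity())
        assert cost == 0.0
        assert mask.all()

    def test_constant_offset_closed_form(self):
        a = vd.Volume3D(np.full((6, 6, 6), 10.0), (4.0, 4.0, 4.0), (0.0, 0.0, 0.0))
        b = vd.Volume3D(np.full((6, 6, 6), 13.0), (4.0, 4.0, 4.0), (0.0, 0.0, 0.0))
        cost, _ = mse_cost(a, b, vd.RigidTransform.identity())
        assert cost == pytest.approx(9.0)

    def test_matches_brute_force_oracle_on_random_volumes(self, rng):
        for _ in range(5):
            a = random_volume(rng)
            b = random_volume(rng)
            cost, _ = mse_cost(a, b, vd.RigidTransform.identity())
            assert cost == pytest.approx(brute_force_mse(a.values, b.values), rel=1e-10)

    def test_empty_overlap_raises(self, rng):
        a = random_volume(rng)
        b = random_volume(rng)
        far = vd.RigidTransform(translation=(1e5, 0.0, 0.0))
        with pytest.raises(vd.RegistrationError):
            mse_cost(a, b, far)


class TestNccCost:
    def config(self):
        # no smoothing / dense sampling so the oracle comparison is exact
        return vd.RegistrationConfig(cost="ncc", smoothing_fwhm_mm=0.0,
                                     sample_spacing_mm=0.0)

    def test_identical_volumes_give_minus_one(self, rng):
        v = random_volume(rng)
        cost, _ = ncc_cost(v, v, vd.RigidTransform.identity(), self.config())
        assert cost == pytest.approx(-1.0, abs=1e-12)

    def test_affine_intensity_invariance(self, rng):
        v = random_volume(rng)
        w = v.with_values(3.0 * v.values + 7.0)
        cost, _ = ncc_cost(v, w, vd.RigidTransform.identity(), self.config())
        assert cost == pytest.approx(-1.0, abs=1e-12)

    def test_matches_brute_force_pearson(self, rng):
        a = random_volume(rng)
        b = random_volume(rng)
        cost, _ = ncc_cost(a, b, vd.RigidTransform.identity(), self.config())
        x = a.values.ravel()
        y = b.values.ravel()
        r = np.sum((x - x.mean()) * (y - y.mean())) / (
            len(x) * x.std() * y.std())
        assert cost == pytest.approx(-r, rel=1e-10)

    def test_zero_variance_raises(self, rng):
        a = random_volume(rng)
        b = a.with_values(np.full(a.shape, 5.0))
        with pytest.raises(vd.RegistrationError):
            ncc_cost(a, b, vd.RigidTransform.identity(), self.config())


class TestRegisterRigid:
    def test_no_motion_recovers_identity(self, small_reference):
        res = vd.register_rigid(small_reference, small_reference)
        assert res.converged
        assert np.abs(res.transform.params()[:3]).max() <= 0.1   # mm
        assert np.abs(res.transform.params()[3:]).max() <= 0.1   # deg
        assert res.final_cost == 0.0

    def test_noiseless_5deg_rotation_recovered(self, small_spec, small_reference):
        spec = dataclasses.replace(small_spec)
        a5, _ = vd.make_phantom(spec, transform=vd.RigidTransform(rotation_deg=(0, 0, 5)))
        tgt = vd.simulate_acquisition(a5, 10.0, 6e6, poisson=False)
        res = vd.register_rigid(small_reference, tgt)
        gt = vd.RigidTransform(rotation_deg=(0.0, 0.0, 5.0),
                               center=tuple(small_reference.center_world()))
        assert res.transform.rotation_error_deg(gt) <= 0.25
        assert res.transform.translation_error_mm(gt) <= 0.5

    def test_noisy_10deg_recovered_within_half_voxel(self, small_spec, small_phantom,
                                                     small_reference):
        a0, _ = small_phantom
        a10, _ = vd.make_phantom(small_spec,
                                 transform=vd.RigidTransform(rotation_deg=(0, 0, 10)))
        ref = vd.simulate_acquisition(a0, 10.0, 6e6, seed=21)
        tgt = vd.simulate_acquisition(a10, 10.0, 6e6, seed=22)
        res = vd.register_rigid(ref, tgt)
        gt = vd.RigidTransform(rotation_deg=(0.0, 0.0, 10.0),
                               center=tuple(small_reference.center_world()))
        assert res.transform.rotation_error_deg(gt) <= 0.5
        assert res.transform.translation_error_mm(gt) <= 2.0  # half of a 4-mm voxel
        trace = res.cost_trace
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))

    def test_final_cost_not_above_identity_cost(self, small_spec, small_reference):
        a5, _ = vd.make_phantom(small_spec,
                                transform=vd.RigidTransform(rotation_deg=(0, 0, 5)))
        tgt = vd.simulate_acquisition(a5, 10.0, 6e6, seed=31)
        res = vd.register_rigid(small_reference, tgt)
        assert res.final_cost <= res.cost_at_identity
        assert res.iterations <= 100

    def test_mismatched_value_kinds_rejected(self, small_reference):
        hu = small_reference.with_values(small_reference.values, value_kind=vd.ValueKind.HU)
        with pytest.raises(vd.RegistrationError):
            vd.register_rigid(small_reference, hu)

    def test_randomized_perturbations_recovered(self, small_spec, small_reference):
        """Median recovery over randomized rigid perturbations stays within
        0.5 degrees and half a voxel; individual failures are surfaced."""
        rng = np.random.default_rng(7)
        rot_errs, trans_errs = [], []
        config = vd.RegistrationConfig(coarse_search=True)
        a0, _ = vd.make_phantom(small_spec)
        # acquisition-level counts (120 views x 500k): the MSE gradient must
        # dominate the subvoxel noise ripple of trilinear interpolation
        ref = vd.simulate_acquisition(a0, 10.0, 6e7, seed=99)
        n = 20
        for i in range(n):
            params = np.concatenate([
                rng.uniform(-10, 10, size=3),     # mm
                rng.uniform(-10, 10, size=3),     # deg
            ])
            t = vd.RigidTransform(tuple(params[:3]), tuple(params[3:]))
            act, _ = vd.make_phantom(small_spec, transform=t)
            tgt = vd.simulate_acquisition(act, 10.0, 6e7, seed=1000 + i)
            res = vd.register_rigid(ref, tgt, config)
            gt = vd.RigidTransform(tuple(params[:3]), tuple(params[3:]),
                                   center=tuple(ref.center_world()))
            rot_errs.append(res.transform.rotation_error_deg(gt))
            trans_errs.append(res.transform.translation_error_mm(gt))
        assert np.median(rot_errs) <= 0.5, rot_errs
        assert np.median(trans_errs) <= 2.0, trans_errs


class TestReslice:
    def test_identity_same_grid_is_exact_copy(self, rng):
        v = random_volume(rng)
        out = vd.reslice(v, vd.RigidTransform.identity(), v)
        np.testing.assert_array_equal(out.values, v.values)

    def test_reslice_then_inverse_recovers_volume(self, small_reference):
        t = vd.RigidTransform((3.0, -2.0, 1.0), (0.0, 0.0, 6.0),
                              center=tuple(small_reference.center_world()))
        fwd = vd.reslice(small_reference, t, small_reference)
        back = vd.reslice(fwd, t.inverse(), small_reference)
        m = back.valid_mask & fwd.valid_mask
        rms = np.sqrt(np.mean((back.values - small_reference.values)[m] ** 2))
        assert rms <= 0.02 * small_reference.values.max()

    def test_total_counts_preserved_for_interior_object(self, small_reference):
        t = vd.RigidTransform(rotation_deg=(0.0, 0.0, 5.0),
                              center=tuple(small_reference.center_world()))
        out = vd.reslice(small_reference, t, small_reference)
        assert out.total() == pytest.approx(small_reference.total(), rel=0.02)


class TestFiducialOrigin:
    def test_origin_moves_to_fiducial_centroid(self, small_spec):
        act, _ = vd.make_phantom(small_spec)
        blur = vd.simulate_acquisition(act, 10.0, 6e6, poisson=False)
        shifted = vd.set_origin_on_fiducial(blur)
        delta = np.asarray(shifted.origin) - np.asarray(blur.origin)
        np.testing.assert_allclose(delta, [-75.0, 0.0, 0.0], atol=2.0)

    def test_manual_point(self, rng):
        v = random_volume(rng)
        out = vd.set_origin_on_fiducial(v, method="manual_point", point_mm=(3.0, 4.0, 5.0))
        np.testing.assert_allclose(
            np.asarray(out.origin) - np.asarray(v.origin), [-3.0, -4.0, -5.0])

    def test_without_fiducial_raises(self, small_spec):
        spec = dataclasses.replace(small_spec, fiducial=None)
        act, _ = vd.make_phantom(spec)
        blur = vd.simulate_acquisition(act, 10.0, 6e6, seed=9)
        with pytest.raises(vd.FiducialNotFoundError):
            vd.set_origin_on_fiducial(blur)

    def test_equal_candidates_tie_break_is_deterministic(self, caplog):
        import logging

        vals = np.zeros((24, 24, 24))
        vals[4:8, 4:8, 4:8] = 50.0       # main object (largest)
        vals[16, 16, 16] = 100.0         # two equal hot single-voxel candidates
        vals[20, 4, 4] = 100.0
        v = vd.Volume3D(vals, (4.0, 4.0, 4.0), (0.0, 0.0, 0.0))
        with caplog.at_level(logging.WARNING, logger="voxdose.registration"):
            out1 = vd.set_origin_on_fiducial(v)
            out2 = vd.set_origin_on_fiducial(v)
        assert "tie" in caplog.text
        assert out1.origin == out2.origin
        # lowest linear index wins: (16,16,16) precedes (20,4,4) in C order
        np.testing.assert_allclose(
            np.asarray(out1.origin) - np.asarray(v.origin), [-64.0, -64.0, -64.0])


class TestFiducialNullEffect:
    def test_recovery_same_with_and_without_fiducial(self, small_spec, small_reference):
        """Registering the same motion with vs without the marker yields
        transforms within 0.5 degrees / half a voxel of each other."""
        t = vd.RigidTransform(rotation_deg=(0.0, 0.0, 5.0))
        results = {}
        for has_fid in (True, False):
            spec = small_spec if has_fid else dataclasses.replace(small_spec, fiducial=None)
            ref_act, _ = vd.make_phantom(spec)
            ref = vd.simulate_acquisition(ref_act, 10.0, 6e6, seed=41)
            act, _ = vd.make_phantom(spec, transform=t)
            tgt = vd.simulate_acquisition(act, 10.0, 6e6, seed=42)
            results[has_fid] = vd.register_rigid(ref, tgt).transform
        assert results[True].rotation_error_deg(results[False]) <= 0.5
        assert results[True].translation_error_mm(results[False]) <= 2.0
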