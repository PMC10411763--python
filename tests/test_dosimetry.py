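"""Kernel convolution dosimetry against the brute-force direct sum."""
import numpy as np
import pytest

import voxdose as vd
from voxdose.dosimetry import (
    DoseKernel,
    TissueMask,
    bland_altman,
    convolve_dose,
    generate_toy_kernel,
    load_kernel,
    pearson,
    save_kernel,
    segment_bone,
    voi_by_cutoff,
)
from voxdose.volumes_io import ValueKind, Volume3D


def tia_volume(vals, spacing=(4.0, 4.0, 4.0)):
    return Volume3D(np.asarray(vals, dtype=float), spacing, (0.0, 0.0, 0.0),
                    value_kind=ValueKind.TIA_MBQ_S)


def direct_convolution(tia, kernel):
    """Independent triple-loop evaluation of the kernel sum (zero padding)."""
    nx, ny, nz = tia.shape
    h = kernel.shape[0] // 2
    out = np.zeros_like(tia)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                q = tia[i, j, k]
                if q == 0.0:
                    continue
                for a in range(-h, h + 1):
                    for b in range(-h, h + 1):
                        for c in range(-h, h + 1):
                            ii, jj, kk = i + a, j + b, k + c
                            if 0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz:
                                out[ii, jj, kk] += q * kernel[h + a, h + b, h + c]
    return out


def random_kernel(rng, side=5, spacing=(4.0, 4.0, 4.0), medium="soft_tissue"):
    vals = rng.random((side, side, side))
    c = side // 2
    vals[c, c, c] = vals.max() + 1.0
    return DoseKernel("Lu177", spacing, medium, vals)


class TestSegmentBone:
    def test_inclusive_300_hu_cutoff(self):
        ct = Volume3D(np.array([-100.0, 299.0, 300.0, 1000.0]).reshape(4, 1, 1),
                      (4.0, 4.0, 4.0), (0.0, 0.0, 0.0), value_kind=ValueKind.HU)
        mask = segment_bone(ct)
        np.testing.assert_array_equal(mask.bone.ravel(), [False, False, True, True])

    def test_all_air_gives_empty_mask(self):
        ct = Volume3D(np.full((4, 4, 4), -1000.0), (4.0, 4.0, 4.0), (0.0, 0.0, 0.0),
                      value_kind=ValueKind.HU)
        assert not segment_bone(ct).bone.any()

    def test_very_low_cutoff_gives_full_mask(self):
        ct = Volume3D(np.full((4, 4, 4), -1000.0), (4.0, 4.0, 4.0), (0.0, 0.0, 0.0),
                      value_kind=ValueKind.HU)
        assert segment_bone(ct, cutoff_hu=-2000.0).bone.all()

    def test_non_hu_input_rejected(self):
        counts = Volume3D(np.ones((4, 4, 4)), (4.0, 4.0, 4.0), (0.0, 0.0, 0.0))
        with pytest.raises(vd.GeometryError):
            segment_bone(counts)


class TestToyKernel:
    def test_single_voxel_table_is_self_dose_only(self):
        k = generate_toy_kernel("Lu177", (4.0, 4.0, 4.0), table_side=1)
        assert k.values.shape == (1, 1, 1)
        assert k.self_dose > 0

    def test_bone_kernel_below_soft_tissue_off_center(self):
        ks = generate_toy_kernel("Y90", (4.0, 4.0, 4.0), 7, "soft_tissue")
        kb = generate_toy_kernel("Y90", (4.0, 4.0, 4.0), 7, "bone")
        off = np.ones((7, 7, 7), dtype=bool)
        off[3, 3, 3] = False
        assert np.all(kb.values[off] <= ks.values[off])

    def test_deterministic_for_fixed_inputs(self):
        a = generate_toy_kernel("I131", (4.0, 4.0, 4.0), 5)
        b = generate_toy_kernel("I131", (4.0, 4.0, 4.0), 5)
        np.testing.assert_array_equal(a.values, b.values)
        assert np.isfinite(a.values.sum())

    def test_monotone_decay_along_axes(self):
        k = generate_toy_kernel("Lu177", (4.0, 4.0, 4.0), 9)
        c = 4
        line = k.values[c:, c, c]
        assert np.all(np.diff(line) <= 0)

    def test_even_side_rejected(self):
        with pytest.raises(vd.ConfigurationError):
            generate_toy_kernel("Lu177", (4.0, 4.0, 4.0), 4)

    def test_unknown_radionuclide_rejected(self):
        with pytest.raises(vd.ConfigurationError):
            generate_toy_kernel("Tc99m", (4.0, 4.0, 4.0), 5)

    def test_provenance_marks_toy(self):
        k = generate_toy_kernel("Lu177", (4.0, 4.0, 4.0), 5)
        assert "not for clinical use" in k.provenance

    def test_file_roundtrip(self, tmp_path):
        k = generate_toy_kernel("Y90", (4.0, 4.0, 4.0), 5, "bone")
        back = load_kernel(save_kernel(k, tmp_path / "k.json"))
        np.testing.assert_array_equal(back.values, k.values)
        assert back.radionuclide == "Y90"
        assert back.medium == "bone"


class TestConvolveDose:
    def soft_only(self, shape):
        return TissueMask(np.zeros(shape, dtype=bool))

    def test_delta_kernel_scales_tia_exactly(self, rng):
        tia = tia_volume(rng.random((8, 8, 8)))
        s0 = 0.25
        delta = DoseKernel("Lu177", (4.0, 4.0, 4.0), "soft_tissue",
                           np.full((1, 1, 1), s0))
        dose = convolve_dose(tia, {"soft_tissue": delta, "bone": delta},
                             self.soft_only(tia.shape))
        np.testing.assert_allclose(dose.values, s0 * tia.values, rtol=1e-12)

    def test_impulse_reproduces_kernel(self, rng):
        vals = np.zeros((9, 9, 9))
        vals[4, 4, 4] = 2.0
        tia = tia_volume(vals)
        k = random_kernel(rng)
        dose = convolve_dose(tia, {"soft_tissue": k, "bone": k}, self.soft_only((9, 9, 9)))
        np.testing.assert_allclose(dose.values[2:7, 2:7, 2:7], 2.0 * k.values,
                                   rtol=1e-10, atol=1e-12)

    def test_fft_equals_triple_loop_oracle(self, rng):
        for _ in range(3):
            tia = tia_volume(rng.random((8, 8, 8)))
            k = random_kernel(rng)
            dose = convolve_dose(tia, {"soft_tissue": k, "bone": k},
                                 self.soft_only((8, 8, 8)))
            brute = direct_convolution(tia.values, k.values)
            np.testing.assert_allclose(dose.values, brute, rtol=1e-10)

    def test_two_media_split_matches_oracle(self, rng):
        tia = tia_volume(rng.random((8, 8, 8)))
        ks = random_kernel(rng, medium="soft_tissue")
        kb = random_kernel(rng, medium="bone")
        bone = rng.random((8, 8, 8)) > 0.5
        dose = convolve_dose(tia, {"soft_tissue": ks, "bone": kb}, TissueMask(bone))
        brute = (direct_convolution(tia.values * ~bone, ks.values)
                 + direct_convolution(tia.values * bone, kb.values))
        np.testing.assert_allclose(dose.values, brute, rtol=1e-10)

    def test_linearity_in_tia(self, rng):
        tia = tia_volume(rng.random((8, 8, 8)))
        k = random_kernel(rng)
        kernels = {"soft_tissue": k, "bone": k}
        d1 = convolve_dose(tia, kernels, self.soft_only((8, 8, 8)))
        d3 = convolve_dose(tia.with_values(3.0 * tia.values), kernels,
                           self.soft_only((8, 8, 8)))
        np.testing.assert_allclose(d3.values, 3.0 * d1.values, rtol=1e-12)

    def test_conservation_for_interior_source(self, rng):
        vals = np.zeros((16, 16, 16))
        vals[7:9, 7:9, 7:9] = rng.random((2, 2, 2))
        tia = tia_volume(vals)
        k = random_kernel(rng)
        dose = convolve_dose(tia, {"soft_tissue": k, "bone": k},
                             self.soft_only((16, 16, 16)))
        assert dose.values.sum() == pytest.approx(vals.sum() * k.values.sum(), rel=1e-9)

    def test_spacing_mismatch_raises(self, rng):
        tia = tia_volume(rng.random((8, 8, 8)), spacing=(4.0, 4.0, 4.0))
        k = random_kernel(rng, spacing=(2.0, 2.0, 2.0))
        with pytest.raises(vd.GeometryError):
            convolve_dose(tia, {"soft_tissue": k, "bone": k}, self.soft_only((8, 8, 8)))

    def test_missing_medium_kernel_raises(self, rng):
        tia = tia_volume(rng.random((8, 8, 8)))
        k = random_kernel(rng)
        with pytest.raises(vd.ConfigurationError):
            convolve_dose(tia, {"soft_tissue": k}, self.soft_only((8, 8, 8)))


class TestVoi:
    def dose_volume(self, vals):
        return Volume3D(np.asarray(vals, dtype=float), (4.0, 4.0, 4.0),
                        (0.0, 0.0, 0.0), value_kind=ValueKind.DOSE_MGY)

    def test_uniform_region_is_whole_region(self):
        vals = np.zeros((10, 10, 10))
        region = np.zeros((10, 10, 10), dtype=bool)
        region[3:6, 3:6, 3:6] = True
        vals[region] = 7.0
        stats = voi_by_cutoff(self.dose_volume(vals), region)
        assert stats.mean_dose_mgy == 7.0
        assert stats.max_dose_mgy == 7.0
        assert stats.mask.sum() == region.sum()
        assert stats.volume_ml == pytest.approx(27 * 0.064)

    def test_40pct_cutoff_excludes_39_and_keeps_40(self):
        vals = np.zeros((12, 12, 12))
        vals[5:7, 5:7, 5:7] = 100.0
        vals[5, 5, 7] = 40.0    # boundary: inclusive
        vals[0:2, 0:2, 0:2] = 39.0
        stats = voi_by_cutoff(self.dose_volume(vals), (22.0, 22.0, 22.0),
                              cutoff_fraction=0.40)
        assert stats.mask[5, 5, 7]
        assert not stats.mask[0, 0, 0]
        assert stats.mask.sum() == 9

    def test_seed_point_hill_climbs_to_local_max(self):
        vals = np.zeros((16, 16, 16))
        xs = np.arange(16.0)
        X, Y, Z = np.meshgrid(xs, xs, xs, indexing="ij")
        vals = 100.0 * np.exp(-((X - 8) ** 2 + (Y - 8) ** 2 + (Z - 8) ** 2) / 18.0)
        stats = voi_by_cutoff(self.dose_volume(vals), (4.0 * 6, 4.0 * 6, 4.0 * 6))
        assert stats.max_dose_mgy == pytest.approx(100.0)

    def test_connectivity_excludes_disjoint_suprathreshold_blob(self):
        vals = np.zeros((12, 12, 12))
        vals[2:4, 2:4, 2:4] = 100.0
        vals[9:11, 9:11, 9:11] = 90.0    # above cutoff but disconnected
        stats = voi_by_cutoff(self.dose_volume(vals), (10.0, 10.0, 10.0))
        assert stats.mask[2, 2, 2]
        assert not stats.mask[9, 9, 9]

    def test_empty_region_raises(self):
        with pytest.raises(vd.VoxdoseError):
            voi_by_cutoff(self.dose_volume(np.ones((4, 4, 4))),
                          np.zeros((4, 4, 4), dtype=bool))

    def test_mean_never_exceeds_max_and_mask_respects_cutoff(self, rng):
        vals = rng.random((10, 10, 10)) * 50.0
        stats = voi_by_cutoff(self.dose_volume(vals), np.ones((10, 10, 10), bool),
                              cutoff_fraction=0.40)
        assert stats.mean_dose_mgy <= stats.max_dose_mgy
        assert np.all(vals[stats.mask] >= 0.40 * stats.max_dose_mgy)


class TestComparison:
    def test_pearson_perfect_and_inverse(self, rng):
        a = rng.random(10) * 100.0
        assert pearson(a, a) == pytest.approx(1.0)
        assert pearson(a, -a) == pytest.approx(-1.0)

    def test_pearson_matches_brute_force_formula(self, rng):
        a = rng.random(20)
        b = rng.random(20)
        r = np.sum((a - a.mean()) * (b - b.mean())) / (20 * a.std() * b.std())
        assert pearson(a, b) == pytest.approx(r, rel=1e-12)

    def test_pearson_zero_variance_raises(self):
        with pytest.raises(vd.VoxdoseError):
            pearson(np.ones(5), np.arange(5.0))

    def test_bland_altman_identical_series(self, rng):
        a = rng.random(8) * 100.0
        out = bland_altman(a, a)
        assert out["mean_difference"] == 0.0
        assert out["limits_of_agreement"] == (0.0, 0.0)

    def test_bland_altman_constant_shift(self, rng):
        a = rng.random(8) * 100.0
        out = bland_altman(a, a + 3.0)
        assert out["mean_difference"] == pytest.approx(-3.0)
        assert out["sd_difference"] == pytest.approx(0.0, abs=1e-12)

    def test_bland_altman_matches_hand_formula(self, rng):
        a = rng.random(12)
        b = rng.random(12)
        out = bland_altman(a, b)
        d = a - b
        assert out["mean_difference"] == pytest.approx(d.mean())
        assert out["limits_of_agreement"][1] == pytest.approx(
            d.mean() + 1.96 * d.std(ddof=1))
        assert len(out["pairs"]) == 12

    def test_length_mismatch_raises(self):
        with pytest.raises(vd.VoxdoseError):
            bland_altman(np.ones(3), np.ones(4))
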