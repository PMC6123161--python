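"""Phantom construction, analytic motion, rendering and simulated observers."""

import numpy as np
import pytest

from irv4d.grid import OAR_ORGANS, ORGAN_LABELS, Grid
from irv4d.irv import diaphragm_excursion
from irv4d.metrics import jaccard
from irv4d.registration import warp_mask
from irv4d.synthetic import (
    ConfigurationError,
    PhantomConfig,
    RaterProfile,
    analytic_motion_field,
    build_anatomy,
    calibrate_rater_profile,
    corrupt_si_edge,
    dome_voxel_index,
    generate_phantom,
    motion_scale_field,
    phase_amplitude_fraction,
    render_phase,
    simulate_rater,
)
from conftest import make_sphere_mask


class TestAnatomy:
    def test_all_labels_present_with_minimum_size(self, tiny_config):
        anatomy, ref = build_anatomy(tiny_config)
        assert set(np.unique(anatomy.labels)) == set(range(7))
        for organ in OAR_ORGANS:
            assert (anatomy.labels == ORGAN_LABELS[organ]).sum() >= 100

    def test_zero_noise_gives_piecewise_constant_intensity(self):
        cfg = PhantomConfig(grid_shape=(32, 32, 24), spacing_mm=(4, 4, 6),
                            noise_sigma=0.0)
        anatomy, ref = build_anatomy(cfg)
        for lab in range(7):
            vals = ref.intensity[anatomy.labels == lab]
            assert np.all(vals == vals[0])

    def test_organ_contrast_exceeds_three_sigma(self, tiny_config):
        anatomy, ref = build_anatomy(tiny_config)
        means = sorted(
            ref.intensity[anatomy.labels == lab].mean() for lab in range(7)
        )
        gaps = np.diff(means)
        assert gaps.min() >= 3 * tiny_config.noise_sigma

    def test_too_small_grid_names_the_organ(self):
        with pytest.raises(ConfigurationError, match="organ"):
            build_anatomy(PhantomConfig(grid_shape=(8, 8, 6), spacing_mm=(4, 4, 6)))

    def test_same_seed_bit_identical(self, tiny_config):
        a = generate_phantom(tiny_config)
        b = generate_phantom(tiny_config)
        assert np.array_equal(a.anatomy.labels, b.anatomy.labels)
        for pa, pb in zip(a.phases, b.phases):
            assert np.array_equal(pa.intensity, pb.intensity)
        for ta, tb in zip(a.truths, b.truths):
            for organ in OAR_ORGANS:
                assert np.array_equal(ta.masks[organ].data, tb.masks[organ].data)


class TestMotionField:
    def test_zero_amplitude_zero_field(self, tiny_config):
        dvf = analytic_motion_field(tiny_config, 0.0)
        assert np.all(dvf.vectors == 0)

    def test_amplitude_outside_unit_interval_rejected(self, tiny_config):
        for bad in (-0.1, 1.1):
            with pytest.raises(ValueError):
                analytic_motion_field(tiny_config, bad)

    def test_dome_displacement_exact_at_full_amplitude(self):
        cfg = PhantomConfig()
        anatomy, _ = build_anatomy(cfg)
        scale = motion_scale_field(cfg)
        for organ, amp in (("right_lung", 16.0), ("left_lung", 17.0)):
            i, j, k = dome_voxel_index(anatomy.organ_mask(organ))
            assert scale[i, j, k] == pytest.approx(amp, abs=1e-9)

    def test_liver_volume_conserved_by_jacobian_oracle(self):
        """Change of variables: integrating det(I + grad u) over the warped
        mask must recover the reference volume within 1.5%."""
        cfg = PhantomConfig()
        anatomy, _ = build_anatomy(cfg)
        dvf = analytic_motion_field(cfg, 1.0)
        liver = anatomy.organ_mask("liver")
        warped = warp_mask(liver, dvf)
        sp = cfg.spacing_mm
        jac = 1.0 + np.gradient(dvf.vectors[..., 2].astype(np.float64), *sp)[2]
        v_ref = liver.voxel_count * cfg.grid.voxel_volume_mm3
        v_jac = float(jac[warped.data].sum()) * cfg.grid.voxel_volume_mm3
        assert abs(v_jac - v_ref) / v_ref <= 0.015

    def test_field_is_smooth(self, tiny_config):
        """Discrete Laplacian of the displacement stays bounded."""
        dvf = analytic_motion_field(tiny_config, 1.0)
        uz = dvf.vectors[..., 2].astype(float)
        lap = sum(np.gradient(np.gradient(uz, s, axis=a), s, axis=a)
                  for a, s in enumerate(tiny_config.spacing_mm))
        assert np.abs(lap).max() < 1.0  # mm / mm^2

    def test_motion_ordering_liver_stomach_below_diaphragm(self, tiny_phantom):
        truths = tiny_phantom.truths
        right = diaphragm_excursion([t.masks["right_lung"] for t in truths], "right")
        left = diaphragm_excursion([t.masks["left_lung"] for t in truths], "left")
        for organ, dome in (("liver", right), ("stomach", left)):
            coms = [t.masks[organ].com_mm()[2] for t in truths]
            assert max(coms) - min(coms) <= dome + 1e-9

    def test_phase_fraction_endpoints(self):
        assert phase_amplitude_fraction(0, 10) == 0.0
        assert phase_amplitude_fraction(9, 10) == pytest.approx(1.0)
        fr = [phase_amplitude_fraction(p, 10) for p in range(10)]
        assert all(b > a for a, b in zip(fr, fr[1:]))


class TestRenderPhase:
    def test_identity_render_reproduces_reference(self, tiny_config):
        anatomy, ref = build_anatomy(tiny_config)
        dvf = analytic_motion_field(tiny_config, 0.0)
        vol, truth = render_phase(anatomy, ref, dvf, noise_sigma=0.0, seed=0)
        assert np.allclose(vol.intensity, ref.intensity, atol=1e-4)
        for organ in OAR_ORGANS:
            assert np.array_equal(truth.masks[organ].data,
                                  anatomy.organ_mask(organ).data)

    def test_pure_translation_shifts_organ_coms(self, tiny_config):
        from conftest import uniform_shift_field
        anatomy, ref = build_anatomy(tiny_config)
        dvf = uniform_shift_field(tiny_config.grid, (0, 0, 10.0))
        _, truth = render_phase(anatomy, ref, dvf, noise_sigma=0.0, seed=0)
        half_slice = tiny_config.spacing_mm[2] / 2
        for organ in OAR_ORGANS:
            before = anatomy.organ_mask(organ).com_mm()[2]
            after = truth.masks[organ].com_mm()[2]
            assert abs((before - after) - 10.0) <= half_slice

    def test_noise_seed_changes_intensity_not_masks(self, tiny_config):
        anatomy, ref = build_anatomy(tiny_config)
        dvf = analytic_motion_field(tiny_config, 0.5)
        v1, t1 = render_phase(anatomy, ref, dvf, tiny_config.noise_sigma, seed=1)
        v2, t2 = render_phase(anatomy, ref, dvf, tiny_config.noise_sigma, seed=2)
        assert not np.array_equal(v1.intensity, v2.intensity)
        for organ in OAR_ORGANS:
            assert np.array_equal(t1.masks[organ].data, t2.masks[organ].data)


class TestSimulatedRater:
    def test_identity_profile_returns_input(self, tiny_phantom):
        liver = tiny_phantom.anatomy.organ_mask("liver")
        out = simulate_rater(liver, RaterProfile(0.0, 0.0, 0.0))
        assert np.array_equal(out.data, liver.data)

    def test_positive_bias_grows_sphere_like_dilation(self):
        """A +2 mm bias on a 30 mm sphere grows the volume by about
        (32/30)^3 - 1, checked against the voxelized-sphere count as well;
        tolerance is in absolute volume-fraction points because the surface
        is only localized to sub-voxel precision on a 1.5 mm grid."""
        grid = Grid((64, 64, 64), (1.5, 1.5, 1.5))
        sphere = make_sphere_mask(grid, (48, 48, 48), 30.0)
        dilated = make_sphere_mask(grid, (48, 48, 48), 32.0)
        out = simulate_rater(sphere, RaterProfile(0.0, 2.0, 0.0))
        analytic = (32.0 / 30.0) ** 3 - 1.0
        voxelized = dilated.voxel_count / sphere.voxel_count - 1.0
        got = out.voxel_count / sphere.voxel_count - 1.0
        assert voxelized == pytest.approx(analytic, abs=0.01)
        assert got == pytest.approx(analytic, abs=0.03)

    def test_boundary_noise_keeps_connectivity_and_perturbs(self, tiny_phantom):
        liver = tiny_phantom.anatomy.organ_mask("liver")
        out = simulate_rater(liver, RaterProfile(2.0, 0.0, 0.0),
                             rng=np.random.default_rng(3))
        assert not np.array_equal(out.data, liver.data)
        from scipy import ndimage
        _, n = ndimage.label(out.data)
        assert n == 1

    def test_outlier_corrupts_si_edge_by_two_slices(self, tiny_phantom):
        liver = tiny_phantom.anatomy.organ_mask("liver")
        rng = np.random.default_rng(0)
        out = corrupt_si_edge(liver.data, rng)
        ks_in = np.flatnonzero(liver.data.any(axis=(0, 1)))
        ks_out = np.flatnonzero(out.any(axis=(0, 1)))
        change = max(abs(ks_in.min() - ks_out.min()), abs(ks_in.max() - ks_out.max()))
        assert change >= 2

    def test_outlier_rate_one_always_corrupts(self, tiny_phantom):
        liver = tiny_phantom.anatomy.organ_mask("liver")
        out = simulate_rater(liver, RaterProfile(0.0, 0.0, 1.0),
                             rng=np.random.default_rng(1))
        assert not np.array_equal(out.data, liver.data)

    def test_calibration_reaches_requested_jaccard_band(self, tiny_phantom):
        liver = tiny_phantom.anatomy.organ_mask("liver")
        prof = calibrate_rater_profile(liver, 0.88, 0.94, n_draws=20, seed=4)
        js = []
        for i in range(20):
            drawn = simulate_rater(liver, prof, rng=np.random.default_rng([4, i]))
            js.append(jaccard(drawn, liver))
        assert 0.88 <= np.mean(js) <= 0.94


def test_volume_conservation_tiny_phantom(tiny_phantom):
    """Heart/liver/stomach ground-truth volumes stay within 1.5% over phases
    (same property the full-size phantom is held to)."""
    for organ in ("heart", "liver", "stomach"):
        vols = np.array([m.volume_mm3 for m in tiny_phantom.truth_masks(organ)])
        assert vols.std(ddof=1) / vols.mean() * 100 <= 1.5
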