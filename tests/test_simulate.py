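import numpy as np
import pytest

import nucspark as ns
from nucspark.simulate import FWHM_PER_SIGMA


def _full_frame_fiber(**kw):
    base = dict(
        image_width_px=64, image_height_px=64, n_frames=10,
        fiber=ns.FiberSpec(center_um=(6.4, 6.4), size_um=(12.8, 12.8)),
        shot_noise=False, read_noise_sd=0.0, seed=0)
    base.update(kw)
    return ns.SimConfig(**base)


class TestGenerateXyt:
    def test_noiseless_null_case_is_flat_baseline(self):
        cfg = _full_frame_fiber(baseline_intensity=30.0)
        channels, truth = ns.generate_xyt(cfg)
        np.testing.assert_array_equal(channels["Ca"].pixels, 30.0)
        assert len(truth.events) == 0

    def test_ground_truth_has_one_row_per_event(self):
        events = tuple(
            ns.EventSpec(center_xy_um=(4.0 + i, 6.0), onset_frame=i + 1)
            for i in range(4))
        _, truth = ns.generate_xyt(_full_frame_fiber(events=events))
        assert len(truth.events) == 4
        assert list(truth.events.event_id) == [0, 1, 2, 3]

    def test_seed_determinism(self):
        cfg = _full_frame_fiber(shot_noise=True, read_noise_sd=2.0, seed=11)
        a, _ = ns.generate_xyt(cfg)
        b, _ = ns.generate_xyt(cfg)
        np.testing.assert_array_equal(a["Ca"].pixels, b["Ca"].pixels)
        np.testing.assert_array_equal(a["DNA"].pixels, b["DNA"].pixels)
        c, _ = ns.generate_xyt(ns.SimConfig(**{**cfg.__dict__, "seed": 12}))
        assert not np.array_equal(a["Ca"].pixels, c["Ca"].pixels)

    def test_event_increment_at_centroid_equals_baseline_times_amplitude(self):
        # event centered exactly on a pixel center: (25+0.5)*0.2 = 5.1 um
        ev = ns.EventSpec(center_xy_um=(5.1, 5.1), onset_frame=3,
                          amplitude_rel=0.7)
        cfg = _full_frame_fiber(events=(ev,), baseline_intensity=40.0)
        channels, _ = ns.generate_xyt(cfg)
        assert channels["Ca"].pixels[3, 25, 25] == pytest.approx(40.0 * 1.7)
        assert channels["Ca"].pixels[0, 25, 25] == pytest.approx(40.0)

    def test_event_outside_fiber_is_rejected(self):
        cfg = ns.SimConfig(
            image_width_px=64, image_height_px=64, n_frames=10,
            fiber=ns.FiberSpec(center_um=(6.4, 6.4), size_um=(6.0, 6.0)),
            events=(ns.EventSpec(center_xy_um=(12.0, 12.0), onset_frame=2),),
            shot_noise=False, read_noise_sd=0.0)
        with pytest.raises(ValueError, match="outside the fiber"):
            ns.generate_xyt(cfg)

    def test_nucleus_outside_fiber_is_rejected(self):
        cfg = ns.SimConfig(
            image_width_px=64, image_height_px=64, n_frames=5,
            fiber=ns.FiberSpec(center_um=(6.4, 6.4), size_um=(6.0, 6.0)),
            nuclei=(ns.NucleusSpec(center_um=(11.0, 11.0)),))
        with pytest.raises(ValueError, match="within the fiber"):
            ns.generate_xyt(cfg)

    def test_noisy_mean_converges_to_noiseless_image(self):
        # Monte Carlo: the mean over realizations approaches the expected
        # image within 3 standard errors at every pixel
        cfg0 = _full_frame_fiber(
            image_width_px=32, image_height_px=32, n_frames=2,
            baseline_intensity=50.0)
        clean, _ = ns.generate_xyt(cfg0)
        n_rep, read_sd = 80, 2.0
        acc = np.zeros_like(clean["Ca"].pixels)
        for k in range(n_rep):
            cfg = ns.SimConfig(**{**cfg0.__dict__, "shot_noise": True,
                                  "read_noise_sd": read_sd, "seed": 100 + k})
            acc += ns.generate_xyt(cfg)[0]["Ca"].pixels
        mean = acc / n_rep
        se = np.sqrt(50.0 + read_sd**2) / np.sqrt(n_rep)
        assert np.all(np.abs(mean - clean["Ca"].pixels) < 3.5 * se + 0.05)

    def test_ground_truth_compartments_match_classifier_rules(self):
        cfg = ns.SimConfig(
            image_width_px=128, image_height_px=128, n_frames=10,
            fiber=ns.FiberSpec(center_um=(12.8, 12.8), size_um=(24.0, 24.0)),
            nuclei=(ns.NucleusSpec(center_um=(10.0, 10.0),
                                   semi_axes_um=(4.0, 3.0)),),
            events=(
                ns.EventSpec(center_xy_um=(10.0, 10.0), onset_frame=1),
                ns.EventSpec(center_xy_um=(15.5, 10.0), onset_frame=3),
                ns.EventSpec(center_xy_um=(20.0, 20.0), onset_frame=5),
            ),
            shot_noise=False, read_noise_sd=0.0)
        _, truth = ns.generate_xyt(cfg)
        assert list(truth.events.compartment) == ["NLCS", "PLCS", "CLCS"]
        nuclei = ns.masks_from_labels(truth.nucleus_labels, cfg.pixel_size_um)
        for row in truth.events.itertuples():
            ev_dist, _, inside = ns.distance_to_nucleus((row.x_um, row.y_um), nuclei)
            expected = ("NLCS" if inside
                        else "PLCS" if ev_dist <= 2.0 else "CLCS")
            assert row.compartment == expected


class TestGenerateXt:
    def test_square_pulse_truth_fdhm_equals_duration(self):
        cfg = ns.LineScanConfig(
            shot_noise=False, read_noise_sd=0.0,
            events=(ns.LineScanEventSpec(position_um=16.0, onset_s=2.0,
                                         duration_s=1.25),))
        _, truth = ns.generate_xt(cfg)
        assert truth.events.fdhm_ms[0] == 1250.0

    def test_triangle_pulse_truth_fdhm_is_half_the_base(self):
        # half-maximum crossings of a symmetric triangle of base 2 s are 1 s apart
        ev = ns.LineScanEventSpec(position_um=16.0, onset_s=2.0,
                                  duration_s=2.0, temporal_profile="triangle")
        assert ev.true_fdhm_ms == 1000.0

    def test_no_events_noiseless_is_constant_baseline(self):
        cfg = ns.LineScanConfig(n_lines=500, shot_noise=False,
                                read_noise_sd=0.0, baseline_intensity=25.0)
        rec, truth = ns.generate_xt(cfg)
        np.testing.assert_array_equal(rec.pixels, 25.0)
        assert truth.events.empty
        assert rec.pixel_size_um == 0.063
        assert rec.line_interval_s == pytest.approx(1 / 800)


class TestBeadStack:
    def test_noiseless_axial_profile_has_requested_half_maximum_width(self):
        stack, centers = ns.generate_bead_stack(
            lateral_fwhm_um=0.48, axial_fwhm_um=1.78, n_beads=1,
            z_step_um=0.1, seed=0)
        bx, by, bz = centers[0]
        ps, zs = stack.pixel_size_um, stack.z_step_um
        col = int(bx / ps)
        row = int(by / ps)
        prof = stack.pixels[:, row, col] - 10.0  # background
        half = prof.max() / 2.0
        above = np.nonzero(prof >= half)[0]
        width = (above[-1] - above[0]) * zs
        assert width == pytest.approx(1.78, abs=2 * zs)

    def test_zero_beads_gives_pure_background(self):
        stack, centers = ns.generate_bead_stack(0.48, 1.78, n_beads=0)
        assert centers.shape == (0, 3)
        np.testing.assert_array_equal(stack.pixels, 10.0)

    def test_unplaceable_separation_is_an_error(self):
        with pytest.raises(ValueError, match="separation"):
            ns.generate_bead_stack(0.48, 1.78, n_beads=500, field_um=10.0)

    def test_beads_respect_minimum_separation(self):
        _, centers = ns.generate_bead_stack(0.4, 1.5, n_beads=6, seed=2)
        lateral = centers[:, :2]
        d = np.linalg.norm(lateral[:, None] - lateral[None, :], axis=-1)
        d[np.diag_indices(len(d))] = np.inf
        assert d.min() >= 5 * 0.4 - 0.1


class TestNucleusZstack:
    def test_center_plane_cross_section_area_is_pi_a_b(self):
        a, b = 5.0, 2.0
        rec, z_center = ns.generate_nucleus_zstack(
            (a, b, 3.0), z_step_um=0.25, pixel_size_um=0.1)
        k = int(round(z_center / rec.z_step_um))
        plane = rec.pixels[k]
        half = (plane.min() + plane.max()) / 2.0
        area = (plane > half).sum() * rec.pixel_size_um**2
        assert area == pytest.approx(np.pi * a * b, rel=0.05)

    def test_plane_beyond_pole_plus_margin_is_near_background(self):
        rec, _ = ns.generate_nucleus_zstack((5.0, 2.0, 3.0), z_step_um=0.25,
                                            background=8.0)
        assert rec.pixels[0].max() == pytest.approx(8.0, rel=0.02)
        assert rec.pixels[-1].max() == pytest.approx(8.0, rel=0.02)

    def test_symmetric_planes_about_center_are_identical(self):
        rec, z_center = ns.generate_nucleus_zstack((5.0, 2.0, 3.0),
                                                   z_step_um=0.5)
        k = int(round(z_center / rec.z_step_um))
        for off in (1, 3, 5):
            np.testing.assert_allclose(rec.pixels[k - off], rec.pixels[k + off],
                                       atol=1e-9)
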