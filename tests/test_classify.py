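import numpy as np
import pytest

import nucspark as ns


def _event(x_um, y_um, eid=0):
    return ns.SparkEvent(event_id=eid, centroid_xy_um=(x_um, y_um),
                         frame_index=0, time_s=0.0, amplitude_rel=0.8,
                         fwhm_um=2.3, area_px=20, fit_quality=0.9,
                         raw_peak_rel=0.8)


@pytest.fixture()
def rect_nucleus():
    """A rectangular nucleus: columns 50..74, rows 40..59, at 0.2 um/px.

    Its right boundary column is 74, so a point in column 74 + k is exactly
    k * 0.2 um away."""
    mask = np.zeros((128, 128), dtype=bool)
    mask[40:60, 50:75] = True
    return ns.NucleusMask(nucleus_id=1, mask=mask, pixel_size_um=0.2)


class TestClassifyEvents:
    def test_centroid_inside_mask_is_nlcs(self, rect_nucleus):
        (c,) = ns.classify_events([_event(12.0, 10.0)], [rect_nucleus])
        assert (c.label, c.nucleus_id, c.distance_um) == ("NLCS", 1, 0.0)

    def test_centroid_within_two_um_is_plcs(self, rect_nucleus):
        # column 74 + 7 -> 1.4 um from the boundary
        (c,) = ns.classify_events([_event((81 + 0.5) * 0.2, 10.0)],
                                  [rect_nucleus])
        assert c.label == "PLCS"
        assert c.distance_um == pytest.approx(1.4)

    def test_centroid_far_away_is_clcs(self, rect_nucleus):
        (c,) = ns.classify_events([_event((99 + 0.5) * 0.2, 10.0)],
                                  [rect_nucleus])
        assert c.label == "CLCS"
        assert c.distance_um == pytest.approx(5.0)

    def test_exactly_two_um_is_plcs_rule_is_inclusive(self, rect_nucleus):
        # column 84 is exactly 10 px = 2.0 um from boundary column 74
        (c,) = ns.classify_events([_event((84 + 0.5) * 0.2, 10.0)],
                                  [rect_nucleus])
        assert c.distance_um == pytest.approx(2.0)
        assert c.label == "PLCS"

    def test_boundary_pixels_count_as_inside(self, rect_nucleus):
        (c,) = ns.classify_events([_event((74 + 0.5) * 0.2, (50 + 0.5) * 0.2)],
                                  [rect_nucleus])
        assert c.label == "NLCS"

    def test_empty_nucleus_list_all_clcs_with_warning(self):
        with pytest.warns(UserWarning, match="no nuclei"):
            out = ns.classify_events([_event(1.0, 1.0), _event(2.0, 2.0)], [])
        assert [c.label for c in out] == ["CLCS", "CLCS"]
        assert all(np.isinf(c.distance_um) for c in out)

    def test_labels_partition_the_event_list(self, rect_nucleus):
        rng = np.random.default_rng(20)
        events = [_event(x, y, i) for i, (x, y) in
                  enumerate(rng.uniform(1.0, 25.0, (40, 2)))]
        out = ns.classify_events(events, [rect_nucleus])
        assert len(out) == 40
        counts = {lbl: sum(c.label == lbl for c in out)
                  for lbl in ("NLCS", "PLCS", "CLCS")}
        assert sum(counts.values()) == 40

    def test_widening_plcs_threshold_only_moves_clcs_to_plcs(self, rect_nucleus):
        rng = np.random.default_rng(21)
        events = [_event(x, y, i) for i, (x, y) in
                  enumerate(rng.uniform(1.0, 25.0, (60, 2)))]
        narrow = ns.classify_events(events, [rect_nucleus],
                                    ns.ClassifierParams(plcs_distance_um=1.0))
        wide = ns.classify_events(events, [rect_nucleus],
                                  ns.ClassifierParams(plcs_distance_um=3.0))
        for a, b in zip(narrow, wide):
            assert (a.label, b.label) != ("PLCS", "CLCS")
            if a.label != b.label:
                assert (a.label, b.label) == ("CLCS", "PLCS")


class TestDetectNgcs:
    def _setup(self, events):
        cfg = ns.SimConfig(
            image_width_px=128, image_height_px=128, n_frames=40,
            fiber=ns.FiberSpec(center_um=(12.8, 12.8), size_um=(22.0, 20.0)),
            nuclei=(ns.NucleusSpec(center_um=(8.0, 8.0)),),
            events=events, shot_noise=False, read_noise_sd=0.0)
        channels, truth = ns.generate_xyt(cfg)
        nucleus = ns.masks_from_labels(truth.nucleus_labels,
                                       cfg.pixel_size_um)[0]
        baseline = ns.estimate_baseline(channels["Ca"])
        return channels["Ca"], nucleus, baseline

    def test_flat_trace_yields_no_ngcs(self):
        record, nucleus, baseline = self._setup(())
        assert ns.detect_ngcs(record, nucleus, baseline) == []

    def test_whole_nucleus_rise_recovered_with_correct_duration(self):
        record, nucleus, baseline = self._setup(
            (ns.EventSpec(center_xy_um=(8.0, 8.0), onset_frame=10,
                          duration_frames=5, amplitude_rel=0.5, kind="ngcs",
                          nucleus_index=0),))
        (g,) = ns.detect_ngcs(record, nucleus, baseline)
        assert g.duration_s == pytest.approx(5 * 0.82)
        assert g.onset_s == pytest.approx(10 * 0.82)
        assert g.peak_amplitude_rel == pytest.approx(0.5, rel=0.05)
        assert not g.oscillatory

    def test_two_runs_separated_by_a_gap_are_oscillatory(self):
        record, nucleus, baseline = self._setup(
            (ns.EventSpec(center_xy_um=(8.0, 8.0), onset_frame=8,
                          duration_frames=4, amplitude_rel=0.5, kind="ngcs",
                          nucleus_index=0),
             ns.EventSpec(center_xy_um=(8.0, 8.0), onset_frame=25,
                          duration_frames=3, amplitude_rel=0.5, kind="ngcs",
                          nucleus_index=0)))
        runs = ns.detect_ngcs(record, nucleus, baseline)
        assert len(runs) == 2
        assert all(g.oscillatory for g in runs)

    def test_localized_spark_does_not_trigger_ngcs(self):
        # a spark covers too little of the nucleus to pass the coverage gate
        record, nucleus, baseline = self._setup(
            (ns.EventSpec(center_xy_um=(8.0, 8.0), onset_frame=10,
                          duration_frames=4, amplitude_rel=0.8,
                          fwhm_um=1.5),))
        assert ns.detect_ngcs(record, nucleus, baseline) == []

    def test_tiny_nucleus_is_an_error(self):
        record, nucleus, baseline = self._setup(())
        small = ns.NucleusMask(1, np.zeros_like(nucleus.mask), 0.2)
        small.mask[10, 10] = True
        with pytest.raises(ValueError, match="10 px"):
            ns.detect_ngcs(record, small, baseline)


class TestVerifyAxialContainment:
    @pytest.fixture()
    def nucleus_stack(self):
        rec, z_center = ns.generate_nucleus_zstack(
            (5.0, 3.0, 4.0), z_step_um=0.25, pixel_size_um=0.2)
        roi = np.zeros(rec.pixels.shape[1:], dtype=bool)
        n = roi.shape[0] // 2
        roi[n - 5:n + 5, n - 5:n + 5] = True  # 2x2 um ROI at the nucleus center
        return rec, z_center, roi

    def test_event_at_ellipsoid_center_is_verified(self, nucleus_stack):
        rec, zc, roi = nucleus_stack
        assert ns.verify_axial_containment(roi, rec, zc, 2.09) == "verified"

    def test_event_near_the_pole_is_not_verified(self, nucleus_stack):
        # 0.5 um below the top pole: no DNA overlap 2.09 um further up
        rec, zc, roi = nucleus_stack
        assert ns.verify_axial_containment(roi, rec, zc + 3.5, 2.09) == \
            "not_verified"

    def test_stack_not_spanning_dm_is_indeterminate(self, nucleus_stack):
        rec, zc, roi = nucleus_stack
        short = ns.ImageRecord(pixels=rec.pixels[:5], modality="zstack",
                               pixel_size_um=rec.pixel_size_um,
                               z_step_um=rec.z_step_um)
        assert ns.verify_axial_containment(roi, short, 0.5, 2.09) == \
            "indeterminate"

    def test_monotone_verified_at_dm_implies_verified_below(self, nucleus_stack):
        rec, zc, roi = nucleus_stack
        assert ns.verify_axial_containment(roi, rec, zc, 2.09) == "verified"
        for d in (1.79, 1.0, 0.5):
            assert ns.verify_axial_containment(roi, rec, zc, d) == "verified"

    def test_roi_shape_mismatch_is_an_error(self, nucleus_stack):
        rec, zc, _ = nucleus_stack
        with pytest.raises(ValueError, match="footprint"):
            ns.verify_axial_containment(np.ones((4, 4), bool), rec, zc, 2.0)
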