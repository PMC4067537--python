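"""Phage standard detection, focus-plane selection and class assignment."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr

from kinquant import (ImageField, PlaneImage, Roi, SimConfig, detect_spots,
                      make_standard_points, select_focus_plane, simulate_field,
                      spots_table, sum_project)
from kinquant.errors import IncompleteStandardSetError
from kinquant.roi import IntensityMeasurement
from kinquant.simulate import render_point_source
from kinquant.standards import (DetectionParams, SpotRecord, assign_classes,
                                assign_classes_from_manifest, measure_spot)


def _spot(net, spot_id="s", centroid=(0.0, 5.0, 5.0)):
    mask = np.zeros((16, 16), dtype=bool)
    mask[5, 5] = True
    meas = IntensityMeasurement(sum_value=max(net, 0.0) + 1.0,
                                background_value=max(net, 0.0) + 1.0 - net,
                                shift_used=(0, 8))
    return SpotRecord(spot_id=spot_id, centroid=centroid, plane_index=0,
                      roi=Roi(mask), measurement=meas)


class TestFocusPlane:
    def test_object_in_plane_seven(self):
        vol = render_point_source((7.0, 20.0, 20.0), 1000.0, (1.5, 2.0, 2.0),
                                  (15, 40, 40))
        field = ImageField(channels={"DAPI": vol})
        assert select_focus_plane(field, "DAPI", np.ones((40, 40), bool)) == 7

    def test_uniform_stack_breaks_ties_low(self):
        field = ImageField(channels={"DAPI": np.ones((8, 10, 10))})
        assert select_focus_plane(field, "DAPI", np.ones((10, 10), bool)) == 0

    def test_fractional_z_matches_analytic_marginal(self):
        # Oracle: argmax of the Gaussian z-marginal integrated per plane.
        z0, sigma_z = 7.4, 1.5
        vol = render_point_source((z0, 20.0, 20.0), 1000.0, (sigma_z, 2.0, 2.0),
                                  (15, 40, 40))
        field = ImageField(channels={"DAPI": vol})
        edges = np.arange(16) - 0.5
        masses = np.diff(ndtr((edges - z0) / sigma_z))
        assert select_focus_plane(field, "DAPI", np.ones((40, 40), bool)) == \
            int(np.argmax(masses))


class TestDetection:
    def test_all_zero_plane_yields_no_spots(self):
        plane = PlaneImage(np.zeros((64, 64)), kind="sum-projection")
        assert detect_spots(plane) == []

    def test_single_noiseless_phage_yields_one_roi_with_centroid(self):
        vol = render_point_source((4.0, 30.0, 33.0), 5000.0, (0.2, 1.5, 1.5),
                                  (9, 64, 64))
        plane = PlaneImage(vol.sum(axis=0), kind="sum-projection")
        rois = detect_spots(plane)
        assert len(rois) == 1
        assert rois[0].mask[30, 33]

    def test_border_touching_components_are_dropped(self):
        px = np.zeros((40, 40))
        px[0:4, 10:14] = 100.0
        px[20:23, 20:23] = 100.0
        notes = []
        rois = detect_spots(PlaneImage(px, kind="single-plane"), qc_notes=notes)
        assert len(rois) == 1
        assert len(notes) == 1

    def test_simulated_field_recall_and_no_false_positives(self):
        # 20 noisy fields at SNR >= 10: every phage recovered within 2 px,
        # and nothing detected that is not a manifest phage.
        found = total = 0
        for seed in range(20):
            cfg = SimConfig(field_shape=(11, 256, 256), n_phage_per_class=3,
                            n_kinetochores=0, seed=1000 + seed)
            field, manifest = simulate_field(cfg)
            proj = sum_project(field, "DAPI")
            rois = detect_spots(proj)
            pos = manifest.phages[["y", "x"]].to_numpy()
            total += len(pos)
            matched = set()
            for roi in rois:
                cy, cx = roi.centroid
                d = np.hypot(pos[:, 0] - cy, pos[:, 1] - cx)
                assert d.min() <= 2.0, "false positive detection"
                matched.add(int(np.argmin(d)))
            found += len(matched)
        assert found / total >= 0.95


class TestAssignment:
    def test_exact_ratio_nets_assign_all_three(self):
        spots = [_spot(480.0, "a"), _spot(900.0, "b"), _spot(1680.0, "c")]
        out = assign_classes(spots)
        assert [s.assigned_class for s in out] == ["lambda", "P1", "T4"]
        points = make_standard_points(out)
        assert {(p.genome_kb, p.net_intensity) for p in points} == \
            {(48.0, 480.0), (90.0, 900.0), (168.0, 1680.0)}

    def test_all_equal_nets_is_incomplete_standard_set(self):
        with pytest.raises(IncompleteStandardSetError):
            assign_classes([_spot(100.0, str(i)) for i in range(6)])

    def test_too_few_positive_spots_rejected(self):
        with pytest.raises(IncompleteStandardSetError):
            assign_classes([_spot(100.0), _spot(-5.0), _spot(-7.0)])

    def test_noisy_cohort_assignment_accuracy(self, rng):
        # 30 spots, 10 per class, 5% intensity noise: >= 28 correct.
        truth, spots = [], []
        for cls, kb in (("lambda", 48.0), ("P1", 90.0), ("T4", 168.0)):
            for i in range(10):
                net = kb * 10.0 * (1 + rng.normal(0, 0.05))
                truth.append(cls)
                spots.append(_spot(net, f"{cls}{i}"))
        out = assign_classes(spots)
        correct = sum(s.assigned_class == t for s, t in zip(out, truth))
        assert correct >= 28

    def test_class_means_strictly_increase(self, rng):
        spots = [_spot(48 * 10 * (1 + rng.normal(0, 0.05)), str(i)) for i in range(5)]
        spots += [_spot(90 * 10 * (1 + rng.normal(0, 0.05)), str(i + 5)) for i in range(5)]
        spots += [_spot(168 * 10 * (1 + rng.normal(0, 0.05)), str(i + 10)) for i in range(5)]
        out = assign_classes(spots)
        means = {}
        for s in out:
            means.setdefault(s.assigned_class, []).append(s.measurement.net)
        assert np.mean(means["lambda"]) < np.mean(means["P1"]) < np.mean(means["T4"])

    def test_ratio_qc_flags_wrong_geometry(self):
        # Three separated clusters whose means do not scale like 48:90:168.
        spots = [_spot(v, str(i)) for i, v in enumerate([100, 101, 500, 501, 620, 621])]
        out = assign_classes(spots)
        assert any("ratio-qc-failed" in s.qc_flags for s in out)

    def test_manifest_assignment_matches_truth(self):
        manifest = pd.DataFrame({
            "class": ["lambda", "T4"], "y": [10.0, 40.0], "x": [10.0, 40.0]})
        spots = [_spot(480, "a", centroid=(0, 10.5, 9.5)),
                 _spot(1700, "b", centroid=(0, 39.0, 41.0))]
        out = assign_classes_from_manifest(spots, manifest)
        assert [s.assigned_class for s in out] == ["lambda", "T4"]

    def test_make_standard_points_skips_unassigned(self):
        spots = assign_classes([_spot(480.0, "a"), _spot(900.0, "b"),
                                _spot(1680.0, "c"), _spot(-3.0, "d")])
        points = make_standard_points(spots)
        assert len(points) == 3
        assert make_standard_points([]) == []


class TestMeasurement:
    def test_noiseless_phage_net_matches_manifest(self, noiseless_field,
                                                  noiseless_cfg):
        field, manifest = noiseless_field
        proj = sum_project(field, "DAPI")
        rois = detect_spots(proj)
        pos = manifest.phages[["y", "x"]].to_numpy()
        expected = manifest.phages["expected_dapi"].to_numpy()
        checked = 0
        for i, roi in enumerate(rois):
            cy, cx = roi.centroid
            d = np.hypot(pos[:, 0] - cy, pos[:, 1] - cx)
            if d.min() > 2.0:
                continue  # a kinetochore, not a phage
            rec = measure_spot(field, "DAPI", roi, spot_id=str(i))
            assert rec.measurement.net == pytest.approx(
                expected[int(np.argmin(d))], rel=0.02)
            checked += 1
        assert checked == len(pos)

    def test_spots_table_columns_and_net_identity(self, noiseless_field):
        field, _ = noiseless_field
        rois = detect_spots(sum_project(field, "DAPI"))
        spots = [measure_spot(field, "DAPI", r, spot_id=str(i))
                 for i, r in enumerate(rois)]
        table = spots_table(spots)
        assert list(table.columns) == ["spot_id", "z", "y", "x", "sum",
                                       "background", "net", "assigned_class", "flags"]
        assert (table["net"] == table["sum"] - table["background"]).all()
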