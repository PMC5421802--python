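"""Enumeration pipeline: segmentation, shape, gating, counting, export."""

import sqlite3

import numpy as np
import pytest
from scipy import ndimage

from conftest import rasterize_disk
from ctcflow.enumeration import (
    CalibrationWarning,
    CellMeasurement,
    GateConfig,
    LabeledMask,
    PrimaryObject,
    calibrate_gates,
    classify_cells,
    enumerate_cells,
    expand_secondary,
    export_gallery,
    export_measurements,
    filter_primary,
    measure_intensity,
    measure_shape,
    run_pipeline,
    segment_primary,
)
from ctcflow.synthetic_fixtures import generate_fixture, ground_truth_counts, random_fixture_config


def two_disk_image():
    img = np.zeros((96, 96))
    for cy, cx in ((25, 25), (70, 65)):
        yy, xx = np.mgrid[0:96, 0:96]
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= 100] = 200.0
    return img


class TestSegmentPrimary:
    def test_constant_image_yields_no_objects(self):
        assert segment_primary(np.zeros((32, 32)), 0.5).n_objects == 0
        assert segment_primary(np.full((32, 32), 9.0), 0.5).n_objects == 0

    def test_two_separated_disks_found(self):
        mask = segment_primary(two_disk_image(), 0.5)
        _, n_oracle = ndimage.label(two_disk_image() > 100)
        assert mask.n_objects == n_oracle == 2

    def test_determinism(self):
        img = two_disk_image()
        assert np.array_equal(segment_primary(img, 0.5).labels, segment_primary(img, 0.5).labels)

    def test_border_objects_removed(self):
        img = np.zeros((64, 64))
        img[0:10, 20:30] = 200.0  # touches the top border
        img[30:40, 30:40] = 200.0
        assert segment_primary(img, 0.5).n_objects == 1

    def test_holes_filled(self):
        img = np.zeros((64, 64))
        img[20:40, 20:40] = 200.0
        img[28:32, 28:32] = 0.0  # interior hole
        mask = segment_primary(img, 0.5)
        assert (mask.labels > 0).sum() == 400

    def test_non_2d_input_rejected(self):
        with pytest.raises(ValueError):
            segment_primary(np.zeros((4, 4, 3)), 0.5)

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            segment_primary(two_disk_image(), 0.5, strategy="magic")

    def test_fixed_threshold_strategy(self):
        mask = segment_primary(two_disk_image(), 0.5, strategy="fixed", fixed_threshold=50.0)
        assert mask.n_objects == 2


class TestMeasureShape:
    def test_disk_eccentricity_is_zero(self):
        mask = LabeledMask(rasterize_disk(20).astype(np.int32), 0.5)
        (obj,) = measure_shape(mask)
        assert obj.eccentricity == pytest.approx(0.0, abs=1e-12)

    def test_two_to_one_ellipse_eccentricity(self):
        # analytic oracle: e = sqrt(1 - b^2/a^2) with a = 2b
        yy, xx = np.mgrid[0:201, 0:401]
        ell = ((xx - 200) / 160.0) ** 2 + ((yy - 100) / 80.0) ** 2 <= 1.0
        (obj,) = measure_shape(LabeledMask(ell.astype(np.int32), 1.0))
        assert obj.eccentricity == pytest.approx(np.sqrt(1 - 0.25), abs=0.02)

    def test_equivalent_diameter_from_area(self):
        mask = LabeledMask(rasterize_disk(10).astype(np.int32), 0.5)
        (obj,) = measure_shape(mask)
        # area-equivalent diameter of a 10 px radius disk at 0.5 um/px
        assert obj.equivalent_diameter_um == pytest.approx(10.0, rel=0.03)
        assert obj.equivalent_diameter_um == pytest.approx(2 * np.sqrt(obj.area_px / np.pi) * 0.5)

    def test_empty_mask_gives_empty_list(self):
        assert measure_shape(LabeledMask(np.zeros((8, 8), dtype=np.int32), 0.5)) == []

    def test_eccentricity_monotone_under_stretch(self):
        yy, xx = np.mgrid[0:101, 0:301]
        prev = -1.0
        for a in (50.0, 75.0, 100.0):
            ell = ((xx - 150) / a) ** 2 + ((yy - 50) / 40.0) ** 2 <= 1.0
            (obj,) = measure_shape(LabeledMask(ell.astype(np.int32), 1.0))
            assert 0.0 <= obj.eccentricity <= 1.0
            assert obj.eccentricity >= prev
            prev = obj.eccentricity


def obj(diam, ecc=0.0, oid=0):
    return PrimaryObject(oid, (0.0, 0.0), 100, diam, ecc)


class TestFilterPrimary:
    def test_diameter_bounds_inclusive(self, gates):
        objects = [obj(8.9, oid=1), obj(9.0, oid=2), obj(36.0, oid=3), obj(36.1, oid=4)]
        kept = filter_primary(objects, gates)
        assert [o.object_id for o in kept] == [2, 3]

    def test_eccentric_objects_excluded(self, gates):
        objects = [obj(15.0, ecc=0.79, oid=1), obj(15.0, ecc=0.81, oid=2)]
        assert [o.object_id for o in filter_primary(objects, gates)] == [1]

    def test_empty_and_identity(self, gates):
        assert filter_primary([], gates) == []
        ok = [obj(10.0, 0.1, 1), obj(20.0, 0.5, 2)]
        assert filter_primary(ok, gates) == ok


class TestExpandSecondary:
    def test_radius_zero_is_identity(self):
        mask = LabeledMask(rasterize_disk(8).astype(np.int32), 0.5)
        out = expand_secondary(mask, 0)
        assert np.array_equal(out.labels, mask.labels)

    def test_expanded_disk_area(self):
        mask = LabeledMask(rasterize_disk(10, pad=6).astype(np.int32), 0.5)
        out = expand_secondary(mask, 3)
        oracle = rasterize_disk(13, pad=3).sum()
        assert abs(int((out.labels > 0).sum()) - int(oracle)) / oracle < 0.05

    def test_nearby_objects_never_merge_and_match_nearest_oracle(self):
        labels = np.zeros((40, 40), dtype=np.int32)
        labels[10, 10] = 1
        labels[10, 20] = 2
        out = expand_secondary(LabeledMask(labels, 1.0), 8)
        assert out.n_objects == 2
        # exhaustive nearest-seed assignment oracle
        seeds = {1: (10, 10), 2: (10, 20)}
        for y in range(40):
            for x in range(40):
                got = out.labels[y, x]
                dists = {k: (y - sy) ** 2 + (x - sx) ** 2 for k, (sy, sx) in seeds.items()}
                if got == 0:
                    assert min(dists.values()) > 64
                elif dists[1] != dists[2]:  # contested equidistant pixels may tie-break either way
                    assert dists[got] == min(dists.values())

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            expand_secondary(LabeledMask(np.zeros((4, 4), dtype=np.int32), 0.5), -1)


class TestMeasureIntensity:
    def test_uniform_channel(self):
        mask = LabeledMask(rasterize_disk(5).astype(np.int32), 0.5)
        means = measure_intensity(mask, np.full(mask.labels.shape, 42.0))
        assert means == {1: pytest.approx(42.0)}

    def test_hand_computed_mean(self):
        labels = np.zeros((2, 4), dtype=np.int32)
        labels[0, :4] = 1
        channel = np.array([[10.0, 20.0, 30.0, 40.0], [0.0, 0.0, 0.0, 0.0]])
        assert measure_intensity(LabeledMask(labels, 1.0), channel)[1] == pytest.approx(25.0)

    def test_locality_between_objects(self):
        labels = np.zeros((4, 4), dtype=np.int32)
        labels[0, 0] = 1
        labels[3, 3] = 2
        ch = np.zeros((4, 4))
        ch[0, 0], ch[3, 3] = 5.0, 9.0
        before = measure_intensity(LabeledMask(labels, 1.0), ch)[2]
        ch[0, 0] = 500.0
        after = measure_intensity(LabeledMask(labels, 1.0), ch)[2]
        assert before == after == pytest.approx(9.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            measure_intensity(LabeledMask(np.zeros((4, 4), dtype=np.int32), 1.0), np.zeros((5, 5)))


def meas(ck, cd, oid=0):
    return CellMeasurement(oid, ck, cd)


class TestCalibrateGates:
    def test_constant_isotype_threshold_is_mean(self):
        gates = calibrate_gates([meas(100.0, 1.0)], [meas(10.0, 10.0)] * 5, k=3.0)
        assert gates.ck_epcam_positive_threshold == pytest.approx(10.0)

    def test_mean_plus_k_sd(self):
        iso = [meas(8.0, 8.0), meas(12.0, 12.0)]  # mean 10, sample SD ~2.83
        gates = calibrate_gates([meas(100.0, 1.0)], iso, k=3.0)
        sd = np.std([8.0, 12.0], ddof=1)
        assert gates.ck_epcam_positive_threshold == pytest.approx(10.0 + 3 * sd)

    def test_threshold_monotone_in_k(self):
        iso = [meas(v, v) for v in (5.0, 10.0, 15.0)]
        thr = [calibrate_gates([meas(99, 0)], iso, k=k).ck_epcam_positive_threshold for k in (1, 2, 3)]
        assert thr == sorted(thr)

    def test_empty_isotype_rejected(self):
        with pytest.raises(ValueError):
            calibrate_gates([meas(99, 0)], [], k=3.0)

    def test_weak_positive_control_warns(self):
        iso = [meas(10.0, 10.0)] * 4
        with pytest.warns(CalibrationWarning):
            calibrate_gates([meas(5.0, 0.0), meas(6.0, 0.0)], iso, k=3.0)


class TestClassifyAndEnumerate:
    def test_gate_rules(self, gates):
        cases = [
            (meas(100.0, 1.0), "CTC"),
            (meas(100.0, 100.0), "DUAL_POSITIVE"),
            (meas(1.0, 100.0), "WBC"),
            (meas(1.0, 1.0), "NEGATIVE"),
            (meas(50.0, 50.0), "NEGATIVE"),  # gate is strict: at-threshold is negative
        ]
        records = classify_cells([m for m, _ in cases], gates)
        assert [r.assigned_class for r in records] == [c for _, c in cases]

    def test_classification_is_a_partition(self, gates, rng):
        ms = [meas(rng.uniform(0, 120), rng.uniform(0, 120), i) for i in range(200)]
        records = classify_cells(ms, gates)
        result = enumerate_cells(records)
        assert sum(result.counts.values()) == result.total_cells == 200

    def test_purity_ratio(self, gates):
        ms = [meas(100.0, 1.0, i) for i in range(10)] + [meas(1.0, 100.0, i) for i in range(10, 1000)]
        result = enumerate_cells(classify_cells(ms, gates))
        assert result.ctc_purity == pytest.approx(0.01)

    def test_empty_records_purity_undefined(self):
        result = enumerate_cells([])
        assert result.total_cells == 0
        assert result.ctc_purity is None and not result.purity_defined


class TestPipelineEndToEnd:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recovers_ground_truth_on_separable_fixture(self, seed, gates):
        rng = np.random.default_rng(seed)
        cfg = random_fixture_config(rng, n_ctc=4, n_wbc=12, n_dual=2, n_negative=2, noise_sd=0.0)
        fx = generate_fixture(cfg)
        _, result, _ = run_pipeline(
            fx.dna_channel, fx.ck_epcam_channel, fx.cd45_channel, cfg.pixel_size, gates
        )
        assert result.counts == ground_truth_counts(fx)

    def test_lobed_wbcs_excluded_by_eccentricity_gate(self, gates):
        rng = np.random.default_rng(7)
        cfg = random_fixture_config(rng, n_ctc=3, n_wbc=10, n_dual=0, n_negative=0, lobed_wbc_fraction=1.0)
        fx = generate_fixture(cfg)
        _, result, _ = run_pipeline(
            fx.dna_channel, fx.ck_epcam_channel, fx.cd45_channel, cfg.pixel_size, gates
        )
        assert result.counts["CTC"] == 3
        assert result.counts["WBC"] < 10  # lobed nuclei dropped before gating


def test_export_measurements_and_gallery(tmp_path, gates):
    rng = np.random.default_rng(11)
    cfg = random_fixture_config(rng, n_ctc=3, n_wbc=5, n_dual=0, n_negative=0, noise_sd=0.0)
    fx = generate_fixture(cfg)
    records, _, _ = run_pipeline(fx.dna_channel, fx.ck_epcam_channel, fx.cd45_channel, cfg.pixel_size, gates)
    export_measurements(records, tmp_path / "t.csv", tmp_path / "t.sqlite")
    assert (tmp_path / "t.csv").exists()
    with sqlite3.connect(tmp_path / "t.sqlite") as conn:
        n = conn.execute("select count(*) from per_object").fetchone()[0]
    assert n == len(records)
    paths = export_gallery(fx, records, tmp_path / "gallery")
    assert set(paths) == {"CTC", "WBC"}  # no montage for empty classes
    import imageio.v3 as iio

    montage = iio.imread(paths["CTC"])
    assert montage.shape[1] == 3 * 48  # 3 CTC tiles side by side
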