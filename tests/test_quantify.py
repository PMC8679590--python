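import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radplan.curves import TimeActivityCurve
from radplan.errors import (
    DegenerateCurveError,
    IncompleteTimepointError,
    InvalidInputError,
    MissingBackgroundError,
)
from radplan.quantify import (
    CountingStandard,
    PlanarStudy,
    ROIRecord,
    SampleCount,
    administered_activity,
    background_cpp,
    conjugate_percent_id,
    net_roi_count,
    percent_id_per_ml,
    scaled_percent_id,
)
from tests.conftest import CAL_RATIO


class TestAdministeredActivity:
    def test_printed_formula(self):
        std = CountingStandard(counts=1000, volume_counted=1, dilution_factor=100,
                               administered_volume=2)
        assert administered_activity(std) == 200_000

    def test_identity_case(self):
        std = CountingStandard(counts=1234, volume_counted=1.5, dilution_factor=1,
                               administered_volume=1.5)
        assert administered_activity(std) == pytest.approx(1234)

    def test_hand_arithmetic(self):
        std = CountingStandard(counts=5000, volume_counted=0.5, dilution_factor=50,
                               administered_volume=1.5)
        assert administered_activity(std) == pytest.approx(750_000)

    def test_non_positive_volume_rejected(self):
        with pytest.raises(InvalidInputError):
            CountingStandard(counts=1000, volume_counted=0, dilution_factor=1,
                             administered_volume=1)
        with pytest.raises(InvalidInputError):
            CountingStandard(counts=1000, volume_counted=1, dilution_factor=1,
                             administered_volume=-2)


class TestPercentId:
    std = CountingStandard(counts=1000, volume_counted=1, dilution_factor=100,
                           administered_volume=2)  # 200,000 cpm administered

    def test_one_percent_definition(self):
        s = SampleCount("m1", "blood", 1.0, counts=2000, amount=1.0)
        assert percent_id_per_ml(s, self.std) == pytest.approx(1.0)

    def test_zero_counts(self):
        s = SampleCount("m1", "blood", 1.0, counts=0, amount=1.0)
        assert percent_id_per_ml(s, self.std) == 0.0

    def test_mass_amount_gives_per_gram(self):
        # generated at 35.3 %ID/g: counts = 0.353 x administered x grams
        grams = 0.2
        s = SampleCount("m1", "blood", 5 / 60, counts=0.353 * 200_000 * grams,
                        amount=grams, amount_unit="g")
        assert percent_id_per_ml(s, self.std) == pytest.approx(35.3, rel=1e-12)

    @given(counts=st.floats(0, 1e9), scale=st.floats(0.1, 10))
    def test_linear_in_counts(self, counts, scale):
        a = percent_id_per_ml(SampleCount("m", "b", 0, counts=counts, amount=1.0), self.std)
        b = percent_id_per_ml(SampleCount("m", "b", 0, counts=counts * scale, amount=1.0),
                              self.std)
        assert b == pytest.approx(a * scale, rel=1e-9, abs=1e-12)

    def test_inverse_in_administered_activity(self):
        s = SampleCount("m", "b", 0, counts=5000, amount=1.0)
        doubled = CountingStandard(counts=2000, volume_counted=1, dilution_factor=100,
                                   administered_volume=2)
        assert percent_id_per_ml(s, doubled) == pytest.approx(
            percent_id_per_ml(s, self.std) / 2
        )


class TestBackgroundCpp:
    def test_single_roi(self):
        r = [ROIRecord(3, "anterior", "background_corner", 500, 100)]
        assert background_cpp(r, "background_corner") == 5.0

    def test_pooled_not_mean_of_ratios(self):
        rois = [
            ROIRecord(3, "anterior", "background_corner", 100, 50),
            ROIRecord(3, "anterior", "background_corner", 300, 50),
        ]
        assert background_cpp(rois, "background_corner") == 4.0  # 400/100

    def test_all_zero(self):
        rois = [ROIRecord(3, "anterior", "background_corner", 0, 50)]
        assert background_cpp(rois, "background_corner") == 0.0

    def test_missing_label(self):
        with pytest.raises(MissingBackgroundError):
            background_cpp([], "background_corner")

    @given(
        counts=st.lists(st.floats(0, 1e6), min_size=1, max_size=8),
        sizes=st.lists(st.floats(1, 1e4), min_size=8, max_size=8),
    )
    def test_partition_invariance(self, counts, sizes):
        """Pooled CPP over n ROIs equals CPP of the merged single ROI."""
        n = len(counts)
        rois = [
            ROIRecord(0, "anterior", "background_corner", c, s)
            for c, s in zip(counts, sizes[:n])
        ]
        merged = [ROIRecord(0, "anterior", "background_corner",
                            sum(counts), sum(sizes[:n]))]
        assert background_cpp(rois, "background_corner") == pytest.approx(
            background_cpp(merged, "background_corner"), rel=1e-12
        )


class TestNetRoiCount:
    def test_basic_subtraction(self):
        roi = ROIRecord(3, "anterior", "liver", 1000, 100)
        assert net_roi_count(roi, 5.0) == 500

    def test_zero_cpp_identity(self):
        roi = ROIRecord(3, "anterior", "liver", 731, 100)
        assert net_roi_count(roi, 0.0) == 731

    def test_negative_net_retained_with_warning(self):
        roi = ROIRecord(3, "anterior", "liver", 400, 100)
        with pytest.warns(UserWarning, match="negative net"):
            assert net_roi_count(roi, 5.0) == -100


class TestConjugateView:
    def test_roundtrip_noiseless(self, monkey_curves, planar_frame):
        curves, _ = monkey_curves
        rois, _ = planar_frame
        recovered = conjugate_percent_id(PlanarStudy.from_frame(rois), CAL_RATIO)
        assert set(recovered) == set(curves)
        for label, rec in recovered.items():
            np.testing.assert_allclose(rec.values, curves[label].values, rtol=1e-9)

    def test_organ_below_whole_body(self, planar_frame):
        rois, _ = planar_frame
        rec = conjugate_percent_id(PlanarStudy.from_frame(rois), CAL_RATIO)
        wb = rec["whole_body"].values
        for label, c in rec.items():
            if label != "whole_body":
                assert np.all(c.values <= wb + 1e-9)

    def test_equal_views_ratio_one(self):
        """ant = post nets, ratio 1: organ %ID = organ net / calib net x 100."""
        rows = []
        for view in ("anterior", "posterior"):
            rows += [
                ROIRecord(3, view, "background_corner", 0, 100),
                ROIRecord(3, view, "body_background", 0, 100),
                ROIRecord(3, view, "calibration_source", 8000, 100),
                ROIRecord(3, view, "liver", 2000, 100),
            ]
        rec = conjugate_percent_id(PlanarStudy("s", rows), std_ratio=1.0)
        assert rec["liver"].values[0] == pytest.approx(2000 / 8000 * 100)

    def test_missing_view_raises(self, planar_frame):
        rois, _ = planar_frame
        broken = rois[~((rois.time_h == 24.0) & (rois.view == "posterior"))]
        with pytest.raises(IncompleteTimepointError, match="24"):
            conjugate_percent_id(PlanarStudy.from_frame(broken), CAL_RATIO)

    def test_missing_calibration_raises(self, planar_frame):
        rois, _ = planar_frame
        broken = rois[~((rois.time_h == 3.0) & (rois.roi_label == "calibration_source"))]
        with pytest.raises(IncompleteTimepointError, match="calibration"):
            conjugate_percent_id(PlanarStudy.from_frame(broken), CAL_RATIO)

    def test_bad_ratio(self, planar_frame):
        rois, _ = planar_frame
        with pytest.raises(InvalidInputError):
            conjugate_percent_id(PlanarStudy.from_frame(rois), 0.0)


class TestScaledPercentId:
    def _curve(self, values, times=None):
        times = times if times is not None else np.arange(len(values), dtype=float)
        return TimeActivityCurve("m", "blood", "pid_per_ml", times, np.asarray(values))

    def test_hand_arithmetic(self):
        # weight 3 kg, peak 0.5 %ID/mL -> max %ID = 0.5 x 3 x 65 = 97.5
        c = scaled_percent_id(self._curve([0.2, 0.5, 0.1]), body_weight_kg=3.0)
        assert c.values[1] == pytest.approx(0.5 / 97.5 * 100, rel=1e-12)
        assert c.values[1] == pytest.approx(0.5128, rel=1e-3)

    def test_scale_invariance(self):
        a = scaled_percent_id(self._curve([0.2, 0.5, 0.1]), 3.0)
        b = scaled_percent_id(self._curve([0.4, 1.0, 0.2]), 3.0)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)

    def test_single_sample(self):
        c = scaled_percent_id(self._curve([0.5], times=[1.0]), 3.0)
        assert c.values[0] == pytest.approx(100 / (3 * 65), rel=1e-12)

    def test_zero_peak(self):
        with pytest.raises(DegenerateCurveError):
            scaled_percent_id(self._curve([0.0, 0.0, 0.0]), 3.0)

    def test_wrong_unit(self):
        c = TimeActivityCurve("m", "liver", "pid", np.array([0.0, 1.0]),
                              np.array([1.0, 2.0]))
        with pytest.raises(InvalidInputError):
            scaled_percent_id(c, 3.0)
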