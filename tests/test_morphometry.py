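"""Label-mask morphometry: geometry recovery, the nano rule, fibers."""

import math

import numpy as np
import pandas as pd
import pytest
from skimage.draw import ellipse as draw_ellipse

from mtisr.errors import ContractError, ValidationError
from mtisr.morphometry import (
    LabelMask,
    classify_nano,
    fiber_quantify,
    group_percent_difference,
    region_features,
    summarize_population,
)
from mtisr.simulate import generate_mask_fixture, place_shapes


def single_ellipse_mask(a, b, rotation=0.0, pixel_size_nm=10.0, pad=3):
    n = int(2 * (a + pad)) + 1
    labels = np.zeros((n, n), dtype=np.uint16)
    rr, cc = draw_ellipse(n // 2, n // 2, a, b, rotation=rotation)
    labels[rr, cc] = 1
    return LabelMask(labels=labels, pixel_size_nm=pixel_size_nm)


class TestRegionFeatures:
    def test_circle_axes_and_ar(self):
        rec = region_features(single_ellipse_mask(20, 20)).iloc[0]
        assert rec["major_axis_nm"] == pytest.approx(400, rel=0.02)
        assert rec["minor_axis_nm"] == pytest.approx(400, rel=0.02)
        assert rec["aspect_ratio"] == pytest.approx(1.0, abs=0.02)

    def test_ellipse_aspect_ratio(self):
        rec = region_features(single_ellipse_mask(30, 10)).iloc[0]
        assert rec["minor_axis_nm"] == pytest.approx(200, rel=0.02)
        assert rec["aspect_ratio"] == pytest.approx(3.0, rel=0.02)
        assert not rec["is_nano"]  # minor < 250 nm but AR fails the rule

    def test_rotation_invariance(self):
        r0 = region_features(single_ellipse_mask(24, 12, rotation=0.0)).iloc[0]
        r90 = region_features(single_ellipse_mask(24, 12, rotation=math.pi / 2)).iloc[0]
        assert r90["area_um2"] == pytest.approx(r0["area_um2"], rel=0.02)
        assert r90["major_axis_nm"] == pytest.approx(r0["major_axis_nm"], rel=0.02)
        assert r90["aspect_ratio"] == pytest.approx(r0["aspect_ratio"], rel=0.02)

    def test_area_conservation_exact(self, mask_fixture):
        mask = LabelMask(mask_fixture.labels, mask_fixture.pixel_size_nm)
        rec = region_features(mask)
        px_area = (mask.pixel_size_nm / 1000.0) ** 2
        assert rec["area_um2"].sum() == pytest.approx(
            int((mask.labels > 0).sum()) * px_area, rel=1e-12
        )

    def test_scale_equivariance(self):
        m1 = single_ellipse_mask(20, 12, pixel_size_nm=10.0)
        m2 = LabelMask(labels=m1.labels, pixel_size_nm=20.0)
        r1, r2 = region_features(m1).iloc[0], region_features(m2).iloc[0]
        assert r2["major_axis_nm"] == pytest.approx(2 * r1["major_axis_nm"])
        assert r2["area_um2"] == pytest.approx(4 * r1["area_um2"])
        assert r2["aspect_ratio"] == pytest.approx(r1["aspect_ratio"])

    def test_tiny_label_flagged_degenerate(self):
        labels = np.zeros((10, 10), dtype=np.uint16)
        labels[4, 4] = 1
        labels[7, 7:9] = 2
        rec = region_features(LabelMask(labels, 10.0)).set_index("label")
        assert rec.loc[1, "degenerate"] and rec.loc[2, "degenerate"]

    def test_axis_recovery_on_planted_population(self, mask_fixture):
        """Recovered axes within 2% of planted for >= 200 random ellipses
        (minor semi-axis >= 8 px), and nano calls identical to planted truth
        (all planted shapes are > 5% clear of both rule boundaries)."""
        mask = LabelMask(mask_fixture.labels, mask_fixture.pixel_size_nm)
        rec = region_features(mask).set_index("label")
        truth = mask_fixture.truth.set_index("label")
        assert len(rec) >= 200
        rel_major = np.abs(rec["major_axis_nm"] / truth["major_axis_nm"] - 1)
        rel_minor = np.abs(rec["minor_axis_nm"] / truth["minor_axis_nm"] - 1)
        assert rel_major.max() < 0.02
        assert rel_minor.max() < 0.02
        assert (rec["is_nano"] == truth["is_nano"]).all()

    def test_nano_calls_invariant_to_physical_rescale(self, mask_fixture):
        """Doubling the pixel size while halving planted pixel axes describes
        the same physical shapes; nano calls on the same mask at the same
        physical scale must not depend on the pixel grid sign-off."""
        mask = LabelMask(mask_fixture.labels, mask_fixture.pixel_size_nm)
        rec = region_features(mask)
        scaled = LabelMask(mask_fixture.labels, mask_fixture.pixel_size_nm * 2)
        rec2 = region_features(scaled)
        # same grid, doubled physical size: axes double, AR unchanged
        assert np.allclose(rec2["minor_axis_nm"], 2 * rec["minor_axis_nm"])
        assert np.allclose(rec2["aspect_ratio"], rec["aspect_ratio"])

    def test_validation(self):
        with pytest.raises(ValidationError):
            LabelMask(np.zeros((4, 4), dtype=np.uint8), pixel_size_nm=0.0)
        with pytest.raises(ValidationError):
            LabelMask(np.zeros((4, 4), dtype=float), pixel_size_nm=10.0)


class TestClassifyNano:
    @pytest.mark.parametrize(
        "minor, ar, expected",
        [
            (249.0, 1.4, True),
            (250.0, 1.0, False),   # strict minor-axis boundary
            (200.0, 1.6, False),   # AR gate
            (200.0, 1.5, False),   # strict AR boundary
            (100.0, 1.0, True),
        ],
    )
    def test_rule(self, minor, ar, expected):
        assert classify_nano(minor, ar) is expected


class TestSummarize:
    def test_planted_nano_fraction_and_medians(self, mask_fixture):
        mask = LabelMask(mask_fixture.labels, mask_fixture.pixel_size_nm)
        rec = region_features(mask)
        s = summarize_population(rec)
        assert s["n"] == len(mask_fixture.truth)
        assert s["pct_nano"] == pytest.approx(
            100.0 * mask_fixture.truth["is_nano"].mean()
        )
        assert s["median_area_um2"] == pytest.approx(
            float(rec["area_um2"].median())
        )

    def test_manual_annotations_tabulated(self, mask_fixture):
        mask = LabelMask(mask_fixture.labels, mask_fixture.pixel_size_nm)
        rec = region_features(mask)
        ann = pd.DataFrame(
            {"label": rec["label"].iloc[:10], "class": ["cristal_inclusion"] * 10}
        )
        s = summarize_population(rec, ann)
        assert s["manual_class_pct"]["cristal_inclusion"] == pytest.approx(1000 / s["n"])

    def test_unknown_annotation_label_rejected(self, mask_fixture):
        mask = LabelMask(mask_fixture.labels, mask_fixture.pixel_size_nm)
        rec = region_features(mask)
        ann = pd.DataFrame({"label": [999999], "class": ["electrolucent"]})
        with pytest.raises(ContractError):
            summarize_population(rec, ann)


class TestFibers:
    def test_uniform_intensity_recovered(self):
        labels = np.repeat(np.arange(1, 5, dtype=np.uint16), 25).reshape(10, 10)
        rec = fiber_quantify(LabelMask(labels, 500.0), np.full((10, 10), 7.0))
        assert np.allclose(rec["mean_intensity"], 7.0)

    def test_planted_group_means_exact(self, fiber_fixture, fiber_annotations):
        mask = LabelMask(fiber_fixture.labels, fiber_fixture.pixel_size_nm)
        rec = fiber_quantify(mask, fiber_fixture.intensity, fiber_annotations)
        means = rec.groupby("ub_status")["csa_um2"].mean()
        assert means["pos"] == pytest.approx(330.0, abs=1e-9)
        assert means["neg"] == pytest.approx(446.9, abs=1e-9)

    def test_shape_mismatch_rejected(self, fiber_fixture):
        mask = LabelMask(fiber_fixture.labels, fiber_fixture.pixel_size_nm)
        with pytest.raises(ContractError):
            fiber_quantify(mask, fiber_fixture.intensity[:-1])

    def test_unannotated_fiber_excluded_from_groups(self, fiber_fixture, fiber_annotations):
        mask = LabelMask(fiber_fixture.labels, fiber_fixture.pixel_size_nm)
        partial = fiber_annotations.iloc[:-1]
        rec = fiber_quantify(mask, fiber_fixture.intensity, partial)
        assert rec["ub_status"].isna().sum() == 1


class TestGroupPercentDifference:
    def _rec(self, pos, neg):
        return pd.DataFrame(
            {
                "ub_status": ["pos"] * len(pos) + ["neg"] * len(neg),
                "mean_intensity": list(pos) + list(neg),
                "csa_um2": list(pos) + list(neg),
            }
        )

    def test_equal_means_zero(self):
        assert group_percent_difference(self._rec([5, 5], [5, 5])) == pytest.approx(0.0)

    def test_planted_ratio(self):
        assert group_percent_difference(self._rec([2712.0], [1000.0])) == pytest.approx(171.2)

    def test_negative_difference_reported(self):
        assert group_percent_difference(self._rec([1.0], [2.0])) == pytest.approx(-50.0)

    def test_single_group_undefined(self):
        assert math.isnan(group_percent_difference(self._rec([1.0], [])))


class TestMaskGeneration:
    def test_overlap_free_and_inside(self):
        plan = place_shapes([(20, 10)] * 30, (400, 400), 10.0, seed=3)
        fix = generate_mask_fixture(plan)
        assert len(np.unique(fix.labels)) == 31  # 30 shapes + background
        border = np.concatenate(
            [fix.labels[0], fix.labels[-1], fix.labels[:, 0], fix.labels[:, -1]]
        )
        assert (border == 0).all()

    def test_placement_error_when_impossible(self):
        from mtisr.errors import PlacementError

        with pytest.raises(PlacementError):
            place_shapes([(30, 30)] * 50, (100, 100), 10.0, seed=0, max_retries=20)
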