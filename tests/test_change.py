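"""The two WMH-change methods: segmentation accuracy, change decomposition,
normalisation/gamma/subtraction mechanics, and the intensification-inflation
behaviour that separates them."""

import numpy as np
import pytest

from wmhdrift.change import (
    gamma_correct,
    normalise_intensities,
    segment_wmh_multispectral,
    solve_gamma,
    subtract_flair,
    subtraction_change,
    wmh_volume_change_independent,
)
from wmhdrift.core import BinaryMask, ImageVolume, dice, volume_ml
from wmhdrift.phantom import LesionSpec, PhantomConfig, generate_subject

GRID = (64, 64, 12)


class TestMultispectralSegmentation:
    def test_recovers_ground_truth(self, small_subject):
        gt = small_subject.ground_truth["gt"]
        for tp in ("baseline", "followup"):
            seg = segment_wmh_multispectral(
                small_subject.image("FLAIR", tp),
                small_subject.image("T2SW", tp),
                small_subject.icv_mask[tp],
                small_subject.stroke_mask[tp],
            )
            assert dice(seg.mask, gt.wmh_mask(tp)) >= 0.90

    def test_stroke_never_in_output(self, small_subject):
        seg = segment_wmh_multispectral(
            small_subject.image("FLAIR", "baseline"),
            small_subject.image("T2SW", "baseline"),
            small_subject.icv_mask["baseline"],
            small_subject.stroke_mask["baseline"],
        )
        assert not (seg.mask.data & small_subject.stroke_mask["baseline"].data).any()

    def test_empty_ground_truth_gives_empty_mask(self):
        cfg = PhantomConfig(
            grid_shape=GRID, seed=2, lesion_plan=[], stroke_prob=0.0, bias_amplitude=0.0
        )
        subj = generate_subject(cfg, "s", 77)
        seg = segment_wmh_multispectral(
            subj.image("FLAIR", "baseline"),
            subj.image("T2SW", "baseline"),
            subj.icv_mask["baseline"],
            subj.stroke_mask["baseline"],
        )
        assert seg.mask.n_voxels == 0

    def test_flair_only_fallback_warns_but_works(self, small_subject):
        seg = segment_wmh_multispectral(
            small_subject.image("FLAIR", "baseline"),
            None,
            small_subject.icv_mask["baseline"],
            small_subject.stroke_mask["baseline"],
        )
        gt = small_subject.ground_truth["gt"]
        assert dice(seg.mask, gt.wmh_mask("baseline")) >= 0.85


class TestChangeDecomposition:
    def _seg(self, data, tp):
        mask = BinaryMask(data, voxel_dims=(1, 1, 1), label="WMH")
        from wmhdrift.change import WmhSegmentation

        return WmhSegmentation(
            mask=mask, timepoint=tp, method="multispectral",
            volume_ml=volume_ml(mask), volume_pct_icv=0.0,
        )

    def test_identity(self):
        data = np.zeros((10, 10, 3), dtype=bool)
        data[2:5, 2:5, 1] = True
        dec = wmh_volume_change_independent(self._seg(data, "baseline"), self._seg(data, "followup"))
        assert dec.net_change_ml == 0.0
        assert dec.increased_mask.n_voxels == 0
        assert dec.disappeared_mask.n_voxels == 0

    def test_nested_masks(self):
        small = np.zeros((10, 10, 3), dtype=bool)
        small[2:4, 2:4, 1] = True
        big = small.copy()
        big[2:6, 2:6, 1] = True
        dec = wmh_volume_change_independent(self._seg(small, "baseline"), self._seg(big, "followup"))
        assert dec.disappeared_mask.n_voxels == 0
        assert dec.net_change_ml == pytest.approx(dec.followup_ml - dec.baseline_ml)

    def test_closure_identities(self, small_subject):
        gt = small_subject.ground_truth["gt"]
        segs = {}
        for tp in ("baseline", "followup"):
            segs[tp] = segment_wmh_multispectral(
                small_subject.image("FLAIR", tp),
                small_subject.image("T2SW", tp),
                small_subject.icv_mask[tp],
                small_subject.stroke_mask[tp],
            )
        dec = wmh_volume_change_independent(segs["baseline"], segs["followup"])
        vox = np.prod(small_subject.icv_mask["baseline"].voxel_dims) / 1000.0
        assert dec.unchanged_ml + dec.increased_ml == pytest.approx(dec.followup_ml, abs=vox)
        assert dec.net_change_ml == pytest.approx(
            dec.increased_ml - dec.disappeared_ml, abs=vox
        )

    def test_antisymmetry_under_timepoint_swap(self, small_subject):
        segs = {}
        for tp in ("baseline", "followup"):
            segs[tp] = segment_wmh_multispectral(
                small_subject.image("FLAIR", tp),
                small_subject.image("T2SW", tp),
                small_subject.icv_mask[tp],
                small_subject.stroke_mask[tp],
            )
        fwd = wmh_volume_change_independent(segs["baseline"], segs["followup"])
        rev = wmh_volume_change_independent(segs["followup"], segs["baseline"])
        assert fwd.net_change_ml == pytest.approx(-rev.net_change_ml)

    def test_recovers_planned_growth(self):
        plan = [
            LesionSpec(kind="deep", tissue="intense", change="grow", target_ml=2.0, grow_ml=3.0)
        ]
        cfg = PhantomConfig(
            grid_shape=GRID, seed=5, lesion_plan=plan, stroke_prob=0.0,
            bias_amplitude=0.0, atrophy_rate=0, halo_prob=0.0,
        )
        subj = generate_subject(cfg, "s", 55)
        segs = {}
        for tp in ("baseline", "followup"):
            segs[tp] = segment_wmh_multispectral(
                subj.image("FLAIR", tp), subj.image("T2SW", tp),
                subj.icv_mask[tp], subj.stroke_mask[tp],
            )
        dec = wmh_volume_change_independent(segs["baseline"], segs["followup"])
        assert dec.net_change_ml == pytest.approx(3.0, abs=0.5)


class TestNormalisationAndGamma:
    def test_idempotent(self, small_subject):
        icv = small_subject.icv_mask["baseline"]
        nb, nf = normalise_intensities(
            small_subject.image("FLAIR", "baseline"),
            small_subject.image("FLAIR", "followup"),
            icv,
        )
        nb2, nf2 = normalise_intensities(nb, nf, icv)
        np.testing.assert_allclose(nb2.data, nb.data, atol=1e-6)
        np.testing.assert_allclose(nf2.data, nf.data, atol=1e-6)

    def test_identical_inputs_identical_outputs(self, small_subject):
        icv = small_subject.icv_mask["baseline"]
        vol = small_subject.image("FLAIR", "baseline")
        na, nb = normalise_intensities(vol, vol.copy_with(vol.data.copy()), icv)
        np.testing.assert_array_equal(na.data, nb.data)

    def test_global_scaling_removed(self, small_subject):
        icv = small_subject.icv_mask["baseline"]
        vol = small_subject.image("FLAIR", "baseline")
        scaled = vol.copy_with(vol.data * 1.3)
        na, nb = normalise_intensities(vol, scaled, icv)
        from wmhdrift.change import _parenchyma_mode

        ma = _parenchyma_mode(na.data[icv.data])
        mb = _parenchyma_mode(nb.data[icv.data])
        assert abs(ma - mb) / ma < 0.01

    def test_gamma_identity_and_arithmetic(self):
        vol = ImageVolume(np.full((4, 4, 2), 0.25), voxel_dims=(1, 1, 1))
        out, g = gamma_correct(vol, gamma=1.0)
        np.testing.assert_array_equal(out.data, vol.data)
        out, _ = gamma_correct(vol, gamma=0.5)
        np.testing.assert_allclose(out.data, 0.5)

    def test_gamma_solve_closed_form(self):
        assert solve_gamma(0.4) == pytest.approx(np.log(0.5) / np.log(0.4))
        with pytest.raises(ValueError):
            solve_gamma(1.0)
        with pytest.raises(ValueError):
            solve_gamma(0.0)


class TestSubtraction:
    def test_identical_timepoints_no_change(self, small_subject):
        icv = small_subject.icv_mask["baseline"]
        vol = small_subject.image("FLAIR", "baseline")
        res = subtraction_change(vol, vol.copy_with(vol.data.copy()), icv)
        assert res.change_volume_ml == 0.0
        assert res.decrease_volume_ml == 0.0

    def test_increase_decrease_disjoint_and_inside_region(self, small_subject):
        icv = small_subject.icv_mask["baseline"]
        stroke = small_subject.stroke_mask["baseline"]
        res = subtraction_change(
            small_subject.image("FLAIR", "baseline"),
            small_subject.image("FLAIR", "followup"),
            icv,
            stroke=stroke,
        )
        assert not (res.increase_mask.data & res.decrease_mask.data).any()
        outside = ~(icv.data & ~stroke.data)
        assert not (res.increase_mask.data & outside).any()

    def test_intensification_inflates_subtraction_not_independent(self):
        # a subtle lesion that intensifies without growing: the subtraction
        # method counts its whole footprint as increase, the independent
        # method sees (nearly) zero net change
        plan = [LesionSpec(kind="deep", tissue="subtle", change="intensify", target_ml=2.0)]
        cfg = PhantomConfig(
            grid_shape=GRID, seed=8, lesion_plan=plan, stroke_prob=0.0,
            bias_amplitude=0.0, atrophy_rate=0,
        )
        subj = generate_subject(cfg, "s", 88)
        icv = subj.icv_mask["baseline"]
        res = subtraction_change(
            subj.image("FLAIR", "baseline"), subj.image("FLAIR", "followup"), icv
        )
        segs = {}
        for tp in ("baseline", "followup"):
            segs[tp] = segment_wmh_multispectral(
                subj.image("FLAIR", tp), subj.image("T2SW", tp),
                subj.icv_mask[tp], subj.stroke_mask[tp],
            )
        dec = wmh_volume_change_independent(segs["baseline"], segs["followup"])
        assert res.change_volume_ml >= 0.9 * 2.0  # at least the footprint
        assert abs(dec.net_change_ml) < 0.5

    def test_pure_growth_methods_agree(self):
        plan = [
            LesionSpec(kind="deep", tissue="intense", change="grow", target_ml=2.0, grow_ml=2.5)
        ]
        cfg = PhantomConfig(
            grid_shape=GRID, seed=9, lesion_plan=plan, stroke_prob=0.0,
            bias_amplitude=0.0, atrophy_rate=0, halo_prob=0.0,
        )
        subj = generate_subject(cfg, "s", 99)
        icv = subj.icv_mask["baseline"]
        res = subtraction_change(
            subj.image("FLAIR", "baseline"), subj.image("FLAIR", "followup"), icv
        )
        segs = {}
        for tp in ("baseline", "followup"):
            segs[tp] = segment_wmh_multispectral(
                subj.image("FLAIR", tp), subj.image("T2SW", tp),
                subj.icv_mask[tp], subj.stroke_mask[tp],
            )
        dec = wmh_volume_change_independent(segs["baseline"], segs["followup"])
        assert res.change_volume_ml == pytest.approx(dec.net_change_ml, rel=0.25)
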