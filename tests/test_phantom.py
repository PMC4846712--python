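"""Synthetic cohort generator: determinism, geometry, lesion bookkeeping,
bias fields and noise statistics."""

import numpy as np
import pytest

from wmhdrift.core import volume_ml
from wmhdrift.phantom import (
    LesionSpec,
    PhantomConfig,
    add_noise,
    apply_bias_field,
    evolve_followup,
    generate_cohort,
    generate_subject,
    make_bias_field,
    make_brain_template,
    plant_lesions,
    render_modalities,
)

GRID = (64, 64, 12)


def cfg_with(**kw):
    base = dict(grid_shape=GRID, seed=9, n_subjects=2, wmh_load_median_ml=5.0)
    base.update(kw)
    return PhantomConfig(**base)


class TestTemplate:
    def test_deterministic(self):
        cfg = cfg_with()
        l1, icv1, v1 = make_brain_template(cfg, 5)
        l2, icv2, v2 = make_brain_template(cfg, 5)
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_array_equal(icv1, icv2)

    def test_icv_fraction_and_ventricles(self):
        cfg = PhantomConfig(seed=0)  # default 128x128x20 grid
        labels, icv, vent = make_brain_template(cfg, 11)
        frac = icv.mean()
        assert 0.2 <= frac <= 0.6
        assert (vent & ~icv).sum() == 0  # ventricles inside ICV
        assert set(np.unique(labels)) == {0, 1, 2}

    def test_grid_too_small(self):
        with pytest.raises(ValueError):
            make_brain_template(PhantomConfig(grid_shape=(32, 32, 4)), 0)


class TestLesions:
    def test_zero_lesions_empty_masks(self):
        cfg = cfg_with(lesion_plan=[], stroke_prob=0.0)
        gt = plant_lesions(make_brain_template(cfg, 1), cfg, 1)
        assert gt.masks["baseline"]["subtle"].n_voxels == 0
        assert gt.masks["baseline"]["intense"].n_voxels == 0

    def test_planted_volume_matches_plan(self):
        plan = [LesionSpec(kind="deep", tissue="intense", change="static", target_ml=2.0)]
        cfg = cfg_with(lesion_plan=plan, stroke_prob=0.0, halo_prob=0.0)
        gt = plant_lesions(make_brain_template(cfg, 2), cfg, 2)
        planted = volume_ml(gt.masks["baseline"]["intense"])
        assert planted == pytest.approx(2.0, rel=0.10)

    def test_subtle_intense_disjoint_and_inside_icv(self):
        cfg = cfg_with()
        gt = plant_lesions(make_brain_template(cfg, 3), cfg, 3)
        m = gt.masks["baseline"]
        assert not (m["subtle"].data & m["intense"].data).any()
        for name in ("subtle", "intense", "stroke"):
            assert not (m[name].data & ~m["icv"].data).any()

    def test_infeasible_plan_raises(self):
        plan = [LesionSpec(kind="deep", tissue="intense", change="static", target_ml=500.0)]
        cfg = cfg_with(lesion_plan=plan)
        with pytest.raises(ValueError):
            plant_lesions(make_brain_template(cfg, 4), cfg, 4)


class TestEvolution:
    def test_static_plan_identity(self):
        plan = [LesionSpec(kind="deep", tissue="intense", change="static", target_ml=1.5)]
        cfg = cfg_with(lesion_plan=plan, atrophy_rate=0, stroke_prob=0.0, halo_prob=0.0)
        gt = plant_lesions(make_brain_template(cfg, 5), cfg, 5)
        gt = evolve_followup(gt, cfg, 6)
        for name in ("subtle", "intense", "csf"):
            np.testing.assert_array_equal(
                gt.masks["baseline"][name].data, gt.masks["followup"][name].data
            )
        assert gt.change_volumes_ml["net"] == pytest.approx(0.0)

    def test_disappearing_lesion_volume(self):
        plan = [
            LesionSpec(kind="deep", tissue="intense", change="disappear", target_ml=2.0,
                       ex_vacuo=False)
        ]
        cfg = cfg_with(lesion_plan=plan, atrophy_rate=0, stroke_prob=0.0, halo_prob=0.0)
        gt = plant_lesions(make_brain_template(cfg, 7), cfg, 7)
        gt = evolve_followup(gt, cfg, 8)
        vox = np.prod(cfg.voxel_dims) / 1000.0
        assert gt.change_volumes_ml["disappeared"] == pytest.approx(2.0, abs=10 * vox)
        assert gt.masks["followup"]["intense"].n_voxels == 0

    def test_intensify_preserves_footprint(self):
        plan = [LesionSpec(kind="deep", tissue="subtle", change="intensify", target_ml=1.0)]
        cfg = cfg_with(lesion_plan=plan, atrophy_rate=0, stroke_prob=0.0)
        gt = plant_lesions(make_brain_template(cfg, 9), cfg, 9)
        gt = evolve_followup(gt, cfg, 10)
        np.testing.assert_array_equal(
            gt.masks["baseline"]["subtle"].data, gt.masks["followup"]["intense"].data
        )
        assert gt.change_volumes_ml["net"] == pytest.approx(0.0)

    def test_bookkeeping_closure(self):
        cfg = cfg_with()
        for seed in (11, 12, 13):
            subj = generate_subject(cfg, "s", seed)
            cv = subj.ground_truth["gt"].change_volumes_ml
            assert cv["unchanged"] + cv["increased"] == pytest.approx(cv["followup"], abs=1e-9)
            assert cv["net"] == pytest.approx(cv["increased"] - cv["disappeared"], abs=1e-9)


class TestRendering:
    def test_contrast_ordering(self, small_subject):
        gt = small_subject.ground_truth["gt"]
        cfg = PhantomConfig(grid_shape=GRID)
        clean = render_modalities(gt, cfg)
        flair = clean[("FLAIR", "baseline")].data
        t2w = clean[("T2W", "baseline")].data
        m = gt.masks["baseline"]
        nawm = m["icv"].data & ~m["csf"].data & ~gt.wmh_mask("baseline").data & ~m["stroke"].data
        if m["intense"].n_voxels:
            assert flair[m["intense"].data].mean() > flair[nawm].mean()
        assert t2w[m["ventricles"].data].mean() > t2w[nawm].mean()

    def test_noiseless_nawm_vmr_zero(self, small_subject):
        from wmhdrift.phantom import _inplane_dilate, render_modalities

        gt = small_subject.ground_truth["gt"]
        cfg = PhantomConfig(grid_shape=GRID)
        flair = render_modalities(gt, cfg)[("FLAIR", "baseline")].data
        m = gt.masks["baseline"]
        # interior NAWM away from every boundary shell
        other = m["csf"].data | gt.wmh_mask("baseline").data | m["stroke"].data | ~m["icv"].data
        interior = m["icv"].data & ~_inplane_dilate(other, 2)
        vals = flair[interior]
        assert len(vals) > 100
        assert vals.var() == 0.0


class TestBiasAndNoise:
    def test_zero_amplitude_identity(self, small_subject):
        cfg = cfg_with(bias_amplitude=0.0)
        vol = small_subject.image("FLAIR", "baseline")
        out, fld = apply_bias_field(vol, cfg, 42)
        np.testing.assert_array_equal(out.data, vol.data)
        np.testing.assert_array_equal(fld.data, np.ones(vol.shape))

    def test_field_range_and_mean(self, small_subject):
        icv = small_subject.icv_mask["baseline"].data
        fld = make_bias_field(GRID, (0.94, 0.94, 6.5), 0.2, seed=17, icv=icv)
        assert fld.data.min() >= 0.8 - 1e-12
        assert fld.data.max() <= 1.2 + 1e-12
        assert 0.95 <= fld.data[icv].mean() <= 1.05

    def test_output_is_product(self, small_subject):
        cfg = cfg_with(bias_amplitude=0.15)
        vol = small_subject.image("FLAIR", "baseline")
        out, fld = apply_bias_field(vol, cfg, 3, icv=small_subject.icv_mask["baseline"].data)
        pos = vol.data > 0
        np.testing.assert_allclose(out.data[pos] / vol.data[pos], fld.data[pos], rtol=1e-12)

    def test_noise_zero_sigma_identity(self, small_subject):
        vol = small_subject.image("FLAIR", "baseline")
        out = add_noise(vol, 0.0, 1)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_noise_sd_matches_nominal(self):
        from wmhdrift.core import ImageVolume

        vol = ImageVolume(np.full((40, 40, 10), 100.0), voxel_dims=(1, 1, 1))
        noisy = add_noise(vol, 0.02, seed=8, reference_mean=100.0)
        sd = noisy.data.std()
        assert sd == pytest.approx(2.0, rel=0.10)
        assert noisy.data.min() >= 0.0

    def test_noise_deterministic(self, small_subject):
        vol = small_subject.image("FLAIR", "baseline")
        a = add_noise(vol, 0.02, seed=5, reference_mean=100.0)
        b = add_noise(vol, 0.02, seed=5, reference_mean=100.0)
        np.testing.assert_array_equal(a.data, b.data)


class TestCohort:
    def test_reproducible_and_structured(self):
        cfg = cfg_with(n_subjects=3)
        subs1, table1 = generate_cohort(cfg)
        subs2, table2 = generate_cohort(cfg)
        assert len(subs1) == 3
        assert list(table1.columns) == list(table2.columns)
        assert table1.equals(table2)
        np.testing.assert_array_equal(
            subs1[0].image("FLAIR", "baseline").data, subs2[0].image("FLAIR", "baseline").data
        )

    def test_cohort_load_right_skewed(self):
        cfg = PhantomConfig(grid_shape=GRID, seed=4, n_subjects=12, wmh_load_median_ml=6.0)
        _, table = generate_cohort(cfg)
        col = table["true_baseline_ml"]
        assert col.median() < col.mean()

    def test_ground_truth_masks_within_icv(self):
        cfg = cfg_with(n_subjects=1)
        subs, _ = generate_cohort(cfg)
        gt = subs[0].ground_truth["gt"]
        for tp in ("baseline", "followup"):
            icv = gt.masks[tp]["icv"].data
            for name in ("subtle", "intense", "stroke", "csf"):
                assert not (gt.masks[tp][name].data & ~icv).any()
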