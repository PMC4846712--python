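"""Benchmark cohorts and end-to-end validation measurements.

Each function here defines one validation study — the phantom conditions and
the quantity measured — used both by the test suite and by the results
script.  Conditions are fixed properties of the studies, not tuning knobs:

* quantiser exactness against an independent exhaustive oracle;
* bias-field recovery on Gaussian-bump phantoms at amplitude 0.2 with the
  acquisition noise (2% of NAWM);
* ΔVMR calibration with the generator's true fields;
* net-volume-change recovery on a cohort with planned changes spanning
  -1 to +6 ml (bias-free: distortion by bias is its own study);
* subtraction-vs-independent inflation on a cohort in which most of the
  subtle baseline WMH intensifies;
* neutrality of total change under HUM correction at moderate (10%) bias.
"""

from __future__ import annotations

import itertools
from typing import Dict, List

import numpy as np

from . import bias as bias_mod
from . import change as change_mod
from . import stats as stats_mod
from .core import BinaryMask, jaccard
from .phantom import LesionSpec, PhantomConfig, generate_subject
from .pipeline import segment_subject
from .quantise import minimum_variance_quantise
from .vmr import delta_vmr, vmr

FULL_GRID = (128, 128, 20)


def _seed_stream(seed: int, n: int) -> List[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# quantiser exactness


def brute_force_partition_sse(values: np.ndarray, weights: np.ndarray, k: int) -> float:
    """Exhaustive minimum within-cluster SSE over contiguous partitions of
    the sorted distinct values (independent oracle)."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = len(v)

    def seg_sse(a, b):
        seg_w, seg_v = w[a:b], v[a:b]
        mu = np.average(seg_v, weights=seg_w)
        return float((seg_w * (seg_v - mu) ** 2).sum())

    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        edges = (0,) + cuts + (n,)
        best = min(best, sum(seg_sse(a, b) for a, b in zip(edges[:-1], edges[1:])))
    return best


def quantiser_oracle_study(n_trials: int = 200, seed: int = 0) -> Dict[str, float]:
    """Compare the quantiser's SSE with the exhaustive optimum on random
    small instances (<= 200 voxels, <= 12 distinct values, k in {2, 3, 5})."""
    from .core import ImageVolume

    rng = np.random.default_rng(seed)
    worst = 0.0
    agree = 0
    done = 0
    while done < n_trials:
        k = int(rng.choice([2, 3, 5]))
        n_distinct = int(rng.integers(k, 13))
        pool = np.round(rng.uniform(0, 100, n_distinct), 2)
        if len(np.unique(pool)) < k:
            continue
        n = int(rng.integers(max(k + 1, 10), 201))
        vals = rng.choice(pool, size=n)
        if len(np.unique(vals)) < k:
            continue
        vol = ImageVolume(vals.reshape(-1, 1, 1), voxel_dims=(1, 1, 1))
        mask = BinaryMask(np.ones(vol.shape, dtype=bool), voxel_dims=(1, 1, 1))
        q = minimum_variance_quantise(vol, mask, k=k)
        uniq, counts = np.unique(vals, return_counts=True)
        sse_opt = brute_force_partition_sse(uniq, counts.astype(float), k)
        gap = abs(q.within_level_sse - sse_opt)
        worst = max(worst, gap)
        agree += gap <= 1e-9
        done += 1
    return {"n": n_trials, "agreement_rate": agree / n_trials, "worst_gap": worst}


# ---------------------------------------------------------------------------
# bias-field recovery and ΔVMR calibration


def gaussian_bump_phantoms(n: int = 10, seed: int = 0):
    """Full-geometry phantoms carrying known Gaussian-bump bias fields of
    amplitude 0.2 (no through-slice hat: that artefact is a separate,
    deliberately non-recoverable component)."""
    cfg = PhantomConfig(
        grid_shape=FULL_GRID, seed=seed, bias_amplitude=0.2, bias_slice_hat=0.0
    )
    for i, s in enumerate(_seed_stream(seed, n)):
        yield generate_subject(cfg, f"bump{i:02d}", s)


def true_nawm_mask(subj, timepoint: str) -> BinaryMask:
    gt = subj.ground_truth["gt"]
    m = gt.masks[timepoint]
    nawm = (
        m["icv"].data
        & ~m["csf"].data
        & ~gt.wmh_mask(timepoint).data
        & ~m["stroke"].data
    )
    return BinaryMask(nawm, voxel_dims=m["icv"].voxel_dims, label="normal_tissue")


def bias_recovery_study(n: int = 10, seed: int = 0) -> Dict[str, float]:
    """HUM field estimation vs the known field, and the NAWM VMR before and
    after correcting with the estimate."""
    correlations, vmr_drops, dvmr_true, dvmr_self = [], [], [], []
    for subj in gaussian_bump_phantoms(n, seed):
        gt = subj.ground_truth["gt"]
        flair = subj.image("FLAIR", "baseline")
        icv = subj.icv_mask["baseline"]
        stroke = subj.stroke_mask["baseline"]
        true_field = gt.true_bias[("FLAIR", "baseline")]
        res = bias_mod.hum_correction(flair, icv, stroke)
        m = icv.data
        correlations.append(float(np.corrcoef(res.field.data[m], true_field.data[m])[0, 1]))
        nawm = true_nawm_mask(subj, "baseline")
        vmr_drops.append(vmr(res.corrected, nawm) - vmr(flair, nawm))
        corrected_true = bias_mod.correct_volume(flair, true_field, icv).corrected
        dvmr_true.append(delta_vmr(flair, corrected_true, nawm))
        dvmr_self.append(delta_vmr(flair, flair, nawm))
    return {
        "n": n,
        "correlation_min": min(correlations),
        "correlation_median": float(np.median(correlations)),
        "vmr_drop_max": max(vmr_drops),  # < 0 means VMR strictly decreased
        "delta_vmr_true_field_max": max(dvmr_true),
        "delta_vmr_self_max_abs": max(abs(d) for d in dvmr_self),
    }


# ---------------------------------------------------------------------------
# volume-change recovery


def recovery_cohort(n: int = 20, seed: int = 0):
    """Cohort with planned net WMH changes spanning [-1, +6] ml.

    Each subject carries two static background lesions plus one changing
    lesion cycling through grow / disappear / new / intensify, with growth
    volumes swept across the range.  Bias-free: the recovery study isolates
    segmentation accuracy at the acquisition noise level.
    """
    seeds = _seed_stream(seed + 1, n)
    for i in range(n):
        frac = i / max(n - 1, 1)
        kind = ("grow", "disappear", "new", "intensify")[i % 4]
        plan = [
            LesionSpec(kind="periventricular", tissue="intense", change="static",
                       target_ml=2.0, halo=(i % 2 == 0)),
            LesionSpec(kind="deep", tissue="subtle", change="static", target_ml=1.5),
        ]
        if kind == "grow":
            plan.append(
                LesionSpec(kind="deep", tissue="intense", change="grow",
                           target_ml=2.0, grow_ml=0.5 + 5.0 * frac)
            )
        elif kind == "disappear":
            plan.append(
                LesionSpec(kind="deep", tissue="intense", change="disappear",
                           target_ml=1.0, ex_vacuo=(i % 8 == 1))
            )
        elif kind == "new":
            plan.append(
                LesionSpec(kind="deep", tissue="intense", change="new",
                           target_ml=1.0 + 3.0 * frac)
            )
        else:
            plan.append(
                LesionSpec(kind="deep", tissue="subtle", change="intensify", target_ml=1.5)
            )
        cfg = PhantomConfig(
            grid_shape=FULL_GRID, seed=seed, bias_amplitude=0.0, lesion_plan=plan
        )
        yield generate_subject(cfg, f"rec{i:02d}", seeds[i])


def _independent_change(subj, with_bfc=False):
    segs = segment_subject(subj, with_bfc=with_bfc)
    return (
        change_mod.wmh_volume_change_independent(
            segs["baseline"], segs["followup"], subj.icv_mask["baseline"]
        ),
        segs,
    )


def _closure_violation_ml(dec) -> float:
    return max(
        abs(dec.unchanged_ml + dec.increased_ml - dec.followup_ml),
        abs(dec.net_change_ml - (dec.increased_ml - dec.disappeared_ml)),
    )


def volume_change_recovery_study(n: int = 20, seed: int = 0) -> Dict[str, float]:
    errors, closure = [], []
    for subj in recovery_cohort(n, seed):
        dec, _ = _independent_change(subj)
        true_net = subj.ground_truth["gt"].change_volumes_ml["net"]
        errors.append(dec.net_change_ml - true_net)
        closure.append(_closure_violation_ml(dec))
    return {
        "n": n,
        "max_abs_error_ml": max(abs(e) for e in errors),
        "mean_abs_error_ml": float(np.mean(np.abs(errors))),
        "closure_violation_max_ml": max(closure),
    }


# ---------------------------------------------------------------------------
# subtraction inflation


def intensify_cohort(n: int = 20, seed: int = 0):
    """Cohort in which well over 30% of the baseline subtle WMH volume
    intensifies at follow-up without footprint growth."""
    seeds = _seed_stream(seed + 2, n)
    for i in range(n):
        frac = i / max(n - 1, 1)
        plan = [
            LesionSpec(kind="periventricular", tissue="intense", change="static",
                       target_ml=1.5 + frac),
            LesionSpec(kind="deep", tissue="subtle", change="intensify",
                       target_ml=1.5 + 2.0 * frac),
            LesionSpec(kind="deep", tissue="subtle", change="static", target_ml=1.0),
            LesionSpec(kind="deep", tissue="intense", change="grow",
                       target_ml=1.0, grow_ml=0.3 + 0.7 * frac),
        ]
        cfg = PhantomConfig(
            grid_shape=FULL_GRID, seed=seed, bias_amplitude=0.0, lesion_plan=plan
        )
        yield generate_subject(cfg, f"int{i:02d}", seeds[i])


def subtraction_inflation_study(n: int = 20, seed: int = 0) -> Dict[str, float]:
    sub_changes, ind_changes, closure = [], [], []
    intensified, subtle_total = 0.0, 0.0
    for subj in intensify_cohort(n, seed):
        gt = subj.ground_truth["gt"]
        for rec in gt.lesions:
            vol = rec["core_baseline"].sum() + rec["halo_baseline"].sum()
            if rec["spec"].tissue == "subtle" or rec["halo_baseline"].any():
                subtle_total += vol
                if rec["spec"].change == "intensify":
                    intensified += vol
        dec, _ = _independent_change(subj)
        closure.append(_closure_violation_ml(dec))
        sub = change_mod.subtraction_change(
            subj.image("FLAIR", "baseline"),
            subj.image("FLAIR", "followup"),
            subj.icv_mask["baseline"],
            stroke=subj.stroke_mask["baseline"],
        )
        sub_changes.append(sub.change_volume_ml)
        ind_changes.append(dec.net_change_ml)
    _, p = stats_mod.wilcoxon_signed_rank(sub_changes, ind_changes, alternative="greater")
    return {
        "n": n,
        "median_subtraction_ml": float(np.median(sub_changes)),
        "median_independent_ml": float(np.median(ind_changes)),
        "wilcoxon_one_sided_p": p,
        "intensified_subtle_fraction": intensified / max(subtle_total, 1),
        "closure_violation_max_ml": max(closure),
    }


# ---------------------------------------------------------------------------
# BFC neutrality of totals


def moderate_bias_cohort(n: int = 20, seed: int = 0):
    cfg = PhantomConfig(grid_shape=FULL_GRID, seed=seed, bias_amplitude=0.1)
    for i, s in enumerate(_seed_stream(seed + 3, n)):
        yield generate_subject(cfg, f"mod{i:02d}", s)


def bfc_neutrality_study(n: int = 20, seed: int = 0) -> Dict[str, float]:
    paired_diffs, nets, jaccards, closure = [], [], [], []
    for subj in moderate_bias_cohort(n, seed):
        dec, segs = _independent_change(subj)
        dec_bfc, segs_bfc = _independent_change(subj, with_bfc=True)
        paired_diffs.append(dec_bfc.net_change_ml - dec.net_change_ml)
        nets.append(dec.net_change_ml)
        jaccards.append(jaccard(segs["baseline"].mask, segs_bfc["baseline"].mask))
        jaccards.append(jaccard(segs["followup"].mask, segs_bfc["followup"].mask))
        closure.append(max(_closure_violation_ml(dec), _closure_violation_ml(dec_bfc)))
    return {
        "n": n,
        "median_net_change_ml": float(np.median(nets)),
        "median_paired_diff_ml": float(np.median(paired_diffs)),
        "paired_diff_fraction": abs(float(np.median(paired_diffs)))
        / max(abs(float(np.median(nets))), 1e-12),
        "median_mask_jaccard": float(np.median(jaccards)),
        "closure_violation_max_ml": max(closure),
    }


# ---------------------------------------------------------------------------
# statistical layer


def statistical_layer_study(seed: int = 0, hz_reps: int = 500) -> Dict[str, float]:
    rng = np.random.default_rng(seed)
    # exact Wilcoxon: all-positive n = 5 case and brute-force agreement
    _, p_all5 = stats_mod.wilcoxon_signed_rank(
        [1.0, 2.0, 3.0, 4.0, 5.0], [0.0] * 5, alternative="greater"
    )
    worst_gap = 0.0
    for _ in range(50):
        n = int(rng.integers(3, 11))
        d = np.round(rng.normal(size=n), 1)
        d = d[d != 0]
        if len(d) == 0:
            continue
        _, p = stats_mod.wilcoxon_signed_rank(d, np.zeros(len(d)))
        p_bf = _brute_force_wilcoxon_two_sided(d)
        worst_gap = max(worst_gap, abs(p - p_bf))
    # Henze-Zirkler type-I error at alpha = 0.05, d = 2, n = 50
    rejections = 0
    for _ in range(hz_reps):
        X = rng.standard_normal((50, 2))
        _, p = stats_mod.henze_zirkler(X)
        rejections += p < 0.05
    ba = stats_mod.bland_altman([1.0, 3.0, 2.0], [2.0, 5.0, 3.0])
    return {
        "n": hz_reps,
        "wilcoxon_all5_one_sided_p": p_all5,
        "wilcoxon_brute_force_worst_gap": worst_gap,
        "hz_type1_rate": rejections / hz_reps,
        "bland_altman_md": ba.mean_difference,
        "bland_altman_loa_low": ba.loa_low,
        "bland_altman_loa_high": ba.loa_high,
    }


def _brute_force_wilcoxon_two_sided(d):
    from scipy import stats as sps

    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    stats_all = []
    for signs in itertools.product([0, 1], repeat=len(d)):
        stats_all.append(sum(r for s, r in zip(signs, ranks) if s))
    stats_all = np.asarray(stats_all)
    p_ge = (stats_all >= w_obs - 1e-12).mean()
    p_le = (stats_all <= w_obs + 1e-12).mean()
    return min(1.0, 2 * min(p_ge, p_le))
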