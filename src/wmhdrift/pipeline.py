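"""End-to-end drivers wiring the stages into the two study workflows.

Workflow A compares the two WMH-change measurement methods (independent
multispectral vs FLAIR subtraction) on a cohort; workflow B measures the
effect of bias-field correction on the quantised levels (Test 1), on the
normal-tissue VMR (Test 2), and on the winning change method.  Every driver
takes explicit seeds so reruns are exact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

from . import bias as bias_mod
from . import change as change_mod
from . import stats as stats_mod
from .vmr import (
    REGIMES,
    cohort_vmr_table,
    delta_vmr as _delta_vmr,
    normal_tissue_mask as _normal_tissue_mask,
    rank_methods,
    vmr as _vmr,
)
from .core import BinaryMask, LongitudinalSubject, jaccard, volume_ml
from .phantom import PhantomConfig, generate_cohort
from .quantise import bfc_level_agreement, minimum_variance_quantise, quantised_change_volumes

logger = logging.getLogger(__name__)

_GT_MASKS = ("subtle", "intense", "csf", "ventricles")


def save_subject(subj: LongitudinalSubject, out_dir) -> None:
    """Write one subject (images, ICV/stroke masks, ground-truth masks when
    present) as NIfTI files in its own directory."""
    from .core import write_volume
    from .phantom import GroundTruth

    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    for (modality, tp), vol in subj.images.items():
        write_volume(vol, d / f"{modality}_{tp}.nii.gz")
    for tp in ("baseline", "followup"):
        write_volume(subj.icv_mask[tp], d / f"icv_{tp}.nii.gz")
        write_volume(subj.stroke_mask[tp], d / f"stroke_{tp}.nii.gz")
    gt: Optional[GroundTruth] = (subj.ground_truth or {}).get("gt")
    if gt is not None:
        for tp in ("baseline", "followup"):
            for name in _GT_MASKS:
                write_volume(gt.masks[tp][name], d / f"gt_{name}_{tp}.nii.gz")


def load_subject(subj_dir) -> LongitudinalSubject:
    """Rebuild a subject from the on-disk layout written by
    :func:`save_subject` (``wmhdrift simulate``).

    Ground-truth tissue masks are restored when present; per-lesion records
    and true bias fields are generator-session objects and are not."""
    from .core import MODALITIES, read_mask, read_volume
    from .phantom import GroundTruth

    d = Path(subj_dir)
    images, icv, stroke = {}, {}, {}
    for tp in ("baseline", "followup"):
        for modality in MODALITIES:
            path = d / f"{modality}_{tp}.nii.gz"
            if path.exists():
                images[(modality, tp)] = read_volume(path, modality=modality, timepoint=tp)
        icv[tp] = read_mask(d / f"icv_{tp}.nii.gz", label="ICV")
        stroke[tp] = read_mask(d / f"stroke_{tp}.nii.gz", label="stroke")
    ground_truth = None
    if (d / "gt_subtle_baseline.nii.gz").exists():
        masks = {}
        for tp in ("baseline", "followup"):
            masks[tp] = {name: read_mask(d / f"gt_{name}_{tp}.nii.gz", label="WMH")
                         for name in _GT_MASKS}
            masks[tp]["icv"] = icv[tp]
            masks[tp]["stroke"] = stroke[tp]
        gt = GroundTruth(masks=masks, lesions=[])
        wmh_b, wmh_f = gt.wmh_mask("baseline"), gt.wmh_mask("followup")
        inc = wmh_f.copy_with(wmh_f.data & ~wmh_b.data)
        dis = wmh_b.copy_with(wmh_b.data & ~wmh_f.data)
        unc = wmh_b.copy_with(wmh_b.data & wmh_f.data)
        gt.change_volumes_ml = {
            "baseline": volume_ml(wmh_b),
            "followup": volume_ml(wmh_f),
            "increased": volume_ml(inc),
            "disappeared": volume_ml(dis),
            "unchanged": volume_ml(unc),
            "net": volume_ml(wmh_f) - volume_ml(wmh_b),
        }
        ground_truth = {"gt": gt}
    return LongitudinalSubject(
        subject_id=d.name, images=images, icv_mask=icv, stroke_mask=stroke,
        ground_truth=ground_truth,
    )


def load_cohort(cohort_dir):
    """Load every subject directory under a simulated-cohort directory,
    plus the ground-truth table when present."""
    d = Path(cohort_dir)
    subjects = [load_subject(p) for p in sorted(d.iterdir()) if p.is_dir()]
    if not subjects:
        raise ValueError(f"no subject directories under {d}")
    truth_path = d / "ground_truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else None
    return subjects, truth


@dataclass
class RunConfig:
    """Resolved configuration for a full pipeline run (YAML-serialisable)."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    bfc_cutoff: float = bias_mod.DEFAULT_CUTOFF
    bfc_order: int = bias_mod.DEFAULT_ORDER
    quantisation_k: int = 5
    subtraction_z: float = change_mod.DEFAULT_Z_THRESHOLD
    min_component_voxels: int = change_mod.DEFAULT_MIN_COMPONENT_VOXELS
    bootstrap_B: int = 1000
    stats_seed: int = 0
    prins_tau_ml: float = stats_mod.PRINS_TAU_ML
    methods: tuple = ("none", "hum")


def _hum_correct(vol, icv: BinaryMask, stroke: Optional[BinaryMask], cutoff, order):
    if stroke is not None and not stroke.data.any():
        stroke = None
    return bias_mod.hum_correction(vol, icv, stroke, cutoff=cutoff, order=order).corrected


def segment_subject(
    subj: LongitudinalSubject,
    with_bfc: bool = False,
    cutoff: float = bias_mod.DEFAULT_CUTOFF,
    order: int = bias_mod.DEFAULT_ORDER,
    k: int = 5,
) -> Dict[str, change_mod.WmhSegmentation]:
    """Independent multispectral segmentation at both time points.

    With ``with_bfc`` the FLAIR and T2*W are HUM-corrected first; the stroke
    mask always comes from the original images.
    """
    out = {}
    for tp in ("baseline", "followup"):
        flair = subj.image("FLAIR", tp)
        t2sw = subj.images.get(("T2SW", tp))
        icv = subj.icv_mask[tp]
        stroke = subj.stroke_mask[tp]
        if with_bfc:
            flair = _hum_correct(flair, icv, stroke, cutoff, order)
            if t2sw is not None:
                t2sw = _hum_correct(t2sw, icv, stroke, cutoff, order)
        out[tp] = change_mod.segment_wmh_multispectral(flair, t2sw, icv, stroke, k=k)
    return out


def subject_change_records(subj: LongitudinalSubject, cfg: RunConfig) -> List[dict]:
    """Net WMH change for one subject under the three pipelines.

    Pipelines: independent multispectral without BFC, the same with HUM
    BFC, and FLAIR subtraction without BFC (the subtraction method reports
    its increase volume).
    """
    records = []
    icv = subj.icv_mask["baseline"]

    segs = segment_subject(subj, with_bfc=False, k=cfg.quantisation_k)
    dec = change_mod.wmh_volume_change_independent(segs["baseline"], segs["followup"], icv)
    records.append(
        {
            "subject_id": subj.subject_id,
            "method": "independent",
            "net_change_ml": dec.net_change_ml,
            "increased_ml": dec.increased_ml,
            "disappeared_ml": dec.disappeared_ml,
            "unchanged_ml": dec.unchanged_ml,
            "baseline_ml": dec.baseline_ml,
            "followup_ml": dec.followup_ml,
        }
    )

    segs_bfc = segment_subject(
        subj, with_bfc=True, cutoff=cfg.bfc_cutoff, order=cfg.bfc_order, k=cfg.quantisation_k
    )
    dec_bfc = change_mod.wmh_volume_change_independent(segs_bfc["baseline"], segs_bfc["followup"], icv)
    records.append(
        {
            "subject_id": subj.subject_id,
            "method": "independent_bfc",
            "net_change_ml": dec_bfc.net_change_ml,
            "increased_ml": dec_bfc.increased_ml,
            "disappeared_ml": dec_bfc.disappeared_ml,
            "unchanged_ml": dec_bfc.unchanged_ml,
            "baseline_ml": dec_bfc.baseline_ml,
            "followup_ml": dec_bfc.followup_ml,
            "mask_jaccard_vs_nobfc_baseline": jaccard(segs["baseline"].mask, segs_bfc["baseline"].mask),
            "mask_jaccard_vs_nobfc_followup": jaccard(segs["followup"].mask, segs_bfc["followup"].mask),
        }
    )

    sub = change_mod.subtraction_change(
        subj.image("FLAIR", "baseline"),
        subj.image("FLAIR", "followup"),
        icv,
        stroke=subj.stroke_mask["baseline"],
        z=cfg.subtraction_z,
        min_size=cfg.min_component_voxels,
    )
    records.append(
        {
            "subject_id": subj.subject_id,
            "method": "subtraction",
            "net_change_ml": sub.change_volume_ml,
            "increased_ml": sub.change_volume_ml,
            "disappeared_ml": sub.decrease_volume_ml,
        }
    )
    return records


def compare_methods(records: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    """Per-subject paired table + cohort medians (IQR) + Wilcoxon p-values.

    ``records`` needs columns subject_id, method, net_change_ml covering
    every (subject, method) cell; missing cells raise with their names.
    """
    pivot = records.pivot_table(
        index="subject_id", columns="method", values="net_change_ml", aggfunc="first"
    )
    missing = [
        (sid, m) for m in pivot.columns for sid in pivot.index[pivot[m].isna()]
    ]
    if missing:
        raise ValueError(f"incomplete pipeline coverage, missing cells: {missing}")

    summary = pd.DataFrame(
        {
            "method": pivot.columns,
            "median_ml": [pivot[m].median() for m in pivot.columns],
            "iqr_ml": [pivot[m].quantile(0.75) - pivot[m].quantile(0.25) for m in pivot.columns],
            "n": [pivot[m].count() for m in pivot.columns],
        }
    )
    pairs = []
    cols = list(pivot.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            stat, p = stats_mod.wilcoxon_signed_rank(pivot[cols[i]], pivot[cols[j]])
            pairs.append({"method_a": cols[i], "method_b": cols[j], "w_plus": stat, "p": p})
    return {
        "per_subject": pivot.reset_index(),
        "summary": summary,
        "wilcoxon": pd.DataFrame(pairs),
    }


def level_agreement_records(
    subj: LongitudinalSubject,
    cutoff: float = bias_mod.DEFAULT_CUTOFF,
    order: int = bias_mod.DEFAULT_ORDER,
    k: int = 5,
) -> List[dict]:
    """Test-1 rows: level-4/5 agreement before vs after HUM BFC, plus the
    changed/unchanged quantised hyperintense volumes across time points."""
    rows = []
    quantised = {}
    for tp in ("baseline", "followup"):
        flair = subj.image("FLAIR", tp)
        icv = subj.icv_mask[tp]
        q_orig = minimum_variance_quantise(flair, icv, k=k)
        corrected = _hum_correct(flair, icv, subj.stroke_mask[tp], cutoff, order)
        q_corr = minimum_variance_quantise(corrected, icv, k=k)
        quantised[tp] = (q_orig, q_corr)
        for la in bfc_level_agreement(q_orig, q_corr, icv):
            rows.append(
                {
                    "subject_id": subj.subject_id,
                    "timepoint": tp,
                    "level": la.level,
                    "jaccard": la.jaccard,
                    "vol_nobfc_pcticv": la.volume_a,
                    "vol_bfc_pcticv": la.volume_b,
                    "mean_pcticv": la.mean_volume,
                    "diff_pcticv": la.difference,
                }
            )
    for label, idx in (("nobfc", 0), ("bfc", 1)):
        changed, unchanged = quantised_change_volumes(
            quantised["baseline"][idx],
            quantised["followup"][idx],
            subj.icv_mask["baseline"],
            subj.icv_mask["followup"],
        )
        rows.append(
            {
                "subject_id": subj.subject_id,
                "timepoint": "change",
                "level": 45,
                "bfc": label,
                "changed_pcticv": changed,
                "unchanged_pcticv": unchanged,
            }
        )
    return rows


def vmr_records(
    subj: LongitudinalSubject,
    cutoff: float = bias_mod.DEFAULT_CUTOFF,
    order: int = bias_mod.DEFAULT_ORDER,
    regimes: Iterable[str] = REGIMES,
    k: int = 5,
) -> List[dict]:
    """Test-2 rows: ΔVMR per modality/timepoint/regime for HUM correction.

    The normal-tissue mask is level 3 of the uncorrected FLAIR quantisation
    minus the stroke lesion, reused across modalities of the same
    subject-timepoint.
    """
    rows = []
    for tp in ("baseline", "followup"):
        icv = subj.icv_mask[tp]
        stroke = subj.stroke_mask[tp]
        q = minimum_variance_quantise(subj.image("FLAIR", tp), icv, k=k)
        normal = _normal_tissue_mask(icv, stroke, q)
        for modality in ("FLAIR", "T2W", "T2SW"):
            vol = subj.images.get((modality, tp))
            if vol is None:
                continue
            for regime in regimes:
                if regime == "raw":
                    est_mask = None
                elif regime == "icv":
                    est_mask = icv
                else:  # icv_nostroke
                    est_mask = icv.copy_with(icv.data & ~stroke.data, label="ICV")
                fld = bias_mod.estimate_bias_hum(vol, est_mask, cutoff=cutoff, order=order)
                corrected = bias_mod.correct_volume(vol, fld, icv).corrected
                v0 = _vmr(vol, normal)
                rows.append(
                    {
                        "subject_id": subj.subject_id,
                        "modality": modality,
                        "timepoint": tp,
                        "method": "hum",
                        "regime": regime,
                        "vmr": v0,
                        "delta_vmr": _delta_vmr(vol, corrected, normal),
                    }
                )
                rows.append(
                    {
                        "subject_id": subj.subject_id,
                        "modality": modality,
                        "timepoint": tp,
                        "method": "none",
                        "regime": regime,
                        "vmr": v0,
                        "delta_vmr": 0.0,
                    }
                )
    return rows


def ratings_table(subjects: Iterable[LongitudinalSubject], tau_ml: float) -> pd.DataFrame:
    rows = []
    for subj in subjects:
        gt = subj.ground_truth["gt"]
        rec = stats_mod.simulate_prins(gt, subject_id=subj.subject_id, tau_ml=tau_ml)
        fz_f = stats_mod.simulate_fazekas(gt, "followup")
        row = {
            "subject_id": subj.subject_id,
            "fazekas_pv_baseline": rec.fazekas_pv,
            "fazekas_deep_baseline": rec.fazekas_deep,
            "fazekas_pv_followup": fz_f[0],
            "fazekas_deep_followup": fz_f[1],
            "prins_total": rec.prins_total,
        }
        # note: regions are geometric sectors of the phantom, not anatomy
        row.update({f"prins_sector_{k}": v for k, v in rec.prins_region_scores.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def correlation_table(compare: Dict[str, pd.DataFrame], ratings: pd.DataFrame,
                      truth: pd.DataFrame, B: int, seed: int) -> pd.DataFrame:
    """Correlations of each method's change with the simulated Prins total,
    of cross-sectional volumes with Fazekas, and with a synthetic age
    covariate correlated with true change."""
    per = compare["per_subject"].merge(ratings, on="subject_id").merge(truth, on="subject_id")
    rng = np.random.default_rng(seed)
    true_net = per["true_net_ml"].to_numpy()
    target_r = 0.25
    noise = rng.standard_normal(len(per))
    zs = (true_net - true_net.mean()) / (true_net.std() or 1.0)
    age = 66 + 10 * (target_r * zs + np.sqrt(1 - target_r**2) * noise)  # synthetic covariate
    rows = []
    for method in ("independent", "independent_bfc", "subtraction"):
        if method not in per.columns:
            continue
        x = per[method].to_numpy()
        for yname, y, corr in (
            ("prins_total", per["prins_total"].to_numpy(), "spearman"),
            ("age_synthetic", age, "pearson"),
        ):
            for remove in (False, True):
                row = {
                    "method": method,
                    "against": yname,
                    "correlation": corr,
                    "outliers_removed": remove,
                    "coefficient": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p": np.nan,
                    "n": len(x),
                    "note": "",
                }
                try:
                    if corr == "spearman":
                        res = stats_mod.spearman_bootstrap_ci(x, y, B=B, seed=seed, remove_outliers=remove)
                    else:
                        xs = np.sign(x) * np.log1p(np.abs(x))  # rescale/log for skew
                        res = stats_mod.pearson_ci(xs, y, B=B, seed=seed, remove_outliers=remove)
                except ValueError as exc:
                    row["note"] = str(exc)
                else:
                    row.update(
                        coefficient=res.coefficient, ci_low=res.ci_low, ci_high=res.ci_high,
                        p=res.p_value, n=res.n,
                    )
                rows.append(row)
    return pd.DataFrame(rows)


def cohort_report(subjects, truth: pd.DataFrame, cfg: RunConfig) -> Dict[str, pd.DataFrame]:
    """Assemble the full report bundle for an in-memory cohort."""
    change_rows, agreement_rows, vmr_rows = [], [], []
    for subj in subjects:
        change_rows.extend(subject_change_records(subj, cfg))
        agreement_rows.extend(
            level_agreement_records(subj, cfg.bfc_cutoff, cfg.bfc_order, cfg.quantisation_k)
        )
        vmr_rows.extend(vmr_records(subj, cfg.bfc_cutoff, cfg.bfc_order, k=cfg.quantisation_k))
        logger.info("processed %s", subj.subject_id)

    changes = pd.DataFrame(change_rows)
    compare = compare_methods(changes)
    ratings = ratings_table(subjects, cfg.prins_tau_ml)
    vmr_table = cohort_vmr_table(vmr_rows)
    corr = correlation_table(compare, ratings, truth, cfg.bootstrap_B, cfg.stats_seed)

    return {
        "ground_truth": truth,
        "change_per_subject": changes,
        "method_per_subject": compare["per_subject"],
        "method_summary": compare["summary"],
        "method_wilcoxon": compare["wilcoxon"],
        "level_agreement": pd.DataFrame(agreement_rows),
        "vmr_medians": vmr_table,
        "vmr_ranking": rank_methods(vmr_table),
        "ratings_synthetic": ratings,
        "correlations": corr,
    }


def run_full_pipeline(cfg: RunConfig, out_dir=None) -> Dict[str, pd.DataFrame]:
    """simulate -> correct -> Test 1 -> Test 2 -> segment/compare -> report."""
    subjects, truth = generate_cohort(cfg.phantom)
    logger.info("generated %d subjects", len(subjects))
    tables = cohort_report(subjects, truth, cfg)
    if out_dir is not None:
        stats_mod.build_report(tables, out_dir)
        out = Path(out_dir)
        resolved = asdict(cfg)
        blob = json.dumps(resolved, sort_keys=True, default=str)
        resolved["run_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
        (out / "run_config.json").write_text(json.dumps(resolved, indent=2, default=str))
    return tables
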