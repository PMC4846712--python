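"""Synthetic two-time-point multimodal brain phantoms with full ground truth.

The generator emulates the statistical structure the longitudinal WMH
analysis assumes: an ellipsoidal head with central lateral ventricles and a
peripheral CSF rim, periventricular and deep white-matter lesions (subtle
and intense), an optional stroke lesion, smooth multiplicative bias fields,
Rician noise, and thick anisotropic slices (0.94 x 0.94 x 6.5 mm, i.e. 5-mm
slices with a 1.5-mm gap).  Lesions evolve between baseline and follow-up by
a per-lesion change plan — grow, disappear (with or without ex-vacuo CSF
replacement), intensify (subtle becomes intense on the same footprint),
appear anew, or stay static — and the ventricles may dilate to mimic
atrophy.  Every random draw flows through named seeds, so regeneration is
exact, and the ground-truth masks, bias fields and change volumes are kept
alongside the rendered images.

Lesion texture is built in-plane (discs spanning one to three slices)
because at 6.5-mm slice spacing real WMH appearance is essentially
slice-wise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .bias import BiasFieldMap
from .core import (
    DEFAULT_VOXEL_DIMS,
    BinaryMask,
    ImageVolume,
    LongitudinalSubject,
    volume_ml,
)

logger = logging.getLogger(__name__)

#: FLAIR ordering CSF < NAWM < subtle WMH < intense WMH is what the 5-level
#: quantisation semantics rely on; subtle sits halfway between NAWM and
#: intense so that subtle lesions straddle the level-3/4 boundary — the
#: regime in which bias-field correction is most disruptive.
DEFAULT_TISSUE_MEANS = {
    "FLAIR": {"csf": 20.0, "nawm": 100.0, "subtle": 140.0, "intense": 180.0, "stroke": 180.0},
    "T2W": {"csf": 200.0, "nawm": 100.0, "subtle": 130.0, "intense": 160.0, "stroke": 160.0},
    "T2SW": {"csf": 180.0, "nawm": 100.0, "subtle": 108.0, "intense": 118.0, "stroke": 125.0},
}

CHANGE_TYPES = ("static", "grow", "disappear", "intensify", "new")


@dataclass
class LesionSpec:
    """Plan and realisation of one lesion."""

    kind: str  # periventricular | deep
    tissue: str  # subtle | intense
    change: str  # static | grow | disappear | intensify | new
    target_ml: float
    grow_ml: float = 0.0
    halo: bool = False
    ex_vacuo: bool = False  # disappearing lesion leaves CSF instead of NAWM


@dataclass
class PhantomConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the acquisition geometry and cohort size of the kind of
    two-time-point small-vessel-disease study the pipeline targets: 46
    subjects, 0.94 x 0.94 x 6.5 mm voxels, 2% Rician noise relative to the
    NAWM mean, multiplicative bias fields of up to +/-20%.
    """

    grid_shape: Tuple[int, int, int] = (128, 128, 20)
    voxel_dims: Tuple[float, float, float] = DEFAULT_VOXEL_DIMS
    n_subjects: int = 46
    seed: int = 0
    tissue_means: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_TISSUE_MEANS.items()}
    )
    noise_sigma: float = 0.02  # fraction of the NAWM mean
    bias_amplitude: float = 0.2  # max multiplicative deviation from 1
    bias_slice_hat: float = 0.3  # weight of the through-slice quadratic term
    atrophy_rate: int = 1  # ventricle dilation (in-plane voxels) at follow-up
    #: cohort lesion-load distribution: log-normal total baseline WMH volume,
    #: parameters giving a median of ~10 ml (plausible small-vessel range)
    wmh_load_median_ml: float = 10.0
    wmh_load_sigma_log: float = 0.6
    #: per-lesion change-type probabilities for the default cohort plan
    change_probs: Dict[str, float] = field(
        default_factory=lambda: {
            "static": 0.35,
            "grow": 0.30,
            "intensify": 0.15,
            "disappear": 0.10,
            "new": 0.10,
        }
    )
    stroke_prob: float = 1.0
    halo_prob: float = 0.5
    lesion_plan: Optional[List[LesionSpec]] = None  # overrides the random plan

    def __post_init__(self):
        if not (0.0 <= self.bias_amplitude <= 0.5):
            raise ValueError("bias_amplitude must be in [0, 0.5]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        fm = self.tissue_means["FLAIR"]
        if not (fm["csf"] < fm["nawm"] < fm["subtle"] < fm["intense"]):
            raise ValueError("FLAIR tissue means must be ordered csf < nawm < subtle < intense")


@dataclass
class GroundTruth:
    """True tissue masks, bias fields and change bookkeeping for one subject."""

    masks: Dict[str, Dict[str, BinaryMask]]  # timepoint -> name -> mask
    lesions: List[dict]  # per-lesion realisation records
    true_bias: Dict[Tuple[str, str], BiasFieldMap] = field(default_factory=dict)
    change_volumes_ml: Dict[str, float] = field(default_factory=dict)

    def wmh_mask(self, timepoint: str) -> BinaryMask:
        m = self.masks[timepoint]
        return m["subtle"].copy_with(m["subtle"].data | m["intense"].data, label="WMH")


# ---------------------------------------------------------------------------
# geometry helpers (all in-plane operations use a (3, 3, 1) structure because
# of the thick slices)

_INPLANE_STRUCT = np.zeros((3, 3, 3), dtype=bool)
_INPLANE_STRUCT[:, :, 1] = [[0, 1, 0], [1, 1, 1], [0, 1, 0]]

#: full in-plane 8-neighbourhood, matching the partial-volume footprint
_INPLANE_SQUARE = np.zeros((3, 3, 3), dtype=bool)
_INPLANE_SQUARE[:, :, 1] = True


def _inplane_dilate(mask, iterations=1):
    if iterations <= 0:
        return mask.copy()
    return ndimage.binary_dilation(mask, structure=_INPLANE_STRUCT, iterations=iterations)


def _inplane_erode(mask, iterations=1):
    if iterations <= 0:
        return mask.copy()
    return ndimage.binary_erosion(mask, structure=_INPLANE_STRUCT, iterations=iterations)


def make_brain_template(cfg: PhantomConfig, subject_seed: int):
    """Ellipsoidal head with central ventricles and a peripheral CSF rim.

    Returns ``(labels, icv_mask, ventricle_mask)`` where labels are
    0 background, 1 CSF, 2 parenchyma (NAWM and grey lumped).  Deterministic
    given the seed; per-subject jitter moves the centres and semi-axes a few
    percent.
    """
    nx, ny, nz = cfg.grid_shape
    if nx < 64 or ny < 64 or nz < 10:
        raise ValueError(f"grid too small for a brain template: {cfg.grid_shape}")
    rng = np.random.default_rng(subject_seed)
    jit = rng.uniform(0.96, 1.04, size=3)
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    rx, ry, rz = 0.40 * nx * jit[0], 0.44 * ny * jit[1], 0.48 * nz * jit[2]
    x, y, z = np.ogrid[:nx, :ny, :nz]
    icv = ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0

    # two lateral ventricles: elongated ellipsoids either side of the midline
    vent = np.zeros_like(icv)
    for side in (-1.0, 1.0):
        vcx = cx + side * 0.10 * nx * rng.uniform(0.9, 1.1)
        vcy = cy + rng.uniform(-0.02, 0.02) * ny
        vrx, vry, vrz = 0.045 * nx, 0.16 * ny, 0.22 * nz
        vent |= ((x - vcx) / vrx) ** 2 + ((y - vcy) / vry) ** 2 + ((z - cz) / vrz) ** 2 <= 1.0
    vent &= icv

    labels = np.zeros(cfg.grid_shape, dtype=np.int8)
    labels[icv] = 2
    # peripheral CSF rim (sulci stand-in), thick enough that no rim voxel
    # has both background and parenchyma in its 8-neighbourhood
    rim = icv & ~ndimage.binary_erosion(icv, structure=_INPLANE_SQUARE, iterations=2)
    labels[rim] = 1
    labels[vent] = 1
    return labels, icv, vent


def _take_nearest(candidates: np.ndarray, centre, n: int, voxel_dims) -> np.ndarray:
    """Boolean mask of the n candidate voxels nearest (in mm) to ``centre``.

    Distance is weighted so that in-plane growth is preferred over crossing
    slices (thick-slice lesion texture).
    """
    idx = np.argwhere(candidates)
    if len(idx) < n:
        raise ValueError(f"lesion plan infeasible: need {n} voxels, only {len(idx)} available")
    dx, dy, dz = voxel_dims
    d2 = (
        ((idx[:, 0] - centre[0]) * dx) ** 2
        + ((idx[:, 1] - centre[1]) * dy) ** 2
        + ((idx[:, 2] - centre[2]) * dz * 3.0) ** 2
    )
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], d2))
    chosen = idx[order[:n]]
    out = np.zeros(candidates.shape, dtype=bool)
    out[chosen[:, 0], chosen[:, 1], chosen[:, 2]] = True
    return out


def _grow_nearest(lesion: np.ndarray, candidates: np.ndarray, n: int, voxel_dims) -> np.ndarray:
    """Add the n candidate voxels nearest to an existing lesion footprint."""
    if n <= 0:
        return lesion.copy()
    sampling = (voxel_dims[0], voxel_dims[1], voxel_dims[2] * 3.0)
    dist = ndimage.distance_transform_edt(~lesion, sampling=sampling)
    idx = np.argwhere(candidates)
    if len(idx) < n:
        raise ValueError(f"growth plan infeasible: need {n} voxels, only {len(idx)} available")
    d = dist[idx[:, 0], idx[:, 1], idx[:, 2]]
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], d))
    chosen = idx[order[:n]]
    out = lesion.copy()
    out[chosen[:, 0], chosen[:, 1], chosen[:, 2]] = True
    return out


def _ml_to_voxels(ml: float, voxel_dims) -> int:
    return max(1, int(round(ml * 1000.0 / float(np.prod(voxel_dims)))))


def _random_plan(cfg: PhantomConfig, rng: np.random.Generator) -> List[LesionSpec]:
    """Draw a per-subject lesion plan from the cohort-level distribution."""
    total_ml = float(
        np.exp(np.log(cfg.wmh_load_median_ml) + cfg.wmh_load_sigma_log * rng.standard_normal())
    )
    total_ml = float(np.clip(total_ml, 1.0, 40.0))
    n_pv = rng.integers(1, 3)
    n_deep = rng.integers(1, 5)
    n = n_pv + n_deep
    w = rng.dirichlet(np.ones(n) * 2.0)
    kinds = ["periventricular"] * n_pv + ["deep"] * n_deep
    types = list(cfg.change_probs)
    probs = np.array([cfg.change_probs[t] for t in types], dtype=float)
    probs /= probs.sum()
    plan = []
    for i, kind in enumerate(kinds):
        tissue = "intense" if (kind == "periventricular" or rng.random() < 0.5) else "subtle"
        change = str(rng.choice(types, p=probs))
        target = max(0.3, total_ml * w[i])
        grow_ml = float(rng.uniform(0.5, 2.0)) if change in ("grow",) else 0.0
        plan.append(
            LesionSpec(
                kind=kind,
                tissue=tissue,
                change=change,
                target_ml=float(target),
                grow_ml=grow_ml,
                halo=(tissue == "intense" and rng.random() < cfg.halo_prob),
                ex_vacuo=(rng.random() < 0.5),
            )
        )
    return plan


def plant_lesions(template, cfg: PhantomConfig, subject_seed: int) -> GroundTruth:
    """Place the planned lesions on the template; returns baseline ground truth.

    Periventricular lesions are seeded on the ventricle wall, deep lesions in
    the interior parenchyma away from both ventricles and the brain edge;
    each lesion is the set of nearest free parenchyma voxels around its seed,
    so the realised volume matches the plan to the voxel.  Intense lesions
    may receive a one-voxel subtle halo.  The optional stroke lesion
    (cortical or lacunar) is placed last.
    """
    labels, icv, vent = template
    rng = np.random.default_rng(subject_seed + 1)
    plan = cfg.lesion_plan if cfg.lesion_plan is not None else _random_plan(cfg, rng)

    parenchyma = labels == 2
    # ependymal gap: lesions keep one voxel clear of all CSF (even after the
    # planned atrophic dilation of the ventricles), so lesion edges blend
    # with NAWM, never with CSF
    csf = labels == 1
    gap = _inplane_dilate(vent, cfg.atrophy_rate + 1) | _inplane_dilate(csf, 1)
    parenchyma_free = parenchyma & ~gap
    wall = _inplane_dilate(vent, cfg.atrophy_rate + 3) & parenchyma_free
    interior = _inplane_erode(icv, 5) & parenchyma_free & ~_inplane_dilate(vent, cfg.atrophy_rate + 4)

    occupied = np.zeros_like(parenchyma)
    subtle = np.zeros_like(parenchyma)
    intense = np.zeros_like(parenchyma)
    lesion_records = []
    for spec in plan:
        seed_pool = wall if spec.kind == "periventricular" else interior
        seed_pool = seed_pool & ~occupied
        cand_idx = np.argwhere(seed_pool)
        if len(cand_idx) == 0:
            raise ValueError("lesion plan infeasible: no free seed voxels")
        centre = cand_idx[rng.integers(len(cand_idx))]
        n = _ml_to_voxels(spec.target_ml, cfg.voxel_dims)
        candidates = parenchyma_free & ~occupied
        core = _take_nearest(candidates, centre, n, cfg.voxel_dims)
        occupied |= core
        halo = np.zeros_like(core)
        present = spec.change != "new"
        if spec.tissue == "intense":
            if present:
                intense |= core
            if spec.halo:
                halo = _inplane_dilate(core, 1) & parenchyma_free & ~occupied
                occupied |= halo
                if present:
                    subtle |= halo
        elif present:
            subtle |= core
        lesion_records.append(
            {
                "spec": spec,
                "core_baseline": core if present else np.zeros_like(core),
                "halo_baseline": halo if present else np.zeros_like(halo),
                "core_planned": core,
                "halo_planned": halo,
            }
        )

    stroke = np.zeros_like(parenchyma)
    if rng.random() < cfg.stroke_prob:
        cortical = rng.random() < 0.5
        if cortical:
            belt = parenchyma_free & ~_inplane_erode(icv, 4) & ~occupied
            size_ml = float(rng.uniform(3.0, 10.0))
        else:
            belt = interior & ~occupied
            size_ml = float(rng.uniform(0.1, 0.5))
        bidx = np.argwhere(belt)
        if len(bidx) > 0:
            centre = bidx[rng.integers(len(bidx))]
            n = min(_ml_to_voxels(size_ml, cfg.voxel_dims), int(belt.sum()))
            stroke = _take_nearest(parenchyma_free & ~occupied, centre, n, cfg.voxel_dims)
            occupied |= stroke

    csf = labels == 1
    vd = cfg.voxel_dims

    def _mask(data, label):
        return BinaryMask(data=data, voxel_dims=vd, label=label)

    masks = {
        "baseline": {
            "icv": _mask(icv, "ICV"),
            "csf": _mask(csf, "normal_tissue"),
            "ventricles": _mask(vent, "normal_tissue"),
            "subtle": _mask(subtle, "WMH"),
            "intense": _mask(intense, "WMH"),
            "stroke": _mask(stroke, "stroke"),
        }
    }
    return GroundTruth(masks=masks, lesions=lesion_records)


def evolve_followup(gt: GroundTruth, cfg: PhantomConfig, subject_seed: int) -> GroundTruth:
    """Apply each lesion's change plan and ventricular atrophy; fill follow-up.

    Change semantics: *grow* adds the planned extra volume around the
    footprint; *disappear* removes the lesion, replacing it with CSF
    (ex-vacuo tissue loss) or NAWM (true regression) per the plan; *intensify*
    turns a subtle footprint intense without growth; *new* makes a planned
    lesion appear only at follow-up; *static* copies baseline.  The ventricles
    dilate by ``atrophy_rate`` in-plane voxels and override lesion voxels
    they reach.  True increased/disappeared/unchanged volumes are recorded
    from the final masks.
    """
    b = gt.masks["baseline"]
    icv = b["icv"].data
    vent_b = b["ventricles"].data
    parenchyma_like = icv & ~b["csf"].data

    vent_f = _inplane_dilate(vent_b, cfg.atrophy_rate) & _inplane_erode(icv, 1)
    csf_gap = _inplane_dilate(b["csf"].data | vent_f, 1)
    subtle_f = np.zeros_like(icv)
    intense_f = np.zeros_like(icv)
    ex_vacuo = np.zeros_like(icv)

    occupied = np.zeros_like(icv)
    for rec in gt.lesions:
        occupied |= rec["core_planned"] | rec["halo_planned"]
    occupied |= b["stroke"].data

    for rec in gt.lesions:
        spec: LesionSpec = rec["spec"]
        core_b, halo_b = rec["core_baseline"], rec["halo_baseline"]
        core_p, halo_p = rec["core_planned"], rec["halo_planned"]
        if spec.change == "static":
            core_f, halo_f = core_b, halo_b
        elif spec.change == "new":
            core_f, halo_f = core_p, halo_p
        elif spec.change == "grow":
            n_extra = _ml_to_voxels(spec.grow_ml, cfg.voxel_dims)
            candidates = parenchyma_like & ~occupied & ~csf_gap
            grown = _grow_nearest(core_b | halo_b, candidates, n_extra, cfg.voxel_dims)
            occupied |= grown
            if spec.tissue == "intense":
                # new voxels join the intense core; the halo stays subtle
                core_f = grown & ~halo_b
                halo_f = halo_b
            else:
                core_f = grown
                halo_f = halo_b
        elif spec.change == "disappear":
            core_f = np.zeros_like(core_b)
            halo_f = np.zeros_like(halo_b)
            if spec.ex_vacuo:
                ex_vacuo |= core_b | halo_b
        elif spec.change == "intensify":
            # subtle tissue becomes intense on the identical footprint
            core_f = core_b | halo_b
            halo_f = np.zeros_like(halo_b)
        else:
            raise ValueError(f"unknown change type {spec.change}")
        rec["core_followup"] = core_f
        rec["halo_followup"] = halo_f
        if spec.tissue == "subtle" and spec.change != "intensify":
            subtle_f |= core_f
        else:
            intense_f |= core_f
        subtle_f |= halo_f

    subtle_f &= ~vent_f
    intense_f &= ~vent_f
    ex_vacuo &= ~vent_f
    subtle_f &= ~intense_f
    stroke_f = b["stroke"].data & ~vent_f

    csf_f = (b["csf"].data | vent_f | ex_vacuo) & ~subtle_f & ~intense_f & ~stroke_f

    vd = cfg.voxel_dims

    def _mask(data, label):
        return BinaryMask(data=data, voxel_dims=vd, label=label)

    gt.masks["followup"] = {
        "icv": _mask(icv, "ICV"),
        "csf": _mask(csf_f, "normal_tissue"),
        "ventricles": _mask(vent_f, "normal_tissue"),
        "subtle": _mask(subtle_f, "WMH"),
        "intense": _mask(intense_f, "WMH"),
        "stroke": _mask(stroke_f, "stroke"),
    }

    wmh_b = gt.wmh_mask("baseline")
    wmh_f = gt.wmh_mask("followup")
    increased = wmh_b.copy_with(wmh_f.data & ~wmh_b.data, label="change")
    disappeared = wmh_b.copy_with(wmh_b.data & ~wmh_f.data, label="change")
    unchanged = wmh_b.copy_with(wmh_b.data & wmh_f.data, label="change")
    gt.change_volumes_ml = {
        "baseline": volume_ml(wmh_b),
        "followup": volume_ml(wmh_f),
        "increased": volume_ml(increased),
        "disappeared": volume_ml(disappeared),
        "unchanged": volume_ml(unchanged),
        "net": volume_ml(wmh_f) - volume_ml(wmh_b),
    }
    return gt


# ---------------------------------------------------------------------------
# rendering


def _label_volume(gt: GroundTruth, timepoint: str) -> np.ndarray:
    m = gt.masks[timepoint]
    labels = np.zeros(m["icv"].shape, dtype=np.int8)
    labels[m["icv"].data] = 2
    labels[m["csf"].data] = 1
    labels[m["ventricles"].data] = 1
    labels[m["subtle"].data] = 3
    labels[m["intense"].data] = 4
    labels[m["stroke"].data] = 5
    return labels


def render_modalities(gt: GroundTruth, cfg: PhantomConfig) -> Dict[Tuple[str, str], ImageVolume]:
    """Render noiseless, bias-free volumes for every modality and time point.

    Tissue classes map to constant means per modality; a one-voxel in-plane
    partial-volume shell at tissue boundaries inside the ICV takes the local
    3x3 in-plane average of the piecewise-constant image.
    """
    out = {}
    for timepoint in gt.masks:
        labels = _label_volume(gt, timepoint)
        icv = gt.masks[timepoint]["icv"].data
        for modality, means in cfg.tissue_means.items():
            for t in ("csf", "nawm", "subtle", "intense", "stroke"):
                if t not in means:
                    raise ValueError(f"missing tissue mean {t} for {modality}")
            lut = np.array(
                [0.0, means["csf"], means["nawm"], means["subtle"], means["intense"], means["stroke"]]
            )
            img = lut[labels]
            # one-voxel partial-volume shells: a boundary voxel takes the
            # mean of the tissue means present in its in-plane 3x3
            # neighbourhood, so shells are discrete intermediate classes.
            # On a discrete grid the blend has to live on one side of the
            # boundary; it is rendered on the higher-tissue-class side (the
            # same anatomical side in every modality), so each structure's
            # ground-truth mask includes its own blurred edge.
            present_sum = np.zeros_like(img)
            present_cnt = np.zeros_like(img)
            for lab in range(6):
                here = ndimage.maximum_filter((labels == lab).astype(np.int8), size=(3, 3, 1)) > 0
                present_sum += here * lut[lab]
                present_cnt += here
            mx = ndimage.maximum_filter(labels, size=(3, 3, 1))
            mn = ndimage.minimum_filter(labels, size=(3, 3, 1))
            boundary = (mx != mn) & (labels == mx) & icv
            img = np.where(boundary, present_sum / np.maximum(present_cnt, 1), img)
            out[(modality, timepoint)] = ImageVolume(
                data=img, voxel_dims=cfg.voxel_dims, modality=modality, timepoint=timepoint
            )
    return out


def make_bias_field(
    shape,
    voxel_dims,
    amplitude: float,
    seed: int,
    icv: Optional[np.ndarray] = None,
    slice_hat: float = 0.3,
) -> BiasFieldMap:
    """Smooth multiplicative field: 2-4 broad 3-D Gaussians plus an optional
    through-slice quadratic (the residual "top/bottom hat" slice effect).

    The field is mean-centred over the ICV (or the whole grid) and scaled so
    max deviation equals ``amplitude``; hence field values lie in
    [1 - a, 1 + a] with mean 1 over the centring region.
    """
    rng = np.random.default_rng(seed)
    nx, ny, nz = shape
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    g = np.zeros(shape, dtype=np.float64)
    for _ in range(int(rng.integers(2, 5))):
        cx = rng.uniform(0.2, 0.8) * nx
        cy = rng.uniform(0.2, 0.8) * ny
        cz = rng.uniform(0.2, 0.8) * nz
        sx = rng.uniform(0.3, 0.6) * nx
        sy = rng.uniform(0.3, 0.6) * ny
        sz = rng.uniform(0.5, 1.0) * nz
        sign = rng.choice([-1.0, 1.0])
        g += sign * np.exp(
            -(((x - cx) / sx) ** 2 + ((y - cy) / sy) ** 2 + ((z - cz) / sz) ** 2) / 2.0
        )
    if slice_hat > 0:
        zz = 2.0 * z / max(nz - 1, 1) - 1.0
        g += slice_hat * (zz**2)
    region = icv if icv is not None else np.ones(shape, dtype=bool)
    g = g - g[region].mean()
    peak = np.abs(g[region]).max()
    if peak > 0 and amplitude > 0:
        g = np.clip(g / peak, -1.0, 1.0) * amplitude
    else:
        g = np.zeros_like(g)
    field = 1.0 + g
    return BiasFieldMap(
        data=field, voxel_dims=voxel_dims, method="true", params={"amplitude": amplitude}
    )


def apply_bias_field(
    vol: ImageVolume,
    cfg: PhantomConfig,
    seed: int,
    icv: Optional[np.ndarray] = None,
) -> Tuple[ImageVolume, BiasFieldMap]:
    """Multiply a volume by a freshly drawn smooth bias field."""
    fld = make_bias_field(
        vol.shape, vol.voxel_dims, cfg.bias_amplitude, seed, icv=icv, slice_hat=cfg.bias_slice_hat
    )
    return vol.copy_with(vol.data * fld.data), fld


def add_noise(
    vol: ImageVolume, sigma_fraction: float, seed: int, reference_mean: Optional[float] = None
) -> ImageVolume:
    """Add Rician noise: sqrt((I + n1)^2 + n2^2), n1, n2 ~ N(0, sd).

    ``sd = sigma_fraction x reference_mean`` where the reference is the NAWM
    mean intensity (defaults to the mean of the positive voxels).
    """
    if sigma_fraction < 0:
        raise ValueError("sigma_fraction must be >= 0")
    if sigma_fraction == 0:
        return vol.copy_with(vol.data.copy())
    if reference_mean is None:
        pos = vol.data[vol.data > 0]
        reference_mean = float(pos.mean()) if len(pos) else 1.0
    sd = sigma_fraction * reference_mean
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sd, size=vol.shape)
    n2 = rng.normal(0.0, sd, size=vol.shape)
    noisy = np.sqrt((vol.data + n1) ** 2 + n2**2)
    return vol.copy_with(noisy)


# ---------------------------------------------------------------------------
# cohort


def generate_subject(cfg: PhantomConfig, subject_id: str, subject_seed: int) -> LongitudinalSubject:
    """Generate one aligned two-time-point subject with ground truth."""
    template = make_brain_template(cfg, subject_seed)
    gt = plant_lesions(template, cfg, subject_seed)
    gt = evolve_followup(gt, cfg, subject_seed + 2)
    clean = render_modalities(gt, cfg)

    images = {}
    ss = np.random.SeedSequence(entropy=subject_seed + 3)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * len(clean))]
    i = 0
    for (modality, timepoint), vol in clean.items():
        icv = gt.masks[timepoint]["icv"].data
        biased, fld = apply_bias_field(vol, cfg, child_seeds[i], icv=icv)
        gt.true_bias[(modality, timepoint)] = fld
        nawm_mean = cfg.tissue_means[modality]["nawm"]
        noisy = add_noise(biased, cfg.noise_sigma, child_seeds[i + 1], reference_mean=nawm_mean)
        images[(modality, timepoint)] = noisy
        i += 2

    return LongitudinalSubject(
        subject_id=subject_id,
        images=images,
        icv_mask={tp: gt.masks[tp]["icv"] for tp in gt.masks},
        stroke_mask={tp: gt.masks[tp]["stroke"] for tp in gt.masks},
        ground_truth={"gt": gt},
    )


def generate_cohort(cfg: PhantomConfig):
    """Generate the full cohort plus the ground-truth bookkeeping table.

    Returns ``(subjects, table)`` where the table has one row per subject
    with the true WMH volumes (ml) at both time points and the true
    increased/disappeared/unchanged/net change volumes.
    """
    master = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in master.spawn(cfg.n_subjects)]
    subjects = []
    rows = []
    for i, seed in enumerate(seeds):
        sid = f"subj{i:03d}"
        subj = generate_subject(cfg, sid, seed)
        gt: GroundTruth = subj.ground_truth["gt"]
        row = {"subject_id": sid}
        row.update({f"true_{k}_ml": v for k, v in gt.change_volumes_ml.items()})
        row["n_lesions"] = len(gt.lesions)
        row["change_types"] = "+".join(sorted({r["spec"].change for r in gt.lesions}))
        rows.append(row)
        subjects.append(subj)
    return subjects, pd.DataFrame(rows)
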