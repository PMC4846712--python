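"""The two longitudinal WMH-change measurements and their decomposition.

Method 1 — *independent multispectral thresholding*: WMH are segmented
separately at each time point by 5-level minimum-variance quantisation of
the FLAIR inside the ICV (levels 4-5 are candidate WMH), with a T2*-weighted
CSF-flow veto, stroke removal, and rule-based cleanup standing in for the
manual editing of clinical protocols.  Change is the voxelwise decomposition
of the two masks into increased / disappeared / unchanged.

Method 2 — *gamma-corrected FLAIR subtraction*: both FLAIR volumes are
linearly intensity-normalised (parenchyma mode -> 0.5, 99.5th ICV percentile
-> 1.0), gamma-corrected so the parenchyma mode sits exactly at 0.5, and
subtracted; voxels whose difference exceeds z standard deviations of the
normal-tissue difference count as change.  Because a subtle lesion that
merely intensifies produces a large FLAIR difference over its whole
footprint, this method counts intensification as volumetric increase — the
inflation mechanism the pipeline is designed to expose.

Stroke masks are always derived from the *original* (uncorrected) images:
every bias correction attenuates large hyperintense lesions and would
shrink the stroke delineation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .core import BinaryMask, ImageVolume, percent_icv, volume_ml
from .quantise import QuantisedVolume, level_masks, minimum_variance_quantise

logger = logging.getLogger(__name__)

DEFAULT_MIN_COMPONENT_VOXELS = 5
DEFAULT_Z_THRESHOLD = 2.0
DEFAULT_EDGE_EROSION = 2  # in-plane voxels: artefact belt near fissures/skull
#: a quantisation level counts as WMH only if its centroid exceeds the
#: parenchyma centroid by this relative contrast (hyperintensity criterion)
DEFAULT_MIN_CONTRAST = 0.2

_INPLANE_STRUCT = np.zeros((3, 3, 3), dtype=bool)
_INPLANE_STRUCT[:, :, 1] = [[0, 1, 0], [1, 1, 1], [0, 1, 0]]


@dataclass
class WmhSegmentation:
    mask: BinaryMask
    timepoint: str
    method: str  # multispectral | subtraction
    volume_ml: float
    volume_pct_icv: float
    provenance: dict = field(default_factory=dict)


@dataclass
class ChangeDecomposition:
    """Voxelwise increased/disappeared/unchanged WMH with volume bookkeeping."""

    increased_mask: BinaryMask
    disappeared_mask: BinaryMask
    unchanged_mask: BinaryMask
    increased_ml: float
    disappeared_ml: float
    unchanged_ml: float
    baseline_ml: float
    followup_ml: float
    net_change_ml: float
    increased_pct_icv: float = 0.0
    disappeared_pct_icv: float = 0.0
    unchanged_pct_icv: float = 0.0


@dataclass
class SubtractionResult:
    normalised_baseline: ImageVolume
    normalised_followup: ImageVolume
    gamma_baseline: float
    gamma_followup: float
    difference: np.ndarray
    increase_mask: BinaryMask
    decrease_mask: BinaryMask
    change_volume_ml: float  # increase only: the quantity this method reports
    decrease_volume_ml: float  # separate: conflates atrophy with WMH regression
    threshold: float


# ---------------------------------------------------------------------------
# method 1: independent multispectral thresholding


def _cleanup_components(
    mask: np.ndarray,
    icv: np.ndarray,
    min_size: int,
    edge_erosion: int,
) -> np.ndarray:
    """Drop small components and components centred in the artefact belt.

    Stands in for the manual editing step of clinical protocols: flow and
    pulsation artefacts concentrate near the brain edge (Sylvian fissures,
    insular cortex), so components whose centroid falls outside an in-plane
    erosion of the ICV are discarded, as are components below ``min_size``
    voxels.
    """
    if edge_erosion > 0:
        interior = ndimage.binary_erosion(icv, structure=_INPLANE_STRUCT, iterations=edge_erosion)
    else:
        interior = icv
    labelled, n = ndimage.label(mask, structure=_INPLANE_STRUCT)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(mask, labelled, index=np.arange(1, n + 1))
    centroids = ndimage.center_of_mass(mask, labelled, index=np.arange(1, n + 1))
    keep = np.zeros(n + 1, dtype=bool)
    for comp in range(1, n + 1):
        if sizes[comp - 1] < min_size:
            continue
        cx, cy, cz = (int(round(c)) for c in centroids[comp - 1])
        cx = np.clip(cx, 0, icv.shape[0] - 1)
        cy = np.clip(cy, 0, icv.shape[1] - 1)
        cz = np.clip(cz, 0, icv.shape[2] - 1)
        if interior[cx, cy, cz]:
            keep[comp] = True
    return keep[labelled]


def segment_wmh_multispectral(
    flair: ImageVolume,
    t2sw: Optional[ImageVolume],
    icv: BinaryMask,
    stroke: Optional[BinaryMask] = None,
    k: int = 5,
    min_size: int = DEFAULT_MIN_COMPONENT_VOXELS,
    edge_erosion: int = DEFAULT_EDGE_EROSION,
    min_contrast: float = DEFAULT_MIN_CONTRAST,
    q_flair: Optional[QuantisedVolume] = None,
) -> WmhSegmentation:
    """Segment WMH at one time point by multispectral thresholding.

    Candidate voxels are the hyperintense FLAIR quantisation levels inside
    the ICV: levels whose centroid exceeds the parenchyma (modal-level)
    centroid by at least ``min_contrast`` — levels {4, 5} whenever the five
    levels map cleanly onto the canonical tissue classes, and a guard
    against counting a split parenchyma peak as WMH otherwise.  A T2*W veto
    then removes CSF-flow artefacts: candidates that are bright on T2*W
    while only moderately bright on FLAIR (below the boundary under the top
    candidate level) are discarded.  The stroke lesion is removed, then
    small/edge components are cleaned up.
    """
    q = q_flair if q_flair is not None else minimum_variance_quantise(flair, icv, k=k)
    counts = np.bincount(q.labels[q.labels > 0], minlength=k + 1)[1:]
    parenchyma_level = int(np.argmax(counts)) + 1
    par_c = q.centroids[parenchyma_level - 1]
    contrast_thr = par_c * (1.0 + min_contrast)
    candidate_levels = [
        lv for lv in range(1, k + 1) if q.centroids[lv - 1] >= contrast_thr
    ]
    if candidate_levels:
        lowest = candidate_levels[0]
        # boundary below the lowest hyperintense level (the level-3/4
        # boundary in the canonical case), guarded by the contrast
        # criterion so a split parenchyma peak never passes
        level_thr = q.boundaries[lowest - 2] if lowest >= 2 else contrast_thr
        threshold = min(level_thr, contrast_thr)
    else:
        threshold = contrast_thr
    candidate = (flair.data > threshold) & icv.data

    if t2sw is not None and candidate.any():
        q_t2 = minimum_variance_quantise(t2sw, icv, k=k)
        t2_counts = np.bincount(q_t2.labels[q_t2.labels > 0], minlength=k + 1)[1:]
        t2_par = q_t2.centroids[int(np.argmax(t2_counts))]
        t2_bright = t2sw.data > t2_par * (1.0 + min_contrast)
        if candidate_levels:
            top = candidate_levels[-1]
            intense_boundary = q.boundaries[top - 2] if top >= 2 else contrast_thr
        else:
            intense_boundary = contrast_thr
        flair_moderate = flair.data < intense_boundary
        candidate &= ~(t2_bright & flair_moderate)
    elif t2sw is None:
        logger.warning("no T2*W volume: falling back to FLAIR-only segmentation")

    if stroke is not None:
        candidate &= ~stroke.data

    cleaned = _cleanup_components(candidate, icv.data, min_size, edge_erosion)

    # boundary completion: lesion edges are partial-volume voxels whose
    # intensity sits between parenchyma and the detection threshold; grow
    # each detected component into adjacent voxels that are still clearly
    # brighter than parenchyma (midway to the threshold)
    grow_thr = (par_c + threshold) / 2.0
    for _ in range(2):
        ring = (
            ndimage.binary_dilation(cleaned, structure=_INPLANE_STRUCT)
            & icv.data
            & (flair.data > grow_thr)
            & ~cleaned
        )
        if stroke is not None:
            ring &= ~stroke.data
        if not ring.any():
            break
        cleaned = cleaned | ring

    mask = BinaryMask(data=cleaned, voxel_dims=flair.voxel_dims, label="WMH")
    return WmhSegmentation(
        mask=mask,
        timepoint=flair.timepoint,
        method="multispectral",
        volume_ml=volume_ml(mask),
        volume_pct_icv=percent_icv(mask, icv),
        provenance={"k": k, "min_size": min_size, "edge_erosion": edge_erosion,
                    "min_contrast": min_contrast,
                    "candidate_levels": candidate_levels,
                    "threshold": float(threshold),
                    "boundaries": q.boundaries.tolist()},
    )


def wmh_volume_change_independent(
    seg_baseline: WmhSegmentation,
    seg_followup: WmhSegmentation,
    icv: Optional[BinaryMask] = None,
) -> ChangeDecomposition:
    """Voxelwise decomposition of two independent segmentations.

    increased = follow-up minus baseline, disappeared = baseline minus
    follow-up, unchanged = intersection; net change = increased −
    disappeared = follow-up volume − baseline volume.
    """
    b, f = seg_baseline.mask, seg_followup.mask
    if b.shape != f.shape:
        raise ValueError("segmentations on different grids")
    increased = b.copy_with(f.data & ~b.data, label="change")
    disappeared = b.copy_with(b.data & ~f.data, label="change")
    unchanged = b.copy_with(b.data & f.data, label="change")
    dec = ChangeDecomposition(
        increased_mask=increased,
        disappeared_mask=disappeared,
        unchanged_mask=unchanged,
        increased_ml=volume_ml(increased),
        disappeared_ml=volume_ml(disappeared),
        unchanged_ml=volume_ml(unchanged),
        baseline_ml=volume_ml(b),
        followup_ml=volume_ml(f),
        net_change_ml=volume_ml(f) - volume_ml(b),
    )
    if icv is not None:
        dec.increased_pct_icv = percent_icv(increased, icv)
        dec.disappeared_pct_icv = percent_icv(disappeared, icv)
        dec.unchanged_pct_icv = percent_icv(unchanged, icv)
    return dec


# ---------------------------------------------------------------------------
# method 2: gamma-corrected FLAIR subtraction


def _parenchyma_mode(values: np.ndarray, bins: int = 200) -> float:
    """Histogram mode of the ICV intensities between the 25th and 99th
    percentile (the parenchyma peak dominates this range; CSF occupies well
    under a quarter of the ICV).

    Quantile-anchored binning makes the estimate equivariant under affine
    intensity maps — including maps followed by clipping at the extremes —
    which is what makes the normalisation idempotent.
    """
    lo, hi = np.percentile(values, [25.0, 99.0])
    if hi <= lo:
        raise ValueError("degenerate intensity histogram")
    hist, edges = np.histogram(values[(values >= lo) & (values <= hi)], bins=bins)
    peak = int(np.argmax(hist))
    return float((edges[peak] + edges[peak + 1]) / 2.0)


def normalise_intensities(
    flair_b: ImageVolume, flair_f: ImageVolume, icv: BinaryMask
) -> Tuple[ImageVolume, ImageVolume]:
    """Linearly rescale both FLAIR volumes to a shared intensity frame.

    Landmarks: the CSF anchor (2nd ICV percentile) maps to 0.1 and the
    parenchyma histogram mode to 0.5; output is clipped to [0, 1.2].  Both
    landmarks sit in tissue whose volume is stable across time points —
    anchoring the bright end instead (e.g. a high percentile) couples the
    scale to the lesion load, which is exactly what changes between scans.
    Applying the map twice is the identity (the landmarks are
    affine-equivariant and unaffected by the clipping).
    """
    if not icv.data.any():
        raise ValueError("empty ICV")
    out = []
    for vol in (flair_b, flair_f):
        vals = vol.data[icv.data]
        mode = _parenchyma_mode(vals)
        p_csf = float(np.percentile(vals, 2.0))
        if mode <= p_csf:
            raise ValueError("degenerate histogram: parenchyma mode <= CSF anchor")
        scale = 0.4 / (mode - p_csf)
        mapped = 0.5 + (vol.data - mode) * scale
        mapped = np.clip(mapped, 0.0, 1.2)
        out.append(vol.copy_with(mapped))
    return tuple(out)


def solve_gamma(mode: float, target: float = 0.5) -> float:
    """Gamma such that mode**gamma == target."""
    if not (0.0 < mode < 1.0):
        raise ValueError(f"parenchyma mode must be in (0, 1) to solve for gamma, got {mode}")
    return float(np.log(target) / np.log(mode))


def gamma_correct(
    vol: ImageVolume, gamma: Optional[float] = None, icv: Optional[BinaryMask] = None
) -> Tuple[ImageVolume, float]:
    """Apply the power law v**gamma voxelwise.

    With ``gamma=None`` the exponent is solved so that the parenchyma mode
    maps to 0.5 (requires ``icv``); values above 1 pass through the power
    law too.
    """
    if gamma is None:
        if icv is None:
            raise ValueError("need an ICV mask to solve for gamma")
        mode = _parenchyma_mode(vol.data[icv.data])
        gamma = solve_gamma(mode)
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    return vol.copy_with(np.power(np.clip(vol.data, 0.0, None), gamma)), float(gamma)


def subtract_flair(
    norm_b: ImageVolume,
    norm_f: ImageVolume,
    icv: BinaryMask,
    stroke: Optional[BinaryMask] = None,
    normal_mask: Optional[BinaryMask] = None,
    z: float = DEFAULT_Z_THRESHOLD,
    min_size: int = DEFAULT_MIN_COMPONENT_VOXELS,
    gamma_b: float = 1.0,
    gamma_f: float = 1.0,
) -> SubtractionResult:
    """Subtract normalised+gamma-corrected FLAIR volumes and threshold.

    D = follow-up − baseline inside ICV minus stroke; increase is D > t,
    decrease is D < −t with t = z x SD of D over normal tissue (the whole
    analysis region when no normal-tissue mask is given).  Components below
    ``min_size`` voxels are dropped.  The reported change volume counts the
    increase mask only; the decrease volume is reported separately because
    it conflates atrophic tissue loss with true WMH regression.
    """
    region = icv.data.copy()
    if stroke is not None:
        region &= ~stroke.data
    diff = np.zeros(norm_b.shape, dtype=np.float64)
    diff[region] = norm_f.data[region] - norm_b.data[region]
    ref = normal_mask.data & region if normal_mask is not None else region
    sd = float(diff[ref].std())
    t = z * sd
    inc = (diff > t) & region
    dec = (diff < -t) & region
    inc = _cleanup_components(inc, icv.data, min_size, 0)
    dec = _cleanup_components(dec, icv.data, min_size, 0)
    inc_mask = BinaryMask(data=inc, voxel_dims=norm_b.voxel_dims, label="change")
    dec_mask = BinaryMask(data=dec, voxel_dims=norm_b.voxel_dims, label="change")
    return SubtractionResult(
        normalised_baseline=norm_b,
        normalised_followup=norm_f,
        gamma_baseline=gamma_b,
        gamma_followup=gamma_f,
        difference=diff,
        increase_mask=inc_mask,
        decrease_mask=dec_mask,
        change_volume_ml=volume_ml(inc_mask),
        decrease_volume_ml=volume_ml(dec_mask),
        threshold=t,
    )


def subtraction_change(
    flair_b: ImageVolume,
    flair_f: ImageVolume,
    icv: BinaryMask,
    stroke: Optional[BinaryMask] = None,
    normal_mask: Optional[BinaryMask] = None,
    z: float = DEFAULT_Z_THRESHOLD,
    min_size: int = DEFAULT_MIN_COMPONENT_VOXELS,
) -> SubtractionResult:
    """Full subtraction pipeline: normalise, gamma-correct, subtract."""
    nb, nf = normalise_intensities(flair_b, flair_f, icv)
    gb, gamma_b = gamma_correct(nb, icv=icv)
    gf, gamma_f = gamma_correct(nf, icv=icv)
    return subtract_flair(
        gb, gf, icv, stroke=stroke, normal_mask=normal_mask, z=z, min_size=min_size,
        gamma_b=gamma_b, gamma_f=gamma_f,
    )
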