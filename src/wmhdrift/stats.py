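"""Statistical layer: agreement, paired tests, robust correlations,
multivariate normality, and simulated visual ratings.

The simulated Fazekas (cross-sectional severity, 0-3) and Prins (regional
change, -1/0/+1 per region) ratings are deterministic rules applied to the
phantom ground truth; on phantoms the "brain regions" are geometric sectors,
not anatomy, and every output that contains them says so.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

logger = logging.getLogger(__name__)

#: MAD-based outlier factor for the "after outliers' removal" correlation rows
MAD_OUTLIER_FACTOR = 2.24


# ---------------------------------------------------------------------------
# Bland-Altman


@dataclass
class BlandAltman:
    mean_difference: float
    sd_difference: float
    loa_low: float
    loa_high: float
    n: int
    units: str = ""


def bland_altman(x, y, units: str = "") -> BlandAltman:
    """Limits-of-agreement analysis of paired measurements.

    Differences d = y − x; mean difference, sample SD (n−1 denominator) and
    the 95% limits of agreement md ± 1.96 sd.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = y - x
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(
        mean_difference=md,
        sd_difference=sd,
        loa_low=md - 1.96 * sd,
        loa_high=md + 1.96 * sd,
        n=n,
        units=units,
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank (exact, tie-aware)

EXACT_N_MAX = 25


def wilcoxon_signed_rank(a, b, alternative: str = "two-sided") -> Tuple[float, float]:
    """Related-samples Wilcoxon signed-rank test.

    Zero differences are discarded (Wilcoxon's original rule — note that
    Pratt's rule would change p); ties get mid-ranks.  For n <= 25 the null
    distribution of the positive-rank sum is enumerated exactly by dynamic
    programming over all 2^n sign assignments; beyond that a normal
    approximation with tie and continuity corrections is used.

    Returns ``(W_plus, p)`` where ``W_plus`` is the positive-rank sum.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        logger.warning("all paired differences are zero: p = 1")
        return 0.0, 1.0
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= EXACT_N_MAX:
        # DP over the generating polynomial prod(1 + x^(2 r_i)); mid-ranks
        # are half-integers so doubling makes every exponent integral.
        s = np.round(2 * ranks).astype(int)
        total = int(s.sum())
        counts = np.zeros(total + 1, dtype=float)
        counts[0] = 1.0
        for si in s:
            counts[si:] += counts[:-si].copy()
        counts /= counts.sum()
        t_obs = int(round(2 * w_plus))
        p_ge = float(counts[t_obs:].sum())
        p_le = float(counts[: t_obs + 1].sum())
    else:
        mean = n * (n + 1) / 4.0
        tie_counts = np.unique(ranks, return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
        sd = np.sqrt(var)
        p_ge = float(sps.norm.sf((w_plus - 0.5 - mean) / sd))
        p_le = float(sps.norm.cdf((w_plus + 0.5 - mean) / sd))

    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    elif alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_ge, p_le))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return w_plus, p


# ---------------------------------------------------------------------------
# robust bootstrap correlations


@dataclass
class CorrelationResult:
    coefficient: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    method: str
    outliers_removed: bool = False


def _mad_outliers(x: np.ndarray, y: np.ndarray, factor: float = MAD_OUTLIER_FACTOR):
    """Bivariate boxplot-style rule: flag points far from the median in
    either coordinate, distance in robust (MAD) units."""

    def flags(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med)) * 1.4826
        if mad == 0:
            return np.zeros(len(v), dtype=bool)
        return np.abs(v - med) / mad > factor

    return flags(x) | flags(y)


def _bootstrap_corr(x, y, stat, B, seed):
    rng = np.random.default_rng(seed)
    n = len(x)
    vals = np.empty(B)
    for i in range(B):
        idx = rng.integers(0, n, size=n)
        vals[i] = stat(x[idx], y[idx])
    vals = vals[np.isfinite(vals)]
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


def _corr_with_ci(x, y, method: str, B: int, seed, remove_outliers: bool):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if remove_outliers:
        bad = _mad_outliers(x, y)
        x, y = x[~bad], y[~bad]
    if len(x) < 5:
        raise ValueError("need at least 5 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    if method == "spearman":
        stat = lambda a, b: sps.spearmanr(a, b).statistic
        r, p = sps.spearmanr(x, y)
    else:
        stat = lambda a, b: sps.pearsonr(a, b).statistic
        r, p = sps.pearsonr(x, y)
    lo, hi = _bootstrap_corr(x, y, stat, B, seed)
    return CorrelationResult(
        coefficient=float(r),
        ci_low=lo,
        ci_high=hi,
        p_value=float(p),
        n=len(x),
        method=method,
        outliers_removed=remove_outliers,
    )


def spearman_bootstrap_ci(x, y, B: int = 1000, seed: int = 0, remove_outliers: bool = False):
    """Spearman rho with a percentile-bootstrap 95% CI."""
    return _corr_with_ci(x, y, "spearman", B, seed, remove_outliers)


def pearson_ci(x, y, B: int = 1000, seed: int = 0, remove_outliers: bool = False):
    """Pearson r with a percentile-bootstrap 95% CI.

    Skewed inputs (e.g. WMH volumes) should be rescaled/log-transformed
    upstream before calling this.
    """
    return _corr_with_ci(x, y, "pearson", B, seed, remove_outliers)


def henze_zirkler(sample) -> Tuple[float, float]:
    """Henze-Zirkler multivariate normality test.

    Returns ``(HZ statistic, p)``; p comes from the log-normal approximation
    of the null distribution with the standard smoothing parameter
    beta(n, d).
    """
    X = np.asarray(sample, dtype=float)
    if X.ndim != 2:
        raise ValueError("sample must be a 2-D (n x d) array")
    n, d = X.shape
    if n <= d:
        raise ValueError("need more observations than dimensions")
    cov = np.cov(X, rowvar=False)
    if np.linalg.matrix_rank(np.atleast_2d(cov)) < d:
        raise ValueError("singular covariance")
    import pingouin

    res = pingouin.multivariate_normality(X)
    return float(res.hz), float(res.pval)


# ---------------------------------------------------------------------------
# simulated visual ratings

_INPLANE_STRUCT = np.zeros((3, 3, 3), dtype=bool)
_INPLANE_STRUCT[:, :, 1] = [[0, 1, 0], [1, 1, 1], [0, 1, 0]]

#: periventricular cap-thickness thresholds (in-plane voxels) for scores 1/2/3
FAZEKAS_PV_THICKNESS = (3, 6)
#: deep-lesion equivalent-diameter thresholds (in-plane voxels) for 1/2/3
FAZEKAS_DEEP_DIAMETER = (4, 8)
PRINS_TAU_ML = 0.25


@dataclass
class RatingRecord:
    subject_id: str
    fazekas_pv: int
    fazekas_deep: int
    prins_region_scores: Dict[str, int] = field(default_factory=dict)
    prins_total: int = 0


def _pv_distance(gt, timepoint):
    vent = gt.masks[timepoint]["ventricles"].data
    if not vent.any():
        return None
    return ndimage.distance_transform_edt(~vent, sampling=(1, 1, 1e6))  # in-plane voxels


def simulate_fazekas(gt, timepoint: str) -> Tuple[int, int]:
    """Deterministic Fazekas-style severity scores from ground truth.

    Periventricular score from the maximum in-plane thickness of WMH caps
    around the ventricles (0 none, 1 thin caps, 2 halo, 3 confluent
    extension); deep score from the largest deep-lesion in-plane equivalent
    diameter (0 none, 1 punctate, 2 early-confluent, 3 confluent).
    """
    wmh = gt.wmh_mask(timepoint).data
    if not wmh.any():
        return 0, 0
    dist = _pv_distance(gt, timepoint)
    t1, t2 = FAZEKAS_PV_THICKNESS
    if dist is None:
        pv_score = 0
        deep = wmh
    else:
        pv_region = dist <= t2 + 1
        pv_wmh = wmh & (dist <= t2)
        if not pv_wmh.any():
            pv_score = 0
        else:
            thickness = dist[wmh & np.isfinite(dist)].max() if wmh.any() else 0
            pv_thickness = dist[pv_wmh].max()
            confluent = bool((wmh & (dist > t2)).any() and pv_wmh.any() and thickness > t2)
            if confluent and pv_thickness >= t2:
                pv_score = 3
            elif pv_thickness > t1:
                pv_score = 2
            else:
                pv_score = 1
        deep = wmh & ~pv_region

    if not deep.any():
        deep_score = 0
    else:
        labelled, ncomp = ndimage.label(deep, structure=_INPLANE_STRUCT)
        sizes = ndimage.sum_labels(deep, labelled, index=np.arange(1, ncomp + 1))
        # equivalent in-plane diameter of the largest component's biggest slice
        largest = int(np.argmax(sizes)) + 1
        comp = labelled == largest
        per_slice = comp.sum(axis=(0, 1)).max()
        diameter = 2.0 * np.sqrt(per_slice / np.pi)
        d1, d2 = FAZEKAS_DEEP_DIAMETER
        if diameter >= d2 or ncomp >= 8:
            deep_score = 3
        elif diameter >= d1 or ncomp >= 4:
            deep_score = 2
        else:
            deep_score = 1
    return pv_score, deep_score


def phantom_region_masks(gt, timepoint: str) -> Dict[str, np.ndarray]:
    """Geometric stand-ins for the rating-scale brain regions.

    The sectors partition the ICV: a periventricular shell, an
    infratentorial band (bottom slices), and anterior / middle / posterior
    sectors of the remaining parenchyma.  They are geometry, not anatomy.
    """
    icv = gt.masks[timepoint]["icv"].data
    dist = _pv_distance(gt, timepoint)
    nz = icv.shape[2]
    ny = icv.shape[1]
    z = np.arange(nz)[None, None, :]
    y = np.arange(ny)[None, :, None]
    pv = (dist <= 3) & icv if dist is not None else np.zeros_like(icv)
    infra = icv & (z < max(2, int(0.15 * nz))) & ~pv
    rest = icv & ~pv & ~infra
    return {
        "periventricular": pv,
        "infratentorial": infra,
        "frontal": rest & (y < 0.4 * ny),
        "temporal": rest & (y >= 0.4 * ny) & (y < 0.6 * ny),
        "parieto-occipital": rest & (y >= 0.6 * ny),
    }


def simulate_prins(gt, subject_id: str = "", tau_ml: float = PRINS_TAU_ML) -> RatingRecord:
    """Prins-style regional change rating from ground truth.

    Per region: +1 if the regional WMH volume increased by at least tau ml,
    −1 if it decreased by at least tau, else 0; the total is the sum over
    regions.
    """
    regions = phantom_region_masks(gt, "baseline")
    vox_ml = float(np.prod(gt.masks["baseline"]["icv"].voxel_dims)) / 1000.0
    wb = gt.wmh_mask("baseline").data
    wf = gt.wmh_mask("followup").data
    scores = {}
    for name, region in regions.items():
        delta = (int((wf & region).sum()) - int((wb & region).sum())) * vox_ml
        scores[name] = 1 if delta >= tau_ml else (-1 if delta <= -tau_ml else 0)
    fz = simulate_fazekas(gt, "baseline")
    return RatingRecord(
        subject_id=subject_id,
        fazekas_pv=fz[0],
        fazekas_deep=fz[1],
        prins_region_scores=scores,
        prins_total=int(sum(scores.values())),
    )


# ---------------------------------------------------------------------------
# report assembly


def build_report(tables: Dict[str, pd.DataFrame], out_dir=None) -> Dict[str, pd.DataFrame]:
    """Validate and (optionally) write the cohort report bundle.

    ``tables`` maps report names to DataFrames (level agreement, ΔVMR
    medians, method comparison, correlations, ratings).  Empty inputs raise
    rather than producing empty files.  When ``out_dir`` is given, each
    table is written as CSV next to an ``index.csv`` listing them.
    """
    if not tables:
        raise ValueError("no tables to report")
    for name, df in tables.items():
        if df is None or len(df) == 0:
            raise ValueError(f"report table {name!r} is empty")
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        index = []
        for name, df in sorted(tables.items()):
            path = out / f"{name}.csv"
            df.to_csv(path, index=False)
            index.append({"table": name, "rows": len(df), "file": path.name})
        pd.DataFrame(index).to_csv(out / "index.csv", index=False)
    return tables
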