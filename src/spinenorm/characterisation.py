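"""Cord/CSF characterisation of the segmented spinal canal.

ADC values inside the canal are bimodal: the spinal cord sits near
1.7e-3 mm^2/s and the surrounding cerebrospinal fluid near 3.2e-3 mm^2/s.
A two-component Gaussian mixture fitted per study separates the tissues;
hard posterior assignment splits the canal mask into cord and CSF, and
simple shape statistics (volume, mean per-slice cross-section) plus overlap
metrics (Dice, precision, recall) quantify segmentation quality.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from sklearn.mixture import GaussianMixture

from .types import GMMResult, ShapeStats, SubSegmentation

__all__ = [
    "fit_canal_gmm", "split_cord_csf", "shape_stats", "overlap_metrics",
    "component_volumes",
]

log = logging.getLogger(__name__)

MIN_CANAL_VALUES = 50
VARIANCE_FLOOR = 1e-4   # in (1e-3 mm^2/s)^2, used when EM collapses


def fit_canal_gmm(adc_values: np.ndarray, seed: int = 0) -> GMMResult:
    """Fit a 2-component Gaussian mixture to in-canal ADC values.

    ``adc_values`` are in mm^2/s (or already in 1e-3 mm^2/s; anything below
    0.1 in magnitude is assumed to be mm^2/s and rescaled).  EM runs with
    k-means initialisation, 5 restarts, tolerance 1e-6 and at most 500
    iterations; components are ordered by mean so component 1 is cord.
    """
    x = np.asarray(adc_values, dtype=np.float64).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("ADC values must be finite")
    if x.size < MIN_CANAL_VALUES:
        raise ValueError(f"need at least {MIN_CANAL_VALUES} canal ADC values, got {x.size}")
    if np.median(np.abs(x)) < 0.1:        # values still in mm^2/s
        x = x * 1e3
    X = x[:, None]

    def _fit(reg: float) -> GaussianMixture:
        gm = GaussianMixture(n_components=2, covariance_type="full",
                             n_init=5, tol=1e-6, max_iter=500,
                             init_params="kmeans", reg_covar=reg,
                             random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm.fit(X)
        return gm

    gm = _fit(1e-9)
    variances = gm.covariances_.ravel()
    if np.any(variances < VARIANCE_FLOOR):
        log.warning("variance collapse in canal GMM; refitting with variance floor")
        gm = _fit(VARIANCE_FLOOR)
        variances = np.maximum(gm.covariances_.ravel(), VARIANCE_FLOOR)

    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    if means[0] >= means[1]:  # identical means after flooring: split artificially
        means = (means[0] - 1e-9, means[1] + 1e-9)
    return GMMResult(
        weights=tuple(gm.weights_[order]),
        means=tuple(means),
        variances=tuple(variances[order]),
    )


def _log_pdf(x: np.ndarray, mean: float, var: float) -> np.ndarray:
    return -0.5 * (np.log(2 * np.pi * var) + (x - mean) ** 2 / var)


def posterior_cord(adc_1e3: np.ndarray, gmm: GMMResult) -> np.ndarray:
    """Posterior probability of the cord (lower-mean) component, with ADC in
    1e-3 mm^2/s."""
    lw = np.log(gmm.weights)
    a = lw[0] + _log_pdf(adc_1e3, gmm.means[0], gmm.variances[0])
    b = lw[1] + _log_pdf(adc_1e3, gmm.means[1], gmm.variances[1])
    m = np.maximum(a, b)
    return np.exp(a - m) / (np.exp(a - m) + np.exp(b - m))


def split_cord_csf(canal_mask: np.ndarray, adc_map: np.ndarray,
                   gmm: GMMResult) -> SubSegmentation:
    """Assign every canal voxel to cord or CSF by the larger posterior.

    Ties go to cord.  The returned masks partition the canal exactly.
    """
    if canal_mask.shape != adc_map.shape:
        raise ValueError("mask and ADC map must share a grid")
    canal_bool = canal_mask.astype(bool)
    if not canal_bool.any():
        return SubSegmentation(cord_mask=canal_bool.copy(), csf_mask=canal_bool.copy())
    adc = adc_map * 1e3 if np.median(np.abs(adc_map[canal_bool])) < 0.1 else adc_map
    p_cord = posterior_cord(adc, gmm)
    canal = canal_mask.astype(bool)
    cord = canal & (p_cord >= 0.5)
    csf = canal & ~cord
    return SubSegmentation(cord_mask=cord, csf_mask=csf)


def shape_stats(mask: np.ndarray, spacing: tuple[float, float, float]) -> ShapeStats:
    """Volume (mL) and average cross-section area (mm^2) of a binary mask.

    The area averages per-slice areas over slices containing at least one
    mask voxel; an empty mask reports (0, 0) with a warning.
    """
    if min(spacing) <= 0:
        raise ValueError("spacing must be positive")
    m = mask.astype(bool)
    voxel_mm3 = spacing[0] * spacing[1] * spacing[2]
    n = int(m.sum())
    if n == 0:
        log.warning("empty mask: volume and area reported as 0")
        return ShapeStats(volume_ml=0.0, average_cross_section_area_mm2=0.0)
    per_slice = m.reshape(m.shape[0], -1).sum(axis=1)
    areas = per_slice[per_slice > 0] * spacing[1] * spacing[2]
    return ShapeStats(volume_ml=n * voxel_mm3 / 1000.0,
                      average_cross_section_area_mm2=float(areas.mean()))


def overlap_metrics(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float, float]:
    """Patient-wise Dice, precision and recall over the whole 3-D volume.

    Two empty masks count as perfect agreement (all metrics 1).
    """
    if pred.shape != truth.shape:
        raise ValueError("masks must share a grid")
    p = pred.astype(bool)
    t = truth.astype(bool)
    tp = float(np.sum(p & t))
    fp = float(np.sum(p & ~t))
    fn = float(np.sum(~p & t))
    if tp + fp + fn == 0:
        log.info("both masks empty: overlap metrics defined as 1")
        return 1.0, 1.0, 1.0
    dice = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    return dice, precision, recall


def component_volumes(gmm: GMMResult, canal_volume_ml: float) -> tuple[float, float]:
    """Mixture-weight-based cord/CSF volumes (weight x canal volume, mL)."""
    return gmm.weights[0] * canal_volume_ml, gmm.weights[1] * canal_volume_ml
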