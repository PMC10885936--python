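"""Monoexponential diffusion modelling and computed DWI (cDWI) synthesis.

The signal of an axial diffusion-weighted acquisition at diffusion weighting
``b`` is modelled per voxel as ``S(b) = S0 * exp(-b * ADC)``.  Fitting the
model over the acquired b-values yields the apparent diffusion coefficient
(ADC, mm^2/s) and intercept S0; from these a *computed* DWI image at any
b-value can be synthesised, which is the first step of whole-body signal
standardisation.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .types import DWIStudy, NetworkInput, ParametricMaps, StationVolume

__all__ = [
    "fit_monoexponential",
    "compute_cdwi",
    "scale_network_input",
    "ADC_SCALE",
]

log = logging.getLogger(__name__)

#: Fixed ADC normalisation constant for the network input channel, mm^2/s.
ADC_SCALE = 3.5e-3

#: Floor applied to signals before taking logarithms, arbitrary units.
SIGNAL_FLOOR = 1e-3


def fit_monoexponential(station: StationVolume) -> ParametricMaps:
    """Fit ``ln S(b) = ln S0 - b * ADC`` per voxel by ordinary least squares.

    Signals are floored at ``1e-3`` a.u. before the log so zero-signal
    (background) voxels remain defined: an all-zero voxel yields a flat
    floored log-signal, hence ADC = 0 and S0 at the floor.  Negative ADC
    estimates are retained; they are legitimate noise outcomes and removing
    them would imprint artificial boundaries on the map.

    For exactly two b-values the OLS solution coincides with the closed form
    ``ADC = ln(S(b1)/S(b2)) / (b2 - b1)``.
    """
    b = np.asarray(station.b_values, dtype=np.float64)
    if len(np.unique(b)) < 2:
        raise ValueError("monoexponential fit needs at least 2 distinct b-values")

    n_zero = int(np.count_nonzero(np.all(station.signal <= 0, axis=0)))
    if n_zero:
        log.debug("flooring %d all-zero voxels before log-linear fit", n_zero)

    logs = np.log(np.maximum(station.signal, SIGNAL_FLOOR))
    # OLS slope/intercept of log-signal against b, vectorised over voxels.
    bm = b.mean()
    lm = logs.mean(axis=0)
    slope = np.tensordot(b - bm, logs - lm, axes=(0, 0)) / np.sum((b - bm) ** 2)
    adc = -slope
    s0 = np.exp(lm + bm * adc)
    return ParametricMaps(
        adc=adc,
        s0=np.maximum(s0, SIGNAL_FLOOR),
        spacing=station.spacing,
        slice_positions=station.slice_positions,
    )


def compute_cdwi(maps: ParametricMaps, b_c: float) -> np.ndarray:
    """Synthesise the computed DWI image ``S0 * exp(-b_c * ADC)``.

    Negative ADC voxels (pure noise) are clamped to zero for the synthesis
    only -- exponentiating a negative ADC at high b would amplify them above
    S0.  The clamp never touches the stored ADC map.
    """
    if b_c < 0:
        raise ValueError("b_c must be non-negative")
    return maps.s0 * np.exp(-b_c * np.maximum(maps.adc, 0.0))


def _resample_slice(img: np.ndarray, in_mm: tuple[float, float],
                    out_shape: tuple[int, int],
                    out_mm: tuple[float, float]) -> np.ndarray:
    """Bilinear in-plane resample to ``out_mm`` pixels, then centre crop/pad
    with zeros to ``out_shape``."""
    zoom = (in_mm[0] / out_mm[0], in_mm[1] / out_mm[1])
    if zoom != (1.0, 1.0):
        img = ndimage.zoom(img, zoom, order=1, prefilter=False)
    out = np.zeros(out_shape, dtype=img.dtype)
    r, c = img.shape
    # centre-aligned copy of the overlapping region
    r0s, r0d = max(0, (r - out_shape[0]) // 2), max(0, (out_shape[0] - r) // 2)
    c0s, c0d = max(0, (c - out_shape[1]) // 2), max(0, (out_shape[1] - c) // 2)
    nr, nc = min(r, out_shape[0]), min(c, out_shape[1])
    out[r0d:r0d + nr, c0d:c0d + nc] = img[r0s:r0s + nr, c0s:c0s + nc]
    return out


def scale_network_input(maps: ParametricMaps, *, out_matrix: int = 256,
                        out_mm: float = 1.6,
                        log_s0_max: float | None = None) -> NetworkInput:
    """Build the two-channel dimensionless network input from parameter maps.

    Channel 1 is ``ADC / 3.5e-3 mm^2/s`` (negatives preserved); channel 2 is
    ``ln(S0) / max(ln(S0))`` with S0 floored at 1 before the log.  The max is
    taken over the whole study so inter-station contrast survives; when
    scaling several stations of one study, pass the pooled ``log_s0_max``
    (see :func:`study_log_s0_max`).  Both channels are resampled in-plane to
    ``out_matrix`` square pixels of ``out_mm`` mm by bilinear interpolation
    with centred zero padding/cropping.
    """
    scaled_adc = maps.adc / ADC_SCALE
    log_s0 = np.log(np.maximum(maps.s0, 1.0))
    mx = float(np.max(log_s0)) if log_s0_max is None else float(log_s0_max)
    if mx <= 0:
        log.warning("max(log S0) <= 0 (all S0 <= 1); S0 channel set to zeros")
        scaled_s0 = np.zeros_like(log_s0)
    else:
        scaled_s0 = log_s0 / mx

    in_plane = (maps.spacing[1], maps.spacing[2])
    shape = (out_matrix, out_matrix)
    mm = (out_mm, out_mm)
    adc_rs = np.stack([_resample_slice(s, in_plane, shape, mm) for s in scaled_adc])
    s0_rs = np.stack([_resample_slice(s, in_plane, shape, mm) for s in scaled_s0])
    return NetworkInput(
        scaled_adc=adc_rs,
        scaled_s0=s0_rs,
        spacing=(maps.spacing[0], out_mm, out_mm),
        slice_positions=maps.slice_positions,
    )


def study_log_s0_max(maps_per_station: list[ParametricMaps]) -> float:
    """Pooled ``max(ln S0)`` across all stations of a study (S0 floored at 1)."""
    return float(max(np.max(np.log(np.maximum(m.s0, 1.0))) for m in maps_per_station))


def fit_study(study: DWIStudy) -> list[ParametricMaps]:
    """Fit the monoexponential model station by station."""
    return [fit_monoexponential(st) for st in study.stations]
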