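"""Core data containers for whole-body diffusion-weighted MRI (WBDWI) pipelines.

A whole-body acquisition is an ordered stack of anatomical *stations*
(superior to inferior), each an axial multi-b-value volume with its own
receive gain.  The containers here carry the raw signal, the fitted
monoexponential parameter maps (ADC in mm^2/s, S0 in arbitrary units), the
spinal-canal segmentation, the two-component Gaussian-mixture description of
in-canal ADC, and the final harmonised / canal-standardised study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StationVolume",
    "DWIStudy",
    "ParametricMaps",
    "NetworkInput",
    "CanalSegmentation",
    "GMMResult",
    "SubSegmentation",
    "ShapeStats",
    "NormalisedStudy",
    "PipelineConfig",
]


@dataclass
class StationVolume:
    """One anatomical acquisition station.

    Parameters
    ----------
    signal
        4-D intensity array indexed ``(b-index, slice, row, col)``,
        arbitrary units, non-negative.
    b_values
        Diffusion weightings in s/mm^2, one per leading index of ``signal``.
    spacing
        ``(slice thickness, row, col)`` in mm.
    slice_positions
        Slice locations along the patient axis in mm, strictly monotonic,
        increasing superior to inferior.
    """

    signal: np.ndarray
    b_values: tuple[float, ...]
    spacing: tuple[float, float, float]
    slice_positions: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.b_values = tuple(float(b) for b in self.b_values)
        self.slice_positions = np.asarray(self.slice_positions, dtype=np.float64)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4-D (b, slice, row, col)")
        if self.signal.shape[0] != len(self.b_values):
            raise ValueError("leading signal axis must match number of b-values")
        if self.signal.shape[1] != len(self.slice_positions):
            raise ValueError("slice axis must match slice_positions")
        if self.signal.shape[1] < 2:
            raise ValueError("a station needs at least 2 slices")
        if np.any(self.signal < 0):
            raise ValueError("signal must be non-negative")
        d = np.diff(self.slice_positions)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("slice_positions must be strictly monotonic")

    @property
    def n_slices(self) -> int:
        return self.signal.shape[1]

    @property
    def matrix(self) -> tuple[int, int]:
        return self.signal.shape[2], self.signal.shape[3]


@dataclass
class DWIStudy:
    """A whole-body acquisition: stations ordered superior -> inferior."""

    stations: list[StationVolume]
    patient_id: str = ""
    scan_label: str = ""

    def __post_init__(self) -> None:
        if not 1 <= len(self.stations) <= 8:
            raise ValueError("station count must be in [1, 8]")
        ref = self.stations[0]
        for st in self.stations[1:]:
            if st.matrix != ref.matrix:
                raise ValueError("stations must share in-plane matrix size")
            if st.spacing[1:] != ref.spacing[1:]:
                raise ValueError("stations must share in-plane voxel spacing")
            if st.b_values != ref.b_values:
                raise ValueError("stations must list identical b-values in order")

    @property
    def b_values(self) -> tuple[float, ...]:
        return self.stations[0].b_values


@dataclass
class ParametricMaps:
    """Voxel-aligned monoexponential fit: ADC (mm^2/s) and S0 (a.u. > 0).

    Negative ADC values are retained so the maps do not carry artificial
    boundaries at noise voxels; consumers that need a physical decay clamp
    on their side.
    """

    adc: np.ndarray
    s0: np.ndarray
    spacing: tuple[float, float, float]
    slice_positions: np.ndarray

    def __post_init__(self) -> None:
        self.adc = np.asarray(self.adc, dtype=np.float64)
        self.s0 = np.asarray(self.s0, dtype=np.float64)
        if self.adc.shape != self.s0.shape:
            raise ValueError("adc and s0 must share shape")
        if np.any(self.s0 <= 0):
            raise ValueError("s0 must be strictly positive (floor before building maps)")


@dataclass
class NetworkInput:
    """Two-channel dimensionless network input on the 256 x 256 / 1.6 mm grid
    (or a reduced grid for small-matrix studies)."""

    scaled_adc: np.ndarray
    scaled_s0: np.ndarray
    spacing: tuple[float, float, float]
    slice_positions: np.ndarray


@dataclass
class CanalSegmentation:
    """Per-voxel spinal-canal probability and the thresholded binary mask."""

    probability: np.ndarray
    mask: np.ndarray
    threshold: float = 0.5
    slice_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.probability.shape != self.mask.shape:
            raise ValueError("probability and mask must share shape")


@dataclass
class GMMResult:
    """Two-component Gaussian mixture of in-canal ADC.

    All values are in units of 1e-3 mm^2/s (means) and (1e-3 mm^2/s)^2
    (variances) so the EM problem is well conditioned.  Component 1 is the
    lower-mean component, interpreted as spinal cord; component 2 is CSF.
    """

    weights: tuple[float, float]
    means: tuple[float, float]
    variances: tuple[float, float]

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if not self.means[0] < self.means[1]:
            raise ValueError("component 1 (cord) must have the lower mean")
        if min(self.variances) <= 0:
            raise ValueError("variances must be positive")


@dataclass
class SubSegmentation:
    """Partition of the canal mask into cord and CSF."""

    cord_mask: np.ndarray
    csf_mask: np.ndarray


@dataclass
class ShapeStats:
    volume_ml: float
    average_cross_section_area_mm2: float


@dataclass
class NormalisedStudy:
    """Whole-body computed-DWI after station harmonisation and canal scaling.

    ``station_scale_factors`` are the cumulative per-station multipliers
    (reference, most superior station = 1); ``canal_reference`` is the 90th
    percentile of harmonised in-canal signal used as the global divisor.
    """

    composed_cdwi: np.ndarray
    station_scale_factors: list[float]
    canal_reference: float
    normalised: np.ndarray
    slice_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.station_scale_factors and self.station_scale_factors[0] != 1.0:
            raise ValueError("reference station factor must be exactly 1")
        if any(f <= 0 for f in self.station_scale_factors):
            raise ValueError("scale factors must be positive")


@dataclass
class PipelineConfig:
    """Knobs of the end-to-end standardisation pipeline."""

    b_c: float = 900.0
    percentile: float = 90.0
    threshold: float = 0.5
    n_adjacent: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must lie in (0, 100)")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")
        if self.n_adjacent < 1:
            raise ValueError("n_adjacent must be >= 1")
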