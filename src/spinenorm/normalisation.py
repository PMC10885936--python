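"""Whole-body signal standardisation of computed DWI.

Three linear stages remove the two dominant sources of intensity
inconsistency in multi-station whole-body DWI:

1. **Composition** -- the per-station computed-DWI volumes are stacked on a
   single superior-to-inferior slice grid.
2. **Inter-station harmonisation** -- each station boundary contributes a
   scalar factor chosen to minimise the mean-square error between the
   empirical cumulative frequency curves of the slices on either side of the
   boundary; factors accumulate downward from the most superior (reference)
   station, cancelling per-station receive-gain differences.
3. **Inter-scan standardisation** -- the whole volume is divided by the 90th
   percentile of the harmonised signal inside the spinal canal, putting every
   scan on a common, dimensionless scale (canal signal ~ 1).

All stages are multiplicative, so within-station intensity ratios -- and
hence contrast-to-noise -- are untouched.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import DWIStudy, NormalisedStudy

__all__ = [
    "compose_stations", "station_scale_factor", "harmonise_stations",
    "normalise_to_canal", "mip",
]

log = logging.getLogger(__name__)

N_CDF_LEVELS = 256
FACTOR_BOUNDS = (0.1, 10.0)


def compose_stations(study: DWIStudy, cdwi_per_station: list[np.ndarray]
                     ) -> tuple[np.ndarray, list[int], np.ndarray]:
    """Stack per-station cDWI volumes on the whole-body slice grid.

    Returns ``(volume, boundaries, positions)`` where ``boundaries[k]`` is
    the index of the first slice of station ``k+1`` in the composed stack and
    ``positions`` are the slice locations.  Slices acquired at the same
    position by two stations are taken from the more superior station.
    """
    if len(cdwi_per_station) != len(study.stations):
        raise ValueError("one cDWI volume per station required")
    shape = cdwi_per_station[0].shape[1:]
    if any(v.shape[1:] != shape for v in cdwi_per_station):
        raise ValueError("inconsistent in-plane geometry across stations")

    slices: dict[float, tuple[int, np.ndarray]] = {}
    for k, (st, vol) in enumerate(zip(study.stations, cdwi_per_station)):
        for j, pos in enumerate(st.slice_positions):
            key = float(pos)
            if key not in slices:      # superior station wins overlaps
                slices[key] = (k, vol[j])
    positions = np.array(sorted(slices))
    stations_of = np.array([slices[p][0] for p in positions])
    volume = np.stack([slices[p][1] for p in positions])
    boundaries = [int(i) for i in np.where(np.diff(stations_of) != 0)[0] + 1]
    return volume, boundaries, positions


def _ecdf(sorted_vals: np.ndarray, grid: np.ndarray) -> np.ndarray:
    return np.searchsorted(sorted_vals, grid, side="right") / sorted_vals.size


def station_scale_factor(upper_slices: np.ndarray, lower_slices: np.ndarray,
                         n_adjacent: int = 3) -> float:
    """Scalar that matches the intensity distribution below a station
    boundary to the one above it.

    Pools the nonzero voxels of the ``n_adjacent`` slices on each side and
    returns the ``s`` in [0.1, 10] minimising the summed squared difference
    between the empirical cumulative frequency curves of the upper voxels and
    of the lower voxels multiplied by ``s``, evaluated on a 256-level grid
    spanning the pooled range.  Background (<= 0) voxels are excluded so
    padding cannot bias the factor.
    """
    upper = np.asarray(upper_slices)[-n_adjacent:].ravel()
    lower = np.asarray(lower_slices)[:n_adjacent].ravel()
    u = np.sort(upper[upper > 0])
    l = np.sort(lower[lower > 0])
    if u.size == 0 or l.size == 0:
        log.warning("all-zero slices at station boundary: factor set to 1")
        return 1.0

    def objective(s: float) -> float:
        ls = l * s
        lo = min(u[0], ls[0])
        hi = max(u[-1], ls[-1])
        grid = np.linspace(lo, hi, N_CDF_LEVELS)
        return float(np.sum((_ecdf(u, grid) - _ecdf(ls, grid)) ** 2))

    # coarse log-spaced scan followed by zooming grid refinements: the ECDF
    # objective is stepped (flat plateaus between grid-level crossings), so a
    # deterministic grid beats a smooth minimiser.  Ties on a zero plateau
    # resolve to the factor closest to 1 (no evidence -> no scaling).
    grid = np.sort(np.append(np.geomspace(*FACTOR_BOUNDS, 200), 1.0))
    best = 1.0
    for _ in range(3):
        vals = np.array([objective(s) for s in grid])
        ties = np.flatnonzero(vals == vals.min())
        i = int(ties[np.argmin(np.abs(np.log(grid[ties])))])
        best = float(grid[i])
        lo_b = grid[max(i - 1, 0)]
        hi_b = grid[min(i + 1, len(grid) - 1)]
        if hi_b - lo_b < 1e-4 * best:
            break
        grid = np.sort(np.append(np.linspace(lo_b, hi_b, 200), best))
    return best


def harmonise_stations(volume: np.ndarray, boundaries: list[int],
                       n_adjacent: int = 3
                       ) -> tuple[np.ndarray, list[float]]:
    """Harmonise a composed volume across its station boundaries.

    For each boundary (superior to inferior) a scale factor is estimated from
    the adjacent slices and applied to everything below; station ``k`` thus
    ends up multiplied by the cumulative product of the boundary factors
    above it (the most superior station is the unscaled reference).  Returns
    the harmonised volume and the cumulative per-station factors.
    """
    out = volume.astype(np.float64).copy()
    cumulative = [1.0]
    running = 1.0
    for b in boundaries:
        s = station_scale_factor(out[:b], out[b:], n_adjacent=n_adjacent)
        out[b:] *= s     # everything below the boundary, so factors accumulate
        running *= s
        cumulative.append(running)
    log.debug("station factors: %s", cumulative)
    return out, cumulative


def normalise_to_canal(harmonised: np.ndarray, canal_mask: np.ndarray,
                       percentile: float = 90.0,
                       station_scale_factors: list[float] | None = None,
                       slice_positions: np.ndarray | None = None) -> NormalisedStudy:
    """Divide the harmonised volume by the given percentile (default 90th,
    linear interpolation) of its in-canal signal."""
    mask = canal_mask.astype(bool)
    if mask.shape != harmonised.shape:
        raise ValueError("canal mask must share the composed grid")
    if not mask.any():
        raise ValueError("empty canal mask: normalisation impossible")
    reference = float(np.percentile(harmonised[mask], percentile))
    if reference <= 0:
        raise ValueError("canal reference percentile is not positive")
    return NormalisedStudy(
        composed_cdwi=harmonised,
        station_scale_factors=station_scale_factors or [1.0],
        canal_reference=reference,
        normalised=harmonised / reference,
        slice_positions=slice_positions,
    )


_AXES = {"coronal": 1, "sagittal": 2}


def mip(volume: np.ndarray, axis: str = "coronal") -> np.ndarray:
    """Maximum-intensity projection along the coronal (row) or sagittal
    (column) axis of a (slice, row, col) volume."""
    if volume.ndim != 3:
        raise ValueError("mip expects a 3-D volume")
    if axis not in _AXES:
        raise ValueError("axis must be 'coronal' or 'sagittal'")
    return volume.max(axis=_AXES[axis])
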