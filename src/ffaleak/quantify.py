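"""Leakage intensity and area time series from registered leakage images.

Three per-timepoint readouts are computed over the shared analysis ROI (the
intersection of all registered fields of view, so every timepoint covers the
same retinal area):

* **relative intensity** ``r_t`` — mean leakage-image intensity minus the
  first frame's mean (so ``r_0 = 0`` exactly); the primary readout, needing
  no threshold;
* **area fraction** ``a_t`` — leakage area delineated by Otsu's threshold,
  divided by the ROI area;
* **in-region intensity** ``s_t`` — summed leakage-image intensity inside
  the Otsu mask, divided by the ROI area.

Series are reported on the native acquisition times and linearly resampled
onto an equally spaced grid (no extrapolation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphology import LeakageImage

__all__ = [
    "DegenerateHistogramError",
    "LeakageTimeSeries",
    "otsu_threshold",
    "leakage_mask",
    "relative_intensity_series",
    "area_fraction_series",
    "in_region_intensity_series",
    "resample_series",
    "quantify_sequence",
]

_N_BINS = 256


class DegenerateHistogramError(ValueError):
    """Raised when a sample has no contrast to threshold."""


def otsu_threshold(values: np.ndarray) -> float:
    """Threshold maximizing between-class variance over a 256-bin histogram.

    The returned value is the lower edge of the first foreground bin, so the
    foreground is ``{v >= T}``.  Ties resolve to the lower threshold.
    """
    values = np.asarray(values, dtype=float).ravel()
    vmin, vmax = values.min(), values.max()
    if vmin == vmax:
        raise DegenerateHistogramError("degenerate histogram: constant input")
    hist, edges = np.histogram(values, bins=_N_BINS, range=(vmin, vmax))
    p = hist / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(p)[:-1]  # class 0 = bins 0..k, k = 0..254
    w1 = 1.0 - w0
    mu_cum = np.cumsum(p * centers)
    mu_total = mu_cum[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_cum[:-1] / w0
        mu1 = (mu_total - mu_cum[:-1]) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, -np.inf)
    k = int(np.argmax(sigma_b))  # first occurrence -> lower threshold on ties
    return float(edges[k + 1])


def leakage_mask(leak: LeakageImage, analysis_roi: np.ndarray) -> tuple[np.ndarray, float | None]:
    """Otsu-delineated leakage region of one frame, within the analysis ROI.

    A contrast-free frame yields an empty mask (with a warning) rather than
    an error: it simply has no detectable leakage.
    """
    analysis_roi = np.asarray(analysis_roi, dtype=bool)
    sample = leak.values[analysis_roi]
    try:
        T = otsu_threshold(sample)
    except DegenerateHistogramError:
        warnings.warn("frame has no leakage contrast; empty leakage mask")
        return np.zeros(leak.shape, dtype=bool), None
    return (leak.values >= T) & analysis_roi, T


def relative_intensity_series(leak_images, analysis_roi: np.ndarray) -> np.ndarray:
    """Mean in-ROI intensity per frame minus the first frame's mean; r_0 = 0."""
    analysis_roi = np.asarray(analysis_roi, dtype=bool)
    means = np.array([li.values[analysis_roi].mean() for li in leak_images])
    out = means - means[0]
    out[0] = 0.0
    return out


def area_fraction_series(masks, analysis_roi: np.ndarray) -> np.ndarray:
    """Leakage-mask area divided by the analysis-ROI area, per frame."""
    analysis_roi = np.asarray(analysis_roi, dtype=bool)
    n = analysis_roi.sum()
    if n == 0:
        raise ValueError("empty analysis ROI")
    return np.array([(np.asarray(m, dtype=bool) & analysis_roi).sum() / n for m in masks])


def in_region_intensity_series(leak_images, masks, analysis_roi: np.ndarray) -> np.ndarray:
    """Summed intensity inside each leakage mask, divided by the ROI area."""
    analysis_roi = np.asarray(analysis_roi, dtype=bool)
    n = analysis_roi.sum()
    if n == 0:
        raise ValueError("empty analysis ROI")
    out = []
    for li, m in zip(leak_images, masks):
        sel = np.asarray(m, dtype=bool) & analysis_roi
        out.append(li.values[sel].sum() / n)
    return np.array(out)


def resample_series(times, values, grid_step: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear interpolation onto an equally spaced grid.

    The grid spans ``[min(times), max(times)]``; no extrapolation is
    performed, and on-grid knots are reproduced exactly.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 2:
        raise ValueError("need at least 2 points to resample")
    if not (np.diff(times) > 0).all():
        raise ValueError("times must be strictly increasing")
    grid = times[0] + grid_step * np.arange(int(np.floor((times[-1] - times[0]) / grid_step)) + 1)
    if grid[0] < times[0] or grid[-1] > times[-1]:
        raise ValueError("grid point outside the acquired time range")
    return grid, np.interp(grid, times, values)


@dataclass
class LeakageTimeSeries:
    """Per-timepoint leakage quantities on native and resampled time grids."""

    times: np.ndarray
    rel_intensity: np.ndarray
    area_fraction: np.ndarray
    in_region_intensity: np.ndarray
    thresholds: list
    analysis_roi: np.ndarray
    masks: list = field(default_factory=list, repr=False)
    grid_times: np.ndarray | None = None
    grid_rel_intensity: np.ndarray | None = None
    grid_area_fraction: np.ndarray | None = None
    grid_in_region_intensity: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times,
                "rel_intensity": self.rel_intensity,
                "area_fraction": self.area_fraction,
                "in_region_intensity": self.in_region_intensity,
                "otsu_T": [t if t is not None else np.nan for t in self.thresholds],
            }
        )


def quantify_sequence(
    leak_images,
    times,
    analysis_roi: np.ndarray,
    grid_step: float = 1.0,
) -> LeakageTimeSeries:
    """All three series (plus per-frame thresholds and masks) for a registered sequence.

    Otsu's threshold is applied per frame independently within the shared
    analysis ROI.
    """
    masks, thresholds = [], []
    for li in leak_images:
        m, T = leakage_mask(li, analysis_roi)
        masks.append(m)
        thresholds.append(T)
    times = np.asarray(times, dtype=float)
    series = LeakageTimeSeries(
        times=times,
        rel_intensity=relative_intensity_series(leak_images, analysis_roi),
        area_fraction=area_fraction_series(masks, analysis_roi),
        in_region_intensity=in_region_intensity_series(leak_images, masks, analysis_roi),
        thresholds=thresholds,
        analysis_roi=analysis_roi,
        masks=masks,
    )
    grid, gv = resample_series(times, series.rel_intensity, grid_step)
    series.grid_times = grid
    series.grid_rel_intensity = gv
    series.grid_area_fraction = resample_series(times, series.area_fraction, grid_step)[1]
    series.grid_in_region_intensity = resample_series(times, series.in_region_intensity, grid_step)[1]
    return series
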