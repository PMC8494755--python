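"""Hysteresis thresholding and two-phase Chan-Vese segmentation.

Two binary products are derived from the filter stages:

* the **large-vessel mask** — hysteresis threshold of the vesselness-filtered
  directional-residue image, used both to remove large vessels from the
  leakage image and to seed the reference-point detector;
* the **vessel segmentation** — two-phase piecewise-constant Chan-Vese
  segmentation of the full vesselness map (the energy, not any particular
  solver, defines the output).

The Chan-Vese energy is minimized by exact alternating coordinate descent:
phase means are updated in closed form, and labels are updated in
checkerboard sweeps (each half-sweep flips a set of mutually non-adjacent
pixels to their locally optimal label), so the energy is non-increasing at
every iteration.  The boundary-length regularizer is the discrete count of
4-neighbor label disagreements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from . import morphology, quadrature
from .io_core import FFAImage
from .morphology import OpeningParams

__all__ = [
    "HysteresisParams",
    "ChanVeseParams",
    "DegenerateSegmentationError",
    "hysteresis",
    "chan_vese",
    "chan_vese_energy",
    "segment_vessels",
    "large_vessel_mask",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


class DegenerateSegmentationError(ValueError):
    """Raised when the input has no contrast to segment."""


@dataclass
class HysteresisParams:
    """Absolute low/high thresholds for hysteresis on an intensity grid."""

    t_low: float
    t_high: float

    def __post_init__(self) -> None:
        if self.t_low > self.t_high:
            raise ValueError(f"t_low ({self.t_low}) must be <= t_high ({self.t_high})")

    @classmethod
    def from_quantiles(cls, values: np.ndarray, q_low: float, q_high: float) -> "HysteresisParams":
        """Thresholds as quantiles of the given sample (e.g. within-ROI values)."""
        lo, hi = np.quantile(np.asarray(values, dtype=float).ravel(), [q_low, q_high])
        return cls(float(lo), float(hi))


@dataclass
class ChanVeseParams:
    """Weights and stopping rules for the two-phase Chan-Vese energy.

    ``mu`` weights the discrete boundary length; ``lambda1``/``lambda2``
    weight the squared deviations from the foreground/background means.
    Iteration stops when the fraction of pixels changing label drops below
    ``tol`` or after ``max_iter`` sweeps.
    """

    mu: float = 0.2
    lambda1: float = 1.0
    lambda2: float = 1.0
    max_iter: int = 200
    tol: float = 1e-4

    def __post_init__(self) -> None:
        if min(self.mu, self.lambda1, self.lambda2) <= 0:
            raise ValueError("weights must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def hysteresis(values: np.ndarray, params: HysteresisParams) -> np.ndarray:
    """Keep 8-connected components of ``{values >= t_low}`` that reach ``t_high``."""
    values = np.asarray(values, dtype=float)
    low = values >= params.t_low
    labels, n = ndi.label(low, structure=_STRUCT8)
    if n == 0:
        return np.zeros(values.shape, dtype=bool)
    keep = np.unique(labels[values >= params.t_high])
    keep = keep[keep > 0]
    if keep.size == 0:
        return np.zeros(values.shape, dtype=bool)
    lut = np.zeros(n + 1, dtype=bool)
    lut[keep] = True
    return lut[labels]


def _boundary_count(labels: np.ndarray) -> int:
    """Number of 4-neighbor pairs with differing labels."""
    return int((labels[1:, :] != labels[:-1, :]).sum() + (labels[:, 1:] != labels[:, :-1]).sum())


def chan_vese_energy(values: np.ndarray, labels: np.ndarray, params: ChanVeseParams) -> float:
    """Two-phase piecewise-constant energy of a labeling (means taken from it)."""
    fg, bg = values[labels], values[~labels]
    e = params.mu * _boundary_count(labels)
    if fg.size:
        e += params.lambda1 * ((fg - fg.mean()) ** 2).sum()
    if bg.size:
        e += params.lambda2 * ((bg - bg.mean()) ** 2).sum()
    return float(e)


def _neighbor_counts(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(foreground-neighbor count, background-neighbor count) over the 4-neighborhood."""
    lab = labels.astype(np.int32)
    fg = np.zeros(labels.shape, dtype=np.int32)
    tot = np.zeros(labels.shape, dtype=np.int32)
    fg[1:, :] += lab[:-1, :]
    fg[:-1, :] += lab[1:, :]
    fg[:, 1:] += lab[:, :-1]
    fg[:, :-1] += lab[:, 1:]
    tot[1:, :] += 1
    tot[:-1, :] += 1
    tot[:, 1:] += 1
    tot[:, :-1] += 1
    return fg, tot - fg


def _auto_init(values: np.ndarray) -> np.ndarray:
    """Deterministic initialization: hysteresis at default quantiles, with an
    Otsu fallback when that mask is trivial (empty or full)."""
    init = hysteresis(values, HysteresisParams.from_quantiles(values, 0.85, 0.97))
    if init.all() or not init.any():
        from skimage.filters import threshold_otsu

        init = values > threshold_otsu(values)
    return init


def chan_vese(
    values: np.ndarray,
    params: ChanVeseParams | None = None,
    init="auto",
    return_energies: bool = False,
):
    """Two-phase Chan-Vese segmentation by alternating exact coordinate descent.

    Deterministic for a fixed ``init``; the returned foreground is the phase
    with the higher mean.  With ``return_energies=True`` also returns the
    per-iteration energy sequence, which is non-increasing by construction.
    """
    params = params or ChanVeseParams()
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    if values.min() == values.max():
        raise DegenerateSegmentationError("degenerate segmentation: constant input")
    labels = _auto_init(values) if isinstance(init, str) else np.asarray(init, dtype=bool).copy()
    if labels.all() or not labels.any():
        labels = _auto_init(values)

    rr, cc = np.indices(values.shape)
    parity = (rr + cc) % 2
    energies = []
    for _ in range(params.max_iter):
        fg, bg = values[labels], values[~labels]
        if fg.size == 0 or bg.size == 0:
            break
        c1, c2 = fg.mean(), bg.mean()
        cost_fg_data = params.lambda1 * (values - c1) ** 2
        cost_bg_data = params.lambda2 * (values - c2) ** 2
        changed = 0
        for p in (0, 1):
            nfg, nbg = _neighbor_counts(labels)
            cost_fg = cost_fg_data + params.mu * nbg
            cost_bg = cost_bg_data + params.mu * nfg
            new = np.where(cost_fg < cost_bg, True, np.where(cost_bg < cost_fg, False, labels))
            sel = parity == p
            changed += int((new[sel] != labels[sel]).sum())
            labels[sel] = new[sel]
        energies.append(chan_vese_energy(values, labels, params))
        if changed / values.size < params.tol:
            break

    # Foreground = phase with higher mean.
    fg, bg = values[labels], values[~labels]
    if fg.size and bg.size and fg.mean() < bg.mean():
        labels = ~labels
    elif not fg.size:
        labels = ~labels
    return (labels, energies) if return_energies else labels


def segment_vessels(
    image: FFAImage,
    cv: ChanVeseParams | None = None,
    n_s: int = 2,
    sigma: float = 3.0,
) -> np.ndarray:
    """Chan-Vese segmentation of the vesselness map, restricted to the ROI."""
    lp = quadrature.enhance(image.pixels, n_s=n_s, sigma=sigma)
    lp = np.where(image.roi, lp, 0.0)
    try:
        mask = chan_vese(lp, cv)
    except DegenerateSegmentationError:
        warnings.warn("no contrast in vesselness map; returning empty vessel mask")
        return np.zeros(image.shape, dtype=bool)
    return mask & image.roi


def large_vessel_mask(
    image: FFAImage,
    params: OpeningParams | None = None,
    hyst_quantiles: tuple[float, float] = (0.85, 0.97),
    n_s: int = 2,
    sigma: float = 3.0,
    s_start: int = 3,
) -> np.ndarray:
    """Binary mask of large vessels: residue image -> vesselness -> hysteresis.

    The directional-residue image is vesselness-filtered to even out
    intensity variations along vessels, then hysteresis-thresholded at the
    given quantiles of the within-ROI values.  The vesselness scales start
    coarser than for full vessel segmentation (``s_start=3``, i.e. center
    periods of 8 and 16 pixels) because only thick vessels survive the
    residue step and the finest scales respond mostly to pixel noise.  The
    result feeds both large-vessel removal and the reference-point detector.
    """
    params = params or OpeningParams()
    iv = morphology.enhance_large_vessels(image, params)
    lp = quadrature.enhance(iv.values, n_s=n_s, sigma=sigma, s_start=s_start)
    sample = lp[image.roi]
    if sample.min() == sample.max():
        return np.zeros(image.shape, dtype=bool)
    hp = HysteresisParams.from_quantiles(sample, *hyst_quantiles)
    return hysteresis(lp, hp) & image.roi
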