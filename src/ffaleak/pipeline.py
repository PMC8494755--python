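"""End-to-end orchestration: frames in, leakage time series out.

Per frame the pipeline computes the small-vessel-removed image, the
large-vessel mask (shared between vessel removal and the reference-point
detector), and the final leakage image; frames are rigidly registered to
the first timepoint with reference-point initialization; leakage images are
resampled into the fixed frame, and the three leakage series are quantified
over the intersection of all registered fields of view.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import morphology as skmorph

from . import morphology, quantify, segmentation
from .io_core import FFAImage, FFASequence
from .morphology import LeakageImage, OpeningParams
from .quantify import LeakageTimeSeries
from .refpoint import ReferencePointError, reference_point_from_mask
from .registration import (
    InitializationError,
    RigidTransform,
    initial_transform,
    register_pair,
    warp,
)

__all__ = ["leakage_image", "analyze_sequence", "SequenceAnalysis"]


def leakage_image(
    image: FFAImage,
    params: OpeningParams | None = None,
    hyst_quantiles: tuple[float, float] = (0.85, 0.97),
    n_s: int = 2,
    sigma: float = 3.0,
    vessel_mask: np.ndarray | None = None,
    mask_close_radius: int = 12,
    mask_dilate_radius: int = 2,
) -> tuple[LeakageImage, np.ndarray]:
    """Vessel-free leakage image of one frame, plus the large-vessel mask used.

    Before removal the vessel mask is morphologically closed (bridging the
    junction gaps near the optic disk, where converging vessels form an
    isotropic blob invisible to the directional residue) and slightly
    dilated (soft vessel edges extend past the hysteresis mask).
    """
    params = params or OpeningParams()
    small_removed = morphology.remove_small_vessels(image, params)
    if vessel_mask is None:
        vessel_mask = segmentation.large_vessel_mask(image, params, hyst_quantiles, n_s, sigma)
    removal_mask = vessel_mask
    if removal_mask.any():
        if mask_close_radius > 0:
            removal_mask = skmorph.closing(removal_mask, skmorph.disk(mask_close_radius))
        if mask_dilate_radius > 0:
            removal_mask = skmorph.dilation(removal_mask, skmorph.disk(mask_dilate_radius))
    if removal_mask.any() and not removal_mask.all():
        leak = morphology.remove_large_vessels(small_removed, removal_mask, params)
    else:
        leak = small_removed
    return leak, vessel_mask


@dataclass
class SequenceAnalysis:
    """Everything the pipeline computes for one eye."""

    series: LeakageTimeSeries
    transforms: list[RigidTransform]
    refpoints: list
    leak_images: list  # registered (fixed-frame) leakage images
    analysis_roi: np.ndarray
    flags: dict = field(default_factory=dict)


def analyze_sequence(
    seq: FFASequence,
    params: OpeningParams | None = None,
    hyst_quantiles: tuple[float, float] = (0.85, 0.97),
    n_s: int = 2,
    sigma: float = 3.0,
    T_b: int = 20,
    L_0: float = 30.0,
    grid_step: float = 1.0,
    retry_ncc: float = 0.9,
    **pair_kwargs,
) -> SequenceAnalysis:
    """Run the full pipeline on a time series of one eye.

    The large-vessel mask of each raw frame is computed once and reused for
    both the reference-point detector and vessel removal; leakage images are
    then warped by the recovered transforms and quantified on the common ROI.

    An outlier reference point (e.g. when strong leakage edges contaminate
    the vessel mask of a late frame) can start the optimizer in the wrong
    basin, so when the final correlation falls below ``retry_ncc`` the pair
    is re-registered from the identity initialization and the better-scoring
    transform is kept.
    """
    if len(seq) < 2:
        raise ValueError("need at least 2 frames")
    params = params or OpeningParams()

    leaks_raw: list[LeakageImage] = []
    refpoints = []
    for frame in seq:
        vmask = segmentation.large_vessel_mask(frame, params, hyst_quantiles, n_s, sigma)
        leak, _ = leakage_image(frame, params, hyst_quantiles, n_s, sigma, vessel_mask=vmask)
        leaks_raw.append(leak)
        try:
            refpoints.append(reference_point_from_mask(vmask, T_b=T_b, L_0=L_0))
        except ReferencePointError:
            warnings.warn(f"no reference point at t={frame.time_min}")
            refpoints.append(None)

    fixed = seq[0]
    identity = RigidTransform(center=tuple(np.argwhere(fixed.roi).mean(axis=0)))
    transforms = [identity]
    flags: dict = {}
    for i in range(1, len(seq)):
        if refpoints[0] is not None and refpoints[i] is not None:
            init = initial_transform(refpoints[i], refpoints[0])
        else:
            init = identity
            flags[i] = "identity-init"
        try:
            res = register_pair(fixed, seq[i], init, **pair_kwargs)
            if res.ncc < retry_ncc and init is not identity:
                retry = register_pair(fixed, seq[i], identity, **pair_kwargs)
                if retry.ncc > res.ncc:
                    res = retry
                    flags[i] = "identity-retry"
            transforms.append(res.transform)
        except InitializationError as exc:
            warnings.warn(f"frame {i} failed to register: {exc}")
            flags[i] = "failed"
            transforms.append(init)

    # Warp leakage images and ROIs into the fixed frame.
    registered_leaks: list[LeakageImage] = []
    rois = []
    for leak, t, frame in zip(leaks_raw, transforms, seq):
        carrier = FFAImage(np.maximum(leak.values, 0.0), frame.roi, frame.time_min)
        w = warp(carrier, t, fixed.shape)
        registered_leaks.append(LeakageImage(w.pixels, w.roi))
        rois.append(w.roi)
    analysis_roi = np.logical_and.reduce(rois)

    series = quantify.quantify_sequence(registered_leaks, seq.times, analysis_roi, grid_step)
    return SequenceAnalysis(
        series=series,
        transforms=transforms,
        refpoints=refpoints,
        leak_images=registered_leaks,
        analysis_roi=analysis_roi,
        flags=flags,
    )
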