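"""Seeded FFA phantom generator with full ground truth.

No public FFA dataset of the targeted mouse model exists, so every test and
study in this package runs on synthetic phantoms that emulate the salient
features of the real frames: a dark camera frame with a circular bright
field of view, a branching tree of bright tubular vessels (Gaussian
cross-section, varying diameter) converging on an optic-disk point, smooth
amorphous leakage blobs whose amplitude and support grow over timepoints, a
small unknown rigid motion between timepoints, and additive Gaussian noise.

Leakage blobs use a raised-cosine radial profile, which is smooth (real
leakage has no sharp boundary) but compactly supported, so a "true support"
mask is well defined for area-recovery tests.

Everything is deterministic under the seed, and the generator returns the
ground truth (vessel mask, centerlines, convergence point, per-timepoint
leakage supports and amplitudes, true rigid transforms) alongside the
frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import line as draw_line

from .io_core import FFAImage, FFASequence
from .registration import RigidTransform, warp

_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))  # FWHM of a unit-sigma Gaussian

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_vessel_tree",
    "generate_sequence",
    "perturb_annotation",
    "default_blob_centers",
]


@dataclass
class PhantomSpec:
    """Parameters of a synthetic FFA eye.

    Times are minutes post injection.  ``amplitudes`` and ``support_radii``
    give the leakage blob peak intensity and support radius per timepoint.
    Rigid jitter per timepoint is drawn uniformly within the given bounds
    (frame 0 always has identity jitter).
    """

    shape: tuple[int, int] = (512, 512)
    roi_center: tuple[float, float] = (256.0, 256.0)
    roi_radius: float = 230.0
    convergence_offset: tuple[float, float] = (-35.0, 45.0)
    n_primaries: int = 6
    depth: int = 2
    diameter_range: tuple[float, float] = (2.0, 8.0)
    tortuosity: float = 0.05
    vessel_amplitude: float = 130.0
    background: float = 25.0
    times: tuple = (1.0, 3.0, 5.0, 7.0, 9.0)
    amplitudes: tuple = (30.0, 50.0, 70.0, 90.0, 110.0)
    support_radii: tuple = (50.0, 54.0, 58.0, 62.0, 66.0)
    blob_centers: tuple | None = None
    jitter_translation_max: float = 15.0
    jitter_angle_max: float = 0.05  # radians, ~3 degrees
    noise_std: float = 3.0

    def __post_init__(self) -> None:
        if min(self.diameter_range) <= 0:
            raise ValueError("diameters must be > 0")
        if not (len(self.times) == len(self.amplitudes) == len(self.support_radii)):
            raise ValueError("times, amplitudes and support_radii must have equal length")

    @property
    def convergence_point(self) -> tuple[float, float]:
        return (
            self.roi_center[0] + self.convergence_offset[0],
            self.roi_center[1] + self.convergence_offset[1],
        )


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom sequence."""

    vessel_mask: np.ndarray
    centerline_mask: np.ndarray
    centerlines: list
    convergence_point: tuple[float, float]
    roi_mask: np.ndarray
    support_masks: list = field(default_factory=list)  # per timepoint, fixed-frame coords
    amplitudes: np.ndarray | None = None
    support_area_fractions: np.ndarray | None = None
    transforms: list = field(default_factory=list)  # moving->fixed truth per frame


def _disk_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.indices(shape)
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def default_blob_centers(spec: PhantomSpec, n_blobs: int = 3) -> list[tuple[float, float]]:
    """Deterministic blob placement between the primary vessels, inside the ROI."""
    c = np.asarray(spec.convergence_point)
    centers = []
    for k in range(n_blobs):
        ang = 2 * math.pi * (k + 0.35) / n_blobs + 0.4
        r = 0.55 * spec.roi_radius
        p = c + r * np.array([math.sin(ang), math.cos(ang)])
        # keep the blob support inside the field of view
        d = p - np.asarray(spec.roi_center)
        dist = np.linalg.norm(d)
        max_r = spec.roi_radius - max(spec.support_radii) - 5
        if dist > max_r:
            p = np.asarray(spec.roi_center) + d / dist * max_r
        centers.append(tuple(p))
    return centers


def _grow_branch(rng, start, angle, length, diameter, tortuosity, spec, segments):
    """Random-walk a branch polyline; record (points, diameter); return its end point/angle.

    Heading noise ramps up with distance from the convergence point: vessels
    leave the optic disk radially and straight, and curve only distally.
    """
    step = 2.0
    pts = [np.asarray(start, dtype=float)]
    pos = pts[0].copy()
    a = angle
    n_steps = max(int(length / step), 2)
    c = np.asarray(spec.roi_center)
    conv = np.asarray(spec.convergence_point)
    ramp_scale = 0.3 * spec.roi_radius
    for _ in range(n_steps):
        ramp = min(1.0, np.linalg.norm(pos - conv) / ramp_scale)
        a += rng.normal(0.0, tortuosity * ramp)
        pos = pos + step * np.array([math.sin(a), math.cos(a)])
        if np.linalg.norm(pos - c) > spec.roi_radius - 6:
            break
        pts.append(pos.copy())
    segments.append((np.array(pts), diameter))
    return pts[-1], a


def generate_vessel_tree(spec: PhantomSpec, rng) -> tuple[np.ndarray, PhantomTruth]:
    """Render the bright vessel tree and its ground truth.

    ``n_primaries`` straight-ish vessels of maximal diameter radiate from the
    convergence point; each spawns two thinner children per depth level.
    Vessels have a Gaussian cross-section whose FWHM equals the branch
    diameter, so the truth mask (profile above half maximum) has exactly that
    width.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    dmin, dmax = spec.diameter_range
    c0 = np.asarray(spec.convergence_point)
    if np.linalg.norm(c0 - np.asarray(spec.roi_center)) > spec.roi_radius - 10:
        raise ValueError("convergence point outside the field of view")
    segments: list[tuple[np.ndarray, float]] = []
    primary_len = 0.55 * spec.roi_radius
    for k in range(spec.n_primaries):
        ang = 2 * math.pi * k / spec.n_primaries + rng.normal(0.0, 0.25 / spec.n_primaries)
        frontier = [(c0, ang, primary_len, dmax)]
        for level in range(spec.depth + 1):
            nxt = []
            for start, a, length, diam in frontier:
                end, a_end = _grow_branch(rng, start, a, length, diam, spec.tortuosity, spec, segments)
                if level < spec.depth:
                    child_d = max(diam * 0.65, dmin)
                    spread = rng.uniform(0.35, 0.65)
                    nxt.append((end, a_end - spread, length * 0.75, child_d))
                    nxt.append((end, a_end + spread, length * 0.75, child_d))
            frontier = nxt

    # rasterize centerlines and carry per-pixel branch radius
    shape = spec.shape
    centerline = np.zeros(shape, dtype=bool)
    sigma_at = np.zeros(shape, dtype=float)  # Gaussian sigma of nearest branch
    halfwidth_at = np.zeros(shape, dtype=float)
    centerlines = []
    for pts, diam in segments:
        ipts = np.round(pts).astype(int)
        if len(ipts) < 2:
            continue
        rr_all, cc_all = [], []
        for (r0, c0_), (r1, c1_) in zip(ipts[:-1], ipts[1:]):
            rr, cc = draw_line(r0, c0_, r1, c1_)
            rr_all.append(rr)
            cc_all.append(cc)
        rr = np.clip(np.concatenate(rr_all), 0, shape[0] - 1)
        cc = np.clip(np.concatenate(cc_all), 0, shape[1] - 1)
        centerline[rr, cc] = True
        sigma_at[rr, cc] = np.maximum(sigma_at[rr, cc], diam / _FWHM)  # FWHM = diameter
        halfwidth_at[rr, cc] = np.maximum(halfwidth_at[rr, cc], diam / 2.0)
        centerlines.append(np.stack([rr, cc], axis=1))

    dist, (ir, ic) = ndi.distance_transform_edt(~centerline, return_indices=True)
    sig = sigma_at[ir, ic]
    hw = halfwidth_at[ir, ic]
    with np.errstate(divide="ignore", invalid="ignore"):
        profile = np.exp(-(dist**2) / (2.0 * sig**2))
    profile[sig == 0] = 0.0
    profile[dist > 4.0 * np.maximum(sig, 1e-9)] = 0.0
    vessel_img = spec.vessel_amplitude * profile
    vessel_mask = dist <= hw

    roi_mask = _disk_mask(shape, spec.roi_center, spec.roi_radius)
    truth = PhantomTruth(
        vessel_mask=vessel_mask & roi_mask,
        centerline_mask=centerline & roi_mask,
        centerlines=centerlines,
        convergence_point=tuple(spec.convergence_point),
        roi_mask=roi_mask,
    )
    return vessel_img, truth


def _blob_image(shape, centers, amplitude, radius) -> np.ndarray:
    """Sum of raised-cosine blobs: A * (0.5 + 0.5 cos(pi r / R)) for r <= R."""
    out = np.zeros(shape, dtype=float)
    rr, cc = np.indices(shape)
    for cy, cx in centers:
        r = np.hypot(rr - cy, cc - cx)
        inside = r <= radius
        out[inside] += amplitude * (0.5 + 0.5 * np.cos(math.pi * r[inside] / radius))
    return out


def generate_sequence(spec: PhantomSpec | None = None, seed: int = 0) -> tuple[FFASequence, PhantomTruth]:
    """Render a jittered, noisy FFA time series plus its ground truth.

    Frame 0 is the canonical (fixed) frame.  Each later frame t carries a
    rigid motion: its truth transform maps frame-t coordinates to frame-0
    coordinates, and registering frame t onto frame 0 should recover it.
    Support masks and area fractions are reported in frame-0 coordinates.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    vessel_img, truth = generate_vessel_tree(spec, rng)
    centers = spec.blob_centers or default_blob_centers(spec)
    scene_static = spec.background + vessel_img
    roi = truth.roi_mask

    frames = []
    truth.amplitudes = np.asarray(spec.amplitudes, dtype=float)
    fractions = []
    for i, (t, A, R) in enumerate(zip(spec.times, spec.amplitudes, spec.support_radii)):
        scene = scene_static + _blob_image(spec.shape, centers, A, R)
        support = np.zeros(spec.shape, dtype=bool)
        for c in centers:
            support |= _disk_mask(spec.shape, c, R)
        support &= roi
        truth.support_masks.append(support)
        fractions.append(support.sum() / roi.sum())

        if i == 0 or (spec.jitter_translation_max == 0 and spec.jitter_angle_max == 0):
            T = RigidTransform(center=tuple(spec.roi_center))
            moved = scene
        else:
            T = RigidTransform(
                angle=float(rng.uniform(-spec.jitter_angle_max, spec.jitter_angle_max)),
                translation=tuple(rng.uniform(-spec.jitter_translation_max,
                                              spec.jitter_translation_max, 2)),
                center=tuple(spec.roi_center),
            )
            src = FFAImage(scene, np.ones(spec.shape, dtype=bool), time_min=t)
            moved = warp(src, T.inverse(), spec.shape).pixels
        truth.transforms.append(T)

        pixels = np.where(roi, moved, 0.0)
        if spec.noise_std > 0:
            pixels = pixels + rng.normal(0.0, spec.noise_std, spec.shape) * roi
        frames.append(FFAImage(np.maximum(pixels, 0.0), roi.copy(), time_min=t))

    truth.support_area_fractions = np.asarray(fractions)
    return FFASequence(frames), truth


def perturb_annotation(mask: np.ndarray, radius: float, boundary_noise: float, seed: int = 0) -> np.ndarray:
    """Morphologically perturb a mask, emulating an annotator's boundary criterion.

    Positive ``radius`` dilates, negative erodes (both in pixels, via the
    signed distance function); ``boundary_noise`` adds a smooth seeded random
    field to the boundary position, modeling the irregular outlines of a
    human annotator.  ``radius=0, boundary_noise=0`` is the identity.
    """
    mask = np.asarray(mask, dtype=bool)
    if radius == 0 and boundary_noise == 0:
        return mask.copy()
    sdf = np.zeros(mask.shape, dtype=float)
    if mask.any():
        sdf[mask] = ndi.distance_transform_edt(mask)[mask]
    if (~mask).any():
        sdf[~mask] = -ndi.distance_transform_edt(~mask)[~mask]
    noise = 0.0
    if boundary_noise > 0:
        rng = np.random.default_rng(seed)
        field_ = ndi.gaussian_filter(rng.standard_normal(mask.shape), 8.0)
        field_ /= field_.std() or 1.0
        noise = boundary_noise * field_
    return (sdf + radius + noise) > 0
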