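"""Rigid registration of FFA sequences to the first timepoint.

Eye movement between timepoints is well modeled by a rotation plus a
translation.  Each later frame is registered to the first frame by maximizing
normalized cross-correlation (NCC) over the fixed frame's field of view with
a regular-step gradient descent (two resolution levels), initialized by
translating the moving frame's vessel-convergence reference point onto the
fixed frame's.  NCC removes the dependence on fluorescein dose, which differs
between timepoints.

A :class:`RigidTransform` maps *moving-frame* coordinates to *fixed-frame*
coordinates: ``f = R(angle) @ (m - center) + center + translation`` in
(row, col) coordinates.  The numerical optimization is delegated to
SimpleITK; transforms are converted to and from this convention at the
boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .io_core import FFAImage, FFASequence

__all__ = [
    "RigidTransform",
    "RegistrationResult",
    "SequenceRegistration",
    "InitializationError",
    "initial_transform",
    "register_pair",
    "warp",
    "register_sequence",
    "masked_ncc",
]


class InitializationError(RuntimeError):
    """Raised when the initial transform leaves no field-of-view overlap."""


def _rot(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s], [s, c]])


@dataclass
class RigidTransform:
    """Rotation + translation mapping moving-frame to fixed-frame (row, col) points."""

    angle: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    center: tuple[float, float] = (0.0, 0.0)

    @property
    def matrix(self) -> np.ndarray:
        return _rot(self.angle)

    @property
    def offset(self) -> np.ndarray:
        """`f = matrix @ m + offset`."""
        c = np.asarray(self.center, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        return c + t - self.matrix @ c

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 2) or (2,) moving-frame points into the fixed frame."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix.T + self.offset
        return out[0] if np.asarray(points).ndim == 1 else out

    @classmethod
    def from_affine(
        cls, matrix: np.ndarray, offset: np.ndarray, center=(0.0, 0.0)
    ) -> "RigidTransform":
        angle = math.atan2(matrix[1, 0], matrix[0, 0])
        c = np.asarray(center, dtype=float)
        t = np.asarray(offset, dtype=float) - c + _rot(angle) @ c
        return cls(angle=angle, translation=tuple(t), center=tuple(c))

    def inverse(self) -> "RigidTransform":
        Minv = self.matrix.T
        return RigidTransform.from_affine(Minv, -Minv @ self.offset, self.center)

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """self o first: apply ``first`` then ``self``."""
        M = self.matrix @ first.matrix
        b = self.matrix @ first.offset + self.offset
        return RigidTransform.from_affine(M, b, self.center)


@dataclass
class RegistrationResult:
    transform: RigidTransform
    ncc: float
    ncc_init: float


@dataclass
class SequenceRegistration:
    transforms: list[RigidTransform]
    registered: FFASequence
    analysis_roi: np.ndarray
    results: list[RegistrationResult | None]
    flags: dict = field(default_factory=dict)


def initial_transform(ref_moving, ref_fixed) -> RigidTransform:
    """Pure translation placing the moving reference point on the fixed one."""
    rm = np.asarray(ref_moving, dtype=float)
    rf = np.asarray(ref_fixed, dtype=float)
    if not (np.isfinite(rm).all() and np.isfinite(rf).all()):
        raise ValueError("reference points must be finite")
    return RigidTransform(angle=0.0, translation=tuple(rf - rm), center=tuple(rf))


def masked_ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Pearson correlation of two images over a boolean mask."""
    x, y = a[mask].astype(float), b[mask].astype(float)
    if x.size < 2:
        return float("nan")
    x = x - x.mean()
    y = y - y.mean()
    denom = math.sqrt((x**2).sum() * (y**2).sum())
    return float((x * y).sum() / denom) if denom > 0 else float("nan")


def warp(moving: FFAImage, t: RigidTransform, fixed_shape=None) -> FFAImage:
    """Resample the moving frame into fixed-frame coordinates.

    Pixels use linear interpolation; the ROI is warped with nearest-neighbor
    and pixels that fall outside the source frame are marked outside the ROI.
    """
    fixed_shape = fixed_shape or moving.shape
    inv = t.inverse()
    pix = ndi.affine_transform(
        moving.pixels, inv.matrix, offset=inv.offset, output_shape=fixed_shape,
        order=1, mode="constant", cval=0.0,
    )
    roi = ndi.affine_transform(
        moving.roi.astype(np.uint8), inv.matrix, offset=inv.offset,
        output_shape=fixed_shape, order=0, mode="constant", cval=0,
    ).astype(bool)
    if not roi.any():
        raise InitializationError("warped field of view is empty")
    return FFAImage(np.maximum(pix, 0.0), roi, moving.time_min, meta=dict(moving.meta))


def _to_sitk_euler(t: RigidTransform):
    """Our moving->fixed (row, col) transform as a SimpleITK fixed->moving (x, y) Euler2D."""
    import SimpleITK as sitk

    inv = t.inverse()  # fixed -> moving, (row, col)
    # coordinate swap (row, col) -> (x, y): conjugate the matrix by the swap
    S = np.array([[0.0, 1.0], [1.0, 0.0]])
    M_xy = S @ inv.matrix @ S
    b_xy = S @ inv.offset
    tr = sitk.Euler2DTransform()
    tr.SetMatrix(tuple(M_xy.ravel()))
    tr.SetTranslation(tuple(b_xy))  # center (0,0): offset == translation
    return tr


def _from_sitk(tr, center_rc) -> RigidTransform:
    """SimpleITK fixed->moving (x, y) transform back to our moving->fixed (row, col)."""
    A = np.array(tr.GetMatrix()).reshape(2, 2)
    c = np.array(tr.GetCenter())
    b = np.array(tr.GetTranslation()) + c - A @ c
    S = np.array([[0.0, 1.0], [1.0, 0.0]])
    M_rc = S @ A @ S
    b_rc = S @ b
    fixed_to_moving = RigidTransform.from_affine(M_rc, b_rc, center_rc)
    return fixed_to_moving.inverse()


def register_pair(
    fixed: FFAImage,
    moving: FFAImage,
    init: RigidTransform | None = None,
    learning_rate: float = 2.0,
    min_step: float = 1e-4,
    max_iterations: int = 300,
    shrink_factors=(2, 1),
    smoothing_sigmas=(1.0, 0.0),
) -> RegistrationResult:
    """Rigidly register ``moving`` onto ``fixed`` by NCC gradient descent.

    Deterministic (full metric sampling, no stochastic subsampling).  The
    returned transform is guaranteed not to score below the initialization:
    if the optimizer ends at a worse NCC the initialization is returned.
    """
    import SimpleITK as sitk

    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving frames must share dimensions")
    if init is None:
        centroid = np.argwhere(fixed.roi).mean(axis=0)
        init = RigidTransform(center=tuple(centroid))

    warped0 = warp(moving, init, fixed.shape)  # raises InitializationError on no overlap
    overlap0 = fixed.roi & warped0.roi
    if not overlap0.any():
        raise InitializationError("initialization out of field")
    ncc_init = masked_ncc(fixed.pixels, warped0.pixels, overlap0)

    f = sitk.GetImageFromArray(fixed.pixels.astype(np.float64))
    m = sitk.GetImageFromArray(moving.pixels.astype(np.float64))
    fmask = sitk.GetImageFromArray(fixed.roi.astype(np.uint8))

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsCorrelation()
    reg.SetMetricFixedMask(fmask)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=learning_rate,
        minStep=min_step,
        numberOfIterations=max_iterations,
        relaxationFactor=0.5,
        gradientMagnitudeTolerance=1e-6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(list(shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(smoothing_sigmas))
    reg.SetInitialTransform(_to_sitk_euler(init), inPlace=True)

    try:
        final = reg.Execute(f, m)
    except RuntimeError as exc:
        warnings.warn(f"optimizer failed ({exc}); keeping initialization")
        return RegistrationResult(init, ncc_init, ncc_init)

    t = _from_sitk(sitk.Euler2DTransform(final), init.center)
    try:
        warped = warp(moving, t, fixed.shape)
        overlap = fixed.roi & warped.roi
        ncc_final = masked_ncc(fixed.pixels, warped.pixels, overlap)
    except InitializationError:
        ncc_final = float("-inf")
    if not np.isfinite(ncc_final) or ncc_final < ncc_init:
        return RegistrationResult(init, ncc_init, ncc_init)
    return RegistrationResult(t, ncc_final, ncc_init)


def register_sequence(
    seq: FFASequence,
    use_refpoint_init: bool = True,
    refpoints: list | None = None,
    T_b: int = 20,
    L_0: float = 30.0,
    refpoint_kwargs: dict | None = None,
    **pair_kwargs,
) -> SequenceRegistration:
    """Register every frame of a sequence to the first timepoint.

    The first frame (smallest leakage, least saturation) is the fixed frame
    and gets the identity transform.  Reference-point initialization is used
    when the point can be detected in both frames; otherwise identity
    initialization is used and logged.  Frames whose registration fails
    outright are flagged and excluded from the shared analysis ROI.
    """
    if len(seq) < 2:
        raise ValueError("need at least 2 frames to register")
    from .refpoint import ReferencePointError, reference_point

    kw = refpoint_kwargs or {}
    if refpoints is None:
        refpoints = []
        for frame in seq:
            if not use_refpoint_init:
                refpoints.append(None)
                continue
            try:
                refpoints.append(reference_point(frame, T_b=T_b, L_0=L_0, **kw))
            except ReferencePointError:
                warnings.warn(f"no reference point at t={frame.time_min}; identity init")
                refpoints.append(None)

    fixed = seq[0]
    identity = RigidTransform(center=tuple(np.argwhere(fixed.roi).mean(axis=0)))
    transforms: list[RigidTransform] = [identity]
    results: list[RegistrationResult | None] = [None]
    warped_frames = [fixed]
    flags: dict = {}
    for i, frame in enumerate(seq.frames[1:], start=1):
        if refpoints[0] is not None and refpoints[i] is not None:
            init = initial_transform(refpoints[i], refpoints[0])
        else:
            init = identity
            flags[i] = "identity-init"
        try:
            res = register_pair(fixed, frame, init, **pair_kwargs)
            transforms.append(res.transform)
            results.append(res)
            warped_frames.append(warp(frame, res.transform, fixed.shape))
        except InitializationError as exc:
            warnings.warn(f"frame {i} (t={frame.time_min}) failed to register: {exc}")
            flags[i] = "failed"
            transforms.append(init)
            results.append(None)
            warped_frames.append(None)

    kept = [w for w in warped_frames if w is not None]
    analysis_roi = np.logical_and.reduce([w.roi for w in kept])
    registered = FFASequence(kept, eye_id=seq.eye_id)
    return SequenceRegistration(transforms, registered, analysis_roi, results, flags)
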