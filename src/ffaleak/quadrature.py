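"""Multi-scale log-Gabor quadrature filter bank and combined vesselness map.

A quadrature filter is a complex-valued bandpass filter whose magnitude
response measures local signal energy independently of phase; a log-Gabor
radial profile guarantees zero response at zero frequency, so the map is
invariant to constant intensity offsets.  The bank has, per scale ``s``, a
center frequency ``w0 = 2**-s`` cycles/pixel (the side length ``N`` cancels
out of ``w0 = 2**(log2(N) - s) / N``), a 2-octave bandwidth, and eight
orientations ``theta_j = (j-1) * pi / 8`` with Gaussian angular windows sized
for near-uniform coverage of the Fourier half-plane.

Responses are combined by summing over orientations per scale, then by an
amplitude-cubed weighted mean over scales,

    P = sum_n q_n |q_n|^3 / sum_n |q_n|^3,

and regularized into the real vesselness map

    LP = Re{ P |P| / (|P|^2 + sigma^2) },

which is bounded by 1 in magnitude for sigma >= 1 and high on bright tubular
structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LogGaborBank",
    "QuadratureResult",
    "build_bank",
    "apply_bank",
    "combine_orientations",
    "combine_scales",
    "vesselness",
    "enhance",
]

N_ORIENT = 8


def _next_pow2(n: int) -> int:
    return 1 << (n - 1).bit_length()


@dataclass
class LogGaborBank:
    """Frequency-domain log-Gabor filters for ``n_scales`` scales x 8 orientations.

    ``filters[s][j]`` is a real nonnegative (M, M) gain grid in FFT layout for
    scale index ``s+1`` and orientation ``theta_j``; the DC gain is exactly
    zero.  ``size`` is the (power-of-two) padded side length the bank was
    built for.
    """

    size: int
    n_scales: int
    bandwidth_octaves: float = 2.0
    angular_sigma: float = math.pi / N_ORIENT
    s_start: int = 1
    filters: list = field(default_factory=list, repr=False)

    @property
    def center_frequencies(self) -> np.ndarray:
        """cycles/pixel, per scale: w0(s) = 2**-s for s = s_start..s_start+n_scales-1."""
        return 2.0 ** -np.arange(self.s_start, self.s_start + self.n_scales)

    @property
    def orientations(self) -> np.ndarray:
        return np.arange(N_ORIENT) * math.pi / N_ORIENT


@dataclass
class QuadratureResult:
    """Per-stage responses of the bank: q_nj -> q_n -> P -> LP."""

    q_nj: np.ndarray  # complex, (n_scales, 8, H, W)
    q_n: np.ndarray | None = None  # complex, (n_scales, H, W)
    P: np.ndarray | None = None  # complex, (H, W)
    sigma: float | None = None
    LP: np.ndarray | None = None  # real, (H, W)


def build_bank(
    N: int,
    n_s: int,
    bandwidth_octaves: float = 2.0,
    angular_sigma: float = math.pi / N_ORIENT,
    s_start: int = 1,
) -> LogGaborBank:
    """Construct the filter bank for images of side length ``N``.

    Non-power-of-two sizes are handled by building the bank for the next
    power of two; :func:`apply_bank` pads and crops accordingly.  The radial
    profile is ``exp(-ln^2(f/w0) / (2 s_ln^2))`` with ``s_ln`` set by the
    octave bandwidth; the angular window is a Gaussian in angular distance to
    the filter orientation (single-lobed, so the spatial response is a
    complex analytic quadrature pair).

    ``s_start`` selects which members of the dyadic scale family the bank
    starts from (``s_start=1`` is the finest, with ``w0 = 0.5``); coarser
    starts suit wider tubular structures.
    """
    if N < 32:
        raise ValueError(f"N must be >= 32, got {N}")
    M = _next_pow2(N)
    if not (1 <= n_s <= math.log2(M) - 2):
        raise ValueError(f"n_s must be in [1, log2(N)-2], got {n_s} for N={M}")
    if s_start < 1 or s_start + n_s - 1 > math.log2(M) - 2:
        raise ValueError(f"scale range [{s_start}, {s_start + n_s - 1}] out of bounds for N={M}")
    # s_ln such that the full width at half maximum spans `bandwidth_octaves`.
    s_ln = bandwidth_octaves * math.log(2) / (2.0 * math.sqrt(2.0 * math.log(2)))
    fy = np.fft.fftfreq(M)[:, None]
    fx = np.fft.fftfreq(M)[None, :]
    f = np.hypot(fy, fx)
    phi = np.arctan2(fy, fx)
    bank = LogGaborBank(M, n_s, bandwidth_octaves, angular_sigma, s_start)
    with np.errstate(divide="ignore"):
        logf = np.where(f > 0, np.log(np.maximum(f, 1e-300)), 0.0)
    for s in range(s_start, s_start + n_s):
        w0 = 2.0**-s
        radial = np.exp(-((logf - math.log(w0)) ** 2) / (2.0 * s_ln**2))
        radial[f == 0] = 0.0  # zero DC, exactly
        per_scale = []
        for theta in bank.orientations:
            d = np.angle(np.exp(1j * (phi - theta)))  # wrapped to (-pi, pi]
            angular = np.exp(-(d**2) / (2.0 * angular_sigma**2))
            per_scale.append(radial * angular)
        bank.filters.append(per_scale)
    return bank


def apply_bank(pixels: np.ndarray, bank: LogGaborBank) -> QuadratureResult:
    """Filter an image with every (scale, orientation) filter of the bank.

    The image is reflectively padded to the bank's power-of-two size,
    transformed once, multiplied by each frequency-domain filter, inverse
    transformed, and cropped back.  Responses are complex quadrature pairs.
    """
    pixels = np.asarray(pixels, dtype=float)
    if not np.isfinite(pixels).all():
        raise ValueError("pixels must be finite")
    h, w = pixels.shape
    M = bank.size
    if h > M or w > M:
        raise ValueError(f"image {pixels.shape} larger than bank size {M}")
    pad_h, pad_w = M - h, M - w
    padded = np.pad(pixels, ((0, pad_h), (0, pad_w)), mode="symmetric") if (pad_h or pad_w) else pixels
    F = np.fft.fft2(padded)
    q = np.empty((bank.n_scales, N_ORIENT, h, w), dtype=complex)
    for s in range(bank.n_scales):
        for j in range(N_ORIENT):
            q[s, j] = np.fft.ifft2(F * bank.filters[s][j])[:h, :w]
    return QuadratureResult(q_nj=q)


def combine_orientations(result: QuadratureResult) -> QuadratureResult:
    """Complex sum of the eight orientation responses at each scale."""
    result.q_n = result.q_nj.sum(axis=1)
    return result


def combine_scales(result: QuadratureResult) -> QuadratureResult:
    """Amplitude-cubed weighted mean of per-scale responses; 0 where all vanish."""
    if result.q_n is None:
        combine_orientations(result)
    mag3 = np.abs(result.q_n) ** 3
    num = (result.q_n * mag3).sum(axis=0)
    den = mag3.sum(axis=0)
    result.P = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0 + 0.0j)
    return result


def vesselness(result: QuadratureResult, sigma: float = 3.0) -> QuadratureResult:
    """Regularized real part of the combined response.

    ``sigma`` suppresses noise-driven responses; any value above 1 gives
    near-identical maps, and 3 is the default.  ``|LP| < 1`` everywhere for
    ``sigma > 0``.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if result.P is None:
        combine_scales(result)
    P = result.P
    result.sigma = float(sigma)
    result.LP = np.real(P * np.abs(P) / (np.abs(P) ** 2 + sigma**2))
    return result


def enhance(
    pixels: np.ndarray, n_s: int = 2, sigma: float = 3.0, s_start: int = 1, **bank_kwargs
) -> np.ndarray:
    """Full vesselness chain: bank construction through the LP map."""
    pixels = np.asarray(pixels, dtype=float)
    bank = build_bank(
        max(pixels.shape[0], pixels.shape[1], 32), n_s, s_start=s_start, **bank_kwargs
    )
    result = apply_bank(pixels, bank)
    combine_orientations(result)
    combine_scales(result)
    vesselness(result, sigma)
    return result.LP
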