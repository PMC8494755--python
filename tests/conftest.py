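import warnings

import numpy as np
import pytest

from ffaleak import segmentation as sg
from ffaleak import synthetic as syn


@pytest.fixture(scope="session")
def default_phantom():
    """One default-condition phantom sequence with ground truth."""
    return syn.generate_sequence(syn.PhantomSpec(), seed=11)


@pytest.fixture(scope="session")
def still_phantom():
    """A phantom sequence without inter-frame motion (identity jitter)."""
    spec = syn.PhantomSpec(jitter_translation_max=0.0, jitter_angle_max=0.0)
    return syn.generate_sequence(spec, seed=3)


@pytest.fixture(scope="session")
def still_frame(still_phantom):
    seq, truth = still_phantom
    return seq[0], truth


@pytest.fixture(scope="session")
def still_vessel_mask(still_frame):
    frame, truth = still_frame
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sg.large_vessel_mask(frame)


# ---------------------------------------------------------------- oracles


def opening_oracle(values: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Brute-force sliding-window grayscale opening with symmetric extension.

    Independent of the scipy-based implementation: explicit min-then-max
    loops over the structuring-element offsets on a symmetrically padded
    copy, cropped back to the original frame.
    """
    values = np.asarray(values, dtype=float)
    k = se.shape[0]
    pad = 2 * k
    padded = np.pad(values, pad, mode="symmetric")
    offs = [(int(r) - k // 2, int(c) - k // 2) for r, c in np.argwhere(se)]
    h, w = padded.shape
    er = np.full_like(padded, np.inf)
    for dr, dc in offs:
        shifted = np.full_like(padded, np.inf)
        rs = slice(max(0, -dr), min(h, h - dr))
        cs = slice(max(0, -dc), min(w, w - dc))
        shifted[rs, cs] = padded[
            max(0, dr) : min(h, h + dr), max(0, dc) : min(w, w + dc)
        ]
        er = np.minimum(er, shifted)
    di = np.full_like(padded, -np.inf)
    for dr, dc in offs:
        shifted = np.full_like(padded, -np.inf)
        rs = slice(max(0, dr), min(h, h + dr))
        cs = slice(max(0, dc), min(w, w + dc))
        shifted[rs, cs] = er[
            max(0, -dr) : min(h, h - dr), max(0, -dc) : min(w, w - dc)
        ]
        di = np.maximum(di, shifted)
    return di[pad:-pad, pad:-pad]


def hysteresis_oracle(values: np.ndarray, t_low: float, t_high: float) -> np.ndarray:
    """Flood-fill hysteresis: BFS over the 8-neighborhood from high seeds."""
    from collections import deque

    values = np.asarray(values, dtype=float)
    low = values >= t_low
    out = np.zeros(values.shape, dtype=bool)
    seeds = deque(map(tuple, np.argwhere(values >= t_high)))
    h, w = values.shape
    while seeds:
        r, c = seeds.popleft()
        if out[r, c] or not low[r, c]:
            continue
        out[r, c] = True
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and low[rr, cc] and not out[rr, cc]:
                    seeds.append((rr, cc))
    return out


def otsu_oracle(values: np.ndarray) -> float:
    """Exhaustive 256-bin between-class-variance search (plain Python loop)."""
    values = np.asarray(values, dtype=float).ravel()
    hist, edges = np.histogram(values, bins=256, range=(values.min(), values.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    n = hist.sum()
    best_k, best = 0, -np.inf
    for k in range(255):
        n0 = hist[: k + 1].sum()
        n1 = n - n0
        if n0 == 0 or n1 == 0:
            continue
        mu0 = (hist[: k + 1] * centers[: k + 1]).sum() / n0
        mu1 = (hist[k + 1 :] * centers[k + 1 :]).sum() / n1
        score = (n0 / n) * (n1 / n) * (mu0 - mu1) ** 2
        if score > best:
            best, best_k = score, k
    return float(edges[best_k + 1])


@pytest.fixture(scope="session")
def oracles():
    return {
        "opening": opening_oracle,
        "hysteresis": hysteresis_oracle,
        "otsu": otsu_oracle,
    }
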