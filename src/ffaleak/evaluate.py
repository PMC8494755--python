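"""Agreement of method quantifications with reference annotations.

Given leakage masks from the method and from two independent annotators
("ground truth 1" and "ground truth 2"), the leakage fluorescence intensity
``L`` (summed leakage-image intensity inside a mask) and leakage area ``A``
are compared by relative differences,

    |L - L_ref| / L_ref,

averaged over frames, for each choice of reference — so the method-vs-
reference difference can be judged against the inter-annotator difference.
Pearson correlations between the method and reference series are reported
alongside.  Intensities are compared unnormalized (no first-frame
subtraction), since normalizing would pin the first frame of every series to
zero and mask genuine disagreement there.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "relative_difference",
    "agreement_table",
    "annotation_quantities",
    "load_annotation_masks",
]


def relative_difference(x: float, ref: float) -> float:
    """|x - ref| / ref.  Not symmetric in its arguments; ``ref`` must be > 0."""
    if ref <= 0:
        raise ValueError(f"reference value must be > 0, got {ref}")
    return abs(x - ref) / ref


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")  # undefined for constant series -> NA
    return float(np.corrcoef(x, y)[0, 1])


def agreement_table(
    method,
    ref1,
    ref2,
    labels: tuple[str, str, str] = ("method", "gt1", "gt2"),
) -> pd.DataFrame:
    """Mean +- SD of relative differences, per reference, plus Pearson r.

    Rows pair each reference annotator with each compared series (the method
    and the other annotator), mirroring a table whose rows are the reference
    used and whose columns are the compared quantifications.
    """
    method = np.asarray(method, dtype=float)
    ref1 = np.asarray(ref1, dtype=float)
    ref2 = np.asarray(ref2, dtype=float)
    if not (len(method) == len(ref1) == len(ref2)):
        raise ValueError("series lengths differ")
    name_m, name_1, name_2 = labels
    rows = []
    for ref_name, ref in ((name_1, ref1), (name_2, ref2)):
        others = [(name_m, method), (name_1, ref1), (name_2, ref2)]
        for other_name, other in others:
            if other_name == ref_name:
                continue
            rd = np.array([relative_difference(x, r) for x, r in zip(other, ref)])
            rows.append(
                {
                    "reference": ref_name,
                    "series": other_name,
                    "mean_rel_diff": rd.mean(),
                    "std_rel_diff": rd.std(),
                    "pearson": _pearson(other, ref),
                }
            )
    return pd.DataFrame(rows)


def annotation_quantities(leak_images, masks) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame leakage intensity (sum of leakage image in mask) and area (pixels)."""
    L, A = [], []
    for li, m in zip(leak_images, masks):
        m = np.asarray(m, dtype=bool)
        L.append(float(li.values[m].sum()))
        A.append(int(m.sum()))
    return np.asarray(L), np.asarray(A, dtype=float)


def load_annotation_masks(directory, pattern: str = "*.png") -> list[np.ndarray]:
    """Read a directory of 0/255 PNG masks (sorted by filename) as boolean grids."""
    import imageio.v3 as iio
    from pathlib import Path

    paths = sorted(Path(directory).glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no masks matching {pattern} in {directory}")
    return [np.asarray(iio.imread(p)) > 127 for p in paths]
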