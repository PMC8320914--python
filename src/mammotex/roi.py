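"""Breast-region masking, fibroglandular ROI extraction and image IO.

A mediolateral-oblique mammogram contains the breast, background
annotations and (usually) a pectoral-muscle wedge in one corner.  The
pipeline here is deliberately simple: a global Otsu threshold isolates the
bright foreground, the largest connected component is kept and its holes
filled, and an optional straight-line corner cut approximates
pectoral-muscle removal.  The centre of the fibroglandular disk is then
located as the intersection of the longest vertical and longest horizontal
foreground runs, and a square ROI is cropped around it (clamped to stay
inside the image) and median-filtered.

Coordinates are 0-based ``(x=column, y=row)`` with pixel centres at
integers.  Labels follow the three-class density scheme Fatty / Glandular
/ Dense, abbreviated ``F`` / ``G`` / ``D``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

__all__ = [
    "CLASS_LABELS",
    "BreastMask",
    "RoiSpec",
    "read_image",
    "write_pgm",
    "read_labels",
    "write_labels",
    "breast_mask",
    "fibroglandular_center",
    "extract_roi",
    "random_subroi",
    "median_denoise",
    "prepare_roi",
]

CLASS_LABELS = ("F", "G", "D")


# ---------------------------------------------------------------------------
# IO: 8-bit grayscale PGM/PNG readers, PGM (P5) writer, label CSV.

def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a grayscale image (PGM binary/ASCII or PNG) as uint8."""
    arr = iio.imread(path)
    if arr.ndim == 3:  # RGB(A) PNG: take luminance-equivalent first channel
        arr = arr[..., 0]
    if arr.dtype != np.uint8:
        arr = arr.astype(np.float64)
        lo, hi = arr.min(), arr.max()
        arr = np.zeros_like(arr) if hi == lo else (arr - lo) * (255.0 / (hi - lo))
        arr = np.rint(arr).astype(np.uint8)
    return arr


def write_pgm(path: str | os.PathLike, img: np.ndarray) -> None:
    """Write a 2-D uint8 array as a binary (P5) PGM file."""
    a = np.asarray(img)
    if a.ndim != 2 or a.dtype != np.uint8:
        raise ValueError("write_pgm expects a 2-D uint8 array")
    h, w = a.shape
    with open(path, "wb") as fh:
        fh.write(f"P5\n{w} {h}\n255\n".encode("ascii"))
        fh.write(a.tobytes())


def read_labels(path: str | os.PathLike) -> pd.DataFrame:
    """Read an ``image_id,class`` CSV; classes must be in {F, G, D}."""
    df = pd.read_csv(path, dtype=str)
    missing = {"image_id", "class"} - set(df.columns)
    if missing:
        raise ValueError(f"label file lacks columns: {sorted(missing)}")
    bad = set(df["class"]) - set(CLASS_LABELS)
    if bad:
        raise ValueError(f"unknown class labels: {sorted(bad)}")
    return df[["image_id", "class"]]


def write_labels(path: str | os.PathLike, records: Iterable[tuple[str, str]]) -> None:
    pd.DataFrame(records, columns=["image_id", "class"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Masking and geometry.

@dataclass
class BreastMask:
    """Binary breast-region mask plus the thresholding provenance."""

    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("breast mask is empty")


def breast_mask(
    img: np.ndarray,
    pectoral_cut: bool = False,
    pectoral_corner: str = "left",
    pectoral_frac: float = 0.25,
) -> BreastMask:
    """Segment the breast: Otsu threshold, largest component, hole filling.

    ``pectoral_cut`` optionally removes a straight-edged triangle of
    relative leg length ``pectoral_frac`` from the chosen top corner, a
    coarse stand-in for dedicated pectoral-muscle segmentation.
    """
    a = np.asarray(img)
    if a.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if a.max() == a.min():
        raise ValueError("image has no contrast: empty foreground")
    thr = threshold_otsu(a)
    fg = a > thr
    if not fg.any():
        raise ValueError("empty foreground after thresholding")
    lab = measure.label(fg, connectivity=2)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    mask = lab == int(np.argmax(counts))
    mask = ndimage.binary_fill_holes(mask)
    prov = {"threshold": float(thr), "pectoral_cut": pectoral_cut}
    if pectoral_cut:
        h, w = mask.shape
        yy, xx = np.mgrid[0:h, 0:w]
        lx, ly = pectoral_frac * w, pectoral_frac * h
        if pectoral_corner == "left":
            tri = (xx / lx + yy / ly) < 1.0
        elif pectoral_corner == "right":
            tri = ((w - 1 - xx) / lx + yy / ly) < 1.0
        else:
            raise ValueError("pectoral_corner must be 'left' or 'right'")
        mask = mask & ~tri
        if not mask.any():
            raise ValueError("pectoral cut removed the whole foreground")
        # the cut may split the component; keep the largest piece again
        lab = measure.label(mask, connectivity=2)
        counts = np.bincount(lab.ravel())
        counts[0] = 0
        mask = lab == int(np.argmax(counts))
        prov.update(corner=pectoral_corner, frac=pectoral_frac)
    return BreastMask(mask=mask, provenance=prov)


def _longest_run(col: np.ndarray) -> int:
    """Length of the longest run of consecutive True values."""
    padded = np.concatenate([[0], col.astype(np.int8), [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    if starts.size == 0:
        return 0
    ends = np.flatnonzero(d == -1)
    return int((ends - starts).max())


def fibroglandular_center(mask: BreastMask | np.ndarray) -> tuple[int, int]:
    """Centre of the fibroglandular disk as the intersection of the longest
    vertical and longest horizontal foreground runs.

    Returns ``(x, y)``; ties between equally long runs are broken toward
    the lowest index (the chest-wall side for left-flush MLO views).
    """
    m = mask.mask if isinstance(mask, BreastMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    col_runs = np.array([_longest_run(m[:, x]) for x in range(m.shape[1])])
    row_runs = np.array([_longest_run(m[y, :]) for y in range(m.shape[0])])
    return int(np.argmax(col_runs)), int(np.argmax(row_runs))


@dataclass(frozen=True)
class RoiSpec:
    """Square ROI description: ``center`` (x, y), ``side`` length in pixels
    and mode (``fibroglandular`` crop or masked ``whole_breast``)."""

    center: tuple[int, int]
    side: int = 256
    mode: str = "fibroglandular"

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise ValueError("ROI side must be positive")
        if self.mode not in ("fibroglandular", "whole_breast"):
            raise ValueError("mode must be 'fibroglandular' or 'whole_breast'")


def extract_roi(
    img: np.ndarray, spec: RoiSpec, mask: BreastMask | None = None
) -> np.ndarray:
    """Crop the ROI described by ``spec`` from ``img``.

    The crop window is clamped so it never leaves the image.  In
    ``whole_breast`` mode the masked breast region (cropped to its
    bounding box, background zeroed) is returned instead.
    """
    a = np.asarray(img)
    h, w = a.shape
    if spec.mode == "whole_breast":
        if mask is None:
            raise ValueError("whole_breast mode requires a mask")
        m = mask.mask
        ys, xs = np.nonzero(m)
        y0, y1 = ys.min(), ys.max() + 1
        x0, x1 = xs.min(), xs.max() + 1
        return (a * m)[y0:y1, x0:x1]
    side = spec.side
    if h < side or w < side:
        raise ValueError(f"image {w}x{h} smaller than ROI side {side}")
    cx, cy = spec.center
    x0 = int(np.clip(cx - side // 2, 0, w - side))
    y0 = int(np.clip(cy - side // 2, 0, h - side))
    return a[y0 : y0 + side, x0 : x0 + side]


def random_subroi(roi: np.ndarray, side: int, seed: int) -> np.ndarray:
    """Uniformly placed square sub-crop of an ROI, for ROI-size sweeps.

    Smaller ROIs (e.g. 100 or 200 px out of a 256-px fibroglandular crop)
    are placed at a seeded uniform random offset so the sweep is
    reproducible.
    """
    a = np.asarray(roi)
    h, w = a.shape
    if side > min(h, w):
        raise ValueError(f"sub-ROI side {side} exceeds ROI {w}x{h}")
    rng = np.random.default_rng(seed)
    x0 = int(rng.integers(0, w - side + 1))
    y0 = int(rng.integers(0, h - side + 1))
    return a[y0 : y0 + side, x0 : x0 + side]


def median_denoise(img: np.ndarray) -> np.ndarray:
    """3x3 median filter with reflected borders."""
    return ndimage.median_filter(np.asarray(img), size=3, mode="reflect")


def prepare_roi(
    img: np.ndarray,
    side: int = 256,
    denoise: bool = True,
    pectoral_cut: bool = False,
) -> np.ndarray:
    """Full preprocessing chain: mask -> centre -> crop -> median filter."""
    bm = breast_mask(img, pectoral_cut=pectoral_cut)
    center = fibroglandular_center(bm)
    out = extract_roi(img, RoiSpec(center=center, side=side))
    return median_denoise(out) if denoise else out
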