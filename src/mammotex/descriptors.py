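"""Local texture descriptors for grayscale tissue images.

Five descriptor families are implemented, all producing a per-pixel integer
code over the interior of an image:

``lbp``
    Classic local binary pattern: each of the P neighbours sampled on a
    circle of radius R is thresholded against the centre intensity and the
    resulting bits are weighted ``2**(i-1)`` for neighbour i = 1..P.
``elbp``
    Elliptical LBP: neighbours lie on an ellipse with semi-axes R1
    (horizontal) and R2 (vertical), optionally rotated by an orientation
    theta.  With R1 == R2 it degenerates exactly to the circular LBP.
``uelbp``
    ELBP restricted to *uniform* patterns (at most two circular 0<->1 bit
    transitions); uniform codes keep individual histogram bins while all
    non-uniform codes share a single bin (59 bins for P = 8).
``melbp``
    Mean-ELBP: each elliptical neighbour is replaced by the mean intensity
    of a small (default 3x3) window centred on the nearest pixel, making
    the comparison robust to pixel-level noise.
``ldp``
    Local directional pattern: the eight Kirsch compass kernels measure
    directional edge strength; the bits of the k strongest absolute
    responses are set, so every code has popcount k.

Geometry convention: coordinates are ``(x, y)`` with x = column and
y = row, 0-based, pixel centres at integers, y increasing downwards.
Neighbour i = 1 sits at angle 0 (east) and the ring proceeds
counter-clockwise (upwards on screen).  Non-integer sampling positions are
resolved by bilinear interpolation by default; nearest-pixel rounding is
available as a configuration option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "FAMILIES",
    "CANONICAL_ORIENTATIONS",
    "PixelNeighborhood",
    "EllipseSpec",
    "DescriptorConfig",
    "CodeImage",
    "threshold_step",
    "lbp_code",
    "ellipse_coords",
    "sample_intensity",
    "elbp_code",
    "melbp_code",
    "transition_count",
    "uniform_bin_index",
    "uniform_bin_count",
    "uniform_bin_map",
    "kirsch_kernels",
    "kirsch_responses",
    "ldp_code",
    "code_image",
]

FAMILIES = ("lbp", "elbp", "uelbp", "melbp", "ldp")

#: The eight orientations at which elliptical descriptors are evaluated.
CANONICAL_ORIENTATIONS = (0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0)


def threshold_step(x: float) -> int:
    """Unit step s(x): 1 if ``x >= 0`` else 0."""
    if not math.isfinite(x):
        raise ValueError("threshold_step requires a finite input")
    return 1 if x >= 0 else 0


def _round_half_up(v: float) -> int:
    # Consistent half-up rounding; avoids numpy's banker's rounding so the
    # scalar and vectorised code paths agree.
    return int(math.floor(v + 0.5))


@dataclass(frozen=True)
class PixelNeighborhood:
    """Centre intensity g_c and its ordered ring of neighbour intensities.

    Neighbours are indexed i = 1..P counter-clockwise starting at angle 0.
    """

    center_value: float
    neighbor_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.neighbor_values) < 1:
            raise ValueError("a neighborhood needs at least one neighbor")

    @property
    def p(self) -> int:
        return len(self.neighbor_values)


def lbp_code(nb: PixelNeighborhood) -> int:
    """Binary-pattern code of a neighbourhood: sum_i s(g_i - g_c) 2^(i-1)."""
    code = 0
    for i, g in enumerate(nb.neighbor_values):
        code |= threshold_step(g - nb.center_value) << i
    return code


@dataclass(frozen=True)
class EllipseSpec:
    """Sampling ellipse: semi-axes ``r1`` (horizontal) and ``r2``
    (vertical), orientation ``theta`` in degrees, ``p`` neighbours."""

    r1: float
    r2: float
    theta: float = 0.0
    p: int = 8

    def __post_init__(self) -> None:
        if self.r1 <= 0 or self.r2 <= 0:
            raise ValueError("ellipse semi-axes must be positive")
        if self.p < 1:
            raise ValueError("need at least one neighbor")

    @property
    def anglestep(self) -> float:
        return 2.0 * math.pi / self.p

    @property
    def reach(self) -> float:
        """Largest axis-aligned offset any sampled point can have."""
        return max(self.r1, self.r2)


def ellipse_coords(center: tuple[float, float], spec: EllipseSpec) -> np.ndarray:
    """Ordered (P, 2) array of ``(x, y)`` sampling coordinates.

    The canonical point i is ``(x_c + r1*cos((i-1)*anglestep),
    y_c - r2*sin((i-1)*anglestep))``; a nonzero ``theta`` rotates the
    canonical offsets about the centre (counter-clockwise on screen, i.e.
    in image coordinates with y pointing down).
    """
    xc, yc = center
    ang = np.arange(spec.p) * spec.anglestep
    dx = spec.r1 * np.cos(ang)
    dy = -spec.r2 * np.sin(ang)
    t = math.radians(spec.theta)
    ct, st = math.cos(t), math.sin(t)
    rx = dx * ct + dy * st
    ry = -dx * st + dy * ct
    # snap float residue (e.g. cos(pi/2) ~ 6e-17) so axis-aligned samples
    # land exactly on pixel centres and never decide a threshold tie
    return np.round(np.column_stack([xc + rx, yc + ry]), 8)


def sample_intensity(img: np.ndarray, coord: tuple[float, float]) -> float:
    """Bilinear intensity at a real-valued ``(x, y)`` coordinate.

    Integer coordinates return the pixel value exactly.  Coordinates
    outside ``[0, W-1] x [0, H-1]`` raise ``ValueError``.
    """
    a = np.asarray(img, dtype=float)
    x, y = coord
    h, w = a.shape
    if not (0.0 <= x <= w - 1 and 0.0 <= y <= h - 1):
        raise ValueError(f"coordinate {coord!r} outside image bounds {w}x{h}")
    x0, y0 = int(math.floor(x)), int(math.floor(y))
    x1, y1 = min(x0 + 1, w - 1), min(y0 + 1, h - 1)
    tx, ty = x - x0, y - y0
    v00, v01 = a[y0, x0], a[y0, x1]
    v10, v11 = a[y1, x0], a[y1, x1]
    # incremental form: exact at equal corners and equivariant under
    # adding/scaling a constant intensity
    return float(
        v00
        + tx * (v01 - v00)
        + ty * (v10 - v00)
        + tx * ty * (v00 - v01 - v10 + v11)
    )


def _sample(img: np.ndarray, x: float, y: float, sampling: str) -> float:
    if sampling == "nearest":
        h, w = img.shape
        xi, yi = _round_half_up(x), _round_half_up(y)
        if not (0 <= xi < w and 0 <= yi < h):
            raise ValueError(f"coordinate ({x}, {y}) outside image bounds")
        return float(img[yi, xi])
    return sample_intensity(img, (x, y))


def elbp_code(
    img: np.ndarray,
    center: tuple[int, int],
    spec: EllipseSpec,
    sampling: str = "bilinear",
) -> int:
    """Elliptical LBP code at an integer pixel ``(x, y)``."""
    a = np.asarray(img, dtype=float)
    xc, yc = center
    gc = a[yc, xc]
    code = 0
    for i, (xi, yi) in enumerate(ellipse_coords((xc, yc), spec)):
        code |= threshold_step(_sample(a, xi, yi, sampling) - gc) << i
    return code


def melbp_code(
    img: np.ndarray,
    center: tuple[int, int],
    spec: EllipseSpec,
    mean_window: int = 3,
) -> int:
    """Mean-ELBP code: each neighbour is the mean of a
    ``mean_window`` x ``mean_window`` patch centred on the nearest pixel."""
    if mean_window < 1 or mean_window % 2 == 0:
        raise ValueError("mean_window must be odd and positive")
    a = np.asarray(img, dtype=float)
    h, w = a.shape
    hw = mean_window // 2
    xc, yc = center
    gc = a[yc, xc]
    code = 0
    for i, (xi, yi) in enumerate(ellipse_coords((xc, yc), spec)):
        xr, yr = _round_half_up(xi), _round_half_up(yi)
        if xr - hw < 0 or yr - hw < 0 or xr + hw >= w or yr + hw >= h:
            raise ValueError("mean window extends outside the image")
        # Compare window sum against n*g_c rather than the mean against g_c:
        # identical sign, but exact for integer-valued images.
        gsum = a[yr - hw : yr + hw + 1, xr - hw : xr + hw + 1].sum()
        code |= threshold_step(gsum - mean_window * mean_window * gc) << i
    return code


def transition_count(code: int, p: int) -> int:
    """Number of circular 0<->1 transitions in the P-bit code."""
    if not 0 <= code < (1 << p):
        raise ValueError(f"code {code} out of range for P={p}")
    t = 0
    for i in range(p):
        if ((code >> i) & 1) != ((code >> ((i + 1) % p)) & 1):
            t += 1
    return t


@lru_cache(maxsize=None)
def _uniform_lut(p: int) -> tuple[tuple[int, ...], int]:
    uniform = tuple(c for c in range(1 << p) if transition_count(c, p) <= 2)
    return uniform, len(uniform) + 1


def uniform_bin_count(p: int) -> int:
    """Number of histogram bins under the uniform-pattern mapping
    (58 uniform bins + 1 shared non-uniform bin = 59 for P = 8)."""
    return _uniform_lut(p)[1]


def uniform_bin_map(p: int) -> np.ndarray:
    """Lookup table mapping every P-bit code to its uniform bin index.

    Uniform codes map injectively, in ascending code order, to bins
    ``0 .. n_uniform - 1``; all non-uniform codes share the last bin.
    """
    uniform, nbins = _uniform_lut(p)
    table = np.full(1 << p, nbins - 1, dtype=np.int64)
    table[list(uniform)] = np.arange(len(uniform))
    return table


def uniform_bin_index(code: int, p: int) -> int:
    if not 0 <= code < (1 << p):
        raise ValueError(f"code {code} out of range for P={p}")
    return int(uniform_bin_map(p)[code])


# Ring of 3x3 cells (row, col) counter-clockwise starting east; used to
# rotate the Kirsch +5 column around the compass.
_RING_RC = ((1, 2), (0, 2), (0, 1), (0, 0), (1, 0), (2, 0), (2, 1), (2, 2))


@lru_cache(maxsize=1)
def kirsch_kernels() -> tuple[np.ndarray, ...]:
    """The eight 3x3 Kirsch compass kernels M_0..M_7.

    M_0 points east (+5 entries in the right column), and M_j is M_0
    rotated counter-clockwise by j*45 degrees.  Each kernel has five -3
    entries, three +5 entries and a 0 centre, so coefficients sum to 0.
    """
    kernels = []
    for j in range(8):
        k = np.full((3, 3), -3.0)
        k[1, 1] = 0.0
        for d in (-1, 0, 1):
            r, c = _RING_RC[(j + d) % 8]
            k[r, c] = 5.0
        k.setflags(write=False)
        kernels.append(k)
    return tuple(kernels)


def kirsch_responses(img: np.ndarray, center: tuple[int, int]) -> np.ndarray:
    """Eight signed directional edge responses m_0..m_7 at a pixel."""
    a = np.asarray(img, dtype=float)
    h, w = a.shape
    x, y = center
    if not (1 <= x <= w - 2 and 1 <= y <= h - 2):
        raise ValueError("Kirsch responses need the full 3x3 neighborhood")
    patch = a[y - 1 : y + 2, x - 1 : x + 2]
    return np.array([float((patch * k).sum()) for k in kirsch_kernels()])


def ldp_code(responses: Sequence[float], k: int) -> int:
    """Directional-pattern code: bit j set iff |m_j| ranks in the top k.

    Ties in |m_j| are broken toward the lower index, so the code is
    deterministic and always has exactly k set bits.
    """
    r = np.asarray(responses, dtype=float)
    if r.shape != (8,):
        raise ValueError("ldp_code expects exactly 8 responses")
    if not 0 <= k <= 8:
        raise ValueError("k must lie in [0, 8]")
    order = np.argsort(-np.abs(r), kind="stable")
    code = 0
    for j in order[:k]:
        code |= 1 << int(j)
    return code


@dataclass(frozen=True)
class DescriptorConfig:
    """Which descriptor to compute and with what geometry.

    Only the fields relevant to ``family`` are consulted: ``radius`` for
    lbp; ``r1``/``r2``/``orientations`` for the elliptical families;
    ``k`` for ldp; ``mean_window`` for melbp.
    """

    family: str
    p: int = 8
    radius: float = 2.0
    r1: float = 4.0
    r2: float = 7.0
    k: int = 3
    mean_window: int = 3
    orientations: tuple[float, ...] = CANONICAL_ORIENTATIONS
    sampling: str = "bilinear"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown descriptor family {self.family!r}")
        if self.p < 1:
            raise ValueError("P must be positive")
        if self.family == "ldp":
            if self.p != 8:
                raise ValueError("ldp is defined on the 8 compass directions")
            if not 0 <= self.k <= 8:
                raise ValueError("ldp k must lie in [0, 8]")
        if self.mean_window < 1 or self.mean_window % 2 == 0:
            raise ValueError("mean_window must be odd and positive")
        if self.sampling not in ("bilinear", "nearest"):
            raise ValueError("sampling must be 'bilinear' or 'nearest'")
        if self.family in ("elbp", "uelbp", "melbp") and not self.orientations:
            raise ValueError("elliptical families need at least one orientation")

    def ellipse(self, theta: float = 0.0) -> EllipseSpec:
        if self.family == "lbp":
            return EllipseSpec(self.radius, self.radius, 0.0, self.p)
        return EllipseSpec(self.r1, self.r2, theta, self.p)

    @property
    def margin(self) -> int:
        """Border width excluded from coding so no sample leaves the image."""
        if self.family == "ldp":
            return 1
        if self.family == "lbp":
            return math.ceil(self.radius)
        m = math.ceil(max(self.r1, self.r2))
        if self.family == "melbp":
            m += (self.mean_window - 1) // 2
        return m

    @property
    def n_bins(self) -> int:
        """Histogram length per orientation block."""
        if self.family == "uelbp":
            return uniform_bin_count(self.p)
        return 1 << self.p

    @property
    def orientation_set(self) -> tuple[float, ...]:
        """Orientations a feature vector spans; lbp and ldp are isotropic
        (ldp's Kirsch responses already cover the 8 compass directions)."""
        if self.family in ("lbp", "ldp"):
            return (0.0,)
        return tuple(self.orientations)


@dataclass
class CodeImage:
    """Per-pixel descriptor codes; ``-1`` marks the invalid border ring."""

    codes: np.ndarray
    margin: int
    p: int

    def valid_codes(self) -> np.ndarray:
        return self.codes[self.codes >= 0]


def _offset_sample(imgf: np.ndarray, dx: float, dy: float, m: int) -> np.ndarray:
    """Bilinear sample of the interior grid shifted by a constant offset."""
    h, w = imgf.shape
    fx, fy = math.floor(dx), math.floor(dy)
    tx, ty = dx - fx, dy - fy

    def blk(oy: int, ox: int) -> np.ndarray:
        return imgf[m + fy + oy : h - m + fy + oy, m + fx + ox : w - m + fx + ox]

    v00 = blk(0, 0)
    out = v00.copy()
    if tx > 0:
        out += tx * (blk(0, 1) - v00)
    if ty > 0:
        out += ty * (blk(1, 0) - v00)
    if tx > 0 and ty > 0:
        out += tx * ty * (v00 - blk(0, 1) - blk(1, 0) + blk(1, 1))
    return out


def _int_offset_sample(imgf: np.ndarray, ix: int, iy: int, m: int) -> np.ndarray:
    h, w = imgf.shape
    return imgf[m + iy : h - m + iy, m + ix : w - m + ix]


def _ldp_code_image(imgf: np.ndarray, k: int) -> np.ndarray:
    resp = np.stack(
        [ndimage.correlate(imgf, kern, mode="nearest") for kern in kirsch_kernels()]
    )[:, 1:-1, 1:-1]
    order = np.argsort(-np.abs(resp), axis=0, kind="stable")
    codes = np.zeros(resp.shape[1:], dtype=np.int32)
    for r in range(k):
        codes |= np.left_shift(1, order[r]).astype(np.int32)
    return codes


def code_image(img: np.ndarray, cfg: DescriptorConfig, theta: float = 0.0) -> CodeImage:
    """Descriptor codes for every interior pixel of ``img``.

    The border ring of width ``cfg.margin`` is marked invalid (-1) so that
    no histogram ever contains codes computed from extrapolated samples.
    """
    a = np.asarray(img, dtype=float)
    if a.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    m = cfg.margin
    h, w = a.shape
    if h < 2 * m + 1 or w < 2 * m + 1:
        raise ValueError(f"image {w}x{h} smaller than 2*margin+1 = {2 * m + 1}")

    if cfg.family == "ldp":
        interior = _ldp_code_image(a, cfg.k)
    else:
        spec = cfg.ellipse(theta)
        offsets = ellipse_coords((0.0, 0.0), spec)
        center = a[m : h - m, m : w - m]
        if cfg.family == "melbp":
            # Window *sums* compared against n*g_c: same sign as the mean
            # comparison but exact for integer-valued images.
            nwin = cfg.mean_window * cfg.mean_window
            base = ndimage.correlate(
                a, np.ones((cfg.mean_window, cfg.mean_window)), mode="nearest"
            )
            ref = center * nwin
        else:
            base = a
            ref = center
        interior = np.zeros(center.shape, dtype=np.int32)
        for i, (dx, dy) in enumerate(offsets):
            if cfg.family == "melbp" or cfg.sampling == "nearest":
                s = _int_offset_sample(base, _round_half_up(dx), _round_half_up(dy), m)
            else:
                s = _offset_sample(base, float(dx), float(dy), m)
            interior |= (s >= ref).astype(np.int32) << i

    full = np.full((h, w), -1, dtype=np.int32)
    full[m : h - m, m : w - m] = interior
    return CodeImage(codes=full, margin=m, p=cfg.p)
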