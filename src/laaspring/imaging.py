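"""Apparent-CT rendering, LAA thresholding, and structural metrics.

A relaxed spring network is converted back to an image by accumulating,
for every pixel, stiffness-weighted spring length: each alive spring
contributes ``k * (segment length inside the pixel)`` to every pixel it
crosses, and the pixel intensity is that sum divided by the pixel area.
An intact uniform lattice therefore renders to a uniform image, and
carved regions render dark.  Thresholding the apparent CT at a fraction
of the intact-network interior intensity recovers an LAA map that can be
compared against the CT-derived ground truth.

Metrics:

- %LAA — LAA pixels as a percentage of the lung area;
- E_LAA — signed difference between a reconstruction's %LAA and the
  ground truth's (negative means the reconstruction under-covers);
- A_L — pixel area of the largest 4-connected LAA cluster;
- exponent D — negative log-log slope of the complementary cumulative
  cluster-size count over a fixed size window;
- D_local — mean absolute per-square %LAA difference between two LAA
  maps on a square partition, excluding squares empty in both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from numba import njit
from scipy import ndimage

from .config import DEFAULT_CONFIG, RunConfig
from .errors import ConfigurationError, LaaSpringError
from .geometry import FOUR_CONNECTED
from .network import EquilibriumState, HexSpringNetwork


# ---------------------------------------------------------------------------
# HU thresholding
# ---------------------------------------------------------------------------

def threshold_laa(
    ct_hu: np.ndarray,
    lung_mask: np.ndarray,
    lo: float = DEFAULT_CONFIG.hu_laa_threshold,
    hi: float = DEFAULT_CONFIG.hu_high_threshold,
) -> Tuple[np.ndarray, np.ndarray]:
    """Split a Hounsfield-unit slice into LAA and high-attenuation masks.

    LAA pixels are strictly below ``lo`` (default −960 HU) and
    high-attenuation pixels strictly above ``hi`` (default −500 HU),
    both restricted to the lung region.  Pixels exactly at a threshold
    belong to neither mask.
    """
    ct_hu = np.asarray(ct_hu, dtype=float)
    lung_mask = np.asarray(lung_mask, dtype=bool)
    if not lung_mask.any():
        raise LaaSpringError("lung mask is empty")
    laa = (ct_hu < lo) & lung_mask
    high = (ct_hu > hi) & lung_mask
    return laa, high


# ---------------------------------------------------------------------------
# apparent CT
# ---------------------------------------------------------------------------

@dataclass
class ApparentCT:
    """Intensity raster proportional to local spring-material density."""

    intensity: np.ndarray

    @property
    def shape(self) -> Tuple[int, int]:
        return self.intensity.shape


@njit(cache=True)
def _accumulate_segments(img, x0a, y0a, x1a, y1a, ka):  # pragma: no cover
    rows, cols = img.shape
    for s in range(len(x0a)):
        x0, y0, x1, y1 = x0a[s], y0a[s], x1a[s], y1a[s]
        k = ka[s]
        dx = x1 - x0
        dy = y1 - y0
        length = (dx * dx + dy * dy) ** 0.5
        if length <= 0.0:
            continue
        # parameter values where the segment crosses pixel borders
        # (pixel (i, j) covers [j-0.5, j+0.5) x [i-0.5, i+0.5))
        ts = np.empty(int(abs(dx)) + int(abs(dy)) + 4)
        nts = 0
        ts[nts] = 0.0
        nts += 1
        if dx != 0.0:
            step = 1.0 if dx > 0 else -1.0
            b = np.floor(x0 + 0.5) + (0.5 if dx > 0 else -0.5)
            while (b - x0) / dx < 1.0:
                t = (b - x0) / dx
                if t > 0.0:
                    ts[nts] = t
                    nts += 1
                b += step
        if dy != 0.0:
            step = 1.0 if dy > 0 else -1.0
            b = np.floor(y0 + 0.5) + (0.5 if dy > 0 else -0.5)
            while (b - y0) / dy < 1.0:
                t = (b - y0) / dy
                if t > 0.0:
                    ts[nts] = t
                    nts += 1
                b += step
        ts[nts] = 1.0
        nts += 1
        tsv = np.sort(ts[:nts])
        for i in range(nts - 1):
            t0 = tsv[i]
            t1 = tsv[i + 1]
            if t1 <= t0:
                continue
            tm = 0.5 * (t0 + t1)
            xm = x0 + tm * dx
            ym = y0 + tm * dy
            col = int(np.floor(xm + 0.5))
            row = int(np.floor(ym + 0.5))
            if 0 <= row < rows and 0 <= col < cols:
                img[row, col] += k * (t1 - t0) * length


def render_apparent_ct(
    net: HexSpringNetwork,
    state: EquilibriumState,
    grid_shape: Tuple[int, int],
    smooth_sigma: float = 0.0,
) -> ApparentCT:
    """Render a network state to an intensity raster.

    Each alive spring deposits ``stiffness * in-pixel length`` into every
    pixel it crosses (exact segment clipping at pixel borders); intensity
    is the deposit divided by the unit pixel area.  With the lattice
    pitch comparable to the pixel pitch the raw per-pixel line density
    aliases badly (a moiré of the honeycomb against the grid), so
    ``smooth_sigma`` optionally applies a Gaussian blur of that many
    pixels — the pipeline uses roughly one lattice edge, emulating a
    detector footprint of the lattice-cell scale.  ``smooth_sigma = 0``
    is the exact accumulation.
    """
    img = np.zeros(grid_shape, dtype=np.float64)
    live = net.alive
    if live.any():
        p0 = state.positions[net.edges[live, 0]]
        p1 = state.positions[net.edges[live, 1]]
        _accumulate_segments(
            img,
            np.ascontiguousarray(p0[:, 0]),
            np.ascontiguousarray(p0[:, 1]),
            np.ascontiguousarray(p1[:, 0]),
            np.ascontiguousarray(p1[:, 1]),
            np.ascontiguousarray(net.stiffness[live].astype(np.float64)),
        )
    if smooth_sigma > 0:
        img = ndimage.gaussian_filter(img, smooth_sigma)
    return ApparentCT(intensity=img)


def intact_reference_intensity(
    ct: ApparentCT, lung_mask: np.ndarray, margin: int = 3
) -> float:
    """Mean intensity of an intact-network render over the eroded lung
    interior; the self-normalizing reference for binarization."""
    lung_mask = np.asarray(lung_mask, dtype=bool)
    interior = ndimage.binary_erosion(lung_mask, iterations=margin)
    if not interior.any():
        interior = lung_mask
    return float(ct.intensity[interior].mean())


def binarize_apparent(
    ct: ApparentCT,
    lung_mask: np.ndarray,
    reference_intensity: Optional[float] = None,
    fraction: float = DEFAULT_CONFIG.binarize_fraction,
) -> np.ndarray:
    """Threshold an apparent CT into an LAA mask.

    A pixel is LAA when its intensity falls below ``fraction`` (default
    0.5) of the intact-network interior mean.  The reference intensity
    must be supplied (compute it once from the uncarved template with
    :func:`intact_reference_intensity`).
    """
    if reference_intensity is None:
        raise ConfigurationError(
            "binarize_apparent needs the intact-network reference intensity"
        )
    lung_mask = np.asarray(lung_mask, dtype=bool)
    return (ct.intensity < fraction * reference_intensity) & lung_mask


# ---------------------------------------------------------------------------
# cluster statistics
# ---------------------------------------------------------------------------

@dataclass
class ClusterStats:
    """Per-cluster sizes and summary structure metrics of an LAA mask."""

    labels: np.ndarray
    sizes: np.ndarray           # per-cluster pixel counts (label 1..n)
    pct_laa: float              # percent of lung area
    largest: int                # A_L in pixels
    exponent: float             # D; nan when the fit is undefined
    exponent_valid: bool
    fit_range: Tuple[int, int]

    @property
    def second_largest(self) -> int:
        if len(self.sizes) < 2:
            return 0
        return int(np.sort(self.sizes)[-2])


def fit_size_exponent(
    sizes: np.ndarray, fit_range: Tuple[int, int] = DEFAULT_CONFIG.fit_range
) -> Tuple[float, bool]:
    """Negative slope of log10 N(S >= s) vs log10 s over ``fit_range``.

    The complementary cumulative count is evaluated at every distinct
    cluster size inside the window; the fit needs at least 3 distinct
    sizes there, otherwise (nan, False) is returned.
    """
    sizes = np.asarray(sizes)
    lo, hi = fit_range
    distinct = np.unique(sizes[(sizes >= lo) & (sizes <= hi)])
    if len(distinct) < 3:
        return float("nan"), False
    counts = np.array([(sizes >= s).sum() for s in distinct], dtype=float)
    slope, _ = np.polyfit(np.log10(distinct), np.log10(counts), 1)
    return float(-slope), True


def cluster_stats(
    mask: np.ndarray,
    lung_mask: np.ndarray,
    fit_range: Tuple[int, int] = DEFAULT_CONFIG.fit_range,
) -> ClusterStats:
    """4-connected cluster labeling plus %LAA, A_L and exponent D."""
    mask = np.asarray(mask, dtype=bool)
    lung_mask = np.asarray(lung_mask, dtype=bool)
    lung_area = int(lung_mask.sum())
    if lung_area == 0:
        raise LaaSpringError("lung mask is empty")
    labels, n = ndimage.label(mask, structure=FOUR_CONNECTED)
    sizes = (
        np.bincount(labels.ravel())[1:] if n else np.empty(0, dtype=int)
    )
    pct = 100.0 * mask.sum() / lung_area
    largest = int(sizes.max()) if n else 0
    exponent, valid = fit_size_exponent(sizes, fit_range)
    return ClusterStats(
        labels=labels,
        sizes=sizes,
        pct_laa=float(pct),
        largest=largest,
        exponent=exponent,
        exponent_valid=valid,
        fit_range=tuple(fit_range),
    )


def laa_error(reconstructed: ClusterStats, ground_truth: ClusterStats) -> float:
    """E_LAA = %LAA(reconstruction) − %LAA(ground truth), in points.

    Negative values mean the reconstructed clusters are smaller than the
    originals.
    """
    return reconstructed.pct_laa - ground_truth.pct_laa


# ---------------------------------------------------------------------------
# local difference
# ---------------------------------------------------------------------------

@dataclass
class LocalDifferenceResult:
    d_local: float              # percent units; nan when undefined
    square_size: int
    n_squares_used: int

    @property
    def defined(self) -> bool:
        return self.n_squares_used > 0


def _square_pct(mask: np.ndarray, size: int) -> np.ndarray:
    rows, cols = mask.shape
    nr = -(-rows // size)
    nc = -(-cols // size)
    pct = np.zeros((nr, nc))
    cnt = np.zeros((nr, nc))
    for i in range(nr):
        for j in range(nc):
            block = mask[i * size:(i + 1) * size, j * size:(j + 1) * size]
            cnt[i, j] = block.size
            pct[i, j] = 100.0 * block.sum() / block.size
    return pct


def d_local(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    square_size: int = DEFAULT_CONFIG.dlocal_square_size,
) -> LocalDifferenceResult:
    """Mean absolute per-square %LAA difference between two LAA maps.

    The masks are partitioned into ``square_size``-pixel squares; squares
    containing no LAA in either mask are excluded from the average.
    Symmetric, non-negative, and zero on identical inputs.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise LaaSpringError("masks must share a shape")
    pa = _square_pct(mask_a, square_size)
    pb = _square_pct(mask_b, square_size)
    qualify = (pa > 0) | (pb > 0)
    n = int(qualify.sum())
    if n == 0:
        return LocalDifferenceResult(float("nan"), square_size, 0)
    value = float(np.abs(pa - pb)[qualify].mean())
    return LocalDifferenceResult(value, square_size, n)
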