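"""Synthetic lung slices and raster I/O.

The generator emulates the features of an emphysematous 2D CT slice the
pipeline actually consumes: a lung-shaped (two-lobed elliptical) region,
LAA clusters with power-law distributed sizes and irregular shapes
placed without overlap inside the lung, scattered vessel-like
high-attenuation curves, and Hounsfield-unit values on either side of
the −960/−500 thresholds.  It does not attempt anatomically realistic
texture — only the structures the thresholding, mapping and progression
stages respond to.

Rasters travel as NPY (float HU) or PNG: masks as 0/255 8-bit images,
HU slices as offset-encoded 16-bit PNG with the offset recorded in a
JSON sidecar.  DICOM and NIfTI readers are attached when the optional
libraries are importable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage import draw as skdraw

from .errors import FormatError, LaaSpringError, PlacementError
from .calibration import generate_synthetic_laa
from .geometry import FOUR_CONNECTED


# ---------------------------------------------------------------------------
# slice generator
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSlice:
    """A generated CT slice with its masks and generator settings."""

    ct_hu: np.ndarray
    lung_mask: np.ndarray
    laa_mask: np.ndarray
    high_atten_mask: np.ndarray
    params: dict

    @property
    def pct_laa(self) -> float:
        return 100.0 * self.laa_mask.sum() / self.lung_mask.sum()

    def save_npz(self, path) -> None:
        np.savez(
            path,
            ct_hu=self.ct_hu,
            lung_mask=self.lung_mask,
            laa_mask=self.laa_mask,
            high_atten_mask=self.high_atten_mask,
            params=json.dumps(self.params),
        )

    @classmethod
    def load_npz(cls, path) -> "SyntheticSlice":
        data = np.load(path, allow_pickle=False)
        return cls(
            ct_hu=data["ct_hu"],
            lung_mask=data["lung_mask"].astype(bool),
            laa_mask=data["laa_mask"].astype(bool),
            high_atten_mask=data["high_atten_mask"].astype(bool),
            params=json.loads(str(data["params"])),
        )


def lung_shape_mask(grid_shape: Tuple[int, int]) -> np.ndarray:
    """Two-lobed elliptical lung silhouette filling most of the grid."""
    rows, cols = grid_shape
    cy = rows / 2.0
    mask = np.zeros(grid_shape, dtype=bool)
    for cx, tilt in ((cols * 0.30, 0.12), (cols * 0.70, -0.12)):
        rr, cc = skdraw.ellipse(
            cy, cx, rows * 0.44, cols * 0.26, shape=grid_shape, rotation=tilt
        )
        mask[rr, cc] = True
    return mask


def _sample_cluster_sizes(
    rng: np.random.Generator,
    target_area: int,
    exponent: float,
    s_min: int = 4,
    s_max: Optional[int] = None,
) -> np.ndarray:
    """Cluster sizes with P(S >= s) ~ (s/s_min)^-exponent summing to ~target."""
    if s_max is None:
        s_max = max(s_min + 1, min(1000, target_area // 3))
    sizes = []
    total = 0
    while total < target_area:
        u = rng.random()
        s = int(round(s_min * u ** (-1.0 / exponent)))
        s = min(max(s, s_min), s_max)
        if total + s > target_area:
            # keep the tail unbiased: redraw instead of clipping the
            # overshooting cluster, stop once close to the target
            if total >= 0.9 * target_area:
                break
            continue
        sizes.append(s)
        total += s
    return np.array(sorted(sizes, reverse=True), dtype=int)


def _small_blob(size: int, rng: np.random.Generator) -> np.ndarray:
    """Random 4-connected blob grown pixel by pixel (for tiny clusters)."""
    half = int(np.ceil(np.sqrt(size))) + 2
    side = 2 * half + 1
    grid = np.zeros((side, side), dtype=bool)
    grid[half, half] = True
    frontier = [(half, half)]
    while grid.sum() < size:
        r, c = frontier[rng.integers(len(frontier))]
        dr, dc = ((0, 1), (0, -1), (1, 0), (-1, 0))[rng.integers(4)]
        nr, nc = r + dr, c + dc
        if 0 <= nr < side and 0 <= nc < side and not grid[nr, nc]:
            grid[nr, nc] = True
            frontier.append((nr, nc))
    rr, cc = np.nonzero(grid)
    return grid[rr.min():rr.max() + 1, cc.min():cc.max() + 1]


def _cluster_mask(size: int, rng: np.random.Generator) -> np.ndarray:
    """A single-cluster footprint of the requested size (tight bbox)."""
    if size < 50:
        return _small_blob(size, rng)
    shape_id = int(rng.integers(1, 5))
    mask = generate_synthetic_laa(
        shape_id, size, seed=int(rng.integers(2**31 - 1))
    )
    rr, cc = np.nonzero(mask)
    return mask[rr.min():rr.max() + 1, cc.min():cc.max() + 1]


def generate_slice(
    target_pct_laa: float,
    exponent: float = 1.5,
    grid_shape: Tuple[int, int] = (128, 128),
    seed: int = 0,
    separation: int = 2,
    max_attempts: int = 500,
    n_vessels: int = 3,
) -> SyntheticSlice:
    """Generate a synthetic emphysematous slice.

    LAA cluster sizes follow P(S >= s) ~ s^-exponent; clusters are placed
    by rejection sampling with a minimum 2-pixel separation (so rupture-
    driven coalescence between neighbors stays observable downstream).
    Realized %LAA lands within 20% relative of the target or a
    :class:`PlacementError` is raised.  Deterministic per seed.
    """
    if not 1.0 <= target_pct_laa <= 60.0:
        raise ValueError("target_pct_laa must be in [1, 60]")
    if not 0.5 <= exponent <= 3.0:
        raise ValueError("exponent must be in [0.5, 3]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 20220318]))
    lung = lung_shape_mask(grid_shape)
    lung_area = int(lung.sum())
    target_area = int(round(target_pct_laa / 100.0 * lung_area))

    interior = ndimage.binary_erosion(lung, iterations=1)
    laa = np.zeros(grid_shape, dtype=bool)
    # blocked = pixels a new cluster may not touch (separation halo + rim)
    blocked = ~interior
    queue = list(_sample_cluster_sizes(rng, target_area, exponent))
    placed_area = 0
    n_placed = 0
    while queue:
        size = int(queue.pop(0))
        footprint = _cluster_mask(size, rng)
        h, w = footprint.shape
        placed = False
        for _ in range(max_attempts):
            r0 = int(rng.integers(0, grid_shape[0] - h + 1))
            c0 = int(rng.integers(0, grid_shape[1] - w + 1))
            window = blocked[r0:r0 + h, c0:c0 + w]
            if not np.any(window & footprint):
                laa[r0:r0 + h, c0:c0 + w] |= footprint
                halo = ndimage.binary_dilation(
                    np.pad(footprint, separation), iterations=separation
                )
                rh = slice(max(r0 - separation, 0),
                           min(r0 + h + separation, grid_shape[0]))
                ch = slice(max(c0 - separation, 0),
                           min(c0 + w + separation, grid_shape[1]))
                pad_r = r0 - separation
                pad_c = c0 - separation
                hh = halo[
                    rh.start - pad_r:rh.stop - pad_r,
                    ch.start - pad_c:ch.stop - pad_c,
                ]
                blocked[rh, ch] |= hh
                placed_area += int(footprint.sum())
                n_placed += 1
                placed = True
                break
        if not placed and size >= 8:
            # crowded grid: split the cluster and try the halves
            queue.extend([size // 2, size - size // 2])
        if placed_area >= target_area:
            break
    realized = 100.0 * placed_area / lung_area
    if abs(realized - target_pct_laa) > 0.2 * target_pct_laa:
        raise PlacementError(
            f"placed {realized:.1f}%LAA vs target {target_pct_laa:.1f}% "
            f"on a {grid_shape} grid (lung area {lung_area} px)"
        )

    # vessel-like high-attenuation curves: short random chords in the lung
    high = np.zeros(grid_shape, dtype=bool)
    lung_pts = np.argwhere(interior)
    for _ in range(n_vessels):
        p = lung_pts[rng.integers(len(lung_pts))]
        angle = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(0.1, 0.25) * min(grid_shape)
        q = np.clip(
            p + length * np.array([np.sin(angle), np.cos(angle)]),
            0, np.array(grid_shape) - 1,
        ).astype(int)
        rr, cc = skdraw.line(p[0], p[1], q[0], q[1])
        high[rr, cc] = True
    high = ndimage.binary_dilation(high) & lung & ~laa

    ct = np.zeros(grid_shape)
    paren = lung & ~laa & ~high
    ct[~lung] = 40.0  # soft-tissue-ish surround; ignored by the lung mask
    ct[paren] = np.clip(
        rng.normal(-870.0, 30.0, int(paren.sum())), -959.0, -501.0
    )
    ct[laa] = np.minimum(
        rng.normal(-980.0, 8.0, int(laa.sum())), -961.0
    )
    ct[high] = rng.uniform(-400.0, 100.0, int(high.sum()))

    return SyntheticSlice(
        ct_hu=ct,
        lung_mask=lung,
        laa_mask=laa,
        high_atten_mask=high,
        params={
            "target_pct_laa": target_pct_laa,
            "exponent": exponent,
            "grid_shape": list(grid_shape),
            "seed": seed,
            "realized_pct_laa": realized,
            "n_clusters": int(n_placed),
        },
    )


def severity_exponent(pct_laa: float) -> float:
    """Cluster-size exponent matched to disease severity.

    In emphysema the cumulative cluster-size exponent D falls as disease
    advances — coalescence removes small clusters and grows large ones —
    so a severity suite spanning 5–40 %LAA pairs mild slices with steep
    distributions (D ≈ 2.2) and severe slices with shallow ones
    (D ≈ 1.1).
    """
    return float(np.clip(2.2 - 0.03 * (pct_laa - 5.0), 1.1, 2.2))


def generate_severity_suite(
    n_slices: int = 20,
    grid_shape: Tuple[int, int] = (128, 128),
    seed: int = 0,
    pct_range: Tuple[float, float] = (5.0, 40.0),
):
    """Slices spanning the severity range with severity-matched exponents.

    Yields one slice per target %LAA on a uniform grid over
    ``pct_range``; a slice whose random packing fails is retried with the
    next derived seed so the suite always has ``n_slices`` members.
    """
    targets = np.linspace(pct_range[0], pct_range[1], n_slices)
    out = []
    for i, pct in enumerate(targets):
        for attempt in range(5):
            try:
                sl = generate_slice(
                    float(pct),
                    exponent=severity_exponent(float(pct)),
                    grid_shape=grid_shape,
                    seed=seed * 1000 + i * 10 + attempt,
                )
                out.append(sl)
                break
            except (PlacementError, LaaSpringError):
                continue
        else:
            raise PlacementError(
                f"could not generate a {pct:.0f} %LAA slice in 5 attempts"
            )
    return out


# ---------------------------------------------------------------------------
# raster I/O
# ---------------------------------------------------------------------------

PNG_HU_OFFSET = 1024  # stored = HU + offset, clipped to uint16


def write_hu_raster(path, hu: np.ndarray) -> None:
    """Write an HU slice as NPY or offset-encoded 16-bit PNG (+sidecar)."""
    path = Path(path)
    hu = np.asarray(hu, dtype=float)
    if path.suffix == ".npy":
        np.save(path, hu)
    elif path.suffix == ".png":
        encoded = np.clip(np.rint(hu) + PNG_HU_OFFSET, 0, 65535).astype(
            np.uint16
        )
        iio.imwrite(path, encoded)
        with open(str(path) + ".json", "w") as fh:
            json.dump({"hu_offset": PNG_HU_OFFSET}, fh)
    else:
        raise FormatError(f"unsupported HU raster format: {path.suffix}")


def read_hu_raster(path) -> np.ndarray:
    """Read an HU slice (NPY, 16-bit PNG+sidecar, DICOM or NIfTI)."""
    path = Path(path)
    suffix = path.suffix.lower()
    try:
        if suffix == ".npy":
            hu = np.load(path).astype(float)
        elif suffix == ".png":
            encoded = iio.imread(path).astype(float)
            offset = PNG_HU_OFFSET
            sidecar = Path(str(path) + ".json")
            if sidecar.exists():
                with open(sidecar) as fh:
                    offset = json.load(fh).get("hu_offset", PNG_HU_OFFSET)
            hu = encoded - offset
        elif suffix == ".dcm":
            hu = _read_dicom(path)
        elif suffix in (".nii", ".gz"):
            hu = _read_nifti(path)
        else:
            raise FormatError(f"unsupported HU raster format: {suffix}")
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if hu.ndim != 2:
        raise FormatError(f"expected a 2D slice, got shape {hu.shape}")
    if hu.min() < -1100 or hu.max() > 3000:
        warnings.warn(
            f"HU range [{hu.min():.0f}, {hu.max():.0f}] outside the sanity "
            "window [-1100, 3000]", stacklevel=2,
        )
    return hu


def _read_dicom(path) -> np.ndarray:
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    return arr * slope + intercept


def _read_nifti(path) -> np.ndarray:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    return np.squeeze(data)


def write_mask(path, mask: np.ndarray) -> None:
    """Write a boolean mask as 0/255 PNG or boolean NPY."""
    path = Path(path)
    mask = np.asarray(mask, dtype=bool)
    if path.suffix == ".npy":
        np.save(path, mask)
    elif path.suffix == ".png":
        iio.imwrite(path, (mask * np.uint8(255)))
    else:
        raise FormatError(f"unsupported mask format: {path.suffix}")


def read_mask(path) -> np.ndarray:
    path = Path(path)
    try:
        if path.suffix == ".npy":
            return np.load(path).astype(bool)
        if path.suffix == ".png":
            return iio.imread(path).astype(bool)
    except Exception as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    raise FormatError(f"unsupported mask format: {path.suffix}")
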