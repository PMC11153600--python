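"""Density-based segmentation of localization maps.

The analysis area of a FOV is defined directly from the localization map: a
disk of fixed physical diameter (default 1 um) is drawn around every emitter
and, per pixel, the overlapping disks are summed.  The resulting raster is a
local emitter density in "emitters within 500 nm" units, independent of the
reconstruction pixel size.  Cell-occupied area is then the set of pixels with
density in (lower, upper]; pixels above the upper threshold mark "torch"
cells — cells with strong photoactivation-independent emission — which are
excluded from quantification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.measure import label as _cc_label

from .io import LocalizationTable, Molecule, molecule_positions


def _positions(obj) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(obj, LocalizationTable):
        return obj.x, obj.y
    if isinstance(obj, (list, tuple)) and (len(obj) == 0 or isinstance(obj[0], Molecule)):
        return molecule_positions(obj)
    if isinstance(obj, tuple) and len(obj) == 2:
        return np.asarray(obj[0], float), np.asarray(obj[1], float)
    raise TypeError(f"cannot extract positions from {type(obj)!r}")


@dataclass
class DensityMap:
    """Local-density raster.

    ``values[iy, ix]`` counts the emitters whose distance from the center of
    pixel (ix, iy) is at most ``disk_diameter_nm / 2``; pixel centers sit at
    ``((i + 0.5) * pixel_size_nm)`` with the origin at the FOV lower-left
    corner.  Disks are truncated at the FOV boundary (no wraparound).
    """

    values: np.ndarray
    pixel_size_nm: float
    disk_diameter_nm: float = 1000.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def build_density_map(
    emitters,
    fov_width_um: float,
    fov_height_um: float,
    pixel_size_nm: float = 20.0,
    disk_diameter_nm: float = 1000.0,
) -> DensityMap:
    """Sum unit disks of ``disk_diameter_nm`` around each emitter position.

    ``emitters`` may be a :class:`LocalizationTable`, a list of merged
    :class:`Molecule` objects, or an ``(x_nm, y_nm)`` pair of arrays.
    """
    if pixel_size_nm <= 0:
        raise ValueError("pixel_size_nm must be > 0")
    if disk_diameter_nm <= 0:
        raise ValueError("disk_diameter_nm must be > 0")
    x, y = _positions(emitters)
    px = float(pixel_size_nm)
    nx = int(np.ceil(fov_width_um * 1000.0 / px))
    ny = int(np.ceil(fov_height_um * 1000.0 / px))
    values = np.zeros((ny, nx), dtype=np.int32)
    if x.size == 0:
        return DensityMap(values, px, disk_diameter_nm)

    radius = disk_diameter_nm / 2.0
    half = int(np.ceil(radius / px)) + 1
    # relative pixel-center offsets of the stamp window
    rel = (np.arange(-half, half + 1) + 0.5) * px
    for xi, yi in zip(x, y):
        ix0 = int(np.floor(xi / px))
        iy0 = int(np.floor(yi / px))
        ix_lo, ix_hi = max(ix0 - half, 0), min(ix0 + half, nx - 1)
        iy_lo, iy_hi = max(iy0 - half, 0), min(iy0 + half, ny - 1)
        if ix_lo > ix_hi or iy_lo > iy_hi:
            continue
        cx = (np.arange(ix_lo, ix_hi + 1) + 0.5) * px - xi
        cy = (np.arange(iy_lo, iy_hi + 1) + 0.5) * px - yi
        mask = (cy[:, None] ** 2 + cx[None, :] ** 2) <= radius**2
        values[iy_lo : iy_hi + 1, ix_lo : ix_hi + 1] += mask
    return DensityMap(values, px, disk_diameter_nm)


@dataclass
class SegmentationResult:
    """Thresholded analysis area and excluded torch area."""

    cell_mask: np.ndarray
    torch_mask: np.ndarray
    area_um2: float
    lower: float
    upper: float
    pixel_size_nm: float

    @property
    def torch_area_um2(self) -> float:
        return float(self.torch_mask.sum()) * self.pixel_size_nm**2 / 1e6


def segment(
    density_map: DensityMap,
    lower: float = 0.0,
    upper: float = 150.0,
    whole_component: bool = False,
) -> SegmentationResult:
    """Apply lower/upper density thresholds.

    ``cell_mask`` keeps pixels with ``lower < value <= upper``; pixels with
    ``value > upper`` form the torch mask.  With ``whole_component=True``
    every 8-connected component of above-lower pixels that touches a torch
    pixel is moved wholly into the torch mask (a torch cell's dimmer rim
    would otherwise survive in the analysis area).
    """
    if lower >= upper:
        raise ValueError("lower threshold must be < upper threshold")
    v = density_map.values
    cell = (v > lower) & (v <= upper)
    torch = v > upper
    if whole_component and torch.any():
        labels = _cc_label(v > lower, connectivity=2)
        torch_labels = np.unique(labels[torch])
        torch_labels = torch_labels[torch_labels > 0]
        comp = np.isin(labels, torch_labels)
        torch = torch | comp
        cell = cell & ~comp
    area = float(cell.sum()) * density_map.pixel_size_nm**2 / 1e6
    return SegmentationResult(
        cell_mask=cell,
        torch_mask=torch,
        area_um2=area,
        lower=lower,
        upper=upper,
        pixel_size_nm=density_map.pixel_size_nm,
    )


def mask_membership(
    x_nm: np.ndarray, y_nm: np.ndarray, mask: np.ndarray, pixel_size_nm: float
) -> tuple[np.ndarray, np.ndarray]:
    """(inside_raster, in_mask) booleans for positions against a pixel mask.

    Pixel membership uses the floor convention: position (x, y) belongs to
    pixel (floor(x/px), floor(y/px)); a point exactly on a pixel boundary is
    assigned to the higher-index pixel.
    """
    px = float(pixel_size_nm)
    ix = np.floor(np.asarray(x_nm) / px).astype(int)
    iy = np.floor(np.asarray(y_nm) / px).astype(int)
    ny, nx = mask.shape
    inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    in_mask = np.zeros(inside.shape, dtype=bool)
    in_mask[inside] = mask[iy[inside], ix[inside]]
    return inside, in_mask


def restrict_to_mask(obj, segmentation: SegmentationResult):
    """Keep localizations/molecules whose position falls in the cell mask.

    Returns ``(subset, report)`` where the report counts the input rows, the
    rows kept, and any positions falling outside the raster.
    """
    x, y = _positions(obj)
    inside, in_mask = mask_membership(
        x, y, segmentation.cell_mask, segmentation.pixel_size_nm
    )
    report = {
        "n_input": int(x.size),
        "n_kept": int(in_mask.sum()),
        "n_outside_raster": int((~inside).sum()),
    }
    if isinstance(obj, LocalizationTable):
        subset = obj.take(np.flatnonzero(in_mask))
    else:
        subset = [m for m, keep in zip(obj, in_mask) if keep]
    return subset, report


def write_segmentation(
    density_map: DensityMap, segmentation: SegmentationResult, directory: str | Path, stem: str
) -> dict[str, Path]:
    """Write the raster and masks as single-plane TIFFs plus a JSON sidecar."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "density": directory / f"{stem}_density.tif",
        "cell_mask": directory / f"{stem}_cellmask.tif",
        "torch_mask": directory / f"{stem}_torchmask.tif",
        "sidecar": directory / f"{stem}_segmentation.json",
    }
    tifffile.imwrite(paths["density"], density_map.values.astype(np.int32))
    tifffile.imwrite(paths["cell_mask"], segmentation.cell_mask.astype(np.uint8))
    tifffile.imwrite(paths["torch_mask"], segmentation.torch_mask.astype(np.uint8))
    with open(paths["sidecar"], "w") as fh:
        json.dump(
            {
                "pixel_size_nm": density_map.pixel_size_nm,
                "disk_diameter_nm": density_map.disk_diameter_nm,
                "lower": segmentation.lower,
                "upper": segmentation.upper,
                "area_um2": segmentation.area_um2,
                "torch_area_um2": segmentation.torch_area_um2,
            },
            fh,
            indent=2,
        )
        fh.write("\n")
    return paths
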