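"""Rasterization, maximum-intensity projection and DBT overlay rendering.

The reconstructed absorption image lives on coarse FEM nodes; for display it
is rasterized onto a regular voxel grid, collapsed along the compression
(z) axis by taking the per-column maximum (the MIP - the optical analogue of
a craniocaudal view), and rendered as a semi-transparent colour layer on a
DBT slice used as the anatomical reference.

Registration: the DBT and DOT exams are acquired under separate
compressions, so only a rigid 2-D similarity transform (scale / rotation /
translation in physical mm, user-adjustable) maps DOT coordinates onto the
DBT pixel grid; automatic intensity-based registration is out of scope.  By
default both modalities are assumed to share their physical frame (the
device geometry places the chest-wall edge and mid-sagittal axis
consistently).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from PIL import Image
from scipy import ndimage

from .fem_forward import Mesh, point_weights
from .recon import ReconResult

__all__ = [
    "VolumeImage",
    "MIPImage",
    "SimilarityTransform2D",
    "FusionOverlay",
    "sensing_aperture",
    "hotspot_centroid",
    "rasterize",
    "mip",
    "fuse_overlay",
    "write_png",
    "read_png_with_sidecar",
    "read_dbt_dicom",
    "write_nifti",
]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class VolumeImage:
    """Regular 3-D grid of absorption values (mm^-1)."""

    values: np.ndarray  # (nx, ny, nz)
    spacing: np.ndarray  # (3,) mm
    origin: np.ndarray  # (3,) mm
    wavelength: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.spacing = np.broadcast_to(
            np.asarray(self.spacing, dtype=float), (3,)
        ).copy()
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("volume must be 3-D")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive")
        if np.any(self.values < 0):
            raise ValueError("absorption values must be non-negative")


@dataclass
class MIPImage:
    """2-D maximum-intensity projection with physical pixel geometry."""

    values: np.ndarray  # (n0, n1)
    spacing: np.ndarray  # (2,) mm
    origin: np.ndarray  # (2,) mm
    axis: str = "z"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.spacing = np.broadcast_to(
            np.asarray(self.spacing, dtype=float), (2,)
        ).copy()
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("MIP must be 2-D")


@dataclass(frozen=True)
class SimilarityTransform2D:
    """Rigid similarity mapping DOT mm coordinates to DBT mm coordinates."""

    scale: float = 1.0
    rotation_deg: float = 0.0
    translation: tuple = (0.0, 0.0)

    def apply(self, xy: np.ndarray) -> np.ndarray:
        th = np.deg2rad(self.rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        return self.scale * (np.atleast_2d(xy) @ rot.T) + np.asarray(
            self.translation
        )

    def inverse_apply(self, xy: np.ndarray) -> np.ndarray:
        th = np.deg2rad(self.rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        return (np.atleast_2d(xy) - np.asarray(self.translation)) @ rot / self.scale


@dataclass
class FusionOverlay:
    """Rendered DBT background + colour-mapped DOT MIP."""

    rgb: np.ndarray  # (H, W, 3) uint8
    background: np.ndarray  # (H, W) float
    foreground: np.ndarray  # (H, W) float, resampled MIP (NaN outside)
    pixel_spacing: float
    alpha: float
    colormap: str
    transform: SimilarityTransform2D


def rasterize(
    result: ReconResult,
    spacing: float,
    wavelength_index: int = 0,
    background: float | None = None,
) -> VolumeImage:
    """Barycentric interpolation of the coarse-mesh image onto a voxel grid
    covering the mesh bounding box.  Voxels outside the mesh (there are none
    for a slab grid, but clamping covers rounding) take the bulk value."""
    mesh = result.coarse_mesh
    if mesh.n_nodes == 0:
        raise ValueError("empty mesh")
    if spacing > float(np.max(mesh.cell_size)) + 1e-9:
        raise ValueError("raster spacing must not exceed the coarse mesh spacing")
    lo, hi = mesh.bounding_box()
    counts = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1) + 1
    axes = [lo[d] + spacing * np.arange(counts[d]) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    inside = np.all((pts >= lo - 1e-9) & (pts <= hi + 1e-9), axis=1)
    vals = np.full(
        len(pts),
        result.bulk[wavelength_index].mu_a if background is None else background,
    )
    w = point_weights(mesh, pts[inside], strict=False)
    vals[inside] = w @ result.mu_a_images[wavelength_index]
    return VolumeImage(
        values=vals.reshape(tuple(counts)),
        spacing=np.full(3, float(spacing)),
        origin=lo,
    )


def mip(vol: VolumeImage, axis: str = "z") -> MIPImage:
    """Per-pixel maximum along ``axis`` (default: the compression axis)."""
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}")
    if vol.values.size == 0:
        raise ValueError("empty volume")
    ax = _AXES[axis]
    rest = [d for d in range(3) if d != ax]
    return MIPImage(
        values=vol.values.max(axis=ax),
        spacing=vol.spacing[rest],
        origin=vol.origin[rest],
        axis=axis,
    )


def sensing_aperture(geometry, margin: float = 2.5):
    """Lateral field of view of a parallel-plate exam: the intersection of
    the source and detector (x, y) footprints, dilated by ``margin`` mm.

    Outside this box no source-detector pair constrains the image locally,
    so reconstructed values there are unreliable; hotspot readouts should be
    restricted to it.  Returns ((xmin, xmax), (ymin, ymax)).
    """
    src = geometry.source_positions[:, :2]
    det = geometry.detector_positions[:, :2]
    return tuple(
        (
            max(src[:, d].min(), det[:, d].min()) - margin,
            min(src[:, d].max(), det[:, d].max()) + margin,
        )
        for d in (0, 1)
    )


def hotspot_centroid(mip_img: MIPImage, within=None):
    """Above-half-maximum intensity centroid of a MIP, in mm.

    ``within`` optionally restricts the search to ((xmin, xmax),
    (ymin, ymax)) physical bounds (e.g. the :func:`sensing_aperture`).
    The background level is the median pixel; pixels whose excess exceeds
    half the maximum excess contribute with their excess as weight.
    """
    vals = mip_img.values
    gx, gy = np.meshgrid(
        mip_img.origin[0] + np.arange(vals.shape[0]) * mip_img.spacing[0],
        mip_img.origin[1] + np.arange(vals.shape[1]) * mip_img.spacing[1],
        indexing="ij",
    )
    mask = np.ones_like(vals, dtype=bool)
    if within is not None:
        (x0, x1), (y0, y1) = within
        mask = (gx >= x0) & (gx <= x1) & (gy >= y0) & (gy <= y1)
    excess = vals - np.median(vals[mask])
    excess[~mask] = 0.0
    peak = excess.max()
    if peak <= 0:
        raise ValueError("MIP contains no excess above background")
    sel = excess >= 0.5 * peak
    w = excess[sel]
    return np.array(
        [(gx[sel] * w).sum(), (gy[sel] * w).sum()]
    ) / w.sum()


def fuse_overlay(
    mip_img: MIPImage,
    dbt_image: np.ndarray,
    dbt_pixel_spacing: float,
    alpha: float = 0.5,
    colormap: str = "inferno",
    transform: SimilarityTransform2D | None = None,
    dbt_origin=(0.0, 0.0),
) -> FusionOverlay:
    """Render the colour-mapped MIP over the DBT background.

    The MIP's physical (x, y) frame is mapped to DBT mm coordinates by
    ``transform`` (identity by default) and resampled bilinearly onto the DBT
    pixel grid; DBT row index corresponds to y, column index to x.  The MIP
    display range is normalized per image to [min, max] (readers assess
    activity relative to the surrounding parenchyma, so relative contrast is
    what is rendered); a constant MIP renders as a uniform colour.
    ``alpha`` = 0 returns the background bit-exactly.
    """
    if dbt_pixel_spacing is None or dbt_pixel_spacing <= 0:
        raise ValueError("DBT image must carry a positive pixel spacing")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    transform = transform or SimilarityTransform2D()
    bg = np.asarray(dbt_image, dtype=float)
    if bg.ndim != 2:
        raise ValueError("DBT background must be a single 2-D slice")
    h, wpx = bg.shape
    # physical mm coordinates of every DBT pixel centre (x = col, y = row)
    cols, rows = np.meshgrid(np.arange(wpx), np.arange(h))
    xy_dbt = np.column_stack(
        [
            dbt_origin[0] + cols.ravel() * dbt_pixel_spacing,
            dbt_origin[1] + rows.ravel() * dbt_pixel_spacing,
        ]
    )
    xy_dot = transform.inverse_apply(xy_dbt)
    # continuous pixel indices into the MIP array (axis 0 = x, axis 1 = y)
    ix = (xy_dot[:, 0] - mip_img.origin[0]) / mip_img.spacing[0]
    iy = (xy_dot[:, 1] - mip_img.origin[1]) / mip_img.spacing[1]
    fg = ndimage.map_coordinates(
        mip_img.values, np.vstack([ix, iy]), order=1, mode="constant",
        cval=np.nan,
    ).reshape(h, wpx)

    lo, hi_ = np.nanmin(mip_img.values), np.nanmax(mip_img.values)
    norm = np.zeros_like(fg)
    valid = np.isfinite(fg)
    if hi_ > lo:
        norm[valid] = np.clip((fg[valid] - lo) / (hi_ - lo), 0.0, 1.0)
    else:
        norm[valid] = 1.0  # constant MIP: uniform colour
    cmap = colormaps[colormap]
    fg_rgb = cmap(norm)[..., :3]
    bglo, bghi = bg.min(), bg.max()
    bgn = (bg - bglo) / (bghi - bglo) if bghi > bglo else np.zeros_like(bg)
    out = np.repeat(bgn[..., None], 3, axis=2)
    if alpha > 0.0:
        mask = valid[..., None]
        out = np.where(mask, (1.0 - alpha) * out + alpha * fg_rgb, out)
    rgb = np.round(np.clip(out, 0.0, 1.0) * 255.0).astype(np.uint8)
    if alpha == 0.0:
        # exact pass-through of the background grey levels
        rgb = np.repeat(
            np.round(np.clip(bgn, 0.0, 1.0) * 255.0).astype(np.uint8)[..., None],
            3,
            axis=2,
        )
    return FusionOverlay(
        rgb=rgb,
        background=bg,
        foreground=fg,
        pixel_spacing=float(dbt_pixel_spacing),
        alpha=float(alpha),
        colormap=colormap,
        transform=transform,
    )


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def write_png(path, image) -> None:
    """8-bit PNG writer for overlays (RGB uint8) or grayscale arrays."""
    arr = image.rgb if isinstance(image, FusionOverlay) else np.asarray(image)
    if arr.dtype != np.uint8:
        arr = np.round(np.clip(arr, 0.0, 1.0) * 255.0).astype(np.uint8)
    Image.fromarray(arr).save(path)


def read_png_with_sidecar(png_path, sidecar_path):
    """(image float [0,1], pixel spacing mm) from a PNG plus JSON sidecar
    with a ``pixel_spacing_mm`` key."""
    img = np.asarray(Image.open(png_path).convert("L"), dtype=float) / 255.0
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    return img, float(meta["pixel_spacing_mm"])


def read_dbt_dicom(path):
    """(slice float array, pixel spacing mm) from a DICOM DBT slice."""
    import pydicom

    ds = pydicom.dcmread(path)
    spacing = None
    if getattr(ds, "PixelSpacing", None):
        spacing = float(ds.PixelSpacing[0])
    elif getattr(ds, "ImagerPixelSpacing", None):
        spacing = float(ds.ImagerPixelSpacing[0])
    if spacing is None:
        raise ValueError("DICOM file carries no pixel spacing")
    return ds.pixel_array.astype(float), spacing


def write_nifti(path, image) -> None:
    """NIfTI writer for VolumeImage / MIPImage (affine from spacing+origin)."""
    import nibabel as nib

    if isinstance(image, VolumeImage):
        affine = np.diag([*image.spacing, 1.0])
        affine[:3, 3] = image.origin
        nib.save(nib.Nifti1Image(image.values, affine), str(path))
    elif isinstance(image, MIPImage):
        affine = np.diag([*image.spacing, 1.0, 1.0])
        affine[:2, 3] = image.origin
        nib.save(
            nib.Nifti1Image(image.values[:, :, None], affine), str(path)
        )
    else:
        raise TypeError("expected VolumeImage or MIPImage")
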