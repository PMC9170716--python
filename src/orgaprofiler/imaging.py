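"""3D multi-channel organoid stacks -> 2D projections and per-organoid label masks.

The screen acquires, per well field, a 16-slice confocal z-stack in three
fluorescence channels (DNA, actin, cell permeability).  The analysis flattens
each stack with a maximum *contrast* projection -- per pixel and channel, the
value of the z-slice whose local neighbourhood has the highest intensity
variance is retained -- and then segments organoids on the projected image by
intensity thresholding plus a distance-transform watershed to split touching
objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_li, threshold_otsu
from skimage.measure import label as sk_label
from skimage.segmentation import relabel_sequential, watershed

CHANNELS = ("dna", "actin", "permeability")


@dataclass
class ImageStack:
    """A multi-channel 3D field: ``pixels`` indexed (channel, z, y, x).

    ``z_step`` is the physical slice spacing in micrometres (5 um in the
    screening protocol), ``pixel_size`` the lateral pixel size in micrometres.
    """

    pixels: np.ndarray
    channels: tuple[str, ...] = CHANNELS
    pixel_size: float = 1.0
    z_step: float = 5.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise ValueError("pixels must be 4-D (channel, z, y, x)")
        if self.pixels.shape[0] != len(self.channels):
            raise ValueError("channel axis does not match channel names")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_slices(self) -> int:
        return self.pixels.shape[1]

    def channel_index(self, name: str) -> int:
        return self.channels.index(name)


@dataclass
class ProjectedImage:
    """A 2D projection with, per pixel, the z-slice it was taken from."""

    pixels: np.ndarray  # (channel, y, x)
    z_index_map: np.ndarray  # (channel, y, x), int
    channels: tuple[str, ...] = CHANNELS
    pixel_size: float = 1.0
    meta: dict = field(default_factory=dict)

    def channel(self, name: str) -> np.ndarray:
        return self.pixels[self.channels.index(name)]


def correct_illumination(stack: ImageStack, flatfield="estimate") -> ImageStack:
    """Divide every slice by a per-channel flatfield gain image.

    ``flatfield`` may be a 2D gain array (shared across channels), a
    (channel, y, x) array, or the string ``"estimate"`` in which case a
    smooth second-order polynomial surface is fitted to the per-channel mean
    slice and used as the gain.  After division each channel is rescaled so
    its mean intensity is preserved.
    """
    pix = stack.pixels.astype(float)
    n_chan, _, ny, nx = pix.shape

    if isinstance(flatfield, str):
        if flatfield != "estimate":
            raise ValueError(f"unknown flatfield mode {flatfield!r}")
        ff = np.stack([_estimate_flatfield(pix[c].mean(axis=0)) for c in range(n_chan)])
    else:
        ff = np.asarray(flatfield, dtype=float)
        if ff.ndim == 2:
            ff = np.broadcast_to(ff, (n_chan,) + ff.shape).copy()
        if ff.shape != (n_chan, ny, nx):
            raise ValueError(
                f"flatfield shape {ff.shape} does not match channels/image {(n_chan, ny, nx)}"
            )
        if np.any(ff <= 0):
            raise ValueError("flatfield gains must be strictly positive")

    out = pix / ff[:, None, :, :]
    for c in range(n_chan):
        before = pix[c].mean()
        after = out[c].mean()
        if after > 0:
            out[c] *= before / after
    return ImageStack(out, stack.channels, stack.pixel_size, stack.z_step, dict(stack.meta))


def _estimate_flatfield(mean_img: np.ndarray) -> np.ndarray:
    """Fit a 2nd-order polynomial shading surface, normalised to mean 1."""
    ny, nx = mean_img.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    y = (yy / max(ny - 1, 1)).ravel()
    x = (xx / max(nx - 1, 1)).ravel()
    design = np.column_stack([np.ones_like(x), x, y, x * y, x**2, y**2])
    coef, *_ = np.linalg.lstsq(design, mean_img.ravel(), rcond=None)
    surface = (design @ coef).reshape(ny, nx)
    surface = np.clip(surface, 1e-6 * max(surface.max(), 1e-12), None)
    return surface / surface.mean()


def max_contrast_project(stack: ImageStack, window: int = 3) -> ProjectedImage:
    """Project a stack to 2D, keeping per pixel the z-slice of highest local contrast.

    Contrast of slice z at (y, x) is the intensity variance in the
    ``window x window`` neighbourhood (reflective boundary).  Ties are broken
    toward the lowest z, so a constant stack projects to slice 0.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    pix = stack.pixels
    n_chan, n_z, ny, nx = pix.shape
    if window > min(ny, nx):
        raise ValueError("window exceeds image extent")

    z_map = np.empty((n_chan, ny, nx), dtype=np.int64)
    for c in range(n_chan):
        var = np.empty((n_z, ny, nx), dtype=np.float64)
        for z in range(n_z):
            im = pix[c, z].astype(np.float64)
            m = ndi.uniform_filter(im, size=window, mode="reflect")
            m2 = ndi.uniform_filter(im * im, size=window, mode="reflect")
            var[z] = np.maximum(m2 - m * m, 0.0)
        z_map[c] = np.argmax(var, axis=0)

    projected = np.take_along_axis(pix, z_map[:, None, :, :], axis=1)[:, 0]
    return ProjectedImage(projected, z_map, stack.channels, stack.pixel_size, dict(stack.meta))


def segment_organoids(
    img: ProjectedImage,
    smoothing_sd: float = 2.0,
    threshold_method: str = "otsu",
    min_seed_distance: int = 10,
    min_foreground_snr: float = 3.0,
) -> np.ndarray:
    """Segment organoids on a projected image; returns an integer label mask.

    Foreground is an automatic threshold on the Gaussian-smoothed sum of the
    DNA and actin channels; touching organoids are split by a
    distance-transform watershed seeded at local maxima at least
    ``min_seed_distance`` pixels apart.  A blank field yields an empty mask;
    a saturated (constant non-zero) field yields a single all-foreground
    component with a warning.  Fields whose foreground/background separation
    is below ``min_foreground_snr`` background standard deviations are
    treated as background-only.
    """
    for ch in ("dna", "actin"):
        if ch not in img.channels:
            raise ValueError(f"projected image lacks required channel {ch!r}")
    composite = img.channel("dna").astype(float) + img.channel("actin").astype(float)
    if composite.max() == composite.min():
        if composite.max() > 0:
            warnings.warn("saturated field: returning a single-component mask")
            return np.ones(composite.shape, dtype=np.int32)
        return np.zeros(composite.shape, dtype=np.int32)

    smoothed = gaussian(composite, sigma=smoothing_sd, preserve_range=True)
    if threshold_method == "otsu":
        thr = threshold_otsu(smoothed)
    elif threshold_method == "li":
        thr = threshold_li(smoothed)
    else:
        raise ValueError(f"unknown threshold method {threshold_method!r}")
    fg = smoothed > thr
    if not fg.any() or fg.all():
        return (fg.astype(np.int32)) if fg.all() else np.zeros(composite.shape, np.int32)

    bg_vals = smoothed[~fg]
    sep = smoothed[fg].mean() - bg_vals.mean()
    if sep < min_foreground_snr * max(bg_vals.std(), 1e-12):
        return np.zeros(composite.shape, dtype=np.int32)

    fg = ndi.binary_fill_holes(fg)
    distance = ndi.distance_transform_edt(fg)
    # smooth the distance map so ragged thresholded boundaries do not seed
    # spurious watershed basins
    smooth_dist = ndi.gaussian_filter(distance, sigma=max(smoothing_sd, 1.0))
    peaks = peak_local_max(
        smooth_dist, min_distance=min_seed_distance, labels=fg, exclude_border=False
    )
    if len(peaks) == 0:
        labels = sk_label(fg)
    else:
        markers = np.zeros_like(distance, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = watershed(-distance, markers, mask=fg)
    labels, *_ = relabel_sequential(labels)
    return labels.astype(np.int32)


def filter_small_objects(mask: np.ndarray, max_removed_area: int = 300) -> np.ndarray:
    """Drop every labelled object with pixel area <= ``max_removed_area``.

    An object of area 301 survives the default threshold of 300; surviving
    objects keep their pixels and are relabelled to contiguous 1..K in the
    order of their original labels.
    """
    if max_removed_area < 0:
        raise ValueError("max_removed_area must be non-negative")
    mask = np.asarray(mask)
    if mask.max() == 0:
        return np.zeros_like(mask, dtype=np.int32)
    areas = np.bincount(mask.ravel())
    keep = np.flatnonzero(areas > max_removed_area)
    keep = keep[keep > 0]
    lut = np.zeros(areas.size, dtype=np.int32)
    lut[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
    return lut[mask]
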