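"""Nuclear segmentation from the DNA-stain channel.

Interphase nuclei are defined by global intensity thresholding of the DNA
(Hoechst) image: pixels strictly above the threshold are grouped into
8-connected components, which are then filtered by physical area and shape
(eccentricity).  The threshold is either supplied manually or derived
automatically so that roughly 95% of stained pixels lie above it — the
quantile rule the assay uses to keep essentially all genuine nuclear pixels
while rejecting background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops


class SegmentationError(ValueError):
    """Raised when thresholding or segmentation cannot proceed."""


@dataclass(frozen=True)
class ChannelImage:
    """A single fluorescence channel of one microscope field.

    Parameters
    ----------
    pixels:
        2-D array of non-negative intensities (arbitrary units); stored as
        float64 regardless of the on-disk bit depth.
    channel:
        One of ``dna``, ``green``, ``red``.
    pixel_size:
        Lateral pixel size in µm/pixel.
    """

    pixels: np.ndarray
    channel: Literal["dna", "green", "red"]
    pixel_size: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("channel image must be 2-D")
        if not np.all(np.isfinite(px)) or np.any(px < 0):
            raise ValueError("intensities must be finite and non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class FieldImageSet:
    """Registered DNA/green/red channels for one field."""

    dna: ChannelImage
    green: ChannelImage
    red: ChannelImage
    sample_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        shp = self.dna.pixels.shape
        if self.green.pixels.shape != shp or self.red.pixels.shape != shp:
            raise ValueError("all channels must share the same shape")
        if not (self.dna.pixel_size == self.green.pixel_size == self.red.pixel_size):
            raise ValueError("all channels must share the same pixel size")

    @property
    def pixel_size(self) -> float:
        return self.dna.pixel_size

    @property
    def shape(self) -> tuple[int, int]:
        return self.dna.pixels.shape


@dataclass(frozen=True)
class NucleusROI:
    """One segmented nuclear region.

    ``coords`` holds the member pixels as an (n, 2) integer array of
    (row, col) pairs; ``area`` is in µm² (pixel count × pixel_size²).
    """

    label: int
    coords: np.ndarray
    area: float
    centroid: tuple[float, float]
    eccentricity: float

    @property
    def n_pixels(self) -> int:
        return len(self.coords)


@dataclass
class SegmentationConfig:
    """Thresholding and ROI-filter settings.

    The default area window (1.1–2.7 µm²) matches the published filter for
    Rat2 nuclei; it is a plain configuration value and should be adapted to
    the magnification and cell line at hand.
    """

    threshold_mode: Literal["manual", "quantile"] = "quantile"
    manual_threshold: float = 0.0
    retain_quantile: float = 0.95
    area_min: float = 1.1
    area_max: float = 2.7
    eccentricity_max: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 < self.retain_quantile < 1.0):
            raise ValueError("retain_quantile must lie in (0, 1)")
        if not (self.area_min < self.area_max):
            raise ValueError("area_min must be < area_max")
        if self.threshold_mode not in ("manual", "quantile"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")


def compute_dna_threshold(dna: ChannelImage, config: SegmentationConfig) -> float:
    """Determine the DNA-channel intensity threshold.

    In ``manual`` mode the configured value is returned unchanged.  In
    ``quantile`` mode foreground (stained) pixels are first separated from
    background with Otsu's two-class criterion; the returned threshold sits
    just below the (1 − q) quantile of the foreground intensities, so that at
    least a fraction q (default 0.95) of stained pixels is *strictly* above
    it.  The "just below" nudge matters for quantized images, where the
    quantile value itself would otherwise be excluded by the strict
    comparison used in :func:`segment_nuclei`.
    """
    px = dna.pixels
    if px.size == 0:
        raise SegmentationError("empty image")
    if config.threshold_mode == "manual":
        return float(config.manual_threshold)
    if np.ptp(px) == 0:
        raise SegmentationError("no foreground detectable: image is constant")
    otsu = threshold_otsu(px)
    fg = px[px > otsu]
    if fg.size == 0:
        raise SegmentationError("no foreground detectable above Otsu split")
    q = float(np.quantile(fg, 1.0 - config.retain_quantile))
    return float(np.nextafter(q, -np.inf))


def segment_nuclei(dna: ChannelImage, threshold: float) -> list[NucleusROI]:
    """Extract 8-connected components of pixels strictly above ``threshold``.

    Labels are consecutive positive integers ordered by the raster-scan
    position of each component's first pixel.  An empty list is returned when
    nothing exceeds the threshold.
    """
    if not np.isfinite(threshold):
        raise SegmentationError("threshold must be finite")
    mask = dna.pixels > threshold
    if not mask.any():
        return []
    labeled = sk_label(mask, connectivity=2)
    props = regionprops(labeled)
    ncols = dna.pixels.shape[1]

    def first_pixel_raster(p) -> int:
        rows, cols = p.coords[:, 0], p.coords[:, 1]
        return int(np.min(rows * ncols + cols))

    props = sorted(props, key=first_pixel_raster)
    ps2 = dna.pixel_size**2
    rois = []
    for new_label, p in enumerate(props, start=1):
        rois.append(
            NucleusROI(
                label=new_label,
                coords=np.asarray(p.coords, dtype=np.intp),
                area=float(p.num_pixels * ps2),
                centroid=(float(p.centroid[0]), float(p.centroid[1])),
                eccentricity=float(p.eccentricity),
            )
        )
    return rois


def filter_nuclei(
    rois: Sequence[NucleusROI], config: SegmentationConfig
) -> list[NucleusROI]:
    """Keep ROIs with area in [area_min, area_max] (closed interval) and
    eccentricity ≤ eccentricity_max; input order is preserved."""
    return [
        r
        for r in rois
        if config.area_min <= r.area <= config.area_max
        and r.eccentricity <= config.eccentricity_max
    ]
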