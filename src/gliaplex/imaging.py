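"""From aligned channel stacks + rectangle annotations to measured profiles.

Implements the image-quantification half of the pipeline: rolling-ball
background subtraction, VIA2 rectangle parsing, per-ROI Otsu segmentation on
the constitutive channel, per-marker mean gray intensity (MGI) measurement,
and lesion geometry (plaque equivalent-circle radius).

Conventions: pixels are 0-based with x rightward and y downward; boxes are
half-open; physical coordinates are µm = px × pixel_size.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import uniform_filter
from scipy.ndimage import zoom as nd_zoom
from skimage.restoration import rolling_ball

from .panel import MarkerPanel, default_panel

__all__ = [
    "ChannelStack",
    "RoiBox",
    "SegmentedProfile",
    "LesionRecord",
    "UnsegmentableRoiError",
    "subtract_background",
    "parse_annotations",
    "otsu_threshold",
    "segment_roi",
    "measure_profile",
    "lesion_geometry",
    "measure_stack",
    "read_stack",
    "write_stack",
]

ROI_CLASSES = ("astrocyte", "microglia", "plaque", "NFT")

#: Channel that drives segmentation for each ROI class.
SEGMENTATION_CHANNEL = {
    "astrocyte": "ALDH1L1",
    "microglia": "IBA1",
    "plaque": "Abeta",
    "NFT": "PHF1",
}


class UnsegmentableRoiError(ValueError):
    """Raised when an ROI crop cannot be thresholded (e.g. constant)."""


@dataclass
class ChannelStack:
    """Aligned per-marker 2-D intensity images for one field."""

    channels: dict  # marker name -> 2-D float array
    pixel_size: float  # µm / px
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels differ in shape: {shapes}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self):
        return next(iter(self.channels.values())).shape

    def __getitem__(self, marker: str) -> np.ndarray:
        return self.channels[marker]

    def subtract_background(self, radius: int = 200) -> "ChannelStack":
        """Return a new stack with rolling-ball background removed per channel."""
        return ChannelStack(
            channels={k: subtract_background(v, radius) for k, v in self.channels.items()},
            pixel_size=self.pixel_size,
            metadata=dict(self.metadata),
        )


@dataclass(frozen=True)
class RoiBox:
    """A rectangle annotation (0-based, half-open)."""

    x: int
    y: int
    width: int
    height: int
    object_class: str
    annotation_id: int = -1

    def clipped(self, shape) -> "RoiBox":
        h, w = shape
        x0 = max(0, self.x)
        y0 = max(0, self.y)
        x1 = min(w, self.x + self.width)
        y1 = min(h, self.y + self.height)
        if x1 - x0 < 2 or y1 - y0 < 2:
            raise ValueError(f"roi {self.annotation_id} degenerate after clipping to image bounds")
        return RoiBox(x0, y0, x1 - x0, y1 - y0, self.object_class, self.annotation_id)

    def crop(self, image: np.ndarray) -> np.ndarray:
        return image[self.y : self.y + self.height, self.x : self.x + self.width]


@dataclass
class SegmentedProfile:
    roi: RoiBox
    mask: np.ndarray  # bool, roi-shaped
    threshold: float
    pixel_size: float
    flagged_empty: bool = False

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def area_um2(self) -> float:
        return self.area_px * self.pixel_size**2

    @property
    def centroid_um(self) -> tuple[float, float]:
        """Mask centroid (x, y) in µm within the full field."""
        ys, xs = np.nonzero(self.mask)
        return (
            float((xs.mean() + self.roi.x) * self.pixel_size),
            float((ys.mean() + self.roi.y) * self.pixel_size),
        )


@dataclass(frozen=True)
class LesionRecord:
    type: str  # "plaque" | "NFT"
    centroid: tuple[float, float]  # µm
    area: float  # µm²

    @property
    def radius(self) -> float:
        """Equivalent-circle radius r = sqrt(area/π); 0 for NFTs."""
        return float(np.sqrt(self.area / np.pi)) if self.type == "plaque" else 0.0


# ---------------------------------------------------------------------------
# operations


def _paraboloid_kernel(image_shape, r: float, extent: float | None = None) -> np.ndarray:
    """Sliding-paraboloid structuring surface with curvature radius ``r``.

    A paraboloid z = d²/(2r) is the scale-free counterpart of the rolling
    ball: it tracks any background whose curvature radius exceeds ``r``
    while penetrating cell-sized objects by a negligible (w/2)²/(2r).
    ``extent`` caps the spatial half-width of the footprint.
    """
    if extent is None:
        extent = r
    half = int(min(extent, max(image_shape) - 1))
    half = max(half, 1)
    coords = np.arange(-half, half + 1)
    d2 = coords[:, None] ** 2 + coords[None, :] ** 2
    kernel = (half**2 - d2) / (2.0 * r)
    kernel[d2 > half**2] = np.inf
    return kernel


def subtract_background(image: np.ndarray, radius: int = 200) -> np.ndarray:
    """Rolling-ball background subtraction (ImageJ-style, radius in px).

    A smooth local background — the upper envelope of a ball rolled beneath
    the intensity surface — is estimated and subtracted; the result is
    clipped at 0 and the input is left unmodified. For radii above 32 px the
    estimate is computed on a downsampled image and re-expanded bilinearly,
    analogous to ImageJ's shrink/enlarge speed-up.
    """
    image = np.asarray(image, dtype=float)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if np.any(image < 0):
        raise ValueError("image must be non-negative")
    if radius >= image.shape[0] and radius >= image.shape[1]:
        warnings.warn(
            "rolling-ball radius exceeds both image dimensions; subtracting the global minimum",
            stacklevel=2,
        )
        return image - image.min()

    # pre-smoothing keeps the ball from riding pixel-noise minima (as the
    # reference ImageJ implementation does before rolling)
    smoothed = uniform_filter(image, size=3)

    shrink = max(1, int(radius // 32))
    if shrink == 1:
        background = rolling_ball(smoothed, kernel=_paraboloid_kernel(smoothed.shape, radius))
    else:
        small = smoothed[::shrink, ::shrink]
        # curvature transforms as r/s² under s-fold spatial downsampling
        bg_small = rolling_ball(
            small, kernel=_paraboloid_kernel(small.shape, max(1.0, radius / shrink**2), extent=radius / shrink)
        )
        background = nd_zoom(bg_small, np.array(image.shape) / np.array(bg_small.shape), order=1)
        background = background[: image.shape[0], : image.shape[1]]
        # the coarse estimate may locally overshoot the image; a background
        # never exceeds the signal it sits under
        background = np.minimum(background, image)
    return np.clip(image - background, 0.0, None)


def parse_annotations(source, image_shape=None) -> list[RoiBox]:
    """Parse a VIA2 project JSON (rectangle dialect) into RoiBoxes.

    Non-rectangle regions are skipped with a warning; unknown class strings
    raise, listing the offending annotation id. Boxes are clipped to
    ``image_shape`` when given.
    """
    if isinstance(source, (str, Path)):
        data = json.loads(Path(source).read_text())
    else:
        data = source
    # VIA2 stores either {"_via_img_metadata": {...}} or the metadata map directly
    meta = data.get("_via_img_metadata", data)
    boxes: list[RoiBox] = []
    skipped = 0
    idx = 0
    for entry in meta.values():
        if not isinstance(entry, dict) or "regions" not in entry:
            continue
        for region in entry["regions"]:
            sa = region.get("shape_attributes", {})
            if sa.get("name") != "rect":
                skipped += 1
                idx += 1
                continue
            cls = region.get("region_attributes", {}).get("type")
            if cls not in ROI_CLASSES:
                raise ValueError(f"annotation {idx}: unknown object class {cls!r}")
            box = RoiBox(
                int(sa["x"]), int(sa["y"]), int(sa["width"]), int(sa["height"]), cls, idx
            )
            if image_shape is not None:
                box = box.clipped(image_shape)
            boxes.append(box)
            idx += 1
    if skipped:
        warnings.warn(f"skipped {skipped} non-rectangle region(s)", stacklevel=2)
    return boxes


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold over a 1-D intensity sample.

    Maximizes between-class variance over a ``nbins``-bin histogram spanning
    the sample range; returns the bin-center cut. Raises
    ``UnsegmentableRoiError`` for a constant sample.
    """
    values = np.asarray(values, dtype=float).ravel()
    lo, hi = values.min(), values.max()
    if hi <= lo:
        raise UnsegmentableRoiError("constant sample has no Otsu threshold")
    counts, edges = np.histogram(values, bins=nbins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2
    w = counts / counts.sum()
    omega0 = np.cumsum(w)
    mu_t = np.cumsum(w * centers)
    mu_total = mu_t[-1]
    omega1 = 1.0 - omega0
    valid = (omega0 > 0) & (omega1 > 0)
    sigma_b = np.full(nbins, -np.inf)
    sigma_b[valid] = (mu_total * omega0[valid] - mu_t[valid]) ** 2 / (
        omega0[valid] * omega1[valid]
    )
    # cut after bin i: threshold between centers i and i+1; ties (a plateau
    # of empty bins between modes) resolve to the plateau average
    top = sigma_b.max()
    tied = np.flatnonzero(sigma_b >= top - 1e-9 * abs(top))
    cuts = [(centers[i] + centers[min(i + 1, nbins - 1)]) / 2 for i in tied]
    return float(np.mean(cuts))


def segment_roi(stack: ChannelStack, roi: RoiBox, panel: MarkerPanel | None = None) -> SegmentedProfile:
    """Segment one annotated ROI by Otsu thresholding its crop.

    The threshold is computed within the ROI crop of the class's
    segmentation channel (constitutive marker for glia, Aβ for plaques,
    PHF1 for NFTs); the mask keeps every pixel at or above it. A crop that
    cannot be thresholded yields a profile flagged empty rather than an
    exception, so callers can count and exclude it.
    """
    del panel  # segmentation channel is fixed per class
    channel = SEGMENTATION_CHANNEL[roi.object_class]
    if channel not in stack.channels:
        raise KeyError(f"stack lacks segmentation channel {channel!r} for {roi.object_class}")
    roi = roi.clipped(stack.shape)
    crop = roi.crop(stack[channel])
    try:
        thr = otsu_threshold(crop)
    except UnsegmentableRoiError:
        return SegmentedProfile(
            roi=roi,
            mask=np.zeros(crop.shape, dtype=bool),
            threshold=np.nan,
            pixel_size=stack.pixel_size,
            flagged_empty=True,
        )
    mask = crop >= thr
    return SegmentedProfile(
        roi=roi,
        mask=mask,
        threshold=thr,
        pixel_size=stack.pixel_size,
        flagged_empty=not mask.any(),
    )


def measure_profile(
    stack: ChannelStack, profile: SegmentedProfile, panel: MarkerPanel | None = None
) -> dict:
    """Per-marker MGI of a segmented profile, plus geometry.

    MGI is the arithmetic mean of the channel's pixel values under the mask.
    Astrocyte profiles are measured on the 7 astrocytic phenotypic markers,
    microglia on the 5 microglial ones; TSPO belongs to both panels.
    """
    if profile.flagged_empty or not profile.mask.any():
        raise ValueError("cannot measure a profile with an empty mask")
    panel = panel or default_panel()
    cls = profile.roi.object_class
    if cls in ("astrocyte", "microglia"):
        markers = panel.phenotypic(cls)
    else:
        markers = []
    out = {
        "object_class": cls,
        "area_um2": profile.area_um2,
        "area_px": profile.area_px,
        "threshold": profile.threshold,
    }
    cx, cy = profile.centroid_um
    out["centroid_x_um"] = cx
    out["centroid_y_um"] = cy
    for mk in markers:
        crop = profile.roi.crop(stack[mk])
        out[mk] = float(crop[profile.mask].mean())
    return out


def lesion_geometry(
    stack: ChannelStack, rois: list[RoiBox], panel: MarkerPanel | None = None
) -> list[LesionRecord]:
    """Segment lesion ROIs and extract centroid/area/radius records.

    Empty (unsegmentable) lesion ROIs are excluded, with a warning tallying
    the count.
    """
    records = []
    n_empty = 0
    for roi in rois:
        if roi.object_class not in ("plaque", "NFT"):
            continue
        prof = segment_roi(stack, roi, panel)
        if prof.flagged_empty or prof.area_px == 0:
            n_empty += 1
            continue
        records.append(
            LesionRecord(
                type=roi.object_class,
                centroid=prof.centroid_um,
                area=prof.area_um2 if roi.object_class == "plaque" else 0.0,
            )
        )
    if n_empty:
        warnings.warn(f"excluded {n_empty} unsegmentable lesion ROI(s)", stacklevel=2)
    return records


def measure_stack(
    stack: ChannelStack,
    rois: list[RoiBox],
    panel: MarkerPanel | None = None,
    ball_radius: int | None = 200,
) -> tuple[pd.DataFrame, list[LesionRecord]]:
    """Full per-field measurement: subtract → segment → measure + lesion geometry.

    Returns a table with one row per glial ROI (marker MGIs, geometry,
    field metadata) and the field's lesion records. MGIs are measured on
    background-subtracted channels; pass ``ball_radius=None`` to skip
    subtraction.
    """
    panel = panel or default_panel()
    work = stack.subtract_background(ball_radius) if ball_radius else stack
    rows = []
    n_empty = 0
    for roi in rois:
        if roi.object_class not in ("astrocyte", "microglia"):
            continue
        prof = segment_roi(work, roi, panel)
        if prof.flagged_empty:
            n_empty += 1
            continue
        row = measure_profile(work, prof, panel)
        row["annotation_id"] = roi.annotation_id
        row.update({k: stack.metadata.get(k) for k in ("field_id", "subject", "diagnosis", "layer")})
        rows.append(row)
    if n_empty:
        warnings.warn(f"excluded {n_empty} unsegmentable glial ROI(s)", stacklevel=2)
    lesions = lesion_geometry(work, rois, panel)
    return pd.DataFrame(rows), lesions


# ---------------------------------------------------------------------------
# stack IO


def write_stack(stack: ChannelStack, out_dir) -> Path:
    """Write one channel per 16-bit grayscale TIFF plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = {}
    for name, img in stack.channels.items():
        fname = f"{name}.tif"
        tifffile.imwrite(
            out / fname, np.clip(np.round(img), 0, 65535).astype(np.uint16)
        )
        entries[name] = fname
    manifest = {
        "pixel_size_um": stack.pixel_size,
        "channels": entries,
        "metadata": stack.metadata,
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def read_stack(manifest_path) -> ChannelStack:
    """Load a stack written by :func:`write_stack`."""
    path = Path(manifest_path)
    manifest = json.loads(path.read_text())
    channels = {
        name: tifffile.imread(path.parent / fname).astype(float)
        for name, fname in manifest["channels"].items()
    }
    return ChannelStack(
        channels=channels,
        pixel_size=float(manifest["pixel_size_um"]),
        metadata=manifest.get("metadata", {}),
    )
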