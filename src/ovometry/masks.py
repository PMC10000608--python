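"""Label-mask I/O, a classical color-threshold segmenter, and endpoint extraction.

Masks are 3-class rasters (background / egg / reference) stored as RGB PNGs
in a fixed palette: background red (255, 0, 0), egg yellow (250, 250, 0),
reference white (255, 255, 255).  The egg and reference endpoints that feed
the measurement construction are *support points* of a class region: the
pixels extremal along a given image direction (typically the direction
toward the vanishing point of the measured axis), at pixel centers, with
ties broken by smaller row then smaller column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import (
    DegenerateInputError,
    EmptySegmentationError,
    PaletteError,
    ShapeError,
    TagError,
)
from .projective import PlanePoint

__all__ = [
    "CLASS_NAMES",
    "DEFAULT_PALETTE",
    "LabelMask",
    "AxisEndpoints",
    "SegmentationConfig",
    "read_label_mask",
    "write_label_mask",
    "segment_classical",
    "region_extreme_points",
    "average_reference_endpoints",
]

CLASS_NAMES = ("background", "egg", "reference")
#: class index -> RGB color of the stored mask
DEFAULT_PALETTE: dict[int, tuple[int, int, int]] = {
    0: (255, 0, 0),      # background
    1: (250, 250, 0),    # egg
    2: (255, 255, 255),  # reference
}


@dataclass
class LabelMask:
    """A 3-class segmentation raster with its class->RGB palette."""

    labels: np.ndarray  # uint8, shape (H, W), values in palette keys
    palette: dict[int, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_PALETTE)
    )

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2:
            raise ShapeError("labels must be a 2-D raster")
        colors = list(self.palette.values())
        if len(set(colors)) != len(colors):
            raise PaletteError("palette colors must be distinct (bijective)")
        unknown = set(np.unique(self.labels)) - set(self.palette)
        if unknown:
            raise PaletteError(f"labels contain classes without palette entry: {unknown}")

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    def class_index(self, cls: int | str) -> int:
        if isinstance(cls, str):
            try:
                return CLASS_NAMES.index(cls)
            except ValueError:
                raise PaletteError(f"unknown class name {cls!r}") from None
        return int(cls)

    def class_mask(self, cls: int | str) -> np.ndarray:
        return self.labels == self.class_index(cls)

    def to_rgb(self) -> np.ndarray:
        rgb = np.zeros((*self.labels.shape, 3), dtype=np.uint8)
        for k, color in self.palette.items():
            rgb[self.labels == k] = color
        return rgb


def write_label_mask(mask: LabelMask, png_path: str | Path) -> None:
    """Write a label mask as an RGB PNG in its palette."""
    Image.fromarray(mask.to_rgb(), mode="RGB").save(str(png_path), format="PNG")


def read_label_mask(
    png_path: str | Path,
    palette: dict[int, tuple[int, int, int]] | None = None,
    tolerance: int = 0,
) -> LabelMask:
    """Read a palette-encoded mask PNG.

    Every pixel must match a palette color exactly, or within ``tolerance``
    per channel (useful for JPEG-recompressed masks); otherwise a
    :class:`PaletteError` lists an offending RGB value.
    """
    palette = dict(DEFAULT_PALETTE) if palette is None else palette
    rgb = np.asarray(Image.open(str(png_path)).convert("RGB"), dtype=np.int16)
    labels = np.full(rgb.shape[:2], 255, dtype=np.uint8)
    dist = np.full(rgb.shape[:2], np.iinfo(np.int16).max, dtype=np.int16)
    for k, color in palette.items():
        d = np.abs(rgb - np.array(color, dtype=np.int16)).max(axis=2)
        hit = (d <= tolerance) & (d < dist)
        labels[hit] = k
        dist[hit] = d[hit]
    if (labels == 255).any():
        bad = rgb[labels == 255][0]
        raise PaletteError(f"unmatched pixel color {tuple(int(c) for c in bad)}")
    return LabelMask(labels=labels, palette=palette)


@dataclass(frozen=True)
class AxisEndpoints:
    """A pair of endpoint image points with the axis they belong to."""

    p1: PlanePoint
    p2: PlanePoint
    axis_tag: str  # "major", "minor" or "reference"

    def __post_init__(self) -> None:
        if self.p1.is_same(self.p2):
            raise DegenerateInputError("axis endpoints coincide")

    @property
    def pixel_length(self) -> float:
        return float(np.linalg.norm(self.p2.xy - self.p1.xy))


@dataclass
class SegmentationConfig:
    """Color-threshold segmentation settings.

    ``class_ranges`` maps class name -> (lower, upper) inclusive RGB bounds.
    Morphological opening/closing radii of 0 disable the operation (clean
    synthetic masks need none; set 1-2 for noisy photographs).  When
    ``largest_component`` is set, only the largest connected region of each
    foreground class is kept.
    """

    class_ranges: dict[str, tuple[tuple[int, int, int], tuple[int, int, int]]] = field(
        default_factory=lambda: {
            "egg": ((190, 170, 0), (255, 255, 140)),
            "reference": ((225, 225, 225), (255, 255, 255)),
        }
    )
    opening_radius: int = 0
    closing_radius: int = 0
    largest_component: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentationConfig":
        cfg = cls()
        if "class_ranges" in d:
            cfg.class_ranges = {
                k: (tuple(v[0]), tuple(v[1])) for k, v in d["class_ranges"].items()
            }
        cfg.opening_radius = int(d.get("opening_radius", cfg.opening_radius))
        cfg.closing_radius = int(d.get("closing_radius", cfg.closing_radius))
        cfg.largest_component = bool(d.get("largest_component", cfg.largest_component))
        return cfg


def _largest_component(binary: np.ndarray) -> np.ndarray:
    from skimage.measure import label

    lab = label(binary, connectivity=2)
    if lab.max() == 0:
        return binary
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == sizes.argmax()


def segment_classical(
    rgb_image: np.ndarray, config: SegmentationConfig | dict | None = None
) -> LabelMask:
    """Deterministic color-threshold segmentation into the 3-class mask.

    Pixels inside a class's RGB range are assigned to it (egg takes priority
    over reference on overlap); optional morphological opening then closing
    cleans speckle; optionally only the largest connected component per
    foreground class is kept.  Everything else is background.
    """
    from skimage.morphology import closing, disk, opening

    if config is None:
        config = SegmentationConfig()
    elif isinstance(config, dict):
        config = SegmentationConfig.from_dict(config)
    rgb = np.asarray(rgb_image)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ShapeError("rgb_image must be an (H, W, 3) array")

    labels = np.zeros(rgb.shape[:2], dtype=np.uint8)
    for name in ("reference", "egg"):  # egg painted last: priority on overlap
        if name not in config.class_ranges:
            continue
        lo, hi = config.class_ranges[name]
        sel = np.logical_and.reduce(
            [(rgb[..., c] >= lo[c]) & (rgb[..., c] <= hi[c]) for c in range(3)]
        )
        if config.opening_radius > 0:
            sel = opening(sel, disk(config.opening_radius)).astype(bool)
        if config.closing_radius > 0:
            sel = closing(sel, disk(config.closing_radius)).astype(bool)
        if config.largest_component:
            sel = _largest_component(sel)
        labels[sel] = CLASS_NAMES.index(name)
    if not (labels == 1).any():
        raise EmptySegmentationError("no egg-class pixels found")
    return LabelMask(labels=labels)


def region_extreme_points(
    mask: LabelMask, cls: int | str, direction, axis_tag: str | None = None
) -> AxisEndpoints:
    """Support points of a class region along a direction.

    Returns the pixels (at pixel centers) minimizing (p1) and maximizing (p2)
    the dot product with ``direction``; exact ties are broken by smaller row,
    then smaller column.
    """
    d = np.asarray(direction, dtype=float).reshape(2)
    n = np.linalg.norm(d)
    if n == 0:
        raise DegenerateInputError("direction must be nonzero")
    d = d / n
    rows, cols = np.nonzero(mask.class_mask(cls))
    if rows.size == 0:
        raise EmptySegmentationError(f"class {cls!r} region is empty")
    if rows.size == 1:
        raise EmptySegmentationError("single-pixel region has no distinct endpoints")
    s = cols * d[0] + rows * d[1]

    def pick(idx: np.ndarray) -> PlanePoint:
        order = np.lexsort((cols[idx], rows[idx]))
        i = idx[order[0]]
        return PlanePoint.from_xy(float(cols[i]), float(rows[i]))

    p1 = pick(np.flatnonzero(s == s.min()))
    p2 = pick(np.flatnonzero(s == s.max()))
    if axis_tag is None:
        axis_tag = "reference" if mask.class_index(cls) == 2 else "major"
    return AxisEndpoints(p1=p1, p2=p2, axis_tag=axis_tag)


def average_reference_endpoints(
    endpoint_sets: list[AxisEndpoints],
) -> AxisEndpoints:
    """Coordinate-wise mean of endpoint sets sharing one axis tag.

    Averaging the reference endpoints over several images of the same scene
    suppresses segmentation noise in the (small, hard-to-segment) reference
    region before the length transfer.
    """
    if len(endpoint_sets) < 1:
        raise ShapeError("need at least one endpoint set")
    tags = {s.axis_tag for s in endpoint_sets}
    if len(tags) != 1:
        raise TagError(f"mixed axis tags: {sorted(tags)}")
    p1 = np.mean([s.p1.xy for s in endpoint_sets], axis=0)
    p2 = np.mean([s.p2.xy for s in endpoint_sets], axis=0)
    return AxisEndpoints(
        p1=PlanePoint.from_xy(*p1), p2=PlanePoint.from_xy(*p2), axis_tag=tags.pop()
    )
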