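"""Formula-defined image morphometry.

Quantifications computed from RGB fluorescence fields where the blue
channel carries the nuclear stain (DAPI) and the red channel a marker of
interest (total YAP or phospho-YAP):

* nuclear aspect ratio NAR = d_short / d_long from the moment-equivalent
  ellipse of each segmented nucleus (1 = round, smaller = more elongated;
  an ``elongation`` flag returns the inverse convention d_long / d_short),
* mean nuclear cross-sectional area = DAPI+ area / number of cells,
* the nuclear colocalization ratio = red+ area inside nuclei / total red+
  area, and
* the normalized red-signal index = red+ area / number of nuclei in the
  field (used for phospho-YAP).

All scores are area-based: they depend on which pixels pass threshold,
not on how bright they are.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .errors import InvalidInputError

__all__ = [
    "ChannelStack",
    "LabeledNuclei",
    "ColocResult",
    "PyapIndex",
    "split_channels",
    "segment_nuclei",
    "nuclear_aspect_ratio",
    "mean_cross_sectional_area",
    "coloc_ratio",
    "per_nucleus_red_fraction",
    "pyap_index",
]


@dataclass(frozen=True)
class ChannelStack:
    """Single-channel views of an RGB field sharing one pixel geometry."""

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        if not (self.red.shape == self.green.shape == self.blue.shape):
            raise InvalidInputError("channel shapes differ")
        if self.pixel_size_um <= 0:
            raise InvalidInputError("pixel size must be positive")

    def to_rgb(self) -> np.ndarray:
        return np.stack([self.red, self.green, self.blue], axis=-1)


@dataclass(frozen=True)
class LabeledNuclei:
    """Per-nucleus records from a segmented nuclear channel.

    ``table`` columns: id, x_um, y_um, long_axis_um, short_axis_um,
    area_um2.  Axes are those of the moment-equivalent ellipse (same
    second central moments as the pixel region).
    """

    table: pd.DataFrame
    pixel_size_um: float
    channel: str = "blue"

    @property
    def n(self) -> int:
        return len(self.table)

    def aspect_ratios(self, elongation: bool = False) -> np.ndarray:
        return np.array(
            [
                nuclear_aspect_ratio(lo, sh, elongation=elongation)
                for lo, sh in zip(self.table["long_axis_um"], self.table["short_axis_um"])
            ]
        )


@dataclass(frozen=True)
class ColocResult:
    """Area partition of thresholded marker signal between compartments."""

    red_in_nuclei_area_um2: float
    total_red_area_um2: float

    @property
    def ratio(self) -> float:
        if self.total_red_area_um2 == 0:
            return float("nan")
        return self.red_in_nuclei_area_um2 / self.total_red_area_um2


@dataclass(frozen=True)
class PyapIndex:
    """Thresholded marker area normalized per nucleus in the field."""

    red_area_um2: float
    n_nuclei: int

    @property
    def index(self) -> float:
        return self.red_area_um2 / self.n_nuclei


def split_channels(rgb_image: np.ndarray, pixel_size_um: float) -> ChannelStack:
    """Split an (H, W, 3) raster into channel views without copying data."""
    img = np.asarray(rgb_image)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise InvalidInputError(f"expected an (H, W, 3) image, got shape {img.shape}")
    return ChannelStack(img[..., 0], img[..., 1], img[..., 2], pixel_size_um)


def _threshold_mask(channel: np.ndarray, threshold) -> np.ndarray:
    chan = np.asarray(channel)
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise InvalidInputError(f"unknown threshold method {threshold!r}")
        if chan.min() == chan.max():
            warnings.warn("channel is constant; nothing passes threshold", stacklevel=3)
            return np.zeros(chan.shape, dtype=bool)
        return chan > threshold_otsu(chan)
    return chan > float(threshold)


def segment_nuclei(
    channel: np.ndarray,
    pixel_size_um: float,
    threshold: float | Literal["otsu"] = "otsu",
    min_area_um2: float = 0.0,
    axis_mode: Literal["ellipse", "bbox"] = "ellipse",
    exclude_border: bool = False,
) -> tuple[LabeledNuclei, np.ndarray]:
    """Threshold, label and measure nuclei in a single channel.

    Components (8-connected) smaller than ``min_area_um2`` are discarded.
    ``axis_mode="ellipse"`` (default) measures long/short axes from the
    moment-equivalent ellipse, which is rotation invariant;
    ``"bbox"`` reports the axis-aligned bounding-box height/width instead,
    replicating a manual height-by-width readout.  ``exclude_border``
    drops nuclei touching the frame edge, whose shape is truncated by the
    field of view (standard practice for shape measurements).
    """
    if min_area_um2 < 0:
        raise InvalidInputError("min_area_um2 must be >= 0")
    if pixel_size_um <= 0:
        raise InvalidInputError("pixel size must be positive")
    mask = _threshold_mask(channel, threshold)
    records = []
    if mask.any():
        labels = label(mask, connectivity=2)
        if exclude_border:
            edge = np.unique(
                np.concatenate(
                    [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
                )
            )
            labels[np.isin(labels, edge[edge > 0])] = 0
        keep = np.zeros(labels.max() + 1, dtype=bool)
        for region in regionprops(labels):
            area = region.area * pixel_size_um**2
            if area < min_area_um2:
                continue
            keep[region.label] = True
            cy, cx = region.centroid
            if axis_mode == "ellipse":
                long_ax = region.axis_major_length * pixel_size_um
                short_ax = region.axis_minor_length * pixel_size_um
            elif axis_mode == "bbox":
                minr, minc, maxr, maxc = region.bbox
                a = (maxr - minr) * pixel_size_um
                b = (maxc - minc) * pixel_size_um
                long_ax, short_ax = max(a, b), min(a, b)
            else:
                raise InvalidInputError(f"unknown axis mode {axis_mode!r}")
            records.append(
                {
                    "id": region.label,
                    "x_um": cx * pixel_size_um,
                    "y_um": cy * pixel_size_um,
                    "long_axis_um": long_ax,
                    "short_axis_um": short_ax,
                    "area_um2": area,
                }
            )
        mask = keep[labels]
    else:
        warnings.warn("blank nuclear channel: no nuclei found", stacklevel=2)
    table = pd.DataFrame(
        records,
        columns=["id", "x_um", "y_um", "long_axis_um", "short_axis_um", "area_um2"],
    )
    return LabeledNuclei(table, pixel_size_um), mask


def nuclear_aspect_ratio(
    long_axis_um: float, short_axis_um: float, elongation: bool = False
) -> float:
    """NAR = d_short / d_long ∈ (0, 1]; 1 iff the nucleus is round.

    With ``elongation=True`` the inverse convention d_long / d_short (≥ 1,
    growing with elongation) is returned instead.
    """
    if long_axis_um <= 0 or short_axis_um <= 0:
        raise InvalidInputError("nucleus axes must be positive")
    lo, sh = max(long_axis_um, short_axis_um), min(long_axis_um, short_axis_um)
    return lo / sh if elongation else sh / lo


def mean_cross_sectional_area(
    nuclei_mask: np.ndarray, n_cells: int, pixel_size_um: float
) -> float:
    """Total nuclear-stain-positive area (μm²) divided by the cell count."""
    if n_cells < 1:
        raise InvalidInputError("n_cells must be >= 1")
    mask = np.asarray(nuclei_mask).astype(bool)
    return float(mask.sum()) * pixel_size_um**2 / n_cells


def coloc_ratio(
    red_channel: np.ndarray,
    nuclei_mask: np.ndarray,
    red_threshold: float | Literal["otsu"] = "otsu",
    pixel_size_um: float = 1.0,
) -> ColocResult:
    """Fraction of thresholded marker area lying inside nuclear boundaries.

    Returns a :class:`ColocResult`; the ratio is NaN (with a warning) when
    no pixel passes the marker threshold.
    """
    red = np.asarray(red_channel)
    mask = np.asarray(nuclei_mask).astype(bool)
    if red.shape != mask.shape:
        raise InvalidInputError("red channel and nuclei mask shapes differ")
    red_pos = _threshold_mask(red, red_threshold)
    total = float(red_pos.sum()) * pixel_size_um**2
    inside = float((red_pos & mask).sum()) * pixel_size_um**2
    if total == 0:
        warnings.warn("no marker-positive pixels; colocalization undefined", stacklevel=2)
    return ColocResult(inside, total)


def per_nucleus_red_fraction(
    red_channel: np.ndarray,
    nuclei_labels: np.ndarray,
    red_threshold: float | Literal["otsu"] = "otsu",
) -> pd.DataFrame:
    """Optional per-nucleus readout: share of total red+ area in each nucleus."""
    red_pos = _threshold_mask(np.asarray(red_channel), red_threshold)
    total = red_pos.sum()
    rows = []
    for region in regionprops(np.asarray(nuclei_labels)):
        inside = red_pos[region.coords[:, 0], region.coords[:, 1]].sum()
        rows.append(
            {
                "id": region.label,
                "red_pixels_inside": int(inside),
                "fraction_of_total_red": inside / total if total else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["id", "red_pixels_inside", "fraction_of_total_red"])


def pyap_index(
    red_channel: np.ndarray,
    n_nuclei: int,
    red_threshold: float | Literal["otsu"] = "otsu",
    pixel_size_um: float = 1.0,
) -> PyapIndex:
    """Thresholded marker area (μm²) per nucleus in the field."""
    if n_nuclei < 1:
        raise InvalidInputError("n_nuclei must be >= 1")
    red_pos = _threshold_mask(np.asarray(red_channel), red_threshold)
    return PyapIndex(float(red_pos.sum()) * pixel_size_um**2, n_nuclei)
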