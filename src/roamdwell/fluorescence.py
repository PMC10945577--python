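"""Reporter-fluorescence quantification.

Per-animal expression of a fluorescent transcriptional reporter is scored as
the maximum pixel intensity within a circular region of interest over the
neuron's cell body, mirroring the manual FIJI workflow: no background
subtraction by default (an optional rolling-minimum flag exists), just the
raw maximum. Condition effects are summarised as the ratio of group means
of the per-animal maxima, e.g. non-ingestible food over ingestible food.
"""

from __future__ import annotations

import dataclasses

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.feature import peak_local_max

from .errors import DetectionError, EmptyInputError, ValidationError
from .types import NeuronROI


def read_intensity_image(path: str | Path) -> np.ndarray:
    """Read a single-channel TIFF as a float 2-D array."""
    image = tifffile.imread(path)
    if image.ndim != 2:
        raise ValidationError(
            f"{path}: expected a single-channel 2-D image, got shape {image.shape}"
        )
    return np.asarray(image, dtype=float)


def write_intensity_image(image: np.ndarray, path: str | Path) -> None:
    """Write a 2-D intensity array as a 16-bit TIFF (values clipped/rounded)."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValidationError("only 2-D single-channel images are written")
    tifffile.imwrite(path, np.clip(np.rint(image), 0, 65535).astype(np.uint16))


def detect_spot_rois(
    image: np.ndarray,
    n_spots: int,
    min_separation_px: int,
    *,
    smooth_sigma_px: float = 2.0,
    radius_px: int = 5,
    neurons: tuple[str, ...] = ("ASJ", "ASI"),
) -> list[NeuronROI]:
    """Detect the ``n_spots`` brightest well-separated local maxima.

    The image is Gaussian-smoothed before peak picking so single hot pixels
    do not masquerade as cell bodies. ROIs are returned in descending peak
    order and assigned neuron names cyclically from ``neurons`` (brightest
    first; identity assignment beyond ranked order is out of scope).
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise EmptyInputError("empty image")
    if n_spots < 1:
        raise ValidationError("n_spots must be >= 1")
    smoothed = ndimage.gaussian_filter(image, smooth_sigma_px)
    coords = peak_local_max(
        smoothed,
        min_distance=max(int(min_separation_px), 1),
        num_peaks=n_spots,
        exclude_border=False,
    )
    # peak_local_max on a constant image returns no peaks
    if len(coords) < n_spots:
        raise DetectionError(
            f"requested {n_spots} spot(s) but found only {len(coords)}"
        )
    return [
        NeuronROI(
            neuron=neurons[i % len(neurons)],
            center_xy_px=(int(c[1]), int(c[0])),
            radius_px=radius_px,
        )
        for i, c in enumerate(coords)
    ]


def roi_max_intensity(image: np.ndarray, roi: NeuronROI) -> float:
    """Maximum pixel value within the disc of ``roi.radius_px`` around the
    ROI centre (pixels whose centre lies within the radius)."""
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    cx, cy = roi.center_xy_px
    r = roi.radius_px
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValidationError(f"ROI centre {roi.center_xy_px} outside {w}x{h} image")
    y0, y1 = max(cy - r, 0), min(cy + r + 1, h)
    x0, x1 = max(cx - r, 0), min(cx + r + 1, w)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return float(image[y0:y1, x0:x1][disc].max())


def subtract_rolling_minimum(image: np.ndarray, window_px: int = 25) -> np.ndarray:
    """Optional background flattening: subtract a rolling-minimum estimate."""
    image = np.asarray(image, dtype=float)
    background = ndimage.minimum_filter(image, size=window_px)
    return np.clip(image - background, 0.0, None)


@dataclasses.dataclass(frozen=True)
class RatioResult:
    """Ratio of group mean maxima between two conditions."""

    genotype: str
    neuron: str
    cond_num: str
    cond_den: str
    ratio: float
    mean_num: float
    mean_den: float
    n_num: int
    n_den: int


def condition_ratio(
    table: pd.DataFrame,
    genotype: str,
    neuron: str,
    cond_num: str,
    cond_den: str,
) -> RatioResult:
    """Fold-change of mean per-animal maximum intensity between conditions.

    ``table`` is a validated fluorescence table (see
    :func:`roamdwell.io.read_fluorescence_table`). Raises
    :class:`ValidationError` when either group is empty or the denominator
    mean is zero.
    """
    sel = (table["genotype"] == genotype) & (table["neuron"] == neuron)
    num = table.loc[sel & (table["condition"] == cond_num), "max_intensity_au"]
    den = table.loc[sel & (table["condition"] == cond_den), "max_intensity_au"]
    if num.empty or den.empty:
        raise ValidationError(
            f"empty group for {genotype}/{neuron}: "
            f"n({cond_num})={len(num)}, n({cond_den})={len(den)}"
        )
    mean_den = float(den.mean())
    if mean_den == 0:
        raise ValidationError(f"denominator group {cond_den!r} has zero mean")
    mean_num = float(num.mean())
    return RatioResult(
        genotype=genotype,
        neuron=neuron,
        cond_num=cond_num,
        cond_den=cond_den,
        ratio=mean_num / mean_den,
        mean_num=mean_num,
        mean_den=mean_den,
        n_num=int(len(num)),
        n_den=int(len(den)),
    )


def group_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per (genotype, neuron, condition) mean, SD and n of the maxima."""
    return (
        table.groupby(["genotype", "neuron", "condition"])["max_intensity_au"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
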