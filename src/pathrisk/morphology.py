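"""Quantitative fluorescence morphometry.

Each field carries three channels: F-actin (phalloidin), focal adhesions
(vinculin) and nuclei (DAPI). Metrics: fraction of the field covered by
cells, nuclei count, the cell-size metric (percent field area covered by
cells divided by the nuclei count), the three shortest inter-nucleus
center distances, and the stain-area fractions of the cell region. Group
differences are evaluated with two-sided Welch t-tests over fields.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy import stats
from scipy.spatial.distance import pdist
from skimage import filters, measure, morphology as skmorph, segmentation, util


@dataclass
class FluorescenceField:
    actin: np.ndarray
    adhesion: np.ndarray
    nuclei: np.ndarray
    sample_id: str = ""
    group: str = "control"  # control | high_risk
    pixel_size: float | None = None  # microns per pixel

    def __post_init__(self) -> None:
        if not (self.actin.shape == self.adhesion.shape == self.nuclei.shape):
            raise ValueError("all three channels must share dimensions")
        for ch in (self.actin, self.adhesion, self.nuclei):
            if np.any(ch < 0):
                raise ValueError("intensities must be non-negative")


@dataclass
class MorphometryResult:
    cell_area_fraction: float
    n_nuclei: int
    cell_size_metric: float
    shortest3: np.ndarray
    actin_fraction: float
    adhesion_fraction: float
    sample_id: str = ""
    group: str = ""


def _to_uint8(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return (img > 0).astype(np.uint8) * 255
    return util.img_as_ubyte((img - lo) / (hi - lo))


def _binarize(image: np.ndarray) -> np.ndarray:
    """8-bit conversion, min-max contrast stretch, Otsu threshold.

    The stretch is full-range (not percentile-clipped): with sparse
    foreground — nuclei often cover <2% of a field — percentile clipping
    rescales background noise to full range and destroys the threshold.
    """
    img8 = _to_uint8(image)  # includes the min-max contrast stretch
    if img8.min() == img8.max():
        return img8 > 0
    return img8 > filters.threshold_otsu(img8)


def segment_cell_area(field: FluorescenceField | np.ndarray) -> tuple[np.ndarray, float]:
    """Binary cell mask and the fraction of the field covered by cells.

    Pipeline: 8-bit conversion, contrast stretch, Otsu threshold,
    morphological closing, hole filling. For a three-channel field, the
    cell region is segmented from the combined actin+adhesion signal.
    """
    if isinstance(field, FluorescenceField):
        image = field.actin.astype(float) + field.adhesion.astype(float)
    else:
        image = np.asarray(field, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    binary = _binarize(image)
    if not binary.any():
        return binary, 0.0
    closed = skmorph.closing(binary, skmorph.disk(3))
    filled = ndi.binary_fill_holes(closed)
    return filled, float(filled.mean())


def count_nuclei(
    nuclei_channel: np.ndarray,
    min_area: int = 30,
    min_peak_distance: int = 5,
) -> tuple[int, np.ndarray]:
    """Count nuclei and return their centroids.

    Binarize, fill holes, then split touching nuclei by marker-controlled
    watershed on the distance transform (edge-guided blob separation);
    particles below ``min_area`` pixels are discarded.
    """
    image = np.asarray(nuclei_channel, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    binary = ndi.binary_fill_holes(_binarize(image))
    if not binary.any():
        return 0, np.empty((0, 2))
    distance = ndi.distance_transform_edt(binary)
    from skimage.feature import peak_local_max

    coords = peak_local_max(distance, min_distance=min_peak_distance, labels=binary)
    markers = np.zeros(binary.shape, dtype=int)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels = measure.label(binary)
    else:
        labels = segmentation.watershed(-distance, markers, mask=binary)
    centers = []
    for region in measure.regionprops(labels):
        if region.area >= min_area:
            centers.append(region.centroid)
    centers_arr = np.asarray(centers) if centers else np.empty((0, 2))
    return len(centers_arr), centers_arr


def cell_size_metric(cell_area_fraction: float, n_nuclei: int) -> float:
    """Percent of field area covered by cells per nucleus: 100 * fraction / count."""
    if n_nuclei < 1:
        warnings.warn("no nuclei detected; cell-size metric undefined", stacklevel=2)
        return float("nan")
    return 100.0 * cell_area_fraction / n_nuclei


def nearest_nucleus_distances(centers: np.ndarray, pixel_size: float | None = None) -> np.ndarray:
    """Three smallest pairwise Euclidean center distances, sorted ascending."""
    centers = np.asarray(centers, dtype=float)
    if len(centers) < 2:
        warnings.warn("fewer than 2 nuclei; no inter-nucleus distances", stacklevel=2)
        return np.empty(0)
    d = np.sort(pdist(centers))[:3]
    return d * pixel_size if pixel_size else d


def stain_fraction(
    stain_channel: np.ndarray,
    cell_mask: np.ndarray,
    background: str = "outside-median",
    median_radius: int = 25,
) -> float:
    """Proportion of the cell area covered by a stain.

    Background subtraction (by default the median intensity outside the
    cell mask — the true background region; optionally a median-filter
    rolling-ball analog), contrast enhancement, Otsu binarization, then
    stain-and-mask pixels over mask pixels.
    """
    stain = np.asarray(stain_channel, dtype=float)
    mask = np.asarray(cell_mask, dtype=bool)
    if not mask.any():
        warnings.warn("empty cell mask; stain fraction undefined", stacklevel=2)
        return float("nan")
    if background == "outside-median":
        bg = float(np.median(stain[~mask])) if (~mask).any() else 0.0
        corrected = np.clip(stain - bg, 0, None)
    elif background == "median-filter":
        bg_img = ndi.median_filter(stain, size=2 * median_radius + 1)
        corrected = np.clip(stain - bg_img, 0, None)
    else:
        raise ValueError(background)
    # threshold from within-cell intensities: the stain channel is trimodal
    # (background / diffuse cell signal / bright stain) and a global Otsu
    # would merge the diffuse signal with the stain
    inside = corrected[mask]
    if inside.min() == inside.max():
        binary = corrected > 0
    else:
        binary = corrected > _otsu_exact(inside)
    return float((binary & mask).sum() / mask.sum())


def _otsu_exact(values: np.ndarray) -> float:
    """Otsu's criterion on exact values (no histogram binning).

    Maximizes between-class variance over splits at midpoints between
    consecutive distinct sorted values; avoids the bin-quantization leak
    of histogram Otsu when a class sits exactly on a bin boundary.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    cum = np.cumsum(v)
    i = np.arange(1, n)
    w1 = i / n
    mu1 = cum[:-1] / i
    mu2 = (cum[-1] - cum[:-1]) / (n - i)
    sb = w1 * (1 - w1) * (mu1 - mu2) ** 2
    sb[v[1:] <= v[:-1]] = -1.0  # only split between distinct values
    j = int(np.argmax(sb))
    return 0.5 * (v[j] + v[j + 1])


def quantify_field(field: FluorescenceField, min_area: int = 30) -> MorphometryResult:
    """All morphometry metrics for one field."""
    mask, frac = segment_cell_area(field)
    n, centers = count_nuclei(field.nuclei, min_area=min_area)
    return MorphometryResult(
        cell_area_fraction=frac,
        n_nuclei=n,
        cell_size_metric=cell_size_metric(frac, n) if n else float("nan"),
        shortest3=nearest_nucleus_distances(centers, field.pixel_size) if n >= 2 else np.empty(0),
        actin_fraction=stain_fraction(field.actin, mask) if mask.any() else float("nan"),
        adhesion_fraction=stain_fraction(field.adhesion, mask) if mask.any() else float("nan"),
        sample_id=field.sample_id,
        group=field.group,
    )


def compare_groups(per_field_metrics: dict[str, dict[str, np.ndarray]]) -> dict[str, dict[str, float]]:
    """Two-sided Welch t-test per metric between two groups of fields.

    ``per_field_metrics`` maps group name -> metric name -> vector of
    per-field values. Fields (not patients) are the statistical unit.
    Returns metric -> {t, p, mean_<group>...}. Zero variance in both
    groups with equal means gives P = 1.
    """
    groups = list(per_field_metrics)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    g1, g2 = groups
    out: dict[str, dict[str, float]] = {}
    for metric in per_field_metrics[g1]:
        x = np.asarray(per_field_metrics[g1][metric], dtype=float)
        y = np.asarray(per_field_metrics[g2][metric], dtype=float)
        x, y = x[~np.isnan(x)], y[~np.isnan(y)]
        if len(x) < 2 or len(y) < 2:
            raise ValueError(f"metric {metric!r}: need >=2 fields per group")
        if x.std() == 0 and y.std() == 0:
            t, p = (0.0, 1.0) if x.mean() == y.mean() else (float("inf"), 0.0)
        else:
            t, p = stats.ttest_ind(x, y, equal_var=False)
        out[metric] = {
            "t": float(t),
            "p": float(p),
            f"mean_{g1}": float(x.mean()),
            f"mean_{g2}": float(y.mean()),
        }
    return out
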