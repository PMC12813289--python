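"""Lymphatic vascular density, vessel reconnection, and IHC area fraction.

LVD follows the imaging workflow: average-project the NIRF stack, enhance
curvilinear structures with a multiscale Hessian tubeness filter, segment
with a trainable pixel classifier (random-forest over a Weka-like feature
stack; Otsu-on-tubeness fallback when untrained), and divide the segmented
area by a genotype-specific normalization ROI. Reconnection of a transected
vessel is declared on the first day a segmented component touches both
lymph-node ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_closing, gaussian_filter
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from skimage.filters import threshold_otsu
from skimage.measure import label
from sklearn.ensemble import RandomForestClassifier

from .pumping import ImageStack, ROI

__all__ = [
    "VesselnessParams",
    "SegmentationModel",
    "NormalizationRoi",
    "LvdResult",
    "ReconnectionResult",
    "average_projection",
    "tubeness",
    "pixel_features",
    "train_segmenter",
    "segment",
    "compute_lvd",
    "reconnection_day",
    "area_fraction",
    "dice",
]


@dataclass(frozen=True)
class VesselnessParams:
    """Multiscale bright-tube filter settings.

    scales are Gaussian sigmas in pixels; the response at each scale is
    sigma^2 * max(0, -lambda2) where lambda2 is the larger-magnitude
    Hessian eigenvalue (negative across a bright ridge), maximized over
    scales. ``normalized=False`` drops the sigma^2 factor.
    """

    scales: tuple[float, ...] = (1.0, 2.0, 3.0)
    normalized: bool = True

    def __post_init__(self) -> None:
        if not self.scales or any(s <= 0 for s in self.scales):
            raise ValueError("scales must be non-empty and all > 0")


@dataclass(frozen=True)
class NormalizationRoi:
    """Genotype normalization region: a square whose side is the mean of
    the ear-to-tail and back-to-belly body lengths (mm)."""

    genotype: str
    ear_to_tail_mm: float
    back_to_belly_mm: float

    def __post_init__(self) -> None:
        if self.ear_to_tail_mm <= 0 or self.back_to_belly_mm <= 0:
            raise ValueError("body lengths must be > 0")

    @property
    def side_mm(self) -> float:
        return 0.5 * (self.ear_to_tail_mm + self.back_to_belly_mm)

    @property
    def area_mm2(self) -> float:
        return self.side_mm**2


@dataclass(frozen=True)
class LvdResult:
    segmented_area: float
    roi_area: float
    density: float
    units: str  # "mm2" or "px2"


@dataclass(frozen=True)
class ReconnectionResult:
    days: tuple[int, ...]
    connected: tuple[bool, ...]
    reconnection_day: int | None  # None = not reconnected

    @property
    def reconnected(self) -> bool:
        return self.reconnection_day is not None


def average_projection(stack: ImageStack) -> np.ndarray:
    """Per-pixel mean across frames (the time-averaged flow image)."""
    return stack.frames.mean(axis=0)


def tubeness(image: np.ndarray, params: VesselnessParams | None = None) -> np.ndarray:
    """Multiscale Hessian vesselness for bright tubes on dark background."""
    params = params or VesselnessParams()
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 2:
        raise ValueError("image must be 2-D, at least 2x2")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    best = np.zeros_like(image)
    for s in params.scales:
        H = hessian_matrix(
            image, sigma=s, mode="reflect", order="rc", use_gaussian_derivatives=True
        )
        e1, e2 = hessian_matrix_eigvals(H)  # e1 >= e2 by value
        lam2 = np.where(np.abs(e1) >= np.abs(e2), e1, e2)  # max |.| eigenvalue
        resp = np.maximum(0.0, -lam2)
        if params.normalized:
            resp = s**2 * resp
        best = np.maximum(best, resp)
    return best


# ---------------------------------------------------------------------------
# trainable segmentation
# ---------------------------------------------------------------------------


def pixel_features(
    image: np.ndarray, scales: tuple[float, ...] = (1.0, 2.0, 3.0)
) -> np.ndarray:
    """Weka-style per-pixel feature stack: raw intensity plus, per scale,
    Gaussian smoothing, gradient magnitude, both Hessian eigenvalues and a
    difference of Gaussians. Shape (H, W, F)."""
    image = np.asarray(image, dtype=float)
    feats = [image]
    for s in scales:
        g = gaussian_filter(image, s)
        gr, gc = np.gradient(g)
        feats.append(g)
        feats.append(np.hypot(gr, gc))
        H = hessian_matrix(image, sigma=s, mode="reflect", order="rc", use_gaussian_derivatives=True)
        e1, e2 = hessian_matrix_eigvals(H)
        feats.extend([e1, e2])
        feats.append(g - gaussian_filter(image, 2.0 * s))
    return np.stack(feats, axis=-1)


@dataclass
class SegmentationModel:
    """Trainable pixel classifier (vessel vs background)."""

    scales: tuple[float, ...] = (1.0, 2.0, 3.0)
    n_trees: int = 100
    seed: int = 0
    classifier: RandomForestClassifier | None = None

    @property
    def trained(self) -> bool:
        return self.classifier is not None


class DegenerateTrainingError(ValueError):
    pass


def train_segmenter(
    image: np.ndarray,
    label_rows: np.ndarray,
    label_cols: np.ndarray,
    label_classes: np.ndarray,
    model: SegmentationModel | None = None,
    seed: int | None = None,
) -> SegmentationModel:
    """Fit the pixel classifier on sparse labels (1 = vessel, 0 = background).

    Both classes must be present. The fitted forest is deterministic for a
    fixed seed and label set.
    """
    model = model or SegmentationModel()
    if seed is not None:
        model.seed = seed
    classes = np.asarray(label_classes, dtype=int)
    if len(np.unique(classes)) < 2:
        raise DegenerateTrainingError("labels must contain both classes")
    F = pixel_features(image, model.scales)
    X = F[np.asarray(label_rows, dtype=int), np.asarray(label_cols, dtype=int)]
    clf = RandomForestClassifier(
        n_estimators=model.n_trees, random_state=model.seed, n_jobs=1
    )
    clf.fit(X, classes)
    model.classifier = clf
    return model


def segment(
    image: np.ndarray,
    model: SegmentationModel | None = None,
    fallback_params: VesselnessParams | None = None,
) -> np.ndarray:
    """Binary vessel mask.

    With a trained model: per-pixel classification over the feature stack.
    Without one: deterministic fallback of Otsu thresholding the tubeness
    map (keeps the pipeline runnable untrained).
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    if model is not None and model.trained:
        F = pixel_features(image, model.scales)
        pred = model.classifier.predict(F.reshape(-1, F.shape[-1]))
        return pred.reshape(image.shape).astype(bool)
    vmap = tubeness(image, fallback_params)
    if vmap.max() == 0:
        return np.zeros(image.shape, dtype=bool)
    mask = vmap > threshold_otsu(vmap)
    # Otsu always splits something, even pure noise; accept the mask only
    # when the putative vessels are actually brighter than the rest
    fg, bg = image[mask], image[~mask]
    if fg.size == 0 or bg.size == 0:
        return np.zeros(image.shape, dtype=bool)
    bg_sd = bg.std()
    if fg.mean() - bg.mean() < 2.0 * (bg_sd if bg_sd > 0 else 1.0):
        return np.zeros(image.shape, dtype=bool)
    return mask


def compute_lvd(
    mask: np.ndarray,
    pixel_size_um: float | None = None,
    norm: NormalizationRoi | float | None = None,
) -> LvdResult:
    """Segmented area divided by the normalization ROI area.

    With ``pixel_size_um`` the numerator is in mm^2 and ``norm`` must be a
    NormalizationRoi (mm^2); uncalibrated, both are in px^2 and ``norm`` is
    a plain area in px^2.
    """
    mask = np.asarray(mask, dtype=bool)
    count = int(mask.sum())
    if isinstance(norm, NormalizationRoi):
        if pixel_size_um is None or pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0 for a mm-based ROI")
        seg_area = count * (pixel_size_um / 1000.0) ** 2
        roi_area = norm.area_mm2
        units = "mm2"
    else:
        if norm is None or norm <= 0:
            raise ValueError("norm area must be > 0")
        seg_area = float(count)
        roi_area = float(norm)
        units = "px2"
    return LvdResult(
        segmented_area=seg_area,
        roi_area=roi_area,
        density=seg_area / roi_area,
        units=units,
    )


def _connected(mask: np.ndarray, roi_a: ROI, roi_b: ROI) -> bool:
    closed = binary_closing(mask, structure=np.ones((3, 3), dtype=bool))
    lab = label(closed, connectivity=2)
    in_a = np.unique(lab[roi_a.mask(mask.shape) & closed])
    in_b = np.unique(lab[roi_b.mask(mask.shape) & closed])
    in_a = set(in_a[in_a > 0])
    in_b = set(in_b[in_b > 0])
    return bool(in_a & in_b)


def reconnection_day(
    series: dict[int, np.ndarray], roi_a: ROI, roi_b: ROI
) -> ReconnectionResult:
    """First day with continuous flow between the two node ROIs.

    A day is connected when, after one pass of 3x3 morphological closing
    (tolerating 1-px segmentation gaps), an 8-connected foreground
    component intersects both ROIs. Re-occlusion on later days is allowed;
    the reconnection day is simply the earliest connected day.
    """
    if not series:
        raise ValueError("series must contain >= 1 day")
    days = tuple(sorted(series))
    shape = np.asarray(series[days[0]]).shape
    if np.any(roi_a.mask(shape) & roi_b.mask(shape)):
        raise ValueError("node ROIs must not overlap")
    flags = tuple(
        _connected(np.asarray(series[d], dtype=bool), roi_a, roi_b) for d in days
    )
    first = next((d for d, f in zip(days, flags) if f), None)
    return ReconnectionResult(days=days, connected=flags, reconnection_day=first)


def area_fraction(mask: np.ndarray, region: ROI | None = None) -> float:
    """Foreground fraction of the region (whole image by default)."""
    mask = np.asarray(mask, dtype=bool)
    if region is None:
        total = mask.size
        pos = int(mask.sum())
    else:
        rr, cc = region.footprint(mask.shape)
        total = rr.size
        pos = int(mask[rr, cc].sum())
    if total == 0:
        raise ValueError("region is empty")
    return pos / total


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
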