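"""Nucleus segmentation with pluggable backends.

The default ``classical`` backend (Gaussian smoothing, automatic ratio
thresholding, distance-transform watershed splitting, area filter) is fully
deterministic and needs no model weights. A ``stardist`` backend delegates
to the published 2-D model when the optional dependency is installed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_isodata, threshold_li, threshold_otsu
from skimage.segmentation import relabel_sequential, watershed

from .errors import (
    BackendUnavailableError,
    ConfigurationError,
    EmptySegmentationWarning,
)
from .image_io import CalibratedImage

__all__ = ["LabelMap", "segment_nuclei", "filter_labels"]

_THRESHOLD_METHODS = {
    "otsu": threshold_otsu,
    "isodata": threshold_isodata,
    "li": threshold_li,
}


@dataclass
class LabelMap:
    """Integer-labeled objects on the image grid.

    ``0`` is background; labels form the contiguous range ``1..K`` and are
    pairwise disjoint (one pixel, one label). Calibration is inherited from
    the source image.
    """

    labels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ConfigurationError("label map must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ConfigurationError("label map must be integer-typed")
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be > 0")
        present = np.unique(self.labels)
        present = present[present > 0]
        k = len(present)
        if k and (present[0] != 1 or present[-1] != k):
            raise ConfigurationError(
                f"labels must be contiguous 1..K; found {present.tolist()[:10]}..."
            )

    @classmethod
    def from_array(cls, labels: np.ndarray, pixel_size_um: float) -> "LabelMap":
        """Build a LabelMap, renumbering to 1..K preserving label order."""
        relabeled, _, _ = relabel_sequential(np.asarray(labels))
        return cls(labels=relabeled.astype(np.int32), pixel_size_um=pixel_size_um)

    @property
    def n_labels(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def label_ids(self) -> list[int]:
        return list(range(1, self.n_labels + 1))

    def mask(self, label_id: int) -> np.ndarray:
        return self.labels == label_id

    def areas_px(self) -> dict[int, int]:
        counts = np.bincount(self.labels.ravel(), minlength=self.n_labels + 1)
        return {lid: int(counts[lid]) for lid in self.label_ids}


@dataclass
class ClassicalParams:
    """Settings for the deterministic classical backend.

    smooth_sigma_um : Gaussian smoothing scale before thresholding.
    threshold_method : 'otsu' | 'isodata' | 'li' (all ratio-based, so the
        result is invariant to a positive rescaling of intensities).
    min_area_um2 : objects smaller than this physical area are dropped.
    split_touching : split merged blobs by watershed on the distance
        transform, seeded at local distance maxima.
    min_peak_distance_um : minimum separation of watershed seeds.
    """

    smooth_sigma_um: float = 0.5
    threshold_method: str = "otsu"
    min_area_um2: float = 0.0
    split_touching: bool = True
    min_peak_distance_um: float = 2.0

    @classmethod
    def from_dict(cls, d: dict | None) -> "ClassicalParams":
        d = dict(d or {})
        known = {f for f in cls.__dataclass_fields__}
        bad = set(d) - known
        if bad:
            raise ConfigurationError(f"unknown classical-backend params: {sorted(bad)}")
        return cls(**d)


def _segment_classical(
    plane: np.ndarray, roi_mask: np.ndarray, pixel_size_um: float, params: ClassicalParams
) -> np.ndarray:
    method = _THRESHOLD_METHODS.get(params.threshold_method)
    if method is None:
        raise ConfigurationError(
            f"unknown threshold method {params.threshold_method!r}; "
            f"choose from {sorted(_THRESHOLD_METHODS)}"
        )
    img = np.where(roi_mask, plane.astype(float), 0.0)
    if img.max() <= 0 or np.ptp(img) == 0:
        return np.zeros(plane.shape, dtype=np.int32)
    sigma_px = params.smooth_sigma_um / pixel_size_um
    smoothed = gaussian(img, sigma=sigma_px, preserve_range=True) if sigma_px > 0 else img
    thresh = method(smoothed)
    # refine to the midpoint of the two class means: for a blurred binary
    # object the half-amplitude level set recovers the original support,
    # which zero-dominated histograms otherwise overgrow
    low = smoothed[smoothed <= thresh]
    high = smoothed[smoothed > thresh]
    if len(low) and len(high):
        thresh = 0.5 * (low.mean() + high.mean())
    binary = (smoothed > thresh) & roi_mask
    if not binary.any():
        return np.zeros(plane.shape, dtype=np.int32)
    if params.split_touching:
        distance = ndi.distance_transform_edt(binary)
        min_dist_px = max(1, int(round(params.min_peak_distance_um / pixel_size_um)))
        blob_labels, _ = ndi.label(binary)
        peaks = peak_local_max(
            distance, min_distance=min_dist_px, labels=blob_labels, exclude_border=False
        )
        markers = np.zeros(plane.shape, dtype=np.int32)
        for i, (py, px) in enumerate(peaks, start=1):
            markers[py, px] = i
        if markers.max() == 0:
            labels = blob_labels
        else:
            labels = watershed(-distance, markers=markers, mask=binary)
    else:
        labels, _ = ndi.label(binary)
    return labels.astype(np.int32)


def _segment_stardist(plane: np.ndarray, params: dict) -> np.ndarray:
    """Adapter around the published StarDist 2-D fluorescence model.

    ``prob_thresh`` / ``nms_thresh`` are passed through; ``None`` keeps the
    plugin defaults.
    """
    try:
        from csbdeep.utils import normalize
        from stardist.models import StarDist2D
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise BackendUnavailableError(
            "stardist backend requested but the 'stardist' package is not "
            "installed; install it or fall back to backend='classical'"
        ) from exc
    model = StarDist2D.from_pretrained(params.get("model", "2D_versatile_fluo"))
    labels, _ = model.predict_instances(
        normalize(plane.astype(float)),
        prob_thresh=params.get("prob_thresh"),
        nms_thresh=params.get("nms_thresh"),
    )
    return np.asarray(labels, dtype=np.int32)


def segment_nuclei(
    image: CalibratedImage,
    roi_mask: np.ndarray | None = None,
    backend: str = "classical",
    params: dict | ClassicalParams | None = None,
) -> LabelMap:
    """Segment nuclei on the nuclear channel of a single-plane image.

    The ROI mask is applied to the nuclear channel before thresholding and
    again to the label output, so pixels outside the ROI are always
    background. An all-background result emits
    :class:`EmptySegmentationWarning`, not an error.
    """
    if image.n_z != 1:
        raise ConfigurationError("segment_nuclei requires a single-plane image; project first")
    plane = image.plane(image.nuclear_channel_index)
    if roi_mask is None:
        roi_mask = np.ones(plane.shape, dtype=bool)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != plane.shape:
        raise ConfigurationError(
            f"roi_mask shape {roi_mask.shape} does not match image {plane.shape}"
        )
    if backend == "classical":
        cparams = params if isinstance(params, ClassicalParams) else ClassicalParams.from_dict(params)
        raw = _segment_classical(plane, roi_mask, image.pixel_size_um, cparams)
        min_area = cparams.min_area_um2
    elif backend == "stardist":
        raw = _segment_stardist(plane, dict(params or {}))
        min_area = float((params or {}).get("min_area_um2", 0.0)) if isinstance(params, dict) else 0.0
    else:
        raise ConfigurationError(f"unknown segmentation backend {backend!r}")
    raw = np.where(roi_mask, raw, 0)
    result = LabelMap.from_array(raw, image.pixel_size_um)
    if min_area > 0:
        result = filter_labels(result, min_area)
    if result.n_labels == 0:
        warnings.warn("segmentation produced no labels", EmptySegmentationWarning, stacklevel=2)
    return result


def filter_labels(
    labels: LabelMap, min_area_um2: float, calibration: float | None = None
) -> LabelMap:
    """Drop labels with physical area below ``min_area_um2``; renumber to 1..K'.

    Area is ``pixel count x calibration^2``; calibration defaults to the
    map's own pixel size. Surviving labels keep their relative order.
    """
    cal = calibration if calibration is not None else labels.pixel_size_um
    if min_area_um2 <= 0:
        return LabelMap.from_array(labels.labels, labels.pixel_size_um)
    areas = labels.areas_px()
    keep = {lid for lid, a in areas.items() if a * cal * cal >= min_area_um2}
    out = np.where(np.isin(labels.labels, sorted(keep)), labels.labels, 0)
    return LabelMap.from_array(out, labels.pixel_size_um)
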