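"""Calibrated images and closed boundary contours.

A leaf blade is represented throughout the package by its closed boundary
polygon in centimetres, oriented counterclockwise with y increasing upward,
together with the index of the base point P where the blade meets the
petiole.  P anchors the radial filtration of the topological method and is
the coordinate origin convention of the synthetic generator.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters import threshold_otsu


class SegmentationError(RuntimeError):
    """Foreground could not be isolated from the image."""


class DegeneracyError(RuntimeError):
    """An operation reduced its input to something unusable."""


class GeometryError(ValueError):
    """Contour violates a geometric precondition (e.g. self-intersection)."""


@dataclass(frozen=True)
class CalibratedImage:
    """2-D intensity grid with a pixels-per-cm calibration.

    ``px_per_cm`` is the calibration of the source image; ``downscale`` is
    the linear factor already applied to it (e.g. a 152 px/cm scan reduced
    by 1/8 is stored with px_per_cm=152, downscale=8, giving an effective
    19 px/cm).
    """

    pixels: np.ndarray
    px_per_cm: float
    downscale: float = 1.0

    def __post_init__(self) -> None:
        if self.px_per_cm <= 0 or self.downscale <= 0:
            raise ValueError("px_per_cm and downscale must be positive")
        if np.asarray(self.pixels).ndim != 2:
            raise ValueError("pixels must be a 2-D grayscale array")

    @property
    def effective_px_per_cm(self) -> float:
        return self.px_per_cm / self.downscale


@dataclass
class PlanarContour:
    """Ordered closed boundary polygon in cm with a marked base point.

    ``points`` has shape (n, 2); the polygon closes implicitly from the
    last vertex back to the first.  Orientation is counterclockwise in a
    y-up coordinate frame; ``base_index`` marks the vertex P.
    """

    points: np.ndarray
    base_index: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise GeometryError("points must have shape (n, 2)")
        if len(pts) < 32:
            raise GeometryError(f"contour needs >= 32 points, got {len(pts)}")
        # drop consecutive duplicates (incl. wrap-around)
        keep = np.any(pts != np.roll(pts, 1, axis=0), axis=1)
        if not keep.all():
            base_xy = pts[self.base_index]
            pts = pts[keep]
            self.base_index = int(np.argmin(np.hypot(*(pts - base_xy).T)))
        if signed_area(pts) < 0:
            pts = pts[::-1]
            self.base_index = len(pts) - 1 - self.base_index
        self.points = pts
        if not 0 <= self.base_index < len(pts):
            raise GeometryError("base_index out of range")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def base_point(self) -> np.ndarray:
        return self.points[self.base_index]

    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def diameter(self) -> float:
        p = self.points
        return float(np.hypot(*(p.max(0) - p.min(0))) )

    def is_simple(self) -> bool:
        from shapely.geometry import LinearRing

        try:
            return LinearRing(self.points).is_simple
        except Exception:
            return False

    def resampled(self, n_points: int) -> "PlanarContour":
        """Equal-arc-length resampling, keeping P as vertex 0."""
        pts = resample_closed(np.roll(self.points, -self.base_index, axis=0),
                              n_points)
        return PlanarContour(pts, base_index=0, meta=dict(self.meta))

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        flag = np.zeros(len(self), dtype=int)
        flag[self.base_index] = 1
        pd.DataFrame({"x_cm": self.points[:, 0], "y_cm": self.points[:, 1],
                      "is_basepoint": flag}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PlanarContour":
        import pandas as pd

        df = pd.read_csv(path)
        base = int(np.flatnonzero(df["is_basepoint"].to_numpy())[0])
        return cls(df[["x_cm", "y_cm"]].to_numpy(float), base_index=base)

    def to_json(self, path: str | Path, **metadata) -> None:
        payload = {"x_cm": self.points[:, 0].tolist(),
                   "y_cm": self.points[:, 1].tolist(),
                   "base_index": int(self.base_index),
                   "metadata": {**self.meta, **metadata}}
        Path(path).write_text(json.dumps(payload))


def signed_area(points: np.ndarray) -> float:
    """Shoelace signed area; positive for counterclockwise (y-up)."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def resample_closed(points: np.ndarray, n_points: int,
                    max_iter: int = 25) -> np.ndarray:
    """Resample a closed polyline to n_points equally spaced in arc length.

    The first input vertex is preserved as the first output vertex, which is
    how the base point stays on the resampled contour.  Spacing is iterated
    to the uniform-chord fixed point (one pass leaves chords unequal where
    the curve bends), which makes the operation idempotent.
    """
    if n_points < 32:
        raise ValueError("n_points must be >= 32")
    pts = np.asarray(points, dtype=float)
    for _ in range(max_iter):
        closed = np.vstack([pts, pts[:1]])
        seg = np.hypot(*np.diff(closed, axis=0).T)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        if total <= 0:
            raise GeometryError("zero-length contour")
        if len(pts) == n_points and np.ptp(seg) <= 1e-12 * seg.mean():
            break
        t = np.linspace(0.0, total, n_points, endpoint=False)
        pts = np.column_stack([np.interp(t, s, closed[:, 0]),
                               np.interp(t, s, closed[:, 1])])
    return pts


# ---------------------------------------------------------------------------
# image path: segment -> remove petiole -> trace -> locate P


def segment_leaf(image: CalibratedImage, threshold_strategy: str = "otsu",
                 foreground: str = "dark") -> np.ndarray:
    """Isolate the leaf as a binary mask.

    Global Otsu threshold (or fixed numeric threshold passed as a string),
    polarity per ``foreground``; the largest connected component is kept and
    interior holes are filled.
    """
    px = np.asarray(image.pixels, dtype=float)
    if px.size == 0:
        raise SegmentationError("empty image")
    if threshold_strategy == "otsu":
        if np.ptp(px) == 0:
            raise SegmentationError("image has no contrast")
        thr = threshold_otsu(px)
    else:
        thr = float(threshold_strategy)
    mask = px < thr if foreground == "dark" else px > thr
    if not mask.any():
        raise SegmentationError("no foreground after thresholding")
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n + 1))
        order = np.argsort(sizes)[::-1]
        if len(sizes) > 1 and sizes[order[1]] > 0.5 * sizes[order[0]]:
            warnings.warn("multiple comparable components; keeping largest")
        mask = labels == order[0] + 1
    return ndimage.binary_fill_holes(mask)


def remove_petiole(mask: np.ndarray, image: CalibratedImage,
                   max_stalk_width_cm: float = 0.3) -> np.ndarray:
    """Strip thin stalk-like protrusions by calibrated morphological opening.

    Protrusions narrower than ``max_stalk_width_cm`` are erased; the blade
    (wider than the opening radius) survives.  Wider stalks are retained —
    callers needing to keep them can pass a smaller width.
    """
    radius_px = max(1, int(round(0.5 * max_stalk_width_cm
                                 * image.effective_px_per_cm)))
    opened = morphology.opening(mask.astype(bool), morphology.disk(radius_px))
    if not opened.any():
        raise DegeneracyError(
            f"opening at max_stalk_width_cm={max_stalk_width_cm} removed "
            "the whole mask")
    labels, n = ndimage.label(opened)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n + 1))
        opened = labels == int(np.argmax(sizes)) + 1
    return opened


def extract_contour(mask: np.ndarray, image: CalibratedImage,
                    n_points: int = 200) -> PlanarContour:
    """Trace the outer boundary of the mask and convert to cm.

    The boundary is traced at sub-pixel resolution, converted with the
    effective calibration into a y-up cm frame, resampled to ``n_points``
    equally spaced in arc length and oriented counterclockwise.
    """
    if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() \
            or mask[:, -1].any():
        raise GeometryError("mask touches the image border; contour clipped")
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise SegmentationError("no boundary found")
    rc = max(contours, key=len)  # outer boundary of the single component
    ppcm = image.effective_px_per_cm
    h = mask.shape[0]
    xy = np.column_stack([rc[:, 1] / ppcm, (h - 1 - rc[:, 0]) / ppcm])
    pts = resample_closed(xy, n_points)
    return PlanarContour(pts, base_index=0,
                         meta={"px_per_cm": image.px_per_cm,
                               "downscale": image.downscale,
                               "n_points": n_points})


def locate_base_point(contour: PlanarContour,
                      petiole_hint: tuple[float, float] | None = None,
                      tol: float = 1e-9) -> PlanarContour:
    """Mark the base point P on a contour.

    With a hint, P is the vertex nearest the hint (the recommended path for
    photographs, where the blade/petiole junction is known approximately).
    Without one, P is the lowest vertex assuming the blade is oriented
    base-down; ties within ``tol`` resolve to the lowest index.
    """
    pts = contour.points
    if petiole_hint is not None:
        hint = np.asarray(petiole_hint, dtype=float)
        d = np.hypot(*(pts - hint).T)
        if d.min() > contour.diameter():
            warnings.warn("petiole hint is farther than the leaf diameter; "
                          "using nearest vertex anyway")
        idx = int(np.argmin(d))
    else:
        y = pts[:, 1]
        candidates = np.flatnonzero(y <= y.min() + tol)
        if len(candidates) > 1:
            warnings.warn("ambiguous lowest point; lowest index wins")
        idx = int(candidates[0])
    return replace(contour, points=pts, base_index=idx)
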