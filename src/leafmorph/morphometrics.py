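"""Blade area, area groups, and the area-from-shape regression.

Area comes from the boundary polygon by Green's theorem (the shoelace
line integral).  Leaves are partitioned into four conventional area
groups, and leaf area is regressed on the first two principal-component
scores of a shape descriptor to quantify how strongly shape encodes area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contour import GeometryError, PlanarContour, signed_area

#: Half-open area intervals in cm^2; the boundary value 24 belongs to A3.
AREA_GROUP_EDGES = (8.0, 16.0, 24.0)
AREA_GROUP_LABELS = ("A1", "A2", "A3", "A4")


@dataclass(frozen=True)
class AreaRecord:
    leaf_id: str
    area: float  # cm^2
    group: str

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("area must be positive")


@dataclass
class RegressionResult:
    """OLS fit of area ~ 1 + PC1 + PC2."""

    coefficients: np.ndarray  # (intercept, b1, b2)
    r_squared: float
    predicted: np.ndarray
    n: int

    def to_frame(self, areas: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame({"measured_cm2": areas,
                             "predicted_cm2": self.predicted})


def polygon_area(contour: PlanarContour | np.ndarray,
                 check_simple: bool = True) -> float:
    """Blade area (cm^2) of the closed boundary polygon, by shoelace."""
    if isinstance(contour, PlanarContour):
        if check_simple and not contour.is_simple():
            raise GeometryError("self-intersecting contour has no area")
        pts = contour.points
    else:
        pts = np.asarray(contour, dtype=float)
    return abs(signed_area(pts))


def assign_area_group(area: float) -> str:
    """Area group label: A1 <= 8 < A2 <= 16 < A3 <= 24 < A4 (cm^2)."""
    if area <= 0:
        raise ValueError("area must be positive")
    return AREA_GROUP_LABELS[int(np.searchsorted(AREA_GROUP_EDGES, area))]


def area_table(contours: dict[str, PlanarContour] | list[PlanarContour],
               check_simple: bool = False) -> pd.DataFrame:
    """Per-leaf area and group, as a tidy table."""
    if not isinstance(contours, dict):
        contours = {f"leaf_{i:04d}": c for i, c in enumerate(contours)}
    rows = []
    for leaf_id, c in contours.items():
        a = polygon_area(c, check_simple=check_simple)
        rows.append({"leaf_id": leaf_id, "area_cm2": a,
                     "group": assign_area_group(a)})
    return pd.DataFrame(rows)


def area_regression(scores: np.ndarray, areas: np.ndarray
                    ) -> RegressionResult:
    """OLS of leaf area on the first two PC scores; R^2 = 1 - SSE/SST."""
    scores = np.asarray(scores, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if scores.ndim != 2 or scores.shape[1] < 2:
        raise ValueError("scores must have at least two columns")
    if len(scores) != len(areas) or len(areas) < 3:
        raise ValueError("need >= 3 aligned (scores, area) pairs")
    X = np.column_stack([np.ones(len(areas)), scores[:, 0], scores[:, 1]])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient design (degenerate scores)")
    beta, *_ = np.linalg.lstsq(X, areas, rcond=None)
    pred = X @ beta
    sse = float(np.sum((areas - pred) ** 2))
    sst = float(np.sum((areas - areas.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    return RegressionResult(coefficients=beta, r_squared=r2,
                            predicted=pred, n=len(areas))
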