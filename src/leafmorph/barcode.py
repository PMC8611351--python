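"""Radial persistence barcodes of leaf contours.

The topological descriptor of a leaf is built from the Euclidean distance
of every contour vertex to the base point P.  Sweeping a threshold r
downward from max(d), the superlevel set {vertices with d >= r} gains a
connected component at every local maximum of the profile and loses one at
every merge; the elder rule ends the younger component's bar.  The result
is a multiset of (birth_r, death_r) intervals: the longest bar measures
blade size (largest distance to P), the second the depth of the central
furrow, shorter bars the depth of marginal indentations.

Bars are computed with a union-find over the cyclic vertex adjacency,
processing vertices by decreasing distance — the standard sublevel/
superlevel 0-dimensional persistence algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contour import PlanarContour
from .ordination import PCAModel, classical_mds, pca_fit

#: Ten-vertex demonstration profile (cyclic radial distances) whose
#: superlevel component counts at r = 8.6, 7.0, 5.4, 3.8 are 4, 3, 2, 1.
EXAMPLE_RADIAL_PROFILE = (0.0, 4.0, 8.8, 7.4, 9.2, 5.2, 8.9, 6.0, 9.5, 0.5)


@dataclass
class RadialProfile:
    """Cyclically ordered distances (cm) from contour vertices to P."""

    d: np.ndarray
    base_index: int = 0

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.ndim != 1 or len(self.d) < 3:
            raise ValueError("profile must be 1-D with >= 3 values")
        if (self.d < 0).any():
            raise ValueError("distances must be non-negative")


@dataclass
class Barcode:
    """Multiset of (birth_r, death_r) bars, birth_r >= death_r >= 0.

    Exactly one bar — the essential component — has death_r = 0 and length
    max(d).  Bars are stored sorted by decreasing length.
    """

    bars: np.ndarray  # (k, 2) columns birth_r, death_r

    def __post_init__(self) -> None:
        b = np.asarray(self.bars, dtype=float).reshape(-1, 2)
        order = np.argsort(b[:, 1] - b[:, 0], kind="stable")
        self.bars = b[order]

    @property
    def lengths(self) -> np.ndarray:
        return self.bars[:, 0] - self.bars[:, 1]

    def __len__(self) -> int:
        return len(self.bars)

    def significant(self, min_length: float) -> "Barcode":
        """Bars longer than ``min_length``; the essential bar is always
        kept.  Useful to ignore machine-precision bars produced by flat
        plateaus of the profile (e.g. an exactly circular margin)."""
        keep = (self.lengths > min_length) | (self.bars[:, 1] == 0)
        return Barcode(self.bars[keep])


@dataclass
class BarcodeVector:
    """Bar lengths sorted descending, zero-padded to a common length."""

    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if (np.diff(v) > 1e-12).any() or (v < 0).any():
            raise ValueError("values must be non-increasing and >= 0")
        self.values = v


def radial_distance_profile(contour: PlanarContour) -> RadialProfile:
    """Euclidean distance (cm) of each contour vertex to the base point P."""
    delta = contour.points - contour.base_point
    d = np.hypot(delta[:, 0], delta[:, 1])
    d[contour.base_index] = 0.0
    return RadialProfile(d=d, base_index=contour.base_index)


def superlevel_barcode(profile: RadialProfile) -> Barcode:
    """0-dimensional persistence of the decreasing-r superlevel filtration.

    Vertices enter by decreasing d (ties by increasing index) into a
    union-find over the cyclic adjacency.  A component is born at the d of
    its first vertex; when two components meet, the younger one (smaller
    birth; birth ties resolved so the smaller first-vertex index survives)
    dies at the current threshold.  The surviving component's bar closes at
    death_r = 0.  Equivalent, for every r > 0, to counting contiguous
    contour segments with d >= r.
    """
    d = profile.d
    n = len(d)
    order = np.lexsort((np.arange(n), -d))
    parent = np.full(n, -1, dtype=int)  # -1: not yet inserted
    birth_val = np.empty(n)
    birth_idx = np.empty(n, dtype=int)
    bars: list[tuple[float, float]] = []

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    for v in order:
        parent[v] = v
        birth_val[v] = d[v]
        birth_idx[v] = v
        for nb in ((v - 1) % n, (v + 1) % n):
            if parent[nb] < 0:
                continue
            ra, rb = find(v), find(nb)
            if ra == rb:
                continue
            # elder rule: the earlier-born (larger birth) component survives
            if (birth_val[ra], -birth_idx[ra]) < (birth_val[rb], -birth_idx[rb]):
                ra, rb = rb, ra
            if birth_val[rb] > d[v]:
                bars.append((birth_val[rb], d[v]))
            parent[rb] = ra
    root = find(int(order[0]))
    bars.append((birth_val[root], 0.0))
    return Barcode(np.array(bars))


def component_count(profile: RadialProfile, r: float) -> int:
    """Number of contiguous cyclic segments with d >= r (r > 0)."""
    mask = profile.d >= r
    if not mask.any():
        return 0
    if mask.all():
        return 1
    starts = mask & ~np.roll(mask, 1)
    return int(starts.sum())


def vectorize_barcode(barcode: Barcode, L: int) -> BarcodeVector:
    """Descending bar lengths zero-padded to length L (never truncated)."""
    lengths = np.sort(barcode.lengths)[::-1]
    if L < len(lengths):
        raise ValueError(f"L={L} is smaller than the bar count {len(lengths)}")
    return BarcodeVector(np.pad(lengths, (0, L - len(lengths))))


def normalize_vector(vector: BarcodeVector) -> BarcodeVector:
    """Divide by the first bar length and drop the leading 1.

    Removes absolute size, leaving relative indentation depths — the
    setting used when modern and fossil leaves are embedded together.
    """
    v = vector.values
    if v[0] <= 0:
        raise ValueError("first bar length must be positive to normalize")
    return BarcodeVector(v[1:] / v[0], normalized=True)


def pad_length(barcodes: list[Barcode]) -> int:
    """Population-wide vector length: the maximum bar count."""
    return max(len(b) for b in barcodes)


def embed_population(vectors: list[BarcodeVector],
                     method: str = "pca",
                     n_components: int | None = None) -> PCAModel:
    """Ordinate a population of barcode vectors.

    ``method='pca'``: centered PCA, no variable scaling.
    ``method='classical_mds'``: principal coordinates of the Euclidean
    distance matrix; scores agree with PCA up to an orthogonal transform.
    """
    if len(vectors) < 2:
        raise ValueError("need >= 2 vectors")
    lengths = {len(v.values) for v in vectors}
    if len(lengths) != 1:
        raise ValueError("vectors must share a common length")
    X = np.vstack([v.values for v in vectors])
    if method == "pca":
        return pca_fit(X, n_components)
    if method == "classical_mds":
        return classical_mds(X, n_components)
    raise ValueError(f"unknown method {method!r}")
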