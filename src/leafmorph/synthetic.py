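"""Parametric fan-shaped leaf contours with known ground truth.

The generator emulates *Ginkgo*-like blades: a fan sector of radius R about
the blade/petiole junction P, a central furrow splitting the blade into two
lobes (or several furrows for multi-lobed, fossil-like forms), and optional
margin crenulation.  In polar coordinates about P = (0, 0), with the blade
opening upward, the margin is

    rho(theta) = R * (1 - f * g(theta)) * (1 + a * sin(k * theta))

over theta in [theta0, pi - theta0], where g is a sum of raised-cosine
bumps (one per furrow) with maximum 1, f is the fractional furrow depth,
and a, k are the crenulation amplitude and count.  Two straight radial
edges join the margin ends to P, so P always lies on the contour with
radial distance exactly zero — the anchor the barcode filtration needs.

Because every generated vertex lies exactly on this model (edges are radial
lines, margin vertices are evaluated from rho), ground-truth radii are
exact and blade area equals the polar integral (1/2) * int rho^2 dtheta.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import simpson

from .contour import CalibratedImage, DegeneracyError, PlanarContour


@dataclass(frozen=True)
class LeafParams:
    """Parameters of one synthetic leaf.

    R: overall blade radius (cm).
    sector_halfangle: half-angle of the fan sector at the base (rad).
    furrow_depth_frac: fractional radial depth f of the furrow(s), in [0, 1).
    furrow_width: angular width of each furrow bump (rad).
    cren_amp: crenulation amplitude as a fraction of R.
    cren_freq: crenulation count around the margin.
    n_lobes: number of lobes (n_lobes - 1 furrows); > 2 emulates
        multi-lobed fossil forms.
    noise_sd: sd of radial jitter (cm), applied to every vertex except P.
    seed: RNG seed for the jitter.
    """

    R: float = 4.0
    sector_halfangle: float = 1.1
    furrow_depth_frac: float = 0.3
    furrow_width: float = 0.5
    cren_amp: float = 0.0
    cren_freq: int = 12
    n_lobes: int = 2
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("R must be positive")
        if not 0.0 <= self.furrow_depth_frac < 1.0:
            raise ValueError("furrow_depth_frac must be in [0, 1)")
        if self.cren_amp < 0 or self.cren_amp + self.furrow_depth_frac >= 1:
            raise ValueError("cren_amp + furrow_depth_frac must stay below 1 "
                             "(radial profile must remain positive)")
        if not 0 < self.sector_halfangle <= np.pi / 2:
            raise ValueError("sector_halfangle must be in (0, pi/2]")
        if self.n_lobes < 1:
            raise ValueError("n_lobes must be >= 1")
        if self.furrow_width <= 0:
            raise ValueError("furrow_width must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SyntheticLeaf:
    """A generated contour plus the exact model values it was drawn from."""

    contour: PlanarContour
    params: LeafParams
    truth_area: float
    truth_max_radius: float
    truth_furrow_min_radius: float = float("nan")


def _furrow_centers(p: LeafParams) -> np.ndarray:
    theta0 = np.pi / 2 - p.sector_halfangle
    span = 2 * p.sector_halfangle
    k = p.n_lobes - 1
    if k == 0:
        return np.empty(0)
    return theta0 + span * np.arange(1, k + 1) / p.n_lobes


def _bump(theta: np.ndarray, p: LeafParams) -> np.ndarray:
    """Sum of raised-cosine furrow bumps, clipped to max 1."""
    g = np.zeros_like(theta)
    for c in _furrow_centers(p):
        inside = np.abs(theta - c) <= p.furrow_width / 2
        g[inside] += 0.5 * (1 + np.cos(2 * np.pi * (theta[inside] - c)
                                       / p.furrow_width))
    return np.minimum(g, 1.0)


def radial_profile_model(theta: np.ndarray, p: LeafParams) -> np.ndarray:
    """Margin radius rho(theta) of the noiseless model."""
    theta = np.asarray(theta, dtype=float)
    rho = p.R * (1 - p.furrow_depth_frac * _bump(theta, p)) \
        * (1 + p.cren_amp * np.sin(p.cren_freq * theta))
    return rho


def generate_leaf(params: LeafParams, n_points: int = 200) -> SyntheticLeaf:
    """Generate one leaf contour with vertices exactly on the polar model.

    Vertices are distributed approximately equally in arc length along
    edge--margin--edge; P = (0, 0) is vertex 0.  Radial jitter of sd
    ``noise_sd`` is added afterwards (P excepted), and a contour that
    self-intersects at the requested noise raises a degeneracy error.
    """
    p = params
    if n_points < 32:
        raise ValueError("n_points must be >= 32")
    theta0 = np.pi / 2 - p.sector_halfangle
    theta1 = np.pi - theta0

    # dense arc-length table of the margin
    tg = np.linspace(theta0, theta1, 4096)
    rho = radial_profile_model(tg, p)
    xy = np.column_stack([rho * np.cos(tg), rho * np.sin(tg)])
    seg = np.hypot(*np.diff(xy, axis=0).T)
    s_arc = np.concatenate([[0.0], np.cumsum(seg)])
    len_arc = s_arc[-1]
    len_e0, len_e1 = rho[0], rho[-1]
    total = len_e0 + len_arc + len_e1

    s = np.linspace(0.0, total, n_points, endpoint=False)
    pts = np.empty((n_points, 2))
    on_e0 = s < len_e0
    on_arc = (s >= len_e0) & (s < len_e0 + len_arc)
    on_e1 = s >= len_e0 + len_arc
    # first radial edge: P out to the margin start
    frac = s[on_e0] / len_e0
    pts[on_e0] = frac[:, None] * xy[0]
    # margin: theta found by arc length, point evaluated from the model
    th = np.interp(s[on_arc] - len_e0, s_arc, tg)
    r = radial_profile_model(th, p)
    pts[on_arc] = np.column_stack([r * np.cos(th), r * np.sin(th)])
    # second radial edge: margin end back to P
    frac = (s[on_e1] - len_e0 - len_arc) / len_e1
    pts[on_e1] = (1 - frac)[:, None] * xy[-1]

    if p.noise_sd > 0:
        from scipy.ndimage import gaussian_filter1d

        rng = np.random.default_rng(p.seed)
        d = np.hypot(pts[:, 0], pts[:, 1])
        # correlated along the contour (margin irregularity is smooth at
        # the vertex spacing); white jitter at neighbouring vertices would
        # fold the polygon onto itself
        jitter = gaussian_filter1d(rng.normal(0.0, 1.0, n_points),
                                   sigma=2.0, mode="wrap")
        jitter *= p.noise_sd / max(jitter.std(), 1e-12)
        # taper jitter near P: a full-amplitude radial kick at a vertex a
        # fraction of a millimetre from the junction would fold the two
        # basal edges across each other
        jitter *= np.minimum(1.0, d / (8.0 * p.noise_sd))
        nonzero = d > 1e-12
        pts[nonzero] *= (1 + jitter[nonzero] / d[nonzero])[:, None]

    contour = PlanarContour(pts, base_index=0,
                            meta={"model": "fan-sector", "seed": p.seed})
    if not contour.is_simple():
        raise DegeneracyError(
            "contour self-intersects at noise_sd="
            f"{p.noise_sd}; lower noise_sd or cren_amp")

    tq = np.linspace(theta0, theta1, 20001)
    rq = radial_profile_model(tq, p)
    area = 0.5 * float(simpson(rq ** 2, x=tq))
    centers = _furrow_centers(p)
    furrow_min = float(radial_profile_model(centers, p).min()) \
        if len(centers) else float("nan")
    return SyntheticLeaf(contour=contour, params=p, truth_area=area,
                         truth_max_radius=float(rq.max()),
                         truth_furrow_min_radius=furrow_min)


DEFAULT_DISTRIBUTIONS: Mapping[str, object] = {
    # ranges chosen to span small short-shoot to large long-shoot blades:
    # areas cover roughly 2-40 cm^2, furrows from absent to deep
    "R": (2.0, 7.0),
    "sector_halfangle": (0.7, 1.3),
    "furrow_depth_frac": (0.0, 0.6),
    "furrow_width": (0.3, 0.7),
    "cren_amp": (0.0, 0.03),
    "cren_freq": (8, 20),
    "n_lobes": 2,
    "noise_sd": 0.01,
}


def generate_population(
    n: int,
    param_distributions: Mapping[str, object] | None = None,
    seed: int = 0,
    n_points: int = 200,
) -> tuple[list[SyntheticLeaf], pd.DataFrame]:
    """Generate ``n`` independent leaves and an aligned trait table.

    ``param_distributions`` maps LeafParams field names to either a fixed
    value, a (low, high) uniform range (integer fields sample integers
    inclusive of both ends), or a callable rng -> value.  Unspecified
    fields use DEFAULT_DISTRIBUTIONS.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    dists = dict(DEFAULT_DISTRIBUTIONS)
    if param_distributions:
        unknown = set(param_distributions) - set(dists) - {"seed"}
        if unknown:
            raise ValueError(f"unknown parameter fields: {sorted(unknown)}")
        dists.update(param_distributions)
    rng = np.random.default_rng(seed)
    int_fields = {"cren_freq", "n_lobes"}

    leaves: list[SyntheticLeaf] = []
    rows = []
    for i in range(n):
        kw: dict = {}
        for name, spec in dists.items():
            if callable(spec):
                kw[name] = spec(rng)
            elif isinstance(spec, (tuple, list)) and len(spec) == 2:
                lo, hi = spec
                if lo > hi:
                    raise ValueError(f"invalid range for {name}: {spec}")
                if name in int_fields:
                    kw[name] = int(rng.integers(lo, hi + 1))
                else:
                    kw[name] = float(rng.uniform(lo, hi))
            else:
                kw[name] = spec
            if name in int_fields:
                kw[name] = int(kw[name])
        kw["seed"] = int(rng.integers(0, 2 ** 31 - 1))
        leaf = generate_leaf(LeafParams(**kw), n_points=n_points)
        leaves.append(leaf)
        rows.append({"leaf_id": f"leaf_{i:04d}", **kw,
                     "area_cm2": leaf.truth_area,
                     "max_radius_cm": leaf.truth_max_radius,
                     "furrow_min_radius_cm": leaf.truth_furrow_min_radius})
    return leaves, pd.DataFrame(rows)


def rasterize_contour(contour: PlanarContour, px_per_cm: float = 50.0,
                      pad_cm: float = 0.5, leaf_level: int = 40,
                      background_level: int = 220) -> CalibratedImage:
    """Render a contour as a calibrated grayscale image (dark leaf on a
    light background), for exercising the image-processing path."""
    from skimage.draw import polygon

    pts = contour.points
    lo = pts.min(0) - pad_cm
    hi = pts.max(0) + pad_cm
    w = int(np.ceil((hi[0] - lo[0]) * px_per_cm))
    h = int(np.ceil((hi[1] - lo[1]) * px_per_cm))
    col = (pts[:, 0] - lo[0]) * px_per_cm
    row = h - 1 - (pts[:, 1] - lo[1]) * px_per_cm
    img = np.full((h, w), background_level, dtype=np.uint8)
    rr, cc = polygon(row, col, shape=img.shape)
    img[rr, cc] = leaf_level
    return CalibratedImage(pixels=img, px_per_cm=px_per_cm, downscale=1.0)


def write_population(leaves: Sequence[SyntheticLeaf], traits: pd.DataFrame,
                     outdir) -> None:
    """Write per-leaf contour CSVs and the trait table."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for leaf_id, leaf in zip(traits["leaf_id"], leaves):
        leaf.contour.to_csv(outdir / f"{leaf_id}.csv")
    traits.to_csv(outdir / "traits.csv", index=False)
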