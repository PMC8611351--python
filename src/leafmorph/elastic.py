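"""Elastic shape analysis of closed planar boundary curves.

Shapes are compared with the square-root-velocity (SRV) elastic metric: a
curve c(t) is mapped to q(t) = c'(t) / sqrt(|c'(t)|), in which the elastic
geodesic distance becomes the L2 distance, and the similarity of two
blades is the minimum of that distance over the nuisance group —
translations (removed by centering), rotations (orthogonal Procrustes,
closed form), cyclic seam shifts and orientation-preserving
reparametrizations (dynamic programming with bounded local slope).  With
the scale-invariant flag, curves are first normalized to unit length.

On top of the metric sit the usual shape-space statistics: the Karcher
mean by iterated align-average-update, tangent-space linearization about
the mean, PCA of the tangent vectors, and geodesic "shoots" along
principal components for visualizing the modes of variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .contour import PlanarContour, resample_closed
from .ordination import PCAModel, pca_fit

# DP moves (di, dj): local slope dj/di confined to [1/3, 3]
_DP_MOVES = ((1, 1), (1, 2), (2, 1), (1, 3), (3, 1), (2, 3), (3, 2))


@dataclass
class ShapeCurve:
    """Closed curve resampled to n points, centered, plus its SRV transform.

    ``points`` (n, 2) are equally spaced in arc length with the centroid at
    the origin; ``q`` (n, 2) holds the discrete SRV samples.  When
    ``scale_invariant`` is set the curve is normalized to unit length, so
    ||q||^2 = 1.
    """

    points: np.ndarray
    scale_invariant: bool = False
    q: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        pts = pts - pts.mean(axis=0)
        self.points = pts
        self.q = srv_transform(pts)

    @property
    def n(self) -> int:
        return len(self.points)

    def length(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def diameter(self) -> float:
        p = self.points
        return float(np.hypot(*(p.max(0) - p.min(0))))


@dataclass
class Alignment:
    """Optimal nuisance transform carrying curve b onto curve a."""

    shift: int
    rotation: np.ndarray  # (2, 2) proper rotation
    gamma: np.ndarray     # (n + 1,) monotone reparametrization of [0, n]
    scale: float = 1.0
    distance: float = float("nan")


def srv_transform(points: np.ndarray) -> np.ndarray:
    """Discrete SRV: q_k = v_k / sqrt(|v_k|) with v the periodic forward
    difference scaled to the unit parameter interval."""
    n = len(points)
    v = (np.roll(points, -1, axis=0) - points) * n
    speed = np.maximum(np.hypot(v[:, 0], v[:, 1]), 1e-300)
    return v / np.sqrt(speed)[:, None]


def srv_inverse(q: np.ndarray) -> np.ndarray:
    """Integrate SRV samples back to a closed, centered curve.

    A generic q does not integrate to an exactly closed curve; the closure
    defect is distributed linearly along arc length.
    """
    n = len(q)
    v = q * np.hypot(q[:, 0], q[:, 1])[:, None] / n
    pts = np.vstack([[0.0, 0.0], np.cumsum(v, axis=0)])
    gap = pts[-1]
    seg = np.hypot(v[:, 0], v[:, 1])
    s = np.concatenate([[0.0], np.cumsum(seg)])
    frac = s / max(s[-1], 1e-300)
    pts = pts - frac[:, None] * gap
    pts = pts[:-1]
    return pts - pts.mean(axis=0)


def to_shape_curve(contour: PlanarContour | np.ndarray, n: int = 100,
                   scale_invariant: bool = False) -> ShapeCurve:
    """Resample a contour to n points, center it, and attach its SRV.

    Accepts a PlanarContour or a raw (m, 2) closed polyline.  For a
    PlanarContour the resampling starts at the base point, so two copies of
    the same outline marked at the same P discretize identically whatever
    their storage seam.
    """
    if n < 50:
        raise ValueError("n must be >= 50")
    if isinstance(contour, PlanarContour):
        pts = np.roll(contour.points, -contour.base_index, axis=0)
    else:
        pts = np.asarray(contour, dtype=float)
    pts = resample_closed(pts, n)
    if scale_invariant:
        d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
        length = np.hypot(d[:, 0], d[:, 1]).sum()
        if length <= 0:
            raise ValueError("degenerate zero-length contour")
        pts = pts / length
    return ShapeCurve(pts, scale_invariant=scale_invariant)


# ---------------------------------------------------------------------------
# metric


def _sq(q: np.ndarray) -> np.ndarray:
    return q[:, 0] ** 2 + q[:, 1] ** 2


def _norm2(q: np.ndarray) -> float:
    """Squared L2 norm with the 1/n quadrature weight."""
    return float(_sq(q).sum() / len(q))


def _optimal_rotation(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||q1 - R q2|| (closed form in 2-D)."""
    a = float(np.sum(q1 * q2))
    b = float(np.sum(q1[:, 1] * q2[:, 0] - q1[:, 0] * q2[:, 1]))
    theta = np.arctan2(b, a)
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def _screen_seams(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Rotation-optimal squared distance for every cyclic seam shift.

    Returns an (n,) array: entry m is min_R ||q1 - R roll(q2, -m)||^2.
    """
    n = len(q1)
    idx = (np.arange(n)[None, :] + np.arange(n)[:, None]) % n
    Q2 = q2[idx]  # (m, k, 2): roll by -m
    a = np.einsum("mkd,kd->m", Q2, q1)
    b = np.einsum("mk,k->m", Q2[:, :, 0], q1[:, 1]) \
        - np.einsum("mk,k->m", Q2[:, :, 1], q1[:, 0])
    cross = np.hypot(a, b)
    return (_sq(q1).sum() + _sq(q2).sum() - 2 * cross) / n


def _interp_q(q: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Periodic linear interpolation of SRV samples at fractional indices."""
    n = len(q)
    pos = np.mod(pos, n)
    i0 = np.floor(pos).astype(int) % n
    i1 = (i0 + 1) % n
    w = (pos - np.floor(pos))[..., None]
    return (1 - w) * q[i0] + w * q[i1]


def _dp_costs(q1: np.ndarray, q2: np.ndarray) -> dict:
    """Edge-cost matrices C[(di, dj)][i, j] for the DP grid.

    The edge ((i-di, j-dj) -> (i, j)) carries the discretized matching
    energy sum_a (1/n) |q1[i-di+a] - sqrt(s) q2(j-dj+a s)|^2, s = dj/di.
    """
    n = len(q1)
    sq1 = _sq(q1)
    costs = {}
    for di, dj in _DP_MOVES:
        s = dj / di
        C = np.zeros((n + 1, n + 1))
        j_end = np.arange(n + 1)
        for a in range(di):
            i_idx = (np.arange(n + 1) - di + a) % n      # rows (valid i >= di)
            pos = (j_end - dj + a * s)                    # cols
            q2f = _interp_q(q2, pos)                      # (n+1, 2)
            term = sq1[i_idx][:, None] + s * _sq(q2f)[None, :] \
                - 2 * np.sqrt(s) * (q1[i_idx] @ q2f.T)
            C += term / n
        costs[(di, dj)] = C
    return costs


def _dp_reparam(q1: np.ndarray, q2: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal monotone correspondence gamma: [0, n] -> [0, n].

    Dynamic program over the (n+1)^2 grid with moves restricted to local
    slopes in [1/3, 3]; both endpoints pinned (the seam is handled by the
    cyclic shift outside).  Returns gamma sampled at integers and the
    matching energy.
    """
    n = len(q1)
    costs = _dp_costs(q1, q2)
    E = np.full((n + 1, n + 1), np.inf)
    choice = np.zeros((n + 1, n + 1), dtype=np.int8)
    E[0, 0] = 0.0
    for i in range(1, n + 1):
        for m, (di, dj) in enumerate(_DP_MOVES):
            if di > i:
                continue
            cand = E[i - di, : n + 1 - dj] + costs[(di, dj)][i, dj:]
            better = cand < E[i, dj:]
            E[i, dj:][better] = cand[better]
            choice[i, dj:][better] = m
    # backtrack
    path_i, path_j = [n], [n]
    i, j = n, n
    while (i, j) != (0, 0):
        di, dj = _DP_MOVES[choice[i, j]]
        i, j = i - di, j - dj
        path_i.append(i)
        path_j.append(j)
    path_i.reverse()
    path_j.reverse()
    gamma = np.interp(np.arange(n + 1), path_i, path_j)
    return gamma, float(E[n, n])


def _apply_gamma(q: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Reparametrize SRV samples: q_new(k) = sqrt(gamma'(k)) q(gamma(k))."""
    dgamma = np.diff(gamma)
    return np.sqrt(np.maximum(dgamma, 0.0))[:, None] * _interp_q(q, gamma[:-1])


def _alternate(q1: np.ndarray, q2m: np.ndarray, max_alternations: int,
               tol: float) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Alternate DP reparametrization and closed-form rotation for one seam.

    Returns (energy, gamma, rotation, aligned q2).
    """
    n = len(q1)
    R = _optimal_rotation(q1, q2m)
    gamma = np.arange(n + 1, dtype=float)
    q2cur = q2m @ R.T
    e = _norm2(q1 - q2cur)
    for _ in range(max_alternations):
        g, _ = _dp_reparam(q1, q2cur)
        gamma_new = _compose_gamma(gamma, g)
        q2warp = _apply_gamma(q2m, gamma_new)
        R_new = _optimal_rotation(q1, q2warp)
        q2_new = q2warp @ R_new.T
        e_new = _norm2(q1 - q2_new)
        if e_new < e:
            gamma, R, q2cur, e = gamma_new, R_new, q2_new, e_new
        if e_new >= e - tol:
            break
    return e, gamma, R, q2cur


def align_q(q1: np.ndarray, q2: np.ndarray, reparam: bool = True,
            refine_seams: int = 3, max_alternations: int = 10,
            tol: float = 1e-10) -> tuple[float, Alignment, np.ndarray]:
    """Align q2 onto q1 over seam shift x rotation (x reparametrization).

    Every cyclic seam shift is evaluated: first with the closed-form
    rotation alone, then — because the rotation-only energy is a poor
    predictor of the post-reparametrization energy — with a single DP
    correspondence pass per seam.  The best ``refine_seams`` seams by
    single-pass energy are refined by alternating DP and re-rotation until
    the energy stops improving.  Returns (distance, Alignment, aligned q2).
    """
    n = len(q1)
    screen = _screen_seams(q1, q2)
    best_e, best_al, best_q = np.inf, None, None
    if not reparam:
        m = int(np.argmin(screen))
        q2m = np.roll(q2, -m, axis=0)
        R = _optimal_rotation(q1, q2m)
        best_e = float(screen[m])
        best_al = Alignment(shift=m, rotation=R,
                            gamma=np.arange(n + 1, dtype=float))
        best_q = q2m @ R.T
    else:
        single = np.empty(n)
        cache: dict[int, tuple] = {}
        for m in range(n):
            q2m = np.roll(q2, -m, axis=0)
            e, gamma, R, q2cur = _alternate(q1, q2m, 1, tol)
            single[m] = e
            cache[m] = (e, gamma, R, q2cur)
        for m in np.argsort(single)[: max(1, refine_seams)]:
            q2m = np.roll(q2, -int(m), axis=0)
            e, gamma, R, q2cur = _alternate(q1, q2m, max_alternations, tol)
            if e > cache[m][0]:
                e, gamma, R, q2cur = cache[m]
            if e < best_e:
                best_e, best_q = e, q2cur
                best_al = Alignment(shift=int(m), rotation=R, gamma=gamma)
    dist = float(np.sqrt(max(best_e, 0.0)))
    best_al.distance = dist
    return dist, best_al, best_q


def _compose_gamma(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """Compose two grid reparametrizations: (g1 o g2)(k) = g1(g2(k))."""
    n = len(g1) - 1
    return np.interp(g2, np.arange(n + 1), g1)


def apply_alignment(b: ShapeCurve, alignment: Alignment) -> ShapeCurve:
    """Carry curve b through its alignment (seam, reparam, rotation)."""
    q = np.roll(b.q, -alignment.shift, axis=0)
    q = _apply_gamma(q, alignment.gamma) @ alignment.rotation.T
    return ShapeCurve(srv_inverse(q), scale_invariant=b.scale_invariant)


def elastic_distance(a: ShapeCurve, b: ShapeCurve, reparam: bool = True,
                     refine_seams: int = 3) -> tuple[float, Alignment]:
    """Elastic (SRV) shape distance between two closed curves.

    Minimizes the SRV L2 distance over rotations, cyclic seam shifts and
    monotone reparametrizations of b; translation is already removed by
    centering, and scale too when both curves are scale-invariant.
    """
    if a.n != b.n:
        raise ValueError("curves must share the same number of points")
    if a.scale_invariant != b.scale_invariant:
        raise ValueError("curves must share the scale_invariant setting")
    dist, alignment, _ = align_q(a.q, b.q, reparam=reparam,
                                 refine_seams=refine_seams)
    return dist, alignment


def geodesic_path(a: ShapeCurve, b: ShapeCurve, alignment: Alignment,
                  k_steps: int = 5) -> list[ShapeCurve]:
    """SRV-space geodesic from a to the aligned b, sampled at k_steps.

    A straight line in SRV space realizes the geodesic of the flat elastic
    metric; endpoints reproduce a and the aligned b.
    """
    if k_steps < 2:
        raise ValueError("k_steps must be >= 2")
    qb = np.roll(b.q, -alignment.shift, axis=0)
    qb = _apply_gamma(qb, alignment.gamma) @ alignment.rotation.T
    out = []
    for t in np.linspace(0.0, 1.0, k_steps):
        if t == 0.0:
            out.append(ShapeCurve(a.points.copy(),
                                  scale_invariant=a.scale_invariant))
        else:
            q = (1 - t) * a.q + t * qb
            out.append(ShapeCurve(srv_inverse(q),
                                  scale_invariant=a.scale_invariant))
    return out


def karcher_mean(curves: list[ShapeCurve], tol: float = 1e-6,
                 max_iter: int = 50, reparam: bool = True,
                 ) -> tuple[ShapeCurve, list[Alignment]]:
    """Karcher (Fréchet) mean shape under the elastic metric.

    Iterates: align every curve to the current mean in SRV space, average
    the aligned SRV representations, map back to a closed curve, recenter.
    Stops when the relative change of the mean SRV falls below ``tol``.
    Initialized from the average of the curves aligned to the first one.
    """
    if not curves:
        raise ValueError("need >= 1 curve")
    if len(curves) == 1:
        c = curves[0]
        return ShapeCurve(c.points.copy(), scale_invariant=c.scale_invariant), \
            [Alignment(0, np.eye(2), np.arange(c.n + 1, dtype=float),
                       distance=0.0)]
    n = curves[0].n
    aligned = [curves[0].q]
    for c in curves[1:]:
        _, _, qal = align_q(curves[0].q, c.q, reparam=reparam)
        aligned.append(qal)
    mean_q = np.mean(aligned, axis=0)
    alignments: list[Alignment] = []
    for it in range(max_iter):
        aligned = []
        alignments = []
        for c in curves:
            _, al, qal = align_q(mean_q, c.q, reparam=reparam)
            aligned.append(qal)
            alignments.append(al)
        new_q = np.mean(aligned, axis=0)
        delta = np.linalg.norm(new_q - mean_q) / max(np.linalg.norm(mean_q),
                                                     1e-300)
        mean_q = new_q
        if delta < tol:
            break
    else:
        warnings.warn(f"Karcher mean did not converge in {max_iter} "
                      "iterations; returning last iterate")
    mean = ShapeCurve(srv_inverse(mean_q),
                      scale_invariant=curves[0].scale_invariant)
    return mean, alignments


def tangent_vectors(curves: list[ShapeCurve], mean: ShapeCurve,
                    reparam: bool = True) -> np.ndarray:
    """Linearize the sample about the mean: aligned SRV minus mean SRV,
    flattened to (n_samples, 2n)."""
    rows = []
    for c in curves:
        _, _, qal = align_q(mean.q, c.q, reparam=reparam)
        rows.append((qal - mean.q).ravel())
    return np.vstack(rows)


def tangent_pca(curves: list[ShapeCurve], mean: ShapeCurve,
                n_components: int | None = None,
                reparam: bool = True) -> PCAModel:
    """PCA of the tangent-space linearization about the Karcher mean."""
    if len(curves) < 2:
        raise ValueError("need >= 2 curves")
    T = tangent_vectors(curves, mean, reparam=reparam)
    return pca_fit(T, n_components)


def geodesic_pca_shoot(mean: ShapeCurve, model: PCAModel, component: int,
                       t_values=(-2.0, -1.0, 0.0, 1.0, 2.0)
                       ) -> list[ShapeCurve]:
    """Curves along a principal mode: mean SRV + t * sigma * component.

    t is in standard deviations of the scores along that component; t = 0
    reproduces the mean exactly.
    """
    comp = model.components[component].reshape(mean.q.shape)
    sigma = float(np.sqrt(model.explained_variance[component]))
    out = []
    for t in t_values:
        if t == 0.0:
            out.append(ShapeCurve(mean.points.copy(),
                                  scale_invariant=mean.scale_invariant))
        else:
            q = mean.q + t * sigma * comp
            out.append(ShapeCurve(srv_inverse(q),
                                  scale_invariant=mean.scale_invariant))
    return out
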