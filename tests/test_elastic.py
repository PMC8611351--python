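"""Elastic shape metric, Karcher mean, tangent PCA, geodesic shoots."""

import numpy as np
import pytest

import leafmorph as lm
from leafmorph.elastic import _DP_MOVES, srv_inverse, srv_transform

# ---------------------------------------------------------------------------
# exhaustive alignment oracle: every seam shift, plain-loop DP, SVD rotation


def _interp_periodic(q, x):
    n = len(q)
    x = x % n
    i0 = int(np.floor(x)) % n
    w = x - np.floor(x)
    return (1 - w) * q[i0] + w * q[(i0 + 1) % n]


def _oracle_rotation(q1, q2):
    u, _, vt = np.linalg.svd(q2.T @ q1)
    R = (u @ vt).T
    if np.linalg.det(R) < 0:
        u[:, -1] *= -1
        R = (u @ vt).T
    return R


def _oracle_dp(q1, q2):
    n = len(q1)
    E = np.full((n + 1, n + 1), np.inf)
    back = {}
    E[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, n + 1):
            for di, dj in _DP_MOVES:
                if di > i or dj > j:
                    continue
                s = dj / di
                c = 0.0
                for a in range(di):
                    diff = q1[(i - di + a) % n] \
                        - np.sqrt(s) * _interp_periodic(q2, j - dj + a * s)
                    c += (diff @ diff) / n
                cand = E[i - di, j - dj] + c
                if cand < E[i, j]:
                    E[i, j] = cand
                    back[(i, j)] = (di, dj)
    path = [(n, n)]
    while path[-1] != (0, 0):
        i, j = path[-1]
        di, dj = back[(i, j)]
        path.append((i - di, j - dj))
    path.reverse()
    pi, pj = zip(*path)
    gamma = np.interp(np.arange(n + 1), pi, pj)
    return gamma, float(E[n, n])


def _oracle_warp(q, gamma):
    n = len(q)
    out = np.empty_like(q)
    for k in range(n):
        dg = gamma[k + 1] - gamma[k]
        out[k] = np.sqrt(max(dg, 0.0)) * _interp_periodic(q, gamma[k])
    return out


def oracle_distance(a, b, max_alternations=10):
    """Minimum SRV distance over ALL seam shifts x DP reparametrization x
    closed-form rotation, alternated to convergence; no pruning."""
    q1, q2 = a.q, b.q
    n = len(q1)
    best = np.inf
    for m in range(n):
        q2m = np.roll(q2, -m, axis=0)
        R = _oracle_rotation(q1, q2m)
        gamma = np.arange(n + 1, dtype=float)
        e = float(np.sum((q1 - q2m @ R.T) ** 2) / n)
        for _ in range(max_alternations):
            g, _ = _oracle_dp(q1, _oracle_warp(q2m, gamma) @ R.T)
            gamma_new = np.interp(g, np.arange(n + 1), gamma)
            warped = _oracle_warp(q2m, gamma_new)
            R_new = _oracle_rotation(q1, warped)
            e_new = float(np.sum((q1 - warped @ R_new.T) ** 2) / n)
            if e_new < e - 1e-12:
                gamma, R, e = gamma_new, R_new, e_new
            else:
                break
        best = min(best, e)
    return float(np.sqrt(max(best, 0.0)))


def closed_curve(fn, n=100):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack(fn(t))


# ---------------------------------------------------------------------------


class TestShapeCurve:
    def test_circle_centered(self):
        c = lm.to_shape_curve(closed_curve(lambda t: (np.cos(t), np.sin(t))),
                              n=64)
        assert np.allclose(c.points.mean(0), 0, atol=1e-10)
        assert c.n == 64

    def test_scale_invariant_removes_size(self, two_lobed_leaf):
        pts = two_lobed_leaf.contour
        a = lm.to_shape_curve(pts, n=80, scale_invariant=True)
        b = lm.to_shape_curve(
            lm.PlanarContour(pts.points * 2.0, pts.base_index), n=80,
            scale_invariant=True)
        assert np.abs(a.points - b.points).max() < 1e-8
        assert a.length() == pytest.approx(1.0, rel=1e-6)

    def test_scale_preserved_when_flag_off(self, two_lobed_leaf):
        c = lm.to_shape_curve(two_lobed_leaf.contour, n=200)
        assert c.length() == pytest.approx(
            two_lobed_leaf.contour.perimeter(), rel=0.01)

    def test_srv_round_trip(self, two_lobed_leaf):
        c = lm.to_shape_curve(two_lobed_leaf.contour, n=80)
        back = srv_inverse(srv_transform(c.points))
        assert np.abs(back - c.points).max() < 1e-8

    def test_degenerate_contour_rejected(self):
        with pytest.raises(Exception):
            lm.to_shape_curve(np.zeros((40, 2)), n=50, scale_invariant=True)


class TestElasticDistance:
    def test_identity(self, shape_population):
        a = shape_population[0]
        d, _ = lm.elastic_distance(a, a)
        assert d < 1e-8

    def test_quotient_invariance(self, shape_population):
        a = shape_population[3]
        th = 1.2
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = lm.ShapeCurve(np.roll(a.points @ R.T + [4.0, -1.5], 17,
                                      axis=0))
        d, _ = lm.elastic_distance(a, moved)
        assert d < 1e-3 * a.diameter()

    def test_symmetry(self, shape_population):
        a, b = shape_population[1], shape_population[2]
        dab, _ = lm.elastic_distance(a, b)
        dba, _ = lm.elastic_distance(b, a)
        assert dab == pytest.approx(dba, rel=1e-3)

    def test_mismatched_n_rejected(self, two_lobed_leaf):
        a = lm.to_shape_curve(two_lobed_leaf.contour, n=60)
        b = lm.to_shape_curve(two_lobed_leaf.contour, n=80)
        with pytest.raises(ValueError):
            lm.elastic_distance(a, b)

    def test_circle_vs_ellipse_matches_oracle(self):
        a = lm.to_shape_curve(
            closed_curve(lambda t: (np.cos(t), np.sin(t)), 50), n=50)
        b = lm.to_shape_curve(
            closed_curve(lambda t: (2 * np.cos(t), np.sin(t)), 50), n=50)
        d, _ = lm.elastic_distance(a, b)
        assert d == pytest.approx(oracle_distance(a, b), abs=1e-6)

    def test_triangle_inequality_sampled(self, shape_population):
        curves = shape_population[:10]
        k = len(curves)
        D = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                D[i, j] = D[j, i] = lm.elastic_distance(curves[i],
                                                        curves[j])[0]
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    assert D[i, j] <= D[i, l] + D[l, j] \
                        + 1e-3 * max(D.max(), 1e-12)


class TestGeodesicPath:
    def test_two_steps_are_endpoints(self, shape_population):
        a, b = shape_population[0], shape_population[1]
        d, al = lm.elastic_distance(a, b)
        path = lm.geodesic_path(a, b, al, k_steps=2)
        assert np.abs(path[0].points - a.points).max() < 1e-9
        aligned_b = lm.apply_alignment(b, al)
        assert np.abs(path[1].points - aligned_b.points).max() < 1e-8
        # the aligned copy stays in b's shape orbit up to the
        # correspondence discretization
        dend, _ = lm.elastic_distance(path[1], b)
        assert dend < 0.02 * b.diameter()

    def test_constant_path_for_identical_endpoints(self, shape_population):
        a = shape_population[2]
        _, al = lm.elastic_distance(a, a)
        path = lm.geodesic_path(a, a, al, k_steps=5)
        for c in path:
            assert np.abs(c.points - a.points).max() < 1e-6 * a.diameter()

    def test_midpoint_eccentricity_between_endpoints(self):
        a = lm.to_shape_curve(
            closed_curve(lambda t: (np.cos(t), np.sin(t))), n=100)
        b = lm.to_shape_curve(
            closed_curve(lambda t: (2 * np.cos(t), np.sin(t))), n=100)
        _, al = lm.elastic_distance(a, b)
        mid = lm.geodesic_path(a, b, al, k_steps=3)[1]

        def axis_ratio(c):
            w = np.linalg.eigvalsh(np.cov(c.points.T))
            return np.sqrt(w[1] / w[0])

        assert axis_ratio(a) < axis_ratio(mid) < axis_ratio(b)

    def test_path_length_close_to_distance(self, shape_population):
        a, b = shape_population[4], shape_population[5]
        d, al = lm.elastic_distance(a, b)
        path = lm.geodesic_path(a, b, al, k_steps=9)
        seg = sum(np.sqrt(np.sum((path[i + 1].q - path[i].q) ** 2)
                          / path[i].n)
                  for i in range(8))
        assert seg == pytest.approx(d, rel=0.05)


class TestKarcherMean:
    def test_single_curve_is_identity(self, shape_population):
        a = shape_population[0]
        mean, als = lm.karcher_mean([a])
        assert np.abs(mean.points - a.points).max() < 1e-12
        assert als[0].distance == 0.0

    def test_two_curve_mean_is_midpoint(self):
        a = lm.to_shape_curve(
            closed_curve(lambda t: (np.cos(t), np.sin(t))), n=100)
        b = lm.to_shape_curve(
            closed_curve(lambda t: (2 * np.cos(t), np.sin(t))), n=100)
        mean, _ = lm.karcher_mean([a, b])
        da, _ = lm.elastic_distance(mean, a)
        db, _ = lm.elastic_distance(mean, b)
        assert da == pytest.approx(db, rel=1e-3)
        dab, _ = lm.elastic_distance(a, b)
        assert da + db == pytest.approx(dab, rel=0.02)

    def test_symmetric_perturbations_cancel(self, rng):
        leaf = lm.generate_leaf(
            lm.LeafParams(R=4.0, furrow_depth_frac=0.3, noise_sd=0.0), 300)
        template = lm.to_shape_curve(leaf.contour, n=60)
        curves = []
        for _ in range(10):
            delta = 0.05 * rng.standard_normal(template.points.shape)
            for sign in (+1, -1):
                curves.append(lm.ShapeCurve(template.points + sign * delta))
        mean, _ = lm.karcher_mean(curves, reparam=False)
        d_mean, _ = lm.elastic_distance(mean, template)
        worst = max(lm.elastic_distance(c, template)[0] for c in curves)
        assert d_mean < worst / 10


class TestTangentPCA:
    def test_scale_only_population_one_mode(self, rng):
        leaf = lm.generate_leaf(
            lm.LeafParams(R=4.0, furrow_depth_frac=0.3, noise_sd=0.0), 300)
        base = leaf.contour
        curves = [lm.to_shape_curve(
            lm.PlanarContour(base.points * s, base.base_index), n=60)
            for s in rng.uniform(0.5, 2.0, 12)]
        mean, _ = lm.karcher_mean(curves)
        model = lm.tangent_pca(curves, mean)
        assert model.explained_variance_ratio[0] > 0.95

    def test_ratios_sum_to_one(self, shape_population):
        curves = shape_population[:8]
        mean, _ = lm.karcher_mean(curves, max_iter=10)
        model = lm.tangent_pca(curves, mean)
        assert model.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_identical_curves_rejected(self, shape_population):
        a = shape_population[0]
        clones = [lm.ShapeCurve(a.points.copy()) for _ in range(5)]
        with pytest.raises(lm.ZeroVarianceError):
            lm.tangent_pca(clones, clones[0])


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(5)
    leaf = lm.generate_leaf(
        lm.LeafParams(R=4.0, furrow_depth_frac=0.3, noise_sd=0.0), 300)
    base = leaf.contour
    curves = [lm.to_shape_curve(
        lm.PlanarContour(base.points * s, base.base_index), n=60)
        for s in rng.uniform(0.5, 2.0, 12)]
    mean, _ = lm.karcher_mean(curves)
    return mean, lm.tangent_pca(curves, mean)


class TestGeodesicShoot:
    def test_t_zero_reproduces_mean(self, fitted):
        mean, model = fitted
        shot = lm.geodesic_pca_shoot(mean, model, 0, t_values=(0.0,))[0]
        assert np.abs(shot.points - mean.points).max() < 1e-12

    def test_plus_minus_t_distinct(self, fitted):
        mean, model = fitted
        lo, hi = lm.geodesic_pca_shoot(mean, model, 0, t_values=(-1.0, 1.0))
        assert np.abs(lo.points - hi.points).max() > 1e-6

    def test_scale_mode_shoot_changes_mostly_size(self, fitted):
        mean, model = fitted
        shots = lm.geodesic_pca_shoot(mean, model, 0,
                                      t_values=(-1.5, 0.0, 1.5))
        lengths = [s.length() for s in shots]
        assert lengths[0] != pytest.approx(lengths[2], rel=0.05)
        # shape stays similar: scale-normalized curves nearly coincide
        a = lm.ShapeCurve(shots[0].points / lengths[0])
        b = lm.ShapeCurve(shots[2].points / lengths[2])
        d, _ = lm.elastic_distance(a, b)
        assert d < 0.1 * np.sqrt(a.length())
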