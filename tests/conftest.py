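"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import leafmorph as lm


# ---------------------------------------------------------------------------
# independent barcode oracle: explicit threshold sweep with merge tracking


def cyclic_segments(mask: np.ndarray) -> list[list[int]]:
    """Contiguous runs of True in a cyclic boolean array."""
    n = len(mask)
    if mask.all():
        return [list(range(n))]
    if not mask.any():
        return []
    segs, cur = [], []
    # start scanning just after a False so no run is split by the seam
    start = int(np.flatnonzero(~mask)[0]) + 1
    for k in range(n):
        v = (start + k) % n
        if mask[v]:
            cur.append(v)
        elif cur:
            segs.append(cur)
            cur = []
    if cur:
        segs.append(cur)
    return segs


def sweep_barcode(d) -> np.ndarray:
    """Brute-force superlevel barcode: at every distinct value of d
    (descending) recount contiguous cyclic segments and track merges by
    overlap with the previous level's segments; on a merge the younger
    component (smaller birth) dies.  Returns bars sorted for comparison."""
    d = np.asarray(d, dtype=float)
    n = len(d)
    labels = -np.ones(n, dtype=int)
    birth: dict[int, float] = {}
    bars: list[tuple[float, float]] = []
    nxt = 0
    for r in np.unique(d)[::-1]:
        mask = d >= r
        new_labels = -np.ones(n, dtype=int)
        for seg in cyclic_segments(mask):
            old = sorted({labels[v] for v in seg if labels[v] >= 0},
                         key=lambda lab: -birth[lab])
            if not old:
                lab = nxt
                nxt += 1
                birth[lab] = r
            else:
                lab = old[0]
                for other in old[1:]:
                    if birth[other] > r:  # zero-length bars are diagonal
                        bars.append((birth[other], r))
            for v in seg:
                new_labels[v] = lab
        labels = new_labels
    survivor = labels[labels >= 0][0]
    bars.append((birth[survivor], 0.0))
    return np.array(sorted(bars))


def bar_multiset(code: lm.Barcode) -> np.ndarray:
    return np.array(sorted(map(tuple, code.bars)))


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def two_lobed_leaf() -> lm.SyntheticLeaf:
    return lm.generate_leaf(
        lm.LeafParams(R=5.0, furrow_depth_frac=0.4, cren_amp=0.0,
                      n_lobes=2, noise_sd=0.0), n_points=400)


@pytest.fixture(scope="session")
def small_population():
    leaves, traits = lm.generate_population(20, seed=11, n_points=200)
    return leaves, traits


@pytest.fixture(scope="session")
def shape_population(small_population):
    leaves, _ = small_population
    return [lm.to_shape_curve(leaf.contour, n=60) for leaf in leaves]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20210978)
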