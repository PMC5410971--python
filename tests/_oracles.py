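"""Independent oracles used by the test suite.

These deliberately re-derive results by different routes than the package:
winding-number containment (vs the even-odd implementation), brute-force
state enumeration (vs pruning), and closed-form cell indexing (vs the
polygon pipeline).
"""

from __future__ import annotations

import itertools

import numpy as np


def winding_number_inside(px, py, xs, ys) -> np.ndarray:
    """Winding-number containment test, vectorised over points.

    xs/ys: open ring (last vertex not repeated). Nonzero winding = inside.
    """
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    wn = np.zeros(px.shape, dtype=np.int64)
    n = len(xs)
    for i in range(n):
        x1, y1 = xs[i], ys[i]
        x2, y2 = xs[(i + 1) % n], ys[(i + 1) % n]
        cross = (x2 - x1) * (py - y1) - (px - x1) * (y2 - y1)
        up = (y1 <= py) & (y2 > py) & (cross > 0)
        down = (y1 > py) & (y2 <= py) & (cross < 0)
        wn += up.astype(np.int64) - down.astype(np.int64)
    return wn != 0


def random_star_polygon(n_vertices: int, rng, center=(0.0, 0.0), rmax=50.0):
    """A random simple (star-shaped) polygon: sorted angles, random radii."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    # enforce distinct angles so edges are non-degenerate
    while np.any(np.diff(angles) < 1e-6):
        angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = rng.uniform(0.1 * rmax, rmax, n_vertices)
    xs = center[0] + radii * np.cos(angles)
    ys = center[1] + radii * np.sin(angles)
    return xs, ys


def min_edge_distance(px, py, xs, ys) -> np.ndarray:
    """Distance from each point to the nearest polygon edge."""
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    best = np.full(px.shape, np.inf)
    n = len(xs)
    for i in range(n):
        x1, y1 = xs[i], ys[i]
        x2, y2 = xs[(i + 1) % n], ys[(i + 1) % n]
        dx, dy = x2 - x1, y2 - y1
        seg2 = dx * dx + dy * dy
        t = np.clip(((px - x1) * dx + (py - y1) * dy) / max(seg2, 1e-300), 0, 1)
        d2 = (px - (x1 + t * dx)) ** 2 + (py - (y1 + t * dy)) ** 2
        best = np.minimum(best, np.sqrt(d2))
    return best


def enumerate_mk_loglik(tree, tip_states, states, Q) -> float:
    """Brute-force Mk log-likelihood: sum over all internal-node state
    assignments, uniform root prior."""
    from scipy.linalg import expm

    k = len(states)
    sidx = {s: i for i, s in enumerate(states)}
    nodes = tree.postorder()
    internals = [n for n in nodes if not n.is_tip]
    P = {
        n: expm(np.asarray(Q) * n.length) for n in nodes if n.parent is not None
    }
    total = 0.0
    for assignment in itertools.product(range(k), repeat=len(internals)):
        amap = dict(zip([id(n) for n in internals], assignment))
        for n in nodes:
            if n.is_tip:
                amap[id(n)] = sidx[tip_states[n.name]]
        lik = 1.0 / k
        for n in nodes:
            if n.parent is None:
                continue
            lik *= P[n][amap[id(n.parent)], amap[id(n)]]
        total += lik
    return float(np.log(total))


def enumerate_node_posterior(tree, tip_states, states, Q, node) -> np.ndarray:
    """Exact conditional posterior of one internal node's state."""
    from scipy.linalg import expm

    k = len(states)
    sidx = {s: i for i, s in enumerate(states)}
    nodes = tree.postorder()
    internals = [n for n in nodes if not n.is_tip]
    P = {n: expm(np.asarray(Q) * n.length) for n in nodes if n.parent is not None}
    post = np.zeros(k)
    for assignment in itertools.product(range(k), repeat=len(internals)):
        amap = dict(zip([id(n) for n in internals], assignment))
        for n in nodes:
            if n.is_tip:
                amap[id(n)] = sidx[tip_states[n.name]]
        lik = 1.0 / k
        for n in nodes:
            if n.parent is None:
                continue
            lik *= P[n][amap[id(n.parent)], amap[id(n)]]
        post[amap[id(node)]] += lik
    return post / post.sum()
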