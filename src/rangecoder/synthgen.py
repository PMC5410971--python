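"""Seeded synthetic-data generators.

These reproduce the benchmark-style inputs the rest of the package is
exercised against: globally uniform occurrence sets, grids of square
polygons sharing corners with their neighbours, squares densified to an
arbitrary vertex count, linear elevation ramps, birth-death trees, and
forward-simulated Mk character histories with full event logs.

Every generator is a pure function of its arguments and seed: identical
inputs give identical outputs. Localities are sampled uniformly in
longitude/latitude degrees (not equal-area) -- the purpose is exercising the
point-in-polygon machinery, not geographic realism.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .formats import ElevationGrid, OccurrenceRecord, OperationalUnit
from .geometry import GeoPoint, PolygonDef
from .phylo import CharacterHistory, MkModel, _PathSampler
from .tree import Node, Tree

WORLD = (-180.0, 180.0, -90.0, 90.0)


def gen_global_localities(
    n: int, seed: int, n_species: int = 100, extent=WORLD
) -> pd.DataFrame:
    """Uniformly distributed localities with species labels cycling over
    ``n_species`` names; columns species/latitude/longitude."""
    lo0, lo1, la0, la1 = extent
    rng = np.random.default_rng(seed)
    lons = rng.uniform(lo0, lo1, size=n)
    lats = rng.uniform(la0, la1, size=n)
    width = max(4, len(str(max(n_species, 1))))
    species = [f"sp_{(i % n_species) + 1:0{width}d}" for i in range(n)]
    return pd.DataFrame(
        {"species": species, "latitude": lats, "longitude": lons}
    )


def localities_to_records(table: pd.DataFrame) -> list[OccurrenceRecord]:
    """In-memory counterpart of writing the table and re-reading it."""
    return [
        OccurrenceRecord(
            str(row.species), GeoPoint(float(row.longitude), float(row.latitude)), i + 2
        )
        for i, row in enumerate(table.itertuples(index=False))
    ]


def write_localities(table: pd.DataFrame, path) -> None:
    table.to_csv(
        path, sep="\t", index=False,
        columns=["species", "latitude", "longitude"],
    )


def gen_polygon_grid(rows: int, cols: int, extent=WORLD) -> list[OperationalUnit]:
    """rows x cols axis-aligned squares tiling the extent.

    Adjacent cells share exactly two corners; names are ``cell_<r>_<c>``
    with row 0 at the south edge.
    """
    lo0, lo1, la0, la1 = extent
    dx = (lo1 - lo0) / cols
    dy = (la1 - la0) / rows
    units = []
    for r in range(rows):
        for c in range(cols):
            x0, x1 = lo0 + c * dx, lo0 + (c + 1) * dx
            y0, y1 = la0 + r * dy, la0 + (r + 1) * dy
            ring = [(x0, y0), (x1, y0), (x1, y1), (x0, y1)]
            name = f"cell_{r}_{c}"
            units.append(OperationalUnit(name, PolygonDef(name, ring)))
    return units


def grid_cell_index(lon: float, lat: float, rows: int, cols: int, extent=WORLD):
    """Closed-form cell index of a point in the polygon grid (oracle).

    Returns (r, c) or None outside the extent. Boundary coordinates floor to
    the higher-index cell, matching the interior assignment of points that
    are not on shared edges; points exactly on shared edges belong to both
    adjacent polygons under the boundary-inside rule and are excluded from
    exact-match comparisons.
    """
    lo0, lo1, la0, la1 = extent
    if not (lo0 <= lon < lo1 and la0 <= lat < la1):
        return None
    c = int(np.floor((lon - lo0) / (lo1 - lo0) * cols))
    r = int(np.floor((lat - la0) / (la1 - la0) * rows))
    return (min(r, rows - 1), min(c, cols - 1))


def gen_complex_polygon(n_nodes: int, extent=(0.0, 10.0, 0.0, 10.0), name="square") -> PolygonDef:
    """A square densified to ``n_nodes`` vertices equally spaced along its
    perimeter (starting at the SW corner); the enclosed region is unchanged."""
    if n_nodes < 3:
        raise ValueError("n_nodes must be >= 3")
    lo0, lo1, la0, la1 = extent
    w, h = lo1 - lo0, la1 - la0
    per = 2 * (w + h)
    ring = []
    for i in range(n_nodes):
        s = per * i / n_nodes
        if s < w:
            ring.append((lo0 + s, la0))
        elif s < w + h:
            ring.append((lo1, la0 + (s - w)))
        elif s < 2 * w + h:
            ring.append((lo1 - (s - w - h), la1))
        else:
            ring.append((lo0, la1 - (s - 2 * w - h)))
    return PolygonDef(name, ring)


def gen_elevation_ramp(
    ncols: int, nrows: int, extent, min_m: float, max_m: float, nodata=-9999.0
) -> ElevationGrid:
    """Linear west-to-east elevation ramp: the westernmost column of cells
    holds ``min_m``, the easternmost ``max_m``."""
    lo0, lo1, la0, la1 = extent
    if ncols < 1 or nrows < 1:
        raise ValueError("grid must have at least one cell")
    col_values = (
        np.full(ncols, min_m)
        if ncols == 1
        else min_m + (max_m - min_m) * np.arange(ncols) / (ncols - 1)
    )
    values = np.tile(col_values, (nrows, 1))
    return ElevationGrid(
        ncols, nrows, lo0, la0, (lo1 - lo0) / ncols, nodata, values
    )


def gen_birthdeath_tree(
    n_tips: int, birth_rate: float, death_rate: float, seed: int
) -> Tree:
    """Ultrametric tree from a constant-rate birth-death process, stopped at
    the moment the ``n_tips``-th extant lineage appears (simple-sampling
    conditioning; runs that go extinct first are restarted)."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed)
    for _ in range(10_000):
        tree = _bd_attempt(n_tips, birth_rate, death_rate, rng)
        if tree is not None:
            return tree
    raise RuntimeError("birth-death simulation failed to reach n_tips")


def _bd_attempt(n_tips, birth, death, rng) -> Tree | None:
    root = Node()
    # alive lineages: (node, birth_time of its pending branch start)
    alive: list[tuple[Node, float]] = [(root, 0.0)]
    t = 0.0
    while len(alive) < n_tips:
        n = len(alive)
        total = n * (birth + death)
        t += rng.exponential(1.0 / total)
        i = int(rng.integers(n))
        node, t0 = alive.pop(i)
        node.length = t - t0
        if rng.random() < birth / (birth + death):
            left, right = Node(), Node()
            left.parent = right.parent = node
            node.children = [left, right]
            alive.append((left, t))
            alive.append((right, t))
        elif not alive:
            return None  # total extinction
    # stop the clock uniformly within the interval during which exactly
    # n_tips lineages are alive (avoids zero-length cherries at the stop)
    n = len(alive)
    t_end = t + rng.exponential(1.0 / (n * (birth + death))) * rng.random()
    for node, t0 in alive:
        node.length = t_end - t0
    # depths below the root exclude the root's own stem branch
    _prune_extinct(root, t_end - (root.length or 0.0))
    tips = [n for n in _iter_tips(root)]
    if len(tips) != n_tips:
        return None
    for i, tip in enumerate(tips):
        tip.name = f"t{i + 1}"
    # drop the root's stem and suppress unary nodes introduced by pruning
    root = _suppress_unary(root)
    root.length = None
    root.parent = None
    for node in _preorder(root):
        for c in node.children:
            c.parent = node
    if root.is_tip or len(_iter_tips(root)) != n_tips:
        return None
    return Tree(root)


def _iter_tips(node: Node) -> list[Node]:
    return [n for n in _preorder(node) if not n.children]


def _preorder(node: Node) -> list[Node]:
    out, stack = [], [node]
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(reversed(n.children))
    return out


def _prune_extinct(root: Node, t_end: float) -> None:
    """Remove lineages that died before t_end (their subtree has no extant tip)."""

    def extant_depth(node: Node, depth: float) -> bool:
        if not node.children:
            keep = abs(depth - t_end) < 1e-9 * max(t_end, 1.0)
            node._keep = keep  # type: ignore[attr-defined]
            return keep
        keep = False
        for c in node.children:
            keep |= extant_depth(c, depth + c.length)
        node.children = [c for c in node.children if getattr(c, "_keep", False)]
        node._keep = keep and bool(node.children)  # type: ignore[attr-defined]
        return node._keep

    extant_depth(root, 0.0)


def _suppress_unary(root: Node) -> Node:
    """Collapse single-child nodes (merging branch lengths); returns new root."""
    while len(root.children) == 1:
        root = root.children[0]
        root.parent = None

    def visit(node: Node) -> None:
        new_children = []
        for c in node.children:
            while len(c.children) == 1:  # collapse a unary chain downwards
                g = c.children[0]
                g.length = (g.length or 0.0) + (c.length or 0.0)
                c = g
            c.parent = node
            new_children.append(c)
            visit(c)
        node.children = new_children

    visit(root)
    return root


def simulate_mk_forward(
    tree: Tree, model: MkModel, root_state: str, seed: int
) -> tuple[dict[str, str], CharacterHistory]:
    """Exact forward CTMC simulation along every branch, retaining the full
    event log (transition ages) -- the oracle for mapping and dispersal tests."""
    rng = np.random.default_rng(seed)
    sidx = {s: i for i, s in enumerate(model.states)}
    if root_state not in sidx:
        raise ValueError(f"unknown root state {root_state!r}")
    node_states: dict[Node, str] = {tree.root: root_state}
    branch_events: dict[Node, list[tuple[float, str, str]]] = {}
    sampler = _PathSampler(np.asarray(model.Q, dtype=float))
    for node in tree.preorder():
        if node is tree.root:
            continue
        a = sidx[node_states[node.parent]]
        events, end = sampler.forward(a, node.length, rng)
        start_age = node.age + node.length
        branch_events[node] = [
            (start_age - s, model.states[f], model.states[to])
            for s, f, to in events
        ]
        node_states[node] = model.states[end]
    tip_states = {n.name: node_states[n] for n in tree.tips()}
    history = CharacterHistory(tree, model.states, node_states, branch_events)
    return tip_states, history
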