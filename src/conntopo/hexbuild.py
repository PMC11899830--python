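"""Benzenoid skeleton construction on the hexagonal lattice.

A benzenoid hydrocarbon's hydrogen-suppressed graph is determined by which
hexagonal cells of the infinite hex lattice it occupies: shared corners of
adjacent cells are merged.  Cells are addressed in axial coordinates (q, r)
with neighbor offsets (+-1, 0), (0, +-1), (+1, -1), (-1, +1).
"""

from __future__ import annotations

import math
from typing import Iterable, List, Sequence, Tuple

from .graph import MolecularGraph

__all__ = ["benzenoid_from_cells", "build_acene"]

_SQRT3 = math.sqrt(3.0)


def _corners(q: int, r: int) -> List[Tuple[float, float]]:
    # pointy-top unit hexagon centred on the axial cell (q, r)
    cx = (q + r / 2.0) * _SQRT3
    cy = r * 1.5
    pts = []
    for k in range(6):
        ang = math.radians(60 * k + 30)
        # corners of adjacent cells coincide exactly up to float rounding;
        # 3 decimals is far below the lattice spacing, far above the error
        pts.append((round(cx + math.cos(ang), 3), round(cy + math.sin(ang), 3)))
    return pts


def benzenoid_from_cells(cells: Sequence[Tuple[int, int]], name: str = "") -> MolecularGraph:
    """Build the skeleton graph of the benzenoid occupying ``cells``.

    Vertices are labelled 1..n in corner-discovery order (cells in the given
    order, corners counterclockwise from the 30-degree corner), so a fixed
    cell layout always produces the identical labelled graph.
    """
    if not cells:
        raise ValueError("at least one hexagonal cell is required")
    vid = {}
    edges = []
    seen = set()
    for (q, r) in cells:
        ids = []
        for c in _corners(q, r):
            if c not in vid:
                vid[c] = str(len(vid) + 1)
            ids.append(vid[c])
        for i in range(6):
            a, b = ids[i], ids[(i + 1) % 6]
            key = (a, b) if a <= b else (b, a)
            if key not in seen:
                seen.add(key)
                edges.append((a, b))
    return MolecularGraph.from_edges(edges, name=name,
                                     vertices=[vid[c] for c in vid])


def build_acene(n: int) -> MolecularGraph:
    """Linear chain of ``n`` fused hexagons (benzene, naphthalene, ...).

    Constructed explicitly as two horizontal paths of 2n+1 vertices joined by
    n+1 vertical rungs at the even positions: 4n+2 vertices, 5n+1 edges.
    """
    if n < 1:
        raise ValueError(f"acene needs at least one hexagon, got n={n}")
    top = [f"t{i}" for i in range(2 * n + 1)]
    bot = [f"b{i}" for i in range(2 * n + 1)]
    edges = [(top[i], top[i + 1]) for i in range(2 * n)]
    edges += [(bot[i], bot[i + 1]) for i in range(2 * n)]
    edges += [(top[2 * i], bot[2 * i]) for i in range(n + 1)]
    return MolecularGraph.from_edges(edges, name=f"acene-{n}", vertices=top + bot)
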