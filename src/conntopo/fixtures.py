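"""Packaged test molecules and property tables.

Two fixture sets ship with the package:

* ``bh22`` — the 22 lower benzenoid hydrocarbons (benzene through coronene)
  with experimental normal boiling points (deg C), standard heats of
  formation, and the published reference columns of the four Zagreb-type
  connection indices.  The skeleton edge lists were generated from hexagonal
  ring layouts (see :mod:`conntopo.hexbuild`) and frozen as text files.
  The published anthanthrene reference row is known to duplicate
  anthracene's values; the set therefore also carries an "as-published"
  anthanthrene variant (anthracene's graph under anthanthrene's name) so
  analyses can be reproduced either against the correct C22H12 skeleton or
  against the data the original study actually used.

* ``coumarin25`` — 11 physicochemical properties for 25 coumarin-related
  anti-cancer drugs (boiling point, molar volume, enthalpy of vaporization,
  density, surface tension, vapor pressure, molar refractivity, index of
  refraction, flash point, polarizability, polar surface area).  Structures
  are user-supplied: the source drawings are not machine-readable.

A seeded random connected graph generator for property-based testing lives
here as well.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .graph import MolecularGraph, parse_edge_list
from .hexbuild import benzenoid_from_cells, build_acene  # noqa: F401 (re-export)

__all__ = [
    "BH_CELLS",
    "BH22_NAMES",
    "FixtureSet",
    "load_bh22",
    "load_coumarin_properties",
    "random_connected_graph",
    "build_acene",
    "compound_slug",
]

#: Hexagonal-cell layouts (axial coordinates) of the 22 benzenoid skeletons.
#: The packaged edge lists are frozen renderings of exactly these layouts.
BH_CELLS: Dict[str, Tuple[Tuple[int, int], ...]] = {
    "Benzene": ((0, 0),),
    "Naphthalene": ((0, 0), (1, 0)),
    "Phenanthrene": ((0, 0), (1, 0), (1, 1)),
    "Anthracene": ((0, 0), (1, 0), (2, 0)),
    "Chrysene": ((0, 0), (1, 0), (1, 1), (2, 1)),
    "Benzo[a]anthracene": ((0, 0), (1, 0), (2, 0), (2, 1)),
    "Triphenylene": ((0, 0), (1, 0), (-1, 1), (0, -1)),
    "Tetracene": ((0, 0), (1, 0), (2, 0), (3, 0)),
    "Benzo[a]pyrene": ((0, 0), (1, 0), (0, 1), (1, 1), (2, -1)),
    "Benzo[e]pyrene": ((0, 0), (1, 0), (0, 1), (1, 1), (2, 1)),
    "Perylene": ((0, 0), (0, 1), (1, 0), (2, -1), (2, 0)),
    "Anthanthrene": ((0, 0), (1, 0), (0, 1), (1, 1), (2, 0), (-1, 1)),
    "Benzo[ghi]perylene": ((0, 0), (0, 1), (1, 0), (2, -1), (2, 0), (1, -1)),
    "Dibenzo[a,c]anthracene": ((0, 0), (1, 0), (2, 0), (2, 1), (3, -1)),
    "Dibenzo[a,h]anthracene": ((0, 0), (1, 0), (2, 0), (-1, 1), (3, -1)),
    "Dibenzo[a,j]anthracene": ((0, 0), (1, 0), (2, 0), (0, -1), (3, -1)),
    "Picene": ((0, 0), (1, 0), (1, 1), (2, 1), (2, 2)),
    "Coronene": ((0, 0), (1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1)),
    "Dibenzo(a,h)pyrene": ((0, 0), (1, 0), (0, 1), (1, 1), (0, -1), (1, 2)),
    "Dibenzo(a,i)pyrene": ((0, 0), (1, 0), (0, 1), (1, 1), (0, -1), (2, 1)),
    "Dibenzo(a,l)pyrene": ((0, 0), (1, 0), (0, 1), (1, 1), (2, -1), (2, 1)),
    "Pyrene": ((0, 0), (1, 0), (0, 1), (1, 1)),
}

BH22_NAMES: Tuple[str, ...] = tuple(BH_CELLS)


def compound_slug(name: str) -> str:
    """Filesystem-safe compound name: 'Benzo[a]pyrene' -> 'benzo_a_pyrene'."""
    return re.sub(r"_+", "_", re.sub(r"[^a-z0-9]", "_", name.lower())).strip("_")


@dataclass
class FixtureSet:
    """A named collection of molecular graphs with an aligned property table.

    ``printed`` carries published reference descriptor columns verbatim (as
    strings, preserving the printed precision) where the set has them.
    """

    name: str
    graphs: Dict[str, MolecularGraph]
    properties: pd.DataFrame
    printed: Optional[pd.DataFrame] = field(default=None)


def _data_root():
    return resources.files("conntopo") / "data"


def _read_graph(relpath: str, name: str) -> MolecularGraph:
    text = (_data_root() / relpath).read_text()
    return parse_edge_list(text, name=name)


def load_bh22(anthanthrene: str = "correct") -> FixtureSet:
    """The 22 lower benzenoid hydrocarbons with their property table.

    ``anthanthrene="correct"`` (default) loads the true C22H12 skeleton;
    ``anthanthrene="as-published"`` substitutes anthracene's graph under the
    anthanthrene name, replicating the reference dataset of the original
    benzenoid screening study (whose anthanthrene descriptor row duplicates
    anthracene's — see the package methods note).
    """
    if anthanthrene not in ("correct", "as-published"):
        raise ValueError("anthanthrene must be 'correct' or 'as-published'")
    graphs = {}
    for name in BH22_NAMES:
        slug = compound_slug(name)
        if name == "Anthanthrene" and anthanthrene == "as-published":
            slug = "anthanthrene_as_published"
        graphs[name] = _read_graph(f"bh22/{slug}.edges", name)
    table = pd.read_csv(_data_root() / "bh22_properties.csv", dtype=str)
    table = table.set_index("compound")
    props = table[["bp", "hf"]].astype(float)
    printed = table[["Mc1", "Mc2", "Pc1", "Pc2"]]
    if list(props.index) != list(BH22_NAMES):
        raise RuntimeError("bh22 property table out of sync with graph registry")
    return FixtureSet(name=f"bh22[{anthanthrene}]", graphs=graphs,
                      properties=props, printed=printed)


def load_coumarin_properties(structure_dir=None) -> FixtureSet:
    """The 25-compound coumarin property table (11 properties per compound).

    If ``structure_dir`` is given, every ``<compound_slug>.edges`` file found
    there is parsed and attached; a file that fails validation raises an
    error naming the compound.
    """
    table = pd.read_csv(_data_root() / "coumarin25_properties.csv")
    table = table.set_index("compound")
    graphs: Dict[str, MolecularGraph] = {}
    if structure_dir is not None:
        from pathlib import Path

        for name in table.index:
            path = Path(structure_dir) / f"{compound_slug(name)}.edges"
            if path.exists():
                try:
                    graphs[name] = parse_edge_list(path.read_text(), name=name)
                except Exception as exc:
                    raise type(exc)(f"{name}: {exc}") from exc
    return FixtureSet(name="coumarin25", graphs=graphs, properties=table)


def random_connected_graph(n: int, m: int, seed: int) -> MolecularGraph:
    """A reproducible connected simple graph: uniform random recursive tree
    plus ``m - (n-1)`` extra edges drawn without replacement.

    Intended for property-based testing (oracle sweeps over small graphs),
    not as a model of chemical structure.
    """
    if n < 1:
        raise ValueError("need at least one vertex")
    max_m = n * (n - 1) // 2
    if not (n - 1 <= m <= max_m):
        raise ValueError(f"infeasible edge count m={m} for n={n} "
                         f"(need {n - 1} <= m <= {max_m})")
    rng = np.random.default_rng(seed)
    labels = [str(i + 1) for i in range(n)]
    edges: List[Tuple[str, str]] = []
    for i in range(1, n):
        j = int(rng.integers(0, i))
        edges.append((labels[j], labels[i]))
    tree = {tuple(sorted(e)) for e in edges}
    extra_pool = [(labels[i], labels[j]) for i in range(n) for j in range(i + 1, n)
                  if (labels[i], labels[j]) not in tree and (labels[j], labels[i]) not in tree]
    k = m - (n - 1)
    if k:
        picks = rng.choice(len(extra_pool), size=k, replace=False)
        edges.extend(extra_pool[int(i)] for i in picks)
    return MolecularGraph.from_edges(edges, name=f"random-{n}-{m}-{seed}",
                                     vertices=labels)
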