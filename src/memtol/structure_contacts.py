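"""Residue contact graphs and packing statistics from 3-D structures.

Two residues are in contact when any pair of their atoms lies strictly
closer than a cutoff (default 5 A). The resulting simple graph supports
the packing analyses: its *size* (node count) versus *order* (edge count)
relation, whose least-squares slope measures contacts per residue, and
the profile of maximal cliques of sizes 3-5, which characterizes the
densest locally packed regions.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import gemmi
import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import linregress


class StructureError(ValueError):
    """Base class for structure/contact errors."""


@dataclass
class Residue:
    """One residue: 1-based sequence index, one-letter type, labelled atoms."""

    index: int
    name: str
    atoms: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError(f"residue {self.index} has no atoms")
        for label, xyz in self.atoms.items():
            arr = np.asarray(xyz, dtype=float)
            if arr.shape != (3,) or not np.all(np.isfinite(arr)):
                raise StructureError(f"bad coordinates for atom {label}")
            self.atoms[label] = arr


@dataclass
class StructureChain:
    """An ordered protein chain with 3-D coordinates in Angstrom."""

    id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        if not self.residues:
            raise StructureError(f"chain {self.id} is empty")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.name for r in self.residues)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureChain":
        """Rigid-body transformed copy of the chain."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        residues = [
            Residue(
                index=r.index,
                name=r.name,
                atoms={k: R @ v + t for k, v in r.atoms.items()},
            )
            for r in self.residues
        ]
        return StructureChain(id=self.id, residues=residues)


def load_chain(
    path: str | Path,
    chain_id: str | None = None,
    *,
    heavy_only: bool = True,
    model_index: int = 0,
) -> StructureChain:
    """Load one protein chain from a PDB or mmCIF file via gemmi.

    Waters and non-amino-acid residues are dropped; alternate locations
    keep the first conformer; hydrogens are excluded unless
    ``heavy_only=False``. Residues are re-indexed 1..n in file order.
    """
    st = gemmi.read_structure(str(path))
    st.remove_alternative_conformations()
    st.remove_waters()
    if model_index >= len(st):
        raise StructureError(f"model {model_index} not in {path}")
    model = st[model_index]
    chain = None
    for c in model:
        if chain_id is None or c.name == chain_id:
            chain = c
            break
    if chain is None:
        raise StructureError(f"chain {chain_id!r} not found in {path}")
    residues: list[Residue] = []
    for res in chain:
        info = gemmi.find_tabulated_residue(res.name)
        if info is None or not info.is_amino_acid():
            continue
        atoms: dict[str, np.ndarray] = {}
        for atom in res:
            if heavy_only and atom.element in (gemmi.Element("H"), gemmi.Element("D")):
                continue
            atoms.setdefault(atom.name, np.array([atom.pos.x, atom.pos.y, atom.pos.z]))
        if not atoms:
            continue
        one = info.one_letter_code.upper()
        residues.append(Residue(index=len(residues) + 1, name=one if one.isalpha() else "X", atoms=atoms))
    return StructureChain(id=f"{Path(path).stem}_{chain.name}", residues=residues)


@dataclass
class ContactGraph:
    """Residue contact graph: nodes are 1-based residue indices.

    Node attribute ``aa`` holds the residue type; edge attribute
    ``min_dist`` the minimum inter-atomic distance.
    """

    graph: nx.Graph
    cutoff_A: float

    @property
    def size(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def order(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, node: int) -> list[int]:
        return sorted(self.graph.neighbors(node))

    def amino_acid(self, node: int) -> str:
        return self.graph.nodes[node].get("aa", "X")

    def edges(self) -> list[tuple[int, int]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "i": i,
                "j": j,
                "aa_i": self.amino_acid(i),
                "aa_j": self.amino_acid(j),
                "min_dist": self.graph.edges[i, j].get("min_dist", np.nan),
            }
            for i, j in self.edges()
        ]
        return pd.DataFrame(rows, columns=["i", "j", "aa_i", "aa_j", "min_dist"])

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[int, int]],
        aa_labels: dict[int, str] | str | None = None,
        cutoff_A: float = 5.0,
    ) -> "ContactGraph":
        """Build a contact graph directly from residue index pairs.

        ``aa_labels`` may be a dict position->amino acid or a reference
        sequence string (1-based indexing).
        """
        g = nx.Graph()
        for i, j in pairs:
            if i == j:
                raise StructureError("self-contact not allowed")
            g.add_edge(int(i), int(j))
        if isinstance(aa_labels, str):
            aa_labels = {p: aa_labels[p - 1] for p in g.nodes}
        for node in g.nodes:
            g.nodes[node]["aa"] = (aa_labels or {}).get(node, "X")
        return cls(graph=g, cutoff_A=cutoff_A)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, cutoff_A: float = 5.0) -> "ContactGraph":
        g = nx.Graph()
        for row in frame.itertuples(index=False):
            g.add_edge(int(row.i), int(row.j), min_dist=float(getattr(row, "min_dist", np.nan)))
            g.nodes[int(row.i)]["aa"] = getattr(row, "aa_i", "X")
            g.nodes[int(row.j)]["aa"] = getattr(row, "aa_j", "X")
        return cls(graph=g, cutoff_A=cutoff_A)


def build_contact_map(
    chain: StructureChain,
    cutoff_A: float = 5.0,
    *,
    min_seq_separation: int = 1,
) -> ContactGraph:
    """Contact graph of a chain at an any-atom distance cutoff (strict ``<``).

    Every residue appears as a node; an edge joins residues i != j when
    some atom of i is closer than ``cutoff_A`` to some atom of j.
    Sequence-adjacent pairs are included by default
    (``min_seq_separation=1``); raise it to exclude near-in-sequence
    contacts.
    """
    if cutoff_A <= 0:
        raise StructureError("cutoff must be positive")
    coords = []
    owner = []
    for res in chain.residues:
        for xyz in res.atoms.values():
            coords.append(xyz)
            owner.append(res.index)
    coords_arr = np.asarray(coords)
    owner_arr = np.asarray(owner)
    g = nx.Graph()
    for res in chain.residues:
        g.add_node(res.index, aa=res.name)
    tree = cKDTree(coords_arr)
    min_dist: dict[tuple[int, int], float] = {}
    for a, b in tree.query_pairs(r=cutoff_A):
        ri, rj = owner_arr[a], owner_arr[b]
        if ri == rj or abs(int(ri) - int(rj)) < min_seq_separation:
            continue
        d = float(np.linalg.norm(coords_arr[a] - coords_arr[b]))
        if d >= cutoff_A:  # strict threshold; KD-tree query is inclusive
            continue
        key = (int(min(ri, rj)), int(max(ri, rj)))
        if d < min_dist.get(key, np.inf):
            min_dist[key] = d
    for (i, j), d in min_dist.items():
        g.add_edge(i, j, min_dist=d)
    return ContactGraph(graph=g, cutoff_A=cutoff_A)


def size_order(graph: ContactGraph | nx.Graph) -> tuple[int, int]:
    """(size, order) = (number of residues, number of contacts)."""
    g = graph.graph if isinstance(graph, ContactGraph) else graph
    return g.number_of_nodes(), g.number_of_edges()


def mean_contacts_per_residue(graph: ContactGraph | nx.Graph) -> float:
    """Mean degree 2*order/size — the per-chain packing-density statistic."""
    size, order = size_order(graph)
    if size == 0:
        raise StructureError("empty graph")
    return 2.0 * order / size


class PackingFit(NamedTuple):
    """Least-squares line through (size, order) points."""

    slope: float
    intercept: float
    residual: float


def fit_packing_line(points: Sequence[tuple[float, float]]) -> PackingFit:
    """Ordinary least-squares fit of order against size.

    The slope is interpretable as contacts per residue across the cohort.
    Requires at least two distinct sizes.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise StructureError("need at least two (size, order) points")
    sizes, orders = pts[:, 0], pts[:, 1]
    if np.allclose(sizes, sizes[0]):
        raise StructureError("degenerate fit: all sizes identical")
    result = linregress(sizes, orders)
    residual = float(np.sum((orders - (result.slope * sizes + result.intercept)) ** 2))
    return PackingFit(slope=float(result.slope), intercept=float(result.intercept), residual=residual)


@dataclass(frozen=True)
class CliqueProfile:
    """Counts of maximal cliques by exact size; larger cliques are diagnostics."""

    counts: tuple[tuple[int, int], ...]
    larger: int = 0

    def mc(self, k: int) -> int:
        return dict(self.counts).get(k, 0)

    def as_dict(self) -> dict[int, int]:
        return dict(self.counts)


def maximal_cliques_by_size(
    graph: ContactGraph | nx.Graph, sizes: Iterable[int] = (3, 4, 5)
) -> CliqueProfile:
    """Count maximal cliques with exactly the requested sizes.

    Maximal cliques — fully connected residue sets not contained in any
    larger clique — are enumerated with networkx's pivoting
    Bron-Kerbosch algorithm. Cliques larger than the largest requested
    size are counted separately under ``larger``.
    """
    g = graph.graph if isinstance(graph, ContactGraph) else graph
    wanted = sorted(set(int(s) for s in sizes))
    if any(s < 1 for s in wanted):
        raise StructureError("clique sizes must be >= 1")
    counts = defaultdict(int)
    larger = 0
    top = max(wanted) if wanted else 0
    for clique in nx.find_cliques(g):
        k = len(clique)
        if k in wanted:
            counts[k] += 1
        elif k > top:
            larger += 1
    return CliqueProfile(counts=tuple((s, counts[s]) for s in wanted), larger=larger)


def chain_summary(chain: StructureChain, cutoff_A: float = 5.0) -> dict[str, float]:
    """Per-chain packing summary: size, order, mean degree, clique profile."""
    cg = build_contact_map(chain, cutoff_A=cutoff_A)
    size, order = size_order(cg)
    profile = maximal_cliques_by_size(cg)
    return {
        "chain": chain.id,
        "size": size,
        "order": order,
        "contacts_per_residue": mean_contacts_per_residue(cg) if size else float("nan"),
        "mc3": profile.mc(3),
        "mc4": profile.mc(4),
        "mc5": profile.mc(5),
    }
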