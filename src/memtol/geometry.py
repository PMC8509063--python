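"""Hydrophobic-contact geometry and Hausdorff-distance comparisons.

Each hydrophobic residue with at least two contacting hydrophobic
neighbours is described by the angles subtended at its side-chain
centroid by every pair of neighbour centroids — a rotation-invariant
encoding of the spatial arrangement of its hydrophobic shell. A protein
becomes a set of such angle vectors; two proteins are compared with the
Hausdorff distance between their vector sets, and a seeded simulated
annealing searches a global angular offset to report the minimum
Hausdorff distance. Cohort comparisons are restricted to same-CATH-class
pairs with similar lengths, mirroring how transmembrane and globular
packing geometries are contrasted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .structure_contacts import ContactGraph, StructureChain

#: Standard hydrophobic residues (one-letter).
HYDROPHOBIC_RESIDUES = frozenset("AVLIMFWC")

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


class GeometryError(ValueError):
    """Base class for geometry errors."""


def representative_point(atoms: Mapping[str, np.ndarray]) -> np.ndarray:
    """Side-chain centroid of a residue; falls back to CA (e.g. glycine)."""
    side = [xyz for name, xyz in atoms.items() if name not in BACKBONE_ATOMS]
    if side:
        return np.mean(side, axis=0)
    if "CA" in atoms:
        return np.asarray(atoms["CA"], dtype=float)
    raise GeometryError("residue has neither side-chain atoms nor CA")


def angle_at(center: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Angle in degrees subtended at ``center`` by points ``a`` and ``b``."""
    u = np.asarray(a, float) - np.asarray(center, float)
    v = np.asarray(b, float) - np.asarray(center, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise GeometryError("degenerate angle: coincident points")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


@dataclass
class AngleVectorSet:
    """Per-residue angle vectors describing a protein's hydrophobic contacts.

    ``vectors`` maps a central residue index to its canonical (sorted
    descending) vector of neighbour-pair angles in degrees.
    ``n_residues`` is the chain length, used for cohort length filtering.
    """

    protein_id: str
    vectors: dict[int, np.ndarray]
    n_residues: int = 0

    def __post_init__(self) -> None:
        canon = {}
        for key, vec in self.vectors.items():
            arr = np.sort(np.asarray(vec, dtype=float))[::-1]
            if arr.size == 0:
                raise GeometryError(f"empty angle vector for residue {key}")
            canon[int(key)] = arr
        self.vectors = canon

    def as_list(self) -> list[np.ndarray]:
        return [self.vectors[k] for k in sorted(self.vectors)]

    def __len__(self) -> int:
        return len(self.vectors)


def hydrophobic_contact_angles(
    chain: StructureChain,
    contacts: ContactGraph,
    hydrophobic: frozenset[str] = HYDROPHOBIC_RESIDUES,
) -> AngleVectorSet:
    """Angle vectors of every hydrophobic residue with >= 2 hydrophobic contacts.

    For a central residue c with hydrophobic contacting neighbours
    n1..nk, the vector holds the angles at c's representative point
    subtended by every neighbour pair, sorted descending.
    """
    if not hydrophobic:
        raise GeometryError("hydrophobic set must be non-empty")
    points: dict[int, np.ndarray] = {}
    names: dict[int, str] = {}
    for res in chain.residues:
        names[res.index] = res.name
        try:
            points[res.index] = representative_point(res.atoms)
        except GeometryError:
            continue  # residue lacks usable atoms: skipped
    vectors: dict[int, np.ndarray] = {}
    for res in chain.residues:
        if names[res.index] not in hydrophobic or res.index not in points:
            continue
        neighbours = [
            n
            for n in contacts.neighbors(res.index)
            if names.get(n) in hydrophobic and n in points
        ]
        if len(neighbours) < 2:
            continue
        center = points[res.index]
        angles = [
            angle_at(center, points[a], points[b]) for a, b in combinations(neighbours, 2)
        ]
        vectors[res.index] = np.asarray(angles)
    return AngleVectorSet(protein_id=chain.id, vectors=vectors, n_residues=len(chain))


def vector_distance(u: np.ndarray, v: np.ndarray, mode: str = "truncate") -> float:
    """Distance between two canonical angle vectors.

    ``truncate`` (default): Euclidean distance over the first
    min(len(u), len(v)) elements. ``pad``: the shorter vector is
    zero-padded before the Euclidean distance.
    """
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    if mode == "truncate":
        k = min(u.size, v.size)
        if k == 0:
            raise GeometryError("empty angle vector")
        return float(np.linalg.norm(u[:k] - v[:k]))
    if mode == "pad":
        k = max(u.size, v.size)
        up = np.pad(u, (0, k - u.size))
        vp = np.pad(v, (0, k - v.size))
        return float(np.linalg.norm(up - vp))
    raise GeometryError(f"unknown vector metric mode {mode!r}")


def _vector_list(A: AngleVectorSet | Sequence[np.ndarray]) -> list[np.ndarray]:
    if isinstance(A, AngleVectorSet):
        return A.as_list()
    return [np.asarray(v, float).ravel() for v in A]


def hausdorff_distance(
    A: AngleVectorSet | Sequence[np.ndarray],
    B: AngleVectorSet | Sequence[np.ndarray],
    *,
    mode: str = "truncate",
    offset: float = 0.0,
) -> float:
    """Symmetric Hausdorff distance between two sets of angle vectors.

    max(h(A,B), h(B,A)) with h(X,Y) = max over x of min over y of the
    vector distance. ``offset`` is added elementwise to every vector of B
    (the transform family searched by :func:`min_hausdorff`).
    """
    a_list = _vector_list(A)
    b_list = [v + offset for v in _vector_list(B)]
    if not a_list or not b_list:
        raise GeometryError("Hausdorff distance needs non-empty sets")
    d = np.array([[vector_distance(u, v, mode) for v in b_list] for u in a_list])
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


@dataclass(frozen=True)
class AnnealingSchedule:
    """Geometric-cooling schedule for the offset search."""

    t0: float = 100.0
    alpha: float = 0.95
    steps: int = 5000

    def __post_init__(self) -> None:
        if self.t0 <= 0 or not 0 < self.alpha < 1 or self.steps < 1:
            raise GeometryError(f"invalid annealing schedule {self}")


class MinHausdorffResult(NamedTuple):
    distance: float
    offset: float


def min_hausdorff(
    A: AngleVectorSet | Sequence[np.ndarray],
    B: AngleVectorSet | Sequence[np.ndarray],
    schedule: AnnealingSchedule | None = None,
    seed: int = 0,
    *,
    mode: str = "truncate",
) -> MinHausdorffResult:
    """Minimum Hausdorff distance over a global angular offset applied to B.

    A seeded simulated annealing (Metropolis acceptance, geometric
    cooling) searches the offset; the identity offset is the start state,
    so the result never exceeds the unminimized distance. Deterministic
    for a given seed.
    """
    schedule = schedule or AnnealingSchedule()
    rng = np.random.default_rng(seed)
    a_list = _vector_list(A)
    b_list = _vector_list(B)

    def cost(offset: float) -> float:
        return hausdorff_distance(a_list, b_list, mode=mode, offset=offset)

    current = 0.0
    current_cost = cost(current)
    best, best_cost = current, current_cost
    t = schedule.t0
    for _ in range(schedule.steps):
        # proposal width shrinks with temperature: global at t0, local late
        sigma = 0.5 + 180.0 * (t / schedule.t0)
        candidate = current + rng.normal(0.0, sigma)
        candidate = float(np.clip(candidate, -360.0, 360.0))
        candidate_cost = cost(candidate)
        delta = candidate_cost - current_cost
        if delta <= 0 or rng.random() < math.exp(-delta / t):
            current, current_cost = candidate, candidate_cost
            if current_cost < best_cost:
                best, best_cost = current, current_cost
        t *= schedule.alpha
    # deterministic local polish around the annealed optimum
    from scipy.optimize import minimize_scalar

    refine = minimize_scalar(
        cost, bounds=(best - 2.0, best + 2.0), method="bounded",
        options={"xatol": 1e-9},
    )
    if refine.fun < best_cost:
        best, best_cost = float(refine.x), float(refine.fun)
    return MinHausdorffResult(distance=best_cost, offset=best)


@dataclass(frozen=True)
class PairComparison:
    """Hausdorff comparison between two proteins of the same CATH class."""

    id_a: str
    id_b: str
    cath_class: str
    raw_hausdorff: float
    min_hausdorff: float
    identical: bool


@dataclass
class CohortComparison:
    comparisons: list[PairComparison]
    class_summary: pd.DataFrame
    fraction_identical: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id_a": c.id_a,
                    "id_b": c.id_b,
                    "cath_class": c.cath_class,
                    "raw_hausdorff": c.raw_hausdorff,
                    "min_hausdorff": c.min_hausdorff,
                    "identical": c.identical,
                }
                for c in self.comparisons
            ],
            columns=["id_a", "id_b", "cath_class", "raw_hausdorff", "min_hausdorff", "identical"],
        )


def compare_cohort(
    angle_sets: Mapping[str, AngleVectorSet],
    cath_labels: Mapping[str, str],
    *,
    max_len_diff: int = 20,
    tolerance: float = 1.0,
    schedule: AnnealingSchedule | None = None,
    seed: int = 0,
    mode: str = "truncate",
) -> CohortComparison:
    """All-vs-all comparison within CATH classes.

    Only pairs sharing a CATH class and differing in length by at most
    ``max_len_diff`` residues are compared. A pair has *identical
    orientation* when its minimized Hausdorff distance is at most
    ``tolerance`` (degrees). Per-class summaries report the median, min
    and max of the minimized distances plus the identical fraction.
    """
    missing = set(angle_sets) - set(cath_labels)
    if missing:
        raise GeometryError(f"missing CATH labels for {sorted(missing)}")
    ids = sorted(angle_sets)
    comparisons: list[PairComparison] = []
    for k, (ia, ib) in enumerate(combinations(ids, 2)):
        if cath_labels[ia] != cath_labels[ib]:
            continue
        A, B = angle_sets[ia], angle_sets[ib]
        if abs(A.n_residues - B.n_residues) > max_len_diff:
            continue
        if len(A) == 0 or len(B) == 0:
            continue
        raw = hausdorff_distance(A, B, mode=mode)
        minimized = min_hausdorff(
            A, B, schedule=schedule, seed=(seed * 100003 + k) % (2**31), mode=mode
        ).distance
        comparisons.append(
            PairComparison(
                id_a=ia,
                id_b=ib,
                cath_class=cath_labels[ia],
                raw_hausdorff=raw,
                min_hausdorff=minimized,
                identical=minimized <= tolerance,
            )
        )
    rows = []
    for cath in sorted({c.cath_class for c in comparisons}):
        dists = [c.min_hausdorff for c in comparisons if c.cath_class == cath]
        n_ident = sum(c.identical for c in comparisons if c.cath_class == cath)
        rows.append(
            {
                "cath_class": cath,
                "n_pairs": len(dists),
                "median": float(np.median(dists)),
                "min": float(np.min(dists)),
                "max": float(np.max(dists)),
                "fraction_identical": n_ident / len(dists),
            }
        )
    summary = pd.DataFrame(
        rows, columns=["cath_class", "n_pairs", "median", "min", "max", "fraction_identical"]
    )
    fraction = (
        sum(c.identical for c in comparisons) / len(comparisons) if comparisons else float("nan")
    )
    return CohortComparison(
        comparisons=comparisons, class_summary=summary, fraction_identical=fraction
    )
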