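"""Seeded generators with known ground truth for every analysis stage.

The generators emulate the three kinds of input the pipeline consumes:

* read pools from a pooled phenotype screen, with planted deleterious and
  compensatory substitutions and a configurable per-base sequencing error
  rate (errors are applied at the nucleotide level, before translation,
  so noise reaches the statistics through the same mechanism as in a real
  amplicon experiment);
* protein-family alignments with independent rows, per-column background
  substitution and planted pairwise-correlated (both-or-neither)
  substitutions;
* 3-D chains: ideal poly-alanine alpha-helices built from canonical
  backbone dihedrals (phi=-57, psi=-47), and compact globular decoys on a
  jittered cubic lattice with realistic inter-residue distances.

Every generator is bit-reproducible given (parameters, seed) and emits a
machine-readable truth table for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .library_design import (
    encoded_amino_acids,
    expected_substitutions,
    hokc_region_layout,
    sns_scheme,
)
from .msa_analysis import Alignment
from .structure_contacts import Residue, StructureChain
from .variant_calling import (
    AMINO_ACIDS,
    ReferenceProtein,
    Substitution,
    VariantGenotype,
    apply_substitutions,
)

__all__ = [
    "hokc_reference",
    "make_ideal_helix",
    "make_globular_decoy",
    "PlantedScreenTruth",
    "default_screen_truth",
    "simulate_read_pools",
    "SimulatedPools",
    "PlantedMsaTruth",
    "simulate_msa",
    "write_pdb",
]


class SyntheticDataError(ValueError):
    """Base class for generator errors."""


# ---------------------------------------------------------------------------
# Reference protein

#: Coding sequence of the short (second-ATG) HokC ORF, residues 1-29 of the
#: transmembrane toxin and its flank, followed by a stop codon.
HOKC_ORF = (
    "ATGAAGCAGCATAAGGCGATGATTGTCGCCCTGATCGTCATCTGTATCACCGCCGTAGTG"
    "GCGGCGCTGGTAACGAGAAAAGACCTCTAA"
)


def hokc_reference() -> ReferenceProtein:
    """The HokC transmembrane-region reference (MKQHKAMIVALIVICITAVVAALVTRKDL)."""
    return ReferenceProtein(
        id="HOKC_ECOLI",
        aa_sequence="MKQHKAMIVALIVICITAVVAALVTRKDL",
        orf_sequence=HOKC_ORF[:-3],
    )


# ---------------------------------------------------------------------------
# 3-D chain generators

_BACKBONE = {
    "n_ca": 1.458,
    "ca_c": 1.525,
    "c_n": 1.329,
    "c_o": 1.231,
    "ca_cb": 1.530,
    "ang_n_ca_c": 111.2,
    "ang_ca_c_n": 116.2,
    "ang_c_n_ca": 121.7,
    "ang_ca_c_o": 120.5,
    "ang_c_ca_cb": 110.6,
    "phi": -57.0,
    "psi": -47.0,
    "omega": 180.0,
    "improper_n_c_ca_cb": -122.6,
}


def _place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle_deg: float, dihedral_deg: float
) -> np.ndarray:
    """Place atom D from frame atoms A-B-C (bond C-D, angle B-C-D, dihedral A-B-C-D)."""
    theta = math.radians(angle_deg)
    chi = math.radians(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * math.cos(theta),
            bond * math.sin(theta) * math.cos(chi),
            bond * math.sin(theta) * math.sin(chi),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def make_ideal_helix(
    n_residues: int, seed: int | None = None, *, jitter: float = 0.0
) -> StructureChain:
    """Ideal poly-alanine alpha-helix (full backbone N/CA/C/O plus CB).

    Built from canonical helical dihedrals (phi=-57, psi=-47, omega=180),
    which yields the textbook ~1.5 A rise and ~100 degree twist per
    residue and consecutive CA-CA distances of ~3.8 A. Optional Gaussian
    coordinate jitter of width ``jitter`` (A) is applied with the seeded
    generator.
    """
    if n_residues < 1:
        raise SyntheticDataError("n_residues must be >= 1")
    p = _BACKBONE
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([p["n_ca"], 0.0, 0.0])
    gamma = math.radians(180.0 - p["ang_n_ca_c"])
    c0 = ca0 + p["ca_c"] * np.array([math.cos(gamma), math.sin(gamma), 0.0])
    backbone: list[dict[str, np.ndarray]] = [{"N": n0, "CA": ca0, "C": c0}]
    for _ in range(1, n_residues):
        prev = backbone[-1]
        n_i = _place_atom(prev["N"], prev["CA"], prev["C"], p["c_n"], p["ang_ca_c_n"], p["psi"])
        ca_i = _place_atom(prev["CA"], prev["C"], n_i, p["n_ca"], p["ang_c_n_ca"], p["omega"])
        c_i = _place_atom(prev["C"], n_i, ca_i, p["ca_c"], p["ang_n_ca_c"], p["phi"])
        backbone.append({"N": n_i, "CA": ca_i, "C": c_i})
    residues: list[Residue] = []
    for i, atoms in enumerate(backbone):
        full = dict(atoms)
        full["O"] = _place_atom(
            atoms["N"], atoms["CA"], atoms["C"], p["c_o"], p["ang_ca_c_o"], p["psi"] + 180.0
        )
        full["CB"] = _place_atom(
            atoms["N"], atoms["C"], atoms["CA"], p["ca_cb"], p["ang_c_ca_cb"], p["improper_n_c_ca_cb"]
        )
        residues.append(Residue(index=i + 1, name="A", atoms=full))
    if jitter > 0:
        rng = np.random.default_rng(seed)
        for res in residues:
            for name in res.atoms:
                res.atoms[name] = res.atoms[name] + rng.normal(0.0, jitter, 3)
    return StructureChain(id=f"helix{n_residues}", residues=residues)


def make_globular_decoy(
    n_residues: int,
    seed: int = 0,
    *,
    spacing: float = 4.2,
    jitter: float = 0.3,
    hydrophobic_fraction: float = 0.5,
    max_attempts: int = 20,
) -> StructureChain:
    """Compact globular decoy: residues on a jittered cubic lattice ball.

    The ``n_residues`` lattice sites nearest the origin are selected
    (giving a compact, connected cluster) and perturbed inside a uniform
    ball of radius ``jitter``, keeping the minimum inter-residue distance
    at ``spacing - 2*jitter`` (>= 3.5 A at the defaults) and every
    nearest-neighbour distance under 5 A. Residue identities are sampled
    with ``hydrophobic_fraction`` hydrophobics. Deterministic per seed.
    """
    if n_residues < 2:
        raise SyntheticDataError("n_residues must be >= 2")
    if spacing - 2 * jitter < 3.5:
        raise SyntheticDataError("spacing/jitter would violate the 3.5 A minimum distance")
    rng = np.random.default_rng(seed)
    radius = int(math.ceil((n_residues ** (1 / 3)))) + 2
    sites = np.array(
        sorted(
            product(range(-radius, radius + 1), repeat=3),
            key=lambda s: (s[0] ** 2 + s[1] ** 2 + s[2] ** 2, s),
        )[:n_residues],
        dtype=float,
    )
    if len(sites) < n_residues:
        raise SyntheticDataError("lattice too small for requested size")
    points = sites * spacing
    for _ in range(max_attempts):
        # uniform jitter inside a ball of the given radius
        direction = rng.normal(size=points.shape)
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        magnitude = jitter * rng.random(len(points)) ** (1 / 3)
        candidate = points + direction * magnitude[:, None]
        diff = candidate[:, None, :] - candidate[None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
        np.fill_diagonal(dist, np.inf)
        if dist.min() >= 3.5:
            points = candidate
            break
    else:
        raise SyntheticDataError("packing failure: could not jitter without clashes")
    hydrophobic = sorted("AVLIMFWC")
    polar = sorted(set(AMINO_ACIDS) - set(hydrophobic))
    names = [
        rng.choice(hydrophobic) if rng.random() < hydrophobic_fraction else rng.choice(polar)
        for _ in range(n_residues)
    ]
    residues = [
        Residue(index=i + 1, name=str(names[i]), atoms={"CA": points[i]})
        for i in range(n_residues)
    ]
    return StructureChain(id=f"globule{n_residues}_s{seed}", residues=residues)


def write_pdb(chain: StructureChain, path: str | Path) -> None:
    """Write a chain as a minimal single-chain PDB file."""
    three = {
        "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
        "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
        "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
        "W": "TRP", "Y": "TYR",
    }
    serial = 1
    with open(path, "w") as fh:
        for res in chain.residues:
            resname = three.get(res.name, "UNK")
            for atom_name, xyz in res.atoms.items():
                element = atom_name[0]
                name_field = atom_name if len(atom_name) == 4 else f" {atom_name:<3s}"
                fh.write(
                    f"ATOM  {serial:5d} {name_field} {resname:>3s} A{res.index:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          {element:>2s}\n"
                )
                serial += 1
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Screen simulation

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


def _codon_for(aa: str) -> str:
    """Deterministic codon choice for an amino acid, preferring SNS codons."""
    candidates = sorted(c for c, a in _TABLE.forward_table.items() if a == aa)
    if not candidates:
        raise SyntheticDataError(f"no codon for amino acid {aa!r}")
    sns = [c for c in candidates if c[0] in "GC" and c[2] in "GC"]
    return (sns or candidates)[0]


@dataclass(frozen=True)
class PlantedScreenTruth:
    """Ground truth of a simulated pooled screen.

    ``deleterious_singles`` lose toxin function on their own;
    ``compensatory_pairs`` are genotypes whose members include at least
    one planted deleterious single yet show the wild-type phenotype;
    ``tolerated_singles`` keep function. ``error_rate`` is the per-base
    sequencing error probability (capped at 5%).
    """

    reference: ReferenceProtein
    deleterious_singles: frozenset[Substitution]
    compensatory_pairs: tuple[frozenset[Substitution], ...]
    tolerated_singles: frozenset[Substitution]
    depth: int = 500
    error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference.orf_sequence is None:
            raise SyntheticDataError("screen truth needs a reference with an ORF")
        if not 0 <= self.error_rate <= 0.05:
            raise SyntheticDataError("error_rate must be in [0, 0.05]")
        if self.depth < 1:
            raise SyntheticDataError("depth must be >= 1")
        for pair in self.compensatory_pairs:
            if not (pair & self.deleterious_singles):
                raise SyntheticDataError(
                    f"compensatory pair {sorted(map(str, pair))} has no deleterious member"
                )
        overlap = self.tolerated_singles & self.deleterious_singles
        if overlap:
            raise SyntheticDataError(f"substitutions both tolerated and deleterious: {overlap}")

    def planted_genotypes(self) -> list[tuple[VariantGenotype, str, str]]:
        """(genotype, category, phenotype) for every planted variant."""
        entries: list[tuple[VariantGenotype, str, str]] = []
        for sub in sorted(self.tolerated_singles):
            entries.append((VariantGenotype((sub,)), "tolerated_single", "wild_type"))
        for sub in sorted(self.deleterious_singles):
            entries.append((VariantGenotype((sub,)), "deleterious_single", "mutant"))
        for pair in self.compensatory_pairs:
            genotype = VariantGenotype(tuple(sorted(pair, key=lambda s: s.position)))
            entries.append((genotype, "compensatory", self.phenotype_of(genotype)))
        return entries

    def phenotype_of(self, genotype: VariantGenotype) -> str:
        """Planted phenotype rule.

        A genotype shows the mutant phenotype (growth, toxin inactive) iff
        it contains a planted deleterious single that is not accompanied by
        the rest of a planted compensatory combination; otherwise the toxin
        still kills and the phenotype is wild type.
        """
        members = frozenset(genotype)
        compensated: set[Substitution] = set()
        for pair in self.compensatory_pairs:
            if pair <= members:
                compensated |= pair & self.deleterious_singles
        for sub in members & self.deleterious_singles:
            if sub not in compensated:
                return "mutant"
        return "wild_type"


def default_screen_truth(
    seed: int = 0, *, depth: int = 500, error_rate: float = 0.005
) -> PlantedScreenTruth:
    """Screen truth emulating the HokC study conditions.

    Deleterious singles and compensatory pairs follow the screen's most
    frequent compensatory combinations (M7W+I12S and companions);
    tolerated singles are every remaining SNS-reachable substitution over
    the 7-region tiling of positions 2-24.
    """
    reference = hokc_reference()
    deleterious = frozenset(
        Substitution.from_string(s)
        for s in ("M7W", "L11P", "I12S", "I12C", "I14S", "V19G", "A22T")
    )
    pair_specs = [
        ("M7W", "I12S"),
        ("I12S", "I14S"),
        ("L11P", "I12S"),
        ("M7W", "I12C"),
        ("M7W", "I14S"),
        ("M7W", "L11P"),
        ("I12S", "V19G"),
        ("I12S", "A22T"),
    ]
    pairs = tuple(
        frozenset(Substitution.from_string(s) for s in spec) for spec in pair_specs
    )
    sns_aas = encoded_amino_acids(sns_scheme()).amino_acids
    tolerated = frozenset(
        expected_substitutions(hokc_region_layout(), sns_aas, reference) - deleterious
    )
    return PlantedScreenTruth(
        reference=reference,
        deleterious_singles=deleterious,
        compensatory_pairs=pairs,
        tolerated_singles=tolerated,
        depth=depth,
        error_rate=error_rate,
        seed=seed,
    )


@dataclass
class SimulatedPools:
    """Simulated read pools plus their ground-truth table."""

    wt_reads: list[str]
    mut_reads: list[str]
    truth: PlantedScreenTruth
    truth_frame: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "wt_pool": outdir / "reads_wt.fasta",
            "mut_pool": outdir / "reads_mut.fasta",
            "reference": outdir / "reference.fasta",
            "truth": outdir / "screen_truth.tsv",
        }
        for key, reads in (("wt_pool", self.wt_reads), ("mut_pool", self.mut_reads)):
            with open(paths[key], "w") as fh:
                for i, seq in enumerate(reads):
                    fh.write(f">read_{key}_{i}\n{seq}\n")
        with open(paths["reference"], "w") as fh:
            fh.write(f">{self.truth.reference.id}\n{self.truth.reference.orf_sequence}\n")
        self.truth_frame.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _mutant_orf(reference: ReferenceProtein, genotype: VariantGenotype) -> str:
    apply_substitutions(reference, genotype)  # validates ref residues
    codons = [
        reference.orf_sequence[i : i + 3] for i in range(0, len(reference.orf_sequence), 3)
    ]
    for sub in genotype:
        codons[sub.position - 1] = _codon_for(sub.alt_aa)
    return "".join(codons)


def simulate_read_pools(truth: PlantedScreenTruth) -> SimulatedPools:
    """Generate phenotype-labelled read pools from a planted truth.

    Every planted genotype is sequenced ``truth.depth`` times; its reads
    go to the pool of its planted phenotype; per-base substitution errors
    are then applied at ``truth.error_rate`` with the seeded generator.
    """
    rng = np.random.default_rng(truth.seed)
    pools: dict[str, list[str]] = {"wild_type": [], "mutant": []}
    records = []
    for genotype, category, phenotype in truth.planted_genotypes():
        orf = _mutant_orf(truth.reference, genotype)
        base_idx = np.array([_BASE_INDEX[b] for b in orf], dtype=np.int8)
        reads_idx = np.tile(base_idx, (truth.depth, 1))
        if truth.error_rate > 0:
            err = rng.random(reads_idx.shape) < truth.error_rate
            shifts = rng.integers(1, 4, size=reads_idx.shape, dtype=np.int8)
            reads_idx = np.where(err, (reads_idx + shifts) % 4, reads_idx)
        base_chars = np.array(list(_BASES))
        for row in reads_idx:
            pools[phenotype].append("".join(base_chars[row]))
        records.append(
            {
                "genotype": str(genotype),
                "category": category,
                "phenotype": phenotype,
                "depth": truth.depth,
            }
        )
    truth_frame = pd.DataFrame(records, columns=["genotype", "category", "phenotype", "depth"])
    return SimulatedPools(
        wt_reads=pools["wild_type"],
        mut_reads=pools["mutant"],
        truth=truth,
        truth_frame=truth_frame,
    )


# ---------------------------------------------------------------------------
# MSA simulation

@dataclass(frozen=True)
class PlantedMsaTruth:
    """Ground truth of a simulated family alignment.

    Rows are drawn independently: each column substitutes to a random
    non-reference residue at ``background_rate``; each planted correlated
    pair (i, j, rate) co-substitutes (both positions or neither) at its
    rate.
    """

    reference: str
    n_rows: int = 148
    background_rate: float = 0.1
    correlated_pairs: tuple[tuple[int, int, float], ...] = ()
    reference_id: str = "REF"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.reference:
            raise SyntheticDataError("empty reference sequence")
        if self.n_rows < 1:
            raise SyntheticDataError("n_rows must be >= 1")
        if not 0 <= self.background_rate <= 1:
            raise SyntheticDataError("background_rate must be in [0, 1]")
        for i, j, rate in self.correlated_pairs:
            if not (1 <= i <= len(self.reference) and 1 <= j <= len(self.reference)):
                raise SyntheticDataError(f"correlated pair ({i},{j}) outside reference")
            if i == j or not 0 <= rate <= 1:
                raise SyntheticDataError(f"invalid correlated pair ({i},{j},{rate})")


@dataclass
class SimulatedMsa:
    alignment: Alignment
    truth: PlantedMsaTruth
    truth_frame: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"alignment": outdir / "family.fasta", "truth": outdir / "msa_truth.tsv"}
        self.alignment.to_fasta(paths["alignment"])
        self.truth_frame.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _random_other_aa(rng: np.random.Generator, ref_aa: str) -> str:
    choices = [a for a in AMINO_ACIDS if a != ref_aa]
    return choices[int(rng.integers(len(choices)))]


def simulate_msa(truth: PlantedMsaTruth) -> SimulatedMsa:
    """Generate an ungapped family alignment with planted correlated pairs.

    The reference appears as the first row. The truth table records, per
    generated row, which planted pairs co-mutated.
    """
    rng = np.random.default_rng(truth.seed)
    ref = truth.reference.upper()
    correlated_positions = {i for i, _, _ in truth.correlated_pairs} | {
        j for _, j, _ in truth.correlated_pairs
    }
    rows: list[tuple[str, str]] = [(truth.reference_id, ref)]
    records = []
    for r in range(truth.n_rows):
        seq = list(ref)
        fired: list[str] = []
        for i, j, rate in truth.correlated_pairs:
            if rng.random() < rate:
                seq[i - 1] = _random_other_aa(rng, ref[i - 1])
                seq[j - 1] = _random_other_aa(rng, ref[j - 1])
                fired.append(f"{i}-{j}")
        for col in range(len(ref)):
            if col + 1 in correlated_positions:
                continue
            if rng.random() < truth.background_rate:
                seq[col] = _random_other_aa(rng, ref[col])
        rid = f"SYN{r + 1:04d}"
        rows.append((rid, "".join(seq)))
        records.append({"row_id": rid, "comutated_pairs": ";".join(fired)})
    alignment = Alignment(rows=tuple(rows), reference_id=truth.reference_id)
    return SimulatedMsa(
        alignment=alignment,
        truth=truth,
        truth_frame=pd.DataFrame(records, columns=["row_id", "comutated_pairs"]),
    )
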