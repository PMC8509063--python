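"""Family-alignment analyses: conservation, compensated homologs, and the
contact-conditioned correlated-mutation index.

Conservation here is identity to a designated reference row: the score of
a reference position is the fraction of alignment rows carrying the same
residue there. Homolog rows are also diffed against the reference to
extract their substitution sets, which supports counting *compensated
sequences* — homologs whose multiple substitutions include one that the
mutagenesis screen found individually deleterious.

The correlated-mutation index conditions on 3-D structure: for every
contacting residue pair the reference amino-acid pair type is tallied
(400 ordered types), a pair counts as *mutated* in a row when both
positions differ from the reference, and the index of a pair type is
mutated events / observed contacting pairs (e.g. 30 contacting Ala-Ala
pairs mutated 15 times gives 0.5, i.e. 50%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO

from .structure_contacts import ContactGraph
from .variant_calling import AMINO_ACIDS, Substitution, VariantGenotype

GAP_CHARS = frozenset("-.")


class MsaError(ValueError):
    """Base class for alignment-analysis errors."""


class CoordinateMismatchError(MsaError):
    """Contact-graph coordinates do not fit the alignment's reference."""


def _is_gap(char: str) -> bool:
    return char in GAP_CHARS


@dataclass(frozen=True)
class Alignment:
    """A gapped multiple sequence alignment with a designated reference row.

    ``column_map[c]`` gives the 1-based reference position of alignment
    column ``c`` (``None`` for columns where the reference is gapped).
    """

    rows: tuple[tuple[str, str], ...]
    reference_id: str
    column_map: tuple[int | None, ...] = field(init=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise MsaError("alignment has no rows")
        rows = tuple((rid, seq.upper()) for rid, seq in self.rows)
        width = len(rows[0][1])
        if any(len(seq) != width for _, seq in rows):
            raise MsaError("alignment rows have unequal lengths")
        object.__setattr__(self, "rows", rows)
        ref_seq = dict(rows).get(self.reference_id)
        if ref_seq is None:
            raise MsaError(f"reference row {self.reference_id!r} not in alignment")
        cmap: list[int | None] = []
        pos = 0
        for char in ref_seq:
            if _is_gap(char):
                cmap.append(None)
            else:
                pos += 1
                cmap.append(pos)
        object.__setattr__(self, "column_map", tuple(cmap))

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    @property
    def reference_row(self) -> str:
        return dict(self.rows)[self.reference_id]

    @property
    def reference_sequence(self) -> str:
        """The ungapped reference sequence."""
        return "".join(c for c in self.reference_row if not _is_gap(c))

    def column_of(self, position: int) -> int:
        """Alignment column (0-based) mapping to a 1-based reference position."""
        for col, pos in enumerate(self.column_map):
            if pos == position:
                return col
        raise MsaError(f"reference position {position} not in alignment")

    @classmethod
    def from_file(
        cls, path: str | Path, reference_id: str, fmt: str | None = None
    ) -> "Alignment":
        path = Path(path)
        if fmt is None:
            fmt = "stockholm" if path.suffix.lower() in {".sto", ".stk", ".stockholm"} else "fasta"
        msa = AlignIO.read(str(path), fmt)
        return cls(rows=tuple((rec.id, str(rec.seq)) for rec in msa), reference_id=reference_id)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rid, seq in self.rows:
                fh.write(f">{rid}\n{seq}\n")


def conservation_scores(
    alignment: Alignment, *, include_gapped_rows: bool = True
) -> dict[int, float]:
    """Identity-to-reference conservation per reference position, in [0, 1].

    score(p) = (# rows matching the reference residue at p) / (# rows).
    A gap never matches; with ``include_gapped_rows=False`` rows gapped at
    a position are dropped from that position's denominator instead.
    """
    ref_row = alignment.reference_row
    scores: dict[int, float] = {}
    for col, pos in enumerate(alignment.column_map):
        if pos is None:
            continue
        ref_aa = ref_row[col]
        matches = 0
        total = 0
        for _, seq in alignment.rows:
            char = seq[col]
            if _is_gap(char):
                if include_gapped_rows:
                    total += 1
                continue
            total += 1
            if char == ref_aa:
                matches += 1
        scores[pos] = matches / total if total else 0.0
    return scores


def reference_substitutions(alignment: Alignment) -> dict[str, VariantGenotype]:
    """Substitution set of every non-reference row, in reference coordinates.

    Columns where either the reference or the row is gapped produce no
    call; non-standard residue codes (X, B, Z, ...) are also skipped.
    """
    ref_row = alignment.reference_row
    out: dict[str, VariantGenotype] = {}
    for rid, seq in alignment.rows:
        if rid == alignment.reference_id:
            continue
        subs = []
        for col, pos in enumerate(alignment.column_map):
            if pos is None:
                continue
            ref_aa, row_aa = ref_row[col], seq[col]
            if _is_gap(row_aa) or row_aa == ref_aa or row_aa not in AMINO_ACIDS:
                continue
            subs.append(Substitution(position=pos, ref_aa=ref_aa, alt_aa=row_aa))
        out[rid] = VariantGenotype(tuple(subs))
    return out


def count_compensated_sequences(
    alignment: Alignment, deleterious: Iterable[Substitution]
) -> tuple[int, dict[str, VariantGenotype]]:
    """Count homolog rows whose multiple substitutions include a deleterious one.

    A row qualifies when it carries >= 2 substitutions relative to the
    reference and at least one of them is in the screen's deleterious set
    — the alignment-level signature of a compensated loss-of-function
    mutation. Returns the count and the qualifying rows' genotypes.
    """
    deleterious_set = frozenset(deleterious)
    qualifying: dict[str, VariantGenotype] = {}
    for rid, genotype in reference_substitutions(alignment).items():
        if len(genotype) >= 2 and any(s in deleterious_set for s in genotype):
            qualifying[rid] = genotype
    return len(qualifying), qualifying


ORDERED_PAIR_TYPES: tuple[tuple[str, str], ...] = tuple(
    (a, b) for a in AMINO_ACIDS for b in AMINO_ACIDS
)


@dataclass
class PairMutationTable:
    """Correlated-mutation index over the 400 ordered amino-acid pair types.

    ``observed[t]`` counts contacting reference pairs of type t;
    ``mutated[t]`` counts (row, contacting pair) events where both
    positions differ from the reference. The normalized frequency is
    mutated/observed (``normalizer="pair"``, the worked-example
    convention), or additionally divided by ``n_rows`` — the number of
    homolog rows compared, reference excluded — with
    ``normalizer="pair_rows"``, which estimates the per-homolog
    co-mutation rate of a pair type.
    """

    observed: dict[tuple[str, str], int]
    mutated: dict[tuple[str, str], int]
    n_rows: int
    normalizer: str = "pair"

    def frequency(self, pair_type: tuple[str, str]) -> float:
        obs = self.observed.get(pair_type, 0)
        if obs == 0:
            return 0.0
        denom = obs * (self.n_rows if self.normalizer == "pair_rows" else 1)
        return self.mutated.get(pair_type, 0) / denom

    def percent(self, pair_type: tuple[str, str]) -> float:
        return 100.0 * self.frequency(pair_type)

    def rank(self, pair_type: tuple[str, str]) -> int:
        """1-based rank of a pair type by normalized frequency (1 = highest)."""
        f = self.frequency(pair_type)
        return 1 + sum(1 for t in ORDERED_PAIR_TYPES if self.frequency(t) > f)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "aa1": a,
                "aa2": b,
                "observed": self.observed.get((a, b), 0),
                "mutated": self.mutated.get((a, b), 0),
                "frequency": self.frequency((a, b)),
            }
            for a, b in ORDERED_PAIR_TYPES
        ]
        return pd.DataFrame(rows, columns=["aa1", "aa2", "observed", "mutated", "frequency"])


def correlated_mutation_index(
    alignment: Alignment,
    contacts: ContactGraph | Iterable[tuple[int, int]],
    *,
    normalizer: str = "pair",
) -> PairMutationTable:
    """Contact-conditioned correlated-mutation index of a protein family.

    Contacting residue pairs (reference coordinates) are typed by their
    reference amino-acid pair; for every alignment row, a contacting pair
    is a *mutated event* when both positions carry non-gap residues that
    differ from the reference. Frequencies follow the convention of the
    worked example: 30 contacting Ala-Ala pairs mutated 15 times -> 0.5.
    """
    if normalizer not in {"pair", "pair_rows"}:
        raise MsaError(f"unknown normalizer {normalizer!r}")
    if isinstance(contacts, ContactGraph):
        pairs = contacts.edges()
    else:
        pairs = sorted(tuple(sorted((int(i), int(j)))) for i, j in contacts)
    ref_seq = alignment.reference_sequence
    n_ref = len(ref_seq)
    for i, j in pairs:
        if not (1 <= i <= n_ref and 1 <= j <= n_ref):
            raise CoordinateMismatchError(
                f"contact ({i},{j}) outside reference of length {n_ref}"
            )
    # Columns for each reference position (reference-gap columns are skipped
    # by construction of column_map).
    col_of = {pos: col for col, pos in enumerate(alignment.column_map) if pos is not None}
    ref_row = alignment.reference_row
    observed: dict[tuple[str, str], int] = {}
    mutated: dict[tuple[str, str], int] = {}
    typed_pairs: list[tuple[tuple[str, str], int, int]] = []
    for i, j in pairs:
        pair_type = (ref_seq[i - 1], ref_seq[j - 1])
        observed[pair_type] = observed.get(pair_type, 0) + 1
        typed_pairs.append((pair_type, col_of[i], col_of[j]))
    for rid, seq in alignment.rows:
        if rid == alignment.reference_id:
            continue
        for pair_type, ci, cj in typed_pairs:
            a, b = seq[ci], seq[cj]
            if _is_gap(a) or _is_gap(b):
                continue
            if a != ref_row[ci] and b != ref_row[cj]:
                mutated[pair_type] = mutated.get(pair_type, 0) + 1
    return PairMutationTable(
        observed=observed,
        mutated=mutated,
        n_rows=alignment.n_rows - 1,  # homolog rows; the reference never mutates
        normalizer=normalizer,
    )


def conservation_frame(alignment: Alignment, **kwargs) -> pd.DataFrame:
    """Conservation scores as a (position, ref_aa, score) table."""
    scores = conservation_scores(alignment, **kwargs)
    ref_seq = alignment.reference_sequence
    return pd.DataFrame(
        [
            {"position": pos, "ref_aa": ref_seq[pos - 1], "score": score}
            for pos, score in sorted(scores.items())
        ],
        columns=["position", "ref_aa", "score"],
    )
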