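"""Degenerate-codon mutagenesis library design.

Saturation-mutagenesis libraries replace selected codons with degenerate
codons. The scheme used for the HokC transmembrane screen is SNS — first
and third base restricted to G or C, any base in the middle — which
encodes 10 of the 20 amino acids (L, P, H, Q, R, V, A, D, E, G), no stop
codons, and keeps physicochemical diversity while shrinking the library.

This module enumerates the codons of a scheme, the amino acids it can
reach, the expected variant counts for a tiled region layout, and
validates the region tiling itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, NamedTuple, Sequence

from Bio.Data import CodonTable

from .variant_calling import ReferenceProtein, Substitution

NUCLEOTIDES = frozenset("ACGT")

#: IUPAC nucleotide degeneracy codes.
IUPAC_CODES: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


class LibraryDesignError(ValueError):
    """Base class for library-design errors."""


class InvalidAlphabetError(LibraryDesignError):
    """A position alphabet contains symbols outside {A, C, G, T}."""


class LayoutError(LibraryDesignError):
    """Mutagenesis regions overlap or fall outside the reference."""


@dataclass(frozen=True)
class DegenerateCodonScheme:
    """Per-position nucleotide alphabets of a degenerate codon.

    ``table_id`` selects the NCBI genetic code (default: standard code 1).
    """

    position_alphabets: tuple[frozenset[str], frozenset[str], frozenset[str]]
    table_id: int = 1

    def __post_init__(self) -> None:
        if len(self.position_alphabets) != 3:
            raise InvalidAlphabetError("a codon scheme needs exactly 3 alphabets")
        alphabets = tuple(frozenset(a) for a in self.position_alphabets)
        for alphabet in alphabets:
            if not alphabet:
                raise InvalidAlphabetError("empty position alphabet")
            bad = alphabet - NUCLEOTIDES
            if bad:
                raise InvalidAlphabetError(f"symbols outside ACGT: {sorted(bad)}")
        object.__setattr__(self, "position_alphabets", alphabets)

    @classmethod
    def from_symbols(cls, symbols: str, table_id: int = 1) -> "DegenerateCodonScheme":
        """Build a scheme from three IUPAC symbols, e.g. ``"SNS"`` or ``"NNK"``."""
        symbols = symbols.strip().upper()
        if len(symbols) != 3:
            raise InvalidAlphabetError(f"need 3 IUPAC symbols, got {symbols!r}")
        try:
            alphabets = tuple(IUPAC_CODES[s] for s in symbols)
        except KeyError as exc:
            raise InvalidAlphabetError(f"unknown IUPAC symbol {exc.args[0]!r}") from exc
        return cls(position_alphabets=alphabets, table_id=table_id)

    @property
    def n_codons(self) -> int:
        a, b, c = self.position_alphabets
        return len(a) * len(b) * len(c)


def sns_scheme() -> DegenerateCodonScheme:
    """The SNS scheme: first/third base in {G, C}, any second base."""
    return DegenerateCodonScheme.from_symbols("SNS")


def enumerate_degenerate_codons(scheme: DegenerateCodonScheme) -> dict[str, str]:
    """Map every concrete codon of the scheme to its translation ('*' = stop)."""
    table = CodonTable.unambiguous_dna_by_id[scheme.table_id]
    out: dict[str, str] = {}
    for bases in product(*(sorted(a) for a in scheme.position_alphabets)):
        codon = "".join(bases)
        out[codon] = "*" if codon in table.stop_codons else table.forward_table[codon]
    return out


class EncodedSet(NamedTuple):
    """Amino acids reachable by a scheme; stop codons reported separately."""

    amino_acids: frozenset[str]
    stop_codons: frozenset[str]


def encoded_amino_acids(scheme: DegenerateCodonScheme) -> EncodedSet:
    """Distinct amino acids encoded by a scheme, excluding (but reporting) stops."""
    codons = enumerate_degenerate_codons(scheme)
    return EncodedSet(
        amino_acids=frozenset(aa for aa in codons.values() if aa != "*"),
        stop_codons=frozenset(c for c, aa in codons.items() if aa == "*"),
    )


class VariantCounts(NamedTuple):
    single_variants: int
    total_combinations: int


def expected_variant_counts(region_length: int, aa_per_position: int) -> VariantCounts:
    """Expected library diversity for one mutagenized region.

    A region of L residues with k amino acids per position yields L*k
    single-point variants and k**L multi-mutant combinations (e.g. a
    3-residue region at 10 aa/position: 30 singles, 1000 combinations).
    """
    if region_length < 1 or aa_per_position < 1:
        raise LibraryDesignError("region_length and aa_per_position must be >= 1")
    return VariantCounts(
        single_variants=region_length * aa_per_position,
        total_combinations=aa_per_position**region_length,
    )


@dataclass(frozen=True, order=True)
class MutagenesisRegion:
    """A contiguous mutagenized span, 1-based inclusive residue coordinates."""

    index: int
    start_pos: int
    end_pos: int

    def __post_init__(self) -> None:
        if self.start_pos < 1 or self.start_pos > self.end_pos:
            raise LayoutError(
                f"invalid region {self.index}: {self.start_pos}-{self.end_pos}"
            )

    def __len__(self) -> int:
        return self.end_pos - self.start_pos + 1

    def positions(self) -> range:
        return range(self.start_pos, self.end_pos + 1)


def region_layout(
    regions: Iterable[MutagenesisRegion | tuple[int, int, int]],
    reference_length: int | None = None,
) -> tuple[MutagenesisRegion, ...]:
    """Validate a region tiling: sorted, non-overlapping, within the reference."""
    parsed = tuple(
        r if isinstance(r, MutagenesisRegion) else MutagenesisRegion(*r)
        for r in regions
    )
    ordered = tuple(sorted(parsed, key=lambda r: r.start_pos))
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.start_pos <= prev.end_pos:
            raise LayoutError(
                f"regions {prev.index} and {nxt.index} overlap "
                f"({prev.start_pos}-{prev.end_pos} vs {nxt.start_pos}-{nxt.end_pos})"
            )
    if reference_length is not None and ordered and ordered[-1].end_pos > reference_length:
        raise LayoutError(
            f"region {ordered[-1].index} ends beyond reference length {reference_length}"
        )
    return ordered


def hokc_region_layout() -> tuple[MutagenesisRegion, ...]:
    """Default 7-region tiling of the HokC transmembrane coding region.

    Regions II and VI span residues 7-9 and 19-21; the initiator Met
    (residue 1) is left untouched.
    """
    return region_layout(
        [(1, 2, 6), (2, 7, 9), (3, 10, 12), (4, 13, 15), (5, 16, 18), (6, 19, 21), (7, 22, 24)]
    )


def expected_substitutions(
    regions: Sequence[MutagenesisRegion],
    amino_acids: Iterable[str],
    reference: ReferenceProtein,
) -> frozenset[Substitution]:
    """All single substitutions a scheme can produce over a region layout.

    Positions where the reference residue is itself in the encoded set
    yield one fewer substitution, so the count can fall below
    ``n_positions * n_amino_acids``.
    """
    aas = sorted(set(amino_acids))
    subs: set[Substitution] = set()
    for region in regions:
        if region.end_pos > len(reference):
            raise LayoutError(f"region {region.index} outside reference")
        for pos in region.positions():
            ref_aa = reference.residue(pos)
            subs.update(
                Substitution(position=pos, ref_aa=ref_aa, alt_aa=aa)
                for aa in aas
                if aa != ref_aa
            )
    return frozenset(subs)


def codon_report(scheme: DegenerateCodonScheme) -> "pd.DataFrame":
    """Tabular report of a scheme's codons and translations."""
    import pandas as pd

    codons = enumerate_degenerate_codons(scheme)
    return pd.DataFrame(
        [{"codon": c, "amino_acid": aa} for c, aa in sorted(codons.items())]
    )
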