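"""Variant calling for pooled phenotype-screening reads.

Reads from a saturation-mutagenesis screen cover the full mutagenized ORF
and are labelled by phenotype pool: *wild_type* (the toxin still kills —
no colony growth under induction) or *mutant* (growth, i.e. the toxin was
inactivated). This module translates reads, diffs them against the
reference protein and aggregates per-genotype and per-substitution counts
that feed the enrichment statistics in :mod:`memtol.phenotype_stats`.

Reads are assumed quality-trimmed upstream. Indels are not called: reads
whose length is inconsistent with the reading frame are discarded and
counted. Reads with a stop codon inside the mutagenized span are tallied
separately as nonsense variants and excluded from missense statistics.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PHENOTYPES = ("wild_type", "mutant")

_SUB_RE = re.compile(r"^([A-Z])(\d+)([A-Z*])$")


class VariantCallingError(ValueError):
    """Base class for errors raised by this module."""


class FrameError(VariantCallingError):
    """Nucleotide sequence length is not a multiple of three."""


class CoverageError(VariantCallingError):
    """Read does not cover the mutagenized span of the reference."""


@dataclass(frozen=True, order=True)
class Substitution:
    """A single amino-acid change, e.g. ``M7W`` (1-based position)."""

    position: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise VariantCallingError(f"position must be >= 1, got {self.position}")
        for aa in (self.ref_aa, self.alt_aa):
            if len(aa) != 1:
                raise VariantCallingError(f"amino acids are single letters, got {aa!r}")
        if self.ref_aa == self.alt_aa:
            raise VariantCallingError(
                f"ref and alt must differ at position {self.position}: {self.ref_aa}"
            )

    def __str__(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"

    @classmethod
    def from_string(cls, text: str) -> "Substitution":
        m = _SUB_RE.match(text.strip())
        if m is None:
            raise VariantCallingError(f"cannot parse substitution {text!r}")
        ref, pos, alt = m.groups()
        return cls(position=int(pos), ref_aa=ref, alt_aa=alt)


@dataclass(frozen=True)
class VariantGenotype:
    """A set of substitutions defining one variant (empty = wild type).

    At most one substitution per position; canonical ordering by position.
    """

    substitutions: tuple[Substitution, ...] = ()

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.substitutions, key=lambda s: s.position))
        positions = [s.position for s in ordered]
        if len(set(positions)) != len(positions):
            raise VariantCallingError(
                f"duplicate positions in genotype: {positions}"
            )
        object.__setattr__(self, "substitutions", ordered)

    @classmethod
    def of(cls, subs: Iterable[Substitution | str]) -> "VariantGenotype":
        parsed = tuple(
            s if isinstance(s, Substitution) else Substitution.from_string(s)
            for s in subs
        )
        return cls(parsed)

    @classmethod
    def from_string(cls, text: str) -> "VariantGenotype":
        text = text.strip()
        if not text or text == "WT":
            return cls()
        return cls.of(part for part in text.split(",") if part.strip())

    @property
    def is_wild_type(self) -> bool:
        return not self.substitutions

    def max_position(self) -> int:
        return max((s.position for s in self.substitutions), default=0)

    def __len__(self) -> int:
        return len(self.substitutions)

    def __iter__(self) -> Iterator[Substitution]:
        return iter(self.substitutions)

    def __contains__(self, sub: Substitution) -> bool:
        return sub in self.substitutions

    def __str__(self) -> str:
        return ",".join(str(s) for s in self.substitutions) if self.substitutions else "WT"


@dataclass(frozen=True)
class ReferenceProtein:
    """Reference protein with optional coding ORF.

    Positions are 1-based on the translated short ORF (the initiator Met
    is residue 1), matching the screen's variant labels (M7, I12, ...).
    """

    id: str
    aa_sequence: str
    orf_sequence: str | None = None

    def __post_init__(self) -> None:
        seq = self.aa_sequence.upper()
        if not seq:
            raise VariantCallingError("empty reference protein sequence")
        bad = set(seq) - set(AMINO_ACIDS)
        if bad:
            raise VariantCallingError(f"non-standard residues in reference: {bad}")
        object.__setattr__(self, "aa_sequence", seq)
        if self.orf_sequence is not None:
            orf = self.orf_sequence.upper()
            object.__setattr__(self, "orf_sequence", orf)
            translated = translate_orf(orf).protein
            if translated != seq:
                raise VariantCallingError(
                    "ORF translation does not match the protein sequence: "
                    f"{translated!r} vs {seq!r}"
                )

    def __len__(self) -> int:
        return len(self.aa_sequence)

    def residue(self, position: int) -> str:
        if not 1 <= position <= len(self.aa_sequence):
            raise VariantCallingError(f"position {position} outside reference")
        return self.aa_sequence[position - 1]

    @classmethod
    def from_fasta(cls, path: str | Path, *, is_orf: bool | None = None) -> "ReferenceProtein":
        record = next(SeqIO.parse(str(path), "fasta"))
        seq = str(record.seq).upper()
        if is_orf is None:
            is_orf = set(seq) <= set("ACGTN")
        if is_orf:
            return cls(id=record.id, aa_sequence=translate_orf(seq).protein, orf_sequence=seq)
        return cls(id=record.id, aa_sequence=seq)


@dataclass(frozen=True)
class PooledObservation:
    """A genotype observed ``count`` times in one phenotype pool."""

    genotype: VariantGenotype
    phenotype: str
    count: int

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise VariantCallingError(f"unknown phenotype {self.phenotype!r}")
        if self.count < 0:
            raise VariantCallingError("count must be non-negative")


class Translation(NamedTuple):
    """Protein sequence plus the 1-based codon index of the first stop."""

    protein: str
    stop_codon: int | None


_STANDARD = CodonTable.unambiguous_dna_by_id[1]


def translate_orf(dna: str, table_id: int = 1) -> Translation:
    """Translate an in-frame ORF, stopping at the first stop codon.

    Codons containing ``N`` translate to ``X``. The position of the first
    stop codon (1-based codon index) is reported alongside the protein.
    """
    dna = dna.strip().upper()
    if not dna:
        raise VariantCallingError("empty nucleotide sequence")
    if len(dna) % 3 != 0:
        raise FrameError(f"sequence length {len(dna)} is not a multiple of 3")
    bad = set(dna) - set("ACGTN")
    if bad:
        raise VariantCallingError(f"invalid nucleotides: {sorted(bad)}")
    table = _STANDARD if table_id == 1 else CodonTable.unambiguous_dna_by_id[table_id]
    out: list[str] = []
    for i in range(0, len(dna), 3):
        codon = dna[i : i + 3]
        if "N" in codon:
            out.append("X")
            continue
        if codon in table.stop_codons:
            return Translation("".join(out), i // 3 + 1)
        out.append(table.forward_table[codon])
    return Translation("".join(out), None)


def call_substitutions(
    aa_seq: str,
    reference: ReferenceProtein,
    *,
    required_span: int | None = None,
) -> VariantGenotype:
    """Diff an ungapped amino-acid sequence against the reference.

    The read is compared position-by-position from residue 1; residues
    past the reference length are ignored. ``X`` residues (ambiguous
    codons) never produce a call. A read shorter than ``required_span``
    (default: the full reference) raises :class:`CoverageError`.
    """
    aa_seq = aa_seq.upper()
    span = len(reference) if required_span is None else required_span
    if len(aa_seq) < span:
        raise CoverageError(
            f"read covers {len(aa_seq)} residues, {span} required"
        )
    subs = [
        Substitution(position=i + 1, ref_aa=ref_aa, alt_aa=alt)
        for i, (ref_aa, alt) in enumerate(zip(reference.aa_sequence, aa_seq))
        if alt != ref_aa and alt != "X"
    ]
    return VariantGenotype(tuple(subs))


def apply_substitutions(reference: ReferenceProtein, genotype: VariantGenotype) -> str:
    """Return the mutant amino-acid sequence for a genotype (inverse of calling)."""
    seq = list(reference.aa_sequence)
    for sub in genotype:
        if reference.residue(sub.position) != sub.ref_aa:
            raise VariantCallingError(
                f"{sub} does not match reference residue {reference.residue(sub.position)}"
            )
        seq[sub.position - 1] = sub.alt_aa
    return "".join(seq)


def filter_by_max_position(
    observations: Sequence[PooledObservation], max_pos: int
) -> tuple[list[PooledObservation], int]:
    """Drop observations with any substitution strictly beyond ``max_pos``.

    The boundary position itself is retained ("beyond" is ``>``). Returns
    the kept observations and the number removed.
    """
    if max_pos < 1:
        raise VariantCallingError("max_pos must be >= 1")
    kept = [o for o in observations if o.genotype.max_position() <= max_pos]
    return kept, len(observations) - len(kept)


class Counts(NamedTuple):
    wt: int
    mut: int


@dataclass
class CountTables:
    """Per-genotype and per-substitution pooled counts."""

    genotype_counts: dict[VariantGenotype, Counts]
    substitution_counts: dict[Substitution, Counts]

    def genotype_frame(self) -> pd.DataFrame:
        rows = [
            {"genotype": str(g), "n_subs": len(g), "wt_count": c.wt, "mut_count": c.mut}
            for g, c in sorted(self.genotype_counts.items(), key=lambda kv: str(kv[0]))
        ]
        return pd.DataFrame(rows, columns=["genotype", "n_subs", "wt_count", "mut_count"])

    def substitution_frame(self) -> pd.DataFrame:
        rows = [
            {
                "position": s.position,
                "ref": s.ref_aa,
                "alt": s.alt_aa,
                "wt_count": c.wt,
                "mut_count": c.mut,
            }
            for s, c in sorted(self.substitution_counts.items())
        ]
        return pd.DataFrame(rows, columns=["position", "ref", "alt", "wt_count", "mut_count"])

    @classmethod
    def from_genotype_counts(
        cls, genotype_counts: Mapping[VariantGenotype, Counts]
    ) -> "CountTables":
        sub_wt: Counter = Counter()
        sub_mut: Counter = Counter()
        for genotype, counts in genotype_counts.items():
            for sub in genotype:
                sub_wt[sub] += counts.wt
                sub_mut[sub] += counts.mut
        subs = {s: Counts(sub_wt[s], sub_mut[s]) for s in set(sub_wt) | set(sub_mut)}
        return cls(genotype_counts=dict(genotype_counts), substitution_counts=subs)

    def single_variant_counts(self) -> dict["Substitution", Counts]:
        """Counts of genotypes carrying exactly one substitution.

        Unlike :attr:`substitution_counts` (which aggregates every
        genotype containing a substitution), these are the counts of the
        single-mutant variant itself — the unit on which deleterious
        calls are made, so that a mutation compensated inside a
        multi-mutant does not mask its own single-mutant phenotype.
        """
        return {
            genotype.substitutions[0]: counts
            for genotype, counts in self.genotype_counts.items()
            if len(genotype) == 1
        }


def tally_counts(observations: Iterable[PooledObservation]) -> CountTables:
    """Aggregate pooled observations into genotype- and substitution-level counts.

    A substitution's counts sum the counts of every genotype containing it,
    so phenotype totals are conserved at the genotype level but a read with
    two substitutions contributes to two substitution rows.
    """
    wt: Counter = Counter()
    mut: Counter = Counter()
    for obs in observations:
        if obs.phenotype == "wild_type":
            wt[obs.genotype] += obs.count
        else:
            mut[obs.genotype] += obs.count
    genotype_counts = {
        g: Counts(wt[g], mut[g]) for g in set(wt) | set(mut)
    }
    return CountTables.from_genotype_counts(genotype_counts)


@dataclass
class PoolCallResult:
    """Outcome of calling two read pools against a reference."""

    tables: CountTables
    observations: list[PooledObservation]
    n_reads: dict[str, int] = field(default_factory=dict)
    n_frame_errors: int = 0
    n_nonsense: int = 0
    n_beyond_max_pos: int = 0


def _iter_sequences(source: str | Path | Iterable[str]) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        path = Path(source)
        fmt = "fastq" if path.suffix.lower() in {".fq", ".fastq"} else "fasta"
        for record in SeqIO.parse(str(path), fmt):
            yield str(record.seq)
    else:
        yield from source


def call_read_pools(
    wt_pool: str | Path | Iterable[str],
    mut_pool: str | Path | Iterable[str],
    reference: ReferenceProtein,
    *,
    max_pos: int | None = None,
    required_span: int | None = None,
) -> PoolCallResult:
    """Translate and call two phenotype-labelled read pools.

    ``wt_pool``/``mut_pool`` are FASTA/FASTQ paths or iterables of DNA
    strings. Frame-broken reads are discarded and counted; reads with a
    stop codon inside the mutagenized span (positions 1..``max_pos`` or the
    full reference) are counted as nonsense and excluded; genotypes with
    substitutions beyond ``max_pos`` are removed.
    """
    span = max_pos if max_pos is not None else len(reference)
    span = min(span, len(reference))
    if required_span is None:
        required_span = span
    counter: Counter = Counter()
    n_reads = {"wild_type": 0, "mutant": 0}
    n_frame = 0
    n_nonsense = 0
    for phenotype, pool in (("wild_type", wt_pool), ("mutant", mut_pool)):
        for dna in _iter_sequences(pool):
            n_reads[phenotype] += 1
            try:
                translation = translate_orf(dna)
            except FrameError:
                n_frame += 1
                continue
            if translation.stop_codon is not None and translation.stop_codon <= span:
                n_nonsense += 1
                continue
            try:
                genotype = call_substitutions(
                    translation.protein, reference, required_span=required_span
                )
            except CoverageError:
                n_frame += 1
                continue
            counter[(genotype, phenotype)] += 1
    observations = [
        PooledObservation(genotype=g, phenotype=p, count=c)
        for (g, p), c in counter.items()
    ]
    if max_pos is not None:
        observations, n_beyond = filter_by_max_position(observations, max_pos)
    else:
        n_beyond = 0
    return PoolCallResult(
        tables=tally_counts(observations),
        observations=observations,
        n_reads=n_reads,
        n_frame_errors=n_frame,
        n_nonsense=n_nonsense,
        n_beyond_max_pos=n_beyond,
    )
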