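"""Enrichment statistics for pooled phenotype screens.

For each variant i observed WT_i times in the wild-type-phenotype pool
(toxin active: no growth under induction) and MUT_i times in the
mutant-phenotype pool (growth), the enrichment statistic is

    F(mut_i) = 100 * (WT_i - MUT_i) / (WT_i + MUT_i)

so F is +100 for a variant seen only with the wild-type phenotype and
-100 for one seen only with the mutant phenotype. Variants whose |F| lies
within the experimental-error band (default 4%) are flagged as ISPAs
(incorrect sequence-phenotype assignments) and excluded from
classification. F above the band means the variant still kills, i.e. the
mutation is *tolerated*; F below the negative band means loss of toxin
function, i.e. *deleterious*.

The module also derives per-position tolerance summaries (a position is
*critical* when intolerant substitutions outnumber tolerant ones),
detects compensatory multi-mutants (genotypes with a wild-type phenotype
that contain an individually deleterious substitution), and computes the
screen-level summary percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import pandas as pd

from .variant_calling import Counts, CountTables, Substitution, VariantGenotype

CLASSIFICATIONS = ("ispa", "tolerated", "deleterious")

DEFAULT_ERROR_RATE = 4.0  # percent; the screen's experimental-error band


class PhenotypeStatsError(ValueError):
    """Base class for statistic errors."""


class UndefinedStatisticError(PhenotypeStatsError):
    """F is undefined when a variant was observed in neither pool."""


def f_statistic(wt_count: int, mut_count: int) -> float:
    """Pooled-count enrichment F = 100*(WT - MUT)/(WT + MUT), in [-100, 100]."""
    if wt_count < 0 or mut_count < 0:
        raise PhenotypeStatsError("counts must be non-negative")
    total = wt_count + mut_count
    if total == 0:
        raise UndefinedStatisticError("F undefined for zero total count")
    return 100.0 * (wt_count - mut_count) / total


def classify_mutation(f_value: float, error_rate: float = DEFAULT_ERROR_RATE) -> str:
    """Classify an F value against the experimental-error band.

    |F| <= error_rate -> ``ispa``; F > error_rate -> ``tolerated``
    (enriched in the wild-type-phenotype pool, toxin still active);
    F < -error_rate -> ``deleterious``.
    """
    if error_rate < 0:
        raise PhenotypeStatsError("error_rate must be >= 0")
    if abs(f_value) <= error_rate:
        return "ispa"
    return "tolerated" if f_value > 0 else "deleterious"


@dataclass(frozen=True)
class MutationStat:
    """Counts, F value and classification for one substitution or genotype."""

    key: Hashable
    wt_count: int
    mut_count: int
    f_value: float
    classification: str


def score_counts(
    counts: Mapping[Hashable, Counts],
    *,
    error_rate: float = DEFAULT_ERROR_RATE,
    min_total: int = 1,
) -> dict[Hashable, MutationStat]:
    """Compute F and classification for every key with total count >= min_total."""
    if min_total < 1:
        raise PhenotypeStatsError("min_total must be >= 1")
    stats: dict[Hashable, MutationStat] = {}
    for key, (wt, mut) in counts.items():
        if wt + mut < min_total:
            continue
        f = f_statistic(wt, mut)
        stats[key] = MutationStat(
            key=key,
            wt_count=wt,
            mut_count=mut,
            f_value=f,
            classification=classify_mutation(f, error_rate),
        )
    return stats


@dataclass(frozen=True)
class PositionSummary:
    """Tolerant/intolerant substitution counts at one reference position."""

    position: int
    tolerant_count: int
    intolerant_count: int

    @property
    def critical(self) -> bool:
        """True when intolerant substitutions strictly outnumber tolerant ones."""
        return self.intolerant_count > self.tolerant_count


def position_summaries(
    substitution_stats: Mapping[Substitution, MutationStat] | Iterable[MutationStat],
) -> list[PositionSummary]:
    """Per-position tolerance summary over classified substitution statistics.

    ISPAs contribute to neither count. Positions are those carrying at
    least one classified (non-ISPA) substitution.
    """
    if isinstance(substitution_stats, Mapping):
        stats = list(substitution_stats.values())
    else:
        stats = list(substitution_stats)
    tolerant: dict[int, int] = {}
    intolerant: dict[int, int] = {}
    for stat in stats:
        sub = stat.key
        if not isinstance(sub, Substitution):
            raise PhenotypeStatsError("position summaries need substitution-level stats")
        if stat.classification == "tolerated":
            tolerant[sub.position] = tolerant.get(sub.position, 0) + 1
            intolerant.setdefault(sub.position, 0)
        elif stat.classification == "deleterious":
            intolerant[sub.position] = intolerant.get(sub.position, 0) + 1
            tolerant.setdefault(sub.position, 0)
    return [
        PositionSummary(
            position=pos,
            tolerant_count=tolerant.get(pos, 0),
            intolerant_count=intolerant.get(pos, 0),
        )
        for pos in sorted(set(tolerant) | set(intolerant))
    ]


def deleterious_singles(
    substitution_stats: Mapping[Substitution, MutationStat],
) -> frozenset[Substitution]:
    """The substitutions classified deleterious at the single-substitution level."""
    return frozenset(
        s for s, stat in substitution_stats.items() if stat.classification == "deleterious"
    )


@dataclass(frozen=True)
class CompensatoryRecord:
    """A multi-mutant with wild-type phenotype carrying a deleterious single."""

    genotype: VariantGenotype
    contained_deleterious: frozenset[Substitution]
    wt_count: int


def find_compensatory(
    genotype_stats: Mapping[VariantGenotype, MutationStat],
    deleterious: Iterable[Substitution],
    *,
    min_count: int = 0,
) -> list[CompensatoryRecord]:
    """Detect compensatory mutations.

    A compensatory record is a genotype with >= 2 substitutions that is
    classified *tolerated* (wild-type phenotype) although it contains at
    least one substitution that is individually deleterious. ``min_count``
    keeps only records seen at least that many times in the wild-type
    pool (a threshold of >100 was used for the screen's headline table).
    Sorted by wild-type count, descending.
    """
    deleterious_set = frozenset(deleterious)
    records: list[CompensatoryRecord] = []
    for genotype, stat in genotype_stats.items():
        if len(genotype) < 2 or stat.classification != "tolerated":
            continue
        contained = frozenset(s for s in genotype if s in deleterious_set)
        if not contained or stat.wt_count < min_count:
            continue
        records.append(
            CompensatoryRecord(
                genotype=genotype,
                contained_deleterious=contained,
                wt_count=stat.wt_count,
            )
        )
    records.sort(key=lambda r: (-r.wt_count, str(r.genotype)))
    return records


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ScreenReport:
    """Screen-level summary: detection and tolerance percentages.

    The deleterious percentage is reported against both denominators
    (detected and expected variants); with the screen's published counts
    both round to the same integer.
    """

    n_expected: int
    n_detected: int
    n_deleterious: int
    pct_detected: float
    pct_tolerated: float
    pct_deleterious_of_detected: float
    pct_deleterious_of_expected: float

    @property
    def rounded(self) -> dict[str, int]:
        """Half-up integer rounding for reporting (e.g. 97.08 -> 97)."""
        return {
            "pct_detected": _round_half_up(self.pct_detected),
            "pct_tolerated": _round_half_up(self.pct_tolerated),
            "pct_deleterious_of_detected": _round_half_up(self.pct_deleterious_of_detected),
            "pct_deleterious_of_expected": _round_half_up(self.pct_deleterious_of_expected),
        }


def summarize_screen(n_expected: int, n_detected: int, n_deleterious: int) -> ScreenReport:
    """Summary percentages of a saturation screen.

    pct_detected = 100*n_detected/n_expected and
    pct_tolerated = 100*(n_detected - n_deleterious)/n_detected.
    """
    if n_expected <= 0:
        raise PhenotypeStatsError("n_expected must be positive")
    if n_detected < 0 or n_deleterious < 0 or n_deleterious > n_detected:
        raise PhenotypeStatsError("need 0 <= n_deleterious <= n_detected")
    pct_detected = 100.0 * n_detected / n_expected
    pct_tolerated = (
        100.0 * (n_detected - n_deleterious) / n_detected if n_detected else float("nan")
    )
    return ScreenReport(
        n_expected=n_expected,
        n_detected=n_detected,
        n_deleterious=n_deleterious,
        pct_detected=pct_detected,
        pct_tolerated=pct_tolerated,
        pct_deleterious_of_detected=(
            100.0 * n_deleterious / n_detected if n_detected else float("nan")
        ),
        pct_deleterious_of_expected=100.0 * n_deleterious / n_expected,
    )


@dataclass
class ScreenAnalysis:
    """Full two-tier analysis of a screen's count tables."""

    substitution_stats: dict[Substitution, MutationStat]
    genotype_stats: dict[VariantGenotype, MutationStat]
    position_summaries: list[PositionSummary] = field(default_factory=list)
    deleterious_singles: frozenset[Substitution] = frozenset()
    compensatory: list[CompensatoryRecord] = field(default_factory=list)

    def substitution_frame(self) -> pd.DataFrame:
        rows = [
            {
                "position": s.position,
                "ref": s.ref_aa,
                "alt": s.alt_aa,
                "wt_count": st.wt_count,
                "mut_count": st.mut_count,
                "f_value": st.f_value,
                "classification": st.classification,
            }
            for s, st in sorted(self.substitution_stats.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["position", "ref", "alt", "wt_count", "mut_count", "f_value", "classification"],
        )

    def position_frame(self) -> pd.DataFrame:
        rows = [
            {
                "position": p.position,
                "tolerant_count": p.tolerant_count,
                "intolerant_count": p.intolerant_count,
                "critical": p.critical,
            }
            for p in self.position_summaries
        ]
        return pd.DataFrame(
            rows, columns=["position", "tolerant_count", "intolerant_count", "critical"]
        )

    def compensatory_frame(self) -> pd.DataFrame:
        rows = [
            {
                "genotype": str(r.genotype),
                "contained_deleterious": ",".join(str(s) for s in sorted(r.contained_deleterious)),
                "wt_count": r.wt_count,
            }
            for r in self.compensatory
        ]
        return pd.DataFrame(rows, columns=["genotype", "contained_deleterious", "wt_count"])


def analyze_screen(
    tables: CountTables,
    *,
    error_rate: float = DEFAULT_ERROR_RATE,
    min_total: int = 1,
    min_compensatory_count: int = 0,
) -> ScreenAnalysis:
    """Run the two-tier screen analysis on tallied counts.

    Single-mutant variant statistics drive the deleterious calls and the
    per-position tolerance summary (a compensated multi-mutant must not
    mask its member's own single-mutant phenotype); genotype-level
    statistics drive compensatory detection.
    """
    sub_stats = score_counts(
        tables.single_variant_counts(), error_rate=error_rate, min_total=min_total
    )
    geno_stats = score_counts(
        tables.genotype_counts, error_rate=error_rate, min_total=min_total
    )
    deleterious = deleterious_singles(sub_stats)
    return ScreenAnalysis(
        substitution_stats=sub_stats,
        genotype_stats=geno_stats,
        position_summaries=position_summaries(sub_stats),
        deleterious_singles=deleterious,
        compensatory=find_compensatory(
            geno_stats, deleterious, min_count=min_compensatory_count
        ),
    )
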