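"""Allele counts/frequencies and within-locus genotype-pair tables.

Allele copies are counted per subject, twice for homozygotes, so the
denominator at a locus is always two times the number of subjects typed
there.  Genotype pairs are unordered; a pair key is the lexicographically
sorted allele tuple and homozygous pairs are keyed ``(x, x)``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .cohort import Cohort, CohortError, GenotypeRecord, is_carrier, subjects_typed_at
from .nomenclature import AlleleName, parse_allele_name, truncate_resolution

__all__ = [
    "AlleleCountTable",
    "GenotypePairTable",
    "count_alleles",
    "genotype_pair_frequencies",
    "carrier_flags",
    "collapse_count_table",
    "pair_table_margins",
]

PairKey = tuple[AlleleName, AlleleName]


@dataclass(frozen=True)
class AlleleCountTable:
    """Allele copy counts at one locus and resolution."""

    locus: str
    resolution: int
    counts: Mapping[AlleleName, int]
    denominator: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.denominator:
            raise ValueError(
                f"allele counts sum to {sum(self.counts.values())}, expected "
                f"denominator {self.denominator}"
            )
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative allele count")

    @property
    def frequencies(self) -> dict[AlleleName, float]:
        return {a: c / self.denominator for a, c in self.counts.items()}

    def frequency(self, allele: AlleleName) -> float:
        return self.counts.get(allele, 0) / self.denominator

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "allele": str(a),
                "count": c,
                "denominator": self.denominator,
                "frequency_pct": round(100.0 * c / self.denominator, 2),
            }
            for a, c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["allele", "count", "denominator", "frequency_pct"])


@dataclass(frozen=True)
class GenotypePairTable:
    """Unordered within-locus allele-pair counts over subjects."""

    locus: str
    resolution: int
    pair_counts: Mapping[PairKey, int]
    n_subjects: int

    def __post_init__(self) -> None:
        if sum(self.pair_counts.values()) != self.n_subjects:
            raise ValueError(
                f"pair counts sum to {sum(self.pair_counts.values())}, expected "
                f"{self.n_subjects} subjects"
            )
        for a, b in self.pair_counts:
            if (a, b) != tuple(sorted((a, b))):
                raise ValueError(f"pair key ({a}, {b}) not in sorted order")

    @property
    def pair_freqs(self) -> dict[PairKey, float]:
        return {p: c / self.n_subjects for p, c in self.pair_counts.items()}

    def frequency(self, pair: PairKey) -> float:
        key = tuple(sorted(pair))
        return self.pair_counts.get(key, 0) / self.n_subjects

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "pair": f"{a}-{b}",
                "count": c,
                "n_subjects": self.n_subjects,
                "frequency_pct": round(100.0 * c / self.n_subjects, 2),
            }
            for (a, b), c in sorted(self.pair_counts.items())
        ]
        return pd.DataFrame(rows, columns=["pair", "count", "n_subjects", "frequency_pct"])


def _truncated_pair(record: GenotypeRecord, locus: str, resolution: int) -> PairKey:
    a, b = record.pair(locus)  # caller guarantees typed
    ta = truncate_resolution(a, resolution) if a.resolution > resolution else a
    tb = truncate_resolution(b, resolution) if b.resolution > resolution else b
    if ta.resolution != resolution or tb.resolution != resolution:
        raise CohortError(
            f"subject {record.subject_id!r} typed at resolution "
            f"{min(a.resolution, b.resolution)} at {locus}; cannot report at "
            f"{resolution}"
        )
    return tuple(sorted((ta, tb)))


def count_alleles(cohort: Cohort, locus: str, resolution: int) -> AlleleCountTable:
    """Allele copy counts for *locus* at *resolution* (homozygotes count twice)."""
    typed = subjects_typed_at(cohort, locus)
    if not typed:
        raise CohortError(f"no subject typed at locus {locus}")
    counts: Counter[AlleleName] = Counter()
    for record, _ in typed:
        a, b = _truncated_pair(record, locus, resolution)
        counts[a] += 1
        counts[b] += 1
    return AlleleCountTable(
        locus=locus,
        resolution=resolution,
        counts=dict(counts),
        denominator=2 * len(typed),
    )


def genotype_pair_frequencies(cohort: Cohort, locus: str, resolution: int) -> GenotypePairTable:
    """Unordered genotype-pair counts for *locus*; one pair per typed subject."""
    typed = subjects_typed_at(cohort, locus)
    if not typed:
        raise CohortError(f"no subject typed at locus {locus}")
    pairs: Counter[PairKey] = Counter()
    for record, _ in typed:
        pairs[_truncated_pair(record, locus, resolution)] += 1
    return GenotypePairTable(
        locus=locus,
        resolution=resolution,
        pair_counts=dict(pairs),
        n_subjects=len(typed),
    )


def carrier_flags(cohort: Cohort, allele: AlleleName | str) -> dict[str, bool]:
    """subject_id -> carries at least one copy truncating to *allele*."""
    if isinstance(allele, str):
        allele = parse_allele_name(allele)
    return {record.subject_id: is_carrier(record, allele) for record, _ in cohort}


def collapse_count_table(table: AlleleCountTable, resolution: int) -> AlleleCountTable:
    """Sum a count table down to a coarser resolution."""
    if resolution > table.resolution:
        raise ValueError("cannot collapse to a finer resolution")
    counts: Counter[AlleleName] = Counter()
    for allele, c in table.counts.items():
        counts[truncate_resolution(allele, resolution)] += c
    return AlleleCountTable(
        locus=table.locus,
        resolution=resolution,
        counts=dict(counts),
        denominator=table.denominator,
    )


def pair_table_margins(pairs: GenotypePairTable) -> AlleleCountTable:
    """Allele counts obtained by marginalising a genotype-pair table."""
    counts: Counter[AlleleName] = Counter()
    for (a, b), c in pairs.pair_counts.items():
        counts[a] += c
        counts[b] += c
    return AlleleCountTable(
        locus=pairs.locus,
        resolution=pairs.resolution,
        counts=dict(counts),
        denominator=2 * pairs.n_subjects,
    )
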