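"""Cohort genotype tables, subject metadata and reference frequency panels.

The canonical cohort file is a delimited table (TSV by default) with one row
per subject: a subject identifier, two allele columns per locus
(``A_1, A_2, ..., DQB1_1, DQB1_2``) and the clinical metadata columns.  A
locus left blank in both of its columns means the subject was not typed
there and is excluded from that locus' denominator only.

Reference frequency panels hold per-locus allele -> population-frequency
mappings together with the total number of typed allele copies (twice the
number of typed individuals), at a single resolution per panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping

import pandas as pd

from .nomenclature import LOCI, AlleleName, parse_allele_name, truncate_resolution

__all__ = [
    "SubjectMeta",
    "GenotypeRecord",
    "Cohort",
    "LocusPanel",
    "FrequencyPanel",
    "CohortError",
    "read_cohort",
    "write_cohort",
    "read_frequency_panel",
    "write_frequency_panel",
    "select_subgroup",
    "is_carrier",
    "COHORT_COLUMNS",
]

SEXES = ("F", "M")
ONSET_CLASSES = ("MGj", "EOMG", "LOMG")
MGFA_CLASSES = ("I", "IIA", "IIB", "IIIA", "IIIB", "IVA", "IVB", "V")
SEROTYPES = ("RAchPos", "MuSKPos", "dSNMG")
THYMIC_STATUSES = ("normal_ct", "thymoma", "follicular_hyperplasia")
TITIN_RYR = ("none", "titin_only", "titin_and_ryr")

#: Age (years) below which onset is juvenile and at/above which it is late.
JUVENILE_ONSET_AGE = 18
LATE_ONSET_AGE = 50

COHORT_COLUMNS = (
    ["subject_id"]
    + [f"{locus}_{i}" for locus in LOCI for i in (1, 2)]
    + [
        "sex",
        "age_at_onset",
        "onset_class",
        "mgfa_max",
        "serotype",
        "thymic_status",
        "autoimmune",
        "titin_ryr",
    ]
)


class CohortError(ValueError):
    """Raised for malformed cohort or panel inputs."""


@dataclass(frozen=True)
class SubjectMeta:
    """Clinical metadata for one subject."""

    subject_id: str
    sex: str
    age_at_onset: float
    onset_class: str
    mgfa_max: str
    serotype: str
    thymic_status: str
    autoimmune_comorbidity: bool
    titin_ryr: str = "none"

    def __post_init__(self) -> None:
        for attr, allowed in (
            ("sex", SEXES),
            ("onset_class", ONSET_CLASSES),
            ("mgfa_max", MGFA_CLASSES),
            ("serotype", SEROTYPES),
            ("thymic_status", THYMIC_STATUSES),
            ("titin_ryr", TITIN_RYR),
        ):
            value = getattr(self, attr)
            if value not in allowed:
                raise CohortError(
                    f"subject {self.subject_id!r}: {attr}={value!r} not in {allowed}"
                )
        if self.age_at_onset < 0:
            raise CohortError(f"subject {self.subject_id!r}: negative age at onset")
        self._check_onset_consistency()

    def _check_onset_consistency(self) -> None:
        age, cls = self.age_at_onset, self.onset_class
        if cls == "MGj" and age >= JUVENILE_ONSET_AGE:
            raise CohortError(
                f"subject {self.subject_id!r}: juvenile onset requires age < "
                f"{JUVENILE_ONSET_AGE}, got {age}"
            )
        if cls == "EOMG" and not (JUVENILE_ONSET_AGE <= age < LATE_ONSET_AGE):
            raise CohortError(
                f"subject {self.subject_id!r}: early onset requires "
                f"{JUVENILE_ONSET_AGE} <= age < {LATE_ONSET_AGE}, got {age}"
            )
        if cls == "LOMG" and age < LATE_ONSET_AGE:
            raise CohortError(
                f"subject {self.subject_id!r}: late onset requires age >= "
                f"{LATE_ONSET_AGE}, got {age}"
            )


@dataclass(frozen=True)
class GenotypeRecord:
    """A subject's unordered allele pair per typed locus."""

    subject_id: str
    genotype: Mapping[str, tuple[AlleleName, AlleleName]]

    def __post_init__(self) -> None:
        for locus, pair in self.genotype.items():
            if locus not in LOCI:
                raise CohortError(f"subject {self.subject_id!r}: unknown locus {locus!r}")
            a, b = pair
            if a.locus != locus or b.locus != locus:
                raise CohortError(
                    f"subject {self.subject_id!r}: alleles {a}/{b} do not belong to "
                    f"locus {locus}"
                )

    def pair(self, locus: str) -> tuple[AlleleName, AlleleName] | None:
        return self.genotype.get(locus)


#: A cohort is an ordered list of (genotype record, metadata) pairs.
Cohort = list[tuple[GenotypeRecord, SubjectMeta]]


@dataclass(frozen=True)
class LocusPanel:
    """Reference frequencies for one locus of a panel."""

    total_allele_count: int
    frequencies: Mapping[AlleleName, float]

    def __post_init__(self) -> None:
        if self.total_allele_count <= 0:
            raise CohortError("panel total allele count must be positive")
        for allele, freq in self.frequencies.items():
            if not 0.0 <= freq <= 1.0:
                raise CohortError(f"panel frequency for {allele} outside [0,1]: {freq}")
        total = sum(self.frequencies.values())
        if total > 1.0 + 0.02:
            raise CohortError(f"panel frequencies sum to {total:.4f} > 1.02")


@dataclass(frozen=True)
class FrequencyPanel:
    """A reference-population frequency panel at a single resolution."""

    name: str
    resolution: int
    loci: Mapping[str, LocusPanel]

    def __post_init__(self) -> None:
        if self.resolution not in (1, 2):
            raise CohortError(f"panel resolution must be 1 or 2, got {self.resolution}")
        for locus, lp in self.loci.items():
            if locus not in LOCI:
                raise CohortError(f"panel references unknown locus {locus!r}")
            for allele in lp.frequencies:
                if allele.resolution != self.resolution:
                    raise CohortError(
                        f"panel {self.name!r} at resolution {self.resolution} contains "
                        f"allele {allele} at resolution {allele.resolution}"
                    )

    def frequency(self, allele: AlleleName) -> float:
        """Panel frequency for *allele*, 0.0 when the allele is not listed."""
        lp = self.loci.get(allele.locus)
        if lp is None:
            raise KeyError(f"panel {self.name!r} does not cover locus {allele.locus}")
        return lp.frequencies.get(allele, 0.0)


def _is_blank(value: object) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or (
        isinstance(value, str) and not value.strip()
    )


def read_cohort(path: str | Path, delimiter: str = "\t") -> Cohort:
    """Read a cohort genotype/metadata table.

    Blank allele cell pairs mark an untyped locus; a half-typed locus (one
    of the two cells blank) is rejected, as are duplicate subject ids and
    unparseable allele names (reported with row and column).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    if df.empty:
        raise CohortError(f"{path}: empty cohort file")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"{path}: missing columns {missing}")

    cohort: Cohort = []
    seen: set[str] = set()
    for row_idx, row in df.iterrows():
        sid = row["subject_id"].strip()
        if not sid:
            raise CohortError(f"{path}: blank subject_id in row {row_idx}")
        if sid in seen:
            raise CohortError(f"{path}: duplicate subject_id {sid!r}")
        seen.add(sid)

        genotype: dict[str, tuple[AlleleName, AlleleName]] = {}
        for locus in LOCI:
            cells = [row[f"{locus}_{i}"] for i in (1, 2)]
            blanks = [_is_blank(c) for c in cells]
            if all(blanks):
                continue
            if any(blanks):
                raise CohortError(
                    f"{path}: subject {sid!r} half-typed at locus {locus} "
                    f"(row {row_idx})"
                )
            alleles = []
            for i, cell in enumerate(cells, start=1):
                try:
                    allele = parse_allele_name(cell)
                except ValueError as exc:
                    raise CohortError(
                        f"{path}: row {row_idx}, column {locus}_{i}: {exc}"
                    ) from exc
                if allele.locus != locus:
                    raise CohortError(
                        f"{path}: row {row_idx}, column {locus}_{i}: allele {allele} "
                        f"does not belong to locus {locus}"
                    )
                # Analyses use at most two fields; collapse deeper typings.
                if allele.resolution > 2:
                    allele = truncate_resolution(allele, 2)
                alleles.append(allele)
            genotype[locus] = (alleles[0], alleles[1])

        meta = SubjectMeta(
            subject_id=sid,
            sex=row["sex"].strip(),
            age_at_onset=float(row["age_at_onset"]),
            onset_class=row["onset_class"].strip(),
            mgfa_max=row["mgfa_max"].strip(),
            serotype=row["serotype"].strip(),
            thymic_status=row["thymic_status"].strip(),
            autoimmune_comorbidity=_parse_bool(row["autoimmune"], path, sid),
            titin_ryr=row["titin_ryr"].strip(),
        )
        cohort.append((GenotypeRecord(subject_id=sid, genotype=genotype), meta))
    return cohort


def _parse_bool(value: str, path: Path, sid: str) -> bool:
    v = value.strip().lower()
    if v in ("1", "true", "yes"):
        return True
    if v in ("0", "false", "no"):
        return False
    raise CohortError(f"{path}: subject {sid!r}: cannot parse boolean {value!r}")


def write_cohort(cohort: Cohort, path: str | Path, delimiter: str = "\t") -> None:
    """Write *cohort* in the canonical column layout (inverse of read_cohort)."""
    rows = []
    for record, meta in cohort:
        row: dict[str, object] = {"subject_id": meta.subject_id}
        for locus in LOCI:
            pair = record.pair(locus)
            row[f"{locus}_1"] = str(pair[0]) if pair else ""
            row[f"{locus}_2"] = str(pair[1]) if pair else ""
        age = meta.age_at_onset
        row.update(
            sex=meta.sex,
            age_at_onset=int(age) if float(age).is_integer() else age,
            onset_class=meta.onset_class,
            mgfa_max=meta.mgfa_max,
            serotype=meta.serotype,
            thymic_status=meta.thymic_status,
            autoimmune=int(meta.autoimmune_comorbidity),
            titin_ryr=meta.titin_ryr,
        )
        rows.append(row)
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    df.to_csv(path, sep=delimiter, index=False)


def read_frequency_panel(path: str | Path, resolution: int, name: str | None = None) -> FrequencyPanel:
    """Read a reference frequency panel.

    Expected columns: ``locus, allele, frequency, frequency_unit, n, n_unit``
    where ``frequency_unit`` is ``fraction`` or ``percent`` and ``n_unit`` is
    ``individuals`` (doubled to allele copies) or ``alleles``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["locus", "allele", "frequency", "frequency_unit", "n", "n_unit"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortError(f"{path}: missing panel columns {missing}")

    per_locus: dict[str, dict[AlleleName, float]] = {}
    totals: dict[str, int] = {}
    for row_idx, row in df.iterrows():
        locus = row["locus"].strip()
        allele = parse_allele_name(row["allele"])
        if allele.locus != locus:
            raise CohortError(
                f"{path}: row {row_idx}: allele {allele} does not match locus column "
                f"{locus!r}"
            )
        raw = float(row["frequency"])
        unit = row["frequency_unit"].strip().lower()
        if unit == "percent":
            freq = raw / 100.0
        elif unit == "fraction":
            if raw > 1.0:
                raise CohortError(
                    f"{path}: row {row_idx}: frequency {raw} > 1 declared as fraction"
                )
            freq = raw
        else:
            raise CohortError(f"{path}: row {row_idx}: unknown frequency_unit {unit!r}")
        if not 0.0 <= freq <= 1.0:
            raise CohortError(f"{path}: row {row_idx}: frequency {freq} outside [0,1]")

        n = int(row["n"])
        n_unit = row["n_unit"].strip().lower()
        if n_unit == "individuals":
            total = 2 * n
        elif n_unit == "alleles":
            total = n
        else:
            raise CohortError(f"{path}: row {row_idx}: unknown n_unit {n_unit!r}")

        if allele.resolution != resolution:
            raise CohortError(
                f"{path}: row {row_idx}: allele {allele} at resolution "
                f"{allele.resolution}, panel declared at {resolution}"
            )
        if locus in totals and totals[locus] != total:
            raise CohortError(
                f"{path}: inconsistent allele totals for locus {locus}: "
                f"{totals[locus]} vs {total}"
            )
        totals[locus] = total
        per_locus.setdefault(locus, {})[allele] = freq

    loci = {
        locus: LocusPanel(total_allele_count=totals[locus], frequencies=freqs)
        for locus, freqs in per_locus.items()
    }
    return FrequencyPanel(name=name or path.stem, resolution=resolution, loci=loci)


def write_frequency_panel(panel: FrequencyPanel, path: str | Path) -> None:
    rows = []
    for locus in LOCI:
        lp = panel.loci.get(locus)
        if lp is None:
            continue
        for allele in sorted(lp.frequencies):
            rows.append(
                {
                    "locus": locus,
                    "allele": str(allele),
                    "frequency": repr(lp.frequencies[allele]),
                    "frequency_unit": "fraction",
                    "n": lp.total_allele_count,
                    "n_unit": "alleles",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def is_carrier(record: GenotypeRecord, allele: AlleleName) -> bool:
    """True iff either pair member at the allele's locus truncates to *allele*."""
    pair = record.pair(allele.locus)
    if pair is None:
        return False
    for member in pair:
        if member.resolution >= allele.resolution:
            if truncate_resolution(member, allele.resolution) == allele:
                return True
    return False


PredicateSpec = Callable[[SubjectMeta], bool] | Mapping[str, object]


def select_subgroup(cohort: Cohort, predicate: PredicateSpec) -> Cohort:
    """Filter *cohort* by a metadata predicate, preserving records unchanged.

    ``predicate`` is either a callable over :class:`SubjectMeta` or a mapping
    of field name -> required value; the pseudo-fields ``carrier`` and
    ``non_carrier`` select on carriage of a named allele.
    """
    if callable(predicate):
        return [(r, m) for r, m in cohort if predicate(m)]

    tests: list[Callable[[GenotypeRecord, SubjectMeta], bool]] = []
    for key, wanted in predicate.items():
        if key in ("carrier", "non_carrier"):
            allele = wanted if isinstance(wanted, AlleleName) else parse_allele_name(str(wanted))
            flag = key == "carrier"
            tests.append(lambda r, m, a=allele, f=flag: is_carrier(r, a) == f)
        elif key == "autoimmune":
            tests.append(lambda r, m, w=bool(wanted): m.autoimmune_comorbidity == w)
        else:
            if not hasattr(SubjectMeta, "__dataclass_fields__") or key not in SubjectMeta.__dataclass_fields__:
                raise CohortError(f"unknown metadata field {key!r} in subgroup predicate")
            tests.append(lambda r, m, k=key, w=wanted: getattr(m, k) == w)

    return [(r, m) for r, m in cohort if all(t(r, m) for t in tests)]


def subjects_typed_at(cohort: Cohort, locus: str) -> Cohort:
    """Members of *cohort* typed at *locus*."""
    return [(r, m) for r, m in cohort if r.pair(locus) is not None]
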