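"""Parsing, validation and resolution-collapse of HLA allele names.

Allele identifiers follow the colon-delimited WHO nomenclature restricted to
the five loci analysed here (HLA-A, -B, -C, -DRB1, -DQB1).  ``resolution`` is
the number of colon-separated numeric fields retained: 1 for allele groups
("two-digit", e.g. ``B*08``) and 2 for protein-level alleles ("four-digit",
e.g. ``DRB1*14:54``).  An optional trailing expression-variant letter
(e.g. ``N`` in ``A*68:18N``) is kept at full resolution and dropped when the
name is truncated below the depth at which it was reported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import total_ordering

__all__ = [
    "LOCI",
    "AlleleName",
    "AlleleParseError",
    "parse_allele_name",
    "truncate_resolution",
]

#: The five loci covered by the analysis, in report order.
LOCI = ("A", "B", "C", "DRB1", "DQB1")

#: Expression-variant suffix letters admitted by the nomenclature.
_SUFFIXES = "NLSCAQ"

_ALLELE_RE = re.compile(
    r"^(?P<locus>[A-Z0-9]+)\*(?P<fields>\d+(?::\d+){0,3})(?P<suffix>[%s]?)$" % _SUFFIXES
)


class AlleleParseError(ValueError):
    """Raised when an allele string cannot be interpreted."""


@total_ordering
@dataclass(frozen=True)
class AlleleName:
    """A parsed HLA allele identifier.

    Attributes
    ----------
    locus:
        One of :data:`LOCI`.
    fields:
        Ordered tuple of 1-4 non-negative integer field values.
    suffix:
        Optional expression-variant letter (``"N"``, ``"L"``, ...).
    """

    locus: str
    fields: tuple[int, ...]
    suffix: str | None = field(default=None)

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise AlleleParseError(f"unknown locus {self.locus!r}; expected one of {LOCI}")
        if not 1 <= len(self.fields) <= 4:
            raise AlleleParseError(f"allele must carry 1-4 fields, got {self.fields!r}")
        if any((not isinstance(f, int)) or f < 0 for f in self.fields):
            raise AlleleParseError(f"fields must be non-negative integers, got {self.fields!r}")
        if self.suffix is not None and self.suffix not in _SUFFIXES:
            raise AlleleParseError(f"unknown expression suffix {self.suffix!r}")

    @property
    def resolution(self) -> int:
        """Number of fields retained (1 = allele group, 2 = protein level)."""
        return len(self.fields)

    def __str__(self) -> str:
        body = ":".join(f"{f:02d}" for f in self.fields)
        return f"{self.locus}*{body}{self.suffix or ''}"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"AlleleName({str(self)!r})"

    def _key(self) -> tuple:
        return (self.locus, self.fields, self.suffix or "")

    def __lt__(self, other: "AlleleName") -> bool:
        if not isinstance(other, AlleleName):
            return NotImplemented
        return self._key() < other._key()


def parse_allele_name(text: str) -> AlleleName:
    """Parse an allele string such as ``"B*44:27"`` into an :class:`AlleleName`.

    Raises
    ------
    AlleleParseError
        If the separator is missing, a field is non-numeric, or the locus is
        not one of the five studied.
    """
    if not isinstance(text, str) or not text.strip():
        raise AlleleParseError("allele name must be a non-empty string")
    text = text.strip()
    if "*" not in text:
        raise AlleleParseError(f"missing '*' separator in allele name {text!r}")
    m = _ALLELE_RE.match(text)
    if m is None:
        raise AlleleParseError(f"malformed allele name {text!r}")
    locus = m.group("locus")
    if locus not in LOCI:
        raise AlleleParseError(f"unknown locus {locus!r} in allele name {text!r}")
    fields = tuple(int(f) for f in m.group("fields").split(":"))
    suffix = m.group("suffix") or None
    return AlleleName(locus=locus, fields=fields, suffix=suffix)


def truncate_resolution(allele: AlleleName, target_fields: int) -> AlleleName:
    """Collapse *allele* to its first *target_fields* fields.

    Truncation never invents precision: requesting more fields than the
    allele carries is an error.  The expression suffix is dropped whenever
    any field is removed, since it qualifies the full-length name.
    """
    if target_fields < 1:
        raise ValueError("target_fields must be >= 1")
    if target_fields > allele.resolution:
        raise ValueError(
            f"cannot expand {allele} to {target_fields} fields; only "
            f"{allele.resolution} available"
        )
    if target_fields == allele.resolution:
        return allele
    return AlleleName(locus=allele.locus, fields=allele.fields[:target_fields], suffix=None)
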