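"""Case-control and within-cohort association statistics.

The contingency machinery reconstructs control allele counts from panel
frequencies (nearest integer, ties rounding half up), applies the
Haldane-Anscombe continuity correction (0.5 added to every cell) whenever a
raw cell is zero before computing odds ratios, and uses the Woolf logit
interval exp(ln OR +/- z * SE) with SE = sqrt(1/a + 1/b + 1/c + 1/d).  The
chi-square test is Pearson's with 1 df, optionally with the Yates
continuity correction for rare counts.  Benjamini-Hochberg adjustment is
applied within a test family (one locus x resolution x case group).

Note on the normal quantile: the default 95% interval uses z = 1.96 (the
two-decimal quantile used by common spreadsheet/epidemiology tooling, which
the reference results reproduce exactly); other alphas fall back to the
exact quantile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .allele_stats import AlleleCountTable, carrier_flags
from .cohort import Cohort, FrequencyPanel, SubjectMeta
from .nomenclature import AlleleName, parse_allele_name

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "CarrierTraitResult",
    "build_contingency",
    "odds_ratio_ci",
    "chi_square_2x2",
    "one_sample_proportion_z",
    "bh_adjust",
    "associate_allele_set",
    "compare_carrier_phenotypes",
    "format_p",
]

#: Two-decimal 97.5% normal quantile; see module docstring.
Z_95 = 1.96


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: case/control x allele-copies-carried/other-copies."""

    a: float  # case, carried
    b: float  # case, other
    c: float  # control, carried
    d: float  # control, other
    corrected: bool = False

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def cells(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)

    def raw(self) -> "ContingencyTable":
        """The integer table before continuity correction."""
        if not self.corrected:
            return self
        return ContingencyTable(
            self.a - 0.5, self.b - 0.5, self.c - 0.5, self.d - 0.5, corrected=False
        )


def build_contingency(
    case_count: int,
    case_denominator: int,
    control_freq: float,
    control_denominator: int,
) -> ContingencyTable:
    """Build the 2x2 allele-copy table for one allele.

    The control carried-copy count is reconstructed as the nearest integer
    to ``control_freq * control_denominator`` (ties round half up).  If any
    of the four raw cells is zero, 0.5 is added to every cell and the table
    is flagged ``corrected``.
    """
    if control_denominator <= 0:
        raise ValueError("control denominator must be positive")
    if not 0 <= case_count <= case_denominator:
        raise ValueError("case count must lie within the case denominator")
    if not 0.0 <= control_freq <= 1.0:
        raise ValueError("control frequency must lie in [0,1]")
    a = case_count
    b = case_denominator - case_count
    c = _round_half_up(control_freq * control_denominator)
    d = control_denominator - c
    if min(a, b, c, d) == 0:
        return ContingencyTable(a + 0.5, b + 0.5, c + 0.5, d + 0.5, corrected=True)
    return ContingencyTable(float(a), float(b), float(c), float(d), corrected=False)


def odds_ratio_ci(
    table: ContingencyTable, alpha: float = 0.05
) -> tuple[float, float, float, float, float]:
    """Odds ratio with Woolf CI and Wald Z on the log scale.

    Returns ``(odds_ratio, ci_low, ci_high, z, p)``.  All cells must be
    positive; zero cells must have been continuity-corrected upstream.
    """
    a, b, c, d = table.cells
    if min(a, b, c, d) <= 0:
        raise ValueError(
            "odds ratio undefined for a zero cell; apply the continuity "
            "correction when building the table"
        )
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z_crit = Z_95 if math.isclose(alpha, 0.05) else float(stats.norm.isf(alpha / 2))
    log_or = math.log(or_)
    ci_low = math.exp(log_or - z_crit * se)
    ci_high = math.exp(log_or + z_crit * se)
    z = log_or / se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return or_, ci_low, ci_high, z, p


def chi_square_2x2(table: ContingencyTable, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square (1 df) on the raw integer cells of *table*.

    With ``yates`` each |observed - expected| is reduced by 0.5 (floored at
    zero).  A zero marginal makes the test undefined; ``(nan, nan)`` is
    returned rather than raising.
    """
    a, b, c, d = table.raw().cells
    n = a + b + c + d
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    if min(row1, row2, col1, col2) == 0 or n == 0:
        return (math.nan, math.nan)
    chi2 = 0.0
    for obs, rm, cm in ((a, row1, col1), (b, row1, col2), (c, row2, col1), (d, row2, col2)):
        exp = rm * cm / n
        dev = abs(obs - exp)
        if yates:
            dev = max(dev - 0.5, 0.0)
        chi2 += dev * dev / exp
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def one_sample_proportion_z(observed_count: int, n: int, p0: float) -> tuple[float, float]:
    """Two-sided one-sample proportion Z test against reference proportion p0."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie strictly inside (0,1); variance degenerate otherwise")
    p_hat = observed_count / n
    z = (p_hat - p0) / math.sqrt(p0 * (1 - p0) / n)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return z, p


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment within one family of tests."""
    ps = np.asarray(list(pvalues), dtype=float)
    if ps.size == 0:
        return []
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("p-values must lie in [0,1]")
    m = ps.size
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / np.arange(1, m + 1)
    # enforce step-up monotonicity from the largest rank downwards
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted
    return out.tolist()


@dataclass(frozen=True)
class AssociationResult:
    """Full association output for one allele."""

    allele: AlleleName
    case_count: int
    case_denominator: int
    control_freq: float
    control_count: int
    control_denominator: int
    chi2: float
    p: float
    p_corrected: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    z_or: float
    p_or: float
    yates: bool
    zero_cell_corrected: bool

    @property
    def case_freq(self) -> float:
        return self.case_count / self.case_denominator


def associate_allele_set(
    case_table: AlleleCountTable,
    panel: FrequencyPanel,
    yates_threshold: int = 5,
    alpha: float = 0.05,
) -> list[AssociationResult]:
    """Test every allele present in the case table or the panel locus.

    The Yates correction is applied when the smallest raw cell of the 2x2
    table is below *yates_threshold*.  BH adjustment is computed across the
    family formed by all alleles tested here (one locus at one resolution
    for one case group).
    """
    if case_table.resolution != panel.resolution:
        raise ValueError(
            f"case table at resolution {case_table.resolution} vs panel at "
            f"{panel.resolution}"
        )
    locus_panel = panel.loci.get(case_table.locus)
    if locus_panel is None:
        raise KeyError(f"panel {panel.name!r} does not cover locus {case_table.locus}")

    alleles = sorted(set(case_table.counts) | set(locus_panel.frequencies))
    partial = []
    for allele in alleles:
        case_count = case_table.counts.get(allele, 0)
        control_freq = locus_panel.frequencies.get(allele, 0.0)
        table = build_contingency(
            case_count,
            case_table.denominator,
            control_freq,
            locus_panel.total_allele_count,
        )
        raw_cells = table.raw().cells
        yates = min(raw_cells) < yates_threshold
        chi2, p = chi_square_2x2(table, yates=yates)
        or_, lo, hi, z, p_or = odds_ratio_ci(table, alpha=alpha)
        partial.append((allele, case_count, control_freq, table, chi2, p, or_, lo, hi, z, p_or, yates))

    family_ps = [row[5] if not math.isnan(row[5]) else 1.0 for row in partial]
    adjusted = bh_adjust(family_ps)
    results = []
    for row, p_c in zip(partial, adjusted):
        allele, case_count, control_freq, table, chi2, p, or_, lo, hi, z, p_or, yates = row
        results.append(
            AssociationResult(
                allele=allele,
                case_count=case_count,
                case_denominator=case_table.denominator,
                control_freq=control_freq,
                control_count=int(table.raw().cells[2]),
                control_denominator=locus_panel.total_allele_count,
                chi2=chi2,
                p=p,
                p_corrected=max(p_c, p) if not math.isnan(p) else p_c,
                odds_ratio=or_,
                ci_low=lo,
                ci_high=hi,
                z_or=z,
                p_or=p_or,
                yates=yates,
                zero_cell_corrected=table.corrected,
            )
        )
    return results


@dataclass(frozen=True)
class CarrierTraitResult:
    """Carrier-vs-non-carrier comparison for one phenotype trait."""

    trait: str
    carriers_with: int
    carriers_total: int
    noncarriers_with: int
    noncarriers_total: int
    chi2: float
    p: float
    degenerate: bool


TraitPredicate = Callable[[SubjectMeta], bool]


def compare_carrier_phenotypes(
    cohort: Cohort,
    allele: AlleleName | str,
    traits: Sequence[tuple[str, TraitPredicate]],
) -> list[CarrierTraitResult]:
    """Chi-square (with Yates) comparison of traits between carriers of
    *allele* and non-carriers."""
    if isinstance(allele, str):
        allele = parse_allele_name(allele)
    flags = carrier_flags(cohort, allele)
    carriers = [(r, m) for r, m in cohort if flags[m.subject_id]]
    noncarriers = [(r, m) for r, m in cohort if not flags[m.subject_id]]
    if not carriers or not noncarriers:
        raise ValueError(
            f"carrier comparison needs both carriers and non-carriers of {allele}"
        )
    results = []
    for name, predicate in traits:
        cw = sum(predicate(m) for _, m in carriers)
        nw = sum(predicate(m) for _, m in noncarriers)
        total_with = cw + nw
        degenerate = total_with == 0 or total_with == len(cohort)
        if degenerate:
            chi2 = p = math.nan
        else:
            table = ContingencyTable(
                float(cw),
                float(len(carriers) - cw),
                float(nw),
                float(len(noncarriers) - nw),
            )
            chi2, p = chi_square_2x2(table, yates=True)
        results.append(
            CarrierTraitResult(
                trait=name,
                carriers_with=cw,
                carriers_total=len(carriers),
                noncarriers_with=nw,
                noncarriers_total=len(noncarriers),
                chi2=chi2,
                p=p,
                degenerate=degenerate,
            )
        )
    return results


def format_p(p: float) -> str:
    """Render a p-value the way the report tables print it."""
    if math.isnan(p):
        return "NA"
    if p < 1e-5:
        return "< 0.00001"
    return f"{p:.4f}"
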