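"""Hardy-Weinberg equilibrium and within-locus linkage-disequilibrium checks.

The HWE chi-square compares observed genotype-pair counts with the counts
expected from the observed allele frequencies (n*p_i^2 for homozygotes,
2*n*p_i*p_j for heterozygotes), pooling genotype classes whose expectation
falls below a threshold.  The LD coefficient is taken literally as
D = P_XY - P_X * P_Y on percent scale: the observed unordered pair
frequency minus the plain product of the two allele frequencies, with no
heterozygosity factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Mapping

from scipy import stats

from .allele_stats import AlleleCountTable, GenotypePairTable, PairKey, pair_table_margins
from .nomenclature import AlleleName

__all__ = ["HWEResult", "LDResult", "hwe_test", "ld_coefficient", "ld_scan"]

FreqSource = AlleleCountTable | Mapping[AlleleName, float]


def _freq_map(freqs: FreqSource) -> dict[AlleleName, float]:
    if isinstance(freqs, AlleleCountTable):
        return freqs.frequencies
    return dict(freqs)


@dataclass(frozen=True)
class HWEResult:
    locus: str
    chi2: float
    df: int
    p: float
    n_classes: int
    n_pooled: int
    pooled_classes: str

    def __post_init__(self) -> None:
        if self.chi2 < 0 or self.df < 1:
            raise ValueError("invalid HWE result")


@dataclass(frozen=True)
class LDResult:
    locus: str
    pair: PairKey
    observed_pct: float
    expected_pct: float

    @property
    def d_pct(self) -> float:
        return self.observed_pct - self.expected_pct


def hwe_test(
    pairs: GenotypePairTable,
    freqs: AlleleCountTable | None = None,
    min_expected: float = 1.0,
) -> HWEResult:
    """Chi-square goodness-of-fit of genotype-pair counts to HWE expectations.

    *freqs* defaults to the allele counts marginalised from *pairs*.
    Every genotype class with at least one observation is retained;
    unobserved classes with expected count below *min_expected* are pooled
    into a single class (observed data are never merged away).  Degrees of
    freedom are ``(#classes - 1) - (#alleles - 1)``, floored at 1.
    """
    if freqs is None:
        freqs = pair_table_margins(pairs)
    if freqs.locus != pairs.locus or freqs.resolution != pairs.resolution:
        raise ValueError("pair table and allele counts must share locus and resolution")
    if pairs.n_subjects < 5:
        raise ValueError("HWE test requires at least 5 subjects")
    p = {a: f for a, f in _freq_map(freqs).items() if f > 0}
    alleles = sorted(p)
    if len(alleles) < 2:
        raise ValueError("HWE not testable with fewer than 2 alleles")
    n = pairs.n_subjects

    kept: list[tuple[float, float]] = []  # (observed, expected)
    pooled_obs = pooled_exp = 0.0
    pooled_names: list[str] = []
    for x, y in combinations_with_replacement(alleles, 2):
        expected = n * (p[x] ** 2 if x == y else 2 * p[x] * p[y])
        observed = float(pairs.pair_counts.get((x, y), 0))
        if observed == 0 and expected < min_expected:
            pooled_obs += observed
            pooled_exp += expected
            pooled_names.append(f"{x}-{y}")
        else:
            kept.append((observed, expected))
    if pooled_exp > 0:
        kept.append((pooled_obs, pooled_exp))

    chi2 = sum((obs - exp) ** 2 / exp for obs, exp in kept)
    df = max((len(kept) - 1) - (len(alleles) - 1), 1)
    pval = float(stats.chi2.sf(chi2, df=df))
    return HWEResult(
        locus=pairs.locus,
        chi2=chi2,
        df=df,
        p=pval,
        n_classes=len(kept),
        n_pooled=len(pooled_names),
        pooled_classes=(
            f"{len(pooled_names)} classes with expected < {min_expected} pooled"
            if pooled_names
            else "no pooling"
        ),
    )


def ld_coefficient(
    pairs: GenotypePairTable,
    freqs: FreqSource,
    pair: PairKey,
) -> LDResult:
    """D = observed pair frequency minus product of allele frequencies (percent)."""
    fmap = _freq_map(freqs)
    x, y = tuple(sorted(pair))
    for allele in (x, y):
        if allele not in fmap:
            raise KeyError(f"allele {allele} absent from frequency source")
    observed_pct = 100.0 * pairs.frequency((x, y))
    expected_pct = 100.0 * fmap[x] * fmap[y]
    return LDResult(locus=pairs.locus, pair=(x, y), observed_pct=observed_pct, expected_pct=expected_pct)


def ld_scan(
    pairs: GenotypePairTable,
    freqs: FreqSource,
    threshold_pct: float,
) -> list[LDResult]:
    """All observed pairs with D >= threshold, sorted by descending D then name."""
    fmap = _freq_map(freqs)
    results = []
    for key, count in pairs.pair_counts.items():
        if count == 0:
            continue
        x, y = key
        if x not in fmap or y not in fmap:
            continue
        res = ld_coefficient(pairs, fmap, key)
        if res.d_pct >= threshold_pct:
            results.append(res)
    results.sort(key=lambda r: (-r.d_pct, str(r.pair[0]), str(r.pair[1])))
    return results
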