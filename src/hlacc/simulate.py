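"""Seeded synthetic cohort generators.

Three generators are provided: i.i.d. sampling of genotypes under
Hardy-Weinberg from arbitrary per-locus allele frequencies (optionally with
forced genotype-pair excesses), injection of a case-control effect of a
target odds ratio, and the deterministic marginal fixture that reproduces
the published cohort tables (delegated to :mod:`hlacc.refdata`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .cohort import Cohort, FrequencyPanel, GenotypeRecord, SubjectMeta
from .nomenclature import AlleleName, parse_allele_name
from . import refdata

__all__ = [
    "SimulationSpec",
    "sample_cohort",
    "inject_case_effect",
    "marginal_fixture",
    "control_pair_fixture",
]

_FREQ_TOL = 1e-9


@dataclass(frozen=True)
class MetadataModel:
    """Categorical proportions for simulated subject metadata."""

    female: float = 0.80
    serotype: tuple[float, float, float] = (0.75, 0.025, 0.225)  # RAch+/MuSK+/dSN
    onset: tuple[float, float, float] = (0.075, 0.575, 0.35)  # MGj/EOMG/LOMG
    autoimmune: float = 0.275


@dataclass(frozen=True)
class SimulationSpec:
    """Specification of a simulated cohort."""

    allele_freqs: Mapping[str, Mapping[AlleleName, float]]
    n_subjects: int
    seed: int = 0
    risk_injections: tuple[tuple[AlleleName, float], ...] = ()
    pair_excess: tuple[tuple[tuple[AlleleName, AlleleName], float], ...] = ()
    metadata: MetadataModel = field(default_factory=MetadataModel)

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        for locus, freqs in self.allele_freqs.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"{locus} allele frequencies sum to {total}, not 1")
            if any(f < 0 for f in freqs.values()):
                raise ValueError(f"negative allele frequency at {locus}")


def spec_from_strings(
    allele_freqs: Mapping[str, Mapping[str, float]], n_subjects: int, seed: int = 0, **kw
) -> SimulationSpec:
    """Convenience constructor taking allele names as strings."""
    parsed = {
        locus: {parse_allele_name(a): f for a, f in freqs.items()}
        for locus, freqs in allele_freqs.items()
    }
    return SimulationSpec(allele_freqs=parsed, n_subjects=n_subjects, seed=seed, **kw)


def _pair_distribution(
    freqs: Mapping[AlleleName, float],
    excesses: Sequence[tuple[tuple[AlleleName, AlleleName], float]],
) -> tuple[list[tuple[AlleleName, AlleleName]], np.ndarray]:
    """Unordered-pair distribution under HWE plus forced pair excesses."""
    alleles = sorted(a for a, f in freqs.items() if f > 0)
    pairs: list[tuple[AlleleName, AlleleName]] = []
    probs: list[float] = []
    for i, x in enumerate(alleles):
        for y in alleles[i:]:
            pairs.append((x, y))
            probs.append(freqs[x] ** 2 if x == y else 2 * freqs[x] * freqs[y])
    prob = np.asarray(probs)
    if excesses:
        # each excess is added to its pair exactly; the untouched pairs are
        # rescaled to restore normalisation
        index = {p: i for i, p in enumerate(pairs)}
        add = np.zeros_like(prob)
        target = np.zeros(len(pairs), dtype=bool)
        for pair, d_pct in excesses:
            key = tuple(sorted(pair))
            if key not in index:
                raise ValueError(f"pair excess references unknown pair {key}")
            add[index[key]] = d_pct / 100.0
            target[index[key]] = True
        new_target = prob[target] + add[target]
        if np.any(new_target < -_FREQ_TOL) or np.any(new_target > 1 + _FREQ_TOL):
            raise ValueError("pair excesses push probabilities outside [0,1]")
        old_rest = 1.0 - prob[target].sum()
        new_rest = 1.0 - new_target.sum()
        if new_rest < -_FREQ_TOL or old_rest <= 0:
            raise ValueError("pair excesses exceed total probability mass")
        prob = np.where(target, prob + add, prob * (new_rest / old_rest))
    prob = np.clip(prob, 0.0, None)
    prob /= prob.sum()
    return pairs, prob


def sample_cohort(spec: SimulationSpec) -> Cohort:
    """Draw ``spec.n_subjects`` i.i.d. subjects; reproducible given the seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects

    genotype_columns: dict[str, list[tuple[AlleleName, AlleleName]]] = {}
    for locus in sorted(spec.allele_freqs):
        freqs = spec.allele_freqs[locus]
        excesses = [(p, d) for p, d in spec.pair_excess if p[0].locus == locus]
        pairs, prob = _pair_distribution(freqs, excesses)
        idx = rng.choice(len(pairs), size=n, p=prob)
        genotype_columns[locus] = [pairs[i] for i in idx]

    md = spec.metadata
    female = rng.random(n) < md.female
    serotype = rng.choice(["RAchPos", "MuSKPos", "dSNMG"], size=n, p=md.serotype)
    onset = rng.choice(["MGj", "EOMG", "LOMG"], size=n, p=md.onset)
    autoimmune = rng.random(n) < md.autoimmune
    ages = {"MGj": (5, 17), "EOMG": (18, 49), "LOMG": (50, 80)}

    cohort: Cohort = []
    for i in range(n):
        sid = f"S{i + 1:04d}"
        genotype = {locus: genotype_columns[locus][i] for locus in genotype_columns}
        lo, hi = ages[str(onset[i])]
        meta = SubjectMeta(
            subject_id=sid,
            sex="F" if female[i] else "M",
            age_at_onset=float(rng.integers(lo, hi + 1)),
            onset_class=str(onset[i]),
            mgfa_max="IIA",
            serotype=str(serotype[i]),
            thymic_status="normal_ct",
            autoimmune_comorbidity=bool(autoimmune[i]),
        )
        cohort.append((GenotypeRecord(subject_id=sid, genotype=genotype), meta))
    return cohort


def inject_case_effect(
    spec: SimulationSpec,
    allele: AlleleName | str,
    target_or: float,
    panel: FrequencyPanel,
) -> SimulationSpec:
    """Return a spec whose case frequency of *allele* implies *target_or*.

    The case frequency q solves q/(1-q) = OR * p/(1-p) with p the panel
    frequency; the other alleles at the locus are rescaled to keep the
    distribution normalised.
    """
    if isinstance(allele, str):
        allele = parse_allele_name(allele)
    if target_or <= 0:
        raise ValueError("target odds ratio must be positive")
    p = panel.frequency(allele)
    if not 0.0 < p < 1.0:
        raise ValueError(f"panel frequency for {allele} must be in (0,1), got {p}")
    odds = target_or * p / (1.0 - p)
    q = odds / (1.0 + odds)

    locus_freqs = dict(spec.allele_freqs[allele.locus])
    old = locus_freqs.get(allele, 0.0)
    rest = 1.0 - old
    if rest <= 0:
        raise ValueError(f"{allele} already fixed in the simulated locus")
    scale = (1.0 - q) / rest
    new_freqs = {a: f * scale for a, f in locus_freqs.items() if a != allele}
    new_freqs[allele] = q
    all_freqs = dict(spec.allele_freqs)
    all_freqs[allele.locus] = new_freqs
    return replace(spec, allele_freqs=all_freqs, risk_injections=spec.risk_injections + ((allele, target_or),))


def marginal_fixture(seed: int = 0) -> Cohort:
    """The deterministic 40-subject cohort matching the published margins."""
    return refdata.build_reference_cohort(seed)


def control_pair_fixture(locus: str):
    """Deterministic control genotype-pair table (see :mod:`hlacc.refdata`)."""
    return refdata.control_pair_fixture(locus)
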