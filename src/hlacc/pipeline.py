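"""Study workflow orchestration and report-table rendering.

``run_study`` executes the full analysis in a fixed order: one-sample
proportion tests against national frequencies, two-digit association versus
the low-resolution panel for the whole cohort and each serotype subgroup,
four-digit association versus the high-resolution panel for the same
groups, the carrier-phenotype comparison for a configured allele, and
genotype-pair tables with Hardy-Weinberg and linkage-disequilibrium checks.
Each stage writes one TSV; a JSON manifest records run parameters, input
sizes and per-stage status.  Subgroups too small to test (for example a
single MuSK+ subject) are skipped with a logged reason, not tested.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .allele_stats import (
    GenotypePairTable,
    count_alleles,
    genotype_pair_frequencies,
    pair_table_margins,
)
from .association import (
    associate_allele_set,
    compare_carrier_phenotypes,
    format_p,
    one_sample_proportion_z,
)
from .cohort import Cohort, read_cohort, read_frequency_panel, select_subgroup
from .nomenclature import LOCI, parse_allele_name
from .popgen import hwe_test, ld_scan
from .refdata import TABLE3_TRAITS

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "run_study", "heatmap_matrix"]

#: Minimum subjects for a subgroup to be analysed at all.
MIN_SUBGROUP_SIZE = 2


@dataclass(frozen=True)
class StudyConfig:
    """Paths, thresholds and options controlling one study run."""

    cohort: Path
    panel_lowres: Path
    panel_highres: Path | None = None
    national_frequencies: Path | None = None
    carrier_allele: str = "B*40"
    yates_threshold: int = 5
    alpha: float = 0.05
    ld_threshold: float = 4.0
    output_dir: Path = Path("hlacc_results")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        paths = {k: Path(v) for k, v in raw.items()
                 if k in ("cohort", "panel_lowres", "panel_highres",
                          "national_frequencies", "output_dir") and v is not None}
        opts = {k: v for k, v in raw.items()
                if k in ("carrier_allele", "yates_threshold", "alpha",
                         "ld_threshold", "seed")}
        cfg = cls(**paths, **opts)
        for name in ("cohort", "panel_lowres", "panel_highres", "national_frequencies"):
            p = getattr(cfg, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config references missing {name}: {p}")
        return cfg


def _association_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "allele": str(r.allele),
            "case_pct": round(100.0 * r.case_freq, 2),
            "case_count": r.case_count,
            "control_pct": round(100.0 * r.control_freq, 2),
            "p": format_p(r.p),
            "p_corrected": format_p(r.p_corrected),
            "odds_ratio": round(r.odds_ratio, 4),
            "ci_low": round(r.ci_low, 4),
            "ci_high": round(r.ci_high, 4),
            "z": round(r.z_or, 3),
            "p_z": format_p(r.p_or),
            "yates": r.yates,
            "zero_cell_corrected": r.zero_cell_corrected,
        })
    return pd.DataFrame(rows)


def _subgroups(cohort: Cohort) -> dict[str, Cohort]:
    groups: dict[str, Cohort] = {"total": cohort}
    for serotype in ("RAchPos", "MuSKPos", "dSNMG"):
        groups[serotype] = select_subgroup(cohort, {"serotype": serotype})
    return groups


def run_study(config: StudyConfig) -> dict:
    """Execute the full workflow; returns the manifest dictionary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {
            "carrier_allele": config.carrier_allele,
            "yates_threshold": config.yates_threshold,
            "alpha": config.alpha,
            "ld_threshold": config.ld_threshold,
            "seed": config.seed,
        },
        "stages": [],
        "outputs": {},
    }

    def stage(name: str, status: str, detail: str = "") -> None:
        logger.info("stage %s: %s %s", name, status, detail)
        manifest["stages"].append({"stage": name, "status": status, "detail": detail})

    try:
        cohort = read_cohort(config.cohort)
        panel1 = read_frequency_panel(config.panel_lowres, resolution=1)
        panel2 = (
            read_frequency_panel(config.panel_highres, resolution=2)
            if config.panel_highres
            else None
        )
        stage("load", "ok", f"{len(cohort)} subjects")
    except Exception as exc:
        stage("load", "failed", str(exc))
        raise RuntimeError(f"stage 'load' failed: {exc}") from exc

    groups = _subgroups(cohort)
    manifest["group_sizes"] = {g: len(c) for g, c in groups.items()}

    # 1. one-sample proportion tests against national frequencies
    if config.national_frequencies:
        nat = pd.read_csv(config.national_frequencies, sep="\t")
        rows = []
        counts_cache: dict[str, object] = {}
        for _, row in nat.iterrows():
            allele = parse_allele_name(row["allele"])
            freq = float(row["frequency"])
            if str(row.get("frequency_unit", "fraction")) == "percent":
                freq /= 100.0
            table = counts_cache.setdefault(
                allele.locus, count_alleles(cohort, allele.locus, allele.resolution)
            )
            z, p = one_sample_proportion_z(
                table.counts.get(allele, 0), table.denominator, freq
            )
            rows.append({
                "allele": str(allele),
                "case_pct": round(100.0 * table.frequency(allele), 2),
                "national_pct": round(100.0 * freq, 2),
                "z": round(z, 3),
                "p": format_p(p),
            })
        path = out / "national_ztests.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        manifest["outputs"]["national_ztests"] = str(path)
        stage("national_ztests", "ok", f"{len(rows)} alleles")
    else:
        stage("national_ztests", "skipped", "no national frequency table configured")

    # 2. association per group x resolution x locus
    for resolution, panel in ((1, panel1), (2, panel2)):
        if panel is None:
            stage(f"association_res{resolution}", "skipped", "panel not configured")
            continue
        for group_name, group in groups.items():
            if len(group) < MIN_SUBGROUP_SIZE:
                stage(
                    f"association_{group_name}_res{resolution}",
                    "skipped",
                    f"subgroup too small (n={len(group)})",
                )
                continue
            frames = []
            for locus in LOCI:
                if locus not in panel.loci:
                    # panels may omit loci (no four-digit DQB1); skip, never impute
                    continue
                try:
                    table = count_alleles(group, locus, resolution)
                except Exception as exc:
                    stage(
                        f"association_{group_name}_res{resolution}_{locus}",
                        "skipped",
                        str(exc),
                    )
                    continue
                results = associate_allele_set(
                    table, panel,
                    yates_threshold=config.yates_threshold,
                    alpha=config.alpha,
                )
                frame = _association_frame(results)
                frame.insert(0, "locus", locus)
                frames.append(frame)
            if frames:
                path = out / f"association_{group_name}_res{resolution}.tsv"
                pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
                manifest["outputs"][f"association_{group_name}_res{resolution}"] = str(path)
                stage(f"association_{group_name}_res{resolution}", "ok", f"n={len(group)}")

    # 3. carrier-phenotype comparison
    try:
        carrier_results = compare_carrier_phenotypes(
            cohort, config.carrier_allele, TABLE3_TRAITS
        )
        rows = [{
            "trait": r.trait,
            "carriers": f"{r.carriers_with}/{r.carriers_total}",
            "non_carriers": f"{r.noncarriers_with}/{r.noncarriers_total}",
            "chi2": round(r.chi2, 4) if not r.degenerate else "",
            "p": format_p(r.p) if not r.degenerate else "degenerate",
        } for r in carrier_results]
        path = out / "carrier_phenotypes.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        manifest["outputs"]["carrier_phenotypes"] = str(path)
        stage("carrier_phenotypes", "ok", config.carrier_allele)
    except ValueError as exc:
        stage("carrier_phenotypes", "skipped", str(exc))

    # 4. genotype pairs, HWE, LD
    hwe_rows, ld_rows = [], []
    pair_tables: dict[str, GenotypePairTable] = {}
    for locus in ("A", "B", "DRB1"):
        pairs = genotype_pair_frequencies(cohort, locus, resolution=1)
        pair_tables[locus] = pairs
        pairs.to_frame().to_csv(out / f"pairs_{locus}.tsv", sep="\t", index=False)
        manifest["outputs"][f"pairs_{locus}"] = str(out / f"pairs_{locus}.tsv")
        hwe = hwe_test(pairs)
        hwe_rows.append({
            "locus": locus, "chi2": round(hwe.chi2, 4), "df": hwe.df,
            "p": format_p(hwe.p), "pooling": hwe.pooled_classes,
        })
        freqs = count_alleles(cohort, locus, 1)
        for res in ld_scan(pairs, freqs, config.ld_threshold):
            ld_rows.append({
                "locus": locus,
                "pair": f"{res.pair[0]}-{res.pair[1]}",
                "observed_pct": round(res.observed_pct, 2),
                "expected_pct": round(res.expected_pct, 2),
                "d_pct": round(res.d_pct, 2),
            })
    pd.DataFrame(hwe_rows).to_csv(out / "hwe.tsv", sep="\t", index=False)
    pd.DataFrame(ld_rows).to_csv(out / "ld.tsv", sep="\t", index=False)
    manifest["outputs"]["hwe"] = str(out / "hwe.tsv")
    manifest["outputs"]["ld"] = str(out / "ld.tsv")
    stage("popgen", "ok", f"LD threshold {config.ld_threshold}")

    # 5. heatmap matrix of pair/allele frequencies per group
    matrix = heatmap_matrix({f"MG_{locus}": table for locus, table in pair_tables.items()})
    matrix.to_csv(out / "heatmap_matrix.tsv", sep="\t")
    manifest["outputs"]["heatmap_matrix"] = str(out / "heatmap_matrix.tsv")
    stage("heatmap", "ok", f"{matrix.shape[0]} rows")

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def heatmap_matrix(pair_tables: Mapping[str, GenotypePairTable]) -> pd.DataFrame:
    """Rectangular frequency matrix: rows = pairs then alleles, columns = groups.

    Values are percentages; pair rows of one group sum to 100.  Pairs or
    alleles absent from a group are reported as 0.00.
    """
    pair_keys = sorted({k for t in pair_tables.values() for k in t.pair_counts})
    allele_keys = sorted({a for t in pair_tables.values() for a in pair_table_margins(t).counts})
    data: dict[str, list[float]] = {}
    for group, table in pair_tables.items():
        margins = pair_table_margins(table)
        col = [round(100.0 * table.frequency(k), 2) for k in pair_keys]
        col += [round(100.0 * margins.frequency(a), 2) for a in allele_keys]
        data[group] = col
    index = [f"{a}-{b}" for a, b in pair_keys] + [str(a) for a in allele_keys]
    return pd.DataFrame(data, index=index)
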