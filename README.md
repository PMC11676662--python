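# hlacc

HLA case–control allele association analysis against reference-population
frequency panels.

The package implements the full analysis pipeline of a small HLA
case–control study design: allele and genotype-pair frequency estimation
from typed cohorts (homozygotes counted twice), association testing against
reference frequency panels at two nomenclature resolutions ("two-digit"
allele groups and "four-digit" protein-level alleles), continuity-corrected
odds ratios with Woolf confidence intervals, per-family Benjamini–Hochberg
correction, one-sample proportion tests against national allele
frequencies, carrier-versus-non-carrier phenotype comparison,
Hardy–Weinberg equilibrium checks, a within-locus linkage-disequilibrium
coefficient, and seeded synthetic cohort generation.

It ships a deterministic 40-subject myasthenia-gravis cohort reconstructed
from published marginal tables (allele counts, genotype-pair tables,
clinical metadata margins) together with the matching reference panels, so
the published headline statistics can be recomputed end to end.

## Layout

| module               | contents                                                            |
|----------------------|---------------------------------------------------------------------|
| `hlacc.nomenclature` | allele-name parsing, validation, resolution truncation              |
| `hlacc.cohort`       | cohort/panel TSV IO, subject metadata, subgroup selection           |
| `hlacc.allele_stats` | allele count tables, genotype-pair tables, carrier flags            |
| `hlacc.association`  | 2×2 machinery, odds ratios/CIs, chi-square, proportion Z test, BH   |
| `hlacc.popgen`       | Hardy–Weinberg chi-square, linkage-disequilibrium coefficient/scan  |
| `hlacc.simulate`     | seeded HWE samplers, effect injection, deterministic margin fixture |
| `hlacc.refdata`      | bundled published tables, panels, control-pair fixtures             |
| `hlacc.pipeline`     | full-study orchestration, report tables, heatmap matrix             |
| `hlacc.cli`          | the `hlacc` command                                                 |

## Command line

```sh
# emit the bundled reconstructed cohort (or sample a synthetic one)
hlacc simulate --fixture --out cohort.tsv
hlacc simulate --spec sim.yaml --seed 7 --out sim_cohort.tsv

# allele counts / genotype pairs for one locus
hlacc count --cohort cohort.tsv --locus B --resolution 2digit

# case-vs-panel association (per-locus BH families by default)
hlacc associate --cohort cohort.tsv --panel panel.tsv --resolution 2digit \
    --group serotype=dSNMG --yates-threshold 5 --bh-scope locus

# one-sample proportion Z tests, carrier comparison, HWE, LD
hlacc ztest --cohort cohort.tsv --national national.tsv
hlacc carriers --cohort cohort.tsv --allele 'B*40'
hlacc hwe --cohort cohort.tsv --locus DRB1
hlacc ld --cohort cohort.tsv --locus B --threshold 4

# the whole workflow from a YAML config
hlacc run --config study.yaml
```

A study config names the cohort, the two panels, the national frequency
table, thresholds and the output directory; `hlacc run` writes one TSV per
report table plus a `manifest.json` with run parameters and per-stage
status.

## File formats

* **Cohort TSV** — one row per subject: `subject_id`, two allele columns
  per locus (`A_1, A_2, …, DQB1_1, DQB1_2`), then `sex, age_at_onset,
  onset_class, mgfa_max, serotype, thymic_status, autoimmune, titin_ryr`.
  Both allele cells blank = locus untyped (excluded from that locus'
  denominator only).
* **Panel TSV** — `locus, allele, frequency, frequency_unit{fraction|percent},
  n, n_unit{individuals|alleles}`; frequencies are stored internally as
  fractions, counts as allele copies (2 × individuals).
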