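"""Bundled reference inputs for the Romanian myasthenia-gravis case-control analysis.

This module carries, as code, the published summary statistics of the study
cohort this package ships as its worked example, and a deterministic
40-subject cohort reconstructed from them:

* two-digit allele counts per locus for the whole cohort and its serotype
  subgroups (denominators 80 / 60 / 18; DQB1 over 78 / 58 / 18 alleles,
  one RAch+ subject being untyped there);
* the within-locus genotype-pair tables for HLA-A, -B and -DRB1;
* subject metadata margins (sex, onset class, MGFA class, serotype, thymic
  status, comorbidity, titin/RyR antibodies) including the B*40
  carrier/non-carrier phenotype split;
* the two reference frequency panels (two-digit, allele denominators
  11,516 / 12,020 / 3,224 / 13,872 / 6,656; four-digit, denominator 2,468
  for HLA-A/B/C/DRB1) and scalar national allele frequencies.

The raw genotypes behind those margins were never deposited, so the
reconstruction is a constraint-consistent completion: every published
marginal is reproduced exactly, and assignments the margins do not pin
down are fixed by the deterministic layout below.  One published
inconsistency exists: the DRB1 pair table implies DRB1*03 x9 / DRB1*10 x1
while the allele-count table prints 8 / 2.  The allele counts win here;
one DRB1*03-DRB1*16 pair is replaced by DRB1*10-DRB1*16.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .allele_stats import GenotypePairTable, count_alleles
from .cohort import (
    Cohort,
    FrequencyPanel,
    GenotypeRecord,
    LocusPanel,
    SubjectMeta,
    read_cohort,
    read_frequency_panel,
)
from .nomenclature import LOCI, AlleleName, parse_allele_name

__all__ = [
    "MG_ALLELE_COUNTS",
    "SUBGROUP_ALLELE_COUNTS",
    "NATIONAL_FREQUENCIES",
    "build_reference_cohort",
    "load_reference_cohort",
    "load_reference_panel",
    "load_national_frequencies",
    "control_pair_fixture",
    "TABLE3_TRAITS",
    "regenerate_data",
]

# --------------------------------------------------------------------------
# Published two-digit allele counts (whole cohort and serotype subgroups).
# --------------------------------------------------------------------------

MG_ALLELE_COUNTS: dict[str, dict[str, int]] = {
    "A": {"A*01": 13, "A*02": 28, "A*03": 6, "A*11": 2, "A*23": 1, "A*24": 12,
          "A*25": 3, "A*26": 4, "A*29": 1, "A*30": 1, "A*31": 1, "A*32": 5,
          "A*33": 2, "A*68": 1},
    "B": {"B*07": 3, "B*08": 12, "B*13": 3, "B*15": 2, "B*18": 9, "B*27": 4,
          "B*35": 11, "B*38": 3, "B*39": 2, "B*40": 8, "B*44": 7, "B*47": 2,
          "B*51": 8, "B*52": 1, "B*55": 1, "B*57": 2, "B*58": 1, "B*73": 1},
    "C": {"C*01": 4, "C*02": 8, "C*03": 6, "C*04": 8, "C*05": 1, "C*06": 9,
          "C*07": 25, "C*12": 10, "C*14": 2, "C*15": 5, "C*16": 2},
    "DRB1": {"DRB1*01": 9, "DRB1*03": 8, "DRB1*04": 7, "DRB1*07": 6, "DRB1*10": 2,
             "DRB1*11": 14, "DRB1*12": 1, "DRB1*13": 1, "DRB1*14": 8,
             "DRB1*15": 10, "DRB1*16": 14},
    "DQB1": {"DQB1*02": 11, "DQB1*03": 23, "DQB1*05": 33, "DQB1*06": 11},
}

SUBGROUP_ALLELE_COUNTS: dict[str, dict[str, dict[str, int]]] = {
    "dSNMG": {
        "A": {"A*01": 2, "A*02": 8, "A*03": 1, "A*24": 4, "A*25": 1, "A*30": 1,
              "A*33": 1},
        "B": {"B*08": 2, "B*13": 1, "B*18": 3, "B*27": 1, "B*35": 2, "B*38": 1,
              "B*40": 2, "B*44": 1, "B*47": 1, "B*51": 2, "B*55": 1, "B*58": 1},
        "C": {"C*01": 3, "C*02": 2, "C*03": 1, "C*04": 1, "C*06": 2, "C*07": 5,
              "C*12": 2, "C*14": 1, "C*15": 1},
        "DRB1": {"DRB1*01": 2, "DRB1*03": 1, "DRB1*04": 1, "DRB1*07": 2,
                 "DRB1*10": 1, "DRB1*11": 4, "DRB1*13": 1, "DRB1*14": 3,
                 "DRB1*15": 1, "DRB1*16": 2},
        "DQB1": {"DQB1*02": 3, "DQB1*03": 5, "DQB1*05": 8, "DQB1*06": 2},
    },
    "RAchPos": {
        "A": {"A*01": 9, "A*02": 20, "A*03": 5, "A*11": 2, "A*23": 1, "A*24": 8,
              "A*25": 2, "A*26": 4, "A*29": 1, "A*31": 1, "A*32": 5, "A*33": 1,
              "A*68": 1},
        "B": {"B*07": 3, "B*08": 9, "B*13": 2, "B*15": 2, "B*18": 6, "B*27": 3,
              "B*35": 9, "B*38": 2, "B*39": 2, "B*40": 6, "B*44": 6, "B*47": 1,
              "B*51": 5, "B*52": 1, "B*57": 2, "B*73": 1},
        "C": {"C*01": 1, "C*02": 6, "C*03": 5, "C*04": 7, "C*05": 1, "C*06": 7,
              "C*07": 19, "C*12": 7, "C*14": 1, "C*15": 4, "C*16": 2},
        "DRB1": {"DRB1*01": 7, "DRB1*03": 7, "DRB1*04": 6, "DRB1*07": 3,
                 "DRB1*10": 1, "DRB1*11": 10, "DRB1*12": 1, "DRB1*14": 4,
                 "DRB1*15": 9, "DRB1*16": 12},
        "DQB1": {"DQB1*02": 8, "DQB1*03": 17, "DQB1*05": 24, "DQB1*06": 9},
    },
}

# --------------------------------------------------------------------------
# Reference panels.
# --------------------------------------------------------------------------

# Two-digit panel; frequencies are fractions, totals are allele copies (2n).
PANEL_LOWRES: dict[str, tuple[int, dict[str, float]]] = {
    "A": (11516, {"A*01": 0.12, "A*02": 0.26, "A*03": 0.09, "A*11": 0.08,
                  "A*23": 0.03, "A*24": 0.12, "A*25": 0.03, "A*26": 0.05,
                  "A*29": 0.02, "A*30": 0.02, "A*31": 0.02, "A*32": 0.04,
                  "A*33": 0.03, "A*36": 0.04, "A*68": 0.03}),
    "B": (12020, {"B*07": 0.05, "B*08": 0.06, "B*13": 0.03, "B*14": 0.02,
                  "B*15": 0.03, "B*18": 0.10, "B*27": 0.04, "B*35": 0.14,
                  "B*38": 0.03, "B*39": 0.03, "B*40": 0.05, "B*41": 0.02,
                  "B*44": 0.08, "B*47": 0.00, "B*49": 0.02, "B*50": 0.02,
                  "B*51": 0.09, "B*52": 0.04, "B*53": 0.02, "B*55": 0.02,
                  "B*56": 0.01, "B*57": 0.01, "B*58": 0.02, "B*73": 0.00,
                  "B*78": 0.03}),
    "C": (3224, {"C*01": 0.05, "C*02": 0.07, "C*03": 0.07, "C*04": 0.15,
                 "C*05": 0.03, "C*06": 0.09, "C*07": 0.26, "C*08": 0.03,
                 "C*12": 0.13, "C*14": 0.03, "C*15": 0.05, "C*16": 0.03,
                 "C*17": 0.01}),
    "DRB1": (13872, {"DRB1*01": 0.08, "DRB1*03": 0.11, "DRB1*04": 0.09,
                     "DRB1*07": 0.07, "DRB1*08": 0.02, "DRB1*10": 0.01,
                     "DRB1*11": 0.19, "DRB1*12": 0.02, "DRB1*13": 0.15,
                     "DRB1*14": 0.07, "DRB1*15": 0.09, "DRB1*16": 0.10}),
    "DQB1": (6656, {"DQB1*02": 0.21, "DQB1*03": 0.29, "DQB1*04": 0.02,
                    "DQB1*05": 0.30, "DQB1*06": 0.18}),
}

# Four-digit panel (no DQB1 coverage); 2,468 allele copies per locus.
PANEL_HIGHRES: dict[str, tuple[int, dict[str, float]]] = {
    "A": (2468, {"A*02:07": 0.0004, "A*02:08": 0.0004, "A*02:27": 0.0004,
                 "A*02:36": 0.0, "A*03:97": 0.0004, "A*24:18": 0.0004,
                 "A*68:18N": 0.0004, "A*74:01": 0.0004, "A*80:01": 0.0004}),
    "B": (2468, {"B*15:09": 0.0004, "B*15:39": 0.0004, "B*15:73": 0.0004,
                 "B*35:14": 0.0004, "B*39:10": 0.0004, "B*39:31": 0.0004,
                 "B*44:04": 0.0004, "B*44:27": 0.0, "B*47:27": 0.0,
                 "B*51:02": 0.0005, "B*53:01": 0.0004, "B*57:02": 0.0008}),
    "C": (2468, {"C*08:01": 0.0004, "C*12:12": 0.0004, "C*15:06": 0.0004}),
    "DRB1": (2468, {"DRB1*01:11": 0.0004, "DRB1*11:11": 0.0004,
                    "DRB1*11:33": 0.0004, "DRB1*11:39": 0.0004,
                    "DRB1*11:43": 0.0004, "DRB1*13:22": 0.0004,
                    "DRB1*14:06": 0.0004, "DRB1*14:54": 0.0,
                    "DRB1*16:01": 0.0644}),
}

# Scalar national allele frequencies used by the one-sample proportion test.
NATIONAL_FREQUENCIES: dict[str, float] = {
    "B*08": 0.077,
    "B*40": 0.05,
    "B*47": 0.006,
    "B*73": 0.001,
    "DRB1*16": 0.096,
    "A*11": 0.093,
    "DRB1*13": 0.105,
}

# --------------------------------------------------------------------------
# Deterministic cohort reconstruction.
# --------------------------------------------------------------------------

# One row per subject: id, allele pairs per locus (four-digit; blank = locus
# untyped), then sex, age at onset, onset class, MGFA, serotype, thymic
# status, autoimmune comorbidity, titin/RyR status.  Subjects MG01-MG30 are
# RAch+, MG31 is the single MuSK+ case, MG32-MG40 are double-seronegative.
_SUBJECT_ROWS: list[tuple] = [
    ("MG01", "A*02:01", "A*02:36", "B*08:01", "B*40:01", "C*01:01", "C*07:01",
     "DRB1*01:01", "DRB1*03:01", "DQB1*02:01", "DQB1*05:01",
     "F", 25, "EOMG", "IIA", "RAchPos", "thymoma", 1, "none"),
    ("MG02", "A*01:01", "A*02:01", "B*18:01", "B*40:01", "C*02:01", "C*07:01",
     "DRB1*01:01", "DRB1*07:01", "DQB1*02:01", "DQB1*05:01",
     "F", 30, "EOMG", "IIA", "RAchPos", "thymoma", 1, "none"),
    ("MG03", "A*01:01", "A*02:01", "B*35:01", "B*40:01", "C*02:01", "C*07:01",
     "DRB1*01:01", "DRB1*11:01", "DQB1*02:01", "DQB1*05:01",
     "F", 35, "EOMG", "IIB", "RAchPos", "thymoma", 1, "none"),
    ("MG04", "A*01:01", "A*03:01", "B*35:01", "B*40:01", "C*02:01", "C*07:01",
     "DRB1*01:01", "DRB1*11:01", "DQB1*02:01", "DQB1*05:01",
     "F", 40, "EOMG", "IIB", "RAchPos", "follicular_hyperplasia", 1, "none"),
    ("MG05", "A*01:01", "A*03:01", "B*40:01", "B*47:27", "C*02:01", "C*07:01",
     "DRB1*01:01", "DRB1*14:01", "DQB1*02:01", "DQB1*05:01",
     "F", 45, "EOMG", "V", "RAchPos", "normal_ct", 0, "none"),
    ("MG06", "A*01:01", "A*03:01", "B*40:01", "B*51:01", "C*02:01", "C*07:01",
     "DRB1*01:01", "DRB1*15:01", "DQB1*02:01", "DQB1*05:01",
     "F", 47, "EOMG", "V", "RAchPos", "normal_ct", 0, "none"),
    ("MG07", "A*01:01", "A*24:01", "B*07:01", "B*35:01", "C*02:01", "C*07:01",
     "DRB1*01:01", "DRB1*16:01", "DQB1*02:01", "DQB1*05:01",
     "F", 15, "MGj", "IIA", "RAchPos", "follicular_hyperplasia", 1, "none"),
    ("MG08", "A*01:01", "A*24:01", "B*07:01", "B*35:01", "C*03:01", "C*07:01",
     "DRB1*03:01", "DRB1*14:54", "DQB1*02:01", "DQB1*05:01",
     "F", 16, "MGj", "IIA", "RAchPos", "follicular_hyperplasia", 1, "none"),
    ("MG09", "A*01:01", "A*32:01", "B*07:01", "B*44:27", "C*03:01", "C*07:01",
     "DRB1*03:01", "DRB1*14:54", "DQB1*03:01", "DQB1*05:01",
     "F", 28, "EOMG", "I", "RAchPos", "thymoma", 1, "none"),
    ("MG10", "A*01:01", "A*32:01", "B*08:01", "B*15:01", "C*03:01", "C*07:01",
     "DRB1*03:01", "DRB1*15:01", "DQB1*03:01", "DQB1*05:01",
     "F", 32, "EOMG", "I", "RAchPos", "thymoma", 1, "none"),
    ("MG11", "A*02:01", "A*02:01", "B*08:01", "B*18:01", "C*03:01", "C*07:01",
     "DRB1*03:01", "DRB1*16:01", "DQB1*03:01", "DQB1*05:01",
     "F", 36, "EOMG", "I", "RAchPos", "follicular_hyperplasia", 1, "none"),
    ("MG12", "A*02:01", "A*02:01", "B*08:01", "B*35:01", "C*03:01", "C*07:01",
     "DRB1*03:01", "DRB1*16:01", "DQB1*03:01", "DQB1*05:01",
     "F", 38, "EOMG", "I", "RAchPos", "normal_ct", 1, "none"),
    ("MG13", "A*02:01", "A*02:01", "B*08:01", "B*38:01", "C*04:01", "C*07:01",
     "DRB1*03:01", "DRB1*16:01", "DQB1*03:01", "DQB1*05:01",
     "F", 42, "EOMG", "IIB", "RAchPos", "normal_ct", 0, "titin_and_ryr"),
    ("MG14", "A*02:01", "A*02:01", "B*08:01", "B*39:01", "C*04:01", "C*07:01",
     "DRB1*04:01", "DRB1*15:01", "DQB1*03:01", "DQB1*05:01",
     "F", 55, "LOMG", "IIB", "RAchPos", "normal_ct", 0, "titin_and_ryr"),
    ("MG15", "A*02:01", "A*11:01", "B*08:01", "B*44:01", "C*04:01", "C*07:01",
     "DRB1*04:01", "DRB1*15:01", "DQB1*03:01", "DQB1*05:01",
     "F", 60, "LOMG", "IIA", "RAchPos", "normal_ct", 0, "titin_only"),
    ("MG16", "A*02:01", "A*24:01", "B*08:01", "B*44:01", "C*04:01", "C*07:01",
     "DRB1*04:01", "DRB1*15:01", "DQB1*03:01", "DQB1*05:01",
     "F", 44, "EOMG", "I", "RAchPos", "normal_ct", 0, "none"),
    ("MG17", "A*02:01", "A*24:01", "B*08:01", "B*73:01", "C*04:01", "C*12:01",
     "DRB1*04:01", "DRB1*16:01", "DQB1*03:01", "DQB1*05:01",
     "F", 52, "LOMG", "IIA", "RAchPos", "thymoma", 0, "none"),
    ("MG18", "A*02:01", "A*25:01", "B*13:01", "B*35:01", "C*04:01", "C*12:01",
     "DRB1*04:01", "DRB1*16:01", "DQB1*03:01", "DQB1*05:01",
     "F", 58, "LOMG", "IIA", "RAchPos", "follicular_hyperplasia", 0, "none"),
    ("MG19", "A*02:01", "A*26:01", "B*13:01", "B*51:01", "C*04:01", "C*12:01",
     "DRB1*04:01", "DRB1*16:01", "DQB1*03:01", "DQB1*05:01",
     "F", 62, "LOMG", "IIA", "RAchPos", "normal_ct", 0, "none"),
    ("MG20", "A*02:01", "A*26:01", "B*15:01", "B*18:01", "C*05:01", "C*12:01",
     "DRB1*07:01", "DRB1*11:01", "DQB1*03:01", "DQB1*05:01",
     "F", 65, "LOMG", "IIA", "RAchPos", "normal_ct", 0, "none"),
    ("MG21", "A*02:01", "A*29:01", "B*18:01", "B*39:01", "C*06:01", "C*12:01",
     "DRB1*07:01", "DRB1*15:01", "DQB1*03:01", "DQB1*06:01",
     "F", 68, "LOMG", "IIA", "RAchPos", "normal_ct", 0, "none"),
    ("MG22", "A*02:01", "A*32:01", "B*18:01", "B*44:01", "C*06:01", "C*12:01",
     "DRB1*10:01", "DRB1*16:01", "DQB1*03:01", "DQB1*06:01",
     "F", 78, "LOMG", "IIA", "RAchPos", "normal_ct", 0, "none"),
    ("MG23", "A*03:01", "A*32:01", "B*18:01", "B*51:01", "C*06:01", "C*12:01",
     "DRB1*11:01", "DRB1*11:01", "DQB1*03:01", "DQB1*06:01",
     "M", 24, "EOMG", "IIA", "RAchPos", "normal_ct", 0, "none"),
    ("MG24", "A*03:01", "A*33:01", "B*27:01", "B*35:01", "C*06:01", "C*14:01",
     "DRB1*11:01", "DRB1*12:01", "DQB1*03:01", "DQB1*06:01",
     "M", 54, "LOMG", "IIB", "RAchPos", "thymoma", 0, "none"),
    ("MG25", "A*11:01", "A*24:01", "B*27:01", "B*51:01", "C*06:01", "C*15:01",
     "DRB1*11:01", "DRB1*15:01", "DQB1*03:01", "DQB1*06:01",
     "M", 57, "LOMG", "IIB", "RAchPos", "follicular_hyperplasia", 0, "none"),
    ("MG26", "A*23:01", "A*68:01", "B*27:01", "B*57:02", "C*06:01", "C*15:01",
     "DRB1*11:01", "DRB1*15:01", "DQB1*05:01", "DQB1*06:01",
     "M", 33, "EOMG", "IIB", "RAchPos", "follicular_hyperplasia", 0, "none"),
    ("MG27", "A*24:01", "A*24:01", "B*35:01", "B*44:01", "C*06:01", "C*15:01",
     "DRB1*11:01", "DRB1*16:01", "DQB1*05:01", "DQB1*06:01",
     "M", 37, "EOMG", "IIB", "RAchPos", "normal_ct", 0, "none"),
    ("MG28", "A*24:01", "A*25:01", "B*35:01", "B*52:01", "C*07:01", "C*15:01",
     "DRB1*11:01", "DRB1*16:01", "DQB1*05:01", "DQB1*06:01",
     "M", 41, "EOMG", "IIIB", "RAchPos", "normal_ct", 0, "none"),
    ("MG29", "A*26:01", "A*26:01", "B*38:01", "B*57:02", "C*07:01", "C*16:01",
     "DRB1*14:01", "DRB1*16:01", "DQB1*05:01", "DQB1*06:01",
     "M", 46, "EOMG", "IIIB", "RAchPos", "normal_ct", 0, "none"),
    ("MG30", "A*31:01", "A*32:01", "B*44:01", "B*51:01", "C*07:01", "C*16:01",
     "DRB1*15:01", "DRB1*16:02", "", "",
     "M", 48, "EOMG", "V", "RAchPos", "normal_ct", 0, "none"),
    ("MG31", "A*01:01", "A*01:01", "B*08:01", "B*51:01", "C*07:01", "C*12:01",
     "DRB1*07:01", "DRB1*14:54", "DQB1*03:01", "DQB1*05:01",
     "F", 39, "EOMG", "V", "MuSKPos", "normal_ct", 0, "none"),
    ("MG32", "A*02:01", "A*30:01", "B*40:01", "B*47:27", "C*01:01", "C*07:01",
     "DRB1*04:01", "DRB1*13:02", "DQB1*02:01", "DQB1*05:01",
     "F", 1, "MGj", "IIB", "dSNMG", "normal_ct", 1, "none"),
    ("MG33", "A*25:01", "A*33:01", "B*18:01", "B*40:01", "C*01:01", "C*07:01",
     "DRB1*10:01", "DRB1*14:54", "DQB1*02:01", "DQB1*05:01",
     "F", 66, "LOMG", "IIA", "dSNMG", "normal_ct", 0, "none"),
    ("MG34", "A*02:01", "A*03:01", "B*08:01", "B*55:01", "C*01:01", "C*07:01",
     "DRB1*03:01", "DRB1*11:01", "DQB1*02:01", "DQB1*05:01",
     "F", 50, "LOMG", "V", "dSNMG", "thymoma", 0, "none"),
    ("MG35", "A*01:01", "A*02:01", "B*51:01", "B*58:01", "C*02:01", "C*07:01",
     "DRB1*01:01", "DRB1*07:01", "DQB1*03:01", "DQB1*05:01",
     "F", 53, "LOMG", "V", "dSNMG", "thymoma", 0, "none"),
    ("MG36", "A*01:01", "A*02:01", "B*08:01", "B*18:01", "C*02:01", "C*07:01",
     "DRB1*07:01", "DRB1*11:01", "DQB1*03:01", "DQB1*05:01",
     "F", 63, "LOMG", "V", "dSNMG", "follicular_hyperplasia", 0, "none"),
    ("MG37", "A*02:01", "A*24:01", "B*18:01", "B*38:01", "C*03:01", "C*06:01",
     "DRB1*01:01", "DRB1*14:54", "DQB1*03:01", "DQB1*05:01",
     "F", 22, "EOMG", "V", "dSNMG", "follicular_hyperplasia", 0, "none"),
    ("MG38", "A*02:01", "A*24:01", "B*13:01", "B*27:01", "C*04:01", "C*06:01",
     "DRB1*11:01", "DRB1*16:01", "DQB1*03:01", "DQB1*05:01",
     "F", 26, "EOMG", "IIB", "dSNMG", "normal_ct", 0, "none"),
    ("MG39", "A*02:01", "A*24:01", "B*35:01", "B*44:27", "C*12:01", "C*14:01",
     "DRB1*11:01", "DRB1*16:01", "DQB1*03:01", "DQB1*06:01",
     "F", 29, "EOMG", "IIA", "dSNMG", "normal_ct", 0, "none"),
    ("MG40", "A*02:01", "A*24:01", "B*35:01", "B*51:01", "C*12:01", "C*15:01",
     "DRB1*14:01", "DRB1*15:01", "DQB1*05:01", "DQB1*06:01",
     "F", 31, "EOMG", "IIB", "dSNMG", "normal_ct", 0, "none"),
]


def build_reference_cohort(seed: int = 0) -> Cohort:
    """Materialise the deterministic reconstructed cohort.

    *seed* is accepted for interface uniformity with the samplers; the
    construction is fully deterministic and the result is identical for
    every seed.  The published marginal allele counts are re-checked on
    every build and any mismatch raises naming the offending locus.
    """
    del seed  # deterministic construction
    cohort: Cohort = []
    for row in _SUBJECT_ROWS:
        sid = row[0]
        genotype: dict[str, tuple[AlleleName, AlleleName]] = {}
        for i, locus in enumerate(LOCI):
            a1, a2 = row[1 + 2 * i], row[2 + 2 * i]
            if not a1 and not a2:
                continue
            pair = (parse_allele_name(a1), parse_allele_name(a2))
            genotype[locus] = pair
        sex, age, onset, mgfa, serotype, thymic, autoimmune, titin = row[11:]
        meta = SubjectMeta(
            subject_id=sid, sex=sex, age_at_onset=float(age), onset_class=onset,
            mgfa_max=mgfa, serotype=serotype, thymic_status=thymic,
            autoimmune_comorbidity=bool(autoimmune), titin_ryr=titin,
        )
        cohort.append((GenotypeRecord(subject_id=sid, genotype=genotype), meta))

    _validate_margins(cohort)
    return cohort


def _validate_margins(cohort: Cohort) -> None:
    for locus, expected in MG_ALLELE_COUNTS.items():
        table = count_alleles(cohort, locus, resolution=1)
        got = {str(a): c for a, c in table.counts.items()}
        if got != expected:
            diff = {
                k: (expected.get(k, 0), got.get(k, 0))
                for k in set(expected) | set(got)
                if expected.get(k, 0) != got.get(k, 0)
            }
            raise ValueError(
                f"reconstructed cohort violates published {locus} allele counts: "
                f"{diff}"
            )


# --------------------------------------------------------------------------
# Packaged-data loaders.
# --------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(resources.files("hlacc").joinpath("data", name))


def load_reference_cohort() -> Cohort:
    """Read the frozen cohort TSV shipped with the package."""
    return read_cohort(_data_path("reference_cohort.tsv"))


def load_reference_panel(resolution: int) -> FrequencyPanel:
    """Read a shipped reference panel (1 = two-digit, 2 = four-digit)."""
    if resolution == 1:
        return read_frequency_panel(_data_path("panel_lowres.tsv"), 1, name="lowres")
    if resolution == 2:
        return read_frequency_panel(_data_path("panel_highres.tsv"), 2, name="highres")
    raise ValueError("resolution must be 1 or 2")


def load_national_frequencies() -> dict[AlleleName, float]:
    return {parse_allele_name(a): f for a, f in NATIONAL_FREQUENCIES.items()}


def build_panel(resolution: int) -> FrequencyPanel:
    """Build a reference panel directly from the in-code constants."""
    spec = PANEL_LOWRES if resolution == 1 else PANEL_HIGHRES
    loci = {
        locus: LocusPanel(
            total_allele_count=total,
            frequencies={parse_allele_name(a): f for a, f in freqs.items()},
        )
        for locus, (total, freqs) in spec.items()
    }
    name = "lowres" if resolution == 1 else "highres"
    return FrequencyPanel(name=name, resolution=resolution, loci=loci)


# --------------------------------------------------------------------------
# Control genotype-pair fixtures.
# --------------------------------------------------------------------------

# Published control genotype-pair frequencies (percent of control subjects).
_CONTROL_PAIR_PCT: dict[str, tuple[int, dict[tuple[str, str], float]]] = {
    "A": (373, {
        ("A*01", "A*01"): 2.41, ("A*01", "A*02"): 10.46, ("A*01", "A*03"): 1.61,
        ("A*01", "A*24"): 4.29, ("A*01", "A*32"): 0.80, ("A*02", "A*02"): 6.97,
        ("A*02", "A*03"): 6.43, ("A*02", "A*11"): 4.02, ("A*02", "A*24"): 6.17,
        ("A*02", "A*25"): 1.34, ("A*02", "A*26"): 2.95, ("A*02", "A*30"): 1.07,
        ("A*02", "A*32"): 2.14, ("A*03", "A*32"): 0.54, ("A*11", "A*24"): 0.80,
        ("A*24", "A*24"): 1.88, ("A*24", "A*25"): 1.61, ("A*31", "A*32"): 0.80,
    }),
    "B": (371, {
        ("B*07", "B*35"): 1.62, ("B*07", "B*44"): 1.35, ("B*08", "B*15"): 0.27,
        ("B*08", "B*18"): 2.70, ("B*08", "B*35"): 1.89, ("B*08", "B*38"): 0.27,
        ("B*08", "B*39"): 0.81, ("B*08", "B*40"): 1.08, ("B*08", "B*44"): 1.08,
        ("B*08", "B*51"): 1.35, ("B*13", "B*35"): 0.81, ("B*13", "B*51"): 1.35,
        ("B*15", "B*18"): 1.89, ("B*18", "B*38"): 1.08, ("B*18", "B*39"): 0.27,
        ("B*18", "B*40"): 1.35, ("B*18", "B*44"): 2.16, ("B*18", "B*51"): 2.70,
        ("B*27", "B*35"): 0.81, ("B*27", "B*51"): 0.54, ("B*27", "B*57"): 0.27,
        ("B*35", "B*40"): 1.62, ("B*35", "B*44"): 2.16, ("B*35", "B*51"): 2.16,
        ("B*35", "B*52"): 1.35, ("B*38", "B*57"): 0.27, ("B*40", "B*51"): 0.81,
        ("B*44", "B*51"): 1.35, ("B*51", "B*58"): 0.27,
        # Not published as a count; fixed at 11/371 (2.97%), the smallest
        # completion consistent with the reported control disequilibrium
        # of the B*15-B*35 pair exceeding 2 percentage points.
        ("B*15", "B*35"): 2.965,
    }),
    "DRB1": (134, {
        ("DRB1*01", "DRB1*03"): 3.73, ("DRB1*01", "DRB1*07"): 0.75,
        ("DRB1*01", "DRB1*11"): 2.24, ("DRB1*01", "DRB1*14"): 0.75,
        ("DRB1*01", "DRB1*15"): 0.75, ("DRB1*01", "DRB1*16"): 0.75,
        ("DRB1*03", "DRB1*11"): 2.99, ("DRB1*03", "DRB1*14"): 2.24,
        ("DRB1*03", "DRB1*15"): 2.99, ("DRB1*03", "DRB1*16"): 2.24,
        ("DRB1*04", "DRB1*13"): 2.99, ("DRB1*04", "DRB1*15"): 1.49,
        ("DRB1*04", "DRB1*16"): 1.49, ("DRB1*07", "DRB1*11"): 5.22,
        ("DRB1*07", "DRB1*14"): 0.75, ("DRB1*07", "DRB1*15"): 0.75,
        ("DRB1*11", "DRB1*11"): 2.99, ("DRB1*11", "DRB1*12"): 0.75,
        ("DRB1*11", "DRB1*15"): 4.48, ("DRB1*11", "DRB1*16"): 5.22,
        ("DRB1*14", "DRB1*16"): 2.99, ("DRB1*15", "DRB1*16"): 2.24,
    }),
}


def control_pair_fixture(locus: str) -> GenotypePairTable:
    """Deterministic control genotype-pair table for *locus*.

    Published pair frequencies are converted to integer counts of the
    published control sample size; the unpublished remainder of the sample
    is completed deterministically in proportion to random-union (HWE)
    expectations computed from the two-digit reference panel, via largest
    remainder allocation over the pairs without a published count.
    """
    if locus not in _CONTROL_PAIR_PCT:
        raise KeyError(f"no control pair data for locus {locus!r}")
    n, pct = _CONTROL_PAIR_PCT[locus]
    fixed: dict[tuple[AlleleName, AlleleName], int] = {}
    for (x, y), p in pct.items():
        key = tuple(sorted((parse_allele_name(x), parse_allele_name(y))))
        count = int(round(p * n / 100.0))
        if count > 0:
            fixed[key] = count
    remaining = n - sum(fixed.values())
    if remaining < 0:
        raise ValueError(f"published {locus} control pairs exceed the sample size")

    _, freqs = PANEL_LOWRES[locus]
    alleles = sorted(parse_allele_name(a) for a, f in freqs.items() if f > 0)
    fmap = {parse_allele_name(a): f for a, f in freqs.items()}
    weights: dict[tuple[AlleleName, AlleleName], float] = {}
    for i, x in enumerate(alleles):
        for y in alleles[i:]:
            key = (x, y)
            if key in fixed:
                continue
            prob = fmap[x] ** 2 if x == y else 2 * fmap[x] * fmap[y]
            if prob > 0:
                weights[key] = prob

    counts = dict(fixed)
    counts.update(_largest_remainder(weights, remaining))
    counts = {k: v for k, v in counts.items() if v > 0}
    return GenotypePairTable(locus=locus, resolution=1, pair_counts=counts, n_subjects=n)


def _largest_remainder(weights: dict, total: int) -> dict:
    """Allocate *total* integer units proportionally to *weights*."""
    if total == 0 or not weights:
        return {}
    wsum = sum(weights.values())
    quotas = {k: total * w / wsum for k, w in weights.items()}
    alloc = {k: int(q) for k, q in quotas.items()}
    leftover = total - sum(alloc.values())
    order = sorted(
        weights, key=lambda k: (-(quotas[k] - alloc[k]), str(k[0]), str(k[1]))
    )
    for k in order[:leftover]:
        alloc[k] += 1
    return alloc


# --------------------------------------------------------------------------
# Carrier-phenotype trait battery.
# --------------------------------------------------------------------------

TABLE3_TRAITS: list[tuple[str, callable]] = [
    ("female", lambda m: m.sex == "F"),
    ("EOMG", lambda m: m.onset_class == "EOMG"),
    ("LOMG", lambda m: m.onset_class == "LOMG"),
    ("MGj", lambda m: m.onset_class == "MGj"),
    ("mgfa_I", lambda m: m.mgfa_max == "I"),
    ("mgfa_IIA", lambda m: m.mgfa_max == "IIA"),
    ("mgfa_V", lambda m: m.mgfa_max == "V"),
    ("bulbar", lambda m: m.mgfa_max in ("IIB", "IIIB")),
    ("autoimmune_comorbidity", lambda m: m.autoimmune_comorbidity),
    ("thymoma", lambda m: m.thymic_status == "thymoma"),
    ("follicular_hyperplasia", lambda m: m.thymic_status == "follicular_hyperplasia"),
]


# --------------------------------------------------------------------------
# Data regeneration (used once to freeze the packaged TSVs).
# --------------------------------------------------------------------------

def regenerate_data(data_dir: str | Path | None = None) -> None:
    """Rewrite the packaged TSV data files from the in-code constants."""
    import pandas as pd

    from .cohort import write_cohort, write_frequency_panel

    data_dir = Path(data_dir) if data_dir else _data_path("").parent / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    write_cohort(build_reference_cohort(), data_dir / "reference_cohort.tsv")
    write_frequency_panel(build_panel(1), data_dir / "panel_lowres.tsv")
    write_frequency_panel(build_panel(2), data_dir / "panel_highres.tsv")
    rows = [
        {"allele": a, "frequency": repr(f), "frequency_unit": "fraction"}
        for a, f in NATIONAL_FREQUENCIES.items()
    ]
    pd.DataFrame(rows).to_csv(data_dir / "national_frequencies.tsv", sep="\t", index=False)
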