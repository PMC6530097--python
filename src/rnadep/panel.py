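"""The bovine milk-protein depletion panel: published assay and benchmark data.

This module packages the wet-lab-validated assay that motivated the tool: the
twelve antisense capture oligonucleotides against the six milk-protein genes
(casein cluster CSN1S1/CSN1S2/CSN2/CSN3 and whey genes LALBA/PAEP), the two
concentration schemes (A: abundance-informed, B: equimolar 25 uM), and the
per-sample benchmark fractions of sequencing fragments assigned to each
target in the validation experiment (three lactating cows, one E. coli
challenged and one control udder quarter each, libraries without depletion
(0) and with depletion variants A and B).

These data serve as ground truth for calibrating the designer's default Tm
conditions and as the reference input for the evaluation statistics.
"""

from __future__ import annotations

import pandas as pd

TARGET_GENES = ("LALBA", "CSN1S1", "CSN3", "CSN2", "CSN1S2", "PAEP")

#: capture oligo sequences (antisense, 5'->3'), two per target gene
CAPTURE_OLIGOS: dict[str, str] = {
    "LGB_R5": "GGGCTCACCTAGATGTGGCACTGCTC",
    "LGB_R6": "GCTCAGCACTGTTCTCCATGCAGAAG",
    "LALBA_R6": "GTCATCAGTAAGATCATCATCCAGGAAC",
    "LALBA_R7": "CAGAACAGAGTGCTTTATGGGCCAACC",
    "CSN1S2_R3": "ATAACCAGGTAGAAGCAGTTAATTCCAG",
    "CSN1S2_R4": "ATGCTGGTTGTATGAAGTAAAGTGGTAG",
    "CSN1S1_R7": "TCAGAATTCACTTGACTCCTCACCACAG",
    "CSN1S1_R8": "TAGGATTAGGGATGTCAGAGAATGATGG",
    "CSN3_R6": "GTAAGAGGAGACGAGGAAGGAGCCAG",
    "CSN3_R7": "ACTGTGTTGATCTCAGGTGGGCTCTC",
    "CSN2_R4": "TCCAGTCGCAGTCAATTCAAAAGTGAG",
    "CSN2_R5": "CTTTCTGGGGAACAGGCAGGACTTTG",
}

#: oligo pair per target gene (the PAEP oligos carry the legacy LGB name)
OLIGOS_BY_GENE: dict[str, tuple[str, str]] = {
    "PAEP": ("LGB_R5", "LGB_R6"),
    "LALBA": ("LALBA_R6", "LALBA_R7"),
    "CSN1S2": ("CSN1S2_R3", "CSN1S2_R4"),
    "CSN1S1": ("CSN1S1_R7", "CSN1S1_R8"),
    "CSN3": ("CSN3_R6", "CSN3_R7"),
    "CSN2": ("CSN2_R4", "CSN2_R5"),
}

#: final per-oligo concentration (uM) in the hybridization assay, scheme A
#: (abundance-informed) and scheme B (equimolar)
CONCENTRATIONS_UM: dict[str, dict[str, float]] = {
    "A": {"PAEP": 16.66, "LALBA": 16.66, "CSN1S2": 8.33,
          "CSN1S1": 16.66, "CSN3": 9.0, "CSN2": 25.0},
    "B": {g: 25.0 for g in TARGET_GENES},
}

# Percentage of assigned fragments per target gene and sample in the bovine
# validation study.  Samples: 3 cows x {non_challenged, challenged} x
# treatments {0 = no depletion, A, B}.  Gene column order: LALBA, CSN1S1,
# CSN3, CSN2, CSN1S2, PAEP.
_BENCHMARK_ROWS = [
    ("non_challenged", 1, "0", 2.7, 15.7, 11.5, 31.1, 4.2, 5.5),
    ("non_challenged", 1, "A", 3.1, 17.9, 0.6, 9.6, 0.3, 4.5),
    ("non_challenged", 1, "B", 2.6, 12.2, 0.2, 8.7, 0.2, 5.9),
    ("non_challenged", 2, "0", 0.8, 18.7, 9.6, 14.3, 4.9, 3.9),
    ("non_challenged", 2, "A", 0.5, 18.7, 0.8, 3.1, 0.1, 2.2),
    ("non_challenged", 2, "B", 0.4, 16.4, 0.2, 2.8, 0.1, 2.0),
    ("non_challenged", 3, "0", 1.0, 16.7, 9.5, 21.6, 4.9, 7.4),
    ("non_challenged", 3, "A", 1.0, 14.3, 0.7, 4.2, 0.1, 5.2),
    ("non_challenged", 3, "B", 0.8, 11.6, 0.1, 3.8, 0.1, 5.0),
    ("challenged", 1, "0", 1.1, 15.2, 11.1, 21.9, 3.3, 4.3),
    ("challenged", 1, "A", 1.0, 12.1, 0.6, 5.9, 0.1, 3.8),
    ("challenged", 1, "B", 0.9, 9.0, 0.2, 5.4, 0.0, 4.0),
    ("challenged", 2, "0", 0.4, 12.3, 7.5, 6.3, 2.1, 4.2),
    ("challenged", 2, "A", 0.2, 6.2, 0.2, 2.2, 0.0, 1.8),
    ("challenged", 2, "B", 0.2, 4.5, 0.0, 1.4, 0.0, 1.7),
    ("challenged", 3, "0", 0.0, 0.1, 0.5, 0.1, 0.0, 0.0),
    ("challenged", 3, "A", 0.0, 0.1, 0.0, 0.0, 0.0, 0.0),
    ("challenged", 3, "B", 0.0, 0.0, 0.1, 0.0, 0.0, 0.0),
]


def benchmark_fractions() -> pd.DataFrame:
    """Published per-sample, per-target fragment percentages (long format).

    Columns: condition, animal, treatment, LALBA..PAEP (percent of all
    assigned fragments in that sample).
    """
    return pd.DataFrame(
        _BENCHMARK_ROWS,
        columns=["condition", "animal", "treatment", *TARGET_GENES])


#: genes crossing the FPKM>1 detection threshold only after (gained) / only
#: before (lost) depletion in the validation study, per variant, and the
#: number of genes above threshold without depletion
DETECTION_SHIFTS: dict[str, dict[str, int]] = {
    "A": {"total_above": 12773, "gained": 554, "lost": 315},
    "B": {"total_above": 12817, "gained": 582, "lost": 304},
}
DETECTION_BASELINE_ABOVE = 12546
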