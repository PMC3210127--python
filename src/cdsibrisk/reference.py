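"""Published reference values used as oracles and desk-scale inputs.

These are the printed results of the original sibling-risk study: the 5x12
Bayes-score table, the Fig-2 group medians, the median-split affected counts,
and integer confusion tables consistent with the printed diagnostic metrics
for 29 affected / 220 unaffected validation sibs.  The underlying cohort
genotypes were never released, so these tables are the only numeric anchor;
the package treats them as inputs for internal-consistency checks, never as
values to fit.
"""

from __future__ import annotations

#: Row order of the published score table: (LPP class, REL class, RGS1 class).
SCORE_TABLE_PROFILES: list[tuple[str, str, str]] = [
    ("CC", "AG|GG", "AC|CC"),
    ("CC", "AG|GG", "AA"),
    ("CC", "AA", "AC|CC"),
    ("CC", "AA", "AA"),
    ("AC", "AG|GG", "AC|CC"),
    ("AC", "AG|GG", "AA"),
    ("AC", "AA", "AC|CC"),
    ("AC", "AA", "AA"),
    ("AA", "AG|GG", "AC|CC"),
    ("AA", "AG|GG", "AA"),
    ("AA", "AA", "AC|CC"),
    ("AA", "AA", "AA"),
]

#: Published BS per profile for HLA groups 1..5 (None = combination not
#: observed in the study's sib cohort, value not printed).
SCORE_TABLE: dict[tuple[str, str, str], tuple[float, float, float | None, float, float]] = {
    ("CC", "AG|GG", "AC|CC"): (0.66, 0.63, 0.32, 0.30, 0.04),
    ("CC", "AG|GG", "AA"): (0.74, 0.73, 0.42, 0.39, 0.06),
    ("CC", "AA", "AC|CC"): (0.71, 0.69, 0.38, 0.35, 0.05),
    ("CC", "AA", "AA"): (0.79, 0.77, 0.48, 0.46, 0.08),
    ("AC", "AG|GG", "AC|CC"): (0.81, 0.80, 0.52, 0.49, 0.09),
    ("AC", "AG|GG", "AA"): (0.87, 0.86, 0.62, 0.60, 0.13),
    ("AC", "AA", "AC|CC"): (0.85, 0.84, 0.58, 0.55, 0.11),
    ("AC", "AA", "AA"): (0.90, 0.89, 0.68, 0.66, 0.16),
    ("AA", "AG|GG", "AC|CC"): (0.91, 0.90, None, 0.69, 0.18),
    ("AA", "AG|GG", "AA"): (0.94, 0.93, 0.79, 0.77, 0.25),
    ("AA", "AA", "AC|CC"): (0.93, 0.92, 0.76, 0.74, 0.22),
    ("AA", "AA", "AA"): (0.95, 0.95, 0.83, 0.81, 0.30),
}

#: Published median BS of all sibs within each HLA group (strip-plot lines).
GROUP_MEDIANS = {1: 0.90, 2: 0.86, 3: 0.62, 4: 0.60, 5: 0.13}

#: Median-split 2x2: affected sibs 21 high / 8 low as published; the
#: unaffected 112/108 split is a synthetic fixture consistent with the
#: published 220 unaffected sibs and a within-group median split.
MEDIAN_SPLIT_2X2 = {"tp": 21, "fn": 8, "fp": 112, "tn": 108}

#: Integer confusion tables for 29 affected / 220 unaffected reproducing the
#: published diagnostic metrics; the cells are the derived integer solution,
#: not printed in the study.
CONFUSION_HLA_SNPS = {"tp": 23, "fn": 6, "fp": 101, "tn": 119}
CONFUSION_HLA_ONLY = {"tp": 13, "fn": 16, "fp": 64, "tn": 156}

#: Published per-SNP genotypic TDT results (model, risk allele, OR, CI, p).
TDT_RESULTS = {
    "rs1464510": ("LPP", "additive", "A", 2.36, (1.64, 3.41), 0.001),
    "rs2816316": ("RGS1", "recessive", "A", 1.75, (1.07, 2.86), 0.025),
    "rs842647": ("REL", "recessive", "A", 1.66, (1.04, 2.65), 0.034),
}

#: Published C statistics for the HLA-only and HLA+SNP classifications.
C_STATISTICS = {"hla": 0.70, "bs": 0.73}


def score_column(group: int) -> dict[tuple[str, str, str], float | None]:
    """One HLA-group column of the published score table."""
    return {p: v[group - 1] for p, v in SCORE_TABLE.items()}


def single_factor_cells(group: int) -> tuple[float, list[float]]:
    """Baseline cell and the three single-factor cells of a group column.

    The baseline is the all-reference profile (CC, AG|GG, AC|CC); the single
    factor cells change exactly one factor to its top risk class (LPP AA,
    REL AA, RGS1 AA) — the inputs for the logit-additivity reconstruction.
    """
    col = score_column(group)
    base = col[("CC", "AG|GG", "AC|CC")]
    singles = [
        col[("AA", "AG|GG", "AC|CC")],
        col[("CC", "AA", "AC|CC")],
        col[("CC", "AG|GG", "AA")],
    ]
    if base is None or any(s is None for s in singles):
        raise ValueError(f"group {group}: required cells not printed")
    return base, singles
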