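"""Validation-set risk classification and diagnostic performance.

Sibs are labelled high/low risk by comparing their Bayes score with the
median score of all sibs in their HLA risk group (high iff BS >= median), or
by the flow-chart rule (groups 1-2 always high, group 5 always low, groups
3-4 decided by the median split).  Performance is summarised as a 2x2 odds
ratio (Woolf CI), sensitivity/specificity/NPV/PPV with Wald CIs, and the
C statistic (Mann-Whitney AUC with half weight for ties).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .bayes import ScoredSib

Z95 = stats.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# Median split


def median_split(scored_sibs: list[ScoredSib]) -> tuple[dict[int, float], list[bool]]:
    """Within-group median thresholds and per-sib high/low labels.

    The median is taken over ALL sibs (affected and unaffected) in each HLA
    group, with the usual midpoint convention for even n; a sib sitting
    exactly on the median is high.
    """
    by_group: dict[int, list[float]] = {}
    for s in scored_sibs:
        by_group.setdefault(s.group, []).append(s.bs)
    thresholds = {g: float(np.median(v)) for g, v in by_group.items()}
    labels = [s.bs >= thresholds[s.group] for s in scored_sibs]
    return thresholds, labels


def flowchart_classify(sib: ScoredSib, thresholds: dict[int, float]) -> bool:
    """Flow-chart rule: G1-2 high, G5 low, G3-4 by the group median split."""
    if sib.group in (1, 2):
        return True
    if sib.group == 5:
        return False
    if sib.group not in thresholds:
        raise KeyError(f"no median threshold available for HLA group {sib.group}")
    return sib.bs >= thresholds[sib.group]


# ---------------------------------------------------------------------------
# 2x2 machinery


@dataclass
class ConfusionCounts:
    """tp/fn = affected high/low; fp/tn = unaffected high/low."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n_affected(self) -> int:
        return self.tp + self.fn

    @property
    def n_unaffected(self) -> int:
        return self.fp + self.tn

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn}


@dataclass
class OddsRatioResult:
    odds_ratio: float
    ci95: tuple[float, float]
    p_value: float
    test: str  # "chi2" or "fisher"
    haldane_corrected: bool

    def to_dict(self) -> dict:
        return {
            "OR": self.odds_ratio,
            "CI_low": self.ci95[0],
            "CI_high": self.ci95[1],
            "p": self.p_value,
            "test": self.test,
            "haldane_corrected": self.haldane_corrected,
        }


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> OddsRatioResult:
    """OR = ad/bc with Woolf (log-scale) 95% CI.

    p comes from the Pearson chi-square unless any expected cell is < 5, in
    which case Fisher's exact test is used.  A zero cell triggers the Haldane
    0.5 correction (applied to all cells, flagged in the result).
    """
    cells = np.array([[a, b], [c, d]], float)
    if cells.sum() == 0:
        raise ValueError("empty 2x2 table")
    haldane = (cells == 0).any()
    work = cells + 0.5 if haldane else cells
    or_est = (work[0, 0] * work[1, 1]) / (work[0, 1] * work[1, 0])
    se = math.sqrt((1.0 / work).sum())
    log_or = math.log(or_est)
    ci = (math.exp(log_or - Z95 * se), math.exp(log_or + Z95 * se))

    expected = np.outer(cells.sum(1), cells.sum(0)) / cells.sum()
    if (expected < 5).any():
        p = float(stats.fisher_exact(cells)[1])
        test = "fisher"
    else:
        chi2, p, _, _ = stats.chi2_contingency(cells, correction=False)
        p = float(p)
        test = "chi2"
    return OddsRatioResult(or_est, ci, p, test, bool(haldane))


def _wald_ci(p: float, n: int) -> tuple[float, float]:
    if n <= 0 or math.isnan(p):
        return (math.nan, math.nan)
    se = math.sqrt(p * (1 - p) / n)
    return (max(0.0, p - Z95 * se), min(1.0, p + Z95 * se))


@dataclass
class DiagnosticReport:
    """Sensitivity/specificity/NPV/PPV with Wald CIs plus the 2x2 OR."""

    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    npv: float
    ppv: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    npv_ci: tuple[float, float]
    ppv_ci: tuple[float, float]
    odds_ratio: OddsRatioResult

    def to_dict(self) -> dict:
        return {
            "counts": self.counts.to_dict(),
            "sensitivity": self.sensitivity,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity": self.specificity,
            "specificity_ci": list(self.specificity_ci),
            "npv": self.npv,
            "npv_ci": list(self.npv_ci),
            "ppv": self.ppv,
            "ppv_ci": list(self.ppv_ci),
            "odds_ratio": self.odds_ratio.to_dict(),
        }


def diagnostic_metrics(counts: ConfusionCounts) -> DiagnosticReport:
    tp, fn, fp, tn = counts.tp, counts.fn, counts.fp, counts.tn
    if tp + fn == 0 or fp + tn == 0:
        raise ValueError("both an affected and an unaffected margin are required")
    sens = tp / (tp + fn)
    spec = tn / (fp + tn)
    # an empty predicted margin (e.g. a degenerate split that labels every
    # sib high) leaves the predictive value undefined, not the whole report
    npv = tn / (tn + fn) if tn + fn > 0 else math.nan
    ppv = tp / (tp + fp) if tp + fp > 0 else math.nan
    return DiagnosticReport(
        counts=counts,
        sensitivity=sens,
        specificity=spec,
        npv=npv,
        ppv=ppv,
        sensitivity_ci=_wald_ci(sens, tp + fn),
        specificity_ci=_wald_ci(spec, fp + tn),
        npv_ci=_wald_ci(npv, tn + fn),
        ppv_ci=_wald_ci(ppv, tp + fp),
        odds_ratio=odds_ratio_2x2(tp, fn, fp, tn),
    )


def c_statistic(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_affected > score_unaffected) + 0.5 P(tie)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)  # average ranks give ties weight 0.5
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


# ---------------------------------------------------------------------------
# Classifier comparison


def _confusion(scored: list[ScoredSib], high: list[bool]) -> ConfusionCounts:
    tp = sum(1 for s, h in zip(scored, high) if s.affected and h)
    fn = sum(1 for s, h in zip(scored, high) if s.affected and not h)
    fp = sum(1 for s, h in zip(scored, high) if not s.affected and h)
    tn = sum(1 for s, h in zip(scored, high) if not s.affected and not h)
    return ConfusionCounts(tp, fn, fp, tn)


@dataclass
class ClassifierComparison:
    thresholds: dict[int, float]
    reports: dict[str, DiagnosticReport]  # hla_only | bs_median | flowchart
    c_statistics: dict[str, float]  # hla | bs

    def to_dict(self) -> dict:
        return {
            "median_thresholds": {str(g): t for g, t in sorted(self.thresholds.items())},
            "classifiers": {k: r.to_dict() for k, r in self.reports.items()},
            "c_statistics": self.c_statistics,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    def summary(self) -> str:
        lines = ["Classifier comparison on the validation sibs", ""]
        lines.append(
            "median BS per HLA group: "
            + ", ".join(f"G{g}={t:.2f}" for g, t in sorted(self.thresholds.items()))
        )
        header = f"{'rule':<12}{'sens':>8}{'spec':>8}{'NPV':>8}{'PPV':>8}{'OR':>8}{'p':>10}"
        lines += ["", header]
        for name, r in self.reports.items():
            lines.append(
                f"{name:<12}{r.sensitivity:>8.2f}{r.specificity:>8.2f}"
                f"{r.npv:>8.2f}{r.ppv:>8.2f}"
                f"{r.odds_ratio.odds_ratio:>8.2f}{r.odds_ratio.p_value:>10.3g}"
            )
        lines.append("")
        lines.append(
            "C statistic: HLA ordinal "
            f"{self.c_statistics['hla']:.2f}, HLA+SNP BS {self.c_statistics['bs']:.2f}"
        )
        return "\n".join(lines)


def evaluate_classifiers(scored_sibs: list[ScoredSib]) -> ClassifierComparison:
    """Confusion tables, metrics and C statistics for the three rules:
    HLA-only (high = groups 1-2), BS >= group median, and the flow-chart."""
    labelled = [s for s in scored_sibs if s.affected is not None]
    thresholds, median_high = median_split(labelled)
    hla_high = [s.group in (1, 2) for s in labelled]
    flow_high = [flowchart_classify(s, thresholds) for s in labelled]
    reports = {
        "hla_only": diagnostic_metrics(_confusion(labelled, hla_high)),
        "bs_median": diagnostic_metrics(_confusion(labelled, median_high)),
        "flowchart": diagnostic_metrics(_confusion(labelled, flow_high)),
    }
    affected = [bool(s.affected) for s in labelled]
    c_stats = {
        "hla": c_statistic([6 - s.group for s in labelled], affected),
        "bs": c_statistic([s.bs for s in labelled], affected),
    }
    return ClassifierComparison(thresholds=thresholds, reports=reports, c_statistics=c_stats)


def strip_plot(scored_sibs: list[ScoredSib], path) -> None:
    """BS-by-HLA-group strip plot with group median lines (validation view)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    thresholds, _ = median_split(scored_sibs)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    rng = np.random.default_rng(0)  # jitter only, cosmetic
    for s in scored_sibs:
        x = s.group + rng.uniform(-0.18, 0.18)
        ax.plot(
            x, s.bs,
            "o" if s.affected else ".",
            color="crimson" if s.affected else "steelblue",
            ms=6 if s.affected else 4, alpha=0.8,
        )
    for g, t in thresholds.items():
        ax.hlines(t, g - 0.3, g + 0.3, color="black", lw=1.5)
    ax.set_xticks([1, 2, 3, 4, 5], [f"G{g}" for g in range(1, 6)])
    ax.set_xlabel("HLA risk group")
    ax.set_ylabel("Bayes score")
    ax.set_title("Sib Bayes scores by HLA group (lines: group medians)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
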