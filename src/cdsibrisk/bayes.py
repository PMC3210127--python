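"""Sequential Bayesian HLA+SNP genotype score.

A prior disease probability is updated by the case/control likelihood ratio
of the HLA risk group and then of each associated SNP genotype class.  On the
odds scale each update multiplies by LR = f_case/f_ctrl, so the final score
is order-invariant:

    posterior = prior*f_case / (prior*f_case + (1-prior)*f_ctrl)
    posterior_odds = prior_odds * prod_k LR_k

The score ("BS") is a ranking of genotype combinations within and across the
five HLA risk groups, not a calibrated absolute risk.  Factors are assumed
conditionally independent given case/control status — the model behind
chaining the updates — consistent with the absence of HLA x SNP interaction
in the association scan.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import product

import pandas as pd

from .panel import Panel
from .pedigree import MISSING, Cohort, Person, assign_hla_group
from .tdt import MODELS, AfbacFrequencies, InheritanceModel, afbac_frequencies, select_model

HLA_KEY = "HLA"

#: Default per-group a priori sibling risks: midpoints of the published risk
#: ranges (>20%, 15-20%, 10-15%, 1-10%, <1%) for groups 1..5.
DEFAULT_HLA_RISK_PRIORS = {1: 0.21, 2: 0.175, 3: 0.125, 4: 0.055, 5: 0.005}


def bayes_update(prior: float, f_case: float, f_ctrl: float) -> float:
    """One Bayes step: posterior odds = prior odds * (f_case / f_ctrl)."""
    if not 0.0 < prior < 1.0:
        raise ValueError(f"prior must lie strictly in (0,1), got {prior}")
    if f_case <= 0 or f_ctrl <= 0:
        raise ValueError("category frequencies must be positive (apply smoothing)")
    return prior * f_case / (prior * f_case + (1.0 - prior) * f_ctrl)


def _posterior_from_lrs(prior: float, lrs) -> float:
    odds = prior / (1.0 - prior)
    for lr in lrs:
        if lr <= 0 or not math.isfinite(lr):
            raise ValueError(f"likelihood ratio must be finite and positive, got {lr}")
        odds *= lr
    return odds / (1.0 + odds)


@dataclass
class LikelihoodRatioTable:
    """Per-factor case/control category frequencies.

    ``factors`` maps a factor name ("HLA" or a locus id) to a mapping from
    category label to (f_case, f_ctrl).  Within each factor both frequency
    vectors sum to one.
    """

    factors: dict[str, dict[object, tuple[float, float]]]
    snp_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, cats in self.factors.items():
            for s in (0, 1):
                tot = sum(v[s] for v in cats.values())
                if abs(tot - 1.0) > 1e-9:
                    raise ValueError(f"{name}: frequencies sum to {tot}, not 1")
        if not self.snp_order:
            self.snp_order = [k for k in self.factors if k != HLA_KEY]

    @classmethod
    def from_afbac(cls, tables: dict[str, AfbacFrequencies], snp_order=None):
        factors = {
            name: {c: (t.f_case[c], t.f_ctrl[c]) for c in t.categories}
            for name, t in tables.items()
        }
        return cls(factors, snp_order=list(snp_order or []))

    def lr(self, factor: str, category) -> float:
        fc, f0 = self.factors[factor][category]
        return fc / f0

    def categories(self, factor: str) -> list:
        return list(self.factors[factor])

    def to_dict(self) -> dict:
        return {
            name: {str(c): {"f_case": v[0], "f_ctrl": v[1], "lr": v[0] / v[1]}
                   for c, v in cats.items()}
            for name, cats in self.factors.items()
        }


def compute_bs(
    group: int,
    profile: dict[str, object],
    lrt: LikelihoodRatioTable,
    prior: float = 0.5,
) -> float:
    """Chain the HLA update then each SNP-class update; order-invariant."""
    if HLA_KEY not in lrt.factors or group not in lrt.factors[HLA_KEY]:
        raise KeyError(f"HLA group {group} missing from likelihood-ratio table")
    lrs = [lrt.lr(HLA_KEY, group)]
    for locus in lrt.snp_order:
        if locus not in profile:
            raise KeyError(f"profile lacks class for {locus}")
        lrs.append(lrt.lr(locus, profile[locus]))
    bs = _posterior_from_lrs(prior, lrs)
    # smoothing keeps every LR finite, so the score is strictly interior
    assert 0.0 < bs < 1.0
    return bs


@dataclass
class ScoreTable:
    """BS for every (HLA group) x (SNP class profile) combination."""

    prior: float
    snp_order: list[str]
    snp_classes: dict[str, list[str]]
    scores: dict[tuple[int, tuple], float]
    groups: tuple[int, ...] = (1, 2, 3, 4, 5)

    @property
    def profiles(self) -> list[tuple]:
        return list(product(*(self.snp_classes[l] for l in self.snp_order)))

    def bs(self, group: int, profile: tuple) -> float:
        return self.scores[(group, tuple(profile))]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for profile in self.profiles:
            row = dict(zip(self.snp_order, profile))
            for g in self.groups:
                row[f"HLA Group {g}"] = self.scores[(g, profile)]
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        df = self.to_dataframe().copy()
        for g in self.groups:
            df[f"HLA Group {g}"] = df[f"HLA Group {g}"].map(lambda v: f"{v:.2f}")
        df.to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        doc = {
            "prior": self.prior,
            "snp_order": self.snp_order,
            "snp_classes": self.snp_classes,
            "scores": [
                {"group": g, "profile": list(p), "bs": v}
                for (g, p), v in sorted(self.scores.items())
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)
            fh.write("\n")


def build_score_table(lrt: LikelihoodRatioTable, prior: float = 0.5) -> ScoreTable:
    """Score every group x profile cell, including combinations never observed
    (smoothing guarantees each category has a finite LR)."""
    snp_classes = {l: lrt.categories(l) for l in lrt.snp_order}
    scores = {}
    for g in (1, 2, 3, 4, 5):
        for profile in product(*(snp_classes[l] for l in lrt.snp_order)):
            scores[(g, profile)] = compute_bs(
                g, dict(zip(lrt.snp_order, profile)), lrt, prior
            )
    return ScoreTable(
        prior=prior, snp_order=list(lrt.snp_order), snp_classes=snp_classes, scores=scores
    )


# ---------------------------------------------------------------------------
# Scoring the validation set


@dataclass
class ScoredSib:
    person: Person
    group: int
    profile: tuple
    bs: float

    @property
    def affected(self) -> bool | None:
        return self.person.affected


def sib_profile(person: Person, panel: Panel, snp_order, snp_models) -> tuple | None:
    """Collapsed class profile of a person; None if any genotype is missing."""
    classes = []
    for locus in snp_order:
        g = person.genotype(locus)
        if g is MISSING:
            return None
        classes.append(panel[locus].class_of_count(g, snp_models[locus].name))
    return tuple(classes)


def score_sibs(
    sibs: list[Person],
    table: ScoreTable,
    panel: Panel,
    snp_models: dict[str, InheritanceModel],
) -> tuple[list[ScoredSib], int]:
    """Attach the table BS to each sib; returns (scored, n_excluded_missing)."""
    scored, excluded = [], 0
    for sib in sibs:
        if sib.hla is None:
            excluded += 1
            continue
        profile = sib_profile(sib, panel, table.snp_order, snp_models)
        if profile is None:
            excluded += 1
            continue
        group = assign_hla_group(sib.hla)
        scored.append(ScoredSib(sib, group, profile, table.bs(group, profile)))
    return scored, excluded


# ---------------------------------------------------------------------------
# Refined risk (HLA-group priors instead of the flat 0.5)


def refined_risk(
    lrt: LikelihoodRatioTable,
    panel: Panel,
    snp_models: dict[str, InheritanceModel],
    priors: dict[int, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Risk per HLA group and SNP profile starting from per-group priors.

    Only the SNP updates are applied (HLA is already encoded in the prior).
    Returns (per-profile frame, per-allele-count frame); the count summary
    attributes 0..2 alleles to additive classes and risk-indicator*2 to
    collapsed classes, averaging profiles with equal total count.
    """
    priors = priors or DEFAULT_HLA_RISK_PRIORS
    if any(not 0 < v < 1 for v in priors.values()):
        raise ValueError("priors must lie in (0,1)")
    rows = []
    classes = {l: lrt.categories(l) for l in lrt.snp_order}
    for g in sorted(priors):
        prior = priors[g]
        for profile in product(*(classes[l] for l in lrt.snp_order)):
            lrs = [lrt.lr(l, c) for l, c in zip(lrt.snp_order, profile)]
            risk = _posterior_from_lrs(prior, lrs)
            count = sum(
                panel[l].allele_count_of_class(c, snp_models[l].name)
                for l, c in zip(lrt.snp_order, profile)
            )
            rows.append(
                {
                    "group": g,
                    **dict(zip(lrt.snp_order, profile)),
                    "risk_allele_count": count,
                    "prior": prior,
                    "risk": risk,
                    "fold_change": risk / prior,
                }
            )
    per_profile = pd.DataFrame(rows)
    by_count = (
        per_profile.groupby(["group", "risk_allele_count"], as_index=False)
        .agg(prior=("prior", "first"), risk=("risk", "mean"))
        .assign(fold_change=lambda d: d["risk"] / d["prior"])
    )
    return per_profile, by_count


# ---------------------------------------------------------------------------
# Reconstruction from a printed score-table column (log-odds additivity)


def reconstruct_bs(baseline: float, single_factor_cells: list[float]) -> float:
    """Rebuild a multi-factor cell from a column's baseline and single-factor
    cells using the additivity of the score on the logit scale.

    With a shared prior, logit(BS) is the sum of per-factor log-LR increments,
    so cell = invlogit(logit(b) + sum_k [logit(s_k) - logit(b)]).
    """
    lrs = [(s / (1 - s)) / (baseline / (1 - baseline)) for s in single_factor_cells]
    return _posterior_from_lrs(baseline, lrs)


# ---------------------------------------------------------------------------
# statsmodels-style front end


class BayesScoreModel:
    """Sequential Bayes score model estimated from a training cohort.

    Fitting (i) runs the genotypic TDT with model selection at every panel
    locus, (ii) keeps loci with selected-model p < ``alpha``, (iii) estimates
    HLA-group and SNP-class case/AFBAC-control frequencies with a smoothing
    pseudo-count, and (iv) tabulates the BS for every HLA x SNP-class
    combination starting from ``prior``.

    Parameters
    ----------
    cohort : Cohort
        Training trios (and validation sibs, used only by downstream scoring).
    panel : Panel
    alpha : float
        Significance threshold for a SNP to enter the score (default 0.05).
    prior : float
        A priori probability for the score table (default 0.5).
    smoothing : float
        Pseudo-count per category (default 0.5, Haldane-Anscombe style).
    loci : list of str, optional
        Fix the associated loci instead of selecting by p-value.
    """

    def __init__(self, cohort: Cohort, panel: Panel, alpha=0.05, prior=0.5,
                 smoothing=0.5, loci=None):
        self.cohort = cohort
        self.panel = panel
        self.alpha = alpha
        self.prior = prior
        self.smoothing = smoothing
        self.loci = loci

    def fit(self) -> "BayesScoreResults":
        trios = self.cohort.trios
        tdt_results, all_fits = {}, {}
        for entry in self.panel:
            best, fits = select_model(trios, entry.locus_id, entry.risk_allele)
            tdt_results[entry.locus_id] = best
            all_fits[entry.locus_id] = fits
        if self.loci is not None:
            significant = list(self.loci)
        else:
            significant = [l for l, r in tdt_results.items() if r.p_value < self.alpha]
        snp_models = {l: tdt_results[l].model for l in significant}
        tables = {HLA_KEY: afbac_frequencies(trios, HLA_KEY, smoothing=self.smoothing)}
        for locus in significant:
            tables[locus] = afbac_frequencies(
                trios, locus, panel=self.panel, model=snp_models[locus],
                smoothing=self.smoothing,
            )
        lrt = LikelihoodRatioTable.from_afbac(tables, snp_order=significant)
        table = build_score_table(lrt, prior=self.prior)
        return BayesScoreResults(self, tdt_results, all_fits, significant,
                                 snp_models, tables, lrt, table)


class BayesScoreResults:
    """Fitted score table plus the association results behind it."""

    def __init__(self, model, tdt_results, all_fits, significant, snp_models,
                 afbac, lrt, score_table):
        self.model = model
        self.tdt_results = tdt_results
        self.all_fits = all_fits
        self.significant_loci = significant
        self.snp_models = snp_models
        self.afbac = afbac
        self.lrt = lrt
        self.score_table = score_table

    def tdt_frame(self) -> pd.DataFrame:
        rows = [r.row() for r in self.tdt_results.values()]
        return pd.DataFrame(rows).sort_values("p").reset_index(drop=True)

    def score_sibs(self, sibs=None) -> tuple[list[ScoredSib], int]:
        sibs = self.model.cohort.sibs if sibs is None else sibs
        return score_sibs(sibs, self.score_table, self.model.panel, self.snp_models)

    def refined_risk(self, priors=None):
        return refined_risk(self.lrt, self.model.panel, self.snp_models, priors)

    def summary(self) -> str:
        lines = [
            "Sequential Bayes HLA+SNP score",
            f"training trios: {len(self.model.cohort.trios)}   prior: {self.model.prior}"
            f"   smoothing: {self.model.smoothing}",
            f"associated loci (p < {self.model.alpha}): "
            + (", ".join(
                f"{l} ({self.snp_models[l].name}, OR {self.tdt_results[l].or_estimate:.2f})"
                for l in self.significant_loci) or "none"),
            "",
            "score table (BS per HLA group x SNP-class profile):",
            self.score_table.to_dataframe().round(2).to_string(index=False),
        ]
        return "\n".join(lines)
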