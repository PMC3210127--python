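"""Genotypic TDT via case + 3 pseudo-controls, AFBAC frequencies, interactions.

For each Mendelian-consistent trio the affected child's genotype is compared
with the three alternative child genotypes constructible from the parental
transmission grid (the Schaid matched set of 4).  Association is the MLE of
the one-parameter conditional logistic likelihood

    l(beta) = sum_sets [ beta*x_case - log sum_{j in set} exp(beta*x_j) ]

under an additive, dominant or recessive coding of the risk-allele count.
Control genotype frequencies come from the AFBAC rule: the genotype formed by
the two parental alleles NOT transmitted to the affected proband.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import optimize, stats

from .panel import Panel
from .pedigree import (
    MISSING,
    Trio,
    assign_hla_group,
    offspring_counts,
    untransmitted_haplotypes,
)

log = logging.getLogger(__name__)

BETA_CAP = 10.0  # |log-OR| bound reported under complete separation
Z95 = stats.norm.ppf(0.975)


class UninformativeLocusError(ValueError):
    """No matched set with varying coded genotype."""


@dataclass(frozen=True)
class InheritanceModel:
    """Genotype-count -> covariate coding; monotone non-decreasing."""

    name: str
    coding: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not (self.coding[0] <= self.coding[1] <= self.coding[2]):
            raise ValueError("coding must be monotone non-decreasing in allele count")

    def code(self, count: int) -> float:
        return self.coding[count]


ADDITIVE = InheritanceModel("additive", (0.0, 1.0, 2.0))
DOMINANT = InheritanceModel("dominant", (0.0, 1.0, 1.0))
RECESSIVE = InheritanceModel("recessive", (0.0, 0.0, 1.0))
MODELS = {m.name: m for m in (ADDITIVE, DOMINANT, RECESSIVE)}


@dataclass(frozen=True)
class MatchedSet:
    """Proband genotype plus the 3 pseudo-control genotypes (counts 0..2)."""

    case_genotype: int
    pseudo_genotypes: tuple[int, int, int]

    @property
    def all_genotypes(self) -> tuple[int, ...]:
        return (self.case_genotype, *self.pseudo_genotypes)


def make_pseudocontrols(trio: Trio, locus_id: str) -> MatchedSet:
    """Enumerate the 2x2 parental transmission grid and peel off the case."""
    gf, gm, gc = trio.genotypes(locus_id)
    if MISSING in (gf, gm, gc):
        raise ValueError(f"family {trio.family_id}: missing genotype at {locus_id}")
    combos = list(offspring_counts(gf, gm))
    if gc not in combos:
        raise ValueError(
            f"family {trio.family_id}: Mendelian inconsistency at {locus_id} "
            f"(parents {gf},{gm}, child {gc})"
        )
    combos.remove(gc)
    return MatchedSet(case_genotype=gc, pseudo_genotypes=tuple(sorted(combos)))


def _aggregate_sets(trios: list[Trio], locus_id: str) -> tuple[Counter, int]:
    """Tally trios by (father, mother, child) genotype; skip missing."""
    tally: Counter = Counter()
    skipped = 0
    for trio in trios:
        gf, gm, gc = trio.genotypes(locus_id)
        if MISSING in (gf, gm, gc):
            skipped += 1
            continue
        tally[(gf, gm, gc)] += 1
    return tally, skipped


def _coded_sets(tally: Counter, model: InheritanceModel):
    """Arrays (x_case, x_sets[T,4], counts) for the distinct matched-set types."""
    x_case, x_sets, counts = [], [], []
    for (gf, gm, gc), n in sorted(tally.items()):
        combos = offspring_counts(gf, gm)
        if gc not in combos:
            raise ValueError(f"Mendelian inconsistency (parents {gf},{gm}, child {gc})")
        x_case.append(model.code(gc))
        x_sets.append([model.code(g) for g in combos])
        counts.append(n)
    return np.asarray(x_case, float), np.asarray(x_sets, float), np.asarray(counts, float)


def conditional_loglik(beta: float, x_case, x_sets, counts) -> float:
    x_case, x_sets, counts = (np.asarray(a, float) for a in (x_case, x_sets, counts))
    lse = np.log(np.exp(beta * x_sets).sum(axis=1))
    return float((counts * (beta * x_case - lse)).sum())


def _score_info(beta: float, x_case, x_sets, counts) -> tuple[float, float]:
    # stabilised softmax weights per set type
    z = beta * x_sets
    z -= z.max(axis=1, keepdims=True)
    w = np.exp(z)
    w /= w.sum(axis=1, keepdims=True)
    m = (w * x_sets).sum(axis=1)
    v = (w * x_sets**2).sum(axis=1) - m**2
    score = float((counts * (x_case - m)).sum())
    info = float((counts * v).sum())
    return score, info


def _fit_coded_sets(x_case, x_sets, counts, cap: float = BETA_CAP):
    """1-D conditional-logistic MLE: Newton from 0, bisection fallback,
    |beta| capped under separation.  Returns (beta, se, n_informative, warnings)."""
    informative = np.ptp(x_sets, axis=1) > 0
    n_informative = int(counts[informative].sum())
    if n_informative == 0:
        raise UninformativeLocusError("uninformative locus: no matched set varies")
    xc, xs, ct = x_case[informative], x_sets[informative], counts[informative]
    warnings: list[str] = []

    s_hi, _ = _score_info(cap, xc, xs, ct)
    s_lo, _ = _score_info(-cap, xc, xs, ct)
    if s_hi > 0 or s_lo < 0:
        beta = cap if s_hi > 0 else -cap
        warnings.append("separation: one-directional transmissions, |beta| capped")
    else:
        beta, converged = 0.0, False
        for _ in range(50):
            score, info = _score_info(beta, xc, xs, ct)
            if info <= 0:
                break
            step = score / info
            beta = float(np.clip(beta + step, -cap, cap))
            if abs(step) < 1e-10:
                converged = True
                break
        if not converged:
            # the score is monotone decreasing (concave loglik): bisect its root
            beta = float(
                optimize.brentq(
                    lambda b: _score_info(b, xc, xs, ct)[0], -cap, cap, xtol=1e-12
                )
            )
            warnings.append("newton fallback: score bisection used")
    _, info = _score_info(beta, xc, xs, ct)
    se = 1.0 / math.sqrt(info) if info > 0 else math.inf
    return beta, se, n_informative, warnings


@dataclass
class TdtResult:
    """Per-locus, per-model genotypic TDT estimate (Table-1-style row)."""

    locus_id: str
    model: InheritanceModel
    risk_allele: str | None
    beta: float
    se: float
    or_estimate: float
    ci95: tuple[float, float]
    p_value: float
    n_informative: int
    n_sets: int
    n_skipped: int = 0
    warnings: list[str] = field(default_factory=list)

    def row(self) -> dict:
        return {
            "locus": self.locus_id,
            "model": self.model.name,
            "risk_allele": self.risk_allele or "",
            "OR": self.or_estimate,
            "CI_low": self.ci95[0],
            "CI_high": self.ci95[1],
            "p": self.p_value,
            "n_informative": self.n_informative,
        }


def fit_genotypic_tdt(
    trios: list[Trio],
    locus_id: str,
    model: InheritanceModel | str,
    risk_allele: str | None = None,
) -> TdtResult:
    """Fit the 1-parameter conditional logistic TDT at one locus."""
    if isinstance(model, str):
        model = MODELS[model]
    tally, skipped = _aggregate_sets(trios, locus_id)
    if not tally:
        raise UninformativeLocusError(f"{locus_id}: no complete trio genotypes")
    x_case, x_sets, counts = _coded_sets(tally, model)
    beta, se, n_informative, warnings = _fit_coded_sets(x_case, x_sets, counts)
    z = beta / se if se > 0 and math.isfinite(se) else 0.0
    p = float(2 * stats.norm.sf(abs(z)))
    ci = (math.exp(beta - Z95 * se), math.exp(beta + Z95 * se))
    for w in warnings:
        log.warning("%s (%s): %s", locus_id, model.name, w)
    return TdtResult(
        locus_id=locus_id,
        model=model,
        risk_allele=risk_allele,
        beta=beta,
        se=se,
        or_estimate=math.exp(beta),
        ci95=ci,
        p_value=p,
        n_informative=n_informative,
        n_sets=int(counts.sum()),
        n_skipped=skipped,
        warnings=warnings,
    )


def select_model(
    trios: list[Trio], locus_id: str, risk_allele: str | None = None
) -> tuple[TdtResult, dict[str, TdtResult]]:
    """Fit all three codings; return the smallest-p result (ties -> additive).

    The selection rule is a heuristic; all three fits are returned alongside.
    """
    fits: dict[str, TdtResult] = {}
    errors: list[str] = []
    for name in ("additive", "dominant", "recessive"):
        try:
            fits[name] = fit_genotypic_tdt(trios, locus_id, name, risk_allele)
        except UninformativeLocusError as e:
            errors.append(str(e))
    if not fits:
        raise UninformativeLocusError("; ".join(errors))
    # smallest p; p ties (incl. underflow to 0) broken by |z|, then additive
    best = min(
        fits.values(),
        key=lambda r: (r.p_value, -abs(r.beta / r.se), r.model.name != "additive"),
    )
    return best, fits


def score_test(trios: list[Trio], locus_id: str, model: InheritanceModel | str = ADDITIVE):
    """Conditional-logistic score test at beta=0: (chi2, p).

    On trios with two heterozygous parents the additive-coding statistic is
    algebraically the classical allelic (McNemar) TDT chi-square.
    """
    if isinstance(model, str):
        model = MODELS[model]
    tally, _ = _aggregate_sets(trios, locus_id)
    x_case, x_sets, counts = _coded_sets(tally, model)
    informative = np.ptp(x_sets, axis=1) > 0
    if not informative.any():
        raise UninformativeLocusError(locus_id)
    score, info = _score_info(
        0.0, x_case[informative], x_sets[informative], counts[informative]
    )
    chi2 = score**2 / info
    return chi2, float(stats.chi2.sf(chi2, df=1))


def allelic_tdt(trios: list[Trio], locus_id: str) -> tuple[int, int, float, float]:
    """Classical allelic TDT: transmissions from heterozygous parents.

    Returns (T, U, chi2, p) with chi2 = (T-U)^2/(T+U).
    """
    T = U = 0
    for trio in trios:
        gf, gm, gc = trio.genotypes(locus_id)
        if MISSING in (gf, gm, gc):
            continue
        if gf == 1 and gm == 1:
            T += gc
            U += 2 - gc
        elif gf == 1 or gm == 1:
            homo = gm if gf == 1 else gf
            t = gc - homo // 2  # transmitted risk alleles from the het parent
            T += t
            U += 1 - t
    if T + U == 0:
        raise UninformativeLocusError("no heterozygous parents")
    chi2 = (T - U) ** 2 / (T + U)
    return T, U, chi2, float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# AFBAC frequencies


@dataclass
class AfbacFrequencies:
    """Case vs affected-family-based-control category frequencies and LRs."""

    key: str  # locus id or "HLA"
    categories: list
    counts_case: dict
    counts_ctrl: dict
    smoothing: float
    f_case: dict = field(init=False)
    f_ctrl: dict = field(init=False)

    def __post_init__(self) -> None:
        self.f_case = self._normalise(self.counts_case)
        self.f_ctrl = self._normalise(self.counts_ctrl)

    def _normalise(self, counts: dict) -> dict:
        raw = {c: counts.get(c, 0) + self.smoothing for c in self.categories}
        total = sum(raw.values())
        if total <= 0:
            raise ValueError(f"{self.key}: empty category tallies and no smoothing")
        return {c: v / total for c, v in raw.items()}

    def lr(self, category) -> float:
        return self.f_case[category] / self.f_ctrl[category]

    def to_dict(self) -> dict:
        return {
            "key": self.key,
            "categories": [str(c) for c in self.categories],
            "f_case": {str(c): self.f_case[c] for c in self.categories},
            "f_ctrl": {str(c): self.f_ctrl[c] for c in self.categories},
            "counts_case": {str(c): self.counts_case.get(c, 0) for c in self.categories},
            "counts_ctrl": {str(c): self.counts_ctrl.get(c, 0) for c in self.categories},
            "smoothing": self.smoothing,
        }


HLA_KEY = "HLA"


def afbac_frequencies(
    trios: list[Trio],
    key: str,
    panel: Panel | None = None,
    model: InheritanceModel | str | None = None,
    smoothing: float = 0.5,
    basis: str = "genotype",
) -> AfbacFrequencies:
    """Case (proband) vs AFBAC-control frequencies for one factor.

    ``key`` is a panel locus or ``"HLA"``.  For a SNP the control genotype is
    formed by the two untransmitted parental alleles (count gf+gm-gc); with
    ``basis="allele"`` single alleles are tallied instead.  For HLA the
    untransmitted haplotype pair is mapped through the risk-group assignment.
    A smoothing pseudo-count is added to every category before normalising so
    downstream likelihood ratios stay finite and positive.
    """
    if key == HLA_KEY:
        categories = [1, 2, 3, 4, 5]
        cc: Counter = Counter()
        cu: Counter = Counter()
        for trio in trios:
            if trio.proband.hla is None or trio.father.hla is None or trio.mother.hla is None:
                continue
            cc[assign_hla_group(trio.proband.hla)] += 1
            cu[assign_hla_group(untransmitted_haplotypes(trio))] += 1
        return AfbacFrequencies(key, categories, dict(cc), dict(cu), smoothing)

    if panel is None or key not in panel:
        raise ValueError(f"locus {key} requires a panel entry")
    entry = panel[key]
    tally, _ = _aggregate_sets(trios, key)
    if basis == "allele":
        categories = [entry.risk_allele, entry.other_allele]
        cc, cu = Counter(), Counter()
        for (gf, gm, gc), n in tally.items():
            u = gf + gm - gc
            cc[entry.risk_allele] += n * gc
            cc[entry.other_allele] += n * (2 - gc)
            cu[entry.risk_allele] += n * u
            cu[entry.other_allele] += n * (2 - u)
        return AfbacFrequencies(key, categories, dict(cc), dict(cu), smoothing)
    if basis != "genotype":
        raise ValueError(f"unknown basis {basis!r}")
    if model is None:
        model = ADDITIVE
    if isinstance(model, str):
        model = MODELS[model]
    categories = entry.class_labels(model.name)
    cc, cu = Counter(), Counter()
    for (gf, gm, gc), n in tally.items():
        u = gf + gm - gc  # genotype paired from the two untransmitted alleles
        cc[entry.class_of_count(gc, model.name)] += n
        cu[entry.class_of_count(u, model.name)] += n
    return AfbacFrequencies(key, categories, dict(cc), dict(cu), smoothing)


# ---------------------------------------------------------------------------
# Interaction checks


def _joint_sets(trios, locus_a, locus_b, code_a, code_b):
    """Joint matched sets for two loci: 4x4 cross of per-locus transmissions."""
    rows = []
    for trio in trios:
        ga = trio.genotypes(locus_a)
        gb = trio.genotypes(locus_b)
        if MISSING in ga or MISSING in gb:
            continue
        ca = offspring_counts(ga[0], ga[1])
        cb = offspring_counts(gb[0], gb[1])
        if ga[2] not in ca or gb[2] not in cb:
            continue
        xa = [code_a(g) for g in ca]
        xb = [code_b(g) for g in cb]
        X = np.array([[a, b, a * b] for a in xa for b in xb], float)  # (16,3)
        x_case = np.array([code_a(ga[2]), code_b(gb[2]), code_a(ga[2]) * code_b(gb[2])])
        rows.append((x_case, X))
    return rows


def _fit_multiparam(rows, max_iter: int = 100):
    """Newton fit of a k-parameter conditional logistic likelihood."""
    k = rows[0][0].size
    beta = np.zeros(k)

    def loglik(b):
        return sum(
            float(b @ xc - np.log(np.exp(X @ b - (X @ b).max()).sum()) - (X @ b).max())
            for xc, X in rows
        )

    ll = loglik(beta)
    for _ in range(max_iter):
        grad = np.zeros(k)
        hess = np.zeros((k, k))
        for xc, X in rows:
            z = X @ beta
            z -= z.max()
            w = np.exp(z)
            w /= w.sum()
            m = w @ X
            grad += xc - m
            hess -= (X.T * w) @ X - np.outer(m, m)
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            break
        # step-halving to guarantee ascent
        for _ in range(20):
            cand = beta + step
            if np.all(np.abs(cand) <= BETA_CAP) and loglik(cand) >= ll - 1e-12:
                break
            step /= 2
        beta = beta + step
        ll = loglik(beta)
        if np.linalg.norm(step) < 1e-9:
            break
    # observed information at the optimum
    hess = np.zeros((k, k))
    for xc, X in rows:
        z = X @ beta
        z -= z.max()
        w = np.exp(z)
        w /= w.sum()
        m = w @ X
        hess += (X.T * w) @ X - np.outer(m, m)
    cov = np.linalg.pinv(hess)
    return beta, cov


@dataclass
class InteractionReport:
    snp_pairs: dict
    snp_hla: dict

    def to_dict(self) -> dict:
        return {
            "snp_pairs": {f"{a}x{b}": v for (a, b), v in self.snp_pairs.items()},
            "snp_hla": self.snp_hla,
        }


def interaction_scan(
    trios: list[Trio],
    loci: list[str],
    models: dict[str, InheritanceModel] | None = None,
) -> InteractionReport:
    """SNPxSNP product-term Wald tests and SNPxHLA stratum heterogeneity.

    SNPxSNP: conditional logistic fit over the joint 16-child pseudo-control
    grid with main effects plus a product term; Wald p for the product term.
    SNPxHLA: per-HLA-group stratum log-OR plus a Cochran-Q-style statistic.
    """
    models = models or {}

    def coder(locus):
        return (models.get(locus) or ADDITIVE).code

    pairs = {}
    for a, b in combinations(loci, 2):
        rows = _joint_sets(trios, a, b, coder(a), coder(b))
        rows = [r for r in rows if np.ptp(r[1], axis=0).sum() > 0]
        if not rows:
            continue
        beta, cov = _fit_multiparam(rows)
        se = math.sqrt(max(cov[2, 2], 0.0)) or math.inf
        z = beta[2] / se if se > 0 else 0.0
        pairs[(a, b)] = {
            "beta_interaction": float(beta[2]),
            "se": se,
            "p": float(2 * stats.norm.sf(abs(z))),
            "n_sets": len(rows),
        }

    snp_hla = {}
    for locus in loci:
        strata: dict[int, list[Trio]] = {}
        for trio in trios:
            if trio.proband.hla is None:
                continue
            strata.setdefault(assign_hla_group(trio.proband.hla), []).append(trio)
        per_stratum, dropped = {}, []
        for g, members in sorted(strata.items()):
            try:
                res = fit_genotypic_tdt(members, locus, models.get(locus, ADDITIVE))
            except UninformativeLocusError:
                dropped.append(g)
                continue
            per_stratum[g] = {"beta": res.beta, "se": res.se, "n_informative": res.n_informative}
        if len(per_stratum) >= 2:
            betas = np.array([v["beta"] for v in per_stratum.values()])
            ws = np.array([1.0 / v["se"] ** 2 for v in per_stratum.values()])
            pooled = float((ws * betas).sum() / ws.sum())
            q = float((ws * (betas - pooled) ** 2).sum())
            df = len(per_stratum) - 1
            p = float(stats.chi2.sf(q, df))
        else:
            pooled, q, df, p = math.nan, math.nan, 0, math.nan
        snp_hla[locus] = {
            "per_stratum": per_stratum,
            "pooled_beta": pooled,
            "Q": q,
            "df": df,
            "p": p,
            "dropped_strata": dropped,
        }
    return InteractionReport(snp_pairs=pairs, snp_hla=snp_hla)


# ---------------------------------------------------------------------------
# statsmodels-style front end


class GenotypicTDT:
    """Model object for the genotypic TDT at one locus.

    Parameters
    ----------
    trios : list of Trio
        Mendelian-consistent training trios.
    locus_id : str
        Panel locus to test.
    model : {"additive", "dominant", "recessive"} or InheritanceModel
    risk_allele : str, optional
        Label carried through to the results table.
    """

    def __init__(self, trios, locus_id, model=ADDITIVE, risk_allele=None):
        self.trios = trios
        self.locus_id = locus_id
        self.model = MODELS[model] if isinstance(model, str) else model
        self.risk_allele = risk_allele

    def fit(self) -> "GenotypicTDTResults":
        return GenotypicTDTResults(
            self, fit_genotypic_tdt(self.trios, self.locus_id, self.model, self.risk_allele)
        )

    def fit_all_models(self) -> "GenotypicTDTResults":
        best, fits = select_model(self.trios, self.locus_id, self.risk_allele)
        res = GenotypicTDTResults(self, best)
        res.all_fits = fits
        return res


class GenotypicTDTResults:
    """Estimates, uncertainty and a text summary for a fitted genotypic TDT."""

    def __init__(self, model: GenotypicTDT, result: TdtResult):
        self.model = model
        self.result = result
        self.all_fits: dict[str, TdtResult] | None = None

    @property
    def params(self) -> float:
        return self.result.beta

    @property
    def bse(self) -> float:
        return self.result.se

    @property
    def pvalues(self) -> float:
        return self.result.p_value

    def conf_int(self) -> tuple[float, float]:
        return self.result.ci95

    def summary(self) -> str:
        r = self.result
        lines = [
            "Genotypic TDT (conditional logistic, case + 3 pseudo-controls)",
            f"locus: {r.locus_id}   model: {r.model.name}   risk allele: {r.risk_allele or '-'}",
            f"matched sets: {r.n_sets} ({r.n_informative} informative, {r.n_skipped} skipped)",
            f"log-OR: {r.beta:+.4f} (SE {r.se:.4f})",
            f"OR: {r.or_estimate:.3f}  95% CI ({r.ci95[0]:.3f}, {r.ci95[1]:.3f})  p = {r.p_value:.3g}",
        ]
        if r.warnings:
            lines += [f"warning: {w}" for w in r.warnings]
        if self.all_fits:
            lines.append("all codings:")
            for name, f in self.all_fits.items():
                lines.append(
                    f"  {name:<9} OR {f.or_estimate:6.3f} "
                    f"({f.ci95[0]:.3f}-{f.ci95[1]:.3f})  p = {f.p_value:.3g}"
                )
        return "\n".join(lines)
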