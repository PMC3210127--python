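"""End-to-end analysis pipeline: train on trios, validate on sibs.

Stages (in study order): read cohort -> per-SNP genotypic TDT with model
selection -> keep associated SNPs -> AFBAC frequencies -> Bayes score table
-> score validation sibs -> median split -> classifier evaluation -> refined
per-group risk.  Validation affection labels are only touched by the final
evaluation stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .bayes import BayesScoreModel, BayesScoreResults, DEFAULT_HLA_RISK_PRIORS
from .classify import ClassifierComparison, evaluate_classifiers, strip_plot
from .panel import Panel
from .pedigree import Cohort, read_cohort, write_summary

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated pipeline configuration, serialised into every output dir."""

    alpha: float = 0.05
    prior: str = "flat"  # flat (0.5) | hla (per-group mean risks)
    smoothing: float = 0.5
    strict: bool = False
    seed: int = 0
    hla_risk_priors: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_HLA_RISK_PRIORS)
    )

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if self.prior not in ("flat", "hla"):
            raise ValueError("prior must be 'flat' or 'hla'")
        if self.smoothing < 0:
            raise ValueError("smoothing pseudo-count must be >= 0")

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "prior": self.prior,
            "smoothing": self.smoothing,
            "strict": self.strict,
            "seed": self.seed,
            "hla_risk_priors": {str(g): v for g, v in self.hla_risk_priors.items()},
        }

    @property
    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: RunConfig
    cohort: Cohort
    scores: BayesScoreResults
    comparison: ClassifierComparison
    n_sibs_excluded: int


def run_pipeline(
    cohort: Cohort,
    panel: Panel,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
    plot: bool = False,
) -> PipelineResult:
    config = config or RunConfig()
    config.validate()

    log.info("stage tdt+score: fitting Bayes score model on %d trios", len(cohort.trios))
    results = BayesScoreModel(
        cohort, panel, alpha=config.alpha, prior=0.5, smoothing=config.smoothing
    ).fit()
    log.info("associated loci: %s", results.significant_loci or "none")

    scored, n_excluded = results.score_sibs()
    log.info("stage score_sibs: %d sibs scored, %d excluded (missing genotypes)",
             len(scored), n_excluded)
    comparison = evaluate_classifiers(scored)

    res = PipelineResult(
        config=config,
        cohort=cohort,
        scores=results,
        comparison=comparison,
        n_sibs_excluded=n_excluded,
    )
    if outdir is not None:
        write_artifacts(res, scored, Path(outdir), plot=plot)
    return res


def write_artifacts(res: PipelineResult, scored, outdir: Path, plot: bool = False) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = res.config.to_dict() | {"config_hash": res.config.digest}
    (outdir / "config.json").write_text(json.dumps(cfg, indent=2) + "\n")
    write_summary(res.cohort, outdir / "cohort_summary.json")

    res.scores.tdt_frame().to_csv(outdir / "tdt_results.tsv", sep="\t", index=False)
    with open(outdir / "afbac.json", "w") as fh:
        json.dump({k: t.to_dict() for k, t in res.scores.afbac.items()}, fh, indent=2)
    res.scores.score_table.to_tsv(outdir / "score_table.tsv")
    res.scores.score_table.to_json(outdir / "score_table.json")

    pd.DataFrame(
        [
            {
                "FID": s.person.family_id,
                "IID": s.person.person_id,
                "hla_group": s.group,
                **dict(zip(res.scores.score_table.snp_order, s.profile)),
                "bs": s.bs,
                "affected": int(bool(s.affected)),
            }
            for s in scored
        ]
    ).to_csv(outdir / "sib_scores.tsv", sep="\t", index=False)

    res.comparison.to_json(outdir / "classification.json")
    rows = []
    for name, rep in res.comparison.reports.items():
        rows.append(
            {
                "classifier": name,
                "sensitivity": round(rep.sensitivity, 4),
                "specificity": round(rep.specificity, 4),
                "npv": round(rep.npv, 4),
                "ppv": round(rep.ppv, 4),
                "OR": round(rep.odds_ratio.odds_ratio, 4),
                "OR_p": rep.odds_ratio.p_value,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "classification.tsv", sep="\t", index=False)

    priors = res.config.hla_risk_priors if res.config.prior == "hla" else None
    per_profile, by_count = res.scores.refined_risk(priors)
    per_profile.to_csv(outdir / "refined_risk_profiles.tsv", sep="\t", index=False)
    by_count.to_csv(outdir / "refined_risk_by_count.tsv", sep="\t", index=False)

    if plot:
        strip_plot(scored, outdir / "sib_scores.png")
    log.info("artifacts written to %s (config %s)", outdir, res.config.digest)


def run_from_files(
    ped_path, panel_path, config: RunConfig | None = None, outdir=None, plot=False
) -> PipelineResult:
    panel = Panel.from_yaml(panel_path)
    cohort = read_cohort(ped_path, panel, strict=(config.strict if config else False))
    return run_pipeline(cohort, panel, config=config, outdir=outdir, plot=plot)


# ---------------------------------------------------------------------------
# Markdown report


_ARTIFACTS = {
    "tdt": "tdt_results.tsv",
    "score_table": "score_table.tsv",
    "classification": "classification.tsv",
}


def render_report(results_dir: str | Path) -> str:
    """Human-readable markdown summary of a results directory; missing
    artifacts are called out by name rather than failing silently."""
    results_dir = Path(results_dir)
    parts = ["# Sibling-risk analysis report", ""]
    cfg_path = results_dir / "config.json"
    if cfg_path.exists():
        parts += ["```", cfg_path.read_text().strip(), "```", ""]

    sections = [
        ("Association (genotypic TDT)", "tdt"),
        ("Bayes score table", "score_table"),
        ("Classifier performance", "classification"),
    ]
    for title, key in sections:
        parts.append(f"## {title}")
        path = results_dir / _ARTIFACTS[key]
        if not path.exists():
            parts += [f"*missing artifact: {_ARTIFACTS[key]}*", ""]
            continue
        df = pd.read_csv(path, sep="\t")
        parts += ["", df.to_markdown(index=False), ""]

    cls_path = results_dir / "classification.json"
    if cls_path.exists():
        doc = json.loads(cls_path.read_text())
        c = doc.get("c_statistics", {})
        if c:
            parts += [
                f"C statistics: HLA ordinal {c.get('hla', float('nan')):.2f}, "
                f"HLA+SNP Bayes score {c.get('bs', float('nan')):.2f}",
                "",
            ]
    return "\n".join(parts)
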