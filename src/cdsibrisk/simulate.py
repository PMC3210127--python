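"""Synthetic ascertained nuclear families for end-to-end pipeline testing.

The generator draws parental HLA-DQ haplotypes and SNP alleles under
Hardy-Weinberg and linkage equilibrium (the modelled loci sit on different
chromosomes), transmits one haplotype/allele per parent to each child, and
assigns disease by multiplicative odds:

    odds(child) = baseline_odds * hla_group_or[group] * prod_snp multiplier

with the per-SNP multiplier OR^dose under the SNP's generative inheritance
model.  Families enter the cohort by rejection sampling under the study's
ascertainment rule: at least one affected child (the proband), at least one
additional sib, and both parents unaffected (forced, matching the
training-set rule).  The full random stream is fixed by a single seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .panel import Panel, default_panel
from .pedigree import Cohort, HlaDqGenotype, Person, Trio, assign_hla_group

DEFAULT_HLA_FREQS = {
    "DQ2.5": 0.05,
    "DQ2.2": 0.08,
    "DQ7(A1*05)": 0.08,
    "DQ8": 0.09,
    "DQX": 0.70,
}

#: Group odds multipliers: a strong, strictly decreasing HLA risk gradient.
#: With the default baseline the realized per-group sib risks decrease
#: ~0.35/0.33/0.26/0.14/0.014 and the overall affected-sib fraction sits near
#: the ~10% first-degree-relative figure.
DEFAULT_HLA_GROUP_OR = {1: 60.0, 2: 45.0, 3: 30.0, 4: 12.0, 5: 1.0}


@dataclass(frozen=True)
class SnpSimSpec:
    """Generative effect of one SNP: allele frequency plus genotype odds."""

    locus_id: str
    risk_allele_freq: float
    model: str  # additive | dominant | recessive
    odds_ratio: float

    def multiplier(self, count: np.ndarray) -> np.ndarray:
        if self.model == "additive":
            dose = count
        elif self.model == "dominant":
            dose = (count >= 1).astype(float)
        elif self.model == "recessive":
            dose = (count == 2).astype(float)
        else:
            raise ValueError(f"unknown model {self.model!r}")
        return self.odds_ratio**dose

    def coded(self, count: np.ndarray) -> np.ndarray:
        if self.model == "additive":
            return np.asarray(count, float)
        if self.model == "dominant":
            return (count >= 1).astype(float)
        return (count == 2).astype(float)


@dataclass
class SimulationParams:
    """Study-shaped generator defaults: 157 ascertained families, the three
    associated SNPs at their published effect sizes, seven null markers."""

    hla_haplotype_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HLA_FREQS)
    )
    snps: list[SnpSimSpec] = field(default_factory=lambda: default_snp_specs())
    hla_group_or: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_HLA_GROUP_OR)
    )
    baseline_penetrance: float = 0.005
    n_families: int = 157
    sibship_size_probs: dict[int, float] = field(
        default_factory=lambda: {2: 0.55, 3: 0.32, 4: 0.13}
    )
    seed: int = 0
    interaction: tuple[str, str, float] | None = None

    def validate(self) -> None:
        for name, dist in (
            ("hla_haplotype_freqs", self.hla_haplotype_freqs),
            ("sibship_size_probs", self.sibship_size_probs),
        ):
            vals = list(dist.values())
            if any(not 0 < v <= 1 for v in vals) or abs(sum(vals) - 1) > 1e-9:
                raise ValueError(f"{name} must be a proper distribution")
        for s in self.snps:
            if not 0 < s.risk_allele_freq < 1:
                raise ValueError(f"{s.locus_id}: allele frequency must be in (0,1)")
            if s.odds_ratio <= 0:
                raise ValueError(f"{s.locus_id}: odds ratio must be positive")
        if any(v <= 0 for v in self.hla_group_or.values()):
            raise ValueError("HLA group odds multipliers must be positive")
        if not 0 < self.baseline_penetrance < 1:
            raise ValueError("baseline penetrance must be in (0,1)")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")

    @property
    def baseline_odds(self) -> float:
        return self.baseline_penetrance / (1.0 - self.baseline_penetrance)


def default_snp_specs() -> list[SnpSimSpec]:
    """All ten panel markers; the three associated SNPs carry their published
    effects, the remaining seven are generative nulls (OR 1)."""
    return [
        SnpSimSpec("rs1464510", 0.45, "additive", 2.36),
        SnpSimSpec("rs2816316", 0.80, "recessive", 1.75),
        SnpSimSpec("rs842647", 0.60, "recessive", 1.66),
        SnpSimSpec("rs2327832", 0.25, "additive", 1.0),
        SnpSimSpec("rs6441961", 0.45, "additive", 1.0),
        SnpSimSpec("rs6822844", 0.85, "additive", 1.0),
        SnpSimSpec("rs1738074", 0.45, "dominant", 1.0),
        SnpSimSpec("rs3184504", 0.50, "additive", 1.0),
        SnpSimSpec("rs17810546", 0.35, "additive", 1.0),
        SnpSimSpec("rs9811792", 0.40, "dominant", 1.0),
    ]


def risk_snp_specs() -> list[SnpSimSpec]:
    return default_snp_specs()[:3]


def default_sim_params(**overrides) -> SimulationParams:
    return SimulationParams(**overrides)


def risk_sim_params(**overrides) -> SimulationParams:
    """Three-SNP variant used by parameter-recovery studies."""
    overrides.setdefault("snps", risk_snp_specs())
    return SimulationParams(**overrides)


def params_panel(params: SimulationParams) -> Panel:
    full = default_panel()
    return Panel({s.locus_id: full[s.locus_id] for s in params.snps})


# ---------------------------------------------------------------------------
# Vectorised candidate generation


class _Machinery:
    """Precomputed lookup tables for one parameter set."""

    def __init__(self, params: SimulationParams):
        params.validate()
        self.params = params
        self.hap_labels = list(params.hla_haplotype_freqs)
        self.hap_freqs = np.array(list(params.hla_haplotype_freqs.values()))
        k = len(self.hap_labels)
        self.group_of_pair = np.array(
            [
                [assign_hla_group(HlaDqGenotype(a, b)) for b in self.hap_labels]
                for a in self.hap_labels
            ]
        )
        self.group_or = np.array(
            [params.hla_group_or[g] for g in range(1, 6)], float
        )
        self.sib_sizes = np.array(sorted(params.sibship_size_probs))
        self.sib_probs = np.array(
            [params.sibship_size_probs[s] for s in self.sib_sizes]
        )
        self.max_children = int(self.sib_sizes.max())


def _simulate_batch(mach: _Machinery, rng: np.random.Generator, size: int) -> dict:
    """Draw `size` candidate families as arrays; no ascertainment filter."""
    p = mach.params
    S = mach.max_children
    hapf = rng.choice(len(mach.hap_labels), size=(size, 2), p=mach.hap_freqs)
    hapm = rng.choice(len(mach.hap_labels), size=(size, 2), p=mach.hap_freqs)
    # parental SNP alleles under HWE: two independent alleles per parent
    fa = {s.locus_id: rng.random((size, 2)) < s.risk_allele_freq for s in p.snps}
    ma = {s.locus_id: rng.random((size, 2)) < s.risk_allele_freq for s in p.snps}
    n_children = rng.choice(mach.sib_sizes, size=size, p=mach.sib_probs)
    pick_f = rng.integers(0, 2, size=(size, S))
    pick_m = rng.integers(0, 2, size=(size, S))
    rows = np.arange(size)[:, None]
    child_hf = hapf[rows, pick_f]
    child_hm = hapm[rows, pick_m]
    group = mach.group_of_pair[child_hf, child_hm]

    odds = p.baseline_odds * mach.group_or[group - 1]
    child_geno: dict[str, np.ndarray] = {}
    for s in p.snps:
        tf = rng.integers(0, 2, size=(size, S))
        tm = rng.integers(0, 2, size=(size, S))
        g = fa[s.locus_id][rows, tf].astype(int) + ma[s.locus_id][rows, tm].astype(int)
        child_geno[s.locus_id] = g
        odds = odds * s.multiplier(g)
    if p.interaction is not None:
        la, lb, or_int = p.interaction
        spec = {s.locus_id: s for s in p.snps}
        xa = spec[la].coded(child_geno[la])
        xb = spec[lb].coded(child_geno[lb])
        odds = odds * or_int ** (xa * xb)

    affected = rng.random((size, S)) < odds / (1.0 + odds)
    sex = rng.integers(1, 3, size=(size, S))
    valid = np.arange(S)[None, :] < n_children[:, None]
    affected = affected & valid
    return {
        "hapf": hapf,
        "hapm": hapm,
        "fa": fa,
        "ma": ma,
        "n_children": n_children,
        "child_hf": child_hf,
        "child_hm": child_hm,
        "group": group,
        "child_geno": child_geno,
        "affected": affected,
        "sex": sex,
        "odds": odds,
        "valid": valid,
    }


def _family_from_row(batch: dict, i: int, fid: str, mach: _Machinery):
    """Materialise one candidate family row into Person objects."""
    p = mach.params
    labels = mach.hap_labels

    def hla(idx_pair) -> HlaDqGenotype:
        return HlaDqGenotype(labels[idx_pair[0]], labels[idx_pair[1]])

    father = Person(fid, "F", "0", "0", sex=1, affected=False, role="parent",
                    hla=hla(batch["hapf"][i]),
                    snps={s.locus_id: int(batch["fa"][s.locus_id][i].sum()) for s in p.snps})
    mother = Person(fid, "M", "0", "0", sex=2, affected=False, role="parent",
                    hla=hla(batch["hapm"][i]),
                    snps={s.locus_id: int(batch["ma"][s.locus_id][i].sum()) for s in p.snps})
    children = []
    for c in range(int(batch["n_children"][i])):
        children.append(
            Person(
                fid, f"C{c + 1}", "F", "M",
                sex=int(batch["sex"][i, c]),
                affected=bool(batch["affected"][i, c]),
                hla=HlaDqGenotype(
                    labels[batch["child_hf"][i, c]], labels[batch["child_hm"][i, c]]
                ),
                snps={s.locus_id: int(batch["child_geno"][s.locus_id][i, c]) for s in p.snps},
            )
        )
    return father, mother, children


def simulate_family(params: SimulationParams, rng: np.random.Generator):
    """One candidate family (no ascertainment): (father, mother, children)."""
    mach = _Machinery(params)
    batch = _simulate_batch(mach, rng, 1)
    return _family_from_row(batch, 0, "FAM1", mach)


@dataclass
class SimulatedCohort:
    """A generated cohort plus the hidden generative truth."""

    cohort: Cohort
    params: SimulationParams
    n_candidates: int

    def truth_report(self) -> dict:
        sibs = self.cohort.sibs
        groups = [assign_hla_group(s.hla) for s in sibs if s.hla is not None]
        return {
            "params": {
                "hla_haplotype_freqs": self.params.hla_haplotype_freqs,
                "hla_group_or": {str(g): v for g, v in self.params.hla_group_or.items()},
                "baseline_penetrance": self.params.baseline_penetrance,
                "seed": self.params.seed,
                "n_families": self.params.n_families,
                "sibship_size_probs": {
                    str(k): v for k, v in self.params.sibship_size_probs.items()
                },
                "snps": [asdict(s) for s in self.params.snps],
                "interaction": list(self.params.interaction)
                if self.params.interaction
                else None,
            },
            "realized": {
                "n_trios": len(self.cohort.trios),
                "n_sibs": len(sibs),
                "n_affected_sibs": sum(1 for s in sibs if s.affected),
                "sib_group_counts": {
                    str(g): int(sum(1 for x in groups if x == g)) for g in range(1, 6)
                },
                "n_candidate_families": self.n_candidates,
                "ascertainment_rate": len(self.cohort.trios) / self.n_candidates,
            },
        }

    def write_truth(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.truth_report(), fh, indent=2)
            fh.write("\n")


def generate_cohort(params: SimulationParams, batch_size: int = 8192) -> SimulatedCohort:
    """Rejection-sample ascertained families until ``n_families`` collected.

    Ascertainment: >=1 affected child (the first by birth order becomes the
    proband), >=1 additional sib, parents unaffected.  Deterministic under
    ``params.seed``.
    """
    mach = _Machinery(params)
    rng = np.random.default_rng(params.seed)
    cohort = Cohort()
    n_candidates = 0
    fam_no = 0
    while len(cohort.trios) < params.n_families:
        batch = _simulate_batch(mach, rng, batch_size)
        keep = np.flatnonzero(batch["affected"].any(axis=1) & (batch["n_children"] >= 2))
        n_candidates += batch_size
        for i in keep:
            if len(cohort.trios) >= params.n_families:
                break
            fam_no += 1
            fid = f"FAM{fam_no:05d}"
            father, mother, children = _family_from_row(batch, int(i), fid, mach)
            proband = next(c for c in children if c.affected)
            proband.role = "proband"
            cohort.trios.append(Trio(proband=proband, father=father, mother=mother))
            for c in children:
                if c is not proband:
                    c.role = "sib"
                    cohort.sibs.append(c)
        if n_candidates >= 100 * batch_size and not cohort.trios:
            raise RuntimeError(
                "ascertainment probability < 1e-5; check penetrance parameters"
            )
    return SimulatedCohort(cohort=cohort, params=params, n_candidates=n_candidates)


def truth_report(sim: SimulatedCohort) -> dict:
    return sim.truth_report()
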