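"""SNP panel configuration.

A panel maps each SNP to its risk allele (the allele whose dosage is the
genotype coding used throughout), the alternative allele, the gene label used
in reports, and the candidate inheritance models to try during association
testing.  Panels round-trip through a small YAML document so that external
cohort files can declare their own marker sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

VALID_MODELS = ("additive", "dominant", "recessive")


@dataclass(frozen=True)
class SnpPanelEntry:
    locus_id: str
    gene: str
    risk_allele: str
    other_allele: str
    model_candidates: tuple[str, ...] = VALID_MODELS

    def __post_init__(self) -> None:
        if self.risk_allele == self.other_allele:
            raise ValueError(f"{self.locus_id}: risk and other allele identical")
        for m in self.model_candidates:
            if m not in VALID_MODELS:
                raise ValueError(f"{self.locus_id}: unknown model {m!r}")

    def genotype_label(self, count: int) -> str:
        """Two-letter genotype label for a risk-allele count, e.g. 0 -> 'CC'."""
        if count == 0:
            return self.other_allele * 2
        if count == 1:
            return "".join(sorted((self.risk_allele, self.other_allele)))
        if count == 2:
            return self.risk_allele * 2
        raise ValueError(f"invalid risk allele count {count}")

    def class_labels(self, model: str) -> list[str]:
        """Genotype class labels under a collapsed inheritance coding.

        additive keeps three classes; dominant pools carriers; recessive pools
        non-double-risk genotypes (e.g. 'AG|GG' for risk allele A over G).
        """
        g0, g1, g2 = (self.genotype_label(c) for c in (0, 1, 2))
        if model == "additive":
            return [g0, g1, g2]
        if model == "dominant":
            return [g0, f"{g1}|{g2}"]
        if model == "recessive":
            return [f"{g1}|{g0}", g2]
        raise ValueError(f"unknown model {model!r}")

    def class_of_count(self, count: int, model: str) -> str:
        labels = self.class_labels(model)
        if model == "additive":
            return labels[count]
        if model == "dominant":
            return labels[0] if count == 0 else labels[1]
        return labels[1] if count == 2 else labels[0]

    def allele_count_of_class(self, label: str, model: str) -> int:
        """Risk-allele count attributed to a class for dose-response summaries.

        Collapsed classes use the risk-class indicator times two; additive
        classes carry their literal dosage.
        """
        labels = self.class_labels(model)
        idx = labels.index(label)
        if model == "additive":
            return idx
        return 2 * idx


@dataclass
class Panel:
    snps: dict[str, SnpPanelEntry] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.snps.values())

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self.snps

    def __getitem__(self, locus_id: str) -> SnpPanelEntry:
        return self.snps[locus_id]

    @property
    def loci(self) -> list[str]:
        return list(self.snps)

    def to_yaml(self, path) -> None:
        doc = {
            "snps": {
                e.locus_id: {
                    "gene": e.gene,
                    "risk_allele": e.risk_allele,
                    "other_allele": e.other_allele,
                    "model_candidates": list(e.model_candidates),
                }
                for e in self
            }
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Panel":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        snps = {}
        for locus_id, d in doc["snps"].items():
            snps[locus_id] = SnpPanelEntry(
                locus_id=locus_id,
                gene=d.get("gene", locus_id),
                risk_allele=d["risk_allele"],
                other_allele=d["other_allele"],
                model_candidates=tuple(d.get("model_candidates", VALID_MODELS)),
            )
        return cls(snps)


def default_panel() -> Panel:
    """The 10-SNP celiac panel with risk alleles as reported for each marker."""
    rows = [
        ("rs1464510", "LPP", "A", "C"),
        ("rs2816316", "RGS1", "A", "C"),
        ("rs842647", "REL", "A", "G"),
        ("rs2327832", "OLIG3", "G", "A"),
        ("rs6441961", "CCR1/CCR3", "A", "G"),
        ("rs6822844", "IL2/IL21", "C", "A"),
        ("rs1738074", "TAGAP", "A", "G"),
        ("rs3184504", "SH2B3", "A", "G"),
        ("rs17810546", "IL12A", "G", "A"),
        ("rs9811792", "IL12A/SCHIP1", "G", "A"),
    ]
    return Panel({r[0]: SnpPanelEntry(*r) for r in rows})


def risk_panel() -> Panel:
    """The three significantly associated SNPs (LPP, RGS1, REL) only."""
    full = default_panel()
    keep = ("rs1464510", "rs842647", "rs2816316")
    return Panel({k: full[k] for k in keep})
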