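"""Nuclear-family pedigree model: people, trios, HLA-DQ risk groups, PED I/O.

Genotypes are stored as risk-allele counts (0/1/2, ``None`` for missing); the
mapping from raw base-pair alleles to counts goes through the SNP panel
configuration.  HLA-DQ status is an unordered pair of haplotype labels from a
fixed vocabulary, collapsed to the five ordinal celiac risk groups G1 (very
high, >20%) down to G5 (negligible, <1%).
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations_with_replacement

from .panel import Panel

log = logging.getLogger(__name__)

HLA_HAPLOTYPES = ("DQ2.5", "DQ2.2", "DQ7(A1*05)", "DQ8", "DQX")

#: unordered label pairs whose risk-group placement is not covered by the
#: published grouping rules; they fall through to G5 and are flagged in logs.
UNLISTED_PAIRS = frozenset(
    {
        frozenset({"DQ7(A1*05)", "DQ8"}),
        frozenset({"DQ7(A1*05)"}),
        frozenset({"DQ7(A1*05)", "DQX"}),
    }
)

MISSING = None


class PedigreeError(ValueError):
    """Malformed pedigree input."""


class VocabularyError(PedigreeError):
    """Unknown HLA haplotype or allele code."""


@dataclass(frozen=True)
class HlaDqGenotype:
    """Unordered pair of HLA-DQ haplotype labels (canonically sorted)."""

    haplotype_1: str
    haplotype_2: str

    def __post_init__(self) -> None:
        for h in (self.haplotype_1, self.haplotype_2):
            if h not in HLA_HAPLOTYPES:
                raise VocabularyError(f"unknown HLA haplotype label {h!r}")
        a, b = sorted((self.haplotype_1, self.haplotype_2))
        object.__setattr__(self, "haplotype_1", a)
        object.__setattr__(self, "haplotype_2", b)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.haplotype_1, self.haplotype_2)


def assign_hla_group(hla: HlaDqGenotype) -> int:
    """Collapse an HLA-DQ haplotype pair to the ordinal risk group 1..5.

    G1: DQ2.5/DQ2.5 or DQ2.5/DQ2.2; G3: any other single DQ2.5 copy (G1 takes
    precedence); G2: DQ2.2 with the DQA1*05-carrying DQ7 haplotype; G4:
    DQ8/DQ8, DQ2.2/DQ8 or DQ2.2/DQ2.2; everything else G5.
    """
    pair = Counter(hla.pair)
    if pair["DQ2.5"] == 2 or (pair["DQ2.5"] == 1 and pair["DQ2.2"] == 1):
        return 1
    if pair["DQ2.5"] == 1:
        return 3
    if pair["DQ2.2"] == 1 and pair["DQ7(A1*05)"] == 1:
        return 2
    if pair["DQ8"] == 2 or pair["DQ2.2"] == 2 or (pair["DQ2.2"] == 1 and pair["DQ8"] == 1):
        return 4
    if frozenset(hla.pair) in UNLISTED_PAIRS:
        log.debug("HLA pair %s not covered by published grouping rules; assigned G5", hla.pair)
    return 5


def all_hla_pairs() -> list[HlaDqGenotype]:
    """The 15 unordered haplotype pairs."""
    return [HlaDqGenotype(a, b) for a, b in combinations_with_replacement(HLA_HAPLOTYPES, 2)]


@dataclass
class Person:
    family_id: str
    person_id: str
    father_id: str
    mother_id: str
    sex: int = 0
    affected: bool | None = None
    role: str = "unknown"  # proband | parent | sib
    hla: HlaDqGenotype | None = None
    snps: dict[str, int | None] = field(default_factory=dict)

    def genotype(self, locus_id: str) -> int | None:
        return self.snps.get(locus_id, MISSING)

    @property
    def is_founder(self) -> bool:
        return self.father_id == "0" and self.mother_id == "0"


@dataclass
class Trio:
    """Affected proband plus both (unaffected) parents — the training unit."""

    proband: Person
    father: Person
    mother: Person

    @property
    def family_id(self) -> str:
        return self.proband.family_id

    def genotypes(self, locus_id: str) -> tuple[int | None, int | None, int | None]:
        return (
            self.father.genotype(locus_id),
            self.mother.genotype(locus_id),
            self.proband.genotype(locus_id),
        )


@dataclass
class Cohort:
    """Training trios plus the validation set of additional sibs."""

    trios: list[Trio] = field(default_factory=list)
    sibs: list[Person] = field(default_factory=list)
    exclusions: list[tuple[str, str]] = field(default_factory=list)  # (family_id, reason)

    def summary(self) -> dict:
        n_aff = sum(1 for s in self.sibs if s.affected is True)
        reasons = Counter(r for _, r in self.exclusions)
        return {
            "n_trios": len(self.trios),
            "n_sibs": len(self.sibs),
            "n_affected_sibs": n_aff,
            "n_unaffected_sibs": sum(1 for s in self.sibs if s.affected is False),
            "n_families_excluded": len({f for f, _ in self.exclusions}),
            "exclusion_reasons": dict(reasons),
        }


# ---------------------------------------------------------------------------
# Mendelian checks


def validate_mendelian(trio: Trio, locus_id: str) -> bool | None:
    """True iff the child's risk-allele count can arise from the parents.

    Returns ``None`` (indeterminate, never treated as consistent) when any of
    the three genotypes is missing.
    """
    gf, gm, gc = trio.genotypes(locus_id)
    if gf is MISSING or gm is MISSING or gc is MISSING:
        return None
    return gc in offspring_counts(gf, gm)


_TRANSMISSIBLE = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def offspring_counts(gf: int, gm: int) -> tuple[int, ...]:
    """The 4 child risk-allele counts (with multiplicity) from the 2x2
    parental transmission grid."""
    return tuple(sorted(f + m for f in _TRANSMISSIBLE[gf] for m in _TRANSMISSIBLE[gm]))


def validate_hla_mendelian(trio: Trio) -> bool | None:
    """Child haplotype pair must take one haplotype from each parent."""
    if trio.father.hla is None or trio.mother.hla is None or trio.proband.hla is None:
        return None
    fa = trio.father.hla.pair
    mo = trio.mother.hla.pair
    child = Counter(trio.proband.hla.pair)
    return any(Counter((f, m)) == child for f in fa for m in mo)


def untransmitted_haplotypes(trio: Trio) -> HlaDqGenotype:
    """The AFBAC control pair: the parents' 4 haplotypes minus the child's 2.

    Well defined as a multiset difference for every Mendelian-consistent trio
    (any valid transmission assignment leaves the same residual pair).
    """
    pool = Counter(trio.father.hla.pair) + Counter(trio.mother.hla.pair)
    pool.subtract(Counter(trio.proband.hla.pair))
    if any(v < 0 for v in pool.values()):
        raise PedigreeError(
            f"family {trio.family_id}: child HLA pair not contained in parental haplotypes"
        )
    rest = sorted(pool.elements())
    return HlaDqGenotype(rest[0], rest[1])


# ---------------------------------------------------------------------------
# PED-style I/O

_FIXED_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENO", "HLA1", "HLA2"]


def _parse_pheno(tok: str, lineno: int) -> bool | None:
    if tok == "2":
        return True
    if tok == "1":
        return False
    if tok in ("0", "-9"):
        return None
    raise PedigreeError(f"line {lineno}: invalid affection code {tok!r}")


def _parse_snp(a1: str, a2: str, entry, lineno: int) -> int | None:
    if a1 == "0" or a2 == "0":  # half-missing treated as missing
        return None
    count = 0
    for a in (a1, a2):
        if a == entry.risk_allele:
            count += 1
        elif a != entry.other_allele:
            raise VocabularyError(
                f"line {lineno}: allele {a!r} not valid for {entry.locus_id} "
                f"({entry.risk_allele}/{entry.other_allele})"
            )
    return count


def read_cohort(path, panel: Panel, strict: bool = False) -> Cohort:
    """Read a header-bearing PED-style table into a training/validation Cohort.

    Columns: FID IID PAT MAT SEX PHENO HLA1 HLA2 then two allele columns per
    panel SNP (``<locus>_1 <locus>_2``); 0 = missing allele/haplotype.  Roles
    are inferred (first affected child with both parents present = proband,
    remaining children = sibs).  Families violating the training-set rules
    (affected parent, Mendelian inconsistency, missing proband HLA, and under
    ``strict`` any missing trio SNP genotype) are excluded and logged; their
    sibs are dropped with them so every retained sib has a proband trio.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise PedigreeError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header[: len(_FIXED_COLS)] != _FIXED_COLS:
        raise PedigreeError(f"{path}: header must start with {' '.join(_FIXED_COLS)}")
    snp_cols = header[len(_FIXED_COLS) :]
    loci: list[str] = []
    for i in range(0, len(snp_cols), 2):
        pair = snp_cols[i : i + 2]
        if len(pair) < 2 or not pair[0].endswith("_1") or pair[1] != pair[0][:-2] + "_2":
            raise PedigreeError(f"{path}: malformed SNP column pair {pair}")
        locus = pair[0][:-2]
        if locus not in panel:
            raise PedigreeError(f"{path}: locus {locus} absent from panel")
        loci.append(locus)

    families: dict[str, list[Person]] = {}
    order: list[str] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        toks = line.split("\t")
        if len(toks) != len(header):
            raise PedigreeError(f"line {lineno}: expected {len(header)} fields, got {len(toks)}")
        fid, iid, pat, mat, sex, pheno = toks[:6]
        hla1, hla2 = toks[6:8]
        hla = None
        if hla1 != "0" and hla2 != "0":
            try:
                hla = HlaDqGenotype(hla1, hla2)
            except VocabularyError as e:
                raise VocabularyError(f"line {lineno}: {e}") from None
        snps: dict[str, int | None] = {}
        for k, locus in enumerate(loci):
            a1, a2 = toks[8 + 2 * k], toks[9 + 2 * k]
            snps[locus] = _parse_snp(a1, a2, panel[locus], lineno)
        try:
            sex_i = int(sex)
        except ValueError:
            raise PedigreeError(f"line {lineno}: invalid sex code {sex!r}") from None
        person = Person(
            family_id=fid,
            person_id=iid,
            father_id=pat,
            mother_id=mat,
            sex=sex_i,
            affected=_parse_pheno(pheno, lineno),
            hla=hla,
            snps=snps,
        )
        families.setdefault(fid, []).append(person)
        if fid not in order:
            order.append(fid)

    cohort = Cohort()
    for fid in order:
        _assemble_family(cohort, fid, families[fid], loci, strict)
    log.info(
        "read %d trios, %d sibs, %d families excluded from %s",
        len(cohort.trios),
        len(cohort.sibs),
        len({f for f, _ in cohort.exclusions}),
        path,
    )
    return cohort


def _assemble_family(cohort: Cohort, fid: str, members: list[Person], loci, strict: bool) -> None:
    by_id = {p.person_id: p for p in members}
    children = [p for p in members if p.father_id in by_id and p.mother_id in by_id]
    parents = {p.person_id for c in children for p in (by_id[c.father_id], by_id[c.mother_id])}

    def exclude(reason: str) -> None:
        cohort.exclusions.append((fid, reason))
        log.warning("family %s excluded: %s", fid, reason)

    if not children:
        return exclude("no_child_with_both_parents")
    affected_children = [c for c in children if c.affected is True]
    if not affected_children:
        return exclude("no_affected_child")
    if any(by_id[pid].affected is True for pid in parents):
        return exclude("affected_parent")

    proband = affected_children[0]
    father, mother = by_id[proband.father_id], by_id[proband.mother_id]
    if not father.is_founder or not mother.is_founder:
        return exclude("parent_has_in_cohort_parents")
    trio = Trio(proband=proband, father=father, mother=mother)
    if any(p.hla is None for p in (proband, father, mother)):
        return exclude("missing_hla")
    if validate_hla_mendelian(trio) is not True:
        return exclude("hla_mendelian_inconsistency")
    for locus in loci:
        verdict = validate_mendelian(trio, locus)
        if verdict is False:
            return exclude(f"mendelian_inconsistency:{locus}")
        if verdict is None and strict:
            return exclude("incomplete_genotyping")

    proband.role = "proband"
    father.role = mother.role = "parent"
    cohort.trios.append(trio)
    for c in children:
        if c is not proband:
            c.role = "sib"
            cohort.sibs.append(c)


def write_cohort(cohort: Cohort, path, panel: Panel) -> None:
    """Write a Cohort back to the PED-style dialect read by :func:`read_cohort`."""
    loci = panel.loci
    header = _FIXED_COLS + [f"{l}_{i}" for l in loci for i in (1, 2)]

    def row(p: Person) -> str:
        pheno = "0" if p.affected is None else ("2" if p.affected else "1")
        hla = list(p.hla.pair) if p.hla else ["0", "0"]
        toks = [p.family_id, p.person_id, p.father_id, p.mother_id, str(p.sex), pheno, *hla]
        for locus in loci:
            g = p.genotype(locus)
            e = panel[locus]
            if g is MISSING:
                toks += ["0", "0"]
            else:
                toks += [e.risk_allele] * g + [e.other_allele] * (2 - g)
        return "\t".join(toks)

    sibs_by_family: dict[str, list[Person]] = {}
    for sib in cohort.sibs:
        sibs_by_family.setdefault(sib.family_id, []).append(sib)
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for trio in cohort.trios:
            fh.write(row(trio.father) + "\n")
            fh.write(row(trio.mother) + "\n")
            fh.write(row(trio.proband) + "\n")
            for sib in sibs_by_family.get(trio.family_id, ()):
                fh.write(row(sib) + "\n")


def write_summary(cohort: Cohort, path) -> None:
    with open(path, "w") as fh:
        json.dump(cohort.summary(), fh, indent=2)
        fh.write("\n")
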