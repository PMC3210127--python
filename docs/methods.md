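# Methods

`cdsibrisk` estimates celiac disease (CD) risk in siblings of affected
children from family genotype data: HLA-DQ haplotype pairs plus a small panel
of non-HLA susceptibility SNPs. The pipeline trains on parent–proband trios
and validates on the probands' siblings, mirroring the two-stage design of
family cohort studies of CD.

## Pedigree model and HLA risk groups

Families are nuclear: two founder parents and ≥1 child. SNP genotypes are
stored as risk-allele counts (0/1/2); the mapping from base-pair alleles is
declared in a YAML panel configuration, so additive/dominant/recessive
codings are trivial downstream. HLA-DQ status is an unordered pair from
{DQ2.5, DQ2.2, DQ7(A1\*05), DQ8, DQX}, collapsed to the five ordinal CD risk
groups:

* **G1** (very high, >20%): DQ2.5/DQ2.5 or DQ2.5/DQ2.2
* **G2** (high, 15–20%): DQ2.2 with the DQA1\*05-carrying DQ7 haplotype
* **G3** (intermediate, 10–15%): any other single copy of DQ2.5 — G1 takes
  precedence, and the DQ2.5/DQ8 compound heterozygote falls here because it
  carries one DQ2.5 copy
* **G4** (moderate, 1–10%): DQ8/DQ8, DQ2.2/DQ8, DQ2.2/DQ2.2
* **G5** (negligible, <1%): everything else. Pairs not covered by the
  published grouping rules (e.g. DQ7(A1\*05)/DQ8) default to G5 and are
  flagged in logs.

Training-set hygiene follows the study design: families with an affected
parent, a Mendelian inconsistency, or missing proband HLA are excluded whole
(reasons logged); missing SNP genotypes are tolerated per locus by default,
or exclude the family under `strict` mode.

## Genotypic TDT

For each trio and locus the affected child's genotype is compared with the
three alternative genotypes constructible from the parents' alleles (the
2×2 transmission grid minus the observed child) — the standard matched set of
1 case + 3 pseudo-controls. The log odds ratio β maximises the
one-parameter conditional logistic likelihood

ℓ(β) = Σ_sets [ β·x_case − log Σ_{j∈set} exp(β·x_j) ]

where x codes the risk-allele count as additive (0,1,2), dominant (0,1,1) or
recessive (0,0,1). Numerics: Newton–Raphson from β=0 with |Δβ|<1e-10
convergence; if Newton fails to converge the score equation is bisected
(the log-likelihood is concave so the score is monotone). Complete
separation (all informative transmissions one-directional) is detected from
the score sign at ±10 and reported as |β| capped at 10 with a warning.
Wald standard errors, 95% CIs and p-values come from the observed
information. Uninformative sets (no variation in the coded genotype)
contribute nothing and a locus with no informative set raises an error.

Model selection fits all three codings and reports the smallest p-value
(p ties, including underflow to zero, broken by the larger Wald z, then
additive). This rule is a heuristic; all three fits are retained in verbose
output. Raw p-values are reported without multiple-testing correction, with
α = 0.05 as the default threshold for a SNP to enter the Bayes score.

On trios with two heterozygous parents, the additive-coding score statistic
at β=0 equals the classical allelic (McNemar) TDT χ² = (T−U)²/(T+U); both
statistics are implemented and the identity is exercised in the tests, along
with a golden-section grid oracle and an independent conditional-logistic
fit in R (`survival::clogit`).

**Interactions.** SNP×SNP interaction is tested by a three-parameter
conditional logistic fit over the joint 4×4 pseudo-control grid of two loci
(main effects + product term, Wald test). SNP×HLA interaction is assessed by
per-HLA-group stratum fits and a Cochran-Q heterogeneity statistic.

## AFBAC control frequencies

Control genotype frequencies are estimated from affected-family-based
controls: the genotype formed by the two parental alleles *not* transmitted
to the proband (count g_father + g_mother − g_child, which is well defined
for every Mendelian-consistent trio). For HLA the untransmitted haplotype
pair (the parents' four haplotypes minus the child's two) is mapped through
the risk-group assignment; categories are the five groups, not raw
genotypes. An allele-based variant is available for SNPs. A smoothing
pseudo-count (default 0.5 per category, Haldane–Anscombe style) keeps every
downstream likelihood ratio finite and positive; it perturbs each frequency
by at most c·K/(n + c·K) for pseudo-count c and K categories.

## Sequential Bayes score (BS)

Starting from an a priori probability of 0.5, the score chains Bayes
updates through the HLA group and each associated SNP class:

posterior = prior·f_case / (prior·f_case + (1−prior)·f_ctrl)

equivalently posterior odds = prior odds × Π LR_k with LR = f_case/f_ctrl.
The update order (HLA → LPP → REL → RGS1 for the canonical panel) is fixed
for reporting only — the product form makes the result order-invariant, and
logit(BS) is additive in the per-factor log-LRs. This chaining assumes the
factors are conditionally independent given case/control status, consistent
with the absence of HLA×SNP interaction in the association scan; the
assumption is stated here because it is the model, not a checked property of
any particular data set.

SNP classes follow the selected inheritance model: three classes for an
additive SNP (e.g. LPP CC/AC/AA), two for a recessive one (e.g. REL AG|GG
vs AA). The score table covers every HLA-group × class-profile combination,
including combinations never observed (smoothing guarantees a finite LR).
BS is a *ranking* of genotype combinations, not a calibrated absolute risk:
the profile ranking within a group is invariant to the prior.

**Refined risk.** For absolute-scale summaries the flat 0.5 prior is
replaced by per-group a priori risks. The published group-specific mean
risks are not printed, so the defaults are the midpoints of the published
risk bands — G1 0.21, G2 0.175, G3 0.125, G4 0.055, G5 0.005 — and are
configurable. Only the SNP updates are applied (HLA is already in the
prior), and the result is reported both per profile and aggregated by total
risk-allele count 0–6, attributing 0–2 alleles to additive classes and
risk-indicator×2 to collapsed classes (a convention: a collapsed
non-risk class mixes 0 and 1 copies). Fold-change risk/prior is reported
alongside, implementing "standardised by the starting HLA risk" as a ratio.

## Risk classification and diagnostics

Validation sibs receive the BS of their HLA×SNP combination. Within each
HLA group the median BS of *all* sibs (affected + unaffected, midpoint
convention for even n) is the threshold: **high risk iff BS ≥ median**. The
flow-chart classifier short-circuits the extremes: G1–G2 always high, G5
always low, G3–G4 decided by the median split. Three rules are compared —
HLA-only (high = G1–G2), BS-median, flow-chart — each summarised by its 2×2
confusion table, sensitivity/specificity/NPV/PPV with Wald 95% CIs, the
odds ratio with Woolf (log-scale) CI, and a Pearson χ² p-value (Fisher's
exact when any expected cell is below 5; Haldane 0.5 correction for zero
cells, flagged). The C statistic is the Mann–Whitney AUC with ties counted
half; the HLA-only classifier uses the ordinal group number (reversed, so
G1 scores highest) as its score. A degenerate split that labels every sib
high (e.g. when no SNP passes the threshold and a group's scores are
constant) leaves PPV/NPV undefined (NaN) rather than aborting the pipeline.

The published OR of 2.53 for the median split carries a printed CI
(1.68–3.39) that is symmetric on the OR scale and not reproducible by Woolf
or exact methods on any integer table compatible with the printed margins;
this package reports standard Woolf CIs and does not attempt to match it.

## Synthetic ascertained families

Because the study's genotypes are unreleased, a generator produces cohorts
with the statistical structure the analysis assumes. Parental HLA haplotypes
and SNP alleles are drawn under Hardy–Weinberg and linkage equilibrium (the
modelled loci are on different chromosomes); children inherit one
haplotype/allele per parent; disease follows multiplicative odds

odds = baseline_odds × hla_group_or[group] × Π OR_snp^dose

with affection ~ Bernoulli(odds/(1+odds)), parents forced unaffected, and
rejection sampling until `n_families` satisfy the ascertainment rule (≥1
affected child — the first by birth order is the proband — plus ≥1
additional sib). A single seed fixes the whole stream; same seed, same PED
bytes. An optional product-term switch adds a SNP×SNP interaction for power
studies.

Defaults emulate the study conditions: 157 families; sibship sizes 2/3/4
with probabilities 0.55/0.32/0.13 (≈1.6 extra sibs per family); the three
associated SNPs at their published effects (LPP rs1464510 additive OR 2.36,
allele frequency 0.45; RGS1 rs2816316 recessive OR 1.75, frequency 0.80;
REL rs842647 recessive OR 1.66, frequency 0.60) plus seven null markers;
HLA group odds multipliers 60/45/30/12/1. Haplotype frequencies
(DQ2.5 0.05, DQ2.2 0.08, DQ7(A1\*05) 0.08, DQ8 0.09, DQX 0.70) were chosen
so sib group occupancy is ordered G5 > G3 > G4 > G1 ≈ G2, qualitatively like
a European cohort. The baseline penetrance (0.005) was calibrated once so
the realized affected-sib fraction sits near the ~10% first-degree-relative
figure (at the default seed, 157 trios / 266 sibs / 29 affected; per-group
sib risks ≈ 0.35/0.33/0.26/0.14/0.014). Under this occupancy ordering the
G5 majority caps the overall affected fraction, so the per-group risks sit
somewhat above the published bands for G2–G4; both cannot be matched at
once with five haplotypes and multiplicative odds.

**What the generator does not emulate:** linkage disequilibrium and
haplotype structure, population stratification, genotyping error and
missingness (missingness enters only through hand-edited fixtures),
variable age at onset (affection is a fixed label, as in the analysis), and
parental affection (parents are forced unaffected rather than resampled,
which slightly distorts prevalence). Passing tests therefore demonstrate
correctness of the estimators under the assumed sampling model, not
robustness to these real-data features.

**Estimand note.** The conditional-logistic TDT estimates penetrance
*ratios*. Under the Bernoulli(odds/(1+odds)) disease model these equal the
generative odds multipliers only when absolute risk is small. With the
cohort-scale defaults (proband risks up to ~50% in G1) the estimates are
visibly attenuated (e.g. ≈1.8 for a generative 2.36); this is a property of
the estimand, not an estimator defect. Parameter-recovery tests therefore
run in the rare-disease regime (flat HLA effect, baseline penetrance
8×10⁻⁴, 5000 two-child families), where a pilot showed negligible bias and
nominal CI coverage.

## Problem sizes used in the test suite

Unit and property tests run on constructed matched sets and cohorts of
25–1200 families. The coverage study uses 100 seeded replicates of 5000
families; the AFBAC recovery check uses 1000 trios; interaction power uses a
single 3000-family cohort with a generative product term of 3. These sizes
were chosen as the smallest at which the asserted statistical properties are
stable.

## Known limitations

* The exact genotype→group lookup table of the original study is
  unpublished; grouping is encoded from the published prose rules, and edge
  pairs default to G5.
* Whether the original TDT used 1 or 3 pseudo-controls is not stated; this
  package implements the 3-pseudo-control standard (the 1-pseudo-control
  variant corresponds to dropping two grid cells and is not exposed).
* Whether AFBAC controls were allele- or genotype-based for SNPs is not
  stated; genotype-based is the default, allele-based is an option.
* The model-selection rule (smallest p) and the even-n median convention are
  reasonable but undocumented in the source study; both are flagged where
  they surface.
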