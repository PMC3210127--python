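"""Sequential Bayes score: updates, score tables, sib scoring, refined risk."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import spearmanr

from cdsibrisk import reference
from cdsibrisk.bayes import (
    BayesScoreModel,
    LikelihoodRatioTable,
    bayes_update,
    build_score_table,
    compute_bs,
    reconstruct_bs,
    refined_risk,
    score_sibs,
)
from cdsibrisk.panel import risk_panel
from cdsibrisk.simulate import generate_cohort, risk_sim_params
from cdsibrisk.tdt import MODELS

LOCI = ["rs1464510", "rs842647", "rs2816316"]  # LPP, REL, RGS1 (table order)


def make_lrt(hla_fcase, hla_fctrl, snp_tables):
    factors = {"HLA": {g + 1: (hla_fcase[g], hla_fctrl[g]) for g in range(5)}}
    order = []
    for locus, (cats, fcase, fctrl) in snp_tables.items():
        factors[locus] = {c: (a, b) for c, a, b in zip(cats, fcase, fctrl)}
        order.append(locus)
    return LikelihoodRatioTable(factors, snp_order=order)


def canonical_lrt(lpp=(0.2, 0.35, 0.45), rel=(0.55, 0.45), rgs=(0.5, 0.5),
                  hla_case=(0.30, 0.20, 0.30, 0.15, 0.05)):
    """A complete LRT over the three-SNP layout with controllable case freqs;
    control frequencies fixed to a reference profile."""
    return make_lrt(
        hla_case,
        (0.10, 0.08, 0.25, 0.17, 0.40),
        {
            "rs1464510": (["CC", "AC", "AA"], lpp, (0.35, 0.45, 0.20)),
            "rs842647": (["AG|GG", "AA"], rel, (0.65, 0.35)),
            "rs2816316": (["AC|CC", "AA"], rgs, (0.40, 0.60)),
        },
    )


class TestBayesUpdate:
    @pytest.mark.parametrize(
        "prior,fc,f0,expected",
        [
            (0.5, 0.2, 0.2, 0.5),
            (0.5, 0.4, 0.2, 2 / 3),
            (0.3, 0.4, 0.2, 6 / 13),  # odds 3/7 * 2 = 6/7 -> 6/13
        ],
    )
    def test_formula(self, prior, fc, f0, expected):
        assert bayes_update(prior, fc, f0) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("prior", [0.0, 1.0, -0.1, 1.1])
    def test_boundary_prior_rejected(self, prior):
        with pytest.raises(ValueError):
            bayes_update(prior, 0.5, 0.5)

    def test_zero_frequency_rejected(self):
        with pytest.raises(ValueError):
            bayes_update(0.5, 0.0, 0.5)

    @given(
        prior=st.floats(0.01, 0.99),
        lrs=st.lists(st.floats(0.05, 20.0), min_size=2, max_size=5),
    )
    def test_update_order_invariance(self, prior, lrs):
        def chain(order):
            p = prior
            for lr in order:
                p = bayes_update(p, lr / (lr + 1), 1 / (lr + 1))
            return p

        base = chain(lrs)
        for perm in itertools.islice(itertools.permutations(lrs), 6):
            assert chain(perm) == pytest.approx(base, abs=1e-12)


class TestComputeBs:
    def test_all_lrs_one_returns_prior(self):
        lrt = make_lrt(
            [0.2] * 5, [0.2] * 5,
            {"rs1464510": (["CC", "AC", "AA"], (1 / 3,) * 3, (1 / 3,) * 3)},
        )
        bs = compute_bs(3, {"rs1464510": "AC"}, lrt, prior=0.37)
        assert bs == pytest.approx(0.37, abs=1e-12)

    def test_odds_product_oracle(self):
        # LRs HLA 4.0, LPP 2.0, REL 1.5, RGS1 1.2 at prior 0.5 -> 14.4/15.4
        lrt = make_lrt(
            [0.4, 0.15, 0.15, 0.15, 0.15],
            [0.1, 0.225, 0.225, 0.225, 0.225],
            {
                "rs1464510": (["CC", "AC", "AA"], (0.5, 0.2, 0.3), (0.25, 0.2, 0.55)),
                "rs842647": (["AG|GG", "AA"], (0.6, 0.4), (0.4, 0.6)),
                "rs2816316": (["AC|CC", "AA"], (0.6, 0.4), (0.5, 0.5)),
            },
        )
        profile = {"rs1464510": "CC", "rs842647": "AG|GG", "rs2816316": "AC|CC"}
        bs = compute_bs(1, profile, lrt, prior=0.5)
        assert bs == pytest.approx(14.4 / 15.4, abs=1e-12)

    def test_missing_profile_entry_or_category_raises(self):
        lrt = make_lrt(
            [0.2] * 5, [0.2] * 5,
            {"rs1464510": (["CC", "AC", "AA"], (1 / 3,) * 3, (1 / 3,) * 3)},
        )
        with pytest.raises(KeyError):
            compute_bs(1, {}, lrt)  # profile lacks the locus
        with pytest.raises(KeyError):
            compute_bs(1, {"rs1464510": "ZZ"}, lrt)  # unknown class label


class TestScoreTable:
    def test_uniform_at_prior_when_lrs_one(self):
        lrt = make_lrt(
            [0.2] * 5, [0.2] * 5,
            {l: (c, f, f) for l, (c, f, _) in {
                "rs1464510": (["CC", "AC", "AA"], (1 / 3,) * 3, None),
                "rs842647": (["AG|GG", "AA"], (0.5, 0.5), None),
                "rs2816316": (["AC|CC", "AA"], (0.5, 0.5), None),
            }.items()},
        )
        table = build_score_table(lrt, prior=0.5)
        assert len(table.scores) == 60
        assert all(v == pytest.approx(0.5, abs=1e-12) for v in table.scores.values())

    @given(data=st.data())
    def test_monotone_when_risk_lrs_exceed_one(self, data):
        """Rows ordered by risk classes and columns by group stay monotone
        whenever every step in risk class multiplies the odds by LR > 1."""
        draw = lambda lo, hi: data.draw(st.floats(lo, hi))
        hla_lr = sorted([draw(0.1, 10.0) for _ in range(5)], reverse=True)
        hla_ctrl = np.array([0.1, 0.08, 0.25, 0.17, 0.40])
        hla_case = hla_ctrl * hla_lr
        hla_case /= hla_case.sum()
        # realised HLA LRs keep the decreasing order after normalisation
        lpp_step = draw(1.05, 4.0)
        rel_step = draw(1.05, 4.0)
        rgs_step = draw(1.05, 4.0)
        lpp_ctrl = np.array([0.35, 0.45, 0.20])
        lpp_case = lpp_ctrl * lpp_step ** np.arange(3)
        lpp_case /= lpp_case.sum()
        rel_ctrl = np.array([0.65, 0.35])
        rel_case = rel_ctrl * rel_step ** np.arange(2)
        rel_case /= rel_case.sum()
        rgs_ctrl = np.array([0.40, 0.60])
        rgs_case = rgs_ctrl * rgs_step ** np.arange(2)
        rgs_case /= rgs_case.sum()
        lrt = make_lrt(
            hla_case, hla_ctrl,
            {
                "rs1464510": (["CC", "AC", "AA"], lpp_case, lpp_ctrl),
                "rs842647": (["AG|GG", "AA"], rel_case, rel_ctrl),
                "rs2816316": (["AC|CC", "AA"], rgs_case, rgs_ctrl),
            },
        )
        table = build_score_table(lrt)
        ranked = {
            "rs1464510": ["CC", "AC", "AA"],
            "rs842647": ["AG|GG", "AA"],
            "rs2816316": ["AC|CC", "AA"],
        }
        for g in range(1, 6):
            for i, locus in enumerate(table.snp_order):
                for profile in table.profiles:
                    pos = ranked[locus].index(profile[i])
                    if pos + 1 < len(ranked[locus]):
                        higher = list(profile)
                        higher[i] = ranked[locus][pos + 1]
                        assert table.bs(g, tuple(higher)) >= table.bs(g, profile) - 1e-12
        for profile in table.profiles:
            for g in range(1, 5):
                assert table.bs(g, profile) >= table.bs(g + 1, profile) - 1e-12

    def test_logit_additivity_exact_on_generated_table(self):
        lrt = canonical_lrt()
        table = build_score_table(lrt, prior=0.5)
        logit = lambda p: math.log(p / (1 - p))
        baseline = table.profiles[0]
        for g in range(1, 6):
            offset = logit(table.bs(g, baseline)) - logit(table.bs(1, baseline))
            for profile in table.profiles:
                assert logit(table.bs(g, profile)) - logit(table.bs(1, profile)) == (
                    pytest.approx(offset, abs=1e-10)
                )

    def test_ranking_invariant_to_prior(self):
        lrt = canonical_lrt()
        tables = {p: build_score_table(lrt, prior=p) for p in (0.1, 0.5, 0.9)}
        profiles = tables[0.5].profiles
        for g in range(1, 6):
            base = [tables[0.5].bs(g, pr) for pr in profiles]
            for p in (0.1, 0.9):
                other = [tables[p].bs(g, pr) for pr in profiles]
                rho = spearmanr(base, other).statistic
                assert rho == pytest.approx(1.0, abs=1e-12)

    def test_scores_strictly_interior_even_with_zero_tallies(self, panel3):
        params = risk_sim_params(n_families=30, seed=5)
        cohort = generate_cohort(params).cohort
        res = BayesScoreModel(cohort, panel3, loci=LOCI).fit()
        assert all(0.0 < v < 1.0 for v in res.score_table.scores.values())


class TestPrintedTableReconstruction:
    """The published 5x12 score table against the logit-additivity identity."""

    def test_corner_cells_reconstruct_to_printed_value(self):
        for group, expected in ((5, 0.30), (4, 0.81)):
            base, singles = reference.single_factor_cells(group)
            assert reconstruct_bs(base, singles) == pytest.approx(expected, abs=0.01)

    def test_all_printed_cells_reconstruct_within_rounding(self):
        # 2-dp rounding of the four input cells propagates through the logit;
        # tolerance reflects that rounding, not model misfit
        logit = lambda p: math.log(p / (1 - p))
        for group in (1, 2, 3, 4, 5):
            col = reference.score_column(group)
            base = col[("CC", "AG|GG", "AC|CC")]
            deltas = {
                "rs1464510": {"CC": 0.0},
                "rs842647": {"AG|GG": 0.0},
                "rs2816316": {"AC|CC": 0.0},
            }
            deltas["rs842647"]["AA"] = logit(col[("CC", "AA", "AC|CC")]) - logit(base)
            deltas["rs2816316"]["AA"] = logit(col[("CC", "AG|GG", "AA")]) - logit(base)
            deltas["rs1464510"]["AC"] = logit(col[("AC", "AG|GG", "AC|CC")]) - logit(base)
            single_aa = col[("AA", "AG|GG", "AC|CC")]
            if single_aa is not None:
                deltas["rs1464510"]["AA"] = logit(single_aa) - logit(base)
            else:
                # group 3's LPP-only cell is the unobserved combination; back
                # it out of the fully loaded cell instead
                deltas["rs1464510"]["AA"] = (
                    logit(col[("AA", "AA", "AA")])
                    - logit(base)
                    - deltas["rs842647"]["AA"]
                    - deltas["rs2816316"]["AA"]
                )
            for (lpp, rel, rgs), printed in col.items():
                if printed is None:
                    continue
                z = (
                    logit(base)
                    + deltas["rs1464510"][lpp]
                    + deltas["rs842647"][rel]
                    + deltas["rs2816316"][rgs]
                )
                rebuilt = 1 / (1 + math.exp(-z))
                assert rebuilt == pytest.approx(printed, abs=0.02), (group, lpp, rel, rgs)


class TestScoreSibs:
    def _fitted(self, n=80, seed=21):
        params = risk_sim_params(n_families=n, seed=seed)
        cohort = generate_cohort(params).cohort
        res = BayesScoreModel(cohort, risk_panel(), loci=LOCI).fit()
        return cohort, res

    def test_identical_genotypes_get_identical_scores(self):
        cohort, res = self._fitted()
        scored, _ = res.score_sibs()
        seen = {}
        for s in scored:
            key = (s.group, s.profile)
            seen.setdefault(key, s.bs)
            assert s.bs == seen[key]

    def test_missing_genotypes_are_excluded_and_counted(self):
        cohort, res = self._fitted()
        cohort.sibs[0].snps["rs1464510"] = None
        cohort.sibs[1].hla = None
        scored, excluded = score_sibs(
            cohort.sibs, res.score_table, risk_panel(), res.snp_models
        )
        assert excluded == 2
        assert len(scored) == len(cohort.sibs) - 2

    def test_affected_sibs_score_higher_on_average(self):
        params = risk_sim_params(n_families=1200, seed=8)
        cohort = generate_cohort(params).cohort
        res = BayesScoreModel(cohort, risk_panel(), loci=LOCI).fit()
        scored, _ = res.score_sibs()
        aff = [s.bs for s in scored if s.affected]
        unaff = [s.bs for s in scored if not s.affected]
        assert len(aff) > 50
        assert np.mean(aff) > np.mean(unaff)


class TestRefinedRisk:
    def test_prior_returned_when_snp_lrs_one(self, panel3):
        lrt = make_lrt(
            [0.2] * 5, [0.2] * 5,
            {l: (c, f, f) for l, (c, f, _) in {
                "rs1464510": (["CC", "AC", "AA"], (1 / 3,) * 3, None),
                "rs842647": (["AG|GG", "AA"], (0.5, 0.5), None),
                "rs2816316": (["AC|CC", "AA"], (0.5, 0.5), None),
            }.items()},
        )
        snp_models = {
            "rs1464510": MODELS["additive"],
            "rs842647": MODELS["recessive"],
            "rs2816316": MODELS["recessive"],
        }
        per_profile, by_count = refined_risk(lrt, panel3, snp_models)
        for _, row in per_profile.iterrows():
            assert row["risk"] == pytest.approx(row["prior"], abs=1e-12)
            assert row["fold_change"] == pytest.approx(1.0, abs=1e-9)
        assert set(by_count["risk_allele_count"]) == {0, 1, 2, 3, 4, 5, 6}

    def test_group5_odds_oracle(self, panel3):
        # single aggregate SNP multiplier of 4 on prior 0.005 -> 0.0197
        lrt = make_lrt(
            [0.2] * 5, [0.2] * 5,
            {"rs1464510": (["CC", "AC", "AA"], (0.1, 0.1, 0.8), (0.4, 0.4, 0.2))},
        )
        snp_models = {"rs1464510": MODELS["additive"]}
        per_profile, _ = refined_risk(
            lrt, panel3, snp_models, priors={5: 0.005}
        )
        row = per_profile[(per_profile["group"] == 5) & (per_profile["rs1464510"] == "AA")]
        expected = (0.005 / 0.995 * 4) / (1 + 0.005 / 0.995 * 4)
        assert row["risk"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_risk_increases_with_allele_count_when_per_allele_lr_constant(self, panel3):
        """With a common per-allele LR s > 1 at every locus, each profile's
        odds scale as s^count, so the count-aggregated curve is strictly
        increasing (the aggregation averages profiles with equal count)."""
        s = 1.3
        lpp_ctrl = np.array([0.35, 0.45, 0.20])
        lpp_case = lpp_ctrl * s ** np.arange(3)
        lpp_case /= lpp_case.sum()
        rel_ctrl = np.array([0.65, 0.35])
        rel_case = rel_ctrl * np.array([1.0, s**2])
        rel_case /= rel_case.sum()
        rgs_ctrl = np.array([0.40, 0.60])
        rgs_case = rgs_ctrl * np.array([1.0, s**2])
        rgs_case /= rgs_case.sum()
        lrt = make_lrt(
            (0.2,) * 5, (0.2,) * 5,
            {
                "rs1464510": (["CC", "AC", "AA"], lpp_case, lpp_ctrl),
                "rs842647": (["AG|GG", "AA"], rel_case, rel_ctrl),
                "rs2816316": (["AC|CC", "AA"], rgs_case, rgs_ctrl),
            },
        )
        snp_models = {
            "rs1464510": MODELS["additive"],
            "rs842647": MODELS["recessive"],
            "rs2816316": MODELS["recessive"],
        }
        _, by_count = refined_risk(lrt, panel3, snp_models, priors={3: 0.1})
        risks = by_count.sort_values("risk_allele_count")["risk"].to_numpy()
        assert np.all(np.diff(risks) > 0)
        # and per-profile: upgrading any single class never lowers the risk
        per_profile, _ = refined_risk(lrt, panel3, snp_models, priors={3: 0.1})
        ranked = {"rs1464510": ["CC", "AC", "AA"], "rs842647": ["AG|GG", "AA"],
                  "rs2816316": ["AC|CC", "AA"]}
        risk_of = {
            (r["rs1464510"], r["rs842647"], r["rs2816316"]): r["risk"]
            for _, r in per_profile.iterrows()
        }
        for (lpp, rel, rgs), risk in risk_of.items():
            for i, locus in enumerate(("rs1464510", "rs842647", "rs2816316")):
                classes = ranked[locus]
                cur = (lpp, rel, rgs)
                pos = classes.index(cur[i])
                if pos + 1 < len(classes):
                    nxt = list(cur)
                    nxt[i] = classes[pos + 1]
                    assert risk_of[tuple(nxt)] > risk
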