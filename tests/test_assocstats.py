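from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from armloy import assocstats, synthcohort as sc
from armloy.assocstats import (
    aberration_union,
    de_by_loy,
    expr_fraction_regression,
    fisher_exact,
    loy_age_logistic,
)

from conftest import male_pair_cohort


def fisher_enumeration(table) -> float:
    """Independent oracle: full hypergeometric enumeration over all 2x2
    tables with the observed margins (probability-mass two-sided rule)."""
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0

    def prob(x):
        return comb(c1, x) * comb(n - c1, r1 - x) / comb(n, r1)

    p_obs = prob(a)
    # relative tie tolerance mirrors the floating-point comparison used by
    # standard implementations of the probability-mass rule
    return sum(prob(x) for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
               if prob(x) <= p_obs * (1 + 1e-7))


def _log2_expr(groups: dict) -> pd.DataFrame:
    df = pd.DataFrame(groups).T
    df.index.name = "gene_id"
    return df


class TestDeByLoy:
    def test_hand_computed_pooled_t(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0, 3.0, 4.0, 5.0]],
            index=pd.Index(["g1"], name="gene_id"),
            columns=["a", "b", "c", "d", "e", "f"],
        )
        flags = pd.Series([True, True, True, False, False, False],
                          index=expr.columns)
        de = de_by_loy(expr, flags, scale="log2")
        row = de.iloc[0]
        assert row["t"] == pytest.approx(-2.449489742783178)
        assert row["df"] == 4
        assert row["p"] == pytest.approx(0.0705, abs=0.0005)

    def test_identical_groups_give_p_one(self):
        expr = pd.DataFrame(
            [[2.0, 2.0, 2.0, 2.0]], index=pd.Index(["g1"], name="gene_id"),
            columns=list("abcd"),
        )
        flags = pd.Series([True, True, False, False], index=expr.columns)
        de = de_by_loy(expr, flags, scale="log2")
        assert de.iloc[0]["t"] == 0.0
        assert de.iloc[0]["p"] == 1.0

    def test_swapping_group_labels_negates_t(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            rng.normal(5, 1, (10, 12)),
            index=pd.Index([f"g{i}" for i in range(10)], name="gene_id"),
            columns=[f"s{i}" for i in range(12)],
        )
        flags = pd.Series([True] * 5 + [False] * 7, index=expr.columns)
        de1 = de_by_loy(expr, flags, scale="log2")
        de2 = de_by_loy(expr, ~flags, scale="log2")
        assert np.allclose(de1["t"], -de2["t"])
        assert np.allclose(de1["p"], de2["p"])

    def test_planted_y_genes_and_only_them_reach_fdr(self):
        cfg = male_pair_cohort(n=34, n_loy=13, tissues=["tumor"])
        truth = sc.plant_events(cfg, 11)
        genes = sc.default_gene_annotation(11, 1000, seed=11)
        expr = sc.simulate_expression(truth, genes, noise_sd_log2=0.3)
        samples = [c for c in expr.columns if c != "chromosome"]
        flags = pd.Series({s: truth.loy_fraction(s) > 0 for s in samples})
        de = de_by_loy(expr, flags)
        sig = de[de["significant"]]
        assert len(sig) == 11
        assert set(sig["chromosome"]) == {"chrY"}
        assert (sig["t"] < 0).all()  # downregulated in carriers

    def test_non_y_genes_stay_null_across_seeds(self):
        bad = 0
        for seed in range(20):
            cfg = male_pair_cohort(n=24, n_loy=9, tissues=["tumor"])
            truth = sc.plant_events(cfg, 300 + seed)
            genes = sc.default_gene_annotation(5, 200, seed=seed)
            expr = sc.simulate_expression(truth, genes, noise_sd_log2=0.3)
            samples = [c for c in expr.columns if c != "chromosome"]
            flags = pd.Series({s: truth.loy_fraction(s) > 0 for s in samples})
            de = de_by_loy(expr, flags)
            if (de["significant"] & (de["chromosome"] != "chrY")).any():
                bad += 1
        assert bad <= 1

    def test_empty_group_rejected(self):
        expr = _log2_expr({"g1": {"a": 1.0, "b": 2.0, "c": 1.5}})
        flags = pd.Series([False, False, False], index=["a", "b", "c"])
        with pytest.raises(ValueError, match="two samples per group"):
            de_by_loy(expr, flags, scale="log2")

    def test_bh_controls_rate_under_global_null(self):
        rng = np.random.default_rng(5)
        n_genes, n = 10_000, 20
        expr = pd.DataFrame(
            rng.normal(0, 1, (n_genes, n)),
            index=pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id"),
            columns=[f"s{i}" for i in range(n)],
        )
        flags = pd.Series([True] * 10 + [False] * 10, index=expr.columns)
        de = de_by_loy(expr, flags, scale="log2")
        assert de["significant"].mean() <= 0.01


class TestExprFractionRegression:
    def test_exact_line_recovered(self):
        f = np.linspace(0, 1, 10)
        fit = expr_fraction_regression(10 - 8 * f, f)
        assert fit.slope == pytest.approx(-8.0)
        assert fit.intercept == pytest.approx(10.0)
        assert fit.r == pytest.approx(-1.0)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            expr_fraction_regression([1.0, 2.0, 3.0], [0.5, 0.5, 0.5])

    def test_generator_slope_recovered_within_two_se(self):
        from scipy import stats as ss

        hits = 0
        for seed in range(5):
            cfg = male_pair_cohort(n=50, n_loy=50, tissues=["tumor"],
                                   lo=1e-9, hi=0.9)
            truth = sc.plant_events(cfg, 40 + seed)
            genes = sc.default_gene_annotation(1, 0, seed=seed)
            base = float(genes["base_rpkm"].iloc[0])
            expr = sc.simulate_expression(truth, genes, noise_sd_log2=0.2)
            samples = [c for c in expr.columns if c != "chromosome"]
            f = np.array([truth.loy_fraction(s) for s in samples])
            fit = expr_fraction_regression(
                expr.loc["geneY01", samples].to_numpy(dtype=float), f
            )
            se = ss.linregress(f, expr.loc["geneY01", samples].astype(float)).stderr
            if fit.slope < 0 and abs(fit.slope - (-base)) < 2 * se:
                hits += 1
        assert hits >= 4


class TestLoyAgeLogistic:
    def test_permuted_ages_control_type_one_error(self):
        rng = np.random.default_rng(12)
        flags = np.array([1] * 8 + [0] * 44)
        ages = rng.normal(60, 8, 52)
        low = 0
        for _ in range(200):
            fit = loy_age_logistic(flags, rng.permutation(ages))
            if not fit.separated and fit.p < 0.05:
                low += 1
        # binomial(200, 0.05): mean 10, sd ~3
        assert low <= 20

    def test_all_flags_identical_rejected(self):
        with pytest.raises(ValueError, match="both"):
            loy_age_logistic([1, 1, 1], [50.0, 60.0, 70.0])

    def test_planted_age_effect_recovered_positive(self):
        positive = 0
        for seed in range(60):
            cfg = dict(
                n_male=52, tissues=["normal"],
                events=[dict(arm="chrY", kind="loss", tissue="normal", n=5,
                             fraction_range=(0.2, 0.6))],
            )
            truth = sc.plant_events(cfg, 500 + seed)
            carriers = set(truth.events["sample_id"])
            flags = truth.samples["sample_id"].isin(carriers).to_numpy()
            fit = loy_age_logistic(flags.astype(int), truth.samples["age"].to_numpy())
            if fit.separated or fit.beta_age > 0:
                positive += 1
        assert positive >= 54  # >= 90% of seeds

    def test_complete_separation_reported_not_raised(self):
        flags = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        ages = np.array([50.0, 51, 52, 53, 70, 71, 72, 73])
        fit = loy_age_logistic(flags, ages)
        assert fit.separated


class TestFisherExact:
    def test_mutation_by_lox_table_reproduces_printed_p(self):
        # 3 mutated samples, all among the 7 X-loss carriers of 41 females
        table = [[3, 0], [4, 34]]
        p = fisher_exact(table)
        assert p == pytest.approx(fisher_enumeration(table), rel=1e-9)
        assert p == pytest.approx(0.003283, abs=1e-5)
        # one-sided mass of the observed table: C(7,3)/C(41,3) = 35/10660
        assert p == pytest.approx(35 / 10660, rel=1e-9)

    def test_balanced_table_enumeration(self):
        assert fisher_exact([[1, 1], [1, 1]]) == pytest.approx(
            fisher_enumeration([[1, 1], [1, 1]])
        )
        assert fisher_exact([[1, 1], [1, 1]]) == 1.0

    def test_zero_margin_gives_p_one(self):
        assert fisher_exact([[0, 0], [5, 7]]) == 1.0
        assert fisher_exact([[3, 0], [4, 0]]) == 1.0

    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    def test_matches_enumeration_and_symmetries(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        t = [[a, b], [c, d]]
        p = fisher_exact(t)
        assert p == pytest.approx(fisher_enumeration(t), rel=1e-8, abs=1e-12)
        assert fisher_exact([[a, c], [b, d]]) == pytest.approx(p, rel=1e-8)  # transpose
        assert fisher_exact([[c, d], [a, b]]) == pytest.approx(p, rel=1e-8)  # row swap

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            fisher_exact([[1.5, 2], [3, 4]])


class TestAberrationUnion:
    def _female_cohort(self):
        # 7 X-loss deletions, 2 extra focal deletions, 3 mutations inside
        # the X-loss set -> union of 9 affected among 41
        lox = [True] * 7 + [False] * 34
        focal = [False] * 7 + [True] * 2 + [False] * 32
        mut = [True] * 3 + [False] * 38
        return pd.DataFrame(
            dict(sex=["female"] * 41, lox_del=lox, focal_del=focal, kdm5c_mut=mut)
        )

    def test_printed_union_counts(self):
        out = aberration_union(
            self._female_cohort(), ["lox_del", "focal_del", "kdm5c_mut"]
        )
        row = out.set_index("sex").loc["female"]
        assert row["n"] == 41
        assert row["n_affected"] == 9
        assert row["percent"] == 22

    def test_all_false_gives_zero(self):
        df = pd.DataFrame(dict(sex=["male"] * 5, a=[False] * 5))
        out = aberration_union(df, ["a"]).set_index("sex").loc["male"]
        assert out["n_affected"] == 0
        assert out["percent"] == 0

    def test_matches_bruteforce_rowwise_or(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            dict(
                sex=rng.choice(["male", "female"], 60),
                a=rng.random(60) < 0.3,
                b=rng.random(60) < 0.2,
                c=rng.random(60) < 0.1,
            )
        )
        out = aberration_union(df, ["a", "b", "c"]).set_index("sex")
        for sex in ("male", "female"):
            sub = df[df["sex"] == sex]
            expect = sum(bool(r.a or r.b or r.c) for r in sub.itertuples())
            assert out.loc[sex, "n_affected"] == expect

    def test_unknown_sex_label_rejected(self):
        df = pd.DataFrame(dict(sex=["male", "other"], a=[True, False]))
        with pytest.raises(ValueError, match="sex"):
            aberration_union(df, ["a"])
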