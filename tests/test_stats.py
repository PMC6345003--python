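import itertools
import math
import random

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bshprof.stats import (
    IndividualMeta,
    chisq_presence,
    cohort_compare,
    mann_whitney_fdr,
    multivariable_adjust,
    screen_individuals,
    spearman_phenotype,
)
from oracles import bh_stepup, mann_whitney_enumeration_p


def person(sample_id="s", population="P", gender="female", age=30.0, bmi=24.0, status="healthy"):
    return IndividualMeta(sample_id, population, gender, age, bmi, status)


class TestScreenIndividuals:
    def test_healthy_in_range_retained(self):
        retained, excluded = screen_individuals([person(bmi=25.0, age=30.0)])
        assert len(retained) == 1 and not excluded

    @pytest.mark.parametrize("bmi", [18.5, 29.9, 31.0, 17.0])
    def test_bmi_strict_bounds(self, bmi):
        retained, excluded = screen_individuals([person(bmi=bmi)])
        assert not retained
        assert "bmi" in excluded[0][1]

    @pytest.mark.parametrize("age", [12.0, 75.0, 80.0, 10.0])
    def test_age_strict_bounds(self, age):
        retained, _ = screen_individuals([person(age=age)])
        assert not retained

    def test_missing_bmi_and_age_pass(self):
        retained, _ = screen_individuals([person(bmi=None, age=None)])
        assert len(retained) == 1
        retained, _ = screen_individuals([person(bmi=float("nan"), age=float("nan"))])
        assert len(retained) == 1

    def test_disease_excluded(self):
        retained, excluded = screen_individuals([person(status="T2D")])
        assert not retained
        assert excluded == [("s", "status=T2D")]


class TestMannWhitneyFdr:
    def test_identical_groups_p_one(self):
        results = mann_whitney_fdr([("t", [1, 2, 3], [1, 2, 3])])
        assert results[0].p_raw == pytest.approx(1.0, abs=0.05)

    def test_spec_example_exact_p(self):
        results = mann_whitney_fdr([("t", [1, 2, 3], [4, 5, 6])])
        assert results[0].p_raw == pytest.approx(0.1)

    def test_bh_family_example(self):
        # the BH implementation used across families agrees with the direct
        # step-up formula on the canonical worked example
        from statsmodels.stats.multitest import multipletests

        pvals = [0.01, 0.02, 0.03, 0.04]
        q_impl = list(multipletests(pvals, method="fdr_bh")[1])
        assert q_impl == pytest.approx([0.04] * 4)
        assert q_impl == pytest.approx(bh_stepup(pvals))

    def test_single_comparison_q_equals_p(self):
        results = mann_whitney_fdr([("only", [1, 2, 5], [4, 8, 9])])
        assert results[0].q_fdr == pytest.approx(results[0].p_raw)

    def test_empty_group_named_in_error(self):
        with pytest.raises(ValueError, match="badcase"):
            mann_whitney_fdr([("badcase", [], [1.0])])

    def test_matches_full_enumeration_for_small_samples(self):
        rng = random.Random(17)
        for _ in range(12):
            n1 = rng.randint(2, 5)
            n2 = rng.randint(2, 10 - n1)
            pooled = rng.sample(range(100), n1 + n2)  # distinct -> no ties
            x, y = pooled[:n1], pooled[n1:]
            expected = mann_whitney_enumeration_p(x, y)
            got = mann_whitney_fdr([("t", x, y)])[0].p_raw
            assert got == pytest.approx(expected), (x, y)

    def test_bh_monotone_after_stepup(self):
        rng = np.random.default_rng(2)
        family = []
        for i in range(8):
            a = rng.normal(0, 1, 12)
            b = rng.normal(0.3 * i, 1, 12)
            family.append((f"t{i}", a, b))
        results = mann_whitney_fdr(family)
        ordered = sorted(results, key=lambda r: r.p_raw)
        qs = [r.q_fdr for r in ordered]
        assert all(q1 <= q2 + 1e-12 for q1, q2 in zip(qs, qs[1:]))


class TestSpearman:
    def phenotype(self, pops, values, indicator="diabetes_death_rate"):
        return pd.DataFrame({"population": pops, indicator: values})

    def test_perfect_monotone_increasing(self):
        pops = ["a", "b", "c", "d"]
        res = spearman_phenotype(
            dict(zip(pops, [1, 2, 3, 4])), self.phenotype(pops, [10, 20, 30, 40]),
            "diabetes_death_rate",
        )
        assert res.statistic == pytest.approx(1.0)

    def test_perfect_monotone_decreasing(self):
        pops = ["a", "b", "c", "d"]
        res = spearman_phenotype(
            dict(zip(pops, [1, 2, 3, 4])), self.phenotype(pops, [40, 30, 20, 10]),
            "diabetes_death_rate",
        )
        assert res.statistic == pytest.approx(-1.0)

    def test_rank_difference_formula_example(self):
        # x = (1..5), y = (1,3,2,5,4): sum d^2 = 4 -> r = 1 - 24/120 = 0.8
        pops = list("abcde")
        res = spearman_phenotype(
            dict(zip(pops, [1, 2, 3, 4, 5])), self.phenotype(pops, [1, 3, 2, 5, 4]),
            "diabetes_death_rate",
        )
        assert res.statistic == pytest.approx(0.8)

    def test_exact_permutation_p_small_n(self):
        pops = list("abcd")
        res = spearman_phenotype(
            dict(zip(pops, [1, 2, 3, 4])), self.phenotype(pops, [10, 20, 30, 40]),
            "diabetes_death_rate",
        )
        # P(|r| = 1) among 4! permutations = 2/24
        assert res.p_raw == pytest.approx(2 / 24)

    def test_too_few_overlapping_populations(self):
        with pytest.raises(ValueError, match="overlap"):
            spearman_phenotype(
                {"a": 1.0, "b": 2.0}, self.phenotype(["a", "b"], [1, 2]),
                "diabetes_death_rate",
            )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(21)
        pops = [f"p{i}" for i in range(12)]
        x = rng.uniform(0, 1, 12)
        y = rng.uniform(0, 1, 12)
        base = spearman_phenotype(
            dict(zip(pops, x)), self.phenotype(pops, y), "diabetes_death_rate"
        )
        transformed = spearman_phenotype(
            dict(zip(pops, np.exp(5 * x))), self.phenotype(pops, y ** 3),
            "diabetes_death_rate",
        )
        assert base.statistic == pytest.approx(transformed.statistic)
        assert -1.0 <= base.statistic <= 1.0


class TestChisqPresence:
    def test_hand_computed_example(self):
        res = chisq_presence([[20, 10], [10, 20]])
        assert res.statistic == pytest.approx(20 / 3)

    def test_identical_rows_statistic_zero(self):
        res = chisq_presence([[15, 5], [15, 5]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_raw == pytest.approx(1.0)

    def test_diagonal_table(self):
        res = chisq_presence([[10, 0], [0, 10]])
        assert res.statistic == pytest.approx(20.0)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chisq_presence([[0, 0], [5, 5]])

    def test_negative_or_float_rejected(self):
        with pytest.raises(ValueError):
            chisq_presence([[1.5, 2.0], [3.0, 4.0]])


def make_cohort(n=200, pop_effect=0.0, seed=0, n_pops=4):
    rng = np.random.default_rng(seed)
    pops = rng.choice([f"P{i}" for i in range(n_pops)], size=n)
    pop_means = {f"P{i}": pop_effect * i for i in range(n_pops)}
    data = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "population": pops,
            "gender": rng.choice(["female", "male"], size=n),
            "age": rng.uniform(18, 70, size=n),
            "bmi": rng.normal(24, 2, size=n),
        }
    )
    data["ra"] = [pop_means[p] for p in pops] + rng.standard_normal(n)
    return data


class TestMultivariableAdjust:
    def test_population_only_response_explains_everything(self):
        data = make_cohort(n=120, pop_effect=1.0, seed=3)
        data["ra"] = data["population"].map({f"P{i}": float(i) for i in range(4)})
        results = {r.factor: r for r in multivariable_adjust(data)}
        assert results["population"].variance_explained == pytest.approx(100.0)
        assert results["age"].variance_explained <= 1e-6

    def test_type_one_error_uniform_p(self):
        # null simulation oracle: with a pure-noise response each factor's
        # partial-F p value is Uniform(0,1)
        pvals = {f: [] for f in ("gender", "age", "bmi", "population")}
        for rep in range(300):
            data = make_cohort(n=60, pop_effect=0.0, seed=1000 + rep)
            for res in multivariable_adjust(data):
                pvals[res.factor].append(res.p_raw)
        from scipy import stats as sps

        for factor, ps in pvals.items():
            ks = sps.kstest(ps, "uniform")
            assert ks.pvalue > 1e-3, factor

    def test_planted_partial_r2_recovered(self):
        rng = np.random.default_rng(7)
        n = 500
        data = make_cohort(n=n, seed=8, n_pops=10)
        mu = data["population"].str.slice(1).astype(float).to_numpy()
        mu = (mu - mu.mean()) / mu.std()
        noise = rng.standard_normal(n)
        noise = (noise - noise.mean()) / noise.std()
        target = 0.35  # the planted share of variance carried by population
        data["ra"] = math.sqrt(target) * mu + math.sqrt(1 - target) * noise
        results = {r.factor: r for r in multivariable_adjust(data)}
        assert results["population"].variance_explained == pytest.approx(35.0, abs=5.0)

    def test_collinearity_named(self):
        data = make_cohort(n=50, seed=5)
        data["bmi"] = data["age"] * 2.0  # aliased
        with pytest.raises(ValueError, match="aliased"):
            multivariable_adjust(data)

    def test_single_level_categorical_rejected(self):
        data = make_cohort(n=40, seed=6)
        data["gender"] = "female"
        with pytest.raises(ValueError, match="gender"):
            multivariable_adjust(data)

    def test_noise_covariate_barely_moves_variance_explained(self):
        data = make_cohort(n=600, pop_effect=1.0, seed=9)
        base = {r.factor: r.variance_explained for r in multivariable_adjust(data)}
        data2 = data.copy()
        rng = np.random.default_rng(10)
        data2["noise"] = rng.standard_normal(len(data2))
        extended = {
            r.factor: r.variance_explained
            for r in multivariable_adjust(
                data2, factors=("gender", "age", "bmi", "population", "noise")
            )
        }
        for factor in ("gender", "age", "bmi", "population"):
            assert abs(base[factor] - extended[factor]) < 1.0


class TestCohortCompare:
    def phylo_ra(self, n_per_arm=40, effect=0.0, absent_fraction=0.0, seed=0):
        rng = np.random.default_rng(seed)
        n = 2 * n_per_arm
        samples = [f"s{i}" for i in range(n)]
        status = ["healthy"] * n_per_arm + ["disease"] * n_per_arm
        data = {}
        for t in range(4):
            values = rng.lognormal(0, 0.5, size=n)
            if effect and t == 0:
                values[n_per_arm:] *= effect
            if absent_fraction and t == 3:
                mask = rng.random(n) < absent_fraction
                values[mask] = 0.0
            data[f"T{t + 1}"] = values
        ra = pd.DataFrame(data, index=samples)
        meta = pd.DataFrame({"sample_id": samples, "status": status})
        return ra, meta

    def test_planted_effect_detected(self):
        detections = 0
        for rep in range(20):
            ra, meta = self.phylo_ra(effect=3.0, seed=100 + rep)
            results = cohort_compare(ra, meta)
            flagged = {r.factor for r in results if r.q_fdr is not None and r.q_fdr < 0.05}
            detections += "T1" in flagged
        assert detections / 20 >= 0.8

    def test_identical_arms_rarely_flagged(self):
        false_hits = 0
        for rep in range(60):
            ra, meta = self.phylo_ra(effect=0.0, seed=500 + rep)
            results = cohort_compare(ra, meta)
            if any(r.q_fdr < 0.05 for r in results if r.q_fdr is not None):
                false_hits += 1
        assert false_hits / 60 <= 0.10

    def test_zero_inflated_phylotype_routed_to_chisq(self):
        ra, meta = self.phylo_ra(absent_fraction=0.7, seed=42)
        results = {r.factor: r for r in cohort_compare(ra, meta)}
        assert results["T4"].test_name == "chisq"
        assert results["T1"].test_name == "mannwhitney"

    def test_single_family_q_equals_p(self):
        ra, meta = self.phylo_ra(seed=7)
        results = cohort_compare(ra[["T1"]], meta)
        assert results[0].q_fdr == pytest.approx(results[0].p_raw)

    def test_missing_contrast_label_rejected(self):
        ra, meta = self.phylo_ra(seed=8)
        meta["status"] = "healthy"
        with pytest.raises(ValueError, match="disease"):
            cohort_compare(ra, meta)
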