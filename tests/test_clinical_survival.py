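import numpy as np
import pandas as pd
import pytest

from ihas import clinical_survival as cs


class TestFeatureFilter:
    def _table(self, feature, values):
        return pd.DataFrame(
            {"sample": [f"s{i}" for i in range(len(values))],
             "feature": feature, "value": values}
        )

    def test_mostly_missing_feature_dropped(self):
        values = ["a", "b"] + [np.nan] * 8
        assert cs.filter_clinical_features(self._table("f", values), 10) == []

    def test_constant_feature_dropped(self):
        assert cs.filter_clinical_features(self._table("f", ["x"] * 10), 10) == []

    def test_continuous_numeric_feature_dropped(self):
        values = [str(v) for v in np.linspace(0, 1, 40)]
        assert cs.filter_clinical_features(self._table("age", values), 40) == []

    def test_categorical_feature_kept(self):
        values = ["low", "high"] * 20
        assert cs.filter_clinical_features(self._table("grade", values), 40) == ["grade"]


class TestConcentrationCoefficient:
    def test_worked_example(self):
        """Three groups dominated by 23/34, 12/20 and 13/24 samples give
        cc = 48/78 = 0.6154."""
        crosstab = pd.DataFrame(
            [[23, 11, 0], [12, 8, 0], [13, 6, 5]],
            index=[1, 2, 3], columns=["low", "intermediate", "high"],
        )
        crosstab.iloc[0] = [23, 6, 5]  # totals 34, 20, 24
        crosstab.iloc[1] = [12, 5, 3]
        crosstab.iloc[2] = [13, 6, 5]
        assert cs.concentration_coefficient(crosstab) == pytest.approx(48 / 78)
        assert cs.concentration_coefficient(crosstab) == pytest.approx(0.6154, abs=1e-4)

    def test_pure_groups_give_one(self):
        crosstab = pd.DataFrame([[10, 0], [0, 7]])
        assert cs.concentration_coefficient(crosstab) == 1.0

    def test_even_split_gives_half(self):
        crosstab = pd.DataFrame([[5, 5], [8, 8]])
        assert cs.concentration_coefficient(crosstab) == 0.5

    def test_finest_partition_gives_one(self):
        groups = {f"s{i}": i for i in range(6)}
        labels = {f"s{i}": "ab"[i % 2] for i in range(6)}
        crosstab = cs.crosstab_groups_labels(groups, labels)
        assert cs.concentration_coefficient(crosstab) == 1.0

    def test_invariant_to_relabeling(self, rng):
        groups = {f"s{i}": int(g) for i, g in enumerate(rng.integers(0, 3, 60))}
        labels = {f"s{i}": f"v{l}" for i, l in enumerate(rng.integers(0, 4, 60))}
        cc1 = cs.concentration_coefficient(cs.crosstab_groups_labels(groups, labels))
        renamed = {s: {"v0": "x3", "v1": "x1", "v2": "x0", "v3": "x2"}[v]
                   for s, v in labels.items()}
        cc2 = cs.concentration_coefficient(cs.crosstab_groups_labels(groups, renamed))
        assert cc1 == pytest.approx(cc2)


class TestPermutationBaseline:
    def test_constant_label_always_one(self, rng):
        groups = {f"s{i}": i % 2 for i in range(10)}
        labels = {f"s{i}": "only" for i in range(10)}
        null = cs.permutation_concentration_baseline(groups, labels, 20, rng)
        np.testing.assert_allclose(null, 1.0)

    def test_small_case_matches_exhaustive_enumeration(self, rng):
        """4 samples, 2 groups: the permutation distribution of cc matches
        enumeration over all 4! label orders."""
        import itertools

        groups = {"s0": 0, "s1": 0, "s2": 1, "s3": 1}
        labels = {"s0": "a", "s1": "a", "s2": "b", "s3": "b"}
        lab = ["a", "a", "b", "b"]
        exact = []
        for perm in itertools.permutations(lab):
            crosstab = cs.crosstab_groups_labels(
                groups, dict(zip(["s0", "s1", "s2", "s3"], perm))
            )
            exact.append(cs.concentration_coefficient(crosstab))
        null = cs.permutation_concentration_baseline(groups, labels, 3000, rng)
        for q in (0.25, 0.5, 0.75):
            assert np.quantile(null, q) == pytest.approx(np.quantile(exact, q), abs=0.01)
        assert np.mean(null) == pytest.approx(np.mean(exact), abs=0.02)

    def test_planted_concentration_beats_null(self, rng):
        groups = {f"s{i}": i // 40 for i in range(120)}
        labels = {}
        values = ["a", "b", "c"]
        for i in range(120):
            g = i // 40
            if rng.random() < 0.9:
                labels[f"s{i}"] = values[g]
            else:
                labels[f"s{i}"] = values[(g + 1) % 3]
        observed = cs.concentration_coefficient(cs.crosstab_groups_labels(groups, labels))
        null = cs.permutation_concentration_baseline(groups, labels, 200, rng)
        assert observed > np.quantile(null, 0.95)


class TestPancancerCodes:
    def test_bit_patterns_map_to_printed_codes(self):
        table = pd.DataFrame(
            {
                "MGG1": [0.1, 0.9, 0.5, 0.2],
                "MGG2": [0.2, 0.8, 0.6, 0.1],
                "MGG3": [0.9, 0.1, 0.5, 0.8],
            },
            index=["SG_001", "SG_110", "SG_mid", "SG_other"],
        )
        codes = cs.assign_pancancer_sample_groups(table)
        assert codes["SG_001"] == 1  # low, low, high
        assert codes["SG_110"] == 6  # high, high, low

    def test_all_low_is_code_zero(self):
        table = pd.DataFrame(
            {"MGG1": [0.0, 1.0], "MGG2": [0.0, 1.0], "MGG3": [0.0, 1.0]},
            index=["low", "high"],
        )
        codes = cs.assign_pancancer_sample_groups(table)
        assert codes["low"] == 0
        assert codes["high"] == 7

    def test_requires_three_columns(self):
        with pytest.raises(ValueError):
            cs.assign_pancancer_sample_groups(pd.DataFrame({"a": [1], "b": [2]}))


def simulate_survival(rng, n, beta, x=None, censor_frac=0.25):
    x = rng.normal(size=n) if x is None else x
    times = rng.exponential(1.0 / np.exp(beta * x))
    censor = np.where(rng.random(n) < censor_frac,
                      rng.uniform(0, times.max(), n), np.inf)
    return pd.DataFrame({
        "sample": [f"s{i}" for i in range(n)],
        "time_days": np.minimum(times, censor),
        "event": (times <= censor).astype(int),
    }), x


class TestCoxCoefficients:
    def test_null_covariates_have_small_beta(self, rng):
        surv, _ = simulate_survival(rng, 1000, 0.0)
        expr = pd.DataFrame(
            rng.normal(size=(100, 1000)),
            index=[f"g{i}" for i in range(100)], columns=surv["sample"],
        )
        stats_ = cs.cox_coefficients(expr, surv)
        small = [abs(s.cox_beta) < 0.1 for s in stats_ if s.converged]
        assert np.mean(small) >= 0.95

    def test_recovers_planted_log_hazard_ratio(self, rng):
        x = rng.integers(0, 2, 1000).astype(float)
        surv, _ = simulate_survival(rng, 1000, np.log(2), x=x)
        expr = pd.DataFrame([x], index=["g"], columns=surv["sample"])
        stat = cs.cox_coefficients(expr, surv)[0]
        assert stat.cox_beta == pytest.approx(np.log(2), abs=0.15)

    def test_matches_independent_newton_oracle(self, rng):
        """n = 20 with no ties: the fitted beta matches a from-scratch
        Newton maximization of the Cox partial likelihood to 1e-6."""
        n = 20
        x = rng.normal(size=n)
        times = rng.exponential(1.0 / np.exp(0.5 * x))
        assert len(np.unique(times)) == n  # no ties
        event = np.ones(n, dtype=int)
        surv = pd.DataFrame({"sample": [f"s{i}" for i in range(n)],
                             "time_days": times, "event": event})
        expr = pd.DataFrame([x], index=["g"], columns=surv["sample"])
        fitted = cs.cox_coefficients(expr, surv)[0].cox_beta

        def partial_derivs(beta):
            order = np.argsort(times)
            xo, to = x[order], times[order]
            d1 = d2 = 0.0
            for i in range(n):
                at_risk = to >= to[i]
                w = np.exp(beta * xo[at_risk])
                s0, s1, s2 = w.sum(), (xo[at_risk] * w).sum(), (xo[at_risk] ** 2 * w).sum()
                d1 += xo[i] - s1 / s0
                d2 += -(s2 / s0 - (s1 / s0) ** 2)
            return d1, d2

        beta = 0.0
        for _ in range(50):
            d1, d2 = partial_derivs(beta)
            step = -d1 / d2
            beta += step
            if abs(step) < 1e-12:
                break
        assert fitted == pytest.approx(beta, abs=1e-6)

    def test_all_censored_raises(self):
        surv = pd.DataFrame({"sample": ["a", "b", "c"],
                             "time_days": [1.0, 2.0, 3.0], "event": [0, 0, 0]})
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=["a", "b", "c"])
        with pytest.raises(ValueError):
            cs.cox_coefficients(expr, surv)


class TestPdiff:
    def test_identical_samples_give_zero(self, rng):
        x = rng.normal(size=50)
        assert cs.pdiff_statistic(x, x.copy(), epsilon=0.0) == pytest.approx(0.0)

    def test_fully_separated_singletons(self):
        assert cs.pdiff_statistic(np.array([1.0]), np.array([0.0]), 0.5) == 1.0

    def test_three_pair_enumeration(self):
        # cross pairs: (0,1) neither; (2,1) greater; (2,1) greater -> 2/3 - 1/3
        val = cs.pdiff_statistic(np.array([0.0, 2.0, 2.0]), np.array([1.0]), 0.5)
        assert val == pytest.approx(2 / 3 - 1 / 3)

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=40), rng.normal(0.3, 1.2, 60)
        assert cs.pdiff_statistic(a, b, 0.1) == pytest.approx(
            -cs.pdiff_statistic(b, a, 0.1)
        )

    def test_bounded_and_monotone_in_epsilon(self, rng):
        a, b = rng.normal(1.0, 1.0, 50), rng.normal(size=70)
        vals = [cs.pdiff_statistic(a, b, e) for e in (0.0, 0.5, 1.0, 2.0)]
        assert all(-1 <= v <= 1 for v in vals)
        assert all(later <= earlier + 1e-12 for earlier, later in zip(vals, vals[1:]))

    def test_subsampled_path_close_to_exact(self, rng):
        a, b = rng.normal(0.5, 1, 4000), rng.normal(size=4000)
        exact = cs.pdiff_statistic(a, b, 0.1)
        approx = cs.pdiff_statistic(a, b, 0.1, max_pairs=90_000)
        assert approx == pytest.approx(exact, abs=0.05)


class TestLogrank:
    def test_identical_groups_are_indistinguishable(self, rng):
        surv1, _ = simulate_survival(rng, 40, 0.0)
        dup = surv1.copy()
        dup["sample"] = [f"t{i}" for i in range(40)]
        surv = pd.concat([surv1, dup], ignore_index=True)
        groups = {**{f"s{i}": 0 for i in range(40)}, **{f"t{i}": 1 for i in range(40)}}
        stat, p, curves = cs.logrank_sample_groups(surv, groups)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-6)
        assert set(curves) == {0, 1}

    def test_hand_computed_two_group_instance(self):
        """6 subjects, no censoring: log-rank statistic computed by hand
        from the observed-vs-expected death table."""
        surv = pd.DataFrame({
            "sample": list("abcdef"),
            "time_days": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [1, 1, 1, 1, 1, 1],
        })
        groups = dict(zip("abcdef", [0, 1, 0, 1, 0, 1]))
        # at each death time: n at risk, group-0 at risk, expected deaths
        # t=1: 6 at risk, 3 in g0, death in g0 -> O-E = 1 - 3/6
        # t=2: 5 at risk, 2 in g0, death in g1 -> 0 - 2/5 ... etc.
        o_minus_e = (1 - 3 / 6) + (0 - 2 / 5) + (1 - 2 / 4) + (0 - 1 / 3) + (1 - 1 / 2)
        var = (
            (3 / 6) * (3 / 6) + (2 / 5) * (3 / 5) + (2 / 4) * (2 / 4)
            + (1 / 3) * (2 / 3) + (1 / 2) * (1 / 2)
        )  # hypergeometric variances with d_j = 1 (last death: 1 at risk, var 0)
        expected_stat = o_minus_e ** 2 / var
        stat, _p, _ = cs.logrank_sample_groups(surv, groups)
        assert stat == pytest.approx(expected_stat, rel=1e-6)

    def test_power_against_planted_hazard_ratio(self):
        """Hazard ratio 3 between two groups of 100: p < 0.01 in at least
        18 of 20 seeds."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = np.repeat([0.0, 1.0], 100)
            surv, _ = simulate_survival(rng, 200, np.log(3.0), x=x)
            groups = {f"s{i}": int(x[i]) for i in range(200)}
            _stat, p, _ = cs.logrank_sample_groups(surv, groups)
            if p < 0.01:
                hits += 1
        assert hits >= 18

    def test_degenerate_groups_raise(self):
        surv = pd.DataFrame({"sample": ["a", "b"], "time_days": [1.0, 2.0],
                             "event": [1, 0]})
        with pytest.raises(ValueError):
            cs.logrank_sample_groups(surv, {"a": 0, "b": 1})
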