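"""Survival and contingency statistics against hand-computed oracles."""

import itertools
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from metaquad import (
    ClinicalTable,
    ConvergenceError,
    ValidationError,
    VariantTable,
    alteration_frequency_test,
    categorical_association,
    cox_fit,
    fisher_exact_rxc,
    km_logrank,
)


def _clin(times, events, **cols):
    idx = [f"p{i}" for i in range(len(times))]
    return ClinicalTable(
        pd.DataFrame({"time": times, "event": events, **cols}, index=idx)
    )


def logrank_oracle(times, events, groups):
    """Tabular k-group log-rank: O-E and hypergeometric variance at each event time."""
    df = pd.DataFrame({"t": times, "e": events, "g": groups})
    levels = sorted(df["g"].unique())
    O = np.zeros(len(levels))
    E = np.zeros(len(levels))
    V = np.zeros((len(levels), len(levels)))
    for t in sorted(df.loc[df["e"] == 1, "t"].unique()):
        at_risk = df[df["t"] >= t]
        n = len(at_risk)
        d = int(((df["t"] == t) & (df["e"] == 1)).sum())
        for i, g in enumerate(levels):
            n_g = int((at_risk["g"] == g).sum())
            d_g = int(((df["t"] == t) & (df["e"] == 1) & (df["g"] == g)).sum())
            O[i] += d_g
            E[i] += d * n_g / n
            for j, h in enumerate(levels):
                n_h = int((at_risk["g"] == h).sum())
                same = 1.0 if i == j else 0.0
                if n > 1:
                    V[i, j] += d * (n_g / n) * (same - n_h / n) * (n - d) / (n - 1)
    z = (O - E)[:-1]
    stat = float(z @ np.linalg.solve(V[:-1, :-1], z))
    return stat


class TestKmLogrank:
    def test_identical_groups_give_null_statistic(self):
        times = [1, 2, 3, 4, 1, 2, 3, 4]
        events = [1, 0, 1, 1, 1, 0, 1, 1]
        clin = _clin(times, events)
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=clin.sample_ids)
        fit = km_logrank(clin, groups)
        assert fit.logrank_stat == pytest.approx(0.0, abs=1e-12)
        assert fit.logrank_p == pytest.approx(1.0)

    def test_matches_tabular_oracle_on_six_event_fixture(self):
        times = [1, 2, 3, 4, 5, 6]
        events = [1] * 6
        clin = _clin(times, events)
        groups = pd.Series(["A", "A", "A", "B", "B", "B"], index=clin.sample_ids)
        fit = km_logrank(clin, groups)
        oracle = logrank_oracle(times, events, list(groups))
        assert fit.logrank_stat == pytest.approx(oracle, rel=1e-9)

    def test_three_group_statistic_matches_oracle(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(10, 30).round(2) + 0.1
        events = rng.integers(0, 2, 30)
        events[0] = 1
        clin = _clin(times, events)
        groups = pd.Series(rng.choice(["a", "b", "c"], 30), index=clin.sample_ids)
        fit = km_logrank(clin, groups)
        oracle = logrank_oracle(times, events, list(groups))
        assert fit.logrank_stat == pytest.approx(oracle, rel=1e-6)
        assert fit.dof == 2

    def test_km_without_censoring_is_empirical_survival(self):
        times = [2.0, 4.0, 6.0, 8.0]
        clin = _clin(times, [1, 1, 1, 1])
        groups = pd.Series(["a", "a", "a", "b"], index=clin.sample_ids)
        fit = km_logrank(clin, groups)
        km = fit.km["a"].set_index("time")["survival"]
        assert km.loc[2.0] == pytest.approx(2 / 3)
        assert km.loc[4.0] == pytest.approx(1 / 3)
        assert km.loc[6.0] == pytest.approx(0.0)

    def test_km_final_value_is_product_of_factors(self):
        times = [1, 2, 2, 3, 5, 7, 7, 9]
        events = [1, 1, 0, 1, 0, 1, 1, 0]
        clin = _clin(times, events)
        groups = pd.Series(["a"] * 8 + [], index=clin.sample_ids)
        groups.iloc[-1] = "b"  # second group so the call is valid
        fit = km_logrank(clin, groups)
        sub = pd.DataFrame({"t": times[:7], "e": events[:7]})
        surv = 1.0
        for t in sorted(sub.loc[sub["e"] == 1, "t"].unique()):
            n = int((sub["t"] >= t).sum())
            d = int(((sub["t"] == t) & (sub["e"] == 1)).sum())
            surv *= 1 - d / n
        assert fit.km["a"]["survival"].iloc[-1] == pytest.approx(surv, rel=1e-12)

    def test_two_group_statistic_is_squared_standardized_oe(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(10, 20).round(1) + 0.1
        events = np.ones(20, dtype=int)
        clin = _clin(times, events)
        groups = pd.Series(rng.choice(["a", "b"], 20), index=clin.sample_ids)
        fit = km_logrank(clin, groups)
        # algebraic identity: chi2 = (O-E)^2 / V for two groups
        df = pd.DataFrame({"t": times, "e": events, "g": list(groups)})
        O = E = V = 0.0
        for t in sorted(df.loc[df.e == 1, "t"].unique()):
            risk = df[df.t >= t]
            n, d = len(risk), int(((df.t == t) & (df.e == 1)).sum())
            n_a = int((risk.g == "a").sum())
            O += int(((df.t == t) & (df.e == 1) & (df.g == "a")).sum())
            E += d * n_a / n
            if n > 1:
                V += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
        assert fit.logrank_stat == pytest.approx((O - E) ** 2 / V, rel=1e-9)

    def test_no_events_rejected(self):
        clin = _clin([1, 2, 3, 4], [0, 0, 0, 0])
        groups = pd.Series(["a", "a", "b", "b"], index=clin.sample_ids)
        with pytest.raises(ValidationError, match="event"):
            km_logrank(clin, groups)


def efron_partial_loglik(beta, times, events, x):
    """Explicit Efron partial log-likelihood for a single covariate."""
    ll = 0.0
    for t in np.unique(times[events == 1]):
        tied = (times == t) & (events == 1)
        risk = times >= t
        m = int(tied.sum())
        eta = beta * x
        r = np.exp(eta[risk]).sum()
        rt = np.exp(eta[tied]).sum()
        ll += beta * x[tied].sum()
        for l in range(m):
            ll -= np.log(r - (l / m) * rt)
    return ll


class TestCoxFit:
    def test_beta_matches_grid_search_oracle(self):
        times = np.array([3.0, 5.0, 7.0, 2.0, 11.0, 4.0, 9.0, 13.0])
        events = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        x = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 1.0, 0.0, 0.0])
        clin = _clin(times, events, x=x)
        res = cox_fit(clin, covariates=("x",))
        grid = np.arange(-5.0, 5.0, 1e-4)
        ll = [efron_partial_loglik(b, times, events, x) for b in grid]
        beta_oracle = grid[int(np.argmax(ll))]
        assert res.summary.loc["x", "coef"] == pytest.approx(beta_oracle, abs=1e-3)

    def test_duplicating_every_record_replication_behavior(self):
        """Replicating every record leaves the Breslow estimate exactly in
        place (the log-likelihood just doubles) while Efron's tie correction
        shifts it only slightly — verified numerically against a Breslow
        partial-likelihood oracle maximized by scalar optimization."""
        from scipy.optimize import minimize_scalar

        rng = np.random.default_rng(5)
        n = 40
        x = rng.integers(0, 2, n).astype(float)
        times = rng.exponential(10 / np.exp(0.7 * x)) + 0.01
        events = (rng.random(n) < 0.8).astype(int)

        def breslow_negloglik(beta, t, e, xv):
            ll = 0.0
            for ti in np.unique(t[e == 1]):
                tied = (t == ti) & (e == 1)
                risk = t >= ti
                ll += beta * xv[tied].sum() - tied.sum() * np.log(np.exp(beta * xv[risk]).sum())
            return -ll

        def breslow_fit(t, e, xv):
            return minimize_scalar(
                breslow_negloglik, args=(t, e, xv), bounds=(-5, 5), method="bounded",
                options={"xatol": 1e-10},
            ).x

        b1 = breslow_fit(times, events, x)
        b2 = breslow_fit(np.r_[times, times], np.r_[events, events], np.r_[x, x])
        assert abs(b1 - b2) < 1e-6  # Breslow: exact replication invariance

        clin = _clin(times, events, x=x)
        doubled = ClinicalTable(
            pd.concat([clin.records, clin.records.set_index(clin.records.index + "_dup")])
        )
        a = cox_fit(clin, covariates=("x",))
        b = cox_fit(doubled, covariates=("x",))
        # Efron is not exactly replication-invariant; the shift stays small
        assert abs(a.summary.loc["x", "coef"] - b.summary.loc["x", "coef"]) < 0.05

    def test_subtype_dummy_coding_against_quiescent(self, small_cohort):
        _, clinical, _, truth, _ = small_cohort
        res = cox_fit(clinical, labels=truth.labels, covariates=("age", "gender"))
        subtype_terms = [t for t in res.summary.index if t.startswith("subtype_")]
        assert sorted(subtype_terms) == [
            "subtype_cholesterogenic",
            "subtype_glycolytic",
            "subtype_mixed",
        ]

    def test_listwise_deletion_counted(self, small_cohort):
        _, clinical, _, truth, _ = small_cohort
        records = clinical.records.copy()
        records.loc[records.index[:10], "grade"] = np.nan
        res = cox_fit(ClinicalTable(records), labels=truth.labels, covariates=("age", "grade"))
        assert res.n_dropped == 10

    def test_constant_covariate_rejected(self):
        clin = _clin([1, 2, 3, 4], [1, 1, 1, 1], x=[1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValidationError, match="constant"):
            cox_fit(clin, covariates=("x",))

    def test_separation_detected(self):
        # perfect separation: all events in one covariate arm, far apart in time
        times = np.r_[np.arange(1.0, 11.0), np.arange(100.0, 110.0)]
        events = np.r_[np.ones(10), np.ones(10)].astype(int)
        x = np.r_[np.ones(10), np.zeros(10)]
        clin = _clin(times, events, x=x)
        with pytest.raises(ConvergenceError):
            cox_fit(clin, covariates=("x",))


def fisher_oracle_exact(table):
    """Independent enumeration with exact rational arithmetic."""
    table = np.asarray(table, dtype=int)
    R, C = table.sum(1), table.sum(0)
    N = int(table.sum())

    def fact(n):
        out = 1
        for i in range(2, n + 1):
            out *= i
        return out

    def prob(t):
        num = 1
        for r in R:
            num *= fact(int(r))
        for c in C:
            num *= fact(int(c))
        den = fact(N)
        for v in t.ravel():
            den *= fact(int(v))
        return Fraction(num, den)

    # enumerate all tables with the same margins
    p_obs = prob(table)
    total = Fraction(0)
    r, c = table.shape
    ranges = [range(min(R[i], C[j]) + 1) for i in range(r - 1) for j in range(c - 1)]
    for cells in itertools.product(*ranges):
        t = np.zeros((r, c), dtype=int)
        t[: r - 1, : c - 1] = np.array(cells).reshape(r - 1, c - 1)
        t[: r - 1, c - 1] = R[: r - 1] - t[: r - 1, : c - 1].sum(1)
        t[r - 1] = C - t[: r - 1].sum(0)
        if (t >= 0).all():
            p = prob(t)
            if p <= p_obs:
                total += p
    return float(total)


class TestFisherExact:
    def test_2x2_example_matches_enumeration_and_scipy(self):
        from scipy.stats import fisher_exact

        table = [[3, 1], [1, 3]]
        p, method = fisher_exact_rxc(table)
        assert method == "exact"
        assert p == pytest.approx(fisher_oracle_exact(table), abs=1e-12)
        assert p == pytest.approx(fisher_exact(table)[1], abs=1e-12)

    def test_2x3_matches_enumeration(self):
        table = [[5, 1, 2], [1, 4, 3]]
        p, method = fisher_exact_rxc(table)
        assert method == "exact"
        assert p == pytest.approx(fisher_oracle_exact(table), abs=1e-12)

    def test_monte_carlo_branch_agrees_with_exact(self):
        table = np.array([[60, 80], [90, 70]])  # total 300 > default exact cutoff
        p_mc, method = fisher_exact_rxc(table, n_mc=100_000)
        assert method == "monte_carlo"
        p_exact, _ = fisher_exact_rxc(table, max_exact_total=1000)
        assert abs(p_mc - p_exact) < 0.01

    def test_monte_carlo_fixed_seed_reproducible(self):
        table = np.array([[60, 80, 50], [90, 70, 60]])
        a, _ = fisher_exact_rxc(table, n_mc=2000)
        b, _ = fisher_exact_rxc(table, n_mc=2000)
        assert a == b


class TestAlterationFrequency:
    @pytest.fixture()
    def variants_and_labels(self):
        rng = np.random.default_rng(6)
        samples = [f"p{i}" for i in range(200)]
        labels = pd.Series(rng.choice(["quiescent", "mixed"], 200), index=samples)
        loss_p = np.where(labels == "mixed", 0.4, 0.1)
        calls = np.where(rng.random(200) < loss_p, "loss", "neutral")
        cnv = pd.DataFrame([calls, ["neutral"] * 200], index=["RB1", "FLAT"], columns=samples)
        return VariantTable(set(), cnv), labels

    def test_enriched_gene_detected_null_gene_not(self, variants_and_labels):
        variants, labels = variants_and_labels
        res = alteration_frequency_test(variants, labels, ["RB1"], mode="cnv_loss")
        assert res["RB1"].p < 0.01
        assert res["RB1"].frequencies["mixed"] > res["RB1"].frequencies["quiescent"]

    def test_null_gene_q_near_one(self):
        rng = np.random.default_rng(7)
        samples = [f"p{i}" for i in range(400)]
        labels = pd.Series(rng.choice(["quiescent", "mixed"], 400), index=samples)
        calls = np.where(rng.random(400) < 0.25, "loss", "neutral")
        cnv = pd.DataFrame([calls], index=["NULLG"], columns=samples)
        res = alteration_frequency_test(
            VariantTable(set(), cnv), labels, ["NULLG"], mode="cnv_loss"
        )
        assert res["NULLG"].q > 0.05

    def test_absent_gene_skipped_with_warning(self, variants_and_labels, caplog):
        variants, labels = variants_and_labels
        with caplog.at_level("WARNING"):
            res = alteration_frequency_test(variants, labels, ["RB1", "GHOST"])
        assert "GHOST" not in res
        assert any("GHOST" in r.message for r in caplog.records)

    def test_planted_default_rates_recovered(self, default_cohort):
        """RB1/LRP1B loss frequencies land within 3 binomial SDs of the
        generator's subtype-specific rates, and the contrast is significant."""
        cfg, (_, _, variants, truth, _) = default_cohort
        res = alteration_frequency_test(variants, truth.labels, ["RB1", "LRP1B"], mode="cnv_loss")
        for gene in ("RB1", "LRP1B"):
            for subtype in ("quiescent", "mixed"):
                p = cfg.cnv_loss_rates[gene][subtype]
                n = int((truth.labels == subtype).sum())
                sd = 100 * np.sqrt(p * (1 - p) / n)
                assert abs(res[gene].frequencies[subtype] - 100 * p) < 3 * sd
            assert res[gene].q < 0.05


class TestCategoricalAssociation:
    def test_hand_chi_square(self):
        labels = pd.Series(["a"] * 10 + ["b"] * 10)
        col = pd.Series(["x"] * 10 + ["y"] * 10)
        res = categorical_association(labels, col)
        assert res.test == "chi-square"
        assert res.statistic == pytest.approx(20.0)  # sum (O-E)^2/E with E=5
        assert res.p < 1e-4

    def test_low_expected_count_switches_to_fisher(self, caplog):
        labels = pd.Series(["a"] * 5 + ["b"] * 5)
        col = pd.Series(["x", "y", "z", "x", "y", "z", "x", "y", "z", "x"])
        with caplog.at_level("INFO"):
            res = categorical_association(labels, col)
        assert res.test.startswith("fisher")
        assert any("expected count" in r.message for r in caplog.records)

    def test_degenerate_variable_rejected(self):
        labels = pd.Series(["a", "a", "a"])
        col = pd.Series(["x", "y", "x"])
        with pytest.raises(ValidationError):
            categorical_association(labels, col)
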