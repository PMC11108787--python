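import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lctau.exceptions import (
    InsufficientDataError,
    StagingError,
    UndefinedCorrelationError,
)
from lctau.staging import (
    CLASS_LABELS,
    StagingThresholds,
    binomial_ci,
    classify_concordance,
    derive_thresholds,
    partial_spearman,
    welch_pairwise,
)
from lctau.synthetic import TangleSimSpec, gen_tangles, gen_threshold_fixture

from oracles import (
    clopper_pearson_by_inversion,
    partial_spearman_matrix_oracle,
    welch_oracle,
)


def _thresholds(lc=0.143, region=2.757, name="hippocampus"):
    return StagingThresholds(
        region=name, lc_max_at_braak0=0.379, lc_cutoff_mean=lc,
        lc_cutoff_ci=(lc - 0.1, lc + 0.1), region_max_at_prior_stage=7.91,
        region_cutoff_mean=region, region_cutoff_ci=(region - 1, region + 1))


class TestDeriveThresholds:
    def test_reproduces_reference_constants(self):
        table = gen_threshold_fixture()
        thr = derive_thresholds(table, "hippocampus")
        assert thr.lc_max_at_braak0 == pytest.approx(0.379, abs=1e-12)
        assert thr.lc_cutoff_mean == pytest.approx(0.143, abs=1e-12)
        assert thr.region_max_at_prior_stage == pytest.approx(7.91,
                                                              abs=1e-12)
        assert thr.region_cutoff_mean == pytest.approx(2.757, abs=1e-12)
        assert thr.lc_cutoff_ci[0] <= thr.lc_cutoff_mean <= \
            thr.lc_cutoff_ci[1]

    def test_all_equal_densities_zero_width_ci(self):
        rows = []
        for i in range(6):
            rows.append({"subject_id": i, "group": "unimpaired",
                         "braak": 0 if i < 3 else 2,
                         "lc_tangle_density": 0.5 if i != 0 else 0.7,
                         "hippocampus": 3.0 if i != 1 else 5.0})
        table = pd.DataFrame(rows)
        thr = derive_thresholds(table, "hippocampus")
        # sub-cutoff sets are constant -> mean == value, CI width 0
        assert thr.lc_cutoff_mean == pytest.approx(0.5)
        assert thr.lc_cutoff_ci[0] == pytest.approx(thr.lc_cutoff_ci[1])

    def test_hand_computed_t_interval(self):
        vals = np.array([0.10, 0.12, 0.15, 0.09, 0.20, 0.11])
        rows = [{"subject_id": "m", "group": "impaired", "braak": 0,
                 "lc_tangle_density": 0.5, "hippocampus": 9.0},
                {"subject_id": "m2", "group": "impaired", "braak": 2,
                 "lc_tangle_density": 0.6, "hippocampus": 10.0}]
        rows += [{"subject_id": i, "group": "unimpaired", "braak": 1,
                  "lc_tangle_density": v, "hippocampus": 2.0 + v}
                 for i, v in enumerate(vals)]
        thr = derive_thresholds(pd.DataFrame(rows), "hippocampus")
        mean = vals.mean()
        half = stats.t.ppf(0.975, 5) * vals.std(ddof=1) / np.sqrt(6)
        assert thr.lc_cutoff_mean == pytest.approx(mean, abs=1e-12)
        assert thr.lc_cutoff_ci == pytest.approx((mean - half, mean + half),
                                                 abs=1e-12)
        assert thr.n_used["lc_mean"] == 6

    def test_row_order_invariance(self):
        table = gen_threshold_fixture()
        shuffled = table.sample(frac=1.0, random_state=3)
        a = derive_thresholds(table, "hippocampus")
        b = derive_thresholds(shuffled, "hippocampus")
        assert (a.lc_cutoff_mean, a.region_cutoff_mean) == \
            (b.lc_cutoff_mean, b.region_cutoff_mean)

    def test_empty_conditioning_set_raises(self):
        table = gen_threshold_fixture()
        table["braak"] = 5  # nobody at Braak 0
        with pytest.raises(StagingError):
            derive_thresholds(table, "hippocampus")


class TestClassify:
    def test_comparison_semantics(self):
        thr = _thresholds()
        table = pd.DataFrame({
            "subject_id": ["a"], "lc_tangle_density": [0.2],
            "hippocampus": [1.0]})
        res = classify_concordance(table, thr)
        assert res.classes.iloc[0] == "lc_only"

    def test_tie_goes_to_low(self):
        thr = _thresholds()
        table = pd.DataFrame({
            "subject_id": ["a"], "lc_tangle_density": [0.143],
            "hippocampus": [2.757]})
        res = classify_concordance(table, thr)
        assert res.classes.iloc[0] == "low_low"

    def test_counts_sum_to_n(self, rng):
        thr = _thresholds()
        table = pd.DataFrame({
            "subject_id": range(50),
            "lc_tangle_density": rng.uniform(0, 0.5, 50),
            "hippocampus": rng.uniform(0, 6, 50)})
        res = classify_concordance(table, thr)
        assert sum(res.counts.values()) == res.n == 50

    def test_monotone_rescale_invariance(self, rng):
        thr = _thresholds()
        table = pd.DataFrame({
            "subject_id": range(40),
            "lc_tangle_density": rng.uniform(0, 0.5, 40),
            "hippocampus": rng.uniform(0, 6, 40)})
        res1 = classify_concordance(table, thr)
        scaled = table.copy()
        scaled["lc_tangle_density"] *= 10
        scaled["hippocampus"] *= 10
        thr2 = _thresholds(lc=1.43, region=27.57)
        res2 = classify_concordance(scaled, thr2)
        assert res1.counts == res2.counts

    def test_recovers_planted_proportions(self):
        spec = TangleSimSpec(n_subjects=160, p_lc_only=0.20,
                             p_hipp_only=0.05, p_both=0.75, seed=9)
        table, truth = gen_tangles(spec)
        thr = _thresholds(lc=truth["lc_cutoff"],
                          region=truth["region_cutoff"])
        res = classify_concordance(table, thr)
        for cls, p in (("lc_only", 0.20), ("region_only", 0.05),
                       ("both", 0.75)):
            p_hat, lo, hi = res.proportions[cls]
            # within the exact-binomial 95% half-width around the truth
            _, tlo, thi, _ = binomial_ci(round(p * 160), 160)
            half = (thi - tlo) / 2
            assert abs(p_hat - p) <= half

    def test_all_both(self):
        spec = TangleSimSpec(n_subjects=30, p_lc_only=0.0, p_hipp_only=0.0,
                             p_both=1.0, seed=2)
        table, truth = gen_tangles(spec)
        thr = _thresholds(lc=truth["lc_cutoff"],
                          region=truth["region_cutoff"])
        res = classify_concordance(table, thr)
        assert res.counts["both"] == 30


class TestBinomialCi:
    @pytest.mark.parametrize("x, n, lo2, hi2", [
        (32, 160, 0.14, 0.27),
        (121, 160, 0.68, 0.82),
        (7, 160, 0.02, 0.09),
    ])
    def test_reference_intervals(self, x, n, lo2, hi2):
        _, lo, hi, _ = binomial_ci(x, n)
        assert round(lo, 2) == lo2
        assert round(hi, 2) == hi2

    def test_zero_boundary(self):
        p_hat, lo, hi, _ = binomial_ci(0, 10)
        assert p_hat == 0.0
        assert lo == 0.0
        assert hi < 1.0

    def test_full_boundary(self):
        _, lo, hi, _ = binomial_ci(10, 10)
        assert hi == 1.0

    def test_matches_tail_inversion_oracle(self):
        lo, hi = clopper_pearson_by_inversion(7, 25)
        _, blo, bhi, _ = binomial_ci(7, 25)
        assert blo == pytest.approx(lo, abs=1e-9)
        assert bhi == pytest.approx(hi, abs=1e-9)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            binomial_ci(11, 10)

    def test_coverage_conservative(self, rng):
        # exact intervals cover at >= nominal rate
        n = 160
        covered = 0
        trials = 400
        for _ in range(trials):
            p = rng.uniform(0.05, 0.95)
            x = rng.binomial(n, p)
            _, lo, hi, _ = binomial_ci(x, n)
            covered += lo <= p <= hi
        assert covered / trials >= 0.94


class TestWelch:
    def test_identical_groups(self):
        vals = list(np.arange(10.0)) * 2
        labels = ["a"] * 10 + ["b"] * 10
        out = welch_pairwise(labels, vals)
        row = out.iloc[0]
        assert row["t"] == pytest.approx(0.0, abs=1e-12)
        assert row["ci_low"] == pytest.approx(-row["ci_high"])

    def test_matches_textbook_formula(self):
        a = [1.1, 2.3, 1.9, 2.8]
        b = [3.0, 3.4, 2.9, 3.8, 3.3]
        out = welch_pairwise(["a"] * 4 + ["b"] * 5, a + b)
        t_o, df_o, ci_o = welch_oracle(np.array(a), np.array(b))
        row = out.iloc[0]
        assert row["t"] == pytest.approx(t_o, abs=1e-10)
        assert row["df"] == pytest.approx(df_o, abs=1e-10)
        assert (row["ci_low"], row["ci_high"]) == pytest.approx(ci_o,
                                                               abs=1e-10)

    def test_power_at_planted_shift(self, rng):
        hits = 0
        for i in range(50):
            r = np.random.default_rng(i)
            a = r.normal(0, 1, 50)
            b = r.normal(2, 1, 50)
            out = welch_pairwise(["a"] * 50 + ["b"] * 50,
                                 np.concatenate([a, b]))
            hits += out.iloc[0]["p"] < 0.001
        assert hits >= 49

    def test_abeta_contrast_in_generated_tangles(self):
        spec = TangleSimSpec(n_subjects=160, abeta_shift_high_braak=2.0,
                             seed=4)
        table, truth = gen_tangles(spec)
        from lctau.staging import classify_concordance
        thr = _thresholds(lc=truth["lc_cutoff"],
                          region=truth["region_cutoff"])
        res = classify_concordance(table, thr)
        out = welch_pairwise(res.classes, table["abeta_pct"])
        row = out[((out.group1 == "both") & (out.group2 == "lc_only")) |
                  ((out.group1 == "lc_only") & (out.group2 == "both"))]
        assert len(row) == 1
        assert row.iloc[0]["p"] < 0.01


class TestPartialSpearman:
    def test_reduces_to_plain_spearman(self, rng):
        x = rng.standard_normal(40)
        y = x + rng.normal(0, 0.5, 40)
        rho, p, n = partial_spearman(x, y)
        expected = stats.spearmanr(x, y).statistic
        assert rho == pytest.approx(expected, abs=1e-10)
        assert n == 40

    def test_monotone_transform_gives_one(self, rng):
        x = rng.standard_normal(30)
        y = np.exp(x)  # monotone
        cov = rng.standard_normal(30)
        rho, _, _ = partial_spearman(x, y, cov)
        assert rho == pytest.approx(1.0, abs=1e-10)

    def test_matches_matrix_algebra_oracle(self, rng):
        x = rng.standard_normal(25)
        y = rng.standard_normal(25)
        cov = rng.standard_normal((25, 3))
        rho, _, _ = partial_spearman(x, y, cov)
        assert rho == pytest.approx(
            partial_spearman_matrix_oracle(x, y, cov), abs=1e-12)

    def test_constant_input_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            partial_spearman(np.ones(20), np.arange(20.0))

    def test_insufficient_n(self):
        with pytest.raises(InsufficientDataError):
            partial_spearman(np.arange(4.0), np.arange(4.0),
                             np.ones((4, 2)))

    def test_generated_tangles_positive_lc_region_rho(self):
        spec = TangleSimSpec(n_subjects=600, within_subject_rho=0.8, seed=8)
        table, _ = gen_tangles(spec)
        un = table[table["group"] == "unimpaired"]
        rho, p, n = partial_spearman(
            un["lc_tangle_density"], un["hippocampus"],
            un[["age", "sex", "lc_neuron_density", "pmi"]].to_numpy())
        assert rho > 0.2
        assert p < 0.05
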