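import math

import numpy as np
import pandas as pd
import pytest

from asep.exceptions import EstimationError, ParameterError
from asep.variability import (
    VariabilityModel,
    beaton_days,
    intraindividual_correlation,
    liu_days,
    liu_error_term,
    pooled_intraindividual_sd,
    required_days_table,
)


def daily_frame(data, categories=None):
    rows = [
        {"participant_id": pid, "daily_asep": float(v)}
        for pid, values in data.items()
        for v in values
    ]
    frame = pd.DataFrame(rows)
    if categories:
        frame["diet_category"] = frame["participant_id"].map(categories)
    return frame


class TestPooledSd:
    def test_single_participant_two_days(self):
        s_hat, per = pooled_intraindividual_sd(daily_frame({"P1": [0.2, 0.4]}))
        assert per["P1"] == pytest.approx(0.1)  # population divisor: d = 2
        assert s_hat == pytest.approx(0.1)

    def test_constant_days_give_zero(self):
        _, per = pooled_intraindividual_sd(daily_frame({"P1": [0.3, 0.3, 0.3]}))
        assert per["P1"] == 0.0

    def test_day_weighted_pooling(self):
        s_hat, _ = pooled_intraindividual_sd(
            daily_frame({"P1": [0.2, 0.4], "P2": [0.3, 0.3]})
        )
        assert s_hat == pytest.approx((2 * 0.1 + 2 * 0.0) / 4)

    def test_vegans_excluded_by_category(self):
        frame = daily_frame(
            {"V": [0.0, 0.0], "O": [0.2, 0.4]},
            categories={"V": "vegan", "O": "omnivore"},
        )
        s_hat, per = pooled_intraindividual_sd(frame)
        assert "V" not in per.index
        assert s_hat == pytest.approx(0.1)

    def test_no_eligible_participant_is_an_error(self):
        with pytest.raises(EstimationError):
            pooled_intraindividual_sd(daily_frame({"V": [0.0, 0.0]}))

    def test_matches_first_principles_oracle_on_cohort(self, cohort_asep):
        daily, _ = cohort_asep
        s_hat, per = pooled_intraindividual_sd(daily)

        # independent brute-force recomputation from the definition
        groups = {}
        for row in daily.itertuples():
            if row.diet_category == "vegan":
                continue
            groups.setdefault(row.participant_id, []).append(row.daily_asep)
        num = den = 0.0
        for pid, values in groups.items():
            d = len(values)
            if d < 2:
                continue
            m = sum(values) / d
            s_i = math.sqrt(sum((v - m) ** 2 for v in values) / d)
            assert per[pid] == pytest.approx(s_i, abs=1e-12)
            num += d * s_i
            den += d
        assert s_hat == pytest.approx(num / den, abs=1e-12)


class TestBeaton:
    @pytest.mark.parametrize(
        "a, expected", [(0.1, 3), (0.05, 11), (0.02, 64), (0.01, 254)]
    )
    def test_day_requirements_from_pooled_sd(self, a, expected):
        assert beaton_days(0.0813, a) == expected

    def test_zero_variance_needs_one_day(self):
        assert beaton_days(0.0, 0.05) == 1

    def test_invalid_deviation_limit(self):
        with pytest.raises(ParameterError):
            beaton_days(0.08, 0.0)

    def test_monotone_in_precision_and_sd(self):
        grid = [0.2, 0.1, 0.05, 0.02, 0.01]
        days = [beaton_days(0.08, a) for a in grid]
        assert days == sorted(days)  # tighter a -> more days
        assert beaton_days(0.12, 0.05) >= beaton_days(0.08, 0.05)

    def test_halving_a_roughly_quadruples_days(self):
        d1 = beaton_days(0.0813, 0.02)
        d2 = beaton_days(0.0813, 0.01)
        assert d1 * 4 - 4 <= d2 <= d1 * 4


class TestLiu:
    def test_perfect_reliability_needs_one_day(self):
        assert liu_error_term(1.0, 1) == pytest.approx(1.0)
        assert liu_days(1.0) == 1

    def test_study_scale_error_term(self):
        # direct evaluation of the closed form at the 4-day design
        assert liu_error_term(0.537, 4) == pytest.approx(0.907, abs=5e-4)

    def test_four_days_for_r_0537(self):
        assert liu_days(0.537, 0.9) == 4

    def test_r_half(self):
        assert liu_days(0.5, 0.9) == 5  # ceil(0.81/0.19 * 1.0)

    def test_error_term_monotone_and_limits(self):
        values = [liu_error_term(0.537, n) for n in (1, 2, 4, 16, 1024)]
        assert values == sorted(values)
        assert values[-1] == pytest.approx(1.0, abs=1e-3)
        assert liu_error_term(0.9, 4) > liu_error_term(0.5, 4)

    def test_returned_days_are_minimal(self):
        for r in (0.2, 0.4, 0.537, 0.7, 0.95):
            d = liu_days(r, 0.9)
            assert liu_error_term(r, d) >= 0.9
            if d > 1:
                assert liu_error_term(r, d - 1) < 0.9

    @pytest.mark.parametrize("r", [0.0, -0.2, 1.5])
    def test_invalid_correlation(self, r):
        with pytest.raises(ParameterError):
            liu_days(r)


class TestPairCorrelation:
    def test_pure_between_person_variance(self):
        frame = daily_frame({"A": [0.2, 0.2], "B": [0.5, 0.5], "C": [0.7, 0.7]})
        r, n_pairs = intraindividual_correlation(frame)
        assert r == pytest.approx(1.0)
        assert n_pairs == 3

    def test_antithetic_two_participants(self):
        # brute force over the 4 ordered pairs gives exactly -1
        frame = daily_frame({"A": [0.0, 1.0], "B": [1.0, 0.0]})
        r, n_pairs = intraindividual_correlation(frame)
        assert r == pytest.approx(-1.0)
        assert n_pairs == 2

    def test_symmetrization_removes_order_dependence(self):
        frame = daily_frame({"A": [0.1, 0.5], "B": [0.3, 0.2], "C": [0.6, 0.9]})
        reversed_frame = daily_frame(
            {"A": [0.5, 0.1], "B": [0.2, 0.3], "C": [0.9, 0.6]}
        )
        r1, _ = intraindividual_correlation(frame)
        r2, _ = intraindividual_correlation(reversed_frame)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_recovers_icc_on_gaussian_cohorts(self):
        # 50 participants x 4 days with known variance components; the
        # pair correlation estimates sigma2_b / (sigma2_b + sigma2_w)
        sigma_b, sigma_w = 0.12, 0.08
        icc = sigma_b**2 / (sigma_b**2 + sigma_w**2)
        rng = np.random.default_rng(42)
        estimates = []
        for _ in range(10):
            mus = rng.normal(0.3, sigma_b, size=50)
            frame = daily_frame(
                {f"P{i}": rng.normal(mu, sigma_w, size=4) for i, mu in enumerate(mus)}
            )
            r, n_pairs = intraindividual_correlation(frame, exclude_vegan=False)
            assert n_pairs == 50 * 6
            estimates.append(r)
        assert np.mean(estimates) == pytest.approx(icc, abs=0.05)


class TestModelInterface:
    def test_fit_and_days_table(self, cohort_asep):
        daily, _ = cohort_asep
        fit = VariabilityModel(daily).fit()
        assert fit.s_hat > 0
        assert -1 <= fit.r_i <= 1
        table = fit.required_days_table(a_values=(0.05, 0.1))
        beaton = table[table["method"] == "beaton_absolute"].set_index("parameter")
        assert beaton.loc[0.05, "days"] == beaton_days(fit.s_hat, 0.05)
        liu_row = table[table["method"] == "liu"]
        assert int(liu_row["days"].iloc[0]) == liu_days(fit.r_i)
        assert "intraindividual" in fit.summary()

    def test_spearman_pair_method_available(self, cohort_asep):
        daily, _ = cohort_asep
        fit = VariabilityModel(daily, pair_method="spearman").fit()
        assert -1 <= fit.r_i <= 1

    def test_required_days_table_layout(self):
        table = required_days_table(s=0.0813, r=0.537)
        beaton = table[table["method"] == "beaton_absolute"]
        assert beaton["parameter"].tolist() == [0.005, 0.01, 0.02, 0.05, 0.1]
        assert beaton["days"].tolist() == [1016, 254, 64, 11, 3]
        liu_row = table[table["method"] == "liu"]
        assert liu_row["days"].tolist() == [4]
        assert liu_row["parameter"].tolist() == [0.9]
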