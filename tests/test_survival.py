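"""Survival curves, stability classes, decay fits, and the nested F test."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from spinedyn import (
    ADULT_SCHEDULE,
    SurvivalCurve,
    classify_spines,
    extra_sum_of_squares_f,
    f_test_from_ss,
    fit_decay,
    survival_curve,
)

# ---------------------------------------------------------------------------
# Independent brute-force oracle, written directly from the definitions:
# S(t) = #spines consistently present to t / #initially observed;
# stable = never absent, recurrent = absent then seen again,
# transient = absent and never seen again.
# ---------------------------------------------------------------------------


def oracle_survival(sequences):
    day0 = [seq for seq in sequences if seq[0] == "present"]
    n = len(day0)
    out = []
    for k in range(len(day0[0])):
        surviving = 0
        for seq in day0:
            if all(seq[i] != "absent" for i in range(k + 1)):
                surviving += 1
        out.append(surviving / n)
    return out


def oracle_classes(sequences):
    counts = {"stable": 0, "recurrent": 0, "transient": 0}
    for seq in sequences:
        if seq[0] != "present":
            continue
        if all(s != "absent" for s in seq):
            counts["stable"] += 1
            continue
        recurrent = any(
            seq[i] == "absent" and seq[j] != "absent"
            for i in range(len(seq))
            for j in range(i + 1, len(seq))
        )
        counts["recurrent" if recurrent else "transient"] += 1
    return counts


class TestSurvivalCurve:
    def test_all_present_is_flat(self, make_dataset):
        ds = make_dataset([("present",) * 8] * 5, days=ADULT_SCHEDULE.session_days)
        assert survival_curve(ds).survival == (1.0,) * 8

    def test_reappearance_does_not_resurrect(self, make_dataset):
        ds = make_dataset(
            [
                ("present", "present", "absent", "present"),
                ("present", "present", "present", "present"),
            ],
            days=(0, 1, 2, 7),
        )
        assert survival_curve(ds).survival == (1.0, 1.0, 0.5, 0.5)

    def test_hundred_spine_fixture(self, make_dataset):
        """20 of 100 day-0 spines first go absent by day 7 -> S(7) = 0.80."""
        days = ADULT_SCHEDULE.session_days
        gone_by_7 = [("present", "present", "absent") + ("absent",) * 5] * 12
        gone_at_7 = [("present", "present", "present", "absent") + ("absent",) * 4] * 8
        persistent = [("present",) * 8] * 80
        ds = make_dataset(gone_by_7 + gone_at_7 + persistent, days=days)
        curve = survival_curve(ds)
        assert curve.n_initial == 100
        assert curve.survival[days.index(7)] == pytest.approx(0.80)

    def test_day0_filopodia_excluded_by_default(self, make_dataset):
        ds = make_dataset(
            [("filopodia", "absent", "absent"), ("present", "present", "present")]
        )
        assert survival_curve(ds).n_initial == 1
        assert survival_curve(ds, include_filopodia=True).n_initial == 2

    def test_no_day0_spines_raises(self, make_dataset):
        ds = make_dataset([("absent", "present", "present")])
        with pytest.raises(ValueError, match="no day-0 spines"):
            survival_curve(ds)

    def test_monotone_and_starts_at_one_on_simulated_data(self):
        from spinedyn import SimulationConfig, simulate_cohort

        cfg = SimulationConfig(
            n_mice=6, n_features0=120, recurrence_prob=0.4, miss_prob=0.05,
            record_positions=False,
        )
        for ds in simulate_cohort({"WT": cfg}, 31):
            s = survival_curve(ds).survival
            assert s[0] == 1.0
            assert all(b <= a for a, b in zip(s, s[1:]))


class TestClassifySpines:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            (("present",) * 8, "stable"),
            (("present", "present", "present", "absent", "absent", "absent", "absent", "absent"), "transient"),
            (("present", "present", "present", "absent", "present", "absent", "absent", "absent"), "recurrent"),
        ],
    )
    def test_rules(self, make_dataset, seq, expected):
        ds = make_dataset([seq], days=ADULT_SCHEDULE.session_days)
        counts = classify_spines(ds)
        assert getattr(counts, f"n_{expected}") == 1
        assert counts.n_total == 1

    def test_two_sessions_is_an_error(self, make_dataset):
        ds = make_dataset([("present", "present")], days=(0, 7))
        with pytest.raises(ValueError, match="at least 3 sessions"):
            classify_spines(ds)


class TestOracleEquivalence:
    def test_exhaustive_single_spine_sequences(self, make_dataset):
        """Every status sequence over 4 sessions, checked against the oracle."""
        days = (0, 1, 2, 7)
        for seq in itertools.product(("present", "absent", "filopodia"), repeat=4):
            if seq[0] != "present":
                continue
            ds = make_dataset([seq], days=days)
            assert tuple(oracle_survival([seq])) == survival_curve(ds).survival
            counts = classify_spines(ds)
            assert oracle_classes([seq]) == {
                "stable": counts.n_stable,
                "recurrent": counts.n_recurrent,
                "transient": counts.n_transient,
            }

    def test_random_status_matrices(self, make_dataset):
        """10 spines x 5 sessions random matrices agree with the oracle and
        the three classes always partition the day-0 spines."""
        rng = np.random.default_rng(42)
        days = (0, 1, 2, 7, 14)
        statuses = np.array(["present", "absent", "filopodia"])
        for _ in range(200):
            seqs = [tuple(rng.choice(statuses, size=5)) for _ in range(9)]
            seqs.append(("present",) * 5)  # ensure >= 1 day-0 spine
            seqs = [s for s in seqs if any(x != "absent" for x in s)]
            ds = make_dataset(seqs, days=days)
            curve = survival_curve(ds)
            assert tuple(oracle_survival(seqs)) == pytest.approx(curve.survival)
            counts = classify_spines(ds)
            ocl = oracle_classes(seqs)
            assert counts.n_stable == ocl["stable"]
            assert counts.n_recurrent == ocl["recurrent"]
            assert counts.n_transient == ocl["transient"]
            assert counts.n_total == sum(1 for s in seqs if s[0] == "present")


# ---------------------------------------------------------------------------
# Decay fitting
# ---------------------------------------------------------------------------


def _noiseless_curve(sp, si, tau, mouse_id="m", times=ADULT_SCHEDULE.session_days):
    t = np.asarray(times, dtype=float)
    s = sp + si * np.exp(-t / tau)
    return SurvivalCurve(mouse_id, tuple(times), tuple(s), n_initial=100)


class TestFitDecay:
    @pytest.mark.parametrize("constrain_s0", [False, True])
    def test_noiseless_recovery(self, constrain_s0):
        curve = _noiseless_curve(0.7, 0.3, 5.0)
        fit = fit_decay([curve], constrain_s0=constrain_s0)
        assert fit.converged
        assert fit.sp == pytest.approx(0.7, abs=1e-6)
        assert fit.si == pytest.approx(0.3, abs=1e-6)
        assert fit.tau == pytest.approx(5.0, abs=1e-5)
        assert fit.ss < 1e-12
        assert fit.n_free_params == (2 if constrain_s0 else 3)
        assert fit.df == 8 - fit.n_free_params

    def test_flat_curve_unidentifiable(self, make_dataset):
        ds = make_dataset([("present",) * 8] * 5, days=ADULT_SCHEDULE.session_days)
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_decay([survival_curve(ds)])

    def test_too_few_points_rejected(self):
        c = SurvivalCurve("m", (0, 7), (1.0, 0.8), 10)
        with pytest.raises(ValueError, match="at least 4"):
            fit_decay([c])
        c2 = SurvivalCurve("n", (0, 7), (1.0, 0.75), 10)
        with pytest.raises(ValueError, match="distinct positive"):
            fit_decay([c, c2])  # 4 points but only one positive time

    def test_order_invariance_and_duplication(self):
        rng = np.random.default_rng(0)
        curves = []
        for i in range(5):
            t = np.asarray(ADULT_SCHEDULE.session_days, float)
            s = 0.75 + 0.25 * np.exp(-t / 7.0) + rng.normal(0, 0.01, t.size)
            s[0] = 1.0
            s = np.minimum.accumulate(np.clip(s, 0, 1))
            curves.append(
                SurvivalCurve(f"m{i}", ADULT_SCHEDULE.session_days, tuple(s), 200)
            )
        fit_fwd = fit_decay(curves)
        fit_rev = fit_decay(curves[::-1])
        assert fit_fwd.sp == pytest.approx(fit_rev.sp, abs=1e-8)
        assert fit_fwd.tau == pytest.approx(fit_rev.tau, rel=1e-6)
        fit_dup = fit_decay(curves * 2)
        assert fit_dup.sp == pytest.approx(fit_fwd.sp, abs=1e-6)
        assert fit_dup.tau == pytest.approx(fit_fwd.tau, rel=1e-4)
        assert fit_dup.ss == pytest.approx(2 * fit_fwd.ss, rel=1e-6)
        assert fit_dup.df == 2 * fit_fwd.n_points - 3

    def test_constrained_mode_pins_intercept(self):
        curve = _noiseless_curve(0.6, 0.4, 9.0)
        fit = fit_decay([curve], constrain_s0=True)
        assert fit.sp + fit.si == pytest.approx(1.0, abs=1e-12)

    def test_mean_pool_mode(self):
        curves = [_noiseless_curve(0.7, 0.3, 5.0, mouse_id=f"m{i}") for i in range(3)]
        fit = fit_decay(curves, pool_mode="mean")
        assert fit.n_points == 8
        assert fit.sp == pytest.approx(0.7, abs=1e-6)


class TestExtraSumOfSquaresF:
    def test_hand_arithmetic(self):
        cmp_ = f_test_from_ss(ss_null=10.0, ss_alt=8.0, df_null=13, df_alt=10)
        assert cmp_.f_statistic == pytest.approx(5.0 / 6.0, rel=1e-12)
        assert (cmp_.df_numerator, cmp_.df_denominator) == (3, 10)
        assert cmp_.p_value == pytest.approx(stats.f.sf(5.0 / 6.0, 3, 10), rel=1e-12)

    def test_perfect_alternative_fit_degenerates(self):
        cmp_ = f_test_from_ss(ss_null=1.0, ss_alt=0.0, df_null=13, df_alt=10)
        assert math.isinf(cmp_.f_statistic)
        assert cmp_.p_value == 0.0
        assert cmp_.degenerate

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            f_test_from_ss(1.0, 0.5, 10, 10)

    def test_identical_groups_give_null_result(self):
        from spinedyn import SimulationConfig, simulate_cohort

        cfg = SimulationConfig(n_mice=4, n_features0=200, record_positions=False)
        curves = [survival_curve(d) for d in simulate_cohort({"WT": cfg}, 77)]
        cmp_, fit_null, fit_a, fit_b = extra_sum_of_squares_f(curves, curves)
        assert cmp_.ss_null == pytest.approx(cmp_.ss_alt, rel=1e-6)
        assert cmp_.f_statistic < 1e-4
        assert cmp_.p_value > 0.999
        assert fit_a.sp == pytest.approx(fit_b.sp)

    def test_distinct_groups_detected(self):
        a = [_noiseless_curve(0.60, 0.40, 7.0, mouse_id=f"a{i}") for i in range(3)]
        rng = np.random.default_rng(5)

        def jitter(c):
            s = np.array(c.survival) + rng.normal(0, 0.005, len(c.survival))
            s[0] = 1.0
            s = np.minimum.accumulate(np.clip(s, 0, 1))
            return SurvivalCurve(c.mouse_id, c.times, tuple(s), c.n_initial)

        a = [jitter(c) for c in a]
        b = [
            jitter(_noiseless_curve(0.85, 0.15, 7.0, mouse_id=f"b{i}"))
            for i in range(3)
        ]
        cmp_, *_ = extra_sum_of_squares_f(a, b)
        assert cmp_.p_value < 1e-6
        assert cmp_.ss_null > cmp_.ss_alt
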