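"""Spine survival curves, stability classes, and exponential-decay fits.

For each mouse the survival fraction at a scheduled day ``t`` is

    S(t) = (# day-0 spines consistently present up to t) / (# day-0 spines)

"consistently present" means present at *every* session up to and
including ``t``: once a spine has been scored absent it never counts as
surviving again, even if it reappears later.  Per-mouse curves are
pooled by group and fit to a single-phase exponential decay

    S(t) = Sp + Si * exp(-t / tau)

whose plateau ``Sp`` is the permanent (long-lived) spine fraction,
``Si`` the impermanent fraction, and ``tau`` the characteristic lifetime
of impermanent spines in days.  Groups are compared with the extra
sum-of-squares F test for nested nonlinear models: the null model fits
one shared parameter set to both groups' pooled points, the alternative
fits each group separately, and

    F = ((ss_null - ss_alt) / (df_null - df_alt)) / (ss_alt / df_alt)

is referred to an F(df_null - df_alt, df_alt) distribution.

Day-0 spines are additionally partitioned into *stable* (present at all
sessions), *recurrent* (disappeared, then seen again later) and
*transient* (disappeared for good).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .tracks import MouseDataset

__all__ = [
    "SurvivalCurve",
    "DecayFit",
    "SpineClassCounts",
    "ModelComparison",
    "survival_curve",
    "classify_spines",
    "fit_decay",
    "extra_sum_of_squares_f",
    "f_test_from_ss",
]


@dataclass(frozen=True)
class SurvivalCurve:
    """Per-mouse survival points S(t) over the imaging schedule."""

    mouse_id: str
    times: tuple[int, ...]
    survival: tuple[float, ...]
    n_initial: int

    def __post_init__(self) -> None:
        if self.n_initial <= 0:
            raise ValueError("n_initial must be > 0")
        if len(self.times) != len(self.survival):
            raise ValueError("times and survival must have equal length")
        if self.survival and abs(self.survival[0] - 1.0) > 1e-12:
            raise ValueError("S(0) must equal 1")
        if any(b > a + 1e-12 for a, b in zip(self.survival, self.survival[1:])):
            raise ValueError("survival must be non-increasing")


@dataclass(frozen=True)
class DecayFit:
    """Fitted single-phase decay S(t) = Sp + Si·exp(-t/tau).

    ``ss`` is the residual sum of squares over the fitted points and
    ``df = n_points - n_free_params`` the residual degrees of freedom.
    """

    sp: float
    si: float
    tau: float
    ss: float
    df: int
    n_points: int
    n_free_params: int
    converged: bool
    constrain_s0: bool
    message: str = ""

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        return self.sp + self.si * np.exp(-t / self.tau)


@dataclass(frozen=True)
class SpineClassCounts:
    """Partition of a mouse's day-0 spines into stability classes."""

    mouse_id: str
    n_stable: int
    n_recurrent: int
    n_transient: int

    @property
    def n_total(self) -> int:
        return self.n_stable + self.n_recurrent + self.n_transient

    @property
    def fractions(self) -> dict[str, float]:
        n = self.n_total
        return {
            "stable": self.n_stable / n,
            "recurrent": self.n_recurrent / n,
            "transient": self.n_transient / n,
        }


@dataclass(frozen=True)
class ModelComparison:
    """Extra sum-of-squares F test of separate vs shared decay fits."""

    f_statistic: float
    df_numerator: int
    df_denominator: int
    p_value: float
    ss_null: float
    ss_alt: float
    degenerate: bool = False


def _day0_spines(dataset: MouseDataset, include_filopodia: bool):
    """Tracks counted as day-0 spines, with their status sequence."""
    day0 = dataset.schedule.session_days[0]
    initial = {"present", "filopodia"} if include_filopodia else {"present"}
    out = []
    for tr in dataset.iter_tracks():
        if tr.status_by_session[day0] in initial:
            out.append([tr.status_by_session[d] for d in dataset.schedule])
    return out


def survival_curve(
    dataset: MouseDataset, include_filopodia: bool = False
) -> SurvivalCurve:
    """Survival fraction of day-0 spines at each scheduled day.

    A spine survives to ``t`` only if it was non-absent at every session
    up to ``t``; later reappearances do not resurrect it.  Day-0
    filopodia are excluded unless ``include_filopodia`` is set (their
    later sessions still count as surviving observations either way,
    since presence scoring covers all protrusions).
    """
    if len(dataset.schedule) < 2:
        raise ValueError("need at least 2 sessions")
    spines = _day0_spines(dataset, include_filopodia)
    n0 = len(spines)
    if n0 == 0:
        raise ValueError(f"mouse {dataset.mouse_id!r}: no day-0 spines")
    n_sessions = len(dataset.schedule)
    alive = np.ones(n0, dtype=bool)
    surv = []
    for s in range(n_sessions):
        for i, seq in enumerate(spines):
            if alive[i] and seq[s] == "absent":
                alive[i] = False
        surv.append(alive.sum() / n0)
    return SurvivalCurve(
        mouse_id=dataset.mouse_id,
        times=dataset.schedule.session_days,
        survival=tuple(float(v) for v in surv),
        n_initial=n0,
    )


def classify_spines(
    dataset: MouseDataset, include_filopodia: bool = False
) -> SpineClassCounts:
    """Partition day-0 spines into stable / recurrent / transient.

    Stable: never absent.  Recurrent: absent at some session, then
    non-absent at a later one.  Transient: absent and never seen again.
    Requires at least 3 sessions (recurrence needs a reappearance
    opportunity after the first possible disappearance).
    """
    if len(dataset.schedule) < 3:
        raise ValueError("spine classification requires at least 3 sessions")
    n_stable = n_rec = n_trans = 0
    for seq in _day0_spines(dataset, include_filopodia):
        try:
            first_absent = seq.index("absent")
        except ValueError:
            n_stable += 1
            continue
        if any(s != "absent" for s in seq[first_absent + 1 :]):
            n_rec += 1
        else:
            n_trans += 1
    return SpineClassCounts(
        mouse_id=dataset.mouse_id,
        n_stable=n_stable,
        n_recurrent=n_rec,
        n_transient=n_trans,
    )


# ---------------------------------------------------------------------------
# Decay fitting
# ---------------------------------------------------------------------------

_SS_RTOL = 1e-8  # relative tolerance for comparing multi-start solutions


def _pooled_points(
    curves: Sequence[SurvivalCurve],
    weight_by_n: bool,
    pool_mode: str,
):
    if pool_mode not in ("points", "mean"):
        raise ValueError("pool_mode must be 'points' or 'mean'")
    if pool_mode == "mean":
        times0 = curves[0].times
        if any(c.times != times0 for c in curves):
            raise ValueError("mean-curve pooling requires identical schedules")
        t = np.asarray(times0, dtype=float)
        s = np.mean([c.survival for c in curves], axis=0)
        w = np.ones_like(t)
        return t, s, w
    t = np.concatenate([np.asarray(c.times, dtype=float) for c in curves])
    s = np.concatenate([np.asarray(c.survival, dtype=float) for c in curves])
    if weight_by_n:
        w = np.concatenate(
            [np.full(len(c.times), math.sqrt(c.n_initial)) for c in curves]
        )
        w = w / w.mean()
    else:
        w = np.ones_like(t)
    return t, s, w


def fit_decay(
    curves: Sequence[SurvivalCurve],
    constrain_s0: bool = False,
    weight_by_n: bool = False,
    pool_mode: str = "points",
) -> DecayFit:
    """Least-squares fit of S(t) = Sp + Si·exp(-t/tau) to pooled curves.

    All per-mouse (t, S) points are concatenated and fitted with equal
    weight (``pool_mode='points'``, the default); ``pool_mode='mean'``
    fits the across-mouse mean curve instead, and ``weight_by_n``
    weights points by the square root of each mouse's initial spine
    count.  Parameters are box-constrained to Sp, Si ∈ [0, 1] and
    tau ∈ (0, 10·t_max].  With ``constrain_s0`` the intercept is pinned
    to S(0) = 1 via Si = 1 - Sp (two free parameters).

    Initialisation is multi-start (tau₀ ∈ {t_max/4, t_max/2, t_max});
    the lowest residual sum of squares wins.

    Raises
    ------
    ValueError
        If fewer than 4 points or fewer than 2 distinct positive times
        are available, or if all survival values are equal (tau is then
        unidentifiable).
    """
    if not curves:
        raise ValueError("no curves to fit")
    t, s, w = _pooled_points(curves, weight_by_n, pool_mode)
    if len(t) < 4:
        raise ValueError("need at least 4 pooled (t, S) points")
    if len(np.unique(t[t > 0])) < 2:
        raise ValueError("need at least 2 distinct positive times")
    if np.allclose(s, s[0], atol=1e-12):
        raise ValueError(
            "all survival values are equal: decay lifetime tau is "
            "unidentifiable (no decay to fit)"
        )

    t_max = float(t.max())
    tau_hi = 10.0 * t_max
    tau_lo = 1e-6
    sp0 = float(np.clip(s.min(), 0.0, 1.0))
    si0 = float(np.clip(1.0 - sp0, 0.0, 1.0))
    n_free = 2 if constrain_s0 else 3

    if constrain_s0:
        def resid(p):
            sp, tau = p
            return w * (sp + (1.0 - sp) * np.exp(-t / tau) - s)
        lo, hi = [0.0, tau_lo], [1.0, tau_hi]
        starts = [[sp0, tau0] for tau0 in (t_max / 4, t_max / 2, t_max)]
    else:
        def resid(p):
            sp, si, tau = p
            return w * (sp + si * np.exp(-t / tau) - s)
        lo, hi = [0.0, 0.0, tau_lo], [1.0, 1.0, tau_hi]
        starts = [[sp0, si0, tau0] for tau0 in (t_max / 4, t_max / 2, t_max)]

    best = None
    any_success = False
    for x0 in starts:
        res = optimize.least_squares(resid, x0, bounds=(lo, hi), method="trf")
        ss = float(2.0 * res.cost)
        any_success = any_success or res.success
        if best is None or ss < best[0] * (1.0 - _SS_RTOL):
            best = (ss, res)
    ss, res = best
    if constrain_s0:
        sp, tau = res.x
        si = 1.0 - sp
    else:
        sp, si, tau = res.x
    return DecayFit(
        sp=float(sp),
        si=float(si),
        tau=float(tau),
        ss=ss,
        df=len(t) - n_free,
        n_points=len(t),
        n_free_params=n_free,
        converged=bool(any_success),
        constrain_s0=constrain_s0,
        message=str(res.message),
    )


def f_test_from_ss(
    ss_null: float, ss_alt: float, df_null: int, df_alt: int
) -> ModelComparison:
    """Extra sum-of-squares F test from residual SS and df of nested fits.

    ``ss_alt = 0`` (perfect separate fits) yields an infinite F with
    p = 0, flagged as degenerate.  A marginally negative SS improvement
    from numerical noise is clipped to zero.
    """
    df_num = df_null - df_alt
    if df_num <= 0:
        raise ValueError("null model must have more residual df than alternative")
    if df_alt <= 0:
        raise ValueError("alternative model must have positive residual df")
    if ss_alt == 0.0:
        return ModelComparison(
            f_statistic=math.inf,
            df_numerator=df_num,
            df_denominator=df_alt,
            p_value=0.0,
            ss_null=ss_null,
            ss_alt=ss_alt,
            degenerate=True,
        )
    f = max(ss_null - ss_alt, 0.0) / df_num / (ss_alt / df_alt)
    p = float(stats.f.sf(f, df_num, df_alt))
    return ModelComparison(
        f_statistic=float(f),
        df_numerator=df_num,
        df_denominator=df_alt,
        p_value=p,
        ss_null=ss_null,
        ss_alt=ss_alt,
    )


def extra_sum_of_squares_f(
    curves_a: Sequence[SurvivalCurve],
    curves_b: Sequence[SurvivalCurve],
    constrain_s0: bool = False,
    weight_by_n: bool = False,
    pool_mode: str = "points",
) -> tuple[ModelComparison, DecayFit, DecayFit, DecayFit]:
    """Compare two groups' decay fits with the extra sum-of-squares F test.

    The null model fits one shared (Sp, Si, tau) to the union of both
    groups' pooled points; the alternative fits each group separately
    (ss_alt = ss_a + ss_b, df_alt = df_a + df_b).  Returns the test plus
    the (null, group A, group B) fits.
    """
    fit_a = fit_decay(curves_a, constrain_s0, weight_by_n, pool_mode)
    fit_b = fit_decay(curves_b, constrain_s0, weight_by_n, pool_mode)
    if pool_mode == "mean":
        # the null pools the two mean curves as two point sets
        t_a, s_a, _ = _pooled_points(curves_a, weight_by_n, "mean")
        t_b, s_b, _ = _pooled_points(curves_b, weight_by_n, "mean")
        pooled = [
            SurvivalCurve("mean_a", tuple(int(v) for v in t_a), tuple(s_a), 1),
            SurvivalCurve("mean_b", tuple(int(v) for v in t_b), tuple(s_b), 1),
        ]
        fit_null = fit_decay(pooled, constrain_s0, weight_by_n, "points")
    else:
        fit_null = fit_decay(
            list(curves_a) + list(curves_b), constrain_s0, weight_by_n, "points"
        )
    comparison = f_test_from_ss(
        ss_null=fit_null.ss,
        ss_alt=fit_a.ss + fit_b.ss,
        df_null=fit_null.df,
        df_alt=fit_a.df + fit_b.df,
    )
    return comparison, fit_null, fit_a, fit_b
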