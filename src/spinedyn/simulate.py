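"""Synthetic spine-kinetics generator with known ground truth.

Generates :class:`~spinedyn.tracks.MouseDataset` cohorts whose day-0
spine population follows the two-population stability model that the
survival analysis assumes: a permanent fraction ``Sp`` that never
disappears, and an impermanent fraction ``1 - Sp`` whose lifetimes are
exponential with mean ``tau`` days.  The continuous birth/death process
is observed only at the scheduled imaging days, so the expected
empirical survival fraction at a scheduled day ``t`` is exactly

    S(t) = Sp + (1 - Sp) * exp(-t / tau)

which makes the generator a closed-form oracle for parameter-recovery
tests.  On top of the day-0 spine pool the generator adds day-0
filopodia with elevated per-session turnover, Poisson formation of new
features between sessions, optional single recurrence of disappeared
spines, and optional observation noise (missed detections).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .tracks import (
    ADULT_SCHEDULE,
    DendriteRecord,
    FeatureTrack,
    ImagingSchedule,
    MouseDataset,
)

__all__ = [
    "SimulationConfig",
    "JUVENILE_CONFIG",
    "simulate_mouse",
    "simulate_cohort",
    "expected_survival",
]

_ABSENT, _PRESENT, _FILO = 0, 1, 2
_CODE_TO_STATUS = {_ABSENT: "absent", _PRESENT: "present", _FILO: "filopodia"}


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one simulated mouse (or cohort).

    Parameters
    ----------
    n_mice : mice per genotype when used with :func:`simulate_cohort`.
    n_features0 : day-0 features per mouse (spines + filopodia).
    permanent_fraction : probability ``Sp`` that a day-0 spine is permanent.
    impermanent_lifetime_days : mean exponential lifetime ``tau`` (days) of
        impermanent spines.
    filopodia_fraction0 : fraction of day-0 features that are filopodia.
    filopodia_session_survival : probability a filopodium survives from one
        session to the next (filopodia turn over much faster than spines).
    formation_rate : expected newly formed features per day per 100 day-0
        features.
    recurrence_prob : probability a disappeared impermanent spine reappears
        at the next scheduled session after a one-session gap (then lives a
        fresh exponential lifetime; at most one recurrence per spine).
    miss_prob : probability each truly present observation is scored absent
        (observer miss), independently per feature per session.
    schedule : imaging schedule in days.
    n_dendrites : dendritic segments per mouse; features are spread evenly.
    spine_density_per_um : nominal day-0 density used to set segment lengths.
    sp_concentration : if set, per-mouse ``Sp`` is drawn from a Beta
        distribution with this concentration and mean ``permanent_fraction``
        (mouse-level heterogeneity for robustness tests); ``None`` = fixed.
    record_positions : store synthetic (x, y, z) µm coordinates per session.
    age_group : label copied onto generated datasets.
    """

    n_mice: int = 5
    n_features0: int = 250
    permanent_fraction: float = 0.75
    impermanent_lifetime_days: float = 7.0
    filopodia_fraction0: float = 0.15
    filopodia_session_survival: float = 0.5
    formation_rate: float = 2.0
    recurrence_prob: float = 0.2
    miss_prob: float = 0.0
    schedule: ImagingSchedule = ADULT_SCHEDULE
    n_dendrites: int = 3
    spine_density_per_um: float = 0.6
    sp_concentration: float | None = None
    record_positions: bool = True
    age_group: str = "adult"

    def __post_init__(self) -> None:
        for name in (
            "permanent_fraction",
            "filopodia_fraction0",
            "filopodia_session_survival",
            "recurrence_prob",
            "miss_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.impermanent_lifetime_days > 0:
            raise ValueError("impermanent_lifetime_days must be > 0")
        if self.formation_rate < 0:
            raise ValueError("formation_rate must be >= 0")
        if self.n_features0 <= 0 or self.n_mice <= 0 or self.n_dendrites <= 0:
            raise ValueError("counts must be positive")
        if not self.spine_density_per_um > 0:
            raise ValueError("spine_density_per_um must be > 0")


#: Juvenile preset: lower spine stability, more filopodia, brisk formation.
#: With Sp = 0.5, tau = 10 d and lambda = 8/day/100 features, the closed-form
#: expected two-day turnover ratio (counting spines only, filopodia excluded)
#: is ~0.14, the magnitude reported for juvenile wild-type cortex.
JUVENILE_CONFIG = SimulationConfig(
    n_features0=250,
    permanent_fraction=0.5,
    impermanent_lifetime_days=10.0,
    filopodia_fraction0=0.25,
    filopodia_session_survival=0.5,
    formation_rate=8.0,
    schedule=ImagingSchedule((0, 1, 2)),
    age_group="juvenile",
)


def expected_survival(t, permanent_fraction: float, lifetime_days: float):
    """Closed-form mean survival fraction S(t) = Sp + (1-Sp)·exp(-t/tau)."""
    t = np.asarray(t, dtype=float)
    sp = permanent_fraction
    return sp + (1.0 - sp) * np.exp(-t / lifetime_days)


def _spine_status_rows(
    n: int,
    days: np.ndarray,
    first_session_idx: int,
    sp: float,
    tau: float,
    p_rec: float,
    allow_recurrence: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """Status codes for ``n`` spines first observed at ``first_session_idx``.

    Lifetimes are anchored at the first observed session day; death is
    continuous and censored to the schedule (a spine dying on day 9 is
    last seen on day 7 of the standard adult schedule).
    """
    n_sessions = len(days)
    status = np.zeros((n, n_sessions), dtype=np.int8)
    t0 = days[first_session_idx]
    permanent = rng.random(n) < sp
    death = np.where(permanent, np.inf, t0 + rng.exponential(tau, size=n))
    obs = days[first_session_idx:]
    alive = obs[None, :] < np.maximum(death[:, None], t0 + 1e-12)
    # the first observed session is present by construction
    alive[:, 0] = True
    status[:, first_session_idx:] = np.where(alive, _PRESENT, _ABSENT)

    if allow_recurrence and p_rec > 0:
        # first absent session index (relative to full schedule)
        n_alive = alive.sum(axis=1)
        dead = ~permanent & (n_alive < len(obs))
        for i in np.flatnonzero(dead):
            j = first_session_idx + int(alive[i].sum())  # first absent session
            if j + 1 >= n_sessions:
                continue
            if rng.random() >= p_rec:
                continue
            # one-session gap: absent at j, back at j+1 with a fresh lifetime
            new_death = days[j + 1] + rng.exponential(tau)
            for k in range(j + 1, n_sessions):
                status[i, k] = _PRESENT if days[k] < new_death or k == j + 1 else _ABSENT
    return status


def simulate_mouse(
    config: SimulationConfig,
    mouse_id: str,
    genotype: str,
    seed: int | np.random.Generator,
) -> MouseDataset:
    """Simulate one mouse's tracked protrusions on the configured schedule.

    Day-0 features are filopodia with probability ``filopodia_fraction0``
    and spines otherwise; day-0 spines are permanent with probability
    ``Sp`` or die after an Exponential(``tau``) lifetime.  Disappeared
    impermanent spines may recur once; filopodia survive session-to-session
    with probability ``filopodia_session_survival``; new features form
    between sessions at rate ``formation_rate`` per day per 100 day-0
    features; each truly present observation is missed with probability
    ``miss_prob``.  Fully reproducible from the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    days = np.asarray(config.schedule.session_days, dtype=float)
    n_sessions = len(days)
    n0 = config.n_features0
    sp = config.permanent_fraction
    if config.sp_concentration is not None:
        k = config.sp_concentration
        a, b = max(sp * k, 1e-9), max((1.0 - sp) * k, 1e-9)
        sp = float(rng.beta(a, b))
    tau = config.impermanent_lifetime_days

    is_filo = rng.random(n0) < config.filopodia_fraction0
    n_filo = int(is_filo.sum())
    n_spine = n0 - n_filo

    blocks: list[np.ndarray] = []
    kinds: list[str] = []

    spine_status = _spine_status_rows(
        n_spine, days, 0, sp, tau, config.recurrence_prob, True, rng
    )
    blocks.append(spine_status)
    kinds.extend(["spine"] * n_spine)

    # day-0 filopodia: geometric per-session survival, no recurrence
    filo_status = np.zeros((n_filo, n_sessions), dtype=np.int8)
    filo_status[:, 0] = _FILO
    if n_sessions > 1 and n_filo > 0:
        survived = rng.random((n_filo, n_sessions - 1)) < config.filopodia_session_survival
        alive_prefix = np.cumprod(survived, axis=1).astype(bool)
        filo_status[:, 1:] = np.where(alive_prefix, _FILO, _ABSENT)
    blocks.append(filo_status)
    kinds.extend(["filopodia"] * n_filo)

    # formation between sessions: Poisson(lambda * dt * n0/100), first seen
    # at the later session of the gap, then the same spine stability law
    for i in range(n_sessions - 1):
        dt = days[i + 1] - days[i]
        mean = config.formation_rate * dt * n0 / 100.0
        n_new = int(rng.poisson(mean)) if mean > 0 else 0
        if n_new == 0:
            continue
        blocks.append(
            _spine_status_rows(
                n_new, days, i + 1, sp, tau, config.recurrence_prob, True, rng
            )
        )
        kinds.extend(["formed"] * n_new)

    status = np.concatenate(blocks, axis=0) if blocks else np.zeros((0, n_sessions), np.int8)

    if config.miss_prob > 0:
        missed = rng.random(status.shape) < config.miss_prob
        status = np.where(missed & (status != _ABSENT), _ABSENT, status)

    keep = (status != _ABSENT).any(axis=1)
    status = status[keep]
    kinds = [k for k, m in zip(kinds, keep) if m]

    # package into dendrites; segment lengths set by the nominal density
    total_len = n0 / config.spine_density_per_um
    seg_len = total_len / config.n_dendrites
    dendrites = [
        DendriteRecord(
            dendrite_id=f"{mouse_id}-d{d + 1}",
            mouse_id=mouse_id,
            tracks=[],
            segment_length_um=round(seg_len, 3),
        )
        for d in range(config.n_dendrites)
    ]
    day_ints = config.schedule.session_days
    for idx in range(status.shape[0]):
        dend = dendrites[idx % config.n_dendrites]
        pos_by_session: dict[int, tuple[float, float, float]] = {}
        if config.record_positions:
            x = float(rng.uniform(0.0, seg_len))
            y = float(rng.normal(0.0, 0.5))
            z = float(rng.normal(0.0, 0.5))
            for s, day in enumerate(day_ints):
                if status[idx, s] != _ABSENT:
                    pos_by_session[day] = (round(x, 3), round(y, 3), round(z, 3))
        dend.tracks.append(
            FeatureTrack(
                feature_id=f"{mouse_id}-{kinds[idx]}-{idx}",
                dendrite_id=dend.dendrite_id,
                status_by_session={
                    day: _CODE_TO_STATUS[int(status[idx, s])]
                    for s, day in enumerate(day_ints)
                },
                position_by_session=pos_by_session,
            )
        )
    return MouseDataset(
        mouse_id=mouse_id,
        genotype=genotype,
        age_group=config.age_group,
        schedule=config.schedule,
        dendrites=dendrites,
    )


def simulate_cohort(
    config_by_genotype: Mapping[str, SimulationConfig],
    seed: int,
) -> list[MouseDataset]:
    """Simulate ``n_mice`` datasets per genotype with derived sub-seeds.

    Mouse ids are ``<genotype><k>``; sub-seeds are spawned deterministically
    from the master seed so the whole cohort is reproducible and mice are
    statistically independent.
    """
    if not config_by_genotype:
        raise ValueError("need at least one genotype")
    datasets: list[MouseDataset] = []
    seen: set[str] = set()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(sum(c.n_mice for c in config_by_genotype.values()))
    it = iter(children)
    for genotype, config in config_by_genotype.items():
        for k in range(config.n_mice):
            mouse_id = f"{genotype}{k + 1}"
            if mouse_id in seen:
                raise ValueError(f"duplicate mouse_id {mouse_id!r}")
            seen.add(mouse_id)
            datasets.append(
                simulate_mouse(
                    config, mouse_id, genotype, np.random.default_rng(next(it))
                )
            )
    return datasets
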