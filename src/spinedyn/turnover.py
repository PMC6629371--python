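"""Two-session turnover statistics, filopodial fraction, density, morphology.

The turnover ratio between two imaging sessions is

    TO = (N_elim + N_form) / (N_elim + N_form + 2 * N_stable)

where, over the features scored at the two sessions, *stable* features
are present at both, *eliminated* present at the first and absent at the
second, and *formed* absent at the first and present at the second.
TO = 0 for a static dendrite and 1 for complete replacement.

Filopodia handling: presence/absence scoring covers all protrusions but
the turnover ratio is conventionally reported for spines.  By default a
feature scored ``filopodia`` at either session matches none of the three
categories (it is neither ``present`` nor ``absent``), so filopodia are
excluded from the counts; with ``include_filopodia=True`` a filopodium
counts as present.  Both modes are reported by the pipeline because
published protocols are ambiguous on this point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .tracks import MorphologyScore, MouseDataset

__all__ = [
    "TurnoverResult",
    "FractionSummary",
    "count_turnover",
    "filopodial_fraction",
    "spine_density",
    "morphology_fractions",
    "summarize_turnover",
]

MORPH_CLASSES = ("mushroom", "intermediate", "filopodia")


@dataclass(frozen=True)
class TurnoverResult:
    """Eliminated/formed/stable counts and the turnover ratio for one mouse.

    ``ratio`` is ``None`` (flagged undefined) when no feature falls in any
    category between the two sessions.
    """

    mouse_id: str
    session_a: int
    session_b: int
    n_eliminated: int
    n_formed: int
    n_stable: int
    ratio: float | None

    @property
    def defined(self) -> bool:
        return self.ratio is not None


@dataclass(frozen=True)
class FractionSummary:
    """A counted fraction with its grouping labels."""

    numerator: int
    denominator: int
    fraction: float
    mouse_id: str | None = None
    genotype: str | None = None
    age_group: str | None = None
    label: str | None = None


def _turnover_ratio(n_elim: int, n_form: int, n_stable: int) -> float | None:
    denom = n_elim + n_form + 2 * n_stable
    if denom == 0:
        return None
    return (n_elim + n_form) / denom


def count_turnover(
    dataset: MouseDataset,
    session_a: int,
    session_b: int,
    include_filopodia: bool = False,
) -> TurnoverResult:
    """Count eliminations, formations and stable features between two sessions.

    Counts are summed over all the mouse's dendrites before the ratio is
    formed (the animal, not the dendrite, is the unit of analysis).

    Parameters
    ----------
    session_a, session_b : scheduled days with ``session_a < session_b``.
    include_filopodia : treat ``filopodia`` status as present (count all
        protrusions) instead of excluding filopodia-scored observations.
    """
    if session_a not in dataset.schedule or session_b not in dataset.schedule:
        raise ValueError(
            f"sessions ({session_a}, {session_b}) must both be in schedule "
            f"{dataset.schedule.session_days}"
        )
    if not session_a < session_b:
        raise ValueError("session_a must precede session_b")

    present = {"present", "filopodia"} if include_filopodia else {"present"}
    n_elim = n_form = n_stable = 0
    n_seen = 0
    for tr in dataset.iter_tracks():
        sa = tr.status_by_session[session_a]
        sb = tr.status_by_session[session_b]
        if sa == "absent" and sb == "absent":
            continue
        n_seen += 1
        pa, pb = sa in present, sb in present
        if pa and pb:
            n_stable += 1
        elif pa and sb == "absent":
            n_elim += 1
        elif sa == "absent" and pb:
            n_form += 1
        # remaining combinations involve an excluded filopodia score
    if n_seen == 0:
        raise ValueError("no analyzable features at the requested sessions")
    return TurnoverResult(
        mouse_id=dataset.mouse_id,
        session_a=session_a,
        session_b=session_b,
        n_eliminated=n_elim,
        n_formed=n_form,
        n_stable=n_stable,
        ratio=_turnover_ratio(n_elim, n_form, n_stable),
    )


def filopodial_fraction(dataset: MouseDataset) -> FractionSummary:
    """Fraction of day-0 non-absent features scored as filopodia."""
    day0 = dataset.schedule.session_days[0]
    n_filo = n_feat = 0
    for tr in dataset.iter_tracks():
        st = tr.status_by_session[day0]
        if st == "absent":
            continue
        n_feat += 1
        if st == "filopodia":
            n_filo += 1
    if n_feat == 0:
        raise ValueError(f"mouse {dataset.mouse_id!r}: no day-0 features")
    return FractionSummary(
        numerator=n_filo,
        denominator=n_feat,
        fraction=n_filo / n_feat,
        mouse_id=dataset.mouse_id,
        genotype=dataset.genotype,
        age_group=dataset.age_group,
        label="filopodial_fraction",
    )


def spine_density(n_spines: int, segment_length_um: float) -> float:
    """Spines per µm of dendrite."""
    if not segment_length_um > 0:
        raise ValueError("segment_length_um must be > 0")
    if n_spines < 0:
        raise ValueError("n_spines must be >= 0")
    return n_spines / segment_length_um


def morphology_fractions(
    scores: Iterable[MorphologyScore],
    group_by: Mapping[str, str] | None = None,
) -> dict[str, dict[str, FractionSummary]]:
    """Per-group fractions of mushroom / intermediate / filopodia classes.

    ``group_by`` maps feature_id to a group label (e.g. genotype); without
    it all scores form a single group ``"all"``.  Fractions within a group
    sum to 1.
    """
    counts: dict[str, dict[str, int]] = {}
    for sc in scores:
        group = group_by.get(sc.feature_id, "all") if group_by else "all"
        counts.setdefault(group, {c: 0 for c in MORPH_CLASSES})
        counts[group][sc.morph_class] += 1
    if not counts:
        raise ValueError("no morphology scores given")
    out: dict[str, dict[str, FractionSummary]] = {}
    for group, by_class in counts.items():
        total = sum(by_class.values())
        out[group] = {
            cls: FractionSummary(
                numerator=n,
                denominator=total,
                fraction=n / total,
                label=f"morphology:{cls}",
                genotype=group if group != "all" else None,
            )
            for cls, n in by_class.items()
        }
    return out


def summarize_turnover(
    datasets: Sequence[MouseDataset],
    session_a: int,
    session_b: int,
    include_filopodia: bool = False,
) -> pd.DataFrame:
    """Per-mouse turnover table with genotype labels, for group summaries.

    Group means should be taken across the per-mouse ratios in the
    returned frame (animal-level n), not by re-pooling counts.
    """
    rows = []
    for ds in datasets:
        res = count_turnover(ds, session_a, session_b, include_filopodia)
        rows.append(
            {
                "mouse_id": ds.mouse_id,
                "genotype": ds.genotype,
                "age_group": ds.age_group,
                "session_a": session_a,
                "session_b": session_b,
                "include_filopodia": include_filopodia,
                "n_eliminated": res.n_eliminated,
                "n_formed": res.n_formed,
                "n_stable": res.n_stable,
                "turnover_ratio": res.ratio,
            }
        )
    return pd.DataFrame(rows)
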