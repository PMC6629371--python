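"""End-to-end pipeline: simulate/load → turnover → survival → compare → report.

Produces plain delimited tables plus one JSON summary per run, and a
manifest recording the seed, the full configuration and its hash, so
that every numeric output is reproducible from the manifest alone.
Logs go to stderr (never interleaved with data outputs).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd

from . import __version__
from .simulate import SimulationConfig, simulate_cohort
from .survival import classify_spines, extra_sum_of_squares_f, fit_decay, survival_curve
from .tracks import ImagingSchedule, MouseDataset, read_track_table, write_track_table
from .turnover import filopodial_fraction, summarize_turnover

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("spinedyn")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`.

    Exactly one of ``input_path`` (a track table CSV) or ``simulation``
    (mapping genotype → :class:`SimulationConfig`) must be given.
    ``turnover_sessions`` defaults to (0, 2) for schedules ending by day
    2 and (0, 7) otherwise, matching the conventional two-day juvenile
    and seven-day adult windows.
    """

    out_dir: str | Path
    seed: int = 0
    input_path: str | Path | None = None
    simulation: Mapping[str, SimulationConfig] | None = None
    turnover_sessions: tuple[int, int] | None = None
    weight_by_n: bool = False
    pool_mode: str = "points"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError("exactly one of input_path or simulation is required")

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", None)
        if sim is not None:
            parsed = {}
            for genotype, fields in sim.items():
                fields = dict(fields)
                if "schedule" in fields:
                    fields["schedule"] = ImagingSchedule(tuple(fields["schedule"]))
                parsed[genotype] = SimulationConfig(**fields)
            sim = parsed
        ts = d.pop("turnover_sessions", None)
        return cls(
            simulation=sim,
            turnover_sessions=None if ts is None else (int(ts[0]), int(ts[1])),
            **d,
        )

    def to_jsonable(self) -> dict:
        out: dict[str, Any] = {
            "out_dir": str(self.out_dir),
            "seed": self.seed,
            "input_path": None if self.input_path is None else str(self.input_path),
            "turnover_sessions": self.turnover_sessions,
            "weight_by_n": self.weight_by_n,
            "pool_mode": self.pool_mode,
            "log_level": self.log_level,
        }
        if self.simulation is not None:
            out["simulation"] = {
                g: {
                    **dataclasses.asdict(c),
                    "schedule": list(c.schedule.session_days),
                }
                for g, c in self.simulation.items()
            }
        else:
            out["simulation"] = None
        return out


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_jsonable(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _fit_report(fit) -> dict:
    return {
        "sp": fit.sp,
        "si": fit.si,
        "tau_days": fit.tau,
        "ss": fit.ss,
        "df": fit.df,
        "n_points": fit.n_points,
        "constrain_s0": fit.constrain_s0,
        "converged": fit.converged,
    }


def _default_sessions(schedule: ImagingSchedule) -> tuple[int, int]:
    days = schedule.session_days
    if max(days) <= 2:
        return (0, 2) if 2 in days else (days[0], days[-1])
    return (0, 7) if 7 in days else (days[0], days[-1])


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write all artifacts under ``out_dir``.

    Writes the track table (when simulated), per-mouse turnover in both
    filopodia-inclusion modes, filopodial fractions, survival curves,
    stability-class counts, per-genotype decay fits in both intercept
    modes, pairwise genotype comparisons, and ``manifest.json``.
    Idempotent: identical config + seed reproduce identical outputs.
    """
    logging.basicConfig(level=config.log_level, stream=sys.stderr)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    # --- stage: input -----------------------------------------------------
    try:
        if config.simulation is not None:
            log.info("simulating cohort (seed=%d)", config.seed)
            datasets = simulate_cohort(config.simulation, config.seed)
            tracks_path = out_dir / "tracks.csv"
            write_track_table(datasets, tracks_path)
            artifacts["tracks"] = str(tracks_path)
        else:
            log.info("reading %s", config.input_path)
            datasets = read_track_table(config.input_path)
    except Exception as exc:
        raise PipelineError(f"input stage failed: {exc}") from exc
    if not datasets:
        raise PipelineError("input stage failed: no datasets")

    # --- stage: turnover --------------------------------------------------
    try:
        frames = []
        for ds in datasets:
            sa, sb = config.turnover_sessions or _default_sessions(ds.schedule)
            for inc in (False, True):
                frames.append(summarize_turnover([ds], sa, sb, include_filopodia=inc))
        turnover_df = pd.concat(frames, ignore_index=True)
        turnover_path = out_dir / "turnover.csv"
        turnover_df.to_csv(turnover_path, index=False)
        artifacts["turnover"] = str(turnover_path)

        filo_df = pd.DataFrame(
            [
                {
                    "mouse_id": f.mouse_id,
                    "genotype": f.genotype,
                    "age_group": f.age_group,
                    "n_filopodia": f.numerator,
                    "n_day0_features": f.denominator,
                    "filopodial_fraction": f.fraction,
                }
                for f in map(filopodial_fraction, datasets)
            ]
        )
        filo_path = out_dir / "filopodia.csv"
        filo_df.to_csv(filo_path, index=False)
        artifacts["filopodia"] = str(filo_path)
    except Exception as exc:
        raise PipelineError(f"turnover stage failed: {exc}") from exc

    # --- stage: survival --------------------------------------------------
    try:
        curves_by_genotype: dict[str, list] = {}
        curve_rows, class_rows = [], []
        for ds in datasets:
            curve = survival_curve(ds)
            curves_by_genotype.setdefault(ds.genotype, []).append(curve)
            for t, s in zip(curve.times, curve.survival):
                curve_rows.append(
                    {
                        "mouse_id": ds.mouse_id,
                        "genotype": ds.genotype,
                        "day": t,
                        "survival": s,
                        "n_initial": curve.n_initial,
                    }
                )
            if len(ds.schedule) >= 3:
                cc = classify_spines(ds)
                class_rows.append(
                    {
                        "mouse_id": ds.mouse_id,
                        "genotype": ds.genotype,
                        "n_stable": cc.n_stable,
                        "n_recurrent": cc.n_recurrent,
                        "n_transient": cc.n_transient,
                        **{f"frac_{k}": v for k, v in cc.fractions.items()},
                    }
                )
        curves_path = out_dir / "survival_curves.csv"
        pd.DataFrame(curve_rows).to_csv(curves_path, index=False)
        artifacts["survival_curves"] = str(curves_path)
        if class_rows:
            class_path = out_dir / "classification.csv"
            pd.DataFrame(class_rows).to_csv(class_path, index=False)
            artifacts["classification"] = str(class_path)

        fits: dict[str, Any] = {}
        fittable = {
            g: cs
            for g, cs in curves_by_genotype.items()
            if sum(len(c.times) for c in cs) >= 4
            and any(max(c.survival) - min(c.survival) > 0 for c in cs)
        }
        for genotype, curves in fittable.items():
            fits[genotype] = {
                "unconstrained": _fit_report(
                    fit_decay(curves, False, config.weight_by_n, config.pool_mode)
                ),
                "constrain_s0": _fit_report(
                    fit_decay(curves, True, config.weight_by_n, config.pool_mode)
                ),
            }
    except Exception as exc:
        raise PipelineError(f"survival stage failed: {exc}") from exc

    # --- stage: comparison ------------------------------------------------
    comparisons: dict[str, Any] = {}
    try:
        genotypes = sorted(fittable)
        for i, ga in enumerate(genotypes):
            for gb in genotypes[i + 1 :]:
                for constrain in (False, True):
                    cmp_, fit_null, fit_a, fit_b = extra_sum_of_squares_f(
                        fittable[ga],
                        fittable[gb],
                        constrain_s0=constrain,
                        weight_by_n=config.weight_by_n,
                        pool_mode=config.pool_mode,
                    )
                    key = f"{ga}_vs_{gb}" + ("_constrained" if constrain else "")
                    comparisons[key] = {
                        "f_statistic": cmp_.f_statistic,
                        "df_numerator": cmp_.df_numerator,
                        "df_denominator": cmp_.df_denominator,
                        "p_value": cmp_.p_value,
                        "ss_null": cmp_.ss_null,
                        "ss_alt": cmp_.ss_alt,
                        "null_fit": _fit_report(fit_null),
                    }
    except Exception as exc:
        raise PipelineError(f"comparison stage failed: {exc}") from exc

    # --- stage: report ----------------------------------------------------
    summary = {"fits": fits, "comparisons": comparisons}
    fits_path = out_dir / "fits.json"
    fits_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    artifacts["fits"] = str(fits_path)

    manifest = {
        "package": "spinedyn",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_jsonable(),
        "config_hash": _config_hash(config),
        "artifacts": artifacts,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    artifacts["manifest"] = str(manifest_path)
    log.info("pipeline complete: %d artifacts in %s", len(artifacts), out_dir)
    return {"artifacts": artifacts, "summary": summary, "manifest": manifest}
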