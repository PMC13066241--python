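"""Study protocol: weakening x speed x misalignment grid and outcome measures.

Runs the full simulated study design -- four plantarflexor weakening levels,
three gait speeds, seven device-axis alignment conditions (aligned plus six
2 cm shifts) -- and computes the outcome measures: marker-pair relative
movement between body and shells, mean stance-phase deviation of the
plantarflexor activation from the healthy reference curve, and residual
(reserve) actuator plausibility.
"""

from __future__ import annotations

import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics_engine import TrialResult, initial_cmc, run_gait_cycle
from .gait_synth import (
    ReferenceActivation,
    SPEED_LEVELS,
    reference_activation,
    synth_gait,
    synth_support,
)
from .leg_afo_model import (
    MISALIGNMENT_DIRECTIONS,
    WEAKENING_LEVELS,
    CoupledModel,
    apply_misalignment,
    apply_weakening,
    build_model,
)

__all__ = [
    "ResidualThresholds",
    "DeviationReport",
    "relative_motion",
    "activation_deviation",
    "grid_conditions",
    "run_grid",
    "residual_check",
]

log = logging.getLogger("afoflex")

PHASE_GRID = np.linspace(0.0, 100.0, 101)


@dataclass(frozen=True)
class ResidualThresholds:
    """Plausibility bounds on residual/reserve usage.

    ``max_force``: bound on residual forces, N; by default 5% of the
    condition's peak ground-reaction magnitude.  ``max_moment``: bound on
    reserve moments, Nm; the default is a conservative fraction of the
    residual-moment magnitudes conventionally accepted for gait simulations.
    """

    max_force: float | None = None
    force_fraction: float = 0.05
    max_moment: float = 25.0

    def __post_init__(self):
        if self.max_force is not None and self.max_force <= 0:
            raise ValueError("max_force must be positive")
        if self.force_fraction <= 0 or self.max_moment <= 0:
            raise ValueError("thresholds must be positive")

    def force_threshold(self, result: TrialResult) -> float:
        if self.max_force is not None:
            return self.max_force
        peak = float(np.max(result.grf_v)) if result.grf_v.size else 0.0
        return self.force_fraction * peak if peak > 0 else self.force_fraction


def relative_motion(result: TrialResult, pairs=None, phase_grid=PHASE_GRID) -> dict:
    """Per-pair relative-displacement traces resampled to gait-cycle phase.

    Returns {pair name: (len(phase_grid), 3) array, m} -- the shell marker
    minus the body-segment marker, expressed in the segment frame.
    """
    if pairs is None:
        pairs = sorted(result.marker_disp)
    out = {}
    for pair in pairs:
        if pair not in result.marker_disp:
            raise KeyError(
                f"marker pair {pair!r} missing from result; available: {sorted(result.marker_disp)}"
            )
        trace = result.marker_disp[pair]
        res = np.empty((len(phase_grid), 3))
        for j in range(3):
            res[:, j] = np.interp(phase_grid, result.phase, trace[:, j])
        out[pair] = res
    return out


def activation_deviation(
    result: TrialResult | list,
    ref: ReferenceActivation,
    phase_window: str | tuple = "stance",
    muscle: str = "plantarflexors",
) -> float:
    """Mean absolute deviation of simulated from reference activation, in
    percentage points of activation, over the phase window.

    ``phase_window`` is ``"stance"`` (vertical ground reaction above 2% of
    its peak), ``"swing"``, ``"cycle"``, or an explicit (lo, hi) phase pair
    in %.  A list of results yields the average across trials.
    """
    if isinstance(result, (list, tuple)):
        if not result:
            raise ValueError("empty result list")
        return float(
            np.mean([activation_deviation(r, ref, phase_window, muscle) for r in result])
        )

    if isinstance(phase_window, str):
        if phase_window == "stance":
            mask = result.stance_mask()
        elif phase_window == "swing":
            mask = ~result.stance_mask()
        elif phase_window == "cycle":
            mask = np.ones_like(result.phase, dtype=bool)
        else:
            raise ValueError(f"unknown phase window {phase_window!r}")
    else:
        lo, hi = phase_window
        mask = (result.phase >= lo) & (result.phase <= hi)
    if not np.any(mask):
        raise ValueError("phase window selects no samples")
    a_sim = result.activations[muscle][mask]
    a_ref = ref.at_phase(result.phase[mask])
    return float(np.mean(np.abs(a_sim - a_ref)) * 100.0)


def residual_check(result: TrialResult, thr: ResidualThresholds | None = None) -> dict:
    """Per-coordinate verdicts on residual/reserve usage.

    Pass iff max |residual| <= threshold (boundary inclusive).  Moment-type
    coordinates (rotational reserves) use ``max_moment``; force-type use the
    ground-reaction-scaled force threshold.  Margins are reported in the
    respective unit.
    """
    thr = thr or ResidualThresholds()
    f_thr = thr.force_threshold(result)
    out = {}
    for coord, trace in result.residuals.items():
        is_force = coord.endswith(("_fx", "_fy", "_fz", "_tx", "_ty", "_tz"))
        limit = f_thr if is_force else thr.max_moment
        peak = float(np.max(np.abs(trace))) if trace.size else 0.0
        out[coord] = {
            "max": peak,
            "threshold": limit,
            "pass": peak <= limit,
            "margin": limit - peak,
        }
    return out


def grid_conditions(
    levels=None, speeds=None, directions=None, subjects=(1,)
) -> list[dict]:
    """The full factorial condition list (level x speed x direction x subject)."""
    levels = list(levels or WEAKENING_LEVELS)
    speeds = list(speeds or SPEED_LEVELS)
    directions = list(directions or MISALIGNMENT_DIRECTIONS)
    return [
        {"level": lvl, "speed": sp, "direction": d, "seed": s}
        for s in subjects
        for sp in speeds
        for d in directions
        for lvl in levels
    ]


@dataclass
class DeviationReport:
    """Aggregated grid outcomes.

    ``conditions``: one row per condition with its metadata, peak
    displacements (mm), mean stance activation deviation (%), residual
    verdict and trace checksum.  ``traces``: phase-resampled
    relative-displacement traces per condition and marker pair.
    """

    conditions: pd.DataFrame
    traces: dict
    thresholds: ResidualThresholds
    metadata: dict = field(default_factory=dict)

    def mean_deviation_table(self) -> pd.DataFrame:
        """Mean stance activation deviation (%) by level x speed, averaged
        over misalignment directions and subjects (mean of per-subject means)."""
        ok = self.conditions[self.conditions["failed"] == False]  # noqa: E712
        per_subject = ok.groupby(["level", "speed", "seed"])["activation_dev_pct"].mean()
        return per_subject.groupby(["level", "speed"]).mean().unstack("speed")

    def save(self, directory) -> None:
        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.conditions.to_csv(directory / "conditions.csv", index=False)
        summary = {
            "metadata": self.metadata,
            "mean_stance_activation_deviation_pct": {
                str(k): {str(s): float(v) for s, v in row.items()}
                for k, row in self.mean_deviation_table().iterrows()
            },
            "all_residuals_pass": bool(self.conditions["residual_pass"].all()),
            "n_conditions": int(len(self.conditions)),
            "n_failed": int(self.conditions["failed"].sum()),
        }
        (directory / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    def plot_panels(self, directory) -> list:
        """Figure-style panels (clearly synthetic data): relative-movement
        traces per axis and mean activation-deviation bars."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        ok = self.conditions[self.conditions["failed"] == False]  # noqa: E712
        if ok.empty:
            return written

        sp = ok["speed"].iloc[0]
        seed = ok["seed"].iloc[0]
        for pair in ("foot", "shank"):
            fig, axes = plt.subplots(1, 3, figsize=(12, 3.2), sharex=True)
            for d in sorted(ok["direction"].unique()):
                key = ("PF25", sp, d, seed)
                if key not in self.traces:
                    continue
                tr = self.traces[key][pair] * 1000.0
                for j, ax_name in enumerate("xyz"):
                    axes[j].plot(PHASE_GRID, tr[:, j], label=d, lw=1)
            for j, ax_name in enumerate("xyz"):
                axes[j].set_xlabel("gait cycle [%]")
                axes[j].set_ylabel(f"{ax_name} displacement [mm]")
            axes[0].legend(fontsize=6)
            fig.suptitle(f"synthetic data: {pair} pair relative movement, PF25, {sp}")
            fig.tight_layout()
            path = directory / f"relative_movement_{pair}.png"
            fig.savefig(path, dpi=110)
            plt.close(fig)
            written.append(path)

        fig, ax = plt.subplots(figsize=(6, 3.2))
        table = self.mean_deviation_table()
        table.plot.bar(ax=ax)
        ax.set_ylabel("mean stance activation deviation [%]")
        ax.set_title("synthetic data: deviation from reference activation")
        fig.tight_layout()
        path = directory / "activation_deviation.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)
        return written


def run_grid(
    model: CoupledModel | None = None,
    levels=None,
    speeds=None,
    directions=None,
    subjects=(1,),
    thresholds: ResidualThresholds | None = None,
    dt: float = 1e-3,
    config_hash: str = "",
    progress: bool = False,
) -> DeviationReport:
    """Run the full study grid and aggregate the outcome measures.

    Per synthetic subject (seed) the grid is levels x speeds x directions
    (4 x 3 x 7 = 84 conditions by default).  The bootstrap ("initial CMC")
    is run once per (subject, speed, direction) on the unweakened model, so
    all weakening levels start from the same settled pose.  Per-condition
    failures are isolated, marked in the report, and do not stop the grid.
    """
    base = model if model is not None else build_model()
    thresholds = thresholds or ResidualThresholds()
    levels = list(levels or WEAKENING_LEVELS)
    speeds = list(speeds or SPEED_LEVELS)
    directions = list(directions or MISALIGNMENT_DIRECTIONS)

    rows = []
    traces = {}
    for seed in subjects:
        for sp in speeds:
            trial = synth_gait(sp, seed, body_mass=base.body_mass)
            ref = reference_activation(sp, seed, base)
            for d in directions:
                aligned = apply_misalignment(base, d)
                try:
                    state0 = initial_cmc(
                        aligned,
                        gait_initial_pose=_initial_pose(trial, aligned),
                        dt=dt,
                    )
                except Exception as exc:  # noqa: BLE001 -- isolate per condition
                    state0 = None
                    boot_error = str(exc)
                for lvl in levels:
                    meta = {"level": lvl, "speed": sp, "direction": d, "seed": seed,
                            "config_hash": config_hash}
                    if state0 is None:
                        rows.append(_failed_row(meta, f"bootstrap failed: {boot_error}"))
                        continue
                    try:
                        mod = apply_weakening(aligned, lvl)
                        tr = trial.with_support(synth_support(lvl, sp, seed, model=base))
                        result = run_gait_cycle(
                            mod, tr, initial_state=state0, dt=dt, metadata=dict(meta)
                        )
                        rows.append(
                            _condition_row(meta, result, ref, thresholds)
                        )
                        traces[(lvl, sp, d, seed)] = relative_motion(result)
                        if progress:
                            log.info(
                                "condition %s/%s/%s seed=%s: dev=%.2f%% residual_pass=%s",
                                lvl, sp, d, seed,
                                rows[-1]["activation_dev_pct"], rows[-1]["residual_pass"],
                            )
                    except Exception as exc:  # noqa: BLE001
                        rows.append(_failed_row(meta, str(exc)))
                        log.warning("condition %s failed: %s", meta, exc)

    frame = pd.DataFrame(rows)
    return DeviationReport(
        conditions=frame,
        traces=traces,
        thresholds=thresholds,
        metadata={
            "subjects": list(subjects),
            "levels": levels,
            "speeds": speeds,
            "directions": directions,
            "dt": dt,
            "config_hash": config_hash,
        },
    )


def _initial_pose(trial, model) -> dict:
    from .gait_synth import TrialKinematics

    kin = TrialKinematics(trial, model)
    return {"ankle": float(kin.theta_ref(0.0)), "shank": float(kin.shank_angle(0.0))}


def _condition_row(meta, result: TrialResult, ref, thresholds) -> dict:
    stance = result.stance_mask()
    row = dict(meta)
    for pair, trace in result.marker_disp.items():
        for j, ax in enumerate("xyz"):
            row[f"peak_{pair}_{ax}_mm"] = float(np.max(np.abs(trace[:, j])) * 1000.0)
            row[f"peak_stance_{pair}_{ax}_mm"] = (
                float(np.max(np.abs(trace[stance, j])) * 1000.0) if stance.any() else 0.0
            )
            row[f"min_stance_{pair}_{ax}_mm"] = (
                float(np.min(trace[stance, j]) * 1000.0) if stance.any() else 0.0
            )
            row[f"max_stance_{pair}_{ax}_mm"] = (
                float(np.max(trace[stance, j]) * 1000.0) if stance.any() else 0.0
            )
    row["activation_dev_pct"] = activation_deviation(result, ref, "stance")
    verdicts = residual_check(result, thresholds)
    row["residual_pass"] = bool(all(v["pass"] for v in verdicts.values()))
    row["residual_max_moment"] = float(
        max(v["max"] for c, v in verdicts.items() if not c.startswith("base_"))
    )
    row["residual_max_force"] = float(
        max((v["max"] for c, v in verdicts.items() if c.startswith("base_")), default=0.0)
    )
    row["checksum"] = result.checksum()
    row["n_flags"] = len(result.flags)
    row["failed"] = False
    row["error"] = ""
    return row


def _failed_row(meta, error: str) -> dict:
    row = dict(meta)
    row.update(
        activation_dev_pct=np.nan, residual_pass=False, residual_max_moment=np.nan,
        residual_max_force=np.nan, checksum="", n_flags=0, failed=True, error=error,
    )
    return row
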