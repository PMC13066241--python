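"""Synthetic gait fixtures: kinematics, ground reaction, and support curves.

Stands in for motion-lab recordings that are not published: cyclic
hip/knee/ankle trajectories at three self-selected speeds, a double-bump
vertical ground-reaction profile with a heel-to-toe center-of-pressure
sweep, and assistance-as-needed-style support-torque curves for the four
foot-drop patient variants (PF25..PF100, dorsiflexors paralyzed).

The joint-angle templates are truncated Fourier series fitted once to
fixed normative control points; they are honest synthetic stand-ins with
normative shape, not subject data.  Seeded jitter adds smooth low-order
inter-trial variability only, so generated trials never contain
non-physiological accelerations.

Sign conventions follow the model frame: x anterior, y up, z the flexion
axis; dorsiflexion, hip flexion and a positive support torque are +z.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy.interpolate import CubicSpline

from .leg_afo_model import WEAKENING_LEVELS, CoupledModel, apply_weakening, build_model

__all__ = [
    "SPEED_LEVELS",
    "GaitTrial",
    "SupportProfile",
    "ReferenceActivation",
    "TrialKinematics",
    "synth_gait",
    "synth_support",
    "reference_activation",
    "ankle_moment_demand",
    "patient_variants",
]

GRAVITY = 9.81  # m/s^2

#: Cycle duration (s), average progression speed (m/s), stance fraction of the
#: cycle, and amplitude scale of the three self-selected speed levels.
SPEED_LEVELS = {
    "slow": {"duration": 1.25, "speed": 1.00, "stance_fraction": 0.62, "amplitude": 0.95},
    "medium": {"duration": 1.05, "speed": 1.25, "stance_fraction": 0.60, "amplitude": 1.00},
    "fast": {"duration": 0.90, "speed": 1.50, "stance_fraction": 0.58, "amplitude": 1.08},
}

#: Normative sagittal joint-angle control points, degrees vs % gait cycle
#: (heel strike to heel strike).  Flexion/dorsiflexion positive.
_ANGLE_CONTROL_POINTS = {
    "hip": [(0, 30), (10, 27), (20, 18), (30, 8), (40, -2), (50, -10),
            (60, -8), (70, 10), (80, 28), (90, 32), (100, 30)],
    "knee": [(0, 5), (10, 15), (20, 12), (30, 6), (40, 5), (50, 12),
             (60, 35), (70, 62), (80, 55), (90, 25), (100, 5)],
    "ankle": [(0, 0), (10, -5), (20, 3), (30, 7), (40, 9), (50, 10),
              (60, -12), (70, -5), (80, 2), (90, 2), (100, 0)],
}

_N_HARMONICS = 3
_N_SAMPLES = 401  # samples per generated cycle


@lru_cache(maxsize=None)
def _fourier_coefficients(joint: str) -> tuple:
    """Least-squares truncated-Fourier fit of the normative control points."""
    pts = np.array(_ANGLE_CONTROL_POINTS[joint], dtype=float)
    phase = pts[:, 0] / 100.0
    target = np.deg2rad(pts[:, 1])
    cols = [np.ones_like(phase)]
    for k in range(1, _N_HARMONICS + 1):
        cols.append(np.cos(2 * np.pi * k * phase))
        cols.append(np.sin(2 * np.pi * k * phase))
    design = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(design, target, rcond=None)
    return tuple(coef)


def _fourier_eval(coef, phase: np.ndarray) -> np.ndarray:
    out = np.full_like(phase, coef[0])
    for k in range(1, (len(coef) - 1) // 2 + 1):
        out = out + coef[2 * k - 1] * np.cos(2 * np.pi * k * phase)
        out = out + coef[2 * k] * np.sin(2 * np.pi * k * phase)
    return out


@dataclass(frozen=True)
class SupportProfile:
    """Device support torque about the AFO axis vs gait-cycle phase.

    Positive torque assists dorsiflexion; the late-stance plantarflexion
    lobe is therefore negative.  ``level`` names the weakening variant the
    profile targets.
    """

    phase: np.ndarray  # % gait cycle, 0..100
    torque: np.ndarray  # Nm
    level: str
    speed: str = "slow"

    def __post_init__(self):
        object.__setattr__(self, "phase", np.asarray(self.phase, dtype=float))
        object.__setattr__(self, "torque", np.asarray(self.torque, dtype=float))

    def at_phase(self, phase) -> np.ndarray:
        return np.interp(np.mod(phase, 100.0), self.phase, self.torque)


@dataclass(frozen=True)
class ReferenceActivation:
    """Healthy ("targeted") plantarflexor activation curve vs phase."""

    phase: np.ndarray
    activation: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "phase", np.asarray(self.phase, dtype=float))
        act = np.asarray(self.activation, dtype=float)
        if np.any(act < 0) or np.any(act > 1):
            raise ValueError("reference activation must lie in [0, 1]")
        object.__setattr__(self, "activation", act)

    def at_phase(self, phase) -> np.ndarray:
        return np.interp(np.mod(phase, 100.0), self.phase, self.activation)


@dataclass(frozen=True)
class GaitTrial:
    """One synthetic gait cycle: kinematics, ground reaction, metadata.

    Joint angles are radians over one heel-strike-to-heel-strike cycle and
    periodic (first sample equals last).  ``cop_x`` is the center of
    pressure anterior of the ankle, m, meaningful during stance.  The
    vertical ground reaction is non-negative and identically zero in swing.
    """

    speed: str
    cycle_duration: float
    stance_fraction: float
    time: np.ndarray
    hip: np.ndarray
    knee: np.ndarray
    ankle: np.ndarray
    grf_v: np.ndarray
    grf_ap: np.ndarray
    cop_x: np.ndarray
    body_mass: float
    seed: int
    support: SupportProfile | None = None

    def __post_init__(self):
        for name in ("time", "hip", "knee", "ankle", "grf_v", "grf_ap", "cop_x"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))

    def validate(self) -> None:
        """Raise if any GaitTrial invariant is violated."""
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time base must be strictly increasing")
        for name in ("hip", "knee", "ankle"):
            arr = getattr(self, name)
            if abs(arr[0] - arr[-1]) > 1e-09:
                raise ValueError(f"{name} trajectory is not periodic over the cycle")
        if np.any(self.grf_v < 0):
            raise ValueError("vertical ground reaction must be non-negative")
        swing = self.time / self.cycle_duration > self.stance_fraction + 1e-09
        if np.any(self.grf_v[swing] != 0):
            raise ValueError("ground reaction must vanish during swing")

    def phase_of(self, t) -> np.ndarray:
        """Gait-cycle phase in %, wrapping at the cycle boundary."""
        return 100.0 * np.mod(np.asarray(t, dtype=float) / self.cycle_duration, 1.0)

    def with_support(self, support: SupportProfile) -> "GaitTrial":
        return replace(self, support=support)


def _smooth_jitter(rng: np.random.Generator, phase: np.ndarray, amplitude: float) -> np.ndarray:
    """Periodic low-order (two-harmonic) perturbation with the given RMS scale."""
    out = np.zeros_like(phase)
    for k in (1, 2):
        a = rng.normal(0.0, amplitude / np.sqrt(2))
        psi = rng.uniform(0, 2 * np.pi)
        out += a * np.cos(2 * np.pi * k * phase + psi)
    return out


def synth_gait(speed: str, seed: int, body_mass: float = 75.0) -> GaitTrial:
    """Generate one synthetic gait cycle at the given speed level.

    Deterministic per (speed, seed); the seed identifies a synthetic
    subject/trial and drives only smooth low-order jitter of the angle
    templates and a small ground-reaction scale factor.
    """
    if speed not in SPEED_LEVELS:
        raise ValueError(f"unknown speed {speed!r}; valid: {', '.join(SPEED_LEVELS)}")
    pars = SPEED_LEVELS[speed]
    rng = np.random.default_rng([seed, list(SPEED_LEVELS).index(speed)])

    duration = pars["duration"] * (1.0 + rng.normal(0.0, 0.015))
    amp = pars["amplitude"]
    stance_frac = pars["stance_fraction"]
    phase = np.linspace(0.0, 1.0, _N_SAMPLES)
    time = phase * duration

    angles = {}
    for joint in ("hip", "knee", "ankle"):
        coef = _fourier_coefficients(joint)
        mean = coef[0]
        curve = mean + amp * (_fourier_eval(coef, phase) - mean)
        curve = curve + _smooth_jitter(rng, phase, np.deg2rad(0.7))
        curve[-1] = curve[0]  # enforce exact periodicity at the seam
        angles[joint] = curve

    # Double-bump vertical ground reaction over stance.  The flat-topped
    # envelope is tapered to zero over the final ~0.18 s of stance: push-off
    # unloading takes roughly constant wall time across speeds, so the taper
    # occupies a larger phase fraction of the shorter fast cycles.  The
    # per-speed compensation factor offsets the taper's area loss and keeps
    # the stance impulse near 0.92 x body weight x stance duration.
    s = np.clip(phase / stance_frac, 0.0, 1.0)
    env = np.sin(np.pi * s)
    valley = {"slow": 0.22, "medium": 0.25, "fast": 0.30}[speed]
    unload_frac = min(0.18 / (stance_frac * duration), 0.45)
    u_off = np.clip((1.0 - s) / unload_frac, 0.0, 1.0)
    taper = 3 * u_off**2 - 2 * u_off**3
    comp = {"slow": 1.00, "medium": 1.04, "fast": 1.10}[speed]
    shape = 1.30 * comp * (env**0.25 - valley * env**8) * taper
    grf_scale = 1.0 + rng.normal(0.0, 0.02)
    weight = body_mass * GRAVITY
    grf_v = weight * shape * grf_scale * (1.0 + 0.3 * (amp - 1.0))
    grf_ap = -0.16 * weight * np.sin(2 * np.pi * s) * grf_scale
    in_stance = phase <= stance_frac
    grf_v[~in_stance] = 0.0
    grf_ap[~in_stance] = 0.0
    grf_v = np.maximum(grf_v, 0.0)

    # Heel-to-toe center-of-pressure progression (anterior of ankle, m); the
    # early sweep is fast so the heel lever is short once the limb is loaded.
    # The excursion is anatomically bounded by foot length, so it scales only
    # weakly with speed.
    cop_range = 0.22 * (1.0 + 0.5 * (amp - 1.0))
    u = s**0.8
    cop = -0.04 + cop_range * (3 * u**2 - 2 * u**3)
    cop[~in_stance] = 0.0

    return GaitTrial(
        speed=speed,
        cycle_duration=duration,
        stance_fraction=stance_frac,
        time=time,
        hip=angles["hip"],
        knee=angles["knee"],
        ankle=angles["ankle"],
        grf_v=grf_v,
        grf_ap=grf_ap,
        cop_x=cop,
        body_mass=body_mass,
        seed=seed,
    )


class TrialKinematics:
    """Smooth, periodic interpolants of a trial's base motion.

    Provides the shank frame angle/rates, the world ankle-point trajectory
    (from a pelvis advancing at the trial's mean progression speed), the
    ankle-angle reference and the ground-reaction interpolants that the
    dynamics engine consumes.  Times outside the cycle wrap periodically.
    """

    def __init__(self, trial: GaitTrial, model: CoupledModel | None = None):
        if model is None:
            model = build_model()
        self.trial = trial
        self.period = trial.cycle_duration
        t = trial.time
        self._hip = CubicSpline(t, trial.hip, bc_type="periodic")
        self._knee = CubicSpline(t, trial.knee, bc_type="periodic")
        self._ankle = CubicSpline(t, trial.ankle, bc_type="periodic")

        l_thigh, l_shank = model.thigh_length, model.shank_length
        self.speed = SPEED_LEVELS[trial.speed]["speed"]
        hip_h = l_thigh + l_shank + 0.08
        alpha = trial.hip - trial.knee  # shank world rotation about z
        ankle_x = (
            self.speed * t
            + l_thigh * np.sin(trial.hip)
            + l_shank * np.sin(alpha)
        )
        ankle_y = hip_h - l_thigh * np.cos(trial.hip) - l_shank * np.cos(alpha)
        drift = ankle_x - self.speed * t
        drift[-1] = drift[0]
        ankle_y = ankle_y.copy()
        ankle_y[-1] = ankle_y[0]
        self._ankle_x_periodic = CubicSpline(t, drift, bc_type="periodic")
        self._ankle_y = CubicSpline(t, ankle_y, bc_type="periodic")
        self._alpha = CubicSpline(t, np.r_[alpha[:-1], alpha[0]], bc_type="periodic")

        self._grf_v = CubicSpline(t, trial.grf_v, bc_type="periodic")
        self._grf_ap = CubicSpline(t, trial.grf_ap, bc_type="periodic")
        self._cop = CubicSpline(t, np.r_[trial.cop_x[:-1], trial.cop_x[0]], bc_type="periodic")

    def _wrap(self, t):
        return np.mod(t, self.period)

    # -- base (prescribed) motion -------------------------------------------
    def shank_angle(self, t):
        return self._alpha(self._wrap(t))

    def shank_rate(self, t):
        return self._alpha(self._wrap(t), 1)

    def shank_acc(self, t):
        return self._alpha(self._wrap(t), 2)

    def ankle_pos_world(self, t):
        tw = self._wrap(t)
        return np.array([self.speed * np.asarray(t, dtype=float) + self._ankle_x_periodic(tw),
                         self._ankle_y(tw)])

    def ankle_acc_world(self, t):
        tw = self._wrap(t)
        return np.array([self._ankle_x_periodic(tw, 2), self._ankle_y(tw, 2)])

    def ankle_height(self, t):
        return float(self._ankle_y(self._wrap(t)))

    # -- ankle-angle reference ----------------------------------------------
    def theta_ref(self, t):
        return self._ankle(self._wrap(t))

    def theta_ref_rate(self, t):
        return self._ankle(self._wrap(t), 1)

    def theta_ref_acc(self, t):
        return self._ankle(self._wrap(t), 2)

    # -- external loads ------------------------------------------------------
    def grf(self, t):
        """(f_ap, f_vertical, cop_x anterior of ankle) at time t."""
        tw = self._wrap(t)
        fv = float(np.clip(self._grf_v(tw), 0.0, None))
        if fv <= 0.0:
            return 0.0, 0.0, 0.0
        return float(self._grf_ap(tw)), fv, float(self._cop(tw))


def ankle_moment_demand(trial: GaitTrial, model: CoupledModel | None = None) -> np.ndarray:
    """Inverse-dynamics ankle actuator moment over the trial's time base, Nm.

    The net muscle-plus-device moment (dorsiflexion positive) required for
    the foot+toes assembly to follow the recorded ankle angle under the
    recorded ground reaction, gravity and base-motion inertia.  This is the
    screening oracle used for support calibration, reference activation and
    speed-demand comparisons.
    """
    if model is None:
        model = build_model()
    kin = TrialKinematics(trial, model)
    m_foot, com, i_com = model.lumped_foot()
    r = float(np.hypot(com[0], com[1]))
    i_ankle = i_com + m_foot * r * r

    t = trial.time
    alpha = kin.shank_angle(t)
    theta = kin.theta_ref(t)
    theta_dd = kin.theta_ref_acc(t)
    alpha_dd = kin.shank_acc(t)
    a_ankle = kin.ankle_acc_world(t)  # world frame
    ankle_y = kin.ankle_pos_world(t)[1]

    # Foot COM position in world-aligned axes (z-moments are frame-invariant).
    foot_angle = alpha + theta
    com_angle = np.arctan2(com[1], com[0])
    rx = r * np.cos(foot_angle + com_angle)
    ry = r * np.sin(foot_angle + com_angle)

    # Effective gravity includes the ankle-point acceleration pseudo-force.
    gx = -a_ankle[0]
    gy = -GRAVITY - a_ankle[1]
    tau_grav = m_foot * (rx * gy - ry * gx)

    tau_grf = trial.grf_v * trial.cop_x - trial.grf_ap * (-ankle_y)
    tau_grf[trial.grf_v <= 0] = 0.0

    return i_ankle * (theta_dd + alpha_dd) - tau_grav - tau_grf


def _healthy_pf_activation(trial: GaitTrial, model: CoupledModel) -> np.ndarray:
    """Healthy plantarflexor activation over the cycle, including the
    first-order activation/deactivation dynamics (so the post-push-off
    deactivation tail is part of the healthy pattern)."""
    demand = ankle_moment_demand(trial, model)
    pf = model.muscles["plantarflexors"]
    capacity = pf.f_max_iso * pf.moment_arm  # unweakened
    target = np.clip(np.clip(-demand, 0.0, None) / capacity, 0.0, 1.0)
    a = np.empty_like(target)
    a0 = target[0]
    dt = np.diff(trial.time)
    for _ in range(2):  # iterate to a periodic steady state
        a[0] = a0
        for i in range(len(target) - 1):
            tau = pf.tau_act if target[i + 1] >= a[i] else pf.tau_deact
            a[i + 1] = a[i] + dt[i] * (target[i + 1] - a[i]) / tau
            a[i + 1] = min(max(a[i + 1], 0.0), 1.0)
        a0 = a[-1]
    return a


def _demand_parts(trial: GaitTrial, model: CoupledModel):
    """Split the net ankle demand into the healthy muscle-group shares.

    The plantarflexor share is the moment the healthy (filtered) activation
    pattern produces; the dorsiflexor share is whatever positive moment
    remains -- including the toe-off window where lingering plantarflexor
    moment must be overcome by the dorsiflexors.
    """
    demand = ankle_moment_demand(trial, model)
    pf = model.muscles["plantarflexors"]
    capacity = pf.f_max_iso * pf.moment_arm
    pf_part = capacity * _healthy_pf_activation(trial, model)  # magnitude (plantarflexion)
    df_part = np.clip(demand + pf_part, 0.0, None)
    return df_part, pf_part


def reference_activation(
    speed: str, seed: int = 0, model: CoupledModel | None = None
) -> ReferenceActivation:
    """Healthy plantarflexor activation implied by the trial's ankle demand."""
    if model is None:
        model = build_model()
    trial = synth_gait(speed, seed, body_mass=model.body_mass)
    activation = _healthy_pf_activation(trial, model)
    phase = 100.0 * trial.time / trial.cycle_duration
    return ReferenceActivation(phase=phase, activation=activation)


def synth_support(
    level: str,
    speed: str,
    seed: int = 0,
    dorsiflexors_paralyzed: bool = True,
    model: CoupledModel | None = None,
) -> SupportProfile:
    """Assistance-as-needed-style support torque for one patient variant.

    Calibration (documented procedure, since the source curves are not
    published): the inverse-dynamics ankle demand is split into the healthy
    plantarflexor share (the filtered healthy activation pattern, including
    its deactivation tail after push-off) and the dorsiflexor share that
    remains.  The device supplies the full dorsiflexor share (dorsiflexors
    are paralyzed in every variant) plus the fraction (1 - w) of the
    plantarflexor share the weakened plantarflexors can no longer produce.
    The swing lobe is hence positive (catching the foot at toe-off, then
    holding it against gravity sag); the late-stance lobe is negative
    (plantarflexion support) and scales with weakness.
    """
    if level not in WEAKENING_LEVELS:
        raise ValueError(
            f"unknown weakening level {level!r}; valid: {', '.join(WEAKENING_LEVELS)}"
        )
    if model is None:
        model = build_model()
    trial = synth_gait(speed, seed, body_mass=model.body_mass)
    df_part, pf_part = _demand_parts(trial, model)
    w = WEAKENING_LEVELS[level]
    torque = (df_part if dorsiflexors_paralyzed else np.zeros_like(df_part)) - (1.0 - w) * pf_part
    phase = 100.0 * trial.time / trial.cycle_duration
    return SupportProfile(phase=phase, torque=torque, level=level, speed=speed)


def patient_variants(base_model: CoupledModel) -> dict:
    """The four foot-drop patient variants, PF25 (weakest) to PF100.

    Pure: the base model is untouched; every variant has paralyzed
    dorsiflexors.
    """
    return {level: apply_weakening(base_model, level) for level in WEAKENING_LEVELS}
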