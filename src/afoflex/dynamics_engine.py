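"""Forward simulation of the coupled leg + AFO model over a gait cycle.

The pelvis, thigh and shank follow recorded (or synthetic) kinematics; the
free generalized coordinates are the ankle angle, the three translations of
the auxiliary body carrying the device axis, and the two shell rotations
(see :data:`afoflex.leg_afo_model.FREE_COORDS`).  The equations of motion
are written in the shank-attached frame with the full planar fictitious
forces of the moving frame (frame translation, centrifugal, Coriolis,
Euler), so they are exact for the modeled subsystem given the prescribed
base motion.

A computed-muscle-control-style controller tracks the reference ankle angle:
PD feedback produces desired accelerations for the tasked coordinates, and a
weighted least-squares optimization distributes them over muscle activations
(activation-squared cost, bounds [0, 1]) and heavily penalized reserve
actuators that absorb any deficit.

The interface stiffness of 1e4 N/m acting on the 1e-5 kg auxiliary body
makes the system extremely stiff (characteristic rates ~3e4 1/s), so time
stepping uses a fixed-step linearly-implicit theta scheme with
finite-difference force Jacobians; explicit integration is not an option at
any practical step size.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .gait_synth import GRAVITY, GaitTrial, TrialKinematics
from .interface_model import bushing_wrench  # noqa: F401  (re-export for tests)
from .leg_afo_model import FREE_COORDS, CoupledModel

__all__ = [
    "State",
    "TrackingTask",
    "ResidualActuator",
    "TrialResult",
    "ExternalLoads",
    "StaticBase",
    "DynamicsEngine",
    "equations_of_motion",
    "cmc_step",
    "initial_cmc",
    "run_gait_cycle",
    "linear_ramp",
]

IDX = {name: i for i, name in enumerate(FREE_COORDS)}
N_Q = len(FREE_COORDS)

#: Default PD gains of the tracking tasks (critical-damping-style pair).
DEFAULT_KP = 100.0  # 1/s^2
DEFAULT_KV = 20.0  # 1/s

#: Task weight of the knee and ankle tracking tasks (other coordinates: 1).
DEFAULT_TASK_WEIGHT = 10.0

#: Reserve actuators are ~100x more expensive than muscles in the optimizer.
RESERVE_PENALTY = 100.0
RESERVE_SCALE = 1.0  # Nm (or N) of generalized force per unit reserve control


@dataclass
class State:
    """Instantaneous simulation state of the free coordinates."""

    q: np.ndarray
    qdot: np.ndarray
    activations: dict
    time: float = 0.0
    flags: tuple = ()

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.qdot = np.asarray(self.qdot, dtype=float)
        if self.q.shape != (N_Q,) or self.qdot.shape != (N_Q,):
            raise ValueError(f"state vectors must have shape ({N_Q},)")
        if not (np.all(np.isfinite(self.q)) and np.all(np.isfinite(self.qdot))):
            raise ValueError("non-finite state")
        for name, a in self.activations.items():
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"activation of {name!r} outside [0, 1]: {a}")

    @classmethod
    def neutral(cls, model: CoupledModel, time: float = 0.0) -> "State":
        return cls(
            q=np.zeros(N_Q),
            qdot=np.zeros(N_Q),
            activations={name: 0.0 for name in model.muscles},
            time=time,
        )

    def copy(self) -> "State":
        return State(self.q.copy(), self.qdot.copy(), dict(self.activations), self.time, self.flags)


@dataclass(frozen=True)
class TrackingTask:
    """One tracked coordinate: reference trajectory plus PD feedback gains."""

    coordinate: str
    reference: object  # t -> value
    reference_rate: object = None
    reference_acc: object = None
    weight: float = 1.0
    k_p: float = DEFAULT_KP
    k_v: float = DEFAULT_KV

    def __post_init__(self):
        if self.coordinate not in IDX:
            raise ValueError(f"unknown coordinate {self.coordinate!r}; valid: {FREE_COORDS}")
        if self.weight <= 0:
            raise ValueError("task weight must be > 0")

    def desired_acceleration(self, t: float, q: float, qdot: float) -> float:
        ref = float(self.reference(t))
        ref_d = float(self.reference_rate(t)) if self.reference_rate else 0.0
        ref_dd = float(self.reference_acc(t)) if self.reference_acc else 0.0
        return ref_dd + self.k_v * (ref_d - qdot) + self.k_p * (ref - q)


@dataclass
class ResidualActuator:
    """Reserve/residual actuator on one coordinate; usage recorded per step."""

    coordinate: str
    scale: float = RESERVE_SCALE
    usage: list = field(default_factory=list)


@dataclass
class TrialResult:
    """Recorded traces of one simulated condition (shared time base)."""

    time: np.ndarray
    phase: np.ndarray
    q: np.ndarray  # (N, 6)
    qdot: np.ndarray
    activations: dict  # name -> (N,)
    wrenches: dict  # element name -> (N, 6): force xyz, moment xyz (element frame)
    marker_disp: dict  # pair name -> (N, 3), segment frame
    residuals: dict  # coordinate -> (N,)
    grf_v: np.ndarray
    support: np.ndarray
    energy: dict  # term -> (N,)
    flags: list
    metadata: dict

    def checksum(self) -> str:
        """Deterministic digest of all traces (round-tripped at 1e-12)."""
        h = hashlib.sha256()
        for arr in self._trace_iter():
            h.update(np.round(np.asarray(arr, dtype=float), 12).tobytes())
        return h.hexdigest()

    def _trace_iter(self):
        yield self.time
        yield self.q
        yield self.qdot
        for key in sorted(self.activations):
            yield self.activations[key]
        for key in sorted(self.wrenches):
            yield self.wrenches[key]
        for key in sorted(self.marker_disp):
            yield self.marker_disp[key]
        for key in sorted(self.residuals):
            yield self.residuals[key]
        yield self.grf_v
        yield self.support

    def stance_mask(self, threshold_fraction: float = 0.02) -> np.ndarray:
        """Stance = vertical ground reaction above 2% of its peak."""
        peak = float(np.max(self.grf_v)) if self.grf_v.size else 0.0
        if peak <= 0:
            return np.zeros_like(self.grf_v, dtype=bool)
        return self.grf_v > threshold_fraction * peak

    def to_frame(self):
        """Tidy per-sample table (one row per time sample)."""
        import pandas as pd

        data = {"time": self.time, "phase": self.phase}
        for i, name in enumerate(FREE_COORDS):
            data[f"q_{name}"] = self.q[:, i]
            data[f"qdot_{name}"] = self.qdot[:, i]
        for name, arr in self.activations.items():
            data[f"act_{name}"] = arr
        for pair, arr in self.marker_disp.items():
            for j, ax in enumerate("xyz"):
                data[f"disp_{pair}_{ax}"] = arr[:, j]
        for coord, arr in self.residuals.items():
            data[f"residual_{coord}"] = arr
        data["grf_v"] = self.grf_v
        data["support"] = self.support
        return pd.DataFrame(data)

    def save(self, directory) -> None:
        """Write the tidy CSV plus a JSON metadata sidecar."""
        import pathlib

        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / "trial.csv", index=False)
        meta = dict(self.metadata)
        meta["checksum"] = self.checksum()
        meta["flags"] = [list(f) for f in self.flags]
        (directory / "trial.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


class StaticBase:
    """Stationary base: shank fixed upright, no frame acceleration."""

    def shank_angle(self, t):
        return 0.0

    def shank_rate(self, t):
        return 0.0

    def shank_acc(self, t):
        return 0.0

    def ankle_acc_world(self, t):
        return np.zeros(2)

    def ankle_height(self, t):
        return 0.08


class _RampBase:
    """Bootstrap base: shank angle ramps linearly to a target, then holds."""

    def __init__(self, target_angle: float, ramp_time: float):
        self.target = float(target_angle)
        self.ramp_time = float(ramp_time)

    def shank_angle(self, t):
        if self.ramp_time <= 0 or t >= self.ramp_time:
            return self.target
        return self.target * max(t, 0.0) / self.ramp_time

    def shank_rate(self, t):
        if 0.0 <= t < self.ramp_time:
            return self.target / self.ramp_time
        return 0.0

    def shank_acc(self, t):
        return 0.0

    def ankle_acc_world(self, t):
        return np.zeros(2)

    def ankle_height(self, t):
        return 0.08


@dataclass
class ExternalLoads:
    """External generalized loads: support torque, ground reaction, gravity."""

    support: object = None  # t -> Nm about the device axis (dorsiflexion +)
    grf: object = None  # t -> (f_ap, f_vertical, cop_x anterior of ankle)
    gravity: bool = True
    extra_generalized: object = None  # t -> (6,) generalized force, for tests

    def support_at(self, t: float) -> float:
        return float(self.support(t)) if self.support is not None else 0.0

    def grf_at(self, t: float):
        return self.grf(t) if self.grf is not None else (0.0, 0.0, 0.0)


def _rot(angle: float, x: float, y: float):
    c, s = math.cos(angle), math.sin(angle)
    return c * x - s * y, s * x + c * y


class DynamicsEngine:
    """Equations of motion and stiff time stepping for one model instance.

    Caches the model geometry (pin-relative shell geometry, element anchors,
    lumped foot properties) so the per-step force evaluation stays cheap.
    """

    def __init__(
        self,
        model: CoupledModel,
        base=None,
        loads: ExternalLoads | None = None,
        dt: float = 1e-3,
        theta: float = 0.6,
        jac_every: int = 10,
    ):
        self.model = model
        self.base = base if base is not None else StaticBase()
        self.loads = loads if loads is not None else ExternalLoads()
        self.dt = float(dt)
        self.theta = float(theta)
        self.jac_every = int(jac_every)

        off = model.misalignment
        self.off = off.copy()
        m_f, c_f, i_f = model.lumped_foot()
        self.foot_mass, self.foot_com, self.foot_icom = m_f, c_f, i_f
        self.foot_iankle = i_f + m_f * (c_f[0] ** 2 + c_f[1] ** 2)
        self.aux_mass = model.segments["aux"].mass

        self.shells = []
        for name, phi_idx in (("foot_shell", IDX["footshell_rz"]), ("calf_shell", IDX["calfshell_rz"])):
            seg = model.segments[name]
            self.shells.append(
                {
                    "name": name,
                    "phi": phi_idx,
                    "mass": seg.mass,
                    "icom": seg.inertia_z,
                    "c_rel": seg.com - off,  # COM relative to the device pin
                }
            )

        self.elements = []
        for e in model.elements:
            self.elements.append(
                {
                    "name": e.name,
                    "foot_side": e.segment in ("foot", "toes"),
                    "phi": IDX["footshell_rz"] if e.shell == "foot_shell" else IDX["calfshell_rz"],
                    "a_seg": e.anchor_segment.copy(),
                    "b_sh": e.anchor_shell_neutral - off,  # anchor relative to the pin
                    "k_t": e.params.k_trans,
                    "c_t": e.params.c_trans,
                    "k_rz": float(e.params.k_rot[2]),
                    "c_rz": float(e.params.c_rot[2]),
                }
            )

        self.markers = []
        for m in model.markers:
            self.markers.append(
                {
                    "name": m.name,
                    "foot_side": m.segment in ("foot", "toes"),
                    "phi": IDX["footshell_rz"] if m.shell == "foot_shell" else IDX["calfshell_rz"],
                    "p": m.position_neutral.copy(),
                    "p_rel": m.position_neutral - off,
                }
            )

        # muscle control columns: unit-activation ankle moments
        self.muscle_names = list(model.muscles)
        self.muscle_tau = np.array(
            [model.muscles[n].sign * model.muscles[n].max_moment() for n in self.muscle_names]
        )

        self._jq = None
        self._jv = None
        self._steps_since_jac = 10**9

    # ------------------------------------------------------------------ EOM
    def mass_matrix(self, q: np.ndarray) -> np.ndarray:
        M = np.zeros((N_Q, N_Q))
        M[0, 0] = self.foot_iankle
        m_d = self.aux_mass
        M[1, 1] += m_d
        M[2, 2] += m_d
        M[3, 3] += m_d
        for sh in self.shells:
            m, icom, phi = sh["mass"], sh["icom"], sh["phi"]
            sx, sy = _rot(q[phi], sh["c_rel"][0], sh["c_rel"][1])
            zx, zy = -sy, sx  # z-hat cross s
            M[1, 1] += m
            M[2, 2] += m
            M[3, 3] += m
            M[1, phi] += m * zx
            M[2, phi] += m * zy
            M[phi, 1] += m * zx
            M[phi, 2] += m * zy
            M[phi, phi] += icom + m * (sx * sx + sy * sy)
        return M

    def forces(self, q, v, t, controls=None, record=False):
        """Generalized forces Q(q, v, t, controls); optionally also a record
        of element wrenches/kinematics and instantaneous power terms."""
        base, loads = self.base, self.loads
        alpha = float(base.shank_angle(t))
        omega = float(base.shank_rate(t))
        omega_dot = float(base.shank_acc(t))
        a_aw = base.ankle_acc_world(t)

        gx_w = -float(a_aw[0])
        gy_w = (-GRAVITY if loads.gravity else 0.0) - float(a_aw[1])
        gex, gey = _rot(-alpha, gx_w, gy_w)  # effective gravity in the shank frame

        Q = np.zeros(N_Q)
        theta, ux, uy, uz, _, _ = q
        theta_d = v[0]
        vx, vy, vz = v[1], v[2], v[3]

        rec = {"elements": {}, "power": {}} if record else None

        def fict(m, rx, ry, vrx, vry):
            # m * (g_eff + w^2 r - wdot z x r - 2 w z x v_rel)
            fx = m * (gex + omega * omega * rx + omega_dot * ry + 2.0 * omega * vry)
            fy = m * (gey + omega * omega * ry - omega_dot * rx - 2.0 * omega * vrx)
            return fx, fy

        # foot (+ toes) about the ankle
        rfx, rfy = _rot(theta, self.foot_com[0], self.foot_com[1])
        ffx, ffy = fict(self.foot_mass, rfx, rfy, -theta_d * rfy, theta_d * rfx)
        Q[0] += rfx * ffy - rfy * ffx - self.foot_icom * omega_dot

        # auxiliary body
        rdx, rdy = self.off[0] + ux, self.off[1] + uy
        fdx, fdy = fict(self.aux_mass, rdx, rdy, vx, vy)
        Q[1] += fdx
        Q[2] += fdy

        # shells
        for sh in self.shells:
            phi = sh["phi"]
            m = sh["mass"]
            sx, sy = _rot(q[phi], sh["c_rel"][0], sh["c_rel"][1])
            phid = v[phi]
            vsx, vsy = vx - phid * sy, vy + phid * sx
            fx, fy = fict(m, rdx + sx, rdy + sy, vsx, vsy)
            Q[1] += fx + m * phid * phid * sx
            Q[2] += fy + m * phid * phid * sy
            Q[phi] += sx * fy - sy * fx - sh["icom"] * omega_dot

        # interface elements
        p_damp = 0.0
        e_spring = 0.0
        for el in self.elements:
            if el["foot_side"]:
                ths, thsd = theta, theta_d
            else:
                ths, thsd = 0.0, 0.0
            ax, ay = _rot(ths, el["a_seg"][0], el["a_seg"][1])
            bx, by = _rot(q[el["phi"]], el["b_sh"][0], el["b_sh"][1])
            dx_s = rdx + bx - ax
            dy_s = rdy + by - ay
            dz = self.off[2] + uz + el["b_sh"][2]
            dex, dey = _rot(-ths, dx_s, dy_s)
            phid = v[el["phi"]]
            vax, vay = -thsd * ay, thsd * ax
            vbx, vby = vx - phid * by, vy + phid * bx
            dvx_s, dvy_s = vbx - vax, vby - vay
            dvex, dvey = _rot(-ths, dvx_s, dvy_s)
            dvex += thsd * dey
            dvey += -thsd * dex
            dth = q[el["phi"]] - ths
            dthd = phid - thsd

            k_t, c_t = el["k_t"], el["c_t"]
            fex = -(k_t[0] * dex + c_t[0] * dvex)
            fey = -(k_t[1] * dey + c_t[1] * dvey)
            fez = -(k_t[2] * dz + c_t[2] * vz)
            mez = -(el["k_rz"] * dth + el["c_rz"] * dthd)

            fsx, fsy = _rot(ths, fex, fey)
            Q[1] += fsx
            Q[2] += fsy
            Q[3] += fez
            Q[el["phi"]] += bx * fsy - by * fsx + mez
            if el["foot_side"]:
                Q[0] += -(ax * fsy - ay * fsx) - mez

            if record:
                rec["elements"][el["name"]] = np.array([fex, fey, fez, 0.0, 0.0, mez])
                p_damp += c_t[0] * dvex**2 + c_t[1] * dvey**2 + c_t[2] * vz**2 + el["c_rz"] * dthd**2
                e_spring += 0.5 * (k_t[0] * dex**2 + k_t[1] * dey**2 + k_t[2] * dz**2 + el["k_rz"] * dth**2)

        # muscles and reserves
        p_muscle = 0.0
        p_reserve = 0.0
        if controls is not None:
            acts = controls.get("activations", {})
            tau_m = 0.0
            for i, name in enumerate(self.muscle_names):
                tau_m += self.muscle_tau[i] * acts.get(name, 0.0)
            Q[0] += tau_m
            p_muscle = tau_m * theta_d
            for coord, val in controls.get("reserves", {}).items():
                Q[IDX[coord]] += val
                p_reserve += val * v[IDX[coord]]

        # support torque between the two shells, about the device axis
        ms = loads.support_at(t)
        Q[IDX["footshell_rz"]] += ms
        Q[IDX["calfshell_rz"]] -= ms
        p_support = ms * (v[IDX["footshell_rz"]] - v[IDX["calfshell_rz"]])

        # ground reaction on the foot at the prescribed center of pressure
        p_grf = 0.0
        fap, fv, cop = loads.grf_at(t)
        if fv > 0.0:
            ankle_y = float(self.base.ankle_height(t))
            tau_grf = cop * fv + ankle_y * fap
            Q[0] += tau_grf
            p_grf = tau_grf * theta_d

        if loads.extra_generalized is not None:
            Q += np.asarray(loads.extra_generalized(t), dtype=float)

        if record:
            rec["power"] = {
                "muscle": p_muscle,
                "support": p_support,
                "grf": p_grf,
                "reserve": p_reserve,
                "damper": p_damp,
            }
            rec["spring_energy"] = e_spring
            rec["gravity_potential"] = self._gravity_potential(q)
            return Q, rec
        return Q

    def _gravity_potential(self, q) -> float:
        """Sum m g y of all free bodies in the shank frame (meaningful for a
        static upright base; recorded for work-energy audits)."""
        theta, ux, uy, uz, _, _ = q
        _, rfy = _rot(theta, self.foot_com[0], self.foot_com[1])
        pe = self.foot_mass * rfy
        rdy = self.off[1] + uy
        pe += self.aux_mass * rdy
        for sh in self.shells:
            _, sy = _rot(q[sh["phi"]], sh["c_rel"][0], sh["c_rel"][1])
            pe += sh["mass"] * (rdy + sy)
        return GRAVITY * pe if self.loads.gravity else 0.0

    def accelerations(self, q, v, t, controls=None) -> np.ndarray:
        M = self.mass_matrix(q)
        cond = np.linalg.cond(M)
        if not np.isfinite(cond) or cond > 1e12:
            raise RuntimeError(f"singular mass matrix (condition number {cond:.3g})")
        return np.linalg.solve(M, self.forces(q, v, t, controls))

    # ----------------------------------------------------------- integrator
    def _refresh_jacobians(self, q, v, t, controls):
        eps = 1e-7
        Q0 = self.forces(q, v, t, controls)
        jq = np.empty((N_Q, N_Q))
        jv = np.empty((N_Q, N_Q))
        for j in range(N_Q):
            dq = q.copy()
            dq[j] += eps
            jq[:, j] = (self.forces(dq, v, t, controls) - Q0) / eps
            dv = v.copy()
            dv[j] += eps
            jv[:, j] = (self.forces(q, dv, t, controls) - Q0) / eps
        self._jq, self._jv = jq, jv
        self._steps_since_jac = 0

    def step(self, q, v, t, controls=None, record=False):
        """One linearly-implicit theta step; returns (q_next, v_next, record)."""
        dt, th = self.dt, self.theta
        if self._steps_since_jac >= self.jac_every:
            self._refresh_jacobians(q, v, t, controls)
        if record:
            Q0, rec = self.forces(q, v, t, controls, record=True)
        else:
            Q0, rec = self.forces(q, v, t, controls), None
        M = self.mass_matrix(q)
        A = M - th * dt * self._jv - th * dt * dt * self._jq
        rhs = Q0 + th * dt * (self._jq @ v)
        a = np.linalg.solve(A, rhs)
        v_next = v + dt * a
        q_next = q + dt * v_next
        self._steps_since_jac += 1
        return q_next, v_next, rec

    # ----------------------------------------------------- marker kinematics
    def marker_displacements(self, q) -> dict:
        """Shell-minus-segment marker displacement per pair, segment frame."""
        theta = q[0]
        pin = self.off + q[1:4]
        out = {}
        for m in self.markers:
            phi = q[m["phi"]]
            if m["foot_side"]:
                px, py = _rot(theta, m["p"][0], m["p"][1])
                ths = theta
            else:
                px, py = m["p"][0], m["p"][1]
                ths = 0.0
            sx, sy = _rot(phi, m["p_rel"][0], m["p_rel"][1])
            dx_s = pin[0] + sx - px
            dy_s = pin[1] + sy - py
            dz = pin[2] + m["p_rel"][2] - m["p"][2]
            dex, dey = _rot(-ths, dx_s, dy_s)
            out[m["name"]] = np.array([dex, dey, dz])
        return out


# --------------------------------------------------------------- controller
class CMCController:
    """Weighted task-space static optimization of activations and reserves."""

    def __init__(self, engine: DynamicsEngine, tasks, reserve_penalty=RESERVE_PENALTY,
                 reserve_scale=RESERVE_SCALE):
        self.engine = engine
        self.tasks = list(tasks)
        self.task_idx = [IDX[t.coordinate] for t in self.tasks]
        self.reserve_scale = reserve_scale
        model = engine.model
        self.muscle_names = engine.muscle_names
        n_mus = len(self.muscle_names)
        n_res = len(self.tasks)
        self.n_controls = n_mus + n_res
        self.lower = np.r_[np.zeros(n_mus), np.full(n_res, -np.inf)]
        self.upper = np.r_[np.ones(n_mus), np.full(n_res, np.inf)]
        self.reg = np.r_[np.ones(n_mus), np.full(n_res, reserve_penalty)]
        self.tau_act = np.array([model.muscles[n].tau_act for n in self.muscle_names])
        self.tau_deact = np.array([model.muscles[n].tau_deact for n in self.muscle_names])

    def solve(self, state: State, t: float, dt: float | None = None):
        """Returns (controls dict, diagnostics dict).

        With ``dt`` given, the activation bounds are the range reachable
        from the current activations within one step under the first-order
        activation/deactivation dynamics (subset of [0, 1]); the reserves
        then knowingly cover what the muscles cannot reach in time.
        Without ``dt`` the bounds are the full [0, 1].
        """
        eng = self.engine
        q, v = state.q, state.qdot
        M = eng.mass_matrix(q)
        Q0 = eng.forces(q, v, t, controls=None)
        # rows of M^-1 for the tasked coordinates
        rhs = np.zeros((N_Q, len(self.tasks)))
        for k, i in enumerate(self.task_idx):
            rhs[i, k] = 1.0
        minv_rows = np.linalg.solve(M, rhs).T  # (n_tasks, N_Q)
        qdd0 = np.linalg.solve(M, Q0)

        b = np.array(
            [task.desired_acceleration(t, q[i], v[i]) - qdd0[i]
             for task, i in zip(self.tasks, self.task_idx)]
        )
        n_mus = len(self.muscle_names)
        A = np.zeros((len(self.tasks), self.n_controls))
        for j in range(n_mus):
            A[:, j] = minv_rows[:, 0] * eng.muscle_tau[j]
        for k, i in enumerate(self.task_idx):
            A[:, n_mus + k] = minv_rows[:, i] * self.reserve_scale

        lower, upper = self.lower.copy(), self.upper.copy()
        if dt is not None:
            n_mus_ = len(self.muscle_names)
            for j in range(n_mus_):
                a = state.activations.get(self.muscle_names[j], 0.0)
                lower[j] = max(0.0, a + dt * (0.0 - a) / self.tau_deact[j])
                upper[j] = min(1.0, a + dt * (1.0 - a) / self.tau_act[j])

        w = np.sqrt(np.array([task.weight for task in self.tasks]))
        u = _bounded_weighted_lsq(A * w[:, None], b * w, np.sqrt(self.reg), lower, upper)

        activations = {name: float(u[j]) for j, name in enumerate(self.muscle_names)}
        reserves = {
            task.coordinate: float(u[n_mus + k] * self.reserve_scale)
            for k, task in enumerate(self.tasks)
        }
        err = A @ u - b
        diag = {
            "task_errors": {task.coordinate: float(err[k]) for k, task in enumerate(self.tasks)},
            "saturated": [self.muscle_names[j] for j in range(n_mus) if u[j] >= 1.0 - 1e-12],
        }
        return {"activations": activations, "reserves": reserves}, diag

    def advance_activations(self, state: State, desired: dict, dt: float) -> dict:
        """First-order activation/deactivation dynamics toward the optimum.

        The excitation is the one-step inverse of the activation filter
        (lookahead compensation, as in computed muscle control), clipped to
        [0, 1]; the filter therefore reaches the optimized activation in one
        step unless the physiological rate limit binds.
        """
        out = {}
        for j, name in enumerate(self.muscle_names):
            a = state.activations.get(name, 0.0)
            target = min(max(desired[name], 0.0), 1.0)
            tau = self.tau_act[j] if target >= a else self.tau_deact[j]
            excitation = min(max(a + (target - a) * tau / dt, 0.0), 1.0)
            a_next = a + dt * (excitation - a) / tau
            out[name] = min(max(a_next, 0.0), 1.0)
        return out


def _bounded_weighted_lsq(A, b, sqrt_reg, lower, upper, max_iter=40):
    """min ||A u - b||^2 + ||diag(sqrt_reg) u||^2 with box bounds.

    Exact primal active-set iteration for this small strictly convex QP:
    solve the free subproblem, clamp the single worst bound violator,
    and release clamped variables whose KKT gradient points back into the
    feasible box.  Deterministic.
    """
    n = A.shape[1]
    H = A.T @ A + np.diag(sqrt_reg**2)
    g0 = A.T @ b
    free = np.ones(n, dtype=bool)
    u = np.clip(np.zeros(n), lower, upper)
    for _ in range(max_iter):
        idx = np.flatnonzero(free)
        fixed = np.flatnonzero(~free)
        if idx.size:
            rhs = g0[idx]
            if fixed.size:
                rhs = rhs - H[np.ix_(idx, fixed)] @ u[fixed]
            u[idx] = np.linalg.solve(H[np.ix_(idx, idx)], rhs)
        excess = np.where(
            free & (u < lower), lower - u, np.where(free & (u > upper), u - upper, 0.0)
        )
        if np.any(excess > 0):
            j = int(np.argmax(excess))
            u[j] = lower[j] if u[j] < lower[j] else upper[j]
            free[j] = False
            continue
        grad = H @ u - g0  # gradient of the half-objective
        released = False
        for j in fixed:
            at_lower = u[j] <= lower[j] + 1e-15
            if (at_lower and grad[j] < -1e-12) or (not at_lower and grad[j] > 1e-12):
                free[j] = True
                released = True
        if not released:
            break
    return np.clip(u, lower, upper)


# ------------------------------------------------------------- spec surface
def equations_of_motion(model: CoupledModel, state: State, externals=None,
                        base=None) -> np.ndarray:
    """Accelerations of the free coordinates under the given external loads."""
    engine = DynamicsEngine(model, base=base, loads=externals)
    return engine.accelerations(state.q, state.qdot, state.time)


def cmc_step(model: CoupledModel, state: State, tasks, dt: float,
             loads: ExternalLoads | None = None, base=None):
    """One controller + integration step; returns (controls, next_state).

    ``controls`` carries the optimized activations and reserve efforts plus
    task-error diagnostics; the step is flagged (never dropped) when a task
    is infeasible for the muscles alone and reserves absorb the deficit.
    The optimization uses the full activation bounds [0, 1]; the activation
    filter then rate-limits what is physically applied during the step.
    """
    engine = DynamicsEngine(model, base=base, loads=loads, dt=dt)
    controller = CMCController(engine, tasks)
    controls, diag = controller.solve(state, state.time)
    new_acts = controller.advance_activations(state, controls["activations"], dt)
    applied = {"activations": new_acts, "reserves": controls["reserves"]}
    q, v, _ = engine.step(state.q, state.qdot, state.time, applied)
    flags = state.flags
    if diag["saturated"] and any(abs(r) > 1e-06 for r in controls["reserves"].values()):
        flags = flags + ((state.time, "muscles saturated; reserves absorb task deficit"),)
    next_state = State(q, v, new_acts, state.time + dt, flags)
    controls = dict(controls, **diag)
    return controls, next_state


def linear_ramp(p0: float, p1: float, n_steps: int, step_dt: float):
    """Piecewise-linear knot interpolation from p0 to p1 over n_steps knots."""
    total = n_steps * step_dt

    def ref(t):
        if total <= 0 or t >= total:
            return p1
        if t <= 0:
            return p0
        return p0 + (p1 - p0) * (t / total)

    def rate(t):
        return (p1 - p0) / total if 0 <= t < total else 0.0

    return ref, rate


def gait_initial_pose(trial: GaitTrial, model: CoupledModel) -> dict:
    kin = TrialKinematics(trial, model)
    return {"ankle": float(kin.theta_ref(0.0)), "shank": float(kin.shank_angle(0.0))}


def initial_cmc(
    model: CoupledModel,
    default_pose: dict | None = None,
    gait_initial_pose: dict | None = None,
    n_steps: int = 10,
    step_dt: float = 0.02,
    settle_time: float = 0.3,
    dt: float = 1e-3,
    settle_tol: float = 1e-3,
) -> State:
    """Bootstrap ("initial CMC"): move from the standard pose to the gait
    start pose and let the device settle.

    The tasked joint angles are adjusted linearly from their standard values
    to the gait-initial values over ``n_steps`` knots; external gait forces
    (ground reaction, support) are excluded and the base floats on virtual
    supports.  The bootstrap always runs on the unweakened model so that
    every weakening level and misalignment starts from the same body pose.
    Returns the settled state (time reset to 0); an unsettled interface
    oscillation above tolerance is flagged on the returned state.
    """
    default_pose = default_pose or {"ankle": 0.0, "shank": 0.0}
    gait_initial_pose = gait_initial_pose or {"ankle": 0.0, "shank": 0.0}

    basic = replace(
        model,
        muscles={
            name: replace(m, weakening=1.0) for name, m in model.muscles.items()
        },
    )
    ramp_time = n_steps * step_dt
    base = _RampBase(gait_initial_pose.get("shank", 0.0), ramp_time)
    # shift the ramp origin if the standard shank pose is nonzero
    alpha0 = default_pose.get("shank", 0.0)
    if alpha0 != 0.0:
        tgt = gait_initial_pose.get("shank", 0.0)
        base = _RampBase(tgt - alpha0, ramp_time)
        shift = alpha0
        inner = base

        class _Shifted:
            def shank_angle(self, t):
                return shift + inner.shank_angle(t)

            shank_rate = staticmethod(inner.shank_rate)
            shank_acc = staticmethod(inner.shank_acc)
            ankle_acc_world = staticmethod(inner.ankle_acc_world)
            ankle_height = staticmethod(inner.ankle_height)

        base = _Shifted()

    ref, rate = linear_ramp(default_pose.get("ankle", 0.0),
                            gait_initial_pose.get("ankle", 0.0), n_steps, step_dt)
    task = TrackingTask("ankle_rz", ref, rate, weight=DEFAULT_TASK_WEIGHT)
    engine = DynamicsEngine(basic, base=base, loads=ExternalLoads(), dt=dt)
    controller = CMCController(engine, [task])

    state = State.neutral(basic)
    state.q[0] = default_pose.get("ankle", 0.0)
    t, t_end = 0.0, ramp_time + settle_time
    q, v, acts = state.q.copy(), state.qdot.copy(), dict(state.activations)
    n = int(round(t_end / dt))
    for _ in range(n):
        st = State(q, v, acts, t)
        controls, diag = controller.solve(st, t, dt)
        acts = controller.advance_activations(st, controls["activations"], dt)
        q, v, _ = engine.step(q, v, t, {"activations": acts, "reserves": controls["reserves"]})
        t += dt

    flags = ()
    if np.max(np.abs(v[1:])) > settle_tol:
        flags = ((t, "interface oscillation above tolerance at end of bootstrap"),)
    return State(q, v, acts, time=0.0, flags=flags)


def run_gait_cycle(
    model: CoupledModel,
    trial: GaitTrial,
    tasks=None,
    initial_state: State | None = None,
    dt: float = 1e-3,
    metadata: dict | None = None,
    theta: float = 0.6,
    jac_every: int = 10,
) -> TrialResult:
    """Simulate one full gait cycle of the coupled model.

    The knee (and hip) are prescribed through the base motion; the ankle is
    tasked with weight 10.  The support torque follows the trial's support
    profile and the recorded ground reaction acts at the moving center of
    pressure.  Returns the full trace record; on an integration failure the
    partial result carries a diagnostic flag at the failure time.
    """
    kin = TrialKinematics(trial, model)
    if tasks is None:
        tasks = [
            TrackingTask(
                "ankle_rz",
                kin.theta_ref,
                kin.theta_ref_rate,
                kin.theta_ref_acc,
                weight=DEFAULT_TASK_WEIGHT,
            )
        ]
    support = trial.support
    loads = ExternalLoads(
        support=(lambda t: support.at_phase(trial.phase_of(t))) if support is not None else None,
        grf=kin.grf,
    )
    engine = DynamicsEngine(model, base=kin, loads=loads, dt=dt, theta=theta, jac_every=jac_every)
    controller = CMCController(engine, tasks)

    if initial_state is None:
        initial_state = initial_cmc(
            model,
            gait_initial_pose={"ankle": float(kin.theta_ref(0.0)),
                               "shank": float(kin.shank_angle(0.0))},
            dt=dt,
        )

    n = int(round(trial.cycle_duration / dt))
    times = np.empty(n)
    qs = np.empty((n, N_Q))
    vs = np.empty((n, N_Q))
    acts_tr = {name: np.empty(n) for name in engine.muscle_names}
    wrench_tr = {e["name"]: np.empty((n, 6)) for e in engine.elements}
    marker_tr = {m["name"]: np.empty((n, 3)) for m in engine.markers}
    resid_tr = {t_.coordinate: np.empty(n) for t_ in tasks}
    resid_tr["base_fx"] = np.zeros(n)  # base kinematics prescribed exactly:
    resid_tr["base_fy"] = np.zeros(n)  # translational residuals vanish
    grf_tr = np.empty(n)
    sup_tr = np.empty(n)
    energy = {k: np.empty(n) for k in
              ("kinetic", "gravity_potential", "spring", "p_muscle", "p_support",
               "p_grf", "p_reserve", "p_damper")}
    flags = list(initial_state.flags)

    q, v, acts = initial_state.q.copy(), initial_state.qdot.copy(), dict(initial_state.activations)
    t = 0.0
    for i in range(n):
        try:
            st = State(q, v, acts, t)
            controls, diag = controller.solve(st, t, dt)
            acts = controller.advance_activations(st, controls["activations"], dt)
            applied = {"activations": acts, "reserves": controls["reserves"]}
            q_new, v_new, rec = engine.step(q, v, t, applied, record=True)
        except (RuntimeError, np.linalg.LinAlgError, ValueError) as exc:
            flags.append((t, f"integration failure: {exc}"))
            n = i
            break

        times[i] = t
        qs[i] = q
        vs[i] = v
        for name in acts:
            acts_tr[name][i] = acts[name]
        for name, wr in rec["elements"].items():
            wrench_tr[name][i] = wr
        for name, disp in engine.marker_displacements(q).items():
            marker_tr[name][i] = disp
        for task in tasks:
            resid_tr[task.coordinate][i] = controls["reserves"][task.coordinate]
        _, fv, _ = loads.grf_at(t)
        grf_tr[i] = fv
        sup_tr[i] = loads.support_at(t)
        M = engine.mass_matrix(q)
        energy["kinetic"][i] = 0.5 * v @ (M @ v)
        energy["gravity_potential"][i] = rec["gravity_potential"]
        energy["spring"][i] = rec["spring_energy"]
        for key in ("muscle", "support", "grf", "reserve", "damper"):
            energy[f"p_{key}"][i] = rec["power"][key]
        if diag["saturated"] and any(abs(r) > 1e-06 for r in controls["reserves"].values()):
            if not flags or flags[-1][1] != "muscles saturated; reserves absorb task deficit":
                flags.append((t, "muscles saturated; reserves absorb task deficit"))

        q, v = q_new, v_new
        t += dt

    sl = slice(0, n)
    meta = dict(metadata or {})
    meta.setdefault("speed", trial.speed)
    meta.setdefault("seed", trial.seed)
    meta.setdefault("dt", dt)
    meta.setdefault("cycle_duration", trial.cycle_duration)
    meta.setdefault("stance_fraction", trial.stance_fraction)
    return TrialResult(
        time=times[sl],
        phase=trial.phase_of(times[sl]),
        q=qs[sl],
        qdot=vs[sl],
        activations={k: a[sl] for k, a in acts_tr.items()},
        wrenches={k: w[sl] for k, w in wrench_tr.items()},
        marker_disp={k: m[sl] for k, m in marker_tr.items()},
        residuals={k: r[sl] for k, r in resid_tr.items()},
        grf_v=grf_tr[sl],
        support=sup_tr[sl],
        energy={k: e[sl] for k, e in energy.items()},
        flags=flags,
        metadata=meta,
    )
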