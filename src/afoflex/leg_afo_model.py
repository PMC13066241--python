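"""Coupled sagittal-plane human-leg + ankle-foot-orthosis multibody model.

Topology: the shank carries the ankle joint; the foot (with welded toes)
pins to the shank about the ankle flexion axis (z).  A massless-in-practice
auxiliary ("dummy") body attaches at the ankle center -- plus an optional
axis-misalignment offset -- through a joint that is free in all three
translations but locked in rotation.  The foot shell and the calf shell each
pin to the auxiliary body about z, so the device rotation axis passes
through the auxiliary body.  Four viscoelastic interface elements couple the
shells back to the body: two between foot and foot shell, two between shank
and calf shell.

Coordinate frame (used everywhere): x anterior, y vertical up, z the ankle
flexion axis (mediolateral), right-handed.  Dorsiflexion is a positive
rotation about z.  All quantities SI.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .interface_model import BushingParams, default_interface_params

__all__ = [
    "AUX_BODY_MASS",
    "FREE_COORDS",
    "MISALIGNMENT_DIRECTIONS",
    "MISALIGNMENT_MAGNITUDE",
    "WEAKENING_LEVELS",
    "Segment",
    "JointSpec",
    "MuscleGroup",
    "InterfaceElement",
    "MarkerPair",
    "CoupledModel",
    "build_model",
    "apply_weakening",
    "apply_misalignment",
    "marker_pairs",
    "marker_positions",
]

#: Mass of the virtual auxiliary body that carries the device rotation axis, kg.
AUX_BODY_MASS = 1e-05

#: Plantarflexor residual-strength fractions of the four patient variants.
#: Dorsiflexors are paralyzed (0%) in every variant.
WEAKENING_LEVELS = {"PF25": 0.25, "PF50": 0.50, "PF75": 0.75, "PF100": 1.00}

#: Signed unit axes of the device-axis shift relative to the ankle axis.
MISALIGNMENT_DIRECTIONS = {
    "zero": np.array([0.0, 0.0, 0.0]),
    "front": np.array([1.0, 0.0, 0.0]),
    "back": np.array([-1.0, 0.0, 0.0]),
    "up": np.array([0.0, 1.0, 0.0]),
    "down": np.array([0.0, -1.0, 0.0]),
    "inside": np.array([0.0, 0.0, -1.0]),
    "outside": np.array([0.0, 0.0, 1.0]),
}

#: Default shift magnitude, m (the literature maximum for AFO donning error).
MISALIGNMENT_MAGNITUDE = 0.02

#: Free generalized coordinates of the coupled model, in EOM order.
FREE_COORDS = ("ankle_rz", "aux_tx", "aux_ty", "aux_tz", "footshell_rz", "calfshell_rz")


@dataclass(frozen=True)
class Segment:
    """Rigid segment: mass properties and marker-anchor landmarks.

    ``com`` and landmark positions are expressed in the segment's own frame,
    whose origin is the segment's proximal joint center (the ankle for foot,
    shells and auxiliary body) and which coincides with the shank frame in
    the model's neutral initial state.
    """

    name: str
    mass: float
    inertia_z: float
    com: np.ndarray
    landmarks: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name != "aux" and self.mass <= 0:
            raise ValueError(f"segment {self.name!r}: mass must be > 0, got {self.mass}")
        object.__setattr__(self, "com", np.asarray(self.com, dtype=float))
        if not np.all(np.isfinite(self.com)):
            raise ValueError(f"segment {self.name!r}: non-finite COM")
        for key, val in self.landmarks.items():
            arr = np.asarray(val, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"segment {self.name!r}: non-finite landmark {key!r}")
            self.landmarks[key] = arr


@dataclass(frozen=True)
class JointSpec:
    name: str
    parent: str
    child: str
    free: tuple = ()
    locked: tuple = ()


@dataclass(frozen=True)
class MuscleGroup:
    """Lumped uniarticular ankle muscle group.

    Produces an ankle moment ``sign * a * weakening * f_max_iso * moment_arm``
    with activation a in [0, 1].  Plantarflexors act in the negative-z
    (plantarflexion) direction, dorsiflexors in positive z.
    """

    name: str
    f_max_iso: float
    moment_arm: float
    sign: int
    weakening: float = 1.0
    tau_act: float = 0.010
    tau_deact: float = 0.030

    def __post_init__(self):
        if not 0.0 <= self.weakening <= 1.0:
            raise ValueError(f"weakening factor must lie in [0, 1], got {self.weakening}")

    def max_moment(self) -> float:
        """Moment magnitude at full activation, Nm."""
        return self.weakening * self.f_max_iso * self.moment_arm

    def moment(self, activation: float) -> float:
        """Signed ankle moment at the given activation, Nm."""
        a = min(max(activation, 0.0), 1.0)
        return self.sign * a * self.max_moment()


@dataclass(frozen=True)
class InterfaceElement:
    """One bushing between a body segment and an orthosis shell.

    ``anchor_segment`` is fixed in the segment frame; ``anchor_shell_neutral``
    is the shell-side anchor position in the neutral initial state (shank
    frame).  Both coincide there, so the element is unloaded at assembly for
    every misalignment condition -- shifting the device axis changes the
    shells' lever arms about the pin, not the donned fit.
    """

    name: str
    site: str
    segment: str
    shell: str
    anchor_segment: np.ndarray
    anchor_shell_neutral: np.ndarray
    params: BushingParams

    def __post_init__(self):
        object.__setattr__(self, "anchor_segment", np.asarray(self.anchor_segment, dtype=float))
        object.__setattr__(
            self, "anchor_shell_neutral", np.asarray(self.anchor_shell_neutral, dtype=float)
        )


@dataclass(frozen=True)
class MarkerPair:
    """Coincident marker pair for relative-motion readout.

    The segment-side marker is fixed in the body segment, the shell-side
    marker in the shell, both at ``position_neutral`` (shank frame, neutral
    state), so the pair distance is zero in the initial state by
    construction.
    """

    name: str
    segment: str
    shell: str
    position_neutral: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "position_neutral", np.asarray(self.position_neutral, dtype=float)
        )


# ---------------------------------------------------------------------------
# Default anthropometry and device geometry (mid-size adult; config-exposed).
# Positions in the shank frame with origin at the ankle center, neutral pose.
# ---------------------------------------------------------------------------
DEFAULT_MODEL_CONFIG = {
    "body_mass": 75.0,  # kg, whole body; used for GRF scaling
    "thigh_length": 0.42,  # m
    "shank_length": 0.43,  # m
    "segments": {
        "foot": {
            "mass": 1.0,
            "inertia_z": 0.010,
            "com": [0.06, -0.05, 0.0],
            "landmarks": {},
        },
        "toes": {
            "mass": 0.2,
            "inertia_z": 0.0005,
            "com": [0.18, -0.06, 0.0],
            "landmarks": {"shell_origin": [0.16, -0.07, 0.0]},
        },
        "shank": {
            "mass": 3.5,
            "inertia_z": 0.050,
            "com": [0.0, 0.18, 0.0],
            "landmarks": {"shell_origin": [0.035, 0.27, 0.0]},
        },
        "foot_shell": {
            "mass": 0.15,
            "inertia_z": 0.0012,
            "com": [0.06, -0.07, 0.0],
            "landmarks": {},
        },
        "calf_shell": {
            "mass": 0.25,
            "inertia_z": 0.0030,
            "com": [-0.02, 0.18, 0.0],
            "landmarks": {},
        },
        "aux": {
            "mass": AUX_BODY_MASS,
            "inertia_z": 1e-09,
            "com": [0.0, 0.0, 0.0],
            "landmarks": {},
        },
    },
    # Strap/landmark anchor points of the four interface elements (neutral
    # shank-frame positions).  The exact shell geometry is config-exposed;
    # defaults are plausible for an off-the-shelf posterior-leaf AFO.
    "anchors": {
        "foot_instep": [0.08, 0.03, 0.0],
        "foot_heel": [-0.06, -0.05, 0.0],
        "tibia_strap": [0.035, 0.20, 0.0],
        "tibia_rim": [-0.035, 0.26, 0.0],
    },
    "interface": {
        "tibia": default_interface_params("tibia").as_dict(),
        "foot": default_interface_params("foot").as_dict(),
    },
    "muscles": {
        "plantarflexors": {"f_max_iso": 4000.0, "moment_arm": 0.05},
        "dorsiflexors": {"f_max_iso": 1500.0, "moment_arm": 0.04},
    },
}


@dataclass(frozen=True)
class CoupledModel:
    """Assembled leg + AFO model with soft-tissue interface elements."""

    segments: dict
    joints: tuple
    muscles: dict
    elements: tuple
    markers: tuple
    misalignment: np.ndarray
    body_mass: float
    thigh_length: float
    shank_length: float

    def __post_init__(self):
        object.__setattr__(self, "misalignment", np.asarray(self.misalignment, dtype=float))

    @property
    def free_coordinates(self) -> tuple:
        return FREE_COORDS

    def lumped_foot(self) -> tuple[float, np.ndarray, float]:
        """(mass, COM, inertia about z through COM) of the foot+toes assembly."""
        foot, toes = self.segments["foot"], self.segments["toes"]
        m = foot.mass + toes.mass
        com = (foot.mass * foot.com + toes.mass * toes.com) / m
        inertia = (
            foot.inertia_z
            + foot.mass * np.sum((foot.com[:2] - com[:2]) ** 2)
            + toes.inertia_z
            + toes.mass * np.sum((toes.com[:2] - com[:2]) ** 2)
        )
        return m, com, inertia

    def elements_at(self, site: str) -> tuple:
        return tuple(e for e in self.elements if e.site == site)


def _segment_from_config(name: str, cfg: dict) -> Segment:
    for fieldname in ("mass", "inertia_z", "com"):
        if fieldname not in cfg:
            raise ValueError(f"segment {name!r}: missing required field {fieldname!r}")
    return Segment(
        name=name,
        mass=float(cfg["mass"]),
        inertia_z=float(cfg["inertia_z"]),
        com=np.asarray(cfg["com"], dtype=float),
        landmarks={k: np.asarray(v, dtype=float) for k, v in cfg.get("landmarks", {}).items()},
    )


def build_model(config: dict | None = None) -> CoupledModel:
    """Assemble the coupled model from a (possibly partial) configuration.

    Missing entries fall back to :data:`DEFAULT_MODEL_CONFIG`.  The returned
    model has exactly two interface elements per region, the auxiliary body
    at the ankle center (zero misalignment), and both marker pairs
    coincident in the initial state.
    """
    cfg = copy.deepcopy(DEFAULT_MODEL_CONFIG)
    if config:
        _deep_update(cfg, config)

    segments = {
        name: _segment_from_config(name, seg_cfg) for name, seg_cfg in cfg["segments"].items()
    }
    required = {"foot", "toes", "shank", "foot_shell", "calf_shell", "aux"}
    missing = required - set(segments)
    if missing:
        raise ValueError(f"missing segment definitions: {sorted(missing)}")

    joints = (
        JointSpec("ankle", "shank", "foot", free=("rz",), locked=("tx", "ty", "tz", "rx", "ry")),
        JointSpec("mtp", "foot", "toes", free=(), locked=("tx", "ty", "tz", "rx", "ry", "rz")),
        JointSpec("aux_attachment", "shank", "aux", free=("tx", "ty", "tz"), locked=("rx", "ry", "rz")),
        JointSpec("footshell_pin", "aux", "foot_shell", free=("rz",), locked=("tx", "ty", "tz", "rx", "ry")),
        JointSpec("calfshell_pin", "aux", "calf_shell", free=("rz",), locked=("tx", "ty", "tz", "rx", "ry")),
    )

    muscles = {
        "plantarflexors": MuscleGroup(
            "plantarflexors",
            f_max_iso=float(cfg["muscles"]["plantarflexors"]["f_max_iso"]),
            moment_arm=float(cfg["muscles"]["plantarflexors"]["moment_arm"]),
            sign=-1,
        ),
        "dorsiflexors": MuscleGroup(
            "dorsiflexors",
            f_max_iso=float(cfg["muscles"]["dorsiflexors"]["f_max_iso"]),
            moment_arm=float(cfg["muscles"]["dorsiflexors"]["moment_arm"]),
            sign=+1,
        ),
    }

    params = {site: BushingParams.from_dict(cfg["interface"][site]) for site in ("tibia", "foot")}
    anchors = {k: np.asarray(v, dtype=float) for k, v in cfg["anchors"].items()}
    elements = (
        InterfaceElement("foot_instep", "foot", "foot", "foot_shell",
                         anchors["foot_instep"], anchors["foot_instep"], params["foot"]),
        InterfaceElement("foot_heel", "foot", "foot", "foot_shell",
                         anchors["foot_heel"], anchors["foot_heel"], params["foot"]),
        InterfaceElement("tibia_strap", "tibia", "shank", "calf_shell",
                         anchors["tibia_strap"], anchors["tibia_strap"], params["tibia"]),
        InterfaceElement("tibia_rim", "tibia", "shank", "calf_shell",
                         anchors["tibia_rim"], anchors["tibia_rim"], params["tibia"]),
    )

    markers = (
        MarkerPair("foot", "toes", "foot_shell", segments["toes"].landmarks["shell_origin"]),
        MarkerPair("shank", "shank", "calf_shell", segments["shank"].landmarks["shell_origin"]),
    )

    return CoupledModel(
        segments=segments,
        joints=joints,
        muscles=muscles,
        elements=elements,
        markers=markers,
        misalignment=np.zeros(3),
        body_mass=float(cfg["body_mass"]),
        thigh_length=float(cfg["thigh_length"]),
        shank_length=float(cfg["shank_length"]),
    )


def _deep_update(base: dict, override: dict) -> None:
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], val)
        else:
            base[key] = val


def apply_weakening(model: CoupledModel, level: str) -> CoupledModel:
    """Return a patient variant: plantarflexors at the level's residual
    strength, dorsiflexors paralyzed.  Pure; idempotent on the factors."""
    if level not in WEAKENING_LEVELS:
        raise ValueError(
            f"unknown weakening level {level!r}; valid levels: {', '.join(WEAKENING_LEVELS)}"
        )
    muscles = dict(model.muscles)
    muscles["plantarflexors"] = replace(muscles["plantarflexors"], weakening=WEAKENING_LEVELS[level])
    muscles["dorsiflexors"] = replace(muscles["dorsiflexors"], weakening=0.0)
    return replace(model, muscles=muscles)


def apply_misalignment(
    model: CoupledModel, direction: str, magnitude: float = MISALIGNMENT_MAGNITUDE
) -> CoupledModel:
    """Shift the auxiliary-body attachment (the device axis) off the ankle axis.

    Pure; only the misalignment offset changes -- interface parameters,
    muscles and mass properties are untouched.
    """
    if direction not in MISALIGNMENT_DIRECTIONS:
        raise ValueError(
            f"unknown misalignment direction {direction!r}; "
            f"valid: {', '.join(MISALIGNMENT_DIRECTIONS)}"
        )
    if magnitude < 0:
        raise ValueError(f"misalignment magnitude must be >= 0, got {magnitude}")
    return replace(model, misalignment=magnitude * MISALIGNMENT_DIRECTIONS[direction])


def marker_pairs(model: CoupledModel) -> list[tuple]:
    """The (body-marker, shell-marker) pairs used for relative-motion readout."""
    return [((m.segment, m.position_neutral), (m.shell, m.position_neutral)) for m in model.markers]


def _rotz_apply(angle: float, vec: np.ndarray) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([c * vec[0] - s * vec[1], s * vec[0] + c * vec[1], vec[2]])


def marker_positions(model: CoupledModel, q: np.ndarray | None = None) -> dict:
    """Shank-frame positions of both markers of each pair for a configuration.

    ``q`` follows :data:`FREE_COORDS`; None means the neutral initial state.
    Shell-side markers ride on their shell about the (possibly misaligned)
    device axis carried by the auxiliary body.
    """
    if q is None:
        q = np.zeros(len(FREE_COORDS))
    q = np.asarray(q, dtype=float)
    theta, ux, uy, uz, phi_f, phi_c = q
    off = model.misalignment
    pin = off + np.array([ux, uy, uz])
    shell_angle = {"foot_shell": phi_f, "calf_shell": phi_c}
    seg_angle = {"toes": theta, "foot": theta, "shank": 0.0}
    out = {}
    for m in model.markers:
        p_seg = _rotz_apply(seg_angle[m.segment], m.position_neutral)
        p_shell = pin + _rotz_apply(shell_angle[m.shell], m.position_neutral - off)
        out[m.name] = (p_seg, p_shell)
    return out
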