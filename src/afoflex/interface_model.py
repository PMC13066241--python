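"""Viscoelastic 6-DOF interface elements ("bushings") for the human-device boundary.

Biological soft tissue between a body segment and an orthosis shell is lumped
into per-axis spring-damper couplers: three translational and three rotational
axes, each with an independent stiffness and damping coefficient.  The element
penalizes the deviation of two attached frames with an equal-and-opposite
wrench, which is how compliant straps, skin, fat and muscle transmit device
loads in this model.

Units are strictly SI: stiffness N/m and Nm/rad, damping N/(m/s) and
Nm/(rad/s), displacements m and rad.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AXES",
    "DEFAULT_DAMPING",
    "INTERFACE_SITES",
    "BushingParams",
    "FramePose",
    "Wrench",
    "bushing_wrench",
    "default_interface_params",
    "interface_power",
    "interface_power_split",
]

AXES = ("x", "y", "z")

#: Single damping coefficient shared by every axis of every element,
#: in the axis's native unit (N/(m/s) translational, Nm/(rad/s) rotational).
DEFAULT_DAMPING = 5.0

#: Per-site translational (N/m) and rotational (Nm/rad) stiffness defaults.
#: The stiff directions (tibia y, foot x) are where straps and Velcro
#: fasteners fix the brace against displacement; the soft directions sit on
#: thick compressible tissue.
_SITE_STIFFNESS = {
    "tibia": {
        "k_trans": (100.0, 10_000.0, 100.0),
        "k_rot": (200.0, 500.0, 200.0),
    },
    "foot": {
        "k_trans": (10_000.0, 500.0, 500.0),
        "k_rot": (500.0, 200.0, 200.0),
    },
}

INTERFACE_SITES = tuple(_SITE_STIFFNESS)


def _as_axis_vector(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"{name} must have one entry per axis (x, y, z); got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        bad = AXES[int(np.flatnonzero(~np.isfinite(arr))[0])]
        raise ValueError(f"{name} is non-finite on axis {bad}")
    return arr


@dataclass(frozen=True)
class BushingParams:
    """Coefficients of one interface element.

    Attributes
    ----------
    k_trans : (3,) array
        Translational stiffness per axis, N/m.
    k_rot : (3,) array
        Rotational stiffness per axis, Nm/rad.
    c_trans : (3,) array
        Translational damping per axis, N/(m/s).
    c_rot : (3,) array
        Rotational damping per axis, Nm/(rad/s).
    """

    k_trans: np.ndarray
    k_rot: np.ndarray
    c_trans: np.ndarray = field(default_factory=lambda: np.full(3, DEFAULT_DAMPING))
    c_rot: np.ndarray = field(default_factory=lambda: np.full(3, DEFAULT_DAMPING))

    def __post_init__(self):
        for name in ("k_trans", "k_rot", "c_trans", "c_rot"):
            arr = _as_axis_vector(getattr(self, name), name)
            if np.any(arr < 0):
                bad = AXES[int(np.flatnonzero(arr < 0)[0])]
                raise ValueError(f"{name} must be non-negative; axis {bad} is {arr[arr < 0][0]!r}")
            object.__setattr__(self, name, arr)

    def as_dict(self) -> dict:
        """Serializable mapping, with mandatory unit declarations."""
        return {
            "k_trans": [float(v) for v in self.k_trans],
            "k_rot": [float(v) for v in self.k_rot],
            "c_trans": [float(v) for v in self.c_trans],
            "c_rot": [float(v) for v in self.c_rot],
            "units": {
                "k_trans": "N/m",
                "k_rot": "Nm/rad",
                "c_trans": "N/(m/s)",
                "c_rot": "Nm/(rad/s)",
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "BushingParams":
        expected_units = cls(np.zeros(3), np.zeros(3)).as_dict()["units"]
        units = data.get("units", expected_units)
        for key, unit in expected_units.items():
            if units.get(key, unit) != unit:
                raise ValueError(
                    f"unit mismatch for {key}: expected {unit!r}, got {units.get(key)!r}"
                )
        return cls(
            k_trans=np.asarray(data["k_trans"], dtype=float),
            k_rot=np.asarray(data["k_rot"], dtype=float),
            c_trans=np.asarray(data.get("c_trans", np.full(3, DEFAULT_DAMPING)), dtype=float),
            c_rot=np.asarray(data.get("c_rot", np.full(3, DEFAULT_DAMPING)), dtype=float),
        )


@dataclass(frozen=True)
class FramePose:
    """Small relative pose (or pose rate) of one frame with respect to another.

    ``rotation`` holds three ordered small-angle components about the fixed
    x, y, z axes; the per-axis spring law differences these components
    directly, which is exact to first order for the few-degree interface
    rotations the element is meant for.
    """

    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "position", _as_axis_vector(self.position, "position"))
        object.__setattr__(self, "rotation", _as_axis_vector(self.rotation, "rotation"))


@dataclass(frozen=True)
class Wrench:
    """Force (N) and moment (Nm) expressed in a named frame.

    The wrench applied to the second connected body is the negation of the
    one applied to the first (action-reaction).
    """

    force: np.ndarray
    moment: np.ndarray
    frame: str = "element"

    def __post_init__(self):
        object.__setattr__(self, "force", _as_axis_vector(self.force, "force"))
        object.__setattr__(self, "moment", _as_axis_vector(self.moment, "moment"))

    def __neg__(self) -> "Wrench":
        return Wrench(-self.force, -self.moment, self.frame)


def default_interface_params(site: str) -> BushingParams:
    """Default stiffness/damping set for one interface region.

    ``site`` is ``"tibia"`` (shank <-> calf shell) or ``"foot"``
    (foot <-> foot shell).  The same parameter set is shared by both
    elements of a region.
    """
    try:
        stiff = _SITE_STIFFNESS[site]
    except KeyError:
        raise ValueError(
            f"unknown interface site {site!r}; valid sites: {', '.join(INTERFACE_SITES)}"
        ) from None
    return BushingParams(
        k_trans=np.array(stiff["k_trans"]),
        k_rot=np.array(stiff["k_rot"]),
        c_trans=np.full(3, DEFAULT_DAMPING),
        c_rot=np.full(3, DEFAULT_DAMPING),
    )


def bushing_wrench(params: BushingParams, rel_pose: FramePose, rel_vel: FramePose) -> Wrench:
    """Restoring wrench of one element, applied to the displaced (child) body.

    Per axis i: force_i = -(k_trans_i * dx_i + c_trans_i * dxdot_i) and
    moment_i = -(k_rot_i * dtheta_i + c_rot_i * dthetadot_i), with the
    deviation measured child-relative-to-parent in the element's reference
    frame on the body-segment side.  The reaction on the parent segment is
    the negation.
    """
    force = -(params.k_trans * rel_pose.position + params.c_trans * rel_vel.position)
    moment = -(params.k_rot * rel_pose.rotation + params.c_rot * rel_vel.rotation)
    return Wrench(force=force, moment=moment)


def interface_power(wrench: Wrench, rel_vel: FramePose, frame: str = "element") -> float:
    """Instantaneous power absorbed by the element, W.

    Positive when the relative motion works against the restoring wrench
    (energy flows into spring storage and damper dissipation).
    """
    if wrench.frame != frame:
        raise ValueError(
            f"frame mismatch: wrench in {wrench.frame!r}, velocity given in {frame!r}"
        )
    return float(-(wrench.force @ rel_vel.position) - (wrench.moment @ rel_vel.rotation))


def interface_power_split(
    params: BushingParams, rel_pose: FramePose, rel_vel: FramePose
) -> tuple[float, float]:
    """(recoverable spring power, dissipated damper power), both W.

    The spring part is the time derivative of stored elastic energy and
    integrates to ~0 over a closed cycle; the damper part is
    sum c_i * v_i^2 >= 0 always (passivity).
    """
    spring = float(
        (params.k_trans * rel_pose.position) @ rel_vel.position
        + (params.k_rot * rel_pose.rotation) @ rel_vel.rotation
    )
    damper = float(
        params.c_trans @ rel_vel.position**2 + params.c_rot @ rel_vel.rotation**2
    )
    return spring, damper


def spring_energy(params: BushingParams, rel_pose: FramePose) -> float:
    """Elastic energy stored in the element, J."""
    return float(
        0.5 * (params.k_trans @ rel_pose.position**2)
        + 0.5 * (params.k_rot @ rel_pose.rotation**2)
    )
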