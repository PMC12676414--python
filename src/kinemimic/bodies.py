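"""Articulated-body representation, forward kinematics and synthetic keypoints.

A :class:`KinematicTree` is a rooted tree of rigid bodies connected by
hinge/slide joints, with marker sites (fixed local offsets standing in for
tracked keypoints), end effectors and actuator metadata. It is the package's
stand-in for a full physics body model: only kinematics is represented —
no inertia, contacts or muscle mechanics.

Conventions: right-handed, z-up, meters and radians; quaternions scalar-first
(see :mod:`kinemimic.quat`). Bodies are listed parent-first; at most one free
joint is allowed, and only at the root body.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from kinemimic import quat


@dataclass(frozen=True)
class Body:
    name: str
    parent: int  # -1 for the root
    offset: np.ndarray  # fixed local offset in the parent frame, meters

    def __post_init__(self):
        object.__setattr__(self, "offset", np.asarray(self.offset, dtype=float).reshape(3))


@dataclass(frozen=True)
class JointSpec:
    """A single degree of freedom (or the root's free joint).

    ``axis`` is a unit 3-vector in the frame of ``body`` (the body this joint
    articulates relative to its parent). ``range`` is a closed interval,
    radians for hinges and meters for slides; it is unused for the free joint.
    """

    name: str
    kind: str  # "hinge" | "slide" | "free"
    axis: np.ndarray
    range: tuple[float, float]
    body: int

    def __post_init__(self):
        if self.kind not in ("hinge", "slide", "free"):
            raise ValueError(f"unknown joint kind {self.kind!r}")
        axis = np.asarray(self.axis, dtype=float).reshape(3)
        n = np.linalg.norm(axis)
        if self.kind != "free":
            if abs(n - 1.0) > 1e-8:
                raise ValueError(f"joint {self.name!r}: axis must have unit norm, got {n}")
            lo, hi = self.range
            if lo > hi:
                raise ValueError(f"joint {self.name!r}: range lo > hi")
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "range", (float(self.range[0]), float(self.range[1])))


@dataclass(frozen=True)
class MarkerBinding:
    """Binding of a named keypoint to a fixed offset on one body."""

    keypoint_name: str
    body: int
    offset: np.ndarray  # meters, body frame

    def __post_init__(self):
        object.__setattr__(self, "offset", np.asarray(self.offset, dtype=float).reshape(3))


@dataclass(frozen=True)
class Actuator:
    label: str
    joint: str  # name of the actuated joint
    tau_max: float = 1.0  # torque/force gain at action = 1
    v_max: float = 4.0  # velocity limit, rad/s or m/s


@dataclass
class KinematicTree:
    bodies: list[Body]
    joints: list[JointSpec]
    sites: list[MarkerBinding] = field(default_factory=list)
    end_effectors: list[int] = field(default_factory=list)
    actuators: list[Actuator] = field(default_factory=list)
    name: str = "tree"

    def __post_init__(self):
        self.validate()

    # -- structure -----------------------------------------------------
    def validate(self) -> None:
        nb = len(self.bodies)
        if nb == 0:
            raise ValueError("tree has no bodies")
        if self.bodies[0].parent != -1:
            raise ValueError("first body must be the root (parent = -1)")
        for i, b in enumerate(self.bodies[1:], start=1):
            if not (0 <= b.parent < i):
                raise ValueError(f"body {b.name!r}: parent must precede it in the list")
        free = [j for j in self.joints if j.kind == "free"]
        if len(free) > 1:
            raise ValueError("at most one free joint allowed")
        if free and free[0].body != 0:
            raise ValueError("free joint only allowed at the root body")
        for j in self.joints:
            if not (0 <= j.body < nb):
                raise ValueError(f"joint {j.name!r}: body id out of range")
        names = [s.keypoint_name for s in self.sites]
        if len(set(names)) != len(names):
            raise ValueError("keypoint names must be unique")
        for s in self.sites:
            if not (0 <= s.body < nb):
                raise ValueError(f"site {s.keypoint_name!r}: body id out of range")
        for e in self.end_effectors:
            if not (0 <= e < nb):
                raise ValueError("end effector body id out of range")
        joint_names = {j.name for j in self.joints if j.kind != "free"}
        for a in self.actuators:
            if a.joint not in joint_names:
                raise ValueError(f"actuator {a.label!r}: unknown joint {a.joint!r}")

    @property
    def has_free_root(self) -> bool:
        return any(j.kind == "free" for j in self.joints)

    @property
    def dof_joints(self) -> list[JointSpec]:
        """Non-free joints, in tree order: the layout of ``Pose.q``."""
        return [j for j in self.joints if j.kind != "free"]

    @property
    def n_dof(self) -> int:
        return len(self.dof_joints)

    @property
    def joint_ranges(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([j.range[0] for j in self.dof_joints])
        hi = np.array([j.range[1] for j in self.dof_joints])
        return lo, hi

    @property
    def keypoint_names(self) -> list[str]:
        return [s.keypoint_name for s in self.sites]

    def descendants(self, body: int) -> np.ndarray:
        """Boolean mask over bodies: body itself and everything below it."""
        mask = np.zeros(len(self.bodies), dtype=bool)
        mask[body] = True
        for i, b in enumerate(self.bodies):
            if b.parent >= 0 and mask[b.parent]:
                mask[i] = True
        return mask

    def joint_v_max(self) -> np.ndarray:
        """Per-DoF velocity limit: max over the actuators driving each joint."""
        out = np.full(self.n_dof, 4.0)
        by_joint = {}
        for a in self.actuators:
            by_joint.setdefault(a.joint, []).append(a.v_max)
        for i, j in enumerate(self.dof_joints):
            if j.name in by_joint:
                out[i] = max(by_joint[j.name])
        return out

    def joint_tau_max(self) -> np.ndarray:
        out = np.full(self.n_dof, 1.0)
        by_joint = {}
        for a in self.actuators:
            by_joint.setdefault(a.joint, []).append(a.tau_max)
        for i, j in enumerate(self.dof_joints):
            if j.name in by_joint:
                out[i] = sum(by_joint[j.name])
        return out

    def identity_pose(self) -> "Pose":
        lo, hi = self.joint_ranges
        q = np.clip(np.zeros(self.n_dof), lo, hi)
        return Pose(np.zeros(3), np.array([1.0, 0.0, 0.0, 0.0]), q)


@dataclass
class Pose:
    """One body configuration: root frame plus the non-root joint vector."""

    root_pos: np.ndarray
    root_quat: np.ndarray
    q: np.ndarray

    def __post_init__(self):
        self.root_pos = np.asarray(self.root_pos, dtype=float).reshape(3)
        self.root_quat = np.asarray(self.root_quat, dtype=float).reshape(4)
        self.q = np.atleast_1d(np.asarray(self.q, dtype=float))

    def validate(self, tree: KinematicTree, atol: float = 1e-9) -> None:
        if self.q.shape != (tree.n_dof,):
            raise ValueError(f"pose has {self.q.size} joint values, tree has {tree.n_dof} DoF")
        if abs(np.linalg.norm(self.root_quat) - 1.0) > atol:
            raise ValueError("root quaternion is not unit norm")
        lo, hi = tree.joint_ranges
        if np.any(self.q < lo - atol) or np.any(self.q > hi + atol):
            raise ValueError("joint vector violates box ranges")

    def copy(self) -> "Pose":
        return Pose(self.root_pos.copy(), self.root_quat.copy(), self.q.copy())

    def qpos(self) -> np.ndarray:
        """Flat [root_pos(3), root_quat(4), q(n)] layout."""
        return np.concatenate([self.root_pos, self.root_quat, self.q])

    @staticmethod
    def from_qpos(arr: np.ndarray) -> "Pose":
        arr = np.asarray(arr, dtype=float)
        return Pose(arr[:3], quat.normalize(arr[3:7]), arr[7:])


@dataclass
class KeypointSeries:
    """Tracked 3D keypoints: frames x keypoints x 3 in meters."""

    values: np.ndarray
    rate: float  # Hz
    names: list[str]
    valid_mask: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != 3:
            raise ValueError("values must have shape (frames, keypoints, 3)")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if len(self.names) != self.values.shape[1]:
            raise ValueError("names must match the keypoint dimension")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.values.shape[:2], dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.values.shape[:2]:
                raise ValueError("valid_mask must have shape (frames, keypoints)")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass
class FrameSet:
    """World-frame result of forward kinematics for one pose."""

    body_rot: np.ndarray  # (B, 3, 3)
    body_pos: np.ndarray  # (B, 3)
    site_pos: np.ndarray  # (K, 3)
    ee_pos: np.ndarray  # (E, 3)
    joint_axis_world: np.ndarray  # (n_dof, 3)
    joint_anchor: np.ndarray  # (n_dof, 3) world origin of the joint's body


def forward_kinematics(
    tree: KinematicTree,
    pose: Pose,
    site_offsets: Sequence[MarkerBinding] | None = None,
) -> FrameSet:
    """Compose rigid transforms along the tree; place sites and end effectors.

    ``site_offsets`` optionally overrides the tree's marker bindings (used by
    STAC calibration, where offsets are free parameters).
    """
    pose.validate(tree)
    nb = len(tree.bodies)
    R = np.empty((nb, 3, 3))
    p = np.empty((nb, 3))

    # group non-free joints by body, preserving order
    joints_by_body: dict[int, list[tuple[int, JointSpec]]] = {}
    for di, j in enumerate(tree.dof_joints):
        joints_by_body.setdefault(j.body, []).append((di, j))

    axis_world = np.zeros((tree.n_dof, 3))
    anchor = np.zeros((tree.n_dof, 3))

    for i, b in enumerate(tree.bodies):
        if i == 0:
            Ri = quat.to_matrix(pose.root_quat)
            pi = pose.root_pos.copy()
        else:
            Ri = R[b.parent].copy()
            pi = p[b.parent] + R[b.parent] @ b.offset
        for di, j in joints_by_body.get(i, []):
            a_world = Ri @ j.axis
            axis_world[di] = a_world
            anchor[di] = pi
            if j.kind == "hinge":
                Ri = Ri @ quat.to_matrix(quat.from_axis_angle(j.axis, pose.q[di]))
            else:  # slide
                pi = pi + a_world * pose.q[di]
        R[i] = Ri
        p[i] = pi

    bindings = tree.sites if site_offsets is None else list(site_offsets)
    site_pos = np.array([p[s.body] + R[s.body] @ s.offset for s in bindings]).reshape(-1, 3)
    ee_pos = np.array([p[e] for e in tree.end_effectors]).reshape(-1, 3)
    return FrameSet(R, p, site_pos, ee_pos, axis_world, anchor)


# ----------------------------------------------------------------------
# fixtures


_MUSCLE_NAMES_4 = ("dorsal_left", "dorsal_right", "ventral_left", "ventral_right")


def make_chain_fixture(
    n_segments: int,
    segment_length: float = 0.04,
    actuators_per_joint: int = 1,
    drop_labels: Sequence[str] = (),
    joint_range: tuple[float, float] = (-1.0, 1.0),
) -> KinematicTree:
    """Serial chain with a free root: the worm-like centerline fixture.

    ``n_segments`` bodies along +x, hinge joints about z between consecutive
    segments (planar bending), one marker site per segment origin, and
    ``actuators_per_joint`` muscle-like labels per joint. Labels listed in
    ``drop_labels`` are removed (must exist).
    """
    if n_segments < 2:
        raise ValueError("need at least 2 segments")
    bodies = [Body("seg00", -1, np.zeros(3))]
    joints = [JointSpec("root", "free", np.zeros(3), (0.0, 0.0), 0)]
    sites = []
    actuators = []
    for i in range(1, n_segments):
        bodies.append(Body(f"seg{i:02d}", i - 1, np.array([segment_length, 0.0, 0.0])))
        jname = f"bend{i - 1:02d}"
        joints.append(JointSpec(jname, "hinge", np.array([0.0, 0.0, 1.0]), joint_range, i))
        if actuators_per_joint == 4:
            subnames = _MUSCLE_NAMES_4
        else:
            subnames = tuple(f"m{k}" for k in range(actuators_per_joint))
        for sn in subnames:
            actuators.append(Actuator(f"j{i - 1:02d}_{sn}", jname, tau_max=0.25, v_max=3.0))
    for i in range(n_segments):
        sites.append(MarkerBinding(f"pt{i:02d}", i, np.zeros(3)))
    # tail tip, so the most distal joint is observable from the markers
    sites.append(MarkerBinding("tip", n_segments - 1, np.array([segment_length, 0.0, 0.0])))

    labels = [a.label for a in actuators]
    for d in drop_labels:
        if d not in labels:
            raise ValueError(f"drop label {d!r} not present")
    actuators = [a for a in actuators if a.label not in set(drop_labels)]
    return KinematicTree(
        bodies, joints, sites, end_effectors=[0, n_segments - 1], actuators=actuators,
        name=f"chain{n_segments}",
    )


def make_worm_fixture() -> KinematicTree:
    """The nematode preset: 25 segments, 24 joints, 4 body-wall muscles per
    joint except the tail joint, which lacks its ventral-right muscle — 95
    muscle labels in total."""
    return make_chain_fixture(
        n_segments=25,
        segment_length=0.04,
        actuators_per_joint=4,
        drop_labels=("j23_ventral_right",),
    )


def make_quadruped_fixture() -> KinematicTree:
    """A toy quadruped: free-root torso, four 2-hinge legs with foot
    end-effector sites, and one head site. 8 actuated DoF."""
    torso_h = 0.2
    half_l, half_w = 0.10, 0.06
    upper, lower = 0.10, 0.10
    bodies = [Body("torso", -1, np.zeros(3))]
    joints = [JointSpec("root", "free", np.zeros(3), (0.0, 0.0), 0)]
    sites = [MarkerBinding("head", 0, np.array([0.13, 0.0, 0.04]))]
    end_effectors = []
    actuators = []
    legs = [("fl", half_l, half_w), ("fr", half_l, -half_w), ("hl", -half_l, half_w), ("hr", -half_l, -half_w)]
    for leg, lx, ly in legs:
        ui = len(bodies)
        bodies.append(Body(f"{leg}_upper", 0, np.array([lx, ly, 0.0])))
        joints.append(JointSpec(f"{leg}_hip", "hinge", np.array([0.0, 1.0, 0.0]), (-1.2, 1.2), ui))
        li = len(bodies)
        bodies.append(Body(f"{leg}_lower", ui, np.array([0.0, 0.0, -upper])))
        joints.append(JointSpec(f"{leg}_knee", "hinge", np.array([0.0, 1.0, 0.0]), (-1.5, 1.5), li))
        sites.append(MarkerBinding(f"{leg}_hip_marker", ui, np.array([0.02, np.sign(ly) * 0.02, 0.0])))
        sites.append(MarkerBinding(f"{leg}_knee", li, np.array([0.0, np.sign(ly) * 0.01, 0.0])))
        sites.append(MarkerBinding(f"{leg}_foot", li, np.array([0.0, 0.0, -lower])))
        end_effectors.append(li)
        actuators.append(Actuator(f"{leg}_hip_act", f"{leg}_hip", tau_max=1.0, v_max=6.0))
        actuators.append(Actuator(f"{leg}_knee_act", f"{leg}_knee", tau_max=1.0, v_max=6.0))
    sites.append(MarkerBinding("spine", 0, np.array([-0.1, 0.0, 0.03])))
    tree = KinematicTree(bodies, joints, sites, end_effectors, actuators, name="quadruped")
    # default stance: torso at a height that puts the feet on the ground plane
    tree.default_root_height = torso_h  # type: ignore[attr-defined]
    return tree


def make_pendulum_fixture(joint_range: tuple[float, float] = (-1.5, 1.5)) -> KinematicTree:
    """A welded-base single-hinge arm: the 1-DoF tracking toy.

    No free joint — the root body is fixed at the origin — so the action
    space is exactly one channel.
    """
    bodies = [Body("base", -1, np.zeros(3)), Body("arm", 0, np.array([0.0, 0.0, 0.1]))]
    joints = [JointSpec("swing", "hinge", np.array([0.0, 1.0, 0.0]), joint_range, 1)]
    sites = [MarkerBinding("tip", 1, np.array([0.1, 0.0, 0.0]))]
    actuators = [Actuator("swing_act", "swing", tau_max=1.0, v_max=4.0)]
    return KinematicTree(bodies, joints, sites, end_effectors=[1], actuators=actuators,
                         name="pendulum")


def synthetic_keypoints(
    tree: KinematicTree,
    trajectory: Sequence[Pose],
    offsets: Sequence[MarkerBinding] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    rate: float = 50.0,
) -> KeypointSeries:
    """Forward-kinematics keypoints plus isotropic Gaussian noise.

    Emulates pose-tracking input: the markers sit at ``offsets`` (defaulting
    to the tree's nominal bindings) on the moving body, observed with
    independent N(0, noise_sd^2) error per coordinate. Deterministic per seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    bindings = tree.sites if offsets is None else list(offsets)
    vals = np.stack(
        [forward_kinematics(tree, p, site_offsets=bindings).site_pos for p in trajectory]
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vals = vals + rng.normal(0.0, noise_sd, size=vals.shape)
    return KeypointSeries(vals, rate, [s.keypoint_name for s in bindings])
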