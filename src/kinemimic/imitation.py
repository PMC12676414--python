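"""Motion-imitation task environment over a kinematic integrator.

The environment drives a :class:`KinematicTree` along a reference clip
(typically a STAC trajectory): the agent observes its own proprioceptive
state plus egocentric differences to the next ``L`` reference frames, acts
in [-1, 1] per degree of freedom, and is rewarded by a weighted sum of
Gaussian kernels on pose error (root position, root orientation, joints,
end effectors). Episodes terminate early on falls or large tracking error.

Physics stand-in, stated loudly: actions integrate at the velocity level
(``q += a * v_max * dt`` with box clamping; the free root gets 6 analogous
channels) — there is no inertia, no contact force, no actuator dynamics.
Contacts reduce to end-effector height tests. Every observation, reward and
termination contract is exact; the dynamics are deliberately not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from kinemimic import quat
from kinemimic.bodies import KinematicTree, Pose, forward_kinematics


# ----------------------------------------------------------------------
# specs


@dataclass
class RewardSpec:
    """Weights and kernel scales of the composite imitation reward.

    Each term is exp(-d^2 / (2 sigma^2)) in its own error metric; the total
    is the weighted sum, so perfect tracking scores sum(weights).
    """

    lam_pos: float = 0.25
    lam_quat: float = 0.25
    lam_joint: float = 0.25
    lam_ee: float = 0.25
    sigma_pos: float = 0.1  # m
    sigma_quat: float = 0.3  # rad
    sigma_joint: float = 0.5  # rad, on the joint-vector L2
    sigma_ee: float = 0.05  # m, on the stacked effector L2

    def __post_init__(self):
        lams = (self.lam_pos, self.lam_quat, self.lam_joint, self.lam_ee)
        if any(l < 0 for l in lams) or not any(l > 0 for l in lams):
            raise ValueError("weights must be non-negative with at least one positive")
        if min(self.sigma_pos, self.sigma_quat, self.sigma_joint, self.sigma_ee) <= 0:
            raise ValueError("kernel scales must be positive")

    @property
    def total_weight(self) -> float:
        return self.lam_pos + self.lam_quat + self.lam_joint + self.lam_ee


@dataclass
class TerminationSpec:
    healthy_z: tuple[float, float] = (-0.5, 1.0)  # m, root height interval
    max_pos_err: float = 0.3  # m
    max_ori_err: float = 1.5  # rad
    max_joint_err: float = 5.0  # rad, L2 aggregate

    def __post_init__(self):
        if self.healthy_z[0] >= self.healthy_z[1]:
            raise ValueError("healthy_z interval is empty")
        if min(self.max_pos_err, self.max_ori_err, self.max_joint_err) <= 0:
            raise ValueError("thresholds must be positive")


# ----------------------------------------------------------------------
# Welford running normalization


@dataclass
class WelfordStats:
    """Streaming mean/variance per observation channel (Welford / Chan).

    ``merge`` implements the parallel (Chan) combination, so merging two
    stat sets equals the statistics of the concatenated stream.
    """

    count: float
    mean: np.ndarray
    m2: np.ndarray

    @staticmethod
    def zeros(dim: int) -> "WelfordStats":
        return WelfordStats(0.0, np.zeros(dim), np.zeros(dim))

    def update(self, batch: np.ndarray) -> None:
        batch = np.atleast_2d(np.asarray(batch, dtype=float))
        for x in batch:
            self.count += 1.0
            delta = x - self.mean
            self.mean = self.mean + delta / self.count
            self.m2 = self.m2 + delta * (x - self.mean)

    def merge(self, other: "WelfordStats") -> "WelfordStats":
        n = self.count + other.count
        if n == 0:
            return WelfordStats.zeros(self.mean.size)
        delta = other.mean - self.mean
        mean = self.mean + delta * (other.count / n)
        m2 = self.m2 + other.m2 + delta ** 2 * (self.count * other.count / n)
        return WelfordStats(n, mean, m2)

    @property
    def variance(self) -> np.ndarray:
        if self.count < 1:
            return np.ones_like(self.mean)
        return self.m2 / self.count

    def normalize(self, obs: np.ndarray) -> np.ndarray:
        """(o - mean) / std with the deviation floored at 1e-6."""
        sd = np.sqrt(np.maximum(self.variance, 0.0))
        return (obs - self.mean) / np.maximum(sd, 1e-6)


def welford_update(stats: WelfordStats, batch: np.ndarray) -> WelfordStats:
    stats.update(batch)
    return stats


def normalize(obs: np.ndarray, stats: WelfordStats) -> np.ndarray:
    return stats.normalize(obs)


# ----------------------------------------------------------------------
# frames and differences


def egocentric(vec: np.ndarray, root: Pose) -> np.ndarray:
    """Express a world vector in the agent's heading (yaw-only) frame.

    The yaw-only frame keeps the gravity direction informative in the
    observation while removing heading dependence.
    """
    Rz = quat.to_matrix(quat.yaw_quat(root.root_quat))
    return Rz.T @ np.asarray(vec, dtype=float)


def quat_difference(q_agent: np.ndarray, q_ref: np.ndarray) -> np.ndarray:
    """Rotation vector of the relative rotation agent^-1 * ref, shortest arc."""
    return quat.to_rotvec(quat.mul(quat.conj(q_agent), q_ref))


# ----------------------------------------------------------------------
# reference clips


@dataclass
class ReferenceClip:
    """A reference motion: poses plus velocities at a fixed frame rate."""

    qpos: np.ndarray  # (T, 7 + n)
    qvel: np.ndarray  # (T, 6 + n)
    rate: float
    name: str = "clip"

    def __post_init__(self):
        self.qpos = np.asarray(self.qpos, dtype=float)
        self.qvel = np.asarray(self.qvel, dtype=float)
        self._body_pos: np.ndarray | None = None
        self._pose_cache: dict[int, Pose] = {}

    @property
    def n_frames(self) -> int:
        return self.qpos.shape[0]

    def pose(self, t: int) -> Pose:
        t = min(t, self.n_frames - 1)
        if t not in self._pose_cache:
            self._pose_cache[t] = Pose.from_qpos(self.qpos[t])
        return self._pose_cache[t]

    def body_positions(self, tree: KinematicTree) -> np.ndarray:
        if self._body_pos is None:
            self._body_pos = np.stack(
                [forward_kinematics(tree, self.pose(t)).body_pos for t in range(self.n_frames)]
            )
        return self._body_pos


# ----------------------------------------------------------------------
# state, observations


@dataclass
class EnvState:
    pose: Pose
    vel: np.ndarray  # (6 + n) velocity estimate from the last step
    clip_id: int
    cursor: int
    steps: int = 0
    done: bool = False
    reason: str = ""
    last_action: np.ndarray | None = None
    last_torque: np.ndarray | None = None


@dataclass
class ProprioObs:
    theta: np.ndarray  # joint angles
    omega: np.ndarray  # joint angular velocities
    tau: np.ndarray  # applied torques
    root_height: float
    up_direction: np.ndarray  # world z expressed in the agent frame, unit
    ee_egocentric: np.ndarray  # (E, 3)

    def flat(self) -> np.ndarray:
        return np.concatenate(
            [self.theta, self.omega, self.tau, [self.root_height], self.up_direction,
             self.ee_egocentric.reshape(-1)]
        )


@dataclass
class RefObs:
    """Egocentric look-ahead differences to the next L reference frames."""

    d_root: np.ndarray  # (L, 3)
    d_quat: np.ndarray  # (L, 3) rotation vectors
    d_joint: np.ndarray  # (L, n)
    d_body: np.ndarray  # (L, B, 3)

    def flat(self) -> np.ndarray:
        return np.concatenate(
            [self.d_root.reshape(-1), self.d_quat.reshape(-1), self.d_joint.reshape(-1),
             self.d_body.reshape(-1)]
        )


def build_observation(
    tree: KinematicTree, state: EnvState, clip: ReferenceClip, lookahead: int = 5
) -> tuple[ProprioObs, RefObs]:
    """Assemble proprioceptive and reference observations.

    Reference differences are computed against frames cursor+1 ... cursor+L,
    holding the final frame at the clip end. All positional differences are
    rotated to the agent's heading frame.
    """
    if lookahead < 1:
        raise ValueError("lookahead must be >= 1")
    n = tree.n_dof
    fr = forward_kinematics(tree, state.pose)
    R_full = quat.to_matrix(state.pose.root_quat)
    # heading frame applied as a row-vector product: v_ego = Rz^T v = v @ Rz
    Rz = quat.to_matrix(quat.yaw_quat(state.pose.root_quat))
    tau = state.last_torque if state.last_torque is not None else np.zeros(n)
    proprio = ProprioObs(
        theta=state.pose.q.copy(),
        omega=state.vel[6:].copy(),
        tau=np.asarray(tau, dtype=float),
        root_height=float(state.pose.root_pos[2]),
        up_direction=R_full.T @ np.array([0.0, 0.0, 1.0]),
        ee_egocentric=(fr.ee_pos - state.pose.root_pos) @ Rz
        if len(tree.end_effectors) else np.zeros((0, 3)),
    )
    body_pos = clip.body_positions(tree)
    agent_bodies = fr.body_pos
    d_root, d_quat, d_joint, d_body = [], [], [], []
    for i in range(1, lookahead + 1):
        t = min(state.cursor + i, clip.n_frames - 1)
        ref = clip.pose(t)
        d_root.append((ref.root_pos - state.pose.root_pos) @ Rz)
        d_quat.append(quat_difference(state.pose.root_quat, ref.root_quat))
        d_joint.append(ref.q - state.pose.q)
        d_body.append((body_pos[t] - agent_bodies) @ Rz)
    return proprio, RefObs(np.stack(d_root), np.stack(d_quat), np.stack(d_joint), np.stack(d_body))


# ----------------------------------------------------------------------
# reward and termination


def imitation_reward(
    tree: KinematicTree, pose: Pose, ref: Pose, spec: RewardSpec
) -> tuple[float, dict[str, float]]:
    """Composite Gaussian-kernel imitation reward and its four components.

    r = sum_i lam_i exp(-d_i^2 / (2 sigma_i^2)) over root position (Euclidean),
    root orientation (geodesic angle), joint vector (L2) and stacked
    end-effector positions (L2). Every component lies in [0, 1].
    """
    d_pos = float(np.linalg.norm(pose.root_pos - ref.root_pos))
    d_quat = quat.geodesic_angle(pose.root_quat, ref.root_quat)
    d_joint = float(np.linalg.norm(pose.q - ref.q))
    if len(tree.end_effectors) and spec.lam_ee > 0:
        ee_a = forward_kinematics(tree, pose).ee_pos
        ee_r = forward_kinematics(tree, ref).ee_pos
        d_ee = float(np.linalg.norm((ee_a - ee_r).reshape(-1)))
    else:
        d_ee = 0.0
    comps = {
        "pos": float(np.exp(-0.5 * (d_pos / spec.sigma_pos) ** 2)),
        "quat": float(np.exp(-0.5 * (d_quat / spec.sigma_quat) ** 2)),
        "joint": float(np.exp(-0.5 * (d_joint / spec.sigma_joint) ** 2)),
        "ee": float(np.exp(-0.5 * (d_ee / spec.sigma_ee) ** 2)),
    }
    total = (
        spec.lam_pos * comps["pos"]
        + spec.lam_quat * comps["quat"]
        + spec.lam_joint * comps["joint"]
        + spec.lam_ee * comps["ee"]
    )
    return float(total), comps


def check_termination(
    state: EnvState, ref: Pose, spec: TerminationSpec, clip_len: int
) -> tuple[bool, str]:
    """Early-termination test: fall, tracking divergence, or clip end."""
    z = state.pose.root_pos[2]
    if not (spec.healthy_z[0] <= z <= spec.healthy_z[1]):
        return True, "fall"
    if np.linalg.norm(state.pose.root_pos - ref.root_pos) > spec.max_pos_err:
        return True, "position_error"
    if quat.geodesic_angle(state.pose.root_quat, ref.root_quat) > spec.max_ori_err:
        return True, "orientation_error"
    if np.linalg.norm(state.pose.q - ref.q) > spec.max_joint_err:
        return True, "joint_error"
    if state.cursor >= clip_len - 1:
        return True, "clip_end"
    return False, ""


# ----------------------------------------------------------------------
# the environment


class ImitationEnv:
    """Reference-tracking environment with a velocity-level integrator.

    Action layout: 6 root channels (world-frame translation, rotation-vector
    rotation) followed by one channel per joint, all in [-1, 1]; a welded
    root drops the 6 root channels. The per-channel velocity limits come from
    the tree's actuators (joints) and ``root_v_max`` (root).
    """

    def __init__(
        self,
        tree: KinematicTree,
        clips: Sequence[ReferenceClip],
        reward_spec: RewardSpec | None = None,
        termination_spec: TerminationSpec | None = None,
        lookahead: int = 5,
        n_init: int = 10,
        reset_noise_sd: float = 0.01,
        root_v_max: tuple[float, float] = (1.0, 6.0),  # m/s, rad/s
    ):
        if not clips:
            raise ValueError("clip library is empty")
        self.tree = tree
        self.clips = list(clips)
        self.reward_spec = reward_spec or RewardSpec()
        self.termination_spec = termination_spec or TerminationSpec()
        self.lookahead = lookahead
        self.n_init = n_init
        self.reset_noise_sd = reset_noise_sd
        self.root_v_max = root_v_max
        self.v_max = tree.joint_v_max()
        self.tau_max = tree.joint_tau_max()
        self.dt = 1.0 / clips[0].rate

    @property
    def action_dim(self) -> int:
        return (6 if self.tree.has_free_root else 0) + self.tree.n_dof

    def obs_dims(self) -> tuple[int, int]:
        state = self.reset(np.random.default_rng(0))
        p, r = build_observation(self.tree, state, self.clips[state.clip_id], self.lookahead)
        return p.flat().size, r.flat().size

    def reset(self, rng: np.random.Generator) -> EnvState:
        return reset_episode(
            self.tree, self.clips, rng, n_init=self.n_init, noise_sd=self.reset_noise_sd
        )

    def step(self, state: EnvState, action: np.ndarray) -> tuple[EnvState, float, dict[str, float]]:
        """Advance one control step; returns (state', reward, components).

        Reward and termination are evaluated against the new cursor's
        reference frame.
        """
        action = np.asarray(action, dtype=float)
        if not np.all(np.isfinite(action)):
            raise ValueError("non-finite action")
        if action.shape != (self.action_dim,):
            raise ValueError(f"action must have shape ({self.action_dim},)")
        action = np.clip(action, -1.0, 1.0)
        if state.done:
            raise RuntimeError("stepping a finished episode; reset first")
        tree, dt = self.tree, self.dt
        lo, hi = tree.joint_ranges
        pose = state.pose.copy()
        free = tree.has_free_root
        a_q = action[6:] if free else action
        vel = np.zeros(6 + tree.n_dof)
        if free:
            dp = action[:3] * self.root_v_max[0] * dt
            drot = action[3:6] * self.root_v_max[1] * dt
            pose.root_pos = pose.root_pos + dp
            pose.root_quat = quat.canonicalize(quat.mul(quat.from_rotvec(drot), pose.root_quat))
            vel[:3] = dp / dt
            vel[3:6] = drot / dt
        q_new = np.clip(pose.q + a_q * self.v_max * dt, lo, hi)
        vel[6:] = (q_new - pose.q) / dt
        pose.q = q_new
        clip = self.clips[state.clip_id]
        new = EnvState(
            pose=pose,
            vel=vel,
            clip_id=state.clip_id,
            cursor=state.cursor + 1,
            steps=state.steps + 1,
            last_action=action.copy(),
            last_torque=a_q * self.tau_max,
        )
        ref = clip.pose(new.cursor)
        reward, comps = imitation_reward(tree, new.pose, ref, self.reward_spec)
        new.done, new.reason = check_termination(new, ref, self.termination_spec, clip.n_frames)
        return new, reward, comps

    def oracle_action(self, state: EnvState) -> np.ndarray:
        """Feed-forward controller: the clipped reference delta per channel.

        With a slow enough clip this tracks it to integrator-clipping error;
        used as the performance yardstick for learned policies.
        """
        clip = self.clips[state.clip_id]
        ref = clip.pose(min(state.cursor + 1, clip.n_frames - 1))
        dt = self.dt
        parts = []
        if self.tree.has_free_root:
            parts.append((ref.root_pos - state.pose.root_pos) / (self.root_v_max[0] * dt))
            drot = quat.to_rotvec(quat.mul(ref.root_quat, quat.conj(state.pose.root_quat)))
            parts.append(drot / (self.root_v_max[1] * dt))
        parts.append((ref.q - state.pose.q) / (self.v_max * dt))
        return np.clip(np.concatenate(parts), -1.0, 1.0)


def reset_episode(
    tree: KinematicTree,
    clips: Sequence[ReferenceClip],
    rng: np.random.Generator,
    n_init: int = 10,
    noise_sd: float = 0.01,
) -> EnvState:
    """Uniform clip and start-frame choice with small pose/velocity noise.

    The start frame is uniform over the first ``n_init`` frames; Gaussian
    noise of scale ``noise_sd`` is added to the pose (positions, joint
    angles, a root rotation-vector perturbation) and velocity to avoid
    overfitting exact initial conditions.
    """
    if not clips:
        raise ValueError("clip library is empty")
    cid = int(rng.integers(0, len(clips)))
    clip = clips[cid]
    start = int(rng.integers(0, min(max(n_init, 1), clip.n_frames)))
    pose = clip.pose(start)
    vel = clip.qvel[min(start, clip.n_frames - 1)].copy()
    if noise_sd > 0:
        lo, hi = tree.joint_ranges
        pose.root_pos = pose.root_pos + rng.normal(0.0, noise_sd, 3)
        pose.root_quat = quat.canonicalize(
            quat.mul(quat.from_rotvec(rng.normal(0.0, noise_sd, 3)), pose.root_quat)
        )
        pose.q = np.clip(pose.q + rng.normal(0.0, noise_sd, pose.q.shape), lo, hi)
        vel = vel + rng.normal(0.0, noise_sd, vel.shape)
    return EnvState(pose=pose, vel=vel, clip_id=cid, cursor=start)


def survival_curve(
    policy: Callable[[EnvState, ImitationEnv], np.ndarray],
    env: ImitationEnv,
    n_episodes: int,
    horizon: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Fraction of episodes not yet terminated at each step of the horizon.

    An episode counts as terminated from its first early termination onward
    (clip exhaustion realigns the cursor to a fresh reset and does not count
    against survival). Monotone non-increasing by construction.
    """
    if n_episodes < 1:
        raise ValueError("need at least one episode")
    alive = np.zeros((n_episodes, horizon), dtype=bool)
    for ep in range(n_episodes):
        state = env.reset(rng)
        ok = True
        for t in range(horizon):
            if ok and state.done:
                if state.reason == "clip_end":
                    state = env.reset(rng)
                else:
                    ok = False
            alive[ep, t] = ok
            if ok:
                state, _, _ = env.step(state, policy(state, env))
    return alive.mean(axis=0)
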