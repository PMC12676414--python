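"""Procedural bowl-escape task: terrain, observations, reward, termination.

The arena is an N x N heightfield on [-h, h]^2 built from a radially
symmetric Gaussian depression (the bowl) plus tileable 2D Perlin noise,
blended by a smoothstep radial gate so the launch zone at the center stays
noise-free, then normalized to [0, 1] and scaled by a vertical factor v.
The agent starts near the center and is rewarded for reaching the rim
(radius-to-rim shaping x uprightness) while moving near a target speed
(triangular tolerance peaked at v*). The episode fails when the torso drops
to within a margin of the terrain under it.

All fields are deterministic per seed and regenerate bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from kinemimic import quat
from kinemimic.bodies import KinematicTree, Pose, forward_kinematics


@dataclass
class HeightfieldSpec:
    n: int = 128  # grid size
    half_width: float = 2.0  # h, meters
    v_scale: float = 0.2  # vertical scale, meters

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("grid size must be >= 2")
        if self.half_width <= 0 or self.v_scale <= 0:
            raise ValueError("world scales must be positive")

    @property
    def spacing(self) -> float:
        """Grid spacing in world units, 2h / (N - 1)."""
        return 2.0 * self.half_width / (self.n - 1)


@dataclass
class BowlParams:
    sigma: float = 1.25  # bowl width on the normalized square
    depth: float = -10.0  # A < 0
    noise_amplitude: float = 0.5  # lambda in [0, 1]
    periods_x: int = 8
    periods_y: int = 8
    r_in: float | None = None  # gate radii in grid units; defaults 0.05 N / 0.25 N
    r_out: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.depth >= 0:
            raise ValueError("bowl depth A must be negative")
        if not (0.0 <= self.noise_amplitude <= 1.0):
            raise ValueError("noise amplitude must lie in [0, 1]")

    def gate_radii(self, n: int) -> tuple[float, float]:
        r_in = 0.05 * n if self.r_in is None else self.r_in
        r_out = 0.25 * n if self.r_out is None else self.r_out
        if not (0 <= r_in < r_out):
            raise ValueError("need 0 <= r_in < r_out")
        return r_in, r_out


@dataclass
class Heightfield:
    heights: np.ndarray  # (N, N) in [0, 1], min exactly 0 and max exactly 1
    spec: HeightfieldSpec

    def __post_init__(self):
        H = np.asarray(self.heights, dtype=float)
        if not np.all(np.isfinite(H)):
            raise ValueError("heightfield contains non-finite values")
        self.heights = H


@dataclass
class EscapeRewardConfig:
    tilt_deg: float = 0.0  # allowable tilt theta
    target_speed: float = 0.75  # v*, m/s
    fail_margin: float = 0.03  # epsilon, m
    horizon: int = 1500  # control steps


# ----------------------------------------------------------------------
# grid mapping


def world_to_grid(x: float, y: float, spec: HeightfieldSpec) -> tuple[int, int]:
    """Map world (x, y) in [-h, h]^2 to grid indices (i, j).

    j indexes the x direction, i the y direction (texture convention).
    Out-of-bounds queries clamp to the border with a warning-level contract
    documented here rather than raised.
    """
    h, n = spec.half_width, spec.n
    u = (x + h) / (2 * h)
    w = (y + h) / (2 * h)
    j = int(np.clip(np.floor(u * (n - 1)), 0, n - 1))
    i = int(np.clip(np.floor(w * (n - 1)), 0, n - 1))
    return i, j


def ground_height(field: Heightfield, x: float, y: float) -> float:
    """World ground height v * H[i, j] at the cell under (x, y)."""
    i, j = world_to_grid(x, y, field.spec)
    return field.spec.v_scale * float(field.heights[i, j])


# ----------------------------------------------------------------------
# terrain construction


def gaussian_bowl(sigma: float, depth: float, n: int) -> np.ndarray:
    """Radially symmetric depression A exp(-(xi^2 + eta^2) / (2 sigma^2))
    sampled on the normalized square [-1, 1]^2."""
    if sigma <= 0 or depth >= 0:
        raise ValueError("need sigma > 0 and depth < 0")
    c = np.linspace(-1.0, 1.0, n)
    xi, eta = np.meshgrid(c, c, indexing="xy")
    return depth * np.exp(-(xi ** 2 + eta ** 2) / (2.0 * sigma ** 2))


def _fade(s: np.ndarray) -> np.ndarray:
    """Quintic fade 6 s^5 - 15 s^4 + 10 s^3 (zero value/slope at 0, one at 1)."""
    return s * s * s * (s * (6.0 * s - 15.0) + 10.0)


def perlin_tileable(
    periods_x: int, periods_y: int, n: int, seed: int = 0, rescale: bool = False
) -> np.ndarray:
    """Tileable 2D Perlin noise sampled at n x n points of [0, 1)^2.

    Unit gradients sit on an (Rx x Ry) lattice with wrap-around indexing, so
    the field is periodic with Rx / Ry periods across the domain; corner dot
    products are blended with the quintic fade. The raw field has zero value
    at every lattice node and approximately zero mean; ``rescale`` maps it
    affinely onto [0, 1].
    """
    if periods_x < 1 or periods_y < 1:
        raise ValueError("periods must be >= 1")
    rng = np.random.default_rng(seed)
    angles = rng.uniform(0.0, 2.0 * np.pi, size=(periods_x, periods_y))
    grad = np.stack([np.cos(angles), np.sin(angles)], axis=-1)  # unit gradients

    # sample on [0, 1) so the first/last rows are one grid step apart (the
    # wrapped continuation), which is what makes tiles seamless
    u = np.arange(n) / n * periods_x
    v = np.arange(n) / n * periods_y
    uu, vv = np.meshgrid(u, v, indexing="xy")
    p = np.floor(uu).astype(int)
    q = np.floor(vv).astype(int)
    tx = uu - p
    ty = vv - q

    def dot(dp: int, dq: int, ox: np.ndarray, oy: np.ndarray) -> np.ndarray:
        g = grad[(p + dp) % periods_x, (q + dq) % periods_y]
        return g[..., 0] * ox + g[..., 1] * oy

    n00 = dot(0, 0, tx, ty)
    n10 = dot(1, 0, tx - 1.0, ty)
    n01 = dot(0, 1, tx, ty - 1.0)
    n11 = dot(1, 1, tx - 1.0, ty - 1.0)
    fx, fy = _fade(tx), _fade(ty)
    n0 = (1.0 - fx) * n00 + fx * n10
    n1 = (1.0 - fx) * n01 + fx * n11
    out = (1.0 - fy) * n0 + fy * n1
    if rescale:
        lo, hi = out.min(), out.max()
        if hi - lo < 1e-15:
            raise ValueError("degenerate noise field (constant)")
        out = (out - lo) / (hi - lo)
    return out


def smoothstep(s: np.ndarray) -> np.ndarray:
    s = np.clip(s, 0.0, 1.0)
    return s * s * (3.0 - 2.0 * s)


def radial_gate(n: int, r_in: float, r_out: float) -> np.ndarray:
    """Smooth radial weight: 0 inside r_in, 1 outside r_out (grid units)."""
    if not r_in < r_out:
        raise ValueError("need r_in < r_out")
    c = (n - 1) / 2.0
    idx = np.arange(n)
    jj, ii = np.meshgrid(idx, idx, indexing="xy")
    r = np.sqrt((ii - c) ** 2 + (jj - c) ** 2)
    return smoothstep((r - r_in) / (r_out - r_in))


def compose_heightfield(spec: HeightfieldSpec, params: BowlParams) -> Heightfield:
    """Bowl + gated noise, normalized so min = 0 and max = 1 exactly.

    H0 = (1 - w) * B + w * (B + lambda * P~); H = (H0 - min) / (max - min).
    Inside the inner gate radius the raw height equals the bowl exactly, so
    the launch zone differs from the pure bowl only through the global
    normalization.
    """
    n = spec.n
    B = gaussian_bowl(params.sigma, params.depth, n)
    r_in, r_out = params.gate_radii(n)
    w = radial_gate(n, r_in, r_out)
    if params.noise_amplitude > 0:
        P = perlin_tileable(params.periods_x, params.periods_y, n, params.seed, rescale=True)
    else:
        P = np.zeros((n, n))
    H0 = (1.0 - w) * B + w * (B + params.noise_amplitude * P)
    lo, hi = H0.min(), H0.max()
    if hi - lo < 1e-15:
        raise ValueError("degenerate heightfield: max(H0) == min(H0)")
    return Heightfield((H0 - lo) / (hi - lo), spec)


def surface_normal(field: Heightfield, i: int, j: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit surface normal and tangents at cell (i, j) by finite differences.

    Central differences in the interior, one-sided at the edges. Tangents:
    t_x = (delta, 0, v dH/dx), t_y = (0, delta, v dH/dy); n = t_x x t_y
    normalized.
    """
    H = field.heights
    n = field.spec.n
    v = field.spec.v_scale
    d = field.spec.spacing

    # dH per index step (central in the interior, one-sided at the edges)
    jp, jm = min(j + 1, n - 1), max(j - 1, 0)
    ip, im = min(i + 1, n - 1), max(i - 1, 0)
    dx = (H[i, jp] - H[i, jm]) / (jp - jm)  # along j (world x)
    dy = (H[ip, j] - H[im, j]) / (ip - im)  # along i (world y)
    tx = np.array([d, 0.0, v * dx])
    ty = np.array([0.0, d, v * dy])
    nrm = np.cross(tx, ty)
    return nrm / np.linalg.norm(nrm), tx, ty


# ----------------------------------------------------------------------
# reward


def tol_linear(s: float, bounds: tuple[float, float], margin: float) -> float:
    """Piecewise-linear tolerance: 1 inside [a, b], decaying linearly to 0 at
    distance ``margin`` outside; for a == b this is a triangular peak."""
    a, b = bounds
    if a > b:
        raise ValueError("bounds must satisfy a <= b")
    if margin <= 0:
        raise ValueError("margin must be positive")
    if a <= s <= b:
        return 1.0
    d = (a - s) if s < a else (s - b)
    return float(max(0.0, 1.0 - d / margin))


@dataclass
class EscapeState:
    """Minimal agent state for the escape task reward/observations."""

    pose: Pose
    vel: np.ndarray  # (6 + n)
    torso_z_axis: np.ndarray | None = None  # local z column; derived if None
    head_z_axis: np.ndarray | None = None


def escape_reward(
    state: EscapeState, field: Heightfield, cfg: EscapeRewardConfig
) -> tuple[float, dict[str, float]]:
    """r = r_esc * r_up + r_spd.

    r_esc ramps linearly with planar radius, saturating at the rim (rho = h);
    r_up averages two linear tolerances on the torso/head uprightness dot
    products with bounds [cos(theta), inf) and margin 1 + cos(theta);
    r_spd is the triangular speed tolerance peaked at the target speed.
    """
    x, y = state.pose.root_pos[0], state.pose.root_pos[1]
    rho = float(np.hypot(x, y))
    r_esc = min(1.0, rho / field.spec.half_width)

    R = quat.to_matrix(state.pose.root_quat)
    torso_z = state.torso_z_axis if state.torso_z_axis is not None else R[:, 2]
    head_z = state.head_z_axis if state.head_z_axis is not None else R[:, 2]
    cos_t = float(np.cos(np.deg2rad(cfg.tilt_deg)))
    margin = 1.0 + cos_t
    big = np.inf
    r_up = 0.5 * tol_linear(float(torso_z @ [0, 0, 1]), (cos_t, big), margin) + \
        0.5 * tol_linear(float(head_z @ [0, 0, 1]), (cos_t, big), margin)

    speed = float(np.linalg.norm(state.vel[:3]))
    r_spd = tol_linear(speed, (cfg.target_speed, cfg.target_speed), cfg.target_speed)
    total = r_esc * r_up + r_spd
    return float(total), {"esc": r_esc, "up": float(r_up), "spd": float(r_spd)}


def check_fail(state: EscapeState, field: Heightfield, eps: float = 0.03) -> bool:
    """Fail iff the torso height is at or below ground + eps (inclusive)."""
    z = float(state.pose.root_pos[2])
    return z <= ground_height(field, state.pose.root_pos[0], state.pose.root_pos[1]) + eps


# ----------------------------------------------------------------------
# observations


def task_observation(
    tree: KinematicTree,
    state: EscapeState,
    last_action: np.ndarray | None,
    field: Heightfield,
    contact_threshold: float = 0.005,
) -> np.ndarray:
    """Concatenated task + proprioceptive observation vector.

    Task block: previous action, base orientation (rotation vector) and
    body-frame linear/angular velocity, joint angles/velocities, boolean
    end-effector ground proximity, and pose relative to the bowl origin
    (planar displacement in the torso frame plus heading). Proprioceptive
    block: q without the 7 free-joint coordinates, qdot without the 6
    free-joint velocities, actuator signals, end-effector positions in the
    torso frame, and the joint kinematics again (the o_kin block appears in
    both halves by construction).
    """
    n_act_dim = (6 if tree.has_free_root else 0) + tree.n_dof
    a_prev = np.zeros(n_act_dim) if last_action is None else np.asarray(last_action, float)
    fr = forward_kinematics(tree, state.pose)
    R = quat.to_matrix(state.pose.root_quat)
    o_base = np.concatenate([
        quat.to_rotvec(state.pose.root_quat),
        R.T @ state.vel[:3],
        R.T @ state.vel[3:6],
    ])
    o_kin = np.concatenate([state.pose.q, state.vel[6:]])
    touch = []
    for p in fr.ee_pos:
        g = ground_height(field, p[0], p[1])
        touch.append(1.0 if p[2] <= g + contact_threshold else 0.0)
    o_touch = np.asarray(touch)
    disp = R.T @ np.array([state.pose.root_pos[0], state.pose.root_pos[1], 0.0])
    heading = quat.yaw(state.pose.root_quat)
    o_orig = np.concatenate([disp[:2], [heading]])
    task = np.concatenate([a_prev, o_base, o_kin, o_touch, o_orig])

    qpos = state.pose.qpos()
    tau = a_prev[6:] * tree.joint_tau_max() if tree.has_free_root else a_prev * tree.joint_tau_max()
    p_ee = (fr.ee_pos - state.pose.root_pos) @ R  # torso frame
    prop = np.concatenate([qpos[7:], state.vel[6:], tau, p_ee.reshape(-1), o_kin])
    return np.concatenate([task, prop])


# ----------------------------------------------------------------------
# export


def save_heightfield(field: Heightfield, params: BowlParams, out_dir: str | Path) -> Path:
    """Write the grid (plain text) with a JSON sidecar and a PNG render."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / "heightfield.txt", field.heights, fmt="%.8f")
    sidecar = {
        "n": field.spec.n,
        "half_width": field.spec.half_width,
        "v_scale": field.spec.v_scale,
        "sigma": params.sigma,
        "depth": params.depth,
        "noise_amplitude": params.noise_amplitude,
        "periods": [params.periods_x, params.periods_y],
        "gate_radii": list(params.gate_radii(field.spec.n)),
        "seed": params.seed,
    }
    (out / "heightfield.json").write_text(json.dumps(sidecar, indent=2))
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        plt.imsave(out / "heightfield.png", field.heights, cmap="gray", origin="lower")
    except Exception:  # rendering is best-effort
        pass
    return out
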