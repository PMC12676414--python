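"""Simultaneous tracking and calibration (STAC).

Registers a kinematic body model to tracked 3D keypoints by alternating two
convex-ish subproblems: inverse kinematics per frame ("tracking", projected
gradient descent over the pose with box joint ranges) and marker-offset
estimation ("calibration", stochastic gradient descent over the fixed local
offsets, pooled over frames). Under an isotropic Gaussian observation model
the maximum-likelihood objective reduces to the unweighted sum of squared
site-to-keypoint distances, which is what is minimized here.

Long sessions are processed as overlapping segments solved independently and
blended with a tanh-sigmoid crossfade; root quaternions are blended by
normalized interpolation with the same weights (shortest arc), since naive
elementwise blending leaves the unit sphere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from kinemimic import quat
from kinemimic.bodies import (
    FrameSet,
    KeypointSeries,
    KinematicTree,
    MarkerBinding,
    Pose,
    forward_kinematics,
)

log = logging.getLogger(__name__)


@dataclass
class StacConfig:
    pose_iters: int = 200
    offset_iters: int = 20  # SGD epochs over the sampled frames
    pose_step: float = 0.5  # fraction of the diagonally preconditioned step
    offset_step: float = 0.25  # per-sample step; Hessian of the per-frame loss is 2I
    tol: float = 1e-8  # stop when the objective decrease falls below this
    segment_length: int = 200
    overlap: int = 20
    crossfade_center: float = 0.5
    crossfade_steepness: float = 10.0
    n_alternations: int = 3
    offset_frames: int | None = 50  # frames sampled per calibration epoch (None: all)
    sgd_with_replacement: bool = False
    joint_refine_iters: int = 40  # bundle-adjustment polish after the alternations
    offset_reg: float = 1e-4  # gauge-fixing prior pulling offsets toward nominal
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.crossfade_center < 1):
            raise ValueError("crossfade center must lie in (0, 1)")
        if self.crossfade_steepness <= 0:
            raise ValueError("crossfade steepness must be positive")
        if self.overlap >= self.segment_length:
            raise ValueError("overlap must be smaller than segment_length")


@dataclass
class StacOutput:
    poses: list[Pose]
    qpos: np.ndarray  # (T, 7 + n)
    qvel: np.ndarray  # (T, 6 + n), finite differences at the series rate
    sites: np.ndarray  # (T, K, 3)
    offsets: list[MarkerBinding]
    objective: np.ndarray  # (T,)
    rate: float
    model_hash: str = ""

    @property
    def n_frames(self) -> int:
        return self.qpos.shape[0]


# ----------------------------------------------------------------------
# registration


def solve_similarity_registration(
    keypoints_ref: np.ndarray, model_sites: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares similarity transform (Umeyama / scaled Procrustes).

    Returns ``(s, R, t)`` minimizing sum ||s R x + t - y||^2 over proper
    rotations, where x are the keypoints and y the model sites. Requires at
    least 3 non-collinear correspondences.
    """
    x = np.asarray(keypoints_ref, dtype=float)
    y = np.asarray(model_sites, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3 or x.shape[0] < 3:
        raise ValueError("need matching K x 3 arrays with K >= 3")
    mx, my = x.mean(axis=0), y.mean(axis=0)
    xc, yc = x - mx, y - my
    if np.linalg.matrix_rank(xc, tol=1e-10) < 2:
        raise ValueError(
            "degenerate registration: keypoints are collinear "
            f"(centered rank < 2; spread = {np.linalg.norm(xc):.3g} m)"
        )
    cov = yc.T @ xc / x.shape[0]
    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2, 2] = -1.0
    R = U @ S @ Vt
    var_x = (xc ** 2).sum() / x.shape[0]
    s = float(np.trace(np.diag(D) @ S) / var_x)
    t = my - s * R @ mx
    return s, R, t


def apply_similarity(series: KeypointSeries, s: float, R: np.ndarray, t: np.ndarray) -> KeypointSeries:
    vals = s * np.einsum("ij,tkj->tki", R, series.values) + t
    return KeypointSeries(vals, series.rate, list(series.names), series.valid_mask.copy())


# ----------------------------------------------------------------------
# objective and gradients


def _objective(frames: FrameSet, kp: np.ndarray, mask: np.ndarray) -> float:
    err = frames.site_pos - kp
    return float((mask[:, None] * err ** 2).sum())


def _pose_gradient(
    tree: KinematicTree,
    frames: FrameSet,
    kp: np.ndarray,
    mask: np.ndarray,
    offsets: Sequence[MarkerBinding],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradient and diagonal Gauss-Newton curvature.

    Uses the geometric Jacobian: a hinge perturbation rotates every downstream
    point about the joint's world axis through its anchor; root perturbations
    rigidly translate/rotate everything. The curvature diagonal (2 |J_col|^2
    per coordinate) preconditions the projected gradient steps, which would
    otherwise crawl on the badly scaled root/joint mixture.
    """
    e = 2.0 * mask[:, None] * (frames.site_pos - kp)  # (K, 3)
    nvalid = float(mask.sum())
    g_pos = e.sum(axis=0)
    h_pos = np.full(3, 2.0 * max(nvalid, 1.0))
    rel = frames.site_pos - frames.body_pos[0]
    g_rot = np.cross(rel, e).sum(axis=0)
    h_rot = np.full(3, 2.0 * max(float((mask[:, None] * rel ** 2).sum()), 1e-6))
    g_q = np.zeros(tree.n_dof)
    h_q = np.full(tree.n_dof, 1e-6)
    site_bodies = np.array([s.body for s in offsets])
    for di, j in enumerate(tree.dof_joints):
        desc = tree.descendants(j.body)
        sel = desc[site_bodies]
        if not np.any(sel):
            continue
        a = frames.joint_axis_world[di]
        if j.kind == "hinge":
            arm = frames.site_pos[sel] - frames.joint_anchor[di]
            jac = np.cross(a, arm)  # (n_sel, 3) site velocity per unit angle
        else:  # slide
            jac = np.broadcast_to(a, (int(sel.sum()), 3))
        g_q[di] = float((jac * e[sel]).sum())
        h_q[di] += 2.0 * float((mask[sel, None] * jac ** 2).sum())
    return (g_pos, g_rot, g_q), (h_pos, h_rot, h_q)


def _kabsch_root_update(
    tree: KinematicTree,
    pose: Pose,
    frames: FrameSet,
    kp: np.ndarray,
    mask: np.ndarray,
    offsets: Sequence[MarkerBinding],
) -> tuple[Pose, FrameSet, float]:
    """Exact rigid (no-scale) alignment of the whole body to the keypoints.

    The free root enters the objective only through a rigid transform of all
    sites, so its optimum given the joints is the weighted Kabsch solution.
    """
    w = mask / max(mask.sum(), 1e-12)
    s_bar = (w[:, None] * frames.site_pos).sum(axis=0)
    v_bar = (w[:, None] * kp).sum(axis=0)
    sc, vc = frames.site_pos - s_bar, kp - v_bar
    cov = (vc * w[:, None]).T @ sc
    U, _, Vt = np.linalg.svd(cov)
    S = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2, 2] = -1.0
    Rd = U @ S @ Vt
    td = v_bar - Rd @ s_bar
    cand = pose.copy()
    cand.root_pos = Rd @ pose.root_pos + td
    cand.root_quat = quat.canonicalize(quat.mul(quat.from_matrix(Rd), pose.root_quat))
    cand_frames = forward_kinematics(tree, cand, offsets)
    return cand, cand_frames, _objective(cand_frames, kp, mask)


def _site_sensitivity(
    tree: KinematicTree, frames: FrameSet, site_bodies: np.ndarray, di: int
) -> np.ndarray:
    """Sites whose position actually responds to joint ``di`` (nonzero Jacobian)."""
    j = tree.dof_joints[di]
    in_desc = tree.descendants(j.body)[site_bodies]
    if j.kind == "slide":
        return in_desc
    arm = np.cross(
        np.broadcast_to(frames.joint_axis_world[di], (len(site_bodies), 3)),
        frames.site_pos - frames.joint_anchor[di],
    )
    return in_desc & (np.linalg.norm(arm, axis=1) > 1e-9)


def _exact_joint_update(
    tree: KinematicTree,
    pose: Pose,
    frames: FrameSet,
    kp: np.ndarray,
    mask: np.ndarray,
    offsets: Sequence[MarkerBinding],
    di: int,
    lo: np.ndarray,
    hi: np.ndarray,
    local: bool = False,
) -> float:
    """Closed-form 1-D minimization for one joint, projected into its range.

    For a hinge, sites downstream rotate about the world axis a through the
    anchor c; the objective in the angle change D is C - A cos(D) - B sin(D),
    minimized at atan2(B, A). For a slide it is an exact quadratic. Returns
    the new (clipped) coordinate; the caller re-runs FK.
    """
    j = tree.dof_joints[di]
    desc = tree.descendants(j.body)
    site_bodies = np.array([s.body for s in offsets])
    sel = desc[site_bodies] & (mask > 0)
    if local:
        # sites owned directly: moved by this joint but by no deeper joint
        owned = _site_sensitivity(tree, frames, site_bodies, di)
        for dj, oj in enumerate(tree.dof_joints):
            if dj != di and desc[oj.body]:
                owned &= ~_site_sensitivity(tree, frames, site_bodies, dj)
        if np.any(owned & (mask > 0)):
            sel = owned & (mask > 0)
    if not np.any(sel):
        return pose.q[di]
    a = frames.joint_axis_world[di]
    if j.kind == "hinge":
        c = frames.joint_anchor[di]
        r = frames.site_pos[sel] - c
        d = kp[sel] - c
        m = mask[sel][:, None]
        A = float((m * (d * r)).sum() - (m[:, 0] * (r @ a) * (d @ a)).sum())
        B = float((m * (d * np.cross(np.broadcast_to(a, r.shape), r))).sum())
        delta = np.arctan2(B, A) if (abs(A) > 1e-15 or abs(B) > 1e-15) else 0.0
        # the 1-D objective is periodic: wrap the step into (-pi, pi]
        delta = (delta + np.pi) % (2 * np.pi) - np.pi
    else:
        resid = kp[sel] - frames.site_pos[sel]
        delta = float((mask[sel][:, None] * resid * a).sum() / max(mask[sel].sum(), 1e-12))
    return float(np.clip(pose.q[di] + delta, lo[di], hi[di]))


def _full_jacobian(
    tree: KinematicTree,
    frames: FrameSet,
    offsets: Sequence[MarkerBinding],
    free_root: bool,
) -> np.ndarray:
    """Stacked site Jacobian, (3K, 6 + n) with the root block zero for
    welded trees: columns are root translation, root rotation (world rotation
    vector about the root origin) and each joint coordinate."""
    K = len(offsets)
    n = tree.n_dof
    J = np.zeros((K, 3, 6 + n))
    if free_root:
        J[:, :, :3] = np.eye(3)
        rel = frames.site_pos - frames.body_pos[0]
        for k in range(K):
            x, y, z = rel[k]
            J[k, :, 3:6] = -np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    site_bodies = np.array([s.body for s in offsets])
    for di, j in enumerate(tree.dof_joints):
        sel = tree.descendants(j.body)[site_bodies]
        if not np.any(sel):
            continue
        a = frames.joint_axis_world[di]
        if j.kind == "hinge":
            J[sel, :, 6 + di] = np.cross(a, frames.site_pos[sel] - frames.joint_anchor[di])
        else:
            J[sel, :, 6 + di] = a
    return J.reshape(3 * K, 6 + n)


def _projected_lm(
    tree: KinematicTree,
    pose: Pose,
    frames: FrameSet,
    f: float,
    kp: np.ndarray,
    mask: np.ndarray,
    offsets: Sequence[MarkerBinding],
    cfg: StacConfig,
    lo: np.ndarray,
    hi: np.ndarray,
    iters: int,
) -> tuple[Pose, FrameSet, float]:
    """Projected damped Gauss-Newton (Levenberg-Marquardt) descent.

    Full-Jacobian steps with adaptive damping; the joint vector is projected
    into its box range after every step and steps are only accepted if the
    objective does not increase, so the result is monotone.
    """
    free = tree.has_free_root
    lam = 1e-4
    for _ in range(iters):
        w = np.repeat(mask, 3)
        J = _full_jacobian(tree, frames, offsets, free) * w[:, None]
        r = ((frames.site_pos - kp) * mask[:, None]).reshape(-1)
        g = 2.0 * J.T @ r
        H = 2.0 * J.T @ J
        accepted = False
        for _ in range(12):
            step = np.linalg.solve(H + lam * np.eye(H.shape[0]), -g)
            cand = pose.copy()
            if free:
                cand.root_pos = pose.root_pos + step[:3]
                cand.root_quat = quat.canonicalize(
                    quat.mul(quat.from_rotvec(step[3:6]), pose.root_quat)
                )
            cand.q = np.clip(pose.q + step[6:], lo, hi)
            cand_frames = forward_kinematics(tree, cand, offsets)
            cand_f = _objective(cand_frames, kp, mask)
            if cand_f <= f:
                improved = f - cand_f > cfg.tol
                pose, frames, f = cand, cand_frames, cand_f
                lam = max(lam * 0.33, 1e-10)
                accepted = True
                break
            lam *= 6.0
        if not accepted or not improved:
            break
    return pose, frames, f


def solve_pose(
    tree: KinematicTree,
    keypoints_t: np.ndarray,
    offsets: Sequence[MarkerBinding],
    init: Pose,
    cfg: StacConfig,
    mask: np.ndarray | None = None,
    frame_index: int | None = None,
) -> tuple[Pose, float]:
    """Inverse kinematics for one frame by projected gradient descent.

    Three phases, warm-starting each from the previous: (1) root position and
    orientation only, (2) all degrees of freedom, (3) each root subtree
    independently. Every step projects the joint vector into its box range;
    a backtracking line search keeps the objective non-increasing, so the
    returned objective never exceeds the initial one.
    """
    kp = np.asarray(keypoints_t, dtype=float).reshape(-1, 3)
    if mask is None:
        mask = np.ones(kp.shape[0], dtype=bool)
    mask = np.asarray(mask, dtype=bool).astype(float)
    lo, hi = tree.joint_ranges
    pose = init.copy()
    frames = forward_kinematics(tree, pose, offsets)
    f = _objective(frames, kp, mask)

    def run_phase(pose, frames, f, update_root: bool, joint_sel: np.ndarray, iters: int):
        step = cfg.pose_step
        for _ in range(iters):
            (g_pos, g_rot, g_q), (h_pos, h_rot, h_q) = _pose_gradient(tree, frames, kp, mask, offsets)
            if not (np.all(np.isfinite(g_pos)) and np.all(np.isfinite(g_rot)) and np.all(np.isfinite(g_q))):
                where = f" at frame {frame_index}" if frame_index is not None else ""
                raise FloatingPointError(f"NaN/inf in pose gradient{where}")
            d_pos, d_rot = g_pos / h_pos, g_rot / h_rot
            d_q = np.where(joint_sel, g_q / h_q, 0.0)
            improved = False
            trial = step
            for _ in range(30):
                cand = pose.copy()
                if update_root:
                    cand.root_pos = pose.root_pos - trial * d_pos
                    cand.root_quat = quat.canonicalize(
                        quat.mul(quat.from_rotvec(-trial * d_rot), pose.root_quat)
                    )
                cand.q = np.clip(pose.q - trial * d_q, lo, hi)
                cand_frames = forward_kinematics(tree, cand, offsets)
                cand_f = _objective(cand_frames, kp, mask)
                if cand_f <= f:
                    improved = cand_f < f - cfg.tol
                    pose, frames, f = cand, cand_frames, cand_f
                    step = min(trial * 2.0, 1.0)
                    break
                trial *= 0.5
            else:
                return pose, frames, f  # no improving step found
            if not improved:
                return pose, frames, f
        return pose, frames, f

    free = tree.has_free_root
    all_joints = np.ones(tree.n_dof, dtype=bool)
    no_joints = np.zeros(tree.n_dof, dtype=bool)
    if free:
        # warm start: root placement first
        pose, frames, f = run_phase(pose, frames, f, True, no_joints, max(cfg.pose_iters // 4, 10))
    # full-body pass
    pose, frames, f = run_phase(pose, frames, f, free, all_joints, cfg.pose_iters)
    # full-Jacobian polish (projected damped Gauss-Newton), monotone
    pose, frames, f = _projected_lm(tree, pose, frames, f, kp, mask, offsets, cfg, lo, hi, cfg.pose_iters)
    scale = max(float((mask[:, None] * kp ** 2).sum()), 1e-12)
    if f > 1e-10 * scale:
        # basin hop: exact root fit, then a greedy root-to-tip pass where each
        # joint aligns only the sites it directly owns (exact for serial
        # chains), then polish again; keep whichever basin ends lower
        alt, alt_frames = pose.copy(), frames
        if free:
            alt, alt_frames, _ = _kabsch_root_update(tree, alt, alt_frames, kp, mask, offsets)
        for di in range(tree.n_dof):
            qi = _exact_joint_update(tree, alt, alt_frames, kp, mask, offsets, di, lo, hi, local=True)
            if qi != alt.q[di]:
                alt.q[di] = qi
                alt_frames = forward_kinematics(tree, alt, offsets)
        alt_f = _objective(alt_frames, kp, mask)
        alt, alt_frames, alt_f = _projected_lm(
            tree, alt, alt_frames, alt_f, kp, mask, offsets, cfg, lo, hi, cfg.pose_iters
        )
        if alt_f < f:
            pose, frames, f = alt, alt_frames, alt_f
    # per-part refinement: each joint optimized independently (exact 1-D
    # minimization holding the rest fixed), accepted only if it improves
    for di in range(tree.n_dof):
        qi = _exact_joint_update(tree, pose, frames, kp, mask, offsets, di, lo, hi)
        if qi != pose.q[di]:
            cand = pose.copy()
            cand.q[di] = qi
            cand_frames = forward_kinematics(tree, cand, offsets)
            cand_f = _objective(cand_frames, kp, mask)
            if cand_f <= f:
                pose, frames, f = cand, cand_frames, cand_f
    return pose, f


def calibrate_offsets(
    tree: KinematicTree,
    poses: Sequence[Pose],
    keypoints: KeypointSeries,
    cfg: StacConfig,
    init: Sequence[MarkerBinding] | None = None,
) -> list[MarkerBinding]:
    """Marker-offset calibration by SGD over sampled frames.

    Per visited frame the gradient of ||R o + p - v||^2 in each marker's
    offset is 2 R^T (site - v); masked (invalid) keypoints contribute nothing,
    so a never-observed marker keeps its initial offset (the documented
    unidentifiable case). Deterministic given ``cfg.seed``.
    """
    if len(poses) < 2:
        raise ValueError("calibration needs at least 2 frames")
    offsets = [replace(s) for s in (init if init is not None else tree.sites)]
    off = np.stack([o.offset for o in offsets])  # (K, 3)
    site_bodies = np.array([o.body for o in offsets])
    rng = np.random.default_rng(cfg.seed)
    T = len(poses)
    n_sample = T if cfg.offset_frames is None else min(cfg.offset_frames, T)
    for _ in range(cfg.offset_iters):
        if cfg.sgd_with_replacement:
            order = rng.integers(0, T, size=n_sample)
        else:
            order = rng.permutation(T)[:n_sample]
        for t in order:
            fr = forward_kinematics(
                tree, poses[t], [replace(o, offset=off[k]) for k, o in enumerate(offsets)]
            )
            err = fr.site_pos - keypoints.values[t]
            m = keypoints.valid_mask[t].astype(float)[:, None]
            R = fr.body_rot[site_bodies]  # (K, 3, 3)
            grad = 2.0 * np.einsum("kji,kj->ki", R, m * err)
            off -= cfg.offset_step * grad
    return [replace(o, offset=off[k]) for k, o in enumerate(offsets)]


def _joint_gauss_newton(
    tree: KinematicTree,
    poses: list[Pose],
    offsets: list[MarkerBinding],
    keypoints: KeypointSeries,
    cfg: StacConfig,
    iters: int,
) -> tuple[list[Pose], list[MarkerBinding]]:
    """Damped Gauss-Newton over all poses and all marker offsets jointly.

    The pose-offset coupling makes coordinate-wise alternation crawl along a
    nearly flat valley (offset error traded against joint angles); the joint
    normal equations eliminate the per-frame pose blocks with a Schur
    complement on the (small) offset block, so the cost per iteration stays
    linear in the frame count. Damping keeps steps monotone; genuinely
    unidentifiable offset directions (leaf-marker rotations about their own
    joint axis) simply stay near their initialization.

    ``cfg.offset_reg`` adds a weak quadratic prior pulling offsets toward the
    model's nominal bindings. Marker placement on a body is never exactly
    flat-direction-free, and without the prior the solver may settle anywhere
    on an observationally equivalent orbit; the prior fixes that gauge while
    biasing well-constrained directions negligibly (it corresponds to the
    MAP estimate under a broad Gaussian prior on marker placement).
    """
    T = len(poses)
    K = len(offsets)
    n = tree.n_dof
    D = 6 + n
    lo, hi = tree.joint_ranges
    free = tree.has_free_root
    site_bodies = np.array([o.body for o in offsets])
    off = np.stack([o.offset for o in offsets])
    off_nominal = np.stack([s.offset for s in tree.sites])
    reg = cfg.offset_reg

    def total(poses_, off_):
        binds = [replace(o, offset=off_[k]) for k, o in enumerate(offsets)]
        s = reg * float(((off_ - off_nominal) ** 2).sum())
        for t in range(T):
            fr = forward_kinematics(tree, poses_[t], binds)
            s += _objective(fr, keypoints.values[t], keypoints.valid_mask[t].astype(float))
        return s

    f = total(poses, off)
    lam = 1e-6
    for _ in range(iters):
        binds = [replace(o, offset=off[k]) for k, o in enumerate(offsets)]
        Hpp, Hpo, gp = [], [], []
        Hoo = np.zeros((3 * K, 3 * K))
        go = np.zeros(3 * K)
        for t in range(T):
            fr = forward_kinematics(tree, poses[t], binds)
            m = keypoints.valid_mask[t].astype(float)
            w = np.repeat(m, 3)
            A = _full_jacobian(tree, fr, binds, free) * w[:, None]
            B = np.zeros((3 * K, 3 * K))
            for k in range(K):
                B[3 * k : 3 * k + 3, 3 * k : 3 * k + 3] = m[k] * fr.body_rot[site_bodies[k]]
            r = ((fr.site_pos - keypoints.values[t]) * m[:, None]).reshape(-1)
            Hpp.append(A.T @ A)
            Hpo.append(A.T @ B)
            gp.append(A.T @ r)
            Hoo += B.T @ B
            go += B.T @ r
        Hoo += reg * np.eye(3 * K)
        go += reg * (off - off_nominal).reshape(-1)
        accepted = False
        for _ in range(10):
            S = Hoo + lam * np.eye(3 * K)
            rhs = go.copy()
            Hpp_inv = []
            for t in range(T):
                Hinv = np.linalg.inv(Hpp[t] + lam * np.eye(D))
                Hpp_inv.append(Hinv)
                S -= Hpo[t].T @ Hinv @ Hpo[t]
                rhs -= Hpo[t].T @ Hinv @ gp[t]
            d_off = np.linalg.solve(S, -rhs).reshape(K, 3)
            cand_poses = []
            for t in range(T):
                dp = Hpp_inv[t] @ (-gp[t] - Hpo[t] @ d_off.reshape(-1))
                p = poses[t].copy()
                if free:
                    p.root_pos = p.root_pos + dp[:3]
                    p.root_quat = quat.canonicalize(quat.mul(quat.from_rotvec(dp[3:6]), p.root_quat))
                p.q = np.clip(p.q + dp[6:], lo, hi)
                cand_poses.append(p)
            cand_off = off + d_off
            cand_f = total(cand_poses, cand_off)
            if cand_f <= f:
                improved = f - cand_f > cfg.tol
                poses, off, f = cand_poses, cand_off, cand_f
                lam = max(lam * 0.33, 1e-10)
                accepted = True
                break
            lam *= 8.0
        if not accepted or not improved:
            break
    return poses, [replace(o, offset=off[k]) for k, o in enumerate(offsets)]


# ----------------------------------------------------------------------
# full fit


def _total_objective(
    tree: KinematicTree,
    poses: Sequence[Pose],
    offsets: Sequence[MarkerBinding],
    keypoints: KeypointSeries,
) -> tuple[float, np.ndarray, np.ndarray]:
    per_frame = np.empty(len(poses))
    sites = np.empty((len(poses), len(offsets), 3))
    for t, p in enumerate(poses):
        fr = forward_kinematics(tree, p, offsets)
        sites[t] = fr.site_pos
        per_frame[t] = _objective(fr, keypoints.values[t], keypoints.valid_mask[t].astype(float))
    return float(per_frame.sum()), per_frame, sites


def finite_difference_velocities(qpos: np.ndarray, rate: float) -> np.ndarray:
    """Central-difference velocities from a (T, 7+n) trajectory.

    Layout: [linear root velocity (3), root angular velocity (3, world-frame
    rotation vector rate), joint velocities (n)]. One-sided at the ends.
    """
    T, width = qpos.shape
    n = width - 7
    qvel = np.zeros((T, 6 + n))
    if T < 2:
        return qvel
    for t in range(T):
        t0, t1 = max(t - 1, 0), min(t + 1, T - 1)
        dt = (t1 - t0) / rate
        qvel[t, :3] = (qpos[t1, :3] - qpos[t0, :3]) / dt
        dq = quat.mul(qpos[t1, 3:7], quat.conj(qpos[t0, 3:7]))
        qvel[t, 3:6] = quat.to_rotvec(dq) / dt
        qvel[t, 6:] = (qpos[t1, 7:] - qpos[t0, 7:]) / dt
    return qvel


def stac_fit(
    tree: KinematicTree,
    keypoints: KeypointSeries,
    cfg: StacConfig,
    register: bool = False,
    init_offsets: Sequence[MarkerBinding] | None = None,
    model_hash: str = "",
) -> StacOutput:
    """Alternate per-frame pose solving and offset calibration.

    Pose solving warm-starts each frame from its predecessor. After every
    calibration pass the total objective is re-evaluated and the new offsets
    are accepted only if they do not increase it, so the objective is
    non-increasing across alternations by construction.
    """
    if register:
        fr0 = forward_kinematics(tree, tree.identity_pose())
        m0 = keypoints.valid_mask[0]
        s, R, t = solve_similarity_registration(keypoints.values[0][m0], fr0.site_pos[m0])
        keypoints = apply_similarity(keypoints, s, R, t)

    offsets = [replace(s) for s in (init_offsets if init_offsets is not None else tree.sites)]
    T = keypoints.n_frames
    poses: list[Pose] = [tree.identity_pose() for _ in range(T)]
    best_total = np.inf
    for rnd in range(cfg.n_alternations):
        init = poses[0]
        for t in range(T):
            poses[t], _ = solve_pose(
                tree, keypoints.values[t], offsets, init, cfg,
                mask=keypoints.valid_mask[t], frame_index=t,
            )
            init = poses[t]
        total, _, _ = _total_objective(tree, poses, offsets, keypoints)
        best_total = min(best_total, total)
        if rnd < cfg.n_alternations - 1 and T >= 2:
            cand = calibrate_offsets(tree, poses, keypoints, cfg, init=offsets)
            cand_total, _, _ = _total_objective(tree, poses, cand, keypoints)
            if cand_total <= best_total:
                offsets, best_total = cand, cand_total
            else:
                log.debug("calibration pass rejected (objective %.3g -> %.3g)", best_total, cand_total)

    if cfg.joint_refine_iters > 0 and T >= 2:
        poses, offsets = _joint_gauss_newton(tree, poses, offsets, keypoints, cfg, cfg.joint_refine_iters)

    _, per_frame, sites = _total_objective(tree, poses, offsets, keypoints)
    qpos = np.stack([p.qpos() for p in poses])
    qvel = finite_difference_velocities(qpos, keypoints.rate)
    return StacOutput(poses, qpos, qvel, sites, offsets, per_frame, keypoints.rate, model_hash)


# ----------------------------------------------------------------------
# long-session segmentation


def crossfade_weights(n: int, cfg: StacConfig) -> np.ndarray:
    if n < 2:
        raise ValueError("crossfade needs at least 2 samples")
    x = np.arange(n) / (n - 1)
    return 0.5 * (1.0 + np.tanh(cfg.crossfade_steepness * (x - cfg.crossfade_center)))


def crossfade_stitch(a: np.ndarray, b: np.ndarray, cfg: StacConfig) -> np.ndarray:
    """Blend two overlapping segments with the tanh-sigmoid mixing weight.

    With normalized position x_j = j/(O-1), the weight is
    m_j = (1 + tanh(s (x_j - c))) / 2 and the output is
    (1 - m_j) a_j + m_j b_j elementwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("overlap segments must have equal shapes")
    m = crossfade_weights(a.shape[0], cfg)
    return (1.0 - m)[:, None] * a.reshape(a.shape[0], -1) + m[:, None] * b.reshape(b.shape[0], -1)


def _segment_starts(T: int, seg: int, overlap: int) -> list[int]:
    if T <= seg:
        return [0]
    hop = seg - overlap
    starts = list(range(0, T - seg, hop))
    starts.append(T - seg)
    return sorted(set(starts))


def process_long_session(
    tree: KinematicTree,
    keypoints: KeypointSeries,
    cfg: StacConfig,
    register: bool = False,
    model_hash: str = "",
) -> StacOutput:
    """STAC a long series as overlapping segments blended by crossfade.

    Segments are solved independently (order-independent contract); overlap
    regions are blended on the joint-vector and root-position channels, and
    root quaternions by normalized interpolation with the same weights.
    Calibrated offsets are averaged across segments and the stitched
    trajectory's sites/objective are recomputed under those offsets.
    """
    T = keypoints.n_frames
    if T <= cfg.segment_length:
        return stac_fit(tree, keypoints, cfg, register=register, model_hash=model_hash)
    if register:
        fr0 = forward_kinematics(tree, tree.identity_pose())
        m0 = keypoints.valid_mask[0]
        s, R, t = solve_similarity_registration(keypoints.values[0][m0], fr0.site_pos[m0])
        keypoints = apply_similarity(keypoints, s, R, t)

    starts = _segment_starts(T, cfg.segment_length, cfg.overlap)
    outputs = []
    for s0 in starts:
        sub = KeypointSeries(
            keypoints.values[s0 : s0 + cfg.segment_length],
            keypoints.rate,
            list(keypoints.names),
            keypoints.valid_mask[s0 : s0 + cfg.segment_length],
        )
        outputs.append(stac_fit(tree, sub, cfg))

    n = tree.n_dof
    qpos = outputs[0].qpos.copy()
    for s_prev, s0, out in zip(starts[:-1], starts[1:], outputs[1:]):
        done = s_prev + cfg.segment_length  # frames [0, done) already in qpos
        O = done - s0
        if O < 2:  # no usable overlap; plain concatenation
            qpos = np.vstack([qpos, out.qpos[done - s0 :]])
            continue
        a, b = qpos[s0:done], out.qpos[:O]
        m = crossfade_weights(O, cfg)
        blended = np.empty_like(a)
        blended[:, :3] = crossfade_stitch(a[:, :3], b[:, :3], cfg)
        blended[:, 7:] = crossfade_stitch(a[:, 7:], b[:, 7:], cfg) if n else a[:, 7:]
        for j in range(O):
            blended[j, 3:7] = quat.nlerp(a[j, 3:7], b[j, 3:7], float(m[j]))
        qpos[s0:done] = blended
        qpos = np.vstack([qpos, out.qpos[O:]])

    off = np.mean([np.stack([o.offset for o in out.offsets]) for out in outputs], axis=0)
    offsets = [replace(o, offset=off[k]) for k, o in enumerate(outputs[0].offsets)]
    poses = [Pose.from_qpos(qpos[t]) for t in range(T)]
    _, per_frame, sites = _total_objective(tree, poses, offsets, keypoints)
    qvel = finite_difference_velocities(qpos, keypoints.rate)
    return StacOutput(poses, qpos, qvel, sites, offsets, per_frame, keypoints.rate, model_hash)
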