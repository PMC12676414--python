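"""PPO training of the encoder-decoder policy at toy scale.

On-policy loop: logically parallel environments are advanced in unroll
segments, observations are normalized by running Welford statistics (updated
after each collection round, frozen within), advantages come from
generalized advantage estimation, and the policy/value networks are updated
with the clipped PPO surrogate plus a ramp-weighted AR(1) KL penalty on the
latent sequence.

The action and latent are treated jointly: the stored log-probability is
log q(z | ref obs) + log p(a | z, proprio), and the PPO ratio is taken over
that joint density, which keeps the surrogate well-defined without
marginalizing the bottleneck.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from kinemimic.autodiff import Tensor, gaussian_log_prob
from kinemimic.bodies import make_pendulum_fixture
from kinemimic.imitation import (
    ImitationEnv,
    ReferenceClip,
    RewardSpec,
    TerminationSpec,
    WelfordStats,
    build_observation,
)
from kinemimic.policy import (
    AR1Prior,
    PolicyParams,
    action_log_prob,
    ar1_kl,
    decode,
    encode,
    value,
)


@dataclass
class TrainConfig:
    n_envs: int = 16
    l_unroll: int = 32
    b_batch: int = 8  # trajectories per mini-batch
    n_minibatch: int = 4
    t_episode: int = 200  # hard episode cap, frames
    gamma: float = 0.97
    gae_lambda: float = 0.95
    clip_eps: float = 0.2
    epochs: int = 8
    lr: float = 5e-4
    value_coef: float = 0.5
    entropy_coef: float = 1e-3
    total_steps: int = 200_000
    d_z: int = 8
    hidden: tuple[int, ...] = (64, 64)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.gamma <= 1.0 and 0.0 <= self.gae_lambda <= 1.0):
            raise ValueError("gamma and gae_lambda must lie in [0, 1]")
        if min(self.n_envs, self.l_unroll, self.b_batch, self.n_minibatch, self.epochs) < 1:
            raise ValueError("counts must be positive")


# ----------------------------------------------------------------------
# GAE


def gae(
    rewards: np.ndarray,
    values: np.ndarray,
    dones: np.ndarray,
    gamma: float,
    lam: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Generalized advantage estimation over one unroll.

    ``values`` has length T + 1 (bootstrap value at the unroll end); episode
    boundaries (``dones``) cut both the bootstrap and the recursion. Returns
    (advantages, returns = advantages + values[:-1]).
    """
    rewards = np.asarray(rewards, dtype=float)
    values = np.asarray(values, dtype=float)
    dones = np.asarray(dones, dtype=bool)
    T = rewards.shape[0]
    if values.shape[0] != T + 1 or dones.shape[0] != T:
        raise ValueError("need len(values) == len(rewards) + 1 == len(dones) + 1")
    adv = np.zeros(T)
    carry = 0.0
    for t in range(T - 1, -1, -1):
        nonterm = 0.0 if dones[t] else 1.0
        delta = rewards[t] + gamma * values[t + 1] * nonterm - values[t]
        carry = delta + gamma * lam * nonterm * carry
        adv[t] = carry
    return adv, adv + values[:-1]


# ----------------------------------------------------------------------
# rollout storage


@dataclass
class RolloutBatch:
    """Trajectories of shape (n_traj, l_unroll, ...); observations stored
    already normalized by the statistics that were frozen during collection."""

    ref: np.ndarray
    proprio: np.ndarray
    z: np.ndarray
    z_prev: np.ndarray
    first: np.ndarray  # episode-start flags (prior reverts to N(0, I))
    u: np.ndarray  # pre-squash actions
    logp: np.ndarray  # joint log q(z) + log p(a|z)
    rewards: np.ndarray
    dones: np.ndarray
    values: np.ndarray  # (n_traj, l_unroll + 1) with bootstrap
    steps: int = 0

    def flat(self, idx: np.ndarray) -> dict[str, np.ndarray]:
        sel = lambda a: a[idx].reshape(-1, *a.shape[2:])
        return {
            "ref": sel(self.ref),
            "proprio": sel(self.proprio),
            "z": sel(self.z),
            "z_prev": sel(self.z_prev),
            "first": sel(self.first),
            "u": sel(self.u),
            "logp": sel(self.logp),
        }


class Runner:
    """Holds the persistent per-environment state between collection rounds."""

    def __init__(self, env: ImitationEnv, policy: PolicyParams, cfg: TrainConfig,
                 rng: np.random.Generator):
        self.env = env
        self.policy = policy
        self.cfg = cfg
        self.rng = rng
        p_dim, r_dim = env.obs_dims()
        self.p_dim, self.r_dim = p_dim, r_dim
        self.stats = WelfordStats.zeros(p_dim + r_dim)
        self.states = [env.reset(rng) for _ in range(cfg.n_envs)]
        self.ep_steps = [0] * cfg.n_envs
        self.z_prev = np.zeros((cfg.n_envs, policy.d_z))
        self.first = np.ones(cfg.n_envs, dtype=bool)
        self.completed_rewards: list[float] = []
        self._ep_reward = [0.0] * cfg.n_envs
        self._comp_sums: dict[str, float] = {}
        self._comp_count = 0
        self.total_steps = 0

    def reward_component_means(self) -> dict[str, float]:
        """Per-term reward means since the last call (for metric streams)."""
        if self._comp_count == 0:
            return {}
        out = {f"reward_{k}": v / self._comp_count for k, v in self._comp_sums.items()}
        self._comp_sums = {}
        self._comp_count = 0
        return out

    def _raw_obs(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        p, r = build_observation(
            self.env.tree, self.states[i], self.env.clips[self.states[i].clip_id],
            self.env.lookahead,
        )
        return p.flat(), r.flat()

    def collect(self) -> RolloutBatch:
        """One data-collection iteration: as many unroll rounds as needed to
        fill the n_minibatch x b_batch trajectory quota; Welford statistics
        update after every round and stay frozen within it."""
        cfg, env, pol = self.cfg, self.env, self.policy
        quota = cfg.n_minibatch * cfg.b_batch
        rounds = -(-quota // cfg.n_envs)
        out: dict[str, list] = {k: [] for k in
                                ("ref", "proprio", "z", "z_prev", "first", "u", "logp",
                                 "rewards", "dones", "values")}
        for _ in range(rounds):
            raw_log: list[np.ndarray] = []
            buf = {k: [] for k in out}
            for _t in range(cfg.l_unroll):
                raws = [self._raw_obs(i) for i in range(cfg.n_envs)]
                raw = np.stack([np.concatenate([p, r]) for p, r in raws])
                raw_log.append(raw)
                norm = self.stats.normalize(raw)
                prop_n, ref_n = norm[:, : self.p_dim], norm[:, self.p_dim :]
                z, mu_e, logvar_e = encode(pol.params, pol.n_layers, pol.d_z, ref_n, self.rng)
                logq = gaussian_log_prob(z.data, mu_e, logvar_e).data
                a, u, logp_a = decode(pol.params, pol.n_layers, pol.n_act, z, prop_n, self.rng)
                v = value(pol.params, pol.n_layers, norm).data
                buf["ref"].append(ref_n)
                buf["proprio"].append(prop_n)
                buf["z"].append(z.data.copy())
                buf["z_prev"].append(self.z_prev.copy())
                buf["first"].append(self.first.copy())
                buf["u"].append(u.data.copy())
                buf["logp"].append(logq + logp_a.data)
                buf["values"].append(v)
                rewards = np.zeros(cfg.n_envs)
                dones = np.zeros(cfg.n_envs, dtype=bool)
                for i in range(cfg.n_envs):
                    st, r_i, comps = env.step(self.states[i], a.data[i])
                    for key, val in comps.items():
                        self._comp_sums[key] = self._comp_sums.get(key, 0.0) + val
                    self._comp_count += 1
                    self.ep_steps[i] += 1
                    self._ep_reward[i] += r_i
                    if self.ep_steps[i] >= cfg.t_episode:
                        st.done, st.reason = True, st.reason or "episode_cap"
                    rewards[i] = r_i
                    dones[i] = st.done
                    if st.done:
                        self.completed_rewards.append(self._ep_reward[i])
                        self._ep_reward[i] = 0.0
                        self.ep_steps[i] = 0
                        st = env.reset(self.rng)
                        self.z_prev[i] = 0.0
                        self.first[i] = True
                    else:
                        self.z_prev[i] = z.data[i]
                        self.first[i] = False
                    self.states[i] = st
                buf["rewards"].append(rewards)
                buf["dones"].append(dones)
                self.total_steps += cfg.n_envs
            # bootstrap values for the unroll end
            raws = [self._raw_obs(i) for i in range(cfg.n_envs)]
            raw = np.stack([np.concatenate([p, r]) for p, r in raws])
            v_boot = value(pol.params, pol.n_layers, self.stats.normalize(raw)).data
            buf["values"].append(v_boot)
            for k in out:
                arr = np.stack(buf[k], axis=1)  # (n_envs, l_unroll[, ...])
                out[k].append(arr)
            self.stats.update(np.concatenate(raw_log, axis=0))
        cat = {k: np.concatenate(v, axis=0) for k, v in out.items()}
        return RolloutBatch(
            ref=cat["ref"], proprio=cat["proprio"], z=cat["z"], z_prev=cat["z_prev"],
            first=cat["first"], u=cat["u"], logp=cat["logp"], rewards=cat["rewards"],
            dones=cat["dones"], values=cat["values"],
            steps=rounds * cfg.n_envs * cfg.l_unroll,
        )


def collect_rollouts(runner: Runner) -> RolloutBatch:
    return runner.collect()


# ----------------------------------------------------------------------
# optimization


class Adam:
    def __init__(self, keys: list[str], lr: float):
        self.lr = lr
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0
        self.keys = keys

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k in self.keys:
            if k not in grads:
                continue
            g = grads[k]
            self.m[k] = b1 * self.m.get(k, 0.0) + (1 - b1) * g
            self.v[k] = b2 * self.v.get(k, 0.0) + (1 - b2) * g ** 2
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + eps)


def ppo_update(
    policy: PolicyParams,
    batch: RolloutBatch,
    cfg: TrainConfig,
    prior: AR1Prior,
    kl_weight: float,
    optimizer: Adam,
    rng: np.random.Generator,
    trainable: tuple[str, ...] = ("enc", "dec", "val"),
) -> dict[str, float]:
    """Clipped-surrogate update with value regression and AR(1) KL penalty.

    Advantages are GAE-computed per trajectory and normalized per batch;
    mini-batches are resampled over trajectories each epoch. Returns the
    mean diagnostics of the final epoch.
    """
    n_traj = batch.ref.shape[0]
    advs = np.zeros_like(batch.rewards)
    rets = np.zeros_like(batch.rewards)
    for i in range(n_traj):
        advs[i], rets[i] = gae(batch.rewards[i], batch.values[i], batch.dones[i],
                               cfg.gamma, cfg.gae_lambda)
    a_mean, a_sd = advs.mean(), advs.std() + 1e-8
    diag: dict[str, float] = {}
    for _ in range(cfg.epochs):
        order = rng.permutation(n_traj)
        for mb in range(cfg.n_minibatch):
            idx = order[mb * cfg.b_batch : (mb + 1) * cfg.b_batch]
            if idx.size == 0:
                continue
            flat = batch.flat(idx)
            adv = ((advs[idx] - a_mean) / a_sd).reshape(-1)
            ret = rets[idx].reshape(-1)
            old_logp = flat["logp"]
            params = policy.tensors(trainable)
            _, mu_e, logvar_e = encode(params, policy.n_layers, policy.d_z, flat["ref"],
                                       deterministic=True)
            logq = gaussian_log_prob(flat["z"], mu_e, logvar_e)
            logp_a = action_log_prob(params, policy.n_layers, policy.n_act,
                                     flat["z"], flat["proprio"], flat["u"])
            new_logp = logq + logp_a
            ratio = (new_logp - Tensor(old_logp)).exp()
            adv_t = Tensor(adv)
            surr = (ratio * adv_t).minimum(
                ratio.clip(1.0 - cfg.clip_eps, 1.0 + cfg.clip_eps) * adv_t
            )
            policy_loss = -surr.mean()
            full_obs = np.concatenate([flat["ref"], flat["proprio"]], axis=-1)
            v = value(params, policy.n_layers, full_obs)
            value_loss = (v - Tensor(ret)).square().mean()
            kl = ar1_kl(mu_e, logvar_e, flat["z_prev"], prior, flat["first"]).mean()
            # sample-based entropy of the joint latent/action density
            entropy = -new_logp.mean()
            loss = (
                policy_loss
                + cfg.value_coef * value_loss
                + kl_weight * kl
                - cfg.entropy_coef * entropy
            )
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite PPO loss (policy={policy_loss.data}, value={value_loss.data}, "
                    f"kl={kl.data})"
                )
            loss.backward()
            grads = {k: t.grad for k, t in params.items() if t.grad is not None}
            optimizer.step(policy.params, grads)
            diag = {
                "policy_loss": float(policy_loss.data),
                "value_loss": float(value_loss.data),
                "kl": float(kl.data),
                "kl_weight": float(kl_weight),
                "ratio_mean": float(ratio.data.mean()),
            }
    return diag


# ----------------------------------------------------------------------
# end-to-end training


def train_tracking(
    env: ImitationEnv,
    cfg: TrainConfig,
    prior: AR1Prior | None = None,
    log_path: str | Path | None = None,
    policy: PolicyParams | None = None,
) -> tuple[PolicyParams, WelfordStats, list[dict]]:
    """Train an encoder-decoder policy on a tracking environment with PPO.

    Deterministic per config seed under serial execution. Returns the
    trained parameters, the observation statistics (required at inference)
    and the per-iteration history.
    """
    rng = np.random.default_rng(cfg.seed)
    prior = prior or AR1Prior(ramp_steps=cfg.total_steps // 10)
    p_dim, r_dim = env.obs_dims()
    if policy is None:
        policy = PolicyParams.initialize(
            rng, ref_dim=r_dim, proprio_dim=p_dim, n_act=env.action_dim,
            d_z=cfg.d_z, hidden=cfg.hidden, prior=prior,
        )
    runner = Runner(env, policy, cfg, rng)
    optimizer = Adam(list(policy.params.keys()), cfg.lr)
    history: list[dict] = []
    log_f = open(log_path, "w") if log_path is not None else None
    while runner.total_steps < cfg.total_steps:
        batch = runner.collect()
        kl_w = prior.weight(runner.total_steps)
        diag = ppo_update(policy, batch, cfg, prior, kl_w, optimizer, rng)
        recent = runner.completed_rewards[-20:]
        row = {
            "steps": runner.total_steps,
            "mean_episode_reward": float(np.mean(recent)) if recent else float("nan"),
            "mean_step_reward": float(batch.rewards.mean()),
            **runner.reward_component_means(),
            **diag,
        }
        history.append(row)
        if log_f is not None:
            log_f.write(json.dumps(row) + "\n")
    if log_f is not None:
        log_f.close()
    return policy, runner.stats, history


def evaluate_policy(
    env: ImitationEnv,
    policy: PolicyParams,
    stats: WelfordStats,
    n_episodes: int,
    rng: np.random.Generator,
    t_episode: int = 10_000,
) -> float:
    """Mean episode reward under the deterministic (mean-action) policy."""
    p_dim, _ = env.obs_dims()
    totals = []
    for _ in range(n_episodes):
        state = env.reset(rng)
        total, steps = 0.0, 0
        while not state.done and steps < t_episode:
            p, r = build_observation(env.tree, state, env.clips[state.clip_id], env.lookahead)
            norm = stats.normalize(np.concatenate([p.flat(), r.flat()]))
            prop_n, ref_n = norm[:p_dim], norm[p_dim:]
            z, _, _ = encode(policy.params, policy.n_layers, policy.d_z, ref_n[None],
                             deterministic=True)
            a, _, _ = decode(policy.params, policy.n_layers, policy.n_act, z, prop_n[None],
                             deterministic=True)
            state, r_t, _ = env.step(state, a.data[0])
            total += r_t
            steps += 1
        totals.append(total)
    return float(np.mean(totals))


def oracle_episode_reward(env: ImitationEnv, rng: np.random.Generator, n_episodes: int = 5,
                          t_episode: int = 10_000) -> float:
    """Mean episode reward of the feed-forward oracle controller."""
    totals = []
    for _ in range(n_episodes):
        state = env.reset(rng)
        total, steps = 0.0, 0
        while not state.done and steps < t_episode:
            state, r_t, _ = env.step(state, env.oracle_action(state))
            total += r_t
            steps += 1
        totals.append(total)
    return float(np.mean(totals))


# ----------------------------------------------------------------------
# checkpoints


def save_checkpoint(path, policy: PolicyParams, stats: WelfordStats, cfg: TrainConfig) -> None:
    """Flat array archive + config snapshot + observation statistics.

    The Welford statistics are part of the checkpoint because inference
    parity requires normalizing observations exactly as during training.
    """
    meta = {
        "d_z": policy.d_z, "n_act": policy.n_act, "ref_dim": policy.ref_dim,
        "proprio_dim": policy.proprio_dim, "hidden": list(policy.hidden),
        "prior_alpha": policy.prior.alpha, "prior_ramp_steps": policy.prior.ramp_steps,
        "prior_final_weight": policy.prior.final_weight,
        "cfg": {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in cfg.__dict__.items()},
    }
    arrays = {f"param:{k}": v for k, v in policy.params.items()}
    arrays["welford:count"] = np.array(stats.count)
    arrays["welford:mean"] = stats.mean
    arrays["welford:m2"] = stats.m2
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[PolicyParams, WelfordStats, TrainConfig]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        params = {k[len("param:"):]: data[k] for k in data.files if k.startswith("param:")}
        stats = WelfordStats(float(data["welford:count"]), data["welford:mean"],
                             data["welford:m2"])
    prior = AR1Prior(meta["prior_alpha"], meta["prior_ramp_steps"], meta["prior_final_weight"])
    policy = PolicyParams(params, meta["d_z"], meta["n_act"], meta["ref_dim"],
                          meta["proprio_dim"], tuple(meta["hidden"]), prior)
    cfg_kwargs = dict(meta["cfg"])
    cfg_kwargs["hidden"] = tuple(cfg_kwargs["hidden"])
    return policy, stats, TrainConfig(**cfg_kwargs)


# ----------------------------------------------------------------------
# the 1-DoF tracking toy


def make_sinusoid_clip(
    n_frames: int = 200, rate: float = 50.0, amplitude: float = 0.8, freq_hz: float = 0.5
) -> ReferenceClip:
    """Reference clip for the pendulum: q(t) = A sin(2 pi f t)."""
    t = np.arange(n_frames) / rate
    q = amplitude * np.sin(2 * np.pi * freq_hz * t)
    qpos = np.zeros((n_frames, 8))
    qpos[:, 3] = 1.0  # identity quaternion
    qpos[:, 7] = q
    qvel = np.zeros((n_frames, 7))
    qvel[:, 6] = amplitude * 2 * np.pi * freq_hz * np.cos(2 * np.pi * freq_hz * t)
    return ReferenceClip(qpos, qvel, rate, name="sinusoid")


def make_quadruped_track_env(
    n_frames: int = 200,
    rate: float = 50.0,
    amplitude: float = 0.3,
    lookahead: int = 5,
    reset_noise_sd: float = 0.005,
) -> ImitationEnv:
    """Whole-body tracking toy: the quadruped fixture following a scripted
    sinusoidal gait-like clip (free root, 14 action channels)."""
    from kinemimic import quat
    from kinemimic.bodies import make_quadruped_fixture

    tree = make_quadruped_fixture()
    lo, hi = tree.joint_ranges
    qpos = np.zeros((n_frames, 7 + tree.n_dof))
    t = np.arange(n_frames) / n_frames
    qpos[:, 0] = 0.1 * t
    qpos[:, 2] = getattr(tree, "default_root_height", 0.2)
    for k in range(n_frames):
        qpos[k, 3:7] = quat.from_axis_angle([0, 0, 1], 0.2 * t[k])
        qpos[k, 7:] = np.clip(
            amplitude * np.sin(2 * np.pi * t[k] + 0.5 * np.arange(tree.n_dof)), lo, hi
        )
    from kinemimic.stac import finite_difference_velocities

    clip = ReferenceClip(qpos, finite_difference_velocities(qpos, rate), rate, name="quad-gait")
    return ImitationEnv(tree, [clip], RewardSpec(), TerminationSpec(healthy_z=(0.05, 0.6)),
                        lookahead=lookahead, n_init=10, reset_noise_sd=reset_noise_sd)


def make_track1d_env(
    n_frames: int = 200,
    rate: float = 50.0,
    amplitude: float = 0.8,
    freq_hz: float = 0.5,
    lookahead: int = 5,
    reset_noise_sd: float = 0.01,
) -> ImitationEnv:
    """The 1-DoF sinusoid-tracking environment used for end-to-end checks."""
    tree = make_pendulum_fixture()
    clip = make_sinusoid_clip(n_frames, rate, amplitude, freq_hz)
    reward = RewardSpec(lam_pos=0.0, lam_quat=0.0, lam_joint=1.0, lam_ee=0.0, sigma_joint=0.5)
    term = TerminationSpec(healthy_z=(-0.5, 1.0), max_pos_err=1.0, max_ori_err=3.0,
                           max_joint_err=2.0)
    return ImitationEnv(tree, [clip], reward, term, lookahead=lookahead,
                        n_init=10, reset_noise_sd=reset_noise_sd)
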