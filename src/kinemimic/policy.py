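"""Encoder-decoder stochastic policy with an AR(1)-regularized latent space.

The policy factorizes as a variational bottleneck: an encoder maps the
reference (look-ahead) observation to a diagonal Gaussian over a latent
"motor intention" z; a decoder maps (z, proprioception) to a pre-squash
Gaussian whose sample is passed through tanh to bound actions in (-1, 1).
A first-order autoregressive prior over the latent sequence — z_t close to
alpha * z_{t-1}, with stationary variance 1 - alpha^2 — is enforced through
a KL penalty, encouraging temporally correlated intentions that remain
explorable when the decoder is later reused on new tasks.

Networks are plain MLPs with SiLU activations followed by layer
normalization (value network: ReLU-like SiLU too, see below) and
LeCun-uniform fan-in initialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from kinemimic.autodiff import Tensor, concat, gaussian_log_prob, layer_norm, tanh_correction


@dataclass
class AR1Prior:
    """First-order autoregressive latent prior.

    The stationary choice prior_var = 1 - alpha^2 keeps the marginal latent
    variance at 1 for any alpha; at the default alpha = 0.95 that gives
    0.0975. The KL weight ramps linearly from 0 to ``final_weight`` over
    ``ramp_steps`` environment steps.
    """

    alpha: float = 0.95
    ramp_steps: int = 100_000
    final_weight: float = 1e-3

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def prior_var(self) -> float:
        return 1.0 - self.alpha ** 2

    def weight(self, step: int) -> float:
        if self.ramp_steps <= 0:
            return self.final_weight
        return self.final_weight * min(max(step, 0) / self.ramp_steps, 1.0)


# ----------------------------------------------------------------------
# MLPs


def _lecun_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(3.0 / fan_in)
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_mlp(rng: np.random.Generator, sizes: list[int], prefix: str) -> dict[str, np.ndarray]:
    params: dict[str, np.ndarray] = {}
    for i, (a, b) in enumerate(zip(sizes[:-1], sizes[1:])):
        params[f"{prefix}.w{i}"] = _lecun_uniform(rng, a, b)
        params[f"{prefix}.b{i}"] = np.zeros(b)
    return params


def mlp_forward(params: dict, prefix: str, x: Tensor, n_layers: int) -> Tensor:
    """SiLU + layer-norm hidden layers, linear output layer."""
    for i in range(n_layers):
        w = params[f"{prefix}.w{i}"]
        b = params[f"{prefix}.b{i}"]
        w = w if isinstance(w, Tensor) else Tensor(w)
        b = b if isinstance(b, Tensor) else Tensor(b)
        x = x @ w + b
        if i < n_layers - 1:
            x = layer_norm(x.silu())
    return x


@dataclass
class PolicyParams:
    """Flat parameter store for encoder, decoder and value networks."""

    params: dict[str, np.ndarray]
    d_z: int
    n_act: int
    ref_dim: int
    proprio_dim: int
    hidden: tuple[int, ...] = (256, 256)
    prior: AR1Prior = field(default_factory=AR1Prior)

    @property
    def n_layers(self) -> int:
        return len(self.hidden) + 1

    @staticmethod
    def initialize(
        rng: np.random.Generator,
        ref_dim: int,
        proprio_dim: int,
        n_act: int,
        d_z: int = 60,
        hidden: tuple[int, ...] = (256, 256),
        prior: AR1Prior | None = None,
    ) -> "PolicyParams":
        h = list(hidden)
        params = {}
        params.update(init_mlp(rng, [ref_dim] + h + [2 * d_z], "enc"))
        params.update(init_mlp(rng, [d_z + proprio_dim] + h + [2 * n_act], "dec"))
        params.update(init_mlp(rng, [ref_dim + proprio_dim] + h + [1], "val"))
        # start the action distribution tight-ish and the latent near-unit
        params["dec.b%d" % len(h)][n_act:] = -1.0
        return PolicyParams(params, d_z, n_act, ref_dim, proprio_dim, tuple(hidden),
                            prior or AR1Prior())

    def tensors(self, trainable_prefixes: tuple[str, ...]) -> dict[str, Tensor]:
        return {
            k: Tensor(v, requires_grad=any(k.startswith(p) for p in trainable_prefixes))
            for k, v in self.params.items()
        }


# ----------------------------------------------------------------------
# heads


def encode(
    params: dict,
    n_layers: int,
    d_z: int,
    refobs: Tensor | np.ndarray,
    rng: np.random.Generator | None = None,
    deterministic: bool = False,
) -> tuple[Tensor, Tensor, Tensor]:
    """Sample the latent by reparameterization: z = mu + exp(logvar/2) * eps.

    Deterministic mode (inference) returns the mean. ``logvar`` is clipped to
    a sane range before exponentiation.
    """
    x = refobs if isinstance(refobs, Tensor) else Tensor(refobs)
    out = mlp_forward(params, "enc", x, n_layers)
    mu = out[..., :d_z]
    logvar = out[..., d_z:].clip(-10.0, 2.0)
    if deterministic:
        return mu, mu, logvar
    if rng is None:
        raise ValueError("stochastic encode needs an rng")
    eps = rng.standard_normal(mu.shape)
    z = mu + (0.5 * logvar).exp() * Tensor(eps)
    return z, mu, logvar


def decode(
    params: dict,
    n_layers: int,
    n_act: int,
    z: Tensor | np.ndarray,
    proprio: Tensor | np.ndarray,
    rng: np.random.Generator | None = None,
    deterministic: bool = False,
) -> tuple[Tensor, Tensor, Tensor]:
    """tanh-squashed Gaussian action head.

    Returns (action, pre-squash sample u, log-prob of the action), where the
    log-prob includes the tanh change-of-variables correction. Deterministic
    mode returns tanh of the mean (log-prob evaluated at that point).
    """
    z = z if isinstance(z, Tensor) else Tensor(z)
    p = proprio if isinstance(proprio, Tensor) else Tensor(proprio)
    out = mlp_forward(params, "dec", concat([z, p], axis=-1), n_layers)
    mu = out[..., :n_act]
    logvar = out[..., n_act:].clip(-10.0, 2.0)
    if deterministic:
        u = mu
    else:
        if rng is None:
            raise ValueError("stochastic decode needs an rng")
        eps = rng.standard_normal(mu.shape)
        u = mu + (0.5 * logvar).exp() * Tensor(eps)
    action = u.tanh()
    logp = gaussian_log_prob(u, mu, logvar) - tanh_correction(u)
    return action, u, logp


def action_log_prob(params: dict, n_layers: int, n_act: int, z, proprio, u) -> Tensor:
    """Log-prob of a stored pre-squash action under (possibly new) parameters."""
    z = z if isinstance(z, Tensor) else Tensor(z)
    p = proprio if isinstance(proprio, Tensor) else Tensor(proprio)
    out = mlp_forward(params, "dec", concat([z, p], axis=-1), n_layers)
    mu = out[..., :n_act]
    logvar = out[..., n_act:].clip(-10.0, 2.0)
    u = u if isinstance(u, Tensor) else Tensor(u)
    return gaussian_log_prob(u, mu, logvar) - tanh_correction(u)


def value(params: dict, n_layers: int, obs: Tensor | np.ndarray) -> Tensor:
    x = obs if isinstance(obs, Tensor) else Tensor(obs)
    return mlp_forward(params, "val", x, n_layers)[..., 0]


def ar1_kl(
    mu: Tensor,
    logvar: Tensor,
    z_prev: np.ndarray | None,
    prior: AR1Prior,
    first_mask: np.ndarray | None = None,
) -> Tensor:
    """KL from the encoder posterior to the AR(1) prior, summed over latent dims.

    First latent of an episode: KL(N(mu, S) || N(0, I)). Later latents:
    KL(N(mu, S) || N(alpha z_prev, (1 - alpha^2) I)). With batches,
    ``first_mask`` marks episode-start rows (z_prev rows there are ignored).
    Returns the per-row KL (shape = batch).
    """
    var = logvar.exp()
    if z_prev is None:
        prior_mean = np.zeros(mu.shape)
        prior_var = np.ones(mu.shape)
    else:
        prior_mean = prior.alpha * np.asarray(z_prev, dtype=float)
        prior_var = np.full(mu.shape, prior.prior_var)
        if first_mask is not None:
            fm = np.asarray(first_mask, dtype=bool)[..., None]
            prior_mean = np.where(fm, 0.0, prior_mean)
            prior_var = np.where(fm, 1.0, prior_var)
    pv = Tensor(prior_var)
    d = mu - Tensor(prior_mean)
    per_dim = 0.5 * ((pv.log() - logvar) + (var + d.square()) / pv - 1.0)
    return per_dim.sum(axis=-1)


# ----------------------------------------------------------------------
# frozen-decoder transfer


class TransferPolicy:
    """Task policy driving a pretrained decoder.

    Modes: ``frozen`` (decoder fixed, only the task head trains — the
    intended reuse), ``learnable`` (decoder fine-tunes too), ``scratch``
    (no decoder: the task head outputs pre-squash actions directly).
    """

    def __init__(
        self,
        pretrained: PolicyParams,
        task_obs_dim: int,
        rng: np.random.Generator,
        mode: str = "frozen",
        hidden: tuple[int, ...] = (256, 256),
        d_z: int | None = None,
    ):
        if mode not in ("frozen", "learnable", "scratch"):
            raise ValueError(f"unknown transfer mode {mode!r}")
        d_z = pretrained.d_z if d_z is None else d_z
        if mode != "scratch" and d_z != pretrained.d_z:
            raise ValueError(
                f"task-policy latent dim {d_z} != pretrained decoder latent dim {pretrained.d_z}"
            )
        self.mode = mode
        self.pretrained = pretrained
        self.d_z = d_z
        self.hidden = tuple(hidden)
        out_dim = pretrained.n_act if mode == "scratch" else d_z
        self.task_params = init_mlp(rng, [task_obs_dim] + list(hidden) + [out_dim], "task")

    @property
    def n_task_layers(self) -> int:
        return len(self.hidden) + 1

    def trainable_prefixes(self) -> tuple[str, ...]:
        return ("task", "dec") if self.mode == "learnable" else ("task",)

    def act(self, obs: np.ndarray, proprio: np.ndarray) -> np.ndarray:
        """Deterministic action for task observation(s)."""
        x = Tensor(np.asarray(obs, dtype=float))
        head = mlp_forward(self.task_params, "task", x, self.n_task_layers)
        if self.mode == "scratch":
            return np.tanh(head.data)
        a, _, _ = decode(
            self.pretrained.params, self.pretrained.n_layers, self.pretrained.n_act,
            head, np.asarray(proprio, dtype=float), deterministic=True,
        )
        return a.data


def transfer_step(
    tp: TransferPolicy,
    task_obs: np.ndarray,
    proprio: np.ndarray,
    target_actions: np.ndarray,
    lr: float = 1e-3,
) -> float:
    """One gradient step of transfer training (action regression).

    Gradients flow only through the parameters the mode marks trainable:
    the decoder stays bit-identical in ``frozen`` mode and updates in
    ``learnable`` mode; ``scratch`` has no decoder in the path at all.
    """
    train = tp.trainable_prefixes()
    params: dict = {}
    for k, v in tp.task_params.items():
        params[k] = Tensor(v, requires_grad=any(k.startswith(p) for p in train))
    for k, v in tp.pretrained.params.items():
        params[k] = Tensor(v, requires_grad=any(k.startswith(p) for p in train))
    head = mlp_forward(params, "task", Tensor(np.asarray(task_obs, dtype=float)),
                       tp.n_task_layers)
    if tp.mode == "scratch":
        action = head.tanh()
    else:
        action, _, _ = decode(
            params, tp.pretrained.n_layers, tp.pretrained.n_act,
            head, np.asarray(proprio, dtype=float), deterministic=True,
        )
    loss = (action - Tensor(np.asarray(target_actions, dtype=float))).square().mean()
    loss.backward()
    for k, t in params.items():
        if t.requires_grad and t.grad is not None:
            store = tp.task_params if k.startswith("task") else tp.pretrained.params
            store[k] = store[k] - lr * t.grad
    return float(loss.data)
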