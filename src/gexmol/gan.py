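"""Networks and losses of the two-stage conditional WGAN-GP.

Stage I maps (noise z, signature c) to a molecular latent; stage II refines
a molecular latent under the same condition through residual blocks.  Each
stage has a Wasserstein critic D (no output squashing) and a conditional
network f scoring whether a latent matches a signature, combined through
the SubMult+NN comparison (elementwise squared difference and elementwise
product of the two branch embeddings, then a dense layer).

Losses (per stage, identical in form):

    L_D = E[−D(x_real)] + E[D(G(·, c))] + λ·E[(‖∇_x̂ D(x̂)‖₂ − 1)²]
    L_G = E[−D(G(·, c)) − α·log f(G(·, c), c)]

with x̂ drawn uniformly on segments between paired real and generated
latents.  λ and α both default to 10.  The conditional networks are trained
with binary cross-entropy on matched versus within-batch shuffled pairs
(the matching-aware construction used throughout the conditional-GAN
literature); f outputs are clamped to [1e−7, 1−1e−7] before the log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gexmol import nn
from gexmol.autodiff import Tensor, as_tensor, concat, grad
from gexmol.exceptions import ConfigurationError, ShapeError

__all__ = [
    "GanConfig",
    "Stage1Generator",
    "Stage2Generator",
    "Critic",
    "ConditionalNet",
    "gradient_penalty",
    "loss_discriminator",
    "loss_generator",
    "conditional_net_loss",
    "sample_noise",
]


@dataclass(frozen=True)
class GanConfig:
    """Architecture and loss hyper-parameters.

    Defaults are the full-scale settings: 978 landmark genes, 1000-d noise,
    256-d molecular latents, branch MLPs of [512, 256], critics of
    [256, 256, 256, 1] with dropout 0.4 between the later layers, two
    residual blocks in stage II, and λ = α = 10.  ``toy`` builds a
    proportionally narrower configuration for desk-scale experiments.
    """

    n_genes: int = 978
    noise_dim: int = 1000
    latent_dim: int = 256
    lambda_gp: float = 10.0
    alpha_cond: float = 10.0
    leaky_slope: float = 0.2
    n_residual_blocks: int = 2
    cond_widths: tuple[int, ...] = (512, 256)
    noise_widths: tuple[int, ...] = (512, 256)
    merge_width: int = 256
    critic_widths: tuple[int, ...] = (256, 256, 256)
    critic_dropout: float = 0.4
    condnet_sig_widths: tuple[int, ...] = (512, 256)
    condnet_lat_widths: tuple[int, ...] = (256, 256)
    condnet_comp_width: int = 256
    condnet_dropout: float = 0.4
    f_clamp: float = 1e-7

    def __post_init__(self):
        if self.lambda_gp < 0 or self.alpha_cond < 0:
            raise ConfigurationError("lambda_gp and alpha_cond must be >= 0")
        if self.n_residual_blocks < 1:
            raise ConfigurationError("n_residual_blocks must be >= 1")
        widths = (
            *self.cond_widths, *self.noise_widths, self.merge_width,
            *self.critic_widths, *self.condnet_sig_widths,
            *self.condnet_lat_widths, self.condnet_comp_width,
        )
        if any(w <= 0 for w in widths):
            raise ConfigurationError("all layer widths must be positive")
        if self.condnet_sig_widths[-1] != self.condnet_lat_widths[-1]:
            raise ConfigurationError(
                "conditional-net branch embeddings must have equal width"
            )

    @classmethod
    def toy(
        cls,
        n_genes: int = 64,
        latent_dim: int = 96,
        noise_dim: int = 64,
        width: int = 64,
        **overrides,
    ) -> "GanConfig":
        """Desk-scale configuration with uniformly narrow layers."""
        defaults = dict(
            n_genes=n_genes,
            noise_dim=noise_dim,
            latent_dim=latent_dim,
            cond_widths=(width, width),
            noise_widths=(width, width),
            merge_width=width,
            critic_widths=(width, width, width),
            condnet_sig_widths=(width, width),
            condnet_lat_widths=(width, width),
            condnet_comp_width=width,
        )
        defaults.update(overrides)
        return cls(**defaults)


def sample_noise(rng: np.random.Generator, batch: int, config: GanConfig) -> np.ndarray:
    """Standard-normal noise vectors z ~ N(0, I)."""
    return rng.normal(size=(batch, config.noise_dim))


def _check_dim(name: str, x: Tensor, dim: int) -> None:
    if x.data.ndim != 2 or x.data.shape[1] != dim:
        raise ShapeError(f"{name}: expected (batch, {dim}), got {x.data.shape}")


class Stage1Generator(nn.Module):
    """G0(z, c): branch MLPs (LeakyReLU + batch norm), merge MLP, tanh output."""

    def __init__(self, config: GanConfig, rng: np.random.Generator):
        self.config = config
        self.cond_mlp = nn.MLP(
            config.n_genes, list(config.cond_widths), rng,
            leaky_slope=config.leaky_slope, batch_norm=True,
        )
        self.noise_mlp = nn.MLP(
            config.noise_dim, list(config.noise_widths), rng,
            leaky_slope=config.leaky_slope, batch_norm=True,
        )
        merged = config.cond_widths[-1] + config.noise_widths[-1]
        self.merge_hidden = nn.Dense(merged, config.merge_width, rng)
        self.out = nn.Dense(config.merge_width, config.latent_dim, rng)

    def __call__(self, z, c, training: bool = False) -> Tensor:
        z, c = as_tensor(z), as_tensor(c)
        _check_dim("noise", z, self.config.noise_dim)
        _check_dim("signature", c, self.config.n_genes)
        hz = self.noise_mlp(z, training=training)
        hc = self.cond_mlp(c, training=training)
        h = concat([hc, hz], axis=1)
        h = self.merge_hidden(h).leaky_relu(self.config.leaky_slope)
        return self.out(h).tanh()


class _ResidualBlock(nn.Module):
    """x ← x + W2·act(W1·x + b1) + b2."""

    def __init__(self, dim: int, slope: float, rng: np.random.Generator):
        self.w1 = nn.Dense(dim, dim, rng)
        self.w2 = nn.Dense(dim, dim, rng)
        self.slope = slope

    def __call__(self, x: Tensor) -> Tensor:
        return x + self.w2(self.w1(x).leaky_relu(self.slope))


class Stage2Generator(nn.Module):
    """G1(s0, c): condition MLP, concatenation, residual blocks, tanh output."""

    def __init__(self, config: GanConfig, rng: np.random.Generator):
        self.config = config
        self.cond_mlp = nn.MLP(
            config.n_genes, list(config.cond_widths), rng,
            leaky_slope=config.leaky_slope, batch_norm=True,
        )
        dim = config.cond_widths[-1] + config.latent_dim
        self.blocks = [
            _ResidualBlock(dim, config.leaky_slope, rng)
            for _ in range(config.n_residual_blocks)
        ]
        self.out = nn.Dense(dim, config.latent_dim, rng)

    def __call__(self, s0, c, training: bool = False) -> Tensor:
        s0, c = as_tensor(s0), as_tensor(c)
        _check_dim("latent", s0, self.config.latent_dim)
        _check_dim("signature", c, self.config.n_genes)
        hc = self.cond_mlp(c, training=training)
        x = concat([s0, hc], axis=1)
        for block in self.blocks:
            x = block(x)
        return self.out(x).tanh()


class Critic(nn.Module):
    """Wasserstein critic: [256, 256, 256, 1] MLP, dropout between late layers."""

    def __init__(self, config: GanConfig, rng: np.random.Generator):
        self.config = config
        w = config.critic_widths
        self.l1 = nn.Dense(config.latent_dim, w[0], rng)
        self.l2 = nn.Dense(w[0], w[1], rng)
        self.l3 = nn.Dense(w[1], w[2], rng)
        self.out = nn.Dense(w[2], 1, rng)
        self.drop = nn.Dropout(config.critic_dropout)

    def __call__(self, x, training: bool = False, rng: np.random.Generator | None = None) -> Tensor:
        x = as_tensor(x)
        _check_dim("latent", x, self.config.latent_dim)
        s = self.config.leaky_slope
        h = self.l1(x).leaky_relu(s)
        h = self.l2(h).leaky_relu(s)
        h = self.drop(h, training=training, rng=rng)
        h = self.l3(h).leaky_relu(s)
        h = self.drop(h, training=training, rng=rng)
        return self.out(h)


class ConditionalNet(nn.Module):
    """f(x, c): probability that latent x matches signature c (SubMult+NN)."""

    def __init__(self, config: GanConfig, rng: np.random.Generator):
        self.config = config
        self.sig_mlp = nn.MLP(
            config.n_genes, list(config.condnet_sig_widths), rng,
            leaky_slope=config.leaky_slope,
        )
        self.lat_mlp = nn.MLP(
            config.latent_dim, list(config.condnet_lat_widths), rng,
            leaky_slope=config.leaky_slope,
        )
        emb = config.condnet_sig_widths[-1]
        self.compare = nn.Dense(2 * emb, config.condnet_comp_width, rng)
        self.out = nn.Dense(config.condnet_comp_width, 1, rng)
        self.drop = nn.Dropout(config.condnet_dropout)

    def branches(self, x, c, training=False, rng=None) -> tuple[Tensor, Tensor]:
        x, c = as_tensor(x), as_tensor(c)
        _check_dim("latent", x, self.config.latent_dim)
        _check_dim("signature", c, self.config.n_genes)
        m = self.drop(self.lat_mlp(x), training=training, rng=rng)
        g = self.drop(self.sig_mlp(c), training=training, rng=rng)
        return m, g

    def __call__(self, x, c, training: bool = False, rng: np.random.Generator | None = None) -> Tensor:
        m, g = self.branches(x, c, training=training, rng=rng)
        diff = m - g
        sub = diff * diff
        mult = m * g
        h = self.compare(concat([sub, mult], axis=1)).leaky_relu(self.config.leaky_slope)
        return self.out(h).sigmoid()


# ---------------------------------------------------------------------------
# losses


def _apply_critic(critic, x: Tensor) -> Tensor:
    # accepts a Critic module or any callable Tensor -> Tensor
    if isinstance(critic, Critic):
        return critic(x, training=False)
    return critic(x)


def gradient_penalty(critic, real_batch, fake_batch, config: GanConfig, seed: int = 0) -> Tensor:
    """λ·E[(‖∇_x̂ D(x̂)‖₂ − 1)²] on uniform interpolates between pairs.

    The critic is evaluated as a deterministic function (no dropout) so the
    input gradient is well defined; differentiable w.r.t. critic weights.
    """
    real = as_tensor(real_batch)
    fake = as_tensor(fake_batch)
    if real.data.shape != fake.data.shape:
        raise ShapeError(
            f"real {real.data.shape} and fake {fake.data.shape} batches must match"
        )
    if real.data.shape[0] == 0:
        raise ValueError("empty batch")
    rng = np.random.default_rng(seed)
    eps = rng.uniform(size=(real.data.shape[0], 1))
    xhat = Tensor(eps * real.data + (1.0 - eps) * fake.data, requires_grad=True)
    score = _apply_critic(critic, xhat)
    g = grad(score.sum(), [xhat], create_graph=True)[0]
    norm = ((g * g).sum(axis=1) + 1e-12) ** 0.5
    return config.lambda_gp * ((norm - 1.0) ** 2).mean()


def loss_discriminator(
    critic,
    real_batch,
    generated_batch,
    config: GanConfig,
    seed: int = 0,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """E[−D(x_real)] + E[D(G(·))] + gradient penalty (either stage)."""
    real = as_tensor(real_batch)
    fake = as_tensor(generated_batch)
    if real.data.shape[0] == 0 or fake.data.shape[0] == 0:
        raise ValueError("empty batch")
    if isinstance(critic, Critic):
        d_real = critic(real, training=training, rng=rng)
        d_fake = critic(fake, training=training, rng=rng)
    else:
        d_real, d_fake = critic(real), critic(fake)
    loss = -1.0 * d_real.mean() + d_fake.mean()
    return loss + gradient_penalty(critic, real, fake, config, seed=seed)


def loss_generator(
    inputs,
    conditions,
    generator,
    critic,
    conditional_net,
    config: GanConfig,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """E[−D(G(·, c)) − α·log f(G(·, c), c)] (either stage).

    ``inputs`` is the noise batch for stage I or the stage-I latents for
    stage II; ``generator``/``critic``/``conditional_net`` select the stage.
    """
    gen = generator(inputs, conditions, training=training)
    if isinstance(critic, Critic):
        d = critic(gen, training=training, rng=rng)
    else:
        d = critic(gen)
    loss = -1.0 * d.mean()
    if config.alpha_cond > 0 and conditional_net is not None:
        f = conditional_net(gen, conditions)
        eps = config.f_clamp
        loss = loss - config.alpha_cond * f.clip(eps, 1.0 - eps).log().mean()
    return loss


def conditional_net_loss(
    real_pairs: tuple,
    mismatched_pairs: tuple,
    conditional_net,
    training: bool = False,
    rng: np.random.Generator | None = None,
    f_clamp: float = 1e-7,
) -> Tensor:
    """Binary cross-entropy: matched (latent, signature) pairs are positives,
    shuffled mismatches negatives."""
    (x_pos, c_pos), (x_neg, c_neg) = real_pairs, mismatched_pairs
    x_pos, c_pos = as_tensor(x_pos), as_tensor(c_pos)
    x_neg, c_neg = as_tensor(x_neg), as_tensor(c_neg)
    if x_pos.data.shape[0] == 0 or x_neg.data.shape[0] == 0:
        raise ValueError("empty batch")
    if isinstance(conditional_net, ConditionalNet):
        f_pos = conditional_net(x_pos, c_pos, training=training, rng=rng)
        f_neg = conditional_net(x_neg, c_neg, training=training, rng=rng)
    else:
        f_pos, f_neg = conditional_net(x_pos, c_pos), conditional_net(x_neg, c_neg)
    f_pos = f_pos.clip(f_clamp, 1.0 - f_clamp)
    f_neg = f_neg.clip(f_clamp, 1.0 - f_clamp)
    n_pos = f_pos.data.shape[0]
    n_neg = f_neg.data.shape[0]
    total = -1.0 * f_pos.log().sum() + -1.0 * (1.0 - f_neg).log().sum()
    return total * (1.0 / (n_pos + n_neg))
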