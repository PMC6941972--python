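"""Training loop of the stacked conditional WGAN-GP, with Fréchet monitoring.

Both stages are stepped in the same loop ("trained simultaneously"): within
each epoch of ``steps_per_epoch`` steps the critics and conditional nets
update every step and the generators once every ``g_update_every`` steps.
All six networks use RMSprop at a single learning rate (full-scale default
5e−5, 1000 epochs × 125 steps at batch 256).

At the end of each epoch one molecular latent is generated per monitored
training signature and compared with the real latent distribution through
the Fréchet distance

    d²((μr, Cr), (μg, Cg)) = ‖μg − μr‖² + Tr(Cg + Cr − 2(Cg·Cr)^{1/2}),

computed by eigendecomposition of Cr^{1/2}·Cg·Cr^{1/2} with negative
eigenvalues clipped at zero.

``ConditionalMoleculeGAN(latents, signatures).fit(seed=...)`` returns a
:class:`GanResults` carrying the trained parameter set, the per-epoch
history and generation methods.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from gexmol import nn
from gexmol.autodiff import Tensor, grad, no_grad
from gexmol.exceptions import ConfigurationError, ShapeError
from gexmol.gan import (
    ConditionalNet,
    Critic,
    GanConfig,
    Stage1Generator,
    Stage2Generator,
    conditional_net_loss,
    gradient_penalty,
    loss_generator,
    sample_noise,
)

__all__ = [
    "TrainingSchedule",
    "TrainingHistory",
    "DistributionMoments",
    "GanParams",
    "ConditionalMoleculeGAN",
    "GanResults",
    "train_gan",
    "compute_moments",
    "frechet_distance",
]


@dataclass(frozen=True)
class TrainingSchedule:
    """Optimization schedule; full-scale defaults, ``toy`` for desk scale."""

    epochs: int = 1000
    steps_per_epoch: int = 125
    batch_size: int = 256
    d_update_every: int = 1
    g_update_every: int = 10
    optimizer: str = "rmsprop"
    learning_rate: float = 5e-5
    monitor_subsample: int | None = None  # signatures per epoch-end FD check

    def __post_init__(self):
        if min(self.epochs, self.steps_per_epoch, self.batch_size,
               self.d_update_every, self.g_update_every) < 1:
            raise ConfigurationError("schedule values must be positive")
        if self.g_update_every < self.d_update_every:
            raise ConfigurationError("g_update_every must be >= d_update_every")
        if self.optimizer != "rmsprop":
            raise ConfigurationError(f"unsupported optimizer {self.optimizer!r}")

    @classmethod
    def toy(cls, epochs: int = 120, steps_per_epoch: int = 25, batch_size: int = 64,
            learning_rate: float = 1e-4, monitor_subsample: int | None = 128,
            **overrides) -> "TrainingSchedule":
        return cls(
            epochs=epochs, steps_per_epoch=steps_per_epoch, batch_size=batch_size,
            learning_rate=learning_rate, monitor_subsample=monitor_subsample,
            **overrides,
        )


@dataclass
class TrainingHistory:
    """Per-epoch mean losses and Fréchet distances."""

    d0: np.ndarray
    d1: np.ndarray
    g0: np.ndarray
    g1: np.ndarray
    f0: np.ndarray
    f1: np.ndarray
    frechet_stage1: np.ndarray
    frechet_stage2: np.ndarray
    wall_clock: np.ndarray

    def __len__(self):
        return len(self.d0)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(len(self)),
                "loss_d0": self.d0, "loss_d1": self.d1,
                "loss_g0": self.g0, "loss_g1": self.g1,
                "loss_f0": self.f0, "loss_f1": self.f1,
                "frechet_stage1": self.frechet_stage1,
                "frechet_stage2": self.frechet_stage2,
                "wall_clock": self.wall_clock,
            }
        )


class GanParams(nn.Module):
    """All trainable networks of both stages."""

    def __init__(self, config: GanConfig, rng: np.random.Generator):
        self.config = config
        self.g0 = Stage1Generator(config, rng)
        self.d0 = Critic(config, rng)
        self.f0 = ConditionalNet(config, rng)
        self.g1 = Stage2Generator(config, rng)
        self.d1 = Critic(config, rng)
        self.f1 = ConditionalNet(config, rng)


# ---------------------------------------------------------------------------
# moments + Fréchet distance


@dataclass(frozen=True)
class DistributionMoments:
    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self):
        cov = np.asarray(self.covariance, dtype=np.float64)
        if not np.allclose(cov, cov.T, atol=1e-8):
            raise ShapeError("covariance must be symmetric")
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=np.float64))
        object.__setattr__(self, "covariance", (cov + cov.T) / 2.0)


def compute_moments(batch: np.ndarray) -> DistributionMoments:
    """Sample mean and covariance of a batch of latent vectors."""
    batch = np.asarray(batch, dtype=np.float64)
    if batch.ndim != 2 or batch.shape[0] < 2:
        raise ValueError("need a 2-d batch with at least 2 rows")
    mean = batch.mean(axis=0)
    cov = np.cov(batch, rowvar=False)
    cov = np.atleast_2d(cov)
    return DistributionMoments(mean=mean, covariance=(cov + cov.T) / 2.0)


def _sqrtm_psd(mat: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    vals, vecs = np.linalg.eigh(mat)
    if vals.min() < -tol * max(1.0, abs(vals.max())):
        raise ValueError(f"matrix is not PSD (min eigenvalue {vals.min():.3e})")
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T

def frechet_distance(a: DistributionMoments, b: DistributionMoments) -> float:
    """Squared Fréchet distance between Gaussians with moments ``a`` and ``b``."""
    if a.mean.shape != b.mean.shape:
        raise ShapeError("moment dimensions differ")
    sqrt_a = _sqrtm_psd(a.covariance)
    inner = _sqrtm_psd(sqrt_a @ b.covariance @ sqrt_a)
    diff = a.mean - b.mean
    d2 = float(diff @ diff + np.trace(a.covariance + b.covariance) - 2.0 * np.trace(inner))
    return max(d2, 0.0) if d2 > -1e-8 else d2


# ---------------------------------------------------------------------------
# the model object


class ConditionalMoleculeGAN:
    """Stacked conditional WGAN-GP over paired (latent, signature) records.

    Latents are the translator encodings of the training molecules;
    signatures are the conditions. ``fit`` runs the full two-stage
    adversarial schedule and returns a :class:`GanResults`.
    """

    def __init__(
        self,
        latents: np.ndarray,
        signatures: np.ndarray,
        config: GanConfig | None = None,
        schedule: TrainingSchedule | None = None,
    ):
        latents = np.asarray(latents, dtype=np.float64)
        signatures = np.asarray(signatures, dtype=np.float64)
        if latents.ndim != 2 or signatures.ndim != 2:
            raise ShapeError("latents and signatures must be 2-d arrays")
        if latents.shape[0] != signatures.shape[0]:
            raise ShapeError("latents and signatures must pair row-for-row")
        if latents.shape[0] == 0:
            raise ConfigurationError("dataset must be nonempty")
        if config is None:
            config = GanConfig.toy(
                n_genes=signatures.shape[1], latent_dim=latents.shape[1]
            )
        if latents.shape[1] != config.latent_dim:
            raise ShapeError(
                f"latent dim {latents.shape[1]} != config {config.latent_dim}"
            )
        if signatures.shape[1] != config.n_genes:
            raise ShapeError(
                f"gene count {signatures.shape[1]} != config {config.n_genes}"
            )
        schedule = schedule or TrainingSchedule.toy()
        if schedule.batch_size > latents.shape[0]:
            raise ConfigurationError("batch_size exceeds dataset size")
        self.latents = latents
        self.signatures = signatures
        self.config = config
        self.schedule = schedule

    @classmethod
    def from_dataset(cls, translator_results, dataset, config=None, schedule=None):
        """Encode a paired SMILES/signature dataset with a fitted translator."""
        latents = translator_results.encode_batch(dataset.smiles)
        return cls(latents, dataset.signatures, config=config, schedule=schedule)

    # -- training -----------------------------------------------------------
    def fit(
        self,
        seed: int = 0,
        verbose: bool = False,
        stages: tuple[int, ...] = (1, 2),
    ) -> "GanResults":
        """Run the adversarial schedule; ``stages=(1,)`` trains stage I alone."""
        if not set(stages) <= {1, 2} or 1 not in stages:
            raise ConfigurationError("stages must be (1,) or (1, 2)")
        train2 = 2 in stages
        cfg, sched = self.config, self.schedule
        ss = np.random.SeedSequence(seed)
        (init_s, batch_s, noise_s, gp_s, drop_s, mon_s) = ss.spawn(6)
        init_rng = np.random.default_rng(init_s)
        batch_rng = np.random.default_rng(batch_s)
        noise_rng = np.random.default_rng(noise_s)
        gp_seed_rng = np.random.default_rng(gp_s)
        drop_rng = np.random.default_rng(drop_s)
        mon_rng = np.random.default_rng(mon_s)

        params = GanParams(cfg, init_rng)
        opts = {
            name: nn.RMSprop(getattr(params, name).parameters(), lr=sched.learning_rate)
            for name in ("g0", "d0", "f0", "g1", "d1", "f1")
        }

        n = self.latents.shape[0]
        mon_idx = np.arange(n)
        if sched.monitor_subsample is not None and sched.monitor_subsample < n:
            mon_idx = mon_rng.choice(n, size=sched.monitor_subsample, replace=False)
        real_moments = compute_moments(self.latents[mon_idx]) if len(mon_idx) >= 2 else None

        hist = {k: [] for k in ("d0", "d1", "g0", "g1", "f0", "f1", "fd1", "fd2", "wall")}
        t_start = time.time()
        for epoch in range(sched.epochs):
            sums = dict.fromkeys(("d0", "d1", "g0", "g1", "f0", "f1"), 0.0)
            counts = dict.fromkeys(sums, 0)
            for step in range(sched.steps_per_epoch):
                idx = batch_rng.integers(0, n, size=sched.batch_size)
                x_real = self.latents[idx]
                c = self.signatures[idx]
                z = sample_noise(noise_rng, sched.batch_size, cfg)

                # fakes (training mode so batch-norm statistics track the run),
                # detached so critic updates do not touch generator weights
                s0 = params.g0(z, c, training=True)
                s0_d = s0.data.copy()
                fakes = [("d0", s0_d)]
                if train2:
                    s1_d = params.g1(s0_d, c, training=True).data.copy()
                    fakes.append(("d1", s1_d))

                if step % sched.d_update_every == 0:
                    for name, fake in fakes:
                        critic = getattr(params, name)
                        d_real = critic(Tensor(x_real), training=True, rng=drop_rng)
                        d_fake = critic(Tensor(fake), training=True, rng=drop_rng)
                        gp = gradient_penalty(
                            critic, x_real, fake, cfg,
                            seed=int(gp_seed_rng.integers(2**31)),
                        )
                        loss = -1.0 * d_real.mean() + d_fake.mean() + gp
                        opts[name].step(grad(loss, critic.parameters()))
                        sums[name] += float(loss.data)
                        counts[name] += 1

                    # conditional nets: matched vs within-batch shuffled pairs
                    shuffle = batch_rng.permutation(sched.batch_size)
                    for name in (("f0", "f1") if train2 else ("f0",)):
                        f_net = getattr(params, name)
                        loss = conditional_net_loss(
                            (x_real, c), (x_real, c[shuffle]), f_net,
                            training=True, rng=drop_rng, f_clamp=cfg.f_clamp,
                        )
                        opts[name].step(grad(loss, f_net.parameters()))
                        sums[name] += float(loss.data)
                        counts[name] += 1

                if (step + 1) % sched.g_update_every == 0:
                    z2 = sample_noise(noise_rng, sched.batch_size, cfg)
                    idx2 = batch_rng.integers(0, n, size=sched.batch_size)
                    c2 = self.signatures[idx2]
                    loss_g0 = loss_generator(
                        z2, c2, params.g0, params.d0, params.f0, cfg,
                        training=True, rng=drop_rng,
                    )
                    opts["g0"].step(grad(loss_g0, params.g0.parameters()))
                    sums["g0"] += float(loss_g0.data)
                    counts["g0"] += 1

                    if train2:
                        with no_grad():
                            s0_for_g1 = params.g0(z2, c2, training=True).data
                        loss_g1 = loss_generator(
                            s0_for_g1, c2, params.g1, params.d1, params.f1, cfg,
                            training=True, rng=drop_rng,
                        )
                        opts["g1"].step(grad(loss_g1, params.g1.parameters()))
                        sums["g1"] += float(loss_g1.data)
                        counts["g1"] += 1

            for key in sums:
                hist[key].append(sums[key] / max(counts[key], 1))
            fd1 = fd2 = np.nan
            if real_moments is not None:
                gen1, gen2 = self._monitor_latents(params, mon_idx, noise_rng)
                fd1 = frechet_distance(real_moments, compute_moments(gen1))
                if train2:
                    fd2 = frechet_distance(real_moments, compute_moments(gen2))
            hist["fd1"].append(fd1)
            hist["fd2"].append(fd2)
            hist["wall"].append(time.time() - t_start)
            if verbose:
                print(
                    f"epoch {epoch}: D0 {hist['d0'][-1]:.3f} G0 {hist['g0'][-1]:.3f} "
                    f"FD1 {fd1:.3f} FD2 {fd2:.3f}"
                )

        history = TrainingHistory(
            d0=np.array(hist["d0"]), d1=np.array(hist["d1"]),
            g0=np.array(hist["g0"]), g1=np.array(hist["g1"]),
            f0=np.array(hist["f0"]), f1=np.array(hist["f1"]),
            frechet_stage1=np.array(hist["fd1"]),
            frechet_stage2=np.array(hist["fd2"]),
            wall_clock=np.array(hist["wall"]),
        )
        return GanResults(model=self, params=params, history=history, seed=seed)

    def _monitor_latents(self, params: GanParams, mon_idx, rng):
        """One generated latent per monitored training signature, both stages."""
        c = self.signatures[mon_idx]
        z = sample_noise(rng, len(mon_idx), self.config)
        with no_grad():
            s0 = params.g0(z, c, training=False).data
            s1 = params.g1(s0, c, training=False).data
        return s0, s1


@dataclass
class GanResults:
    """Fitted stacked GAN: parameters, history, conditional generation."""

    model: ConditionalMoleculeGAN
    params: GanParams
    history: TrainingHistory
    seed: int = 0

    @property
    def config(self) -> GanConfig:
        return self.model.config

    def generate_latents(
        self,
        signatures: np.ndarray,
        n_per_signature: int = 1,
        stage: int = 2,
        seed: int = 0,
    ) -> np.ndarray:
        """Generate latents per condition; shape (n_signatures, n_per, L)."""
        if stage not in (1, 2):
            raise ConfigurationError("stage must be 1 or 2")
        signatures = np.atleast_2d(np.asarray(signatures, dtype=np.float64))
        rng = np.random.default_rng(seed)
        cfg = self.config
        outs = []
        with no_grad():
            for sig in signatures:
                c = np.repeat(sig[None, :], n_per_signature, axis=0)
                z = sample_noise(rng, n_per_signature, cfg)
                s = self.params.g0(z, c, training=False).data
                if stage == 2:
                    s = self.params.g1(s, c, training=False).data
                outs.append(s)
        return np.stack(outs)

    def refine_latents(self, latents: np.ndarray, signature: np.ndarray) -> np.ndarray:
        """Stage-II refinement of arbitrary latents toward a condition."""
        latents = np.atleast_2d(np.asarray(latents, dtype=np.float64))
        c = np.repeat(np.asarray(signature, dtype=np.float64)[None, :], latents.shape[0], axis=0)
        with no_grad():
            return self.params.g1(latents, c, training=False).data

    def conditional_score(
        self, latents: np.ndarray, signatures: np.ndarray, stage: int = 1
    ) -> np.ndarray:
        """f-network match probability for (latent, signature) pairs."""
        f_net = self.params.f0 if stage == 1 else self.params.f1
        with no_grad():
            out = f_net(np.atleast_2d(latents), np.atleast_2d(signatures))
        return out.data.ravel()

    def summary(self) -> str:
        cfg, sched = self.config, self.model.schedule
        h = self.history
        lines = [
            "Conditional stacked WGAN-GP",
            "=" * 34,
            f"records               {self.model.latents.shape[0]}",
            f"genes (condition)     {cfg.n_genes}",
            f"latent dimension      {cfg.latent_dim}",
            f"noise dimension       {cfg.noise_dim}",
            f"lambda (grad penalty) {cfg.lambda_gp}",
            f"alpha (conditional)   {cfg.alpha_cond}",
            f"epochs x steps        {sched.epochs} x {sched.steps_per_epoch}",
            f"batch size            {sched.batch_size}",
            f"learning rate         {sched.learning_rate}",
            f"final losses          D0 {h.d0[-1]:.3f}  D1 {h.d1[-1]:.3f}  "
            f"G0 {h.g0[-1]:.3f}  G1 {h.g1[-1]:.3f}",
            f"Frechet (stage I)     {h.frechet_stage1[0]:.3f} -> {h.frechet_stage1[-1]:.3f}",
            f"Frechet (stage II)    {h.frechet_stage2[0]:.3f} -> {h.frechet_stage2[-1]:.3f}",
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        cfg, sched = self.config, self.model.schedule
        config = {
            "kind": "gexmol-gan",
            "schema": 1,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(cfg).items()
            },
            "schedule": {k: v for k, v in vars(sched).items()},
            "seed": self.seed,
        }
        state = self.params.state_dict()
        for name in ("d0", "d1", "g0", "g1", "f0", "f1"):
            state[f"history/{name}"] = getattr(self.history, name)
        state["history/fd1"] = self.history.frechet_stage1
        state["history/fd2"] = self.history.frechet_stage2
        state["history/wall"] = self.history.wall_clock
        state["data/latents"] = self.model.latents
        state["data/signatures"] = self.model.signatures
        nn.save_archive(path, config, state)

    @classmethod
    def load(cls, path) -> "GanResults":
        config, state = nn.load_archive(path)
        if config.get("kind") != "gexmol-gan":
            raise ConfigurationError("not a GAN archive")
        cfg_kw = dict(config["config"])
        for key, val in cfg_kw.items():
            if isinstance(val, list):
                cfg_kw[key] = tuple(val)
        cfg = GanConfig(**cfg_kw)
        sched = TrainingSchedule(**config["schedule"])
        latents = state.pop("data/latents")
        signatures = state.pop("data/signatures")
        history = TrainingHistory(
            d0=state.pop("history/d0"), d1=state.pop("history/d1"),
            g0=state.pop("history/g0"), g1=state.pop("history/g1"),
            f0=state.pop("history/f0"), f1=state.pop("history/f1"),
            frechet_stage1=state.pop("history/fd1"),
            frechet_stage2=state.pop("history/fd2"),
            wall_clock=state.pop("history/wall"),
        )
        model = ConditionalMoleculeGAN(latents, signatures, config=cfg, schedule=sched)
        params = GanParams(cfg, np.random.default_rng(0))
        params.load_state_dict(state)
        return cls(model=model, params=params, history=history, seed=config.get("seed", 0))


def train_gan(
    latents: np.ndarray,
    signatures: np.ndarray,
    schedule: TrainingSchedule | None = None,
    config: GanConfig | None = None,
    seed: int = 0,
    verbose: bool = False,
) -> GanResults:
    """Functional wrapper: build the model and fit it in one call."""
    return ConditionalMoleculeGAN(
        latents, signatures, config=config, schedule=schedule
    ).fit(seed=seed, verbose=verbose)
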