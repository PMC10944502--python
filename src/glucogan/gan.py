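"""Sequence-to-sequence conditional Wasserstein GAN.

The generator maps one normalized (PI, RA) condition pair plus a normal
latent vector z to a window of 18 future BG samples; the critic scores the
concatenated signal [PI, RA, BG window] (length 2 + 18).  Training follows
the classic weight-clipped WGAN recipe: the critic loss is

    mean(critic(fake)) - mean(critic(real))

(minimised by the critic — equivalent to maximising the Kantorovich-
Rubinstein dual objective), every critic update is followed by clipping all
critic parameters to [-c, c], the critic takes ``n_critic`` updates per
generator update, and the generator minimises

    -mean(critic(fake)) + lambda_l2 * MSE(fake_window, real_window)

so it both fools the critic and stays close to the paired ground truth.
Real windows carry label -1 and generated windows label +1; the Wasserstein
losses never consume the labels numerically, they are kept as metadata of the
convention.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import asdict, dataclass, field
from io import BytesIO

import numpy as np
from sklearn.base import BaseEstimator

from .nn import (
    Conv1d,
    ConvTranspose1d,
    Dense,
    LeakyReLU,
    Reshape,
    RMSprop,
    Sequential,
)
from .preprocessing import (
    DEFAULT_SHIFT,
    SignalNormalizer,
    build_shifted_pairs,
    pairs_to_arrays,
    record_to_conditions,
)

REAL_LABEL = -1
FAKE_LABEL = 1


@dataclass
class TrainConfig:
    """Training protocol constants.

    Defaults are the weight-clipped WGAN recommendations (RMSprop, lr 5e-5,
    clip 0.01, 5 critic updates per generator update) with batch size 1 and
    50 epochs.
    """

    epochs: int = 50
    batch_size: int = 1
    n_critic: int = 5
    clip: float = 0.01
    lambda_l2: float = 10.0
    lr: float = 5e-5
    d_z: int = 32
    seed: int = 0
    shift: int = DEFAULT_SHIFT
    real_label: int = REAL_LABEL
    fake_label: int = FAKE_LABEL

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.n_critic < 1:
            raise ValueError("n_critic must be >= 1")
        if self.lambda_l2 < 0:
            raise ValueError("lambda_l2 must be >= 0")
        if self.clip <= 0:
            raise ValueError("clip must be positive")
        if not 0 < self.d_z < 100:
            raise ValueError("latent dimension must be in (0, 100)")


def critic_loss(real_scores, fake_scores) -> float:
    """Critic objective: mean(fake) - mean(real), minimised by the critic."""
    real_scores = np.atleast_1d(np.asarray(real_scores, float))
    fake_scores = np.atleast_1d(np.asarray(fake_scores, float))
    if real_scores.size == 0 or fake_scores.size == 0:
        raise ValueError("score collections must be non-empty")
    return float(fake_scores.mean() - real_scores.mean())


def generator_loss(fake_scores, generated_window, real_window,
                   lambda_l2: float) -> float:
    """Generator objective: -mean(fake scores) + lambda * MSE(gen, real)."""
    if lambda_l2 < 0:
        raise ValueError("lambda_l2 must be >= 0")
    fake_scores = np.atleast_1d(np.asarray(fake_scores, float))
    gen = np.asarray(generated_window, float)
    real = np.asarray(real_window, float)
    if gen.shape != real.shape:
        raise ValueError("generated and real windows must have equal shape")
    return float(-fake_scores.mean() + lambda_l2 * np.mean((gen - real) ** 2))


def clip_weights(net: Sequential, c: float) -> Sequential:
    """Clip every parameter of ``net`` to [-c, c] in place and return it."""
    net.clip_(c)
    return net


def _build_critic(shift: int, channels, kernels, strides,
                  rng: np.random.Generator) -> Sequential:
    layers: list = []
    c_in, length = 1, 2 + shift
    for i, (c_out, k, s) in enumerate(zip(channels, kernels, strides)):
        k = min(k, length)  # final stages collapse whatever length remains
        conv = Conv1d(c_in, c_out, k, s, rng)
        layers.append(conv)
        length = conv.out_length(length)
        if i < len(channels) - 1:
            layers.append(LeakyReLU(0.2))
        c_in = c_out
    if length != 1 or channels[-1] != 1:
        raise ValueError(
            f"critic stack does not collapse to a scalar (length {length})"
        )
    layers.append(Reshape(()))
    return Sequential(layers)


def _build_generator(shift: int, d_z: int, base_channels: int, channels,
                     rng: np.random.Generator) -> Sequential:
    layers: list = [
        Dense(2 + d_z, base_channels * shift, rng),
        Reshape((base_channels, shift)),
        LeakyReLU(0.2),
    ]
    c_in = base_channels
    for i, c_out in enumerate(channels):
        layers.append(ConvTranspose1d(c_in, c_out, 3, 1, rng, crop=(1, 1)))
        if i < len(channels) - 1:
            layers.append(LeakyReLU(0.2))
        c_in = c_out
    layers.append(Reshape((shift,)))
    return Sequential(layers)


class SeqToSeqWGAN(BaseEstimator):
    """Conditional WGAN estimator over causal (condition, window) pairs.

    Parameters follow :class:`TrainConfig`; architecture widths are exposed
    so desk-scale tests can shrink the networks.  ``fit`` expects
    min-max-normalized data: ``X`` of shape (n_pairs, 2) holding the (PI, RA)
    conditions and ``y`` of shape (n_pairs, shift) holding the future BG
    windows.

    Attributes
    ----------
    generator_, critic_ : Sequential
        Trained networks.
    loss_history_ : list of dict
        Per-epoch mean critic loss, generator adversarial loss and L2 term.
    n_critic_updates_, n_generator_updates_ : int
        Update bookkeeping (n_critic critic steps per generator step).
    """

    def __init__(self, epochs: int = 50, batch_size: int = 1, n_critic: int = 5,
                 clip: float = 0.01, lambda_l2: float = 10.0, lr: float = 5e-5,
                 d_z: int = 32, seed: int = 0, shift: int = DEFAULT_SHIFT,
                 critic_channels: tuple = (32, 64, 128, 64, 1),
                 critic_kernels: tuple = (4, 4, 3, 1, 1),
                 critic_strides: tuple = (2, 2, 1, 1, 1),
                 gen_base_channels: int = 8,
                 gen_channels: tuple = (64, 32, 16, 1)):
        self.epochs = epochs
        self.batch_size = batch_size
        self.n_critic = n_critic
        self.clip = clip
        self.lambda_l2 = lambda_l2
        self.lr = lr
        self.d_z = d_z
        self.seed = seed
        self.shift = shift
        self.critic_channels = critic_channels
        self.critic_kernels = critic_kernels
        self.critic_strides = critic_strides
        self.gen_base_channels = gen_base_channels
        self.gen_channels = gen_channels

    # -- internals -----------------------------------------------------

    def _init_networks(self, rng: np.random.Generator) -> None:
        self.critic_ = _build_critic(
            self.shift, self.critic_channels, self.critic_kernels,
            self.critic_strides, rng,
        )
        self.generator_ = _build_generator(
            self.shift, self.d_z, self.gen_base_channels, self.gen_channels, rng,
        )

    def _critic_input(self, X: np.ndarray, windows: np.ndarray) -> np.ndarray:
        return np.concatenate([X, windows], axis=1)[:, None, :]

    # -- estimator API -------------------------------------------------

    def fit(self, X, y):
        cfg = self.train_config()  # validates hyperparameters
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have shape (n_pairs, 2)")
        if y.ndim != 2 or y.shape[1] != self.shift:
            raise ValueError(f"y must have shape (n_pairs, {self.shift})")
        n = X.shape[0]
        if n == 0:
            raise ValueError("training set is empty")

        rng = np.random.default_rng(self.seed)
        self._init_networks(rng)
        opt_c = RMSprop(self.critic_, lr=self.lr)
        opt_g = RMSprop(self.generator_, lr=self.lr)

        self.loss_history_ = []
        self.n_critic_updates_ = 0
        self.n_generator_updates_ = 0

        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            c_losses, g_losses, l2_terms = [], [], []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb = X[idx], y[idx]
                b = len(idx)

                for _ in range(cfg.n_critic):
                    z = rng.standard_normal((b, self.d_z))
                    fake = self.generator_.forward(
                        np.concatenate([xb, z], axis=1)
                    )
                    # one combined pass: real windows then fake windows
                    cin = self._critic_input(
                        np.concatenate([xb, xb]), np.concatenate([yb, fake])
                    )
                    scores = self.critic_.forward(cin)
                    c_losses.append(critic_loss(scores[:b], scores[b:]))
                    dy = np.concatenate(
                        [np.full(b, -1.0 / b), np.full(b, 1.0 / b)]
                    )
                    self.critic_.backward(dy)
                    opt_c.step()
                    self.critic_.clip_(cfg.clip)
                    self.n_critic_updates_ += 1

                z = rng.standard_normal((b, self.d_z))
                fake = self.generator_.forward(np.concatenate([xb, z], axis=1))
                scores = self.critic_.forward(self._critic_input(xb, fake))
                l2 = float(np.mean((fake - yb) ** 2))
                g_losses.append(float(-scores.mean()))
                l2_terms.append(l2)
                dcin = self.critic_.backward(np.full(b, -1.0 / b))
                dfake = dcin[:, 0, 2:] + cfg.lambda_l2 * 2.0 * (fake - yb) / (
                    b * self.shift
                )
                self.generator_.backward(dfake)
                opt_g.step()
                self.n_generator_updates_ += 1

            self.loss_history_.append(
                {
                    "critic_loss": float(np.mean(c_losses)),
                    "generator_adv_loss": float(np.mean(g_losses)),
                    "l2_term": float(np.mean(l2_terms)),
                }
            )
        return self

    def generate(self, X, z=None, rng=None):
        """Generate one normalized BG window per condition row of ``X``."""
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, float))
        if z is None:
            rng = np.random.default_rng(rng) if not isinstance(
                rng, np.random.Generator
            ) else rng
            z = rng.standard_normal((X.shape[0], self.d_z))
        z = np.atleast_2d(np.asarray(z, float))
        if z.shape != (X.shape[0], self.d_z):
            raise ValueError(
                f"latent must have shape ({X.shape[0]}, {self.d_z}), got {z.shape}"
            )
        return self.generator_.forward(np.concatenate([X, z], axis=1))

    def score_pairs(self, X, windows):
        """Critic score of (condition, window) tuples."""
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, float))
        windows = np.atleast_2d(np.asarray(windows, float))
        if windows.shape[1] != self.shift:
            raise ValueError(f"window length must be {self.shift}")
        return self.critic_.forward(self._critic_input(X, windows))

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs, batch_size=self.batch_size,
            n_critic=self.n_critic, clip=self.clip, lambda_l2=self.lambda_l2,
            lr=self.lr, d_z=self.d_z, seed=self.seed, shift=self.shift,
        )

    def _check_fitted(self):
        if not hasattr(self, "generator_"):
            raise RuntimeError("model is not trained; call fit first")


def critic_score(est: SeqToSeqWGAN, pi: float, ra: float, bg_window) -> float:
    """Score one (PI, RA, BG window) tuple with the trained critic."""
    return float(est.score_pairs([[pi, ra]], [bg_window])[0])


def generate_window(est: SeqToSeqWGAN, pi: float, ra: float, z) -> np.ndarray:
    """Generate one normalized 18-sample BG window from (PI, RA, z)."""
    return est.generate([[pi, ra]], z=[z])[0]


@dataclass
class GanModel:
    """A trained model plus everything generation needs.

    Bundles the fitted estimator with the normalizers fitted on its training
    cohort and the id of the patient left out of training.
    """

    est: SeqToSeqWGAN
    normalizers: dict[str, SignalNormalizer]
    held_out_patient_id: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for key in ("pi", "ra", "bg"):
            if key not in self.normalizers:
                raise ValueError(f"missing normalizer for signal {key!r}")

    @property
    def shift(self) -> int:
        return self.est.shift

    def generate_windows(self, pi_norm, ra_norm, Z) -> np.ndarray:
        """Normalized windows for arrays of normalized conditions."""
        X = np.column_stack([pi_norm, ra_norm])
        return self.est.generate(X, z=Z)

    # -- checkpointing -------------------------------------------------

    def save(self, path) -> None:
        arrays = {}
        for tag, net in (("G", self.est.generator_), ("C", self.est.critic_)):
            for name, arr in net.state_arrays().items():
                arrays[f"{tag}.{name}"] = arr
        meta = {
            "params": self.est.get_params(),
            "normalizers": {
                k: [v.data_min_, v.data_max_] for k, v in self.normalizers.items()
            },
            "held_out_patient_id": self.held_out_patient_id,
            "train_config": asdict(self.est.train_config()),
            "meta": self.meta,
        }
        buf = BytesIO()
        np.savez(buf, **arrays)
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("weights.npz", buf.getvalue())
            zf.writestr("meta.json", json.dumps(meta, indent=2, default=str))

    @classmethod
    def load(cls, path) -> "GanModel":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            weights = np.load(BytesIO(zf.read("weights.npz")))
            params = meta["params"]
            for key in ("critic_channels", "critic_kernels", "critic_strides",
                        "gen_channels"):
                params[key] = tuple(params[key])
            est = SeqToSeqWGAN(**params)
            est._init_networks(np.random.default_rng(est.seed))
            est.generator_.load_state_arrays(
                {k[2:]: weights[k] for k in weights.files if k.startswith("G.")}
            )
            est.critic_.load_state_arrays(
                {k[2:]: weights[k] for k in weights.files if k.startswith("C.")}
            )
        normalizers = {
            k: SignalNormalizer.from_range(lo, hi)
            for k, (lo, hi) in meta["normalizers"].items()
        }
        return cls(
            est=est,
            normalizers=normalizers,
            held_out_patient_id=meta["held_out_patient_id"],
            meta=meta.get("meta", {}),
        )


def fit_cohort_normalizers(conditions: dict[str, tuple[np.ndarray, np.ndarray]],
                           records: dict[str, np.ndarray],
                           train_ids: list[str]) -> dict[str, SignalNormalizer]:
    """Fit per-signal min-max normalizers on the training patients only."""
    pi = np.concatenate([conditions[pid][0] for pid in train_ids])
    ra = np.concatenate([conditions[pid][1] for pid in train_ids])
    bg = np.concatenate([records[pid] for pid in train_ids])
    return {
        "pi": SignalNormalizer().fit(pi),
        "ra": SignalNormalizer().fit(ra),
        "bg": SignalNormalizer().fit(bg),
    }


def train(pairs, cfg: TrainConfig,
          normalizers: dict[str, SignalNormalizer] | None = None,
          **est_kwargs) -> GanModel:
    """Train a model on a sequence of (already normalized) PairedSamples."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("training set is empty")
    X, y = pairs_to_arrays(pairs)
    est = SeqToSeqWGAN(
        epochs=cfg.epochs, batch_size=cfg.batch_size, n_critic=cfg.n_critic,
        clip=cfg.clip, lambda_l2=cfg.lambda_l2, lr=cfg.lr, d_z=cfg.d_z,
        seed=cfg.seed, shift=cfg.shift, **est_kwargs,
    )
    est.fit(X, y)
    if normalizers is None:
        normalizers = {
            "pi": SignalNormalizer.from_range(0.0, 1.0),
            "ra": SignalNormalizer.from_range(0.0, 1.0),
            "bg": SignalNormalizer.from_range(0.0, 1.0),
        }
    return GanModel(est=est, normalizers=normalizers)


def loo_train(cohort, cfg: TrainConfig, **est_kwargs) -> dict[str, GanModel]:
    """Leave-one-out training: one model per patient, trained on the others.

    Conditions (PI, RA) are derived from each record, normalizers are fitted
    on the training patients only, and the held-out patient's id is recorded
    on its model.
    """
    cohort = list(cohort)
    if len(cohort) < 2:
        raise ValueError("leave-one-out needs at least 2 patients")
    conditions = {r.patient_id: record_to_conditions(r) for r in cohort}
    bg_by_id = {r.patient_id: r.bg for r in cohort}
    models: dict[str, GanModel] = {}
    for held_out in cohort:
        train_ids = [r.patient_id for r in cohort if r.patient_id != held_out.patient_id]
        norms = fit_cohort_normalizers(conditions, bg_by_id, train_ids)
        pairs = []
        for pid in train_ids:
            pi, ra = conditions[pid]
            pairs.extend(
                build_shifted_pairs(
                    norms["pi"].transform(pi),
                    norms["ra"].transform(ra),
                    norms["bg"].transform(bg_by_id[pid]),
                    shift=cfg.shift,
                )
            )
        model = train(pairs, cfg, normalizers=norms, **est_kwargs)
        model.held_out_patient_id = held_out.patient_id
        model.meta["train_patient_ids"] = train_ids
        models[held_out.patient_id] = model
    return models
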