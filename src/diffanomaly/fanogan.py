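"""f-AnoGAN-style anomaly model: Wasserstein GAN + encoder, and the local score.

The model of *normal* inter-visit appearance change is learned in two stages:

1. ``train_wgan`` — a generator G maps a latent vector z to a patch and a
   critic D scores realism; both are trained adversarially with the
   Wasserstein objective (critic weight clipping) on normal patches only.
2. ``train_encoder`` — with G and D frozen, an encoder E learns to embed a
   patch x into latent space so that the reconstruction y = G(E(x)) matches x
   (izif objective: pixel MSE plus MSE of the critic's intermediate features).

Scoring a patch x then yields
``L(x) = L_R(x) + k * L_D(x)``, k = 0.1, where ``L_R`` is the mean squared
pixel residual between x and y and ``L_D`` the mean squared difference of the
critic's intermediate features f(x) and f(y). A patch far from the learned
normal-change manifold reconstructs poorly and scores high.

Networks are small dense nets (see :mod:`diffanomaly.nn`); inputs are
normalized patches in [-1, 1], flattened internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import Adam, Dense, LeakyReLU, Sequential, Tanh
from .preprocess import NormStats

__all__ = [
    "ModelConfig",
    "AnomalyModel",
    "AnomalyScoreBreakdown",
    "build_networks",
    "train_wgan",
    "train_encoder",
    "reconstruct",
    "anomaly_score",
    "save_model",
    "load_model",
    "IdentityStubModel",
    "ConstantScoreModel",
]

DEFAULT_K = 0.1


@dataclass
class ModelConfig:
    """Architecture and optimisation settings for the anomaly model."""

    patch_side: int = 64
    latent_dim: int = 32
    width: int = 128              # hidden width of all three networks
    batch_size: int = 64
    critic_steps: int = 5         # critic updates per generator update
    gen_steps: int = 300          # generator updates for train_wgan
    encoder_steps: int = 400
    lr: float = 1e-4
    adam_beta1: float = 0.0
    adam_beta2: float = 0.9
    clip: float = 0.05            # Wasserstein critic weight-clipping bound
    kappa_feat: float = 1.0       # feature-loss weight in the encoder objective
    k: float = DEFAULT_K          # score weighting L = L_R + k * L_D
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def build_networks(config: ModelConfig) -> tuple[Sequential, Sequential, Sequential]:
    """Freshly initialised (G, D, E) for the configured patch size."""
    d = config.patch_side ** 2
    w = config.width
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed & 0x7FFFFFFF, 17]))
    G = Sequential([Dense(config.latent_dim, w, rng), LeakyReLU(),
                    Dense(w, w, rng), LeakyReLU(),
                    Dense(w, d, rng), Tanh()])
    D = Sequential([Dense(d, w, rng), LeakyReLU(),
                    Dense(w, w, rng), LeakyReLU(),
                    Dense(w, 1, rng)])
    E = Sequential([Dense(d, w, rng), LeakyReLU(),
                    Dense(w, w, rng), LeakyReLU(),
                    Dense(w, config.latent_dim, rng)])
    return G, D, E

# index of the critic layer whose activations are the feature map f(.)
# (the penultimate layer: everything before the final Dense)
_FEATURE_LAYERS = 4


def _critic_features(D: Sequential, x: np.ndarray) -> np.ndarray:
    return D.forward_upto(x, _FEATURE_LAYERS)


@dataclass
class AnomalyModel:
    """Trained G, D, E with scoring parameters and normalization statistics."""

    G: Sequential
    D: Sequential
    E: Sequential
    config: ModelConfig
    norm_stats: NormStats | None = None
    k: float = DEFAULT_K
    training_log: dict = field(default_factory=dict)

    @property
    def patch_side(self) -> int:
        return self.config.patch_side

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return reconstruct(x, self)

    def features(self, x_flat: np.ndarray) -> np.ndarray:
        return _critic_features(self.D, x_flat)


@dataclass
class AnomalyScoreBreakdown:
    """L = L_R + k * L_D, all components non-negative and finite."""

    L_R: np.ndarray
    L_D: np.ndarray
    L: np.ndarray
    k: float


def _as_batch(x: np.ndarray, patch_side: int) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        x = x[None]
        single = True
    elif x.ndim == 3:
        single = False
    else:
        raise ValueError(f"expected (p,p) or (n,p,p) patches, got shape {x.shape}")
    if x.shape[1] != patch_side or x.shape[2] != patch_side:
        raise ValueError(
            f"patch shape {x.shape[1:]} does not match model patch side {patch_side}"
        )
    return x, single


def train_wgan(normal_patches: np.ndarray, config: ModelConfig,
               seed: int | None = None) -> tuple[Sequential, Sequential, dict]:
    """Train (G, D) on normalized normal patches with the Wasserstein objective.

    The critic is regularized by weight clipping; ``critic_steps`` critic
    updates alternate with one generator update, for ``gen_steps`` rounds.
    Returns (G, D, loss_log). Deterministic given config/seed and a fixed
    BLAS thread count.
    """
    if seed is not None:
        config = ModelConfig(**{**config.to_dict(), "seed": seed})
    x = np.asarray(normal_patches, dtype=np.float64)
    if x.ndim == 3:
        x = x.reshape(x.shape[0], -1)
    n, d = x.shape
    if d != config.patch_side ** 2:
        raise ValueError(f"patches have {d} pixels, expected {config.patch_side ** 2}")
    if n < config.batch_size:
        raise ValueError(
            f"need at least batch_size={config.batch_size} patches, got {n}")

    G, D, _ = build_networks(config)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed & 0x7FFFFFFF, 23]))
    opt_G = Adam(G.params, config.lr, config.adam_beta1, config.adam_beta2)
    opt_D = Adam(D.params, config.lr, config.adam_beta1, config.adam_beta2)
    B = config.batch_size
    log = {"step": [], "critic_loss": [], "gen_loss": []}

    for step in range(config.gen_steps):
        closs = 0.0
        for _ in range(config.critic_steps):
            xr = x[rng.choice(n, B, replace=False)]
            z = rng.normal(size=(B, config.latent_dim))
            xf = G(z)
            D.zero_grad()
            sr = D(xr)
            D.backward(np.full_like(sr, -1.0 / B))   # maximize D(real)
            sf = D(xf)
            D.backward(np.full_like(sf, 1.0 / B))    # minimize D(fake)
            closs = float(sf.mean() - sr.mean())
            if not np.isfinite(closs):
                raise FloatingPointError(
                    f"non-finite critic loss at generator step {step}")
            opt_D.step(D.grads)
            D.clip_params(config.clip)
        z = rng.normal(size=(B, config.latent_dim))
        G.zero_grad()
        D.zero_grad()
        xf = G(z)
        sf = D(xf)
        gloss = float(-sf.mean())
        if not np.isfinite(gloss):
            raise FloatingPointError(f"non-finite generator loss at step {step}")
        gx = D.backward(np.full_like(sf, -1.0 / B))
        G.backward(gx)
        opt_G.step(G.grads)
        log["step"].append(step)
        log["critic_loss"].append(closs)
        log["gen_loss"].append(gloss)
    return G, D, log


def train_encoder(normal_patches: np.ndarray, G: Sequential, D: Sequential,
                  config: ModelConfig, seed: int | None = None
                  ) -> tuple[Sequential, dict]:
    """Train E with G, D frozen: minimise MSE(x, G(E(x))) + kappa * MSE(f(x), f(y)).

    The critic-feature term uses the activations of D's penultimate layer.
    Returns (E, loss_log).
    """
    if seed is not None:
        config = ModelConfig(**{**config.to_dict(), "seed": seed})
    x_all = np.asarray(normal_patches, dtype=np.float64)
    if x_all.ndim == 3:
        x_all = x_all.reshape(x_all.shape[0], -1)
    n, d = x_all.shape
    if n < config.batch_size:
        raise ValueError(
            f"need at least batch_size={config.batch_size} patches, got {n}")
    _, _, E = build_networks(config)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed & 0x7FFFFFFF, 31]))
    opt_E = Adam(E.params, config.lr, config.adam_beta1, config.adam_beta2)
    B = config.batch_size
    log = {"step": [], "encoder_loss": []}

    for step in range(config.encoder_steps):
        xb = x_all[rng.choice(n, B, replace=False)]
        E.zero_grad()
        G.zero_grad()
        D.zero_grad()
        z = E(xb)
        y = G(z)
        fx = _critic_features(D, xb).copy()
        fy = _critic_features(D, y)
        nf = fy.size
        loss = float(((y - xb) ** 2).mean()
                     + config.kappa_feat * ((fy - fx) ** 2).mean())
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite encoder loss at step {step}")
        # dL/dy: pixel term + feature term backpropagated through D's feature layers
        gy = 2.0 * (y - xb) / y.size
        gy = gy + D.backward(2.0 * config.kappa_feat * (fy - fx) / nf,
                             from_layer=_FEATURE_LAYERS)
        gz = G.backward(gy)
        E.backward(gz)
        opt_E.step(E.grads)
        log["step"].append(step)
        log["encoder_loss"].append(loss)
    return E, log


def reconstruct(x: np.ndarray, model) -> np.ndarray:
    """y = G(E(x)); accepts a single (p,p) patch or an (n,p,p) batch.

    Models without explicit G/E networks (test stubs) supply their own
    ``reconstruct`` method instead.
    """
    xb, single = _as_batch(x, model.patch_side)
    if hasattr(model, "G") and hasattr(model, "E"):
        flat = xb.reshape(xb.shape[0], -1)
        y = model.G(model.E(flat)).reshape(xb.shape)
    else:
        y = np.asarray(model.reconstruct(xb), dtype=np.float64)
    return y[0] if single else y


def anomaly_score(x: np.ndarray, model) -> AnomalyScoreBreakdown:
    """Local anomaly score of normalized patch(es) x.

    ``L_R`` = mean squared pixel residual between x and y = G(E(x)),
    ``L_D`` = mean squared difference of the critic's intermediate features
    f(x) vs f(y), and ``L = L_R + k * L_D``. Means (rather than sums) make the
    score independent of patch size.
    """
    xb, single = _as_batch(x, model.patch_side)
    flat = xb.reshape(xb.shape[0], -1)
    y = np.asarray(model.reconstruct(xb), dtype=np.float64)
    yflat = y.reshape(y.shape[0], -1)
    fx = np.asarray(model.features(flat), dtype=np.float64)
    fy = np.asarray(model.features(yflat), dtype=np.float64)
    L_R = ((flat - yflat) ** 2).mean(axis=1)
    L_D = ((fx - fy) ** 2).mean(axis=1)
    k = float(model.k)
    L = L_R + k * L_D
    if not (np.isfinite(L_R).all() and np.isfinite(L_D).all()):
        bad = int(np.nonzero(~(np.isfinite(L_R) & np.isfinite(L_D)))[0][0])
        raise FloatingPointError(f"non-finite anomaly score for patch index {bad}")
    if single:
        return AnomalyScoreBreakdown(L_R=float(L_R[0]), L_D=float(L_D[0]),
                                     L=float(L[0]), k=k)
    return AnomalyScoreBreakdown(L_R=L_R, L_D=L_D, L=L, k=k)


def train_anomaly_model(normal_patches: np.ndarray, config: ModelConfig,
                        norm_stats: NormStats | None = None) -> AnomalyModel:
    """Convenience: both training stages on one normalized patch set."""
    G, D, gan_log = train_wgan(normal_patches, config)
    E, enc_log = train_encoder(normal_patches, G, D, config)
    return AnomalyModel(G=G, D=D, E=E, config=config, norm_stats=norm_stats,
                        k=config.k, training_log={**gan_log, **enc_log})


# ---------------------------------------------------------------------------
# serialization

def save_model(model: AnomalyModel, path) -> None:
    """Single-archive checkpoint: weights + config + normalization stats."""
    meta = {
        "config": model.config.to_dict(),
        "k": model.k,
        "norm_stats": None if model.norm_stats is None else
            {"lo": model.norm_stats.lo, "hi": model.norm_stats.hi,
             "percentiles": list(model.norm_stats.percentiles)},
    }
    arrays = {}
    for name, net in (("G", model.G), ("D", model.D), ("E", model.E)):
        for key, val in net.state_dict().items():
            arrays[f"{name}_{key}"] = val
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path) -> AnomalyModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode("utf-8"))
        config = ModelConfig(**meta["config"])
        G, D, E = build_networks(config)
        for name, net in (("G", G), ("D", D), ("E", E)):
            state = {k[len(name) + 1:]: data[k] for k in data.files
                     if k.startswith(name + "_p")}
            net.load_state_dict(state)
    stats = meta["norm_stats"]
    norm = None if stats is None else NormStats(
        lo=stats["lo"], hi=stats["hi"], percentiles=tuple(stats["percentiles"]))
    return AnomalyModel(G=G, D=D, E=E, config=config, norm_stats=norm,
                        k=meta["k"])


# ---------------------------------------------------------------------------
# stub models for tests and plumbing checks

class IdentityStubModel:
    """G(E(x)) = x and f(x) = x: perfect reconstruction, so L = 0 everywhere."""

    def __init__(self, patch_side: int, k: float = DEFAULT_K,
                 norm_stats: NormStats | None = None):
        self.patch_side = patch_side
        self.k = k
        self.norm_stats = norm_stats

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=np.float64).copy()

    def features(self, x_flat: np.ndarray) -> np.ndarray:
        return np.asarray(x_flat, dtype=np.float64).copy()


class ConstantScoreModel:
    """Scores every patch with a fixed L, via a constant pixel offset.

    The reconstruction is x + sqrt(L), so L_R = L exactly and L_D = 0.
    Scoring code may also dispatch on an optional ``score_batch`` method
    (see :func:`diffanomaly.scoring.score_patches`), which test stubs use to
    inject arbitrary deterministic window scores.
    """

    def __init__(self, patch_side: int, L: float = 1.0, k: float = DEFAULT_K,
                 norm_stats: NormStats | None = None):
        self.patch_side = patch_side
        self.L = L
        self.k = k
        self.norm_stats = norm_stats

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=np.float64) + np.sqrt(self.L)

    def features(self, x_flat: np.ndarray) -> np.ndarray:
        return np.zeros((np.asarray(x_flat).shape[0], 1))
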