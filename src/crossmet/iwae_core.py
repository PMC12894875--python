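"""Importance-weighted autoencoder for incomplete tabular data.

The model is a small MLP encoder/decoder pair trained on the K-sample
importance-weighted lower bound

    L_K = E[ log (1/K) sum_k p(x_vis | z_k) p(z_k) / q(z_k | x_in) ]

where the decoder likelihood factorises over matrix entries and is
evaluated only on the entries the loss targets: every truly observed entry
for the ``missing-data-IWAE`` variant, or only the artificially hidden
entries for the denoising ``standard-IWAE`` variant.  Hidden entries are
zero-filled at the encoder input and a visibility mask channel is appended.
Imputation draws L posterior samples and combines decoder means with
self-normalised importance weights.

Runs on the package's numpy autodiff engine, so training is deterministic
given the seed and needs no deep-learning framework.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .autodiff import Tensor, constant, parameter

__all__ = [
    "IWAEConfig",
    "MaskBatch",
    "TrainedIWAE",
    "iw_lower_bound",
    "elbo",
    "train",
    "impute",
    "imputation_error",
    "grid_search",
    "default_grid",
]

_LOG2PI = float(np.log(2.0 * np.pi))
_VARIANTS = ("standard-IWAE", "missing-data-IWAE")
_LOSSES = ("gaussian-nll", "mse", "mae")


@dataclass
class IWAEConfig:
    variant: str = "missing-data-IWAE"
    latent_dim: int = 8
    encoder_widths: tuple[int, ...] = (64,)
    decoder_widths: tuple[int, ...] = (64,)
    K: int = 5
    L: int = 50
    value_mask_rate: float = 0.3
    target_mask_rate: float = 0.5
    mixup_alpha: float | None = None  # None = off
    dropout_rate: float = 0.0
    batch_norm: bool = False
    loss: str = "gaussian-nll"
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 10
    val_metric: str = "mae"  # mae | rmse | mse
    seed: int = 0

    def validate(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.loss not in _LOSSES:
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.K < 1 or self.L < 1:
            raise ValueError("K and L must be >= 1")
        for name in ("value_mask_rate", "target_mask_rate", "dropout_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate < 1.0 and not (name == "target_mask_rate" and rate == 1.0):
                raise ValueError(f"{name}={rate} outside [0, 1)")
        if self.value_mask_rate == 0.0 and self.target_mask_rate == 0.0:
            raise ValueError("vacuous objective: both masking rates are zero")
        if not 1 <= self.patience <= 20:
            raise ValueError("patience must be in [1, 20]")
        # overfitting guard: small nets, bounded depth
        for widths in (self.encoder_widths, self.decoder_widths):
            if len(widths) > 3:
                raise ValueError("at most 3 hidden layers")
        if self.mixup_alpha is not None and self.mixup_alpha <= 0:
            raise ValueError("mixup_alpha must be positive when set")


@dataclass
class MaskBatch:
    """A training batch: values, true observation mask, and the artificially
    hidden subset of observed entries that the loss targets."""

    x: np.ndarray
    observed: np.ndarray
    train_mask: np.ndarray

    def __post_init__(self):
        self.observed = np.asarray(self.observed, dtype=bool)
        self.train_mask = np.asarray(self.train_mask, dtype=bool)
        if np.any(self.train_mask & ~self.observed):
            raise ValueError("train_mask must be a subset of observed")

    @property
    def visible(self) -> np.ndarray:
        """Entries the encoder may see."""
        return self.observed & ~self.train_mask


def _glorot(rng, fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.standard_normal((fan_in, fan_out)) * scale


def _bounded(t: Tensor, bound: float = 5.0) -> Tensor:
    """Smoothly clamp log-variances into (-bound, bound) for stability."""
    return (t * (1.0 / bound)).tanh() * bound


class _MLP:
    """Hidden stack with optional batch-norm (pre-activation) and dropout."""

    def __init__(self, rng, in_dim: int, widths: tuple[int, ...], batch_norm: bool):
        self.weights, self.biases = [], []
        self.bn_gamma, self.bn_beta, self.bn_mean, self.bn_var = [], [], [], []
        self.batch_norm = batch_norm
        prev = in_dim
        for w in widths:
            self.weights.append(parameter(_glorot(rng, prev, w)))
            self.biases.append(parameter(np.zeros(w)))
            if batch_norm:
                self.bn_gamma.append(parameter(np.ones(w)))
                self.bn_beta.append(parameter(np.zeros(w)))
                self.bn_mean.append(np.zeros(w))
                self.bn_var.append(np.ones(w))
            prev = w
        self.out_dim = prev

    @property
    def params(self) -> list[Tensor]:
        return self.weights + self.biases + self.bn_gamma + self.bn_beta

    def __call__(self, h: Tensor, training: bool, dropout_rate: float, rng) -> Tensor:
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if self.batch_norm:
                h = self._bn(h, i, training)
            h = h.tanh()
            if training and dropout_rate > 0.0:
                keep = rng.random(h.shape) >= dropout_rate
                h = h * constant(keep / (1.0 - dropout_rate))
        return h

    def _bn(self, h: Tensor, i: int, training: bool, momentum: float = 0.9) -> Tensor:
        width = h.shape[-1]
        if training:
            flat = h.reshape(-1, width)
            mu = flat.mean(axis=0)
            var = ((flat - mu) ** 2).mean(axis=0)
            self.bn_mean[i] = momentum * self.bn_mean[i] + (1 - momentum) * mu.data
            self.bn_var[i] = momentum * self.bn_var[i] + (1 - momentum) * var.data
            norm = (h - mu) * (var + 1e-5) ** -0.5
        else:
            norm = (h - constant(self.bn_mean[i])) * constant(self.bn_var[i] + 1e-5) ** -0.5
        return norm * self.bn_gamma[i] + self.bn_beta[i]


class _IWAEModel:
    def __init__(self, config: IWAEConfig, n_features: int, rng):
        self.config = config
        self.n_features = n_features
        m = config.latent_dim
        self.encoder = _MLP(rng, 2 * n_features, config.encoder_widths, config.batch_norm)
        self.enc_mu_w = parameter(_glorot(rng, self.encoder.out_dim, m))
        self.enc_mu_b = parameter(np.zeros(m))
        self.enc_lv_w = parameter(_glorot(rng, self.encoder.out_dim, m))
        self.enc_lv_b = parameter(np.zeros(m))
        self.decoder = _MLP(rng, m, config.decoder_widths, config.batch_norm)
        self.dec_mu_w = parameter(_glorot(rng, self.decoder.out_dim, n_features))
        self.dec_mu_b = parameter(np.zeros(n_features))
        # learned per-feature observation log-variance (gaussian-nll only)
        self.dec_logvar = parameter(np.zeros(n_features))

    @property
    def params(self) -> list[Tensor]:
        return (
            self.encoder.params
            + [self.enc_mu_w, self.enc_mu_b, self.enc_lv_w, self.enc_lv_b]
            + self.decoder.params
            + [self.dec_mu_w, self.dec_mu_b, self.dec_logvar]
        )

    def state(self) -> list[np.ndarray]:
        arrays = [p.data.copy() for p in self.params]
        for mlp in (self.encoder, self.decoder):
            arrays += [a.copy() for a in mlp.bn_mean] + [a.copy() for a in mlp.bn_var]
        return arrays

    def load_state(self, arrays: list[np.ndarray]) -> None:
        n = len(self.params)
        for p, a in zip(self.params, arrays[:n]):
            p.data = a.copy()
        rest = list(arrays[n:])
        for mlp in (self.encoder, self.decoder):
            for store in (mlp.bn_mean, mlp.bn_var):
                for i in range(len(store)):
                    store[i] = rest.pop(0).copy()

    # ------------------------------------------------------------------ passes
    def encode(self, x_vis: np.ndarray, vis: np.ndarray, training: bool, rng):
        inp = constant(np.concatenate([x_vis, vis.astype(np.float64)], axis=-1))
        h = self.encoder(inp, training, self.config.dropout_rate, rng)
        mu = h @ self.enc_mu_w + self.enc_mu_b
        logvar = _bounded(h @ self.enc_lv_w + self.enc_lv_b)
        return mu, logvar

    def decode(self, z: Tensor, training: bool, rng):
        h = self.decoder(z, training, self.config.dropout_rate, rng)
        mean = h @ self.dec_mu_w + self.dec_mu_b
        return mean, _bounded(self.dec_logvar)

    def _log_lik(self, x: np.ndarray, mean: Tensor, logvar: Tensor, mask: np.ndarray) -> Tensor:
        """Sum of per-entry log-likelihood over masked entries; (K, B)."""
        diff = constant(x) - mean
        if self.config.loss == "gaussian-nll":
            ll = (diff**2 * (-logvar).exp() + logvar + _LOG2PI) * -0.5
        elif self.config.loss == "mse":
            ll = diff**2 * -0.5
        else:  # mae -> Laplace with unit scale
            ll = -diff.abs()
        return (ll * constant(mask.astype(np.float64))).sum(axis=-1)

    def log_weights(
        self,
        batch: MaskBatch,
        K: int,
        rng,
        eps: np.ndarray | None = None,
        training: bool = False,
    ) -> Tensor:
        """(K, B) unnormalised log importance weights."""
        vis = batch.visible
        x_vis = np.where(vis, batch.x, 0.0)
        mu, logvar = self.encode(x_vis, vis, training, rng)
        if eps is None:
            eps = rng.standard_normal((K,) + mu.shape)
        eps_t = constant(eps)
        z = mu + (logvar * 0.5).exp() * eps_t  # (K, B, m)
        mean, dec_logvar = self.decode(z, training, rng)
        if self.config.variant == "missing-data-IWAE":
            loss_mask = batch.observed
        else:
            loss_mask = batch.train_mask
        log_px = self._log_lik(batch.x, mean, dec_logvar, loss_mask)
        log_prior = ((z**2 + _LOG2PI) * -0.5).sum(axis=-1)
        log_q = ((eps_t**2 + logvar + _LOG2PI) * -0.5).sum(axis=-1)
        return log_px + log_prior - log_q


def iw_lower_bound(
    batch: MaskBatch, model: _IWAEModel, K: int, rng=None, eps=None, training: bool = False
) -> Tensor:
    """Mean per-example K-sample importance-weighted bound (scalar Tensor)."""
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = rng or np.random.default_rng(0)
    log_w = model.log_weights(batch, K, rng, eps=eps, training=training)
    if not np.all(np.isfinite(log_w.data)):
        bad = int(np.argwhere(~np.isfinite(log_w.data))[0][-1])
        raise FloatingPointError(f"non-finite likelihood at batch index {bad}")
    return (log_w.logsumexp(axis=0) - np.log(K)).mean()


def elbo(batch: MaskBatch, model: _IWAEModel, rng=None, eps=None) -> Tensor:
    """Single-sample variational lower bound; independent code path used to
    verify the K=1 reduction of :func:`iw_lower_bound`."""
    rng = rng or np.random.default_rng(0)
    log_w = model.log_weights(batch, 1, rng, eps=eps)
    return log_w.mean()


class _Adam:
    def __init__(self, params: list[Tensor], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


@dataclass
class TrainedIWAE:
    config: IWAEConfig
    feature_ids: list[str]
    target_idx: np.ndarray  # indices of target-platform columns
    training_history: pd.DataFrame = field(repr=False, default=None)
    stopped_epoch: int = 0
    _model: _IWAEModel = field(repr=False, default=None)

    @property
    def model(self) -> _IWAEModel:
        return self._model

    def save(self, path) -> None:
        """Single-archive serialization: weights, config, feature ids."""
        import json

        meta = dict(self.config.__dict__)
        meta["encoder_widths"] = list(meta["encoder_widths"])
        meta["decoder_widths"] = list(meta["decoder_widths"])
        arrays = {f"arr_{i}": a for i, a in enumerate(self._model.state())}
        np.savez(
            path,
            __meta__=json.dumps(
                {
                    "format_version": 1,
                    "config": meta,
                    "feature_ids": self.feature_ids,
                    "target_idx": self.target_idx.tolist(),
                    "stopped_epoch": self.stopped_epoch,
                }
            ),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "TrainedIWAE":
        import json

        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["__meta__"]))
            arrays = [archive[f"arr_{i}"] for i in range(len(archive.files) - 1)]
        cfg = meta["config"]
        cfg["encoder_widths"] = tuple(cfg["encoder_widths"])
        cfg["decoder_widths"] = tuple(cfg["decoder_widths"])
        config = IWAEConfig(**cfg)
        model = _IWAEModel(config, len(meta["feature_ids"]), np.random.default_rng(0))
        model.load_state(arrays)
        return cls(
            config=config,
            feature_ids=meta["feature_ids"],
            target_idx=np.asarray(meta["target_idx"], dtype=int),
            stopped_epoch=meta["stopped_epoch"],
            _model=model,
        )


def _make_train_mask(observed: np.ndarray, target_idx: np.ndarray, config: IWAEConfig, rng):
    hidden = np.zeros_like(observed)
    if config.value_mask_rate > 0.0:
        hidden |= (rng.random(observed.shape) < config.value_mask_rate) & observed
    if config.target_mask_rate > 0.0 and target_idx.size:
        cols = target_idx[rng.random(target_idx.size) < config.target_mask_rate]
        hidden[:, cols] |= observed[:, cols]
    return hidden


def _mixup(batch: MaskBatch, alpha: float, rng) -> MaskBatch:
    lam = float(rng.beta(alpha, alpha))
    perm = rng.permutation(batch.x.shape[0])
    x = lam * np.where(batch.observed, batch.x, 0.0) + (1 - lam) * np.where(
        batch.observed[perm], batch.x[perm], 0.0
    )
    observed = batch.observed & batch.observed[perm]
    train_mask = (batch.train_mask | batch.train_mask[perm]) & observed
    return MaskBatch(x, observed, train_mask)


def train(
    x_train: np.ndarray,
    obs_train: np.ndarray,
    x_val: np.ndarray,
    obs_val: np.ndarray,
    feature_ids: list[str],
    target_idx: np.ndarray,
    config: IWAEConfig,
) -> TrainedIWAE:
    """Fit the autoencoder with masked training and early stopping.

    Per batch, ``value_mask_rate`` of observed entries plus a random subset
    of whole target columns are hidden; after each epoch the validation
    imputation error is computed with all target columns masked, and
    training stops when it has not improved for ``patience`` epochs (best
    weights restored).  Deterministic given ``config.seed``.
    """
    config.validate()
    target_idx = np.asarray(target_idx, dtype=int)
    n, d = x_train.shape
    master = np.random.default_rng(config.seed)
    init_rng, mask_rng, shuffle_rng, sample_rng = (
        np.random.default_rng(master.integers(2**63)) for _ in range(4)
    )
    val_seed = int(master.integers(2**31))
    model = _IWAEModel(config, d, init_rng)
    opt = _Adam(model.params, config.learning_rate)

    x_train = np.where(obs_train, x_train, 0.0)
    history: list[dict] = []
    best_err, best_state, best_epoch = np.inf, model.state(), 0
    since_best = 0
    for epoch in range(1, config.max_epochs + 1):
        order = shuffle_rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            rows = order[start : start + config.batch_size]
            if rows.size < 2:
                continue
            obs_b = obs_train[rows]
            hidden = _make_train_mask(obs_b, target_idx, config, mask_rng)
            if config.variant == "standard-IWAE" and not hidden.any():
                continue
            batch = MaskBatch(x_train[rows], obs_b, hidden)
            if config.mixup_alpha is not None:
                batch = _mixup(batch, config.mixup_alpha, mask_rng)
            loss = -iw_lower_bound(
                batch, model, config.K, rng=sample_rng, training=True
            )
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"training diverged at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        val_err = imputation_error(
            model, x_val, obs_val, target_idx, config.val_metric,
            L=min(config.L, 10), seed=val_seed,
        )
        history.append(
            {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1), "val_error": val_err}
        )
        if val_err < best_err - 1e-9:
            best_err, best_state, best_epoch = val_err, model.state(), epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    model.load_state(best_state)
    return TrainedIWAE(
        config=config,
        feature_ids=list(feature_ids),
        target_idx=target_idx,
        training_history=pd.DataFrame(history),
        stopped_epoch=best_epoch,
        _model=model,
    )


def impute(
    trained: TrainedIWAE | _IWAEModel,
    x: np.ndarray,
    observed_mask: np.ndarray,
    L: int | None = None,
    rng=None,
    sample_noise: bool = False,
) -> np.ndarray:
    """One stochastic imputation cycle.

    Draws L posterior samples, self-normalises importance weights in
    log-space, and returns the weighted mean of decoder means at hidden
    entries; observed entries pass through unchanged.

    With ``sample_noise=True`` the cycle is a proper multiple-imputation
    draw instead: one mixture component is resampled per example from the
    importance weights and decoder observation noise is added, so poorly
    predicted features also carry their predictive uncertainty.
    """
    model = trained.model if isinstance(trained, TrainedIWAE) else trained
    config = model.config
    L = config.L if L is None else L
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(0)
    observed_mask = np.asarray(observed_mask, dtype=bool)
    x_filled = np.where(observed_mask, x, 0.0)
    batch = MaskBatch(x_filled, observed_mask, np.zeros_like(observed_mask))
    vis = batch.visible
    mu, logvar = model.encode(np.where(vis, x_filled, 0.0), vis, False, rng)
    eps = rng.standard_normal((L,) + mu.shape)
    z = mu.data + np.exp(0.5 * logvar.data) * eps
    mean_t, dec_lv = model.decode(constant(z), False, rng)
    means = mean_t.data  # (L, B, d)
    # log w_k = log p(x_vis | z_k) + log p(z_k) - log q(z_k | x)
    diff = x_filled - means
    if config.loss == "gaussian-nll":
        lv = dec_lv.data
        ll = -0.5 * (diff**2 * np.exp(-lv) + lv + _LOG2PI)
    elif config.loss == "mse":
        ll = -0.5 * diff**2
    else:
        ll = -np.abs(diff)
    log_px = (ll * vis).sum(axis=-1)
    log_prior = (-0.5 * (z**2 + _LOG2PI)).sum(axis=-1)
    log_q = (-0.5 * (eps**2 + logvar.data + _LOG2PI)).sum(axis=-1)
    log_w = log_px + log_prior - log_q  # (L, B)
    log_w -= log_w.max(axis=0, keepdims=True)
    w = np.exp(log_w)
    denom = w.sum(axis=0, keepdims=True)
    if np.any(denom <= 0.0) or not np.all(np.isfinite(denom)):
        raise FloatingPointError("degenerate importance weights")
    w /= denom
    if sample_noise:
        cum = np.cumsum(w, axis=0)
        picks = (rng.random(w.shape[1])[None, :] < cum).argmax(axis=0)
        drawn = means[picks, np.arange(means.shape[1]), :]
        if config.loss == "gaussian-nll":
            scale = np.exp(0.5 * dec_lv.data)
        else:
            scale = np.ones(means.shape[-1])
        drawn = drawn + scale * rng.standard_normal(drawn.shape)
        return np.where(observed_mask, x, drawn)
    posterior_mean = np.einsum("lb,lbd->bd", w, means)
    return np.where(observed_mask, x, posterior_mean)


def imputation_error(
    trained,
    x: np.ndarray,
    observed_mask: np.ndarray,
    target_idx: np.ndarray,
    metric: str = "mae",
    L: int = 10,
    seed: int = 0,
) -> float:
    """Error after masking every target column and imputing it back,
    scored on the truly observed target entries."""
    target_idx = np.asarray(target_idx, dtype=int)
    vis = observed_mask.copy()
    vis[:, target_idx] = False
    imputed = impute(trained, np.where(vis, x, 0.0), vis, rng=np.random.default_rng(seed), L=L)
    score_mask = observed_mask.copy() & ~vis
    diff = (imputed - np.where(observed_mask, x, 0.0))[score_mask]
    if diff.size == 0:
        return float("nan")
    if metric == "mae":
        return float(np.mean(np.abs(diff)))
    if metric == "rmse":
        return float(np.sqrt(np.mean(diff**2)))
    if metric == "mse":
        return float(np.mean(diff**2))
    raise ValueError(f"unknown metric {metric!r}")


def default_grid(n_features: int, seed: int = 0, **overrides) -> list[IWAEConfig]:
    """Default coarse grid; widths and latent size scale with the panel.

    Full Cartesian product over variant, masking rates, mix-up, dropout,
    batch normalisation and error function — prune before running at desk
    scale (432 configs).
    """
    widths = (min(512, 2 * n_features), min(128, max(n_features // 2, 8)))
    base = dict(
        latent_dim=max(4, min(64, n_features // 4)),
        encoder_widths=widths,
        decoder_widths=widths[::-1],
        K=5,
        L=50,
        seed=seed,
    )
    base.update(overrides)
    grid = []
    for variant in _VARIANTS:
        for value_rate in (0.1, 0.3, 0.5):
            for target_rate in (0.25, 0.5, 1.0):
                for mixup in (None, 0.2):
                    for dropout in (0.0, 0.2):
                        for bn in (True, False):
                            for loss in _LOSSES:
                                grid.append(
                                    IWAEConfig(
                                        variant=variant,
                                        value_mask_rate=value_rate,
                                        target_mask_rate=target_rate,
                                        mixup_alpha=mixup,
                                        dropout_rate=dropout,
                                        batch_norm=bn,
                                        loss=loss,
                                        **base,
                                    )
                                )
    return grid


def _refine(config: IWAEConfig) -> list[IWAEConfig]:
    """Default fine-stage neighbourhood around a coarse winner."""
    out = []
    for lr_mult in (0.5, 2.0):
        out.append(replace(config, learning_rate=config.learning_rate * lr_mult))
    for delta in (-0.1, 0.1):
        rate = float(np.clip(config.value_mask_rate + delta, 0.05, 0.9))
        if abs(rate - config.value_mask_rate) > 1e-9:
            out.append(replace(config, value_mask_rate=rate))
    return out


def grid_search(
    x_train, obs_train, x_val, obs_val, feature_ids, target_idx,
    grid: list[IWAEConfig],
    refine=None,
) -> tuple[IWAEConfig, pd.DataFrame]:
    """Coarse-to-fine search ranked by validation imputation error with all
    target columns masked. Returns the winning config and a leaderboard."""
    if not grid:
        raise ValueError("empty grid")
    refine = refine if refine is not None else _refine
    rows, trained_err = [], {}

    def _run(config: IWAEConfig, stage: str) -> float:
        fitted = train(x_train, obs_train, x_val, obs_val, feature_ids, target_idx, config)
        err = float(fitted.training_history["val_error"].min())
        rows.append({"stage": stage, "config": config, "val_error": err})
        return err

    for config in grid:
        trained_err[id(config)] = _run(config, "coarse")
    best = min(rows, key=lambda r: r["val_error"])["config"]
    if len(grid) > 1:
        for config in refine(best):
            _run(config, "fine")
    leaderboard = pd.DataFrame(rows).sort_values("val_error", ignore_index=True)
    return leaderboard.loc[0, "config"], leaderboard
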