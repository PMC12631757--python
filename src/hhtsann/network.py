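"""The HHT-SANN forward model: HHT feature layer, SE recalibration,
temporal self-attention and a softmax classification head.

Architecture (per epoch):

1. **HHT layer** — each electrode's trace is z-scored, decomposed by EMD and
   Hilbert-analysed; the instantaneous amplitude/frequency planes of up to
   ``max_imfs`` IMFs, together with the raw (z-scored) channel planes, form
   the feature map ``F in R^{T' x C'}``. The temporal axis is average-pooled
   by ``time_pool`` so that T x T attention stays cheap on a CPU. The raw
   planes make the raw-vs-HHT attribution comparison well-posed; they can be
   switched off (``include_raw=False``) for an HHT-only model.
2. **SE block** — squeeze: ``z_c = mean_t F(t, c)``; excite:
   ``s = sigmoid(W2 . relu(W1 . z))`` with bottleneck width ``C'/r``; scale:
   ``F~(t, c) = s_c F(t, c)``.
3. **Self-attention** — single-head scaled dot product over time:
   ``A = softmax((F~ Wq)(F~ Wk)^T / sqrt(d)) (F~ Wv)``.
4. **Head** — global average over time, dense layer to 2 logits, softmax over
   {HC, MDD}.

EMD sifting is not differentiable, so the HHT layer is a fixed transform
computed inside the forward pass; learning is confined to the SE, attention
and head parameters, for which exact gradients are implemented by hand
(the model is plain numpy). Feature columns are standardised with statistics
fitted on the training split; the statistics travel with the checkpoint.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .emd import EmdConfig
from .exceptions import ConfigurationError, DimensionError
from .hht import ColumnKey, hht_features

CLASS_NAMES = ("HC", "MDD")  # column order of probabilities/logits


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    x = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(x)
    return e / np.sum(e, axis=axis, keepdims=True)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# SE block and attention as standalone operations
# ---------------------------------------------------------------------------

@dataclass
class SEParams:
    """Squeeze-and-excitation weights: W1 (bottleneck x C'), W2 (C' x bottleneck)."""

    W1: np.ndarray
    W2: np.ndarray
    r: int = 4

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=np.float64)
        self.W2 = np.asarray(self.W2, dtype=np.float64)
        if self.r < 1:
            raise DimensionError("reduction ratio r must be >= 1")
        if self.W1.ndim != 2 or self.W2.ndim != 2 or self.W2.shape != self.W1.shape[::-1]:
            raise DimensionError(
                f"inconsistent SE shapes {self.W1.shape} / {self.W2.shape}"
            )

    @classmethod
    def random(cls, n_channels: int, r: int, rng: np.random.Generator) -> "SEParams":
        hidden = max(1, n_channels // r)
        return cls(
            W1=_uniform_fan_in(rng, (hidden, n_channels)),
            W2=_uniform_fan_in(rng, (n_channels, hidden)),
            r=r,
        )


@dataclass
class AttentionParams:
    """Single-head query/key/value projections, each C' x d."""

    Wq: np.ndarray
    Wk: np.ndarray
    Wv: np.ndarray

    def __post_init__(self) -> None:
        self.Wq = np.asarray(self.Wq, dtype=np.float64)
        self.Wk = np.asarray(self.Wk, dtype=np.float64)
        self.Wv = np.asarray(self.Wv, dtype=np.float64)
        if not (self.Wq.shape == self.Wk.shape == self.Wv.shape) or self.Wq.ndim != 2:
            raise DimensionError("Wq, Wk, Wv must share one 2-D shape")

    @property
    def d(self) -> int:
        return self.Wq.shape[1]

    @classmethod
    def random(cls, n_channels: int, d: int, rng: np.random.Generator) -> "AttentionParams":
        return cls(*(_uniform_fan_in(rng, (n_channels, d)) for _ in range(3)))


def squeeze(F: np.ndarray) -> np.ndarray:
    """Global average pooling over time: ``z_c = (1/T) sum_t F(t, c)``."""
    F = np.asarray(F, dtype=np.float64)
    return F.mean(axis=-2)


def excite(z: np.ndarray, p: SEParams) -> np.ndarray:
    """Gating vector ``s = sigmoid(W2 . relu(W1 . z))``; entries in (0, 1)."""
    z = np.asarray(z, dtype=np.float64)
    if z.shape[-1] != p.W1.shape[1]:
        raise DimensionError(f"z has {z.shape[-1]} channels, W1 expects {p.W1.shape[1]}")
    hidden = np.maximum(z @ p.W1.T, 0.0)
    return sigmoid(hidden @ p.W2.T)


def se_scale(F: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Broadcast channel-wise rescaling ``F~(t, c) = s_c F(t, c)``."""
    F = np.asarray(F, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    if s.shape[-1] != F.shape[-1]:
        raise DimensionError(f"gate length {s.shape[-1]} != {F.shape[-1]} channels")
    return F * s[..., None, :] if F.ndim == 3 else F * s


def self_attention(
    F: np.ndarray, p: AttentionParams, return_weights: bool = False
):
    """Scaled dot-product self-attention over the temporal axis.

    ``A = softmax_rows((F Wq)(F Wk)^T / sqrt(d)) (F Wv)`` for F of shape
    [T x C']; returns [T x d] (and the row-stochastic weight matrix if asked).
    """
    F = np.asarray(F, dtype=np.float64)
    if F.shape[-1] != p.Wq.shape[0]:
        raise DimensionError(f"F has {F.shape[-1]} channels, Wq expects {p.Wq.shape[0]}")
    q, k, v = F @ p.Wq, F @ p.Wk, F @ p.Wv
    scores = q @ np.swapaxes(k, -1, -2) / np.sqrt(p.d)
    weights = softmax(scores, axis=-1)
    out = weights @ v
    return (out, weights) if return_weights else out


def _uniform_fan_in(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = 1.0 / np.sqrt(shape[0])
    return rng.uniform(-limit, limit, size=shape)


# ---------------------------------------------------------------------------
# Feature tensor preparation (the fixed HHT layer)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkConfig:
    """Model hyper-parameters.

    max_imfs : IMF planes per electrode (fixed tensor shape).
    reduction : SE bottleneck ratio r.
    attn_dim : attention dimension d.
    time_pool : temporal average-pooling factor applied to the feature map
        before SE/attention (1 disables pooling).
    include_raw / include_hht : which plane families enter the feature map.
    sd_threshold, max_sift_iters : EMD sifting controls.
    seed : parameter-initialisation seed.
    """

    max_imfs: int = 4
    reduction: int = 4
    attn_dim: int = 32
    time_pool: int = 16
    include_raw: bool = True
    include_hht: bool = True
    sd_threshold: float = 0.2
    max_sift_iters: int = 100
    seed: int = 42

    def __post_init__(self) -> None:
        if not (self.include_raw or self.include_hht):
            raise ConfigurationError("at least one plane family must be enabled")
        if self.time_pool < 1 or self.attn_dim < 1 or self.reduction < 1:
            raise ConfigurationError("time_pool, attn_dim, reduction must be >= 1")

    def emd_config(self) -> EmdConfig:
        return EmdConfig(
            max_imfs=self.max_imfs,
            max_sift_iters=self.max_sift_iters,
            sd_threshold=self.sd_threshold,
        )


def _zscore_rows(epoch: np.ndarray) -> np.ndarray:
    mean = epoch.mean(axis=1, keepdims=True)
    std = np.maximum(epoch.std(axis=1, keepdims=True), 1e-12)
    return (epoch - mean) / std


def compute_feature_tensor(
    epochs: np.ndarray,
    fs: float,
    cfg: NetworkConfig,
    channel_names: list[str] | None = None,
):
    """Run the HHT layer on a batch of raw epochs.

    Parameters
    ----------
    epochs : ndarray, shape (B, n_electrodes, T)
    fs : sampling rate in Hz.
    cfg : NetworkConfig.
    channel_names : electrode labels for the column map.

    Returns
    -------
    X : ndarray, shape (B, T', C')
        Pooled feature tensor, ``T' = T // time_pool``.
    index : list of ColumnKey
        Column map; raw planes carry ``kind="raw"`` and ``imf_index=-1``.
    """
    epochs = np.asarray(epochs, dtype=np.float64)
    if epochs.ndim != 3:
        raise DimensionError("epoch batch must be (B, n_electrodes, T)")
    B, n_elec, T = epochs.shape
    if T < max(3, cfg.time_pool):
        raise DimensionError(f"epoch length {T} too short for time_pool={cfg.time_pool}")
    if channel_names is None:
        channel_names = [f"Ch{i + 1}" for i in range(n_elec)]
    emd_cfg = cfg.emd_config()
    mats = []
    index: list[ColumnKey] = []
    for b in range(B):
        z = _zscore_rows(epochs[b])
        planes = []
        idx: list[ColumnKey] = []
        if cfg.include_raw:
            planes.append(z.T)
            idx.extend(ColumnKey(name, -1, "raw") for name in channel_names)
        if cfg.include_hht:
            feats = hht_features(z, emd_cfg, fs, channel_names)
            planes.append(feats.matrix)
            idx.extend(feats.channel_index)
        mats.append(np.concatenate(planes, axis=1))
        if b == 0:
            index = idx
    X = np.stack(mats)
    if cfg.time_pool > 1:
        Tp = T // cfg.time_pool
        X = X[:, : Tp * cfg.time_pool].reshape(B, Tp, cfg.time_pool, -1).mean(axis=2)
    return X, index


def features_for_epochset(es, cfg: NetworkConfig):
    """Convenience wrapper: feature tensor for a whole :class:`EpochSet`."""
    return compute_feature_tensor(es.epochs, es.fs, cfg, es.channel_names or None)


# ---------------------------------------------------------------------------
# Classifier with manual backprop
# ---------------------------------------------------------------------------

@dataclass
class ModelOutput:
    """Per-epoch class probabilities over (HC, MDD) and raw logits."""

    probabilities: np.ndarray  # (B, 2)
    logits: np.ndarray  # (B, 2)


class HhtSannClassifier:
    """SE + self-attention classifier over HHT feature tensors.

    Parameters are plain float64 arrays; forward and gradients are exact and
    deterministic, so two passes over the same batch agree bitwise.
    """

    CHECKPOINT_VERSION = 1

    def __init__(
        self,
        n_features: int,
        cfg: NetworkConfig = NetworkConfig(),
        rng: np.random.Generator | int | None = None,
    ) -> None:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        elif isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(int(rng))
        self.cfg = cfg
        self.n_features = int(n_features)
        C, d = self.n_features, cfg.attn_dim
        hidden = max(1, C // cfg.reduction)
        self.params: dict[str, np.ndarray] = {
            "W1": _uniform_fan_in(rng, (hidden, C)),
            "W2": _uniform_fan_in(rng, (C, hidden)),
            "Wq": _uniform_fan_in(rng, (C, d)),
            "Wk": _uniform_fan_in(rng, (C, d)),
            "Wv": _uniform_fan_in(rng, (C, d)),
            "Wh": _uniform_fan_in(rng, (d, 2)),
            "bh": np.zeros(2),
        }
        self.feature_mean = np.zeros(C)
        self.feature_std = np.ones(C)
        self.channel_index: list[ColumnKey] = []

    # -- feature handling ---------------------------------------------------

    def fit_standardizer(self, X: np.ndarray) -> None:
        """Fit per-column standardisation on a (training) feature tensor."""
        flat = X.reshape(-1, X.shape[-1])
        self.feature_mean = flat.mean(axis=0)
        self.feature_std = np.maximum(flat.std(axis=0), 1e-8)

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.feature_mean) / self.feature_std

    # -- forward ------------------------------------------------------------

    def _forward(self, Xs: np.ndarray) -> dict:
        p = self.params
        T = Xs.shape[1]
        z = Xs.mean(axis=1)                                   # squeeze (B, C)
        h1 = z @ p["W1"].T
        a1 = np.maximum(h1, 0.0)
        s = sigmoid(a1 @ p["W2"].T)                           # excitation (B, C)
        Xg = Xs * s[:, None, :]                               # scale
        q, k, v = Xg @ p["Wq"], Xg @ p["Wk"], Xg @ p["Wv"]
        scores = q @ np.swapaxes(k, 1, 2) / np.sqrt(self.cfg.attn_dim)
        A = softmax(scores, axis=-1)
        att = A @ v                                           # (B, T, d)
        g = att.mean(axis=1)
        logits = g @ p["Wh"] + p["bh"]
        probs = softmax(logits, axis=-1)
        return {
            "Xs": Xs, "z": z, "h1": h1, "a1": a1, "s": s, "Xg": Xg,
            "q": q, "k": k, "v": v, "A": A, "att": att, "g": g,
            "logits": logits, "probs": probs, "T": T,
        }

    def forward_features(self, X: np.ndarray) -> ModelOutput:
        """Forward pass on a raw-scale feature tensor (B, T', C')."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3 or X.shape[-1] != self.n_features:
            raise DimensionError(
                f"expected (B, T, {self.n_features}) feature tensor, got {X.shape}"
            )
        cache = self._forward(self.standardize(X))
        return ModelOutput(probabilities=cache["probs"], logits=cache["logits"])

    def forward(
        self, epochs: np.ndarray, fs: float, channel_names: list[str] | None = None
    ) -> ModelOutput:
        """Full pipeline: HHT layer + SE + attention + head on raw epochs."""
        X, index = compute_feature_tensor(epochs, fs, self.cfg, channel_names)
        if not self.channel_index:
            self.channel_index = index
        return self.forward_features(X)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward_features(X).probabilities

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    # -- backward -----------------------------------------------------------

    def loss_and_grads(
        self, X: np.ndarray, y: np.ndarray, sample_weights: np.ndarray | None = None
    ):
        """Weighted cross-entropy loss and exact parameter gradients."""
        p = self.params
        cache = self._forward(self.standardize(np.asarray(X, dtype=np.float64)))
        y = np.asarray(y, dtype=np.int64)
        B, T = cache["Xs"].shape[0], cache["T"]
        w = np.ones(B) if sample_weights is None else np.asarray(sample_weights, float)
        wsum = w.sum()
        probs = cache["probs"]
        eps = 1e-12
        loss = float(-(w * np.log(probs[np.arange(B), y] + eps)).sum() / wsum)

        onehot = np.zeros_like(probs)
        onehot[np.arange(B), y] = 1.0
        dlogits = (probs - onehot) * (w / wsum)[:, None]      # (B, 2)
        grads: dict[str, np.ndarray] = {}
        grads["Wh"] = cache["g"].T @ dlogits
        grads["bh"] = dlogits.sum(axis=0)
        dg = dlogits @ p["Wh"].T                              # (B, d)
        datt = np.repeat(dg[:, None, :], T, axis=1) / T
        dA = datt @ np.swapaxes(cache["v"], 1, 2)             # (B, T, T)
        dv = np.swapaxes(cache["A"], 1, 2) @ datt
        A = cache["A"]
        dscores = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        scale = 1.0 / np.sqrt(self.cfg.attn_dim)
        dq = dscores @ cache["k"] * scale
        dk = np.swapaxes(dscores, 1, 2) @ cache["q"] * scale
        Xg = cache["Xg"]
        grads["Wq"] = np.einsum("btc,btd->cd", Xg, dq)
        grads["Wk"] = np.einsum("btc,btd->cd", Xg, dk)
        grads["Wv"] = np.einsum("btc,btd->cd", Xg, dv)
        dXg = dq @ p["Wq"].T + dk @ p["Wk"].T + dv @ p["Wv"].T
        s = cache["s"]
        ds = (dXg * cache["Xs"]).sum(axis=1)                  # (B, C)
        dh2 = ds * s * (1.0 - s)
        grads["W2"] = dh2.T @ cache["a1"]
        da1 = dh2 @ p["W2"]
        dh1 = da1 * (cache["h1"] > 0)
        grads["W1"] = dh1.T @ cache["z"]
        return loss, grads

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Single-file checkpoint: version tag, config, params, standardiser."""
        meta = {
            "version": self.CHECKPOINT_VERSION,
            "n_features": self.n_features,
            "config": asdict(self.cfg),
            "channel_index": [list(k) for k in self.channel_index],
        }
        np.savez(
            path,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            feature_mean=self.feature_mean,
            feature_std=self.feature_std,
            **self.params,
        )

    @classmethod
    def load(cls, path) -> "HhtSannClassifier":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(bytes(z["meta"].tobytes()).decode())
            model = cls(meta["n_features"], NetworkConfig(**meta["config"]))
            for name in model.params:
                model.params[name] = z[name]
            model.feature_mean = z["feature_mean"]
            model.feature_std = z["feature_std"]
        model.channel_index = [ColumnKey(e, int(i), k) for e, i, k in meta["channel_index"]]
        return model

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for k, v in params.items():
            self.params[k] = v.copy()
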