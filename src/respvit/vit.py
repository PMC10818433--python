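"""Encoder-only Vision Transformer classifier, implemented in numpy.

The model follows the classic recipe: a square RGB feature image is split
into non-overlapping patches, each patch is linearly embedded, a learnable
classification token is prepended, learnable position embeddings are added,
and the token sequence passes through a stack of identical encoder layers.
Each layer applies multi-head scaled dot-product self-attention and a
position-wise feed-forward network, with the *post-norm* residual form
``LayerNorm(x + Sublayer(x))`` used by the original transformer.  The class
token's final state feeds a linear softmax head.

Forward and backward passes are written out explicitly (no autodiff
framework), which keeps the arithmetic inspectable and lets the test suite
verify the analytic gradients against central differences.  Training uses
Adam with optional early stopping on validation loss; everything is
deterministic under a seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy.stats import truncnorm

from .errors import ConfigurationError, NumericError, ParameterError
from .tf_features import FeatureImage

_LN_EPS = 1e-5


@dataclass(frozen=True)
class ViTConfig:
    """Architecture hyperparameters.

    Defaults follow the reference ViT-on-224px convention with the original
    transformer's d_model = 512 / 6 layers; the desk-scale test profile uses
    64x64 images, d_model 64 and 2 layers.
    """

    image_size: int = 224
    patch_size: int = 16
    d_model: int = 512
    n_layers: int = 6
    n_heads: int = 8
    d_ff: int = 2048
    n_classes: int = 4
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size % self.patch_size != 0:
            raise ParameterError(
                f"image_size {self.image_size} not divisible by patch_size {self.patch_size}"
            )
        if self.d_model % self.n_heads != 0:
            raise ParameterError(
                f"d_model {self.d_model} not divisible by n_heads {self.n_heads}"
            )
        if self.n_layers < 1:
            raise ParameterError("need at least one encoder layer")
        if not (0.0 <= self.dropout < 1.0):
            raise ParameterError(f"dropout must be in [0, 1), got {self.dropout}")

    @property
    def n_patches(self) -> int:
        return (self.image_size // self.patch_size) ** 2

    @property
    def patch_dim(self) -> int:
        return self.patch_size * self.patch_size * 3


@dataclass
class TokenSequence:
    """(P+1) x d_model embedded tokens; row 0 is the classification token."""

    tokens: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        if self.tokens.shape[0] != self.positions.size:
            raise ParameterError("token row count must match position count")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol: Adam, lr 0.001, batch 16, 30 epochs, patience 10."""

    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 1e-3
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ParameterError("batch_size must be >= 1")


# ---------------------------------------------------------------------------
# patching and embedding (functional surface)

def patchify(image: FeatureImage | np.ndarray, patch_size: int) -> np.ndarray:
    """Split a square RGB image into row-major flattened patches.

    Returns a (P, patch_size^2 * 3) float array with pixel values scaled to
    [0, 1]; P = (side / patch_size)^2.
    """
    px = image.pixels if isinstance(image, FeatureImage) else np.asarray(image)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ParameterError(f"expected an H x W x 3 image, got shape {px.shape}")
    if px.shape[0] != px.shape[1]:
        raise ParameterError(f"image must be square, got {px.shape[:2]}")
    side = px.shape[0]
    if side % patch_size != 0:
        raise ParameterError(f"side {side} not divisible by patch size {patch_size}")
    g = side // patch_size
    x = px.astype(np.float64)
    if px.dtype == np.uint8:
        x = x / 255.0
    return (
        x.reshape(g, patch_size, g, patch_size, 3)
        .transpose(0, 2, 1, 3, 4)
        .reshape(g * g, patch_size * patch_size * 3)
    )


def embed(patches: np.ndarray, cfg: ViTConfig, params: dict) -> TokenSequence:
    """Linear patch embedding + class token + position embeddings."""
    patches = np.asarray(patches, dtype=np.float64)
    if patches.shape != (cfg.n_patches, cfg.patch_dim):
        raise ConfigurationError(
            f"expected {cfg.n_patches} patches of dim {cfg.patch_dim}, got {patches.shape}"
        )
    W, b = params["patch_W"], params["patch_b"]
    if W.shape != (cfg.patch_dim, cfg.d_model):
        raise ConfigurationError(f"patch projection shape {W.shape} inconsistent with config")
    proj = patches @ W + b
    tokens = np.vstack([params["cls"].reshape(1, -1), proj]) + params["pos"]
    return TokenSequence(tokens=tokens, positions=np.arange(cfg.n_patches + 1))


# ---------------------------------------------------------------------------
# parameter initialization

def init_params(cfg: ViTConfig, rng: np.random.Generator | None = None) -> dict:
    """Truncated-normal (sigma = 0.02, clipped at 2 sigma) weights, zero biases."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    def tn(*shape):
        return truncnorm.rvs(-2, 2, scale=0.02, size=shape, random_state=rng)

    d, ff = cfg.d_model, cfg.d_ff
    p: dict[str, np.ndarray] = {
        "patch_W": tn(cfg.patch_dim, d),
        "patch_b": np.zeros(d),
        "cls": tn(1, d),
        "pos": tn(cfg.n_patches + 1, d),
        "head_W": tn(d, cfg.n_classes),
        "head_b": np.zeros(cfg.n_classes),
    }
    for i in range(cfg.n_layers):
        for name in ("q", "k", "v", "o"):
            p[f"l{i}.W{name}"] = tn(d, d)
            p[f"l{i}.b{name}"] = np.zeros(d)
        p[f"l{i}.W1"], p[f"l{i}.b1"] = tn(d, ff), np.zeros(ff)
        p[f"l{i}.W2"], p[f"l{i}.b2"] = tn(ff, d), np.zeros(d)
        p[f"l{i}.ln1_g"], p[f"l{i}.ln1_b"] = np.ones(d), np.zeros(d)
        p[f"l{i}.ln2_g"], p[f"l{i}.ln2_b"] = np.ones(d), np.zeros(d)
    return p


# ---------------------------------------------------------------------------
# primitive forward/backward pairs

def _linear_fwd(x, W, b):
    return x @ W + b, x


def _linear_bwd(dout, cache, W):
    x = cache
    dx = dout @ W.T
    x2 = x.reshape(-1, x.shape[-1])
    d2 = dout.reshape(-1, dout.shape[-1])
    return dx, x2.T @ d2, d2.sum(axis=0)


def _layernorm_fwd(x, g, b):
    mu = x.mean(axis=-1, keepdims=True)
    var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
    std = np.sqrt(var + _LN_EPS)
    xhat = (x - mu) / std
    return g * xhat + b, (xhat, std)


def _layernorm_bwd(dout, cache, g):
    xhat, std = cache
    dxhat = dout * g
    dx = (
        dxhat
        - dxhat.mean(axis=-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
    ) / std
    axes = tuple(range(dout.ndim - 1))
    return dx, (dout * xhat).sum(axis=axes), dout.sum(axis=axes)


def _softmax(z, axis=-1):
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _split_heads(x, n_heads):
    B, T, D = x.shape
    return x.reshape(B, T, n_heads, D // n_heads).transpose(0, 2, 1, 3)


def _merge_heads(x):
    B, H, T, dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(B, T, H * dh)


def _mhsa_fwd(x, p, i, n_heads):
    """Multi-head scaled dot-product self-attention on (B, T, D) tokens."""
    q, cq = _linear_fwd(x, p[f"l{i}.Wq"], p[f"l{i}.bq"])
    k, ck = _linear_fwd(x, p[f"l{i}.Wk"], p[f"l{i}.bk"])
    v, cv = _linear_fwd(x, p[f"l{i}.Wv"], p[f"l{i}.bv"])
    qh, kh, vh = (_split_heads(t, n_heads) for t in (q, k, v))
    scale = 1.0 / np.sqrt(qh.shape[-1])
    scores = np.einsum("bhtd,bhsd->bhts", qh, kh) * scale
    A = _softmax(scores)
    ctx = np.einsum("bhts,bhsd->bhtd", A, vh)
    merged = _merge_heads(ctx)
    out, co = _linear_fwd(merged, p[f"l{i}.Wo"], p[f"l{i}.bo"])
    cache = (cq, ck, cv, co, qh, kh, vh, A, scale)
    return out, A, cache


def _mhsa_bwd(dout, cache, p, i, grads):
    cq, ck, cv, co, qh, kh, vh, A, scale = cache
    dmerged, dWo, dbo = _linear_bwd(dout, co, p[f"l{i}.Wo"])
    grads[f"l{i}.Wo"] += dWo
    grads[f"l{i}.bo"] += dbo
    n_heads = qh.shape[1]
    dctx = _split_heads(dmerged, n_heads)
    dA = np.einsum("bhtd,bhsd->bhts", dctx, vh)
    dvh = np.einsum("bhts,bhtd->bhsd", A, dctx)
    ds = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
    dqh = np.einsum("bhts,bhsd->bhtd", ds, kh) * scale
    dkh = np.einsum("bhts,bhtd->bhsd", ds, qh) * scale
    dx = np.zeros_like(cq)
    for dt, name, cch in ((dqh, "q", cq), (dkh, "k", ck), (dvh, "v", cv)):
        dflat = _merge_heads(dt)
        dxi, dW, db = _linear_bwd(dflat, cch, p[f"l{i}.W{name}"])
        grads[f"l{i}.W{name}"] += dW
        grads[f"l{i}.b{name}"] += db
        dx += dxi
    return dx


def _ffn_fwd(x, p, i):
    h1, c1 = _linear_fwd(x, p[f"l{i}.W1"], p[f"l{i}.b1"])
    a = np.maximum(h1, 0.0)
    out, c2 = _linear_fwd(a, p[f"l{i}.W2"], p[f"l{i}.b2"])
    return out, (c1, h1, c2)


def _ffn_bwd(dout, cache, p, i, grads):
    c1, h1, c2 = cache
    da, dW2, db2 = _linear_bwd(dout, c2, p[f"l{i}.W2"])
    grads[f"l{i}.W2"] += dW2
    grads[f"l{i}.b2"] += db2
    dh1 = da * (h1 > 0)
    dx, dW1, db1 = _linear_bwd(dh1, c1, p[f"l{i}.W1"])
    grads[f"l{i}.W1"] += dW1
    grads[f"l{i}.b1"] += db1
    return dx


def encoder_layer(
    seq: TokenSequence | np.ndarray, params: dict, layer: int = 0, n_heads: int = 1
) -> TokenSequence | np.ndarray:
    """One post-norm encoder layer: LN(h + FFN(h)), h = LN(x + MHSA(x)).

    Accepts a single TokenSequence or a (B, T, D) batch array; attention rows
    are softmax-normalized over key positions.
    """
    single = isinstance(seq, TokenSequence)
    x = seq.tokens[None] if single else np.asarray(seq, dtype=np.float64)
    out, _, _ = _encoder_layer_fwd(x, params, layer, n_heads)
    if single:
        return TokenSequence(tokens=out[0], positions=seq.positions)
    return out


def _encoder_layer_fwd(x, p, i, n_heads):
    att, A, c_att = _mhsa_fwd(x, p, i, n_heads)
    h, c_ln1 = _layernorm_fwd(x + att, p[f"l{i}.ln1_g"], p[f"l{i}.ln1_b"])
    f, c_ffn = _ffn_fwd(h, p, i)
    out, c_ln2 = _layernorm_fwd(h + f, p[f"l{i}.ln2_g"], p[f"l{i}.ln2_b"])
    if not np.all(np.isfinite(out)):
        raise NumericError(f"non-finite activations in encoder layer {i}")
    return out, A, (c_att, c_ln1, c_ffn, c_ln2)


def _encoder_layer_bwd(dout, cache, p, i, grads):
    c_att, c_ln1, c_ffn, c_ln2 = cache
    dsum2, dg2, db2 = _layernorm_bwd(dout, c_ln2, p[f"l{i}.ln2_g"])
    grads[f"l{i}.ln2_g"] += dg2
    grads[f"l{i}.ln2_b"] += db2
    dh = dsum2 + _ffn_bwd(dsum2, c_ffn, p, i, grads)
    dsum1, dg1, db1 = _layernorm_bwd(dh, c_ln1, p[f"l{i}.ln1_g"])
    grads[f"l{i}.ln1_g"] += dg1
    grads[f"l{i}.ln1_b"] += db1
    dx = dsum1 + _mhsa_bwd(dsum1, c_att, p, i, grads)
    return dx


# ---------------------------------------------------------------------------
# full model

class ViTClassifier:
    """Encoder-only ViT with a class-token softmax head.

    ``params`` is a flat dict of numpy arrays; :meth:`loss_and_grads` returns
    the cross-entropy and its exact analytic gradient for every parameter.
    """

    def __init__(self, cfg: ViTConfig, params: dict | None = None):
        self.cfg = cfg
        self.params = params if params is not None else init_params(cfg)

    # -- forward -----------------------------------------------------------

    def _images_to_patches(self, images: np.ndarray) -> np.ndarray:
        """(B, S, S, 3) images -> (B, P, patch_dim), pixels scaled to [0, 1]."""
        images = np.asarray(images)
        if images.ndim == 3:
            images = images[None]
        B, S = images.shape[0], self.cfg.image_size
        if images.shape[1:] != (S, S, 3):
            raise ConfigurationError(
                f"expected images of shape (B, {S}, {S}, 3), got {images.shape}"
            )
        x = images.astype(np.float64)
        if images.dtype == np.uint8:
            x = x / 255.0
        ps, g = self.cfg.patch_size, S // self.cfg.patch_size
        return (
            x.reshape(B, g, ps, g, ps, 3)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(B, g * g, self.cfg.patch_dim)
        )

    def _forward(self, images, train=False, rng=None):
        p, cfg = self.params, self.cfg
        patches = self._images_to_patches(images)
        B = patches.shape[0]
        proj, c_proj = _linear_fwd(patches, p["patch_W"], p["patch_b"])
        cls = np.broadcast_to(p["cls"], (B, 1, cfg.d_model))
        x = np.concatenate([cls, proj], axis=1) + p["pos"]
        drop_mask = None
        if train and cfg.dropout > 0:
            drop_mask = (rng.random(x.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
            x = x * drop_mask
        caches = []
        for i in range(cfg.n_layers):
            x, _, cache = _encoder_layer_fwd(x, p, i, cfg.n_heads)
            caches.append(cache)
        cls_out = x[:, 0, :]
        logits, c_head = _linear_fwd(cls_out, p["head_W"], p["head_b"])
        return logits, (c_proj, drop_mask, caches, c_head, B)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Class probabilities, (B, n_classes), rows summing to 1."""
        logits, _ = self._forward(images)
        return _softmax(logits)

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Argmax class indices; ties break toward the lower index."""
        return np.argmax(self.predict_proba(images), axis=1)

    # -- loss and gradients -------------------------------------------------

    def loss_and_grads(self, images, y, train=True, rng=None):
        """Mean cross-entropy over the batch and d(loss)/d(param) for all params."""
        y = np.asarray(y, dtype=np.int64)
        logits, (c_proj, drop_mask, caches, c_head, B) = self._forward(
            images, train=train, rng=rng
        )
        probs = _softmax(logits)
        loss = -np.mean(np.log(np.maximum(probs[np.arange(B), y], 1e-300)))
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        dcls_out, dWh, dbh = _linear_bwd(dlogits, c_head, self.params["head_W"])
        grads["head_W"] += dWh
        grads["head_b"] += dbh
        dx = np.zeros((B, self.cfg.n_patches + 1, self.cfg.d_model))
        dx[:, 0, :] = dcls_out
        for i in range(self.cfg.n_layers - 1, -1, -1):
            dx = _encoder_layer_bwd(dx, caches[i], self.params, i, grads)
        if drop_mask is not None:
            dx = dx * drop_mask
        grads["pos"] += dx.sum(axis=0)
        grads["cls"] += dx[:, 0, :].sum(axis=0, keepdims=True)
        dproj = dx[:, 1:, :]
        _, dWp, dbp = _linear_bwd(dproj, c_proj, self.params["patch_W"])
        grads["patch_W"] += dWp
        grads["patch_b"] += dbp
        return loss, grads

    # -- training ------------------------------------------------------------

    def fit(
        self,
        images: np.ndarray,
        y: np.ndarray,
        tcfg: TrainConfig,
        val_images: np.ndarray | None = None,
        val_y: np.ndarray | None = None,
    ) -> list[dict]:
        """Adam training with optional early stopping on validation loss.

        Returns the per-epoch history (train loss/accuracy, validation
        loss/accuracy when a validation set is given).  The parameters kept
        are those of the best validation epoch (or the final epoch without
        validation data).
        """
        y = np.asarray(y, dtype=np.int64)
        if len(y) == 0:
            raise ConfigurationError("empty training split")
        rng = np.random.default_rng(tcfg.seed)
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(va) for k, va in self.params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        history: list[dict] = []
        best_val = np.inf
        best_params = None
        stall = 0
        for epoch in range(tcfg.epochs):
            order = rng.permutation(len(y))
            losses = []
            for start in range(0, len(y), tcfg.batch_size):
                idx = order[start : start + tcfg.batch_size]
                loss, grads = self.loss_and_grads(
                    images[idx], y[idx], train=True, rng=rng
                )
                losses.append(loss)
                t += 1
                for k in self.params:
                    g = grads[k]
                    m[k] = beta1 * m[k] + (1 - beta1) * g
                    v[k] = beta2 * v[k] + (1 - beta2) * g * g
                    mhat = m[k] / (1 - beta1 ** t)
                    vhat = v[k] / (1 - beta2 ** t)
                    self.params[k] -= tcfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
            rec = {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "train_acc": float(np.mean(self.predict(images) == y)),
            }
            if val_images is not None and len(val_y) > 0:
                vprobs = self.predict_proba(val_images)
                vy = np.asarray(val_y, dtype=np.int64)
                rec["val_loss"] = float(
                    -np.mean(np.log(np.maximum(vprobs[np.arange(len(vy)), vy], 1e-300)))
                )
                rec["val_acc"] = float(np.mean(np.argmax(vprobs, axis=1) == vy))
                if rec["val_loss"] < best_val - 1e-12:
                    best_val = rec["val_loss"]
                    best_params = {k: p.copy() for k, p in self.params.items()}
                    stall = 0
                else:
                    stall += 1
            history.append(rec)
            if val_images is not None and stall >= tcfg.patience:
                break
        if best_params is not None:
            self.params = best_params
        return history

    # -- serialization -------------------------------------------------------

    def save(self, path) -> None:
        """Single-file checkpoint: all weights plus the embedded config."""
        np.savez(path, __config__=json.dumps(asdict(self.cfg)), **self.params)

    @classmethod
    def load(cls, path) -> "ViTClassifier":
        with np.load(path, allow_pickle=False) as data:
            cfg = ViTConfig(**json.loads(str(data["__config__"])))
            params = {k: data[k] for k in data.files if k != "__config__"}
        return cls(cfg, params)


# functional wrappers matching the operation-level surface -------------------

def forward(image, cfg: ViTConfig, params: dict) -> np.ndarray:
    """Class probability vector for one image (sums to 1)."""
    model = ViTClassifier(cfg, params)
    px = image.pixels if isinstance(image, FeatureImage) else np.asarray(image)
    return model.predict_proba(px[None])[0]


def predict(images, cfg: ViTConfig, params: dict) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and probabilities for a batch of images."""
    model = ViTClassifier(cfg, params)
    stack = np.stack(
        [im.pixels if isinstance(im, FeatureImage) else np.asarray(im) for im in images]
    )
    probs = model.predict_proba(stack)
    return np.argmax(probs, axis=1), probs


def train(
    images: np.ndarray,
    y: np.ndarray,
    patient_ids: np.ndarray,
    cfg: ViTConfig,
    tcfg: TrainConfig,
    split: tuple,
) -> tuple[dict, list[dict]]:
    """Train on the patients in split[0], early-stop on those in split[1].

    ``split`` holds two disjoint patient-id collections; cycles are routed by
    their patient, never individually, so no patient leaks across sets.
    """
    train_pat, val_pat = set(split[0]), set(split[1])
    if train_pat & val_pat:
        raise ConfigurationError("train and validation patient sets overlap")
    pid = np.asarray(patient_ids)
    tr = np.isin(pid, list(train_pat))
    va = np.isin(pid, list(val_pat))
    if not tr.any():
        raise ConfigurationError("empty training split")
    model = ViTClassifier(cfg, init_params(cfg, np.random.default_rng(cfg.seed)))
    history = model.fit(
        images[tr], np.asarray(y)[tr], tcfg,
        val_images=images[va] if va.any() else None,
        val_y=np.asarray(y)[va] if va.any() else None,
    )
    return model.params, history
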