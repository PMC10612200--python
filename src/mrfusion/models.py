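"""The four predictive models and their training harness.

* ``RS``   — ridge regression on the 1116-dim concatenation of the three
  per-sequence feature vectors, with the regularization weight selected by
  stratified 5-fold cross-validation over lambda in {0.001, ..., 1.000}
  (step 0.001), maximizing mean out-of-fold AUC.
* ``CFRS`` — channel-attention fusion of the 3 x n feature matrix: a small
  conv stack (32 filters 3x1 -> 32 filters 1x1 -> 1 filter 1x1) feeds a
  3-unit sigmoid head whose outputs weight the three channel rows into one
  fused n-vector, classified by a 1-unit sigmoid head.
* ``DL``   — shallow CNN on the 3 x 80 x 80 patch (3 conv blocks of
  3x3 conv + batch-norm + ReLU + 2x2 max-pool, widths 16/32/64, then
  FC 6400 -> 64 -> 1).
* ``CFDL`` — the same backbone with squeeze-and-excitation gates: one SE
  block on the 3-channel input (r=1) and one after the first conv (r=4).

DL and CFDL share an identical backbone; DL simply pins every SE gate to
1, so the comparison isolates the channel-attention mechanism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import _nn
from ._nn import Adam, BatchNorm2d, Conv2d, Dense, Flatten, MaxPool2x2, ReLU, SEBlock, Sequential
from .io_formats import MultiSequencePatch
from .radiomics import FeatureMatrix

MODEL_KINDS = ("RS", "CFRS", "DL", "CFDL")
LAMBDA_GRID = np.round(np.arange(1, 1001) * 0.001, 3)  # 0.001 .. 1.000


@dataclass
class AttentionWeights:
    """Per-channel sigmoid attention coefficients in (T2w, T1c, ADC) order."""

    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64)
        if self.w.shape != (3,):
            raise ValueError("attention weights must have exactly 3 components")
        if not np.all((self.w > 0) & (self.w < 1)):
            raise ValueError("attention weights must lie in the open interval (0, 1)")


@dataclass
class TrainConfig:
    """Training hyperparameters (all model-agnostic defaults).

    The neural models use Adam on binary cross-entropy with early stopping
    on validation AUC; ``seed`` fixes every source of randomness so a run
    is reproducible on one device.
    """

    loss: str = "bce"
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 20
    seed: int = 0
    val_fraction: float = 0.3
    class_weight: str | None = None  # None or "balanced"
    augment: bool = False  # random flips/rotations for image models
    cnn_widths: tuple[int, int, int] = (16, 32, 64)
    fc_width: int = 64
    se_input_reduction: int = 1
    se_conv_reduction: int = 4
    lambda_grid: tuple[float, ...] | None = None  # RS only; default LAMBDA_GRID


# ---------------------------------------------------------------------------
# ridge (RS)


@dataclass
class RidgeModel:
    """Closed-form ridge fit of the penalized squared loss.

    The loss is sum_i (y_i - x_i^T w)^2 + lambda * ||w||^2.  Features and
    labels are centered before solving, which is equivalent to fitting an
    unpenalized intercept; prediction scores are x^T w + intercept.
    """

    w: np.ndarray
    lam: float
    intercept: float
    x_mean: np.ndarray

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_mean) @ self.w + self.intercept


def rs_fit(X: np.ndarray, y: np.ndarray, lam: float) -> RidgeModel:
    """Solve (Xc^T Xc + lambda I) w = Xc^T yc exactly (SVD form)."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if np.isnan(X).any():
        raise ValueError("NaN in feature matrix")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc, yc = X - x_mean, y - y_mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    d = s / (s**2 + lam)
    w = Vt.T @ (d * (U.T @ yc))
    return RidgeModel(w=w, lam=float(lam), intercept=float(y_mean), x_mean=x_mean)


def _auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with ties counted 1/2 (rank formulation)."""
    labels = np.asarray(labels)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: only one class present")
    from scipy.stats import rankdata

    r = rankdata(scores)
    return float((r[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def select_lambda_cv(
    X: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray | None = None,
    k: int = 5,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Pick lambda maximizing mean out-of-fold AUC over a stratified k-fold.

    Ties are broken toward the larger lambda (stronger regularization).
    A fold whose validation part is single-class has undefined AUC and is
    skipped with a warning.  Returns ``(lambda_star, mean_auc_per_lambda)``.

    The per-fold SVD is computed once and reused across the whole grid, so
    the full 1000-value sweep stays cheap.
    """
    import warnings

    grid = LAMBDA_GRID if grid is None else np.asarray(grid, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    aucs = np.zeros((0, grid.size))
    for tr, va in skf.split(X, y):
        if len(np.unique(y[va])) < 2:
            warnings.warn("validation fold with a single class: AUC undefined, fold skipped")
            continue
        x_mean = X[tr].mean(axis=0)
        y_mean = y[tr].mean()
        U, s, Vt = np.linalg.svd(X[tr] - x_mean, full_matrices=False)
        A = (X[va] - x_mean) @ Vt.T  # n_val x r
        b = U.T @ (y[tr] - y_mean)  # r
        fold = np.empty(grid.size)
        for gi, lam in enumerate(grid):
            scores = A @ (s / (s**2 + lam) * b)
            fold[gi] = _auc(scores, y[va])
        aucs = np.vstack([aucs, fold])
    mean_auc = aucs.mean(axis=0)
    # argmax with larger-lambda tie-break: take the last index attaining the max
    best = np.flatnonzero(mean_auc >= mean_auc.max() - 1e-12)[-1]
    return float(grid[best]), mean_auc


# ---------------------------------------------------------------------------
# CFRS


class CfrsNet:
    """Feature-matrix channel-attention network.

    Input is the standardized 3 x n feature matrix; output is the poor-
    responder probability plus the three attention weights and the fused
    n-vector (``fused[j] = sum_c w_c m[c, j]``).
    """

    def __init__(self, n_features: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.n = n_features
        self.conv = Sequential(
            [
                Conv2d(1, 32, 3, 1, rng, name="conv1"),
                ReLU(name="relu1"),
                Conv2d(32, 32, 1, 1, rng, name="conv2"),
                ReLU(name="relu2"),
                Conv2d(32, 1, 1, 1, rng, name="conv3"),
            ]
        )
        # zero-initialized heads: attention starts at 0.5 per channel and the
        # output at probability 0.5, which keeps early training stable
        self.fc_att = Dense(n_features, 3, rng, name="fc_att")
        self.fc_att.W[...] = 0.0
        self.fc_out = Dense(n_features, 1, rng, name="fc_out")
        self.fc_out.W[...] = 0.0

    def params(self):
        return self.conv.params() + self.fc_att.params() + self.fc_out.params()

    def grads(self):
        return self.conv.grads() + self.fc_att.grads() + self.fc_out.grads()

    def get_weights(self):
        return [p.copy() for p in self.params()]

    def set_weights(self, weights):
        for p, w in zip(self.params(), weights, strict=True):
            p[...] = w

    def forward(self, m: np.ndarray, train: bool = False, force_weights=None):
        """Returns (probability, attention weights, fused feature), batched."""
        m = np.asarray(m, dtype=np.float64)
        if m.ndim == 2:
            m = m[None]
        if m.shape[1:] != (3, self.n):
            raise ValueError(f"expected batch of 3 x {self.n} matrices, got {m.shape}")
        self._m = m
        conv_out = self.conv.forward(m[:, None, :, :], train=train)  # b,1,1,n
        flat = conv_out.reshape(m.shape[0], self.n)
        att_logit = self.fc_att.forward(flat, train)
        w = _nn.sigmoid(att_logit) if force_weights is None else np.broadcast_to(
            np.asarray(force_weights, dtype=np.float64), (m.shape[0], 3)
        )
        self._w, self._forced = w, force_weights is not None
        fused = np.einsum("bc,bcn->bn", w, m)
        self._fused = fused
        logit = self.fc_out.forward(fused, train)[:, 0]
        prob = _nn.sigmoid(logit)
        self._prob = prob
        return prob, w, fused

    def backward(self, dprob_logit: np.ndarray) -> None:
        """Backprop from d(loss)/d(output logit); fills parameter grads."""
        dfused = self.fc_out.backward(dprob_logit[:, None])
        m, w = self._m, self._w
        dw = np.einsum("bn,bcn->bc", dfused, m)
        dm = dfused[:, None, :] * w[:, :, None]  # unused downstream (input grad)
        if not self._forced:
            datt = dw * w * (1 - w)
            dflat = self.fc_att.backward(datt)
            self.conv.backward(dflat.reshape(-1, 1, 1, self.n))
        return dm


def cfrs_forward(matrix: FeatureMatrix | np.ndarray, net: CfrsNet, force_weights=None):
    """Single-matrix convenience wrapper around :meth:`CfrsNet.forward`."""
    m = matrix.values if isinstance(matrix, FeatureMatrix) else np.asarray(matrix)
    prob, w, fused = net.forward(m, train=False, force_weights=force_weights)
    return float(prob[0]), AttentionWeights(np.clip(w[0], 1e-12, 1 - 1e-12)), fused[0]


# ---------------------------------------------------------------------------
# shallow CNN (DL / CFDL)


class ShallowCnn:
    """3-conv-block CNN with optional squeeze-and-excitation gates.

    With ``se_enabled=False`` every SE gate is pinned to 1, which makes the
    network the attention-free DL model while keeping the parameterization
    (and hence the ablation) architecture-controlled.
    """

    def __init__(self, cfg: TrainConfig | None = None, seed: int = 0, se_enabled: bool = True):
        cfg = cfg or TrainConfig()
        rng = np.random.default_rng(seed)
        w1, w2, w3 = cfg.cnn_widths
        self.net = Sequential(
            [
                SEBlock(3, cfg.se_input_reduction, rng, name="se_input"),
                Conv2d(3, w1, 3, 3, rng, pad=1, name="conv1"),
                BatchNorm2d(w1, name="bn1"),
                ReLU(name="relu1"),
                SEBlock(w1, cfg.se_conv_reduction, rng, name="se1"),
                MaxPool2x2(name="pool1"),
                Conv2d(w1, w2, 3, 3, rng, pad=1, name="conv2"),
                BatchNorm2d(w2, name="bn2"),
                ReLU(name="relu2"),
                MaxPool2x2(name="pool2"),
                Conv2d(w2, w3, 3, 3, rng, pad=1, name="conv3"),
                BatchNorm2d(w3, name="bn3"),
                ReLU(name="relu3"),
                MaxPool2x2(name="pool3"),
                Flatten(name="flatten"),
                Dense(w3 * 10 * 10, cfg.fc_width, rng, name="fc1"),
                ReLU(name="relu_fc"),
                Dense(cfg.fc_width, 1, rng, name="fc2"),
            ]
        )
        self.se_enabled = se_enabled
        if not se_enabled:
            self.pin_se_gates(1.0)
            # nothing upstream of conv1 trains when the gates are pinned
            self.net.layer("conv1").skip_input_grad = True

    def pin_se_gates(self, value: float | None) -> None:
        for l in self.net.layers:
            if isinstance(l, SEBlock):
                l.force_gate = value

    def se_gates(self, layer: str = "se_input") -> np.ndarray:
        """Per-sample gates recorded on the most recent forward pass."""
        block = self.net.layer(layer)
        if block.last_gates is None:
            raise RuntimeError("no forward pass recorded yet")
        return block.last_gates

    def logits(self, x: np.ndarray, train: bool = False, cache: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=_nn.DTYPE)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != (3, 80, 80):
            raise ValueError(f"expected batch of 3 x 80 x 80 patches, got {x.shape}")
        return self.net.forward(x, train=train, cache=cache)[:, 0]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return _nn.sigmoid(self.logits(x, train=train))

    def get_weights(self):
        return self.net.get_weights()

    def set_weights(self, weights):
        self.net.set_weights(weights)


def dl_forward(patch: MultiSequencePatch | np.ndarray, model: ShallowCnn) -> float:
    x = patch.channels if isinstance(patch, MultiSequencePatch) else np.asarray(patch)
    return float(model.forward(x)[0])


cfdl_forward = dl_forward  # identical call surface; the model instance differs


def se_block(x: np.ndarray, block: SEBlock) -> np.ndarray:
    """Apply one squeeze-and-excitation gate to a C x H x W tensor."""
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 3
    out = block.forward(x[None] if single else x, train=False)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# datasets and training


@dataclass
class TrainHistory:
    epoch_loss: list[float] = field(default_factory=list)
    val_auc: list[float] = field(default_factory=list)
    best_epoch: int = -1
    lambda_star: float | None = None


def stratified_split(
    labels: np.ndarray, val_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Index split preserving class proportions (70/30 by default)."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_val = int(round(len(idx) * val_fraction))
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def _as_arrays(dataset) -> tuple[np.ndarray, np.ndarray]:
    """Accepts (X, y) arrays or lists of FeatureMatrix / MultiSequencePatch."""
    if isinstance(dataset, tuple) and len(dataset) == 2:
        X, y = dataset
        if isinstance(X, np.ndarray):
            return np.asarray(X, dtype=np.float64), np.asarray(y, dtype=np.float64)
        first = X[0]
        if isinstance(first, FeatureMatrix):
            return (
                np.stack([m.values for m in X]).astype(np.float64),
                np.asarray(y, dtype=np.float64),
            )
        if isinstance(first, MultiSequencePatch):
            return (
                np.stack([p.channels for p in X]).astype(np.float64),
                np.asarray(y, dtype=np.float64),
            )
    raise TypeError("dataset must be a (inputs, labels) pair")


def _augment_batch(xb: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = xb.copy()
    for i in range(out.shape[0]):
        if rng.random() < 0.5:
            out[i] = out[i, :, :, ::-1]
        k = rng.integers(0, 4)
        if k:
            out[i] = np.rot90(out[i], k=int(k), axes=(1, 2))
    return out


def _train_neural(model_kind: str, X, y, cfg: TrainConfig):
    rng = np.random.default_rng(cfg.seed)
    tr, va = stratified_split(y, cfg.val_fraction, cfg.seed)
    if len(np.unique(y[tr])) < 2:
        raise ValueError("training split contains a single class")
    Xtr, ytr, Xva, yva = X[tr], y[tr], X[va], y[va]

    if model_kind == "CFRS":
        net = CfrsNet(X.shape[2], seed=cfg.seed)
        fwd = lambda xb, train: net.forward(xb, train=train)[0]
        bwd = net.backward
        is_image = False
    else:
        net = ShallowCnn(cfg, seed=cfg.seed, se_enabled=(model_kind == "CFDL"))
        def fwd(xb, train):
            logit = net.logits(xb, train=train)
            net._last_logit_sig = _nn.sigmoid(logit)
            return net._last_logit_sig
        def bwd(g):
            net.net.backward(g[:, None])
        is_image = True

    weight_pos = weight_neg = 1.0
    if cfg.class_weight == "balanced":
        prev = ytr.mean()
        weight_pos, weight_neg = 0.5 / prev, 0.5 / (1 - prev)

    opt = Adam(net.params() if model_kind == "CFRS" else net.net.params(), lr=cfg.learning_rate)
    grads = net.grads() if model_kind == "CFRS" else net.net.grads()
    history = TrainHistory()
    best_auc, best_weights, since_best = -np.inf, net.get_weights(), 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(tr))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            xb, yb = Xtr[sel], ytr[sel]
            if cfg.augment and is_image:
                xb = _augment_batch(xb, rng)
            prob = fwd(xb, True).astype(np.float64)
            cw = np.where(yb == 1, weight_pos, weight_neg)
            p = np.clip(prob, 1e-12, 1 - 1e-12)
            loss = float(np.mean(cw * -(yb * np.log(p) + (1 - yb) * np.log(1 - p))))
            # d(mean weighted BCE)/d(logit) — stable even when prob saturates
            dlogit = (cw * (prob - yb) / len(yb)).astype(_nn.DTYPE)
            bwd(dlogit)
            opt.step([g.copy() for g in grads])
            losses.append(loss)
        history.epoch_loss.append(float(np.mean(losses)))

        val_prob = fwd(Xva, False) if len(va) else fwd(Xtr, False)
        val_y = yva if len(va) else ytr
        try:
            auc = _auc(val_prob, val_y)
        except ValueError:
            auc = 0.5
        history.val_auc.append(auc)
        if auc > best_auc:
            best_auc, best_weights, since_best = auc, net.get_weights(), 0
            history.best_epoch = epoch
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break

    net.set_weights(best_weights)
    return net, history


def train_model(model_kind: str, dataset, cfg: TrainConfig | None = None):
    """Train one of {RS, CFRS, DL, CFDL}; returns ``(model, history)``.

    ``dataset`` is ``(inputs, labels)`` where inputs are concatenated
    feature rows (RS), 3 x n feature matrices (CFRS) or 3 x 80 x 80
    patches (DL/CFDL).  RS is solved in closed form after the stratified
    5-fold lambda search; the neural models run seeded Adam/BCE training
    with early stopping on the validation AUC and return the best-
    validation checkpoint.
    """
    cfg = cfg or TrainConfig()
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}; expected one of {MODEL_KINDS}")
    X, y = _as_arrays(dataset)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes present")

    if model_kind == "RS":
        if X.ndim == 3:  # accept 3 x n matrices; concatenate channel rows
            X = X.reshape(X.shape[0], -1)
        grid = None if cfg.lambda_grid is None else np.asarray(cfg.lambda_grid)
        lam, _ = select_lambda_cv(X, y, grid=grid, seed=cfg.seed)
        model = rs_fit(X, y, lam)
        history = TrainHistory(lambda_star=lam)
        return model, history
    return _train_neural(model_kind, X, y, cfg)


def predict_scores(model, X) -> np.ndarray:
    """Uniform scoring across the four model types."""
    if isinstance(model, RidgeModel):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 3:
            X = X.reshape(X.shape[0], -1)
        return model.decision_function(X)
    if isinstance(model, CfrsNet):
        return model.forward(np.asarray(X), train=False)[0]
    if isinstance(model, ShallowCnn):
        X = np.asarray(X, dtype=np.float64)
        out = np.empty(X.shape[0])
        for start in range(0, X.shape[0], 64):  # bounded memory
            out[start : start + 64] = model.forward(X[start : start + 64], train=False)
        return out
    raise TypeError(f"unsupported model type {type(model)!r}")


# ---------------------------------------------------------------------------
# checkpoints

SCHEMA_VERSION = 1


def save_checkpoint(path, model_kind: str, model, cfg: TrainConfig, feature_names=None):
    """Serialize a trained model with schema version, channel order and config."""
    meta = {
        "schema_version": SCHEMA_VERSION,
        "model_kind": model_kind,
        "channel_order": ["T2w", "T1c", "ADC"],
        "train_config": asdict(cfg),
        "feature_names": list(feature_names) if feature_names is not None else None,
    }
    arrays = {}
    if isinstance(model, RidgeModel):
        arrays = {"w": model.w, "x_mean": model.x_mean,
                  "intercept": np.array(model.intercept), "lam": np.array(model.lam)}
    else:
        for i, p in enumerate(model.get_weights()):
            arrays[f"p{i}"] = p
        if isinstance(model, ShallowCnn):
            meta["se_enabled"] = model.se_enabled
            for l in model.net.layers:
                if isinstance(l, BatchNorm2d):
                    arrays[f"rm_{l.name}"] = l.running_mean
                    arrays[f"rv_{l.name}"] = l.running_var
        elif isinstance(model, CfrsNet):
            meta["n_features"] = model.n
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path):
    """Restore ``(model_kind, model, meta)`` from :func:`save_checkpoint`."""
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    kind = meta["model_kind"]
    cfg = TrainConfig(**{k: tuple(v) if isinstance(v, list) else v
                         for k, v in meta["train_config"].items()})
    if kind == "RS":
        model = RidgeModel(w=data["w"], lam=float(data["lam"]),
                           intercept=float(data["intercept"]), x_mean=data["x_mean"])
    elif kind == "CFRS":
        model = CfrsNet(meta["n_features"], seed=cfg.seed)
        model.set_weights([data[f"p{i}"] for i in range(len(model.params()))])
    else:
        model = ShallowCnn(cfg, seed=cfg.seed, se_enabled=meta.get("se_enabled", kind == "CFDL"))
        model.set_weights([data[f"p{i}"] for i in range(len(model.net.params()))])
        for l in model.net.layers:
            if isinstance(l, BatchNorm2d):
                l.running_mean = data[f"rm_{l.name}"]
                l.running_var = data[f"rv_{l.name}"]
    return kind, model, meta
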