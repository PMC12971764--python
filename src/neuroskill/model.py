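"""CNN-LSTM classifier with masked additive attention over temporal steps.

Architecture (per window of shape (T, S, F)):

1. a 1-D convolution applied to each of the T temporal steps independently
   (ReLU, L2 penalty on the kernel), followed by per-step max pooling and
   flattening — the spatial feature extractor;
2. a single LSTM over the T per-step feature vectors (L2 on both kernels),
   returning the full output sequence;
3. additive attention over the T step outputs, score_t = v . tanh(W h_t + b),
   with fully padded steps excluded from the softmax (score -inf, weight
   exactly 0) so padding cannot influence the context vector;
4. dropout -> dense ReLU -> dropout -> dense softmax over the 3 skill
   classes.

Training minimizes class-weighted categorical cross-entropy with Adam,
early-stopping when the monitored validation loss fails to improve for
``patience`` consecutive epochs (best weights restored).  All randomness
(initialization, shuffling, dropout) derives from ``ModelConfig.seed``, so
identical seeds give identical trained weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.utils.class_weight import compute_class_weight as _sk_class_weight

from .nn.autograd import (Adam, Tensor, conv1d_timedist, masked_softmax,
                          maxpool1d_timedist, softmax_probs, stack,
                          weighted_cross_entropy)
from .windows import WindowBatch

N_CLASSES = 3


@dataclass
class ModelConfig:
    """Hyperparameters; grid values follow the study's search space."""

    conv_filters: int = 64          # {32, 64, 128}
    kernel_size: int = 5            # {3, 5}
    pool_size: int = 2
    lstm_units: int = 100           # {50, 100, 150, 200}
    attention_units: int | None = None   # defaults to lstm_units
    dropout: float = 0.5            # {0.5, 0.6, 0.8}
    l2: float = 0.001               # {0.1, 0.01, 0.001}
    dense_units: int = 64
    epochs: int = 50                # {50, 100}
    batch_size: int = 64            # {64, 128, 256}
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    seed: int = 0

    def key(self) -> tuple:
        """Lexicographic identity used for deterministic tie-breaking."""
        return tuple(sorted(self.__dict__.items(),
                            key=lambda kv: kv[0]))


def compute_class_weights(labels: np.ndarray) -> dict[int, float]:
    """'Balanced' weights, w_c = n_total / (n_classes * n_c).

    All three classes must be present (an absent class would get infinite
    weight and the loss would be undefined for it).
    """
    labels = np.asarray(labels)
    present = np.unique(labels)
    if not np.array_equal(present, np.array([1, 2, 3])):
        missing = sorted(set([1, 2, 3]) - set(present.tolist()))
        raise ValueError(f"class(es) {missing} absent from labels")
    w = _sk_class_weight("balanced", classes=np.array([1, 2, 3]), y=labels)
    return {c: float(wi) for c, wi in zip([1, 2, 3], w)}


def _glorot(rng: np.random.Generator, shape: tuple) -> np.ndarray:
    fan_in = int(np.prod(shape[:-1]))
    fan_out = int(shape[-1])
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class SkillClassifier:
    """The CNN-LSTM-attention network, parameters stored as nn Tensors."""

    def __init__(self, cfg: ModelConfig, input_shape: tuple[int, int, int]):
        t_steps, s_len, n_feat = input_shape
        if s_len < cfg.kernel_size:
            raise ValueError("step length shorter than convolution kernel")
        self.cfg = cfg
        self.input_shape = tuple(input_shape)
        rng = np.random.default_rng(cfg.seed)
        u = cfg.lstm_units
        a = cfg.attention_units or u
        conv_out = s_len - cfg.kernel_size + 1
        pooled = conv_out // cfg.pool_size
        if pooled < 1:
            raise ValueError("pooling collapses the convolution output")
        self.flat_dim = pooled * cfg.conv_filters

        def p(shape):
            return Tensor(_glorot(rng, shape), requires_grad=True)

        self.params: dict[str, Tensor] = {
            "conv_w": p((cfg.kernel_size, n_feat, cfg.conv_filters)),
            "conv_b": Tensor(np.zeros(cfg.conv_filters), requires_grad=True),
            "lstm_wx": p((self.flat_dim, 4 * u)),
            "lstm_wh": p((u, 4 * u)),
            "lstm_b": Tensor(np.zeros(4 * u), requires_grad=True),
            "att_w": p((u, a)),
            "att_b": Tensor(np.zeros(a), requires_grad=True),
            "att_v": p((a, 1)),
            "dense_w": p((u, cfg.dense_units)),
            "dense_b": Tensor(np.zeros(cfg.dense_units), requires_grad=True),
            "out_w": p((cfg.dense_units, N_CLASSES)),
            "out_b": Tensor(np.zeros(N_CLASSES), requires_grad=True),
        }
        self.history: dict[str, list] = {"loss": [], "val_loss": []}
        self.stopped_epoch: int | None = None
        # forget-gate bias of 1: standard LSTM initialization
        self.params["lstm_b"].data[u:2 * u] = 1.0

    # -- forward -----------------------------------------------------------
    def forward(self, x: np.ndarray, mask: np.ndarray,
                training: bool = False,
                rng: np.random.Generator | None = None,
                return_attention: bool = False):
        """x: (N, T, S, F); mask: (N, T) bool -> logits Tensor (N, 3)."""
        p = self.params
        cfg = self.cfg
        n, t_steps = x.shape[0], x.shape[1]
        u = cfg.lstm_units

        h = conv1d_timedist(Tensor(x), p["conv_w"], p["conv_b"]).relu()
        h = maxpool1d_timedist(h, cfg.pool_size)
        h = h.reshape(n, t_steps, self.flat_dim)

        hid = Tensor(np.zeros((n, u), dtype=np.float32))
        cell = Tensor(np.zeros((n, u), dtype=np.float32))
        outs = []
        for t in range(t_steps):
            xt = h[:, t, :]
            gates = xt @ p["lstm_wx"] + hid @ p["lstm_wh"] + p["lstm_b"]
            i_g = gates[:, 0 * u:1 * u].sigmoid()
            f_g = gates[:, 1 * u:2 * u].sigmoid()
            g_g = gates[:, 2 * u:3 * u].tanh()
            o_g = gates[:, 3 * u:4 * u].sigmoid()
            cell = f_g * cell + i_g * g_g
            hid = o_g * cell.tanh()
            outs.append(hid)
        seq = stack(outs, axis=1)                       # (N, T, U)

        att_h = (seq @ p["att_w"] + p["att_b"]).tanh()  # (N, T, A)
        scores = (att_h @ p["att_v"]).reshape(n, t_steps)
        alpha = masked_softmax(scores, mask)            # (N, T)
        context = (alpha.reshape(n, t_steps, 1) * seq).sum(axis=1)

        context = self._dropout(context, training, rng)
        dense = (context @ p["dense_w"] + p["dense_b"]).relu()
        dense = self._dropout(dense, training, rng)
        logits = dense @ p["out_w"] + p["out_b"]
        if return_attention:
            return logits, alpha.data
        return logits

    def _dropout(self, x: Tensor, training: bool,
                 rng: np.random.Generator | None) -> Tensor:
        p_drop = self.cfg.dropout
        if not training or p_drop <= 0:
            return x
        keep = (rng.random(x.shape) >= p_drop) / (1.0 - p_drop)
        return x * keep.astype(np.float32)

    def _l2_penalty(self) -> Tensor:
        p = self.params
        pen = (p["conv_w"].square_sum() + p["lstm_wx"].square_sum()
               + p["lstm_wh"].square_sum())
        return Tensor(np.float32(self.cfg.l2)) * pen

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k, v in weights.items():
            self.params[k].data = v.copy()

    # -- loss / training ---------------------------------------------------
    def _loss(self, batch: WindowBatch, idx: np.ndarray,
              class_weights: dict[int, float], training: bool,
              rng: np.random.Generator | None) -> Tensor:
        x = batch.data[idx]
        mask = batch.mask[idx]
        y = batch.labels[idx] - 1
        w = np.array([class_weights[c] for c in batch.labels[idx]])
        logits = self.forward(x, mask, training=training, rng=rng)
        loss = weighted_cross_entropy(logits, y, w)
        if self.cfg.l2 > 0 and training:
            loss = loss + self._l2_penalty()
        return loss

    def evaluate_loss(self, batch: WindowBatch,
                      class_weights: dict[int, float],
                      chunk: int = 256) -> float:
        """Monitored (inference-mode, unregularized) weighted CE."""
        total, wtot = 0.0, 0.0
        for s in range(0, batch.n, chunk):
            idx = np.arange(s, min(s + chunk, batch.n))
            y = batch.labels[idx] - 1
            w = np.array([class_weights[c] for c in batch.labels[idx]])
            logits = self.forward(batch.data[idx], batch.mask[idx]).data
            probs = softmax_probs(logits)
            nll = -np.log(np.maximum(probs[np.arange(len(y)), y], 1e-12))
            total += float((w * nll).sum())
            wtot += float(w.sum())
        return total / max(wtot, 1e-12)

    def fit(self, train_batch: WindowBatch,
            val_batch: WindowBatch | None = None,
            class_weights: dict[int, float] | None = None,
            patience: int = 10) -> "SkillClassifier":
        if train_batch.n == 0:
            raise ValueError("empty training batch")
        cfg = self.cfg
        if class_weights is None:
            class_weights = {1: 1.0, 2: 1.0, 3: 1.0}
        rng = np.random.default_rng(cfg.seed + 1)
        opt = Adam(list(self.params.values()), lr=cfg.learning_rate)
        best = np.inf
        best_weights = self.get_weights()
        wait = 0
        for epoch in range(cfg.epochs):
            order = rng.permutation(train_batch.n)
            epoch_loss, n_batches = 0.0, 0
            for s in range(0, train_batch.n, cfg.batch_size):
                idx = order[s:s + cfg.batch_size]
                opt.zero_grad()
                loss = self._loss(train_batch, idx, class_weights,
                                  training=True, rng=rng)
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data)
                n_batches += 1
            self.history["loss"].append(epoch_loss / max(n_batches, 1))

            monitor_batch = val_batch if val_batch is not None else train_batch
            mon = self.evaluate_loss(monitor_batch, class_weights)
            self.history["val_loss"].append(mon)
            if mon < best - 1e-6:
                best = mon
                best_weights = self.get_weights()
                wait = 0
            else:
                wait += 1
                if wait >= patience:
                    self.stopped_epoch = epoch + 1
                    break
        self.set_weights(best_weights)
        return self

    def predict(self, batch: WindowBatch, chunk: int = 256
                ) -> tuple[np.ndarray, np.ndarray]:
        """Class probabilities (N, 3) and argmax labels in {1, 2, 3}."""
        if batch.data.shape[1:] != (self.input_shape[0],
                                    self.input_shape[1],
                                    self.input_shape[2]):
            raise ValueError(
                f"batch shape {batch.data.shape[1:]} does not match model "
                f"input {self.input_shape}")
        probs = np.empty((batch.n, N_CLASSES))
        for s in range(0, batch.n, chunk):
            e = min(s + chunk, batch.n)
            logits = self.forward(batch.data[s:e], batch.mask[s:e]).data
            probs[s:e] = softmax_probs(logits)
        return probs, probs.argmax(axis=1) + 1


def build_model(cfg: ModelConfig,
                input_shape: tuple[int, int, int]) -> SkillClassifier:
    """Construct an untrained classifier for windows of (T, S, F)."""
    return SkillClassifier(cfg, input_shape)


def train(model: SkillClassifier, train_batch: WindowBatch,
          val_batch: WindowBatch | None = None,
          class_weights: dict[int, float] | None = None,
          patience: int = 10) -> SkillClassifier:
    """Fit in place and return the model (convenience wrapper)."""
    return model.fit(train_batch, val_batch, class_weights, patience)


def predict(model: SkillClassifier, batch: WindowBatch
            ) -> tuple[np.ndarray, np.ndarray]:
    return model.predict(batch)
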