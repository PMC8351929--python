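"""Bidirectional-LSTM contact classifier for gait cycles.

The detector treats step-event detection as per-frame binary sequence
labelling: given four kinematic channels over one gait cycle it predicts, for
every frame, the probability that the foot is in contact with the ground.
Foot-strike and toe-off then fall out as the start and end of the predicted
contact phase.

The LSTM cell follows the standard gated formulation: with the concatenated
recurrent input ``[h_{t-1}, x_t]``, three sigmoid gates (forget ``f``, input
``i``, output ``o``) and a tanh candidate drive

    c_t = f_t * c_{t-1} + i_t * tanh(w_c [h_{t-1}, x_t] + b_c)
    h_t = o_t * tanh(c_t)

The network stacks two bidirectional LSTM layers (forward and time-reversed
unit pairs, outputs concatenated), a per-timestep dense ReLU layer and a
single sigmoid output node. Training minimises the masked binary
cross-entropy with Adam, in mini-batches, with dropout after each recurrent
layer and the dense layer, and early stopping on masked validation frame
accuracy.

Everything is implemented directly in NumPy — forward pass, backpropagation
through time and the optimiser — so the arithmetic is a transparent, testable
realisation of the cell equations rather than a framework call. Sequences are
zero-padded at the start to a fixed length; the recurrence is gated by the
sample mask, so state updates are skipped at padded positions and neither the
loss, the reported accuracy nor any real-frame output depends on values stored
in the padding.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .cycles import PaddedBatch, Scaler

__all__ = [
    "LSTMCellParams",
    "LSTMState",
    "ModelConfig",
    "PredictedContact",
    "ContactModel",
    "TrainingHistory",
    "CrossValResult",
    "lstm_cell_step",
    "train",
    "cross_validate",
    "masked_bce",
    "masked_accuracy",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # tanh form of the logistic function: stable and markedly faster than exp
    return 0.5 * (1.0 + np.tanh(0.5 * z))


# ---------------------------------------------------------------------------
# single LSTM cell


@dataclass
class LSTMCellParams:
    """Weights of one LSTM cell acting on the concatenation ``[h_{t-1}, x_t]``.

    ``gate_weights`` stacks the forget, input and output gate rows
    (``3*hidden x (hidden + input)``); ``cell_weights`` holds the tanh
    candidate (``hidden x (hidden + input)``).
    """

    gate_weights: np.ndarray
    gate_bias: np.ndarray
    cell_weights: np.ndarray
    cell_bias: np.ndarray

    def __post_init__(self) -> None:
        h = self.hidden_size
        if self.gate_weights.shape[0] != 3 * h or self.gate_bias.shape != (3 * h,):
            raise ValueError("gate weight/bias shapes inconsistent with hidden size")
        if self.cell_weights.shape[1] != self.gate_weights.shape[1]:
            raise ValueError("gate and cell weights disagree on input size")

    @property
    def hidden_size(self) -> int:
        return self.cell_weights.shape[0]

    @property
    def input_size(self) -> int:
        return self.gate_weights.shape[1] - self.hidden_size


@dataclass
class LSTMState:
    """Cell state ``c_t`` (internal memory) and hidden state ``h_t`` (output)."""

    cell: np.ndarray
    hidden: np.ndarray


def lstm_cell_step(params: LSTMCellParams, state: LSTMState, x: np.ndarray) -> LSTMState:
    """Advance one LSTM cell a single timestep.

    Supports a single sample (``x`` of shape ``(input,)``) or a batch
    (``(batch, input)``); states broadcast accordingly.
    """
    x = np.asarray(x, dtype=float)
    h_prev, c_prev = np.asarray(state.hidden, float), np.asarray(state.cell, float)
    if x.shape[-1] != params.input_size:
        raise ValueError(
            f"input size {x.shape[-1]} does not match parameters ({params.input_size})"
        )
    hsz = params.hidden_size
    concat = np.concatenate([h_prev, x], axis=-1)
    gates = _sigmoid(concat @ params.gate_weights.T + params.gate_bias)
    f, i, o = gates[..., :hsz], gates[..., hsz : 2 * hsz], gates[..., 2 * hsz :]
    g = np.tanh(concat @ params.cell_weights.T + params.cell_bias)
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    return LSTMState(cell=c, hidden=h)


# ---------------------------------------------------------------------------
# model configuration and containers


@dataclass
class ModelConfig:
    """Published architecture and training hyperparameters.

    Defaults reproduce the full-size network (two bidirectional LSTM layers of
    400 units, a 200-node dense layer, dropout 0.5, Adam on binary
    cross-entropy in mini-batches of 200, at most 100 epochs with early
    stopping after 10 stagnant validation epochs). ``scaled_down`` switches to
    a 2x64-unit / 32-node profile that trains in minutes on one CPU and is
    used by the package's own continuous tests.
    """

    lstm_layers: int = 2
    lstm_units: int = 400
    dense_units: int = 200
    dropout: float = 0.5
    batch_size: int = 200
    max_epochs: int = 100
    patience: int = 10
    learning_rate: float = 1e-3
    seed: int = 0
    scaled_down: bool = False
    dtype: str = "float64"

    def __post_init__(self) -> None:
        if self.scaled_down:
            self.lstm_units = 64
            self.dense_units = 32
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.patience > self.max_epochs:
            raise ValueError("patience cannot exceed max_epochs")
        if self.lstm_layers < 1:
            raise ValueError("need at least one recurrent layer")


@dataclass
class PredictedContact:
    """Per-frame contact probabilities for one cycle, with its sample mask."""

    probabilities: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.probabilities.shape != self.mask.shape:
            raise ValueError("probability and mask shapes differ")


@dataclass
class TrainingHistory:
    """Per-epoch losses and masked frame accuracies."""

    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": self.epochs,
                "train_loss": self.train_loss,
                "train_accuracy": self.train_accuracy,
                "val_loss": self.val_loss,
                "val_accuracy": self.val_accuracy,
            }
        )


def masked_bce(logits: np.ndarray, targets: np.ndarray, mask: np.ndarray) -> float:
    """Mean binary cross-entropy over unmasked frames, from logits."""
    per_frame = np.logaddexp(0.0, logits) - targets * logits
    denom = mask.sum()
    if denom == 0:
        raise ValueError("mask selects no frames")
    return float((per_frame * mask).sum() / denom)


def masked_accuracy(proba: np.ndarray, targets: np.ndarray, mask: np.ndarray) -> float:
    """Fraction of unmasked frames whose binarised prediction matches the label."""
    pred = (proba >= 0.5).astype(float)
    denom = mask.sum()
    if denom == 0:
        raise ValueError("mask selects no frames")
    return float(((pred == targets) * mask).sum() / denom)


# ---------------------------------------------------------------------------
# vectorised directional LSTM with mask-gated recurrence


def _init_direction(rng: np.random.Generator, d: int, h: int, dtype) -> dict[str, np.ndarray]:
    # Glorot-uniform input weights, orthogonal-ish recurrent weights, zero bias
    # with forget-gate bias 1 (standard recipe easing gradient flow early on)
    lim = np.sqrt(6.0 / (d + 4 * h))
    wx = rng.uniform(-lim, lim, size=(d, 4 * h))
    wh = rng.uniform(-np.sqrt(6.0 / (2 * h)), np.sqrt(6.0 / (2 * h)), size=(h, 4 * h))
    b = np.zeros(4 * h)
    b[:h] = 1.0
    return {"Wx": wx.astype(dtype), "Wh": wh.astype(dtype), "b": b.astype(dtype)}


def _lstm_dir_forward(p: dict, x: np.ndarray, mask: np.ndarray, want_cache: bool):
    """One directional LSTM over (B, T, D) with mask-gated state updates.

    Gate layout along the last axis of the pre-activation: [f, i, o, g].
    Returns outputs (B, T, H) and, when requested, the caches for BPTT.
    """
    b_, t_, _ = x.shape
    h_ = p["Wh"].shape[0]
    zx = x @ p["Wx"] + p["b"]
    h = np.zeros((b_, h_), dtype=x.dtype)
    c = np.zeros((b_, h_), dtype=x.dtype)
    out = np.empty((b_, t_, h_), dtype=x.dtype)
    cache = None
    if want_cache:
        cache = {k: np.empty((t_, b_, h_), dtype=x.dtype) for k in
                 ("f", "i", "o", "g", "c_prev", "tanh_c", "h_prev")}
    for t in range(t_):
        z = zx[:, t] + h @ p["Wh"]
        gates = _sigmoid(z[:, : 3 * h_])
        f = gates[:, :h_]
        i = gates[:, h_ : 2 * h_]
        o = gates[:, 2 * h_ :]
        g = np.tanh(z[:, 3 * h_ :])
        c_new = f * c + i * g
        tanh_c = np.tanh(c_new)
        h_new = o * tanh_c
        m = mask[:, t : t + 1]
        if want_cache:
            cache["f"][t], cache["i"][t], cache["o"][t], cache["g"][t] = f, i, o, g
            cache["c_prev"][t], cache["tanh_c"][t], cache["h_prev"][t] = c, tanh_c, h
        c = m * c_new + (1.0 - m) * c
        h = m * h_new + (1.0 - m) * h
        out[:, t] = h
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite activations in recurrent layer")
    return out, cache


def _lstm_dir_backward(p: dict, x: np.ndarray, mask: np.ndarray, cache: dict, d_out: np.ndarray):
    """BPTT for one directional LSTM; mirrors the gated forward recurrence."""
    b_, t_, d_ = x.shape
    h_ = p["Wh"].shape[0]
    d_wx = np.zeros_like(p["Wx"])
    d_wh = np.zeros_like(p["Wh"])
    d_b = np.zeros_like(p["b"])
    d_x = np.empty_like(x)
    dh_carry = np.zeros((b_, h_), dtype=x.dtype)
    dc_carry = np.zeros((b_, h_), dtype=x.dtype)
    for t in range(t_ - 1, -1, -1):
        m = mask[:, t : t + 1]
        f, i, o, g = cache["f"][t], cache["i"][t], cache["o"][t], cache["g"][t]
        c_prev, tanh_c, h_prev = cache["c_prev"][t], cache["tanh_c"][t], cache["h_prev"][t]
        dh_total = d_out[:, t] + dh_carry
        dh_new = m * dh_total
        dh_skip = (1.0 - m) * dh_total
        dc_new = m * dc_carry
        dc_skip = (1.0 - m) * dc_carry
        do = dh_new * tanh_c
        dc_new = dc_new + dh_new * o * (1.0 - tanh_c**2)
        df = dc_new * c_prev
        di = dc_new * g
        dg = dc_new * i
        dc_carry = dc_new * f + dc_skip
        dz = np.concatenate(
            [df * f * (1 - f), di * i * (1 - i), do * o * (1 - o), dg * (1 - g**2)],
            axis=1,
        )
        d_x[:, t] = dz @ p["Wx"].T
        d_wx += x[:, t].T @ dz
        d_wh += h_prev.T @ dz
        d_b += dz.sum(axis=0)
        dh_carry = dz @ p["Wh"].T + dh_skip
    return d_x, {"Wx": d_wx, "Wh": d_wh, "b": d_b}


# ---------------------------------------------------------------------------
# the full network


class ContactModel:
    """Stacked bidirectional LSTM contact-phase classifier."""

    def __init__(self, config: ModelConfig, input_dim: int = 4, scaler: Scaler | None = None):
        self.config = config
        self.input_dim = input_dim
        self.scaler = scaler
        self.dtype = np.dtype(config.dtype)
        rng = np.random.default_rng(config.seed)
        h = config.lstm_units
        self.params: dict[str, np.ndarray] = {}
        d = input_dim
        for layer in range(config.lstm_layers):
            for direction in ("fw", "bw"):
                for k, v in _init_direction(rng, d, h, self.dtype).items():
                    self.params[f"l{layer}_{direction}_{k}"] = v
            d = 2 * h
        k = config.dense_units
        lim = np.sqrt(6.0 / (d + k))
        self.params["dense_W"] = rng.uniform(-lim, lim, size=(d, k)).astype(self.dtype)
        self.params["dense_b"] = np.zeros(k, dtype=self.dtype)
        lim = np.sqrt(6.0 / (k + 1))
        self.params["out_w"] = rng.uniform(-lim, lim, size=(k,)).astype(self.dtype)
        self.params["out_b"] = np.zeros(1, dtype=self.dtype)

    # -- forward ------------------------------------------------------------

    def forward(
        self,
        inputs: np.ndarray,
        mask: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ):
        """Run the network; returns (logits, caches). Dropout only when training."""
        x = np.asarray(inputs, dtype=self.dtype)
        m = np.asarray(mask, dtype=self.dtype)
        if x.ndim != 3 or x.shape[2] != self.input_dim:
            raise ValueError(f"inputs must be (cycles, frames, {self.input_dim})")
        t_full = x.shape[1]
        # columns masked for every cycle (the shared padded prefix) carry no
        # state under the gated recurrence; skip them and refill logits with 0
        # (probability 0.5) afterwards
        any_real = m.astype(bool).any(axis=0)
        t0 = int(np.argmax(any_real)) if any_real.any() else 0
        x, m = x[:, t0:], m[:, t0:]
        caches: dict = {"layers": [], "dropout": [], "x": x, "t0": t0}
        p_drop = self.config.dropout if training else 0.0
        if training and p_drop > 0 and rng is None:
            raise ValueError("training forward pass with dropout needs an rng")
        out = x
        for layer in range(self.config.lstm_layers):
            per_dir = []
            outs = []
            for direction in ("fw", "bw"):
                p = {k: self.params[f"l{layer}_{direction}_{k}"] for k in ("Wx", "Wh", "b")}
                if direction == "fw":
                    o_, cache = _lstm_dir_forward(p, out, m, training)
                    per_dir.append((p, out, m, cache))
                    outs.append(o_)
                else:
                    xr, mr = out[:, ::-1], m[:, ::-1]
                    o_, cache = _lstm_dir_forward(p, xr, mr, training)
                    per_dir.append((p, xr, mr, cache))
                    outs.append(o_[:, ::-1])
            out = np.concatenate(outs, axis=2)
            caches["layers"].append(per_dir)
            if p_drop > 0:
                keep = (rng.random(out.shape) >= p_drop).astype(self.dtype) / (1 - p_drop)
                out = out * keep
                caches["dropout"].append(keep)
            else:
                caches["dropout"].append(None)
        caches["lstm_out"] = out
        pre = out @ self.params["dense_W"] + self.params["dense_b"]
        relu = np.maximum(pre, 0.0)
        caches["pre_relu"] = pre
        if p_drop > 0:
            keep = (rng.random(relu.shape) >= p_drop).astype(self.dtype) / (1 - p_drop)
            relu = relu * keep
            caches["dense_dropout"] = keep
        else:
            caches["dense_dropout"] = None
        caches["relu"] = relu
        logits_active = relu @ self.params["out_w"] + self.params["out_b"][0]
        if not np.all(np.isfinite(logits_active)):
            raise FloatingPointError("non-finite activations at output layer")
        logits = np.zeros((x.shape[0], t_full), dtype=self.dtype)
        logits[:, t0:] = logits_active
        return logits, caches

    def predict_proba(self, inputs: np.ndarray, mask: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(inputs, mask, training=False)
        return _sigmoid(logits)

    def predict(self, batch: PaddedBatch) -> list[PredictedContact]:
        """Per-cycle contact probabilities for a padded batch."""
        proba = self.predict_proba(batch.inputs, batch.mask)
        return [
            PredictedContact(probabilities=proba[i], mask=batch.mask[i])
            for i in range(batch.n_cycles)
        ]

    # -- backward -----------------------------------------------------------

    def loss_and_grads(
        self,
        inputs: np.ndarray,
        targets: np.ndarray,
        mask: np.ndarray,
        rng: np.random.Generator | None = None,
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Masked BCE loss and its gradient for one mini-batch."""
        y = np.asarray(targets, dtype=self.dtype)
        m = np.asarray(mask, dtype=self.dtype)
        logits, caches = self.forward(inputs, mask, training=True, rng=rng)
        loss = masked_bce(logits, y, m)
        t0 = caches["t0"]
        y, m, logits = y[:, t0:], m[:, t0:], logits[:, t0:]
        denom = m.sum()
        dlogits = (_sigmoid(logits) - y) * m / denom

        grads: dict[str, np.ndarray] = {}
        relu = caches["relu"]
        grads["out_w"] = np.einsum("btk,bt->k", relu, dlogits)
        grads["out_b"] = np.array([dlogits.sum()], dtype=self.dtype)
        drelu = dlogits[..., None] * self.params["out_w"]
        if caches["dense_dropout"] is not None:
            drelu = drelu * caches["dense_dropout"]
        dpre = drelu * (caches["pre_relu"] > 0)
        lstm_out = caches["lstm_out"]
        grads["dense_W"] = np.einsum("btd,btk->dk", lstm_out, dpre)
        grads["dense_b"] = dpre.sum(axis=(0, 1))
        d_out = dpre @ self.params["dense_W"].T

        for layer in range(self.config.lstm_layers - 1, -1, -1):
            keep = caches["dropout"][layer]
            if keep is not None:
                d_out = d_out * keep
            h = self.config.lstm_units
            d_next = None
            for di, direction in enumerate(("fw", "bw")):
                p, x_dir, m_dir, cache = caches["layers"][layer][di]
                d_slice = d_out[:, :, di * h : (di + 1) * h]
                if direction == "bw":
                    d_slice = d_slice[:, ::-1]
                d_x, g = _lstm_dir_backward(p, x_dir, m_dir, cache, d_slice)
                if direction == "bw":
                    d_x = d_x[:, ::-1]
                for k, v in g.items():
                    grads[f"l{layer}_{direction}_{k}"] = v
                d_next = d_x if d_next is None else d_next + d_x
            d_out = d_next
        return loss, grads

    # -- training -----------------------------------------------------------

    def evaluate(self, batch: PaddedBatch) -> tuple[float, float]:
        """(masked BCE loss, masked frame accuracy) without dropout."""
        logits, _ = self.forward(batch.inputs, batch.mask, training=False)
        m = batch.mask.astype(self.dtype)
        y = batch.targets.astype(self.dtype)
        return masked_bce(logits, y, m), masked_accuracy(_sigmoid(logits), y, m)

    def fit(self, train_batch: PaddedBatch, val_batch: PaddedBatch) -> TrainingHistory:
        """Mini-batch Adam training with early stopping on validation accuracy.

        The best-validation weights are restored when training stops.
        """
        if train_batch.n_cycles == 0:
            raise ValueError("empty training set")
        cfg = self.config
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
        adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        history = TrainingHistory()
        best_acc, best_params, best_epoch = -np.inf, None, -1
        n = train_batch.n_cycles
        for epoch in range(1, cfg.max_epochs + 1):
            order = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                loss, grads = self.loss_and_grads(
                    train_batch.inputs[idx],
                    train_batch.targets[idx],
                    train_batch.mask[idx],
                    rng=rng,
                )
                step += 1
                lr_t = cfg.learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
                for k, g in grads.items():
                    adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * g
                    adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * g * g
                    self.params[k] -= (lr_t * adam_m[k] / (np.sqrt(adam_v[k]) + eps)).astype(
                        self.dtype
                    )
                epoch_loss += loss
                n_batches += 1
            _, train_acc = self.evaluate(train_batch)
            val_loss, val_acc = self.evaluate(val_batch)
            history.epochs.append(epoch)
            history.train_loss.append(epoch_loss / n_batches)
            history.train_accuracy.append(train_acc)
            history.val_loss.append(val_loss)
            history.val_accuracy.append(val_acc)
            if val_acc > best_acc:
                best_acc, best_epoch = val_acc, epoch
                best_params = copy.deepcopy(self.params)
            if epoch - best_epoch >= cfg.patience:
                history.stopped_early = True
                break
        if best_params is not None:
            self.params = best_params
        history.best_epoch = best_epoch
        return history

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Serialise weights, config and scaler into a single .npz file."""
        meta = {"config": asdict(self.config), "input_dim": self.input_dim}
        arrays = dict(self.params)
        if self.scaler is not None:
            arrays["scaler_mean"] = self.scaler.mean
            arrays["scaler_sd"] = self.scaler.sd
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "ContactModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg_dict = meta["config"]
            # scaled_down already applied to the stored unit counts
            cfg_dict["scaled_down"] = False
            cfg = ModelConfig(**cfg_dict)
            scaler = None
            if "scaler_mean" in data:
                scaler = Scaler(mean=data["scaler_mean"], sd=data["scaler_sd"])
            model = cls(cfg, input_dim=meta["input_dim"], scaler=scaler)
            for k in model.params:
                model.params[k] = data[k]
        return model


# ---------------------------------------------------------------------------
# protocols


def train(
    config: ModelConfig, train_batch: PaddedBatch, val_batch: PaddedBatch
) -> tuple[ContactModel, TrainingHistory]:
    """Train a fresh model; convenience wrapper around `ContactModel.fit`."""
    model = ContactModel(config, input_dim=train_batch.inputs.shape[2], scaler=train_batch.scaler)
    history = model.fit(train_batch, val_batch)
    return model, history


@dataclass
class CrossValResult:
    """Participant-wise k-fold cross-validation outcome."""

    fold_accuracies: list[float]
    mean_accuracy: float
    sd_accuracy: float
    best_fold: int
    final_model: ContactModel
    histories: list[TrainingHistory]
    final_history: TrainingHistory


def cross_validate(config: ModelConfig, folds: list[list]) -> CrossValResult:
    """K-fold cross-validation over participant-wise folds of gait cycles.

    For each fold, a model trains on the remaining folds (with the scaler
    fitted on that training portion only) and is scored on the held-out fold.
    The winning configuration is then refitted on all folds combined — scaler
    refitted likewise — for final testing, using the best fold as the early
    stopping monitor.
    """
    from .cycles import standardise_and_pad

    if len(folds) < 2:
        raise ValueError("need at least two folds")
    for i, f in enumerate(folds):
        if not f:
            raise ValueError(f"fold {i} contains no cycles")
    accs: list[float] = []
    histories: list[TrainingHistory] = []
    for i in range(len(folds)):
        train_cycles = [c for j, f in enumerate(folds) if j != i for c in f]
        tb = standardise_and_pad(train_cycles)
        vb = standardise_and_pad(folds[i], scaler=tb.scaler)
        model, hist = train(config, tb, vb)
        _, acc = model.evaluate(vb)
        accs.append(acc)
        histories.append(hist)
    best = int(np.argmax(accs))
    all_cycles = [c for f in folds for c in f]
    tb = standardise_and_pad(all_cycles)
    vb = standardise_and_pad(folds[best], scaler=tb.scaler)
    final_model, final_history = train(config, tb, vb)
    return CrossValResult(
        fold_accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        sd_accuracy=float(np.std(accs)),
        best_fold=best,
        final_model=final_model,
        histories=histories,
        final_history=final_history,
    )
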