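"""A compact feed-forward multilayer perceptron in numpy.

The classifier backbone is a seven-hidden-layer MLP: rectified-linear
activations on hidden layers 1-6, a logistic sigmoid on hidden layer 7,
and a single sigmoid output unit giving P(SPLX).  Inverted dropout follows
every hidden layer during training; optimisation is Adam on the binary
cross-entropy with mini-batches and early stopping on a monitoring set.
With the default widths (72, 96, 72, 48, 32, 16, 8) and a 7-feature input
the network has 20,313 trainable parameters.

Everything is plain numpy, so training is bit-reproducible for a fixed
Generator on a given platform and fast enough for the ensemble sizes this
package uses (tens of networks on a few thousand rows).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, TrainingError

__all__ = ["NetworkSpec", "MLPNetwork"]

_DEFAULT_WIDTHS = (72, 96, 72, 48, 32, 16, 8)


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture and training hyper-parameters.

    ``input_dim`` may be ``None`` to be inferred from the data at training
    time.  The hidden activation plan is fixed: ReLU on layers 1-6,
    sigmoid on layer 7 (and on the output unit).
    """

    input_dim: int | None = None
    hidden_widths: tuple[int, ...] = _DEFAULT_WIDTHS
    dropout_rate: float = 0.2
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 32
    patience: int = 20
    min_delta: float = 1e-4

    def validate(self) -> None:
        if len(self.hidden_widths) != 7:
            raise ConfigError(
                f"the architecture uses exactly 7 hidden layers, got {len(self.hidden_widths)}"
            )
        if any(w < 1 for w in self.hidden_widths):
            raise ConfigError(f"hidden widths must be >= 1, got {self.hidden_widths}")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.input_dim is not None and self.input_dim < 1:
            raise ConfigError(f"input_dim must be >= 1, got {self.input_dim}")
        if self.epochs < 1 or self.batch_size < 1 or self.patience < 0:
            raise ConfigError("epochs and batch_size must be >= 1, patience >= 0")

    def n_parameters(self, input_dim: int | None = None) -> int:
        """Total trainable parameter count for the given input width."""
        d = input_dim if input_dim is not None else self.input_dim
        if d is None:
            raise ConfigError("input_dim is required to count parameters")
        widths = (d, *self.hidden_widths, 1)
        return sum((a + 1) * b for a, b in zip(widths, widths[1:]))


def _fused_adam(params, grads, m, v, lr, b1, b2, eps, t) -> None:
    """In-place Adam update with bias correction folded into scalars."""
    dt = params.dtype.type
    np.multiply(m, dt(b1), out=m)
    m += dt(1 - b1) * grads
    np.multiply(v, dt(b2), out=v)
    gsq = grads * grads
    v += dt(1 - b2) * gsq
    s2 = np.sqrt(1 - b2**t)
    denom = np.sqrt(v, out=gsq)  # reuse the gsq buffer
    denom += dt(eps * s2)
    step = np.divide(m, denom, out=denom)
    np.multiply(step, dt(lr * s2 / (1 - b1**t)), out=step)
    params -= step


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class MLPNetwork:
    """One trainable member network.

    Layers 0-5 are ReLU, layer 6 sigmoid, output sigmoid.  Weights are
    He-initialised on ReLU layers and Glorot-initialised on sigmoid layers.
    """

    def __init__(self, spec: NetworkSpec, input_dim: int, rng: np.random.Generator):
        spec.validate()
        if input_dim < 1:
            raise ConfigError(f"input_dim must be >= 1, got {input_dim}")
        self.spec = spec
        self.input_dim = int(input_dim)
        widths = (self.input_dim, *spec.hidden_widths, 1)
        self.n_layers = len(widths) - 1  # 8 weight layers
        # all parameters live in one flat vector; W[i]/b[i] are views into
        # it, so the Adam update is a handful of whole-vector operations
        shapes = [(a, b) for a, b in zip(widths, widths[1:])]
        n_params = sum((a + 1) * b for a, b in shapes)
        # float32 throughout: the standard precision for network training,
        # and twice the memory bandwidth of float64 on these small matmuls
        self._params = np.zeros(n_params, dtype=np.float32)
        self._grads = np.zeros(n_params, dtype=np.float32)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        self._gW: list[np.ndarray] = []
        self._gb: list[np.ndarray] = []
        offset = 0
        for fan_in, fan_out in shapes:
            w = self._params[offset : offset + fan_in * fan_out].reshape(fan_in, fan_out)
            gw = self._grads[offset : offset + fan_in * fan_out].reshape(fan_in, fan_out)
            offset += fan_in * fan_out
            self.W.append(w)
            self._gW.append(gw)
        for fan_in, fan_out in shapes:
            self.b.append(self._params[offset : offset + fan_out])
            self._gb.append(self._grads[offset : offset + fan_out])
            offset += fan_out
        for layer, (fan_in, fan_out) in enumerate(shapes):
            if layer < 6:  # ReLU layers: He normal
                self.W[layer][:] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            else:  # sigmoid layers: Glorot uniform
                limit = np.sqrt(6.0 / (fan_in + fan_out))
                self.W[layer][:] = rng.uniform(-limit, limit, size=(fan_in, fan_out))
        self._rng = rng
        self._m = np.zeros(n_params, dtype=np.float32)
        self._v = np.zeros(n_params, dtype=np.float32)
        self._adam_t = 0

    # -- forward -----------------------------------------------------------
    def _forward(self, X: np.ndarray, training: bool):
        """Return (post-dropout inputs per layer, pre-dropout activations,
        dropout masks, output probabilities)."""
        inputs = [X]  # what each weight layer consumed
        pre_acts: list[np.ndarray] = []  # activation outputs before dropout
        masks: list[np.ndarray | None] = []
        h = X
        rate = self.spec.dropout_rate
        dropout = training and rate > 0.0
        if dropout:
            # one random block per batch, sliced per layer
            total = sum(self.spec.hidden_widths)
            big_mask = (
                self._rng.random((len(X), total)) >= rate
            ).astype(np.float32) * np.float32(1.0 / (1.0 - rate))
        offset = 0
        for layer in range(self.n_layers - 1):  # hidden layers
            z = h @ self.W[layer] + self.b[layer]
            a = np.maximum(z, 0.0) if layer < 6 else _sigmoid(z)
            pre_acts.append(a)
            if dropout:
                width = a.shape[1]
                mask = big_mask[:, offset : offset + width]
                offset += width
                h = a * mask
            else:
                mask = None
                h = a
            masks.append(mask)
            inputs.append(h)
        z_out = h @ self.W[-1] + self.b[-1]
        p = _sigmoid(z_out)[:, 0]
        return inputs, pre_acts, masks, p

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(SPLX) per row, dropout off."""
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 2 or X.shape[1] != self.input_dim:
            raise ConfigError(
                f"expected input of width {self.input_dim}, got shape {X.shape}"
            )
        return self._forward(X, training=False)[3]

    @staticmethod
    def _bce(p: np.ndarray, y: np.ndarray) -> float:
        eps = 1e-7
        p = np.clip(np.asarray(p, dtype=np.float64), eps, 1.0 - eps)
        y = np.asarray(y, dtype=np.float64)
        return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))

    # -- training ----------------------------------------------------------
    def _adam_step(self) -> None:
        lr = self.spec.learning_rate
        b1, b2, eps = 0.9, 0.999, 1e-8
        self._adam_t += 1
        t = self._adam_t
        _fused_adam(self._params, self._grads, self._m, self._v, lr, b1, b2, eps, t)

    def _backward(self, inputs, pre_acts, masks, p, y) -> None:
        """Accumulate BCE gradients into the flat gradient vector."""
        n = len(y)
        # output layer: d(BCE)/dz = (p - y) / n  (sigmoid + BCE)
        delta = ((p - y) * np.float32(1.0 / n))[:, None]
        np.matmul(inputs[-1].T, delta, out=self._gW[-1])
        self._gb[-1][:] = delta.sum(axis=0)
        upstream = delta @ self.W[-1].T
        for layer in range(self.n_layers - 2, -1, -1):
            if masks[layer] is not None:
                upstream *= masks[layer]
            a = pre_acts[layer]
            if layer < 6:
                dz = upstream * (a > 0.0)
            else:
                dz = upstream * (a * (1.0 - a))
            np.matmul(inputs[layer].T, dz, out=self._gW[layer])
            self._gb[layer][:] = dz.sum(axis=0)
            if layer > 0:
                upstream = dz @ self.W[layer].T

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_monitor: np.ndarray | None = None,
        y_monitor: np.ndarray | None = None,
    ) -> dict:
        """Train with Adam + early stopping; returns the loss history.

        ``y`` is 1 for SPLX, 0 for SPL-sham.  When a monitoring set is
        given, training stops after ``patience`` epochs without a
        ``min_delta`` improvement in monitoring loss and the best weights
        are restored; otherwise the full epoch budget runs.
        """
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        if len(X) == 0:
            raise TrainingError("empty training set")
        if len(np.unique(y)) < 2:
            raise TrainingError("training set contains a single class")
        spec = self.spec
        monitor = X_monitor is not None and y_monitor is not None and len(X_monitor) > 0
        history = {"train_loss": [], "monitor_loss": []}
        best_loss = np.inf
        best_params = None
        stale = 0
        n = len(X)
        for _epoch in range(spec.epochs):
            order = self._rng.permutation(n)
            batch_losses: list[float] = []
            for start in range(0, n, spec.batch_size):
                idx = order[start : start + spec.batch_size]
                yb = y[idx]
                inputs, pre_acts, masks, p = self._forward(X[idx], training=True)
                batch_losses.append(self._bce(p, yb) * len(yb))
                self._backward(inputs, pre_acts, masks, p, yb)
                self._adam_step()
            history["train_loss"].append(sum(batch_losses) / n)
            if monitor:
                mon_loss = self._bce(self.predict_proba(X_monitor), np.asarray(y_monitor, float))
                history["monitor_loss"].append(mon_loss)
                if mon_loss < best_loss - spec.min_delta:
                    best_loss = mon_loss
                    best_params = self._params.copy()
                    stale = 0
                else:
                    stale += 1
                    if stale >= spec.patience:
                        break
        if monitor and best_params is not None:
            self._params[:] = best_params
        return history


def fit_members(
    networks: list[MLPNetwork],
    Xs: list[np.ndarray],
    ys: list[np.ndarray],
    X_monitors: list[np.ndarray] | None = None,
    y_monitor: np.ndarray | None = None,
) -> list[dict]:
    """Train several members jointly via stacked (batched) linear algebra.

    Arithmetic per member matches :meth:`MLPNetwork.fit` — same Adam
    schedule, same per-member RNG draws for shuffling and dropout, same
    early-stopping rule evaluated per member — but the matmuls and Adam
    updates run stacked over members, which removes most of the
    per-operation overhead of training members one at a time.  Members
    whose early stopping has triggered keep their frozen best weights; the
    loop ends when every member has stopped or the epoch budget is spent.

    All members must share one spec and equally sized training sets; when
    they do not, this falls back to sequential fitting.
    """
    m_count = len(networks)
    if m_count == 0:
        return []
    spec = networks[0].spec
    same_shape = (
        all(net.spec == spec for net in networks)
        and len({x.shape for x in Xs}) == 1
    )
    monitor = (
        X_monitors is not None
        and y_monitor is not None
        and all(len(x) > 0 for x in X_monitors)
    )
    if not same_shape or m_count == 1:
        return [
            net.fit(
                X,
                y,
                X_monitors[i] if monitor else None,
                y_monitor if monitor else None,
            )
            for i, (net, X, y) in enumerate(zip(networks, Xs, ys))
        ]
    for X, y in zip(Xs, ys):
        if len(X) == 0:
            raise TrainingError("empty training set")
        if len(np.unique(y)) < 2:
            raise TrainingError("training set contains a single class")

    n, d = Xs[0].shape
    n_layers = networks[0].n_layers
    X_st = np.stack([np.asarray(x, dtype=np.float32) for x in Xs])     # (M, n, d)
    y_st = np.stack([np.asarray(y, dtype=np.float32) for y in ys])     # (M, n)
    if monitor:
        Xm_st = np.stack([np.asarray(x, dtype=np.float32) for x in X_monitors])
        ym = np.asarray(y_monitor, dtype=np.float32)

    # stacked parameters / Adam state; per-layer views into (M, P) blocks
    P = len(networks[0]._params)
    params = np.stack([net._params for net in networks])               # (M, P)
    grads = np.zeros_like(params)
    adam_m = np.zeros_like(params)
    adam_v = np.zeros_like(params)
    widths = (d, *spec.hidden_widths, 1)
    W_views, gW_views = [], []
    offset = 0
    for fan_in, fan_out in zip(widths, widths[1:]):
        size = fan_in * fan_out
        W_views.append(params[:, offset : offset + size].reshape(m_count, fan_in, fan_out))
        gW_views.append(grads[:, offset : offset + size].reshape(m_count, fan_in, fan_out))
        offset += size
    b_views, gb_views = [], []
    for fan_in, fan_out in zip(widths, widths[1:]):
        b_views.append(params[:, offset : offset + fan_out])
        gb_views.append(grads[:, offset : offset + fan_out])
        offset += fan_out

    rate = spec.dropout_rate
    total_hidden = sum(spec.hidden_widths)
    lr, b1, b2, eps_adam = spec.learning_rate, 0.9, 0.999, 1e-8
    rows = np.arange(m_count)[:, None]

    def forward_stacked(h, training, rngs=None):
        inputs = [h]
        pre_acts = []
        masks = []
        if training and rate > 0.0:
            big = np.stack([r.random((h.shape[1], total_hidden)) for r in rngs])
            big_mask = (big >= rate).astype(np.float32) * np.float32(1.0 / (1.0 - rate))
        off = 0
        for layer in range(n_layers - 1):
            z = h @ W_views[layer] + b_views[layer][:, None, :]
            a = np.maximum(z, 0.0) if layer < 6 else _sigmoid(z)
            pre_acts.append(a)
            if training and rate > 0.0:
                w = a.shape[2]
                mask = big_mask[:, :, off : off + w]
                off += w
                h = a * mask
            else:
                mask = None
                h = a
            masks.append(mask)
            inputs.append(h)
        z_out = h @ W_views[-1] + b_views[-1][:, None, :]
        p = _sigmoid(z_out)[..., 0]                                    # (M, b)
        return inputs, pre_acts, masks, p

    def bce_per_member(p, y):
        pc = np.clip(p, 1e-12, 1.0 - 1e-12)
        return -np.mean(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc), axis=-1)

    histories = [{"train_loss": [], "monitor_loss": []} for _ in range(m_count)]
    best_loss = np.full(m_count, np.inf)
    best_params = [None] * m_count
    stale = np.zeros(m_count, dtype=int)
    stopped = np.zeros(m_count, dtype=bool)
    adam_t = 0
    rngs = [net._rng for net in networks]

    for _epoch in range(spec.epochs):
        orders = np.stack([r.permutation(n) for r in rngs])
        loss_accum = np.zeros(m_count)
        for start in range(0, n, spec.batch_size):
            idx = orders[:, start : start + spec.batch_size]
            Xb = X_st[rows, idx]                                       # (M, b, d)
            yb = y_st[rows, idx]
            inputs, pre_acts, masks, p = forward_stacked(Xb, True, rngs)
            loss_accum += bce_per_member(p, yb) * idx.shape[1]
            # backward
            delta = ((p - yb) * np.float32(1.0 / idx.shape[1]))[..., None]
            gW_views[-1][:] = np.swapaxes(inputs[-1], 1, 2) @ delta
            gb_views[-1][:] = delta.sum(axis=1)
            upstream = delta @ np.swapaxes(W_views[-1], 1, 2)
            for layer in range(n_layers - 2, -1, -1):
                if masks[layer] is not None:
                    upstream *= masks[layer]
                a = pre_acts[layer]
                dz = upstream * (a > 0.0) if layer < 6 else upstream * (a * (1.0 - a))
                gW_views[layer][:] = np.swapaxes(inputs[layer], 1, 2) @ dz
                gb_views[layer][:] = dz.sum(axis=1)
                if layer > 0:
                    upstream = dz @ np.swapaxes(W_views[layer], 1, 2)
            # Adam on the stacked flat parameters
            adam_t += 1
            _fused_adam(params, grads, adam_m, adam_v, lr, b1, b2, eps_adam, adam_t)
        train_losses = loss_accum / n
        for i in range(m_count):
            histories[i]["train_loss"].append(float(train_losses[i]))
        if monitor:
            _, _, _, pm = forward_stacked(Xm_st, False)
            mon_losses = bce_per_member(pm, ym[None, :])
            for i in range(m_count):
                if stopped[i]:
                    continue
                ml = float(mon_losses[i])
                histories[i]["monitor_loss"].append(ml)
                if ml < best_loss[i] - spec.min_delta:
                    best_loss[i] = ml
                    best_params[i] = params[i].copy()
                    stale[i] = 0
                else:
                    stale[i] += 1
                    if stale[i] >= spec.patience:
                        stopped[i] = True
            if stopped.all():
                break
    for i, net in enumerate(networks):
        if monitor and best_params[i] is not None:
            net._params[:] = best_params[i]
        else:
            net._params[:] = params[i]
    return histories
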