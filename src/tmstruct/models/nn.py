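"""Sequence-labelling neural networks in plain NumPy.

Architecture: an embedding layer maps the one-hot sequence to a dense
vector, which is concatenated with the evolutionary profile and fed to a
hidden stack of convolutions (plain or dilated, ReLU) or bidirectional
LSTM layers (tanh outputs of both directions concatenated), optionally
with residual connections; a stack of window-1 dense convolutions feeds
one output head per target (linear / sigmoid / softmax with the matching
squared-error / cross-entropy loss).  Per-target masks zero out invalid
residues in every loss.

Training is Adam with gradient accumulation over ``batch_size`` sequences
per update, validation-based early stopping (patience 10 epochs), and
learning-rate decay (x0.1 after 5 epochs without improvement); the weights
of the best validation epoch are restored.
"""

from __future__ import annotations

import numpy as np

from .specs import ArchitectureSpec, TargetDef, TrainConfig

__all__ = ["Network", "build_network", "train_network", "EarlyStopper", "Adam"]

_EPS = 1e-12


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Conv1D:
    """1-D convolution over the sequence axis with optional dilation.

    Window size 1 makes this a per-position dense layer.
    """

    def __init__(self, c_in, c_out, w, dilation=1, relu=True, rng=None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (w * c_in)) if relu else np.sqrt(1.0 / (w * c_in))
        self.W = rng.normal(0.0, scale, size=(w * c_in, c_out))
        self.b = np.zeros(c_out)
        self.c_in, self.c_out, self.w, self.dilation = c_in, c_out, w, dilation
        self.relu = relu
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def _offsets(self):
        half = (self.w - 1) // 2
        return [(k - half) * self.dilation for k in range(self.w)]

    def forward(self, X):
        L = len(X)
        Xw = np.zeros((L, self.w, self.c_in))
        for k, off in enumerate(self._offsets()):
            lo, hi = max(0, -off), min(L, L - off)
            if lo < hi:
                Xw[lo:hi, k] = X[lo + off:hi + off]
        Z = Xw.reshape(L, -1) @ self.W + self.b
        Y = np.maximum(Z, 0.0) if self.relu else Z
        self._cache = (Xw, Z, L)
        return Y

    def backward(self, dY):
        Xw, Z, L = self._cache
        dZ = dY * (Z > 0) if self.relu else dY
        self.dW += Xw.reshape(L, -1).T @ dZ
        self.db += dZ.sum(axis=0)
        dXw = (dZ @ self.W.T).reshape(L, self.w, self.c_in)
        dX = np.zeros((L, self.c_in))
        for k, off in enumerate(self._offsets()):
            lo, hi = max(0, -off), min(L, L - off)
            if lo < hi:
                dX[lo + off:hi + off] += dXw[lo:hi, k]
        return dX


def _lstm_forward(X, Wx, Wh, b):
    L = len(X)
    H = Wh.shape[0]
    gates = np.zeros((L, 4, H))
    C = np.zeros((L, H))
    Hs = np.zeros((L, H))
    h = np.zeros(H)
    c = np.zeros(H)
    for t in range(L):
        a = X[t] @ Wx + h @ Wh + b
        i = _sigmoid(a[:H])
        f = _sigmoid(a[H:2 * H])
        g = np.tanh(a[2 * H:3 * H])
        o = _sigmoid(a[3 * H:])
        c = f * c + i * g
        h = o * np.tanh(c)
        gates[t, 0], gates[t, 1], gates[t, 2], gates[t, 3] = i, f, g, o
        C[t] = c
        Hs[t] = h
    return Hs, (X, gates, C, Hs)


def _lstm_backward(dHs, cache, Wx, Wh, dWx, dWh, db):
    X, gates, C, Hs = cache
    L, H = Hs.shape
    dX = np.zeros_like(X)
    dh_next = np.zeros(H)
    dc_next = np.zeros(H)
    for t in range(L - 1, -1, -1):
        i, f, g, o = gates[t]
        c_prev = C[t - 1] if t > 0 else np.zeros(H)
        h_prev = Hs[t - 1] if t > 0 else np.zeros(H)
        tanh_c = np.tanh(C[t])
        dh = dHs[t] + dh_next
        do = dh * tanh_c
        dc = dc_next + dh * o * (1.0 - tanh_c ** 2)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        da = np.concatenate([
            di * i * (1 - i), df * f * (1 - f), dg * (1 - g ** 2), do * o * (1 - o)
        ])
        dWx += np.outer(X[t], da)
        dWh += np.outer(h_prev, da)
        db += da
        dX[t] = da @ Wx.T
        dh_next = da @ Wh.T
        dc_next = dc * f
    return dX


class BiLSTM:
    """Bidirectional LSTM: one pass over the sequence, one over its
    reverse; each direction's hidden states go through tanh and the two
    are concatenated per position (output width 2H)."""

    def __init__(self, c_in, hidden, rng=None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(1.0 / c_in)
        self.c_in, self.hidden = c_in, hidden
        self.c_out = 2 * hidden

        def w():
            return rng.normal(0.0, scale, size=(c_in, 4 * hidden))

        def u():
            return rng.normal(0.0, np.sqrt(1.0 / hidden), size=(hidden, 4 * hidden))

        self.Wx_f, self.Wh_f, self.b_f = w(), u(), np.zeros(4 * hidden)
        self.Wx_b, self.Wh_b, self.b_b = w(), u(), np.zeros(4 * hidden)
        self._zero_grads()

    def _zero_grads(self):
        self.dWx_f = np.zeros_like(self.Wx_f)
        self.dWh_f = np.zeros_like(self.Wh_f)
        self.db_f = np.zeros_like(self.b_f)
        self.dWx_b = np.zeros_like(self.Wx_b)
        self.dWh_b = np.zeros_like(self.Wh_b)
        self.db_b = np.zeros_like(self.b_b)

    @property
    def params(self):
        return [self.Wx_f, self.Wh_f, self.b_f, self.Wx_b, self.Wh_b, self.b_b]

    @property
    def grads(self):
        return [self.dWx_f, self.dWh_f, self.db_f,
                self.dWx_b, self.dWh_b, self.db_b]

    def forward(self, X):
        Hf, cache_f = _lstm_forward(X, self.Wx_f, self.Wh_f, self.b_f)
        Hb_rev, cache_b = _lstm_forward(X[::-1], self.Wx_b, self.Wh_b, self.b_b)
        Yf = np.tanh(Hf)
        Yb = np.tanh(Hb_rev)[::-1]
        self._cache = (cache_f, cache_b, Yf, Yb)
        return np.hstack([Yf, Yb])

    def backward(self, dY):
        cache_f, cache_b, Yf, Yb = self._cache
        H = self.hidden
        dHf = dY[:, :H] * (1.0 - Yf ** 2)
        dHb = (dY[:, H:] * (1.0 - Yb ** 2))[::-1]
        dXf = _lstm_backward(dHf, cache_f, self.Wx_f, self.Wh_f,
                             self.dWx_f, self.dWh_f, self.db_f)
        dXb = _lstm_backward(dHb, cache_b, self.Wx_b, self.Wh_b,
                             self.dWx_b, self.dWh_b, self.db_b)
        return dXf + dXb[::-1]


class Residual:
    """Identity mapping around a hidden unit: 'add' sums layer input and
    output (projecting with a window-1 convolution when widths differ),
    'concat' appends the input to the output."""

    def __init__(self, inner, mode, c_in, rng=None):
        self.inner = inner
        self.mode = mode
        self.proj = None
        if mode == "add" and c_in != inner.c_out:
            self.proj = Conv1D(c_in, inner.c_out, w=1, relu=False, rng=rng)
        self.c_out = inner.c_out if mode == "add" else inner.c_out + c_in

    @property
    def params(self):
        return self.inner.params + (self.proj.params if self.proj else [])

    @property
    def grads(self):
        return self.inner.grads + (self.proj.grads if self.proj else [])

    def forward(self, X):
        Y = self.inner.forward(X)
        if self.mode == "add":
            return Y + (self.proj.forward(X) if self.proj else X)
        return np.hstack([Y, X])

    def backward(self, dOut):
        if self.mode == "add":
            dX = self.inner.backward(dOut)
            dX += self.proj.backward(dOut) if self.proj else dOut
            return dX
        k = self.inner.c_out
        return self.inner.backward(dOut[:, :k]) + dOut[:, k:]


def _head_loss_grad(kind, Z, target, mask):
    """Masked loss and gradient w.r.t. the head pre-activation."""
    L = len(Z)
    m = np.asarray(mask, dtype=float)
    n = max(m.sum(), 1.0)
    t = np.asarray(target, dtype=float).reshape(L, -1)
    if kind == "linear":
        diff = (Z - t) * m[:, None]
        return float((diff ** 2).sum() / n), 2.0 * diff / n, Z
    if kind == "binary":
        P = _sigmoid(Z)
        ll = t * np.log(P + _EPS) + (1 - t) * np.log(1 - P + _EPS)
        loss = float(-(m[:, None] * ll).sum() / n)
        return loss, m[:, None] * (P - t) / n, P
    if kind == "categorical":
        P = _softmax(Z)
        loss = float(-(m * (t * np.log(P + _EPS)).sum(axis=1)).sum() / n)
        return loss, m[:, None] * (P - t) / n, P
    raise ValueError(f"unknown head kind {kind!r}")


class Network:
    """A multi-head sequence labeller built from an ArchitectureSpec."""

    def __init__(self, spec: ArchitectureSpec, group, rng=None):
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        self.spec = spec
        self.group = list(group)
        self.W_emb = rng.normal(0.0, 0.3, size=(20, spec.n_embedding))
        self.dW_emb = np.zeros_like(self.W_emb)

        width = spec.n_embedding + 20
        self.hidden = []
        for _ in range(spec.n_hidden_layers):
            if spec.hidden_type == "conv":
                unit = Conv1D(width, spec.n_hidden_neurons, spec.w, rng=rng)
            elif spec.hidden_type == "dconv":
                unit = _DconvBlock(width, spec.n_hidden_neurons, spec.w,
                                   spec.n_dconv_layers, rng=rng)
            else:
                unit = BiLSTM(width, spec.n_hidden_neurons, rng=rng)
            if spec.residual != "none":
                unit = Residual(unit, spec.residual, width, rng=rng)
            self.hidden.append(unit)
            width = unit.c_out
        self.dense = [
            Conv1D(width if i == 0 else spec.n_dense_neurons,
                   spec.n_dense_neurons, w=1, rng=rng)
            for i in range(spec.n_dense_layers)
        ]
        width = spec.n_dense_neurons if spec.n_dense_layers else width
        self.heads = {
            t.name: Conv1D(width, t.dim, w=1, relu=False, rng=rng)
            for t in self.group
        }

    # --- parameter plumbing -------------------------------------------------
    def _units(self):
        return self.hidden + self.dense + [self.heads[t.name] for t in self.group]

    def params(self):
        out = [self.W_emb]
        for u in self._units():
            out.extend(u.params)
        return out

    def grads(self):
        out = [self.dW_emb]
        for u in self._units():
            out.extend(u.grads)
        return out

    def zero_grads(self):
        for g in self.grads():
            g[...] = 0.0

    def get_state(self):
        return [p.copy() for p in self.params()]

    def set_state(self, state):
        for p, s in zip(self.params(), state):
            p[...] = s

    # --- forward / backward -------------------------------------------------
    def _forward_trunk(self, onehot, profile):
        E = onehot @ self.W_emb
        X = np.hstack([E, profile])
        self._trunk_cache = onehot
        for unit in self.hidden:
            X = unit.forward(X)
        for unit in self.dense:
            X = unit.forward(X)
        return X

    def forward(self, onehot, profile, targets=None, masks=None):
        """Returns (loss, outputs); loss is None without targets."""
        D = self._forward_trunk(np.asarray(onehot, float), np.asarray(profile, float))
        outputs = {}
        loss = 0.0
        self._head_dZ = {}
        for t in self.group:
            Z = self.heads[t.name].forward(D)
            if targets is not None:
                l, dZ, P = _head_loss_grad(t.kind, Z, targets[t.name], masks[t.name])
                loss += l
                self._head_dZ[t.name] = dZ
            else:
                P = {"linear": lambda z: z, "binary": _sigmoid,
                     "categorical": _softmax}[t.kind](Z)
            outputs[t.name] = P if t.kind == "categorical" else P.reshape(len(P))
            if t.kind == "linear":
                outputs[t.name] = Z.reshape(len(Z)) if t.dim == 1 else Z
        return (loss if targets is not None else None), outputs

    def backward(self):
        dD = None
        for t in self.group:
            d = self.heads[t.name].backward(self._head_dZ[t.name])
            dD = d if dD is None else dD + d
        for unit in reversed(self.dense):
            dD = unit.backward(dD)
        for unit in reversed(self.hidden):
            dD = unit.backward(dD)
        n_emb = self.spec.n_embedding
        self.dW_emb += self._trunk_cache.T @ dD[:, :n_emb]

    def predict(self, onehot, profile) -> dict:
        _, outputs = self.forward(onehot, profile)
        return outputs

    def evaluate(self, data) -> float:
        """Mean masked loss over a list of samples."""
        total = 0.0
        for s in data:
            loss, _ = self.forward(s["onehot"], s["profile"], s["targets"], s["masks"])
            total += loss
        return total / max(len(data), 1)


class _DconvBlock:
    """A block of dilated convolutions, dilation 2^(l-1) for layer l."""

    def __init__(self, c_in, c_out, w, n_layers, rng=None):
        self.layers = []
        self.c_in, self.c_out = c_in, c_out
        width = c_in
        for l in range(1, n_layers + 1):
            self.layers.append(Conv1D(width, c_out, w, dilation=2 ** (l - 1), rng=rng))
            width = c_out

    @property
    def params(self):
        return [p for lay in self.layers for p in lay.params]

    @property
    def grads(self):
        return [g for lay in self.layers for g in lay.grads]

    def forward(self, X):
        for lay in self.layers:
            X = lay.forward(X)
        return X

    def backward(self, dY):
        for lay in reversed(self.layers):
            dY = lay.backward(dY)
        return dY


def build_network(spec: ArchitectureSpec, group, seed: int = 0) -> Network:
    """Construct a network for a target group (list of TargetDef)."""
    return Network(spec, group, rng=np.random.default_rng(seed))


class Adam:
    """Adam with per-weight adaptive rates; ``lr`` is mutable (decay)."""

    def __init__(self, params, lr=1e-2, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class EarlyStopper:
    """Patience bookkeeping for early stopping and lr decay.

    ``update`` returns 'improved', 'continue', 'decay' (every
    ``patience_lr`` stale epochs) or 'stop' (after ``patience_stop``).
    """

    def __init__(self, patience_stop: int = 10, patience_lr: int = 5):
        self.patience_stop = patience_stop
        self.patience_lr = patience_lr
        self.best = np.inf
        self.best_epoch = 0
        self.since = 0
        self.epoch = 0

    def update(self, loss) -> str:
        self.epoch += 1
        if loss < self.best:
            self.best = loss
            self.best_epoch = self.epoch
            self.since = 0
            return "improved"
        self.since += 1
        if self.since >= self.patience_stop:
            return "stop"
        if self.since % self.patience_lr == 0:
            return "decay"
        return "continue"


def train_network(network: Network, train_data, val_data, config: TrainConfig):
    """Train with Adam + early stopping; returns (network, history).

    ``train_data`` / ``val_data`` are lists of samples, each a dict with
    'onehot', 'profile', 'targets' (name -> array) and 'masks'.  The
    returned network carries the weights of the best validation epoch.
    """
    rng = np.random.default_rng(config.seed)
    adam = Adam(network.params(), lr=config.initial_lr)
    stopper = EarlyStopper(config.patience_stop, config.patience_lr)
    best_state = network.get_state()
    history = {"train_loss": [], "val_loss": [], "lr": []}
    for _ in range(config.max_epochs):
        order = rng.permutation(len(train_data))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            network.zero_grads()
            for i in batch:
                s = train_data[i]
                loss, _ = network.forward(s["onehot"], s["profile"],
                                          s["targets"], s["masks"])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss ({loss}) at epoch "
                        f"{stopper.epoch + 1}; lr={adam.lr}"
                    )
                network.backward()
                epoch_loss += loss
            for g in network.grads():
                g /= len(batch)
            adam.step(network.params(), network.grads())
        val_loss = network.evaluate(val_data)
        if not np.isfinite(val_loss):
            raise RuntimeError("non-finite validation loss")
        history["train_loss"].append(epoch_loss / max(len(train_data), 1))
        history["val_loss"].append(val_loss)
        history["lr"].append(adam.lr)
        action = stopper.update(val_loss)
        if action == "improved":
            best_state = network.get_state()
        elif action == "decay":
            adam.lr *= config.lr_factor
        elif action == "stop":
            break
    network.set_state(best_state)
    history["best_epoch"] = stopper.best_epoch
    return network, history
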