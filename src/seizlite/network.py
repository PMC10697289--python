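"""The PCNN-BiLSTM network, implemented from its defining equations.

Architecture: three strided, unpadded Conv-BN-ReLU blocks with non-increasing
filter counts (a "pyramid" 1-D CNN — stride replaces pooling), a
bidirectional LSTM over the resulting feature sequence, and a dense softmax
head over the flattened BiLSTM output. The LSTM follows the standard gate
equations

    f_t = sigmoid(W_f [h_{t-1}, x_t] + b_f)        (forget gate)
    i_t = sigmoid(W_i [h_{t-1}, x_t] + b_i)        (input gate)
    o_t = sigmoid(W_o [h_{t-1}, x_t] + b_o)        (output gate)
    c'_t = tanh(W_c [h_{t-1}, x_t] + b_c)          (candidate state)
    c_t = f_t * c_{t-1} + i_t * c'_t
    h_t = o_t * tanh(c_t)

Everything — forward pass, backpropagation, and the analytic parameter/FLOP
accounting — is plain numpy, so the analytic counts can be validated against
the network's actual variable list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ConvBlockSpec:
    kernel_size: int
    stride: int
    filters_out: int
    has_bn: bool = True

    def __post_init__(self) -> None:
        if self.kernel_size < 1 or self.stride < 1 or self.filters_out < 1:
            raise ValueError("kernel_size, stride and filters_out must be >= 1")


@dataclass
class ModelConfig:
    """Full architecture description; parameters and FLOPs derive from it."""

    input_length: int
    conv_blocks: list[ConvBlockSpec]
    lstm_hidden: int
    num_classes: int = 3
    in_channels: int = 1
    bn_eps: float = 1e-3

    def __post_init__(self) -> None:
        if len(self.conv_blocks) != 3:
            raise ValueError("the pyramid CNN has exactly 3 conv blocks")
        filters = [b.filters_out for b in self.conv_blocks]
        if any(f2 > f1 for f1, f2 in zip(filters, filters[1:])):
            raise ValueError(
                f"pyramid constraint violated: filter counts {filters} must be non-increasing"
            )
        if self.lstm_hidden < 1:
            raise ValueError("lstm_hidden must be >= 1")
        self.sequence_length()  # raises if any block underflows

    @classmethod
    def lightweight(cls, input_length: int = 256) -> "ModelConfig":
        """The reference lightweight configuration: kernels 5/3/3, strides
        3/2/2, filters 19/19/13, BiLSTM hidden width 19. At window 256 this
        network has exactly 9,371 trainable parameters."""
        return cls(
            input_length=input_length,
            conv_blocks=[
                ConvBlockSpec(kernel_size=5, stride=3, filters_out=19),
                ConvBlockSpec(kernel_size=3, stride=2, filters_out=19),
                ConvBlockSpec(kernel_size=3, stride=2, filters_out=13),
            ],
            lstm_hidden=19,
        )

    @classmethod
    def small(cls, input_length: int = 256) -> "ModelConfig":
        """A reduced-width variant for desk-scale smoke training."""
        return cls(
            input_length=input_length,
            conv_blocks=[
                ConvBlockSpec(kernel_size=5, stride=3, filters_out=8),
                ConvBlockSpec(kernel_size=3, stride=2, filters_out=6),
                ConvBlockSpec(kernel_size=3, stride=2, filters_out=4),
            ],
            lstm_hidden=8,
        )

    def sequence_length(self) -> int:
        """Time steps seen by the BiLSTM (repeated strided-conv shrinkage)."""
        L = self.input_length
        for i, blk in enumerate(self.conv_blocks):
            L = conv_output_length(L, blk.kernel_size, blk.stride, name=f"conv{i + 1}")
        return L


def conv_output_length(L: int, kernel: int, stride: int, name: str = "conv") -> int:
    """Output length of a valid (unpadded) strided convolution."""
    if L < kernel:
        raise ValueError(f"{name}: input length {L} shorter than kernel {kernel}")
    return (L - kernel) // stride + 1


# ---------------------------------------------------------------------------
# equation-level LSTM primitives (single sequence; the oracle-friendly path)


@dataclass
class LSTMState:
    h: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        if self.h.shape != self.c.shape:
            raise ValueError("h and c must share a shape")


@dataclass
class GateWeights:
    """Gate matrices acting on the concatenation [h_{t-1}, x_t]."""

    W_f: np.ndarray
    W_i: np.ndarray
    W_o: np.ndarray
    W_c: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_o: np.ndarray
    b_c: np.ndarray

    @property
    def hidden(self) -> int:
        return self.b_f.shape[0]

    @classmethod
    def zeros(cls, n_features: int, hidden: int) -> "GateWeights":
        W = lambda: np.zeros((hidden, hidden + n_features))
        b = lambda: np.zeros(hidden)
        return cls(W(), W(), W(), W(), b(), b(), b(), b())


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def lstm_step(x_t: np.ndarray, state: LSTMState, w: GateWeights) -> LSTMState:
    """One LSTM step evaluated literally from the gate equations."""
    hx = np.concatenate([state.h, x_t])
    f_t = _sigmoid(w.W_f @ hx + w.b_f)
    i_t = _sigmoid(w.W_i @ hx + w.b_i)
    o_t = _sigmoid(w.W_o @ hx + w.b_o)
    c_cand = np.tanh(w.W_c @ hx + w.b_c)
    c_t = f_t * state.c + i_t * c_cand
    h_t = o_t * np.tanh(c_t)
    return LSTMState(h=h_t, c=c_t)


def lstm_forward(sequence: np.ndarray, w: GateWeights) -> np.ndarray:
    """Run the step equation over t = 1..T from zero initial state."""
    sequence = np.atleast_2d(sequence)
    state = LSTMState(h=np.zeros(w.hidden), c=np.zeros(w.hidden))
    out = np.empty((sequence.shape[0], w.hidden))
    for t, x_t in enumerate(sequence):
        state = lstm_step(x_t, state, w)
        out[t] = state.h
    return out


def bilstm_forward(
    sequence: np.ndarray, fwd: GateWeights, bwd: GateWeights
) -> np.ndarray:
    """Forward LSTM and time-reversed backward LSTM, concatenated on features."""
    sequence = np.atleast_2d(sequence)
    if sequence.shape[0] == 0:
        raise ValueError("empty sequence")
    forward = lstm_forward(sequence, fwd)
    backward = lstm_forward(sequence[::-1], bwd)[::-1]
    return np.concatenate([forward, backward], axis=1)


# ---------------------------------------------------------------------------
# batched trainable network


def conv_block_forward(
    x: np.ndarray,
    spec: ConvBlockSpec,
    weights: dict,
    training: bool = False,
    bn_eps: float = 1e-3,
) -> np.ndarray:
    """Valid strided 1-D cross-correlation, batch norm, ReLU.

    ``x`` is (batch, length, channels); ``weights`` holds ``W`` of shape
    (kernel*channels, filters), ``b``, and BN ``gamma``/``beta`` plus running
    ``mean``/``var`` used at inference.
    """
    y, _ = _conv_bn_relu_forward(x, spec, weights, training=training, bn_eps=bn_eps)
    return y


def _im2col(x: np.ndarray, kernel: int, stride: int) -> np.ndarray:
    n, L, c = x.shape
    T = (L - kernel) // stride + 1
    starts = np.arange(T) * stride
    cols = x[:, starts[:, None] + np.arange(kernel)[None, :], :]  # (n, T, k, c)
    return cols.reshape(n, T, kernel * c)


def _conv_bn_relu_forward(x, spec, weights, training, bn_eps, momentum=0.9):
    cols = _im2col(x, spec.kernel_size, spec.stride)
    z = cols @ weights["W"] + weights["b"]
    if spec.has_bn:
        if training:
            mean = z.mean(axis=(0, 1))
            var = z.var(axis=(0, 1))
            weights["run_mean"] = momentum * weights["run_mean"] + (1 - momentum) * mean
            weights["run_var"] = momentum * weights["run_var"] + (1 - momentum) * var
        else:
            mean, var = weights["run_mean"], weights["run_var"]
        inv_std = 1.0 / np.sqrt(var + bn_eps)
        xhat = (z - mean) * inv_std
        pre = weights["gamma"] * xhat + weights["beta"]
    else:
        inv_std = xhat = None
        pre = z
    y = np.maximum(pre, 0.0)
    cache = {"cols": cols, "xhat": xhat, "inv_std": inv_std, "mask": pre > 0,
             "L_in": x.shape[1]}
    return y, cache


class PCNNBiLSTM:
    """Trainable numpy implementation of the architecture.

    Parameters live in ``self.params`` (name -> array); gradients appear in
    ``self.grads`` after :meth:`backward`. BN running statistics are buffers,
    not trainable parameters.
    """

    def __init__(self, config: ModelConfig, seed: int = 0) -> None:
        self.config = config
        self.params: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        c_in = config.in_channels
        for i, blk in enumerate(config.conv_blocks):
            fan_in = blk.kernel_size * c_in
            self.params[f"conv{i}_W"] = _glorot(rng, fan_in, blk.filters_out,
                                                (fan_in, blk.filters_out))
            self.params[f"conv{i}_b"] = np.zeros(blk.filters_out)
            self.params[f"conv{i}_gamma"] = np.ones(blk.filters_out)
            self.params[f"conv{i}_beta"] = np.zeros(blk.filters_out)
            self.buffers[f"conv{i}_run_mean"] = np.zeros(blk.filters_out)
            self.buffers[f"conv{i}_run_var"] = np.ones(blk.filters_out)
            c_in = blk.filters_out
        H = config.lstm_hidden
        for d in ("fwd", "bwd"):
            self.params[f"lstm_{d}_Wx"] = _glorot(rng, c_in, H, (c_in, 4 * H))
            self.params[f"lstm_{d}_Wh"] = _glorot(rng, H, H, (H, 4 * H))
            self.params[f"lstm_{d}_b"] = np.zeros(4 * H)
        T = config.sequence_length()
        self.params["dense_W"] = _glorot(rng, T * 2 * H, config.num_classes,
                                         (T * 2 * H, config.num_classes))
        self.params["dense_b"] = np.zeros(config.num_classes)
        self._cache: dict = {}

    # -- forward ----------------------------------------------------------

    def forward(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits for a (batch, input_length) matrix."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.config.input_length:
            raise ValueError(
                f"expected input length {self.config.input_length}, got {X.shape[1]}"
            )
        h = X[:, :, None]
        caches = []
        for i, blk in enumerate(self.config.conv_blocks):
            w = self._block_weights(i)
            h, cache = _conv_bn_relu_forward(
                h, blk, w, training=training, bn_eps=self.config.bn_eps
            )
            if training:
                self.buffers[f"conv{i}_run_mean"] = w["run_mean"]
                self.buffers[f"conv{i}_run_var"] = w["run_var"]
            cache["x_shape"] = None
            caches.append(cache)
        seq_f, cache_f = self._lstm_batch(h, "fwd")
        seq_b, cache_b = self._lstm_batch(h[:, ::-1, :], "bwd")
        seq_b = seq_b[:, ::-1, :]
        feats = np.concatenate([seq_f, seq_b], axis=2)  # (N, T, 2H)
        flat = feats.reshape(feats.shape[0], -1)
        logits = flat @ self.params["dense_W"] + self.params["dense_b"]
        self._cache = {
            "conv": caches, "conv_in_shapes": None,
            "lstm_f": cache_f, "lstm_b": cache_b,
            "flat": flat, "h_seq_shape": h.shape,
        }
        return logits

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits = self.forward(X, training=False)
        return softmax(logits)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Argmax class; ties break toward the lower class index."""
        return np.argmax(self.predict_proba(X), axis=1)

    def _block_weights(self, i: int) -> dict:
        return {
            "W": self.params[f"conv{i}_W"],
            "b": self.params[f"conv{i}_b"],
            "gamma": self.params[f"conv{i}_gamma"],
            "beta": self.params[f"conv{i}_beta"],
            "run_mean": self.buffers[f"conv{i}_run_mean"],
            "run_var": self.buffers[f"conv{i}_run_var"],
        }

    def _lstm_batch(self, x: np.ndarray, d: str):
        """Batched LSTM over (N, T, F); gate packing order is [i, f, o, g]."""
        Wx = self.params[f"lstm_{d}_Wx"]
        Wh = self.params[f"lstm_{d}_Wh"]
        b = self.params[f"lstm_{d}_b"]
        N, T, _ = x.shape
        H = self.config.lstm_hidden
        h = np.zeros((N, H))
        c = np.zeros((N, H))
        gates = np.empty((T, N, 4 * H))
        cs = np.empty((T, N, H))
        tanh_cs = np.empty((T, N, H))
        h_prevs = np.empty((T, N, H))
        c_prevs = np.empty((T, N, H))
        out = np.empty((N, T, H))
        zx = x @ Wx  # (N, T, 4H), hoisted out of the loop
        for t in range(T):
            h_prevs[t], c_prevs[t] = h, c
            z = zx[:, t, :] + h @ Wh + b
            i_g = _sigmoid(z[:, :H])
            f_g = _sigmoid(z[:, H: 2 * H])
            o_g = _sigmoid(z[:, 2 * H: 3 * H])
            g_g = np.tanh(z[:, 3 * H:])
            c = f_g * c + i_g * g_g
            tc = np.tanh(c)
            h = o_g * tc
            gates[t] = np.concatenate([i_g, f_g, o_g, g_g], axis=1)
            cs[t], tanh_cs[t] = c, tc
            out[:, t, :] = h
        cache = {"x": x, "gates": gates, "cs": cs, "tanh_cs": tanh_cs,
                 "h_prevs": h_prevs, "c_prevs": c_prevs}
        return out, cache

    # -- backward ---------------------------------------------------------

    def backward(self, dlogits: np.ndarray) -> None:
        """Populate ``self.grads`` given d(loss)/d(logits)."""
        cache = self._cache
        flat = cache["flat"]
        self.grads = {}
        self.grads["dense_W"] = flat.T @ dlogits
        self.grads["dense_b"] = dlogits.sum(axis=0)
        dflat = dlogits @ self.params["dense_W"].T
        N, T, _ = cache["h_seq_shape"]
        H = self.config.lstm_hidden
        dfeats = dflat.reshape(N, T, 2 * H)
        dseq = self._lstm_batch_backward(dfeats[:, :, :H], cache["lstm_f"], "fwd")
        dseq_b = self._lstm_batch_backward(
            dfeats[:, ::-1, H:], cache["lstm_b"], "bwd"
        )
        dh = dseq + dseq_b[:, ::-1, :]
        for i in reversed(range(len(self.config.conv_blocks))):
            blk = self.config.conv_blocks[i]
            dh = self._conv_block_backward(dh, blk, i, cache["conv"][i])
        # dh is now d(loss)/d(input); discarded

    def _conv_block_backward(self, dy, blk, i, cache):
        dpre = dy * cache["mask"]
        if blk.has_bn:
            gamma = self.params[f"conv{i}_gamma"]
            xhat, inv_std = cache["xhat"], cache["inv_std"]
            n = dpre.shape[0] * dpre.shape[1]
            self.grads[f"conv{i}_gamma"] = np.sum(dpre * xhat, axis=(0, 1))
            self.grads[f"conv{i}_beta"] = np.sum(dpre, axis=(0, 1))
            dxhat = dpre * gamma
            dz = (inv_std / n) * (
                n * dxhat
                - dxhat.sum(axis=(0, 1))
                - xhat * np.sum(dxhat * xhat, axis=(0, 1))
            )
        else:
            self.grads[f"conv{i}_gamma"] = np.zeros_like(self.params[f"conv{i}_gamma"])
            self.grads[f"conv{i}_beta"] = np.zeros_like(self.params[f"conv{i}_beta"])
            dz = dpre
        cols = cache["cols"]
        W = self.params[f"conv{i}_W"]
        self.grads[f"conv{i}_W"] = np.tensordot(cols, dz, axes=([0, 1], [0, 1]))
        self.grads[f"conv{i}_b"] = dz.sum(axis=(0, 1))
        dcols = dz @ W.T  # (N, T, k*Cin)
        n_batch, T_out, _ = dz.shape
        c_in = self.config.in_channels if i == 0 else self.config.conv_blocks[i - 1].filters_out
        k, s = blk.kernel_size, blk.stride
        # trailing input samples past the last full window got zero gradient
        L_in = cache["L_in"]
        dcols = dcols.reshape(n_batch, T_out, k, c_in)
        dx = np.zeros((n_batch, L_in, c_in))
        starts = np.arange(T_out) * s
        for j in range(k):  # offsets within one j are distinct, so += is safe
            dx[:, starts + j, :] += dcols[:, :, j, :]
        return dx

    def _lstm_batch_backward(self, dout, cache, d):
        """BPTT for one direction; ``dout`` is (N, T, H) in that direction's
        own time order. Returns d(loss)/d(input sequence)."""
        Wx = self.params[f"lstm_{d}_Wx"]
        Wh = self.params[f"lstm_{d}_Wh"]
        x = cache["x"]
        N, T, F = x.shape
        H = self.config.lstm_hidden
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * H)
        dx = np.zeros_like(x)
        dh_next = np.zeros((N, H))
        dc_next = np.zeros((N, H))
        for t in reversed(range(T)):
            g = cache["gates"][t]
            i_g, f_g, o_g, g_g = g[:, :H], g[:, H:2 * H], g[:, 2 * H:3 * H], g[:, 3 * H:]
            tc = cache["tanh_cs"][t]
            dh = dout[:, t, :] + dh_next
            do = dh * tc
            dc = dh * o_g * (1.0 - tc * tc) + dc_next
            di = dc * g_g
            df = dc * cache["c_prevs"][t]
            dg = dc * i_g
            dc_next = dc * f_g
            dz = np.concatenate(
                [di * i_g * (1 - i_g), df * f_g * (1 - f_g),
                 do * o_g * (1 - o_g), dg * (1 - g_g * g_g)],
                axis=1,
            )
            dWx += x[:, t, :].T @ dz
            dWh += cache["h_prevs"][t].T @ dz
            db += dz.sum(axis=0)
            dx[:, t, :] = dz @ Wx.T
            dh_next = dz @ Wh.T
        self.grads[f"lstm_{d}_Wx"] = dWx
        self.grads[f"lstm_{d}_Wh"] = dWh
        self.grads[f"lstm_{d}_b"] = db
        return dx

    # -- bookkeeping ------------------------------------------------------

    def n_trainable(self) -> int:
        """Trainable parameter total from the actual variable list."""
        return int(sum(p.size for p in self.params.values()))


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def model_forward(segment: np.ndarray, net: PCNNBiLSTM) -> np.ndarray:
    """Class probability vector for one segment (stateless inference)."""
    segment = np.asarray(segment, dtype=np.float64)
    if segment.ndim != 1 or segment.shape[0] != net.config.input_length:
        raise ValueError(f"segment must be a vector of length {net.config.input_length}")
    return net.predict_proba(segment[None, :])[0]


# ---------------------------------------------------------------------------
# analytic accounting


@dataclass
class ModelSummary:
    """Per-layer trainable-parameter and MAC breakdown.

    ``flop_count`` is computed from the MAC table under the convention named
    in ``convention``:

    * ``"mac"`` (default): 1 multiply-accumulate = 1 FLOP, all layers;
    * ``"mac2"``: 2 FLOPs per MAC, all layers;
    * ``"static-graph"``: 2 FLOPs per MAC over the statically-traced layers
      only (conv + dense) — the convention graph profilers effectively apply
      to models whose recurrent loop is dynamic and therefore untraced.
    """

    per_layer_params: dict[str, int]
    per_layer_macs: dict[str, int]
    convention: str = "mac"

    @property
    def trainable_parameter_count(self) -> int:
        return sum(self.per_layer_params.values())

    @property
    def flop_count(self) -> float:
        if self.convention == "mac":
            return float(sum(self.per_layer_macs.values()))
        if self.convention == "mac2":
            return 2.0 * sum(self.per_layer_macs.values())
        if self.convention == "static-graph":
            static = sum(v for k, v in self.per_layer_macs.items()
                         if not k.startswith("bilstm"))
            return 2.0 * static
        raise ValueError(f"unknown FLOP convention {self.convention!r}")

    @property
    def mflops(self) -> float:
        return self.flop_count / 1e6

    def table(self) -> str:
        lines = [f"{'layer':<12}{'params':>10}{'MACs':>12}"]
        for name in self.per_layer_params:
            lines.append(
                f"{name:<12}{self.per_layer_params[name]:>10}"
                f"{self.per_layer_macs.get(name, 0):>12}"
            )
        lines.append(
            f"{'total':<12}{self.trainable_parameter_count:>10}"
            f"{sum(self.per_layer_macs.values()):>12}"
        )
        lines.append(f"FLOPs ({self.convention}): {self.flop_count:,.0f}"
                     f" = {self.mflops:.3f}M")
        return "\n".join(lines)


def summarize(config: ModelConfig, convention: str = "mac") -> ModelSummary:
    """Analytic per-layer parameter and MAC accounting.

    Conv block: ``kernel * c_in * c_out`` weights + ``c_out`` bias + BN scale
    and shift (2 * c_out trainable; running statistics excluded). LSTM per
    direction: ``4 * ((features + hidden) * hidden + hidden)``. Dense:
    ``in * out + out``. MACs: conv ``T_out * kernel * c_in * c_out``; LSTM
    ``T * 4 * (features + hidden) * hidden`` per direction; dense
    ``in * out``.
    """
    params: dict[str, int] = {}
    macs: dict[str, int] = {}
    L = config.input_length
    c_in = config.in_channels
    for i, blk in enumerate(config.conv_blocks):
        T_out = conv_output_length(L, blk.kernel_size, blk.stride, name=f"conv{i + 1}")
        p = blk.kernel_size * c_in * blk.filters_out + blk.filters_out
        if blk.has_bn:
            p += 2 * blk.filters_out
        params[f"conv{i + 1}"] = p
        macs[f"conv{i + 1}"] = T_out * blk.kernel_size * c_in * blk.filters_out
        L, c_in = T_out, blk.filters_out
    H = config.lstm_hidden
    per_dir = 4 * ((c_in + H) * H + H)
    params["bilstm"] = 2 * per_dir
    macs["bilstm"] = 2 * L * 4 * (c_in + H) * H
    # gate nonlinearities and state updates, per element per step:
    # 3H sigmoid + 2H tanh + 3H cell update + H hidden update = 9H
    params["bilstm_pointwise"] = 0
    macs["bilstm_pointwise"] = 2 * L * 9 * H
    dense_in = L * 2 * H
    params["dense"] = dense_in * config.num_classes + config.num_classes
    macs["dense"] = dense_in * config.num_classes
    return ModelSummary(per_layer_params=params, per_layer_macs=macs,
                        convention=convention)


def count_parameters(config: ModelConfig) -> ModelSummary:
    """Analytic trainable-parameter count (BN running stats excluded)."""
    return summarize(config)


def count_flops(config: ModelConfig, convention: str = "mac") -> ModelSummary:
    """Per-forward-pass operation count under the named convention."""
    return summarize(config, convention=convention)
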