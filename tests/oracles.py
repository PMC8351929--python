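"""Independent brute-force oracles used by the test suite.

Everything here is written with explicit Python loops and scalar math so it
shares no code path with the package implementation it checks.
"""

import math

import numpy as np


def scalar_cell_step(params, c_prev, h_prev, x):
    """Pure-Python, per-element evaluation of the gated LSTM cell equations."""
    hsz = params.hidden_size
    concat = list(h_prev) + list(x)

    def affine(w_row, bias):
        return sum(w * v for w, v in zip(w_row, concat)) + bias

    def sig(z):
        return 1.0 / (1.0 + math.exp(-z))

    c, h = [], []
    for j in range(hsz):
        f = sig(affine(params.gate_weights[j], params.gate_bias[j]))
        i = sig(affine(params.gate_weights[hsz + j], params.gate_bias[hsz + j]))
        o = sig(affine(params.gate_weights[2 * hsz + j], params.gate_bias[2 * hsz + j]))
        g = math.tanh(affine(params.cell_weights[j], params.cell_bias[j]))
        cj = f * c_prev[j] + i * g
        c.append(cj)
        h.append(o * math.tanh(cj))
    return c, h


def scalar_lstm_sequence(params, xs):
    """Run one directional cell over a list of input vectors from zero states."""
    hsz = params.hidden_size
    c = [0.0] * hsz
    h = [0.0] * hsz
    outputs = []
    for x in xs:
        c, h = scalar_cell_step(params, c, h, x)
        outputs.append(list(h))
    return outputs


def scalar_network_forward(model, x_seq):
    """Scalar-loop forward pass of the full stacked bidirectional network.

    ``x_seq`` is a list of per-timestep input vectors for one fully unmasked
    cycle. Returns the per-timestep contact probabilities.
    """
    from gaitevents import LSTMCellParams

    def params_of(layer, direction):
        wx = model.params[f"l{layer}_{direction}_Wx"]
        wh = model.params[f"l{layer}_{direction}_Wh"]
        b = model.params[f"l{layer}_{direction}_b"]
        hsz = wh.shape[0]
        # combined layout [f, i, o, g] along columns, x- and h-parts separate;
        # rebuild the [h, x]-concatenated per-gate matrices
        full = np.concatenate([wh, wx], axis=0).T  # (4H, H+D)
        bias = np.asarray(b, dtype=float)
        return LSTMCellParams(
            gate_weights=np.asarray(full[: 3 * hsz], dtype=float),
            gate_bias=bias[: 3 * hsz],
            cell_weights=np.asarray(full[3 * hsz :], dtype=float),
            cell_bias=bias[3 * hsz :],
        )

    seq = [list(map(float, x)) for x in x_seq]
    for layer in range(model.config.lstm_layers):
        fw = scalar_lstm_sequence(params_of(layer, "fw"), seq)
        bw = scalar_lstm_sequence(params_of(layer, "bw"), seq[::-1])[::-1]
        seq = [f + b for f, b in zip(fw, bw)]
    dense_w = model.params["dense_W"]
    dense_b = model.params["dense_b"]
    out_w = model.params["out_w"]
    out_b = float(model.params["out_b"][0])
    probs = []
    for h in seq:
        hidden = []
        for k in range(dense_w.shape[1]):
            z = sum(h[d] * float(dense_w[d, k]) for d in range(len(h))) + float(dense_b[k])
            hidden.append(max(z, 0.0))
        logit = sum(hk * float(wk) for hk, wk in zip(hidden, out_w)) + out_b
        probs.append(1.0 / (1.0 + math.exp(-logit)))
    return probs


def brute_force_qc(f, rate):
    """Exhaustive scan of the terminal 100->50 N interval for loading rates."""
    last = None
    for i in range(len(f) - 1):
        if f[i] >= 100.0 and f[i + 1] < 100.0:
            last = i
    if last is None:
        return True
    j = len(f) - 1
    for k in range(last + 1, len(f)):
        if f[k] < 50.0:
            j = k
            break
    for k in range(last, j):
        if (f[k + 1] - f[k]) * rate >= 200.0:
            return False
    return True


def percentile_linear(values, q):
    """Linear-interpolation percentile computed by hand on sorted data."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    pos = q / 100.0 * (n - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return xs[lo] * (1 - frac) + xs[hi] * frac


def pearson_r(x, y):
    """Pearson correlation with explicit sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)
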