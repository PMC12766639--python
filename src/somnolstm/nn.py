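"""Nested local-global bidirectional LSTM, implemented in NumPy.

The model consumes, for every 30-s epoch, the 30 spectral components as 30
sequential steps of 5 channel values (x, y, z, magnitude, HR). A *local*
LSTM runs over those component steps and its final hidden state is the epoch
embedding; a *global* bidirectional LSTM runs over the night's sequence of
epoch embeddings; a linear softmax head maps each epoch's global state to
class probabilities. Training minimises class-weighted cross-entropy with
Adam, dropout on both embedding levels, truncated backpropagation over
fixed-length night chunks, and early stopping on held-out validation
sequences (patience 5, at most 50 passes).

Forward, backward (exact gradients through both recurrences) and the Adam
update are written against NumPy only, so CPU-only execution is the native
mode and every source of randomness is an explicit seeded generator.
"""

from __future__ import annotations

import numpy as np

from .exceptions import InferenceError, TrainingError

_GATES = 4  # input, forget, cell, output


def _sigmoid(a: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


def _init_lstm(rng: np.random.Generator, d_in: int, d_h: int, dtype) -> dict:
    k = 1.0 / np.sqrt(d_h)
    b = np.zeros(_GATES * d_h, dtype=dtype)
    b[d_h : 2 * d_h] = 1.0  # forget-gate bias
    return {
        "Wx": rng.uniform(-k, k, size=(d_in, _GATES * d_h)).astype(dtype),
        "Wh": rng.uniform(-k, k, size=(d_h, _GATES * d_h)).astype(dtype),
        "b": b,
    }


def _lstm_forward(X_seq: np.ndarray, p: dict) -> tuple[np.ndarray, list]:
    """Run an LSTM over ``X_seq`` (T, N, D) -> hidden states (T, N, H)."""
    T, N, _ = X_seq.shape
    H = p["Wh"].shape[0]
    h = np.zeros((N, H), dtype=X_seq.dtype)
    c = np.zeros((N, H), dtype=X_seq.dtype)
    out = np.empty((T, N, H), dtype=X_seq.dtype)
    caches = []
    for t in range(T):
        x = X_seq[t]
        a = x @ p["Wx"] + h @ p["Wh"] + p["b"]
        i = _sigmoid(a[:, :H])
        f = _sigmoid(a[:, H : 2 * H])
        g = np.tanh(a[:, 2 * H : 3 * H])
        o = _sigmoid(a[:, 3 * H :])
        c_prev, h_prev = c, h
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h = o * tc
        out[t] = h
        caches.append((x, h_prev, c_prev, i, f, g, o, tc))
    return out, caches


def _lstm_backward(
    dh_seq: np.ndarray, caches: list, p: dict
) -> tuple[dict, np.ndarray]:
    """Backprop through time. ``dh_seq`` (T, N, H) is the upstream gradient
    on each step's hidden state. Returns parameter grads and dX (T, N, D)."""
    T, N, H = dh_seq.shape
    dWx = np.zeros_like(p["Wx"])
    dWh = np.zeros_like(p["Wh"])
    db = np.zeros_like(p["b"])
    dX = np.empty((T, N, p["Wx"].shape[0]), dtype=dh_seq.dtype)
    dh_carry = np.zeros((N, H), dtype=dh_seq.dtype)
    dc_carry = np.zeros((N, H), dtype=dh_seq.dtype)
    for t in range(T - 1, -1, -1):
        x, h_prev, c_prev, i, f, g, o, tc = caches[t]
        dh = dh_seq[t] + dh_carry
        do = dh * tc
        dc = dc_carry + dh * o * (1.0 - tc * tc)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dc_carry = dc * f
        dA = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        dWx += x.T @ dA
        dWh += h_prev.T @ dA
        db += dA.sum(axis=0)
        dX[t] = dA @ p["Wx"].T
        dh_carry = dA @ p["Wh"].T
    return {"Wx": dWx, "Wh": dWh, "b": db}, dX


class LocalGlobalLSTM:
    """Local-global bidirectional LSTM sequence classifier.

    Parameters
    ----------
    n_classes : number of output classes (fixed class order).
    n_components, n_channels : per-epoch block geometry (K steps x C values).
    local_hidden : hidden size of the within-epoch (local) LSTM; its final
        state is the epoch embedding.
    hidden : hidden size of each direction of the night-level (global)
        bidirectional LSTM.
    dropout : dropout probability applied to the epoch embedding and to the
        concatenated global state.
    lr : Adam learning rate.
    chunk_len : truncated-backpropagation window, in epochs (~1 h of night
        context per gradient step at the 30-s epoch length).
    batch_chunks : chunks per gradient step.
    """

    def __init__(
        self,
        n_classes: int,
        n_components: int = 30,
        n_channels: int = 5,
        local_hidden: int = 32,
        hidden: int = 128,
        dropout: float = 0.1,
        lr: float = 1e-4,
        seed: int = 0,
        max_passes: int = 50,
        patience: int = 5,
        chunk_len: int = 120,
        batch_chunks: int = 16,
        dtype=np.float32,
    ):
        self.n_classes = n_classes
        self.n_components = n_components
        self.n_channels = n_channels
        self.local_hidden = local_hidden
        self.hidden = hidden
        self.dropout = float(dropout)
        self.lr = float(lr)
        self.seed = int(seed)
        self.max_passes = max_passes
        self.patience = patience
        self.chunk_len = chunk_len
        self.batch_chunks = batch_chunks
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        k = 1.0 / np.sqrt(2 * hidden)
        self.params: dict[str, dict | np.ndarray] = {
            "local": _init_lstm(rng, n_channels, local_hidden, dtype),
            "gfwd": _init_lstm(rng, local_hidden, hidden, dtype),
            "gbwd": _init_lstm(rng, local_hidden, hidden, dtype),
            "Wo": rng.uniform(-k, k, size=(2 * hidden, n_classes)).astype(dtype),
            "bo": np.zeros(n_classes, dtype=dtype),
        }
        self._rng = rng
        self.n_passes_ = 0
        self.history_: list[dict] = []

    # -- forward / backward ------------------------------------------------

    def _forward(self, Xb: np.ndarray, train: bool, rng: np.random.Generator):
        """Xb (B, T, K, C) -> probs (B, T, n_classes) (+ caches)."""
        B, T, K, C = Xb.shape
        if K != self.n_components or C != self.n_channels:
            raise InferenceError(
                f"block shape ({K},{C}) differs from configured "
                f"({self.n_components},{self.n_channels})"
            )
        flat = Xb.reshape(B * T, K, C).transpose(1, 0, 2).astype(self.dtype)
        h_loc, loc_caches = _lstm_forward(flat, self.params["local"])
        emb = h_loc[-1]  # (B*T, Hl): final local state is the epoch embedding

        keep = 1.0 - self.dropout
        if train and self.dropout > 0:
            m1 = (rng.random(emb.shape) < keep).astype(self.dtype) / keep
            emb = emb * m1
        else:
            m1 = None

        E = emb.reshape(B, T, -1).transpose(1, 0, 2)  # (T, B, Hl)
        h_f, f_caches = _lstm_forward(E, self.params["gfwd"])
        h_b_rev, b_caches = _lstm_forward(E[::-1], self.params["gbwd"])
        h_b = h_b_rev[::-1]
        Hcat = np.concatenate([h_f, h_b], axis=2)  # (T, B, 2Hg)

        if train and self.dropout > 0:
            m2 = (rng.random(Hcat.shape) < keep).astype(self.dtype) / keep
            Hd = Hcat * m2
        else:
            m2 = None
            Hd = Hcat

        logits = Hd @ self.params["Wo"] + self.params["bo"]  # (T, B, n_cls)
        z = logits - logits.max(axis=2, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=2, keepdims=True)
        cache = (loc_caches, f_caches, b_caches, Hd, m1, m2, B, T)
        return probs, cache

    def loss_and_grads(
        self,
        Xb: np.ndarray,
        yb: np.ndarray,
        class_weights: np.ndarray,
        train: bool = True,
        rng: np.random.Generator | None = None,
    ) -> tuple[float, dict]:
        """Weighted cross-entropy and exact parameter gradients for a batch
        of equal-length sequences. ``yb`` is (B, T) integer classes."""
        rng = self._rng if rng is None else rng
        probs, cache = self._forward(Xb, train, rng)
        loc_caches, f_caches, b_caches, Hd, m1, m2, B, T = cache
        probs_tb = probs  # (T, B, C)
        y_tb = yb.T  # (T, B)
        w = class_weights[y_tb].astype(self.dtype)  # (T, B)
        wsum = w.sum()
        p_true = np.take_along_axis(probs_tb, y_tb[:, :, None], axis=2)[:, :, 0]
        loss = float(np.sum(w * -np.log(np.maximum(p_true, 1e-12))) / wsum)
        if not np.isfinite(loss):
            raise TrainingError("non-finite training loss")

        dlogits = probs_tb.copy()
        np.put_along_axis(
            dlogits,
            y_tb[:, :, None],
            np.take_along_axis(dlogits, y_tb[:, :, None], axis=2) - 1.0,
            axis=2,
        )
        dlogits *= (w / wsum)[:, :, None]

        Hd2 = Hd.reshape(T * B, -1)
        dWo = Hd2.T @ dlogits.reshape(T * B, -1)
        dbo = dlogits.sum(axis=(0, 1))
        dHd = dlogits @ self.params["Wo"].T
        if m2 is not None:
            dHd = dHd * m2
        Hg = self.hidden
        g_f, dE_f = _lstm_backward(dHd[:, :, :Hg], f_caches, self.params["gfwd"])
        g_b, dE_b_rev = _lstm_backward(
            dHd[::-1, :, Hg:], b_caches, self.params["gbwd"]
        )
        dE = dE_f + dE_b_rev[::-1]  # (T, B, Hl)

        demb = dE.transpose(1, 0, 2).reshape(B * T, -1)
        if m1 is not None:
            demb = demb * m1
        dh_seq = np.zeros(
            (self.n_components, B * T, self.local_hidden), dtype=self.dtype
        )
        dh_seq[-1] = demb
        g_l, _ = _lstm_backward(dh_seq, loc_caches, self.params["local"])

        grads = {"local": g_l, "gfwd": g_f, "gbwd": g_b, "Wo": dWo, "bo": dbo}
        return loss, grads

    # -- optimisation ------------------------------------------------------

    def _adam_init(self):
        def zeros_like_tree(p):
            if isinstance(p, dict):
                return {k: zeros_like_tree(v) for k, v in p.items()}
            return np.zeros_like(p)

        self._m = zeros_like_tree(self.params)
        self._v = zeros_like_tree(self.params)
        self._t = 0

    def _adam_step(self, grads, b1=0.9, b2=0.999, eps=1e-8):
        self._t += 1
        corr1 = 1.0 - b1**self._t
        corr2 = 1.0 - b2**self._t

        def upd(p, g, m, v):
            if isinstance(p, dict):
                for k in p:
                    upd(p[k], g[k], m[k], v[k])
                return
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + eps)

        upd(self.params, grads, self._m, self._v)

    def _snapshot(self):
        def cp(p):
            return {k: cp(v) for k, v in p.items()} if isinstance(p, dict) else p.copy()

        return cp(self.params)

    def fit(
        self,
        sequences: list[np.ndarray],
        labels: list[np.ndarray],
        class_weights: np.ndarray,
        val_sequences: list[np.ndarray] | None = None,
        val_labels: list[np.ndarray] | None = None,
    ) -> "LocalGlobalLSTM":
        """Train on whole nights (list of (T_i, K, C) blocks + int labels).

        Nights are cut into ``chunk_len``-epoch windows; same-length chunks
        are batched. If validation sequences are given, early stopping keeps
        the parameters of the pass with the lowest validation loss.
        """
        cw = np.asarray(class_weights, dtype=self.dtype)
        chunks = []
        for si, X in enumerate(sequences):
            for s in range(0, len(X), self.chunk_len):
                e = min(s + self.chunk_len, len(X))
                if e > s:
                    chunks.append((si, s, e))
        if not chunks:
            raise TrainingError("no training epochs")
        rng = np.random.default_rng(self.seed + 1)
        self._adam_init()
        best_loss = np.inf
        best_params = None
        bad = 0
        for p in range(self.max_passes):
            order = rng.permutation(len(chunks))
            ordered = sorted(
                (chunks[i] for i in order), key=lambda c: c[2] - c[1]
            )
            pos = 0
            while pos < len(ordered):
                L = ordered[pos][2] - ordered[pos][1]
                batch = [ordered[pos]]
                pos += 1
                while (
                    pos < len(ordered)
                    and len(batch) < self.batch_chunks
                    and ordered[pos][2] - ordered[pos][1] == L
                ):
                    batch.append(ordered[pos])
                    pos += 1
                Xb = np.stack([sequences[si][s:e] for si, s, e in batch])
                yb = np.stack([labels[si][s:e] for si, s, e in batch])
                _, grads = self.loss_and_grads(Xb, yb, cw, train=True, rng=rng)
                self._adam_step(grads)
            self.n_passes_ = p + 1
            if val_sequences:
                vloss = self.evaluate_loss(val_sequences, val_labels, cw)
                self.history_.append({"pass": p, "val_loss": vloss})
                if vloss < best_loss - 1e-6:
                    best_loss = vloss
                    best_params = self._snapshot()
                    bad = 0
                else:
                    bad += 1
                    if bad >= self.patience:
                        break
        if best_params is not None:
            self.params = best_params
        return self

    def evaluate_loss(self, sequences, labels, class_weights) -> float:
        tot = 0.0
        wtot = 0.0
        for X, y in zip(sequences, labels):
            probs = self.predict_proba_night(X)
            w = class_weights[y]
            p_true = probs[np.arange(len(y)), y]
            tot += float(np.sum(w * -np.log(np.maximum(p_true, 1e-12))))
            wtot += float(w.sum())
        return tot / max(wtot, 1e-12)

    def predict_proba_night(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities for one night's (T, K, C) block sequence."""
        probs, _ = self._forward(X[None], train=False, rng=self._rng)
        return np.asarray(probs[:, 0, :], dtype=np.float64)
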