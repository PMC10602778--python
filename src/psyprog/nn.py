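"""Recurrent multi-modal network for next-visit outcome prediction.

One LSTM branch per dynamic modality (PANSS, PSP, CGI) consumes visits
0..t; at every timestep the branch hidden states are concatenated with the
static feature vector in a fusion layer, passed through per-outcome
time-distributed interaction layers, and emit (a) softmax class
probabilities for the three remission outcomes (SR, FR, CR) at the next
visit and (b) a regression of the next visit's dynamic feature vector. The
multi-objective loss is w_mse * MSE(next-visit regression) + w_ce *
cross-entropy(outcome classes), evaluated only at visits the mask marks as
attended.

Implemented in NumPy with explicit backpropagation through time; gradients
are validated against numerical differentiation in the test suite. All
randomness flows through a caller-supplied Generator, so training is
bit-reproducible single-threaded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ArchitectureConfig

HEADS = ("sr", "fr", "cr")
_GATES = 4  # input, forget, cell, output


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, (fan_in, fan_out))


@dataclass
class Batch:
    """One mini-batch of encoded patients."""

    static: np.ndarray                 # (B, Ds)
    dynamic: np.ndarray                # (B, T, Dd)
    mask: np.ndarray                   # (B, T) bool
    labels: dict[str, np.ndarray] | None = None   # head -> (B,) in {-1,0,1}


class RemissionNetwork:
    """The multi-modal recurrent architecture (parameters + forward/backward)."""

    def __init__(self, arch: ArchitectureConfig, static_dim: int,
                 modality_dims: dict[str, int],
                 rng: np.random.Generator | None = None,
                 zero_init: bool = False):
        arch.validate()
        for m in ("panss", "psp", "cgi"):
            if m not in modality_dims:
                raise ValueError(f"dynamic modality {m!r} missing from schema")
        self.arch = arch
        self.static_dim = static_dim
        self.modality_dims = dict(modality_dims)
        self.hidden = {"panss": arch.hidden_panss, "psp": arch.hidden_psp,
                       "cgi": arch.hidden_cgi}
        self.dyn_total = sum(modality_dims.values())
        rng = rng or np.random.default_rng(arch.seed)
        P: dict[str, np.ndarray] = {}
        for m, d in self.modality_dims.items():
            h = self.hidden[m]
            P[f"W_{m}"] = _glorot(rng, d, _GATES * h)
            P[f"U_{m}"] = _glorot(rng, h, _GATES * h)
            P[f"b_{m}"] = np.zeros(_GATES * h)
            P[f"b_{m}"][h:2 * h] = 1.0        # forget-gate bias
        fusion_in = sum(self.hidden.values()) + static_dim
        P["W_fuse"] = _glorot(rng, fusion_in, arch.fusion_width)
        P["b_fuse"] = np.zeros(arch.fusion_width)
        for o in HEADS:
            P[f"W_int_{o}"] = _glorot(rng, arch.fusion_width, arch.interaction_width)
            P[f"b_int_{o}"] = np.zeros(arch.interaction_width)
            P[f"W_cls_{o}"] = _glorot(rng, arch.interaction_width, 2)
            P[f"b_cls_{o}"] = np.zeros(2)
        P["W_reg"] = _glorot(rng, arch.fusion_width, self.dyn_total)
        P["b_reg"] = np.zeros(self.dyn_total)
        if zero_init:
            P = {k: np.zeros_like(v) for k, v in P.items()}
        self.params = P

    # -- shapes ---------------------------------------------------------
    def n_parameters(self) -> int:
        return sum(v.size for v in self.params.values())

    def _split_modalities(self, dynamic: np.ndarray) -> dict[str, np.ndarray]:
        out, j = {}, 0
        for m, d in self.modality_dims.items():
            out[m] = dynamic[:, :, j:j + d]
            j += d
        return out

    # -- forward --------------------------------------------------------
    def _lstm_forward(self, m: str, x: np.ndarray) -> tuple[np.ndarray, list]:
        B, T, _ = x.shape
        h_sz = self.hidden[m]
        W, U, b = (self.params[f"W_{m}"], self.params[f"U_{m}"],
                   self.params[f"b_{m}"])
        h = np.zeros((B, h_sz))
        c = np.zeros((B, h_sz))
        H = np.zeros((B, T, h_sz))
        cache = []
        for t in range(T):
            a = x[:, t] @ W + h @ U + b
            i = _sigmoid(a[:, :h_sz])
            f = _sigmoid(a[:, h_sz:2 * h_sz])
            g = np.tanh(a[:, 2 * h_sz:3 * h_sz])
            o = _sigmoid(a[:, 3 * h_sz:])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            cache.append((x[:, t], h, c, i, f, g, o, c_new))
            h, c = h_new, c_new
            H[:, t] = h
        return H, cache

    def forward(self, batch: Batch) -> dict[str, np.ndarray]:
        """Full forward pass; returns per-timestep head probabilities,
        regression outputs, and the caches needed for backprop."""
        P = self.params
        mods = self._split_modalities(batch.dynamic)
        H, lstm_cache = {}, {}
        for m in self.modality_dims:
            H[m], lstm_cache[m] = self._lstm_forward(m, mods[m])
        B, T = batch.mask.shape
        stat = np.repeat(batch.static[:, None, :], T, axis=1)
        z = np.concatenate([H[m] for m in self.modality_dims] + [stat], axis=2)
        f_pre = z @ P["W_fuse"] + P["b_fuse"]
        fuse = np.tanh(f_pre)
        out: dict[str, np.ndarray] = {"fuse": fuse, "z": z,
                                      "lstm_cache": lstm_cache, "H": H}
        for o in HEADS:
            g = np.tanh(fuse @ P[f"W_int_{o}"] + P[f"b_int_{o}"])
            logits = g @ P[f"W_cls_{o}"] + P[f"b_cls_{o}"]
            out[f"g_{o}"] = g
            out[f"probs_{o}"] = _softmax(logits)
        out["reg"] = fuse @ P["W_reg"] + P["b_reg"]
        return out

    def predict_proba(self, batch: Batch, upto_visit: int,
                      head: str = "sr") -> np.ndarray:
        """Raw (uncalibrated) positive-class probability at step ``upto_visit``."""
        T = batch.dynamic.shape[1]
        if not 0 <= upto_visit < T:
            raise ValueError(f"upto_visit must be in [0, {T - 1}], got {upto_visit}")
        fwd = self.forward(batch)
        return fwd[f"probs_{head}"][:, upto_visit, 1]

    # -- loss & gradients ----------------------------------------------
    def loss_and_grads(self, batch: Batch) -> tuple[float, dict[str, np.ndarray],
                                                    dict[str, float]]:
        P = self.params
        arch = self.arch
        fwd = self.forward(batch)
        fuse, z = fwd["fuse"], fwd["z"]
        B, T = batch.mask.shape
        mask = batch.mask.astype(float)
        grads = {k: np.zeros_like(v) for k, v in P.items()}
        d_fuse = np.zeros_like(fuse)
        parts: dict[str, float] = {}

        # classification heads: CE at every attended visit, label broadcast
        ce_total = 0.0
        for o in HEADS:
            labels = batch.labels[o]
            lab_ok = labels >= 0
            pos = mask * lab_ok[:, None].astype(float)
            n_pos = max(pos.sum(), 1.0)
            probs = fwd[f"probs_{o}"]
            onehot = np.zeros((B, 2))
            onehot[np.arange(B), np.clip(labels, 0, 1)] = 1.0
            ce = -(np.log(np.clip(probs, 1e-12, None))
                   * onehot[:, None, :]).sum(axis=2)
            ce_o = float((ce * pos).sum() / n_pos)
            ce_total += ce_o
            parts[f"ce_{o}"] = ce_o
            if arch.w_ce > 0:
                d_logits = (probs - onehot[:, None, :]) * pos[:, :, None] / n_pos
                d_logits *= arch.w_ce
                g = fwd[f"g_{o}"]
                grads[f"W_cls_{o}"] += np.einsum("bti,btj->ij", g, d_logits)
                grads[f"b_cls_{o}"] += d_logits.sum(axis=(0, 1))
                d_g = d_logits @ P[f"W_cls_{o}"].T * (1.0 - g ** 2)
                grads[f"W_int_{o}"] += np.einsum("bti,btj->ij", fuse, d_g)
                grads[f"b_int_{o}"] += d_g.sum(axis=(0, 1))
                d_fuse += d_g @ P[f"W_int_{o}"].T

        # regression: predict the next visit's dynamic vector
        nxt = np.zeros_like(batch.dynamic)
        nxt[:, :-1] = batch.dynamic[:, 1:]
        pair = np.zeros((B, T))
        pair[:, :-1] = mask[:, :-1] * mask[:, 1:]
        n_pair = max(pair.sum() * self.dyn_total, 1.0)
        resid = (fwd["reg"] - nxt) * pair[:, :, None]
        mse = float((resid ** 2).sum() / n_pair)
        parts["mse"] = mse
        if arch.w_mse > 0:
            d_reg = 2.0 * resid / n_pair * arch.w_mse
            grads["W_reg"] += np.einsum("bti,btj->ij", fuse, d_reg)
            grads["b_reg"] += d_reg.sum(axis=(0, 1))
            d_fuse += d_reg @ P["W_reg"].T

        # fusion -> z
        d_pre = d_fuse * (1.0 - fuse ** 2)
        grads["W_fuse"] += np.einsum("bti,btj->ij", z, d_pre)
        grads["b_fuse"] += d_pre.sum(axis=(0, 1))
        d_z = d_pre @ P["W_fuse"].T

        # split z gradient back into the modality branches
        j = 0
        mods = self._split_modalities(batch.dynamic)
        for m in self.modality_dims:
            h_sz = self.hidden[m]
            self._lstm_backward(m, mods[m], fwd["lstm_cache"][m],
                                d_z[:, :, j:j + h_sz], grads)
            j += h_sz

        loss = arch.w_mse * mse + arch.w_ce * ce_total
        parts["loss"] = loss
        return loss, grads, parts

    def _lstm_backward(self, m: str, x: np.ndarray, cache: list,
                       dH: np.ndarray, grads: dict[str, np.ndarray]) -> None:
        h_sz = self.hidden[m]
        U = self.params[f"U_{m}"]
        B, T, _ = x.shape
        dh_next = np.zeros((B, h_sz))
        dc_next = np.zeros((B, h_sz))
        for t in reversed(range(T)):
            x_t, h_prev, c_prev, i, f, g, o, c_new = cache[t]
            dh = dH[:, t] + dh_next
            tc = np.tanh(c_new)
            d_o = dh * tc
            dc = dh * o * (1.0 - tc ** 2) + dc_next
            d_i = dc * g
            d_g = dc * i
            d_f = dc * c_prev
            da = np.concatenate([
                d_i * i * (1.0 - i),
                d_f * f * (1.0 - f),
                d_g * (1.0 - g ** 2),
                d_o * o * (1.0 - o)], axis=1)
            grads[f"W_{m}"] += x_t.T @ da
            grads[f"U_{m}"] += h_prev.T @ da
            grads[f"b_{m}"] += da.sum(axis=0)
            dh_next = da @ U.T
            dc_next = dc * f


@dataclass
class AdamState:
    """Adam with exponential learning-rate decay; step counter is global."""

    lr0: float
    decay_rate: float
    decay_steps: int
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    weight_decay: float = 0.0          # decoupled L2, applied to W/U only
    step: int = 0
    m: dict[str, np.ndarray] = field(default_factory=dict)
    v: dict[str, np.ndarray] = field(default_factory=dict)

    def learning_rate(self, step: int | None = None) -> float:
        s = self.step if step is None else step
        return self.lr0 * self.decay_rate ** (s / self.decay_steps)

    def update(self, params: dict[str, np.ndarray],
               grads: dict[str, np.ndarray]) -> None:
        self.step += 1
        lr = self.learning_rate()
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g ** 2
            mhat = self.m[k] / (1 - self.beta1 ** self.step)
            vhat = self.v[k] / (1 - self.beta2 ** self.step)
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay > 0 and not k.startswith("b_"):
                params[k] *= 1.0 - lr * self.weight_decay
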