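"""The spectrum transformer: peak encoder, Graphormer-bias encoder, heads.

Each peak ``(m, i)`` is encoded as the concatenation of a deep feed-forward
transform of its mass-tolerant Fourier features (width ``d_m``) and a shallow
transform of the raw pair (width ``d_p``). A pre-norm transformer encoder
(no linear biases, ReLU activations) with an additive attention-bias term on
pairwise Fourier-feature differences then refines the peak set; the column of
the precursor token is the spectrum embedding. Task heads project the final
representations to masked-mass bins, retention order, molecular properties,
fluorine probability, an embedding, or a 4,096-bit fingerprint.
"""

from __future__ import annotations

import io as _io
import zipfile
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import yaml

from ..fourier import FourierGrid, build_fourier_grid, fourier_features
from .autodiff import Tensor

N_PROPERTIES = 11
FINGERPRINT_BITS = 4096

TASKS = ("mass", "order", "properties", "fluorine", "embedding", "fingerprint")


@dataclass
class EncoderConfig:
    d: int = 1024
    d_m: int = 980
    d_p: int = 44
    layers: int = 7
    heads: int = 8
    c: int = 20000  # mass bins of the masked-peak classification head
    n_peaks: int = 60
    ffn_f_depth: int = 4
    ffn_f_hidden: Optional[int] = None  # default 2*d_m
    ffn_p_hidden: Optional[int] = None  # default d_p
    bias_prefix_2t: Optional[int] = None  # None = all 2B components
    m_min: float = 1e-4
    m_max: int = 1000
    high_stride: int = 2

    def __post_init__(self) -> None:
        if self.d != self.d_m + self.d_p:
            raise ValueError("d must equal d_m + d_p")
        if self.c < 2:
            raise ValueError("need at least 2 mass bins")
        if self.d % self.heads != 0:
            raise ValueError("d must be divisible by the head count")
        if self.ffn_f_hidden is None:
            self.ffn_f_hidden = 2 * self.d_m
        if self.ffn_p_hidden is None:
            self.ffn_p_hidden = self.d_p

    def grid(self) -> FourierGrid:
        return build_fourier_grid(self.m_min, self.m_max, self.high_stride)


def _glorot(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    scale = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.standard_normal((fan_out, fan_in)) * scale


class SpectrumTransformer:
    """All learnable parameters plus the forward passes."""

    def __init__(self, cfg: EncoderConfig, seed: int = 0):
        self.cfg = cfg
        self.grid = cfg.grid()
        rng = np.random.default_rng(seed)
        two_b = 2 * len(self.grid)
        p: dict[str, Tensor] = {}

        dims = [two_b] + [cfg.ffn_f_hidden] * (cfg.ffn_f_depth - 1) + [cfg.d_m]
        for i, (a, b) in enumerate(zip(dims, dims[1:])):
            p[f"ffn_f.{i}"] = Tensor(_glorot(rng, b, a), requires_grad=True)
        p["ffn_p.0"] = Tensor(_glorot(rng, cfg.ffn_p_hidden, 2), requires_grad=True)
        p["ffn_p.1"] = Tensor(_glorot(rng, cfg.d_p, cfg.ffn_p_hidden), requires_grad=True)

        for layer in range(cfg.layers):
            pre = f"block{layer}."
            p[pre + "ln1"] = Tensor(np.ones(cfg.d), requires_grad=True)
            for name in ("wq", "wk", "wv", "wo"):
                p[pre + name] = Tensor(_glorot(rng, cfg.d, cfg.d), requires_grad=True)
            p[pre + "ln2"] = Tensor(np.ones(cfg.d), requires_grad=True)
            p[pre + "ffn0"] = Tensor(_glorot(rng, 4 * cfg.d, cfg.d), requires_grad=True)
            p[pre + "ffn1"] = Tensor(_glorot(rng, cfg.d, 4 * cfg.d), requires_grad=True)
        p["ln_out"] = Tensor(np.ones(cfg.d), requires_grad=True)

        p["w_mass"] = Tensor(_glorot(rng, cfg.c, cfg.d), requires_grad=True)
        p["w_order"] = Tensor(_glorot(rng, 1, 2 * cfg.d), requires_grad=True)
        p["w_props"] = Tensor(_glorot(rng, N_PROPERTIES, cfg.d), requires_grad=True)
        p["w_f"] = Tensor(_glorot(rng, 1, cfg.d), requires_grad=True)
        p["w_emb"] = Tensor(_glorot(rng, cfg.d, cfg.d), requires_grad=True)
        p["w_fp0"] = Tensor(_glorot(rng, cfg.d, cfg.d), requires_grad=True)
        p["w_fp1"] = Tensor(_glorot(rng, FINGERPRINT_BITS, cfg.d), requires_grad=True)
        self.params = p

    # -- bookkeeping ---------------------------------------------------------

    def parameters(self) -> list[Tensor]:
        return [self.params[k] for k in sorted(self.params)]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].data = np.asarray(v, dtype=np.float64)

    # -- building blocks -----------------------------------------------------

    def _layernorm(self, x: Tensor, gain: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + 1e-5) ** -0.5 * gain

    def encode_peaks(self, values: np.ndarray) -> Tensor:
        """PeakEncoder: ``(B, 2, n+1)`` spectrum matrices to ``(B, n+1, d)``."""
        mz = values[:, 0, :]
        phi = fourier_features(mz, self.grid)  # (B, n+1, 2B)
        h = Tensor(phi)
        n_f = self.cfg.ffn_f_depth
        for i in range(n_f):
            h = h @ self.params[f"ffn_f.{i}"].T
            if i < n_f - 1:
                h = h.relu()
        raw = Tensor(np.swapaxes(values, 1, 2))  # (B, n+1, 2)
        hp = (raw @ self.params["ffn_p.0"].T).relu() @ self.params["ffn_p.1"].T
        return Tensor.concat([h, hp], axis=-1)

    def attention_bias(self, mz: np.ndarray) -> np.ndarray:
        """Additive Graphormer-like attention term on Fourier differences.

        Entry (i, j) is the sum over the first ``2t`` feature components of
        ``phi(m_i) - phi(m_j)``; antisymmetric with a zero diagonal. Shared
        across heads and not learned.
        """
        phi = fourier_features(mz, self.grid)
        two_t = self.cfg.bias_prefix_2t
        if two_t is None:
            two_t = phi.shape[-1]
        s = phi[..., :two_t].sum(axis=-1)  # (..., n+1)
        return s[..., :, None] - s[..., None, :]

    def forward_encoder(self, values: np.ndarray, pad_mask: np.ndarray) -> Tensor:
        """Full encoder: spectrum matrices to final peak representations.

        ``values``: (B, 2, n+1); ``pad_mask``: (B, n+1) True on padding.
        Returns (B, n+1, d); column 0 is the spectrum embedding. Padded
        columns are excluded from attention as keys.
        """
        cfg = self.cfg
        x = self.encode_peaks(values)
        bias = self.attention_bias(values[:, 0, :])  # (B, n+1, n+1)
        key_mask = np.where(pad_mask[:, None, None, :], -1e9, 0.0)  # (B,1,1,n+1)
        bias4 = bias[:, None, :, :]
        scale = 1.0 / np.sqrt(cfg.d)
        B, n1 = pad_mask.shape
        dh = cfg.d // cfg.heads

        def split_heads(t: Tensor) -> Tensor:
            return t.reshape(B, n1, cfg.heads, dh).swapaxes(1, 2)

        for layer in range(cfg.layers):
            pre = f"block{layer}."
            h = self._layernorm(x, self.params[pre + "ln1"])
            q = split_heads(h @ self.params[pre + "wq"].T)
            k = split_heads(h @ self.params[pre + "wk"].T)
            v = split_heads(h @ self.params[pre + "wv"].T)
            scores = (q @ k.T + bias4) * scale + key_mask
            attn = scores.softmax(axis=-1)
            ctx = (attn @ v).swapaxes(1, 2).reshape(B, n1, cfg.d)
            x = x + ctx @ self.params[pre + "wo"].T
            h = self._layernorm(x, self.params[pre + "ln2"])
            h = (h @ self.params[pre + "ffn0"].T).relu() @ self.params[pre + "ffn1"].T
            x = x + h
        return self._layernorm(x, self.params["ln_out"])

    # -- heads ----------------------------------------------------------------

    def head_mass_log_probs(self, s_masked: Tensor) -> Tensor:
        """Log-probabilities over the c mass bins for masked-peak rows."""
        return (s_masked @ self.params["w_mass"].T).log_softmax(axis=-1)

    def head_order(self, s0_i: Tensor, s0_j: Tensor) -> Tensor:
        both = Tensor.concat([s0_i, s0_j], axis=-1)
        return (both @ self.params["w_order"].T).sigmoid()

    def heads_forward(self, s_l: Tensor, task: str, pad_mask: Optional[np.ndarray] = None):
        """Dispatch the task heads on final representations ``(B, n+1, d)``."""
        if task not in TASKS:
            raise ValueError(f"unknown task {task!r}")
        s0 = s_l[:, 0, :]
        if task == "mass":
            return (s_l @ self.params["w_mass"].T).softmax(axis=-1)
        if task == "order":
            half = s0.shape[0] // 2
            return self.head_order(s0[:half], s0[half:])
        if task == "properties":
            return s0 @ self.params["w_props"].T
        if task == "fluorine":
            return (s0 @ self.params["w_f"].T).sigmoid()
        if task == "embedding":
            return s0 @ self.params["w_emb"].T
        # fingerprint: DeepSets-style sum over real peak positions
        h = (s_l @ self.params["w_fp0"].T).relu()
        if pad_mask is not None:
            h = h * Tensor((~pad_mask)[..., None].astype(np.float64))
        return h.sum(axis=1) @ self.params["w_fp1"].T

    def embed(self, values: np.ndarray, pad_mask: np.ndarray) -> np.ndarray:
        """Spectrum embeddings (precursor-token column), as plain arrays."""
        s_l = self.forward_encoder(values, pad_mask)
        return s_l.data[:, 0, :].copy()


# -- checkpoints --------------------------------------------------------------


def save_checkpoint(model: SpectrumTransformer, path: str) -> None:
    """Single-archive checkpoint: weights as .npy entries + config YAML."""
    cfg = asdict(model.cfg)
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("config.yaml", yaml.safe_dump(cfg))
        for name, arr in model.state_dict().items():
            buf = _io.BytesIO()
            np.save(buf, arr)
            zf.writestr(f"weights/{name}.npy", buf.getvalue())


def load_checkpoint(path: str) -> SpectrumTransformer:
    with zipfile.ZipFile(path, "r") as zf:
        cfg = EncoderConfig(**yaml.safe_load(zf.read("config.yaml")))
        model = SpectrumTransformer(cfg, seed=0)
        state = {}
        for info in zf.namelist():
            if info.startswith("weights/"):
                name = info[len("weights/") : -len(".npy")]
                state[name] = np.load(_io.BytesIO(zf.read(info)))
    model.load_state_dict(state)
    return model
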