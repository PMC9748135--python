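"""The denoising multimodal autoencoder.

One encoder consumes the concatenation of the (noise-corrupted) normalized
RNA matrix and the second modality (ADT or ATAC); two decoders reconstruct
each modality from the shared bottleneck. Each decoder ends in three affine
heads producing the ZINB parameters: the mean (exp, scaled per cell by the
size factor), the dispersion (exp), and the dropout probability (sigmoid).
In conditional mode a one-hot batch indicator is appended to the encoder and
decoder inputs so the network can absorb batch-specific variation.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._autodiff import DTYPE, Tensor, concat
from ._nn import Dense, HiddenStack

# numerical guards on exp-activated heads
_MEAN_CLAMP = (-11.5, 13.8)   # exp range ~ [1e-5, 1e6]
_DISP_CLAMP = (-9.2, 9.2)     # exp range ~ [1e-4, 1e4]


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    Defaults are the CITE-seq preset: encoder {256, 64, 32, 16} (16-d latent),
    RNA decoder {16, 64, 256}, ADT decoder {16, 20}, corruption noise weights
    sigma_rna=2.5 and sigma_second=1.5. The multiome (RNA+ATAC) preset uses
    encoder {256, 128, 64}, both decoders {64, 128, 256}, sigma_second=2.5.
    """

    encoder_dims: list = field(default_factory=lambda: [256, 64, 32, 16])
    decoder_dims_rna: list = field(default_factory=lambda: [16, 64, 256])
    decoder_dims_second: list = field(default_factory=lambda: [16, 20])
    sigma_rna: float = 2.5
    sigma_second: float = 1.5
    n_batches: int = 0

    def __post_init__(self):
        for dims in (self.encoder_dims, self.decoder_dims_rna, self.decoder_dims_second):
            if not dims or any(w <= 0 for w in dims):
                raise ValueError("layer width lists must be non-empty and positive")

    @property
    def latent_dim(self) -> int:
        return self.encoder_dims[-1]

    @classmethod
    def cite_preset(cls, n_batches: int = 0) -> "NetworkConfig":
        return cls(n_batches=n_batches)

    @classmethod
    def smage_preset(cls, n_batches: int = 0) -> "NetworkConfig":
        return cls(encoder_dims=[256, 128, 64],
                   decoder_dims_rna=[64, 128, 256],
                   decoder_dims_second=[64, 128, 256],
                   sigma_second=2.5, n_batches=n_batches)


@dataclass
class ZINBParams:
    """Per-entry ZINB parameter matrices for one modality."""

    mean: np.ndarray
    dispersion: np.ndarray
    dropout: np.ndarray


class _ZINBHeads:
    def __init__(self, n_hidden: int, n_out: int, rng: np.random.Generator):
        self.mean = Dense(n_hidden, n_out, rng)
        self.disp = Dense(n_hidden, n_out, rng)
        self.drop = Dense(n_hidden, n_out, rng)

    def __call__(self, h: Tensor, size_factors: Tensor):
        mu = self.mean(h).clamp(*_MEAN_CLAMP).exp() * size_factors
        theta = self.disp(h).clamp(*_DISP_CLAMP).exp()
        pi = self.drop(h).sigmoid()
        return mu, theta, pi

    def parameters(self):
        return self.mean.parameters() + self.disp.parameters() + self.drop.parameters()


class Model:
    """Encoder + two decoders + ZINB heads, with optional batch conditioning."""

    def __init__(self, cfg: NetworkConfig, input_dims: tuple, seed: int = 0):
        rna_dim, second_dim = input_dims
        if rna_dim <= 0 or second_dim <= 0:
            raise ValueError("input dims must be positive")
        self.cfg = cfg
        self.input_dims = (rna_dim, second_dim)
        rng = np.random.default_rng(seed)
        m = cfg.n_batches
        # the bottleneck is the last encoder layer
        self.encoder = HiddenStack(rna_dim + second_dim + m, cfg.encoder_dims, rng)
        z = cfg.latent_dim
        self.decoder_rna = HiddenStack(z + m, cfg.decoder_dims_rna, rng)
        self.decoder_second = HiddenStack(z + m, cfg.decoder_dims_second, rng)
        self.heads_rna = _ZINBHeads(self.decoder_rna.n_out, rna_dim, rng)
        self.heads_second = _ZINBHeads(self.decoder_second.n_out, second_dim, rng)

    # ---- forward -------------------------------------------------------
    def encode(self, rna_in, second_in, batches=None, training: bool = False) -> Tensor:
        parts = [Tensor._wrap(rna_in), Tensor._wrap(second_in)]
        if self.cfg.n_batches:
            if batches is None:
                raise ValueError("conditional model requires a batch matrix")
            parts.append(Tensor._wrap(batches))
        return self.encoder(concat(parts, axis=1), training)

    def decode(self, Z: Tensor, s_rna, s_second, batches=None, training: bool = False):
        zin = Z
        if self.cfg.n_batches:
            zin = concat([Z, Tensor._wrap(batches)], axis=1)
        h_r = self.decoder_rna(zin, training)
        h_s = self.decoder_second(zin, training)
        sr = Tensor._wrap(np.asarray(s_rna, dtype=DTYPE).reshape(-1, 1))
        ss = Tensor._wrap(np.asarray(s_second, dtype=DTYPE).reshape(-1, 1))
        out_r = self.heads_rna(h_r, sr)
        out_s = self.heads_second(h_s, ss)
        return out_r, out_s

    def forward(self, rna_in, second_in, s_rna, s_second, batches=None,
                training: bool = False):
        """Returns (Z, ZINB params RNA, ZINB params second) as tensors."""
        Z = self.encode(rna_in, second_in, batches, training)
        out_r, out_s = self.decode(Z, s_rna, s_second, batches, training)
        return Z, out_r, out_s

    def embed(self, rna_norm, second_norm, batches=None) -> np.ndarray:
        """Deterministic latent coordinates from clean inputs (eval mode)."""
        return self.encode(rna_norm, second_norm, batches, training=False).data.copy()

    def zinb_params(self, rna_norm, second_norm, s_rna, s_second, batches=None):
        """Evaluation-mode ZINB parameter matrices for both modalities."""
        Z, (mr, tr, pr), (ms, ts, ps) = self.forward(
            rna_norm, second_norm, s_rna, s_second, batches, training=False)
        return (ZINBParams(mr.data, tr.data, pr.data),
                ZINBParams(ms.data, ts.data, ps.data))

    def parameters(self):
        return (self.encoder.parameters() + self.decoder_rna.parameters()
                + self.decoder_second.parameters()
                + self.heads_rna.parameters() + self.heads_second.parameters())

    # ---- generic stream API (used by the trainer) ----------------------
    @property
    def n_streams(self) -> int:
        return 2

    @property
    def sigmas(self):
        return (self.cfg.sigma_rna, self.cfg.sigma_second)

    def encode_inputs(self, inputs, batches=None, training: bool = False) -> Tensor:
        parts = [Tensor._wrap(x) for x in inputs]
        if self.cfg.n_batches:
            if batches is None:
                raise ValueError("conditional model requires a batch matrix")
            parts.append(Tensor._wrap(batches))
        return self.encoder(concat(parts, axis=1), training)

    def decode_all(self, Z: Tensor, size_factors, batches=None, training: bool = False):
        out = self.decode(Z, size_factors[0], size_factors[1], batches, training)
        return list(out)

    # ---- persistence ---------------------------------------------------
    def save(self, path: str, extra: Optional[dict] = None) -> None:
        state = {
            "cfg": self.cfg,
            "input_dims": self.input_dims,
            "params": [p.data for p in self.parameters()],
            "bn_stats": [(bn.running_mean, bn.running_var)
                         for stack in (self.encoder, self.decoder_rna, self.decoder_second)
                         for _, bn in stack.blocks],
            "extra": extra or {},
        }
        with open(path, "wb") as f:
            pickle.dump(state, f)

    @classmethod
    def load(cls, path: str):
        with open(path, "rb") as f:
            state = pickle.load(f)
        model = cls(state["cfg"], state["input_dims"])
        for p, d in zip(model.parameters(), state["params"]):
            p.data = np.asarray(d, dtype=DTYPE)
        bns = [bn for stack in (model.encoder, model.decoder_rna, model.decoder_second)
               for _, bn in stack.blocks]
        for bn, (rm, rv) in zip(bns, state["bn_stats"]):
            bn.running_mean, bn.running_var = np.asarray(rm), np.asarray(rv)
        return model, state["extra"]


class UnimodalModel:
    """Single-stream variant: one encoder, one decoder, one set of ZINB heads.

    Used for the ablation sub-models (RNA-only, ADT/ATAC-only, and the
    concatenated-input single-decoder variant). Exposes the same generic
    stream API as the bimodal model so the trainer treats both uniformly.
    """

    def __init__(self, cfg: NetworkConfig, input_dim: int, seed: int = 0):
        if input_dim <= 0:
            raise ValueError("input dim must be positive")
        self.cfg = cfg
        self.input_dims = (input_dim,)
        rng = np.random.default_rng(seed)
        m = cfg.n_batches
        self.encoder = HiddenStack(input_dim + m, cfg.encoder_dims, rng)
        self.decoder = HiddenStack(cfg.latent_dim + m, cfg.decoder_dims_rna, rng)
        self.heads = _ZINBHeads(self.decoder.n_out, input_dim, rng)

    @property
    def n_streams(self) -> int:
        return 1

    @property
    def sigmas(self):
        return (self.cfg.sigma_rna,)

    def encode_inputs(self, inputs, batches=None, training: bool = False) -> Tensor:
        parts = [Tensor._wrap(x) for x in inputs]
        if self.cfg.n_batches:
            parts.append(Tensor._wrap(batches))
        return self.encoder(concat(parts, axis=1), training)

    def decode_all(self, Z: Tensor, size_factors, batches=None, training: bool = False):
        zin = Z
        if self.cfg.n_batches:
            zin = concat([Z, Tensor._wrap(batches)], axis=1)
        h = self.decoder(zin, training)
        s = Tensor._wrap(np.asarray(size_factors[0], dtype=DTYPE).reshape(-1, 1))
        return [self.heads(h, s)]

    def embed(self, x, batches=None) -> np.ndarray:
        return self.encode_inputs([x], batches, training=False).data.copy()

    def parameters(self):
        return (self.encoder.parameters() + self.decoder.parameters()
                + self.heads.parameters())


def corrupt(x: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Additive Gaussian corruption x + sigma * N(0, 1); input untouched."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    x = np.asarray(x)
    if sigma == 0:
        return x.copy()
    return x + sigma * rng.standard_normal(x.shape).astype(x.dtype, copy=False)


def build_model(cfg: NetworkConfig, input_dims: tuple, seed: int = 0) -> Model:
    """Construct a model with seeded initialization."""
    return Model(cfg, input_dims, seed=seed)
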