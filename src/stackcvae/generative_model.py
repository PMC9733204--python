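"""Conditional VAE over SMILES with a stack-augmented recurrent encoder.

The encoder runs a (multi-layer) stack-RNN over the embedded token sequence,
each step's input concatenated with the molecule's standardized condition
vector (MW, LogP, TPSA); the final hidden state maps linearly to the mean
and log-variance of the approximate posterior Q(z|X,c).  The decoder is a
multi-layer GRU that receives [token embedding, z, c] at every step and
predicts the next token through a linear layer and softmax.

Training minimizes reconstruction cross-entropy plus the closed-form KL
divergence from the standard-normal prior (the negative of the usual CVAE
evidence lower bound).  Generation is autoregressive sampling from the
decoder starting at the start token '<', stopping at '>' or a length cap.

Setting ``use_stack=False`` in the configuration disables the external
stack, giving the plain recurrent-encoder CVAE used as the ablation
baseline; everything else in the pipeline is unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import stack_cell
from .autodiff import (Adam, Tensor, concatenate, constant, exp, log_softmax,
                       parameter, sigmoid, tanh, tsum)
from .chem_io import (ConditionVector, SmilesRecord, Vocabulary,
                      build_vocabulary, compute_conditions, tokenize)
from .stack_cell import StackCellParams

COND_DIM = 3

__all__ = [
    "ModelConfig",
    "PosteriorParams",
    "TrainingCurve",
    "ConditionScaler",
    "StackCVAE",
    "encode",
    "sample_latent",
    "cvae_loss",
    "pretrain",
    "generate_smiles",
]


@dataclass
class ModelConfig:
    """Architecture and optimization settings.

    Defaults mirror the full-size architecture (3-layer stack-RNN encoder
    with 512 hidden units, stack width 50 and depth 10, 3-layer GRU
    decoder); tests and examples shrink these for speed.
    """

    hidden_size: int = 512
    num_layers: int = 3
    stack_width: int = 50
    stack_depth: int = 10
    latent_dim: int = 128
    embedding_dim: int = 128
    max_len: int = 100
    use_stack: bool = True
    kl_weight: float = 1.0
    learning_rate: float = 1e-3
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self):
        for name in ("hidden_size", "num_layers", "stack_width", "stack_depth",
                     "latent_dim", "embedding_dim", "max_len", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.kl_weight < 0 or self.learning_rate <= 0:
            raise ValueError("kl_weight must be >= 0 and learning_rate > 0")


@dataclass(frozen=True)
class PosteriorParams:
    mean: np.ndarray
    log_variance: np.ndarray


@dataclass
class TrainingCurve:
    loss: List[float] = field(default_factory=list)
    reward: List[float] = field(default_factory=list)


class ConditionScaler:
    """Z-score scaling of (MW, LogP, TPSA) using training-corpus statistics."""

    def __init__(self, mean: np.ndarray, std: np.ndarray):
        self.mean = np.asarray(mean, dtype=np.float64)
        self.std = np.where(np.asarray(std, dtype=np.float64) > 0, std, 1.0)

    @classmethod
    def fit(cls, conditions: Sequence[ConditionVector]) -> "ConditionScaler":
        arr = np.stack([c.as_array() for c in conditions])
        return cls(arr.mean(axis=0), arr.std(axis=0))

    def transform(self, cond: ConditionVector) -> np.ndarray:
        return (cond.as_array() - self.mean) / self.std

    def transform_many(self, conds: Sequence[ConditionVector]) -> np.ndarray:
        return np.stack([self.transform(c) for c in conds])


def _gru_layer(rng, in_dim, m, make):
    s = 0.1
    return {
        "Wz": make(rng.normal(0, s, (m, in_dim))), "Uz": make(rng.normal(0, s, (m, m))),
        "bz": make(np.zeros(m)),
        "Wr": make(rng.normal(0, s, (m, in_dim))), "Ur": make(rng.normal(0, s, (m, m))),
        "br": make(np.zeros(m)),
        "Wc": make(rng.normal(0, s, (m, in_dim))), "Uc": make(rng.normal(0, s, (m, m))),
        "bc": make(np.zeros(m)),
    }


def gru_step(x, h, layer):
    """One GRU step; works on ndarrays or Tensors."""
    z = sigmoid(x @ layer["Wz"].T + h @ layer["Uz"].T + layer["bz"])
    r = sigmoid(x @ layer["Wr"].T + h @ layer["Ur"].T + layer["br"])
    c = tanh(x @ layer["Wc"].T + (r * h) @ layer["Uc"].T + layer["bc"])
    return (1.0 - z) * h + z * c


class StackCVAE:
    """Stack-encoder conditional VAE over tokenized SMILES."""

    def __init__(self, vocab: Vocabulary, config: ModelConfig, scaler: ConditionScaler):
        self.vocab = vocab
        self.config = config
        self.scaler = scaler
        rng = np.random.default_rng(config.seed)
        m, e, dz = config.hidden_size, config.embedding_dim, config.latent_dim
        V = len(vocab)
        make = parameter
        self.embedding = make(rng.normal(0, 0.1, (V, e)))
        self.enc_layers: List[StackCellParams] = []
        for layer in range(config.num_layers):
            in_dim = e + COND_DIM if layer == 0 else m
            self.enc_layers.append(
                stack_cell.init_params(in_dim, m, config.stack_width, rng, make=make))
        self.W_mu = make(rng.normal(0, 0.1, (dz, m)))
        self.b_mu = make(np.zeros(dz))
        self.W_lv = make(rng.normal(0, 0.1, (dz, m)))
        self.b_lv = make(np.zeros(dz))
        self.dec_layers = []
        for layer in range(config.num_layers):
            in_dim = e + dz + COND_DIM if layer == 0 else m
            self.dec_layers.append(_gru_layer(rng, in_dim, m, make))
        self.W_out = make(rng.normal(0, 0.1, (V, m)))
        self.b_out = make(np.zeros(V))

    # -- parameter bookkeeping ----------------------------------------------
    def encoder_parameters(self) -> List[Tensor]:
        out = [self.embedding, self.W_mu, self.b_mu, self.W_lv, self.b_lv]
        for p in self.enc_layers:
            out += [p.A, p.D, p.U, p.R, p.P]
        return out

    def decoder_parameters(self) -> List[Tensor]:
        out = []
        for layer in self.dec_layers:
            out += list(layer.values())
        out += [self.W_out, self.b_out]
        return out

    def parameters(self) -> List[Tensor]:
        return self.encoder_parameters() + self.decoder_parameters()

    def _np_dec_layers(self):
        return [{k: v.data for k, v in layer.items()} for layer in self.dec_layers]

    # -- encoder -------------------------------------------------------------
    def encode_batch(self, tokens: np.ndarray, cond: np.ndarray) -> Tuple[Tensor, Tensor]:
        """Posterior (mean, log-variance) Tensors for padded token ids (B, T)."""
        B, T = tokens.shape
        cfg = self.config
        emb = self.embedding[tokens]  # (B, T, e)
        cond_t = constant(cond)
        mask = (tokens != self.vocab.pad_id).astype(np.float64)
        hs = [constant(np.zeros((B, cfg.hidden_size))) for _ in range(cfg.num_layers)]
        stacks = [constant(np.zeros((B, cfg.stack_depth, cfg.stack_width)))
                  for _ in range(cfg.num_layers)]
        for t in range(T):
            x = concatenate([emb[:, t, :], cond_t], axis=-1)
            m_t = mask[:, t : t + 1]
            for layer in range(cfg.num_layers):
                p = self.enc_layers[layer]
                if cfg.use_stack:
                    h_new, s_new = stack_cell.cell_step(x, hs[layer], stacks[layer], p)
                    stacks[layer] = m_t[:, :, None] * s_new + (1.0 - m_t[:, :, None]) * stacks[layer]
                else:
                    h_new = sigmoid(x @ p.U.T + hs[layer] @ p.R.T)
                hs[layer] = m_t * h_new + (1.0 - m_t) * hs[layer]
                x = hs[layer]
        h_final = hs[-1]
        mu = h_final @ self.W_mu.T + self.b_mu
        logvar = h_final @ self.W_lv.T + self.b_lv
        return mu, logvar

    # -- decoder -------------------------------------------------------------
    def decode_logprobs(self, tokens: np.ndarray, z, cond: np.ndarray) -> Tensor:
        """Log-probabilities (B, T-1, V) of each next token under teacher forcing."""
        B, T = tokens.shape
        cfg = self.config
        z_t = z if isinstance(z, Tensor) else constant(z)
        cond_t = constant(cond)
        emb = self.embedding[tokens[:, :-1]]  # (B, T-1, e)
        hs = [constant(np.zeros((B, cfg.hidden_size))) for _ in range(cfg.num_layers)]
        step_logits = []
        for t in range(T - 1):
            x = concatenate([emb[:, t, :], z_t, cond_t], axis=-1)
            for layer in range(cfg.num_layers):
                hs[layer] = gru_step(x, hs[layer], self.dec_layers[layer])
                x = hs[layer]
            logits = x @ self.W_out.T + self.b_out  # (B, V)
            step_logits.append(logits.reshape(B, 1, len(self.vocab)))
        return log_softmax(concatenate(step_logits, axis=1), axis=-1)

    # -- training loss -------------------------------------------------------
    def loss_batch(self, tokens: np.ndarray, cond: np.ndarray,
                   rng: np.random.Generator) -> Tuple[Tensor, float, float]:
        """(total loss Tensor, reconstruction float, KL float) for one batch."""
        B, T = tokens.shape
        mu, logvar = self.encode_batch(tokens, cond)
        eps = rng.standard_normal((B, self.config.latent_dim))
        z = mu + exp(logvar * 0.5) * eps
        logp = self.decode_logprobs(tokens, z, cond)
        targets = tokens[:, 1:]
        mask = (targets != self.vocab.pad_id).astype(np.float64)
        b_idx, t_idx = np.meshgrid(np.arange(B), np.arange(T - 1), indexing="ij")
        chosen = logp[(b_idx.ravel(), t_idx.ravel(), targets.ravel())]
        recon = tsum(chosen * (-mask.ravel())) / float(B)
        kl = tsum(mu * mu + exp(logvar) - 1.0 - logvar) * (0.5 / float(B))
        total = recon + self.config.kl_weight * kl
        return total, float(recon.data), float(kl.data)

    # -- generation ----------------------------------------------------------
    def sample_tokens(self, cond: np.ndarray, z: Optional[np.ndarray],
                      rng: np.random.Generator,
                      max_len: Optional[int] = None) -> Tuple[List[int], List[float], bool]:
        """Autoregressive sampling (NumPy forward pass only).

        Returns (interior token ids, per-step chosen-token probabilities for
        the interior tokens, truncated flag).  The probability of the final
        '>' is not part of the per-step record, matching a reward defined on
        the finished string only.
        """
        cfg = self.config
        max_len = cfg.max_len if max_len is None else max_len
        if z is None:
            z = rng.standard_normal(cfg.latent_dim)
        z = np.asarray(z, dtype=np.float64)
        cond = np.asarray(cond, dtype=np.float64)
        E = self.embedding.data
        layers = self._np_dec_layers()
        W_out, b_out = self.W_out.data, self.b_out.data
        hs = [np.zeros(cfg.hidden_size) for _ in range(cfg.num_layers)]
        token = self.vocab.start_id
        ids: List[int] = []
        probs: List[float] = []
        truncated = True
        for _ in range(max_len):
            x = np.concatenate([E[token], z, cond])
            for layer in range(cfg.num_layers):
                hs[layer] = gru_step(x, hs[layer], layers[layer])
                x = hs[layer]
            logits = x @ W_out.T + b_out
            logits = logits - logits.max()
            p = np.exp(logits)
            p /= p.sum()
            # The full softmax is sampled (padding included) so the recorded
            # step probability equals the differentiable recomputation exactly;
            # a sampled pad/start token simply yields an invalid string, which
            # the reward already penalizes.
            token = int(rng.choice(len(p), p=p))
            if token == self.vocab.end_id:
                truncated = False
                break
            ids.append(token)
            probs.append(float(p[token]))
        return ids, probs, truncated

    # -- persistence ---------------------------------------------------------
    def _named_parameters(self) -> Dict[str, Tensor]:
        named = {"embedding": self.embedding, "W_mu": self.W_mu, "b_mu": self.b_mu,
                 "W_lv": self.W_lv, "b_lv": self.b_lv,
                 "W_out": self.W_out, "b_out": self.b_out}
        for i, p in enumerate(self.enc_layers):
            for f in ("A", "D", "U", "R", "P"):
                named[f"enc{i}.{f}"] = getattr(p, f)
        for i, layer in enumerate(self.dec_layers):
            for k, v in layer.items():
                named[f"dec{i}.{k}"] = v
        return named

    def save(self, directory) -> None:
        """Checkpoint: weights.npz plus a JSON manifest with vocab/config/scaler."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz",
                 **{k: v.data for k, v in self._named_parameters().items()})
        manifest = {
            "format_version": 1,
            "config": asdict(self.config),
            "vocabulary": self.vocab.tokens,
            "condition_mean": self.scaler.mean.tolist(),
            "condition_std": self.scaler.std.tolist(),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory) -> "StackCVAE":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        vocab = Vocabulary(manifest["vocabulary"])
        assert vocab.tokens == manifest["vocabulary"], "vocabulary order drifted"
        config = ModelConfig(**manifest["config"])
        scaler = ConditionScaler(np.array(manifest["condition_mean"]),
                                 np.array(manifest["condition_std"]))
        model = cls(vocab, config, scaler)
        weights = np.load(directory / "weights.npz")
        for name, tensor in model._named_parameters().items():
            tensor.data = weights[name].astype(np.float64)
        return model


# -- module-level operations --------------------------------------------------

def encode(seq: Sequence[str], cond: ConditionVector, model: StackCVAE) -> PosteriorParams:
    """Posterior parameters for one delimited token sequence."""
    ids = model.vocab.encode(seq)[None, :]
    cond_std = model.scaler.transform(cond)[None, :]
    mu, logvar = model.encode_batch(ids, cond_std)
    return PosteriorParams(mean=mu.data[0].copy(), log_variance=logvar.data[0].copy())


def sample_latent(post: PosteriorParams, seed: int) -> np.ndarray:
    """Reparameterized draw z = mu + exp(logvar/2) * eps, eps ~ N(0, I)."""
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(post.mean.shape)
    return post.mean + np.exp(post.log_variance * 0.5) * eps


def gaussian_kl(mean: np.ndarray, log_variance: np.ndarray) -> float:
    """Closed-form KL(N(mean, diag exp(logvar)) || N(0, I))."""
    mean = np.asarray(mean, dtype=np.float64)
    lv = np.asarray(log_variance, dtype=np.float64)
    return float(0.5 * np.sum(mean ** 2 + np.exp(lv) - 1.0 - lv))


def cvae_loss(target_ids: Sequence[int], cond: ConditionVector, post: PosteriorParams,
              step_dists: Sequence[np.ndarray]) -> Tuple[float, float, float]:
    """(total, reconstruction, kl) for one sequence of next-token targets.

    ``step_dists[t]`` is the predicted distribution over the vocabulary for
    target token ``target_ids[t]``; reconstruction is the summed token-wise
    cross-entropy and the KL term is the closed-form Gaussian divergence
    from the standard-normal prior.
    """
    if len(target_ids) != len(step_dists):
        raise ValueError("step_dists must align with target tokens")
    recon = -sum(float(np.log(step_dists[t][target_ids[t]])) for t in range(len(target_ids)))
    kl = gaussian_kl(post.mean, post.log_variance)
    return recon + kl, recon, kl


def _prepare_batchable(corpus: Sequence[SmilesRecord], vocab: Vocabulary,
                       scaler: ConditionScaler):
    seqs, conds = [], []
    for rec in corpus:
        seqs.append(vocab.encode(tokenize(rec.smiles, vocab)))
        conds.append(scaler.transform(compute_conditions(rec.smiles)))
    return seqs, np.stack(conds)


def _pad(seqs: Sequence[np.ndarray], pad_id: int) -> np.ndarray:
    T = max(len(s) for s in seqs)
    out = np.full((len(seqs), T), pad_id, dtype=np.int64)
    for i, s in enumerate(seqs):
        out[i, : len(s)] = s
    return out


def pretrain(corpus: Sequence[SmilesRecord], config: ModelConfig, seed: int,
             epochs: int = 30) -> Tuple[StackCVAE, TrainingCurve]:
    """Teacher-forced training of the CVAE objective on a SMILES corpus.

    Builds the vocabulary and condition scaler from the corpus, then runs
    `epochs` passes of Adam over shuffled mini-batches.  Fully reproducible
    for a fixed seed.
    """
    if not corpus:
        raise ValueError("cannot pretrain on an empty corpus")
    vocab = build_vocabulary(corpus)
    conditions = [compute_conditions(rec.smiles) for rec in corpus]
    scaler = ConditionScaler.fit(conditions)
    config = ModelConfig(**{**asdict(config), "seed": seed})
    model = StackCVAE(vocab, config, scaler)
    seqs, conds = _prepare_batchable(corpus, vocab, scaler)
    rng = np.random.default_rng(seed + 1)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    curve = TrainingCurve()
    n = len(seqs)
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            tokens = _pad([seqs[i] for i in idx], vocab.pad_id)
            total, _, _ = model.loss_batch(tokens, conds[idx], rng)
            opt.zero_grad()
            total.backward()
            opt.step()
            epoch_losses.append(float(total.data))
        curve.loss.append(float(np.mean(epoch_losses)))
    return model, curve


def generate_smiles(model: StackCVAE, cond, z: Optional[np.ndarray] = None,
                    max_len: Optional[int] = None, seed: Optional[int] = None,
                    rng: Optional[np.random.Generator] = None) -> str:
    """Sample one SMILES string from the decoder.

    ``cond`` may be a ConditionVector (standardized internally) or an
    already-standardized 3-vector; if ``z`` is None a fresh standard-normal
    latent is drawn.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if isinstance(cond, ConditionVector):
        cond = model.scaler.transform(cond)
    ids, _, _ = model.sample_tokens(np.asarray(cond), z, rng, max_len=max_len)
    return "".join(model.vocab.decode(ids))
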