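"""Policy-gradient (REINFORCE) fine-tuning of the decoder.

The decoder of the pretrained CVAE is treated as the policy: each episode
draws a fresh latent z ~ N(0, I), samples a SMILES autoregressively under a
fixed reference condition vector, and receives a terminal reward from the
synthesizability/affinity engine (intermediate rewards are zero).  The loss

    L = - sum_{t=0}^{T-1} log(y_t) * G_t,      G_t = R * gamma^(T-1-t)

propagates the terminal reward R back through the T interior tokens with
geometric attenuation (discount rate gamma, default 0.1).  Only the decoder
parameters (GRU layers and the output head) are updated; the encoder is
unused once z is drawn from the prior, and the shared token embedding is
kept frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .autodiff import Adam, Tensor, tsum
from .chem_io import ConditionVector
from .generative_model import StackCVAE, TrainingCurve
from .reward_engine import (AffinityOracle, RewardComponents, SynthOracle,
                            TargetPanel, total_reward)

__all__ = [
    "RLConfig",
    "EpisodeTrace",
    "sample_episode",
    "discount_rewards",
    "policy_gradient_loss",
    "finetune",
]


@dataclass
class RLConfig:
    """Reinforcement-learning loop settings (gamma = discount rate)."""

    gamma: float = 0.1
    epochs: int = 500
    episodes_per_epoch: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    use_baseline: bool = False  # optional moving-average variance reduction

    def __post_init__(self):
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must satisfy 0 < gamma <= 1")
        if self.epochs < 0 or self.episodes_per_epoch <= 0 or self.learning_rate <= 0:
            raise ValueError("epochs >= 0, episodes_per_epoch > 0, learning_rate > 0 required")


@dataclass
class EpisodeTrace:
    """One sampled generation episode and its reward bookkeeping."""

    token_ids: List[int]  # interior token ids (delimiters excluded)
    step_probs: np.ndarray  # probability of each chosen interior token
    terminal_reward: RewardComponents
    discounted: np.ndarray  # per-step discounted reward, same length
    z: np.ndarray  # latent used for the episode
    smiles: str
    truncated: bool = False


def discount_rewards(total: float, T: int, gamma: float) -> np.ndarray:
    """Terminal reward attenuated backwards: value at step t is total * gamma^(T-1-t)."""
    if T < 1:
        raise ValueError("T must be >= 1")
    powers = np.arange(T - 1, -1, -1, dtype=np.float64)
    return total * gamma ** powers


def sample_episode(model: StackCVAE, cond: np.ndarray, panel: TargetPanel,
                   aff_oracle: AffinityOracle, synth_oracle: SynthOracle,
                   rng_or_seed, gamma: float = 0.1,
                   reward_fn: Optional[Callable[[str], float]] = None) -> EpisodeTrace:
    """Sample one SMILES and attach its discounted terminal reward.

    ``cond`` is an already-standardized condition vector; z is drawn fresh
    from N(0, I).  ``reward_fn`` overrides the reward engine when supplied
    (used e.g. by bandit-style diagnostics).
    """
    rng = rng_or_seed if isinstance(rng_or_seed, np.random.Generator) \
        else np.random.default_rng(rng_or_seed)
    z = rng.standard_normal(model.config.latent_dim)
    ids, probs, truncated = model.sample_tokens(cond, z, rng)
    smiles = "".join(model.vocab.decode(ids))
    if reward_fn is not None:
        r = float(reward_fn(smiles))
        reward = RewardComponents(aff_a=np.nan, aff_d=np.nan, rascore=0.0,
                                  reward1=r, reward2=0.0, reward3=0.0, valid=True)
    else:
        reward = total_reward(smiles, panel, aff_oracle, synth_oracle)
    T = len(ids)
    discounted = discount_rewards(reward.total, T, gamma) if T > 0 else np.zeros(0)
    return EpisodeTrace(token_ids=ids, step_probs=np.asarray(probs, dtype=np.float64),
                        terminal_reward=reward, discounted=discounted, z=z,
                        smiles=smiles, truncated=truncated)


def policy_gradient_loss(trace: EpisodeTrace) -> float:
    """REINFORCE loss for one episode: -sum_t log(y_t) * G_t."""
    if len(trace.step_probs) != len(trace.discounted):
        raise ValueError("step_probs and discounted rewards must align")
    if len(trace.step_probs) == 0:
        return 0.0
    if np.any(trace.step_probs <= 0.0):
        raise ValueError("chosen-token probability must be positive")
    return float(-(np.log(trace.step_probs) * trace.discounted).sum())


def _episode_loss_graph(model: StackCVAE, traces: Sequence[EpisodeTrace],
                        cond: np.ndarray, baseline: float = 0.0) -> Tensor:
    """Differentiable mean episode loss: re-runs the decoder (teacher-forced on
    the sampled tokens) and weights chosen-token log-probs by the discounted
    returns."""
    live = [tr for tr in traces if len(tr.token_ids) > 0]
    if not live:
        return Tensor(0.0)
    vocab = model.vocab
    T_max = max(len(tr.token_ids) for tr in live)
    B = len(live)
    tokens = np.full((B, T_max + 2), vocab.pad_id, dtype=np.int64)
    weights = np.zeros((B, T_max + 1), dtype=np.float64)
    for i, tr in enumerate(live):
        seq = [vocab.start_id] + tr.token_ids + [vocab.end_id]
        tokens[i, : len(seq)] = seq
        weights[i, : len(tr.token_ids)] = tr.discounted - baseline
    z = np.stack([tr.z for tr in live])
    cond_b = np.broadcast_to(cond, (B, cond.shape[-1]))
    logp = model.decode_logprobs(tokens, z, cond_b)  # (B, T_max+1, V)
    targets = tokens[:, 1:]
    b_idx, t_idx = np.meshgrid(np.arange(B), np.arange(T_max + 1), indexing="ij")
    chosen = logp[(b_idx.ravel(), t_idx.ravel(), targets.ravel())]
    return tsum(chosen * (-weights.ravel())) / float(len(traces))


def finetune(model: StackCVAE, panel: Optional[TargetPanel],
             aff_oracle: Optional[AffinityOracle], synth_oracle: Optional[SynthOracle],
             rl_config: RLConfig, cond,
             reward_fn: Optional[Callable[[str], float]] = None,
             trace_callback: Optional[Callable[[int, List[EpisodeTrace]], None]] = None,
             ) -> Tuple[StackCVAE, TrainingCurve]:
    """REINFORCE loop over the decoder.  Returns the model and per-epoch curve.

    ``cond`` is the reference molecule's ConditionVector (or an already
    standardized 3-vector) held fixed across episodes.  The curve records
    the mean Eq.-style loss and the mean total reward per epoch.
    """
    if isinstance(cond, ConditionVector):
        cond = model.scaler.transform(cond)
    cond = np.asarray(cond, dtype=np.float64)
    rng = np.random.default_rng(rl_config.seed)
    opt = Adam(model.decoder_parameters(), lr=rl_config.learning_rate)
    curve = TrainingCurve()
    baseline = 0.0
    for epoch in range(rl_config.epochs):
        traces = [
            sample_episode(model, cond, panel, aff_oracle, synth_oracle, rng,
                           gamma=rl_config.gamma, reward_fn=reward_fn)
            for _ in range(rl_config.episodes_per_epoch)
        ]
        loss = _episode_loss_graph(model, traces, cond,
                                   baseline=baseline if rl_config.use_baseline else 0.0)
        if loss.requires_grad:
            opt.zero_grad()
            loss.backward()
            opt.step()
        mean_reward = float(np.mean([tr.terminal_reward.total for tr in traces]))
        if rl_config.use_baseline:
            baseline = 0.9 * baseline + 0.1 * mean_reward
        curve.loss.append(float(loss.data))
        curve.reward.append(mean_reward)
        if trace_callback is not None:
            trace_callback(epoch, traces)
    return model, curve
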