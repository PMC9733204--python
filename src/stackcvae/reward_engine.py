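"""Reward shaping for molecule generation.

Three components are summed into the scalar episode reward:

* ``reward1`` — synthesizability: 1 if RAscore = 0, else ``5*RAscore + 1``.
* ``reward2`` — on-target affinity: ``(affA - 4)^2 + 1`` if ``affA > 5``
  (strictly), else 1, where ``affA`` is the mean predicted binding affinity
  over the desired-target panel (group A).
* ``reward3`` — off-target avoidance: 6 if ``affD < 5.5``, else 1, where
  ``affD`` is the mean affinity over the undesired panel (group D).

Affinity and synthesizability predictors are pluggable callables; the
packaged mock oracles are deterministic, structure-dependent functions so
the whole reinforcement-learning loop is testable offline.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Sequence, Tuple

from rdkit import Chem

from .chem_io import is_valid_smiles

AffinityOracle = Callable[[str, str], float]  # (smiles, protein id) -> affinity
SynthOracle = Callable[[str], float]  # smiles -> RAscore in [0, 1]

MIN_COMPONENT = 1.0
MIN_TOTAL = 3.0

__all__ = [
    "TargetPanel",
    "RewardComponents",
    "mean_affinity",
    "reward_synth",
    "reward_on_target",
    "reward_off_target",
    "total_reward",
    "make_mock_oracles",
    "ORACLE_REGISTRY",
    "register_oracle_factory",
]


@dataclass(frozen=True)
class TargetPanel:
    """Protein panels: group A should bind the molecule, group D should not."""

    group_a: Tuple[str, ...]
    group_d: Tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "group_a", tuple(self.group_a))
        object.__setattr__(self, "group_d", tuple(self.group_d))
        if not self.group_a:
            raise ValueError("group_a must be non-empty")
        if set(self.group_a) & set(self.group_d):
            raise ValueError("group_a and group_d must be disjoint")


@dataclass(frozen=True)
class RewardComponents:
    aff_a: float
    aff_d: float
    rascore: float
    reward1: float
    reward2: float
    reward3: float
    valid: bool = True

    @property
    def total(self) -> float:
        return self.reward1 + self.reward2 + self.reward3


def mean_affinity(smiles: str, proteins: Sequence[str], oracle: AffinityOracle) -> float:
    if not proteins:
        raise ValueError("protein panel is empty")
    return sum(oracle(smiles, p) for p in proteins) / len(proteins)


def reward_synth(rascore: float) -> float:
    """Synthesizability reward: 1 at RAscore 0, otherwise 5*RAscore + 1."""
    if not 0.0 <= rascore <= 1.0:
        raise ValueError(f"RAscore must be in [0, 1], got {rascore}")
    return 1.0 if rascore == 0.0 else rascore * 5.0 + 1.0


def reward_on_target(aff_a: float, threshold: float = 5.0, offset: float = 4.0) -> float:
    """On-target reward: (affA - 4)^2 + 1 above the (strict) threshold, else 1."""
    return (aff_a - offset) ** 2 + 1.0 if aff_a > threshold else 1.0


def reward_off_target(aff_d: float, threshold: float = 5.5) -> float:
    """Off-target reward: 6 when the undesired-panel affinity stays below 5.5."""
    return 6.0 if aff_d < threshold else 1.0


def total_reward(smiles: str, panel: TargetPanel, aff_oracle: AffinityOracle,
                 synth_oracle: SynthOracle, on_threshold: float = 5.0,
                 off_threshold: float = 5.5) -> RewardComponents:
    """All reward components for one generated SMILES.

    Unparseable strings receive every component at its minimum (total 3),
    keeping the policy-gradient loss finite while still penalizing
    invalidity against any valid molecule that clears a threshold.
    """
    if not is_valid_smiles(smiles):
        return RewardComponents(
            aff_a=math.nan, aff_d=math.nan, rascore=0.0,
            reward1=MIN_COMPONENT, reward2=MIN_COMPONENT, reward3=MIN_COMPONENT,
            valid=False,
        )
    try:
        aff_a = mean_affinity(smiles, panel.group_a, aff_oracle)
        aff_d = mean_affinity(smiles, panel.group_d, aff_oracle) if panel.group_d else -math.inf
    except Exception as e:
        raise RuntimeError(f"affinity oracle failed on {smiles!r}: {e}") from e
    try:
        rascore = synth_oracle(smiles)
    except Exception as e:
        raise RuntimeError(f"synthesizability oracle failed on {smiles!r}: {e}") from e
    return RewardComponents(
        aff_a=aff_a,
        aff_d=aff_d,
        rascore=rascore,
        reward1=reward_synth(rascore),
        reward2=reward_on_target(aff_a, threshold=on_threshold),
        reward3=reward_off_target(aff_d, threshold=off_threshold),
    )


# -- mock oracles ------------------------------------------------------------

def _atom_counts(smiles: str) -> Tuple[int, int]:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    heavy = mol.GetNumHeavyAtoms()
    nitrogens = sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "N")
    return nitrogens, heavy


def make_mock_oracles(seed: int = 0) -> Tuple[AffinityOracle, SynthOracle]:
    """Deterministic structure-dependent stand-ins for real predictors.

    Affinity grows with the nitrogen fraction of the molecule (plus a small
    per-protein offset derived from a seeded hash), and the mock RAscore is
    a logistic function of heavy-atom count favouring small molecules — so
    reinforcement learning has a smooth, interpretable signal to climb.
    """

    def protein_offset(protein: str) -> float:
        h = zlib.crc32(f"{seed}:{protein}".encode()) / 0xFFFFFFFF
        return (h - 0.5) * 1.0  # in [-0.5, 0.5]

    def affinity(smiles: str, protein: str) -> float:
        nitrogens, heavy = _atom_counts(smiles)
        frac = nitrogens / heavy if heavy else 0.0
        return 3.0 + 4.0 * frac + protein_offset(protein)

    def rascore(smiles: str) -> float:
        _, heavy = _atom_counts(smiles)
        return 1.0 / (1.0 + math.exp((heavy - 20.0) / 4.0))

    return affinity, rascore


ORACLE_REGISTRY: Dict[str, Callable[[int], Tuple[AffinityOracle, SynthOracle]]] = {
    "mock": make_mock_oracles,
}


def register_oracle_factory(name: str,
                            factory: Callable[[int], Tuple[AffinityOracle, SynthOracle]]) -> None:
    """Register a named oracle factory (e.g. an adapter for a real predictor)."""
    ORACLE_REGISTRY[name] = factory
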