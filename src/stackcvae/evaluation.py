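"""Evaluation of generated molecule sets.

Covers the standard generation metrics (percent valid, percent valid and
unique, percent valid, unique and novel relative to the training set),
property-window counting against a reference drug, and the composite
similarity score used to rank candidates:

    score = 1 / (0.3 * (mw + logP + TPSA)/3
                 + 0.7 * (bindA + 1 - bindD + 1 - RAscore)/3)

where mw/logP/TPSA are 0-1 min-max scaled absolute differences from the
reference and bindA/bindD are 0-1 scaled mean affinities over the on- and
off-target panels.  The formula is applied literally as published,
including the sign of the bindA term; ``corrected_bind_a=True`` switches
that term to ``1 - bindA`` for users who want higher on-target affinity to
raise the score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .chem_io import canonical_smiles, compute_conditions, is_valid_smiles
from .reward_engine import AffinityOracle, SynthOracle, TargetPanel, mean_affinity

SCORE_EPS = 1e-9

__all__ = [
    "GenerationReport",
    "validity_uniqueness_novelty",
    "property_within_window",
    "minmax_scale",
    "score_molecule",
    "rank_top_k",
    "score_molecules",
    "property_window_report",
]


@dataclass(frozen=True)
class GenerationReport:
    n_generated: int
    pct_valid: float
    pct_valid_unique: float
    pct_valid_unique_novel: float


def validity_uniqueness_novelty(generated: Sequence[str], training_set: Iterable[str],
                                canonical: bool = True) -> GenerationReport:
    """Percent valid / valid+unique / valid+unique+novel of a generated set.

    With ``canonical=True`` (default) uniqueness and novelty compare
    canonical SMILES, i.e. structural identity; otherwise raw strings.
    """
    if not generated:
        raise ValueError("empty generation set")
    n = len(generated)
    norm = canonical_smiles if canonical else (lambda s: s if is_valid_smiles(s) else None)
    train: Set[str] = set()
    for s in training_set:
        c = norm(s)
        train.add(c if c is not None else s)
    valid_forms: List[str] = []
    for s in generated:
        c = norm(s)
        if c is not None:
            valid_forms.append(c)
    unique = set(valid_forms)
    novel = unique - train
    return GenerationReport(
        n_generated=n,
        pct_valid=100.0 * len(valid_forms) / n,
        pct_valid_unique=100.0 * len(unique) / n,
        pct_valid_unique_novel=100.0 * len(novel) / n,
    )


def property_within_window(value: float, reference: float, tol: float = 0.10) -> bool:
    """True when |value - reference| <= tol * |reference| (inclusive)."""
    if reference == 0:
        raise ValueError("reference must be nonzero for a relative window")
    return abs(value - reference) <= tol * abs(reference)


def minmax_scale(values: Sequence[float]) -> np.ndarray:
    """(v - min)/(max - min) over the batch; a constant batch scales to all zeros."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.size < 2:
        raise ValueError("need at least 2 values to min-max scale")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def score_molecule(mw: float, logp: float, tpsa: float, bind_a: float, bind_d: float,
                   rascore: float, eps: float = SCORE_EPS,
                   corrected_bind_a: bool = False) -> float:
    """Composite similarity score from 0-1 scaled inputs (see module docstring)."""
    for name, v in (("mw", mw), ("logp", logp), ("tpsa", tpsa),
                    ("bind_a", bind_a), ("bind_d", bind_d), ("rascore", rascore)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be 0-1 scaled, got {v}")
    bind_term = (1.0 - bind_a) if corrected_bind_a else bind_a
    denom = 0.3 * (mw + logp + tpsa) / 3.0 + 0.7 * (bind_term + 1.0 - bind_d + 1.0 - rascore) / 3.0
    return 1.0 / max(denom, eps)


def rank_top_k(scores: Sequence[Tuple[str, float]], k: int = 100) -> List[Tuple[str, float]]:
    """Top-k by descending score; ties broken lexicographically by SMILES."""
    if k > len(scores):
        raise ValueError(f"k={k} exceeds number of scored molecules ({len(scores)})")
    return sorted(scores, key=lambda t: (-t[1], t[0]))[:k]


def score_molecules(smiles_list: Sequence[str], reference_smiles: str, panel: TargetPanel,
                    aff_oracle: AffinityOracle, synth_oracle: SynthOracle,
                    corrected_bind_a: bool = False) -> pd.DataFrame:
    """Score a batch of valid SMILES against a reference drug.

    Computes per-molecule |descriptor - reference| differences and panel
    affinities, min-max scales each column over the batch, applies the
    composite score, and returns a DataFrame sorted best-first.
    """
    ref = compute_conditions(reference_smiles)
    rows = []
    for s in smiles_list:
        if not is_valid_smiles(s):
            continue
        c = compute_conditions(s)
        rows.append({
            "smiles": s,
            "d_mw": abs(c.mol_weight - ref.mol_weight),
            "d_logp": abs(c.logp - ref.logp),
            "d_tpsa": abs(c.tpsa - ref.tpsa),
            "aff_a": mean_affinity(s, panel.group_a, aff_oracle),
            "aff_d": mean_affinity(s, panel.group_d, aff_oracle) if panel.group_d else 0.0,
            "rascore": synth_oracle(s),
        })
    if len(rows) < 2:
        raise ValueError("need at least 2 valid molecules to scale and score")
    df = pd.DataFrame(rows)
    scaled = {
        "mw": minmax_scale(df["d_mw"]), "logp": minmax_scale(df["d_logp"]),
        "tpsa": minmax_scale(df["d_tpsa"]),
        "bind_a": minmax_scale(df["aff_a"]), "bind_d": minmax_scale(df["aff_d"]),
    }
    df["score"] = [
        score_molecule(scaled["mw"][i], scaled["logp"][i], scaled["tpsa"][i],
                       scaled["bind_a"][i], scaled["bind_d"][i],
                       float(df["rascore"][i]), corrected_bind_a=corrected_bind_a)
        for i in range(len(df))
    ]
    return df.sort_values(["score", "smiles"], ascending=[False, True]).reset_index(drop=True)


def property_window_report(smiles_list: Sequence[str], reference_smiles: str,
                           panel: Optional[TargetPanel] = None,
                           aff_oracle: Optional[AffinityOracle] = None,
                           synth_oracle: Optional[SynthOracle] = None,
                           tol: float = 0.10) -> pd.DataFrame:
    """Count molecules whose properties fall within a relative window of the
    reference drug's (descriptors always; affinities/RAscore when oracles
    are supplied)."""
    ref = compute_conditions(reference_smiles)
    targets: Dict[str, float] = {"mol_weight": ref.mol_weight, "logp": ref.logp,
                                 "tpsa": ref.tpsa}
    if panel is not None and aff_oracle is not None:
        targets["aff_a"] = mean_affinity(reference_smiles, panel.group_a, aff_oracle)
        if panel.group_d:
            targets["aff_d"] = mean_affinity(reference_smiles, panel.group_d, aff_oracle)
    if synth_oracle is not None:
        targets["rascore"] = synth_oracle(reference_smiles)
    valid = [s for s in smiles_list if is_valid_smiles(s)]
    counts = {k: 0 for k in targets}
    for s in valid:
        c = compute_conditions(s)
        values = {"mol_weight": c.mol_weight, "logp": c.logp, "tpsa": c.tpsa}
        if "aff_a" in targets:
            values["aff_a"] = mean_affinity(s, panel.group_a, aff_oracle)
        if "aff_d" in targets:
            values["aff_d"] = mean_affinity(s, panel.group_d, aff_oracle)
        if "rascore" in targets:
            values["rascore"] = synth_oracle(s)
        for k, ref_v in targets.items():
            if ref_v != 0 and property_within_window(values[k], ref_v, tol):
                counts[k] += 1
    n = len(valid)
    return pd.DataFrame({
        "property": list(targets),
        "reference": [targets[k] for k in targets],
        "count": [counts[k] for k in targets],
        "pct": [100.0 * counts[k] / n if n else 0.0 for k in targets],
    })
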