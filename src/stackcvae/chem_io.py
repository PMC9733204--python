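"""SMILES corpus handling: tokenization, vocabulary, descriptors, filtering.

Tokenization is character-level with two exceptions: the two-character
halogens ``Cl`` and ``Br`` and bracket atoms such as ``[nH]`` or ``[O-]``
are kept as single tokens, so that the generative model never has to learn
to pair an orphan ``l`` or a dangling ``[``.

Descriptors (molecular weight in Da, Crippen LogP, TPSA in Å²) come from
RDKit and form the 3-component condition vector of the conditional model.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors

RDLogger.DisableLog("rdApp.*")

START, END, PAD = "<", ">", "_"

__all__ = [
    "START",
    "END",
    "PAD",
    "SmilesRecord",
    "ConditionVector",
    "Vocabulary",
    "tokenize_smiles",
    "tokenize",
    "detokenize",
    "build_vocabulary",
    "compute_conditions",
    "is_valid_smiles",
    "canonical_smiles",
    "filter_corpus",
    "generate_toy_corpus",
    "read_corpus",
    "write_corpus",
]


@dataclass(frozen=True)
class SmilesRecord:
    id: str
    smiles: str

    def __post_init__(self):
        if not self.smiles or any(c.isspace() for c in self.smiles):
            raise ValueError(f"invalid SMILES string {self.smiles!r} (empty or whitespace)")


@dataclass(frozen=True)
class ConditionVector:
    """Molecular weight (Da), LogP (unitless) and TPSA (Å²) of one molecule."""

    mol_weight: float
    logp: float
    tpsa: float

    def __post_init__(self):
        vals = (self.mol_weight, self.logp, self.tpsa)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("condition values must be finite")
        if self.mol_weight <= 0 or self.tpsa < 0:
            raise ValueError("require mol_weight > 0 and tpsa >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.mol_weight, self.logp, self.tpsa], dtype=np.float64)


class Vocabulary:
    """Bijection between SMILES tokens and integer indices.

    Index 0 is the padding token, followed by the start/end delimiters and
    the remaining tokens in sorted order, so two corpora with the same token
    alphabet always yield identical vocabularies.
    """

    def __init__(self, tokens: Iterable[str]):
        extras = sorted(set(tokens) - {PAD, START, END})
        self.tokens: List[str] = [PAD, START, END] + extras
        self.index: Dict[str, int] = {t: i for i, t in enumerate(self.tokens)}

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def encode(self, tokens: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self.index[t] for t in tokens], dtype=np.int64)
        except KeyError as e:
            raise KeyError(f"token {e.args[0]!r} not in vocabulary") from None

    def decode(self, ids: Sequence[int]) -> List[str]:
        return [self.tokens[i] for i in ids]

    @property
    def pad_id(self) -> int:
        return self.index[PAD]

    @property
    def start_id(self) -> int:
        return self.index[START]

    @property
    def end_id(self) -> int:
        return self.index[END]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.tokens))

    @classmethod
    def from_json(cls, path) -> "Vocabulary":
        return cls(json.loads(Path(path).read_text()))


def tokenize_smiles(smiles: str) -> List[str]:
    """Split a raw SMILES string into tokens (no delimiters added)."""
    if not smiles:
        raise ValueError("cannot tokenize an empty SMILES string")
    tokens: List[str] = []
    i = 0
    while i < len(smiles):
        c = smiles[i]
        if c == "[":
            j = smiles.find("]", i)
            if j < 0:
                raise ValueError(f"unclosed bracket atom at position {i} in {smiles!r}")
            tokens.append(smiles[i : j + 1])
            i = j + 1
        elif smiles[i : i + 2] in ("Cl", "Br"):
            tokens.append(smiles[i : i + 2])
            i += 2
        else:
            tokens.append(c)
            i += 1
    return tokens


def tokenize(smiles: str, vocab: Vocabulary) -> List[str]:
    """Tokenize and wrap with start/end delimiters, validating membership."""
    tokens = tokenize_smiles(smiles)
    for pos, t in enumerate(tokens):
        if t not in vocab:
            raise ValueError(f"token {t!r} at position {pos} not in vocabulary")
    return [START] + tokens + [END]


def detokenize(tokens: Sequence[str]) -> str:
    """Inverse of :func:`tokenize`: strip delimiters and concatenate."""
    if len(tokens) < 2 or tokens[0] != START or tokens[-1] != END:
        raise ValueError("token sequence must start with '<' and end with '>'")
    return "".join(tokens[1:-1])


def build_vocabulary(corpus: Sequence[SmilesRecord]) -> Vocabulary:
    if not corpus:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    tokens = set()
    for rec in corpus:
        tokens.update(tokenize_smiles(rec.smiles))
    return Vocabulary(tokens)


def _mol(smiles: str):
    return Chem.MolFromSmiles(smiles) if smiles else None


def is_valid_smiles(smiles: str) -> bool:
    return _mol(smiles) is not None


def canonical_smiles(smiles: str) -> str | None:
    mol = _mol(smiles)
    return Chem.MolToSmiles(mol) if mol is not None else None


def compute_conditions(smiles: str) -> ConditionVector:
    """Molecular weight, Crippen LogP and TPSA of a valid SMILES."""
    mol = _mol(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return ConditionVector(
        mol_weight=Descriptors.MolWt(mol),
        logp=Crippen.MolLogP(mol),
        tpsa=Descriptors.TPSA(mol),
    )


def filter_corpus(records: Sequence[SmilesRecord], max_len: int = 100,
                  mw_min: float = 150.0, mw_max: float = 500.0) -> List[SmilesRecord]:
    """Keep valid molecules with string length < max_len and MW in [mw_min, mw_max]."""
    kept = []
    for rec in records:
        if len(rec.smiles) >= max_len:
            continue
        mol = _mol(rec.smiles)
        if mol is None:
            continue
        if mw_min <= Descriptors.MolWt(mol) <= mw_max:
            kept.append(rec)
    return kept


# -- toy corpus --------------------------------------------------------------

# Fragment grammar: every fragment starts and ends on an atom that accepts one
# more single bond, so any concatenation of middle fragments plus one optional
# terminal parses as a valid molecule.
_MIDDLE_FRAGMENTS = [
    "C", "CC", "CCC", "CO", "CN", "C(C)C", "C(=O)N", "C(=O)O", "CNC",
    "c1ccccc1", "c1ccncc1", "C1CCCCC1", "C1CCNCC1", "c1ccc(F)cc1",
]
_TERMINAL_FRAGMENTS = ["C", "N", "O", "Cl", "Br", "F", "C(C)=O"]


def generate_toy_corpus(n: int, seed: int, min_units: int = 3, max_units: int = 7) -> List[SmilesRecord]:
    """Seeded random assembly of short valid SMILES from a fragment grammar.

    Every output parses in RDKit by construction; unit counts are chosen so
    most molecules fall inside the 150–500 Da training window.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        units = rng.integers(min_units, max_units + 1)
        parts = [str(rng.choice(_MIDDLE_FRAGMENTS)) for _ in range(units)]
        if rng.random() < 0.5:
            parts.append(str(rng.choice(_TERMINAL_FRAGMENTS)))
        records.append(SmilesRecord(id=f"toy{i:05d}", smiles="".join(parts)))
    return records


# -- corpus file formats ------------------------------------------------------

def read_corpus(path) -> List[SmilesRecord]:
    """Read .smi (one SMILES per line) or .csv with columns id,smiles."""
    path = Path(path)
    records: List[SmilesRecord] = []
    if path.suffix.lower() == ".csv":
        with path.open(newline="") as fh:
            for row in csv.DictReader(fh):
                records.append(SmilesRecord(id=row["id"], smiles=row["smiles"].strip()))
    else:
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if line:
                records.append(SmilesRecord(id=f"mol{i:06d}", smiles=line.split()[0]))
    return records


def write_corpus(records: Sequence[SmilesRecord], path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "smiles"])
            for rec in records:
                writer.writerow([rec.id, rec.smiles])
    else:
        path.write_text("".join(rec.smiles + "\n" for rec in records))
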