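"""SMILES handling: tokenization, vocabularies, fingerprints and properties.

SMILES strings are the working representation throughout the package: the
generator emits them token by token, the permeability model consumes Morgan
(ECFP-style) fingerprints derived from them, and every diversity statistic is
an average Tanimoto distance over fingerprint sets.

Tokenization rule: the two-character organic-subset halogens ``Cl`` and ``Br``
and any bracketed atom expression ``[...]`` are single tokens; every other
character is its own token.  This is the minimal scheme for which
detokenize(tokenize(s)) reproduces s exactly.
"""

from __future__ import annotations

import csv
import logging
import os
import re
import sys
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, QED, RDConfig, rdFingerprintGenerator

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib, shipped with the rdkit package)

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

START = "^"
END = "$"
PAD = " "

_TOKEN_RE = re.compile(r"(\[[^\]]*\]|Cl|Br|.)")


class UnknownTokenError(KeyError):
    """A token in a SMILES string is absent from the vocabulary."""


class InvalidMoleculeError(ValueError):
    """A SMILES string failed RDKit sanitization."""


def smiles_tokens(s: str) -> list[str]:
    """Split a SMILES string into tokens (no vocabulary lookup)."""
    if not s:
        raise ValueError("empty SMILES string")
    return _TOKEN_RE.findall(s)


@dataclass(frozen=True)
class Vocabulary:
    """Ordered token inventory with a token <-> index bijection.

    PAD is always index 0 so padded id arrays are zero-filled; START and END
    follow.  Built from a corpus rather than hard-coded: the token set is
    data-driven and recorded in run manifests.
    """

    tokens: tuple[str, ...]
    index_of: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("vocabulary tokens must be unique")
        for reserved in (PAD, START, END):
            if reserved not in self.tokens:
                raise ValueError(f"reserved token {reserved!r} missing")
        if self.tokens[0] != PAD:
            raise ValueError("PAD must sit at index 0")
        object.__setattr__(
            self, "index_of", {t: i for i, t in enumerate(self.tokens)}
        )

    @classmethod
    def from_corpus(cls, corpus: Iterable[str]) -> "Vocabulary":
        seen: dict[str, None] = {}
        for s in corpus:
            for tok in smiles_tokens(s):
                seen.setdefault(tok, None)
        return cls((PAD, START, END) + tuple(sorted(seen)))

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad_id(self) -> int:
        return 0

    @property
    def start_id(self) -> int:
        return self.index_of[START]

    @property
    def end_id(self) -> int:
        return self.index_of[END]

    def encode(self, tokens: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self.index_of[t] for t in tokens], dtype=np.int64)
        except KeyError as exc:
            raise UnknownTokenError(str(exc)) from exc

    def decode(self, ids: Sequence[int]) -> list[str]:
        return [self.tokens[i] for i in ids]


def tokenize(s: str, vocab: Vocabulary | None = None) -> list[str]:
    """Tokenize a SMILES string, validating every token against ``vocab``.

    Raises :class:`UnknownTokenError` naming the offending position when a
    token is not in the vocabulary.
    """
    toks = smiles_tokens(s)
    if vocab is not None:
        pos = 0
        for t in toks:
            if t not in vocab.index_of:
                raise UnknownTokenError(
                    f"token {t!r} at position {pos} of {s!r} not in vocabulary"
                )
            pos += len(t)
    return toks


def detokenize(tokens: Sequence[str]) -> str:
    """Concatenate tokens back into a SMILES string, stripping markers."""
    return "".join(t for t in tokens if t not in (START, END, PAD))


def is_valid(s: str) -> bool:
    """True iff RDKit sanitization accepts the SMILES string."""
    if not s:
        return False
    return Chem.MolFromSmiles(s) is not None


def canonical(s: str) -> str:
    """Canonical SMILES (stereo preserved); raises on invalid input."""
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise InvalidMoleculeError(f"cannot sanitize SMILES {s!r}")
    return Chem.MolToSmiles(mol)


def fingerprint(s: str, n_bits: int = 2048, radius: int = 2) -> np.ndarray:
    """Morgan/ECFP-style circular fingerprint as a uint8 0/1 vector."""
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise InvalidMoleculeError(f"cannot sanitize SMILES {s!r}")
    gen = _morgan_generator(radius, n_bits)
    return gen.GetFingerprintAsNumPy(mol).astype(np.uint8)


_GEN_CACHE: dict[tuple[int, int], object] = {}


def _morgan_generator(radius: int, n_bits: int):
    key = (radius, n_bits)
    if key not in _GEN_CACHE:
        _GEN_CACHE[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits
        )
    return _GEN_CACHE[key]


def fingerprints(smiles: Iterable[str], n_bits: int = 2048, radius: int = 2) -> np.ndarray:
    """Stack fingerprints for many SMILES into an (n, n_bits) matrix."""
    return np.array([fingerprint(s, n_bits, radius) for s in smiles], dtype=np.uint8)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| of two bit vectors.

    Two all-zero fingerprints compare as identical (similarity 1), keeping
    the distance of an object to itself at 0.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    inter = int(np.count_nonzero(np.logical_and(a, b)))
    union = int(np.count_nonzero(np.logical_or(a, b)))
    if union == 0:
        return 1.0
    return inter / union


def set_diversity(a: np.ndarray | Sequence, b: np.ndarray | Sequence) -> float:
    """Mean pairwise Tanimoto distance between two fingerprint sets.

    delta(A, B) = (1/|A||B|) * sum_a sum_b (1 - Ts(a, b)); internal diversity
    of a set is ``set_diversity(A, A)``.  Vectorized: bit intersections via a
    single integer matmul.
    """
    A = np.atleast_2d(np.asarray(a, dtype=np.float64))
    B = np.atleast_2d(np.asarray(b, dtype=np.float64))
    if A.size == 0 or B.size == 0:
        raise ValueError("set_diversity requires non-empty fingerprint sets")
    if A.shape[1] != B.shape[1]:
        raise ValueError("fingerprint length mismatch")
    inter = A @ B.T
    pa = A.sum(axis=1)[:, None]
    pb = B.sum(axis=1)[None, :]
    union = pa + pb - inter
    with np.errstate(invalid="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
    return float(np.mean(1.0 - sim))


def compute_properties(s: str) -> dict[str, float]:
    """logP, molecular weight (g/mol), QED and SAS for a valid SMILES."""
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise InvalidMoleculeError(f"cannot sanitize SMILES {s!r}")
    return {
        "logP": float(Crippen.MolLogP(mol)),
        "MW": float(Descriptors.MolWt(mol)),
        "QED": float(QED.qed(mol)),
        "SAS": float(sascorer.calculateScore(mol)),
    }


@dataclass
class MoleculeRecord:
    """A molecule plus its computed / predicted properties."""

    smiles: str
    properties: dict[str, float] = field(default_factory=dict)


def read_smi(path: str | os.PathLike) -> list[str]:
    """Read a .smi file (one SMILES per line, no header); blank lines skipped."""
    out: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            s = line.strip()
            if s:
                out.append(s)
    logger.info("read %d SMILES from %s", len(out), path)
    return out


def write_smi(path: str | os.PathLike, smiles: Iterable[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in smiles:
            fh.write(s + "\n")


def read_labeled_csv(path: str | os.PathLike, label_kind: str) -> tuple[list[str], np.ndarray]:
    """Read ``smiles,pIC50`` (label_kind='pic50') or ``smiles,label`` CSV.

    Binary labels must be 0/1 (1 = BBB permeable).  Malformed rows raise with
    their line number.
    """
    if label_kind not in ("pic50", "binary"):
        raise ValueError("label_kind must be 'pic50' or 'binary'")
    smiles: list[str] = []
    labels: list[float] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or len(header) < 2 or header[0].strip().lower() != "smiles":
            raise ValueError(f"{path}: expected header 'smiles,<label>'")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            try:
                val = float(row[1])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric label {row[1]!r}"
                ) from exc
            if label_kind == "binary" and val not in (0.0, 1.0):
                raise ValueError(f"{path}:{lineno}: binary label must be 0 or 1")
            smiles.append(row[0].strip())
            labels.append(val)
    logger.info("read %d labeled molecules from %s", len(smiles), path)
    dtype = np.int64 if label_kind == "binary" else np.float64
    return smiles, np.asarray(labels, dtype=dtype)


def write_labeled_csv(path: str | os.PathLike, smiles: Sequence[str],
                      labels: Sequence[float], label_name: str) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["smiles", label_name])
        for s, y in zip(smiles, labels):
            writer.writerow([s, y])
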