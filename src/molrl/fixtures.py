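"""Self-contained synthetic inputs: SMILES corpora, property oracles, datasets.

Everything the training and RL machinery consumes can be produced offline by
this module: a rule-enumerated corpus of small valid molecules, two pure
deterministic property oracles that stand in for trained QSAR models in tests,
and an imbalanced labeled fingerprint dataset built from a seeded bit-mask
rule.

The two oracles are deliberately competing at toy scale: aromatic rings raise
the pseudo-affinity (aromatic-fraction rule) while the extra ring mass raises
molecular weight and therefore lowers the pseudo-permeability (logistic in
MW), mirroring the tension between potency and brain availability that the
full framework trades off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

from .chemio import fingerprints, is_valid, smiles_tokens

__all__ = [
    "FixtureSpec", "make_corpus", "corpus_capacity", "mock_affinity_oracle",
    "mock_bbb_oracle", "mock_bbb_label", "make_imbalanced_dataset",
]

# Attachable substituent fragments (written so "core(X)" stays parseable).
_SUBSTITUENTS = [
    "C", "CC", "CCC", "CCCC", "C(C)C", "C(C)(C)C", "O", "OC", "OCC", "N",
    "NC", "N(C)C", "F", "Cl", "Br", "C#N", "C(=O)C", "C(=O)OC", "C(=O)N",
    "CO", "CCO", "OC(=O)C", "S", "SC", "C(F)(F)F",
]

# Mono-substituted templates: aromatic cores, N-heterocycles, saturated rings.
_MONO_TEMPLATES = [
    "c1ccc({A})cc1", "c1ccnc({A})c1", "c1cc({A})cnc1", "c1cc({A})[nH]c1",
    "c1cc({A})n(C)c1", "c1cc({A})oc1", "c1cc({A})sc1", "c1cnc({A})[nH]1",
    "C1CCC({A})CC1", "C1CCC({A})C1",
]

# Di-substituted aromatic templates (three benzene patterns + two heterocycles).
_DI_TEMPLATES = [
    "c1cc({A})cc({B})c1", "c1ccc({A})c({B})c1", "c1cc({A})ccc1{B}",
    "c1cc({A})nc({B})c1", "c1c({A})cc({B})s1",
]

# 1,3,5-trisubstituted benzenes: the combinatorial bulk of the pool.
_TRI_TEMPLATE = "c1c({A})cc({B})cc1{C}"

_CHAINS = ["C", "CC", "CCC", "CCCC", "CCCCC", "CCCCCC", "CCCCCCC", "CCCCCCCC"]

_BRANCH_TEMPLATES = ["CC({A})C", "CCC({A})CC", "CCCC({A})C"]

_PLAIN = [
    "c1ccccc1", "c1ccncc1", "c1cc[nH]c1", "c1ccoc1", "c1ccsc1", "C1CCCCC1",
    "C1CCCC1", "CC(C)C", "CC(C)(C)C", "CCOCC", "CCNCC", "CC(=O)OCC",
]


@dataclass
class FixtureSpec:
    """Corpus request: size, seed and a heavy-atom ceiling."""

    n_molecules: int
    seed: int = 0
    max_heavy_atoms: int = 24


def _enumerate_pool(max_heavy_atoms: int) -> list[str]:
    """Deterministic, order-stable enumeration of the full template space."""
    raw: list[str] = list(_PLAIN)
    for chain in _CHAINS:
        for sub in _SUBSTITUENTS:
            raw.append(chain + sub)
        raw.append(chain)
    for tpl in _MONO_TEMPLATES:
        for sub in _SUBSTITUENTS:
            raw.append(tpl.format(A=sub))
    for tpl in _BRANCH_TEMPLATES:
        for sub in _SUBSTITUENTS:
            raw.append(tpl.format(A=sub))
    for tpl in _DI_TEMPLATES:
        for a in _SUBSTITUENTS:
            for b in _SUBSTITUENTS:
                raw.append(tpl.format(A=a, B=b))
    for a in _SUBSTITUENTS:
        for b in _SUBSTITUENTS:
            for c in _SUBSTITUENTS:
                raw.append(_TRI_TEMPLATE.format(A=a, B=b, C=c))
    pool: list[str] = []
    seen: set[str] = set()
    for s in raw:
        mol = Chem.MolFromSmiles(s)
        if mol is None or mol.GetNumHeavyAtoms() > max_heavy_atoms:
            continue
        can = Chem.MolToSmiles(mol)
        if can in seen:
            continue
        seen.add(can)
        pool.append(s)  # keep the written form; uniqueness is canonical
    return pool


_POOL_CACHE: dict[int, list[str]] = {}


def _pool(max_heavy_atoms: int) -> list[str]:
    if max_heavy_atoms not in _POOL_CACHE:
        _POOL_CACHE[max_heavy_atoms] = _enumerate_pool(max_heavy_atoms)
    return _POOL_CACHE[max_heavy_atoms]


def corpus_capacity(max_heavy_atoms: int = 24) -> int:
    """Number of unique valid molecules the template space can produce."""
    return len(_pool(max_heavy_atoms))


def make_corpus(spec: FixtureSpec) -> list[str]:
    """``spec.n_molecules`` unique valid SMILES, reproducible under the seed."""
    if spec.n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    pool = _pool(spec.max_heavy_atoms)
    if spec.n_molecules > len(pool):
        raise ValueError(
            f"requested {spec.n_molecules} molecules but the template space "
            f"holds only {len(pool)}")
    rng = np.random.default_rng(spec.seed)
    idx = rng.permutation(len(pool))[:spec.n_molecules]
    return [pool[i] for i in idx]


def mock_affinity_oracle(s: str) -> float:
    """Pseudo-pIC50 = 3 + 8 * (aromatic heavy atoms / heavy atoms), in [3, 11]."""
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise ValueError(f"invalid SMILES {s!r}")
    heavy = mol.GetNumHeavyAtoms()
    if heavy == 0:
        raise ValueError(f"no heavy atoms in {s!r}")
    aromatic = sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())
    return float(np.clip(3.0 + 8.0 * aromatic / heavy, 3.0, 11.0))


def mock_bbb_oracle(s: str) -> float:
    """Pseudo-permeability = logistic in molecular weight, midpoint 350 g/mol."""
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise ValueError(f"invalid SMILES {s!r}")
    mw = Descriptors.MolWt(mol)
    return float(1.0 / (1.0 + np.exp((mw - 350.0) / 50.0)))


def mock_bbb_label(s: str, mw_cutoff: float = 200.0) -> int:
    """Binary toy permeability label: 1 (BBB+) iff MW < ``mw_cutoff``.

    The fixture templates produce small molecules, so the label cut sits at
    200 g/mol (not the oracle's 350 midpoint) to split the corpus into a
    permeable majority and a heavier non-permeable minority, mirroring the
    imbalance of real BBB datasets.
    """
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise ValueError(f"invalid SMILES {s!r}")
    return int(Descriptors.MolWt(mol) < mw_cutoff)


def make_imbalanced_dataset(
    n: int, minority_fraction: float, seed: int = 0, *,
    n_bits: int = 2048, radius: int = 2, mask_size: int = 64,
    overlap_threshold: int = 4, max_heavy_atoms: int = 24,
):
    """Labeled fingerprint dataset with a seeded bit-mask labelling rule.

    Molecules come from the fixture corpus pool; the label is 1 (minority)
    iff the fingerprint shares at least ``overlap_threshold`` bits with a
    fixed ``mask_size``-bit mask drawn (seeded) from the most frequent
    fingerprint bits.  Class counts match the requested fractions within one
    sample.  Returns ``(smiles, X, y, info)``.
    """
    if not 0.0 < minority_fraction < 0.5:
        raise ValueError("minority_fraction must be in (0, 0.5)")
    pool = _pool(max_heavy_atoms)
    X_all = fingerprints(pool, n_bits=n_bits, radius=radius)
    rng = np.random.default_rng(seed)
    bit_counts = X_all.sum(axis=0).astype(np.int64)
    freq_order = np.argsort(-bit_counts, kind="stable")
    n_min = int(round(n * minority_fraction))
    n_maj = n - n_min

    # Slide a window down the bit-frequency ranking until the fixed-threshold
    # rule yields enough candidates in both classes; frequent bits make the
    # rule fire too often, rare bits never.
    window = 4 * mask_size
    mask = minority_idx = majority_idx = None
    for offset in range(0, len(freq_order) - window, mask_size):
        cand = freq_order[offset:offset + window]
        trial = rng.choice(cand, size=mask_size, replace=False)
        overlap = X_all[:, trial].sum(axis=1).astype(np.int64)
        y_trial = (overlap >= overlap_threshold).astype(np.int64)
        pos = np.flatnonzero(y_trial == 1)
        neg = np.flatnonzero(y_trial == 0)
        if len(pos) >= n_min and len(neg) >= n_maj:
            mask, minority_idx, majority_idx = trial, pos, neg
            y_all = y_trial
            break
    if mask is None:
        raise ValueError(
            f"infeasible class counts: no {mask_size}-bit mask window gives "
            f">= {n_min} minority and >= {n_maj} majority candidates")
    chosen = np.concatenate([
        rng.choice(minority_idx, size=n_min, replace=False),
        rng.choice(majority_idx, size=n_maj, replace=False),
    ])
    chosen = rng.permutation(chosen)
    smiles = [pool[i] for i in chosen]
    info = {"mask": np.sort(mask), "overlap_threshold": overlap_threshold,
            "n_minority": n_min, "n_majority": n_maj}
    return smiles, X_all[chosen], y_all[chosen], info


def max_token_length(corpus: list[str]) -> int:
    return max(len(smiles_tokens(s)) for s in corpus)


def _self_check(corpus: list[str]) -> None:  # pragma: no cover - debug helper
    assert all(is_valid(s) for s in corpus)
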