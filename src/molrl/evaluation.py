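"""Batch evaluation of generators: validity, uniqueness, diversity, windows.

Mirrors how generative-chemistry models are customarily characterized: sample
n molecules, report the percentage that parse, the percentage of unique
canonical structures among the valid ones, internal diversity (mean pairwise
Tanimoto distance within the sample), external diversity against a reference
corpus, the share of *desirable* molecules (predicted pIC50 above the cut
AND predicted P(BBB+) > 0.5), and drug-likeness property distributions
(QED, SAS, logP, MW).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .chemio import (MoleculeRecord, canonical, compute_properties,
                     fingerprints, is_valid, set_diversity)
from .generator import PolicyNetwork, sample
from .rl_engine import RLConfig

__all__ = [
    "GeneratorReport", "evaluate_generator", "compare_generators",
    "property_window_fractions",
]

_HIST_PROPS = ("pIC50", "p_bbb", "QED", "SAS", "logP", "MW")


@dataclass
class GeneratorReport:
    """Summary statistics plus the per-molecule log they derive from."""

    n_sampled: int
    pct_valid: float
    pct_unique: float
    internal_diversity: float
    external_diversity: float | None
    pct_desirable: float
    records: list[MoleculeRecord] = field(default_factory=list)
    histograms: dict[str, dict] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_sampled": self.n_sampled,
            "pct_valid": self.pct_valid,
            "pct_unique": self.pct_unique,
            "internal_diversity": self.internal_diversity,
            "external_diversity": self.external_diversity,
            "pct_desirable": self.pct_desirable,
            "records": [
                {"smiles": r.smiles, "properties": r.properties}
                for r in self.records
            ],
            "histograms": self.histograms,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorReport":
        records = [MoleculeRecord(r["smiles"], dict(r["properties"]))
                   for r in d["records"]]
        return cls(d["n_sampled"], d["pct_valid"], d["pct_unique"],
                   d["internal_diversity"], d["external_diversity"],
                   d["pct_desirable"], records, d.get("histograms", {}))


def _histogram(values: np.ndarray, bins: int = 20) -> dict:
    counts, edges = np.histogram(values, bins=bins)
    return {"counts": counts.tolist(), "edges": edges.tolist()}


def evaluate_generator(policy: PolicyNetwork, n: int, affinity, bbb,
                       reference: list[str] | None, cfg: RLConfig,
                       rng: np.random.Generator | None = None,
                       temperature: float | None = None,
                       max_diversity_molecules: int = 1000
                       ) -> GeneratorReport:
    """Sample ``n`` molecules and summarize the batch.

    ``affinity``/``bbb`` are models with ``.predict`` or plain callables.
    Diversity uses at most ``max_diversity_molecules`` valid molecules
    (seeded subsample) to keep the pairwise computation tractable.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = rng or np.random.default_rng(0)
    aff_fn = affinity.predict if hasattr(affinity, "predict") else affinity
    bbb_fn = bbb.predict if hasattr(bbb, "predict") else bbb

    batch = sample(policy, n, temperature=temperature, rng=rng)
    smiles = batch.smiles()
    records: list[MoleculeRecord] = []
    valid_smiles: list[str] = []
    n_desirable = 0
    for s in smiles:
        if not is_valid(s):
            records.append(MoleculeRecord(s, {"valid": 0.0}))
            continue
        props = compute_properties(s)
        props["valid"] = 1.0
        props["pIC50"] = float(aff_fn(s))
        props["p_bbb"] = float(bbb_fn(s))
        desirable = (props["pIC50"] > cfg.desirable_pic50
                     and props["p_bbb"] > 0.5)
        props["desirable"] = float(desirable)
        n_desirable += desirable
        records.append(MoleculeRecord(s, props))
        valid_smiles.append(s)

    n_valid = len(valid_smiles)
    uniques = {canonical(s) for s in valid_smiles}
    if n_valid:
        sub = valid_smiles
        if n_valid > max_diversity_molecules:
            keep = rng.choice(n_valid, size=max_diversity_molecules,
                              replace=False)
            sub = [valid_smiles[i] for i in keep]
        fps = fingerprints(sub, n_bits=cfg.fingerprint_bits,
                           radius=cfg.fingerprint_radius)
        internal = set_diversity(fps, fps) if len(sub) > 0 else 0.0
        external = None
        if reference:
            ref = list(reference)
            if len(ref) > max_diversity_molecules:
                keep = rng.choice(len(ref), size=max_diversity_molecules,
                                  replace=False)
                ref = [ref[i] for i in keep]
            ref_fps = fingerprints(ref, n_bits=cfg.fingerprint_bits,
                                   radius=cfg.fingerprint_radius)
            external = set_diversity(fps, ref_fps)
    else:
        internal, external = 0.0, None

    histograms = {}
    for prop in _HIST_PROPS:
        vals = np.array([r.properties[prop] for r in records
                         if prop in r.properties])
        if len(vals):
            histograms[prop] = _histogram(vals)

    return GeneratorReport(
        n_sampled=n,
        pct_valid=100.0 * n_valid / n,
        pct_unique=100.0 * len(uniques) / n_valid if n_valid else 0.0,
        internal_diversity=float(internal),
        external_diversity=None if external is None else float(external),
        pct_desirable=100.0 * n_desirable / n_valid if n_valid else 0.0,
        records=records, histograms=histograms)


def compare_generators(unbiased_report: GeneratorReport,
                       biased_report: GeneratorReport) -> dict:
    """Property-shift summary between an unbiased and a biased generator."""
    if unbiased_report.n_sampled != biased_report.n_sampled:
        warnings.warn("reports built from different sample sizes")

    def prop_values(report, prop):
        return np.array([r.properties[prop] for r in report.records
                         if prop in r.properties])

    shifts: dict[str, dict] = {}
    for prop in _HIST_PROPS:
        a = prop_values(unbiased_report, prop)
        b = prop_values(biased_report, prop)
        if len(a) == 0 or len(b) == 0:
            continue
        shifts[prop] = {
            "mean_unbiased": float(a.mean()),
            "mean_biased": float(b.mean()),
            "mean_shift": float(b.mean() - a.mean()),
        }
    return {
        "per_property": shifts,
        "pct_valid": {"unbiased": unbiased_report.pct_valid,
                      "biased": biased_report.pct_valid},
        "pct_desirable": {
            "unbiased": unbiased_report.pct_desirable,
            "biased": biased_report.pct_desirable,
            "shift": biased_report.pct_desirable
            - unbiased_report.pct_desirable,
        },
        "internal_diversity": {
            "unbiased": unbiased_report.internal_diversity,
            "biased": biased_report.internal_diversity,
        },
    }


def property_window_fractions(records: list[MoleculeRecord],
                              qed_cut: float = 0.5) -> dict[str, float]:
    """Fractions of molecules inside the drug-likeness windows.

    MW < 500 g/mol; logP in the closed interval [1, 4]; QED >= qed_cut;
    SAS <= 6 (a score above 6 marks a molecule as hard to synthesize).
    """
    withprops = [r for r in records if "MW" in r.properties]
    if not withprops:
        raise ValueError("no molecules with computed properties")
    n = len(withprops)
    mw = np.array([r.properties["MW"] for r in withprops])
    logp = np.array([r.properties["logP"] for r in withprops])
    qed = np.array([r.properties["QED"] for r in withprops])
    sas = np.array([r.properties["SAS"] for r in withprops])
    return {
        "MW_lt_500": float(np.mean(mw < 500.0)),
        "logP_1_to_4": float(np.mean((logp >= 1.0) & (logp <= 4.0))),
        f"QED_ge_{qed_cut}": float(np.mean(qed >= qed_cut)),
        "SAS_le_6": float(np.mean(sas <= 6.0)),
        "n": n,
    }
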