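"""Synthetic compound sets with the statistical structure of fu collections.

The generator assembles drug-like SMILES strings from a small fragment
grammar (alkyl/aromatic body units plus ionizable termini) and derives the
fraction unbound from a latent lipophilicity score: fu is the inverse logit
of the negated score plus noise, clipped to (1e-4, 1].  Lipophilic
compounds therefore bind strongly (small fu), which reproduces the
right-skewed fu distribution of real plasma-protein-binding collections,
with the bulk of compounds below fu = 0.1.

Every record carries ground truth for downstream tests: the ionization
class implied by the termini (with matching rule-table pKa values), the
functional-group categories implied by the fragments used, and — via
:func:`plant_coral_signal` — an endpoint that is exactly linear in the
compound's SMILES-attribute counts, so the correlation-weight optimizer has
a recoverable planted signal.  Category error inflation is applied post hoc
to simulated predictions, giving the outlier analysis a known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from . import coral
from .curation import CompoundRecord, classify_ionization, standardize_structure
from .endpoints import EndpointVector

__all__ = [
    "Fragment",
    "SyntheticConfig",
    "default_grammar",
    "generate_dataset",
    "plant_coral_signal",
    "simulate_predictions",
    "write_dataset",
]


@dataclass(frozen=True)
class Fragment:
    """One body unit of the SMILES grammar.

    ``smiles`` must stay valid when concatenated between other units;
    ``lip`` is its additive contribution to the latent lipophilicity score.
    """

    smiles: str
    weight: float
    lip: float
    categories: tuple = ()


def default_grammar() -> list[Fragment]:
    return [
        Fragment("C", 0.28, 0.5),
        Fragment("CC", 0.17, 1.0),
        Fragment("C(C)", 0.12, 0.8),
        Fragment("c1ccccc1", 0.15, 1.8),
        Fragment("CO", 0.08, -0.5),
        Fragment("C(C(=O)OCC)", 0.08, -0.2, ("aliphatic_ester",)),
        Fragment("c1ccc(O)cc1", 0.07, 0.9, ("aromatic_hydroxyl",)),
        Fragment("CSC", 0.05, 0.3, ("sulfide",)),
    ]


# Ionizable termini: (prefix, suffix, latent shift, pKa lists).  The pKa
# values match the curation rule table, so the classifier recovers the
# intended class.
_CLASS_TERMINI = {
    "acid": ("", "C(=O)O", -0.7, [4.5], []),
    "base": ("NC", "", -0.9, [], [10.5]),
    "neutral": ("", "", -0.3, [], []),
    "zwitterion": ("NC", "C(=O)O", -1.6, [4.5], [10.5]),
}

# Approximate class mix of curated human fu collections.
_CLASS_PROBS = {"acid": 0.24, "base": 0.27, "neutral": 0.38, "zwitterion": 0.11}


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults define the study conditions."""

    n_compounds: int = 500
    seed: int = 0
    fragment_grammar: list = field(default_factory=default_grammar)
    category_effects: dict = field(default_factory=lambda: {"aliphatic_ester": 3.0})
    skew_target: str = "low_fu"
    noise_sd: float = 1.2  # sd of the latent-score noise
    min_units: int = 2
    max_units: int = 7

    def validate(self) -> None:
        if self.n_compounds < 0:
            raise ValueError("n_compounds must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for frag in self.fragment_grammar:
            if Chem.MolFromSmiles(frag.smiles) is None:
                raise ValueError(f"invalid grammar fragment: {frag.smiles!r}")


def _latent_to_fu(score: float) -> float:
    fu = 1.0 / (1.0 + np.exp(score))
    return float(np.clip(fu, 1e-4, 1.0))


def generate_dataset(config: SyntheticConfig) -> list[CompoundRecord]:
    """Generate ``n_compounds`` curation-clean records with ground truth.

    Structures are unique by canonical SMILES (so curation's duplicate
    filter never fires), fu lies in (0, 1] with a right-skewed distribution
    under the default settings, and each record's ionization class and
    category set reflect the fragments actually used.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_noise = [np.random.default_rng(s) for s in ss.spawn(2)]

    grammar = list(config.fragment_grammar)
    weights = np.array([f.weight for f in grammar], dtype=float)
    weights = weights / weights.sum()
    class_names = list(_CLASS_PROBS)
    class_probs = np.array([_CLASS_PROBS[c] for c in class_names])

    records: list[CompoundRecord] = []
    seen: set[str] = set()
    attempts = 0
    max_attempts = 50 * max(config.n_compounds, 1) + 100
    while len(records) < config.n_compounds:
        attempts += 1
        if attempts > max_attempts:  # pragma: no cover - generous cap
            raise RuntimeError("could not generate enough unique structures")
        cls = class_names[rng_struct.choice(len(class_names), p=class_probs)]
        prefix, suffix, shift, pka_acid, pka_base = _CLASS_TERMINI[cls]
        k = int(rng_struct.integers(config.min_units, config.max_units + 1))
        idx = rng_struct.choice(len(grammar), size=k, p=weights)
        body = [grammar[j] for j in idx]
        smiles = prefix + "".join(f.smiles for f in body) + suffix
        std = standardize_structure(smiles)
        if std in seen:
            continue
        seen.add(std)
        lip = sum(f.lip for f in body) + shift
        score = lip + float(rng_noise.normal(0.0, config.noise_sd))
        if config.skew_target != "low_fu":
            score = -score
        fu = _latent_to_fu(score)
        categories = set().union(*(set(f.categories) for f in body)) if body else set()
        if cls == "neutral" and body and body[-1].smiles == "CO" and not suffix:
            categories.add("primary_alcohol")
        rec = CompoundRecord(
            id=f"syn{len(records):04d}",
            smiles_raw=smiles,
            smiles_std=std,
            fu=fu,
            pka_acid=list(pka_acid),
            pka_base=list(pka_base),
            ionization_class=classify_ionization(pka_acid, pka_base),
            categories=categories,
        )
        records.append(rec)
    return records


def plant_coral_signal(
    records: Sequence[CompoundRecord],
    true_weights: dict,
    c0: float,
    c1: float,
    noise_sd: float,
    seed: Optional[int] = None,
) -> tuple[EndpointVector, np.ndarray]:
    """Endpoint linear in SMILES-attribute counts, plus its noiseless value.

    endpoint_i = c0 + c1 * sum(true_weights over the attributes of compound
    i, counted with multiplicity) + Normal(0, noise_sd).  Returns the noisy
    EndpointVector and the noiseless array for oracle tests.
    """
    rng = np.random.default_rng(seed)
    noiseless = []
    for rec in records:
        attrs = coral.extract_attributes(rec.smiles_std or rec.smiles_raw)
        s = sum(true_weights.get(k, 0.0) * c for k, c in attrs.all_keys().items())
        noiseless.append(c0 + c1 * s)
    noiseless = np.asarray(noiseless, dtype=float)
    if noise_sd > 0:
        noisy = noiseless + rng.normal(0.0, noise_sd, size=noiseless.size)
    else:
        noisy = noiseless.copy()
    # planted endpoints live on an arbitrary linear scale; tagged sqrt_fu
    # because that is the transform the optimizer is normally fed
    ev = EndpointVector(noisy, "sqrt_fu", [r.id for r in records])
    return ev, noiseless


def simulate_predictions(
    records: Sequence[CompoundRecord],
    endpoint_values: Sequence[float],
    noise_sd: float,
    category_effects: dict | None = None,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Simulated model predictions with category-inflated error.

    Each prediction is the true endpoint plus Gaussian noise whose standard
    deviation is multiplied by the largest matching category effect; this
    plants a known high-error category for the outlier analysis.
    """
    rng = np.random.default_rng(seed)
    effects = category_effects or {}
    y = np.asarray(endpoint_values, dtype=float)
    scales = np.array(
        [
            max((effects[c] for c in rec.categories if c in effects), default=1.0)
            for rec in records
        ]
    )
    return y + rng.normal(0.0, noise_sd, size=y.size) * scales


def write_dataset(records, csv_path, truth_path=None, config: SyntheticConfig | None = None):
    """Standard compound CSV plus an optional JSON sidecar with the truth."""
    df = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "smiles": [r.smiles_raw for r in records],
            "fu": [r.fu for r in records],
            "true_class": [r.ionization_class for r in records],
            "true_categories": ["|".join(sorted(r.categories)) for r in records],
        }
    )
    df.to_csv(csv_path, index=False)
    if truth_path is not None:
        truth = {
            "seed": config.seed if config else None,
            "category_effects": config.category_effects if config else {},
            "records": {
                r.id: {
                    "class": r.ionization_class,
                    "categories": sorted(r.categories),
                    "pka_acid": r.pka_acid,
                    "pka_base": r.pka_base,
                }
                for r in records
            },
        }
        with open(truth_path, "w") as fh:
            json.dump(truth, fh, indent=1)
    return df
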