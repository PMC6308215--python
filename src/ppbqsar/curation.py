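"""Structure standardization, rejection filters and pH-7.4 ionization classes.

Curation mirrors the cleaning usually applied to literature fraction-unbound
collections: salts are stripped to the largest organic fragment, charges are
neutralized where a neutral parent exists (permanently charged centres such
as quaternary nitrogen are kept), records without a usable activity value,
metal complexes, inorganics and duplicate structures are rejected.

The ionization class at physiological plasma pH (7.4) is derived from pKa
values via the Henderson--Hasselbalch relation.  A molecule that is more
than 10% deprotonated at an acidic site is an acid, more than 10% protonated
at a basic site a base; both at once make a zwitterion, neither a neutral
(>90% neutral microspecies).  pKa values can be supplied by the user;
otherwise a small substructure rule table estimates them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "CompoundRecord",
    "standardize_structure",
    "filter_record",
    "curate_records",
    "classify_ionization",
    "estimate_pka",
    "ionized_smiles",
    "IONIZATION_CLASSES",
    "REJECT_REASONS",
]

IONIZATION_CLASSES = ("acid", "base", "neutral", "zwitterion", "unknown")
REJECT_REASONS = (
    "unparseable",
    "no_activity",
    "range_value",
    "metal",
    "inorganic",
    "ambiguous",
    "duplicate",
)

# Elements allowed in an "organic" record; anything else is treated as a metal
# (or metalloid outside ordinary drug space).
_ORGANIC_ELEMENTS = {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"}


@dataclass
class CompoundRecord:
    """One curated chemical and everything downstream stages need."""

    id: str
    smiles_raw: str
    smiles_std: Optional[str] = None
    fu: Optional[float] = None
    pka_acid: list = field(default_factory=list)
    pka_base: list = field(default_factory=list)
    ionization_class: str = "unknown"
    categories: set = field(default_factory=set)
    rejected: bool = False
    reject_reason: Optional[str] = None

    def reject(self, reason: str) -> "CompoundRecord":
        if reason not in REJECT_REASONS:
            raise ValueError(f"unknown rejection reason {reason!r}")
        self.rejected = True
        self.reject_reason = reason
        return self


_FRAGMENT_CHOOSER = rdMolStandardize.LargestFragmentChooser()
_UNCHARGER = rdMolStandardize.Uncharger()


def standardize_structure(smiles_raw: str) -> str:
    """Canonical SMILES of the neutralized largest organic fragment.

    Counter-ions are dropped, ionized sites with a neutral parent are
    neutralized (a quaternary nitrogen has none and keeps its charge).
    The operation is idempotent.  Raises ``ValueError`` on unparseable input.
    """
    mol = Chem.MolFromSmiles(smiles_raw)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles_raw!r}")
    mol = _FRAGMENT_CHOOSER.choose(mol)
    mol = _UNCHARGER.uncharge(mol)
    return Chem.MolToSmiles(mol)


def _contains_metal(mol: Chem.Mol) -> bool:
    return any(a.GetSymbol() not in _ORGANIC_ELEMENTS for a in mol.GetAtoms())


def _is_inorganic(mol: Chem.Mol) -> bool:
    return not any(a.GetAtomicNum() == 6 for a in mol.GetAtoms())


def filter_record(record: CompoundRecord) -> CompoundRecord:
    """Apply the rejection filters in place (activity, metal, inorganic).

    Duplicate elimination needs the whole collection and lives in
    :func:`curate_records`.  Surviving records are untouched.
    """
    if record.rejected:
        return record
    if record.fu is None:
        return record.reject("no_activity")
    if not (0.0 < record.fu <= 1.0):
        return record.reject("ambiguous")
    if record.smiles_std is None:
        try:
            record.smiles_std = standardize_structure(record.smiles_raw)
        except ValueError:
            return record.reject("unparseable")
    mol = Chem.MolFromSmiles(record.smiles_std)
    if mol is None:  # pragma: no cover - standardization output always parses
        return record.reject("unparseable")
    if _contains_metal(mol):
        return record.reject("metal")
    if _is_inorganic(mol):
        return record.reject("inorganic")
    return record


def parse_fu(raw) -> tuple[Optional[float], Optional[str]]:
    """Parse an activity cell; returns (value, reject_reason)."""
    if raw is None:
        return None, "no_activity"
    if isinstance(raw, (int, float)):
        v = float(raw)
        return (None, "no_activity") if math.isnan(v) else (v, None)
    text = str(raw).strip()
    if not text:
        return None, "no_activity"
    for sep in ("-", "–", ".."):
        # a dash between two numbers denotes a range, not a negative value
        if sep in text[1:]:
            return None, "range_value"
    try:
        return float(text), None
    except ValueError:
        return None, "ambiguous"


def curate_records(records: Iterable[CompoundRecord]) -> list[CompoundRecord]:
    """Standardize, filter, deduplicate and classify a collection.

    Duplicates are detected on the canonical standardized SMILES; the first
    occurrence is kept.  Ionization classes are filled in from the records'
    pKa lists (user-supplied or previously estimated).
    """
    seen: dict[str, str] = {}
    out = []
    for rec in records:
        if not rec.rejected and rec.smiles_std is None:
            try:
                rec.smiles_std = standardize_structure(rec.smiles_raw)
            except ValueError:
                rec.reject("unparseable")
        filter_record(rec)
        if not rec.rejected:
            if rec.smiles_std in seen:
                rec.reject("duplicate")
            else:
                seen[rec.smiles_std] = rec.id
        if not rec.rejected:
            if not rec.pka_acid and not rec.pka_base:
                acid, base = estimate_pka(rec.smiles_std)
                rec.pka_acid, rec.pka_base = acid, base
            rec.ionization_class = classify_ionization(rec.pka_acid, rec.pka_base)
        out.append(rec)
    return out


def fraction_deprotonated(pka: float, ph: float = 7.4) -> float:
    """Henderson--Hasselbalch fraction of an acidic site in the anionic form."""
    return 1.0 / (1.0 + 10.0 ** (pka - ph))


def fraction_protonated(pka: float, ph: float = 7.4) -> float:
    """Henderson--Hasselbalch fraction of a basic site in the cationic form."""
    return 1.0 / (1.0 + 10.0 ** (ph - pka))


def classify_ionization(
    pka_acid: Sequence[float], pka_base: Sequence[float], ph: float = 7.4
) -> str:
    """Ionization class at the given pH from per-site pKa values.

    The most ionized site of each kind decides: strictly more than 10%
    anionic flags an acid, strictly more than 10% cationic a base, both a
    zwitterion, neither a neutral.  Exactly 10% is "not more than 10%".
    """
    if ph <= 0:
        raise ValueError("ph must be positive")
    f_a = max((fraction_deprotonated(p, ph) for p in pka_acid), default=0.0)
    f_b = max((fraction_protonated(p, ph) for p in pka_base), default=0.0)
    if f_a > 0.10 and f_b > 0.10:
        return "zwitterion"
    if f_a > 0.10:
        return "acid"
    if f_b > 0.10:
        return "base"
    return "neutral"


# ---------------------------------------------------------------------------
# Built-in pKa rule table.  Typical literature values for common ionizable
# groups, matched by SMARTS.  Deliberately small: users with measured or
# predicted pKa values should supply them instead.
# ---------------------------------------------------------------------------

_ACID_RULES = [
    ("carboxylic_acid", "[CX3](=O)[OX2H1]", 4.5),
    ("sulfonic_acid", "[SX4](=O)(=O)[OX2H1]", -1.0),
    ("phosphonic_acid", "[PX4](=O)([OX2H1])", 2.0),
    ("tetrazole", "c1nnn[nH]1", 4.9),
    ("acyl_sulfonamide", "[SX4](=O)(=O)[NX3H1][CX3]=O", 4.5),
    ("phenol", "[c][OX2H1]", 10.0),
    ("thiol", "[#6][SX2H1]", 10.5),
]

_BASE_RULES = [
    ("aliphatic_amine", "[NX3;H2,H1,H0;!$(N[#6]=[O,S,N]);!$(N=*);!$(Nc);!$(N[S,P]=O)]", 10.5),
    ("amidine", "[NX3][CX3]=[NX2]", 11.5),
    ("imidazole", "c1cnc[nH]1", 7.0),
    ("pyridine", "[nX2;$(n1ccccc1)]", 5.2),
    ("aromatic_amine", "[NX3;H2,H1][c]", 4.6),
]

_ACID_PATTERNS = [(n, Chem.MolFromSmarts(s), p) for n, s, p in _ACID_RULES]
_BASE_PATTERNS = [(n, Chem.MolFromSmarts(s), p) for n, s, p in _BASE_RULES]


def estimate_pka(smiles: str) -> tuple[list[float], list[float]]:
    """Estimate per-site pKa lists (acidic, basic) from the rule table.

    One entry is emitted per matched site.  This is a coarse fallback for
    records without user-supplied values.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    acid, base = [], []
    for _, patt, pka in _ACID_PATTERNS:
        n = len(mol.GetSubstructMatches(patt))
        acid.extend([pka] * n)
    for _, patt, pka in _BASE_PATTERNS:
        n = len(mol.GetSubstructMatches(patt))
        base.extend([pka] * n)
    return acid, base


_DEPROTONATE = [
    Chem.MolFromSmarts(s)
    for s in ("[CX3](=O)[OX2H1]", "[SX4](=O)(=O)[OX2H1]", "[PX4](=O)([OX2H1])")
]
_PROTONATE = [
    Chem.MolFromSmarts("[NX3;H2,H1,H0;+0;!$(N[#6]=[O,S,N]);!$(N=*);!$(Nc);!$(N[S,P]=O)]"),
]


def ionized_smiles(smiles_std: str, ph: float = 7.4) -> str:
    """Main (de)protonated microspecies at the given pH.

    Charge edits are limited to the rule-table sites whose majority species
    at the pH is charged: carboxylic/sulfonic/phosphonic acids are
    deprotonated, aliphatic amines protonated.  Everything else (phenols,
    anilines, azines) stays neutral at pH 7.4.
    """
    mol = Chem.MolFromSmiles(smiles_std)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles_std!r}")
    rw = Chem.RWMol(mol)
    for patt in _DEPROTONATE:
        for match in rw.GetSubstructMatches(patt):
            # the hydroxyl oxygen is the last atom of each acid pattern
            o = rw.GetAtomWithIdx(match[-1])
            if o.GetTotalNumHs() > 0 and o.GetFormalCharge() == 0:
                o.SetFormalCharge(-1)
                o.SetNumExplicitHs(0)
                o.SetNoImplicit(True)
    for patt in _PROTONATE:
        for match in rw.GetSubstructMatches(patt):
            n = rw.GetAtomWithIdx(match[0])
            if n.GetFormalCharge() == 0:
                n.SetFormalCharge(1)
                n.SetNumExplicitHs(n.GetTotalNumHs() + 1)
                n.SetNoImplicit(True)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)
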