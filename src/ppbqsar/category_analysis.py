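"""Outlier flagging and functional-group category enrichment statistics.

A compound is "badly predicted" (an outlier) when its absolute prediction
error exceeds the mean absolute error of the whole set.  For each
functional-group category the 2x2 table

    [[TP, positives - TP], [FP, negatives - FP]]

is built, where TP are category members among the badly predicted
compounds, FP category members among the correctly predicted ones,
positives/negatives the totals of badly/correctly predicted compounds.
Association is tested with a two-sided Fisher exact test (raw p < 0.05)
and its strength summarized by the likelihood ratio

    LR = (TP / FP) * (negatives / positives),

which equals 1 when the category's outlier rate matches the global rate.
Both directions (enrichment among the badly and among the well predicted)
are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from scipy import stats

__all__ = [
    "CategoryStats",
    "CATEGORY_PATTERNS",
    "assign_categories",
    "flag_outliers",
    "fisher_exact",
    "likelihood_ratio",
    "category_report",
]


# Substructure definitions for the functional-group categories tracked in
# the enrichment report.  Open SMARTS mirroring common functional-group
# count descriptors.
CATEGORY_PATTERNS = {
    "quaternary_N": "[NX4+]",
    "charged_N_positive": "[#7+]",
    "aliphatic_ester": "[#6;!$([#6]=O)][OX2][CX3](=[OX1])[#6]",
    "tertiary_alcohol": "[CX4]([#6])([#6])([#6])[OX2H1]",
    "primary_aliphatic_amide": "[CX3](=[OX1])[NX3H2]",
    "secondary_aliphatic_amide": "[CX3](=[OX1])[NX3H1][#6;!c]",
    "ch2rx": "[CH2X4][F,Cl,Br,I]",
    "urea_derivative": "[NX3][CX3](=[OX1,SX1])[NX3]",
    "aromatic_hydroxyl": "[c][OX2H1]",
    "quaternary_C": "[CX4]([#6])([#6])([#6])[#6]",
    "ring_quaternary_C": "[CX4;R]([#6])([#6])([#6])[#6]",
    "beta_lactam": "[CX3]1(=[OX1])[CX4][CX4][NX3]1",
    "sulfide": "[SX2]([#6])[#6]",
    "imidazole": "c1cnc[nH]1",
    "primary_alcohol": "[CX4H2][OX2H1]",
}

_COMPILED = {name: Chem.MolFromSmarts(s) for name, s in CATEGORY_PATTERNS.items()}


def assign_categories(smiles: str) -> set:
    """Functional-group categories present in a structure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return {name for name, patt in _COMPILED.items() if mol.HasSubstructMatch(patt)}


@dataclass
class CategoryStats:
    category: str
    direction: str  # "badly_predicted" or "well_predicted"
    tp: int
    fp: int
    positives: int
    negatives: int
    p_value: float
    lr: float
    significant: bool


def flag_outliers(abs_errors: Sequence[float]) -> list[bool]:
    """True where the absolute error strictly exceeds the mean absolute error."""
    arr = np.asarray(abs_errors, dtype=float)
    if arr.size == 0:
        raise ValueError("empty error vector")
    if np.any(arr < 0):
        raise ValueError("absolute errors must be non-negative")
    mae = float(arr.mean())
    return [bool(e > mae) for e in arr]


def fisher_exact(tp: int, fp: int, positives: int, negatives: int) -> float:
    """Two-sided Fisher exact p-value for the category 2x2 table.

    The table is [[tp, positives - tp], [fp, negatives - fp]]; the p-value
    is the hypergeometric probability mass of all tables with the same
    margins that are no more probable than the observed one.
    """
    for name, v in (("tp", tp), ("fp", fp), ("positives", positives), ("negatives", negatives)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    if tp > positives or fp > negatives:
        raise ValueError("inconsistent counts: tp <= positives and fp <= negatives required")
    table = [[tp, positives - tp], [fp, negatives - fp]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p)


def likelihood_ratio(tp: int, fp: int, positives: int, negatives: int) -> float:
    """LR = (TP/FP) * (negatives/positives).

    Undefined denominators are signalled, never silently zero: FP = 0 with
    TP > 0 yields +inf, and positives = 0 (or TP = FP = 0) yields nan.
    """
    if min(tp, fp, positives, negatives) < 0:
        raise ValueError("counts must be non-negative")
    if positives == 0:
        return float("nan")
    if fp == 0:
        return float("inf") if tp > 0 else float("nan")
    if tp == 0:
        return 0.0
    return (tp / fp) * (negatives / positives)


def category_report(
    records: Sequence,
    flags: Sequence[bool],
    categories: Iterable[str] | None = None,
) -> list[CategoryStats]:
    """Per-category enrichment among badly and well predicted compounds.

    ``records`` may be CompoundRecord objects (their ``categories`` sets are
    used) or plain sets of category names.  One row per (category,
    direction); rows with p < 0.05 are flagged significant.  The report is
    invariant to compound ordering.
    """
    if len(records) != len(flags):
        raise ValueError("records and flags are not aligned")
    member_sets = [
        rec.categories if hasattr(rec, "categories") else set(rec) for rec in records
    ]
    if categories is None:
        categories = sorted(set().union(*member_sets)) if member_sets else []
    flags = [bool(f) for f in flags]
    positives = sum(flags)
    negatives = len(flags) - positives
    out = []
    for cat in categories:
        in_cat = [cat in m for m in member_sets]
        if not any(in_cat):
            continue
        tp_bad = sum(1 for c, f in zip(in_cat, flags) if c and f)
        fp_bad = sum(1 for c, f in zip(in_cat, flags) if c and not f)
        for direction, tp, fp, pos, neg in (
            ("badly_predicted", tp_bad, fp_bad, positives, negatives),
            ("well_predicted", fp_bad, tp_bad, negatives, positives),
        ):
            p = fisher_exact(tp, fp, pos, neg) if pos and neg else 1.0
            lr = likelihood_ratio(tp, fp, pos, neg)
            out.append(
                CategoryStats(
                    category=cat,
                    direction=direction,
                    tp=tp,
                    fp=fp,
                    positives=pos,
                    negatives=neg,
                    p_value=p,
                    lr=lr,
                    significant=bool(p < 0.05),
                )
            )
    return sorted(out, key=lambda s: (s.direction, s.category))


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """Optional FDR adjustment for the report (off by default upstream)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return adj.tolist()
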