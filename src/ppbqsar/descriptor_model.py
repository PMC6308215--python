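"""Descriptor-based random-forest regression with three-step selection.

The pipeline is: compute 2D molecular descriptors with an open backend
(RDKit), remove constant and highly inter-correlated columns, run a
three-step random-forest variable selection (thresholding on permutation
importance against injected decoys, an interpretation step picking the
OOB-optimal importance-ordered prefix, and a parsimony step that keeps a
variable only if it buys more than a noise-scaled OOB improvement), then
fit a bootstrap random forest with sqrt(p) candidate descriptors per split.

Performance metrics follow the conventional QSAR definitions:
r2 = 1 - sum (y - yhat)^2 / sum (y - ybar)^2, RMSE, and the cross-validated
determination coefficient Q2 assembled from out-of-fold predictions with the
full-data mean in the denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, GraphDescriptors, Lipinski, rdMolDescriptors
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import KFold

from .curation import CompoundRecord

__all__ = [
    "DescriptorMatrix",
    "ModelReport",
    "compute_descriptors",
    "prefilter",
    "VSURFSelector",
    "vsurf_select",
    "fit_rf",
    "regression_metrics",
    "rmse",
    "cross_validate_q2",
]


# ---------------------------------------------------------------------------
# Descriptor backend
# ---------------------------------------------------------------------------

def _aromatic_carbons(mol):
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 6 and a.GetIsAromatic())


def _sp2_carbons(mol):
    return sum(
        1
        for a in mol.GetAtoms()
        if a.GetAtomicNum() == 6 and a.GetHybridization() == Chem.HybridizationType.SP2
    )


def _sp3_carbons(mol):
    return sum(
        1
        for a in mol.GetAtoms()
        if a.GetAtomicNum() == 6 and a.GetHybridization() == Chem.HybridizationType.SP3
    )


def _total_charge(mol):
    return sum(a.GetFormalCharge() for a in mol.GetAtoms())


# 2D descriptor set: lipophilicity, size, shape/topology, polarity, charge.
_DESCRIPTOR_FUNCS = {
    "logp": Crippen.MolLogP,
    "mr": Crippen.MolMR,
    "mw": Descriptors.MolWt,
    "tpsa": rdMolDescriptors.CalcTPSA,
    "hbd": Lipinski.NumHDonors,
    "hba": Lipinski.NumHAcceptors,
    "nhoh": Lipinski.NHOHCount,
    "no_count": Lipinski.NOCount,
    "rot_bonds": Lipinski.NumRotatableBonds,
    "rings": rdMolDescriptors.CalcNumRings,
    "aromatic_rings": rdMolDescriptors.CalcNumAromaticRings,
    "heavy_atoms": Lipinski.HeavyAtomCount,
    "frac_csp3": rdMolDescriptors.CalcFractionCSP3,
    "aromatic_carbons": _aromatic_carbons,
    "sp2_carbons": _sp2_carbons,
    "sp3_carbons": _sp3_carbons,
    "total_charge": _total_charge,
    "balaban_j": GraphDescriptors.BalabanJ,
    "bertz_ct": GraphDescriptors.BertzCT,
    "chi0v": GraphDescriptors.Chi0v,
    "chi1v": GraphDescriptors.Chi1v,
    "chi2v": GraphDescriptors.Chi2v,
    "kappa1": GraphDescriptors.Kappa1,
    "kappa2": GraphDescriptors.Kappa2,
    "kappa3": GraphDescriptors.Kappa3,
    "hall_kier_alpha": GraphDescriptors.HallKierAlpha,
    "labute_asa": rdMolDescriptors.CalcLabuteASA,
    "max_partial_charge": Descriptors.MaxPartialCharge,
    "min_partial_charge": Descriptors.MinPartialCharge,
}

BACKEND = "rdkit"


@dataclass
class DescriptorMatrix:
    """Descriptor table with provenance (backend, ionized-or-neutral form)."""

    data: pd.DataFrame  # rows indexed by compound id
    backend: str = BACKEND
    ionized: bool = False
    dropped_ids: list = field(default_factory=list)

    @property
    def ids(self):
        return list(self.data.index)

    @property
    def columns(self):
        return list(self.data.columns)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def compute_descriptors(
    records: Iterable[CompoundRecord], use_ionized: bool = False
) -> DescriptorMatrix:
    """2D descriptors for every record; rows with incomputable values dropped.

    ``use_ionized=True`` computes on the main (de)protonated microspecies at
    pH 7.4; the default uses the neutral parent.  Column names are
    namespaced ``rdkit:<name>`` to declare provenance.
    """
    from .curation import ionized_smiles

    rows, ids, dropped = [], [], []
    for rec in records:
        smi = rec.smiles_std or rec.smiles_raw
        if use_ionized:
            smi = ionized_smiles(smi)
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            dropped.append(rec.id)
            continue
        vals = {}
        ok = True
        for name, func in _DESCRIPTOR_FUNCS.items():
            try:
                v = float(func(mol))
            except Exception:
                v = float("nan")
            if not np.isfinite(v):
                ok = False
                break
            vals[f"{BACKEND}:{name}"] = v
        if ok:
            rows.append(vals)
            ids.append(rec.id)
        else:
            dropped.append(rec.id)
    data = pd.DataFrame(rows, index=ids)
    return DescriptorMatrix(data=data, ionized=use_ionized, dropped_ids=dropped)


def prefilter(X: DescriptorMatrix, corr_threshold: float = 0.95) -> DescriptorMatrix:
    """Drop constant columns, then the later member of any correlated pair.

    Columns are scanned in name-sorted order; of a pair with |Pearson r|
    above the threshold, the later column is removed, so the result is
    deterministic and invariant to row order.
    """
    df = X.data[sorted(X.data.columns)]
    keep = [c for c in df.columns if df[c].std(ddof=0) > 0]
    df = df[keep]
    if len(keep) > 1:
        corr = np.abs(np.corrcoef(df.to_numpy(dtype=float), rowvar=False))
        retained: list[int] = []
        for j in range(corr.shape[0]):
            if all(corr[i, j] <= corr_threshold for i in retained):
                retained.append(j)
        df = df.iloc[:, retained]
    return DescriptorMatrix(
        data=df.copy(), backend=X.backend, ionized=X.ionized, dropped_ids=list(X.dropped_ids)
    )


# ---------------------------------------------------------------------------
# Three-step variable selection
# ---------------------------------------------------------------------------

class VSURFSelector(BaseEstimator):
    """Random-forest three-step variable selection.

    Step 1 (thresholding): ``n_forests`` forests are fit on the data
    augmented with ``n_decoys`` row-permuted decoy columns; variables whose
    mean permutation importance does not exceed the mean decoy importance
    (the estimated null level) are dropped.

    Step 2 (interpretation): survivors are ordered by importance and nested
    forests are fit on each importance-ordered prefix; the prefix with the
    smallest out-of-bag (OOB) mean squared error is kept.

    Step 3 (prediction): walking through the interpretation set in order, a
    variable is retained only if adding it lowers the OOB error by more than
    the standard deviation of the step-2 OOB errors (a noise-scaled margin).

    Parameters
    ----------
    n_estimators : trees per forest (default 500 for stable importances).
    n_forests : forests averaged in step 1.
    n_decoys : permuted decoy columns injected to estimate the null level.
    n_repeats : permutation-importance repeats.
    random_state : seed for all internal randomness.
    """

    def __init__(
        self,
        n_estimators: int = 500,
        n_forests: int = 5,
        n_decoys: int = 5,
        n_repeats: int = 3,
        random_state: int | None = None,
    ):
        self.n_estimators = n_estimators
        self.n_forests = n_forests
        self.n_decoys = n_decoys
        self.n_repeats = n_repeats
        self.random_state = random_state

    def _oob_mse(self, X, y, seed):
        rf = RandomForestRegressor(
            n_estimators=self.n_estimators,
            max_features="sqrt",
            bootstrap=True,
            oob_score=True,
            random_state=seed,
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rf.fit(X, y)
        oob = rf.oob_prediction_
        return float(np.mean((np.asarray(y) - oob) ** 2))

    def fit(self, X, y):
        if isinstance(X, DescriptorMatrix):
            X = X.data
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y are not aligned")
        if X.shape[0] < 20:
            raise ValueError("variable selection needs at least 20 observations")
        names = list(X.columns)
        rng = np.random.default_rng(self.random_state)

        # --- step 1: importance thresholding against permuted decoys
        decoy_src = rng.choice(len(names), size=self.n_decoys, replace=True)
        X_aug = X.copy()
        decoy_names = []
        for k, j in enumerate(decoy_src):
            dn = f"__decoy_{k}"
            X_aug[dn] = rng.permutation(X.iloc[:, j].to_numpy())
            decoy_names.append(dn)
        imp = np.zeros(X_aug.shape[1])
        for f in range(self.n_forests):
            seed = int(rng.integers(2**31 - 1))
            rf = RandomForestRegressor(
                n_estimators=self.n_estimators,
                max_features="sqrt",
                bootstrap=True,
                random_state=seed,
                n_jobs=1,
            )
            rf.fit(X_aug, y)
            pi = permutation_importance(
                rf, X_aug, y, n_repeats=self.n_repeats, random_state=seed, n_jobs=1
            )
            imp += pi.importances_mean
        imp /= self.n_forests
        real_imp = dict(zip(X_aug.columns, imp))
        null_level = float(np.mean([real_imp[d] for d in decoy_names]))
        self.null_level_ = null_level
        self.importances_ = {n: real_imp[n] for n in names}
        survivors = [n for n in names if real_imp[n] > null_level]
        if not survivors:
            best = max(names, key=lambda n: real_imp[n])
            warnings.warn(
                "no variable importance exceeded the null level; "
                f"keeping the single most important variable {best!r}"
            )
            self.thresholded_ = [best]
            self.interpretation_ = [best]
            self.selected_ = [best]
            return self
        survivors.sort(key=lambda n: real_imp[n], reverse=True)
        self.thresholded_ = survivors

        # --- step 2: OOB-optimal importance-ordered prefix
        oob_errors = []
        for m in range(1, len(survivors) + 1):
            seed = int(rng.integers(2**31 - 1))
            oob_errors.append(self._oob_mse(X[survivors[:m]], y, seed))
        best_m = int(np.argmin(oob_errors)) + 1
        self.interpretation_ = survivors[:best_m]
        self.step2_oob_errors_ = oob_errors

        # --- step 3: parsimony with a noise-scaled margin
        margin = float(np.std(oob_errors)) if len(oob_errors) > 1 else 0.0
        selected = [self.interpretation_[0]]
        seed = int(rng.integers(2**31 - 1))
        current = self._oob_mse(X[selected], y, seed)
        for cand in self.interpretation_[1:]:
            seed = int(rng.integers(2**31 - 1))
            err = self._oob_mse(X[selected + [cand]], y, seed)
            if current - err > margin:
                selected.append(cand)
                current = err
        self.selected_ = selected
        return self

    def transform(self, X):
        if isinstance(X, DescriptorMatrix):
            X = X.data
        return pd.DataFrame(X)[self.selected_]


def vsurf_select(X, y, params: dict | None = None, seed: int | None = None) -> list[str]:
    """Functional wrapper around :class:`VSURFSelector`; returns the names."""
    sel = VSURFSelector(random_state=seed, **(params or {}))
    sel.fit(X, y)
    return list(sel.selected_)


# ---------------------------------------------------------------------------
# Random forest and metrics
# ---------------------------------------------------------------------------

def fit_rf(X, y, seed: int | None = None, n_estimators: int = 500) -> RandomForestRegressor:
    """Bootstrap random forest with floor(sqrt(p)) candidate splits per node."""
    if isinstance(X, DescriptorMatrix):
        X = X.data
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 5:
        raise ValueError("need at least 5 observations to fit a forest")
    rf = RandomForestRegressor(
        n_estimators=n_estimators,
        max_features="sqrt",
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    return rf


def rmse(obs, pred) -> float:
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    return float(np.sqrt(np.sum((pred - obs) ** 2) / obs.size))


def regression_metrics(obs, pred) -> tuple[float, float]:
    """Determination coefficient and root-mean-square error.

    r2 = 1 - sum (y - yhat)^2 / sum (y - ybar)^2.  For constant observations
    r2 is undefined: nan is returned with a warning while the RMSE is still
    computed.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("obs and pred must be equal-length vectors of size >= 2")
    e = rmse(obs, pred)
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        warnings.warn("r2 undefined for constant observations; returning nan")
        return float("nan"), e
    r2 = 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot
    return r2, e


def cross_validate_q2(
    X,
    y,
    k: int = 5,
    seed: int | None = None,
    model_factory=None,
) -> tuple[float, np.ndarray]:
    """Cross-validated determination coefficient Q2.

    Out-of-fold predictions y' are assembled over a seeded k-fold partition
    and Q2 = 1 - sum (y - y')^2 / sum (y - ybar)^2 with ybar the full-data
    mean.  Returns (q2, out_of_fold_predictions).
    """
    if isinstance(X, DescriptorMatrix):
        X = X.data
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if k > n:
        raise ValueError(f"k={k} exceeds the number of observations {n}")
    if model_factory is None:
        model_factory = lambda fold_seed: RandomForestRegressor(  # noqa: E731
            n_estimators=200,
            max_features="sqrt",
            bootstrap=True,
            random_state=fold_seed,
            n_jobs=1,
        )
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    y_oof = np.empty(n)
    rng = np.random.default_rng(seed)
    for train, test in kf.split(X):
        model = model_factory(int(rng.integers(2**31 - 1)))
        model.fit(X[train], y[train])
        y_oof[test] = model.predict(X[test])
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("Q2 undefined for constant observations")
    q2 = 1.0 - float(np.sum((y - y_oof) ** 2)) / ss_tot
    return q2, y_oof


@dataclass
class ModelReport:
    """Summary statistics for one fitted model."""

    r2: float
    rmse: float
    q2: float | None = None
    per_fold: list = field(default_factory=list)
    selected_descriptors: list = field(default_factory=list)
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "r2": self.r2,
            "rmse": self.rmse,
            "q2": self.q2,
            "per_fold": self.per_fold,
            "selected_descriptors": list(self.selected_descriptors),
            "seed": self.seed,
        }
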