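"""Seven applicability-domain (AD) methods behind one fit/apply interface.

An AD method decides, per compound, whether a model's prediction should be
trusted: the compound must lie in the region of descriptor or structure
space covered by the training set (TS).  Methods operating on descriptors:

* ``real_random`` — a random-forest classifier trained to separate the TS
  from a column-permuted mirror copy; compounds the classifier confidently
  labels "random" are out of domain.
* ``leverage`` — hat-matrix leverage h_i with the Williams-plot threshold
  h* = 3(p+1)/n.
* ``pca_sd`` — the first two principal components of the autoscaled TS,
  with per-component bounds mean +/- 3 sd.
* ``pca_pct`` — as above with empirical quantile bounds (0.05, 0.95 by
  default).
* ``knn_dist`` — distance to the nearest TS neighbour compared against the
  mean of all pairwise TS distances.

Methods operating on structures:

* ``acf`` — atom-centred fragments (a heavy atom with its bonded
  neighbours); a compound is in domain iff every one of its fragments
  occurs in the TS dictionary.
* ``fingerprint`` — mean Tanimoto similarity to the TS on substructure-key
  (MACCS) fingerprints, out of domain below 0.1.

Coverage is the fraction of compounds retained in domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import MACCSkeys
from rdkit.DataStructs import BulkTanimotoSimilarity
from scipy.spatial.distance import cdist, pdist
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.preprocessing import StandardScaler

__all__ = [
    "ADVerdict",
    "AD_METHODS",
    "fit_ad",
    "apply_ad",
    "RealRandomAD",
    "LeverageAD",
    "PcaSdAD",
    "PcaPercentileAD",
    "KnnDistAD",
    "AcfAD",
    "FingerprintAD",
]


@dataclass
class ADVerdict:
    method: str
    in_ad: dict  # compound id -> bool
    coverage: float
    threshold_params: dict = field(default_factory=dict)


def _as_frame(X) -> pd.DataFrame:
    from .descriptor_model import DescriptorMatrix

    if isinstance(X, DescriptorMatrix):
        return X.data
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, index=range(len(X)))


class _DescriptorAD(BaseEstimator):
    """Shared column bookkeeping for descriptor-space AD methods."""

    def _store_columns(self, df: pd.DataFrame):
        self.columns_ = list(df.columns)

    def _check_columns(self, df: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.columns_ if c not in df.columns]
        if missing:
            raise ValueError(f"test matrix is missing descriptor columns: {missing}")
        return df[self.columns_]


class RealRandomAD(_DescriptorAD):
    """Two-class real-vs-random classification AD.

    The TS matrix is mirrored by permuting each column independently, the
    real and mirror matrices are merged, and a classifier learns to tell
    them apart.  A compound is in domain iff the classifier's probability
    of "real" is at least 0.5.
    """

    method = "real_random"

    def __init__(self, n_estimators: int = 200, random_state: int | None = None):
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X):
        df = _as_frame(X)
        self._store_columns(df)
        rng = np.random.default_rng(self.random_state)
        real = df.to_numpy(dtype=float)
        mirror = np.column_stack([rng.permutation(real[:, j]) for j in range(real.shape[1])])
        Xc = np.vstack([real, mirror])
        yc = np.concatenate([np.ones(len(real)), np.zeros(len(mirror))])
        self.clf_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        self.clf_.fit(Xc, yc)
        return self

    def decide(self, X) -> np.ndarray:
        df = self._check_columns(_as_frame(X))
        proba = self.clf_.predict_proba(df.to_numpy(dtype=float))
        real_col = list(self.clf_.classes_).index(1.0)
        return proba[:, real_col] >= 0.5

    def params(self) -> dict:
        return {"probability_cutoff": 0.5, "n_estimators": self.n_estimators}


class LeverageAD(_DescriptorAD):
    """Leverage (hat-matrix diagonal) AD with threshold h* = 3(p+1)/n."""

    method = "leverage"

    def __init__(self):
        pass

    def fit(self, X):
        df = _as_frame(X)
        self._store_columns(df)
        A = np.column_stack([np.ones(len(df)), df.to_numpy(dtype=float)])
        self.pinv_gram_ = np.linalg.pinv(A.T @ A)
        self.h_star_ = 3.0 * (df.shape[1] + 1) / len(df)
        return self

    def leverages(self, X) -> np.ndarray:
        df = self._check_columns(_as_frame(X))
        A = np.column_stack([np.ones(len(df)), df.to_numpy(dtype=float)])
        return np.einsum("ij,jk,ik->i", A, self.pinv_gram_, A)

    def decide(self, X) -> np.ndarray:
        return self.leverages(X) <= self.h_star_

    def params(self) -> dict:
        return {"h_star": self.h_star_}


class PcaSdAD(_DescriptorAD):
    """Bounds of mean +/- 3 sd on the first two principal components."""

    method = "pca_sd"
    n_components = 2

    def __init__(self, n_sd: float = 3.0):
        self.n_sd = n_sd

    def fit(self, X):
        df = _as_frame(X)
        self._store_columns(df)
        self.scaler_ = StandardScaler().fit(df.to_numpy(dtype=float))
        k = min(self.n_components, df.shape[1], len(df))
        self.pca_ = PCA(n_components=k, random_state=0).fit(
            self.scaler_.transform(df.to_numpy(dtype=float))
        )
        scores = self.pca_.transform(self.scaler_.transform(df.to_numpy(dtype=float)))
        mu, sd = scores.mean(axis=0), scores.std(axis=0)
        self.lo_, self.hi_ = mu - self.n_sd * sd, mu + self.n_sd * sd
        return self

    def decide(self, X) -> np.ndarray:
        df = self._check_columns(_as_frame(X))
        scores = self.pca_.transform(self.scaler_.transform(df.to_numpy(dtype=float)))
        return np.all((scores >= self.lo_) & (scores <= self.hi_), axis=1)

    def params(self) -> dict:
        return {"lo": self.lo_.tolist(), "hi": self.hi_.tolist(), "n_sd": self.n_sd}


class PcaPercentileAD(PcaSdAD):
    """Quantile bounds on the first two principal components.

    Default bounds are the 0.05 and 0.95 quantiles; ``literal=True`` uses
    (0.005, 0.95) instead.
    """

    method = "pca_pct"

    def __init__(self, quantiles=(0.05, 0.95), literal: bool = False):
        self.quantiles = quantiles
        self.literal = literal

    def fit(self, X):
        df = _as_frame(X)
        self._store_columns(df)
        self.scaler_ = StandardScaler().fit(df.to_numpy(dtype=float))
        k = min(self.n_components, df.shape[1], len(df))
        self.pca_ = PCA(n_components=k, random_state=0).fit(
            self.scaler_.transform(df.to_numpy(dtype=float))
        )
        scores = self.pca_.transform(self.scaler_.transform(df.to_numpy(dtype=float)))
        q = (0.005, 0.95) if self.literal else self.quantiles
        self.lo_ = np.quantile(scores, q[0], axis=0)
        self.hi_ = np.quantile(scores, q[1], axis=0)
        return self

    def params(self) -> dict:
        return {"lo": self.lo_.tolist(), "hi": self.hi_.tolist(), "literal": self.literal}


class KnnDistAD(_DescriptorAD):
    """Nearest-neighbour distance AD.

    The threshold is the mean Euclidean distance over all TS pairs; a test
    compound whose nearest TS neighbour is farther than the threshold is
    out of domain.
    """

    method = "knn_dist"

    def __init__(self, threshold: float | None = None):
        self.threshold = threshold

    def fit(self, X):
        df = _as_frame(X)
        self._store_columns(df)
        self.ts_ = df.to_numpy(dtype=float)
        if self.threshold is None:
            self.threshold_ = float(pdist(self.ts_).mean()) if len(self.ts_) > 1 else 0.0
        else:
            self.threshold_ = float(self.threshold)
        return self

    def decide(self, X) -> np.ndarray:
        df = self._check_columns(_as_frame(X))
        d = cdist(df.to_numpy(dtype=float), self.ts_)
        return d.min(axis=1) <= self.threshold_

    def params(self) -> dict:
        return {"threshold": self.threshold_}


def atom_centered_fragments(smiles: str) -> set:
    """Atom-centred fragment keys: central heavy atom plus bonded atoms.

    The key records the central element with aromaticity and formal charge,
    and the sorted multiset of (bond type, neighbour element) pairs.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    frags = set()
    for atom in mol.GetAtoms():
        centre = (atom.GetSymbol(), atom.GetIsAromatic(), atom.GetFormalCharge())
        neigh = tuple(
            sorted(
                (str(b.GetBondType()), b.GetOtherAtom(atom).GetSymbol())
                for b in atom.GetBonds()
            )
        )
        frags.add((centre, neigh))
    return frags


class AcfAD(BaseEstimator):
    """Atom-centred-fragment AD: all test fragments must be known in the TS."""

    method = "acf"

    def __init__(self):
        pass

    def fit(self, smiles_list):
        self.dictionary_ = set()
        for smi in smiles_list:
            self.dictionary_ |= atom_centered_fragments(smi)
        return self

    def decide(self, smiles_list) -> np.ndarray:
        return np.array(
            [atom_centered_fragments(s) <= self.dictionary_ for s in smiles_list]
        )

    def params(self) -> dict:
        return {"n_fragments": len(self.dictionary_)}


class FingerprintAD(BaseEstimator):
    """Mean Tanimoto similarity to the TS on substructure-key fingerprints.

    Compounds with mean similarity below the threshold (0.1) are outside
    the domain.
    """

    method = "fingerprint"

    def __init__(self, threshold: float = 0.1):
        self.threshold = threshold

    @staticmethod
    def _fp(smiles: str):
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smiles!r}")
        return MACCSkeys.GenMACCSKeys(mol)

    def fit(self, smiles_list):
        self.fps_ = [self._fp(s) for s in smiles_list]
        return self

    def decide(self, smiles_list) -> np.ndarray:
        out = []
        for s in smiles_list:
            sims = BulkTanimotoSimilarity(self._fp(s), self.fps_)
            out.append(float(np.mean(sims)) >= self.threshold)
        return np.array(out)

    def params(self) -> dict:
        return {"similarity_threshold": self.threshold}


AD_METHODS = {
    "real_random": RealRandomAD,
    "leverage": LeverageAD,
    "pca_sd": PcaSdAD,
    "pca_pct": PcaPercentileAD,
    "knn_dist": KnnDistAD,
    "acf": AcfAD,
    "fingerprint": FingerprintAD,
}

#: methods that consume SMILES strings instead of descriptor matrices
STRUCTURE_METHODS = ("acf", "fingerprint")


def fit_ad(method: str, X_ts, params: dict | None = None, seed: int | None = None):
    """Fit one of the seven AD methods on the training set."""
    if method not in AD_METHODS:
        raise ValueError(
            f"unknown AD method {method!r}; valid methods: {sorted(AD_METHODS)}"
        )
    kwargs = dict(params or {})
    cls = AD_METHODS[method]
    if method == "real_random" and seed is not None:
        kwargs.setdefault("random_state", seed)
    model = cls(**kwargs)
    return model.fit(X_ts)


def apply_ad(ad_model, X_test, ids=None) -> ADVerdict:
    """Apply a fitted AD model; returns per-compound verdicts and coverage."""
    flags = ad_model.decide(X_test)
    if ids is None:
        df = X_test
        try:
            ids = list(_as_frame(X_test).index)
        except Exception:
            ids = list(range(len(flags)))
        if len(ids) != len(flags):
            ids = list(range(len(flags)))
    in_ad = {i: bool(f) for i, f in zip(ids, flags)}
    coverage = float(np.mean(flags)) if len(flags) else 0.0
    return ADVerdict(
        method=ad_model.method,
        in_ad=in_ad,
        coverage=coverage,
        threshold_params=ad_model.params(),
    )
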