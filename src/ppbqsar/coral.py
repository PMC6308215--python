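"""Optimal-SMILES-descriptor regression with Monte-Carlo correlation weights.

The model reads a compound as its canonical SMILES string and extracts four
families of attributes: single tokens (Sk), adjacent token pairs (SSk),
adjacent token triples (SSSk), and one composite HARD key recording the
presence or absence of eight elements (N, O, S, P, F, Cl, Br, I) and of
double, triple and stereo bonds.  Each attribute carries a correlation
weight CW; a molecule's descriptor is the sum

    DCW(T, N) = CW(HARD) + sum CW(Sk) + sum CW(SSk) + sum CW(SSSk)

over all attribute occurrences, and the endpoint is modelled as the linear
calibration ``endpoint = C0 + C1 * DCW``.  T is the minimum training-set
prevalence an attribute needs to take part (rarer attributes are blocked,
their weight pinned at zero), N the number of Monte-Carlo epochs.

Weights are optimized by seeded hill climbing on the target function

    TF = R + R' - |R - R'| + 1.1 * IIC

where R and R' are the correlation coefficients on the visible and
invisible training sets and IIC is the index of ideality of correlation on
the calibration set: the correlation coefficient damped by the ratio of the
smaller to the larger one-sided mean absolute residual, which rewards
residuals balanced around zero.

The model's applicability domain is attribute coverage: a compound is in
domain only if every one of its attributes was active during training.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .splitting import coral_subsplit

__all__ = [
    "tokenize",
    "extract_attributes",
    "SmilesAttributeSet",
    "dcw",
    "iic",
    "target_function",
    "CoralRegressor",
    "mc_optimize",
]

# Elements tracked by the HARD key, in fixed slot order, followed by the
# three bond slots (double, triple, stereo).
_HARD_ELEMENTS = ("N", "O", "S", "P", "F", "Cl", "Br", "I")

_TWO_LETTER = ("Cl", "Br")
_ATOM_CHARS = set("BCNOSPFIbcnosp")
_BOND_CHARS = set("=#/\\")


def tokenize(smiles: str) -> list[str]:
    """Split a canonical SMILES into model tokens.

    Bracket atoms ``[...]`` are one token, the two-letter organic-subset
    elements Cl and Br are one token, ring-closure digits (and ``%nn``
    labels) are tokens, the bond symbols ``=``, ``#``, ``/`` and ``\\`` are
    tokens.  Branch parentheses and explicit single bonds are dropped; a
    fragment separator ``.`` is kept as a break marker so that pairs and
    triples never span fragments.
    """
    tokens: list[str] = []
    i, n = 0, len(smiles)
    while i < n:
        ch = smiles[i]
        if ch == "[":
            j = smiles.find("]", i)
            if j < 0:
                raise ValueError(f"unbalanced bracket in SMILES: {smiles!r}")
            tokens.append(smiles[i : j + 1])
            i = j + 1
        elif ch == "%":
            if i + 2 >= n or not smiles[i + 1 : i + 3].isdigit():
                raise ValueError(f"malformed ring-closure label in {smiles!r}")
            tokens.append(smiles[i : i + 3])
            i += 3
        elif smiles[i : i + 2] in _TWO_LETTER:
            tokens.append(smiles[i : i + 2])
            i += 2
        elif ch in _ATOM_CHARS:
            tokens.append(ch)
            i += 1
        elif ch.isdigit():
            tokens.append(ch)
            i += 1
        elif ch in _BOND_CHARS:
            tokens.append(ch)
            i += 1
        elif ch in "()-":
            i += 1
        elif ch == ".":
            tokens.append(".")
            i += 1
        elif ch == "]":
            raise ValueError(f"unbalanced bracket in SMILES: {smiles!r}")
        else:
            raise ValueError(f"unsupported SMILES character {ch!r} in {smiles!r}")
    return tokens


_BRACKET_ELEMENT = re.compile(r"\[[0-9]*([A-Za-z][a-z]?)")


def _token_element(token: str) -> str | None:
    """Element symbol carried by a token, or None for non-atom tokens."""
    if token.startswith("["):
        m = _BRACKET_ELEMENT.match(token)
        return m.group(1).capitalize() if m else None
    if token in _TWO_LETTER:
        return token
    if token in _ATOM_CHARS:
        return token.upper()
    return None


@dataclass
class SmilesAttributeSet:
    """Multisets of SMILES attributes for one compound."""

    sk: Counter = field(default_factory=Counter)
    ssk: Counter = field(default_factory=Counter)
    sssk: Counter = field(default_factory=Counter)
    hard: str = ""

    def all_keys(self) -> Counter:
        """Every attribute with its multiplicity, HARD included once."""
        total = Counter()
        total.update(self.sk)
        total.update(self.ssk)
        total.update(self.sssk)
        if self.hard:
            total[self.hard] += 1
        return total


def _pair_key(a: str, b: str) -> str:
    lo, hi = sorted((a, b))
    return f"{lo}_{hi}"


def _triple_key(a: str, b: str, c: str) -> str:
    lo, hi = sorted((a, c))
    return f"{lo}_{b}_{hi}"


def extract_attributes(smiles: str) -> SmilesAttributeSet:
    """Sk/SSk/SSSk multisets plus the HARD key for one canonical SMILES.

    Pair keys are symmetric in their two tokens and triple keys symmetric
    in the outer tokens around the fixed middle one, so a string written in
    either direction yields identical attributes.
    """
    tokens = tokenize(smiles)
    attrs = SmilesAttributeSet()
    runs: list[list[str]] = [[]]
    for t in tokens:
        if t == ".":
            runs.append([])
        else:
            runs[-1].append(t)
    for run in runs:
        attrs.sk.update(run)
        for a, b in zip(run, run[1:]):
            attrs.ssk[_pair_key(a, b)] += 1
        for a, b, c in zip(run, run[1:], run[2:]):
            attrs.sssk[_triple_key(a, b, c)] += 1

    elements = {e for t in tokens for e in [_token_element(t)] if e}
    bits = ["1" if e in elements else "0" for e in _HARD_ELEMENTS]
    bits.append("1" if "=" in tokens else "0")
    bits.append("1" if "#" in tokens else "0")
    bits.append("1" if ("/" in tokens or "\\" in tokens) else "0")
    attrs.hard = "HARD_" + "".join(bits)
    return attrs


def dcw(attrs: SmilesAttributeSet, cw: dict) -> float:
    """Descriptor from correlation weights: attribute-weighted sum.

    Weights are counted with multiplicity; unknown or blocked keys
    contribute zero.
    """
    return float(sum(cw.get(k, 0.0) * c for k, c in attrs.all_keys().items()))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def iic(obs, pred) -> float:
    """Index of ideality of correlation.

    r(obs, pred) scaled by min(MAE-, MAE+)/max(MAE-, MAE+), where MAE- and
    MAE+ are the mean absolute residuals over observations with negative
    and non-negative residual (obs - pred).  If either residual class is
    empty the index is 0; if all residuals vanish the ratio is taken as 1.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.size < 3:
        raise ValueError("iic requires at least 3 observations")
    resid = obs - pred
    neg = resid[resid < 0]
    pos = resid[resid >= 0]
    if neg.size == 0 or pos.size == 0:
        return 0.0
    mae_neg = float(np.mean(np.abs(neg)))
    mae_pos = float(np.mean(np.abs(pos)))
    hi = max(mae_neg, mae_pos)
    ratio = 1.0 if hi == 0 else min(mae_neg, mae_pos) / hi
    return _pearson(obs, pred) * ratio


def target_function(R: float, R_prime: float, iic_value: float, iic_weight: float = 1.1) -> float:
    """Monte-Carlo target TF = R + R' - |R - R'| + iic_weight * IIC."""
    return R + R_prime - abs(R - R_prime) + iic_weight * iic_value


class CoralRegressor(BaseEstimator, RegressorMixin):
    """Optimal-SMILES-descriptor model fitted by Monte-Carlo hill climbing.

    Parameters
    ----------
    threshold_T : minimum number of visible-training-set compounds an
        attribute must occur in to be active; rarer attributes are blocked
        (weight fixed at 0) and put a compound out of the applicability
        domain.
    epochs_N : Monte-Carlo epochs; each epoch visits every active attribute
        in a seeded random order and probes a uniform step and its mirror
        image, keeping the better one if it improves the target function.
    delta : half-width of the uniform proposal step.
    init_cw : initial correlation weight of every active attribute.  The
        default 0 starts from a null descriptor; the target function is
        scale-invariant in the weights, so the step width only sets the
        scale of the fitted weights, not the optimization path.
    iic_weight : multiplier on the IIC term of the target function.
    subsplit_fractions : fractions used to carve ITS and CS out of the
        training data when they are not supplied explicitly.
    random_state : seed for the sub-split and the proposal stream.

    Fitted attributes
    -----------------
    cw_ : dict attribute -> correlation weight (active attributes only).
    c0_, c1_ : intercept and slope of the linear calibration.
    active_attributes_ : frozenset of attributes used by the model.
    tf_trace_ : target-function value after initialization and after each
        accepted proposal (non-decreasing by construction).
    eval_trace_ : list of (R, R', IIC, TF) tuples, one per evaluated
        proposal.
    """

    def __init__(
        self,
        threshold_T: int = 1,
        epochs_N: int = 50,
        delta: float = 0.1,
        init_cw: float = 0.0,
        iic_weight: float = 1.1,
        subsplit_fractions=(108 / 391, 140 / 391, 143 / 391),
        random_state: int | None = None,
    ):
        self.threshold_T = threshold_T
        self.epochs_N = epochs_N
        self.delta = delta
        self.init_cw = init_cw
        self.iic_weight = iic_weight
        self.subsplit_fractions = subsplit_fractions
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------

    @staticmethod
    def _as_attrs(X) -> list[SmilesAttributeSet]:
        out = []
        for x in X:
            out.append(x if isinstance(x, SmilesAttributeSet) else extract_attributes(x))
        return out

    @staticmethod
    def _count_matrix(attr_sets, keys) -> np.ndarray:
        idx = {k: j for j, k in enumerate(keys)}
        M = np.zeros((len(attr_sets), len(keys)))
        for i, a in enumerate(attr_sets):
            for k, c in a.all_keys().items():
                j = idx.get(k)
                if j is not None:
                    M[i, j] = c
        return M

    @staticmethod
    def _calibrate(d: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        """One-variable least squares of y on the descriptor."""
        var = float(np.var(d))
        if var == 0:
            return float(np.mean(y)), 0.0
        c1 = float(np.cov(d, y, bias=True)[0, 1]) / var
        c0 = float(np.mean(y) - c1 * np.mean(d))
        return c0, c1

    # -- estimator API ----------------------------------------------------

    def fit(self, X, y, roles=None):
        """Fit on SMILES (or pre-extracted attribute sets) and endpoints.

        ``roles`` optionally assigns each observation to "TS" (visible
        training), "ITS" or "CS"; when omitted a seeded random sub-split
        with ``subsplit_fractions`` is drawn.
        """
        attrs = self._as_attrs(X)
        y = np.asarray(y, dtype=float)
        if len(attrs) != y.size:
            raise ValueError("X and y are not aligned")
        if roles is None:
            sub = coral_subsplit(
                range(len(attrs)), self.subsplit_fractions, seed=self.random_state
            )
            roles = [sub[i] for i in range(len(attrs))]
        roles = list(roles)
        sub_i = [i for i, r in enumerate(roles) if r == "TS"]
        its_i = [i for i, r in enumerate(roles) if r == "ITS"]
        cs_i = [i for i, r in enumerate(roles) if r == "CS"]
        if not sub_i or not its_i or not cs_i:
            raise ValueError("each of TS, ITS and CS must be non-empty")

        prevalence = Counter()
        for i in sub_i:
            for k in attrs[i].all_keys():
                prevalence[k] += 1
        active = sorted(k for k, c in prevalence.items() if c >= self.threshold_T)
        if not active:
            raise ValueError(f"no active attributes at threshold T={self.threshold_T}")

        A_sub = self._count_matrix([attrs[i] for i in sub_i], active)
        A_its = self._count_matrix([attrs[i] for i in its_i], active)
        A_cs = self._count_matrix([attrs[i] for i in cs_i], active)
        y_sub, y_its, y_cs = y[sub_i], y[its_i], y[cs_i]

        cw = np.full(len(active), float(self.init_cw))
        d_sub, d_its, d_cs = A_sub @ cw, A_its @ cw, A_cs @ cw

        def evaluate(ds, di, dc):
            c0, c1 = self._calibrate(ds, y_sub)
            R = _pearson(y_sub, c0 + c1 * ds)
            Rp = _pearson(y_its, c0 + c1 * di)
            ii = iic(y_cs, c0 + c1 * dc)
            tf = target_function(R, Rp, ii, self.iic_weight)
            return tf, R, Rp, ii, c0, c1

        tf, R, Rp, ii, c0, c1 = evaluate(d_sub, d_its, d_cs)
        rng = np.random.default_rng(self.random_state)
        self.tf_trace_ = [tf]
        self.eval_trace_ = [(R, Rp, ii, tf)]
        for _ in range(self.epochs_N):
            for j in rng.permutation(len(active)):
                u = float(rng.uniform(-self.delta, self.delta))
                # two-sided probe: the drawn step and its mirror image
                best = None
                for step in (u, -u):
                    d_sub_n = d_sub + step * A_sub[:, j]
                    d_its_n = d_its + step * A_its[:, j]
                    d_cs_n = d_cs + step * A_cs[:, j]
                    tf_n, R_n, Rp_n, ii_n, c0_n, c1_n = evaluate(d_sub_n, d_its_n, d_cs_n)
                    self.eval_trace_.append((R_n, Rp_n, ii_n, tf_n))
                    if tf_n > tf and (best is None or tf_n > best[0]):
                        best = (tf_n, step, d_sub_n, d_its_n, d_cs_n, c0_n, c1_n)
                if best is not None:
                    tf, step, d_sub, d_its, d_cs, c0, c1 = best
                    cw[j] += step
                    self.tf_trace_.append(tf)

        self.cw_ = dict(zip(active, cw.tolist()))
        self.c0_, self.c1_ = c0, c1
        self.active_attributes_ = frozenset(active)
        self.roles_ = roles
        self.best_tf_ = tf
        return self

    def decision_descriptor(self, X) -> np.ndarray:
        """DCW values for each compound."""
        attrs = self._as_attrs(X)
        return np.array([dcw(a, self.cw_) for a in attrs])

    def predict(self, X) -> np.ndarray:
        return self.c0_ + self.c1_ * self.decision_descriptor(X)

    def in_domain(self, X) -> np.ndarray:
        """Attribute-coverage applicability domain.

        A compound is in domain iff every one of its attributes (HARD key
        included) was active during training.
        """
        attrs = self._as_attrs(X)
        return np.array(
            [all(k in self.active_attributes_ for k in a.all_keys()) for a in attrs]
        )

    def predict_with_ad(self, X) -> tuple[np.ndarray, np.ndarray]:
        return self.predict(X), self.in_domain(X)

    def to_dict(self) -> dict:
        return {
            "cw": dict(self.cw_),
            "c0": self.c0_,
            "c1": self.c1_,
            "threshold_T": self.threshold_T,
            "epochs_N": self.epochs_N,
            "active_attributes": sorted(self.active_attributes_),
            "seed": self.random_state,
        }


def mc_optimize(
    sub_ts, its, cs, threshold_T: int = 1, epochs_N: int = 50, seed: int | None = None,
    **kwargs,
) -> CoralRegressor:
    """Fit a :class:`CoralRegressor` from explicit (attrs, endpoint) triples.

    Each of ``sub_ts``, ``its``, ``cs`` is a pair (list of SMILES or
    attribute sets, endpoint array); the three sets must be disjoint.
    """
    X = list(sub_ts[0]) + list(its[0]) + list(cs[0])
    y = np.concatenate([np.asarray(s[1], dtype=float) for s in (sub_ts, its, cs)])
    roles = ["TS"] * len(sub_ts[0]) + ["ITS"] * len(its[0]) + ["CS"] * len(cs[0])
    model = CoralRegressor(
        threshold_T=threshold_T, epochs_N=epochs_N, random_state=seed, **kwargs
    )
    return model.fit(X, y, roles=roles)
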