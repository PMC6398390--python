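"""Discretization of continuous features into interval items and conjunction rules.

A conjunction rule is a product of one-dimensional interval indicators,
e.g. ``I(1.0 <= x3 <= 2.0) I(x5 >= 0.5) I(x6 <= 0.8)``; it evaluates to 1
iff every interval is satisfied (closed bounds).  Rules are represented as
itemsets over a finite catalogue built by cutting each feature at its
empirical quantiles: each cut value c on feature j spawns a ``<=``-item
``(j, LEQ, c)`` and a ``>=``-item ``(j, GEQ, c)``.  Conjunctions of items
on one feature reduce to an interval, so the rule space is itemset-shaped
and can be searched by weighted itemset mining.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LEQ",
    "GEQ",
    "EMPTY",
    "Dataset",
    "CutpointTable",
    "Item",
    "ConjunctionRule",
    "TransactionMatrix",
    "build_cutpoints",
    "build_transactions",
    "evaluate_rule",
    "reduce_itemset",
    "read_table",
]

LEQ = "LEQ"
GEQ = "GEQ"

#: Sentinel returned by :func:`reduce_itemset` when bounds contradict.
EMPTY = "EMPTY"


class InvalidConfigurationError(ValueError):
    """A hyperparameter is outside its allowed range."""


@dataclass
class Dataset:
    """Feature matrix with binary labels in {+1, -1}.

    Parameters
    ----------
    X : (n, p) float array of continuous feature values.
    y : (n,) int array of labels, +1 (positive / disease) or -1 (negative).
    feature_names : p strings; defaults to ``x0 .. x{p-1}``.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n, p = self.X.shape
        if n < 2:
            raise ValueError("need at least 2 samples")
        if p < 1:
            raise ValueError("need at least 1 feature")
        if self.y.shape != (n,):
            raise ValueError("y length must match number of rows of X")
        if not np.all(np.isin(self.y, (-1, 1))):
            raise ValueError("labels must be +1 or -1")
        if np.isnan(self.X).any():
            raise ValueError(
                "missing values in X; impute or drop before constructing a Dataset"
            )
        if not self.feature_names:
            self.feature_names = [f"x{j}" for j in range(p)]
        if len(self.feature_names) != p:
            raise ValueError("feature_names length must equal number of columns")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class Item:
    """One-dimensional half-interval indicator: x[feature] <= / >= threshold."""

    feature: int
    direction: str  # LEQ or GEQ
    threshold: float

    def sort_key(self) -> tuple:
        # catalogue order: feature, LEQ before GEQ, threshold ascending
        return (self.feature, 0 if self.direction == LEQ else 1, self.threshold)


@dataclass(frozen=True)
class ConjunctionRule:
    """Conjunction of per-feature closed intervals.

    ``intervals`` maps feature index -> (lo, hi); lo may be -inf, hi +inf.
    The empty rule (no intervals) evaluates to 1 everywhere.
    """

    intervals: tuple[tuple[int, float, float], ...]

    @classmethod
    def from_dict(cls, d: dict[int, tuple[float, float]]) -> "ConjunctionRule":
        ivals = tuple(sorted((j, lo, hi) for j, (lo, hi) in d.items()))
        for j, lo, hi in ivals:
            if not lo <= hi:
                raise ValueError(f"empty interval on feature {j}: ({lo}, {hi})")
        return cls(ivals)

    def as_dict(self) -> dict[int, tuple[float, float]]:
        return {j: (lo, hi) for j, lo, hi in self.intervals}

    @property
    def order(self) -> int:
        return len(self.intervals)

    def items(self, catalogue_lookup: bool = False) -> frozenset[Item]:
        """Canonical itemset: finite lo -> GEQ item, finite hi -> LEQ item."""
        out = []
        for j, lo, hi in self.intervals:
            if np.isfinite(lo):
                out.append(Item(j, GEQ, lo))
            if np.isfinite(hi):
                out.append(Item(j, LEQ, hi))
        return frozenset(out)

    def activations(self, X: np.ndarray) -> np.ndarray:
        """Vectorized 0/1 evaluation on every row of X."""
        X = np.asarray(X, dtype=float)
        act = np.ones(X.shape[0], dtype=bool)
        for j, lo, hi in self.intervals:
            act &= (X[:, j] >= lo) & (X[:, j] <= hi)
        return act.astype(float)

    def describe(self, feature_names: Sequence[str] | None = None) -> str:
        parts = []
        for j, lo, hi in self.intervals:
            name = feature_names[j] if feature_names else f"x{j}"
            if np.isfinite(lo) and np.isfinite(hi):
                parts.append(f"I({lo:g} <= {name} <= {hi:g})")
            elif np.isfinite(lo):
                parts.append(f"I({name} >= {lo:g})")
            else:
                parts.append(f"I({name} <= {hi:g})")
        return " ".join(parts) if parts else "I(true)"


@dataclass
class CutpointTable:
    """Per-feature strictly increasing cut values from B-quantile discretization."""

    cuts: list[np.ndarray]
    bin_count: int

    @property
    def p(self) -> int:
        return len(self.cuts)


@dataclass
class TransactionMatrix:
    """Binary sample-by-item incidence feeding the itemset miner.

    ``incidence[i, k]`` is True iff sample i satisfies item k.  The item
    catalogue is ordered by (feature, LEQ<GEQ, threshold) for deterministic
    tie-breaking downstream.
    """

    incidence: np.ndarray  # (n, m) bool
    catalogue: list[Item]

    @property
    def n(self) -> int:
        return self.incidence.shape[0]

    @property
    def m(self) -> int:
        return self.incidence.shape[1]


def build_cutpoints(X: np.ndarray, B: int = 10) -> CutpointTable:
    """Discretize each feature at its interior B-quantiles.

    Cuts are the (1/B, 2/B, ..., (B-1)/B) empirical quantiles of the observed
    values, deduplicated and excluding the feature's min/max (a cut at an
    extreme separates nothing).  A constant feature gets an empty cut list.
    """
    if B < 2:
        raise InvalidConfigurationError(f"bin count B must be >= 2, got {B}")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be 2-dimensional with at least one column")
    qs = np.arange(1, B) / B
    cuts: list[np.ndarray] = []
    for j in range(X.shape[1]):
        col = X[:, j]
        lo, hi = col.min(), col.max()
        if lo == hi:
            cuts.append(np.empty(0))
            continue
        c = np.unique(np.quantile(col, qs))
        c = c[(c > lo) & (c < hi)]
        cuts.append(c)
    return CutpointTable(cuts=cuts, bin_count=B)


def build_transactions(X: np.ndarray, cuts: CutpointTable) -> TransactionMatrix:
    """Materialize the item catalogue and its incidence on X."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != cuts.p:
        raise ValueError(
            f"column count mismatch: X has {X.shape[1]}, cutpoints built for {cuts.p}"
        )
    catalogue: list[Item] = []
    cols: list[np.ndarray] = []
    for j in range(cuts.p):
        for c in cuts.cuts[j]:
            catalogue.append(Item(j, LEQ, float(c)))
            cols.append(X[:, j] <= c)
        for c in cuts.cuts[j]:
            catalogue.append(Item(j, GEQ, float(c)))
            cols.append(X[:, j] >= c)
    order = sorted(range(len(catalogue)), key=lambda k: catalogue[k].sort_key())
    catalogue = [catalogue[k] for k in order]
    if cols:
        incidence = np.stack([cols[k] for k in order], axis=1)
    else:
        incidence = np.zeros((X.shape[0], 0), dtype=bool)
    return TransactionMatrix(incidence=incidence, catalogue=catalogue)


def reduce_itemset(items) -> ConjunctionRule | str:
    """Reduce an itemset to a per-feature interval conjunction.

    Per feature: lo = max of GEQ thresholds, hi = min of LEQ thresholds.
    Returns the :data:`EMPTY` sentinel if any lo > hi.
    """
    lo: dict[int, float] = {}
    hi: dict[int, float] = {}
    for it in items:
        if it.direction == GEQ:
            lo[it.feature] = max(lo.get(it.feature, -np.inf), it.threshold)
        else:
            hi[it.feature] = min(hi.get(it.feature, np.inf), it.threshold)
    intervals = {}
    for j in sorted(set(lo) | set(hi)):
        l, h = lo.get(j, -np.inf), hi.get(j, np.inf)
        if l > h:
            return EMPTY
        intervals[j] = (l, h)
    return ConjunctionRule.from_dict(intervals)


def evaluate_rule(rule: ConjunctionRule, x: np.ndarray) -> int:
    """Evaluate a rule on a single feature vector; 1 iff every interval holds."""
    x = np.asarray(x, dtype=float)
    for j, lo, hi in rule.intervals:
        if j >= x.shape[0]:
            raise IndexError(f"rule references feature {j}, vector has {x.shape[0]}")
        if not (lo <= x[j] <= hi):
            return 0
    return 1


def read_table(
    path,
    label_col: str,
    positive_label: str | None = None,
    sep: str | None = None,
) -> Dataset:
    """Read a CSV/TSV feature table (header row required) into a Dataset.

    ``positive_label`` names the label value mapped to +1; every other value
    maps to -1.  If omitted, labels must already be in {+1, -1} (or {0, 1},
    where 1 is positive).
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if label_col not in df.columns:
        raise ValueError(f"label column {label_col!r} not found in {list(df.columns)}")
    labels = df[label_col]
    feats = df.drop(columns=[label_col])
    if positive_label is not None:
        y = np.where(labels.astype(str) == str(positive_label), 1, -1)
    else:
        vals = set(labels.unique().tolist())
        if vals <= {-1, 1}:
            y = labels.to_numpy(dtype=int)
        elif vals <= {0, 1}:
            y = np.where(labels.to_numpy() == 1, 1, -1)
        else:
            raise ValueError(
                "labels not in {+1,-1} or {0,1}; pass positive_label to map them"
            )
    return Dataset(
        X=feats.to_numpy(dtype=float), y=y, feature_names=list(feats.columns)
    )
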