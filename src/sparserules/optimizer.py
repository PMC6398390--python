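"""L1-penalized double-hinge rule learning by LP column generation.

The classifier is the weighted rule sum ``f(x) = sum_j a_j h_j(x) + b``
over the (exponentially large) space of interval-conjunction rules h_j.
Training minimizes

    sum_j |a_j|  +  C+ * sum_{y_i=+1} phi(f(x_i))  +  C- * sum_{y_i=-1} phi(-f(x_i))

where phi is the double hinge loss with rejection cost d.  The L1 penalty
makes the optimum sparse, so the problem is solved by column generation:
a restricted master LP over the rules found so far alternates with a
pricing step that searches the full rule space — by depth-first
branch-and-bound weighted itemset mining — for the rule whose dual
constraint is most violated.  Because the objective is a linear program,
the procedure terminates at a global optimum of the full problem.

LP formulation (primal)
-----------------------
Split a_j = a_j+ - a_j- with a_j± >= 0 and introduce slack xi_i >= 0:

    min  sum_j (a_j+ + a_j-) + sum_i C_{y_i} xi_i
    s.t. xi_i >= 1 - z_i,   xi_i >= 1 - k z_i,   k = (1-d)/d,
         z_i  = y_i (sum_j (a_j+ - a_j-) h_j(x_i) + b),  b free.

This is exact because phi(z) = max(0, 1-z, 1-k z) for d <= 0.5.  With dual
multipliers alpha_i, beta_i on the two slack constraints, the effective
per-sample mining weight is u_i = alpha_i + k beta_i; dual feasibility for
a rule h reads |sum_i y_i u_i h(x_i)| <= 1, so the pricing problem is to
maximize the absolute weighted cover sum over itemsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .rulespace import (
    EMPTY,
    CutpointTable,
    Dataset,
    InvalidConfigurationError,
    TransactionMatrix,
    ConjunctionRule,
    build_cutpoints,
    build_transactions,
    reduce_itemset,
)

__all__ = [
    "FitConfig",
    "RuleModel",
    "DualWeights",
    "double_hinge",
    "objective",
    "solve_master",
    "find_best_rule",
    "fit",
    "UnfittableError",
]


class UnfittableError(ValueError):
    """The data admit no model (single class, or no discretizable feature)."""


class MasterSolverError(RuntimeError):
    """The restricted master LP failed to solve."""


@dataclass
class FitConfig:
    """Hyperparameters of the rule-ensemble fit.

    C : single misclassification-cost knob; per-class costs are
        C+ = C*n/(2 n+), C- = C*n/(2 n-) unless ``C_pos``/``C_neg`` are
        given explicitly (balanced weighting under class imbalance).
    d : rejection cost in (0, 0.5]; d = 0.5 recovers the plain hinge loss.
    bins : quantile bin count B for discretization.
    max_rule_order : maximum number of intervals per rule.
    """

    C: float = 1.0
    C_pos: float | None = None
    C_neg: float | None = None
    d: float = 0.5
    bins: int = 10
    max_rule_order: int = 3
    max_iterations: int = 100
    pricing_tolerance: float = 1e-6
    lp_tolerance: float = 1e-7
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.d <= 0.5):
            raise InvalidConfigurationError(f"rejection cost d must be in (0, 0.5], got {self.d}")
        if self.C <= 0 or (self.C_pos is not None and self.C_pos <= 0) or (
            self.C_neg is not None and self.C_neg <= 0
        ):
            raise InvalidConfigurationError("misclassification costs must be positive")
        if self.max_rule_order < 1:
            raise InvalidConfigurationError("max_rule_order must be >= 1")

    @property
    def k(self) -> float:
        """Slope ratio (1-d)/d of the steep negative-margin branch."""
        return (1.0 - self.d) / self.d

    def class_costs(self, y: np.ndarray) -> tuple[float, float]:
        """Resolve (C+, C-), applying balanced weighting when not set explicitly."""
        n = y.shape[0]
        n_pos = int(np.sum(y == 1))
        n_neg = n - n_pos
        c_pos = self.C_pos if self.C_pos is not None else self.C * n / (2.0 * max(n_pos, 1))
        c_neg = self.C_neg if self.C_neg is not None else self.C * n / (2.0 * max(n_neg, 1))
        return float(c_pos), float(c_neg)


@dataclass
class DualWeights:
    """Per-sample nonnegative mining weights u_i = alpha_i + k*beta_i."""

    u: np.ndarray


@dataclass
class RuleModel:
    """Sparse weighted rule set: f(x) = sum_j a_j h_j(x) + b."""

    rules: list[ConjunctionRule]
    weights: np.ndarray
    bias: float
    cutpoints: CutpointTable
    config: FitConfig
    feature_names: list[str] = field(default_factory=list)
    objective_trajectory: list[float] = field(default_factory=list)
    n_iterations: int = 0

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        s = np.full(X.shape[0], self.bias, dtype=float)
        for a, r in zip(self.weights, self.rules):
            s += a * r.activations(X)
        return s

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Hard labels at rejection rate 0: sign of the score (0 -> -1)."""
        s = self.score(X)
        return np.where(s > 0, 1, -1)


def double_hinge(z, d: float):
    """Double hinge loss phi(z) = max(0, 1-z, 1-((1-d)/d) z).

    Piecewise linear and convex: zero for z >= 1, slope -1 on [0, 1), and
    the steeper slope -(1-d)/d for z < 0.  At d = 0.5 it coincides with the
    ordinary hinge loss max(0, 1-z).
    """
    if not (0.0 < d <= 0.5):
        raise InvalidConfigurationError(f"rejection cost d must be in (0, 0.5], got {d}")
    z = np.asarray(z, dtype=float)
    k = (1.0 - d) / d
    out = np.maximum(0.0, np.maximum(1.0 - z, 1.0 - k * z))
    return float(out) if out.ndim == 0 else out


def objective(model: RuleModel, data: Dataset, cfg: FitConfig) -> float:
    """Primal objective value of a model on a dataset."""
    f = model.score(data.X)
    c_pos, c_neg = cfg.class_costs(data.y)
    pos = data.y == 1
    loss = c_pos * np.sum(double_hinge(f[pos], cfg.d)) + c_neg * np.sum(
        double_hinge(-f[~pos], cfg.d)
    )
    return float(np.sum(np.abs(model.weights)) + loss)


def solve_master(
    columns: list[np.ndarray],
    y: np.ndarray,
    cfg: FitConfig,
) -> tuple[np.ndarray, float, DualWeights, float]:
    """Solve the restricted master LP over the supplied rule-activation columns.

    Returns (weights a, bias b, duals, objective value).  The duals satisfy
    dual feasibility on every supplied column: |sum_i y_i u_i h_j(x_i)| <= 1
    up to lp_tolerance.
    """
    y = np.asarray(y, dtype=int)
    n = y.shape[0]
    if not (np.any(y == 1) and np.any(y == -1)):
        raise UnfittableError("both classes must be present")
    m = len(columns)
    H = np.stack([np.asarray(c, dtype=float) for c in columns], axis=1) if m else np.zeros((n, 0))
    k = cfg.k
    c_pos, c_neg = cfg.class_costs(y)
    C_i = np.where(y == 1, c_pos, c_neg)

    # variables: [a+ (m), a- (m), b+, b-, xi (n)]
    nvar = 2 * m + 2 + n
    cost = np.concatenate([np.ones(2 * m), [0.0, 0.0], C_i])
    yH = y[:, None] * H  # (n, m)
    eye = np.eye(n)
    # xi_i >= 1 - z_i   ->  -z_i - xi_i <= -1
    A1 = np.hstack([-yH, yH, -y[:, None], y[:, None], -eye])
    # xi_i >= 1 - k z_i ->  -k z_i - xi_i <= -1
    A2 = np.hstack([-k * yH, k * yH, -k * y[:, None], k * y[:, None], -eye])
    A_ub = np.vstack([A1, A2])
    b_ub = -np.ones(2 * n)
    res = linprog(cost, A_ub=A_ub, b_ub=b_ub, bounds=[(0, None)] * nvar, method="highs")
    if not res.success:
        raise MasterSolverError(f"master LP failed: {res.message}")
    x = res.x
    a = x[:m] - x[m : 2 * m]
    b = float(x[2 * m] - x[2 * m + 1])
    marg = res.ineqlin.marginals
    alpha = np.clip(-marg[:n], 0.0, None)
    beta = np.clip(-marg[n:], 0.0, None)
    u = alpha + k * beta
    return a, b, DualWeights(u=u), float(res.fun)


class _Miner:
    """Depth-first branch-and-bound search for the max |weighted cover sum| itemset.

    The bound at a node with cover V is max(sum of positive w in V,
    -sum of negative w in V): anti-monotone under cover shrinkage, so it
    prunes without ever cutting the optimum.  Items are explored in
    catalogue order and the incumbent is replaced only on strict
    improvement, which breaks ties toward the smallest itemset under
    catalogue order.
    """

    def __init__(self, transactions: TransactionMatrix, w: np.ndarray, max_order: int):
        self.inc = transactions.incidence
        self.catalogue = transactions.catalogue
        self.w = w
        self.w_pos = np.where(w > 0, w, 0.0)
        self.w_neg = np.where(w < 0, w, 0.0)
        self.max_order = max_order
        self.best_gain = 0.0
        self.best_items: tuple[int, ...] | None = None

    def run(self) -> tuple[tuple[int, ...] | None, float]:
        n, m = self.inc.shape
        all_rows = np.arange(n)
        self._extend((), all_rows, 0)
        return self.best_items, self.best_gain

    def _extend(self, items: tuple[int, ...], cover: np.ndarray, start: int) -> None:
        for kk in range(start, len(self.catalogue)):
            if items and self._redundant(items, kk):
                continue
            sub = cover[self.inc[cover, kk]]
            if sub.size == 0:
                continue
            gain = abs(float(np.sum(self.w[sub])))
            if gain > self.best_gain + 1e-15:
                self.best_gain = gain
                self.best_items = items + (kk,)
            if len(items) + 1 < self.max_order:
                bound = max(
                    float(np.sum(self.w_pos[sub])), -float(np.sum(self.w_neg[sub]))
                )
                if bound > self.best_gain + 1e-15:
                    self._extend(items + (kk,), sub, kk + 1)

    def _redundant(self, items: tuple[int, ...], kk: int) -> bool:
        # a second item with the same feature+direction never changes the
        # cover beyond what the tighter item alone achieves; skip it so ties
        # resolve to the smaller itemset
        cand = self.catalogue[kk]
        return any(
            self.catalogue[i].feature == cand.feature
            and self.catalogue[i].direction == cand.direction
            for i in items
        )


def find_best_rule(
    transactions: TransactionMatrix,
    y: np.ndarray,
    duals: DualWeights,
    max_order: int,
    tolerance: float = 1e-6,
):
    """Pricing oracle: the itemset maximizing g(S) = |sum_{i in cover(S)} y_i u_i|.

    Returns ``(itemset, gain)`` with the itemset as a tuple of catalogue
    indices, or ``None`` when the best gain is <= 1 + tolerance — i.e. no
    dual constraint is violated and column generation has converged.
    """
    w = np.asarray(y, dtype=float) * duals.u
    if transactions.m == 0 or not np.any(w):
        return None
    miner = _Miner(transactions, w, max_order)
    items, gain = miner.run()
    if items is None or gain <= 1.0 + tolerance:
        return None
    return items, gain


def fit(data: Dataset, cfg: FitConfig | None = None) -> RuleModel:
    """Train a sparse rule ensemble by column generation.

    Starts from the bias-only master problem and, each iteration, adds the
    single rule whose dual constraint is most violated (found by the
    branch-and-bound miner), until no violated constraint remains or
    ``max_iterations`` is reached.  On exhaustively enumerable instances
    the final objective equals the full-LP optimum.
    """
    cfg = cfg or FitConfig()
    if not (np.any(data.y == 1) and np.any(data.y == -1)):
        raise UnfittableError("both classes must be present in y")
    cutpoints = build_cutpoints(data.X, cfg.bins)
    transactions = build_transactions(data.X, cutpoints)
    if transactions.m == 0:
        raise UnfittableError("all features are constant; no rules can be formed")

    columns: list[np.ndarray] = []
    rules: list[ConjunctionRule] = []
    trajectory: list[float] = []
    seen: set[tuple[int, ...]] = set()
    a = np.zeros(0)
    b = 0.0
    it = 0
    while True:
        a, b, duals, obj = solve_master(columns, data.y, cfg)
        trajectory.append(obj)
        if it >= cfg.max_iterations:
            break
        found = find_best_rule(
            transactions, data.y, duals, cfg.max_rule_order, cfg.pricing_tolerance
        )
        if found is None:
            break
        items, _gain = found
        if items in seen:  # numerically stalled pricing; terminate
            break
        seen.add(items)
        rule = reduce_itemset([transactions.catalogue[k] for k in items])
        if rule is EMPTY:  # cannot happen: empty covers are pruned in the miner
            break
        columns.append(rule.activations(data.X))
        rules.append(rule)
        it += 1

    keep = np.abs(a) > 1e-12 if a.size else np.zeros(0, dtype=bool)
    model = RuleModel(
        rules=[r for r, k in zip(rules, keep) if k],
        weights=np.asarray(a)[keep] if a.size else np.zeros(0),
        bias=b,
        cutpoints=cutpoints,
        config=cfg,
        feature_names=list(data.feature_names),
        objective_trajectory=trajectory,
        n_iterations=it,
    )
    return model
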