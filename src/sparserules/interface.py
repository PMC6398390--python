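"""Model serialization, per-subject explanations, visualization and CV harness.

Models serialize to a versioned JSON document (human-auditable, matching
the interpretability mission).  An Explanation decomposes a subject's
score exactly into the sum of active rule weights plus the bias, and the
intersection-matrix renderer lays rules out as columns over feature rows,
with each rule's selected intervals marked — the structured layout
description emitted alongside the image is the machine-checkable surface.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .optimizer import FitConfig, RuleModel
from .rejection import CalibratedModel, IsotonicMap, metrics as _metrics
from .rulespace import ConjunctionRule, CutpointTable, Dataset

__all__ = [
    "FORMAT_VERSION",
    "save_model",
    "load_model",
    "Explanation",
    "explain",
    "render_intersection_matrix",
    "cv_evaluate",
    "train_test_evaluate",
]

FORMAT_VERSION = 1


class ModelFileError(ValueError):
    """Corrupt or unsupported model file."""


def _rule_to_json(rule: ConjunctionRule) -> list[dict]:
    return [
        {"feature": int(j), "lo": None if math.isinf(lo) else lo, "hi": None if math.isinf(hi) else hi}
        for j, lo, hi in rule.intervals
    ]


def _rule_from_json(obj: list[dict]) -> ConjunctionRule:
    return ConjunctionRule.from_dict(
        {
            int(d["feature"]): (
                -np.inf if d["lo"] is None else float(d["lo"]),
                np.inf if d["hi"] is None else float(d["hi"]),
            )
            for d in obj
        }
    )


def save_model(model: RuleModel | CalibratedModel, path) -> None:
    """Write a model to versioned JSON; lossless round trip guaranteed."""
    cal = None
    if isinstance(model, CalibratedModel):
        cal = {
            "x": [float(v) for v in model.calibration_map.x],
            "y": [float(v) for v in model.calibration_map.y],
            "folds": model.folds,
            "seed": model.seed,
        }
        base = model.base
    else:
        base = model
    doc = {
        "format_version": FORMAT_VERSION,
        "cutpoints": {
            "bin_count": base.cutpoints.bin_count,
            "cuts": [[float(c) for c in cc] for cc in base.cutpoints.cuts],
        },
        "rules": [_rule_to_json(r) for r in base.rules],
        "weights": [float(w) for w in base.weights],
        "bias": float(base.bias),
        "config": {
            "C": base.config.C,
            "C_pos": base.config.C_pos,
            "C_neg": base.config.C_neg,
            "d": base.config.d,
            "bins": base.config.bins,
            "max_rule_order": base.config.max_rule_order,
            "max_iterations": base.config.max_iterations,
            "pricing_tolerance": base.config.pricing_tolerance,
            "lp_tolerance": base.config.lp_tolerance,
            "seed": base.config.seed,
        },
        "feature_names": list(base.feature_names),
        "calibration": cal,
        "provenance": {
            "seed": base.config.seed,
            "n_iterations": base.n_iterations,
            "objective_trajectory": [float(v) for v in base.objective_trajectory],
            "model_hash": None,
        },
    }
    payload = json.dumps(doc, sort_keys=True).encode()
    doc["provenance"]["model_hash"] = hashlib.sha256(payload).hexdigest()
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def load_model(path) -> RuleModel | CalibratedModel:
    """Load a model JSON; returns CalibratedModel when a calibration map is stored."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelFileError(f"corrupt model file {path}: {exc}") from exc
    version = doc.get("format_version")
    if version != FORMAT_VERSION:
        raise ModelFileError(
            f"unsupported model format version {version!r} (supported: {FORMAT_VERSION})"
        )
    cfg = FitConfig(**doc["config"])
    base = RuleModel(
        rules=[_rule_from_json(r) for r in doc["rules"]],
        weights=np.asarray(doc["weights"], dtype=float),
        bias=float(doc["bias"]),
        cutpoints=CutpointTable(
            cuts=[np.asarray(c, dtype=float) for c in doc["cutpoints"]["cuts"]],
            bin_count=int(doc["cutpoints"]["bin_count"]),
        ),
        config=cfg,
        feature_names=list(doc["feature_names"]),
        objective_trajectory=list(doc["provenance"]["objective_trajectory"]),
        n_iterations=int(doc["provenance"]["n_iterations"]),
    )
    cal = doc.get("calibration")
    if cal is None:
        return base
    return CalibratedModel(
        base=base,
        calibration_map=IsotonicMap(
            x=np.asarray(cal["x"], dtype=float), y=np.asarray(cal["y"], dtype=float)
        ),
        folds=int(cal["folds"]),
        seed=int(cal["seed"]),
    )


@dataclass
class Explanation:
    """Exact decomposition of one subject's score into rule contributions.

    ``score == sum of active weights + bias`` to machine equality on the
    stored weights.  When ``truncated`` is set, fewer rules are displayed
    than the model holds, so the displayed contributions need not sum to
    the full score.
    """

    rule_order: list[int]  # model rule indices sorted by |weight| desc
    weights: list[float]
    activations: list[int]
    intervals: list[list[dict]]
    feature_values: list[float]
    bias: float
    score: float
    truncated: bool
    eta: float | None = None
    decision: int | None = None
    displayed_rules: int = 0


def explain(model: RuleModel | CalibratedModel, x, top_k: int = 10) -> Explanation:
    """Explain one prediction: activations, contributions, score decomposition."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    base = model.base if isinstance(model, CalibratedModel) else model
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != len(base.feature_names):
        raise ValueError(
            f"feature vector has {x.shape[0]} entries, model expects {len(base.feature_names)}"
        )
    acts = [int(r.activations(x[None, :])[0]) for r in base.rules]
    score = float(base.bias + sum(w * a for w, a in zip(base.weights, acts)))
    order = sorted(range(len(base.rules)), key=lambda j: -abs(base.weights[j]))
    shown = order[:top_k]
    eta = decision = None
    if isinstance(model, CalibratedModel):
        eta = float(model.calibration_map(score)[0])
        from .rejection import decide

        decision = int(decide(np.array([eta]), base.config.d)[0])
    return Explanation(
        rule_order=order,
        weights=[float(base.weights[j]) for j in order],
        activations=[acts[j] for j in order],
        intervals=[_rule_to_json(base.rules[j]) for j in order],
        feature_values=[float(v) for v in x],
        bias=float(base.bias),
        score=score,
        truncated=len(shown) < len(base.rules),
        eta=eta,
        decision=decision,
        displayed_rules=len(shown),
    )


def _layout(model: RuleModel, explanations: list[Explanation]) -> dict:
    """Structured description of the intersection-matrix figure."""
    order = sorted(range(len(model.rules)), key=lambda j: -abs(model.weights[j]))
    columns = []
    for j in order:
        columns.append(
            {
                "rule_index": j,
                "importance": abs(float(model.weights[j])),
                "weight": float(model.weights[j]),
                "cells": _rule_to_json(model.rules[j]),
            }
        )
    return {
        "rows": list(model.feature_names),
        "columns": columns,
        "subjects": [
            {
                "feature_values": e.feature_values,
                "score": e.score,
                "activations": e.activations,
            }
            for e in explanations
        ],
    }


def render_intersection_matrix(
    model: RuleModel | CalibratedModel, explanations: list[Explanation], path
) -> dict:
    """Render the rules-by-features intersection matrix and return its layout.

    Rows are features, columns are rules sorted by importance (|weight|);
    each cell marks the rule's selected interval on that feature, with an
    importance bar per rule and, per explained subject, value markers and
    a score pointer.  The returned layout dict (also written as a JSON
    sidecar next to the image) is the testable contract; pixels are not.
    """
    if not explanations:
        raise ValueError("at least one explanation is required")
    base = model.base if isinstance(model, CalibratedModel) else model
    layout = _layout(base, explanations)

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_rules = max(len(layout["columns"]), 1)
    n_feat = len(layout["rows"])
    fig, (ax_bar, ax) = plt.subplots(
        2,
        1,
        figsize=(1.2 + 0.9 * n_rules, 1.5 + 0.45 * n_feat),
        gridspec_kw={"height_ratios": [1, 4]},
        sharex=True,
    )
    importances = [c["importance"] for c in layout["columns"]]
    ax_bar.bar(range(len(importances)), importances, color="#4878cf")
    ax_bar.set_ylabel("|weight|")
    ax_bar.set_title("rule importance")
    for ci, col in enumerate(layout["columns"]):
        involved = {c["feature"] for c in col["cells"]}
        for fi in range(n_feat):
            color = "#f4a7a3" if fi in involved else "#b8d8b8"
            ax.add_patch(
                plt.Circle((ci, fi), 0.28, color=color, zorder=1)
            )
        for cell in col["cells"]:
            fi = cell["feature"]
            lo = cell["lo"] if cell["lo"] is not None else -1
            hi = cell["hi"] if cell["hi"] is not None else 1
            ax.plot([ci - 0.2, ci + 0.2], [fi, fi], color="#8b0000", lw=3, zorder=2)
            ax.annotate(
                f"[{lo:.2g},{hi:.2g}]",
                (ci, fi + 0.32),
                ha="center",
                fontsize=6,
                zorder=3,
            )
    ax.set_yticks(range(n_feat))
    ax.set_yticklabels(layout["rows"], fontsize=7)
    ax.set_xticks(range(n_rules))
    ax.set_xticklabels([f"R{c['rule_index']}" for c in layout["columns"]], fontsize=7)
    ax.set_xlim(-0.6, n_rules - 0.4)
    ax.set_ylim(-0.6, n_feat - 0.4)
    ax.invert_yaxis()
    ax.set_title(
        "; ".join(f"subject score = {s['score']:+.3f}" for s in layout["subjects"][:3])
    )
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    sidecar = str(path) + ".layout.json"
    with open(sidecar, "w") as fh:
        json.dump(layout, fh, indent=1)
    return layout


def _eval_fold(model: RuleModel, X, y) -> dict:
    scores = model.score(X)
    decisions = np.where(scores > 0, 1, -1)
    etas = 1.0 / (1.0 + np.exp(-scores))  # rank-preserving squash for AUC only
    m = _metrics(decisions, y, etas)
    return {"SN": m.sensitivity, "SP": m.specificity, "ACC": m.accuracy, "AUC": m.auc}


def cv_evaluate(
    data: Dataset,
    cfg: FitConfig,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeated stratified k-fold CV; mean and SD of SN/SP/ACC/AUC across folds x repeats."""
    from sklearn.model_selection import StratifiedKFold

    from .optimizer import fit as _fit

    if folds < 2 or repeats < 1:
        raise ValueError("need folds >= 2 and repeats >= 1")
    counts = [int(np.sum(data.y == c)) for c in (-1, 1)]
    if min(counts) < folds:
        raise ValueError(
            f"cannot stratify {folds} folds: smallest class has {min(counts)} samples"
        )
    rows = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        for tr, te in skf.split(data.X, data.y):
            sub = Dataset(data.X[tr], data.y[tr], list(data.feature_names))
            model = _fit(sub, cfg)
            rows.append(_eval_fold(model, data.X[te], data.y[te]))
    df = pd.DataFrame(rows)
    return pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)})


def train_test_evaluate(
    data: Dataset, cfg: FitConfig, test_fraction: float = 1 / 3, seed: int = 0
) -> dict:
    """Single stratified train/test split (default 2/3 train, 1/3 test)."""
    from sklearn.model_selection import train_test_split

    from .optimizer import fit as _fit

    idx = np.arange(data.n)
    tr, te = train_test_split(
        idx, test_size=test_fraction, stratify=data.y, random_state=seed
    )
    model = _fit(Dataset(data.X[tr], data.y[tr], list(data.feature_names)), cfg)
    return _eval_fold(model, data.X[te], data.y[te])
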