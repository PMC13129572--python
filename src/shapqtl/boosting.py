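"""Gradient-boosted regression trees with a transparent tree structure.

Fitting is delegated to xgboost (squared-error objective); this module owns
the hyperparameter presets and a lossless structural dump (split features,
thresholds, children, leaf weights, covers) that the Shapley engine
traverses.  Routing convention everywhere: a feature value strictly less
than the threshold goes left.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import xgboost as xgb

__all__ = [
    "BoostConfig",
    "Tree",
    "TreeEnsemble",
    "fit_ensemble",
    "predict",
    "extract_structure",
]


@dataclass(frozen=True)
class BoostConfig:
    """Boosting hyperparameters; presets pin the three fitting regimes.

    ``moderate`` keeps the library defaults (learning rate 0.3, depth 6, L2
    penalty 1, gamma 0, no subsampling) with early stopping after 3 stalled
    rounds; ``underfit`` lowers the rate to 0.1 and depth to 3; ``overfit``
    runs exactly 50 rounds with no early stopping.
    """

    learning_rate: float = 0.3
    max_depth: int = 6
    early_stopping_rounds: int | None = 3
    max_rounds: int = 200
    preset: str = "moderate"
    reg_lambda: float = 1.0
    gamma: float = 0.0

    @classmethod
    def moderate(cls) -> "BoostConfig":
        return cls()

    @classmethod
    def underfit(cls) -> "BoostConfig":
        return cls(learning_rate=0.1, max_depth=3, preset="underfit")

    @classmethod
    def overfit(cls) -> "BoostConfig":
        return cls(early_stopping_rounds=None, max_rounds=50, preset="overfit")

    @classmethod
    def from_preset(cls, name: str) -> "BoostConfig":
        try:
            return {"moderate": cls.moderate, "underfit": cls.underfit, "overfit": cls.overfit}[
                name
            ]()
        except KeyError:
            raise ValueError(f"unknown preset {name!r}") from None


@dataclass
class Tree:
    """One regression tree in flat-array form; node 0 is the root.

    ``feature[k] == -1`` marks a leaf; internal nodes carry a threshold and
    child ids, leaves carry a weight.  ``cover`` is the training-weight mass
    (hessian sum; instance count under squared error) reaching each node.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    cover: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.feature.size

    def used_features(self) -> set[int]:
        return set(self.feature[self.feature >= 0].tolist())

    def predict_one(self, x: np.ndarray) -> float:
        k = 0
        while self.feature[k] >= 0:
            k = self.left[k] if x[self.feature[k]] < self.threshold[k] else self.right[k]
        return float(self.value[k])


@dataclass
class TreeEnsemble:
    """Additive ensemble: prediction = base_prediction + sum of tree outputs.

    ``booster`` (if present) is the fitted xgboost handle used for fast SHAP
    computation; the flat trees are authoritative for structure.
    """

    trees: list[Tree]
    base_prediction: float
    n_features: int
    booster: xgb.Booster | None = field(default=None, repr=False)
    n_rounds_used: int = 0

    def used_features(self) -> set[int]:
        out: set[int] = set()
        for t in self.trees:
            out |= t.used_features()
        return out


def _parse_dump(tree_json: str) -> Tree:
    """Flatten one tree of an xgboost JSON dump (with_stats) into arrays."""
    nodes: dict[int, dict] = {}

    def walk(d: dict) -> None:
        nodes[d["nodeid"]] = d
        for ch in d.get("children", []):
            walk(ch)

    walk(json.loads(tree_json))
    n = len(nodes)
    ids = sorted(nodes)
    remap = {nid: k for k, nid in enumerate(ids)}
    feature = np.full(n, -1, dtype=np.int64)
    threshold = np.zeros(n)
    left = np.full(n, -1, dtype=np.int64)
    right = np.full(n, -1, dtype=np.int64)
    value = np.zeros(n)
    cover = np.zeros(n)
    for nid in ids:
        d = nodes[nid]
        k = remap[nid]
        cover[k] = d["cover"]
        if "leaf" in d:
            value[k] = d["leaf"]
        else:
            feature[k] = int(str(d["split"]).lstrip("f"))
            threshold[k] = d["split_condition"]
            left[k] = remap[d["yes"]]
            right[k] = remap[d["no"]]
    return Tree(feature, threshold, left, right, value, cover)


def extract_structure(booster: xgb.Booster, n_rounds: int | None = None) -> TreeEnsemble:
    """Dump a fitted booster into a TreeEnsemble (first ``n_rounds`` trees)."""
    if booster.num_boosted_rounds() == 0:
        raise ValueError("booster has no fitted trees")
    dumps = booster.get_dump(dump_format="json", with_stats=True)
    if n_rounds is None:
        n_rounds = len(dumps)
    cfg = json.loads(booster.save_config())
    base = float(cfg["learner"]["learner_model_param"]["base_score"])
    trees = [_parse_dump(d) for d in dumps[:n_rounds]]
    return TreeEnsemble(
        trees=trees,
        base_prediction=base,
        n_features=booster.num_features(),
        booster=booster,
        n_rounds_used=n_rounds,
    )


def fit_ensemble(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_valid: np.ndarray | None = None,
    y_valid: np.ndarray | None = None,
    config: BoostConfig | None = None,
    rng_seed: int = 0,
) -> TreeEnsemble:
    """Fit squared-error boosted trees, with early stopping on held-out RMSE.

    When early stopping is enabled the returned ensemble is truncated to the
    best validation iteration.  The base prediction is the training-phenotype
    mean, so leaf weights model deviations from it.
    """
    if config is None:
        config = BoostConfig.moderate()
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    if X_train.shape[0] == 0:
        raise ValueError("empty training set")
    params = {
        "objective": "reg:squarederror",
        "eta": config.learning_rate,
        "max_depth": config.max_depth,
        "lambda": config.reg_lambda,
        "gamma": config.gamma,
        "subsample": 1.0,
        "colsample_bytree": 1.0,
        "base_score": float(y_train.mean()),
        "eval_metric": "rmse",
        "nthread": 1,
        "seed": int(rng_seed),
    }
    dtrain = xgb.DMatrix(X_train, label=y_train)
    if config.early_stopping_rounds is not None:
        if X_valid is None or y_valid is None or len(np.asarray(y_valid)) == 0:
            raise ValueError("early stopping requires a non-empty validation set")
        dvalid = xgb.DMatrix(np.asarray(X_valid, dtype=float), label=np.asarray(y_valid, dtype=float))
        booster = xgb.train(
            params,
            dtrain,
            num_boost_round=config.max_rounds,
            evals=[(dvalid, "valid")],
            early_stopping_rounds=config.early_stopping_rounds,
            verbose_eval=False,
        )
        n_rounds = booster.best_iteration + 1
    else:
        booster = xgb.train(params, dtrain, num_boost_round=config.max_rounds)
        n_rounds = config.max_rounds
    return extract_structure(booster, n_rounds)


def predict(ensemble: TreeEnsemble, X: np.ndarray) -> np.ndarray:
    """Route rows of X through the stored trees and sum leaf weights."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != ensemble.n_features:
        raise ValueError(
            f"X has {X.shape[1]} features, ensemble expects {ensemble.n_features}"
        )
    out = np.full(X.shape[0], ensemble.base_prediction)
    for tree in ensemble.trees:
        node = np.zeros(X.shape[0], dtype=np.int64)
        active = tree.feature[node] >= 0
        while active.any():
            idx = np.flatnonzero(active)
            k = node[idx]
            goes_left = X[idx, tree.feature[k]] < tree.threshold[k]
            node[idx] = np.where(goes_left, tree.left[k], tree.right[k])
            active[idx] = tree.feature[node[idx]] >= 0
        out += tree.value[node]
    return out
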