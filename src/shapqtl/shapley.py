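"""SHAP values and SHAP interaction values for tree ensembles.

Two routes are provided.  The exact route enumerates feature subsets and
applies the Shapley weights directly to the tree-conditional expectations
(the cooperative-game definition, with the cover-weighted path-dependent
expectation as value function).  The fast route (:func:`tree_shap`,
:func:`tree_shap_interactions`) delegates to the fitting library's exact
tree-SHAP output when a fitted booster is attached to the ensemble, and
falls back to the enumeration otherwise.  The exact route is the oracle the
fast route is validated against.

Value function: E[f(x) | x_S] per tree — at a node splitting on a feature in
S the traversal follows x's branch; at any other node it takes the
cover-weighted average of both children.  Features that appear in no tree
are dummy players: they receive zero attribution and do not perturb the
others, which lets the enumeration run over the ensemble's used features
only.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
import xgboost as xgb

from .boosting import Tree, TreeEnsemble, predict

__all__ = [
    "ShapVector",
    "ShapInteractionMatrix",
    "conditional_expectation",
    "shapley_exact",
    "shapley_interactions_exact",
    "tree_shap",
    "tree_shap_interactions",
]

EXACT_GUARD_MAIN = 15
EXACT_GUARD_INTERACTION = 12


@dataclass(frozen=True)
class ShapVector:
    """Per-feature attributions phi_i for one instance, plus the base value.

    Local accuracy: base_value + sum(phi) equals the model prediction.
    """

    phi: np.ndarray
    base_value: float


@dataclass(frozen=True)
class ShapInteractionMatrix:
    """Symmetric p x p attribution matrix for one instance.

    Off-diagonal entries are the pairwise interaction values phi_ij (each
    pair's total effect is 2 phi_ij); the diagonal carries the main effects
    phi_ii, defined so every row sums to the feature's phi_i.
    """

    phi_ij: np.ndarray
    base_value: float

    @property
    def phi(self) -> np.ndarray:
        return self.phi_ij.sum(axis=1)


def _tree_expectation(tree: Tree, x: np.ndarray, in_S: np.ndarray, node: int = 0) -> float:
    f = tree.feature[node]
    if f < 0:
        return float(tree.value[node])
    left, right = tree.left[node], tree.right[node]
    if in_S[f]:
        child = left if x[f] < tree.threshold[node] else right
        return _tree_expectation(tree, x, in_S, child)
    cl, cr = tree.cover[left], tree.cover[right]
    return (
        cl * _tree_expectation(tree, x, in_S, left)
        + cr * _tree_expectation(tree, x, in_S, right)
    ) / (cl + cr)


def conditional_expectation(
    ensemble: TreeEnsemble, x: np.ndarray, S: set[int] | frozenset[int]
) -> float:
    """E[f(x) | x_S]: condition on the features in S, average out the rest."""
    x = np.asarray(x, dtype=float)
    in_S = np.zeros(ensemble.n_features, dtype=bool)
    if S:
        in_S[list(S)] = True
    total = ensemble.base_prediction
    for tree in ensemble.trees:
        total += _tree_expectation(tree, x, in_S)
    return total


class _ValueTable:
    """Memoised v(S) over subsets of the ensemble's used features."""

    def __init__(self, ensemble: TreeEnsemble, x: np.ndarray):
        self.ensemble = ensemble
        self.x = np.asarray(x, dtype=float)
        self.used = sorted(ensemble.used_features())
        self.pos = {f: k for k, f in enumerate(self.used)}
        self._cache: dict[int, float] = {}

    def mask(self, S: frozenset[int]) -> int:
        m = 0
        for f in S:
            if f in self.pos:
                m |= 1 << self.pos[f]
        return m

    def value(self, S: frozenset[int]) -> float:
        m = self.mask(S)
        if m not in self._cache:
            in_S = np.zeros(self.ensemble.n_features, dtype=bool)
            for f, k in self.pos.items():
                if m >> k & 1:
                    in_S[f] = True
            total = self.ensemble.base_prediction
            for tree in self.ensemble.trees:
                total += _tree_expectation(tree, self.x, in_S)
            self._cache[m] = total
        return self._cache[m]


def _subsets(items: list[int]):
    n = len(items)
    for m in range(1 << n):
        yield frozenset(items[k] for k in range(n) if m >> k & 1)


def shapley_exact(
    ensemble: TreeEnsemble, x: np.ndarray, guard: int = EXACT_GUARD_MAIN
) -> ShapVector:
    """Brute-force Shapley values by subset enumeration.

    phi_i = sum over S not containing i of |S|!(M-|S|-1)!/M! times
    [v(S + i) - v(S)].  Enumeration runs over the used features (dummy
    features get exactly zero); M is their count, which leaves phi unchanged
    because dummies contribute nothing to any marginal.
    """
    table = _ValueTable(ensemble, x)
    used = table.used
    M = len(used)
    if M > guard:
        raise ValueError(
            f"{M} active features exceeds the enumeration guard ({guard}); "
            "use tree_shap for large ensembles"
        )
    phi = np.zeros(ensemble.n_features)
    w = [factorial(s) * factorial(M - s - 1) / factorial(M) for s in range(M)]
    for i in used:
        rest = [f for f in used if f != i]
        for S in _subsets(rest):
            phi[i] += w[len(S)] * (table.value(S | {i}) - table.value(S))
    return ShapVector(phi=phi, base_value=table.value(frozenset()))


def shapley_interactions_exact(
    ensemble: TreeEnsemble, x: np.ndarray, guard: int = EXACT_GUARD_INTERACTION
) -> ShapInteractionMatrix:
    """Brute-force Shapley interaction matrix by subset enumeration.

    Off-diagonal: phi_ij = sum over S excluding i,j of
    |S|!(M-|S|-2)!/(2(M-1)!) times delta_ij(S), with
    delta_ij(S) = v(S+ij) - v(S+i) - v(S+j) + v(S).  Diagonal:
    phi_ii = phi_i - sum_{j != i} phi_ij.
    """
    table = _ValueTable(ensemble, x)
    used = table.used
    M = len(used)
    if M > guard:
        raise ValueError(
            f"{M} active features exceeds the enumeration guard ({guard}); "
            "use tree_shap_interactions for large ensembles"
        )
    p = ensemble.n_features
    phi_ij = np.zeros((p, p))
    if M >= 2:
        w2 = [
            factorial(s) * factorial(M - s - 2) / (2.0 * factorial(M - 1))
            for s in range(M - 1)
        ]
        for a in range(M):
            for b in range(a + 1, M):
                i, j = used[a], used[b]
                rest = [f for f in used if f != i and f != j]
                val = 0.0
                for S in _subsets(rest):
                    delta = (
                        table.value(S | {i, j})
                        - table.value(S | {i})
                        - table.value(S | {j})
                        + table.value(S)
                    )
                    val += w2[len(S)] * delta
                phi_ij[i, j] = phi_ij[j, i] = val
    sv = shapley_exact(ensemble, x, guard=max(guard, EXACT_GUARD_MAIN))
    off = phi_ij.sum(axis=1)
    phi_ij[np.arange(p), np.arange(p)] = sv.phi - off
    return ShapInteractionMatrix(phi_ij=phi_ij, base_value=sv.base_value)


def _booster_range(ensemble: TreeEnsemble) -> tuple[int, int]:
    return (0, ensemble.n_rounds_used or len(ensemble.trees))


def tree_shap(ensemble: TreeEnsemble, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fast per-row SHAP values; returns (phi: n x p, base_values: n).

    With a fitted booster attached, delegates to its exact path-dependent
    tree-SHAP contributions; otherwise falls back to subset enumeration
    (small ensembles only).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if ensemble.booster is not None:
        contrib = ensemble.booster.predict(
            xgb.DMatrix(X), pred_contribs=True, iteration_range=_booster_range(ensemble)
        )
        return contrib[:, :-1].astype(float), contrib[:, -1].astype(float)
    phi = np.empty((X.shape[0], ensemble.n_features))
    base = np.empty(X.shape[0])
    for r in range(X.shape[0]):
        sv = shapley_exact(ensemble, X[r])
        phi[r], base[r] = sv.phi, sv.base_value
    return phi, base


def tree_shap_interactions(
    ensemble: TreeEnsemble, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Fast per-row SHAP interaction tensors; returns (n x p x p, base: n)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if ensemble.booster is not None:
        inter = ensemble.booster.predict(
            xgb.DMatrix(X), pred_interactions=True, iteration_range=_booster_range(ensemble)
        )
        phi_ij = inter[:, :-1, :-1].astype(float)
        # the exact object is symmetric; remove float32 round-off asymmetry
        phi_ij = 0.5 * (phi_ij + phi_ij.transpose(0, 2, 1))
        return phi_ij, inter[:, -1, -1].astype(float)
    p = ensemble.n_features
    phi_ij = np.empty((X.shape[0], p, p))
    base = np.empty(X.shape[0])
    for r in range(X.shape[0]):
        sm = shapley_interactions_exact(ensemble, X[r])
        phi_ij[r], base[r] = sm.phi_ij, sm.base_value
    return phi_ij, base


def local_accuracy_gap(ensemble: TreeEnsemble, X: np.ndarray) -> float:
    """Max |base + sum(phi) - prediction| over rows — a diagnostic."""
    phi, base = tree_shap(ensemble, X)
    return float(np.abs(base + phi.sum(axis=1) - predict(ensemble, X)).max())
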