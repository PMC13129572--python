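import numpy as np
import pytest

from shapqtl.boosting import Tree, TreeEnsemble


def make_stump(
    feature: int,
    n_features: int,
    threshold: float = 0.0,
    left_val: float = -1.0,
    right_val: float = 1.0,
    left_cover: float = 50.0,
    right_cover: float = 50.0,
    base: float = 0.0,
) -> TreeEnsemble:
    """Single-split tree: x[feature] < threshold -> left_val else right_val."""
    tree = Tree(
        feature=np.array([feature, -1, -1]),
        threshold=np.array([threshold, 0.0, 0.0]),
        left=np.array([1, -1, -1]),
        right=np.array([2, -1, -1]),
        value=np.array([0.0, left_val, right_val]),
        cover=np.array([left_cover + right_cover, left_cover, right_cover]),
    )
    return TreeEnsemble(trees=[tree], base_prediction=base, n_features=n_features)


def make_xor_ensemble(n_features: int = 2) -> TreeEnsemble:
    """Depth-2 tree computing sign(x0) * sign(x1) with equal covers.

    Leaves: (x0<0, x1<0) -> +1, (x0<0, x1>=0) -> -1, (x0>=0, x1<0) -> -1,
    (x0>=0, x1>=0) -> +1.  Symmetric construction: both mains are zero and
    all signal sits in the pairwise interaction.
    """
    tree = Tree(
        feature=np.array([0, 1, 1, -1, -1, -1, -1]),
        threshold=np.array([0.0, 0.0, 0.0, 0, 0, 0, 0]),
        left=np.array([1, 3, 5, -1, -1, -1, -1]),
        right=np.array([2, 4, 6, -1, -1, -1, -1]),
        value=np.array([0.0, 0.0, 0.0, 1.0, -1.0, -1.0, 1.0]),
        cover=np.array([100.0, 50.0, 50.0, 25.0, 25.0, 25.0, 25.0]),
    )
    return TreeEnsemble(trees=[tree], base_prediction=0.0, n_features=n_features)


def random_fitted_ensemble(seed: int, max_depth: int = 3, p_max: int = 10):
    """Small xgboost-fitted ensemble on random genotype-like data."""
    from shapqtl.boosting import BoostConfig, fit_ensemble

    rng = np.random.default_rng(seed)
    p = int(rng.integers(3, p_max + 1))
    n = 60
    X = rng.choice([-1.0, 0.0, 1.0], (n, p))
    y = rng.normal(0, 0.5, n) + X[:, 0] + X[:, 1] * X[:, p - 1]
    cfg = BoostConfig(
        max_depth=max_depth,
        early_stopping_rounds=None,
        max_rounds=int(rng.integers(2, 7)),
        preset="overfit",
    )
    return fit_ensemble(X, y, config=cfg, rng_seed=seed), X


@pytest.fixture
def two_locus_map():
    """Single chromosome with two markers 10 cM apart."""
    from shapqtl.genetics import GeneticMap

    return GeneticMap([("1", 10.0)], [("A", "1", 0.0), ("B", "1", 10.0)])
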