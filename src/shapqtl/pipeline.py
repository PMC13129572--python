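"""The SHAP-assisted boosting pipeline for QTL mapping.

For each of ``n_boot`` bootstrap replicates: resample lines with replacement
(in-bag lines train the booster, out-of-bag lines drive early stopping),
then compute SHAP values and SHAP interaction values for *all* original
lines under that replicate's model.  Per-line values are averaged across
replicates; global marker scores are means of absolute averaged values
across lines:

* compound score of marker j — mean_i |mean_b phi_i(j)| (interactions folded
  into each marker's attribution),
* pure score — mean_i |mean_b phi_ii(j)| (main effects only),
* interaction score of pair (j, k) — mean_i |2 mean_b phi_ijk|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .boosting import BoostConfig, fit_ensemble, predict
from .shapley import tree_shap, tree_shap_interactions

__all__ = ["ShapXgbResult", "run_shap_xgb", "score_mode", "pair_scores"]

logger = logging.getLogger(__name__)


@dataclass
class ShapXgbResult:
    """Bootstrap-averaged local SHAP values and the global marker scores."""

    mean_phi: np.ndarray  # n x p
    mean_phi_main: np.ndarray  # n x p (diagonal phi_ii)
    mean_phi_int: np.ndarray | None  # n x p x p, None if interactions skipped
    mean_base: np.ndarray  # n
    mean_prediction: np.ndarray  # n
    global_compound: np.ndarray  # p
    global_pure: np.ndarray  # p
    global_interaction: np.ndarray | None  # p x p, zero diagonal
    n_boot: int
    seeds: list[int] = field(default_factory=list)


def _bootstrap_split(
    n: int, rng: np.random.Generator, max_redraw: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """In-bag indices (with replacement) and the out-of-bag complement."""
    for _ in range(max_redraw):
        in_bag = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), in_bag)
        if oob.size > 0:
            return in_bag, oob
        logger.warning("bootstrap replicate had empty out-of-bag set; redrawing")
    raise RuntimeError("could not draw a bootstrap sample with a non-empty OOB set")


def run_shap_xgb(
    X: np.ndarray,
    y: np.ndarray,
    config: BoostConfig | None = None,
    n_boot: int = 100,
    rng_seed: int = 0,
    compute_interactions: bool = True,
) -> ShapXgbResult:
    """Run the bootstrap SHAP-boosting pipeline on coded genotypes.

    ``compute_interactions=False`` skips the n x p x p interaction tensor
    (and hence the pure and interaction scores), which makes main-effect
    scans much faster on large marker panels.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 20:
        raise ValueError("need at least 20 lines")
    if p < 2:
        raise ValueError("need at least 2 markers")
    if not np.isfinite(y).all():
        raise ValueError("phenotypes must be finite")
    if config is None:
        config = BoostConfig.moderate()

    sum_phi = np.zeros((n, p))
    sum_base = np.zeros(n)
    sum_pred = np.zeros(n)
    sum_int = np.zeros((n, p, p)) if compute_interactions else None
    seeds = [int(rng_seed) + b for b in range(n_boot)]

    for b, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        in_bag, oob = _bootstrap_split(n, rng)
        if config.early_stopping_rounds is not None:
            ens = fit_ensemble(X[in_bag], y[in_bag], X[oob], y[oob], config, rng_seed=seed)
        else:
            ens = fit_ensemble(X[in_bag], y[in_bag], config=config, rng_seed=seed)
        phi, base = tree_shap(ens, X)
        sum_phi += phi
        sum_base += base
        sum_pred += predict(ens, X)
        if compute_interactions:
            phi_int, _ = tree_shap_interactions(ens, X)
            sum_int += phi_int

    mean_phi = sum_phi / n_boot
    mean_base = sum_base / n_boot
    mean_pred = sum_pred / n_boot
    if compute_interactions:
        mean_int = sum_int / n_boot
        mean_main = np.diagonal(mean_int, axis1=1, axis2=2).copy()
        global_pure = np.abs(mean_main).mean(axis=0)
        global_int = np.abs(2.0 * mean_int).mean(axis=0)
        np.fill_diagonal(global_int, 0.0)
    else:
        mean_int = None
        mean_main = np.full((n, p), np.nan)
        global_pure = np.full(p, np.nan)
        global_int = None

    return ShapXgbResult(
        mean_phi=mean_phi,
        mean_phi_main=mean_main,
        mean_phi_int=mean_int,
        mean_base=mean_base,
        mean_prediction=mean_pred,
        global_compound=np.abs(mean_phi).mean(axis=0),
        global_pure=global_pure,
        global_interaction=global_int,
        n_boot=n_boot,
        seeds=seeds,
    )


def score_mode(result: ShapXgbResult, mode: str = "compound") -> np.ndarray:
    """Select the global main-effect score vector: 'compound' or 'pure'."""
    if mode == "compound":
        return result.global_compound
    if mode == "pure":
        if result.mean_phi_int is None:
            raise ValueError("pure scores require interaction computation")
        return result.global_pure
    raise ValueError(f"unknown score mode {mode!r}")


def pair_scores(
    result: ShapXgbResult,
    marker_names: list[str] | None = None,
    positions: list[tuple[str, float]] | None = None,
    min_distance_cM: float = 0.0,
) -> list[tuple[int, int, float]]:
    """Upper-triangle interaction scores sorted descending.

    ``min_distance_cM`` (with marker ``positions`` as (chrom, cM)) drops
    pairs of nearby same-chromosome markers, a visualization aid for maps
    with tight linkage; by default nothing is dropped.  Returns (a, b,
    score) index triples with a < b; ``marker_names`` swaps indices for
    names.
    """
    if result.global_interaction is None:
        raise ValueError("pair scores require interaction computation")
    g = result.global_interaction
    p = g.shape[0]
    out = []
    for a in range(p):
        for b in range(a + 1, p):
            if min_distance_cM > 0 and positions is not None:
                ca, pa = positions[a]
                cb, pb = positions[b]
                if ca == cb and abs(pa - pb) < min_distance_cM:
                    continue
            name_a = marker_names[a] if marker_names else a
            name_b = marker_names[b] if marker_names else b
            out.append((name_a, name_b, float(g[a, b])))
    out.sort(key=lambda t: -t[2])
    return out
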