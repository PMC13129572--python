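"""Detection-performance evaluation for simulated QTL scenarios.

Markers within a +/-10 cM window of a QTL (same chromosome) are the
positives for main-effect detection; a marker pair is positive when its two
members tag the two distinct QTL of an interacting pair.  Global marker and
pair scores are then evaluated with ROC curves and AUC.

The nine study scenarios share one map layout (8 chromosomes x 120 cM, 20
uniformly placed markers each, 5 QTL, broad-sense heritability 0.8) and
vary population type (F2/RIL), gene action, population size, interaction
variance, the number of QTL with main effects, and QTL linkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .boosting import BoostConfig
from .genetics import GeneticMap, QTLLayout, make_map, place_qtls, simulate_f2, simulate_ril, split_markers
from .phenotypes import PhenotypeSet, QTLModel, add_noise, code_genotypes, draw_effects, genetic_values
from .pipeline import ShapXgbResult, run_shap_xgb
from . import pipeline as _pipeline

__all__ = [
    "ScenarioSpec",
    "SCENARIOS",
    "LabelSet",
    "ROCResult",
    "label_markers",
    "label_pairs",
    "roc_auc",
    "pair_auc",
    "ScenarioReplicate",
    "simulate_replicate",
    "run_scenario",
    "dependency_data",
]

N_CHROMOSOMES = 8
CHROM_LEN_CM = 120.0
MARKERS_PER_CHR = 20
H2_TARGET = 0.8


@dataclass(frozen=True)
class ScenarioSpec:
    pop_type: str  # "F2" or "RIL"
    action: str
    n: int
    interaction_sd: float = 1.0
    n_nonzero_main: int = 5
    linked: bool = False  # scenario 9 layout


SCENARIOS: dict[int, ScenarioSpec] = {
    1: ScenarioSpec("F2", "additive", 200),
    2: ScenarioSpec("RIL", "additive", 200),
    3: ScenarioSpec("F2", "complete_dominance", 200),
    4: ScenarioSpec("F2", "overdominance", 200),
    5: ScenarioSpec("F2", "additive", 200, interaction_sd=4.0),
    6: ScenarioSpec("F2", "additive", 200, n_nonzero_main=2),
    7: ScenarioSpec("F2", "additive", 400),
    8: ScenarioSpec("RIL", "additive", 400),
    9: ScenarioSpec("F2", "additive", 200, linked=True),
}


@dataclass(frozen=True)
class LabelSet:
    """Positive/negative labels for markers and marker pairs."""

    marker_labels: np.ndarray  # p bools
    pair_labels: np.ndarray  # p x p bools, symmetric, zero diagonal


def _marker_qtl_distance(gmap: GeneticMap, layout: QTLLayout) -> np.ndarray:
    """p x 5 matrix of same-chromosome cM distances (inf across chromosomes)."""
    p = gmap.n_markers
    dist = np.full((p, 5), np.inf)
    for m, (_, chrom, pos) in enumerate(gmap.markers):
        for q, (qc, qp) in enumerate(layout.qtl_loci):
            if qc == chrom:
                dist[m, q] = abs(pos - qp)
    return dist


def label_markers(gmap: GeneticMap, layout: QTLLayout, window_cM: float = 10.0) -> LabelSet:
    """Label markers (and pairs) positive within the QTL windows.

    A marker is positive iff it lies within ``window_cM`` (inclusive) of at
    least one QTL on the same chromosome.  A pair (a, b) is positive iff for
    some interacting QTL pair (q, r), one member tags q and the other tags r.
    """
    if window_cM < 0:
        raise ValueError("window must be non-negative")
    dist = _marker_qtl_distance(gmap, layout)
    near = dist <= window_cM  # p x 5
    marker_labels = near.any(axis=1)
    p = gmap.n_markers
    pair = np.zeros((p, p), dtype=bool)
    for q, r in layout.interacting_pairs:
        hit = np.outer(near[:, q], near[:, r])
        pair |= hit | hit.T
    np.fill_diagonal(pair, False)
    return LabelSet(marker_labels=marker_labels, pair_labels=pair)


def label_pairs(gmap: GeneticMap, layout: QTLLayout, window_cM: float = 10.0) -> np.ndarray:
    """Symmetric p x p positive-pair indicator (see :func:`label_markers`)."""
    return label_markers(gmap, layout, window_cM).pair_labels


def window_marker_counts(
    gmap: GeneticMap, layout: QTLLayout, window_cM: float = 10.0
) -> tuple[np.ndarray, int]:
    """Markers inside each QTL's window and the count outside all windows.

    Returns (per-window counts, length 5; number of markers not within
    ``window_cM`` of any QTL).  A marker falling in two overlapping windows
    is counted in both but only once for the outside tally.
    """
    near = _marker_qtl_distance(gmap, layout) <= window_cM
    return near.sum(axis=0), int((~near.any(axis=1)).sum())


@dataclass(frozen=True)
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC curve and AUC (rank statistic with half credit for ties)."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.all() or not labels.any():
        raise ValueError("AUC undefined: labels contain a single class")
    fpr, tpr, _ = roc_curve(labels, scores)
    return ROCResult(fpr=fpr, tpr=tpr, auc=float(roc_auc_score(labels, scores)))


def pair_auc(global_interaction: np.ndarray, pair_labels: np.ndarray) -> ROCResult:
    """AUC over the upper triangle of the pair score/label matrices."""
    iu = np.triu_indices_from(pair_labels, k=1)
    return roc_auc(global_interaction[iu], pair_labels[iu])


@dataclass
class ScenarioReplicate:
    """All inputs of one simulation replicate, before the mapping step."""

    gmap: GeneticMap
    layout: QTLLayout
    model: QTLModel
    phenotypes: PhenotypeSet
    X: np.ndarray  # n x p coded marker genotypes
    marker_dosages: np.ndarray
    labels: LabelSet


def simulate_replicate(
    scenario_id: int, rng_seed: int, window_cM: float = 10.0
) -> ScenarioReplicate:
    """Generate map, cross, effects and phenotypes for one replicate."""
    spec = SCENARIOS[scenario_id]
    rng = np.random.default_rng(rng_seed)
    gmap = make_map(N_CHROMOSOMES, CHROM_LEN_CM, MARKERS_PER_CHR, rng)
    layout = place_qtls(gmap, scenario_id, rng)
    simulate = simulate_f2 if spec.pop_type == "F2" else simulate_ril
    pop = simulate(gmap, layout, spec.n, rng)
    marker_dosages, qtl_dosages = split_markers(pop)
    model = draw_effects(
        layout,
        action=spec.action,
        interaction_sd=spec.interaction_sd,
        n_nonzero_main=spec.n_nonzero_main,
        rng_seed=rng,
    )
    z = code_genotypes(qtl_dosages, spec.action)
    main, inter = genetic_values(z, model)
    phen = add_noise(main, inter, H2_TARGET, rng_seed=rng)
    X = code_genotypes(marker_dosages, spec.action)
    labels = label_markers(gmap, layout, window_cM)
    return ScenarioReplicate(gmap, layout, model, phen, X, marker_dosages, labels)


def run_scenario(
    scenario_id: int,
    n_reps: int = 10,
    master_seed: int = 0,
    config: BoostConfig | None = None,
    score_mode: str = "compound",
    n_boot: int = 100,
    compute_interactions: bool = True,
    window_cM: float = 10.0,
) -> pd.DataFrame:
    """Full detection experiment: simulate, map, and score each replicate.

    Returns one row per replicate with the main-effect AUC, the
    pair-interaction AUC (NaN when interactions are skipped), and the
    realized variance shares.
    """
    if scenario_id not in SCENARIOS:
        raise ValueError("scenario_id must be in 1..9")
    seed_rng = np.random.default_rng(master_seed)
    rows = []
    for rep in range(n_reps):
        rep_seed = int(seed_rng.integers(2**31))
        replicate = simulate_replicate(scenario_id, rep_seed, window_cM)
        result = run_shap_xgb(
            replicate.X,
            replicate.phenotypes.phenotypes,
            config=config,
            n_boot=n_boot,
            rng_seed=rep_seed,
            compute_interactions=compute_interactions,
        )
        scores = _pipeline.score_mode(result, score_mode)
        auc_main = roc_auc(scores, replicate.labels.marker_labels).auc
        if compute_interactions:
            auc_int = pair_auc(result.global_interaction, replicate.labels.pair_labels).auc
        else:
            auc_int = np.nan
        rows.append(
            {
                "replicate": rep,
                "scenario": scenario_id,
                "auc_main": auc_main,
                "auc_interaction": auc_int,
                "realized_VA": replicate.phenotypes.realized_VA,
                "realized_VI": replicate.phenotypes.realized_VI,
            }
        )
    return pd.DataFrame(rows)


def dependency_data(
    result: ShapXgbResult,
    coded_genotypes: np.ndarray,
    marker_a: int,
    marker_b: int,
    line_ids: list | None = None,
) -> pd.DataFrame:
    """Per-line interaction values for one marker pair, for dependency plots.

    Each line contributes one row (line_id, geno_a, geno_b,
    interaction_value); plotted as interaction_value against geno_a coloured
    by geno_b, with per-genotype regression lines, this visualizes how one
    locus's effect depends on the other's genotype.
    """
    if marker_a == marker_b:
        raise ValueError("markers must be distinct")
    if result.mean_phi_int is None:
        raise ValueError("dependency data requires interaction computation")
    p = result.mean_phi_int.shape[1]
    if not (0 <= marker_a < p and 0 <= marker_b < p):
        raise ValueError("unknown marker index")
    n = coded_genotypes.shape[0]
    if line_ids is None:
        line_ids = list(range(n))
    return pd.DataFrame(
        {
            "line_id": line_ids,
            "geno_a": coded_genotypes[:, marker_a],
            "geno_b": coded_genotypes[:, marker_b],
            "interaction_value": result.mean_phi_int[:, marker_a, marker_b],
        }
    )
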