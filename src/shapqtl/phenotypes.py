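"""QTL effects, gene-action codings, and phenotype generation.

Five QTL carry main effects and five QTL pairs carry pairwise interaction
(epistatic) effects, all drawn from centred normal distributions.  Genetic
values are linear in the coded genotypes: main effects multiply the per-QTL
codes, interaction effects multiply products of codes (additive-by-additive
under the additive coding, dominance-by-dominance under a dominance coding).
Residual noise is scaled so each replicate hits a target broad-sense
heritability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genetics import QTLLayout

__all__ = [
    "GENE_ACTION_CODES",
    "QTLModel",
    "PhenotypeSet",
    "draw_effects",
    "code_genotypes",
    "genetic_values",
    "add_noise",
]

# dosage (count of parent-A alleles) -> coded genotype, per gene action
GENE_ACTION_CODES: dict[str, tuple[int, int, int]] = {
    "additive": (-1, 0, 1),
    "complete_dominance": (0, 1, 1),
    "overdominance": (0, 1, 0),
}


@dataclass(frozen=True)
class QTLModel:
    """QTL layout plus drawn effect sizes under one gene action."""

    layout: QTLLayout
    action: str
    main_effects: np.ndarray  # length 5
    interaction_effects: np.ndarray  # length 5, one per interacting pair
    main_sd: float
    interaction_sd: float

    def __post_init__(self) -> None:
        if self.action not in GENE_ACTION_CODES:
            raise ValueError(f"unknown gene action {self.action!r}")
        if len(self.main_effects) != 5 or len(self.interaction_effects) != 5:
            raise ValueError("expected 5 main and 5 interaction effects")


@dataclass(frozen=True)
class PhenotypeSet:
    """Phenotypes with their genetic and residual components.

    ``realized_VA`` and ``realized_VI`` are the sample-variance shares of the
    main and interaction genetic values in the phenotypic variance.
    """

    main_values: np.ndarray
    interaction_values: np.ndarray
    residuals: np.ndarray
    phenotypes: np.ndarray
    H2_target: float
    realized_VA: float
    realized_VI: float


def draw_effects(
    layout: QTLLayout,
    action: str = "additive",
    main_sd: float = 1.0,
    interaction_sd: float = 1.0,
    n_nonzero_main: int = 5,
    rng_seed: int | np.random.Generator = 0,
) -> QTLModel:
    """Draw main and interaction effects from N(0, sd^2).

    ``n_nonzero_main`` limits how many QTL carry a main effect (2 or 5); when
    fewer than 5, the carriers are a uniform random subset and the rest get a
    main effect of exactly zero (their interactions remain).
    """
    if n_nonzero_main not in (2, 5):
        raise ValueError("n_nonzero_main must be 2 or 5")
    if main_sd <= 0 or interaction_sd <= 0:
        raise ValueError("effect standard deviations must be positive")
    rng = np.random.default_rng(rng_seed)
    main = rng.normal(0.0, main_sd, 5)
    if n_nonzero_main < 5:
        zero_idx = rng.choice(5, size=5 - n_nonzero_main, replace=False)
        main[zero_idx] = 0.0
    inter = rng.normal(0.0, interaction_sd, 5)
    return QTLModel(layout, action, main, inter, float(main_sd), float(interaction_sd))


def code_genotypes(dosage_matrix: np.ndarray, action: str) -> np.ndarray:
    """Map allele dosages {0,1,2} to the coding for a gene action."""
    if action not in GENE_ACTION_CODES:
        raise ValueError(f"unknown gene action {action!r}")
    d = np.asarray(dosage_matrix)
    if not np.isin(d, (0, 1, 2)).all():
        raise ValueError("dosages must be 0, 1 or 2")
    codes = np.array(GENE_ACTION_CODES[action], dtype=np.int8)
    return codes[d.astype(np.intp)]


def genetic_values(
    coded_qtl_matrix: np.ndarray, model: QTLModel
) -> tuple[np.ndarray, np.ndarray]:
    """Main and interaction genetic values per line.

    main_i = sum_q a_q z_iq; interaction_i = sum_{(q,r)} b_qr z_iq z_ir over
    the interacting pairs.
    """
    z = np.asarray(coded_qtl_matrix, dtype=float)
    if z.shape[1] != 5:
        raise ValueError("expected 5 coded QTL columns")
    main = z @ model.main_effects
    inter = np.zeros(z.shape[0])
    for b, (q, r) in zip(model.interaction_effects, model.layout.interacting_pairs):
        inter += b * z[:, q] * z[:, r]
    return main, inter


def add_noise(
    main_values: np.ndarray,
    interaction_values: np.ndarray,
    H2_target: float = 0.8,
    rng_seed: int | np.random.Generator = 0,
) -> PhenotypeSet:
    """Add Gaussian residuals hitting a target broad-sense heritability.

    The residual variance is scaled against the realized sample variance of
    the total genetic value g: sigma_e^2 = Var(g) (1 - H2) / H2, so every
    replicate targets the same H2 regardless of the drawn effects.
    """
    if not 0.0 < H2_target <= 1.0:
        raise ValueError("H2_target must be in (0, 1]")
    g = np.asarray(main_values, dtype=float) + np.asarray(interaction_values, dtype=float)
    var_g = float(np.var(g, ddof=1))
    if var_g == 0.0:
        raise ValueError("genetic values are constant; heritability is undefined")
    rng = np.random.default_rng(rng_seed)
    sigma2_e = var_g * (1.0 - H2_target) / H2_target
    residuals = (
        rng.normal(0.0, np.sqrt(sigma2_e), g.size) if sigma2_e > 0 else np.zeros(g.size)
    )
    phenotypes = g + residuals
    var_p = float(np.var(phenotypes, ddof=1))
    return PhenotypeSet(
        main_values=np.asarray(main_values, dtype=float),
        interaction_values=np.asarray(interaction_values, dtype=float),
        residuals=residuals,
        phenotypes=phenotypes,
        H2_target=float(H2_target),
        realized_VA=float(np.var(main_values, ddof=1)) / var_p,
        realized_VI=float(np.var(interaction_values, ddof=1)) / var_p,
    )
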