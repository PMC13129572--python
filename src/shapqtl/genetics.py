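"""Genetic maps and biparental-cross simulation.

Simulates F2 and recombinant-inbred-line (RIL) populations segregating for
markers and hidden QTL on a shared genetic map.  Meiosis follows the Haldane
model: crossover counts per chromosome are Poisson with mean length/100 (in
Morgans) and crossover positions are uniform, i.e. no interference.  QTL are
simulated as extra loci on the same gametes as the markers, so marker-QTL
linkage is exact, and are hidden from the analysis by :func:`split_markers`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeneticMap",
    "LocusSet",
    "QTLLayout",
    "CrossPopulation",
    "haldane",
    "make_map",
    "place_qtls",
    "simulate_f2",
    "simulate_ril",
    "split_markers",
]


def haldane(d_cM: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction for a map distance in cM (no interference).

    r = (1 - exp(-2d/100)) / 2; r -> 0 as d -> 0 and r -> 1/2 as d -> inf.
    """
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker positions (cM) on one or more chromosomes."""

    chromosomes: list[tuple[str, float]]
    markers: list[tuple[str, str, float]]  # (name, chrom, pos_cM)

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        names = [m[0] for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("marker names must be unique")
        chrom_order = {c: i for i, (c, _) in enumerate(self.chromosomes)}
        prev = None
        for name, chrom, pos in self.markers:
            if chrom not in lengths:
                raise ValueError(f"marker {name!r} on unknown chromosome {chrom!r}")
            if not 0.0 <= pos <= lengths[chrom]:
                raise ValueError(f"marker {name!r} position {pos} outside [0, {lengths[chrom]}]")
            key = (chrom_order[chrom], pos)
            if prev is not None and key < prev:
                raise ValueError("markers must be sorted by (chromosome, position)")
            prev = key

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def chrom_markers(self, chrom: str) -> list[tuple[str, float]]:
        return [(n, p) for n, c, p in self.markers if c == chrom]


@dataclass(frozen=True)
class LocusSet:
    """Markers plus hidden QTL loci, ordered along the map."""

    loci: list[tuple[str, str, float, bool]]  # (name, chrom, pos_cM, is_marker)

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def marker_mask(self) -> np.ndarray:
        return np.array([l[3] for l in self.loci], dtype=bool)

    @property
    def names(self) -> list[str]:
        return [l[0] for l in self.loci]


@dataclass(frozen=True)
class QTLLayout:
    """Five QTL positions and the five interacting pairs among them."""

    qtl_loci: list[tuple[str, float]]  # (chrom, pos_cM)
    interacting_pairs: list[tuple[int, int]]  # indices into qtl_loci, i < j

    def __post_init__(self) -> None:
        if len(self.qtl_loci) != 5:
            raise ValueError("layouts carry exactly 5 QTL")
        if len(self.interacting_pairs) != 5:
            raise ValueError("layouts carry exactly 5 interacting pairs")
        for i, j in self.interacting_pairs:
            if not 0 <= i < j < 5:
                raise ValueError("pairs must be (i, j) with 0 <= i < j < 5")
        if len(set(self.interacting_pairs)) != 5:
            raise ValueError("interacting pairs must be distinct")


@dataclass
class CrossPopulation:
    """Raw allele-dosage genotypes for one simulated cross.

    ``raw_genotypes[i, l]`` counts parent-A alleles (0, 1 or 2) carried by
    line ``i`` at locus ``l``; RIL populations are fully homozygous (0/2).
    """

    pop_type: str  # "F2" or "RIL"
    raw_genotypes: np.ndarray
    locus_set: LocusSet
    seed: int = field(default=0)

    def __post_init__(self) -> None:
        if self.pop_type not in ("F2", "RIL"):
            raise ValueError("pop_type must be 'F2' or 'RIL'")
        g = np.asarray(self.raw_genotypes)
        if g.ndim != 2 or g.shape[0] < 1:
            raise ValueError("raw_genotypes must be a non-empty 2-D matrix")
        if g.shape[1] != len(self.locus_set):
            raise ValueError("column count must match the locus set")
        if self.pop_type == "RIL" and np.any(g == 1):
            raise ValueError("RIL genotypes cannot be heterozygous")

    @property
    def n(self) -> int:
        return self.raw_genotypes.shape[0]


def make_map(
    n_chr: int, chr_len_cM: float, markers_per_chr: int, rng_seed: int | np.random.Generator
) -> GeneticMap:
    """Draw a random map: uniform marker positions on each chromosome.

    Markers are named ``D{c}M{k}`` (chromosome c, k-th marker in map order).
    """
    if n_chr < 1 or markers_per_chr < 2 or chr_len_cM <= 0:
        raise ValueError("need n_chr >= 1, markers_per_chr >= 2, chr_len_cM > 0")
    rng = np.random.default_rng(rng_seed)
    chromosomes = [(str(c + 1), float(chr_len_cM)) for c in range(n_chr)]
    markers = []
    for c in range(n_chr):
        pos = np.sort(rng.uniform(0.0, chr_len_cM, markers_per_chr))
        for k, p in enumerate(pos):
            markers.append((f"D{c + 1}M{k + 1}", str(c + 1), float(p)))
    return GeneticMap(chromosomes, markers)


def place_qtls(
    gmap: GeneticMap, scenario_id: int, rng_seed: int | np.random.Generator
) -> QTLLayout:
    """Place 5 QTL on a map following the study's scenario layouts.

    Scenarios 1-8 put one QTL at a uniform position on each of 5 randomly
    chosen chromosomes and declare 5 of the 10 QTL pairs interacting, chosen
    at random.  Scenario 9 places a linked triple (30 cM spacing) on one
    chromosome and a linked duo (30 cM spacing) on another; interacting pairs
    are the 3 within-triple pairs, the within-duo pair, and one random
    cross-chromosome pair.
    """
    if not 1 <= scenario_id <= 9:
        raise ValueError("scenario_id must be in 1..9")
    rng = np.random.default_rng(rng_seed)
    chrom_ids = [c for c, _ in gmap.chromosomes]
    lengths = dict(gmap.chromosomes)

    if scenario_id != 9:
        if len(chrom_ids) < 5:
            raise ValueError("need at least 5 chromosomes")
        chosen = rng.choice(len(chrom_ids), size=5, replace=False)
        qtl_loci = [
            (chrom_ids[c], float(rng.uniform(0.0, lengths[chrom_ids[c]]))) for c in chosen
        ]
        all_pairs = list(itertools.combinations(range(5), 2))
        pick = rng.choice(len(all_pairs), size=5, replace=False)
        pairs = sorted(all_pairs[k] for k in pick)
        return QTLLayout(qtl_loci, pairs)

    if len(chrom_ids) < 2:
        raise ValueError("scenario 9 needs at least 2 chromosomes")
    c3, c2 = rng.choice(len(chrom_ids), size=2, replace=False)
    len3, len2 = lengths[chrom_ids[c3]], lengths[chrom_ids[c2]]
    if len3 < 60 or len2 < 30:
        raise ValueError("chromosomes too short for the linked-QTL spacing")
    s3 = float(rng.uniform(0.0, len3 - 60.0))
    s2 = float(rng.uniform(0.0, len2 - 30.0))
    qtl_loci = [
        (chrom_ids[c3], s3),
        (chrom_ids[c3], s3 + 30.0),
        (chrom_ids[c3], s3 + 60.0),
        (chrom_ids[c2], s2),
        (chrom_ids[c2], s2 + 30.0),
    ]
    cross = list(itertools.product(range(3), range(3, 5)))
    extra = cross[rng.integers(len(cross))]
    pairs = sorted([(0, 1), (0, 2), (1, 2), (3, 4), extra])
    return QTLLayout(qtl_loci, pairs)


def _build_locus_set(gmap: GeneticMap, qtls: QTLLayout | None) -> LocusSet:
    loci: list[tuple[str, str, float, bool]] = [
        (name, chrom, pos, True) for name, chrom, pos in gmap.markers
    ]
    if qtls is not None:
        for q, (chrom, pos) in enumerate(qtls.qtl_loci):
            loci.append((f"QTL{q + 1}", chrom, pos, False))
    chrom_order = {c: i for i, (c, _) in enumerate(gmap.chromosomes)}
    # stable sort: QTL at a marker's exact position sorts after the marker
    loci.sort(key=lambda l: (chrom_order[l[1]], l[2]))
    return LocusSet(loci)


def _gametes(
    positions: np.ndarray, chrom_len: float, n_gametes: int, rng: np.random.Generator
) -> np.ndarray:
    """Simulate parental origin (0/1) of n gametes at given positions.

    One chromosome: Poisson(len/100) crossovers at uniform positions; the
    allele at a locus flips with each crossover below it.
    """
    counts = rng.poisson(chrom_len / 100.0, n_gametes)
    start = rng.integers(0, 2, n_gametes)
    out = np.empty((n_gametes, positions.size), dtype=np.int8)
    for g in range(n_gametes):
        k = counts[g]
        if k == 0:
            out[g] = start[g]
            continue
        xo = np.sort(rng.uniform(0.0, chrom_len, k))
        # parity of crossovers to the left of each locus
        flips = np.searchsorted(xo, positions, side="right") % 2
        out[g] = start[g] ^ flips
    return out


def simulate_f2(
    gmap: GeneticMap, qtls: QTLLayout | None, n: int, rng_seed: int | np.random.Generator
) -> CrossPopulation:
    """Simulate an F2 population: each line is two independent F1 gametes."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    locus_set = _build_locus_set(gmap, qtls)
    dosage = np.empty((n, len(locus_set)), dtype=np.int8)
    col = 0
    for chrom, length in gmap.chromosomes:
        pos = np.array([p for _, c, p, _ in locus_set.loci if c == chrom])
        if pos.size == 0:
            continue
        g1 = _gametes(pos, length, n, rng)
        g2 = _gametes(pos, length, n, rng)
        dosage[:, col : col + pos.size] = g1 + g2
        col += pos.size
    seed = rng_seed if isinstance(rng_seed, int) else 0
    return CrossPopulation("F2", dosage, locus_set, seed)


def simulate_ril(
    gmap: GeneticMap, qtls: QTLLayout | None, n: int, rng_seed: int | np.random.Generator
) -> CrossPopulation:
    """Simulate selfed RIL: homozygous lines with map expansion.

    Along each chromosome the parental origin is a Markov chain whose switch
    probability between adjacent loci at F2 recombination fraction r is
    r* = 2r / (1 + 2r), the standard asymptotic result for RIL by selfing.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    locus_set = _build_locus_set(gmap, qtls)
    dosage = np.empty((n, len(locus_set)), dtype=np.int8)
    col = 0
    for chrom, _length in gmap.chromosomes:
        pos = np.array([p for _, c, p, _ in locus_set.loci if c == chrom])
        if pos.size == 0:
            continue
        r = haldane(np.diff(pos))
        r_star = 2.0 * r / (1.0 + 2.0 * r)
        origin = np.empty((n, pos.size), dtype=np.int8)
        origin[:, 0] = rng.integers(0, 2, n)
        if pos.size > 1:
            switch = rng.random((n, pos.size - 1)) < r_star
            origin[:, 1:] = np.cumsum(switch, axis=1) % 2
            origin[:, 1:] ^= origin[:, [0]]
        dosage[:, col : col + pos.size] = 2 * origin
        col += pos.size
    seed = rng_seed if isinstance(rng_seed, int) else 0
    return CrossPopulation("RIL", dosage, locus_set, seed)


def split_markers(pop: CrossPopulation) -> tuple[np.ndarray, np.ndarray]:
    """Partition genotype columns into (marker_matrix, qtl_matrix).

    Marker columns keep map order; QTL columns are returned in QTL-index
    order (QTL1..QTL5) so they align with effect vectors.
    """
    mask = pop.locus_set.marker_mask
    markers = pop.raw_genotypes[:, mask]
    qtl_idx = [i for i, m in enumerate(mask) if not m]
    qtl_idx.sort(key=lambda i: pop.locus_set.loci[i][0])
    qtls = pop.raw_genotypes[:, qtl_idx]
    return markers, qtls
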