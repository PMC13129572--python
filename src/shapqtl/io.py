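"""CSV formats and run manifests.

One canonical dialect everywhere: UTF-8 CSV with a header row.  Genotype
files carry ``line_id`` in the first column and one column per marker; map
files carry ``marker,chrom,pos_cM``; phenotype files carry
``line_id,phenotype``.  Genotype coding (raw dosages vs. coded values) is
declared by the caller, never inferred.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .genetics import GeneticMap

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_map",
    "write_map",
    "read_phenotypes",
    "write_phenotypes",
    "align_phenotypes",
    "write_scores",
    "write_pairs",
    "write_shap",
    "write_interactions_long",
    "write_manifest",
]

_VALID_CODES = {
    "raw": {0, 1, 2},
    "additive": {-1, 0, 1},
    "complete_dominance": {0, 1},
    "overdominance": {0, 1},
}


def read_genotypes(path: str | Path, coding: str = "raw"):
    """Read a genotype CSV -> (line_ids, marker_names, int matrix)."""
    if coding not in _VALID_CODES:
        raise ValueError(f"unknown coding {coding!r}")
    df = pd.read_csv(path)
    if df.shape[1] < 2 or df.shape[0] < 1:
        raise ValueError(f"{path}: expected line_id plus at least one marker column")
    line_ids = df.iloc[:, 0].astype(str).tolist()
    if len(set(line_ids)) != len(line_ids):
        raise ValueError(f"{path}: duplicate line ids")
    marker_names = df.columns[1:].tolist()
    mat = df.iloc[:, 1:].to_numpy()
    if not np.issubdtype(mat.dtype, np.number):
        bad = df.columns[1:][df.iloc[:, 1:].apply(lambda c: not pd.api.types.is_numeric_dtype(c))]
        raise ValueError(f"{path}: non-numeric genotype column(s): {list(bad)}")
    allowed = _VALID_CODES[coding]
    if not np.isin(mat, list(allowed)).all():
        bad_val = mat[~np.isin(mat, list(allowed))].flat[0]
        raise ValueError(f"{path}: value {bad_val} invalid under coding {coding!r}")
    return line_ids, marker_names, mat.astype(np.int8)


def write_genotypes(path: str | Path, line_ids, marker_names, matrix) -> None:
    df = pd.DataFrame(matrix, columns=marker_names)
    df.insert(0, "line_id", line_ids)
    df.to_csv(path, index=False)


def read_map(path: str | Path) -> GeneticMap:
    """Read a map CSV (marker,chrom,pos_cM); unsorted rows are sorted."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"marker", "chrom", "pos_cM"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: map needs columns {sorted(required)}")
    df["chrom"] = df["chrom"].astype(str)
    chrom_order = df["chrom"].drop_duplicates().tolist()
    key = df["chrom"].map({c: i for i, c in enumerate(chrom_order)})
    if not (df.assign(_k=key).sort_values(["_k", "pos_cM"]).index == df.index).all():
        warnings.warn(f"{path}: map rows were not sorted; sorting by (chrom, pos_cM)")
        df = df.assign(_k=key).sort_values(["_k", "pos_cM"]).drop(columns="_k")
    chroms = [(c, float(df.loc[df["chrom"] == c, "pos_cM"].max())) for c in chrom_order]
    markers = [(str(r.marker), str(r.chrom), float(r.pos_cM)) for r in df.itertuples()]
    return GeneticMap(chroms, markers)


def write_map(path: str | Path, gmap: GeneticMap) -> None:
    pd.DataFrame(gmap.markers, columns=["marker", "chrom", "pos_cM"]).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_phenotypes(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"line_id", "phenotype"}.issubset(df.columns):
        raise ValueError(f"{path}: phenotype file needs columns line_id,phenotype")
    s = pd.Series(df["phenotype"].to_numpy(float), index=df["line_id"].astype(str))
    if s.index.duplicated().any():
        raise ValueError(f"{path}: duplicate line ids")
    return s


def write_phenotypes(path: str | Path, line_ids, phenotypes) -> None:
    pd.DataFrame({"line_id": line_ids, "phenotype": phenotypes}).to_csv(path, index=False)


def align_phenotypes(phenotypes: pd.Series, line_ids: list[str]) -> np.ndarray:
    """Match phenotypes to genotype lines by id (order-independent)."""
    missing = [l for l in line_ids if l not in phenotypes.index]
    if missing:
        raise ValueError(f"lines without phenotypes: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    return phenotypes.loc[line_ids].to_numpy()


def check_marker_consistency(marker_names: list[str], gmap: GeneticMap) -> None:
    map_names = [m[0] for m in gmap.markers]
    if set(marker_names) != set(map_names):
        only_g = sorted(set(marker_names) - set(map_names))[:5]
        only_m = sorted(set(map_names) - set(marker_names))[:5]
        raise ValueError(
            f"marker sets differ between genotypes and map (genotypes-only {only_g}, map-only {only_m})"
        )


def write_scores(path: str | Path, marker_names, scores, gmap: GeneticMap | None = None) -> None:
    df = pd.DataFrame({"marker": marker_names, "score": scores})
    if gmap is not None:
        pos = {name: (chrom, p) for name, chrom, p in gmap.markers}
        df["chrom"] = [pos[m][0] if m in pos else "" for m in marker_names]
        df["pos_cM"] = [pos[m][1] if m in pos else np.nan for m in marker_names]
    df.to_csv(path, index=False, float_format="%.17g")


def write_pairs(path: str | Path, pairs: list[tuple]) -> None:
    pd.DataFrame(pairs, columns=["marker_a", "marker_b", "score"]).to_csv(
        path, index=False, float_format="%.17g"
    )


def write_shap(path: str | Path, line_ids, marker_names, phi: np.ndarray) -> None:
    df = pd.DataFrame(phi, columns=marker_names)
    df.insert(0, "line_id", line_ids)
    df.to_csv(path, index=False, float_format="%.17g")


def write_interactions_long(
    path: str | Path,
    line_ids,
    marker_names,
    phi_int: np.ndarray,
    pairs: list[tuple[int, int]] | None = None,
) -> None:
    """Per-line interaction values as long CSV: line_id,marker_a,marker_b,value.

    Writes the upper triangle (a < b); ``pairs`` restricts the export (the
    full table has n * p(p-1)/2 rows, unwieldy beyond small panels).
    """
    n, p, _ = phi_int.shape
    if pairs is None:
        pairs = [(a, b) for a in range(p) for b in range(a + 1, p)]
    rows = {
        "line_id": np.repeat(line_ids, len(pairs)),
        "marker_a": [marker_names[a] for _ in range(n) for a, _b in pairs],
        "marker_b": [marker_names[b] for _ in range(n) for _a, b in pairs],
        "value": np.concatenate([[phi_int[i, a, b] for a, b in pairs] for i in range(n)]),
    }
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_manifest(path: str | Path, config: dict) -> None:
    """Record everything needed to reproduce a run bit-for-bit."""
    import sklearn
    import xgboost

    manifest = {
        "format_version": 1,
        "config": config,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "xgboost": xgboost.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
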