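"""Tab-delimited I/O, case/control pairing, and the weighted-density grid.

Expected formats (all plain TSV with a header row):

* expression matrix — first column gene id, remaining columns one sample
  each;
* pairing map — columns ``pair_id``, ``case_col``, ``control_col`` naming
  the matrix columns that form each pair;
* difference matrix — first column gene id, remaining columns one pair of
  within-pair log2 differences each.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .model import InputError, MixtureModel, PairedDiffMatrix, log_marginals, logger

__all__ = [
    "read_differences",
    "read_expression",
    "write_differences",
    "write_labels",
    "read_labels",
    "density_grid",
    "write_density_grid",
    "write_results",
]


def _read_numeric_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise InputError(f"duplicated sample columns in {path}: {dupes}")
    if df.index.duplicated().any():
        raise InputError(f"duplicated gene ids in {path}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = numeric.isna().stack()
        gene, col = bad[bad].index[0]
        raise InputError(f"non-numeric cell in {path} at gene {gene!r}, column {col!r}")
    return numeric


def _looks_raw_scale(values: np.ndarray) -> bool:
    """Heuristic: intensities on the raw scale vs already log2."""
    return bool(values.max() > 50 or (np.all(values > 0) and values.max() > 30))


def read_differences(path: str | Path) -> PairedDiffMatrix:
    """Read a genes x pairs matrix of within-pair log2 differences."""
    df = _read_numeric_table(path)
    return PairedDiffMatrix(values=df.to_numpy(float),
                            gene_ids=tuple(map(str, df.index)),
                            pair_ids=tuple(map(str, df.columns)))


def read_expression(matrix_path: str | Path, pairing_path: str | Path,
                    scale: str = "auto") -> PairedDiffMatrix:
    """Build within-pair differences from an expression matrix and a pairing map.

    ``scale``: 'log2' (use columns as-is), 'raw' (log2-transform first), or
    'auto' (transform when the values look like raw intensities).
    """
    df = _read_numeric_table(matrix_path)
    pairing = pd.read_csv(pairing_path, sep="\t", dtype=str)
    required = {"pair_id", "case_col", "control_col"}
    if not required.issubset(pairing.columns):
        raise InputError(
            f"pairing file {pairing_path} must have columns {sorted(required)}, "
            f"got {list(pairing.columns)}"
        )
    for col_field in ("case_col", "control_col"):
        missing = set(pairing[col_field]) - set(df.columns)
        if missing:
            raise InputError(
                f"pairing file references absent matrix column(s): {sorted(missing)}"
            )
    used = pairing["case_col"].tolist() + pairing["control_col"].tolist()
    if len(set(used)) != len(used):
        raise InputError("a sample column is used in more than one pairing role")

    values = df.to_numpy(float)
    if scale not in ("auto", "log2", "raw"):
        raise InputError(f"scale must be auto|log2|raw, got {scale!r}")
    if scale == "raw" or (scale == "auto" and _looks_raw_scale(values)):
        if np.any(values <= 0):
            raise InputError("raw-scale matrix has non-positive entries; cannot log2")
        logger.info("log2-transforming raw-scale expression matrix")
        df = np.log2(df)

    case = df[pairing["case_col"].tolist()].to_numpy(float)
    control = df[pairing["control_col"].tolist()].to_numpy(float)
    return PairedDiffMatrix(values=case - control,
                            gene_ids=tuple(map(str, df.index)),
                            pair_ids=tuple(map(str, pairing["pair_id"])))


def write_differences(d: PairedDiffMatrix, path: str | Path) -> None:
    df = pd.DataFrame(d.values, index=list(d.gene_ids), columns=list(d.pair_ids))
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.6g")


def write_labels(gene_ids, labels, path: str | Path) -> None:
    pd.DataFrame({"gene_id": list(gene_ids), "label": list(labels)}).to_csv(
        path, sep="\t", index=False
    )


def read_labels(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "label"}.issubset(df.columns):
        raise InputError(f"labels file {path} must have columns gene_id, label")
    return df["gene_id"].to_numpy(), df["label"].to_numpy()


def density_grid(model: MixtureModel, grid: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Weighted one-dimensional marginal densities on a grid.

    Evaluates pi_c f_c(t) with the n = 1 marginals at each grid point —
    the one-sample approximation used to visualize the fitted mixture —
    returning the OE, UE, NE curves and their sum.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or not np.all(np.isfinite(grid)):
        raise InputError("grid must be a finite 1-D vector")
    log_f = log_marginals(grid[:, None], model.hyper)
    w = np.exp(log_f) * np.array(model.pi)
    return w[:, 0], w[:, 1], w[:, 2], w.sum(axis=1)


def write_density_grid(model: MixtureModel, grid: np.ndarray, path: str | Path) -> None:
    w1, w2, w3, tot = density_grid(model, grid)
    pd.DataFrame({"d": grid, "oe": w1, "ue": w2, "ne": w3, "total": tot}).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def write_results(gene_ids, resp_matrix: np.ndarray, labels, path: str | Path) -> None:
    """Per-gene responsibilities and maximum-posterior label."""
    df = pd.DataFrame({
        "gene_id": list(gene_ids),
        "z_oe": resp_matrix[:, 0],
        "z_ue": resp_matrix[:, 1],
        "z_ne": resp_matrix[:, 2],
        "label": list(labels),
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
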