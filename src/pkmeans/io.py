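"""Readers and writers for delimited and Matrix Market inputs and for the
pipeline's result files."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io

from .matrix import DataMatrix
from .pipeline import PipelineResult


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in (".tsv", ".tab", ".txt"):
        return "tsv"
    if suffix == ".mtx":
        return "mtx"
    raise ValueError(f"cannot infer format from suffix {suffix!r}; pass format=")


def _read_delimited(path: Path, sep: str) -> DataMatrix:
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed delimited file {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ValueError(f"{path} has no columns")
    obs_ids = None
    first = df.columns[0]
    # a non-numeric first column is treated as observation ids
    if df[first].dtype == object or str(first).lower() in ("", "id", "cell", "cell_id", "unnamed: 0"):
        try:
            df[first].astype(float)
        except (ValueError, TypeError):
            obs_ids = df[first].astype(str).tolist()
            df = df.drop(columns=[first])
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"non-numeric cells in columns {non_numeric} of {path}")
    return DataMatrix(df.to_numpy(dtype=float), [str(c) for c in df.columns], obs_ids)


def _read_mtx(path: Path) -> DataMatrix:
    mat = scipy_io.mmread(path)
    values = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
    rows_file = path.with_name(path.stem + "_rows.txt")
    cols_file = path.with_name(path.stem + "_cols.txt")
    for companion in (rows_file, cols_file):
        if not companion.exists():
            raise FileNotFoundError(
                f"missing companion name file {companion} for {path}"
            )
    obs_ids = rows_file.read_text().split()
    names = cols_file.read_text().split()
    if len(obs_ids) != values.shape[0] or len(names) != values.shape[1]:
        raise ValueError(
            f"companion name files do not match matrix shape {values.shape}"
        )
    return DataMatrix(values, names, obs_ids)


def read_matrix(path, format: str | None = None) -> DataMatrix:
    """Read a matrix from CSV/TSV (header row of variable names, optional
    first column of observation ids) or Matrix Market coordinate format with
    ``*_rows.txt`` / ``*_cols.txt`` companion name files."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    fmt = format or _infer_format(path)
    if fmt == "csv":
        return _read_delimited(path, ",")
    if fmt == "tsv":
        return _read_delimited(path, "\t")
    if fmt == "mtx":
        return _read_mtx(path)
    raise ValueError(f"unknown format {fmt!r} (expected csv, tsv or mtx)")


def write_matrix(data: DataMatrix, path, labels: np.ndarray | None = None) -> None:
    """Write a DataMatrix as CSV with an id column; optionally write a
    companion ``*_labels.csv`` file of ground-truth labels."""
    path = Path(path)
    df = data.to_dataframe()
    df.index.name = "id"
    df.to_csv(path)
    if labels is not None:
        lab = pd.DataFrame({"id": data.observation_ids, "label": np.asarray(labels)})
        lab.to_csv(path.with_name(path.stem + "_labels.csv"), index=False)


def _centers_frame(centers: np.ndarray, mask: np.ndarray, names: list[str]) -> pd.DataFrame:
    df = pd.DataFrame(centers, columns=names)
    df.index.name = "cluster"
    return df.where(mask)  # non-defining entries become empty cells


def write_results(result: PipelineResult, output_dir) -> dict[str, Path]:
    """Write assignments, center matrices (preprocessed and original units;
    empty cells mark non-defining variables), the tuning report and a JSON
    run summary.  Returns the paths written."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    assignments = pd.DataFrame(
        {"observation_id": result.observation_ids, "cluster": result.partition.labels}
    )
    paths["assignments"] = out / "assignments.tsv"
    assignments.to_csv(paths["assignments"], sep="\t", index=False)

    paths["centers"] = out / "centers.tsv"
    _centers_frame(result.model.centers, result.defining_mask, result.variable_names).to_csv(
        paths["centers"], sep="\t"
    )
    paths["centers_original_units"] = out / "centers_original_units.tsv"
    _centers_frame(
        result.centers_original_units, result.defining_mask, result.variable_names
    ).to_csv(paths["centers_original_units"], sep="\t")

    paths["tuning"] = out / "tuning.tsv"
    result.tuning.report().to_csv(paths["tuning"], sep="\t", index=False)

    summary = {
        "seed": result.seed,
        "route": result.route,
        "n_clusters": result.n_clusters,
        "selected_penalty": result.tuning.optimal_penalty,
        "final_penalty": result.model.penalty,
        "boundary_warning": bool(result.tuning.boundary_warning),
        "stopped_by": result.tuning.stopped_by,
        "N_r": result.tuning.N_r,
        "rounds_per_penalty": int(result.tuning.runs_per_penalty),
        "log2_applied": bool(result.preprocess_record.log_applied),
        "centering_mode": result.preprocess_record.centering_mode,
        "defining_variables": {
            str(m): names for m, names in enumerate(result.defining_variables)
        },
    }
    paths["summary"] = out / "summary.json"
    paths["summary"].write_text(json.dumps(summary, indent=2) + "\n")
    return paths


def read_assignments(path) -> np.ndarray:
    """Read back an assignments TSV; returns the label vector."""
    df = pd.read_csv(path, sep="\t")
    return df["cluster"].to_numpy(dtype=int)
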