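"""Delimited-table input, tidy curve output, configuration and manifests.

Cell tables are plain CSV/TSV with one row per cell; the column mapping is
explicit (no header-dialect guessing).  When a subject was imaged more
than once and an image-id column is mapped, the image with the maximum
number of cells represents the subject.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from .entropy import CellPattern, SPICurve
from .exceptions import SchemaError
from .fpca import FPCAModel, FunctionalSample

__all__ = [
    "ColumnMapping",
    "PipelineConfig",
    "read_cell_table",
    "write_spi_curves",
    "read_spi_curves",
    "write_fpca_model",
    "build_manifest",
]


class ColumnMapping(BaseModel):
    """Names of the required columns in a cell table."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    x: str = "x"
    y: str = "y"
    cell_type: str = "cell_type"
    subject_id: str = "subject_id"
    image_id: str | None = None


class PipelineConfig(BaseModel):
    """Validated configuration for the end-to-end pipeline.

    Unknown keys are rejected so that typos fail before any computation.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    cells: str
    clinical: str | None = None
    mapping: ColumnMapping = ColumnMapping()
    sep: str = ","
    n_bins: int = 50
    floor_ratio: float = 20.0
    fve_threshold: float = 0.92
    mean_bandwidth: float | str = "auto"
    cov_bandwidth: float | str = "auto"
    clinical_covariates: list[str] = ["age"]
    duration_col: str = "time"
    event_col: str = "event"
    ties: str = "breslow"
    seed: int = 0
    outdir: str = "spatent_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


def read_cell_table(
    path,
    mapping: ColumnMapping = None,
    label_set=None,
    sep: str = ",",
) -> list[CellPattern]:
    """Parse a delimited cell table into one ``CellPattern`` per subject.

    Coordinates are taken as continuous microns with arbitrary origin.
    Subjects with fewer than 2 cells are skipped with a warning.  The
    label set defaults to the sorted union of observed cell types so that
    every subject shares the same co-occurrence categories.
    """
    mapping = mapping or ColumnMapping()
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"cell table not found: {path}")
    df = pd.read_csv(path, sep=sep)
    needed = [mapping.x, mapping.y, mapping.cell_type, mapping.subject_id]
    if mapping.image_id is not None:
        needed.append(mapping.image_id)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(
            f"missing column(s) {missing} in {path.name}; available columns: {list(df.columns)}"
        )
    for col in (mapping.x, mapping.y):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r} at row {row}"
            )
        df[col] = numeric
    if df[[mapping.x, mapping.y, mapping.cell_type, mapping.subject_id]].isna().any().any():
        raise SchemaError("cell table contains missing values in mapped columns")

    labels = tuple(sorted(label_set)) if label_set is not None else tuple(
        sorted(df[mapping.cell_type].astype(str).unique())
    )
    patterns = []
    for sid, sub in df.groupby(mapping.subject_id, sort=True):
        if mapping.image_id is not None:
            counts = sub.groupby(mapping.image_id).size()
            sub = sub[sub[mapping.image_id] == counts.idxmax()]
        if len(sub) < 2:
            warnings.warn(f"subject {sid!r} has fewer than 2 cells; skipped", stacklevel=2)
            continue
        patterns.append(
            CellPattern(
                str(sid),
                sub[[mapping.x, mapping.y]].to_numpy(dtype=float),
                sub[mapping.cell_type].astype(str).to_numpy(),
                labels,
            )
        )
    if not patterns:
        raise SchemaError(f"no usable subjects in {path.name}")
    return patterns


def write_spi_curves(curves: dict, path, totals_path=None) -> pd.DataFrame:
    """Write ``{subject_id: SPICurve}`` as one tidy CSV (+ JSON totals)."""
    frames = [curve.to_frame(sid) for sid, curve in curves.items()]
    tidy = pd.concat(frames, ignore_index=True)
    tidy.to_csv(path, index=False)
    if totals_path is not None:
        payload = {sid: curve.totals_dict() for sid, curve in curves.items()}
        Path(totals_path).write_text(json.dumps(payload, indent=2))
    return tidy


def read_spi_curves(path) -> FunctionalSample:
    """Read a tidy curve CSV back as a functional sample (NaN bins dropped)."""
    df = pd.read_csv(path)
    for col in ("subject_id", "midpoint", "spi"):
        if col not in df.columns:
            raise SchemaError(f"curve table missing column {col!r}")
    return FunctionalSample.from_dataframe(df)


def write_fpca_model(model: FPCAModel, outdir) -> None:
    """Persist an FPCA fit as CSVs plus a JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"s": model.grid, "mean": model.mean}).to_csv(outdir / "mean.csv", index=False)
    eig = pd.DataFrame(model.eigenfunctions, columns=[f"phi_{l + 1}" for l in range(model.n_components)])
    eig.insert(0, "s", model.grid)
    eig.to_csv(outdir / "eigenfunctions.csv", index=False)
    L = model.n_selected
    scores = pd.DataFrame(model.scores[:, :L], columns=[f"score_{l + 1}" for l in range(L)])
    scores.insert(0, "subject_id", list(model.ids))
    scores.to_csv(outdir / "scores.csv", index=False)
    summary = {
        "eigenvalues": model.eigenvalues.tolist(),
        "fve": model.fve.tolist(),
        "n_selected": model.n_selected,
        "sigma2": model.sigma2,
        "mean_bandwidth": model.config.mean_bandwidth,
        "cov_bandwidth": model.config.cov_bandwidth,
        "n_grid": int(model.grid.size),
    }
    (outdir / "model.json").write_text(json.dumps(summary, indent=2))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(config, inputs: dict, seeds: dict) -> dict:
    """Reproducibility manifest: config snapshot, input digests, seeds."""
    from . import __version__

    return {
        "software": {"package": "spatent", "version": __version__},
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": config.model_dump() if isinstance(config, BaseModel) else dict(config),
        "inputs": {name: {"path": str(p), "sha256": _sha256(p)} for name, p in inputs.items() if p},
        "seeds": seeds,
    }
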