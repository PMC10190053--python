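"""Readers and writers for the on-disk formats the tool touches.

Count matrices come either as dense CSV/TSV (genes x spots with header row
and index column, or transposed with a flag) or as a MatrixMarket triplet
with companion ``barcodes.tsv``/``features.tsv`` files as in 10x Visium
exports. Marker matrices, cell counts and coordinates are plain CSV. Spot
identifiers are the join key everywhere; file order is irrelevant.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import ExpressionMatrix, MarkerMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_counts",
    "write_counts",
    "write_counts_mtx",
    "read_marker_matrix",
    "write_marker_matrix",
    "read_cell_counts",
    "read_coordinates",
    "load_yaml_config",
    "write_manifest",
]


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def read_counts(path, orientation: str = "gene_by_spot") -> ExpressionMatrix:
    """Read a count matrix from dense CSV/TSV or a MatrixMarket triplet.

    For ``.mtx`` input, ``features.tsv`` (genes, matrix rows) and
    ``barcodes.tsv`` (spots, columns) must sit next to the matrix file.
    """
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        from scipy.io import mmread
        mat = np.asarray(mmread(path).todense())
        features = pd.read_csv(path.parent / "features.tsv", sep="\t", header=None)
        barcodes = pd.read_csv(path.parent / "barcodes.tsv", sep="\t", header=None)
        frame = pd.DataFrame(mat, index=features[0].astype(str), columns=barcodes[0].astype(str))
    else:
        frame = _read_table(path)
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"non-numeric count at row {frame.index[r]!r}, column {frame.columns[c]!r}")
    return ExpressionMatrix.from_frame(numeric, orientation=orientation)


def write_counts(data: ExpressionMatrix, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    data.to_frame().to_csv(path, sep=sep)


def write_counts_mtx(data: ExpressionMatrix, directory) -> None:
    """Write matrix.mtx + features.tsv + barcodes.tsv (10x-style layout)."""
    from scipy.io import mmwrite
    from scipy.sparse import coo_matrix

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mmwrite(directory / "matrix.mtx", coo_matrix(data.counts))
    pd.Series(data.gene_ids).to_csv(directory / "features.tsv", sep="\t",
                                    header=False, index=False)
    pd.Series(data.spot_ids).to_csv(directory / "barcodes.tsv", sep="\t",
                                    header=False, index=False)


def read_marker_matrix(path, counts: ExpressionMatrix | None = None) -> MarkerMatrix:
    """Read a gene x type 0/1 CSV; appends a dummy column when absent.

    When ``counts`` is given, marker genes absent from it are dropped with
    a warning.
    """
    frame = _read_table(Path(path))
    if not frame.isin((0, 1)).all().all():
        raise ValueError("marker matrix entries must be 0 or 1")
    if counts is not None:
        present = frame.index.isin(counts.gene_ids)
        if not present.all():
            dropped = list(frame.index[~present])
            logger.warning("marker genes absent from counts dropped: %s", dropped[:10])
            frame = frame.loc[present]
    had_dummy = (frame == 0).all(axis=0).any()
    matrix = MarkerMatrix.from_frame(frame)
    if not had_dummy:
        logger.info("no all-zero column found; dummy type appended")
    return matrix


def write_marker_matrix(markers: MarkerMatrix, path) -> None:
    markers.to_frame().to_csv(Path(path))


def _spot_series(path, spot_ids, what: str) -> pd.DataFrame:
    frame = _read_table(Path(path))
    missing = [s for s in spot_ids if s not in frame.index]
    if missing:
        raise ValueError(f"{what} missing for spots: {missing[:10]}")
    return frame.loc[list(spot_ids)]


def read_cell_counts(path, spot_ids) -> np.ndarray:
    """Per-spot prior cell counts; first column, aligned to ``spot_ids``."""
    frame = _spot_series(path, spot_ids, "cell counts")
    counts = pd.to_numeric(frame.iloc[:, 0], errors="coerce")
    if counts.isna().any() or (counts <= 0).any():
        bad = list(frame.index[counts.isna() | (counts <= 0)])[:5]
        raise ValueError(f"cell counts must be positive numbers; offending spots: {bad}")
    return counts.to_numpy(dtype=float)


def read_coordinates(path, spot_ids) -> pd.DataFrame:
    """Array coordinates (x, y) per spot, aligned to ``spot_ids``."""
    frame = _spot_series(path, spot_ids, "coordinates")
    xy = frame.iloc[:, :2].apply(pd.to_numeric, errors="coerce")
    if xy.isna().any().any():
        raise ValueError("coordinates must be numeric (two columns: x, y)")
    xy.columns = ["x", "y"]
    return xy


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_manifest(manifest: dict, path) -> None:
    """Persist a run manifest (config, seeds, versions, config hash)."""
    from . import __version__

    manifest = dict(manifest)
    manifest["spotmix_version"] = __version__
    payload = yaml.safe_dump(manifest, sort_keys=True)
    manifest["config_hash"] = hashlib.sha256(payload.encode()).hexdigest()[:16]
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
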