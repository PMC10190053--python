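"""Validated containers for counts, marker signatures and model hyperparameters.

The internal orientation is fixed: count matrices are stored gene x spot,
marker matrices gene x type. Readers that encounter the transposed layout
re-orient on input (see :mod:`spotmix.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "MarkerMatrix",
    "Hyperparameters",
    "DUMMY_TYPE_NAME",
]

DUMMY_TYPE_NAME = "dummy"


def _check_unique(ids, what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dup = set(), set()
        for i in ids:
            (dup if i in seen else seen).add(i)
        raise ValueError(f"duplicate {what}: {sorted(dup)[:5]}")
    return ids


@dataclass
class ExpressionMatrix:
    """Observed read counts ``C[g, s]`` for marker genes across spots.

    Parameters
    ----------
    counts
        Non-negative integer matrix, genes in rows, spots in columns.
    gene_ids, spot_ids
        Unique identifiers matching the matrix dimensions.
    """

    counts: np.ndarray
    gene_ids: list[str]
    spot_ids: list[str]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix (gene x spot)")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded, atol=1e-9) or not np.all(np.isfinite(counts)):
                raise ValueError("counts must be integer-valued")
            counts = rounded.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            g, s = np.argwhere(counts < 0)[0]
            raise ValueError(f"negative count at gene {g}, spot {s}")
        self.counts = counts
        self.gene_ids = _check_unique(self.gene_ids, "gene ids")
        self.spot_ids = _check_unique(self.spot_ids, "spot ids")
        if counts.shape != (len(self.gene_ids), len(self.spot_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.spot_ids)} spots"
            )

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_spots(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.spot_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, orientation: str = "gene_by_spot") -> "ExpressionMatrix":
        if orientation == "spot_by_gene":
            frame = frame.T
        elif orientation != "gene_by_spot":
            raise ValueError(f"unknown orientation {orientation!r}")
        return cls(frame.to_numpy(), list(frame.index), list(frame.columns))

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        idx = [self.gene_ids.index(g) for g in genes]
        return ExpressionMatrix(self.counts[idx], [self.gene_ids[i] for i in idx], list(self.spot_ids))


@dataclass
class MarkerMatrix:
    """Binary marker-gene signature ``B[g, t]`` with a mandatory dummy type.

    The dummy type has no markers (an all-zero column) and absorbs cells of
    types not represented in the signature.
    """

    B: np.ndarray
    gene_ids: list[str]
    type_names: list[str]
    dummy_index: int = -1

    def __post_init__(self) -> None:
        B = np.asarray(self.B)
        if B.ndim != 2:
            raise ValueError("B must be 2-D (gene x type)")
        if not np.isin(B, (0, 1)).all():
            raise ValueError("marker matrix entries must be 0 or 1")
        B = B.astype(np.int8)
        self.gene_ids = _check_unique(self.gene_ids, "gene ids")
        self.type_names = _check_unique(self.type_names, "type names")
        if B.shape != (len(self.gene_ids), len(self.type_names)):
            raise ValueError("B shape does not match gene/type identifier lengths")
        if self.dummy_index < 0:
            self.dummy_index += B.shape[1]
        if not 0 <= self.dummy_index < B.shape[1]:
            raise ValueError("dummy_index out of range")
        if B[:, self.dummy_index].any():
            raise ValueError("dummy type column must be all zeros")
        non_dummy = np.delete(np.arange(B.shape[1]), self.dummy_index)
        empty = [self.type_names[t] for t in non_dummy if B[:, t].sum() == 0]
        if empty:
            raise ValueError(f"non-dummy types without any marker: {empty}")
        orphan = [self.gene_ids[g] for g in range(B.shape[0]) if B[g].sum() == 0]
        if orphan:
            raise ValueError(f"genes that are markers for no type: {orphan[:5]}")
        self.B = B

    @property
    def n_genes(self) -> int:
        return self.B.shape[0]

    @property
    def n_types(self) -> int:
        return self.B.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.B, index=self.gene_ids, columns=self.type_names)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, dummy_name: str = DUMMY_TYPE_NAME) -> "MarkerMatrix":
        """Build from a gene x type 0/1 table; a dummy column is appended if absent."""
        if not (frame == 0).all(axis=0).any():
            frame = frame.copy()
            name = dummy_name
            while name in frame.columns:
                name += "_"
            frame[name] = 0
        zero_cols = list(frame.columns[(frame == 0).all(axis=0)])
        dummy_index = list(frame.columns).index(zero_cols[-1])
        return cls(frame.to_numpy(), list(frame.index), [str(c) for c in frame.columns], dummy_index)


@dataclass
class Hyperparameters:
    """Fixed hyperparameters of the hierarchical model.

    alpha
        Concentration of the Beta-Bernoulli feature-allocation prior; the
        expected number of types per spot is ``t_N * alpha / (t_N + alpha)``.
    a, b / a0, b0
        Gamma shape/rate for the unnormalized abundance theta when a type is
        present / absent; Gamma(a, b) must sit well above Gamma(a0, b0).
    l
        Per-spot prior cell counts (image-derived estimates).
    sigma
        Standard deviation of the truncated-normal prior on the per-spot cell
        number N_s; large sigma means the counts in ``l`` are barely trusted.
    """

    alpha: float = 10.0
    a: float = 10.0
    b: float = 1.0
    a0: float = 0.1
    b0: float = 1.0
    l: np.ndarray | None = None
    sigma: float = 4.0

    def __post_init__(self) -> None:
        for name in ("alpha", "a", "b", "a0", "b0", "sigma"):
            v = float(getattr(self, name))
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
            setattr(self, name, v)
        if self.a / self.b <= self.a0 / self.b0:
            raise ValueError(
                "Gamma(a, b) must dominate Gamma(a0, b0) in location: "
                f"a/b={self.a / self.b} <= a0/b0={self.a0 / self.b0}"
            )
        if self.l is not None:
            l = np.asarray(self.l, dtype=float)
            if (l <= 0).any() or not np.isfinite(l).all():
                raise ValueError("per-spot prior cell counts l must be positive and finite")
            self.l = l

    def with_counts(self, l: np.ndarray, sigma: float | None = None) -> "Hyperparameters":
        return Hyperparameters(
            alpha=self.alpha, a=self.a, b=self.b, a0=self.a0, b0=self.b0,
            l=np.asarray(l, dtype=float),
            sigma=self.sigma if sigma is None else float(sigma),
        )
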