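"""Semi-automatic lead-gene-driven marker selection.

For every cell type the user supplies a (possibly large, uncurated) list of
candidate marker genes and one high-confidence *lead gene*. The procedure
acts as a sieve:

1. keep candidates expressed above level r_K in more than r_N spots;
2. correlate each retained candidate with the lead gene across spots
   (Kendall tau and Pearson rho);
3. normalize each type's correlation vectors by their maxima;
4. keep genes whose normalized tau and rho both exceed the thresholds.

Genes ending up assigned to more than ``max_types_per_gene`` types are
dropped entirely, and a zero dummy column is appended to the final binary
signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kendalltau, pearsonr

from .data import DUMMY_TYPE_NAME, ExpressionMatrix, MarkerMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerSelectionConfig",
    "CorrelationReport",
    "filter_low_expression",
    "lead_correlations",
    "normalize_and_select",
    "build_marker_matrix",
    "select_markers",
]


@dataclass
class MarkerSelectionConfig:
    """Inputs and thresholds of the selection sieve.

    ``tau_star``/``rho_star`` may be global scalars or per-type maps.
    """

    candidates: dict = field(default_factory=dict)   # type -> [gene, ...]
    lead_gene: dict = field(default_factory=dict)    # type -> gene
    r_N: int = 5
    r_K: float = 0.0
    tau_star: float | dict = 0.3
    rho_star: float | dict = 0.3
    max_types_per_gene: int = 2

    def threshold(self, which: str, cell_type: str) -> float:
        v = getattr(self, which)
        v = v[cell_type] if isinstance(v, dict) else v
        if not 0 < v <= 1:
            raise ValueError(f"{which} must lie in (0, 1], got {v}")
        return float(v)

    def validate(self, data: ExpressionMatrix) -> None:
        genes = set(data.gene_ids)
        for t, lead in self.lead_gene.items():
            if t not in self.candidates:
                raise ValueError(f"type {t!r} has a lead gene but no candidate list")
            if lead not in self.candidates[t]:
                raise ValueError(f"lead gene {lead!r} is not among candidates for {t!r}")
            if lead not in genes:
                raise ValueError(f"lead gene {lead!r} absent from the expression matrix")
        missing = set(self.candidates) - set(self.lead_gene)
        if missing:
            raise ValueError(f"types without a lead gene: {sorted(missing)}")


@dataclass
class CorrelationReport:
    """Per-type retained sets plus raw and max-normalized correlations."""

    retained: dict            # type -> [gene]
    raw: dict                 # type -> DataFrame(tau, rho) indexed by gene
    normalized: dict = field(default_factory=dict)
    flagged: list = field(default_factory=list)


def filter_low_expression(candidates, data: ExpressionMatrix, r_N: int = 5,
                          r_K: float = 0.0):
    """Retain genes expressed at level > r_K in strictly more than r_N spots.

    Candidates missing from the matrix are dropped with a warning.
    """
    gene_pos = {g: i for i, g in enumerate(data.gene_ids)}
    retained = []
    for g in candidates:
        if g not in gene_pos:
            logger.warning("candidate gene %r not in the expression matrix; dropped", g)
            continue
        n_spots = int((data.counts[gene_pos[g]] > r_K).sum())
        if n_spots > r_N:
            retained.append(g)
    return retained


def lead_correlations(retained, data: ExpressionMatrix, lead: str) -> pd.DataFrame:
    """Kendall tau-b and Pearson rho of each retained gene with the lead gene.

    Count data are tie-heavy, hence the tie-corrected tau-b variant. Genes
    with zero variance across spots have undefined correlation and are
    excluded with a warning; the lead gene's own entries are exactly 1.
    """
    gene_pos = {g: i for i, g in enumerate(data.gene_ids)}
    lead_expr = data.counts[gene_pos[lead]].astype(float)
    rows = {}
    for g in retained:
        expr = data.counts[gene_pos[g]].astype(float)
        if g == lead:
            rows[g] = (1.0, 1.0)
            continue
        if expr.std() == 0 or lead_expr.std() == 0:
            logger.warning("gene %r has zero variance; correlation undefined, excluded", g)
            continue
        tau = kendalltau(lead_expr, expr, variant="b").statistic
        rho = pearsonr(lead_expr, expr).statistic
        rows[g] = (float(tau), float(rho))
    return pd.DataFrame.from_dict(rows, orient="index", columns=["tau", "rho"])


def normalize_and_select(report: CorrelationReport, tau_star, rho_star):
    """Divide each type's tau/rho vectors by their maxima and threshold.

    A gene passes when both normalized values strictly exceed the
    thresholds; the gene attaining a maximum (normalized value exactly 1)
    always passes that criterion, so the lead gene can never exclude
    itself.
    """
    selected = {}
    for t, raw in report.raw.items():
        ts = tau_star[t] if isinstance(tau_star, dict) else tau_star
        rs = rho_star[t] if isinstance(rho_star, dict) else rho_star
        if raw.empty:
            report.flagged.append(t)
            selected[t] = []
            continue
        maxima = raw.max(axis=0)
        if (maxima <= 0).any():
            logger.warning("type %r: nonpositive correlation maximum; no selection", t)
            report.flagged.append(t)
            selected[t] = []
            continue
        norm = raw / maxima
        report.normalized[t] = norm
        passes = ((norm["tau"] > ts) | (norm["tau"] == 1.0)) \
            & ((norm["rho"] > rs) | (norm["rho"] == 1.0))
        selected[t] = list(norm.index[passes])
    return selected


def build_marker_matrix(marker_sets: dict, max_types_per_gene: int = 2,
                        type_order=None) -> MarkerMatrix:
    """Binary signature over the union of selected genes, plus a dummy column.

    Genes selected for more than ``max_types_per_gene`` types are removed
    entirely.
    """
    types = list(type_order) if type_order is not None else list(marker_sets)
    n_hits = {}
    for t in types:
        for g in marker_sets.get(t, []):
            n_hits[g] = n_hits.get(g, 0) + 1
    genes = [g for g in n_hits if n_hits[g] <= max_types_per_gene]
    dropped = [g for g in n_hits if n_hits[g] > max_types_per_gene]
    if dropped:
        logger.info("removed %d genes assigned to more than %d types",
                    len(dropped), max_types_per_gene)
    if not genes:
        raise ValueError("no marker genes survive selection")
    B = np.zeros((len(genes), len(types) + 1), dtype=np.int8)
    pos = {g: i for i, g in enumerate(genes)}
    for t_i, t in enumerate(types):
        for g in marker_sets.get(t, []):
            if g in pos:
                B[pos[g], t_i] = 1
    return MarkerMatrix(B, genes, [str(t) for t in types] + [DUMMY_TYPE_NAME],
                        dummy_index=len(types))


def select_markers(config: MarkerSelectionConfig, data: ExpressionMatrix):
    """Run the whole sieve; returns (MarkerMatrix, CorrelationReport)."""
    config.validate(data)
    report = CorrelationReport(retained={}, raw={})
    for t, cands in config.candidates.items():
        retained = filter_low_expression(cands, data, config.r_N, config.r_K)
        if not retained:
            logger.warning("type %r: empty retained set after expression filtering", t)
            report.flagged.append(t)
        report.retained[t] = retained
        report.raw[t] = lead_correlations(retained, data, config.lead_gene[t])
    tau = {t: config.threshold("tau_star", t) for t in config.candidates}
    rho = {t: config.threshold("rho_star", t) for t in config.candidates}
    selected = normalize_and_select(report, tau, rho)
    matrix = build_marker_matrix(selected, config.max_types_per_gene,
                                 type_order=list(config.candidates))
    return matrix, report
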