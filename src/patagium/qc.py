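"""Cell quality control, log-normalisation, HVG selection, cluster annotation.

The QC rules operate per library ("sample"): cells are removed when their
total UMI count exceeds 4x the sample mean or falls below 0.2x the sample
median; when their ribosomal UMI fraction leaves the band median +/- 3xMAD
(MAD unscaled by default); or when their genes-detected / total-UMI ratio
drops below 0.15 while the total is below two thirds of the sample median
(a low-complexity rule that only bites for small cells).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datasets import CellDataset, DatasetError, LOGNORM_LAYER

QC_RULES = ("umi_upper", "umi_lower", "ribo_upper", "ribo_lower", "low_complexity")


def _mad(x: np.ndarray, scale: float = 1.0) -> float:
    """Median absolute deviation; ``scale=1.4826`` gives the normal-consistent MAD."""
    x = np.asarray(x, float)
    return float(scale * np.median(np.abs(x - np.median(x))))


@dataclass
class QCThresholds:
    umi_upper: float
    umi_lower: float
    ribo_upper: float
    ribo_lower: float
    genes_per_umi_min: float = 0.15
    umi_relative_floor: float = 2.0 / 3.0
    umi_median: float = 0.0
    sample_id: str = ""
    ribo_enabled: bool = True
    # the low-complexity rule couples its two clauses with AND by default;
    # the disjunctive reading is selectable
    complexity_conjunction: bool = True

    def __post_init__(self) -> None:
        if not self.umi_lower < self.umi_upper:
            raise ValueError("umi_lower must be below umi_upper")
        if self.ribo_enabled and not self.ribo_lower <= self.ribo_upper:
            raise ValueError("ribo_lower must not exceed ribo_upper")


@dataclass
class QCReport:
    thresholds: dict
    cell_pass: pd.Series
    violations: pd.Series  # per cell: list of violated rule names
    removed_per_rule: dict = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return int((~self.cell_pass).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pass": self.cell_pass,
            "violations": self.violations.map(lambda v: ",".join(v)),
        })


def compute_qc_thresholds(dataset: CellDataset, sample_id: str = "",
                          mad_scale: float = 1.0,
                          umi_upper_factor: float = 4.0,
                          umi_lower_factor: float = 0.2,
                          mad_multiplier: float = 3.0,
                          ribo_two_sided: bool = True) -> QCThresholds:
    """Per-sample thresholds: 4x mean / 0.2x median totals, median +/- 3 MAD ribo."""
    if dataset.n_cells == 0:
        raise DatasetError("cannot compute QC thresholds on an empty dataset")
    totals = dataset.total_umis().astype(float)
    umi_upper = umi_upper_factor * float(np.mean(totals))
    umi_lower = umi_lower_factor * float(np.median(totals))
    ribo_enabled = bool(dataset.adata.var["ribosomal"].any())
    if ribo_enabled:
        frac = dataset.ribo_fraction()
        med, mad = float(np.median(frac)), _mad(frac, mad_scale)
        ribo_upper = med + mad_multiplier * mad
        ribo_lower = med - mad_multiplier * mad if ribo_two_sided else -np.inf
    else:
        warnings.warn("no ribosomal gene flags: ribosomal QC rules disabled")
        ribo_lower, ribo_upper = -np.inf, np.inf
    return QCThresholds(
        umi_upper=umi_upper, umi_lower=umi_lower,
        ribo_upper=ribo_upper, ribo_lower=ribo_lower,
        umi_median=float(np.median(totals)),
        sample_id=sample_id, ribo_enabled=ribo_enabled)


def evaluate_qc_rules(dataset: CellDataset, thresholds: QCThresholds) -> pd.DataFrame:
    """Boolean rule-violation matrix (cells x rules) under the given thresholds."""
    totals = dataset.total_umis().astype(float)
    genes = dataset.genes_detected().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(totals > 0, genes / np.maximum(totals, 1), 0.0)
    out = pd.DataFrame(index=dataset.cell_ids)
    out["umi_upper"] = totals > thresholds.umi_upper
    out["umi_lower"] = totals < thresholds.umi_lower
    if thresholds.ribo_enabled:
        frac = dataset.ribo_fraction()
        out["ribo_upper"] = frac > thresholds.ribo_upper
        out["ribo_lower"] = frac < thresholds.ribo_lower
    else:
        out["ribo_upper"] = False
        out["ribo_lower"] = False
    low_ratio = ratio < thresholds.genes_per_umi_min
    low_total = totals < thresholds.umi_relative_floor * thresholds.umi_median
    out["low_complexity"] = (low_ratio & low_total
                             if thresholds.complexity_conjunction
                             else low_ratio | low_total)
    return out


def apply_qc(dataset: CellDataset, thresholds: QCThresholds):
    """Remove rule-violating cells; return (filtered dataset, QCReport)."""
    rules = evaluate_qc_rules(dataset, thresholds)
    violated = rules.apply(lambda row: [r for r in rules.columns if row[r]], axis=1)
    cell_pass = ~rules.any(axis=1)
    report = QCReport(
        thresholds=asdict(thresholds),
        cell_pass=cell_pass,
        violations=violated,
        removed_per_rule={r: int(rules[r].sum()) for r in rules.columns},
    )
    return dataset.subset_cells(cell_pass.to_numpy()), report


def log_normalize(dataset: CellDataset, scale_factor: float = 10_000.0) -> CellDataset:
    """Fill the lognorm layer: ln(1 + scale_factor * count / cell_total)."""
    totals = dataset.total_umis().astype(float)
    if np.any(totals == 0):
        bad = dataset.cell_ids[totals == 0].tolist()
        raise DatasetError(f"cells with zero total UMIs cannot be normalized: {bad[:5]}")
    norm = dataset.counts.astype(float).tocsr(copy=True)
    row = np.repeat(np.arange(dataset.n_cells), np.diff(norm.indptr))
    norm.data = np.log1p(scale_factor * norm.data / totals[row])
    dataset.adata.layers[LOGNORM_LAYER] = norm
    dataset.adata.uns["normalization"] = {
        "method": "lognorm", "base": "e", "pseudocount": 1.0,
        "scale_factor": float(scale_factor)}
    return dataset


def select_hvgs(dataset: CellDataset, mad_scale: float = 1.0) -> list[str]:
    """Genes whose variance of normalized expression exceeds median + MAD."""
    norm = dataset.require_normalized()
    if dataset.n_cells < 2:
        raise DatasetError("need at least 2 cells for variance-based HVG selection")
    n = norm.shape[0]
    mean = np.asarray(norm.mean(axis=0)).ravel()
    sq = norm.copy()
    sq.data = sq.data ** 2
    ex2 = np.asarray(sq.mean(axis=0)).ravel()
    var = (ex2 - mean ** 2) * n / (n - 1)
    cutoff = float(np.median(var)) + _mad(var, mad_scale)
    keep = var > cutoff
    return dataset.gene_ids[keep].tolist()


def annotate_clusters_by_majority(cell_labels: pd.Series,
                                  cell_clusters: pd.Series,
                                  reference_group_of_label: dict) -> dict:
    """Majority vote: per cluster pick the winning label group, then the most
    frequent label inside it; ties break lexicographically."""
    labels = pd.Series(cell_labels)
    clusters = pd.Series(cell_clusters)
    if labels.isna().any():
        raise ValueError("every cell needs a candidate label")
    out = {}
    for cl, idx in clusters.groupby(clusters).groups.items():
        sub = labels.loc[idx]
        if len(sub) == 0:
            raise ValueError(f"cluster {cl!r} is empty")
        groups = sub.map(reference_group_of_label)
        gcounts = groups.value_counts()
        top = gcounts[gcounts == gcounts.max()].index.min()  # lexicographic tie-break
        in_group = sub[groups == top]
        lcounts = in_group.value_counts()
        out[cl] = lcounts[lcounts == lcounts.max()].index.min()
    return out


def haemoglobin_cluster_filter(dataset: CellDataset, max_fraction: float = 0.1) -> list[str]:
    """Clusters whose mean haemoglobin UMI fraction exceeds ``max_fraction``.

    Exposed as an explicit filter (the source data contained one erythroid
    cluster dominated by haemoglobin transcripts); never applied automatically.
    """
    mask = dataset.adata.var["haemoglobin"].to_numpy(bool)
    if not mask.any():
        return []
    totals = dataset.total_umis().astype(float)
    hb = np.asarray(dataset.counts[:, mask].sum(axis=1)).ravel()
    frac = np.where(totals > 0, hb / np.maximum(totals, 1), 0.0)
    per_cluster = pd.Series(frac, index=dataset.cell_ids).groupby(
        dataset.clusters.to_numpy()).mean()
    return per_cluster[per_cluster > max_fraction].index.tolist()
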