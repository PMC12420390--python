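"""Proximo-distal dissection: module scores with binned control genes, the
PD score, cluster classification, cross-species gene categorisation,
co-expression and composition summaries.

The module score of a gene set in a cell is the mean normalized expression
of the set genes minus the mean over a pool of expression-matched control
genes: genes are binned into ``n_bins`` equal-count bins by their average
normalized expression across cells, and each set gene contributes
``n_ctrl`` controls sampled with replacement from its bin (set genes are
excluded from the pools, which makes constant-expression cases exact).
The PD score is distal-set score minus proximal-set score; the top and
bottom thirds of clusters by mean PD are called very distal / very proximal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import CellDataset, DatasetError, OrthologyMap

DISTAL_SET = ("HOXD13", "MSX1")
PROXIMAL_SET = ("SHOX2",)
CHONDROGENIC_SET = ("SOX9", "COL2A1")
FIBROBLASTIC_SET = ("DCN", "ZFHX3")


def module_score(dataset: CellDataset, gene_set, n_bins: int = 24,
                 n_ctrl: int = 100, seed: int = 0) -> np.ndarray:
    """Per-cell score: mean(set genes) - mean(pooled binned control genes)."""
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("gene_set is empty")
    set_idx = dataset.gene_index(gene_set)
    norm = dataset.require_normalized()
    avg = np.asarray(norm.mean(axis=0)).ravel()

    # equal-count bins by average expression (ties broken by gene order)
    order = np.argsort(avg, kind="stable")
    n_genes = len(avg)
    bins = np.empty(n_genes, dtype=int)
    n_bins_eff = min(n_bins, n_genes)
    bins[order] = np.minimum((np.arange(n_genes) * n_bins_eff) // n_genes,
                             n_bins_eff - 1)

    in_set = np.zeros(n_genes, bool)
    in_set[set_idx] = True
    rng = np.random.default_rng(seed)
    ctrl_idx = []
    for gi in set_idx:
        pool = np.flatnonzero((bins == bins[gi]) & ~in_set)
        if len(pool) == 0:  # bin holds only set genes: widen to all non-set genes
            pool = np.flatnonzero(~in_set)
        if len(pool) == 0:
            raise ValueError("no control genes available outside the gene set")
        ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=True))
    ctrl_idx = np.concatenate(ctrl_idx)

    set_mean = np.asarray(norm[:, set_idx].mean(axis=1)).ravel()
    dense_ctrl = norm[:, ctrl_idx]  # keeps control multiplicity
    ctrl_mean = np.asarray(dense_ctrl.mean(axis=1)).ravel()
    return set_mean - ctrl_mean


@dataclass
class ModuleScoreSet:
    """Named per-cell module scores plus the scoring parameters used."""

    scores: pd.DataFrame
    params: dict = field(default_factory=dict)

    @classmethod
    def compute(cls, dataset: CellDataset, gene_sets: dict,
                n_bins: int = 24, n_ctrl: int = 100, seed: int = 0) -> "ModuleScoreSet":
        cols = {name: module_score(dataset, genes, n_bins, n_ctrl, seed)
                for name, genes in gene_sets.items()}
        df = pd.DataFrame(cols, index=dataset.cell_ids)
        return cls(scores=df, params={"n_bins": n_bins, "n_ctrl": n_ctrl, "seed": seed})


def pd_score(distal_scores: np.ndarray, proximal_scores: np.ndarray) -> np.ndarray:
    """PD[c] = distal score - proximal score (positive = distal identity)."""
    distal = np.asarray(distal_scores, float)
    proximal = np.asarray(proximal_scores, float)
    if distal.shape != proximal.shape:
        raise ValueError("distal and proximal score vectors are misaligned")
    return distal - proximal


def classify_clusters_pd(per_cluster_mean_pd: pd.Series,
                         extreme_fraction: float = 1.0 / 3.0) -> pd.Series:
    """Top third of clusters by mean PD -> very-distal, bottom third ->
    very-proximal, the rest intermediate.  Ties break by cluster name."""
    means = pd.Series(per_cluster_mean_pd).astype(float)
    k = len(means)
    if k < 3:
        raise ValueError("need at least 3 clusters to classify PD extremes")
    n_extreme = math.floor(k * extreme_fraction)
    # deterministic: sort by (value, name)
    ordered = means.iloc[np.lexsort((means.index.astype(str), means.to_numpy()))]
    cats = pd.Series("intermediate", index=means.index, name="pd_category")
    if n_extreme:
        cats[ordered.index[:n_extreme]] = "very-proximal"
        cats[ordered.index[-n_extreme:]] = "very-distal"
    return cats


@dataclass
class GeneCategoryResult:
    typical_distal: list
    typical_proximal: list
    evidence: pd.DataFrame
    excluded_chondrogenic: list


def _pseudo_log2fc(mean_in: np.ndarray, mean_out: np.ndarray,
                   pseudocount: float = 1.0) -> np.ndarray:
    return np.log2(mean_in + pseudocount) - np.log2(mean_out + pseudocount)


def _species_evidence(datasets_with_categories, genes, min_detect=0.2,
                      min_cluster_fraction=0.2):
    """Per-gene detection/log2FC evidence for one species, pooled over datasets.

    Returns a frame with, for each direction (distal, proximal): the number of
    very-<direction> clusters where the gene is detected in >= ``min_detect``
    of cells, the cluster quorum ceil(0.2 x K), and the log2FC of pooled
    very-distal vs very-proximal cells (and vice versa).
    """
    det_pass = {"distal": [], "proximal": []}
    k_clusters = {"distal": 0, "proximal": 0}
    pooled = {"distal": [], "proximal": []}
    for dataset, categories in datasets_with_categories:
        gidx = dataset.gene_index(genes)
        norm = dataset.require_normalized()
        expm1 = norm.copy()
        expm1.data = np.expm1(expm1.data)
        clusters = dataset.clusters
        for direction, cat in (("distal", "very-distal"), ("proximal", "very-proximal")):
            for cl in categories[categories == cat].index:
                mask = (clusters == cl).to_numpy()
                if mask.sum() == 0:
                    continue
                k_clusters[direction] += 1
                det = dataset.detection_fraction(mask)[gidx]
                det_pass[direction].append(det >= min_detect)
            mask_all = clusters.isin(categories[categories == cat].index).to_numpy()
            pooled[direction].append(
                np.asarray(expm1[mask_all][:, gidx].mean(axis=0)).ravel()
                if mask_all.sum() else np.zeros(len(gidx)))
    out = pd.DataFrame(index=pd.Index(genes, name="gene"))
    for direction in ("distal", "proximal"):
        k = k_clusters[direction]
        quorum = max(1, math.ceil(min_cluster_fraction * k)) if k else 1
        n_pass = (np.sum(det_pass[direction], axis=0)
                  if det_pass[direction] else np.zeros(len(genes)))
        out[f"{direction}_clusters_detected"] = n_pass
        out[f"{direction}_cluster_quorum"] = quorum
        out[f"{direction}_n_clusters"] = k
    mean_d = np.mean(pooled["distal"], axis=0)
    mean_p = np.mean(pooled["proximal"], axis=0)
    out["log2fc_distal_vs_proximal"] = _pseudo_log2fc(mean_d, mean_p)
    out["log2fc_proximal_vs_distal"] = _pseudo_log2fc(mean_p, mean_d)
    return out


def chondrogenic_high_genes(dataset: CellDataset, chondro_scores: np.ndarray,
                            genes, top_quantile: float = 0.9,
                            log2_margin: float = 1.0) -> set:
    """Genes whose mean expression in the top-decile chondrogenic-score cells
    exceeds their global mean by more than ``log2_margin`` (log2, pseudocount 1)."""
    gidx = dataset.gene_index(genes)
    norm = dataset.require_normalized()
    expm1 = norm.copy()
    expm1.data = np.expm1(expm1.data)
    cut = np.quantile(np.asarray(chondro_scores, float), top_quantile)
    mask = np.asarray(chondro_scores, float) >= cut
    mean_top = np.asarray(expm1[mask][:, gidx].mean(axis=0)).ravel()
    mean_all = np.asarray(expm1[:, gidx].mean(axis=0)).ravel()
    lfc = _pseudo_log2fc(mean_top, mean_all)
    return {g for g, v in zip(genes, lfc) if v > log2_margin}


def categorize_pd_genes(datasets_by_species: dict, orthology: OrthologyMap,
                        chondro_scores_by_species: dict | None = None,
                        min_detect: float = 0.2, min_cluster_fraction: float = 0.2,
                        lfc_threshold: float = 0.15,
                        chondro_log2_margin: float = 1.0) -> GeneCategoryResult:
    """Typical proximal/distal genes, required to pass in BOTH species.

    ``datasets_by_species`` maps the two species names (orthology species_a
    first) to lists of ``(dataset, categories)`` pairs; the shared gene space
    is the orthology-mapped intersection, and all evidence columns are reported
    on species-a gene ids.
    """
    species = list(datasets_by_species)
    if len(species) != 2:
        raise DatasetError("categorize_pd_genes needs exactly two species")
    sp_a, sp_b = species
    a2b = orthology.a_to_b()
    genes_a_all = set.intersection(*[set(d.gene_ids)
                                     for d, _ in datasets_by_species[sp_a]])
    genes_b_all = set.intersection(*[set(d.gene_ids)
                                     for d, _ in datasets_by_species[sp_b]])
    shared_a = sorted(g for g in genes_a_all if a2b.get(g) in genes_b_all)
    if not shared_a:
        raise DatasetError("orthology leaves no shared genes between species")
    shared_b = [a2b[g] for g in shared_a]

    ev_a = _species_evidence(datasets_by_species[sp_a], shared_a,
                             min_detect, min_cluster_fraction)
    ev_b = _species_evidence(datasets_by_species[sp_b], shared_b,
                             min_detect, min_cluster_fraction)
    ev_b.index = pd.Index(shared_a, name="gene")

    def passes(ev, direction):
        det = ev[f"{direction}_clusters_detected"] >= ev[f"{direction}_cluster_quorum"]
        opp = "proximal" if direction == "distal" else "distal"
        lfc = ev[f"log2fc_{direction}_vs_{opp}"] > lfc_threshold
        return det & lfc

    distal = passes(ev_a, "distal") & passes(ev_b, "distal")
    proximal = passes(ev_a, "proximal") & passes(ev_b, "proximal")

    excluded = set()
    if chondro_scores_by_species:
        for spn, sets in datasets_by_species.items():
            scores = chondro_scores_by_species.get(spn)
            if scores is None:
                continue
            for (dataset, _), sc in zip(sets, scores):
                local = shared_a if spn == sp_a else shared_b
                high = chondrogenic_high_genes(dataset, sc, local,
                                               log2_margin=chondro_log2_margin)
                if spn == sp_b:
                    b2a = orthology.b_to_a()
                    high = {b2a[g] for g in high if g in b2a}
                excluded |= high

    evidence = ev_a.add_suffix(f"_{sp_a}").join(ev_b.add_suffix(f"_{sp_b}"))
    typical_distal = sorted(set(distal[distal].index) - excluded)
    typical_proximal = sorted((set(proximal[proximal].index) - excluded)
                              - set(typical_distal))
    return GeneCategoryResult(
        typical_distal=typical_distal,
        typical_proximal=typical_proximal,
        evidence=evidence,
        excluded_chondrogenic=sorted(excluded))


def top_marker_display_filter(gene_evidence: pd.DataFrame, n: int = 15,
                              max_opposite_pct: float = 0.15,
                              lfc_col: str = "log2fc",
                              opposite_pct_col: str = "opposite_pct") -> list:
    """Among genes detected in < ``max_opposite_pct`` of the opposite cells,
    return the ``n`` highest by log2FC."""
    qual = gene_evidence[gene_evidence[opposite_pct_col] < max_opposite_pct]
    return qual.sort_values(lfc_col, ascending=False,
                            kind="stable").head(n).index.tolist()


def coexpression_fraction(dataset: CellDataset, gene_x: str, gene_y: str,
                          by: str | None = "cluster") -> pd.DataFrame:
    """Fraction of cells with raw counts of both genes > 0, per group.

    Reports the joint fraction alongside the single-gene detection fractions.
    ``by=None`` treats the whole dataset as one group.
    """
    ix, iy = dataset.gene_index([gene_x, gene_y])
    cx = np.asarray(dataset.counts[:, ix].todense()).ravel() > 0
    cy = np.asarray(dataset.counts[:, iy].todense()).ravel() > 0
    if by is None:
        groups = pd.Series("all", index=dataset.cell_ids)
    else:
        groups = dataset.clusters if by == "cluster" else dataset.cell_meta[by]
    df = pd.DataFrame({"x": cx, "y": cy, "both": cx & cy,
                       "group": groups.to_numpy()})
    agg = df.groupby("group").agg(
        n=("both", "size"), frac_x=("x", "mean"),
        frac_y=("y", "mean"), frac_both=("both", "mean"))
    agg.insert(0, "gene_x", gene_x)
    agg.insert(1, "gene_y", gene_y)
    return agg


def cluster_composition(labels) -> pd.DataFrame:
    """Counts and proportions per label; proportions sum to 1."""
    s = pd.Series(labels)
    if len(s) == 0:
        raise ValueError("empty label vector")
    counts = s.value_counts().sort_index()
    return pd.DataFrame({"count": counts,
                         "proportion": counts / counts.sum()})
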