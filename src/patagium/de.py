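"""Rank-based differential expression and programme derivation.

``wilcoxon_de`` is a Wilcoxon rank-sum test over normalized expression with
the detection-percentage and log2FC gates used throughout the analysis.
Fold changes follow the convention log2((mean_in + 1) / (mean_out + 1)) on
de-logged (expm1) normalized expression.  P values come from an exact,
tie-aware permutation distribution of the rank sum when the smaller group
has at most ``exact_max_group`` cells and the total is small enough to
enumerate, and from a tie-corrected normal approximation otherwise;
Benjamini-Hochberg adjustment runs across tested genes only.

``derive_programme`` implements the two-round reciprocal derivation of the
proximo-distal fibroblast programme: distal fibroblasts vs all other cells
except proximal fibroblasts, and vice versa, first on highly variable
genes, then re-tested on the union of round-1 DE genes; the shared
programme is the genes with log2FC > 0.1 in both round-2 comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import CellDataset, DatasetError, OrthologyMap


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum machinery
# ---------------------------------------------------------------------------

def exact_ranksum_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided p for the rank-sum of ``x``, by tie-aware enumeration.

    Uses the permutation distribution of the sum of ``len(x)`` mid-ranks drawn
    without replacement from the pooled mid-ranks (shift-algorithm dynamic
    programme), so ties are handled exactly.  Two-sided p = 2 x min(tails),
    capped at 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n = len(x), len(x) + len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    r2 = np.round(ranks * 2).astype(int)  # doubled mid-ranks are integers
    w_obs = int(round(r2[:n1].sum()))
    max_sum = int(r2.sum())
    # dp[k, s]: number of k-subsets of the items seen so far with doubled-rank sum s
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in r2:
        dp[1:, r:] += dp[:-1, : max_sum + 1 - r]
    dist = dp[n1]
    total = dist.sum()
    lower = dist[: w_obs + 1].sum() / total
    upper = dist[w_obs:].sum() / total
    return float(min(1.0, 2.0 * min(lower, upper)))


def _tie_corrected_normal_p(ranks_in_sum, n1, n2, tie_term):
    """Vectorised two-sided normal approximation with tie correction."""
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    var = np.maximum(var, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (ranks_in_sum - mu) / np.sqrt(var)
    z = np.where(var > 0, z, 0.0)
    return 2.0 * stats.norm.sf(np.abs(z))


def _tie_terms(sorted_cols: np.ndarray) -> np.ndarray:
    """Sum of (t^3 - t) over tie groups, per column of a column-sorted matrix."""
    n, g = sorted_cols.shape
    out = np.zeros(g)
    for j in range(g):
        _, counts = np.unique(sorted_cols[:, j], return_counts=True)
        t = counts[counts > 1].astype(float)
        out[j] = np.sum(t ** 3 - t)
    return out


@dataclass
class DERecord:
    gene: str
    log2fc: float
    pct_in: float
    pct_out: float
    p: float
    p_adj: float
    group_in: str = ""
    group_out: str = ""


def wilcoxon_de(dataset: CellDataset, group_in: np.ndarray, group_out: np.ndarray,
                min_pct: float = 0.25, lfc_threshold: float = 0.5,
                gene_subset=None, pseudocount: float = 1.0,
                exact_max_group: int = 8, exact_max_total: int = 30,
                group_in_name: str = "in", group_out_name: str = "out") -> pd.DataFrame:
    """Rank-sum DE of ``group_in`` vs ``group_out`` cells.

    Returns a frame indexed by gene with columns log2fc, pct_in, pct_out,
    tested, p, p_adj.  Genes failing the ``max(pct) >= min_pct`` or
    ``|log2fc| >= lfc_threshold`` gates are reported untested with NaN p.
    """
    group_in = np.asarray(group_in, bool)
    group_out = np.asarray(group_out, bool)
    if group_in.sum() == 0 or group_out.sum() == 0:
        raise DatasetError("both DE groups must be non-empty")
    if (group_in & group_out).any():
        raise DatasetError("DE groups overlap")
    norm = dataset.require_normalized()
    if gene_subset is not None:
        gidx = dataset.gene_index(gene_subset)
        genes = pd.Index(gene_subset)
    else:
        gidx = np.arange(dataset.n_genes)
        genes = dataset.gene_ids

    pct_in = dataset.detection_fraction(group_in)[gidx]
    pct_out = dataset.detection_fraction(group_out)[gidx]

    sub_in = norm[group_in][:, gidx]
    sub_out = norm[group_out][:, gidx]
    expm1_in = np.asarray(sub_in.todense())
    expm1_out = np.asarray(sub_out.todense())
    np.expm1(expm1_in, out=expm1_in)
    np.expm1(expm1_out, out=expm1_out)
    mean_in = expm1_in.mean(axis=0)
    mean_out = expm1_out.mean(axis=0)
    log2fc = np.log2(mean_in + pseudocount) - np.log2(mean_out + pseudocount)

    tested = (np.maximum(pct_in, pct_out) >= min_pct) & (np.abs(log2fc) >= lfc_threshold)

    n1, n2 = int(group_in.sum()), int(group_out.sum())
    p = np.full(len(gidx), np.nan)
    t_idx = np.flatnonzero(tested)
    if len(t_idx):
        # rank on the normalized values (monotone in expm1, identical ranks)
        stacked = np.vstack([np.asarray(sub_in[:, t_idx].todense()),
                             np.asarray(sub_out[:, t_idx].todense())])
        use_exact = (min(n1, n2) <= exact_max_group
                     and (n1 + n2) <= exact_max_total)
        if use_exact:
            for k, j in enumerate(t_idx):
                p[j] = exact_ranksum_pvalue(stacked[:n1, k], stacked[n1:, k])
        else:
            ranks = stats.rankdata(stacked, axis=0)
            w_in = ranks[:n1].sum(axis=0)
            ties = _tie_terms(np.sort(stacked, axis=0))
            p[t_idx] = _tie_corrected_normal_p(w_in, n1, n2, ties)

    p_adj = np.full(len(gidx), np.nan)
    if len(t_idx):
        p_adj[t_idx] = multipletests(p[t_idx], method="fdr_bh")[1]

    return pd.DataFrame({
        "log2fc": log2fc, "pct_in": pct_in, "pct_out": pct_out,
        "tested": tested, "p": p, "p_adj": p_adj,
        "group_in": group_in_name, "group_out": group_out_name,
    }, index=pd.Index(genes, name="gene"))


# ---------------------------------------------------------------------------
# Programme derivation
# ---------------------------------------------------------------------------

@dataclass
class ProgrammeSets:
    distal_enriched: list
    proximal_enriched: list
    shared: list
    distal_only: list
    proximal_only: list
    cross_species_shared: list = field(default_factory=list)
    round2_distal: pd.DataFrame | None = None
    round2_proximal: pd.DataFrame | None = None

    def all_programme_genes(self) -> list:
        return sorted(set(self.distal_enriched) | set(self.proximal_enriched))

    def to_dict(self) -> dict:
        return {k: sorted(getattr(self, k)) for k in (
            "distal_enriched", "proximal_enriched", "shared",
            "distal_only", "proximal_only", "cross_species_shared")}


def _cluster_masks(dataset: CellDataset, distal_cluster, proximal_clusters):
    clusters = dataset.clusters
    proximal_clusters = list(proximal_clusters)
    m_distal = (clusters == distal_cluster).to_numpy()
    m_proximal = clusters.isin(proximal_clusters).to_numpy()
    if m_distal.sum() == 0:
        raise DatasetError(f"distal cluster {distal_cluster!r} has no cells")
    if m_proximal.sum() == 0:
        raise DatasetError(f"proximal clusters {proximal_clusters!r} have no cells")
    m_rest = ~(m_distal | m_proximal)
    return m_distal, m_proximal, m_rest


def derive_programme(dataset: CellDataset, distal_cluster, proximal_clusters,
                     hvgs, orthology: OrthologyMap | None = None,
                     dataset_other: CellDataset | None = None,
                     other_proximal_clusters=None,
                     min_pct: float = 0.25, lfc_threshold: float = 0.5,
                     shared_lfc: float = 0.1, alpha: float = 0.05) -> ProgrammeSets:
    """Two-round reciprocal programme derivation (see module docstring).

    Round 1 tests (distal vs rest-except-proximal) and (proximal vs
    rest-except-distal) on ``hvgs`` with the marker-DE gates; round 2 re-tests
    both comparisons, ungated, on the union of round-1 DE genes.  When
    ``orthology`` and ``dataset_other`` are given, the cross-species-shared set
    is the shared genes whose orthologue is enriched (p_adj < alpha and
    log2FC > ``shared_lfc``) in the other species' proximal fibroblasts.
    """
    hvgs = list(hvgs)
    if not hvgs:
        raise DatasetError("hvgs must be non-empty")
    m_distal, m_proximal, m_rest = _cluster_masks(
        dataset, distal_cluster, proximal_clusters)

    def run(gene_subset, gated: bool):
        kw = dict(min_pct=min_pct, lfc_threshold=lfc_threshold) if gated else \
            dict(min_pct=0.0, lfc_threshold=0.0)
        de_d = wilcoxon_de(dataset, m_distal, m_rest, gene_subset=gene_subset,
                           group_in_name="distal_fb", group_out_name="rest", **kw)
        de_p = wilcoxon_de(dataset, m_proximal, m_rest, gene_subset=gene_subset,
                           group_in_name="proximal_fb", group_out_name="rest", **kw)
        return de_d, de_p

    r1_d, r1_p = run(hvgs, gated=True)
    sig = lambda df: set(df.index[(df["tested"]) & (df["p_adj"] < alpha)])
    union = sorted(sig(r1_d) | sig(r1_p))
    if not union:
        empty = pd.DataFrame()
        return ProgrammeSets([], [], [], [], [], [], empty, empty)

    r2_d, r2_p = run(union, gated=False)
    enr_d = set(r2_d.index[(r2_d["p_adj"] < alpha) & (r2_d["log2fc"] > shared_lfc)])
    enr_p = set(r2_p.index[(r2_p["p_adj"] < alpha) & (r2_p["log2fc"] > shared_lfc)])
    both_up = set(r2_d.index[(r2_d["log2fc"] > shared_lfc)
                             & (r2_p["log2fc"] > shared_lfc)])
    shared = (enr_d | enr_p) & both_up
    distal_only = enr_d - shared
    proximal_only = enr_p - shared

    cross = []
    if orthology is not None and dataset_other is not None and shared:
        if other_proximal_clusters is None:
            raise DatasetError("other_proximal_clusters required for cross-species set")
        a2b = orthology.a_to_b()
        mapped = {g: a2b[g] for g in shared if g in a2b}
        present = {g: m for g, m in mapped.items()
                   if m in set(dataset_other.gene_ids)}
        if present:
            oc = dataset_other.clusters
            m_in = oc.isin(list(other_proximal_clusters)).to_numpy()
            m_out = ~m_in
            de_o = wilcoxon_de(dataset_other, m_in, m_out,
                               gene_subset=sorted(set(present.values())),
                               min_pct=0.0, lfc_threshold=0.0,
                               group_in_name="proximal_fb_other",
                               group_out_name="rest_other")
            enr_o = set(de_o.index[(de_o["p_adj"] < alpha)
                                   & (de_o["log2fc"] > shared_lfc)])
            cross = sorted(g for g, m in present.items() if m in enr_o)

    return ProgrammeSets(
        distal_enriched=sorted(enr_d), proximal_enriched=sorted(enr_p),
        shared=sorted(shared), distal_only=sorted(distal_only),
        proximal_only=sorted(proximal_only), cross_species_shared=cross,
        round2_distal=r2_d, round2_proximal=r2_p)


# ---------------------------------------------------------------------------
# Cross-species concordance, over-representation, mutant evaluation
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceResult:
    paired: pd.DataFrame  # log2fc_a, log2fc_b, delta, within_band
    band: float
    unpaired: list = field(default_factory=list)

    @property
    def fraction_within_band(self) -> float:
        if len(self.paired) == 0:
            return float("nan")
        return float(self.paired["within_band"].mean())


def crossspecies_lfc_compare(de_a: pd.DataFrame, de_b: pd.DataFrame,
                             orthology: OrthologyMap,
                             gene_sets: dict | None = None,
                             band: float = 0.25) -> ConcordanceResult:
    """Pair per-gene log2FCs across species via orthology; flag |delta| <= band."""
    a2b = orthology.a_to_b()
    rows, unpaired = [], []
    for g in de_a.index:
        m = a2b.get(g)
        if m is None or m not in de_b.index:
            unpaired.append(g)
            continue
        la, lb = float(de_a.loc[g, "log2fc"]), float(de_b.loc[m, "log2fc"])
        delta = la - lb
        rows.append((g, m, la, lb, delta, abs(delta) <= band))
    paired = pd.DataFrame(rows, columns=["gene_a", "gene_b", "log2fc_a",
                                         "log2fc_b", "delta", "within_band"])
    paired = paired.set_index("gene_a")
    if gene_sets:
        for name, genes in gene_sets.items():
            paired[f"in_{name}"] = paired.index.isin(set(genes))
    return ConcordanceResult(paired=paired, band=band, unpaired=unpaired)


def overrepresentation(hits, reference_set, universe):
    """Upper-tail hypergeometric p for the overlap of hits with a reference set."""
    hits, reference_set, universe = set(hits), set(reference_set), set(universe)
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    if not reference_set <= universe:
        raise ValueError("reference_set must be a subset of the universe")
    overlap = len(hits & reference_set)
    m, n_ref, n_draw = len(universe), len(reference_set), len(hits)
    p = float(stats.hypergeom.sf(overlap - 1, m, n_ref, n_draw))
    return overlap, min(1.0, p)


def build_universe(dataset: CellDataset, min_cells: int = 9) -> list:
    """Background universe: genes detected (count > 0) in at least min_cells cells."""
    n_det = np.asarray((dataset.counts > 0).sum(axis=0)).ravel()
    return dataset.gene_ids[n_det >= min_cells].tolist()


def mutant_gene_filter(dataset: CellDataset, genotypes: pd.Series,
                       min_pct: float = 0.15,
                       exclude_flags=("chrx", "mitochondrial", "ribosomal")) -> list:
    """Genes detected in >= min_pct of cells of either genotype, excluding
    chrX / mitochondrial / ribosomal-flagged genes."""
    genotypes = pd.Series(genotypes)
    levels = genotypes.unique()
    keep = np.zeros(dataset.n_genes, bool)
    for lv in levels:
        mask = (genotypes == lv).to_numpy()
        keep |= dataset.detection_fraction(mask) >= min_pct
    excluded = np.zeros(dataset.n_genes, bool)
    import warnings as _warnings
    for flag in exclude_flags:
        if flag not in dataset.adata.var.columns:
            _warnings.warn(f"gene flag {flag!r} missing; exclusion skipped")
            continue
        excluded |= dataset.adata.var[flag].to_numpy(bool)
    return dataset.gene_ids[keep & ~excluded].tolist()


def profile_correlation(query_dataset: CellDataset,
                        reference_dataset: CellDataset,
                        reference_cluster, gene_set,
                        query_gene_map: dict | None = None) -> pd.DataFrame:
    """Pearson r of each query cell to the mean reference-cluster profile.

    The profile is the mean normalized expression of ``gene_set`` in the
    reference cluster; ``query_gene_map`` translates reference gene ids to
    query ids (orthology) when the two datasets use different namespaces.
    Zero-variance query cells get NaN.
    """
    gene_set = list(gene_set)
    ref_idx = reference_dataset.gene_index(gene_set)
    ref_norm = reference_dataset.require_normalized()
    mask = (reference_dataset.clusters == reference_cluster).to_numpy()
    if mask.sum() == 0:
        raise DatasetError(f"reference cluster {reference_cluster!r} is empty")
    profile = np.asarray(ref_norm[mask][:, ref_idx].mean(axis=0)).ravel()

    q_genes = [query_gene_map.get(g, g) for g in gene_set] if query_gene_map else gene_set
    q_idx = query_dataset.gene_index(q_genes)
    q = np.asarray(query_dataset.require_normalized()[:, q_idx].todense())

    pc = profile - profile.mean()
    qc = q - q.mean(axis=1, keepdims=True)
    denom = np.sqrt((qc ** 2).sum(axis=1)) * np.sqrt((pc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (qc @ pc) / denom
    r = np.where(denom > 0, r, np.nan)
    return pd.DataFrame({"r": r}, index=query_dataset.cell_ids)
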