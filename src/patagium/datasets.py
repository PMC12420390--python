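"""Core data containers: cell-by-gene count datasets and orthology maps.

``CellDataset`` wraps an :class:`anndata.AnnData` holding raw UMI counts
(cells x genes, sparse integer), per-cell metadata (species, limb, stage,
library, optional cluster label), per-gene boolean flags (ribosomal,
mitochondrial, chrX, haemoglobin, chondrogenic marker) and, once computed,
a log-normalised layer.  ``OrthologyMap`` is a strict one-to-one gene-ID
pairing between two species and gates every cross-species comparison.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

GENE_FLAGS = ("ribosomal", "mitochondrial", "chrx", "haemoglobin", "chondrogenic_marker")
META_COLUMNS = ("species", "limb", "stage", "library")

LOGNORM_LAYER = "lognorm"


class DatasetError(ValueError):
    """Raised for malformed or inconsistent dataset inputs."""


@dataclass
class CellDataset:
    """Sparse UMI counts plus aligned cell metadata and gene flags."""

    adata: ad.AnnData

    def __post_init__(self) -> None:
        X = self.adata.X
        if not sp.issparse(X):
            self.adata.X = sp.csr_matrix(np.asarray(X))
        else:
            self.adata.X = X.tocsr()
        if self.adata.X.nnz and (self.adata.X.data < 0).any():
            raise DatasetError("counts must be non-negative")
        if self.adata.X.nnz and np.any(self.adata.X.data != np.round(self.adata.X.data)):
            raise DatasetError("counts must be integers")
        if self.adata.var_names.duplicated().any():
            dupes = self.adata.var_names[self.adata.var_names.duplicated()].tolist()
            raise DatasetError(f"duplicate gene ids: {dupes[:5]}")
        for flag in GENE_FLAGS:
            if flag not in self.adata.var.columns:
                self.adata.var[flag] = False

    # -- basic accessors -------------------------------------------------
    @property
    def counts(self) -> sp.csr_matrix:
        return self.adata.X

    @property
    def n_cells(self) -> int:
        return self.adata.n_obs

    @property
    def n_genes(self) -> int:
        return self.adata.n_vars

    @property
    def gene_ids(self) -> pd.Index:
        return self.adata.var_names

    @property
    def cell_ids(self) -> pd.Index:
        return self.adata.obs_names

    @property
    def cell_meta(self) -> pd.DataFrame:
        return self.adata.obs

    @property
    def normalized(self) -> sp.csr_matrix | None:
        return self.adata.layers.get(LOGNORM_LAYER)

    @property
    def clusters(self) -> pd.Series:
        if "cluster" not in self.adata.obs.columns:
            raise DatasetError("dataset has no cluster labels")
        return self.adata.obs["cluster"]

    def require_normalized(self) -> sp.csr_matrix:
        norm = self.normalized
        if norm is None:
            raise DatasetError("dataset is not normalized; run log_normalize first")
        return norm

    # -- derived per-cell / per-gene quantities -------------------------
    def total_umis(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def genes_detected(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    def ribo_fraction(self) -> np.ndarray:
        """Per-cell fraction of UMIs on ribosomal-flagged genes."""
        totals = self.total_umis().astype(float)
        mask = self.adata.var["ribosomal"].to_numpy(bool)
        ribo = np.asarray(self.counts[:, mask].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, ribo / np.maximum(totals, 1), 0.0)
        return frac

    def detection_fraction(self, cell_mask: np.ndarray | None = None) -> np.ndarray:
        """Per-gene fraction of (masked) cells with raw count > 0."""
        mat = self.counts if cell_mask is None else self.counts[cell_mask]
        if mat.shape[0] == 0:
            return np.zeros(self.n_genes)
        return np.asarray((mat > 0).sum(axis=0)).ravel() / mat.shape[0]

    def gene_index(self, genes) -> np.ndarray:
        idx = self.gene_ids.get_indexer(list(genes))
        if (idx < 0).any():
            missing = [g for g, i in zip(genes, idx) if i < 0]
            raise DatasetError(f"genes absent from dataset: {missing[:10]}")
        return idx

    def subset_cells(self, mask: np.ndarray) -> "CellDataset":
        return CellDataset(self.adata[np.asarray(mask)].copy())

    def copy(self) -> "CellDataset":
        return CellDataset(self.adata.copy())


# -- MatrixMarket / TSV IO ----------------------------------------------

def read_cell_dataset(matrix_path: str, metadata_path: str,
                      barcodes_path: str | None = None,
                      features_path: str | None = None) -> CellDataset:
    """Load a 10x-style MTX triplet (genes x cells) or dense TSV plus metadata.

    The MTX convention follows CellRanger: rows are genes (features), columns
    are cells; the returned dataset is cells x genes.  Dense TSV input is
    cells x genes with gene ids as header and cell ids as the index column.
    """
    if matrix_path.endswith(".mtx"):
        base = os.path.dirname(matrix_path)
        barcodes_path = barcodes_path or os.path.join(base, "barcodes.tsv")
        features_path = features_path or os.path.join(base, "features.tsv")
        mat = scipy.io.mmread(matrix_path)
        if np.any(mat.data != np.round(mat.data)):
            raise DatasetError(f"non-integer entries in {matrix_path}")
        counts = sp.csr_matrix(mat.T)
        barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str)
        features = pd.read_csv(features_path, sep="\t", header=None)
        gene_ids = features[0].astype(str)
        flag_cols = {}
        for j, flag in enumerate(GENE_FLAGS, start=1):
            if features.shape[1] > j:
                flag_cols[flag] = features[j].astype(int).astype(bool).to_numpy()
        if counts.shape[0] != len(barcodes):
            raise DatasetError(
                f"matrix has {counts.shape[0]} cells but {len(barcodes)} barcodes")
        if counts.shape[1] != len(gene_ids):
            raise DatasetError(
                f"matrix has {counts.shape[1]} genes but {len(gene_ids)} features")
    else:
        dense = pd.read_csv(matrix_path, sep="\t", index_col=0)
        vals = dense.to_numpy()
        if not np.all(vals == np.round(vals)):
            raise DatasetError(f"non-integer entries in {matrix_path}")
        counts = sp.csr_matrix(vals)
        barcodes = dense.index.astype(str)
        gene_ids = pd.Series(dense.columns.astype(str))
        flag_cols = {}

    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    if len(meta) != counts.shape[0]:
        raise DatasetError(
            f"metadata has {len(meta)} rows for {counts.shape[0]} cells")
    meta.index = meta.index.astype(str)
    if not (meta.index == pd.Index(barcodes)).all():
        meta = meta.reindex(pd.Index(barcodes))
        if meta.isna().all(axis=1).any():
            raise DatasetError("metadata barcodes do not match matrix barcodes")

    var = pd.DataFrame(index=pd.Index(gene_ids, name="gene"))
    for flag, col in flag_cols.items():
        var[flag] = col
    if "cluster" in meta.columns:
        meta["cluster"] = meta["cluster"].astype(str)
    adata = ad.AnnData(X=counts, obs=meta, var=var)
    adata.obs_names = pd.Index(barcodes, name="cell")
    return CellDataset(adata)


def write_cell_dataset(dataset: CellDataset, out_dir: str) -> dict:
    """Write MTX (genes x cells) + barcodes/features/metadata TSV; return paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "matrix": os.path.join(out_dir, "matrix.mtx"),
        "barcodes": os.path.join(out_dir, "barcodes.tsv"),
        "features": os.path.join(out_dir, "features.tsv"),
        "metadata": os.path.join(out_dir, "metadata.tsv"),
    }
    mat = sp.coo_matrix(dataset.counts.T.astype(np.int64))
    # mmwrite emits a deterministic coordinate file for a canonical COO
    buf = io.BytesIO()
    scipy.io.mmwrite(buf, mat, field="integer")
    with open(paths["matrix"], "wb") as fh:
        fh.write(buf.getvalue())
    pd.Series(dataset.cell_ids).to_csv(paths["barcodes"], sep="\t",
                                       header=False, index=False)
    feats = pd.DataFrame({"gene": dataset.gene_ids})
    for flag in GENE_FLAGS:
        feats[flag] = dataset.adata.var[flag].astype(int).to_numpy()
    feats.to_csv(paths["features"], sep="\t", header=False, index=False)
    dataset.cell_meta.to_csv(paths["metadata"], sep="\t")
    return paths


@dataclass
class OrthologyMap:
    """One-to-one orthologue pairing between species A and species B gene ids."""

    pairs: pd.DataFrame  # columns: gene_a, gene_b
    species_a: str = "species_a"
    species_b: str = "species_b"
    unmapped_a: list = field(default_factory=list)
    unmapped_b: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pairs = self.pairs.reset_index(drop=True)
        for col in ("gene_a", "gene_b"):
            if col not in self.pairs.columns:
                raise DatasetError(f"orthology table missing column {col!r}")
            if self.pairs[col].duplicated().any():
                dup = self.pairs[col][self.pairs[col].duplicated()].tolist()
                raise DatasetError(
                    f"gene appears in more than one orthology pair: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.pairs)

    def a_to_b(self) -> dict:
        return dict(zip(self.pairs["gene_a"], self.pairs["gene_b"]))

    def b_to_a(self) -> dict:
        return dict(zip(self.pairs["gene_b"], self.pairs["gene_a"]))

    def map_genes(self, genes, direction: str = "a_to_b") -> dict:
        """Map an iterable of ids; unmapped ids are silently dropped."""
        table = self.a_to_b() if direction == "a_to_b" else self.b_to_a()
        return {g: table[g] for g in genes if g in table}

    def to_tsv(self, path: str) -> None:
        out = self.pairs.rename(columns={"gene_a": self.species_a,
                                         "gene_b": self.species_b})
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str, species_a: str | None = None,
                 species_b: str | None = None) -> "OrthologyMap":
        df = pd.read_csv(path, sep="\t")
        if df.shape[1] < 2:
            raise DatasetError("orthology TSV needs two gene-id columns")
        cols = list(df.columns[:2])
        pairs = df[cols].rename(columns={cols[0]: "gene_a", cols[1]: "gene_b"})
        return cls(pairs=pairs, species_a=species_a or cols[0],
                   species_b=species_b or cols[1])
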