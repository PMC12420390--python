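"""Synthetic two-species limb single-cell data and regulatory-domain tracks.

The generator emulates the statistical structure the downstream analysis
assumes: two species (a "mouse"-like reference and a "bat"-like species
whose forelimb carries a unique distal fibroblast cluster) x two limbs,
cluster-structured negative-binomial UMI counts (gamma-Poisson with a
shared dispersion), planted proximal/distal marker genes, a planted
fibroblast gene programme (shared / distal-only / proximal-only), planted
QC-failing cells, a planted co-expressed gene pair, and TAD-tiled signal
and peak tracks with a planted enriched subpopulation.  All ground truth
is returned in a :class:`SyntheticTruth` so recovery is testable without
any external accession.

Counts are drawn per cell as ``Poisson(L_c * p_g * G_cg)`` with
``G ~ Gamma(1/phi, phi)`` (mean 1, variance ``phi``), library size ``L_c``
log-normal, and cluster-specific relative expression obtained by scaling a
base gene-weight vector by ``2**effect`` for the planted genes of the
cluster's role.  Per-cell ribosomal weight share is pinned to a sampled
target fraction so the ribosomal QC rule sees a controlled distribution.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp
import anndata as ad

from .datasets import CellDataset, OrthologyMap, GENE_FLAGS

ROLES = ("proximal-fibroblast", "distal-fibroblast", "interdigital-RA",
         "chondrogenic", "other")

_DEFAULT_CLUSTERS = [
    ("FbProx", "proximal-fibroblast"),
    ("FbDist", "distal-fibroblast"),
    ("RAId", "interdigital-RA"),
    ("Chondro", "chondrogenic"),
    ("Mes1", "other"),
    ("Mes2", "other"),
]

_DEFAULT_MARKERS = {
    "distal-fibroblast": [("HOXD13", 2.0), ("MSX1", 1.5), ("MEIS2", 1.5),
                          ("TBX3", 1.5), ("DCN", 1.0), ("ZFHX3", 1.0)],
    "proximal-fibroblast": [("SHOX2", 2.0), ("MEIS2", 2.0), ("DCN", 1.0),
                            ("ZFHX3", 1.0)],
    "chondrogenic": [("SOX9", 2.0), ("COL2A1", 2.5)],
    "interdigital-RA": [("ALDH1A2", 2.0), ("RDH10", 1.5), ("MSX1", 1.0),
                        ("HOXD13", 1.0)],
    "other": [],
}

NAMED_GENES = ["HOXD13", "MSX1", "SHOX2", "MEIS2", "TBX3", "SOX9", "COL2A1",
               "DCN", "ZFHX3", "ALDH1A2", "RDH10"]


class SpecValidationError(ValueError):
    """A SimulationSpec field is inconsistent; the message names the field."""


@dataclass
class ProgrammeConfig:
    n_shared: int = 150
    n_distal_only: int = 25
    n_proximal_only: int = 60
    log2_effect: float = 1.0
    cross_species_fraction: float = 1.0  # shared genes also planted in species A


@dataclass
class TadConfig:
    n_tads: int = 200
    tad_length: int = 100_000
    signal_bin: int = 1_000
    peak_bin: int = 100
    bulk_mean: float = 1.0
    enriched_mean: float = 3.0
    component_sd: float = 0.25          # 8-SD separation at the defaults
    enriched_weight: float = 0.2
    bin_noise_shape: float = 20.0
    bulk_coverage: tuple = (0.02, 0.10)
    enriched_coverage: tuple = (0.30, 0.50)


@dataclass
class SimulationSpec:
    n_cells_per_cluster: int = 140
    n_genes: int = 5_000
    cluster_labels: list = field(default_factory=lambda: list(_DEFAULT_CLUSTERS))
    species_limb_design: list = field(default_factory=lambda: [
        ("mouse", "FL"), ("mouse", "HL"), ("bat", "FL"), ("bat", "HL")])
    species_b: str = "bat"
    library_size_lognormal_params: tuple = (np.log(5_000.0), 0.3)
    nb_dispersion: float = 0.15
    marker_config: dict = field(default_factory=lambda: {
        r: list(v) for r, v in _DEFAULT_MARKERS.items()})
    programme_config: ProgrammeConfig = field(default_factory=ProgrammeConfig)
    ribo_fraction_range: tuple = (0.04, 0.06)
    coexpression_pair: tuple = ("MEIS2", "TBX3", 0.16)
    coexpression_background: float = 0.02
    outlier_config: dict = field(default_factory=lambda: {
        "umi_upper": 3, "umi_lower": 3, "ribo_upper": 3,
        "ribo_lower": 3, "low_complexity": 3})
    n_ribo_genes: int = 40
    n_mito_genes: int = 10
    n_chrx_genes: int = 50
    n_haemoglobin_genes: int = 2
    n_species_specific: int = 50
    orthology_mapped_fraction: float = 0.9
    base_weight_sigma: float = 1.5
    special_gene_weight: float = 3.0
    special_weight_sigma: float = 0.4  # dynamic range of planted-gene baselines
    ribo_gene_weight: float = 1.0
    tad_config: TadConfig = field(default_factory=TadConfig)
    seed: int = 0

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_labels)

    def validate(self) -> None:
        if self.n_cells_per_cluster <= 0:
            raise SpecValidationError("n_cells_per_cluster must be positive")
        if self.n_genes <= 0:
            raise SpecValidationError("n_genes must be positive")
        if self.n_clusters <= 0:
            raise SpecValidationError("cluster_labels must be non-empty")
        for name, role in self.cluster_labels:
            if role not in ROLES:
                raise SpecValidationError(f"cluster_labels: unknown role {role!r}")
        names = [n for n, _ in self.cluster_labels]
        if len(set(names)) != len(names):
            raise SpecValidationError("cluster_labels: duplicate cluster names")
        if self.nb_dispersion <= 0:
            raise SpecValidationError("nb_dispersion must be positive")
        pc = self.programme_config
        for f in ("n_shared", "n_distal_only", "n_proximal_only"):
            if getattr(pc, f) < 0:
                raise SpecValidationError(f"programme_config.{f} must be >= 0")
        if not np.isfinite(pc.log2_effect):
            raise SpecValidationError("programme_config.log2_effect must be finite")
        if not 0 <= pc.cross_species_fraction <= 1:
            raise SpecValidationError(
                "programme_config.cross_species_fraction must be in [0, 1]")
        lo, hi = self.ribo_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise SpecValidationError("ribo_fraction_range must be within [0, 1]")
        if not 0 <= self.coexpression_pair[2] <= 1:
            raise SpecValidationError(
                "coexpression_pair: joint-detection probability must be in [0, 1]")
        for role, markers in self.marker_config.items():
            for g, e in markers:
                if not np.isfinite(e):
                    raise SpecValidationError(
                        f"marker_config[{role!r}]: effect for {g} must be finite")
        n_special = (len(NAMED_GENES) + self.n_ribo_genes + self.n_mito_genes
                     + self.n_haemoglobin_genes + pc.n_shared + pc.n_distal_only
                     + pc.n_proximal_only + self.n_species_specific)
        if n_special > self.n_genes:
            raise SpecValidationError(
                f"n_genes: planted gene sets require at least {n_special} genes")
        if not 0 <= self.orthology_mapped_fraction <= 1:
            raise SpecValidationError("orthology_mapped_fraction must be in [0, 1]")
        tc = self.tad_config
        if tc.component_sd <= 0:
            raise SpecValidationError("tad_config.component_sd must be positive")
        if tc.n_tads <= 0 or tc.tad_length <= 0:
            raise SpecValidationError("tad_config sizes must be positive")


@dataclass
class SyntheticTruth:
    cell_cluster_assignment: dict = field(default_factory=dict)
    cluster_role: pd.DataFrame | None = None
    planted_programme: dict = field(default_factory=dict)
    planted_qc_failures: dict = field(default_factory=dict)
    planted_coexpression_prob: dict = field(default_factory=dict)
    enriched_tads: list = field(default_factory=list)
    tad_signal_params: dict = field(default_factory=dict)
    gene_flags: dict = field(default_factory=dict)
    species_specific_genes: list = field(default_factory=list)

    def to_json(self, path: str) -> None:
        payload = {
            "cell_cluster_assignment": self.cell_cluster_assignment,
            "cluster_role": (self.cluster_role.to_dict(orient="records")
                             if self.cluster_role is not None else None),
            "planted_programme": self.planted_programme,
            "planted_qc_failures": self.planted_qc_failures,
            "planted_coexpression_prob": self.planted_coexpression_prob,
            "enriched_tads": self.enriched_tads,
            "tad_signal_params": self.tad_signal_params,
            "species_specific_genes": self.species_specific_genes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Gene universe
# ---------------------------------------------------------------------------

@dataclass
class _GeneUniverse:
    names: list
    flags: dict                 # flag -> boolean array
    programme: dict             # shared / distal_only / proximal_only / cross_species_shared
    species_specific: list
    special_idx: np.ndarray     # named + programme + ribo genes (elevated base weight)
    ribo_idx: np.ndarray


def _build_gene_universe(spec: SimulationSpec) -> _GeneUniverse:
    names: list[str] = list(NAMED_GENES)
    ribo = [f"RPS{i}" if i % 2 else f"RPL{i}" for i in range(spec.n_ribo_genes)]
    mito = [f"MT-G{i}" for i in range(spec.n_mito_genes)]
    hb = [f"HBB{i}" for i in range(spec.n_haemoglobin_genes)]
    names += ribo + mito + hb
    pc = spec.programme_config
    shared = [f"G{i:05d}" for i in range(pc.n_shared)]
    offset = pc.n_shared
    distal_only = [f"G{i:05d}" for i in range(offset, offset + pc.n_distal_only)]
    offset += pc.n_distal_only
    proximal_only = [f"G{i:05d}" for i in range(offset, offset + pc.n_proximal_only)]
    offset += pc.n_proximal_only
    spp = [f"G{i:05d}" for i in range(offset, offset + spec.n_species_specific)]
    offset += spec.n_species_specific
    n_generic = spec.n_genes - len(names) - offset
    generic = [f"G{i:05d}" for i in range(offset, offset + n_generic)]
    names += shared + distal_only + proximal_only + spp + generic
    if len(set(names)) != len(names):
        raise SpecValidationError("gene universe: duplicate gene IDs")

    name_idx = {n: i for i, n in enumerate(names)}
    flags = {f: np.zeros(spec.n_genes, bool) for f in GENE_FLAGS}
    flags["ribosomal"][[name_idx[g] for g in ribo]] = True
    flags["mitochondrial"][[name_idx[g] for g in mito]] = True
    flags["haemoglobin"][[name_idx[g] for g in hb]] = True
    flags["chondrogenic_marker"][[name_idx[g] for g in ("SOX9", "COL2A1")]] = True
    # chrX flags live on a slice of generic genes
    flags["chrx"][[name_idx[g] for g in generic[:spec.n_chrx_genes]]] = True

    n_cross = int(round(pc.cross_species_fraction * pc.n_shared))
    programme = {
        "shared": shared, "distal_only": distal_only,
        "proximal_only": proximal_only,
        "cross_species_shared": shared[:n_cross],
    }
    special = [name_idx[g] for g in NAMED_GENES + shared + distal_only
               + proximal_only + spp]
    return _GeneUniverse(
        names=names, flags=flags, programme=programme, species_specific=spp,
        special_idx=np.array(special, int),
        ribo_idx=np.array([name_idx[g] for g in ribo], int))


def _base_weights(spec: SimulationSpec, uni: _GeneUniverse,
                  rng: np.random.Generator) -> np.ndarray:
    w = rng.lognormal(mean=0.0, sigma=spec.base_weight_sigma, size=spec.n_genes)
    # planted genes sit in the moderately-expressed range but span a dynamic
    # range, as real marker/programme genes do
    w[uni.special_idx] = spec.special_gene_weight * rng.lognormal(
        0.0, spec.special_weight_sigma, size=len(uni.special_idx))
    # ribosomal weights get rescaled per cell to the target fraction; the base
    # value only matters for their relative composition
    w[uni.ribo_idx] = spec.ribo_gene_weight
    return w


def _cluster_effects(spec: SimulationSpec, uni: _GeneUniverse, role: str,
                     species: str, limb: str) -> np.ndarray:
    """Per-gene log2 effect vector for one cluster role in one block."""
    name_idx = {n: i for i, n in enumerate(uni.names)}
    e = np.zeros(spec.n_genes)
    for g, eff in spec.marker_config.get(role, []):
        if g not in name_idx:
            raise SpecValidationError(f"marker_config: unknown gene {g!r}")
        e[name_idx[g]] += eff
    pc = spec.programme_config
    prog = uni.programme
    is_b = species == spec.species_b
    if role == "distal-fibroblast":
        for g in prog["shared"] + prog["distal_only"]:
            e[name_idx[g]] += pc.log2_effect
    if role == "proximal-fibroblast":
        if is_b:
            targets = prog["shared"] + prog["proximal_only"]
        else:
            targets = prog["cross_species_shared"] + prog["proximal_only"]
        for g in targets:
            e[name_idx[g]] += pc.log2_effect
    if is_b:
        for g in uni.species_specific:
            e[name_idx[g]] += 2.0
    return e


# ---------------------------------------------------------------------------
# Count generation
# ---------------------------------------------------------------------------

def _draw_counts(rng, libsizes, probs, dispersion):
    """Gamma-Poisson counts for one homogeneous group of cells."""
    nc, ng = len(libsizes), probs.shape[-1]
    shape = 1.0 / dispersion
    gamma = rng.gamma(shape, scale=dispersion, size=(nc, ng))
    lam = libsizes[:, None] * probs * gamma
    return rng.poisson(lam)


def _cell_probs(weights, ribo_idx, ribo_fracs):
    """Per-cell gene probabilities with the ribosomal share pinned per cell."""
    nonribo = np.ones(len(weights), bool)
    nonribo[ribo_idx] = False
    w_nr = weights * nonribo
    w_r = weights * ~nonribo
    p = np.empty((len(ribo_fracs), len(weights)))
    p[:] = w_nr / w_nr.sum()
    p *= (1.0 - ribo_fracs)[:, None]
    p[:, ribo_idx] = np.outer(ribo_fracs, w_r[ribo_idx] / w_r[ribo_idx].sum())
    return p


def generate_limb_dataset(spec: SimulationSpec):
    """Generate the full multi-block dataset; returns (CellDataset, SyntheticTruth)."""
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    uni = _build_gene_universe(spec)
    rng_base = np.random.default_rng(root.spawn(1)[0])
    weights = _base_weights(spec, uni, rng_base)
    mu, sigma = spec.library_size_lognormal_params

    blocks = []
    truth = SyntheticTruth()
    truth.planted_programme = dict(uni.programme)
    truth.species_specific_genes = list(uni.species_specific)
    truth.gene_flags = {k: uni.flags[k].tolist() for k in uni.flags}
    role_rows = []
    cx_gene_x, cx_gene_y, cx_prob = spec.coexpression_pair
    gi_x = uni.names.index(cx_gene_x)
    gi_y = uni.names.index(cx_gene_y)

    block_seeds = root.spawn(1 + len(spec.species_limb_design))[1:]
    cell_counter = 0
    for (species, limb), bseed in zip(spec.species_limb_design, block_seeds):
        rng = np.random.default_rng(bseed)
        is_b_fl = species == spec.species_b and limb == "FL"
        # the distal-fibroblast cluster exists only in the species-B forelimb
        clusters = [(n, r) for n, r in spec.cluster_labels
                    if r != "distal-fibroblast" or is_b_fl]
        lib_mean = float(np.exp(mu + sigma ** 2 / 2))
        lib_median = float(np.exp(mu))

        mats, metas = [], []
        for cname, role in clusters:
            role_rows.append({"species": species, "limb": limb,
                              "cluster": cname, "role": role})
            eff = _cluster_effects(spec, uni, role, species, limb)
            w = weights * np.exp2(eff)
            nc = spec.n_cells_per_cluster
            libs = rng.lognormal(mu, sigma, size=nc)
            fr = rng.uniform(*spec.ribo_fraction_range, size=nc)
            probs = _cell_probs(w, uni.ribo_idx, fr)
            counts = _draw_counts(rng, libs, probs, spec.nb_dispersion)
            # planted co-expression: Bernoulli gate with exact joint probability
            p_joint = cx_prob if role == "distal-fibroblast" \
                else spec.coexpression_background
            gate = rng.random(nc) < p_joint
            counts[gate, gi_x] = np.maximum(counts[gate, gi_x], 1)
            counts[gate, gi_y] = np.maximum(counts[gate, gi_y], 1)
            counts[~gate, gi_y] = 0
            truth.planted_coexpression_prob[f"{species}|{limb}|{cname}"] = float(p_joint)
            mats.append(counts)
            metas.append(pd.DataFrame({
                "species": species, "limb": limb, "stage": "E13",
                "library": f"{species}_{limb}_rep1", "cluster": cname,
            }, index=range(nc)))

        # planted QC-failing cells, appended per rule
        out_rules = []
        for rule, n_out in spec.outlier_config.items():
            for _ in range(int(n_out)):
                cname, role = clusters[int(rng.integers(len(clusters)))]
                eff = _cluster_effects(spec, uni, role, species, limb)
                w = weights * np.exp2(eff)
                fr = float(rng.uniform(*spec.ribo_fraction_range))
                lib = float(rng.lognormal(mu, sigma))
                restrict = None
                if rule == "umi_upper":
                    lib = 8.0 * lib_mean
                elif rule == "umi_lower":
                    lib = 0.05 * lib_median
                elif rule == "ribo_upper":
                    fr = 0.5
                elif rule == "ribo_lower":
                    fr = 0.0
                elif rule == "low_complexity":
                    lib = 0.4 * lib_median
                    restrict = np.argsort(w)[::-1][:40]  # 40 most expressed genes
                else:
                    raise SpecValidationError(
                        f"outlier_config: unknown rule {rule!r}")
                probs = _cell_probs(w, uni.ribo_idx, np.array([fr]))
                if restrict is not None:
                    mask = np.zeros(spec.n_genes, bool)
                    mask[restrict] = True
                    probs = probs * mask
                    probs /= probs.sum()
                counts = _draw_counts(rng, np.array([lib]), probs,
                                      spec.nb_dispersion)
                mats.append(counts)
                metas.append(pd.DataFrame({
                    "species": species, "limb": limb, "stage": "E13",
                    "library": f"{species}_{limb}_rep1", "cluster": cname,
                }, index=[0]))
                out_rules.append(rule)

        block_counts = np.vstack(mats)
        meta = pd.concat(metas, ignore_index=True)
        n_block = len(meta)
        ids = [f"{species}_{limb}_c{cell_counter + i:05d}" for i in range(n_block)]
        cell_counter += n_block
        meta.index = pd.Index(ids, name="cell")
        n_planted = len(out_rules)
        for cid, rule in zip(ids[n_block - n_planted:], out_rules):
            truth.planted_qc_failures[cid] = rule
        blocks.append((block_counts, meta))

    X = sp.csr_matrix(np.vstack([b[0] for b in blocks]))
    obs = pd.concat([b[1] for b in blocks])
    var = pd.DataFrame(index=pd.Index(uni.names, name="gene"))
    for flag in GENE_FLAGS:
        var[flag] = uni.flags[flag]
    adata = ad.AnnData(X=X, obs=obs, var=var)
    dataset = CellDataset(adata)
    truth.cell_cluster_assignment = dict(zip(obs.index, obs["cluster"]))
    truth.cluster_role = pd.DataFrame(role_rows)
    return dataset, truth


def split_blocks(dataset: CellDataset) -> dict:
    """Split the combined dataset into per-(species, limb) CellDatasets."""
    out = {}
    meta = dataset.cell_meta
    for (species, limb), idx in meta.groupby(["species", "limb"],
                                             observed=True).groups.items():
        mask = meta.index.isin(idx)
        out[(species, limb)] = dataset.subset_cells(mask)
    return out


# ---------------------------------------------------------------------------
# Orthology
# ---------------------------------------------------------------------------

def generate_orthology(spec: SimulationSpec,
                       mapped_fraction: float | None = None) -> OrthologyMap:
    """One-to-one orthology over a configurable fraction of the gene universe.

    Species-B-specific genes are always left unmapped; the remaining unmapped
    quota is drawn (seeded) from genes that carry no planted role, so every
    cross-species operation keeps the planted markers and programme.
    """
    spec.validate()
    species = list(dict.fromkeys(s for s, _ in spec.species_limb_design))
    if len(species) != 2:
        raise SpecValidationError("species_limb_design must contain two species")
    frac = (spec.orthology_mapped_fraction if mapped_fraction is None
            else mapped_fraction)
    if not 0 <= frac <= 1:
        raise SpecValidationError("orthology_mapped_fraction must be in [0, 1]")
    uni = _build_gene_universe(spec)
    n_mapped = int(round(frac * spec.n_genes))
    n_unmapped = spec.n_genes - n_mapped
    # species-specific genes fill the unmapped quota first
    forced = set(uni.species_specific[:n_unmapped])
    protected = set(uni.names[i] for i in uni.special_idx) | \
        {uni.names[i] for i in np.flatnonzero(
            np.any([uni.flags[f] for f in uni.flags], axis=0))}
    eligible = [g for g in uni.names if g not in forced and g not in protected]
    extra = max(0, n_unmapped - len(forced))
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 17]))
    chosen = set(rng.choice(eligible, size=min(extra, len(eligible)),
                            replace=False)) if extra else set()
    unmapped = forced | chosen
    mapped = [g for g in uni.names if g not in unmapped]
    pairs = pd.DataFrame({"gene_a": mapped, "gene_b": mapped})
    sp_a = species[0] if species[1] == spec.species_b else species[1]
    return OrthologyMap(pairs=pairs, species_a=sp_a, species_b=spec.species_b,
                        unmapped_a=sorted(unmapped), unmapped_b=sorted(unmapped))


# ---------------------------------------------------------------------------
# Regulatory tracks
# ---------------------------------------------------------------------------

def generate_regulatory_tracks(spec: SimulationSpec):
    """TAD-tiled signal/peak tracks with a planted enriched subpopulation.

    Returns (tads, peaks, signal, gene_map, truth): BED-like frames for the
    TAD tiling and merged peaks, a bedGraph-like step track, a gene->TSS
    table, and the truth carrying the enriched TAD names and mixture
    parameters.
    """
    spec.validate()
    tc = spec.tad_config
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 23]))
    uni = _build_gene_universe(spec)
    chrom = "chrS"
    starts = np.arange(tc.n_tads) * tc.tad_length
    tads = pd.DataFrame({
        "chrom": chrom, "start": starts, "end": starts + tc.tad_length,
        "name": [f"TAD_{i:04d}" for i in range(tc.n_tads)]})

    enriched = rng.random(tc.n_tads) < tc.enriched_weight
    means = np.where(enriched,
                     rng.normal(tc.enriched_mean, tc.component_sd, tc.n_tads),
                     rng.normal(tc.bulk_mean, tc.component_sd, tc.n_tads))
    means = np.maximum(means, 1e-3)

    n_bins = tc.tad_length // tc.signal_bin
    sig_rows = []
    peak_rows = []
    for i in range(tc.n_tads):
        noise = rng.gamma(tc.bin_noise_shape, 1.0 / tc.bin_noise_shape, n_bins)
        vals = means[i] * noise
        s0 = starts[i]
        bs = s0 + np.arange(n_bins) * tc.signal_bin
        sig_rows.append(pd.DataFrame({
            "chrom": chrom, "start": bs, "end": bs + tc.signal_bin,
            "value": np.round(vals, 6)}))
        cov_lo, cov_hi = (tc.enriched_coverage if enriched[i]
                          else tc.bulk_coverage)
        target = float(rng.uniform(cov_lo, cov_hi))
        target_len = int(round(target * tc.tad_length / tc.peak_bin)) * tc.peak_bin
        if target_len > 0:
            n_peaks = max(1, target_len // 2_000)
            peak_len = target_len // n_peaks
            rem = target_len - peak_len * n_peaks
            gap = (tc.tad_length - target_len) // (n_peaks + 1)
            pos = s0 + gap
            for j in range(n_peaks):
                ln = peak_len + (rem if j == 0 else 0)
                peak_rows.append((chrom, pos, pos + ln))
                pos += ln + gap
    signal = pd.concat(sig_rows, ignore_index=True)
    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end"])

    genome_len = tc.n_tads * tc.tad_length
    tss = rng.integers(0, genome_len, size=spec.n_genes)
    gene_map = pd.DataFrame({"gene": uni.names, "chrom": chrom, "tss": tss})

    truth = SyntheticTruth(
        enriched_tads=tads["name"][enriched].tolist(),
        tad_signal_params={
            "bulk_mean": tc.bulk_mean, "enriched_mean": tc.enriched_mean,
            "component_sd": tc.component_sd,
            "enriched_weight": tc.enriched_weight,
            "n_enriched_drawn": int(enriched.sum())},
        planted_programme=dict(uni.programme))
    return tads, peaks, signal, gene_map, truth


def write_tracks(tads, peaks, signal, gene_map, out_dir: str) -> dict:
    from .domains import write_bed
    os.makedirs(out_dir, exist_ok=True)
    paths = {"tads": os.path.join(out_dir, "tads.bed"),
             "peaks": os.path.join(out_dir, "peaks.bed"),
             "signal": os.path.join(out_dir, "signal.bedgraph"),
             "genes": os.path.join(out_dir, "gene_tss.tsv")}
    write_bed(tads, paths["tads"])
    write_bed(peaks, paths["peaks"])
    signal.to_csv(paths["signal"], sep="\t", header=False, index=False)
    gene_map.to_csv(paths["genes"], sep="\t", index=False)
    return paths
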