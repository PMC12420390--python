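"""End-to-end orchestration: config-driven reproducible runs.

A run either simulates its inputs (synthetic mode) or loads them from
files, then executes the stage chain

    simulate|load -> qc -> normalise -> pd-dissect -> programme
    -> compare-species -> tad-enrich -> mutant-eval (when genotypes exist)

writing TSV/JSON outputs plus a manifest with the config hash, seeds and
per-output checksums.  All stage parameters default to the analysis'
canonical constants (normalisation scale 10,000; DE gates 0.25 / 0.5;
shared-programme log2FC 0.1; category log2FC 0.15; concordance band 0.25;
universe floor nine cells; extreme-cluster fraction one third; top 20
candidates), so a zero-override config runs the reference analysis.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import CellDataset, OrthologyMap, read_cell_dataset
from . import simulate as sim
from . import qc as qcmod
from . import scoring
from . import de as demod
from . import domains

DEFAULT_PARAMETERS = {
    "scale_factor": 10_000.0,
    "marker_min_pct": 0.25,
    "marker_lfc": 0.5,
    "shared_lfc": 0.1,
    "category_lfc": 0.15,
    "compare_threshold": 0.0001,
    "band": 0.25,
    "universe_min_cells": 9,
    "mutant_min_pct": 0.15,
    "top_n": 20,
    "extreme_fraction": 1.0 / 3.0,
    "n_bins": 24,
    "n_ctrl": 100,
    "alpha": 0.05,
    "chondro_log2_margin": 1.0,
    "mad_scale": 1.0,
}

PARAM_RANGES = {
    "scale_factor": (1e-6, np.inf),
    "marker_min_pct": (0.0, 1.0), "marker_lfc": (0.0, np.inf),
    "shared_lfc": (0.0, np.inf), "category_lfc": (0.0, np.inf),
    "compare_threshold": (0.0, 1.0), "band": (0.0, np.inf),
    "universe_min_cells": (0, np.inf), "mutant_min_pct": (0.0, 1.0),
    "top_n": (1, np.inf), "extreme_fraction": (0.0, 0.5),
    "n_bins": (1, np.inf), "n_ctrl": (1, np.inf), "alpha": (0.0, 1.0),
    "chondro_log2_margin": (0.0, np.inf), "mad_scale": (0.0, np.inf),
}

TOP_KEYS = {"seed", "output_dir", "simulation", "inputs", "parameters",
            "programme", "compare_gene_sets"}

STAGES = ("simulate", "qc", "normalise", "pd-dissect", "programme",
          "compare-species", "tad-enrich", "mutant-eval")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "patagium_run"
    simulation: dict | None = None
    inputs: dict | None = None
    parameters: dict = field(default_factory=dict)
    programme: dict = field(default_factory=lambda: {
        "distal_cluster": "FbDist", "proximal_clusters": ["FbProx"],
        "other_proximal_clusters": ["FbProx"]})

    def __post_init__(self) -> None:
        if self.simulation is not None and self.inputs is not None:
            raise ConfigError("config must set exactly one of simulation/inputs")
        if self.simulation is None and self.inputs is None:
            self.simulation = {}
        merged = dict(DEFAULT_PARAMETERS)
        merged.update(self.parameters)
        self.parameters = merged

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        report = validate_config_dict(raw)
        if report:
            raise ConfigError("; ".join(report))
        return cls(**{k: v for k, v in raw.items()
                      if k in {"seed", "output_dir", "simulation", "inputs",
                               "parameters", "programme"}})

    def canonical_hash(self) -> str:
        blob = json.dumps({"seed": self.seed, "simulation": self.simulation,
                           "inputs": self.inputs, "parameters": self.parameters,
                           "programme": self.programme},
                          sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def validate_config_dict(raw: dict) -> list[str]:
    """Report unknown keys, out-of-range values and missing files."""
    report = []
    for key in raw:
        if key not in TOP_KEYS:
            report.append(f"unknown key: {key}")
    if raw.get("simulation") is not None and raw.get("inputs") is not None:
        report.append("exactly one of simulation/inputs allowed")
    params = raw.get("parameters") or {}
    for k, v in params.items():
        if k not in DEFAULT_PARAMETERS:
            report.append(f"unknown parameter: {k}")
        else:
            lo, hi = PARAM_RANGES[k]
            if not (lo <= float(v) <= hi):
                report.append(f"parameter {k}={v} outside [{lo}, {hi}]")
    inputs = raw.get("inputs") or {}
    for k, path in inputs.items():
        if isinstance(path, str) and not os.path.exists(path):
            report.append(f"missing input file: {k}={path}")
    if inputs:
        meta_path = inputs.get("metadata")
        if meta_path and os.path.exists(meta_path):
            meta = pd.read_csv(meta_path, sep="\t", nrows=1000)
            if "species" in meta.columns and meta["species"].nunique() > 1 \
                    and "orthology" not in inputs:
                report.append("missing orthology path with two species configured")
    return report


def validate_config(path: str) -> list[str]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config_dict(raw)


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    stages: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: str, index: bool = True) -> str:
    df.to_csv(path, sep="\t", float_format="%.6g", index=index)
    return path


class PipelineRun:
    """Holds intermediate state across stages of one run."""

    def __init__(self, config: PipelineConfig, out_dir: str | None = None,
                 seed: int | None = None):
        self.config = config
        self.out_dir = out_dir or config.output_dir
        self.seed = config.seed if seed is None else seed
        os.makedirs(self.out_dir, exist_ok=True)
        self.params = config.parameters
        self.manifest = RunManifest(config_hash=config.canonical_hash(),
                                    version=__version__, seed=self.seed)
        self.dataset: CellDataset | None = None
        self.truth = None
        self.orthology: OrthologyMap | None = None
        self.tracks = None
        self.blocks: dict = {}
        self.hvgs: list = []
        self.pd_categories: dict = {}
        self.module_scores: dict = {}
        self.programme: demod.ProgrammeSets | None = None
        self.concordance = None
        self.candidates = None
        self.sim_spec = None

    # -- stages ---------------------------------------------------------
    def stage_simulate(self):
        if self.config.simulation is not None:
            overrides = dict(self.config.simulation)
            overrides.setdefault("seed", self.seed)
            overrides = _coerce_sim_overrides(overrides)
            spec = sim.SimulationSpec(**overrides)
            self.sim_spec = spec
            self.dataset, self.truth = sim.generate_limb_dataset(spec)
            self.orthology = sim.generate_orthology(spec)
            self.tracks = sim.generate_regulatory_tracks(spec)
            self.truth.enriched_tads = self.tracks[4].enriched_tads
            self.truth.tad_signal_params = self.tracks[4].tad_signal_params
            truth_path = os.path.join(self.out_dir, "truth.json")
            self.truth.to_json(truth_path)
        else:
            inp = self.config.inputs
            self.dataset = read_cell_dataset(inp["matrix"], inp["metadata"])
            if "orthology" in inp:
                self.orthology = OrthologyMap.from_tsv(inp["orthology"])
            if all(k in inp for k in ("tads", "peaks", "signal", "gene_tss")):
                tads = domains.read_bed(inp["tads"])
                peaks = domains.read_bed(inp["peaks"])
                signal = domains.read_bedgraph(inp["signal"])
                gene_map = pd.read_csv(inp["gene_tss"], sep="\t")
                self.tracks = (tads, peaks, signal, gene_map, None)
        self.orthology.to_tsv(os.path.join(self.out_dir, "orthology.tsv")) \
            if self.orthology is not None else None

    def stage_qc(self):
        meta = self.dataset.cell_meta
        reports = []
        keep = np.zeros(self.dataset.n_cells, bool)
        for lib, idx in meta.groupby("library", observed=True).groups.items():
            mask = meta.index.isin(idx)
            sub = self.dataset.subset_cells(mask)
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                thr = qcmod.compute_qc_thresholds(
                    sub, sample_id=str(lib), mad_scale=self.params["mad_scale"])
                _, report = qcmod.apply_qc(sub, thr)
            self.manifest.warnings += [str(w.message) for w in caught]
            keep[mask] = report.cell_pass.to_numpy()
            frame = report.to_frame()
            frame.insert(0, "library", lib)
            reports.append(frame)
        qc_frame = pd.concat(reports)
        _write_tsv(qc_frame, os.path.join(self.out_dir, "qc_report.tsv"))
        with open(os.path.join(self.out_dir, "qc_summary.json"), "w") as fh:
            json.dump({"n_cells_in": int(self.dataset.n_cells),
                       "n_removed": int((~keep).sum())}, fh, indent=1)
        self.dataset = self.dataset.subset_cells(keep)

    def stage_normalise(self):
        qcmod.log_normalize(self.dataset, self.params["scale_factor"])
        self.blocks = sim.split_blocks(self.dataset)
        bat_fl = self._block(self.config.programme.get("species_b", "bat"), "FL")
        self.hvgs = qcmod.select_hvgs(bat_fl, self.params["mad_scale"])
        with open(os.path.join(self.out_dir, "hvgs.txt"), "w") as fh:
            fh.write("\n".join(self.hvgs) + "\n")

    def _block(self, species, limb) -> CellDataset:
        key = (species, limb)
        if key not in self.blocks:
            raise ConfigError(f"no cells for block {key}")
        return self.blocks[key]

    def stage_pd_dissect(self):
        p = self.params
        gene_sets = {
            "distal": list(scoring.DISTAL_SET),
            "proximal": list(scoring.PROXIMAL_SET),
            "chondrogenic": list(scoring.CHONDROGENIC_SET),
            "fibroblastic": list(scoring.FIBROBLASTIC_SET),
        }
        rows = []
        datasets_by_species: dict = {}
        chondro_by_species: dict = {}
        for (species, limb), block in sorted(self.blocks.items()):
            mss = scoring.ModuleScoreSet.compute(
                block, gene_sets, n_bins=int(p["n_bins"]),
                n_ctrl=int(p["n_ctrl"]), seed=self.seed)
            pd_vec = scoring.pd_score(mss.scores["distal"].to_numpy(),
                                      mss.scores["proximal"].to_numpy())
            per_cluster = pd.Series(pd_vec, index=block.cell_ids).groupby(
                block.clusters.to_numpy()).mean()
            cats = scoring.classify_clusters_pd(per_cluster,
                                                p["extreme_fraction"])
            self.pd_categories[(species, limb)] = cats
            self.module_scores[(species, limb)] = mss
            datasets_by_species.setdefault(species, []).append((block, cats))
            chondro_by_species.setdefault(species, []).append(
                mss.scores["chondrogenic"].to_numpy())
            for cl in per_cluster.index:
                rows.append({"species": species, "limb": limb, "cluster": cl,
                             "mean_pd": per_cluster[cl], "category": cats[cl]})
        _write_tsv(pd.DataFrame(rows),
                   os.path.join(self.out_dir, "pd_clusters.tsv"), index=False)

        if self.orthology is not None and len(datasets_by_species) == 2:
            result = scoring.categorize_pd_genes(
                datasets_by_species, self.orthology,
                chondro_scores_by_species=chondro_by_species,
                lfc_threshold=p["category_lfc"],
                chondro_log2_margin=p["chondro_log2_margin"])
            with open(os.path.join(self.out_dir, "pd_gene_categories.json"),
                      "w") as fh:
                json.dump({"typical_distal": result.typical_distal,
                           "typical_proximal": result.typical_proximal,
                           "excluded_chondrogenic": result.excluded_chondrogenic},
                          fh, indent=1, sort_keys=True)
            _write_tsv(result.evidence,
                       os.path.join(self.out_dir, "pd_gene_evidence.tsv"))
        # co-expression summary for the planted pair (when present)
        pair = (self.sim_spec.coexpression_pair[:2] if self.sim_spec
                else ("MEIS2", "TBX3"))
        try:
            bat_fl = self._block(self._species_b(), "FL")
            coex = scoring.coexpression_fraction(bat_fl, pair[0], pair[1])
            _write_tsv(coex, os.path.join(self.out_dir, "coexpression.tsv"))
        except Exception:
            pass

    def _species_b(self) -> str:
        return self.sim_spec.species_b if self.sim_spec else \
            self.config.programme.get("species_b", "bat")

    def _species_a(self) -> str:
        species = sorted({s for s, _ in self.blocks})
        other = [s for s in species if s != self._species_b()]
        return other[0] if other else species[0]

    def stage_programme(self):
        p = self.params
        prog_cfg = self.config.programme
        bat_fl = self._block(self._species_b(), "FL")
        mouse_fl = self._block(self._species_a(), "FL")
        self.programme = demod.derive_programme(
            bat_fl, prog_cfg["distal_cluster"], prog_cfg["proximal_clusters"],
            self.hvgs, orthology=self.orthology, dataset_other=mouse_fl,
            other_proximal_clusters=prog_cfg["other_proximal_clusters"],
            min_pct=p["marker_min_pct"], lfc_threshold=p["marker_lfc"],
            shared_lfc=p["shared_lfc"], alpha=p["alpha"])
        with open(os.path.join(self.out_dir, "programme.json"), "w") as fh:
            json.dump(self.programme.to_dict(), fh, indent=1, sort_keys=True)
        if self.programme.round2_distal is not None and \
                len(self.programme.round2_distal):
            _write_tsv(self.programme.round2_distal,
                       os.path.join(self.out_dir, "programme_round2_distal.tsv"))
            _write_tsv(self.programme.round2_proximal,
                       os.path.join(self.out_dir, "programme_round2_proximal.tsv"))

    def stage_compare_species(self):
        p = self.params
        genes = self.programme.all_programme_genes() if self.programme else []
        genes = sorted(set(genes) | set(scoring.DISTAL_SET)
                       | set(scoring.PROXIMAL_SET))
        if not genes or self.orthology is None:
            return
        a2b = self.orthology.a_to_b()
        genes_a = [g for g in genes if g in a2b]
        sp_a, sp_b = self._species_a(), self._species_b()
        ds_a, ds_b = self._block(sp_a, "FL"), self._block(sp_b, "FL")
        genes_b = [a2b[g] for g in genes_a]
        prox = self.config.programme["other_proximal_clusters"]

        distal = self.config.programme["distal_cluster"]

        def de_for(ds, gene_list, prox_clusters):
            # background excludes both fibroblast compartments so the two
            # species' out-groups have matching cluster composition
            m_in = ds.clusters.isin(prox_clusters).to_numpy()
            m_out = ~m_in & ~(ds.clusters == distal).to_numpy()
            present = [g for g in gene_list if g in set(ds.gene_ids)]
            return demod.wilcoxon_de(
                ds, m_in, m_out, gene_subset=present,
                min_pct=p["compare_threshold"],
                lfc_threshold=p["compare_threshold"])

        de_a = de_for(ds_a, genes_a, prox)
        de_b = de_for(ds_b, genes_b, self.config.programme["proximal_clusters"])
        self.concordance = demod.crossspecies_lfc_compare(
            de_a, de_b, self.orthology,
            gene_sets={"programme": genes}, band=p["band"])
        _write_tsv(self.concordance.paired,
                   os.path.join(self.out_dir, "crossspecies_concordance.tsv"))
        with open(os.path.join(self.out_dir, "concordance_summary.json"),
                  "w") as fh:
            json.dump({"band": p["band"],
                       "n_paired": int(len(self.concordance.paired)),
                       "fraction_within_band":
                           self.concordance.fraction_within_band},
                      fh, indent=1)

    def stage_tad_enrich(self):
        if self.tracks is None:
            return
        p = self.params
        tads, peaks, signal, gene_map = self.tracks[:4]
        auc = domains.tad_signal_auc(signal, tads)
        cov = domains.tad_peak_coverage(peaks, tads)
        summary = auc.merge(cov, on=["chrom", "start", "end"])
        summary["name"] = tads["name"].to_numpy() if "name" in tads.columns \
            else summary.index.astype(str)
        dp_sig = domains.density_dividing_point(summary["mean_signal"])
        dp_cov = domains.density_dividing_point(summary["peak_coverage"])
        flagged = domains.flag_enriched(summary, dp_sig.threshold,
                                        dp_cov.threshold)
        gene_tads = domains.assign_genes_to_tads(gene_map, tads)
        prog_genes = self.programme.all_programme_genes() if self.programme else []
        self.candidates = domains.candidate_genes(
            gene_tads, flagged, prog_genes, top_n=int(p["top_n"]))
        _write_tsv(flagged, os.path.join(self.out_dir, "tad_summary.tsv"),
                   index=False)
        _write_tsv(self.candidates,
                   os.path.join(self.out_dir, "candidate_genes.tsv"),
                   index=False)
        with open(os.path.join(self.out_dir, "tad_thresholds.json"), "w") as fh:
            json.dump({"signal_threshold": dp_sig.threshold,
                       "signal_fallback": dp_sig.fallback_used,
                       "coverage_threshold": dp_cov.threshold,
                       "coverage_fallback": dp_cov.fallback_used}, fh, indent=1)

    def stage_mutant_eval(self):
        if "genotype" not in self.dataset.cell_meta.columns:
            return
        p = self.params
        genotypes = self.dataset.cell_meta["genotype"]
        genes = demod.mutant_gene_filter(self.dataset, genotypes,
                                         min_pct=p["mutant_min_pct"])
        levels = sorted(genotypes.unique())
        if len(levels) != 2 or not genes:
            return
        m_mut = (genotypes == levels[1]).to_numpy()
        de = demod.wilcoxon_de(self.dataset, m_mut, ~m_mut, gene_subset=genes,
                               min_pct=0.0, lfc_threshold=0.0)
        hits = de.index[(de["p"] < 0.01) & (de["log2fc"] > 0.25)].tolist()
        universe = demod.build_universe(self.dataset,
                                        int(p["universe_min_cells"]))
        prog = set(self.programme.all_programme_genes()) if self.programme else set()
        overlap, pval = demod.overrepresentation(
            set(hits) & set(universe), prog & set(universe), universe)
        _write_tsv(de, os.path.join(self.out_dir, "mutant_de.tsv"))
        with open(os.path.join(self.out_dir, "mutant_overrepresentation.json"),
                  "w") as fh:
            json.dump({"n_de": len(hits), "overlap": overlap, "p": pval},
                      fh, indent=1)

    STAGE_FUNCS = {
        "simulate": stage_simulate, "qc": stage_qc, "normalise": stage_normalise,
        "pd-dissect": stage_pd_dissect, "programme": stage_programme,
        "compare-species": stage_compare_species, "tad-enrich": stage_tad_enrich,
        "mutant-eval": stage_mutant_eval,
    }

    def run(self, up_to: str | None = None) -> RunManifest:
        stages = list(STAGES)
        if up_to is not None:
            stages = stages[: stages.index(up_to) + 1]
        for name in stages:
            t0 = time.time()
            try:
                self.STAGE_FUNCS[name](self)
            except Exception as exc:
                with open(os.path.join(self.out_dir, "FAILED"), "w") as fh:
                    fh.write(f"stage {name}: {exc}\n")
                raise RuntimeError(f"stage {name} failed: {exc}") from exc
            self.manifest.stages[name] = round(time.time() - t0, 3)
        for fn in sorted(os.listdir(self.out_dir)):
            path = os.path.join(self.out_dir, fn)
            if os.path.isfile(path) and fn != "manifest.json":
                self.manifest.checksums[fn] = _sha256(path)
        self.manifest.to_json(os.path.join(self.out_dir, "manifest.json"))
        return self.manifest


def _coerce_sim_overrides(overrides: dict) -> dict:
    out = dict(overrides)
    if "programme_config" in out and isinstance(out["programme_config"], dict):
        out["programme_config"] = sim.ProgrammeConfig(**out["programme_config"])
    if "tad_config" in out and isinstance(out["tad_config"], dict):
        out["tad_config"] = sim.TadConfig(**out["tad_config"])
    if "cluster_labels" in out:
        out["cluster_labels"] = [tuple(x) for x in out["cluster_labels"]]
    if "species_limb_design" in out:
        out["species_limb_design"] = [tuple(x) for x in out["species_limb_design"]]
    return out


def run_pipeline(config: PipelineConfig, out_dir: str | None = None,
                 seed: int | None = None, up_to: str | None = None) -> RunManifest:
    return PipelineRun(config, out_dir=out_dir, seed=seed).run(up_to=up_to)
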