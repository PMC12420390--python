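"""Generator contracts: determinism, planted structure, marginals, truth."""

import numpy as np
import pandas as pd
import pytest

import patagium as pg
from patagium.simulate import SpecValidationError


def _programme_idx(dataset, truth, key):
    return dataset.gene_index(truth.planted_programme[key])


class TestLimbDataset:
    def test_same_seed_identical(self):
        spec = pg.SimulationSpec(n_cells_per_cluster=25, n_genes=700, seed=7)
        d1, t1 = pg.generate_limb_dataset(spec)
        d2, t2 = pg.generate_limb_dataset(
            pg.SimulationSpec(n_cells_per_cluster=25, n_genes=700, seed=7))
        assert (d1.counts != d2.counts).nnz == 0
        assert list(d1.cell_ids) == list(d2.cell_ids)
        assert t1.planted_qc_failures == t2.planted_qc_failures

    def test_different_seed_differs(self):
        d1, _ = pg.generate_limb_dataset(
            pg.SimulationSpec(n_cells_per_cluster=25, n_genes=700, seed=1))
        d2, _ = pg.generate_limb_dataset(
            pg.SimulationSpec(n_cells_per_cluster=25, n_genes=700, seed=2))
        assert (d1.counts != d2.counts).nnz > 0

    def test_null_effects_flatten_programme(self):
        spec = pg.SimulationSpec(
            n_cells_per_cluster=250, n_genes=900, seed=3,
            species_limb_design=[("bat", "FL")],
            marker_config={r: [] for r in
                           ("distal-fibroblast", "proximal-fibroblast",
                            "chondrogenic", "interdigital-RA", "other")},
            programme_config=pg.ProgrammeConfig(log2_effect=0.0),
            outlier_config={})
        ds, truth = pg.generate_limb_dataset(spec)
        idx = _programme_idx(ds, truth, "shared")
        distal = (ds.clusters == "FbDist").to_numpy()
        m_in = np.asarray(ds.counts[distal][:, idx].mean(axis=0)).ravel().mean()
        m_out = np.asarray(ds.counts[~distal][:, idx].mean(axis=0)).ravel().mean()
        assert abs(np.log2(m_in / m_out)) < 0.15

    def test_planted_effect_measurable(self):
        spec = pg.SimulationSpec(
            n_cells_per_cluster=250, n_genes=900, seed=4,
            species_limb_design=[("bat", "FL")], outlier_config={})
        ds, truth = pg.generate_limb_dataset(spec)
        idx = _programme_idx(ds, truth, "distal_only")
        distal = (ds.clusters == "FbDist").to_numpy()
        # compare against the non-fibroblast background (no planted effect)
        backgr = ds.clusters.isin(["Mes1", "Mes2"]).to_numpy()
        m_in = np.asarray(ds.counts[distal][:, idx].mean(axis=0)).ravel()
        m_out = np.asarray(ds.counts[backgr][:, idx].mean(axis=0)).ravel()
        lfc = np.log2(m_in.mean() / m_out.mean())
        assert abs(lfc - spec.programme_config.log2_effect) < 0.3

    def test_distal_cluster_only_in_species_b_forelimb(self, small_sim):
        _, dataset, truth = small_sim
        roles = truth.cluster_role
        has_distal = roles[roles["role"] == "distal-fibroblast"]
        assert set(zip(has_distal["species"], has_distal["limb"])) == {("bat", "FL")}

    def test_library_size_marginal(self):
        spec = pg.SimulationSpec(n_cells_per_cluster=350, n_genes=600, seed=9,
                                 species_limb_design=[("bat", "FL")],
                                 outlier_config={})
        ds, _ = pg.generate_limb_dataset(spec)
        mu, sigma = spec.library_size_lognormal_params
        expected = np.exp(mu + sigma ** 2 / 2)
        assert ds.n_cells >= 2000
        assert abs(ds.total_umis().mean() / expected - 1) < 0.05

    def test_coexpression_joint_probability(self):
        spec = pg.SimulationSpec(
            n_cells_per_cluster=5000, n_genes=400, seed=12,
            species_limb_design=[("bat", "FL")],
            cluster_labels=[("A", "distal-fibroblast")],
            coexpression_pair=("MEIS2", "TBX3", 0.3),
            programme_config=pg.ProgrammeConfig(n_shared=5, n_distal_only=2,
                                                n_proximal_only=2),
            outlier_config={})
        ds, truth = pg.generate_limb_dataset(spec)
        frac = pg.coexpression_fraction(ds, "MEIS2", "TBX3")
        assert abs(frac.loc["A", "frac_both"] - 0.3) < 0.02
        assert truth.planted_coexpression_prob["bat|FL|A"] == 0.3

    def test_planted_qc_cells_violate_intended_rule(self, small_sim):
        _, dataset, truth = small_sim
        for lib, idx in dataset.cell_meta.groupby("library").groups.items():
            sub = dataset.subset_cells(dataset.cell_ids.isin(idx))
            thr = pg.compute_qc_thresholds(sub, sample_id=str(lib))
            rules = pg.evaluate_qc_rules(sub, thr)
            for cell, rule in truth.planted_qc_failures.items():
                if cell in rules.index:
                    assert bool(rules.loc[cell, rule]), (cell, rule)

    def test_invalid_spec_names_field(self):
        with pytest.raises(SpecValidationError, match="n_genes"):
            pg.generate_limb_dataset(pg.SimulationSpec(n_genes=50))
        with pytest.raises(SpecValidationError, match="nb_dispersion"):
            pg.SimulationSpec(nb_dispersion=-1).validate()
        with pytest.raises(SpecValidationError, match="ribo_fraction_range"):
            pg.SimulationSpec(ribo_fraction_range=(0.5, 0.2)).validate()
        with pytest.raises(SpecValidationError, match="coexpression"):
            pg.SimulationSpec(coexpression_pair=("A", "B", 1.5)).validate()


class TestOrthology:
    def test_full_mapping_is_bijective(self):
        spec = pg.SimulationSpec(n_genes=700, seed=0,
                                 orthology_mapped_fraction=1.0)
        orth = pg.generate_orthology(spec)
        assert len(orth) == 700
        assert orth.pairs["gene_a"].is_unique and orth.pairs["gene_b"].is_unique

    def test_partial_mapping_counts(self):
        spec = pg.SimulationSpec(n_genes=700, seed=0,
                                 orthology_mapped_fraction=0.8)
        orth = pg.generate_orthology(spec)
        assert len(orth) == round(0.8 * 700)
        assert len(orth.unmapped_a) == 700 - len(orth)

    def test_species_specific_genes_unmapped(self):
        spec = pg.SimulationSpec(n_genes=700, seed=0)
        orth = pg.generate_orthology(spec)
        ds, truth = pg.generate_limb_dataset(
            pg.SimulationSpec(n_genes=700, seed=0, n_cells_per_cluster=5,
                              outlier_config={}))
        mapped = set(orth.pairs["gene_a"])
        assert not mapped & set(truth.species_specific_genes)
        # planted programme genes stay mapped
        assert set(truth.planted_programme["shared"]) <= mapped

    def test_duplicate_pair_rejected(self):
        with pytest.raises(Exception, match="more than one"):
            pg.OrthologyMap(pairs=pd.DataFrame(
                {"gene_a": ["x", "x"], "gene_b": ["u", "v"]}))


class TestRegulatoryTracks:
    def test_tads_tile_genome(self):
        spec = pg.SimulationSpec(seed=2)
        tads, peaks, signal, gene_map, truth = pg.generate_regulatory_tracks(spec)
        assert (tads["start"].to_numpy()[1:] == tads["end"].to_numpy()[:-1]).all()
        assert len(tads) == spec.tad_config.n_tads

    def test_enriched_truth_matches_draws(self):
        spec = pg.SimulationSpec(seed=2)
        *_, truth = pg.generate_regulatory_tracks(spec)
        assert len(truth.enriched_tads) == truth.tad_signal_params["n_enriched_drawn"]

    def test_zero_enriched_weight_empty_truth(self):
        spec = pg.SimulationSpec(seed=2, tad_config=pg.TadConfig(enriched_weight=0.0))
        *_, truth = pg.generate_regulatory_tracks(spec)
        assert truth.enriched_tads == []

    def test_peak_length_matches_target(self):
        spec = pg.SimulationSpec(seed=5, tad_config=pg.TadConfig(
            n_tads=10, tad_length=10_000, bulk_coverage=(0.5, 0.5),
            enriched_coverage=(0.5, 0.5)))
        tads, peaks, *_ = pg.generate_regulatory_tracks(spec)
        merged = pg.merge_intervals(peaks)
        for _, tad in tads.iterrows():
            inside = merged[(merged["start"] >= tad["start"])
                            & (merged["end"] <= tad["end"])]
            total = (inside["end"] - inside["start"]).sum()
            assert abs(total - 5_000) <= spec.tad_config.peak_bin

    def test_each_gene_in_at_most_one_tad(self):
        spec = pg.SimulationSpec(seed=2, n_genes=500)
        tads, _, _, gene_map, _ = pg.generate_regulatory_tracks(spec)
        assigned = pg.assign_genes_to_tads(gene_map, tads)
        assert assigned.index.is_unique
        assert len(assigned) == 500  # tiling covers the whole genome

    def test_bad_mixture_sd_rejected(self):
        with pytest.raises(SpecValidationError, match="component_sd"):
            pg.generate_regulatory_tracks(
                pg.SimulationSpec(tad_config=pg.TadConfig(component_sd=0.0)))

    def test_track_determinism(self):
        a = pg.generate_regulatory_tracks(pg.SimulationSpec(seed=6))
        b = pg.generate_regulatory_tracks(pg.SimulationSpec(seed=6))
        pd.testing.assert_frame_equal(a[2], b[2])
        assert a[4].enriched_tads == b[4].enriched_tads
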