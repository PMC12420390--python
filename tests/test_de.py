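"""Differential expression: exact Wilcoxon, gates, BH, programme derivation,
concordance, over-representation, mutant filtering, profile correlation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import patagium as pg
from patagium.de import exact_ranksum_pvalue, wilcoxon_de, _cluster_masks
from patagium.datasets import DatasetError
from conftest import make_dataset, set_lognorm


def enumeration_ranksum_p(x, y):
    """Brute-force permutation oracle: enumerate every group assignment."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    w_obs = ranks[:n1].sum()
    ws = np.array([ranks[list(c)].sum()
                   for c in itertools.combinations(range(len(pooled)), n1)])
    lower = np.mean(ws <= w_obs + 1e-9)
    upper = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(lower, upper))


class TestExactWilcoxon:
    def test_textbook_separation(self):
        assert exact_ranksum_pvalue([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_matches_enumeration_small_sizes(self):
        rng = np.random.default_rng(5)
        for n1 in range(1, 11):
            for n2 in range(1, 13 - n1):
                x = rng.integers(0, 4, n1).astype(float)
                y = rng.integers(0, 4, n2).astype(float)
                if len(np.unique(np.concatenate([x, y]))) < 2:
                    y = y + 1
                assert exact_ranksum_pvalue(x, y) == pytest.approx(
                    enumeration_ranksum_p(x, y), abs=1e-12)

    def test_identical_groups_p_one(self):
        vals = np.array([[1.0], [1.0], [1.0], [1.0]])
        ds = set_lognorm(make_dataset(np.ones((4, 1), int)), vals)
        grp = np.array([True, True, False, False])
        de = wilcoxon_de(ds, grp, ~grp, min_pct=0.0, lfc_threshold=0.0)
        assert de["log2fc"].iloc[0] == 0.0
        assert de["p"].iloc[0] == 1.0


class TestDEGates:
    def test_low_detection_not_tested(self):
        # gene detected in 10% of both groups with min_pct 0.25
        counts = np.zeros((40, 2), int)
        counts[:, 1] = 5                    # keeper gene for totals
        counts[[0, 1, 20, 21], 0] = 3       # 10% detection per group of 20
        ds = pg.log_normalize(make_dataset(counts))
        grp = np.arange(40) < 20
        de = wilcoxon_de(ds, grp, ~grp, min_pct=0.25, lfc_threshold=0.0)
        assert not de.loc["g0", "tested"]
        assert np.isnan(de.loc["g0", "p"])

    def test_empty_group_rejected(self):
        ds = pg.log_normalize(make_dataset(np.ones((4, 2), int)))
        with pytest.raises(DatasetError):
            wilcoxon_de(ds, np.zeros(4, bool), np.ones(4, bool))

    def test_bh_monotone(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(2.0, size=(60, 300))
        ds = pg.log_normalize(make_dataset(counts))
        grp = np.arange(60) < 30
        de = wilcoxon_de(ds, grp, ~grp, min_pct=0.0, lfc_threshold=0.0)
        tested = de[de["tested"]].dropna(subset=["p"])
        by_p = tested.sort_values(["p", "p_adj"]).index
        by_padj = tested.sort_values(["p_adj", "p"], kind="stable")
        assert (tested["p_adj"] >= tested["p"] - 1e-12).all()
        assert list(tested.loc[by_p, "p_adj"]) == sorted(tested["p_adj"])


@pytest.fixture(scope="module")
def small_programme():
    spec = pg.SimulationSpec(
        n_cells_per_cluster=150, n_genes=1200, seed=33,
        species_limb_design=[("mouse", "FL"), ("bat", "FL")],
        outlier_config={})
    ds, truth = pg.generate_limb_dataset(spec)
    pg.log_normalize(ds)
    blocks = pg.split_blocks(ds)
    orth = pg.generate_orthology(spec)
    return spec, truth, blocks, orth


class TestProgramme:

    def test_shared_rule_matches_brute_force(self, small_programme):
        spec, truth, blocks, orth = small_programme
        bat = blocks[("bat", "FL")]
        hvgs = pg.select_hvgs(bat)
        prog = pg.derive_programme(bat, "FbDist", ["FbProx"], hvgs)
        # brute-force re-test of the round-2 shared rule on the union genes
        m_d, m_p, m_rest = _cluster_masks(bat, "FbDist", ["FbProx"])
        union = sorted(set(prog.round2_distal.index))
        de_d = wilcoxon_de(bat, m_d, m_rest, gene_subset=union,
                          min_pct=0.0, lfc_threshold=0.0)
        de_p = wilcoxon_de(bat, m_p, m_rest, gene_subset=union,
                          min_pct=0.0, lfc_threshold=0.0)
        enr = set(de_d.index[(de_d["p_adj"] < 0.05) & (de_d["log2fc"] > 0.1)]) \
            | set(de_p.index[(de_p["p_adj"] < 0.05) & (de_p["log2fc"] > 0.1)])
        expect = {g for g in union
                  if de_d.loc[g, "log2fc"] > 0.1 and de_p.loc[g, "log2fc"] > 0.1
                  and g in enr}
        assert set(prog.shared) == expect

    def test_invariant_to_cell_order(self, small_programme):
        spec, truth, blocks, orth = small_programme
        bat = blocks[("bat", "FL")]
        hvgs = pg.select_hvgs(bat)
        prog1 = pg.derive_programme(bat, "FbDist", ["FbProx"], hvgs)
        perm = np.random.default_rng(0).permutation(bat.n_cells)
        shuffled = pg.CellDataset(bat.adata[perm].copy())
        prog2 = pg.derive_programme(shuffled, "FbDist", ["FbProx"], hvgs)
        assert prog1.to_dict() == prog2.to_dict()

    def test_cross_species_shared_requires_other_species(self, small_programme):
        spec, truth, blocks, orth = small_programme
        bat, mouse = blocks[("bat", "FL")], blocks[("mouse", "FL")]
        hvgs = pg.select_hvgs(bat)
        prog = pg.derive_programme(bat, "FbDist", ["FbProx"], hvgs,
                                   orthology=orth, dataset_other=mouse,
                                   other_proximal_clusters=["FbProx"])
        assert set(prog.cross_species_shared) <= set(prog.shared)
        assert len(prog.cross_species_shared) > 0

    def test_missing_cluster_rejected(self, small_programme):
        _, _, blocks, _ = small_programme
        bat = blocks[("bat", "FL")]
        with pytest.raises(DatasetError):
            pg.derive_programme(bat, "NoSuch", ["FbProx"], ["HOXD13"])

    def test_programme_set_invariants(self, small_programme):
        spec, truth, blocks, orth = small_programme
        bat, mouse = blocks[("bat", "FL")], blocks[("mouse", "FL")]
        prog = pg.derive_programme(bat, "FbDist", ["FbProx"],
                                   pg.select_hvgs(bat), orthology=orth,
                                   dataset_other=mouse,
                                   other_proximal_clusters=["FbProx"])
        shared = set(prog.shared)
        assert shared <= set(prog.distal_enriched) | set(prog.proximal_enriched)
        assert not set(prog.distal_only) & shared
        assert not set(prog.proximal_only) & shared


class TestConcordance:
    def _de_frame(self, lfcs):
        return pd.DataFrame({"log2fc": list(lfcs.values())},
                            index=pd.Index(lfcs.keys(), name="gene"))

    def test_band_membership(self):
        orth = pg.OrthologyMap(pairs=pd.DataFrame(
            {"gene_a": ["g1", "g2"], "gene_b": ["g1", "g2"]}))
        de_a = self._de_frame({"g1": 0.5, "g2": 0.5})
        de_b = self._de_frame({"g1": 0.5, "g2": 0.1})
        res = pg.crossspecies_lfc_compare(de_a, de_b, orth, band=0.25)
        assert bool(res.paired.loc["g1", "within_band"])
        assert not bool(res.paired.loc["g2", "within_band"])
        assert res.fraction_within_band == pytest.approx(0.5)

    def test_unpaired_recorded_not_error(self):
        orth = pg.OrthologyMap(pairs=pd.DataFrame(
            {"gene_a": ["g1"], "gene_b": ["g1"]}))
        de_a = self._de_frame({"g1": 0.2, "orphan": 1.0})
        de_b = self._de_frame({"g1": 0.3})
        res = pg.crossspecies_lfc_compare(de_a, de_b, orth)
        assert res.unpaired == ["orphan"]


class TestOverrepresentation:
    def test_exact_combinatorial_value(self):
        universe = [f"u{i}" for i in range(10)]
        hits = universe[:5]
        ref = universe[:5]
        overlap, p = pg.overrepresentation(hits, ref, universe)
        assert overlap == 5
        assert p == pytest.approx(1 / 252)

    def test_reference_equals_universe(self):
        universe = [f"u{i}" for i in range(8)]
        _, p = pg.overrepresentation(universe[:3], universe, universe)
        assert p == pytest.approx(1.0)

    def test_zero_overlap_tail_is_one(self):
        universe = [f"u{i}" for i in range(10)]
        _, p = pg.overrepresentation([universe[9]], universe[:5], universe)
        assert p <= 1.0
        overlap, p0 = pg.overrepresentation([], universe[:5], universe)
        assert p0 == pytest.approx(1.0)

    def test_non_subset_rejected(self):
        with pytest.raises(ValueError):
            pg.overrepresentation(["x"], ["a"], ["a", "b"])

    def test_matches_subset_enumeration(self):
        # exhaustive subset enumeration oracle on a small universe
        universe = list(range(9))
        ref = set(range(4))
        for n_draw in (1, 3, 5):
            hits = list(range(n_draw))
            obs = len(set(hits) & ref)
            count = sum(1 for c in itertools.combinations(universe, n_draw)
                        if len(set(c) & ref) >= obs)
            expected = count / len(list(
                itertools.combinations(universe, n_draw)))
            _, p = pg.overrepresentation(
                [str(h) for h in hits], [str(r) for r in ref],
                [str(u) for u in universe])
            assert p == pytest.approx(expected)


class TestUniverseAndMutant:
    def test_universe_min_cells_boundary(self):
        counts = np.zeros((12, 3), int)
        counts[:9, 0] = 1   # 9 cells -> in
        counts[:8, 1] = 1   # 8 cells -> out
        counts[:, 2] = 1    # keep totals positive
        ds = make_dataset(counts)
        uni = pg.build_universe(ds, min_cells=9)
        assert "g0" in uni and "g1" not in uni

    def test_empty_matrix_empty_universe(self):
        ds = make_dataset(np.zeros((3, 2), int))
        assert pg.build_universe(ds) == []

    def test_mutant_filter_rules(self):
        counts = np.zeros((40, 4), int)
        counts[:, 3] = 1
        wt = np.arange(40) < 20
        counts[np.flatnonzero(wt)[:4], 0] = 2   # 20% in wt, 5% in mut
        counts[np.flatnonzero(~wt)[:1], 0] = 2
        counts[:, 1] = 3                        # ribosomal, high everywhere
        counts[np.flatnonzero(wt)[:2], 2] = 1   # 10%/10%
        counts[np.flatnonzero(~wt)[:2], 2] = 1
        ds = make_dataset(counts, flags={"ribosomal": [False, True, False, False]})
        geno = pd.Series(np.where(wt, "wt", "mut"), index=ds.cell_ids)
        kept = pg.mutant_gene_filter(ds, geno, min_pct=0.15)
        assert "g0" in kept        # 20% in one genotype
        assert "g1" not in kept    # ribosomal
        assert "g2" not in kept    # 10%/10%

    def test_missing_flag_warns(self):
        ds = make_dataset(np.ones((4, 2), int))
        ds.adata.var.drop(columns=["chrx"], inplace=True)
        geno = pd.Series(["wt", "wt", "mut", "mut"], index=ds.cell_ids)
        with pytest.warns(UserWarning, match="chrx"):
            pg.mutant_gene_filter(ds, geno)


class TestProfileCorrelation:
    def _reference(self):
        rng = np.random.default_rng(0)
        vals = rng.gamma(2.0, 1.0, size=(30, 8))
        ds = set_lognorm(make_dataset(np.ones((30, 8), int),
                                      clusters=["ref"] * 30), vals)
        return ds, vals

    def test_identical_cell_r_one(self):
        ref, vals = self._reference()
        profile = vals.mean(axis=0)
        query = set_lognorm(make_dataset(np.ones((1, 8), int)),
                            profile[None, :])
        out = pg.profile_correlation(query, ref, "ref", list(ref.gene_ids))
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_negated_cell_r_minus_one(self):
        ref, vals = self._reference()
        profile = vals.mean(axis=0)
        negated = 2 * profile.mean() - profile  # mirrored about its mean
        query = set_lognorm(make_dataset(np.ones((1, 8), int)),
                            negated[None, :])
        out = pg.profile_correlation(query, ref, "ref", list(ref.gene_ids))
        assert out["r"].iloc[0] == pytest.approx(-1.0)

    def test_zero_variance_cell_missing(self):
        ref, _ = self._reference()
        query = set_lognorm(make_dataset(np.ones((1, 8), int)),
                            np.full((1, 8), 2.0))
        out = pg.profile_correlation(query, ref, "ref", list(ref.gene_ids))
        assert np.isnan(out["r"].iloc[0])
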