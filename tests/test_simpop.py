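"""Unit tests for the synthetic-population generator."""

import numpy as np
import pandas as pd
import pytest

from mlcqtl.iomodel import (
    FamilyAssignment, GenotypeMatrix, read_families, read_genotypes, read_map,
    read_plots,
)
from mlcqtl.linkage import haldane
from mlcqtl.simpop import (
    ConfigError, EpistaticPair, FamilySpec, SimConfig, TrueQTL, default_config,
    genetic_values, make_consensus_map, realized_locus, simulate_dataset,
    simulate_dh_family, simulate_entry_means, simulate_field_trial,
    standard_truth, write_dataset,
)

from conftest import small_config, study_families


class TestConsensusMap:
    def test_spacing_and_endpoints(self):
        lmap = make_consensus_map([("C1", 100.0), ("C2", 47.0)], 10.0)
        c1 = lmap.table[lmap.table["chromosome"] == "C1"]["position"].to_numpy()
        assert c1[0] == 0.0 and c1[-1] == 100.0
        assert np.allclose(np.diff(c1), 10.0)
        c2 = lmap.table[lmap.table["chromosome"] == "C2"]["position"].to_numpy()
        assert c2[-1] == 47.0  # chromosome end always carries a marker

    def test_jitter_keeps_order(self):
        lmap = make_consensus_map([("C1", 100.0)], 5.0, seed=3, jitter=0.4)
        p = lmap.table["position"].to_numpy()
        assert np.all(np.diff(p) > 0)
        assert p[0] == 0.0 and p[-1] == 100.0

    def test_errors(self):
        with pytest.raises(ConfigError):
            make_consensus_map([], 10.0)
        with pytest.raises(ConfigError):
            make_consensus_map([("C1", 50.0)], 0.0)


class TestDHFamily:
    def _family(self, n=4000, seed=0):
        lmap = make_consensus_map([("C1", 50.0), ("C2", 50.0)], 10.0)
        h1 = np.ones(lmap.n_markers, dtype=int)
        h2 = np.zeros(lmap.n_markers, dtype=int)
        return lmap, simulate_dh_family(lmap, h1, h2, n, seed, ref_alleles=h1)

    def test_codes_are_dh(self):
        _, gm = self._family(n=200)
        assert set(np.unique(gm.values)) <= {0.0, 2.0}

    def test_segregation_one_to_one(self):
        _, gm = self._family()
        freq = gm.values.mean(axis=0) / 2.0
        assert np.all(np.abs(freq - 0.5) < 0.05)  # 4000 lines, ~6 sigma

    def test_adjacent_recombination_matches_haldane(self):
        lmap, gm = self._family()
        G = gm.values
        tab = lmap.table
        for chrom in ("C1", "C2"):
            idx = np.flatnonzero((tab["chromosome"] == chrom).to_numpy())
            for a, b in zip(idx[:-1], idx[1:]):
                r_obs = float(np.mean(G[:, a] != G[:, b]))
                assert r_obs == pytest.approx(haldane(10.0), abs=0.02)

    def test_chromosomes_unlinked(self):
        lmap, gm = self._family()
        G = gm.values
        last_c1 = 5   # last marker of C1 (6 markers per chromosome)
        first_c2 = 6
        r_obs = float(np.mean(G[:, last_c1] != G[:, first_c2]))
        assert r_obs == pytest.approx(0.5, abs=0.03)

    def test_determinism(self):
        _, a = self._family(n=50, seed=9)
        _, b = self._family(n=50, seed=9)
        _, c = self._family(n=50, seed=10)
        assert a.frame.equals(b.frame)
        assert not a.frame.equals(c.frame)

    def test_errors(self):
        lmap = make_consensus_map([("C1", 20.0)], 10.0)
        with pytest.raises(ConfigError):
            simulate_dh_family(lmap, [1, 1], [0, 0], 5, 0)  # wrong length
        with pytest.raises(ConfigError):
            simulate_dh_family(lmap, [1, 1, 1], [0, 0, 0], 0, 0)


class TestGeneticValues:
    def test_hand_computed_case(self):
        lmap = make_consensus_map([("C1", 10.0), ("C2", 10.0)], 10.0)
        geno = GenotypeMatrix(pd.DataFrame(
            [[2.0, 0.0, 2.0, 2.0], [0.0, 2.0, 0.0, 2.0]],
            index=["x", "y"], columns=lmap.markers))
        fams = FamilyAssignment(pd.DataFrame(
            {"line": ["x", "y"], "family": ["A", "A"],
             "parent1": "P1", "parent2": "P2"}))
        qtl = [TrueQTL("C1", 2.0, np.array([[1.5]]))]        # nearest marker: C1 @ 0
        pairs = [EpistaticPair("C1", 10.0, "C2", 0.0, np.array([[0.5]]))]
        g = genetic_values(geno, fams, qtl, pairs, 0, lmap)
        # line x: z = (+1, -1, +1) -> 1.5*1 + 0.5*(-1*1) = 1.0
        # line y: z = (-1, +1, -1) -> -1.5 + 0.5*(1*-1)  = -2.0
        assert np.allclose(g, [1.0, -2.0])

    def test_stage_out_of_range(self):
        lmap = make_consensus_map([("C1", 10.0)], 10.0)
        geno = GenotypeMatrix(pd.DataFrame([[2.0, 0.0]], index=["x"],
                                           columns=lmap.markers))
        fams = FamilyAssignment(pd.DataFrame(
            {"line": ["x"], "family": ["A"], "parent1": "P1", "parent2": "P2"}))
        qtl = [TrueQTL("C1", 0.0, np.array([[1.0, 2.0]]))]
        with pytest.raises(IndexError):
            genetic_values(geno, fams, qtl, [], 2, lmap)


class TestFounderForcing:
    def test_segregation_matches_effect_pattern(self, small_dataset):
        ds = small_dataset
        codes = ds.families.codes_for(ds.genotypes.line_ids)
        for q in ds.truth.true_qtl:
            _, mpos = realized_locus(ds.linkage_map, q.chromosome, q.position)
            j = list(ds.linkage_map.markers).index(
                ds.linkage_map.table.loc[
                    (ds.linkage_map.table["chromosome"] == q.chromosome)
                    & (ds.linkage_map.table["position"] == mpos), "marker"].iloc[0])
            col = ds.genotypes.values[:, j]
            for f in range(ds.families.n_families):
                v = col[codes == f]
                segregates = len(set(v)) > 1
                assert segregates == bool(np.any(q.effects[f] != 0.0))

    def test_conflicting_requirements_raise(self):
        chroms = [("C1", 40.0)]
        fams = [FamilySpec("FA", 10, "P1", "P2"), FamilySpec("FB", 10, "P1", "P2")]
        # same parents, same locus: FA must segregate, FB must not
        qtl = [TrueQTL("C1", 20.0, np.array([[1.0], [0.0]]))]
        cfg = SimConfig(chromosome_spec=chroms, marker_spacing=10.0,
                        family_spec=fams, true_qtl=qtl, stage_count=1,
                        stage_means=(100.0,), plots_per_environment=30)
        with pytest.raises(ConfigError):
            simulate_dataset(cfg)


class TestFieldTrial:
    def test_layout_counts(self, small_dataset):
        plots = small_dataset.plots.frame
        cfg = small_dataset.config
        for env, grp in plots.groupby("environment"):
            assert len(grp) == cfg.plots_per_environment
            # every entry appears at least once per environment
            non_check = grp.loc[~grp["is_check"], "entry"]
            assert non_check.nunique() == 120
        # mean replication strictly between 1 and 2 for a p-rep layout
        non_check = plots.loc[~plots["is_check"]]
        rep = len(non_check) / (non_check["entry"].nunique() * cfg.n_environments)
        assert 1.0 < rep < 2.0
        # checks replicated in every environment
        checks = plots.loc[plots["is_check"]]
        assert checks["entry"].nunique() == cfg.n_checks
        per_env = checks.groupby(["entry", "environment"]).size()
        assert (per_env >= 1).all()

    def test_zero_noise_entry_means_recover_truth(self):
        cfg = small_config(sigma_gxe=0.0, sigma_e=0.0)
        ds = simulate_dataset(cfg)
        frame = ds.plots.frame
        non_check = frame.loc[~frame["is_check"]]
        # average the per-environment means so p-rep double plots don't bias
        env_means = non_check.groupby(["entry", "environment"])["PH1"].mean()
        means = env_means.groupby("entry").mean()
        want = pd.Series(cfg.stage_means[0] + ds.truth.genetic[:, 0],
                         index=ds.genotypes.line_ids)
        assert np.allclose(means.loc[want.index], want, atol=1e-9)

    def test_capacity_error(self):
        cfg = small_config()
        g = np.zeros((200, 3))
        with pytest.raises(ConfigError):
            simulate_field_trial(g, cfg, seed=0)  # 200 entries > 140 plots


class TestEntryMeans:
    def test_h2_one_is_exact_truth(self, small_dataset):
        blues = simulate_entry_means(small_dataset, h2=1.0, seed=0)
        g = small_dataset.truth.genetic
        for s, name in enumerate(small_dataset.config.stage_names):
            v = blues.stage_values(name, small_dataset.genotypes.line_ids)
            assert np.allclose(v, small_dataset.config.stage_means[s] + g[:, s])

    def test_target_h2_realized(self):
        cfg = small_config(seed=3)
        ds = simulate_dataset(cfg)
        blues = simulate_entry_means(ds, h2=0.8, seed=5)
        g = ds.truth.genetic[:, 0]
        codes = ds.families.codes_for(ds.genotypes.line_ids)
        y = blues.stage_values("PH1", ds.genotypes.line_ids)
        noise = y - cfg.stage_means[0] - g
        gw = g - np.array([g[codes == f].mean() for f in range(3)])[codes]
        h2_real = np.var(gw) / (np.var(gw) + np.var(noise))
        assert h2_real == pytest.approx(0.8, abs=0.06)

    def test_h2_domain(self, small_dataset):
        with pytest.raises(ConfigError):
            simulate_entry_means(small_dataset, h2=0.0)


class TestStandardTruth:
    def test_major_chromosome_reserved(self):
        chroms = [(f"C{i}", 100.0) for i in range(1, 8)]
        fams = study_families()
        qtl, pairs = standard_truth(chroms, fams, seed=0)
        major = qtl[0]
        assert major.chromosome == "C1"
        others = [q for q in qtl[1:]]
        for q in others:
            assert q.chromosome != "C1"
        for p in pairs:
            assert p.chromosome1 != "C1" and p.chromosome2 != "C1"
        # the major segregates in exactly one family
        seg = np.any(major.effects != 0.0, axis=1)
        assert seg.sum() == 1

    def test_major_share_realized(self):
        chroms = [(f"C{i}", 100.0) for i in range(1, 8)]
        fams = study_families()
        qtl, pairs = standard_truth(chroms, fams, seed=1)
        cfg = SimConfig(chromosome_spec=chroms, marker_spacing=10.0,
                        family_spec=fams, true_qtl=qtl, epistatic_pairs=pairs,
                        seed=1)
        ds = simulate_dataset(cfg)
        codes = ds.families.codes_for(ds.genotypes.line_ids)
        g_major = genetic_values(ds.genotypes, ds.families, [qtl[0]], [], 0,
                                 ds.linkage_map)
        g_all = ds.truth.genetic[:, 0]

        def centred_var(v):
            c = v - np.array([v[codes == f].mean() for f in range(4)])[codes]
            return float(np.var(c))

        share = centred_var(g_major) / centred_var(g_all)
        assert share == pytest.approx(0.45, abs=0.07)

    def test_minimum_locus_separation(self):
        chroms = [(f"C{i}", 100.0) for i in range(1, 8)]
        qtl, pairs = standard_truth(chroms, study_families(), seed=2)
        loci = [(q.chromosome, q.position) for q in qtl]
        for p in pairs:
            loci += [(p.chromosome1, p.position1), (p.chromosome2, p.position2)]
        for i, (c1, p1) in enumerate(loci):
            for c2, p2 in loci[i + 1:]:
                if c1 == c2:
                    assert abs(p1 - p2) >= 15.0


class TestConfigValidation:
    def test_bad_positions_and_shapes(self):
        chroms = [("C1", 50.0)]
        fams = [FamilySpec("FA", 10, "P1", "P2")]
        with pytest.raises(ConfigError):
            SimConfig(chromosome_spec=chroms, marker_spacing=10.0,
                      family_spec=fams,
                      true_qtl=[TrueQTL("C9", 10.0, np.zeros((1, 3)))])
        with pytest.raises(ConfigError):
            SimConfig(chromosome_spec=chroms, marker_spacing=10.0,
                      family_spec=fams,
                      true_qtl=[TrueQTL("C1", 60.0, np.zeros((1, 3)))])
        with pytest.raises(ConfigError):
            SimConfig(chromosome_spec=chroms, marker_spacing=10.0,
                      family_spec=fams,
                      true_qtl=[TrueQTL("C1", 10.0, np.zeros((2, 3)))])
        with pytest.raises(ConfigError):
            SimConfig(chromosome_spec=chroms, marker_spacing=10.0,
                      family_spec=fams, sigma_e=-1.0)
        with pytest.raises(ConfigError):
            SimConfig(chromosome_spec=[], marker_spacing=10.0, family_spec=fams)


class TestDatasetRoundTrip:
    def test_write_and_read_back(self, small_dataset, tmp_path):
        paths = write_dataset(small_dataset, tmp_path, seed=11)
        lmap = read_map(paths["map"])
        geno = read_genotypes(paths["genotypes"], lmap)
        fams = read_families(paths["families"])
        plots = read_plots(paths["plots"])
        assert lmap.table.equals(small_dataset.linkage_map.table)
        assert np.allclose(geno.values, small_dataset.genotypes.values)
        assert list(fams.family_ids) == list(small_dataset.families.family_ids)
        assert len(plots.frame) == len(small_dataset.plots.frame)
        assert (tmp_path / "truth.json").exists()

    def test_determinism(self):
        a = simulate_dataset(small_config(seed=21))
        b = simulate_dataset(small_config(seed=21))
        c = simulate_dataset(small_config(seed=22))
        assert a.genotypes.frame.equals(b.genotypes.frame)
        assert a.plots.frame.equals(b.plots.frame)
        assert not a.plots.frame.equals(c.plots.frame)

    def test_missing_rate_applied(self):
        ds = simulate_dataset(small_config(seed=4, missing_rate=0.1))
        miss = float(np.isnan(ds.genotypes.values).mean())
        assert miss == pytest.approx(0.1, abs=0.02)


def test_default_config_study_scale():
    cfg = default_config(seed=0)
    assert len(cfg.chromosome_spec) == 21
    assert sum(f.size for f in cfg.family_spec) == 647
    assert cfg.stage_count == 3
    assert len(cfg.true_qtl) == 10 and len(cfg.epistatic_pairs) == 2


def test_realized_locus_nearest_marker():
    lmap = make_consensus_map([("C1", 50.0)], 10.0)
    assert realized_locus(lmap, "C1", 24.0) == ("C1", 20.0)
    assert realized_locus(lmap, "C1", 26.0) == ("C1", 30.0)
    with pytest.raises(ConfigError):
        realized_locus(lmap, "C9", 5.0)
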