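"""The synthetic world: planted structure must be exactly recoverable."""

import numpy as np
import pytest

import biohotspots as bh
from biohotspots.synthetic import ConfigurationError


def small_cfg(**kw):
    defaults = dict(
        seed=3, n_species=40, extent=(0, 0, 500, 500), cell_size=50,
        n_hotspot_clusters=1, cluster_radius=100, n_nnr=5, n_pnr=8,
        n_env_layers=4,
    )
    defaults.update(kw)
    return bh.SyntheticConfig(**defaults)


class TestConfig:
    def test_invalid_fractions_rejected(self):
        with pytest.raises(ConfigurationError):
            small_cfg(category_fractions={"CR": 0.5, "EN": 0.6, "VU": 0, "NT": 0, "CC": 0})
        with pytest.raises(ConfigurationError):
            small_cfg(frac_endemic=1.5)
        with pytest.raises(ConfigurationError):
            small_cfg(reserve_coverage=1.2)

    def test_yaml_round_trip(self, tmp_path):
        cfg = small_cfg()
        path = tmp_path / "config.yaml"
        cfg.to_yaml(path)
        assert bh.SyntheticConfig.from_yaml(path) == cfg


class TestChecklist:
    def test_largest_remainder_example(self):
        counts = bh.largest_remainder_counts(
            10, {"CR": 0.1, "EN": 0.2, "VU": 0.3, "NT": 0.2, "CC": 0.2}
        )
        assert counts == {"CR": 1, "EN": 2, "VU": 3, "NT": 2, "CC": 2}

    def test_headline_composition(self):
        """458 species split 88/88/88 CR/EN/VU, 56 NT, 138 CC."""
        cfg = small_cfg(n_species=458)
        checklist = bh.generate_checklist(cfg)
        counts = checklist["category"].value_counts()
        assert counts["NT"] == 56
        assert counts["CC"] == 138
        assert counts[["CR", "EN", "VU"]].sum() == 264
        assert len(checklist) == 458

    def test_deterministic(self):
        cfg = small_cfg()
        a = bh.generate_checklist(cfg)
        b = bh.generate_checklist(cfg)
        assert a.equals(b)


class TestOccurrences:
    def test_range_floor_single_species(self):
        cfg = small_cfg(n_species=1, range_size_median=1.0, range_size_shape=0.0,
                        n_hotspot_clusters=0)
        checklist = bh.generate_checklist(cfg)
        occ = bh.generate_occurrences(cfg, checklist)
        pm = bh.build_presence(occ, cfg.grid(), species_order=checklist["species_id"])
        assert bh.range_sizes(pm).tolist() == [1]

    def test_narrow_species_confined_to_disks(self):
        cfg = small_cfg(n_species=60, range_size_shape=1.6, range_size_median=2.0)
        checklist = bh.generate_checklist(cfg)
        occ = bh.generate_occurrences(cfg, checklist)
        narrow = set(bh.narrow_species(cfg, checklist))
        assert len(narrow) >= 20
        grid = cfg.grid()
        pm = bh.build_presence(occ, grid, species_order=checklist["species_id"])
        centers = grid.cell_centers()
        # every narrow species' occupied cells sit inside one disk of the
        # planted radius (disk membership is by cell center)
        for sid in narrow:
            cells = np.flatnonzero(pm.occupancy[:, pm.species_index([sid])[0]])
            pts = centers[cells]
            spread = np.hypot(*(pts - pts.mean(axis=0)).T).max() if len(pts) > 1 else 0
            assert spread <= 2 * cfg.cluster_radius

    def test_every_species_has_a_record(self):
        cfg = small_cfg()
        checklist = bh.generate_checklist(cfg)
        occ = bh.generate_occurrences(cfg, checklist)
        assert set(occ["species_id"]) == set(checklist["species_id"])
        xmin, ymin, xmax, ymax = cfg.extent
        assert occ["x"].between(xmin, xmax).all()
        assert occ["y"].between(ymin, ymax).all()

    def test_byte_identical_regeneration(self, tmp_path):
        from biohotspots.io import write_occurrences

        cfg = small_cfg()
        checklist = bh.generate_checklist(cfg)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_occurrences(bh.generate_occurrences(cfg, checklist), p1)
        write_occurrences(bh.generate_occurrences(cfg, checklist), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_extent_too_small_for_clusters(self):
        cfg = small_cfg(extent=(0, 0, 150, 150), cluster_radius=100)
        checklist = bh.generate_checklist(cfg)
        with pytest.raises(ConfigurationError):
            bh.generate_occurrences(cfg, checklist)


class TestReserves:
    def test_coverage_within_contract(self):
        cfg = small_cfg(reserve_coverage=0.2)
        layer = bh.generate_reserves(cfg)
        xmin, ymin, xmax, ymax = cfg.extent
        extent_area = (xmax - xmin) * (ymax - ymin)
        total = sum(g.area for g in layer.geometries)
        assert total / extent_area == pytest.approx(0.2, rel=0.2)
        assert layer.tiers.count("NNR") == cfg.n_nnr
        assert layer.tiers.count("PNR") == cfg.n_pnr

    def test_empty_layer_means_all_gaps(self, tiny_grid):
        cfg = small_cfg(n_nnr=0, n_pnr=0)
        layer = bh.generate_reserves(cfg)
        assert len(layer) == 0
        status = bh.protection_status(tiny_grid, layer)
        assert bh.gap_cells({0, 1, 2}, status, "either") == {0, 1, 2}

    def test_total_coverage_single_rectangle(self):
        from shapely.geometry import box

        grid = bh.build_grid((0, 0, 100, 100), 50)
        layer = bh.ReserveLayer([box(0, 0, 100, 100)], ["NNR"])
        status = bh.protection_status(grid, layer)
        assert status.by_nnr.all()

    def test_geojson_round_trip_preserves_tiers(self, tmp_path):
        from biohotspots.io import read_reserves, write_reserves

        cfg = small_cfg()
        layer = bh.generate_reserves(cfg)
        path = tmp_path / "reserves.geojson"
        write_reserves(layer, path)
        back = read_reserves(path)
        assert back.tiers == layer.tiers
        assert all(
            a.equals_exact(b, 1e-9)
            for a, b in zip(back.geometries, layer.geometries)
        )


class TestSuitability:
    def make_world(self, **kw):
        cfg = small_cfg(**kw)
        checklist = bh.generate_checklist(cfg)
        occ = bh.generate_occurrences(cfg, checklist)
        pm = bh.build_presence(occ, cfg.grid(), species_order=checklist["species_id"])
        return cfg, pm

    def test_current_stack_recovers_occupancy(self):
        cfg, pm = self.make_world()
        cur, _, _ = bh.generate_suitability(cfg, pm)
        np.testing.assert_array_equal(bh.binary_range(cur), pm.occupancy.T)

    def test_total_loss_empties_future_range(self):
        cfg, pm = self.make_world(loss_fractions=1.0, gain_fractions=0.0)
        _, fut, _ = bh.generate_suitability(cfg, pm)
        assert not bh.binary_range(fut).any()
        change = bh.habitat_change(
            pm.occupancy.T, bh.binary_range(fut), pm.species
        )
        assert (change["lsa"] == 1.0).all()
        out = bh.reassess(change, bh.generate_checklist(cfg), "RCP8.5")
        assert (out["projected_category"] == "EX").all()

    def test_zero_change_is_identity(self):
        cfg, pm = self.make_world(loss_fractions=0.0, gain_fractions=0.0)
        cur, fut, _ = bh.generate_suitability(cfg, pm)
        np.testing.assert_array_equal(bh.binary_range(cur), bh.binary_range(fut))

    def test_planted_loss_count(self):
        # deterministic loss on a known range size: 0.65 on A_cur cells
        # drops exactly round(0.65 * A_cur) cells
        cfg, pm = self.make_world(loss_fractions=0.65, gain_fractions=0.0)
        cur, fut, _ = bh.generate_suitability(cfg, pm)
        lost = (bh.binary_range(cur) & ~bh.binary_range(fut)).sum(axis=1)
        a_cur = pm.occupancy.T.sum(axis=1)
        np.testing.assert_array_equal(lost, np.floor(0.65 * a_cur + 0.5))

    def test_planted_low_auc(self):
        cfg, pm = self.make_world(n_low_auc=3)
        _, _, auc = bh.generate_suitability(cfg, pm)
        assert (auc["auc"].iloc[:3] < 0.7).all()
        assert (auc["auc"].iloc[3:] >= 0.7).all()
        kept = bh.auc_filter(auc)
        assert len(kept) == len(pm.species) - 3

    def test_invalid_loss_rejected(self):
        cfg, pm = self.make_world()
        cfg.loss_fractions = 1.5
        with pytest.raises(ConfigurationError):
            bh.generate_suitability(cfg, pm)


class TestEnvLayers:
    def test_perfect_correlation(self):
        cfg = small_cfg(n_env_layers=2, env_corr=1.0)
        env = bh.generate_env_layers(cfg, cfg.grid())
        r = np.corrcoef(env.values[0], env.values[1])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-6)
        assert bh.prune_variables(env) == [env.names[0]]

    def test_independent_layers(self):
        cfg = bh.SyntheticConfig(
            seed=5, n_species=2, extent=(0, 0, 5000, 5000), cell_size=50,
            n_env_layers=2, env_corr=0.0, n_hotspot_clusters=0,
        )
        env = bh.generate_env_layers(cfg, cfg.grid())  # 10,000 cells
        r = np.corrcoef(env.values[0], env.values[1])[0, 1]
        assert abs(r) < 0.05

    def test_target_correlation_recovered(self):
        cfg = small_cfg(n_env_layers=5, env_corr=0.6, extent=(0, 0, 2500, 2500))
        env = bh.generate_env_layers(cfg, cfg.grid())
        rs = np.corrcoef(env.values)
        off = rs[np.triu_indices(5, 1)]
        assert np.allclose(off, 0.6, atol=0.1)

    def test_infeasible_negative_equicorrelation(self):
        cfg = small_cfg(n_env_layers=4, env_corr=-0.9)
        with pytest.raises(ConfigurationError):
            bh.generate_env_layers(cfg, cfg.grid())
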