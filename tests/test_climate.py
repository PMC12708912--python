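"""Variable pruning, model filters, range change and threat reassessment."""

import numpy as np
import pandas as pd
import pytest

import biohotspots as bh


def env_stack(columns: dict[str, list[float]]) -> bh.EnvStack:
    names = list(columns)
    return bh.EnvStack(names, np.array([columns[n] for n in names], dtype=float))


class TestPruneVariables:
    def test_duplicate_dropped(self):
        env = env_stack({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]})
        assert bh.prune_variables(env) == ["a"]

    def test_independent_retained(self):
        env = env_stack({"a": [1, 2, 3, 4], "b": [4, 1, 3, 2]})
        assert bh.prune_variables(env) == ["a", "b"]

    def test_chain_of_identical_layers_keeps_first(self):
        env = env_stack(
            {"a": [1, 2, 3, 4], "b": [1, 2, 3, 4], "c": [1, 2, 3, 4]}
        )
        assert bh.prune_variables(env) == ["a"]

    def test_anticorrelation_counts(self):
        env = env_stack({"a": [1, 2, 3, 4], "b": [4, 3, 2, 1]})
        assert bh.prune_variables(env) == ["a"]

    def test_constant_layer_retained_logged(self, caplog):
        env = env_stack({"a": [1, 2, 3, 4], "k": [5, 5, 5, 5]})
        with caplog.at_level("WARNING"):
            kept = bh.prune_variables(env)
        assert kept == ["a", "k"]
        assert caplog.records

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=50)
        cols = {
            "a": base,
            "b": base + rng.normal(scale=0.05, size=50),
            "c": rng.normal(size=50),
            "d": -base,
        }
        env = env_stack({k: list(v) for k, v in cols.items()})
        kept = bh.prune_variables(env)
        env2 = env_stack({k: list(cols[k]) for k in kept})
        assert bh.prune_variables(env2) == kept


class TestFilters:
    def test_record_count_boundary(self):
        counts = pd.Series({"a": 5, "b": 4, "c": 100})
        assert bh.eligible_species(counts) == ["a", "c"]

    def test_auc_boundary_and_missing(self, caplog):
        table = pd.DataFrame(
            {"species_id": ["a", "b", "c"], "auc": [0.7, 0.69, np.nan]}
        )
        with caplog.at_level("WARNING"):
            kept = bh.auc_filter(table)
        assert kept == ["a"]
        assert caplog.records

    def test_binary_range_strict_threshold(self):
        stack = bh.SuitabilityStack(
            "current", ["a"], np.array([[0.6, 0.61, 0.0]])
        )
        assert bh.binary_range(stack).tolist() == [[False, True, False]]


class TestRangeChange:
    def test_identity_scenario(self):
        rng = np.random.default_rng(0)
        cur = rng.random((5, 20)) < 0.4
        out = bh.richness_and_change(cur, cur)
        assert not out["gain"].any() and not out["loss"].any()
        assert not out["net"].any()
        change = bh.habitat_change(cur, cur, [f"s{i}" for i in range(5)])
        assert (change["change_class"] == "no_change").all()
        assert (change.loc[change["assessable"], "lsa"] == 0).all()

    def test_single_cell_loss(self):
        cur = np.array([[True, True]])
        fut = np.array([[True, False]])
        out = bh.richness_and_change(cur, fut)
        assert out["loss"].tolist() == [0, 1]
        assert out["net"].tolist() == [0, -1]

    def test_conservation_identity_random(self):
        rng = np.random.default_rng(1)
        cur = rng.random((10, 50)) < 0.5
        fut = rng.random((10, 50)) < 0.5
        out = bh.richness_and_change(cur, fut)
        np.testing.assert_array_equal(
            out["richness_fut"], out["richness_cur"] + out["gain"] - out["loss"]
        )

    def test_habitat_change_classes(self):
        # 3 current cells: lose 2 -> contraction, LSA 2/3;
        # gain only -> expansion with LSA 0
        cur = np.array([[1, 1, 1, 0, 0], [1, 1, 0, 0, 0]], dtype=bool)
        fut = np.array([[1, 0, 0, 0, 0], [1, 1, 1, 1, 0]], dtype=bool)
        change = bh.habitat_change(cur, fut, ["a", "b"]).set_index("species_id")
        assert change.loc["a", "change_class"] == "contraction"
        assert change.loc["a", "lsa"] == pytest.approx(2 / 3)
        assert change.loc["b", "change_class"] == "expansion"
        assert change.loc["b", "lsa"] == 0
        assert change.loc["b", "shift_fraction"] == 1.0

    def test_empty_current_range_flagged(self, caplog):
        cur = np.array([[False, False]])
        fut = np.array([[True, False]])
        with caplog.at_level("WARNING"):
            change = bh.habitat_change(cur, fut, ["a"])
        assert not change.iloc[0]["assessable"]
        assert np.isnan(change.iloc[0]["lsa"])


class TestReclassify:
    @pytest.mark.parametrize(
        "lsa, category",
        [
            (1.0, "EX"),
            (0.9, "CR"),
            (0.8, "CR"),
            (0.65, "EN"),
            (0.5, "EN"),
            (0.45, "VU"),
            (0.30, "VU"),
            (0.29, "CC"),
            (0.0, "CC"),
        ],
    )
    def test_band_edges(self, lsa, category):
        assert bh.reclassify_threat("CC", lsa) == category

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh.reclassify_threat("CC", 1.1)

    def test_upgrade_only_for_unthreatened(self, tiny_checklist):
        change = pd.DataFrame(
            {
                "species_id": list("ABCDE"),
                "a_cur": [10] * 5,
                "a_fut": [1] * 5,
                "cells_lost": [9] * 5,
                "cells_gained": [0] * 5,
                "change_class": ["contraction"] * 5,
                "lsa": [0.9] * 5,
                "shift_fraction": [0.9] * 5,
                "assessable": [True] * 5,
            }
        )
        out = bh.reassess(change, tiny_checklist, "RCP8.5")
        out = out.set_index("species_id")
        assert (out["projected_category"] == "CR").all()
        # A (CR) and B, E (VU/EN) are already threatened: no upgrade flag
        assert out["upgraded"].tolist() == [False, False, True, True, False]


class TestImpactSummary:
    def test_counts_and_percentages(self, tiny_checklist):
        change = pd.DataFrame(
            {
                "species_id": list("ABCDE"),
                "a_cur": [10, 10, 10, 10, 0],
                "a_fut": [10, 5, 10, 2, 3],
                "cells_lost": [0, 5, 0, 9, 0],
                "cells_gained": [0, 0, 0, 1, 3],
                "change_class": [
                    "no_change", "contraction", "no_change", "contraction",
                    "expansion",
                ],
                "lsa": [0.0, 0.5, 0.0, 0.9, np.nan],
                "shift_fraction": [0.0, 0.5, 0.0, 1.0, np.nan],
                "assessable": [True, True, True, True, False],
            }
        )
        out = bh.reassess(change, tiny_checklist, "RCP2.6")
        summary = bh.impact_summary(out, n_total=5)
        assert summary["n_assessed"] == 4
        # D is a CC species projected CR: the only upgrade cross-cell
        assert summary["upgrade_counts"].loc["CC", "CR"] == 1
        assert summary["upgrade_pct"].loc["CC", "CR"] == 20.0
        assert summary["n_upgraded"] == 1
        assert summary["change_proportions"]["contraction"] == 0.5
        assert summary["lsa_over_30"] == 2
        assert summary["lsa_over_60"] == 1
        assert summary["shift_over_60"] == 1

    def test_all_no_change_is_all_zero(self, tiny_checklist):
        cur = np.ones((5, 4), dtype=bool)
        change = bh.habitat_change(cur, cur, list("ABCDE"))
        out = bh.reassess(change, tiny_checklist, "RCP2.6")
        summary = bh.impact_summary(out, n_total=5)
        assert summary["n_upgraded"] == 0
        # only the NT/CC species (C, D) appear in the cross table; both
        # stay in the CC band
        assert summary["upgrade_counts"].to_numpy().sum() == 2
        assert (summary["upgrade_counts"][["EX", "CR", "EN", "VU"]].to_numpy() == 0).all()
        assert summary["change_proportions"]["contraction"] == 0
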