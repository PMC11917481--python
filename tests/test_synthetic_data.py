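"""Ground-truth generators: determinism and post-condition recovery."""

import numpy as np
import pandas as pd
import pytest

from slrpev import cluster_evolution as ce
from slrpev import expression as ex
from slrpev import motif as mt
from slrpev import synthetic_data as sd


class TestClusterSimulation:
    def test_zero_rates_give_full_clusters(self, history):
        tables, scenario = sd.simulate_cluster_family(sd.ClusterSimConfig(seed=7))
        assert scenario.events == ()
        for tip in "ABCD":
            names = [g.name for g in tables[tip] if g.family == "slrp"]
            assert names == [f"{tip}_c{i}" for i in (1, 2, 3, 4)]

    def test_canonical_preset_tip_compositions(self):
        tables, _ = sd.simulate_cluster_family(
            sd.ClusterSimConfig(seed=0), scenario=ce.canonical_scenario()
        )
        comp = {
            tip: {g.name.split("_", 1)[1] for g in loci if g.family == "slrp"}
            for tip, loci in tables.items()
        }
        assert comp["A"] == {"c1", "c2", "c3b", "c4"}
        assert comp["B"] == {"c1", "c2"}
        assert comp["C"] == {"c1", "c2", "c3a", "c3b", "c4"}
        assert comp["D"] == {"c2", "c3a", "c3a'", "c3b", "c4"}

    def test_same_seed_identical_output(self):
        cfg = sd.ClusterSimConfig(seed=1, dup_rate=0.5, loss_rate=0.5)
        t1, s1 = sd.simulate_cluster_family(cfg)
        t2, s2 = sd.simulate_cluster_family(cfg)
        assert s1 == s2 and t1 == t2

    @pytest.mark.parametrize("seed", range(8))
    def test_tables_equal_replay_of_emitted_scenario(self, history, seed):
        cfg = sd.ClusterSimConfig(seed=seed, dup_rate=0.6, loss_rate=0.4)
        tables, scenario = sd.simulate_cluster_family(cfg)
        comp = ce.replay(scenario, history)
        for tip in history.tips:
            names = [
                g.name.split("_", 1)[1]
                for g in tables[tip]
                if g.family == "slrp"
            ]
            assert tuple(names) == comp[tip]

    def test_coordinates_one_based_ordered_with_gaps(self):
        cfg = sd.ClusterSimConfig(seed=0, gene_length=1000, intergene_gap=500)
        tables, _ = sd.simulate_cluster_family(cfg)
        genes = [g for g in tables["A"] if g.family == "slrp"]
        assert genes[0].start == 1
        for prev, nxt in zip(genes, genes[1:]):
            assert nxt.start - prev.end - 1 == 500

    def test_anchor_neighbor_planted(self):
        tables, _ = sd.simulate_cluster_family(sd.ClusterSimConfig(seed=0))
        for loci in tables.values():
            assert any(g.family == "neighbor" for g in loci)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            sd.ClusterSimConfig(dup_rate=-1)


class TestProteins:
    def test_none_mode_no_hits_either_pattern(self):
        seq = sd.generate_lrr_protein(0, "none", seed=0)
        assert mt.scan(mt.STANDARD_LRRCE, seq) == []
        assert mt.scan(mt.RELAXED_LRRCE, seq) == []

    def test_standard_mode_has_standard_motif(self):
        seq = sd.generate_lrr_protein(6, "standard", seed=1)
        assert mt.has_lrrce(seq, "standard")[0]

    def test_relaxed_mode_breaks_standard_tail_only(self):
        """An 11-residue C-terminal spacer satisfies X(8,12)-C but cannot
        satisfy X(8,9)-[FYMPVAIS]-X-C."""
        seq = sd.generate_lrr_protein(6, "relaxed", seed=2)
        assert not mt.has_lrrce(seq, "standard")[0]
        assert mt.has_lrrce(seq, "relaxed")[0]

    def test_deterministic(self):
        assert sd.generate_lrr_protein(4, "standard", seed=9) == (
            sd.generate_lrr_protein(4, "standard", seed=9)
        )

    def test_negative_lrr_rejected(self):
        with pytest.raises(ValueError):
            sd.generate_lrr_protein(-1, "standard")


class TestExpressionGenerator:
    def test_noise_free_enriched_cell_is_row_maximum(self):
        spec = sd.ExpressionSpec(
            n_genes=3, n_samples=5, enriched=((0, 2, 10.0),), noise_cv=0.0
        )
        matrix, mask = sd.generate_expression_matrix(spec, seed=0)
        assert matrix.iloc[0].idxmax() == matrix.columns[2]
        assert mask.iloc[0, 2] and mask.to_numpy().sum() == 1

    def test_noise_free_unenriched_rows_have_zero_z(self):
        spec = sd.ExpressionSpec(n_genes=4, n_samples=5, noise_cv=0.0)
        matrix, _ = sd.generate_expression_matrix(spec, seed=1)
        with pytest.warns(UserWarning):
            z = ex.zscores(matrix)
        assert (z.to_numpy() == 0).all()

    def test_default_shape_matches_packaged_panel(self):
        matrix, _ = sd.generate_expression_matrix(sd.ExpressionSpec(), seed=0)
        assert matrix.shape == (21, 13)

    def test_mask_recovered_at_zero_noise(self):
        spec = sd.ExpressionSpec(
            n_genes=6,
            n_samples=6,
            enriched=((0, 1, 20.0), (3, 4, 20.0)),
            noise_cv=0.0,
        )
        matrix, mask = sd.generate_expression_matrix(spec, seed=3)
        calls = ex.classify_enrichment(matrix)
        called = set(
            map(tuple, calls[calls.category != "none"][["gene", "sample"]].values)
        )
        planted = {
            (matrix.index[g], matrix.columns[s])
            for g, s in zip(*np.nonzero(mask.to_numpy()))
        }
        assert called == planted

    def test_matrix_non_negative(self):
        spec = sd.ExpressionSpec(n_genes=5, n_samples=4, noise_cv=1.0)
        matrix, _ = sd.generate_expression_matrix(spec, seed=4)
        assert (matrix.to_numpy() >= 0).all()

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            sd.ExpressionSpec(n_samples=2)
        with pytest.raises(ValueError):
            sd.ExpressionSpec(enriched=((0, 0, 1.0),))


class TestQpcrGenerator:
    def test_known_folds_recovered_exactly_at_zero_noise(self):
        spec = sd.QpcrSpec(folds=(("a", 1.0), ("b", 2.0), ("c", 4.0)))
        cp = sd.generate_qpcr_table(spec, seed=0)
        folds = ex.qpcr_normalize(cp, "target")
        assert np.allclose(folds.loc[["a", "b", "c"]], [1.0, 2.0, 4.0])

    def test_all_unit_folds(self):
        spec = sd.QpcrSpec(folds=(("a", 1.0), ("b", 1.0), ("c", 1.0)))
        cp = sd.generate_qpcr_table(spec, seed=1)
        assert np.allclose(ex.qpcr_normalize(cp, "target"), 1.0)

    def test_deterministic(self):
        spec = sd.QpcrSpec(noise_sd=0.2)
        pd.testing.assert_frame_equal(
            sd.generate_qpcr_table(spec, seed=5),
            sd.generate_qpcr_table(spec, seed=5),
        )

    def test_reference_point_required(self):
        with pytest.raises(ValueError):
            sd.QpcrSpec(folds=(("a", 2.0), ("b", 4.0)))


class TestObservedFamilyBridge:
    def test_groups_are_true_lineages(self):
        tables, scenario = sd.simulate_cluster_family(
            sd.ClusterSimConfig(seed=3, dup_rate=0.5, loss_rate=0.3)
        )
        family = sd.observed_family_from_tables(tables)
        observed_lineages = set(family.orthology_groups)
        comp = ce.replay(scenario, ce.default_2r_tree())
        surviving = {lin for tip in "ABCD" for lin in comp[tip]}
        assert observed_lineages == surviving
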