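import numpy as np
import pandas as pd
import pytest

from rnscore import deg, synthdata
from rnscore.errors import ParameterError


class TestSynthExpression:
    def test_same_seed_is_bit_identical(self):
        a, pa = synthdata.synth_expression(n_genes=50, n_tumor=6, n_normal=6,
                                           n_deg=5, seed=11)
        b, pb = synthdata.synth_expression(n_genes=50, n_tumor=6, n_normal=6,
                                           n_deg=5, seed=11)
        pd.testing.assert_frame_equal(a.values, b.values)
        assert pa == pb

    def test_planted_degs_recovered_at_high_effect(self):
        recovered = []
        for seed in range(10):
            ds, planted = synthdata.synth_expression(
                n_genes=300, n_tumor=40, n_normal=40, n_deg=10,
                effect_sd=3.0, seed=seed)
            found = deg.filter_degs(deg.test_all_genes(ds))
            recovered.append(len(found & planted) / len(planted))
        assert np.mean(recovered) >= 0.95

    def test_null_effect_yields_few_degs(self):
        counts = []
        for seed in range(5):
            ds, planted = synthdata.synth_expression(
                n_genes=400, n_tumor=30, n_normal=30, n_deg=10,
                effect_sd=0.0, seed=seed)
            found = deg.filter_degs(deg.test_all_genes(ds))
            counts.append(len(found))
        assert np.mean(counts) <= 0.05 * 400

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            synthdata.synth_expression(n_genes=0)
        with pytest.raises(ParameterError):
            synthdata.synth_expression(n_genes=10, n_deg=11)


class TestSynthNetwork:
    def test_planted_targets_have_moderate_degree(self):
        genes = [f"G{i:04d}" for i in range(300)]
        targets = genes[:6]
        edges = synthdata.synth_network(genes, targets, seed=4,
                                        core_genes=genes[:40])
        net = synthdata.network_from_frame(edges, 0.9)
        for t in targets:
            assert 2 <= net.graph.degree[t] <= 5

    def test_heavy_tailed_degree_distribution(self):
        genes = [f"G{i:04d}" for i in range(1000)]
        edges = synthdata.synth_network(genes, seed=9)
        net = synthdata.network_from_frame(edges, 0.0)
        degrees = np.array([d for _, d in net.graph.degree])
        assert degrees.max() > 3 * np.median(degrees)

    def test_confidences_in_string_high_band(self):
        genes = [f"G{i:04d}" for i in range(100)]
        edges = synthdata.synth_network(genes, seed=2)
        assert (edges["combined_score"] >= 0.9).all()
        assert (edges["combined_score"] <= 1.0).all()

    def test_same_seed_identical_edges(self):
        genes = [f"G{i:04d}" for i in range(120)]
        a = synthdata.synth_network(genes, genes[:4], seed=5, core_genes=genes[:20])
        b = synthdata.synth_network(genes, genes[:4], seed=5, core_genes=genes[:20])
        pd.testing.assert_frame_equal(a, b)


class TestSynthSurvival:
    def test_censoring_fraction_approximate(self):
        table = synthdata.synth_survival(n_patients=2000, censor_frac=0.3, seed=1)
        frac = 1 - table.events.mean()
        assert frac == pytest.approx(0.3, abs=0.05)

    def test_no_censoring_all_events(self):
        table = synthdata.synth_survival(n_patients=100, censor_frac=0.0, seed=2)
        assert table.events.sum() == 100

    def test_hazard_shortens_high_expression_survival(self):
        table = synthdata.synth_survival(
            n_patients=2000, prognostic_genes=("g",), hazard_ratio=3.0,
            censor_frac=0.0, seed=3)
        expr = table.data["g"].to_numpy()
        high = expr > np.median(expr)
        ratio = table.times[~high].mean() / table.times[high].mean()
        assert ratio == pytest.approx(3.0, rel=0.25)

    def test_times_strictly_positive(self):
        table = synthdata.synth_survival(n_patients=500, censor_frac=0.5, seed=4)
        assert (table.times > 0).all()


class TestSynthStructure:
    def test_helix_contact_graph_connected(self):
        from rnscore import gnm

        s = synthdata.synth_structure(20, "helix")
        res = gnm.gnm_analyze(s, cutoff=7.3)
        assert res.n_zero_modes == 1

    def test_dumbbell_lobes_only_touch_via_linker(self):
        import numpy as np

        n = 21
        s = synthdata.synth_structure(n, "dumbbell")
        linker = synthdata.dumbbell_linker_index(n)
        from scipy.spatial.distance import cdist

        lobe1, lobe2 = s.coords[:linker], s.coords[linker + 1:]
        assert cdist(lobe1, lobe2).min() > 7.3
        assert np.linalg.norm(s.coords[linker] - lobe1[-1]) <= 7.3
        assert np.linalg.norm(s.coords[linker] - lobe2[0]) <= 7.3

    def test_coil_determinism_and_bond_length(self):
        a = synthdata.synth_structure(30, "coil", seed=8)
        b = synthdata.synth_structure(30, "coil", seed=8)
        np.testing.assert_array_equal(a.coords, b.coords)
        bonds = np.linalg.norm(np.diff(a.coords, axis=0), axis=1)
        np.testing.assert_allclose(bonds, 3.8, atol=1e-9)


class TestSynthStudy:
    def test_ground_truth_nesting_and_determinism(self):
        a = synthdata.synth_study(n_genes=200, n_deg=16, n_targets=4,
                                  dataset_sizes=((10, 10), (8, 8)), seed=21)
        b = synthdata.synth_study(n_genes=200, n_deg=16, n_targets=4,
                                  dataset_sizes=((10, 10), (8, 8)), seed=21)
        assert a.planted_targets <= a.planted_degs
        assert a.planted_degs <= set(a.datasets[0].gene_ids)
        assert a.planted_targets == b.planted_targets
        pd.testing.assert_frame_equal(a.edges, b.edges)
        pd.testing.assert_frame_equal(a.datasets[0].values, b.datasets[0].values)

    def test_study_pieces_are_consistent(self):
        study = synthdata.synth_study(n_genes=200, n_deg=16, n_targets=4,
                                      dataset_sizes=((10, 10), (8, 8)), seed=22)
        assert set(study.structures) == study.planted_targets
        for t in sorted(study.planted_targets):
            assert t in study.survival.gene_ids
            assert 2 <= study.network.graph.degree[t] <= 5
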