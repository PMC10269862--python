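"""Synthetic-data generators: determinism, planted truth, censoring."""

import numpy as np
import pandas as pd
import pytest

from flymgwa import (
    SimConfig,
    plant_effects,
    simulate_annotation,
    simulate_cfu,
    simulate_pangenome,
    simulate_similarity_graph,
)
from flymgwa.simulate import (
    SimTruth,
    SimulationError,
    sample_coalescent_tree,
    simulate_all,
    stage_rng,
    synthetic_partition,
)


class TestSimulatePangenome:
    def test_all_core_gives_all_ones(self):
        config = SimConfig(n_strains=4, n_ogs=10, core_fraction=1.0, seed=0)
        matrix, _ = simulate_pangenome(config)
        assert matrix.data.shape == (10, 4)
        assert (matrix.data.to_numpy() == 1).all()

    def test_zero_rate_freezes_root_state(self):
        config = SimConfig(
            n_strains=10, n_ogs=50, core_fraction=0.0, gain_loss_rate=0.0, seed=5
        )
        matrix, _ = simulate_pangenome(config)
        freqs = matrix.frequencies()
        assert set(freqs.unique()) <= {0.0, 1.0}

    def test_same_seed_byte_identical(self, tmp_path):
        config = SimConfig(n_strains=10, n_ogs=100, seed=42)
        m1, t1 = simulate_pangenome(config)
        m2, t2 = simulate_pangenome(config)
        pd.testing.assert_frame_equal(m1.data, m2.data)
        assert t1.newick() == t2.newick()
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        m1.to_tsv(p1)
        m2.to_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_matches_independent_gain_loss_reimplementation(self):
        """Oracle: a plain recursive gain/loss walk, replaying the documented
        RNG order (stationary probabilities, root draw, then one keep and
        one redraw vector per branch, preorder, children in creation
        order), must reproduce the accessory block bit for bit."""
        import math

        config = SimConfig(
            n_strains=12, n_ogs=80, core_fraction=0.25, gain_loss_rate=0.5, seed=9
        )
        matrix, _ = simulate_pangenome(config)
        n_core = int(round(config.core_fraction * config.n_ogs))
        n_acc = config.n_ogs - n_core

        rng = stage_rng(config.seed, "pangenome")
        tree = sample_coalescent_tree(config.n_strains, rng)
        from flymgwa.simulate import STATIONARY_BETA

        pi = rng.beta(STATIONARY_BETA, STATIONARY_BETA, size=n_acc)
        states = np.zeros((n_acc, config.n_strains), dtype=bool)

        def walk(node, state):
            if node < tree.n_leaves:
                states[:, node] = state
                return
            for child, length in tree.children[node]:
                keep = rng.random(n_acc) < math.exp(-config.gain_loss_rate * length)
                redraw = rng.random(n_acc) < pi
                walk(child, np.where(keep, state, redraw))

        walk(tree.root, rng.random(n_acc) < pi)
        expected = matrix.data.to_numpy()[n_core:].astype(bool)
        assert (states == expected).all()

    @pytest.mark.parametrize("rate", [0.5, 1.0])
    def test_accessory_frequency_spectrum_is_u_shaped(self, rate):
        config = SimConfig(
            n_strains=40, n_ogs=1000, core_fraction=0.5, gain_loss_rate=rate, seed=1
        )
        matrix, _ = simulate_pangenome(config)
        freqs = matrix.frequencies().to_numpy()[500:]
        edges = ((freqs < 0.1) | (freqs > 0.9)).sum()
        middle = ((freqs >= 0.4) & (freqs <= 0.6)).sum()
        assert edges > middle

    def test_invalid_config_rejected(self):
        with pytest.raises(SimulationError):
            simulate_pangenome(SimConfig(core_fraction=1.5))


class TestPlantEffects:
    def test_no_causal_means_only_noise(self):
        config = SimConfig(n_strains=10, n_ogs=50, n_causal=0, strain_sd=0.5, seed=2)
        matrix, _ = simulate_pangenome(config)
        truth = plant_effects(matrix, config)
        assert truth.causal_ogs == set()
        spread = np.std(list(truth.strain_means.values()))
        assert spread < 4 * config.strain_sd

    def test_single_causal_zero_noise_shift_is_exact(self):
        config = SimConfig(
            n_strains=12, n_ogs=200, n_causal=1, effect_size=4.0,
            strain_sd=0.0, seed=3,
        )
        matrix, _ = simulate_pangenome(config)
        truth = plant_effects(matrix, config)
        (og,) = truth.causal_ogs
        carriers = matrix.data.loc[og].astype(bool)
        means = pd.Series(truth.strain_means)
        shift = means[carriers.values].mean() - means[~carriers.values].mean()
        assert shift == pytest.approx(4.0)

    def test_causal_frequencies_mid_range_and_both_signs(self):
        config = SimConfig(n_strains=24, n_ogs=400, n_causal=5, seed=7)
        matrix, _ = simulate_pangenome(config)
        truth = plant_effects(matrix, config)
        assert len(truth.causal_ogs) == 5
        freqs = matrix.frequencies()
        for og in truth.causal_ogs:
            assert 0.2 <= freqs[og] <= 0.8
        signs = {np.sign(e) for e in truth.causal_effects.values()}
        assert signs == {1.0, -1.0}

    def test_too_few_mid_frequency_patterns_rejected(self):
        config = SimConfig(n_strains=6, n_ogs=4, core_fraction=1.0, n_causal=2, seed=0)
        matrix, _ = simulate_pangenome(config)
        with pytest.raises(SimulationError, match="n_ogs"):
            plant_effects(matrix, config)


class TestSimulateCfu:
    def test_mean_above_ceiling_censors_every_fly(self):
        config = SimConfig(n_strains=2, n_ogs=10, n_causal=0, fly_sd=0.0, seed=0)
        truth = SimTruth(
            strain_means={"S01": np.log2(128_001.0), "S02": np.log2(128_001.0)}
        )
        records = simulate_cfu(truth, config)
        assert records["too_dense"].all()

    def test_zero_mean_zero_sd_gives_zero_counts(self):
        config = SimConfig(n_strains=2, n_ogs=10, fly_sd=0.0, contamination_prob=0.0)
        truth = SimTruth(strain_means={"S01": 0.0, "S02": 0.0})
        records = simulate_cfu(truth, config)
        assert (records["colony_count"] == 0).all()
        assert not records["too_dense"].any()

    def test_censoring_flag_consistent(self, small_sim):
        config, *_, records = small_sim
        over = records["colony_count"] > config.ceiling_colonies
        assert not (over & ~records["too_dense"]).any()

    def test_strain_means_recovered_within_three_sem(self):
        # strain means are kept well above the colony quantization scale
        # (1 colony = 800 CFU ~ 9.6 on the log2 scale) and well below the
        # censoring ceiling, so neither rounding nor censoring biases the
        # comparison and the sampling-error bound applies
        config = SimConfig(
            n_strains=20, n_ogs=300, n_causal=2, effect_size=1.0,
            baseline_log_cfu=13.5, strain_sd=0.3, fly_sd=0.8,
            contamination_prob=0.0, seed=3,
        )
        matrix, _ = simulate_pangenome(config)
        truth = plant_effects(matrix, config)
        records = simulate_cfu(truth, config)
        n_flies = (
            config.n_experiments
            * config.n_vials_per_experiment
            * config.n_flies_per_vial
        )
        sem = config.fly_sd / np.sqrt(n_flies)
        observed = (
            np.log2(
                np.where(
                    records["too_dense"], 128_000, records["colony_count"] * 800
                )
                + 1.0
            )
        )
        records = records.assign(log_cfu=observed)
        per_strain = records.groupby("strain")["log_cfu"].mean()
        # small extra margin for colony-count rounding
        for strain, value in per_strain.items():
            assert abs(value - truth.strain_means[strain]) < 3 * sem + 0.1

    def test_deterministic_records(self, small_sim):
        config, *_ , _records = small_sim
        matrix, _ = simulate_pangenome(config)
        truth = plant_effects(matrix, config)
        r1 = simulate_cfu(truth, config)
        r2 = simulate_cfu(truth, config)
        pd.testing.assert_frame_equal(r1, r2)


class TestSimilarityGraph:
    def test_noise_free_graph_is_union_of_cliques(self):
        partition = synthetic_partition(4, 4)
        edges = simulate_similarity_graph(partition, seed=1, p_noise=0.0)
        assert len(edges) == 4 * 6  # C(4,2) per group
        assert (edges["weight"] >= 0.7).all()

    def test_three_protein_group_has_three_edges(self):
        partition = {"a|p1": "OG1", "b|p2": "OG1", "c|p3": "OG1"}
        edges = simulate_similarity_graph(partition, seed=0, p_noise=0.0)
        assert len(edges) == 3

    def test_noise_edges_are_weak_and_cross_group(self):
        partition = synthetic_partition(20, 5)
        edges = simulate_similarity_graph(partition, seed=2, p_noise=0.05)
        weak = edges[edges["weight"] < 0.7]
        assert len(weak) > 0
        for row in weak.itertuples():
            assert partition[row.source] != partition[row.target]
            assert row.weight <= 0.2

    def test_deterministic(self):
        partition = synthetic_partition(10, 4)
        e1 = simulate_similarity_graph(partition, seed=3)
        e2 = simulate_similarity_graph(partition, seed=3)
        pd.testing.assert_frame_equal(e1, e2)


class TestSimulateAnnotation:
    def test_each_og_at_most_one_ko_one_pathway(self):
        ogs = [f"OG_{i:04d}" for i in range(1, 101)]
        table, planted = simulate_annotation(ogs, ogs[:10], n_pathways=10, seed=4)
        assert table["og_id"].is_unique
        assert table["ko_id"].is_unique
        assert planted == "map00001"
        assert table["pathway_id"].nunique() <= 10

    def test_planted_pathway_overloaded_with_significant_ogs(self):
        ogs = [f"OG_{i:04d}" for i in range(1, 501)]
        significant = set(ogs[:50])
        table, planted = simulate_annotation(
            ogs, significant, n_pathways=10, seed=4, odds_ratio=10.0
        )
        in_planted = table[table["pathway_id"] == planted]
        sig_rate_in = in_planted["og_id"].isin(significant).mean()
        background_rate = table["og_id"].isin(significant).mean()
        assert sig_rate_in > 2 * background_rate

    def test_significant_not_subset_rejected(self):
        with pytest.raises(SimulationError):
            simulate_annotation(["OG1"], ["OG2"], seed=0)


def test_simulate_all_writes_complete_input_set(tmp_path):
    config = SimConfig(n_strains=8, n_ogs=60, seed=6)
    truth = simulate_all(config, tmp_path)
    for name in (
        "cfu_records.tsv", "similarity.abc", "groups.txt",
        "annotation.tsv", "tree.nwk", "truth.json",
    ):
        assert (tmp_path / name).exists(), name
    assert truth.enriched_pathways == {"map00001"}
    assert len(truth.causal_ogs) == config.n_causal
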