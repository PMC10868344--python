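"""Generator tests: topology, planted signals, missingness, determinism."""

import re

import numpy as np
import pytest
from scipy import stats

import helpers
from ppibench import features, goldstandard, synthetic
from ppibench.core import ConfigurationError
from ppibench.synthetic import FACETS, MOTIF_DICTIONARY, SyntheticConfig


random_pairs = helpers.random_pairs
mean_jaccard = helpers.mean_facet_jaccard


class TestNetwork:
    def test_minimal_attachment_graph(self):
        cfg = SyntheticConfig(n_proteins=3, n_edges_per_new_node=1, seed=0)
        edges, degrees = synthetic.generate_network(cfg)
        assert len(edges) == 2
        assert (degrees >= 1).all()

    @pytest.mark.parametrize("n,m", [(1, 1), (5, 5), (5, 0)])
    def test_invalid_size_raises_naming_field(self, n, m):
        cfg = SyntheticConfig(n_proteins=n, n_edges_per_new_node=m)
        with pytest.raises(ConfigurationError, match="n_proteins|n_edges_per_new_node"):
            synthetic.generate_network(cfg)

    def test_heavy_tail_top20_share(self):
        cfg = SyntheticConfig(n_proteins=2000, n_edges_per_new_node=2, seed=1)
        edges, degrees = synthetic.generate_network(cfg)
        hubs = goldstandard.hub_set(degrees, 0.20)
        share = goldstandard.endpoint_share(edges, hubs)
        assert share > 0.5

    def test_heavier_tail_than_erdos_renyi(self):
        """Preferential attachment concentrates edges on hubs well beyond an
        equal-density random graph."""
        cfg = SyntheticConfig(n_proteins=1000, n_edges_per_new_node=2, seed=3)
        edges, degrees = synthetic.generate_network(cfg)
        hubs = goldstandard.hub_set(degrees, 0.20)
        ba_share = goldstandard.endpoint_share(edges, hubs)
        er_share = helpers.er_top_share(1000, len(edges), seed=3)
        assert ba_share > er_share

    def test_deterministic_given_seed(self):
        cfg = SyntheticConfig(n_proteins=300, seed=9)
        e1, d1 = synthetic.generate_network(cfg)
        e2, d2 = synthetic.generate_network(cfg)
        assert e1 == e2 and (d1 == d2).all()
        e3, _ = synthetic.generate_network(SyntheticConfig(n_proteins=300, seed=10))
        assert e1 != e3


class TestAnnotations:
    def test_facet_missingness_matches_configured_rates(self):
        universe = synthetic.generate_universe(SyntheticConfig(seed=21))
        for facet, rate in (("domain", 0.58), ("motif", 0.89)):
            empty = np.mean([p.facet_terms(facet) is None for p in universe.proteins])
            assert abs(empty - rate) < 0.03
        for facet in ("biological_process", "cellular_compartment", "molecular_function"):
            assert all(p.facet_terms(facet) is not None for p in universe.proteins)

    def test_hub_annotation_inflation(self):
        cfg = SyntheticConfig(
            fg_signal=0.0,
            hub_annotation_inflation=3.0,
            missing_rate_per_facet=helpers.zero_missing(),
            seed=4,
        )
        edges, degrees = synthetic.generate_network(cfg)
        annotations, truth = synthetic.generate_annotations(edges, degrees, cfg)
        hubs = truth["hubs"]
        hub_counts = [len(annotations[p]["biological_process"]) for p in hubs]
        lone_counts = [
            len(annotations[p]["biological_process"])
            for p in annotations
            if p not in hubs
        ]
        assert np.mean(hub_counts) == pytest.approx(3 * np.mean(lone_counts), rel=0.05)

    def test_no_signal_means_no_jaccard_gap(self):
        cfg = SyntheticConfig(
            fg_signal=0.0,
            hub_annotation_inflation=1.0,
            missing_rate_per_facet=helpers.zero_missing(),
            seed=5,
        )
        edges, degrees = synthetic.generate_network(cfg)
        annotations, _ = synthetic.generate_annotations(edges, degrees, cfg)
        rng = np.random.default_rng(5)
        pos = mean_jaccard(edges[:1000], annotations)
        rand = mean_jaccard(random_pairs(list(degrees.index), 1000, rng), annotations)
        gap = pos.mean() - rand.mean()
        se = np.sqrt(pos.var() / pos.size + rand.var() / rand.size)
        assert abs(gap) < 4 * se

    def test_planted_signal_separates_positive_pairs(self):
        cfg = SyntheticConfig(
            fg_signal=0.9,
            hub_annotation_inflation=1.0,
            missing_rate_per_facet=helpers.zero_missing(),
            seed=5,
        )
        edges, degrees = synthetic.generate_network(cfg)
        annotations, _ = synthetic.generate_annotations(edges, degrees, cfg)
        rng = np.random.default_rng(5)
        pos = mean_jaccard(edges[:1000], annotations)
        rand = mean_jaccard(random_pairs(list(degrees.index), 1000, rng), annotations)
        assert stats.mannwhitneyu(pos, rand, alternative="greater").pvalue < 0.01

    def test_jaccard_gap_monotone_in_signal(self):
        gaps = []
        for signal in (0.0, 0.3, 0.6, 0.9):
            cfg = SyntheticConfig(
                fg_signal=signal,
                hub_annotation_inflation=1.0,
                missing_rate_per_facet=helpers.zero_missing(),
                seed=6,
            )
            edges, degrees = synthetic.generate_network(cfg)
            annotations, _ = synthetic.generate_annotations(edges, degrees, cfg)
            rng = np.random.default_rng(6)
            pos = mean_jaccard(edges[:1000], annotations)
            rand = mean_jaccard(random_pairs(list(degrees.index), 1000, rng), annotations)
            gaps.append(pos.mean() - rand.mean())
        assert all(b >= a for a, b in zip(gaps, gaps[1:]))


class TestExpression:
    def test_noise_free_co_module_profiles_perfectly_correlated(self):
        cfg = SyntheticConfig(n_proteins=200, expr_noise_sd=0.0, seed=7)
        edges, _ = synthetic.generate_network(cfg)
        expr, truth = synthetic.generate_expression(edges, cfg)
        modules = truth["modules"]
        same = [
            (a, b) for a, b in edges if modules[a] == modules[b]
        ]
        a, b = same[0]
        rho, miss = features.expression_correlation(
            expr.loc[a].to_numpy(), expr.loc[b].to_numpy()
        )
        assert miss == 0 and rho == pytest.approx(1.0)

    def test_extreme_noise_destroys_correlation(self):
        # enough conditions that a null Spearman rho concentrates near zero
        cfg = SyntheticConfig(
            n_proteins=600, expr_noise_sd=100.0, expr_n_conditions=100, seed=7
        )
        edges, _ = synthetic.generate_network(cfg)
        expr, truth = synthetic.generate_expression(edges, cfg)
        modules = truth["modules"]
        same = [(a, b) for a, b in edges if modules[a] == modules[b]][:500]
        rhos = [
            features.expression_correlation(expr.loc[a].to_numpy(), expr.loc[b].to_numpy())[0]
            for a, b in same
        ]
        assert np.mean(np.abs(rhos)) < 0.1

    def test_single_condition_flags_missing_downstream(self):
        cfg = SyntheticConfig(n_proteins=50, expr_n_conditions=1, seed=7)
        edges, _ = synthetic.generate_network(cfg)
        expr, _ = synthetic.generate_expression(edges, cfg)
        a, b = expr.index[0], expr.index[1]
        rho, miss = features.expression_correlation(
            expr.loc[a].to_numpy(), expr.loc[b].to_numpy()
        )
        assert (rho, miss) == (0.0, 1)


class TestSequences:
    def test_alphabet_is_canonical_amino_acids(self):
        cfg = SyntheticConfig(n_proteins=100, seed=8)
        edges, _ = synthetic.generate_network(cfg)
        seqs, _ = synthetic.generate_sequences(edges, cfg)
        pattern = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")
        assert all(pattern.match(s) for s in seqs.values())

    def test_full_motif_signal_plants_lock_key_in_every_pair(self):
        cfg = SyntheticConfig(n_proteins=150, motif_signal=1.0, seed=8)
        edges, _ = synthetic.generate_network(cfg)
        seqs, truth = synthetic.generate_sequences(edges, cfg)
        assert set(truth["planted_motifs"]) == set(edges)
        for a, b in edges:
            assert features.motif_cooccurrence(seqs[a], seqs[b]).any()

    def test_zero_motif_signal_plants_nothing(self):
        cfg = SyntheticConfig(n_proteins=150, motif_signal=0.0, seed=8)
        edges, _ = synthetic.generate_network(cfg)
        _, truth = synthetic.generate_sequences(edges, cfg)
        assert truth["planted_motifs"] == {}

    def test_active_subset_differs_between_universes(self):
        cfg_a = SyntheticConfig(n_proteins=100, seed=31)
        cfg_b = SyntheticConfig(n_proteins=100, seed=32)
        edges_a, _ = synthetic.generate_network(cfg_a)
        edges_b, _ = synthetic.generate_network(cfg_b)
        _, truth_a = synthetic.generate_sequences(edges_a, cfg_a)
        _, truth_b = synthetic.generate_sequences(edges_b, cfg_b)
        assert truth_a["active_motifs"] != truth_b["active_motifs"]

    def test_motif_dictionary_shape(self):
        assert len(MOTIF_DICTIONARY) == 16
        assert all(len(lock) == 6 and len(key) == 6 for lock, key in MOTIF_DICTIONARY)


class TestUniverse:
    def test_bit_identical_under_same_seed(self):
        cfg = SyntheticConfig(n_proteins=200, seed=12)
        u1 = synthetic.generate_universe(cfg)
        u2 = synthetic.generate_universe(cfg)
        assert u1.positive_pairs == u2.positive_pairs
        for p1, p2 in zip(u1.proteins, u2.proteins):
            assert p1.sequence == p2.sequence
            assert p1.annotations == p2.annotations
            assert np.array_equal(p1.expression, p2.expression)

    def test_no_self_pairs_and_ids_resolve(self, default_universe):
        ids = set(default_universe.protein_ids)
        for a, b in default_universe.positive_pairs:
            assert a != b and a < b
            assert a in ids and b in ids

    def test_config_roundtrip_and_validation_messages(self):
        cfg = SyntheticConfig(seed=3)
        assert SyntheticConfig.from_json(cfg.to_json()) == cfg
        with pytest.raises(ConfigurationError, match="fg_signal"):
            SyntheticConfig(fg_signal=1.5).validate()
        with pytest.raises(ConfigurationError, match="seq_length_range"):
            SyntheticConfig(seq_length_range=(300, 80)).validate()

    def test_write_universe_artifacts(self, tmp_path, default_universe):
        paths = synthetic.write_universe(default_universe, tmp_path)
        assert paths["sequences"].exists()
        fasta = paths["sequences"].read_text()
        assert fasta.startswith(">P00000")
        annotations = paths["annotations"].read_text().splitlines()
        assert annotations[0] == "protein_id\tfacet\tterm"
        cfg = synthetic.SyntheticConfig.from_json(paths["config"].read_text())
        assert cfg == default_universe.config
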