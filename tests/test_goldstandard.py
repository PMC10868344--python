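"""Curation, degree/hub computation and negative-sampling tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ppibench import goldstandard, synthetic
from ppibench.core import (
    ConfigurationError,
    EvidenceRecord,
    InfeasibleSamplingError,
    IntegrityError,
    LabeledPair,
)
from ppibench.goldstandard import NoPositivesError


def pairs(*keys):
    return [LabeledPair(a, b, "positive", "curated") for a, b in keys]


class TestCuration:
    def test_colocalization_only_pair_is_dropped(self):
        with pytest.raises(NoPositivesError, match="no positives survive"):
            goldstandard.curate_positives([EvidenceRecord("A", "B", "colocalization")])

    def test_any_qualifying_evidence_keeps_pair(self):
        kept = goldstandard.curate_positives(
            [
                EvidenceRecord("A", "B", "colocalization"),
                EvidenceRecord("B", "A", "binary-physical"),
            ]
        )
        assert [(p.id_a, p.id_b) for p in kept] == [("A", "B")]

    def test_self_pairs_dropped(self):
        with pytest.raises(NoPositivesError):
            goldstandard.curate_positives([EvidenceRecord("A", "A", "binary-physical")])

    def test_empty_evidence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            goldstandard.curate_positives([])

    def test_deduplication_and_canonical_order(self):
        kept = goldstandard.curate_positives(
            [
                EvidenceRecord("B", "A", "binary-physical"),
                EvidenceRecord("A", "B", "two-hybrid"),
            ]
        )
        assert len(kept) == 1 and kept[0].key == ("A", "B")


class TestDegreesAndHubs:
    def test_single_pair_degrees_and_hub_cut(self):
        table = goldstandard.degree_table(pairs(("A", "B")))
        assert table.loc["A", "degree"] == 1 and table.loc["B", "degree"] == 1
        # ceil(0.2 * 2) = 1 hub; degree tie broken lexicographically
        assert table["hub"].sum() == 1 and bool(table.loc["A", "hub"])

    def test_top_two_of_ten_are_hubs(self):
        degrees = [5, 4, 3, 2, 1, 1, 1, 1, 1, 1]
        series = pd.Series(degrees, index=[f"P{i}" for i in range(10)])
        hubs = goldstandard.hub_set(series, 0.20)
        assert hubs == {"P0", "P1"}

    def test_empty_positives_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            goldstandard.degree_table([])

    def test_invalid_quantile_rejected(self):
        with pytest.raises(ConfigurationError, match="hub_quantile"):
            goldstandard.degree_table(pairs(("A", "B")), hub_quantile=1.5)

    def test_proteome_extension_gives_zero_degrees(self):
        table = goldstandard.degree_table(pairs(("A", "B")), proteome=["A", "B", "C", "D"])
        assert table.loc["C", "degree"] == 0 and not table.loc["C", "hub"]


class TestEndpointShare:
    def test_full_and_empty_subsets(self):
        keys = [("A", "B"), ("C", "D")]
        assert goldstandard.endpoint_share(keys, {"A", "B", "C", "D"}) == 1.0
        assert goldstandard.endpoint_share(keys, set()) == 0.0

    def test_half_share(self):
        assert goldstandard.endpoint_share([("A", "B"), ("C", "D")], {"A"}) == 0.5


class TestSampleNegatives:
    def test_balanced_with_no_candidate_pairs_is_infeasible(self):
        with pytest.raises(InfeasibleSamplingError, match="candidate pairs"):
            goldstandard.sample_negatives(
                pairs(("A", "B")), ["A", "B", "C"], scheme="balanced", ratio=1.0
            )

    def test_uniform_small_case_draws_a_non_positive_pair(self):
        negatives = goldstandard.sample_negatives(
            pairs(("A", "B")), ["A", "B", "C"], scheme="uniform", ratio=1.0, seed=4
        )
        assert len(negatives) == 1
        assert negatives[0].key in {("A", "C"), ("B", "C")}

    def test_zero_degree_proteins_never_sampled_under_balanced(self, net500):
        _, edges, degrees = net500
        proteome = list(degrees.index) + [f"X{i}" for i in range(50)]
        negatives = goldstandard.sample_negatives(edges, proteome, "balanced", seed=2)
        touched = {pid for p in negatives for pid in p.key}
        assert not any(pid.startswith("X") for pid in touched)

    def test_negatives_never_collide_with_positives(self, net500):
        _, edges, degrees = net500
        for scheme in ("uniform", "balanced"):
            negatives = goldstandard.sample_negatives(
                edges, list(degrees.index), scheme, seed=3
            )
            keys = {p.key for p in negatives}
            assert len(keys) == len(negatives)
            assert not keys & set(edges)

    def test_deterministic_given_seed(self, net500):
        _, edges, degrees = net500
        a = goldstandard.sample_negatives(edges, list(degrees.index), "balanced", seed=9)
        b = goldstandard.sample_negatives(edges, list(degrees.index), "balanced", seed=9)
        assert [p.key for p in a] == [p.key for p in b]

    def test_balanced_endpoint_frequencies_match_positive_set(self, net500):
        """10,000 balanced draws: endpoint frequencies reproduce the positive
        set's endpoint frequencies (small TV distance; chi-square GOF does not
        reject at alpha=0.01, zero-mass proteins excluded)."""
        _, edges, degrees = net500
        negatives = goldstandard.sample_negatives(
            edges, list(degrees.index), "balanced", seed=3, n_pairs=10000
        )
        counts = goldstandard.endpoint_counts([p.key for p in negatives]).reindex(
            degrees.index, fill_value=0
        )
        support = degrees > 0
        target = (degrees / degrees.sum())[support]
        empirical = (counts / counts.sum())[support]
        tv = 0.5 * np.abs(target - empirical).sum()
        assert tv < 0.05
        expected = target * counts[support].sum()
        chi2 = (((counts[support] - expected) ** 2) / expected).sum()
        p = stats.chi2.sf(chi2, int(support.sum()) - 1)
        assert p > 0.01

    def test_uniform_vs_balanced_hub_contrast(self):
        """The mechanism behind the hubs-dominate-positives contrast: uniform
        negatives involve hubs far less than positives do, balanced negatives
        mirror the positive hub share.  Checked at interactome-like density
        (m=3); sparser attachment graphs keep a small assortativity residual
        that endpoint-marginal matching cannot remove."""
        cfg = synthetic.SyntheticConfig(n_edges_per_new_node=3, seed=11)
        edges, degrees = synthetic.generate_network(cfg)
        ids = list(degrees.index)
        table = goldstandard.degree_table(edges, proteome=ids)
        hubs = set(table.index[table["hub"]])
        pos_share = goldstandard.endpoint_share(edges, hubs)
        uniform = goldstandard.sample_negatives(edges, ids, "uniform", seed=5)
        balanced = goldstandard.sample_negatives(edges, ids, "balanced", seed=5)
        uni_share = goldstandard.endpoint_share([p.key for p in uniform], hubs)
        bal_share = goldstandard.endpoint_share([p.key for p in balanced], hubs)
        assert uni_share < pos_share
        assert abs(bal_share - pos_share) < 0.05

    def test_invalid_inputs(self):
        with pytest.raises(ConfigurationError, match="proteome"):
            goldstandard.sample_negatives(pairs(("A", "B")), ["A", "B"])
        with pytest.raises(ConfigurationError, match="ratio"):
            goldstandard.sample_negatives(pairs(("A", "B")), ["A", "B", "C"], ratio=0)
        with pytest.raises(ConfigurationError, match="scheme"):
            goldstandard.sample_negatives(pairs(("A", "B")), ["A", "B", "C"], scheme="fancy")


class TestAssembleGoldStandard:
    def test_disjoint_union_sizes_add(self):
        gold = goldstandard.assemble_gold_standard(
            pairs(("A", "B")),
            [LabeledPair("C", "D", "negative", "sampled-uniform")],
        )
        assert len(gold) == 2
        assert set(gold["label"]) == {"positive", "negative"}

    def test_pair_with_both_labels_is_integrity_error(self):
        with pytest.raises(IntegrityError, match="both positive and negative"):
            goldstandard.assemble_gold_standard(
                pairs(("A", "B")),
                [LabeledPair("A", "B", "negative", "sampled-uniform")],
            )

    def test_reversed_duplicates_collapse_to_one_row(self):
        gold = goldstandard.assemble_gold_standard(
            [
                LabeledPair("A", "B", "positive", "curated"),
                LabeledPair("A", "B", "positive", "curated"),
            ],
            [],
        )
        assert len(gold) == 1
        assert (gold.loc[0, "idA"], gold.loc[0, "idB"]) == ("A", "B")


class TestIO:
    def test_evidence_tsv_roundtrip(self, tmp_path):
        path = tmp_path / "evidence.tsv"
        path.write_text(
            "idA\tidB\tmethod_class\tn_publications\n"
            "A\tB\tbinary-physical\t3\n"
            "C\tD\tcolocalization\t1\n"
        )
        records = goldstandard.read_evidence_tsv(path)
        assert records[0] == EvidenceRecord("A", "B", "binary-physical", 3)
        kept = goldstandard.curate_positives(records)
        assert [p.key for p in kept] == [("A", "B")]

    def test_gold_tsv_roundtrip_canonicalizes(self, tmp_path):
        path = tmp_path / "gold.tsv"
        path.write_text("idA\tidB\tlabel\tsource\nB\tA\tpositive\tcurated\n")
        frame = goldstandard.read_gold_tsv(path)
        assert (frame.loc[0, "idA"], frame.loc[0, "idB"]) == ("A", "B")
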