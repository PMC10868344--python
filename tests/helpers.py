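"""Shared builders and independent oracles for the test suite.

Oracles here deliberately avoid the library code paths they check (brute
force enumeration, Monte-Carlo permutation), so tests compare two
independent routes to the same quantity.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ppibench import features, goldstandard, models, splits, synthetic
from ppibench.core import POSITIVE, LabeledPair


def zero_missing() -> dict[str, float]:
    return {facet: 0.0 for facet in synthetic.FACETS}


def strong_signal_config(seed: int) -> synthetic.SyntheticConfig:
    """Strong planted-annotation-signal universe: fg_signal 0.9, no
    missingness, hub-annotation coupling switched off so the recovery test
    isolates the planted overlap signal."""
    return synthetic.SyntheticConfig(
        fg_signal=0.9,
        hub_annotation_inflation=1.0,
        missing_rate_per_facet=zero_missing(),
        seed=seed,
    )


def null_signal_config(seed: int) -> synthetic.SyntheticConfig:
    """No planted signal and no hub-annotation coupling: features carry no
    information about interaction."""
    return synthetic.SyntheticConfig(
        fg_signal=0.0, hub_annotation_inflation=1.0, seed=seed
    )


def build_gold(universe: synthetic.SyntheticUniverse, seed: int, scheme: str = "balanced"):
    positives = [
        LabeledPair(a, b, POSITIVE, "curated") for a, b in sorted(universe.positive_pairs)
    ]
    negatives = goldstandard.sample_negatives(
        positives, universe.protein_ids, scheme=scheme, seed=seed
    )
    return goldstandard.assemble_gold_standard(positives, negatives)


def build_benchmark_data(
    config: synthetic.SyntheticConfig,
    split_seed: int,
    t1_size: int = 2000,
    t2_size: int = 2000,
    feature_groups: tuple[str, ...] = ("fg",),
):
    """Universe -> gold -> splits -> per-split feature tables and labels."""
    universe = synthetic.generate_universe(config)
    gold = build_gold(universe, split_seed)
    heldout = splits.hold_out_proteins(universe.protein_ids, 0.10, split_seed)
    split_cfg = splits.SplitConfig(t1_size=t1_size, t2_size=t2_size, seed=split_seed)
    assignment = splits.make_splits(gold, heldout, split_cfg, proteome=universe.protein_ids)
    index = universe.protein_index
    data = {}
    for name in ("train", "T1", "T2"):
        part = assignment[assignment["split"] == name]
        table = features.build_feature_table(
            zip(part["idA"], part["idB"]), index, feature_groups
        )
        y = (part["label"] == POSITIVE).astype(int).to_numpy()
        data[name] = {"table": table, "y": y, "part": part}
    return universe, assignment, data


def fit_and_score(family: str, data: dict, seed: int = 1):
    fit = models.fit(models.ModelSpec(family, seed=seed), data["train"]["table"], data["train"]["y"])
    scores = {
        name: models.predict_scores(fit, data[name]["table"]) for name in ("T1", "T2")
    }
    return fit, scores


def random_pairs(ids, n, rng):
    pairs = set()
    while len(pairs) < n:
        a, b = rng.choice(ids, size=2, replace=False)
        pairs.add((a, b) if a < b else (b, a))
    return sorted(pairs)


def mean_facet_jaccard(pairs, annotations):
    """Per-pair mean Jaccard over non-missing facets."""
    values = []
    for a, b in pairs:
        sims = []
        for facet in synthetic.FACETS:
            sim, miss = features.facet_similarity(annotations[a][facet], annotations[b][facet])
            if not miss:
                sims.append(sim)
        if sims:
            values.append(np.mean(sims))
    return np.array(values)


def positive_vs_random_jaccard_gap(fg_signal: float, seed: int) -> float:
    """Mean positive-pair minus mean random-pair Jaccard at a signal level,
    with hub inflation and missingness switched off."""
    cfg = synthetic.SyntheticConfig(
        fg_signal=fg_signal,
        hub_annotation_inflation=1.0,
        missing_rate_per_facet=zero_missing(),
        seed=seed,
    )
    edges, degrees = synthetic.generate_network(cfg)
    annotations, _ = synthetic.generate_annotations(edges, degrees, cfg)
    rng = np.random.default_rng(seed)
    pos = mean_facet_jaccard(edges[:1000], annotations)
    rand = mean_facet_jaccard(random_pairs(list(degrees.index), 1000, rng), annotations)
    return float(pos.mean() - rand.mean())


# ---------------------------------------------------------------------------
# Independent oracles

def brute_force_auroc(labels, scores) -> float:
    """Concordant-pair fraction over all positive x negative pairs, ties 1/2."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (pos.size * neg.size)


def permutation_roc_test(labels, scores_a, scores_b, n_perm: int = 10000, seed: int = 0) -> float:
    """Stratified permutation oracle for comparing two correlated ROC curves.

    Model identity is swapped per subject with probability 1/2 in each
    permutation; the two-sided p-value is the fraction of permuted
    |AUROC difference| values at least as large as the observed one.
    """
    y = np.asarray(labels).astype(int)
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    rng = np.random.default_rng(seed)

    def midrank_auc(matrix: np.ndarray) -> np.ndarray:
        ranks = stats.rankdata(matrix, axis=1)
        m = int(y.sum())
        n = y.size - m
        return (ranks[:, y == 1].sum(axis=1) - m * (m + 1) / 2.0) / (m * n)

    observed = abs(
        midrank_auc(sa[None, :])[0] - midrank_auc(sb[None, :])[0]
    )
    swap = rng.random((n_perm, y.size)) < 0.5
    perm_a = np.where(swap, sb, sa)
    perm_b = np.where(swap, sa, sb)
    diffs = np.abs(midrank_auc(perm_a) - midrank_auc(perm_b))
    return float((diffs >= observed - 1e-12).mean())


def er_top_share(n_nodes: int, n_edges: int, seed: int) -> float:
    """Top-20%-degree endpoint share of an equal-density Erdos-Renyi graph."""
    import networkx as nx

    graph = nx.gnm_random_graph(n_nodes, n_edges, seed=seed)
    degrees = dict(graph.degree())
    order = sorted(degrees, key=lambda v: (-degrees[v], v))
    top = set(order[: int(np.ceil(0.2 * n_nodes))])
    hits = sum(1 for u, v in graph.edges() if u in top or v in top)
    return hits / graph.number_of_edges()
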