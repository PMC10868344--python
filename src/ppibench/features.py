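"""Pair featurization: annotation overlap, co-expression, sequence features.

Functional-genomics (FG) features are per-facet Jaccard similarities between
the two proteins' term sets, each with an explicit missingness indicator:
when either protein lacks the facet the similarity is imputed to 0 and the
flag is set, so linear models can learn missingness effects instead of
conflating "no overlap" with "no data".  Expression similarity is Spearman
rank correlation.  Sequence features are a k-mer composition cosine and
lock-key motif co-occurrence indicators; they are optional columns, off by
default for FG models.

All features are symmetric in the pair by construction.
"""

from __future__ import annotations

from collections import Counter
from typing import Callable, Iterable, Mapping, Optional, Sequence

import math

import numpy as np
import pandas as pd
from scipy import stats

from .core import FACETS, ProteinRecord, UnknownProteinError, canonical_pair
from .synthetic import MOTIF_DICTIONARY

FG = "fg"
EXPR = "expr"
SEQ = "seq"
DEFAULT_FEATURES = (FG,)

#: Column names for the per-dictionary-entry motif co-occurrence indicators.
MOTIF_COLUMNS = tuple(f"motif_pair_{i:02d}" for i in range(len(MOTIF_DICTIONARY)))
SEQ_COLUMNS = ("kmer_cos", "shared_motif") + MOTIF_COLUMNS


def jaccard(set_a: frozenset, set_b: frozenset) -> float:
    union = len(set_a | set_b)
    return len(set_a & set_b) / union if union else 0.0


def overlap_coefficient(set_a: frozenset, set_b: frozenset) -> float:
    smaller = min(len(set_a), len(set_b))
    return len(set_a & set_b) / smaller if smaller else 0.0


def facet_similarity(
    set_a: Optional[frozenset],
    set_b: Optional[frozenset],
    measure: Callable[[frozenset, frozenset], float] = jaccard,
) -> tuple[float, int]:
    """(similarity, missing_flag); missing when either set is absent/empty."""
    if not set_a or not set_b:
        return 0.0, 1
    return measure(set_a, set_b), 0


def expression_correlation(
    vec_a: Optional[np.ndarray], vec_b: Optional[np.ndarray]
) -> tuple[float, int]:
    """Spearman rank correlation, or (0, missing=1) when not estimable.

    Not estimable: either profile absent, fewer than 3 conditions, or a
    constant profile (rank correlation undefined).
    """
    if vec_a is None or vec_b is None:
        return 0.0, 1
    vec_a = np.asarray(vec_a, dtype=float)
    vec_b = np.asarray(vec_b, dtype=float)
    if vec_a.shape != vec_b.shape:
        raise ValueError(
            f"expression profiles differ in length: {vec_a.shape} vs {vec_b.shape}"
        )
    if vec_a.size < 3 or np.ptp(vec_a) == 0 or np.ptp(vec_b) == 0:
        return 0.0, 1
    rho = stats.spearmanr(vec_a, vec_b).statistic
    if math.isnan(rho):
        return 0.0, 1
    return float(rho), 0


def _kmer_counts(seq: str, k: int) -> Counter:
    return Counter(seq[i : i + k] for i in range(len(seq) - k + 1))


def kmer_cosine(seq_a: str, seq_b: str, k: int = 3) -> float:
    """Cosine similarity of k-mer count vectors; in [0, 1]."""
    if not seq_a or not seq_b or len(seq_a) < k or len(seq_b) < k:
        raise ValueError(f"sequences must be at least k={k} residues long")
    counts_a = _kmer_counts(seq_a, k)
    counts_b = _kmer_counts(seq_b, k)
    dot = sum(counts_a[kmer] * counts_b[kmer] for kmer in counts_a.keys() & counts_b.keys())
    norm = math.sqrt(sum(c * c for c in counts_a.values())) * math.sqrt(
        sum(c * c for c in counts_b.values())
    )
    return dot / norm if norm else 0.0


def motif_cooccurrence(seq_a: str, seq_b: str) -> np.ndarray:
    """Per-dictionary-entry indicator that the pair carries lock and key.

    Entry i fires when one sequence contains the lock and the other the key
    (either orientation), i.e. the complementary interface motif is present.
    """
    flags = np.zeros(len(MOTIF_DICTIONARY), dtype=int)
    for i, (lock, key) in enumerate(MOTIF_DICTIONARY):
        if (lock in seq_a and key in seq_b) or (lock in seq_b and key in seq_a):
            flags[i] = 1
    return flags


def pair_features(
    rec_a: ProteinRecord,
    rec_b: ProteinRecord,
    features: Sequence[str] = DEFAULT_FEATURES,
    k: int = 3,
    measure: Callable[[frozenset, frozenset], float] = jaccard,
) -> dict[str, float]:
    """Feature dict for one unordered pair; symmetric in (rec_a, rec_b)."""
    row: dict[str, float] = {}
    if FG in features:
        for facet in FACETS:
            sim, miss = facet_similarity(
                rec_a.facet_terms(facet), rec_b.facet_terms(facet), measure
            )
            row[f"sim_{facet}"] = sim
            row[f"miss_{facet}"] = miss
    if EXPR in features:
        rho, miss = expression_correlation(rec_a.expression, rec_b.expression)
        row["expr_corr"] = rho
        row["miss_expr"] = miss
    if SEQ in features:
        if rec_a.sequence is None or rec_b.sequence is None:
            row["kmer_cos"] = 0.0
            row["miss_seq"] = 1
            flags = np.zeros(len(MOTIF_DICTIONARY), dtype=int)
        else:
            row["kmer_cos"] = kmer_cosine(rec_a.sequence, rec_b.sequence, k)
            row["miss_seq"] = 0
            flags = motif_cooccurrence(rec_a.sequence, rec_b.sequence)
        row["shared_motif"] = int(flags.any())
        for name, flag in zip(MOTIF_COLUMNS, flags):
            row[name] = int(flag)
    return row


def build_feature_table(
    pairs: Iterable[tuple[str, str]],
    protein_index: Mapping[str, ProteinRecord],
    features: Sequence[str] = DEFAULT_FEATURES,
    k: int = 3,
    measure: Callable[[frozenset, frozenset], float] = jaccard,
) -> pd.DataFrame:
    """One row per pair: idA, idB, then the requested feature columns.

    Raises :class:`UnknownProteinError` listing all unresolvable ids.
    """
    unknown = set(features) - {FG, EXPR, SEQ}
    if unknown:
        raise ValueError(f"unknown feature groups: {sorted(unknown)}")
    pair_list = [canonical_pair(a, b) for a, b in pairs]
    missing = sorted(
        {pid for key in pair_list for pid in key if pid not in protein_index}
    )
    if missing:
        raise UnknownProteinError(f"unknown protein ids in pair list: {missing}")
    rows = []
    for a, b in pair_list:
        row: dict[str, object] = {"idA": a, "idB": b}
        row.update(pair_features(protein_index[a], protein_index[b], features, k, measure))
        rows.append(row)
    columns = ["idA", "idB"] + feature_columns(features)
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows, columns=columns)


def feature_columns(features: Sequence[str] = DEFAULT_FEATURES) -> list[str]:
    """The feature-column schema for a feature-group selection."""
    cols: list[str] = []
    if FG in features:
        for facet in FACETS:
            cols += [f"sim_{facet}", f"miss_{facet}"]
    if EXPR in features:
        cols += ["expr_corr", "miss_expr"]
    if SEQ in features:
        cols += ["kmer_cos", "miss_seq", "shared_motif", *MOTIF_COLUMNS]
    return cols


def write_feature_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_feature_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"idA": str, "idB": str})
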