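"""Gold-standard construction: positive curation, degrees/hubs, negatives.

Positives come from evidence tables after a method-class quality filter
(spatial colocalization alone, or purely computational prediction, is not
accepted as evidence of physical interaction).  Negatives are sampled pairs:
because true interactions are sparse, a random non-positive pair is a
negative with high probability.  Two endpoint marginals are supported:

* ``uniform`` — every protein equally likely; representative of the general
  pair population and therefore the right choice for evaluation sets;
* ``balanced`` — endpoint mass proportional to the protein's frequency among
  positive-pair endpoints, so negatives mirror the positives' degree profile.
  This prevents models from learning "hub involved => interacts" and is the
  right choice for training sets.

The contrast matters on scale-free interactomes, where the top 20% of
proteins by degree touch nearly all positive pairs but only a minority of
uniformly sampled ones.
"""

from __future__ import annotations

import math
from typing import Collection, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    NEGATIVE,
    POSITIVE,
    ConfigurationError,
    EvidenceRecord,
    InfeasibleSamplingError,
    IntegrityError,
    LabeledPair,
    PPIBenchError,
    canonical_pair,
    round_half_up,
)

#: Method classes whose evidence alone does not qualify a positive pair.
DEFAULT_EXCLUDED_METHOD_CLASSES = frozenset({"colocalization", "predicted"})


class NoPositivesError(PPIBenchError):
    """All evidence was filtered out; no positive pairs survive."""


def curate_positives(
    evidence: Iterable[EvidenceRecord],
    excluded_method_classes: Collection[str] = DEFAULT_EXCLUDED_METHOD_CLASSES,
) -> list[LabeledPair]:
    """Filter and deduplicate evidence into canonical positive pairs.

    A pair is kept if *any* of its evidence records has a method class
    outside the excluded set; self-pairs are dropped.  Raises
    :class:`NoPositivesError` when nothing survives.
    """
    excluded = frozenset(excluded_method_classes)
    qualifying: set[tuple[str, str]] = set()
    seen_any = False
    for record in evidence:
        seen_any = True
        if record.id_a == record.id_b:
            continue
        if record.method_class in excluded:
            continue
        qualifying.add(canonical_pair(record.id_a, record.id_b))
    if not seen_any:
        raise ValueError("evidence list is empty")
    if not qualifying:
        raise NoPositivesError(
            "no positives survive filters: every pair's evidence is excluded "
            f"(excluded method classes: {sorted(excluded)})"
        )
    return [
        LabeledPair(a, b, POSITIVE, "curated") for a, b in sorted(qualifying)
    ]


def _pair_keys(pairs: Iterable) -> set[tuple[str, str]]:
    keys = set()
    for p in pairs:
        if isinstance(p, LabeledPair):
            keys.add(p.key)
        else:
            keys.add(canonical_pair(p[0], p[1]))
    return keys


def endpoint_counts(pairs: Iterable) -> pd.Series:
    """Number of pairs each protein participates in (its degree)."""
    counter: dict[str, int] = {}
    for a, b in _pair_keys(pairs):
        counter[a] = counter.get(a, 0) + 1
        counter[b] = counter.get(b, 0) + 1
    series = pd.Series(counter, dtype=int).sort_index()
    series.index.name = "protein"
    return series


def hub_set(degrees: pd.Series, hub_quantile: float = 0.20) -> set[str]:
    """The top ``ceil(hub_quantile * n)`` proteins by degree.

    Ties at the cut are broken by lexicographic protein id so the hub set is
    deterministic.
    """
    if not 0.0 < hub_quantile < 1.0:
        raise ConfigurationError(f"hub_quantile must be in (0, 1), got {hub_quantile}")
    n_hubs = math.ceil(hub_quantile * len(degrees))
    order = sorted(degrees.index, key=lambda pid: (-int(degrees[pid]), pid))
    return set(order[:n_hubs])


def degree_table(
    positives: Iterable,
    hub_quantile: float = 0.20,
    proteome: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-protein degree in the positive set plus hub flag.

    When ``proteome`` is given, proteins absent from the positives are
    included with degree 0 (and count toward the hub-quantile denominator).
    """
    keys = _pair_keys(positives)
    if not keys:
        raise ValueError("positives must be nonempty")
    counts = endpoint_counts(keys)
    if proteome is not None:
        counts = counts.reindex(sorted(set(proteome) | set(counts.index)), fill_value=0)
        counts.index.name = "protein"
    hubs = hub_set(counts, hub_quantile)
    table = pd.DataFrame({"degree": counts, "hub": [pid in hubs for pid in counts.index]})
    return table


def endpoint_share(pairs: Iterable, protein_subset: Collection[str]) -> float:
    """Fraction of pairs with at least one endpoint in ``protein_subset``."""
    keys = _pair_keys(pairs)
    if not keys:
        raise ValueError("pairs must be nonempty")
    subset = set(protein_subset)
    hit = sum(1 for a, b in keys if a in subset or b in subset)
    return hit / len(keys)


def _endpoint_marginal(
    scheme: str, proteome: Sequence[str], positive_keys: set[tuple[str, str]]
) -> pd.Series:
    ids = sorted(set(proteome))
    if scheme == "uniform":
        return pd.Series(1.0 / len(ids), index=ids)
    if scheme == "balanced":
        counts = endpoint_counts(positive_keys).reindex(ids, fill_value=0).astype(float)
        total = counts.sum()
        if total == 0:
            raise InfeasibleSamplingError("balanced sampling needs a nonempty positive set")
        return counts / total
    raise ConfigurationError(f"scheme must be 'uniform' or 'balanced', got {scheme!r}")


def _apportion(probs: np.ndarray, total: int, rng: np.random.Generator) -> np.ndarray:
    """Integer endpoint quotas summing to ``total``, proportional to ``probs``.

    Largest-remainder apportionment; ties among equal remainders are broken
    by a seeded random permutation so small cases are not id-biased.
    """
    ideal = probs * total
    base = np.floor(ideal).astype(int)
    short = total - int(base.sum())
    if short:
        frac = ideal - base
        # random permutation first, then stable sort by remainder descending
        perm = rng.permutation(len(probs))
        order = perm[np.argsort(-frac[perm], kind="stable")]
        base[order[:short]] += 1
    return base


def sample_negatives(
    positives: Iterable,
    proteome: Sequence[str],
    scheme: str = "balanced",
    ratio: float = 1.0,
    seed: int = 0,
    exclude: Optional[Iterable[tuple[str, str]]] = None,
    n_pairs: Optional[int] = None,
    pairing: Optional[str] = None,
) -> list[LabeledPair]:
    """Draw unique non-positive pairs whose endpoints follow a marginal.

    ``round(ratio * n_positives)`` pairs (or ``n_pairs``, when given) are
    drawn; self-pairs, positives, pairs in ``exclude`` and duplicates are
    never emitted.  Under ``balanced``, proteins with zero positive degree
    have zero mass and can never appear in a negative.

    Two pair-construction mechanisms are available via ``pairing``:

    * ``"independent"`` — endpoints drawn i.i.d. from the marginal with
      rejection.  Simple, but the uniqueness constraint systematically
      starves high-mass endpoints once popular pairs are used up, so the
      realized endpoint frequencies drift from the target as the draw count
      grows.  Default for ``uniform``, where per-pair uniformity is the
      point.
    * ``"matched"`` — endpoint quotas are apportioned to the marginal
      (largest remainder), then stubs are randomly matched configuration-
      model style, rewiring conflicts.  Realized endpoint frequencies equal
      the target up to rounding, which is exactly the guarantee balanced
      sampling exists to provide; default for ``balanced``.

    Raises :class:`InfeasibleSamplingError` up front when the candidate space
    cannot supply the requested number of pairs.  Deterministic given
    ``seed``.
    """
    positive_keys = _pair_keys(positives)
    ids = sorted(set(proteome))
    if len(ids) < 3:
        raise ConfigurationError(f"proteome must have >= 3 proteins, got {len(ids)}")
    if n_pairs is None:
        if ratio <= 0:
            raise ConfigurationError(f"ratio must be > 0, got {ratio}")
        n_pairs = round_half_up(ratio * len(positive_keys))
    if pairing is None:
        pairing = "matched" if scheme == "balanced" else "independent"
    if pairing not in ("independent", "matched"):
        raise ConfigurationError(f"pairing must be 'independent' or 'matched', got {pairing!r}")
    excluded_keys = _pair_keys(exclude) if exclude else set()

    marginal = _endpoint_marginal(scheme, ids, positive_keys)
    support = [pid for pid in ids if marginal[pid] > 0]
    support_set = set(support)
    n_support = len(support)
    n_candidates = n_support * (n_support - 1) // 2
    blocked = {
        key
        for key in positive_keys | excluded_keys
        if key[0] in support_set and key[1] in support_set
    }
    available = n_candidates - len(blocked)
    if n_pairs > available:
        raise InfeasibleSamplingError(
            f"requested {n_pairs} negatives under scheme={scheme!r} but only "
            f"{available} candidate pairs exist ({n_support} proteins with "
            f"nonzero mass, {len(blocked)} pairs blocked)"
        )

    rng = np.random.default_rng(seed)
    probs = marginal.loc[support].to_numpy()
    probs = probs / probs.sum()
    support_arr = np.array(support)
    chosen: list[tuple[str, str]] = []
    chosen_set: set[tuple[str, str]] = set()

    if pairing == "matched":
        counts = _apportion(probs, 2 * n_pairs, rng)
        stubs = np.repeat(np.arange(n_support), counts)
        stalled = 0
        while stubs.size and len(chosen) < n_pairs and stalled < 10:
            rng.shuffle(stubs)
            leftover: list[int] = []
            for i in range(0, stubs.size - 1, 2):
                ia, ib = int(stubs[i]), int(stubs[i + 1])
                if ia == ib:
                    leftover += [ia, ib]
                    continue
                key = canonical_pair(str(support_arr[ia]), str(support_arr[ib]))
                if key in blocked or key in chosen_set:
                    leftover += [ia, ib]
                    continue
                chosen.append(key)
                chosen_set.add(key)
            stalled = stalled + 1 if len(leftover) == stubs.size else 0
            stubs = np.array(leftover, dtype=int)
        # any stub conflicts that could not be rewired are topped off below

    max_rounds = 1000
    for _ in range(max_rounds):
        if len(chosen) >= n_pairs:
            break
        batch = max(256, 2 * (n_pairs - len(chosen)))
        a_draw = rng.choice(support_arr, size=batch, p=probs)
        b_draw = rng.choice(support_arr, size=batch, p=probs)
        for a, b in zip(a_draw, b_draw):
            if a == b:
                continue
            key = canonical_pair(str(a), str(b))
            if key in blocked or key in chosen_set:
                continue
            chosen.append(key)
            chosen_set.add(key)
            if len(chosen) >= n_pairs:
                break
    else:
        raise InfeasibleSamplingError(
            f"rejection sampling failed to find {n_pairs} unique negatives in "
            f"{max_rounds} rounds; candidate space is nearly exhausted"
        )
    source = f"sampled-{scheme}"
    return [LabeledPair(a, b, NEGATIVE, source) for a, b in chosen]


def assemble_gold_standard(
    positives: Iterable[LabeledPair], negatives: Iterable[LabeledPair]
) -> pd.DataFrame:
    """Merge positives and negatives into one canonical, deduplicated table.

    Raises :class:`IntegrityError` if any pair key carries both labels.
    """
    rows: dict[tuple[str, str], LabeledPair] = {}
    for pair in list(positives) + list(negatives):
        key = canonical_pair(pair.id_a, pair.id_b)
        previous = rows.get(key)
        if previous is not None and previous.label != pair.label:
            raise IntegrityError(
                f"pair {key} appears as both positive and negative"
            )
        rows[key] = LabeledPair(key[0], key[1], pair.label, pair.source)
    frame = pd.DataFrame(
        [(p.id_a, p.id_b, p.label, p.source) for p in rows.values()],
        columns=["idA", "idB", "label", "source"],
    )
    return frame.sort_values(["label", "idA", "idB"], ascending=[False, True, True]).reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# Tabular IO

def read_evidence_tsv(path) -> list[EvidenceRecord]:
    frame = pd.read_csv(path, sep="\t", dtype={"idA": str, "idB": str})
    required = {"idA", "idB", "method_class"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"evidence TSV missing columns: {sorted(missing)}")
    if "n_publications" not in frame.columns:
        frame["n_publications"] = 1
    return [
        EvidenceRecord(r.idA, r.idB, r.method_class, int(r.n_publications))
        for r in frame.itertuples()
    ]


def write_gold_tsv(gold: pd.DataFrame, path) -> None:
    gold.to_csv(path, sep="\t", index=False)


def read_gold_tsv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"idA": str, "idB": str})
    swapped = frame["idA"] > frame["idB"]
    if swapped.any():
        frame.loc[swapped, ["idA", "idB"]] = frame.loc[swapped, ["idB", "idA"]].to_numpy()
    return frame
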