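"""Train / T1 / T2 partitioning with protein-level leakage control.

Pair-level disjointness between train and test is necessary but not
sufficient: the same *proteins* recur across pairs, and models that memorize
proteins look better on test pairs whose endpoints were seen in training.
The design here makes that effect measurable:

* a fraction of the proteome is held out of training entirely;
* **T1** is a balanced (default 50% positive) comparison set drawn to
  populate all three protein-overlap strata — both endpoints seen in
  training pairs (``both-seen``), one (``one-seen``), neither
  (``none-seen``);
* **T2** is a generalization set at realistic prevalence (default 1%
  positive), topped up with fresh uniformly sampled negatives.

Gold-standard pairs that touch held-out proteins but are not drawn into
T1/T2 cannot be placed in train without defeating the hold-out, so they are
emitted with split label ``unused`` rather than silently dropped; every
input pair appears exactly once in the output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Collection, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    NEGATIVE,
    POSITIVE,
    ConfigurationError,
    InfeasibleSamplingError,
    PPIBenchError,
    UnknownProteinError,
    round_half_up,
)
from . import goldstandard

OVERLAP_STRATA = ("both-seen", "one-seen", "none-seen")
TOPOLOGY_STRATA = ("hub-hub", "hub-lone", "lone-lone")
SPLIT_COLUMNS = ["idA", "idB", "label", "split", "overlap_stratum", "topology_stratum"]


class InfeasibleStratumError(PPIBenchError):
    """A required T1 overlap stratum has no candidate pairs at all."""


@dataclass
class SplitConfig:
    heldout_protein_fraction: float = 0.10
    t1_positive_fraction: float = 0.50
    t2_positive_fraction: float = 0.01
    t1_size: int = 2000
    t2_size: int = 2000
    seed: int = 0

    def validate(self) -> None:
        for name in ("heldout_protein_fraction", "t1_positive_fraction", "t2_positive_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        for name in ("t1_size", "t2_size"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SplitConfig":
        return cls(**json.loads(text))


def hold_out_proteins(
    proteome: Sequence[str], fraction: float, seed: int
) -> set[str]:
    """Uniform random protein subset of size ``round(fraction * n)``."""
    ids = sorted(set(proteome))
    if not 0.0 < fraction < 1.0:
        raise ConfigurationError(
            f"heldout_protein_fraction must be in (0, 1), got {fraction}"
        )
    size = round_half_up(fraction * len(ids))
    if size == 0 or size == len(ids):
        raise ConfigurationError(
            f"heldout fraction {fraction} yields a degenerate subset "
            f"({size} of {len(ids)} proteins)"
        )
    rng = np.random.default_rng(seed)
    return set(rng.choice(np.array(ids), size=size, replace=False))


def overlap_stratum(pair: tuple[str, str], train_protein_set: Collection[str]) -> str:
    """both-seen / one-seen / none-seen from endpoint membership in train."""
    seen = sum(1 for pid in pair[:2] if pid in train_protein_set)
    return OVERLAP_STRATA[2 - seen]


def topology_stratum(pair: tuple[str, str], degrees: pd.DataFrame) -> str:
    """hub-hub / hub-lone / lone-lone from the degree table's hub flags."""
    unknown = [pid for pid in pair[:2] if pid not in degrees.index]
    if unknown:
        raise UnknownProteinError(f"proteins not in degree table: {unknown}")
    n_hubs = int(degrees.loc[pair[0], "hub"]) + int(degrees.loc[pair[1], "hub"])
    return TOPOLOGY_STRATA[2 - n_hubs]


def _even_targets(total: int) -> dict[str, int]:
    # Even thirds across strata; the remainder goes to both-seen, which is
    # always the largest candidate pool.
    base = total // 3
    remainder = total - 3 * base
    return {"none-seen": base, "one-seen": base, "both-seen": base + remainder}


def _take_stratified(
    pools: dict[str, list[int]],
    total: int,
    rng: np.random.Generator,
    what: str,
) -> list[int]:
    """Draw ``total`` row indices filling none-seen, one-seen, both-seen.

    Targets start even; a stratum whose pool is too small contributes what it
    has and the deficit cascades to the next stratum.  A stratum with an
    empty pool, or an overall shortfall, raises loudly.
    """
    empty = [stratum for stratum in OVERLAP_STRATA if not pools.get(stratum)]
    if empty:
        raise InfeasibleStratumError(
            f"no {what} pairs available for T1 stratum(s) {empty}"
        )
    if total > sum(len(p) for p in pools.values()):
        raise InfeasibleSamplingError(
            f"T1 requests {total} {what} pairs but only "
            f"{sum(len(p) for p in pools.values())} are available"
        )
    targets = _even_targets(total)
    chosen: list[int] = []
    deficit = 0
    for stratum in ("none-seen", "one-seen", "both-seen"):
        want = targets[stratum] + deficit
        pool = pools[stratum]
        take = min(want, len(pool))
        deficit = want - take
        picked = rng.choice(len(pool), size=take, replace=False)
        chosen.extend(pool[i] for i in sorted(picked))
    if deficit:
        # Cascade back down: strata earlier in the fill order may have spare.
        for stratum in ("one-seen", "none-seen"):
            pool = pools[stratum]
            already = set(chosen)
            spare = [i for i in pool if i not in already]
            take = min(deficit, len(spare))
            picked = rng.choice(len(spare), size=take, replace=False)
            chosen.extend(spare[i] for i in sorted(picked))
            deficit -= take
            if deficit == 0:
                break
    if deficit:
        raise InfeasibleSamplingError(
            f"T1 {what} allocation short by {deficit} pairs after cascading"
        )
    return chosen


def make_splits(
    gold: pd.DataFrame,
    heldout: Collection[str],
    config: SplitConfig,
    proteome: Optional[Sequence[str]] = None,
    degrees: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Assign every gold pair to train / T1 / T2 (or ``unused``).

    ``proteome`` (all sampleable protein ids) is needed to draw T2's fresh
    uniform negatives; it defaults to the proteins occurring in ``gold``.
    ``degrees`` (from :func:`ppibench.goldstandard.degree_table`) supplies
    hub flags for topology strata; it is recomputed from the gold positives
    when absent.  Overlap strata in the output are computed against the
    *realized* train protein set.  Deterministic given ``config.seed``.
    """
    config.validate()
    heldout = set(heldout)
    gold = gold.reset_index(drop=True)
    labels = gold["label"].to_numpy()
    keys = list(zip(gold["idA"], gold["idB"]))
    if proteome is None:
        proteome = sorted({pid for key in keys for pid in key})
    rng = np.random.default_rng(config.seed)

    t1_pos_n = round_half_up(config.t1_size * config.t1_positive_fraction)
    t1_neg_n = config.t1_size - t1_pos_n
    t2_pos_n = round_half_up(config.t2_size * config.t2_positive_fraction)
    t2_neg_n = config.t2_size - t2_pos_n

    # Provisional strata from held-out endpoint counts guide T1 allocation;
    # final labels are recomputed against the realized train protein set.
    n_held = np.array([sum(pid in heldout for pid in key) for key in keys])
    provisional = np.array([OVERLAP_STRATA[h] for h in n_held])  # 0 held -> both-seen

    def pools_for(label: str) -> dict[str, list[int]]:
        return {
            stratum: [
                i
                for i in range(len(gold))
                if labels[i] == label and provisional[i] == stratum
            ]
            for stratum in OVERLAP_STRATA
        }

    t1_rows = set(_take_stratified(pools_for(POSITIVE), t1_pos_n, rng, "positive"))
    t1_rows |= set(_take_stratified(pools_for(NEGATIVE), t1_neg_n, rng, "negative"))

    remaining_pos = [
        i for i in range(len(gold)) if labels[i] == POSITIVE and i not in t1_rows
    ]
    if t2_pos_n > len(remaining_pos):
        raise InfeasibleSamplingError(
            f"T2 requests {t2_pos_n} positives but only {len(remaining_pos)} remain"
        )
    picked = rng.choice(len(remaining_pos), size=t2_pos_n, replace=False)
    t2_rows = {remaining_pos[i] for i in sorted(picked)}

    # Fresh uniform negatives for T2, disjoint from every gold pair.
    t2_negatives = goldstandard.sample_negatives(
        keys,
        proteome,
        scheme="uniform",
        seed=int(rng.integers(2**31 - 1)),
        n_pairs=t2_neg_n,
    )

    split = np.full(len(gold), "train", dtype=object)
    for i in range(len(gold)):
        if i in t1_rows:
            split[i] = "T1"
        elif i in t2_rows:
            split[i] = "T2"
        elif n_held[i] > 0:
            split[i] = "unused"

    frame = gold[["idA", "idB", "label"]].copy()
    frame["split"] = split
    extra = pd.DataFrame(
        [(p.id_a, p.id_b, p.label, "T2") for p in t2_negatives],
        columns=["idA", "idB", "label", "split"],
    )
    frame = pd.concat([frame, extra], ignore_index=True)

    train_proteins = realized_train_proteins(frame)
    frame["overlap_stratum"] = [
        overlap_stratum((a, b), train_proteins)
        for a, b in zip(frame["idA"], frame["idB"])
    ]

    if degrees is None:
        positives = [k for k, lab in zip(keys, labels) if lab == POSITIVE]
        degrees = goldstandard.degree_table(positives, proteome=proteome)
    else:
        missing = sorted(
            {pid for key in zip(frame["idA"], frame["idB"]) for pid in key}
            - set(degrees.index)
        )
        if missing:
            raise UnknownProteinError(f"degree table missing proteins: {missing[:5]}")
    frame["topology_stratum"] = [
        topology_stratum((a, b), degrees) for a, b in zip(frame["idA"], frame["idB"])
    ]
    return frame[SPLIT_COLUMNS]


def realized_train_proteins(assignment: pd.DataFrame) -> set[str]:
    """Proteins occurring in at least one train pair of an assignment."""
    train = assignment[assignment["split"] == "train"]
    return set(train["idA"]) | set(train["idB"])


def check_assignment(assignment: pd.DataFrame) -> None:
    """Re-verify structural invariants of a split assignment; raises on error."""
    keys = list(zip(assignment["idA"], assignment["idB"]))
    if len(keys) != len(set(keys)):
        raise IntegrityErrorFromDuplicates(keys)
    train_proteins = realized_train_proteins(assignment)
    recomputed = [overlap_stratum(k, train_proteins) for k in keys]
    mismatch = (assignment["overlap_stratum"].to_numpy() != np.array(recomputed)).sum()
    if mismatch:
        raise PPIBenchError(f"{mismatch} overlap_stratum labels do not recompute")


class IntegrityErrorFromDuplicates(PPIBenchError):
    def __init__(self, keys):
        seen, dups = set(), []
        for k in keys:
            if k in seen:
                dups.append(k)
            seen.add(k)
        super().__init__(f"duplicate pair keys in assignment: {dups[:5]}")


def write_split_tsv(assignment: pd.DataFrame, path) -> None:
    assignment.to_csv(path, sep="\t", index=False)


def read_split_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"idA": str, "idB": str})
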