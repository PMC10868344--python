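"""Synthetic proteomes and interactomes with benchmark-relevant structure.

The generator plants, in a fully seeded way, the statistical features that
make protein-protein interaction benchmarking hard on real data:

* a scale-free positive network (preferential attachment), so a few hubs
  dominate the edge list while most proteins are "lone";
* hub-inflated annotation counts — highly connected proteins carry many more
  functional terms, which dilutes overlap-based similarity for hub pairs;
* per-facet annotation overlap that is predictive of interaction (a shared
  term injected into interacting pairs with probability ``fg_signal``);
* whole-facet missingness at controllable per-facet rates, emulating the
  sparse coverage of domain/motif annotation in curated databases;
* module-structured expression profiles with co-assignment of interacting
  pairs; and
* random amino-acid sequences in which interacting pairs carry complementary
  lock-key motifs drawn from a fixed dictionary.  Each universe activates a
  small random subset of the dictionary, so the motif vocabulary mediating
  interaction differs between independently seeded universes the way
  interface vocabularies differ between species.

Everything flows from one integer seed; identical config + seed gives
bit-identical universes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .core import FACETS, ConfigurationError, ProteinRecord, canonical_pair
from .goldstandard import hub_set

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Fixed lock-key motif dictionary: 16 complementary pairs of length-6
#: peptides.  The dictionary itself never changes; which entries a universe
#: uses is drawn from its seed (``motif_active_count`` entries).
MOTIF_DICTIONARY: tuple[tuple[str, str], ...] = (
    ("WCLAMP", "HNDGRI"),
    ("KEYHLE", "LCKHLE"),
    ("DERAIL", "RAILDE"),
    ("MAGNET", "TENGAM"),
    ("VELCRW", "WRCLEV"),
    ("HANDLE", "ELDNAH"),
    ("SPRING", "GNIRPS"),
    ("ANCHRD", "DRHCNA"),
    ("LATCHK", "KHCTAL"),
    ("SCREWD", "DWERCS"),
    ("PLIERS", "SREILP"),
    ("WRENCH", "HCNERW"),
    ("STAPLE", "ELPATS"),
    ("RIVETS", "STEVIR"),
    ("CLINCH", "HCNILC"),
    ("TETHER", "REHTET"),
)

_STAGE_NETWORK = 1
_STAGE_ANNOT = 2
_STAGE_EXPR = 3
_STAGE_SEQ = 4

#: Probability that the two endpoints of an interacting pair share an
#: expression module (propagated along edges during module assignment).
CO_MODULE_PROB = 0.7


def _default_vocab_sizes() -> dict[str, int]:
    return {
        "biological_process": 400,
        "cellular_compartment": 80,
        "molecular_function": 250,
        "domain": 300,
        "motif": 200,
    }


def _default_missing_rates() -> dict[str, float]:
    # Domain and motif annotation coverage in curated human data is sparse:
    # roughly 58% and 89% of proteins lack them entirely.
    return {
        "biological_process": 0.0,
        "cellular_compartment": 0.0,
        "molecular_function": 0.0,
        "domain": 0.58,
        "motif": 0.89,
    }


@dataclass
class SyntheticConfig:
    """All generator knobs; defaults are the toolkit's reference conditions."""

    n_proteins: int = 2000
    n_edges_per_new_node: int = 2
    facet_vocab_sizes: dict[str, int] = field(default_factory=_default_vocab_sizes)
    base_terms_per_protein: int = 4
    hub_annotation_inflation: float = 3.0
    fg_signal: float = 0.6
    missing_rate_per_facet: dict[str, float] = field(default_factory=_default_missing_rates)
    expr_n_conditions: int = 20
    expr_module_count: int = 12
    expr_noise_sd: float = 0.5
    seq_length_range: tuple[int, int] = (80, 300)
    motif_signal: float = 0.5
    motif_active_count: int = 4
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 2:
            raise ConfigurationError(f"n_proteins must be >= 2, got {self.n_proteins}")
        if not (1 <= self.n_edges_per_new_node < self.n_proteins):
            raise ConfigurationError(
                "n_edges_per_new_node must satisfy 1 <= m < n_proteins, "
                f"got m={self.n_edges_per_new_node}, n={self.n_proteins}"
            )
        for facet in FACETS:
            if facet not in self.facet_vocab_sizes:
                raise ConfigurationError(f"facet_vocab_sizes missing facet {facet!r}")
            if self.facet_vocab_sizes[facet] < self.base_terms_per_protein:
                raise ConfigurationError(
                    f"facet_vocab_sizes[{facet!r}] must be >= base_terms_per_protein"
                )
            rate = self.missing_rate_per_facet.get(facet, 0.0)
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(
                    f"missing_rate_per_facet[{facet!r}] must be in [0, 1], got {rate}"
                )
        if self.base_terms_per_protein < 1:
            raise ConfigurationError("base_terms_per_protein must be positive")
        if self.hub_annotation_inflation < 1.0:
            raise ConfigurationError("hub_annotation_inflation must be >= 1")
        for name in ("fg_signal", "motif_signal"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        if self.expr_n_conditions < 1:
            raise ConfigurationError("expr_n_conditions must be positive")
        if self.expr_module_count < 1:
            raise ConfigurationError("expr_module_count must be >= 1")
        if self.expr_noise_sd < 0:
            raise ConfigurationError("expr_noise_sd must be nonnegative")
        lo, hi = self.seq_length_range
        if not (0 < lo <= hi):
            raise ConfigurationError(
                f"seq_length_range must satisfy 0 < min <= max, got {self.seq_length_range}"
            )
        if lo < max(len(s) for pair in MOTIF_DICTIONARY for s in pair):
            raise ConfigurationError(
                "seq_length_range minimum must fit a dictionary motif (length 6)"
            )
        if not (1 <= self.motif_active_count <= len(MOTIF_DICTIONARY)):
            raise ConfigurationError(
                f"motif_active_count must be in [1, {len(MOTIF_DICTIONARY)}]"
            )

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["seq_length_range"] = list(self.seq_length_range)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticConfig":
        d = json.loads(text)
        if "seq_length_range" in d:
            d["seq_length_range"] = tuple(d["seq_length_range"])
        return cls(**d)


@dataclass
class SyntheticUniverse:
    """A generated proteome plus its ground-truth interactome.

    ``truth_log`` records the signals actually planted per pair (shared
    terms, motif dictionary entry, expression co-module) for diagnostics; it
    must never be used as a model input.
    """

    config: SyntheticConfig
    proteins: list[ProteinRecord]
    positive_pairs: set[tuple[str, str]]
    degrees: pd.Series
    truth_log: dict

    @property
    def protein_ids(self) -> list[str]:
        return [p.id for p in self.proteins]

    @property
    def protein_index(self) -> dict[str, ProteinRecord]:
        return {p.id: p for p in self.proteins}


def _rng(config: SyntheticConfig, stage: int) -> np.random.Generator:
    # Deterministic per-stage substream: stages can be regenerated
    # independently without consuming each other's draws.
    return np.random.default_rng([config.seed & 0x7FFFFFFF, stage])


def _protein_id(i: int) -> str:
    return f"P{i:05d}"


def generate_network(config: SyntheticConfig) -> tuple[list[tuple[str, str]], pd.Series]:
    """Preferential-attachment interactome: canonical edge list + degrees.

    Uses a Barabasi-Albert graph, the canonical scale-free generator: each
    new protein attaches to ``n_edges_per_new_node`` existing proteins with
    probability proportional to their current degree, yielding the few-hubs /
    many-lone-proteins topology of curated interactomes.
    """
    config.validate()
    rng = _rng(config, _STAGE_NETWORK)
    graph = nx.barabasi_albert_graph(
        config.n_proteins,
        config.n_edges_per_new_node,
        seed=int(rng.integers(2**31 - 1)),
    )
    ids = [_protein_id(i) for i in range(config.n_proteins)]
    edges = sorted(canonical_pair(ids[u], ids[v]) for u, v in graph.edges())
    degree = pd.Series(0, index=pd.Index(ids, name="protein"), dtype=int)
    for a, b in edges:
        degree[a] += 1
        degree[b] += 1
    return edges, degree


def generate_annotations(
    edges: list[tuple[str, str]],
    degrees: pd.Series,
    config: SyntheticConfig,
) -> tuple[dict[str, dict[str, Optional[frozenset[str]]]], dict]:
    """Facet-wise term sets per protein, with planted pairwise signal.

    Order of operations: background terms (hub-inflated counts) -> shared-term
    injection into interacting pairs with probability ``fg_signal`` per facet
    -> whole-facet missingness masks.  Masking last means a planted signal can
    be lost to missingness, exactly as an informative annotation would be.
    """
    config.validate()
    rng = _rng(config, _STAGE_ANNOT)
    ids = list(degrees.index)
    hubs = hub_set(degrees, hub_quantile=0.20)

    annotations: dict[str, dict[str, Optional[frozenset[str]]]] = {
        pid: {} for pid in ids
    }
    working: dict[str, dict[str, set[str]]] = {pid: {} for pid in ids}
    for facet in FACETS:
        vocab_size = config.facet_vocab_sizes[facet]
        for pid in ids:
            n_terms = config.base_terms_per_protein
            if pid in hubs:
                n_terms = int(round(config.hub_annotation_inflation * n_terms))
            n_terms = min(n_terms, vocab_size)
            chosen = rng.choice(vocab_size, size=n_terms, replace=False)
            working[pid][facet] = {f"{facet}:{int(t):04d}" for t in chosen}

    shared_log: dict[tuple[str, str], dict[str, str]] = {}
    for a, b in edges:
        planted: dict[str, str] = {}
        for facet in FACETS:
            if rng.random() < config.fg_signal:
                term = f"{facet}:{int(rng.integers(config.facet_vocab_sizes[facet])):04d}"
                working[a][facet].add(term)
                working[b][facet].add(term)
                planted[facet] = term
        if planted:
            shared_log[(a, b)] = planted

    for facet in FACETS:
        rate = config.missing_rate_per_facet.get(facet, 0.0)
        mask = rng.random(len(ids)) < rate
        for pid, missing in zip(ids, mask):
            annotations[pid][facet] = None if missing else frozenset(working[pid][facet])

    truth = {"shared_terms": shared_log, "hubs": hubs}
    return annotations, truth


def generate_expression(
    edges: list[tuple[str, str]],
    config: SyntheticConfig,
    ids: Optional[list[str]] = None,
) -> tuple[pd.DataFrame, dict]:
    """Module-structured expression matrix (proteins x conditions).

    Each protein belongs to a latent co-expression module; interacting pairs
    are co-assigned with probability ``CO_MODULE_PROB`` (modules propagate
    along edges in canonical order).  A profile is its module's mean vector
    plus i.i.d. Gaussian noise.
    """
    config.validate()
    rng = _rng(config, _STAGE_EXPR)
    if ids is None:
        ids = [_protein_id(i) for i in range(config.n_proteins)]
    module_means = rng.normal(size=(config.expr_module_count, config.expr_n_conditions))
    modules = {pid: int(m) for pid, m in zip(ids, rng.integers(config.expr_module_count, size=len(ids)))}
    for a, b in sorted(edges):
        if rng.random() < CO_MODULE_PROB:
            modules[b] = modules[a]
    profiles = np.vstack(
        [
            module_means[modules[pid]]
            + rng.normal(scale=config.expr_noise_sd, size=config.expr_n_conditions)
            for pid in ids
        ]
    )
    frame = pd.DataFrame(
        profiles,
        index=pd.Index(ids, name="protein"),
        columns=[f"cond{j:03d}" for j in range(config.expr_n_conditions)],
    )
    return frame, {"modules": modules}


def generate_sequences(
    edges: list[tuple[str, str]],
    config: SyntheticConfig,
    ids: Optional[list[str]] = None,
) -> tuple[dict[str, str], dict]:
    """Random amino-acid sequences with planted lock-key motifs.

    The universe first draws its active subset of the motif dictionary; each
    interacting pair then, with probability ``motif_signal``, gets one active
    entry's lock spliced into one endpoint and the key into the other
    (in-place substitution, so lengths are preserved).
    """
    config.validate()
    rng = _rng(config, _STAGE_SEQ)
    if ids is None:
        ids = [_protein_id(i) for i in range(config.n_proteins)]
    lo, hi = config.seq_length_range
    alphabet = np.array(list(AMINO_ACIDS))
    seqs: dict[str, list[str]] = {}
    for pid in ids:
        length = int(rng.integers(lo, hi + 1))
        seqs[pid] = list(rng.choice(alphabet, size=length))

    active = sorted(
        int(i)
        for i in rng.choice(len(MOTIF_DICTIONARY), size=config.motif_active_count, replace=False)
    )
    # Planted spans per protein; new insertions avoid them so one planted
    # motif never destroys another (hubs receive many insertions).
    occupied: dict[str, list[tuple[int, int]]] = {pid: [] for pid in ids}

    def _insert(pid: str, motif: str) -> None:
        seq = seqs[pid]
        width = len(motif)
        free = [
            pos
            for pos in range(len(seq) - width + 1)
            if all(pos + width <= s or pos >= e for s, e in occupied[pid])
        ]
        pos = int(free[int(rng.integers(len(free)))]) if free else int(
            rng.integers(0, len(seq) - width + 1)
        )
        seq[pos : pos + width] = list(motif)
        occupied[pid].append((pos, pos + width))

    motif_log: dict[tuple[str, str], int] = {}
    for a, b in edges:
        if rng.random() < config.motif_signal:
            entry = int(active[int(rng.integers(len(active)))])
            lock, key = MOTIF_DICTIONARY[entry]
            first, second = (a, b) if rng.random() < 0.5 else (b, a)
            _insert(first, lock)
            _insert(second, key)
            motif_log[(a, b)] = entry

    sequences = {pid: "".join(chars) for pid, chars in seqs.items()}
    return sequences, {"active_motifs": active, "planted_motifs": motif_log}


def generate_universe(config: SyntheticConfig) -> SyntheticUniverse:
    """Run all four stages and assemble ProteinRecords."""
    config.validate()
    edges, degrees = generate_network(config)
    annotations, annot_truth = generate_annotations(edges, degrees, config)
    ids = list(degrees.index)
    expression, expr_truth = generate_expression(edges, config, ids)
    sequences, seq_truth = generate_sequences(edges, config, ids)

    proteins = [
        ProteinRecord(
            id=pid,
            species=f"synthetic-{config.seed}",
            sequence=sequences[pid],
            annotations=annotations[pid],
            expression=expression.loc[pid].to_numpy(),
        )
        for pid in ids
    ]
    truth = {**annot_truth, **expr_truth, **seq_truth}
    return SyntheticUniverse(
        config=config,
        proteins=proteins,
        positive_pairs=set(edges),
        degrees=degrees,
        truth_log=truth,
    )


def write_universe(universe: SyntheticUniverse, outdir: str | Path) -> dict[str, Path]:
    """Write the universe as plain-text artifacts; returns path map.

    Formats: FASTA for sequences, long-form TSV for annotations, a TSV matrix
    for expression, an edge TSV for positives, and the JSON config used.
    """
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["sequences"] = outdir / "sequences.fasta"
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description="")
        for p in universe.proteins
        if p.sequence is not None
    ]
    seqio_write(records, str(paths["sequences"]), "fasta")

    paths["annotations"] = outdir / "annotations.tsv"
    rows = []
    for p in universe.proteins:
        for facet in FACETS:
            terms = p.facet_terms(facet)
            if terms is None:
                continue
            rows.extend((p.id, facet, term) for term in sorted(terms))
    pd.DataFrame(rows, columns=["protein_id", "facet", "term"]).to_csv(
        paths["annotations"], sep="\t", index=False
    )

    paths["expression"] = outdir / "expression.tsv"
    expr = pd.DataFrame(
        [p.expression for p in universe.proteins],
        index=pd.Index(universe.protein_ids, name="protein"),
    )
    expr.columns = [f"cond{j:03d}" for j in range(expr.shape[1])]
    expr.to_csv(paths["expression"], sep="\t")

    paths["positive_pairs"] = outdir / "positive_pairs.tsv"
    pd.DataFrame(sorted(universe.positive_pairs), columns=["idA", "idB"]).to_csv(
        paths["positive_pairs"], sep="\t", index=False
    )

    paths["config"] = outdir / "config.json"
    paths["config"].write_text(universe.config.to_json())
    return paths
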