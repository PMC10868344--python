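"""Shared record types, error hierarchy and pair canonicalization.

Every protein pair in the toolkit is unordered: ``(a, b)`` and ``(b, a)``
denote the same observation.  All tables and sets store pairs in canonical
(lexicographically sorted) order so that set membership, de-duplication and
joins behave as pair-level operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

#: Annotation facets carried by every protein record.  These mirror the major
#: functional-genomics sources used for interaction prediction: GO biological
#: process / cellular compartment / molecular function, plus protein domains
#: and sequence motifs.
FACETS: tuple[str, ...] = (
    "biological_process",
    "cellular_compartment",
    "molecular_function",
    "domain",
    "motif",
)

POSITIVE = "positive"
NEGATIVE = "negative"


class PPIBenchError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(PPIBenchError):
    """An invalid configuration value; the message names the offending field."""


class InfeasibleSamplingError(PPIBenchError):
    """A sampling request exceeds the available candidate pool."""


class IntegrityError(PPIBenchError):
    """A dataset violates a structural invariant (e.g. a pair labeled twice)."""


class UnknownProteinError(PPIBenchError):
    """A pair references a protein id missing from the relevant index."""


class SchemaMismatchError(PPIBenchError):
    """A feature table does not match the schema a model was trained on."""


def canonical_pair(id_a: str, id_b: str) -> tuple[str, str]:
    """Return the unordered pair key ``(min(a, b), max(a, b))``.

    Self-pairs are not canonicalizable interactions; callers that must drop
    them silently should test ``id_a == id_b`` first.
    """
    if id_a == id_b:
        raise ValueError(f"self-pair ({id_a!r}, {id_b!r}) has no canonical form")
    return (id_a, id_b) if id_a < id_b else (id_b, id_a)


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: identity, species, sequence, annotations, expression.

    ``annotations`` maps facet name to a frozenset of term identifiers, or to
    ``None`` when the facet is missing for this protein (unannotated, which is
    distinct from annotated-with-nothing only in provenance; both are treated
    as missing downstream).  ``expression`` is a 1-D profile across
    conditions, or ``None``.
    """

    id: str
    species: str = "synthetic"
    sequence: Optional[str] = None
    annotations: Optional[Mapping[str, Optional[frozenset[str]]]] = None
    expression: Optional[np.ndarray] = field(default=None, compare=False)

    def facet_terms(self, facet: str) -> Optional[frozenset[str]]:
        if self.annotations is None:
            return None
        return self.annotations.get(facet)


@dataclass(frozen=True)
class EvidenceRecord:
    """One line of interaction evidence between two proteins."""

    id_a: str
    id_b: str
    method_class: str
    n_publications: int = 1


@dataclass(frozen=True)
class LabeledPair:
    """A canonical unordered pair with its gold-standard label and provenance."""

    id_a: str
    id_b: str
    label: str
    source: str

    @classmethod
    def make(cls, id_a: str, id_b: str, label: str, source: str) -> "LabeledPair":
        a, b = canonical_pair(id_a, id_b)
        if label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be positive/negative, got {label!r}")
        return cls(a, b, label, source)

    @property
    def key(self) -> tuple[str, str]:
        return (self.id_a, self.id_b)


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero toward +inf.

    Used for every ``fraction x size`` computation in the toolkit so realized
    counts are bit-reproducible and documented (Python's ``round`` rounds
    halves to even, which would make 0.5 x 5 = 2).
    """
    return int(np.floor(x + 0.5))
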