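"""Pathway content model and functional-interaction (FI) extraction.

A functional interaction links two proteins that take part in the same
biochemical reaction — as an input, catalyst, activator or inhibitor — or
that are components of the same protein complex.  Reaction outputs never
contribute FIs: producing a protein is not evidence that the product acts
together with the reaction's participants.

Direction tags follow the usual pathway-diagram semantics: a catalyst or
activator points an "activates" arrow at each reaction input, an inhibitor
points an "inhibits" T-bar at each input, and transcription-factor → target
records carry "expression_regulates".  Pairs among co-inputs, among
co-regulators, or within a complex are undirected.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

__all__ = [
    "ProteinRef",
    "ComplexRecord",
    "ReactionRecord",
    "PathwayRecord",
    "FunctionalInteraction",
    "PathwayStructureError",
    "Direction",
    "extract_fis_from_reaction",
    "extract_fis_from_complex",
    "build_pathway_fi_set",
    "merge_fi",
]

_ISOFORM_SUFFIX = re.compile(r"-\d+$")


class PathwayStructureError(ValueError):
    """Raised for malformed pathway content (e.g. cyclic complex nesting)."""


class Direction:
    """Allowed FI direction tags."""

    UNDIRECTED = "undirected"
    ACTIVATES = "activates"
    INHIBITS = "inhibits"
    EXPRESSION = "expression_regulates"

    ALL = frozenset({UNDIRECTED, ACTIVATES, INHIBITS, EXPRESSION})


@dataclass(frozen=True)
class ProteinRef:
    """A protein identified by a stable accession.

    Splice-isoform suffixes (``P12345-2``) are stripped so identity is by
    base accession.
    """

    accession: str
    gene_symbol: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        base = _ISOFORM_SUFFIX.sub("", self.accession)
        object.__setattr__(self, "accession", base)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProteinRef):
            return NotImplemented
        return self.accession == other.accession

    def __hash__(self) -> int:
        return hash(self.accession)


Member = Union[ProteinRef, "ComplexRecord"]


@dataclass(frozen=True)
class ComplexRecord:
    """A protein complex; components may be proteins or nested complexes."""

    id: str
    components: frozenset = field(default_factory=frozenset)

    def flatten(self) -> frozenset:
        """Recursively resolve components to the set of ProteinRef.

        Raises :class:`PathwayStructureError` on cyclic nesting.
        """
        return self._flatten(frozenset())

    def _flatten(self, seen: frozenset) -> frozenset:
        if self.id in seen:
            raise PathwayStructureError(
                f"cyclic complex nesting involving {self.id!r}"
            )
        seen = seen | {self.id}
        proteins: set = set()
        for m in self.components:
            if isinstance(m, ProteinRef):
                proteins.add(m)
            elif isinstance(m, ComplexRecord):
                proteins |= m._flatten(seen)
            else:  # pragma: no cover - guarded by constructors
                raise PathwayStructureError(f"bad complex member {m!r}")
        return frozenset(proteins)


@dataclass(frozen=True)
class ReactionRecord:
    """A reaction with role-tagged participants.

    Role sets may overlap (the same protein can be input and catalyst).
    """

    id: str
    inputs: frozenset = field(default_factory=frozenset)
    catalysts: frozenset = field(default_factory=frozenset)
    activators: frozenset = field(default_factory=frozenset)
    inhibitors: frozenset = field(default_factory=frozenset)
    outputs: frozenset = field(default_factory=frozenset)


@dataclass
class PathwayRecord:
    """A pathway: a bag of reactions and complexes from one source database."""

    id: str
    source: str
    reactions: list = field(default_factory=list)
    complexes: list = field(default_factory=list)


@dataclass(frozen=True)
class FunctionalInteraction:
    """An unordered protein pair with provenance and direction annotations.

    ``pair`` is a sorted accession tuple.  ``direction_source`` names the
    acting protein for directed FIs (the catalyst/activator/inhibitor/TF).
    """

    pair: tuple
    provenance: str = "pathway"
    direction: str = Direction.UNDIRECTED
    direction_source: Optional[str] = None
    sources: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        a, b = self.pair
        if a == b:
            raise ValueError("FI members must be distinct")
        if a > b:
            object.__setattr__(self, "pair", (b, a))
        if self.direction not in Direction.ALL:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.direction != Direction.UNDIRECTED:
            if self.provenance != "pathway":
                raise ValueError("only pathway FIs may carry a direction")
            if self.direction_source not in self.pair:
                raise ValueError("direction_source must be a pair member")


def _flatten_role(members: Iterable[Member]) -> frozenset:
    proteins: set = set()
    for m in members:
        if isinstance(m, ComplexRecord):
            proteins |= m.flatten()
        else:
            proteins.add(m)
    return frozenset(proteins)


def extract_fis_from_reaction(
    r: ReactionRecord, sources: Iterable[str] = ()
) -> set:
    """All FIs implied by one reaction.

    Every unordered pair over the flattened union of inputs, catalysts,
    activators and inhibitors is an FI; outputs are excluded.  Complexes
    appearing in roles are flattened first, and their internal pairs are
    emitted too (they are complex FIs in any case).
    """
    sources = frozenset(sources)
    inputs = _flatten_role(r.inputs)
    catalysts = _flatten_role(r.catalysts)
    activators = _flatten_role(r.activators)
    inhibitors = _flatten_role(r.inhibitors)
    participants = sorted(
        inputs | catalysts | activators | inhibitors, key=lambda p: p.accession
    )
    positive_reg = catalysts | activators
    fis: set = set()
    for x, y in itertools.combinations(participants, 2):
        direction = Direction.UNDIRECTED
        src: Optional[str] = None
        # regulator -> input pairs are directed; everything else undirected
        for reg, tgt in ((x, y), (y, x)):
            if reg in positive_reg and tgt in inputs and tgt not in positive_reg:
                direction, src = Direction.ACTIVATES, reg.accession
                break
            if (
                reg in inhibitors
                and reg not in positive_reg
                and tgt in inputs
                and tgt not in inhibitors
            ):
                direction, src = Direction.INHIBITS, reg.accession
                break
        fis.add(
            FunctionalInteraction(
                pair=(x.accession, y.accession),
                provenance="pathway",
                direction=direction,
                direction_source=src,
                sources=sources,
            )
        )
    return fis


def extract_fis_from_complex(
    c: ComplexRecord, sources: Iterable[str] = ()
) -> set:
    """All undirected FIs among the recursively flattened complex members."""
    sources = frozenset(sources)
    proteins = sorted(c.flatten(), key=lambda p: p.accession)
    if not proteins:
        warnings.warn(f"complex {c.id!r} has no protein components")
        return set()
    return {
        FunctionalInteraction(
            pair=(x.accession, y.accession), sources=sources
        )
        for x, y in itertools.combinations(proteins, 2)
    }


def merge_fi(
    a: FunctionalInteraction, b: FunctionalInteraction
) -> FunctionalInteraction:
    """Merge two reports of the same pair into one FI.

    Pathway provenance beats predicted; a directed report beats an
    undirected one (first directed report wins under deterministic
    iteration); sources are unioned.
    """
    if a.pair != b.pair:
        raise ValueError("can only merge FIs over the same pair")
    if a.provenance != b.provenance:
        keep, other = (a, b) if a.provenance == "pathway" else (b, a)
    elif a.direction == Direction.UNDIRECTED != b.direction:
        keep, other = b, a
    else:
        keep, other = a, b
    return FunctionalInteraction(
        pair=keep.pair,
        provenance=keep.provenance,
        direction=keep.direction,
        direction_source=keep.direction_source,
        sources=keep.sources | other.sources,
    )


def build_pathway_fi_set(pathways: Iterable[PathwayRecord]) -> set:
    """Deduplicated FI union over all reactions and complexes.

    Each FI records every contributing pathway-database label; a directed
    and an undirected report of the same pair merge into one FI keeping
    the direction.
    """
    by_pair: dict = {}
    for pw in pathways:
        labels = (pw.source,)
        batches = [extract_fis_from_reaction(r, labels) for r in pw.reactions]
        batches += [extract_fis_from_complex(c, labels) for c in pw.complexes]
        for batch in batches:
            for fi in sorted(batch, key=lambda f: f.pair):
                if fi.pair in by_pair:
                    by_pair[fi.pair] = merge_fi(by_pair[fi.pair], fi)
                else:
                    by_pair[fi.pair] = fi
    return set(by_pair.values())
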