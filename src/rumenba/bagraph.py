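"""Rule-based bile-acid biotransformation engine.

A bile acid is encoded by the state of its steroid-ring positions C3, C6, C7
and C12 (hydroxyl in alpha or beta orientation, an oxo group, or nothing) plus
the A/B ring-junction configuration at C5 (5alpha "allo" vs the usual 5beta).
Reaction operators act on one position at a time:

* epimerization   - flips an existing hydroxyl alpha <-> beta (at C5 it flips
                    the ring-junction configuration); classically realised by
                    a pair of hydroxysteroid dehydrogenases via an oxo
                    intermediate,
* dehydroxylation - removes a hydroxyl (the bai-operon 7alpha-dehydroxylation
                    pathway, e.g. CA -> DCA, HCA -> HDCA),
* oxidation       - hydroxyl -> oxo (an HSDH half-reaction),
* reduction       - oxo -> hydroxyl with a chosen orientation.

Enumerating every (structure, operator) pair over a set of bile acids yields
the biotransformation graph among them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable

import networkx as nx

__all__ = [
    "PosState",
    "BAStructure",
    "ReactionOperator",
    "TransformationGraph",
    "STRUCTURES",
    "RUMEN_PATHWAY_EDGES",
    "FIG_REACTION_CLASSES",
    "conventional_reaction",
    "apply_operator",
    "all_operators",
    "enumerate_edges",
    "validate_pathway",
    "reachable",
    "deconjugate",
]


class PosState(str, Enum):
    """State of one steroid ring position."""

    ABSENT = "absent"
    OH_ALPHA = "OH-alpha"
    OH_BETA = "OH-beta"
    OXO = "oxo"


_HYDROXYL = (PosState.OH_ALPHA, PosState.OH_BETA)
_POSITIONS = (3, 5, 6, 7, 12)


@dataclass(frozen=True)
class BAStructure:
    """One bile acid: ring-position states, C5 configuration, and tags.

    ``tags`` carries conjugation/sulfation markers (``tauro``, ``glyco``,
    ``3-sulfate``) which are inert to the ring operators.
    """

    name: str
    c3: PosState = PosState.ABSENT
    c6: PosState = PosState.ABSENT
    c7: PosState = PosState.ABSENT
    c12: PosState = PosState.ABSENT
    c5: str = "beta"
    tags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.c5 not in ("alpha", "beta"):
            raise ValueError(f"{self.name}: C5 configuration must be alpha or beta")

    def state(self, position: int) -> PosState:
        return {3: self.c3, 6: self.c6, 7: self.c7, 12: self.c12}[position]

    def with_state(self, position: int, state: PosState) -> "BAStructure":
        key = {3: "c3", 6: "c6", 7: "c7", 12: "c12"}[position]
        return replace(self, **{key: state})

    @property
    def core(self):
        """Ring skeleton identity, ignoring the name."""
        return (self.c3, self.c6, self.c7, self.c12, self.c5, self.tags)

    def hydroxyl_count(self) -> int:
        return sum(self.state(p) in _HYDROXYL for p in (3, 6, 7, 12))

    def systematic_name(self) -> str:
        parts = []
        for pos in (3, 6, 7, 12):
            st = self.state(pos)
            if st is PosState.OH_ALPHA:
                parts.append(f"{pos}a-OH")
            elif st is PosState.OH_BETA:
                parts.append(f"{pos}b-OH")
            elif st is PosState.OXO:
                parts.append(f"{pos}-oxo")
        parts.append(f"5{'a' if self.c5 == 'alpha' else 'b'}")
        if self.tags:
            parts.extend(sorted(self.tags))
        return "BA[" + ",".join(parts) + "]"


@dataclass(frozen=True)
class ReactionOperator:
    """One elementary transformation at one ring position."""

    reaction: str  # epimerization | dehydroxylation | oxidation | reduction
    position: int
    target_orientation: str | None = None  # for reduction / epimerization

    def __post_init__(self) -> None:
        if self.reaction not in ("epimerization", "dehydroxylation",
                                 "oxidation", "reduction"):
            raise ValueError(f"unknown reaction class {self.reaction!r}")
        if self.position not in _POSITIONS:
            raise ValueError(f"position must be one of {_POSITIONS}")
        if self.position == 5 and self.reaction != "epimerization":
            raise ValueError("only epimerization is defined at C5")
        if self.reaction == "reduction" and self.target_orientation not in (
                "alpha", "beta"):
            raise ValueError("reduction requires target_orientation alpha|beta")

    def label(self) -> str:
        suffix = f"->{self.target_orientation}" if self.target_orientation else ""
        return f"{self.reaction}@{self.position}{suffix}"


def apply_operator(s: BAStructure, op: ReactionOperator,
                   dictionary: dict[str, BAStructure] | None = None,
                   ) -> BAStructure | None:
    """Apply one operator; return the product or None if the precondition fails.

    The product name is looked up in ``dictionary`` (default: the shipped
    structure table) when the resulting skeleton matches a known bile acid;
    otherwise a systematic name is generated.
    """
    if op.position == 5:
        flipped = "alpha" if s.c5 == "beta" else "beta"
        product = replace(s, c5=flipped)
        return _named(product, dictionary)
    st = s.state(op.position)
    if op.reaction == "epimerization":
        if st not in _HYDROXYL:
            return None
        new = PosState.OH_BETA if st is PosState.OH_ALPHA else PosState.OH_ALPHA
    elif op.reaction == "dehydroxylation":
        # Orientation-agnostic: removes whichever hydroxyl is present.
        if st not in _HYDROXYL:
            return None
        new = PosState.ABSENT
    elif op.reaction == "oxidation":
        if st not in _HYDROXYL:
            return None
        new = PosState.OXO
    else:  # reduction
        if st is not PosState.OXO:
            return None
        new = (PosState.OH_ALPHA if op.target_orientation == "alpha"
               else PosState.OH_BETA)
    return _named(s.with_state(op.position, new), dictionary)


def _named(product: BAStructure,
           dictionary: dict[str, BAStructure] | None) -> BAStructure:
    table = STRUCTURES if dictionary is None else dictionary
    for known in table.values():
        if known.core == product.core:
            return replace(product, name=known.name)
    return replace(product, name=product.systematic_name())


def all_operators() -> list[ReactionOperator]:
    """Every elementary operator over positions 3, 5, 6, 7, 12."""
    ops: list[ReactionOperator] = [ReactionOperator("epimerization", 5)]
    for pos in (3, 6, 7, 12):
        ops.append(ReactionOperator("epimerization", pos))
        ops.append(ReactionOperator("dehydroxylation", pos))
        ops.append(ReactionOperator("oxidation", pos))
        ops.append(ReactionOperator("reduction", pos, "alpha"))
        ops.append(ReactionOperator("reduction", pos, "beta"))
    return ops


@dataclass
class TransformationGraph:
    """Directed multigraph of (substrate, product, operator) edges."""

    nodes: list[str]
    edges: list[tuple[str, str, ReactionOperator]]

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.nodes)
        for sub, prod, op in self.edges:
            g.add_edge(sub, prod, reaction=op.reaction, position=op.position,
                       orientation=op.target_orientation, label=op.label())
        return g

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(s, p) for s, p, _ in self.edges}


def enumerate_edges(structures: Iterable[BAStructure],
                    mode: str = "both") -> TransformationGraph:
    """Enumerate all single-operator transformations within a structure set.

    mode:
      ``direct_epimerization`` - epimerization + dehydroxylation operators only;
      ``composite_via_oxo``    - epimerization decomposed into oxidation and
                                 reduction half-steps (oxo intermediates appear
                                 only when present in the set), plus
                                 dehydroxylation;
      ``both``                 - the union.
    """
    if mode not in ("direct_epimerization", "composite_via_oxo", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    structs = list(structures)
    cores = [s.core for s in structs]
    if len(set(cores)) < len(cores):
        raise ValueError("duplicate structures in input set")
    by_core = {s.core: s for s in structs}
    table = {s.name: s for s in structs}

    direct = mode in ("direct_epimerization", "both")
    composite = mode in ("composite_via_oxo", "both")
    ops: list[ReactionOperator] = [ReactionOperator("epimerization", 5)]
    for pos in (3, 6, 7, 12):
        ops.append(ReactionOperator("dehydroxylation", pos))
        if direct:
            ops.append(ReactionOperator("epimerization", pos))
        if composite:
            ops.append(ReactionOperator("oxidation", pos))
            ops.append(ReactionOperator("reduction", pos, "alpha"))
            ops.append(ReactionOperator("reduction", pos, "beta"))

    edges: list[tuple[str, str, ReactionOperator]] = []
    for s in structs:
        for op in ops:
            product = apply_operator(s, op, table)
            if product is None:
                continue
            hit = by_core.get(product.core)
            if hit is not None and hit.core != s.core:
                edges.append((s.name, hit.name, op))
    return TransformationGraph(nodes=[s.name for s in structs], edges=edges)


def validate_pathway(graph: TransformationGraph,
                     expected_edges: list[tuple[str, str]]):
    """Partition expected (substrate, product) pairs into found / missing.

    Returns a dict with ``found``, ``missing`` and ``extra`` lists; ``extra``
    holds graph edges absent from the expected list.
    """
    known = set(graph.nodes)
    for sub, prod in expected_edges:
        if sub not in known or prod not in known:
            raise ValueError(f"expected edge {sub}->{prod} references a "
                             "structure missing from the graph")
    have = graph.edge_pairs()
    expected = list(dict.fromkeys(expected_edges))
    found = [e for e in expected if e in have]
    missing = [e for e in expected if e not in have]
    extra = sorted(have - set(expected))
    return {"found": found, "missing": missing, "extra": extra}


def reachable(seeds: Iterable[str], structures: Iterable[BAStructure],
              mode: str = "both") -> set[str]:
    """Transitive closure of the transformation graph from seed bile acids."""
    structs = list(structures)
    names = {s.name for s in structs}
    seeds = set(seeds)
    if not seeds <= names:
        raise ValueError(f"seeds not in structure set: {sorted(seeds - names)}")
    g = enumerate_edges(structs, mode).to_networkx()
    out = set(seeds)
    for s in seeds:
        out |= nx.descendants(g, s)
    return out


def deconjugate(s: BAStructure) -> BAStructure:
    """Strip conjugation tags (BSH chemistry); ring positions untouched."""
    stripped = s.tags - {"tauro", "glyco"}
    if stripped == s.tags:
        return s
    return _named(replace(s, tags=frozenset(stripped)), None)


def conventional_reaction(substrate: BAStructure, op: ReactionOperator,
                          product: BAStructure) -> str:
    """Pathway-convention name for an edge, e.g. ``7β-epimerization``.

    Epimerization is named for the product orientation; dehydroxylation is
    conventionally written ``kα-dehydroxylation`` whatever the substrate's
    orientation (the literature labels the 7β-OH case the same way); the
    oxidation/reduction half-steps are folded into the epimerization they
    realise, oriented by the reduction target (oxidation named for the
    beta-ward reading used in pathway descriptions).
    """
    pos = op.position
    if op.reaction == "epimerization":
        if pos == 5:
            return f"5{'α' if product.c5 == 'alpha' else 'β'}-epimerization"
        orient = "β" if product.state(pos) is PosState.OH_BETA else "α"
        return f"{pos}{orient}-epimerization"
    if op.reaction == "dehydroxylation":
        return f"{pos}α-dehydroxylation"
    if op.reaction == "reduction":
        orient = "β" if op.target_orientation == "beta" else "α"
        return f"{pos}{orient}-epimerization"
    return f"{pos}β-epimerization"   # oxidation half-step


#: The five reaction classes of the proposed rumen pathway figure.
FIG_REACTION_CLASSES = frozenset({
    "7β-epimerization", "3β-epimerization", "5α-epimerization",
    "6β-epimerization", "7α-dehydroxylation",
})


def _s(name, c3, c6, c7, c12, c5, *tags) -> BAStructure:
    return BAStructure(name=name, c3=PosState(c3), c6=PosState(c6),
                       c7=PosState(c7), c12=PosState(c12), c5=c5,
                       tags=frozenset(tags))


#: Shipped structure dictionary (standard steroid nomenclature).
STRUCTURES: dict[str, BAStructure] = {s.name: s for s in [
    _s("CA",        "OH-alpha", "absent",   "OH-alpha", "OH-alpha", "beta"),
    _s("alloCA",    "OH-alpha", "absent",   "OH-alpha", "OH-alpha", "alpha"),
    _s("UCA",       "OH-alpha", "absent",   "OH-beta",  "OH-alpha", "beta"),
    _s("3β-CA",     "OH-beta",  "absent",   "OH-alpha", "OH-alpha", "beta"),
    _s("3-DHCA",    "oxo",      "absent",   "OH-alpha", "OH-alpha", "beta"),
    _s("CDCA",      "OH-alpha", "absent",   "OH-alpha", "absent",   "beta"),
    _s("UDCA",      "OH-alpha", "absent",   "OH-beta",  "absent",   "beta"),
    _s("LCA",       "OH-alpha", "absent",   "absent",   "absent",   "beta"),
    _s("isoLCA",    "OH-beta",  "absent",   "absent",   "absent",   "beta"),
    _s("DHLCA",     "oxo",      "absent",   "absent",   "absent",   "beta"),
    _s("isoUDCA",   "OH-beta",  "absent",   "OH-beta",  "absent",   "beta"),
    _s("HCA",       "OH-alpha", "OH-alpha", "OH-alpha", "absent",   "beta"),
    _s("ω-MCA",     "OH-alpha", "OH-alpha", "OH-beta",  "absent",   "beta"),
    _s("HDCA",      "OH-alpha", "OH-alpha", "absent",   "absent",   "beta"),
    _s("isoHDCA",   "OH-beta",  "OH-alpha", "absent",   "absent",   "beta"),
    _s("MDCA",      "OH-alpha", "OH-beta",  "absent",   "absent",   "beta"),
    _s("6-ketoLCA", "OH-alpha", "oxo",      "absent",   "absent",   "beta"),
    # MCA side-chain variants kept for classification; 6-beta forms.
    _s("α-MCA",     "OH-alpha", "OH-beta",  "OH-alpha", "absent",   "beta"),
    _s("β-MCA",     "OH-alpha", "OH-beta",  "OH-beta",  "absent",   "beta"),
    # Other measured species that can enter graphs when supplied.
    _s("DCA",       "OH-alpha", "absent",   "absent",   "OH-alpha", "beta"),
    _s("3-epiDCA",  "OH-beta",  "absent",   "absent",   "OH-alpha", "beta"),
    _s("7-ketoLCA", "OH-alpha", "absent",   "oxo",      "absent",   "beta"),
    _s("12-ketoLCA","OH-alpha", "absent",   "absent",   "oxo",      "beta"),
    _s("7-ketoDCA", "OH-alpha", "absent",   "oxo",      "OH-alpha", "beta"),
    # Conjugated / sulfated species: tags only, no ring operators on them here.
    _s("TCA",       "OH-alpha", "absent",   "OH-alpha", "OH-alpha", "beta", "tauro"),
    _s("TCDCA",     "OH-alpha", "absent",   "OH-alpha", "absent",   "beta", "tauro"),
    _s("GCA",       "OH-alpha", "absent",   "OH-alpha", "OH-alpha", "beta", "glyco"),
]}


#: Proposed rumen biotransformation pathway among the mutual bile acids:
#: each entry is (substrate, product, conventional reaction name).
RUMEN_PATHWAY_EDGES: list[tuple[str, str, str]] = [
    ("CA", "UCA", "7β-epimerization"),
    ("CA", "3-DHCA", "3β-epimerization"),       # oxidation half-step at C3
    ("CA", "alloCA", "5α-epimerization"),
    ("HCA", "HDCA", "7α-dehydroxylation"),
    ("HDCA", "isoHDCA", "3β-epimerization"),
    ("CDCA", "LCA", "7α-dehydroxylation"),
    ("CDCA", "UDCA", "7β-epimerization"),
    ("UDCA", "LCA", "7α-dehydroxylation"),
    ("LCA", "DHLCA", "3β-epimerization"),       # oxidation half-step at C3
    ("UDCA", "isoUDCA", "3β-epimerization"),
    ("HCA", "ω-MCA", "7β-epimerization"),
    ("ω-MCA", "HDCA", "7α-dehydroxylation"),
    ("DHLCA", "isoLCA", "3β-epimerization"),    # reduction half-step at C3
    ("isoUDCA", "isoLCA", "7α-dehydroxylation"),
    # Drawn on the pathway figure (C6 inversion among the mutual bile acids);
    # realisable directly or through the 6-ketoLCA intermediate.
    ("HDCA", "MDCA", "6β-epimerization"),
]
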