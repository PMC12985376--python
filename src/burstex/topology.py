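"""Cohesin chemical states, transitions, and reaction-network topologies.

The model tracks the core cohesin complex (RAD21 as proxy) through one
unloaded and four loaded chemical states distinguished by which regulator
(NIPBL, PDS5 or WAPL) is bound.  Regulators bind mutually exclusively, so a
transition into a regulator-bound state consumes that regulator from its
free nuclear pool, and a transition out of it releases it.  A topology is a
small reaction network over these states with exactly eight rate constants.

Topology families
-----------------
``cycle``
    Irreversible load into the first loaded state, three reversible
    regulator-exchange pairs along an ordered sequence of the four loaded
    states, and irreversible unload from the last.  There are 4! = 24 such
    cycles, identified by strings like ``"RN-R-RP-RW"``.
``acyclic_linear`` / ``acyclic_branched`` / ``acyclic_star``
    Fully reversible tree networks (every edge is a reversible pair, load
    included), classified by the shape of the spanning tree.
``nipbl_excursion`` / ``pds5_excursion``
    Cycles in which the named regulator-bound state hangs off the main
    load/unload cycle as a reversible excursion.
``pds5_wapl_cobinding``
    A cycle in which the WAPL-bound state is replaced by a PDS5+WAPL
    co-bound state and unloading exits only from that co-bound state.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

__all__ = [
    "CohesinState",
    "Transition",
    "NetworkTopology",
    "REGULATORS",
    "enumerate_cycles",
    "enumerate_variants",
    "selected_wt_cycle",
]


class CohesinState(str, Enum):
    """Chemical state of one cohesin complex.

    Values follow the compact field notation: ``R`` is the bare loaded core
    complex, ``RN``/``RP``/``RW`` the NIPBL-, PDS5- and WAPL-bound loaded
    states, and ``RPW`` the PDS5+WAPL co-bound state used only by the
    co-binding topology variant.
    """

    FREE = "free"
    BARE = "R"
    NIPBL_BOUND = "RN"
    PDS5_BOUND = "RP"
    WAPL_BOUND = "RW"
    PDS5_WAPL_BOUND = "RPW"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


S = CohesinState

#: Regulators bound in each state.  Mutual exclusivity means at most one,
#: except in the co-binding variant state.
REGULATORS: dict[CohesinState, frozenset[str]] = {
    S.FREE: frozenset(),
    S.BARE: frozenset(),
    S.NIPBL_BOUND: frozenset({"NIPBL"}),
    S.PDS5_BOUND: frozenset({"PDS5"}),
    S.WAPL_BOUND: frozenset({"WAPL"}),
    S.PDS5_WAPL_BOUND: frozenset({"PDS5", "WAPL"}),
}

#: The four canonical loaded states of the five-state model.
LOADED_STATES = (S.NIPBL_BOUND, S.BARE, S.PDS5_BOUND, S.WAPL_BOUND)


@dataclass(frozen=True)
class Transition:
    """One elementary reaction ``source -> target``.

    The consumed/released regulators are derived from the state labels:
    binding consumes from the free pool, unbinding releases back into it,
    and a direct exchange between two regulator-bound states is a concerted
    swap (one released, the other consumed, in a single reaction).
    Bimolecular transitions (non-empty ``consumed``) have pseudo-first-order
    propensity ``k * [source] * prod(free pools of consumed)``.
    """

    source: CohesinState
    target: CohesinState
    irreversible: bool = False

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("transition must connect two distinct states")

    @property
    def consumed(self) -> frozenset[str]:
        return REGULATORS[self.target] - REGULATORS[self.source]

    @property
    def released(self) -> frozenset[str]:
        return REGULATORS[self.source] - REGULATORS[self.target]

    @property
    def key(self) -> str:
        """Stable string key (used by :class:`~burstex.network.RateSet`)."""
        return f"{self.source.value}->{self.target.value}"

    def __repr__(self) -> str:
        arrow = "->" if self.irreversible else "<->"[:2]
        return f"Transition({self.source.value}{arrow}{self.target.value})"


@dataclass(frozen=True)
class NetworkTopology:
    """A reaction network over cohesin states with eight rate constants."""

    name: str
    family: str
    transitions: tuple[Transition, ...]
    loaded_sequence: Optional[tuple[CohesinState, ...]] = None

    def __post_init__(self) -> None:
        if len(self.transitions) != 8:
            raise ValueError(
                f"topology {self.name!r} has {len(self.transitions)} transitions, expected 8"
            )
        keys = [t.key for t in self.transitions]
        if len(set(keys)) != len(keys):
            raise ValueError(f"duplicate transitions in topology {self.name!r}")
        if self.family == "cycle":
            n_irr = sum(t.irreversible for t in self.transitions)
            if n_irr != 2:
                raise ValueError("cycle topology must have exactly 2 irreversible transitions")

    @property
    def states(self) -> tuple[CohesinState, ...]:
        seen: dict[CohesinState, None] = {}
        for t in self.transitions:
            seen.setdefault(t.source)
            seen.setdefault(t.target)
        # stable order: FREE first, then loaded states in enum order
        order = [S.FREE, S.BARE, S.NIPBL_BOUND, S.PDS5_BOUND, S.WAPL_BOUND, S.PDS5_WAPL_BOUND]
        return tuple(s for s in order if s in seen)

    @property
    def loaded_states(self) -> tuple[CohesinState, ...]:
        return tuple(s for s in self.states if s is not S.FREE)

    @property
    def loading_transitions(self) -> tuple[Transition, ...]:
        return tuple(t for t in self.transitions if t.source is S.FREE)

    @property
    def unloading_transitions(self) -> tuple[Transition, ...]:
        return tuple(t for t in self.transitions if t.target is S.FREE)

    def bound_states(self, regulator: str) -> tuple[CohesinState, ...]:
        return tuple(s for s in self.loaded_states if regulator in REGULATORS[s])

    def has_directed_cycle_through_free(self) -> bool:
        """True if a directed cycle passes through the unloaded state.

        For fully reversible tree networks this is False: every path out of
        the unloaded state returns along the same edges.
        """
        edges = {(t.source, t.target) for t in self.transitions}
        # DFS from FREE avoiding immediate back-tracking over the same
        # reversible edge; a cycle exists iff we can leave FREE and return
        # without reusing the entry edge in reverse.
        for first in [t for t in self.transitions if t.source is S.FREE]:
            stack = [(first.target, first.source)]
            seen = {first.target}
            while stack:
                node, prev = stack.pop()
                for (a, b) in edges:
                    if a is not node:
                        continue
                    if b is prev and (node, prev) in edges and (prev, node) in edges:
                        continue  # reversible back-edge
                    if b is S.FREE:
                        return True
                    if b not in seen:
                        seen.add(b)
                        stack.append((b, node))
        return False

    def __repr__(self) -> str:
        return f"NetworkTopology({self.name!r}, family={self.family!r})"


def _cycle(sequence: tuple[CohesinState, ...]) -> NetworkTopology:
    trans = [Transition(S.FREE, sequence[0], irreversible=True)]
    for a, b in itertools.pairwise(sequence):
        trans.append(Transition(a, b))
        trans.append(Transition(b, a))
    trans.append(Transition(sequence[-1], S.FREE, irreversible=True))
    return NetworkTopology(
        name="-".join(s.value for s in sequence),
        family="cycle",
        transitions=tuple(trans),
        loaded_sequence=sequence,
    )


def enumerate_cycles() -> list[NetworkTopology]:
    """All 24 orderings of the four loaded states along the load->unload path.

    When the bare state comes first, loading consumes no regulator (the
    load transition is then unimolecular).
    """
    return [_cycle(seq) for seq in itertools.permutations(LOADED_STATES)]


def selected_wt_cycle() -> NetworkTopology:
    """The NIPBL-load / WAPL-unload cycle selected by pruning (``RN-R-RP-RW``)."""
    return _cycle((S.NIPBL_BOUND, S.BARE, S.PDS5_BOUND, S.WAPL_BOUND))


def _tree(edges: tuple[tuple[CohesinState, CohesinState], ...]) -> NetworkTopology:
    trans: list[Transition] = []
    for a, b in edges:
        trans.append(Transition(a, b))
        trans.append(Transition(b, a))
    # classify the shape of the 5-node tree
    deg: dict[CohesinState, int] = {}
    for a, b in edges:
        deg[a] = deg.get(a, 0) + 1
        deg[b] = deg.get(b, 0) + 1
    maxdeg = max(deg.values())
    if maxdeg == 2:
        family = "acyclic_linear"
    elif maxdeg == 4:
        family = "acyclic_star"
    else:
        family = "acyclic_branched"
    name = "tree:" + "|".join(f"{a.value}-{b.value}" for a, b in edges)
    return NetworkTopology(name=name, family=family, transitions=tuple(trans))


def _all_loaded_trees() -> list[tuple[tuple[CohesinState, CohesinState], ...]]:
    """All labelled spanning trees on the four loaded states (16 by Cayley)."""
    nodes = list(LOADED_STATES)
    all_edges = list(itertools.combinations(nodes, 2))
    trees = []
    for combo in itertools.combinations(all_edges, 3):
        deg: dict[CohesinState, int] = {n: 0 for n in nodes}
        parent = {n: n for n in nodes}

        def find(x: CohesinState) -> CohesinState:
            while parent[x] is not x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        acyclic = True
        for a, b in combo:
            ra, rb = find(a), find(b)
            if ra is rb:
                acyclic = False
                break
            parent[ra] = rb
            deg[a] += 1
            deg[b] += 1
        if acyclic:
            trees.append(combo)
    return trees


def enumerate_variants() -> list[NetworkTopology]:
    """Alternative topology families explored alongside the 24 cycles.

    Returns all fully reversible acyclic (tree) networks — the unloaded
    state attached as a leaf to each possible loaded state of each of the
    16 loaded-state spanning trees — plus the NIPBL-excursion,
    PDS5-excursion and PDS5+WAPL co-binding cycles.
    """
    out: list[NetworkTopology] = []
    for tree_edges in _all_loaded_trees():
        for attach in LOADED_STATES:
            out.append(_tree(((S.FREE, attach),) + tree_edges))

    # NIPBL-bound state as an excursion off the main cycle: loading does
    # not consume NIPBL.
    out.append(
        NetworkTopology(
            name="nipbl-excursion",
            family="nipbl_excursion",
            transitions=(
                Transition(S.FREE, S.BARE, irreversible=True),
                Transition(S.BARE, S.NIPBL_BOUND),
                Transition(S.NIPBL_BOUND, S.BARE),
                Transition(S.BARE, S.PDS5_BOUND),
                Transition(S.PDS5_BOUND, S.BARE),
                Transition(S.PDS5_BOUND, S.WAPL_BOUND),
                Transition(S.WAPL_BOUND, S.PDS5_BOUND),
                Transition(S.WAPL_BOUND, S.FREE, irreversible=True),
            ),
        )
    )
    # PDS5 reversibly binds the core complex but does not recruit WAPL.
    out.append(
        NetworkTopology(
            name="pds5-excursion",
            family="pds5_excursion",
            transitions=(
                Transition(S.FREE, S.NIPBL_BOUND, irreversible=True),
                Transition(S.NIPBL_BOUND, S.BARE),
                Transition(S.BARE, S.NIPBL_BOUND),
                Transition(S.BARE, S.PDS5_BOUND),
                Transition(S.PDS5_BOUND, S.BARE),
                Transition(S.BARE, S.WAPL_BOUND),
                Transition(S.WAPL_BOUND, S.BARE),
                Transition(S.WAPL_BOUND, S.FREE, irreversible=True),
            ),
        )
    )
    # WAPL and PDS5 co-bind RAD21 and are jointly required for unloading:
    # the co-bound state replaces the PDS5->WAPL swap and is the only exit.
    out.append(
        NetworkTopology(
            name="pds5-wapl-cobinding",
            family="pds5_wapl_cobinding",
            transitions=(
                Transition(S.FREE, S.NIPBL_BOUND, irreversible=True),
                Transition(S.NIPBL_BOUND, S.BARE),
                Transition(S.BARE, S.NIPBL_BOUND),
                Transition(S.BARE, S.PDS5_BOUND),
                Transition(S.PDS5_BOUND, S.BARE),
                Transition(S.PDS5_BOUND, S.PDS5_WAPL_BOUND),
                Transition(S.PDS5_WAPL_BOUND, S.PDS5_BOUND),
                Transition(S.PDS5_WAPL_BOUND, S.FREE, irreversible=True),
            ),
        )
    )
    return out
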