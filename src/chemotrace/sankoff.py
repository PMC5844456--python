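"""Minimum-cost (Sankoff) ancestral state reconstruction with step matrices.

The dynamic programme assigns to every node v and state s the minimal cost
of v's subtree given v is in state s:

    S_v(s) = sum over children c of  min_t [ cost(s -> t) + S_c(t) ]

Polytomies contribute additively over all children (hard-polytomy
semantics).  Leaves observed in state s get 0 at s and infinity elsewhere;
leaves coded missing get 0 everywhere, so adding a dataless leaf never
changes the optimum.  A virtual stem above the root, fixed to ``absent`` by
default, charges an origin at the root as a gain: for a character that is a
derived innovation, the ancestral lineage below the study group did not
have it.  Costs are exact (integers/Fractions); no floating-point cost
accumulation.

Most-parsimonious reconstructions (MPRs) are enumerated by deterministic
backtracking; origin-count bounds over the full MPR set are obtained
without enumeration by a lexicographic DP on (cost, gains) pairs, which is
exact because the lexicographic order is translation-invariant under
componentwise addition.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

from .errors import CharacterLookupError, ConfigurationError, OracleSizeError
from .phylogeny import BoundCharacters, Node, PhyloTree

__all__ = [
    "ABSENT",
    "PRESENT",
    "MISSING",
    "INF",
    "StepMatrix",
    "CostTable",
    "Reconstruction",
    "MPRSet",
    "EventCounts",
    "min_cost",
    "enumerate_mprs",
    "origin_bounds",
    "count_events",
    "brute_force_oracle",
]

ABSENT = "absent"
PRESENT = "present"
MISSING = "missing"

INF = float("inf")

# Edge rules used by constrained (scenario) reconstructions.
ALLOW = "allow"            # gains and losses as priced by the step matrix
NO_GAIN = "no_gain"        # absent->present forbidden on this edge
FORCED_GAIN = "forced_gain"  # the edge must be exactly absent->present


class StepMatrix:
    """State-transition cost table; costs are exact Fractions."""

    def __init__(
        self,
        states: Sequence[str],
        costs: Mapping[tuple[str, str], int | Fraction],
    ) -> None:
        self.states = tuple(states)
        self._costs: dict[tuple[str, str], Fraction] = {}
        for s in self.states:
            for t in self.states:
                c = Fraction(costs.get((s, t), 0))
                if s == t and c != 0:
                    raise ConfigurationError("cost(i->i) must be 0")
                if c < 0:
                    raise ConfigurationError("costs must be non-negative")
                self._costs[(s, t)] = c

    def cost(self, s: str, t: str) -> Fraction:
        return self._costs[(s, t)]

    @classmethod
    def gain_loss(
        cls, gain: int | Fraction = 2, loss: int | Fraction = 1
    ) -> "StepMatrix":
        """Binary asymmetric matrix; default makes a gain twice a loss."""
        return cls(
            (ABSENT, PRESENT),
            {(ABSENT, PRESENT): Fraction(gain), (PRESENT, ABSENT): Fraction(loss)},
        )

    @property
    def gain_loss_ratio(self) -> Fraction:
        """cost(absent->present) / cost(present->absent) for binary matrices."""
        loss = self.cost(PRESENT, ABSENT)
        if loss == 0:
            raise ConfigurationError("loss cost is 0; ratio undefined")
        return self.cost(ABSENT, PRESENT) / loss

    def __repr__(self) -> str:  # pragma: no cover
        return f"<StepMatrix states={self.states}>"


def default_step_matrix() -> StepMatrix:
    """The package default: gains cost 2, losses cost 1."""
    return StepMatrix.gain_loss(2, 1)


@dataclass
class CostTable:
    """Per node (by preorder index), per state: minimal subtree cost."""

    states: tuple[str, ...]
    table: dict[int, dict[str, object]]  # cost values: Fraction or INF

    def cost(self, node_index: int, state: str):
        return self.table[node_index][state]


@dataclass(frozen=True)
class EventCounts:
    gains: int
    losses: int

    @property
    def origin_count(self) -> int:
        return self.gains


@dataclass
class Reconstruction:
    """A full node -> state assignment achieving a (constrained) optimum."""

    node_states: dict[int, str]  # preorder index -> state
    total_cost: Fraction
    stem_state: str | None
    events: list[tuple[int, str]] = field(default_factory=list)
    # events: (child node index, "gain" | "loss"); index of the root means
    # the virtual stem edge.

    @property
    def gains(self) -> int:
        return sum(1 for _, kind in self.events if kind == "gain")

    @property
    def losses(self) -> int:
        return sum(1 for _, kind in self.events if kind == "loss")

    @property
    def origin_count(self) -> int:
        return self.gains

    def gain_edges(self) -> frozenset[int]:
        return frozenset(i for i, kind in self.events if kind == "gain")


@dataclass
class MPRSet:
    """Enumerated MPRs plus a truncation flag (never silently incomplete)."""

    reconstructions: list[Reconstruction]
    truncated: bool
    cost: Fraction

    def __len__(self) -> int:
        return len(self.reconstructions)

    def __iter__(self):
        return iter(self.reconstructions)


def count_events(rec: Reconstruction) -> EventCounts:
    """Typed gain/loss counts of a reconstruction (virtual stem included)."""
    return EventCounts(rec.gains, rec.losses)


# ---------------------------------------------------------------------------
# DP core


def _leaf_value(state: str | None, s: str, extra: tuple) -> tuple:
    zero = (Fraction(0),) + extra
    if state is None or state == MISSING or state == s:
        return zero
    return (INF,) + extra


def _resolve_states(bound: BoundCharacters, character: str) -> dict[str, str]:
    if character not in bound.characters:
        raise CharacterLookupError(
            f"character {character!r} not bound (have {bound.character_names})"
        )
    return bound.characters[character]


def _rule_for(edge_rules: Mapping[int, str] | None, node: Node) -> str:
    if edge_rules is None:
        return ALLOW
    return edge_rules.get(node.index, ALLOW)


def _trans_value(
    sm: StepMatrix, rule: str, s: str, t: str, gain_weight: int
) -> tuple:
    """(cost, weighted gain indicator) for one edge transition, or infinity."""
    is_gain = s == ABSENT and t == PRESENT
    if rule == NO_GAIN and is_gain:
        return (INF, 0)
    if rule == FORCED_GAIN and not is_gain:
        return (INF, 0)
    return (sm.cost(s, t), gain_weight if is_gain else 0)


def _add(a: tuple, b: tuple) -> tuple:
    return tuple(x + y for x, y in zip(a, b))


def _dp_tables(
    tree: PhyloTree,
    leaf_states: Mapping[str, str],
    sm: StepMatrix,
    edge_rules: Mapping[int, str] | None,
    gain_weight: int = 0,
) -> dict[int, dict[str, tuple]]:
    """Post-order fill of S_v(s) with tuple-valued costs.

    With ``gain_weight`` 0 the value is effectively (cost,); +1/-1 tracks
    (cost, +-gains) for the lexicographic origin-bound DP.
    """
    tables: dict[int, dict[str, tuple]] = {}
    extra = (0,)
    for node in tree.postorder():
        if node.is_leaf:
            obs = leaf_states.get(node.label)
            tables[node.index] = {
                s: _leaf_value(obs, s, extra) for s in sm.states
            }
            continue
        row: dict[str, tuple] = {}
        for s in sm.states:
            total = (Fraction(0), 0)
            for child in node.children:
                rule = _rule_for(edge_rules, child)
                best = min(
                    _add(
                        _trans_value(sm, rule, s, t, gain_weight),
                        tables[child.index][t],
                    )
                    for t in sm.states
                )
                total = _add(total, best)
            row[s] = total
        tables[node.index] = row
    return tables


def _root_value(
    tree: PhyloTree,
    tables: dict[int, dict[str, tuple]],
    sm: StepMatrix,
    stem_state: str | None,
    edge_rules: Mapping[int, str] | None,
    gain_weight: int = 0,
) -> tuple:
    root = tree.root
    if stem_state is None:
        return min(tables[root.index][s] for s in sm.states)
    rule = _rule_for(edge_rules, root)
    return min(
        _add(
            _trans_value(sm, rule, stem_state, s, gain_weight),
            tables[root.index][s],
        )
        for s in sm.states
    )


def min_cost(
    bound: BoundCharacters,
    character: str,
    sm: StepMatrix | None = None,
    stem_state: str | None = ABSENT,
    edge_rules: Mapping[int, str] | None = None,
) -> tuple[Fraction | float, CostTable]:
    """Minimum total transition cost of *character* on the bound tree.

    With ``stem_state`` fixed (default ``absent``) the optimum includes the
    cost of the virtual stem edge above the root; ``stem_state=None`` frees
    the root.  Returns the cost (``inf`` if no feasible assignment exists
    under *edge_rules*) and the filled DP table.
    """
    sm = sm or default_step_matrix()
    leaf_states = _resolve_states(bound, character)
    tables = _dp_tables(bound.tree, leaf_states, sm, edge_rules)
    total = _root_value(bound.tree, tables, sm, stem_state, edge_rules)
    cost_table = CostTable(
        sm.states,
        {i: {s: v[0] for s, v in row.items()} for i, row in tables.items()},
    )
    return total[0], cost_table


def origin_bounds(
    bound: BoundCharacters,
    character: str,
    sm: StepMatrix | None = None,
    stem_state: str | None = ABSENT,
    edge_rules: Mapping[int, str] | None = None,
) -> tuple[int, int]:
    """(min, max) number of gains over *all* MPRs, computed exactly by DP."""
    sm = sm or default_step_matrix()
    leaf_states = _resolve_states(bound, character)
    lo = _root_value(
        bound.tree,
        _dp_tables(bound.tree, leaf_states, sm, edge_rules, gain_weight=1),
        sm,
        stem_state,
        edge_rules,
        gain_weight=1,
    )
    hi = _root_value(
        bound.tree,
        _dp_tables(bound.tree, leaf_states, sm, edge_rules, gain_weight=-1),
        sm,
        stem_state,
        edge_rules,
        gain_weight=-1,
    )
    if lo[0] == INF:
        raise ConfigurationError("no feasible reconstruction; cost is infinite")
    return int(lo[1]), int(-hi[1])


# ---------------------------------------------------------------------------
# MPR enumeration


def _events_of(
    tree: PhyloTree, assignment: dict[int, str], stem_state: str | None
) -> list[tuple[int, str]]:
    events: list[tuple[int, str]] = []
    root = tree.root
    if stem_state is not None:
        s, t = stem_state, assignment[root.index]
        if (s, t) == (ABSENT, PRESENT):
            events.append((root.index, "gain"))
        elif (s, t) == (PRESENT, ABSENT):
            events.append((root.index, "loss"))
    for node in tree.preorder():
        for child in node.children:
            s, t = assignment[node.index], assignment[child.index]
            if (s, t) == (ABSENT, PRESENT):
                events.append((child.index, "gain"))
            elif (s, t) == (PRESENT, ABSENT):
                events.append((child.index, "loss"))
    return events


def _recompute_cost(
    tree: PhyloTree,
    assignment: dict[int, str],
    sm: StepMatrix,
    stem_state: str | None,
) -> Fraction:
    total = Fraction(0)
    if stem_state is not None:
        total += sm.cost(stem_state, assignment[tree.root.index])
    for node in tree.preorder():
        for child in node.children:
            total += sm.cost(assignment[node.index], assignment[child.index])
    return total


def enumerate_mprs(
    bound: BoundCharacters,
    character: str,
    sm: StepMatrix | None = None,
    stem_state: str | None = ABSENT,
    cap: int = 10000,
    edge_rules: Mapping[int, str] | None = None,
) -> MPRSet:
    """Backtrack every minimum-cost node-state assignment, up to *cap*.

    Enumeration order is deterministic: states in step-matrix order, nodes
    in preorder.  Each reconstruction is re-summed and verified against the
    DP optimum.  If more than *cap* MPRs exist the set is truncated and
    flagged, never silently shortened.
    """
    if cap < 1:
        raise ConfigurationError("cap must be >= 1")
    sm = sm or default_step_matrix()
    leaf_states = _resolve_states(bound, character)
    tree = bound.tree
    tables = _dp_tables(tree, leaf_states, sm, edge_rules)
    best = _root_value(tree, tables, sm, stem_state, edge_rules)
    if best[0] == INF:
        return MPRSet([], False, INF)

    def subtree_assignments(node: Node, s: str):
        """Yield assignments of node's subtree given node is in state s."""
        if node.is_leaf:
            yield {node.index: s}
            return
        per_child: list[list[dict[int, str]]] = []
        for child in node.children:
            rule = _rule_for(edge_rules, child)
            options = [
                _add(_trans_value(sm, rule, s, t, 0), tables[child.index][t])
                for t in sm.states
            ]
            opt = min(options)
            choices: list[dict[int, str]] = []
            for t, val in zip(sm.states, options):
                if val == opt:
                    choices.extend(subtree_assignments(child, t))
            per_child.append(choices)
        for combo in itertools.product(*per_child):
            merged = {node.index: s}
            for part in combo:
                merged.update(part)
            yield merged

    def root_assignments():
        root = tree.root
        for s in sm.states:
            if stem_state is None:
                val = tables[root.index][s]
            else:
                rule = _rule_for(edge_rules, root)
                val = _add(
                    _trans_value(sm, rule, stem_state, s, 0), tables[root.index][s]
                )
            if val == best:
                yield from subtree_assignments(root, s)

    recs: list[Reconstruction] = []
    truncated = False
    for assignment in root_assignments():
        if len(recs) >= cap:
            truncated = True
            break
        total = _recompute_cost(tree, assignment, sm, stem_state)
        assert total == best[0], "enumerated MPR does not re-sum to the optimum"
        recs.append(
            Reconstruction(
                node_states=assignment,
                total_cost=total,
                stem_state=stem_state,
                events=_events_of(tree, assignment, stem_state),
            )
        )
    return MPRSet(recs, truncated, best[0])


# ---------------------------------------------------------------------------
# exhaustive oracle


def brute_force_oracle(
    bound: BoundCharacters,
    character: str,
    sm: StepMatrix | None = None,
    stem_state: str | None = ABSENT,
    edge_rules: Mapping[int, str] | None = None,
    max_internal: int = 12,
) -> Fraction | float:
    """Exact minimum by enumerating all internal-node state assignments.

    Independent of the DP (no shared cost tables); used as the test oracle.
    Missing leaves take, per assignment, the cheapest feasible state.
    Refuses instances with more than *max_internal* internal nodes.
    """
    sm = sm or default_step_matrix()
    leaf_states = _resolve_states(bound, character)
    tree = bound.tree
    internal = [n for n in tree.preorder() if not n.is_leaf]
    if len(internal) > max_internal:
        raise OracleSizeError(
            f"{len(internal)} internal nodes exceeds limit {max_internal}"
        )
    best: Fraction | float = INF
    for combo in itertools.product(sm.states, repeat=len(internal)):
        assigned = {n.index: s for n, s in zip(internal, combo)}
        total: Fraction | float = Fraction(0)
        if stem_state is not None:
            rule = _rule_for(edge_rules, tree.root)
            total = _trans_value(
                sm, rule, stem_state, assigned[tree.root.index], 0
            )[0]
        for node in internal:
            s = assigned[node.index]
            for child in node.children:
                rule = _rule_for(edge_rules, child)
                if child.is_leaf:
                    obs = leaf_states.get(child.label)
                    if obs is None or obs == MISSING:
                        step = min(
                            _trans_value(sm, rule, s, t, 0)[0] for t in sm.states
                        )
                    else:
                        step = _trans_value(sm, rule, s, obs, 0)[0]
                else:
                    step = _trans_value(sm, rule, s, assigned[child.index], 0)[0]
                total = total + step
                if total == INF:
                    break
            if total == INF:
                break
        if total < best:
            best = total
    return best
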