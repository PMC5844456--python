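"""Competing origin hypotheses as constrained parsimony reconstructions.

A scenario names a set of *origins*; each origin is a group of one or more
clades whose stem edges are the only edges on which an absent->present
change is permitted (losses stay unconstrained).  With ``required`` set,
every listed stem edge must carry a gain.  The number of *origin events*
of a reconstruction is the number of origin groups whose edge set carries
at least one gain — a single hypothesised origin realised on two
non-sister clades of the working tree still counts once.

Ranking competing scenarios for the same character is by constrained
parsimony cost; a scenario with no finite-cost reconstruction is reported
as infeasible, not raised.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .errors import ConfigurationError
from .phylogeny import BoundCharacters
from .sankoff import (
    ABSENT,
    ALLOW,
    FORCED_GAIN,
    INF,
    NO_GAIN,
    MPRSet,
    StepMatrix,
    default_step_matrix,
    enumerate_mprs,
    min_cost,
    origin_bounds,
)

__all__ = [
    "Scenario",
    "ScenarioResult",
    "load_scenarios",
    "constrained_min_cost",
    "compare_scenarios",
]

_DATA = resources.files("chemotrace.data")


@dataclass(frozen=True)
class Scenario:
    """One origin hypothesis for a binary character."""

    label: str
    character: str
    origins: tuple[tuple[str, tuple[str, ...]], ...]  # (group name, clade labels)
    required: bool = True

    @property
    def allowed_clades(self) -> tuple[str, ...]:
        return tuple(c for _, clades in self.origins for c in clades)

    def validate_against(self, bound: BoundCharacters) -> None:
        seen: set[str] = set()
        for _, clades in self.origins:
            for clade in clades:
                if clade in seen:
                    raise ConfigurationError(
                        f"scenario {self.label}: clade {clade!r} listed twice"
                    )
                seen.add(clade)
                try:
                    bound.tree.find(clade)
                except KeyError as exc:
                    raise ConfigurationError(
                        f"scenario {self.label}: clade {clade!r} not in tree"
                    ) from exc


def load_scenarios(path: str | Path | None = None) -> list[Scenario]:
    """Read scenario definitions from YAML (defaults to the packaged six)."""
    if path is None:
        raw = yaml.safe_load((_DATA / "scenarios.yaml").read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    scenarios = []
    for entry in raw:
        origins = tuple(
            (str(group), tuple(clades))
            for group, clades in entry["origins"].items()
        )
        scenarios.append(
            Scenario(
                label=str(entry["label"]),
                character=str(entry["character"]),
                origins=origins,
                required=bool(entry.get("required", True)),
            )
        )
    return scenarios


def _edge_rules(scenario: Scenario, bound: BoundCharacters) -> dict[int, str]:
    """Map every node index to its edge rule under *scenario*.

    The rule of a node governs the edge from its parent (for the root: the
    virtual stem).  Default is ``no_gain``; clade stems listed by the
    scenario are ``forced_gain`` (required) or ``allow``.
    """
    scenario.validate_against(bound)
    rules = {node.index: NO_GAIN for node in bound.tree.preorder()}
    for clade in scenario.allowed_clades:
        node = bound.tree.find(clade)
        rules[node.index] = FORCED_GAIN if scenario.required else ALLOW
    return rules


@dataclass
class ScenarioResult:
    scenario: Scenario
    feasible: bool
    cost: Fraction | float
    mprs: MPRSet | None
    origin_events: int | None  # groups carrying >= 1 gain (same in every MPR
    # when required; otherwise the minimum over enumerated MPRs)
    gains_min: int | None
    gains_max: int | None

    @property
    def label(self) -> str:
        return self.scenario.label


def _origin_events(scenario: Scenario, bound: BoundCharacters, rec) -> int:
    gained = rec.gain_edges()
    hit = 0
    for _, clades in scenario.origins:
        edge_idxs = {bound.tree.find(c).index for c in clades}
        if edge_idxs & gained:
            hit += 1
    return hit


def constrained_min_cost(
    bound: BoundCharacters,
    character: str | None = None,
    sm: StepMatrix | None = None,
    scenario: Scenario | None = None,
    stem_state: str | None = ABSENT,
    cap: int = 10000,
) -> ScenarioResult:
    """Minimum-cost reconstructions of a character under a scenario.

    Runs the Sankoff DP with edge-specific rules (gains forbidden off the
    scenario's stems, forced on them when required).  An infeasible
    scenario — e.g. no allowed gain edge for a character with present
    leaves — yields ``feasible=False`` rather than an exception.
    """
    if scenario is None:
        raise ConfigurationError("a scenario is required")
    sm = sm or default_step_matrix()
    character = character or scenario.character
    rules = _edge_rules(scenario, bound)
    cost, _ = min_cost(bound, character, sm, stem_state, edge_rules=rules)
    if cost == INF:
        return ScenarioResult(scenario, False, INF, None, None, None, None)
    mprs = enumerate_mprs(bound, character, sm, stem_state, cap, edge_rules=rules)
    g_lo, g_hi = origin_bounds(bound, character, sm, stem_state, edge_rules=rules)
    events = min(_origin_events(scenario, bound, r) for r in mprs)
    return ScenarioResult(scenario, True, cost, mprs, events, g_lo, g_hi)


def compare_scenarios(
    bound: BoundCharacters,
    scenarios: Sequence[Scenario],
    sm: StepMatrix | None = None,
    stem_state: str | None = ABSENT,
    cap: int = 10000,
) -> pd.DataFrame:
    """Rank >= 2 scenarios for one character by constrained parsimony cost.

    Returns a table with one row per scenario, ordered deterministically by
    (cost, label); ``delta_cost`` is relative to the best feasible scenario
    and ``delta_unconstrained`` to the unconstrained minimum.
    """
    if len(scenarios) < 2:
        raise ConfigurationError("need at least 2 scenarios to compare")
    labels = [s.label for s in scenarios]
    if len(set(labels)) != len(labels):
        raise ConfigurationError(f"duplicate scenario labels: {sorted(labels)}")
    characters = {s.character for s in scenarios}
    if len(characters) != 1:
        raise ConfigurationError(
            f"scenarios mix characters {sorted(characters)}; compare one at a time"
        )
    character = characters.pop()
    sm = sm or default_step_matrix()
    base_cost, _ = min_cost(bound, character, sm, stem_state)
    rows = []
    for scn in scenarios:
        res = constrained_min_cost(bound, character, sm, scn, stem_state, cap)
        rows.append(
            {
                "scenario": scn.label,
                "character": character,
                "feasible": res.feasible,
                "cost": float(res.cost) if res.feasible else float("inf"),
                "origin_events": res.origin_events,
                "gains_min": res.gains_min,
                "gains_max": res.gains_max,
                "n_mprs": len(res.mprs) if res.mprs is not None else 0,
            }
        )
    df = pd.DataFrame(rows).sort_values(["cost", "scenario"], kind="stable")
    finite = df.loc[df["feasible"], "cost"]
    best = finite.min() if not finite.empty else float("nan")
    df["delta_cost"] = df["cost"] - best
    df["delta_unconstrained"] = df["cost"] - float(base_cost)
    return df.reset_index(drop=True)
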