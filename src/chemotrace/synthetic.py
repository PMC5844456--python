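"""Synthetic data: trees, simulated trait histories, noisy detection tables,
and GC calibration fixtures, plus ancestry-recovery experiments.

The trait simulator runs a two-state continuous-time Markov chain
root-to-tips from state ``absent``, with gain rate q01 and loss rate q10
(events per unit branch length), drawing exact event times per edge, so
asymmetric gain/loss regimes analogous to the 2:1 step matrix are
expressible.  All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .chemo_matrix import (
    CompoundRecord,
    DetectionMatrix,
    DetectionState,
    Taxon,
    CodingPolicy,
)
from .errors import ConfigurationError
from .phylogeny import BoundCharacters, Node, PhyloTree
from .retention_index import AlkaneLadder, Peak
from .sankoff import ABSENT, PRESENT, StepMatrix, min_cost, origin_bounds

__all__ = [
    "SimulationConfig",
    "SimulatedHistory",
    "random_tree",
    "simulate_history",
    "recovery_experiment",
    "make_detection_fixture",
    "make_gc_fixture",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a trait-simulation / recovery experiment."""

    n_leaves: int = 24
    polytomy_prob: float = 0.25
    q01: float = 0.1   # gain rate, events per unit branch length
    q10: float = 0.2   # loss rate
    branch_length: float = 1.0
    replicates: int = 100
    seed: int = 0
    condition: str | None = None  # None | "single_gain"

    def __post_init__(self) -> None:
        if self.q01 < 0 or self.q10 < 0:
            raise ConfigurationError("rates must be >= 0")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if not 0 <= self.polytomy_prob <= 1:
            raise ConfigurationError("polytomy_prob must be in [0, 1]")
        if self.condition not in (None, "single_gain"):
            raise ConfigurationError(f"unknown condition {self.condition!r}")


@dataclass
class SimulatedHistory:
    """True states and events of one simulated character history."""

    node_states: dict[int, str]          # preorder index -> state
    events: list[tuple[int, str, float]]  # (child index, gain/loss, time on edge)
    tip_states: dict[str, str]
    seed: int | None = None

    @property
    def n_gains(self) -> int:
        return sum(1 for _, kind, _ in self.events if kind == "gain")

    @property
    def n_losses(self) -> int:
        return sum(1 for _, kind, _ in self.events if kind == "loss")


def random_tree(
    n_leaves: int, polytomy_prob: float = 0.0, rng: np.random.Generator | None = None
) -> PhyloTree:
    """Random rooted tree by sequential leaf attachment.

    Each new leaf either subdivides a uniformly chosen leaf edge (creating a
    new binary node) or, with probability *polytomy_prob*, joins the chosen
    leaf's parent as an extra child, so hard polytomies of any degree arise.
    """
    if n_leaves < 2:
        raise ConfigurationError("need at least 2 leaves")
    rng = rng if rng is not None else np.random.default_rng()
    root = Node("root")
    a, b = Node("T1"), Node("T2")
    root.add(a)
    root.add(b)
    leaves = [a, b]
    for i in range(3, n_leaves + 1):
        target = leaves[int(rng.integers(len(leaves)))]
        new = Node(f"T{i}")
        if rng.random() < polytomy_prob:
            target.parent.add(new)
        else:
            parent = target.parent
            joint = Node()
            parent.children[parent.children.index(target)] = joint
            joint.parent = parent
            joint.add(target)
            joint.add(new)
        leaves.append(new)
    return PhyloTree(root)


def _evolve_edge(
    state: str, length: float, q01: float, q10: float, rng: np.random.Generator
) -> tuple[str, list[tuple[str, float]]]:
    """Run the 2-state CTMC along one edge; returns end state and flips."""
    t = 0.0
    flips: list[tuple[str, float]] = []
    while True:
        rate = q01 if state == ABSENT else q10
        if rate == 0:
            return state, flips
        t += rng.exponential(1.0 / rate)
        if t >= length:
            return state, flips
        state = PRESENT if state == ABSENT else ABSENT
        flips.append(("gain" if state == PRESENT else "loss", t))


def simulate_history(
    tree: PhyloTree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedHistory:
    """Simulate one binary-character history on *tree* under *config*.

    The root starts absent.  With ``condition="single_gain"`` the stochastic
    process is replaced by exactly one gain on a uniformly chosen edge
    (rates are ignored) — the regime where parsimony recovery should be
    exact.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    states: dict[int, str] = {tree.root.index: ABSENT}
    events: list[tuple[int, str, float]] = []
    if config.condition == "single_gain":
        non_root = [n for n in tree.preorder() if n.parent is not None]
        chosen = non_root[int(rng.integers(len(non_root)))]
        for node in tree.preorder():
            if node.parent is None:
                continue
            inherited = states[node.parent.index]
            if node is chosen:
                states[node.index] = PRESENT
                events.append(
                    (node.index, "gain", float(rng.uniform(0, config.branch_length)))
                )
            else:
                states[node.index] = inherited
    else:
        for node in tree.preorder():
            if node.parent is None:
                continue
            start = states[node.parent.index]
            end, flips = _evolve_edge(
                start, config.branch_length, config.q01, config.q10, rng
            )
            states[node.index] = end
            events.extend((node.index, kind, when) for kind, when in flips)
    tips = {leaf.label: states[leaf.index] for leaf in tree.leaves()}
    return SimulatedHistory(states, events, tips, seed=config.seed)


def _bind_tips(tree: PhyloTree, tips: Mapping[str, str], character: str):
    return BoundCharacters(tree, {character: dict(tips)})


def recovery_experiment(
    config: SimulationConfig,
    tree: PhyloTree | None = None,
    sm: StepMatrix | None = None,
) -> pd.DataFrame:
    """Simulate-and-reconstruct replicates; per-replicate recovery metrics.

    Each replicate simulates a history, reconstructs with the asymmetric
    step matrix (default gain 2 : loss 1, stem fixed absent), and compares
    the minimum origin count over MPRs to the true number of gains.
    Columns: true_gains, true_losses, min_origins, max_origins, cost,
    exact_recovery (min_origins == true_gains), root_correct.
    """
    sm = sm or StepMatrix.gain_loss(2, 1)
    rng = np.random.default_rng(config.seed)
    rows = []
    for rep in range(config.replicates):
        t = tree if tree is not None else random_tree(
            config.n_leaves, config.polytomy_prob, rng
        )
        hist = simulate_history(t, config, rng)
        bound = _bind_tips(t, hist.tip_states, "trait")
        cost, table = min_cost(bound, "trait", sm, stem_state=ABSENT)
        lo, hi = origin_bounds(bound, "trait", sm, stem_state=ABSENT)
        # root state of the min-gain optimum: absent iff keeping the root
        # absent is at least as cheap (stem gain charged) as present
        root_cost_absent = table.cost(t.root.index, ABSENT)
        root_cost_present = table.cost(t.root.index, PRESENT) + sm.cost(
            ABSENT, PRESENT
        )
        recon_root = ABSENT if root_cost_absent <= root_cost_present else PRESENT
        rows.append(
            {
                "replicate": rep,
                "seed": config.seed,
                "true_gains": hist.n_gains,
                "true_losses": hist.n_losses,
                "cost": float(cost),
                "min_origins": lo,
                "max_origins": hi,
                "exact_recovery": lo == hist.n_gains,
                "root_correct": recon_root == ABSENT,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# detection-table and GC fixtures


def make_detection_fixture(
    tree: PhyloTree,
    history: SimulatedHistory,
    library: Mapping[str, CompoundRecord],
    policy: CodingPolicy,
    character: str,
    noise: float = 0.0,
    rng: np.random.Generator | None = None,
) -> DetectionMatrix:
    """Emit a detection table consistent with a simulated history.

    A present tip gets a ``detected`` cell for one compound sampled from the
    character's contributing set and ``not_detected`` elsewhere; an absent
    tip is all ``not_detected``.  Each cell is then independently replaced
    by ``inconclusive`` with probability *noise*.  With ``noise=0``,
    ``binarize`` recovers the simulated tip states exactly.
    """
    if not 0 <= noise < 1:
        raise ConfigurationError("noise must be in [0, 1)")
    rng = rng if rng is not None else np.random.default_rng()
    codes = list(policy.characters[character])
    compounds = [c for c in codes if c in library]
    if not compounds:
        raise ConfigurationError(
            f"no compound of character {character!r} is in the library"
        )
    all_codes = list(library)
    taxa = [Taxon(leaf.label) for leaf in tree.leaves()]
    cells: dict[tuple[str, str], DetectionState] = {}
    for taxon in taxa:
        chosen = compounds[int(rng.integers(len(compounds)))]
        for code in all_codes:
            if history.tip_states[taxon.name] == PRESENT and code == chosen:
                cells[(taxon.name, code)] = DetectionState.DETECTED
            else:
                cells[(taxon.name, code)] = DetectionState.NOT_DETECTED
    if noise > 0:
        for key in list(cells):
            if rng.random() < noise:
                cells[key] = DetectionState.INCONCLUSIVE
    return DetectionMatrix(taxa, all_codes, cells)


def make_gc_fixture(
    library: Mapping[str, CompoundRecord],
    c_min: int = 9,
    c_max: int = 36,
    t_start: float = 2.0,
    minutes_per_carbon: float = 1.0,
) -> tuple[AlkaneLadder, list[Peak]]:
    """Build an alkane ladder and peaks whose RIs equal the library values.

    The ladder is linear in carbon number (one alkane per carbon, as in a
    C9-C36 standard mix on a linear temperature programme); each library
    compound's retention time is back-computed so that Kovats interpolation
    recovers its reference RI exactly, and its diagnostic ions plus
    molecular ion are attached to the peak.
    """
    ladder = AlkaneLadder(
        tuple(
            (n, t_start + minutes_per_carbon * n) for n in range(c_min, c_max + 1)
        )
    )
    peaks: list[Peak] = []
    for code in library:
        rec = library[code]
        if rec.ri is None:
            continue
        if not 100 * c_min <= rec.ri <= 100 * c_max:
            raise ConfigurationError(
                f"{code}: RI {rec.ri} outside ladder span "
                f"[{100 * c_min}, {100 * c_max}]"
            )
        n0 = min(int(rec.ri // 100), c_max - 1)
        t0 = t_start + minutes_per_carbon * n0
        t1 = t_start + minutes_per_carbon * (n0 + 1)
        rt = t0 + (rec.ri / 100.0 - n0) * (t1 - t0)
        ions = tuple(rec.diagnostic_ions)
        if rec.molecular_ion is not None:
            ions = (rec.molecular_ion,) + ions
        peaks.append(Peak(rt, ions, peak_id=code))
    return ladder, peaks
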