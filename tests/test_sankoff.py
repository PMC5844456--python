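"""The Sankoff engine: DP correctness, MPR enumeration, event counting."""

from fractions import Fraction

import numpy as np
import pytest

import chemotrace as ct
from chemotrace.errors import ConfigurationError, OracleSizeError
from chemotrace.sankoff import ABSENT, INF, MISSING, PRESENT, StepMatrix

from conftest import bind_states, hartigan_length, random_binary_instance

SM21 = StepMatrix.gain_loss(2, 1)


class TestStepMatrix:
    def test_default_gain_loss_ratio_is_two(self):
        assert ct.default_step_matrix().gain_loss_ratio == Fraction(2)
        assert SM21.cost(ABSENT, PRESENT) == 2
        assert SM21.cost(PRESENT, ABSENT) == 1

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ConfigurationError):
            StepMatrix(("a", "b"), {("a", "a"): 1})
        with pytest.raises(ConfigurationError):
            StepMatrix(("a", "b"), {("a", "b"): -1})


class TestMinCost:
    def test_cherry_one_present_single_gain_beats_root_present(self):
        tree = ct.read_tree("(A,B);")
        b = bind_states(tree, {"A": PRESENT, "B": ABSENT})
        cost, _ = ct.min_cost(b, "trait", SM21, stem_state=ABSENT)
        assert cost == 2
        assert ct.brute_force_oracle(b, "trait", SM21, stem_state=ABSENT) == 2

    def test_all_missing_leaves_cost_zero(self):
        tree = ct.read_tree("((A,B),(C,D,E));")
        b = bind_states(tree, {l.label: MISSING for l in tree.leaves()})
        cost, _ = ct.min_cost(b, "trait", SM21)
        assert cost == 0

    @pytest.mark.parametrize("n,k", [(3, 1), (4, 2), (5, 1), (6, 4), (7, 7)])
    def test_star_tree_closed_form(self, n, k):
        labels = [f"T{i}" for i in range(1, n + 1)]
        tree = ct.read_tree("(" + ",".join(labels) + ");")
        states = {l: PRESENT if i < k else ABSENT for i, l in enumerate(labels)}
        b = bind_states(tree, states)
        cost, _ = ct.min_cost(b, "trait", SM21, stem_state=ABSENT)
        assert cost == min(2 * k, 2 + (n - k))
        assert cost == ct.brute_force_oracle(b, "trait", SM21, stem_state=ABSENT)

    def test_dp_equals_brute_force_on_random_instances(self, rng):
        for _ in range(500):
            tree, states = random_binary_instance(rng, missing=0.2)
            gain = Fraction(int(rng.integers(0, 5)))
            loss = Fraction(int(rng.integers(0, 5)))
            sm = StepMatrix.gain_loss(gain, loss)
            stem = [ABSENT, PRESENT, None][int(rng.integers(3))]
            b = bind_states(tree, states)
            dp, _ = ct.min_cost(b, "trait", sm, stem_state=stem)
            assert dp == ct.brute_force_oracle(b, "trait", sm, stem_state=stem)

    def test_unit_cost_free_root_equals_hartigan_fitch(self, rng):
        sm = StepMatrix.gain_loss(1, 1)
        for _ in range(300):
            tree, states = random_binary_instance(rng, n_max=12)
            b = bind_states(tree, states)
            cost, _ = ct.min_cost(b, "trait", sm, stem_state=None)
            assert cost == hartigan_length(tree, states)

    def test_monotone_in_every_cost_entry(self, rng):
        for _ in range(50):
            tree, states = random_binary_instance(rng)
            b = bind_states(tree, states)
            base, _ = ct.min_cost(b, "trait", StepMatrix.gain_loss(2, 1))
            up_gain, _ = ct.min_cost(b, "trait", StepMatrix.gain_loss(3, 1))
            up_loss, _ = ct.min_cost(b, "trait", StepMatrix.gain_loss(2, 2))
            assert up_gain >= base and up_loss >= base

    def test_adding_missing_leaf_never_changes_cost(self, rng):
        for _ in range(50):
            tree, states = random_binary_instance(rng)
            b = bind_states(tree, states)
            base, _ = ct.min_cost(b, "trait", SM21)
            # graft a dataless leaf under a random internal node
            newick = tree.newick()
            host = states and sorted(states)[int(rng.integers(len(states)))]
            grown = ct.read_tree(newick.replace(host, f"({host},Ghost_leaf)", 1))
            b2 = bind_states(grown, {**states, "Ghost_leaf": MISSING})
            cost2, _ = ct.min_cost(b2, "trait", SM21)
            assert cost2 == base

    def test_unknown_character_raises(self, bound):
        with pytest.raises(ct.errors.CharacterLookupError):
            ct.min_cost(bound, "petal-colour")


class TestEnumerateMprs:
    def test_cherry_both_present_unique_stem_gain(self):
        tree = ct.read_tree("(A,B);")
        b = bind_states(tree, {"A": PRESENT, "B": PRESENT})
        mprs = ct.enumerate_mprs(b, "trait", SM21, stem_state=ABSENT)
        assert len(mprs) == 1 and mprs.cost == 2
        (rec,) = mprs
        counts = ct.count_events(rec)
        assert (counts.gains, counts.losses) == (1, 0)
        assert rec.node_states[tree.root.index] == PRESENT

    def test_symmetric_cherry_free_root_has_two_mprs(self):
        tree = ct.read_tree("(A,B);")
        b = bind_states(tree, {"A": PRESENT, "B": ABSENT})
        mprs = ct.enumerate_mprs(
            b, "trait", StepMatrix.gain_loss(1, 1), stem_state=None
        )
        assert len(mprs) == 2
        roots = {r.node_states[tree.root.index] for r in mprs}
        assert roots == {ABSENT, PRESENT}

    def test_all_absent_tree_has_one_eventless_mpr(self):
        tree = ct.read_tree("((A,B),(C,D));")
        b = bind_states(tree, {l.label: ABSENT for l in tree.leaves()})
        mprs = ct.enumerate_mprs(b, "trait", SM21)
        assert len(mprs) == 1
        counts = ct.count_events(mprs.reconstructions[0])
        assert (counts.gains, counts.losses, counts.origin_count) == (0, 0, 0)

    def test_every_mpr_resums_to_minimum_and_is_unique(self, rng):
        for _ in range(100):
            tree, states = random_binary_instance(rng, missing=0.15)
            b = bind_states(tree, states)
            best, _ = ct.min_cost(b, "trait", SM21)
            mprs = ct.enumerate_mprs(b, "trait", SM21, cap=5000)
            assert not mprs.truncated
            seen = set()
            for rec in mprs:
                assert rec.total_cost == best
                key = tuple(sorted(rec.node_states.items()))
                assert key not in seen
                seen.add(key)

    def test_cost_identity_two_gains_plus_losses(self, rng):
        # under gain=2/loss=1 with stem fixed absent, cost == 2g + l exactly
        for _ in range(100):
            tree, states = random_binary_instance(rng, missing=0.15)
            b = bind_states(tree, states)
            for rec in ct.enumerate_mprs(b, "trait", SM21, cap=5000):
                assert rec.total_cost == 2 * rec.gains + rec.losses

    def test_origin_bounds_agree_with_enumeration(self, rng):
        for _ in range(100):
            tree, states = random_binary_instance(rng, missing=0.2)
            b = bind_states(tree, states)
            mprs = ct.enumerate_mprs(b, "trait", SM21, cap=5000)
            gains = [r.gains for r in mprs]
            assert ct.origin_bounds(b, "trait", SM21) == (min(gains), max(gains))

    def test_cap_sets_truncation_flag(self):
        # unit-cost star with 2 present / 2 absent leaves has several MPRs
        tree = ct.read_tree("(A,B,C,D);")
        b = bind_states(
            tree, {"A": PRESENT, "B": PRESENT, "C": ABSENT, "D": ABSENT}
        )
        sm = StepMatrix.gain_loss(1, 1)
        full = ct.enumerate_mprs(b, "trait", sm, stem_state=None)
        assert len(full) > 1 and not full.truncated
        capped = ct.enumerate_mprs(b, "trait", sm, stem_state=None, cap=1)
        assert len(capped) == 1 and capped.truncated


class TestOracle:
    def test_refuses_oversized_instances(self, rng):
        tree = ct.random_tree(40, 0.0, rng)
        b = bind_states(tree, {l.label: ABSENT for l in tree.leaves()})
        with pytest.raises(OracleSizeError):
            ct.brute_force_oracle(b, "trait", SM21)


class TestCompositeReconstruction:
    def test_benzoquinone_class_needs_at_least_two_origins(self, bound):
        lo, hi = ct.origin_bounds(bound, "BQ-class", SM21, stem_state=ABSENT)
        assert lo >= 2
        mprs = ct.enumerate_mprs(bound, "BQ-class", SM21, cap=10000)
        assert not mprs.truncated
        assert all(r.origin_count >= 2 for r in mprs)

    def test_naphthoquinone_reconstruction_is_finite_and_consistent(self, bound):
        cost, _ = ct.min_cost(bound, "NQ-class", SM21)
        assert cost < INF
        for rec in ct.enumerate_mprs(bound, "NQ-class", SM21, cap=10000):
            assert rec.total_cost == cost
            assert rec.total_cost == 2 * rec.gains + rec.losses
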