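"""Walk geometry: vertex classification, feature counting, atmospheres."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trailzeros import (
    Direction,
    DIRECTIONS,
    FeatureCounts,
    LatticeWalk,
    ModelWeights,
    WalkError,
    classify_doubly_visited_site,
    count_features,
    legal_continuations,
)
from conftest import random_walk

E, N, W, S = Direction.E, Direction.N, Direction.W, Direction.S


class TestClassification:
    @pytest.mark.parametrize(
        "pass_a, pass_b, expected",
        [
            # transversal straight passages cross
            ((E, E), (N, N), "crossing"),
            ((W, W), (S, S), "crossing"),
            # both passages turn: touching corners, a collision
            ((E, N), (W, S), "collision"),
            # loop endpoint: fewer than four bonds cannot cross
            ((None, E), (S, None), "collision"),
            # one straight passage, one endpoint-degenerate half passage
            ((E, E), (None, N), "collision"),
        ],
    )
    def test_examples(self, pass_a, pass_b, expected):
        assert classify_doubly_visited_site(pass_a, pass_b) == expected

    def test_order_invariance(self):
        cases = [((E, E), (N, N)), ((E, N), (W, S)), ((None, E), (S, None))]
        for a, b in cases:
            assert classify_doubly_visited_site(a, b) == \
                classify_doubly_visited_site(b, a)

    def test_lattice_symmetry_invariance(self):
        """Classification is unchanged under the 8 square-lattice symmetries."""
        def transform(d, k, reflect):
            x, y = d.dx, d.dy
            if reflect:
                x, y = x, -y
            for _ in range(k):
                x, y = -y, x
            return {(1, 0): E, (0, 1): N, (-1, 0): W, (0, -1): S}[(x, y)]

        cases = [((E, E), (N, N)), ((E, N), (W, S)), ((E, E), (None, N)),
                 ((None, E), (S, None))]
        for a, b in cases:
            ref = classify_doubly_visited_site(a, b)
            for k in range(4):
                for reflect in (False, True):
                    ta = tuple(None if d is None else transform(d, k, reflect)
                               for d in a)
                    tb = tuple(None if d is None else transform(d, k, reflect)
                               for d in b)
                    assert classify_doubly_visited_site(ta, tb) == ref

    def test_shared_bond_is_structural_error(self):
        with pytest.raises(WalkError):
            classify_doubly_visited_site((E, N), (S.opposite, S))


class TestFeatureCounts:
    def test_straight_rod_on_wall(self):
        w = ModelWeights.isat(surface=True)
        f = count_features(LatticeWalk("EEE", surface=True), w)
        assert (f.n_coll, f.n_cross, f.n_straight, f.n_surface) == (0, 0, 2, 3)

    def test_rod_site_contact_convention(self):
        w = ModelWeights.isat(surface=True, surface_convention="sites")
        f = count_features(LatticeWalk("EEE", surface=True), w)
        # three wall sites beyond the anchored start
        assert f.n_surface == 3

    def test_square_loop_is_endpoint_collision(self, isat):
        f = count_features(LatticeWalk("ENWS"), isat)
        assert (f.n_coll, f.n_cross, f.n_straight) == (1, 0, 0)

    def test_hand_laid_crossing(self, isat):
        # (0,0)->(1,0)->(2,0)->(2,1)->(1,1)->(1,0)->(1,-1): site (1,0) is
        # passed straight through horizontally then vertically
        f = count_features(LatticeWalk("EENWSS"), isat)
        assert (f.n_coll, f.n_cross, f.n_straight) == (0, 1, 0)

    def test_reversal_invariance(self, isat):
        rng = np.random.default_rng(7)
        for _ in range(50):
            walk = random_walk(isat, 14, rng)
            if len(walk) == 0:
                continue
            f = count_features(walk, isat)
            r = count_features(walk.reversed(), isat)
            assert (f.n_coll, f.n_cross, f.n_straight) == \
                (r.n_coll, r.n_cross, r.n_straight)

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError):
            FeatureCounts(n=4, n_coll=3)
        with pytest.raises(ValueError):
            FeatureCounts(n=3, n_straight=3)
        with pytest.raises(ValueError):
            FeatureCounts(n=2, n_surface=3)


class TestWalkInvariants:
    def test_bond_reuse_rejected(self):
        with pytest.raises(WalkError):
            LatticeWalk("EW")

    def test_triple_visit_rejected(self):
        # two loops through the origin: third occupancy via a fresh bond
        with pytest.raises(WalkError):
            LatticeWalk("ENWSWSEN")

    def test_below_wall_rejected(self):
        with pytest.raises(WalkError):
            LatticeWalk("S", surface=True)
        # the same walk is fine in the bulk
        assert len(LatticeWalk("S")) == 1

    def test_surface_start_off_wall_rejected(self):
        with pytest.raises(WalkError):
            LatticeWalk("E", start=(0, 2), surface=True)


class TestAtmosphere:
    def test_empty_walk_bulk(self, isat):
        assert legal_continuations(LatticeWalk(), isat) == set(DIRECTIONS)

    def test_empty_walk_on_wall(self):
        w = ModelWeights.isat(surface=True)
        atm = legal_continuations(LatticeWalk(surface=True), w)
        assert atm == {E, N, W}

    def test_closed_loop_can_leave_through_free_bonds(self, isat):
        # after E,N,W,S the head rests on the doubly occupied start; E and N
        # would reuse bonds, while W and S leave through fresh bonds and do
        # not occupy the origin a third time
        atm = legal_continuations(LatticeWalk("ENWS"), isat)
        assert atm == {W, S}

    def test_visaw_forbids_crossing_move(self):
        visaw = ModelWeights.visaw()
        isat = ModelWeights.isat()
        walk = LatticeWalk("EENWS")  # head on (1,0), straight exit S crosses
        assert legal_continuations(walk, isat) == {S}
        # all other bonds at the head are used, so VISAW is trapped here
        assert legal_continuations(walk, visaw) == set()

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(DIRECTIONS), min_size=1, max_size=16))
    def test_any_legal_prefix_has_reversal_invariant_features(self, dirs):
        """The longest legal prefix of an arbitrary direction string has
        the same interaction features when traversed from either end."""
        isat = ModelWeights.isat()
        steps = []
        for d in dirs:
            try:
                LatticeWalk(steps + [d])
            except WalkError:
                break
            steps.append(d)
        if not steps:
            return
        walk = LatticeWalk(steps)
        f = count_features(walk, isat)
        r = count_features(walk.reversed(), isat)
        assert (f.n_coll, f.n_cross, f.n_straight) == \
            (r.n_coll, r.n_cross, r.n_straight)
        assert f.n_interactions <= len(walk) // 2

    def test_grown_walks_respect_model_constraints(self):
        rng = np.random.default_rng(3)
        visaw = ModelWeights.visaw()
        for _ in range(30):
            walk = random_walk(visaw, 16, rng)
            feats = count_features(walk, visaw)  # raises on any crossing
            assert feats.n_cross == 0
            assert max(walk.visit_counts().values()) <= 2
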