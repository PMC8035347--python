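import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from fish3d.config import RunConfig
from fish3d.pairing import (
    BREAKAPART,
    COLOCALIZED,
    call_pairs,
    distance_3d,
    greedy_match,
)
from conftest import make_spot
from oracles import greedy_pairs_direct


class TestDistance:
    def test_identical_positions(self):
        a = make_spot(1.0, 2.0, 3.0)
        b = make_spot(1.0, 2.0, 3.0, channel="TRITC")
        assert distance_3d(a, b) == 0.0

    def test_three_four_five(self):
        assert distance_3d(
            make_spot(0, 0, 0), make_spot(3.0, 4.0, 0.0, channel="TRITC")
        ) == pytest.approx(5.0)

    def test_two_layers_apart_is_twice_the_z_interval(self):
        # same pixel, layers 0 and 2 at 0.6 μm interval -> 1.2 μm
        a = make_spot(1.6, 1.6, 0 * 0.6)
        b = make_spot(1.6, 1.6, 2 * 0.6, channel="TRITC")
        assert distance_3d(a, b) == pytest.approx(1.2)

    def test_symmetry(self, rng):
        a = make_spot(*rng.random(3) * 10)
        b = make_spot(*rng.random(3) * 10, channel="TRITC")
        assert distance_3d(a, b) == distance_3d(b, a)


class TestGreedyMatch:
    def test_single_pair(self):
        f = [make_spot(0, 0, 0, "FITC", 0)]
        t = [make_spot(1, 0, 0, "TRITC", 0)]
        pairs, un_f, un_t = greedy_match(f, t)
        assert len(pairs) == 1 and not un_f and not un_t

    def test_greedy_rule_not_minimum_total_assignment(self):
        # d(F1,T1)=1, d(F2,T1)=2, d(F1,T2)=3, d(F2,T2)=10
        # greedy accepts {(F1,T1), (F2,T2)}; optimal total would be 2+3=5
        f1 = make_spot(0, 0, 0, "FITC", 0)
        f2 = make_spot(-1, 0, 0, "FITC", 1)
        t1 = make_spot(1, 0, 0, "TRITC", 0)
        t2 = make_spot(-11, 0, 0, "TRITC", 1)
        pairs, _, _ = greedy_match([f1, f2], [t1, t2])
        got = {(p.fitc.id, p.tritc.id, round(p.distance_um, 6)) for p in pairs}
        assert got == {(0, 0, 1.0), (1, 1, 10.0)}

    def test_no_tritc_leaves_all_fitc_unpaired(self):
        f = [make_spot(0, 0, 0, "FITC", 0), make_spot(5, 0, 0, "FITC", 1)]
        pairs, un_f, un_t = greedy_match(f, [])
        assert pairs == [] and len(un_f) == 2 and un_t == []

    def test_pair_count_is_min_of_channel_counts(self, rng):
        for _ in range(50):
            nf, nt = rng.integers(0, 7, size=2)
            f = [make_spot(*rng.random(3) * 5, "FITC", i) for i in range(nf)]
            t = [make_spot(*rng.random(3) * 5, "TRITC", i) for i in range(nt)]
            pairs, un_f, un_t = greedy_match(f, t)
            assert len(pairs) == min(nf, nt)
            assert len(un_f) == nf - len(pairs)
            assert len(un_t) == nt - len(pairs)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            nf, nt = rng.integers(1, 7, size=2)
            fpos = [tuple(rng.random(3) * 5) for _ in range(nf)]
            tpos = [tuple(rng.random(3) * 5) for _ in range(nt)]
            f = [make_spot(*p, "FITC", i) for i, p in enumerate(fpos)]
            t = [make_spot(*p, "TRITC", i) for i, p in enumerate(tpos)]
            pairs, _, _ = greedy_match(f, t)
            got = [(p.fitc.id, p.tritc.id) for p in pairs]
            assert sorted(got) == sorted(greedy_pairs_direct(fpos, tpos))

    def test_permutation_invariance(self, rng):
        fpos = [tuple(rng.random(3) * 5) for _ in range(5)]
        tpos = [tuple(rng.random(3) * 5) for _ in range(5)]
        f = [make_spot(*p, "FITC", i) for i, p in enumerate(fpos)]
        t = [make_spot(*p, "TRITC", i) for i, p in enumerate(tpos)]
        base = {(p.fitc.id, p.tritc.id) for p in greedy_match(f, t)[0]}
        for _ in range(5):
            perm_f = list(rng.permutation(len(f)))
            perm_t = list(rng.permutation(len(t)))
            pairs, _, _ = greedy_match([f[i] for i in perm_f], [t[i] for i in perm_t])
            assert {(p.fitc.id, p.tritc.id) for p in pairs} == base

    def test_mutually_nearest_pairs_equal_optimal_assignment(self, rng):
        # spread sites far apart so closest pairs are mutually nearest
        for _ in range(20):
            n = int(rng.integers(2, 5))
            centers = rng.random((n, 3)) * 100
            f = [make_spot(*(c + rng.random(3) * 0.5), "FITC", i) for i, c in enumerate(centers)]
            t = [make_spot(*(c + rng.random(3) * 0.5), "TRITC", i) for i, c in enumerate(centers)]
            cost = np.array(
                [[distance_3d(a, b) for b in t] for a in f]
            )
            ri, ci = linear_sum_assignment(cost)
            optimal = set(zip(ri.tolist(), ci.tolist()))
            pairs, _, _ = greedy_match(f, t)
            assert {(p.fitc.id, p.tritc.id) for p in pairs} == optimal


class TestCallPairs:
    def _pair_at(self, d):
        f = make_spot(0, 0, 0, "FITC", 0)
        t = make_spot(d, 0, 0, "TRITC", 0)
        pairs, _, _ = greedy_match([f], [t])
        return pairs

    @pytest.mark.parametrize(
        "distance,call",
        [
            (0.0, COLOCALIZED),
            (0.5, COLOCALIZED),
            (1.1999, COLOCALIZED),
            (1.2, BREAKAPART),  # boundary inclusive: cutoff is "twice or more"
            (2.0, BREAKAPART),
        ],
    )
    def test_cutoff_boundary(self, config, distance, call):
        (mp,) = call_pairs(self._pair_at(distance), config)
        assert mp.call == call

    def test_custom_cutoff(self):
        cfg = RunConfig(breakapart_cutoff_um=0.1)
        (mp,) = call_pairs(self._pair_at(0.5), cfg)
        assert mp.call == BREAKAPART
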