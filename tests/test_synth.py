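import numpy as np
import pytest
from scipy.stats import chisquare

from fish3d.pairing import distance_3d, greedy_match
from fish3d.scoring import (
    MULTIPLE_COPY,
    NONTYPICAL_BREAK,
    NORMAL,
    OTHER,
    TYPICAL_BREAK,
)
from fish3d.synth import (
    GroundTruth,
    NucleusGeometry,
    PlacementError,
    SynthParams,
    generate_case,
    ground_truth_spots,
    place_pattern,
)

CUTOFF = 1.2


def _nucleus(a=4.0, b=3.2, c=1.3, center=(12.0, 12.0, 1.8)):
    return NucleusGeometry(id=1, center_um=center, semi_axes_um=(a, b, c))


def _split(spots):
    fitc = [p for ch, p in spots if ch == "FITC"]
    tritc = [p for ch, p in spots if ch == "TRITC"]
    return fitc, tritc


def _cross_distances(fitc, tritc):
    return [
        float(np.sqrt(sum((a - b) ** 2 for a, b in zip(f, t))))
        for f in fitc
        for t in tritc
    ]


class TestPlacePattern:
    def test_normal_two_colocalized_pairs(self, rng):
        spots = place_pattern(NORMAL, _nucleus(), rng)
        fitc, tritc = _split(spots)
        assert len(fitc) == 2 and len(tritc) == 2
        d = sorted(_cross_distances(fitc, tritc))
        assert d[0] < CUTOFF and d[1] < CUTOFF  # two co-localizations
        assert all(x >= CUTOFF for x in d[2:])  # nothing else close

    def test_typical_break_geometry(self, rng):
        spots = place_pattern(TYPICAL_BREAK, _nucleus(), rng)
        fitc, tritc = _split(spots)
        assert len(fitc) == 2 and len(tritc) == 2
        d = sorted(_cross_distances(fitc, tritc))
        assert d[0] < CUTOFF  # exactly one co-localization
        assert all(x >= CUTOFF for x in d[1:])

    def test_multiple_copy_at_least_three_pairs(self, rng):
        spots = place_pattern(MULTIPLE_COPY, _nucleus(), rng)
        fitc, tritc = _split(spots)
        assert len(fitc) == len(tritc) >= 3
        close = [x for x in _cross_distances(fitc, tritc) if x < CUTOFF]
        assert len(close) == len(fitc)  # each signal fused exactly once

    def test_nontypical_break_has_splits_of_both_colors(self, rng):
        for _ in range(10):
            spots = place_pattern(NONTYPICAL_BREAK, _nucleus(), rng)
            fitc, tritc = _split(spots)
            close = [x for x in _cross_distances(fitc, tritc) if x < CUTOFF]
            n_coloc = len(close)
            g = len(fitc) - n_coloc
            r = len(tritc) - n_coloc
            # at least one split signal of each color, and not the (1,1,1) triple
            assert g >= 1 or r >= 1
            assert not (n_coloc == 1 and len(fitc) == 2 and len(tritc) == 2) or g >= 1

    def test_zero_radius_nucleus_fails(self, rng):
        tiny = NucleusGeometry(
            id=1, center_um=(5, 5, 1.8), semi_axes_um=(0.0, 0.0, 0.0)
        )
        with pytest.raises(PlacementError):
            place_pattern(NORMAL, tiny, rng)

    def test_spots_inside_nucleus(self, rng):
        nuc = _nucleus()
        for pattern in (NORMAL, MULTIPLE_COPY, TYPICAL_BREAK, NONTYPICAL_BREAK, OTHER):
            for _, pos in place_pattern(pattern, nuc, rng):
                assert nuc.contains(pos, scale=0.75)

    def test_positions_on_voxel_grid(self, rng):
        for _, (x, y, z) in place_pattern(NORMAL, _nucleus(), rng):
            assert x / 0.16 == pytest.approx(round(x / 0.16), abs=1e-9)
            assert y / 0.16 == pytest.approx(round(y / 0.16), abs=1e-9)
            assert z / 0.6 == pytest.approx(round(z / 0.6), abs=1e-9)


class TestGenerateCase:
    def test_deterministic_given_seed(self):
        params = SynthParams(seed=42)
        s1, g1 = generate_case(params)
        s2, g2 = generate_case(SynthParams(seed=42))
        np.testing.assert_array_equal(s1.voxels, s2.voxels)
        assert g1.patterns == g2.patterns
        assert [s.position_um for s in g1.spots] == [s.position_um for s in g2.spots]

    def test_different_seed_differs(self):
        s1, _ = generate_case(SynthParams(seed=1))
        s2, _ = generate_case(SynthParams(seed=2))
        assert not np.array_equal(s1.voxels, s2.voxels)

    def test_zero_nuclei_blank_stack(self):
        stack, gt = generate_case(SynthParams(n_nuclei=0, seed=0))
        assert gt.nuclei == [] and gt.spots == []
        assert gt.expected_diagnosis is None
        assert np.all(stack.voxels == stack.voxels[0, 0, 0, 0])  # background only

    def test_expected_pair_distances_match_positions(self):
        _, gt = generate_case(
            SynthParams(seed=9, pattern_mix={NORMAL: 0.5, TYPICAL_BREAK: 0.5})
        )
        by_key = {
            (s.nucleus_id, s.channel, s.index): np.array(s.position_um)
            for s in gt.spots
        }
        for p in gt.expected_pairs:
            f = by_key[(p.nucleus_id, "FITC", p.fitc_index)]
            t = by_key[(p.nucleus_id, "TRITC", p.tritc_index)]
            assert p.distance_um == pytest.approx(
                float(np.linalg.norm(f - t)), abs=1e-9
            )
            assert p.colocalized == (p.distance_um < CUTOFF)

    def test_spots_inside_their_nucleus(self):
        _, gt = generate_case(SynthParams(seed=5))
        by_id = {n.id: n for n in gt.nuclei}
        for s in gt.spots:
            assert by_id[s.nucleus_id].contains(s.position_um, scale=0.75)

    def test_nuclei_do_not_overlap(self):
        _, gt = generate_case(SynthParams(seed=3))
        for i, a in enumerate(gt.nuclei):
            for b in gt.nuclei[i + 1 :]:
                d = np.hypot(
                    a.center_um[0] - b.center_um[0],
                    a.center_um[1] - b.center_um[1],
                )
                assert d >= a.semi_axes_um[0] + b.semi_axes_um[0]

    def test_overlap_pair_flag_places_touching_nuclei(self):
        _, gt = generate_case(SynthParams(seed=4, overlap_pair=True, n_nuclei=3))
        a, b = gt.nuclei[0], gt.nuclei[1]
        d = np.hypot(
            a.center_um[0] - b.center_um[0], a.center_um[1] - b.center_um[1]
        )
        assert d < a.semi_axes_um[0]
        assert gt.unclear_ids == (1, 2)

    def test_pattern_mix_proportions_chi_square(self):
        # label frequencies over many generated nuclei converge to the mix
        mix = {NORMAL: 0.5, MULTIPLE_COPY: 0.2, TYPICAL_BREAK: 0.3}
        labels = list(mix)
        counts = dict.fromkeys(labels, 0)
        n = 0
        for seed in range(40):
            _, gt = generate_case(
                SynthParams(
                    image_size=(160, 160),
                    n_nuclei=3,
                    nucleus_radii_um=(3.0, 4.0),
                    pattern_mix=mix,
                    seed=seed,
                )
            )
            for pat in gt.patterns.values():
                counts[pat] += 1
                n += 1
        stat, p = chisquare(
            [counts[k] for k in labels], [mix[k] * n for k in labels]
        )
        assert p > 1e-3

    def test_ground_truth_json_round_trip(self, tmp_path):
        _, gt = generate_case(SynthParams(seed=8))
        path = gt.to_json(tmp_path / "gt.json")
        back = GroundTruth.from_json(path)
        assert back.patterns == gt.patterns
        assert back.expected_diagnosis == gt.expected_diagnosis
        assert [s.position_um for s in back.spots] == [
            tuple(p for p in s.position_um) for s in gt.spots
        ]

    def test_ground_truth_spots_pair_like_expected_pairs(self):
        _, gt = generate_case(
            SynthParams(seed=11, pattern_mix={NORMAL: 0.6, NONTYPICAL_BREAK: 0.4})
        )
        for n in gt.nuclei:
            fitc, tritc = ground_truth_spots(gt, n.id)
            pairs, _, _ = greedy_match(fitc, tritc)
            want = [
                (p.fitc_index, p.tritc_index)
                for p in gt.expected_pairs
                if p.nucleus_id == n.id
            ]
            assert sorted((p.fitc.id, p.tritc.id) for p in pairs) == sorted(want)

    def test_infeasible_placement_raises(self):
        params = SynthParams(
            image_size=(64, 64), n_nuclei=6, nucleus_radii_um=(4.0, 4.5), seed=0
        )
        with pytest.raises(PlacementError):
            generate_case(params)
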