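"""Segment metrics, random baseline, grid boxes and report aggregation."""

import itertools

import numpy as np
import pytest

import rxnbind as rb
from rxnbind.evaluation import SegmentSet


def seg(*intervals):
    return SegmentSet(tuple(intervals))


class TestSegmentSet:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            seg((5, 5))
        with pytest.raises(ValueError):
            seg((5, 3))
        with pytest.raises(ValueError):
            seg((0, 5), (3, 8))  # overlap
        with pytest.raises(ValueError):
            seg((0, 5), (5, 8))  # touching, unmerged

    def test_from_intervals_normalizes(self):
        s = SegmentSet.from_intervals([(9, 14), (0, 5), (5, 9)])
        assert s.segments == ((0, 14),)
        assert s.total_length == 14

    def test_residues_and_coverage(self):
        s = seg((0, 3), (10, 12))
        assert s.residues() == {0, 1, 2, 10, 11}
        assert s.coverage(10) == 0.5


class TestOverlapScore:
    def test_identity_is_one(self):
        assert rb.overlap_score(seg((10, 20)), seg((10, 20))) == 1.0

    def test_half_overlap_worked_example(self):
        assert rb.overlap_score(seg((15, 25)), seg((10, 20))) == 0.5

    def test_disjoint_is_zero(self):
        assert rb.overlap_score(seg((0, 5)), seg((10, 20))) == 0.0

    def test_empty_truth_undefined(self):
        with pytest.raises(ValueError):
            rb.overlap_score(seg((0, 5)), SegmentSet(()))

    def test_monotone_in_added_prediction_segments(self):
        truth = seg((10, 30), (50, 60))
        intervals = [(0, 5), (12, 18), (25, 35), (55, 58), (70, 80)]
        prev = 0.0
        for n in range(1, len(intervals) + 1):
            cur = rb.overlap_score(SegmentSet.from_intervals(intervals[:n]), truth)
            assert cur >= prev
            prev = cur


class TestFalsePositiveRate:
    def test_worked_example_per_segment_indicator(self):
        # [0,10) touches the truth, [30,40) does not: 10 of 20 residues
        assert rb.false_positive_rate(seg((0, 10), (30, 40)), seg((5, 15))) == 0.5

    def test_all_segments_touch_truth(self):
        assert rb.false_positive_rate(seg((0, 10)), seg((5, 6))) == 0.0

    def test_fully_disjoint_is_one(self):
        assert rb.false_positive_rate(seg((0, 10)), seg((20, 30))) == 1.0

    def test_empty_prediction_undefined(self):
        with pytest.raises(ValueError):
            rb.false_positive_rate(SegmentSet(()), seg((0, 5)))

    def test_residue_variant_differs_on_partial_segments(self):
        pred, truth = seg((0, 10)), seg((8, 12))
        assert rb.false_positive_rate(pred, truth) == 0.0
        assert rb.false_positive_rate_residues(pred, truth) == 0.8


def _residue_oracle_os(pred: SegmentSet, truth: SegmentSet) -> float:
    return len(pred.residues() & truth.residues()) / len(truth.residues())


def _residue_oracle_fpr(pred: SegmentSet, truth: SegmentSet) -> float:
    truth_res = truth.residues()
    num = sum(
        (b - a) for a, b in pred.segments if not (set(range(a, b)) & truth_res)
    )
    return num / pred.total_length


def random_segment_set(rng, max_end=80):
    n = int(rng.integers(1, 5))
    cuts = np.sort(rng.choice(max_end, size=2 * n, replace=False))
    return SegmentSet.from_intervals(
        [(int(cuts[2 * i]), int(cuts[2 * i + 1])) for i in range(n)]
    )


def test_metric_formulas_agree_with_residue_oracles():
    rng = np.random.default_rng(42)
    for _ in range(300):
        pred, truth = random_segment_set(rng), random_segment_set(rng)
        assert rb.overlap_score(pred, truth) == pytest.approx(_residue_oracle_os(pred, truth))
        assert rb.false_positive_rate(pred, truth) == pytest.approx(
            _residue_oracle_fpr(pred, truth)
        )
        assert 0.0 <= rb.overlap_score(pred, truth) <= 1.0
        assert 0.0 <= rb.false_positive_rate(pred, truth) <= 1.0


class TestRandomBaseline:
    def test_full_coverage_single_segment(self):
        s = rb.random_baseline(30, coverage=1.0, n_segments=1, seed=0)
        assert s.segments == ((0, 30),)

    def test_same_seed_same_segments(self):
        a = rb.random_baseline(100, 0.3, 3, seed=9)
        b = rb.random_baseline(100, 0.3, 3, seed=9)
        assert a == b

    def test_total_length_and_count(self):
        for seed in range(30):
            s = rb.random_baseline(100, 0.25, 3, seed=seed)
            assert s.total_length == 25
            assert len(s) == 3  # separated placement is feasible here

    def test_infeasible_raises(self):
        with pytest.raises(ValueError):
            rb.random_baseline(100, coverage=0.02, n_segments=5, seed=0)

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        """Mean OS over seeds matches the exact mean over all separated
        placements of two 3-residue segments in a length-20 sequence."""
        L, total, n = 20, 6, 2
        truth = seg((8, 12))
        sizes = (3, 3)
        exact_scores = []
        for s1 in range(L - total - 1 + 1):
            for s2 in range(s1 + sizes[0] + 1, L - sizes[1] + 1):
                placed = seg((s1, s1 + sizes[0]), (s2, s2 + sizes[1]))
                exact_scores.append(rb.overlap_score(placed, truth))
        exact_mean = float(np.mean(exact_scores))
        mc = [
            rb.overlap_score(rb.random_baseline(L, total / L, n, seed=s), truth)
            for s in range(4000)
        ]
        mc_mean = float(np.mean(mc))
        sigma = float(np.std(mc)) / np.sqrt(len(mc))
        assert abs(mc_mean - exact_mean) < 3 * sigma + 1e-12


class TestGridBox:
    def test_center_is_mean_and_side_default(self):
        box = rb.grid_box([(0, 0, 0), (2, 2, 2)])
        assert box.center == (1.0, 1.0, 1.0)
        assert box.side == 50.0

    def test_single_point_and_permutation_invariance(self):
        assert rb.grid_box([(3, 4, 5)]).center == (3.0, 4.0, 5.0)
        pts = [(0, 1, 2), (5, 5, 5), (-1, 0, 3)]
        assert rb.grid_box(pts).center == rb.grid_box(pts[::-1]).center

    def test_translation_equivariance(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(7, 3))
        v = np.array([1.5, -2.0, 0.25])
        c1 = np.array(rb.grid_box(pts).center)
        c2 = np.array(rb.grid_box(pts + v).center)
        assert np.allclose(c2, c1 + v)

    def test_empty_points_rejected(self):
        with pytest.raises(ValueError):
            rb.grid_box([])

    def test_barycenter_distance(self):
        b1 = rb.GridBox((0, 0, 0))
        b2 = rb.GridBox((3, 4, 0))
        assert rb.barycenter_distance(b1, b2) == 5.0
        assert rb.barycenter_distance(b1, b1) == 0.0
        assert rb.barycenter_distance(b2, b1) == rb.barycenter_distance(b1, b2)


def _pdb_line(serial, name, resname, chain, resseq, x, y, z, element):
    return (
        f"ATOM  {serial:>5} {name:<4}{'':1}{resname:>3} {chain}{resseq:>4}{'':1}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2}\n"
    )


def test_pdb_site_coordinates_to_grid_box(tmp_path):
    pdb = tmp_path / "site.pdb"
    lines = [
        _pdb_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, "N"),
        _pdb_line(2, "CA", "ALA", "A", 1, 2.0, 0.0, 0.0, "C"),
        _pdb_line(3, "CA", "GLY", "A", 2, 0.0, 2.0, 2.0, "C"),
        _pdb_line(4, "CA", "SER", "A", 3, 9.0, 9.0, 9.0, "C"),
        "END\n",
    ]
    pdb.write_text("".join(lines))
    coords = rb.extract_site_coordinates(pdb, "A", [1, 2])
    assert coords.shape == (3, 3)
    box = rb.grid_box(coords)
    assert np.allclose(box.center, (2 / 3, 2 / 3, 2 / 3))
    with pytest.raises(ValueError):
        rb.extract_site_coordinates(pdb, "A", [99])


class TestEvaluateReport:
    def test_three_example_hand_means(self):
        preds = {
            "a": seg((15, 25)),            # OS 0.5, FPR 0.0
            "b": seg((0, 10), (30, 40)),   # vs (5,15): OS 0.5, FPR 0.5
            "c": seg((0, 4)),              # disjoint: OS 0.0, FPR 1.0
        }
        truths = {"a": seg((10, 20)), "b": seg((5, 15)), "c": seg((10, 20))}
        report = rb.evaluate(preds, truths, sequence_lengths={"a": 100, "b": 100, "c": 100})
        assert report.mean_overlap_score == pytest.approx((0.5 + 0.5 + 0.0) / 3)
        assert report.mean_false_positive_rate == pytest.approx((0.0 + 0.5 + 1.0) / 3)
        # pooled: intersections (5 + 5 + 0) / truth lengths (10 + 10 + 10)
        assert report.pooled_overlap_score == pytest.approx(10 / 30)
        assert report.mean_coverage == pytest.approx((10 + 20 + 4) / 300)

    def test_single_example(self):
        report = rb.evaluate({"x": seg((15, 25))}, {"x": seg((10, 20))})
        assert report.mean_overlap_score == 0.5

    def test_identifier_mismatch_lists_ids(self):
        with pytest.raises(ValueError, match="only-pred"):
            rb.evaluate({"only-pred": seg((0, 1))}, {"only-truth": seg((0, 1))})

    def test_empty_prediction_counted_not_scored(self):
        preds = {"a": SegmentSet(()), "b": seg((0, 5))}
        truths = {"a": seg((0, 5)), "b": seg((0, 5))}
        report = rb.evaluate(preds, truths)
        assert report.n_missing_prediction == 1
        # empty prediction contributes OS 0 but no FPR
        assert report.mean_overlap_score == pytest.approx(0.5)
        assert report.mean_false_positive_rate == 0.0

    def test_segments_json_round_trip(self, tmp_path):
        data = {"a": seg((0, 5), (8, 12)), "b": seg((3, 4))}
        path = tmp_path / "segs.json"
        rb.save_segments_json(data, path)
        assert rb.load_segments_json(path) == data
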