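"""FROC scoring: worked table examples, matching rules, brute-force oracle."""

import numpy as np
import pytest

from ribfrac import average_sensitivity, froc, match_scan, voxel_iou
from ribfrac.froc import ProposalRecord, ScanEvaluation
from ribfrac.inference import DetectionProposal


def _proposal(conf, coords, scan="s", cid=0):
    coords = np.asarray(coords, dtype=np.int32).reshape(-1, 3)
    bbox = tuple((int(coords[:, a].min()), int(coords[:, a].max()) + 1) for a in range(3))
    return DetectionProposal(
        scan_id=scan, confidence=conf, volume=len(coords), bbox=bbox, voxels=coords, component_id=cid
    )


def _block(z0, n):
    """n voxels in a row starting at (z0, 0, 0)."""
    return [(z0, 0, k) for k in range(n)]


# -- IoU --------------------------------------------------------------------


def test_iou_identical_and_disjoint():
    a = np.zeros((4, 4, 4), dtype=bool)
    a[0, 0, :2] = True
    assert voxel_iou(a, a) == 1.0
    b = np.zeros_like(a)
    b[3, 3, :2] = True
    assert voxel_iou(a, b) == 0.0


def test_iou_partial_overlap():
    a = np.array([[0, 0, 0], [0, 0, 1]])
    b = np.array([[0, 0, 1], [0, 0, 2]])
    assert voxel_iou(a, b, shape=(4, 4, 4)) == pytest.approx(1 / 3)


def test_iou_both_empty_rejected():
    with pytest.raises(ValueError):
        voxel_iou(np.zeros((2, 2, 2), dtype=bool), np.zeros((2, 2, 2), dtype=bool))


# -- matching ---------------------------------------------------------------


def test_iou_exactly_threshold_is_false_positive():
    # proposal and lesion of 3 voxels each, overlap 1: IoU = 1/5 = 0.2 exactly
    gt = [np.array(_block(0, 3))]
    prop = _proposal(0.9, _block(0, 3)[2:] + [(0, 0, 3), (0, 0, 4)])
    ev = match_scan([prop], gt, shape=(8, 8, 8), iou_thresh=0.2)
    assert ev.records[0].is_tp is False
    # one more shared voxel: IoU = 2/4 > 0.2 -> TP
    prop2 = _proposal(0.9, _block(0, 3)[1:] + [(0, 0, 3)])
    ev2 = match_scan([prop2], gt, shape=(8, 8, 8), iou_thresh=0.2)
    assert ev2.records[0].is_tp is True


def test_match_mixed_tp_fp():
    gt = [np.array(_block(0, 4)), np.array(_block(4, 4))]
    hit = _proposal(0.9, _block(0, 4)[:3])  # IoU 3/5 = 0.6 with lesion 0
    miss = _proposal(0.8, _block(7, 4))
    ev = match_scan([hit, miss], gt, shape=(8, 8, 8))
    assert [r.is_tp for r in ev.records] == [True, False]
    assert ev.n_gt == 2


def test_one_lesion_cannot_be_matched_twice():
    gt = [np.array(_block(0, 4))]
    strong = _proposal(0.9, _block(0, 4))
    weak = _proposal(0.5, _block(0, 4)[:2] + [(1, 0, 0), (1, 0, 1)])
    ev = match_scan([weak, strong], gt, shape=(8, 8, 8))
    by_conf = {r.confidence: r.is_tp for r in ev.records}
    assert by_conf[0.9] is True and by_conf[0.5] is False


def test_match_order_invariant_after_sort():
    gt = [np.array(_block(0, 4)), np.array(_block(4, 4))]
    props = [
        _proposal(0.9, _block(0, 4), cid=1),
        _proposal(0.7, _block(4, 4), cid=2),
        _proposal(0.3, _block(7, 3), cid=3),
    ]
    fwd = match_scan(props, gt, shape=(8, 8, 8))
    rev = match_scan(props[::-1], gt, shape=(8, 8, 8))
    assert [(r.confidence, r.is_tp) for r in fwd.records] == [
        (r.confidence, r.is_tp) for r in rev.records
    ]


# -- FROC curve -------------------------------------------------------------


def oracle_froc(evaluations, rates):
    """Brute force: enumerate every threshold, recount TPs/FPs from scratch."""
    total_gt = sum(e.n_gt for e in evaluations)
    n_scans = len(evaluations)
    all_conf = sorted({r.confidence for e in evaluations for r in e.records}, reverse=True)
    points = []
    for t in all_conf:
        tp = fp = 0
        for e in evaluations:
            for r in e.records:
                if r.confidence >= t:
                    tp += r.is_tp
                    fp += not r.is_tp
        points.append((fp / n_scans, tp / total_gt))
    sens = []
    for rate in rates:
        ok = [s for f, s in points if f <= rate]
        sens.append(100.0 * max(ok) if ok else 0.0)
    return sens


def test_froc_worked_example():
    ev = ScanEvaluation(
        "s",
        n_gt=2,
        records=[
            ProposalRecord(0.9, True, 0),
            ProposalRecord(0.8, False, None),
            ProposalRecord(0.7, True, 1),
        ],
    )
    res = froc([ev])
    assert res.sensitivities_pct[0] == pytest.approx(50.0)  # 0.5 FPs/scan
    assert res.sensitivities_pct[1] == pytest.approx(100.0)  # 1 FP/scan
    assert res.sensitivities_pct[-1] == pytest.approx(100.0)


def test_froc_perfect_detector():
    evs = [
        ScanEvaluation("a", 2, [ProposalRecord(0.9, True, 0), ProposalRecord(0.8, True, 1)]),
        ScanEvaluation("b", 1, [ProposalRecord(0.7, True, 0)]),
    ]
    res = froc(evs)
    assert res.sensitivities_pct == (100.0,) * 5
    assert res.average_pct == pytest.approx(100.0)


def test_froc_no_proposals():
    res = froc([ScanEvaluation("a", 3, [])])
    assert res.sensitivities_pct == (0.0,) * 5


def test_froc_zero_gt_rejected():
    with pytest.raises(ValueError):
        froc([ScanEvaluation("a", 0, [])])


def test_froc_monotone_in_rate(rng):
    for _ in range(20):
        evs = _random_evaluations(rng)
        res = froc(evs)
        assert all(
            res.sensitivities_pct[i] <= res.sensitivities_pct[i + 1] + 1e-12
            for i in range(4)
        )


def _random_evaluations(rng):
    evs = []
    for s in range(int(rng.integers(1, 6))):
        n_gt = int(rng.integers(0, 4))
        n_props = int(rng.integers(0, 11))
        matched = 0
        records = []
        for _ in range(n_props):
            tp = matched < n_gt and rng.random() < 0.4
            matched += tp
            records.append(ProposalRecord(float(rng.random()), bool(tp), None))
        evs.append(ScanEvaluation(f"s{s}", n_gt, records))
    if not any(e.n_gt for e in evs):
        evs[0] = ScanEvaluation("fix", 1, evs[0].records)
    return evs


def test_froc_agrees_with_exhaustive_oracle(rng):
    for _ in range(100):
        evs = _random_evaluations(rng)
        res = froc(evs)
        expect = oracle_froc(evs, res.rates)
        assert list(res.sensitivities_pct) == pytest.approx(expect)


def test_low_confidence_fp_does_not_hurt_strict_operating_points():
    base = [ScanEvaluation("a", 2, [ProposalRecord(0.9, True, 0)])]
    res0 = froc(base)
    with_fp = [
        ScanEvaluation(
            "a", 2, [ProposalRecord(0.9, True, 0), ProposalRecord(0.0, False, None)]
        )
    ]
    res1 = froc(with_fp)
    # the extra FP sits at 1 FP/scan; all rates >= 1 still admit the TP
    assert res1.sensitivities_pct[1:] == res0.sensitivities_pct[1:]


# -- averaging: worked rows -------------------------------------------------


@pytest.mark.parametrize(
    "row,expected",
    [
        ([67.15, 76.92, 84.78, 87.98, 89.58], 81.28),
        ([60.10, 70.03, 79.01, 82.21, 85.90], 75.45),
        ([100.0, 100.0, 100.0, 100.0, 100.0], 100.00),
    ],
)
def test_average_sensitivity_worked_rows(row, expected):
    assert average_sensitivity(row) == pytest.approx(expected, abs=0.005)


def test_average_sensitivity_wrong_count_rejected():
    with pytest.raises(ValueError):
        average_sensitivity([1.0, 2.0])
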