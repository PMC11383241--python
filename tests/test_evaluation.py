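"""Detection evaluation: IoU, greedy matching, PR/AP with a threshold-sweep
oracle, confusion matrix bookkeeping, percent correct, early stopping."""

import numpy as np
import pytest

from floracount.evaluation import (
    BACKGROUND,
    Detection,
    EvalConfig,
    average_precision,
    confusion_matrix,
    early_stop,
    evaluate,
    iou,
    match_class,
    mean_ap,
    percent_correct,
    pr_curve,
    read_detections_csv,
    write_detections_csv,
)
from floracount.voc import Annotation, Box


def det(xmin, ymin, xmax, ymax, label="A", score=1.0):
    return Detection(Box(xmin, ymin, xmax, ymax), label, score)


def gt(xmin, ymin, xmax, ymax, label="A", aid="g"):
    return Annotation(label, Box(xmin, ymin, xmax, ymax), aid)


# --- IoU ---------------------------------------------------------------


def pixel_grid_iou(b1: Box, b2: Box) -> float:
    """Independent oracle: enumerate pixels on the half-open grids."""
    cells1 = {(x, y) for x in range(b1.xmin, b1.xmax) for y in range(b1.ymin, b1.ymax)}
    cells2 = {(x, y) for x in range(b2.xmin, b2.xmax) for y in range(b2.ymin, b2.ymax)}
    return len(cells1 & cells2) / len(cells1 | cells2)


def test_iou_basic():
    b = Box(0, 0, 10, 10)
    assert iou(b, b) == 1.0
    assert iou(b, Box(20, 20, 30, 30)) == 0.0
    # [0,10)^2 vs [5,15)x[0,10): intersection 50, union 150
    v = iou(b, Box(5, 0, 15, 10))
    assert v == pytest.approx(50 / 150)
    assert v == pytest.approx(pixel_grid_iou(b, Box(5, 0, 15, 10)))


def test_iou_against_pixel_enumeration():
    rng = np.random.default_rng(4)
    for _ in range(50):
        x0, y0 = int(rng.integers(0, 20)), int(rng.integers(0, 20))
        b1 = Box(x0, y0, x0 + int(rng.integers(1, 15)), y0 + int(rng.integers(1, 15)))
        x0, y0 = int(rng.integers(0, 20)), int(rng.integers(0, 20))
        b2 = Box(x0, y0, x0 + int(rng.integers(1, 15)), y0 + int(rng.integers(1, 15)))
        assert iou(b1, b2) == pytest.approx(pixel_grid_iou(b1, b2))
        assert iou(b1, b2) == iou(b2, b1)


# --- matching ----------------------------------------------------------


def test_match_single_pair():
    ms = match_class([det(0, 0, 10, 10)], [gt(0, 0, 10, 10)], 0.5)
    assert (ms.n_tp, ms.n_fp, len(ms.missed)) == (1, 0, 0)


def test_duplicate_detections_highest_iou_wins():
    """Two overlapping proposals on one annotation: the higher-IoU one is the
    TP, the duplicate an FP."""
    g = gt(0, 0, 10, 10)
    close = det(0, 0, 10, 9)   # IoU 0.9
    looser = det(0, 0, 10, 14)  # IoU 10/14
    ms = match_class([looser, close], [g], 0.5)
    flags = {id(m.detection): m.flag for m in ms.matches}
    assert flags[id(close)] == "TP"
    assert flags[id(looser)] == "FP"


def test_label_aware_vs_agnostic():
    g = gt(0, 0, 10, 10, label="A")
    d = det(0, 0, 10, 10, label="B")
    assert match_class([d], [g], 0.5, label_aware=True).n_tp == 0
    assert match_class([d], [g], 0.5, label_aware=False).n_tp == 1


def oracle_match_flags(dets, gts, thr):
    """Brute-force maximum-IoU-first assignment."""
    pairs = {}
    used_d, used_g = set(), set()
    while True:
        best = None
        for i, d in enumerate(dets):
            if i in used_d:
                continue
            for j, g in enumerate(gts):
                if j in used_g or d.label != g.species_label:
                    continue
                v = iou(d.box, g.box)
                if v > thr and (best is None or v > best[0]):
                    best = (v, i, j)
        if best is None:
            break
        _, i, j = best
        pairs[i] = j
        used_d.add(i)
        used_g.add(j)
    return ["TP" if i in pairs else "FP" for i in range(len(dets))]


def test_match_against_bruteforce_oracle():
    rng = np.random.default_rng(17)
    for _ in range(60):
        gts = [
            gt(x, y, x + 8, y + 8, label=f"s{int(rng.integers(2))}", aid=f"g{j}")
            for j, (x, y) in enumerate(
                zip(rng.integers(0, 30, 4), rng.integers(0, 30, 4))
            )
        ]
        dets = [
            det(int(x), int(y), int(x) + 8, int(y) + 8, label=f"s{int(rng.integers(2))}",
                score=float(rng.uniform(0.1, 1)))
            for x, y in zip(rng.integers(0, 30, 6), rng.integers(0, 30, 6))
        ]
        ms = match_class(dets, gts, 0.3)
        assert [m.flag for m in ms.matches] == oracle_match_flags(dets, gts, 0.3)


# --- PR / AP -----------------------------------------------------------


def test_pr_curve_hand_example():
    """Ranked TP, FP, TP over two annotations."""
    gts = {"i": [gt(0, 0, 10, 10, aid="g0"), gt(100, 100, 110, 110, aid="g1")]}
    dets = {
        "i": [
            det(0, 0, 10, 10, score=0.9),        # TP
            det(40, 40, 50, 50, score=0.8),      # FP
            det(100, 100, 110, 110, score=0.7),  # TP
        ]
    }
    curve = pr_curve(dets, gts, "A", 0.5)
    assert curve == [
        (0.5, 1.0),
        (0.5, 0.5),
        (1.0, pytest.approx(2 / 3)),
    ]
    assert average_precision(curve) == pytest.approx(0.5 * 1.0 + 0.5 * (2 / 3))


def test_pr_curve_edge_cases():
    gts = {"i": [gt(0, 0, 10, 10)]}
    assert pr_curve({"i": [det(0, 0, 10, 10, score=0.3)]}, gts, "A") == [(1.0, 1.0)]
    curve = pr_curve({"i": [det(50, 50, 60, 60, score=0.9)] }, gts, "A")
    assert all(p == 0.0 for _, p in curve)
    with pytest.raises(ValueError, match="absent"):
        pr_curve({"i": []}, gts, "B")


def ap_threshold_sweep(flagged, n_gt):
    """Independent AP oracle: sweep the confidence threshold over every
    observed score, collect (recall, precision) points, integrate the step
    area under the decreasing precision envelope."""
    pts = []
    for thr in sorted({s for s, _ in flagged}, reverse=True):
        sel = [is_tp for s, is_tp in flagged if s >= thr]
        tp = sum(sel)
        pts.append((tp / n_gt, tp / len(sel)))
    pts.sort()
    area, prev_r = 0.0, 0.0
    for r, _ in pts:
        if r > prev_r:
            env = max(p for rr, p in pts if rr >= r - 1e-15)
            area += (r - prev_r) * env
            prev_r = r
    return area


def test_average_precision_against_sweep_oracle():
    """200 random instances with distinct scores: rank-based all-point AP
    equals the exhaustive threshold-sweep area to 1e-12."""
    rng = np.random.default_rng(23)
    for _ in range(200):
        n = int(rng.integers(1, 12))
        n_gt = int(rng.integers(1, 8))
        scores = rng.permutation(np.linspace(0.05, 0.95, n))
        n_tp = int(rng.integers(0, min(n, n_gt) + 1))
        flags = [True] * n_tp + [False] * (n - n_tp)
        rng.shuffle(flags)
        flagged = list(zip(scores.tolist(), flags))
        ranked = sorted(flagged, key=lambda t: -t[0])
        curve = []
        tp = fp = 0
        for _, is_tp in ranked:
            tp, fp = tp + is_tp, fp + (not is_tp)
            curve.append((tp / n_gt, tp / (tp + fp)))
        assert average_precision(curve) == pytest.approx(
            ap_threshold_sweep(flagged, n_gt), abs=1e-12
        )


def test_average_precision_trivia():
    assert average_precision([(1.0, 1.0)]) == 1.0
    assert average_precision([]) == 0.0
    assert 0.0 <= average_precision([(0.3, 0.4), (0.6, 0.2)]) <= 1.0
    # 11-point interpolation of the perfect curve is also 1
    assert average_precision([(1.0, 1.0)], interpolation="11point") == 1.0


def test_mean_ap():
    assert mean_ap({"A": 1.0}) == 1.0
    assert mean_ap({"A": 1.0, "B": 0.5}) == 0.75
    rng = np.random.default_rng(5)
    aps = {f"c{i}": float(rng.uniform()) for i in range(7)}
    assert mean_ap(aps) == pytest.approx(sum(aps.values()) / 7)
    with pytest.raises(ValueError):
        mean_ap({})


# --- confusion matrix --------------------------------------------------


def test_confusion_perfect_diagonal():
    gts = {
        "i": [gt(0, 0, 10, 10, "A", "g0"), gt(30, 30, 40, 40, "B", "g1")],
    }
    dets = {
        "i": [det(0, 0, 10, 10, "A", 0.9), det(30, 30, 40, 40, "B", 0.9)],
    }
    cm = confusion_matrix(dets, gts)
    assert cm.loc["A", "A"] == 1 and cm.loc["B", "B"] == 1
    assert cm.to_numpy().sum() == 2
    assert percent_correct(cm) == 100.0


def test_confusion_label_swap_moves_mass():
    gts = {"i": [gt(0, 0, 10, 10, "A", "g0")]}
    dets = {"i": [det(0, 0, 10, 10, "B", 0.9)]}
    cm = confusion_matrix(dets, gts)
    assert cm.loc["A", "B"] == 1
    assert cm.loc["A", "A"] == 0


def test_confusion_background_row_and_column():
    gts = {"i": [gt(0, 0, 10, 10, "A", "g0")]}  # will be missed
    dets = {"i": [det(50, 50, 60, 60, "A", 0.9)]}  # spurious
    cm = confusion_matrix(dets, gts)
    assert cm.loc["A", BACKGROUND] == 1  # miss
    assert cm.loc[BACKGROUND, "A"] == 1  # spurious detection
    # sub-threshold detections are discarded before matching
    cm2 = confusion_matrix({"i": [det(0, 0, 10, 10, "A", 0.4)]}, gts)
    assert cm2.loc["A", BACKGROUND] == 1


def test_confusion_row_sums_equal_gt_counts():
    """Conservation under random corruption: each species row sums to its
    annotation count; total = n_gt + unmatched detections."""
    rng = np.random.default_rng(8)
    from floracount import synth

    species = synth.default_species(3)
    cfg = synth.SceneConfig(
        width=256, height=192, species=species,
        abundance=synth.PoissonAbundance({s.name: 4 for s in species}),
        overlap_allowed=False, clutter_rate=0.0,
    )
    corr = synth.CorruptionSpec(
        miss_rate=0.2, jitter_px=1, false_positive_rate=2.0,
        label_confusion={"species_00": {"species_01": 0.5}},
        tp_score=(0.6, 1.0),
    )
    images, _ = synth.generate_dataset(cfg, 10, seed=21)
    gts = {i.image_id: i.annotations for i in images}
    dets = {
        i.image_id: synth.oracle_detect(i, corr, seed=j, species_specs=species)
        for j, i in enumerate(images)
    }
    cm = confusion_matrix(dets, gts, EvalConfig(score_threshold=0.5))
    from collections import Counter

    gt_counts = Counter(a.species_label for anns in gts.values() for a in anns)
    for sp, n in gt_counts.items():
        assert cm.loc[sp].sum() == n
    kept = sum(1 for ds in dets.values() for d in ds if d.score > 0.5)
    n_gt = sum(gt_counts.values())
    matched = sum(cm.loc[sp, c] for sp in gt_counts for c in cm.columns if c != BACKGROUND)
    assert cm.to_numpy().sum() == n_gt + (kept - matched)


def test_percent_correct_hand_matrix():
    import pandas as pd

    labels = ["A", "B", "C", BACKGROUND]
    cm = pd.DataFrame(
        [[8, 1, 0, 1], [0, 5, 2, 3], [1, 0, 6, 3], [2, 1, 0, 0]],
        index=labels, columns=labels,
    )
    # 19 correct of 30 annotations; background row excluded from denominator
    assert percent_correct(cm) == pytest.approx(100 * 19 / 30)
    with pytest.raises(ValueError):
        percent_correct(cm * 0)


def test_chance_level_percent_correct():
    """Uniform random labelling over K classes has expected percent correct
    100/K; for the 49-species case that is 2.0% after rounding."""
    assert round(100 / 49, 1) == 2.0
    rng = np.random.default_rng(6)
    K, n_per_class = 10, 400
    import pandas as pd

    labels = [f"s{i}" for i in range(K)]
    cm = pd.DataFrame(0, index=labels + [BACKGROUND], columns=labels + [BACKGROUND])
    for true in labels:
        for pred in rng.integers(0, K, n_per_class):
            cm.loc[true, labels[pred]] += 1
    measured = percent_correct(cm)
    se = 100 * np.sqrt((1 / K) * (1 - 1 / K) / (K * n_per_class))
    assert abs(measured - 100 / K) < 3 * se + 1e-9


# --- early stopping ----------------------------------------------------


@pytest.mark.parametrize(
    "history, expected",
    [
        ([0.5, 0.5, 0.5, 0.5, 0.5, 0.49], True),
        ([0.5, 0.5, 0.5, 0.5, 0.5, 0.51], False),
        ([0.5, 0.5, 0.5, 0.5, 0.5, 0.5], False),  # equal is not lower
        ([0.5, 0.4, 0.3], False),  # insufficient history
        ([], False),
        ([0.2, 0.4, 0.6, 0.7, 0.8, 0.9, 0.5], True),  # window is the last five
    ],
)
def test_early_stop(history, expected):
    assert early_stop(history, window=5) is expected


# --- round-trip of detections CSV --------------------------------------


def test_detections_csv_roundtrip(tmp_path):
    dets = {
        "img1": [det(0, 0, 10, 10, "A", 0.9), det(5, 5, 20, 20, "B", 0.25)],
        "img2": [det(1, 2, 3, 4, "A", 1.0)],
    }
    path = write_detections_csv(dets, tmp_path / "dets.csv")
    back = read_detections_csv(path)
    assert set(back) == {"img1", "img2"}
    for k in dets:
        assert [(d.box, d.label, d.score) for d in back[k]] == [
            (d.box, d.label, d.score) for d in dets[k]
        ]


def test_evaluate_integration():
    gts = {"i": [gt(0, 0, 10, 10, "A", "g0"), gt(30, 30, 42, 42, "B", "g1")]}
    dets = {"i": [det(0, 0, 10, 10, "A", 1.0), det(30, 30, 42, 42, "B", 1.0)]}
    res = evaluate(dets, gts)
    assert res.map == 1.0
    assert res.per_class_ap == {"A": 1.0, "B": 1.0}
    assert res.percent_correct == 100.0
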