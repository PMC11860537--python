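import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching
from skimage.morphology import skeletonize

from ridgekit import minutiae as mq
from ridgekit import ridge_field as rf


def make_field(nb=(4, 4), coherence=1.0):
    theta = np.zeros(nb)
    return rf.OrientationField(
        block_size=40,
        theta=theta,
        coherence=np.full(nb, float(coherence)),
        orientation=theta,
    )


class TestCrossingNumber:
    def test_straight_line_has_two_endings(self):
        skel = np.zeros((20, 20), bool)
        skel[10, 4:16] = True
        cn = mq.crossing_number(skel)
        assert cn[10, 4] == 1 and cn[10, 15] == 1
        assert (cn[10, 5:15] == 2).all()

    def test_y_junction_one_bifurcation_three_tips(self):
        skel = np.zeros((21, 21), bool)
        skel[10, 2:11] = True          # stem
        for s in range(1, 9):          # two diagonal branches
            skel[10 - s, 10 + s] = True
            skel[10 + s, 10 + s] = True
        cn = mq.crossing_number(skel)
        on = cn[skel]
        assert (on == 3).sum() == 1
        assert (on == 1).sum() == 3

    def test_extract_suppresses_border_minutiae(self):
        skel = np.zeros((60, 60), bool)
        skel[30, 1:59] = True  # line touching both mask edges
        mask = np.ones((60, 60), bool)
        found = mq.extract_minutiae(skel, mask, border_margin=16)
        assert found == []  # both endings sit within the border margin


class TestBinarizeAndThin:
    def test_parallel_ridges_skeleton_line_count(self):
        period = 8.0
        ii = np.mgrid[0:80, 0:80][0]
        img = 128 + 100 * np.sin(2 * np.pi * ii / period)
        mask = np.ones(img.shape, bool)
        skel = mq.binarize_and_thin(img, mask, block_size=40)
        # one skeleton line per period: ~W/period lines crossing a column
        per_col = skel[:, 20:60].sum(axis=0)
        assert abs(per_col.mean() - 80 / period) <= 1.0

    def test_all_zero_input_rejected(self):
        with pytest.raises(ValueError):
            mq.binarize_and_thin(np.zeros((40, 40)), np.ones((40, 40), bool))

    def test_thinning_is_fixed_point(self):
        rng = np.random.default_rng(17)
        blob = rng.random((60, 60)) > 0.6
        skel = skeletonize(blob)
        np.testing.assert_array_equal(skeletonize(skel), skel)


class TestScoreQuality:
    def test_high_coherence_high_contrast_scores_high(self):
        enhanced = np.zeros((80, 80))
        enhanced[20:60, 20:60] = np.where(np.mgrid[0:40, 0:40][0] % 2 == 0, 255.0, 0.0)
        m = mq.Minutia(40.0, 40.0, "ending")
        q = mq.score_quality(m, make_field((2, 2), coherence=1.0), enhanced)
        assert q >= 0.9

    def test_flat_patch_zero_coherence_clamps_to_floor(self):
        m = mq.Minutia(40.0, 40.0, "ending")
        q = mq.score_quality(m, make_field((2, 2), coherence=0.0), np.zeros((80, 80)))
        assert q == pytest.approx(0.01)

    def test_quality_always_in_range(self):
        rng = np.random.default_rng(18)
        for _ in range(500):
            enhanced = rng.uniform(0, 255, (40, 40)) * rng.choice([0.0, 0.1, 1.0])
            fld = make_field((1, 1), coherence=rng.uniform(0, 1))
            m = mq.Minutia(rng.uniform(0, 39), rng.uniform(0, 39), "ending")
            q = mq.score_quality(m, fld, enhanced)
            assert 0.01 <= q <= 0.99


class TestMatchMinutiae:
    def test_identical_lists_all_tp(self):
        rng = np.random.default_rng(19)
        pts = [
            mq.Minutia(*rng.uniform(0, 100, 2), kind="ending") for _ in range(10)
        ]
        lab_d, lab_t = mq.match_minutiae(pts, pts)
        assert all(m.label == "TP" for m in lab_d)
        assert all(m.label == "TP" for m in lab_t)

    def test_type_mismatch_is_fp_even_at_same_position(self):
        truth = [mq.Minutia(50.0, 50.0, "ending")]
        near = [mq.Minutia(52.0, 48.0, "ending")]
        wrong = [mq.Minutia(50.0, 50.0, "bifurcation")]
        assert mq.match_minutiae(near, truth)[0][0].label == "TP"
        assert mq.match_minutiae(wrong, truth)[0][0].label == "FP"

    def test_order_independence(self):
        rng = np.random.default_rng(20)
        truth = [mq.Minutia(*rng.uniform(0, 80, 2), kind="ending") for _ in range(15)]
        det = [mq.Minutia(m.row + rng.normal(0, 2), m.col + rng.normal(0, 2), m.kind) for m in truth]
        a, _ = mq.match_minutiae(det, truth)
        b, _ = mq.match_minutiae(det[::-1], truth)
        assert sum(m.label == "TP" for m in a) == sum(m.label == "TP" for m in b)

    def test_agrees_with_max_cardinality_oracle(self):
        rng = np.random.default_rng(0)
        trials, agree, maxdiff = 40, 0, 0
        for _ in range(trials):
            n = 50
            truth = [
                mq.Minutia(*rng.uniform(0, 300, 2), kind=rng.choice(["ending", "bifurcation"]))
                for _ in range(n)
            ]
            det = [
                mq.Minutia(*rng.uniform(0, 300, 2), kind=rng.choice(["ending", "bifurcation"]))
                for _ in range(n)
            ]
            lab_d, _ = mq.match_minutiae(det, truth, radius=10)
            tp_greedy = sum(1 for m in lab_d if m.label == "TP")
            rows, cols = [], []
            for i, d in enumerate(det):
                for j, t in enumerate(truth):
                    if d.kind == t.kind and np.hypot(d.row - t.row, d.col - t.col) <= 10:
                        rows.append(i)
                        cols.append(j)
            graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
            tp_opt = int((maximum_bipartite_matching(graph, perm_type="column") >= 0).sum())
            agree += tp_opt == tp_greedy
            maxdiff = max(maxdiff, abs(tp_opt - tp_greedy))
        assert agree / trials >= 0.95
        assert maxdiff <= 1


class TestQualityCounts:
    def test_hand_computed_fixture(self):
        labeled = [
            mq.Minutia(0, 0, "ending", quality=q, label="TP")
            for q in (0.95, 0.85, 0.75)
        ]
        c = mq.quality_counts(labeled)
        assert c.per_threshold == {0.7: 3, 0.8: 2, 0.9: 1}
        assert c.survival_sum == 6
        assert c.n_tp_09 == 1

    def test_no_tp_all_zero(self):
        labeled = [mq.Minutia(0, 0, "ending", quality=0.99, label="FP")]
        c = mq.quality_counts(labeled)
        assert c.survival_sum == 0 and c.n_tp_09 == 0 and c.n_tp == 0

    def test_all_high_quality_triples(self):
        labeled = [
            mq.Minutia(0, 0, "ending", quality=0.99, label="TP") for _ in range(7)
        ]
        assert mq.quality_counts(labeled).survival_sum == 21

    def test_survival_monotone_in_quality(self):
        base = [0.65, 0.72, 0.85]
        low = [mq.Minutia(0, 0, "ending", quality=q, label="TP") for q in base]
        high = [mq.Minutia(0, 0, "ending", quality=min(q + 0.1, 0.99), label="TP") for q in base]
        assert mq.quality_counts(high).survival_sum >= mq.quality_counts(low).survival_sum


class TestEndToEndRecall:
    def test_clean_pattern_recall(self, clean_truth):
        from ridgekit.pipeline import PipelineConfig, run_single

        spec, truth = clean_truth
        res = run_single(truth.clean_image, PipelineConfig(match_radius=4.0), truth=truth.minutiae)
        recall = res.counts.n_tp / len(truth.minutiae)
        assert recall >= 0.9

    def test_wet_condition_scores_at_least_dry(self):
        # Qualitative direction: high-contrast captures yield at least as many
        # high-quality true minutiae as low-contrast captures of the same finger.
        from ridgekit.pipeline import PipelineConfig, run_single
        from ridgekit.synthetic import SyntheticSpec, emit_condition_set

        cfg = PipelineConfig()
        wet, dry = [], []
        for seed in range(8):
            spec = SyntheticSpec(
                width=480, height=320, orientation_model=("linear", -0.6, 0.6),
                seed=seed, n_dislocations=10,
            )
            out = emit_condition_set(spec, ["WC", "DC"])
            for label, store in (("WC", wet), ("DC", dry)):
                img, truth = out[label]
                res = run_single(img, cfg, truth=truth.minutiae)
                store.append(res.counts.survival_sum)
        assert np.median(wet) >= np.median(dry)
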