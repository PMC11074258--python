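import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pcppn import (RatingTable, box_iou, confounding_probe, disagreement,
                   explain_prototype, relevancy, relevancy_by_class,
                   stability_summary)


def _table(scores, owners=None):
    scores = np.asarray(scores)
    return RatingTable(scores=scores,
                       prototype_ids=[f"p{j}" for j in range(scores.shape[0])],
                       rater_ids=[f"r{i}" for i in range(scores.shape[1])],
                       owners=owners)


class TestRelevancy:
    def test_all_three_and_all_zero(self):
        assert relevancy(_table(np.full((5, 3), 3))) == 100.0
        assert relevancy(_table(np.zeros((5, 3), dtype=int))) == 0.0

    def test_two_prototype_hand_sum(self):
        rt = _table([[3, 3, 3], [0, 0, 0]])
        assert relevancy(rt) == pytest.approx(50.0)

    def test_invalid_score_rejected(self):
        with pytest.raises(ValueError):
            _table([[4, 0]])
        with pytest.raises(ValueError):
            _table([[-1, 2]])

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(deadline=None, max_examples=20)
    def test_permutation_and_duplicate_rater_invariance(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 4, size=(6, 3))
        base = relevancy(_table(scores))
        assert 0.0 <= base <= 100.0
        perm = rng.permutation(6)
        assert relevancy(_table(scores[perm])) == pytest.approx(base)
        assert relevancy(_table(scores[:, rng.permutation(3)])) == pytest.approx(base)
        # duplicating the whole rater panel leaves the metric unchanged
        doubled = np.hstack([scores, scores])
        assert relevancy(_table(doubled)) == pytest.approx(base)

    def test_linear_in_each_score(self):
        scores = np.zeros((2, 2), dtype=int)
        r0 = relevancy(_table(scores))
        scores[0, 0] = 3
        r1 = relevancy(_table(scores))
        assert r1 - r0 == pytest.approx(100.0 / (2 * 2))


class TestRelevancyByClass:
    def test_split_and_pooled(self):
        rt = _table([[3, 3, 3], [0, 0, 0]], owners=[0, 1])
        per = relevancy_by_class(rt)
        assert per == {0: 100.0, 1: 0.0}
        assert relevancy(rt) == pytest.approx(50.0)

    def test_single_class_equals_pooled(self):
        rt = _table([[1, 2], [2, 3]], owners=[0, 0])
        assert relevancy_by_class(rt)[0] == pytest.approx(relevancy(rt))

    def test_class_without_prototypes_omitted(self):
        rt = _table([[1, 2]], owners=[1])
        assert 0 not in relevancy_by_class(rt)

    def test_weighted_mean_identity(self):
        rng = np.random.default_rng(0)
        scores = rng.integers(0, 4, size=(7, 3))
        owners = np.array([0, 0, 0, 1, 1, 1, 1])
        rt = _table(scores, owners=owners)
        per = relevancy_by_class(rt)
        weighted = (3 * per[0] + 4 * per[1]) / 7
        assert relevancy(rt) == pytest.approx(weighted)


class TestDisagreement:
    def test_unanimous_iff_zero(self):
        assert disagreement(_table([[2, 2, 2], [0, 0, 0]]))["overall"] == 0.0
        out = disagreement(_table([[2, 2, 3]]))
        assert out["overall"] > 0.0

    def test_zero_three_pair_under_both_conventions(self):
        rt = _table([[0, 3]])
        assert disagreement(rt, ddof=1)["overall"] == pytest.approx(2.1213, abs=1e-4)
        assert disagreement(rt, ddof=0)["overall"] == pytest.approx(1.5)

    def test_average_of_per_prototype_stds_hand_check(self):
        scores = np.array([[0, 1, 2], [3, 3, 3], [0, 0, 3]])
        out = disagreement(_table(scores), ddof=1)
        expected = np.mean([np.std(row, ddof=1) for row in scores])
        assert out["overall"] == pytest.approx(expected)

    def test_single_rater_rejected(self):
        with pytest.raises(ValueError):
            disagreement(_table([[1], [2]]))

    def test_per_class_averaging(self):
        rt = _table([[0, 3], [1, 1]], owners=[0, 1])
        out = disagreement(rt, ddof=0)
        assert out["per_class"] == {0: 1.5, 1: 0.0}


class TestStabilitySummary:
    def test_identical_values_zero_std(self):
        out = stability_summary({"runs": [70.0, 70.0, 70.0]})
        assert out.loc["runs", "std"] == 0.0

    def test_three_run_mean_and_std(self):
        out = stability_summary({"w": [70.83, 81.25, 89.58]})
        assert out.loc["w", "mean"] == pytest.approx(80.55, abs=0.01)
        assert out.loc["w", "std"] == pytest.approx(9.39, abs=0.01)

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError, match="single"):
            stability_summary({"single": [1.0]})


class TestBoxIoU:
    def test_identical_boxes(self):
        assert box_iou((0, 0, 10, 10), (0, 0, 10, 10)) == 1.0

    def test_disjoint_boxes(self):
        assert box_iou((0, 0, 5, 5), (6, 6, 9, 9)) == 0.0

    def test_half_overlap(self):
        assert box_iou((0, 0, 10, 10), (0, 5, 10, 15)) == pytest.approx(1 / 3)


class TestExplainPrototype:
    def test_missing_provenance_rejected(self, tiny_net, split_sets):
        train, _ = split_sets
        with pytest.raises(ValueError, match="projection"):
            explain_prototype(tiny_net, train, 0)

    def test_constant_activation_gives_full_image_box(self, tiny_net, split_sets):
        train, _ = split_sets
        # zero the final add-on conv: sigmoid(0)=0.5 everywhere -> constant z,
        # hence a spatially constant activation map for every prototype
        final_conv = tiny_net.addon.layers[2]
        final_conv.params["W"][:] = 0.0
        final_conv.params["b"][:] = 0.0
        tiny_net.bank.provenance[0] = (train.ids[0], 0, 0)
        expl = explain_prototype(tiny_net, train, 0)
        assert expl.box == (0, 0, 64, 64)

    def test_projected_prototype_box_on_trained_model(self, trained_model,
                                                      pseudo_labeled_train):
        model, _ = trained_model
        train, _ = pseudo_labeled_train
        expl = explain_prototype(model, train, 0)
        r0, c0, r1, c1 = expl.box
        assert 0 <= r0 < r1 <= 64 and 0 <= c0 < c1 <= 64
        assert expl.max_similarity == pytest.approx(np.log(1e4), abs=1e-3)


class TestConfoundingProbe:
    def test_iou_computation_against_hand_placed_boxes(self, trained_model,
                                                       pseudo_labeled_train):
        """Truth boxes set equal to a prototype's own explanation box score
        IoU exactly 1; a hand-placed disjoint box scores what box_iou says."""
        import pandas as pd

        model, _ = trained_model
        train, _ = pseudo_labeled_train
        from pcppn.imageset_io import source_id
        j = next(j for j in range(model.bank.M)
                 if "#aug" not in model.bank.provenance[j][0])
        expl = explain_prototype(model, train, j)
        sid = source_id(model.bank.provenance[j][0])
        r0, c0, r1, c1 = expl.box
        same = pd.DataFrame([{"id": sid, "r0": r0, "c0": c0, "r1": r1, "c1": c1}])
        out = confounding_probe(model, train, same)
        assert out["iou_per_prototype"][j] == pytest.approx(1.0)

        far_r0 = 0 if r0 > 32 else 63
        hand_box = (far_r0, 0, far_r0 + 1, 1)
        disjoint = pd.DataFrame([{"id": sid, "r0": hand_box[0], "c0": hand_box[1],
                                  "r1": hand_box[2], "c1": hand_box[3]}])
        out2 = confounding_probe(model, train, disjoint)
        assert out2["iou_per_prototype"][j] == pytest.approx(
            box_iou(expl.box, hand_box))

    def test_no_matching_truth_rejected(self, trained_model, pseudo_labeled_train):
        import pandas as pd

        model, _ = trained_model
        train, _ = pseudo_labeled_train
        truth = pd.DataFrame([{"id": "nope", "r0": 0, "c0": 0, "r1": 1, "c1": 1}])
        with pytest.raises(ValueError, match="ground-truth"):
            confounding_probe(model, train, truth)


class TestRatingCSV:
    def test_round_trip(self, tmp_path):
        rt = _table(np.random.default_rng(0).integers(0, 4, size=(4, 3)))
        rt.to_csv(tmp_path / "r.csv")
        back = RatingTable.from_csv(tmp_path / "r.csv")
        np.testing.assert_array_equal(back.scores, rt.scores)
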