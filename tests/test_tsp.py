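import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stresspair import TspModel, ValidationError, fit_tsp, predict_tsp, score_pair
from conftest import make_fm, random_labeled_fm


def brute_force_pair(values, labels, i, j):
    """Naive double-loop indicator count of p_c = P(value_i < value_j)."""
    levels = sorted(set(labels))
    ps = []
    for level in levels:
        count = total = 0
        for row, lab in zip(values, labels):
            if lab != level:
                continue
            total += 1
            if row[i] < row[j]:
                count += 1
        ps.append(count / total)
    return ps[0], ps[1], abs(ps[0] - ps[1])


class TestScorePair:
    def test_perfectly_separating_pair(self):
        fm = make_fm([[1, 2], [1, 3], [2, 1], [3, 1]], labels=["A", "A", "B", "B"])
        s = score_pair(fm, 0, 1)
        assert (s.p1, s.p2, s.delta) == (1.0, 0.0, 1.0)

    def test_identical_classes_score_zero(self):
        fm = make_fm([[1, 2], [2, 1], [1, 2], [2, 1]], labels=["A", "A", "B", "B"])
        assert score_pair(fm, 0, 1).delta == 0.0

    def test_same_feature_twice_rejected(self):
        fm = make_fm([[1, 2], [2, 1]], labels=["A", "B"])
        with pytest.raises(ValidationError, match="distinct"):
            score_pair(fm, 0, 0)

    def test_accepts_names_or_indices(self):
        fm = make_fm([[1, 2], [2, 1]], labels=["A", "B"])
        assert score_pair(fm, "f0", "f1") == score_pair(fm, 0, 1)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_counting(self, seed):
        rng = np.random.default_rng(seed)
        # integer grid forces ties, exercising the strict-inequality rule
        values = rng.integers(0, 4, size=(10, 4)).astype(float)
        labels = ["A"] * 5 + ["B"] * 5
        fm = make_fm(values, labels=labels)
        for i, j in itertools.combinations(range(4), 2):
            s = score_pair(fm, i, j)
            p1, p2, delta = brute_force_pair(values, labels, i, j)
            assert (s.p1, s.p2, s.delta) == (p1, p2, delta)

    def test_swapping_features_complements_probabilities(self):
        rng = np.random.default_rng(3)
        fm = random_labeled_fm(rng, n=12, p=3)  # continuous: no ties
        fwd, rev = score_pair(fm, 0, 2), score_pair(fm, 2, 0)
        assert rev.p1 == pytest.approx(1 - fwd.p1)
        assert rev.p2 == pytest.approx(1 - fwd.p2)
        assert rev.delta == pytest.approx(fwd.delta)
        assert rev.gamma == pytest.approx(fwd.gamma)


class TestFitTsp:
    def test_single_informative_pair_selected(self):
        rng = np.random.default_rng(4)
        n = 20
        noise = rng.standard_normal((2 * n, 3))
        a = np.r_[np.zeros(n), np.ones(n) * 2]
        b = np.r_[np.ones(n), np.zeros(n) * 2]
        fm = make_fm(
            np.column_stack([noise[:, 0], a + 0.01 * rng.standard_normal(2 * n), b, noise[:, 1:]]),
            labels=["A"] * n + ["B"] * n,
            feature_names=["n1", "up", "down", "n2", "n3"],
        )
        model = fit_tsp(fm)
        assert set(model.pair) == {"up", "down"}

    def test_matches_exhaustive_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        fm = random_labeled_fm(rng, n=14, p=5)
        model = fit_tsp(fm)
        best = max(
            (
                (*brute_force_pair(fm.values, list(fm.labels), i, j), i, j)
                for i, j in itertools.combinations(range(5), 2)
            ),
            key=lambda t: t[2],
        )
        assert model.delta == pytest.approx(best[2])
        assert set(model.pair) == {fm.feature_names[best[3]], fm.feature_names[best[4]]}

    def test_all_zero_deltas_warn_but_return(self, caplog):
        fm = make_fm([[1, 2], [1, 2], [1, 2], [1, 2]], labels=["A", "A", "B", "B"])
        with caplog.at_level("WARNING"):
            model = fit_tsp(fm)
        assert model.delta == 0.0
        assert "no pairwise rank signal" in caplog.text

    def test_orientation_is_majority_ordering_class(self):
        fm = make_fm([[1, 2], [1, 3], [2, 1], [3, 1]], labels=["A", "A", "B", "B"])
        model = fit_tsp(fm)
        assert model.orientation == "A"  # A rows have f0 < f1

    def test_needs_two_samples_per_class(self):
        fm = make_fm([[1, 2], [2, 1], [2, 3]], labels=["A", "B", "B"])
        with pytest.raises(ValidationError, match=">= 2 samples"):
            fit_tsp(fm)

    def test_ranked_pair_list_is_sorted(self, train_valid):
        model = fit_tsp(train_valid[0])
        deltas = [s.delta for s in model.pair_scores]
        assert deltas == sorted(deltas, reverse=True)
        assert len(deltas) == 28 * 27 // 2


class TestPredictTsp:
    def test_tie_goes_to_orientation_class(self):
        fm = make_fm([[1, 2], [1, 3], [2, 1], [3, 1]], labels=["A", "A", "B", "B"])
        model = fit_tsp(fm)
        tied = make_fm([[5.0, 5.0]])
        assert predict_tsp(model, tied).iloc[0] == model.orientation

    def test_missing_feature_errors(self, train_valid):
        model = fit_tsp(train_valid[0])
        bad = make_fm([[1.0, 2.0]], feature_names=["x", "y"])
        with pytest.raises(ValidationError, match="missing"):
            predict_tsp(model, bad)

    def test_training_misclassification_matches_recount(self, train_valid):
        train, _ = train_valid
        model = fit_tsp(train)
        pred = predict_tsp(model, train)
        vi = train.data[model.feature_i].to_numpy()
        vj = train.data[model.feature_j].to_numpy()
        other = [lev for lev in model.class_levels if lev != model.orientation][0]
        expected = np.where(vi <= vj, model.orientation, other)
        miss_direct = int((expected != train.labels.to_numpy()).sum())
        assert int((pred.to_numpy() != train.labels.to_numpy()).sum()) == miss_direct

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), transform=st.sampled_from(["exp", "cube", "log"]))
    def test_invariance_under_joint_monotone_transform(self, seed, transform):
        """delta and predictions depend only on the within-sample order of the
        pair, so any strictly increasing map applied to both features jointly
        leaves them unchanged."""
        rng = np.random.default_rng(seed)
        fm = random_labeled_fm(rng, n=16, p=4)
        model = fit_tsp(fm)
        base_pred = predict_tsp(model, fm)
        f = {
            "exp": np.exp,
            "cube": lambda x: x**3,
            "log": lambda x: np.log(x - x.min() + 1.0),
        }[transform]
        cols = list(model.pair)
        warped = fm.data.copy()
        joint = f(warped[cols].to_numpy())
        warped[cols] = joint
        warped_fm = make_fm(warped.to_numpy(), labels=list(fm.labels))
        assert score_pair(warped_fm, *cols).delta == pytest.approx(model.delta)
        assert (predict_tsp(model, warped_fm.select_features(fm.feature_names)) == base_pred).all()

    def test_invariance_under_constant_offset(self, train_valid):
        train, valid = train_valid
        model = fit_tsp(train)
        shifted = valid.data.copy()
        shifted[list(model.pair)] += 42.0
        from stresspair import FeatureMatrix

        shifted_fm = FeatureMatrix(shifted, labels=valid.labels)
        assert (predict_tsp(model, shifted_fm) == predict_tsp(model, valid)).all()


class TestPermutationNull:
    def test_label_permutation_kills_generalization(self, default_fm):
        """Fitting on permuted labels still finds a positive best delta
        (selection maximizes over pairs) but validation accuracy sits at
        chance."""
        from stresspair import FeatureMatrix, subset_split

        rng = np.random.default_rng(77)
        subset = default_fm.feature_names[:12]
        fm = default_fm.select_features(subset)
        train, valid = subset_split(fm, "train"), subset_split(fm, "validation")
        deltas, accs = [], []
        for _ in range(100):
            permuted = FeatureMatrix(
                train.data,
                labels=rng.permutation(train.labels.to_numpy()),
                split=train.split,
            )
            model = fit_tsp(permuted)
            deltas.append(model.delta)
            accs.append((model.predict(valid).to_numpy() == valid.labels.to_numpy()).mean())
        assert np.mean(deltas) > 0
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - 0.5) < max(3 * se, 0.05)


class TestSerialization:
    def test_json_round_trip(self, train_valid, tmp_path):
        model = fit_tsp(train_valid[0])
        path = model.save(tmp_path / "model.json")
        back = TspModel.load(path)
        assert back.pair == model.pair
        assert back.orientation == model.orientation
        assert (back.predict(train_valid[1]) == model.predict(train_valid[1])).all()
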