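"""Gain-ratio decision tree: split optimality, pruning, determinism."""

import numpy as np
import pandas as pd
import pytest

import seatsense as ss

from _oracles import (
    WEATHER_COLUMNS,
    WEATHER_PLAY,
    best_split_exhaustive,
    gain_ratio,
)
from conftest import separable_rows


def weather_frame() -> pd.DataFrame:
    df = pd.DataFrame(WEATHER_COLUMNS, dtype=float)
    df["activity"] = WEATHER_PLAY
    return df


class TestTraining:
    def test_single_class_gives_single_leaf(self):
        rows = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0], "activity": ["swing"] * 4})
        model = ss.train(rows)
        assert model.root.is_leaf
        assert model.root.prediction == "swing"

    def test_separable_1d_gives_depth_1_tree(self):
        rows = pd.DataFrame(
            {
                "f": list(np.linspace(-1, 0, 10)) + list(np.linspace(1, 2, 10)),
                "activity": ["a"] * 10 + ["b"] * 10,
            }
        )
        model = ss.train(rows)
        assert model.depth() == 1
        assert 0.0 < model.root.threshold < 1.0
        pred = ss.predict(model, rows)
        assert (pred == rows["activity"].to_numpy()).all()

    def test_weather_root_split_matches_hand_computation(self):
        """Root split of the classic 14-row fixture: humidity <= 82.5.

        That cut sends 7 rows (6 yes / 1 no) left and 7 (3 yes / 4 no)
        right: gain = H(9,5) - 0.5 H(6,1) - 0.5 H(3,4) = 0.151836 bits, and
        the split information of a 7/7 cut is exactly 1 bit, so the gain
        ratio equals the gain.
        """
        model = ss.train(weather_frame(), params=ss.TreeParams(), prune=False)
        assert model.root.feature == "humidity"
        assert model.root.threshold == pytest.approx(82.5)
        got = gain_ratio(
            WEATHER_COLUMNS["humidity"], WEATHER_PLAY, model.root.threshold
        )
        assert got == pytest.approx(0.15183550136234164, abs=1e-12)

    def test_all_identical_rows_mixed_classes_single_leaf(self):
        rows = pd.DataFrame({"f": [1.0] * 6, "activity": ["a", "b"] * 3})
        model = ss.train(rows)
        assert model.root.is_leaf
        assert model.root.prediction == "a"  # majority tie -> lexicographic

    def test_empty_training_set_rejected(self):
        with pytest.raises(ss.ValidationError):
            ss.train(pd.DataFrame({"f": [], "activity": []}))


class TestSplitOptimality:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_chosen_split_maximises_gain_ratio(self, seed):
        """Root choice equals exhaustive search over all (feature, midpoint)."""
        rng = np.random.default_rng(seed)
        n = rng.integers(20, 200)
        rows = pd.DataFrame(
            {
                "a": rng.normal(size=n).round(2),
                "b": rng.normal(size=n).round(2),
                "c": rng.integers(0, 4, size=n).astype(float),
                "activity": rng.choice(["x", "y", "z"], size=n),
            }
        )
        model = ss.train(rows, prune=False)
        columns = {k: rows[k].tolist() for k in ("a", "b", "c")}
        expected = best_split_exhaustive(columns, rows["activity"].tolist())
        if expected is None:
            assert model.root.is_leaf
        else:
            got = gain_ratio(
                columns[model.root.feature],
                rows["activity"].tolist(),
                model.root.threshold,
            )
            assert got == pytest.approx(expected[0], abs=1e-10)


class TestPruning:
    def test_pruning_never_grows_the_tree(self, tiny_features):
        params = ss.TreeParams()
        unpruned = ss.train(tiny_features, params=params, prune=False)
        pruned = ss.train(tiny_features, params=params, prune=True)
        assert pruned.n_nodes() <= unpruned.n_nodes()

    def test_pruned_training_error_not_lower(self):
        rng = np.random.default_rng(9)
        n = 200
        rows = pd.DataFrame(
            {
                "f": rng.normal(size=n),
                "g": rng.normal(size=n),
                "activity": rng.choice(["a", "b"], size=n),
            }
        )
        unpruned = ss.train(rows, prune=False)
        pruned = ss.train(rows, prune=True)
        y = rows["activity"].to_numpy()
        err_unpruned = (ss.predict(unpruned, rows) != y).mean()
        err_pruned = (ss.predict(pruned, rows) != y).mean()
        assert err_pruned >= err_unpruned
        assert pruned.n_nodes() < unpruned.n_nodes()  # noise should collapse


class TestPredict:
    def test_memorises_distinct_rows_when_unpruned(self):
        rng = np.random.default_rng(3)
        rows = pd.DataFrame(
            {
                "f": rng.permutation(np.linspace(0, 1, 30)),
                "activity": rng.choice(["a", "b", "c"], size=30),
            }
        )
        model = ss.train(rows, params=ss.TreeParams(min_leaf=1), prune=False)
        assert (ss.predict(model, rows) == rows["activity"].to_numpy()).all()

    def test_single_leaf_predicts_constant(self):
        rows = pd.DataFrame({"f": [0.0, 1.0], "activity": ["a", "a"]})
        model = ss.train(rows)
        out = ss.predict(model, pd.DataFrame({"f": [-5.0, 0.5, 99.0]}))
        assert list(out) == ["a", "a", "a"]

    def test_invariant_to_row_order(self, tiny_features):
        model = ss.train(tiny_features, target="activity")
        shuffled = tiny_features.sample(frac=1.0, random_state=4)
        direct = ss.predict(model, shuffled)
        via_original = pd.Series(
            ss.predict(model, tiny_features), index=tiny_features.index
        ).loc[shuffled.index]
        assert (direct == via_original.to_numpy()).all()

    def test_missing_feature_rejected(self):
        model = ss.train(separable_rows())
        with pytest.raises(ss.ValidationError):
            ss.predict(model, pd.DataFrame({"other": [1.0]}))


class TestDeterminismAndSerialization:
    def test_same_data_same_tree(self, tiny_features):
        m1 = ss.train(tiny_features, target="activity")
        m2 = ss.train(tiny_features, target="activity")
        assert m1.to_json() == m2.to_json()

    def test_json_round_trip(self, tmp_path, tiny_features):
        model = ss.train(tiny_features, target="level")
        path = tmp_path / "model.json"
        model.to_json(path)
        back = ss.DecisionTreeModel.from_json(path)
        assert back.classes == model.classes
        assert back.feature_names == model.feature_names
        pred1 = ss.predict(model, tiny_features)
        pred2 = ss.predict(back, tiny_features)
        assert (pred1 == pred2).all()


class TestLibraryCrossCheck:
    def test_sklearn_backend_agrees_on_separable_data(self):
        """An independent library tree reaches the same answer on clean data."""
        from sklearn.tree import DecisionTreeClassifier

        rows = separable_rows(n_per_class=30, seed=2)
        model = ss.train(rows)
        skl = DecisionTreeClassifier(random_state=0).fit(
            rows[["f"]], rows["activity"]
        )
        new = pd.DataFrame({"f": np.linspace(-1, 2, 50)})
        assert (ss.predict(model, new) == skl.predict(new[["f"]])).all()
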