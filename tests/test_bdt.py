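import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ligandtree.bdt import (
    LabeledFeatureSet,
    PairingEvaluationError,
    SplitEvaluation,
    compare_to_control,
    evaluate_splits,
    train_bagged,
    train_tree,
    _best_split,
)


def _dataset(X, y, lines=None, ligands=None, names=None):
    n = len(y)
    return LabeledFeatureSet(
        X=np.asarray(X, float),
        y=np.asarray(y, bool),
        feature_names=tuple(names or (f"f{i}" for i in range(np.asarray(X).shape[1]))),
        cell_lines=np.asarray(lines if lines is not None else [f"L{i}" for i in range(n)]),
        ligands=np.asarray(ligands if ligands is not None else ["EGF"] * n),
    )


def _planted(n_lines=30, n_noise=4, noise=0.1, seed=0):
    """One planted threshold feature + pure-noise features, split by line."""
    rng = np.random.default_rng(seed)
    ligands = ("EGF", "HRG", "HGF")
    rows, lines, ligs = [], [], []
    for i in range(n_lines):
        for lig in ligands:
            rows.append(rng.normal(size=n_noise + 1))
            lines.append(f"L{i:02d}")
            ligs.append(lig)
    X = np.asarray(rows)
    y = X[:, 0] > 0
    flip = rng.random(len(y)) < noise
    return _dataset(X, y ^ flip, lines=lines, ligands=ligs,
                    names=["planted"] + [f"noise{i}" for i in range(n_noise)])


class TestTree:
    def test_perfectly_separating_feature_gives_depth_one_tree(self):
        X = np.column_stack([np.r_[np.zeros(10), np.ones(10)], np.random.default_rng(0).normal(size=20)])
        data = _dataset(X, np.r_[np.zeros(10), np.ones(10)].astype(bool))
        tree = train_tree(data)
        assert not tree.root.is_leaf
        assert tree.root.left.is_leaf and tree.root.right.is_leaf
        assert (tree.predict(data.X) == data.y).all()

    def test_pure_data_gives_single_leaf(self):
        data = _dataset(np.random.default_rng(1).normal(size=(12, 3)), np.ones(12))
        assert train_tree(data).root.is_leaf

    def test_constant_features_give_single_leaf(self):
        data = _dataset(np.ones((12, 3)), np.r_[np.zeros(6), np.ones(6)])
        assert train_tree(data).root.is_leaf

    def test_xor_needs_depth_two(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(-1, 1, size=(240, 2))
        y = (X[:, 0] > 0) ^ (X[:, 1] > 0)
        data = _dataset(X, y)
        deep = train_tree(data, depth_limit=3, min_leaf=3)
        shallow = train_tree(data, depth_limit=1, min_leaf=3)
        assert np.mean(deep.predict(X) == y) > 0.9
        assert np.mean(shallow.predict(X) == y) <= 0.6

    def test_split_search_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 1))
        y = rng.random(40) < 0.4
        idx = np.arange(40)
        got = _best_split(X, y, idx, 0, min_leaf=3, criterion="s2n")
        # oracle: enumerate every admissible threshold directly
        best = None
        xs = np.sort(np.unique(X[:, 0]))
        for thr in (xs[:-1] + xs[1:]) / 2:
            left = X[:, 0] <= thr
            nl, nr = left.sum(), (~left).sum()
            if nl < 3 or nr < 3:
                continue
            Sl, Sr, S = y[left].sum(), y[~left].sum(), y.sum()
            gain = Sl**2 / nl + Sr**2 / nr - S**2 / 40
            if best is None or gain > best[0] + 1e-12:
                best = (gain, thr)
        assert got[0] == pytest.approx(best[0])
        assert got[1] == pytest.approx(best[1])

    def test_every_split_has_positive_gain(self):
        data = _planted(seed=4)
        for crit in ("s2n", "gini"):
            tree = train_tree(data, criterion=crit)
            assert all(node.gain > 0 for node in tree.splits())


class TestBagging:
    def test_single_tree_without_bootstrap_equals_train_tree(self):
        data = _planted(seed=5)
        bag = train_bagged(data, n_trees=1, bootstrap_fraction=0.0, seed=0)
        single = train_tree(data)
        assert (bag.predict(data.X) == single.predict(data.X)).all()

    def test_separable_data_high_heldout_accuracy(self):
        data = _planted(noise=0.0, seed=6)
        ev = evaluate_splits(data, n_reps=20, seed=1, n_trees=25,
                            exclude_ligands=(), target_ligand="all")
        assert ev.mean_accuracy > 0.95

    def test_importance_prefers_planted_over_noise_features(self):
        wins = 0
        for seed in range(20):
            data = _planted(seed=seed)
            bag = train_bagged(data, n_trees=40, seed=seed)
            imp = bag.importance(normalize=False)
            noise = max(v for k, v in imp.items() if k.startswith("noise"))
            wins += imp["planted"] > noise
        assert wins >= 19

    def test_both_criteria_recover_planted_signal(self):
        data = _planted(seed=7)
        for crit in ("s2n", "gini"):
            bag = train_bagged(data, n_trees=40, seed=3, criterion=crit)
            imp = bag.importance()
            assert max(imp, key=imp.get) == "planted"

    def test_model_round_trips_to_text(self, tmp_path):
        import yaml

        data = _planted(seed=8)
        bag = train_bagged(data, n_trees=5, seed=0)
        path = tmp_path / "bdt.yaml"
        bag.to_text(path)
        payload = yaml.safe_load(path.read_text())
        assert len(payload["trees"]) == 5
        assert payload["feature_names"] == list(data.feature_names)

    def test_invalid_tree_count_rejected(self):
        with pytest.raises(ValueError):
            train_bagged(_planted(seed=9), n_trees=0)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.sampled_from(["exp", "cube", "affine"]))
    def test_prediction_invariant_under_monotone_transform(self, kind):
        data = _planted(seed=10)
        transform = {"exp": np.exp, "cube": lambda v: v**3,
                     "affine": lambda v: 3.0 * v + 7.0}[kind]
        X2 = data.X.copy()
        X2[:, 0] = transform(X2[:, 0])
        data2 = _dataset(X2, data.y, lines=data.cell_lines, ligands=data.ligands,
                         names=data.feature_names)
        bag1 = train_bagged(data, n_trees=20, seed=4)
        bag2 = train_bagged(data2, n_trees=20, seed=4)
        assert (bag1.predict(data.X) == bag2.predict(X2)).all()


class TestEvaluation:
    def test_labels_must_be_unique_per_line_and_ligand(self):
        with pytest.raises(ValueError, match="one label"):
            _dataset(np.zeros((2, 1)), [0, 1], lines=["A", "A"], ligands=["EGF", "EGF"])

    def test_random_control_converges_to_half(self):
        data = _planted(n_lines=24, seed=11)
        ev = evaluate_splits(data, n_reps=400, seed=2, control=True,
                             exclude_ligands=(), target_ligand="all")
        assert abs(ev.mean_accuracy - 0.5) < 0.02
        # binomial scaling of the per-rep spread: sd ~ 0.5/sqrt(m) test rows
        m = 3 * round(24 * 0.3)
        assert ev.sd_accuracy == pytest.approx(0.5 / np.sqrt(m), rel=0.4)

    def test_target_ligand_restriction(self):
        data = _planted(seed=12)
        ev = evaluate_splits(data, n_reps=10, seed=3, target_ligand="HRG",
                             exclude_ligands=(), n_trees=10)
        assert ev.target_ligand == "HRG"
        with pytest.raises(ValueError, match="IGF1"):
            evaluate_splits(data, n_reps=2, target_ligand="IGF1", exclude_ligands=())

    def test_train_fraction_robustness_on_planted_data(self):
        data = _planted(n_lines=36, seed=13)
        means = [
            evaluate_splits(data, n_reps=30, seed=4, train_fraction=f,
                            exclude_ligands=(), n_trees=20).mean_accuracy
            for f in (0.5, 0.7, 0.9)
        ]
        assert max(means) - min(means) < 0.1

    def test_compare_to_control_directionality(self):
        base = np.clip(np.random.default_rng(6).normal(0.5, 0.05, 200), 0, 1)
        a = SplitEvaluation(base + 0.2, "all", 200, 0.7, 0)
        b = SplitEvaluation(base, "all", 200, 0.7, 0)
        assert compare_to_control(a, b) < 1e-3
        assert compare_to_control(b, a) > 0.99
        assert compare_to_control(b, b) >= 0.5

    def test_compare_requires_equal_reps(self):
        a = SplitEvaluation(np.full(10, 0.5), "all", 10, 0.7, 0)
        b = SplitEvaluation(np.full(20, 0.5), "all", 20, 0.7, 0)
        with pytest.raises(PairingEvaluationError):
            compare_to_control(a, b)


def test_labeled_set_from_tables_log_transform_and_indicators():
    feats = pd.DataFrame({
        "cell_line": ["A", "A", "B", "B"],
        "ligand": ["EGF", "HRG", "EGF", "HRG"],
        "auc_pS6": [1e4, 1e6, 1e5, 1e7],
        "kras_mutant": [True, True, False, False],
        "pik3ca_mutant": [False, False, False, True],
    })
    labels = pd.DataFrame({
        "cell_line": ["A", "A", "B", "B"],
        "ligand": ["EGF", "HRG", "EGF", "HRG"],
        "responder": [True, False, False, True],
    })
    data = LabeledFeatureSet.from_tables(feats, labels)
    assert "ligand_EGF" in data.feature_names and "ligand_HRG" in data.feature_names
    col = data.X[:, data.feature_names.index("auc_pS6")]
    assert col == pytest.approx(np.log10(feats["auc_pS6"].to_numpy()))
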