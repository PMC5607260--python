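"""Bagged decision trees with a signal-to-noise split criterion.

Each tree greedily partitions feature space; at a node with S responders
("signal") and B non-responders ("background") among n = S + B rows, the
node significance is Z = S/sqrt(S+B) and a split is scored by the gain in
squared significance

    gain = sum_children S_c^2 / n_c  -  S^2 / n,

which is zero exactly when the split leaves the responder fraction
unchanged and positive otherwise, so uninformative nodes become leaves.
(The naive "sum of child Z" score is linear in how the signal is allocated
between fixed-size children and cannot rank features; see the methods
note.)  Gini gain is available as an alternative criterion.

Bagging trains each tree on a bootstrap resample; prediction is the
majority vote, and feature importance is the mean split gain per feature
over all trees.  Evaluation follows the leave-whole-cell-lines-out scheme:
lines are split into train/test repeatedly, training uses all ligands, and
accuracy (fraction of true predictions) is scored on the held-out lines for
the target ligand only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

_MIN_GAIN = 1e-12


class PairingEvaluationError(ValueError):
    """Two split evaluations cannot be compared pairwise."""


@dataclass
class LabeledFeatureSet:
    """Feature rows joined to responder labels, one row per (line, ligand)."""

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...]
    cell_lines: np.ndarray
    ligands: np.ndarray
    #: bootstrap resamples may repeat rows; source datasets may not
    resampled: bool = False

    def __post_init__(self):
        if np.any(pd.isna(self.y)):
            raise ValueError("missing labels are not allowed")
        if not self.resampled:
            key = list(zip(self.cell_lines, self.ligands))
            if len(set(key)) != len(key):
                raise ValueError("more than one label per (cell line, ligand)")
        self.y = np.asarray(self.y, dtype=bool)
        self.X = np.asarray(self.X, dtype=float)

    @classmethod
    def from_tables(cls, features: pd.DataFrame, labels: pd.DataFrame,
                    log10_features: bool = True,
                    include_ligand_indicator: bool = True) -> "LabeledFeatureSet":
        """Join a feature table to a label table on (cell_line, ligand).

        Continuous features are log10-transformed (with floor 1e-12) by
        default — receptor inputs span orders of magnitude and the transform
        is order-preserving, so tree splits are unaffected but thresholds
        become readable.  Ligand identity enters as one boolean column per
        ligand.
        """
        merged = features.merge(labels[["cell_line", "ligand", "responder"]],
                                on=["cell_line", "ligand"], how="inner")
        meta = {"cell_line", "ligand", "responder"}
        bool_cols = [c for c in merged.columns if merged[c].dtype == bool and c not in meta]
        num_cols = [c for c in merged.columns
                    if c not in meta and c not in bool_cols
                    and np.issubdtype(merged[c].dtype, np.number)]
        cols = []
        names: list[str] = []
        for c in num_cols:
            v = merged[c].to_numpy(float)
            cols.append(np.log10(np.maximum(v, 1e-12)) if log10_features else v)
            names.append(c)
        for c in bool_cols:
            cols.append(merged[c].to_numpy(float))
            names.append(c)
        if include_ligand_indicator:
            for lig in sorted(merged["ligand"].unique()):
                cols.append((merged["ligand"] == lig).to_numpy(float))
                names.append(f"ligand_{lig}")
        return cls(
            X=np.column_stack(cols),
            y=merged["responder"].to_numpy(),
            feature_names=tuple(names),
            cell_lines=merged["cell_line"].to_numpy(),
            ligands=merged["ligand"].to_numpy(),
        )

    def subset(self, mask: np.ndarray, resampled: bool = False) -> "LabeledFeatureSet":
        return LabeledFeatureSet(self.X[mask], self.y[mask], self.feature_names,
                                 self.cell_lines[mask], self.ligands[mask],
                                 resampled=resampled or self.resampled)


# ---------------------------------------------------------------------------
# single tree

@dataclass
class TreeNode:
    n: int
    n_signal: int
    feature: int = -1          # -1 marks a leaf
    threshold: float = 0.0
    gain: float = 0.0
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature < 0

    @property
    def signal_fraction(self) -> float:
        return self.n_signal / self.n if self.n else 0.0


@dataclass
class Tree:
    root: TreeNode
    feature_names: tuple[str, ...]

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(len(X), dtype=bool)
        for i, row in enumerate(X):
            node = self.root
            while not node.is_leaf:
                node = node.left if row[node.feature] <= node.threshold else node.right
            out[i] = node.signal_fraction > 0.5
        return out

    def splits(self):
        stack, found = [self.root], []
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                found.append(node)
                stack.extend([node.left, node.right])
        return found


def _best_split(X, y, idx, feature, min_leaf, criterion):
    x = X[idx, feature]
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    ys = y[idx][order].astype(float)
    n = len(idx)
    cs = np.cumsum(ys)
    S = cs[-1]
    pos = np.arange(min_leaf, n - min_leaf + 1)  # cut after xs[pos-1]
    if len(pos) == 0:
        return None
    pos = pos[xs[pos - 1] < xs[pos]]
    if len(pos) == 0:
        return None
    nl = pos.astype(float)
    nr = n - nl
    Sl = cs[pos - 1]
    Sr = S - Sl
    if criterion == "s2n":
        gain = Sl * Sl / nl + Sr * Sr / nr - S * S / n
    elif criterion == "gini":
        Bl, Br, B = nl - Sl, nr - Sr, n - S
        g_parent = 1.0 - (S / n) ** 2 - (B / n) ** 2
        g_l = 1.0 - (Sl / nl) ** 2 - (Bl / nl) ** 2
        g_r = 1.0 - (Sr / nr) ** 2 - (Br / nr) ** 2
        gain = n * (g_parent - (nl / n) * g_l - (nr / n) * g_r)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    k = int(np.argmax(gain))
    thr = 0.5 * (xs[pos[k] - 1] + xs[pos[k]])
    return float(gain[k]), thr


def train_tree(data: LabeledFeatureSet, depth_limit: int = 4, min_leaf: int = 3,
               rng: np.random.Generator | None = None,
               criterion: str = "s2n") -> Tree:
    """Greedy recursive partitioning maximizing the split gain.

    Ties on equal gain resolve to the lowest feature index (the feature loop
    keeps a strictly-greater comparison), and thresholds are midpoints —
    both for determinism.  Pure nodes, exhausted depth, or an absence of
    positive-gain splits produce leaves; all-constant features therefore
    yield a single-leaf tree.
    """
    X, y = data.X, data.y

    def grow(idx: np.ndarray, depth: int) -> TreeNode:
        S = int(y[idx].sum())
        node = TreeNode(n=len(idx), n_signal=S)
        if S in (0, len(idx)) or depth >= depth_limit or len(idx) < 2 * min_leaf:
            return node
        best = None
        for f in range(X.shape[1]):
            res = _best_split(X, y, idx, f, min_leaf, criterion)
            if res is None:
                continue
            gain, thr = res
            if best is None or gain > best[0] + _MIN_GAIN:
                best = (gain, f, thr)
        if best is None or best[0] <= _MIN_GAIN:
            return node
        gain, f, thr = best
        mask = X[idx, f] <= thr
        node.feature, node.threshold, node.gain = f, thr, gain
        node.left = grow(idx[mask], depth + 1)
        node.right = grow(idx[~mask], depth + 1)
        return node

    return Tree(root=grow(np.arange(len(y)), 0), feature_names=data.feature_names)


# ---------------------------------------------------------------------------
# bagging

@dataclass
class BaggedTreeModel:
    trees: list[Tree]
    feature_names: tuple[str, ...]
    seed: int
    bootstrap_seeds: tuple[int, ...]
    criterion: str = "s2n"

    def predict(self, X: np.ndarray) -> np.ndarray:
        votes = np.zeros(len(X))
        for tree in self.trees:
            votes += tree.predict(X)
        return votes > len(self.trees) / 2.0

    def importance(self, normalize: bool = True) -> dict[str, float]:
        """Mean split gain per feature over all trees."""
        acc = np.zeros(len(self.feature_names))
        for tree in self.trees:
            for node in tree.splits():
                acc[node.feature] += node.gain
        acc /= max(len(self.trees), 1)
        if normalize and acc.max() > 0:
            acc = acc / acc.max()
        return dict(zip(self.feature_names, acc))

    def to_text(self, path) -> None:
        import yaml

        def node_dict(node: TreeNode):
            d = {"n": node.n, "n_signal": node.n_signal}
            if not node.is_leaf:
                d.update(feature=self.feature_names[node.feature],
                         threshold=float(node.threshold), gain=float(node.gain),
                         left=node_dict(node.left), right=node_dict(node.right))
            return d

        payload = {
            "seed": self.seed,
            "criterion": self.criterion,
            "bootstrap_seeds": list(self.bootstrap_seeds),
            "feature_names": list(self.feature_names),
            "trees": [node_dict(t.root) for t in self.trees],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def train_bagged(data: LabeledFeatureSet, n_trees: int = 200,
                 bootstrap_fraction: float = 1.0, seed: int = 0,
                 depth_limit: int = 4, min_leaf: int = 3,
                 criterion: str = "s2n") -> BaggedTreeModel:
    """Bootstrap-aggregated trees; ``bootstrap_fraction=0`` disables
    resampling (``n_trees=1`` then reduces to a single train_tree)."""
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(data.y)
    trees = []
    boot_seeds = []
    for _ in range(n_trees):
        s = int(rng.integers(0, 2**31 - 1))
        boot_seeds.append(s)
        if bootstrap_fraction > 0:
            sub_rng = np.random.default_rng(s)
            idx = sub_rng.integers(0, n, size=max(1, int(round(bootstrap_fraction * n))))
            subset = data.subset(idx, resampled=True)
            if subset.y.all() or not subset.y.any():
                log.debug("bootstrap sample is single-class; tree becomes a leaf")
        else:
            subset = data
        trees.append(train_tree(subset, depth_limit=depth_limit, min_leaf=min_leaf,
                                criterion=criterion))
    return BaggedTreeModel(trees=trees, feature_names=data.feature_names, seed=seed,
                           bootstrap_seeds=tuple(boot_seeds), criterion=criterion)


# ---------------------------------------------------------------------------
# split evaluation

@dataclass
class SplitEvaluation:
    """Per-repetition held-out accuracies of the leave-lines-out scheme."""

    accuracies: np.ndarray
    target_ligand: str
    n_reps: int
    train_fraction: float
    seed: int
    control: bool = False
    per_ligand: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.accuracies, ddof=1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rep": np.arange(self.n_reps),
            "ligand": self.target_ligand,
            "accuracy": self.accuracies,
        })


def evaluate_splits(data: LabeledFeatureSet, n_reps: int = 500,
                    train_fraction: float = 0.7, target_ligand: str = "all",
                    exclude_ligands: tuple[str, ...] = ("IGF1",),
                    seed: int = 0, control: bool = False,
                    n_trees: int = 50, depth_limit: int = 4, min_leaf: int = 3,
                    criterion: str = "s2n") -> SplitEvaluation:
    """Random train/test splits by whole cell line.

    Training always uses all (non-excluded) ligand rows of the training
    lines; accuracy is the fraction of true predictions on held-out lines,
    restricted to ``target_ligand`` (or all non-excluded ligands for
    ``"all"``).  ``control=True`` replaces the classifier by a coin flip,
    the 50%-true-predictions reference.
    """
    keep = ~np.isin(data.ligands, exclude_ligands) if exclude_ligands else np.ones(len(data.y), bool)
    if target_ligand != "all":
        if target_ligand not in set(data.ligands):
            raise ValueError(f"no rows for target ligand {target_ligand!r}")
        keep_test = keep & (data.ligands == target_ligand)
    else:
        keep_test = keep
    lines = np.unique(data.cell_lines)
    n_train = max(1, int(round(train_fraction * len(lines))))
    if n_train >= len(lines):
        raise ValueError("train_fraction leaves no test lines")
    rng = np.random.default_rng(seed)
    accs = np.empty(n_reps)
    rep = 0
    attempts = 0
    while rep < n_reps:
        attempts += 1
        if attempts > 20 * n_reps:
            raise RuntimeError("could not draw splits with non-empty test sets")
        perm = rng.permutation(lines)
        train_lines = set(perm[:n_train])
        in_train = np.isin(data.cell_lines, list(train_lines))
        test_mask = ~in_train & keep_test
        if not test_mask.any():
            log.debug("resampling: empty test split for ligand %s", target_ligand)
            continue
        y_test = data.y[test_mask]
        if control:
            pred = rng.random(len(y_test)) < 0.5
        else:
            train = data.subset(in_train & keep)
            model = train_bagged(train, n_trees=n_trees, seed=int(rng.integers(2**31 - 1)),
                                 depth_limit=depth_limit, min_leaf=min_leaf,
                                 criterion=criterion)
            pred = model.predict(data.X[test_mask])
        accs[rep] = float(np.mean(pred == y_test))
        rep += 1
    return SplitEvaluation(accuracies=accs, target_ligand=target_ligand, n_reps=n_reps,
                           train_fraction=train_fraction, seed=seed, control=control)


def compare_to_control(eval_a: SplitEvaluation, eval_b: SplitEvaluation) -> float:
    """One-sided p for 'a is more accurate than b', paired over repetitions
    (Wilcoxon signed-rank on the per-rep accuracy differences)."""
    if eval_a.n_reps != eval_b.n_reps:
        raise PairingEvaluationError("evaluations have different repetition counts")
    diff = eval_a.accuracies - eval_b.accuracies
    if np.allclose(diff, 0.0):
        return 1.0
    res = stats.wilcoxon(diff, alternative="greater", zero_method="zsplit")
    return float(res.pvalue)
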