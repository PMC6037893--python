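"""Out-of-bag random-forest classification and group-comparison statistics.

Each tree in the forest is a CART decision tree (Gini impurity, grown to
purity) fitted on a bootstrap sample drawn *with replacement* of size
ceil(2n/3); the subjects a tree never saw (its out-of-bag set) form that
tree's internal test set, so no held-out dataset is needed. A subject's
OOB prediction is the majority vote over the trees whose bootstrap excluded
it. Variable importance (VIMP) is classical permutation importance: the
mean decrease in a tree's OOB accuracy when one feature's values are
permuted within the OOB samples, averaged over trees.

The size-ceil(2n/3) bootstrap is deliberately non-standard (the classical
bagging bootstrap has size n, leaving ~1/3 of subjects out-of-bag per
tree); ``conventional_bootstrap=True`` switches to the size-n convention.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as ss
from sklearn.tree import DecisionTreeClassifier

from qeeg.features import FEATURE_NAMES, FeatureVector


@dataclass
class ClassifierReport:
    """OOB classification outcome: accuracy, sensitivity, specificity, VIMP."""

    accuracy: float
    sensitivity: float
    specificity: float
    vimp: dict[str, float]
    oob_predictions: dict[str, str]      # subject id -> predicted label
    positive_label: str
    n_tree: int
    m_try: int
    seed: int
    never_oob: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)

    def top_vimp(self, k: int = 5) -> list[tuple[str, float]]:
        return sorted(self.vimp.items(), key=lambda kv: -kv[1])[:k]


def random_forest_oob(
    features: list[FeatureVector],
    labels: list[str] | None = None,
    n_tree: int = 1000,
    m_try: int = 5,
    seed: int = 0,
    positive_label: str | None = None,
    conventional_bootstrap: bool = False,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
) -> ClassifierReport:
    """Two-group random forest with internal out-of-bag cross-validation.

    ``labels`` defaults to each vector's ``group_label``. The positive
    class for sensitivity/specificity defaults to the lexicographically
    first label. Fully deterministic given ``seed``.
    """
    X = np.vstack([f.values for f in features])
    if labels is None:
        labels = [f.group_label for f in features]
    y = np.asarray(labels)
    ids = [f.subject_id or str(i) for i, f in enumerate(features)]
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    counts = {c: int(np.sum(y == c)) for c in classes}
    if min(counts.values()) < 5:
        raise ValueError(f"need >= 5 subjects per class, got {counts}")
    n, p = X.shape
    if m_try > p:
        raise ValueError(f"m_try={m_try} exceeds {p} features")
    if positive_label is None:
        positive_label = classes[0]
    elif positive_label not in classes:
        raise ValueError(f"positive label {positive_label!r} not among {classes}")

    boot_size = n if conventional_bootstrap else math.ceil(2 * n / 3)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))

    votes = np.zeros((n, 2), dtype=int)           # OOB votes per class
    vimp_acc = np.zeros(p)
    vimp_trees = 0
    class_index = {c: k for k, c in enumerate(classes)}

    for _ in range(n_tree):
        boot = rng.integers(0, n, size=boot_size)
        oob = np.setdiff1d(np.arange(n), boot)
        if len(np.unique(y[boot])) < 2:
            continue  # degenerate bootstrap cannot grow a two-class tree
        tree = DecisionTreeClassifier(
            criterion="gini", max_features=m_try,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[boot], y[boot])
        if oob.size == 0:
            continue
        pred = tree.predict(X[oob])
        for idx, pr in zip(oob, pred):
            votes[idx, class_index[pr]] += 1
        # permutation VIMP on this tree's OOB block
        base_acc = float(np.mean(pred == y[oob]))
        for j in range(p):
            perm = rng.permutation(oob.size)
            Xp = X[oob].copy()
            Xp[:, j] = Xp[perm, j]
            vimp_acc[j] += base_acc - float(np.mean(tree.predict(Xp) == y[oob]))
        vimp_trees += 1

    never = [ids[i] for i in range(n) if votes[i].sum() == 0]
    preds = {}
    for i in range(n):
        if votes[i].sum() == 0:
            continue
        # majority vote; ties resolved toward the lexicographically first class
        preds[ids[i]] = classes[int(np.argmax(votes[i]))] if votes[i, 0] != votes[i, 1] \
            else classes[0]

    scored = [i for i in range(n) if ids[i] in preds]
    y_true = y[scored]
    y_pred = np.array([preds[ids[i]] for i in scored])
    pos = positive_label
    tp = int(np.sum((y_true == pos) & (y_pred == pos)))
    tn = int(np.sum((y_true != pos) & (y_pred != pos)))
    fp = int(np.sum((y_true != pos) & (y_pred == pos)))
    fn = int(np.sum((y_true == pos) & (y_pred != pos)))
    accuracy = (tp + tn) / max(1, len(scored))
    sensitivity = tp / max(1, tp + fn)
    specificity = tn / max(1, tn + fp)

    vimp = dict(zip(feature_names[:p] if len(feature_names) >= p
                    else [f"f{j}" for j in range(p)],
                    (vimp_acc / max(1, vimp_trees)).tolist()))
    return ClassifierReport(
        accuracy=float(accuracy), sensitivity=float(sensitivity),
        specificity=float(specificity), vimp=vimp, oob_predictions=preds,
        positive_label=pos, n_tree=n_tree, m_try=m_try, seed=seed,
        never_oob=never,
    )


def compare_groups(groups: dict[str, np.ndarray]) -> dict:
    """One-way ANOVA and Kruskal-Wallis across >= 2 groups of one feature,
    with Bonferroni-multiplied pairwise post-hoc t-tests (capped at 1)."""
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = []
    for name in names:
        arr = np.asarray(groups[name], dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
        arrays.append(arr)

    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        f_stat, f_p = 0.0, 1.0   # identical constant groups: no variance anywhere
    else:
        f_stat, f_p = ss.f_oneway(*arrays)
    try:
        h_stat, h_p = ss.kruskal(*arrays)
    except ValueError:          # all values identical
        h_stat, h_p = 0.0, 1.0

    n_pairs = len(names) * (len(names) - 1) // 2
    posthoc = {}
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            if np.ptp(arrays[a]) == 0 and np.ptp(arrays[b]) == 0 \
                    and arrays[a][0] == arrays[b][0]:
                raw = 1.0
            else:
                raw = float(ss.ttest_ind(arrays[a], arrays[b], equal_var=False).pvalue)
            posthoc[f"{names[a]} vs {names[b]}"] = min(1.0, raw * n_pairs)

    return {
        "anova": {"F": float(f_stat), "p": float(f_p)},
        "kruskal": {"H": float(h_stat), "p": float(h_p)},
        "posthoc_bonferroni": posthoc,
    }


def bonferroni(p_values: list[float]) -> list[float]:
    """Bonferroni multiplication, capped at 1."""
    k = len(p_values)
    return [min(1.0, p * k) for p in p_values]
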