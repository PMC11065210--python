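"""Random-forest accession classification and minimal-depth descriptor
selection.

A forest of CART trees (100 by default) is fitted on a stratified 70%
training split; the remaining 30% provides the validation confusion
matrix, while out-of-bag (OOB) votes on the training rows provide the
OOB error rate.  A descriptor's importance is its *mean minimal depth*
(MDM): in each tree, the depth of the shallowest split that uses it
(root = 0); descriptors a tree never uses are assigned that tree's
depth + 1 so unused descriptors are penalized rather than ignored.
Lower MDM = used earlier = more discriminating.  One-hot children of a
nominal descriptor are collapsed to their parent by per-tree minimum
before averaging.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split

from .descriptors import DescriptorMatrix, encode_for_rf

__all__ = [
    "RFConfig",
    "ForestFit",
    "SelectionResult",
    "DescriptorSelector",
    "fit_forest",
    "minimal_depth",
    "minimal_depth_from_arrays",
    "evaluate",
    "select_top",
]


@dataclass(frozen=True)
class RFConfig:
    """Forest and selection settings (defaults follow common genebank
    classification practice: 100 trees, 70/30 split, top 15 kept)."""

    n_trees: int = 100
    train_fraction: float = 0.7
    top_n: int = 15
    seed: int = 0
    stratify: bool = True

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class ForestFit:
    """A fitted forest plus its recorded train/validation split."""

    model: RandomForestClassifier
    x_train: pd.DataFrame
    y_train: np.ndarray
    x_val: pd.DataFrame
    y_val: np.ndarray
    feature_names: list
    reverse_map: dict
    config: RFConfig

    def split_hash(self) -> str:
        """Digest of every tree's split record (feature/threshold arrays);
        identical seeds must give identical digests."""
        h = hashlib.sha256()
        for est in self.model.estimators_:
            t = est.tree_
            h.update(t.feature.tobytes())
            h.update(np.round(t.threshold, 12).tobytes())
        h.update(np.sort(self.x_train.index.to_numpy().astype(str)).tobytes())
        return h.hexdigest()


@dataclass
class SelectionResult:
    """Minimal-depth ranking with classification diagnostics."""

    mdm: pd.DataFrame            # index descriptor; columns mdm, usage
    depths: pd.DataFrame         # descriptor x tree minimal depths
    oob_error: float
    confusion: pd.DataFrame      # true x predicted proportions
    selected: list
    config: RFConfig
    classes: list = field(default_factory=list)

    @property
    def ranking(self) -> list:
        return list(self.mdm.index)

    def summary(self) -> str:
        lines = [
            "Random-forest descriptor selection",
            "==================================",
            f"trees: {self.config.n_trees}   "
            f"train fraction: {self.config.train_fraction}   "
            f"classes: {len(self.classes)}",
            f"OOB error rate: {self.oob_error:.3f}",
            f"selected top {len(self.selected)} descriptors (ascending MDM):",
        ]
        for name in self.selected:
            row = self.mdm.loc[name]
            lines.append(
                f"  {name:<24s} MDM={row['mdm']:7.3f}  used in {int(row['usage'])} trees"
            )
        return "\n".join(lines)

    def plot_minimal_depth(self, ax=None, top_n: int | None = None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        names = self.ranking[: top_n or len(self.selected)]
        ax.barh(range(len(names)), self.mdm.loc[names, "mdm"], color="#4878b0")
        ax.set_yticks(range(len(names)), names)
        ax.invert_yaxis()
        ax.set_xlabel("mean minimal depth (MDM)")
        return ax

    def plot_confusion(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(self.confusion.to_numpy(), cmap="viridis", vmin=0, vmax=1)
        ax.set_xticks(range(len(self.confusion.columns)), self.confusion.columns,
                      rotation=90, fontsize=7)
        ax.set_yticks(range(len(self.confusion.index)), self.confusion.index,
                      fontsize=7)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        ax.figure.colorbar(im, ax=ax, label="row proportion")
        return ax


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def fit_forest(
    encoded: pd.DataFrame,
    labels,
    config: RFConfig,
    reverse_map: dict | None = None,
) -> ForestFit:
    """Stratified 70/30 split and bootstrap forest with sqrt(p) feature
    subsampling.  Any class with a single row is a hard error."""
    y = np.asarray(labels).astype(str)
    counts = pd.Series(y).value_counts()
    singles = sorted(counts[counts < 2].index)
    if singles:
        raise ValueError(
            f"class(es) with fewer than 2 rows cannot be split: {singles}"
        )
    if counts.size < 2:
        raise ValueError("need at least 2 classes")

    x_train, x_val, y_train, y_val = train_test_split(
        encoded,
        y,
        train_size=config.train_fraction,
        stratify=y if config.stratify else None,
        random_state=config.seed,
    )
    model = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features="sqrt",
        bootstrap=True,
        oob_score=True,
        random_state=config.seed,
        min_samples_leaf=1,
    )
    with warnings.catch_warnings():
        # small training sets can leave a few rows without OOB votes;
        # those rows are excluded explicitly in evaluate()
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB")
        model.fit(x_train.to_numpy(), y_train)
    return ForestFit(
        model=model,
        x_train=x_train,
        y_train=y_train,
        x_val=x_val,
        y_val=y_val,
        feature_names=list(encoded.columns),
        reverse_map=reverse_map or {c: c for c in encoded.columns},
        config=config,
    )


def _tree_min_depths(children_left, children_right, feature):
    """Per-feature shallowest split depth and the tree's leaf depth.

    Iterative DFS over the node arrays (sklearn ``tree_`` layout:
    ``feature[i] < 0`` marks a leaf).
    """
    min_depth: dict = {}
    max_depth = 0
    stack = [(0, 0)]
    while stack:
        node, depth = stack.pop()
        max_depth = max(max_depth, depth)
        f = feature[node]
        if f >= 0:
            if f not in min_depth or depth < min_depth[f]:
                min_depth[f] = depth
            stack.append((children_left[node], depth + 1))
            stack.append((children_right[node], depth + 1))
    return min_depth, max_depth


def minimal_depth_from_arrays(
    trees,
    feature_names,
    reverse_map: dict | None = None,
) -> pd.DataFrame:
    """Minimal-depth table from raw tree arrays.

    ``trees`` is an iterable of ``(children_left, children_right,
    feature)`` triples.  Returns a descriptor x tree DataFrame of
    per-tree minimal depths (absent descriptors filled with that tree's
    leaf depth + 1), already collapsed to parent descriptors.
    """
    reverse_map = reverse_map or {c: c for c in feature_names}
    parents = sorted(set(reverse_map.values()), key=list(reverse_map.values()).index)
    columns = []
    for left, right, feat in trees:
        md, depth = _tree_min_depths(left, right, feat)
        fill = depth + 1
        per_parent = {p: fill for p in parents}
        for f_idx, d in md.items():
            parent = reverse_map[feature_names[f_idx]]
            per_parent[parent] = min(per_parent[parent], d)
        columns.append(per_parent)
    return pd.DataFrame(columns, index=range(len(columns))).T


def minimal_depth(fit: ForestFit) -> tuple:
    """Mean minimal depth per parent descriptor over the forest.

    Returns ``(table, depths)``: ``table`` has columns ``mdm`` (mean of
    the per-tree minimal depths) and ``usage`` (number of trees whose
    splits actually use the descriptor); ``depths`` is the full
    descriptor x tree distribution.
    """
    trees = [
        (e.tree_.children_left, e.tree_.children_right, e.tree_.feature)
        for e in fit.model.estimators_
    ]
    depths = minimal_depth_from_arrays(trees, fit.feature_names, fit.reverse_map)

    usage = pd.Series(0, index=depths.index, dtype=int)
    for left, right, feat in trees:
        used_parents = {
            fit.reverse_map[fit.feature_names[f]] for f in feat if f >= 0
        }
        for p in used_parents:
            usage[p] += 1
    table = pd.DataFrame({"mdm": depths.mean(axis=1), "usage": usage})
    table = (
        table.reset_index(names="name")
        .sort_values(by=["mdm", "usage", "name"], ascending=[True, False, True],
                     kind="stable")
        .set_index("name")
        .rename_axis(None)
    )
    return table, depths


def evaluate(fit: ForestFit) -> tuple:
    """OOB error on training rows and row-normalized validation confusion.

    Training rows without any OOB vote (possible at small n) are
    excluded from the error; validation classes with zero rows get NaN
    confusion rows.
    """
    oob = fit.model.oob_decision_function_
    has_votes = np.asarray(oob).sum(axis=1) > 0
    pred_idx = np.argmax(oob[has_votes], axis=1)
    pred = fit.model.classes_[pred_idx]
    oob_error = float(np.mean(pred != fit.y_train[has_votes]))

    classes = sorted(set(fit.y_train) | set(fit.y_val))
    y_pred = fit.model.predict(fit.x_val.to_numpy())
    counts = confusion_matrix(fit.y_val, y_pred, labels=classes).astype(float)
    support = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        props = np.where(support > 0, counts / support, np.nan)
    confusion = pd.DataFrame(props, index=classes, columns=classes)
    return oob_error, confusion


def select_top(mdm: pd.DataFrame, top_n: int = 15) -> list:
    """Descriptors by ascending MDM; ties broken by higher usage count,
    then lexicographically."""
    order = mdm.reset_index(names="name").sort_values(
        by=["mdm", "usage", "name"], ascending=[True, False, True], kind="stable"
    )
    return order["name"].head(top_n).tolist()


# --------------------------------------------------------------------------
# model-style wrapper
# --------------------------------------------------------------------------

class DescriptorSelector:
    """Fit a classification forest on a descriptor matrix and rank
    descriptors by mean minimal depth.

    ``label_level`` chooses the class label: ``"accession"`` (the usual
    target: can each accession be told apart?) or ``"species"``.
    """

    def __init__(
        self,
        matrix: DescriptorMatrix,
        config: RFConfig | None = None,
        label_level: str = "accession",
    ):
        if label_level not in ("accession", "species"):
            raise ValueError("label_level must be 'accession' or 'species'")
        self.matrix = matrix
        self.config = config or RFConfig()
        self.label_level = label_level

    def fit(self) -> SelectionResult:
        encoded, reverse_map = encode_for_rf(self.matrix)
        labels = (
            self.matrix.accession
            if self.label_level == "accession"
            else self.matrix.species
        )
        forest = fit_forest(encoded, labels, self.config, reverse_map)
        table, depths = minimal_depth(forest)
        oob_error, confusion = evaluate(forest)
        selected = select_top(table, self.config.top_n)
        result = SelectionResult(
            mdm=table,
            depths=depths,
            oob_error=oob_error,
            confusion=confusion,
            selected=selected,
            config=self.config,
            classes=list(forest.model.classes_),
        )
        result.forest_ = forest
        return result
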