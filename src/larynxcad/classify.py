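"""Decision-tree-structured SVM for five laryngeal conditions.

Binary SVMs are arranged in a fixed tree that mirrors the feature logic:
the root separates geometrically abnormal cords (convex protrusion: polyp
or cyst) from the rest; the abnormal branch separates polyp from cyst on
the protrusion's length-to-width ratio; the normal branch separates healthy
cords from hue-changed ones on the gray standard deviation, and finally
leukoplakia from tumor.  Every input is routed root-to-leaf, so the
classification is exhaustive and exclusive; each node's SVM (RBF kernel by
default) is trained only on the samples its parent routes to it, using the
feature subset declared for that node.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from larynxcad.config import ClassifyConfig
from larynxcad.errors import TrainingError
from larynxcad.phantom import LABELS

MODEL_FORMAT_VERSION = "1"

# (node name, feature subset, class split) — left branch first.
DEFAULT_TOPOLOGY: list[tuple[str, list[str], tuple[tuple[str, ...], tuple[str, ...]]]] = [
    (
        "geometry",
        ["any_abnormal", "max_deviation"],
        (("polyp", "cyst"), ("healthy", "leukoplakia", "tumor")),
    ),
    ("protrusion", ["lw_ratio", "max_deviation"], (("polyp",), ("cyst",))),
    (
        "hue",
        ["gray_std_max"],
        (("healthy",), ("leukoplakia", "tumor")),
    ),
    ("texture", ["gray_std_max", "max_deviation"], (("leukoplakia",), ("tumor",))),
]


@dataclass
class _Node:
    name: str
    feature_names: list[str]
    groups: tuple[tuple[str, ...], tuple[str, ...]]
    svm: Pipeline | None = None
    children: list["_Node | str"] = field(default_factory=list)

    @property
    def classes(self) -> set[str]:
        return set(self.groups[0]) | set(self.groups[1])


@dataclass
class TreeSvmModel:
    """Trained decision-tree SVM."""

    root: _Node
    feature_columns: list[str]
    training_meta: dict = field(default_factory=dict)

    def predict_one(self, row: dict[str, float]) -> tuple[str, list[str]]:
        """Route one feature row root-to-leaf; returns (label, node path)."""
        node: _Node | str = self.root
        path: list[str] = []
        while isinstance(node, _Node):
            if node.svm is None:
                raise TrainingError(f"node '{node.name}' is untrained")
            x = np.array([[row[f] for f in node.feature_names]])
            branch = int(node.svm.predict(x)[0])
            path.append(f"{node.name}:{branch}")
            node = node.children[branch]
        return node, path

    def predict(self, table: pd.DataFrame) -> list[str]:
        return [self.predict_one(row) [0] for row in table.to_dict("records")]


def _build_topology(topology=None) -> _Node:
    topology = topology if topology is not None else DEFAULT_TOPOLOGY
    nodes = {name: _Node(name, list(feats), (tuple(g0), tuple(g1))) for name, feats, (g0, g1) in topology}
    by_group: dict[frozenset, _Node] = {frozenset(n.classes): n for n in nodes.values()}
    for node in nodes.values():
        children: list[_Node | str] = []
        for group in node.groups:
            if len(group) == 1:
                children.append(group[0])
            else:
                child = by_group.get(frozenset(group))
                if child is None:
                    raise TrainingError(f"no node handles class group {group}")
                children.append(child)
        node.children = children
    root = by_group[frozenset(LABELS)]
    return root


def build_tree(
    features: pd.DataFrame,
    labels: Sequence[str],
    config: ClassifyConfig | None = None,
    seed: int = 0,
    topology=None,
) -> TreeSvmModel:
    """Train every node SVM of the decision tree on its routed subset.

    Routing during training follows the true labels, so each node sees
    exactly the samples whose class belongs to its subtree.  Raises
    :class:`TrainingError` naming the node if a branch has no samples.
    """
    config = config or ClassifyConfig()
    labels = np.asarray(labels, dtype=object)
    unknown = set(labels) - set(LABELS)
    if unknown:
        raise TrainingError(f"unknown labels: {sorted(unknown)}")
    root = _build_topology(topology)
    stack = [root]
    while stack:
        node = stack.pop()
        in_node = np.isin(labels, sorted(node.classes))
        y = np.isin(labels[in_node], node.groups[1]).astype(int)
        if len(np.unique(y)) < 2:
            raise TrainingError(
                f"node '{node.name}' needs samples from both branches {node.groups}"
            )
        x = features.loc[in_node, node.feature_names].to_numpy(dtype=float)
        node.svm = make_pipeline(
            StandardScaler(),
            SVC(kernel=config.kernel, C=config.C, gamma=config.gamma, random_state=seed),
        )
        node.svm.fit(x, y)
        stack.extend(c for c in node.children if isinstance(c, _Node))
    return TreeSvmModel(
        root=root,
        feature_columns=list(features.columns),
        training_meta={
            "n_samples": int(len(labels)),
            "class_counts": {c: int((labels == c).sum()) for c in LABELS},
            "seed": int(seed),
            "kernel": config.kernel,
            "C": config.C,
            "format_version": MODEL_FORMAT_VERSION,
        },
    )


def classify(model: TreeSvmModel, feature_row: dict[str, float]) -> tuple[str, list[str]]:
    """Label one feature vector; returns the label and the audit node path."""
    return model.predict_one(feature_row)


def cross_validate(
    features: pd.DataFrame,
    labels: Sequence[str],
    k: int = 10,
    seed: int = 0,
    config: ClassifyConfig | None = None,
) -> dict:
    """Stratified k-fold cross-validation of the tree SVM.

    Returns per-class recognition rates and the overall rate; folds are
    stratified by class and fully determined by ``seed``.
    """
    labels = np.asarray(labels, dtype=object)
    if k < 2:
        raise ValueError("need k >= 2 folds")
    counts = {c: int((labels == c).sum()) for c in np.unique(labels)}
    starved = [c for c, n in counts.items() if n < k]
    if starved:
        raise TrainingError(f"classes with fewer samples than folds: {starved}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    predicted = np.empty_like(labels)
    for train_idx, test_idx in skf.split(features, labels):
        model = build_tree(features.iloc[train_idx], labels[train_idx], config, seed=seed)
        predicted[test_idx] = model.predict(features.iloc[test_idx])
    per_class = {
        c: float((predicted[labels == c] == c).mean()) for c in np.unique(labels)
    }
    return {
        "per_class": per_class,
        "overall": float((predicted == labels).mean()),
        "k": k,
        "seed": seed,
    }


def save_model(model: TreeSvmModel, path: str | Path) -> None:
    """Persist a trained model (joblib archive with a format version)."""
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, Path(path))


def load_model(path: str | Path) -> TreeSvmModel:
    payload = joblib.load(Path(path))
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise TrainingError(f"unsupported model format: {payload.get('format_version')}")
    return payload["model"]
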