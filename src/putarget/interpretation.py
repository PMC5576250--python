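"""Feature importance and decision-tree rule extraction.

Two filter-style importance measures are computed against the binary label
without removing any feature: the chi-squared statistic of the
bin x label contingency table, and the information gain
H(label) - H(label | bin) in bits.  Continuous features are discretised
into equal-frequency bins, with the (typically dominant) zeros collapsed
into a bin of their own so sparsity does not swamp the quantiles.

A shallow CART-style classification tree, fitted with scikit-learn, offers
human-readable classification criteria: each node reports the split, the
majority class, per-class counts and the share of observations reaching it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeClassifier


@dataclass
class TreeNode:
    node_id: int
    depth: int
    feature: str | None  # None for leaves
    threshold: float | None
    predicted_class: int
    class_counts: tuple[int, int]  # (non-target, target)
    percentage: float  # share of all observations reaching this node
    children: tuple[int, int] | None  # (left, right) node ids


@dataclass
class TreeReport:
    nodes: list[TreeNode]

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.nodes if n.children is None]

    def root(self) -> TreeNode:
        return self.nodes[0]

    def render(self) -> str:
        """Indented text listing, one line per node."""
        lines = []
        for n in self.nodes:
            pad = "  " * n.depth
            rule = (
                f"{n.feature} <= {n.threshold:.4g}" if n.children is not None else "leaf"
            )
            lines.append(
                f"{pad}[{n.node_id}] {rule} | class {n.predicted_class} "
                f"| counts {n.class_counts[0]}/{n.class_counts[1]} "
                f"| {n.percentage:.1f}%"
            )
        return "\n".join(lines)

    def to_records(self) -> list[dict]:
        return [
            {
                "node_id": n.node_id,
                "depth": n.depth,
                "feature": n.feature,
                "threshold": n.threshold,
                "predicted_class": n.predicted_class,
                "count_non_target": n.class_counts[0],
                "count_target": n.class_counts[1],
                "percentage": n.percentage,
                "children": n.children,
            }
            for n in self.nodes
        ]


def discretise(values: np.ndarray, n_bins: int = 5) -> np.ndarray:
    """Equal-frequency bin codes, with zeros collapsed into bin 0.

    Non-zero values are cut at their empirical quantiles into up to
    ``n_bins`` bins (fewer when ties collapse edges).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = np.asarray(values, dtype=float)
    codes = np.zeros(len(x), dtype=int)
    nz = x != 0
    if nz.sum():
        nonzero = pd.Series(x[nz])
        binned = pd.qcut(nonzero, q=min(n_bins, nonzero.nunique()), duplicates="drop")
        codes[nz] = binned.cat.codes.to_numpy() + 1
    return codes


def _entropy_bits(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def feature_importance(
    features: pd.DataFrame,
    labels,
    method: str = "infogain",
    n_bins: int = 5,
) -> pd.DataFrame:
    """Per-feature relevance score against the binary label.

    ``method`` is ``chisq`` (chi-squared statistic, no continuity
    correction) or ``infogain`` (mutual information in bits).  Constant
    features score 0 with a warning.  Returns a frame indexed by feature
    with columns ``value`` and ``n_bins_used``.
    """
    if method not in ("chisq", "infogain"):
        raise ValueError(f"unknown importance method: {method!r}")
    y = np.asarray(labels, dtype=int)
    rows = []
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        if np.all(x == x[0]):
            warnings.warn(f"feature {col!r} is constant; importance 0")
            rows.append({"feature": col, "value": 0.0, "n_bins_used": 1})
            continue
        codes = discretise(x, n_bins=n_bins)
        table = pd.crosstab(codes, y).to_numpy()
        if method == "chisq":
            value = float(stats.chi2_contingency(table, correction=False)[0])
        else:
            n = table.sum()
            h_y = _entropy_bits(table.sum(axis=0))
            h_y_given_bin = sum(
                row.sum() / n * _entropy_bits(row) for row in table
            )
            value = max(h_y - h_y_given_bin, 0.0)
        rows.append({"feature": col, "value": value, "n_bins_used": table.shape[0]})
    return pd.DataFrame(rows).set_index("feature")


def fit_inspection_tree(
    features: pd.DataFrame,
    labels,
    max_depth: int = 3,
    min_samples_leaf: int = 1,
    seed: int = 0,
) -> TreeReport:
    """Fit a shallow classification tree and extract its rule structure."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        warnings.warn("single-class data; inspection tree is a single node")
    clf = DecisionTreeClassifier(
        max_depth=max_depth, min_samples_leaf=min_samples_leaf, random_state=seed
    )
    clf.fit(features.to_numpy(dtype=float), y)
    t = clf.tree_
    total = float(t.n_node_samples[0])
    class_order = list(clf.classes_)

    def counts_at(i: int) -> tuple[int, int]:
        raw = t.value[i][0] * t.weighted_n_node_samples[i]
        # sklearn >= 1.3 stores normalised values; recover counts
        raw = np.rint(raw / raw.sum() * t.n_node_samples[i]).astype(int)
        out = [0, 0]
        for cls, cnt in zip(class_order, raw):
            out[int(cls)] = int(cnt)
        return (out[0], out[1])

    nodes: list[TreeNode] = []

    def walk(i: int, depth: int) -> None:
        left, right = t.children_left[i], t.children_right[i]
        is_leaf = left == -1
        cc = counts_at(i)
        nodes.append(
            TreeNode(
                node_id=int(i),
                depth=depth,
                feature=None if is_leaf else str(features.columns[t.feature[i]]),
                threshold=None if is_leaf else float(t.threshold[i]),
                predicted_class=int(class_order[int(np.argmax(t.value[i][0]))]),
                class_counts=cc,
                percentage=100.0 * t.n_node_samples[i] / total,
                children=None if is_leaf else (int(left), int(right)),
            )
        )
        if not is_leaf:
            walk(int(left), depth + 1)
            walk(int(right), depth + 1)

    walk(0, 0)
    return TreeReport(nodes=nodes)
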