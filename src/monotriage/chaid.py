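"""CHAID (chi-square automatic interaction detection) tree induction.

Classification CHAID with a two-level dependent variable: at each node,
each predictor's categories are first merged bottom-up (the least
significant pair of category groups by Pearson chi-square is merged until
every remaining pair differs at ``alpha_merge``), the merged table's
chi-square p-value is Bonferroni-adjusted by the number of ways the
original categories can be partitioned into the final groups (Stirling
number of the second kind; 1 for binary predictors), and the node splits
on the predictor with the smallest adjusted p-value if it clears
``alpha_split`` and the node-size floors. The first split can be forced
onto a named predictor, mirroring a laboratory constraint that a smear
is always reviewed when any independent trigger demands it.

Pearson chi-square is computed without continuity correction throughout
(CHAID convention), and p-value ties break on a fixed predictor order.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ValidationError

__all__ = [
    "ChaidConfig",
    "ChaidNode",
    "ChaidTree",
    "ChaidModel",
    "ChaidResults",
    "merge_categories",
    "grow",
    "predict",
    "stirling2",
]

#: Clinical ordering of the binarized predictors, used for tie-breaking.
DEFAULT_PREDICTOR_ORDER = ("any_trigger", "monoscore_pos", "dysplasia_pos", "cmo_pos")


@dataclass(frozen=True)
class ChaidConfig:
    alpha_merge: float = 0.05
    alpha_split: float = 0.05
    bonferroni: bool = True
    min_parent: int = 20
    min_child: int = 7
    max_depth: int = 4
    forced_first_split: str | None = None

    def __post_init__(self) -> None:
        for name in ("alpha_merge", "alpha_split"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must lie strictly between 0 and 1")
        if self.min_child > self.min_parent:
            raise ValidationError("min_child cannot exceed min_parent")
        if self.max_depth < 1:
            raise ValidationError("max_depth must be at least 1")


def stirling2(n: int, k: int) -> int:
    """Number of ways to partition n labelled items into k nonempty groups."""
    return sum(
        (-1) ** i * math.comb(k, i) * (k - i) ** n for i in range(k + 1)
    ) // math.factorial(k)


def _chi2_p(counts: np.ndarray) -> float:
    """Pearson chi-square p (no continuity correction) of a groups x class
    table; degenerate tables (a zero row/column) give p = 1."""
    counts = counts[counts.sum(axis=1) > 0]
    if counts.shape[0] < 2 or (counts.sum(axis=0) > 0).sum() < 2:
        return 1.0
    _, p, _, _ = stats.chi2_contingency(counts, correction=False)
    return float(p)


def merge_categories(
    counts: pd.DataFrame | Mapping[Hashable, Sequence[int]],
    cfg: ChaidConfig = ChaidConfig(),
) -> tuple[list[tuple[Hashable, ...]], float]:
    """CHAID category merging for one predictor at one node.

    ``counts`` maps each predictor category to its per-class counts
    (a DataFrame with categories as rows works directly). Pairs of
    category groups are merged, least significant first, until every
    remaining pair differs at ``alpha_merge``. Binary predictors are
    returned unmerged. Returns the partition (tuples of original
    categories) and the chi-square p of the final merged table.
    """
    if not isinstance(counts, pd.DataFrame):
        counts = pd.DataFrame.from_dict(dict(counts), orient="index")
    table = counts.to_numpy(dtype=float)
    if table.shape[0] < 2:
        raise ValidationError("merging requires at least two categories")
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise ValidationError("counts must be nonnegative integers")
    if table.sum() == 0:
        raise ValidationError("zero-total contingency table")
    groups: list[tuple[Hashable, ...]] = [(c,) for c in counts.index]
    rows = [table[i] for i in range(table.shape[0])]
    while len(groups) > 2:
        best_pair, best_p = None, -1.0
        for i, j in combinations(range(len(groups)), 2):
            p = _chi2_p(np.vstack([rows[i], rows[j]]))
            if p > best_p:
                best_pair, best_p = (i, j), p
        if best_p <= cfg.alpha_merge:
            break
        i, j = best_pair
        groups[i] = groups[i] + groups[j]
        rows[i] = rows[i] + rows[j]
        del groups[j], rows[j]
    return groups, _chi2_p(np.vstack(rows))


@dataclass
class ChaidNode:
    node_id: int
    depth: int
    class_counts: dict  # class label -> count at this node
    predictor: str | None = None  # split predictor; None for a leaf
    groups: list[tuple] = field(default_factory=list)
    children: list[int] = field(default_factory=list)  # child node ids, parallel to groups
    p_adjusted: float | None = None

    @property
    def is_leaf(self) -> bool:
        return self.predictor is None

    @property
    def n(self) -> int:
        return sum(self.class_counts.values())

    @property
    def majority_class(self):
        # deterministic tie-break on the label itself
        return max(sorted(self.class_counts), key=lambda c: self.class_counts[c])


@dataclass
class ChaidTree:
    nodes: dict[int, ChaidNode]
    root_id: int
    predictors: tuple[str, ...]
    classes: tuple
    config: ChaidConfig

    @property
    def depth(self) -> int:
        return max(n.depth for n in self.nodes.values())

    @property
    def leaves(self) -> list[ChaidNode]:
        return [n for n in self.nodes.values() if n.is_leaf]

    def route(self, record: Mapping) -> ChaidNode:
        """Walk a record to its leaf."""
        node = self.nodes[self.root_id]
        while not node.is_leaf:
            if node.predictor not in record:
                raise ValidationError(f"record missing predictor {node.predictor!r}")
            value = record[node.predictor]
            for group, child_id in zip(node.groups, node.children):
                if value in group:
                    node = self.nodes[child_id]
                    break
            else:
                raise ValidationError(
                    f"value {value!r} of {node.predictor!r} matches no category group"
                )
        return node

    def predict(self, record: Mapping):
        leaf = self.route(record)
        return leaf.majority_class, leaf.node_id

    def to_dict(self) -> dict:
        def node_dict(nid: int) -> dict:
            n = self.nodes[nid]
            d = {
                "node_id": n.node_id,
                "depth": n.depth,
                "n": n.n,
                "class_counts": {str(k): v for k, v in n.class_counts.items()},
                "majority_class": str(n.majority_class),
            }
            if not n.is_leaf:
                d["predictor"] = n.predictor
                d["p_adjusted"] = n.p_adjusted
                d["children"] = [
                    {"group": [str(g) for g in grp], "node": node_dict(cid)}
                    for grp, cid in zip(n.groups, n.children)
                ]
            return d

        return {
            "predictors": list(self.predictors),
            "classes": [str(c) for c in self.classes],
            "tree": node_dict(self.root_id),
        }

    def render(self) -> str:
        """Plain-text rendering of the tree."""
        lines: list[str] = []

        def walk(nid: int, indent: str, label: str) -> None:
            n = self.nodes[nid]
            counts = ", ".join(f"{k}={v}" for k, v in sorted(n.class_counts.items(), key=str))
            if n.is_leaf:
                lines.append(f"{indent}{label}leaf #{n.node_id} [{counts}] -> {n.majority_class}")
            else:
                lines.append(
                    f"{indent}{label}node #{n.node_id} [{counts}] split on "
                    f"{n.predictor} (adj p={n.p_adjusted:.3g})"
                )
                for grp, cid in zip(n.groups, n.children):
                    walk(cid, indent + "  ", f"{n.predictor} in {list(grp)}: ")

        walk(self.root_id, "", "")
        return "\n".join(lines)


def _node_counts(y: pd.Series, classes: Sequence) -> dict:
    vc = y.value_counts()
    return {c: int(vc.get(c, 0)) for c in classes}


def _best_split(df: pd.DataFrame, predictors: Sequence[str], target: str,
                classes: Sequence, cfg: ChaidConfig, force: str | None):
    """Return (predictor, groups, p_adj) or None if no admissible split."""
    candidates = [force] if force is not None else list(predictors)
    best = None
    for pred in candidates:
        levels = df[pred].unique()
        if len(levels) < 2:
            continue
        counts = pd.crosstab(df[pred], df[target]).reindex(columns=classes, fill_value=0)
        groups, p = merge_categories(counts, cfg)
        if cfg.bonferroni:
            multiplier = stirling2(len(counts.index), len(groups))
            p = min(1.0, p * multiplier)
        # node-size floor: every child must keep min_child records
        sizes = [int(df[pred].isin(grp).sum()) for grp in groups]
        if min(sizes) < cfg.min_child:
            continue
        if force is None and p > cfg.alpha_split:
            continue
        if best is None or p < best[2]:  # strict <: ties keep earlier predictor
            best = (pred, groups, p)
    return best


def grow(
    data: pd.DataFrame,
    target: str = "consensus_dx",
    predictors: Sequence[str] | None = None,
    cfg: ChaidConfig = ChaidConfig(),
) -> ChaidTree:
    """Induce a CHAID tree from a feature table.

    ``data`` holds one row per record with categorical predictor columns
    and a two-level target column. Predictors are considered in the given
    order (default: the clinical ordering trigger, Monoscore, dysplasia,
    cMo restricted to the columns present), which also breaks ties in
    adjusted p. Growth is deterministic given the config and invariant to
    record order.
    """
    if predictors is None:
        predictors = [c for c in DEFAULT_PREDICTOR_ORDER if c in data.columns]
        if not predictors:
            predictors = [c for c in data.columns if c != target]
    classes = tuple(sorted(pd.unique(data[target]), key=str))
    if len(classes) > 2:
        raise ValidationError(f"CHAID target must have at most 2 levels, got {classes}")
    # a pure-class dataset degenerates to a single leaf (one observed level)
    if cfg.forced_first_split is not None and cfg.forced_first_split not in predictors:
        raise ValidationError(
            f"forced_first_split {cfg.forced_first_split!r} is not among the predictors"
        )
    # sort for record-order invariance of all chi-square inputs
    data = data.sort_values(by=[target, *predictors], kind="mergesort").reset_index(drop=True)

    nodes: dict[int, ChaidNode] = {}
    counter = iter(range(10 ** 9))

    def build(df: pd.DataFrame, depth: int, force: str | None) -> int:
        nid = next(counter)
        node = ChaidNode(node_id=nid, depth=depth,
                         class_counts=_node_counts(df[target], classes))
        nodes[nid] = node
        pure = any(node.class_counts[c] == node.n for c in classes)
        if depth >= cfg.max_depth or node.n < cfg.min_parent or pure:
            return nid
        split = _best_split(df, predictors, target, classes, cfg, force)
        if split is None:
            return nid
        pred, groups, p_adj = split
        node.predictor, node.groups, node.p_adjusted = pred, list(groups), p_adj
        for grp in groups:
            child_df = df[df[pred].isin(grp)]
            node.children.append(build(child_df, depth + 1, None))
        return nid

    root = build(data, 0, cfg.forced_first_split)
    return ChaidTree(nodes=nodes, root_id=root, predictors=tuple(predictors),
                     classes=classes, config=cfg)


def predict(tree: ChaidTree, record: Mapping):
    """Route one record through the tree; returns (class, leaf id)."""
    return tree.predict(record)


# --------------------------------------------------------------------------
# Model/Results surface
# --------------------------------------------------------------------------

class ChaidModel:
    """Model-object wrapper over :func:`grow`.

    Built from a feature table and a target column; ``fit`` returns a
    :class:`ChaidResults` carrying the induced tree, per-leaf class
    distributions and a text summary.
    """

    def __init__(self, data: pd.DataFrame, target: str = "consensus_dx",
                 predictors: Sequence[str] | None = None,
                 config: ChaidConfig = ChaidConfig()):
        self.data = data
        self.target = target
        self.predictors = predictors
        self.config = config

    @classmethod
    def from_cohort(cls, cohort, score_cfg=None, config: ChaidConfig = ChaidConfig()):
        from .report import cohort_feature_table  # local import to avoid a cycle
        return cls(cohort_feature_table(cohort, score_cfg), config=config)

    def fit(self) -> "ChaidResults":
        tree = grow(self.data, self.target, self.predictors, self.config)
        return ChaidResults(model=self, tree=tree)


@dataclass
class ChaidResults:
    model: ChaidModel
    tree: ChaidTree

    def predict(self, records: pd.DataFrame) -> pd.Series:
        return pd.Series(
            [self.tree.predict(row)[0] for _, row in records.iterrows()],
            index=records.index, name="predicted",
        )

    def summary(self) -> str:
        t = self.tree
        head = (
            f"CHAID classification tree: {len(t.nodes)} nodes, "
            f"{len(t.leaves)} leaves, depth {t.depth}\n"
            f"predictors: {', '.join(t.predictors)}; classes: "
            f"{', '.join(str(c) for c in t.classes)}\n"
        )
        return head + t.render()

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.tree.to_dict(), **kwargs)
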