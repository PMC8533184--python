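"""UPGMA cluster validation of a methylation signature.

Given cohorts restricted to the signature probes, samples are clustered
by UPGMA (unweighted pair-group method with arithmetic mean) on plain
Euclidean distance over β values.  Cutting the dendrogram at the root
yields two clusters; each cluster is assigned the majority class of its
labelled members and unlabelled samples inherit their cluster's class.
Confusion counts against the true labels give sensitivity, specificity
and the error rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .matrix import BetaMatrix

__all__ = [
    "Dendrogram",
    "DendrogramNode",
    "ClassMetrics",
    "euclidean_distances",
    "upgma",
    "two_cluster_classes",
    "classification_metrics",
    "cut_clusters",
    "cluster_composition",
]


def euclidean_distances(m: BetaMatrix) -> pd.DataFrame:
    """Symmetric sample-by-sample Euclidean distance over all probes."""
    if not m.is_complete():
        raise ValueError("matrix has missing values")
    x = m.values.T  # samples x probes
    sq = (x**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.maximum(d2, 0.0, out=d2)
    d = np.sqrt(d2)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return pd.DataFrame(d, index=m.sample_ids, columns=m.sample_ids)


@dataclass
class DendrogramNode:
    """Binary merge-tree node; leaves carry a sample id and height 0."""

    height: float
    children: tuple["DendrogramNode", ...] = ()
    leaf_id: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def leaves(self) -> tuple[str, ...]:
        if self.is_leaf:
            return (self.leaf_id,)
        out: tuple[str, ...] = ()
        for c in self.children:
            out += c.leaves
        return out


class Dendrogram:
    """UPGMA merge tree over sample leaves with non-decreasing heights."""

    def __init__(self, root: DendrogramNode):
        self.root = root

    @property
    def leaf_ids(self) -> tuple[str, ...]:
        return self.root.leaves

    def merge_heights(self) -> list[float]:
        """All internal-node heights, in merge (ascending) order."""
        out: list[float] = []

        def walk(n: DendrogramNode) -> None:
            if not n.is_leaf:
                out.append(n.height)
                for c in n.children:
                    walk(c)

        walk(self.root)
        return sorted(out)

    def cophenetic(self) -> pd.DataFrame:
        """Pairwise cophenetic distances (height of the lowest common merge)."""
        ids = list(self.leaf_ids)
        coph = pd.DataFrame(0.0, index=ids, columns=ids)

        def walk(n: DendrogramNode) -> None:
            if n.is_leaf:
                return
            left, right = n.children
            for a in left.leaves:
                for b in right.leaves:
                    coph.loc[a, b] = n.height
                    coph.loc[b, a] = n.height
            walk(left)
            walk(right)

        walk(self.root)
        return coph

    def to_newick(self) -> str:
        """Newick string with merge-height differences as branch lengths."""

        def fmt(n: DendrogramNode, parent_height: float) -> str:
            length = parent_height - n.height
            if n.is_leaf:
                return f"{n.leaf_id}:{length:g}"
            inner = ",".join(fmt(c, n.height) for c in n.children)
            return f"({inner}):{length:g}"

        left, right = self.root.children
        inner = ",".join(fmt(c, self.root.height) for c in (left, right))
        return f"({inner});"


def upgma(d: pd.DataFrame) -> Dendrogram:
    """Agglomerate samples by average linkage (UPGMA).

    At each step the two clusters at minimal average cross-pair distance
    merge, at a height equal to that distance.  When several pairs tie
    exactly, the pair whose combined, sorted member-id tuple is
    lexicographically smallest merges first (deterministic; the choice is
    otherwise arbitrary).
    """
    ids = list(d.index)
    if list(d.columns) != ids:
        raise ValueError("distance table must have matching index and columns")
    if len(ids) < 2:
        raise ValueError("need >= 2 samples")
    dm = d.to_numpy(dtype=float)
    if not np.allclose(dm, dm.T, rtol=0, atol=1e-12):
        raise ValueError("distance table is not symmetric")
    if (np.diag(dm) != 0).any():
        raise ValueError("distance table diagonal must be zero")

    nodes: dict[int, DendrogramNode] = {
        i: DendrogramNode(0.0, leaf_id=ids[i]) for i in range(len(ids))
    }
    sizes: dict[int, int] = {i: 1 for i in range(len(ids))}
    members: dict[int, tuple[str, ...]] = {i: (ids[i],) for i in range(len(ids))}
    dist: dict[tuple[int, int], float] = {}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            dist[(i, j)] = float(dm[i, j])
    next_id = len(ids)
    active = set(range(len(ids)))

    while len(active) > 1:
        dmin = min(dist[p] for p in dist)
        candidates = [p for p, v in dist.items() if v == dmin]
        i, j = min(candidates, key=lambda p: tuple(sorted(members[p[0]] + members[p[1]])))
        merged = DendrogramNode(dmin, children=(nodes[i], nodes[j]))
        ni, nj = sizes[i], sizes[j]
        new = next_id
        next_id += 1
        for other in active - {i, j}:
            di = dist[(min(i, other), max(i, other))]
            dj = dist[(min(j, other), max(j, other))]
            # arithmetic mean over all cross leaf pairs
            dist[(other, new)] = (ni * di + nj * dj) / (ni + nj)
        for p in list(dist):
            if i in p or j in p:
                del dist[p]
        active -= {i, j}
        active.add(new)
        nodes[new] = merged
        sizes[new] = ni + nj
        members[new] = tuple(sorted(members[i] + members[j]))
    (root_id,) = active
    return Dendrogram(nodes[root_id])


def cut_clusters(t: Dendrogram, k: int) -> list[tuple[str, ...]]:
    """The k-cluster cut: split the highest merges until k groups remain."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(t.leaf_ids):
        raise ValueError("k exceeds the number of leaves")
    groups: list[DendrogramNode] = [t.root]
    while len(groups) < k:
        splittable = [n for n in groups if not n.is_leaf]
        tallest = max(splittable, key=lambda n: n.height)
        groups.remove(tallest)
        groups.extend(tallest.children)
    return [g.leaves for g in groups]


def cluster_composition(
    t: Dendrogram, k: int, labels: Mapping[str, str]
) -> pd.DataFrame:
    """Per-cluster label counts for the k-cluster cut (descriptive output
    for multi-cohort explorations; class prediction uses the 2-cut)."""
    rows = []
    for ci, grp in enumerate(cut_clusters(t, k), start=1):
        counts: dict[str, int] = {}
        for s in grp:
            lab = labels.get(s, "(unlabelled)")
            counts[lab] = counts.get(lab, 0) + 1
        for lab, n in sorted(counts.items()):
            rows.append({"cluster": ci, "class_label": lab, "n": n})
    return pd.DataFrame(rows, columns=["cluster", "class_label", "n"])


def two_cluster_classes(
    t: Dendrogram, reference_labels: Mapping[str, str]
) -> dict[str, str]:
    """Predict classes from the two-cluster segregation of the dendrogram.

    The root's two child clusters are each assigned the majority class of
    their labelled members; unlabelled samples inherit their cluster's
    class.  A cluster without labelled members takes the remaining class
    when the labelled side leaves exactly one; both clusters sharing a
    majority class is a non-segregation error.
    """
    if t.root.is_leaf or len(t.root.children) != 2:
        raise ValueError("root cut does not yield exactly 2 clusters")
    known = {s: c for s, c in reference_labels.items() if c is not None}
    if not any(s in known for s in t.leaf_ids):
        raise ValueError("no labelled sample among the leaves")
    clusters = [c.leaves for c in t.root.children]

    majorities: list[str | None] = []
    for grp in clusters:
        labs = [known[s] for s in grp if s in known]
        if not labs:
            majorities.append(None)
            continue
        counts: dict[str, int] = {}
        for c in labs:
            counts[c] = counts.get(c, 0) + 1
        best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        majorities.append(best[0][0])

    if majorities[0] is not None and majorities[0] == majorities[1]:
        raise ValueError(
            f"non-segregation: both clusters have majority class "
            f"{majorities[0]!r}"
        )
    all_classes = set(known.values())
    for idx in (0, 1):
        if majorities[idx] is None:
            other = majorities[1 - idx]
            remaining = all_classes - {other}
            if len(remaining) != 1:
                raise ValueError(
                    "cluster with no labelled member and no unique "
                    "unclaimed class"
                )
            majorities[idx] = remaining.pop()

    out: dict[str, str] = {}
    for grp, cls in zip(clusters, majorities):
        for s in grp:
            out[s] = cls
    return out


@dataclass
class ClassMetrics:
    """Confusion counts and the rates derived from them."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def error_rate(self) -> float:
        return (self.fp + self.fn) / self.total

    def as_dict(self) -> dict:
        """Full-precision counts plus display-rounded rates (percentages to
        one decimal, error rate to three)."""
        return {
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "error_rate": self.error_rate,
            "sensitivity_pct": round(100.0 * self.sensitivity, 1),
            "specificity_pct": round(100.0 * self.specificity, 1),
            "error_rate_rounded": round(self.error_rate, 3),
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.as_dict(), indent=2, sort_keys=True) + "\n")
        return path


def classification_metrics(
    true_labels: Mapping[str, str],
    predicted_labels: Mapping[str, str],
    positive_class: str,
) -> ClassMetrics:
    """Confusion metrics of predicted vs true classes.

    Samples of ``positive_class`` count toward sensitivity; everything
    else is pooled as negative.  The two label maps must share a key set.
    """
    if set(true_labels) != set(predicted_labels):
        raise ValueError("true and predicted labels must share a key set")
    if positive_class not in set(true_labels.values()) | set(
        predicted_labels.values()
    ):
        raise ValueError(f"unknown positive class {positive_class!r}")
    tp = fn = tn = fp = 0
    for s, t in true_labels.items():
        p = predicted_labels[s]
        if t == positive_class:
            if p == positive_class:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_class:
                fp += 1
            else:
                tn += 1
    return ClassMetrics(tp=tp, fn=fn, tn=tn, fp=fp)
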