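"""Partitioning items into symptom groups.

:class:`Clustering` is the common currency of the three analysis arms: an
assignment of every analyzed item to exactly one label, tagged with the
method that produced it (``expert``, ``kmeans``, ``llm``, or ``truth``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .embedding import EmbeddingMatrix
from .errors import ValidationError

METHODS = frozenset({"expert", "kmeans", "llm", "truth"})


@dataclass
class Clustering:
    """Assignment of item ids to cluster labels."""

    assignments: dict[str, str | int]
    method: str

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(f"unknown clustering method {self.method!r}")
        if not self.assignments:
            raise ValidationError("clustering has no assignments")

    @property
    def k(self) -> int:
        """Number of distinct labels actually used."""
        return len(set(self.assignments.values()))

    @property
    def item_ids(self) -> list[str]:
        return list(self.assignments)

    def labels_for(self, item_ids: list[str]) -> list[str | int]:
        missing = [i for i in item_ids if i not in self.assignments]
        if missing:
            raise ValidationError(f"clustering does not cover items {missing}")
        return [self.assignments[i] for i in item_ids]


def kmeans_cluster(matrix: EmbeddingMatrix, k: int, seed: int = 0,
                   n_init: int = 10, max_iter: int = 300) -> Clustering:
    """k-means partition of the embedding rows into *k* clusters.

    Best of ``n_init`` k-means++ initializations by within-cluster sum of
    squares; deterministic given *seed*.  Labels are integers ``0..k-1``.
    """
    n = matrix.n_items
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} outside valid range 1..{n}")
    if k > 1 and np.allclose(matrix.values, matrix.values[0]):
        raise ValidationError(
            "degenerate input: all embedding rows identical but k > 1")
    km = KMeans(n_clusters=k, n_init=n_init, max_iter=max_iter,
                init="k-means++", random_state=seed)
    labels = km.fit_predict(matrix.values)
    return Clustering(
        assignments={iid: int(lab) for iid, lab in zip(matrix.item_ids, labels)},
        method="kmeans")


def expert_k(consensus: Clustering) -> int:
    """The cluster count the k-means arm must use: distinct labels USED by
    the expert consensus on the analyzed item subset (not the catalog size)."""
    if consensus.method != "expert":
        raise ValidationError(
            f"expert_k requires an expert clustering, got {consensus.method!r}")
    return consensus.k


def write_clustering(clustering: Clustering, path: str | Path,
                     run_id: str = "") -> None:
    """Write the clustering CSV (item_id, label, method, run_id), sorted by item_id."""
    frame = pd.DataFrame(
        {"item_id": list(clustering.assignments),
         "label": list(clustering.assignments.values())})
    frame["method"] = clustering.method
    frame["run_id"] = run_id
    frame.sort_values("item_id", kind="stable").to_csv(path, index=False)


def read_clustering(path: str | Path) -> Clustering:
    frame = pd.read_csv(path, dtype={"item_id": str, "label": str})
    methods = frame["method"].unique()
    if len(methods) != 1:
        raise ValidationError(f"{path}: mixed methods {sorted(methods)}")
    return Clustering(
        assignments=dict(zip(frame["item_id"], frame["label"])),
        method=str(methods[0]))
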