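"""Clustering agreement: Adjusted Rand Index, strength bands, permutation null.

The ARI is computed from the contingency table with exact integer
arithmetic, so analytic anchors (self-comparison = 1.0, the attainable
minimum of -0.5) hold without floating-point slack:

    ARI = [ sum_ij C(n_ij,2) - sum_i C(a_i,2) * sum_j C(b_j,2) / C(n,2) ]
        / [ (sum_i C(a_i,2) + sum_j C(b_j,2)) / 2
            - sum_i C(a_i,2) * sum_j C(b_j,2) / C(n,2) ]

Multiplying numerator and denominator by 2*C(n,2) keeps everything in
integers until the final division.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from .clustering import Clustering, kmeans_cluster
from .embedding import EmbeddingMatrix, permute_embeddings
from .errors import PipelineError, ValidationError

#: Verbal strength bands applied to both ARI and Jaccard values.  Half-open
#: at the 0.2/0.4/0.6/0.8 boundaries, evaluated on the unrounded value.
_BANDS = [
    (0.2, "very weak"),
    (0.4, "weak"),
    (0.6, "moderate"),
    (0.8, "strong"),
]


@dataclass
class AgreementReport:
    """One pairwise agreement measurement."""

    ari: float
    band: str
    pair: tuple[str, str]


@dataclass
class NullDistribution:
    """Permutation-null ARI values with an empirical 95% CI."""

    values: np.ndarray
    B: int
    ci_low: float
    ci_high: float
    seed: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.B,):
            raise ValidationError(f"expected {self.B} null values, got {self.values.shape}")
        if not self.ci_low <= self.ci_high:
            raise ValidationError("ci_low must not exceed ci_high")

    @property
    def mean(self) -> float:
        return float(self.values.mean())


def _as_labels(c: Clustering | dict) -> dict:
    return c.assignments if isinstance(c, Clustering) else dict(c)


def _partition_signature(labels: list) -> frozenset[frozenset[int]]:
    groups: dict[object, set[int]] = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(lab, set()).add(idx)
    return frozenset(frozenset(g) for g in groups.values())


def adjusted_rand_index(c1: Clustering | dict, c2: Clustering | dict) -> float:
    """Chance-corrected agreement between two partitions of the same items.

    Symmetric, invariant to label names, and exactly 1.0 for identical
    partitions.  The attainable range is [-0.5, 1].  When both partitions
    are trivial (the formula's 0/0 case) the value is 1.0 if they are
    identical and 0.0 otherwise.
    """
    a1, a2 = _as_labels(c1), _as_labels(c2)
    ids1, ids2 = set(a1), set(a2)
    if ids1 != ids2:
        raise ValidationError(
            f"clusterings cover different items; symmetric difference: "
            f"{sorted(ids1 ^ ids2)}")
    n = len(a1)
    if n < 2:
        raise ValidationError(f"need at least 2 items, got {n}")
    item_ids = sorted(ids1)
    x = [a1[i] for i in item_ids]
    y = [a2[i] for i in item_ids]

    table: dict[tuple, int] = {}
    row: dict[object, int] = {}
    col: dict[object, int] = {}
    for xi, yi in zip(x, y):
        table[(xi, yi)] = table.get((xi, yi), 0) + 1
        row[xi] = row.get(xi, 0) + 1
        col[yi] = col.get(yi, 0) + 1

    sum_ij = sum(comb(v, 2) for v in table.values())
    sum_a = sum(comb(v, 2) for v in row.values())
    sum_b = sum(comb(v, 2) for v in col.values())
    c2n = comb(n, 2)
    # integer-exact form: multiply numerator and denominator by 2*C(n,2)
    numer = 2 * (c2n * sum_ij - sum_a * sum_b)
    denom = c2n * (sum_a + sum_b) - 2 * sum_a * sum_b
    if denom == 0:
        return 1.0 if _partition_signature(x) == _partition_signature(y) else 0.0
    return numer / denom


def pairwise_rater_ari(labelings: list) -> tuple[np.ndarray, float]:
    """Symmetric rater × rater ARI matrix and its mean over distinct pairs.

    Accepts RaterLabeling objects or plain item→label dicts; the diagonal is
    1 and excluded from the mean (3 raters → mean over 3 pairs).
    """
    if len(labelings) < 2:
        raise ValidationError("need at least 2 labelings")
    dicts = [getattr(lab, "assignments", lab) for lab in labelings]
    m = len(dicts)
    matrix = np.eye(m)
    values = []
    for i, j in combinations(range(m), 2):
        value = adjusted_rand_index(dicts[i], dicts[j])
        matrix[i, j] = matrix[j, i] = value
        values.append(value)
    return matrix, float(np.mean(values))


def permutation_null_ari(
    matrix: EmbeddingMatrix,
    k: int,
    reference: Clustering,
    B: int = 1000,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
) -> NullDistribution:
    """Null distribution of the k-means-vs-reference ARI under embedding shuffling.

    Each repetition permutes which vector belongs to which item, re-runs
    k-means, and scores against the untouched *reference*.  Repetition ``b``
    is seeded by child ``b`` of ``SeedSequence(seed)``, so enlarging *B*
    never reshuffles earlier repetitions.  The CI is the empirical 2.5th and
    97.5th percentile (type-7 quantiles).
    """
    if B < 1:
        raise ValidationError(f"B must be >= 1, got {B}")
    ref_ids = set(reference.assignments)
    if set(matrix.item_ids) != ref_ids:
        raise ValidationError(
            "reference clustering does not cover the embedding's items; "
            f"difference: {sorted(set(matrix.item_ids) ^ ref_ids)}")
    children = np.random.SeedSequence(seed).spawn(B)
    values = np.empty(B)
    for b, child in enumerate(children):
        perm_seed, km_seed = (int(s) for s in child.generate_state(2))
        try:
            permuted = permute_embeddings(matrix, perm_seed)
            clustering = kmeans_cluster(permuted, k, seed=km_seed,
                                        n_init=n_init, max_iter=max_iter)
        except Exception as exc:
            raise PipelineError("permutation_null", f"repetition {b}", str(exc)) from exc
        values[b] = adjusted_rand_index(clustering, reference)
    ci_low, ci_high = np.quantile(values, [0.025, 0.975])
    return NullDistribution(values=values, B=B, ci_low=float(ci_low),
                            ci_high=float(ci_high), seed=seed)


def strength_band(value: float) -> str:
    """Verbal strength label for an agreement or overlap value.

    Negative values are "below chance"; the positive scale is very weak
    [0, 0.2), weak [0.2, 0.4), moderate [0.4, 0.6), strong [0.6, 0.8),
    very strong [0.8, 1].
    """
    if value < 0:
        return "below chance"
    for upper, label in _BANDS:
        if value < upper:
            return label
    return "very strong"


def agreement_report(c1: Clustering, c2: Clustering) -> AgreementReport:
    """Convenience wrapper pairing an ARI value with its strength band."""
    value = adjusted_rand_index(c1, c2)
    return AgreementReport(ari=value, band=strength_band(value),
                           pair=(c1.method, c2.method))
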