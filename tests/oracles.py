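"""Independent oracles used to cross-check the package implementation.

These deliberately avoid the contingency-table route: the ARI oracle counts
agreeing/disagreeing item pairs directly, and partitions are enumerated by
brute-force recursion.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations


def pair_counting_ari(labels_a: list, labels_b: list) -> Fraction:
    """ARI from explicit pair counts (exact rational arithmetic).

    With n11 pairs co-clustered in both partitions, n00 separated in both,
    and n10/n01 the disagreements:

        ARI = 2 (n11 n00 - n10 n01)
              / [ (n11 + n10)(n10 + n00) + (n11 + n01)(n01 + n00) ]

    Degenerate denominator (both partitions trivial): 1 if the partitions
    agree on every pair, else 0 — matching the documented convention.
    """
    assert len(labels_a) == len(labels_b)
    n11 = n00 = n10 = n01 = 0
    for i, j in combinations(range(len(labels_a)), 2):
        same_a = labels_a[i] == labels_a[j]
        same_b = labels_b[i] == labels_b[j]
        if same_a and same_b:
            n11 += 1
        elif not same_a and not same_b:
            n00 += 1
        elif same_a:
            n10 += 1
        else:
            n01 += 1
    denom = (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
    if denom == 0:
        return Fraction(1) if n10 == n01 == 0 else Fraction(0)
    return Fraction(2 * (n11 * n00 - n10 * n01), denom)


def set_partitions(n: int) -> list[list[int]]:
    """All partitions of {0..n-1} as label vectors in restricted-growth form
    (the first occurrence of each block gets the next unused integer)."""
    results: list[list[int]] = []

    def extend(labels: list[int]) -> None:
        if len(labels) == n:
            results.append(list(labels))
            return
        next_label = max(labels, default=-1) + 1
        for lab in range(next_label + 1):
            labels.append(lab)
            extend(labels)
            labels.pop()

    extend([])
    return results
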