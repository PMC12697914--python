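"""Content overlap between questionnaires.

Overlap is measured on symptom *sets*: each questionnaire's profile is the
set of distinct symptom labels assigned to its items, and pairs of profiles
are compared with the Jaccard index.  The symptom universe for occurrence
reporting is the set of labels used anywhere in the clustering, not the
full catalog.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .clustering import Clustering
from .errors import ValidationError
from .item_bank import ItemBank


@dataclass
class OverlapReport:
    """Pairwise Jaccard structure of one diagnostic domain.

    ``jaccard`` is a symmetric questionnaire × questionnaire DataFrame with
    unit diagonal; ``per_questionnaire_mean`` excludes the diagonal;
    ``domain_mean`` averages the C(Q,2) unordered pairs.  ``occurrence`` is
    a boolean symptom × questionnaire table; universal symptoms appear in
    every questionnaire, idiosyncratic ones in exactly one.
    """

    questionnaire_ids: list[str]
    jaccard: pd.DataFrame
    per_questionnaire_mean: dict[str, float]
    domain_mean: float
    occurrence: pd.DataFrame
    universal_symptoms: set[str]
    idiosyncratic_symptoms: dict[str, str]
    profiles: dict[str, set[str]]


def symptom_profile(clustering: Clustering, bank: ItemBank,
                    questionnaire_id: str) -> set[str]:
    """Set of distinct labels assigned to a questionnaire's non-excluded items."""
    if questionnaire_id not in bank.questionnaires:
        raise ValidationError(
            f"unknown questionnaire {questionnaire_id!r} in domain {bank.domain!r}")
    ids = [i.item_id for i in bank.analyzed_items
           if i.questionnaire_id == questionnaire_id]
    return {str(lab) for lab in clustering.labels_for(ids)}


def jaccard_index(a: set, b: set) -> float:
    """|A ∩ B| / |A ∪ B| for non-empty sets; 1 means complete overlap."""
    if not a or not b:
        raise ValidationError("jaccard_index requires non-empty sets")
    return len(a & b) / len(a | b)


def occurrence_matrix(clustering: Clustering, bank: ItemBank
                      ) -> tuple[pd.DataFrame, set[str], dict[str, str]]:
    """Boolean symptom × questionnaire table plus the universal and
    idiosyncratic symptom structure."""
    qids = [qid for qid in bank.questionnaires
            if any(i.questionnaire_id == qid for i in bank.analyzed_items)]
    profiles = {qid: symptom_profile(clustering, bank, qid) for qid in qids}
    symptoms = sorted({s for prof in profiles.values() for s in prof})
    table = pd.DataFrame(
        [[s in profiles[q] for q in qids] for s in symptoms],
        index=symptoms, columns=qids, dtype=bool)
    counts = table.sum(axis=1)
    universal = set(counts.index[counts == len(qids)])
    idiosyncratic = {
        s: table.columns[table.loc[s]].item()
        for s in counts.index[counts == 1]
    }
    return table, universal, idiosyncratic


def overlap_matrix(clustering: Clustering, bank: ItemBank) -> OverlapReport:
    """Full pairwise-Jaccard report for a domain with >= 2 questionnaires."""
    qids = [qid for qid in bank.questionnaires
            if any(i.questionnaire_id == qid for i in bank.analyzed_items)]
    if len(qids) < 2:
        raise ValidationError(
            f"overlap requires >= 2 questionnaires, domain {bank.domain!r} has {len(qids)}")
    profiles = {qid: symptom_profile(clustering, bank, qid) for qid in qids}
    empty = [q for q, p in profiles.items() if not p]
    if empty:
        raise ValidationError(f"questionnaires with empty symptom profiles: {empty}")

    matrix = pd.DataFrame(np.eye(len(qids)), index=qids, columns=qids)
    pair_values = []
    for qa, qb in combinations(qids, 2):
        value = jaccard_index(profiles[qa], profiles[qb])
        matrix.loc[qa, qb] = matrix.loc[qb, qa] = value
        pair_values.append(value)
    per_mean = {
        q: float(matrix.loc[q].drop(q).mean()) for q in qids
    }
    occurrence, universal, idiosyncratic = occurrence_matrix(clustering, bank)
    return OverlapReport(
        questionnaire_ids=qids,
        jaccard=matrix,
        per_questionnaire_mean=per_mean,
        domain_mean=float(np.mean(pair_values)),
        occurrence=occurrence,
        universal_symptoms=universal,
        idiosyncratic_symptoms=idiosyncratic,
        profiles=profiles,
    )
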