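import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from qoverlap.item_bank import Item, ItemBank, Questionnaire, SymptomCatalog
from qoverlap.synthetic import SyntheticConfig, generate_synthetic_domain


def make_bank(layout: dict[str, list[tuple[str, str, bool]]],
              domain: str = "toy") -> ItemBank:
    """Build a bank from {questionnaire_id: [(text, 'SR'|'OR'|'SR+OR', excluded)]}."""
    items, questionnaires = [], {}
    for qid, rows in layout.items():
        ratings = frozenset()
        for ordinal, (text, rating, excluded) in enumerate(rows, start=1):
            rt = frozenset(rating.split("+"))
            ratings |= rt
            items.append(Item(item_id=f"{qid}:{ordinal}", questionnaire_id=qid,
                              text=text, rating_types=rt, excluded=excluded))
        questionnaires[qid] = Questionnaire(qid, qid, ratings)
    return ItemBank(domain=domain, items=items, questionnaires=questionnaires)


@pytest.fixture
def toy_bank() -> ItemBank:
    return make_bank({
        "QA": [("I feel sad", "SR", False),
               ("I sleep badly", "SR", False),
               ("honest answers", "SR", True)],
        "QB": [("Feeling down", "OR", False),
               ("Low appetite", "SR+OR", False)],
    })


@pytest.fixture
def toy_catalog() -> SymptomCatalog:
    return SymptomCatalog(domain="toy",
                          symptoms=["sadness", "sleep problems", "appetite"])


@pytest.fixture
def small_domain():
    """A small planted domain: (bank, catalog, truth) with clear structure."""
    config = SyntheticConfig(
        seed=7, n_questionnaires=4, items_per_questionnaire=(10, 14),
        n_symptoms=6, embedding_dim=16, separation=10.0, rater_error=0.1,
        excluded_rate=0.5)
    return generate_synthetic_domain(config)
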