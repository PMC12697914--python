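"""Synthetic domains with planted structure.

Generates item banks whose items carry a known true symptom, embeddings
drawn from separated Gaussian components (one per symptom), noisy raters
whose labels corrupt the truth at a controllable rate, and a lookup
assignment backend standing in for a prompted LLM — everything the pipeline
needs, with known ground truth and no downloads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import Clustering
from .embedding import EmbeddingMatrix, l2_normalize
from .errors import ValidationError
from .item_bank import Item, ItemBank, Questionnaire, SymptomCatalog


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults are sized like a mid-sized domain
    (7 questionnaires, ~180 items, 23 symptoms)."""

    n_questionnaires: int = 7
    items_per_questionnaire: tuple[int, int] = (15, 35)
    n_symptoms: int = 23
    symptom_overlap: float = 0.5   # rho: probability a slot draws from the shared core
    embedding_dim: int = 768
    separation: float = 5.0        # center distance in units of component sd
    rater_error: float = 0.1
    seed: int = 0
    domain: str = "synthetic"
    or_fraction: float = 0.2       # fraction of questionnaires that are observer-rated
    dual_fraction: float = 0.1     # fraction rated both SR and OR
    excluded_rate: float = 0.0     # chance a questionnaire gets one quality item

    def __post_init__(self) -> None:
        lo, hi = self.items_per_questionnaire
        if self.n_questionnaires < 1 or lo < 1 or hi < lo:
            raise ValidationError("questionnaire/item counts must be positive")
        for name in ("symptom_overlap", "rater_error", "or_fraction",
                     "dual_fraction", "excluded_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {value}")
        if self.separation < 0:
            raise ValidationError("separation must be >= 0")


def generate_synthetic_domain(config: SyntheticConfig
                              ) -> tuple[ItemBank, SymptomCatalog, Clustering]:
    """Build (bank, catalog, truth) with planted symptom structure.

    The catalog splits into a shared core (first half) and peripheral
    symptoms dealt round-robin to questionnaires as private symptoms.  Each
    questionnaire's symptom pool contains one anchored core symptom, every
    other core symptom independently with probability rho, and each of its
    private symptoms with probability 1-rho — so rho directly controls how
    much the questionnaires' symptom sets overlap, and rho=1 gives every
    questionnaire the identical all-core pool.  Item texts are templated
    variants of their true symptom.  Byte-identical output for the same
    seed.
    """
    if config.n_symptoms < 2:
        raise ValidationError("need at least 2 symptoms")
    rng = np.random.default_rng(config.seed)
    width = len(str(config.n_symptoms))
    catalog = SymptomCatalog(
        domain=config.domain,
        symptoms=[f"symptom {i + 1:0{width}d}" for i in range(config.n_symptoms)])
    core_size = max(2, config.n_symptoms // 2)
    core = catalog.symptoms[:core_size]
    peripheral = catalog.symptoms[core_size:]
    private: dict[int, list[str]] = {q: [] for q in range(config.n_questionnaires)}
    for idx, symptom in enumerate(peripheral):
        private[idx % config.n_questionnaires].append(symptom)

    items: list[Item] = []
    questionnaires: dict[str, Questionnaire] = {}
    truth: dict[str, str | int] = {}
    lo, hi = config.items_per_questionnaire
    for q in range(config.n_questionnaires):
        qid = f"Q{q + 1:02d}"
        u = rng.random()
        if u < config.dual_fraction:
            rating = frozenset({"SR", "OR"})
        elif u < config.dual_fraction + config.or_fraction:
            rating = frozenset({"OR"})
        else:
            rating = frozenset({"SR"})
        questionnaires[qid] = Questionnaire(qid, f"Synthetic scale {q + 1}", rating)

        n_items = int(rng.integers(lo, hi + 1))
        rho = config.symptom_overlap
        anchor = core[q % len(core)]
        pool: list[str] = [anchor]
        pool += [s for s in core if s != anchor and rng.random() < rho]
        pool += [s for s in private[q] if rng.random() < 1.0 - rho]
        for j in range(n_items):
            # first |pool| items cover the pool deterministically, the rest
            # draw uniformly, so every pool symptom is used when items suffice
            if j < len(pool):
                symptom = pool[j]
            else:
                symptom = pool[int(rng.integers(len(pool)))]
            item_id = f"{qid}:{j + 1}"
            items.append(Item(
                item_id=item_id, questionnaire_id=qid,
                text=f"{symptom} phrased variant {j + 1}",
                rating_types=rating, excluded=False))
            truth[item_id] = symptom
        if rng.random() < config.excluded_rate:
            items.append(Item(
                item_id=f"{qid}:quality", questionnaire_id=qid,
                text="These answers represent my honest feelings",
                rating_types=rating, excluded=True))

    bank = ItemBank(domain=config.domain, items=items, questionnaires=questionnaires)
    return bank, catalog, Clustering(assignments=truth, method="truth")


def generate_planted_embeddings(truth: Clustering, dim: int, separation: float,
                                seed: int, normalize: bool = True) -> EmbeddingMatrix:
    """One unit-variance Gaussian component per true symptom.

    Component centers sit on mutually orthogonal directions scaled so every
    pair of centers is ``separation`` apart (in units of the component sd);
    requires ``dim`` >= number of symptoms.  Rows are L2-normalized.
    """
    if dim < 2:
        raise ValidationError("dim must be >= 2")
    labels = sorted({str(v) for v in truth.assignments.values()})
    k = len(labels)
    if k > dim:
        raise ValidationError(
            f"cannot place {k} mutually orthogonal centers in dimension {dim}; "
            f"use dim >= {k}")
    rng = np.random.default_rng(seed)
    basis, _ = np.linalg.qr(rng.standard_normal((dim, k)))
    # orthonormal columns scaled so pairwise center distance == separation
    centers = {lab: basis[:, i] * (separation / np.sqrt(2.0))
               for i, lab in enumerate(labels)}
    item_ids = list(truth.assignments)
    rows = np.stack([
        centers[str(truth.assignments[iid])] + rng.standard_normal(dim)
        for iid in item_ids
    ])
    if normalize:
        rows = l2_normalize(rows)
    return EmbeddingMatrix(item_ids=item_ids, values=rows)


class PlantedBackend:
    """Embedding backend serving planted Gaussian vectors keyed by item id."""

    deterministic = True

    def __init__(self, truth: Clustering, dim: int = 64, separation: float = 5.0,
                 seed: int = 0, normalize: bool = True):
        self.name = f"planted:dim={dim},sep={separation},seed={seed}"
        matrix = generate_planted_embeddings(truth, dim, separation, seed,
                                             normalize=normalize)
        self._rows = {iid: matrix.values[r]
                      for r, iid in enumerate(matrix.item_ids)}

    def embed(self, items) -> np.ndarray:
        from .errors import BackendError
        try:
            return np.stack([self._rows[i.item_id] for i in items])
        except KeyError as exc:
            raise BackendError(f"no planted vector for item {exc}",
                               item_id=str(exc)) from exc


def _corrupt_label(true_label: str, catalog: SymptomCatalog, error_rate: float,
                   rng: np.random.Generator) -> str:
    if rng.random() >= error_rate or len(catalog.symptoms) < 2:
        return true_label
    others = [s for s in catalog.symptoms if s != true_label]
    return others[int(rng.integers(len(others)))]


def generate_noisy_raters(truth: Clustering, catalog: SymptomCatalog,
                          n_raters: int = 3, error_rate: float = 0.1,
                          seed: int = 0) -> list:
    """Raters who keep the true label with probability 1-eps and otherwise
    substitute a uniformly random different catalog label, independently."""
    from .assignment import RaterLabeling
    if not 0.0 <= error_rate <= 1.0:
        raise ValidationError("error_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    labelings = []
    for r in range(n_raters):
        assignments = {
            iid: _corrupt_label(str(lab), catalog, error_rate, rng)
            for iid, lab in truth.assignments.items()
        }
        labelings.append(RaterLabeling(rater_id=f"rater_{r + 1}",
                                       assignments=assignments))
    return labelings


class LookupBackend:
    """Deterministic assignment backend answering with the (optionally
    corrupted) true label; stands in for a prompted LLM in tests.

    ``malformed_rate`` items instead get an off-catalog response on every
    call, exercising the validation layer.
    """

    deterministic = True

    def __init__(self, truth: Clustering, catalog: SymptomCatalog,
                 error_rate: float = 0.0, seed: int = 0,
                 malformed_rate: float = 0.0):
        if not 0.0 <= error_rate <= 1.0 or not 0.0 <= malformed_rate <= 1.0:
            raise ValidationError("rates must be in [0, 1]")
        self.name = f"lookup:eps={error_rate},seed={seed}"
        rng = np.random.default_rng(seed)
        self._responses: dict[str, str] = {}
        for iid, lab in truth.assignments.items():
            if rng.random() < malformed_rate:
                self._responses[iid] = f"### not a symptom ({iid}) ###"
            else:
                self._responses[iid] = _corrupt_label(str(lab), catalog,
                                                      error_rate, rng)

    def respond(self, item, prompt: str) -> str:
        try:
            return self._responses[item.item_id]
        except KeyError as exc:
            from .errors import BackendError
            raise BackendError(f"no lookup response for item {exc}",
                               item_id=item.item_id) from exc


def make_lookup_backend(truth: Clustering, catalog: SymptomCatalog,
                        error_rate: float = 0.0, seed: int = 0,
                        malformed_rate: float = 0.0) -> LookupBackend:
    """Factory mirroring the other generators' call style."""
    return LookupBackend(truth, catalog, error_rate=error_rate, seed=seed,
                         malformed_rate=malformed_rate)
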