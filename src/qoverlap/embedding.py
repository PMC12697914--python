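"""Item embeddings: backend contract, file loading, and the permutation used by the null.

A backend maps item texts to fixed-length vectors (default dimensionality
768).  The reference backends are *precomputed* (a TSV of vectors) and
*planted* (synthetic Gaussian components, :mod:`qoverlap.synthetic`); a
sentence-transformer backend is available as an optional extra and is never
required for building or testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

from .errors import BackendError, ValidationError
from .item_bank import Item, ItemBank


@dataclass
class EmbeddingMatrix:
    """Dense item × dimension matrix, rows aligned one-to-one with ``item_ids``."""

    item_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("embedding values must be a 2-d matrix")
        if len(self.item_ids) != self.values.shape[0]:
            raise ValidationError(
                f"{len(self.item_ids)} item ids but {self.values.shape[0]} rows")
        if self.values.shape[1] < 2:
            raise ValidationError("embedding dimensionality must be >= 2")
        if not np.all(np.isfinite(self.values)):
            bad = [self.item_ids[r] for r in
                   np.unique(np.nonzero(~np.isfinite(self.values))[0])]
            raise ValidationError(f"non-finite embedding values for items {bad}")

    @property
    def dim(self) -> int:
        return int(self.values.shape[1])

    @property
    def n_items(self) -> int:
        return int(self.values.shape[0])


@runtime_checkable
class EmbeddingBackend(Protocol):
    """Contract for vectorizing items.

    A deterministic backend must return bit-identical vectors for the same
    item texts and configuration.
    """

    name: str
    deterministic: bool

    def embed(self, items: Sequence[Item]) -> np.ndarray:
        """Return one vector per item, in input order."""
        ...


def l2_normalize(matrix: np.ndarray) -> np.ndarray:
    """Scale every row to unit Euclidean norm (zero rows are left unchanged)."""
    norms = np.linalg.norm(matrix, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return matrix / norms


def embed_items(bank: ItemBank, backend: EmbeddingBackend,
                normalize: bool = True) -> EmbeddingMatrix:
    """Embed every non-excluded item of *bank*, in bank order.

    Rows are L2-normalized by default so that Euclidean k-means downstream
    approximates cosine similarity.  Backend failures and non-finite outputs
    raise :class:`BackendError` carrying the offending item id.
    """
    items = bank.analyzed_items
    if not items:
        raise ValidationError(f"bank {bank.domain!r} has no items to embed")
    try:
        values = np.asarray(backend.embed(items), dtype=float)
    except BackendError:
        raise
    except Exception as exc:  # noqa: BLE001 - backend contract boundary
        raise BackendError(f"backend {backend.name!r} failed: {exc}") from exc
    if values.shape[0] != len(items):
        raise BackendError(
            f"backend {backend.name!r} returned {values.shape[0]} rows "
            f"for {len(items)} items")
    bad_rows = np.unique(np.nonzero(~np.isfinite(values))[0])
    if bad_rows.size:
        raise BackendError(
            f"backend {backend.name!r} produced non-finite vectors",
            item_id=items[int(bad_rows[0])].item_id)
    if normalize:
        values = l2_normalize(values)
    return EmbeddingMatrix(item_ids=[i.item_id for i in items], values=values)


def load_embeddings(path: str | Path, bank: ItemBank) -> EmbeddingMatrix:
    """Load a precomputed embedding TSV and align rows to bank order.

    The file must have a header ``item_id<TAB>v1...vD`` and cover exactly
    the bank's non-excluded item ids; extra or missing ids are an error
    listing them.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype={0: str})
    if frame.columns[0] != "item_id":
        raise ValidationError(f"{path}: first column must be 'item_id'")
    file_ids = frame["item_id"].astype(str).tolist()
    wanted = bank.analyzed_ids
    missing = sorted(set(wanted) - set(file_ids))
    extra = sorted(set(file_ids) - set(wanted))
    if missing or extra:
        raise ValidationError(
            f"{path}: embedding ids do not match bank "
            f"(missing={missing}, extra={extra})")
    try:
        values = frame.drop(columns="item_id").to_numpy(dtype=float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric embedding cell ({exc})") from exc
    order = pd.Index(file_ids).get_indexer(wanted)
    return EmbeddingMatrix(item_ids=list(wanted), values=values[order])


def save_embeddings(matrix: EmbeddingMatrix, path: str | Path) -> None:
    """Write the TSV format understood by :func:`load_embeddings`."""
    frame = pd.DataFrame(matrix.values,
                         columns=[f"v{j + 1}" for j in range(matrix.dim)])
    frame.insert(0, "item_id", matrix.item_ids)
    frame.to_csv(path, sep="\t", index=False)


def permute_embeddings(matrix: EmbeddingMatrix, seed: int) -> EmbeddingMatrix:
    """Shuffle which vector is attached to which item.

    The item id list is untouched; the rows are placed in a uniformly random
    order drawn from a generator seeded with *seed*, so the multiset of rows
    is preserved exactly and the permutation is reproducible.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(matrix.n_items)
    return EmbeddingMatrix(item_ids=list(matrix.item_ids),
                           values=matrix.values[perm])


class PrecomputedBackend:
    """Embedding backend that serves vectors read from a TSV file."""

    deterministic = True

    def __init__(self, path: str | Path, bank: ItemBank):
        self.name = f"precomputed:{Path(path).name}"
        matrix = load_embeddings(path, bank)
        self._rows = {iid: matrix.values[r] for r, iid in enumerate(matrix.item_ids)}

    def embed(self, items: Sequence[Item]) -> np.ndarray:
        try:
            return np.stack([self._rows[i.item_id] for i in items])
        except KeyError as exc:
            raise BackendError(f"no precomputed vector for item {exc}",
                               item_id=str(exc)) from exc


class SbertBackend:
    """Optional sentence-transformers backend (not used in the test path).

    Requires the ``sbert`` extra; model weights are downloaded on first use.
    """

    deterministic = True

    def __init__(self, model_name: str = "all-mpnet-base-v2"):
        try:
            from sentence_transformers import SentenceTransformer
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "SbertBackend requires the 'sentence-transformers' package "
                "(install the 'sbert' extra)") from exc
        self.name = f"sbert:{model_name}"
        self._model = SentenceTransformer(model_name)

    def embed(self, items: Sequence[Item]) -> np.ndarray:  # pragma: no cover
        return np.asarray(self._model.encode([i.text for i in items]), dtype=float)
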