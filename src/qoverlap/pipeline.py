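"""End-to-end orchestration: config, the three analysis arms, and report exports.

A run loads an item bank, catalog, rater labelings, and embeddings, and for
every requested stratum produces: the expert consensus (with adjudication),
the k-means arm scored against it with a permuted-embedding null, the
prompted-assignment arm, pairwise expert agreement, and the content-overlap
report.  Exports mirror the published report surfaces (agreement table,
overlap summary, occurrence table, sunburst JSON) plus a manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .agreement import (NullDistribution, adjusted_rand_index,
                        pairwise_rater_ari, permutation_null_ari, strength_band)
from .assignment import (DEFAULT_PROMPT_TEMPLATE, AssignmentBackend,
                         RaterLabeling, TranscriptRecord, apply_adjudication,
                         assign_items, consensus_labeling, read_adjudication,
                         read_rater_labelings, write_transcript)
from .clustering import Clustering, expert_k, kmeans_cluster, write_clustering
from .embedding import EmbeddingBackend, PrecomputedBackend, embed_items
from .errors import PipelineError, ValidationError
from .item_bank import ItemBank, SymptomCatalog, filter_items, read_item_bank, read_symptom_catalog
from .overlap import OverlapReport, overlap_matrix

STRATA = ("all", "SR", "OR")


class KMeansParams(BaseModel):
    n_init: int = 10
    max_iter: int = 300


class RunConfig(BaseModel):
    """Everything a reproducible run needs; see the README for the schema."""

    bank: Path
    catalog: Path
    raters: Path
    adjudication: Path | None = None
    embeddings: Path | None = None
    llm_responses: Path | None = None
    strata: list[str] = Field(default_factory=lambda: ["all"])
    kmeans: KMeansParams = Field(default_factory=KMeansParams)
    B: int = 1000
    seed: int = 0
    normalize_embeddings: bool = True
    prompt_template: str = DEFAULT_PROMPT_TEMPLATE
    max_retries: int = 2
    overlap_arm: str = "llm"   # which arm's clustering feeds the overlap report
    out_dir: Path = Path("qoverlap_out")

    def model_post_init(self, __context) -> None:
        if self.B < 1:
            raise ValidationError(f"B must be >= 1, got {self.B}")
        bad = set(self.strata) - set(STRATA)
        if bad:
            raise ValidationError(f"unknown strata {sorted(bad)}; valid: {STRATA}")
        if self.overlap_arm not in {"llm", "expert", "kmeans"}:
            raise ValidationError(f"unknown overlap_arm {self.overlap_arm!r}")


class FileResponseBackend:
    """Assignment backend replaying recorded responses from a CSV
    (columns: item_id, response) — the offline stand-in for a live LLM."""

    deterministic = True

    def __init__(self, path: str | Path):
        self.name = f"file:{Path(path).name}"
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = {"item_id", "response"} - set(frame.columns)
        if missing:
            raise ValidationError(f"{path}: missing columns {sorted(missing)}")
        self._responses = dict(zip(frame["item_id"], frame["response"]))

    def respond(self, item, prompt: str) -> str:
        try:
            return self._responses[item.item_id]
        except KeyError:
            raise ValidationError(
                f"no recorded response for item {item.item_id!r}") from None


@dataclass
class StratumResult:
    """Outputs of one rating-type stratum."""

    stratum: str
    k: int
    expert: Clustering
    expert_mean_ari: float
    rater_matrix: np.ndarray
    kmeans: Clustering
    kmeans_ari: float
    null: NullDistribution
    llm: Clustering
    llm_ari: float
    llm_failures: set[str]
    transcript: list[TranscriptRecord]
    overlap: OverlapReport | None
    item_questionnaire: dict[str, str] = field(default_factory=dict)


@dataclass
class RunBundle:
    config: RunConfig
    domain: str
    results: dict[str, StratumResult]
    backends: dict[str, str] = field(default_factory=dict)


def _restrict(labeling: RaterLabeling, ids: set[str]) -> RaterLabeling:
    return RaterLabeling(
        rater_id=labeling.rater_id,
        assignments={i: s for i, s in labeling.assignments.items() if i in ids})


def _run_stratum(
    stratum: str,
    bank: ItemBank,
    catalog: SymptomCatalog,
    labelings: list[RaterLabeling],
    adjudication: dict[str, str],
    embedding_backend: EmbeddingBackend,
    assignment_backend: AssignmentBackend,
    config: RunConfig,
) -> StratumResult:
    rating = None if stratum == "all" else stratum
    try:
        sub_bank = filter_items(bank, rating_type=rating, drop_excluded=True)
    except Exception as exc:
        raise PipelineError("filter", stratum, str(exc)) from exc
    ids = set(sub_bank.analyzed_ids)

    try:
        sub_labelings = [_restrict(lab, ids) for lab in labelings]
        result = consensus_labeling(sub_labelings, catalog)
        uncovered = result.unresolved - set(adjudication)
        if uncovered:
            raise ValidationError(
                f"unresolved items need adjudication: {sorted(uncovered)}")
        expert = apply_adjudication(result, adjudication, catalog)
        rater_matrix, expert_mean = pairwise_rater_ari(sub_labelings)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("consensus", stratum, str(exc)) from exc

    k = expert_k(expert)

    try:
        matrix = embed_items(sub_bank, embedding_backend,
                             normalize=config.normalize_embeddings)
        km = kmeans_cluster(matrix, k, seed=config.seed,
                            n_init=config.kmeans.n_init,
                            max_iter=config.kmeans.max_iter)
        kmeans_ari = adjusted_rand_index(km, expert)
        null = permutation_null_ari(
            matrix, k, expert, B=config.B, seed=config.seed,
            n_init=config.kmeans.n_init, max_iter=config.kmeans.max_iter)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("kmeans", stratum, str(exc)) from exc

    try:
        llm, failures, transcript = assign_items(
            sub_bank, catalog, assignment_backend,
            max_retries=config.max_retries, template=config.prompt_template)
        # score on the items the backend managed to label
        expert_on_llm = Clustering(
            assignments={i: expert.assignments[i] for i in llm.assignments},
            method="expert")
        llm_ari = adjusted_rand_index(llm, expert_on_llm)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("llm", stratum, str(exc)) from exc

    overlap_clustering = {"llm": llm, "expert": expert, "kmeans": km}[config.overlap_arm]
    try:
        if failures and config.overlap_arm == "llm":
            covered = [i for i in sub_bank.items
                       if i.excluded or i.item_id in llm.assignments]
            overlap_bank = ItemBank(bank.domain, covered,
                                    dict(sub_bank.questionnaires))
        else:
            overlap_bank = sub_bank
        overlap = overlap_matrix(overlap_clustering, overlap_bank)
    except Exception as exc:
        raise PipelineError("overlap", stratum, str(exc)) from exc

    return StratumResult(
        stratum=stratum, k=k, expert=expert, expert_mean_ari=expert_mean,
        rater_matrix=rater_matrix, kmeans=km, kmeans_ari=kmeans_ari,
        null=null, llm=llm, llm_ari=llm_ari, llm_failures=failures,
        transcript=transcript, overlap=overlap,
        item_questionnaire={i.item_id: i.questionnaire_id
                            for i in sub_bank.analyzed_items})


def run_pipeline(
    config: RunConfig,
    embedding_backend: EmbeddingBackend | None = None,
    assignment_backend: AssignmentBackend | None = None,
) -> RunBundle:
    """Execute every configured stratum; any stage error aborts with the
    stage name and stratum attached."""
    try:
        bank = read_item_bank(config.bank)
        catalog = read_symptom_catalog(config.catalog, domain=bank.domain)
        labelings = read_rater_labelings(config.raters)
        adjudication = (read_adjudication(config.adjudication)
                        if config.adjudication else {})
    except Exception as exc:
        raise PipelineError("load", "-", str(exc)) from exc

    if embedding_backend is None:
        if config.embeddings is None:
            raise PipelineError("load", "-",
                                "no embeddings file and no embedding backend given")
        embedding_backend = PrecomputedBackend(config.embeddings, bank)
    if assignment_backend is None:
        if config.llm_responses is None:
            raise PipelineError("load", "-",
                                "no llm_responses file and no assignment backend given")
        assignment_backend = FileResponseBackend(config.llm_responses)

    results = {
        stratum: _run_stratum(stratum, bank, catalog, labelings, adjudication,
                              embedding_backend, assignment_backend, config)
        for stratum in config.strata
    }
    return RunBundle(config=config, domain=bank.domain, results=results,
                     backends={"embedding": embedding_backend.name,
                               "assignment": assignment_backend.name})


# ---------------------------------------------------------------------------
# exports

_EXPORT_FILES = ("agreement.csv", "overlap_pairs.csv", "overlap_summary.csv",
                 "occurrence.csv", "sunburst.json", "manifest.json")


def _agreement_frame(bundle: RunBundle) -> pd.DataFrame:
    rows = []
    for stratum, res in bundle.results.items():
        rows.append((bundle.domain, stratum, "expert-expert",
                     res.expert_mean_ari, "", "",
                     strength_band(res.expert_mean_ari)))
        rows.append((bundle.domain, stratum, "kmeans-expert",
                     res.kmeans_ari, res.null.ci_low, res.null.ci_high,
                     strength_band(res.kmeans_ari)))
        rows.append((bundle.domain, stratum, "llm-expert",
                     res.llm_ari, "", "", strength_band(res.llm_ari)))
    return pd.DataFrame(rows, columns=["domain", "stratum", "comparison",
                                       "ari", "ci_low", "ci_high", "band"])


def _sunburst(bundle: RunBundle, res: StratumResult) -> dict:
    clustering = {"llm": res.llm, "expert": res.expert,
                  "kmeans": res.kmeans}[bundle.config.overlap_arm]
    children = []
    for qid in res.overlap.questionnaire_ids:
        by_symptom: dict[str, list[str]] = {}
        for iid, lab in clustering.assignments.items():
            if res.item_questionnaire.get(iid) == qid:
                by_symptom.setdefault(str(lab), []).append(iid)
        children.append({
            "name": qid,
            "children": [
                {"name": symptom, "children": [{"name": iid} for iid in sorted(iids)]}
                for symptom, iids in sorted(by_symptom.items())
            ],
        })
    return {"name": bundle.domain, "children": children}


def export_reports(bundle: RunBundle, out_dir: str | Path) -> list[Path]:
    """Write the deterministic file set; removes partial output on failure.

    The agreement table covers every stratum; the overlap exports use the
    first configured stratum (the headline analysis).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    primary = bundle.results[bundle.config.strata[0]]
    if primary.overlap is None:
        raise ValidationError("bundle has no overlap report to export")
    written: list[Path] = []
    try:
        path = out_dir / "agreement.csv"
        _agreement_frame(bundle).to_csv(path, index=False)
        written.append(path)

        pairs = [
            (qa, qb, primary.overlap.jaccard.loc[qa, qb])
            for i, qa in enumerate(primary.overlap.questionnaire_ids)
            for qb in primary.overlap.questionnaire_ids[i + 1:]
        ]
        path = out_dir / "overlap_pairs.csv"
        pd.DataFrame(pairs, columns=["questionnaire_a", "questionnaire_b",
                                     "jaccard"]).to_csv(path, index=False)
        written.append(path)

        bank = read_item_bank(bundle.config.bank)
        n_items = {q: 0 for q in primary.overlap.questionnaire_ids}
        for item in bank.analyzed_items:
            if item.questionnaire_id in n_items:
                n_items[item.questionnaire_id] += 1
        summary = pd.DataFrame({
            "questionnaire": primary.overlap.questionnaire_ids,
            "n_items": [n_items[q] for q in primary.overlap.questionnaire_ids],
            "n_symptoms": [len(primary.overlap.profiles[q])
                           for q in primary.overlap.questionnaire_ids],
            "mean_jaccard": [primary.overlap.per_questionnaire_mean[q]
                             for q in primary.overlap.questionnaire_ids],
        })
        path = out_dir / "overlap_summary.csv"
        summary.to_csv(path, index=False)
        written.append(path)

        path = out_dir / "occurrence.csv"
        primary.overlap.occurrence.astype(int).to_csv(path, index_label="symptom")
        written.append(path)

        path = out_dir / "sunburst.json"
        path.write_text(json.dumps(_sunburst(bundle, primary), indent=1),
                        encoding="utf-8")
        written.append(path)

        config_json = bundle.config.model_dump_json()
        manifest = {
            "package_version": __version__,
            "domain": bundle.domain,
            "config": json.loads(config_json),
            "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
            "seed": bundle.config.seed,
            "backends": bundle.backends,
            "strata": {
                s: {"k": r.k, "n_llm_failures": len(r.llm_failures)}
                for s, r in bundle.results.items()
            },
        }
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=1, default=str),
                        encoding="utf-8")
        written.append(path)

        for stratum, res in bundle.results.items():
            tpath = out_dir / f"transcript_{stratum}.jsonl"
            write_transcript(res.transcript, tpath)
            written.append(tpath)
            cpath = out_dir / f"clustering_{bundle.config.overlap_arm}_{stratum}.csv"
            clustering = {"llm": res.llm, "expert": res.expert,
                          "kmeans": res.kmeans}[bundle.config.overlap_arm]
            write_clustering(clustering, cpath, run_id=stratum)
            written.append(cpath)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return written
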