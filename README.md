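# qoverlap

Observer-independent content-overlap analysis for mental-health
questionnaires. The package clusters questionnaire items by symptom along
three arms — expert consensus from three independent raters, k-means on
sentence embeddings, and prompted symptom assignment via a pluggable
backend — quantifies agreement between the arms with the Adjusted Rand
Index against a permuted-embedding null distribution, and measures content
overlap between questionnaires with the Jaccard index over per-questionnaire
symptom sets.

## Package layout

| module | role |
|---|---|
| `qoverlap.item_bank` | item-bank and symptom-catalog I/O, validation, rating-type stratification |
| `qoverlap.embedding` | embedding backends, TSV loading, row permutation for the null |
| `qoverlap.clustering` | k-means partitioning, `k` derived from the expert consensus |
| `qoverlap.assignment` | rater consensus + adjudication, prompted assignment with response validation |
| `qoverlap.agreement` | exact contingency-table ARI, strength bands, permutation null with 95% CI |
| `qoverlap.overlap` | symptom profiles, pairwise Jaccard, occurrence / universal / idiosyncratic structure |
| `qoverlap.synthetic` | planted-partition domains, Gaussian embeddings, noisy raters, lookup backends |
| `qoverlap.pipeline` + `qoverlap.cli` | end-to-end orchestration, report exports, `overlap` CLI |

## CLI

```bash
# write a complete synthetic fixture (bank, catalog, truth, embeddings,
# raters, recorded LLM responses, adjudication, run config)
overlap simulate --seed 0 --out fixture/

# run the full three-arm analysis
overlap run --config fixture/run.yaml

# individual stages
overlap embed   --bank fixture/bank.csv --truth fixture/truth.csv --out emb.tsv
overlap cluster --bank fixture/bank.csv --embeddings emb.tsv --k 12 --out km.csv
overlap assign  --bank fixture/bank.csv --catalog fixture/catalog.csv \
                --responses fixture/llm_responses.csv --out llm.csv
overlap agree   --a km.csv --b llm.csv
overlap content --bank fixture/bank.csv --clustering llm.csv --out report/
```

`overlap run` writes `agreement.csv`, `overlap_pairs.csv`,
`overlap_summary.csv`, `occurrence.csv`, `sunburst.json`, and
`manifest.json` (plus per-stratum clusterings and assignment transcripts)
to the configured output directory; two runs with the same config and seed
produce byte-identical reports.

## File formats

- **Item bank** (CSV/TSV/JSON): columns `domain, questionnaire_id,
  questionnaire_name, item_id, text, rating_type (SR|OR|SR+OR),
  excluded (0/1)`. Missing item ids are generated as
  `<questionnaire_id>:<ordinal>`.
- **Symptom catalog**: one-column CSV (`symptom`) or a JSON array.
- **Embeddings**: TSV with header `item_id, v1..vD`.
- **Rater labels**: CSV `rater_id, item_id, symptom`; adjudication:
  `item_id, symptom`; recorded LLM responses: `item_id, response`.

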