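# Methods

## Model

`kgdiag` treats syndrome differentiation as link prediction on a typed,
undirected knowledge graph. Nodes are patients, clinical findings
(symptoms, tongue/pulse signs, pre-binned attributes), the five syndrome
patterns, and optional curated concepts (diseases, drugs, treatments).
Edges link each patient to their findings and, for diagnosed patients, to
their syndrome; curated knowledge triples (e.g. *finding — indicates —
syndrome*) may be fused in after entity alignment.

### Edge weights

For a labeled cohort with syndrome label `Y` and binary presence `X_e` of
finding `e`:

- `w_if(e) = H(Y) − H(Y | X_e)` — the information gain, identically the
  mutual information `I(X_e; Y)`, computed in **bits** (base-2 logs). For a
  5-class label it is bounded by `log2 5 ≈ 2.32`. Base 2 is a modeling
  choice; the published weight magnitudes are consistent with bits (all 50
  reference values are below `log2 5 + 1`).
- `w_sd(e, s) = (#patients with s presenting e + α) / (#patients with s + 2α)`
  — the syndrome-conditional presence probability, add-α smoothed. The
  default is `α = 0` (plain relative frequency; zero probabilities are
  representable); α is exposed for robustness on small folds.
- `Weight(e, s) = w_if(e) + w_sd(e, s)` — the combined symptom→syndrome
  edge weight. The same finding carries one `w_if` but a different `w_sd`
  per syndrome, so a shared pulse finding can count more toward one pattern
  than another.

Findings are strictly binary present/absent entities; multi-category or
continuous findings must arrive pre-binned as distinct labels (e.g.
`duration:>1y`). No continuous-feature MI estimator is provided.

### Similarity and diagnosis

The similarity of query `x` to labeled candidate `y` sums over the 2-hop
paths `x – h – y` through shared feature entities `h`:

```
score(x, y) = Σ_{h ∈ CN(x,y)} Weight(h, syndrome(y))
```

The crediting rule is configurable because the path-weight convention is
genuinely open: the default credits each shared entity once with its weight
toward the **candidate's** syndrome (the only weights the model defines —
the query has no syndrome, so no query-side syndrome-conditional weight
exists); `both-hops` credits the weight on each hop, doubling every term
and hence every score, which cannot change any ranking; `unweighted`
reduces to the common-neighbor count. Patient- and syndrome-typed nodes are
excluded as middle nodes: a shared syndrome node has no defined weight, and
including it would leak the label being predicted.

Diagnosis is a top-k vote (`k = 20` default): candidates are sorted by
score (ties: shared-entity count, then candidate id — a deterministic total
order), and the modal syndrome among the top k wins; vote ties break by the
larger summed score, then lexicographically. Class scores — the per-class
share of top-k score mass, falling back to vote fractions when all scores
are zero — provide the continuous value needed for ROC analysis of a
vote-based classifier; they are a harness construction, not part of the
vote itself.

Baselines Adamic–Adar (`Σ 1/ln deg(h)`, natural log, undirected degree) and
resource allocation (`Σ 1/deg h`) use the full graph degree of the shared
entity, including knowledge-triple edges; the transiently attached query
node contributes to those degrees, so a shared entity always has degree
≥ 2 and the logarithm never vanishes.

### Entity alignment

Near-duplicate entity names from heterogeneous sources are merged by string
similarity: normalized Levenshtein, `1 − editdistance / max(len)`,
computed on Unicode code points so Chinese clinical terms behave
per-character (an LCS-ratio variant is available). A raw label maps to the
highest-similarity canonical label when that similarity reaches the
threshold (default 0.6 — short clinical strings warrant a permissive
cutoff), otherwise it passes through unchanged. A manual-override file
(raw → canonical TSV) provides a reproducible, auditable stand-in for
manual curation and always wins over automatic matches.

## Synthetic cohorts

The generator emulates syndrome-conditional binary symptom profiles: for
each syndrome, each entity is present independently with a configured
Bernoulli probability. The defaults are the study-scale conditions:

| parameter | default | rationale |
|---|---|---|
| class sizes | KED 339, LFBU 307, PFSI 194, QDSS 270, WFAI 155 (n = 1265) | published cohort composition |
| signature entities | the 10 published weighted findings per syndrome | shared vocabulary with the reference weight table |
| signature presence p | 0.9 → 0.6, linearly spaced in descending published-weight order | higher-weight findings made more prevalent; one-time choice |
| background findings | 10 generic entities, p = 0.05 → 0.2, identical across syndromes | non-diagnostic noise floor |
| non-signature presence p | 0.10 | signature findings of other syndromes are common complaints, not exclusive |

Signature names shared across syndromes (Duration under all five; Fine
pulse and Dreaminess under both QDSS and KED) reproduce the documented
confusability of those two patterns without extra machinery. Patients who
draw no findings are resampled, so records are never empty; all randomness
flows from a single seed.

Conditional independence given the syndrome is deliberate: it is the
simplest model under which the estimated `w_sd` is exactly the generating
parameter, making parameter-recovery tests sharp. Real records correlate
findings within a patient and carry demographic covariates; neither is
modeled, so passing tests demonstrate correctness of the machinery and the
method's behavior under its own assumptions — not clinical performance on
real records.

## Evaluation

Stratified k-fold cross-validation (default 5 folds, shuffled with a fixed
seed) partitions patients; knowledge triples, when supplied, are global
background and are not folded. Per fold, the graph and weight table are
rebuilt from the training records only (leakage-safe default; a
whole-cohort weighting mode is available via `run_cv(leakage_safe=False)`
or the estimator's `weight_table` override to mirror protocols that weight
before splitting). Metrics are one-vs-rest per syndrome — accuracy,
precision, sensitivity, specificity, F1, and rank-based AUC (ties counted
½, computed from the class scores) — reported per fold and as mean (SD)
across folds; "accuracy" is the per-class one-vs-rest accuracy, consistent
with reporting one accuracy per syndrome, alongside the plain multiclass
accuracy. Ratios with empty denominators are reported as 0 and flagged;
AUC for a class absent from a test fold is reported as missing.

## Numerical choices

- Entropies clamp `0 · log 0 = 0`; information gain is clamped at 0 against
  last-ulp negatives; distribution sums are validated to 1e-6, identities
  asserted to 1e-9.
- The vectorized estimator scoring path and the per-pair graph traversal
  are cross-checked for equality in the test suite; the score a ranking
  used is the score reported, so emitted lists are exactly sorted.
- Sorting and tie-breaking are total orders everywhere (scores, votes,
  fold assignment), which is what makes identical seeds give bitwise
  identical cohorts, folds and reports.
- Entity ids are ASCII slugs with a display-label map; non-ASCII labels get
  a short stable hash id. TSV/JSON graph round-trips are bit-exact
  (`repr`-formatted floats); GraphML is a visualization export and
  collapses parallel relations between a node pair.

## Problem sizes

The default test and acceptance runs use: 1000 random contingency tables
for the entropy/MI identity; 200 random graphs (≤ 50 nodes) for
brute-force oracle equivalence of all four scores; a 5000-patient cohort
for parameter recovery (≥ 95% of signature probabilities within 3 binomial
SEs; background findings below 0.02 bits of gain); the full 1265-patient
cohort for 5-fold CV; and 100 random diagnoses for explanation
faithfulness. These sizes keep a full run in the tens of seconds on one
CPU while leaving the binomial error bars tight enough for the recovery
claims.

## Known limitations

- The exact published path-weight convention and score normalization are
  not recoverable from prose; the candidate-syndrome rule is the package's
  default and the alternatives stay switchable. Absolute published scores
  are therefore not reproduction targets — ordering properties are.
- The generator's independence assumption understates the difficulty of
  real cohorts; reported synthetic metrics are upper bounds on what equally
  sized real data would give.
- No free-text extraction: records must arrive structured. No treatment
  recommendation: drug/treatment nodes exist as types but are never scored.
- Whole-cohort weighting (the leakage-prone protocol) is intentionally
  opt-in.
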