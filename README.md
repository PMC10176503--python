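# hedkit

Quality control and ontology-driven semantic enrichment for multimodal
tabular health data.

Health datasets — clinical pathology, epidemiology, mutation panels,
treatment records — arrive as patient-by-variable tables riddled with ad hoc
missing-value encodings, internal contradictions, free-text fields and
unencoded category labels. hedkit prepares such tables for analysis:

- **Quality assessment**: per-variable and per-record completeness, a
  clustered missingness matrix for heatmaps, zero-entropy flagging, and
  internal-consistency checking against user-supplied semantic-dependency
  rules (e.g. *positive lymph nodes ≤ lymph nodes examined*).
- **Quality control**: standardisation of missing-value encodings to one
  canonical marker, information-theoretically scored variable merging,
  ordinal / binary / one-hot / frequency encoding with a label-to-code
  mapping reference table, free-text term extraction, and a final
  all-numeric assertion.
- **Review**: cell-level modification tracking (unchanged / substitution /
  removal / addition), value-combination tallies and completeness deltas
  between dataset versions.
- **Semantic enrichment**: variables mapped to entities of an ontology
  (a child→parent DAG, SNOMED CT / Gene Ontology style) are grouped by
  common ancestry; each group is labelled by its **most informative common
  ancestor (MICA)** and aggregated row-wise into candidate **meta-variables**,
  of which the informative (nonzero-entropy) ones are appended.

## The statistics at the core

For a value vector *X* with empirical element probabilities *p(xᵢ)* (missing
values excluded throughout), hedkit computes in bits:

- Entropy  H(X) = −Σ_c p_c log₂ p_c  over the distinct values *c*;
- Information content  IC(X) = −Σ_i log₂ p(xᵢ)  over the elements, so that
  IC(X) = n·H(X) for discrete data; continuous variables use an adaptive
  (Abramson) Gaussian kernel density estimate of *p*;
- Mutual information content  MIC(X, Y) = MI(X; Y) · n  with *n* the number
  of complete cases — a merge is lossless for input X exactly when
  MIC(X, merged) = IC(X);
- Symmetric uncertainty  SU(X, Y) = 2·(H(X) + H(Y) − H(X,Y)) / (H(X) + H(Y))
  ∈ [0, 1], the redundancy measure of the enrichment audit;
- Min–max normalisation  X_norm = (X − min X) / (max X − min X), applied per
  constituent before aggregation when magnitudes differ.

Ontology node specificity blends depth and relative number of descendants:

    IC(c) = k·(1 − ln(hypo(c)+1)/ln N) + (1−k)·ln(depth(c))/ln(depth_max)

with hypo(c) the node's ontology descendants, N the ontology size, depth the
longest root-path in nodes and k = 0.5 by default. Roots score 0, a
childless node at maximal depth scores 1.

## Worked example

`examples/03_semantic_enrichment.py` enriches five 0/1 comorbidity
indicators through a small cardiology ontology:

```
variable sets found: 2
  MICA 'ischaemic heart disease' (IC 0.533) covers ['ihd', 'mi']
    appended: ['SUM', 'MIN', 'MAX', 'AVG', 'MULT']; dropped as zero-entropy: []
  MICA 'heart disease' (IC 0.000) covers ['arrhythmia', 'hf', 'ihd', 'mi', 'valve_disease']
    appended: ['SUM', 'MAX', 'AVG']; dropped as zero-entropy: ['MIN', 'MULT']

candidates 10 - dropped 2 = appended 8

MV_heart_disease_SUM per record (comorbidity burden, missing values skipped):
  r1: 2.0
  r2: 0.0
  r3: 3.0
  r4: <NA>
  ...
```

All five variables share the "heart disease" ancestor; the {mi, ihd} pair is
additionally subsumed by the deeper, higher-IC "ischaemic heart disease"
node, so it forms its own set. `MV_heart_disease_SUM` counts each patient's
comorbidity burden over whatever was recorded (record r4, entirely missing,
stays missing); the MIN and MULT aggregations of the 5-set are constant zero
here, carry no information, and are dropped. The other examples walk through
quality control (`01`), merge evaluation (`02`) and encoding plus free-text
extraction (`04`).

## Command line

```sh
hedkit simulate --n-records 200 --seed 3 --out fixtures/
hedkit qc --input fixtures/cohort.csv --config fixtures/config.yaml \
          --rules fixtures/rules.csv --out qc_out/
hedkit enrich --input cleaned.csv --ontology edges.csv --mapping map.csv \
              --labels labels.csv --k 0.5 --out enrich_out/
hedkit report --before raw.csv --after qc_out/cleaned.csv --out review.md
```

`qc` writes the cleaned all-numeric table, the mapping reference table,
completeness and inconsistency reports and a markdown quality review;
`enrich` writes the enriched table, the per-set MICA report and the
symmetric-uncertainty redundancy audit.

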