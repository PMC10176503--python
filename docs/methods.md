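# Methods

This note records the models, estimators, conventions and deliberate design
choices behind hedkit, in the spirit of a statistical package's methods
documentation. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Data model

A dataset is a rectangular table of records (patients) by variables, with a
single canonical missing marker that is out-of-band: it is not a string, so
the literal label "NA" remains representable as a category value.
Serialisation writes the marker as `NA`. Every variable carries semantic
metadata — one of {continuous, integer, ordinal, nominal_binary,
nominal_multi, free_text, identifier}, a free-text modality tag, and for
ordinals an explicit level order. The integer/continuous distinction is
reporting-only; both are numeric downstream.

Type inference is heuristic and deliberately conservative, because user
review of the assignments is a mandatory workflow step: all-numeric parse →
continuous (integer when every value is integral); otherwise mean
whitespace-token count > 3 → free text; otherwise ≤ 2 distinct values →
binary, ≤ 10 (`max_levels_nominal`) → multi-level nominal, else free text.
Ordinal is never inferred — level order is domain knowledge. The thresholds
are declared defaults, not estimates of anything.

## Information measures

All measures are in bits (base 2) and complete-case: the missing marker
never contributes probability mass.

- **Entropy** is the standard non-negative Shannon form
  H(X) = −Σ p log₂ p. The package relies on the equivalence
  "zero entropy ⇔ at most one distinct observed value" for flagging
  uninformative variables, which requires the signed form.
- **Discrete information content** sums over elements, not distinct values:
  IC(X) = −Σᵢ log₂ p(xᵢ) = n·H(X). This scaling with n is intentional — IC
  is only ever compared against MIC, which is scaled by the same n.
- **Continuous information content** replaces p with an adaptive Gaussian
  kernel density estimate: a Silverman rule-of-thumb pilot
  (h = 0.9·min(sd, IQR/1.349)·n^(−1/5)) seeds Abramson local bandwidths
  λⱼ = (p̂_pilot(xⱼ)/g)^(−1/2) (g the geometric mean pilot density), and
  densities are floored at 1e-12 before the log. Requires ≥ 5 observations
  and a non-degenerate spread; a constant vector is an error rather than an
  arbitrary cap. The estimator (kernel, pilot, α = 0.5, floor) is a declared
  default; its plug-in estimate is verified against the true generating
  density on simulated normal data (within 5% at n = 1000) and against the
  exact change-of-variables shift n·log₂ s under scaling by s.
- **Mutual information** is the plug-in estimate from the joint contingency
  table. A side is treated as continuous only when it is all-numeric with
  more distinct values than the bin budget (10); such sides are discretised
  into equal-frequency bins, min(10, √n) of them. Discrete numeric codes
  (e.g. 0/1/2 encodings) therefore pass through unbinned. This is an
  estimator choice, stated as such; no bias-corrected or k-NN estimators are
  provided.
- **Mutual information content** MIC = MI · n_complete. On complete discrete
  data MIC(X,Y) ≤ IC(X), with equality exactly when X is a deterministic
  function of Y on the observed pairs — the test suite verifies this
  equivalence against a brute-force recoverability oracle, and merge-loss
  verdicts use it with tolerance 1e-9 bits.
- **Symmetric uncertainty** SU = 2(H(X)+H(Y)−H(X,Y))/(H(X)+H(Y)) on complete
  cases, clipped to [0, 1]; when both marginal entropies are zero SU is
  defined as 0 (a constant shares no information).

## Quality control conventions

- **Missing-value standardisation** matches string tokens case-insensitively
  and numeric tokens after numeric parse ("-1" also catches "-1.0"). The
  operation is idempotent and logs every altered cell.
- **Consistency rules** follow a two-form schema: numeric operator rules
  (`var_a OP var_b`) and boundary rules (value of A inside its boundary set
  requires value of B inside its boundary set), with ";"-separated category
  sets or colon-separated inclusive numeric ranges. Records with a missing
  operand are skipped by default — a missing value is never evidence of
  inconsistency — with a `skip_missing=False` escape hatch that flags
  half-missing operator pairs.
- **Completeness matrix**: numeric cells pass through, non-numeric cells are
  encoded as the count of distinct values in their variable, and missing
  cells as a distant value (default 2·(max |value| + 1)) so missingness
  dominates the geometry; rows and columns are ordered by single-linkage
  hierarchical clustering of Euclidean distances. The binary present/missing
  mask is returned alongside for plotting with any heatmap tool.
- **Zero-entropy flagging** includes all-missing variables: they cannot
  stratify the cohort either way.
- **Review** classifies each compared cell as unchanged, substitution,
  removal (value → missing) or addition (missing → value); the four counts
  partition the compared cells. Numbers are compared after canonical
  formatting at 12 significant digits so float noise is not a substitution.
  Variables present in only one version are excluded from cell tracking and
  surfaced by the variable diff instead.

## Encoding

Ordinal labels map to their 1-based position in the declared level order
(N0/N1/N2 → 1/2/3 style); binary variables to 1 for the declared positive
label; multi-level nominals expand to one-hot indicators plus a `_NA`
indicator whenever missingness exists, so each record's indicators sum to
exactly 1 and the expanded columns contain no missing values. Frequency
encoding ranks labels by descending cohort frequency (most common = 0), with
lexicographic tie-breaks for determinism. All original labels are preserved
in a mapping reference table, and a final assertion verifies every
non-identifier variable parses as numeric.

Free-text extraction lowercases, applies an optional user substitution table
(regex → replacement; automatic spelling correction is out of scope), strips
punctuation and stopwords (a vendored English snapshot), and forms unigrams
plus skipgrams (default length 2, skip window 1). Terms present in at least
`min_record_frequency` records (default 2) become 0/1 presence variables;
records with missing text stay missing in every generated variable.

## Semantic enrichment

The ontology is consumed as a child→parent edge table (precomputed upstream
from OWL/RF2/OBO sources; hedkit does no ontology reasoning beyond is_a
edges) plus a variable→entity mapping table; unmapped dataset variables
simply take no part. Node information content blends two specificity
notions with weight k (default 0.5):

    IC(c) = k·(1 − ln(hypo(c)+1)/ln N) + (1−k)·ln(depth(c))/ln(depth_max)

Conventions, chosen where several readings were possible and fixed for
determinism: hypo(c) and N count ontology nodes only (attached variable
nodes are excluded); depth is the longest root-to-node path counted in
nodes, so roots have depth 1; with multiple roots each node's depth is taken
from its deepest applicable root (equivalently a virtual super-root excluded
from N); a single-node or single-level ontology scores 0 everywhere.

Each ontology node subsumes the variables mapped to it or to any of its
descendants. Nodes whose variable sets are identical and of size ≥ 2 are
grouped; the group's MICA is the member of maximal IC, ties broken by
greater depth then lexicographic id. A variable mapped to several entities
counts under any ancestor of any of them. The implementation is verified
against exhaustive ancestor enumeration on random DAGs.

Each set yields five candidates — row-wise sum, minimum, maximum, average
and product — computed over the non-missing constituents only; a record with
all constituents missing stays missing. Consequently a meta-variable is at
least as complete as its most complete constituent. Optional min–max
normalisation precedes aggregation when constituents differ in magnitude
(it errors on constants rather than guessing). Candidates whose values
(rounded to 12 decimals) are constant are dropped; survivors are appended as
`MV_<mica label>_<AGG>` (whitespace → underscores, collisions suffixed), and
the report carries set counts, the conservation identity
candidates − dropped = appended, and the SU of every appended meta-variable
with each constituent as a redundancy audit.

## Synthetic data

The cohort generator is a pure function of its spec (fixed seed →
byte-identical output). Its defaults emulate the structure of a real
multimodal colorectal-cancer cohort: 661 records and 154 variables plus
identifier across four modalities (clinical pathology, epidemiology,
mutation, treatment/outcomes); eight distinct missing-value tokens
("NA", "N/A", "unknown", "Unknown", "missing", "", "-1", "999" — structural
stand-ins, not any cohort's actual tokens) at an overall rate of 4.3%,
placed as modality-aligned rectangular blocks plus uniform noise; four
constant variables; and 40 violations of a bundled lymph-node staging rule
set (positive ≤ examined; N2 requires ≥ 4 positive nodes), planted so that
each violating record breaks exactly one rule and no violation arises by
accident. Every planted defect is written to a ground-truth ledger, which
is what makes exact-recovery testing possible.

What the generator does **not** emulate: realistic marginal distributions or
inter-variable correlations, real mutation panels, longitudinal structure,
or the content of any licensed ontology. Passing tests therefore demonstrate
correctness of the mechanics (counting, flagging, grouping, aggregating) on
data with known ground truth — not clinical validity on any particular
cohort.

A further constructed fixture exercises enrichment arithmetic at scale: 36
independent two-variable sets (180 candidates) whose constituents are chosen
so that exactly 31 candidates are constant, leaving 149 appended — the
conservation identity under realistic set counts.

## Problem sizes

The default verification sizes were chosen to make every check exact or
near-exhaustive while remaining quick on one CPU: all 1,092 category vectors
of length ≤ 6 over a 3-letter alphabet for entropy; all 5,004 achievable
joint-distribution multisets at n ≤ 6 for mutual information (both
implementations are order-invariant, so multisets cover all pairs;
order-invariance is itself spot-checked); 1,000 random vectors for the
IC = n·H identity; 200 random surjective merge maps for the recoverability
equivalence; 100 random DAGs of ≤ 40 nodes and ≤ 10 variables for MICA
discovery; and cohorts of 120–661 records for planted-defect recovery.

## Known limitations

- The continuous-MI discretiser and the KDE-based continuous IC are
  estimator conventions; different choices give numerically different (not
  comparable) values.
- No imputation, outlier detection, stemming/lemmatisation, clinical NER,
  OWL/RF2 parsing, or automatic variable→ontology mapping; mappings are
  curated inputs.
- Aggregated meta-variables assume constituents point in a consistent
  direction; variables encoding negative findings or missingness indicators
  should not be mapped, as aggregation would let them cancel positive
  findings.
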