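# Methods

This note documents the models and procedures `idlink` implements, the
assumptions behind them, the tunable parameters, and what the synthetic-data
experiments do and do not establish.

## 1. Identifier cleaning

Every field-level cleaner maps raw input to a normalised value or `None`;
cleaning never raises on bad data and never invents a value. Rules and
defaults:

| Field | Rule | Default |
|---|---|---|
| names | uppercase, strip non-A–Z, null if < 2 letters; forenames nulled when containing a placeholder token | placeholders `BABY, INFANT, TWIN, TRIPLET, UNNAMED, UNKNOWN` (substring match) |
| name swap | forename/surname reversed when the forename is unknown but the surname is a known forename | reference set built from the data (`reference_forenames`, min count 2) |
| sex | synonym table, else leading character if in {M, F, U} | `MALE→M, FEMALE→F, UNKNOWN/UNK/NOTKNOWN→U` |
| dates | parse `ddmmyyyy` (wire format), ISO, or `dd/mm/yyyy`; null if before 1860-01-01 or in the future | floor 1860-01-01 |
| NHS number | exactly 10 digits, Modulus-11 check (weights 10..2, check = 11 − sum mod 11, 11→0, 10→invalid), blacklist | blacklist = all-same-digit values |
| hospital number | whitespace stripped, optional trailing check digit stripped (off by default — the check-digit format varies by site), numeric range check, `CODE:` prefix when a hospital code is given | range 1–10⁷ |
| policy | suppressed-clinic records have **all** identifiers nulled; internal test patients have names nulled | clinics `GUM, GENITOURINARY, OCCH, OCCUPATIONALHEALTH`; test names `ZZTEST, XXTEST, TESTPATIENT, DONOTUSE` |

Cleaning is idempotent: re-cleaning a cleaned frame is a no-op (already-prefixed
hospital numbers are recognised; ISO dates re-parse). Dates are carried as ISO
strings so cleaned frames round-trip through CSV byte-identically.

## 2. Composite identifier

`SURNAME|FFF|YYYY-MM-DD` — whole surname, first three forename letters (both
letters when the cleaned forename has only two; cleaning guarantees ≥ 2), ISO
birthdate, `|` separator (unreachable in cleaned names). Null when any
component is missing. `cardinality_report` quantifies identifier quality as
(distinct values, mean distinct reference identifiers per value); a mean near
1 marks a usable near-unique key, and adding components can only increase
cardinality.

## 3. Exact-match linkage

`link` computes connected components of the identifier-sharing graph by
**min-label propagation**: each sweep, per identifier field, every record's
cluster id is replaced by the minimum id among records sharing its value;
sweeps repeat to a fixed point. Each sweep is a vectorised O(mn) group-min
(`numpy.minimum.at` over factorised values); convergence is typically 1–3
sweeps because post-merge shared identifiers are rare. The partition is
provably independent of record and field order; the iteration count is
reported. A design alternative — union-find with value→root hash maps — gives
the same partition; the sweep form was chosen because it is the natural
vectorisation in numpy and directly exposes `single_pass_join`, the one-field
join used in the worked example. The tiny re-clustering inside the splitting
loop *does* use union-find (pure Python beats vectorised overhead at n ≤ 10).

Cluster id = minimum member *start id* (integer record_id, else 1-based input
position): deterministic and stable under merges. Records with no valid
identifier at all cannot be linked; they are excluded before linkage and
reported. `dedupe=True` collapses identical identifier tuples first (the
partition is unchanged). `incremental_add` extends an existing result and is
contractually equivalent to re-linking the union.

## 4. Collision detection

Only *complex* clusters (> 1 distinct non-null value in some linkage
identifier) can contain two people. The rule test labels a cluster good when
two independent identifiers are each present and invariant (NHS + hospital,
NHS + composite, or hospital + composite).

Features are per-field **maximal pairwise distances** over all record pairs:
Levenshtein on zero-padded day/month (2 digits) and year (4 digits) and on
M/F/U sex codes; 1 − Jaro–Winkler similarity (prefix scale 0.1, max prefix 4)
on forename, surname and hospital number. Distance orientation is a package
decision: all features are dissimilarities, so the positive forename
coefficient reads "more different forename → more likely bad". Pairs with a
null on either side are skipped and a field with < 2 non-null values
contributes 0 — missingness must not mimic conflict.

The shipped classifier: intercept −3.33; coefficients dob day 0.25, month
0.43, year 5.12, forename 2.45, hospital number −0.56, sex 0.80; cutoff −1.5
(strict: a score exactly at the cutoff is good). One published set serves both
the any-female and no-female models; the surname term is absent from both (no
separate no-female surname coefficient was published, and in female-containing
clusters surname conflict is benign). The birth-year term dominates: any
single-digit year conflict contributes ≥ 5.12, taking the score from −3.33 to
+1.79, which is why randomly combined patients are detected so reliably and
why false positives concentrate in same-birth-year pairs.

`fit_logistic_backward_aic` re-fits on a user's own rule-good / simulated-bad
sample: statsmodels Logit (Newton/IRLS), then backward elimination removing
the term whose deletion most reduces AIC until none does. Complete separation
is reported with a warning and coefficients clipped at ±30 (configurable)
rather than an error.

## 5. Collision resolution

Candidates are the (record, field, value) instances whose value is shared by
≥ 2 cluster records — only shared values form edges, so only these can
disconnect anything. Each variant nulls **one instance** (the error model is
"one record carries a wrong number"; `value_level=True` nulls every instance
of the value instead), re-clusters, and computes `quality_gain`: the count of
(part, field) combinations with non-null cardinality exactly 1, minus the
same count on the unsplit cluster. The winner must divide the cluster *and*
achieve strictly positive gain; ties break uniformly at random under the
given seed (tie counts are reported). A division into > 2 parts is accepted
and its part count recorded.

`resolve_all` scores every complex cluster, splits the bad ones (one split per
cluster per pass), rebuilds cluster ids by the min-start-id rule, and
re-scores the output once, reporting residual bad clusters. Because splitting
only deletes, the output partition always refines the input and record counts
are conserved.

## 6. Synthetic data

The generator states a world and keeps it fixed:

* **Patients**: names from bundled pools (~70 forenames per sex, ~120
  surnames) sampled with Zipf-like skew (exponent 0.9) so namesakes occur;
  sex 50/50; birthdates uniform over 1920–2005 (day 1–28 to stay in-month);
  unique check-digit-valid NHS numbers; unique hospital numbers in 1–10⁷.
* **Records**: 1–5 per patient, sources weighted like a hospital's mix (two
  laboratory feeds dominating), per-source presence patterns for (hospital
  number, NHS number, name/dob) shaped like observed combinations — including
  a small fraction of identifier-free laboratory records, which linkage
  excludes and reports.
* **Errors** (defaults chosen once as plausible rates, documented here because
  no empirical value was available): typo rate 0.001 per identifier field
  (single-character substitution), surname change for 10% of female patients
  (the married name appearing on ~half their records), cross-patient
  hospital-number collisions off by default. `ErrorModel.none()` is the
  error-free, fully identified limit, in which linkage recovers the true
  partition exactly.

**Collision experiments.** Good clusters for both simulations are 2–5
complete, internally consistent records per patient — the stated experimental
world, in which clusters are rule-good by construction. Bad clusters for the
classifier experiment are random disjoint pairings of good clusters. The
splitting experiment forges a collision by overwriting one randomly selected
hospital number of cluster A with the *maximal* hospital number of cluster B,
runs the heuristic, and scores success when the deleted instance equals the
forged one. In this world every identifier value appears at least twice per
source cluster, so the forged instance is the unique candidate whose deletion
divides the cluster, and measured recovery is ~100% — above the ≥ 96.9%
floor observed on real clusters, where missing identifiers and benign
variation create ties the simulation does not model. A green test therefore
establishes the heuristic's correctness in the single-error regime, not its
field performance on sparse or multiply-erroneous clusters.

## 7. Fuzzy search

The trigram index registers all distinct 3-character substrings of surname,
forename, birthdate (as `ddmmyyyy`, its native wire format), hospital and NHS
numbers; values shorter than 3 characters contribute themselves as one token.
Queries rank candidates by the count of **distinct** shared trigrams pooled
across fields (unweighted; multiplicity was a judgement call and distinct
counting is documented as such), ties by ascending record id, the query's own
record excluded. Output is a candidate list for human review; fuzzy evidence
never merges clusters automatically.

## Numerical and degenerate-input choices

* Levenshtein/Jaro–Winkler are implemented in-package (two short, fully
  tested functions; no suitable dependency was available in the target
  environment). Jaro of two empty strings is 1; empty vs non-empty is 0.
* Cluster scoring with a model whose coefficient names a missing feature is a
  hard error (misconfiguration), while missing *data* degrades gracefully to
  zero-distance features.
* `evaluate_resolution(0, ...)` returns an empty result, not an error; an odd
  cluster in bad-pair simulation is dropped.
* All randomness flows through `numpy.random.Generator` seeds; fixed seeds
  give byte-identical generated CSVs and pipeline outputs (wall-clock timings
  are kept out of written artifacts for that reason).

## Known limitations

* Records sharing no exact identifier with the rest of a person's records
  stay unlinked; that is inherent to exact matching and the reason for the
  fuzzy audit tool.
* Clusters welded by two or more coincident errors are out of the splitting
  heuristic's scope (single-deletion variants cannot divide them cleanly).
* The synthetic world does not emulate transliteration variants,
  double-barrelled names, shared (non-unique) hospital numbers, or
  date-component swaps, all of which occur in real data and degrade both
  classifier specificity and splitting recovery.
* No phonetic normalisation (e.g. double metaphone) and no address/postcode
  handling.
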