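# idlink

Exact-match record linkage for large multi-source person-record sets, with
graph-based detection and repair of **identity collisions**.

## The problem

Hospitals and registries hold millions of records — admissions, laboratory
samples, historical name changes — that must be assigned to the individuals
who generated them without a master patient list. Identifiers that should be
unique (NHS numbers, hospital numbers) are missing from many records and
occasionally mistyped; with sequentially issued numbers, a single typo often
produces *another patient's* valid identifier. Pairwise probabilistic linkage
is O(n²) and needs blocking heuristics; pure exact matching is fast but welds
two people into one cluster whenever such a typo occurs.

`idlink` implements a two-step scheme that keeps the speed of exact matching
and repairs its failure mode:

1. **Exact-match clustering.** Records are cleaned (`cleaning`), given a
   constructed high-cardinality key — surname + first three forename letters +
   date of birth (`composite`) — and clustered by iterated set union over the
   identifiers (`linkage`): a cluster is a connected component of the graph
   whose edges are shared identifier values. Each sweep is O(mn) for m
   identifiers and n records and the result is order-independent.
2. **Collision handling.** Clusters with internal identifier variation are
   scored with a logistic classifier over per-field *maximal pairwise
   distances* (`detection`) — Levenshtein on date-of-birth components and sex
   codes, 1 − Jaro–Winkler on names and hospital numbers:

   score = −3.33 + 0.25·d_day + 0.43·d_month + 5.12·d_year
            + 2.45·d_forename − 0.56·d_hospital + 0.80·d_sex

   with scores > −1.5 flagged *bad* (clusters containing any female record are
   scored without a surname term, since surnames legitimately change on
   marriage). Flagged clusters are split (`resolution`) by deleting the single
   identifier instance whose removal disconnects the cluster while maximising
   the number of *invariant* identifiers (fields with within-cluster
   cardinality 1), then re-scored once.

A synthetic-population generator (`simulate`) reproduces the structure of
multi-source hospital data — per-source missingness, surname change on
marriage, typos, forged hospital-number collisions — and powers every
experiment; a trigram index (`fuzzy`) supports near-duplicate auditing.

## Worked example

```python
import idlink as il

worked = il.datasets.worked_example()   # six records, all "DAVID WILSON"
res = il.link(worked)                   # NHS + hospital + composite identifier
for c in res.clusters():
    print(c.cluster_id, c.members)
```

prints

```
1 [1]
2 [2]
3 [3, 4, 5, 6]
```

Records 3–6 chain together (3–5 share an NHS number, 3–6 a hospital number,
3–4–5–6 the composite `WILSON|DAV|1969-01-20`), while records 1 and 2 — same
name, different birthdates — remain separate patients. A single NHS-number
pass alone yields new cluster ids `1 2 3 4 3 6`: only record 5 is merged.

The `examples/` directory walks through each capability (cleaning audit,
linkage, cardinality reporting, collision detection, resolution, fuzzy
search, full pipeline); each script prints its numbers with an explanation.
The full pipeline is one call:

```python
result = il.run_pipeline(records, il.PipelineConfig(seed=43))
print(result.report.as_dict())          # stage counts + timings
```

## Acceptance script

`scripts/acceptance.py` recomputes the package's headline quantities from
scratch: the worked-example join assignments, the fraction of 1,000 simulated
single-identifier collisions correctly partitioned by the splitting heuristic,
and the sensitivity of the published logistic classifier on 500 simulated
bad clusters. Run it from the repository root:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

```
src/idlink/        cleaning, composite, linkage, detection, resolution,
                   simulate, fuzzy, pipeline, datasets
examples/          one narrative script per capability
tests/             pytest suite (unit, property and acceptance tests)
docs/methods.md    models, assumptions, numerical choices, limitations
```
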