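"""The whole scheme end to end: clean -> composite -> link -> detect -> resolve.

Generates a noisy multi-source population with deliberate cross-patient
hospital-number collisions, runs the pipeline, and prints the stage report
plus the multiple-identifier audit before and after resolution.
"""

import idlink as il

patients = il.generate_patients(500, rng_seed=41)
records, truth = il.generate_records(
    patients, rng_seed=42,
    error_model=il.ErrorModel(typo_rate=0.002, surname_change_rate=0.1, collision_rate=0.01),
)
result = il.run_pipeline(records, il.PipelineConfig(seed=43))

r = result.report
print(f"records in:            {r.n_records_in}")
print(f"no valid identifiers:  {r.n_unidentified} (excluded, reported)")
print(f"clusters after link:   {r.n_clusters}  ({r.n_complex} complex)")
print(f"flagged bad:           {r.n_flagged_bad}, splits performed: {r.n_splits}")
print(f"clusters after resolve:{r.n_clusters_after}  (bad on re-score: {r.n_bad_after_rescore})")

print("\nclusters with multiple values per field (before -> after resolution):")
before = il.multi_identifier_report(result.linkage)
after = il.multi_identifier_report(result.resolved)
for field in before.index:
    print(f"  {field:16s} {before[field]:4d} -> {after[field]:4d}")
print(
    "\nResolution only ever splits clusters, so every 'multiple identifiers' count"
    "\ncan only drop; the surname counts that remain reflect benign variation"
    "\n(marriage), which is exactly why the classifier ignores surname conflicts in"
    "\nclusters containing women."
)
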