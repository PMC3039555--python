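"""Splitting a welded cluster by deleting the single erroneous identifier.

Forges a collision — one record of patient A receives patient B's hospital
number — then shows that the splitting heuristic finds and deletes exactly
that instance, restoring the two original clusters. Ends with the 1,000-trial
recovery experiment.
"""

import idlink as il

a, b = il.make_good_clusters(2, rng_seed=21)
merged, truth = il.inject_hospital_collision(a, b, rng_seed=22)
print("welded cluster (note the forged hospital number):")
print(merged.records[["record_id", "nhs_number", "hospital_number", "surname",
                      "forename", "birthdate"]].to_string(index=False))
print(f"\ninjected error: record {truth.record_id}, {truth.field} = {truth.value}")

outcome = il.split_cluster(merged, rng_seed=23)
print(f"heuristic deleted: record {outcome.deleted.record_id}, "
      f"{outcome.deleted.field} = {outcome.deleted.value}")
print(f"parts after split: {[c.members for c in outcome.clusters]}, "
      f"invariant-identifier gain {outcome.quality_gain}")
print("correct!" if outcome.deleted == truth else "missed.")

result = il.evaluate_resolution(1000, rng_seed=24)
print(
    f"\nfull experiment: {100 * result.success_fraction:.1f}% of {result.n_trials} "
    "simulated collisions correctly partitioned\n(the deleted instance equals the "
    "injected one), because only the forged instance\ndisconnects the cluster while "
    "maximising the count of invariant identifiers."
)
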