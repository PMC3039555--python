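"""Scoring clusters for identity collisions with the published logistic model.

Builds clean single-person clusters, welds random pairs into simulated 'bad'
clusters, extracts per-field maximal pairwise distances, and scores both
groups. Scores above the -1.5 cutoff are flagged bad.
"""

import idlink as il

good = il.make_good_clusters(200, rng_seed=11)
bad = il.simulate_bad_by_combination(good[:100], rng_seed=12)

good_table = il.features_frame(good[100:])
bad_table = il.features_frame(bad)

print("example bad-cluster feature rows (maximal pairwise distances):")
print(bad_table[["cluster_id", "dob_year", "forename", "hospital_number", "sex",
                 "score", "label"]].head(5).to_string(index=False))

sens = (bad_table["label"] == "bad").mean()
spec = (good_table["label"] == "good").mean()
print(f"\nsensitivity on {len(bad_table)} simulated collisions: {100 * sens:.1f}%")
print(f"specificity on {len(good_table)} clean clusters:        {100 * spec:.1f}%")
print(
    "\nA conflict in birth year (coefficient 5.12 per Levenshtein edit) is almost"
    "\nenough on its own to cross the -1.5 cutoff from the -3.33 intercept, which is"
    "\nwhy randomly paired patients are detected so reliably, while internally"
    "\nconsistent clusters sit at the intercept and are labelled good."
)
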