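"""Why surname + forename prefix + birthdate works as a linkage key.

Generates a synthetic population, then reports the cardinality of candidate
identifiers and the mean number of distinct NHS numbers mapping to each value.
A mean close to 1 means the candidate behaves like a unique identifier.
"""

import idlink as il

patients = il.generate_patients(2000, rng_seed=7)
records, _ = il.generate_records(patients, rng_seed=8, error_model=il.ErrorModel.none())
cleaned = il.clean_frame(records)

report = il.cardinality_report(
    cleaned,
    {
        "surname": ["surname"],
        "surname, forename": ["surname", "forename"],
        "surname, forename, date of birth": ["surname", "forename", "birthdate"],
    },
    reference_field="nhs_number",
)
print(report.to_string(index=False))
print(
    "\nCardinality rises and the mean NHS-numbers-per-value falls towards 1 as"
    "\ncomponents are added: names alone are shared across patients (Zipf-skewed"
    "\npools), but adding the birthdate makes the combination nearly unique."
)
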