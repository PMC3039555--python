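"""Identifier cleaning: malformed values are nulled, never propagated.

Builds a handful of messy raw rows, cleans them, and prints the before/after
audit. Note the placeholder forename, the NHS number failing its Modulus-11
check digit, and the suppressed genito-urinary clinic record.
"""

import pandas as pd

import idlink as il

raw = pd.DataFrame(
    [
        {"record_id": 1, "surname": "de Souza", "forename": "Maria", "sex": "female",
         "birthdate": "14061940", "nhs_number": "4010232137", "hospital_number": " 44 96644"},
        {"record_id": 2, "surname": "WILSON", "forename": "Baby", "sex": "M",
         "birthdate": "20011969", "nhs_number": "5170231111", "hospital_number": "4118890"},
        {"record_id": 3, "surname": "Smith", "forename": "John", "sex": "M",
         "birthdate": "01011850", "nhs_number": None, "hospital_number": "123456",
         "hospital_code": "A", "clinic_code": None},
        {"record_id": 4, "surname": "Jones", "forename": "Ann", "sex": "F",
         "birthdate": "02021990", "nhs_number": None, "hospital_number": "777",
         "clinic_code": "GUM"},
    ]
)

cleaned, audit = il.clean_frame(raw, with_audit=True)
print("cleaned records:")
print(cleaned[["record_id", "surname", "forename", "sex", "birthdate",
               "nhs_number", "hospital_number", "suppressed"]].to_string(index=False))
print("\naudit trail (what was changed and why it matters):")
print(audit.to_string(index=False))
print(
    "\nRecord 1 survives intact (its NHS number passes the check digit); record 2's"
    "\nplaceholder forename and invalid NHS number are nulled; record 3's 1850 birthdate"
    "\nis impossible and its hospital number gains the issuing-hospital prefix A:;"
    "\nrecord 4 is a suppressed-clinic record, so every identifier is removed by policy."
)
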