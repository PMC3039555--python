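"""Small bundled datasets for documentation and worked examples."""

from __future__ import annotations

import pandas as pd

from .composite import add_composite

__all__ = ["worked_example"]


def worked_example() -> pd.DataFrame:
    """Six already-cleaned records for three patients all named David Wilson.

    A classic demonstration set: the records differ in dates of birth, NHS and
    hospital numbers, and only the combination of identifiers separates the
    three individuals. Record ids double as start cluster ids (1-6); a single
    NHS-number join merges records 3 and 5, and full linkage over NHS number,
    hospital number and the composite identifier yields three clusters
    {1}, {2}, {3, 4, 5, 6}.

    The NHS numbers are fabricated demonstration values and deliberately do
    not pass the Modulus-11 check, so the frame is supplied in clean form and
    is meant to be fed straight to linkage.
    """
    frame = pd.DataFrame(
        [
            (1, None, "4496644", "WILSON", "DAVID", "M", "1940-06-14"),
            (2, "5170231111", None, "WILSON", "DAVID", "M", "1939-05-01"),
            (3, "3319004037", "4118890", "WILSON", "DAVID", "M", "1969-01-20"),
            (4, None, None, "WILSON", "DAVID", "M", "1969-01-20"),
            (5, "3319004037", None, "WILSON", "DAVID", "M", "1969-01-20"),
            (6, None, "4118890", "WILSON", "DAVID", "M", "1969-01-20"),
        ],
        columns=["record_id", "nhs_number", "hospital_number", "surname", "forename", "sex", "birthdate"],
    )
    return add_composite(frame)
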