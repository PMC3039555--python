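"""Bundled name pools for the synthetic patient generator.

Small, UK-flavoured lists; sampling applies a Zipf-like skew so common names
recur across patients (several distinct patients sharing a full name is a
normal feature of real data and exercises the composite identifier).
"""

MALE_FORENAMES = (
    "DAVID", "JOHN", "MICHAEL", "JAMES", "ROBERT", "WILLIAM", "PETER", "PAUL",
    "ANDREW", "MARK", "STEPHEN", "RICHARD", "CHRISTOPHER", "DANIEL", "THOMAS",
    "MATTHEW", "GEORGE", "EDWARD", "ANTHONY", "KEVIN", "BRIAN", "ALAN", "IAN",
    "COLIN", "GRAHAM", "NEIL", "STUART", "DEREK", "ROGER", "KEITH", "BARRY",
    "TREVOR", "NIGEL", "MARTIN", "PHILIP", "SIMON", "ADAM", "BENJAMIN", "SAMUEL",
    "JOSEPH", "HENRY", "CHARLES", "FRANCIS", "PATRICK", "DUNCAN", "GORDON",
    "MALCOLM", "NORMAN", "RAYMOND", "RONALD", "TERENCE", "VICTOR", "WALTER",
    "ARTHUR", "ALBERT", "ERIC", "FRANK", "HAROLD", "LEONARD", "STANLEY",
    "CHRIS", "OLIVER", "HARRY", "JACK", "LUKE", "NATHAN", "RYAN", "JOSHUA",
    "LIAM", "CALLUM",
)

FEMALE_FORENAMES = (
    "MARGARET", "MARY", "ELIZABETH", "SUSAN", "SARAH", "PATRICIA", "CAROL",
    "LINDA", "JANET", "CHRISTINE", "HELEN", "KAREN", "JULIE", "JACQUELINE",
    "ANNE", "JANE", "CATHERINE", "FRANCES", "ALISON", "CLAIRE", "EMMA",
    "LOUISE", "REBECCA", "RACHEL", "VICTORIA", "HANNAH", "LUCY", "SOPHIE",
    "CHARLOTTE", "AMY", "LAURA", "GILLIAN", "PAULINE", "SHEILA", "JOAN",
    "JOYCE", "JEAN", "DOROTHY", "KATHLEEN", "IRENE", "AUDREY", "BARBARA",
    "BERYL", "BRENDA", "DAPHNE", "DOREEN", "EDNA", "ETHEL", "FLORENCE",
    "GLADYS", "HILDA", "IVY", "LILIAN", "MABEL", "MAUREEN", "MURIEL", "NORA",
    "OLIVE", "PHYLLIS", "ROSEMARY", "SYLVIA", "VERA", "WENDY", "YVONNE",
    "NICOLA", "TRACEY", "DONNA", "GEMMA", "KELLY", "STACEY",
)

SURNAMES = (
    "SMITH", "JONES", "WILLIAMS", "TAYLOR", "BROWN", "DAVIES", "EVANS",
    "WILSON", "THOMAS", "JOHNSON", "ROBERTS", "ROBINSON", "THOMPSON", "WRIGHT",
    "WALKER", "WHITE", "EDWARDS", "HUGHES", "GREEN", "HALL", "LEWIS", "HARRIS",
    "CLARKE", "PATEL", "JACKSON", "WOOD", "TURNER", "MARTIN", "COOPER", "HILL",
    "WARD", "MORRIS", "MOORE", "CLARK", "LEE", "KING", "BAKER", "HARRISON",
    "MORGAN", "ALLEN", "JAMES", "SCOTT", "PHILLIPS", "WATSON", "DAVIS",
    "PARKER", "PRICE", "BENNETT", "YOUNG", "GRIFFITHS", "MITCHELL", "KELLY",
    "COOK", "CARTER", "RICHARDSON", "BAILEY", "COLLINS", "BELL", "SHAW",
    "MURPHY", "MILLER", "COX", "RICHARDS", "KHAN", "MARSHALL", "ANDERSON",
    "SIMPSON", "ELLIS", "ADAMS", "SINGH", "BEGUM", "WILKINSON", "FOSTER",
    "CHAPMAN", "POWELL", "WEBB", "ROGERS", "GRAY", "MASON", "ALI", "HUNT",
    "HUSSAIN", "CAMPBELL", "MATTHEWS", "OWEN", "PALMER", "HOLMES", "MILLS",
    "BARNES", "KNIGHT", "LLOYD", "BUTLER", "RUSSELL", "BARKER", "FISHER",
    "STEVENS", "JENKINS", "MURRAY", "DIXON", "HARVEY", "GRAHAM", "PEARSON",
    "ANSARI", "BATES", "REID", "ARMSTRONG", "DESOUZA", "NGUYEN", "OKONKWO",
    "KOWALSKI", "SCHMIDT", "IVANOV", "ROSSI", "GARCIA", "FERNANDEZ", "SILVA",
    "TANAKA", "CHEN", "WONG", "KIM", "OBRIEN",
)
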