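"""Synthetic multi-source hospital records with controllable error injection.

Real hospital linkage data cannot be distributed, so every experiment in this
package runs on synthetic populations that emulate its structure:

* patients with Zipf-skewed names (shared full names occur, as in real data),
  sex, birthdates uniform over a configurable year range, a unique check-digit
  valid NHS number and a unique hospital number;
* per-source missingness patterns shaped like the observed presence/absence
  combinations of hospital number, NHS number and name/date-of-birth across a
  patient administration system, two laboratory systems, an emergency tracker
  and a names-history feed;
* benign within-person variation (surname change on marriage) and injected
  errors (single-character typos; hospital-number collisions copying another
  patient's number).

``inject_hospital_collision`` and ``evaluate_resolution`` reproduce the
splitting-heuristic experiment: combine two good clusters by overwriting one
randomly selected hospital number in one with the maximal hospital number of
the other, then check whether the splitting heuristic deletes exactly the
corrupted instance.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._names import FEMALE_FORENAMES, MALE_FORENAMES, SURNAMES
from .composite import add_composite
from .linkage import Cluster, link
from .resolution import SplitCandidate, split_cluster

__all__ = [
    "SyntheticPatient",
    "PopulationConfig",
    "ErrorModel",
    "DEFAULT_MISSINGNESS",
    "generate_patients",
    "generate_records",
    "make_good_clusters",
    "inject_hospital_collision",
    "evaluate_resolution",
    "EvaluationResult",
]

_NHS_WEIGHTS = (10, 9, 8, 7, 6, 5, 4, 3, 2)


@dataclass(frozen=True)
class SyntheticPatient:
    true_id: int
    forename: str
    surname: str
    sex: str
    birthdate: dt.date
    nhs_number: str
    hospital_number: str


@dataclass(frozen=True)
class PopulationConfig:
    """Stated world for the synthetic population."""

    birth_year_range: tuple[int, int] = (1920, 2005)
    hospital_number_range: tuple[int, int] = (1, 10_000_000)
    zipf_exponent: float = 0.9  # name-frequency skew
    records_per_patient: tuple[int, int] = (1, 5)


# Presence patterns (hospital number, NHS number, name+dob) per source, with
# probabilities shaped like the observed mix: an admissions system rich in
# hospital numbers, laboratory feeds with many name/dob-only records, and a
# small fraction of records carrying no identifiers at all.
DEFAULT_MISSINGNESS: dict[str, list[tuple[tuple[int, int, int], float]]] = {
    "JONAH": [((1, 1, 1), 0.72), ((1, 0, 1), 0.28)],
    "LIMS": [
        ((1, 1, 1), 0.04),
        ((1, 0, 1), 0.32),
        ((1, 0, 0), 0.005),
        ((0, 1, 1), 0.015),
        ((0, 0, 1), 0.565),
        ((0, 0, 0), 0.055),
    ],
    "MICRO": [
        ((1, 1, 1), 0.285),
        ((1, 1, 0), 0.001),
        ((1, 0, 1), 0.186),
        ((1, 0, 0), 0.007),
        ((0, 1, 1), 0.155),
        ((0, 0, 1), 0.238),
        ((0, 0, 0), 0.128),
    ],
    "PAS": [((1, 1, 1), 0.533), ((1, 1, 0), 0.008), ((1, 0, 1), 0.381), ((1, 0, 0), 0.078)],
    "PASHISTORY": [((1, 1, 1), 0.834), ((1, 1, 0), 0.001), ((1, 0, 1), 0.162), ((1, 0, 0), 0.003)],
}

# record-volume mix across sources (laboratory feeds dominate)
DEFAULT_SOURCE_WEIGHTS = {"LIMS": 0.45, "MICRO": 0.35, "PAS": 0.15, "JONAH": 0.04, "PASHISTORY": 0.01}


@dataclass(frozen=True)
class ErrorModel:
    """Rates of benign variation and error injection; all rates in [0, 1].

    Defaults: single-character typos at 0.001 per identifier field (clerical
    error is rare per keystroke), a 0.1 chance that a female patient has a
    second (married) surname appearing on some records, and no deliberate
    cross-patient collisions. ``ErrorModel.none()`` gives the error-free,
    fully-identified limit used as ground truth.
    """

    typo_rate: float = 0.001
    missingness: Optional[dict] = None  # None -> DEFAULT_MISSINGNESS; {} -> all fields present
    surname_change_rate: float = 0.1
    collision_rate: float = 0.0

    @classmethod
    def none(cls) -> "ErrorModel":
        return cls(typo_rate=0.0, missingness={}, surname_change_rate=0.0, collision_rate=0.0)


def _rng(rng_seed) -> np.random.Generator:
    return rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)


def _zipf_weights(n: int, s: float) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** s
    return w / w.sum()


def nhs_check_digit(nine_digits: str) -> Optional[int]:
    """Modulus-11 check digit for a 9-digit stem; None when the stem is unissuable."""
    total = sum(int(d) * w for d, w in zip(nine_digits, _NHS_WEIGHTS))
    check = 11 - total % 11
    if check == 11:
        return 0
    return None if check == 10 else check


def _new_nhs_number(rng: np.random.Generator, used: set) -> str:
    while True:
        stem = "".join(str(d) for d in rng.integers(0, 10, 9))
        check = nhs_check_digit(stem)
        if check is None:
            continue
        value = stem + str(check)
        if value in used or len(set(value)) == 1:
            continue
        used.add(value)
        return value


def generate_patients(
    n: int,
    rng_seed,
    config: Optional[PopulationConfig] = None,
) -> list[SyntheticPatient]:
    """Deterministically generate ``n`` patients with unique valid identifiers."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = config or PopulationConfig()
    rng = _rng(rng_seed)
    y0, y1 = cfg.birth_year_range
    used_nhs: set = set()
    used_hosp: set = set()
    lo, hi = cfg.hospital_number_range
    patients = []
    wm = _zipf_weights(len(MALE_FORENAMES), cfg.zipf_exponent)
    wf = _zipf_weights(len(FEMALE_FORENAMES), cfg.zipf_exponent)
    ws = _zipf_weights(len(SURNAMES), cfg.zipf_exponent)
    for i in range(n):
        sex = "M" if rng.random() < 0.5 else "F"
        pool, w = (MALE_FORENAMES, wm) if sex == "M" else (FEMALE_FORENAMES, wf)
        forename = pool[rng.choice(len(pool), p=w)]
        surname = SURNAMES[rng.choice(len(SURNAMES), p=ws)]
        year = int(rng.integers(y0, y1 + 1))
        month = int(rng.integers(1, 13))
        day = int(rng.integers(1, 29))  # stay within every month
        while True:
            hosp = str(int(rng.integers(lo, hi + 1)))
            if hosp not in used_hosp:
                used_hosp.add(hosp)
                break
        patients.append(
            SyntheticPatient(
                true_id=i + 1,
                forename=forename,
                surname=surname,
                sex=sex,
                birthdate=dt.date(year, month, day),
                nhs_number=_new_nhs_number(rng, used_nhs),
                hospital_number=hosp,
            )
        )
    return patients


def _typo(value: str, rng: np.random.Generator) -> str:
    pos = int(rng.integers(len(value)))
    alphabet = "0123456789" if value[pos].isdigit() else "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    repl = alphabet[int(rng.integers(len(alphabet)))]
    while repl == value[pos]:
        repl = alphabet[int(rng.integers(len(alphabet)))]
    return value[:pos] + repl + value[pos + 1:]


def generate_records(
    patients: Sequence[SyntheticPatient],
    rng_seed,
    error_model: Optional[ErrorModel] = None,
    config: Optional[PopulationConfig] = None,
    source_weights: Optional[dict] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand patients into raw multi-source records with variation and errors.

    Returns ``(records, truth)``: raw records (dates in ddmmyyyy, one row per
    record, sequential integer record_id) and the record_id -> true_id ground
    truth.
    """
    em = error_model or ErrorModel()
    cfg = config or PopulationConfig()
    rng = _rng(rng_seed)
    weights = source_weights or DEFAULT_SOURCE_WEIGHTS
    sources = list(weights)
    source_p = np.array([weights[s] for s in sources], dtype=float)
    source_p = source_p / source_p.sum()
    missingness = DEFAULT_MISSINGNESS if em.missingness is None else em.missingness
    k_lo, k_hi = cfg.records_per_patient
    all_hosp = [p.hospital_number for p in patients]

    rows = []
    truth = []
    rid = 0
    for p in patients:
        married: Optional[str] = None
        if p.sex == "F" and rng.random() < em.surname_change_rate:
            married = SURNAMES[int(rng.integers(len(SURNAMES)))]
            while married == p.surname:
                married = SURNAMES[int(rng.integers(len(SURNAMES)))]
        n_rec = int(rng.integers(k_lo, k_hi + 1))
        for _ in range(n_rec):
            rid += 1
            source = sources[int(rng.choice(len(sources), p=source_p))]
            patterns = missingness.get(source)
            if patterns:
                probs = np.array([q for _, q in patterns], dtype=float)
                pattern = patterns[int(rng.choice(len(patterns), p=probs / probs.sum()))][0]
            else:
                pattern = (1, 1, 1)
            has_hosp, has_nhs, has_namedob = pattern

            surname = p.surname
            if married is not None and rng.random() < 0.5:
                surname = married
            forename = p.forename
            nhs = p.nhs_number if has_nhs else None
            hosp = p.hospital_number if has_hosp else None
            if hosp is not None and em.collision_rate and rng.random() < em.collision_rate:
                hosp = all_hosp[int(rng.integers(len(all_hosp)))]
            if em.typo_rate:
                if nhs is not None and rng.random() < em.typo_rate:
                    nhs = _typo(nhs, rng)
                if hosp is not None and rng.random() < em.typo_rate:
                    hosp = _typo(hosp, rng)
                if has_namedob and rng.random() < em.typo_rate:
                    surname = _typo(surname, rng)
                if has_namedob and rng.random() < em.typo_rate:
                    forename = _typo(forename, rng)
            rows.append(
                {
                    "record_id": rid,
                    "source": source,
                    "surname": surname if has_namedob else None,
                    "forename": forename if has_namedob else None,
                    "sex": p.sex,
                    "birthdate": p.birthdate.strftime("%d%m%Y") if has_namedob else None,
                    "deathdate": None,
                    "nhs_number": nhs,
                    "hospital_number": hosp,
                    "hospital_code": None,
                    "clinic_code": None,
                }
            )
            truth.append({"record_id": rid, "true_id": p.true_id})
    return pd.DataFrame(rows), pd.DataFrame(truth)


def make_good_clusters(
    n_clusters: int,
    rng_seed,
    size_range: tuple[int, int] = (2, 5),
    config: Optional[PopulationConfig] = None,
) -> list[Cluster]:
    """Clean single-person clusters: 2-5 complete, internally consistent records each.

    Every record carries the patient's full identifier set, so each cluster is
    rule-good by construction (all three linkage identifiers invariant). These
    are the inputs to the collision-simulation experiments.
    """
    cfg = config or PopulationConfig()
    rng = _rng(rng_seed)
    patients = generate_patients(n_clusters, rng, cfg)
    clusters = []
    rid = 0
    for p in patients:
        n_rec = int(rng.integers(size_range[0], size_range[1] + 1))
        rows = []
        for _ in range(n_rec):
            rid += 1
            rows.append(
                {
                    "record_id": rid,
                    "source": "PAS",
                    "surname": p.surname,
                    "forename": p.forename,
                    "sex": p.sex,
                    "birthdate": p.birthdate.isoformat(),
                    "deathdate": None,
                    "nhs_number": p.nhs_number,
                    "hospital_number": p.hospital_number,
                    "suppressed": False,
                }
            )
        frame = add_composite(pd.DataFrame(rows))
        clusters.append(Cluster(p.true_id, frame))
    return clusters


def inject_hospital_collision(
    cluster_a: Cluster,
    cluster_b: Cluster,
    rng_seed,
) -> tuple[Cluster, SplitCandidate]:
    """Forge a collision: one randomly selected hospital number of ``cluster_a``
    is overwritten with the maximal hospital number of ``cluster_b``.

    Returns the merged cluster and the ground-truth corrupted instance.
    """
    rng = _rng(rng_seed)
    a = cluster_a.records.copy()
    b = cluster_b.records
    a_idx = [i for i, v in enumerate(a["hospital_number"]) if v is not None and v == v]
    b_vals = [v for v in b["hospital_number"] if v is not None and v == v]
    if not a_idx or not b_vals:
        raise ValueError("both clusters need at least one non-null hospital number")
    target = a_idx[int(rng.integers(len(a_idx)))]
    forged = max(b_vals, key=lambda v: int(str(v).split(":")[-1]))
    a.iloc[target, a.columns.get_loc("hospital_number")] = forged
    merged = pd.concat([a, b.copy()], ignore_index=True)
    truth = SplitCandidate(a.iloc[target]["record_id"], "hospital_number", forged)
    return (
        Cluster(min(cluster_a.cluster_id, cluster_b.cluster_id), merged),
        truth,
    )


@dataclass
class EvaluationResult:
    success_fraction: float
    n_trials: int
    trials: pd.DataFrame


def evaluate_resolution(
    n_trials: int,
    rng_seed,
    size_range: tuple[int, int] = (2, 5),
    config: Optional[PopulationConfig] = None,
) -> EvaluationResult:
    """End-to-end splitting-heuristic experiment.

    Per trial: take two fresh good clusters, inject a hospital-number
    collision, verify the merged records link into one cluster, run the
    splitting heuristic, and score success when the deleted instance equals
    the injected one. Returns the success fraction and a per-trial log.
    """
    if n_trials < 1:
        return EvaluationResult(float("nan"), 0, pd.DataFrame())
    rng = _rng(rng_seed)
    clusters = make_good_clusters(2 * n_trials, rng, size_range, config)
    rows = []
    successes = 0
    for t in range(n_trials):
        a, b = clusters[2 * t], clusters[2 * t + 1]
        merged, truth = inject_hospital_collision(a, b, rng)
        relinked = link(merged.records)
        assert relinked.assignment.nunique() == 1, "forged identifier must weld the pair"
        outcome = split_cluster(merged, rng_seed=rng)
        success = outcome.deleted == truth
        successes += success
        rows.append(
            {
                "trial": t,
                "truth_record_id": truth.record_id,
                "deleted_record_id": outcome.deleted.record_id if outcome.deleted else None,
                "deleted_field": outcome.deleted.field if outcome.deleted else None,
                "n_parts": outcome.n_parts,
                "quality_gain": outcome.quality_gain,
                "tie_count": outcome.tie_count,
                "success": success,
            }
        )
    return EvaluationResult(successes / n_trials, n_trials, pd.DataFrame(rows))
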