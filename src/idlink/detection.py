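"""Detection of identity collisions inside exact-match clusters.

A mistyped identifier that coincides with another person's identifier welds two
people into one cluster. Such collisions leave a signature: conflicting values
of fields that rarely vary within one person (birth year above all). Detection
proceeds in three layers:

1. ``is_complex`` — any variation at all in the linkage identifiers; only
   complex clusters can possibly contain two people.
2. ``rule_classify`` — a sensitive rule set labelling clusters *good* when two
   independent identifiers are each invariant.
3. a logistic classifier over per-field **maximal pairwise distances** within
   the cluster (Levenshtein on date-of-birth components and sex codes,
   1 - Jaro-Winkler on names and hospital numbers), scoring the odds that the
   cluster combines two people. Scores above the cutoff (default -1.5) are
   labelled *bad*.

The shipped coefficients are the published estimates; clusters containing any
female record are scored without a surname term because surnames legitimately
change on marriage. ``fit_logistic_backward_aic`` re-fits the model on a
rule-good / simulated-bad training set for users with their own data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._text import jaro_winkler_distance, levenshtein
from .linkage import DEFAULT_IDENTIFIER_FIELDS, Cluster

__all__ = [
    "ClusterFeatures",
    "LogisticModel",
    "RuleVerdict",
    "FEATURE_FIELDS",
    "PUBLISHED_INTERCEPT",
    "PUBLISHED_COEFFICIENTS",
    "DEFAULT_CUTOFF",
    "published_models",
    "is_complex",
    "rule_classify",
    "extract_features",
    "score_cluster",
    "simulate_bad_by_combination",
    "fit_logistic_backward_aic",
    "features_frame",
]

FEATURE_FIELDS = ("dob_day", "dob_month", "dob_year", "forename", "surname", "hospital_number", "sex")

# Published multivariate logistic model classifying bad clusters from good.
PUBLISHED_INTERCEPT = -3.33
PUBLISHED_COEFFICIENTS = {
    "dob_day": 0.25,
    "dob_month": 0.43,
    "dob_year": 5.12,
    "forename": 2.45,
    "hospital_number": -0.56,
    "sex": 0.80,
}
DEFAULT_CUTOFF = -1.5


@dataclass
class ClusterFeatures:
    """Per-field maximal pairwise distances over all record pairs in a cluster.

    Date-of-birth components and sex use Levenshtein on zero-padded strings
    (integers >= 0); names and hospital number use 1 - Jaro-Winkler similarity
    (reals in [0, 1]). Pairs with a null on either side are skipped; a field
    with fewer than two non-null values contributes 0, so missingness never
    mimics conflict.
    """

    dob_day: float = 0.0
    dob_month: float = 0.0
    dob_year: float = 0.0
    forename: float = 0.0
    surname: float = 0.0
    hospital_number: float = 0.0
    sex: float = 0.0
    any_female: bool = False
    is_complex: bool = False

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in FEATURE_FIELDS}


@dataclass(frozen=True)
class LogisticModel:
    """Named coefficients + intercept + cutoff for bad-cluster scoring."""

    intercept: float
    coefficients: dict[str, float]
    cutoff: float = DEFAULT_CUTOFF
    applies_when: str = "no_female"  # or "any_female"

    def score(self, features: ClusterFeatures) -> float:
        total = self.intercept
        for name, coef in self.coefficients.items():
            if not hasattr(features, name):
                raise KeyError(f"model coefficient {name!r} has no matching feature")
            total += coef * float(getattr(features, name))
        return total


@dataclass(frozen=True)
class RuleVerdict:
    label: str  # "good" | "uncertain"
    matched_rule: Optional[str] = None


def published_models(cutoff: float = DEFAULT_CUTOFF) -> tuple[LogisticModel, LogisticModel]:
    """The published (any_female, no_female) model pair.

    One coefficient set serves both; the any-female model carries no surname
    term (marriage-driven surname change would swamp it), and no separate
    surname coefficient was published for the no-female model either.
    """
    coefs = dict(PUBLISHED_COEFFICIENTS)
    return (
        LogisticModel(PUBLISHED_INTERCEPT, coefs, cutoff, applies_when="any_female"),
        LogisticModel(PUBLISHED_INTERCEPT, dict(coefs), cutoff, applies_when="no_female"),
    )


def is_complex(cluster: Cluster, identifier_fields: Sequence[str] = DEFAULT_IDENTIFIER_FIELDS) -> bool:
    """True iff any linkage identifier takes more than one distinct non-null value."""
    return any(len(cluster.values(f)) > 1 for f in identifier_fields)


_RULE_PAIRS = (
    ("one_nhs_one_hospital", ("nhs_number", "hospital_number")),
    ("one_nhs_one_composite", ("nhs_number", "composite_id")),
    ("one_hospital_one_composite", ("hospital_number", "composite_id")),
)


def rule_classify(cluster: Cluster) -> RuleVerdict:
    """Sensitive single-person test: good when two independent identifiers are
    each present and invariant (exactly one distinct non-null value)."""
    for name, (fa, fb) in _RULE_PAIRS:
        if len(cluster.values(fa)) == 1 and len(cluster.values(fb)) == 1:
            return RuleVerdict("good", name)
    return RuleVerdict("uncertain")


def _dob_parts(birthdate) -> Optional[tuple[str, str, str]]:
    if birthdate is None or birthdate != birthdate:
        return None
    iso = str(birthdate)
    y, m, d = iso.split("-")
    return d.zfill(2), m.zfill(2), y.zfill(4)


def _max_pairwise(values: list, dist) -> float:
    nonnull = [v for v in values if v is not None and v == v and v != ""]
    if len(nonnull) < 2:
        return 0.0
    return max(dist(str(a), str(b)) for a, b in combinations(nonnull, 2))


def extract_features(cluster: Cluster) -> ClusterFeatures:
    """Maximal pairwise distances per field across all record pairs of a cluster."""
    rec = cluster.records
    dobs = [_dob_parts(b) for b in rec["birthdate"]]
    days = [p[0] if p else None for p in dobs]
    months = [p[1] if p else None for p in dobs]
    years = [p[2] if p else None for p in dobs]
    sexes = [s for s in rec["sex"]]
    lev = lambda a, b: float(levenshtein(a, b))
    return ClusterFeatures(
        dob_day=_max_pairwise(days, lev),
        dob_month=_max_pairwise(months, lev),
        dob_year=_max_pairwise(years, lev),
        forename=_max_pairwise(list(rec["forename"]), jaro_winkler_distance),
        surname=_max_pairwise(list(rec["surname"]), jaro_winkler_distance),
        hospital_number=_max_pairwise(list(rec["hospital_number"]), jaro_winkler_distance),
        sex=_max_pairwise(sexes, lev),
        any_female=any(s == "F" for s in sexes),
        is_complex=is_complex(cluster),
    )


def score_cluster(
    features: ClusterFeatures,
    models: Optional[tuple[LogisticModel, LogisticModel]] = None,
) -> tuple[float, str]:
    """Score a cluster with the model matching its sex composition.

    Returns ``(score, label)``; the label is ``"bad"`` iff the score strictly
    exceeds the model's cutoff.
    """
    any_female_model, no_female_model = models if models is not None else published_models()
    model = any_female_model if features.any_female else no_female_model
    score = model.score(features)
    return score, ("bad" if score > model.cutoff else "good")


def features_frame(
    clusters: Sequence[Cluster],
    models: Optional[tuple[LogisticModel, LogisticModel]] = None,
) -> pd.DataFrame:
    """Feature + score table for a list of clusters (one row per cluster)."""
    rows = []
    for c in clusters:
        feats = extract_features(c)
        score, label = score_cluster(feats, models)
        row = {"cluster_id": c.cluster_id, "n_records": len(c)}
        row.update(feats.as_dict())
        row.update(
            {
                "any_female": feats.any_female,
                "is_complex": feats.is_complex,
                "score": score,
                "label": label,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_bad_by_combination(
    good_clusters: Sequence[Cluster],
    rng_seed,
) -> list[Cluster]:
    """Simulate collision clusters by randomly pairing distinct good clusters.

    Each output cluster is the union of one disjoint random pair (an odd
    leftover cluster is dropped); the pairing is deterministic for a fixed
    seed.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    if len(good_clusters) < 2:
        return []
    order = rng.permutation(len(good_clusters))
    out = []
    for i in range(0, len(order) - 1, 2):
        a, b = good_clusters[order[i]], good_clusters[order[i + 1]]
        merged = pd.concat([a.records, b.records], ignore_index=True)
        out.append(Cluster(min(a.cluster_id, b.cluster_id), merged))
    return out


@dataclass
class LogisticFit:
    """A fitted model plus the diagnostics a re-fitting user needs."""

    model: LogisticModel
    stderr: dict[str, float]
    aic: float
    eliminated: tuple[str, ...]
    converged: bool


def _fit_logit(X: pd.DataFrame, y: np.ndarray, clip: float):
    import statsmodels.api as sm

    design = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(disp=0, method="newton", maxiter=100)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            res = sm.Logit(y, design).fit(disp=0, method="bfgs", maxiter=500)
            converged = False
    params = res.params.copy()
    if np.abs(params).max() > clip:
        warnings.warn(
            "possible complete separation: coefficients clipped to "
            f"+/-{clip}", RuntimeWarning, stacklevel=3,
        )
        params = params.clip(-clip, clip)
        converged = False
    return res, params, converged


def fit_logistic_backward_aic(
    features: pd.DataFrame,
    labels,
    included_fields: Optional[Sequence[str]] = None,
    cutoff: float = DEFAULT_CUTOFF,
    applies_when: str = "no_female",
    clip: float = 30.0,
) -> LogisticFit:
    """Maximum-likelihood logistic fit with backward elimination on AIC.

    Starting from ``included_fields`` (default: every feature column present),
    repeatedly drops the term whose removal most reduces AIC until no removal
    reduces it. Labels are 1 = bad, 0 = good (strings "bad"/"good" accepted).
    Complete separation is reported with a warning and coefficient clipping at
    ``clip`` rather than an error.
    """
    y = np.asarray([1 if (l in (1, True, "bad")) else 0 for l in labels], dtype=float)
    if y.min() == y.max():
        raise ValueError("both labels must be present to fit the classifier")
    cols = list(included_fields) if included_fields is not None else [
        c for c in FEATURE_FIELDS if c in features.columns
    ]
    if len(y) <= len(cols) + 1:
        raise ValueError("need more observations than model terms")
    X = features[cols].astype(float)

    eliminated: list[str] = []
    res, params, converged = _fit_logit(X[cols], y, clip)
    best_aic = res.aic
    while cols:
        trial = []
        for c in cols:
            reduced = [k for k in cols if k != c]
            r, p, conv = _fit_logit(X[reduced], y, clip)
            trial.append((r.aic, c, r, p, conv))
        trial.sort(key=lambda t: t[0])
        if trial[0][0] < best_aic - 1e-9:
            best_aic, drop, res, params, converged = trial[0]
            cols = [k for k in cols if k != drop]
            eliminated.append(drop)
        else:
            break

    coefs = {c: float(params[c]) for c in cols}
    model = LogisticModel(float(params["const"]), coefs, cutoff, applies_when)
    stderr = {k: float(v) for k, v in res.bse.items()}
    return LogisticFit(model, stderr, float(best_aic), tuple(eliminated), converged)
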