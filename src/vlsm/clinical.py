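"""Clinical covariates, seizure descriptors, and cohort statistics.

Seizure frequency in the 3 months before surgery is graded on an ordinal
0-4 scale (0 no history, 1 only one or two seizures ever, 2 more than
once per month, 3 more than once per week, 4 more than once per day);
scores >= 2 define the "frequent" group.  Surgical seizure outcome uses
the Engel scale dichotomized as Class I (seizure free) versus II-IV
(uncontrolled).  Group comparisons follow the usual clinical-cohort
toolkit: Pearson chi-square (no continuity correction) for categorical
variables, Mann-Whitney U for continuous ones, and multivariate logistic
regression over the univariately significant (p < 0.05) variables.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "SeizureType",
    "FrequencyCategory",
    "Resection",
    "Pathology",
    "Hemisphere",
    "Lobe",
    "EngelClass",
    "ClinicalRecord",
    "ContingencyResult",
    "RankTestResult",
    "LogisticResult",
    "DegenerateTableError",
    "score_frequency",
    "is_frequent",
    "dichotomize_engel",
    "chi_square_test",
    "mann_whitney",
    "logistic_regression",
    "cohort_summary",
    "outcome_analysis",
    "select_multivariate",
    "format_p",
    "records_to_dataframe",
    "dataframe_to_records",
    "CSV_COLUMNS",
]


class SeizureType(str, enum.Enum):
    FOCAL_AWARE = "focal_aware"
    FOCAL_IMPAIRED_AWARENESS = "focal_impaired_awareness"
    FOCAL_TO_BILATERAL_TONIC_CLONIC = "focal_to_bilateral_tonic_clonic"
    NONE = "none"


class FrequencyCategory(str, enum.Enum):
    NONE = "none"
    RARE_1_2 = "rare_1_2"
    MONTHLY = "monthly"
    WEEKLY = "weekly"
    DAILY = "daily"


class Resection(str, enum.Enum):
    GROSS_TOTAL = "gross_total"
    PARTIAL = "partial"


class Pathology(str, enum.Enum):
    OLIGODENDROGLIOMA = "oligodendroglioma"
    ASTROCYTOMA = "astrocytoma"
    OLIGOASTROCYTOMA = "oligoastrocytoma"


class Hemisphere(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class Lobe(str, enum.Enum):
    FRONTAL = "frontal"
    TEMPORAL = "temporal"
    INSULA = "insula"
    PARIETAL = "parietal"
    OCCIPITAL = "occipital"


class EngelClass(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


_FREQUENCY_SCORES: dict[FrequencyCategory, int] = {
    FrequencyCategory.NONE: 0,
    FrequencyCategory.RARE_1_2: 1,
    FrequencyCategory.MONTHLY: 2,
    FrequencyCategory.WEEKLY: 3,
    FrequencyCategory.DAILY: 4,
}

#: Minimum ordinal score counted as a frequent (>= once/month) seizure.
FREQUENT_SCORE_CUTOFF = 2


@dataclass
class ClinicalRecord:
    """One subject's covariates, seizure descriptors and outcome.

    Sex is coded male = 1, female = 0 (the coding is a nuisance column in
    the lesion-mapping model, so the choice cannot affect the frequency
    statistic).
    """

    subject_id: str
    age: float
    sex: int
    tumor_volume: float
    frequency_category: FrequencyCategory
    seizure_type: SeizureType
    asm_use: bool
    resection: Resection
    pathology: Pathology
    hemisphere: Hemisphere
    lobes: frozenset[Lobe] = field(default_factory=frozenset)
    engel_class: EngelClass | None = None

    def __post_init__(self) -> None:
        self.frequency_category = FrequencyCategory(self.frequency_category)
        self.seizure_type = SeizureType(self.seizure_type)
        self.resection = Resection(self.resection)
        self.pathology = Pathology(self.pathology)
        self.hemisphere = Hemisphere(self.hemisphere)
        self.lobes = frozenset(Lobe(l) for l in self.lobes)
        if self.engel_class is not None:
            self.engel_class = EngelClass(self.engel_class)
        if self.age <= 0:
            raise ValueError(f"{self.subject_id}: age must be positive")
        if self.tumor_volume < 0:
            raise ValueError(f"{self.subject_id}: tumor volume must be >= 0")
        if int(self.sex) not in (0, 1):
            raise ValueError(f"{self.subject_id}: sex must be 0 (female) or 1 (male)")
        self.sex = int(self.sex)
        no_freq = self.frequency_category == FrequencyCategory.NONE
        no_type = self.seizure_type == SeizureType.NONE
        if no_freq != no_type:
            raise ValueError(
                f"{self.subject_id}: seizure type and frequency category disagree "
                f"({self.seizure_type.value} vs {self.frequency_category.value})"
            )

    @property
    def has_seizure(self) -> bool:
        return self.frequency_category != FrequencyCategory.NONE

    @property
    def frequency_score(self) -> int:
        return score_frequency(self.frequency_category)


@dataclass
class ContingencyResult:
    statistic: float
    df: int
    p_value: float
    table: np.ndarray


@dataclass
class RankTestResult:
    u_statistic: float
    p_value: float
    n1: int
    n2: int


@dataclass
class LogisticResult:
    params: pd.Series
    std_errors: pd.Series
    odds_ratios: pd.Series
    conf_int: pd.DataFrame  # 95% CI on the odds-ratio scale
    p_values: pd.Series
    converged: bool
    separation: bool = False


class DegenerateTableError(ValueError):
    """Contingency table has a zero margin; the test is undefined."""


def score_frequency(category: FrequencyCategory | str) -> int:
    """Map a preoperative frequency category to the ordinal 0-4 score."""
    try:
        cat = FrequencyCategory(category)
    except ValueError as exc:
        raise ValueError(f"unknown frequency category: {category!r}") from exc
    return _FREQUENCY_SCORES[cat]


def is_frequent(score: int) -> bool:
    """True iff the ordinal score means >= one seizure per month (score >= 2)."""
    if score not in (0, 1, 2, 3, 4):
        raise ValueError(f"frequency score must be in 0..4, got {score!r}")
    return score >= FREQUENT_SCORE_CUTOFF


def dichotomize_engel(engel: EngelClass | str | None) -> str | None:
    """Engel Class I -> 'seizure_free'; II-IV -> 'uncontrolled'.

    A missing class returns None: the subject is excluded from outcome
    analyses rather than raising.
    """
    if engel is None or (isinstance(engel, float) and np.isnan(engel)) or engel == "":
        return None
    cls = EngelClass(engel)
    return "seizure_free" if cls == EngelClass.I else "uncontrolled"


def chi_square_test(table: Sequence[Sequence[int]] | np.ndarray) -> ContingencyResult:
    """Pearson chi-square on an r x c table, no continuity correction."""
    obs = np.asarray(table)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError(f"need at least a 2x2 table, got shape {obs.shape}")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("observed counts must be non-negative integers")
    obs = np.round(obs).astype(np.int64)
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise DegenerateTableError("table has a zero row or column margin")
    res = stats.chi2_contingency(obs, correction=False)
    return ContingencyResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
        table=obs,
    )


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float]) -> RankTestResult:
    """Two-sided Mann-Whitney U with midranks for ties.

    The p-value uses the normal approximation with the tie-corrected
    variance (no continuity correction); the ordinal frequency scores this
    test is applied to are heavily tied, where exact enumeration is not
    defined without extra convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return RankTestResult(
        u_statistic=float(res.statistic),
        p_value=min(1.0, float(res.pvalue)),
        n1=a.size,
        n2=b.size,
    )


def logistic_regression(
    outcome: Sequence[int] | np.ndarray,
    predictors: pd.DataFrame | np.ndarray,
    add_intercept: bool = True,
) -> LogisticResult:
    """Maximum-likelihood logistic fit with Wald p-values and 95% OR CIs.

    Non-convergence or (quasi-)perfect separation is flagged; in that case
    the coefficient tables are withheld (empty) rather than reported.
    """
    y = np.asarray(outcome, dtype=float)
    X = pd.DataFrame(predictors).copy()
    X.columns = [str(c) for c in X.columns]
    if y.size <= X.shape[1] + 1:
        raise ValueError("need more subjects than predictors")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant")
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")

    separation = False
    converged = False
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
        warnings.simplefilter("ignore", category=RuntimeWarning)
        try:
            model = sm.Logit(y, X.astype(float))
            result = model.fit(disp=0, maxiter=100)
            converged = bool(result.mle_retvals.get("converged", False))
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning,
                np.linalg.LinAlgError):
            separation = True
    if result is not None and not separation:
        # huge coefficients with huge SEs are the numeric signature of separation
        if np.any(np.abs(result.params) > 15):
            separation = True
    if separation or not converged or result is None:
        empty = pd.Series(dtype=float)
        return LogisticResult(
            params=empty, std_errors=empty, odds_ratios=empty,
            conf_int=pd.DataFrame(), p_values=empty,
            converged=converged and not separation, separation=separation,
        )
    ci = np.exp(result.conf_int(alpha=0.05))
    ci.columns = ["or_ci_low", "or_ci_high"]
    return LogisticResult(
        params=result.params,
        std_errors=result.bse,
        odds_ratios=np.exp(result.params),
        conf_int=ci,
        p_values=result.pvalues,
        converged=True,
    )


def format_p(p: float) -> str:
    """Render a p-value the way clinical tables print it."""
    if p < 0.001:
        return "<0.001"
    return f"{p:.3f}"


def select_multivariate(univariate_p: dict[str, float], cutoff: float = 0.05) -> list[str]:
    """Variables entering the multivariate model: univariate p strictly < cutoff."""
    return [k for k, v in univariate_p.items() if v < cutoff]


# ---------------------------------------------------------------------------
# Cohort summary (Table-1-style report)
# ---------------------------------------------------------------------------

def _binary_row(name, flags_a, flags_b):
    """Counts and chi-square p for a yes/no variable across two groups."""
    a, b = np.asarray(flags_a, bool), np.asarray(flags_b, bool)
    table = np.array([[a.sum(), (~a).sum()], [b.sum(), (~b).sum()]]).T
    try:
        res = chi_square_test(table)
        p, note = res.p_value, ""
    except DegenerateTableError:
        p, note = np.nan, "degenerate"
    return {
        "variable": name, "group1_yes": int(a.sum()), "group1_n": a.size,
        "group2_yes": int(b.sum()), "group2_n": b.size,
        "p_value": p, "test": "chi_square", "note": note,
    }


def _continuous_row(name, vals_a, vals_b):
    res = mann_whitney(vals_a, vals_b)
    return {
        "variable": name,
        "group1_median": float(np.median(vals_a)), "group1_n": len(vals_a),
        "group2_median": float(np.median(vals_b)), "group2_n": len(vals_b),
        "p_value": res.p_value, "test": "mann_whitney", "note": "",
    }


def cohort_summary(records: Iterable[ClinicalRecord], grouping: str) -> pd.DataFrame:
    """Grouped Table-1-style counts and per-variable tests.

    grouping='frequent_vs_nonfrequent' compares frequent (score >= 2)
    against non-frequent (score 1) seizure patients; patients without a
    seizure history are excluded.  grouping='seizure_vs_none' compares
    any-seizure against no-seizure.  Age and tumor volume use
    Mann-Whitney; everything else chi-square.  Age is additionally
    dichotomized at 40 years, matching common reporting.
    """
    recs = list(records)
    if grouping == "frequent_vs_nonfrequent":
        recs = [r for r in recs if r.has_seizure]
        g1 = [r for r in recs if is_frequent(r.frequency_score)]
        g2 = [r for r in recs if not is_frequent(r.frequency_score)]
        labels = ("frequent", "non_frequent")
    elif grouping == "seizure_vs_none":
        g1 = [r for r in recs if r.has_seizure]
        g2 = [r for r in recs if not r.has_seizure]
        labels = ("seizure", "no_seizure")
    else:
        raise ValueError(f"unknown grouping: {grouping!r}")
    if not g1 or not g2:
        raise ValueError(f"empty comparison group for grouping {grouping!r}")

    rows = []
    rows.append(_continuous_row("age", [r.age for r in g1], [r.age for r in g2]))
    rows.append(_binary_row("age_gt_40", [r.age > 40 for r in g1], [r.age > 40 for r in g2]))
    rows.append(_binary_row("male", [r.sex == 1 for r in g1], [r.sex == 1 for r in g2]))
    rows.append(_binary_row(
        "left_hemisphere",
        [r.hemisphere == Hemisphere.LEFT for r in g1],
        [r.hemisphere == Hemisphere.LEFT for r in g2],
    ))
    for lobe in Lobe:
        rows.append(_binary_row(
            f"lobe_{lobe.value}",
            [lobe in r.lobes for r in g1],
            [lobe in r.lobes for r in g2],
        ))
    rows.append(_continuous_row(
        "tumor_volume_cm3", [r.tumor_volume for r in g1], [r.tumor_volume for r in g2]
    ))
    if grouping == "frequent_vs_nonfrequent":
        for stype in (SeizureType.FOCAL_AWARE,
                      SeizureType.FOCAL_IMPAIRED_AWARENESS,
                      SeizureType.FOCAL_TO_BILATERAL_TONIC_CLONIC):
            rows.append(_binary_row(
                f"type_{stype.value}",
                [r.seizure_type == stype for r in g1],
                [r.seizure_type == stype for r in g2],
            ))
        # pairwise reading: focal aware vs focal-to-bilateral only
        pair1 = [r for r in g1 if r.seizure_type in
                 (SeizureType.FOCAL_AWARE, SeizureType.FOCAL_TO_BILATERAL_TONIC_CLONIC)]
        pair2 = [r for r in g2 if r.seizure_type in
                 (SeizureType.FOCAL_AWARE, SeizureType.FOCAL_TO_BILATERAL_TONIC_CLONIC)]
        if pair1 and pair2:
            rows.append(_binary_row(
                "type_focal_aware_vs_bilateral",
                [r.seizure_type == SeizureType.FOCAL_AWARE for r in pair1],
                [r.seizure_type == SeizureType.FOCAL_AWARE for r in pair2],
            ))
    rows.append(_binary_row("asm_use", [r.asm_use for r in g1], [r.asm_use for r in g2]))
    rows.append(_binary_row(
        "gross_total_resection",
        [r.resection == Resection.GROSS_TOTAL for r in g1],
        [r.resection == Resection.GROSS_TOTAL for r in g2],
    ))
    for path in Pathology:
        rows.append(_binary_row(
            f"pathology_{path.value}",
            [r.pathology == path for r in g1],
            [r.pathology == path for r in g2],
        ))
    df = pd.DataFrame(rows)
    df.attrs["groups"] = labels
    df.attrs["group_sizes"] = (len(g1), len(g2))
    df["p_formatted"] = [format_p(p) if np.isfinite(p) else "NA" for p in df["p_value"]]
    return df


# ---------------------------------------------------------------------------
# Seizure outcome (Engel) analysis
# ---------------------------------------------------------------------------

def outcome_analysis(records: Iterable[ClinicalRecord]) -> dict:
    """Univariate screen + multivariate logistic for 6-month seizure outcome.

    Subjects without an Engel class are dropped.  The outcome is the
    dichotomized Engel scale (uncontrolled = 1).  Binary candidate
    predictors are screened by chi-square; those with p strictly below
    0.05 enter a multivariate logistic regression.
    """
    kept = [r for r in records if r.has_seizure and dichotomize_engel(r.engel_class)]
    if len(kept) < 10:
        raise ValueError("too few subjects with a recorded Engel class")
    y = np.array([dichotomize_engel(r.engel_class) == "uncontrolled" for r in kept], int)
    predictors = {
        "frequent_seizures": [is_frequent(r.frequency_score) for r in kept],
        "focal_aware": [r.seizure_type == SeizureType.FOCAL_AWARE for r in kept],
        "oligodendroglioma": [r.pathology == Pathology.OLIGODENDROGLIOMA for r in kept],
        "partial_resection": [r.resection == Resection.PARTIAL for r in kept],
        "left_hemisphere": [r.hemisphere == Hemisphere.LEFT for r in kept],
        "male": [r.sex == 1 for r in kept],
        "age_gt_40": [r.age > 40 for r in kept],
    }
    univariate: dict[str, float] = {}
    for name, flags in predictors.items():
        x = np.asarray(flags, bool)
        table = np.array([[int((x & (y == 1)).sum()), int((x & (y == 0)).sum())],
                          [int((~x & (y == 1)).sum()), int((~x & (y == 0)).sum())]])
        try:
            univariate[name] = chi_square_test(table).p_value
        except DegenerateTableError:
            univariate[name] = np.nan
    entered = select_multivariate({k: v for k, v in univariate.items() if np.isfinite(v)})
    multivariate = None
    if entered:
        X = pd.DataFrame({k: np.asarray(predictors[k], float) for k in entered})
        multivariate = logistic_regression(y, X)
    return {
        "n_subjects": len(kept),
        "n_uncontrolled": int(y.sum()),
        "univariate_p": univariate,
        "entered": entered,
        "multivariate": multivariate,
    }


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------

CSV_COLUMNS = [
    "subject_id", "age", "sex", "tumor_volume", "has_seizure", "seizure_type",
    "frequency_category", "asm_use", "resection", "pathology", "hemisphere",
    "lobes", "engel_class",
]


def records_to_dataframe(records: Iterable[ClinicalRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "subject_id": r.subject_id,
            "age": r.age,
            "sex": r.sex,
            "tumor_volume": r.tumor_volume,
            "has_seizure": int(r.has_seizure),
            "seizure_type": r.seizure_type.value,
            "frequency_category": r.frequency_category.value,
            "asm_use": int(r.asm_use),
            "resection": r.resection.value,
            "pathology": r.pathology.value,
            "hemisphere": r.hemisphere.value,
            "lobes": ";".join(sorted(l.value for l in r.lobes)),
            "engel_class": r.engel_class.value if r.engel_class else "",
        })
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def dataframe_to_records(df: pd.DataFrame) -> list[ClinicalRecord]:
    missing = [c for c in CSV_COLUMNS if c not in df.columns and c != "has_seizure"]
    if missing:
        raise ValueError(f"clinical table is missing required columns: {missing}")
    records = []
    for _, row in df.iterrows():
        lobes = str(row.get("lobes", "") or "")
        engel = row.get("engel_class", "")
        engel = None if (pd.isna(engel) or engel == "") else str(engel)
        records.append(ClinicalRecord(
            subject_id=str(row["subject_id"]),
            age=float(row["age"]),
            sex=int(row["sex"]),
            tumor_volume=float(row["tumor_volume"]),
            frequency_category=str(row["frequency_category"]),
            seizure_type=str(row["seizure_type"]),
            asm_use=bool(int(row["asm_use"])),
            resection=str(row["resection"]),
            pathology=str(row["pathology"]),
            hemisphere=str(row["hemisphere"]),
            lobes=frozenset(s for s in lobes.split(";") if s),
            engel_class=engel,
        ))
    return records
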