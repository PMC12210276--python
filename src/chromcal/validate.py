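"""Validation of a differential-region set.

Two bespoke checks: (i) a label-permutation test — diagnosis labels are
permuted at the subject level (both of a subject's libraries flip together),
the full differential pipeline is rerun per permutation, and the observed
number of FDR-significant regions is compared to the permuted counts; (ii) a
classifier-based check — six standard classifiers predict case/control status
by repeated stratified 5-fold cross-validation on the differential-region
features versus equally sized random region sets.

The permutation report carries both the conventional add-one empirical p
(>= rule) and a tie-randomized empirical p, which is exactly uniform under
exchangeability even when many permuted counts tie (the usual situation at a
stringent FDR on null data); calibration checks should use the latter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold, cross_val_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .datamodel import SampleSheet, ValidationError
from .differential import DifferentialSettings, differential_analysis

__all__ = [
    "PermutationReport",
    "MLReport",
    "permutation_validation",
    "pvalue_uniformity",
    "ml_discrimination",
    "default_classifiers",
]


@dataclass
class PermutationReport:
    observed_n_significant: int
    permuted_n_significant: list[int]
    empirical_p: float
    empirical_p_randomized: float
    uniformity_statistic: float
    observed_pvalues: np.ndarray
    seed: int


def _permute_subject_diagnosis(
    sheet: SampleSheet, rng: np.random.Generator
) -> SampleSheet:
    """Shuffle diagnosis labels across subjects (never the identity permutation
    when an alternative exists); every sample of a subject flips together."""
    df = sheet.data.copy()
    subjects = df["subject_id"].drop_duplicates().tolist()
    dx = df.drop_duplicates("subject_id").set_index("subject_id")["diagnosis"]
    orig = dx.loc[subjects].to_numpy()
    if len(set(orig)) < 2:
        raise ValidationError("need both diagnosis labels to permute")
    for _ in range(1000):
        perm = rng.permutation(orig)
        if not np.array_equal(perm, orig):
            break
    mapping = dict(zip(subjects, perm))
    df["diagnosis"] = df["subject_id"].map(mapping)
    return SampleSheet(df.reset_index(drop=True))


def permutation_validation(
    normalized: pd.DataFrame,
    sheet: SampleSheet,
    cell_type: str,
    n_perm: int = 100,
    fdr: float = 0.05,
    seed: int = 0,
    settings: DifferentialSettings | None = None,
) -> PermutationReport:
    """Rerun the differential pipeline on n_perm subject-level permutations of
    case/control status with identical settings; report observed vs permuted
    counts of regions significant at the given FDR."""
    sheet = sheet.aligned_to(normalized.columns)
    n_subjects = sheet.data["subject_id"].nunique()
    n_cases = (
        sheet.data.drop_duplicates("subject_id")["diagnosis"] == "case"
    ).sum()
    n_distinct = math.comb(n_subjects, int(n_cases))
    if n_distinct < n_perm:
        warnings.warn(
            f"only {n_distinct} distinct label assignments exist; permutations "
            "are sampled with replacement"
        )
    rng = np.random.default_rng(seed)

    observed_table = differential_analysis(normalized, sheet, cell_type, settings)
    observed_n = int((observed_table["q_value"] < fdr).sum())

    permuted_counts = []
    for _ in range(n_perm):
        # a permutation can make sex collinear with diagnosis in tiny cohorts;
        # redraw (the null distribution stays exchangeable over full-rank
        # labelings, of which the observed one is a member)
        for _attempt in range(100):
            perm_sheet = _permute_subject_diagnosis(sheet, rng)
            try:
                table = differential_analysis(
                    normalized, perm_sheet, cell_type, settings
                )
                break
            except ValidationError:
                continue
        else:
            raise ValidationError(
                "could not find a full-rank label permutation in 100 draws"
            )
        permuted_counts.append(int((table["q_value"] < fdr).sum()))

    perm = np.array(permuted_counts)
    emp_p = (1 + int((perm >= observed_n).sum())) / (n_perm + 1)
    # randomized tie-break: exactly uniform under exchangeability
    v = rng.random()
    emp_p_rand = (
        int((perm > observed_n).sum()) + v * (1 + int((perm == observed_n).sum()))
    ) / (n_perm + 1)
    ks = pvalue_uniformity(observed_table["p_value"].to_numpy())[0]
    return PermutationReport(
        observed_n_significant=observed_n,
        permuted_n_significant=permuted_counts,
        empirical_p=emp_p,
        empirical_p_randomized=emp_p_rand,
        uniformity_statistic=ks,
        observed_pvalues=observed_table["p_value"].to_numpy(),
        seed=seed,
    )


def pvalue_uniformity(pvalues) -> tuple[float, pd.DataFrame]:
    """One-sample KS distance of p-values against Uniform(0, 1), plus an
    expected-vs-observed quantile table."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    ks = stats.kstest(p, "uniform").statistic
    probs = np.linspace(0.05, 0.95, 19)
    qq = pd.DataFrame(
        {"expected": probs, "observed": np.quantile(p, probs)}
    )
    return float(ks), qq


def default_classifiers(seed: int = 0, n_estimators: int = 100) -> dict:
    """The six classifier families of the validation protocol: naive Bayes,
    random forest, nearest neighbor, logistic regression, linear-kernel SVM
    and polynomial-kernel SVM."""
    return {
        "naive_bayes": GaussianNB(),
        "random_forest": RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed
        ),
        "knn": make_pipeline(StandardScaler(), KNeighborsClassifier()),
        "logistic": make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000)
        ),
        "svm_linear": make_pipeline(StandardScaler(), SVC(kernel="linear")),
        "svm_poly": make_pipeline(StandardScaler(), SVC(kernel="poly")),
    }


@dataclass
class MLReport:
    table: pd.DataFrame  # classifier x (diff_mean, diff_sd, random_mean, delta)
    leakage_warning: str = field(
        default="differential regions were selected on the full data set; "
        "cross-validated accuracies on them are optimistically biased "
        "(feature selection happened outside the CV loop)"
    )


def ml_discrimination(
    normalized: pd.DataFrame,
    labels: pd.Series,
    differential_regions,
    n_random_draws: int = 10,
    cv_folds: int = 5,
    cv_repeats: int = 10,
    classifiers: dict | None = None,
    seed: int = 0,
) -> MLReport:
    """Repeated stratified k-fold CV accuracy of each classifier on the
    differential-region features versus ``n_random_draws`` equally sized
    random region sets; delta = differential score - mean random score."""
    differential_regions = list(differential_regions)
    if not differential_regions:
        raise ValidationError("empty differential region set")
    labels = labels.reindex(normalized.columns)
    y = labels.to_numpy()
    counts = pd.Series(y).value_counts()
    if (counts < cv_folds).any():
        raise ValidationError(
            f"every class needs >= {cv_folds} samples for {cv_folds}-fold CV"
        )
    classifiers = classifiers or default_classifiers(seed=seed)
    rng = np.random.default_rng(seed)
    all_regions = list(normalized.index)

    cv = RepeatedStratifiedKFold(
        n_splits=cv_folds, n_repeats=cv_repeats, random_state=seed
    )
    X_diff = normalized.loc[differential_regions].to_numpy().T

    random_sets = [
        list(rng.choice(all_regions, size=len(differential_regions), replace=False))
        for _ in range(n_random_draws)
    ]

    rows = []
    for name, clf in classifiers.items():
        diff_scores = cross_val_score(clf, X_diff, y, cv=cv, scoring="accuracy")
        rand_means = []
        for rset in random_sets:
            Xr = normalized.loc[rset].to_numpy().T
            rand_means.append(
                cross_val_score(clf, Xr, y, cv=cv, scoring="accuracy").mean()
            )
        rows.append(
            {
                "classifier": name,
                "diff_mean": float(diff_scores.mean()),
                "diff_sd": float(diff_scores.std(ddof=1)),
                "random_mean": float(np.mean(rand_means)),
                "delta": float(diff_scores.mean() - np.mean(rand_means)),
            }
        )
    return MLReport(table=pd.DataFrame(rows).set_index("classifier"))
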