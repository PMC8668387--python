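"""Group comparison and diagnostic-performance statistics for biomarker cohorts.

Per parameter: two-sided Wilcoxon rank-sum for continuous values (Pearson
chi-squared on the 2x2 table for the binary SVP), ROC analysis with AUC from
the rank statistic, sensitivity/specificity at the Youden-J cutoff, and a
seeded stratified-bootstrap percentile CI for the AUC. Biomarker panels are
combined by maximum-likelihood logistic regression and the in-sample
predicted probabilities are scored with the same ROC machinery (apparent
performance; no cross-validation is claimed). Percentages are reported on the
0-100 scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve

from .errors import InputError

__all__ = [
    "DiagnosticResult",
    "PanelResult",
    "compare_groups",
    "roc_analysis",
    "logistic_panel",
    "evaluate_cohort",
    "PANELS",
]

CONTINUOUS_PARAMETERS = [
    "vdr", "mvfd",
    "md_mean", "md_median", "md_max", "md_min",
    "ba_mean", "ba_median", "ba_max", "ba_min",
]

# the "new biomarker" panel: mvFD, SVP, BA, MD
PANELS: dict[str, list[str]] = {
    "new": ["mvfd", "svp", "ba_mean", "md_mean"],
}


@dataclass(frozen=True)
class DiagnosticResult:
    parameter: str
    p_value: float
    auc_pct: float
    sensitivity_pct: float
    specificity_pct: float
    ci_pct: tuple[float, float]
    cutoff: float
    higher_in_malignant: bool


@dataclass(frozen=True)
class PanelResult:
    panel: str
    features: tuple[str, ...]
    auc_pct: float
    sensitivity_pct: float
    specificity_pct: float
    ci_pct: tuple[float, float]
    penalized: bool = False


def compare_groups(values_benign, values_malignant, binary: bool = False) -> float:
    """Two-sided group-difference p-value.

    Continuous data: Wilcoxon rank-sum (Mann-Whitney U with tie correction,
    asymptotic, two-sided). Binary data: Pearson chi-squared on the 2x2
    contingency table, without continuity correction.
    """
    a = np.asarray(values_benign, dtype=float)
    b = np.asarray(values_malignant, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InputError("need at least 2 observations per group")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        warnings.warn("all values tied across groups; p = 1", stacklevel=2)
        return 1.0
    if binary:
        table = np.array(
            [
                [(a == 0).sum(), (a == 1).sum()],
                [(b == 0).sum(), (b == 1).sum()],
            ]
        )
        if (table.sum(axis=0) == 0).any():
            warnings.warn("degenerate 2x2 table; p = 1", stacklevel=2)
            return 1.0
        _, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(p)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def _rank_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the rank statistic (equals the concordant-pair fraction)."""
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    ranks = stats.rankdata(values)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_analysis(
    values,
    labels,
    n_boot: int = 2000,
    seed: int = 0,
    parameter: str = "",
) -> DiagnosticResult:
    """ROC analysis of one marker against binary labels (1 = positive/malignant).

    Orientation is auto-chosen so AUC >= 0.5 (markers lower in the positive
    class are negated before thresholding); the cutoff maximizes Youden's J;
    the 95% CI is a stratified bootstrap percentile interval, seeded.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise InputError("both classes must be present for ROC analysis")
    if v.shape != y.shape:
        raise InputError("values and labels must have the same length")

    auc = _rank_auc(v, y)
    higher_in_malignant = auc >= 0.5
    scores = v if higher_in_malignant else -v
    if not higher_in_malignant:
        auc = 1.0 - auc

    fpr, tpr, thresholds = roc_curve(y, scores)
    youden = tpr - fpr
    best = int(np.argmax(youden))
    sens = float(tpr[best])
    spec = float(1.0 - fpr[best])
    cutoff = float(thresholds[best] if higher_in_malignant else -thresholds[best])

    rng = np.random.default_rng(seed)
    idx_pos = np.nonzero(y == 1)[0]
    idx_neg = np.nonzero(y == 0)[0]
    boot = np.empty(n_boot)
    for i in range(n_boot):
        take = np.concatenate(
            [
                rng.choice(idx_pos, size=len(idx_pos), replace=True),
                rng.choice(idx_neg, size=len(idx_neg), replace=True),
            ]
        )
        boot[i] = _rank_auc(scores[take], y[take])
    lo, hi = np.percentile(boot, [2.5, 97.5])
    lo = min(lo, auc)
    hi = max(hi, auc)

    return DiagnosticResult(
        parameter=parameter,
        p_value=np.nan,
        auc_pct=100.0 * auc,
        sensitivity_pct=100.0 * sens,
        specificity_pct=100.0 * spec,
        ci_pct=(100.0 * float(lo), 100.0 * float(hi)),
        cutoff=cutoff,
        higher_in_malignant=higher_in_malignant,
    )


def logistic_panel(
    features: pd.DataFrame | np.ndarray,
    labels,
    panel: str = "new",
    n_boot: int = 2000,
    seed: int = 0,
) -> PanelResult:
    """Multivariable logistic combination of a biomarker panel, scored in-sample.

    Fits an unpenalized maximum-likelihood logistic model; if the classes are
    perfectly separated (fit diverges), falls back to a ridge-penalized fit
    with a warning. The predicted probabilities are scored by
    :func:`roc_analysis`.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels).astype(int)
    if len(X) <= X.shape[1] + 1:
        raise InputError("need more observations than features + 1")
    names = (
        tuple(features.columns) if isinstance(features, pd.DataFrame) else
        tuple(f"x{i}" for i in range(X.shape[1]))
    )

    penalized = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = LogisticRegression(penalty=None, solver="lbfgs", max_iter=2000)
        model.fit(X, y)
    # a hyperplane that classifies the training data perfectly means the
    # classes are separable and the unpenalized MLE diverges
    if (
        not np.all(np.isfinite(model.coef_))
        or (model.predict(X) == y).all()
    ):
        warnings.warn(
            "perfect separation detected; falling back to ridge-penalized fit",
            stacklevel=2,
        )
        penalized = True
        model = LogisticRegression(penalty="l2", C=1.0, solver="lbfgs", max_iter=2000)
        model.fit(X, y)
    probs = model.predict_proba(X)[:, 1]
    roc = roc_analysis(probs, y, n_boot=n_boot, seed=seed, parameter=f"panel:{panel}")
    return PanelResult(
        panel=panel,
        features=names,
        auc_pct=roc.auc_pct,
        sensitivity_pct=roc.sensitivity_pct,
        specificity_pct=roc.specificity_pct,
        ci_pct=roc.ci_pct,
        penalized=penalized,
    )


def evaluate_cohort(
    cohort: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[pd.DataFrame, PanelResult]:
    """Per-parameter diagnostics plus the combined new-biomarker panel.

    ``cohort`` is one row per lesion with a ``label`` column in
    {benign, malignant} and the parameter columns. Returns a results table
    (one row per parameter: p-value, Sen, Sp, AUC, CI) and the logistic
    panel result for (mvfd, svp, ba_mean, md_mean).
    """
    if "label" not in cohort.columns:
        raise InputError("cohort needs a 'label' column")
    y = (cohort["label"] == "malignant").astype(int).to_numpy()
    benign = cohort[cohort["label"] == "benign"]
    malignant = cohort[cohort["label"] == "malignant"]
    rows = []
    for i, name in enumerate(["svp"] + CONTINUOUS_PARAMETERS):
        if name not in cohort.columns:
            continue
        binary = name == "svp"
        p = compare_groups(benign[name], malignant[name], binary=binary)
        roc = roc_analysis(
            cohort[name].to_numpy(), y, n_boot=n_boot, seed=seed + i, parameter=name
        )
        rows.append(
            {
                "parameter": name,
                "p_value": p,
                "sen_pct": roc.sensitivity_pct,
                "sp_pct": roc.specificity_pct,
                "auc_pct": roc.auc_pct,
                "ci_lo_pct": roc.ci_pct[0],
                "ci_hi_pct": roc.ci_pct[1],
                "cutoff": roc.cutoff,
            }
        )
    table = pd.DataFrame(rows)
    features = cohort[PANELS["new"]]
    panel = logistic_panel(features, y, panel="new", n_boot=n_boot, seed=seed)
    return table, panel
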