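"""Statistics and cross-validated prediction of epileptic-network focality.

Univariate comparisons (Cohen's d, Mann-Whitney U / AUC), DeLong AUC
confidence intervals and paired AUC comparisons, Holm-Bonferroni correction,
leave-one-out cross-validated L1-penalized logistic regression over three
nested feature sets (pre-implant score alone; + implant distance; + the 12
abnormality distances), operating-point selection on the ROC curve, subgroup
analyses (therapy, outcome, implant type, non-focal subtype) and a
Table-1-style cohort comparison (Yates-corrected chi-square for 2x2
categorical contrasts, U-test for continuous variables).

The DeLong machinery uses structural components (Sun & Xu's midrank
formulation): for positives ``V10_i = mean_j psi(x_i, y_j)`` and negatives
``V01_j = mean_i psi(x_i, y_j)`` with psi = 1, 1/2, 0 for x>y, x=y, x<y.
``AUC = mean(V10) = mean(V01)`` equals the Mann-Whitney U statistic divided
by n_pos*n_neg, and the variance of the AUC (or of a difference of paired
AUCs) follows from the empirical (co)variances of the components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

FIVE_SENSE_COL = "five_sense"
IMPLANT_COL = "implant_distance_mm"


# ---------------------------------------------------------------------------
# Univariate statistics
# ---------------------------------------------------------------------------

def cohens_d(group_a, group_b) -> float:
    """Cohen's d = (mean_a − mean_b) / pooled SD (n−1-weighted pooling)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Cohen's d needs at least two observations per group")
    pooled = np.sqrt(
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2)
    )
    if pooled == 0:
        raise ValueError("zero pooled standard deviation; effect size undefined")
    return float((a.mean() - b.mean()) / pooled)


def mann_whitney_auc(pos, neg) -> tuple[float, float, float]:
    """Mann-Whitney U of pos vs neg with two-tailed p and AUC = U/(n₁n₂).

    Ties get half credit. The p-value is exact for small samples without
    ties and a tie-corrected normal approximation otherwise (scipy's
    default policy).
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be non-empty")
    res = sp_stats.mannwhitneyu(pos, neg, alternative="two-sided", method="auto")
    auc = float(res.statistic) / (pos.size * neg.size)
    return float(res.statistic), float(res.pvalue), auc


# ---------------------------------------------------------------------------
# DeLong machinery
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return sp_stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Structural components (V10 per positive, V01 per negative) and AUC."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return v10, v01, float(auc)


@dataclass
class RocResult:
    """AUC with DeLong 95% CI and the ROC operating point."""

    auc: float
    ci: tuple[float, float]
    variance: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    threshold: float
    sensitivity: float
    specificity: float
    confusion: np.ndarray  # [[tn, fp], [fn, tp]]


def _coerce_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype != bool:
        y = y.astype(float) > 0.5
    return y


def delong_auc_variance(scores, labels) -> tuple[float, float]:
    """AUC and its DeLong variance."""
    scores = np.asarray(scores, dtype=float)
    y = _coerce_labels(labels)
    v10, v01, auc = _delong_components(scores, y)
    var = 0.0
    if v10.size > 1:
        var += v10.var(ddof=1) / v10.size
    if v01.size > 1:
        var += v01.var(ddof=1) / v01.size
    return auc, float(var)


def optimal_operating_point(
    fpr: np.ndarray, tpr: np.ndarray, thresholds: np.ndarray
) -> tuple[float, float, float]:
    """Youden's J maximizer; ties broken toward higher sensitivity.

    Returns (threshold, sensitivity, specificity).
    """
    j = tpr - fpr
    best = j.max()
    candidates = np.flatnonzero(j >= best - 1e-12)
    k = candidates[np.argmax(tpr[candidates])]
    return float(thresholds[k]), float(tpr[k]), float(1.0 - fpr[k])


def delong_auc_ci(scores, labels, level: float = 0.95) -> RocResult:
    """AUC with a DeLong-variance Wald CI (truncated to [0, 1]) and ROC."""
    scores = np.asarray(scores, dtype=float)
    y = _coerce_labels(labels)
    auc, var = delong_auc_variance(scores, y)
    z = sp_stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    fpr, tpr, thr = roc_curve(y.astype(int), scores)
    threshold, sens, spec = optimal_operating_point(fpr, tpr, thr)
    pred = scores >= threshold
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))
    return RocResult(
        auc=auc,
        ci=ci,
        variance=var,
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        threshold=threshold,
        sensitivity=sens,
        specificity=spec,
        confusion=np.array([[tn, fp], [fn, tp]]),
    )


def delong_paired_test(scores_1, scores_2, labels) -> tuple[float, float, float]:
    """Paired DeLong test for ΔAUC of two models scored on the same patients.

    Returns (delta_auc = AUC₁ − AUC₂, z, two-sided p). Identical score
    vectors (zero variance of the difference) give p = 1 by convention.
    """
    s1 = np.asarray(scores_1, dtype=float)
    s2 = np.asarray(scores_2, dtype=float)
    y = _coerce_labels(labels)
    if s1.shape != s2.shape or s1.shape != y.shape:
        raise ValueError("score vectors and labels must be aligned")
    v10_1, v01_1, auc1 = _delong_components(s1, y)
    v10_2, v01_2, auc2 = _delong_components(s2, y)
    delta = auc1 - auc2
    m, n = v10_1.size, v01_1.size
    var = 0.0
    if m > 1:
        s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
        var += (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
    if n > 1:
        s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
        var += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 1e-16:
        return float(delta), 0.0, 1.0
    z = delta / np.sqrt(var)
    p = 2.0 * sp_stats.norm.sf(abs(z))
    return float(delta), float(z), float(min(p, 1.0))


def holm_bonferroni(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down adjusted p-values and rejection flags."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return p_adj, reject


# ---------------------------------------------------------------------------
# Cross-validated models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """A named feature set for the focality logistic regression."""

    name: str
    features: tuple[str, ...]
    C: float = 1.0
    standardize: bool = True


def model_specs(feature_columns: Sequence[str], include_implant_in_full: bool = True) -> list[ModelSpec]:
    """The three nested models: 5-SENSE; + implant distance; + abnormality.

    The full model includes implant distance alongside the 12 abnormality
    distances by default; ``include_implant_in_full=False`` reproduces the
    stricter reading where the third model is 5-SENSE + abnormality only.
    """
    wsd = tuple(c for c in feature_columns if c.startswith("wsd_"))
    full = (FIVE_SENSE_COL,) + ((IMPLANT_COL,) if include_implant_in_full else ()) + wsd
    return [
        ModelSpec("five_sense_only", (FIVE_SENSE_COL,)),
        ModelSpec("five_sense+implant", (FIVE_SENSE_COL, IMPLANT_COL)),
        ModelSpec("five_sense+implant+abnormality", full),
    ]


@dataclass
class CVPredictionSet:
    """Out-of-fold probabilities and per-fold coefficients from LOOCV."""

    model: ModelSpec
    probabilities: np.ndarray  # (n,), one held-out prediction per patient
    coefficients: np.ndarray  # (n_folds, n_features), standardized space
    feature_names: tuple[str, ...]

    def coefficient_summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "coef_mean": self.coefficients.mean(axis=0),
                "coef_sd": self.coefficients.std(axis=0, ddof=1),
                "zeroed_fraction": (self.coefficients == 0).mean(axis=0),
            }
        )


def loocv_predict(features: pd.DataFrame, labels, spec: ModelSpec) -> CVPredictionSet:
    """Leave-one-out cross-validated lasso logistic regression.

    For each patient, an L1-penalized logistic regression (inverse
    regularization strength ``C``) is fit on the other n−1 patients, with
    features standardized to the training fold's mean/SD, and the held-out
    patient's probability of being focal is recorded. The held-out label is
    never seen by its own fold's model.
    """
    X = features.loc[:, list(spec.features)].to_numpy(dtype=float)
    y = _coerce_labels(labels).astype(int)
    n = X.shape[0]
    if n < 10:
        raise ValueError("need at least 10 patients for leave-one-out CV")
    if not np.all(np.isfinite(X)):
        raise ValueError("missing features; exclude incomplete patients upstream")
    probs = np.empty(n)
    coefs = np.empty((n, X.shape[1]))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_train = y[mask]
        if y_train.min() == y_train.max():
            raise ValueError(f"training fold {i} contains a single class")
        X_train = X[mask]
        if spec.standardize:
            mu = X_train.mean(axis=0)
            sd = X_train.std(axis=0)
            sd[sd == 0] = 1.0
        else:
            mu, sd = 0.0, 1.0
        clf = LogisticRegression(
            l1_ratio=1.0, C=spec.C, solver="liblinear", max_iter=1000, random_state=0
        )
        clf.fit((X_train - mu) / sd, y_train)
        probs[i] = clf.predict_proba(((X[i] - mu) / sd)[None, :])[0, 1]
        coefs[i] = clf.coef_[0]
    return CVPredictionSet(
        model=spec, probabilities=probs, coefficients=coefs, feature_names=spec.features
    )


# ---------------------------------------------------------------------------
# Model comparison and subgroup analyses
# ---------------------------------------------------------------------------

def univariate_table(features: pd.DataFrame, labels, columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-feature focal vs non-focal comparison: Cohen's d, U-test, AUC+CI."""
    y = _coerce_labels(labels)
    cols = list(columns) if columns is not None else [
        c for c in features.columns
        if c == FIVE_SENSE_COL or c == IMPLANT_COL or c.startswith("wsd_")
    ]
    rows = []
    for c in cols:
        vals = features[c].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        if ok.sum() < 4 or y[ok].min() == y[ok].max():
            continue
        pos, neg = vals[ok & y], vals[ok & ~y]
        _, p, auc = mann_whitney_auc(pos, neg)
        roc = delong_auc_ci(vals[ok], y[ok])
        rows.append(
            {
                "feature": c,
                "d": cohens_d(pos, neg),
                "p_utest": p,
                "auc": auc,
                "auc_ci_low": roc.ci[0],
                "auc_ci_high": roc.ci[1],
                "n": int(ok.sum()),
            }
        )
    return pd.DataFrame(rows)


def model_comparison_suite(
    features: pd.DataFrame,
    labels,
    include_implant_in_full: bool = True,
    alpha: float = 0.05,
) -> dict:
    """Fit the three nested models and compare their cross-validated AUCs.

    Paired DeLong tests form a family of three sequential comparisons
    (full vs 5-SENSE, full vs 5-SENSE+implant, 5-SENSE+implant vs 5-SENSE),
    Holm-corrected together.
    """
    y = _coerce_labels(labels)
    specs = model_specs(features.columns, include_implant_in_full)
    cv = {s.name: loocv_predict(features, y, s) for s in specs}
    roc = {name: delong_auc_ci(pred.probabilities, y) for name, pred in cv.items()}

    pairs = [
        (specs[2].name, specs[0].name),
        (specs[2].name, specs[1].name),
        (specs[1].name, specs[0].name),
    ]
    raw = []
    comparisons = []
    for a, b in pairs:
        delta, z, p = delong_paired_test(cv[a].probabilities, cv[b].probabilities, y)
        raw.append(p)
        comparisons.append({"model_a": a, "model_b": b, "delta_auc": delta, "z": z, "p": p})
    p_adj, reject = holm_bonferroni(raw, alpha=alpha)
    for row, pa, rej in zip(comparisons, p_adj, reject):
        row["p_holm"] = float(pa)
        row["reject"] = bool(rej)

    model_table = pd.DataFrame(
        [
            {
                "model": name,
                "auc": r.auc,
                "ci_low": r.ci[0],
                "ci_high": r.ci[1],
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
            }
            for name, r in roc.items()
        ]
    )
    return {
        "cv": cv,
        "roc": roc,
        "models": model_table,
        "comparisons": pd.DataFrame(comparisons),
    }


def subgroup_analysis(
    probabilities: np.ndarray,
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    min_n: int = 3,
) -> pd.DataFrame:
    """AUC of the full model's predictions across clinical subgroup contrasts.

    Families (Holm-corrected within family): surgical outcome
    (seizure-free vs not, seizure-free vs neurostimulation) and non-focal
    subtype (unifocal vs bifocal / multifocal / bifocal-vs-multifocal).
    Implant-type rows report per-group focality AUC without a family.
    Subgroups below ``min_n`` are reported as insufficient.
    """
    probs = np.asarray(probabilities, dtype=float)
    df = cohort.reset_index(drop=True)

    def _contrast(name, family, mask_pos, mask_neg):
        n1, n0 = int(mask_pos.sum()), int(mask_neg.sum())
        if n1 < min_n or n0 < min_n:
            return {"contrast": name, "family": family, "n_pos": n1, "n_neg": n0, "status": "insufficient"}
        pos, neg = probs[mask_pos], probs[mask_neg]
        _, p, auc = mann_whitney_auc(pos, neg)
        sel = mask_pos | mask_neg
        roc = delong_auc_ci(probs[sel], mask_pos[sel])
        return {
            "contrast": name,
            "family": family,
            "n_pos": n1,
            "n_neg": n0,
            "auc": auc,
            "auc_ci_low": roc.ci[0],
            "auc_ci_high": roc.ci[1],
            "p": p,
            "status": "ok",
        }

    surgical = df["therapy"].isin(["resection", "ablation"]).to_numpy()
    good = (df["outcome"] == "ILAE 1-2").to_numpy() & surgical
    poor = (df["outcome"] == "ILAE 3-6").to_numpy() & surgical
    stim = (df["therapy"] == "neurostimulation").to_numpy()
    focal = (df["focality_label"] == "focal").to_numpy()
    rows = [
        _contrast("seizure_free_vs_not_free", "outcome", good, poor),
        _contrast("seizure_free_vs_neurostimulation", "outcome", good, stim),
        _contrast("surgery_vs_device", "therapy", surgical, stim),
    ]
    for implant in ("ECOG", "SEEG"):
        m = (df["implant_type"] == implant).to_numpy()
        rows.append(_contrast(f"focal_vs_nonfocal_{implant}", "implant", focal & m, ~focal & m))
    uni = focal
    bif = (df["subtype"] == "bifocal").to_numpy()
    multi = (df["subtype"] == "multifocal").to_numpy()
    rows += [
        _contrast("unifocal_vs_bifocal", "subtype", uni, bif),
        _contrast("unifocal_vs_multifocal", "subtype", uni, multi),
        _contrast("bifocal_vs_multifocal", "subtype", bif, multi),
    ]
    out = pd.DataFrame(rows)
    out["p_holm"] = np.nan
    for family in ("outcome", "subtype"):
        m = (out["family"] == family) & (out["status"] == "ok")
        if m.any():
            adj, _ = holm_bonferroni(out.loc[m, "p"].to_numpy(), alpha=alpha)
            out.loc[m, "p_holm"] = adj
    return out


# ---------------------------------------------------------------------------
# Table-1-style cohort statistics
# ---------------------------------------------------------------------------

def yates_chi2(table) -> tuple[float, float]:
    """Yates-continuity-corrected chi-square on a 2x2 contingency table."""
    tab = np.asarray(table, dtype=float)
    res = sp_stats.chi2_contingency(tab, correction=(tab.shape == (2, 2)))
    return float(res.statistic), float(res.pvalue)


def cohort_stats(
    cohort: pd.DataFrame,
    group_col: str = "focality_label",
    continuous: Sequence[str] = (FIVE_SENSE_COL,),
    categorical: Mapping[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Group comparison table: U-test for continuous, Yates chi² for 2x2 counts.

    ``categorical`` maps a column name to the (level_a, level_b) pair forming
    the 2x2 table against the two cohort groups; by default therapy
    (surgery vs device) and implant type (SEEG vs ECOG) are compared.
    """
    groups = sorted(cohort[group_col].dropna().unique().tolist())
    if len(groups) != 2:
        raise ValueError("cohort_stats expects exactly two groups")
    g0 = cohort[group_col] == groups[0]
    g1 = cohort[group_col] == groups[1]
    rows = []
    for col in continuous:
        a = cohort.loc[g0, col].dropna().to_numpy(dtype=float)
        b = cohort.loc[g1, col].dropna().to_numpy(dtype=float)
        _, p, _ = mann_whitney_auc(a, b)
        rows.append(
            {
                "variable": col,
                "kind": "continuous",
                f"{groups[0]}": f"{a.mean():.2f} ({a.std(ddof=1):.2f})",
                f"{groups[1]}": f"{b.mean():.2f} ({b.std(ddof=1):.2f})",
                "p": p,
            }
        )
    if categorical is None:
        categorical = {}
        if "therapy" in cohort.columns:
            surg = cohort["therapy"].isin(["resection", "ablation"])
            cohort = cohort.assign(_therapy_bin=np.where(surg, "surgery", "device"))
            categorical["_therapy_bin"] = ("surgery", "device")
        if "implant_type" in cohort.columns:
            categorical["implant_type"] = ("SEEG", "ECOG")
        g0 = cohort[group_col] == groups[0]
        g1 = cohort[group_col] == groups[1]
    for col, (la, lb) in categorical.items():
        tab = np.array(
            [
                [int(((cohort[col] == la) & g0).sum()), int(((cohort[col] == lb) & g0).sum())],
                [int(((cohort[col] == la) & g1).sum()), int(((cohort[col] == lb) & g1).sum())],
            ]
        )
        if tab.sum() == 0 or tab.sum(axis=1).min() == 0:
            continue
        _, p = yates_chi2(tab)
        rows.append(
            {
                "variable": col.lstrip("_"),
                "kind": "categorical",
                f"{groups[0]}": f"{la}:{tab[0,0]} {lb}:{tab[0,1]}",
                f"{groups[1]}": f"{la}:{tab[1,0]} {lb}:{tab[1,1]}",
                "p": p,
            }
        )
    return pd.DataFrame(rows)
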