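"""ROC analysis: predicting cell fate from initial protein levels.

Given a simulated heterogeneous population, each cell's fate (apoptotic or
not at 24 h) is treated as the ground-truth label, and the 19 candidate
predictors are the 16 sampled initial concentrations plus three derived
features: [XIAP]/[PARP], [PARP]/[XIAP] and |[PARP] - [XIAP]|.  Single
features are scored by the area under the ROC curve; the AUC equals the
Mann-Whitney U probability that a random apoptotic cell scores above a
random non-apoptotic cell (ties counted half).

Predictors are auto-oriented: a feature whose low values mark apoptosis
(XIAP) is reported with AUC = 1 - AUC_raw and the flip recorded, so
reported AUCs are always >= 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .population import PopulationResult

__all__ = [
    "FeatureTable",
    "RocCurve",
    "build_feature_table",
    "roc",
    "auc_ci",
    "compare_fate_distributions",
    "rank_predictors",
]

DERIVED_FEATURES = ("XIAP/PARP", "PARP/XIAP", "|PARP-XIAP|")


@dataclass
class FeatureTable:
    """Per-cell predictors and fate labels."""

    features: pd.DataFrame  # cells x 19 predictors
    labels: np.ndarray  # boolean, apoptotic at 24 h

    @property
    def predictor_names(self) -> list:
        return list(self.features.columns)


def build_feature_table(pop: PopulationResult) -> FeatureTable:
    """Construct the 19-predictor table from a population simulation.

    Raises when the population contains only one fate class (ROC analysis
    is undefined without both positives and negatives).
    """
    labels = np.asarray(pop.fate, bool)
    if labels.all() or not labels.any():
        raise ValueError("population has a single fate class; ROC undefined")
    feats = pop.ic_matrix.copy()
    xiap = feats["XIAP"].to_numpy()
    parp = feats["PARP"].to_numpy()
    feats["XIAP/PARP"] = xiap / parp
    feats["PARP/XIAP"] = parp / xiap
    feats["|PARP-XIAP|"] = np.abs(parp - xiap)
    if feats.shape[1] != 19:
        raise ValueError(
            f"expected 19 predictors, got {feats.shape[1]}"
        )
    return FeatureTable(feats, labels)


@dataclass
class RocCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    orientation: int  # +1 higher-score-positive, -1 inverted
    degenerate: bool = False


def roc(scores: np.ndarray, labels: np.ndarray, orient: bool = False) -> RocCurve:
    """ROC curve and AUC for one score vector.

    With ``orient=True`` the score sign is flipped when that raises the
    AUC above 0.5 (flip recorded in ``orientation``).  Constant scores
    yield the chance diagonal (AUC 0.5) with the degenerate flag set.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    if labels.all() or not labels.any():
        raise ValueError("need at least one positive and one negative")
    if np.ptp(scores) == 0:
        return RocCurve(
            thresholds=np.array([np.inf, scores[0]]),
            tpr=np.array([0.0, 1.0]),
            fpr=np.array([0.0, 1.0]),
            auc=0.5,
            orientation=+1,
            degenerate=True,
        )
    orientation = +1
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    a = _sk_auc(fpr, tpr)
    if orient and a < 0.5:
        orientation = -1
        fpr, tpr, thr = _sk_roc_curve(labels, -scores)
        a = _sk_auc(fpr, tpr)
    return RocCurve(thresholds=thr, tpr=tpr, fpr=fpr, auc=float(a),
                    orientation=orientation)


def auc_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    level: float = 0.95,
    method: str = "bootstrap",
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """AUC with a confidence interval and a p-value against AUC = 0.5.

    ``method='bootstrap'``: stratified bootstrap (resampling positives and
    negatives separately), percentile interval.  ``method='hanley'``: the
    Hanley-McNeil closed-form standard error with a normal interval.  The
    p-value is from the two-sided Mann-Whitney U test of the scores
    between classes (exactly the AUC = 0.5 null).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    point = roc(scores, labels).auc
    pos, neg = scores[labels], scores[~labels]
    if min(pos.size, neg.size) < 10:
        import warnings

        warnings.warn("fewer than 10 cells in a class; interval is wide",
                      RuntimeWarning)
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        vals = np.empty(n_boot)
        for b in range(n_boot):
            ps = rng.choice(pos, pos.size, replace=True)
            ns = rng.choice(neg, neg.size, replace=True)
            vals[b] = stats.mannwhitneyu(ps, ns).statistic / (
                ps.size * ns.size
            )
        alpha = 1.0 - level
        lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    elif method == "hanley":
        a = point
        n1, n2 = pos.size, neg.size
        q1 = a / (2 - a)
        q2 = 2 * a * a / (1 + a)
        se = np.sqrt(
            (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n2 - 1) * (q2 - a * a))
            / (n1 * n2)
        )
        z = stats.norm.ppf(0.5 + level / 2)
        lo, hi = a - z * se, min(1.0, a + z * se)
    else:
        raise ValueError("method must be 'bootstrap' or 'hanley'")
    p = stats.mannwhitneyu(pos, neg, alternative="two-sided").pvalue
    return {"auc": point, "ci": (float(lo), float(hi)), "p_vs_half": float(p),
            "level": level, "method": method}


def compare_fate_distributions(
    pop: PopulationResult, species: list | None = None, test: str = "ranksum"
) -> pd.DataFrame:
    """Per-species comparison of initial concentrations between fate groups.

    Default test is the two-sided Wilcoxon rank-sum; ``test='welch'``
    switches to Welch's t.  Reports group medians and the p-value.
    """
    labels = np.asarray(pop.fate, bool)
    if labels.all() or not labels.any():
        raise ValueError("both fate groups must be non-empty")
    if species is None:
        species = list(pop.ic_matrix.columns)
    rows = []
    for name in species:
        x = pop.ic_matrix[name].to_numpy()
        a, n = x[labels], x[~labels]
        if test == "ranksum":
            p = stats.mannwhitneyu(a, n, alternative="two-sided").pvalue
        elif test == "welch":
            p = stats.ttest_ind(a, n, equal_var=False).pvalue
        else:
            raise ValueError("test must be 'ranksum' or 'welch'")
        rows.append(
            {
                "species": name,
                "median_apoptotic": float(np.median(a)),
                "median_nonapoptotic": float(np.median(n)),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)


def rank_predictors(
    table: FeatureTable,
    level: float = 0.95,
    method: str = "bootstrap",
    seed: int = 0,
) -> pd.DataFrame:
    """Score every predictor by auto-oriented AUC with CI and p vs 0.5.

    Returns a DataFrame sorted by AUC (descending) with the orientation
    (+1: high values predict apoptosis; -1: low values do).
    """
    rows = []
    for name in table.predictor_names:
        scores = table.features[name].to_numpy()
        curve = roc(scores, table.labels, orient=True)
        oriented = scores * curve.orientation
        ci = auc_ci(oriented, table.labels, level=level, method=method,
                    seed=seed)
        rows.append(
            {
                "predictor": name,
                "auc": curve.auc,
                "ci_lo": ci["ci"][0],
                "ci_hi": ci["ci"][1],
                "p_vs_half": ci["p_vs_half"],
                "orientation": curve.orientation,
            }
        )
    return (
        pd.DataFrame(rows).sort_values("auc", ascending=False).reset_index(drop=True)
    )
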