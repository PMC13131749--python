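"""PRS and composite clinical risk scoring, with discrimination/calibration.

Two scores are implemented:

* the log-additive polygenic risk score (PRS): an HLA-DQ risk-genotype
  weight plus Σ weight × effect-allele dosage over a table of non-HLA SNPs;
* the composite clinical score: a logistic-regression linear predictor over
  the PRS, family history, and clinical diagnoses (diarrhea, vitamin D
  deficiency, anemia, hypothyroidism) plus a high/moderate HLA indicator —
  fitted with seropositive cases as positives.

Evaluation machinery: ROC/AUC (rank-based, tie-corrected), threshold
selection (maximum accuracy, or the largest threshold keeping sensitivity
≥ 90%), Platt post-hoc probability calibration, and the Brier score.
Published weight tables for the real 38-SNP panel are not redistributable,
so weight tables are an input file and the test suite ships a synthetic one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import seropositive_column

__all__ = [
    "PrsWeightTable",
    "ScoreModel",
    "RocResult",
    "CompositeScoreModel",
    "PlattCalibrator",
    "SeparationError",
    "COMPOSITE_FEATURES",
    "compute_prs",
    "compute_prs_frame",
    "build_feature_frame",
    "fit_composite",
    "score",
    "score_frame",
    "roc",
    "select_threshold",
    "platt_calibrate",
    "brier",
]

COMPOSITE_FEATURES = (
    "prs",
    "family_history",
    "diarrhea",
    "vitamin_d_deficiency",
    "anemia",
    "hypothyroidism",
    "high_or_moderate_hla",
)


class SeparationError(RuntimeError):
    """Raised when a logistic fit is perfectly separated.

    Refit with ``penalize=True`` (small ridge penalty) to obtain finite
    coefficients.
    """


@dataclass(frozen=True)
class PrsWeightTable:
    """Per-variant PRS weights plus per-risk-genotype HLA weights."""

    entries: tuple  # of (variant_id, effect_allele, weight)
    hla_genotype_weights: Mapping[str, float] = field(
        default_factory=lambda: {"high": 0.0, "moderate": 0.0, "low": 0.0, "none": 0.0}
    )

    def __post_init__(self) -> None:
        ids = [e[0] for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate variant ids in PRS weight table")
        for vid, _, w in self.entries:
            if not math.isfinite(w):
                raise ValueError(f"non-finite weight for {vid}")
        for cat, w in self.hla_genotype_weights.items():
            if not math.isfinite(w):
                raise ValueError(f"non-finite HLA weight for {cat}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"variant_id": v, "effect_allele": a, "weight": w}
            for v, a, w in self.entries
        ]
        rows += [
            {"variant_id": f"HLA:{cat}", "effect_allele": ".", "weight": w}
            for cat, w in self.hla_genotype_weights.items()
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PrsWeightTable":
        entries, hla = [], {}
        for row in frame.itertuples(index=False):
            vid = str(row.variant_id)
            if vid.startswith("HLA:"):
                hla[vid[4:]] = float(row.weight)
            else:
                entries.append((vid, str(row.effect_allele), float(row.weight)))
        return cls(tuple(entries), hla)


def compute_prs(record, weights: PrsWeightTable) -> float:
    """Log-additive PRS for one participant.

    score = HLA genotype weight + Σ weight × dosage.  Missing dosages count
    as 0 with a warning.
    """
    get = record.get if hasattr(record, "get") else lambda k, d=None: getattr(record, k, d)
    hla_term = weights.hla_genotype_weights.get(get("risk_category", "none"), 0.0)
    total = hla_term
    missing = []
    for vid, _, w in weights.entries:
        dosage = get(f"dos_{vid}")
        if dosage is None or (isinstance(dosage, float) and np.isnan(dosage)):
            missing.append(vid)
            continue
        total += w * float(dosage)
    if missing:
        warnings.warn(
            f"{len(missing)} missing dosage(s) imputed as 0 "
            f"(first: {missing[0]})", stacklevel=2
        )
    return float(total)


def compute_prs_frame(cohort: pd.DataFrame, weights: PrsWeightTable) -> pd.Series:
    """Vectorized PRS over a cohort table (requires ``risk_category``)."""
    if "risk_category" not in cohort.columns:
        raise KeyError("cohort must carry risk_category; run call_dq_frame first")
    total = cohort["risk_category"].map(
        lambda c: weights.hla_genotype_weights.get(c, 0.0)
    ).astype(float)
    n_missing = 0
    for vid, _, w in weights.entries:
        col = f"dos_{vid}"
        if col in cohort.columns:
            total = total + w * cohort[col].fillna(0.0).astype(float)
        else:
            n_missing += 1
    if n_missing:
        warnings.warn(
            f"{n_missing} panel variant(s) absent from cohort; dosages "
            "imputed as 0", stacklevel=2
        )
    return total.rename("prs")


def build_feature_frame(
    cohort: pd.DataFrame,
    weights: PrsWeightTable | None = None,
    features: Sequence[str] = COMPOSITE_FEATURES,
) -> pd.DataFrame:
    """Assemble the composite-score design matrix from an annotated cohort."""
    out = pd.DataFrame(index=cohort.index)
    for feat in features:
        if feat == "prs":
            if "prs" in cohort.columns:
                out["prs"] = cohort["prs"].astype(float)
            else:
                if weights is None:
                    raise ValueError("PRS weights required to build 'prs' feature")
                out["prs"] = compute_prs_frame(cohort, weights)
        elif feat == "high_or_moderate_hla":
            out[feat] = cohort["risk_category"].isin(["high", "moderate"]).astype(float)
        else:
            out[feat] = cohort[feat].astype(float)
    return out


@dataclass(frozen=True)
class ScoreModel:
    """Intercept + named feature weights for a log-additive score."""

    intercept: float
    feature_weights: Mapping[str, float]

    def __post_init__(self) -> None:
        if not math.isfinite(self.intercept):
            raise ValueError("non-finite intercept")
        for name, w in self.feature_weights.items():
            if not math.isfinite(w):
                raise ValueError(f"non-finite weight for feature {name!r}")


def score(record, model: ScoreModel) -> float:
    """Linear-predictor score for one participant (flags enter as 0/1)."""
    get = record.get if hasattr(record, "get") else lambda k: getattr(record, k)
    total = model.intercept
    for name, w in model.feature_weights.items():
        total += w * float(get(name))
    return float(total)


def score_frame(X: pd.DataFrame, model: ScoreModel) -> pd.Series:
    """Vectorized :func:`score` over a feature frame."""
    total = pd.Series(model.intercept, index=X.index, dtype=float)
    for name, w in model.feature_weights.items():
        total = total + w * X[name].astype(float)
    return total.rename("score")


class CompositeScoreModel:
    """Additive logistic risk model fitted by Newton/IRLS (sklearn style).

    Parameters
    ----------
    features : sequence of str or None
        Columns of the design matrix to use; None means all columns.
    penalize : bool
        Ridge fallback (λ = 1e-4 on standardized features) for separated or
        collinear designs.
    tol, max_iter : float, int
        IRLS convergence contract: stop when the max coefficient change is
        below ``tol``, cap at ``max_iter`` iterations.

    Attributes (after ``fit``)
    --------------------------
    intercept_ : float
    coef_ : dict feature -> weight
    model_ : ScoreModel
    """

    def __init__(
        self,
        features: Sequence[str] | None = None,
        penalize: bool = False,
        tol: float = 1e-8,
        max_iter: int = 100,
    ) -> None:
        self.features = features
        self.penalize = penalize
        self.tol = tol
        self.max_iter = max_iter

    def get_params(self, deep: bool = True) -> dict:
        return {
            "features": self.features, "penalize": self.penalize,
            "tol": self.tol, "max_iter": self.max_iter,
        }

    def set_params(self, **params) -> "CompositeScoreModel":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X: pd.DataFrame, y) -> "CompositeScoreModel":
        cols = list(self.features) if self.features else list(X.columns)
        design = X[cols].astype(float)
        labels = np.asarray(y, dtype=float)
        if set(np.unique(labels)) - {0.0, 1.0}:
            raise ValueError("labels must be binary 0/1")
        if labels.sum() == 0 or labels.sum() == len(labels):
            raise ValueError("need at least one case and one control")
        if self.penalize:
            intercept, coefs = _ridge_logistic(design.to_numpy(), labels)
        else:
            intercept, coefs = _irls_logistic(
                design.to_numpy(), labels, tol=self.tol, max_iter=self.max_iter
            )
        self.intercept_ = float(intercept)
        self.coef_ = dict(zip(cols, map(float, coefs)))
        self.model_ = ScoreModel(self.intercept_, dict(self.coef_))
        return self

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        return score_frame(X, self.model_).to_numpy()

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        s = self.decision_function(X)
        p = 1.0 / (1.0 + np.exp(-s))
        return np.c_[1.0 - p, p]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.decision_function(X) >= 0).astype(int)


def _irls_logistic(X: np.ndarray, y: np.ndarray, tol: float, max_iter: int):
    """Unpenalized logistic fit via statsmodels' Newton/IRLS.

    Raises :class:`SeparationError` on (quasi-)separation or a singular
    design — refit with the ridge fallback in that case.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    design = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            # separation/convergence warnings are hard errors here
            warnings.simplefilter("error")
            fit = sm.Logit(y, design).fit(
                disp=0, method="newton", tol=tol, maxiter=max_iter
            )
    except (PerfectSeparationError, np.linalg.LinAlgError, Warning) as exc:
        raise SeparationError(
            "logistic fit did not converge (separation or collinearity); "
            "refit with penalize=True"
        ) from exc
    params = np.asarray(fit.params)
    if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 1e6:
        raise SeparationError(
            "logistic coefficients diverged; refit with penalize=True"
        )
    return params[0], params[1:]


def _ridge_logistic(X: np.ndarray, y: np.ndarray, lam: float = 1e-4):
    """Ridge-penalized logistic fit on standardized features, mapped back."""
    from sklearn.linear_model import LogisticRegression

    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd
    model = LogisticRegression(C=1.0 / lam, solver="lbfgs", max_iter=2000,
                               tol=1e-8)
    model.fit(Z, y)
    beta_std = model.coef_.ravel()
    beta = beta_std / sd
    intercept = model.intercept_[0] - float(np.dot(beta_std, mu / sd))
    return intercept, beta


def fit_composite(
    X: pd.DataFrame,
    y,
    features: Sequence[str] | None = None,
    penalize: bool = False,
) -> ScoreModel:
    """Fit the composite score (functional wrapper over the estimator)."""
    est = CompositeScoreModel(features=features, penalize=penalize)
    return est.fit(X, y).model_


def composite_training_labels(cohort: pd.DataFrame, cutoff: float = 20.0) -> pd.Series:
    """Training labels: seropositive CeD cases = 1, everyone else = 0."""
    case = cohort["ced_ehr"].astype(bool) | cohort["ced_survey"].astype(bool)
    return (case & seropositive_column(cohort, cutoff)).astype(int)


# ---------------------------------------------------------------------------
# discrimination and calibration


@dataclass
class RocResult:
    """ROC sweep, AUC, and (optionally) a chosen threshold and calibration."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    chosen_threshold: float = float("nan")
    criterion: str = ""
    platt_params: tuple = ()
    brier: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        })


def roc(scores, labels) -> RocResult:
    """ROC sweep and AUC (rank/Mann–Whitney with tie correction).

    Classification at threshold ``t`` is ``score ≥ t``; the sweep runs over
    the unique score values plus a top sentinel where nothing is positive.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal length")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute a ROC curve")

    from scipy.stats import rankdata

    ranks = rankdata(s)  # midranks give the tie-corrected AUC
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    uniq = np.unique(s)
    thresholds = np.r_[uniq, uniq[-1] + 1.0][::-1]
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    pos_scores = np.sort(s[y == 1])
    neg_scores = np.sort(s[y == 0])
    for i, t in enumerate(thresholds):
        tp = n_pos - np.searchsorted(pos_scores, t, side="left")
        tn = np.searchsorted(neg_scores, t, side="left")
        sens[i] = tp / n_pos
        spec[i] = tn / n_neg
    return RocResult(thresholds, sens, spec, float(auc), n_pos, n_neg)


def select_threshold(roc_result: RocResult, criterion: str = "max_accuracy") -> float:
    """Choose a classification threshold from a ROC sweep.

    ``max_accuracy`` maximizes (TP+TN)/N, breaking ties toward higher
    specificity, and returns the midpoint of the indifference gap below the
    optimal cutpoint (so a perfectly separating threshold sits mid-gap).
    ``sensitivity_90`` returns the largest threshold with sensitivity ≥ 0.90.
    """
    t = roc_result.thresholds
    sens, spec = roc_result.sensitivity, roc_result.specificity
    n_pos, n_neg = roc_result.n_pos, roc_result.n_neg
    if criterion == "max_accuracy":
        acc = (sens * n_pos + spec * n_neg) / (n_pos + n_neg)
        best = acc.max()
        ties = np.flatnonzero(np.isclose(acc, best))
        chosen = ties[np.argmax(spec[ties])]
        t_star = t[chosen]
        lower = t[t < t_star]
        if len(lower):
            return float((t_star + lower.max()) / 2.0)
        return float(t_star)
    if criterion == "sensitivity_90":
        ok = np.flatnonzero(sens >= 0.90)
        if len(ok) == 0:
            raise ValueError("no threshold reaches 90% sensitivity")
        return float(t[ok].max())
    raise ValueError(f"unknown threshold criterion {criterion!r}")


class PlattCalibrator:
    """Platt post-hoc calibration: logistic map from raw score to probability.

    Attributes (after ``fit``): ``slope_``, ``intercept_``.
    """

    def __init__(self, penalize: bool = False) -> None:
        self.penalize = penalize

    def get_params(self, deep: bool = True) -> dict:
        return {"penalize": self.penalize}

    def set_params(self, **params) -> "PlattCalibrator":
        for key, value in params.items():
            setattr(self, key, value)
        return self

    def fit(self, scores, labels) -> "PlattCalibrator":
        s = np.asarray(scores, dtype=float).reshape(-1, 1)
        y = np.asarray(labels, dtype=float)
        if y.sum() == 0 or y.sum() == len(y):
            raise ValueError("both classes must be present for calibration")
        if np.ptp(s) == 0:
            # degenerate constant score: probability = prevalence
            self.slope_ = 0.0
            prev = y.mean()
            self.intercept_ = float(math.log(prev / (1 - prev)))
            return self
        if self.penalize:
            intercept, coefs = _ridge_logistic(s, y)
        else:
            intercept, coefs = _irls_logistic(s, y, tol=1e-8, max_iter=100)
        self.slope_ = float(coefs[0])
        self.intercept_ = float(intercept)
        return self

    def predict_proba(self, scores) -> np.ndarray:
        s = np.asarray(scores, dtype=float)
        return 1.0 / (1.0 + np.exp(-(self.slope_ * s + self.intercept_)))


def platt_calibrate(scores, labels, penalize: bool = False):
    """Fit Platt scaling; returns ``((slope, intercept), calibrated_probs)``."""
    cal = PlattCalibrator(penalize=penalize).fit(scores, labels)
    return (cal.slope_, cal.intercept_), cal.predict_proba(scores)


def brier(probs, labels) -> float:
    """Mean squared error between predicted probabilities and outcomes."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if p.shape != y.shape:
        raise ValueError("probs and labels must have equal length")
    return float(np.mean((p - y) ** 2))
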