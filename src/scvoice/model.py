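"""Two-stage Sasang-constitution classifier.

Stage 1 — per-class scores.  For each constitution type k in
{TE, SE, SY} an L1-penalized least-squares regression of the class
indicator on the 21 standardized vocal features gives a sparse affine
score

    eta_k = b_k0 + x' b_k .

The penalty weight lambda is shared across the three fits and chosen
by 10-fold cross-validation on the pooled mean absolute error with the
one-standard-error rule (largest lambda whose CV error is within one
standard error of the minimum).

Stage 2 — age-adjusted multinomial logistic regression on
c = [age, eta1, eta2, eta3] with SY as the reference class:

    log(pi_l / pi_SY) = g_l0 + c' g_l ,   l in {TE, SE},

with class probabilities from the softmax over the two logits and the
zero reference logit, and the predicted type the argmax.

The bundled reference coefficient sets (one per sex) make the deployed
model's arithmetic exactly reproducible; see :mod:`scvoice.published`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import Lasso
from sklearn.model_selection import StratifiedKFold

from .audio import FEATURE_NAMES
from . import published

CLASSES: tuple[str, str, str] = ("TE", "SE", "SY")
REFERENCE_CLASS = "SY"
MLR_INPUTS: tuple[str, ...] = ("age", "eta1", "eta2", "eta3")


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class LassoScoreModel:
    """Per-class affine scores: intercepts (3,) and coefficients (3, 21)."""

    intercepts: np.ndarray
    coefficients: np.ndarray
    lam: float
    sex: str = ""

    def __post_init__(self) -> None:
        icpt = np.asarray(self.intercepts, dtype=np.float64)
        coef = np.asarray(self.coefficients, dtype=np.float64)
        if icpt.shape != (3,) or coef.shape != (3, len(FEATURE_NAMES)):
            raise ModelError(
                f"expected intercepts (3,) and coefficients (3, {len(FEATURE_NAMES)}), "
                f"got {icpt.shape} and {coef.shape}"
            )
        object.__setattr__(self, "intercepts", icpt)
        object.__setattr__(self, "coefficients", coef)


@dataclass(frozen=True)
class MlrModel:
    """TE and SE logits vs the SY reference over [age, eta1, eta2, eta3]."""

    intercepts: np.ndarray  # (2,) for TE, SE
    coefficients: np.ndarray  # (2, 4)
    sex: str = ""
    reference: str = REFERENCE_CLASS

    def __post_init__(self) -> None:
        icpt = np.asarray(self.intercepts, dtype=np.float64)
        coef = np.asarray(self.coefficients, dtype=np.float64)
        if icpt.shape != (2,) or coef.shape != (2, 4):
            raise ModelError(
                f"expected intercepts (2,) and coefficients (2, 4), "
                f"got {icpt.shape} and {coef.shape}"
            )
        object.__setattr__(self, "intercepts", icpt)
        object.__setattr__(self, "coefficients", coef)

    def logits(self, c) -> np.ndarray:
        """The three logits (TE, SE, SY=0) at c = [age, eta1, eta2, eta3]."""
        c = np.asarray(c, dtype=np.float64)
        if c.shape != (4,):
            raise ModelError(f"c must be a 4-vector, got shape {c.shape}")
        return np.append(self.intercepts + self.coefficients @ c, 0.0)


# ---------------------------------------------------------------------------
# stage 1: L1-penalized least squares


def fit_lasso_class(X, y, lam: float) -> tuple[float, np.ndarray]:
    """Minimize sum (y_i - b0 - x_i' b)^2 + lam * sum |b_j|.

    With centred columns the intercept is the response mean.  At
    lam = 0 the solution is ordinary least squares; at
    lam >= lambda_max every coefficient is exactly zero.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ModelError("non-finite values in LASSO inputs")
    if lam < 0:
        raise ModelError("lambda must be non-negative")
    n = X.shape[0]
    if lam == 0.0:
        Xc = np.column_stack([np.ones(n), X])
        beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
        return float(beta[0]), beta[1:]
    # sklearn objective is (1/2n)||r||^2 + alpha ||b||_1 => alpha = lam / (2n)
    est = Lasso(alpha=lam / (2.0 * n), fit_intercept=True, max_iter=200_000, tol=1e-10)
    est.fit(X, y)
    return float(est.intercept_), est.coef_.copy()


def lambda_max(X, y) -> float:
    """Smallest penalty at which all coefficients are zero: 2 max |x_j'(y - ybar)|."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    return float(2.0 * np.max(np.abs(X.T @ (y - y.mean()))))


def _lambda_grid(lam_max: float, n_lambda: int = 100, ratio: float = 1e-4) -> np.ndarray:
    if not lam_max > 0:
        raise ModelError("degenerate lambda grid: lambda_max is not positive")
    return np.geomspace(lam_max, ratio * lam_max, n_lambda)


def cv_mae_table(
    X, labels, folds: int = 10, seed: int | None = 0, n_lambda: int = 100
) -> pd.DataFrame:
    """Cross-validated pooled MAE of the three class-indicator fits.

    Folds are stratified by class.  For each lambda on a log-spaced
    grid from the pooled lambda_max down by four decades, the held-out
    absolute error |1{class k} - eta_k| is pooled over the three
    classes; the table reports the per-fold means, their mean and the
    standard error across folds.
    """
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    n = X.shape[0]
    if n < folds:
        raise ModelError(f"need at least {folds} rows for {folds}-fold CV")
    Y = np.column_stack([(labels == c).astype(float) for c in CLASSES])
    lam_max = max(lambda_max(X, Y[:, k]) for k in range(3))
    grid = _lambda_grid(lam_max, n_lambda=n_lambda)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_mae = np.empty((folds, grid.size))
    for f, (tr, te) in enumerate(skf.split(X, labels)):
        for j, lam in enumerate(grid):
            errs = []
            for k in range(3):
                b0, b = fit_lasso_class(X[tr], Y[tr, k], lam)
                errs.append(np.abs(Y[te, k] - (b0 + X[te] @ b)))
            fold_mae[f, j] = np.mean(np.concatenate(errs))
    mean = fold_mae.mean(axis=0)
    se = fold_mae.std(axis=0, ddof=1) / np.sqrt(folds)
    return pd.DataFrame(
        {"lambda": grid, "mean_mae": mean, "se_mae": se}
    )


def one_se_lambda_from_table(table: pd.DataFrame) -> float:
    """Largest lambda with mean MAE within one SE of the minimum."""
    i_min = int(table["mean_mae"].idxmin())
    cutoff = table.loc[i_min, "mean_mae"] + table.loc[i_min, "se_mae"]
    ok = table.loc[table["mean_mae"] <= cutoff, "lambda"]
    return float(ok.max())


def select_lambda_one_se(
    X, labels, folds: int = 10, seed: int | None = 0, n_lambda: int = 100
) -> tuple[float, pd.DataFrame]:
    """One-standard-error choice of the shared penalty; returns (lambda, CV table)."""
    table = cv_mae_table(X, labels, folds=folds, seed=seed, n_lambda=n_lambda)
    return one_se_lambda_from_table(table), table


def fit_score_model(X, labels, lam: float, sex: str = "") -> LassoScoreModel:
    """Fit the three one-vs-rest indicator regressions at a common lambda."""
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    intercepts = np.empty(3)
    coefs = np.empty((3, X.shape[1]))
    for k, cls in enumerate(CLASSES):
        intercepts[k], coefs[k] = fit_lasso_class(X, (labels == cls).astype(float), lam)
    return LassoScoreModel(intercepts, coefs, lam=lam, sex=sex)


def compute_scores(model: LassoScoreModel, x) -> np.ndarray:
    """eta_k = b_k0 + x' b_k for k = TE, SE, SY."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape == (len(FEATURE_NAMES),):
        return model.intercepts + model.coefficients @ x
    if x.ndim == 2 and x.shape[1] == len(FEATURE_NAMES):
        return model.intercepts[None, :] + x @ model.coefficients.T
    raise ModelError(
        f"x must have {len(FEATURE_NAMES)} features, got shape {x.shape}"
    )


# ---------------------------------------------------------------------------
# stage 2: multinomial logistic regression


def fit_mlr(C, labels, sex: str = "") -> MlrModel:
    """Maximum-likelihood multinomial logit of the labels on
    c = [age, eta1, eta2, eta3], with SY as the reference class.

    Constant input columns (e.g. scores fully shrunk to their
    intercepts) are dropped from the fit and given zero coefficients.
    If the Newton MLE diverges — which happens under (quasi-)complete
    separation, where the unpenalized likelihood has no maximum — the
    model is refitted with a very light L2 stabilizer and a warning.
    """
    import warnings as _warnings

    C = np.asarray(C, dtype=np.float64)
    labels = np.asarray(labels)
    if C.ndim != 2 or C.shape[1] != 4:
        raise ModelError(f"C must be n x 4, got {C.shape}")
    present = set(labels)
    if not set(CLASSES) <= present:
        raise ModelError(f"all three classes required, got {sorted(present)}")
    active = np.ptp(C, axis=0) > 1e-12
    if not active.any():
        raise ModelError("all MLR input columns are constant")
    Ca = C[:, active]
    # category codes with the reference first so its logit is fixed to 0
    order = (REFERENCE_CLASS, "TE", "SE")
    codes = np.array([order.index(lbl) for lbl in labels])
    exog = sm.add_constant(Ca, has_constant="add")

    params = None
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            try:
                fit = sm.MNLogit(codes, exog).fit(
                    method="newton", maxiter=200, disp=False
                )
                if fit.mle_retvals.get("converged", True) and np.all(
                    np.isfinite(np.asarray(fit.params))
                ):
                    params = np.asarray(fit.params)
            except (np.linalg.LinAlgError, ValueError):
                params = None
    if params is None:
        _warnings.warn(
            "multinomial logit MLE diverged (separation or collinear scores); "
            "refitting with a light L2 stabilizer",
            stacklevel=2,
        )
        from sklearn.linear_model import LogisticRegression

        est = LogisticRegression(C=1e3, max_iter=5000, tol=1e-10)
        est.fit(Ca, codes)
        # softmax parametrization -> reference-class logits
        by_code = {c: i for i, c in enumerate(est.classes_)}
        W = np.column_stack([est.intercept_, est.coef_])
        rel = W[[by_code[1], by_code[2]]] - W[by_code[0]]
        params = rel.T  # (k+1, 2), columns TE, SE

    intercepts = params[0, :].copy()
    coefs = np.zeros((2, 4))
    coefs[:, active] = params[1:, :].T
    return MlrModel(intercepts=intercepts, coefficients=coefs, sex=sex)


def class_probabilities(model: MlrModel, c) -> np.ndarray:
    """Softmax class probabilities (TE, SE, SY) at c = [age, eta1..3]."""
    logits = model.logits(c)
    shifted = logits - logits.max()
    e = np.exp(shifted)
    return e / e.sum()


def classify(pi) -> str:
    """Most probable type; ties resolved toward the earlier of TE, SE, SY."""
    pi = np.asarray(pi, dtype=np.float64)
    if pi.shape != (3,) or not np.all(np.isfinite(pi)):
        raise ModelError(f"invalid probability vector {pi!r}")
    return CLASSES[int(np.argmax(pi))]


def predict_cohort(
    score_model: LassoScoreModel, mlr_model: MlrModel, df: pd.DataFrame
) -> pd.DataFrame:
    """Scores, probabilities and predicted type for each cohort row."""
    X = df[list(FEATURE_NAMES)].to_numpy(dtype=float)
    eta = compute_scores(score_model, X)
    out = df.copy()
    out[["eta1", "eta2", "eta3"]] = eta
    C = np.column_stack([df["age"].to_numpy(dtype=float), eta])
    pis = np.vstack([class_probabilities(mlr_model, c) for c in C])
    out[["pi_TE", "pi_SE", "pi_SY"]] = pis
    out["predicted"] = [classify(pi) for pi in pis]
    return out


# ---------------------------------------------------------------------------
# evaluation


def _round1(x: float) -> float:
    """Round to one decimal with halves up, the printed-report convention."""
    return float(np.floor(10.0 * x + 0.5) / 10.0)


@dataclass(frozen=True)
class ConfusionMatrix:
    """3x3 counts, true class by row / predicted by column (TE, SE, SY)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (3, 3):
            raise ModelError("confusion matrix must be 3x3")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        """Overall accuracy in percent, to one decimal."""
        return _round1(100.0 * np.trace(self.counts) / self.total)

    @property
    def sensitivity(self) -> dict[str, float]:
        """Per-class recall in percent, to one decimal."""
        out = {}
        for k, cls in enumerate(CLASSES):
            row = self.counts[k].sum()
            out[cls] = _round1(100.0 * self.counts[k, k] / row) if row else float("nan")
        return out

    def to_dict(self) -> dict:
        return {
            "classes": list(CLASSES),
            "counts": self.counts.tolist(),
            "total": self.total,
            "accuracy_pct": self.accuracy,
            "sensitivity_pct": self.sensitivity,
        }


def evaluate(truth, predicted) -> ConfusionMatrix:
    """Confusion matrix with accuracy and per-class sensitivity."""
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise ModelError("truth and predicted must have equal length")
    if len(truth) == 0:
        raise ModelError("empty label sequences")
    counts = np.zeros((3, 3), dtype=np.int64)
    for t, p in zip(truth, predicted):
        if t not in CLASSES or p not in CLASSES:
            raise ModelError(f"label outside {CLASSES}: ({t!r}, {p!r})")
        counts[CLASSES.index(t), CLASSES.index(p)] += 1
    return ConfusionMatrix(counts)


# ---------------------------------------------------------------------------
# composition, bundled models, serialization


def train_full(
    df: pd.DataFrame, sex: str = "", seed: int | None = 0, folds: int = 10
) -> tuple[LassoScoreModel, MlrModel, float]:
    """Train both stages on a standardized cohort of one sex.

    Selects the shared penalty by the one-SE rule, fits the three
    per-class scores, evaluates them on the training rows, and fits
    the age-adjusted multinomial logit on [age, eta].  Returns
    (score model, MLR model, selected lambda).
    """
    X = df[list(FEATURE_NAMES)].to_numpy(dtype=float)
    labels = df["sc_label"].to_numpy()
    lam, _ = select_lambda_one_se(X, labels, folds=folds, seed=seed)
    score_model = fit_score_model(X, labels, lam, sex=sex)
    eta = compute_scores(score_model, X)
    C = np.column_stack([df["age"].to_numpy(dtype=float), eta])
    mlr_model = fit_mlr(C, labels, sex=sex)
    return score_model, mlr_model, lam


def load_published_model(sex: str) -> tuple[LassoScoreModel, MlrModel]:
    """The bundled reference coefficient sets for ``male`` or ``female``."""
    if sex not in published.SCORE_COEFFICIENTS:
        raise ModelError(f"unknown sex tag {sex!r}; expected 'male' or 'female'")
    score = published.SCORE_COEFFICIENTS[sex]
    intercepts = np.array([score[c]["intercept"] for c in CLASSES])
    coefs = np.zeros((3, len(FEATURE_NAMES)))
    for k, cls in enumerate(CLASSES):
        for feat, val in score[cls]["coefficients"].items():
            coefs[k, FEATURE_NAMES.index(feat)] = val
    mlr = published.MLR_COEFFICIENTS[sex]
    m_icpt = np.array([mlr[l]["intercept"] for l in ("TE", "SE")])
    m_coef = np.array(
        [[mlr[l][v] for v in MLR_INPUTS] for l in ("TE", "SE")]
    )
    return (
        LassoScoreModel(intercepts, coefs, lam=float("nan"), sex=sex),
        MlrModel(m_icpt, m_coef, sex=sex),
    )


def model_to_dict(score_model: LassoScoreModel, mlr_model: MlrModel) -> dict:
    return {
        "sex": score_model.sex,
        "lambda": None if np.isnan(score_model.lam) else score_model.lam,
        "classes": [
            {
                "name": cls,
                "intercept": float(score_model.intercepts[k]),
                "coefficients": {
                    f: float(v) for f, v in zip(FEATURE_NAMES, score_model.coefficients[k])
                },
            }
            for k, cls in enumerate(CLASSES)
        ],
        "mlr": [
            {
                "logit": logit,
                "intercept": float(mlr_model.intercepts[l]),
                **{
                    name: float(v)
                    for name, v in zip(MLR_INPUTS, mlr_model.coefficients[l])
                },
            }
            for l, logit in enumerate(("TE", "SE"))
        ],
        "reference": mlr_model.reference,
    }


def model_from_dict(d: dict) -> tuple[LassoScoreModel, MlrModel]:
    intercepts = np.empty(3)
    coefs = np.empty((3, len(FEATURE_NAMES)))
    by_name = {c["name"]: c for c in d["classes"]}
    for k, cls in enumerate(CLASSES):
        intercepts[k] = by_name[cls]["intercept"]
        coefs[k] = [by_name[cls]["coefficients"][f] for f in FEATURE_NAMES]
    lam = d.get("lambda")
    score = LassoScoreModel(
        intercepts, coefs, lam=float("nan") if lam is None else float(lam), sex=d["sex"]
    )
    by_logit = {m["logit"]: m for m in d["mlr"]}
    m_icpt = np.array([by_logit[l]["intercept"] for l in ("TE", "SE")])
    m_coef = np.array([[by_logit[l][v] for v in MLR_INPUTS] for l in ("TE", "SE")])
    return score, MlrModel(m_icpt, m_coef, sex=d["sex"], reference=d.get("reference", "SY"))


def save_model(path, score_model: LassoScoreModel, mlr_model: MlrModel) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(score_model, mlr_model), fh, indent=2)


def load_model(path) -> tuple[LassoScoreModel, MlrModel]:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
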