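"""Cohort-level cleaning for the vocal-feature diagnosis pipeline.

The cohort is a pandas DataFrame with columns ``subject_id``, ``age``
(years), ``sex`` (``male``/``female``), ``sc_label`` (TE/SE/SY/TY) and
the 21 vocal features.  Cleaning proceeds in a fixed order:

1. eligibility — drop subjects younger than 15 and the rare TY type;
2. robust multivariate outlier removal (projection-pursuit adjusted
   outlyingness with skew-adjusted boxplot fences);
3. moving age standardization — each feature is centred and scaled by
   the mean/SD of subjects within +/-5 years of age, then rescaled so
   every column has overall mean 0 and SD 1;
4. influence screening — leverage, standardized residuals, Cook's
   distance and DFFITS from one-vs-rest binary logistic fits; a row
   exceeding a conventional cutoff on any measure in any fit is
   dropped.

Every excluded subject is recorded with a single reason, assigned in
that order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.stattools import medcouple as _sm_medcouple
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .audio import FEATURE_NAMES

VALID_LABELS = ("TE", "SE", "SY")
COHORT_COLUMNS = ("subject_id", "age", "sex", "sc_label", *FEATURE_NAMES)


class PreprocessingError(ValueError):
    pass


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise PreprocessingError(f"cohort is missing columns: {missing}")
    if df[list(FEATURE_NAMES)].isna().any().any():
        raise PreprocessingError("cohort contains missing feature values")
    if (df["age"] < 0).any():
        raise PreprocessingError("negative ages in cohort")
    return df


@dataclass
class ExclusionReport:
    """Excluded subject ids with one reason each, in application order."""

    reasons: dict[str, str] = field(default_factory=dict)

    ORDER = ("underage", "TY", "outlier", "influential")

    def add(self, ids, reason: str) -> None:
        if reason not in self.ORDER:
            raise ValueError(f"unknown exclusion reason {reason!r}")
        for sid in ids:
            self.reasons.setdefault(str(sid), reason)

    @property
    def counts(self) -> dict[str, int]:
        return {
            r: sum(1 for v in self.reasons.values() if v == r) for r in self.ORDER
        }

    def to_dict(self) -> dict:
        return {"excluded": dict(self.reasons), "counts": self.counts}


def filter_eligibility(
    df: pd.DataFrame, report: ExclusionReport | None = None
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop subjects under 15 years and those labelled TY, in that order."""
    report = report if report is not None else ExclusionReport()
    underage = df["age"] < 15
    report.add(df.loc[underage, "subject_id"], "underage")
    kept = df.loc[~underage]
    ty = kept["sc_label"] == "TY"
    report.add(kept.loc[ty, "subject_id"], "TY")
    return kept.loc[~ty].reset_index(drop=True), report


# ---------------------------------------------------------------------------
# robust univariate tools


def medcouple(values) -> float:
    """Robust skewness in [-1, 1]: the median of the standard kernel
    h(xi, xj) = ((xj - med) - (med - xi)) / (xj - xi) over pairs with
    xi <= med <= xj, with the sign-based kernel for ties at the median.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 1 or x.size < 3:
        raise PreprocessingError("medcouple requires at least 3 one-dimensional values")
    if np.ptp(x) == 0.0:
        raise PreprocessingError("medcouple undefined for constant data")
    return float(_sm_medcouple(x))


def adjusted_boxplot_fences(values) -> tuple[float, float]:
    """Skew-adjusted boxplot whiskers.

    For medcouple MC >= 0 the fences are
    [Q1 - 1.5 exp(-4 MC) IQR, Q3 + 1.5 exp(3 MC) IQR]; for MC < 0 the
    exponents swap to (-3, 4).  At MC = 0 they reduce to the classical
    Tukey fences.  Quartiles use linear interpolation.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size < 4:
        raise PreprocessingError("adjusted boxplot requires at least 4 values")
    mc = medcouple(x)
    q1, q3 = np.quantile(x, [0.25, 0.75])
    iqr = q3 - q1
    if mc >= 0:
        lo, hi = q1 - 1.5 * np.exp(-4.0 * mc) * iqr, q3 + 1.5 * np.exp(3.0 * mc) * iqr
    else:
        lo, hi = q1 - 1.5 * np.exp(-3.0 * mc) * iqr, q3 + 1.5 * np.exp(4.0 * mc) * iqr
    return float(lo), float(hi)


def _univariate_ao(z: np.ndarray) -> np.ndarray:
    """Skew-adjusted outlyingness of each value within its own sample."""
    med = np.median(z)
    lo, hi = adjusted_boxplot_fences(z)
    out = np.zeros_like(z)
    upper = z > med
    if hi > med:
        out[upper] = (z[upper] - med) / (hi - med)
    lower = z < med
    if med > lo:
        out[lower] = (med - z[lower]) / (med - lo)
    return out


def adjusted_outlyingness(
    X, n_directions: int | None = None, seed: int | None = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Projection-pursuit multivariate outlyingness with skewness-aware
    flagging.

    Each row's outlyingness AO_i is the maximum over random projection
    directions (differences of random point pairs, unit-normalized) of
    its skew-adjusted univariate outlyingness along that direction.  A
    row is flagged when its AO exceeds the adjusted-boxplot upper fence
    of the AO distribution, which accommodates the right skew AO
    naturally has.

    Returns ``(ao, flags)``.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise PreprocessingError("X must be a 2-D matrix")
    n, p = X.shape
    if not n > p:
        raise PreprocessingError(f"need more rows than features (n={n}, p={p})")
    if n_directions is None:
        n_directions = 250 * p
    if n_directions < 1:
        raise PreprocessingError("n_directions must be at least 1")
    rng = np.random.default_rng(seed)
    ao = np.zeros(n)
    made = 0
    attempts = 0
    while made < n_directions:
        attempts += 1
        if attempts > 20 * n_directions:
            raise PreprocessingError(
                "could not generate non-degenerate projection directions "
                "(data may be affinely dependent)"
            )
        i, j = rng.integers(0, n, size=2)
        d = X[i] - X[j]
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            continue
        z = X @ (d / norm)
        if np.ptp(z) < 1e-12:
            continue
        try:
            ao = np.maximum(ao, _univariate_ao(z))
        except PreprocessingError:
            continue
        made += 1
    _, hi = adjusted_boxplot_fences(ao)
    return ao, ao > hi


# ---------------------------------------------------------------------------
# moving age standardization


@dataclass
class AgeNorm:
    """Training-derived standardization tables.

    ``window_stats`` maps each integer age on the training grid to the
    per-feature mean/SD of training subjects within the +/-halfwidth
    window; ``final_mean``/``final_sd`` are the column statistics of
    the window-standardized training data used for the final rescale
    to mean 0, SD 1.
    """

    halfwidth: float
    window_stats: dict[int, dict[str, tuple[float, float]]]
    final_mean: dict[str, float]
    final_sd: dict[str, float]

    def ages(self) -> np.ndarray:
        return np.array(sorted(self.window_stats))

    def nearest_age(self, age: float) -> int:
        grid = self.ages()
        return int(grid[np.argmin(np.abs(grid - age))])

    def to_dict(self) -> dict:
        return {
            "halfwidth": self.halfwidth,
            "window_stats": {
                str(a): {f: list(ms) for f, ms in stats.items()}
                for a, stats in self.window_stats.items()
            },
            "final_mean": self.final_mean,
            "final_sd": self.final_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AgeNorm":
        return cls(
            halfwidth=float(d["halfwidth"]),
            window_stats={
                int(a): {f: (float(ms[0]), float(ms[1])) for f, ms in stats.items()}
                for a, stats in d["window_stats"].items()
            },
            final_mean={k: float(v) for k, v in d["final_mean"].items()},
            final_sd={k: float(v) for k, v in d["final_sd"].items()},
        )


def moving_age_standardize(
    train: pd.DataFrame, halfwidth: float = 5.0
) -> tuple[pd.DataFrame, AgeNorm]:
    """Standardize each feature by its moving age-window mean and SD.

    For a subject of age ``a`` each feature is centred and scaled by
    the mean and SD of training subjects with age in ``[a - h, a + h]``
    (windows at the age-range edges simply truncate to the subjects
    available).  Afterwards every column is rescaled to overall mean 0
    and SD 1, matching the convention that the cleaned training matrix
    is fully standardized.
    """
    validate_cohort(train)
    if train.empty:
        raise PreprocessingError("empty training cohort")
    ages = train["age"].to_numpy(dtype=float)
    grid = np.arange(int(np.floor(ages.min())), int(np.ceil(ages.max())) + 1)
    feats = train[list(FEATURE_NAMES)].to_numpy(dtype=float)

    window_stats: dict[int, dict[str, tuple[float, float]]] = {}
    for a in grid:
        mask = np.abs(ages - a) <= halfwidth
        if mask.sum() < 2:
            raise PreprocessingError(
                f"age window [{a - halfwidth}, {a + halfwidth}] contains "
                f"fewer than 2 training subjects"
            )
        mu = feats[mask].mean(axis=0)
        sd = feats[mask].std(axis=0, ddof=1)
        for f, s in zip(FEATURE_NAMES, sd):
            if s <= 0.0:
                raise PreprocessingError(
                    f"zero SD for feature {f} in age window around {a}"
                )
        window_stats[int(a)] = {
            f: (float(m), float(s)) for f, m, s in zip(FEATURE_NAMES, mu, sd)
        }

    partial = _apply_window_stats(train, window_stats)
    z = partial[list(FEATURE_NAMES)].to_numpy(dtype=float)
    fm = z.mean(axis=0)
    fs = z.std(axis=0, ddof=1) if len(train) > 1 else np.ones(z.shape[1])
    if np.any(fs <= 0.0):
        raise PreprocessingError("zero overall SD after window standardization")
    norm = AgeNorm(
        halfwidth=halfwidth,
        window_stats=window_stats,
        final_mean={f: float(m) for f, m in zip(FEATURE_NAMES, fm)},
        final_sd={f: float(s) for f, s in zip(FEATURE_NAMES, fs)},
    )
    out = partial.copy()
    out[list(FEATURE_NAMES)] = (z - fm) / fs
    return out, norm


def _apply_window_stats(
    df: pd.DataFrame, window_stats: dict[int, dict[str, tuple[float, float]]]
) -> pd.DataFrame:
    grid = np.array(sorted(window_stats))
    out = df.copy()
    ages = df["age"].to_numpy(dtype=float)
    nearest = grid[np.argmin(np.abs(ages[:, None] - grid[None, :]), axis=1)]
    for f in FEATURE_NAMES:
        mu = np.array([window_stats[int(a)][f][0] for a in nearest])
        sd = np.array([window_stats[int(a)][f][1] for a in nearest])
        out[f] = (df[f].to_numpy(dtype=float) - mu) / sd
    return out


def apply_age_standardize(test: pd.DataFrame, norm: AgeNorm) -> pd.DataFrame:
    """Standardize a test cohort with training-derived statistics only."""
    validate_cohort(test)
    if not norm.window_stats:
        raise PreprocessingError("empty AgeNorm")
    grid = norm.ages()
    ages = test["age"].to_numpy(dtype=float)
    outside = (ages < grid.min()) | (ages > grid.max())
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} test subject(s) outside the training age range "
            f"[{grid.min()}, {grid.max()}]; nearest-age statistics used",
            stacklevel=2,
        )
    partial = _apply_window_stats(test, norm.window_stats)
    out = partial.copy()
    for f in FEATURE_NAMES:
        out[f] = (partial[f] - norm.final_mean[f]) / norm.final_sd[f]
    return out


def invert_age_standardize(std: pd.DataFrame, norm: AgeNorm) -> pd.DataFrame:
    """Algebraic inverse of :func:`apply_age_standardize`."""
    grid = norm.ages()
    ages = std["age"].to_numpy(dtype=float)
    nearest = grid[np.argmin(np.abs(ages[:, None] - grid[None, :]), axis=1)]
    out = std.copy()
    for f in FEATURE_NAMES:
        mu = np.array([norm.window_stats[int(a)][f][0] for a in nearest])
        sd = np.array([norm.window_stats[int(a)][f][1] for a in nearest])
        z = std[f].to_numpy(dtype=float) * norm.final_sd[f] + norm.final_mean[f]
        out[f] = z * sd + mu
    return out


# ---------------------------------------------------------------------------
# influence screening


@dataclass(frozen=True)
class InfluenceThresholds:
    """Conventional cutoffs; p counts model parameters incl. intercept."""

    dffits_factor: float = 2.0  # |DFFITS| > factor * sqrt(p/n)
    hat_factor: float = 2.0  # hat > factor * p/n
    resid_cutoff: float = 2.0  # |standardized residual| > cutoff
    cooks_factor: float = 4.0  # Cook's D > factor / n


def influence_screen(
    X,
    labels,
    thresholds: InfluenceThresholds = InfluenceThresholds(),
) -> tuple[np.ndarray, pd.DataFrame]:
    """Flag influential rows via one-vs-rest binary logistic diagnostics.

    For each class a binary logistic regression of the one-vs-rest
    indicator on the (standardized) features is fitted and the hat
    values, Pearson standardized residuals, Cook's distances and DFFITS
    are computed from the weighted fit.  A row is influential if it
    exceeds its cutoff on any measure in any of the per-class fits.
    A fit with perfect separation is skipped with a warning.

    Returns ``(flags, measures)`` where ``measures`` has one column per
    (class, measure) pair.
    """
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    n, p_feat = X.shape
    p = p_feat + 1
    exog = sm.add_constant(X, has_constant="add")
    flags = np.zeros(n, dtype=bool)
    cols: dict[str, np.ndarray] = {}
    for cls in VALID_LABELS:
        y = (labels == cls).astype(float)
        if y.min() == y.max():
            raise PreprocessingError(f"one-vs-rest split for {cls} has a single class")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                fit = sm.GLM(y, exog, family=sm.families.Binomial()).fit()
        except (PerfectSeparationError, PerfectSeparationWarning):
            warnings.warn(
                f"perfect separation in the {cls}-vs-rest fit; "
                "influence measures for this split skipped",
                stacklevel=2,
            )
            continue
        infl = fit.get_influence()
        hat = infl.hat_matrix_diag
        resid = fit.resid_pearson / np.sqrt(np.maximum(1.0 - hat, 1e-12))
        cooks = infl.cooks_distance[0]
        dffits = resid * np.sqrt(hat / np.maximum(1.0 - hat, 1e-12))
        cols[f"{cls}_hat"] = hat
        cols[f"{cls}_std_resid"] = resid
        cols[f"{cls}_cooks"] = cooks
        cols[f"{cls}_dffits"] = dffits
        flags |= (
            (np.abs(dffits) > thresholds.dffits_factor * np.sqrt(p / n))
            | (hat > thresholds.hat_factor * p / n)
            | (np.abs(resid) > thresholds.resid_cutoff)
            | (cooks > thresholds.cooks_factor / n)
        )
    return flags, pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# full pipeline


def preprocess_cohort(
    df: pd.DataFrame,
    sex: str | None = None,
    halfwidth: float = 5.0,
    seed: int | None = 0,
    thresholds: InfluenceThresholds = InfluenceThresholds(),
    n_directions: int | None = None,
) -> tuple[pd.DataFrame, AgeNorm, ExclusionReport]:
    """Run the full cleaning chain for one sex.

    Order: eligibility (underage, TY) -> multivariate outlier removal on
    the raw features -> moving age standardization -> influence
    screening on the standardized features.  Outlier detection runs
    within the selected sex, matching the sex-specific models trained
    downstream.
    """
    validate_cohort(df)
    if sex is not None:
        df = df[df["sex"] == sex].reset_index(drop=True)
        if df.empty:
            raise PreprocessingError(f"no subjects with sex={sex!r}")
    kept, report = filter_eligibility(df)
    if kept.empty:
        return kept, AgeNorm(halfwidth, {}, {}, {}), report

    X = kept[list(FEATURE_NAMES)].to_numpy(dtype=float)
    _, out_flags = adjusted_outlyingness(X, n_directions=n_directions, seed=seed)
    report.add(kept.loc[out_flags, "subject_id"], "outlier")
    kept = kept.loc[~out_flags].reset_index(drop=True)

    std, norm = moving_age_standardize(kept, halfwidth=halfwidth)
    infl_flags, _ = influence_screen(
        std[list(FEATURE_NAMES)].to_numpy(dtype=float),
        std["sc_label"].to_numpy(),
        thresholds=thresholds,
    )
    report.add(std.loc[infl_flags, "subject_id"], "influential")
    clean = std.loc[~infl_flags].reset_index(drop=True)
    return clean, norm, report
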