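"""Group-level inference over fROI parameters.

For each ROI parameter a multivariate GLM regresses the parameter on the
group label plus demographic and acquisition nuisance covariates
(mean-centered, intercept excluded from centering).  Continuous
parameters use an ordinary (Gaussian, identity-link) model with
t-referenced coefficients; the binary found-flag uses a binomial model
with a logit link and normal-referenced Wald statistics.

Multiple comparisons are handled with the adjustment

    corrected p = 1 - (1 - p)^m

(the Sidak form), with m = 6 for a priori predictors corrected over the
six ROI parameters per region, m = 12 for the two ADOS scores, and
m = 54 for exploratory predictors (6 parameters x 9 predictors).

Evidence for the null is quantified with the JZS default Bayes factor
(Zellner-Siow Cauchy prior on standardized effect size, scale r), using
the coefficient's t statistic and an effective two-group sample size
n1*n2/(n1+n2).  Collinearity is screened with Belsley condition indices
and variance-decomposition proportions, and a 3-SD screen flags group-B
members outside the group-A distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import integrate, stats

__all__ = [
    "DesignMatrix", "GlmFit", "CollinearityReport",
    "build_design", "fit_gaussian_glm", "fit_binomial_glm",
    "correct_p", "conf_interval", "jzs_bf01", "belsley", "outlier_screen",
    "PerfectSeparationError",
]

#: the nine-column design of the full-sample analysis
FULL_PREDICTORS = ("age", "gender", "group", "modality", "coil",
                   "n_stimuli", "mean_words", "task_type")

_CATEGORICAL_CODES = {
    "gender": {"M": 0.0, "F": 1.0},
    "group": {"NT": 0.0, "ASD": 1.0},
    "modality": {"visual": 0.0, "auditory": 1.0},
    "coil": {"12ch": 0.0, "32ch": 1.0},
    "task_type": {"TF": 0.0, "FITB": 1.0, "MTS": 2.0},
}

_COLUMN_ALIASES = {
    "n_stimuli": "n_stimuli_per_cond",
    "mean_words": "mean_words_per_stim",
}


class PerfectSeparationError(RuntimeError):
    """Logit fit separated perfectly; coefficients diverge."""


@dataclass
class DesignMatrix:
    """Mean-centered predictor matrix with an uncentered intercept."""

    frame: pd.DataFrame  # includes 'intercept' column of ones
    centering: dict[str, float]
    dropped_rows: pd.Index
    dropped_columns: list[str]

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def index(self) -> pd.Index:
        return self.frame.index


@dataclass
class GlmFit:
    parameter: str
    predictor: str
    beta: float
    se: float
    statistic: float
    df: int
    p_uncorrected: float
    p_corrected: float
    ci99: tuple[float, float]
    bf01: float | None
    n_nt: int
    n_asd: int


@dataclass
class CollinearityReport:
    condition_indices: np.ndarray  # nondecreasing, >= 1
    proportions: pd.DataFrame  # predictor x condition-index proportions
    flags: list[tuple[str, int]]  # (predictor, index position) over tolerance


def build_design(records: pd.DataFrame, predictor_list=FULL_PREDICTORS,
                 task_coding: str = "integer") -> DesignMatrix:
    """Code, filter and center the predictor matrix.

    Binary factors are coded 0/1; task type is a single integer-coded
    column by default (preserving the nine-column layout) with
    ``task_coding='dummy'`` available.  Rows with missing values in any
    requested predictor are dropped.  Constant (degenerate) columns are
    excluded with a record in ``dropped_columns``.  All non-intercept
    columns are mean-centered.
    """
    cols = {}
    for name in predictor_list:
        source = _COLUMN_ALIASES.get(name, name)
        if source not in records.columns:
            raise KeyError(f"predictor {name!r} (column {source!r}) missing "
                           f"from cohort table")
        series = records[source]
        if name in _CATEGORICAL_CODES:
            if name == "task_type" and task_coding == "dummy":
                for level in ("FITB", "MTS"):
                    cols[f"task_{level}"] = (series == level).astype(float)
                continue
            coded = series.map(_CATEGORICAL_CODES[name])
            if coded.isna().any() and not series.isna().all():
                bad = series[coded.isna() & series.notna()].unique()
                raise ValueError(f"unknown level(s) {bad!r} in {name!r}")
            cols[name] = coded.astype(float)
        else:
            cols[name] = pd.to_numeric(series, errors="coerce")
    frame = pd.DataFrame(cols, index=records.index)
    complete = frame.notna().all(axis=1)
    dropped_rows = frame.index[~complete]
    frame = frame.loc[complete]

    dropped_columns = [c for c in frame.columns if frame[c].nunique() <= 1]
    frame = frame.drop(columns=dropped_columns)

    centering = {c: float(frame[c].mean()) for c in frame.columns}
    for c in frame.columns:
        frame[c] = frame[c] - centering[c]
    frame.insert(0, "intercept", 1.0)
    return DesignMatrix(frame=frame, centering=centering,
                        dropped_rows=dropped_rows,
                        dropped_columns=dropped_columns)


def _group_counts(records: pd.DataFrame, index) -> tuple[int, int]:
    sub = records.loc[index, "group"] if "group" in records.columns else None
    if sub is None:
        return (len(index), 0)
    return (int((sub == "NT").sum()), int((sub == "ASD").sum()))


def fit_gaussian_glm(y, X: DesignMatrix, records: pd.DataFrame | None = None,
                     parameter: str = "", m: int = 1,
                     bf_predictors=("group",),
                     prior_scale: float = 1.0) -> dict[str, GlmFit]:
    """OLS fit of a continuous ROI parameter on the design.

    Rows where y is missing (ROI not found) are dropped listwise.
    Returns one GlmFit per non-intercept predictor; statistics are
    t-referenced at residual df = n - p.
    """
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    ok = y.notna()
    yv = y[ok].to_numpy()
    Xf = X.frame.loc[ok]
    n, p = Xf.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than design "
                         f"columns ({p})")
    rank = np.linalg.matrix_rank(Xf.to_numpy())
    if rank < p:
        corr = np.corrcoef(Xf.drop(columns="intercept").to_numpy(),
                           rowvar=False)
        dep = [c for i, c in enumerate(Xf.columns[1:])
               if np.any(np.abs(np.delete(corr[i], i)) > 0.999)]
        raise ValueError(f"design is rank deficient; dependent columns "
                         f"likely among {dep}")
    res = sm.OLS(yv, Xf.to_numpy()).fit()
    df = n - p
    n_nt, n_asd = _group_counts(records if records is not None else X.frame,
                                Xf.index)
    return _collect_fits(res.params, res.bse, Xf.columns, df, "t",
                         parameter, m, bf_predictors, prior_scale,
                         n_nt, n_asd)


def fit_binomial_glm(found, X: DesignMatrix,
                     records: pd.DataFrame | None = None,
                     parameter: str = "found", m: int = 1,
                     bf_predictors=("group",),
                     prior_scale: float = 1.0) -> dict[str, GlmFit]:
    """Logit fit of the binary found-flag on the design.

    Wald statistics are referred to the standard normal; df = n - p is
    reported for bookkeeping only.  Perfect separation raises.
    """
    found = pd.Series(np.asarray(found, dtype=float), index=X.index)
    ok = found.notna()
    fv = found[ok].to_numpy()
    Xf = X.frame.loc[ok]
    classes = np.unique(fv)
    if len(classes) < 2:
        raise ValueError("found-flag has a single class; logit model "
                         "is undefined")
    n, p = Xf.shape
    try:
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # separation detected below
            res = sm.GLM(fv, Xf.to_numpy(),
                         family=sm.families.Binomial()).fit(maxiter=200)
    except Exception as exc:
        raise PerfectSeparationError(str(exc)) from exc
    if (np.any(np.abs(res.params) > 30) or np.any(res.bse > 1e3)
            or not np.all(np.isfinite(res.bse))):
        raise PerfectSeparationError(
            "coefficients diverged; data are (quasi-)separated")
    df = n - p
    n_nt, n_asd = _group_counts(records if records is not None else X.frame,
                                Xf.index)
    return _collect_fits(res.params, res.bse, Xf.columns, df, "z",
                         parameter, m, bf_predictors, prior_scale,
                         n_nt, n_asd)


def _collect_fits(params, bses, columns, df, reference, parameter, m,
                  bf_predictors, prior_scale, n_nt, n_asd):
    fits = {}
    for beta, se, name in zip(params, bses, columns):
        if name == "intercept":
            continue
        stat = beta / se
        if reference == "t":
            p_unc = 2.0 * stats.t.sf(abs(stat), df)
            q = stats.t.ppf(0.995, df)
        else:
            p_unc = 2.0 * stats.norm.sf(abs(stat))
            q = stats.norm.ppf(0.995)
        bf = None
        if name in bf_predictors and min(n_nt, n_asd) > 0:
            bf = jzs_bf01(stat, n_nt, n_asd, df, prior_scale=prior_scale)
        fits[name] = GlmFit(
            parameter=parameter, predictor=name, beta=float(beta),
            se=float(se), statistic=float(stat), df=int(df),
            p_uncorrected=float(p_unc),
            p_corrected=float(correct_p(p_unc, m)),
            ci99=(float(beta - q * se), float(beta + q * se)),
            bf01=bf, n_nt=n_nt, n_asd=n_asd)
    return fits


def correct_p(p_uncorrected, m: int):
    """Multiple-comparison adjustment 1 - (1 - p)^m."""
    p = np.asarray(p_uncorrected, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    out = 1.0 - (1.0 - p) ** m
    return float(out) if np.isscalar(p_uncorrected) else out


def conf_interval(beta: float, statistic: float, df: int,
                  level: float = 0.99, reference: str = "t"):
    """Symmetric CI recovered from a coefficient and its statistic.

    se = beta/statistic; bounds are beta -/+ q*se with q the (1+level)/2
    quantile of the t distribution at df (or the normal for Wald fits).
    """
    if statistic == 0:
        raise ValueError("statistic must be nonzero to recover the se")
    if df < 1:
        raise ValueError("df must be >= 1")
    se = abs(beta / statistic)
    if level <= 0:
        return (beta, beta)
    if reference == "t":
        q = stats.t.ppf(0.5 + level / 2.0, df)
    else:
        q = stats.norm.ppf(0.5 + level / 2.0)
    return (beta - q * se, beta + q * se)


def jzs_bf01(statistic: float, n1: int, n2: int, df: int,
             prior_scale: float = 1.0) -> float:
    """JZS default Bayes factor for the null over the alternative.

    Two-sample form (Rouder et al.): effective sample size
    N = n1*n2/(n1+n2); the alternative places a Cauchy(0, r) prior on the
    standardized effect, integrated numerically over the implied
    inverse-chi-square mixing variable g.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    if df < 1:
        raise ValueError("df must be >= 1")
    t = float(statistic)
    v = float(df)
    N = n1 * n2 / (n1 + n2)
    r = float(prior_scale)

    def log_integrand(g):
        return (-0.5 * np.log1p(N * g)
                - (v + 1) / 2.0 * np.log1p(t * t / ((1 + N * g) * v))
                - 0.5 * np.log(2 * np.pi) + np.log(r)
                - 1.5 * np.log(g) - r * r / (2 * g))

    def integrand(g):
        return np.exp(log_integrand(g))

    num, err = integrate.quad(integrand, 0, np.inf, limit=400,
                              epsabs=0.0, epsrel=1e-10)
    if not np.isfinite(num) or num <= 0 or err > 1e-6 * num:
        raise RuntimeError(
            f"Bayes factor integration failed: value={num}, err={err}")
    log_den = -(v + 1) / 2.0 * np.log1p(t * t / v)
    return float(np.exp(log_den) / num)


def belsley(X: DesignMatrix | np.ndarray,
            index_tolerance: float = 30.0,
            proportion_tolerance: float = 0.5) -> CollinearityReport:
    """Belsley condition-index / variance-decomposition diagnosis.

    Columns are scaled to unit length; condition indices are
    sigma_max/sigma_k of the scaled matrix; each predictor's variance is
    decomposed over singular values via the squared right-singular-vector
    loadings, normalized to sum to 1 per predictor.  Flags (predictor,
    condition-index position) pairs where the proportion exceeds 0.5 at a
    condition index above 30 (MATLAB ``collintest`` tolerances).
    """
    if isinstance(X, DesignMatrix):
        mat = X.values
        names = X.columns
    else:
        mat = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(mat.shape[1])]
    if mat.size == 0:
        raise ValueError("empty design")
    norms = np.linalg.norm(mat, axis=0)
    if np.any(norms == 0):
        raise ValueError("design contains a zero column")
    scaled = mat / norms
    _, s, vt = np.linalg.svd(scaled, full_matrices=False)
    cond = s[0] / s  # nondecreasing, >= 1
    phi = (vt.T ** 2) / (s ** 2)  # predictors x singular values
    proportions = phi / phi.sum(axis=1, keepdims=True)
    prop_df = pd.DataFrame(proportions, index=names,
                           columns=[f"ci_{i}" for i in range(len(s))])
    flags = [(names[j], int(k))
             for j in range(len(names))
             for k in range(len(s))
             if proportions[j, k] > proportion_tolerance
             and cond[k] > index_tolerance]
    return CollinearityReport(condition_indices=cond, proportions=prop_df,
                              flags=flags)


def outlier_screen(values, groups, k: float = 3.0,
                   reference_group: str = "NT",
                   test_group: str = "ASD") -> pd.Series:
    """Members of the test group beyond k SD of the reference group.

    Returns the subset of test-group values with |z| > k, where z is
    standardized by the reference group's mean and SD.
    """
    values = pd.Series(np.asarray(values, dtype=float))
    groups = pd.Series(np.asarray(groups, dtype=object),
                       index=values.index)
    ref = values[(groups == reference_group) & values.notna()]
    if len(ref) < 2:
        raise ValueError("need >= 2 reference-group values")
    sd = ref.std(ddof=1)
    if sd == 0:
        raise ValueError("reference group has zero SD")
    test = values[(groups == test_group) & values.notna()]
    z = (test - ref.mean()) / sd
    return test[np.abs(z) > k]
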