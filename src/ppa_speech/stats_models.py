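"""Group comparisons, predictor screening, discriminant fit, and the
published diagnostic index models.

The discriminant "fit" is deliberately ordinary least squares of a 0/1
group code on the screened predictors (two-group discriminant analysis
via linear regression), not canonical LDA.  The two published models are
exposed with their printed coefficients:

* Model 1 (silence + duration): constant 2.387, arcsin-transformed
  proportion of silence time -2.057, silence-duration MAD (seconds)
  +2.991, |PVI duration WS| -0.010.  The source table prints B = +0.010
  for the PVI term against a negative standardized coefficient and t
  statistic; the sign here follows the standardized coefficient and is
  overridable via the ``coefficients`` argument.
* Model 2 (duration only): constant 1.763, |PVI duration WS| -0.008,
  |PVI duration SW| -0.007.

Rounding the continuous index to zero decimals (half away from zero,
clamped to {0, 1}) gives the class code: 0 = lvPPA, 1 = nfvPPA.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ComputationError, ValidationError

__all__ = [
    "FEATURE_COLUMNS",
    "MODEL1_COEFFICIENTS",
    "MODEL2_COEFFICIENTS",
    "GROUP_CODES",
    "DFAFit",
    "DiagnosticResult",
    "PairwiseComparison",
    "MedianTestResult",
    "ScreenResult",
    "moment_screen",
    "anova_oneway",
    "tukey_kramer",
    "median_test",
    "collinearity_screen",
    "mahalanobis_screen",
    "chi2_critical",
    "fit_dfa",
    "duration_index",
    "silence_duration_index",
]

#: Canonical feature-table columns (subject metadata + predictors).
FEATURE_COLUMNS = [
    "subject_id",
    "group",
    "arcsin_pst",
    "mad_silence_s",
    "median_silence_s",
    "pvi_dur_ws",
    "pvi_dur_sw",
    "pvi_int_ws",
    "pvi_int_sw",
]

GROUP_CODES = {"lvPPA": 0, "nfvPPA": 1}
_CODE_LABELS = {0: "lvPPA", 1: "nfvPPA"}

MODEL1_COEFFICIENTS: Mapping[str, float] = {
    "constant": 2.387,
    "arcsin_pst": -2.057,
    "mad_silence_s": 2.991,
    "pvi_dur_ws": -0.010,
}
MODEL2_COEFFICIENTS: Mapping[str, float] = {
    "constant": 1.763,
    "pvi_dur_ws": -0.008,
    "pvi_dur_sw": -0.007,
}


@dataclass(frozen=True)
class DiagnosticResult:
    """Continuous diagnostic index plus the rounded 0/1 class."""

    index: float
    class_code: int
    label: str


@dataclass(frozen=True)
class DFAFit:
    """OLS discriminant fit: per-predictor coefficients and fit summary."""

    predictors: tuple[str, ...]
    b: np.ndarray
    se: np.ndarray
    beta: np.ndarray
    t: np.ndarray
    p: np.ndarray
    constant: float
    constant_se: float
    constant_t: float
    constant_p: float
    r2: float
    n: int
    df_resid: int

    def to_dict(self) -> dict:
        return {
            "predictors": list(self.predictors),
            "b": self.b.tolist(),
            "se": self.se.tolist(),
            "beta": self.beta.tolist(),
            "t": self.t.tolist(),
            "p": self.p.tolist(),
            "constant": self.constant,
            "constant_se": self.constant_se,
            "constant_t": self.constant_t,
            "constant_p": self.constant_p,
            "r2": self.r2,
            "n": self.n,
            "df_resid": self.df_resid,
        }

    def coefficients(self) -> dict[str, float]:
        """Coefficient mapping usable by the index evaluators."""
        out = {"constant": self.constant}
        out.update(zip(self.predictors, self.b.tolist()))
        return out


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: int
    group_b: int
    mean_diff: float
    q: float
    p: float
    significant: bool


@dataclass(frozen=True)
class MedianTestResult:
    p: float
    statistic: float | None
    method: str
    grand_median: float
    table: np.ndarray  # 2 x k: above / not-above counts per group


@dataclass(frozen=True)
class ScreenResult:
    retained: tuple[str, ...]
    excluded: tuple[str, ...]
    correlations: pd.DataFrame


def _as_groups(groups: Sequence[Sequence[float]], min_n: int = 2) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValidationError("need at least 2 groups")
    for i, g in enumerate(arrays):
        if g.size < min_n:
            raise ValidationError(f"group {i} has n={g.size} < {min_n}")
        if not np.all(np.isfinite(g)):
            raise ValidationError(f"group {i} contains non-finite values")
    return arrays


def moment_screen(x: Sequence[float]) -> tuple[float, float]:
    """Sample skewness and excess kurtosis (adjusted/bias-corrected forms).

    Uses the adjusted Fisher-Pearson skewness and the adjusted Fisher
    excess kurtosis, matching common statistics-package output.
    """
    arr = np.asarray(x, dtype=float)
    if arr.size < 3:
        raise ValidationError(f"moment screen needs n >= 3, got {arr.size}")
    if np.ptp(arr) == 0:
        raise ComputationError("moment screen undefined for zero-variance data")
    skew = float(sps.skew(arr, bias=False))
    if arr.size < 4:
        kurt = float("nan")
    else:
        kurt = float(sps.kurtosis(arr, bias=False, fisher=True))
    return skew, kurt


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, int, int, float]:
    """One-way ANOVA: ``(F, df_between, df_within, p)``."""
    arrays = _as_groups(groups)
    if np.ptp(np.concatenate(arrays)) == 0:
        raise ComputationError("ANOVA undefined: all values identical")
    k = len(arrays)
    n = sum(g.size for g in arrays)
    res = sps.f_oneway(*arrays)
    return float(res.statistic), k - 1, n - k, float(res.pvalue)


def tukey_kramer(
    groups: Sequence[Sequence[float]], alpha: float = 0.05
) -> list[PairwiseComparison]:
    """Tukey HSD pairwise comparisons with the Kramer unequal-n correction.

    For each pair, ``q = |mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j))``
    is referred to the studentized-range distribution with ``k`` groups
    and the within-group degrees of freedom.
    """
    arrays = _as_groups(groups)
    k = len(arrays)
    n = sum(g.size for g in arrays)
    df_w = n - k
    ssw = sum(float(((g - g.mean()) ** 2).sum()) for g in arrays)
    msw = ssw / df_w
    if msw <= 0:
        raise ComputationError("within-group variance is zero; Tukey-Kramer undefined")
    out = []
    for i, j in itertools.combinations(range(k), 2):
        gi, gj = arrays[i], arrays[j]
        diff = float(gi.mean() - gj.mean())
        se = math.sqrt(msw / 2.0 * (1.0 / gi.size + 1.0 / gj.size))
        q = abs(diff) / se
        p = float(sps.studentized_range.sf(q, k, df_w))
        out.append(PairwiseComparison(i, j, diff, q, p, p < alpha))
    return out


def median_test(groups: Sequence[Sequence[float]]) -> MedianTestResult:
    """Independent-samples median test.

    Values are classified as above vs not-above the pooled grand median;
    independence of group and side is tested with a chi-square test, or
    Fisher's exact test for two groups when any expected count is < 5.
    """
    arrays = _as_groups(groups, min_n=1)
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise ComputationError("median test undefined: all values equal")
    grand = float(np.median(pooled))
    above = np.array([int((g > grand).sum()) for g in arrays])
    not_above = np.array([g.size for g in arrays]) - above
    table = np.vstack([above, not_above])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        raise ComputationError("degenerate median-test table (empty row or column)")
    expected = sps.contingency.expected_freq(table)
    if table.shape[1] == 2 and expected.min() < 5:
        _, p = sps.fisher_exact(table, alternative="two-sided")
        return MedianTestResult(float(p), None, "fisher-exact", grand, table)
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return MedianTestResult(float(p), float(chi2), "chi-square", grand, table)


def collinearity_screen(
    features: pd.DataFrame,
    predictors: Sequence[str],
    cutoff: float = 0.80,
    drop_priority: Sequence[str] = ("median_silence_s",),
) -> ScreenResult:
    """Exclude predictors involved in pairwise ``|r| > cutoff``.

    For each offending pair, the member listed earlier in
    ``drop_priority`` is dropped; if neither is listed, the one with the
    larger mean absolute correlation to the remaining predictors goes
    (deterministic tie-break by column order).
    """
    predictors = list(predictors)
    if len(predictors) < 2:
        raise ValidationError("collinearity screen needs >= 2 predictors")
    sub = features[predictors].astype(float)
    if len(sub) < 3:
        raise ValidationError("collinearity screen needs >= 3 subjects")
    if (sub.std(ddof=1) == 0).any():
        const = sub.columns[(sub.std(ddof=1) == 0)].tolist()
        raise ComputationError(f"constant predictor(s): {const}")
    corr = sub.corr(method="pearson")
    excluded: list[str] = []
    active = list(predictors)
    while True:
        worst: tuple[float, str] | None = None
        for a, b in itertools.combinations(active, 2):
            r = abs(float(corr.loc[a, b]))
            if r > cutoff and (worst is None or r > worst[0]):
                worst = (r, _pick_drop(a, b, corr, active, drop_priority))
        if worst is None:
            break
        active.remove(worst[1])
        excluded.append(worst[1])
    return ScreenResult(tuple(active), tuple(excluded), corr)


def _pick_drop(a, b, corr, active, drop_priority) -> str:
    for name in drop_priority:
        if name == a:
            return a
        if name == b:
            return b
    others = [c for c in active if c not in (a, b)]
    if others:
        ma = float(corr.loc[a, others].abs().mean())
        mb = float(corr.loc[b, others].abs().mean())
        if ma != mb:
            return a if ma > mb else b
    return b


def mahalanobis_screen(
    x: np.ndarray | pd.DataFrame, alpha: float = 0.001
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-row squared Mahalanobis distances with outlier flags.

    Distances use the sample covariance (n-1 denominator) and are
    compared with the upper-``alpha`` chi-square critical value at
    ``df = n_features``.  Returns ``(d2, flags, critical)``.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    n, p = arr.shape
    if n < p + 1:  # sample covariance must be invertible
        raise ValidationError(f"need n >= n_features + 1, got n={n}, features={p}")
    mean = arr.mean(axis=0)
    cov = np.cov(arr, rowvar=False, ddof=1).reshape(p, p)
    try:
        inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise ComputationError(f"singular sample covariance: {exc}") from exc
    centred = arr - mean
    d2 = np.einsum("ij,jk,ik->i", centred, inv, centred)
    critical = chi2_critical(p, alpha)
    return d2, d2 > critical, critical


def chi2_critical(df: int, alpha: float) -> float:
    """Upper-tail chi-square critical value: P(X > c) = alpha."""
    if df < 1:
        raise ValidationError(f"df must be >= 1, got {df}")
    if not (0 < alpha < 1):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    return float(sps.chi2.isf(alpha, df))


def fit_dfa(
    features: pd.DataFrame | np.ndarray,
    outcome: Sequence[float] | str,
    predictors: Sequence[str] | None = None,
) -> DFAFit:
    """Two-group discriminant fit as OLS of a 0/1 group code on predictors.

    ``features`` may be a DataFrame (with ``predictors`` naming columns,
    and ``outcome`` either a column name or a vector) or a plain matrix.
    Reports unstandardized coefficients with standard errors, t and p
    (two-sided, residual df), standardized coefficients
    ``beta_j = b_j * sd(x_j) / sd(y)``, and r².
    """
    if isinstance(features, pd.DataFrame):
        if predictors is None:
            raise ValidationError("predictors must be named when passing a DataFrame")
        missing = [c for c in predictors if c not in features.columns]
        if missing:
            raise ValidationError(f"predictor column(s) not in table: {missing}")
        xmat = features[list(predictors)].to_numpy(dtype=float)
        if isinstance(outcome, str):
            if outcome not in features.columns:
                raise ValidationError(f"outcome column {outcome!r} not in table")
            yraw = features[outcome].to_numpy()
        else:
            yraw = np.asarray(outcome)
        names = tuple(predictors)
    else:
        xmat = np.asarray(features, dtype=float)
        if xmat.ndim == 1:
            xmat = xmat[:, None]
        yraw = np.asarray(outcome)
        names = tuple(predictors) if predictors else tuple(f"x{i}" for i in range(xmat.shape[1]))

    if yraw.dtype.kind in "OUS":
        try:
            y = np.array([GROUP_CODES[str(v)] for v in yraw], dtype=float)
        except KeyError as exc:
            raise ValidationError(f"unknown group label {exc}; expected {set(GROUP_CODES)}") from exc
    else:
        y = yraw.astype(float)

    n, p = xmat.shape
    if n != y.size:
        raise ValidationError(f"outcome length {y.size} != n rows {n}")
    if n <= p + 1:
        raise ValidationError(f"need n > predictors + 1, got n={n}, predictors={p}")
    design = np.column_stack([np.ones(n), xmat])
    if np.linalg.matrix_rank(design) < p + 1:
        raise ComputationError("rank-deficient design matrix (collinear predictors)")
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    df_resid = n - p - 1
    rss = float(resid @ resid)
    s2 = rss / df_resid
    cov = s2 * np.linalg.inv(design.T @ design)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = coef / se
    pvals = 2.0 * sps.t.sf(np.abs(tvals), df_resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    sy = float(np.std(y, ddof=1))
    sx = np.std(xmat, axis=0, ddof=1)
    beta = coef[1:] * sx / sy
    return DFAFit(
        predictors=names,
        b=coef[1:],
        se=se[1:],
        beta=beta,
        t=tvals[1:],
        p=pvals[1:],
        constant=float(coef[0]),
        constant_se=float(se[0]),
        constant_t=float(tvals[0]),
        constant_p=float(pvals[0]),
        r2=r2,
        n=n,
        df_resid=df_resid,
    )


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def _classify(index: float) -> DiagnosticResult:
    code = min(1, max(0, _round_half_away(index)))
    return DiagnosticResult(index=index, class_code=code, label=_CODE_LABELS[code])


def duration_index(
    pvi_dur_ws_abs: float,
    pvi_dur_sw_abs: float,
    coefficients: Mapping[str, float] = MODEL2_COEFFICIENTS,
) -> DiagnosticResult:
    """Model 2 diagnostic index from absolute duration-PVI medians.

    ``index = constant + c_ws * |PVI_WS| + c_sw * |PVI_SW|``; the rounded
    index gives class 0 (lvPPA) or 1 (nfvPPA).  Monotone non-increasing
    in each argument with the default (negative) coefficients: lower
    contrastiveness is more nfvPPA-like.
    """
    if pvi_dur_ws_abs < 0 or pvi_dur_sw_abs < 0:
        raise ValidationError(
            "duration_index expects absolute (non-negative) PVI values, got "
            f"ws={pvi_dur_ws_abs}, sw={pvi_dur_sw_abs}"
        )
    index = (
        coefficients["constant"]
        + coefficients["pvi_dur_ws"] * pvi_dur_ws_abs
        + coefficients["pvi_dur_sw"] * pvi_dur_sw_abs
    )
    return _classify(index)


def silence_duration_index(
    arcsin_pst: float,
    mad_silence_s: float,
    pvi_dur_ws_abs: float,
    coefficients: Mapping[str, float] = MODEL1_COEFFICIENTS,
) -> DiagnosticResult:
    """Model 1 diagnostic index from silence and duration-PVI features.

    ``arcsin_pst`` is consumed already arcsin-transformed (radians);
    ``mad_silence_s`` is in seconds (values > 5 s trigger a unit-check
    warning, as they suggest milliseconds were passed).
    """
    if not (0.0 <= arcsin_pst <= math.pi / 2 + 1e-9):
        raise ValidationError(f"arcsin_pst must be in [0, pi/2], got {arcsin_pst}")
    if pvi_dur_ws_abs < 0:
        raise ValidationError("silence_duration_index expects an absolute PVI value")
    if mad_silence_s > 5.0:
        warnings.warn(
            f"mad_silence_s={mad_silence_s} looks like milliseconds; "
            "this model expects seconds",
            stacklevel=2,
        )
    index = (
        coefficients["constant"]
        + coefficients["arcsin_pst"] * arcsin_pst
        + coefficients["mad_silence_s"] * mad_silence_s
        + coefficients["pvi_dur_ws"] * pvi_dur_ws_abs
    )
    return _classify(index)
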