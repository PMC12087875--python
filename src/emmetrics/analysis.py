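"""Descriptive analyses of a derived cohort.

Summary tables (emmetropic subset vs entire cohort), Pearson correlation
matrices with Bonferroni masking, 1 D refractive binning, anterior-segment
alignment regressions with per-refractive-group slopes, uniqueness pair
counting at instrument repeatability, and the relative (AL-scaled) geometry
profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .optics import scale_to_al

__all__ = [
    "EmmetropiaCriterion",
    "UniquenessSpec",
    "RegressionResult",
    "emmetropic_mask",
    "descriptive_table",
    "correlation_matrix",
    "binned_group_summary",
    "se_bin_index",
    "fit_alignment_regressions",
    "uniqueness_pairs",
    "relative_scaling_profile",
    "BONFERRONI_ALPHA",
]

#: Significance threshold with the Bonferroni correction for the 11
#: parameter comparisons: 0.05 / 11.
BONFERRONI_ALPHA = 0.05 / 11

#: Parameter order of the descriptive table: (column, unit).
_TABLE_PARAMS = [
    ("age_y", "years"), ("SE_D", "D"), ("CCT_mm", "mm"), ("AD_mm", "mm"),
    ("LT_mm", "mm"), ("VCD_mm", "mm"), ("AL_mm", "mm"), ("P_c_D", "D"),
    ("P_lb_D", "D"), ("P_eye_D", "D"), ("P_ax_D", "D"),
]

#: Parameter order of the correlation matrix.
_CORR_PARAMS = ["SE_D", "AD_mm", "LT_mm", "VCD_mm", "AL_mm",
                "P_c_D", "P_lb_D", "P_eye_D", "P_ax_D"]


@dataclass(frozen=True)
class EmmetropiaCriterion:
    """Refractive definition of emmetropia: ``lower <= SE <= upper`` (D)."""

    lower: float = -0.5
    upper: float = 0.5
    lower_inclusive: bool = True
    upper_inclusive: bool = True

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("lower bound must be below upper bound")

    def mask(self, se) -> np.ndarray:
        se = np.asarray(se, dtype=float)
        lo = se >= self.lower if self.lower_inclusive else se > self.lower
        hi = se <= self.upper if self.upper_inclusive else se < self.upper
        return lo & hi


def emmetropic_mask(df: pd.DataFrame,
                    criterion: EmmetropiaCriterion = EmmetropiaCriterion()) -> np.ndarray:
    return criterion.mask(df["SE_D"])


@dataclass(frozen=True)
class UniquenessSpec:
    """Indistinguishability tolerances from instrument repeatability.

    Two eyes are indistinguishable when every listed parameter differs by at
    most ``limit_factor`` (limits of agreement, 1.96) times its
    repeatability.
    """

    parameters: tuple[str, ...] = ("SE_D", "P_c_D", "P_lb_D", "ACD_tot_mm", "LT_mm", "AL_mm")
    repeatabilities: tuple[float, ...] = (0.25, 0.12, 0.25, 0.009, 0.015, 0.019)
    limit_factor: float = 1.96

    def __post_init__(self) -> None:
        if len(self.parameters) != len(self.repeatabilities):
            raise ValueError("one repeatability per parameter required")
        if any(r <= 0 for r in self.repeatabilities):
            raise ValueError("repeatabilities must be positive")

    @property
    def tolerances(self) -> np.ndarray:
        return self.limit_factor * np.asarray(self.repeatabilities)


class RegressionResult(NamedTuple):
    response: str
    slope: float
    intercept: float
    r2: float
    residual_sd: float
    n: int
    al_window: tuple[float, float]


# ---------------------------------------------------------------------------


def descriptive_table(derived: pd.DataFrame,
                      criterion: EmmetropiaCriterion = EmmetropiaCriterion()) -> pd.DataFrame:
    """Two-group summary: emmetropic subset vs the entire cohort.

    One row per parameter in the conventional order, with mean, SD, range
    and group size for both groups, the unpaired two-sample t statistic
    comparing the emmetropic eyes with the *entire* cohort (the groups
    overlap by design — the emmetropic eyes are a subset), and significance
    at the Bonferroni-corrected ``0.05/11``.
    """
    if len(derived) == 0:
        raise ValueError("empty cohort")
    emm = derived[emmetropic_mask(derived, criterion)]
    if len(emm) == 0:
        import warnings
        warnings.warn("no emmetropic eyes under the given criterion")
    rows = []
    for col, unit in _TABLE_PARAMS:
        if col not in derived or derived[col].isna().all():
            continue
        a = emm[col].to_numpy(dtype=float)
        b = derived[col].to_numpy(dtype=float)
        if len(a) >= 2 and len(b) >= 2 and (np.std(a) > 0 or np.std(b) > 0):
            t, p = stats.ttest_ind(a, b, equal_var=True)
        else:
            t, p = np.nan, np.nan
        rows.append({
            "parameter": col, "unit": unit,
            "emmetropic_n": len(a),
            "emmetropic_mean": a.mean() if len(a) else np.nan,
            "emmetropic_sd": a.std(ddof=1) if len(a) > 1 else (0.0 if len(a) else np.nan),
            "emmetropic_min": a.min() if len(a) else np.nan,
            "emmetropic_max": a.max() if len(a) else np.nan,
            "all_n": len(b),
            "all_mean": b.mean(),
            "all_sd": b.std(ddof=1) if len(b) > 1 else 0.0,
            "all_min": b.min(),
            "all_max": b.max(),
            "t_p_value": p,
            "significant": bool(p < BONFERRONI_ALPHA) if np.isfinite(p) else False,
        })
    return pd.DataFrame(rows).set_index("parameter")


class CorrelationMatrices(NamedTuple):
    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame  # boolean mask at the Bonferroni threshold


def correlation_matrix(derived: pd.DataFrame, subset=None,
                       parameters=None,
                       alpha: float = BONFERRONI_ALPHA) -> CorrelationMatrices:
    """Pairwise Pearson correlations with p-values and a significance mask.

    Zero-variance columns give NaN r with p = 1 (flagged, not propagated).
    ``subset`` is an optional boolean mask restricting the rows (e.g. the
    emmetropic eyes).
    """
    params = [p for p in (parameters or _CORR_PARAMS) if p in derived]
    df = derived if subset is None else derived[np.asarray(subset, bool)]
    if len(df) < 3:
        raise ValueError("need at least 3 rows for correlations")
    k = len(params)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            x = df[params[i]].to_numpy(float)
            y = df[params[j]].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = 1.0
            else:
                res = stats.pearsonr(x, y)
                r[i, j] = r[j, i] = res.statistic
                p[i, j] = p[j, i] = res.pvalue
    rf = pd.DataFrame(r, index=params, columns=params)
    pf = pd.DataFrame(p, index=params, columns=params)
    sig = (pf < alpha) & np.isfinite(rf) & ~np.eye(k, dtype=bool)
    return CorrelationMatrices(rf, pf, sig)


def se_bin_index(se, bin_width: float = 1.0):
    """Refractive bin of each eye: integer-centred, half-integer edges.

    Left-closed convention: SE = 0.49 D falls in bin 0, SE = 0.50 D in
    bin 1.
    """
    se = np.asarray(se, dtype=float)
    return np.floor(se / bin_width + 0.5).astype(int)


def binned_group_summary(derived: pd.DataFrame, bin_width: float = 1.0,
                         parameters=("P_c_D", "P_lb_D", "ACD_tot_mm", "AL_mm"),
                         min_n_ci: int = 3) -> pd.DataFrame:
    """Per-refractive-bin means with 95% confidence intervals.

    Rows are (bin centre, parameter); bins with fewer than ``min_n_ci``
    eyes are reported with suppressed (NaN) confidence limits.
    """
    if len(derived) == 0:
        raise ValueError("empty cohort")
    bins = se_bin_index(derived["SE_D"], bin_width)
    rows = []
    for b in np.unique(bins):
        sel = derived[bins == b]
        for par in parameters:
            if par not in sel:
                continue
            v = sel[par].to_numpy(float)
            n = len(v)
            mean = v.mean()
            if n >= min_n_ci and np.std(v) > 0:
                half = stats.t.ppf(0.975, n - 1) * v.std(ddof=1) / np.sqrt(n)
                lo, hi = mean - half, mean + half
            else:
                lo = hi = np.nan
            rows.append({"bin_center": b * bin_width, "parameter": par,
                         "n": n, "mean": mean, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


def _ols(y: np.ndarray, x: np.ndarray, response: str,
         window: tuple[float, float]) -> RegressionResult:
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    resid_sd = float(np.std(fit.resid, ddof=2))
    return RegressionResult(response, float(fit.params[1]), float(fit.params[0]),
                            float(fit.rsquared), resid_sd, int(len(y)), window)


@dataclass
class AlignmentRegressions:
    """Anterior-segment alignment vs axial length."""

    acd_tot: RegressionResult
    asl: RegressionResult
    group_slopes: pd.DataFrame = field(default_factory=pd.DataFrame)


def fit_alignment_regressions(derived: pd.DataFrame,
                              al_window: tuple[float, float] = (20.0, 27.0),
                              bin_width: float = 1.0,
                              min_group_n: int = 20) -> AlignmentRegressions:
    """OLS of ACD_tot and ASL on AL, plus per-refractive-group slopes.

    The fit is restricted to eyes with AL inside ``al_window`` (beyond
    ~27 mm the anterior segment no longer tracks axial length).  Group
    slopes regress P_c, P_lb and ACD_tot on AL within each 1 D refractive
    bin holding at least ``min_group_n`` eyes.
    """
    al = derived["AL_mm"].to_numpy(float)
    sel = (al >= al_window[0]) & (al <= al_window[1])
    sub = derived[sel]
    if len(sub) < 10:
        raise ValueError(f"fewer than 10 eyes inside the AL window {al_window}")
    x = sub["AL_mm"].to_numpy(float)
    if np.std(x) == 0:
        raise ValueError("degenerate axial-length variance in window")
    acd = _ols(sub["ACD_tot_mm"].to_numpy(float), x, "ACD_tot_mm", al_window)
    asl = _ols(sub["ASL_mm"].to_numpy(float), x, "ASL_mm", al_window)

    rows = []
    bins = se_bin_index(sub["SE_D"], bin_width)
    for b in np.unique(bins):
        grp = sub[bins == b]
        if len(grp) < min_group_n or np.std(grp["AL_mm"]) == 0:
            continue
        for par in ("P_c_D", "P_lb_D", "ACD_tot_mm"):
            res = _ols(grp[par].to_numpy(float), grp["AL_mm"].to_numpy(float), par, al_window)
            rows.append({"bin_center": b * bin_width, "parameter": par,
                         "slope": res.slope, "intercept": res.intercept,
                         "r2": res.r2, "n": res.n})
    return AlignmentRegressions(acd, asl, pd.DataFrame(rows))


def uniqueness_pairs(derived: pd.DataFrame,
                     spec: UniquenessSpec = UniquenessSpec(),
                     subset=None) -> tuple[int, list[tuple[object, object]]]:
    """Count indistinguishable eye pairs at instrument repeatability.

    Exhaustive comparison of all unordered pairs: a pair counts iff the
    absolute difference in *every* spec parameter is within its limit of
    agreement.  All unordered pairs are counted (matched eyes are not
    removed), so three mutually identical eyes yield three pairs.
    """
    df = derived if subset is None else derived[np.asarray(subset, bool)]
    if len(df) < 2:
        return 0, []
    X = df[list(spec.parameters)].to_numpy(float)
    ids = df["eye_id"].to_numpy() if "eye_id" in df else df.index.to_numpy()
    tol = spec.tolerances
    n = len(X)
    pairs: list[tuple[object, object]] = []
    # chunked O(n^2) broadcast keeps memory bounded for cohort-sized n
    chunk = max(1, int(2e7 // max(n, 1)))
    for s in range(0, n, chunk):
        e = min(s + chunk, n)
        close = np.all(
            np.abs(X[s:e, None, :] - X[None, :, :]) <= tol, axis=2
        )
        ii, jj = np.nonzero(close)
        keep = (ii + s) < jj
        pairs.extend(zip(ids[ii[keep] + s], ids[jj[keep]]))
    return len(pairs), pairs


def relative_scaling_profile(derived: pd.DataFrame,
                             include_effectivity: bool = False) -> pd.DataFrame:
    """Per-eye surface positions as % of AL and power-contribution ratios.

    Positions of the posterior cornea (CCT), anterior lens (ACD_tot) and
    posterior lens (ASL) surfaces as percentages of axial length, plus the
    contributions of cornea and lens to the whole-eye power,
    ``P_c/P_eye`` and ``P_lb/P_eye``.

    With ``include_effectivity=True`` an alternative, *non-normative*
    contribution is added in which each element's power is vergence-
    translated to the eye's second principal plane before forming the
    ratio; the two translated contributions do not sum to one and are
    reported for comparison only.
    """
    scaled = scale_to_al(derived)
    out = pd.DataFrame({
        "pos_post_cornea_pct": 100.0 * scaled["CCT"],
        "pos_ant_lens_pct": 100.0 * scaled["ACD_tot"],
        "pos_post_lens_pct": 100.0 * scaled["ASL"],
        "corneal_contribution": derived["P_c_D"] / derived["P_eye_D"],
        "lens_contribution": derived["P_lb_D"] / derived["P_eye_D"],
    }, index=derived.index)
    if include_effectivity:
        n = 4.0 / 3.0
        p_c = derived["P_c_D"].to_numpy(float)
        p_lb = derived["P_lb_D"].to_numpy(float)
        p_eye = derived["P_eye_D"].to_numpy(float)
        pp2 = derived["pp_eye2_mm"].to_numpy(float)
        acd = derived["ACD_tot_mm"].to_numpy(float)
        lt = derived["LT_mm"].to_numpy(float)
        z_l1 = acd + 0.571 * lt
        p_c_eff = p_c / (1.0 - (pp2 / (1000.0 * n)) * p_c)
        p_lb_eff = p_lb / (1.0 - ((pp2 - z_l1) / (1000.0 * n)) * p_lb)
        out["corneal_contribution_effectivity"] = p_c_eff / p_eye
        out["lens_contribution_effectivity"] = p_lb_eff / p_eye
    return out
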