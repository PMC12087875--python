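"""Synthetic ocular-biometry cohorts with planted statistical structure.

Generates cohorts that emulate an adult population-based eye study: the
refractive error follows the reference bigaussian mixture
(:data:`~emmetrics.bigaussian.REFERENCE_SE_FIT`), the biometric parameters
have the published cohort means/SDs, and their pairwise Pearson correlations
match the published correlation matrix.  Every synthetic eye is optically
self-consistent: its lens power is obtained by Bennett inversion, so the
forward paraxial model reproduces the drawn refraction exactly.

The default mode is *refraction-first*: draw SE from the mixture, draw
(AD, LT, AL, P_c) from the Gaussian conditional given SE, draw CCT
independently (it shows no meaningful correlation with anything), invert
P_c into corneal radii at a fixed posterior/anterior ratio, and solve for
the Bennett lens power.  The SE conditioning uses the mixture's own implied
mean and variance so that the planted correlations are reproduced without
attenuation even though SE is not Gaussian.

A *biometry-first* mode (draw all biometry jointly, compute SE forward) is
provided for stress-testing only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import optics
from .bigaussian import BigaussianParams, REFERENCE_SE_FIT, component_weights, mixture_moments
from .schema import RAW_COLUMNS, SE_SCREEN_LIMIT

logger = logging.getLogger(__name__)

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "CohortValidation",
    "TABLE_MEANS",
    "TABLE_SDS",
    "TABLE_CORRELATIONS",
    "sample_se_mixture",
    "generate_cohort",
    "validate_cohort",
]

#: Published entire-cohort means (mm / D) used as generator defaults.
TABLE_MEANS: Mapping[str, float] = {
    "SE": 0.02, "CCT": 0.53, "AD": 2.64, "LT": 4.25,
    "VCD": 15.72, "AL": 23.14, "P_c": 42.02, "P_lb": 26.00,
}

#: Published entire-cohort standard deviations used as generator defaults.
TABLE_SDS: Mapping[str, float] = {
    "SE": 1.52, "CCT": 0.03, "AD": 0.32, "LT": 0.29,
    "VCD": 0.85, "AL": 0.90, "P_c": 1.47, "P_lb": 1.88,
}

_CORR_ORDER = ("SE", "AD", "LT", "VCD", "AL", "P_c", "P_lb")
# entire-cohort Pearson correlations (lower triangle of the published matrix)
_CORR_LOWER = [
    [1.0],
    [-0.313, 1.0],
    [0.191, -0.576, 1.0],
    [-0.552, 0.345, -0.362, 1.0],
    [-0.570, 0.491, -0.225, 0.951, 1.0],
    [-0.111, -0.008, -0.023, -0.588, -0.569, 1.0],
    [-0.085, -0.367, 0.273, -0.525, -0.537, 0.174, 1.0],
]


def _full_corr() -> pd.DataFrame:
    m = np.eye(len(_CORR_ORDER))
    for i, row in enumerate(_CORR_LOWER):
        for j, v in enumerate(row):
            m[i, j] = m[j, i] = v
    return pd.DataFrame(m, index=_CORR_ORDER, columns=_CORR_ORDER)


#: Published entire-cohort correlation matrix over (SE, AD, LT, VCD, AL, P_c, P_lb).
TABLE_CORRELATIONS: pd.DataFrame = _full_corr()

#: Dimensions the refraction-first generator samples directly; VCD follows
#: from the accounting identity and P_lb from Bennett inversion.
_SAMPLED = ("AD", "LT", "AL", "P_c")


@dataclass(frozen=True)
class CohortSpec:
    """Generator parameters for one synthetic cohort."""

    n: int = 2000
    seed: int = 0
    se_params: BigaussianParams = REFERENCE_SE_FIT
    means: Mapping[str, float] = field(default_factory=lambda: dict(TABLE_MEANS))
    sds: Mapping[str, float] = field(default_factory=lambda: dict(TABLE_SDS))
    correlations: pd.DataFrame = field(default_factory=_full_corr)
    mode: str = "refraction-first"
    se_limit: float = SE_SCREEN_LIMIT
    al_bounds: tuple[float, float] = (19.0, 32.0)
    rejection_cap_factor: int = 10
    #: fixed posterior/anterior corneal radius ratio for the P_c inversion
    radius_ratio: float = 6.5 / 7.8

    def __post_init__(self) -> None:
        c = self.correlations.to_numpy()
        if not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
            raise ValueError("correlation matrix must be symmetric with unit diagonal")
        for k, v in self.sds.items():
            if not v >= 0:
                raise ValueError(f"negative SD for {k}")
        if self.mode not in ("refraction-first", "biometry-first"):
            raise ValueError(f"unknown generator mode {self.mode!r}")


@dataclass
class SyntheticCohort:
    """Generated cohort: raw table + latent component label per eye."""

    data: pd.DataFrame
    component: np.ndarray
    spec: CohortSpec
    n_rejected: int = 0

    @property
    def rejection_rate(self) -> float:
        total = len(self.data) + self.n_rejected
        return self.n_rejected / total if total else 0.0


def sample_se_mixture(n: int, params: BigaussianParams = REFERENCE_SE_FIT,
                      seed=None, limit: float = SE_SCREEN_LIMIT):
    """Sample refractions from the normalized bigaussian mixture.

    Component 1 (narrow) is chosen with probability ``w1`` from
    :func:`component_weights`; values are Normal(mu_i, sigma_i/sqrt(2)) —
    the sqrt(2) follows from the exponent convention — truncated to
    ``+-limit`` by resampling.  Returns ``(values, component_labels)`` with
    labels in {1, 2}.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n == 0:
        return np.empty(0), np.empty(0, dtype=int)
    w1, _ = component_weights(params)
    comp = np.where(rng.random(n) < w1, 1, 2)
    mu = np.where(comp == 1, params.mu1, params.mu2)
    sd = np.where(comp == 1, params.sigma1, params.sigma2) / np.sqrt(2.0)
    se = rng.normal(mu, sd)
    out = np.abs(se) > limit
    while out.any():
        comp[out] = np.where(rng.random(out.sum()) < w1, 1, 2)
        mu_o = np.where(comp[out] == 1, params.mu1, params.mu2)
        sd_o = np.where(comp[out] == 1, params.sigma1, params.sigma2) / np.sqrt(2.0)
        se[out] = rng.normal(mu_o, sd_o)
        out = np.abs(se) > limit
    return se, comp


def _nearest_pd(cov: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues to repair a near-PD matrix (logged)."""
    lam, vec = np.linalg.eigh(cov)
    if lam.min() > 0:
        return cov
    logger.warning("repairing non-positive-definite covariance (min eig %.3g)", lam.min())
    floor = 1e-8 * lam.max()
    lam = np.maximum(lam, floor)
    return (vec * lam) @ vec.T


def _radii_from_corneal_power(p_c, cct, ratio: float,
                              indices: optics.RefractiveIndices = optics.GULLSTRAND_EMSLEY_INDICES):
    """Invert the thick-lens corneal formula for the anterior radius.

    With ``r_cp = ratio * r_ca`` fixed, ``P_c(r_ca)`` is a quadratic
    ``P_c r^2 - (A + B) r + C = 0`` whose physical (positive) root is taken.
    """
    A = 1000.0 * (indices.n_cornea - indices.n_air)
    B = 1000.0 * (indices.n_humours - indices.n_cornea) / ratio
    C = 0.001 * A * B * np.asarray(cct, float) / indices.n_cornea
    p_c = np.asarray(p_c, float)
    disc = (A + B) ** 2 - 4.0 * p_c * C
    ok = (disc > 0) & (p_c > 0)
    r_ca = np.full(p_c.shape, np.nan)
    r_ca[ok] = ((A + B) + np.sqrt(disc[ok])) / (2.0 * p_c[ok])
    return r_ca, ratio * r_ca


def _draw_refraction_first(spec: CohortSpec, n: int, rng: np.random.Generator):
    """One batch of candidate rows (some may be rejected)."""
    se, comp = sample_se_mixture(n, spec.se_params, rng, spec.se_limit)

    corr = spec.correlations
    idx = ["SE", *_SAMPLED]
    sub = corr.loc[idx, idx].to_numpy()
    sd = np.array([np.sqrt(mixture_moments(spec.se_params).variance)]
                  + [spec.sds[k] for k in _SAMPLED])
    mean = np.array([mixture_moments(spec.se_params).mean]
                    + [spec.means[k] for k in _SAMPLED])
    cov = sub * np.outer(sd, sd)
    b = cov[1:, 0] / cov[0, 0]                       # regression on SE
    cond_cov = _nearest_pd(cov[1:, 1:] - np.outer(b, b) * cov[0, 0])
    L = np.linalg.cholesky(cond_cov)
    z = rng.standard_normal((n, len(_SAMPLED)))
    bio = mean[1:] + np.outer(se - mean[0], b) + z @ L.T
    ad, lt, al, p_c = bio.T
    cct = rng.normal(spec.means["CCT"], spec.sds["CCT"], size=n)
    return se, comp, cct, ad, lt, al, p_c


def _draw_biometry_first(spec: CohortSpec, n: int, rng: np.random.Generator):
    """Joint biometry draw (stress-testing mode); SE computed forward later."""
    idx = [*_SAMPLED, "P_lb"]
    sub = spec.correlations.loc[idx, idx].to_numpy()
    sd = np.array([spec.sds[k] for k in idx])
    mean = np.array([spec.means[k] for k in idx])
    cov = _nearest_pd(sub * np.outer(sd, sd))
    bio = rng.multivariate_normal(mean, cov, size=n)
    ad, lt, al, p_c, p_lb = bio.T
    cct = rng.normal(spec.means["CCT"], spec.sds["CCT"], size=n)
    return cct, ad, lt, al, p_c, p_lb


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a validated synthetic cohort according to ``spec``.

    Rows violating physiological bounds (axial length outside
    ``spec.al_bounds``, non-positive distances or vitreous depth, no
    Bennett root in the physiological bracket, refraction outside the
    screening limit) are rejected and redrawn; generation fails if the
    total number of draws exceeds ``rejection_cap_factor * n``.
    Identical spec and seed give a bit-identical cohort.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    cols = {k: np.empty(n) for k in ("SE", "CCT", "AD", "LT", "AL", "r_ca", "r_cp", "P_lb")}
    comp_out = np.empty(n, dtype=int)
    filled = 0
    drawn = 0
    rejected = 0
    while filled < n:
        batch = min(n - filled + 64, n)
        if drawn + batch > spec.rejection_cap_factor * max(n, 1) + 64:
            raise RuntimeError(
                f"rejection cap exceeded: {drawn} draws for {filled}/{n} accepted rows"
            )
        drawn += batch
        if spec.mode == "refraction-first":
            se, comp, cct, ad, lt, al, p_c = _draw_refraction_first(spec, batch, rng)
            p_lb = np.full(batch, np.nan)
        else:
            cct, ad, lt, al, p_c, p_lb = _draw_biometry_first(spec, batch, rng)
            se = np.full(batch, np.nan)
            comp = np.zeros(batch, dtype=int)

        ok = (
            (al >= spec.al_bounds[0]) & (al <= spec.al_bounds[1])
            & (cct > 0) & (ad > 0) & (lt > 0)
            & (al - (cct + ad + lt) > 0)
        )
        r_ca, r_cp = _radii_from_corneal_power(p_c, cct, spec.radius_ratio)
        ok &= np.isfinite(r_ca) & (r_ca > 0)

        if spec.mode == "refraction-first":
            # Bennett inversion: keep rows with a bracketed physiological root
            lo, hi = optics.BENNETT_BRACKET
            i = np.flatnonzero(ok)
            if i.size:
                flo = optics.se_model(r_ca[i], r_cp[i], cct[i], ad[i], lt[i], al[i], lo) - se[i]
                fhi = optics.se_model(r_ca[i], r_cp[i], cct[i], ad[i], lt[i], al[i], hi) - se[i]
                rootable = flo * fhi <= 0
                ok[i[~rootable]] = False
                j = i[rootable]
                if j.size:
                    p_lb[j] = optics.bennett_lens_power(
                        se[j], r_ca[j], r_cp[j], cct[j], ad[j], lt[j], al[j]
                    )
        else:
            i = np.flatnonzero(ok)
            if i.size:
                se[i] = optics.se_model(r_ca[i], r_cp[i], cct[i], ad[i], lt[i], al[i], p_lb[i])
                ok[i] &= np.abs(se[i]) <= spec.se_limit

        take = np.flatnonzero(ok)[: n - filled]
        rejected += batch - len(np.flatnonzero(ok))
        sl = slice(filled, filled + take.size)
        for name, arr in (("SE", se), ("CCT", cct), ("AD", ad), ("LT", lt),
                          ("AL", al), ("r_ca", r_ca), ("r_cp", r_cp), ("P_lb", p_lb)):
            cols[name][sl] = arr[take]
        comp_out[sl] = comp[take]
        filled += take.size
        if n == 0:
            break

    if rejected:
        logger.info("generate_cohort: %d candidate rows rejected (%.2f%% of draws)",
                    rejected, 100.0 * rejected / max(drawn, 1))

    data = pd.DataFrame({
        "eye_id": np.arange(n),
        "age_y": np.full(n, np.nan),
        "sex": ["U"] * n,
        "SE_D": cols["SE"],
        "r_ca_mm": cols["r_ca"],
        "r_cp_mm": cols["r_cp"],
        "CCT_mm": cols["CCT"],
        "AD_mm": cols["AD"],
        "LT_mm": cols["LT"],
        "AL_mm": cols["AL"],
    }, columns=RAW_COLUMNS)
    return SyntheticCohort(data, comp_out, spec, n_rejected=rejected)


# ---------------------------------------------------------------------------
# validation


@dataclass
class CohortValidation:
    """Pass/fail report of the generator's statistical targets."""

    checks: list[tuple[str, bool, str]]
    info: dict

    @property
    def passed(self) -> bool:
        return all(ok for _, ok, _ in self.checks)

    def failures(self) -> list[str]:
        return [name for name, ok, _ in self.checks if not ok]


def validate_cohort(cohort: SyntheticCohort, spec: CohortSpec | None = None,
                    corr_tol: float = 0.05, mean_sigmas: float = 4.0) -> CohortValidation:
    """Check a generated cohort against its generating spec.

    Means of the sampled parameters must lie within ``mean_sigmas`` standard
    errors of their targets; the *imposed* correlations (pairs among SE, AD,
    LT, AL, P_c) and the emergent AL-VCD correlation must be within
    ``corr_tol``; the SE distribution must be leptokurtic; and every row
    must satisfy the raw-biometry invariants.  Lens-power correlations are
    emergent (Bennett-derived), so they are reported in ``info`` but not
    graded.
    """
    spec = spec or cohort.spec
    df = cohort.data
    n = len(df)
    checks: list[tuple[str, bool, str]] = []
    info: dict = {}

    values = {
        "SE": df["SE_D"].to_numpy(float),
        "CCT": df["CCT_mm"].to_numpy(float),
        "AD": df["AD_mm"].to_numpy(float),
        "LT": df["LT_mm"].to_numpy(float),
        "AL": df["AL_mm"].to_numpy(float),
        "P_c": optics.corneal_power(df["r_ca_mm"], df["r_cp_mm"], df["CCT_mm"]).P_c,
    }
    values["VCD"] = values["AL"] - (values["CCT"] + values["AD"] + values["LT"])

    for k in ("CCT", "AD", "LT", "AL", "P_c"):
        se_mean = spec.sds[k] / np.sqrt(n)
        dev = abs(values[k].mean() - spec.means[k])
        checks.append((
            f"mean[{k}]", dev <= mean_sigmas * se_mean,
            f"|{values[k].mean():.4f} - {spec.means[k]}| vs {mean_sigmas}*SE={mean_sigmas * se_mean:.4f}",
        ))

    pairs = [("SE", b) for b in _SAMPLED] + [
        (a, b) for i, a in enumerate(_SAMPLED) for b in _SAMPLED[i + 1:]
    ] + [("AL", "VCD")]
    for a, b in pairs:
        target = float(spec.correlations.loc[a, b])
        r = float(np.corrcoef(values[a], values[b])[0, 1])
        checks.append((
            f"corr[{a},{b}]", abs(r - target) <= corr_tol,
            f"r={r:.3f} target={target:.3f} tol={corr_tol}",
        ))

    kurt = float(stats.kurtosis(values["SE"], fisher=True))
    checks.append(("SE leptokurtic", kurt > 0, f"excess kurtosis {kurt:.3f}"))

    invariants_ok = bool(
        (df[["r_ca_mm", "r_cp_mm", "CCT_mm", "AD_mm", "LT_mm", "AL_mm"]] > 0).all().all()
        and (values["VCD"] > 0).all()
        and (np.abs(values["SE"]) <= spec.se_limit).all()
    )
    checks.append(("raw invariants", invariants_ok, "positivity, vitreous depth, SE screen"))

    # emergent lens-power correlations, informational only
    try:
        derived, _ = optics.derive_all(df)
        p_lb = derived["P_lb_D"].to_numpy(float)
        info["emergent_P_lb_corr"] = {
            k: float(np.corrcoef(p_lb, values[k][:len(p_lb)])[0, 1])
            for k in ("SE", "AD", "LT", "AL", "P_c")
        }
        info["P_lb_mean"] = float(p_lb.mean())
    except Exception:  # pragma: no cover - informational
        pass
    info["rejection_rate"] = cohort.rejection_rate
    return CohortValidation(checks, info)
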