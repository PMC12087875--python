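"""Shared fixtures: synthetic cohorts and random physiological eyes."""

from __future__ import annotations

import numpy as np
import pytest

from emmetrics import cohort, optics


def random_physiological_eyes(n: int, seed: int) -> dict[str, np.ndarray]:
    """Random eyes spanning the physiological biometry ranges.

    The refraction is generated *forward* from a drawn lens power, so every
    eye is guaranteed to have a Bennett root and the drawn ``P_lb`` is the
    ground truth for inversion checks.
    """
    rng = np.random.default_rng(seed)
    r_ca = rng.uniform(7.2, 8.4, n)
    r_cp = 6.5 / 7.8 * r_ca * rng.uniform(0.97, 1.03, n)
    cct = rng.uniform(0.47, 0.62, n)
    ad = rng.uniform(2.2, 3.3, n)
    lt = rng.uniform(3.8, 4.8, n)
    al = rng.uniform(21.5, 26.5, n)
    p_lb = rng.uniform(16.0, 34.0, n)
    se = optics.se_model(r_ca, r_cp, cct, ad, lt, al, p_lb)
    keep = np.abs(se) <= 14.5
    return {
        "r_ca": r_ca[keep], "r_cp": r_cp[keep], "CCT": cct[keep],
        "AD": ad[keep], "LT": lt[keep], "AL": al[keep],
        "P_lb": p_lb[keep], "SE": se[keep],
    }


@pytest.fixture(scope="session")
def synth_cohort():
    """Default synthetic cohort at the study's sample size."""
    return cohort.generate_cohort(cohort.CohortSpec(n=2000, seed=7))


@pytest.fixture(scope="session")
def derived_cohort(synth_cohort):
    derived, exclusions = optics.derive_all(synth_cohort.data)
    assert not exclusions
    return derived


@pytest.fixture(scope="session")
def planted_mixture_sample():
    """Well-separated two-component 5-D Gaussian sample with known labels.

    Weights (0.7, 0.3); the component covariances are full (correlated) and
    the means are far apart relative to the spreads, so recovery is easy and
    label identification unambiguous.
    """
    rng = np.random.default_rng(2024)
    n = 1500
    w1 = 0.7
    d = 5
    a = rng.uniform(-0.3, 0.3, (d, d))
    cov1 = np.eye(d) + a @ a.T
    cov2 = 2.0 * (np.eye(d) + (a * 0.5) @ (a * 0.5).T)
    mean1 = np.zeros(d)
    mean2 = np.full(d, 8.0)
    labels = (rng.random(n) >= w1).astype(int)  # 0 = component 1
    X = np.empty((n, d))
    X[labels == 0] = rng.multivariate_normal(mean1, cov1, size=(labels == 0).sum())
    X[labels == 1] = rng.multivariate_normal(mean2, cov2, size=(labels == 1).sum())
    return {"X": X, "labels": labels, "weights": (w1, 1 - w1),
            "means": (mean1, mean2), "covs": (cov1, cov2)}


@pytest.fixture(scope="session")
def overlapping_mixture_cohort():
    """Two overlapping 5-D components with a known analytic mixture.

    The components overlap enough that the all-pairs Regulated region can
    capture part of the broad component, so an ellipse-scale calibration to
    the narrow weight (0.714 here) is attainable inside the search bracket.
    """
    from emmetrics.bigaussian import MultivariateMixture

    rng = np.random.default_rng(77)
    n = 3000
    d = 5
    w1 = 0.714
    mean1, cov1 = np.zeros(d), np.eye(d)
    mean2, cov2 = np.full(d, 2.5), 4.0 * np.eye(d)
    comp = (rng.random(n) >= w1).astype(int)
    X = np.empty((n, d))
    X[comp == 0] = rng.multivariate_normal(mean1, cov1, size=(comp == 0).sum())
    X[comp == 1] = rng.multivariate_normal(mean2, cov2, size=(comp == 1).sum())
    mix = MultivariateMixture(
        dimensions=tuple(f"x{i}" for i in range(d)),
        weights=np.array([w1, 1 - w1]),
        means=np.stack([mean1, mean2]),
        covariances=np.stack([cov1, cov2]),
        log_likelihood=0.0, aic=0.0,
    )
    return {"X": X, "mixture": mix, "w1": w1}
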