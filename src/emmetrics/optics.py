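"""Paraxial optics of the phakic eye.

Implements the per-eye derivation chain used throughout the package: corneal
power from the thick-lens equation, Bennett's estimate of crystalline-lens
power, whole-eye power and cardinal points, the axial power of an eye of a
given length, and the model refraction

    SE_model = P_ax - P_eye,

i.e. the difference between the power that would focus a distant object on
the retina and the power the eye actually has.

Two computation routes coexist deliberately:

* closed-form expressions (anterior/posterior corneal surface powers, the
  thick-lens combinations) written exactly as the classical formulas with
  explicit ``1000`` mm/m factors, and
* a reduced-angle ray-transfer-matrix engine (:class:`ParaxialSystem`) that
  is *normative* for every principal-point position.

The two must agree to numerical precision for the powers; the engine is the
single source of truth for cardinal points because the classical shorthand
formulas for the second principal point are ambiguous about their reference
vertex (see :func:`paper_literal_corneal_pp2`).

Conventions
-----------
Distances in millimetres, powers in dioptres.  Axial positions are signed,
measured from the anterior corneal vertex, positive towards the retina.
The crystalline lens is a thin power ``P_lb`` flanked by principal points at
``0.571*LT`` behind the anterior lens vertex and ``0.378*LT`` in front of the
posterior lens vertex (Gullstrand-Emsley lens proportions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .schema import DERIVED_COLUMNS, SE_SCREEN_LIMIT

logger = logging.getLogger(__name__)

__all__ = [
    "RefractiveIndices",
    "GULLSTRAND_EMSLEY_INDICES",
    "ParaxialSystem",
    "RawBiometry",
    "derive_distances",
    "corneal_system",
    "corneal_power",
    "eye_system",
    "eye_power_closed_form",
    "eye_cardinal_points",
    "axial_power_and_refraction",
    "se_model",
    "bennett_lens_power",
    "spectacle_to_corneal_plane",
    "scale_to_al",
    "derive_all",
    "paper_literal_corneal_pp2",
    "paper_literal_eye_pp2",
]

#: Position of the first lenticular principal point, as a fraction of lens
#: thickness behind the anterior lens vertex.
LENS_PP1_FRACTION = 0.571
#: Position of the second lenticular principal point, as a fraction of lens
#: thickness in front of the posterior lens vertex (hence the sign).
LENS_PP2_FRACTION = -0.378

#: Physiological bracket for the Bennett lens-power inversion, dioptres.
BENNETT_BRACKET = (5.0, 45.0)


@dataclass(frozen=True)
class RefractiveIndices:
    """Refractive indices of the reduced eye model.

    Defaults follow the Gullstrand-Emsley convention: air 1.000, cornea
    1.376 and a single index 4/3 for both aqueous and vitreous humours.
    """

    n_air: float = 1.000
    n_cornea: float = 1.376
    n_humours: float = 4.0 / 3.0

    def __post_init__(self) -> None:
        for name in ("n_air", "n_cornea", "n_humours"):
            if not getattr(self, name) > 0:
                raise ValueError(f"refractive index {name} must be positive")


GULLSTRAND_EMSLEY_INDICES = RefractiveIndices()


class ParaxialSystem:
    """Reduced-angle ray-transfer matrix for a sequence of optical elements.

    Rays are column vectors ``(y, w)`` with height ``y`` (m) and reduced
    angle ``w = n*u``.  A refraction of power ``P`` (D) maps
    ``w -> w - P*y``; a translation of length ``d`` (mm) in index ``n`` maps
    ``y -> y + (d / 1000 / n) * w``.  Every elementary matrix has unit
    determinant in this convention, so the composed matrix does too.

    All entries broadcast, so one system object can represent a whole cohort
    of eyes at once.
    """

    def __init__(self, n_object: float, n_image: float):
        self.n_object = float(n_object)
        self.n_image = float(n_image)
        # identity
        self.A, self.B, self.C, self.D = 1.0, 0.0, 0.0, 1.0
        self.elements: list[tuple[str, object]] = []

    def _compose(self, a, b, c, d) -> None:
        # left-multiply: new element acts after the current system
        A, B, C, D = self.A, self.B, self.C, self.D
        self.A, self.B = a * A + b * C, a * B + b * D
        self.C, self.D = c * A + d * C, c * B + d * D

    def add_refraction(self, power_d) -> "ParaxialSystem":
        """Append a thin refraction of ``power_d`` dioptres."""
        power_d = np.asarray(power_d, dtype=float)
        self._compose(1.0, 0.0, -power_d, 1.0)
        self.elements.append(("refraction", power_d))
        return self

    def add_gap(self, distance_mm, index: float) -> "ParaxialSystem":
        """Append a homogeneous gap of ``distance_mm`` in medium ``index``."""
        t = np.asarray(distance_mm, dtype=float) / (1000.0 * index)
        self._compose(1.0, t, 0.0, 1.0)
        self.elements.append(("gap", (distance_mm, index)))
        return self

    @property
    def matrix(self):
        """System matrix entries ``(A, B, C, D)`` (broadcastable arrays)."""
        return self.A, self.B, self.C, self.D

    @property
    def power(self):
        """Equivalent power of the system, dioptres (``-C``)."""
        return -1.0 * self.C

    def principal_points(self):
        """Principal-point positions ``(pp1, pp2)`` in mm.

        ``pp1`` is measured from the system's input plane, ``pp2`` from its
        output plane; both are signed (positive towards the image).
        """
        P = self.power
        pp1 = 1000.0 * self.n_object * (1.0 - self.D) / P
        pp2 = 1000.0 * self.n_image * (self.A - 1.0) / P
        return pp1, pp2


class AxialDistances(NamedTuple):
    ACD_tot: np.ndarray
    ASL: np.ndarray
    VCD: np.ndarray


class CornealOptics(NamedTuple):
    P_ca: np.ndarray
    P_cp: np.ndarray
    P_c: np.ndarray
    pp_c1: np.ndarray
    pp_c2: np.ndarray


class EyeCardinalPoints(NamedTuple):
    P_eye: np.ndarray
    pp_eye1: np.ndarray
    pp_eye2: np.ndarray
    f_eye2: np.ndarray
    F: np.ndarray


@dataclass(frozen=True)
class RawBiometry:
    """One eye's measured quantities (validated on construction).

    SE in dioptres; every other field in millimetres.
    """

    SE: float
    r_ca: float
    r_cp: float
    CCT: float
    AD: float
    LT: float
    AL: float
    eye_id: str | int | None = None

    def __post_init__(self) -> None:
        for name in ("r_ca", "r_cp", "CCT", "AD", "LT", "AL"):
            if not getattr(self, name) > 0:
                raise ValueError(self._msg(f"{name} must be positive"))
        if not self.AL > self.CCT + self.AD + self.LT:
            raise ValueError(self._msg("non-positive vitreous depth (AL <= ASL)"))
        if not abs(self.SE) <= SE_SCREEN_LIMIT:
            raise ValueError(self._msg(f"|SE| exceeds the {SE_SCREEN_LIMIT} D screening limit"))

    def _msg(self, reason: str) -> str:
        tag = "" if self.eye_id is None else f"eye {self.eye_id}: "
        return tag + reason


def derive_distances(cct, ad, lt, al, eye_id=None) -> AxialDistances:
    """Accounting identities for the axial distances.

    ``ACD_tot = CCT + AD`` (anterior chamber including the cornea),
    ``ASL = ACD_tot + LT`` (anterior segment length) and
    ``VCD = AL - ASL`` (vitreous chamber depth).  A non-positive vitreous
    depth is anatomically impossible and raises, naming the eye when an id
    is supplied.
    """
    cct, ad, lt, al = np.broadcast_arrays(
        *(np.asarray(v, dtype=float) for v in (cct, ad, lt, al))
    )
    acd_tot = cct + ad
    asl = acd_tot + lt
    vcd = al - asl
    if np.any(vcd <= 0):
        bad = np.atleast_1d(vcd <= 0)
        if eye_id is not None:
            ids = np.atleast_1d(np.broadcast_to(eye_id, bad.shape))[bad]
            raise ValueError(f"non-positive vitreous depth for eye(s) {list(ids)}")
        raise ValueError("non-positive vitreous depth (AL <= ASL)")
    return AxialDistances(acd_tot, asl, vcd)


def corneal_system(r_ca, r_cp, cct, indices: RefractiveIndices = GULLSTRAND_EMSLEY_INDICES) -> ParaxialSystem:
    """Two-surface thick cornea as a :class:`ParaxialSystem` (air to aqueous)."""
    r_ca = np.asarray(r_ca, dtype=float)
    r_cp = np.asarray(r_cp, dtype=float)
    if np.any(r_ca == 0) or np.any(r_cp == 0):
        raise ValueError("zero corneal radius of curvature")
    p_ca = 1000.0 * (indices.n_cornea - indices.n_air) / r_ca
    p_cp = 1000.0 * (indices.n_humours - indices.n_cornea) / r_cp
    sys = ParaxialSystem(indices.n_air, indices.n_humours)
    sys.add_refraction(p_ca)
    sys.add_gap(cct, indices.n_cornea)
    sys.add_refraction(p_cp)
    return sys


def corneal_power(r_ca, r_cp, cct, indices: RefractiveIndices = GULLSTRAND_EMSLEY_INDICES) -> CornealOptics:
    """Surface powers, total corneal power and corneal principal points.

    ``P_ca = 1000 (n_c - n_air)/r_ca``, ``P_cp = 1000 (n - n_c)/r_cp`` and
    the thick-lens combination
    ``P_c = P_ca + P_cp - 0.001 P_ca P_cp CCT / n_c``.  Principal points
    come from the matrix engine and are referenced to the **anterior**
    corneal vertex (negative values lie in front of the eye); infinite radii
    are accepted and give zero surface power.
    """
    r_ca, r_cp, cct = np.broadcast_arrays(
        *(np.asarray(v, dtype=float) for v in (r_ca, r_cp, cct))
    )
    if np.any(r_ca == 0) or np.any(r_cp == 0):
        raise ValueError("zero corneal radius of curvature")
    p_ca = 1000.0 * (indices.n_cornea - indices.n_air) / r_ca
    p_cp = 1000.0 * (indices.n_humours - indices.n_cornea) / r_cp
    p_c = p_ca + p_cp - 0.001 * p_ca * p_cp * cct / indices.n_cornea

    sys = corneal_system(r_ca, r_cp, cct, indices)
    pp1, pp2 = sys.principal_points()
    # pp1 is already relative to the anterior vertex; pp2 is relative to the
    # posterior vertex and must be shifted by the corneal thickness.
    return CornealOptics(p_ca, p_cp, p_c, pp1, cct + pp2)


def eye_system(r_ca, r_cp, cct, ad, lt, p_lb,
               indices: RefractiveIndices = GULLSTRAND_EMSLEY_INDICES) -> tuple[ParaxialSystem, np.ndarray]:
    """Whole-eye system from the anterior corneal vertex to the lens pp2.

    The lens enters as its principal-plane pair: a gap (in aqueous) from the
    posterior cornea to the first lenticular principal point, then the thin
    power ``p_lb``.  Because the mapping between conjugate principal planes
    is the identity, no translation is inserted between them; the output
    reference plane of the returned system is the *second* lenticular
    principal point, whose axial position (mm from the anterior corneal
    vertex) is returned alongside.
    """
    ad = np.asarray(ad, dtype=float)
    lt = np.asarray(lt, dtype=float)
    p_lb = np.asarray(p_lb, dtype=float)
    sys = corneal_system(r_ca, r_cp, cct, indices)
    sys.add_gap(ad + LENS_PP1_FRACTION * lt, indices.n_humours)
    sys.add_refraction(p_lb)
    sys.n_image = indices.n_humours
    # the inter-principal-plane jump exists only by virtue of the lens; a
    # powerless lens degenerates to its first principal plane
    jump = np.where(p_lb != 0.0, (1.0 + LENS_PP2_FRACTION - LENS_PP1_FRACTION) * lt, 0.0)
    z_out = np.asarray(cct, dtype=float) + ad + LENS_PP1_FRACTION * lt + jump
    return sys, z_out


def eye_power_closed_form(p_c, p_lb, separation_mm,
                          indices: RefractiveIndices = GULLSTRAND_EMSLEY_INDICES):
    """Thick-lens combination of cornea and lens.

    ``P_eye = P_c + P_lb - 0.001 P_c P_lb d / n`` with ``d`` the signed
    distance (mm) from the cornea's second principal point to the lens's
    first principal point.
    """
    return p_c + p_lb - 0.001 * p_c * p_lb * separation_mm / indices.n_humours


def eye_cardinal_points(r_ca, r_cp, cct, ad, lt, p_lb,
                        indices: RefractiveIndices = GULLSTRAND_EMSLEY_INDICES) -> EyeCardinalPoints:
    """Whole-eye power, principal points and focal geometry.

    Returns ``P_eye`` (D), the ocular principal points ``pp_eye1``/
    ``pp_eye2`` (mm from the anterior corneal vertex), the back focal
    distance ``f_eye2 = 1000 n / P_eye`` (mm, from ``pp_eye2``) and the
    position ``F = pp_eye2 + f_eye2`` of the back focal point.

    Raises if any eye has non-positive equivalent power (a non-converging
    system cannot focus a distant object).
    """
    sys, z_out = eye_system(r_ca, r_cp, cct, ad, lt, p_lb, indices)
    p_eye = sys.power
    if np.any(np.asarray(p_eye) <= 0):
        raise ValueError("non-positive whole-eye power")
    pp1, pp2 = sys.principal_points()
    pp_eye1 = pp1  # input plane is the anterior corneal vertex
    pp_eye2 = z_out + pp2
    f_eye2 = 1000.0 * indices.n_humours / p_eye
    return EyeCardinalPoints(p_eye, pp_eye1, pp_eye2, f_eye2, pp_eye2 + f_eye2)


def axial_power_and_refraction(al, p_eye, pp_eye2,
                               indices: RefractiveIndices = GULLSTRAND_EMSLEY_INDICES):
    """Axial power and the model refraction.

    ``P_ax = 1000 n / (AL - pp_eye2)`` is the whole-eye power that would put
    the back focal point exactly on the retina; ``SE_model = P_ax - P_eye``
    is then the eye's refractive error in the corneal plane.
    """
    al = np.asarray(al, dtype=float)
    pp_eye2 = np.asarray(pp_eye2, dtype=float)
    if np.any(al <= pp_eye2):
        raise ValueError("axial length does not exceed pp_eye2")
    p_ax = 1000.0 * indices.n_humours / (al - pp_eye2)
    return p_ax, p_ax - np.asarray(p_eye, dtype=float)


def se_model(r_ca, r_cp, cct, ad, lt, al, p_lb,
             indices: RefractiveIndices = GULLSTRAND_EMSLEY_INDICES):
    """Forward model: refraction of an eye with lens power ``p_lb``."""
    cp = eye_cardinal_points(r_ca, r_cp, cct, ad, lt, p_lb, indices)
    _, se = axial_power_and_refraction(al, cp.P_eye, cp.pp_eye2, indices)
    return se


def spectacle_to_corneal_plane(se_spectacle, vertex_mm: float = 12.0):
    """Translate a spectacle-plane refraction to the corneal plane.

    Provided for completeness; the reproduction pipeline treats the input
    SE as already referenced to the cornea and never applies this.
    """
    se = np.asarray(se_spectacle, dtype=float)
    return se / (1.0 - 0.001 * vertex_mm * se)


def bennett_lens_power(se, r_ca, r_cp, cct, ad, lt, al,
                       indices: RefractiveIndices = GULLSTRAND_EMSLEY_INDICES,
                       method: str = "eq1-solve",
                       bracket: tuple[float, float] = BENNETT_BRACKET):
    """Bennett's estimate of crystalline-lens power.

    ``method="eq1-solve"`` (default) finds the lens power for which the
    forward model reproduces the measured refraction, i.e. the unique root
    of ``SE_model(P_lb) = SE`` inside ``bracket``, by bisection to machine
    precision.  This guarantees an exact round trip through the forward
    model.

    ``method="vergence"`` is the classical vergence calculation: the
    incoming vergence ``SE + P_c`` at the cornea's second principal point is
    propagated over the reduced distance to the first lenticular principal
    point, and the lens power is the difference between the required exit
    vergence ``1000 n / (AL - z_l2)`` (``z_l2`` the second lenticular
    principal point) and the propagated entrance vergence.  The two methods
    agree within a quarter dioptre on physiological eyes and the agreement
    is enforced by a test, not at run time.
    """
    se, r_ca, r_cp, cct, ad, lt, al = np.broadcast_arrays(
        *(np.asarray(v, dtype=float) for v in (se, r_ca, r_cp, cct, ad, lt, al))
    )
    scalar = se.ndim == 0
    se, r_ca, r_cp, cct, ad, lt, al = (
        np.atleast_1d(v) for v in (se, r_ca, r_cp, cct, ad, lt, al)
    )
    n = indices.n_humours
    acd_tot = cct + ad

    if method == "vergence":
        co = corneal_power(r_ca, r_cp, cct, indices)
        z_l1 = acd_tot + LENS_PP1_FRACTION * lt
        z_l2 = acd_tot + (1.0 + LENS_PP2_FRACTION) * lt
        d1 = z_l1 - co.pp_c2  # cornea pp2 -> lens pp1, mm
        v1 = se + co.P_c
        denom = 1.0 - d1 / (1000.0 * n) * v1
        if np.any(denom <= 0) or np.any(al - z_l2 <= 0):
            raise ValueError("non-positive vergence denominator in Bennett calculation")
        v1p = v1 / denom
        v2 = 1000.0 * n / (al - z_l2)
        p_lb = v2 - v1p
    elif method == "eq1-solve":
        lo = np.full(se.shape, float(bracket[0]))
        hi = np.full(se.shape, float(bracket[1]))
        f = lambda p: se_model(r_ca, r_cp, cct, ad, lt, al, p, indices) - se
        flo, fhi = f(lo), f(hi)
        if np.any(flo * fhi > 0):
            bad = np.flatnonzero(flo * fhi > 0)
            raise ValueError(
                f"no Bennett root in [{bracket[0]}, {bracket[1]}] D for "
                f"{bad.size} eye(s) (first index {bad[0]})"
            )
        # SE_model is strictly decreasing in lens power, so plain bisection
        # converges; ~90 halvings exhaust double precision on a 40 D bracket.
        for _ in range(90):
            mid = 0.5 * (lo + hi)
            fm = f(mid)
            take_lo = np.sign(fm) == np.sign(flo)
            lo = np.where(take_lo, mid, lo)
            flo = np.where(take_lo, fm, flo)
            hi = np.where(take_lo, hi, mid)
        p_lb = 0.5 * (lo + hi)
    else:
        raise ValueError(f"unknown Bennett method {method!r}")
    return float(p_lb[0]) if scalar else p_lb


def paper_literal_corneal_pp2(cct, p_ca, p_c,
                              indices: RefractiveIndices = GULLSTRAND_EMSLEY_INDICES,
                              n_a: float | None = None):
    """Classical shorthand ``pp_c2 = -CCT * n_a/n_c * P_ca/P_c``.

    The symbol ``n_a`` is ambiguous in the classical notation: with
    ``n_a = n_air`` (the default here) the value disagrees with thick-lens
    optics, with ``n_a = n`` (humours) it equals the matrix-engine principal
    point *referenced to the posterior corneal vertex*.  This function
    exists to quantify that discrepancy; the matrix engine is normative.
    """
    if n_a is None:
        n_a = indices.n_air
    return -np.asarray(cct, dtype=float) * (n_a / indices.n_cornea) * (
        np.asarray(p_ca, dtype=float) / np.asarray(p_c, dtype=float)
    )


def paper_literal_eye_pp2(asl, pp_c2, acd_tot, lt, p_c, p_eye,
                          indices: RefractiveIndices = GULLSTRAND_EMSLEY_INDICES,
                          n_v: float | None = None, n_a: float | None = None):
    """Classical shorthand for the ocular second principal point.

    ``pp_eye2 = ASL - (pp_c2 + ACD_tot + pp_l1) * n_v/n_a * P_c/P_eye`` with
    the ambiguous indices defaulting to ``n_v = n`` (humours) and
    ``n_a = n_air``.  Reported for comparison only; the matrix engine is
    normative.
    """
    if n_v is None:
        n_v = indices.n_humours
    if n_a is None:
        n_a = indices.n_air
    d = np.asarray(pp_c2, float) + np.asarray(acd_tot, float) + LENS_PP1_FRACTION * np.asarray(lt, float)
    return np.asarray(asl, float) - d * (n_v / n_a) * (
        np.asarray(p_c, float) / np.asarray(p_eye, float)
    )


# ---------------------------------------------------------------------------
# cohort-level derivation


_SCALE_DISTANCE_COLS = [
    "r_ca_mm", "r_cp_mm", "CCT_mm", "AD_mm", "LT_mm", "AL_mm",
    "ACD_tot_mm", "ASL_mm", "VCD_mm", "pp_eye2_mm",
]
_SCALE_POWER_COLS = ["P_ca_D", "P_cp_D", "P_c_D", "P_lb_D", "P_eye_D", "P_ax_D"]


def scale_to_al(derived: pd.DataFrame) -> pd.DataFrame:
    """Rescale a derived cohort to its own axial length.

    Every axial distance is divided by AL and every power multiplied by
    ``AL/1000``, which makes all entries unitless and, by construction,
    ``AL`` itself equal to 1.  Under this isotropic rescaling the thick-lens
    combinations are form-invariant: scaled surface powers compose to the
    scaled total power exactly.
    """
    al = derived["AL_mm"].to_numpy(dtype=float)
    if np.any(al <= 0):
        raise ValueError("non-positive axial length")
    out = {}
    for col in _SCALE_DISTANCE_COLS:
        if col in derived:
            out[col.rsplit("_", 1)[0]] = derived[col].to_numpy(dtype=float) / al
    for col in _SCALE_POWER_COLS:
        if col in derived:
            out[col.rsplit("_", 1)[0]] = derived[col].to_numpy(dtype=float) * al / 1000.0
    return pd.DataFrame(out, index=derived.index)


def derive_all(cohort: pd.DataFrame,
               indices: RefractiveIndices = GULLSTRAND_EMSLEY_INDICES,
               se_column: str = "SE_D") -> tuple[pd.DataFrame, list[tuple[object, str]]]:
    """Row-wise optical derivation of a raw cohort table.

    Takes a DataFrame with the raw-cohort schema and returns ``(derived,
    exclusions)`` where ``derived`` carries the input columns plus every
    derived quantity and ``exclusions`` lists ``(eye_id, reason)`` for rows
    that fail validation or have no physiological Bennett solution.  Per-row
    failures are logged and excluded, never fatal.
    """
    if len(cohort) == 0:
        logger.warning("derive_all called on an empty cohort")
        return cohort.copy(), []

    df = cohort.reset_index(drop=True)
    ids = df["eye_id"] if "eye_id" in df else pd.Series(df.index, name="eye_id")
    se = df[se_column].to_numpy(dtype=float)
    r_ca = df["r_ca_mm"].to_numpy(dtype=float)
    r_cp = df["r_cp_mm"].to_numpy(dtype=float)
    cct = df["CCT_mm"].to_numpy(dtype=float)
    ad = df["AD_mm"].to_numpy(dtype=float)
    lt = df["LT_mm"].to_numpy(dtype=float)
    al = df["AL_mm"].to_numpy(dtype=float)

    reasons = np.full(len(df), "", dtype=object)
    ok = np.isfinite(se) & np.isfinite(r_ca) & np.isfinite(r_cp) & np.isfinite(cct) \
        & np.isfinite(ad) & np.isfinite(lt) & np.isfinite(al)
    reasons[~ok] = "non-finite measurement"

    positive = (r_ca > 0) & (r_cp > 0) & (cct > 0) & (ad > 0) & (lt > 0) & (al > 0)
    newly = ok & ~positive
    reasons[newly] = "non-positive measurement"
    ok &= positive

    vitreous = al - (cct + ad + lt) > 0
    newly = ok & ~vitreous
    reasons[newly] = "non-positive vitreous depth (AL <= ASL)"
    ok &= vitreous

    screened = np.abs(se) <= SE_SCREEN_LIMIT
    newly = ok & ~screened
    reasons[newly] = f"|SE| > {SE_SCREEN_LIMIT} D screening limit"
    ok &= screened

    p_lb = np.full(len(df), np.nan)
    if ok.any():
        idx = np.flatnonzero(ok)
        # per-eye Bennett root; eyes without a bracketed root are excluded
        try:
            p_lb[idx] = bennett_lens_power(
                se[idx], r_ca[idx], r_cp[idx], cct[idx], ad[idx], lt[idx], al[idx], indices
            )
        except ValueError:
            for i in idx:
                try:
                    p_lb[i] = bennett_lens_power(
                        se[i], r_ca[i], r_cp[i], cct[i], ad[i], lt[i], al[i], indices
                    )
                except ValueError:
                    reasons[i] = "no Bennett lens-power root in the physiological bracket"
                    ok[i] = False

    out = df.copy()
    for col in DERIVED_COLUMNS:
        out[col] = np.nan
    if ok.any():
        idx = np.flatnonzero(ok)
        dist = derive_distances(cct[idx], ad[idx], lt[idx], al[idx])
        co = corneal_power(r_ca[idx], r_cp[idx], cct[idx], indices)
        cp = eye_cardinal_points(r_ca[idx], r_cp[idx], cct[idx], ad[idx], lt[idx], p_lb[idx], indices)
        p_ax, se_mod = axial_power_and_refraction(al[idx], cp.P_eye, cp.pp_eye2, indices)
        out.loc[idx, "ACD_tot_mm"] = dist.ACD_tot
        out.loc[idx, "ASL_mm"] = dist.ASL
        out.loc[idx, "VCD_mm"] = dist.VCD
        out.loc[idx, "P_ca_D"] = co.P_ca
        out.loc[idx, "P_cp_D"] = co.P_cp
        out.loc[idx, "P_c_D"] = co.P_c
        out.loc[idx, "P_lb_D"] = p_lb[idx]
        out.loc[idx, "P_eye_D"] = cp.P_eye
        out.loc[idx, "pp_eye2_mm"] = cp.pp_eye2
        out.loc[idx, "P_ax_D"] = p_ax
        out.loc[idx, "SE_model_D"] = se_mod
        out.loc[idx, "P_cr"] = co.P_c / cp.P_eye
        out.loc[idx, "AL_CR"] = al[idx] / r_ca[idx]

    exclusions = [(ids.iloc[i], reasons[i]) for i in np.flatnonzero(~ok)]
    for eye, reason in exclusions:
        logger.info("excluding eye %s: %s", eye, reason)
    return out[ok].reset_index(drop=True), exclusions
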