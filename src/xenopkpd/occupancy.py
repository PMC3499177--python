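"""Receptor occupancy: ratiometric competitive binding and Kd estimation.

Models the two-color flow-cytometry assay in which PE-labeled antibody at a
fixed concentration ``L`` competes with unlabeled antibody at ``U`` for
cell-surface EGFR, with a non-competing anti-EGFR antibody providing the
total-receptor denominator.  Under no-depletion equilibrium with equal
affinities (both species are the same antibody) the labeled-bound receptor
fraction is ``L / (L + U + Kd)``; the ratiometric signal is proportional to
it.  Saturation by the unlabeled antibody is read off a standard curve built
from a zero-competitor anchor, ``S = 100 * (1 - ratio/ratio0)``, and the
saturation-vs-concentration relationship is a hyperbolic Emax (Langmuir)
model ``S(C) = Smax * C / (Kd + C)`` whose half-saturation point is Kd.

Concentrations are in nM; the antibody molar bridge (1 ug/mL = 6.8 nM for
this IgG2) converts serum concentrations for in vivo predictions.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import least_squares

from .pk import FitResult, _covariance_from_fit

logger = logging.getLogger("xenopkpd.occupancy")

#: molar bridge for the antibody: 1 ug/mL corresponds to 6.8 nM
NM_PER_UG_PER_ML = 6.8
#: labeled-antibody concentration fixed by the assay design (nM)
DEFAULT_LABELED_NM = 6.8
#: competitor concentration series of the standard curve (nM)
STANDARD_COMPETITOR_NM = (0.0, 0.21, 0.63, 1.83, 5.64, 17.0)

__all__ = [
    "NM_PER_UG_PER_ML",
    "DEFAULT_LABELED_NM",
    "STANDARD_COMPETITOR_NM",
    "OccupancyParams",
    "CompetitionPoint",
    "StandardCurve",
    "SaturationObservation",
    "nM_from_ug_per_mL",
    "ug_per_mL_from_nM",
    "occupancy_fraction",
    "competitive_labeled_fraction",
    "build_standard_curve",
    "invert_standard_curve",
    "fit_kd",
]


def nM_from_ug_per_mL(conc_ug_per_mL):
    """Convert antibody serum concentration ug/mL -> nM via the molar bridge."""
    return np.asarray(conc_ug_per_mL, dtype=float) * NM_PER_UG_PER_ML


def ug_per_mL_from_nM(conc_nM):
    return np.asarray(conc_nM, dtype=float) / NM_PER_UG_PER_ML


@dataclass(frozen=True)
class OccupancyParams:
    """Hyperbolic binding parameters: Kd (nM) and maximal saturation Smax (%)."""

    Kd: float
    Smax: float = 100.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.Kd) or self.Kd <= 0:
            raise ValueError(f"OccupancyParams.Kd must be > 0 nM, got {self.Kd!r}")
        if not (0.0 < self.Smax <= 100.0):
            raise ValueError(f"OccupancyParams.Smax must be in (0, 100] %, got {self.Smax!r}")

    @property
    def Kd_ug_per_mL(self) -> float:
        return self.Kd / NM_PER_UG_PER_ML


@dataclass(frozen=True)
class CompetitionPoint:
    """One point of the competition series: ratio of labeled-bound to total receptor."""

    unlabeled_conc: float
    ratio: float
    labeled_conc: float = DEFAULT_LABELED_NM

    def __post_init__(self) -> None:
        if self.unlabeled_conc < 0:
            raise ValueError(f"unlabeled_conc must be >= 0 nM, got {self.unlabeled_conc!r}")
        if self.ratio < 0:
            raise ValueError(f"ratio must be >= 0, got {self.ratio!r}")


@dataclass(frozen=True)
class SaturationObservation:
    """An in vivo saturation readout on a given study day."""

    sample_id: str
    day: float
    saturation: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.saturation <= 100.0):
            raise ValueError(f"saturation must be in [0, 100] %, got {self.saturation!r}")


def occupancy_fraction(C, params: OccupancyParams):
    """Percent receptor saturation at free concentration ``C`` (nM): Smax*C/(Kd+C)."""
    C_arr = np.asarray(C, dtype=float)
    if np.any(C_arr < 0):
        raise ValueError(f"concentration must be >= 0 nM, got minimum {C_arr.min()!r}")
    out = params.Smax * C_arr / (params.Kd + C_arr)
    return float(out) if np.isscalar(C) else out


def competitive_labeled_fraction(L, U, Kd):
    """Fraction of receptors bound by the labeled species under competition.

    No-depletion equilibrium with equal affinities: ``L / (L + U + Kd)``.
    Valid when receptor density is small relative to the antibody
    concentrations (the assay's design regime).
    """
    L_arr = np.asarray(L, dtype=float)
    U_arr = np.asarray(U, dtype=float)
    if np.any(L_arr < 0) or np.any(U_arr < 0):
        raise ValueError("labeled and unlabeled concentrations must be >= 0 nM")
    if Kd < 0:
        raise ValueError(f"Kd must be >= 0 nM, got {Kd!r}")
    denom = L_arr + U_arr + Kd
    out = np.where(denom > 0, L_arr / np.where(denom > 0, denom, 1.0), 0.0)
    if np.isscalar(L) and np.isscalar(U):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# standard curve
# ---------------------------------------------------------------------------

@dataclass
class StandardCurve:
    """Ratio-to-saturation standard curve with a monotone (PCHIP) interpolant.

    ``concs`` are competitor concentrations (nM) in increasing order,
    ``ratios`` the replicate-averaged signal ratios, ``saturations`` the
    normalized percent saturations anchored at 0% for zero competitor.
    """

    concs: np.ndarray
    ratios: np.ndarray
    saturations: np.ndarray
    ratio0: float
    _interp: object  # monotone interpolant, ratio -> saturation %

    def saturation_at_conc(self, conc) -> np.ndarray | float:
        """Monotone interpolation of saturation vs competitor concentration."""
        interp = PchipInterpolator(self.concs, self.saturations)
        out = np.clip(interp(np.asarray(conc, dtype=float)), 0.0, 100.0)
        return float(out) if np.isscalar(conc) else out


def build_standard_curve(
    points: Sequence[CompetitionPoint] | pd.DataFrame,
    monotone_tol: float = 10.0,
) -> StandardCurve:
    """Build the saturation standard curve from a competition series.

    Replicate ratios at the same competitor concentration are averaged, each
    average is normalized to the zero-competitor anchor ``ratio0`` and turned
    into percent saturation ``100*(1 - ratio/ratio0)``, and a shape-preserving
    monotone interpolant over the ratio axis is fitted (guaranteeing
    invertibility).  Saturation must be non-decreasing in concentration; dips
    larger than ``monotone_tol`` percentage points are rejected with
    diagnostics, smaller ones (assay noise scale) are flattened.
    """
    if isinstance(points, pd.DataFrame):
        pts = [CompetitionPoint(r.unlabeled_conc_nM, r.ratio,
                                getattr(r, "labeled_conc_nM", DEFAULT_LABELED_NM))
               for r in points.itertuples()]
    else:
        pts = list(points)
    if not pts:
        raise ValueError("empty competition series")
    tab: dict[float, list[float]] = {}
    for p in pts:
        tab.setdefault(p.unlabeled_conc, []).append(p.ratio)
    concs = np.array(sorted(tab), dtype=float)
    if concs.size < 3:
        raise ValueError(f"insufficient standard curve: need >= 3 distinct concentrations, got {concs.size}")
    if concs[0] != 0.0:
        raise ValueError("standard curve requires a zero-competitor anchor point")
    ratios = np.array([float(np.mean(tab[c])) for c in concs])
    ratio0 = ratios[0]
    if ratio0 <= 0:
        raise ValueError(f"zero-competitor anchor ratio must be > 0, got {ratio0!r}")
    sats = 100.0 * (1.0 - ratios / ratio0)
    dips = np.diff(sats)
    if np.any(dips < -monotone_tol):
        worst = int(np.argmin(dips))
        raise ValueError(
            "standard curve not monotone: saturation drops "
            f"{-dips[worst]:.2f} points between {concs[worst]} and {concs[worst + 1]} nM "
            f"(tolerance {monotone_tol})"
        )
    sats = np.maximum.accumulate(sats)
    sats[0] = 0.0
    # enforce the same monotonization on the ratio axis so the inverse map is valid
    ratios_mono = ratio0 * (1.0 - sats / 100.0)
    r_asc, idx = np.unique(ratios_mono[::-1], return_index=True)
    s_asc = sats[::-1][idx]
    if r_asc.size >= 2:
        interp = PchipInterpolator(r_asc, s_asc)
    else:  # degenerate flat curve (e.g. no competition signal at all)
        const = float(s_asc[0])

        def interp(x, _c=const):
            return np.full_like(np.asarray(x, dtype=float), _c)
    return StandardCurve(concs=concs, ratios=ratios_mono, saturations=sats,
                         ratio0=float(ratio0), _interp=interp)


def invert_standard_curve(curve: StandardCurve, observed_ratio: float) -> float:
    """Percent saturation for an observed signal ratio, by monotone interpolation.

    Ratios outside the span of the curve knots are clamped to the nearest
    endpoint with a warning.
    """
    if curve.concs.size == 0:
        raise ValueError("empty standard curve")
    lo, hi = float(curve.ratios.min()), float(curve.ratios.max())
    r = float(observed_ratio)
    if r < lo or r > hi:
        warnings.warn(
            f"observed ratio {r:.4g} outside standard-curve span [{lo:.4g}, {hi:.4g}]; clamped",
            stacklevel=2,
        )
        r = min(max(r, lo), hi)
    return float(np.clip(curve._interp(r), 0.0, 100.0))


# ---------------------------------------------------------------------------
# Kd fitting
# ---------------------------------------------------------------------------

def fit_kd(
    data,
    init: OccupancyParams,
    fit_smax: bool = False,
    max_nfev: int = 1000,
) -> FitResult:
    """Estimate Kd by nonlinear least squares.

    Two data routes are supported:

    * **competition route** — ``data`` is a DataFrame with columns
      ``unlabeled_conc_nM``, ``ratio`` (and optionally ``labeled_conc_nM``):
      the model ``ratio = r0 * L / (L + U + Kd)`` is fitted on log ratios
      (proportional error), estimating ``Kd`` jointly with the zero-competitor
      signal scale ``r0``.  The known labeled concentration makes the fitted
      Kd the true dissociation constant rather than the competition-shifted
      apparent one.
    * **direct route** — ``data`` is a ``(concentrations, saturations)`` pair
      (nM, percent): the hyperbola ``Smax * C / (Kd + C)`` is fitted (Smax
      fixed at ``init.Smax`` unless ``fit_smax``).

    Flags non-identifiable designs (all concentrations far above Kd, i.e.
    saturation flat at Smax) via ``converged=False`` with a message.
    """
    if isinstance(data, pd.DataFrame):
        return _fit_kd_competition(data, init, max_nfev)
    conc, sat = data
    conc = np.asarray(conc, dtype=float)
    sat = np.asarray(sat, dtype=float)
    if conc.shape != sat.shape or conc.ndim != 1:
        raise ValueError("concentrations and saturations must be 1-D arrays of equal length")
    pos = conc > 0
    if np.count_nonzero(pos) < 3:
        raise ValueError("need >= 3 positive concentrations to fit Kd")
    if np.all(np.abs(sat) < 1e-12):
        raise ValueError("all saturations are zero; Kd is not identifiable")

    names = ["Kd", "Smax"] if fit_smax else ["Kd"]
    theta0 = np.log([init.Kd] + ([init.Smax] if fit_smax else []))

    def residuals(theta):
        kd = math.exp(theta[0])
        smax = math.exp(theta[1]) if fit_smax else init.Smax
        return smax * conc / (kd + conc) - sat

    res = least_squares(residuals, theta0, method="lm", max_nfev=max_nfev)
    estimates = {"Kd": math.exp(res.x[0]),
                 "Smax": math.exp(res.x[1]) if fit_smax else init.Smax}
    cov = _covariance_from_fit(res, conc.size)
    converged = bool(res.success) and cov is not None
    ses = None
    message = res.message
    if converged:
        se_log = np.sqrt(np.diag(cov))
        ses = {n: estimates[n] * float(s) for n, s in zip(names, se_log)}
    if estimates["Kd"] < 0.05 * conc[pos].min() and (
            ses is None or ses["Kd"] > 0.5 * estimates["Kd"]):
        converged = False
        message = (
            "non-identifiable design: all concentrations far above the fitted Kd "
            "(saturation flat at Smax)"
        )
        ses = None
    return FitResult(estimates, ses, float(2.0 * res.cost), converged, cov,
                     int(res.nfev), message)


def _fit_kd_competition(df: pd.DataFrame, init: OccupancyParams, max_nfev: int) -> FitResult:
    if "unlabeled_conc_nM" not in df.columns or "ratio" not in df.columns:
        raise ValueError("competition table needs columns unlabeled_conc_nM and ratio")
    U = df["unlabeled_conc_nM"].to_numpy(dtype=float)
    L = (df["labeled_conc_nM"].to_numpy(dtype=float)
         if "labeled_conc_nM" in df.columns else np.full_like(U, DEFAULT_LABELED_NM))
    r = df["ratio"].to_numpy(dtype=float)
    if np.any(r <= 0):
        raise ValueError("competition ratios must be > 0 for the proportional-error fit")
    if np.unique(U).size < 3:
        raise ValueError("need >= 3 distinct competitor concentrations")
    r0_init = float(np.mean(r[U == U.min()])) if np.any(U == U.min()) else float(r.max())
    theta0 = np.log([init.Kd, max(r0_init, 1e-12)])
    logr = np.log(r)

    def residuals(theta):
        kd, r0 = np.exp(theta)
        pred = r0 * L / (L + U + kd)
        return np.log(pred) - logr

    res = least_squares(residuals, theta0, method="lm", max_nfev=max_nfev)
    kd, r0 = np.exp(res.x)
    estimates = {"Kd": float(kd), "ratio0": float(r0), "Smax": init.Smax}
    cov = _covariance_from_fit(res, r.size)
    converged = bool(res.success) and cov is not None
    ses = None
    if converged:
        se_log = np.sqrt(np.diag(cov))
        ses = {"Kd": float(kd * se_log[0]), "ratio0": float(r0 * se_log[1])}
    return FitResult(estimates, ses, float(2.0 * res.cost), converged, cov,
                     int(res.nfev), res.message)
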