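"""Open two-compartment pharmacokinetics with first-order absorption.

The model is the standard linear mammillary system used for intraperitoneally
dosed monoclonal antibodies in mice: a depot at the injection site feeding the
central (sampled) compartment by a first-order process ``ka``, distribution to
a peripheral compartment via intercompartmental clearance ``Q``, and
first-order elimination from central via systemic clearance ``CL``::

    dAd/dt = -ka*Ad
    dAc/dt =  ka*Ad - (CL/Vc)*Ac - (Q/Vc)*Ac + (Q/Vp)*Ap
    dAp/dt =  (Q/Vc)*Ac - (Q/Vp)*Ap

with serum concentration ``C = Ac/Vc``.  Amounts are in micrograms, volumes in
mL, time in hours throughout; clearances quoted in mL/day are converted on
ingestion.  Because the system is linear, multiple doses superpose and
exposure metrics scale exactly with dose.

The module provides both an ODE simulation path and the tri-exponential
closed-form solution (the eigen-solution of the disposition system), which
cross-check each other, plus exposure metrics and pooled nonlinear
least-squares fitting on log concentrations.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

logger = logging.getLogger("xenopkpd.pk")

#: hours per day, used for every day<->hour unit bridge
HOURS_PER_DAY = 24.0
#: default lower limit of quantification for serum concentrations (ug/mL)
DEFAULT_LLOQ_UG_PER_ML = 0.05
#: default twice-weekly dosing interval (uniform spacing), hours
TWICE_WEEKLY_INTERVAL_H = 84.0

__all__ = [
    "HOURS_PER_DAY",
    "DEFAULT_LLOQ_UG_PER_ML",
    "TWICE_WEEKLY_INTERVAL_H",
    "PKParams",
    "DoseEvent",
    "DoseRegimen",
    "ConcentrationTimecourse",
    "PKMetrics",
    "PKObservation",
    "FitResult",
    "closed_form_concentration",
    "regimen_concentration",
    "simulate_pk_profile",
    "pk_metrics",
    "scale_dose_proportional",
    "fit_pk",
    "read_pk_csv",
    "write_pk_csv",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PKParams:
    """Parameters of the two-compartment absorption model.

    Attributes
    ----------
    ka : float
        First-order absorption rate constant, 1/h.
    Vc : float
        Central volume of distribution, mL.
    CL : float
        Systemic clearance, mL/h (use :meth:`from_daily_clearance` for the
        mL/day convention used in study reports).
    Q : float
        Intercompartmental clearance, mL/h.  ``Q = 0`` reduces the model
        exactly to the one-compartment (Bateman) absorption model.
    Vp : float
        Peripheral volume, mL.
    F : float
        Bioavailable fraction of the administered dose (0 < F <= 1).
    """

    ka: float
    Vc: float
    CL: float
    Q: float = 0.04
    Vp: float = 2.6
    F: float = 1.0

    def __post_init__(self) -> None:
        for name in ("ka", "Vc", "CL", "Vp"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"PKParams.{name} must be finite and > 0, got {v!r}")
        if not math.isfinite(self.Q) or self.Q < 0:
            raise ValueError(f"PKParams.Q must be finite and >= 0, got {self.Q!r}")
        if not (0.0 < self.F <= 1.0):
            raise ValueError(f"PKParams.F must be in (0, 1], got {self.F!r}")

    @classmethod
    def from_daily_clearance(
        cls,
        ka_per_h: float,
        Vc_mL: float,
        CL_mL_per_day: float,
        Q_mL_per_h: float = 0.04,
        Vp_mL: float = 2.6,
        F: float = 1.0,
    ) -> "PKParams":
        """Build parameters with clearance given in mL/day (report convention)."""
        return cls(ka=ka_per_h, Vc=Vc_mL, CL=CL_mL_per_day / HOURS_PER_DAY,
                   Q=Q_mL_per_h, Vp=Vp_mL, F=F)

    @property
    def CL_mL_per_day(self) -> float:
        return self.CL * HOURS_PER_DAY

    def micro_rates(self) -> tuple[float, float, float]:
        """Micro rate constants (k10, k12, k21), each 1/h."""
        return self.CL / self.Vc, self.Q / self.Vc, self.Q / self.Vp

    def disposition_eigenvalues(self) -> tuple[float, float]:
        """Macro rates (alpha, beta) of the disposition system, alpha >= beta."""
        k10, k12, k21 = self.micro_rates()
        a = k10 + k12 + k21
        disc = math.sqrt(max(a * a - 4.0 * k10 * k21, 0.0))
        return (a + disc) / 2.0, (a - disc) / 2.0


@dataclass(frozen=True)
class DoseEvent:
    """A single administration: ``amount`` ug given at ``time`` h after study start."""

    time: float
    amount: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.time) or self.time < 0:
            raise ValueError(f"DoseEvent.time must be >= 0 h, got {self.time!r}")
        if not math.isfinite(self.amount) or self.amount <= 0:
            raise ValueError(f"DoseEvent.amount must be > 0 ug, got {self.amount!r}")


@dataclass(frozen=True)
class DoseRegimen:
    """An ordered sequence of dose events; equal-time events are merged."""

    events: tuple[DoseEvent, ...] = ()

    def __post_init__(self) -> None:
        merged: dict[float, float] = {}
        for ev in self.events:
            merged[ev.time] = merged.get(ev.time, 0.0) + ev.amount
        norm = tuple(DoseEvent(t, a) for t, a in sorted(merged.items()))
        object.__setattr__(self, "events", norm)

    @property
    def times(self) -> np.ndarray:
        return np.array([ev.time for ev in self.events], dtype=float)

    @property
    def total_amount(self) -> float:
        return float(sum(ev.amount for ev in self.events))

    def scaled(self, factor: float) -> "DoseRegimen":
        """Same schedule with every amount multiplied by ``factor`` (> 0)."""
        if factor <= 0:
            raise ValueError(f"scale factor must be > 0, got {factor!r}")
        return DoseRegimen(tuple(DoseEvent(ev.time, ev.amount * factor) for ev in self.events))

    @classmethod
    def single(cls, amount: float, time: float = 0.0) -> "DoseRegimen":
        return cls((DoseEvent(time, amount),))

    @classmethod
    def twice_weekly(
        cls,
        amount: float,
        n_doses: int,
        interval_h: float = TWICE_WEEKLY_INTERVAL_H,
        pattern: str = "uniform",
        start_h: float = 0.0,
    ) -> "DoseRegimen":
        """Twice-weekly schedule.

        ``pattern="uniform"`` spaces doses every ``interval_h`` (default 84 h,
        i.e. days 0, 3.5, 7, ...); ``pattern="3-4"`` alternates 72 h / 96 h
        gaps (e.g. Monday/Thursday dosing).
        """
        if n_doses < 1:
            raise ValueError(f"n_doses must be >= 1, got {n_doses!r}")
        times = [start_h]
        for i in range(1, n_doses):
            if pattern == "uniform":
                gap = interval_h
            elif pattern == "3-4":
                gap = 72.0 if i % 2 == 1 else 96.0
            else:
                raise ValueError(f"unknown dosing pattern {pattern!r}")
            times.append(times[-1] + gap)
        return cls(tuple(DoseEvent(t, amount) for t in times))


@dataclass
class ConcentrationTimecourse:
    """Serum concentration (ug/mL) evaluated on a strictly increasing time grid (h)."""

    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must be 1-D arrays of equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.concentrations < -1e-12):
            raise ValueError("concentrations must be non-negative")


@dataclass
class PKMetrics:
    """Exposure metrics of a modeled profile.

    ``auc_first_dose`` is the trapezoidal AUC over the first dosing interval
    (or a caller-specified window); ``auc_inf_single`` is the analytic
    single-dose AUC to infinity, F*Dose/CL.  Both in ug*day/mL.
    """

    cmax: float
    tmax_h: float
    auc_first_dose: float
    auc_inf_single: float


@dataclass(frozen=True)
class PKObservation:
    """One measured serum concentration from one animal."""

    animal_id: str
    dose_group: float
    time: float
    concentration: float
    below_lloq: bool = False

    def __post_init__(self) -> None:
        if self.concentration < 0 and not self.below_lloq:
            raise ValueError(
                f"concentration must be >= 0 unless censored, got {self.concentration!r}"
            )


@dataclass
class FitResult:
    """Outcome of a nonlinear least-squares fit (shared by all modules).

    ``standard_errors`` and ``covariance`` are present only when the fit
    converged with a well-conditioned Jacobian.
    """

    estimates: dict[str, float]
    standard_errors: dict[str, float] | None
    objective: float
    converged: bool
    covariance: np.ndarray | None = None
    n_evaluations: int = 0
    message: str = ""


# ---------------------------------------------------------------------------
# closed-form solution
# ---------------------------------------------------------------------------

def closed_form_concentration(
    params: PKParams,
    dose: DoseEvent,
    t: float | Sequence[float] | np.ndarray,
    degenerate: str = "limit",
) -> np.ndarray | float:
    """Tri-exponential closed-form central concentration for a single dose.

    The concentration is the eigen-solution of the linear system,

    ``C(tau) = (F*D*ka/Vc) * sum_i (k21 - l_i) / prod_{j!=i}(l_j - l_i) * exp(-l_i*tau)``

    over the three rates ``l = (alpha, beta, ka)`` with ``tau = t - dose.time``
    (zero before the dose).  When ``ka`` coincides with a disposition
    eigenvalue the solution has a ``tau*exp`` confluent limit: for the
    one-compartment case (``Q = 0``) the exact Bateman limit branch
    ``(F*D/Vc)*ka*tau*exp(-ka*tau)`` is used; for a two-compartment
    coincidence the rate is split by a 1e-7 relative offset, which matches the
    analytic limit to the same order.  ``degenerate="raise"`` turns either
    case into an error instead.
    """
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    if np.any(~np.isfinite(t_arr)):
        raise ValueError("query times must be finite")
    tau = t_arr - dose.time
    out = np.zeros_like(tau)
    active = tau >= 0
    if np.any(tau < -1e-9):
        # t before the dose is allowed (contribution is zero) for superposition
        pass
    ka = params.ka
    alpha, beta = params.disposition_eigenvalues()
    k10, k12, k21 = params.micro_rates()
    scale = params.F * dose.amount * ka / params.Vc
    tol = 1e-10 * ka

    if params.Q == 0.0:
        # exact one-compartment (Bateman) limit: beta = 0 and the beta term vanishes
        ke = k10
        if abs(ka - ke) < tol:
            if degenerate == "raise":
                raise ValueError(f"ka = ke = {ka} h^-1: absorption/elimination rate coincidence")
            out[active] = (params.F * dose.amount / params.Vc) * ka * tau[active] * np.exp(-ka * tau[active])
        else:
            out[active] = scale / (ka - ke) * (np.exp(-ke * tau[active]) - np.exp(-ka * tau[active]))
    else:
        if min(abs(ka - alpha), abs(ka - beta), abs(alpha - beta)) < tol:
            if degenerate == "raise":
                raise ValueError(
                    f"rate coincidence among ka={ka}, alpha={alpha}, beta={beta} (1/h); "
                    "enable the limit branch (degenerate='limit') or perturb the parameters"
                )
            ka = ka * (1.0 + 1e-7) if min(abs(ka - alpha), abs(ka - beta)) < tol else ka
            if abs(alpha - beta) < tol:
                alpha = alpha * (1.0 + 1e-7)
        lams = np.array([alpha, beta, ka])
        coeffs = np.empty(3)
        for i in range(3):
            others = np.prod([lams[j] - lams[i] for j in range(3) if j != i])
            coeffs[i] = (k21 - lams[i]) / others
        out[active] = scale * (coeffs[:, None] * np.exp(-np.outer(lams, tau[active]))).sum(axis=0)
    out[tau == 0] = 0.0  # depot-only input: exactly zero at the dose instant
    out = np.clip(out, 0.0, None)
    return float(out[0]) if scalar else out


def _exponential_terms(params: PKParams) -> tuple[np.ndarray, np.ndarray]:
    """Rates and coefficients of the closed form: for a dose D at time t0,
    ``C(tau) = (F*D*ka/Vc) * sum_i coeffs[i] * exp(-lams[i]*tau)``.

    Rate coincidences are split by a tiny relative offset (the confluent
    ``tau*exp`` limit cannot be written as plain exponentials); the resulting
    error is far below integration tolerances.  Used to build fast
    piecewise-exponential exposure drivers.
    """
    ka = params.ka
    alpha, beta = params.disposition_eigenvalues()
    _, _, k21 = params.micro_rates()
    tol = 1e-9 * ka
    if min(abs(ka - alpha), abs(ka - beta)) < tol:
        ka = ka * (1.0 + 1e-7)
    if abs(alpha - beta) < tol:
        alpha = alpha * (1.0 + 1e-7) + tol
    lams = np.array([alpha, beta, ka])
    coeffs = np.empty(3)
    for i in range(3):
        others = np.prod([lams[j] - lams[i] for j in range(3) if j != i])
        coeffs[i] = (k21 - lams[i]) / others
    return lams, coeffs


def regimen_concentration(
    params: PKParams,
    regimen: DoseRegimen,
    t: float | Sequence[float] | np.ndarray,
) -> np.ndarray | float:
    """Concentration under a multi-dose regimen by superposition (the model is linear)."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    total = np.zeros_like(t_arr)
    for ev in regimen.events:
        total += closed_form_concentration(params, ev, t_arr)
    return float(total[0]) if np.asarray(t, dtype=float).ndim == 0 else total


# ---------------------------------------------------------------------------
# ODE simulation
# ---------------------------------------------------------------------------

def _pk_rhs(t: float, y: np.ndarray, ka: float, k10: float, k12: float,
            k21: float) -> list[float]:
    ad, ac, ap_, _ = y
    dad = -ka * ad
    dac = ka * ad - (k10 + k12) * ac + k21 * ap_
    dap = k12 * ac - k21 * ap_
    dael = k10 * ac
    return [dad, dac, dap, dael]


def simulate_pk_profile(
    params: PKParams,
    regimen: DoseRegimen,
    times: Sequence[float] | np.ndarray,
    method: str = "DOP853",
    rtol: float = 1e-10,
    atol: float = 1e-13,
    return_states: bool = False,
):
    """Simulate the depot/central/peripheral system under a dosing regimen.

    Each dose event adds ``F * amount`` to the depot at its event time; the
    integration is restarted at every event so the discontinuity is exact.
    Returns a :class:`ConcentrationTimecourse` at the requested times, or
    ``(timecourse, states)`` with the full amount trajectory (columns
    depot, central, peripheral, eliminated; ug) when ``return_states``.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(t)):
        raise ValueError("times must be finite")
    if np.any(t < 0):
        raise ValueError(f"times must be >= 0 h, got minimum {t.min()!r}")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    ka = params.ka
    k10, k12, k21 = params.micro_rates()
    t_end = float(t[-1])
    dose_map = {ev.time: params.F * ev.amount for ev in regimen.events if ev.time <= t_end}
    breakpoints = np.unique(np.concatenate([[0.0], list(dose_map), [t_end]]))

    y = np.zeros(4)
    out = np.empty((t.size, 4))
    if breakpoints.size == 1:  # single query time at t = 0
        y[0] += dose_map.get(0.0, 0.0)
        out[:] = y
    for seg_start, seg_end in zip(breakpoints[:-1], breakpoints[1:]):
        if seg_start in dose_map:
            y[0] += dose_map[seg_start]
        sel = (t >= seg_start) & ((t < seg_end) | (seg_end == t_end) & (t == t_end))
        t_query = t[sel]
        t_eval = np.union1d(t_query, [seg_end])
        sol = solve_ivp(
            _pk_rhs, (seg_start, seg_end), y, method=method, t_eval=t_eval,
            rtol=rtol, atol=atol, args=(ka, k10, k12, k21),
        )
        if not sol.success:  # pragma: no cover - defensive
            raise RuntimeError(f"PK integration failed: {sol.message}")
        if t_query.size:
            out[sel] = sol.y[:, np.searchsorted(sol.t, t_query)].T
        y = sol.y[:, -1].copy()

    conc = np.clip(out[:, 1] / params.Vc, 0.0, None)
    tc = ConcentrationTimecourse(t, conc)
    if return_states:
        return tc, out
    return tc


# ---------------------------------------------------------------------------
# exposure metrics
# ---------------------------------------------------------------------------

def pk_metrics(
    tc: ConcentrationTimecourse,
    params: PKParams,
    dose: DoseEvent,
    auc_window_h: tuple[float, float] | None = None,
) -> PKMetrics:
    """Exposure metrics from a (dense) modeled curve.

    Cmax/Tmax come from the supplied grid; the first-dose AUC is trapezoidal
    over ``auc_window_h`` (default: the whole supplied timecourse from the
    dose time); AUC to infinity for a single dose is the analytic F*Dose/CL.
    AUCs are reported in ug*day/mL.
    """
    if tc.times.size == 0:
        raise ValueError("empty timecourse")
    i = int(np.argmax(tc.concentrations))
    cmax = float(tc.concentrations[i])
    tmax = float(tc.times[i])
    if auc_window_h is None:
        lo, hi = float(dose.time), float(tc.times[-1])
    else:
        lo, hi = map(float, auc_window_h)
    sel = (tc.times >= lo) & (tc.times <= hi)
    auc_trapz_h = float(np.trapezoid(tc.concentrations[sel], tc.times[sel])) if sel.sum() >= 2 else 0.0
    auc_inf = params.F * dose.amount / (params.CL * HOURS_PER_DAY)
    return PKMetrics(
        cmax=cmax,
        tmax_h=tmax,
        auc_first_dose=auc_trapz_h / HOURS_PER_DAY,
        auc_inf_single=auc_inf,
    )


def scale_dose_proportional(metric_value: float, ref_dose: float, target_dose: float) -> float:
    """Scale an exposure metric between doses under linear PK (exact proportionality)."""
    if ref_dose <= 0:
        raise ValueError(f"ref_dose must be > 0, got {ref_dose!r}")
    if target_dose <= 0:
        raise ValueError(f"target_dose must be > 0, got {target_dose!r}")
    return metric_value * target_dose / ref_dose


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_PK_PARAM_NAMES = ("ka", "Vc", "CL", "Q", "Vp")


def _covariance_from_fit(res, n_obs: int) -> np.ndarray | None:
    p = res.x.size
    dof = n_obs - p
    if dof <= 0:
        return None
    s2 = 2.0 * res.cost / dof
    jtj = res.jac.T @ res.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(cov)):
        return None
    return cov


def fit_pk(
    data: pd.DataFrame | Sequence[PKObservation],
    regimens: Mapping[float, DoseRegimen],
    init: PKParams,
    vary: Sequence[str] = ("ka", "Vc", "CL"),
    n_starts: int = 5,
    seed: int = 0,
    start_spread: float = 3.0,
    max_nfev: int = 2000,
) -> FitResult:
    """Fit the PK model to pooled observations across dose groups.

    Least squares on log concentrations (proportional-error assumption over a
    multi-decade concentration range) with parameters shared across all
    groups.  Censored (below-LLOQ) observations are excluded from the
    objective.  Multi-start: ``n_starts`` initializations log-uniformly
    perturbed within a factor of ``start_spread`` around ``init``; the best
    final objective wins (ties to first found).  Standard errors come from
    the Jacobian-based covariance at the optimum, transformed back to the
    natural scale.

    By default only the reportable parameters (``ka``, ``Vc``, ``CL``) are
    estimated: with no samples inside the absorption or distribution phases
    (first draw 24 h post-dose), ``Q`` and ``Vp`` are structural assumptions
    the design cannot inform, and are held at their configured values.  Pass
    ``vary`` to estimate any subset of the five.
    """
    df = _as_pk_frame(data)
    fit_df = df[(~df["below_lloq"].astype(bool)) & (df["conc_ug_per_ml"] > 0)]
    if fit_df.empty:
        raise ValueError("all observations are censored or non-positive; nothing to fit")
    n_times = fit_df["time_h"].nunique()
    if n_times < 6:
        raise ValueError(
            f"under-determined: need >= 6 distinct sampling times across groups, got {n_times}"
        )
    unknown = set(vary) - set(_PK_PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown PK parameters to vary: {sorted(unknown)}")

    groups = []
    for dose, sub in fit_df.groupby("dose_group_ug"):
        if dose not in regimens:
            raise ValueError(f"no dosing regimen supplied for dose group {dose} ug")
        groups.append((regimens[dose], sub["time_h"].to_numpy(),
                       np.log(sub["conc_ug_per_ml"].to_numpy())))
    n_obs = int(sum(t.size for _, t, _ in groups))

    base = {name: getattr(init, name) for name in _PK_PARAM_NAMES}
    vary = tuple(vary)
    theta0 = np.log([base[name] for name in vary])

    def residuals(theta: np.ndarray) -> np.ndarray:
        vals = dict(base)
        vals.update({name: float(np.exp(min(max(th, -30.0), 30.0)))
                     for name, th in zip(vary, theta)})
        try:
            p = PKParams(F=init.F, **vals)
        except ValueError:
            return np.full(n_obs, 1e6)
        res = []
        for regimen, t, logc in groups:
            pred = regimen_concentration(p, regimen, t)
            res.append(np.log(np.maximum(pred, 1e-12)) - logc)
        return np.concatenate(res)

    rng = np.random.default_rng(seed)
    best = None
    nfev = 0
    for k in range(max(1, n_starts)):
        start = theta0 if k == 0 else theta0 + rng.uniform(
            -math.log(start_spread), math.log(start_spread), size=theta0.size)
        try:
            res = least_squares(residuals, start, method="lm", max_nfev=max_nfev)
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("PK fit start %d failed: %s", k, exc)
            continue
        nfev += res.nfev
        if best is None or res.cost < best.cost - 1e-12:
            best = res

    if best is None:
        return FitResult({}, None, math.inf, False, None, nfev, "all starts failed")

    est_log = {name: float(th) for name, th in zip(vary, best.x)}
    estimates = dict(base)
    estimates.update({name: math.exp(v) for name, v in est_log.items()})
    estimates["F"] = init.F
    cov = _covariance_from_fit(best, n_obs)
    converged = bool(best.success) and cov is not None
    ses = None
    if converged:
        se_log = np.sqrt(np.diag(cov))
        ses = {name: estimates[name] * float(s) for name, s in zip(vary, se_log)}
    return FitResult(
        estimates=estimates,
        standard_errors=ses,
        objective=float(2.0 * best.cost),
        converged=converged,
        covariance=cov,
        n_evaluations=nfev,
        message=best.message,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

PK_CSV_COLUMNS = ["animal_id", "dose_group_ug", "time_h", "conc_ug_per_ml", "below_lloq"]


def _as_pk_frame(data: pd.DataFrame | Sequence[PKObservation]) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        missing = set(PK_CSV_COLUMNS) - set(data.columns)
        if missing:
            raise ValueError(f"PK table missing columns: {sorted(missing)}")
        return data
    return pd.DataFrame(
        [(o.animal_id, o.dose_group, o.time, o.concentration, int(o.below_lloq))
         for o in data],
        columns=PK_CSV_COLUMNS,
    )


def read_pk_csv(path) -> pd.DataFrame:
    """Read a serum-concentration table (columns as in :data:`PK_CSV_COLUMNS`)."""
    df = pd.read_csv(path)
    return _as_pk_frame(df)


def write_pk_csv(df: pd.DataFrame, path) -> None:
    _as_pk_frame(df).to_csv(path, index=False)
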