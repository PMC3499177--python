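"""Simeoni-type tumor growth inhibition driven by the PK profile.

Unperturbed growth follows the exponential-then-linear switching law

    dw/dt = lambda0 * w / [1 + (lambda0 * w / lambda1)^psi]^(1/psi)

which is exponential at rate ``lambda0`` (1/h) for small tumors and linear at
rate ``lambda1`` (mm^3/h) for large ones, with ``psi`` (default 20) making
the switch sharp.  Drug effect is a saturating kill term acting on the
proliferating compartment: at serum concentration ``C`` the per-cell death
commitment rate is ``K(C) = Emax * C / (EC50 + C)``.  Committed cells pass
through a chain of transit (damage) compartments at rate ``k1`` before
leaving the tumor mass::

    dx1/dt = g(w) * x1 / w - K(C(t)) * x1
    dx2/dt = K(C(t)) * x1 - k1 * x2
    dxi/dt = k1 * (x_{i-1} - x_i)          i = 3..n+1
    w      = sum_i x_i

where ``g(w)`` is the switching growth function above.  The tumor-static
("eradication") concentration is the steady exposure at which kill exactly
balances exponential-phase growth: ``CT = lambda0 * EC50 / (Emax - lambda0)``,
finite only when ``Emax > lambda0``.

Volumes are mm^3 (1 mL = 1000 mm^3 for reporting), time in hours.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .pk import (
    DoseRegimen,
    FitResult,
    PKParams,
    _covariance_from_fit,
    _exponential_terms,
    regimen_concentration,
)

logger = logging.getLogger("xenopkpd.tgi")

#: volume bridge for reporting growth rates quoted per mL
MM3_PER_ML = 1000.0
#: floor applied to volumes in log-scale fitting objectives (mm^3)
LOG_VOLUME_FLOOR_MM3 = 1.0

__all__ = [
    "MM3_PER_ML",
    "LOG_VOLUME_FLOOR_MM3",
    "TGIParams",
    "TumorTimecourse",
    "TumorObservation",
    "kill_rate",
    "unperturbed_growth",
    "simulate_tgi",
    "eradication_concentration",
    "fit_tgi",
]


@dataclass(frozen=True)
class TGIParams:
    """Growth, kill, and damage-transit parameters of the tumor model.

    ``lambda0`` (1/h) and ``lambda1`` (mm^3/h) are the exponential- and
    linear-phase growth parameters and are deliberately stored separately:
    the eradication criterion is only dimensionally coherent against the
    first-order rate.  ``lambda1 = inf`` selects the pure-exponential
    configuration.
    """

    lambda0: float
    lambda1: float
    Emax: float
    EC50: float
    k1: float
    w0: float = 300.0
    psi: float = 20.0
    n_transit: int = 3

    def __post_init__(self) -> None:
        for name in ("lambda0", "Emax", "EC50", "k1", "w0"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"TGIParams.{name} must be finite and > 0, got {v!r}")
        if not (self.lambda1 > 0):  # inf allowed
            raise ValueError(f"TGIParams.lambda1 must be > 0, got {self.lambda1!r}")
        if not math.isfinite(self.psi) or self.psi < 1:
            raise ValueError(f"TGIParams.psi must be >= 1, got {self.psi!r}")
        if self.n_transit < 1:
            raise ValueError(f"TGIParams.n_transit must be >= 1, got {self.n_transit!r}")


@dataclass
class TumorTimecourse:
    """Tumor volume trajectory split into proliferating and damage compartments."""

    times: np.ndarray
    total_volume: np.ndarray
    proliferating_volume: np.ndarray
    damaged_volumes: np.ndarray  # shape (n_times, n_transit)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.total_volume = np.asarray(self.total_volume, dtype=float)


@dataclass(frozen=True)
class TumorObservation:
    """One caliper measurement (length x width x height, mm^3) from one animal."""

    animal_id: str
    dose_group: float
    time: float
    volume: float

    def __post_init__(self) -> None:
        if self.volume < 0:
            raise ValueError(f"volume must be >= 0 mm^3, got {self.volume!r}")


def kill_rate(C, Emax: float, EC50: float):
    """Saturating per-cell death commitment rate Emax*C/(EC50+C), 1/h."""
    C_arr = np.asarray(C, dtype=float)
    if np.any(C_arr < 0):
        raise ValueError(f"concentration must be >= 0, got minimum {C_arr.min()!r}")
    if Emax < 0 or EC50 <= 0:
        raise ValueError(f"need Emax >= 0 and EC50 > 0, got Emax={Emax!r}, EC50={EC50!r}")
    out = Emax * C_arr / (EC50 + C_arr)
    return float(out) if np.isscalar(C) else out


def _per_capita_growth(w: float, p: TGIParams) -> float:
    """Switching per-capita growth rate g(w)/w, numerically stable for large w."""
    if w <= 0:
        return 0.0
    if not math.isfinite(p.lambda1):
        return p.lambda0
    r = p.lambda0 * w / p.lambda1
    if r < 1e-12:
        return p.lambda0
    if r > 1.0:
        # (1 + r^psi)^(1/psi) = r * (1 + r^-psi)^(1/psi), avoids overflow
        return p.lambda0 / (r * (1.0 + r ** (-p.psi)) ** (1.0 / p.psi))
    return p.lambda0 / (1.0 + r ** p.psi) ** (1.0 / p.psi)


def unperturbed_growth(
    params: TGIParams,
    times: Sequence[float] | np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-9,
) -> TumorTimecourse:
    """Drug-free tumor growth from ``w0`` (all mass proliferating)."""
    t = _validated_times(times)

    def rhs(tt, y):
        return [_per_capita_growth(y[0], params) * y[0]]

    if t[-1] == 0.0:
        w = np.full(t.size, params.w0)
    else:
        sol = solve_ivp(rhs, (0.0, t[-1]), [params.w0], t_eval=t,
                        method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:  # pragma: no cover - defensive
            raise RuntimeError(f"growth integration failed: {sol.message}")
        w = sol.y[0]
    damaged = np.zeros((t.size, params.n_transit))
    return TumorTimecourse(t, w.copy(), w.copy(), damaged)


def _validated_times(times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(t)) or np.any(t < 0):
        raise ValueError("times must be finite and >= 0 h")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return t


def simulate_tgi(
    tgi: TGIParams,
    pk: PKParams | None = None,
    regimen: DoseRegimen | None = None,
    times: Sequence[float] | np.ndarray = (),
    conc_fn: Callable[[np.ndarray], np.ndarray] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-9,
) -> TumorTimecourse:
    """Simulate the transit-compartment tumor model under a drug exposure.

    The driving concentration is the central serum concentration: either the
    closed-form profile of ``pk`` under ``regimen`` or an arbitrary
    ``conc_fn(t)`` (e.g. a constant exposure for threshold studies).  The
    integration restarts at dose times, where the exposure has a slope
    discontinuity.  Total volume is the sum of all compartments by
    construction.
    """
    t = _validated_times(times)
    use_pk = conc_fn is None
    if use_pk:
        if pk is None or regimen is None:
            raise ValueError("provide either conc_fn or both pk params and a regimen")
        dose_times = [ev.time for ev in regimen.events if 0.0 < ev.time < t[-1]]
        lams, base_coeffs = _exponential_terms(pk)
        ev_t0 = np.array([ev.time for ev in regimen.events])
        ev_scale = np.array([pk.F * ev.amount * pk.ka / pk.Vc for ev in regimen.events])
    else:
        dose_times = []

    n = tgi.n_transit
    emax, ec50, k1 = tgi.Emax, tgi.EC50, tgi.k1

    def make_rhs(seg_conc):
        def rhs(tt, y):
            w = float(np.sum(y))
            x1 = y[0]
            c = seg_conc(tt)
            k = emax * c / (ec50 + c)
            dy = np.empty(n + 1)
            dy[0] = _per_capita_growth(w, tgi) * x1 - k * x1
            dy[1] = k * x1 - k1 * y[1]
            for i in range(2, n + 1):
                dy[i] = k1 * (y[i - 1] - y[i])
            return dy
        return rhs

    def segment_conc(seg_start: float):
        # within a segment the active-dose superposition collapses onto the
        # model's three exponentials; all exponents are non-positive
        if not use_pk:
            def conc(tt):
                c = conc_fn(tt)
                return max(float(c if np.isscalar(c) else np.atleast_1d(c)[0]), 0.0)
            return conc
        active = ev_t0 <= seg_start + 1e-12
        if not np.any(active):
            return lambda tt: 0.0
        B = (ev_scale[active, None] * base_coeffs[None, :]
             * np.exp(-lams[None, :] * (seg_start - ev_t0[active, None]))).sum(axis=0)

        def conc(tt):
            return max(float(B @ np.exp(-lams * (tt - seg_start))), 0.0)
        return conc

    y = np.zeros(n + 1)
    y[0] = tgi.w0
    breakpoints = np.unique(np.concatenate([[0.0], dose_times, [t[-1]]]))
    out = np.empty((t.size, n + 1))
    if breakpoints.size == 1:
        out[:] = y
    for seg_start, seg_end in zip(breakpoints[:-1], breakpoints[1:]):
        sel = (t >= seg_start) & ((t < seg_end) | (t == t[-1]) & (seg_end == t[-1]))
        t_query = t[sel]
        t_eval = np.union1d(t_query, [seg_end])
        sol = solve_ivp(make_rhs(segment_conc(seg_start)), (seg_start, seg_end), y,
                        t_eval=t_eval, method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:  # pragma: no cover - defensive
            raise RuntimeError(f"TGI integration failed on [{seg_start}, {seg_end}]: {sol.message}")
        if np.any(sol.y < -1e-6 * tgi.w0):
            raise RuntimeError("negative tumor compartment beyond solver tolerance; "
                               "tighten tolerances or check parameters")
        if t_query.size:
            out[sel] = sol.y[:, np.searchsorted(sol.t, t_query)].T
        y = np.clip(sol.y[:, -1], 0.0, None)

    out = np.clip(out, 0.0, None)
    return TumorTimecourse(
        times=t,
        total_volume=out.sum(axis=1),
        proliferating_volume=out[:, 0],
        damaged_volumes=out[:, 1:],
    )


def eradication_concentration(tgi: TGIParams) -> float:
    """Tumor-static (eradication) concentration, ug/mL.

    Solves ``Emax*CT/(EC50+CT) = lambda0`` for the steady exposure at which
    drug-induced kill exactly balances exponential-phase growth:
    ``CT = lambda0*EC50/(Emax - lambda0)``.  Raises when ``Emax <= lambda0``
    (no finite exposure eradicates the tumor); the condition is reported,
    never a number.
    """
    if tgi.Emax <= tgi.lambda0:
        raise ValueError(
            f"no finite eradication concentration: Emax ({tgi.Emax} 1/h) does not exceed "
            f"the exponential growth rate lambda0 ({tgi.lambda0} 1/h)"
        )
    return tgi.lambda0 * tgi.EC50 / (tgi.Emax - tgi.lambda0)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

TUMOR_CSV_COLUMNS = ["animal_id", "dose_group_ug", "time_h", "volume_mm3"]


def _as_tumor_frame(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        missing = set(TUMOR_CSV_COLUMNS) - set(data.columns)
        if missing:
            raise ValueError(f"tumor table missing columns: {sorted(missing)}")
        return data
    return pd.DataFrame(
        [(o.animal_id, o.dose_group, o.time, o.volume) for o in data],
        columns=TUMOR_CSV_COLUMNS,
    )


def _log_floored(v: np.ndarray) -> np.ndarray:
    return np.log(np.maximum(v, LOG_VOLUME_FLOOR_MM3))


def fit_tgi(
    data,
    regimens: Mapping[float, DoseRegimen],
    pk: PKParams,
    init: TGIParams,
    n_starts: int = 1,
    seed: int = 0,
    max_nfev: int = 400,
    rtol: float = 1e-8,
) -> FitResult:
    """Fit the tumor model to group-mean volume curves, sequentially.

    Stage 1 fits the growth parameters (``lambda0``, ``lambda1``, ``w0``) on
    the control group (dose 0); stage 2 fits the kill parameters (``Emax``,
    ``EC50``, ``k1``) on the treated groups with growth and PK fixed.  The
    objective is least squares on log volumes floored at 1 mm^3 (eradicated
    tumors recorded as 0).  ``psi`` and ``n_transit`` are taken from ``init``
    and held fixed.
    """
    df = _as_tumor_frame(data)
    doses = sorted(df["dose_group_ug"].unique())
    if 0.0 not in doses:
        raise ValueError("growth unidentifiable: no control (dose 0) group in the data")
    treated = [d for d in doses if d > 0]
    if len(treated) < 2:
        raise ValueError(
            f"need >= 2 treated dose groups to identify Emax and EC50, got {len(treated)}"
        )

    means = (df.groupby(["dose_group_ug", "time_h"])["volume_mm3"]
             .mean().reset_index())
    ctrl = means[means["dose_group_ug"] == 0.0]
    t_ctrl = ctrl["time_h"].to_numpy()
    logv_ctrl = _log_floored(ctrl["volume_mm3"].to_numpy())

    rng = np.random.default_rng(seed)
    nfev_total = 0

    # -- stage 1: growth on control ------------------------------------------------
    def ctrl_residuals(theta):
        lam0, lam1, w0 = np.exp(theta)
        try:
            p = replace(init, lambda0=lam0, lambda1=lam1, w0=w0)
        except ValueError:
            return np.full(t_ctrl.size, 1e6)
        tc = unperturbed_growth(p, t_ctrl, rtol=rtol)
        return _log_floored(tc.total_volume) - logv_ctrl

    theta0_g = np.log([init.lambda0, init.lambda1 if math.isfinite(init.lambda1) else 1e3,
                       init.w0])
    best_g = None
    for k in range(max(1, n_starts)):
        start = theta0_g if k == 0 else theta0_g + rng.uniform(-math.log(3), math.log(3), 3)
        res = least_squares(ctrl_residuals, start, method="lm", max_nfev=max_nfev)
        nfev_total += res.nfev
        if best_g is None or res.cost < best_g.cost - 1e-12:
            best_g = res
    lam0, lam1, w0 = np.exp(best_g.x)
    growth_fit = replace(init, lambda0=lam0, lambda1=lam1, w0=w0)
    cov_g = _covariance_from_fit(best_g, t_ctrl.size)

    # -- stage 2: kill on treated groups -------------------------------------------
    groups = []
    for d in treated:
        sub = means[means["dose_group_ug"] == d]
        if d not in regimens:
            raise ValueError(f"no dosing regimen supplied for tumor dose group {d} ug")
        groups.append((regimens[d], sub["time_h"].to_numpy(),
                       _log_floored(sub["volume_mm3"].to_numpy())))
    n_obs_k = int(sum(t.size for _, t, _ in groups))

    def kill_residuals(theta):
        emax, ec50, k1 = np.exp(theta)
        try:
            p = replace(growth_fit, Emax=emax, EC50=ec50, k1=k1)
        except ValueError:
            return np.full(n_obs_k, 1e6)
        res = []
        for regimen, t, logv in groups:
            tc = simulate_tgi(p, pk=pk, regimen=regimen, times=t, rtol=rtol)
            res.append(_log_floored(tc.total_volume) - logv)
        return np.concatenate(res)

    theta0_k = np.log([init.Emax, init.EC50, init.k1])
    best_k = None
    for k in range(max(1, n_starts)):
        start = theta0_k if k == 0 else theta0_k + rng.uniform(-math.log(3), math.log(3), 3)
        res = least_squares(kill_residuals, start, method="lm", max_nfev=max_nfev)
        nfev_total += res.nfev
        if best_k is None or res.cost < best_k.cost - 1e-12:
            best_k = res
    emax, ec50, k1 = np.exp(best_k.x)
    cov_k = _covariance_from_fit(best_k, n_obs_k)

    estimates = {
        "lambda0": float(lam0), "lambda1": float(lam1), "w0": float(w0),
        "Emax": float(emax), "EC50": float(ec50), "k1": float(k1),
        "psi": init.psi, "n_transit": float(init.n_transit),
    }
    converged = bool(best_g.success and best_k.success) and cov_g is not None and cov_k is not None
    ses = None
    if converged:
        se_g = np.sqrt(np.diag(cov_g))
        se_k = np.sqrt(np.diag(cov_k))
        ses = {
            "lambda0": float(lam0 * se_g[0]), "lambda1": float(lam1 * se_g[1]),
            "w0": float(w0 * se_g[2]),
            "Emax": float(emax * se_k[0]), "EC50": float(ec50 * se_k[1]),
            "k1": float(k1 * se_k[2]),
        }
    return FitResult(
        estimates=estimates,
        standard_errors=ses,
        objective=float(2.0 * (best_g.cost + best_k.cost)),
        converged=converged,
        covariance=cov_k,
        n_evaluations=nfev_total,
        message=f"growth: {best_g.message}; kill: {best_k.message}",
    )


def read_tumor_csv(path) -> pd.DataFrame:
    """Read a tumor-volume table (columns as in :data:`TUMOR_CSV_COLUMNS`)."""
    df = pd.read_csv(path)
    if "day" in df.columns and "time_h" not in df.columns:
        df = df.assign(time_h=df["day"] * 24.0).drop(columns=["day"])
    return _as_tumor_frame(df)


def write_tumor_csv(df: pd.DataFrame, path) -> None:
    _as_tumor_frame(df).to_csv(path, index=False)
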