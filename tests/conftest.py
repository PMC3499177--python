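"""Shared fixtures and independent numerical oracles.

The oracles re-implement the model right-hand sides from scratch and
integrate them with a different adaptive method and much tighter tolerances
than the package uses, so agreement is a genuine cross-check rather than a
tautology.
"""
import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.integrate import solve_ivp

from xenopkpd import synthetic as syn
from xenopkpd.pk import PKParams, regimen_concentration

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def printed_pk() -> PKParams:
    return syn.printed_pk_params()


@pytest.fixture(scope="session")
def truth() -> syn.TruthSet:
    return syn.default_truth()


def random_pk_params(rng: np.random.Generator) -> PKParams:
    """A physiologically sensible random parameter draw with well-separated rates."""
    while True:
        p = PKParams(
            ka=float(np.exp(rng.uniform(np.log(0.05), np.log(2.0)))),
            Vc=float(rng.uniform(1.0, 5.0)),
            CL=float(rng.uniform(1.0, 10.0)) / 24.0,
            Q=float(np.exp(rng.uniform(np.log(0.01), np.log(0.2)))),
            Vp=float(rng.uniform(0.5, 8.0)),
        )
        alpha, beta = p.disposition_eigenvalues()
        seps = [abs(p.ka - alpha), abs(p.ka - beta), abs(alpha - beta)]
        if min(seps) > 1e-3 * p.ka:
            return p


def pk_ode_oracle(params: PKParams, regimen, times, rtol=1e-12, atol=1e-14):
    """High-accuracy depot/central/peripheral integration, independent of the
    package's simulation path (own RHS, Radau, event-split segments)."""
    ka = params.ka
    k10, k12, k21 = params.micro_rates()

    def rhs(t, y):
        ad, ac, ap_ = y
        return [-ka * ad,
                ka * ad - (k10 + k12) * ac + k21 * ap_,
                k12 * ac - k21 * ap_]

    t = np.asarray(times, dtype=float)
    dose_map = {ev.time: params.F * ev.amount for ev in regimen.events if ev.time <= t[-1]}
    bps = np.unique(np.concatenate([[0.0], list(dose_map), [t[-1]]]))
    y = np.zeros(3)
    out = np.empty(t.size)
    if bps.size == 1:
        out[:] = 0.0
    for a, b in zip(bps[:-1], bps[1:]):
        if a in dose_map:
            y[0] += dose_map[a]
        sel = (t >= a) & ((t < b) | (t == t[-1]) & (b == t[-1]))
        te = np.union1d(t[sel], [b])
        sol = solve_ivp(rhs, (a, b), y, t_eval=te, method="Radau", rtol=rtol, atol=atol)
        assert sol.success
        if t[sel].size:
            out[sel] = sol.y[1, np.searchsorted(sol.t, t[sel])]
        y = sol.y[:, -1].copy()
    return out / params.Vc


def tgi_ode_oracle(p, pk, regimen, times, rtol=1e-11, atol=1e-13):
    """Independent stiff integration of the transit tumor model (Radau, own RHS,
    exposure evaluated through the superposed closed form at every step)."""
    n = p.n_transit

    def growth(w):
        if w <= 0:
            return 0.0
        if not math.isfinite(p.lambda1):
            return p.lambda0
        r = p.lambda0 * w / p.lambda1
        if r <= 1.0:
            return p.lambda0 / (1.0 + r ** p.psi) ** (1.0 / p.psi)
        return p.lambda0 / (r * (1.0 + r ** (-p.psi)) ** (1.0 / p.psi))

    def rhs(t, y):
        w = float(np.sum(y))
        c = float(np.atleast_1d(regimen_concentration(pk, regimen, t))[0])
        k = p.Emax * c / (p.EC50 + c)
        dy = np.empty(n + 1)
        dy[0] = growth(w) * y[0] - k * y[0]
        dy[1] = k * y[0] - p.k1 * y[1]
        for i in range(2, n + 1):
            dy[i] = p.k1 * (y[i - 1] - y[i])
        return dy

    t = np.asarray(times, dtype=float)
    y0 = np.zeros(n + 1)
    y0[0] = p.w0
    sol = solve_ivp(rhs, (0.0, t[-1]), y0, t_eval=t, method="Radau",
                    rtol=rtol, atol=atol, max_step=42.0)
    assert sol.success
    return sol.y.sum(axis=0)


def binding_equilibrium_oracle(L_total, U_total, Kd, R_total, tol=1e-14):
    """Brute-force competitive-binding equilibrium including receptor depletion.

    Fixed-point iteration on free ligand concentrations for two species of
    equal affinity competing for R_total receptors; returns the labeled-bound
    fraction of receptors.  As R_total -> 0 this converges to the
    no-depletion expression.
    """
    Lf, Uf = L_total, U_total
    for _ in range(10000):
        Rf = R_total / (1.0 + Lf / Kd + Uf / Kd)
        Lf_new = L_total / (1.0 + Rf / Kd)
        Uf_new = U_total / (1.0 + Rf / Kd)
        if abs(Lf_new - Lf) < tol and abs(Uf_new - Uf) < tol:
            Lf, Uf = Lf_new, Uf_new
            break
        Lf, Uf = Lf_new, Uf_new
    Rf = R_total / (1.0 + Lf / Kd + Uf / Kd)
    bound_L = Rf * Lf / Kd
    return bound_L / R_total
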