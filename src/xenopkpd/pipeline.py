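"""Study-level orchestration: simulate -> fit PK -> fit occupancy -> fit TGI
-> eradication threshold -> machine-readable report.

Estimation is sequential, mirroring the analysis order of the underlying
study: the PK model is fitted first, the fitted exposure then drives the
tumor model (no joint PK/PD fit).  Each stage's failure is recorded in the
report explicitly; later stages fall back to the configured initial
parameters where an upstream fit is unavailable.

Configuration and reports are pydantic models, so both are schema-validated
JSON documents; the report carries provenance (config hash, seed, package
version) so every number is traceable.
"""
from __future__ import annotations

import hashlib
import logging
import math
from datetime import datetime, timezone
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from . import occupancy as occ
from . import pk as pkmod
from . import synthetic as syn
from . import tgi as tgimod
from .occupancy import OccupancyParams
from .pk import HOURS_PER_DAY, DoseEvent, PKParams
from .tgi import TGIParams

logger = logging.getLogger("xenopkpd.pipeline")

__all__ = [
    "PipelineConfig",
    "StudyReport",
    "RecoveryReport",
    "run_study_pipeline",
    "parameter_recovery_experiment",
    "save_plots",
]


# ---------------------------------------------------------------------------
# configuration models
# ---------------------------------------------------------------------------

class PKTruthConfig(BaseModel):
    """PK generating truth / fit initialization, unit-suffixed keys."""

    ka_per_h: float = 0.54
    Vc_mL: float = 2.61
    CL_mL_per_day: float = 3.11
    Q_mL_per_h: float = 0.04
    Vp_mL: float = 2.6
    F: float = 1.0

    def to_params(self) -> PKParams:
        return PKParams.from_daily_clearance(self.ka_per_h, self.Vc_mL,
                                             self.CL_mL_per_day, self.Q_mL_per_h,
                                             self.Vp_mL, self.F)


class TGITruthConfig(BaseModel):
    lambda0_per_h: float = 0.005
    lambda1_mm3_per_h: Optional[float] = 6.0  # null selects pure-exponential growth
    Emax_per_h: float = 0.011
    EC50_ug_per_mL: float = 5.0
    k1_per_h: float = 0.03
    w0_mm3: float = 300.0
    psi: float = 20.0
    n_transit: int = 3

    def to_params(self) -> TGIParams:
        lam1 = math.inf if self.lambda1_mm3_per_h is None else self.lambda1_mm3_per_h
        return TGIParams(lambda0=self.lambda0_per_h, lambda1=lam1,
                         Emax=self.Emax_per_h, EC50=self.EC50_ug_per_mL,
                         k1=self.k1_per_h, w0=self.w0_mm3, psi=self.psi,
                         n_transit=self.n_transit)


class OccupancyTruthConfig(BaseModel):
    Kd_nM: float = 0.922
    Smax_pct: float = 100.0

    def to_params(self) -> OccupancyParams:
        return OccupancyParams(Kd=self.Kd_nM, Smax=self.Smax_pct)


class TruthConfig(BaseModel):
    pk: PKTruthConfig = Field(default_factory=PKTruthConfig)
    tgi: TGITruthConfig = Field(default_factory=TGITruthConfig)
    occupancy: OccupancyTruthConfig = Field(default_factory=OccupancyTruthConfig)

    def to_truth(self) -> syn.TruthSet:
        return syn.TruthSet(pk=self.pk.to_params(), tgi=self.tgi.to_params(),
                            occupancy=self.occupancy.to_params())


class DesignConfig(BaseModel):
    """Mirror of :class:`xenopkpd.synthetic.StudyDesign` for JSON configs."""

    groups: list[tuple[float, int]] = [(0.0, 10), (5.0, 10), (20.0, 10),
                                       (200.0, 10), (500.0, 10)]
    pk_doses: list[float] = [20.0, 200.0, 500.0]
    pk_n_per_timepoint: int = 5
    pk_sampling_days: list[float] = [1.0, 2.0, 3.0, 4.0, 7.0, 14.0]
    dose_interval_h: float = 84.0
    dosing_pattern: Literal["uniform", "3-4"] = "uniform"
    dosing_duration_days: float = 50.0
    study_duration_days: float = 52.0
    tumor_measurement_interval_days: float = 3.5
    pk_noise_cv: float = 0.20
    tumor_noise_cv: float = 0.15
    tumor_additive_sd_mm3: float = 5.0
    w0_cv: float = 0.20
    lloq_ug_per_mL: float = 0.05
    ratio_noise_cv: float = 0.05
    invivo_sat_sd_pct: float = 5.0

    def to_design(self, seed: int) -> syn.StudyDesign:
        return syn.StudyDesign(
            groups=tuple((float(d), int(n)) for d, n in self.groups),
            pk_doses=tuple(self.pk_doses),
            pk_n_per_timepoint=self.pk_n_per_timepoint,
            pk_sampling_days=tuple(self.pk_sampling_days),
            dose_interval_h=self.dose_interval_h,
            dosing_pattern=self.dosing_pattern,
            dosing_duration_days=self.dosing_duration_days,
            study_duration_days=self.study_duration_days,
            tumor_measurement_interval_days=self.tumor_measurement_interval_days,
            pk_noise_cv=self.pk_noise_cv,
            tumor_noise_cv=self.tumor_noise_cv,
            tumor_additive_sd=self.tumor_additive_sd_mm3,
            w0_cv=self.w0_cv,
            lloq=self.lloq_ug_per_mL,
            ratio_noise_cv=self.ratio_noise_cv,
            invivo_sat_sd_pct=self.invivo_sat_sd_pct,
            seed=seed,
        )


class InputsConfig(BaseModel):
    """Optional external tables; every path unset means synthesis."""

    pk_csv: Optional[str] = None
    tumor_csv: Optional[str] = None
    saturation_invitro_csv: Optional[str] = None


class FitConfig(BaseModel):
    pk_n_starts: int = 5
    pk_vary: list[str] = ["ka", "Vc", "CL"]
    tgi_n_starts: int = 1
    fit_smax: bool = False


class PipelineConfig(BaseModel):
    """Top-level configuration for the study pipeline."""

    seed: int = 0
    stages: list[Literal["pk", "occupancy", "tgi"]] = ["pk", "occupancy", "tgi"]
    design: DesignConfig = Field(default_factory=DesignConfig)
    truth: TruthConfig = Field(default_factory=TruthConfig)
    inputs: InputsConfig = Field(default_factory=InputsConfig)
    fit: FitConfig = Field(default_factory=FitConfig)

    def config_hash(self) -> str:
        return hashlib.sha256(
            self.model_dump_json().encode("utf-8")).hexdigest()[:16]


# ---------------------------------------------------------------------------
# report models
# ---------------------------------------------------------------------------

class StageResult(BaseModel):
    name: str
    ok: bool
    converged: Optional[bool] = None
    estimates: dict[str, float] = {}
    standard_errors: Optional[dict[str, float]] = None
    objective: Optional[float] = None
    error: Optional[str] = None


class DoseProportionalityRow(BaseModel):
    """Modeled single-dose exposure metrics per dose, with exact linear scaling
    from the reference (lowest) dose."""

    dose_ug: float
    cmax_ug_per_mL: float
    tmax_h: float
    auc_inf_ug_day_per_mL: float
    cmax_scaled_from_ref: float
    auc_scaled_from_ref: float


class Provenance(BaseModel):
    config_hash: str
    seed: int
    package_version: str
    timestamp: str


class StudyReport(BaseModel):
    """Full pipeline output; every number traces to a module fit or metric."""

    stages: list[StageResult]
    eradication_ug_per_mL: Optional[float] = None
    eradication_finite: Optional[bool] = None
    dose_proportionality: list[DoseProportionalityRow] = []
    flags: list[str] = []
    provenance: Provenance


class ParameterRecovery(BaseModel):
    truth: float
    estimates: list[float]
    mean_estimate: float
    relative_bias: float
    median_relative_error: float
    coverage_2se: Optional[float] = None


class RecoveryReport(BaseModel):
    """Monte-Carlo generate -> fit aggregate over seeds."""

    n_seeds: int
    n_failures: int
    stages: list[str]
    parameters: dict[str, ParameterRecovery]
    provenance: Provenance


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _provenance(config: PipelineConfig) -> Provenance:
    return Provenance(
        config_hash=config.config_hash(),
        seed=config.seed,
        package_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )


def run_study_pipeline(config: PipelineConfig) -> StudyReport:
    """Execute the configured stages sequentially and assemble the report.

    Stage failures are captured as explicit entries (``ok=False`` with the
    error message); downstream stages still run with initial-parameter
    fallbacks, so a partially failed study still produces a complete report.
    """
    design = config.design.to_design(seed=config.seed)
    truth = config.truth.to_truth()
    stages: list[StageResult] = []
    report_kwargs: dict = {}

    pk_for_tgi = truth.pk
    regimens = {d: design.regimen(d) for d in list(design.pk_doses)
                + [d for d, _ in design.groups]}

    if "pk" in config.stages:
        logger.info("stage pk: fitting two-compartment model (init ka=%.3g, Vc=%.3g, CL=%.3g mL/h)",
                    truth.pk.ka, truth.pk.Vc, truth.pk.CL)
        try:
            if config.inputs.pk_csv:
                pk_data = pkmod.read_pk_csv(config.inputs.pk_csv)
            else:
                pk_data = syn.generate_pk_dataset(truth, design)
            fit = pkmod.fit_pk(pk_data, regimens, truth.pk,
                               vary=tuple(config.fit.pk_vary),
                               n_starts=config.fit.pk_n_starts, seed=design.seed)
            stages.append(StageResult(name="pk", ok=True, converged=fit.converged,
                                      estimates=fit.estimates,
                                      standard_errors=fit.standard_errors,
                                      objective=fit.objective))
            if fit.converged:
                pk_for_tgi = PKParams(ka=fit.estimates["ka"], Vc=fit.estimates["Vc"],
                                      CL=fit.estimates["CL"], Q=fit.estimates["Q"],
                                      Vp=fit.estimates["Vp"], F=fit.estimates["F"])
        except Exception as exc:
            logger.warning("stage pk failed: %s", exc)
            stages.append(StageResult(name="pk", ok=False, error=str(exc)))

    if "occupancy" in config.stages:
        logger.info("stage occupancy: fitting Kd (init %.3g nM)", truth.occupancy.Kd)
        try:
            if config.inputs.saturation_invitro_csv:
                invitro = pd.read_csv(config.inputs.saturation_invitro_csv)
            else:
                invitro, _ = syn.generate_saturation_dataset(truth, design)
            fit = occ.fit_kd(invitro, truth.occupancy)
            stages.append(StageResult(name="occupancy", ok=True, converged=fit.converged,
                                      estimates=fit.estimates,
                                      standard_errors=fit.standard_errors,
                                      objective=fit.objective))
        except Exception as exc:
            logger.warning("stage occupancy failed: %s", exc)
            stages.append(StageResult(name="occupancy", ok=False, error=str(exc)))

    if "tgi" in config.stages:
        logger.info("stage tgi: fitting tumor model (PK %s)",
                    "from fitted stage" if pk_for_tgi is not truth.pk else "from config")
        try:
            if config.inputs.tumor_csv:
                tumor_data = tgimod.read_tumor_csv(config.inputs.tumor_csv)
            else:
                tumor_data = syn.generate_tumor_dataset(truth, design)
            fit = tgimod.fit_tgi(tumor_data, regimens, pk_for_tgi, truth.tgi,
                                 n_starts=config.fit.tgi_n_starts, seed=design.seed)
            stages.append(StageResult(name="tgi", ok=True, converged=fit.converged,
                                      estimates=fit.estimates,
                                      standard_errors=fit.standard_errors,
                                      objective=fit.objective))
            fitted = TGIParams(lambda0=fit.estimates["lambda0"],
                               lambda1=fit.estimates["lambda1"],
                               Emax=fit.estimates["Emax"], EC50=fit.estimates["EC50"],
                               k1=fit.estimates["k1"], w0=fit.estimates["w0"],
                               psi=truth.tgi.psi, n_transit=truth.tgi.n_transit)
            try:
                ct = tgimod.eradication_concentration(fitted)
                report_kwargs["eradication_ug_per_mL"] = ct
                report_kwargs["eradication_finite"] = True
            except ValueError:
                report_kwargs["eradication_ug_per_mL"] = None
                report_kwargs["eradication_finite"] = False
        except Exception as exc:
            logger.warning("stage tgi failed: %s", exc)
            stages.append(StageResult(name="tgi", ok=False, error=str(exc)))

    dp_rows = []
    if design.pk_doses:
        ref = min(design.pk_doses)
        dense = np.linspace(0.0, design.dose_interval_h, 2001)[1:]
        ref_metrics = None
        for dose in design.pk_doses:
            tc = pkmod.simulate_pk_profile(pk_for_tgi, pkmod.DoseRegimen.single(dose),
                                           np.concatenate([[0.0], dense]))
            m = pkmod.pk_metrics(tc, pk_for_tgi, DoseEvent(0.0, dose))
            if dose == ref:
                ref_metrics = m
            dp_rows.append(DoseProportionalityRow(
                dose_ug=dose, cmax_ug_per_mL=m.cmax, tmax_h=m.tmax_h,
                auc_inf_ug_day_per_mL=m.auc_inf_single,
                cmax_scaled_from_ref=pkmod.scale_dose_proportional(ref_metrics.cmax, ref, dose),
                auc_scaled_from_ref=pkmod.scale_dose_proportional(
                    ref_metrics.auc_inf_single, ref, dose),
            ))

    flags = []
    if (design.pk_noise_cv == 0 and design.tumor_noise_cv == 0
            and design.tumor_additive_sd == 0 and design.w0_cv == 0
            and design.ratio_noise_cv == 0):
        flags.append("noise-free")

    return StudyReport(stages=stages, dose_proportionality=dp_rows, flags=flags,
                       provenance=_provenance(config), **report_kwargs)


def parameter_recovery_experiment(
    config: PipelineConfig,
    n_seeds: int,
    stages: Sequence[str] = ("pk", "occupancy"),
) -> RecoveryReport:
    """Repeat generate -> fit across seeds; aggregate bias and 2-SE coverage.

    PK (and optionally occupancy) recovery; each seed gets an independent
    deterministic sub-stream derived from the base seed.  Individual seed
    failures are excluded with their count reported.
    """
    if n_seeds < 10:
        raise ValueError(f"need >= 10 seeds for a coverage estimate, got {n_seeds}")
    truth = config.truth.to_truth()
    truth_vals: dict[str, float] = {}
    if "pk" in stages:
        truth_vals.update({f"pk.{n}": getattr(truth.pk, n)
                           for n in ("ka", "Vc", "CL", "Q", "Vp")})
    if "occupancy" in stages:
        truth_vals["occupancy.Kd"] = truth.occupancy.Kd

    ests: dict[str, list[float]] = {k: [] for k in truth_vals}
    hits: dict[str, list[bool]] = {k: [] for k in truth_vals}
    n_failures = 0
    for i in range(n_seeds):
        seed_i = int((config.seed * 100003 + 7919 * i + 1) % (2**31 - 1))
        design = config.design.to_design(seed=seed_i)
        try:
            if "pk" in stages:
                data = syn.generate_pk_dataset(truth, design)
                regimens = {d: design.regimen(d) for d in design.pk_doses}
                fit = pkmod.fit_pk(data, regimens, truth.pk,
                                   vary=tuple(config.fit.pk_vary),
                                   n_starts=config.fit.pk_n_starts, seed=seed_i)
                for n in ("ka", "Vc", "CL", "Q", "Vp"):
                    key = f"pk.{n}"
                    ests[key].append(fit.estimates[n])
                    if fit.standard_errors and n in fit.standard_errors:
                        hits[key].append(
                            abs(fit.estimates[n] - truth_vals[key])
                            <= 2.0 * fit.standard_errors[n])
            if "occupancy" in stages:
                invitro, _ = syn.generate_saturation_dataset(truth, design)
                fit = occ.fit_kd(invitro, truth.occupancy)
                ests["occupancy.Kd"].append(fit.estimates["Kd"])
                if fit.standard_errors:
                    hits["occupancy.Kd"].append(
                        abs(fit.estimates["Kd"] - truth_vals["occupancy.Kd"])
                        <= 2.0 * fit.standard_errors["Kd"])
        except Exception as exc:
            logger.warning("recovery seed %d failed: %s", seed_i, exc)
            n_failures += 1

    parameters = {}
    for key, truth_v in truth_vals.items():
        e = np.asarray(ests[key], dtype=float)
        if e.size == 0:
            continue
        parameters[key] = ParameterRecovery(
            truth=truth_v,
            estimates=[float(x) for x in e],
            mean_estimate=float(e.mean()),
            relative_bias=float((e.mean() - truth_v) / truth_v),
            median_relative_error=float(np.median(np.abs(e - truth_v) / truth_v)),
            coverage_2se=(float(np.mean(hits[key])) if hits[key] else None),
        )
    return RecoveryReport(n_seeds=n_seeds, n_failures=n_failures,
                          stages=list(stages), parameters=parameters,
                          provenance=_provenance(config))


# ---------------------------------------------------------------------------
# plots (optional artifacts)
# ---------------------------------------------------------------------------

def save_plots(config: PipelineConfig, out_dir) -> list[str]:
    """Write concentration-time, tumor-growth, and standard-curve figures.

    Purely presentational; all numbers come from the same module calls the
    pipeline report uses.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.design.to_design(seed=config.seed)
    truth = config.truth.to_truth()
    written = []

    fig, ax = plt.subplots(figsize=(6, 4))
    t = np.linspace(0, 14 * HOURS_PER_DAY, 500)
    for dose in design.pk_doses:
        tc = pkmod.simulate_pk_profile(truth.pk, design.regimen(dose), t)
        ax.semilogy(t / HOURS_PER_DAY, np.maximum(tc.concentrations, 1e-3),
                    label=f"{dose:g} ug")
    ax.set(xlabel="time (days)", ylabel="serum concentration (ug/mL)",
           title="Modeled PK profiles, twice-weekly IP dosing")
    ax.legend()
    p = out / "pk_profiles.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(str(p))

    fig, ax = plt.subplots(figsize=(6, 4))
    t = design.tumor_measurement_times_h
    for dose, _ in design.groups:
        if dose <= 0:
            tc = tgimod.unperturbed_growth(truth.tgi, t)
        else:
            tc = tgimod.simulate_tgi(truth.tgi, pk=truth.pk,
                                     regimen=design.regimen(dose), times=t)
        ax.plot(t / HOURS_PER_DAY, tc.total_volume, label=f"{dose:g} ug")
    ax.set(xlabel="time (days)", ylabel="tumor volume (mm$^3$)",
           title="Modeled tumor growth inhibition")
    ax.legend()
    p = out / "tumor_growth.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(str(p))

    fig, ax = plt.subplots(figsize=(6, 4))
    invitro, _ = syn.generate_saturation_dataset(truth, design)
    curve = occ.build_standard_curve(invitro)
    ax.plot(curve.concs, curve.saturations, "o-")
    ax.set(xlabel="competitor concentration (nM)", ylabel="saturation (%)",
           title="Competition standard curve")
    p = out / "standard_curve.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(str(p))
    return written
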