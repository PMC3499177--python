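"""Synthetic xenograft studies with the statistical structure the analysis assumes.

Emulates the study design: nude mice bearing A431 epidermoid-carcinoma
xenografts (~300 mm^3 at treatment start) receive antibody intraperitoneally
twice weekly at 5/20/200/500 ug alongside a vehicle control; serum PK is
sampled on days 1, 2, 3, 4, 7 and 14 after the first dose (n = 5 per time
point; PK groups 20/200/500 ug); tumor volumes are recorded twice weekly; the
in vitro competition series runs unlabeled antibody at 0, 0.21, 0.63, 1.83,
5.64 and 17 nM against labeled antibody fixed at 6.8 nM.

Noise models are standard pharmacometric choices: mean-one lognormal
multiplicative noise for concentrations and assay ratios (strictly positive
data), additive-plus-proportional normal noise truncated at zero for tumor
volumes, per-animal baseline volumes drawn lognormally around 300 mm^3.  One
global seed spawns independent, deterministic sub-streams per dataset.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import occupancy as occ
from . import pk as pkmod
from . import tgi as tgimod
from .occupancy import OccupancyParams
from .pk import HOURS_PER_DAY, DoseRegimen, PKParams
from .tgi import TGIParams

logger = logging.getLogger("xenopkpd.synthetic")

__all__ = [
    "StudyDesign",
    "TruthSet",
    "printed_pk_params",
    "printed_occupancy_params",
    "printed_tgi_params",
    "study_consistent_tgi_params",
    "default_truth",
    "generate_pk_dataset",
    "generate_tumor_dataset",
    "generate_saturation_dataset",
    "write_bundle",
]


@dataclass(frozen=True)
class StudyDesign:
    """Study layout, sampling schedules, and noise levels for synthesis."""

    groups: tuple[tuple[float, int], ...] = ((0.0, 10), (5.0, 10), (20.0, 10),
                                             (200.0, 10), (500.0, 10))
    pk_doses: tuple[float, ...] = (20.0, 200.0, 500.0)
    pk_n_per_timepoint: int = 5
    pk_sampling_days: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 7.0, 14.0)
    dose_interval_h: float = pkmod.TWICE_WEEKLY_INTERVAL_H
    dosing_pattern: str = "uniform"
    dosing_duration_days: float = 50.0
    study_duration_days: float = 52.0
    tumor_measurement_interval_days: float = 3.5
    pk_noise_cv: float = 0.20
    tumor_noise_cv: float = 0.15
    tumor_additive_sd: float = 5.0
    w0_cv: float = 0.20
    lloq: float = pkmod.DEFAULT_LLOQ_UG_PER_ML
    invitro_concs_nM: tuple[float, ...] = occ.STANDARD_COMPETITOR_NM
    labeled_conc_nM: float = occ.DEFAULT_LABELED_NM
    invitro_replicates: int = 3
    ratio_noise_cv: float = 0.05
    invivo_days: tuple[float, ...] = (1.0, 3.0, 4.0, 7.0)
    invivo_n_per_day: int = 3
    invivo_sat_sd_pct: float = 5.0
    invivo_dose: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for _, n in self.groups):
            raise ValueError("every group must have n > 0 animals")
        for name in ("pk_noise_cv", "tumor_noise_cv", "tumor_additive_sd",
                     "w0_cv", "ratio_noise_cv", "invivo_sat_sd_pct"):
            if getattr(self, name) < 0:
                raise ValueError(f"StudyDesign.{name} must be >= 0")

    @property
    def n_doses(self) -> int:
        return int(self.dosing_duration_days * HOURS_PER_DAY // self.dose_interval_h) + 1

    def regimen(self, dose: float) -> DoseRegimen:
        """Twice-weekly regimen for a dose group; empty regimen for control."""
        if dose <= 0:
            return DoseRegimen(())
        return DoseRegimen.twice_weekly(dose, self.n_doses, self.dose_interval_h,
                                        self.dosing_pattern)

    @property
    def pk_sampling_times_h(self) -> np.ndarray:
        return np.asarray(self.pk_sampling_days, dtype=float) * HOURS_PER_DAY

    @property
    def tumor_measurement_times_h(self) -> np.ndarray:
        step = self.tumor_measurement_interval_days * HOURS_PER_DAY
        end = self.study_duration_days * HOURS_PER_DAY
        return np.arange(0.0, end + 0.5 * step, step)

    def noise_free(self) -> "StudyDesign":
        """Copy of the design with every noise source switched off."""
        return replace(self, pk_noise_cv=0.0, tumor_noise_cv=0.0,
                       tumor_additive_sd=0.0, w0_cv=0.0, ratio_noise_cv=0.0,
                       invivo_sat_sd_pct=0.0)


# ---------------------------------------------------------------------------
# truth sets
# ---------------------------------------------------------------------------

def printed_pk_params() -> PKParams:
    """PK truth from the reported mouse estimates: ka 0.54 1/h, Vc 2.61 mL,
    CL 3.11 mL/day; Q and Vp are unreported and carry assumed defaults."""
    return PKParams.from_daily_clearance(0.54, 2.61, 3.11, Q_mL_per_h=0.04, Vp_mL=2.6)


def printed_occupancy_params() -> OccupancyParams:
    """Binding truth from the reported estimate: Kd 0.922 nM, Smax 100%."""
    return OccupancyParams(Kd=0.922, Smax=100.0)


def printed_tgi_params(lambda0: float = 0.005, lambda1: float = 6.0) -> TGIParams:
    """Tumor parameters carrying the reported kill values (Emax 8.97 1/h,
    EC50 0.81 ug/mL) with growth rates supplied by the caller.

    A kill rate of ~9 1/h saturates at every study dose and empties the
    proliferating compartment within minutes of the first dose, so a study
    generated from these values carries no information about Emax or EC50;
    use :func:`study_consistent_tgi_params` for recovery work.
    """
    return TGIParams(lambda0=lambda0, lambda1=lambda1, Emax=8.97, EC50=0.81,
                     k1=0.03, w0=300.0)


def study_consistent_tgi_params() -> TGIParams:
    """Tumor truth reproducing the study's qualitative outcome.

    Growth: exponential at 0.005 1/h (doubling ~5.8 days) switching to a
    linear 6 mm^3/h phase near 1200 mm^3, matching control tumors reaching a
    few thousand mm^3 within three weeks from 300 mm^3.  Kill: Emax 0.011 1/h,
    EC50 5 ug/mL, transit rate 0.03 1/h — chosen so that the 5 and 20 ug
    groups are only partially inhibited while 200 and 500 ug drive
    regression, as observed, with a tumor-static concentration of
    ~4.2 ug/mL between the sustained exposures of those dose bands.
    """
    return TGIParams(lambda0=0.005, lambda1=6.0, Emax=0.011, EC50=5.0,
                     k1=0.03, w0=300.0)


@dataclass(frozen=True)
class TruthSet:
    """Generating parameters for a complete synthetic study."""

    pk: PKParams = field(default_factory=printed_pk_params)
    tgi: TGIParams = field(default_factory=study_consistent_tgi_params)
    occupancy: OccupancyParams = field(default_factory=printed_occupancy_params)


def default_truth() -> TruthSet:
    """Default truth: reported PK and Kd estimates; study-consistent tumor
    parameters (see :func:`study_consistent_tgi_params`)."""
    return TruthSet()


def _substream(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the requested CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(0.0, sigma, size=size) - 0.5 * sigma * sigma)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_pk_dataset(truth: TruthSet, design: StudyDesign) -> pd.DataFrame:
    """Serum-concentration observations at the design's sampling schedule.

    Noiseless profiles from the PK model multiplied by mean-one lognormal
    noise at ``pk_noise_cv``; values below the LLOQ are flagged (retained but
    censored for fitting).  Deterministic under the design seed.
    """
    rng = _substream(design.seed, 1)
    times = design.pk_sampling_times_h
    rows = []
    for dose in design.pk_doses:
        regimen = design.regimen(dose)
        tc = pkmod.simulate_pk_profile(truth.pk, regimen, times)
        for j, t in enumerate(times):
            noise = _lognormal_factor(rng, design.pk_noise_cv, design.pk_n_per_timepoint)
            for i in range(design.pk_n_per_timepoint):
                c = tc.concentrations[j] * noise[i]
                rows.append((f"pk-{dose:g}-{j}-{i}", dose, t, c, int(c < design.lloq)))
    return pd.DataFrame(rows, columns=pkmod.PK_CSV_COLUMNS)


def generate_tumor_dataset(truth: TruthSet, design: StudyDesign) -> pd.DataFrame:
    """Tumor-volume observations for all groups at the measurement schedule.

    Each animal gets a lognormally jittered baseline volume, its own model
    curve, then proportional (CV ``tumor_noise_cv``) plus additive
    (``tumor_additive_sd`` mm^3) normal noise, truncated at zero.
    """
    rng = _substream(design.seed, 2)
    times = design.tumor_measurement_times_h
    rows = []
    for dose, n_animals in design.groups:
        regimen = design.regimen(dose)
        w0_jitter = truth.tgi.w0 * _lognormal_factor(rng, design.w0_cv, n_animals)
        for i in range(n_animals):
            p = replace(truth.tgi, w0=float(w0_jitter[i]))
            if dose <= 0:
                tc = tgimod.unperturbed_growth(p, times)
            else:
                tc = tgimod.simulate_tgi(p, pk=truth.pk, regimen=regimen, times=times)
            prop = rng.normal(0.0, 1.0, times.size) * design.tumor_noise_cv
            add = rng.normal(0.0, 1.0, times.size) * design.tumor_additive_sd
            vols = np.maximum(tc.total_volume * (1.0 + prop) + add, 0.0)
            for t, v in zip(times, vols):
                rows.append((f"tv-{dose:g}-{i}", dose, float(t), float(v)))
    return pd.DataFrame(rows, columns=tgimod.TUMOR_CSV_COLUMNS)


def generate_saturation_dataset(
    truth: TruthSet, design: StudyDesign
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """In vitro competition series and in vivo saturation observations.

    In vitro: labeled-bound ratios from the competitive-binding model at the
    design's competitor grid, with mean-one lognormal noise on each replicate.
    In vivo: saturations predicted from the PK-driven serum concentration via
    the hyperbolic occupancy model, with additive normal noise clipped to
    [0, 100].
    """
    rng = _substream(design.seed, 3)
    kd = truth.occupancy.Kd
    L = design.labeled_conc_nM
    rows_vitro = []
    for U in design.invitro_concs_nM:
        r_true = occ.competitive_labeled_fraction(L, U, kd)
        noise = _lognormal_factor(rng, design.ratio_noise_cv, design.invitro_replicates)
        for i in range(design.invitro_replicates):
            rows_vitro.append((f"sc-{U:g}-{i}", U, L, float(r_true * noise[i])))
    invitro = pd.DataFrame(rows_vitro,
                           columns=["sample_id", "unlabeled_conc_nM", "labeled_conc_nM", "ratio"])

    regimen = design.regimen(design.invivo_dose)
    days = np.asarray(design.invivo_days, dtype=float)
    tc = pkmod.simulate_pk_profile(truth.pk, regimen, days * HOURS_PER_DAY)
    rows_vivo = []
    for day, c_serum in zip(days, tc.concentrations):
        sat_true = occ.occupancy_fraction(occ.nM_from_ug_per_mL(c_serum), truth.occupancy)
        noise = rng.normal(0.0, design.invivo_sat_sd_pct, design.invivo_n_per_day)
        for i in range(design.invivo_n_per_day):
            sat = float(np.clip(sat_true + noise[i], 0.0, 100.0))
            rows_vivo.append((f"iv-{day:g}-{i}", float(day), sat))
    invivo = pd.DataFrame(rows_vivo, columns=["sample_id", "day", "saturation_pct"])
    return invitro, invivo


def write_bundle(directory, truth: TruthSet, design: StudyDesign) -> dict:
    """Write all three datasets plus a manifest recording truth, design, seed.

    Emits the exact CSV dialects the pk, occupancy and tgi fitting interfaces
    consume.  Returns the manifest dict.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pk_df = generate_pk_dataset(truth, design)
    tumor_df = generate_tumor_dataset(truth, design)
    invitro, invivo = generate_saturation_dataset(truth, design)
    pk_df.to_csv(directory / "pk_observations.csv", index=False)
    tumor_df.to_csv(directory / "tumor_volumes.csv", index=False)
    invitro.to_csv(directory / "saturation_invitro.csv", index=False)
    invivo.to_csv(directory / "saturation_invivo.csv", index=False)
    manifest = {
        "seed": design.seed,
        "truth": {
            "pk": asdict(truth.pk),
            "tgi": {k: (None if isinstance(v, float) and math.isinf(v) else v)
                    for k, v in asdict(truth.tgi).items()},
            "occupancy": asdict(truth.occupancy),
        },
        "design": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(design).items()},
        "files": ["pk_observations.csv", "tumor_volumes.csv",
                  "saturation_invitro.csv", "saturation_invivo.csv"],
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=list)
    return manifest
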