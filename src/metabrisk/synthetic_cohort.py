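"""Synthetic cohort and spectrum generator.

Emulates the statistical structure of a single-center elderly breast-cancer
serum study: 140 early-stage patients (29 of whom relapse during follow-up)
and 27 metastatic patients, each contributing one frequency-domain 1H NMR
trace per pulse sequence, acquired over a 2008-2018 window that imprints a
linear technical drift on the spectra.

Every patient carries a latent "metastatic likeness" in [0, 1] — high for
advanced disease, intermediate for early patients who relapse, low for
relapse-free early patients — which scales the relapse hazard
(rate = baseline_hazard * exp(hazard_log_ratio_high_latent * latent)).
Metabolite concentrations shift by group-specific log fold changes
(:mod:`metabrisk.regions`), on top of per-patient biological variation and
an overall dilution factor that PQN is meant to remove.

Because the generator pins the observed relapse count exactly, relapse
times for designated relapsers are drawn from the latent-scaled exponential
hazard conditioned on the event preceding administrative follow-up
(truncated inverse-CDF); the unconditional sampler
:func:`sample_event_times` is public for survival-construction checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .regions import DEFAULT_PANEL, MetaboliteSpec, PPM_RANGE
from .spectral_processing import PULSE_SEQUENCES, Spectrum, write_spectrum_csv

STAGE_GROUPS = ("eBC_FFDR", "eBC_relapsed", "aBC")
SUBTYPES = ("luminal", "HER2pos", "TN")

#: Lorentzian half-width at half-maximum of a synthetic resonance, ppm.
PEAK_WIDTH_PPM = 0.004

#: (peak scale, baseline scale) per pulse sequence: CPMG attenuates broad
#: macromolecule signal, diffusion editing attenuates sharp metabolite lines.
_PULSE_WEIGHTS = {
    "NOESY1D": (1.0, 1.0),
    "CPMG": (1.0, 0.15),
    "DIFFUSION": (0.25, 1.0),
}


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults reproduce the emulated study: 140 early patients, 29 relapsed,
    27 advanced; subtype mixes of 77/10/13% (early) and 48/30/22% (advanced);
    acquisition dates spanning November 2008 - August 2018.
    """

    n_ebc: int = 140
    n_ebc_relapsed: int = 29
    n_abc: int = 27
    subtype_frequencies: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "eBC": {"luminal": 0.77, "HER2pos": 0.10, "TN": 0.13},
            "aBC": {"luminal": 0.48, "HER2pos": 0.30, "TN": 0.22},
        }
    )
    t_stage_frequencies: tuple[float, float] = (81 / 140, 59 / 140)  # T1, T2
    n_stage_frequencies: tuple[float, float, float, float] = (
        79 / 139, 38 / 139, 10 / 139, 12 / 139
    )  # N0..N3
    grade_frequencies: tuple[float, float, float] = (24 / 140, 76 / 140, 40 / 140)
    acquisition_window: tuple[date, date] = (date(2008, 11, 1), date(2018, 8, 31))
    #: Additive intensity drift per day, scalar or one value per 0.02 ppm bin.
    #: Over the 10-year window the accumulated drift is a modest fraction of
    #: the baseline intensity, as expected of a maintained spectrometer.
    drift_slope_per_bin: float | np.ndarray = 3e-5
    #: Gaussian noise s.d. per spectral grid point.
    noise_sd: float = 0.05
    #: Relapse hazard at latent = 0, events / year.
    baseline_hazard: float = 0.03
    #: Log hazard ratio between latent = 1 and latent = 0.
    hazard_log_ratio_high_latent: float = 2.0
    #: Rate of random (non-administrative) censoring, events / year.
    censoring_rate: float = 0.02
    seed: int = 0
    # --- secondary knobs -------------------------------------------------
    #: Multiplies every log fold change and the hazard log ratio; 0 gives a
    #: null cohort, 1 the default signal regime.
    effect_scale: float = 1.0
    #: s.d. of per-patient, per-metabolite log-normal biological variation.
    biological_cv: float = 0.40
    #: s.d. of the per-patient log-normal dilution factor (removed by PQN).
    dilution_sd: float = 0.15
    #: Mean amplitude of the broad macromolecule baseline (0 disables it).
    baseline_amplitude: float = 1.0
    baseline_amplitude_sd: float = 0.20
    #: Beta-distribution means of the latent metastatic likeness per group.
    latent_means: Mapping[str, float] = field(
        default_factory=lambda: {"eBC_FFDR": 0.30, "eBC_relapsed": 0.55, "aBC": 0.80}
    )
    latent_concentration: float = 10.0
    #: Administrative follow-up drawn uniformly over this window (years).
    followup_window_years: tuple[float, float] = (8.0, 11.0)
    p_death_after_relapse: float = 0.85
    post_relapse_death_rate: float = 0.35
    other_cause_death_rate: float = 0.035
    pulse_sequences: tuple[str, ...] = PULSE_SEQUENCES
    ppm_step: float = 0.001

    def __post_init__(self) -> None:
        if self.n_ebc_relapsed > self.n_ebc:
            raise ConfigurationError("n_ebc_relapsed cannot exceed n_ebc")
        if min(self.n_ebc, self.n_abc) < 0 or self.n_ebc_relapsed < 0:
            raise ConfigurationError("cohort sizes must be nonnegative")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be positive")
        if self.censoring_rate < 0:
            raise ConfigurationError("censoring_rate must be nonnegative")
        for group, freqs in self.subtype_frequencies.items():
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"subtype proportions for {group} must sum to 1")
        for s in self.pulse_sequences:
            if s not in PULSE_SEQUENCES:
                raise ConfigurationError(f"unknown pulse sequence {s!r}")


@dataclass
class PatientRecord:
    """Clinical covariates and outcomes of one synthetic patient."""

    patient_id: str
    stage_group: str  # eBC_FFDR | eBC_relapsed | aBC
    subtype: str
    t_stage: str
    n_stage: str
    grade: str
    acquisition_date: date
    latent_metastatic_likeness: float
    followup_years: float
    relapse_time_years: float | None = None
    death_time_years: float | None = None
    death_bc_related: bool = False

    def __post_init__(self) -> None:
        if self.stage_group not in STAGE_GROUPS:
            raise InputError(f"unknown stage group {self.stage_group!r}")
        if not (0.0 <= self.latent_metastatic_likeness <= 1.0):
            raise InputError("latent metastatic likeness must lie in [0, 1]")
        if self.followup_years <= 0:
            raise InputError("followup_years must be positive")
        if self.stage_group == "eBC_relapsed":
            if self.relapse_time_years is None:
                raise InputError("relapsed patients must carry a relapse time")
            if self.relapse_time_years > self.followup_years + 1e-12:
                raise InputError("relapse time exceeds follow-up")
        if self.stage_group == "aBC" and self.relapse_time_years is not None:
            raise InputError("advanced-stage patients carry no relapse fields")
        if self.death_bc_related:
            if self.relapse_time_years is None or self.death_time_years is None:
                raise InputError("BC-related death requires a prior relapse")
            if self.death_time_years < self.relapse_time_years:
                raise InputError("BC-related death must follow relapse")

    @property
    def is_ebc(self) -> bool:
        return self.stage_group in ("eBC_FFDR", "eBC_relapsed")


# ---------------------------------------------------------------------------
# event-time machinery

def sample_event_times(
    latent: np.ndarray,
    baseline_hazard: float,
    hazard_log_ratio: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unconditional exponential event times with latent-scaled hazard.

    rate_i = baseline_hazard * exp(hazard_log_ratio * latent_i).
    """
    latent = np.asarray(latent, dtype=float)
    rate = baseline_hazard * np.exp(hazard_log_ratio * latent)
    return rng.exponential(1.0 / rate)


def _truncated_event_time(rate: float, upper: float, rng: np.random.Generator) -> float:
    """Exponential(rate) draw conditioned on being <= upper (inverse CDF)."""
    u = rng.uniform()
    mass = -np.expm1(-rate * upper)  # P(T <= upper)
    return float(-np.log1p(-u * mass) / rate)


# ---------------------------------------------------------------------------
# spectrum synthesis

def ppm_grid(config: CohortConfig) -> np.ndarray:
    lo, hi = PPM_RANGE
    n = int(round((hi - lo) / config.ppm_step))
    return lo + (hi - lo) * np.arange(n + 1) / n


def _lorentzian(x: np.ndarray, center: float, width: float = PEAK_WIDTH_PPM) -> np.ndarray:
    return (width / math.pi) / ((x - center) ** 2 + width**2)


def peak_templates(
    metabolites: Sequence[MetaboliteSpec], grid: np.ndarray
) -> np.ndarray:
    """(n_metabolites, n_grid) matrix of unit-concentration line shapes.

    Each ppm region contributes one unit-area Lorentzian centred in the
    region; multi-region metabolites split their area evenly over regions.
    """
    T = np.zeros((len(metabolites), grid.size))
    for i, m in enumerate(metabolites):
        share = 1.0 / len(m.ppm_regions)
        for lo, hi in m.ppm_regions:
            T[i] += share * _lorentzian(grid, 0.5 * (lo + hi))
    return T


def baseline_shape(grid: np.ndarray) -> np.ndarray:
    """Broad macromolecule envelope (lipoprotein humps + gentle offset)."""
    return (
        1.5 * np.exp(-0.5 * ((grid - 1.30) / 0.25) ** 2)
        + 1.0 * np.exp(-0.5 * ((grid - 0.90) / 0.20) ** 2)
        + 0.8 * np.exp(-0.5 * ((grid - 3.20) / 0.60) ** 2)
        + 0.2
    )


def _drift_profile(config: CohortConfig, grid: np.ndarray) -> np.ndarray:
    """Per-grid-point drift slope (intensity units per day)."""
    s = config.drift_slope_per_bin
    if np.isscalar(s):
        return np.full(grid.size, float(s))
    s = np.asarray(s, dtype=float)
    lo, hi = PPM_RANGE
    width = 0.02
    n_bins = int(round((hi - lo) / width))
    if s.shape != (n_bins,):
        raise ConfigurationError(
            f"drift_slope_per_bin vector must have length {n_bins}"
        )
    idx = np.clip(((grid - lo) / width).astype(int), 0, n_bins - 1)
    return s[idx]


def region_calibration(metabolite: MetaboliteSpec, grid: np.ndarray) -> float:
    """Integral over the metabolite's regions of its unit template.

    This is the proportionality constant between concentration and the
    region integral of a noise-free, baseline-free spectrum.
    """
    t = peak_templates([metabolite], grid)[0]
    total = 0.0
    for lo, hi in metabolite.ppm_regions:
        mask = (grid >= lo) & (grid <= hi)
        total += np.trapezoid(t[mask], grid[mask])
    return float(total)


def draw_concentrations(
    patient: PatientRecord,
    metabolites: Sequence[MetaboliteSpec],
    config: CohortConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-metabolite concentrations for one patient.

    log c = log base + effect_scale * group log fold change
            + Normal(0, biological_cv).
    """
    lfc = np.zeros(len(metabolites))
    for i, m in enumerate(metabolites):
        if patient.stage_group == "aBC":
            lfc[i] = m.abc_log_fold_change
        elif patient.stage_group == "eBC_relapsed":
            lfc[i] = m.relapse_log_fold_change
    bases = np.array([m.base_concentration for m in metabolites])
    noise = rng.normal(0.0, config.biological_cv, size=len(metabolites))
    return bases * np.exp(config.effect_scale * lfc + noise)


def generate_spectrum(
    patient: PatientRecord,
    metabolites: Sequence[MetaboliteSpec],
    config: CohortConfig,
    pulse_sequence: str = "NOESY1D",
    concentrations: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    _grid: np.ndarray | None = None,
    _templates: np.ndarray | None = None,
) -> Spectrum:
    """Synthesize one frequency-domain trace for a patient.

    Intensity = dilution * (peaks + baseline) + drift * days + noise, where
    peaks are unit-area Lorentzians scaled by metabolite concentrations.
    When ``concentrations`` is omitted they are drawn via
    :func:`draw_concentrations` from ``rng`` (default: a generator derived
    from ``config.seed`` and the patient id, so the call is deterministic).
    """
    if pulse_sequence not in _PULSE_WEIGHTS:
        raise ConfigurationError(f"unknown pulse sequence {pulse_sequence!r}")
    if rng is None:
        import zlib

        rng = np.random.default_rng(
            [config.seed, zlib.crc32(patient.patient_id.encode()) % 2**31]
        )
    grid = ppm_grid(config) if _grid is None else _grid
    T = peak_templates(metabolites, grid) if _templates is None else _templates
    if concentrations is None:
        concentrations = draw_concentrations(patient, metabolites, config, rng)
    peak_w, base_w = _PULSE_WEIGHTS[pulse_sequence]
    intensity = peak_w * (concentrations @ T)
    if config.baseline_amplitude > 0:
        amp = config.baseline_amplitude * math.exp(
            rng.normal(0.0, config.baseline_amplitude_sd)
        )
        intensity = intensity + base_w * amp * baseline_shape(grid)
    dilution = math.exp(rng.normal(0.0, config.dilution_sd)) if config.dilution_sd else 1.0
    intensity = intensity * dilution
    days = (patient.acquisition_date - config.acquisition_window[0]).days
    drift = _drift_profile(config, grid)
    intensity = intensity + drift * days
    if config.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, config.noise_sd, size=grid.size)
    return Spectrum(
        sample_id=patient.patient_id,
        pulse_sequence=pulse_sequence,
        ppm=grid.copy(),
        intensity=intensity,
        acquisition_date=patient.acquisition_date,
    )


# ---------------------------------------------------------------------------
# cohort generation

def _beta_params(mean: float, k: float) -> tuple[float, float]:
    return mean * k, (1.0 - mean) * k


def generate_cohort(
    config: CohortConfig = CohortConfig(),
    metabolites: Sequence[MetaboliteSpec] = DEFAULT_PANEL,
) -> tuple[list[PatientRecord], list[Spectrum]]:
    """Generate the full synthetic cohort.

    Returns one :class:`PatientRecord` per patient (early patients first,
    ids ``EBC-001``.., then ``ABC-001``..) and one :class:`Spectrum` per
    patient per configured pulse sequence.  Identical config and seed give
    bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    window_days = (config.acquisition_window[1] - config.acquisition_window[0]).days
    if window_days < 0:
        raise ConfigurationError("acquisition window end precedes start")

    relapse_idx = set(
        rng.choice(config.n_ebc, size=config.n_ebc_relapsed, replace=False).tolist()
    )
    patients: list[PatientRecord] = []
    for i in range(config.n_ebc + config.n_abc):
        if i < config.n_ebc:
            pid = f"EBC-{i + 1:03d}"
            group = "eBC_relapsed" if i in relapse_idx else "eBC_FFDR"
            sub_freqs = config.subtype_frequencies["eBC"]
        else:
            pid = f"ABC-{i - config.n_ebc + 1:03d}"
            group = "aBC"
            sub_freqs = config.subtype_frequencies["aBC"]
        subtype = rng.choice(list(sub_freqs), p=list(sub_freqs.values()))
        t_stage = rng.choice(["T1", "T2"], p=config.t_stage_frequencies)
        n_stage = rng.choice(["N0", "N1", "N2", "N3"], p=config.n_stage_frequencies)
        grade = rng.choice(["G1", "G2", "G3"], p=config.grade_frequencies)
        acq = config.acquisition_window[0] + timedelta(
            days=int(rng.integers(0, window_days + 1))
        )
        a, b = _beta_params(config.latent_means[group], config.latent_concentration)
        latent = float(rng.beta(a, b))

        fu_lo, fu_hi = config.followup_window_years
        followup = float(rng.uniform(fu_lo, fu_hi))
        if config.censoring_rate > 0:
            followup = min(followup, float(rng.exponential(1.0 / config.censoring_rate)))
            followup = max(followup, 0.25)  # samples are taken at baseline

        relapse_time = None
        death_time = None
        death_bc = False
        if group == "eBC_relapsed":
            rate = config.baseline_hazard * math.exp(
                config.effect_scale * config.hazard_log_ratio_high_latent * latent
            )
            relapse_time = _truncated_event_time(rate, followup, rng)
            if rng.uniform() < config.p_death_after_relapse:
                gap = float(rng.exponential(1.0 / config.post_relapse_death_rate))
                if relapse_time + gap <= followup:
                    death_time = relapse_time + gap
                    death_bc = True
        if death_time is None and group != "aBC":
            other = float(rng.exponential(1.0 / config.other_cause_death_rate))
            if other <= followup:
                death_time = other
                if relapse_time is not None and death_time < relapse_time:
                    # death precedes the scheduled relapse: keep the relapse
                    # (group membership is by design) but cap it first
                    relapse_time = min(relapse_time, max(death_time - 1e-6, 1e-6))
        patients.append(
            PatientRecord(
                patient_id=pid,
                stage_group=group,
                subtype=str(subtype),
                t_stage=str(t_stage),
                n_stage=str(n_stage),
                grade=str(grade),
                acquisition_date=acq,
                latent_metastatic_likeness=latent,
                followup_years=followup,
                relapse_time_years=relapse_time,
                death_time_years=death_time,
                death_bc_related=death_bc,
            )
        )

    grid = ppm_grid(config)
    templates = peak_templates(metabolites, grid)
    spectra: list[Spectrum] = []
    for p in patients:
        conc = draw_concentrations(p, metabolites, config, rng)
        for seq in config.pulse_sequences:
            spectra.append(
                generate_spectrum(
                    p, metabolites, config, seq,
                    concentrations=conc, rng=rng,
                    _grid=grid, _templates=templates,
                )
            )
    return patients, spectra


def patients_to_frame(patients: Sequence[PatientRecord]) -> pd.DataFrame:
    """Clinical table, one row per patient, ISO-8601 dates."""
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "stage_group": [p.stage_group for p in patients],
            "subtype": [p.subtype for p in patients],
            "t_stage": [p.t_stage for p in patients],
            "n_stage": [p.n_stage for p in patients],
            "grade": [p.grade for p in patients],
            "acquisition_date": [p.acquisition_date.isoformat() for p in patients],
            "latent_metastatic_likeness": [
                p.latent_metastatic_likeness for p in patients
            ],
            "followup_years": [p.followup_years for p in patients],
            "relapse_time_years": [p.relapse_time_years for p in patients],
            "death_time_years": [p.death_time_years for p in patients],
            "death_bc_related": [p.death_bc_related for p in patients],
        }
    )


def patients_from_frame(df: pd.DataFrame) -> list[PatientRecord]:
    out = []
    for r in df.itertuples():
        out.append(
            PatientRecord(
                patient_id=r.patient_id,
                stage_group=r.stage_group,
                subtype=r.subtype,
                t_stage=r.t_stage,
                n_stage=r.n_stage,
                grade=r.grade,
                acquisition_date=date.fromisoformat(r.acquisition_date),
                latent_metastatic_likeness=float(r.latent_metastatic_likeness),
                followup_years=float(r.followup_years),
                relapse_time_years=None
                if pd.isna(r.relapse_time_years)
                else float(r.relapse_time_years),
                death_time_years=None
                if pd.isna(r.death_time_years)
                else float(r.death_time_years),
                death_bc_related=bool(r.death_bc_related),
            )
        )
    return out


def write_cohort(
    patients: Sequence[PatientRecord],
    spectra: Sequence[Spectrum],
    out_dir,
) -> None:
    """Write clinical CSV, per-sample spectrum CSVs and a manifest."""
    out = Path(out_dir)
    (out / "spectra").mkdir(parents=True, exist_ok=True)
    patients_to_frame(patients).to_csv(out / "clinical.csv", index=False)
    manifest = []
    for s in spectra:
        rel = f"spectra/{s.sample_id}_{s.pulse_sequence}.csv"
        write_spectrum_csv(s, out / rel)
        manifest.append(
            {
                "patient_id": s.sample_id,
                "pulse_sequence": s.pulse_sequence,
                "path": rel,
                "acquisition_date": s.acquisition_date.isoformat(),
            }
        )
    pd.DataFrame(manifest).to_csv(out / "manifest.csv", index=False)


def read_cohort(in_dir) -> tuple[list[PatientRecord], list[Spectrum]]:
    from .spectral_processing import read_spectrum_csv

    root = Path(in_dir)
    patients = patients_from_frame(pd.read_csv(root / "clinical.csv"))
    manifest = pd.read_csv(root / "manifest.csv")
    spectra = [
        read_spectrum_csv(
            root / r.path, r.patient_id, r.pulse_sequence,
            date.fromisoformat(r.acquisition_date),
        )
        for r in manifest.itertuples()
    ]
    return patients, spectra
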