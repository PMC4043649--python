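"""Generator configuration, population templates, and cohort calibration.

The wild-type cohort preset encodes the published cohort statistics of the
murine myeloid compartment: per-population mean absolute concentrations and
between-animal coefficients of variation, the mean monocyte subset
composition (classical 52.4%, non-classical 40.4%, intermediate 7.2% of
MHCII-negative monocytes), and per-population technical (duplicate-level)
noise.  Between-animal and within-population intensity distributions are
log-normal throughout (strictly positive, right-skewed, accommodates CVs up
to ~86%), with CV mapped to the log-scale sigma via sigma^2 = ln(1 + CV^2).

Monocyte subsets are generated as per-animal fractions times a per-animal
total monocyte concentration T.  The printed subset concentration means and
fraction means are mutually consistent only if the classical fraction
co-varies positively with T (Ly6C-high monocytosis): the calibration solves
E[conc_s] = E[frac_s]*E[T] + cov_s with the covariances summing to zero, for
any choice of the free parameter E[T].
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

from ..panel import (
    CHANNELS,
    FLUOR_CHANNELS,
    INSTRUMENT_RANGE,
    LEUKOCYTE_SUBSETS,
    MONO_SUBSETS,
    POPULATIONS,
)
from .kinetics import KineticsAnchors, default_anchors

#: small-sample bias factor of an SD estimated from n = 2 values (c4 constant)
C4_PAIR = math.sqrt(2.0 / math.pi)


class CalibrationError(ValueError):
    """Raised when the requested cohort moments are jointly infeasible."""


def cv_to_sigma(cv: float) -> float:
    """Log-scale sigma of a log-normal with the given coefficient of variation."""
    if cv < 0:
        raise ValueError("CV must be non-negative")
    return math.sqrt(math.log1p(cv * cv))


@dataclass
class PopulationTemplate:
    """Per-population channel intensity model (true, pre-spillover scale).

    ``medians`` are per-channel median intensities in arbitrary units;
    ``spreads`` are the robust CVs of the log-normal intensity distribution
    (0 means every event sits exactly at the median).
    """

    population_id: str
    medians: dict[str, float]
    spreads: dict[str, float]

    def __post_init__(self) -> None:
        if self.population_id not in POPULATIONS:
            raise ValueError(f"unknown population {self.population_id!r}")
        for ch in CHANNELS:
            if ch not in self.medians:
                raise ValueError(f"{self.population_id}: missing median for {ch}")
            if self.medians[ch] <= 0:
                raise ValueError(f"{self.population_id}: median for {ch} must be > 0")
            if self.spreads.get(ch, 0.0) < 0:
                raise ValueError(f"{self.population_id}: spread for {ch} must be >= 0")

    def with_spread(self, spread: float) -> "PopulationTemplate":
        return PopulationTemplate(
            self.population_id,
            dict(self.medians),
            {ch: spread for ch in CHANNELS},
        )


@dataclass
class AnimalParams:
    """True per-animal state: cells/ul of blood per leukocyte population."""

    animal_id: str
    concentrations: dict[str, float]
    group: str = "WT-cohort"

    def __post_init__(self) -> None:
        for pop, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"{self.animal_id}: negative concentration for {pop}")

    @property
    def total_monocytes(self) -> float:
        return sum(self.concentrations[s] for s in MONO_SUBSETS)


# --- published cohort statistics (wild-type C57BL/6, n = 180) -----------------

COHORT_MEAN = {  # cells/ul
    "neutrophil": 654.2,
    "eosinophil": 144.0,
    "activated_monomac": 18.7,
    "lymphocyte": 4267.0,
}
COHORT_CV = {
    "neutrophil": 0.858,
    "eosinophil": 0.533,
    "activated_monomac": 0.697,
    "lymphocyte": 0.382,
}
MONO_CONC_MEAN = {"classical_mono": 135.6, "nonclassical_mono": 86.1}
MONO_CONC_CV = {"classical_mono": 0.688, "nonclassical_mono": 0.511}
FRACTION_MEAN = {  # proportions of MHCII-neg monocytes
    "classical_mono": 0.524,
    "nonclassical_mono": 0.404,
    "intermediate_mono": 0.072,
}
# Printed fraction SEs (1, 1, 0.2 percentage points at n = 180) converted to
# between-animal SDs: SD = SE * sqrt(180).
FRACTION_SD = {
    "classical_mono": 0.01 * math.sqrt(180.0),
    "nonclassical_mono": 0.01 * math.sqrt(180.0),
    "intermediate_mono": 0.002 * math.sqrt(180.0),
}
#: published duplicate inter-assay CVs (mean of per-pair CVs over 12 animals)
INTER_ASSAY_CV = {
    "classical_mono": 0.021,
    "intermediate_mono": 0.021,
    "nonclassical_mono": 0.046,
    "neutrophil": 0.038,
    "eosinophil": 0.051,
}


def default_templates(spread: float | None = None) -> dict[str, PopulationTemplate]:
    """Channel templates realizing the panel's phenotype definitions.

    F4/80 medians for the monocytic subsets are the published MFIs
    (classical 421, intermediate 455, non-classical 794, MHCII-pos 1350);
    all other medians are plausible instrument-scale values chosen to give
    well-separated populations (> 3 log-scale SDs from every gate at the
    default spread).  ``spread`` overrides the per-channel robust CV on all
    fluorescence channels.
    """
    fl = 0.25 if spread is None else spread  # fluorescence robust CV
    sc = 0.15 if spread is None else spread  # scatter robust CV
    bd = 0.05 if spread is None else spread  # bead robust CV (tight singlet peak)
    #              FSC     SSC    CD43   Lin    MHCII  F480    CD11b    Ly6C
    rows = {
        "neutrophil": (60000, 45000, 200, 9000, 80, 60, 5000, 3000),
        "eosinophil": (55000, 40000, 200, 120, 80, 2000, 5000, 300),
        "classical_mono": (50000, 9000, 250, 120, 80, 421, 6000, 10000),
        "intermediate_mono": (50000, 9000, 1500, 120, 80, 455, 6000, 2200),
        "nonclassical_mono": (50000, 9000, 8000, 120, 80, 794, 6000, 400),
        "activated_monomac": (52000, 10000, 8000, 120, 6000, 1350, 6000, 700),
        "lymphocyte": (40000, 6000, 200, 7000, 2000, 60, 90, 150),
        "bead": (30000, 2500, 10, 10, 10, 10, 150000, 10),
    }
    templates = {}
    for pop, vals in rows.items():
        medians = dict(zip(CHANNELS, map(float, vals)))
        s = bd if pop == "bead" else fl
        spreads = {ch: (sc if ch in ("FSC", "SSC") else s) for ch in CHANNELS}
        if pop == "bead":
            spreads = {ch: bd for ch in CHANNELS}
        templates[pop] = PopulationTemplate(pop, medians, spreads)
    _check_template_orderings(templates)
    return templates


def _check_template_orderings(templates: dict[str, PopulationTemplate]) -> None:
    """Phenotype orderings the downstream gates rely on."""
    m = {p: t.medians for p, t in templates.items()}
    if not (
        m["classical_mono"]["Ly6C"]
        > m["intermediate_mono"]["Ly6C"]
        > m["nonclassical_mono"]["Ly6C"]
    ):
        raise ValueError("Ly6C medians must be ordered classical > intermediate > non-classical")
    if not (
        m["nonclassical_mono"]["CD43"]
        > m["intermediate_mono"]["CD43"]
        > m["classical_mono"]["CD43"]
    ):
        raise ValueError("CD43 medians must be ordered non-classical > intermediate > classical")
    if not (
        m["activated_monomac"]["F480"]
        > m["nonclassical_mono"]["F480"]
        > max(m["classical_mono"]["F480"], m["intermediate_mono"]["F480"]) * 0.99
    ):
        raise ValueError("F4/80 medians must form the activated > non-classical > classical gradient")


def default_spillover() -> np.ndarray:
    """Plausible 6x6 spillover for the FITC/PE/PE-Cy7/APC/AF700/PacBlue panel.

    Entry (i, j) is the fraction of true channel-i signal appearing in
    detector j; diagonal exactly 1.  Channel order follows
    :data:`cytovar.panel.FLUOR_CHANNELS`.
    """
    k = len(FLUOR_CHANNELS)
    s = np.eye(k)
    idx = {c: i for i, c in enumerate(FLUOR_CHANNELS)}
    pairs = {
        ("CD43", "Lin"): 0.12,   # FITC -> PE
        ("CD43", "Ly6C"): 0.01,  # FITC -> PacBlue
        ("Lin", "CD43"): 0.04,   # PE -> FITC
        ("Lin", "MHCII"): 0.06,  # PE -> PE-Cy7
        ("MHCII", "Lin"): 0.02,
        ("MHCII", "CD11b"): 0.02,
        ("F480", "CD11b"): 0.10,  # APC -> AF700
        ("CD11b", "F480"): 0.05,  # AF700 -> APC
        ("Ly6C", "CD43"): 0.02,  # PacBlue -> FITC
    }
    for (src, dst), v in pairs.items():
        s[idx[src], idx[dst]] = v
    return s


@dataclass
class GeneratorConfig:
    """Everything the generator needs for one study.

    Concentrations are cells/ul of blood; fractions are proportions of the
    MHCII-negative monocyte compartment; all CVs are dimensionless.
    ``total_mono_mean`` (E[T]) and ``total_mono_cv`` are free calibration
    parameters: the published tables give subset concentrations and
    fractions but not the total-monocyte distribution.
    """

    templates: dict[str, PopulationTemplate] = field(default_factory=default_templates)
    cohort_mean: dict[str, float] = field(default_factory=lambda: dict(COHORT_MEAN))
    cohort_cv: dict[str, float] = field(default_factory=lambda: dict(COHORT_CV))
    mono_conc_mean: dict[str, float] = field(default_factory=lambda: dict(MONO_CONC_MEAN))
    mono_conc_cv: dict[str, float] = field(default_factory=lambda: dict(MONO_CONC_CV))
    fraction_mean: dict[str, float] = field(default_factory=lambda: dict(FRACTION_MEAN))
    fraction_sd: dict[str, float] = field(default_factory=lambda: dict(FRACTION_SD))
    total_mono_mean: float = 240.0
    total_mono_cv: float = 0.55
    technical_cv: dict[str, float] = field(default_factory=dict)
    day_noise_cv: float = 0.10
    beads_per_tube: float = 50_000.0
    acquisition_fraction: float = 1.0
    volume_ul: float = 50.0
    spillover: np.ndarray = field(default_factory=default_spillover)
    kinetics: KineticsAnchors = field(default_factory=default_anchors)
    base_seed: int = 0
    instrument_range: float = INSTRUMENT_RANGE
    # set by calibrate_cohort_preset
    mono_rho: dict[str, float] | None = None
    intermediate_mean: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.acquisition_fraction <= 1.0:
            raise ValueError("acquisition_fraction must be in (0, 1]")
        if self.volume_ul <= 0:
            raise ValueError("volume_ul must be positive")
        for name, cv in {**self.cohort_cv, **self.technical_cv}.items():
            if cv < 0:
                raise ValueError(f"negative CV for {name}")
        frac_total = sum(self.fraction_mean[s] for s in MONO_SUBSETS)
        if abs(frac_total - 1.0) > 1e-9:
            raise ValueError("monocyte fraction means must sum to 100%")
        self.spillover = np.asarray(self.spillover, dtype=float)

    @property
    def calibrated(self) -> bool:
        return self.mono_rho is not None

    def copy(self, **overrides: Any) -> "GeneratorConfig":
        return dataclasses.replace(self, **overrides)


# --- calibration --------------------------------------------------------------


def calibrate_cohort_preset(config: GeneratorConfig) -> GeneratorConfig:
    """Solve the fraction/total covariance structure against the printed means.

    The per-animal construction is T = exp(mu_T + sigma_T z) with z standard
    normal, and frac_s = mean_s + sd_s * (rho_s z + sqrt(1 - rho_s^2) eps_s)
    for the classical and intermediate fractions (the non-classical fraction
    is the complement).  Since cov(z, T) = E[T] sigma_T, matching
    E[conc_s] = E[frac_s] E[T] + cov_s requires
    rho_s = cov_s / (sd_s * E[T] * sigma_T) with
    cov_s = printed_mean_s - frac_mean_s * E[T].  The intermediate subset's
    unprinted concentration mean is implied: E[T] minus the two printed
    means, which makes the three covariances sum to zero identically.

    Raises :class:`CalibrationError` if any implied correlation magnitude
    exceeds 1, or (in the degenerate zero-variance case) if the printed
    means are inconsistent with frac_mean * E[T].
    """
    et = config.total_mono_mean
    sigma_t = cv_to_sigma(config.total_mono_cv)
    implied_intermediate = et - sum(config.mono_conc_mean.values())
    if implied_intermediate <= 0:
        raise CalibrationError(
            f"total monocyte mean {et} leaves non-positive intermediate mean "
            f"{implied_intermediate:.2f}"
        )
    conc_mean = dict(config.mono_conc_mean)
    conc_mean["intermediate_mono"] = implied_intermediate

    rho: dict[str, float] = {}
    for subset in ("classical_mono", "intermediate_mono"):
        cov = conc_mean[subset] - config.fraction_mean[subset] * et
        sd = config.fraction_sd[subset]
        if sd == 0.0 or sigma_t == 0.0:
            if abs(cov) > 1e-9 * max(et, 1.0):
                raise CalibrationError(
                    f"zero variance but printed mean for {subset} implies "
                    f"non-zero covariance {cov:.3f} cells/ul"
                )
            rho[subset] = 0.0
            continue
        r = cov / (sd * et * sigma_t)
        if abs(r) > 1.0:
            raise CalibrationError(
                f"implied correlation {r:.3f} for {subset} is outside [-1, 1]"
            )
        rho[subset] = r
    return config.copy(mono_rho=rho, intermediate_mean=implied_intermediate)


def calibrate_technical_cv(
    printed_cv: float,
    conc_mean: float,
    conc_cv: float,
    volume_ul: float,
    acquisition_fraction: float,
    beads_per_tube: float,
) -> float:
    """Technical noise tau reproducing a printed duplicate inter-assay CV.

    The published statistic is the mean over animals of per-pair CVs
    (n - 1 SD over two values), whose expectation is c4(2) = sqrt(2/pi)
    times the per-measurement CV; the per-measurement CV in turn combines
    the staining/pipetting noise tau with Poisson cell counting
    (E[1/N] = (1 + CV^2)/(mean * V * f) across the cohort) and bead
    counting.  tau is the positive root, floored at zero when counting
    noise alone already exceeds the printed value (which happens for
    sparse subsets).
    """
    target_sq = (printed_cv / C4_PAIR) ** 2
    poisson_sq = (1.0 + conc_cv**2) / (conc_mean * volume_ul * acquisition_fraction)
    bead_sq = 1.0 / (beads_per_tube * acquisition_fraction)
    return math.sqrt(max(target_sq - poisson_sq - bead_sq, 0.0))


def _calibrated_technical_noise(config: GeneratorConfig) -> dict[str, float]:
    all_mean = {**config.cohort_mean, **config.mono_conc_mean}
    all_cv = {**config.cohort_cv, **config.mono_conc_cv}
    all_mean["intermediate_mono"] = config.total_mono_mean - sum(
        config.mono_conc_mean.values()
    )
    all_cv["intermediate_mono"] = 0.6  # unprinted; only enters a (1+CV^2) factor
    tau = {}
    for pop in LEUKOCYTE_SUBSETS:
        printed = INTER_ASSAY_CV.get(pop)
        if printed is None:
            tau[pop] = 0.03  # unprinted (activated, lymphocyte): modest default
            continue
        tau[pop] = calibrate_technical_cv(
            printed,
            all_mean[pop],
            all_cv[pop],
            config.volume_ul,
            config.acquisition_fraction,
            config.beads_per_tube,
        )
    return tau


# --- presets ------------------------------------------------------------------


def wt_cohort_preset(**overrides: Any) -> GeneratorConfig:
    """Calibrated wild-type cohort preset (`wt_cohort_180`), 50 ul samples."""
    config = GeneratorConfig(**overrides)
    config = config.copy(technical_cv=_calibrated_technical_noise(config))
    return calibrate_cohort_preset(config)


def duplicates_preset(**overrides: Any) -> GeneratorConfig:
    """Duplicate inter-assay experiment preset (`duplicates_n12`)."""
    return wt_cohort_preset(**overrides)


def volume_pair_preset(**overrides: Any) -> GeneratorConfig:
    """Paired 50 ul / 20 ul volume-equivalence preset (`volume_pair_n10`)."""
    return wt_cohort_preset(**overrides)


def timecourse_preset(**overrides: Any) -> GeneratorConfig:
    """Sequential MI / sham / control study preset (`timecourse_mi_sham_ctrl`).

    Serial sampling uses 20 ul draws (daily limit for repeated bleeding).
    """
    overrides.setdefault("volume_ul", 20.0)
    return wt_cohort_preset(**overrides)


def crosssection_preset(**overrides: Any) -> GeneratorConfig:
    """Cross-sectional groups at days 2/3/5/7 (`crosssection_d2357`)."""
    overrides.setdefault("volume_ul", 20.0)
    return wt_cohort_preset(**overrides)


PRESETS = {
    "wt_cohort_180": wt_cohort_preset,
    "duplicates_n12": duplicates_preset,
    "volume_pair_n10": volume_pair_preset,
    "timecourse_mi_sham_ctrl": timecourse_preset,
    "crosssection_d2357": crosssection_preset,
}


# --- YAML round-trip ----------------------------------------------------------


def _config_to_dict(config: GeneratorConfig) -> dict[str, Any]:
    d: dict[str, Any] = {}
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        if f.name == "templates":
            v = {
                p: {"medians": t.medians, "spreads": t.spreads}
                for p, t in v.items()
            }
        elif f.name == "spillover":
            v = np.asarray(v).tolist()
        elif f.name == "kinetics":
            v = v.to_dict()
        d[f.name] = v
    return d


def save_config(config: GeneratorConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=False)


def load_config(path: str) -> GeneratorConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["templates"] = {
        p: PopulationTemplate(p, t["medians"], t["spreads"])
        for p, t in d["templates"].items()
    }
    d["spillover"] = np.asarray(d["spillover"], dtype=float)
    d["kinetics"] = KineticsAnchors.from_dict(d["kinetics"])
    return GeneratorConfig(**d)
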