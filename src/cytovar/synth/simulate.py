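"""Event-level and cohort-level simulation.

Per-animal concentrations are drawn log-normally (monocyte subsets via the
calibrated fraction-times-total construction), acquisitions draw Poisson
event counts at concentration x volume x acquisition fraction, per-event
channel intensities are log-normal around the population template medians,
and the observed intensities are the true intensities mixed through the
configured spillover matrix.  Every generated event carries its
ground-truth subset label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..events import EventTable
from ..panel import (
    CHANNELS,
    FLUOR_INDEX,
    LABEL_CODE,
    LEUKOCYTE_SUBSETS,
    MONO_SUBSETS,
)
from .config import AnimalParams, GeneratorConfig, cv_to_sigma

_NONMONO = tuple(s for s in LEUKOCYTE_SUBSETS if s not in MONO_SUBSETS)


# --- animal-level sampling ----------------------------------------------------


def _require_calibrated(config: GeneratorConfig) -> None:
    if not config.calibrated:
        raise ValueError("config must pass through calibrate_cohort_preset first")


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma = cv_to_sigma(cv)
    return math.log(mean) - 0.5 * sigma * sigma, sigma


def _draw_cohort_concentrations(
    config: GeneratorConfig, n: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Vectorized per-animal true concentrations for n animals."""
    _require_calibrated(config)
    conc: dict[str, np.ndarray] = {}
    for pop in _NONMONO:
        mu, sigma = _lognormal_params(config.cohort_mean[pop], config.cohort_cv[pop])
        conc[pop] = np.exp(mu + sigma * rng.standard_normal(n))

    mu_t, sigma_t = _lognormal_params(config.total_mono_mean, config.total_mono_cv)
    rho_cl = config.mono_rho["classical_mono"]
    rho_im = config.mono_rho["intermediate_mono"]
    m_cl, sd_cl = config.fraction_mean["classical_mono"], config.fraction_sd["classical_mono"]
    m_im, sd_im = config.fraction_mean["intermediate_mono"], config.fraction_sd["intermediate_mono"]

    f_cl = np.empty(n)
    f_im = np.empty(n)
    total = np.empty(n)
    todo = np.arange(n)
    while todo.size:  # rejection loop keeps fractions in (0, 1); < 1% of draws
        k = todo.size
        z = rng.standard_normal(k)
        e1 = rng.standard_normal(k)
        e2 = rng.standard_normal(k)
        t = np.exp(mu_t + sigma_t * z)
        fc = m_cl + sd_cl * (rho_cl * z + math.sqrt(1.0 - rho_cl**2) * e1)
        fi = m_im + sd_im * (rho_im * z + math.sqrt(1.0 - rho_im**2) * e2)
        ok = (fc > 0.0) & (fi > 0.0) & (fc + fi < 1.0)
        f_cl[todo[ok]] = fc[ok]
        f_im[todo[ok]] = fi[ok]
        total[todo[ok]] = t[ok]
        todo = todo[~ok]

    conc["classical_mono"] = f_cl * total
    conc["intermediate_mono"] = f_im * total
    conc["nonclassical_mono"] = (1.0 - f_cl - f_im) * total
    return conc


def sample_cohort_params(
    config: GeneratorConfig,
    n: int,
    rng: np.random.Generator,
    group: str = "WT-cohort",
    id_prefix: str = "wt",
) -> list[AnimalParams]:
    """Draw n independent animals from the calibrated cohort distribution."""
    conc = _draw_cohort_concentrations(config, n, rng)
    return [
        AnimalParams(
            animal_id=f"{id_prefix}{i:04d}",
            concentrations={pop: float(conc[pop][i]) for pop in LEUKOCYTE_SUBSETS},
            group=group,
        )
        for i in range(n)
    ]


def sample_animal_params(
    config: GeneratorConfig,
    rng: np.random.Generator,
    animal_id: str = "animal0000",
    group: str = "WT-cohort",
) -> AnimalParams:
    """Draw one animal; monocyte subset concentrations sum exactly to its total."""
    animal = sample_cohort_params(config, 1, rng, group=group)[0]
    animal.animal_id = animal_id
    return animal


# --- acquisition-level sampling -----------------------------------------------


def _technical_multipliers(
    config: GeneratorConfig, rng: np.random.Generator
) -> dict[str, float]:
    mult = {}
    for pop in LEUKOCYTE_SUBSETS:
        tau = config.technical_cv.get(pop, 0.0)
        if tau > 0.0:
            mu, sigma = _lognormal_params(1.0, tau)
            mult[pop] = float(np.exp(mu + sigma * rng.standard_normal()))
        else:
            mult[pop] = 1.0
    return mult


def _draw_population_events(
    template, n: int, rng: np.random.Generator
) -> np.ndarray:
    out = np.empty((n, len(CHANNELS)))
    for j, ch in enumerate(CHANNELS):
        med = template.medians[ch]
        spread = template.spreads.get(ch, 0.0)
        if spread == 0.0:
            out[:, j] = med
        else:
            sigma = cv_to_sigma(spread)
            out[:, j] = np.exp(math.log(med) + sigma * rng.standard_normal(n))
    return out


def simulate_sample(
    animal: AnimalParams,
    volume_ul: float,
    config: GeneratorConfig,
    rng: np.random.Generator,
    technical: bool = True,
    rate_multiplier: dict[str, float] | None = None,
    **meta_extra,
) -> EventTable:
    """One stained TruCount-tube acquisition for one animal.

    Event counts are Poisson at concentration x volume x acquisition
    fraction, modulated by per-population multiplicative technical noise
    (drawn here unless ``technical=False``) and any caller-supplied
    ``rate_multiplier`` (used by the longitudinal designs).  Bead events are
    Poisson at beads_per_tube x acquisition fraction.  Observed intensities
    are the true per-event intensities mixed through the spillover matrix,
    clipped at the instrument range, and shuffled; ground-truth labels ride
    along in the same order.
    """
    if volume_ul <= 0:
        raise ValueError("volume_ul must be positive")
    if not config.templates:
        raise ValueError("config has no population templates")
    f = config.acquisition_fraction
    tech = _technical_multipliers(config, rng) if technical else {p: 1.0 for p in LEUKOCYTE_SUBSETS}

    blocks: list[np.ndarray] = []
    label_blocks: list[np.ndarray] = []
    true_counts: dict[str, int] = {}
    for pop in LEUKOCYTE_SUBSETS:
        conc = animal.concentrations[pop]
        mult = tech[pop] * (rate_multiplier or {}).get(pop, 1.0)
        n = int(rng.poisson(conc * volume_ul * f * mult))
        true_counts[pop] = n
        if n:
            blocks.append(_draw_population_events(config.templates[pop], n, rng))
            label_blocks.append(np.full(n, LABEL_CODE[pop], dtype=np.int8))
    n_beads = int(rng.poisson(config.beads_per_tube * f))
    true_counts["bead"] = n_beads
    if n_beads:
        blocks.append(_draw_population_events(config.templates["bead"], n_beads, rng))
        label_blocks.append(np.full(n_beads, LABEL_CODE["bead"], dtype=np.int8))

    if blocks:
        true = np.vstack(blocks)
        labels = np.concatenate(label_blocks)
    else:
        true = np.empty((0, len(CHANNELS)))
        labels = np.empty(0, dtype=np.int8)

    observed = true.copy()
    fl = list(FLUOR_INDEX)
    observed[:, fl] = true[:, fl] @ config.spillover
    saturated = int(np.count_nonzero(observed > config.instrument_range))
    np.clip(observed, None, config.instrument_range, out=observed)

    perm = rng.permutation(observed.shape[0])
    meta = {
        "animal_id": animal.animal_id,
        "group": animal.group,
        "volume_ul": float(volume_ul),
        "acquisition_fraction": f,
        "beads_per_tube": config.beads_per_tube,
        "true_counts": true_counts,
        "n_saturated": saturated,
        **meta_extra,
    }
    return EventTable(data=observed[perm], meta=meta, labels=labels[perm])


def simulate_duplicates(
    animal: AnimalParams,
    n_pairs: int,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> list[tuple[EventTable, EventTable]]:
    """Duplicate acquisitions of the same blood draw.

    Both members of a pair share the animal's true concentrations and
    differ only by independent multiplicative technical noise (log-normal,
    CV tau per population) and Poisson sampling.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    pairs = []
    for k in range(n_pairs):
        a = simulate_sample(animal, config.volume_ul, config, rng, duplicate=0, pair=k)
        b = simulate_sample(animal, config.volume_ul, config, rng, duplicate=1, pair=k)
        pairs.append((a, b))
    return pairs


def simulate_single_stain_controls(
    config: GeneratorConfig,
    rng: np.random.Generator,
    n_positive: int = 4000,
    n_negative: int = 4000,
    bright: float = 20000.0,
    baseline: float = 50.0,
    spread: float = 0.2,
) -> list[EventTable]:
    """One single-stain compensation control per fluorescence channel.

    Each control holds a bright population positive only on its primary
    channel (pre-spillover) over an unstained negative population; the
    configured spillover is applied.  Positive events come first;
    ``meta['n_positive']`` records the split and ``meta['control_channel']``
    the primary channel.
    """
    sigma = cv_to_sigma(spread)
    fl = list(FLUOR_INDEX)
    controls = []
    for ci, channel in enumerate(np.array(CHANNELS)[fl]):
        true = np.empty((n_positive + n_negative, len(CHANNELS)))
        # scatter: one mononuclear-like cloud, never compensated
        true[:, 0] = np.exp(math.log(50000.0) + 0.15 * rng.standard_normal(len(true)))
        true[:, 1] = np.exp(math.log(9000.0) + 0.15 * rng.standard_normal(len(true)))
        for j_rel, j in enumerate(fl):
            med = bright if j_rel == ci else baseline
            true[:n_positive, j] = np.exp(math.log(med) + sigma * rng.standard_normal(n_positive))
            true[n_positive:, j] = np.exp(
                math.log(baseline) + sigma * rng.standard_normal(n_negative)
            )
        observed = true.copy()
        observed[:, fl] = true[:, fl] @ config.spillover
        controls.append(
            EventTable(
                data=observed,
                meta={"control_channel": str(channel), "n_positive": n_positive},
            )
        )
    return controls


# --- longitudinal designs -----------------------------------------------------


@dataclass
class StudyDesign:
    """Groups (name -> n animals), sampling days, and design mode."""

    groups: dict[str, int]
    days: tuple[float, ...]
    mode: str = "sequential"  # or "cross-sectional"

    def __post_init__(self) -> None:
        if self.mode not in ("sequential", "cross-sectional"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.days = tuple(float(d) for d in self.days)


def sequential_design(
    n_mi: int = 15, n_sham: int = 7, n_ctrl: int = 4
) -> StudyDesign:
    """The serial-sampling study: daily draws through day 7, then 14 and 21."""
    return StudyDesign(
        groups={"MI": n_mi, "SHAM": n_sham, "CTRL": n_ctrl},
        days=(0, 1, 2, 3, 4, 5, 6, 7, 14, 21),
        mode="sequential",
    )


def crosssection_design(n_per_day: int = 20) -> StudyDesign:
    """Independent MI groups sacrificed at days 2, 3, 5, 7."""
    return StudyDesign(groups={"MI": n_per_day}, days=(2, 3, 5, 7), mode="cross-sectional")


def _log_medians(config: GeneratorConfig) -> dict[str, float]:
    """Approximate log-scale population medians used as shrinkage anchors."""
    out = {}
    for pop in _NONMONO:
        mu, _ = _lognormal_params(config.cohort_mean[pop], config.cohort_cv[pop])
        out[pop] = mu
    mu_t, _ = _lognormal_params(config.total_mono_mean, config.total_mono_cv)
    for s in MONO_SUBSETS:
        out[s] = math.log(config.fraction_mean[s]) + mu_t
    return out


def _day_noise(config: GeneratorConfig, rng: np.random.Generator) -> float:
    eta = config.day_noise_cv
    if eta <= 0:
        return 1.0
    mu, sigma = _lognormal_params(1.0, eta)
    return float(np.exp(mu + sigma * rng.standard_normal()))


def simulate_timecourse(
    design: StudyDesign,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> list[EventTable]:
    """Simulate a longitudinal study; one EventTable per animal x day.

    Sequential mode reuses each animal's baseline draw: on day t the
    log-concentration of subset s is the baseline log-concentration shrunk
    toward the cohort log-median by the dispersion scale s(t), shifted by
    the log median-multiplier m(t), plus day-level biological noise.
    Cross-sectional mode draws fresh animals per day at full cohort
    dispersion scaled by m(t).  Non-operated controls carry m = s = 1, so
    their trajectories are flat in expectation.
    """
    _require_calibrated(config)
    anchors = config.kinetics
    for group in design.groups:
        if group not in anchors.multiplier:
            raise KeyError(f"unknown group {group!r}")
    for day in design.days:
        anchors._check_day(day)

    log_med = _log_medians(config)
    acquisitions: list[EventTable] = []

    if design.mode == "sequential":
        for group, n in design.groups.items():
            baseline = sample_cohort_params(config, n, rng, group=group, id_prefix=group.lower())
            for day in design.days:
                for animal in baseline:
                    conc = {}
                    for pop in LEUKOCYTE_SUBSETS:
                        m = anchors.multiplier_at(group, pop, day)
                        s = anchors.dispersion_at(group, pop, day)
                        ln_c0 = math.log(animal.concentrations[pop])
                        ln_c = log_med[pop] + math.log(m) + s * (ln_c0 - log_med[pop])
                        conc[pop] = math.exp(ln_c) * _day_noise(config, rng)
                    shifted = AnimalParams(animal.animal_id, conc, group)
                    acquisitions.append(
                        simulate_sample(
                            shifted, config.volume_ul, config, rng,
                            day=day, mode=design.mode,
                        )
                    )
    else:
        for day in design.days:
            for group, n in design.groups.items():
                fresh = sample_cohort_params(
                    config, n, rng, group=group, id_prefix=f"{group.lower()}d{day:g}_"
                )
                for animal in fresh:
                    conc = {
                        pop: animal.concentrations[pop]
                        * anchors.multiplier_at(group, pop, day)
                        * _day_noise(config, rng)
                        for pop in LEUKOCYTE_SUBSETS
                    }
                    shifted = AnimalParams(animal.animal_id, conc, group)
                    acquisitions.append(
                        simulate_sample(
                            shifted, config.volume_ul, config, rng,
                            day=day, mode=design.mode,
                        )
                    )
    return acquisitions
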