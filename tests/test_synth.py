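"""Generator behavior: calibration identities, cohort moments, event sampling."""

import numpy as np
import pytest

from cytovar.panel import LEUKOCYTE_SUBSETS, MONO_SUBSETS, LABEL_CODE
from cytovar.synth import (
    CalibrationError,
    GeneratorConfig,
    KineticsAnchors,
    StudyDesign,
    calibrate_cohort_preset,
    default_anchors,
    sample_animal_params,
    sample_cohort_params,
    simulate_duplicates,
    simulate_sample,
    simulate_single_stain_controls,
    simulate_timecourse,
    wt_cohort_preset,
)
from cytovar.synth.config import FRACTION_MEAN, MONO_CONC_MEAN
from cytovar.synth.simulate import _draw_cohort_concentrations, sequential_design


class TestCalibration:
    def test_calibration_identity(self, wt_config):
        """cov_s = printed_mean_s - frac_s * E[T]; classical must come out +9.84."""
        et = wt_config.total_mono_mean
        assert et == 240.0
        cov_classical = MONO_CONC_MEAN["classical_mono"] - FRACTION_MEAN["classical_mono"] * et
        assert cov_classical == pytest.approx(9.84, abs=1e-9)
        assert wt_config.intermediate_mean == pytest.approx(et - 135.6 - 86.1)
        # rho encodes exactly that covariance
        sigma_t = np.sqrt(np.log1p(wt_config.total_mono_cv**2))
        back = (
            wt_config.mono_rho["classical_mono"]
            * wt_config.fraction_sd["classical_mono"]
            * et
            * sigma_t
        )
        assert back == pytest.approx(cov_classical, rel=1e-12)

    def test_monte_carlo_moments(self, wt_config):
        """1e5 animals reproduce both printed constraint sets within 3 SE."""
        n = 100_000
        conc = _draw_cohort_concentrations(wt_config, n, np.random.default_rng(7))
        total = sum(conc[s] for s in MONO_SUBSETS)
        for s, printed in (("classical_mono", 135.6), ("nonclassical_mono", 86.1)):
            se = conc[s].std() / np.sqrt(n)
            assert abs(conc[s].mean() - printed) < 3 * se
        for s, frac in FRACTION_MEAN.items():
            f = conc[s] / total
            assert abs(f.mean() - frac) < 3 * f.std() / np.sqrt(n)

    def test_law_of_large_numbers_neutrophils(self, wt_config):
        conc = _draw_cohort_concentrations(wt_config, 100_000, np.random.default_rng(11))
        v = conc["neutrophil"]
        assert v.mean() == pytest.approx(654.2, rel=0.01)
        assert v.std() / v.mean() == pytest.approx(0.858, rel=0.02)

    def test_classical_drives_monocytosis(self, wt_config):
        """Total monocyte numbers track the classical subset more than the non-classical."""
        conc = _draw_cohort_concentrations(wt_config, 10_000, np.random.default_rng(3))
        total = sum(conc[s] for s in MONO_SUBSETS)
        r_cl = np.corrcoef(conc["classical_mono"], total)[0, 1]
        r_nc = np.corrcoef(conc["nonclassical_mono"], total)[0, 1]
        assert r_cl > r_nc

    def test_degenerate_zero_cv(self):
        """With all variances zero the preset is feasible only if means line up."""
        et = 240.0
        consistent = GeneratorConfig(
            cohort_cv={k: 0.0 for k in wt_cohort_preset().cohort_cv},
            mono_conc_mean={
                "classical_mono": FRACTION_MEAN["classical_mono"] * et,
                "nonclassical_mono": FRACTION_MEAN["nonclassical_mono"] * et,
            },
            fraction_sd={k: 0.0 for k in FRACTION_MEAN},
            total_mono_cv=0.0,
        )
        cfg = calibrate_cohort_preset(consistent)
        animals = sample_cohort_params(cfg, 5, np.random.default_rng(0))
        first = animals[0].concentrations
        for a in animals[1:]:
            assert a.concentrations == first  # every animal identical to the mean vector

        inconsistent = GeneratorConfig(
            fraction_sd={k: 0.0 for k in FRACTION_MEAN},
        )  # printed means imply non-zero covariance
        with pytest.raises(CalibrationError):
            calibrate_cohort_preset(inconsistent)

    def test_infeasible_correlation_names_subset(self):
        cfg = GeneratorConfig(
            fraction_sd={
                "classical_mono": 1e-4,
                "nonclassical_mono": 1e-4,
                "intermediate_mono": 1e-4,
            }
        )
        with pytest.raises(CalibrationError, match="classical_mono"):
            calibrate_cohort_preset(cfg)

    def test_subsets_sum_to_total(self, wt_config, rng):
        animal = sample_animal_params(wt_config, rng)
        total = sum(animal.concentrations[s] for s in MONO_SUBSETS)
        assert animal.total_monocytes == pytest.approx(total, rel=1e-12)


class TestSampleSimulation:
    def test_poisson_event_counts(self, noiseless_config):
        """conc 100 cells/ul x 20 ul at f=1 -> 2000 expected events of that population."""
        cfg = noiseless_config.copy(acquisition_fraction=1.0)
        from cytovar.synth.config import AnimalParams

        conc = {p: 0.0 for p in LEUKOCYTE_SUBSETS}
        conc["neutrophil"] = 100.0
        animal = AnimalParams("a0", conc)
        rng = np.random.default_rng(5)
        counts = [
            np.count_nonzero(
                simulate_sample(animal, 20.0, cfg, rng).labels == LABEL_CODE["neutrophil"]
            )
            for _ in range(20)
        ]
        # mean of 20 Poisson(2000) draws: SE = sqrt(2000/20) = 10
        assert abs(np.mean(counts) - 2000) < 4 * np.sqrt(2000 / 20)

    def test_acquisition_fraction_thins_cells_and_beads(self, noiseless_config, rng):
        animal = sample_animal_params(noiseless_config, rng)
        full = noiseless_config.copy(acquisition_fraction=1.0)
        half = noiseless_config.copy(acquisition_fraction=0.5)
        n_full = [simulate_sample(animal, 20.0, full, rng).meta["true_counts"] for _ in range(5)]
        n_half = [simulate_sample(animal, 20.0, half, rng).meta["true_counts"] for _ in range(5)]
        for pop in ("lymphocyte", "bead"):
            a = np.mean([c[pop] for c in n_full])
            b = np.mean([c[pop] for c in n_half])
            assert b == pytest.approx(a / 2, rel=0.1)

    def test_zero_spread_identity_spillover_yields_template_medians(self, noiseless_config, rng):
        cfg = noiseless_config.copy(spillover=np.eye(6))
        animal = sample_animal_params(cfg, rng)
        events = simulate_sample(animal, 20.0, cfg, rng)
        for pop in LEUKOCYTE_SUBSETS:
            mask = events.labels == LABEL_CODE[pop]
            if not mask.any():
                continue
            expected = [cfg.templates[pop].medians[ch] for ch in events.channels]
            assert np.allclose(events.data[mask], expected)

    def test_bad_volume_rejected(self, wt_config, rng):
        animal = sample_animal_params(wt_config, rng)
        with pytest.raises(ValueError):
            simulate_sample(animal, 0.0, wt_config, rng)


class TestDuplicates:
    def test_pair_shares_truth_and_technical_noise_is_off_when_zero(self, noiseless_config, rng):
        """tau = 0 at high counts: duplicate counts differ only by Poisson noise."""
        animal = sample_animal_params(noiseless_config, rng)
        (a, b), = simulate_duplicates(animal, 1, noiseless_config, rng)
        na = a.meta["true_counts"]["lymphocyte"]
        nb = b.meta["true_counts"]["lymphocyte"]
        lam = animal.concentrations["lymphocyte"] * 20.0 * 0.2
        assert abs(na - nb) < 6 * np.sqrt(2 * lam)

    def test_invalid_pair_count(self, wt_config, rng):
        animal = sample_animal_params(wt_config, rng)
        with pytest.raises(ValueError):
            simulate_duplicates(animal, 0, wt_config, rng)


class TestSingleStainControls:
    def test_identity_spillover_controls_flat_off_channel(self, wt_config, rng):
        cfg = wt_config.copy(spillover=np.eye(6))
        controls = simulate_single_stain_controls(cfg, rng)
        for control in controls:
            npos = control.meta["n_positive"]
            primary = control.meta["control_channel"]
            for ch in ("CD43", "Lin", "MHCII", "F480", "CD11b", "Ly6C"):
                if ch == primary:
                    continue
                pos_med = np.median(control.column(ch)[:npos])
                neg_med = np.median(control.column(ch)[npos:])
                assert pos_med == pytest.approx(neg_med, rel=0.05)

    def test_configured_spillover_shifts_off_channel_median(self, wt_config, rng):
        s = np.eye(6)
        s[0, 1] = 0.10  # 10% of CD43 signal into the Lin detector
        cfg = wt_config.copy(spillover=s)
        control = simulate_single_stain_controls(cfg, rng)[0]
        npos = control.meta["n_positive"]
        assert control.meta["control_channel"] == "CD43"
        shift = np.median(control.column("Lin")[:npos]) - np.median(control.column("Lin")[npos:])
        signal = np.median(control.column("CD43")[:npos]) - np.median(control.column("CD43")[npos:])
        assert shift / signal == pytest.approx(0.10, abs=0.02)


class TestKinetics:
    def test_anchor_validation(self):
        anchors = default_anchors()
        assert anchors.multiplier_at("CTRL", "classical_mono", 10.0) == 1.0
        assert anchors.multiplier_at("MI", "classical_mono", 0.0) == 1.0
        with pytest.raises(ValueError):
            anchors.multiplier_at("MI", "classical_mono", 30.0)
        with pytest.raises(KeyError):
            anchors.multiplier_at("KO", "classical_mono", 1.0)
        bad = {"MI": {"classical_mono": (0.9, 1, 1, 1, 1, 1, 1)}}
        with pytest.raises(ValueError):
            KineticsAnchors(multiplier=bad)

    def test_early_dip_hits_nonclassical_and_eosinophils(self):
        anchors = default_anchors()
        for subset in ("nonclassical_mono", "eosinophil"):
            assert anchors.multiplier_at("MI", subset, 1.0) < 1.0
        assert anchors.multiplier_at("MI", "nonclassical_mono", 1.0) <= 0.5

    def test_mi_and_sham_share_anchors(self):
        anchors = default_anchors()
        assert anchors.multiplier["MI"] == anchors.multiplier["SHAM"]
        assert anchors.dispersion["MI"] == anchors.dispersion["SHAM"]


class TestTimecourse:
    def test_ctrl_counts_constant_up_to_poisson(self, noiseless_config):
        """Non-operated controls: repeated sampling leaves counts at baseline."""
        design = StudyDesign(groups={"CTRL": 3}, days=(0, 2, 5), mode="sequential")
        acqs = simulate_timecourse(design, noiseless_config, np.random.default_rng(2))
        by_animal: dict = {}
        for ev in acqs:
            by_animal.setdefault(ev.meta["animal_id"], []).append(
                ev.meta["true_counts"]["lymphocyte"]
            )
        for counts in by_animal.values():
            lam = np.mean(counts)
            assert np.ptp(counts) < 8 * np.sqrt(lam)

    def test_sequential_tracks_animals_cross_sectional_does_not(self, fast_config):
        """Within-animal day-to-day correlation exists only in sequential mode."""
        def day_corr(mode, seed):
            design = StudyDesign(groups={"MI": 30}, days=(2, 3), mode=mode)
            if mode == "sequential":
                design = StudyDesign(groups={"MI": 30}, days=(0, 2, 3), mode=mode)
            acqs = simulate_timecourse(design, fast_config, np.random.default_rng(seed))
            d2 = [e.meta["true_counts"]["classical_mono"] for e in acqs if e.meta["day"] == 2]
            d3 = [e.meta["true_counts"]["classical_mono"] for e in acqs if e.meta["day"] == 3]
            return np.corrcoef(d2, d3)[0, 1]

        assert day_corr("sequential", 4) > 0.5
        assert abs(day_corr("cross-sectional", 4)) < 0.45

    def test_unknown_group_and_day_rejected(self, fast_config, rng):
        with pytest.raises(KeyError):
            simulate_timecourse(
                StudyDesign(groups={"KO": 2}, days=(0,)), fast_config, rng
            )
        with pytest.raises(ValueError):
            simulate_timecourse(
                StudyDesign(groups={"MI": 2}, days=(0, 28)), fast_config, rng
            )

    def test_sequential_design_defaults(self):
        d = sequential_design()
        assert d.groups == {"MI": 15, "SHAM": 7, "CTRL": 4}
        assert d.days == (0, 1, 2, 3, 4, 5, 6, 7, 14, 21)
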