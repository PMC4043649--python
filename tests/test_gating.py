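"""Gate placement, bead identification, and the sequential classification hierarchy."""

import numpy as np
import pytest

from cytovar.events import EventTable
from cytovar.gating import (
    boolean_combine,
    classify_events,
    derive_gates,
    identify_beads,
    interval_gate,
    kde_valley_cut,
    label_counts,
    template_midpoint_gates,
)
from cytovar.panel import CHANNELS, LABEL_CODE, MONO_SUBSETS, SUBSET_LABELS
from cytovar.preprocess import biexp_inverse, biexp_transform, compensate
from cytovar.synth import sample_animal_params, simulate_sample


def _event(config, **channel_values):
    """Single uncompensated=already-true event at given raw channel intensities."""
    row = np.full(len(CHANNELS), 50.0)
    for ch, v in channel_values.items():
        row[CHANNELS.index(ch)] = v
    return EventTable(data=row[None, :], compensated=True)


@pytest.fixture(scope="module")
def gates(wt_config):
    return template_midpoint_gates(wt_config)


@pytest.fixture(scope="module")
def classified_noiseless(noiseless_config):
    rng = np.random.default_rng(42)
    animal = sample_animal_params(noiseless_config, rng)
    events = simulate_sample(animal, 20.0, noiseless_config, rng)
    comp = compensate(events, noiseless_config.spillover)
    gates = template_midpoint_gates(noiseless_config)
    return comp, classify_events(comp, gates)


class TestBeads:
    def test_all_beads_flagged_on_noiseless_fixture(self, classified_noiseless, noiseless_config):
        comp, _ = classified_noiseless
        mask = identify_beads(comp, template_midpoint_gates(noiseless_config))
        truth = comp.labels == LABEL_CODE["bead"]
        assert np.array_equal(mask, truth)

    def test_no_beads_no_exception(self, gates):
        table = EventTable(data=np.full((10, len(CHANNELS)), 100.0), compensated=True)
        assert identify_beads(table, gates).sum() == 0

    def test_flag_rate_order_invariant(self, classified_noiseless, noiseless_config, rng):
        comp, _ = classified_noiseless
        gates = template_midpoint_gates(noiseless_config)
        perm = rng.permutation(comp.n_events)
        shuffled = EventTable(data=comp.data[perm], compensated=True)
        assert identify_beads(shuffled, gates).sum() == identify_beads(comp, gates).sum()


class TestDeriveGates:
    def test_config_mode_returns_template_midpoints_verbatim(self, wt_config):
        assert derive_gates(None, wt_config) == template_midpoint_gates(wt_config)

    def test_kde_valley_between_constructed_modes(self):
        """Two modes at transformed positions 1.0 and 3.0: the cut falls between."""
        rng = np.random.default_rng(1)
        transformed = np.concatenate(
            [rng.normal(1.0, 0.15, 3000), rng.normal(3.0, 0.15, 3000)]
        )
        cut = kde_valley_cut(transformed)
        assert 1.5 < cut < 2.5

    def test_unimodal_falls_back(self):
        rng = np.random.default_rng(2)
        values = rng.normal(2.0, 0.1, 2000)
        assert kde_valley_cut(values, fallback=7.5) == 7.5
        with pytest.raises(ValueError):
            kde_valley_cut(values)

    def test_data_driven_deterministic(self, fast_config):
        rng = np.random.default_rng(3)
        animal = sample_animal_params(fast_config, rng)
        events = compensate(
            simulate_sample(animal, 20.0, fast_config, rng), fast_config.spillover
        )
        g1 = derive_gates(events, fast_config, data_driven=True)
        g2 = derive_gates(events, fast_config, data_driven=True)
        assert g1 == g2

    def test_data_driven_needs_events(self, fast_config):
        tiny = EventTable(data=np.full((10, len(CHANNELS)), 100.0), compensated=True)
        with pytest.raises(ValueError):
            derive_gates(tiny, fast_config, data_driven=True)


class TestClassification:
    def test_classical_monocyte_definition(self, wt_config, gates):
        ev = _event(
            wt_config, SSC=9000, Lin=120, CD11b=6000, MHCII=80, Ly6C=10000, CD43=250
        )
        assert classify_events(ev, gates)[0] == LABEL_CODE["classical_mono"]

    @pytest.mark.parametrize(
        "channels,expected",
        [
            (dict(SSC=45000, Lin=9000, CD11b=5000, F480=60), "neutrophil"),
            (dict(SSC=40000, Lin=120, CD11b=5000, F480=2000), "eosinophil"),
            (dict(SSC=9000, Lin=120, CD11b=6000, MHCII=80, Ly6C=2200, CD43=1500),
             "intermediate_mono"),
            (dict(SSC=9000, Lin=120, CD11b=6000, MHCII=80, Ly6C=400, CD43=8000),
             "nonclassical_mono"),
            (dict(SSC=9000, Lin=120, CD11b=6000, MHCII=6000, Ly6C=700, CD43=8000),
             "activated_monomac"),
            (dict(SSC=6000, Lin=7000, CD11b=90), "lymphocyte"),
            (dict(SSC=9000, Lin=120, CD11b=90), "ungated"),
        ],
    )
    def test_phenotype_definitions(self, wt_config, gates, channels, expected):
        ev = _event(wt_config, **channels)
        assert SUBSET_LABELS[classify_events(ev, gates)[0]] == expected

    def test_event_on_cut_goes_to_upper_side(self, wt_config, gates):
        """Half-open convention: an event exactly on the Ly6C-high cut is classical."""
        ly6c_cut_raw = biexp_inverse(gates.ly6c_hi_cut, gates.cofactor)
        ev = _event(
            wt_config, SSC=9000, Lin=120, CD11b=6000, MHCII=80,
            Ly6C=float(ly6c_cut_raw), CD43=250,
        )
        assert classify_events(ev, gates)[0] == LABEL_CODE["classical_mono"]

    def test_noiseless_sample_matches_ground_truth(self, classified_noiseless):
        comp, labels = classified_noiseless
        agreement = np.mean(labels == comp.labels)
        assert agreement >= 0.999

    def test_default_noise_misclassification_below_1pct(self, wt_config):
        rng = np.random.default_rng(9)
        cfg = wt_config.copy(acquisition_fraction=0.25)
        animal = sample_animal_params(cfg, rng)
        comp = compensate(simulate_sample(animal, 50.0, cfg, rng), cfg.spillover)
        labels = classify_events(comp, template_midpoint_gates(cfg))
        for pop in ("neutrophil", "eosinophil", "lymphocyte", *MONO_SUBSETS):
            truth = comp.labels == LABEL_CODE[pop]
            if truth.sum() < 200:
                continue
            assert np.mean(labels[truth] == LABEL_CODE[pop]) > 0.99, pop

    def test_labels_partition_events(self, classified_noiseless):
        comp, labels = classified_noiseless
        counts = label_counts(labels)
        assert sum(counts.values()) == comp.n_events
        # ground-truth monocytes all end up in exactly one of the three subset bins
        truth_mono = np.isin(comp.labels, [LABEL_CODE[s] for s in MONO_SUBSETS])
        assigned = np.isin(labels, [LABEL_CODE[s] for s in MONO_SUBSETS])
        assert np.array_equal(truth_mono, assigned)

    def test_classification_order_invariant(self, classified_noiseless, noiseless_config, rng):
        comp, labels = classified_noiseless
        perm = rng.permutation(comp.n_events)
        shuffled = EventTable(data=comp.data[perm], compensated=True)
        relabeled = classify_events(shuffled, template_midpoint_gates(noiseless_config))
        assert np.array_equal(relabeled, labels[perm])

    def test_unordered_cuts_rejected(self, gates):
        import dataclasses

        with pytest.raises(ValueError):
            dataclasses.replace(gates, ly6c_lo_cut=gates.ly6c_hi_cut + 1.0)


class TestBooleanCombine:
    def test_and_equals_set_intersection(self, fast_config, rng):
        animal = sample_animal_params(fast_config, rng)
        events = compensate(
            simulate_sample(animal, 20.0, fast_config, rng), fast_config.spillover
        )
        g = template_midpoint_gates(fast_config)
        ly6c = interval_gate("Ly6C", g.ly6c_lo_cut, g.ly6c_hi_cut, g.cofactor)
        cd43 = interval_gate("CD43", g.cd43_lo_cut, g.cd43_hi_cut, g.cofactor)
        combined = boolean_combine([ly6c, cd43])(events)
        brute = np.array(
            [bool(a and b) for a, b in zip(ly6c(events), cd43(events))]
        )
        assert np.array_equal(combined, brute)
        # commutative
        assert np.array_equal(combined, boolean_combine([cd43, ly6c])(events))

    def test_always_true_and_empty(self, fast_config, rng):
        animal = sample_animal_params(fast_config, rng)
        events = simulate_sample(animal, 20.0, fast_config, rng)
        always = interval_gate("Ly6C")  # (-inf, inf)
        assert boolean_combine([always, always])(events).all()
        with pytest.raises(ValueError):
            boolean_combine([])
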