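"""Generator contracts: determinism, truth-label recovery, dose-response."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytosynth.io_core import ChannelDef
from cytosynth import synthetic_data as sd


def _one_pop_design(medians, n=1000, seed=0, **kw):
    panel = [ChannelDef(name, kind="biosynthesis") for name in medians]
    pop = sd.PopulationSpec(name="p", frequency=1.0, channel_medians=dict(medians))
    return sd.ExperimentDesign(panel=panel, populations=[pop], n_events=n, seed=seed, **kw)


def test_same_seed_same_table():
    design = sd.make_scenario("cellcycle", seed=9, n_events=3000)
    a = sd.simulate_experiment(design, seed=5)
    b = sd.simulate_experiment(design, seed=5)
    np.testing.assert_array_equal(a.values, b.values)
    assert a.labels.equals(b.labels)


def test_all_zero_medians_give_all_zero_table():
    t = sd.simulate_events(_one_pop_design({"BRU": 0.0, "IdU": 0.0}, n=500))
    assert t.values.max() == 0


def test_population_frequencies_recovered():
    panel = [ChannelDef("CD45", kind="phenotype")]
    pops = [
        sd.PopulationSpec(name=n, frequency=f, channel_medians={"CD45": m})
        for n, f, m in [("a", 0.5, 10), ("b", 0.3, 100), ("c", 0.2, 1000)]
    ]
    design = sd.ExperimentDesign(panel=panel, populations=pops, n_events=50_000, seed=2)
    t = sd.simulate_events(design)
    freqs = t.labels["population"].value_counts(normalize=True)
    for name, expected in [("a", 0.5), ("b", 0.3), ("c", 0.2)]:
        assert abs(freqs[name] - expected) < 0.01


def test_frequencies_must_sum_to_one():
    panel = [ChannelDef("CD45")]
    pops = [sd.PopulationSpec(name="a", frequency=0.6, channel_medians={})]
    with pytest.raises(ValueError, match="sum"):
        sd.ExperimentDesign(panel=panel, populations=pops)


class TestInhibitor:
    @pytest.mark.parametrize(
        "dose,ic50,hill,floor,expected",
        [
            (0.0, 1.0, 1.0, 0.0, 100.0),  # no dose, baseline unchanged
            (1e9, 1.0, 1.0, 0.25, 25.0),  # saturating dose hits the floor
            (1.0, 1.0, 1.0, 0.0, 50.0),  # dose = ic50 halves the median
        ],
    )
    def test_hill_closed_forms(self, dose, ic50, hill, floor, expected):
        model = sd.InhibitorModel("BRU", ic50=ic50, hill=hill, floor=floor)
        out = sd.apply_inhibitor({"BRU": 100.0}, model, dose)
        assert out["BRU"] == pytest.approx(expected, rel=1e-6)

    def test_negative_dose_rejected(self):
        model = sd.InhibitorModel("BRU", ic50=1.0)
        with pytest.raises(ValueError):
            sd.apply_inhibitor({"BRU": 100.0}, model, -1.0)

    def test_secondary_targets_use_own_parameters(self):
        model = sd.InhibitorModel(
            "Puromycin", ic50=1.0, secondary_targets={"BRU": (10.0, 1.0, 0.5)}
        )
        out = sd.apply_inhibitor({"Puromycin": 100.0, "BRU": 100.0, "IdU": 40.0}, model, 10.0)
        assert out["Puromycin"] == pytest.approx(100 / 11)
        assert out["BRU"] == pytest.approx(100 * (0.5 + 0.5 / 2))
        assert out["IdU"] == 40.0  # untargeted channel untouched

    @settings(max_examples=30, deadline=None)
    @given(
        doses=st.lists(st.floats(0, 1e4), min_size=2, max_size=6),
        hill=st.floats(0.5, 4),
        floor=st.floats(0, 1),
    )
    def test_monotone_nonincreasing_in_dose(self, doses, hill, floor):
        model = sd.InhibitorModel("BRU", ic50=3.0, hill=hill, floor=floor)
        meds = [sd.apply_inhibitor({"BRU": 200.0}, model, d)["BRU"] for d in sorted(doses)]
        assert all(a >= b - 1e-9 for a, b in zip(meds, meds[1:]))


class TestCellCycle:
    def test_pure_g0g1_population(self):
        design = sd.make_scenario("cellcycle", seed=0)
        spec = design.populations[0]
        spec.phase_profile["fractions"] = {"G0G1": 1.0, "S": 0, "G2": 0, "M_early": 0, "M_late": 0}
        t = sd.simulate_cell_cycle(spec, design.panel, n=2000, seed=1)
        assert (t.labels["phase"] == "G0G1").all()
        assert np.median(t.column("CyclinB1")) < 20  # CyclinB1-low
        assert np.median(t.column("IdU")) <= 2  # background DNA synthesis

    def test_mitotic_fraction_binomial_bound(self):
        design = sd.make_scenario("cellcycle", seed=0, m_fraction=0.02)
        t = sd.simulate_cell_cycle(design.populations[0], design.panel, n=100_000, seed=3)
        n_mitotic = t.labels["phase"].isin(["M_early", "M_late"]).sum()
        assert abs(n_mitotic - 2000) <= 150

    def test_configured_m_g2_bru_ratio_recovered(self):
        design = sd.make_scenario("cellcycle", seed=0, m_bru_ratio=0.3)
        t = sd.simulate_cell_cycle(design.populations[0], design.panel, n=100_000, seed=4)
        phases = t.labels["phase"]
        bru = t.column("BRU")
        ratio = np.median(bru[phases.isin(["M_early", "M_late"])]) / np.median(
            bru[phases == "G2"]
        )
        assert abs(ratio - 0.3) < 0.05

    def test_phase_fractions_validated(self):
        with pytest.raises(ValueError, match="phase fractions"):
            sd.PopulationSpec(
                name="x",
                frequency=1.0,
                phase_profile={"fractions": {"G0G1": 0.5, "S": 0.1}},
            )


class TestBarcoding:
    def _tables(self, n_samples, n_each, seed=0):
        design = _one_pop_design({"BRU": 100.0}, n=n_each)
        return [
            sd.simulate_events(design, seed=seed + i, sample_name=f"s{i}")
            for i in range(n_samples)
        ]

    def test_single_sample_no_doublets_is_identity_plus_barcodes(self):
        (t,) = self._tables(1, 200)
        scheme = sd.BarcodeScheme.default_3_of_6(doublet_rate=0.0)
        pooled = sd.pool_with_barcodes([t], scheme, seed=1)
        assert pooled.n_events == 200
        order = np.argsort(pooled.labels.index)  # pooling shuffles; values preserved
        np.testing.assert_array_equal(
            np.sort(pooled.columns(["BRU"]).ravel()), np.sort(t.column("BRU"))
        )
        high = pooled.columns([scheme.channels[j] for j in scheme.keys[0]])
        assert (high > 50).all()

    def test_pooled_sample_sizes_exact(self):
        tables = self._tables(10, 1000)
        scheme = sd.BarcodeScheme.default_3_of_6(doublet_rate=0.0)
        pooled = sd.pool_with_barcodes(tables, scheme, seed=2)
        assert pooled.n_events == 10_000
        sizes = pooled.labels["barcode_id"].value_counts()
        assert (sizes == 1000).all()

    def test_doublet_count_binomial_bound(self):
        tables = self._tables(10, 2000)
        scheme = sd.BarcodeScheme.default_3_of_6(doublet_rate=0.05)
        pooled = sd.pool_with_barcodes(tables, scheme, seed=3)
        n_doublets = int(pooled.labels["doublet"].sum())
        assert abs(n_doublets - 1000) <= 120

    def test_more_samples_than_keys_rejected(self):
        tables = self._tables(2, 10)
        scheme = sd.BarcodeScheme(channels=["a", "b", "c"], keys=[(0, 1)])
        with pytest.raises(ValueError, match="keys"):
            sd.pool_with_barcodes(tables, scheme, seed=0)


class TestSpillover:
    def test_zero_fraction_unchanged(self):
        t = sd.simulate_events(_one_pop_design({"BRU": 500.0, "Puromycin": 100.0}, n=500))
        out = sd.inject_spillover(t, [("BRU", "Puromycin", 0.0)], seed=1)
        np.testing.assert_array_equal(out.values, t.values)

    def test_zero_source_leaves_destination(self):
        t = sd.simulate_events(_one_pop_design({"BRU": 0.0, "Puromycin": 100.0}, n=500))
        out = sd.inject_spillover(t, [("BRU", "Puromycin", 0.1)], seed=1)
        np.testing.assert_array_equal(out.values, t.values)

    def test_mean_increment_matches_poisson_mean(self):
        design = _one_pop_design({"BRU": 500.0, "Puromycin": 0.0}, n=50_000, seed=5)
        design.populations[0].channel_spreads = {"BRU": 0.1}
        t = sd.simulate_events(design)
        out = sd.inject_spillover(t, [("BRU", "Puromycin", 0.02)], seed=6)
        increment = (out.column("Puromycin") - t.column("Puromycin")).mean()
        expected = 0.02 * t.column("BRU").mean()
        assert abs(increment - expected) < 1.0
        np.testing.assert_array_equal(out.column("BRU"), t.column("BRU"))


class TestScenarios:
    def test_make_scenario_deterministic(self):
        assert sd.make_scenario("pbmc_timecourse", seed=4) == sd.make_scenario(
            "pbmc_timecourse", seed=4
        )

    def test_unknown_scenario_names_valid_ones(self):
        with pytest.raises(ValueError, match="cellcycle"):
            sd.make_scenario("nope")

    def test_pbmc_has_six_timepoints_with_quiet_phenotypes_at_t0(self):
        design = sd.make_scenario("pbmc_timecourse", seed=0)
        assert len(design.samples) == 6
        assert design.samples[0].channel_multipliers == {}
        for s in design.samples:  # phenotype markers never modulated
            assert not set(s.channel_multipliers) & {"CD3", "CD4", "CD19", "CD14", "CD56"}

    def test_marrow_plasma_cells_high_protein_low_rna(self):
        design = sd.make_scenario("marrow_hierarchy", seed=0)
        by_name = {p.name: p for p in design.populations}
        plasma, hsc = by_name["Plasma"], by_name["HSC"]
        assert plasma.channel_medians["BRU"] <= 5  # background de novo RNA
        assert plasma.channel_medians["Puromycin"] >= hsc.channel_medians["Puromycin"]
        assert len(design.populations) >= 12
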