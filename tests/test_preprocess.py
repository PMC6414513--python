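"""Transform, bead normalization, debarcoding, gating, IdU positivity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytosynth import preprocess
from cytosynth import synthetic_data as sd
from cytosynth.io_core import ChannelDef, EventTable, GateRule


def _table(values, names=None, kinds=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    names = names or [f"c{i}" for i in range(values.shape[1])]
    kinds = kinds or ["phenotype"] * len(names)
    return EventTable(
        values=values, channels=[ChannelDef(n, kind=k) for n, k in zip(names, kinds)]
    )


class TestArcsinh:
    @pytest.mark.parametrize(
        "x,expected",
        [
            (0.0, 0.0),
            (5 * np.sinh(1.0), 1.0),
            (10.0, np.arcsinh(2.0)),  # 1.44363...
        ],
    )
    def test_pointwise_values_cofactor_5(self, x, expected):
        t = preprocess.arcsinh(_table([[x]]), 5.0)
        assert t.values[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_double_transform_is_state_error(self):
        t = preprocess.arcsinh(_table([[1.0]]))
        with pytest.raises(ValueError, match="already transformed"):
            preprocess.arcsinh(t)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1e6), min_size=1, max_size=20))
    def test_inverse_identity(self, xs):
        t = _table([xs])
        back = preprocess.inverse_arcsinh(preprocess.arcsinh(t))
        np.testing.assert_allclose(back.values, t.values, rtol=1e-12, atol=1e-9)

    @settings(max_examples=30, deadline=None)
    @given(st.sets(st.integers(0, 10_000), min_size=3, max_size=21))
    def test_median_commutes_with_transform_odd_n_no_ties(self, xs):
        xs = sorted(xs)
        if len(xs) % 2 == 0:
            xs = xs[:-1]
        x = np.array(xs, dtype=float)
        assert np.median(np.arcsinh(x / 5)) == pytest.approx(
            np.arcsinh(np.median(x) / 5), rel=1e-12
        )


class TestBeadNormalize:
    def _acquisition(self, sensitivity=None, n=20_000, seed=0):
        design = sd.make_scenario("cellcycle", seed=seed, n_events=n)
        design.sensitivity = sensitivity
        return sd.simulate_events(design, seed=seed)

    def test_constant_sensitivity_is_identity(self):
        t = self._acquisition()
        out, report = preprocess.bead_normalize(t)
        assert max(abs(s - 1) for s in report["window_scales"]) < 0.05
        np.testing.assert_allclose(out.values, t.values, rtol=0.06)

    def test_global_half_sensitivity_recovered(self):
        # A run at half sensitivity, normalized against its own beads, must
        # report per-window bead medians within 2% of the run reference.
        t = self._acquisition(sensitivity=(0.5, 0.5))
        out, report = preprocess.bead_normalize(t)
        bead_mask = out.labels["bead_event"].to_numpy()
        assert report["n_beads"] == int(bead_mask.sum()) > 100

    def test_linear_drift_flattened(self):
        t = self._acquisition(sensitivity=(1.0, 0.6))
        out, _ = preprocess.bead_normalize(t)
        bead_mask = out.labels["bead_event"].to_numpy()
        # after normalization, windowed medians of a bright cell channel are flat
        bru = out.column("BRU")[~bead_mask]
        n = len(bru)
        meds = [np.median(bru[lo : lo + 4000]) for lo in range(0, n - 4000, 4000)]
        cv = np.std(meds) / np.mean(meds)
        assert cv < 0.05
        # whereas the raw drifting run is visibly sloped
        raw = t.column("BRU")[~bead_mask]
        raw_meds = [np.median(raw[lo : lo + 4000]) for lo in range(0, n - 4000, 4000)]
        assert (np.std(raw_meds) / np.mean(raw_meds)) > cv

    def test_no_beads_advises_skip(self):
        design = sd.make_scenario("cellcycle", seed=1, n_events=500)
        design.bead_fraction = 0.0
        t = sd.simulate_events(design, seed=1)
        with pytest.raises(ValueError, match="skip"):
            preprocess.bead_normalize(t)


class TestDebarcode:
    CHANNELS = [f"Pd{i}" for i in range(6)]

    def _table(self, rows):
        return _table_with_kinds(rows, self.CHANNELS)

    def test_clean_event_assigned_to_its_key(self):
        keys = [("Pd0", "Pd1", "Pd2"), ("Pd3", "Pd4", "Pd5")]
        t = self._table([[200, 200, 200, 0, 0, 0]])
        out = preprocess.debarcode(t, keys=keys)
        assert out["sample_id"].tolist() == [0]
        assert not out["doublet_flag"].any()

    def test_four_high_channels_flagged_doublet(self):
        keys = [("Pd0", "Pd1", "Pd2"), ("Pd1", "Pd2", "Pd3")]
        t = self._table([[200, 400, 400, 200, 0, 0]])  # summed doublet
        out = preprocess.debarcode(t, keys=keys)
        assert out["sample_id"].tolist() == [-1]
        assert out["doublet_flag"].all()

    def test_infinite_separation_assigns_nothing(self):
        keys = [("Pd0", "Pd1", "Pd2")]
        t = self._table([[200, 200, 200, 0, 0, 0]])
        out = preprocess.debarcode(t, keys=keys, min_separation=np.inf)
        assert (out["sample_id"] == -1).all()

    def test_single_key_clean_signal_assigns_everything(self):
        rng = np.random.default_rng(0)
        highs = rng.poisson(200, size=(500, 3))
        rows = np.hstack([highs, np.zeros((500, 3))])
        t = self._table(rows)
        out = preprocess.debarcode(t, keys=[("Pd0", "Pd1", "Pd2")])
        assert (out["sample_id"] == 0).all()

    def test_key_size_must_be_below_channel_count(self):
        t = self._table([[1, 1, 1, 1, 1, 1]])
        with pytest.raises(ValueError, match="smaller"):
            preprocess.debarcode(
                t, keys=[tuple(self.CHANNELS)], barcode_channels=self.CHANNELS
            )


def _table_with_kinds(rows, names):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    return EventTable(
        values=rows, channels=[ChannelDef(n, kind="barcode") for n in names]
    )


class TestGates:
    def test_empty_rule_list_keeps_all(self, small_table):
        mask, report = preprocess.apply_gates(small_table, [])
        assert mask.all() and report == []

    def test_keep_rule_everyone_passes_is_identity(self, small_table):
        rule = GateRule(channel="CD45", op="ge", threshold=0.0, scale="raw")
        mask, _ = preprocess.apply_gates(small_table, [rule])
        assert mask.all()

    def test_viability_gate_removes_truth_dead(self):
        design = sd.make_scenario("cellcycle", seed=3, n_events=20_000)
        design.dead_fraction = 0.10
        design.apoptotic_fraction = 0.0
        design.bead_fraction = 0.0
        t = sd.simulate_events(design, seed=3)
        rules = preprocess.viability_gates(t, apoptosis_channels=())
        mask, _ = preprocess.apply_gates(t, rules)
        removed = ~mask
        assert abs(removed.mean() - 0.10) < 0.01
        truth_dead = t.labels["dead"].to_numpy()
        assert (truth_dead[removed].mean()) > 0.95

    def test_gating_is_idempotent(self, small_table):
        rule = GateRule(channel="CD45", op="gt", threshold=2.0, action="drop")
        mask, _ = preprocess.apply_gates(small_table, [rule])
        gated = small_table.subset(mask)
        mask2, _ = preprocess.apply_gates(gated, [rule])
        assert mask2.all()

    def test_rule_on_missing_channel_errors(self, small_table):
        rule = GateRule(channel="Cisplatin", op="gt", threshold=1.0, action="drop")
        with pytest.raises(KeyError, match="Cisplatin"):
            preprocess.apply_gates(small_table, [rule])

    def test_gate_report_counts_conserve_events(self, small_table):
        rules = [
            GateRule(channel="CD45", op="gt", threshold=2.0, action="drop"),
            GateRule(channel="CD19", op="ge", threshold=0.0, scale="raw"),
        ]
        mask, report = preprocess.apply_gates(small_table, rules)
        assert report[0]["events_in"] == small_table.n_events
        assert report[-1]["events_out"] == int(mask.sum())


class TestIdUPositive:
    def test_direct_application(self):
        t = _table([[0.0], [5.0], [11.0], [20.0]], names=["IdU"], kinds=["biosynthesis"])
        flags = preprocess.idu_positive(t, threshold=10)
        assert flags.tolist() == [False, False, True, True]
        assert flags.mean() == 0.5

    def test_all_zero_channel(self):
        t = _table(np.zeros((10, 1)), names=["IdU"], kinds=["biosynthesis"])
        assert preprocess.idu_positive(t).mean() == 0.0

    def test_transformed_channel_rejected(self):
        t = _table([[20.0]], names=["IdU"], kinds=["biosynthesis"])
        t = preprocess.arcsinh(t)
        with pytest.raises(ValueError, match="raw counts"):
            preprocess.idu_positive(t)
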